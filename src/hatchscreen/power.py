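"""Bootstrap sub-sampling sample-size determination.

To ask "how many replicate wells per condition are enough?", every
crosswise pair of independent screening plates is pooled (8 + 8 = 16
wells per condition), and from each pooled pair dataset k wells per
condition are repeatedly drawn *without* replacement and re-tested with
the full adaptive two-sample procedure.  The fraction of draws rejecting
the null at a given alpha estimates the rejection probability at that
sample size; the minimum sufficient well count is the smallest k whose
rejection probability reaches the criterion (default 99.5%) in every
pair dataset simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from collections.abc import Sequence

import numpy as np

from .data_model import CI_CONTROL, CI_TREATED, ScreenDataset
from .exceptions import DegenerateVarianceError, HatchScreenError
from .screen_stats import compare_conditions

DEFAULT_CRITERION = 0.995
DEFAULT_K_RANGE = tuple(range(3, 17))
DEFAULT_RESAMPLES = 2000
#: Bootstrap replicates used when a sub-sampled draw lands on the
#: bootstrap-t branch; 1000 gives ~0.001 p-value resolution, ample for
#: rejection decisions at alpha >= 0.01.
SUBSAMPLE_BOOT_REPS = 1000


@dataclass(frozen=True)
class PlatePair:
    """One crosswise pairing of plates, pooled per condition."""

    pair_id: str
    plate_ids: tuple[str, str]
    group_a: np.ndarray  # per-well rates, first condition (e.g. ci-control)
    group_b: np.ndarray  # per-well rates, second condition (e.g. ci-treated)


@dataclass(frozen=True)
class PowerCurve:
    """Rejection probability versus wells-per-condition.

    ``rejection_probability`` maps pair_id -> tuple aligned with
    ``wells_axis``.  ``min_sufficient_k`` is the smallest k meeting
    ``criterion`` in *every* pair dataset, or None if no swept k does.
    """

    alpha: float
    wells_axis: tuple[int, ...]
    rejection_probability: dict[str, tuple[float, ...]]
    n_resamples: int
    criterion: float
    min_sufficient_k: int | None

    def to_records(self) -> list[dict]:
        return [
            {"pair_id": pid, "k": k, "rejection_probability": p}
            for pid, probs in self.rejection_probability.items()
            for k, p in zip(self.wells_axis, probs)
        ]


def plate_pairs(
    plates: Sequence[ScreenDataset],
    conditions: tuple[str, str] = (CI_CONTROL, CI_TREATED),
) -> list[PlatePair]:
    """All unordered plate pairs, wells pooled per condition."""
    if len(plates) < 2:
        raise HatchScreenError(f"need >= 2 plates, got {len(plates)}")
    labelled = []
    for plate in plates:
        ids = plate.plate_ids()
        if len(ids) != 1:
            raise HatchScreenError("each element must be a single-plate dataset")
        labelled.append((ids[0], plate))
    pairs = []
    for (id_a, pa), (id_b, pb) in combinations(labelled, 2):
        group_a = np.concatenate([pa.per_well_rates(conditions[0]), pb.per_well_rates(conditions[0])])
        group_b = np.concatenate([pa.per_well_rates(conditions[1]), pb.per_well_rates(conditions[1])])
        pairs.append(
            PlatePair(
                pair_id=f"{id_a}x{id_b}",
                plate_ids=(id_a, id_b),
                group_a=group_a,
                group_b=group_b,
            )
        )
    return pairs


def subsample_pvalues(
    a: np.ndarray,
    b: np.ndarray,
    k: int,
    n_resamples: int,
    rng: np.random.Generator,
    boot_reps: int = SUBSAMPLE_BOOT_REPS,
) -> np.ndarray:
    """p-values of the adaptive test over repeated k-well sub-samples.

    Each resample draws k wells without replacement from each group and
    re-runs the full adaptive procedure (test re-selected per draw).  A
    draw with a zero-variance group carries no distributional signal and
    is recorded as p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if k > a.size or k > b.size:
        raise HatchScreenError(f"k={k} exceeds group sizes ({a.size}, {b.size})")
    out = np.empty(n_resamples)
    for i in range(n_resamples):
        sub_a = a[rng.choice(a.size, size=k, replace=False)]
        sub_b = b[rng.choice(b.size, size=k, replace=False)]
        try:
            out[i] = compare_conditions(sub_a, sub_b, boot_reps=boot_reps, seed=rng).p_value
        except DegenerateVarianceError:
            out[i] = 1.0
    return out


def rejection_probability(
    pooled_a,
    pooled_b,
    k: int,
    alpha: float,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int | np.random.Generator | None = None,
    boot_reps: int = SUBSAMPLE_BOOT_REPS,
) -> float:
    """Fraction of k-well sub-samples rejecting at `alpha`."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pvals = subsample_pvalues(
        np.asarray(pooled_a, float), np.asarray(pooled_b, float), k, n_resamples, rng, boot_reps
    )
    return float(np.mean(pvals < alpha))


def power_curves(
    plates: Sequence[ScreenDataset],
    alphas: Sequence[float] = (0.05,),
    criterion: float = DEFAULT_CRITERION,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int | np.random.Generator | None = None,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
    conditions: tuple[str, str] = (CI_CONTROL, CI_TREATED),
    boot_reps: int = SUBSAMPLE_BOOT_REPS,
) -> dict[float, PowerCurve]:
    """Power curves for several alphas from one shared set of sub-samples.

    The sub-sampled p-values are computed once per (pair, k) and judged
    against each alpha, so multi-alpha sweeps cost the same as one.
    Deterministic given (plates, seed, n_resamples): one child random
    stream per plate pair.
    """
    pairs = plate_pairs(plates, conditions=conditions)
    k_axis = tuple(int(k) for k in k_range)
    if isinstance(seed, np.random.Generator):
        pair_rngs = [seed for _ in pairs]
    else:
        pair_rngs = [
            np.random.default_rng(child)
            for child in np.random.SeedSequence(seed).spawn(len(pairs))
        ]
    # pvals[pair_id][j] = p-values for k_axis[j]
    rejection: dict[float, dict[str, list[float]]] = {a: {} for a in alphas}
    for pair, rng in zip(pairs, pair_rngs):
        for alpha in alphas:
            rejection[alpha][pair.pair_id] = []
        for k in k_axis:
            pvals = subsample_pvalues(pair.group_a, pair.group_b, k, n_resamples, rng, boot_reps)
            for alpha in alphas:
                rejection[alpha][pair.pair_id].append(float(np.mean(pvals < alpha)))
    curves = {}
    for alpha in alphas:
        probs = {pid: tuple(v) for pid, v in rejection[alpha].items()}
        min_k = None
        for j, k in enumerate(k_axis):
            if all(p[j] >= criterion for p in probs.values()):
                min_k = k
                break
        curves[alpha] = PowerCurve(
            alpha=float(alpha),
            wells_axis=k_axis,
            rejection_probability=probs,
            n_resamples=n_resamples,
            criterion=criterion,
            min_sufficient_k=min_k,
        )
    return curves


def min_sufficient_wells(
    plates: Sequence[ScreenDataset],
    alpha: float = 0.05,
    criterion: float = DEFAULT_CRITERION,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int | np.random.Generator | None = None,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
    boot_reps: int = SUBSAMPLE_BOOT_REPS,
) -> PowerCurve:
    """Sweep k ascending and find the minimum sufficient well count."""
    return power_curves(
        plates,
        alphas=(alpha,),
        criterion=criterion,
        n_resamples=n_resamples,
        seed=seed,
        k_range=k_range,
        boot_reps=boot_reps,
    )[alpha]
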