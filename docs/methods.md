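# Methods

## The screen and its readout

The assay quantifies cytoplasmic incompatibility (CI): uninfected
*Drosophila simulans* females crossed to *Wolbachia*-infected males lay
eggs of which only a small fraction hatch, while infected mothers rescue
hatch to near-normal levels. A chemical-suppression screen asks whether
feeding a compound to uninfected mothers raises the CI hatch rate. The
unit of replication is a well of a 24-well plate (ten females laying
over roughly a day); each screening plate carries three conditions of
eight wells: CI control, CI + treatment, and rescue control. The
per-well readout is the hatch proportion, hatched/laid; pooled
(egg-weighted) rates are used for vial and mass-mating experiments where
wells are not the replicate unit.

Two analysis routes coexist deliberately. Plate screens compare the two
groups of per-well proportions with the adaptive procedure below — the
well is the replicate. Vial-format baseline crosses, for which only
pooled egg totals are recorded, use a chi-square goodness of fit of the
(hatched, unhatched) counts against the control group's observed hatch
rate, treated as a fixed expectation; with control samples of 500+ eggs
the distinction from a two-sample homogeneity test is numerically
negligible.

## Synthetic data generator

Per well, eggs `n ~ Poisson(λ)` with zero redrawn (a well without eggs
carries no rate information), and hatched `y | n ~ BetaBinomial(n, p, ρ)`
parameterised by mean hatch probability `p` and intraclass correlation
`ρ` (beta shape parameters `a = p(1−ρ)/ρ`, `b = (1−p)(1−ρ)/ρ`; `ρ = 0`
degenerates to a binomial). The per-well rate variance is
`p(1−p)(1+(n−1)ρ)/n`: the `ρ` term models between-well heterogeneity —
female age, feeding history, local food quality — which a plain binomial
underestimates. A root seed expands through `numpy.random.SeedSequence`
into one child stream per plate, so datasets are bit-reproducible and
plates are independently parallelisable.

Defaults are the screen's operating points: `p` = 0.12 (CI control, the
midpoint of the observed 11–14% range and the boundary of the inclusion
gate), 0.25 (treated CI, midpoint of the 20–30% suppression window),
0.92 (rescue control), 0.90 (uninfected control cross); `λ = 150`
eggs/well (ten females over the ~day-long lay window); `ρ = 0.002`.
`λ` and `ρ` are calibration knobs, not estimates — true per-well egg
counts and their dispersion are not recorded in the reference screen's
summary tables. With these values the CI-control per-well rate sd is
≈ 0.030 and the rescue-control sd ≈ 0.025, which places the simulated
per-plate Z′ around 0.80 ± 0.04 — inside the 0.76–0.89 window the
reference screen reports. About 84% of simulated plates individually
clear Z′ = 0.76; the floor is a typical-plate property, not a guarantee
for every draw.

What the generator does *not* emulate: per-female fecundity structure
within a well, day effects shared across a plate's conditions (plate
effects enter only through independent sampling noise), edge-well
artefacts, and any dose–response relationship. Passing tests therefore
certify the statistical machinery under idealised exchangeable wells,
not robustness to those real-data features.

## QC gate and dose grading

A plate is scored only if its pooled CI-control hatch rate is ≤ 12%,
boundary inclusive. The observed CI-control range (11–14%) straddles
this rule; the gate implements the rule as stated, so simulated plates
at the 0.12 calibration fail it roughly half the time — that is the
assay's real operating tension, reproduced rather than smoothed over.

Dose tolerability is graded per dose from a 12-day, two-vial series:
for each window (early, days 1–6; late, days 7–12) and each stage
(eggs, larvae, pupae), a loss of ≥ 40% relative to the stage-matched
control marks the window defective. Defects in both windows grade "−",
a defective late window alone grades "some", anything else "+"; the
feeding dose is the highest "+" dose. The 40% boundary is inclusive.
Losses confined to the early window alone grade "+" — the grading rule
is keyed to persistent or late-emerging toxicity; no numeric rule is
applied to adult mortality.

## Adaptive two-sample procedure

Groups of per-well proportions are screened with Shapiro–Wilk (each
group) and Levene's test centred at the mean (the SPSS convention),
both at a fixed, unadjusted 0.05: normal + homogeneous → Student *t*;
normal + heterogeneous → Welch *t*; non-normal + homogeneous →
Mann–Whitney *U* (exact for small groups without ties); non-normal +
heterogeneous → bootstrap-*t*. All tests are two-sided. Groups need ≥ 3
observations; a zero-variance group raises a degenerate-variance error
rather than feeding a variance test undefined input.

The bootstrap-*t* imposes the null by shifting both groups to the grand
mean, resamples each with replacement (observation resampling), and
refers the observed Welch statistic to the resampled |t| distribution
with the (b+1)/(B+1) correction; B = 10,000 by default (p-value noise
≤ ~10⁻²), seeded.

Bonferroni scaling is explicit: `AlphaPolicy(alpha, m)` judges
significance at α/m, with m supplied per experiment (6 for three-cross
comparisons, 4 for the treated-vial comparisons).

Hit grades use a two-threshold band chosen to be consistent with every
grade in the reference screen's hit tables: **Yes** p < 0.04,
**Borderline** 0.04 ≤ p < 0.05, **No** p ≥ 0.05; both thresholds are
configurable. Censored table entries "<0.001" are parsed as 0.0009 for
grading.

## Z′ and the hit range

`Z′ = 1 − 3(σ_CI + σ_R)/|μ_R − μ_CI|` with means and sample sds
(n−1 denominator, the screening-literature convention) over per-well
hatch proportions of the two control conditions; ≥ 2 wells per control
required, negative values reported rather than clipped (they diagnose
failed plates). A treatment's plate mean is placed on the normalized
scale `(μ_T − μ_CI)/(μ_R − μ_CI)` and flagged as in the hit range when
the *mean* clears `μ_CI + 3σ_CI` without entering `μ_R − 3σ_R`; the
3-sd rule applies to the plate-level mean, not individual wells.

## Sub-sampling sample-size determination

All C(plates, 2) crosswise plate pairs are pooled per condition
(8 + 8 = 16 wells). For each pair and each k in 3..16, B sub-samples
draw k wells per condition *without* replacement (a sub-sample of
distinct wells; replacement across draws) and re-run the full adaptive
procedure, test re-selected per draw. The rejection fraction at a given
α estimates power at that sample size; the minimum sufficient k is the
smallest k reaching the 99.5% criterion in *every* pair dataset
simultaneously (the criterion is applied per pair, not pooled). B
defaults to 2000, bounding the SE of a probability near 0.995 at
~0.0016. Sub-sampled draws that land on the bootstrap branch use 1000
bootstrap replicates (~0.001 p-value resolution, ample for rejection
decisions at α ≥ 0.01). A sub-sample with a zero-variance group is
recorded as p = 1 — it carries no distributional evidence. Multi-α
sweeps share one set of sub-sampled p-values, so the α = 0.05 and
α = 0.01 curves cost one sweep and are exactly consistent (rejection at
0.01 never exceeds rejection at 0.05 on the same draws).

Two discreteness effects are worth knowing. At k = 3 the exact
Mann–Whitney test's smallest two-sided p is 2/20 = 0.1, so draws
screened as non-normal cannot reject at 0.05 and the rejection
probability saturates below 1 even under complete separation; from
k = 4 (min p = 2/70) every branch can reject. And the rejection
probability conditional on one finite dataset fluctuates around the
nominal level; the type-I calibration statement is marginal over
datasets.

## Problem sizes and numerical choices

The packaged analyses run at desk scale: five simulated plates (10
pairs), k swept over 3..16, B = 2000 — about 2.8 × 10⁵ adaptive tests,
a few minutes on one CPU. Type-I calibration uses 1000 null screen
simulations (3-binomial-SE acceptance band); generator moment checks
use 10⁴ wells. Monotonicity of power in k is asserted with tolerance
0.02 at B = 5000, absorbing Monte-Carlo jitter and the rank-test
discreteness above. Hatched counts reconstructed from printed
(rate, total) pairs use `round(rate × total)` — only percentages and
totals are printed. Proportions are never rounded internally.

## Known limitations

- λ and ρ are calibrated, not estimated; inference about real plates
  should re-fit them from pilot data (method-of-moments on the pooled
  rate and per-well variance recovers p within 1% absolute and ρ within
  a factor of 2 at 10⁴ wells).
- The decision tree's branch frequencies under the calibration are
  ~83% t, ~10% Mann–Whitney, ~6% Welch, ~1% bootstrap at n = 8; which
  branch produced any particular published p-value is not recoverable.
- The chi-square route conditions on the control rate; for small
  control samples a two-sample homogeneity test would differ.
- No multiple-testing correction is applied across screened compounds,
  matching the reference screen's per-experiment-only Bonferroni.
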