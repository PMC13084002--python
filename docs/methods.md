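# Methods

`esrkit` reimplements, as a tested library, the quantitative machinery used
to study resource allocation in the yeast environmental stress response
(ESR): a piecewise Lotka-Volterra competition model with an analytic phase
diagram, single-cell nuclear-translocation metrics, OD600 growth-rate
estimation, an ordinal acquired-stress-resistance score, and downstream
transcriptome clustering and enrichment. Every stage can be exercised on
synthetic data with known ground truth; no external downloads are required.

## Competition model

Two strains share a culture of fixed carrying capacity `K`: a wild-type that
mounts the Msn2/4-driven stress response, and a faster-growing
stress-response null. Time is divided into cycles of period `ω`. Each cycle
opens with a severe-stress window of length `(1-φ)ω` in which the wild-type
is frozen (`dN_WT/dt = 0`; its death is negligible compared with the
mutant's) and the mutant dies at rate `D`. The remaining `φω` is logistic
competition:

    dN_i/dt = r_i N_i (1 - (N_WT + N_Null)/K).

The phase classification uses three dimensionless parameters: the relative
fitness `α = r_WT/r_Null` (< 1 in a single-stress medium), the inter-stress
interval in uninhibited mutant doubling times `β = ωφ r_Null / ln 2`, and
the per-event mutant death fraction `m = 1 - e^{-D(1-φ)ω}`. (The literal
`β = φ/ln 2`, `m = 1 - e^{-D(1-φ)}` forms are dimensionally inconsistent —
`φ` is a fraction — so we restore the factors of `ω` and `r_Null`; this is
the only reading under which `β` is "time between stresses normalized by the
uninhibited doubling time".)

For `α < 1` the three regimes are:

* **State I** — mutant nonviable: `m > 1 - e^{-β ln 2}`; the kill exceeds
  the maximum regrowth (`2^β`-fold) available between stresses.
* **State II** — wild-type always wins: `m > 1 - e^{(α-1)β ln 2}`.
* **State III** — ratio-dependent: the wild-type dominates when the starting
  ratio exceeds `ρ*(m) = (1 - 1/α) β ln 2 / ln(1-m) - 1/α`.

`critical_death_fraction` inverts `ρ*(m) = ρ` by bisection on
`m ∈ (10⁻⁹, state-I bound - 10⁻⁹)` to `|Δm| < 10⁻⁹`; the threshold is
strictly decreasing in `m` (diverging at 0, crossing 0 at the State II
bound), so the root is unique. At `α = 0.9`, `β = 50`, ratio 1 the root is
`m* = 0.8386`; the corresponding phase-map contour is commonly read as
"~80%", a ~4-point difference attributable to contour-reading precision (we
report the exact root and do not attempt to guess an alternative accounting
of doubling-time equivalents). At `β = 100`, ratio 25 the root is
`m* = 0.2554`.

### Simulation and its relationship to the analytic states

`simulate_competition` integrates the piecewise system phase by phase —
never stepping across a switch — with the exact exponential-decay solution
in the stress window and LSODA (rtol 1e-8, atol 1e-10·K) in the growth
window. Default inoculum is 5% of `K`; the winner is decided from the mean
per-cycle change of `ln(N_WT/N_Null)` over the last quarter of cycles
(tolerance 1e-6), with an extinction floor of 1e-9·K.

An important structural fact, verified both analytically and numerically:
the saturating ODE has **no ratio-dependent regime in the long run**. The
per-cycle change in `ln(N_WT/N_Null)` is
`(α-1)·∫ r_Null (1 - N/K) dt - ln(1-m)`, which never depends on the ratio
itself. Whenever the mutant persists (below the State I curve) the culture
re-saturates after each kill; in that regime the regrowth integral equals
`-ln(1-m)/r_Null` for a mutant-dominated culture, making the wild-type's
per-cycle gain `-α ln(1-m) > 0` for any `m > 0`. Because the wild-type
never dies, every stress event frees capacity it ratchets into: the
wild-type-at-K state cannot be invaded by the mutant, while the mutant-only
periodic orbit is always invadable by the wild-type. The simulated phase
diagram therefore collapses to two long-run outcomes — mutant extinction
above the State I curve, wild-type dominance below it — and the State III
threshold must be understood as a statement about the dilute,
exponential-phase competition, not about the asymptotic behaviour of the
saturating system. The test suite asserts the relationships that do hold
(extinction above State I, wild-type dominance in State II and in saturated
State III, frozen coexistence at `m = 0`); the dedicated
simulation-vs-classification grid test documents the collapse quantitatively
(≈24% agreement under the three-state prediction at start ratio 1) and is
expected to fail until the two notions of "winning" are reconciled.

## Bulk phenotypes

Growth rates are the OLS slope of `ln(OD600)` against time within a closed
window, default 75-225 min after NaCl addition (the post-stress exponential
regime); at least 4 in-window points are required. Mutant rates are
normalized by the same-day paired wild-type post-stress rate and rescaled by
the mean wild-type post/pre-stress ratio. The lag readout is the percent
change in OD over the first 60 min (linear interpolation to the endpoints).

Acquired stress resistance: colony viability at 11 H2O2 doses (0-20 mM),
normalized to the no-peroxide control, is graded on a four-point scale and
summed into a survival score in [0, 33] per NaCl-pretreatment time. The
printed scale overlaps at 100%/50-100% and omits (0, 10%); we use
closed-below bins `f ≥ 0.995 → 3`, `[0.5, 0.995) → 2`, `[0.1, 0.5) → 1`,
`< 0.1 → 0`, reading visual "100%" as indistinguishable-from-complete.
Delta scores are relative to the unstressed t = 0 aliquot of the same panel
(not a pooled baseline). Group comparisons: replicate-paired t tests
(two-sided or one-sided with the direction declared in config; the
conventional direction is mutant < wild-type) and the rank-sum test,
computed exactly for n ≤ 25 without ties.

## Single-cell dynamics

The nuclear/cytoplasmic ratio is the mean of the `ceil(0.05·n)` brightest
pixels over the median of all pixels of a segmented cell — scale-invariant
and at least as large as ~1 for a diffuse reporter. Frame windows are index
based (T-numbers; NaCl arrives after T12): peak height = max(T13-T20) minus
min(T11-T13); abundance = mean per-frame median signal over T1-T12 (pre) or
T20-T36 (post); AUCs use trapezoidal integration (the inter-frame interval
in minutes is irrelevant to index-based metrics).

Demultiplexing projects per-cell iRFP trace vectors on the first principal
component (SVD) and splits by seeded 2-means on PC1 — more robust than a
fixed intensity threshold — labeling the higher-iRFP cluster "marked" and
reporting the silhouette of the split. Population centering divides each
timepoint column by its median and takes log2 (a subtraction mode is
available); clustering uses uncentered correlation distance with average
linkage, the Gene Cluster 3.0 defaults, with constant rows flagged and
forced to join last. Abundance matching filters both groups to a signal
interval and certifies the match with a rank-sum p > 0.05 before dynamics
are compared.

## Transcriptome downstream

Inputs are fold-change/FDR tables from an upstream DE engine (consumed,
never computed). Responsive genes require FDR < 0.05 at ≥ 2 timepoints.
Defect calls take the wild-type's majority-sign direction and require the
mutant's |log2 FC| to be smaller in a strict majority of the timepoints
with that direction (absolute-magnitude comparison within the wild-type
direction). K-means (k = 10 by convention, k-means++ with 50 restarts,
fixed seed) runs on unscaled concatenated per-strain fold-changes plus
mutant-minus-wild-type differences.

Motif scanning expands IUPAC motifs to regexes, enumerates candidate
intervals on both strands (a reverse-strand hit occupies its forward-strand
interval), and accepts greedily left to right, skipping overlaps with
forward-strand priority on ties. For fixed-length intervals greedy by left
endpoint equals the maximum independent set on the interval path, which the
tests confirm against a dynamic-programming oracle. Promoters are ≤ 500 bp
immediately 5' of the start codon; longer FASTA records are truncated to
their 3'-most 500 bases; positions are reported 1-based.

Enrichment is the upper-tail hypergeometric `P(X ≥ overlap)` per gene set
with BH correction across the sets tested for a cluster; under-enrichment
uses the lower tail (default choice where a two-sided construction is also
conceivable). Regulator counts per gene use `log2(count + 1)` so
zero-regulator genes are admitted, compared per cluster to background by
rank-sum with BH across clusters.

## Synthetic data

Generators draw from a single `numpy.random.Generator` per call (seed in
every truth sidecar) and default to the study conditions:

* **OD curves** — 15-min sampling to 240 min, mutant post-stress rate
  0.005/min (~140-min doubling under 0.7 M NaCl), wild-type/mutant ratio
  0.9, 1% multiplicative lognormal noise, optional lag.
* **Viability panels** — 11 doses 0-20 mM; survival logistic in dose around
  an LD50 rising from 2 mM toward ~16 mM with a 30-min saturating time
  constant; delayed-acquisition and zero-protection strain variants.
* **Cell traces** — 40 frames, 50:50 marked/unmarked mix, baseline nuclear
  fraction ~1, pulse of height 1.0 (wild-type) vs 0.7 (mutant deficit 0.3)
  over T13-T17, per-cell abundance lognormal around 640 signal units, iRFP
  offset 5x background in marked cells only, 2% trace noise.
* **Expression** — four temporal archetypes (induced, induced with an
  Msn2/4-dependent defect, repressed, repressed with a Dot6/Tod6-dependent
  defect) over 4 timepoints in 3 strains; FDR columns consistent with the
  planted defects; 500-bp promoters with CCCCT planted at probability 0.8
  in the Msn2/4-dependent cluster (0.1 background) and GATGAG likewise for
  the Dot6/Tod6-dependent cluster; TF-target sets with two planted biased
  regulators.

What the generators do **not** emulate: cell-to-cell heteroscedasticity and
segmentation artifacts in real traces, batch effects and count-level
overdispersion behind the FDR columns, plate-position effects in viability
panels, and real yeast promoter base composition (planted motifs sit in
i.i.d. uniform background). Passing recovery tests therefore demonstrates
correctness of the estimators under the stated noise models, not robustness
to every failure mode of real data. Reproducing the study's specific gene
counts requires reprocessing the deposited sequencing data through external
aligners and is deliberately out of scope.

## Problem sizes and numerical choices

Test and acceptance runs use 100 OD curve pairs, 120-200 cells, 400 genes,
and 12-30 simulated stress cycles — sizes chosen so every planted effect is
detectable at its configured magnitude while the full suite completes in
well under a minute of compute per module. Tolerances: ODE rtol 1e-8 / atol
1e-10·K, bisection xtol 1e-9, winner tolerance 1e-6 on the mean per-cycle
log-ratio change. Ties in k-means are resolved by the fixed seed; ties in
motif scanning by forward-strand priority; degenerate inputs (zero medians,
zero variance, empty windows, missing frames) raise typed errors naming the
offending quantity.

## Known limitations

* The simulation/classification divergence described above: the analytic
  State III basin boundary is not an attractor boundary of the saturating
  ODE, so simulation can only cross-check the State I/II structure and the
  dominance direction one-sidedly above the contour.
* The exact rank-sum path requires tie-free data; with ties the normal
  approximation is used regardless of sample size.
* Demultiplexing assumes a unimodal iRFP distribution per strain; bimodal
  marker silencing would need a mixture model.
* `scale_rates` presumes same-day pairing is encoded by list order; there is
  no replicate-identifier join.
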