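# Methods

## Dynamic indentation model

A spherical probe of radius `R` (57–125 µm) indents the tissue to a mean
depth `h` (10–60 µm) under depth control: ramp at 2 µm/s, 10 s stress
relaxation, then small sinusoidal depth oscillations (amplitude
`h₀ = 0.3 µm`, frequencies 0.1 / 1 / 10 Hz). With Hertzian contact
(`a = √(R h)`, `A = π a²`) and an incompressible sample (ν = 0.5), the
apparent storage and loss moduli follow from the complex dynamic stiffness
`S* = F₀/h₀ · e^{iΦ}`:

    K′ = (F₀/h₀) cos Φ · √π / (2√A) = (F₀/h₀) cos Φ / (2a)
    K″ = (F₀/h₀) sin Φ · √π / (2√A)

and `tan Φ = K″/K′`. Because the oscillation (≤ 2% of depth) barely moves
the contact, `a` is evaluated at the mean depth of each oscillation
segment and treated as constant within it. All file I/O stays in µm/µN;
modulus arithmetic converts to SI (F₀/h₀ in µN/µm is numerically N/m).

**Amplitude/phase extraction.** Each segment is fit by linear least squares
to `c + A sin(2πft) + B cos(2πft)` at the known drive frequency, for depth
and load separately; the phase lag is `phase(F) − phase(h)` wrapped to
[−π, π]. Values outside the physical [0, π/2] are flagged, never clipped.
On noise-free integer-period segments this coincides with the DFT bin at f
(the independent oracle used in the tests) to better than 10⁻⁶ relative.

**Contact detection.** Contact is the first sample where the load exceeds
the approach-baseline mean + 3 SD for at least 50 ms. With a finite noise
floor this threshold necessarily fires late (for 0.7 kPa tissue and R =
57 µm, a 3σ threshold at 5 nm deflection noise is only crossed ~1 µm past
contact, biasing K′ by ≈ +3.5%), so the analysis refines the contact
point by regressing `F^(2/3)` on the probe position over the early ramp
(loads between 5% and 50% of the ramp maximum; `F^(2/3)` is linear in
depth for a Hertzian sphere) and extrapolating to zero load. Depth is then
`h(t) = (piezo − piezo_contact) − (deflection − baseline)`.

**Statistics.** Per frequency, Shapiro–Wilk normality on the K′ and K″
samples; across frequencies, Kruskal–Wallis (tie-corrected) with
significance reported at 0.01 and 0.0005. All-identical groups are
reported as H = 0, p = 1 rather than an error.

## Tissue model in the generator

`TissueModel.standard_linear_solid` uses the single-relaxation-time forms
`K′ = K_e + ΔK·x/(1+x)`, `K″ = ΔK·√x/(1+x)` with `x = (f/f_r)²`; the
`retina_like` preset solves `K_e, ΔK` so K′ passes through 0.7 kPa at
0.1 Hz and 1.7 kPa at 10 Hz with `f_r = 1 Hz` (giving K″ ≈ 0.10/0.51/0.10
kPa at the three sweep frequencies). The trace generator inverts the
moduli relations exactly: at drive frequency f the load oscillation has
amplitude `F₀ = h₀·2a·|K*|` and phase `atan2(K″, K′)`; the ramp follows
the quasi-static Hertz law and the relaxation is a phenomenological
exponential (the relaxation segment is not analyzed). Gaussian noise of
configurable SD is added to the cantilever deflection; load and piezo
stay consistent with `F = k_c·d` and depth control.

Acquisition defaults are 1 kHz sampling and ≥ 12 s (integer periods,
minimum 3) per oscillation segment. These mirror an interferometric
readout's operating point and give the phase SNR needed to resolve the
small loss angle at 10 Hz (tan Φ ≈ 0.06): at coarser sampling or shorter
dwells, K″ scatter at 5 nm noise grows several-fold while K′ is barely
affected.

## Spike-train generator

Each unit is an inhomogeneous Poisson process (thinning; one RNG
substream per unit from a single seed). Rate of unit i:

    r_i(t) = b_i · m_i(t) + b_i · g_flash · f_i(t)

* `b_i` — basal rate, default 5 Hz (optionally gamma-distributed with
  shape 8 for realistic heterogeneity).
* `m_i(t)` — mechanically evoked modulation: a box-car with exponential
  rise (τ = 1 s) starting `latency + 0.5 s/mm × distance` after
  stimulation onset and/or offset, lasting ~6 s; excitation multiplies
  the rate by the cluster gain (default 3), suppression scales it toward
  1/gain. These shapes encode "prolonged rate increases lasting a few
  seconds, delayed with distance from the indentation site"; the exact
  kinetics are a modeling choice, not a measured quantity.
* `f_i(t)` — a 200 ms half-cosine transient after each preferred flash
  (ON: white; OFF: black; ON-OFF: both; NC: none), peak `g_flash · b_i`
  (default gain 3).

The four-cluster preset plants three onset assemblies at latencies
2/14/26 s plus one offset assembly (6 s durations): temporally disjoint
envelopes keep the planted assemblies mutually near-orthogonal, which is
what makes membership recovery a well-posed benchmark — a "both"-type
assembly correlates ≈ 0.5 with onset and offset assemblies and bridges
them under average linkage. Responsive assemblies carry ~20 percentage
points more ON cells than the OFF-dominated background (25% ON / 35% OFF
/ 20% ON-OFF / 20% NC), so cell-type-composition analyses have a known
planted contrast.

What the generator does **not** emulate: refractoriness (optional flag
only), bursting, common slow drifts, adaptation, spatially continuous
response gradients, spike-sorting errors, or electrode noise. Passing
tests therefore demonstrate correctness of the analysis chain under
Poisson statistics, not robustness to every failure mode of real
recordings.

## Spike pipeline

Units firing < 0.1 spikes/s are dropped. Rates are counted in a 2 s
window sliding in 10 ms steps (centered bins fully inside the interval;
windows are half-open `[c−w/2, c+w/2)`), z-scored per unit with the
population-SD convention; zero-variance rows are flagged and excluded
from correlation rather than propagated as NaN. The basal window is the
120 s preceding stimulation onset; the indentation window runs from onset
to offset + 10 s (offset responses fall inside it; configurable).

Clustering is agglomerative with average linkage on `d = 1 − |ρ|` — the
absolute value deliberately merges correlated with anti-correlated units.
For each k in [4, 60] the dendrogram is cut and the silhouette score
evaluated on the precomputed distance; the argmax (smallest k on ties)
is selected; if the silhouette is undefined for every k (all-identical
signals) a single cluster is returned with a warning.

**Responsive clusters** are those with ≥ 3 members whose mean
basal-referenced z-rate (`(rate − basal mean)/basal SD` per unit,
averaged over members) exceeds 3 somewhere in the indentation window.
Basal-referenced standardization matters: z-scoring within the
indentation window normalizes away part of the response itself and
dilutes clusters that absorbed background members, while noise-selected
clumps can reach within-window peaks of ~2.5 precisely because
clustering selected their correlations. Against the basal reference,
planted assemblies score ≳ 4 and background clumps stay below ~2.5.

**A structural property worth knowing** (measured with this package, and
the reason one acceptance-style expectation is not met): with ~300
independent background units and the protocol window parameters, noise
correlations between unrelated units have SD ≈ 0.13 (a 60–70 s window
smoothed over 2 s leaves ~35 effective samples), and the silhouette
criterion then *prefers fragmenting the background* into many small
noise-correlated clumps: the score rises monotonically toward the k = 60
boundary (~0.16) while the ground-truth partition (4 assemblies + one
background blob) scores only ~0.10. The selected k is therefore large
even when exactly four assemblies are planted; the assemblies themselves
are still recovered intact as individual clusters and are the only ones
flagged responsive. With no background units the silhouette correctly
selects k = 4 with exact membership. Interpreting the selected k as a
count of *mechanically responsive* groups requires the responsive-cluster
step; k itself mostly reflects the background noise structure.

## Flash classification

A_w and A_b are peaks of the trial-averaged PSTH (100 ms window, 10 ms
step) over a response window of flash duration + 0.5 s, minus the basal
mean, floored at 0 (the Bias Index presumes non-negative amplitudes, so
suppressive flash responses are not signed). The NC (non-classified)
rule runs first: a unit whose raw PSTH peak stays below
`basal mean + 1·basal SD` has no detectable flash response. Basal mean
and SD are computed from the distribution of *raw* sliding-window rates
over the basal recording — the unit's own firing variability — not from
the trial-averaged baseline: averaging over N repeats shrinks baseline
noise by √N, and a threshold tied to it would tag essentially every unit
as responsive. Then BI > 0.3 → ON, BI < −0.3 → OFF (strict
inequalities; BI = 0.3 exactly is ON-OFF), otherwise ON-OFF; undefined
BI (A_w = A_b = 0) → NC.

## Probe localization

The shadow is the largest 4-connected component of non-saturating
electrodes with at least `min_region` (default 8) members;
4-connectivity resists diagonal noise bridges from flipped electrodes.
The center is the centroid rounded to the nearest electrode, half-integer
ties breaking toward the smaller index. Among multiple frames, the one
maximizing `n_saturating × n_non_saturating` is selected. A
`manual_override` escape hatch reproduces the manual workflow.

## Trial predictors

Features per trial: contact area `πRh`, strain `ε = a/R = √(h/R)`,
pressure `F_max/(πRh)`, depth, `d5` (units within 5 electrode distances
of the center, inclusive), `r5` (their mean basal rate; undefined when
d5 = 0, and such trials are dropped). A `DecisionTreeClassifier` (Gini,
unlimited depth) is refit `n_repeats = 1000` times; "different initial
conditions" means a repeat-specific seed controlling a stratified 80/20
train split and the tree's tie-breaking — a tree on a fixed full dataset
is deterministic, so resampling is the only meaningful variation source
(a `seed_only` mode fits the full table every time). Importances are
sklearn's normalized Gini importances (sum to 1 per repeat whenever the
tree splits at all), reported as mean ± SD.

The synthetic trial sampler draws radii from {57, 73, 125} µm, depths
10–60 µm, loads ∝ depth^1.5 with lognormal scatter (pressures span tens
to hundreds of Pa, matching the protocol loads of 0.3–34 µN), d5 ~
Poisson(8) and r5 ~ Gamma; success is planted as
`pressure > 100 Pa AND d5 > 7` with 5% label flips. Thresholds sit near
the feature medians so both outcome classes are well populated.

## Determinism and problem sizes

Every stochastic stage consumes an explicit seed; per-unit RNG substreams
come from `numpy.random.SeedSequence.spawn`, so one unit's spikes do not
depend on how many others exist. The full pipeline writes byte-identical
artifacts for identical config + seed (reports contain no timestamps).

Test and demonstration sizes were chosen to keep every run on a laptop
scale while leaving comfortable statistical margins: 10–50 Monte-Carlo
seeds per claim, retinas of 300–440 units, 200-trial feature tables,
200-seed calibration of the Kruskal–Wallis test. The acceptance script
reports with each quantity the problem size it used.

## Known limitations

* The strain definition `ε = a/R` follows common indentation practice;
  the threshold ε > 0.05 quoted in the source literature may assume a
  different convention (e.g. 0.2·a/R), so strain-based comparisons across
  studies need care.
* The literal NC-rule wording in the source ("one standard deviation
  below the mean basal firing rate") is ambiguous; the implemented
  convention is stated above and should be kept in mind when comparing
  NC fractions.
* Pressure is defined as `F/(πRh)`; published minimum-stimulating-pressure
  figures may use a different contact-area convention and are not forced
  to agree.
* Silhouette-based k selection is unreliable in the presence of many
  uncorrelated units (see above); downstream conclusions rest on the
  responsive-cluster step, not on k.
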