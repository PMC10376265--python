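# Methods

## Degree of oxidation and Nernst potentials

The analysis-side model is the standard two-endpoint calibration of a
ratiometric redox probe. A measurement is the excitation ratio
`R = I405/I488` of background-subtracted ROI-mean intensities; the degree of
oxidation is

    OxD(R) = (R − R_red) / [ k·(R_ox − R) + (R − R_red) ],   k = I488min/I488max.

This is the unique fractional-saturation form with `OxD(R_red) = 0` and
`OxD(R_ox) = 1`; both boundary identities are pinned by unit tests, as is
the algebraic inverse used by the simulator (round trip to 1e−12).

Potentials come from the Nernst equation with `RT/zF = 12.848 mV`
(R = 8.315 J·K⁻¹·mol⁻¹, T = 298.15 K, z = 2, F = 9.648 × 10⁴ C·mol⁻¹):
the probe-couple form `E_probe = E0_probe − (RT/zF)·ln[(1−OxD)/OxD]` and the
concentration-dependent glutathione-couple form
`E_GSH = E0_gsh − (RT/zF)·ln[2·GSH_tot·(1−OxD)²/OxD]` with `GSH_tot` in
molar. The two forms answer different questions (probe state vs glutathione
pool state) and are both reported; no attempt is made to reconcile them into
a single "true" potential. Midpoint potentials are not instrument
observables; the defaults (−280 mV for roGFP2, −240 mV for the glutathione
couple, GSH_tot = 2.5 mM) are standard literature values and are
config-overridable. The simulator uses the same constants, so recovery
experiments are self-consistent.

Numerical policies:

* **Averaging order.** OxD and E are computed per replicate and then
  averaged; the alternative (E of the mean OxD) differs by a Jensen gap of
  roughly a millivolt at realistic spreads. The order is fixed and tested.
* **Clamping.** Ratios outside `[R_red, R_ox]` are clamped to the endpoints
  with a warning (noise makes small excursions routine; erroring would bias
  the remaining sample). Before the Nernst step OxD is clamped into
  `[1e−4, 1 − 1e−4]` so boundary replicates yield finite potentials;
  requesting a potential at exactly OxD ∈ {0, 1} raises instead.
* **Background.** Per-channel mean over background-labelled pixels; no
  rolling-ball or morphological estimation. Saturated pixels are excluded
  from ROI means and counted.
* **Ratio of means, not mean of ratios.** Compartment ratios use ROI-mean
  intensities (the convention for ROI-based intensity measurement); a
  pixelwise mode exists behind a flag for sensitivity checks.
* **Grand means.** The treatment-level summary is the mean of the 13
  per-timepoint means, with SEM across timepoints — the analogue of a
  "mean over the 24 h window" table row.

## Synthetic image sets

A field is ~20 elliptical cells on a jittered grid (256×256 px default),
each a nucleus ellipse nested in a cytosol ring; mask IDs pair them as
(2i−1, 2i) with background 0. Per-cell base 488-nm intensity is lognormal
(median 2500 counts, σ_log 0.25; cytosol at 0.6× the nucleus); the 405-nm
channel is the inverted-ratio image of the 488 channel at the compartment's
true OxD. Noise is additive Gaussian with variance
`photon_scale·signal + read_noise²` (a Gaussian approximation to shot noise,
adequate at thousands of counts) plus a uniform background offset of 100
counts; pixels clip at the 16-bit cap. True OxD is jittered on the logit
scale — once per replicate (SD 0.08, the biological replicate variability;
this keeps values inside (0,1) and yields per-measurement OxD spreads of
~1.7 points, consistent with SEM-scale scatter in this kind of assay) and
once per cell (SD 0.03).

The calibration pair shares one base field (geometry and brightness draws)
between the reduced (OxD = 0) and oxidised (OxD = 1) sets, with the
oxidised 488 channel scaled by `1/k` — the simulated analogue of re-imaging
the same roots after each calibration treatment. This makes `k` estimable
from pooled pixels to well under 2 % at default noise.

Ground-truth OxD trajectories (13 points, 0–24 h) are frozen constants in
`config.py`. Each trajectory's mean equals its scenario's treatment-level
mean OxD, and anchored points encode the documented transients (HC cytosol
0.37 and HU cytosol 0.32 at 2 h). The HC nuclear trajectory is a step shape
(reduced through 12 h, strongly oxidised after) solved once so that its
mean OxD *and* the mean of its per-timepoint probe potentials match the
treatment-level values simultaneously — the second condition fixes the
spread of the step. All randomness descends from the scenario seed through
`SeedSequence(seed, spawn_key=(domain, scenario, timepoint, replicate))`,
so every generator is bit-reproducible and streams are independent across
arms.

## Flow cytometry

The generator draws exact component counts (largest-remainder rounding of
the requested G1/S/G2 fractions), then G1 ~ N(μ, CV·μ) at the 2C channel
μ = 200, G2 ~ N(2μ, CV·2μ), S as a uniform bridge on (μ, 2μ) broadened by
the G1 σ, and a debris fraction (default 2 %) with exponential low-channel
DNA fluorescence (scale μ/4) and low FSC/SSC. Default CV is 5 % and the
default table is 100,000 events. Synthetic tables carry a `true_phase`
column for oracle tests; it is never written to the canonical CSV and the
gating code never reads it.

Gating replaces the manual bench procedure with a deterministic rule set
(all thresholds in `GatingParams`): a rectangular FSC/SSC lower-bound gate
plus a low-DNA cut at 25 % of the provisional G1 mode; then the G1 peak is
the histogram mode in a search band (5–60 % of the channel range, falling
back to the global mode when the band holds no substantial peak, as in
samples without a 4C population), the G2 peak the highest mode at 1.8–2.2×
the G1 position, and each peak core gets a Gaussian σ by curve-fit to the
histogram within ±12 % of the peak (median/MAD short-circuit returns σ = 0
for delta-like noise-free peaks, which makes noiseless classification exact
per generating component). Events within ±2σ of a peak are G1/G2 (boundary
ties to the peak), events strictly between the cores are S, and flank
events join the nearest peak. S is deliberately "between the cores" rather
than a Dean–Jett–Fox deconvolution — it matches rectangular-gate practice
and is adequate in the ~8 %-S regime; DJF modelling is out of scope. The
DNA axis is linear, as conventional for PI content. If no 4C peak exists
the classifier degrades to a threshold at max(1.5×G1, G1+2σ) and flags the
result (the midpoint threshold, rather than G1+2σ alone, keeps a clean
single-population sample from shedding its upper tail into G2).

Known biases: ±2σ cores capture 95.4 % of a Gaussian peak, so ~2.3 % of G1
leaks into S while part of the bridge near each core is absorbed — a net
~1 point understatement of G1 at the default geometry, inside the ±2–3
point tolerances used throughout. Fractions are scale-equivariant (all
thresholds are relative) and always sum to 1 over gated events.

## Growth and statistics

Per-seedling growth rate is the length increment over an interval divided
by elapsed days; tables default to 30 seedlings (3 biological replicates of
10). The generator gives each seedling a Gaussian rate deviation
(SD 0.10 mm/d) and each length measurement Gaussian noise (SD 0.10 mm,
image-analysis-scale error). Control truth is 1.4 mm/d (0–24 h) and
1.7 mm/d (24–48 h); post-release factors are 0.45× (HC) and 0.72× (HU) on
the first interval, with HC recovering to 1.0× and HU to 0.65× on the
second. "Recovery to control levels" is operationalised as Tukey HSD
non-significance versus control at α = 0.01 on the interval.

ANOVA is the classical fixed-effects one-way decomposition; Tukey HSD uses
the studentized-range distribution (scipy's numerically integrated CDF, so
any (k, df) is supported) with the Tukey–Kramer harmonic-mean group size
for unbalanced designs. Compact letters come from insert-and-absorb, and a
property test verifies letter/significance equivalence on arbitrary
matrices. Degenerate inputs: zero within-group variance with distinct means
takes an exact-separation path (all pairs significant, warning); all-equal
data returns the single-letter null result. With two groups the adjusted p
equals the pooled t-test p (q = √2·|t|), asserted numerically against both
scipy's t-test and statsmodels' Tukey implementation.

## What the simulations do and do not show

Passing recovery tests demonstrates that the analysis chain is unbiased and
correctly calibrated *for data matching the generator's assumptions*:
symmetric noise, uniform background, exact nucleus/cytosol masks, Gaussian
DNA peaks at an exact 2C:4C ratio, linear growth within intervals. Real
confocal data add optical blur and bleed-through, autofluorescence
gradients, segmentation error, photobleaching and pH sensitivity; real
cytometry adds doublets and staining variability; none of these are
simulated, and no claim about instrument-specific performance follows from
these tests. Problem sizes (5 replicates × 13 timepoints, 10⁵ events,
30 seedlings) are the study-design sizes, which also keep full runs to a
few seconds.

## Limitations

* The calibration model assumes both endpoints are measurable in the same
  optical configuration; failed calibration treatments surface only as the
  R_ox ≤ R_red inversion error.
* S-phase estimation by core-exclusion slightly redistributes peak tails;
  do not use it for S-rich populations (> ~20 % S) without a deconvolution
  model.
* The glutathione-couple potential assumes equilibrium between probe and
  pool and a known total glutathione concentration; both are conventions,
  not measurements.
* Technical-versus-biological replicate nesting is not modelled; replicates
  enter as exchangeable fields.
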