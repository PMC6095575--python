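# Methods

This package re-implements, as a tested pipeline, a multi-parametric
imaging-response analysis for primary renal cell carcinoma (RCC) treated
with stereotactic ablative body radiotherapy (SABR): ADC histogram measures
from diffusion-weighted MRI, semi-quantitative and pharmacokinetic analysis
of dynamic contrast-enhanced (DCE) MRI, ellipsoid CT volumetry with
RECIST 1.1 categories, and Spearman correlation of per-patient MRI-parameter
changes against CT volume changes.  Because no patient imaging is publicly
available, every quantitative claim the package makes is validated on
digital phantoms with known ground truth; this note records the models, the
defaults, and the design choices that were genuinely open.

## CT volumetry and RECIST

Tumour volume is computed from tri-axial measurements as an ellipsoid,
V = π/6 · AP · TR · CC (mm³).  Percentage change versus baseline is a pure
ratio, so the π/6 factor cancels.  RECIST 1.1 categories are assigned from
the longest of the three reported axes: PR at a ≥ 30 % decrease, PD at a
≥ 20 % increase that is also ≥ 5 mm, SD otherwise.  Strict RECIST uses the
longest *axial in-plane* diameter; only tri-axial maxima are available in
the measurement table this package ships, and the max-axis rule reproduces
all twelve published categories, so it is adopted and documented as a
deviation.  Complete response is not modelled (no CR occurs in the cohort).
Missing table cells ("-") become absent records, never zeros.

## ADC analysis

The mono-exponential model S(b) = S0·exp(−b·ADC) is fitted per voxel by
ordinary least squares of ln S on b (b = 50, 400, 800 s/mm² by default).
With two b-values this reduces to the exact two-point formula.  Voxels with
any non-positive signal are excluded and flagged; a negative fitted ADC is
clamped to zero and flagged.  The fit is unweighted: it is deterministic and
exact on noiseless data, and weighted variants are out of scope.

ROI histogram statistics use *biased* moment estimators with Pearson
kurtosis (normal = 3) — the default convention of the numerical environment
used for the original histogram analysis — so values are comparable with
that convention.  Zero-variance ROIs yield flagged-undefined skewness and
kurtosis rather than arbitrary numbers.  Changes are absolute differences
(follow-up − baseline).

## Semi-quantitative DCE model

Each voxel's signal is normalised to the mean of the first two frames,
e(t) = S(t)/S̄_base − 1, and four nested continuous piecewise-linear models
are fitted by exhaustive search over breakpoint frames (each segment ≥ 2
frame intervals), with the per-breakpoint linear subproblem solved in closed
form for all voxels simultaneously:

* M0 constant — non-enhancing (1 parameter)
* M1 constant → rising — persistent (3)
* M2 constant → rising → flat — plateau (4)
* M3 constant → rising → flat → falling — washout (6)

Candidates with a negative uptake slope or positive washout slope are
rejected.  Extracted parameters: Tonset (first breakpoint, s), IRE (uptake
slope, enhancement/s), ME (fitted maximum), and for washout Twashout (final
breakpoint) and IRW (magnitude of the falling slope).  Fields that do not
exist for a class are absent, never zero-filled.

**Model selection.**  "Smallest error" alone cannot choose among nested
models, so selection uses a BIC-style criterion.  The textbook form
n·ln(sse/n) + k·ln n is degenerate on noiseless data: the likelihood term is
scale-free, so any smooth curve hands the win to the most flexible model
regardless of the penalty.  Model selection needs a noise scale, so the
criterion here is

    BIC_m = n · ln((sse_m + n·σ0²)/n) + k_m · ln n,

with a residual floor σ0 = 0.05 enhancement units by default — deliberately
equal to the non-enhancement threshold, since both express the same
judgement that changes below ~5 % of baseline are indistinguishable from
acquisition noise.  Ties break toward the simpler model.  Both σ0 and the
threshold are configurable.  Whether the original software used a penalty or
an F-test is unknown; this criterion is this package's documented choice,
not a claim about that software.

A voxel whose fitted maximum enhancement falls below the threshold (default
0.05) is classified non-enhancing regardless of the winning model.  ROI
summaries report class percentages over *all* voxels but parameter means
over enhancing voxels only (Twashout/IRW over washout voxels only); an ROI
with no enhancing voxel reports absent means with a flag — the situation
does occur in noisy clinical data and must not crash a cohort run.

## Pharmacokinetic DCE model

Signal is converted to gadolinium concentration through the spoiled
gradient-echo (SPGR) steady-state equation anchored at a fixed native T1:
the two-frame baseline pins M0·sin α at R1 = 1/T1_native, each frame is
inverted for R1(t), and C(t) = (R1(t) − 1/T1_native)/r1.  Constants follow
the published fixed-T1 analysis: r1 = 2.8 L·mmol⁻¹·s⁻¹ (gadoterate at 3 T),
T1 = 1664 ms for arterial blood and 1142 ms for kidney tissue, flip angle
20°.  The TWIST repetition time is not part of the published description;
TR = 4 ms is a typical 3D-TWIST value and is configurable (the inversion is
well-conditioned across the plausible range).  A linearised dS ∝ dR1 mode is
available as a config option.  Frames implying non-physical E1 are flagged
per frame.

The arterial input is measured from an aorta ROI with the blood T1 and
divided by (1 − Hct), Hct = 0.42 by default, to give plasma concentration —
the quantity the extended Tofts model is defined on.  The published analysis
does not mention a hematocrit correction, so it can be disabled.

The extended Tofts model

    Ct(t) = Ktrans · ∫₀ᵗ Cp(τ)·e^(−kep(t−τ)) dτ + vp·Cp(t),  kep = Ktrans/ve

is evaluated by trapezoidal convolution on the native 5.2 s frame grid (no
upsampling by default).  Fitting is bounded nonlinear least squares over
(Ktrans, ve, vp) ∈ [0, 5] min⁻¹ × (0, 1] × [0, 0.5], multi-started from a
fixed 4-point grid for determinism, with an early exit when a start reaches
an exact fit.  Ktrans is reported in min⁻¹ (field convention).  iAUGC60 is
the trapezoidal integral of Ct over the first 60 s after the specified
onset frame, linearly interpolated at the window endpoint and flagged when
fewer than 60 s of samples exist.  PK means are taken over enhancing,
converged voxels only, mirroring the GD-map exclusion rule.

## Statistics

Spearman's rho is computed from average ranks (mid-ranks for ties).  The
p-value policy mirrors the default behaviour of the statistics environment
named for the original analysis: for n ≤ 9 without ties, the exact
permutation distribution (enumerated through the Σd² statistic) gives a
two-sided p; otherwise the t approximation t = ρ·√((n−2)/(1−ρ²)) with n − 2
degrees of freedom.  Which of the two produced each published table cell
cannot be determined; the hybrid is the documented default.  p ≤ 0.05 flags
significance, with no multiple-comparison adjustment by default (matching
the original analysis); Benjamini–Hochberg is available as a switch.
Correlations use pairwise-complete pairs with n reported per cell; cells
with n < 4 are reported absent.  Cohort-level exclusions (e.g. a divergent
histology, or a scan in which no voxel fitted) are applied from a config
list to DCE columns only, so DWI columns keep their larger n.

## Digital phantoms

The phantom generator defines the validation conditions; its defaults are
fixed once and stated here.

**Geometry.**  The tumour ROI is a centred ellipsoid (88 % of the grid
extent per axis); a small blood-pool region sits in a grid corner so the
AIF can be re-measured from the images.  Default acquisition matches the
protocol being emulated: 30 frames at 5.2 s, onset frame 5, b = 50/400/800
s/mm².

**AIF.**  A parametric population curve substitutes for the manual aorta
measurement: a gamma-variate first pass (peak 1.2 mM, 12 s after onset,
sharpness 2) plus a dispersed bi-exponential equilibrium tail (amplitude
1.0 mM, rise 5 s, decays 900 s and 5400 s, 40 % fast fraction).  The tail
decay constants sit on contrast-agent redistribution/renal-excretion
timescales, so plasma concentration is nearly flat over the 2.6-minute
acquisition.  This matters scientifically: with a near-constant tail,
low-kep tissue integrates to the steady ramp that clinicians call
persistent enhancement, while high-kep/high-vp tissue tracks the first pass
and washes out.  The curve is zero before onset and deterministic.

**DCE phantom.**  ROI voxels draw behaviour labels from the configured
class fractions (multinomial, seeded; defaults 0.22/0.20/0.20/0.38 for
persistent/plateau/washout/none, reflecting that roughly a third of tumour
voxels in this setting are non-enhancing).  "None" voxels keep Ktrans =
vp = 0 and a flat curve.  Enhancing voxels draw (Ktrans, ve, vp) uniformly
from the *global* configured ranges (defaults 0.05–0.8 min⁻¹, 0.08–0.9,
0–0.15) and are rejection-sampled until the induced noiseless enhancement
curve *earns* the label.  The label rules keep the 10 % washout boundary
convention (washout: final value > 10 % of maximum below the maximum;
plateau: maximum reached, decline ≤ 10 %; persistent: monotone
non-decreasing, no maximum reached), but sampling applies stricter margins
so curves sit away from the decision boundary and labels are unambiguous
test oracles: washout requires a ≥ 15 % relative *and* ≥ 0.20 absolute
fall (a fall must dwarf the σ0 floor to be detectable in principle);
plateau requires ≤ 5 % decline, a flat last quarter (≤ 2 % rise) and 95 %
of maximum reached within 65 % of the window; persistent requires strict
monotonicity, a ≥ 8 % last-quarter rise and a late slope at least 90 % of
the mid-curve slope (no plateau forming).  Enhancing classes must peak at
≥ 2× the non-enhancement threshold.  A class-specific kinetic pre-filter
skips draws that cannot pass (a superset of the accepting region; the shape
rule always decides).  Tissue signal is the SPGR forward conversion of the
Tofts curve at the fixed tissue T1 (baseline level 200 signal units); the
blood-pool signal uses the blood T1 and whole-blood concentration
Cp·(1 − Hct).  Noise is additive Gaussian on the magnitude signal, sd 5 by
default (SNR ≈ 40 at baseline).

**DWI phantom.**  ADC is uniform over the configured range (default
1.0–2.5 × 10⁻³ mm²/s, the renal-tumour regime) inside the ROI; noiseless
signals obey the mono-exponential law exactly (S0 = 1000 by default).

**CT tables.**  Baseline axes are integers in 15–75 mm; follow-ups scale
all axes by (1 + target)^⅓ and round to integer millimetres, interpolating
intermediate timepoints linearly in volume change.  Entries whose rounded
change misses the target by > 5 percentage points are flagged.

**Longitudinal cohorts.**  The cohort generator writes a pipeline-ready
workspace (12 patients × 3 MRI sessions + CT table) and can inject monotone
trends: per-patient volume-change targets are evenly spaced over −85 % to
+90 %, and the washout fraction (span 0.8), the Ktrans upper bound (gain
0.8) and the ADC range (shift 0.8 × 10⁻³ mm²/s) shift with the patient's
position in the volume-change ordering, split symmetrically between the
baseline and second follow-up scan so no class fraction needs clipping.
Only the Ktrans *upper* bound shifts, keeping the slow-uptake corner of
parameter space reachable in every scan.

**What the phantoms do not emulate** — hence what passing tests do and do
not show: no respiratory motion or registration error (inputs are assumed
motion-corrected), no coil inhomogeneity or k-space artefacts, Gaussian
rather than Rician noise (the distinction is small at the simulated SNRs
but real at low signal), no papillary-RCC enhancement, no partial-volume
boundary voxels, and signal generated by the same SPGR/Tofts forward
models the analysis inverts — recovery tests therefore validate the
numerics and the inference machinery, not the physiological fidelity of
the models themselves.  The original study reports no noise or SNR
figures, so phantom noise defaults are stated, not calibrated.

## Numerical choices and degenerate inputs

* Piecewise search: breakpoints on frame times; unconstrained per-candidate
  linear solves with sign post-checks; exhaustive enumeration is O(n³)
  candidates but each solves all voxels at once (a 4 000-voxel, 30-frame
  phantom classifies in a few seconds).
* Tofts fitting: tolerances 1e-14; on noiseless self-consistent data the
  recovered parameters are exact to ~1e-12 relative.  ve is reported but
  poorly identified when Ct ≡ 0 (flagged via near-zero Ktrans and vp).
* SPGR inversion failures (signal implying E1 outside (0,1)) are flagged per
  frame, not fatal; non-positive baselines mark the voxel unanalysable.
* Spearman with constant input raises; correlation cells below n = 4 are
  absent with a reason string.
* All file writes are atomic (temp-then-rename); outputs carry no
  timestamps, so identical (config, seed) reruns are byte-identical.

## Problem sizes used in the validation experiments

Classification recovery uses a 32×32×12 grid (≈ 4 300 ROI voxels,
noiseless, equal class mix); Tofts recovery a 20×20×5 grid (720 ROI voxels,
plateau/washout mix so vp is bounded away from zero and every relative
error is well-defined; the persistent corner is covered separately by a
3×3×3 forward-model grid test); ADC recovery a 22×22×8 grid (≈ 1 370 ROI
voxels); the cohort experiment 12 patients × 3 scans on 10×10×5 grids.
These sizes give stable statistics while keeping a full validation run in
the minutes range on one CPU.

## Known limitations

* The max-axis RECIST rule and the fixed-T1 SPGR conversion are documented
  approximations to under-specified clinical procedure.
* The BIC variance floor is a principled but package-specific resolution of
  an under-determined model-selection rule.
* Percentages, volumes and correlations are validated against the published
  cohort table; the voxelwise DCE/DWI machinery is validated only against
  synthetic ground truth.
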