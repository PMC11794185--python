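# Methods

`ctisim` implements the model chain behind electrodeless low-frequency
conductivity estimation from diffusion micro-structure MRI, together with a
synthetic cohort generator and the ROI-level statistics used to compare the
predictions of three diffusion models. This note records the models, the
tunable parameters, the numerical choices, and what the synthetic data can
and cannot show.

## The conductivity relation

Conductivity tensor imaging (CTI) relates the low-frequency conductivity of
tissue to its diffusion properties. Per voxel, given the extracellular
volume fraction α, direction-averaged intra- and extracellular diffusivities
d_i and d_e (mm²/s), and a high-frequency conductivity σ_H (S/m),

    η   = α σ_H / (α d_e + β (1 − α) d_i)
    σ_L = η d_e

where β is the ratio of intracellular to extracellular ionic
concentrations. With nonnegative inputs, 0 ≤ σ_L ≤ σ_H holds algebraically,
with equality when α = 1 or d_i = 0; σ_L is nondecreasing in α and d_e and
nonincreasing in d_i and β. These identities are asserted by randomized
tests.

**β (default 0.41, dimensionless).** β is not measurable from diffusion
data. The default follows the CTI literature this pipeline builds on
(Sajib et al.); because it rescales every model's predictions the same way,
model *comparisons* are insensitive to it, while absolute σ_L values are
not. It is a required, explicit field of every run configuration and is
recorded in the output manifest.

**Denominator floor (default 1e-12 mm²/s).** Voxels where
α d_e + β(1−α) d_i falls below the floor (e.g. fully intracellular voxels)
are masked rather than allowed to produce unbounded η.

## High-frequency conductivity σ_H

Instead of a measured electric-properties-tomography map, σ_H is modeled:
each tissue class (gray matter, white matter, CSF) receives the
conductivity predicted by the Gabriel parametric dielectric model — a
four-term Cole-Cole dispersion plus an ionic term,

    ε̂(ω) = ε_∞ + Σ_k Δε_k / (1 + (iωτ_k)^(1−a_k)) + σ_i/(iωε₀),
    σ(ω) = −ω ε₀ Im ε̂(ω),

evaluated at the 3 T Larmor frequency (taken literally as 128 MHz). The
packaged Gabriel brain-tissue coefficients evaluate to 0.5867 / 0.3422 /
2.1430 S/m (GM / WM / CSF) at 128 MHz. The per-class values assigned by the
atlas painter at the default frequency are the conventional reference
numbers 0.5864 / 0.3420 / 2.1429 S/m; the dispersion evaluation agrees with
these to about 3×10⁻⁴ S/m, and the dispersion path is used verbatim at any
non-default frequency. Both paths are exposed (`cole_cole_sigma`,
`class_values`) so the approximation is auditable.

## Model adapters

All three adapters emit the same triplet (α, d_i, d_e) plus a validity
mask. Diffusivities are stored in mm²/s throughout; values quoted in
μm²/ms are numerically 10⁻³ mm²/s and converted at the boundary. Inputs
slightly outside their physical range (a routine feature of fitted real
maps) are clipped with a warning rather than rejected; NaNs propagate to
the mask.

### NODDI

Parameters: neurite fraction f_i, orientation dispersion index ODI,
isotropic fraction f_iso; fixed intrinsic stick diffusivity
d_∥ = 1.7×10⁻³ mm²/s and isotropic diffusivity d_iso = 3.0×10⁻³ mm²/s.
The orientation chain is

    κ = 1 / tan(π ODI / 2),
    τ(κ) = −1/(2κ) + 1/(2√κ · D(√κ)),   D = Dawson function,

where τ = E[cos²θ] under the Watson distribution, running from 1/3
(isotropic) to 1 (coherent). The τ implementation is validated against
direct numerical quadrature of the Watson integral to 10⁻⁶. Below
κ = 10⁻⁶ the series 1/3 + 4κ/45 avoids catastrophic cancellation; κ is
capped at 10⁶ as ODI → 0 (τ is within 10⁻³ of 1 long before the cap, so
the cap has no effect at output precision).

The conversion then computes a scaled parallel diffusivity
d_i∥ = f_i (1 − f_iso) d_∥, sets d_i = d_i∥/3 (sticks have zero
perpendicular diffusivity), applies the tortuosity expressions
d_e∥ = d_i∥(1 − f_i(1−τ)) and d_e⊥ = d_i∥(1 − f_i(1+τ)/2), and mixes the
extracellular-matrix mean with the free-water compartment:

    α  = f_iso + (1 − f_iso)(1 − f_i)
    d_e = [(1−f_iso)(1−f_i) d_ecm + f_iso d_iso] / α.

The mixing weights sum to 1 whenever α > 0; α = 0 voxels are masked.

**`noddi_scaling` switch.** Pre-scaling the tortuosity base by
f_i(1 − f_iso) is one published convention; canonical NODDI tortuosity uses
the unscaled d_∥. Both are implemented (`"scaled"`, the default, and
`"canonical"`); the scaled form compresses d_e wherever neurite density is
low. The choice is recorded in output provenance.

### SANDI

Parameters: extracellular fraction f_e, intra-neurite fraction f_in (of
the intracellular space), neurite diffusivity D_in, extracellular
diffusivity D_ec; fixed soma diffusivity D_is = 3×10⁻³ mm²/s. Conversion:

    α = f_e,  d_i = (1 − f_e)(f_in D_in + (1 − f_in) D_is),  d_e = f_e D_ec.

The (1 − f_e) scaling of d_i and the f_e prefactor on d_e follow the source
convention of this analysis chain and are applied as stated; the pure
compartment mixture would omit them. They are flagged in the manifest's
interpretation notices.

### SMT

Parameters: intra-neurite fraction f_in, intrinsic diffusivity D_in,
extra-neurite microscopic mean diffusivity D_e. The intra-neurite space is
identified with the intracellular space:

    α = 1 − f_in,  d_i = f_in D_in,  d_e = D_e.

The α and d_e assignments are the direct completion of the fraction
mapping; they are listed in the interpretation notices rather than silently
assumed.

### Generic compartment reduction

`cti_alpha_de` implements the three-compartment reduction used when a
fitted model distinguishes an extracellular matrix from extracellular
water: α = (f_ecm + f_ecw)/(f_ecm + f_ecw + f_i) and d_e the
volume-weighted mean of d_ecm and d_ecw (d_ecw fixed at 3×10⁻³ mm²/s).
Voxels with no extracellular space return a masked d_e.

## The synthetic phantom

The phantom emulates a registered, atlas-labeled cohort: three nested
ellipsoids (CSF shell, gray-matter shell, white-matter core) on an
identity-scaled pseudo-MNI grid (default 64³, 1 mm voxels), with 25 blocky
ROIs: genu/body/splenium corpus-callosum segments, a cingulum pair, an
inferior/superior cerebellar-peduncle pair, bilateral amygdala, pallidum,
putamen, thalamus, hippocampus (subdivided into CA1 / CA2-3 / CA4DG
subfields, with the whole hippocampus available as a composite ROI),
anterior/posterior cingulate and pre/postcentral strips. Left/right ROIs
are exact mirror images along the first axis, so partners are
voxel-count-equal by construction; midline ROIs are symmetrised in place.
Grids below 16 voxels per axis, or too small to give every ROI at least two
voxels per axis, raise a sizing error naming the first ROI that failed.

Per-subject parameter maps are drawn i.i.d. per tissue class from
truncated normal distributions (inverse-CDF sampling, exact and fully
vectorised), truncated to each parameter's physical range. The default
distributions (e.g. NODDI WM f_i 0.60±0.05, GM f_i 0.40±0.05; SMT WM f_in
0.65±0.05, GM 0.35±0.05; SANDI GM f_e 0.45±0.05 — see
`ctisim.phantom.DEFAULT_TISSUE_PARAMS`) are plausible stand-ins chosen once
to make white and gray matter separable; they are **not** calibrated to any
fitted human cohort, and every value is overridable. Under these defaults
the pipeline reproduces the qualitative ordering reported for real
cohorts — NODDI predicts the largest conductivities, SANDI the smallest,
SMT between — but that ordering is a property of the configuration, not a
universal fact about the models.

Randomness: a master seed plus the subject index feed a `SeedSequence`
spawn key, so subject k depends only on (seed, k, spec) and cohorts of
different sizes share their leading subjects. Asymmetry injections add a
constant offset to one named ROI's voxels after sampling (re-clipped to
physical range), giving controllable left-right conductivity differences.

What the phantom does **not** model: anatomy, diffusion signal formation
and fitting noise, scanner artifacts, registration error, partial-volume
mixing at tissue boundaries, or between-subject anatomical variability.
Passing tests therefore demonstrate correctness of the conversion and
statistics machinery and its operating characteristics under clean
conditions — not agreement with human data.

## ROI statistics and equivalence testing

Per subject and ROI, the median and interquartile range of σ_L are taken
over valid voxels only (quartiles by linear interpolation between order
statistics — the common scientific-software default, fixed here for
reproducibility). All cohort-level statistics operate on the per-subject
medians. CSF conductivity is never tabulated. Normality is screened per
(ROI, model) with the Shapiro-Wilk test at α = 0.05; a zero-variance sample
is reported as non-normal with a degeneracy flag. Box-plot exports use
1.5×IQR whisker fences, labelled as such.

Paired comparisons (left/right, anterior/posterior, inferior/superior,
corpus-callosum segments) use the Wilcoxon signed-rank test on per-subject
differences:

* **difference**: two-sided test of zero median difference;
* **equivalence (TOST)**: one-sided tests against the bounds ±0.05 S/m;
  equivalence is declared when both reject at α = 0.05.

The signed-rank implementation drops zero differences, midranks ties, uses
the exact rank-sum distribution for n ≤ 25 (dynamic programming over
doubled ranks, which stay integral under midranking) and a tie-corrected
normal approximation without continuity correction above. It is validated
against brute-force enumeration of all 2ⁿ sign assignments and against an
independent library implementation. The paired reading is the default
because the compared groups are within-subject; an independent-groups
("pooled", rank-sum) mode is provided for sensitivity analysis. No
multiple-testing correction is applied across the roster, matching the
per-comparison reporting style this analysis mirrors. The two verdicts are
deliberately not exclusive: a tiny consistent offset can be detectably
nonzero yet equivalent.

Operating characteristics verified by simulation: with paired differences
i.i.d. N(0, 0.01²) at n = 199, equivalence is declared in >95% of
replicates; a constant 0.2 S/m offset yields 0% equivalence and 100%
difference; with a true offset at a bound, false equivalence claims stay
at or below α.

## Pipeline, determinism and problem sizes

`run_study`/`run_pipeline` chain phantom → adapters → σ_H → σ_L → tables →
roster. Outputs are deterministic given (config, seed), including written
NIfTI trees. All fixed constants (d_∥, d_iso, D_is, d_ecw, β, the σ_H
reference values) and the adapters' interpretation notices are surfaced in
the run manifest. The default study size used throughout the tests and
examples — 30 subjects on a 64³ grid (≈110k brain voxels per volume) — was
chosen as the smallest cohort at which the roster's verdicts are stable
across seeds; a full study at this size runs in well under a minute on one
CPU.

## Known limitations

* Only the isotropic scalar σ_L is computed; the tensor form C = ηD_e and
  orientation-resolved extracellular diffusivity are out of scope.
* Low-frequency CSF conductivity is deliberately not reported.
* β, and hence absolute σ_L, is assumed rather than estimated.
* The phantom's clean tissue blocks cannot exhibit partial-volume or
  registration effects, which are substantial in real ROI statistics.
* Adapters consume already-fitted parameter maps; signal-level model
  fitting is not implemented.
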