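# Methods

## Model and assumptions

The pipeline quantifies focal radioligand uptake in one limb by comparing it
voxel-wise against the contralateral limb of the same examination. The
underlying statistical model is deliberately minimal: under the null
hypothesis of no focal uptake, the emission values of the two arms are draws
from the same distribution, so expressing the whole volume in SD units of the
unaffected arm (`z = (v − μ_ref)/σ_ref`) makes "suprathreshold" voxels
(`z > 2.5`, strict) a calibrated rarity — for Gaussian voxel noise the
expected suprathreshold fraction of a null arm is the normal tail
P(Z > 2.5) ≈ 0.0062. Everything above that floor is attributed to focal
uptake and summarised as the suprathreshold volume `V` (mL), its mean Z `Z̄`,
and the Volume intensity score `VIS = V·Z̄` (mL·SD).

Assumptions worth stating explicitly:

- **The unaffected arm is a valid reference.** Systemic tracer availability,
  injected dose and global kinetics are assumed symmetric between arms within
  one session. References are never pooled across sessions, because injected
  dose varies between examinations; each before/after examination uses its
  own same-day reference.
- **One common reference for both arms.** Both the mean *and* the SD of the
  Z transform come from the unaffected arm. This is the only choice under
  which Z values are comparable between arms (each arm scaled by its own SD
  would standardise away genuine signal heterogeneity in the affected arm).
  A per-arm-SD variant is available behind the `per_arm_sd` flag for
  sensitivity analysis; in hotspot phantoms it shrinks the affected arm's Z
  values, as expected.
- **No voxel-wise multiple-comparison correction** is applied: the object of
  inference is the per-arm aggregate (volume/VIS), not any individual voxel.

## The score definition

The composite score is described in two ways that differ only by a constant:
volume times *mean* Z, or voxel volume times *summed* Z. Since
`V·Z̄ = (n·v_voxel)·(ΣZ/n) = v_voxel·ΣZ`, the implementation computes
`VIS = supra_volume_ml × supra_mean_z` and also reports `supra_sum_z`; the
identity holds to 1e-9 relative for every computed record and is asserted in
the tests. The printed units (mL·SD) and the printed per-subject scores in
the packaged reference table are consistent with the volume-times-mean-Z
reading. An empty suprathreshold set reports volume = mean Z = VIS = 0
rather than an undefined mean, matching the zero rows of the reference table.

## The packaged reference table

The per-arm results table (36 rows: 10 subjects × 2 arms before treatment,
8 × 2 after; two subjects have no after-treatment examination) ships verbatim
as `data/table2.tsv` with a `note` column flagging two apparent transcription
artefacts in the source:

- the subject-2 after-treatment rows print identical mean intensities for
  both arms;
- the subject-7 after-treatment affected row prints a score (1186.3) that no
  rounding of its printed volume (316 mL) and mean Z (5.9) can produce
  (316 × 5.9 = 1864.4). The printed score, not the reconstruction, is what
  enters the printed group means.

Reconstructing `V·Z̄` from the printed columns therefore matches the printed
score within 1.5 % relative on 32 of 36 rows; three sub-2 mL rows miss only
through coarse printing of the inputs (absolute discrepancies ≤ 0.04 mL·SD),
and the flagged subject-7 row is irreconcilable. Values are shipped exactly
as printed and never "corrected".

Pain is rated per arm (0–100 mm VAS), so pain lives on each arm row; the
rank correlations between pain and VIS use all 36 per-arm rows (R = 0.70)
and the 18 affected-arm rows (R = 0.30), with average ranks for ties.

## Segmentation

- **Threshold:** 2-class Otsu on the density histogram by default —
  deterministic and parameter-free; overridable by flag. The threshold must
  separate air from tissue; an all-air or single-component volume is a hard
  error, not a guess.
- **Connectivity:** 26-neighbourhood, robust to diagonal voxel chains at limb
  edges.
- **Component selection:** the two largest components of at least 100 voxels
  (configurable); the historical semi-automatic step is preserved as an
  optional pair of seed voxels selecting the components containing them.
- **No morphological closing by default**, to avoid silently changing the
  measured volumes; a closing radius can be added for noisy data.
- **Side labels** are assigned by centroid order along axis 0 (smaller
  coordinate = left) and are therefore invariant to component discovery
  order. Analyze 7.5 carries no orientation convention, so axis 0 is *defined*
  as the subject's left→right axis of the prone, arms-overhead posture; the
  affected side is operator-supplied metadata.

## The phantom generator

The generator emulates the acquisition geometry — a 128×128×63 grid at
2.0×2.0×2.46 mm spacing — with two straight circular cylinders (axis 1) of
tissue density in air. Defaults: 20 mm arm radius, 120 mm centre separation
(≈3×10⁴ voxels per arm, the magnitude of real per-arm counts), arm emission
2000 ± 500 Bq, Gaussian voxel noise, zero-mean background. The optional
hotspot is a hard sphere of uniform added amplitude expressed in SD units;
it is intersected with the affected arm's mask and its ground-truth volume is
computed from the resulting voxel count, so truth stays exact even when the
sphere is clipped. A `poisson_scaled` noise model (variance proportional to
the local mean, calibrated to the requested arm SD) exists for
sensitivity checks; Gaussian is the default because the 2.5 SD tail analysis
is Gaussian.

What the phantom does **not** emulate: scanner point-spread, attenuation,
scatter, decay, reconstruction artefacts, and realistic bent-arm anatomy.
Passing phantom tests therefore validates the *computational* pipeline —
segmentation, normalisation, extraction, scoring — not the physics of any
scanner; spatial noise correlation from reconstruction would widen the null
tail beyond 0.0062 on real data.

Tests and the acceptance script use three phantom sizes: a compact
64×32×32 grid for fast unit tests, a 36 mm-arm phantom (≥10⁵ voxels per arm)
for tail calibration, and a 40 mm-arm phantom carrying a ~151 mL, 8 SD
hotspot for recovery checks. Hotspot recovery is asserted within ±25 %: the
measured arm suprathreshold volume exceeds truth by the arm's Gaussian-tail
false positives (≈0.6 % of arm volume) and loses the hotspot voxels whose
noise pulls them under threshold (negligible at amplitude ≥ 6 SD).

## Numerical choices

- Voxel statistics use the sample SD (denominator n−1) everywhere; a
  reference region with zero SD or fewer than two voxels is a hard error.
- Threshold comparison is strict (`>`).
- Full precision is kept in all stored outputs; rounding (half away from
  zero, as printed tables round) is applied only when rendering reports and
  when comparing against printed values.
- t and F p-values come from the exact distributions, two-tailed. The arm
  contrast defaults to the paired t (arms are within-subject), but pooled and
  Welch modes are always computed alongside — the headline before-treatment
  volume contrast is below p = 0.001 in all three.
- I/O: byte order is auto-detected via the 348 sentinel and never guessed;
  an image file whose length disagrees with the header is rejected; a nonzero
  scale-factor field multiplies stored values on read (a known dialect
  divergence of Analyze 7.5).

## Known limitations

- Whole-arm fields of view only; no separation of forearm compartments.
- No kinetic modelling, SUV computation or partial-volume correction.
- The segmentation stand-in for the historical semi-automatic procedure is
  the two-largest-components rule; on data where the arms touch (single
  component) it fails loudly rather than splitting them.
- The statistics layer implements exactly the tests used by the study design
  (t, unbalanced one-way ANOVA, Spearman); no mixed models or reliability
  analysis.
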