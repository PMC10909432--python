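# Methods

## MRI signal model and phantom

The simulator uses the spoiled gradient-recalled echo (SPGR) steady state
with mono-exponential T2\* decay:

    S(TE) = PD · sin α · (1 − E1) / (1 − cos α · E1) · exp(−TE · R2*),
    E1 = exp(−TR / T1).

Default acquisition parameters emulate a 9.4 T mouse-brain MGE3D protocol:
TR = 32.55 ms, TE₁ = 2.5 ms, echo spacing 4 ms, 6 echoes
(TE = 2.5 … 22.5 ms), flip angle 13°, acquired matrix 256×192×192
zero-filled to 256³, FOV 22.5 mm isotropic. Tissue background:
R2\* = 40 s⁻¹ and T1 = 1.9 s (grey-matter-like values at high field),
uniform proton density.

The phantom is a uniform background with two disjoint spherical striatal
ROIs (ipsilateral/tumour-bearing and contralateral) and two families of
spherical ΔR2\* foci:

* *macrophage foci* (endogenous iron-laden perivascular macrophages):
  ΔR2\* = 300 s⁻¹, radius 0.4 mm, present in **both** scan states — they
  create pre-existing hypointensities that cancel in the post-minus-pre
  difference;
* *MPIO foci* (endothelium-bound particles): ΔR2\* = 500 s⁻¹, radius
  0.4 mm, present **only** post-contrast.

Susceptibility blooming is deliberately reduced to a local ΔR2\* sphere —
no dipole-field or phase simulation — because the analysis consumes
magnitude hypointensity only. ΔR2\* values were chosen so that focus cores
are driven to near-complete signal loss at the last echo
(exp(−540 s⁻¹ · 22.5 ms) ≈ 5·10⁻⁶ of background) while the background
(exp(−0.9) ≈ 0.41 of its echo-1 signal) stays well above the detection
threshold at the default SNR; overlapping foci add.

Magnitude noise is Rician: `sqrt((s+n₁)² + n₂²)` with `n₁, n₂ ~ N(0, σ)`.
SNR is defined as the noiseless contralateral-striatum mean at echo 1
divided by σ — the same region in which the detection threshold is
estimated. The in vivo SNR of such scans is not pinned down by published
protocol parameters; the default **SNR = 40** is a deliberate simulation
choice representative of 3D gradient-echo mouse imaging at high field, and
is freely configurable.

Scenario presets encode targeting specificity through the expected number
of MPIO foci per animal (Poisson-distributed): VCAM 90, RGD 30,
scrambled-peptide RDG / isotype IgG 0; the PBS vehicle preset has neither
MPIO nor macrophage foci (no tumour). Tumour-bearing presets carry a mean
of 12 macrophage foci. The mean counts implement the qualitative ordering
VCAM > RGD ≫ controls; absolute per-animal voxel counts are therefore
scale-bound (64³ grid) and are not comparable to animal data.

The default grid is 64³ with FOV-preserving 0.3516 mm voxels — a
desk-scale configuration chosen so a full pre+post simulation and
quantification runs in well under a second; the acquisition-faithful
256×192×192 matrix is available through `AcqParams`/`PhantomSpec`.

## Hypointensity statistic

Per scan: mean μ and **sample** standard deviation σ (n−1 denominator; the
convention is configurable knowledge, documented here because either
definition is defensible) over the contralateral ROI; a voxel is
hypointense iff `x < μ − k·σ` with strict inequality ("more than k SD
below") and k = 3 by default. Counting is voxelwise with no connectivity
filtering. Each scan is thresholded against its own contralateral ROI — no
inter-scan intensity normalisation — so global scanner drift between pre
and post scans cancels exactly (the statistic is invariant under affine
intensity maps `a·x + b`, `a > 0`). Reported quantities per hemisphere:
`diff_raw = N_post − N_pre` and `diff_clipped = max(diff_raw, 0)`; negative
differences are attributed to the technique's noise floor and clipped.
The analysis volume defaults to the **last echo** (TE = 22.5 ms), which
maximises T2\* contrast; single/mean/SqrtSOS echo combination is
configurable because published descriptions analyse "individual echoes"
without fixing one.

## Histology scene model

A field (default 2000×2000 μm at 0.5 μm/px) contains circular vessel
lumina (radius U(3, 8) μm, centres uniform with a hard 100 μm minimum
separation), iron-laden macrophages, and single 1 μm MPIO beads attached
just outside vessel walls. Macrophage centre-to-lumen-centre distances
follow a lognormal with median 10 μm and σ_log = ln(2.5)/z₀.₉ = 0.715, so
the 90th percentile is 25 μm — the two quantiles reported for perivascular
macrophages fix both parameters, and the lognormal is the natural
two-parameter family with positive support. Placement draws each
macrophage's distance **once** and resamples only the parent vessel and
angle on disc collisions, so the hard-core non-overlap constraint cannot
distort the distance distribution; because vessels are ≥100 μm apart and
P(r > 50 μm) ≈ 0.01, the parent lumen is the nearest one for essentially
every macrophage and realised nearest-centre distances follow the
calibrated law. Iron areas are U(5, 15) μm² — large enough to dominate the
single-bead area (π/4 μm²) by ≥6×, small enough that disjoint placement is
geometrically feasible in the crowded small-distance annulus around each
vessel.

Rendering mimics Perls' Prussian blue with nuclear fast red counterstain
and DAB-brown vessel staining: iron → blue discs, vessel walls → brown
annuli (2 μm), background → pink. Discs are rasterised by pixel-centre
distance, so painted areas converge to true disc areas as pixel size
shrinks (a 1 μm bead needs ≤0.25 μm/px to be area-accurate; at the default
0.5 μm/px it covers 5 pixels and is still classified correctly).

What the generator does *not* emulate: stain intensity variation and
chromogen mixing, section thickness and out-of-plane effects, non-circular
lumina and vessel branching, clustered (non-Poisson) macrophage
recruitment, tissue texture and artefacts. Passing tests therefore
demonstrate correctness of the measurement operators under the stated
geometric model, not robustness to real-slide appearance.

## Histology quantification choices

* Blue-class pixels: `B − max(R, G) ≥ margin` (default 30); a simple,
  configurable colour rule — no stain deconvolution.
* Blob classification: aggregation iff area ≥ 2 × bead area (tie →
  aggregation); 2× is the smallest area inconsistent with one bead and is
  configurable.
* Distances are 2D centre-to-centre against ground-truth lumen centres
  (the synthetic pipeline uses centroids as "centres"); lumen radius is not
  subtracted. Nearest-neighbour queries use a k-d tree; tests verify
  against an exhaustive all-pairs oracle.
* Cumulative distance histogram bin width: 5 μm.
* Positive-pixel intensity: Rec.601 luma (0.299R + 0.587G + 0.114B) on
  0–255; the windows themselves — moderate [185, 202] inclusive, strong
  < 10 strict — are implemented verbatim; the proprietary hue/saturation
  logic of whole-slide PPC software is not reproduced.

## Numerical and degenerate-input behaviour

* Noiseless uniform contralateral ROI ⇒ σ = 0 and the threshold equals the
  mean; the strict inequality then flags only true signal deficits, making
  noiseless end-to-end counts exact (verified against a brute-force
  per-voxel oracle).
* Zero-fill uses a centred-DC, floor-split padding convention
  (`before = (target − source)//2`) and the image-domain variant rescales
  by the matrix-size ratio so amplitudes are preserved; crop-back is an
  exact inverse.
* Empty ROIs, overlapping hemisphere masks, grid mismatches, non-positive
  T1/TR/σ, vessel-free scenes with macrophages, and fields too small to
  host the requested objects all raise `ValueError` rather than degrade.
* All generators are pure functions of (spec, seed): identical inputs give
  bit-identical outputs.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run desk-scale problems chosen
as the package's own study conditions: 64³ phantoms, cohorts of 20
simulated animals per scenario preset, and 20 histology fields of 500
macrophages around 60 vessels (10 000 pooled distance measurements). At
these sizes the pooled median recovers the calibrated 10 μm to within a
few percent and the within-25 μm fraction sits at 90% ± ~0.6 pp
(Monte-Carlo).

## Known limitations

* The hypointensity statistic is count-based and scale-bound: absolute
  voxel counts depend on grid resolution and focus geometry, so only
  within-configuration comparisons (scenario orderings, noise floors) are
  meaningful.
* No tumour segmentation: ROI masks are inputs, as in manual workflows.
* No group-level inferential statistics (ANOVA, t-tests, regressions) —
  standard tooling handles those downstream of the cohort table.
* The renderer's idealised colours make colour-class segmentation nearly
  noise-free; margin sensitivity on real stains is untested.
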