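# mpioquant

Quantification of microparticle-of-iron-oxide (MPIO) binding in
T2\*-weighted brain MRI, and of perivascular iron in Prussian-blue
histology — with seed-controlled synthetic generators for both modalities.

Targeted MPIO (~1 μm) bind endothelial markers (e.g. integrin αvβ3 via RGD
peptides, or VCAM-1 via antibodies) on brain-metastasis vasculature and
cause focal signal voids ("blooming") on T2\*-weighted multi-gradient-echo
(MGE3D) images. Two confounds complicate quantification: tumours carry
pre-existing hypointensities from endogenous iron-laden perivascular
macrophages, and magnitude images carry Rician noise. This package
implements the standard analysis for that setting, for imaging scientists
who want a tested, reproducible version of it:

* **MRI arm** — square-root-of-sum-of-squares (SqrtSOS) reconstruction and
  k-space zero-filling; a voxel is *hypointense* when its intensity `x`
  satisfies `x < μ_contra − k·σ_contra` (strict; `k = 3`) with `μ, σ`
  estimated from a contralateral-striatum ROI of the same scan; the
  MPIO-induced burden is `max(N_post − N_pre, 0)` per hemisphere — the
  post-minus-pre difference of hypointense-voxel counts, clipped at zero.
  A control-cohort helper estimates the noise floor (mean ± SD of control
  differences, and as a fraction of the contralateral ROI).
* **Histology arm** — segmentation of the Prussian-blue (ferric iron)
  colour class into blobs; area-based classification into single MPIO
  vs iron aggregations (macrophage-internalised iron); nearest
  vessel-lumen-centre distance statistics (median, fraction ≤ 25 μm,
  cumulative histogram); MPIO per mm² endothelium; per-field-of-view
  counts; positive-pixel area fractions with fixed intensity windows
  (moderate [185, 202], strong < 10 on 0–255).
* **Synthetic generators** — an SPGR/MGE3D phantom simulator
  (`S(TE) = PD·sin α·(1−E1)/(1−cos α·E1)·e^{−TE·R2*}`, `E1 = e^{−TR/T1}`,
  Rician noise) with scenario presets (VCAM, RGD, scrambled RDG, IgG, PBS)
  whose MPIO focus counts encode targeting specificity, and a 2D histology
  scene generator whose macrophage-to-lumen distances follow a lognormal
  calibrated to a 10 μm median and a 25 μm 90th percentile.

See `docs/methods.md` for models, parameters and limitations.

## Worked example

Simulate five RGD-targeted animals (64³ desk-scale phantoms, SNR 40) and
quantify them end to end:

```bash
mpioquant run --scenario RGD --seed 7 --n-animals 5
```

prints (abridged):

```json
{
 "config_hash": "484da1429ec6377b",
 "contra_roi_voxels": 2132,
 "ipsi_diff_clipped_mean": 189.6,
 "ipsi_diff_raw_mean": 189.6,
 "ipsi_diff_raw_sd": 38.2,
 "n_animals": 5,
 "seed": 7
}
```

i.e. RGD-MPIO binding produces on average 189.6 MPIO-induced hypointense
voxels in the tumour-bearing striatum (≈9% of the 2132-voxel contralateral
ROI at this desk scale). The scrambled-peptide control run
(`--scenario RDG`, same seed) yields a mean of 1.4 clipped voxels with a
raw-difference noise floor of 0.0 ± 4.1 — binding signal is absent and only
threshold noise remains.

The same stages are available programmatically
(`mpioquant.run_pipeline`, `mpioquant.hypo`, `mpioquant.histo`,
`mpioquant.synth`) and as separate CLI steps: `mpioquant simulate
mri|histo`, `mpioquant recon`, `mpioquant quantify-mri`,
`mpioquant quantify-histo`.

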