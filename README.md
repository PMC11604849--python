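# facmri

Fatty-acid-composition (FAC) MRI of adipose tissue: an end-to-end
implementation of accelerated chemical-shift-encoded mapping of the
proton density fat fraction (PDFF) and the saturated (SFA),
monounsaturated (MUFA) and polyunsaturated (PUFA) fat fractions from
multi-echo golden-angle radial acquisitions.

The package is aimed at quantitative-MRI researchers who want to
design, simulate and reconstruct this kind of acquisition without
scanner data: it provides the acquisition schedule (interleaved 16-TE
dual echo trains, constant-signal variable flip angles, golden-angle
stack-of-stars projection angles), a digital oil-emulsion phantom
simulator with known ground truth, a reconstruction chain
(gradient-delay correction, coil compression, density-compensated
gridding, sensitivity-based coil combination, locally-low-rank
denoising by adaptive singular value hard thresholding), and the
voxelwise variable-projection (VARPRO) fit of the nine-resonance
triglyceride signal model.

## Model

A voxel's multi-echo signal is

    y(t_n) = (W + Σ_m ρ_m e^{i 2π f_m t_n}) e^{i 2π ψ t_n} e^{iφ} e^{−R2* t_n}

where the nine triglyceride resonance magnitudes ρ_m are affine in the
mean-triglyceride parameters (cl, ndb, nmidb).  Writing the fat signal
as subcomponents proportional to the triglyceride count, ndb and
nmidb gives a model linear in x = (W, Fntg, Fndb, Fnmidb); for fixed
confounders (ψ, R2*, φ) the real amplitudes and the initial phase have
closed forms, and the confounders are found on a discrete grid with
spatial smoothness of the ψ map resolving the water–fat ambiguity.
Composition follows as ndb = |Fndb|/|Fntg|, nmidb = |Fnmidb|/|Fntg|,
UFA = (ndb−nmidb)/3, PUFA = nmidb/3, MUFA = UFA−PUFA, SFA = 1−UFA, and
PDFF = F/(F+W) with F = Fntg+Fndb+Fnmidb in proton-density units.

See `docs/methods.md` for the full model, numerical choices and
limitations.

## Worked example

Simulate the oil-emulsion phantom, reconstruct and fit it, and print
the recovery statistics:

```python
from facmri import run_phantom_study

res = run_phantom_study(seed=3, grid=80, n_spokes=126, snr=100.0)
print(res.vial_table[["vial", "true_pdff", "meas_pdff",
                      "true_ndb", "meas_ndb"]].head(4))
print("ndb slope:", round(res.ndb_regression["slope"], 4),
      " r:", round(res.ndb_regression["r"], 5))
print("PDFF MAE [pp]:", round(res.pdff_mae_pp, 2))
```

```
   vial  true_pdff  meas_pdff  true_ndb  meas_ndb
0     0   0.249380   0.239058       0.3  0.304535
1     1   0.499173   0.462405       0.3  0.190202
2     2   0.749379   0.732328       0.3  0.235919
3     3   1.000000   0.995022       0.3  0.322425
```

```
ndb slope: 0.9936  r: 0.9999
PDFF MAE [pp]: 1.3
```

Each row is one vial of the 5-oil × 4-concentration layout: the fitted
per-vial mean PDFF tracks the nominal value from the volumetric
oil/water conversion, and the regression of fitted against true double
bond counts over the pure-oil vials has slope ≈ 1 with r > 0.999 —
the desk-scale analogue of physical phantom validation.

The same steps are available from the shell:

```bash
facmri simulate --seed 7 --grid 64 --out phantom.h5
facmri recon phantom.h5 --sensitivities oracle --out recon.h5
facmri fit recon.h5 --cl 17.4 --ratio 0.26 --out maps/
facmri roi-stats maps/ --rois rois.nii.gz --out stats.csv
```

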