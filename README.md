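# psfrc — a digital sphere-phantom lab for PET resolution-modeling artifacts

Point-spread-function (PSF) reconstruction — iterative PET reconstruction
whose system model includes the scanner's resolution blur — sharpens images
and boosts lesion detectability, but for *sub-centimeter* objects it
introduces quantification artifacts: Gibbs-type edge overshoot that drives
recovery coefficients above 1, a recovery-versus-size curve that peaks
around 8 mm instead of falling monotonically, slowed convergence, and
poorer reproducibility. These artifacts can invert apparent treatment
response when small lesions are monitored with SUV-type measures.

`psfrc` reproduces this phenomenology entirely in silico, for physicists
and method developers who want a controlled, fully synthetic testbed:

1. **Phantom** (`psfrc.phantom`) — twelve wall-less gel spheres (3–12 mm
   diameter) of uniform ¹⁸F concentration strung along a line inside a
   250-mL ¹¹C background, plus a large ¹⁸F reference source. Because ¹¹C
   (T½ = 20.36 min) decays ~5.4× faster than ¹⁸F (T½ = 109.77 min), the
   true sphere-to-background ratio sweeps 1:1 → ~15:1 over ten 10-minute
   frames by decay alone.
2. **Acquisition** (`psfrc.acquisition`) — isotropic Gaussian system blur
   (4.5 mm FWHM), slice-wise 2D parallel-beam projection with an exact
   sparse adjoint, Poisson counts scaled to the frame activity. Scatter,
   attenuation and randoms are treated as already corrected; no TOF.
3. **Reconstruction** (`psfrc.reconstruction`) — OSEM/MLEM,
   `x ← x/s · Bᵀ(y/Bx)` with `s = Bᵀ1`, where `B = P` (no PSF) or
   `B = P∘G` with an image-space Gaussian kernel `G` (PSF modeling,
   matched 4.5 mm by default); optional Gaussian post-filter after the
   final iteration. Defaults mirror clinical presets: 16 subsets without
   PSF, 21 with.
4. **Quantification** (`psfrc.metrics`) — per-sphere VOIs of the physical
   diameter; metrics `A_max`, `A_50bg` (mean above the background-corrected
   50% isocontour `T = bg + 0.5·(A_max − bg)`), and `A_avg`; recovery
   coefficients `RC = A / A_true` with the true concentration read from a
   6-mL reference VOI (and background from a 15-mL VOI), exactly as a
   physical scan is analyzed.
5. **Experiments** (`psfrc.pipeline`) — contrast sweep, iteration sweep,
   noise reproducibility, monotonicity diagnostics and the
   minimal-artifact-suppressing post-filter scan, each returning tidy
   pandas tables.

## Worked example

Recovery at a true sphere-to-background ratio of ≈ 8:1, with and without
resolution modeling (reduced study phantom, one sphere per diameter):

```python
from psfrc import ExperimentConfig, ReconParams, study_phantom
from psfrc.pipeline import run_contrast_sweep

phantom, grid = study_phantom()
cfg = ExperimentConfig(
    phantom=phantom, grid=grid, seed=1,
    recon_params=(
        ReconParams(iterations=4, psf_modeled=False, postfilter_fwhm=2.0),
        ReconParams(iterations=4, psf_modeled=True, postfilter_fwhm=2.0),
    ),
)
table = run_contrast_sweep(cfg, frame_indices=[7])  # true ratio ~ 8:1
print(table.pivot_table(index="diameter", columns="recon", values="rc_50bg").round(2))
```

```
recon     nopsf-i4-s16-f2  psf-i4-s21-f2
diameter
3.0                  0.18           0.21
4.0                  0.25           0.35
6.0                  0.37           0.66
8.0                  0.55           1.10
10.0                 0.67           1.14
12.0                 0.72           0.99
```

Without PSF, RC_50bg falls monotonically as spheres shrink — the familiar
partial-volume behavior. With PSF the curve is non-monotonic: the 8–10 mm
spheres overshoot past 1 while the 12-mm sphere reads *lower* than the
10-mm one, so a tumor shrinking from 12 to 8 mm would appear to *gain*
uptake. Wider post-filters (≥ 3–4 mm here) restore monotonicity at the
cost of resolution (`find_minimal_restoring_filter`).

A command-line interface mirrors the library:

```bash
psf-rc-lab simulate --frames 10 --out runs/sim
psf-rc-lab reconstruct runs/sim/frame07.npz --psf --iterations 4 --out runs/psf.nii.gz
psf-rc-lab analyze runs/psf.nii.gz --phantom runs/sim/phantom.yaml --out runs/rc
psf-rc-lab experiment iteration-sweep --out runs/sweep --plots
```

## Layout

- `src/psfrc/` — library (`decay`, `grid`, `phantom`, `acquisition`,
  `reconstruction`, `metrics`, `pipeline`, `io`, `cli`)
- `docs/methods.md` — models, assumptions, numerical choices, limitations
- `tests/` — unit, property and end-to-end phenomenology tests
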