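# bootpet

Self-supervised (bootstrap-optimized) MAPEM reconstruction for low-count
emission tomography, with an MR-guided Bowsher prior, the clinical-standard
MLEM baseline, a synthetic PET/MR brain phantom, and objective image-quality
evaluation.

## The problem

PET images reconstructed with maximum-likelihood expectation-maximization
(MLEM) degrade badly when the injected dose — and hence the count level — is
reduced: the ML estimate fits the Poisson noise, and noise is amplified with
iterations. Penalized (MAP-EM) reconstruction controls this with a smoothing
prior of strength β, but β normally has to be tuned per dataset, which blocks
clinical use. The self-supervised approach removes that burden: at each
iteration the measured sinogram is bootstrap-resampled, and β is chosen so
that the *regularized* update computed from the bootstrapped counts best
matches the *unregularized* update computed from the original counts. Since
the only systematic difference between the two updates is the resampling
noise, the selected β is the regularization needed to compensate for noise —
no training data, no user-set hyperparameter. The chosen β is then used to
update the image from the original measured data.

## The model

Counts y follow a Poisson model with expectation **A**θ, where θ is the
activity image and **A** = **P**·**G** a parallel-beam projector composed
with an isotropic image-space Gaussian PSF. MLEM iterates

    θ ← (θ / s) · Aᵀ(y / Aθ),   s = Aᵀ1.

MAP-EM maximises L(θ) − β·U(θ) with the isotropic quadratic penalty

    U(θ) = ¼ Σ_j Σ_{k∈N_j} w_jk (θ_j − θ_k)²

over 3×3(×3) neighbourhoods, solved by De Pierro's modified EM (separable
surrogate, closed-form nonnegative voxel update, provably monotone for
symmetric nonnegative weights). The *unguided* variant uses uniform weights
(1/27 in 3-D, 1/9 in 2-D). The *MR-guided* variant computes bilateral weights
from a co-registered MR image,

    w_jk = exp(−‖f_j − f_k‖²/2σ_f²) · exp(−‖r_j − r_k‖²/2σ_s²),

with features normalised to unit SD per element (σ_f = 1, σ_s = 4 mm), keeps
the 7 largest weights per voxel (Bowsher's largest-value sparsification) and
symmetrises. Smoothed variants apply a 4.5 mm post-reconstruction Gaussian;
the MLEM baseline runs 63 iterations with a 2.5 mm modelled PSF and a 4 mm
post-filter, matching clinical practice.

## Worked example

```python
import bootpet as bp

pair = bp.make_phantom(bp.PhantomSpec(), seed=0)          # activity + MR + labels
geom = bp.Geometry()                                      # 60 angles x 95 bins
scanner = bp.build_system(geom, psf_fwhm_mm=4.5)          # true resolution
sino = bp.simulate_acquisition(pair.activity, scanner, total_counts=2_000_000, seed=1)
low = bp.thin_counts(sino, 0.05, seed=2)                  # 5% dose level

w = bp.bowsher_weights(bp.normalize_features(pair.mr), bp.GuidanceParams(),
                       pair.spacing_mm)
cfg = bp.ReconConfig(n_iterations=200, post_smooth_fwhm_mm=4.5,
                     record_objective=False)
res = bp.SelfSupervisedMAPEM(low, scanner, w, cfg).fit(seed=3)
print(res.summary())
```

```
SelfSupervisedMAPEM reconstruction
==================================
iterations:        200
PSF FWHM:          4.5 mm
post-smooth FWHM:  4.5 mm
image total:       832.2
counts total:      99883
final beta:        0.02976
median beta:       0.1048
```

The β trace is the method's output of interest: it is selected automatically
every iteration (larger when the data are noisier) and is available as
`res.beta_trace`. Comparing against the MLEM baseline on the same 5% data
with `bp.compute_metrics` (NRMSE against the known phantom, grey/white CNR,
caudate–putamen separation, white-matter CoV):

```
guided nrmse=0.328 cnr=4.72 cp=4.49 cov=0.400
mlem   nrmse=0.344 cnr=4.49 cp=4.05 cov=0.372
```

i.e. at a 5% count level the MR-guided self-supervised reconstruction
recovers the phantom more accurately than clinical-standard MLEM and
separates the caudate and putamen more clearly.

A command-line pipeline wraps the same steps:

```bash
bootpet run-all --outdir out --seed 0            # simulate + all methods + metrics
bootpet simulate --outdir out --count-level 0.05
bootpet reconstruct --sinogram out/sino_thinned --method mapem_guided \
        --mr out/mr.nii --outdir out
bootpet evaluate --image mlem out/mlem.nii --truth out/activity.nii \
        --labels out/labels.nii --outdir out
```

## Layout

- `bootpet.phantom` — synthetic PET/MR brain phantom, Poisson acquisition,
  binomial count thinning
- `bootpet.projector` — parallel-beam system model with image-space PSF,
  Gaussian smoothing
- `bootpet.recon` — MLEM / fixed-β MAPEM models, quadratic penalty,
  De Pierro update
- `bootpet.selfsup` — sinogram bootstrap and per-iteration β selection
- `bootpet.weights` — uniform and MR-guided (Bowsher) weight maps
- `bootpet.metrics` — quality proxies, Wilcoxon signed-rank, Spearman ρ
- `bootpet.experiments` — the replicated method×dose study
- `bootpet.cli` / `bootpet.io` — command-line pipeline and file formats

See `docs/methods.md` for the scientific details and design choices.
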