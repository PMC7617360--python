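# Methods

## Data model and reconstruction

Binned coincidence counts y are modelled as independent Poisson variables
with expectation **A**θ, θ ≥ 0 the activity image. The system operator
factorises as **A** = **P**·**G**: **P** is a 2-D parallel-beam ray-driven
projector (equally spaced sample points at half-voxel steps, bilinear
interpolation, line integrals in mm) assembled once as a sparse matrix, and
**G** is an isotropic image-space Gaussian modelling scanner resolution.
The backprojector is the exact adjoint **G**·**Pᵀ** — **G** is symmetric
under zero-padded convolution — so ⟨**A**x, y⟩ = ⟨x, **Aᵀ**y⟩ holds to
machine precision, which is what the EM convergence theory assumes. Voxels
whose sensitivity s = **Aᵀ**1 falls below 10⁻⁶ of its maximum are outside
the field of view and are excluded from updates and metrics.

MLEM is the standard multiplicative ascent. The penalized objective is
L(θ) − β·U(θ) with the isotropic quadratic penalty
U(θ) = ¼ Σ_j Σ_{k∈N_j} w_jk (θ_j − θ_k)². No closed-form M-step exists, so
the MAP update uses De Pierro's modified EM: the convexity bound
(θ_j − θ_k)² ≤ ½(2θ_j − θ_jⁿ − θ_kⁿ)² + ½(2θ_k − θ_kⁿ − θ_jⁿ)² yields a
separable surrogate whose per-voxel stationarity condition is the quadratic

    2βW_j θ² + (s_j − βS_j) θ − s_j θ_j^EM = 0,
    W_j = Σ_k w_jk,  S_j = Σ_k w_jk (θ_jⁿ + θ_kⁿ),

whose unique nonnegative root is the update. This was chosen over
one-step-late MAP-EM because the root is closed-form, automatically
nonnegative, reduces exactly to MLEM at β = 0, and never decreases the
penalized objective for symmetric nonnegative weights — a guarantee the test
suite asserts directly. Where β·W_j = 0 the quadratic degenerates and the EM
value is substituted. The self offset is carried in the weight map (the
uniform map stores 1/27 everywhere, as conventional) but contributes nothing
to U or the surrogate sums, since θ_j − θ_j = 0.

Division guards use ε = 10⁻¹² × max(y). The initializer is a uniform image
at (Σy)/(Σs) on the field of view: scale-matched and reproducible.

## Guidance weights

The unguided penalty uses uniform weights 1/3^d over the full 3^d
neighbourhood; out-of-bounds neighbours at edges are dropped without
renormalisation. The MR-guided weights are bilateral products of a feature
kernel (σ_f = 1 on SD-normalised MR intensities) and a spatial kernel
(σ_s = 4 mm, distances in mm via the voxel spacing). Per voxel the 7 largest
weights among the in-bounds non-self neighbours are kept (largest-value
sparsification, the Bowsher construction); ties are broken by lexicographic
offset order so runs are reproducible. Boundary voxels keep all their
in-bounds candidates when fewer than 7 exist; n_keep larger than the interior
neighbourhood is rejected. After sparsification the map is symmetrised,
w ← (w + wᵀ)/2, because the De Pierro monotonicity guarantee requires
symmetric weights; the asymmetric Bowsher original is available via
`symmetrize=False` (and is refused by the MAP-EM update, whose guarantee it
would void). Guided weights are not renormalised to unit sum. Features are
MR voxel values (one element per voxel); a multichannel extension normalises
each element independently and flags zero-SD elements instead of raising.

## Self-supervised β selection

Each iteration draws a bootstrap replicate of the measured counts —
multinomial redistribution of the N observed events over bins with
probabilities y/N, which preserves the total exactly and each bin's
expectation (a per-bin Poisson alternative is available). β is selected to
minimise the L2 distance, over field-of-view voxels, between the regularized
De Pierro update computed from the bootstrapped counts and the unregularized
EM update computed from the original counts; the discrepancy between those
two updates is attributable to resampling noise, so the minimising β is read
as the regularization needed to compensate for noise. The selected β then
updates the image from the original data; the bootstrapped data never
directly update the returned image.

The matching objective is smooth and empirically unimodal in log β, so the
search evaluates a 9-point log-spaced grid and refines by golden-section in
log β (relative tolerance 10⁻²). The bracket spans 10⁻⁴–10⁴ times a
data-scaled pivot (the β at which the penalty terms of the update quadratic
are commensurate with the sensitivity), and the exact β = 0 endpoint is
always a candidate: when no regularization fits best — e.g. when the
bootstrap equals the original data — the selection returns 0 and the
iteration is exactly MLEM. Because the EM ingredients of both updates are
independent of β, a β candidate costs only an elementwise root solve; the
whole per-iteration search adds about one forward/backprojection pair.
The bootstrap is redrawn every iteration by default (configurable).

## Synthetic phantom and acquisition

The phantom is a 2-D piecewise-constant ellipse composition on a 64×64 grid
at 2 mm: white-matter interior, grey-matter cortical rim at GM:WM = 4:1
(typical FDG contrast), a low-uptake ventricle, and a caudate and putamen at
grey-matter uptake separated by a white-matter-level band, so
caudate–putamen distinguishability is measurable. The MR image shares every
boundary but carries a different, roughly T1-like intensity ordering
(WM > cortex > caudate/putamen > ventricle), so guidance contributes
boundary information, not uptake information. Optional seeded jitter of
structure centres/sizes (SD 1.5 mm, 4%) makes replicates act as different
subjects, and an optional lesion present only in the activity image
emulates PET/MR mismatch.

Acquisition: the noiseless forward projection through the *true-resolution*
system (4.5 mm FWHM PSF) is scaled to a 2×10⁶ expected total — a realistic
single-slice FDG count — and each bin is drawn Poisson. Reduced dose is
emulated by per-bin binomial thinning at fraction p, chosen because it maps
Poisson(λ) exactly to Poisson(pλ), matching dose-reduction semantics; the
5% level is the study's low-dose condition. Reconstruction arms deliberately
differ in modelled resolution: MLEM uses a 2.5 mm kernel (the
clinical-standard under-modelling of the true resolution) with 63 iterations
and a 4 mm post-filter, while the MAPEM arms model the full 4.5 mm and run
200 iterations (scaled down from the 1000 used at clinical scale — the
β trace and ranking stabilise well before 200 on this grid), with a 4.5 mm
post-filter for the smoothed variants.

What the generator does *not* emulate: anatomically faithful atlases,
attenuation, scatter, randoms, detector normalisation, motion, and 3-D
scanner geometry. Passing tests therefore demonstrate the mathematical and
statistical behaviour of the algorithms (monotonicity, adjointness,
noise-adaptivity, method ranking under matched conditions), not clinical
image quality.

## Evaluation

Clinical reads score axes like grey/white contrast, caudate–putamen
separation and white-matter uniformity; on phantoms these are recast as
objective ROI quantities: NRMSE against the known activity, CNR =
|mean(GM) − mean(WM)|/SD(WM), CP separation =
(mean(caudate ∪ putamen) − mean(between-band))/SD(WM), and white-matter
CoV = SD(WM)/mean(WM). The ratio metrics are invariant under global positive
rescaling. A sharpness proxy is deliberately omitted: edge-gradient measures
are dominated by the synthetic phantom's geometry. Reconstructions come out
in count units (the sinogram is scaled to the count budget), so NRMSE
divides by the recorded activity→counts factor first.

Paired comparisons use a Wilcoxon signed-rank test: zero differences dropped,
mid-ranks on ties, exact two-sided p for n ≤ 12 via convolution of the
rank-sum distribution (mid-ranks doubled to integers), normal approximation
with tie correction above, without continuity correction. Spearman's ρ is
mid-ranks followed by Pearson correlation. The overall performance score
min–max rescales each metric across the compared set (error-like metrics
flipped), averages metrics per item, and summarises per method as mean ± SD
across items; with a single item the SD is reported as NaN rather than 0.

## Numerical and degenerate-input choices

- ε floor 10⁻¹²×max(y) in all ratios; zero-count bins contribute 0 to the
  EM numerator naturally.
- Zero voxels are absorbing under the multiplicative updates (by design);
  the FOV mask prevents divisions by zero sensitivity.
- A constant MR image yields a pure spatial kernel; its top-7 selection is
  then decided by the deterministic offset order.
- `simulate_acquisition` refuses an activity image that projects to zero;
  `bootstrap_sinogram` refuses a zero-total sinogram; `thin_counts` requires
  p ∈ (0, 1].
- Smoothing uses zero-padded convolution; mass conservation is only claimed
  (and tested) for interior-supported images.

## Known limitations

- The projector is 2-D parallel-beam; the algorithms are
  dimension-agnostic (weights and penalty support 3-D) but no 3-D system
  matrix is provided.
- The per-iteration matching criterion under-regularises relative to an
  oracle β on this small phantom: the selected β values at 5% counts are
  well below the NRMSE-optimal fixed β, though reliably larger than at 100%
  and sufficient to restore the expected method ranking.
- Bootstrap resampling of binned counts is an interpretation of event-level
  resampling; the multinomial scheme conditions on the observed total.
- Count thinning is binomial per bin; event-level (list-mode) thinning is
  not represented.
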