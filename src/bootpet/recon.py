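"""MLEM and penalized (MAP-EM) reconstruction.

The data model is the standard emission-tomography Poisson likelihood: binned
counts y with expectation A·θ, where θ is the nonnegative activity image and A
the system model.  MLEM is the multiplicative EM ascent

    θ ← (θ / s) · Aᵀ(y / Aθ),        s = Aᵀ1 (the sensitivity image).

MAP-EM maximises the penalized objective  L(θ) − β·U(θ)  with the isotropic
quadratic penalty

    U(θ) = ¼ Σ_j Σ_{k∈N_j} w_jk (θ_j − θ_k)²,

using De Pierro's modified EM: the penalty is majorised by the separable
surrogate ¼ Σ_j Σ_k w_jk (2θ_j − θ_jⁿ − θ_kⁿ)², which combines with the EM
surrogate into a per-voxel quadratic whose unique nonnegative root is the
update.  For symmetric nonnegative weights this update never decreases the
penalized objective, and at β = 0 it reduces exactly to MLEM.

Model classes follow the ``Model(...).fit() -> Results`` convention: build an
:class:`MLEM` or :class:`MAPEM` from a sinogram and system model, call
``fit()``, and read the estimate and its diagnostics off the returned
:class:`ReconResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import Sinogram
from .projector import SystemModel, backproject, forward, gaussian_smooth
from .weights import WeightMap, shifted

#: epsilon floor for divisions, as a fraction of the data maximum
EPSILON_SCALE = 1e-12


@dataclass(frozen=True)
class ReconConfig:
    """Iteration and post-filtering settings.

    Defaults follow clinical practice for MLEM (63 iterations, 4 mm Gaussian
    post-filter); self-supervised MAP-EM conventionally runs longer (1000
    iterations at full scale) with a 4.5 mm post-filter for its smoothed
    variant or none for the unsmoothed one.
    """

    n_iterations: int = 63
    post_smooth_fwhm_mm: float = 4.0
    epsilon: float = None  # derived from the data if None
    record_objective: bool = True

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be at least 1")
        if self.post_smooth_fwhm_mm < 0:
            raise ValueError("post_smooth_fwhm_mm must be nonnegative")
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class ImageEstimate:
    """A nonnegative activity image with spacing and iteration provenance."""

    values: np.ndarray
    spacing_mm: tuple
    iteration: int = 0


def _epsilon_for(counts, epsilon=None):
    if epsilon is not None:
        return epsilon
    return EPSILON_SCALE * max(float(np.max(counts)), 1.0)


def _counts_array(counts):
    if isinstance(counts, Sinogram):
        return counts.counts
    return np.asarray(counts)


def uniform_initializer(system: SystemModel, counts) -> np.ndarray:
    """Scale-matched flat start: (total counts)/(total sensitivity) on the FOV."""
    y = _counts_array(counts)
    total = float(y.sum())
    sens_total = float(system.sensitivity.sum())
    value = total / sens_total if sens_total > 0 else 1.0
    init = np.where(system.fov_mask, max(value, np.finfo(float).tiny), 0.0)
    return init


def mlem_update(system: SystemModel, image, counts, epsilon=None) -> np.ndarray:
    """One multiplicative EM update; zero voxels stay zero.

    Implements θ_new = (θ / s) · Aᵀ(y / max(Aθ, ε)) restricted to the FOV.
    """
    theta = np.asarray(image, dtype=float)
    if (theta < 0).any():
        raise ValueError("image must be nonnegative")
    y = _counts_array(counts)
    if y.shape != system.geometry.sinogram_shape:
        raise ValueError("counts shape does not match system geometry")
    eps = _epsilon_for(y, epsilon)
    proj = forward(system, theta)
    ratio = y / np.maximum(proj, eps)
    bp = backproject(system, ratio)
    sens = system.sensitivity
    new = np.where(
        system.fov_mask, theta * bp / np.maximum(sens, np.finfo(float).tiny), 0.0
    )
    return new


def log_likelihood(system: SystemModel, image, counts, epsilon=None) -> float:
    """Poisson log-likelihood Σ_i [y_i log(max((Aθ)_i, ε)) − (Aθ)_i] (no y! term)."""
    y = _counts_array(counts)
    eps = _epsilon_for(y, epsilon)
    proj = forward(system, np.asarray(image, dtype=float))
    return float(np.sum(y * np.log(np.maximum(proj, eps)) - proj))


def quadratic_penalty(image, weights: WeightMap) -> float:
    """Isotropic quadratic penalty U(θ) = ¼ Σ_j Σ_k w_jk (θ_j − θ_k)²."""
    theta = np.asarray(image, dtype=float)
    if theta.shape != weights.grid_shape:
        raise ValueError("image shape does not match weight map grid")
    total = 0.0
    for i in weights.neighbor_indices():
        o = weights.offsets[i]
        diff = theta - shifted(theta, o)
        total += float(np.sum(weights.weights[i] * diff**2))
    return 0.25 * total


def _neighbor_sums(theta, weights: WeightMap):
    """W_j = Σ_k w_jk and S_j = Σ_k w_jk (θ_j + θ_k), self offset excluded."""
    wsum = np.zeros_like(theta)
    ssum = np.zeros_like(theta)
    for i in weights.neighbor_indices():
        o = weights.offsets[i]
        wi = weights.weights[i]
        wsum += wi
        ssum += wi * (theta + shifted(theta, o))
    return wsum, ssum


def _depierro_root(em_image, sens, wsum, ssum, beta, fov_mask):
    """Nonnegative root of the De Pierro per-voxel surrogate quadratic.

    Solves 2βW θ² + (s − βS) θ − s·θ_EM = 0 per voxel; as βW → 0 this tends to
    θ_EM, which is substituted directly where the quadratic degenerates.
    """
    a = 2.0 * beta * wsum
    b = sens - beta * ssum
    c = sens * em_image  # N_j = s_j * θ_j^EM
    disc = b * b + 4.0 * a * c
    disc = np.maximum(disc, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        root = (-b + np.sqrt(disc)) / (2.0 * a)
    degenerate = a <= 0
    root = np.where(degenerate, em_image, root)
    root = np.where(fov_mask, np.maximum(root, 0.0), 0.0)
    return root


def mapem_update(
    system: SystemModel, image, counts, weights: WeightMap, beta, epsilon=None
) -> np.ndarray:
    """One De Pierro MAP-EM update for the weighted quadratic penalty.

    Requires β ≥ 0 and symmetric nonnegative weights (the monotonicity
    guarantee is void otherwise).  β = 0 returns exactly the MLEM update.
    """
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    if not (weights.symmetrized or weights.is_symmetric()):
        raise ValueError("weights must be symmetric for the MAP-EM update")
    theta = np.asarray(image, dtype=float)
    if theta.shape != weights.grid_shape:
        raise ValueError("image shape does not match weight map grid")
    em = mlem_update(system, theta, counts, epsilon)
    if beta == 0:
        return em
    wsum, ssum = _neighbor_sums(theta, weights)
    return _depierro_root(em, system.sensitivity, wsum, ssum, beta, system.fov_mask)


def penalized_objective(
    system: SystemModel, image, counts, weights: WeightMap, beta, epsilon=None
) -> float:
    """Monitored MAP objective: Poisson log-likelihood minus β·U(θ)."""
    ll = log_likelihood(system, image, counts, epsilon)
    if beta == 0:
        return ll
    return ll - beta * quadratic_penalty(image, weights)


@dataclass
class ReconResult:
    """Reconstruction results: the estimate, traces and diagnostics.

    ``image`` is the post-filtered estimate delivered to the user;
    ``pre_smooth`` is the raw iterate before the post-reconstruction filter.
    ``objective_trace[t]`` is the monitored objective of iterate t (recorded
    after each update), and ``beta_trace`` is filled by the self-supervised
    variant only.
    """

    image: ImageEstimate
    pre_smooth: np.ndarray
    objective_trace: np.ndarray
    model: object
    beta_trace: object = None

    @property
    def values(self):
        return self.image.values

    def nrmse(self, truth, mask=None) -> float:
        """‖estimate − truth‖₂ / ‖truth‖₂ over ``mask`` (default: system FOV)."""
        truth = np.asarray(truth, dtype=float)
        if mask is None:
            mask = self.model.system.fov_mask
        num = np.linalg.norm((self.values - truth)[mask])
        den = np.linalg.norm(truth[mask])
        if den == 0:
            raise ValueError("truth is zero on the evaluation mask")
        return float(num / den)

    def plot(self, truth=None):
        """Quick-look figure: the estimate, the objective trace and (for the
        self-supervised variant) the selected-β trace."""
        import matplotlib.pyplot as plt

        n = 1 + (self.objective_trace is not None) + (self.beta_trace is not None)
        fig, axes = plt.subplots(1, n, figsize=(4 * n, 3.5))
        axes = np.atleast_1d(axes)
        im = axes[0].imshow(self.values, cmap="magma")
        axes[0].set_title(type(self.model).__name__)
        fig.colorbar(im, ax=axes[0], shrink=0.8)
        k = 1
        if self.objective_trace is not None:
            axes[k].plot(self.objective_trace)
            axes[k].set_xlabel("iteration")
            axes[k].set_ylabel("objective")
            k += 1
        if self.beta_trace is not None:
            axes[k].semilogy(np.maximum(self.beta_trace.betas, 1e-12))
            axes[k].set_xlabel("iteration")
            axes[k].set_ylabel(r"selected $\beta$")
        fig.tight_layout()
        return fig

    def summary(self) -> str:
        m = self.model
        lines = [
            f"{type(m).__name__} reconstruction",
            "=" * 34,
            f"iterations:        {m.config.n_iterations}",
            f"PSF FWHM:          {m.system.psf_fwhm_mm:g} mm",
            f"post-smooth FWHM:  {m.config.post_smooth_fwhm_mm:g} mm",
            f"image total:       {self.values.sum():.4g}",
            f"counts total:      {int(_counts_array(m.counts).sum())}",
        ]
        if self.objective_trace is not None and len(self.objective_trace):
            lines.append(f"final objective:   {self.objective_trace[-1]:.6g}")
        if self.beta_trace is not None:
            betas = np.asarray(self.beta_trace.betas)
            lines.append(f"final beta:        {betas[-1]:.4g}")
            lines.append(f"median beta:       {np.median(betas):.4g}")
        return "\n".join(lines)


class MLEM:
    """Maximum-likelihood EM reconstruction model.

    Parameters
    ----------
    counts : Sinogram or ndarray
        Measured binned counts.
    system : SystemModel
        Forward/backprojection pair (typically built with a 2.5 mm PSF for
        the clinical-standard mode).
    config : ReconConfig, optional
        Defaults to 63 iterations with 4 mm Gaussian post-smoothing.
    """

    def __init__(self, counts, system: SystemModel, config: ReconConfig = None):
        self.counts = counts
        self.system = system
        self.config = config if config is not None else ReconConfig()

    def _objective(self, theta, eps):
        return log_likelihood(self.system, theta, self.counts, eps)

    def _update(self, theta, eps):
        return mlem_update(self.system, theta, self.counts, eps)

    def fit(self, start=None) -> ReconResult:
        y = _counts_array(self.counts)
        eps = _epsilon_for(y, self.config.epsilon)
        theta = (
            np.asarray(start, dtype=float)
            if start is not None
            else uniform_initializer(self.system, self.counts)
        )
        trace = []
        for _ in range(self.config.n_iterations):
            theta = self._update(theta, eps)
            if self.config.record_objective:
                trace.append(self._objective(theta, eps))
        smoothed = gaussian_smooth(
            theta,
            self.config.post_smooth_fwhm_mm,
            self.system.geometry.voxel_spacing_mm,
        )
        return ReconResult(
            image=ImageEstimate(
                values=smoothed,
                spacing_mm=tuple(self.system.geometry.voxel_spacing_mm),
                iteration=self.config.n_iterations,
            ),
            pre_smooth=theta,
            objective_trace=np.asarray(trace) if trace else None,
            model=self,
        )


class MAPEM(MLEM):
    """MAP-EM with a fixed penalty strength β (De Pierro update).

    Same interface as :class:`MLEM` plus the weight map and β.  The recorded
    objective is the penalized one, L(θ) − β·U(θ), which the De Pierro update
    never decreases.
    """

    def __init__(
        self,
        counts,
        system: SystemModel,
        weights: WeightMap,
        beta: float,
        config: ReconConfig = None,
    ):
        if config is None:
            config = ReconConfig(n_iterations=200, post_smooth_fwhm_mm=0.0)
        super().__init__(counts, system, config)
        if beta < 0:
            raise ValueError("beta must be nonnegative")
        self.weights = weights
        self.beta = float(beta)

    def _objective(self, theta, eps):
        return penalized_objective(
            self.system, theta, self.counts, self.weights, self.beta, eps
        )

    def _update(self, theta, eps):
        return mapem_update(
            self.system, theta, self.counts, self.weights, self.beta, eps
        )
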