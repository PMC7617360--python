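"""Bootstrap-optimized self-supervised selection of the penalty strength β.

The idea: resample the measured counts (a nonparametric bootstrap of the
binned events), and at each iteration find the β for which the *regularized*
update from the bootstrapped data best matches the *unregularized* EM update
from the original data.  Since the two updates would coincide in the absence
of noise, their discrepancy is attributed to noise, and the β that brings them
into agreement is taken as the regularization needed to compensate for it.
That β is then used to update the image from the original measured data — the
bootstrapped data never directly updates the returned image.

The matching objective is the plain L2 distance over field-of-view voxels; it
is evaluated on a coarse logarithmic β grid (with the exact β = 0 endpoint as
a candidate) and refined by golden-section search in log β.  The search is
cheap: the EM ingredients of both updates are independent of β, so each β
candidate costs only an elementwise quadratic-root evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import Sinogram
from .recon import (
    MLEM,
    ImageEstimate,
    ReconConfig,
    ReconResult,
    _counts_array,
    _depierro_root,
    _epsilon_for,
    _neighbor_sums,
    log_likelihood,
    mlem_update,
    uniform_initializer,
)
from .projector import SystemModel, gaussian_smooth
from .weights import WeightMap

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class BetaSearchConfig:
    """Search-space and schedule settings for the per-iteration β selection.

    The bracket is ``[bracket_lo_factor, bracket_hi_factor]`` times a
    data-scaled pivot (the β at which the penalty terms of the per-voxel
    update quadratic are commensurate with the sensitivity); β = 0 is always
    included as an explicit candidate.  ``refresh_bootstrap_every`` controls
    how often the bootstrap replicate is redrawn (1 = every iteration).
    """

    n_coarse: int = 9
    bracket_lo_factor: float = 1e-4
    bracket_hi_factor: float = 1e4
    tolerance: float = 1e-2
    refresh_bootstrap_every: int = 1
    scheme: str = "multinomial"  # or "poisson", "identity"

    def __post_init__(self):
        if self.n_coarse < 3:
            raise ValueError("n_coarse must be at least 3")
        if not 0 < self.bracket_lo_factor < self.bracket_hi_factor:
            raise ValueError("bracket factors must satisfy 0 < lo < hi")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.refresh_bootstrap_every < 1:
            raise ValueError("refresh_bootstrap_every must be at least 1")
        if self.scheme not in ("multinomial", "poisson", "identity"):
            raise ValueError(f"unknown bootstrap scheme {self.scheme!r}")


@dataclass
class BetaTrace:
    """Per-iteration record of the self-selected penalty strengths."""

    betas: list = field(default_factory=list)
    objectives: list = field(default_factory=list)
    bracket: tuple = None
    seed: int = None

    def __len__(self):
        return len(self.betas)


def bootstrap_sinogram(counts, seed: int = 0, scheme: str = "multinomial") -> Sinogram:
    """Bootstrap-resample binned counts.

    ``multinomial`` (default) redistributes the N observed events over bins
    with probabilities counts/N, preserving the total exactly and the per-bin
    expectation.  ``poisson`` draws each bin Poisson(count) independently.
    ``identity`` returns a copy (a degenerate scheme useful for testing).
    """
    y = _counts_array(counts)
    total = int(y.sum())
    if total < 1:
        raise ValueError("cannot bootstrap a zero-total sinogram")
    rng = np.random.default_rng(seed)
    if scheme == "multinomial":
        boot = rng.multinomial(total, y.ravel() / total).reshape(y.shape)
    elif scheme == "poisson":
        boot = rng.poisson(y)
    elif scheme == "identity":
        boot = y.copy()
    else:
        raise ValueError(f"unknown bootstrap scheme {scheme!r}")
    geometry = counts.geometry if isinstance(counts, Sinogram) else None
    meta = dict(counts.meta) if isinstance(counts, Sinogram) else {}
    meta["bootstrap"] = scheme
    return Sinogram(counts=boot.astype(np.int64), geometry=geometry, meta=meta)


def _beta_pivot(system, theta):
    """Data-scaled β around which the search bracket is centred."""
    fov = system.fov_mask
    sens = np.median(system.sensitivity[fov])
    mean_theta = float(np.mean(theta[fov]))
    if mean_theta <= 0:
        mean_theta = 1.0
    return sens / (2.0 * mean_theta)


class _MatchingObjective:
    """L2 discrepancy ‖mapem_update(θ; boot, β) − mlem_update(θ; orig)‖² over FOV.

    Precomputes everything β-independent so evaluating a β candidate is an
    elementwise root solve plus a reduction.
    """

    def __init__(self, system, theta, em_orig, em_boot, weights):
        self.system = system
        self.em_orig = em_orig
        self.em_boot = em_boot
        self.wsum, self.ssum = _neighbor_sums(theta, weights)
        self.fov = system.fov_mask

    def candidate(self, beta):
        if beta == 0:
            return self.em_boot
        return _depierro_root(
            self.em_boot, self.system.sensitivity, self.wsum, self.ssum, beta, self.fov
        )

    def __call__(self, beta):
        diff = self.candidate(beta) - self.em_orig
        val = float(np.sum(diff[self.fov] ** 2))
        if not np.isfinite(val):
            raise RuntimeError(
                f"non-finite matching objective at beta={beta:g}"
            )
        return val


def _minimize_log_golden(fun, lo, hi, tol):
    """Golden-section minimisation in log β on [lo, hi]; returns (β, f(β))."""
    llo, lhi = np.log(lo), np.log(hi)
    a, b = llo, lhi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = fun(np.exp(c)), fun(np.exp(d))
    while (b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = fun(np.exp(c))
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = fun(np.exp(d))
    x = np.exp((a + b) / 2.0)
    return x, fun(x)


def select_beta(
    system: SystemModel,
    image,
    counts_orig,
    counts_boot,
    weights: WeightMap,
    cfg: BetaSearchConfig = None,
    epsilon=None,
    _objective_out: list = None,
) -> float:
    """Select the penalty strength matching the bootstrapped regularized update
    to the original unregularized one.

    Coarse logarithmic grid (plus the exact β = 0 endpoint) followed by
    golden-section refinement around the grid minimum.  Deterministic given
    its inputs.
    """
    cfg = cfg if cfg is not None else BetaSearchConfig()
    theta = np.asarray(image, dtype=float)
    em_orig = mlem_update(system, theta, counts_orig, epsilon)
    em_boot = mlem_update(system, theta, counts_boot, epsilon)
    obj = _MatchingObjective(system, theta, em_orig, em_boot, weights)

    pivot = _beta_pivot(system, theta)
    lo = cfg.bracket_lo_factor * pivot
    hi = cfg.bracket_hi_factor * pivot
    grid = np.exp(np.linspace(np.log(lo), np.log(hi), cfg.n_coarse))
    candidates = np.concatenate([[0.0], grid])
    values = np.array([obj(b) for b in candidates])
    best = int(np.argmin(values))

    if best == 0:
        beta, val = 0.0, values[0]
    else:
        # refine between the grid neighbours of the coarse minimum
        gi = best - 1
        blo = grid[max(gi - 1, 0)]
        bhi = grid[min(gi + 1, len(grid) - 1)]
        if blo == bhi:
            beta, val = grid[gi], values[best]
        else:
            beta, val = _minimize_log_golden(
                obj, blo, bhi, np.log(1.0 + cfg.tolerance)
            )
            if values[best] < val:
                beta, val = grid[gi], values[best]
        if values[0] <= val:
            beta, val = 0.0, values[0]
    if _objective_out is not None:
        _objective_out.append(val)
    return float(beta)


def selfsup_mapem(
    system: SystemModel,
    counts,
    weights: WeightMap,
    config: ReconConfig = None,
    search: BetaSearchConfig = None,
    seed: int = 0,
):
    """Run the self-supervised MAP-EM loop; see :class:`SelfSupervisedMAPEM`."""
    model = SelfSupervisedMAPEM(counts, system, weights, config=config, search=search)
    result = model.fit(seed=seed)
    return result.image, result.beta_trace


class SelfSupervisedMAPEM(MLEM):
    """Self-supervised MAP-EM: per-iteration bootstrap-optimized β.

    Each iteration draws (or reuses, per the refresh schedule) a bootstrap
    replicate of the measured counts, selects β by matching the regularized
    bootstrap update to the unregularized original update, and applies the De
    Pierro update with that β to the original data.  ``fit`` returns a
    :class:`ReconResult` whose ``beta_trace`` records the selected β and the
    matching-objective minimum at every iteration.

    With uniform weights this is the "unguided" variant; with MR-derived
    Bowsher weights the "MR-guided" one.  A smoothed variant applies a 4.5 mm
    post-reconstruction Gaussian (set ``config.post_smooth_fwhm_mm``).
    """

    def __init__(
        self,
        counts,
        system: SystemModel,
        weights: WeightMap,
        config: ReconConfig = None,
        search: BetaSearchConfig = None,
    ):
        if config is None:
            config = ReconConfig(n_iterations=1000, post_smooth_fwhm_mm=0.0)
        super().__init__(counts, system, config)
        if not (weights.symmetrized or weights.is_symmetric()):
            raise ValueError("weights must be symmetric for the MAP-EM update")
        self.weights = weights
        self.search = search if search is not None else BetaSearchConfig()

    def fit(self, seed: int = 0, start=None) -> ReconResult:
        y = _counts_array(self.counts)
        eps = _epsilon_for(y, self.config.epsilon)
        theta = (
            np.asarray(start, dtype=float)
            if start is not None
            else uniform_initializer(self.system, self.counts)
        )
        rng = np.random.default_rng(seed)
        pivot0 = _beta_pivot(self.system, theta)
        trace = BetaTrace(
            bracket=(
                self.search.bracket_lo_factor * pivot0,
                self.search.bracket_hi_factor * pivot0,
            ),
            seed=seed,
        )
        obj_trace = []
        boot = None
        for t in range(self.config.n_iterations):
            if boot is None or t % self.search.refresh_bootstrap_every == 0:
                boot = bootstrap_sinogram(
                    self.counts,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    scheme=self.search.scheme,
                )
            em_orig = mlem_update(self.system, theta, self.counts, eps)
            em_boot = mlem_update(self.system, theta, boot, eps)
            matcher = _MatchingObjective(
                self.system, theta, em_orig, em_boot, self.weights
            )
            beta, match_val = self._select(matcher, theta)
            # update from the ORIGINAL data with the selected beta
            if beta == 0:
                theta = em_orig
            else:
                theta = _depierro_root(
                    em_orig,
                    self.system.sensitivity,
                    matcher.wsum,
                    matcher.ssum,
                    beta,
                    self.system.fov_mask,
                )
            if not np.isfinite(theta).all():
                raise RuntimeError(f"non-finite voxel at iteration {t}")
            trace.betas.append(beta)
            trace.objectives.append(match_val)
            if self.config.record_objective:
                obj_trace.append(log_likelihood(self.system, theta, self.counts, eps))
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
            objective_trace=np.asarray(obj_trace) if obj_trace else None,
            model=self,
            beta_trace=trace,
        )

    def _select(self, matcher: _MatchingObjective, theta):
        cfg = self.search
        pivot = _beta_pivot(self.system, theta)
        lo = cfg.bracket_lo_factor * pivot
        hi = cfg.bracket_hi_factor * pivot
        grid = np.exp(np.linspace(np.log(lo), np.log(hi), cfg.n_coarse))
        candidates = np.concatenate([[0.0], grid])
        values = np.array([matcher(b) for b in candidates])
        best = int(np.argmin(values))
        if best == 0:
            return 0.0, float(values[0])
        gi = best - 1
        blo = grid[max(gi - 1, 0)]
        bhi = grid[min(gi + 1, len(grid) - 1)]
        beta, val = grid[gi], float(values[best])
        if blo < bhi:
            b2, v2 = _minimize_log_golden(matcher, blo, bhi, np.log(1.0 + cfg.tolerance))
            if v2 < val:
                beta, val = b2, v2
        if values[0] <= val:
            return 0.0, float(values[0])
        return float(beta), val
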