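"""Penalty weight maps: uniform (unguided) and MR-guided Bowsher-style weights.

A :class:`WeightMap` stores one nonnegative weight w_jk per (voxel j, neighbour
offset) over the full 3×3 (2-D) or 3×3×3 (3-D) neighbourhood, including the
self offset (which never contributes to the penalty since θ_j − θ_j = 0).
Out-of-bounds neighbours carry weight 0 and are never renormalised.

The unguided map sets every in-bounds weight to 1/9 in 2-D or 1/27 in 3-D.
The guided map computes bilateral weights from an MR image,

    w_jk = exp(−‖f_j − f_k‖² / 2σ_f²) · exp(−‖r_j − r_k‖² / 2σ_s²),

with features f normalised to unit standard deviation per element, keeps the
``n_keep`` largest weights per voxel (largest-value sparsification, the
Bowsher construction; 7 by default) and finally symmetrises w ← (w + wᵀ)/2 so
the De Pierro MAP-EM monotonicity guarantee applies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np


def neighborhood_offsets(ndim: int):
    """All offsets of the 3^ndim neighbourhood in lexicographic order."""
    return tuple(itertools.product((-1, 0, 1), repeat=ndim))


def shifted(arr, offset, fill=0.0):
    """Array whose entry at j holds arr[j + offset]; out-of-bounds filled."""
    out = np.full_like(np.asarray(arr, dtype=float), fill)
    src = []
    dst = []
    for o, n in zip(offset, arr.shape):
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    out[tuple(dst)] = np.asarray(arr, dtype=float)[tuple(src)]
    return out


def inbounds_mask(shape, offset):
    """Boolean grid: True where voxel j + offset is inside the grid."""
    mask = np.ones(shape, dtype=bool)
    for ax, (o, n) in enumerate(zip(offset, shape)):
        idx = np.arange(n)
        ok = (idx + o >= 0) & (idx + o < n)
        sh = [1] * len(shape)
        sh[ax] = n
        mask &= ok.reshape(sh)
    return mask


@dataclass
class WeightMap:
    """Per-voxel neighbour weights over the full 3^ndim offset neighbourhood."""

    offsets: tuple
    weights: np.ndarray  # (n_offsets, *grid_shape)
    symmetrized: bool = False
    _symmetric: bool = field(default=None, repr=False)

    @property
    def grid_shape(self):
        return self.weights.shape[1:]

    @property
    def self_index(self):
        return self.offsets.index((0,) * len(self.grid_shape))

    def neighbor_indices(self):
        """Offset indices excluding the self offset."""
        si = self.self_index
        return [i for i in range(len(self.offsets)) if i != si]

    def is_symmetric(self, tol=1e-12):
        """True iff w_jk == w_kj for every stored in-bounds pair."""
        if self._symmetric is None:
            ok = True
            for i in self.neighbor_indices():
                o = self.offsets[i]
                neg = self.offsets.index(tuple(-c for c in o))
                if not np.allclose(
                    self.weights[i], shifted(self.weights[neg], o), atol=tol, rtol=0
                ):
                    ok = False
                    break
            self._symmetric = ok
        return self._symmetric


def uniform_weights(grid_shape) -> WeightMap:
    """Uniform unguided map: every in-bounds weight is 1/3^ndim.

    In 3-D this is the 1/27 weighting over the 3×3×3 neighbourhood; the 2-D
    analogue is 1/9.  Out-of-bounds offsets at edges are dropped (weight 0)
    with no renormalisation of the rest.
    """
    ndim = len(grid_shape)
    offsets = neighborhood_offsets(ndim)
    value = 1.0 / 3**ndim
    w = np.zeros((len(offsets),) + tuple(grid_shape))
    for i, o in enumerate(offsets):
        w[i][inbounds_mask(grid_shape, o)] = value
    return WeightMap(offsets=offsets, weights=w, symmetrized=True)


@dataclass
class FeatureImage:
    """Per-voxel feature vectors with their normalisation record.

    ``values`` has shape grid + (m,); each element has been divided by its
    across-image standard deviation (``sd``) so that the normalised SD is 1,
    unless the raw SD was 0, in which case the element is passed through
    unscaled and flagged in ``constant_elements``.
    """

    values: np.ndarray
    raw: np.ndarray
    sd: np.ndarray
    constant_elements: np.ndarray  # bool per element

    @property
    def grid_shape(self):
        return self.values.shape[:-1]

    @property
    def n_elements(self):
        return self.values.shape[-1]


def normalize_features(mr, multichannel: bool = False) -> FeatureImage:
    """Normalise features by the per-element standard deviation across voxels.

    A plain image is treated as a one-element feature vector per voxel.  With
    ``multichannel=True`` the trailing axis is read as the feature axis
    (grid + (m,)) and each element is normalised independently.  Constant
    elements (SD = 0) are passed through unchanged and flagged, not raised.
    """
    raw = np.asarray(mr, dtype=float)
    if not np.isfinite(raw).all():
        raise ValueError("features must be finite")
    if not multichannel:
        raw = raw[..., None]
    flat = raw.reshape(-1, raw.shape[-1])
    sd = flat.std(axis=0, ddof=0)
    constant = sd == 0
    scale = np.where(constant, 1.0, sd)
    return FeatureImage(
        values=raw / scale, raw=raw, sd=sd, constant_elements=constant
    )


@dataclass(frozen=True)
class GuidanceParams:
    """Bilateral-kernel parameters for MR-guided weights.

    sigma_f: feature kernel width (on SD-normalised features, default 1).
    sigma_s: spatial kernel width in mm (default 4).
    n_keep: weights retained per voxel by largest-value sparsification
        (default 7, the Bowsher convention).
    """

    sigma_f: float = 1.0
    sigma_s: float = 4.0
    n_keep: int = 7

    def __post_init__(self):
        if self.sigma_f <= 0 or self.sigma_s <= 0:
            raise ValueError("sigma_f and sigma_s must be positive")
        if self.n_keep < 1:
            raise ValueError("n_keep must be at least 1")


def bowsher_weights(
    features: FeatureImage,
    params: GuidanceParams,
    spacing_mm,
    symmetrize: bool = True,
) -> WeightMap:
    """MR-guided bilateral weights with top-``n_keep`` sparsification.

    For every voxel the raw bilateral weight is computed for each in-bounds
    neighbour (self excluded), the ``n_keep`` largest are retained (ties broken
    by lexicographic offset order, for reproducibility) and the rest zeroed.
    With ``symmetrize=True`` (default) the sparsified map is averaged with its
    transpose so downstream MAP-EM monotonicity holds; the asymmetric Bowsher
    original is available with ``symmetrize=False``.
    """
    grid = features.grid_shape
    ndim = len(grid)
    offsets = neighborhood_offsets(ndim)
    n_neighbors = len(offsets) - 1
    if params.n_keep > n_neighbors:
        raise ValueError(
            f"n_keep={params.n_keep} exceeds the {n_neighbors} available "
            "neighbours of the 3^ndim neighbourhood"
        )
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (ndim,))

    f = features.values
    w = np.zeros((len(offsets),) + tuple(grid))
    self_idx = offsets.index((0,) * ndim)
    for i, o in enumerate(offsets):
        if i == self_idx:
            continue
        dist2 = float(np.sum((np.asarray(o) * spacing) ** 2))
        spatial = np.exp(-dist2 / (2.0 * params.sigma_s**2))
        fk = np.stack([shifted(f[..., m], o) for m in range(f.shape[-1])], axis=-1)
        feat2 = np.sum((f - fk) ** 2, axis=-1)
        wi = np.exp(-feat2 / (2.0 * params.sigma_f**2)) * spatial
        wi[~inbounds_mask(grid, o)] = 0.0
        w[i] = wi

    # largest-value sparsification: stable sort keeps the lexicographically
    # first offset on ties
    order = np.argsort(-w, axis=0, kind="stable")
    rank = np.empty_like(order)
    np.put_along_axis(rank, order, np.arange(len(offsets)).reshape((-1,) + (1,) * ndim), axis=0)
    keep = rank < params.n_keep
    keep &= w > 0
    w = np.where(keep, w, 0.0)

    if symmetrize:
        w_sym = np.zeros_like(w)
        for i, o in enumerate(offsets):
            if i == self_idx:
                continue
            neg = offsets.index(tuple(-c for c in o))
            w_sym[i] = 0.5 * (w[i] + shifted(w[neg], o))
            w_sym[i][~inbounds_mask(grid, o)] = 0.0
        w = w_sym

    return WeightMap(offsets=offsets, weights=w, symmetrized=symmetrize)
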