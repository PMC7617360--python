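"""Synthetic co-registered PET/MR brain phantom and Poisson acquisition simulation.

The default phantom is a 2-D piecewise-constant ellipse composition emulating a
transaxial FDG brain slice: a white-matter interior with a grey-matter cortical
rim (GM:WM uptake 4:1, typical of FDG), a ventricle, and a caudate and putamen
separated by a lower-uptake band so that caudate–putamen distinguishability is a
measurable quantity.  A co-aligned MR guidance image shares every tissue
boundary but carries a different (roughly T1-like) intensity ordering, so it
contributes boundary information rather than uptake information.  An optional
lesion can be placed in the activity image only, to emulate PET/MR mismatch.

Acquisition is simulated by scaling the noiseless forward projection to a total
count budget and drawing independent Poisson counts per sinogram bin.  Reduced
injected dose is emulated by binomial thinning of the binned counts, which maps
Poisson(λ) bins exactly to Poisson(p·λ).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .projector import Geometry, SystemModel, forward

# label codes; the label map partitions the grid
BACKGROUND = 0
WHITE = 1
GREY = 2
CAUDATE = 3
PUTAMEN = 4
BETWEEN_CP = 5
VENTRICLE = 6

LABEL_NAMES = {
    BACKGROUND: "background",
    WHITE: "white_matter",
    GREY: "grey_matter",
    CAUDATE: "caudate",
    PUTAMEN: "putamen",
    BETWEEN_CP: "between_cp",
    VENTRICLE: "ventricle",
}


class InvalidSpecError(ValueError):
    """Raised when a phantom specification is geometrically inconsistent."""


@dataclass(frozen=True)
class Ellipse:
    """Axis-rotated ellipse primitive; centre/semi-axes in mm, angle in degrees."""

    center_mm: tuple
    semiaxes_mm: tuple
    angle_deg: float = 0.0

    def mask(self, grid_shape, spacing_mm):
        nr, nc = grid_shape
        dr, dc = spacing_mm
        rows = (np.arange(nr) - (nr - 1) / 2.0) * dr
        cols = (np.arange(nc) - (nc - 1) / 2.0) * dc
        yy, xx = np.meshgrid(rows, cols, indexing="ij")
        cx, cy = self.center_mm
        a, b = self.semiaxes_mm
        th = np.deg2rad(self.angle_deg)
        u = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
        v = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0


@dataclass(frozen=True)
class Structure:
    """One painted tissue structure: label, geometry, activity and MR intensity."""

    name: str
    label: int
    primitive: Ellipse
    activity: float
    mr: float


def _default_structures(gm_wm_ratio):
    gm = float(gm_wm_ratio)
    # paint order matters: later structures overwrite earlier ones
    return [
        Structure("cortex", GREY, Ellipse((0.0, 0.0), (52.0, 44.0)), gm, 0.55),
        Structure("white_matter", WHITE, Ellipse((0.0, 0.0), (44.0, 36.0)), 1.0, 1.0),
        Structure("ventricle", VENTRICLE, Ellipse((8.0, -2.0), (9.0, 6.0), 10.0), 0.1, 0.15),
        Structure("between_cp", BETWEEN_CP, Ellipse((-19.0, 6.0), (10.0, 13.0), 25.0), 1.0, 0.8),
        Structure("caudate", CAUDATE, Ellipse((-13.0, 12.0), (4.5, 8.0), 20.0), gm, 0.45),
        Structure("putamen", PUTAMEN, Ellipse((-25.0, 0.0), (4.5, 9.0), 20.0), gm, 0.40),
    ]


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative phantom description.

    ``gm_wm_ratio`` is the grey/white activity ratio (4.0 is typical for FDG).
    With ``jitter=True`` structure centres and sizes receive small seeded random
    perturbations so repeated draws act like different subjects.
    ``mismatch_lesion`` (if given) is painted into the activity image only, at
    ``lesion_activity`` times the local value, and is absent from MR and labels.
    """

    grid_shape: tuple = (64, 64)
    spacing_mm: tuple = (2.0, 2.0)
    gm_wm_ratio: float = 4.0
    structures: tuple = None
    mismatch_lesion: Ellipse = None
    lesion_activity: float = 1.5
    jitter: bool = False
    jitter_center_mm: float = 1.5
    jitter_scale_sd: float = 0.04

    def __post_init__(self):
        if any(s < 32 for s in self.grid_shape):
            raise InvalidSpecError("grid must be at least 32 voxels per axis")
        if any(s <= 0 for s in self.spacing_mm):
            raise InvalidSpecError("spacing_mm must be positive")
        if self.gm_wm_ratio < 0:
            raise InvalidSpecError("activity values must be nonnegative")
        if self.structures is None:
            object.__setattr__(
                self, "structures", tuple(_default_structures(self.gm_wm_ratio))
            )
        names = [s.name for s in self.structures]
        if len(set(names)) != len(names):
            raise InvalidSpecError("structure names must be unique")
        if any(s.activity < 0 for s in self.structures):
            raise InvalidSpecError("activity values must be nonnegative")


@dataclass
class PhantomPair:
    """Co-registered activity, MR guidance and integer label grids."""

    activity: np.ndarray
    mr: np.ndarray
    labels: np.ndarray
    spacing_mm: tuple

    def roi(self, label):
        return self.labels == label


def _jittered(structures, rng, center_sd, scale_sd):
    out = []
    for s in structures:
        dx, dy = rng.normal(0.0, center_sd, size=2)
        sa = np.clip(1.0 + rng.normal(0.0, scale_sd, size=2), 0.8, 1.2)
        prim = Ellipse(
            (s.primitive.center_mm[0] + dx, s.primitive.center_mm[1] + dy),
            (s.primitive.semiaxes_mm[0] * sa[0], s.primitive.semiaxes_mm[1] * sa[1]),
            s.primitive.angle_deg,
        )
        out.append(replace(s, primitive=prim))
    return out


def make_phantom(spec: PhantomSpec, seed: int = 0) -> PhantomPair:
    """Render a phantom specification into co-registered grids.

    Deterministic for fixed ``(spec, seed)``.  Raises :class:`InvalidSpecError`
    if the caudate and putamen overlap or any declared structure rasterises to
    zero voxels.
    """
    rng = np.random.default_rng(seed)
    structures = list(spec.structures)
    if spec.jitter:
        structures = _jittered(
            structures, rng, spec.jitter_center_mm, spec.jitter_scale_sd
        )

    activity = np.zeros(spec.grid_shape)
    mr = np.zeros(spec.grid_shape)
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    masks = {}
    for s in structures:
        m = s.primitive.mask(spec.grid_shape, spec.spacing_mm)
        if not m.any():
            raise InvalidSpecError(f"structure {s.name!r} occupies zero voxels")
        masks[s.name] = m
        activity[m] = s.activity
        mr[m] = s.mr
        labels[m] = s.label

    if (labels == CAUDATE).any() and (labels == PUTAMEN).any():
        cm = next((masks[s.name] for s in structures if s.label == CAUDATE), None)
        pm = next((masks[s.name] for s in structures if s.label == PUTAMEN), None)
        if cm is not None and pm is not None and (cm & pm).any():
            raise InvalidSpecError("caudate and putamen primitives overlap")

    for s in structures:
        if not (labels == s.label).any():
            raise InvalidSpecError(
                f"structure {s.name!r} fully overwritten; zero voxels remain"
            )

    if spec.mismatch_lesion is not None:
        m = spec.mismatch_lesion.mask(spec.grid_shape, spec.spacing_mm)
        if not m.any():
            raise InvalidSpecError("mismatch lesion occupies zero voxels")
        activity[m] *= spec.lesion_activity

    return PhantomPair(
        activity=activity, mr=mr, labels=labels, spacing_mm=spec.spacing_mm
    )


@dataclass
class Sinogram:
    """Binned coincidence counts (angle × radial bin) plus geometry metadata."""

    counts: np.ndarray
    geometry: Geometry
    meta: dict = field(default_factory=dict)

    @property
    def total(self):
        return int(self.counts.sum())


def simulate_acquisition(
    activity, system: SystemModel, total_counts: int, seed: int = 0
) -> Sinogram:
    """Simulate a Poisson acquisition with a fixed expected total count.

    The noiseless forward projection is rescaled so its sum equals
    ``total_counts``; each bin is then an independent Poisson draw with that
    mean.  Deterministic for fixed ``(activity, system, seed)``.
    """
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    expected = forward(system, activity)
    s = expected.sum()
    if s <= 0:
        raise ValueError("activity projects to zero counts; cannot scale")
    rng = np.random.default_rng(seed)
    scale = total_counts / s
    counts = rng.poisson(expected * scale)
    return Sinogram(
        counts=counts.astype(np.int64),
        geometry=system.geometry,
        meta={
            "count_level": "100%",
            "expected_total": int(total_counts),
            # activity -> expected-counts factor; reconstructions come out in
            # count units, divide by this to return to activity units
            "scale": float(scale),
        },
    )


def thin_counts(sino: Sinogram, fraction: float, seed: int = 0) -> Sinogram:
    """Binomially thin binned counts, emulating a reduced injected dose.

    Each bin's thinned count is Binomial(count, fraction), independently; a
    Poisson(λ) bin therefore becomes Poisson(fraction·λ).  Geometry and header
    metadata are preserved, with the count-level tag updated.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        thinned = sino.counts.copy()
    else:
        rng = np.random.default_rng(seed)
        thinned = rng.binomial(sino.counts, fraction)
    meta = dict(sino.meta)
    meta["count_level"] = f"{100 * fraction:g}%"
    if "scale" in meta:
        meta["scale"] = float(meta["scale"]) * fraction
    return Sinogram(
        counts=thinned.astype(np.int64), geometry=sino.geometry, meta=meta
    )
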