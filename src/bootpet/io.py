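"""File formats: NIfTI images, header+CSV sinograms, CSV traces, YAML provenance.

Images travel as NIfTI with the voxel spacing in the affine (2-D grids get a
singleton third axis).  A sinogram is a two-part artifact: a YAML header with
the acquisition geometry and count-level tag, and a CSV count matrix, one row
per projection angle (row-major, angle-major).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .phantom import Sinogram
from .projector import Geometry


def save_image(path, values, spacing_mm):
    values = np.asarray(values, dtype=float)
    spacing = list(np.broadcast_to(np.asarray(spacing_mm, dtype=float), (values.ndim,)))
    if values.ndim == 2:
        values = values[..., None]
        spacing = spacing + [1.0]
    affine = np.diag(spacing + [1.0])
    nib.save(nib.Nifti1Image(values, affine), str(path))


def load_image(path):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    spacing = img.header.get_zooms()[: data.ndim]
    if data.ndim == 3 and data.shape[-1] == 1:
        data = data[..., 0]
        spacing = spacing[:2]
    return data, tuple(float(s) for s in spacing)


def save_labels(path, labels, spacing_mm):
    labels = np.asarray(labels)
    spacing = list(np.broadcast_to(np.asarray(1.0 * np.array(spacing_mm)), (labels.ndim,)))
    if labels.ndim == 2:
        labels = labels[..., None]
        spacing = spacing + [1.0]
    affine = np.diag(spacing + [1.0])
    nib.save(nib.Nifti1Image(labels.astype(np.int16), affine), str(path))


def load_labels(path):
    data, spacing = load_image(path)
    return np.rint(data).astype(np.int16), spacing


def save_sinogram(stem, sino: Sinogram):
    """Write ``<stem>.yaml`` (header) and ``<stem>.csv`` (counts)."""
    stem = Path(stem)
    header = {"geometry": sino.geometry.to_dict(), "meta": dict(sino.meta)}
    stem.with_suffix(".yaml").write_text(yaml.safe_dump(header, sort_keys=False))
    np.savetxt(stem.with_suffix(".csv"), sino.counts, fmt="%d", delimiter=",")


def load_sinogram(stem) -> Sinogram:
    stem = Path(stem)
    header = yaml.safe_load(stem.with_suffix(".yaml").read_text())
    geom = Geometry.from_dict(header["geometry"])
    counts = np.loadtxt(stem.with_suffix(".csv"), dtype=np.int64, delimiter=",")
    counts = counts.reshape(geom.sinogram_shape)
    return Sinogram(counts=counts, geometry=geom, meta=header.get("meta", {}))


def save_trace(path, **columns):
    """CSV trace with an ``iteration`` index column."""
    n = max(len(v) for v in columns.values())
    df = pd.DataFrame({"iteration": np.arange(n), **columns})
    df.to_csv(path, index=False)


def load_trace(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_provenance(path, config: dict):
    from . import __version__

    payload = {"bootpet_version": __version__, **config}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_provenance(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
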