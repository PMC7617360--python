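"""Objective image-quality metrics and paired comparison statistics.

Clinical reads of reconstructed brain PET are scored on axes such as
grey/white contrast, caudate–putamen distinguishability and white-matter
uniformity.  This module provides objective ROI-based proxies for those axes
on phantom data where the ground truth and tissue labels are known:

- ``nrmse``          — ‖img − truth‖₂ / ‖truth‖₂ over the evaluation mask;
- ``cnr``            — |mean(GM) − mean(WM)| / SD(WM);
- ``cp_separation``  — (mean(caudate ∪ putamen) − mean(between-band)) / SD(WM);
- ``noise_cov``      — SD(WM) / mean(WM), the white-matter coefficient of
  variation.

The last three are invariant under global positive rescaling of the image.

For paired method comparisons the module provides a Wilcoxon signed-rank test
(exact enumeration-free null for n ≤ 12 via distribution convolution, normal
approximation with tie correction above) and Spearman's rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import phantom as ph

EXACT_WILCOXON_MAX_N = 12

#: metrics where smaller is better (sign-flipped before aggregation)
LOWER_IS_BETTER = ("nrmse", "noise_cov")


class EmptyROIError(ValueError):
    """Raised when a required ROI label has no voxels."""


@dataclass
class MetricReport:
    """Objective proxies for the clinical quality axes of one reconstruction."""

    nrmse: float
    cnr: float
    cp_separation: float
    noise_cov: float
    method: str = ""
    count_level: str = ""

    def as_dict(self):
        return {
            "nrmse": self.nrmse,
            "cnr": self.cnr,
            "cp_separation": self.cp_separation,
            "noise_cov": self.noise_cov,
            "method": self.method,
            "count_level": self.count_level,
        }

    METRIC_NAMES = ("nrmse", "cnr", "cp_separation", "noise_cov")


def _roi(labels, label, name):
    mask = labels == label
    if not mask.any():
        raise EmptyROIError(f"ROI {name!r} (label {label}) has no voxels")
    return mask


def compute_metrics(
    image, truth, labels, mask=None, method: str = "", count_level: str = ""
) -> MetricReport:
    """Compute the objective quality proxies for one reconstructed image.

    ``labels`` must contain white matter, grey matter, caudate, putamen and
    the between-band; ``mask`` (optional) restricts the NRMSE support (e.g.
    to the scanner field of view).
    """
    img = np.asarray(image, dtype=float)
    tru = np.asarray(truth, dtype=float)
    labels = np.asarray(labels)
    if img.shape != tru.shape or img.shape != labels.shape:
        raise ValueError("image, truth and labels must share a grid")

    if mask is None:
        mask = np.ones(img.shape, dtype=bool)
    den = np.linalg.norm(tru[mask])
    if den == 0:
        raise ValueError("truth is zero on the evaluation mask")
    nrmse = float(np.linalg.norm((img - tru)[mask]) / den)

    wm = _roi(labels, ph.WHITE, "white_matter")
    gm = _roi(labels, ph.GREY, "grey_matter")
    cd = _roi(labels, ph.CAUDATE, "caudate")
    pu = _roi(labels, ph.PUTAMEN, "putamen")
    bt = _roi(labels, ph.BETWEEN_CP, "between_cp")

    wm_mean = float(img[wm].mean())
    wm_sd = float(img[wm].std(ddof=0))
    cnr = abs(float(img[gm].mean()) - wm_mean) / wm_sd if wm_sd > 0 else np.inf
    cp = float(img[cd | pu].mean()) - float(img[bt].mean())
    cp_separation = cp / wm_sd if wm_sd > 0 else np.inf
    noise_cov = wm_sd / wm_mean if wm_mean != 0 else np.inf

    if wm_sd == 0:
        # noiseless piecewise-constant white matter: report the degenerate
        # ratios as large-but-finite only when the numerator is 0
        cnr = 0.0 if img[gm].mean() == wm_mean else np.inf
        cp_separation = 0.0 if cp == 0 else np.inf
        noise_cov = 0.0

    return MetricReport(
        nrmse=nrmse,
        cnr=cnr,
        cp_separation=cp_separation,
        noise_cov=noise_cov,
        method=method,
        count_level=count_level,
    )


def _signed_rank_statistic(diffs):
    """Drop zeros, midrank |d|, return (W+, ranks, n)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero; the test is undefined")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    return w_plus, ranks, d.size


def _exact_two_sided_p(w_plus, ranks):
    """Exact null distribution of W+ by convolution over doubled midranks."""
    scaled = np.rint(2 * ranks).astype(int)
    dist = np.array([1.0])
    for r in scaled:
        new = np.zeros(len(dist) + r)
        new[: len(dist)] += dist
        new[r:] += dist
        dist = new
    dist /= dist.sum()
    w2 = int(round(2 * w_plus))
    p_lo = dist[: w2 + 1].sum()
    p_hi = dist[w2:].sum()
    return min(1.0, 2.0 * min(p_lo, p_hi))


def wilcoxon_signed_rank(pairs):
    """Two-sided Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped (classic convention).  For n ≤ 12 remaining
    pairs the p-value is exact over all 2ⁿ sign assignments; above that a
    normal approximation with tie correction is used.  Returns
    ``(W+, p_two_sided)``.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (a, b) tuples")
    diffs = arr[:, 0] - arr[:, 1]
    w_plus, ranks, n = _signed_rank_statistic(diffs)
    if n <= EXACT_WILCOXON_MAX_N:
        p = _exact_two_sided_p(w_plus, ranks)
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if var <= 0:
            raise ValueError("zero variance under the null (all ranks tied)")
        from scipy.stats import norm

        z = (w_plus - mean) / np.sqrt(var)
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return w_plus, p


def spearman_rho(x, y) -> float:
    """Spearman's rank correlation: midranks then Pearson on the ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input; correlation undefined")
    rx = rankdata(x)
    ry = rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def score_table(reports) -> pd.DataFrame:
    """Tidy table of metric values: one row per (item, method, metric)."""
    rows = []
    for item, rep in reports:
        for m in MetricReport.METRIC_NAMES:
            rows.append(
                {
                    "item": item,
                    "method": rep.method,
                    "metric": m,
                    "value": getattr(rep, m),
                }
            )
    return pd.DataFrame(rows)


def overall_performance(table: pd.DataFrame) -> pd.DataFrame:
    """Per-method overall score: mean of min–max rescaled metrics.

    Each metric is rescaled to [0, 1] across all cells of the table
    (``nrmse`` and ``noise_cov`` flipped so higher is always better), averaged
    over metrics per item, then summarised per method as mean ± SD across
    items.  With a single item the SD is reported as NaN, not zero.
    """
    required = {"item", "method", "metric", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if table["method"].nunique() < 2:
        raise ValueError("need at least 2 methods to rank")
    t = table.copy()

    def rescale(group):
        v = group["value"].astype(float)
        lo, hi = v.min(), v.max()
        scaled = (v - lo) / (hi - lo) if hi > lo else pd.Series(0.5, index=v.index)
        if group.name in LOWER_IS_BETTER:
            scaled = 1.0 - scaled
        return scaled

    t["scaled"] = (
        t.groupby("metric", group_keys=False)[["metric", "value"]].apply(rescale)
    )
    per_item = t.groupby(["method", "item"])["scaled"].mean()
    out = per_item.groupby("method").agg(["mean", "std", "count"])
    out.loc[out["count"] < 2, "std"] = np.nan
    return out.rename(columns={"mean": "overall", "std": "sd", "count": "n_items"})


def significance_matrix(table: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Per-metric Wilcoxon comparison of every method against a reference.

    Cells hold {'sig_better', 'sig_worse', 'n.s.', 'c.d.'} at α = 0.05;
    'c.d.' (cannot determine) marks metrics with < 5 usable pairs.  Direction
    accounts for lower-is-better metrics.
    """
    methods = [m for m in table["method"].unique() if m != reference]
    out = {}
    for method in methods:
        row = {}
        for metric in table["metric"].unique():
            a = table.query("method == @method and metric == @metric").set_index("item")[
                "value"
            ]
            b = table.query("method == @reference and metric == @metric").set_index(
                "item"
            )["value"]
            common = a.index.intersection(b.index)
            pairs = np.column_stack([a.loc[common], b.loc[common]])
            nz = np.count_nonzero(pairs[:, 0] - pairs[:, 1]) if len(pairs) else 0
            if nz < 5:
                row[metric] = "c.d."
                continue
            _, p = wilcoxon_signed_rank(pairs)
            if p >= 0.05:
                row[metric] = "n.s."
            else:
                better = np.median(pairs[:, 0] - pairs[:, 1]) > 0
                if metric in LOWER_IS_BETTER:
                    better = not better
                row[metric] = "sig_better" if better else "sig_worse"
        out[method] = row
    return pd.DataFrame(out).T
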