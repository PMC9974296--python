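"""Nanostructure trait summaries, ordination, and hybrid transgression
metrics.

The transgression metrics describe where a hybrid phenotype H sits relative
to the two parental phenotypes P1, P2 in a 2-D trait plane. With
v = P2 − P1, midpoint M = (P1 + P2)/2 and w = H − M:

    d_parent_bias = |w·v̂| / (‖v‖/2)    (0 = intermediate, 1 = on a parent)
    d_mismatch    = ‖w − (w·v̂)v̂‖ / ‖v‖ (0 = on the transect, >1 = displaced
                                         farther than the parents are apart)

Multi-trait tables are reduced to the mean of these metrics over all
unordered 2-D trait pairs, computed on group centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DivergenceResult",
    "summarize_nanostructure",
    "pca",
    "parent_bias_mismatch_2d",
    "average_pairwise_divergence",
]

#: columns required for a nanostructure summary (air measured twice)
NANO_TRAITS = ("cortex", "pt_top", "mel", "ker", "n_layers")
AIR_COLS = ("air_par", "air_perp")


@dataclass(frozen=True)
class DivergenceResult:
    d_parent_bias: float
    d_mismatch: float
    per_pair: pd.DataFrame | None = field(default=None, compare=False)


def summarize_nanostructure(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-image trait means with 95% CIs across images.

    ``measurements`` has one row per individual measurement with an ``image``
    column, trait columns, and the air diameter measured both parallel and
    perpendicular to the barbule surface. Air spaces are assumed roughly
    isometric in cross-section, so ``air`` is the mean of the two directions
    (sectioning deformation acts mostly perpendicular).

    Returns a frame with one row per image (trait means) plus summary
    attributes ``.attrs['ci95']`` mapping trait -> (lo, hi) across images;
    the CI is flagged undefined (NaN) with a single image.
    """
    for col in AIR_COLS + NANO_TRAITS:
        if col not in measurements.columns:
            raise ValueError(f"missing required column {col!r}")
    df = measurements.copy()
    df["air"] = (df["air_par"] + df["air_perp"]) / 2.0
    keep = ["air", *NANO_TRAITS]
    group_cols = [c for c in ("image",) if c in df.columns]
    if not group_cols:
        raise ValueError("measurements need an 'image' column")
    per_image = df.groupby("image")[keep].mean()
    ci = {}
    n = len(per_image)
    for t in keep:
        if n < 2:
            ci[t] = (float("nan"), float("nan"))
        else:
            m = per_image[t].mean()
            half = 1.96 * per_image[t].std(ddof=1) / np.sqrt(n)
            ci[t] = (m - half, m + half)
    per_image.attrs["ci95"] = ci
    per_image.attrs["n_images"] = n
    return per_image


def pca(table: pd.DataFrame, centre: bool = True, scale: bool = False):
    """PCA by eigendecomposition of the (optionally scaled) covariance.

    Sign convention: within each component the largest-magnitude loading is
    positive. Returns (scores, loadings, variance_explained_percent).
    """
    X = table.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    mu = X.mean(axis=0) if centre else np.zeros(X.shape[1])
    Xc = X - mu
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance column cannot be scaled")
        Xc = Xc / sd
    cov = np.cov(Xc, rowvar=False)
    if not np.any(cov):
        raise ValueError("rank-0 input")
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0.0, None)
    for j in range(vecs.shape[1]):
        if vecs[np.argmax(np.abs(vecs[:, j])), j] < 0:
            vecs[:, j] = -vecs[:, j]
    scores = Xc @ vecs
    var_pct = 100.0 * vals / vals.sum()
    cols = [f"PC{i + 1}" for i in range(vecs.shape[1])]
    return (
        pd.DataFrame(scores, index=table.index, columns=cols),
        pd.DataFrame(vecs, index=table.columns, columns=cols),
        var_pct,
    )


def parent_bias_mismatch_2d(p1, p2, h) -> DivergenceResult:
    """Transgression metrics for one 2-D plane (see module docstring)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h = np.asarray(h, dtype=float)
    v = p2 - p1
    sep = np.linalg.norm(v)
    if sep == 0:
        raise ValueError("parental centroids coincide; transect undefined")
    vhat = v / sep
    w = h - (p1 + p2) / 2.0
    along = float(np.dot(w, vhat))
    perp = float(np.linalg.norm(w - along * vhat))
    return DivergenceResult(
        d_parent_bias=abs(along) / (sep / 2.0),
        d_mismatch=perp / sep,
    )


def _centroids(table: pd.DataFrame, group_col: str = "group"):
    if group_col not in table.columns:
        raise ValueError(f"missing {group_col!r} column")
    groups = table.groupby(group_col)
    want = {"parent1", "parent2", "hybrid"}
    have = set(groups.groups)
    if not want <= have:
        raise ValueError(f"need groups {sorted(want)}, have {sorted(have)}")
    num = table.drop(columns=[group_col])
    cent = groups[num.columns.tolist()].mean()
    return cent.loc["parent1"], cent.loc["parent2"], cent.loc["hybrid"]


def average_pairwise_divergence(
    table: pd.DataFrame, group_col: str = "group"
) -> DivergenceResult:
    """Mean transgression metrics over all unordered 2-D trait pairs.

    Group centroids (arithmetic means of rows labelled parent1 / parent2 /
    hybrid) are projected into each pair of trait columns; the per-pair
    metrics are averaged, with the full breakdown attached.
    """
    c1, c2, ch = _centroids(table, group_col)
    traits = list(c1.index)
    if len(traits) < 2:
        raise ValueError("need at least 2 trait columns")
    rows = []
    for i in range(len(traits)):
        for j in range(i + 1, len(traits)):
            ta, tb = traits[i], traits[j]
            r = parent_bias_mismatch_2d(
                [c1[ta], c1[tb]], [c2[ta], c2[tb]], [ch[ta], ch[tb]]
            )
            rows.append((ta, tb, r.d_parent_bias, r.d_mismatch))
    per_pair = pd.DataFrame(
        rows, columns=["trait_a", "trait_b", "d_parent_bias", "d_mismatch"]
    )
    return DivergenceResult(
        d_parent_bias=float(per_pair["d_parent_bias"].mean()),
        d_mismatch=float(per_pair["d_mismatch"].mean()),
        per_pair=per_pair,
    )
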