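"""Evaluation statistics: silhouette over given labels and pseudo-time r².

The silhouette of cell i contrasts its mean intra-cluster distance a_i with
the mean distance b_i to the nearest other cluster:

    s_i = (b_i - a_i) / max(a_i, b_i)

and is reported per cell and as the mean over cells.  Pseudo-time accuracy is
the squared Pearson correlation of an inferred pseudo-time vector against
ordered stage annotations, together with the least-squares line
y = a + b x, b = r s_y / s_x, a = ȳ - b x̄.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy import stats


@dataclass
class SilhouetteResult:
    s: np.ndarray
    a: np.ndarray
    b: np.ndarray
    mean_silhouette: float
    metric: str
    labels: np.ndarray
    singleton_mask: np.ndarray


def silhouette(
    X: np.ndarray, labels, metric: str = "euclidean"
) -> SilhouetteResult:
    """Per-cell and mean silhouette of ``X`` under the given cluster labels.

    Cells in singleton clusters get s_i = 0 (a_i is undefined there) and are
    flagged.  Raises if fewer than two clusters are present.
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("matrix must be finite")
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels length must match number of rows")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least two clusters")

    D = cdist(X, X, metric=metric)
    n = X.shape[0]
    members = {u: np.flatnonzero(labels == u) for u in uniq}
    a = np.zeros(n)
    b = np.full(n, np.inf)
    singleton = np.zeros(n, dtype=bool)
    for u in uniq:
        idx = members[u]
        within = D[np.ix_(idx, idx)]
        if idx.size == 1:
            singleton[idx] = True
            a[idx] = 0.0
        else:
            a[idx] = within.sum(axis=1) / (idx.size - 1)
        for v in uniq:
            if v == u:
                continue
            other = members[v]
            mean_to_v = D[np.ix_(idx, other)].mean(axis=1)
            b[idx] = np.minimum(b[idx], mean_to_v)
    denom = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom > 0, (b - a) / denom, 0.0)
    s[singleton] = 0.0
    return SilhouetteResult(
        s=s,
        a=a,
        b=b,
        mean_silhouette=float(s.mean()),
        metric=metric,
        labels=labels,
        singleton_mask=singleton,
    )


@dataclass
class PseudotimeFit:
    slope: float
    intercept: float
    r: float
    r_squared: float
    defined: bool = True


def stage_codes(stages) -> np.ndarray:
    """Numeric stages pass through; categorical/string stages become 0, 1, 2,
    ... in category order (or order of first appearance)."""
    stages = pd.Series(stages)
    if isinstance(stages.dtype, pd.CategoricalDtype):
        return stages.cat.codes.to_numpy(dtype=float)
    if pd.api.types.is_numeric_dtype(stages):
        return stages.to_numpy(dtype=float)
    seen: dict = {}
    codes = np.empty(len(stages), dtype=float)
    for i, v in enumerate(stages):
        codes[i] = seen.setdefault(v, len(seen))
    return codes


def pseudotime_r2(pseudotime, stages) -> PseudotimeFit:
    """Least-squares fit of pseudo-time on stage codes and its r².

    ``stages`` may be numeric codes or ordered categorical values (mapped to
    0, 1, 2, ... in order of first appearance).  Zero variance in either
    vector yields an explicitly flagged undefined fit rather than r² = 0.
    """
    y = np.asarray(pseudotime, dtype=float)
    x = stage_codes(stages)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("pseudotime and stages must be equal-length vectors")
    if y.size < 3:
        raise ValueError("need at least 3 cells")
    if np.unique(x).size < 2:
        raise ValueError("stages must have at least two distinct values")
    if np.std(y) == 0 or np.std(x) == 0:
        return PseudotimeFit(
            slope=np.nan, intercept=np.nan, r=np.nan, r_squared=np.nan, defined=False
        )
    r = float(stats.pearsonr(x, y).statistic)
    b = r * (np.std(y, ddof=1) / np.std(x, ddof=1))
    a = float(np.mean(y) - b * np.mean(x))
    return PseudotimeFit(slope=float(b), intercept=a, r=r, r_squared=r * r)


def compare_conditions(
    scenarios,
    *,
    denoiser=None,
    seeds=(0,),
    metric: str = "euclidean",
) -> pd.DataFrame:
    """Mean silhouette over true labels, raw vs denoised, per scenario x seed.

    ``scenarios`` is a list of (name, SimulationConfig) pairs or bare configs;
    ``denoiser`` maps a CountMatrix to a (matrix, labels) pair and defaults to
    the preprocessing-only identity (raw condition is always reported).
    """
    from dataclasses import replace

    from .preprocess import normalize
    from .simulate import simulate_counts

    rows = []
    for item in scenarios:
        name, config = item if isinstance(item, tuple) else (repr(item), item)
        for seed in seeds:
            cfg = replace(config, seed=int(seed))
            data = simulate_counts(cfg)
            norm = normalize(data, n_top=min(data.n_genes, 2000))
            raw_sil = silhouette(norm.z_scores, data.cell_labels, metric=metric)
            rows.append(
                {
                    "scenario": name,
                    "condition": "raw",
                    "seed": int(seed),
                    "mean_silhouette": raw_sil.mean_silhouette,
                }
            )
            if denoiser is not None:
                den_matrix, den_labels = denoiser(data)
                den_sil = silhouette(den_matrix, den_labels, metric=metric)
                rows.append(
                    {
                        "scenario": name,
                        "condition": "denoised",
                        "seed": int(seed),
                        "mean_silhouette": den_sil.mean_silhouette,
                    }
                )
    return pd.DataFrame(rows)
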