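"""Count-matrix preprocessing: HVG selection, z-scoring, unit-interval rescaling.

The network input is built in three deterministic steps: (1) rank genes by
mean-binned normalized dispersion and keep the top ``n_top``; (2) z-score each
selected gene, ``z = (G - mean) / sd``; (3) min-max map each gene into [0, 1]
so the binary-cross-entropy reconstruction loss is well defined.  Every step
stores the parameters needed to invert it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import CountMatrix


@dataclass
class HVGReport:
    """Per-gene dispersion statistics and ranking.

    ``table`` has columns mean, variance, dispersion, dispersion_norm, rank
    (1 = most variable; ranks are a permutation of 1..n_genes), and selected.
    """

    table: pd.DataFrame
    n_selected: int

    @property
    def selected_indices(self) -> np.ndarray:
        order = np.argsort(self.table["rank"].to_numpy(), kind="stable")
        return order[: self.n_selected]


def zscore(X: np.ndarray | CountMatrix, ddof: int = 0):
    """Per-gene z-scores with their means/sds; zero-variance genes get z = 0.

    Returns ``(z, means, sds, zero_variance_mask)``.  Raises on a single-cell
    input, where the variance is undefined.
    """
    if isinstance(X, CountMatrix):
        X = X.counts
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("zscore needs a 2-D matrix with at least 2 cells")
    if not np.isfinite(X).all():
        raise ValueError("input must be finite")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=ddof)
    zero_var = sds == 0
    safe_sds = np.where(zero_var, 1.0, sds)
    z = (X - means) / safe_sds
    z[:, zero_var] = 0.0
    return z, means, sds, zero_var


def _trend_expected_sd(means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """Expected sd from a quadratic mean-variance trend fitted on log scale."""
    pos = (means > 0) & (variances > 0)
    if pos.sum() < 3:
        return np.sqrt(variances)
    coef = np.polyfit(np.log1p(means[pos]), np.log(variances[pos]), deg=2)
    fitted = np.exp(np.polyval(coef, np.log1p(means)))
    return np.sqrt(np.maximum(fitted, 1e-12))


def select_hvg(
    data: CountMatrix | np.ndarray,
    n_top: int,
    *,
    n_bins: int = 20,
    log1p: bool = True,
) -> HVGReport:
    """Rank genes by normalized dispersion and select the top ``n_top``.

    Dispersion is variance/mean; within each of ``n_bins`` equal-count mean
    bins it is standardized (z-scored against the bin's dispersion mean and
    sd), so highly expressed genes do not dominate the ranking.  Ties break by
    gene index, zero-variance genes rank last.
    """
    X = data.counts if isinstance(data, CountMatrix) else np.asarray(data)
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("counts must be non-negative")
    n_genes = X.shape[1]
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_top > n_genes:
        raise ValueError("n_top exceeds the number of genes")
    if log1p:
        X = np.log1p(X)
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)

    # Standardize dispersion within equal-count mean bins.
    n_bins_eff = min(n_bins, n_genes)
    bin_edges = np.quantile(mean, np.linspace(0, 1, n_bins_eff + 1))
    bin_idx = np.clip(np.searchsorted(bin_edges, mean, side="right") - 1, 0, n_bins_eff - 1)
    disp_norm = np.zeros(n_genes)
    for b in np.unique(bin_idx):
        in_bin = bin_idx == b
        d = disp[in_bin]
        sd = d.std(ddof=0)
        disp_norm[in_bin] = (d - d.mean()) / sd if sd > 0 else 0.0

    positive_var = var > 0
    # Sort key: zero-variance genes last, then descending normalized dispersion,
    # then gene index (stable sort gives the index tie-break for free).
    order = np.lexsort((np.arange(n_genes), -disp_norm, ~positive_var))
    rank = np.empty(n_genes, dtype=int)
    rank[order] = np.arange(1, n_genes + 1)

    table = pd.DataFrame(
        {
            "mean": mean,
            "variance": var,
            "dispersion": disp,
            "dispersion_norm": disp_norm,
            "rank": rank,
            "selected": rank <= n_top,
        }
    )
    if isinstance(data, CountMatrix):
        table.index = np.asarray(data.gene_ids, dtype=str)
    return HVGReport(table=table, n_selected=n_top)


@dataclass
class NormalizedMatrix:
    """[0,1]-scaled network input plus everything needed to invert it."""

    values: np.ndarray
    z_scores: np.ndarray
    selected_gene_ids: np.ndarray
    gene_means: np.ndarray
    gene_sds: np.ndarray
    scale_min: np.ndarray
    scale_max: np.ndarray
    cell_labels: np.ndarray | None = None
    zero_variance: np.ndarray | None = None
    log1p: bool = False

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


def rescale_unit(
    z: np.ndarray,
    *,
    z_scores: np.ndarray | None = None,
    selected_gene_ids: np.ndarray | None = None,
    gene_means: np.ndarray | None = None,
    gene_sds: np.ndarray | None = None,
    cell_labels: np.ndarray | None = None,
    zero_variance: np.ndarray | None = None,
    log1p: bool = False,
) -> NormalizedMatrix:
    """Per-gene min-max map into [0, 1]; constant columns map to 0.5."""
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("z-scores must be finite")
    lo = z.min(axis=0)
    hi = z.max(axis=0)
    span = hi - lo
    constant = span == 0
    safe_span = np.where(constant, 1.0, span)
    vals = (z - lo) / safe_span
    vals[:, constant] = 0.5
    n_genes = z.shape[1]
    return NormalizedMatrix(
        values=vals,
        z_scores=z if z_scores is None else z_scores,
        selected_gene_ids=(
            np.arange(n_genes) if selected_gene_ids is None else selected_gene_ids
        ),
        gene_means=np.zeros(n_genes) if gene_means is None else gene_means,
        gene_sds=np.ones(n_genes) if gene_sds is None else gene_sds,
        scale_min=lo,
        scale_max=hi,
        cell_labels=cell_labels,
        zero_variance=zero_variance,
        log1p=log1p,
    )


def inverse_rescale(norm: NormalizedMatrix, values: np.ndarray | None = None) -> np.ndarray:
    """Map [0,1] values back to the z-score scale using the stored bounds."""
    v = norm.values if values is None else np.asarray(values, dtype=float)
    span = norm.scale_max - norm.scale_min
    constant = span == 0
    z = v * np.where(constant, 0.0, span) + norm.scale_min
    z[:, constant] = norm.scale_min[constant]
    return z


def inverse_zscore(norm: NormalizedMatrix, z: np.ndarray | None = None) -> np.ndarray:
    """Map z-scores back to the (possibly log1p) expression scale."""
    zz = norm.z_scores if z is None else np.asarray(z, dtype=float)
    sds = np.where(norm.gene_sds == 0, 0.0, norm.gene_sds)
    return zz * sds + norm.gene_means


def inverse_expression(norm: NormalizedMatrix, values: np.ndarray | None = None) -> np.ndarray:
    """Full inversion of the chain: [0,1] values -> original expression scale."""
    expr = inverse_zscore(norm, inverse_rescale(norm, values))
    return np.expm1(expr) if norm.log1p else expr


def normalize(
    data: CountMatrix,
    n_top: int | None = None,
    *,
    log1p: bool = True,
    sigma_mode: str = "per_gene",
    n_bins: int = 20,
) -> NormalizedMatrix:
    """Full preprocessing chain: HVG selection -> z-score -> [0,1] rescale.

    ``sigma_mode`` selects the divisor of the z-score: ``"per_gene"`` uses the
    plain per-gene standard deviation; ``"trend"`` uses the expected sd from a
    fitted global mean-variance trend.
    """
    if sigma_mode not in ("per_gene", "trend"):
        raise ValueError(f"unknown sigma_mode: {sigma_mode!r}")
    X = np.asarray(data.counts, dtype=float)
    if n_top is None:
        n_top = min(X.shape[1], 2000)
    report = select_hvg(data, n_top, n_bins=n_bins, log1p=log1p)
    idx = report.selected_indices
    sub = np.log1p(X[:, idx]) if log1p else X[:, idx]

    means = sub.mean(axis=0)
    if sigma_mode == "per_gene":
        sds = sub.std(axis=0, ddof=0)
    else:
        sds = _trend_expected_sd(means, sub.var(axis=0, ddof=0))
        sds[sub.std(axis=0, ddof=0) == 0] = 0.0
    zero_var = sds == 0
    z = (sub - means) / np.where(zero_var, 1.0, sds)
    z[:, zero_var] = 0.0

    return rescale_unit(
        z,
        selected_gene_ids=np.asarray(data.gene_ids)[idx],
        gene_means=means,
        gene_sds=sds,
        cell_labels=None if data.cell_labels is None else data.cell_labels.copy(),
        zero_variance=zero_var,
        log1p=log1p,
    )
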