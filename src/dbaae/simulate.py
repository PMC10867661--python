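"""Synthetic scRNA-seq count matrices with known group structure and dropout.

The generator follows the gamma-Poisson hierarchy popularized by the Splatter
simulator: per-gene baseline means are gamma distributed, per-cell library-size
factors are log-normal, group identity multiplies a subset of genes by
log-normal differential-expression factors, and observed counts are Poisson
around the resulting expected value.  Dropout is a separate, explicitly masked
zeroing step whose probability follows a logistic curve in the log expected
value, so technical zeros can be distinguished from biological zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class ConfigurationError(ValueError):
    """A simulation parameter violates its contract; the message names the field."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the gamma-Poisson group simulation.

    Attributes
    ----------
    n_genes, n_cells, n_groups
        Matrix dimensions and number of virtual cell types.
    group_proportions
        Probability of each group; defaults to uniform. Must sum to 1.
    mean_shape, mean_rate
        Gamma(shape, rate) distribution of baseline gene mean proportions.
    libsize_location, libsize_scale
        Log-normal parameters of per-cell expected total counts.
    de_prob
        Probability that a gene is differentially expressed in a given group.
    de_log2fc_sd
        Standard deviation (log2 scale) of DE multiplicative factors.
    dropout_enabled, dropout_midpoint, dropout_shape
        Whether and how the logistic dropout step is applied; see
        :func:`apply_dropout`.
    seed
        RNG seed; identical config + seed gives bit-identical output.
    """

    n_genes: int = 200
    n_cells: int = 2000
    n_groups: int = 2
    group_proportions: tuple[float, ...] | None = None
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    libsize_location: float = 7.0
    libsize_scale: float = 0.2
    de_prob: float = 0.3
    de_log2fc_sd: float = 1.0
    dropout_enabled: bool = False
    dropout_midpoint: float = 2.0
    dropout_shape: float = 1.5
    seed: int = 0

    def proportions(self) -> np.ndarray:
        if self.group_proportions is None:
            return np.full(self.n_groups, 1.0 / self.n_groups)
        return np.asarray(self.group_proportions, dtype=float)

    def validate(self) -> None:
        for name in ("n_genes", "n_cells", "n_groups"):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be a positive integer")
        for name in ("mean_shape", "mean_rate", "libsize_scale", "de_log2fc_sd"):
            if float(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if not 0.0 <= self.de_prob <= 1.0:
            raise ConfigurationError("de_prob must lie in [0, 1]")
        p = self.proportions()
        if p.shape != (self.n_groups,):
            raise ConfigurationError(
                "group_proportions length must equal n_groups"
            )
        if (p < 0).any():
            raise ConfigurationError("group_proportions entries must be >= 0")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError("group_proportions must sum to 1")


def fig2_preset(
    n_groups: int = 6, *, n_cells: int = 2000, dropout: bool = True, seed: int = 0
) -> SimulationConfig:
    """Preset mirroring the simulated benchmark layout: 200 genes, 2/6/8 groups.

    Distributional parameter values are package defaults (Splatter-style), not
    values taken from any publication.
    """
    return SimulationConfig(
        n_genes=200,
        n_cells=n_cells,
        n_groups=n_groups,
        dropout_enabled=dropout,
        seed=seed,
    )


@dataclass
class CountMatrix:
    """Raw cells x genes count matrix with per-cell group labels.

    ``means`` carries the per-entry expected value of the Poisson draw; it is
    required by :func:`apply_dropout` and preserved through h5ad round trips.
    """

    counts: np.ndarray
    cell_labels: np.ndarray | None
    gene_ids: np.ndarray
    is_dropout_mask: np.ndarray | None = None
    means: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        c = self.counts
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(c.dtype, np.integer):
            if not np.allclose(c, np.round(c)):
                raise ValueError("counts must be integer-valued")
        if self.cell_labels is not None and len(self.cell_labels) != c.shape[0]:
            raise ValueError("cell_labels length must equal number of cells")
        if len(self.gene_ids) != c.shape[1]:
            raise ValueError("gene_ids length must equal number of genes")
        if self.is_dropout_mask is not None:
            if self.is_dropout_mask.shape != c.shape:
                raise ValueError("dropout mask shape must match counts")
            if (c[self.is_dropout_mask] != 0).any():
                raise ValueError("masked entries must be zero")


def simulate_counts(config: SimulationConfig) -> CountMatrix:
    """Draw a count matrix under ``config`` (dropout is *not* applied here).

    The expected value of entry (c, g) is ``libsize_c * p_gk`` where ``p_gk``
    is the per-group normalized expression proportion of gene g: baseline gamma
    mean times the group's DE factor, renormalized over genes so library size
    has its usual interpretation as expected total counts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    base_mean = rng.gamma(config.mean_shape, 1.0 / config.mean_rate, size=config.n_genes)
    # Per-group multiplicative DE factors, log-normal around 1 on the log2 scale.
    is_de = rng.random((config.n_groups, config.n_genes)) < config.de_prob
    log2fc = rng.normal(0.0, config.de_log2fc_sd, size=(config.n_groups, config.n_genes))
    de_factor = np.where(is_de, np.exp2(log2fc), 1.0)

    group_mean = base_mean[None, :] * de_factor          # groups x genes
    group_prop = group_mean / group_mean.sum(axis=1, keepdims=True)

    labels_idx = rng.choice(config.n_groups, size=config.n_cells, p=config.proportions())
    libsize = rng.lognormal(config.libsize_location, config.libsize_scale, size=config.n_cells)

    means = libsize[:, None] * group_prop[labels_idx, :]  # cells x genes
    counts = rng.poisson(means).astype(np.int64)

    labels = np.array([f"Group{k + 1}" for k in labels_idx])
    gene_ids = np.array([f"Gene{g + 1}" for g in range(config.n_genes)])
    out = CountMatrix(counts=counts, cell_labels=labels, gene_ids=gene_ids, means=means)
    if config.dropout_enabled:
        out = apply_dropout(
            out, config.dropout_midpoint, config.dropout_shape, seed=config.seed + 1
        )
    return out


def dropout_probability(means: np.ndarray, midpoint: float, shape: float) -> np.ndarray:
    """Logistic zeroing probability p = 1 / (1 + exp(-shape * (midpoint - ln(1+mu)))).

    Positive ``shape`` makes lowly expressed entries (log1p mean below the
    midpoint) more likely to drop out, the documented behavior of
    logistic-of-log-mean dropout simulators.
    """
    from scipy.special import expit

    return expit(shape * (midpoint - np.log1p(means)))


def apply_dropout(
    data: CountMatrix, midpoint: float, shape: float, seed: int
) -> CountMatrix:
    """Independently zero entries with logistic probability in their expected value.

    Requires the expected-value channel produced by :func:`simulate_counts`.
    Returns a new matrix; non-zeroed entries are unchanged and the applied
    mask is recorded in ``is_dropout_mask``.
    """
    if data.means is None:
        raise ValueError(
            "apply_dropout needs per-entry expected values; the matrix was not "
            "produced by simulate_counts and no means were supplied"
        )
    if (data.counts < 0).any():
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    p = dropout_probability(data.means, midpoint, shape)
    mask = rng.random(data.counts.shape) < p
    counts = np.where(mask, 0, data.counts)
    return CountMatrix(
        counts=counts.astype(np.int64),
        cell_labels=None if data.cell_labels is None else data.cell_labels.copy(),
        gene_ids=data.gene_ids.copy(),
        is_dropout_mask=mask,
        means=data.means.copy(),
    )


# ---------------------------------------------------------------------------
# I/O: AnnData h5ad round trip plus thin CSV / MatrixMarket export


def to_anndata(data: CountMatrix) -> ad.AnnData:
    obs = pd.DataFrame(index=[f"Cell{i + 1}" for i in range(data.n_cells)])
    if data.cell_labels is not None:
        obs["cell_type"] = pd.Categorical(data.cell_labels)
    var = pd.DataFrame(index=np.asarray(data.gene_ids, dtype=str))
    adata = ad.AnnData(X=data.counts.copy(), obs=obs, var=var)
    if data.is_dropout_mask is not None:
        adata.layers["dropout_mask"] = data.is_dropout_mask.astype(np.uint8)
    if data.means is not None:
        adata.layers["expected_mean"] = data.means.copy()
    return adata


def from_anndata(adata: ad.AnnData) -> CountMatrix:
    X = adata.X
    if sparse.issparse(X):
        X = X.toarray()
    X = np.asarray(X)
    if np.allclose(X, np.round(X)):
        X = np.round(X).astype(np.int64)
    labels = None
    if "cell_type" in adata.obs:
        labels = np.asarray(adata.obs["cell_type"].astype(str))
    mask = None
    if "dropout_mask" in adata.layers:
        mask = np.asarray(adata.layers["dropout_mask"]).astype(bool)
    means = None
    if "expected_mean" in adata.layers:
        means = np.asarray(adata.layers["expected_mean"], dtype=float)
    return CountMatrix(
        counts=X,
        cell_labels=labels,
        gene_ids=np.asarray(adata.var_names),
        is_dropout_mask=mask,
        means=means,
    )


def write_h5ad(data: CountMatrix, path: str | Path) -> None:
    to_anndata(data).write_h5ad(Path(path))


def read_h5ad(path: str | Path) -> CountMatrix:
    try:
        adata = ad.read_h5ad(Path(path))
    except Exception as exc:  # pragma: no cover - passthrough context
        raise ValueError(f"could not parse h5ad file {path}: {exc}") from exc
    return from_anndata(adata)


def write_csv(data: CountMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        data.counts, columns=np.asarray(data.gene_ids, dtype=str)
    )
    if data.cell_labels is not None:
        df.insert(0, "cell_type", data.cell_labels)
    df.to_csv(Path(path), index=False)


def write_mtx(data: CountMatrix, path: str | Path) -> None:
    spio.mmwrite(str(path), sparse.csr_matrix(data.counts))
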