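"""End-to-end orchestration: read -> preprocess -> batch search -> train ->
reconstruct -> inverse transform -> write.

A run is fully described by a serializable :class:`RunConfig`; the config, the
batch-search records and the selection are embedded in the output AnnData so
any run can be replayed from its own output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np

from .aae import AAEConfig, AAEModel
from .batching import (
    BatchSearchConfig,
    BatchSearchRecord,
    final_train,
    records_to_frame,
    search,
)
from .preprocess import NormalizedMatrix, inverse_rescale, inverse_zscore, normalize
from .simulate import CountMatrix, from_anndata, read_h5ad


@dataclass
class RunConfig:
    """Everything needed to reproduce a denoising run."""

    input_path: str | None = None
    output_path: str | None = None
    n_top_hvg: int | None = None
    log1p: bool = True
    sigma_mode: str = "per_gene"
    batch_search: BatchSearchConfig = field(default_factory=BatchSearchConfig)
    model: AAEConfig = field(default_factory=AAEConfig)
    output_scale: str = "zscore"  # or "expression"
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["batch_search"] = BatchSearchConfig(**d["batch_search"])
        d["model"] = AAEConfig.from_dict(d["model"])
        return cls(**d)


@dataclass
class DenoisedOutput:
    denoised: np.ndarray
    selected_gene_ids: np.ndarray
    selected_batch_size: int
    records: list[BatchSearchRecord]
    loss_trajectory: list
    normalized: NormalizedMatrix
    model: AAEModel
    config: RunConfig


def denoise(
    config: RunConfig, data: CountMatrix | None = None
) -> DenoisedOutput:
    """Run the full denoising chain and (optionally) write the output h5ad."""
    if data is None:
        if config.input_path is None:
            raise ValueError("either a CountMatrix or config.input_path is required")
        path = Path(config.input_path)
        if not path.exists():
            raise FileNotFoundError(f"input file not found: {path}")
        data = read_h5ad(path)

    norm = normalize(
        data, n_top=config.n_top_hvg, log1p=config.log1p, sigma_mode=config.sigma_mode
    )

    bs_config = BatchSearchConfig(
        **{**asdict(config.batch_search), "seed": config.seed}
    )
    model_cfg = AAEConfig(
        **{**config.model.to_dict(), "input_dim": norm.n_genes, "seed": config.seed}
    )
    selected, records = search(bs_config, norm, model_cfg)
    model, trajectory = final_train(
        model_cfg, norm, selected, bs_config.final_epochs, config.seed
    )
    recon = model.reconstruct_full(norm.values, selected)
    denoised_z = inverse_rescale(norm, recon)
    if config.output_scale == "expression":
        denoised = inverse_zscore(norm, denoised_z)
        if norm.log1p:
            denoised = np.expm1(denoised)
    else:
        denoised = denoised_z

    out = DenoisedOutput(
        denoised=denoised,
        selected_gene_ids=norm.selected_gene_ids,
        selected_batch_size=selected,
        records=records,
        loss_trajectory=trajectory,
        normalized=norm,
        model=model,
        config=config,
    )
    if config.output_path is not None:
        write_denoised(out, data, Path(config.output_path))
    return out


def write_denoised(out: DenoisedOutput, data: CountMatrix, path: Path) -> None:
    """Persist the HVG-subset raw counts with the denoised layer and metadata."""
    import pandas as pd

    gene_index = {g: i for i, g in enumerate(np.asarray(data.gene_ids))}
    idx = np.array([gene_index[g] for g in np.asarray(out.selected_gene_ids)])
    obs = pd.DataFrame(index=[f"Cell{i + 1}" for i in range(data.n_cells)])
    if data.cell_labels is not None:
        obs["cell_type"] = pd.Categorical(data.cell_labels)
    adata = ad.AnnData(
        X=np.asarray(data.counts)[:, idx].copy(),
        obs=obs,
        var=pd.DataFrame(index=np.asarray(out.selected_gene_ids, dtype=str)),
    )
    adata.layers["dbaae_denoised"] = out.denoised
    adata.uns["dbaae"] = {
        "config": json.dumps(out.config.to_dict()),
        "selected_batch_size": int(out.selected_batch_size),
        "search_records": records_to_frame(out.records).to_dict(orient="list"),
        "final_rec_loss": (
            float(out.loss_trajectory[-1].L_rec) if out.loss_trajectory else float("nan")
        ),
    }
    adata.write_h5ad(path)


def read_run_config(path: str | Path) -> RunConfig:
    """Recover the RunConfig embedded in a denoised output file."""
    adata = ad.read_h5ad(Path(path))
    return RunConfig.from_dict(json.loads(adata.uns["dbaae"]["config"]))
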