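"""Dynamic batch-size search: sweep candidate sizes, record, select, retrain.

Each candidate batch size gets a fresh model (seeded per candidate so records
are comparable) trained for a short cycle; the cycle stores the candidate's
minimum reconstruction loss and a held-out accuracy.  The winner minimizes
the recorded minimum loss, with ties broken by higher accuracy and then by
smaller batch size, and is used for the final full training run.  An optional
successive-halving mode (``hyperband``) prunes weak candidates early instead
of training every one to the full cycle length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aae import AAEConfig, AAEModel, StepLosses, train
from .preprocess import NormalizedMatrix


@dataclass(frozen=True)
class BatchSearchConfig:
    batch_start: int = 32
    batch_end: int = 256
    batch_step: int = 32
    epochs_per_cycle: int = 20
    final_epochs: int = 300
    seed: int = 0
    holdout_fraction: float = 0.1
    strategy: str = "sweep"  # or "hyperband" (successive halving)

    def validate(self) -> None:
        if self.batch_start <= 0 or self.batch_end <= 0:
            raise ValueError("batch sizes must be positive")
        if self.batch_start > self.batch_end:
            raise ValueError("batch_start must be <= batch_end")
        if self.batch_step < 1:
            raise ValueError("batch_step must be >= 1")
        if self.strategy not in ("sweep", "hyperband"):
            raise ValueError(f"unknown strategy {self.strategy!r}")

    def candidates(self, n_cells: int) -> list[int]:
        grid = range(self.batch_start, self.batch_end + 1, self.batch_step)
        out = sorted({min(b, n_cells) for b in grid if b >= 1})
        return out


@dataclass
class BatchSearchRecord:
    batch_size: int
    accuracy: float
    min_loss: float
    epochs_run: int


def _holdout_split(n_cells: int, fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_cells)
    n_hold = max(1, int(round(fraction * n_cells))) if fraction > 0 else 0
    return perm[n_hold:], perm[:n_hold]


def _cycle_accuracy(model: AAEModel, held_out: np.ndarray) -> float:
    """1 - mean absolute reconstruction error on held-out cells (in [0, 1])."""
    if held_out.shape[0] == 0:
        return float("nan")
    recon = model.reconstruct_full(held_out, batch_size=max(1, held_out.shape[0]))
    return float(1.0 - np.mean(np.abs(held_out - recon)))


def run_cycle(
    model_config: AAEConfig,
    data: NormalizedMatrix,
    batch_size: int,
    epochs: int,
    seed: int,
    *,
    holdout_fraction: float = 0.1,
) -> BatchSearchRecord:
    """Train a fresh model at one candidate batch size and record the outcome."""
    n_cells = data.n_cells
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if batch_size > n_cells:
        import warnings

        warnings.warn(
            f"batch_size {batch_size} exceeds n_cells {n_cells}; clipping",
            stacklevel=2,
        )
        batch_size = n_cells
    train_idx, hold_idx = _holdout_split(n_cells, holdout_fraction, seed)
    train_vals = data.values[train_idx]
    hold_vals = data.values[hold_idx]

    cfg = AAEConfig(**{**model_config.to_dict(), "input_dim": data.n_genes, "seed": seed})
    model = AAEModel(cfg)
    if epochs > 0:
        traj = train(model, train_vals, batch_size, epochs, seed=seed)
        min_loss = float(min(s.L_rec for s in traj))
    else:
        # empty cycle: report the untrained model's reconstruction loss
        from .aae import reconstruction_loss

        recon = model.reconstruct_full(train_vals, batch_size)
        min_loss = reconstruction_loss(train_vals, recon)
    accuracy = _cycle_accuracy(model, hold_vals)
    return BatchSearchRecord(
        batch_size=batch_size, accuracy=accuracy, min_loss=min_loss, epochs_run=epochs
    )


def select_from_records(records: list[BatchSearchRecord]) -> int:
    """Pure selection rule: min loss, then max accuracy, then smaller batch."""
    finite = [r for r in records if np.isfinite(r.min_loss)]
    if not finite:
        diag = ", ".join(
            f"batch={r.batch_size}: loss={r.min_loss}" for r in records
        )
        raise RuntimeError(f"all search cycles diverged ({diag})")
    acc = lambda r: r.accuracy if np.isfinite(r.accuracy) else -np.inf
    best = min(finite, key=lambda r: (r.min_loss, -acc(r), r.batch_size))
    return best.batch_size


def search(
    config: BatchSearchConfig,
    data: NormalizedMatrix,
    model_config: AAEConfig | None = None,
) -> tuple[int, list[BatchSearchRecord]]:
    """Run one cycle per candidate batch size and pick the winner."""
    config.validate()
    model_config = model_config or AAEConfig(input_dim=data.n_genes)
    candidates = config.candidates(data.n_cells)
    if not candidates:
        raise ValueError("candidate batch-size list is empty")
    seeds = np.random.SeedSequence(config.seed).generate_state(len(candidates))
    records: list[BatchSearchRecord] = []
    if config.strategy == "sweep":
        for bs, s in zip(candidates, seeds):
            records.append(
                run_cycle(
                    model_config,
                    data,
                    bs,
                    config.epochs_per_cycle,
                    int(s % 2**31),
                    holdout_fraction=config.holdout_fraction,
                )
            )
    else:  # successive halving over the same grid
        rungs = max(1, int(np.ceil(np.log2(len(candidates)))))
        survivors = list(zip(candidates, seeds))
        budget = max(1, config.epochs_per_cycle // rungs)
        epochs_used = {bs: 0 for bs in candidates}
        scores: dict[int, BatchSearchRecord] = {}
        for rung in range(rungs):
            for bs, s in survivors:
                epochs_used[bs] += budget
                rec = run_cycle(
                    model_config,
                    data,
                    bs,
                    epochs_used[bs],
                    int(s % 2**31),
                    holdout_fraction=config.holdout_fraction,
                )
                scores[bs] = rec
            survivors.sort(key=lambda c: scores[c[0]].min_loss)
            keep = max(1, len(survivors) // 2)
            if rung < rungs - 1:
                survivors = survivors[:keep]
        records = [scores[bs] for bs in candidates]
    selected = select_from_records(records)
    return selected, records


def final_train(
    model_config: AAEConfig,
    data: NormalizedMatrix,
    batch_size: int,
    epochs: int,
    seed: int,
    *,
    early_stop_patience: int | None = 20,
    early_stop_tol: float = 1e-5,
) -> tuple[AAEModel, list[StepLosses]]:
    """Train the final model at the selected batch size on all cells."""
    cfg = AAEConfig(**{**model_config.to_dict(), "input_dim": data.n_genes, "seed": seed})
    model = AAEModel(cfg)
    trajectory: list[StepLosses] = []
    if epochs > 0:
        trajectory = train(
            model,
            data.values,
            batch_size,
            epochs,
            seed=seed,
            early_stop_patience=early_stop_patience,
            early_stop_tol=early_stop_tol,
        )
        if trajectory and not np.isfinite(trajectory[-1].L_rec):
            raise RuntimeError("final training diverged; see trajectory")
    return model, trajectory


def records_to_frame(records: list[BatchSearchRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "batch_size": r.batch_size,
                "accuracy": r.accuracy,
                "min_loss": r.min_loss,
                "epochs_run": r.epochs_run,
            }
            for r in records
        ]
    )
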