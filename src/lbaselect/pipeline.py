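"""Study orchestration: job planning, execution, aggregation, figures.

A study is the cross of a replicate-expanded design with the four model
fits per dataset and the selection methods per fit. Jobs derive their
seeds deterministically from the master seed, so any execution order (and
resuming after an interrupt) yields identical results.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .design import DesignCell, design_manifest, enumerate_cells, generate_dataset
from .metrics import ALL_METHODS
from .model_space import VARIANTS
from .scoring import agreement_matrix, score_cell
from .selection import compare_models

__all__ = [
    "StudyConfig",
    "plan_jobs",
    "run_study",
    "summarize",
    "plot_heatmap",
    "read_metrics",
]

log = logging.getLogger("lbaselect")


def read_metrics(path) -> pd.DataFrame:
    """Read a tidy metrics CSV ('null' is a variant name, not a missing value)."""
    return pd.read_csv(path, keep_default_na=False, na_values=[""])


@dataclass
class StudyConfig:
    """Everything needed to (re)run a study deterministically."""

    design: str = "main"
    cells: Optional[List[str]] = None  # subset of cell labels, e.g. ["NN", "MME"]
    replicates: int = 100
    trials_per_condition: int = 300
    methods: Sequence[str] = tuple(ALL_METHODS)
    parameterization: str = "per-condition"
    prior_level: str = "default"
    n_chains: Optional[int] = None  # default: 3k
    burn: int = 1000
    keep: int = 1000
    n_temperatures: int = 40
    alpha: float = 0.05
    master_seed: int = 0
    outdir: str = "study_out"

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["methods"] = list(self.methods)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def dataset_cells(self) -> List[DesignCell]:
        cells = enumerate_cells(
            self.design, self.replicates, self.trials_per_condition
        )
        if self.cells is not None:
            keep = set(self.cells)
            known = {c.label for c in cells}
            bad = keep - known
            if bad:
                raise ValueError(f"unknown cell labels {sorted(bad)}")
            cells = [c for c in cells if c.label in keep]
            if not cells:
                raise ValueError("cell filter selected no datasets")
        return cells


def plan_jobs(config: StudyConfig) -> pd.DataFrame:
    """Deterministic job manifest: one row per (dataset, model) fit.

    Each fit carries one evaluation per requested method (the chi-square
    decision tree spans models but is booked once per model, matching the
    fits x methods accounting of the study).
    """
    cells = config.dataset_cells()
    manifest = design_manifest(cells, config.master_seed)
    rows = []
    for _, d in manifest.iterrows():
        for variant in VARIANTS:
            rows.append(
                {
                    "dataset_id": d["dataset_id"],
                    "cell": d["cell"],
                    "replicate": d["replicate"],
                    "true_variant": d["true_variant"],
                    "variant": variant,
                    "n_metrics": len(config.methods),
                }
            )
    return pd.DataFrame(rows)


def _dataset_seed(config: StudyConfig, dataset_id: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        entropy=config.master_seed, spawn_key=(7001, dataset_id)
    )


def run_study(config: StudyConfig, resume: bool = True) -> pd.DataFrame:
    """Generate, fit, and score every dataset of a study; returns tidy metrics.

    Results stream to ``<outdir>/metrics.csv``; with ``resume=True``,
    datasets already present there are skipped. A failing dataset is logged
    and recorded in ``failures.csv`` without stopping the study.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cells = config.dataset_cells()
    manifest = design_manifest(cells, config.master_seed)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    config.to_yaml(outdir / "config.yaml")

    metrics_path = outdir / "metrics.csv"
    done = set()
    if resume and metrics_path.exists():
        done = set(pd.read_csv(metrics_path, usecols=["dataset_id"])["dataset_id"])
    elif metrics_path.exists():
        metrics_path.unlink()

    for _, d in manifest.iterrows():
        did = int(d["dataset_id"])
        if did in done:
            continue
        cell = cells[did]
        try:
            data = generate_dataset(cell, config.master_seed)
            sel = compare_models(
                data,
                methods=config.methods,
                parameterization=config.parameterization,
                prior_level=config.prior_level,
                n_chains=config.n_chains,
                burn=config.burn,
                keep=config.keep,
                n_temperatures=config.n_temperatures,
                alpha=config.alpha,
                seed=_dataset_seed(config, did),
            )
            rows = sel.to_tidy(
                dataset_id=did,
                cell=d["cell"],
                replicate=int(d["replicate"]),
                true_variant=d["true_variant"],
            )
            rows.to_csv(
                metrics_path, mode="a", header=not metrics_path.exists(), index=False
            )
            log.info("dataset %d (%s rep %d) done", did, d["cell"], d["replicate"])
        except Exception:  # noqa: BLE001 - keep the study alive
            log.exception("dataset %d failed", did)
            pd.DataFrame([{"dataset_id": did, "cell": d["cell"]}]).to_csv(
                outdir / "failures.csv",
                mode="a",
                header=not (outdir / "failures.csv").exists(),
                index=False,
            )
    return read_metrics(metrics_path)


def summarize(results: pd.DataFrame, cells: Optional[Sequence[str]] = None):
    """Per-cell method summaries and agreement matrices from tidy metric rows.

    Returns ``(summary, agreement)``: the first has one row per
    (cell, method) with selection proportions and Brier scores; the second
    is long-format pairwise agreement per cell. Cells requested but missing
    from the results produce a warning and are skipped.
    """
    if cells is None:
        cells = list(pd.unique(results["cell"]))
    if len(cells) == 0:
        raise ValueError("no cells to summarize")
    summaries, agreements = [], []
    for cell in cells:
        sub = results[results["cell"] == cell]
        if sub.empty:
            log.warning("cell %s missing from results; skipped", cell)
            continue
        true_variant = sub["true_variant"].iloc[0]
        s = score_cell(sub, true_variant).reset_index()
        s.insert(0, "cell", cell)
        summaries.append(s)
        wide = (
            sub[sub["selected"]]
            .pivot(index="replicate", columns="method", values="variant")
        )
        a = agreement_matrix(wide).stack().rename("agreement").reset_index()
        a.columns = ["method_a", "method_b", "agreement"]
        a.insert(0, "cell", cell)
        agreements.append(a)
    if not summaries:
        raise ValueError("none of the requested cells are present")
    return pd.concat(summaries, ignore_index=True), pd.concat(
        agreements, ignore_index=True
    )


def plot_heatmap(
    summary: pd.DataFrame, value: str = "prop_correct", path=None
):
    """Per-method heat maps of a summary quantity over the design grid.

    Rows index the threshold effect, columns the drift effect; two-way
    cells are split by arrangement (suffix E/B in the cell label).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    methods = list(pd.unique(summary["method"]))
    row_labels = ["N", "S", "M", "L"]
    col_labels = ["N", "S", "SB", "M", "MB", "L", "LB"]

    def cell_pos(label):
        drift, thresh = label[0], label[1]
        arr = label[2] if len(label) > 2 else ""
        col = {"N": 0, "S": 1, "M": 3, "L": 5}[drift] + (1 if arr == "B" else 0)
        return row_labels.index(thresh), col if arr else {"N": 0, "S": 1, "M": 3, "L": 5}[drift]

    ncol = min(3, len(methods))
    nrow = int(np.ceil(len(methods) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3.2 * nrow), squeeze=False)
    for ax in axes.ravel():
        ax.set_visible(False)
    for i, method in enumerate(methods):
        ax = axes[i // ncol][i % ncol]
        ax.set_visible(True)
        grid = np.full((len(row_labels), len(col_labels)), np.nan)
        for _, r in summary[summary["method"] == method].iterrows():
            ri, ci = cell_pos(r["cell"])
            grid[ri, ci] = r[value]
        im = ax.imshow(grid, vmin=-1 if "brier" in value else 0, vmax=1, cmap="RdYlGn")
        ax.set_xticks(range(len(col_labels)), col_labels)
        ax.set_yticks(range(len(row_labels)), row_labels)
        ax.set_xlabel("drift effect")
        ax.set_ylabel("threshold effect")
        ax.set_title(method)
    fig.colorbar(im, ax=axes.ravel().tolist(), shrink=0.7)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
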