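"""Dataset manifests, experiment plans, and seeded experiment orchestration.

A *manifest* (YAML/JSON) names the per-block tables of a study; an
*experiment plan* names the method, the target block, and the obsNum /
maskObs grid.  Every (obs_num, mask_obs, repetition) cell receives a
distinct seed derived from the base seed, so any cell is reproducible in
isolation from the frozen resolved plan.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cgan import CganConfig, cgan_fit_and_impute
from .data import (
    LongitudinalDataset,
    mask_mcar,
    read_omics_table,
    split_dataset,
    write_omics_table,
)
from .errors import ConfigError
from .evaluation import PBReport, pb_report
from .networks import NetworkConfig, impute_missing_block
from .objectives import LossWeights
from .training import TrainingConfig, fit

__all__ = [
    "load_manifest",
    "write_manifest",
    "ExperimentPlan",
    "derive_seeds",
    "run_experiment",
]


def load_manifest(path) -> LongitudinalDataset:
    """Read a dataset manifest and all referenced block tables."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    blocks = {}
    for entry in doc.get("blocks", []):
        block_path = Path(entry["path"])
        if not block_path.is_absolute():
            block_path = path.parent / block_path
        block = read_omics_table(block_path, entry["view_id"], entry["timepoint_id"])
        blocks[block.key] = block
    if not blocks:
        raise ConfigError(f"{path}: manifest declares no blocks")
    sample_ids = next(iter(blocks.values())).sample_ids
    missing = {tuple(m) for m in doc.get("missing_blocks", [])}
    return LongitudinalDataset(
        blocks,
        sample_ids,
        doc.get("view_ids") or [],
        doc.get("timepoint_ids") or [],
        missing,
    )


def write_manifest(dataset: LongitudinalDataset, out_dir, fmt: str = "csv") -> Path:
    """Write per-block tables plus the manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for (view, tp), block in dataset.blocks.items():
        name = f"{view}_{tp}.{fmt}"
        write_omics_table(block, out_dir / name)
        entries.append({"path": name, "view_id": view, "timepoint_id": tp})
    doc = {
        "blocks": entries,
        "view_ids": dataset.view_ids,
        "timepoint_ids": dataset.timepoint_ids,
        "missing_blocks": [list(k) for k in sorted(dataset.missing_blocks)],
    }
    manifest = out_dir / "manifest.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return manifest


@dataclass
class ExperimentPlan:
    target: tuple[str, str]
    method: str = "leopard"            # leopard | cgan
    obs_num_grid: list[int] = field(default_factory=lambda: [0])
    mask_obs_grid: list[float] = field(default_factory=lambda: [0.0])
    repetitions: int = 1
    base_seed: int = 0
    split_ratios: tuple[float, float, float] = (0.64, 0.16, 0.20)
    max_epochs: int = 600
    batch_size: int | None = None

    def __post_init__(self):
        self.target = tuple(self.target)
        if self.repetitions < 1:
            raise ConfigError("repetitions must be >= 1")
        if self.method not in ("leopard", "cgan"):
            raise ConfigError(f"unknown method {self.method!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["target"] = list(self.target)
        d["split_ratios"] = list(self.split_ratios)
        return d


def derive_seeds(base_seed: int, n: int) -> list[int]:
    """Distinct per-cell seeds (< 2**31) derived from the base seed."""
    state = np.random.SeedSequence(base_seed).generate_state(n, dtype=np.uint64)
    seeds = [int(s % (2**31)) for s in state]
    if len(set(seeds)) != n:  # astronomically unlikely; fall back to offsets
        seeds = [int((base_seed + i) % (2**31)) for i in range(n)]
    return seeds


def _fit_and_impute_leopard(dataset, split, target, obs_num, seed,
                            max_epochs, batch_size):
    training = TrainingConfig(
        seed=seed, obs_num=obs_num, max_epochs=max_epochs,
        **({"batch_size": batch_size} if batch_size else {}))
    model, history = fit(dataset, split, target, training,
                         NetworkConfig(), LossWeights())
    eval_dataset = dataset
    if target in dataset.blocks:
        # the model never sees the target's test rows; drop the block so the
        # imputation path cannot read it either
        blocks = {k: b for k, b in dataset.blocks.items() if k != target}
        eval_dataset = LongitudinalDataset(
            blocks, dataset.sample_ids, dataset.view_ids,
            dataset.timepoint_ids, set(dataset.missing_blocks) | {target})
    imputed = impute_missing_block(eval_dataset, target, model,
                                   sample_ids=split.test_ids)
    return imputed, model, history


def run_experiment(
    dataset: LongitudinalDataset,
    plan: ExperimentPlan,
    out_dir=None,
) -> dict:
    """Execute the full (obs_num x mask_obs x repetition) grid for one method.

    Percent bias is averaged across repetitions per grid point.  Artifacts
    (imputed blocks, PB tables, the frozen resolved plan) are written under
    ``out_dir`` when given.  Cells that fail are recorded and skipped.
    """
    if plan.target not in dataset.blocks:
        raise ConfigError("run_experiment needs ground truth for the target block "
                          "to score percent bias")
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        with open(out_path / "plan.json", "w") as fh:
            json.dump(plan.to_dict(), fh, indent=2)

    split = split_dataset(dataset, plan.split_ratios, plan.base_seed)
    n_cells = len(plan.obs_num_grid) * len(plan.mask_obs_grid) * plan.repetitions
    seeds = derive_seeds(plan.base_seed, n_cells)
    observed_target = dataset.blocks[plan.target]
    test_rows = observed_target.row_indices(split.test_ids)
    truth_block = type(observed_target)(
        observed_target.view_id, observed_target.timepoint_id,
        list(split.test_ids), list(observed_target.variable_ids),
        observed_target.values[test_rows], observed_target.observed_mask[test_rows])

    reports: list[PBReport] = []
    errors: list[dict] = []
    cell = 0
    for obs_num in plan.obs_num_grid:
        for rate in plan.mask_obs_grid:
            for rep in range(plan.repetitions):
                seed = seeds[cell]
                cell += 1
                try:
                    work = dataset
                    if rate > 0:
                        blocks = {
                            k: (mask_mcar(b, rate, seed) if k != plan.target else b)
                            for k, b in dataset.blocks.items()
                        }
                        work = LongitudinalDataset(
                            blocks, dataset.sample_ids, dataset.view_ids,
                            dataset.timepoint_ids, set(dataset.missing_blocks))
                    if plan.method == "leopard":
                        imputed, _model, _hist = _fit_and_impute_leopard(
                            work, split, plan.target, obs_num, seed,
                            plan.max_epochs, plan.batch_size)
                    else:
                        cfg = CganConfig(max_epochs=plan.max_epochs)
                        if plan.batch_size:
                            cfg.batch_size = plan.batch_size
                        imputed = cgan_fit_and_impute(
                            work, split, plan.target, obs_num, cfg, seed)
                    report = pb_report(truth_block, imputed, plan.method,
                                       obs_num, rate, rep)
                    reports.append(report)
                    if out_path is not None:
                        stem = f"{plan.method}_obs{obs_num}_mask{rate}_rep{rep}"
                        write_omics_table(imputed, out_path / f"imputed_{stem}.csv")
                        report.to_frame().to_csv(out_path / f"pb_{stem}.csv",
                                                 index=False)
                except Exception as exc:  # noqa: BLE001 - per-cell error records
                    errors.append({"obs_num": obs_num, "mask_obs": rate,
                                   "repetition": rep, "error": str(exc)})

    averaged: dict[tuple[int, float], dict[str, float]] = {}
    for obs_num in plan.obs_num_grid:
        for rate in plan.mask_obs_grid:
            cell_reports = [r for r in reports
                            if r.obs_num == obs_num and r.mask_obs_rate == rate]
            if not cell_reports:
                continue
            variables = list(cell_reports[0].per_variable_pb)
            mean_pb = {
                v: float(np.mean([r.per_variable_pb[v] for r in cell_reports]))
                for v in variables
            }
            averaged[(obs_num, rate)] = mean_pb
    result = {"plan": plan.to_dict(), "split": split, "reports": reports,
              "averaged_pb": averaged, "errors": errors}
    if out_path is not None:
        rows = []
        for (obs_num, rate), pbs in averaged.items():
            for v, pb in pbs.items():
                rows.append({"obs_num": obs_num, "mask_obs": rate,
                             "variable": v, "mean_pb": pb})
        if rows:
            import pandas as pd

            pd.DataFrame(rows).to_csv(out_path / "pb_averaged.csv", index=False)
    return result
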