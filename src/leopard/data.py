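"""Longitudinal multi-view data model and delimited-table I/O.

A study is a :class:`LongitudinalDataset`: one :class:`DataBlock` per
(view, timepoint) source class, all indexed by the same ordered master
sample list.  A *view* is an omics panel, biochemical class, or modality;
a *missing view* is the complete absence of one block.  Cells that were
never measured (missing data points within an observed view) are tracked
with a boolean ``observed_mask``; the value matrix carries ``NaN`` in those
positions purely as an internal sentinel - every loss and metric reads the
mask, never the sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, FormatError

__all__ = [
    "DataBlock",
    "LongitudinalDataset",
    "SplitAssignment",
    "read_omics_table",
    "write_omics_table",
    "split_dataset",
    "select_training_observations",
    "mask_mcar",
    "mean_encode",
    "training_means",
]

#: Tokens treated as missing when reading tables (case-insensitive).
NA_TOKENS = {"", "na", "nan"}


@dataclass
class DataBlock:
    """One samples x variables matrix for a single source class (view, timepoint)."""

    view_id: str
    timepoint_id: str
    sample_ids: list[str]
    variable_ids: list[str]
    values: np.ndarray
    observed_mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.values.shape != self.observed_mask.shape:
            raise FormatError("values and observed_mask must have identical shape")
        if self.values.shape != (len(self.sample_ids), len(self.variable_ids)):
            raise FormatError("matrix shape does not match sample/variable ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in block")
        if len(set(self.variable_ids)) != len(self.variable_ids):
            raise FormatError("duplicate variable ids in block")

    @property
    def key(self) -> tuple[str, str]:
        return (self.view_id, self.timepoint_id)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variables(self) -> int:
        return len(self.variable_ids)

    def copy(self) -> "DataBlock":
        return replace(
            self,
            sample_ids=list(self.sample_ids),
            variable_ids=list(self.variable_ids),
            values=self.values.copy(),
            observed_mask=self.observed_mask.copy(),
        )

    def row_indices(self, sample_ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise DataError(f"sample {exc.args[0]!r} not in block {self.key}") from exc

    def observed_rows(self) -> np.ndarray:
        """Boolean flag per sample: has at least one measured cell."""
        return self.observed_mask.any(axis=1)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, index=self.sample_ids, columns=self.variable_ids)
        return frame.mask(~self.observed_mask)


@dataclass
class LongitudinalDataset:
    """Collection of blocks sharing a master sample index.

    ``missing_blocks`` declares the (view, timepoint) classes absent from the
    study - the completion targets.
    """

    blocks: dict[tuple[str, str], DataBlock]
    sample_ids: list[str]
    view_ids: list[str] = field(default_factory=list)
    timepoint_ids: list[str] = field(default_factory=list)
    missing_blocks: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self):
        if not self.view_ids:
            self.view_ids = sorted({v for v, _ in self.all_keys()})
        if not self.timepoint_ids:
            self.timepoint_ids = sorted({t for _, t in self.all_keys()})
        for key, block in self.blocks.items():
            if key != block.key:
                raise FormatError(f"block stored under {key} reports key {block.key}")
            if block.sample_ids != self.sample_ids:
                raise FormatError(
                    f"block {key} does not index the master sample list in order"
                )

    def all_keys(self) -> set[tuple[str, str]]:
        return set(self.blocks) | set(self.missing_blocks)

    def observed_keys(self) -> list[tuple[str, str]]:
        return [k for k in self.iter_keys() if k not in self.missing_blocks]

    def iter_keys(self) -> list[tuple[str, str]]:
        """All declared (view, timepoint) keys in canonical order."""
        return [
            (v, t)
            for v in self.view_ids
            for t in self.timepoint_ids
            if (v, t) in self.blocks or (v, t) in self.missing_blocks
        ]

    def timepoint_index(self, timepoint_id: str) -> int:
        return self.timepoint_ids.index(timepoint_id)

    def with_block(self, block: DataBlock) -> "LongitudinalDataset":
        blocks = dict(self.blocks)
        blocks[block.key] = block
        return LongitudinalDataset(
            blocks,
            self.sample_ids,
            list(self.view_ids),
            list(self.timepoint_ids),
            set(self.missing_blocks) - {block.key},
        )


@dataclass
class SplitAssignment:
    train_ids: list[str]
    validation_ids: list[str]
    test_ids: list[str]
    ratios: tuple[float, float, float]

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.validation_ids), set(self.test_ids)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ConfigError("split sets are not pairwise disjoint")


# --------------------------------------------------------------------- I/O


def _delimiter_for(path: str) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".txt")) else ","


def read_omics_table(path, view_id: str, timepoint_id: str) -> DataBlock:
    """Read a delimited omics table (header = variable ids, first column = sample ids)."""
    frame = pd.read_csv(path, sep=_delimiter_for(path), index_col=0, dtype=str,
                        keep_default_na=False)
    if frame.shape[0] == 0:
        raise FormatError(f"{path}: no data rows")
    sample_ids = [str(s) for s in frame.index]
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{path}: duplicate sample id")
    raw = frame.to_numpy()
    values = np.empty(raw.shape, dtype=np.float64)
    observed = np.ones(raw.shape, dtype=bool)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            token = raw[i, j].strip()
            if token.lower() in NA_TOKENS:
                values[i, j] = np.nan
                observed[i, j] = False
            else:
                try:
                    values[i, j] = float(token)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: non-numeric cell {token!r} at "
                        f"({sample_ids[i]}, {frame.columns[j]})"
                    ) from exc
    return DataBlock(view_id, timepoint_id, sample_ids,
                     [str(c) for c in frame.columns], values, observed)


def write_omics_table(block: DataBlock, path) -> None:
    block.to_frame().to_csv(path, sep=_delimiter_for(path), index_label="sample_id",
                            na_rep="NA")


# ------------------------------------------------------------------ splits


def split_dataset(dataset: LongitudinalDataset, ratios, seed: int) -> SplitAssignment:
    """Seeded train/validation/test partition of the master sample list.

    Allocation rule: ``n_test = floor(r_test * N)``, ``n_val = floor(r_val * N)``,
    ``n_train = N - n_test - n_val`` (the canonical 64/16/20 split gives
    1335/333/417 for N = 2085).
    """
    r_train, r_val, r_test = (float(r) for r in ratios)
    if any(r < 0 for r in (r_train, r_val, r_test)):
        raise ConfigError("split ratios must be non-negative")
    if abs(r_train + r_val + r_test - 1.0) > 1e-9:
        raise ConfigError("split ratios must sum to 1")
    n = len(dataset.sample_ids)
    n_test = int(np.floor(r_test * n))
    n_val = int(np.floor(r_val * n))
    n_train = n - n_test - n_val
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    ids = np.asarray(dataset.sample_ids, dtype=object)
    return SplitAssignment(
        train_ids=list(ids[perm[:n_train]]),
        validation_ids=list(ids[perm[n_train:n_train + n_val]]),
        test_ids=list(ids[perm[n_train + n_val:]]),
        ratios=(r_train, r_val, r_test),
    )


def select_training_observations(
    block: DataBlock, train_ids, obs_num: int, seed: int
) -> DataBlock:
    """Keep exactly ``obs_num`` seeded-random training rows of the block observed.

    All other training rows become fully unobserved.  ``obs_num`` is the
    number of observed samples from the to-be-completed block that are
    revealed during training; 0 leaves the block completely missing there.
    """
    train_ids = list(train_ids)
    if obs_num < 0 or obs_num > len(train_ids):
        raise ConfigError(
            f"obs_num={obs_num} outside [0, {len(train_ids)}] training rows"
        )
    out = block.copy()
    rows = out.row_indices(train_ids)
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(rows), size=obs_num, replace=False)
    drop = np.setdiff1d(np.arange(len(rows)), keep)
    out.observed_mask[rows[drop], :] = False
    out.values[rows[drop], :] = np.nan
    return out


def mask_mcar(block: DataBlock, rate: float, seed: int) -> DataBlock:
    """Mask exactly ``round(rate * n_observed_cells)`` observed cells MCAR."""
    if not 0.0 <= rate <= 1.0:
        raise ConfigError(f"MCAR rate {rate} outside [0, 1]")
    obs_idx = np.flatnonzero(block.observed_mask)
    if obs_idx.size == 0:
        raise DataError("block has no observed cells")
    n_mask = int(round(rate * obs_idx.size))
    out = block.copy()
    if n_mask == 0:
        return out
    rng = np.random.default_rng(seed)
    chosen = rng.choice(obs_idx, size=n_mask, replace=False)
    flat_mask = out.observed_mask.ravel()
    flat_vals = out.values.ravel()
    flat_mask[chosen] = False
    flat_vals[chosen] = np.nan
    out.observed_mask = flat_mask.reshape(block.observed_mask.shape)
    out.values = flat_vals.reshape(block.values.shape)
    return out


# ------------------------------------------------------------- mean encoding


def training_means(block: DataBlock, train_ids) -> np.ndarray:
    """Per-variable means over observed training cells only."""
    rows = block.row_indices(list(train_ids))
    vals = block.values[rows]
    mask = block.observed_mask[rows]
    counts = mask.sum(axis=0)
    if np.any(counts == 0):
        bad = [v for v, c in zip(block.variable_ids, counts) if c == 0]
        raise DataError(f"variables with zero observed training cells: {bad}")
    sums = np.where(mask, vals, 0.0).sum(axis=0)
    return sums / counts


def mean_encode(block: DataBlock, reference_means) -> tuple[DataBlock, np.ndarray]:
    """Replace unobserved cells with per-variable training means.

    Returns the encoded block and an ``imputation_mask`` flagging exactly the
    filled cells, so the reconstruction loss can exclude them.
    """
    means = np.asarray(reference_means, dtype=np.float64)
    if means.shape != (block.n_variables,):
        raise ConfigError("reference_means length must equal the variable count")
    if np.any(~np.isfinite(means)):
        raise DataError("reference means contain non-finite entries")
    out = block.copy()
    imputation_mask = ~out.observed_mask
    out.values = np.where(imputation_mask, means[None, :], out.values)
    out.observed_mask = np.ones_like(out.observed_mask)
    return out, imputation_mask
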