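"""The LEOPARD architecture.

Data of every view are first mapped to a shared embedding width by
view-specific pre-layers.  Two encoders shared across all views and
timepoints then factorize each embedding into a *content* representation
(view-specific, timepoint-invariant; the content encoder applies instance
normalization after each dense layer to strip per-sample style statistics)
and a *temporal* representation (timepoint-specific, view-invariant).  The
generator re-entangles a content vector with temporal knowledge through
Adaptive Instance Normalization (AdaIN) and view-specific post-layers map
the result back to omics units.  A multi-task discriminator with one
sigmoid head per source class (view, timepoint) provides the adversarial
signal.

Inputs are z-scored per variable with training-set observed statistics
pooled per view across timepoints (so the temporal distribution shift is
preserved for the model to learn), and predictions are mapped back to the
original units on output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data import DataBlock, LongitudinalDataset, mean_encode
from .errors import ConfigError, DataError, NumericError
from .nn import (
    Dense,
    InstanceNorm,
    Module,
    PReLU,
    Sequential,
    Sigmoid,
    Tensor,
    as_tensor,
)

__all__ = [
    "NetworkConfig",
    "RepresentationPair",
    "adain",
    "LeopardModel",
    "impute_missing_block",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters (defaults are the tuned values)."""

    view_widths: dict[str, int] = field(default_factory=dict)
    embed_dim: int = 64
    encoder_layers: int = 3
    generator_layers: int = 3
    discriminator_layers: int = 2
    discriminator_width: int = 128
    temperature: float = 0.05
    projection_head: int | None = None
    dropout_rate: float = 0.0
    learning_rate: float = 1e-3
    adam_betas: tuple[float, float] = (0.9, 0.999)

    def __post_init__(self):
        if self.temperature <= 0:
            raise ConfigError("temperature must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must lie in [0, 1)")


@dataclass
class RepresentationPair:
    """Per-sample content and temporal vectors with their source class."""

    content: np.ndarray
    temporal: np.ndarray
    source: tuple[str, str]
    provenance: str = "observed"  # or "generated"


def adain(z_content, z_temporal):
    """Adaptive instance normalization of a content vector toward temporal statistics.

    output = sigma(z_t) * (z_c - mu(z_c)) / sigma(z_c) + mu(z_t)

    with mu / sigma the mean and population standard deviation over the
    vector's elements.  Works on single vectors or (samples x dim) batches
    (statistics per sample); raises for (near-)constant content vectors.
    """
    tensor_mode = isinstance(z_content, Tensor) or isinstance(z_temporal, Tensor)
    c, t = as_tensor(z_content), as_tensor(z_temporal)
    if c.shape != t.shape:
        raise ConfigError("content and temporal vectors must have equal shape")
    axis = c.ndim - 1
    if c.shape[axis] < 2:
        raise ConfigError("AdaIN requires vectors of length >= 2")
    c_var = c.var(axis=axis, keepdims=True)
    if np.any(c_var.data < 1e-24):
        raise NumericError("AdaIN undefined for constant content vector (sigma = 0)")
    mu_c = c.mean(axis=axis, keepdims=True)
    mu_t = t.mean(axis=axis, keepdims=True)
    sd_c = c_var**0.5
    sd_t = (t.var(axis=axis, keepdims=True)) ** 0.5
    out = sd_t * (c - mu_c) / sd_c + mu_t
    return out if tensor_mode else out.data


def _encoder(layers: int, width: int, rng, instance_norm: bool) -> Sequential:
    blocks: list[Module] = []
    for _ in range(layers):
        blocks.append(Dense(width, width, rng))
        if instance_norm:
            blocks.append(InstanceNorm())
        blocks.append(PReLU())
    return Sequential(*blocks)


class LeopardModel(Module):
    """Pre/post adapters, shared encoders, AdaIN generator, multi-task discriminator."""

    def __init__(self, config: NetworkConfig, source_classes: list[tuple[str, str]],
                 seed: int = 0):
        super().__init__()
        if not config.view_widths:
            raise ConfigError("NetworkConfig.view_widths must name every view")
        self.config = config
        self.source_classes = list(source_classes)
        self.views = list(config.view_widths)
        rng = np.random.default_rng(seed)
        d = config.embed_dim
        self.pre = {
            v: Sequential(Dense(w, d, rng), PReLU())
            for v, w in config.view_widths.items()
        }
        self.content_encoder = _encoder(config.encoder_layers, d, rng, instance_norm=True)
        self.temporal_encoder = _encoder(config.encoder_layers, d, rng, instance_norm=False)
        self.generator = _encoder(config.generator_layers, d, rng, instance_norm=False)
        self.post = {
            v: Dense(d, w, rng) for v, w in config.view_widths.items()
        }
        dw = config.discriminator_width
        self.disc_in = {
            v: Sequential(Dense(w, dw, rng), Sigmoid())
            for v, w in config.view_widths.items()
        }
        hidden: list[Module] = []
        for _ in range(config.discriminator_layers):
            hidden.extend([Dense(dw, dw, rng), Sigmoid()])
        self.disc_hidden = Sequential(*hidden)
        self.disc_heads = Dense(dw, len(self.source_classes), rng)
        # per-view standardization statistics (set by fit)
        self.standardize_mean: dict[str, np.ndarray] = {}
        self.standardize_sd: dict[str, np.ndarray] = {}

    # ------------------------------------------------------------ generator side
    def _check_view(self, view: str) -> None:
        if view not in self.pre:
            raise ConfigError(f"unknown view {view!r}")

    def set_standardization(self, view: str, mean: np.ndarray, sd: np.ndarray) -> None:
        sd = np.asarray(sd, dtype=float)
        if np.any(sd <= 0):
            raise DataError(f"non-positive standardization sd for view {view!r}")
        self.standardize_mean[view] = np.asarray(mean, dtype=float)
        self.standardize_sd[view] = sd

    def standardize(self, rows: np.ndarray, view: str) -> np.ndarray:
        if view not in self.standardize_mean:
            return np.asarray(rows, dtype=float)
        return (np.asarray(rows, dtype=float) - self.standardize_mean[view]) / \
            self.standardize_sd[view]

    def destandardize(self, rows: np.ndarray, view: str) -> np.ndarray:
        if view not in self.standardize_mean:
            return np.asarray(rows, dtype=float)
        return np.asarray(rows, dtype=float) * self.standardize_sd[view] + \
            self.standardize_mean[view]

    def pre_embed(self, rows, view: str) -> Tensor:
        """Map raw rows of ``view`` (already standardized) to width-embed_dim vectors."""
        self._check_view(view)
        x = as_tensor(rows)
        if x.shape[-1] != self.config.view_widths[view]:
            raise ConfigError(
                f"row width {x.shape[-1]} does not match view {view!r} "
                f"({self.config.view_widths[view]} variables)"
            )
        return self.pre[view](x)

    def encode_content(self, z_pre) -> Tensor:
        z_pre = as_tensor(z_pre)
        if z_pre.shape[-1] != self.config.embed_dim:
            raise ConfigError("pre-embedding width mismatch")
        return self.content_encoder(z_pre)

    def encode_temporal(self, z_pre) -> Tensor:
        z_pre = as_tensor(z_pre)
        if z_pre.shape[-1] != self.config.embed_dim:
            raise ConfigError("pre-embedding width mismatch")
        return self.temporal_encoder(z_pre)

    def generate_std(self, content, temporal, target_view: str) -> Tensor:
        """Generator output in standardized units."""
        self._check_view(target_view)
        mixed = adain(as_tensor(content), as_tensor(temporal))
        return self.post[target_view](self.generator(mixed))

    def generate_view(self, content, temporal, target_view: str) -> np.ndarray:
        """Re-entangle content with temporal knowledge; rows in omics units."""
        out = self.generate_std(content, temporal, target_view)
        return self.destandardize(out.data, target_view)

    def encode_block_rows(self, rows: np.ndarray, view: str) -> tuple[Tensor, Tensor]:
        """Standardize raw rows, pre-embed, and return (content, temporal)."""
        z_pre = self.pre_embed(self.standardize(rows, view), view)
        return self.encode_content(z_pre), self.encode_temporal(z_pre)

    # ------------------------------------------------------------ discriminator
    def discriminate(self, rows, source: tuple[str, str]):
        """Per-source-class sigmoid scores for rows of view ``source[0]``.

        Only the head matching the rows' source class participates in losses;
        the full score matrix is returned for inspection.
        """
        if source not in self.source_classes:
            raise ConfigError(f"unregistered source class {source!r}")
        view = source[0]
        self._check_view(view)
        x = as_tensor(rows)
        h = self.disc_hidden(self.disc_in[view](x))
        return self.disc_heads(h).sigmoid()

    def head_score(self, rows, source: tuple[str, str]) -> Tensor:
        scores = self.discriminate(rows, source)
        idx = self.source_classes.index(source)
        return scores[(slice(None), idx)]

    def generator_parameters(self):
        params = []
        for v in self.views:
            params.extend(self.pre[v].parameters())
            params.extend(self.post[v].parameters())
        params.extend(self.content_encoder.parameters())
        params.extend(self.temporal_encoder.parameters())
        params.extend(self.generator.parameters())
        return params

    def discriminator_parameters(self):
        params = []
        for v in self.views:
            params.extend(self.disc_in[v].parameters())
        params.extend(self.disc_hidden.parameters())
        params.extend(self.disc_heads.parameters())
        return params


# ------------------------------------------------------------------ imputation


def content_source_timepoint(dataset: LongitudinalDataset, view: str,
                             target_timepoint: str) -> str:
    """Observed timepoint of ``view`` nearest to the target (ties -> earlier)."""
    target_idx = dataset.timepoint_index(target_timepoint)
    candidates = [
        t for (v, t) in dataset.observed_keys()
        if v == view and t != target_timepoint
    ]
    if not candidates:
        raise DataError(f"no observed content source for view {view!r}")
    return min(candidates, key=lambda t: (abs(dataset.timepoint_index(t) - target_idx),
                                          dataset.timepoint_index(t)))


def temporal_source_view(dataset: LongitudinalDataset, target_view: str,
                         timepoint: str) -> str:
    """An observed view other than the target at ``timepoint`` (first in order)."""
    candidates = [v for (v, t) in dataset.observed_keys()
                  if t == timepoint and v != target_view]
    if not candidates:
        raise DataError(f"no observed temporal source at timepoint {timepoint!r}")
    return candidates[0]


def impute_missing_block(dataset: LongitudinalDataset, target: tuple[str, str],
                         model: LeopardModel, sample_ids=None) -> DataBlock:
    """Complete the block ``target`` = (view w, timepoint s) for the given samples.

    Per sample: content from the view-w row at the nearest observed
    timepoint, temporal knowledge from the other view's row at s.
    """
    view, timepoint = target
    model.eval()
    if sample_ids is None:
        sample_ids = dataset.sample_ids
    sample_ids = list(sample_ids)
    t_content = content_source_timepoint(dataset, view, timepoint)
    v_temporal = temporal_source_view(dataset, view, timepoint)
    content_block = dataset.blocks[(view, t_content)]
    temporal_block = dataset.blocks[(v_temporal, timepoint)]
    for name, blk in (("content", content_block), ("temporal", temporal_block)):
        rows = blk.row_indices(sample_ids)
        missing = ~blk.observed_rows()[rows]
        if np.any(missing):
            bad = [s for s, m in zip(sample_ids, missing) if m]
            raise DataError(f"no {name} source rows for samples {bad}")
    c_rows = _complete_rows(content_block, model, sample_ids)
    t_rows = _complete_rows(temporal_block, model, sample_ids)
    z_c, _ = model.encode_block_rows(c_rows, content_block.view_id)
    _, z_t = model.encode_block_rows(t_rows, temporal_block.view_id)
    values = model.generate_view(z_c, z_t, view)
    n_vars = model.config.view_widths[view]
    variable_ids = (dataset.blocks[(view, t_content)].variable_ids
                    if (view, t_content) in dataset.blocks else
                    [f"{view}_{j}" for j in range(n_vars)])
    return DataBlock(view, timepoint, sample_ids, list(variable_ids), values,
                     np.ones_like(values, dtype=bool))


def _complete_rows(block: DataBlock, model: LeopardModel, sample_ids) -> np.ndarray:
    """Raw rows with missing points mean-encoded (in omics units)."""
    if block.observed_mask.all():
        return block.values[block.row_indices(sample_ids)]
    view = block.view_id
    if view in model.standardize_mean:
        means = model.standardize_mean[view]
    else:  # fall back to block-wide observed means
        means = np.nanmean(np.where(block.observed_mask, block.values, np.nan), axis=0)
    encoded, _ = mean_encode(block, means)
    return encoded.values[encoded.row_indices(sample_ids)]


# ------------------------------------------------------------------ checkpoints

CHECKPOINT_VERSION = 1


def save_checkpoint(model: LeopardModel, path, extra: dict | None = None) -> None:
    """Single-file archive: config, registries, standardization stats, parameters."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "kind": "leopard",
        "config": {
            **{k: v for k, v in vars(model.config).items() if k != "view_widths"},
            "view_widths": dict(model.config.view_widths),
        },
        "source_classes": [list(c) for c in model.source_classes],
        "extra": extra or {},
    }
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    for v in model.standardize_mean:
        arrays[f"std_mean_{v}"] = model.standardize_mean[v]
        arrays[f"std_sd_{v}"] = model.standardize_sd[v]
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> LeopardModel:
    archive = np.load(path, allow_pickle=False)
    meta = json.loads(str(archive["meta"]))
    if meta.get("kind") != "leopard":
        raise ConfigError(f"checkpoint at {path} is not a LEOPARD model")
    cfg_dict = dict(meta["config"])
    cfg_dict["adam_betas"] = tuple(cfg_dict.get("adam_betas", (0.9, 0.999)))
    config = NetworkConfig(**cfg_dict)
    model = LeopardModel(config, [tuple(c) for c in meta["source_classes"]])
    n_params = len(model.state_arrays())
    model.set_state([archive[f"param_{i}"] for i in range(n_params)])
    for v in config.view_widths:
        if f"std_mean_{v}" in archive:
            model.set_standardization(v, archive[f"std_mean_{v}"], archive[f"std_sd_{v}"])
    return model
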