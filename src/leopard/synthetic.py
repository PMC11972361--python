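"""Synthetic longitudinal multi-view omics generator with known ground truth.

The generative model mirrors the structure the completion method exploits:

* each subject i carries a latent content vector ``c_i`` (standard normal,
  ``content_dim`` factors) that is constant across timepoints and shared by
  all views, plus ``private_dim`` *view-private* factors per view - stable
  subject-level variation visible in only one view (genetics, lifestyle,
  platform-specific biology).  Private factors are the structural reason a
  direct view-to-view regression is lossy: they are unpredictable from the
  other view, but trivially carried over time by a method that takes its
  content from the same view at another timepoint;
* each view v maps latent content to its variables through a fixed loading
  matrix ``L_v`` plus a saturating (tanh) component - the nonlinearity makes
  the cross-view mapping region-dependent, so a view-to-view regression
  learned at one timepoint does not extrapolate to the shifted latent region
  of another (the failure mode of cross-sectional imputers on longitudinal
  data).  Per-variable baseline abundances are additive, with a configurable
  fraction of variables near a low-abundance floor, which produces the
  characteristic blow-up of percent bias for low-abundance analytes
  (absolute error is abundance-independent, so the relative error explodes
  as the denominator shrinks);
* temporal change is an affine transform of the *shared* latent state,
  ``c -> a_t * c + d_t`` (identity at the first timepoint).  Because the
  transform acts on the latent factors common to all views, the distribution
  shift of a view that is completely missing at a timepoint is still
  identified by the shift observed in the other view - the property that
  separates temporal-knowledge transfer from cross-sectional mapping.
  Optional per-(view, timepoint) variable-space offsets add view-private
  shift on top (default off);
* i.i.d. Gaussian measurement noise and optional MCAR missing points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DataBlock, LongitudinalDataset, mask_mcar
from .errors import ConfigError
from .networks import RepresentationPair

__all__ = ["SyntheticSpec", "simulate_dataset", "disentanglement_probe"]


@dataclass
class SyntheticSpec:
    """Study conditions for one simulated cohort."""

    n_subjects: int = 600
    n_variables: tuple[int, ...] = (70, 36)   # per view
    n_timepoints: int = 2
    content_dim: int = 8
    private_dim: int = 4              # view-private subject factors per view
    private_weight: float = 1.4       # sd of private relative to shared signal
    latent_scale_sd: float = 0.15     # spread of a_t around 1 at later timepoints
    latent_offset_sd: float = 1.5     # spread of d_t (the "strong" temporal shift)
    view_shift_sd: float = 0.0        # optional view-private variable-space offset
    global_shift: float = 1.2         # shared intensity offset at later timepoints
    signal_scale: float = 0.5         # sd of the per-variable signal component
    nonlinearity: float = 0.6         # weight of the saturating loading component
    nonlinear_gain: float = 2.0       # steepness of the tanh saturation
    noise_sd: float = 0.1
    low_abundance_fraction: float = 0.2
    abundance_floor: float = 4.0
    high_abundance_range: tuple[float, float] = (10.0, 18.0)
    mcar_rate: float = 0.0
    seed: int = 0

    view_ids: list[str] = field(default_factory=list)
    timepoint_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.n_subjects < 1 or self.content_dim < 1 or self.n_timepoints < 1:
            raise ConfigError("counts must be positive")
        if any(p < 1 for p in self.n_variables):
            raise ConfigError("every view needs at least one variable")
        if not 0.0 <= self.low_abundance_fraction <= 1.0:
            raise ConfigError("low_abundance_fraction must lie in [0, 1]")
        if not 0.0 <= self.mcar_rate <= 1.0:
            raise ConfigError("mcar_rate must lie in [0, 1]")
        if not self.view_ids:
            self.view_ids = [f"v{i + 1}" for i in range(len(self.n_variables))]
        if not self.timepoint_ids:
            self.timepoint_ids = [f"t{i + 1}" for i in range(self.n_timepoints)]
        if len(self.view_ids) != len(self.n_variables):
            raise ConfigError("view_ids must match n_variables")
        if len(self.timepoint_ids) != self.n_timepoints:
            raise ConfigError("timepoint_ids must match n_timepoints")


def simulate_dataset(spec: SyntheticSpec) -> tuple[LongitudinalDataset, dict]:
    """Draw one cohort; returns the dataset and its ground truth.

    Ground truth holds the latent factors, loadings, baselines, the latent
    temporal transforms and the per-(view, timepoint) variable-space mean
    offsets they induce.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.content_dim
    n = spec.n_subjects
    latent = rng.standard_normal((n, k))
    sample_ids = [f"S{i:04d}" for i in range(n)]

    loadings: dict[str, np.ndarray] = {}
    sat_loadings: dict[str, np.ndarray] = {}
    private_latent: dict[str, np.ndarray] = {}
    private_loadings: dict[str, np.ndarray] = {}
    baselines: dict[str, np.ndarray] = {}
    low_mask: dict[str, np.ndarray] = {}
    for view, p in zip(spec.view_ids, spec.n_variables):
        loadings[view] = rng.standard_normal((k, p)) / np.sqrt(k)
        sat_loadings[view] = rng.standard_normal((k, p)) / np.sqrt(k)
        if spec.private_dim > 0:
            private_latent[view] = rng.standard_normal((n, spec.private_dim))
            private_loadings[view] = (rng.standard_normal((spec.private_dim, p))
                                      / np.sqrt(spec.private_dim))
        lo, hi = spec.high_abundance_range
        base = rng.uniform(lo, hi, size=p)
        n_low = int(round(spec.low_abundance_fraction * p))
        low_idx = rng.choice(p, size=n_low, replace=False)
        base[low_idx] = rng.uniform(spec.abundance_floor,
                                    spec.abundance_floor + 0.5, size=n_low)
        baselines[view] = base
        flags = np.zeros(p, dtype=bool)
        flags[low_idx] = True
        low_mask[view] = flags

    latent_scale = {spec.timepoint_ids[0]: np.ones(k)}
    latent_offset = {spec.timepoint_ids[0]: np.zeros(k)}
    # shared intensity drift (batch / assay-version effect): identical across
    # views, alternating sign over successive timepoints, zero at baseline
    global_offset = {spec.timepoint_ids[0]: 0.0}
    for j, t in enumerate(spec.timepoint_ids[1:], start=1):
        latent_scale[t] = 1.0 + rng.normal(0.0, spec.latent_scale_sd, size=k)
        latent_offset[t] = rng.normal(0.0, spec.latent_offset_sd, size=k)
        global_offset[t] = spec.global_shift * (-1.0) ** (j - 1)

    view_offsets: dict[tuple[str, str], np.ndarray] = {}
    blocks: dict[tuple[str, str], DataBlock] = {}
    for view, p in zip(spec.view_ids, spec.n_variables):
        variable_ids = [f"{view}_var{j:03d}" for j in range(p)]
        for t in spec.timepoint_ids:
            if t == spec.timepoint_ids[0] or spec.view_shift_sd == 0:
                vo = np.zeros(p)
            else:
                vo = rng.normal(0.0, spec.view_shift_sd, size=p)
            view_offsets[(view, t)] = vo
            shifted = latent * latent_scale[t] + latent_offset[t]
            signal = shifted @ loadings[view]
            if spec.nonlinearity:
                signal = signal + spec.nonlinearity * np.tanh(
                    spec.nonlinear_gain * (shifted @ sat_loadings[view]))
            if spec.private_dim > 0:
                signal = signal + spec.private_weight * (
                    private_latent[view] @ private_loadings[view])
            noise = rng.normal(0.0, spec.noise_sd, size=(n, p))
            values = (baselines[view][None, :] + spec.signal_scale * signal
                      + global_offset[t] + vo[None, :] + noise)
            block = DataBlock(view, t, list(sample_ids), list(variable_ids),
                              values, np.ones_like(values, dtype=bool))
            if spec.mcar_rate > 0:
                block = mask_mcar(block, spec.mcar_rate,
                                  seed=int(rng.integers(2**31)))
            blocks[(view, t)] = block

    dataset = LongitudinalDataset(blocks, list(sample_ids),
                                  list(spec.view_ids), list(spec.timepoint_ids))
    truth = {
        "latent": latent,
        "loadings": loadings,
        "sat_loadings": sat_loadings,
        "private_latent": private_latent,
        "private_loadings": private_loadings,
        "baselines": baselines,
        "low_abundance": low_mask,
        "latent_scale": latent_scale,
        "latent_offset": latent_offset,
        "global_offset": global_offset,
        "view_offsets": view_offsets,
        # exact expected per-variable t-shift for the linear model
        # (nonlinearity = 0, latent_scale_sd = 0); diagnostic otherwise
        "mean_shift": {
            (v, t): spec.signal_scale * (latent_offset[t] @ loadings[v])
            + global_offset[t] + view_offsets[(v, t)]
            for v in spec.view_ids for t in spec.timepoint_ids
        },
    }
    return dataset, truth


# ------------------------------------------------------------------- probing


def _loo_neighbors(x: np.ndarray, k: int) -> np.ndarray:
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    _, idx = nn.kneighbors(x)
    return idx[:, 1:]  # drop self


def _vote_accuracy(neighbor_idx: np.ndarray, labels: np.ndarray) -> float:
    neighbor_labels = labels[neighbor_idx]
    uniq = np.unique(labels)
    counts = np.stack([(neighbor_labels == u).sum(axis=1) for u in uniq], axis=1)
    pred = uniq[np.argmax(counts, axis=1)]
    return float(np.mean(pred == labels))


def _loo_knn_accuracy(x: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Leave-one-out k-nearest-neighbour classification accuracy."""
    return _vote_accuracy(_loo_neighbors(x, k), labels)


def disentanglement_probe(
    representations: dict[tuple[str, str], RepresentationPair],
    k: int = 5,
    n_permutations: int = 100,
    seed: int = 0,
) -> dict[str, float]:
    """Quantify disentanglement by leave-one-out kNN probes.

    Good factorization means: the *view* is recoverable from content vectors
    and the *timepoint* from temporal vectors (both near 1), while the
    cross-probes (timepoint from content, view from temporal) stay near the
    permutation-estimated chance level.
    """
    views = sorted({v for (v, _t) in representations})
    tps = sorted({t for (_v, t) in representations})
    if len(views) < 2 or len(tps) < 2:
        raise ConfigError("probe needs >= 2 views and >= 2 timepoints")
    content, temporal, view_labels, tp_labels = [], [], [], []
    for (v, t), rep in representations.items():
        content.append(np.atleast_2d(rep.content))
        temporal.append(np.atleast_2d(rep.temporal))
        n = np.atleast_2d(rep.content).shape[0]
        view_labels.extend([v] * n)
        tp_labels.extend([t] * n)
    content = np.concatenate(content, axis=0)
    temporal = np.concatenate(temporal, axis=0)
    view_labels = np.asarray(view_labels)
    tp_labels = np.asarray(tp_labels)
    for labels in (view_labels, tp_labels):
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() <= k:
            raise ConfigError(f"every class needs more than k={k} members")

    def _std(x: np.ndarray) -> np.ndarray:
        sd = x.std(axis=0, ddof=1)
        return (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    content = _std(content)
    temporal = _std(temporal)
    content_nn = _loo_neighbors(content, k)
    temporal_nn = _loo_neighbors(temporal, k)
    rng = np.random.default_rng(seed)
    out = {
        "content_view_accuracy": _vote_accuracy(content_nn, view_labels),
        "content_timepoint_accuracy": _vote_accuracy(content_nn, tp_labels),
        "temporal_timepoint_accuracy": _vote_accuracy(temporal_nn, tp_labels),
        "temporal_view_accuracy": _vote_accuracy(temporal_nn, view_labels),
    }
    # empirical chance by label permutation (respects class imbalance);
    # the neighbour graph is fixed, only the labels are shuffled
    for name, nn_idx, labels in (
        ("chance_view", content_nn, view_labels),
        ("chance_timepoint", content_nn, tp_labels),
    ):
        accs = [
            _vote_accuracy(nn_idx, rng.permutation(labels))
            for _ in range(n_permutations)
        ]
        out[name] = float(np.mean(accs))
    return out
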