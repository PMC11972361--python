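"""Imputation evaluation: percent bias, pooling of multiple imputations,
paired method comparison, the fit-on-train UMAP protocol, and prevalence
baselines.

Percent bias (PB) for variable i over m imputations:

    PB_i = (1/m) * sum_imp median_samples( |x_hat_i - x_i| / x_i )

the median taken over samples within each imputation, then the mean over
imputations.  PB is a relative error, so it is scale-invariant and directly
comparable across variables measured in different units; variables with a
nonpositive observed value have an ill-defined ratio and are reported
separately with a warning rather than silently included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import DataBlock
from .errors import ConfigError, DataError

__all__ = [
    "PBReport",
    "percent_bias",
    "pb_report",
    "pool_imputations",
    "compare_methods_pb",
    "umap_eval_protocol",
    "prevalence_baseline",
]


@dataclass
class PBReport:
    """Per-variable percent-bias values for one imputation experiment."""

    method: str
    per_variable_pb: dict[str, float]
    obs_num: int = 0
    mask_obs_rate: float = 0.0
    repetition: int = 0
    excluded_variables: list[str] = field(default_factory=list)

    def median(self) -> float:
        return float(np.median(list(self.per_variable_pb.values())))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variable": list(self.per_variable_pb),
            "percent_bias": list(self.per_variable_pb.values()),
            "method": self.method,
            "obs_num": self.obs_num,
            "mask_obs_rate": self.mask_obs_rate,
            "repetition": self.repetition,
        })


def percent_bias(observed, imputations) -> float:
    """PB for one variable: observed test values vs m sets of imputed values."""
    observed = np.asarray(observed, dtype=float)
    if observed.ndim != 1 or observed.size == 0:
        raise ConfigError("observed must be a non-empty 1-D array")
    imps = np.atleast_2d(np.asarray(imputations, dtype=float))
    if imps.shape[1] != observed.size:
        raise ConfigError("imputations must align with observed samples")
    if np.all(observed == 0):
        raise DataError("all observed values are zero; percent bias undefined")
    if np.any(observed == 0):
        warnings.warn("observed values contain zeros; variable should be excluded",
                      RuntimeWarning, stacklevel=2)
    medians = np.median(np.abs(imps - observed[None, :]) / observed[None, :], axis=1)
    return float(medians.mean())


def pb_report(observed_block: DataBlock, imputed_blocks, method: str,
              obs_num: int = 0, mask_obs_rate: float = 0.0,
              repetition: int = 0) -> PBReport:
    """PB per variable for one experiment; m > 1 blocks = multiple imputations."""
    if isinstance(imputed_blocks, DataBlock):
        imputed_blocks = [imputed_blocks]
    pbs: dict[str, float] = {}
    excluded: list[str] = []
    for j, var in enumerate(observed_block.variable_ids):
        obs_col = observed_block.values[:, j]
        mask = observed_block.observed_mask[:, j]
        obs = obs_col[mask]
        if obs.size == 0 or np.any(obs <= 0):
            excluded.append(var)
            continue
        imps = np.stack([b.values[:, j][mask] for b in imputed_blocks])
        pbs[var] = percent_bias(obs, imps)
    if excluded:
        warnings.warn(f"{len(excluded)} variables with nonpositive observed values "
                      f"excluded from percent bias", RuntimeWarning, stacklevel=2)
    return PBReport(method, pbs, obs_num, mask_obs_rate, repetition,
                    excluded_variables=excluded)


def pool_imputations(imputations) -> DataBlock:
    """Cellwise mean across m imputed blocks (Rubin-style point estimate)."""
    blocks = list(imputations)
    if not blocks:
        raise ConfigError("no imputations to pool")
    first = blocks[0]
    for b in blocks[1:]:
        if b.values.shape != first.values.shape or \
                b.sample_ids != first.sample_ids or \
                b.variable_ids != first.variable_ids:
            raise ConfigError("imputations have mismatched shapes or indices")
    out = first.copy()
    out.values = np.mean([b.values for b in blocks], axis=0)
    return out


_SIG_BINS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _significance(p: float) -> str:
    for cut, label in _SIG_BINS:
        if p < cut:
            return label
    return "ns"


def compare_methods_pb(reports: dict[str, PBReport], reference: str) -> pd.DataFrame:
    """Two-sided paired Wilcoxon signed-rank tests of per-variable PB vs a reference.

    P-values are Bonferroni-multiplied by the number of comparisons (capped
    at 1) and binned ns / * / ** / *** at 0.05 / 0.01 / 0.001.
    """
    if reference not in reports:
        raise ConfigError(f"reference method {reference!r} missing from reports")
    ref = reports[reference]
    ref_vars = list(ref.per_variable_pb)
    competitors = [m for m in reports if m != reference]
    n_comp = len(competitors)
    rows = []
    for method in competitors:
        rep = reports[method]
        if set(rep.per_variable_pb) != set(ref_vars):
            raise ConfigError(f"method {method!r} covers a different variable set")
        a = np.array([rep.per_variable_pb[v] for v in ref_vars])
        b = np.array([ref.per_variable_pb[v] for v in ref_vars])
        if np.allclose(a, b):
            p_raw = 1.0
        else:
            p_raw = float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
        p_adj = min(1.0, p_raw * n_comp)
        rows.append({
            "method": method,
            "reference": reference,
            "n_variables": len(ref_vars),
            "median_pb": float(np.median(a)),
            "reference_median_pb": float(np.median(b)),
            "p_raw": p_raw,
            "p_adjusted": p_adj,
            "significance": _significance(p_adj),
        })
    return pd.DataFrame(rows)


def umap_eval_protocol(train_blocks, test_observed: DataBlock,
                       imputed_blocks: dict[str, DataBlock], seed: int = 0,
                       n_neighbors: int = 15, min_dist: float = 0.1) -> pd.DataFrame:
    """Fixed-reference UMAP: fit once on training data, transform everything else.

    The projection is fitted on the concatenated training blocks of the
    target view (both timepoints) with training-set z-scoring; the same
    fitted model then embeds the observed test block and every method's
    imputed block, so embedding differences reflect the data, not refits.
    """
    import umap

    train_blocks = list(train_blocks)
    variables = train_blocks[0].variable_ids
    for b in train_blocks + [test_observed] + list(imputed_blocks.values()):
        if b.variable_ids != variables:
            raise ConfigError("variable sets differ across blocks")
    x_train = np.concatenate([b.values for b in train_blocks], axis=0)
    mu = x_train.mean(axis=0)
    sd = x_train.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    reducer = umap.UMAP(n_neighbors=n_neighbors, min_dist=min_dist,
                        random_state=seed)
    emb_train = reducer.fit_transform((x_train - mu) / sd)
    frames = []
    row = 0
    for b in train_blocks:
        n = b.n_samples
        frames.append(pd.DataFrame({
            "sample_id": b.sample_ids,
            "source": f"train_{b.view_id}_{b.timepoint_id}",
            "dim1": emb_train[row:row + n, 0],
            "dim2": emb_train[row:row + n, 1],
        }))
        row += n
    def _transform(block: DataBlock, label: str) -> pd.DataFrame:
        emb = reducer.transform((block.values - mu) / sd)
        return pd.DataFrame({
            "sample_id": block.sample_ids,
            "source": label,
            "dim1": emb[:, 0],
            "dim2": emb[:, 1],
        })
    frames.append(_transform(test_observed, "test_observed"))
    for method, block in imputed_blocks.items():
        frames.append(_transform(block, f"imputed_{method}"))
    return pd.concat(frames, ignore_index=True)


def prevalence_baseline(n_positive: int, n_total: int) -> float:
    """Proportion of positive cases - the non-discriminative PR baseline."""
    if n_total <= 0:
        raise ConfigError("n_total must be positive")
    if not 0 <= n_positive <= n_total:
        raise ConfigError("n_positive must lie in [0, n_total]")
    return round(n_positive / n_total, 3)
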