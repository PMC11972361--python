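"""Variable-level quality-control rules for omics panels.

The rules mirror common targeted-metabolomics / Olink practice:

* ``require_no_missing`` - drop variables with any missing value;
* ``lod_fraction`` - keep a variable only if *at least* that fraction of its
  measured values is at or above the limit of detection (LOD) of the
  corresponding plate (0.50 for metabolomics panels, 0.75 for Olink
  proteomics);
* ``rsd_threshold_pct`` - the median across plates of the per-plate relative
  standard deviation (100 * sd / mean) of QC replicate samples must be
  *strictly below* the threshold (25%);
* ``remeasure_corr_threshold`` - Spearman correlation between the original
  and a remeasured platform must be *strictly above* the threshold (0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError

__all__ = ["QcRuleSet", "apply_qc"]


@dataclass
class QcRuleSet:
    require_no_missing: bool = True
    lod_fraction: float | None = 0.5
    rsd_threshold_pct: float | None = 25.0
    remeasure_corr_threshold: float | None = 0.5

    def __post_init__(self):
        if self.lod_fraction is not None and not 0.0 <= self.lod_fraction <= 1.0:
            raise ConfigError("lod_fraction must lie in [0, 1]")


def _median_rsd(qc_replicates: dict[str, np.ndarray], j: int) -> float:
    """Median over plates of per-plate RSD (%) for variable column j."""
    rsds = []
    for plate_values in qc_replicates.values():
        col = np.asarray(plate_values, dtype=float)[:, j]
        col = col[np.isfinite(col)]
        if col.size < 2:
            continue
        mean = col.mean()
        sd = col.std(ddof=1)
        rsds.append(100.0 * sd / mean)
    if not rsds:
        return np.nan
    return float(np.median(rsds))


def apply_qc(
    values: pd.DataFrame,
    rules: QcRuleSet,
    lod=None,
    qc_replicates: dict[str, np.ndarray] | None = None,
    remeasured: pd.DataFrame | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the active QC rules; a variable is kept iff it passes every one.

    Parameters
    ----------
    values
        samples x variables measurements (NaN = missing).
    rules
        Which rules are active and their thresholds (``None`` deactivates a
        threshold rule).
    lod
        Per-variable detection limits: either a 1-D array-like aligned with
        the columns of ``values``, or a mapping plate id -> (row mask over
        samples, per-variable LOD vector) for per-plate limits.
    qc_replicates
        Mapping plate id -> QC-replicate matrix (replicates x variables).
    remeasured
        Second-platform measurements sharing the variable axis (sample
        overlap is used for the correlation rule).

    Returns the kept variable ids and a per-variable report with each rule's
    statistic and pass flag plus the final ``keep`` flag.
    """
    variables = [str(c) for c in values.columns]
    report = pd.DataFrame(index=variables)
    keep = np.ones(len(variables), dtype=bool)
    mat = values.to_numpy(dtype=float)

    if rules.require_no_missing:
        n_missing = np.sum(~np.isfinite(mat), axis=0)
        passed = n_missing == 0
        report["n_missing"] = n_missing
        report["pass_no_missing"] = passed
        keep &= passed

    if rules.lod_fraction is not None:
        if lod is None:
            raise ConfigError("lod_fraction rule is active but no LOD supplied")
        measured = np.isfinite(mat)
        if isinstance(lod, dict):
            detect = np.zeros(mat.shape, dtype=bool)
            for row_mask, lod_vec in lod.values():
                row_mask = np.asarray(row_mask, dtype=bool)
                lod_vec = np.asarray(lod_vec, dtype=float)
                detect[row_mask] = mat[row_mask] >= lod_vec[None, :]
        else:
            lod_vec = np.asarray(lod, dtype=float)
            detect = mat >= lod_vec[None, :]
        with np.errstate(invalid="ignore"):
            frac = np.where(
                measured.sum(axis=0) > 0,
                (detect & measured).sum(axis=0) / np.maximum(measured.sum(axis=0), 1),
                0.0,
            )
        passed = frac >= rules.lod_fraction  # "at least" the stated fraction
        report["detectable_fraction"] = frac
        report["pass_lod"] = passed
        keep &= passed

    if rules.rsd_threshold_pct is not None:
        if qc_replicates is None:
            raise ConfigError("rsd_threshold rule is active but no QC replicates supplied")
        med_rsd = np.array([_median_rsd(qc_replicates, j) for j in range(len(variables))])
        passed = med_rsd < rules.rsd_threshold_pct  # strict "< 25%"
        report["median_qc_rsd_pct"] = med_rsd
        report["pass_rsd"] = passed
        keep &= passed

    if rules.remeasure_corr_threshold is not None:
        if remeasured is None:
            raise ConfigError("remeasure_corr rule is active but no remeasured data supplied")
        shared = values.index.intersection(remeasured.index)
        corr = np.full(len(variables), np.nan)
        for j, var in enumerate(variables):
            if var not in remeasured.columns:
                continue
            a = values.loc[shared, var].to_numpy(dtype=float)
            b = remeasured.loc[shared, var].to_numpy(dtype=float)
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() >= 3:
                corr[j] = stats.spearmanr(a[ok], b[ok]).statistic
        passed = corr > rules.remeasure_corr_threshold  # strict "> 0.5"
        report["remeasure_spearman"] = corr
        report["pass_remeasure"] = passed
        keep &= passed

    report["keep"] = keep
    kept = [v for v, k in zip(variables, keep) if k]
    return kept, report
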