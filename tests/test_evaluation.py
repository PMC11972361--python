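"""Percent bias, pooling, paired Wilcoxon comparison, UMAP protocol,
prevalence baselines."""

import itertools

import numpy as np
import pytest

from leopard import (
    DataBlock,
    PBReport,
    compare_methods_pb,
    pb_report,
    percent_bias,
    pool_imputations,
    prevalence_baseline,
    umap_eval_protocol,
)
from leopard.errors import ConfigError, DataError


def block_of(values, view="v2", tp="t2", prefix="m"):
    values = np.atleast_2d(np.asarray(values, float))
    return DataBlock(view, tp, [f"s{i}" for i in range(values.shape[0])],
                     [f"{prefix}{j}" for j in range(values.shape[1])],
                     values, np.ones_like(values, dtype=bool))


# ------------------------------------------------------------- percent bias


def test_pb_identity_is_zero(rng):
    obs = rng.uniform(1, 5, size=10)
    assert percent_bias(obs, obs[None, :]) == 0.0


def test_pb_doubling_gives_one():
    assert percent_bias([1.0, 2.0], [[2.0, 4.0]]) == pytest.approx(1.0)


def test_pb_two_imputation_oracle(rng):
    obs = rng.uniform(1, 4, size=9)
    imp1 = obs * (1 + rng.uniform(-0.5, 0.5, size=9))
    imp2 = obs * (1 + rng.uniform(-0.5, 0.5, size=9))
    med1 = np.median(np.abs(imp1 - obs) / obs)
    med2 = np.median(np.abs(imp2 - obs) / obs)
    assert percent_bias(obs, [imp1, imp2]) == pytest.approx((med1 + med2) / 2,
                                                            rel=1e-12)


def test_pb_scale_invariance(rng):
    obs = rng.uniform(1, 4, size=12)
    imp = obs + rng.normal(0, 0.2, size=12)
    for c in (0.01, 1.0, 250.0):
        assert percent_bias(c * obs, [c * imp]) == pytest.approx(
            percent_bias(obs, [imp]), rel=1e-12)


def test_pb_zero_handling():
    with pytest.warns(RuntimeWarning):
        percent_bias([0.0, 1.0], [[1.0, 1.0]])
    with pytest.raises(DataError):
        percent_bias([0.0, 0.0], [[1.0, 1.0]])


def test_pb_report_excludes_nonpositive_variables(rng):
    obs = block_of([[1.0, -2.0], [2.0, 3.0]])
    imp = block_of([[1.5, 1.0], [2.5, 2.0]])
    with pytest.warns(RuntimeWarning):
        report = pb_report(obs, imp, "m")
    assert report.excluded_variables == ["m1"]
    assert set(report.per_variable_pb) == {"m0"}


# ------------------------------------------------------------------ pooling


def test_pool_single_imputation_is_identity(rng):
    b = block_of(rng.uniform(1, 2, size=(4, 3)))
    out = pool_imputations([b])
    assert np.array_equal(out.values, b.values)


def test_pool_cellwise_mean_oracle(rng):
    blocks = [block_of(rng.uniform(1, 2, size=(3, 2))) for _ in range(4)]
    out = pool_imputations(blocks)
    for i in range(3):
        for j in range(2):
            assert out.values[i, j] == pytest.approx(
                np.mean([b.values[i, j] for b in blocks]), rel=1e-12)


def test_pool_commutes_with_sample_reordering(rng):
    vals = [rng.uniform(1, 2, size=(5, 2)) for _ in range(3)]
    pooled = pool_imputations([block_of(v) for v in vals]).values
    perm = rng.permutation(5)
    pooled_perm = pool_imputations([block_of(v[perm]) for v in vals]).values
    assert np.allclose(pooled[perm], pooled_perm)


def test_pool_shape_mismatch():
    with pytest.raises(ConfigError):
        pool_imputations([block_of(np.ones((2, 2))), block_of(np.ones((3, 2)))])


# ------------------------------------------------------------- comparisons


def _report(method, pbs):
    return PBReport(method, {f"m{i}": p for i, p in enumerate(pbs)})


def test_identical_pb_vectors_are_ns():
    pbs = [0.1, 0.2, 0.3, 0.15]
    table = compare_methods_pb({"ref": _report("ref", pbs),
                                "other": _report("other", list(pbs))}, "ref")
    row = table.iloc[0]
    assert row["p_adjusted"] == 1.0 and row["significance"] == "ns"


def test_bonferroni_multiplication_and_cap():
    rng = np.random.default_rng(5)
    base = rng.uniform(0.1, 0.3, size=15)
    reports = {"ref": _report("ref", base)}
    for i in range(3):
        reports[f"m{i}"] = _report(f"m{i}", base + rng.uniform(0, 0.1, size=15))
    table = compare_methods_pb(reports, "ref").set_index("method")
    for i in range(3):
        row = table.loc[f"m{i}"]
        assert row["p_adjusted"] == pytest.approx(min(1.0, row["p_raw"] * 3))


def test_signed_rank_p_matches_exhaustive_enumeration():
    """n=6 paired differences, all positive: exact two-sided p from the 2^6
    sign-assignment distribution of the signed-rank statistic."""
    ref = [0.10, 0.12, 0.14, 0.16, 0.18, 0.20]
    other = [r + d for r, d in zip(ref, [0.01, 0.02, 0.03, 0.04, 0.05, 0.06])]
    diffs = np.array(other) - np.array(ref)
    ranks = np.argsort(np.argsort(np.abs(diffs))) + 1
    observed_w = ranks.sum()  # all positive
    count_ge = sum(
        1 for signs in itertools.product([1, -1], repeat=6)
        if sum(r for r, s in zip(ranks, signs) if s > 0) >= observed_w
    )
    count_le = sum(
        1 for signs in itertools.product([1, -1], repeat=6)
        if sum(r for r, s in zip(ranks, signs) if s > 0)
        <= (ranks.sum() - observed_w)
    )
    expected_two_sided = min(1.0, 2 * min(count_ge, count_le) / 2**6)
    table = compare_methods_pb({"ref": _report("ref", ref),
                                "other": _report("other", other)}, "ref")
    assert table.iloc[0]["p_raw"] == pytest.approx(expected_two_sided, rel=1e-9)


def test_comparison_rejects_different_variable_sets():
    with pytest.raises(ConfigError):
        compare_methods_pb({"ref": _report("ref", [0.1, 0.2]),
                            "other": PBReport("other", {"x": 0.1})}, "ref")


# ---------------------------------------------------------------- UMAP


def test_umap_protocol_shapes_and_determinism(rng):
    train1 = block_of(rng.normal(10, 1, size=(40, 6)), tp="t1")
    train2 = block_of(rng.normal(12, 1, size=(40, 6)), tp="t2")
    test_obs = block_of(rng.normal(12, 1, size=(10, 6)), tp="t2")
    imputed = {"m": block_of(rng.normal(12, 1, size=(10, 6)), tp="t2")}
    emb = umap_eval_protocol([train1, train2], test_obs, imputed, seed=3)
    assert len(emb) == 40 + 40 + 10 + 10
    assert set(emb.columns) == {"sample_id", "source", "dim1", "dim2"}
    emb2 = umap_eval_protocol([train1, train2], test_obs, imputed, seed=3)
    assert np.allclose(emb[["dim1", "dim2"]], emb2[["dim1", "dim2"]])


def test_umap_protocol_variable_mismatch():
    a = block_of(np.ones((5, 3)))
    b = block_of(np.ones((5, 4)))
    with pytest.raises(ConfigError):
        umap_eval_protocol([a], a, {"m": b}, seed=0)


# ------------------------------------------------------------- prevalence


@pytest.mark.parametrize("pos,total,expected", [
    (56, 416, 0.135),
    (36, 212, 0.170),
    (30, 43, 0.698),
    (0, 7, 0.0),
])
def test_prevalence_baselines(pos, total, expected):
    assert prevalence_baseline(pos, total) == pytest.approx(expected, abs=5e-4)


def test_prevalence_errors():
    with pytest.raises(ConfigError):
        prevalence_baseline(1, 0)
    with pytest.raises(ConfigError):
        prevalence_baseline(5, 3)
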