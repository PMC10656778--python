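import itertools

import numpy as np
import pandas as pd
import pytest

from refstab import (
    SimSpec,
    bestkeeper_stability,
    delta_ct_stability,
    genorm_stability,
    normfinder_stability,
    simulate_ct,
)
from refstab.errors import DimensionError, GroupingError, TableValueError

from conftest import make_ct


# ---------------------------------------------------------------------------
# brute-force oracles (plain loops, independent of the vectorized paths)
# ---------------------------------------------------------------------------

def brute_delta_ct(values):
    g = values.shape[0]
    stats = []
    for i in range(g):
        sds = []
        for k in range(g):
            if k == i:
                continue
            diffs = [values[i, j] - values[k, j] for j in range(values.shape[1])]
            sds.append(np.std(diffs, ddof=1))
        stats.append(float(np.mean(sds)))
    return np.array(stats)


def brute_genorm_initial_m(values):
    logq = values.min(axis=1, keepdims=True) - values  # E = 2 => log2 quantities
    g = values.shape[0]
    m = []
    for j in range(g):
        vs = []
        for k in range(g):
            if k == j:
                continue
            ratios = [logq[j, s] - logq[k, s] for s in range(values.shape[1])]
            vs.append(np.std(ratios, ddof=1))
        m.append(float(np.mean(vs)))
    return np.array(m)


def naive_normfinder(values, labels):
    """Plain-loop transcription of the model-based variance decomposition."""
    k = values.shape[0]
    uniq = list(dict.fromkeys(labels))
    G = len(uniq)
    sigma2 = np.zeros((k, G))
    gmean = np.zeros((k, G))
    nper = np.zeros(G)
    for gi, g in enumerate(uniq):
        cols = [j for j, l in enumerate(labels) if l == g]
        n = len(cols)
        nper[gi] = n
        block = values[:, cols]
        s2 = np.zeros(k)
        for i in range(k):
            ssr = 0.0
            for j in range(n):
                r = block[i, j] - block[i, :].mean() - block[:, j].mean() + block.mean()
                ssr += r * r
            s2[i] = ssr / (n - 1)
        for i in range(k):
            sigma2[i, gi] = max(0.0, (s2[i] - s2.mean() / (k - 1)) * k / (k - 2))
            gmean[i, gi] = block[i, :].mean()
    if G == 1:
        return np.sqrt(sigma2[:, 0])
    grand = values.mean(axis=1)
    d = gmean - grand[:, None]
    for gi in range(G):
        d[:, gi] -= d[:, gi].mean()
    v = sigma2 / nper[None, :]
    gamma2 = max(0.0, (d**2).sum() / ((k - 1) * (G - 1)) - v.mean())
    rho = np.zeros((k, G))
    for gi in range(G):
        for i in range(k):
            if gamma2 > 0:
                h = gamma2 / (gamma2 + v[i, gi])
                rho[i, gi] = abs(d[i, gi] * h) + np.sqrt(v[i, gi] * h)
            else:
                rho[i, gi] = np.sqrt(v[i, gi])
    return rho.mean(axis=1)


# ---------------------------------------------------------------------------
# comparative delta-Ct
# ---------------------------------------------------------------------------

def test_delta_ct_worked_fixture(worked_ct):
    table = delta_ct_stability(worked_ct).table.set_index("gene_id")
    np.testing.assert_allclose(table.loc[["G1", "G2", "G3"], "statistic"], [0.5, 0.5, 1.0])
    assert table.loc["G3", "rank"] == 3
    np.testing.assert_allclose(
        table.loc[["G1", "G2", "G3"], "statistic"], brute_delta_ct(worked_ct.values)
    )


def test_delta_ct_identical_genes_all_zero():
    ct = make_ct(np.tile([20.0, 22.5, 21.0, 23.0], (4, 1)))
    assert (delta_ct_stability(ct).table["statistic"] == 0).all()


def test_delta_ct_sample_offset_invariance(worked_ct):
    shifted = worked_ct.values.copy()
    shifted[:, 1] += 2.0  # add 2 cycles to every gene in one sample
    ct2 = make_ct(shifted)
    np.testing.assert_allclose(
        delta_ct_stability(worked_ct).table["statistic"],
        delta_ct_stability(ct2).table["statistic"],
    )


def test_delta_ct_two_genes_share_single_pairwise_sd():
    ct = make_ct([[20, 21, 22], [20, 20, 20]])
    stats = delta_ct_stability(ct).table["statistic"]
    np.testing.assert_allclose(stats, [1.0, 1.0])


def test_delta_ct_one_gene_rejected():
    with pytest.raises(DimensionError):
        delta_ct_stability(make_ct([[20, 21, 22]]))


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------

def test_bestkeeper_plain_sd(worked_ct):
    t = bestkeeper_stability(worked_ct)
    detail = t.extras["detail"].set_index("gene_id")
    assert detail.loc["G1", "sd"] == pytest.approx(1.0)
    assert detail.loc["G1", "cv_pct"] == pytest.approx(100.0 / 21.0)
    assert detail.loc["G3", "sd"] == 0.0 and detail.loc["G3", "cv_pct"] == 0.0
    assert t.table.iloc[0]["gene_id"] == "G3"  # constant gene is most stable


def test_bestkeeper_mad_geomean(worked_ct):
    t = bestkeeper_stability(worked_ct, variant="mad_geomean")
    detail = t.extras["detail"].set_index("gene_id")
    geo = (20.0 * 21.0 * 22.0) ** (1.0 / 3.0)
    expected = np.mean(np.abs(np.array([20.0, 21.0, 22.0]) - geo))
    assert detail.loc["G1", "sd"] == pytest.approx(expected, abs=1e-4)
    assert detail.loc["G1", "sd"] == pytest.approx(0.6720, abs=1e-4)


def test_bestkeeper_not_loading_invariant():
    rng = np.random.default_rng(0)
    base = rng.uniform(20, 25, size=(4, 6))
    shifted = base + rng.uniform(1, 3, size=6)[None, :]
    s1 = bestkeeper_stability(make_ct(base)).table.set_index("gene_id")["statistic"]
    s2 = bestkeeper_stability(make_ct(shifted)).table.set_index("gene_id")["statistic"]
    assert not np.allclose(s1, s2)


def test_bestkeeper_unknown_variant():
    with pytest.raises(TableValueError):
        bestkeeper_stability(make_ct([[20, 21], [22, 23]]), variant="nope")


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

def test_genorm_worked_fixture(worked_ct):
    res, table = genorm_stability(worked_ct)
    np.testing.assert_allclose(res.initial_m.loc[["G1", "G2", "G3"]], [0.5, 0.5, 1.0])
    np.testing.assert_allclose(
        res.initial_m.loc[["G1", "G2", "G3"]], brute_genorm_initial_m(worked_ct.values)
    )
    assert res.removal_order == ["G3"]
    assert res.final_pair == ("G1", "G2")
    tf = table.table.set_index("gene_id")
    assert tf.loc["G1", "frac_rank"] == 1.5 and tf.loc["G2", "frac_rank"] == 1.5


def test_genorm_identical_pair_mutual_v_zero():
    ct = make_ct([[20, 21, 22], [20, 21, 22], [20, 20, 20]])
    logq = ct.values.min(axis=1, keepdims=True) - ct.values
    v12 = np.std(logq[0] - logq[1], ddof=1)
    assert v12 == 0.0
    res, _ = genorm_stability(ct)
    assert res.final_pair == ("G1", "G2")


def test_genorm_loading_shift_invariance():
    rng = np.random.default_rng(1)
    base = rng.uniform(18, 28, size=(5, 8))
    shift = rng.uniform(-2, 2, size=8)
    m1 = genorm_stability(make_ct(base))[0].initial_m
    m2 = genorm_stability(make_ct(base + shift[None, :]))[0].initial_m
    np.testing.assert_allclose(m1, m2, atol=1e-9)


def test_genorm_removal_never_increases_mean_m(worked_ct):
    res, _ = genorm_stability(worked_ct)
    full_mean = res.initial_m.mean()
    remaining = res.initial_m.drop(res.removal_order[0])
    # recompute M on the remaining pair
    keep = [g for g in worked_ct.gene_ids if g != res.removal_order[0]]
    sub = make_ct(worked_ct.data.loc[keep].to_numpy(), gene_ids=keep)
    logq = sub.values.min(axis=1, keepdims=True) - sub.values
    pair_m = np.std(logq[0] - logq[1], ddof=1)
    assert pair_m <= full_mean


def test_genorm_efficiency_correction_changes_scale(worked_ct):
    effs = {g: 100.0 for g in worked_ct.gene_ids}  # E = 2: same as default
    res_default, _ = genorm_stability(worked_ct)
    res_e, _ = genorm_stability(worked_ct, efficiencies=effs)
    np.testing.assert_allclose(res_default.initial_m, res_e.initial_m)
    with pytest.raises(TableValueError):
        genorm_stability(worked_ct, efficiencies={"G1": 100.0})  # missing genes


def test_genorm_pairwise_variation_indexing():
    rng = np.random.default_rng(2)
    ct = make_ct(rng.uniform(18, 30, size=(6, 9)))
    res, _ = genorm_stability(ct)
    assert list(res.pairwise_variation.index) == [2, 3, 4, 5]
    assert (res.pairwise_variation >= 0).all()


def test_genorm_needs_three_genes():
    with pytest.raises(DimensionError):
        genorm_stability(make_ct([[20, 21], [22, 23]]))


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

def test_normfinder_all_constant_is_zero():
    ct = make_ct(
        np.tile([[20.0], [22.0], [24.0]], (1, 8)),
        groups=["a"] * 4 + ["b"] * 4,
        bio_reps=[1, 2, 3, 4] * 2,
    )
    stats = normfinder_stability(ct).table["statistic"]
    np.testing.assert_allclose(stats, 0.0, atol=1e-12)


def test_normfinder_single_group_ranks_noisy_gene_last():
    rng = np.random.default_rng(4)
    n = 30
    loading = rng.normal(0, 1, n)
    values = np.vstack(
        [
            20 + loading + rng.normal(0, 0.1, n),
            24 + loading + rng.normal(0, 0.1, n),
            28 + loading + rng.normal(0, 1.0, n),
        ]
    )
    values = np.clip(values, 10, 40)
    ct = make_ct(values)
    result = normfinder_stability(ct)
    assert result.extras["mode"] == "single_group"
    assert result.table.iloc[-1]["gene_id"] == "G3"


def test_normfinder_matches_naive_oracle_multigroup():
    rng = np.random.default_rng(7)
    mu = rng.uniform(18, 30, 8)
    tau = np.array([0.05, 0.1, 0.2, 0.3, 0.5, 0.8, 1.2, 2.0])
    spec = SimSpec(mu=mu, tau=tau, n_groups=4, n_bio_reps=6, loading_sd=1.0, noise_sd=0.2, seed=7)
    ct, _ = simulate_ct(spec)
    impl = normfinder_stability(ct).table.set_index("gene_id")["statistic"]
    oracle = naive_normfinder(ct.values, list(ct.meta["group"]))
    np.testing.assert_allclose(impl.loc[ct.gene_ids].to_numpy(), oracle, atol=1e-12)


def test_normfinder_matches_naive_oracle_single_group():
    rng = np.random.default_rng(9)
    ct = make_ct(np.clip(rng.uniform(18, 30, size=(5, 12)), 10, 40))
    impl = normfinder_stability(ct).table.set_index("gene_id")["statistic"]
    oracle = naive_normfinder(ct.values, ["g"] * 12)
    np.testing.assert_allclose(impl.loc[ct.gene_ids].to_numpy(), oracle, atol=1e-12)


def test_normfinder_singleton_group_rejected():
    ct = make_ct(
        np.random.default_rng(0).uniform(18, 30, size=(3, 5)),
        groups=["a", "a", "a", "a", "b"],
        bio_reps=[1, 2, 3, 4, 1],
    )
    with pytest.raises(GroupingError):
        normfinder_stability(ct)


# ---------------------------------------------------------------------------
# cross-method invariants
# ---------------------------------------------------------------------------

def test_gene_relabeling_permutation_equivariance():
    rng = np.random.default_rng(12)
    values = rng.uniform(18, 30, size=(5, 12))
    groups = ["a"] * 6 + ["b"] * 6
    bio = [1, 2, 3, 4, 5, 6] * 2
    ct = make_ct(values, groups=groups, bio_reps=bio)
    perm = [3, 0, 4, 1, 2]
    names = [f"G{i + 1}" for i in range(5)]
    ct_perm = make_ct(values[perm], gene_ids=[names[i] for i in perm], groups=groups, bio_reps=bio)
    for fn in (delta_ct_stability, bestkeeper_stability, normfinder_stability):
        s1 = fn(ct).table.set_index("gene_id")["statistic"]
        s2 = fn(ct_perm).table.set_index("gene_id")["statistic"]
        np.testing.assert_allclose(s1.sort_index(), s2.sort_index(), atol=1e-9)
    m1 = genorm_stability(ct)[0].initial_m.sort_index()
    m2 = genorm_stability(ct_perm)[0].initial_m.sort_index()
    np.testing.assert_allclose(m1, m2, atol=1e-9)


def test_all_methods_rank_planted_unstable_gene_last():
    rng = np.random.default_rng(21)
    mu = rng.uniform(18, 30, 6)
    tau = np.full(6, 0.05)
    tau[2] = 2.5  # >= 10x separation
    spec = SimSpec(mu=mu, tau=tau, n_groups=6, n_bio_reps=3, loading_sd=1.0, noise_sd=0.2, seed=21)
    ct, _ = simulate_ct(spec)
    bad = ct.gene_ids[2]
    for fn in (delta_ct_stability, bestkeeper_stability, normfinder_stability):
        assert fn(ct).table.iloc[-1]["gene_id"] == bad
    assert genorm_stability(ct)[1].table.iloc[-1]["gene_id"] == bad
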