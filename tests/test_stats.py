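"""Paired tests, correlations, summary tables and cluster permutation."""

import numpy as np
import pytest

from miattn.indices import SubjectIndices
from miattn.montage import electrode_adjacency
from miattn.paradigm import ATTENTION, CHANNELS_32, INATTENTION
from miattn.reference_tables import as_subject_indices, erd_ami_table
from miattn.stats import (bonferroni_per_second, build_summary_table,
                          cluster_perm_channels, cluster_perm_tf,
                          normality_check, paired_t, pearson_r, summary_stats)


# ---------------------------------------------------------------------------
# scalar statistics
# ---------------------------------------------------------------------------

def test_paired_t_hand_oracle():
    """Differences {-1,-1,-1,1}: mean -0.5, sd 1.0 -> t = -1, df = 3."""
    t, df, p = paired_t([0, 0, 0, 0], [1, 1, 1, -1])
    assert t == pytest.approx(-1.0)
    assert df == 3


def test_paired_t_degenerate_and_mismatch():
    with pytest.raises(ValueError):
        paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        paired_t([1.0, 2.0], [1.0])


def test_paired_t_null_calibration():
    """Rejection rate at alpha=0.05 under the null, n=14."""
    rng = np.random.default_rng(0)
    reject = 0
    reps = 4000
    for _ in range(reps):
        a = rng.standard_normal(14)
        b = rng.standard_normal(14)
        _, _, p = paired_t(a, b)
        reject += p < 0.05
    assert 0.04 <= reject / reps <= 0.06


def test_pearson_r_identities():
    x = np.arange(10.0)
    r, _ = pearson_r(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    r, _ = pearson_r(x, -x)
    assert r == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        pearson_r(x, np.ones(10))


def test_pearson_affine_invariance():
    rng = np.random.default_rng(1)
    x = rng.normal(size=20)
    y = rng.normal(size=20)
    r1, p1 = pearson_r(x, y)
    r2, p2 = pearson_r(3.0 * x + 5.0, y)
    assert r1 == pytest.approx(r2)
    assert p1 == pytest.approx(p2)


def test_shapiro_calibration_and_power():
    rng = np.random.default_rng(2)
    normal_ok = sum(normality_check(rng.standard_normal(14))[1] > 0.05
                    for _ in range(100))
    assert normal_ok >= 90
    lognormal_flag = sum(
        normality_check(np.exp(rng.standard_normal(14)))[1] < 0.05
        for _ in range(100))
    assert lognormal_flag >= 50
    with pytest.raises(ValueError):
        normality_check(np.ones(10))


def test_summary_stats_population_convention():
    mean, sd = summary_stats([1.0, 2.0, 3.0, 4.0])
    assert mean == 2.5
    assert sd == pytest.approx(np.sqrt(1.25))
    assert summary_stats([7.0]) == (7.0, 0.0)
    with pytest.raises(ValueError):
        summary_stats([])


# ---------------------------------------------------------------------------
# cluster permutation: time-frequency grid
# ---------------------------------------------------------------------------

def test_cluster_tf_exact_null_is_empty():
    rng = np.random.default_rng(3)
    maps = rng.normal(size=(6, 10, 10))
    res = cluster_perm_tf(maps, maps.copy(), n_perm=100, seed=0)
    assert res.clusters == []
    assert np.all(res.sig_mask == 0)


def test_cluster_tf_recovers_injected_block():
    rng = np.random.default_rng(4)
    n, block = 14, (slice(5, 13), slice(5, 13))
    a = rng.normal(size=(n, 20, 20))
    b = rng.normal(size=(n, 20, 20))
    a[:, block[0], block[1]] -= 1.5
    res = cluster_perm_tf(a, b, n_perm=500, seed=1)
    sig = res.significant
    assert len(sig) == 1
    mask = np.zeros((20, 20), dtype=bool)
    mask.ravel()[sig[0].bins] = True
    inject = np.zeros((20, 20), dtype=bool)
    inject[block] = True
    coverage = (mask & inject).sum() / inject.sum()
    outside = (mask & ~inject).sum() / inject.sum()
    assert sig[0].sign == -1
    assert coverage >= 0.8
    assert outside <= 0.05


def test_cluster_tf_sign_separated():
    """Adjacent positive and negative effects never join one cluster."""
    n = 14
    rng = np.random.default_rng(5)
    a = rng.normal(size=(n, 10, 10), scale=0.2)
    b = rng.normal(size=(n, 10, 10), scale=0.2)
    a[:, 2:5, :] += 2.0
    a[:, 5:8, :] -= 2.0
    res = cluster_perm_tf(a, b, n_perm=200, seed=2)
    signs = {c.sign for c in res.significant}
    assert signs == {1, -1}
    for c in res.clusters:
        t_vals = res.t_map.ravel()[c.bins]
        assert np.all(np.sign(t_vals) == c.sign)


def test_cluster_tf_deterministic_and_monotone():
    rng = np.random.default_rng(6)
    a = rng.normal(size=(8, 12, 12))
    b = rng.normal(size=(8, 12, 12))
    r1 = cluster_perm_tf(a, b, n_perm=200, seed=9)
    r2 = cluster_perm_tf(a, b, n_perm=200, seed=9)
    assert np.array_equal(r1.null, r2.null)
    assert [c.p for c in r1.clusters] == [c.p for c in r2.clusters]
    ordered = sorted(r1.clusters, key=lambda c: abs(c.mass), reverse=True)
    ps = [c.p for c in ordered]
    assert all(p1 <= p2 + 1e-12 for p1, p2 in zip(ps, ps[1:]))


def test_cluster_tf_matches_independent_implementation():
    """Observed clusters agree with an established permutation cluster test."""
    import mne
    from scipy import stats as sst

    rng = np.random.default_rng(7)
    n = 12
    x = rng.normal(size=(n, 15, 15))
    x[:, 3:8, 4:10] -= 1.2
    res = cluster_perm_tf(x, np.zeros_like(x), n_perm=300, seed=0)
    tcrit = float(sst.t.ppf(1 - 0.025, n - 1))
    T, clu, pv, _ = mne.stats.permutation_cluster_1samp_test(
        x, threshold=tcrit, n_permutations=300, tail=0, seed=0,
        out_type="mask", verbose="error")
    ours = sorted(round(c.mass, 6) for c in res.clusters)
    theirs = sorted(round(float(T[m].sum()), 6) for m in clu)
    assert ours == theirs
    our_sig = {round(c.mass, 6) for c in res.significant}
    their_sig = {round(float(T[m].sum()), 6)
                 for m, p in zip(clu, pv) if p < 0.05}
    assert our_sig == their_sig


# ---------------------------------------------------------------------------
# cluster permutation: electrode space
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def adjacency():
    return electrode_adjacency(CHANNELS_32)


def _channel_effect(rng, targets, n=14, delta=1.0, labels=CHANNELS_32):
    """Paired values identical everywhere except a per-subject shift at
    the target electrodes."""
    base = rng.normal(size=(n, len(labels)))
    a = base.copy()
    for t in targets:
        a[:, labels.index(t)] += delta + 0.2 * rng.standard_normal(n)
    return a, base


def test_cluster_channels_identical_is_empty(adjacency):
    rng = np.random.default_rng(8)
    v = rng.normal(size=(10, 32))
    res = cluster_perm_channels(v, v.copy(), adjacency, n_perm=100, seed=0)
    assert res.clusters == []


def test_cluster_channels_localizes_adjacent_pair(adjacency):
    rng = np.random.default_rng(9)
    a, b = _channel_effect(rng, ("F4", "FC4"))
    res = cluster_perm_channels(a, b, adjacency, n_perm=300, seed=1,
                                labels=CHANNELS_32)
    sig = res.significant
    assert len(sig) == 1
    members = {CHANNELS_32[i] for i in sig[0].bins}
    assert members == {"F4", "FC4"}


def test_cluster_channels_never_merges_non_adjacent(adjacency):
    rng = np.random.default_rng(10)
    for seed in range(10):
        a, b = _channel_effect(rng, ("F4", "O1"))
        res = cluster_perm_channels(a, b, adjacency, n_perm=150, seed=seed,
                                    labels=CHANNELS_32)
        for c in res.clusters:
            members = {CHANNELS_32[i] for i in c.bins}
            assert not {"F4", "O1"} <= members


def test_cluster_channels_unknown_electrode(adjacency):
    rng = np.random.default_rng(11)
    v = rng.normal(size=(5, 2))
    with pytest.raises(KeyError):
        cluster_perm_channels(v, v + 1, adjacency, n_perm=100,
                              labels=("F4", "XX9"))


# ---------------------------------------------------------------------------
# per-second Bonferroni tests
# ---------------------------------------------------------------------------

def test_bonferroni_identical_series_not_significant():
    v = np.tile(np.linspace(2.0, 3.0, 5), (8, 1))
    table = bonferroni_per_second(v, v.copy())
    assert not table["significant"].any()
    assert (table["p_corrected"] == 1.0).all()


def test_bonferroni_selective_sensitivity():
    rng = np.random.default_rng(12)
    n = 14
    a = 2.5 + 0.05 * rng.standard_normal((n, 5))
    b = a + 0.05 * rng.standard_normal((n, 5))
    b[:, 1:4] += 0.5  # separation only at seconds 2-4
    table = bonferroni_per_second(a, b, times=[1, 2, 3, 4, 5])
    assert list(table.loc[table["significant"], "time"]) == [2, 3, 4]


def test_bonferroni_single_second_uncorrected():
    rng = np.random.default_rng(13)
    a = rng.standard_normal((10, 1))
    b = a + 1.0 + 0.1 * rng.standard_normal((10, 1))
    table = bonferroni_per_second(a, b)
    assert table["p_raw"][0] == table["p_corrected"][0]


def test_bonferroni_misaligned_series():
    with pytest.raises(ValueError):
        bonferroni_per_second(np.zeros((4, 5)), np.zeros((4, 4)))


# ---------------------------------------------------------------------------
# summary tables
# ---------------------------------------------------------------------------

def test_summary_table_reproduces_reference_rows():
    table = build_summary_table(as_subject_indices(erd_ami_table()),
                                metrics=("erd", "ami"))
    assert table.loc["Mean", (ATTENTION, "ERD")] == pytest.approx(-1.7700, abs=1e-4)
    assert table.loc["Mean", (ATTENTION, "AMI")] == pytest.approx(-0.0419, abs=1e-4)
    assert table.loc["Mean", (INATTENTION, "ERD")] == pytest.approx(-0.0094, abs=1e-4)
    assert table.loc["Mean", (INATTENTION, "AMI")] == pytest.approx(0.0093, abs=1e-4)
    assert table.loc["SDT", (ATTENTION, "ERD")] == pytest.approx(1.3849, abs=1e-4)
    assert table.loc["r", (ATTENTION, "AMI")] == pytest.approx(0.9641, abs=5e-4)
    assert table.loc["p", (ATTENTION, "AMI")] < 1e-6


def test_summary_table_single_subject():
    rows = [SubjectIndices("S1", ATTENTION, erd=-2.0, ami=-0.05),
            SubjectIndices("S1", INATTENTION, erd=-0.1, ami=0.01)]
    table = build_summary_table(rows, metrics=("erd", "ami"))
    assert table.loc["Mean", (ATTENTION, "ERD")] == -2.0
    assert table.loc["SDT", (ATTENTION, "ERD")] == 0.0
    assert np.isnan(table.loc["r", (ATTENTION, "AMI")])
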