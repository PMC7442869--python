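import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from crowdkit import group_stats as gs
from crowdkit.errors import DomainError, IncompleteDesignError


def long_table(y, factors):
    """Build a tidy frame from tensor y[subject, f1, f2, ...]."""
    names = list(factors)
    rows = []
    for idx in np.ndindex(*y.shape):
        row = {"subject_id": f"S{idx[0]}"}
        for name, lev in zip(names, idx[1:]):
            row[name] = f"{name}{lev}"
        row["value"] = y[idx]
        rows.append(row)
    return pd.DataFrame(rows)


class TestPairedT:
    def test_identical_inputs_flagged(self):
        res = gs.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.undefined
        assert res.t == 0.0

    def test_hand_arithmetic(self):
        # d = (1, 2, 3): t = 2 / (1 / sqrt(3))
        res = gs.paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(2.0 * math.sqrt(3.0), abs=1e-12)
        assert res.df == 2

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=10), rng.normal(size=10)
        res = gs.paired_t(x, y)
        ref = sps.ttest_rel(x, y)
        assert res.t == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_p_matches_sign_flip_permutation(self):
        # permutation oracle: 1e5 random sign flips of the differences
        rng = np.random.default_rng(7)
        d = rng.normal(0.4, 1.0, size=15)
        res = gs.paired_t(d, np.zeros_like(d))
        signs = rng.choice([-1.0, 1.0], size=(100_000, len(d)))
        flipped = signs * d
        t_perm = flipped.mean(axis=1) / (
            flipped.std(axis=1, ddof=1) / math.sqrt(len(d))
        )
        p_perm = np.mean(np.abs(t_perm) >= abs(res.t))
        assert abs(res.p - p_perm) < 0.02

    def test_too_short(self):
        with pytest.raises(DomainError):
            gs.paired_t([1.0, 2.0], [0.0, 1.0])


def projection_anova_oracle(y, effect_axes):
    """Independent linear-algebra oracle for the within-subject ANOVA.

    y has shape (subjects, l1, ..., lk).  The SS of an effect is
    ||P y||^2 with P a Kronecker product of centering matrices (factor in
    the effect), averaging matrices (factor not in it, and the subject
    axis), and the error term uses the centering matrix on subjects.
    """
    def centerer(m):
        return np.eye(m) - np.ones((m, m)) / m

    def averager(m):
        return np.ones((m, m)) / m

    dims = y.shape
    flat = y.reshape(-1)

    def ss(projs):
        p = projs[0]
        for q in projs[1:]:
            p = np.kron(p, q)
        v = p @ flat
        return float(v @ v)

    eff_projs = [averager(dims[0])] + [
        centerer(dims[ax]) if ax in effect_axes else averager(dims[ax])
        for ax in range(1, len(dims))
    ]
    err_projs = [centerer(dims[0])] + eff_projs[1:]
    df_num = int(np.prod([dims[ax] - 1 for ax in effect_axes]))
    df_den = df_num * (dims[0] - 1)
    f = (ss(eff_projs) / df_num) / (ss(err_projs) / df_den)
    return f, df_num, df_den


class TestRmAnova:
    def test_two_level_factor_equals_paired_t_squared(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(9, 2))
        table = long_table(y, ["cond"])
        res = gs.rm_anova(table, "value", within=["cond"])
        t = gs.paired_t(y[:, 0], y[:, 1])
        eff = res["cond"]
        assert eff.f == pytest.approx(t.t**2, rel=1e-10)
        assert eff.p == pytest.approx(t.p, rel=1e-10)
        assert (eff.df_num, eff.df_den) == (1, 8)

    def test_constant_data_flagged(self):
        y = np.full((6, 2, 2), 3.14)
        res = gs.rm_anova(long_table(y, ["a", "b"]), "value", within=["a", "b"])
        for eff in res.effects.values():
            assert eff.undefined
            assert eff.f == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_projection_oracle_2x2x2(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=(6, 2, 2, 2))
        table = long_table(y, ["a", "b", "c"])
        res = gs.rm_anova(table, "value", within=["a", "b", "c"])
        axes_by_name = {"a": 1, "b": 2, "c": 3}
        for r in range(1, 4):
            for combo in itertools.combinations("abc", r):
                f_ref, dfn, dfd = projection_anova_oracle(
                    y, tuple(axes_by_name[f] for f in combo)
                )
                eff = res["*".join(combo)]
                assert eff.f == pytest.approx(f_ref, rel=1e-8), combo
                assert (eff.df_num, eff.df_den) == (dfn, dfd)

    def test_matches_projection_oracle_2x4(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=(17, 2, 4))
        res = gs.rm_anova(long_table(y, ["axis", "day"]), "value",
                          within=["axis", "day"])
        for combo, axes in (("axis", (1,)), ("day", (2,)), ("axis*day", (1, 2))):
            f_ref, dfn, dfd = projection_anova_oracle(y, axes)
            eff = res[combo]
            assert eff.f == pytest.approx(f_ref, rel=1e-8)
            assert (eff.df_num, eff.df_den) == (dfn, dfd)
        # the study design's dfs
        assert res["day"].df_num == 3 and res["day"].df_den == 48
        assert res["axis"].df_num == 1 and res["axis"].df_den == 16

    def test_missing_cell_reported(self):
        y = np.random.default_rng(0).normal(size=(5, 2))
        table = long_table(y, ["cond"]).iloc[:-1]
        with pytest.raises(IncompleteDesignError, match="missing"):
            gs.rm_anova(table, "value", within=["cond"])

    def test_duplicate_cell_reported(self):
        y = np.random.default_rng(0).normal(size=(5, 2))
        table = long_table(y, ["cond"])
        table = pd.concat([table, table.iloc[[0]]])
        with pytest.raises(IncompleteDesignError, match="duplicated"):
            gs.rm_anova(table, "value", within=["cond"])

    def test_gg_correction_reduces_significance(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(8, 4))
        table = long_table(y, ["day"])
        plain = gs.rm_anova(table, "value", within=["day"])
        gg = gs.rm_anova(table, "value", within=["day"],
                         sphericity_correction="gg")
        assert gg["day"].gg_epsilon is not None
        assert 1 / 3 <= gg["day"].gg_epsilon <= 1.0
        assert gg["day"].p >= plain["day"].p - 1e-12

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        y = rng.normal(size=(10, 2, 4))
        table = long_table(y, ["axis", "day"])
        mine = gs.rm_anova(table, "value", within=["axis", "day"],
                           sphericity_correction="gg")
        ref = pg.rm_anova(data=table, dv="value", within=["axis", "day"],
                          subject="subject_id", detailed=True)
        ref = ref.set_index("Source")
        for eff, src in (("axis", "axis"), ("day", "day"), ("axis*day", "axis * day")):
            assert mine[eff].f == pytest.approx(ref.loc[src, "F"], rel=1e-9)
            if mine[eff].gg_epsilon is not None:
                assert mine[eff].gg_epsilon == pytest.approx(
                    ref.loc[src, "eps"], rel=1e-9
                )

    def test_null_p_uniform(self):
        # 1000 null replicates; KS test against uniform at alpha = 0.01
        rng = np.random.default_rng(123)
        ps = []
        for _ in range(1000):
            y = rng.normal(size=(8, 3))
            ps.append(gs.rm_anova(long_table(y, ["cond"]), "value",
                                  within=["cond"])["cond"].p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestSpearman:
    def test_monotone_perfect(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 11.0])
        res = gs.spearman(x, x**2)
        assert res.rs == pytest.approx(1.0)
        rev = gs.spearman(x, -x)
        assert rev.rs == pytest.approx(-1.0)

    def test_constant_input_flagged(self):
        res = gs.spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert res.undefined

    def test_ties_match_bruteforce_oracle_n6(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0])
        res = gs.spearman(x, y)
        # independent oracle: Pearson of midranks + exhaustive permutations
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        rs_ref = np.corrcoef(rx, ry)[0, 1]
        assert res.rs == pytest.approx(rs_ref, abs=1e-12)
        count = 0
        perms = list(itertools.permutations(range(6)))
        for perm in perms:
            rs_p = np.corrcoef(rx, ry[list(perm)])[0, 1]
            if abs(rs_p) >= abs(rs_ref) - 1e-12:
                count += 1
        assert res.method == "exact"
        assert res.p == pytest.approx(count / len(perms), abs=1e-12)

    def test_t_approx_matches_permutation(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=14)
        y = 0.6 * x + rng.normal(size=14)
        res = gs.spearman(x, y)
        assert res.method == "t-approx"
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        hits = 0
        n_mc = 20000
        for _ in range(n_mc):
            rs_p = np.corrcoef(rx, rng.permutation(ry))[0, 1]
            if abs(rs_p) >= abs(res.rs) - 1e-12:
                hits += 1
        p_perm = hits / n_mc
        assert abs(res.p - p_perm) < 0.03 + 3 * math.sqrt(p_perm * (1 - p_perm) / n_mc)

    def test_matches_scipy_rs(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = gs.spearman(x, y)
        assert res.rs == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        base = gs.spearman(x, y)
        trans = gs.spearman(np.exp(x), 2.0 * y**3 + 1.0)
        assert trans.rs == pytest.approx(base.rs, abs=1e-12)
        assert trans.p == pytest.approx(base.p, abs=1e-12)

    def test_too_short(self):
        with pytest.raises(DomainError):
            gs.spearman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestPairedTNullUniformity:
    def test_null_p_uniform(self):
        rng = np.random.default_rng(1)
        ps = [
            gs.paired_t(rng.normal(size=12), rng.normal(size=12)).p
            for _ in range(1000)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestAnisotropyChangeCorrelation:
    def test_identity_gives_rs_one(self):
        vals = {f"S{i}": float(v) for i, v in enumerate([0.1, -0.2, 0.3, 0.05, -0.4])}
        res = gs.anisotropy_change_correlation(vals, vals)
        assert res.rs == pytest.approx(1.0)

    def test_subject_mismatch_rejected(self):
        a = {"S1": 0.1, "S2": 0.2, "S3": 0.3, "S4": 0.4}
        b = {"S1": 0.1, "S2": 0.2, "S3": 0.3, "S5": 0.4}
        with pytest.raises(DomainError, match="S5"):
            gs.anisotropy_change_correlation(a, b)

    def test_standardization_does_not_change_rs(self):
        rng = np.random.default_rng(2)
        a = {f"S{i}": float(rng.normal()) for i in range(10)}
        b = {f"S{i}": float(rng.normal()) for i in range(10)}
        res = gs.anisotropy_change_correlation(a, b)
        order = sorted(a)
        raw = gs.spearman([a[s] for s in order], [b[s] for s in order])
        assert res.rs == pytest.approx(raw.rs, abs=1e-12)
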