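import numpy as np
import pandas as pd
import pytest

from rtmconform.stats import (
    cell_means_table,
    holm_pairwise,
    one_sample_t,
    paired_t,
    pearson_between_participants,
    rm_anova_mixed,
    two_sample_t,
)


def toy_cells(n=8, k=3, seed=3, shift=(0.0, 0.4, 0.9)):
    rng = np.random.default_rng(seed)
    Y = rng.normal(size=(n, k)) + np.asarray(shift)
    return pd.DataFrame(Y, index=[f"p{i}" for i in range(n)],
                        columns=[f"c{j}" for j in range(k)])


def holm_stepdown(pvals):
    """Direct evaluation of the step-down rule: sort ascending,
    p_(i) <- max_{j<=i} (m-j+1) p_(j), capped at 1."""
    p = np.asarray(pvals, float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


class TestMixedAnova:
    def test_against_pingouin_mixed(self):
        pg = pytest.importorskip("pingouin")
        cells = toy_cells()
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=cells.index)
        res = rm_anova_mixed(cells, groups)
        long = cells.reset_index().melt(
            id_vars="index", var_name="cond", value_name="y"
        ).rename(columns={"index": "subj"})
        long["grp"] = long.subj.map(groups)
        ref = pg.mixed_anova(long, dv="y", within="cond", subject="subj",
                             between="grp", effsize="ng2").set_index("Source")
        assert res.effects["deviation"].F == pytest.approx(ref.loc["cond", "F"])
        assert res.effects["group"].F == pytest.approx(ref.loc["grp", "F"])
        assert res.effects["deviation_x_group"].F == pytest.approx(
            ref.loc["Interaction", "F"]
        )
        for mine, theirs in [("deviation", "cond"), ("group", "grp"),
                             ("deviation_x_group", "Interaction")]:
            assert res.effects[mine].eta2_G == pytest.approx(
                ref.loc[theirs, "ng2"], rel=1e-9
            )
            assert res.effects[mine].p_uncorrected == pytest.approx(
                ref.loc[theirs, "p_unc"], rel=1e-9
            )

    def test_against_pingouin_single_group(self):
        pg = pytest.importorskip("pingouin")
        cells = toy_cells(n=9, seed=6)
        res = rm_anova_mixed(cells)
        long = cells.reset_index().melt(
            id_vars="index", var_name="cond", value_name="y"
        ).rename(columns={"index": "subj"})
        ref = pg.rm_anova(long, dv="y", within="cond", subject="subj",
                          correction=True, effsize="ng2", detailed=True)
        row = ref.set_index("Source").loc["cond"]
        assert res.effects["deviation"].F == pytest.approx(row["F"])
        assert res.effects["deviation"].eta2_G == pytest.approx(row["ng2"], rel=1e-9)
        sph = pg.sphericity(long, dv="y", within="cond", subject="subj")
        assert res.sphericity.mauchly_w == pytest.approx(sph.W, rel=1e-9)
        assert res.sphericity.p == pytest.approx(sph.pval, rel=1e-9)
        assert res.sphericity.epsilon_gg == pytest.approx(
            pg.epsilon(long, dv="y", within="cond", subject="subj", correction="gg"),
            rel=1e-9,
        )
        assert res.sphericity.epsilon_hf == pytest.approx(
            pg.epsilon(long, dv="y", within="cond", subject="subj", correction="hf"),
            rel=1e-9,
        )

    def test_inline_sums_of_squares_oracle(self):
        # independent raw SS evaluation on a 6-participant, 2-group table
        cells = toy_cells(n=6, seed=12)
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=cells.index)
        res = rm_anova_mixed(cells, groups)
        Y = cells.to_numpy()
        grand = Y.mean()
        ss_cond = 6 * ((Y.mean(0) - grand) ** 2).sum()
        ss_err_w = 0.0
        cellm = {g: Y[np.asarray(groups) == g].mean(0) for g in ("a", "b")}
        gm = {g: Y[np.asarray(groups) == g].mean() for g in ("a", "b")}
        ss_int = 3 * sum(
            ((cellm[g] - gm[g] - Y.mean(0) + grand) ** 2).sum() for g in ("a", "b")
        )
        for i, row in enumerate(Y):
            g = groups.iloc[i]
            ss_err_w += (
                (row - row.mean() - cellm[g] + gm[g]) ** 2
            ).sum()
        F_cond = (ss_cond / 2) / (ss_err_w / 8)
        assert res.effects["deviation"].F == pytest.approx(F_cond, rel=1e-9)
        assert res.effects["deviation_x_group"].F == pytest.approx(
            (ss_int / 2) / (ss_err_w / 8), rel=1e-9
        )

    def test_no_within_variance_gives_zero_F(self):
        cells = pd.DataFrame(
            {"c1": [1.0, 2.0, 3.0], "c2": [1.0, 2.0, 3.0], "c3": [1.0, 2.0, 3.0]}
        )
        res = rm_anova_mixed(cells)
        assert res.effects["deviation"].F == 0.0
        assert res.effects["deviation"].eta2_G == 0.0

    def test_exact_sphericity_gives_W_one(self):
        # construct contrast scores with exactly identity covariance,
        # then map them back through the orthonormal contrast basis
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(12, 2))
        Z -= Z.mean(0)
        L = np.linalg.cholesky(np.cov(Z, rowvar=False))
        Z = Z @ np.linalg.inv(L).T  # sample covariance exactly I
        C = np.linalg.qr(np.vstack([np.ones(3), np.eye(3)[:2]]).T)[0][:, 1:].T
        cells = pd.DataFrame(Z @ C, columns=["c1", "c2", "c3"])
        res = rm_anova_mixed(cells)
        assert res.sphericity.mauchly_w == pytest.approx(1.0, abs=1e-9)
        assert res.sphericity.epsilon_gg == pytest.approx(1.0, abs=1e-9)
        assert not res.sphericity.correction_applied

    def test_epsilon_bounds_random_tables(self):
        for seed in range(20):
            res = rm_anova_mixed(toy_cells(n=10, seed=seed))
            s = res.sphericity
            assert 0.5 - 1e-12 <= s.epsilon_gg <= 1.0 + 1e-12
            assert s.epsilon_hf >= s.epsilon_gg - 1e-12
            assert s.epsilon_hf <= 1.0
            assert 0.0 < s.mauchly_w <= 1.0

    def test_single_group_has_no_between_rows(self):
        res = rm_anova_mixed(toy_cells())
        assert set(res.effects) == {"deviation"}

    def test_missing_cell_rejected(self, default_items):
        broken = default_items[
            ~((default_items.participant_id == "c01")
              & (default_items.condition == "peers_equal"))
        ]
        with pytest.raises(ValueError):
            cell_means_table(broken, "c")


class TestHolm:
    def test_stepdown_worked_example(self):
        assert np.allclose(holm_stepdown([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04])

    def test_pairwise_matches_stepdown_rule(self):
        cells = toy_cells(n=10, seed=1)
        out = holm_pairwise(cells)
        assert len(out) == 3
        assert np.allclose(out.p_holm, holm_stepdown(out.p_raw), atol=1e-12)

    def test_all_ones_capped(self):
        assert np.allclose(holm_stepdown([1.0, 1.0, 1.0]), 1.0)

    def test_single_pair_unadjusted(self):
        cells = toy_cells(n=6, k=2, seed=2, shift=(0.0, 0.5))
        out = holm_pairwise(cells)
        assert len(out) == 1
        assert out.p_holm[0] == pytest.approx(out.p_raw[0])


class TestTTests:
    def test_one_sample_symmetric(self):
        res = one_sample_t([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert res.t == 0.0
        assert res.cohens_d == 0.0

    def test_one_sample_hand_computed(self):
        x = np.array([0.3, 0.1, 0.4, 0.15, 0.25])
        res = one_sample_t(x)
        mean, sd = x.mean(), x.std(ddof=1)
        assert res.t == pytest.approx(mean / (sd / np.sqrt(5)))
        assert res.cohens_d == pytest.approx(mean / sd)
        assert res.df == 4

    def test_shift_by_constant_d_identity(self):
        x = np.array([1.0, 2.0, 3.0])
        res = one_sample_t(x + 5.0, mu0=5.0)
        assert res.cohens_d == pytest.approx(x.mean() / x.std(ddof=1))

    def test_two_sample_identical_groups(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.df == 4

    def test_two_sample_translation_equivariance(self):
        a = np.array([1.0, 2.5, 3.0])
        b = np.array([0.5, 1.0, 2.0])
        base = two_sample_t(a, b)
        shifted = two_sample_t(a + 0.7, b)
        assert shifted.mean_difference == pytest.approx(base.mean_difference + 0.7)

    def test_two_sample_hand_computed_pooled(self):
        a = np.array([3.0, 4.0, 5.0])
        b = np.array([1.0, 2.0, 6.0])
        res = two_sample_t(a, b)
        sp2 = (a.var(ddof=1) + b.var(ddof=1)) / 2
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert res.t == pytest.approx(t)
        assert res.df == 4
        assert res.cohens_d == pytest.approx((a.mean() - b.mean()) / np.sqrt(sp2))

    def test_paired_reduces_to_one_sample_on_differences(self):
        a = np.array([1.0, 2.0, 3.5, 2.2])
        b = np.array([0.5, 2.5, 2.0, 1.0])
        assert paired_t(a, b) == one_sample_t(a - b)

    def test_paired_identical_is_null(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == 1.0

    def test_paired_constant_offset_degenerate(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [1.5, 2.5, 3.5])

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([2.0, 2.0, 2.0], mu0=0.0)
        with pytest.raises(ValueError):
            two_sample_t([1.0, 1.0], [1.0, 1.0])


class TestPearson:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_between_participants(x, x)["r"] == pytest.approx(1.0)
        assert pearson_between_participants(x, [-v for v in x])["r"] == pytest.approx(-1.0)

    def test_hand_computed(self):
        x = np.array([0.1, 0.5, 0.2, 0.9, 0.4])
        y = np.array([0.2, 0.4, 0.1, 0.8, 0.6])
        out = pearson_between_participants(x, y)
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert out["r"] == pytest.approx(num / den)
        assert out["df"] == 3

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_between_participants([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
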