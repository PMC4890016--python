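"""Group statistics: class-wise FDR t-tests, mixed ANOVAs, bootstrap LI."""

import numpy as np
import pytest
from scipy import stats

from facedcm.groupstats import (
    ParameterClass,
    bootstrap_li,
    mixed_anova_2x2,
    mixed_anova_3way,
    ttest_and_fdr,
)


def brute_force_bh(pvals, alpha=0.05):
    """Benjamini-Hochberg by direct definition."""
    p = np.asarray(pvals)
    order = np.argsort(p)
    m = len(p)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank / m * alpha:
            k_max = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


class TestTtestFdr:
    def test_rejections_match_brute_force_bh(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            x = r.standard_normal((12, 9)) + np.linspace(0, 1.2, 9)
            classes = [ParameterClass("c1", [0, 1, 2, 3]),
                       ParameterClass("c2", [4, 5, 6, 7, 8])]
            tab = ttest_and_fdr(x, classes)
            for c in classes:
                expected = brute_force_bh(tab["p"].values[c.members])
                np.testing.assert_array_equal(
                    tab["significant"].values[c.members], expected)

    def test_equal_pvalues_all_pass_together(self, rng):
        # BH with equal p-values accepts all of them iff p <= alpha
        x = np.tile(rng.standard_normal(12)[:, None], (1, 10)) + 1.0
        tab = ttest_and_fdr(x, [ParameterClass("all", list(range(10)))])
        assert tab["p"].nunique() == 1
        assert tab["significant"].all() == (tab["p"].iloc[0] <= 0.05)

    def test_single_member_classes_reduce_to_uncorrected(self, rng):
        x = rng.standard_normal((15, 4)) + 0.6
        classes = [ParameterClass(f"c{i}", [i]) for i in range(4)]
        tab = ttest_and_fdr(x, classes)
        np.testing.assert_allclose(tab["p_fdr"], tab["p"])

    def test_two_sample_null_type_one_rate(self):
        # identical-distribution groups: after correction, most null
        # simulations show no significant parameter
        clean = 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            a, b = r.standard_normal((2, 10, 6))
            tab = ttest_and_fdr(a, [ParameterClass("all", list(range(6)))],
                                mode="two-sample", values2=b)
            clean += not tab["significant"].any()
        assert clean >= 0.95 * 200 * 0.9   # allow binomial slack around 95%

    def test_zero_variance_flagged_not_tested(self):
        x = np.ones((8, 2))
        x[:, 1] = np.random.default_rng(0).standard_normal(8)
        tab = ttest_and_fdr(x, [ParameterClass("all", [0, 1])])
        assert not tab["tested"].iloc[0]
        assert tab["tested"].iloc[1]

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            ttest_and_fdr(np.zeros((2, 3)), [ParameterClass("all", [0])])


def anova2_oracle(data, group):
    """Split-plot 2x2 oracle: between effect as a one-way ANOVA on subject
    means, interaction as a two-sample t-test on within-difference scores."""
    levels = np.unique(group)
    m = data.mean(axis=1)
    d = data[:, 1] - data[:, 0]
    f_g, _ = stats.f_oneway(m[group == levels[0]], m[group == levels[1]])
    t_int, _ = stats.ttest_ind(d[group == levels[0]], d[group == levels[1]])
    return f_g, t_int ** 2


class TestMixedAnova2x2:
    def test_pure_group_main_effect_no_interaction(self, rng):
        base = rng.standard_normal((12, 2))
        group = np.array(["a"] * 6 + ["b"] * 6)
        data = base + np.where(group == "a", 2.0, 0.0)[:, None]
        tab = mixed_anova_2x2(data, group)
        base_tab = mixed_anova_2x2(base, group)
        assert tab.loc["group x within", "F"] == pytest.approx(
            base_tab.loc["group x within", "F"], abs=1e-9)

    def test_matches_sums_of_squares_oracle(self, rng):
        data = rng.standard_normal((8, 2))
        group = np.array(["a", "a", "a", "a", "b", "b", "b", "b"])
        tab = mixed_anova_2x2(data, group)
        f_g, f_int = anova2_oracle(data, group)
        assert tab.loc["group", "F"] == pytest.approx(f_g, rel=1e-10)
        assert tab.loc["group x within", "F"] == pytest.approx(f_int,
                                                               rel=1e-10)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        data = rng.standard_normal((10, 2)) + [0.3, -0.2]
        group = np.array(["a"] * 5 + ["b"] * 5)
        tab = mixed_anova_2x2(data, group)
        long = pd.DataFrame({
            "y": data.ravel(),
            "within": ["w1", "w2"] * 10,
            "subject": np.repeat(np.arange(10), 2),
            "group": np.repeat(group, 2),
        })
        ref = pg.mixed_anova(long, dv="y", within="within", subject="subject",
                             between="group").set_index("Source")
        assert tab.loc["group", "F"] == pytest.approx(ref.loc["group", "F"],
                                                      rel=1e-8)
        assert tab.loc["within", "F"] == pytest.approx(ref.loc["within", "F"],
                                                       rel=1e-8)
        assert tab.loc["group x within", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-8)

    def test_group_relabeling_invariance(self, rng):
        data = rng.standard_normal((10, 2))
        group = np.array(["a"] * 5 + ["b"] * 5)
        flipped = np.where(group == "a", "b", "a")
        t1 = mixed_anova_2x2(data, group)
        t2 = mixed_anova_2x2(data, flipped)
        np.testing.assert_allclose(t1["F"], t2["F"], rtol=1e-10)

    def test_interaction_df(self, rng):
        tab = mixed_anova_2x2(rng.standard_normal((14, 2)),
                              np.repeat(["a", "b"], 7))
        assert tab.loc["group x within", "df1"] == 1
        assert tab.loc["group x within", "df2"] == 12

    def test_missing_cells_rejected(self):
        data = np.ones((6, 2)); data[0, 0] = np.nan
        with pytest.raises(ValueError):
            mixed_anova_2x2(data, np.repeat(["a", "b"], 3))


class TestMixedAnova3way:
    def test_location_invariance(self, rng):
        data = rng.standard_normal((10, 3, 2))
        group = np.repeat(["a", "b"], 5)
        t1 = mixed_anova_3way(data, group)
        t2 = mixed_anova_3way(data + 11.0, group)
        np.testing.assert_allclose(t1["F"], t2["F"], rtol=1e-9)

    def test_null_type_one_rates(self):
        # pure-noise data: each effect's empirical rejection rate ~ alpha
        counts = None
        n_sim = 500
        for seed in range(n_sim):
            r = np.random.default_rng(10_000 + seed)
            tab = mixed_anova_3way(r.standard_normal((12, 3, 2)),
                                   np.repeat(["a", "b"], 6))
            rej = (tab["p"] < 0.05).astype(int)
            counts = rej if counts is None else counts + rej
        rates = counts / n_sim
        assert np.all(np.abs(rates - 0.05) <= 0.03), rates.to_dict()

    def test_injected_interaction_dominates(self):
        # a pure group x stimulus effect: that interaction is detected more
        # often than a hemifield main effect
        hits_int, hits_hemi = 0, 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            data = r.standard_normal((20, 3, 2))
            group = np.repeat(["a", "b"], 10)
            effect = np.array([1.0, 0.0, -1.0]) * 0.8
            data[group == "a"] += effect[None, :, None]
            tab = mixed_anova_3way(data, group)
            hits_int += tab.loc["group x stimulus", "p"] < 0.05
            hits_hemi += tab.loc["hemifield", "p"] < 0.05
        assert hits_int > hits_hemi

    def test_matches_r_aov_strata(self, tmp_path, rng):
        # independent oracle: R's aov with Error(subject/(A*B)) strata
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        data = np.round(rng.standard_normal((8, 3, 2)), 6)
        group = np.repeat(["g1", "g2"], 4)
        rows = []
        for s in range(8):
            for i in range(3):
                for j in range(2):
                    rows.append(f"{s},{group[s]},s{i},h{j},{data[s, i, j]}")
        csv = tmp_path / "d.csv"
        csv.write_text("subject,group,A,B,y\n" + "\n".join(rows) + "\n")
        rscript = tmp_path / "aov.R"
        rscript.write_text(
            'd <- read.csv("%s")\n'
            "d$subject <- factor(d$subject); d$group <- factor(d$group)\n"
            "d$A <- factor(d$A); d$B <- factor(d$B)\n"
            "m <- aov(y ~ group*A*B + Error(subject/(A*B)), data=d)\n"
            "s <- summary(m)\n"
            "for (strat in s) { tab <- strat[[1]];"
            " for (r in rownames(tab)) {"
            ' if (!is.na(tab[r, "F value"]))'
            ' cat(trimws(r), tab[r, "F value"], "\\n") } }\n'
            % csv
        )
        out = subprocess.run(["Rscript", str(rscript)], capture_output=True,
                             text=True, check=True).stdout
        ref = {}
        for line in out.strip().splitlines():
            toks = line.split()
            if len(toks) >= 2:
                ref[" ".join(toks[:-1])] = float(toks[-1])
        tab = mixed_anova_3way(data, group)
        mapping = {
            "group": "group", "A": "stimulus", "B": "hemifield",
            "group:A": "group x stimulus", "group:B": "group x hemifield",
            "A:B": "stimulus x hemifield",
            "group:A:B": "group x stimulus x hemifield",
        }
        for rname, mine in mapping.items():
            assert tab.loc[mine, "F"] == pytest.approx(ref[rname], rel=1e-6), rname

    def test_unequal_groups_rejected(self):
        with pytest.raises(ValueError):
            mixed_anova_3way(np.zeros((7, 3, 2)),
                             np.array(["a"] * 3 + ["b"] * 4))


class TestBootstrapLI:
    def test_full_right_dominance(self):
        res = bootstrap_li(np.array([0.01]), np.array([2.0, 3.0]),
                           threshold=1.0, seed=0)
        assert res.li == -1.0

    def test_identical_sides_symmetric(self, rng):
        v = np.abs(rng.standard_normal(50)) + 1.0
        res = bootstrap_li(v, v.copy(), threshold=0.0, seed=1)
        assert res.li == pytest.approx(0.0, abs=0.01)

    def test_degenerate_three_to_one_ratio(self):
        left = np.full(30, 3.0)
        right = np.full(30, 1.0)
        res = bootstrap_li(left, right, threshold=0.0, seed=2)
        assert res.li == pytest.approx(0.5, abs=1e-12)

    def test_antisymmetry(self, rng):
        left = np.abs(rng.standard_normal(40)) + 0.5
        right = np.abs(rng.standard_normal(40)) + 1.0
        a = bootstrap_li(left, right, threshold=0.0, seed=3)
        b = bootstrap_li(right, left, threshold=0.0, seed=3)
        assert a.li == pytest.approx(-b.li, abs=0.02)

    def test_li_bounds_and_ci(self, rng):
        left = np.abs(rng.standard_normal(30)) + 0.2
        right = np.abs(rng.standard_normal(30)) + 0.2
        res = bootstrap_li(left, right, threshold=0.0, seed=4)
        assert -1.0 <= res.li <= 1.0
        assert res.ci[0] <= res.li <= res.ci[1]

    def test_default_threshold_half_max(self):
        left = np.array([10.0, 0.1, 0.2])
        right = np.array([4.0, 0.3])
        res = bootstrap_li(left, right, seed=5)
        assert res.threshold == pytest.approx(5.0)
        assert res.li == 1.0      # only the left 10.0 survives

    def test_both_sides_empty_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_li(np.array([]), np.array([]))
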