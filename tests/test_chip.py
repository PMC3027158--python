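"""Two-channel analysis: ratios, normalization, filters, tests, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from medip_tile import chip
from medip_tile.chip import (
    AnalysisParams,
    NormalizedMatrix,
    compute_ratios,
    differential_table,
    expression_overlap,
    filter_probes,
    median_classes,
    normalize_to_control,
    pca_scores,
    probe_to_gene,
    term_enrichment,
    welch_test,
)
from medip_tile.datasets import load_hcc_concordance
from medip_tile.probes import ArrayDesign, Probe
from medip_tile.synthetic import (
    MethylationParams,
    SignalModel,
    default_groups,
    flat_design,
    flat_truth_islands,
    make_methylation,
    simulate_array,
)


def _channels(values: dict[str, dict[str, tuple[float, float, bool]]], groups: dict[str, str]):
    """Long channel table from {probe: {sample: (cy3, cy5, present)}}."""
    rows = []
    for probe, per_sample in values.items():
        for sample, (cy3, cy5, present) in per_sample.items():
            rows.append(
                {"sample_id": sample, "group": groups[sample], "probe_id": probe,
                 "cy3": cy3, "cy5": cy5, "present": present}
            )
    return pd.DataFrame(rows)


class TestRatiosAndNormalization:
    def test_ratio_values(self):
        groups = {"s1": "control", "s2": "control"}
        ch = _channels({"p1": {"s1": (50, 100, True), "s2": (80, 80, True)}}, groups)
        raw = compute_ratios(ch)
        assert raw.loc["p1", "s1"] == 2.0
        assert raw.loc["p1", "s2"] == 1.0

    def test_nonpositive_cy3_marked_invalid(self):
        groups = {"s1": "control", "s2": "control"}
        ch = _channels({"p1": {"s1": (0, 100, True), "s2": (10, 100, True)}}, groups)
        raw = compute_ratios(ch)
        assert np.isnan(raw.loc["p1", "s1"]) and raw.loc["p1", "s2"] == 10.0

    def test_control_self_normalization(self):
        groups = {f"c{i}": "control" for i in range(4)}
        ch = _channels({"p1": {f"c{i}": (1, 2, True) for i in range(4)}}, groups)
        mat = normalize_to_control(compute_ratios(ch), pd.Series(groups))
        assert (mat.ratios.loc["p1"] == 1.0).all()

    def test_tumor_ratio_relative_to_control_mean(self):
        groups = {"c1": "control", "c2": "control", "t1": "tumor"}
        ch = _channels(
            {"p1": {"c1": (1, 2, True), "c2": (1, 2, True), "t1": (1, 4, True)}}, groups
        )
        mat = normalize_to_control(compute_ratios(ch), pd.Series(groups))
        assert mat.ratios.loc["p1", "t1"] == 2.0

    def test_control_means_exactly_one_on_random_table(self):
        rng = np.random.default_rng(0)
        groups = dict(default_groups())
        probes = [f"p{i}" for i in range(50)]
        vals = {
            p: {s: (rng.uniform(1, 5), rng.uniform(1, 500), True) for s in groups}
            for p in probes
        }
        mat = normalize_to_control(compute_ratios(_channels(vals, groups)), pd.Series(groups))
        controls = mat.samples_in("control")
        np.testing.assert_allclose(mat.ratios[controls].mean(axis=1), 1.0, rtol=1e-12)

    def test_positive_negative_excluded_from_reference(self):
        groups = {"c1": "control", "c2": "control", "pos": "positive"}
        ch = _channels(
            {"p1": {"c1": (1, 2, True), "c2": (1, 2, True), "pos": (1, 1000, True)}}, groups
        )
        mat = normalize_to_control(compute_ratios(ch), pd.Series(groups))
        assert (mat.ratios.loc["p1", ["c1", "c2"]] == 1.0).all()


class TestFilters:
    def _setup(self, n_present=10, cy5=100.0, tumor_vals=None):
        groups = dict(default_groups())  # 4C + 4T + POS + NEG = 10 samples
        samples = list(groups)
        vals = {"p1": {}}
        for i, s in enumerate(samples):
            present = i < n_present
            vals["p1"][s] = (1.0, cy5, present)
        if tumor_vals:
            for s, v in tumor_vals.items():
                vals["p1"][s] = v
        ch = _channels(vals, groups)
        mat = normalize_to_control(compute_ratios(ch), pd.Series(groups))
        return mat, ch

    def test_present_in_3_of_10_removed(self):
        mat, ch = self._setup(n_present=3)
        filtered, audit = filter_probes(mat, ch)
        assert audit["removed_presence"] == 1 and len(filtered.ratios) == 0
        assert filtered.filter_status["p1"] == "removed:presence"

    def test_present_in_4_of_10_kept(self):
        mat, ch = self._setup(n_present=4)
        filtered, audit = filter_probes(mat, ch)
        assert audit["retained"] == 1

    def test_low_intensity_removed(self):
        mat, ch = self._setup(cy5=24.0)
        _, audit = filter_probes(mat, ch)
        assert audit["removed_intensity"] == 1

    def test_high_group_sd_removed(self):
        groups = dict(default_groups())
        tumor = {"T1": (1.0, 10.0, True), "T2": (1.0, 400.0, True),
                 "T3": (1.0, 10.0, True), "T4": (1.0, 400.0, True)}
        mat, ch = self._setup(tumor_vals=tumor)
        _, audit = filter_probes(mat, ch)
        assert audit["removed_sd"] == 1


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert t == 0.0 and p == 1.0

    def test_constant_equal_groups_convention(self):
        t, df, p = welch_test([2, 2, 2], [2, 2, 2])
        assert (t, p) == (0.0, 1.0)

    def test_hand_formula_oracle(self):
        a = np.array([1.1, 0.9, 1.0, 1.0])
        b = np.array([2.1, 1.9, 2.0, 2.0])
        se2 = a.var(ddof=1) / 4 + b.var(ddof=1) / 4
        t_hand = (a.mean() - b.mean()) / math.sqrt(se2)
        df_hand = se2**2 / (
            (a.var(ddof=1) / 4) ** 2 / 3 + (b.var(ddof=1) / 4) ** 2 / 3
        )
        p_hand = 2 * stats.t.sf(abs(t_hand), df_hand)
        t, df, p = welch_test(a, b)
        assert abs(t - t_hand) < 1e-12 and abs(df - df_hand) < 1e-12 and abs(p - p_hand) < 1e-12

    def test_antisymmetry(self):
        a, b = [1.0, 1.2, 0.8, 1.1], [2.0, 2.1, 1.9, 2.2]
        t1, _, p1 = welch_test(a, b)
        t2, _, p2 = welch_test(b, a)
        assert t1 == -t2 and p1 == p2

    def test_matches_scipy_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            na, nb = rng.integers(2, 12, size=2)
            a = rng.normal(0, rng.uniform(0.5, 2), na)
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), nb)
            t, df, p = welch_test(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert abs(t - ref.statistic) < 1e-10
            assert abs(df - ref.df) < 1e-10
            assert abs(p - ref.pvalue) < 1e-10

    def test_group_too_small_raises(self):
        with pytest.raises(ValueError):
            welch_test([1.0], [1.0, 2.0])


class TestDifferential:
    def _matrix(self, tumor, control):
        data = {}
        for i, v in enumerate(control):
            data[f"c{i}"] = v
        for i, v in enumerate(tumor):
            data[f"t{i}"] = v
        df = pd.DataFrame(data, index=["p1"]).astype(float)
        groups = pd.Series(
            {**{f"c{i}": "control" for i in range(len(control))},
             **{f"t{i}": "tumor" for i in range(len(tumor))}}
        )
        return NormalizedMatrix(ratios=df, groups=groups)

    def test_strong_decrease_called_hypo(self):
        mat = self._matrix([0.5, 0.52, 0.48, 0.5], [1.0, 1.02, 0.98, 1.0])
        table = differential_table(mat)
        assert table.loc[0, "direction"] == "hypo"
        assert table.loc[0, "fc"] == pytest.approx(0.5)

    def test_small_fold_not_called_despite_significance(self):
        mat = self._matrix([1.2, 1.2001, 1.1999, 1.2], [1.0, 1.0001, 0.9999, 1.0])
        table = differential_table(mat)
        assert table.loc[0, "p"] < 0.001
        assert table.loc[0, "direction"] == "ns"

    def test_hypo_hyper_disjoint_and_thresholds_hold(self):
        design = flat_design(2000)
        truth = make_methylation(
            flat_truth_islands(2000), default_groups(),
            MethylationParams(n_hypo=100, n_hyper=50, seed=3),
        )
        ch = simulate_array(design, truth, SignalModel(noise_cv=0.15), seed=3)
        res = chip.run_analysis(ch)
        hypo, hyper = res["hypo"], res["hyper"]
        assert set(hypo.probe_id).isdisjoint(hyper.probe_id)
        params = AnalysisParams()
        assert (hypo.fc <= 1 / params.fc_cut).all() and (hypo.p < params.alpha).all()
        assert (hyper.fc >= params.fc_cut).all() and (hyper.p < params.alpha).all()

    def test_null_not_anticonservative_and_joint_rate_bounded(self):
        design = flat_design(10_000)
        truth = make_methylation(
            flat_truth_islands(10_000), default_groups(), MethylationParams(seed=5)
        )
        ch = simulate_array(design, truth, SignalModel(noise_cv=0.15), seed=5)
        res = chip.run_analysis(ch)
        tab = res["table"]
        p_rate = (tab.p < 0.05).mean()
        joint_rate = ((tab.p < 0.05) & ((tab.fc >= 1.5) | (tab.fc <= 1 / 1.5))).mean()
        se = math.sqrt(0.05 * 0.95 / len(tab))
        assert p_rate <= 0.05 + 3 * se  # Welch at n=4+4 is conservative, never inflated
        assert joint_rate <= p_rate


class TestGeneAggregation:
    def _design(self):
        probes = [
            Probe("p1", "c", 0, 60, "", "i1", ("gA",)),
            Probe("p2", "c", 25, 85, "", "i1", ("gA",)),
            Probe("p3", "c", 0, 60, "", "i2", ("gB",)),
            Probe("p4", "c", 0, 60, "", "i3", ("gC",)),
        ]
        return ArrayDesign(probes=probes)

    def _table(self, directions):
        return pd.DataFrame(
            {"probe_id": list(directions), "gene_ids": "", "mean_tumor": 1.0,
             "mean_control": 1.0, "fc": 1.0, "t": 0.0, "df": 1.0, "p": 0.01,
             "direction": list(directions.values())}
        )

    def test_unanimous_gene_direction(self):
        out = probe_to_gene(self._table({"p1": "hypo", "p2": "hypo"}), self._design())
        assert (out[out.gene_id == "gA"].gene_direction == "hypo").all()

    def test_mixed_gene_preserves_both_rows(self):
        out = probe_to_gene(self._table({"p1": "hypo", "p2": "hyper"}), self._design())
        ga = out[out.gene_id == "gA"]
        assert set(ga.direction) == {"hypo", "hyper"}
        assert (ga.gene_direction == "mixed").all()

    def test_nonsignificant_genes_absent(self):
        out = probe_to_gene(self._table({"p1": "hypo", "p3": "ns"}), self._design())
        assert "gB" not in set(out.gene_id)


class TestMedianClasses:
    def test_all_equal_yields_empty_classes(self):
        lower, higher = median_classes(pd.Series({"g1": 1.0, "g2": 1.0, "g3": 1.0}))
        assert lower == [] and higher == []

    def test_high_outlier_in_higher_class(self):
        signals = pd.Series({f"g{i}": 1.0 for i in range(4)} | {"gx": 4.0})
        lower, higher = median_classes(signals)
        assert higher == ["gx"] and lower == []

    def test_low_outlier_in_lower_class_with_boundary_included(self):
        signals = pd.Series({f"g{i}": 1.0 for i in range(4)} | {"gx": 0.25, "gy": 0.5})
        lower, _ = median_classes(signals)
        assert lower == ["gx", "gy"]  # 0.5 == median/2 boundary included


class TestPca:
    def test_identical_samples_score_zero(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]] * 3, index=["a", "b", "c"])
        scores = pca_scores(m)
        assert np.allclose(scores.to_numpy(), 0.0)

    def test_small_matrix_matches_eigendecomposition(self):
        X = np.array([[1.0, 2.0], [3.0, 1.0], [2.0, 4.0]])
        m = pd.DataFrame(X, index=["s1", "s2", "s3"])
        scores = pca_scores(m)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1]
        expected = Xc @ evecs[:, order]
        for j in range(2):
            got = scores.iloc[:, j].to_numpy()
            assert np.allclose(got, expected[:, j]) or np.allclose(got, -expected[:, j])

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(6, 10)))
        s1, s2 = pca_scores(m), pca_scores(m.copy())
        pd.testing.assert_frame_equal(s1, s2)


class TestEnrichment:
    def test_universal_term_has_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        terms = {g: {"T"} for g in universe}
        res = term_enrichment(universe[:3], universe, terms)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_exhaustive_combinatorial_oracle(self):
        # N=20, K=5, n=5, k=5 -> p = 1/C(20,5)
        universe = [f"g{i}" for i in range(20)]
        terms = {g: {"T"} for g in universe[:5]}
        res = term_enrichment(universe[:5], universe, terms)
        assert res.loc[0, "k"] == 5
        assert res.loc[0, "p"] == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            N = int(rng.integers(8, 25))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            universe = [f"g{i}" for i in range(N)]
            terms = {g: {"T"} for g in universe[:K]}
            sel = list(rng.choice(universe, size=n, replace=False))
            res = term_enrichment(sel, universe, terms)
            k = res.loc[0, "k"]
            p_enum = sum(
                math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(K, n) + 1)
            ) / math.comb(N, n)
            assert res.loc[0, "p"] == pytest.approx(p_enum, rel=1e-10)

    def test_permutation_null_rarely_significant(self):
        rng = np.random.default_rng(8)
        universe = [f"g{i}" for i in range(200)]
        terms = {g: {f"T{rng.integers(0, 10)}"} for g in universe}
        n_sig = 0
        for _ in range(20):
            sel = list(rng.choice(universe, size=30, replace=False))
            res = term_enrichment(sel, universe, terms)
            n_sig += int(res["significant"].sum())
        assert n_sig <= 2

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            term_enrichment([], ["g1"], {})


class TestExpressionOverlap:
    def test_empty_expression_table(self):
        design = ArrayDesign(probes=[Probe("p1", "c", 0, 60, "", "i1", ("gA",))])
        funnel, rows = expression_overlap(
            pd.DataFrame(columns=["gene_id", "direction"]),
            pd.DataFrame(columns=["gene_id", "direction"]),
            design,
        )
        assert funnel["expression_significant"] == 0 and funnel["both_significant"] == 0

    def test_reference_concordance_table_has_22_distinct_genes(self):
        table = load_hcc_concordance()
        assert len(table) == 25
        assert table["gene_id"].nunique() == 22

    def test_funnel_matches_bookkeeping_on_synthetic_run(self):
        probes = [Probe(f"p{i}", "c", 0, 60, "", f"i{i}", (f"g{i}",)) for i in range(6)]
        design = ArrayDesign(probes=probes)
        islands = {f"g{i}": ["island"] for i in range(4)} | {"g8": ["island"], "g9": []}
        expression = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(4)] + ["g8", "g9"],
             "direction": ["up"] * 6}
        )
        meth = pd.DataFrame({"gene_id": ["g0", "g1"], "direction": ["hypo", "hyper"],
                             "probe_id": ["p0", "p1"], "fc": [0.5, 2.0], "p": [0.01, 0.01]})
        funnel, rows = expression_overlap(meth, expression, design, islands)
        # g0..g3 have islands and probes; g8 has island, no probe; g9 neither
        assert funnel == {
            "expression_significant": 6, "with_promoter_cgi": 5, "on_array": 4,
            "both_significant": 2, "percent_concordant": 50.0,
        }
        assert set(rows.gene_id) == {"g0", "g1"}
        assert set(rows.expression) == {"up"}


@given(
    st.floats(min_value=0.01, max_value=100, allow_nan=False),
    st.floats(min_value=0.01, max_value=100, allow_nan=False),
)
def test_fold_direction_consistency(mt, mc):
    """fc and 1/fc swap roles when tumor and control are exchanged."""
    assert mt / mc == pytest.approx(1 / (mc / mt))
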