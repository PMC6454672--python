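"""Network structure, MLE conditional probabilities, and subsampling inference."""

import networkx as nx
import numpy as np
import pytest

from strokescreen import (
    FACTORS,
    BayesianNetworkIncidence,
    CohortConfig,
    FactorPattern,
    build_structure,
    enumerate_patterns,
    fit_cpt_mle,
    generate_cohort,
    infer_incidence,
    resample_incidence,
    true_conditional_incidence,
)
from tests.conftest import make_cohort, random_cohort


def toy_hypertension_cohort():
    """4 hypertensive records with 1 stroke, 6 non-hypertensive with 0."""
    X = np.zeros((10, 8), dtype=bool)
    X[:4, 0] = True
    strokes = np.zeros(10, dtype=bool)
    strokes[0] = True
    return make_cohort(X, strokes)


class TestStructure:
    def test_three_factor_star(self):
        g = build_structure(FactorPattern(["smoking", "overweight", "hypertension"]))
        assert g.number_of_nodes() == 4
        assert g.number_of_edges() == 3
        assert g.in_degree("stroke") == 3
        assert g.out_degree("stroke") == 0
        assert nx.is_directed_acyclic_graph(g)

    def test_empty_pattern_single_node(self):
        g = build_structure(FactorPattern([]))
        assert list(g.nodes) == ["stroke"]
        assert g.number_of_edges() == 0


class TestEnumeration:
    @pytest.mark.parametrize("k,expected", [(1, 8), (2, 28), (3, 56)])
    def test_counts(self, k, expected):
        pats = enumerate_patterns(k)
        assert len(pats) == expected
        assert len({p.positive_factors for p in pats}) == expected

    def test_canonical_order_is_deterministic(self):
        assert [p.label() for p in enumerate_patterns(1)] == list(FACTORS)
        assert enumerate_patterns(2)[0].label() == "hypertension;atrial_fibrillation"

    @pytest.mark.parametrize("k", [0, 4, -1])
    def test_out_of_range_k(self, k):
        with pytest.raises(ValueError):
            enumerate_patterns(k)


class TestCPT:
    def test_toy_counts(self):
        df = toy_hypertension_cohort()
        cpt = fit_cpt_mle(df, build_structure(FactorPattern(["hypertension"])))
        assert cpt.loc[(1,), "p"] == pytest.approx(0.25)
        assert cpt.loc[(0,), "p"] == pytest.approx(0.0)
        assert cpt.loc[(1,), "support"] == 4
        assert cpt.loc[(1,), "events"] == 1

    def test_zero_support_cells_flagged_not_numbered(self):
        df = toy_hypertension_cohort()  # nobody smokes
        cpt = fit_cpt_mle(df, build_structure(FactorPattern(["hypertension", "smoking"])))
        row = cpt.loc[(1, 1)]
        assert not row["supported"]
        assert np.isnan(row["p"])

    def test_rows_normalise(self):
        rng = np.random.default_rng(8)
        df = random_cohort(rng, n=50)
        cpt = fit_cpt_mle(df, build_structure(FactorPattern(["diabetes", "overweight"])))
        supported = cpt[cpt["supported"]]
        assert ((supported["p"] >= 0) & (supported["p"] <= 1)).all()
        # P(stroke=1|.) + P(stroke=0|.) = 1 by construction of events/support
        assert (supported["events"] + (supported["support"] - supported["events"])
                == supported["support"]).all()


class TestInference:
    def test_toy_marginal(self):
        df = toy_hypertension_cohort()
        assert infer_incidence(df, FactorPattern(["hypertension"])) == pytest.approx(0.25)

    def test_zero_events_returns_zero_with_flag(self):
        df = toy_hypertension_cohort()
        est = BayesianNetworkIncidence(random_state=0, n_iterations=10).fit(df)
        out = est.estimate(FactorPattern(["dyslipidemia"]))  # nobody has it
        assert out.point == 0.0
        assert out.unsupported
        out2 = est.estimate(FactorPattern(["hypertension"], "exact"))
        # hypertensive-only records exist, one stroked
        assert out2.point == pytest.approx(0.25)

    def test_oracle_equivalence_brute_force(self):
        """MLE inference equals direct filter-and-count on random small cohorts,
        for every pattern of sizes 1-3 under both semantics."""
        rng = np.random.default_rng(123)
        all_patterns = [p for k in (1, 2, 3) for p in enumerate_patterns(k)]
        for _ in range(8):
            df = random_cohort(rng, n=int(rng.integers(5, 21)))
            X = df[list(FACTORS)].to_numpy()
            y = df["incident_stroke"].to_numpy()
            est_m = BayesianNetworkIncidence(semantics="marginal").fit(df)
            est_e = BayesianNetworkIncidence(semantics="exact").fit(df)
            for pat in all_patterns:
                named = np.array(pat.mask())
                m_mask = X[:, named].all(axis=1)
                e_mask = (X == named).all(axis=1)
                for est, mask in ((est_m, m_mask), (est_e, e_mask)):
                    expected = y[mask].sum() / mask.sum() if mask.sum() else 0.0
                    value, support, events = est.point_estimate(pat)
                    assert value == pytest.approx(expected)
                    assert support == mask.sum()

    def test_exact_support_never_exceeds_marginal(self):
        rng = np.random.default_rng(7)
        df = random_cohort(rng, n=200)
        est_m = BayesianNetworkIncidence(semantics="marginal").fit(df)
        est_e = BayesianNetworkIncidence(semantics="exact").fit(df)
        for pat in enumerate_patterns(2):
            _, s_m, _ = est_m.point_estimate(pat)
            _, s_e, _ = est_e.point_estimate(pat)
            assert s_e <= s_m

    def test_cpt_agrees_with_estimator(self):
        rng = np.random.default_rng(5)
        df = random_cohort(rng, n=100)
        pat = FactorPattern(["hypertension", "diabetes"])
        cpt = fit_cpt_mle(df, build_structure(pat))
        value, support, _ = BayesianNetworkIncidence().fit(df).point_estimate(pat)
        row = cpt.loc[(1, 1)]
        if row["supported"]:
            assert value == pytest.approx(row["p"])
            assert support == row["support"]


class TestResampling:
    def test_fraction_one_collapses_to_point(self):
        df = toy_hypertension_cohort()
        out = resample_incidence(df, FactorPattern(["hypertension"]),
                                 n_iterations=50, fraction=1.0, seed=0)
        assert out.resample_mean == pytest.approx(out.point)
        assert out.ci90 == (out.point, out.point)

    def test_paper_style_summary_format(self):
        df = generate_cohort(CohortConfig(n_people=20000, seed=2))
        out = resample_incidence(df, FactorPattern(["hypertension"]),
                                 n_iterations=2000, seed=3)
        text = out.summary()
        mean_s, half_s = text.split(" ± ")
        assert float(mean_s) == pytest.approx(out.resample_mean, abs=1e-5)
        assert float(half_s) == pytest.approx((out.ci90[1] - out.ci90[0]) / 2, abs=1e-5)

    def test_seed_determinism_and_divergence(self):
        df = generate_cohort(CohortConfig(n_people=10000, seed=4))
        pat = FactorPattern(["diabetes"])
        a = resample_incidence(df, pat, n_iterations=500, seed=11)
        b = resample_incidence(df, pat, n_iterations=500, seed=11)
        c = resample_incidence(df, pat, n_iterations=500, seed=12)
        assert a.resample_mean == b.resample_mean
        assert a.ci90 == b.ci90
        assert a.resample_mean != c.resample_mean

    def test_two_seeds_agree_within_monte_carlo_error(self):
        df = generate_cohort(CohortConfig(n_people=50000, seed=6))
        pat = FactorPattern(["hypertension"])
        a = resample_incidence(df, pat, n_iterations=10000, seed=21)
        b = resample_incidence(df, pat, n_iterations=10000, seed=22)
        se_a = (a.ci90[1] - a.ci90[0]) / (2 * 1.6449)
        se_b = (b.ci90[1] - b.ci90[0]) / (2 * 1.6449)
        assert abs(a.resample_mean - b.resample_mean) < 4 * np.hypot(se_a, se_b)

    def test_hypergeometric_path_matches_literal_subsampling(self):
        """The O(1) count-draw path and literal subsample materialisation are
        the same distribution: their means and spreads must agree closely."""
        df = generate_cohort(CohortConfig(n_people=4000, seed=8))
        pat = FactorPattern(["hypertension"])
        fast = resample_incidence(df, pat, n_iterations=3000, seed=31, method="hypergeometric")
        slow = resample_incidence(df, pat, n_iterations=3000, seed=31, method="subsample")
        se = (fast.ci90[1] - fast.ci90[0]) / (2 * 1.6449)
        assert fast.point == slow.point
        assert abs(fast.resample_mean - slow.resample_mean) < 5 * se
        sd_fast = se * np.sqrt(3000)
        sd_slow = (slow.ci90[1] - slow.ci90[0]) / (2 * 1.6449) * np.sqrt(3000)
        assert sd_slow == pytest.approx(sd_fast, rel=0.15)

    def test_invalid_parameters_rejected(self):
        df = toy_hypertension_cohort()
        with pytest.raises(ValueError):
            resample_incidence(df, FactorPattern(["smoking"]), n_iterations=1)
        with pytest.raises(ValueError):
            resample_incidence(df, FactorPattern(["smoking"]), fraction=0.0)
        with pytest.raises(ValueError):
            BayesianNetworkIncidence(semantics="weird").fit(df)


def test_percentile_interval_coverage_at_half_sampling(clean_config):
    """Delete-half subsampling percentile intervals should cover the generator
    truth at roughly the nominal 90% rate across replicates."""
    pat = FactorPattern(["hypertension"])
    truth = true_conditional_incidence(clean_config, pat)
    covered = 0
    reps = 200
    for i in range(reps):
        cfg = CohortConfig(**{**clean_config.__dict__, "n_people": 8000, "seed": 1000 + i})
        df = generate_cohort(cfg)
        est = BayesianNetworkIncidence(fraction=0.5, n_iterations=400, random_state=i).fit(df)
        out = est.estimate(pat)
        if out.percentile90[0] <= truth <= out.percentile90[1]:
            covered += 1
    assert 0.85 * reps <= covered <= 0.95 * reps
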