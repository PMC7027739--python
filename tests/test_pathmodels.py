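"""DAG handling, d-separation basis set, Fisher's C and the piecewise SEM."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from microsoc import (GraphError, PathModel, PiecewiseSEM, SyntheticConfig,
                      UndefinedValueError, basis_set, default_path_model,
                      dsep_pvalue, fishers_c, generate_dataset)


class TestPathModel:
    def test_cycle_raises(self):
        with pytest.raises(GraphError):
            PathModel([("a", "b"), ("b", "c"), ("c", "a")])

    def test_vertex_classification(self):
        m = default_path_model()
        assert m.exogenous == ["psr_log"]
        assert set(m.endogenous) == {"root_c", "growth", "cmic",
                                     "respiration", "soc"}
        assert m.parents("cmic") == ["psr_log", "root_c", "growth"]

    def test_text_roundtrip(self):
        m = default_path_model()
        m2 = PathModel.from_text(m.to_text())
        assert set(m2.edges) == set(m.edges)
        assert m2.transforms == m.transforms

    def test_bad_text(self):
        with pytest.raises(Exception):
            PathModel.from_text("a => b\n")


class TestBasisSet:
    def test_textbook_chain(self):
        claims = basis_set(PathModel([("a", "b"), ("b", "c")]))
        assert len(claims) == 1
        c = claims[0]
        assert (c.x, c.y, c.cond) == ("a", "c", ("b",))

    def test_fully_connected_triangle_is_empty(self):
        m = PathModel([("a", "b"), ("a", "c"), ("b", "c")])
        assert basis_set(m) == []

    def test_study_dag_has_seven_claims(self):
        m = default_path_model()
        claims = basis_set(m)
        # combinatorial oracle: 6 vertices -> 15 pairs, 8 edges -> 7 claims
        n_pairs = len(list(itertools.combinations(m.vertices, 2)))
        assert n_pairs - len(m.edges) == 7
        assert len(claims) == 7

    def test_claims_valid_on_all_small_dags(self):
        """Exhaustive check on every DAG with <= 5 vertices (edges along a
        fixed vertex order): claim count equals the number of non-adjacent
        pairs, and every claim is a true d-separation of the graph."""
        for n in (2, 3, 4, 5):
            names = [f"v{i}" for i in range(n)]
            slots = list(itertools.combinations(range(n), 2))
            for mask in range(1, 2 ** len(slots)):
                edges = [(names[i], names[j])
                         for k, (i, j) in enumerate(slots) if mask >> k & 1]
                model = PathModel(edges)
                g = nx.DiGraph(edges)
                g.add_nodes_from(names)
                present = [v for v in names if v in model.graph]
                nonadj = [
                    (x, y) for x, y in itertools.combinations(present, 2)
                    if not (g.has_edge(x, y) or g.has_edge(y, x))
                ]
                claims = basis_set(model)
                assert len(claims) == len(nonadj)
                for c in claims:
                    assert nx.is_d_separator(g, {c.x}, {c.y}, set(c.cond))


class TestFishersC:
    def test_hand_example(self):
        C, df, p = fishers_c([np.exp(-1.0)] * 7)
        assert C == pytest.approx(14.0, rel=1e-12)
        assert df == 14

    def test_all_ones_fit_perfectly(self):
        C, df, p = fishers_c([1.0, 1.0, 1.0])
        assert C == 0.0 and p == 1.0

    def test_zero_pvalue_floored(self):
        C, df, p = fishers_c([0.0, 0.5])
        assert np.isfinite(C)
        assert C == pytest.approx(-2 * (np.log(1e-16) + np.log(0.5)))

    def test_invalid_pvalues(self):
        with pytest.raises(UndefinedValueError):
            fishers_c([1.2])


class TestDsep:
    def test_exact_dependence_rejected(self, rng):
        x = rng.normal(size=60)
        data = pd.DataFrame({"x": x, "y": x, "block": np.arange(60) % 4})
        claims = basis_set(PathModel([("x", "z"), ("y", "z")]))
        # x,y pair is the only claim; y = x exactly => p ~ 0
        data["z"] = rng.normal(size=60)
        p = dsep_pvalue(claims[0], data)
        assert p < 1e-10

    def test_null_pvalues_uniform(self):
        """x,y independent noise: claim p-values are ~Uniform(0,1)."""
        from scipy import stats

        rng = np.random.default_rng(5)
        model = PathModel([("x", "z"), ("y", "z")])
        claim = basis_set(model)[0]
        ps = []
        for _ in range(300):
            n = 60
            data = pd.DataFrame({
                "x": rng.normal(size=n), "y": rng.normal(size=n),
                "z": rng.normal(size=n), "block": np.arange(n) % 4,
            })
            ps.append(dsep_pvalue(claim, data))
        frac = np.mean(np.array(ps) < 0.05)
        assert 0.02 <= frac <= 0.09
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_mediator_blocks_dependence(self):
        """Conditioning on the true mediator of x -> m -> y makes the claim
        hold: rejection stays near the nominal level."""
        rng = np.random.default_rng(6)
        model = PathModel([("x", "m"), ("m", "y")])
        claim = basis_set(model)[0]
        assert claim.cond == ("m",)
        rej = 0
        reps = 200
        for _ in range(reps):
            n = 60
            x = rng.normal(size=n)
            m = 0.7 * x + rng.normal(size=n)
            y = 0.7 * m + rng.normal(size=n)
            data = pd.DataFrame({"x": x, "m": m, "y": y,
                                 "block": np.arange(n) % 4})
            rej += dsep_pvalue(claim, data) < 0.05
        assert 0.01 <= rej / reps <= 0.10


class TestPiecewiseSEM:
    def test_saturated_model_is_perfect_fit(self, rng):
        n = 40
        data = pd.DataFrame({"a": rng.normal(size=n)})
        data["b"] = data["a"] + rng.normal(size=n)
        data["c"] = data["b"] + rng.normal(size=n)
        data["block"] = np.arange(n) % 4
        m = PathModel([("a", "b"), ("a", "c"), ("b", "c")])
        fit = PiecewiseSEM(m, data).fit()
        assert fit.fisher_c == 0.0
        assert fit.dsep_df == 0
        assert fit.dsep_p == 1.0

    def test_standardization_identity(self, dataset):
        """beta equals raw coefficient x SD(cause)/SD(effect) on the
        analysis scale, for every fitted edge."""
        model = default_path_model()
        sem = PiecewiseSEM(model, dataset.latent)
        fit = sem.fit(dsep=False)
        sd = sem.data[model.vertices].std(ddof=1)
        for _, row in fit.paths.iterrows():
            want = row["coef"] * sd[row["cause"]] / sd[row["effect"]]
            assert row["beta"] == pytest.approx(want, rel=1e-10)

    def test_aic_relationships(self, dataset):
        fit = PiecewiseSEM(default_path_model(), dataset.latent).fit()
        assert fit.aic == pytest.approx(fit.fisher_c + 2 * fit.k_params)
        assert fit.aicc > fit.aic  # finite-n penalty is strictly larger
        assert fit.dsep_df == 14
        assert fit.dsep_df % 2 == 0

    def test_indirect_effects_chain_product(self, rng):
        n = 500
        a = rng.normal(size=n)
        b = 0.5 * a + rng.normal(size=n) * np.sqrt(1 - 0.25)
        c = 0.4 * b + rng.normal(size=n) * np.sqrt(1 - 0.16)
        data = pd.DataFrame({"a": a, "b": b, "c": c,
                             "block": np.arange(n) % 4})
        fit = PiecewiseSEM(PathModel([("a", "b"), ("b", "c")]), data).fit(
            dsep=False)
        table, total = fit.indirect_effects("a", "c")
        assert len(table) == 1
        assert total == pytest.approx(fit.beta("a", "b") * fit.beta("b", "c"),
                                      rel=1e-12)
        assert total == pytest.approx(0.2, abs=0.08)
        # no mediated route / source == target -> empty
        _, none = fit.indirect_effects("b", "c")
        assert none == 0.0
        _, same = fit.indirect_effects("a", "a")
        assert same == 0.0

    def test_separate_indirect_routes_reported(self, dataset):
        fit = PiecewiseSEM(default_path_model(), dataset.latent).fit(dsep=False)
        table, total = fit.indirect_effects("psr_log", "cmic")
        routes = set(table["path"])
        assert "psr_log -> growth -> cmic" in routes
        assert "psr_log -> root_c -> cmic" in routes
        assert "psr_log -> root_c -> growth -> cmic" in routes
        assert total == pytest.approx(table["effect"].sum())

    def test_summary_and_json(self, dataset):
        fit = PiecewiseSEM(default_path_model(), dataset.latent).fit()
        text = fit.summary()
        assert "Fisher's C" in text and "cmic -> soc" in text
        d = fit.to_dict()
        assert len(d["claims"]) == 7
        assert len(d["paths"]) == 8


def test_parameter_recovery_moderate(default_config):
    """Mean recovered standardized coefficients across seeds stay close to
    the generator's values (deep version runs in the acceptance suite)."""
    from dataclasses import replace

    from microsoc.synthdata import DEFAULT_PATH_BETA, scale_replication

    model = default_path_model()
    rep = scale_replication(default_config.n_per_psr, 200)
    est = {e: [] for e in DEFAULT_PATH_BETA if model.graph.has_edge(*e)}
    for r in range(40):
        cfg = replace(default_config, seed=5000 + r, n_per_psr=rep)
        fit = PiecewiseSEM(model, generate_dataset(cfg).latent).fit(dsep=False)
        for e in est:
            est[e].append(fit.beta(*e))
    for e, vals in est.items():
        assert abs(np.mean(vals) - DEFAULT_PATH_BETA[e]) < 0.05
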