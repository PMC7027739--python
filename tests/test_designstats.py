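"""Block correction, sequential LR tests and the correlation matrix."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from microsoc import (DesignError, SyntheticConfig, UndefinedValueError,
                      block_correct, correlation_matrix, generate_design,
                      sequential_lr_tests, significance_code)
from microsoc.designstats import fit_lmm


class TestBlockCorrect:
    def test_hand_example(self):
        # blocks A:(1,3), B:(5,7); grand mean 4; block means 2 and 6.
        # Recentring each block on the grand mean shifts A by +2 and B by
        # -2: A -> (3,5), B -> (3,5); both block means now equal 4.
        out = block_correct([1, 3, 5, 7], ["A", "A", "B", "B"])
        np.testing.assert_allclose(out, [3, 5, 3, 5])

    def test_single_block_is_identity(self):
        x = np.array([1.0, 2.0, 5.0])
        np.testing.assert_allclose(block_correct(x, ["A"] * 3), x)

    @given(hnp.arrays(float, st.integers(4, 40),
                      elements=st.floats(-50, 50)))
    def test_grand_mean_preserved_and_idempotent(self, x):
        blocks = np.arange(len(x)) % 3
        once = block_correct(x, blocks)
        assert once.mean() == pytest.approx(x.mean(), abs=1e-9)
        twice = block_correct(once, blocks)
        np.testing.assert_allclose(twice, once, atol=1e-9)
        # every corrected block mean equals the grand mean
        for b in range(3):
            assert once[blocks == b].mean() == pytest.approx(x.mean(),
                                                             abs=1e-9)

    def test_empty_raises(self):
        with pytest.raises(DesignError):
            block_correct([], [])


class TestSignificanceCodes:
    @pytest.mark.parametrize("p,code", [
        (0.0005, "***"), (0.001, "***"), (0.005, "**"), (0.01, "**"),
        (0.03, "*"), (0.05, "*"), (0.07, "†"), (0.1, "†"), (0.5, ""),
        (1.0, ""),
    ])
    def test_thresholds_boundaries_to_stronger_code(self, p, code):
        assert significance_code(p) == code

    def test_invalid_p(self):
        with pytest.raises(UndefinedValueError):
            significance_code(1.5)


def _design_with_response(seed, effect=0.0, tau=0.5):
    cfg = SyntheticConfig(seed=seed)
    d = generate_design(cfg)
    rng = np.random.default_rng(seed + 999)
    psr_log = np.log(d["psr_sown"].astype(float))
    z = (psr_log - psr_log.mean()) / psr_log.std(ddof=1)
    d["y"] = (effect * z + tau * rng.normal(size=4)[d["block"] - 1]
              + rng.normal(size=len(d)))
    return d


class TestSequentialLrTests:
    def test_constant_response_gives_null_tests(self):
        d = _design_with_response(3)
        d["y"] = 1.0  # exactly constant
        out = sequential_lr_tests(d, "y")
        assert list(out["term"]) == ["PSR_log", "PFGR", "SH", "TH", "GR", "LEG"]
        assert (out["df"] == 1).all()
        assert (out["L"] < 0.05).all()
        assert (out["p"] > 0.8).all()

    def test_psr_effect_detected_others_null(self):
        """A pure species-richness effect: PSR test hits, identity terms do
        not reject much above the nominal level."""
        hits_psr = 0
        hits_other = 0
        reps = 40
        for r in range(reps):
            d = _design_with_response(100 + r, effect=0.8)
            out = sequential_lr_tests(d, "y").set_index("term")
            hits_psr += out.loc["PSR_log", "p"] < 0.05
            hits_other += (out.drop(index="PSR_log")["p"] < 0.05).sum()
        assert hits_psr == reps
        assert hits_other / (5 * reps) < 0.15

    def test_type_one_error_near_nominal(self):
        """Null response: LR rejection rate of the PSR test is ~5%."""
        rej = 0
        reps = 500
        d = _design_with_response(0)
        rng = np.random.default_rng(42)
        d = d.copy()
        for _ in range(reps):
            d["y"] = (rng.normal(size=len(d))
                      + 0.5 * rng.normal(size=4)[d["block"] - 1])
            full = fit_lmm(d.assign(psr_log=np.log(d.psr_sown)), "y",
                           ["psr_log"])
            base = fit_lmm(d, "y", [])
            _, _, p = full.lr_test(base)
            rej += p < 0.05
        assert 0.03 <= rej / reps <= 0.08

    def test_orders_swap_first_two_steps(self):
        d = _design_with_response(5, effect=0.5)
        a = sequential_lr_tests(d, "y", order="psr-first").set_index("term")
        b = sequential_lr_tests(d, "y", order="pfgr-first").set_index("term")
        # identity-flag tests condition on both terms, so they agree exactly
        np.testing.assert_allclose(a.loc[["SH", "TH", "GR", "LEG"], "L"],
                                   b.loc[["SH", "TH", "GR", "LEG"], "L"],
                                   atol=1e-6)
        assert set(a.index) == set(b.index)


class TestCorrelationMatrix:
    def test_structure_and_exact_cases(self, rng):
        n = 30
        x = rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": -x, "z": rng.normal(size=n),
                           "block": np.arange(n) % 4})
        r, p = correlation_matrix(df, ["x", "y", "z"])
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r.values, r.values.T)
        assert r.loc["x", "y"] == pytest.approx(-1.0)
        assert p.loc["x", "y"] < 1e-12

    def test_block_correction_removes_block_signal(self, rng):
        n = 80
        blocks = np.arange(n) % 4
        shift = np.array([0.0, 5.0, -5.0, 10.0])[blocks]
        df = pd.DataFrame({
            "a": shift + rng.normal(size=n) * 0.5,
            "b": shift + rng.normal(size=n) * 0.5,
            "block": blocks,
        })
        r_raw, _ = correlation_matrix(df, ["a", "b"])
        r_corr, _ = correlation_matrix(df, ["a", "b"], blocks="block")
        # the raw correlation is inflated by the shared block effect
        assert r_raw.loc["a", "b"] > 0.9
        assert abs(r_corr.loc["a", "b"]) < 0.35

    def test_zero_variance_raises(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0], "y": [1, 2, 3, 4.0]})
        with pytest.raises(UndefinedValueError):
            correlation_matrix(df, ["x", "y"])

    def test_cmic_soc_among_strongest(self, dataset):
        """Under the generator's causal chain, biomass-SOC is the dominant
        association, matching the reported correlation structure."""
        plots = dataset.latent
        r, _ = correlation_matrix(plots,
                                  ["soc", "cmic", "growth", "respiration"],
                                  blocks="block")
        off = r.where(~np.eye(len(r), dtype=bool))
        assert r.loc["cmic", "soc"] > 0.4
        assert r.loc["cmic", "soc"] == pytest.approx(off.max().max())
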