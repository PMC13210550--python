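"""Piecewise SEM: basis sets, Fisher's C, fitting and effect decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from bromeval import piecewise_sem as ps, synthetic_data as sd


def chain_model():
    return ps.PathModel(edges=(("x", "m"), ("m", "y")))


class TestBasisSet:
    def test_saturated_model_empty(self):
        model = ps.PathModel(edges=(("a", "b"), ("a", "c"), ("b", "c")))
        assert ps.basis_set(model) == []

    def test_three_node_chain(self):
        claims = ps.basis_set(chain_model())
        assert len(claims) == 1
        c = claims[0]
        assert {c.x, c.y} == {"x", "y"}
        assert c.conditioning == ("m",)
        assert c.response == "y"

    def test_common_child_of_two_exogenous(self):
        model = ps.PathModel(edges=(("a", "c"), ("b", "c")))
        claims = ps.basis_set(model)
        assert len(claims) == 1
        assert {claims[0].x, claims[0].y} == {"a", "b"}
        assert claims[0].conditioning == ()

    def test_invariant_to_declaration_order(self):
        edges = tuple(sd.YIELD_PATHWAY_COEFFS)
        a = ps.basis_set(ps.PathModel(edges=edges))
        b = ps.basis_set(ps.PathModel(edges=tuple(reversed(edges))))
        assert a == b

    def test_cyclic_model_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            ps.basis_set(ps.PathModel(edges=(("a", "b"), ("b", "a"))))


class TestFishersC:
    def test_all_ones(self):
        c, df, p = ps.fishers_c([1.0, 1.0, 1.0])
        assert c == 0.0 and df == 6 and p == 1.0

    def test_hand_value(self):
        c, df, p = ps.fishers_c([0.5, 0.5, 0.5])
        assert c == pytest.approx(-6 * np.log(0.5), abs=1e-9)
        assert c == pytest.approx(4.159, abs=1e-3)
        assert df == 6

    def test_chi_square_tail_reference_point(self):
        # C = 5.3 on 6 df sits squarely in the non-significant region.
        assert stats.chi2.sf(5.3, 6) == pytest.approx(0.506, abs=5e-4)

    @given(
        a=st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=4),
        b=st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=4),
    )
    def test_additive_over_claim_sets(self, a, b):
        c_a, df_a, _ = ps.fishers_c(a)
        c_b, df_b, _ = ps.fishers_c(b)
        c_ab, df_ab, _ = ps.fishers_c(a + b)
        assert c_ab == pytest.approx(c_a + c_b, rel=1e-9, abs=1e-9)
        assert df_ab == df_a + df_b

    def test_empty_set_saturated_warning(self):
        with pytest.warns(UserWarning, match="saturated"):
            c, df, p = ps.fishers_c([])
        assert (c, df, p) == (0.0, 0, 1.0)

    def test_zero_p_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floor"):
            c, df, p = ps.fishers_c([0.0, 0.5])
        assert np.isfinite(c)


class TestFit:
    def test_identity_path_beta_one(self):
        x = np.linspace(-2, 2, 50)
        data = pd.DataFrame({"x": x, "y": x.copy()})
        fit = ps.fit(ps.PathModel(edges=(("x", "y"),)), data)
        assert fit.beta("x", "y") == pytest.approx(1.0)

    def test_recovers_planted_coefficient(self):
        truth = sd.SemGroundTruth(coefficients={("x", "y"): -0.52})
        data = sd.generate_sem_dataset(truth, n=10_000, seed=21)
        fit = ps.fit(ps.PathModel(edges=(("x", "y"),)), data)
        assert fit.beta("x", "y") == pytest.approx(-0.52, abs=0.03)

    def test_beta_equals_zscored_regression(self):
        truth = sd.yield_pathway_truth()
        data = sd.generate_sem_dataset(truth, n=2000, seed=22)
        model = ps.PathModel(edges=tuple(truth.coefficients))
        fit = ps.fit(model, data)
        z = (data - data.mean()) / data.std(ddof=1)
        parents = ["adf", "plant_height", "stem_diameter"]
        X = np.column_stack([np.ones(len(z))] + [z[p] for p in parents])
        coef = np.linalg.lstsq(X, z["hay_yield"], rcond=None)[0]
        for k, parent in enumerate(parents):
            assert fit.beta(parent, "hay_yield") == pytest.approx(
                coef[k + 1], abs=1e-9
            )

    def test_correct_model_fisher_c_calibrated(self):
        truth = sd.yield_pathway_truth()
        model = ps.PathModel(edges=tuple(truth.coefficients))
        ok = sum(
            ps.fit(model, sd.generate_sem_dataset(truth, n=400, seed=s)).p_value > 0.05
            for s in range(25)
        )
        assert ok >= 21

    def test_missing_strong_edge_detected(self):
        truth = sd.yield_pathway_truth()
        reduced = tuple(
            e for e in truth.coefficients if e != ("plant_height", "hay_yield")
        )
        model = ps.PathModel(edges=reduced)
        rejected = sum(
            ps.fit(model, sd.generate_sem_dataset(truth, n=400, seed=s)).p_value
            < 0.05
            for s in range(25)
        )
        assert rejected >= 23

    def test_collinear_parents_rejected(self):
        x = np.linspace(0, 1, 30)
        data = pd.DataFrame({"a": x, "b": 2 * x, "y": x + 1})
        model = ps.PathModel(edges=(("a", "y"), ("b", "y")))
        with pytest.raises(ValueError, match="collinear"):
            ps.fit(model, data)

    def test_categorical_parent_block_p(self):
        rng = np.random.default_rng(31)
        g = np.repeat(["a", "b", "c"], 40)
        y = (g == "b") * 2.0 + rng.normal(size=120)
        data = pd.DataFrame({"g": g, "y": y})
        model = ps.PathModel(edges=(("g", "y"),), categorical=frozenset({"g"}))
        fit = ps.fit(model, data)
        row = fit.paths.iloc[0]
        assert np.isnan(row["beta"])
        assert row["p"] < 1e-6

    def test_spec_text_round_trip(self):
        model = ps.PathModel.from_spec(
            """
            m ~ x
            y ~ m
            """
        )
        assert set(model.edges) == {("x", "m"), ("m", "y")}


class TestDecomposeEffects:
    def _fit_chain(self, b1=0.5, b2=0.4):
        rng = np.random.default_rng(41)
        n = 20_000
        x = rng.normal(size=n)
        m = b1 * x + rng.normal(size=n) * np.sqrt(1 - b1**2)
        y = b2 * m + rng.normal(size=n) * np.sqrt(1 - b2**2)
        data = pd.DataFrame({"x": x, "m": m, "y": y})
        return ps.fit(chain_model(), data)

    def test_chain_indirect_product(self):
        fit = self._fit_chain()
        eff = ps.decompose_effects(fit).set_index(["source", "target"])
        row = eff.loc[("x", "y")]
        assert row["direct"] == 0.0
        assert row["indirect"] == pytest.approx(0.20, abs=0.02)
        assert row["total"] == pytest.approx(row["indirect"])

    def test_direct_only_total_equals_direct(self):
        truth = sd.SemGroundTruth(coefficients={("x", "y"): 0.3})
        data = sd.generate_sem_dataset(truth, n=5000, seed=42)
        fit = ps.fit(ps.PathModel(edges=(("x", "y"),)), data)
        eff = ps.decompose_effects(fit).set_index(["source", "target"])
        row = eff.loc[("x", "y")]
        assert row["total"] == row["direct"]
        assert row["indirect"] == 0.0

    def test_parallel_mediators_cancel(self):
        # Synthetic fit: plant two mediation paths with products +0.1 and -0.1.
        model = ps.PathModel(
            edges=(("x", "m1"), ("x", "m2"), ("m1", "y"), ("m2", "y"))
        )
        paths = pd.DataFrame(
            {
                "child": ["m1", "m2", "y", "y"],
                "parent": ["x", "x", "m1", "m2"],
                "b": [0.5, 0.5, 0.2, -0.2],
                "beta": [0.5, 0.5, 0.2, -0.2],
                "p": [0.01] * 4,
            }
        )
        fit = ps.SemFit(
            model=model, paths=paths, claims=pd.DataFrame(), fishers_c=0.0, df=0, p_value=1.0
        )
        eff = ps.decompose_effects(fit).set_index(["source", "target"])
        assert eff.loc[("x", "y"), "indirect"] == pytest.approx(0.0, abs=1e-12)
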