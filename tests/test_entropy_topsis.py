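"""Entropy weighting and TOPSIS ranking, checked against a brute-force oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bromeval import entropy_topsis as et, synthetic_data as sd


def topsis_oracle(X: pd.DataFrame, directions: dict) -> dict:
    """Straight-line transcription of the entropy-TOPSIS equations.

    Deliberately naive (explicit loops, no shared code with the module) so it
    can serve as an independent oracle.
    """
    alts = list(X.index)
    inds = list(X.columns)
    n = len(alts)
    p = {(i, j): X.loc[i, j] / sum(X.loc[i2, j] for i2 in alts) for i in alts for j in inds}
    e = {}
    for j in inds:
        s = 0.0
        for i in alts:
            if p[(i, j)] > 0:
                s += p[(i, j)] * math.log(p[(i, j)])
        e[j] = -s / math.log(n)
    d = {j: 1.0 - e[j] for j in inds}
    w = {j: d[j] / sum(d.values()) for j in inds}
    v = {(i, j): w[j] * p[(i, j)] for i in alts for j in inds}
    v_plus, v_minus = {}, {}
    for j in inds:
        col = [v[(i, j)] for i in alts]
        if directions[j] == "benefit":
            v_plus[j], v_minus[j] = max(col), min(col)
        else:
            v_plus[j], v_minus[j] = min(col), max(col)
    c = {}
    for i in alts:
        d_plus = math.sqrt(sum((v[(i, j)] - v_plus[j]) ** 2 for j in inds))
        d_minus = math.sqrt(sum((v[(i, j)] - v_minus[j]) ** 2 for j in inds))
        c[i] = d_minus / (d_plus + d_minus)
    return {"w": w, "c": c}


class TestProportionNormalize:
    def test_uniform_column(self):
        X = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0]})
        assert np.allclose(et.proportion_normalize(X)["a"], 0.25)

    def test_hand_value(self):
        X = pd.DataFrame({"a": [1.0, 3.0]})
        assert np.allclose(et.proportion_normalize(X)["a"], [0.25, 0.75])

    def test_columns_sum_to_one(self, rng):
        X = pd.DataFrame(rng.uniform(0.1, 10, size=(6, 4)))
        p = et.proportion_normalize(X)
        assert np.allclose(p.sum(axis=0), 1.0, atol=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            et.proportion_normalize(pd.DataFrame({"a": [1.0, 0.0]}))


class TestEntropyWeights:
    def test_uniform_column_maximum_entropy(self):
        p = pd.DataFrame({"a": [0.25] * 4, "b": [0.7, 0.1, 0.1, 0.1]})
        ew = et.entropy_weights(p)
        assert ew.e["a"] == pytest.approx(1.0)
        assert ew.d["a"] == pytest.approx(0.0)

    def test_one_hot_column_minimum_entropy(self):
        # exercises the 0 * ln 0 = 0 convention
        p = pd.DataFrame({"a": [1.0, 0.0, 0.0], "b": [0.5, 0.3, 0.2]})
        ew = et.entropy_weights(p)
        assert ew.e["a"] == pytest.approx(0.0)
        assert ew.d["a"] == pytest.approx(1.0)

    def test_weight_hand_arithmetic(self):
        # engineered so d = {0.5, 0.25} => w = {2/3, 1/3}
        e_target = {"a": 0.5, "b": 0.75}

        def column_with_entropy(e):
            # two-point column [q, 1-q] has entropy H(q)/ln 2; solve numerically
            from scipy.optimize import brentq

            f = lambda q: -(q * np.log(q) + (1 - q) * np.log(1 - q)) / np.log(2) - e
            q = brentq(f, 1e-9, 0.5)
            return [q, 1 - q]

        p = pd.DataFrame({k: column_with_entropy(v) for k, v in e_target.items()})
        ew = et.entropy_weights(p)
        assert ew.w["a"] == pytest.approx(2 / 3, abs=1e-6)
        assert ew.w["b"] == pytest.approx(1 / 3, abs=1e-6)

    def test_all_uniform_degenerate(self):
        p = pd.DataFrame({"a": [0.5, 0.5], "b": [0.5, 0.5]})
        with pytest.raises(et.DegenerateWeightsError):
            et.entropy_weights(p)

    def test_weights_sum_to_one(self, rng, schema):
        X = sd.generate_decision_fixture(5, schema, seed=42)
        ew = et.entropy_weights(et.proportion_normalize(X))
        assert abs(ew.w.sum() - 1.0) < 1e-12
        assert (ew.w >= 0).all()


class TestTopsisRank:
    def test_dominant_alternative_rank_one(self, schema):
        X = sd.generate_decision_fixture(5, schema, dominant="G1", seed=5)
        res = et.topsis_rank(et.DecisionMatrix.from_schema(X, schema))
        assert res.ranks["G1"] == 1
        assert ((res.closeness >= 0) & (res.closeness <= 1)).all()

    def test_two_row_extremes(self, schema):
        X = sd.generate_decision_fixture(2, schema, dominant="G1", seed=6)
        res = et.topsis_rank(et.DecisionMatrix.from_schema(X, schema))
        assert res.closeness["G1"] == pytest.approx(1.0)
        assert res.closeness["G2"] == pytest.approx(0.0)

    def test_identical_rows_undefined(self, schema):
        row = np.linspace(1, 15, 15)
        X = pd.DataFrame([row, row], columns=list(schema.indicators), index=["a", "b"])
        with pytest.raises(ValueError, match="undefined|identical"):
            et.topsis_rank(et.DecisionMatrix.from_schema(X, schema))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, schema, seed):
        X = sd.generate_decision_fixture(5, schema, seed=seed)
        dm = et.DecisionMatrix.from_schema(X, schema)
        res = et.topsis_rank(dm)
        oracle = topsis_oracle(X, dict(schema.directions))
        for j in schema.indicators:
            assert res.weights.w[j] == pytest.approx(oracle["w"][j], abs=1e-12)
        for i in X.index:
            assert res.closeness[i] == pytest.approx(oracle["c"][i], abs=1e-12)

    @given(factor=st.floats(0.1, 1000.0), col=st.integers(0, 13))
    def test_column_scale_invariance(self, factor, col):
        schema = sd.default_schema()
        X = sd.generate_decision_fixture(5, schema, seed=9)
        base = et.topsis_rank(et.DecisionMatrix.from_schema(X, schema))
        scaled = X.copy()
        scaled.iloc[:, col] *= factor
        res = et.topsis_rank(et.DecisionMatrix.from_schema(scaled, schema))
        assert np.allclose(res.closeness, base.closeness, atol=1e-9)
        assert np.allclose(res.weights.w, base.weights.w, atol=1e-9)

    def test_monotone_in_benefit_with_fixed_weights(self, schema):
        X = sd.generate_decision_fixture(5, schema, seed=10)
        w = pd.Series(1.0 / 15, index=list(schema.indicators))
        base = et.topsis_rank(et.DecisionMatrix.from_schema(X, schema), weights=w)
        improved = X.copy()
        improved.loc["G3", "plant_height"] *= 1.5  # benefit indicator
        res = et.topsis_rank(et.DecisionMatrix.from_schema(improved, schema), weights=w)
        assert res.closeness["G3"] >= base.closeness["G3"] - 1e-12

    def test_duplicating_indicator_changes_entropy_weights(self, schema):
        # Documented behaviour: under entropy weighting the duplicated
        # information is counted twice, so weights (and C) shift.
        X = sd.generate_decision_fixture(5, schema, seed=11)
        dm = et.DecisionMatrix.from_schema(X, schema)
        base = et.topsis_rank(dm)
        X2 = X.copy()
        X2["cp_copy"] = X2["cp"]
        directions = dict(schema.directions) | {"cp_copy": "benefit"}
        res = et.topsis_rank(et.DecisionMatrix(X2, directions))
        assert not np.allclose(
            res.weights.w.reindex(base.weights.w.index), base.weights.w
        )


class TestRescale:
    def test_rescale_bounds_and_order(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10)})
        out = et.rescale_to_positive(X)
        assert out["a"].min() == pytest.approx(0.05)
        assert out["a"].max() == pytest.approx(1.0)
        assert (out["a"].rank() == X["a"].rank()).all()
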