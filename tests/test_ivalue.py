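"""The I-value statistic, model variable sets, ranking and enumeration."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cellcycle as cc
from cellcycle.errors import ConfigurationError, UndefinedCorrelationError
from cellcycle.lineage import PANEL_VARIABLES


def _independent_table(n, k=4, seed=0, names=None):
    rng = np.random.default_rng(seed)
    names = names or [f"v{i}" for i in range(k)]
    return pd.DataFrame({name: rng.normal(size=n) for name in names})


def test_independent_series_have_unit_i_value():
    tab = _independent_table(50_000)
    res = cc.i_value(tab, ["v0", "v1", "v2", "v3"])
    assert res.i_value == pytest.approx(1.0, abs=0.01)
    assert res.n == 50_000
    np.testing.assert_allclose(np.diag(res.correlation_matrix), 1.0)


def test_duplicated_variable_collapses_i_to_zero():
    tab = _independent_table(1000)
    tab["dup"] = tab["v0"]
    res = cc.i_value(tab, ["v0", "dup", "v1", "v2"])
    assert res.i_value == 0.0


def test_i_value_bounded_and_order_invariant(ida_table):
    quad = list(cc.model_variable_set("ida"))
    a = cc.i_value(ida_table, quad)
    b = cc.i_value(ida_table, quad[::-1])
    assert 0.0 <= a.i_value <= 1.0
    assert a.i_value == pytest.approx(b.i_value, abs=1e-12)


def test_i_value_invariant_under_affine_rescaling(ida_table):
    quad = cc.model_variable_set("ida")
    a = cc.i_value(ida_table, quad)
    scaled = ida_table.copy()
    scaled["S_b"] = 5.0 * scaled["S_b"] - 2.0
    b = cc.i_value(scaled, quad)
    assert b.i_value == pytest.approx(a.i_value, abs=1e-12)


def test_i_value_converges_to_one_with_sample_size():
    gap_small = 1.0 - cc.i_value(_independent_table(1000, seed=1),
                                 ["v0", "v1", "v2", "v3"]).i_value
    gap_large = 1.0 - cc.i_value(_independent_table(100_000, seed=1),
                                 ["v0", "v1", "v2", "v3"]).i_value
    assert gap_large < gap_small
    assert gap_large < 1e-3


def test_i_value_input_validation(ida_table):
    with pytest.raises(ConfigurationError):
        cc.i_value(ida_table, ["lambda", "S_b"])  # too few
    with pytest.raises(ConfigurationError):
        cc.i_value(ida_table, ["lambda", "S_b", "nope", "s_i"])
    with pytest.raises(ConfigurationError):
        cc.i_value(ida_table.head(5), ["lambda", "S_b", "S_d", "s_i"])
    const = ida_table.copy()
    const["S_b"] = 1.0
    with pytest.raises(UndefinedCorrelationError):
        cc.i_value(const, ["lambda", "S_b", "S_d", "s_i"])


@settings(deadline=None, derandomize=True, max_examples=20)
@given(st.integers(0, 10_000))
def test_i_value_of_arbitrary_gaussian_data_in_unit_interval(seed):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(200, 2))
    tab = pd.DataFrame({
        "a": base[:, 0],
        "b": base[:, 1],
        "c": base[:, 0] + 0.5 * rng.normal(size=200),
        "d": base[:, 1] - base[:, 0] + rng.normal(size=200),
    })
    res = cc.i_value(tab, ["a", "b", "c", "d"])
    assert 0.0 <= res.i_value <= 1.0


def test_model_variable_sets():
    assert cc.model_variable_set("rda") == ("lambda", "delta_id",
                                            "delta_ii", "s_i")
    assert cc.model_variable_set("ida") == ("lambda", "Delta_d",
                                            "delta_ii", "S_b")
    with pytest.raises(ConfigurationError):
        cc.model_variable_set("cccp")  # adjustable model: no fixed quadruple


def test_rank_models_self_consistency(ida_table, rda_table):
    on_ida = cc.rank_models(ida_table, ["rda", "ida"])
    assert on_ida[0][0] == "ida"
    on_rda = cc.rank_models(rda_table, ["rda", "ida"])
    assert on_rda[0][0] == "rda"
    single = cc.rank_models(ida_table, ["ida"])
    assert len(single) == 1 and single[0][0] == "ida"


def test_enumeration_counts_and_bounds(ida_table):
    enum = cc.enumerate_quadruples(ida_table)
    assert len(enum.results) == 3060  # C(18, 4)
    values = [r.i_value for r in enum.results]
    assert all(0.0 <= v <= 1.0 for v in values)
    assert values == sorted(values, reverse=True)
    assert {"RDA", "IDA"} <= set(enum.model_ranks)
    # the critique: even on IDA-generated data, quadruples that correspond
    # to no meaningful model outrank the IDA quadruple
    assert enum.model_ranks["IDA"] > 1
    assert enum.model_ranks["IDA"] < enum.model_ranks["RDA"]


def test_enumeration_requires_full_panel(ida_table):
    with pytest.raises(ConfigurationError):
        cc.enumerate_quadruples(ida_table.drop(columns=["a_i"]))


def test_overlap_warning_emitted_for_multifork_data():
    lin = cc.generate_fixture("ida", "overlap", seed=5)
    tab = cc.extract_observables(lin)
    with pytest.warns(UserWarning, match="overlapping"):
        p = cc.ivalue.warn_if_overlapping(tab)
    assert p is not None and p >= 1


def test_panel_membership_of_all_model_sets():
    for model in ("shc", "ia", "rda", "ida"):
        assert set(cc.model_variable_set(model)) <= set(PANEL_VARIABLES)
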