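"""Sequential parametric synthesizer: recovery, determinism, fidelity."""

import numpy as np
import pandas as pd
import pytest

from immersim.errors import DegenerateModelError, SchemaMismatchError
from immersim.tabular_synthesis import (
    add_incidence,
    fidelity_report,
    fit_synthesizer,
    sample_synthetic,
    synthesize_by_store,
)


def test_marginal_recovery_single_column():
    rng = np.random.default_rng(0)
    table = pd.DataFrame({"x": rng.normal(0.0, 1.0, 1000)})
    model = fit_synthesizer(table, ["x"], log_columns=(), gates={})
    cm = model.columns["x"]
    assert cm.coef[0] == pytest.approx(0.0, abs=0.1)
    assert cm.resid_sd == pytest.approx(1.0, abs=0.1)


def test_balanced_binary_intercept_near_zero():
    table = pd.DataFrame({"b": [0, 1] * 250})
    model = fit_synthesizer(table, ["b"], log_columns=(), gates={})
    assert model.columns["b"].logit_coef[0] == pytest.approx(0.0, abs=1e-9)


def test_deterministic_dependence_gives_zero_residual():
    x = np.linspace(0, 10, 200)
    table = pd.DataFrame({"x": x, "y": 2 * x + 1})
    model = fit_synthesizer(table, ["x", "y"], log_columns=(), gates={})
    assert model.columns["y"].resid_sd == pytest.approx(0.0, abs=1e-8)
    assert model.columns["y"].coef[1] == pytest.approx(2.0, abs=1e-8)


def test_constant_column_named_in_error():
    table = pd.DataFrame({"x": np.arange(25.0), "flat": 3.0})
    with pytest.raises(DegenerateModelError, match="flat"):
        fit_synthesizer(table, ["x", "flat"], log_columns=(), gates={})


def test_sampling_deterministic_and_moment_matched():
    rng = np.random.default_rng(1)
    table = pd.DataFrame(
        {"x": rng.normal(5, 2, 800), "y": rng.normal(0, 1, 800)}
    )
    table["y"] += 0.5 * table["x"]
    model = fit_synthesizer(table, ["x", "y"], log_columns=(), gates={})
    s1 = sample_synthetic(model, 10000, 7)
    s2 = sample_synthetic(model, 10000, 7)
    pd.testing.assert_frame_equal(s1, s2)
    for col in ("x", "y"):
        assert s1[col].mean() == pytest.approx(table[col].mean(), rel=0.05)
        assert s1[col].std() == pytest.approx(table[col].std(), rel=0.05)


def test_visit_order_isolation():
    """Permuting a later variable's training values cannot change an
    earlier variable's synthetic marginal."""
    rng = np.random.default_rng(3)
    table = pd.DataFrame({"x": rng.normal(0, 1, 300), "y": rng.normal(0, 1, 300)})
    shuffled = table.copy()
    shuffled["y"] = rng.permutation(shuffled["y"].to_numpy())
    m1 = fit_synthesizer(table, ["x", "y"], log_columns=(), gates={})
    m2 = fit_synthesizer(shuffled, ["x", "y"], log_columns=(), gates={})
    s1 = sample_synthetic(m1, 500, 11)
    s2 = sample_synthetic(m2, 500, 11)
    np.testing.assert_allclose(s1["x"], s2["x"], rtol=1e-12)


def test_gated_amount_zero_when_gate_zero(default_sessions_with_metrics):
    df = add_incidence(default_sessions_with_metrics)
    ws = df[df["store"] == "WS"]
    model = fit_synthesizer(ws)
    synth = sample_synthetic(model, 2000, 5)
    assert (synth.loc[synth["purchased"] == 0, "purchase_usd"] == 0).all()
    assert (synth.loc[synth["purchased"] == 1, "purchase_usd"] > 0).mean() > 0.95
    assert synth["purchased"].mean() == pytest.approx(ws["purchased"].mean(), abs=0.12)


def test_fidelity_identical_tables_exact_zero():
    rng = np.random.default_rng(4)
    table = pd.DataFrame({"x": rng.normal(size=200), "b": rng.integers(0, 2, 200)})
    rep = fidelity_report(table, table.copy())
    assert rep.mean_quantile_mse == 0.0
    for v in rep.variables:
        assert v.quantile_mse == 0.0
        if v.kind == "continuous":
            assert v.ks_statistic == 0.0 and v.ks_p_value == 1.0


def test_fidelity_detects_shifted_distribution():
    rng = np.random.default_rng(5)
    a = pd.DataFrame({"x": rng.normal(0, 1, 500)})
    b = pd.DataFrame({"x": rng.normal(3, 1, 500)})
    rep = fidelity_report(a, b)
    assert rep.variables[0].ks_p_value < 1e-6
    assert rep.variables[0].quantile_mse > 1.0


def test_fidelity_schema_mismatch():
    with pytest.raises(SchemaMismatchError):
        fidelity_report(
            pd.DataFrame({"x": [1.0, 2.0]}), pd.DataFrame({"y": [1.0, 2.0]}), columns=["x"]
        )


def test_store_stratified_synthesis(default_sessions_with_metrics):
    synth = synthesize_by_store(default_sessions_with_metrics, 400, 17)
    assert set(synth["store"]) == {"WS", "MS"}
    assert len(synth) == 800
    # store-conditional dwell ordering survives synthesis
    means = synth.groupby("store")["dwell_min"].mean()
    assert means["WS"] > means["MS"]
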