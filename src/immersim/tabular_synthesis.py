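"""Sequential parametric synthesis of session tables, with fidelity checks.

The expansion step of the pipeline: fit a chain of simple parametric
conditional models to an observed session table (each variable modelled
given the variables before it in a fixed *visit order*), then sample an
arbitrarily large synthetic table from the chain.  Continuous variables
use normal-linear regressions (optionally on a log1p scale for skewed
amounts), binary variables use logistic regressions, and the purchase
amount is gated by the purchase-incidence flag so zero-inflation is
reproduced exactly in rate.

Fidelity between observed and synthetic tables is summarised per variable
by the two-sample Kolmogorov-Smirnov test (continuous) or the rate
difference (binary), plus a quantile-grid mean squared error (mean squared
difference of the 1st-99th percentile grids), which is independent of the
two sample sizes and exactly zero for identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .errors import DegenerateModelError, SchemaMismatchError

#: default causal visit order for per-store synthesis (store itself is the
#: stratification variable and is not part of the chain)
DEFAULT_VISIT_ORDER = [
    "age",
    "female",
    "loyal",
    "companion",
    "avg_immersion",
    "peak_immersion",
    "dwell_min",
    "purchased",
    "purchase_usd",
]

#: variables fitted on a log1p scale (heavy right tails)
DEFAULT_LOG_COLUMNS = ("dwell_min", "purchase_usd")

#: amount variables only defined when their gate flag is 1
DEFAULT_GATES = {"purchase_usd": "purchased"}


@dataclass
class _ColumnModel:
    name: str
    kind: str                       # "continuous" | "binary"
    parents: list[str]
    log_transform: bool = False
    gate: str | None = None
    # continuous: intercept + coefs on parents, residual sd
    coef: np.ndarray | None = None
    resid_sd: float = 0.0
    # binary: fitted logistic intercept + coefs
    logit_coef: np.ndarray | None = None
    constant_value: float | None = None  # binary columns observed at 0 or 1 rate


@dataclass
class SynthesisModel:
    """Fitted sequential conditional model over ``visit_order``."""

    visit_order: list[str]
    columns: dict[str, _ColumnModel]
    log_columns: tuple[str, ...]
    gates: Mapping[str, str]


def _is_binary(x: pd.Series) -> bool:
    vals = set(pd.unique(x.dropna()))
    return vals.issubset({0, 1, 0.0, 1.0, True, False})


def _design(table: pd.DataFrame, parents: Sequence[str], log_columns: Sequence[str]) -> np.ndarray:
    cols = []
    for p in parents:
        v = table[p].to_numpy(float)
        if p in log_columns:
            v = np.log1p(v)
        cols.append(v)
    if not cols:
        return np.ones((len(table), 1))
    return np.column_stack([np.ones(len(table))] + cols)


def fit_synthesizer(
    table: pd.DataFrame,
    visit_order: Sequence[str] | None = None,
    log_columns: Sequence[str] = DEFAULT_LOG_COLUMNS,
    gates: Mapping[str, str] = DEFAULT_GATES,
) -> SynthesisModel:
    """Fit the sequential conditional chain to an observed table.

    The first variable in ``visit_order`` is modelled marginally; each
    later variable conditions on all variables before it.  A gated
    variable (e.g. purchase amount) is fitted on the rows where its gate
    flag is 1 only.  Requires >= 20 complete rows.
    """
    if visit_order is None:
        visit_order = [c for c in DEFAULT_VISIT_ORDER if c in table.columns]
    visit_order = list(visit_order)
    if len(set(visit_order)) != len(visit_order):
        raise ValueError("visit_order must not repeat variables")
    missing = [c for c in visit_order if c not in table.columns]
    if missing:
        raise SchemaMismatchError(f"columns not in table: {missing}")
    if len(table) < 20:
        raise ValueError("need >= 20 rows to fit the synthesizer")
    if table[visit_order].isna().any().any():
        raise ValueError("table must have no missing values in modelled columns")

    columns: dict[str, _ColumnModel] = {}
    for k, name in enumerate(visit_order):
        gate = gates.get(name)
        # gated amounts are fitted on gate==1 rows, so the gate flag itself
        # (constant there) and other gated variables are not parents
        parents = [p for p in visit_order[:k] if p not in gates and p != gate]
        y = table[name]
        sub = table
        if gate is not None:
            if gate not in visit_order[:k]:
                raise ValueError(f"gate {gate!r} must precede {name!r} in visit_order")
            sub = table[table[gate] == 1]
            y = sub[name]
        if _is_binary(table[name]) and name not in log_columns:
            rate = float(y.mean())
            cm = _ColumnModel(name, "binary", parents, gate=gate)
            if rate in (0.0, 1.0):
                cm.constant_value = rate
            elif parents:
                X = _design(sub, parents, log_columns)[:, 1:]
                lr = LogisticRegression(C=1000.0, max_iter=2000)
                lr.fit(X, y.to_numpy(int))
                cm.logit_coef = np.concatenate([lr.intercept_, lr.coef_.ravel()])
            else:
                cm.logit_coef = np.array([np.log(rate / (1.0 - rate))])
            columns[name] = cm
        else:
            if float(np.std(y.to_numpy(float))) == 0.0:
                raise DegenerateModelError(f"constant column: {name!r}")
            log_t = name in log_columns
            yv = y.to_numpy(float)
            if log_t:
                yv = np.log1p(yv)
            X = _design(sub, parents, log_columns)
            coef, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
            resid = yv - X @ coef
            dof = max(len(yv) - X.shape[1], 1)
            columns[name] = _ColumnModel(
                name,
                "continuous",
                parents,
                log_transform=log_t,
                gate=gate,
                coef=coef,
                resid_sd=float(np.sqrt((resid**2).sum() / dof)),
            )
    return SynthesisModel(visit_order, columns, tuple(log_columns), dict(gates))


def sample_synthetic(model: SynthesisModel, n: int, rng_seed: int) -> pd.DataFrame:
    """Draw ``n`` rows sequentially from the fitted conditionals."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    out = pd.DataFrame(index=range(n))
    for name in model.visit_order:
        cm = model.columns[name]
        if cm.kind == "binary":
            if cm.constant_value is not None:
                out[name] = int(cm.constant_value)
                continue
            X = _design(out, cm.parents, model.log_columns)
            logit = X @ cm.logit_coef
            p = 1.0 / (1.0 + np.exp(-logit))
            out[name] = (rng.random(n) < p).astype(int)
        else:
            X = _design(out, cm.parents, model.log_columns)
            mu = X @ cm.coef
            v = mu + rng.normal(0.0, cm.resid_sd, size=n)
            if cm.log_transform:
                v = np.expm1(v)
                v = np.maximum(v, 0.0)
            if cm.gate is not None:
                v = np.where(out[cm.gate].to_numpy(int) == 1, v, 0.0)
            out[name] = v
    return out


@dataclass(frozen=True)
class VariableFidelity:
    name: str
    kind: str
    ks_statistic: float | None
    ks_p_value: float | None
    rate_difference: float | None
    quantile_mse: float


@dataclass(frozen=True)
class FidelityReport:
    variables: list[VariableFidelity]
    mean_quantile_mse: float

    def to_dict(self) -> dict:
        return {
            "variables": [v.__dict__ for v in self.variables],
            "mean_quantile_mse": self.mean_quantile_mse,
        }

    @property
    def min_ks_p(self) -> float:
        ps = [v.ks_p_value for v in self.variables if v.ks_p_value is not None]
        return min(ps) if ps else float("nan")


def fidelity_report(
    observed: pd.DataFrame, synthetic: pd.DataFrame, columns: Sequence[str] | None = None
) -> FidelityReport:
    """Per-variable distributional agreement between two tables.

    Continuous variables: two-sample KS statistic/p-value and the mean
    squared difference of the two tables' 1st-99th percentile grids.
    Binary variables: rate difference (squared for the MSE summary).
    """
    if columns is None:
        columns = [c for c in observed.columns if c in synthetic.columns
                   and pd.api.types.is_numeric_dtype(observed[c])]
    miss = [c for c in columns if c not in observed.columns or c not in synthetic.columns]
    if miss:
        raise SchemaMismatchError(f"columns missing from one table: {miss}")
    grid = np.arange(1, 100)
    variables = []
    for c in columns:
        x = observed[c].to_numpy(float)
        y = synthetic[c].to_numpy(float)
        if _is_binary(observed[c]) and _is_binary(synthetic[c]):
            diff = float(y.mean() - x.mean())
            variables.append(VariableFidelity(c, "binary", None, None, diff, diff**2))
        else:
            qx = np.percentile(x, grid)
            qy = np.percentile(y, grid)
            mse = float(np.mean((qx - qy) ** 2))
            if np.array_equal(np.sort(x), np.sort(y)):
                ks, p = 0.0, 1.0
            else:
                res = stats.ks_2samp(x, y, method="asymp")
                ks, p = float(res.statistic), float(res.pvalue)
            variables.append(VariableFidelity(c, "continuous", ks, p, None, mse))
    mean_mse = float(np.mean([v.quantile_mse for v in variables])) if variables else 0.0
    return FidelityReport(variables, mean_mse)


def add_incidence(table: pd.DataFrame, amount_col: str = "purchase_usd") -> pd.DataFrame:
    """Insert the binary ``purchased`` gate flag ahead of synthesis if absent."""
    if "purchased" in table.columns:
        return table
    out = table.copy()
    out["purchased"] = (out[amount_col].to_numpy(float) > 0).astype(int)
    return out


def synthesize_by_store(
    table: pd.DataFrame,
    n_per_store: int,
    rng_seed: int,
    visit_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Store-stratified synthesis: one chain per store arm, concatenated."""
    root = np.random.SeedSequence(rng_seed)
    frames = []
    stores = list(table["store"].drop_duplicates())
    for store, child in zip(stores, root.spawn(len(stores))):
        sub = table[table["store"] == store]
        model = fit_synthesizer(sub, visit_order=visit_order)
        synth = sample_synthetic(model, n_per_store, int(child.generate_state(1)[0] % (2**31)))
        synth.insert(0, "store", store)
        frames.append(synth)
    return pd.concat(frames, ignore_index=True)
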