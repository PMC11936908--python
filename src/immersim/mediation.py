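"""Linear mediation of purchases by dwell time, with bootstrap inference.

The causal chain under test: the associate's Peak Immersion (predictor X)
raises the customer's dwell time (mediator M), which in turn raises the
purchase amount (outcome Y).  Two linear equations are fitted by ordinary
least squares (the maximum-likelihood estimator under Gaussian errors):

    M = i1 + a*X            (+ covariates)
    Y = i2 + c'*X + b*M     (+ covariates)

The indirect effect is a*b, the direct effect is c', and for this linear
specification total = c' + a*b exactly equals the slope of Y on X alone
(with the same covariates).  Uncertainty for the indirect effect comes
from a percentile bootstrap over row resampling; the closed-form Sobel
normal approximation is reported as a complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .stats_battery import TestResult


@dataclass(frozen=True)
class MediationSpec:
    predictor: str = "peak_immersion"
    mediator: str = "dwell_min"
    outcome: str = "purchase_usd"
    covariates: tuple[str, ...] = ()
    standardize: bool = False
    bootstrap_reps: int = 5000
    ci_level: float = 0.95
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")


@dataclass(frozen=True)
class PathEstimate:
    estimate: float
    se: float
    p_value: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class MediationResult:
    a_path: PathEstimate        # X -> M
    b_path: PathEstimate        # M -> Y | X
    c_prime: PathEstimate       # direct X -> Y | M
    indirect: PathEstimate      # a*b, bootstrap CI
    total: float                # c' + a*b
    sobel: TestResult
    n: int
    spec: MediationSpec

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "a_path": self.a_path.__dict__,
            "b_path": self.b_path.__dict__,
            "c_prime": self.c_prime.__dict__,
            "indirect": self.indirect.__dict__,
            "total": self.total,
            "sobel_z": self.sobel.statistic,
            "sobel_p": self.sobel.p_value,
            "spec": {
                "predictor": self.spec.predictor,
                "mediator": self.spec.mediator,
                "outcome": self.spec.outcome,
                "covariates": list(self.spec.covariates),
                "standardize": self.spec.standardize,
                "bootstrap_reps": self.spec.bootstrap_reps,
                "ci_level": self.spec.ci_level,
                "rng_seed": self.spec.rng_seed,
            },
        }


def sobel_test(a: float, se_a: float, b: float, se_b: float) -> TestResult:
    """Closed-form normal test of the product a*b."""
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be > 0")
    se = np.sqrt(a**2 * se_b**2 + b**2 * se_a**2)
    z = 0.0 if se == 0 else a * b / se
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(statistic=float(z), df=np.nan, p_value=float(p))


def _check_collinear(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"collinear design columns among {list(names)}")


def _slopes(X_m: np.ndarray, m: np.ndarray, X_y: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(a, b, c') from the two least-squares fits; columns: [1, X, covs] and [1, X, M, covs]."""
    beta_m, _, _, _ = np.linalg.lstsq(X_m, m, rcond=None)
    beta_y, _, _, _ = np.linalg.lstsq(X_y, y, rcond=None)
    return float(beta_m[1]), float(beta_y[2]), float(beta_y[1])


def fit_mediation(table: pd.DataFrame, spec: MediationSpec) -> MediationResult:
    """Estimate paths, bootstrap the indirect effect, and run the Sobel test."""
    cols = [spec.predictor, spec.mediator, spec.outcome, *spec.covariates]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    data = table[cols].astype(float)
    if len(data) < 30:
        raise ValueError("need >= 30 rows")
    if data.isna().any().any():
        raise ValueError("missing values in used columns")

    x = data[spec.predictor].to_numpy()
    m = data[spec.mediator].to_numpy()
    y = data[spec.outcome].to_numpy()
    covs = data[list(spec.covariates)].to_numpy() if spec.covariates else np.empty((len(data), 0))
    if spec.standardize:
        x = (x - x.mean()) / x.std(ddof=1)
        m = (m - m.mean()) / m.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1)

    n = len(x)
    ones = np.ones(n)
    X_m = np.column_stack([ones, x, covs])
    X_y = np.column_stack([ones, x, m, covs])
    _check_collinear(X_y, ["const", spec.predictor, spec.mediator, *spec.covariates])

    fit_m = sm.OLS(m, X_m).fit()
    fit_y = sm.OLS(y, X_y).fit()
    a, se_a, p_a = fit_m.params[1], fit_m.bse[1], fit_m.pvalues[1]
    c_prime, se_c, p_c = fit_y.params[1], fit_y.bse[1], fit_y.pvalues[1]
    b, se_b, p_b = fit_y.params[2], fit_y.bse[2], fit_y.pvalues[2]
    indirect = a * b
    total = c_prime + indirect

    rng = np.random.default_rng(spec.rng_seed)
    boot = np.empty((spec.bootstrap_reps, 4))
    for r in range(spec.bootstrap_reps):
        idx = rng.integers(0, n, size=n)
        ab = _slopes(X_m[idx], m[idx], X_y[idx], y[idx])
        boot[r] = (ab[0], ab[1], ab[2], ab[0] * ab[1])
    alpha = 1.0 - spec.ci_level
    qs = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)

    tcrit = stats.t.ppf(1 - alpha / 2, n - X_y.shape[1])

    def path(est, se, p) -> PathEstimate:
        return PathEstimate(float(est), float(se), float(p),
                            float(est - tcrit * se), float(est + tcrit * se))

    indirect_se = float(boot[:, 3].std(ddof=1))
    sob = sobel_test(a, se_a, b, se_b)
    indirect_pe = PathEstimate(float(indirect), indirect_se, float(sob.p_value),
                               float(qs[0, 3]), float(qs[1, 3]))
    return MediationResult(
        a_path=path(a, se_a, p_a),
        b_path=path(b, se_b, p_b),
        c_prime=path(c_prime, se_c, p_c),
        indirect=indirect_pe,
        total=float(total),
        sobel=sob,
        n=n,
        spec=spec,
    )
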