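"""Two-good procedural-utility choice model.

A shopper allocates income M between two stores selling at the same price
p.  Store 1 additionally provides a valued shopping experience, entering
utility through a multiplier e on the log-consumption term:

    max_{c1, c2}  e * ln(c1) + ln(c2)   s.t.  p*c1 + p*c2 <= M

This is a Cobb-Douglas problem, so the optimal spend in the experience
store is the expenditure share  p*c1* = M * e / (1 + e), independent of the
price level.  A second, literal variant M * e / (p + e) is also exposed
(see :func:`optimal_spend`); the two coincide at p = 1, the numeraire used
throughout the cohort simulator.

The experience multiplier is driven by the neurologic value of the
encounter, and the model links it to behaviour through two monotone
channels: spend in the experience store and dwell time are both increasing
in e, with dwell assumed proportional to e.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

FormulaVariant = Literal["derived", "as_printed"]


@dataclass(frozen=True)
class UtilityParams:
    """Model parameters: experience multiplier e, price level p, income M."""

    e: float
    p: float
    income: float

    def __post_init__(self) -> None:
        if self.p <= 0:
            raise ValueError("price must be > 0")
        if self.income <= 0:
            raise ValueError("income must be > 0")
        if self.e < 0:
            raise ValueError("experience multiplier must be >= 0")


@dataclass(frozen=True)
class OptimumResult:
    """Solved optimum: spend and consumption in each store."""

    spend_store1: float
    spend_store2: float
    c1: float
    c2: float
    formula_variant: str
    corner: bool = False


def utility(c1: float, c2: float, e: float) -> float:
    """Objective e*ln(c1) + ln(c2)."""
    if c1 <= 0 or c2 <= 0:
        raise ValueError("consumption must be > 0")
    return e * np.log(c1) + np.log(c2)


def optimal_spend(params: UtilityParams, variant: FormulaVariant = "derived") -> OptimumResult:
    """Closed-form optimal spend in the experience store.

    ``derived`` (default) is the Cobb-Douglas expenditure share
    M*e/(1+e); ``as_printed`` is the literal M*e/(p+e) form.  At p = 1
    they coincide.  e = 0 gives the corner solution (all spend in store 2).
    """
    e, p, m = params.e, params.p, params.income
    if variant == "derived":
        s1 = m * e / (1.0 + e)
    elif variant == "as_printed":
        s1 = m * e / (p + e)
    else:
        raise ValueError(f"unknown variant: {variant!r}")
    s2 = m - s1
    return OptimumResult(
        spend_store1=float(s1),
        spend_store2=float(s2),
        c1=float(s1 / p),
        c2=float(s2 / p),
        formula_variant=variant,
        corner=(e == 0),
    )


def numeric_optimum(params: UtilityParams, grid_step: float = 1e-3) -> OptimumResult:
    """Grid-search maximisation of the objective over the budget line.

    Independent numeric oracle for :func:`optimal_spend`: evaluates the
    utility at spend levels s1 in (0, M) spaced by ``grid_step`` and
    returns the argmax, which lies within ``grid_step`` of the true
    optimum.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    e, p, m = params.e, params.p, params.income
    if grid_step >= m:
        raise ValueError("grid_step must be smaller than income")
    s1 = np.arange(grid_step, m, grid_step)
    c1 = s1 / p
    c2 = (m - s1) / p
    u = e * np.log(c1) + np.log(c2)
    k = int(np.argmax(u))
    return OptimumResult(
        spend_store1=float(s1[k]),
        spend_store2=float(m - s1[k]),
        c1=float(c1[k]),
        c2=float(c2[k]),
        formula_variant="numeric",
    )


def predicted_dwell(e: float, kappa: float) -> float:
    """Dwell time implied by the proportionality of experience value and time.

    ``kappa`` is minutes of dwell per unit of e; a shopper deriving no
    experiential value leaves immediately.
    """
    if e < 0:
        raise ValueError("experience multiplier must be >= 0")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    return kappa * e
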