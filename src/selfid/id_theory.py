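"""Analytic metrics for the evolution of the selfing rate.

Without pollen discounting, a rare modifier allele that shifts the selfing
rate of its carrier from ``alpha`` to ``alpha + f(alpha)`` has mean fitness

    w_m = w_M + (E[w_self f] / E[w_out f] - 1/2) * E[w_out f],

where the resident mean fitness is
``w_M = E[alpha w_self + (1-alpha)/2 w_out] + E[(1-alpha)/2 w_out]``
(selfed offspring, outcrossed ovules, exported pollen). Writing
``delta_f = 1 - E[w_self f] / E[w_out f]``, a selfing-increasing modifier
(``E[w_out f] > 0``) invades exactly when ``delta_f < 1/2``.

Two linear approximations make ``delta_f`` measurable from per-family data.
With ``rho_self``/``rho_out`` the regression slopes of offspring fitness on
maternal selfing rate and ``V_alpha`` the selfing-rate variance:

* modifier form:
  ``delta = 1 - (E[w_self] + rho_self V_alpha g) / (E[w_out] + rho_out V_alpha g)``
  with ``g = f'(alpha_bar) / f(alpha_bar)``; constant ``f`` reduces this to
  the baseline ``delta0 = 1 - E[w_self]/E[w_out]``.
* quantitative-trait form: the selection gradient on mean selfing rate is
  ``w_out(ab) * ((w_self(ab) + ab rho_self + (1-ab)/2 rho_out)/w_out(ab) - 1/2)``
  at ``ab = alpha_bar``, which defines
  ``delta = 1 - (w_self(ab) + ab rho_self + (1-ab)/2 rho_out) / w_out(ab)``;
  the mean selfing rate increases exactly when this ``delta < 1/2``.

Inputs can come from a simulated family assay
(:func:`theory_inputs_from_assay`) or from any empirical per-family table
of ``(alpha, w_self, w_out)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import bisect

from .id_metrics import corr_and_slope

__all__ = [
    "ModifierEffect",
    "TheoryInputs",
    "InvasionResult",
    "invasion_fitness",
    "delta_eq_modifier",
    "delta_eq_gradient",
    "selection_gradient",
    "invasion_threshold",
    "theory_inputs_from_assay",
    "read_family_table",
    "theory_report",
]


@dataclass(frozen=True)
class ModifierEffect:
    """Effect function ``f(alpha)`` of a rare selfing-rate modifier.

    ``f(alpha)`` is the change in selfing rate when one resident allele is
    replaced in a background with selfing rate ``alpha``; ``g(alpha_bar) =
    f'(alpha_bar)/f(alpha_bar)`` is the log-derivative entering the
    association correction.
    """

    kind: str
    f: Callable[[np.ndarray], np.ndarray]
    g: Callable[[float], float]
    magnitude: float = 0.01

    @staticmethod
    def constant(magnitude: float = 0.01) -> "ModifierEffect":
        """Same selfing-rate change in every background: ``g = 0``."""
        return ModifierEffect(
            kind="constant",
            f=lambda a: np.full_like(np.asarray(a, dtype=float), magnitude),
            g=lambda ab: 0.0,
            magnitude=magnitude,
        )

    @staticmethod
    def proportional_outcrossing(magnitude: float = 0.01) -> "ModifierEffect":
        """``f(alpha) = c (1 - alpha)``, hence ``g(ab) = -1/(1-ab)``."""
        return ModifierEffect(
            kind="proportional_outcrossing",
            f=lambda a: magnitude * (1.0 - np.asarray(a, dtype=float)),
            g=lambda ab: -1.0 / (1.0 - ab),
            magnitude=magnitude,
        )

    @staticmethod
    def custom(
        f: Callable[[np.ndarray], np.ndarray],
        g: Callable[[float], float] | None = None,
        eps: float = 1e-6,
    ) -> "ModifierEffect":
        """User-supplied ``f``; ``g`` defaults to a central finite difference."""
        if g is None:

            def g(ab: float) -> float:
                fa = float(f(np.asarray(ab)))
                d = (float(f(np.asarray(ab + eps))) - float(f(np.asarray(ab - eps)))) / (
                    2 * eps
                )
                return d / fa

        return ModifierEffect(kind="custom", f=f, g=g)


@dataclass(frozen=True)
class TheoryInputs:
    """Population summaries feeding the analytic ID metrics.

    ``E_wself``/``E_wout`` are plain means of selfed/outcrossed offspring
    fitness; ``w_self_bar``/``w_out_bar`` are the linear-fit values at the
    mean selfing rate (identical to the means under OLS at the mean);
    ``rho_self``/``rho_out`` are the fitness-on-alpha regression slopes
    (or Pearson correlations, if so constructed).
    """

    E_wself: float
    E_wout: float
    w_self_bar: float
    w_out_bar: float
    alpha_bar: float
    rho_self: float
    rho_out: float
    V_alpha: float

    def __post_init__(self) -> None:
        if not self.E_wout > 0:
            raise ValueError(f"E_wout must be > 0, got {self.E_wout}")
        if not 0.0 <= self.V_alpha <= 0.25 + 1e-12:
            raise ValueError(f"V_alpha must be in [0, 0.25], got {self.V_alpha}")
        if not 0.0 < self.alpha_bar < 1.0:
            raise ValueError(f"alpha_bar must be in (0, 1), got {self.alpha_bar}")


@dataclass(frozen=True)
class InvasionResult:
    """Mean fitness of resident and modifier alleles and the invasion call."""

    w_M: float
    w_m: float
    advantage: float
    delta_f: float

    @property
    def invades(self) -> bool:
        return self.advantage > 0


def _table_arrays(samples) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = pd.DataFrame(samples)
    missing = {"alpha", "w_self", "w_out"} - set(t.columns)
    if missing:
        raise ValueError(f"family table missing columns: {sorted(missing)}")
    return (
        np.asarray(t["alpha"], dtype=float),
        np.asarray(t["w_self"], dtype=float),
        np.asarray(t["w_out"], dtype=float),
    )


def invasion_fitness(samples, effect: ModifierEffect) -> InvasionResult:
    """Exact modifier invasion analysis on a per-family table.

    Expectations are sample means over the table's families. The advantage
    ``w_m - w_M = E[w_self f] - E[w_out f]/2`` is positive exactly when
    ``delta_f = 1 - E[w_self f]/E[w_out f] < 1/2`` (for ``E[w_out f] > 0``).
    """
    alpha, w_self, w_out = _table_arrays(samples)
    if alpha.size < 1:
        raise ValueError("need at least one family")
    fv = np.asarray(effect.f(alpha), dtype=float)
    e_wof = float(np.mean(w_out * fv))
    if e_wof == 0.0:
        raise ValueError("E[w_out * f(alpha)] is zero; delta_f undefined")
    e_wsf = float(np.mean(w_self * fv))
    w_M = float(np.mean(alpha * w_self + 0.5 * (1 - alpha) * w_out)) + 0.5 * float(
        np.mean((1 - alpha) * w_out)
    )
    advantage = e_wsf - 0.5 * e_wof
    return InvasionResult(
        w_M=w_M,
        w_m=w_M + advantage,
        advantage=advantage,
        delta_f=1.0 - e_wsf / e_wof,
    )


def delta_eq_modifier(inputs: TheoryInputs, g: float | ModifierEffect) -> float:
    """Association-corrected ID for a modifier with log-derivative ``g``.

    ``delta = 1 - (E_wself + rho_self V g) / (E_wout + rho_out V g)``.
    With ``g = 0`` (constant-effect modifier) or vanishing associations this
    is the baseline ``delta0``.
    """
    if isinstance(g, ModifierEffect):
        g = g.g(inputs.alpha_bar)
    denom = inputs.E_wout + inputs.rho_out * inputs.V_alpha * g
    if denom == 0.0:
        raise ValueError("denominator of association-corrected ID vanishes")
    num = inputs.E_wself + inputs.rho_self * inputs.V_alpha * g
    return 1.0 - num / denom


def delta_eq_gradient(inputs: TheoryInputs) -> float:
    """Quantitative-genetic ID governing the mean selfing rate.

    ``delta = 1 - (w_self_bar + ab rho_self + (1-ab)/2 rho_out) / w_out_bar``
    at ``ab = alpha_bar``; the mean selfing rate increases iff this is
    below 1/2.
    """
    if not inputs.w_out_bar > 0:
        raise ValueError(f"w_out_bar must be > 0, got {inputs.w_out_bar}")
    ab = inputs.alpha_bar
    num = inputs.w_self_bar + ab * inputs.rho_self + 0.5 * (1 - ab) * inputs.rho_out
    return 1.0 - num / inputs.w_out_bar


def selection_gradient(inputs: TheoryInputs) -> float:
    """Selection gradient on the mean selfing rate (linear approximation).

    ``w_out_bar * ((w_self_bar + ab rho_self + (1-ab)/2 rho_out)/w_out_bar - 1/2)``;
    its sign equals the sign of ``1/2 - delta_eq_gradient(inputs)``.
    """
    return inputs.w_out_bar * (0.5 - delta_eq_gradient(inputs))


def _default_scenario(delta: float, w_out: float = 0.8) -> pd.DataFrame:
    """Association-free family table whose baseline ID equals ``delta``."""
    alpha = np.linspace(0.1, 0.9, 9)
    return pd.DataFrame(
        {
            "alpha": alpha,
            "w_self": np.full_like(alpha, (1.0 - delta) * w_out),
            "w_out": np.full_like(alpha, w_out),
        }
    )


def invasion_threshold(
    effect: ModifierEffect | None = None,
    scenario: Callable[[float], pd.DataFrame] | None = None,
    *,
    mode: str = "invasion",
    lo: float = 0.0,
    hi: float = 1.0,
    tol: float = 1e-6,
    w_out_bar: float = 0.8,
    alpha_bar: float = 0.5,
    V_alpha: float = 0.04,
) -> float:
    """Critical ID ``delta*`` at which selfing stops being favored.

    ``mode='invasion'`` bisects the sign of the modifier advantage computed
    on ``scenario(delta)`` family tables (default: association-free tables
    with baseline ID ``delta``). ``mode='gradient'`` bisects the sign of the
    selection gradient with both association terms set to zero. Raises if
    the objective does not change sign on ``[lo, hi]``.
    """
    if mode == "invasion":
        if effect is None:
            effect = ModifierEffect.constant()
        if scenario is None:
            scenario = _default_scenario

        def objective(delta: float) -> float:
            return invasion_fitness(scenario(delta), effect).advantage

    elif mode == "gradient":

        def objective(delta: float) -> float:
            inputs = TheoryInputs(
                E_wself=(1.0 - delta) * w_out_bar,
                E_wout=w_out_bar,
                w_self_bar=(1.0 - delta) * w_out_bar,
                w_out_bar=w_out_bar,
                alpha_bar=alpha_bar,
                rho_self=0.0,
                rho_out=0.0,
                V_alpha=V_alpha,
            )
            return selection_gradient(inputs)

    else:
        raise ValueError(f"unknown mode {mode!r}")
    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if np.sign(f_lo) == np.sign(f_hi):
        raise ValueError(f"no sign change of the advantage on [{lo}, {hi}]")
    return float(bisect(objective, lo, hi, xtol=tol))


def theory_inputs_from_assay(
    assay, use_pearson: bool = False, fitted_at_mean: bool = True
) -> TheoryInputs:
    """Build :class:`TheoryInputs` from a per-family ``(alpha, w_self, w_out)`` table.

    ``rho_self``/``rho_out`` are regression slopes by default (Pearson
    correlations with ``use_pearson=True``). ``w_self_bar``/``w_out_bar``
    are the linear-fit values at the mean selfing rate, which for OLS
    coincide with the sample means; ``fitted_at_mean=False`` keeps the
    sample means explicitly.
    """
    alpha, w_self, w_out = _table_arrays(assay)
    r_s, b_s = corr_and_slope(alpha, w_self)
    r_o, b_o = corr_and_slope(alpha, w_out)
    rho_self = r_s if use_pearson else b_s
    rho_out = r_o if use_pearson else b_o
    e_ws, e_wo = float(w_self.mean()), float(w_out.mean())
    # OLS fitted value at x = mean(x) is mean(y); kept as an explicit branch
    # so a different fit could be slotted in.
    ws_bar, wo_bar = (e_ws, e_wo) if fitted_at_mean else (e_ws, e_wo)
    return TheoryInputs(
        E_wself=e_ws,
        E_wout=e_wo,
        w_self_bar=ws_bar,
        w_out_bar=wo_bar,
        alpha_bar=float(alpha.mean()),
        rho_self=float(rho_self),
        rho_out=float(rho_out),
        V_alpha=float(alpha.var()),
    )


def read_family_table(path) -> pd.DataFrame:
    """Read a per-family table (TSV with columns alpha, w_self, w_out)."""
    table = pd.read_csv(path, sep="\t", comment="#")
    _table_arrays(table)  # validates columns
    return table


def theory_report(
    table: pd.DataFrame,
    effect: ModifierEffect,
    use_pearson: bool = False,
) -> dict:
    """All analytic ID metrics for one family table and modifier effect."""
    inputs = theory_inputs_from_assay(table, use_pearson=use_pearson)
    inv = invasion_fitness(table, effect)
    delta0 = 1.0 - inputs.E_wself / inputs.E_wout
    return {
        "delta0": delta0,
        "delta_modifier": delta_eq_modifier(inputs, effect),
        "delta_gradient": delta_eq_gradient(inputs),
        "selection_gradient": selection_gradient(inputs),
        "delta_f_exact": inv.delta_f,
        "advantage": inv.advantage,
        "invades": inv.invades,
        "alpha_bar": inputs.alpha_bar,
        "V_alpha": inputs.V_alpha,
        "rho_self": inputs.rho_self,
        "rho_out": inputs.rho_out,
    }
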