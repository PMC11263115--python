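"""Inbreeding-depression assays and selfing-rate association statistics.

The measurement layer around the simulator: each adult is assayed with one
selfed and one outcrossed offspring whose deleterious fitness component
``w2`` gives the family-level inbreeding depression ``1 - w_self/w_out``,
and the population-level baseline ``delta0 = 1 - mean(w_self)/mean(w_out)``
(a ratio of means, not a mean of ratios). Association statistics between
the maternal selfing rate ``alpha`` and mutation load / offspring fitness
are reported both as Pearson correlations and as OLS regression slopes: the
slope is what enters the analytic ID metrics of :mod:`selfid.id_theory`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from . import _kernels
from .genome_model import SimParams

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .sim_engine import Population, RNGStream

__all__ = [
    "RECORD_COLUMNS",
    "AssociationSummary",
    "family_assay",
    "population_id",
    "association_summary",
    "binned_homozygosity",
    "summarize_equilibrium",
    "corr_and_slope",
    "generation_metrics",
]

#: Column order of per-generation metric records (and of the TSV writer).
RECORD_COLUMNS = [
    "generation",
    "alpha_bar",
    "V_alpha",
    "mean_mut_copies",
    "mean_n_het",
    "mean_n_hom",
    "mean_homozygosity",
    "delta0",
    "corr_alpha_nmut",
    "corr_alpha_wout",
    "corr_alpha_wself",
    "corr_alpha_famID",
    "slope_alpha_wself",
    "slope_alpha_wout",
]


def corr_and_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation and OLS slope of ``y`` on ``x``.

    Both are NaN when ``Var(x) = 0``; the correlation is additionally NaN
    when ``Var(y) = 0``. The identity ``slope * Var(x) = Cov(x, y)`` holds
    by construction.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    vx = x.var()
    vy = y.var()
    if vx == 0.0:
        return math.nan, math.nan
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    slope = cov / vx
    r = cov / math.sqrt(vx * vy) if vy > 0.0 else math.nan
    return r, slope


def family_assay(
    adults: "Population", params: SimParams, rng: "RNGStream"
) -> pd.DataFrame:
    """Selfed/outcrossed offspring assay, one row per adult.

    Columns: ``alpha`` (maternal selfing rate), ``w_self``, ``w_out``
    (deleterious fitness component ``w2`` of one selfed and one outcrossed
    assay offspring) and ``family_id = 1 - w_self/w_out`` (NaN where
    ``w_out = 0``). Assay offspring are generated with the production
    meiosis/mutation path but are never added to the population.
    """
    if adults.N < 2:
        raise ValueError("family assay needs at least 2 adults")
    w_self, w_out = _kernels.family_assay_kernel(
        adults.trait,
        adults.positions,
        adults.offsets,
        params.s,
        params.h,
        params.L,
        params.U,
        params.U_z,
        params.n_z,
        rng.child_seed(),
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        fam = np.where(w_out > 0, 1.0 - w_self / np.where(w_out > 0, w_out, 1.0), np.nan)
    return pd.DataFrame(
        {"alpha": adults.alpha, "w_self": w_self, "w_out": w_out, "family_id": fam}
    )


def population_id(assay: pd.DataFrame) -> float:
    """Population-level baseline ID: ``1 - mean(w_self) / mean(w_out)``."""
    mean_out = float(np.mean(assay["w_out"]))
    if not mean_out > 0:
        raise ValueError("mean outcrossed-offspring fitness is zero")
    return 1.0 - float(np.mean(assay["w_self"])) / mean_out


@dataclass
class AssociationSummary:
    """Fig-1-style association statistics of one adult population."""

    alpha_bar: float
    V_alpha: float
    mean_homozygosity: float
    corr_alpha_nmut: float
    slope_alpha_nmut: float
    corr_alpha_wout: float
    slope_alpha_wout: float
    corr_alpha_wself: float
    slope_alpha_wself: float
    corr_alpha_famID: float
    slope_alpha_famID: float
    n_famid_excluded: int
    alpha_defined: bool
    homozygosity_profile: pd.DataFrame = field(repr=False, default=None)

    def rho(self, which: str, use_pearson: bool = False) -> float:
        """``rho_self`` or ``rho_out`` as used by the analytic ID metrics.

        Defaults to the regression slope; ``use_pearson=True`` returns the
        Pearson correlation instead.
        """
        if which not in ("self", "out"):
            raise ValueError("which must be 'self' or 'out'")
        if use_pearson:
            return getattr(self, f"corr_alpha_w{which}")
        return getattr(self, f"slope_alpha_w{which}")

    @property
    def rho_self(self) -> float:
        return self.slope_alpha_wself

    @property
    def rho_out(self) -> float:
        return self.slope_alpha_wout


def association_summary(
    adults: "Population", assay: pd.DataFrame, n_bins: int = 10
) -> AssociationSummary:
    """Correlations/slopes of ``alpha`` against load and offspring fitness.

    Families with undefined family-level ID (``w_out = 0``) are excluded
    from the family-ID statistics, with the exclusion count reported. When
    ``alpha`` has zero variance all correlations and slopes are NaN and
    ``alpha_defined`` is False.
    """
    if len(assay) < 3:
        raise ValueError("need at least 3 families for association statistics")
    alpha = np.asarray(assay["alpha"], dtype=np.float64)
    v_alpha = float(alpha.var())
    nmut = adults.mutation_copies
    r_nm, b_nm = corr_and_slope(alpha, nmut)
    r_wo, b_wo = corr_and_slope(alpha, assay["w_out"])
    r_ws, b_ws = corr_and_slope(alpha, assay["w_self"])
    ok = np.isfinite(assay["family_id"])
    n_excl = int((~ok).sum())
    if ok.sum() >= 3:
        r_f, b_f = corr_and_slope(alpha[ok], assay["family_id"][ok])
    else:
        r_f = b_f = math.nan
    return AssociationSummary(
        alpha_bar=float(alpha.mean()),
        V_alpha=v_alpha,
        mean_homozygosity=float(adults.homozygosity.mean()),
        corr_alpha_nmut=r_nm,
        slope_alpha_nmut=b_nm,
        corr_alpha_wout=r_wo,
        slope_alpha_wout=b_wo,
        corr_alpha_wself=r_ws,
        slope_alpha_wself=b_ws,
        corr_alpha_famID=r_f,
        slope_alpha_famID=b_f,
        n_famid_excluded=n_excl,
        alpha_defined=v_alpha > 0.0,
        homozygosity_profile=binned_homozygosity(adults, n_bins),
    )


def binned_homozygosity(adults: "Population", n_bins: int = 10) -> pd.DataFrame:
    """Mean individual homozygosity per equal-width selfing-rate bin.

    Bins partition [0, 1] with half-open edges ``[lo, hi)`` (the last bin is
    closed at 1). Empty bins carry NaN means; few individuals are expected
    near ``alpha = 0`` or ``alpha = 1``.
    """
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(adults.alpha, edges[1:-1], right=False), 0, n_bins - 1)
    frac = adults.homozygosity
    mean = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=np.int64)
    for b in range(n_bins):
        sel = idx == b
        count[b] = sel.sum()
        if count[b]:
            mean[b] = frac[sel].mean()
    return pd.DataFrame(
        {
            "alpha_lo": edges[:-1],
            "alpha_hi": edges[1:],
            "mean_homozygosity": mean,
            "n": count,
        }
    )


def generation_metrics(
    pop: "Population",
    w_self: np.ndarray | None = None,
    w_out: np.ndarray | None = None,
) -> dict:
    """One record row for the current adult population.

    Composition metrics are always computed; ``delta0`` and association
    columns need the assay arrays and are NaN when those are absent (or
    undefined: zero alpha variance, zero mean ``w_out``).
    """
    alpha = pop.alpha
    row = {
        "generation": pop.generation,
        "alpha_bar": float(alpha.mean()),
        "V_alpha": float(alpha.var()),
        "mean_mut_copies": float(pop.mutation_copies.mean()),
        "mean_n_het": float(pop.n_het.mean()),
        "mean_n_hom": float(pop.n_hom.mean()),
        "mean_homozygosity": float(pop.homozygosity.mean()),
        "delta0": math.nan,
        "corr_alpha_nmut": math.nan,
        "corr_alpha_wout": math.nan,
        "corr_alpha_wself": math.nan,
        "corr_alpha_famID": math.nan,
        "slope_alpha_wself": math.nan,
        "slope_alpha_wout": math.nan,
    }
    if w_self is None or w_out is None:
        return row
    mean_out = float(np.mean(w_out))
    if mean_out > 0:
        row["delta0"] = 1.0 - float(np.mean(w_self)) / mean_out
    r_nm, _ = corr_and_slope(alpha, pop.mutation_copies)
    r_wo, b_wo = corr_and_slope(alpha, w_out)
    r_ws, b_ws = corr_and_slope(alpha, w_self)
    row["corr_alpha_nmut"] = r_nm
    row["corr_alpha_wout"] = r_wo
    row["corr_alpha_wself"] = r_ws
    row["slope_alpha_wself"] = b_ws
    row["slope_alpha_wout"] = b_wo
    ok = w_out > 0
    if ok.sum() >= 3:
        fam = 1.0 - w_self[ok] / w_out[ok]
        r_f, _ = corr_and_slope(alpha[ok], fam)
        row["corr_alpha_famID"] = r_f
    return row


def summarize_equilibrium(records: pd.DataFrame, window: int) -> pd.DataFrame:
    """Trailing-window averages of every metric column.

    Selects the rows whose ``generation`` lies in the final ``window``
    generations, then averages each column, skipping undefined (NaN)
    entries. Returns a frame indexed by metric with columns ``mean``,
    ``n_used`` and ``n_missing``.
    """
    if records.empty:
        raise ValueError("no records to summarize")
    last = int(records["generation"].max())
    if window > last:
        raise ValueError(f"window {window} exceeds run length {last}")
    tail = records[records["generation"] > last - window]
    cols = [c for c in records.columns if c != "generation"]
    mean = tail[cols].mean(skipna=True)
    n_used = tail[cols].notna().sum()
    n_missing = tail[cols].isna().sum()
    return pd.DataFrame({"mean": mean, "n_used": n_used, "n_missing": n_missing})
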