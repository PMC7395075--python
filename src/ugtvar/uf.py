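"""From posterior draws to reported quantities: CV, UF95/UF97.5, report rows.

For a lognormal PK parameter with log-scale interindividual SD sigma,

    CV   = sqrt(exp(sigma^2) - 1)
    UF_p = exp(z_p * sigma) = exp(z_p * sqrt(ln(1 + CV^2)))

where UF_p is the ratio of the p-th population percentile to the median
(z_95 = 1.6449, z_97.5 = 1.9600).  The UF is the pathway-related refinement
of the default toxicokinetic factor 3.16 (10^0.5).

Posterior summaries use the inverted-CDF (order-statistic) quantile so that
quantiles commute exactly with monotone transforms: the reported median UF
is the UF of the median CV, as required of a coherent summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import Parameter, Route
from .model import PosteriorDraws
from .standardize import CANONICAL_UNITS

__all__ = [
    "DEFAULT_TK_UF",
    "Interval",
    "VariabilitySummary",
    "cv_from_sigma",
    "sigma_from_cv",
    "uf_from_cv",
    "summarize_variability",
    "build_report_table",
    "format_report_text",
]

#: The default toxicokinetic uncertainty factor, 10^0.5, used as a report
#: annotation for comparison (never in any computation).
DEFAULT_TK_UF = 3.16


def cv_from_sigma(sigma: float) -> float:
    """Lognormal coefficient of variation from the log-scale SD (= lnGSD)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return math.sqrt(math.expm1(sigma * sigma))


def sigma_from_cv(cv: float) -> float:
    """Exact inverse of :func:`cv_from_sigma`."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    return math.sqrt(math.log1p(cv * cv))


def uf_from_cv(cv: float, percentile: float) -> float:
    """Percentile-to-median ratio of a lognormal with the given CV.

    ``percentile`` is on the (50, 100) scale, e.g. 95 or 97.5.
    """
    if not 50.0 < percentile < 100.0:
        raise ValueError("percentile must lie in (50, 100)")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    z = norm.ppf(percentile / 100.0)
    return math.exp(z * sigma_from_cv(cv))


@dataclass(frozen=True)
class Interval:
    """Posterior median with equal-tailed 95% credible bounds."""

    median: float
    low95: float
    high95: float

    def __iter__(self):
        return iter((self.median, self.low95, self.high95))


@dataclass(frozen=True)
class VariabilitySummary:
    """One report-table row: a substrate (or the isoform 'overall') summary."""

    scope: str
    route: Route
    parameter: Parameter
    nst: int
    n_total: int
    gm: Interval | None
    cv: Interval
    uf95: Interval
    uf975: Interval


def _interval(x: np.ndarray) -> Interval:
    lo, med, hi = np.quantile(x, [0.025, 0.5, 0.975], method="inverted_cdf")
    return Interval(float(med), float(lo), float(hi))


def summarize_variability(
    draws: PosteriorDraws,
    scope: str,
    counts: tuple[int, int],
    route: Route | None = None,
    parameter: Parameter | None = None,
    rng: np.random.Generator | None = None,
    percentiles: tuple[float, float] = (95.0, 97.5),
) -> VariabilitySummary:
    """Posterior medians and 95% credible intervals of GM, CV and UFs.

    ``scope`` is a substrate id, or ``"overall"`` for the isoform level.  For
    a pooled (multi-substrate) fit the overall row uses the predictive
    distribution of a new substrate's sigma_ind — exp of a Normal(M, S) draw
    per posterior draw, which requires ``rng`` — and reports no GM.  For a
    single-substrate fit that substrate *is* the overall scope.
    """
    if draws.n_draws == 0:
        raise ValueError("empty posterior draws")
    nst, n_total = counts
    if scope == "overall":
        if draws.hyper_m is not None:
            if rng is None:
                raise ValueError("overall scope on a pooled fit needs an rng for the predictive draw")
            m = draws.flat("hyper_m")
            s = draws.flat("hyper_s")
            sigma = np.exp(m + s * rng.standard_normal(m.size))
            gm = None
        elif len(draws.substrate_ids) == 1:
            sigma = draws.flat("sigma_ind", draws.substrate_ids[0])
            gm = _interval(np.exp(draws.flat("mu", draws.substrate_ids[0])))
        else:
            raise ValueError("overall scope requires a pooled fit or a single substrate")
    else:
        sigma = draws.flat("sigma_ind", scope)
        gm = _interval(np.exp(draws.flat("mu", scope)))
    cv = np.sqrt(np.expm1(sigma * sigma))
    p_lo, p_hi = percentiles
    if not (50.0 < p_lo < 100.0 and 50.0 < p_hi < 100.0):
        raise ValueError("percentiles must lie in (50, 100)")
    z95, z975 = norm.ppf([p_lo / 100.0, p_hi / 100.0])
    return VariabilitySummary(
        scope=scope,
        route=route if route is not None else Route.ORAL,
        parameter=parameter if parameter is not None else Parameter.AUC,
        nst=nst,
        n_total=n_total,
        gm=gm,
        cv=_interval(cv),
        uf95=_interval(np.exp(z95 * sigma)),
        uf975=_interval(np.exp(z975 * sigma)),
    )


def _round_half_up(x: float, decimals: int) -> float:
    scale = 10.0 ** decimals
    return math.floor(x * scale + 0.5) / scale


def _fmt_uf(x: float) -> str:
    return f"{_round_half_up(x, 1):.1f}"


def _fmt_ci(iv: Interval) -> str:
    return f"{_round_half_up(iv.low95, 1):.1f}-{_round_half_up(iv.high95, 1):.1f}"


def build_report_table(summaries: list[VariabilitySummary]) -> pd.DataFrame:
    """Format summaries as a report table (one grouping of route x parameter).

    CV is printed as an integer percent, UFs and their interval bounds to
    one decimal (half-up); GM keeps three significant digits in canonical
    units.  Rounding happens only here, never upstream.
    """
    groupings = {(s.route, s.parameter) for s in summaries}
    if len(groupings) > 1:
        raise ValueError("summaries mix routes or parameters; build one table per grouping")
    ordered = sorted(summaries, key=lambda s: (s.scope == "overall", s.scope))
    rows = []
    for s in ordered:
        rows.append(
            {
                "compound": s.scope,
                "route": s.route.value,
                "parameter": s.parameter.value,
                "nst": s.nst,
                "n": s.n_total,
                "CV%": int(_round_half_up(100.0 * s.cv.median, 0)),
                "GM": "" if s.gm is None else f"{s.gm.median:.3g}",
                "UF95": _fmt_uf(s.uf95.median),
                "UF95 95% CI": _fmt_ci(s.uf95),
                "UF97.5": _fmt_uf(s.uf975.median),
                "UF97.5 95% CI": _fmt_ci(s.uf975),
            }
        )
    return pd.DataFrame(rows)


def format_report_text(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering of a report table."""
    if table.empty:
        return "(no rows)\n"
    parameter = table["parameter"].iloc[0]
    unit = CANONICAL_UNITS[Parameter(parameter)]
    header = f"{table['route'].iloc[0]} {parameter} ({unit}); default TK UF = {DEFAULT_TK_UF}"
    body = table.drop(columns=["route", "parameter"]).to_string(index=False)
    return header + "\n" + body + "\n"
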