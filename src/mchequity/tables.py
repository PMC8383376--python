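"""Equity tables: weighted prevalences, risk ratios, and per-indicator rows.

Assembles the standard equity summary for each binary MCH indicator:
average weighted prevalence, the weighted concentration index with
significance stars, the richest-vs-poorest risk ratios (quintile 5 vs 1
and decile 10 vs 1), and stratified risk ratios for urban vs rural
residence and higher vs lower education. Risk-ratio inference uses the
Katz log-normal method with Kish effective sample sizes; survey clustering
is not modeled, and table metadata says so.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .concentration import (
    ConcentrationResult,
    RankedHealthSeries,
    analyze_series,
    fractional_ranks,
    significance_stars,
)
from .simulate import SyntheticSurvey
from .wealth import WealthIndex, build_wealth_index

__all__ = [
    "IndicatorRecord",
    "RiskRatioResult",
    "EquityTableRow",
    "weighted_prevalence",
    "risk_ratio",
    "build_equity_table",
    "equity_table_frame",
]


@dataclass(frozen=True)
class IndicatorRecord:
    """One individual's value for one binary indicator, with stratifiers."""

    unit_id: str
    household_id: str
    weight: float
    indicator: str
    value: int
    residence: str  # urban | rural
    education: str  # lower | higher

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError(f"unit {self.unit_id}: indicator value must be 0/1")
        if not self.weight > 0:
            raise ValueError(f"unit {self.unit_id}: weight must be positive")


@dataclass(frozen=True)
class RiskRatioResult:
    """Weighted prevalence ratio between two strata with Katz inference."""

    group_a: str
    group_b: str
    prevalence_a: float
    prevalence_b: float
    rr: float
    ci95: tuple[float, float]
    p_value: float
    n_a: int
    n_b: int
    continuity_corrected: bool = False

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


@dataclass
class EquityTableRow:
    """Full equity summary for one indicator (one table row)."""

    indicator: str
    indicator_class: str
    prevalence_pct: float
    concentration: ConcentrationResult | None
    rr_quintile: RiskRatioResult | None
    rr_decile: RiskRatioResult | None
    rr_residence: RiskRatioResult | None
    rr_education: RiskRatioResult | None
    note: str = ""


def weighted_prevalence(
    values: Sequence[float], weights: Sequence[float], stratum: str = ""
) -> float:
    """Design-weighted proportion sum(w*v)/sum(w), as a fraction."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        where = f" in stratum {stratum!r}" if stratum else ""
        raise ValueError(f"prevalence undefined: no records{where}")
    return float(np.sum(w * v) / np.sum(w))


def _effective_n(weights: np.ndarray) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    return float(weights.sum() ** 2 / np.sum(weights**2))


def risk_ratio(
    values_a: Sequence[float],
    weights_a: Sequence[float],
    values_b: Sequence[float],
    weights_b: Sequence[float],
    group_a: str = "a",
    group_b: str = "b",
) -> RiskRatioResult:
    """Weighted risk ratio RR = prevalence(a) / prevalence(b).

    The 95% interval and two-sided p-value come from the Katz log-RR
    normal method with effective sample sizes; no clustering adjustment.
    A 0.5 continuity correction on effective counts is applied only when a
    zero cell blocks the log-RR variance, and the result is flagged. A
    zero denominator prevalence yields an infinite-RR sentinel with a
    warning rather than an error.
    """
    va, wa = np.asarray(values_a, float), np.asarray(weights_a, float)
    vb, wb = np.asarray(values_b, float), np.asarray(weights_b, float)
    if va.size == 0 or vb.size == 0:
        raise ValueError(
            f"risk ratio undefined: empty group {group_a if va.size == 0 else group_b!r}"
        )
    pa = weighted_prevalence(va, wa, group_a)
    pb = weighted_prevalence(vb, wb, group_b)
    na, nb = _effective_n(wa), _effective_n(wb)
    if pb == 0.0:
        warnings.warn(
            f"zero prevalence in denominator group {group_b!r}: RR is infinite",
            stacklevel=2,
        )
        return RiskRatioResult(
            group_a=group_a, group_b=group_b, prevalence_a=pa, prevalence_b=pb,
            rr=np.inf, ci95=(np.nan, np.nan), p_value=np.nan,
            n_a=int(va.size), n_b=int(vb.size),
        )
    rr = pa / pb
    xa, xb = pa * na, pb * nb  # effective event counts
    corrected = False
    if xa == 0.0 or xa == na or xb == nb:
        xa, xb, na_c, nb_c = xa + 0.5, xb + 0.5, na + 1.0, nb + 1.0
        corrected = True
    else:
        na_c, nb_c = na, nb
    pa_c, pb_c = xa / na_c, xb / nb_c
    rr_c = pa_c / pb_c if corrected else rr
    # Katz: var(log RR) = (1-pa)/(pa*na) + (1-pb)/(pb*nb)
    var_log = (1.0 - pa_c) / (pa_c * na_c) + (1.0 - pb_c) / (pb_c * nb_c)
    se_log = float(np.sqrt(var_log))
    z = 1.959963984540054
    lo, hi = float(np.exp(np.log(rr_c) - z * se_log)), float(np.exp(np.log(rr_c) + z * se_log))
    if se_log == 0.0:
        p = 1.0 if rr_c == 1.0 else 0.0
    else:
        p = 2.0 * float(stats.norm.sf(abs(np.log(rr_c)) / se_log))
    return RiskRatioResult(
        group_a=group_a, group_b=group_b, prevalence_a=pa, prevalence_b=pb,
        rr=rr, ci95=(lo, hi), p_value=p,
        n_a=int(va.size), n_b=int(vb.size), continuity_corrected=corrected,
    )


def _records_from_survey(survey: SyntheticSurvey, indicator: str) -> list[IndicatorRecord]:
    return [
        IndicatorRecord(
            unit_id=r.unit_id,
            household_id=r.household_id,
            weight=r.weight,
            indicator=indicator,
            value=int(r.values[indicator]),
            residence=r.residence,
            education=r.education,
        )
        for r in survey.individuals
        if indicator in r.values
    ]


def _rr_between(
    records: list[IndicatorRecord],
    in_a: Callable[[IndicatorRecord], bool],
    in_b: Callable[[IndicatorRecord], bool],
    label_a: str,
    label_b: str,
) -> RiskRatioResult | None:
    rec_a = [r for r in records if in_a(r)]
    rec_b = [r for r in records if in_b(r)]
    if not rec_a or not rec_b:
        return None
    return risk_ratio(
        [r.value for r in rec_a], [r.weight for r in rec_a],
        [r.value for r in rec_b], [r.weight for r in rec_b],
        group_a=label_a, group_b=label_b,
    )


def build_equity_table(
    survey: SyntheticSurvey,
    wealth_index: list[WealthIndex] | None = None,
    indicators: Sequence[tuple[str, str]] | None = None,
    se_method: str = "analytic",
    bootstrap_B: int = 1000,
    rng=None,
    rank_convention: str = "endpoint",
    use_weights: bool = True,
) -> list[EquityTableRow]:
    """One equity row per indicator: prevalence, CI, and the four RRs.

    ``indicators`` is a list of (name, class) pairs; by default every
    indicator in the survey's truth sidecar, in order. An indicator whose
    weighted mean is zero gets its CI marked undefined (None) and the
    pipeline continues. Richest-vs-poorest RRs use only the top and bottom
    wealth groups; residence RR is urban:rural, education higher:lower.
    ``rank_convention`` selects endpoint (default) or midpoint fractional
    ranks for the CI; ``use_weights=False`` runs the whole analysis
    unweighted (ranking weights still come from the wealth index passed in).
    """
    if wealth_index is None:
        wealth_index, _, _ = build_wealth_index(survey.households)
    if indicators is None:
        params = survey.truth.config.indicators
        indicators = [(i.name, i.indicator_class) for i in params]
    by_hh = {wi.household_id: wi for wi in wealth_index}
    rows: list[EquityTableRow] = []
    for name, cls in indicators:
        records = _records_from_survey(survey, name)
        if not use_weights:
            records = [dataclasses.replace(r, weight=1.0) for r in records]
        if not records:
            rows.append(
                EquityTableRow(
                    indicator=name, indicator_class=cls, prevalence_pct=np.nan,
                    concentration=None, rr_quintile=None, rr_decile=None,
                    rr_residence=None, rr_education=None, note="no records",
                )
            )
            continue
        prev = weighted_prevalence([r.value for r in records], [r.weight for r in records])
        # concentration: rank individuals by household wealth rank, tie-break unit_id
        ordered = sorted(records, key=lambda r: (by_hh[r.household_id].rank, r.unit_id))
        h = np.array([r.value for r in ordered], dtype=float)
        w = np.array([r.weight for r in ordered])
        conc: ConcentrationResult | None
        note = ""
        if h.sum() == 0:
            conc = None
            note = "CI undefined: zero prevalence"
        else:
            series = RankedHealthSeries(
                h=h,
                fractional_rank=fractional_ranks(w, convention=rank_convention),
                weight=w,
            )
            conc = analyze_series(series, se_method=se_method, B=bootstrap_B, rng=rng)
        q = lambda r: by_hh[r.household_id].quintile  # noqa: E731
        d = lambda r: by_hh[r.household_id].decile  # noqa: E731
        rows.append(
            EquityTableRow(
                indicator=name,
                indicator_class=cls,
                prevalence_pct=100.0 * prev,
                concentration=conc,
                rr_quintile=_rr_between(
                    records, lambda r: q(r) == 5, lambda r: q(r) == 1,
                    "quintile5", "quintile1",
                ),
                rr_decile=_rr_between(
                    records, lambda r: d(r) == 10, lambda r: d(r) == 1,
                    "decile10", "decile1",
                ),
                rr_residence=_rr_between(
                    records, lambda r: r.residence == "urban",
                    lambda r: r.residence == "rural", "urban", "rural",
                ),
                rr_education=_rr_between(
                    records, lambda r: r.education == "higher",
                    lambda r: r.education == "lower", "higher_educ", "lower_educ",
                ),
                note=note,
            )
        )
    return rows


def equity_table_frame(rows: list[EquityTableRow]) -> pd.DataFrame:
    """Flatten equity rows into a table mirroring the published layout.

    Metadata note: p-values are design-naive (no clustering adjustment).
    """
    def _rr_cells(rr: RiskRatioResult | None, prefix: str) -> dict:
        if rr is None:
            return {f"{prefix}_rr": np.nan, f"{prefix}_p": np.nan, f"{prefix}_stars": ""}
        return {
            f"{prefix}_rr": rr.rr,
            f"{prefix}_p": rr.p_value,
            f"{prefix}_stars": rr.stars,
        }

    out = []
    for row in rows:
        rec = {
            "indicator": row.indicator,
            "indicator_class": row.indicator_class,
            "avg_prevalence_pct": row.prevalence_pct,
            "CI": row.concentration.C if row.concentration else np.nan,
            "CI_se": row.concentration.se if row.concentration else np.nan,
            "CI_p": row.concentration.p_value if row.concentration else np.nan,
            "CI_stars": row.concentration.stars if row.concentration else "",
            "direction": row.concentration.direction if row.concentration else "undefined",
        }
        rec.update(_rr_cells(row.rr_quintile, "rr_q5_q1"))
        rec.update(_rr_cells(row.rr_decile, "rr_d10_d1"))
        rec.update(_rr_cells(row.rr_residence, "rr_urban_rural"))
        rec.update(_rr_cells(row.rr_education, "rr_higher_lower_educ"))
        rec["note"] = row.note
        out.append(rec)
    df = pd.DataFrame(out)
    df.attrs["variance_note"] = (
        "p-values are design-naive: survey clustering is not modeled"
    )
    return df
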