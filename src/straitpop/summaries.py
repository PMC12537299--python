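"""Descriptive field summaries: recapture rates, catch-per-unit-effort, and
annual roll-up tables per subregion-year, plus prosomal-width distributions.

Rates are rounded half-up at two decimals (the convention that reproduces
the published monitoring tables cell-for-cell). CPUE is individuals per
person-time for Kinmen and Taiwan and individuals per net set for Penghu.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from straitpop.errors import StraitpopError

SUMMARY_COLUMNS = [
    "subregion",
    "year",
    "captured_total",
    "marked_total",
    "recaptured_total",
    "recapture_rate_pct",
    "effort_total",
    "effort_unit",
    "cpue",
]


class UndefinedRateError(StraitpopError):
    """Rate with a zero denominator."""


def _round2(numerator: int, denominator: int, scale: int = 1) -> float:
    """Exact rational division rounded half-up to 2 decimals."""
    q = Decimal(numerator) * scale / Decimal(denominator)
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def recapture_rate(recaptured: int, captured: int) -> float:
    """Recaptures as a percentage of total captures, half-up at 2 decimals."""
    if captured == 0:
        raise UndefinedRateError("recapture rate undefined for captured = 0")
    if not 0 <= recaptured <= captured:
        raise ValueError(f"recaptured={recaptured} outside [0, captured={captured}]")
    return _round2(recaptured, captured, scale=100)


def cpue(total_individuals: int, total_effort: int) -> float:
    """Catch per unit effort, half-up at 2 decimals."""
    if total_effort <= 0:
        raise UndefinedRateError("CPUE undefined for zero effort")
    return _round2(total_individuals, total_effort)


def summarize(events: pd.DataFrame, efforts: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per subregion-year: capture totals, recapture rate, CPUE.

    ``captured_total`` counts every capture event (including recaptures),
    ``marked_total`` the newly tagged-and-released animals, and
    ``recaptured_total`` the recapture events, mirroring the three roles of
    an annual mark-recapture roll-up. CPUE is NaN when no effort is logged
    for a subregion-year with events.
    """
    if events.empty:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    ev = events.copy()
    ev["event_date"] = pd.to_datetime(ev["event_date"])
    ev["year"] = ev["event_date"].dt.year

    eff_lookup = {}
    if efforts is not None and len(efforts):
        grouped = efforts.groupby(["subregion", "year"])
        for (sub, year), g in grouped:
            units = g["effort_unit"].unique()
            eff_lookup[(sub, int(year))] = (int(g["effort_amount"].sum()), units[0])

    rows = []
    for (sub, year), g in ev.groupby(["subregion", "year"], sort=True):
        captured = len(g)
        marked = int((g["event_kind"] == "first_capture_tagged").sum())
        recaptured = int((g["event_kind"] == "recapture").sum())
        effort_total, unit = eff_lookup.get((sub, int(year)), (None, None))
        rows.append(
            {
                "subregion": sub,
                "year": int(year),
                "captured_total": captured,
                "marked_total": marked,
                "recaptured_total": recaptured,
                "recapture_rate_pct": recapture_rate(recaptured, captured),
                "effort_total": effort_total,
                "effort_unit": unit,
                "cpue": cpue(captured, effort_total) if effort_total else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def size_summary(events: pd.DataFrame) -> pd.DataFrame:
    """Five-number summary of prosomal width (cm) per subregion and sex."""
    if events.empty or events["prosomal_width_cm"].dropna().empty:
        return pd.DataFrame(
            columns=["subregion", "sex", "n", "min", "q1", "median", "q3", "max"]
        )
    ev = events.dropna(subset=["prosomal_width_cm"])
    rows = []
    for (sub, sex), g in ev.groupby(["subregion", "sex"], sort=True):
        w = g["prosomal_width_cm"].astype(float)
        rows.append(
            {
                "subregion": sub,
                "sex": sex,
                "n": len(w),
                "min": w.min(),
                "q1": w.quantile(0.25),
                "median": w.quantile(0.5),
                "q3": w.quantile(0.75),
                "max": w.max(),
            }
        )
    return pd.DataFrame(rows)
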