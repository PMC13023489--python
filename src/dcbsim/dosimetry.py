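"""Tissue dosimetry: unit conversion, clinical criteria, optimal dilation time.

Clinical use of paclitaxel balloons imposes two requirements: the tissue
concentration must fall below the toxic level (85.40 ug/g) within 24 h of
implantation, and it should stay above the effective level (0.047 ug/g) for
as long as possible within the 8-week horizon.  Toxicity is judged on the
spatial *maximum* (conservative), efficacy on the spatial *mean*; both
statistics are carried in the concentration time series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError
from .retention import DAY, WEEK, ConcentrationTimeSeries

__all__ = [
    "DosimetryReport",
    "to_tissue_concentration",
    "effective_duration",
    "safety_check",
    "make_report",
    "select_optimal",
]


@dataclass(frozen=True)
class DosimetryReport:
    """Clinical summary of one candidate dilation time."""

    dilation_time: float  # s
    safe_at_24h: bool
    effective_duration: float  # weeks
    peak_concentration_24h: float  # ug/g (spatial maximum)
    mean_concentration_24h: float  # ug/g (spatial mean)

    def to_dict(self) -> dict:
        return {
            "dilation_time_s": self.dilation_time,
            "safe_at_24h": self.safe_at_24h,
            "effective_duration_weeks": self.effective_duration,
            "peak_concentration_24h_ug_per_g": self.peak_concentration_24h,
            "mean_concentration_24h_ug_per_g": self.mean_concentration_24h,
        }


def to_tissue_concentration(phi, rho_tissue: float):
    """Convert a concentration (kg/m^3) to tissue mass concentration (ug/g).

    ``c[ug/g] = phi[kg/m^3] * 1e6 / rho_tissue[kg/m^3]``.
    """
    if rho_tissue <= 0:
        raise DomainError("tissue density must be positive")
    return np.asarray(phi, dtype=float) * 1e6 / rho_tissue


def effective_duration(
    series: ConcentrationTimeSeries, c_effective: float, horizon_weeks: float = 8.0
) -> float:
    """Last checkpoint time (weeks) with mean concentration >= c_effective.

    Returns 0 if the mean is below the threshold at every checkpoint inside
    the horizon.
    """
    if len(series.times_s) == 0:
        raise ValidationError("empty concentration series")
    weeks = series.times_s / WEEK
    ok = (series.mean_ug_per_g >= c_effective) & (weeks <= horizon_weeks + 1e-9)
    if not np.any(ok):
        return 0.0
    return float(weeks[ok].max())


def _checkpoint_at(series: ConcentrationTimeSeries, t: float) -> int:
    idx = np.flatnonzero(np.isclose(series.times_s, t, rtol=1e-9, atol=1.0))
    if len(idx) == 0:
        raise ValidationError(f"series has no checkpoint at t = {t:g} s")
    return int(idx[0])


def safety_check(series: ConcentrationTimeSeries, c_toxic: float) -> bool:
    """True iff the maximum tissue concentration at 24 h is strictly below
    the toxic threshold."""
    k = _checkpoint_at(series, DAY)
    return bool(series.max_ug_per_g[k] < c_toxic)


def make_report(
    dilation_time: float,
    series: ConcentrationTimeSeries,
    c_toxic: float,
    c_effective: float,
    horizon_weeks: float = 8.0,
) -> DosimetryReport:
    k = _checkpoint_at(series, DAY)
    return DosimetryReport(
        dilation_time=dilation_time,
        safe_at_24h=safety_check(series, c_toxic),
        effective_duration=effective_duration(series, c_effective, horizon_weeks),
        peak_concentration_24h=float(series.max_ug_per_g[k]),
        mean_concentration_24h=float(series.mean_ug_per_g[k]),
    )


def select_optimal(reports) -> DosimetryReport | None:
    """Pick the optimal dilation time among candidate reports.

    Among candidates safe at 24 h, maximise the effective duration; ties go
    to the shortest dilation time (least barotrauma exposure).  Returns
    ``None`` when no candidate is admissible.
    """
    reports = list(reports)
    if not reports:
        raise ValidationError("at least one report is required")
    safe = [r for r in reports if r.safe_at_24h]
    if not safe:
        return None
    best_duration = max(r.effective_duration for r in safe)
    winners = [r for r in safe if r.effective_duration == best_duration]
    return min(winners, key=lambda r: r.dilation_time)
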