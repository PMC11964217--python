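"""Sleep parameters and facet consolidation.

Diary-style self reports (bed time, wake time, sleep-onset latency, for
school days and free days separately) are reduced to four per-person sleep
facets:

* **SQI** -- four-item Sleep Quality Index, the mean of four 1-6 frequency
  ratings of disturbed-sleep symptoms; screening flag at >= 3.
* **WASD** -- weekly average sleep duration, the 5:2 weighted mean of
  school-day and free-day nightly durations, latency-adjusted.
* **Chronotype (MSF)** -- midpoint of sleep on free days, hours past
  midnight, without sleep-debt correction.
* **Social jetlag (SJL)** -- signed difference between free-day and
  school-day midsleep, in hours.

Clock convention: all times live on a continuous axis centred at midnight.
Bedtimes before midnight are *negative* (23:00 -> -1.0), wake times are
positive hours past midnight.  This keeps midsleep arithmetic monotone with
no modular wrap-around.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "sleep_duration",
    "wasd",
    "midsleep",
    "social_jetlag",
    "sqi_score",
    "recode_screen_hours",
    "derive_sleep_facets",
    "SQI_CUTOFF",
    "FACET_COLUMNS",
]

#: Screening cut-off on the SQI mean score (inclusive).
SQI_CUTOFF = 3.0

#: Columns appended by :func:`derive_sleep_facets`.
FACET_COLUMNS = [
    "dur_school",
    "dur_free",
    "wasd",
    "msw",
    "msf",
    "sjl",
    "sqi",
    "sqi_flag",
]


def sleep_duration(bedtime: float, latency: float, waketime: float) -> float:
    """Nightly sleep duration in hours: waketime - (bedtime + latency).

    Raises
    ------
    ValueError
        If latency is negative or the implied duration is non-positive.
    """
    if latency < 0:
        raise ValueError(f"negative sleep-onset latency: {latency}")
    duration = waketime - (bedtime + latency)
    if duration <= 0:
        raise ValueError(
            "non-positive sleep duration: "
            f"bedtime={bedtime}, latency={latency}, waketime={waketime}"
        )
    return duration


def wasd(duration_school: float, duration_free: float) -> float:
    """Weekly average sleep duration: (5*school + 2*free) / 7 hours."""
    if duration_school <= 0 or duration_free <= 0:
        raise ValueError(
            "durations must be positive, got "
            f"school={duration_school}, free={duration_free}"
        )
    return (5.0 * duration_school + 2.0 * duration_free) / 7.0


def midsleep(bedtime: float, latency: float, duration: float) -> float:
    """Midpoint of sleep, hours past midnight: onset + duration/2.

    Sleep onset is bedtime + latency.  Chronotype is this quantity computed
    on free days (no correction for accumulated sleep debt).
    """
    if latency < 0:
        raise ValueError(f"negative sleep-onset latency: {latency}")
    if duration <= 0:
        raise ValueError(f"non-positive sleep duration: {duration}")
    return (bedtime + latency) + duration / 2.0


def social_jetlag(msf: float, msw: float) -> float:
    """Signed social jetlag: free-day midsleep minus school-day midsleep."""
    return msf - msw


def sqi_score(items) -> tuple[float, bool]:
    """Sleep Quality Index: mean of four 1-6 items plus screening flag.

    Any missing item yields a missing score (no partial mean).  Returns
    ``(nan, False)`` in that case.
    """
    arr = np.asarray(items, dtype=float)
    if arr.shape != (4,):
        raise ValueError(f"SQI requires exactly 4 items, got shape {arr.shape}")
    if np.isnan(arr).any():
        return float("nan"), False
    if ((arr < 1) | (arr > 6)).any():
        raise ValueError(f"SQI items must lie in 1..6, got {arr.tolist()}")
    score = float(arr.mean())
    return score, score >= SQI_CUTOFF


#: Upper edges (inclusive) of the hour bins for the 1-6 ordinal recode:
#: <1 h; 1-2 h; 3-4 h; 5-6 h; 7-8 h; 9-24 h.
_SCREEN_BIN_UPPER = (0, 2, 4, 6, 8, 24)


def recode_screen_hours(hours) -> int:
    """Recode daily online hours (0-24 integer scale) onto the 1-6 bins.

    Non-integer inputs are floored before binning.
    """
    h = int(np.floor(hours))
    if h < 0 or h > 24:
        raise ValueError(f"hours must lie in [0, 24], got {hours}")
    for code, upper in enumerate(_SCREEN_BIN_UPPER, start=1):
        if h <= upper:
            return code
    raise AssertionError("unreachable")


def derive_sleep_facets(panel: pd.DataFrame) -> pd.DataFrame:
    """Append per-person sleep facet columns to a three-wave panel.

    Expects wave-2 diary columns ``bed_school``, ``bed_free``,
    ``wake_school``, ``wake_free``, ``lat_school``, ``lat_free`` (hours,
    midnight-centred) and SQI items ``q1..q4``.  Appends the columns listed
    in :data:`FACET_COLUMNS`.  Missing or invalid diary fields (negative
    latency, non-positive implied duration) propagate to missing facets
    row-wise; no error is raised.
    """
    out = panel.copy()
    bed_s = out["bed_school"].to_numpy(dtype=float)
    bed_f = out["bed_free"].to_numpy(dtype=float)
    wake_s = out["wake_school"].to_numpy(dtype=float)
    wake_f = out["wake_free"].to_numpy(dtype=float)
    lat_s = out["lat_school"].to_numpy(dtype=float)
    lat_f = out["lat_free"].to_numpy(dtype=float)

    with np.errstate(invalid="ignore"):
        dur_s = wake_s - (bed_s + lat_s)
        dur_f = wake_f - (bed_f + lat_f)
        bad_s = (lat_s < 0) | (dur_s <= 0)
        bad_f = (lat_f < 0) | (dur_f <= 0)
    dur_s = np.where(bad_s, np.nan, dur_s)
    dur_f = np.where(bad_f, np.nan, dur_f)

    msw = (bed_s + lat_s) + dur_s / 2.0
    msf = (bed_f + lat_f) + dur_f / 2.0

    out["dur_school"] = dur_s
    out["dur_free"] = dur_f
    out["wasd"] = (5.0 * dur_s + 2.0 * dur_f) / 7.0
    out["msw"] = msw
    out["msf"] = msf
    out["sjl"] = msf - msw

    q = out[["q1", "q2", "q3", "q4"]].to_numpy(dtype=float)
    sqi = q.mean(axis=1)  # NaN if any item missing
    out["sqi"] = sqi
    out["sqi_flag"] = sqi >= SQI_CUTOFF
    return out
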