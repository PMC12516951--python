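"""Rainfall flags, time-since-rain, and rain-driven community-distance analyses.

Combined sewers receive stormwater, and rain mobilizes biofilm and sediment
biomass into the water phase.  Two rainfall descriptors drive the analyses:

* a per-sample flag for measurable rain (>= 0.5 mm) within the hour before
  sampling, and
* the daily "time since rain" (TSR): the number of consecutive days with
  < 2 mm of rainfall, where a rain event is a day with >= 2 mm.  Two days
  after a rain-event day the TSR resets to zero (the lag absorbs the 24-hour
  composite sampling window and in-network travel time); with consecutive
  event days the reset anchors to the last event day of the run.

Community consequences are quantified as Bray-Curtis distances between each
water-phase sample (SWW or IWW) and every sewer-surface sample, compared
between rain groups and regressed against TSR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diversity_stats import DistanceMatrix, linear_fit, welch_t_test
from .io_formats import SEWER_HABITATS

EVENT_THRESHOLD_MM = 2.0
RESET_LAG_DAYS = 2
TSR_CUT = 3


def flag_rain_before_sampling(
    hourly: pd.DataFrame,
    sampling_times,
    window_hours: float = 1.0,
    threshold_mm: float = 0.5,
) -> pd.Series:
    """True when rainfall summed over (t - window, t] reaches the threshold."""
    times = pd.to_datetime(hourly["datetime"]).to_numpy()
    mm = hourly["mm"].to_numpy(dtype=float)
    sampling_times = pd.to_datetime(pd.Series(list(sampling_times)))
    out = []
    for t in sampling_times:
        lo = t - pd.Timedelta(hours=window_hours)
        in_window = (times > np.datetime64(lo)) & (times <= np.datetime64(t))
        out.append(bool(mm[in_window].sum() >= threshold_mm))
    return pd.Series(out, index=sampling_times.to_numpy(), name="rainy")


def compute_tsr(
    daily: pd.DataFrame,
    event_threshold_mm: float = EVENT_THRESHOLD_MM,
    reset_lag_days: int = RESET_LAG_DAYS,
) -> pd.DataFrame:
    """Time-since-rain per day with the lagged reset rule.

    Returns a DataFrame (date, mm, event_day, tsr) where ``tsr`` is a
    nullable integer: a day d is a reset (tsr = 0) when the most recent
    event day e satisfies d - e = lag with no further event in between;
    afterwards tsr counts consecutive sub-threshold days.  During an event
    run and its lag window the previous count is held; days before the first
    observable reset are undefined (<NA>).
    """
    dates = pd.to_datetime(daily["date"]).dt.normalize()
    if len(dates) == 0:
        raise ValueError("empty rainfall series")
    steps = dates.diff().dropna()
    if not (steps == pd.Timedelta(days=1)).all():
        raise ValueError("daily rainfall series has gaps; no imputation is done")
    mm = daily["mm"].to_numpy(dtype=float)
    event = mm >= event_threshold_mm
    n = len(mm)
    tsr = np.full(n, -1, dtype=np.int64)  # -1 encodes undefined
    last_event = None
    for i in range(n):
        if event[i]:
            if i > 0 and tsr[i - 1] >= 0:
                tsr[i] = tsr[i - 1]  # hold during the event run
            last_event = i
            continue
        if last_event is not None and i - last_event == reset_lag_days:
            tsr[i] = 0
        elif last_event is not None and i - last_event < reset_lag_days:
            if tsr[i - 1] >= 0:
                tsr[i] = tsr[i - 1]  # hold within the lag window
        elif i > 0 and tsr[i - 1] >= 0:
            tsr[i] = tsr[i - 1] + 1
    out = pd.DataFrame(
        {
            "date": dates.to_numpy(),
            "mm": mm,
            "event_day": event,
            "tsr": pd.array([v if v >= 0 else pd.NA for v in tsr], dtype="Int64"),
        }
    )
    return out


def tsr_group(tsr_value, cut: int = TSR_CUT):
    """Group a TSR value as 'lt3' / 'ge3'; undefined values return None."""
    if tsr_value is None or pd.isna(tsr_value):
        return None
    return "ge3" if int(tsr_value) >= cut else "lt3"


def _cross_pairs(dm: DistanceMatrix, water_ids, sewer_ids) -> pd.DataFrame:
    rows = []
    for w in water_ids:
        iw = dm.sample_ids.index(w)
        for s in sewer_ids:
            rows.append((w, s, dm.d[iw, dm.sample_ids.index(s)]))
    return pd.DataFrame(rows, columns=["water_sample", "sewer_sample", "bc"])


def rain_bc_analysis(
    dm: DistanceMatrix,
    meta: pd.DataFrame,
    water_habitat: str = "SWW_g",
    rain_flags: pd.Series | None = None,
    tsr_by_sample: pd.Series | None = None,
    cut: int = TSR_CUT,
) -> dict:
    """Grouped water-vs-sewer Bray-Curtis distances with tests and a TSR fit.

    Every (water sample, sewer sample) cross-habitat pair contributes one
    distance.  With ``rain_flags`` (bool per water sample) the rainy and dry
    pools are compared by Welch's t-test; with ``tsr_by_sample`` (TSR per
    water sample) pairs are additionally grouped at TSR >= cut and regressed
    (BC ~ TSR).  Returns a dict of group means, test results and fit
    coefficients.
    """
    by_sample = meta.set_index("sample_id")["habitat"]
    water = [s for s in dm.sample_ids if by_sample.get(s) == water_habitat]
    sewer = [s for s in dm.sample_ids if by_sample.get(s) in SEWER_HABITATS]
    if not water or not sewer:
        raise ValueError("need both water-phase and sewer-surface samples")
    pairs = _cross_pairs(dm, water, sewer)
    result: dict = {"water_habitat": water_habitat, "n_pairs": len(pairs)}
    if rain_flags is not None:
        flagged = pairs["water_sample"].map(rain_flags)
        rainy = pairs.loc[flagged == True, "bc"]  # noqa: E712
        dry = pairs.loc[flagged == False, "bc"]  # noqa: E712
        t, p = welch_t_test(rainy, dry) if len(rainy) > 1 and len(dry) > 1 else (np.nan, np.nan)
        result["rain_flag"] = {
            "mean_bc_rainy": float(rainy.mean()),
            "mean_bc_dry": float(dry.mean()),
            "n_rainy": int(len(rainy)),
            "n_dry": int(len(dry)),
            "t_statistic": t,
            "p_value": p,
        }
    if tsr_by_sample is not None:
        tsr = pairs["water_sample"].map(tsr_by_sample)
        ok = tsr.notna()
        sub, tsr = pairs.loc[ok], tsr[ok].astype(float)
        grp = tsr >= cut
        lo, hi = sub.loc[~grp.to_numpy(), "bc"], sub.loc[grp.to_numpy(), "bc"]
        t, p = welch_t_test(hi, lo) if len(lo) > 1 and len(hi) > 1 else (np.nan, np.nan)
        slope, intercept, r2 = linear_fit(tsr.to_numpy(), sub["bc"].to_numpy())
        result["tsr"] = {
            "mean_bc_lt_cut": float(lo.mean()),
            "mean_bc_ge_cut": float(hi.mean()),
            "n_lt_cut": int(len(lo)),
            "n_ge_cut": int(len(hi)),
            "t_statistic": t,
            "p_value": p,
            "slope": slope,
            "intercept": intercept,
            "r_squared": r2,
        }
    return result
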