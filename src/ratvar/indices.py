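"""Composite autonomic indices and per-animal / per-group aggregation.

Two indices summarize the spectral results physiologically:

* the sympathovagal balance LF/HF — the ratio of absolute LF to HF power
  of heart-rate variability;
* the alpha index ``alpha_LF = sqrt(LF_HRV / LF_SAPV)`` (ms/mmHg), an
  estimate of spontaneous baroreflex sensitivity from the LF powers of the
  tachogram and systogram spectra.

Both are ratios, so they are always computed per animal and only then
averaged across a group — the group mean of per-animal ratios is not the
ratio of group mean powers (Jensen gap).  When an animal has several
stationary fragments, band powers are first averaged across its fragments
and the indices computed from the per-animal averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd

from .beats import BeatSeries, HemodynamicSummary, summarize_hemodynamics
from .spectral import (BandPowers, DEFAULT_FRAGMENT_LEN, DEFAULT_ORDER_RANGE,
                       K_MEAN, K_VAR, RAT_BANDS, analyze_fragment,
                       select_coincident_fragments)


@dataclass(frozen=True)
class AutonomicProfile:
    """Per-animal autonomic outcome vector."""

    hrv: BandPowers  # ms^2
    sapv: BandPowers  # mmHg^2
    alpha_lf: float  # ms/mmHg, NaN when undefined
    lf_hf: float  # dimensionless, NaN when undefined
    hemodynamics: HemodynamicSummary
    n_fragments: int = 1
    ar_orders: tuple[int, ...] = ()


def alpha_lf(lf_hrv_abs: float, lf_sapv_abs: float) -> float:
    """Spontaneous baroreflex sensitivity sqrt(LF_HRV / LF_SAPV), ms/mmHg.

    Returns NaN when the systogram LF power is zero (undefined, never
    infinity).
    """
    if lf_hrv_abs < 0 or lf_sapv_abs < 0:
        raise ValueError("LF powers must be non-negative")
    if lf_sapv_abs == 0:
        return math.nan
    return math.sqrt(lf_hrv_abs / lf_sapv_abs)


def sympathovagal_balance(hrv: BandPowers) -> float:
    """LF/HF ratio of heart-rate variability; NaN when HF power is zero."""
    if hrv.hf_abs == 0:
        return math.nan
    return hrv.lf_abs / hrv.hf_abs


def _mean_band_powers(items: list[BandPowers]) -> BandPowers:
    """Average absolute powers and peaks across fragments; recompute the
    normalized units and LF/HF from the averaged powers."""
    def avg(name):
        vals = np.array([getattr(b, name) for b in items], dtype=float)
        vals = vals[np.isfinite(vals)]
        return float(np.mean(vals)) if vals.size else math.nan

    vlf, lf, hf = avg("vlf_abs"), avg("lf_abs"), avg("hf_abs")
    total = avg("total")
    if lf + hf > 0:
        lf_nu = 100.0 * lf / (lf + hf)
        hf_nu = 100.0 - lf_nu
    else:
        lf_nu = hf_nu = math.nan
    return BandPowers(vlf_abs=vlf, lf_abs=lf, hf_abs=hf, total=total,
                      lf_nu=lf_nu, hf_nu=hf_nu,
                      lf_hf=lf / hf if hf > 0 else math.nan,
                      lf_peak=avg("lf_peak"), hf_peak=avg("hf_peak"))


def build_profile(beats: BeatSeries, *,
                  target_len: int = DEFAULT_FRAGMENT_LEN,
                  k_mean: float = K_MEAN, k_var: float = K_VAR,
                  order_range: tuple[int, int] = DEFAULT_ORDER_RANGE,
                  bands=RAT_BANDS) -> AutonomicProfile:
    """Full per-animal analysis: fragments -> AR spectra -> indices.

    All coincident stationary tachogram/systogram fragment pairs are
    analyzed independently; band powers are averaged per animal and the
    ratio indices computed from the averages.
    """
    pairs = select_coincident_fragments(beats, target_len, k_mean, k_var)
    hrv_list, sapv_list, orders = [], [], []
    for tach, syst in pairs:
        m_t, bp_t = analyze_fragment(tach, *order_range, bands=bands)
        m_s, bp_s = analyze_fragment(syst, *order_range, bands=bands)
        hrv_list.append(bp_t)
        sapv_list.append(bp_s)
        orders.extend([m_t.order, m_s.order])
    hrv = _mean_band_powers(hrv_list)
    sapv = _mean_band_powers(sapv_list)
    return AutonomicProfile(
        hrv=hrv, sapv=sapv,
        alpha_lf=alpha_lf(hrv.lf_abs, sapv.lf_abs),
        lf_hf=sympathovagal_balance(hrv),
        hemodynamics=summarize_hemodynamics(beats),
        n_fragments=len(pairs), ar_orders=tuple(orders))


#: column order of a per-animal profile row
PROFILE_FIELDS = (
    "hr_bpm", "sap_mmhg", "dap_mmhg", "map_mmhg",
    "hrv_ms2", "hrv_lf_peak_hz", "hrv_lf_ms2", "hrv_lf_nu",
    "hrv_hf_peak_hz", "hrv_hf_ms2", "hrv_hf_nu", "lf_hf",
    "sapv_mmhg2", "sapv_vlf_mmhg2", "sapv_lf_peak_hz", "sapv_lf_mmhg2",
    "sapv_hf_peak_hz", "sapv_hf_mmhg2", "alpha_lf",
)


def profile_row(profile: AutonomicProfile) -> dict[str, float]:
    """Flatten a profile into the standard per-animal outcome columns."""
    h = profile.hemodynamics
    return {
        "hr_bpm": h.hr, "sap_mmhg": h.sap_mean, "dap_mmhg": h.dap_mean,
        "map_mmhg": h.map_mean,
        "hrv_ms2": profile.hrv.total, "hrv_lf_peak_hz": profile.hrv.lf_peak,
        "hrv_lf_ms2": profile.hrv.lf_abs, "hrv_lf_nu": profile.hrv.lf_nu,
        "hrv_hf_peak_hz": profile.hrv.hf_peak,
        "hrv_hf_ms2": profile.hrv.hf_abs, "hrv_hf_nu": profile.hrv.hf_nu,
        "lf_hf": profile.lf_hf,
        "sapv_mmhg2": profile.sapv.total,
        "sapv_vlf_mmhg2": profile.sapv.vlf_abs,
        "sapv_lf_peak_hz": profile.sapv.lf_peak,
        "sapv_lf_mmhg2": profile.sapv.lf_abs,
        "sapv_hf_peak_hz": profile.sapv.hf_peak,
        "sapv_hf_mmhg2": profile.sapv.hf_abs,
        "alpha_lf": profile.alpha_lf,
    }


def aggregate_group(rows: pd.DataFrame, group_label: str,
                    group_col: str = "group") -> pd.DataFrame:
    """Mean, SD and non-missing count per outcome column for one group.

    NaNs are excluded per field; a group needs at least two animals.
    Returns a frame indexed by field with columns mean/sd/n.
    """
    sub = rows[rows[group_col] == group_label]
    if len(sub) == 0:
        raise ValueError(f"empty group {group_label!r}")
    if len(sub) < 2:
        raise ValueError(f"group {group_label!r} has fewer than 2 animals")
    numeric = sub.select_dtypes(include=[np.number])
    out = pd.DataFrame({
        "mean": numeric.mean(skipna=True),
        "sd": numeric.std(skipna=True, ddof=1),
        "n": numeric.notna().sum(),
    })
    return out
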