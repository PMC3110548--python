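"""Autoregressive spectral analysis of tachograms and systograms.

The variability of a beat series is quantified parametrically: a stationary
fragment of about 300 beats is mean-centred and fitted with an AR(p) model
by the Burg recursion, the model order chosen by AIC.  The characteristic
polynomial is factored and each real pole (or complex-conjugate pair)
yields one spectral component whose power is obtained by residue
evaluation of the AR spectral density, so that the component powers sum to
the process variance.  Pole angles are beat-domain frequencies; they are
mapped to Hz by dividing by the fragment's mean beat interval, the usual
convention for beat-sampled cardiovascular series.

Band powers use the rat frequency bands: VLF 0.0-0.2 Hz, LF 0.2-0.75 Hz,
HF 0.75-3.0 Hz (half-open at the lower edge, closed at 3.0 Hz).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .beats import BeatSeries

logger = logging.getLogger("ratvar")

#: rat spectral bands in Hz: (VLF, LF, HF)
RAT_BANDS = ((0.0, 0.2), (0.2, 0.75), (0.75, 3.0))
#: default AR order search range
DEFAULT_ORDER_RANGE = (8, 20)
#: default stationary-fragment length in beats
DEFAULT_FRAGMENT_LEN = 300
#: stationarity thresholds: sub-window mean span < K_MEAN * SD,
#: sub-window variance span < K_VAR * variance
K_MEAN = 0.5
K_VAR = 1.0
#: pole magnitude above which a near-unit-circle warning is logged
NEAR_UNIT_RADIUS = 0.9995


class ShortInputError(ValueError):
    """Series shorter than the requested fragment length."""


class NoStationaryFragmentError(ValueError):
    """No window of the series satisfied the stationarity criterion."""


class ZeroVarianceError(ValueError):
    """Fragment has (numerically) zero variance; no AR model can be fitted."""


@dataclass(frozen=True)
class Fragment:
    """A stationary stretch of a tachogram (ms) or systogram (mmHg)."""

    values: np.ndarray
    mean_interval: float  # s, mean beat interval of the fragment
    kind: str  # 'tachogram' or 'systogram'
    start: int = 0  # beat index of the fragment within its recording

    def __post_init__(self) -> None:
        object.__setattr__(self, "values",
                           np.asarray(self.values, dtype=float))
        if self.kind not in ("tachogram", "systogram"):
            raise ValueError("kind must be 'tachogram' or 'systogram'")
        if self.mean_interval <= 0:
            raise ValueError("mean_interval must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fragment values must be finite")

    @property
    def n_beats(self) -> int:
        return self.values.size

    @property
    def variance(self) -> float:
        return float(np.var(self.values))


@dataclass(frozen=True)
class ARModel:
    """Fitted AR(p) process ``x_k = sum_i a_i x_{k-i} + e_k``."""

    order: int
    coefficients: np.ndarray  # a_1..a_p
    innovation_variance: float  # units^2 of the input
    mean_interval: float  # s

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients",
                           np.asarray(self.coefficients, dtype=float))
        if self.coefficients.size != self.order:
            raise ValueError("coefficient count must equal the order")
        if self.innovation_variance <= 0:
            raise ValueError("innovation_variance must be positive")
        if self.order > 0:
            roots = self.poles()
            if np.any(np.abs(roots) >= 1.0):
                raise ValueError("AR model is unstable")

    def poles(self) -> np.ndarray:
        """Roots of the characteristic polynomial z^p - a_1 z^{p-1} - ..."""
        if self.order == 0:
            return np.empty(0, dtype=complex)
        return np.roots(np.concatenate(([1.0], -self.coefficients)))

    def psd(self, freqs: np.ndarray) -> np.ndarray:
        """Two-sided spectral density (units^2 / Hz) at frequencies in Hz."""
        dt = self.mean_interval
        omega = 2.0 * np.pi * np.asarray(freqs, dtype=float) * dt
        k = np.arange(1, self.order + 1)
        a_term = np.exp(-1j * np.outer(omega, k)) @ self.coefficients
        denom = np.abs(1.0 - a_term) ** 2
        return self.innovation_variance * dt / denom

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.mean_interval)


@dataclass(frozen=True)
class SpectralComponent:
    """One pole-resolved oscillatory (or non-oscillatory) component."""

    central_freq: float  # Hz
    power: float  # ms^2 or mmHg^2 (may be slightly negative for crowded poles)
    is_complex_pair: bool


@dataclass(frozen=True)
class BandPowers:
    """Band-resolved powers of one fragment's spectrum.

    ``total`` is the fragment variance; band powers are sums of component
    powers whose central frequency falls inside the band.  ``lf_nu`` and
    ``hf_nu`` are percentages of LF + HF power and sum to 100 whenever
    defined.  ``lf_hf`` is NaN when the HF power is zero.
    """

    vlf_abs: float
    lf_abs: float
    hf_abs: float
    total: float
    lf_nu: float
    hf_nu: float
    lf_hf: float
    lf_peak: float  # Hz
    hf_peak: float  # Hz


# ---------------------------------------------------------------------------
# stationary-fragment selection
# ---------------------------------------------------------------------------

def _window_is_stationary(x: np.ndarray, k_mean: float, k_var: float) -> bool:
    """Thirds test: sub-window means within k_mean*SD and variances within
    k_var*variance of each other."""
    n = x.size
    third = n // 3
    parts = [x[:third], x[third:2 * third], x[2 * third:]]
    sd = float(np.std(x))
    var = sd * sd
    if var == 0.0:
        return True
    means = [float(np.mean(p)) for p in parts]
    variances = [float(np.var(p)) for p in parts]
    if max(means) - min(means) >= k_mean * sd:
        return False
    if max(variances) - min(variances) >= k_var * var:
        return False
    return True


def stationary_windows(arrays: list[np.ndarray], target_len: int,
                       k_mean: float = K_MEAN, k_var: float = K_VAR,
                       step: int = 1) -> list[tuple[int, int]]:
    """Non-overlapping windows of ``target_len`` that are stationary in
    every array of ``arrays`` simultaneously (greedy left-to-right scan).
    """
    n = min(a.size for a in arrays)
    if n < target_len:
        raise ShortInputError(
            f"series of {n} beats is shorter than target_len={target_len}")
    windows: list[tuple[int, int]] = []
    start = 0
    while start + target_len <= n:
        window = (start, start + target_len)
        if all(_window_is_stationary(a[window[0]:window[1]], k_mean, k_var)
               for a in arrays):
            windows.append(window)
            start += target_len  # non-overlapping
        else:
            start += step
    if not windows:
        raise NoStationaryFragmentError(
            "no stationary fragment found (criterion unmet in every window)")
    return windows


def select_stationary_fragments(series, target_len: int = DEFAULT_FRAGMENT_LEN,
                                *, kind: str = "tachogram",
                                mean_interval: float | None = None,
                                k_mean: float = K_MEAN, k_var: float = K_VAR,
                                step: int = 1) -> list[Fragment]:
    """Select stationary fragments of about ``target_len`` beats.

    ``series`` is a 1-D array (a tachogram in ms or systogram in mmHg).
    For a tachogram, ``mean_interval`` defaults to the fragment mean PI in
    seconds; for a systogram it must be supplied (the coincident
    tachogram's timing).
    """
    x = np.asarray(series, dtype=float)
    windows = stationary_windows([x], target_len, k_mean, k_var, step)
    fragments = []
    for lo, hi in windows:
        vals = x[lo:hi]
        if mean_interval is None:
            if kind != "tachogram":
                raise ValueError("mean_interval is required for systograms")
            mi = float(np.mean(vals)) / 1000.0
        else:
            mi = mean_interval
        fragments.append(Fragment(values=vals, mean_interval=mi, kind=kind,
                                  start=lo))
    return fragments


def select_coincident_fragments(beats: BeatSeries,
                                target_len: int = DEFAULT_FRAGMENT_LEN,
                                k_mean: float = K_MEAN, k_var: float = K_VAR,
                                step: int = 1,
                                ) -> list[tuple[Fragment, Fragment]]:
    """Coincident (same beat indices) tachogram/systogram fragment pairs.

    A window qualifies only if both the PI series and the SAP series are
    stationary over it; the pairs share timing through the tachogram's
    mean interval.
    """
    pi = beats.pi
    sap = beats.sap[:-1]  # align the systogram with the PI series
    windows = stationary_windows([pi, sap], target_len, k_mean, k_var, step)
    pairs = []
    for lo, hi in windows:
        mi = float(np.mean(pi[lo:hi])) / 1000.0
        tach = Fragment(values=pi[lo:hi], mean_interval=mi, kind="tachogram",
                        start=lo)
        syst = Fragment(values=sap[lo:hi], mean_interval=mi, kind="systogram",
                        start=lo)
        pairs.append((tach, syst))
    return pairs


# ---------------------------------------------------------------------------
# Burg AR estimation and order selection
# ---------------------------------------------------------------------------

def burg(x: np.ndarray, max_order: int) -> tuple[list[np.ndarray], np.ndarray]:
    """Burg recursion up to ``max_order``.

    Returns ``(coeffs, errs)`` where ``coeffs[p]`` are the AR(p)
    coefficients ``a_1..a_p`` in the prediction convention
    ``x_k = sum a_i x_{k-i} + e_k`` and ``errs[p]`` is the prediction-error
    power of the order-p model.  Reflection coefficients are bounded by 1 in
    magnitude, so every returned model is stable.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if max_order >= n:
        raise ValueError("order must be smaller than the series length")
    f = x.copy()
    b = x.copy()
    c = np.zeros(0)  # polynomial convention 1 + sum c_i z^-i
    e = float(np.dot(x, x)) / n
    errs = [e]
    coeffs: list[np.ndarray] = [np.zeros(0)]
    for m in range(1, max_order + 1):
        f_seg = f[m:]
        b_seg = b[m - 1:n - 1]
        den = float(np.dot(f_seg, f_seg) + np.dot(b_seg, b_seg))
        k = 0.0 if den <= 0.0 else -2.0 * float(np.dot(f_seg, b_seg)) / den
        c = np.concatenate((c, [0.0])) + k * np.concatenate((c[::-1], [1.0]))
        f_new = f.copy()
        b_new = b.copy()
        f_new[m:] = f_seg + k * b_seg
        b_new[m:] = b_seg + k * f_seg
        f, b = f_new, b_new
        e *= (1.0 - k * k)
        errs.append(e)
        coeffs.append(-c)  # back to prediction convention
    return coeffs, np.asarray(errs)


def fit_ar(fragment: Fragment, order: int) -> ARModel:
    """Fit an AR model of a given order to a fragment (Burg estimator).

    The fragment is mean-centred internally.
    """
    if order < 1:
        raise ValueError("order must be at least 1")
    if fragment.n_beats <= 2 * order:
        raise ValueError("fragment must be longer than twice the order")
    x = fragment.values - np.mean(fragment.values)
    if float(np.var(x)) <= 0.0:
        raise ZeroVarianceError("fragment has zero variance")
    coeffs, errs = burg(x, order)
    return ARModel(order=order, coefficients=coeffs[order],
                   innovation_variance=float(errs[order]),
                   mean_interval=fragment.mean_interval)


def aic_curve(fragment: Fragment, p_max: int) -> np.ndarray:
    """AIC(p) = n ln(innovation_variance_p) + 2p for p = 0..p_max."""
    x = fragment.values - np.mean(fragment.values)
    if float(np.var(x)) <= 0.0:
        raise ZeroVarianceError("fragment has zero variance")
    _, errs = burg(x, p_max)
    n = x.size
    with np.errstate(divide="ignore"):
        return n * np.log(errs) + 2.0 * np.arange(p_max + 1)


def select_order(fragment: Fragment, p_min: int = DEFAULT_ORDER_RANGE[0],
                 p_max: int = DEFAULT_ORDER_RANGE[1]) -> int:
    """AIC-minimizing order over [p_min, p_max]; ties go to the smaller p."""
    if p_min < 1:
        raise ValueError("p_min must be at least 1")
    if p_max >= fragment.n_beats / 2:
        raise ValueError("p_max must be below half the fragment length")
    aic = aic_curve(fragment, p_max)
    candidates = aic[p_min:p_max + 1]
    return p_min + int(np.argmin(candidates))  # argmin takes the first = smallest p


# ---------------------------------------------------------------------------
# spectral decomposition
# ---------------------------------------------------------------------------

def decompose_spectrum(model: ARModel) -> list[SpectralComponent]:
    """Pole-resolved components of an AR model's spectrum.

    Each real pole gives one component; each complex-conjugate pair gives
    one oscillatory component.  The component power is the residue of the
    spectral density at the pole (doubled for a pair), so the powers sum to
    the process variance.  A flat single component is returned for an
    order-0 (or all-zero) model.
    """
    a = model.coefficients
    sigma2 = model.innovation_variance
    if model.order == 0 or np.allclose(a, 0.0):
        return [SpectralComponent(central_freq=0.0, power=sigma2,
                                  is_complex_pair=False)]
    poles = model.poles()
    radii = np.abs(poles)
    if np.any(radii > NEAR_UNIT_RADIUS):
        logger.warning("near-unit-circle pole (|z| = %.5f): component powers "
                       "may be ill-conditioned", float(np.max(radii)))
    p = model.order
    components: list[SpectralComponent] = []
    used = np.zeros(p, dtype=bool)
    for k in range(p):
        if used[k]:
            continue
        pk = poles[k]
        others = np.delete(poles, k)
        denom = np.prod(pk - others) * np.prod(1.0 - poles * pk)
        if denom == 0:
            raise np.linalg.LinAlgError("degenerate (repeated) AR poles")
        residue = sigma2 * pk ** (p - 1) / denom
        freq = abs(np.angle(pk)) / (2.0 * np.pi * model.mean_interval)
        if abs(pk.imag) > 1e-10:
            # pair with the conjugate pole
            conj_idx = None
            for j in range(k + 1, p):
                if not used[j] and abs(poles[j] - np.conj(pk)) < 1e-8 * max(1.0, abs(pk)):
                    conj_idx = j
                    break
            if conj_idx is None:
                # numerically unpaired; fall back to nearest-conjugate match
                rem = [j for j in range(p) if not used[j] and j != k]
                conj_idx = min(rem, key=lambda j: abs(poles[j] - np.conj(pk)))
            used[conj_idx] = True
            power = 2.0 * residue.real
            components.append(SpectralComponent(central_freq=freq,
                                                power=float(power),
                                                is_complex_pair=True))
        else:
            components.append(SpectralComponent(central_freq=freq,
                                                power=float(residue.real),
                                                is_complex_pair=False))
        used[k] = True
    return components


def band_powers(components: list[SpectralComponent], mean_interval: float,
                bands=RAT_BANDS, total: float | None = None) -> BandPowers:
    """Assign component powers to the VLF/LF/HF bands.

    Bands are half-open at the lower edge and the HF band is closed at its
    upper edge; components above the HF edge are excluded from band sums
    but still counted in ``total`` when it is derived from the components.
    Band sums are floored at zero (residue powers of crowded poles can be
    marginally negative).  ``total`` defaults to the sum of all component
    powers; the pipeline passes the fragment variance instead.
    """
    (v_lo, v_hi), (l_lo, l_hi), (h_lo, h_hi) = bands
    if not (v_lo < v_hi <= l_lo < l_hi <= h_lo < h_hi):
        raise ValueError("band edges must be strictly increasing")
    sums = {"vlf": 0.0, "lf": 0.0, "hf": 0.0}
    peaks = {"lf": (np.nan, -np.inf), "hf": (np.nan, -np.inf)}
    for comp in components:
        f = comp.central_freq
        if v_lo <= f < v_hi:
            sums["vlf"] += comp.power
        elif l_lo <= f < l_hi:
            sums["lf"] += comp.power
            if comp.power > peaks["lf"][1]:
                peaks["lf"] = (f, comp.power)
        elif h_lo <= f <= h_hi:
            sums["hf"] += comp.power
            if comp.power > peaks["hf"][1]:
                peaks["hf"] = (f, comp.power)
    vlf = max(sums["vlf"], 0.0)
    lf = max(sums["lf"], 0.0)
    hf = max(sums["hf"], 0.0)
    if total is None:
        total = float(sum(c.power for c in components))
    if lf + hf > 0:
        lf_nu = 100.0 * lf / (lf + hf)
        hf_nu = 100.0 - lf_nu
    else:
        lf_nu = hf_nu = np.nan
    lf_hf = lf / hf if hf > 0 else np.nan
    return BandPowers(vlf_abs=vlf, lf_abs=lf, hf_abs=hf, total=float(total),
                      lf_nu=lf_nu, hf_nu=hf_nu, lf_hf=lf_hf,
                      lf_peak=peaks["lf"][0], hf_peak=peaks["hf"][0])


def analyze_fragment(fragment: Fragment,
                     p_min: int = DEFAULT_ORDER_RANGE[0],
                     p_max: int = DEFAULT_ORDER_RANGE[1],
                     bands=RAT_BANDS) -> tuple[ARModel, BandPowers]:
    """Order selection, AR fit, decomposition and band powers in one step.

    The reported total is the fragment variance (the conventional
    definition of total HRV/SAPV), not the AR-implied variance.
    """
    order = select_order(fragment, p_min, p_max)
    model = fit_ar(fragment, order)
    components = decompose_spectrum(model)
    return model, band_powers(components, fragment.mean_interval, bands,
                              total=fragment.variance)
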