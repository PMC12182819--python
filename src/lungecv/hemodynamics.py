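"""Stroke volume, cardiac output, mitral regurgitant fraction, pulmonary
transit time and pulmonary blood volume from time-series inputs.

Indicator-dilution: the pulmonary transit time (PTT) is the difference of
the first moments (centroids) of gamma-variate fits to the RV and LV
first-pass curves, after baseline subtraction and truncation of
recirculation at 50% of the peak on the down-slope.  With cardiac output it
gives the pulmonary blood volume, PBV = PTT * CO.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import simpson
from scipy.optimize import curve_fit

from .phantom import gamma_variate
from .types import FirstPassCurves, FlowCurve, LungECVError, LVVolumeCurve, ValidationError

__all__ = [
    "stroke_volume",
    "cardiac_output",
    "regurgitant_fraction",
    "lv_stroke_volume",
    "fit_gamma_variate",
    "pulmonary_transit_time",
    "pulmonary_blood_volume",
    "PTTFitError",
]


class PTTFitError(LungECVError):
    """Gamma-variate fit failed on a first-pass curve."""


# --------------------------------------------------------------------------- #
# Flow-derived quantities
# --------------------------------------------------------------------------- #

def _detect_beats(time_s: np.ndarray, flow: np.ndarray) -> np.ndarray:
    """Beat boundaries from flow onsets (rising crossings of a 2% threshold)."""
    peak = float(np.max(flow))
    if peak <= 0:
        raise ValidationError("flow curve has no forward flow")
    thr = 0.02 * peak
    above = flow > thr
    onsets = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if onsets.size < 1:
        raise ValidationError("no beat onset found in the flow curve")
    # walk each onset back through the sub-threshold diastole so the
    # integration window starts at the quiescent phase (keeps the waveform
    # kinks aligned with the sample pairing of the integrator)
    refined = []
    for i in onsets:
        j = int(i)
        while j > 0 and flow[j - 1] <= thr:
            j -= 1
        refined.append(j)
    onsets = np.unique(refined)
    return time_s[onsets]


def stroke_volume(flow: FlowCurve) -> float:
    """Forward stroke volume (mL): integral of flow over one beat, averaged
    across the complete beats of the recording.

    Beat boundaries come from the curve's R-wave times when present,
    otherwise from flow-onset detection.  Integration uses Simpson's rule.
    """
    t, q = flow.time_s, flow.flow_ml_s
    if flow.beat_times_s is not None and len(flow.beat_times_s) >= 2:
        bounds = np.asarray(flow.beat_times_s, float)
    else:
        onsets = _detect_beats(t, q)
        bounds = onsets
    bounds = bounds[(bounds >= t[0] - 1e-9) & (bounds <= t[-1] + 1e-9)]
    if bounds.size < 2:
        raise ValidationError("no complete beat in the flow recording")
    svs = []
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        sel = (t >= b0 - 1e-9) & (t <= b1 + 1e-9)
        if sel.sum() < 4:
            continue
        svs.append(simpson(q[sel], x=t[sel]))
    if not svs:
        raise ValidationError("no complete beat in the flow recording")
    return float(np.mean(svs))


def cardiac_output(stroke_volume_ml: float, heart_rate_bpm: float) -> float:
    """Cardiac output (L/min) = SV * HR."""
    if stroke_volume_ml < 0 or heart_rate_bpm <= 0:
        raise ValidationError("need SV >= 0 and HR > 0")
    return stroke_volume_ml * heart_rate_bpm / 1e3


def regurgitant_fraction(sv_left_ventricle_ml: float,
                         sv_aorta_ml: float,
                         flags: list[str] | None = None) -> float:
    """Mitral regurgitant fraction = (SV_LV - SV_aorta) / SV_LV.

    Negative values (aortic SV exceeding LV SV) are flagged, not clipped.
    """
    if sv_left_ventricle_ml <= 0:
        raise ValidationError("LV stroke volume must be positive")
    rf = (sv_left_ventricle_ml - sv_aorta_ml) / sv_left_ventricle_ml
    if flags is not None and rf < 0:
        flags.append("negative_regurgitant_fraction")
    return rf


def lv_stroke_volume(lv: LVVolumeCurve) -> float:
    """LV stroke volume (mL): end-diastolic minus end-systolic volume."""
    return float(np.max(lv.volume_ml) - np.min(lv.volume_ml))


# --------------------------------------------------------------------------- #
# Indicator dilution
# --------------------------------------------------------------------------- #

def _gamma_peak_form(t, ymax, t0, tp, alpha):
    """Gamma-variate in the numerically stable peak parameterization:
    y = ymax (tau/tp)^alpha exp(alpha (1 - tau/tp)), tau = t - t0 > 0."""
    t = np.asarray(t, float)
    out = np.zeros_like(t)
    m = t > t0
    r = (t[m] - t0) / tp
    out[m] = ymax * np.exp(alpha * (np.log(r) + 1.0 - r))
    return out


def fit_gamma_variate(time_s: np.ndarray, y: np.ndarray
                      ) -> tuple[np.ndarray, float]:
    """Fit a gamma-variate to a baseline-subtracted, truncated bolus curve.

    The fit runs in the (peak, arrival, time-to-peak, alpha) form, which is
    far better conditioned than the raw k tau^alpha scale.  Returns
    (params (k, t0, alpha, beta), first moment t0 + (alpha+1)*beta).
    """
    t = np.asarray(time_s, float)
    y = np.asarray(y, float)
    peak_idx = int(np.argmax(y))
    peak = y[peak_idx]
    if peak <= 0:
        raise PTTFitError("curve has no positive peak")
    dt = t[1] - t[0] if t.size > 1 else 1.0
    ys = np.convolve(y, np.ones(3) / 3.0, mode="same") if y.size >= 3 else y
    above = np.flatnonzero(ys > 0.1 * np.max(ys))
    t_arr = t[above[0]] if above.size else t[0]
    t0_0 = max(t_arr - dt, t[0] - 5.0)
    tp_0 = max(t[peak_idx] - t0_0, dt)
    # bounds encode bolus physiology: arrival within two frames of the 10%
    # upslope, time-to-peak near the observed one, moderate skewness
    lower = [0.0, t_arr - 2.0 * dt, dt / 2.0, 1.0]
    upper = [np.inf, t[peak_idx], (t[peak_idx] - t_arr) + 3.0 * dt, 10.0]
    p0 = [peak, t0_0, tp_0, 3.0]
    p0 = np.clip(p0, lower, upper)
    try:
        popt, _ = curve_fit(_gamma_peak_form, t, y, p0=p0,
                            bounds=(lower, upper), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise PTTFitError(f"gamma-variate fit failed: {exc}") from exc
    ymax, t0, tp, alpha = popt
    beta = tp / alpha
    k = ymax / (tp ** alpha * np.exp(-alpha))
    params = np.array([k, t0, alpha, beta])
    return params, float(t0 + (alpha + 1.0) * beta)


def _prepare_bolus(t: np.ndarray, y: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-subtract and truncate recirculation at 50% of the peak on
    the down-slope.

    Landmark decisions (arrival, peak, truncation point) are taken on a
    3-point moving average so single noisy frames cannot shift them; the
    returned samples are the raw data.
    """
    ys = np.convolve(y, np.ones(3) / 3.0, mode="same") if y.size >= 3 else y
    peak_idx = int(np.argmax(ys))
    peak = ys[peak_idx]
    pre = np.flatnonzero(ys > 0.1 * (peak - ys.min()) + ys.min())
    baseline = (float(np.median(y[: pre[0]]))
                if pre.size and pre[0] > 0 else float(ys.min()))
    yc = y - baseline
    peak_s = peak - baseline
    if peak_s <= 0:
        raise PTTFitError("degenerate first-pass curve after baseline removal")
    cut = yc.size
    for i in range(peak_idx + 1, yc.size):
        if ys[i] - baseline < 0.5 * peak_s:
            cut = i + 1
            break
    return t[:cut], yc[:cut]


def pulmonary_transit_time(curves: FirstPassCurves) -> float:
    """Pulmonary transit time (s): difference of gamma-variate first moments
    of the LV and RV first-pass curves."""
    t_rv, y_rv = _prepare_bolus(curves.time_s, curves.rv)
    t_lv, y_lv = _prepare_bolus(curves.time_s, curves.lv)
    _, m_rv = fit_gamma_variate(t_rv, y_rv)
    _, m_lv = fit_gamma_variate(t_lv, y_lv)
    return float(m_lv - m_rv)


def pulmonary_blood_volume(ptt_s: float, cardiac_output_l_min: float) -> float:
    """Pulmonary blood volume (mL) = PTT (s) * CO (mL/s)."""
    if ptt_s < 0 or cardiac_output_l_min < 0:
        raise ValidationError("PTT and CO must be nonnegative")
    return ptt_s * cardiac_output_l_min * 1e3 / 60.0
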