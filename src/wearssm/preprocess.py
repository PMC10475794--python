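"""Channel preprocessing before model fitting.

Long-term CGM trends are removed with a squared-exponential Gaussian
process (length scale 48 h by default); activity/HR/HRV are normalized by
their sample standard deviations; HRV (RMSSD, ms) is inverted to the
modeled RMSSD^-1 variable.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg as sla

from wearssm.datamodel_io import Channel, DataError, SensorSeries


@dataclasses.dataclass
class DetrendResult:
    trend: np.ndarray
    detrended: SensorSeries
    length_scale: float
    noise_sd: float


def _default_noise_sd(values: np.ndarray) -> float:
    # scale-matched default: SD of first differences / sqrt(2); with a
    # smooth trend this estimates the short-term fluctuation scale.
    d = np.diff(values)
    sd = float(np.std(d, ddof=1) / np.sqrt(2.0)) if d.size > 1 else 1.0
    return sd if sd > 0 else 1.0


def gp_detrend(
    glucose: SensorSeries,
    length_scale: float = 48.0,
    noise_sd: float | None = None,
) -> DetrendResult:
    """Remove long-term trends with a squared-exponential GP.

    The GP posterior mean is fitted to the mean-centred observed values
    with kernel ``exp(-|t-t'|^2 / (2 l^2))`` and evaluated on the full
    grid; the detrended series is ``data - trend + grand mean`` so the
    participant's mean glucose level is preserved.
    """
    if length_scale <= 0:
        raise ValueError("length scale must be positive")
    t_obs, y_obs = glucose.observed_arrays()
    if t_obs.size < 2:
        raise ValueError("need at least 2 observed points to detrend")
    if noise_sd is None:
        noise_sd = _default_noise_sd(y_obs)
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")

    mean = float(np.mean(y_obs))
    yc = y_obs - mean
    d2 = (t_obs[:, None] - t_obs[None, :]) ** 2
    K = np.exp(-d2 / (2.0 * length_scale**2))
    A = K + (noise_sd**2) * np.eye(t_obs.size)
    try:
        cf = sla.cho_factor(A, lower=True)
        alpha = sla.cho_solve(cf, yc)
    except sla.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            "singular kernel system; increase noise_sd (jitter) or thin the grid"
        ) from exc

    d2x = (glucose.times[:, None] - t_obs[None, :]) ** 2
    Kx = np.exp(-d2x / (2.0 * length_scale**2))
    trend = Kx @ alpha + mean

    values = glucose.values - trend + mean
    values = np.where(glucose.missing, glucose.values, values)
    detrended = glucose.replace(values=values)
    return DetrendResult(trend, detrended, float(length_scale), float(noise_sd))


def sd_normalize(series: SensorSeries) -> tuple[SensorSeries, float]:
    """Divide observed values by their sample SD; return (series, sd)."""
    _, v = series.observed_arrays()
    if v.size < 2:
        raise ValueError("need at least 2 observed values")
    sd = float(np.std(v, ddof=1))
    if sd == 0:
        raise ValueError("zero variance: cannot SD-normalize")
    return series.replace(values=series.values / sd), sd


def rmssd_inverse(series: SensorSeries) -> SensorSeries:
    """Elementwise reciprocal (RMSSD ms -> RMSSD^-1 ms^-1); missing propagated."""
    obs = series.observed
    if np.any(series.values[obs] <= 0):
        raise DataError("nonpositive RMSSD value observed")
    values = series.values.copy()
    values[obs] = 1.0 / values[obs]
    units = "ms^-1" if series.units == "ms" else "ms"
    return series.replace(values=values, units=units)


def prepare_cardio(
    record_series: dict[Channel, SensorSeries],
) -> tuple[dict[Channel, SensorSeries], dict[Channel, float]]:
    """HRV inversion followed by SD normalization of all three channels."""
    out: dict[Channel, SensorSeries] = {}
    sds: dict[Channel, float] = {}
    for ch in (Channel.ACTIVITY, Channel.HR, Channel.HRV):
        s = record_series[ch]
        if ch is Channel.HRV:
            s = rmssd_inverse(s)
        out[ch], sds[ch] = sd_normalize(s)
    return out, sds
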