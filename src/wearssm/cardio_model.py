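"""Model 2: coupled physical activity, HR and HRV dynamics.

Activity drives HR and HRV through a lower-triangular drift; HR and HRV
fluctuations are correlated through the process-noise covariance. All
three channels are SD-normalized (HRV as inverted RMSSD) and carry their
own circadian baseline in the observation mean.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from wearssm.datamodel_io import Channel, ParticipantRecord
from wearssm.glucose_model import circadian_baseline, cosinor_fit
from wearssm.inference import (
    Flat,
    HalfNormal,
    Identity,
    Log,
    LogNormal,
    Normal,
    ParamModel,
    ParamSpec,
    Tanh,
)
from wearssm.preprocess import prepare_cardio
from wearssm.ssm_core import LTISystem, kalman_filter, kalman_smooth

CARDIO_CHANNELS = (Channel.ACTIVITY, Channel.HR, Channel.HRV)
H_CARDIO = np.eye(3)


@dataclasses.dataclass
class CircadianTriple:
    A0: float
    A1: float
    phi: float

    def __post_init__(self) -> None:
        if self.A1 < 0:
            raise ValueError("circadian amplitude must be nonnegative")


@dataclasses.dataclass
class CardioParams:
    C11: float
    C21: float
    C22: float
    C31: float
    C33: float
    D11: float
    D22: float
    D33: float
    rho: float
    circadian: dict[Channel, CircadianTriple]
    sigma: dict[Channel, float]

    def __post_init__(self) -> None:
        for name in ("C11", "C21", "C22", "C31", "C33"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("D11", "D22", "D33"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not -1 < self.rho < 1:
            raise ValueError("rho must lie in (-1, 1)")
        for ch in CARDIO_CHANNELS:
            if self.sigma[ch] <= 0:
                raise ValueError(f"sigma[{ch.value}] must be positive")

    @property
    def W(self) -> np.ndarray:
        return np.array(
            [
                [-self.C11, 0.0, 0.0],
                [self.C21, -self.C22, 0.0],
                [self.C31, 0.0, -self.C33],
            ]
        )

    @property
    def Q(self) -> np.ndarray:
        # printed off-diagonal "rho D22 D33" read as rho*sqrt(D22*D33) so
        # that |rho| < 1 bounds the fluctuation correlation
        c = self.rho * np.sqrt(self.D22 * self.D33)
        return np.array(
            [[self.D11, 0.0, 0.0], [0.0, self.D22, c], [0.0, c, self.D33]]
        )

    def sigma_vec(self) -> np.ndarray:
        return np.array([self.sigma[ch] for ch in CARDIO_CHANNELS])


def build_cardio_system(params: CardioParams) -> LTISystem:
    """LTI system for Model 2 (raises if Q is not PSD)."""
    return LTISystem(params.W, params.Q)


def circadian_means(params: CardioParams, t: np.ndarray) -> np.ndarray:
    """(T, 3) circadian observation means for activity/HR/HRV."""
    cols = [
        circadian_baseline(tr.A0, tr.A1, tr.phi, t)
        for tr in (params.circadian[ch] for ch in CARDIO_CHANNELS)
    ]
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CardioData:
    """Normalized aux channels on a common grid with per-channel masks."""

    times: np.ndarray
    y: np.ndarray  # (T, 3) normalized values (HRV inverted first)
    mask: np.ndarray  # (T, 3) True = observed
    sds: dict[Channel, float]

    @property
    def n_obs(self) -> int:
        return int(np.count_nonzero(self.mask))


def prepare_cardio_data(record: ParticipantRecord) -> CardioData:
    series, sds = prepare_cardio(record.series)
    base = series[Channel.ACTIVITY].times
    for ch in CARDIO_CHANNELS:
        if not np.array_equal(series[ch].times, base):
            raise ValueError("cardio channels must share one time grid")
    y = np.column_stack([series[ch].values for ch in CARDIO_CHANNELS])
    mask = np.column_stack([series[ch].observed for ch in CARDIO_CHANNELS])
    y = np.where(mask, y, 0.0)
    return CardioData(base, y, mask, sds)


def model2_loglik(params: CardioParams, data: CardioData) -> float:
    """Exact likelihood with per-step missing-channel handling."""
    m = circadian_means(params, data.times)
    res = kalman_filter(
        build_cardio_system(params),
        data.times,
        data.y,
        data.mask,
        m,
        params.sigma_vec() ** 2,
        H_CARDIO,
    )
    return res.loglik


# ---------------------------------------------------------------------------
# ParamModel construction
# ---------------------------------------------------------------------------

_RATE_NAMES = ("C11", "C21", "C22", "C31", "C33")
_DIFF_NAMES = ("D11", "D22", "D33")
_CH_TAGS = {Channel.ACTIVITY: "act", Channel.HR: "hr", Channel.HRV: "hrv"}


def theta_to_cardio(theta: np.ndarray) -> CardioParams:
    rates = dict(zip(_RATE_NAMES, theta[:5]))
    diffs = dict(zip(_DIFF_NAMES, theta[5:8]))
    rho = float(theta[8])
    circ = {}
    for i, ch in enumerate(CARDIO_CHANNELS):
        a0, a1, phi = theta[9 + 3 * i : 12 + 3 * i]
        circ[ch] = CircadianTriple(float(a0), float(a1), float(phi) % 24.0)
    sig = {ch: float(theta[18 + i]) for i, ch in enumerate(CARDIO_CHANNELS)}
    return CardioParams(rho=rho, circadian=circ, sigma=sig, **rates, **diffs)


def cardio_to_theta(params: CardioParams) -> np.ndarray:
    out = [getattr(params, n) for n in _RATE_NAMES + _DIFF_NAMES] + [params.rho]
    for ch in CARDIO_CHANNELS:
        tr = params.circadian[ch]
        out += [tr.A0, tr.A1, tr.phi]
    out += [params.sigma[ch] for ch in CARDIO_CHANNELS]
    return np.array(out, dtype=float)


def default_cardio_init(data: CardioData) -> CardioParams:
    circ = {}
    for i, ch in enumerate(CARDIO_CHANNELS):
        obs = data.mask[:, i]
        mesor, amp, phase = cosinor_fit(data.times[obs], data.y[obs, i])
        circ[ch] = CircadianTriple(mesor, min(max(amp, 0.05), 5.0), phase)
    return CardioParams(
        C11=2.0, C21=1.0, C22=2.0, C31=1.0, C33=2.0,
        D11=1.0, D22=1.0, D33=1.0, rho=0.0,
        circadian=circ,
        sigma={ch: 0.3 for ch in CARDIO_CHANNELS},
    )


def model2_param_model(
    data: CardioData,
    priors: dict[str, object] | None = None,
    init: CardioParams | None = None,
) -> ParamModel:
    init = init or default_cardio_init(data)
    init_theta = cardio_to_theta(init)
    prior_map: dict[str, object] = {n: LogNormal(0.5, 1.0) for n in _RATE_NAMES}
    prior_map.update({n: HalfNormal(2.0) for n in _DIFF_NAMES})
    prior_map["rho"] = Flat()  # uniform over (-1, 1) via the tanh transform
    for ch in CARDIO_CHANNELS:
        tag = _CH_TAGS[ch]
        prior_map[f"A0_{tag}"] = Normal(0.0, 10.0)
        prior_map[f"A1_{tag}"] = HalfNormal(2.0)
        prior_map[f"phi_{tag}"] = Flat()
        prior_map[f"sigma_{tag}"] = HalfNormal(2.0)
    if priors:
        prior_map.update(priors)

    specs: list[ParamSpec] = []
    idx = 0
    for n in _RATE_NAMES + _DIFF_NAMES:
        specs.append(ParamSpec(n, prior_map[n], Log(), float(init_theta[idx])))
        idx += 1
    specs.append(ParamSpec("rho", prior_map["rho"], Tanh(), float(init_theta[idx])))
    idx += 1
    for ch in CARDIO_CHANNELS:
        tag = _CH_TAGS[ch]
        specs.append(ParamSpec(f"A0_{tag}", prior_map[f"A0_{tag}"], Identity(), float(init_theta[idx])))
        specs.append(ParamSpec(f"A1_{tag}", prior_map[f"A1_{tag}"], Log(), float(init_theta[idx + 1])))
        specs.append(ParamSpec(f"phi_{tag}", prior_map[f"phi_{tag}"], Identity(), float(init_theta[idx + 2])))
        idx += 3
    for ch in CARDIO_CHANNELS:
        tag = _CH_TAGS[ch]
        specs.append(ParamSpec(f"sigma_{tag}", prior_map[f"sigma_{tag}"], Log(), float(init_theta[idx])))
        idx += 1

    def loglik(theta: np.ndarray) -> float:
        return model2_loglik(theta_to_cardio(theta), data)

    model = ParamModel(specs, loglik)
    model.to_params = theta_to_cardio  # type: ignore[attr-defined]
    return model


# ---------------------------------------------------------------------------
# Conditional prediction / variance decomposition
# ---------------------------------------------------------------------------


def conditional_prediction(
    params: CardioParams,
    data: CardioData,
    target: Channel,
    included: Sequence[Channel],
    smooth: bool = True,
) -> np.ndarray:
    """E[target channel | observations of the included channels] on the
    full grid, including the target's circadian mean.

    ``included`` must not contain the target. With no included channels
    the prediction is exactly the circadian curve. Uses fixed-interval
    smoothing by default; ``smooth=False`` uses filtered estimates.
    """
    if target in included:
        raise ValueError("target must not be among the included channels")
    for ch in list(included) + [target]:
        if ch not in CARDIO_CHANNELS:
            raise ValueError(f"unknown cardio channel {ch}")
    inc_idx = [CARDIO_CHANNELS.index(ch) for ch in included]
    tgt = CARDIO_CHANNELS.index(target)

    m = circadian_means(params, data.times)
    mask = np.zeros_like(data.mask)
    for i in inc_idx:
        mask[:, i] = data.mask[:, i]
    res = kalman_filter(
        build_cardio_system(params),
        data.times,
        data.y,
        mask,
        m,
        params.sigma_vec() ** 2,
        H_CARDIO,
    )
    if smooth:
        sm, _ = kalman_smooth(res)
    else:
        sm = res.filt_mean
    return sm[:, tgt] + m[:, tgt]


def explained_variance_table(
    params: CardioParams, data: CardioData, smooth: bool = True
) -> dict[str, float]:
    """Point-parameter explained-variance decomposition.

    HR: circadian only, then circadian + activity. HRV: circadian only,
    + activity, + activity and HR.
    """
    out: dict[str, float] = {}
    cases = {
        "hr|circ": (Channel.HR, []),
        "hr|circ+act": (Channel.HR, [Channel.ACTIVITY]),
        "hrv|circ": (Channel.HRV, []),
        "hrv|circ+act": (Channel.HRV, [Channel.ACTIVITY]),
        "hrv|circ+act+hr": (Channel.HRV, [Channel.ACTIVITY, Channel.HR]),
    }
    for key, (target, included) in cases.items():
        tgt = CARDIO_CHANNELS.index(target)
        obs = data.mask[:, tgt]
        yt = conditional_prediction(params, data, target, included, smooth=smooth)
        y = data.y[obs, tgt]
        out[key] = 1.0 - float(np.var(y - yt[obs])) / float(np.var(y))
    return out
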