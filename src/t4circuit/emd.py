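"""Minimal Hassenstein-Reichardt (HR) and Barlow-Levick (BL) detectors.

Both models combine two input channels with spatially offset fields of
view, one carrying a delay (here a first-order low-pass with time constant
τ), through a nonlinearity:

* HR (correlator): ``mean_t[ LP(s1)·s2 − s1·LP(s2) ]`` — preferred-direction
  enhancement, exactly antisymmetric under channel swap;
* BL: ``mean_t[ rect(s2 − g·LP(s1)) ]`` with a delayed *inhibitory* channel
  1 of gain g — null-direction suppression: motion that reaches the
  inhibitory field first arrives at the excitatory field with inhibition
  already built up.

For a BL detector the preferred direction therefore points **from the
excitatory toward the inhibitory field centre**: moving that way the
stimulus hits excitation first and escapes the delayed inhibition.
Mapped onto T4 anatomy — non-delayed excitation at the Mi1/Tm3 (shaft)
subfield centre, delayed inhibition at the Mi4/C3/CT1 (base) centre — this
predicts a preferred direction from shaft toward base, i.e. opposite to
the direction the dendrites extend.

The delay τ is a free parameter (default 150 ms), not a fit: the measured
Mi1/Tm3 latency difference (~15 ms) is too small to set the ~1 Hz temporal
frequency optimum, so no particular biophysical delay is asserted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .hexgrid import CartPoint
from .model import CellType

__all__ = [
    "DetectorConfig",
    "StimulusSpec",
    "sample_stimulus",
    "lowpass",
    "detector_response",
    "dsi",
    "circuit_from_anatomy",
    "direction_tuning",
    "transmitter_signs",
    "KNOWN_SIGNS",
]

#: Putative transmitter signs from immunolabelling: cholinergic (+) Mi1,
#: Tm3 and T4; GABAergic (-) Mi4, C3, CT1 and TmY15.  Mi9 (glutamatergic)
#: is deliberately absent: its sign is tentative and must be chosen
#: explicitly via :func:`transmitter_signs`.
KNOWN_SIGNS: dict[CellType, str] = {
    CellType.Mi1: "+",
    CellType.Tm3: "+",
    CellType.Mi4: "-",
    CellType.C3: "-",
    CellType.CT1: "-",
    CellType.TmY15: "-",
    CellType.T4a: "+",
    CellType.T4b: "+",
    CellType.T4c: "+",
    CellType.T4d: "+",
}


def transmitter_signs(mi9_sign: Optional[str] = None) -> dict[CellType, str]:
    """The sign table, optionally committing to a sign for Mi9.

    Mi9 is glutamatergic and could be excitatory or inhibitory depending
    on receptor expression; both choices are runnable, neither is a
    default truth.
    """
    signs = dict(KNOWN_SIGNS)
    if mi9_sign is not None:
        if mi9_sign not in ("+", "-"):
            raise ValueError("mi9_sign must be '+' or '-'")
        signs[CellType.Mi9] = mi9_sign
    return signs


@dataclass(frozen=True)
class DetectorConfig:
    """Two-channel detector: channel 1 carries the delay τ, channel 2 does not."""

    offset_1: CartPoint  # delayed channel, ommatidial units
    offset_2: CartPoint  # non-delayed channel
    sign_1: str = "-"
    sign_2: str = "+"
    tau: float = 0.150  # s
    model: str = "BL"  # 'HR' | 'BL'
    dt: float = 0.001  # s
    gain: float = 1.0  # inhibitory gain g (BL)

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.dt <= 0:
            raise ValueError("tau and dt must be positive")
        if self.model not in ("HR", "BL"):
            raise ValueError(f"unknown model {self.model!r}")
        o1, o2 = tuple(self.offset_1), tuple(self.offset_2)
        if o1 == o2:
            raise ValueError("channel offsets must be distinct")

    def swapped(self) -> "DetectorConfig":
        return replace(
            self,
            offset_1=self.offset_2,
            offset_2=self.offset_1,
            sign_1=self.sign_2,
            sign_2=self.sign_1,
        )

    def mirrored(self) -> "DetectorConfig":
        return replace(
            self,
            offset_1=CartPoint(-self.offset_1[0], -self.offset_1[1]),
            offset_2=CartPoint(-self.offset_2[0], -self.offset_2[1]),
        )


@dataclass(frozen=True)
class StimulusSpec:
    """A visual stimulus in lattice coordinates (ommatidial units).

    kind 'moving_edge': an ON edge sweeping along ``direction`` at
    ``speed`` units/s (luminance steps 0 → contrast as the edge passes);
    'drifting_sinusoid': a grating of the given spatial ``wavelength``
    drifting along ``direction``; 'static': constant luminance.
    """

    kind: str = "moving_edge"
    direction: float = 0.0  # radians
    speed: float = 1.0  # units / s
    contrast: float = 1.0
    duration: float = 4.0  # s
    wavelength: float = 4.0  # units (sinusoid)
    edge_start: float = -2.0  # units behind the origin along the direction

    def __post_init__(self) -> None:
        if self.kind not in ("moving_edge", "drifting_sinusoid", "static"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if not (0 < self.duration < math.inf):
            raise ValueError("duration must be finite and positive")


def sample_stimulus(
    spec: StimulusSpec, point: Sequence[float], times: np.ndarray
) -> np.ndarray:
    """Luminance time series at one spatial point."""
    t = np.asarray(times, dtype=float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    u = np.array([math.cos(spec.direction), math.sin(spec.direction)])
    proj = float(np.dot(np.asarray(point, dtype=float)[:2], u))
    if spec.kind == "static":
        return np.full_like(t, spec.contrast)
    if spec.kind == "moving_edge":
        edge = spec.edge_start + spec.speed * t
        return np.where(edge >= proj, spec.contrast, 0.0)
    phase = 2.0 * math.pi * (spec.speed * t - proj) / spec.wavelength
    return spec.contrast * np.sin(phase)


def lowpass(signal: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """First-order exponential low-pass with unit DC gain.

    Discretized with the exact decay factor exp(-dt/τ), so an impulse
    decays with time constant τ and a constant input converges to itself;
    a sinusoid at frequency f is attenuated by ~1/sqrt(1 + (2πfτ)²).
    """
    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be positive")
    x = np.asarray(signal, dtype=float)
    decay = math.exp(-dt / tau)
    from scipy.signal import lfilter

    y = lfilter([1.0 - decay], [1.0, -decay], x)
    return y


def detector_response(
    config: DetectorConfig,
    spec: StimulusSpec,
    return_series: bool = False,
) -> float | tuple[float, np.ndarray]:
    """Time-averaged detector output for one stimulus.

    The first filter time constant of the response is discarded as
    transient before averaging.
    """
    n = max(int(round(spec.duration / config.dt)), 2)
    t = np.arange(n) * config.dt
    s1 = sample_stimulus(spec, config.offset_1, t)
    s2 = sample_stimulus(spec, config.offset_2, t)
    lp1 = lowpass(s1, config.tau, config.dt)
    if config.model == "HR":
        lp2 = lowpass(s2, config.tau, config.dt)
        r = lp1 * s2 - s1 * lp2
    else:
        drive = s2 - config.gain * lp1 if config.sign_1 == "-" else s2 + config.gain * lp1
        r = np.maximum(drive, 0.0)
    skip = min(int(round(config.tau / config.dt)), n - 1)
    mean = float(r[skip:].mean())
    if return_series:
        return mean, r
    return mean


def dsi(r_pd: float, r_nd: float) -> float:
    """Direction selectivity index (PD - ND) / (PD + ND) in [-1, 1].

    Responses are first offset to be non-negative (a common shift changes
    neither the sign nor the ordering); a zero denominator is degenerate.
    """
    shift = min(r_pd, r_nd, 0.0)
    pd = r_pd - shift
    nd = r_nd - shift
    if pd + nd == 0:
        raise ValueError("degenerate responses: PD + ND = 0 after offsetting")
    return (pd - nd) / (pd + nd)


def circuit_from_anatomy(
    subfield_centres: Mapping[CellType | str, Sequence[float]],
    signs: Mapping[CellType | str, str],
    tau: float = 0.150,
    dt: float = 0.001,
    gain: float = 1.0,
) -> DetectorConfig:
    """Build a BL detector from anatomical subfield centres and signs.

    The non-delayed excitatory channel sits at the mean centre of the
    excitatory ('+') subfields (Mi1/Tm3, dendrite shaft); the delayed
    inhibitory channel at the mean centre of the inhibitory ('-') subfields
    (Mi4/C3/CT1, dendrite base).  Predicted preferred direction: from the
    excitatory toward the inhibitory centre.
    """
    exc: list[np.ndarray] = []
    inh: list[np.ndarray] = []
    for key, centre in subfield_centres.items():
        t = CellType(key) if not isinstance(key, CellType) else key
        sign = signs.get(t) or signs.get(t.value)
        if sign is None:
            continue
        c = np.asarray(tuple(centre)[:2], dtype=float)
        if sign == "+":
            exc.append(c)
        elif sign == "-":
            inh.append(c)
    if not exc:
        raise ValueError("no excitatory subfield centre available")
    if not inh:
        raise ValueError("no inhibitory subfield centre available")
    e = np.mean(exc, axis=0)
    i = np.mean(inh, axis=0)
    return DetectorConfig(
        offset_1=CartPoint(float(i[0]), float(i[1])),
        offset_2=CartPoint(float(e[0]), float(e[1])),
        sign_1="-",
        sign_2="+",
        tau=tau,
        dt=dt,
        model="BL",
        gain=gain,
    )


def direction_tuning(
    config: DetectorConfig,
    directions: Iterable[float],
    speed: float = 1.0,
    kind: str = "moving_edge",
    contrast: float = 1.0,
) -> dict[float, float]:
    """Detector response per motion direction (radians).

    The edge start and duration are chosen so that the stimulus fully
    crosses both channels and the response settles, at every direction.
    """
    span = float(
        np.max(
            np.abs(
                [
                    config.offset_1[0],
                    config.offset_1[1],
                    config.offset_2[0],
                    config.offset_2[1],
                ]
            )
        )
    )
    lead = span + 1.0
    duration = (2.0 * lead) / speed + 6.0 * config.tau
    out = {}
    for theta in directions:
        spec = StimulusSpec(
            kind=kind,
            direction=float(theta),
            speed=speed,
            contrast=contrast,
            duration=duration,
            edge_start=-lead,
        )
        out[float(theta)] = detector_response(config, spec)
    return out
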