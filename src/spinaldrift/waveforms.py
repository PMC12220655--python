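"""Flow-rate waveforms and fluid parameters.

The oscillatory flow through the canal is prescribed by the cross-sectional
flow rate Q(t) over one period T (in the application, the cardiac-gated CSF
flow rate through the cervical canal).  The characteristic stroke volume

    V_s = (1/2) * integral over one period of |Q| dt

and the dimensionless stroke length ``eps = V_s / V_ref`` (with V_ref the
fluid volume of one canal segment) control the validity of the small-stroke
asymptotics for the mean Lagrangian velocity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError


@dataclass(frozen=True)
class FluidParams:
    """Newtonian fluid properties and oscillation period.

    density : kg/m^3, kinematic_viscosity : m^2/s, period : s.
    CSF defaults: rho ~ 1000 kg/m^3, nu ~ 0.7e-6 m^2/s, T = 1 s.
    """

    density: float = 1000.0
    kinematic_viscosity: float = 0.7e-6
    period: float = 1.0

    def __post_init__(self):
        if self.density <= 0 or self.kinematic_viscosity <= 0 or self.period <= 0:
            raise InputError("fluid parameters must be positive")

    @property
    def nu_cm2s(self) -> float:
        """Kinematic viscosity in the package's working units, cm^2/s."""
        return self.kinematic_viscosity * 1e4


@dataclass(frozen=True)
class FlowRateWaveform:
    """One period of a T-periodic flow-rate waveform.

    times : sample times t_k in [0, T), s, strictly increasing.
    flow_rate : Q(t_k), mL/s.  The waveform is treated as T-periodic; the
    cycle mean is reported but not forced to zero.
    """

    times: np.ndarray
    flow_rate: np.ndarray
    period: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        q = np.asarray(self.flow_rate, dtype=float)
        if t.size == 0:
            raise InputError("empty waveform")
        if t.size != q.size:
            raise InputError("times and flow_rate must have equal length")
        if self.period <= 0:
            raise InputError("period must be positive")
        if np.any(np.diff(t) <= 0):
            raise InputError("waveform times must be strictly increasing")
        if t[0] < 0 or t[-1] >= self.period:
            raise InputError("waveform times must lie in [0, T)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "flow_rate", q)

    @classmethod
    def sinusoid(
        cls, amplitude: float, period: float = 1.0, n_samples: int = 100,
        mean: float = 0.0,
    ) -> "FlowRateWaveform":
        """Single-harmonic waveform Q(t) = mean + amplitude*sin(2 pi t / T)."""
        t = np.arange(n_samples) * period / n_samples
        return cls(t, mean + amplitude * np.sin(2 * np.pi * t / period), period)

    def __call__(self, t) -> np.ndarray:
        """Periodic linear interpolation of Q at arbitrary times."""
        tm = np.mod(np.asarray(t, dtype=float), self.period)
        tp = np.concatenate([self.times, [self.times[0] + self.period]])
        qp = np.concatenate([self.flow_rate, [self.flow_rate[0]]])
        return np.interp(tm, tp, qp)

    def resample(self, n: int) -> "FlowRateWaveform":
        t = np.arange(n) * self.period / n
        return FlowRateWaveform(t, self(t), self.period)

    def scaled(self, factor: float) -> "FlowRateWaveform":
        return FlowRateWaveform(self.times, factor * self.flow_rate, self.period)

    @property
    def cycle_mean(self) -> float:
        """<Q> by trapezoidal quadrature with periodic closure, mL/s."""
        return _periodic_trapz(self.times, self.flow_rate, self.period) / self.period

    def harmonics(self, threshold: float = 1e-10):
        """Complex harmonic amplitudes (Q_hat_0 real mean, Q_hat_k for k>=1).

        Q(t) = Q_hat_0 + sum_k Re[Q_hat_k exp(i k omega t)].  The waveform is
        resampled to a uniform grid before the FFT.  Returns the list of
        (k, Q_hat_k) whose magnitude exceeds ``threshold`` x the largest.
        """
        n = max(self.times.size, 64)
        q = self.resample(n).flow_rate
        spec = np.fft.rfft(q) / n
        amps = [(0, float(spec[0].real))]
        mags = 2 * np.abs(spec[1:])
        if mags.size:
            top = max(mags.max(), abs(spec[0].real), 1e-300)
            for k in np.flatnonzero(mags > threshold * top):
                amps.append((int(k + 1), 2 * spec[k + 1]))
        return amps


def _periodic_trapz(t: np.ndarray, f: np.ndarray, period: float) -> float:
    """Trapezoidal integral of a T-periodic sampled function over one period."""
    tp = np.concatenate([t, [t[0] + period]])
    fp = np.concatenate([f, [f[0]]])
    return float(np.trapezoid(fp, tp))


def stroke_volume(waveform: FlowRateWaveform) -> float:
    """V_s = (1/2) * integral |Q| dt over one period, mL (trapezoid)."""
    return 0.5 * _periodic_trapz(
        waveform.times, np.abs(waveform.flow_rate), waveform.period
    )


def stroke_volume_and_epsilon(
    waveform: FlowRateWaveform, reference_volume: float
) -> tuple[float, float]:
    """Stroke volume V_s (mL) and dimensionless stroke length eps = V_s/V_ref.

    ``reference_volume`` is the fluid volume (mL) of one canal segment.
    """
    if reference_volume <= 0:
        raise InputError("reference volume must be positive")
    vs = stroke_volume(waveform)
    return vs, vs / reference_volume
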