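"""Parametric vascular input functions (VIF).

In patient data the plasma input is measured from the superior sagittal
sinus; the digital phantom replaces it with a smooth, causal, analytically
integrable bolus so that the Patlak forward model and its oracles have
closed forms. All shapes expose the plasma concentration ``cp(t)`` and its
running integral ``cumulative(t)`` from time zero (both vectorized, mmol/L
and mmol*s/L).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gamma as _gamma, gammainc

from .protocol import AcquisitionProtocol


def _check_nonneg(**params: float) -> None:
    for name, value in params.items():
        if not np.isfinite(value) or value < 0:
            raise ValueError(f"VIF parameter {name} must be finite and >= 0, got {value}")


class VIFShape:
    """Base class: causal plasma concentration curve with analytic integral."""

    def __call__(self, t):
        raise NotImplementedError

    def cumulative(self, t):
        """Running integral int_0^t Cp dtau (mmol*s/L)."""
        raise NotImplementedError


@dataclass(frozen=True)
class BoxcarVIF(VIFShape):
    """Constant plasma concentration c0 over [t_on, t_off], zero outside."""

    c0: float
    t_on: float
    t_off: float

    def __post_init__(self):
        _check_nonneg(c0=self.c0, t_on=self.t_on)
        if self.t_off <= self.t_on:
            raise ValueError("t_off must exceed t_on")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return np.where((t >= self.t_on) & (t <= self.t_off), self.c0, 0.0)

    def cumulative(self, t):
        t = np.asarray(t, dtype=float)
        return self.c0 * np.clip(t - self.t_on, 0.0, self.t_off - self.t_on)


@dataclass(frozen=True)
class BiexponentialVIF(VIFShape):
    """Cp(t) = a1 exp(-m1 (t-t0)) + a2 exp(-m2 (t-t0)) for t >= t0.

    The classical two-compartment washout description of the plasma curve
    after an instantaneous bolus at t0.
    """

    a1: float
    m1: float
    a2: float
    m2: float
    t0: float = 0.0

    def __post_init__(self):
        _check_nonneg(a1=self.a1, m1=self.m1, a2=self.a2, m2=self.m2, t0=self.t0)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        tau = np.maximum(t - self.t0, 0.0)
        val = self.a1 * np.exp(-self.m1 * tau) + self.a2 * np.exp(-self.m2 * tau)
        return np.where(t >= self.t0, val, 0.0)

    def cumulative(self, t):
        t = np.asarray(t, dtype=float)
        tau = np.maximum(t - self.t0, 0.0)

        def term(a, m):
            if m == 0:
                return a * tau
            return a / m * (1.0 - np.exp(-m * tau))

        return term(self.a1, self.m1) + term(self.a2, self.m2)


@dataclass(frozen=True)
class GammaVariateBolus(VIFShape):
    """First-pass bolus: Cp(t) = peak * (tau/ttp)^alpha * exp(alpha (1 - tau/ttp)).

    tau = t - t0; peaks at value ``peak`` at tau = ttp; shape parameter
    alpha controls the sharpness of the first pass.
    """

    peak: float
    ttp: float
    alpha: float
    t0: float = 0.0

    def __post_init__(self):
        _check_nonneg(peak=self.peak, t0=self.t0)
        if self.ttp <= 0 or self.alpha <= 0:
            raise ValueError("ttp and alpha must be positive")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        tau = np.maximum(t - self.t0, 0.0)
        x = tau / self.ttp
        with np.errstate(divide="ignore", invalid="ignore"):
            val = self.peak * np.power(x, self.alpha) * np.exp(self.alpha * (1.0 - x))
        return np.where(tau > 0, val, 0.0)

    def cumulative(self, t):
        # int_0^tau s^a exp(-a s/ttp) ds = beta^(a+1) * gamma_lower(a+1, tau/beta)
        # with beta = ttp/alpha; normalization restores the peak scaling.
        t = np.asarray(t, dtype=float)
        tau = np.maximum(t - self.t0, 0.0)
        a = self.alpha
        beta = self.ttp / a
        scale = self.peak * np.exp(a) / self.ttp ** a
        lower = _gamma(a + 1.0) * gammainc(a + 1.0, tau / beta)
        return scale * beta ** (a + 1.0) * lower


@dataclass(frozen=True)
class WashoutTerm(VIFShape):
    """Recirculation/washout: a * (exp(-m_decay tau) - exp(-m_rise tau)).

    Rises with rate m_rise (> m_decay) and decays slowly with m_decay,
    modelling the mixed plasma phase that sustains late-time leakage.
    """

    amplitude: float
    m_decay: float
    m_rise: float
    t0: float = 0.0

    def __post_init__(self):
        _check_nonneg(amplitude=self.amplitude, m_decay=self.m_decay,
                      m_rise=self.m_rise, t0=self.t0)
        if self.m_rise <= self.m_decay:
            raise ValueError("m_rise must exceed m_decay")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        tau = np.maximum(t - self.t0, 0.0)
        val = self.amplitude * (np.exp(-self.m_decay * tau) - np.exp(-self.m_rise * tau))
        return np.where(tau > 0, val, 0.0)

    def cumulative(self, t):
        t = np.asarray(t, dtype=float)
        tau = np.maximum(t - self.t0, 0.0)

        def cum(m):
            if m == 0:
                return tau
            return (1.0 - np.exp(-m * tau)) / m

        return self.amplitude * (cum(self.m_decay) - cum(self.m_rise))


class CompositeVIF(VIFShape):
    """Sum of component shapes (linearity of concentration and integral)."""

    def __init__(self, *components: VIFShape):
        self.components = components

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return sum(c(t) for c in self.components)

    def cumulative(self, t):
        t = np.asarray(t, dtype=float)
        return sum(c.cumulative(t) for c in self.components)


def population_vif(onset: float = 10.0, peak: float = 8.0, ttp: float = 10.0,
                   alpha: float = 3.0, washout_amplitude: float = 1.0,
                   washout_decay: float = 1.0 / 600.0,
                   washout_rise: float = 1.0 / 15.0) -> CompositeVIF:
    """Default plasma input: gamma-variate first pass + slow washout plateau.

    Defaults give a ~8 mmol/L plasma peak ~10 s after bolus arrival and a
    ~1 mmol/L plateau decaying with a 10 min time constant — the magnitudes
    expected for a standard 0.1 mmol/kg gadobutrol bolus at 3 ml/s.
    """
    _check_nonneg(onset=onset)
    return CompositeVIF(
        GammaVariateBolus(peak=peak, ttp=ttp, alpha=alpha, t0=onset),
        WashoutTerm(amplitude=washout_amplitude, m_decay=washout_decay,
                    m_rise=washout_rise, t0=onset),
    )


_SHAPES = {
    "population": population_vif,
    "boxcar": BoxcarVIF,
    "biexponential": BiexponentialVIF,
    "gamma": GammaVariateBolus,
}


def generate_vif(protocol: AcquisitionProtocol, shape: str = "population",
                 **params) -> VIFShape:
    """Build a parametric plasma input curve.

    Parameters
    ----------
    protocol : AcquisitionProtocol
        Validated acquisition protocol (reserved for dose-dependent scaling).
    shape : str
        One of 'population', 'boxcar', 'biexponential', 'gamma'.
    **params
        Shape parameters; all must be finite and non-negative where the
        shape requires it.
    """
    if shape not in _SHAPES:
        raise ValueError(f"unknown VIF shape {shape!r}; choose from {sorted(_SHAPES)}")
    return _SHAPES[shape](**params)
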