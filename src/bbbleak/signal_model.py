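"""Spoiled gradient-echo (SPGR) steady-state signal model.

Links gadolinium concentration to measured signal through the longitudinal
relaxation rate R1(t) = 1/T10 + r1 * C(t). Used forward by the phantom to
synthesize dynamic signal, and inverted by the quantification stage to
recover concentration from relative enhancement plus the pre-contrast T1 map.
"""

from __future__ import annotations

import numpy as np

from .protocol import AcquisitionProtocol


def spgr_signal(concentration, t10, protocol: AcquisitionProtocol,
                s0_scale: float = 100.0):
    """SPGR steady-state signal for a given contrast concentration.

    S = s0_scale * sin(a) * (1 - E1) / (1 - cos(a) * E1),
    E1 = exp(-TR * R1),  R1 = 1/T10 + r1 * C.

    Monotonically increasing in C for flip angles in (0, 90] and TR > 0.
    T2* decay at the (short) TE is absorbed into ``s0_scale``: it is
    concentration-independent to first order and cancels in the relative
    enhancement used downstream.

    Parameters
    ----------
    concentration : array_like
        Gadolinium concentration (mmol/L), >= 0.
    t10 : array_like
        Pre-contrast longitudinal relaxation time (s), > 0.
    """
    c = np.asarray(concentration, dtype=float)
    t10 = np.asarray(t10, dtype=float)
    if np.any(t10 <= 0):
        raise ValueError("t10 must be positive")
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    a = np.deg2rad(protocol.flip_angle)
    r1 = 1.0 / t10 + protocol.r1_relaxivity * c
    e1 = np.exp(-protocol.tr * r1)
    return s0_scale * np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1)


def concentration_from_spgr(signal, s0, t10, protocol: AcquisitionProtocol,
                            c_max: float = 50.0):
    """Invert the SPGR equation to concentration, given baseline S0 and T10.

    The equilibrium magnetization term is eliminated using the measured
    pre-contrast signal S0 together with the known T10, so no absolute scale
    is needed. Signals beyond the invertible range of the model (at or
    above the saturation ceiling, or implying C > ``c_max``) are clamped to
    the physical ceiling ``c_max`` (mmol/L, default well above any
    physiologic blood peak) and counted, so one noisy saturated sample
    cannot dominate spatial averages downstream.

    Returns
    -------
    concentration : ndarray (mmol/L)
    n_clamped : int
        Number of samples clamped to keep the inversion defined.
    """
    s = np.asarray(signal, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    t10 = np.asarray(t10, dtype=float)
    if np.any(t10 <= 0):
        raise ValueError("t10 must be positive")
    a = np.deg2rad(protocol.flip_angle)
    cos_a = np.cos(a)
    e10 = np.exp(-protocol.tr / t10)
    # amplitude term A = s0_scale*sin(a)*M0, recovered from baseline
    amp = s0 * (1.0 - cos_a * e10) / (1.0 - e10)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (amp - s) / (amp - cos_a * s)
    # E1 bounds corresponding to C in [-1/(r1*T10) (R1=0), c_max]
    e1_min = np.exp(-protocol.tr * (1.0 / t10 + protocol.r1_relaxivity * c_max))
    upper = 1.0 - 1e-12
    out_of_range = ~np.isfinite(e1) | (e1 < e1_min) | (e1 > upper)
    n_clamped = int(np.sum(out_of_range))
    e1 = np.clip(np.where(np.isfinite(e1), e1, e1_min), e1_min, upper)
    r1 = -np.log(e1) / protocol.tr
    conc = (r1 - 1.0 / t10) / protocol.r1_relaxivity
    return conc, n_clamped


def linearized_concentration(signal, s0, t10, protocol: AcquisitionProtocol):
    """First-order fallback: C ~ RE / (r1 * T10_eff).

    Valid for small relative enhancement RE = (S - S0)/S0; offered for
    degenerate protocols where the full inversion is ill-conditioned.
    The effective T10 factor comes from the derivative of the SPGR signal
    with respect to R1 at baseline.
    """
    s = np.asarray(signal, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    t10 = np.asarray(t10, dtype=float)
    a = np.deg2rad(protocol.flip_angle)
    cos_a = np.cos(a)
    e10 = np.exp(-protocol.tr / t10)
    re = (s - s0) / s0
    # dS/dR1 / S at baseline -> RE = k * dR1, with
    # k = TR * E10 * (1 - cos a) / ((1 - E10)(1 - cos a * E10))
    k = protocol.tr * e10 * (1.0 - cos_a) / ((1.0 - e10) * (1.0 - cos_a * e10))
    return re / (k * protocol.r1_relaxivity)
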