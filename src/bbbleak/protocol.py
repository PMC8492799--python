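"""Acquisition protocol for dual-time-resolution DCE-MRI.

The protocol interleaves two spoiled gradient-echo dynamic sequences: a fast
one (short dynamic scan time, DST) that samples the bolus first pass, and a
slow one that follows the subtle leakage phase for ~20 minutes. Both share
TR/TE/flip angle; only the volume time and count differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing and signal parameters of the dual dynamic acquisition.

    Parameters
    ----------
    fast_dst, slow_dst : float
        Dynamic scan time (seconds per volume) of the fast and slow sequence.
    fast_volumes, slow_volumes : int
        Number of dynamic volumes per sequence.
    tr, te : float
        Repetition / echo time of the spoiled gradient-echo readout (s).
    flip_angle : float
        Excitation flip angle (degrees).
    r1_relaxivity : float
        Longitudinal relaxivity of the contrast agent (L mmol^-1 s^-1).
        Default 5.0, typical for gadobutrol at 3 T.
    dose : float
        Contrast dose (mmol per kg body weight).
    hematocrit : float
        Large-vessel hematocrit used to convert whole-blood to plasma
        concentration, Cp = Cb / (1 - Hct).
    """

    fast_dst: float = 3.2
    fast_volumes: int = 29
    slow_dst: float = 30.5
    slow_volumes: int = 45
    tr: float = 5.6e-3
    te: float = 2.5e-3
    flip_angle: float = 10.0
    r1_relaxivity: float = 5.0
    dose: float = 0.1
    hematocrit: float = 0.45

    def __post_init__(self) -> None:
        for name in ("fast_dst", "slow_dst", "tr", "te", "flip_angle",
                     "r1_relaxivity", "dose"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("fast_volumes", "slow_volumes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if not 0.0 < self.hematocrit < 1.0:
            raise ValueError("hematocrit must lie in (0, 1)")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AcquisitionProtocol":
        return cls(**d)
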