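"""Signal-to-Ki quantification chain.

Converts dual-resolution dynamic signal to gadolinium concentration via the
pre-contrast T1 map, merges the fast and slow sequences onto one time line,
extracts the vascular input function from the sagittal-sinus blood pool,
and fits the Patlak graphical model voxel-wise:

    Ct(t)/Cp(t) = Ki * [int_0^t Cp dtau / Cp(t)] + vp

The slope of this line is the leakage rate Ki (converted to min^-1); the
intercept is the plasma volume fraction vp. Negative fitted slopes are
retained deliberately — the downstream histogram noise correction depends
on the sign-symmetric noise distribution around Ki = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .protocol import AcquisitionProtocol
from .signal_model import concentration_from_spgr, linearized_concentration


@dataclass
class DynamicSeries:
    """A 4D dynamic acquisition with per-volume midpoint times (s)."""

    data: np.ndarray
    times: np.ndarray
    sequence_tag: str
    baseline_count: int = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, t)")
        if len(self.times) != self.data.shape[-1]:
            raise ValueError("times length must match the number of volumes")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.baseline_count < 1:
            raise ValueError("baseline_count must be >= 1")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]


@dataclass
class ConcentrationSeries:
    """4D gadolinium concentration (mmol/L) on a time grid (s)."""

    conc: np.ndarray
    times: np.ndarray
    sequence_tag: str = ""
    baseline_count: int = 0
    source: np.ndarray | None = None  # per-volume provenance tags after merge

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.conc.ndim != 4 or len(self.times) != self.conc.shape[-1]:
            raise ValueError("conc must be 4-D with one time per volume")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class VascularInputFunction:
    """Plasma input on the merged grid with its running integral."""

    times: np.ndarray         # s
    cb: np.ndarray            # whole-blood concentration (mmol/L)
    cp: np.ndarray            # plasma concentration = cb / (1 - Hct)
    hematocrit: float
    integral: np.ndarray      # running int Cp dtau (mmol*s/L), trapezoid


@dataclass
class KiMap:
    """Voxel-wise Patlak fit results."""

    ki: np.ndarray            # slope, min^-1 (sign-preserving)
    vp: np.ndarray            # intercept, plasma fraction
    r2: np.ndarray            # coefficient of determination
    n_points: np.ndarray      # points entering each fit
    valid: np.ndarray         # voxels with a usable fit


def concentration_from_signal(series: DynamicSeries, t1_map: np.ndarray,
                              protocol: AcquisitionProtocol,
                              mask: np.ndarray | None = None,
                              method: str = "spgr") -> tuple[ConcentrationSeries, dict]:
    """Convert dynamic signal to concentration using relative enhancement.

    Per voxel the pre-contrast baseline S0 is the mean of the first
    ``baseline_count`` volumes; the SPGR signal equation is inverted with
    the voxel's T10 to give R1(t) and C(t) = (R1(t) - 1/T10) / r1. Voxels
    with S0 <= 0 are flagged invalid; non-invertible samples (enhancement
    outside the model range) are clamped and counted in the QC report.

    Parameters
    ----------
    method : 'spgr' (full inversion, default) or 'linear' (first-order
        fallback C ~ RE / (k * r1) for degenerate protocols).
    """
    t1_map = np.asarray(t1_map, dtype=float)
    if t1_map.shape != series.data.shape[:3]:
        raise ValueError("t1_map and series must share the spatial grid")
    if mask is None:
        mask = np.ones(t1_map.shape, dtype=bool)
    if np.any(t1_map[mask] <= 0):
        raise ValueError("t10 must be positive on in-mask voxels")

    s0 = series.data[..., :series.baseline_count].mean(axis=-1)
    invalid_s0 = mask & (s0 <= 0)
    ok = mask & ~invalid_s0

    conc = np.zeros_like(series.data)
    n_clamped = 0
    if np.any(ok):
        sig = series.data[ok, :]
        s0_ok = s0[ok, None]
        t10_ok = t1_map[ok, None]
        if method == "spgr":
            c, n_clamped = concentration_from_spgr(sig, s0_ok, t10_ok, protocol)
        elif method == "linear":
            c = linearized_concentration(sig, s0_ok, t10_ok, protocol)
        else:
            raise ValueError("method must be 'spgr' or 'linear'")
        conc[ok, :] = c

    qc = {
        "n_invalid_s0": int(invalid_s0.sum()),
        "n_clamped_samples": int(n_clamped),
        "invalid_mask": invalid_s0,
        "method": method,
    }
    out = ConcentrationSeries(conc=conc, times=series.times,
                              sequence_tag=series.sequence_tag,
                              baseline_count=series.baseline_count)
    return out, qc


def merge_dual_sequences(fast, slow, drop_baselines: bool = True):
    """Merge the fast and slow sequences onto one chronological time line.

    Each sequence's pre-contrast baseline volumes are dropped by default
    (they serve only to define S0). The remaining fast volumes must all
    precede the remaining slow volumes; overlap is an error listing the
    offending volumes. Per-volume provenance tags are retained. Passing a
    single series (other one None) returns it trimmed/sorted.
    """

    def arrays(series):
        if series is None:
            return None
        data = series.conc if isinstance(series, ConcentrationSeries) else series.data
        nb = series.baseline_count if drop_baselines else 0
        dyn_times = series.times[series.baseline_count:]
        return data[..., nb:], series.times[nb:], series.sequence_tag, dyn_times

    parts = [p for p in (arrays(fast), arrays(slow)) if p is not None and p[0].shape[-1] > 0]
    if not parts:
        raise ValueError("nothing to merge")
    if len(parts) == 2:
        # pre-contrast baselines may sort anywhere; the dynamic (post-
        # baseline) fast volumes must all precede the dynamic slow ones
        ft_dyn, st_dyn = parts[0][3], parts[1][3]
        if len(ft_dyn) and len(st_dyn):
            overlap = st_dyn <= ft_dyn.max()
            if np.any(overlap):
                raise ValueError(
                    f"fast and slow time ranges overlap: slow volumes at t="
                    f"{st_dyn[overlap].tolist()} s precede the last fast "
                    f"volume at t={ft_dyn.max():.3f} s")
    data = np.concatenate([p[0] for p in parts], axis=-1)
    times = np.concatenate([p[1] for p in parts])
    source = np.concatenate([np.full(p[0].shape[-1], p[2]) for p in parts])
    order = np.argsort(times, kind="stable")
    times = times[order]
    if np.any(np.diff(times) == 0):
        raise ValueError("duplicate timestamps after merge")
    merged = ConcentrationSeries(conc=data[..., order], times=times,
                                 sequence_tag="merged", baseline_count=0,
                                 source=source[order])
    return merged


def extract_vif(merged: ConcentrationSeries, sinus_mask: np.ndarray,
                hematocrit: float) -> VascularInputFunction:
    """Extract the plasma input from the sagittal-sinus blood pool.

    Whole-blood concentration is the spatial mean over sinus voxels at each
    time; plasma concentration applies the hematocrit correction
    Cp = Cb / (1 - Hct); the running integral uses the trapezoid rule with
    integral 0 at the first sample.
    """
    sinus_mask = np.asarray(sinus_mask, dtype=bool)
    if not np.any(sinus_mask):
        raise ValueError("sinus mask is empty")
    if not 0.0 <= hematocrit < 1.0:
        raise ValueError("hematocrit must lie in [0, 1)")
    if np.any(np.diff(merged.times) <= 0):
        raise ValueError("merged times must be strictly increasing")
    cb = merged.conc[sinus_mask, :].mean(axis=0)
    cp = cb / (1.0 - hematocrit)
    integral = cumulative_trapezoid(cp, merged.times, initial=0.0)
    return VascularInputFunction(times=merged.times.copy(), cb=cb, cp=cp,
                                 hematocrit=hematocrit, integral=integral)


def patlak_fit(conc: ConcentrationSeries, vif: VascularInputFunction,
               tissue_mask: np.ndarray | None = None,
               fit_window: tuple[float, float] | None = None,
               cp_floor: float = 1e-3) -> KiMap:
    """Voxel-wise Patlak graphical fit.

    Ordinary least squares of y = Ct/Cp against x = int Cp / Cp over the
    fit window. The default window starts at the first slow-sequence volume
    (after the bolus first pass, where the Patlak linearity assumption
    holds) and runs to the last volume. Time points with Cp below
    ``cp_floor`` (mmol/L) are excluded to avoid division blow-up; voxels
    with fewer than 3 usable points are marked invalid.
    """
    if not np.array_equal(conc.times, vif.times):
        raise ValueError("concentration series and VIF must share the time grid")
    if tissue_mask is None:
        tissue_mask = np.ones(conc.conc.shape[:3], dtype=bool)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)

    if fit_window is None:
        if conc.source is not None and np.any(conc.source == "slow"):
            t_start = conc.times[conc.source == "slow"].min()
        else:
            t_start = conc.times[0]
        fit_window = (t_start, conc.times[-1])

    in_window = (conc.times >= fit_window[0]) & (conc.times <= fit_window[1])
    usable = in_window & (vif.cp > cp_floor)
    if usable.sum() < 3:
        raise ValueError(
            f"fewer than 3 usable time points in fit window {fit_window} "
            f"with Cp > {cp_floor}")

    cp = vif.cp[usable]
    x = vif.integral[usable] / cp                       # s
    ct = conc.conc[tissue_mask][:, usable]
    y = ct / cp                                          # dimensionless

    # closed-form OLS, shared design across voxels
    n = len(x)
    x_mean = x.mean()
    y_mean = y.mean(axis=1)
    dx = x - x_mean
    sxx = np.dot(dx, dx)
    sxy = y @ dx
    slope = sxy / sxx                                    # s^-1
    intercept = y_mean - slope * x_mean
    resid = y - (slope[:, None] * x[None, :] + intercept[:, None])
    ss_res = np.einsum("ij,ij->i", resid, resid)
    ss_tot = np.einsum("ij,ij->i", y - y_mean[:, None], y - y_mean[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)

    shape = conc.conc.shape[:3]
    ki = np.full(shape, np.nan)
    vp = np.full(shape, np.nan)
    r2_map = np.full(shape, np.nan)
    n_points = np.zeros(shape, dtype=int)
    valid = np.zeros(shape, dtype=bool)
    ki[tissue_mask] = slope * 60.0                        # -> min^-1
    vp[tissue_mask] = intercept
    r2_map[tissue_mask] = r2
    n_points[tissue_mask] = n
    finite = np.isfinite(ki) & np.isfinite(vp)
    valid[tissue_mask] = finite[tissue_mask]
    return KiMap(ki=ki, vp=vp, r2=r2_map, n_points=n_points, valid=valid)
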