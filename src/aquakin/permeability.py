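"""Water-permeability kinetics: stopped-flow shrinkage, calcein quench,
membrane accumulation.

Liposome shrinkage under a hyperosmotic step is fitted with a
double-exponential approach to plateau; the larger rate constant reflects
protein-containing liposomes and is converted to the osmotic water
permeability

    Pf (cm/s) = k / ((S/V0) * Vw * C_out)

with S/V0 the initial surface-to-volume ratio (3/r for a sphere), Vw the
partial molar volume of water (18 cm^3/mol) and C_out the external
osmolality (mol/cm^3). Dividing the protein-specific Pf by the channel
density per unit membrane area (SuD, derived from the lipid-to-protein
ratio and the area per lipid) yields the single-channel permeability
Pu = Pf / SuD in cm^3/s.

Cell water permeability is read out by calcein self-quenching: intracellular
fluorescence decays single-exponentially as the cell shrinks under an
osmotic challenge and the rate constant is proportional to membrane water
permeability. Membrane accumulation time courses are fitted with
1 - exp(-k t), giving t1/2 = ln(2)/k.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "StopFlowTrace",
    "DoubleExpFit",
    "LiposomeGeometry",
    "PermeabilityResult",
    "QuenchTrace",
    "QuenchFit",
    "VolumeCalibration",
    "AccumulationFit",
    "fit_double_exponential",
    "osmotic_permeability",
    "channel_density",
    "single_channel_permeability",
    "fit_quench",
    "to_volume",
    "accumulation_halftime",
    "injection_concentration",
]

V_W = 18.0  # cm^3 mol^-1, partial molar volume of water


@dataclasses.dataclass
class StopFlowTrace:
    """Stopped-flow shrinkage fluorescence trace (rising on shrinkage)."""

    time: np.ndarray
    fluorescence: np.ndarray
    osmotic_step: float = 0.1  # Osm
    temperature: float = 18.0  # °C, recorded only; no correction applied

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclasses.dataclass
class DoubleExpFit:
    """Two-exponential decomposition; ``k_selected`` is the faster rate.

    The slower component tracks residual (protein-free) liposomes and is
    insensitive to reconstitution efficiency, so the faster rate is the
    one carried forward to Pf.
    """

    k_fast: float
    k_slow: float
    a_fast: float
    a_slow: float
    baseline: float
    k_selected: float
    residual_norm: float = np.nan
    converged: bool = True
    single_exponential: bool = False


@dataclasses.dataclass
class LiposomeGeometry:
    """Geometry and composition constants for Pf and SuD.

    Defaults describe 100-nm-extruded spherical liposomes (radius 50 nm),
    a 0.1 Osm external osmotic step, a theoretical area per lipid of
    0.47 nm^2 and a lipid-to-protein ratio (LPR) of 200. ``lpr_basis``
    selects whether the LPR counts molecules ("molar") or grams ("mass");
    ``oligomer`` is the number of protein subunits per channel particle
    (1 = per-monomer permeability).
    """

    radius: float = 50e-7  # cm
    s_over_v0: float | None = None  # cm^-1; default 3/radius (sphere)
    v_w: float = V_W
    c_out: float = 1e-4  # mol cm^-3 (= 0.1 Osm)
    area_per_lipid: float = 0.47  # nm^2
    lpr: float = 200.0
    lpr_basis: str = "mass"
    leaflets: int = 2
    oligomer: int = 1

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.s_over_v0 is None:
            self.s_over_v0 = 3.0 / self.radius
        if self.s_over_v0 <= 0 or self.v_w <= 0 or self.c_out <= 0:
            raise ValueError("s_over_v0, v_w and c_out must all be positive")
        if self.lpr_basis not in ("mass", "molar"):
            raise ValueError("lpr_basis must be 'mass' or 'molar'")
        if self.lpr <= 0 or self.area_per_lipid <= 0:
            raise ValueError("lpr and area_per_lipid must be positive")
        if self.leaflets not in (1, 2):
            raise ValueError("leaflets must be 1 or 2")


@dataclasses.dataclass
class PermeabilityResult:
    pf: float  # cm s^-1
    pf_control: float | None = None
    su_d: float | None = None  # channels cm^-2
    pu: float | None = None  # cm^3 s^-1
    flags: list[str] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class QuenchTrace:
    """Calcein fluorescence under hyperosmotic challenge (falls on shrinkage)."""

    time: np.ndarray
    fluorescence: np.ndarray
    osmotic_gradient: float = 200.0  # mOsm

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclasses.dataclass
class QuenchFit:
    k: float  # s^-1
    f0: float
    f_inf: float
    injection_time: float
    residual_norm: float = np.nan
    decay_detected: bool = True


@dataclasses.dataclass
class VolumeCalibration:
    """Monotone map from normalized fluorescence to normalized volume.

    Built from a cell-sizer (Coulter-counter style) standard curve;
    ``method="piecewise"`` interpolates linearly between calibration
    points, ``method="linear"`` fits one straight line through them.
    The map must pass through (1, 1): unchanged fluorescence means
    unchanged volume.
    """

    fluorescence: np.ndarray
    volume: np.ndarray
    method: str = "piecewise"

    def __post_init__(self) -> None:
        f = np.asarray(self.fluorescence, dtype=float)
        v = np.asarray(self.volume, dtype=float)
        order = np.argsort(f)
        f, v = f[order], v[order]
        if len(f) < 2:
            raise ValueError("calibration needs at least 2 points")
        if np.any(np.diff(f) <= 0) or np.any(np.diff(v) <= 0):
            raise ValueError("calibration mapping must be strictly monotone")
        self.fluorescence, self.volume = f, v
        if self.method not in ("linear", "piecewise"):
            raise ValueError("method must be 'linear' or 'piecewise'")
        if self.method == "linear":
            self._slope, self._intercept = np.polyfit(f, v, 1)
        if abs(float(self(1.0)) - 1.0) > 1e-6:
            raise ValueError("calibration must map fluorescence 1.0 to volume 1.0")

    def __call__(self, f):
        f = np.asarray(f, dtype=float)
        if self.method == "linear":
            out = self._slope * f + self._intercept
        else:
            out = np.interp(f, self.fluorescence, self.volume)
        return out if out.ndim else float(out)

    def in_range(self, f) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        return (f >= self.fluorescence[0]) & (f <= self.fluorescence[-1])


@dataclasses.dataclass
class AccumulationFit:
    k: float
    t_half: float
    residual_norm: float = np.nan
    converged: bool = True


# ---------------------------------------------------------------------------
# stopped-flow double exponential


def _dexp_model(t, baseline, a_fast, k_fast, a_slow, k_slow):
    return (
        baseline
        + a_fast * (1.0 - np.exp(-k_fast * t))
        + a_slow * (1.0 - np.exp(-k_slow * t))
    )


def fit_double_exponential(
    trace: StopFlowTrace,
    min_rate_ratio: float = 1.5,
    min_amp_frac: float = 0.01,
) -> DoubleExpFit:
    """Fit baseline + a_f(1-e^-k_f t) + a_s(1-e^-k_s t) to a shrinkage trace.

    Components are ordered so k_fast >= k_slow and the fast rate is selected.
    If the two rates collapse (ratio < ``min_rate_ratio``) or one amplitude
    is below ``min_amp_frac`` of the total, the trace is refitted with a
    single exponential and flagged. Works for rising or falling traces
    (signed amplitudes).
    """
    t = trace.time - trace.time[0]
    y = trace.fluorescence
    if len(t) < 20:
        raise ValueError("need at least 20 samples for a double-exponential fit")

    span = float(y[-1] - y[0])
    # non-plateauing guard: final quarter still drifts as much as mid-trace
    q = len(y) // 4
    late_drift = abs(float(np.mean(y[-q // 2 or 1:]) - np.mean(y[-q: -q // 2 or None])))
    plateaued = late_drift < 0.25 * abs(span) if span != 0 else True

    T = t[-1] if t[-1] > 0 else 1.0
    b0 = float(y[0])

    def resid(theta):
        b, af, lkf, as_, lks = theta
        return _dexp_model(t, b, af, np.exp(lkf), as_, np.exp(lks)) - y

    best = None
    for kf0, ks0 in ((20 / T, 2 / T), (60 / T, 5 / T), (5 / T, 0.5 / T)):
        res = optimize.least_squares(
            resid,
            x0=[b0, 0.7 * span, np.log(kf0), 0.3 * span, np.log(ks0)],
            method="trf", xtol=1e-12, ftol=1e-12,
        )
        if best is None or res.cost < best.cost:
            best = res

    b, af, lkf, as_, lks = best.x
    kf, ks = np.exp(lkf), np.exp(lks)
    if kf < ks:  # order components
        kf, ks, af, as_ = ks, kf, as_, af

    total_amp = abs(af) + abs(as_)
    degenerate = (
        total_amp == 0
        or kf / max(ks, 1e-300) < min_rate_ratio
        or abs(af) < min_amp_frac * total_amp
        or abs(as_) < min_amp_frac * total_amp
    )

    if degenerate:
        single = _fit_single_exponential(t, y, b0, span, T)
        b1, a1, k1, rn = single
        return DoubleExpFit(
            k_fast=k1, k_slow=0.0, a_fast=a1, a_slow=0.0, baseline=b1,
            k_selected=k1, residual_norm=rn,
            converged=bool(best.success) and plateaued, single_exponential=True,
        )

    rn = float(np.sqrt(np.sum(resid(best.x) ** 2)))
    return DoubleExpFit(
        k_fast=float(kf), k_slow=float(ks), a_fast=float(af), a_slow=float(as_),
        baseline=float(b), k_selected=float(kf), residual_norm=rn,
        converged=bool(best.success) and plateaued, single_exponential=False,
    )


def _fit_single_exponential(t, y, b0, span, T):
    def resid(theta):
        b, a, lk = theta
        return b + a * (1.0 - np.exp(-np.exp(lk) * t)) - y

    best = None
    for k0 in (2 / T, 10 / T, 50 / T):
        res = optimize.least_squares(resid, x0=[b0, span, np.log(k0)],
                                     xtol=1e-12, ftol=1e-12)
        if best is None or res.cost < best.cost:
            best = res
    b, a, lk = best.x
    rn = float(np.sqrt(np.sum(resid(best.x) ** 2)))
    return float(b), float(a), float(np.exp(lk)), rn


# ---------------------------------------------------------------------------
# permeability conversions


def osmotic_permeability(k: float, geom: LiposomeGeometry | None = None) -> float:
    """Pf (cm/s) = k / ((S/V0) * Vw * C_out); exactly linear in k."""
    if geom is None:
        geom = LiposomeGeometry()
    if k < 0:
        raise ValueError("rate constant must be non-negative")
    return k / (geom.s_over_v0 * geom.v_w * geom.c_out)


def channel_density(
    geom: LiposomeGeometry | None = None,
    protein_mw: float | None = None,
    lipid_mw: float | None = None,
) -> float:
    """Channels per cm^2 of membrane from the LPR and area per lipid.

    Molar basis: lipids per channel = LPR * oligomer. Mass basis: LPR grams
    of lipid per gram of protein, so lipids per channel =
    LPR * (protein_mw * oligomer / lipid_mw). The membrane area occupied by
    those lipids is split over ``leaflets``; SuD is its reciprocal.
    """
    if geom is None:
        geom = LiposomeGeometry()
    if geom.lpr_basis == "mass":
        if protein_mw is None or lipid_mw is None:
            raise ValueError(
                "mass-basis LPR requires protein_mw and lipid_mw (g/mol)"
            )
        lipids_per_channel = geom.lpr * (protein_mw * geom.oligomer / lipid_mw)
    else:
        lipids_per_channel = geom.lpr * geom.oligomer
    area_nm2 = lipids_per_channel * geom.area_per_lipid / geom.leaflets
    area_cm2 = area_nm2 * 1e-14
    return 1.0 / area_cm2


def single_channel_permeability(
    pf: float,
    su_d: float,
    pf_control: float | None = None,
    subtract_background: bool = True,
) -> PermeabilityResult:
    """Pu = (Pf - Pf_control) / SuD (cm^3/s); background subtraction default.

    Control (protein-free) liposomes still pass water through the bare
    bilayer; subtracting their Pf isolates the channel-mediated flux. A
    control exceeding the sample is clamped to Pu = 0 with a warning flag.
    """
    if su_d <= 0:
        raise ValueError("su_d must be positive")
    flags: list[str] = []
    eff = pf
    if subtract_background and pf_control is not None:
        eff = pf - pf_control
        if eff < 0:
            flags.append("pf_control_exceeds_pf:pu_clamped_to_zero")
            eff = 0.0
    return PermeabilityResult(
        pf=pf, pf_control=pf_control, su_d=su_d, pu=eff / su_d, flags=flags
    )


def injection_concentration(
    stock: float, injected_volume: float, initial_volume: float
) -> float:
    """Final concentration after injecting ``injected_volume`` of ``stock``
    into ``initial_volume`` of solute-free medium (same volume units)."""
    if injected_volume <= 0 or initial_volume < 0:
        raise ValueError("volumes must be positive")
    return stock * injected_volume / (injected_volume + initial_volume)


# ---------------------------------------------------------------------------
# calcein quench


def fit_quench(
    trace: QuenchTrace,
    injection_time: float | None = 5.0,
    post_injection_only: bool = True,
    alpha: float = 0.05,
) -> QuenchFit:
    """Fit F(t) = F_inf + (F0 - F_inf) e^{-k t'} on the post-injection segment.

    ``injection_time=None`` detects the injection as the point of maximum
    absolute derivative. A trace with no resolvable decay (the exponential
    does not beat a constant model) is returned with k = 0 and
    ``decay_detected=False``.
    """
    t, y = trace.time, trace.fluorescence
    if injection_time is None:
        dy = np.abs(np.diff(y) / np.diff(t))
        injection_time = float(t[int(np.argmax(dy))])
    if post_injection_only:
        m = t >= injection_time
        ts, ys = t[m], y[m]
    else:
        ts, ys = t, y
    if len(ts) < 4:
        raise ValueError("fewer than 4 samples after the injection time")
    ts = ts - ts[0]
    T = ts[-1] if ts[-1] > 0 else 1.0

    def resid(theta):
        f_inf, f0, lk = theta
        return f_inf + (f0 - f_inf) * np.exp(-np.exp(lk) * ts) - ys

    best = None
    for k0 in (0.5 / T, 2 / T, 10 / T):
        res = optimize.least_squares(
            resid, x0=[float(ys[-1]), float(ys[0]), np.log(k0)],
            xtol=1e-12, ftol=1e-12,
        )
        if best is None or res.cost < best.cost:
            best = res
    f_inf, f0, lk = best.x
    k = float(np.exp(lk))
    ss_fit = float(np.sum(resid(best.x) ** 2))
    ss_const = float(np.sum((ys - np.mean(ys)) ** 2))

    from aquakin.binding import _beats_constant

    detected = _beats_constant(ss_const, ss_fit, len(ys), 3, alpha) and abs(
        f0 - f_inf
    ) > 1e-12
    if not detected:
        return QuenchFit(k=0.0, f0=float(np.mean(ys)), f_inf=float(np.mean(ys)),
                         injection_time=float(injection_time),
                         residual_norm=np.sqrt(ss_const), decay_detected=False)
    return QuenchFit(k=k, f0=float(f0), f_inf=float(f_inf),
                     injection_time=float(injection_time),
                     residual_norm=np.sqrt(ss_fit), decay_detected=True)


def to_volume(
    fluorescence: Sequence[float] | np.ndarray,
    cal: VolumeCalibration,
) -> tuple[np.ndarray, list[str]]:
    """Map a normalized fluorescence series to normalized volumes.

    Values outside the calibrated fluorescence range are still mapped (the
    piecewise map clamps, the linear map extrapolates) but flagged.
    """
    f = np.asarray(fluorescence, dtype=float)
    flags: list[str] = []
    if not np.all(cal.in_range(f)):
        flags.append("extrapolation_outside_calibrated_range")
    return cal(f), flags


# ---------------------------------------------------------------------------
# membrane accumulation


def accumulation_halftime(
    time: Sequence[float] | np.ndarray,
    signal: Sequence[float] | np.ndarray,
) -> AccumulationFit:
    """Fit a normalized accumulation time course with 1 - exp(-k t).

    The signal must be normalized to a unit plateau. t1/2 = ln(2)/k, the
    time to half-maximal surface abundance. Non-saturating data (signal
    still far from plateau at the last time point under the best fit) are
    flagged ``converged=False``.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(signal, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")

    def resid(lk):
        return 1.0 - np.exp(-np.exp(lk[0]) * t) - y

    T = t[-1]
    best = None
    for k0 in (0.2 / T, 2 / T, 20 / T):
        res = optimize.least_squares(resid, x0=[np.log(k0)], xtol=1e-14, ftol=1e-14)
        if best is None or res.cost < best.cost:
            best = res
    k = float(np.exp(best.x[0]))
    rn = float(np.sqrt(np.sum(resid(best.x) ** 2)))
    saturated = 1.0 - np.exp(-k * T) > 0.5  # plateau at least half-reached
    return AccumulationFit(
        k=k, t_half=float(np.log(2.0) / k), residual_norm=rn,
        converged=bool(best.success) and saturated,
    )
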