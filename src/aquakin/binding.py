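"""Microscale-thermophoresis binding analysis.

Two models are fitted here. The first is a one-to-one binding isotherm with
an explicit correction for ligand depletion: because the titrated species
(the receptor protein, at total concentration ``l_tot``) binds a fixed
concentration ``p_tot`` of the fluorescent partner, the free titrant
concentration is obtained from the exact quadratic solution of the 1:1
mass balance rather than approximated by the total,

    L_free = 0.5 (L_tot - P_tot - Kd) + sqrt(0.25 (Kd + P_tot - L_tot)^2
                                             + L_tot Kd),

and the observed signal interpolates between the unbound level S1 and the
bound level S2 with the usual hyperbolic occupancy in L_free.

The second is the four-parameter log-logistic dose-response curve

    y = A1 + (A2 - A1) / (1 + 10^((x0 - x) p)),

with x the log10 inhibitor concentration, x0 the midpoint (IC50 = 10^x0)
and p the Hill coefficient.

MST raw traces are reduced to Fnorm, the ratio of mean fluorescence in a
window before infrared heating (F0) to a window after it (F1); the F1
window may be chosen automatically as the one maximising signal-to-noise.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MstTrace",
    "TitrationSeries",
    "BindingFit",
    "DoseResponseFit",
    "extract_fnorm",
    "free_ligand",
    "binding_signal",
    "fit_binding",
    "dose_response_signal",
    "fit_dose_response",
]

KD_BOUNDS = (1e-3, 1e5)  # μM; isotherm likelihood flattens for Kd >> max(L_tot)


# ---------------------------------------------------------------------------
# containers


@dataclasses.dataclass
class MstTrace:
    """A raw MST fluorescence trace with F0/F1 windows.

    ``f1_window`` may be the string ``"auto"``, in which case a fixed-width
    window slid over the post-F0 region is chosen to maximise
    |ΔF| / pooled SD.
    """

    time: np.ndarray
    rel_fluorescence: np.ndarray
    f0_window: tuple[float, float]
    f1_window: tuple[float, float] | str = "auto"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.rel_fluorescence = np.asarray(self.rel_fluorescence, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.rel_fluorescence.shape:
            raise ValueError("time and rel_fluorescence must be 1-D and equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        t0, t1 = self.f0_window
        if not (self.time[0] <= t0 < t1 <= self.time[-1]):
            raise ValueError("f0_window outside trace extent")
        if self.f1_window != "auto":
            s0, s1 = self.f1_window
            if not (self.time[0] <= s0 < s1 <= self.time[-1]):
                raise ValueError("f1_window outside trace extent")
            if s0 < t1:
                raise ValueError("f1_window must start after the f0_window ends")


@dataclasses.dataclass
class TitrationSeries:
    """Titration table: ligand concentrations vs normalized MST signal.

    ``l_tot`` is the titrated (varied) species in μM; ``p_tot`` the fixed
    fluorescent partner concentration in μM. ``signal`` may be Fnorm or
    ΔFnorm — the fitted baseline parameters absorb the offset convention.
    """

    l_tot: np.ndarray
    signal: np.ndarray
    p_tot: float = 0.0
    replicate_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.l_tot = np.asarray(self.l_tot, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.l_tot.shape != self.signal.shape or self.l_tot.ndim != 1:
            raise ValueError("l_tot and signal must be 1-D and equal length")
        if np.any(self.l_tot <= 0):
            raise ValueError("l_tot concentrations must be positive")
        if self.p_tot < 0:
            raise ValueError("p_tot must be non-negative")
        if self.replicate_id is not None:
            self.replicate_id = np.asarray(self.replicate_id)
            if self.replicate_id.shape != self.l_tot.shape:
                raise ValueError("replicate_id must match l_tot length")


@dataclasses.dataclass
class BindingFit:
    """One-to-one binding fit: S1 (unbound), S2 (bound), Kd with SEs."""

    s1: float
    s2: float
    kd: float
    se_s1: float = np.nan
    se_s2: float = np.nan
    se_kd: float = np.nan
    residual_norm: float = np.nan
    converged: bool = True
    binding_detected: bool = True
    n_points: int = 0


@dataclasses.dataclass
class DoseResponseFit:
    """Log-logistic dose-response fit; ic50 = 10**x0 in concentration units."""

    a1: float
    a2: float
    x0: float
    p: float
    ic50: float
    se_x0: float = np.nan
    se_ic50: float = np.nan
    se_p: float = np.nan
    residual_norm: float = np.nan
    converged: bool = True


# ---------------------------------------------------------------------------
# Fnorm extraction


def _window_slice(time: np.ndarray, window: tuple[float, float]) -> slice:
    i0 = int(np.searchsorted(time, window[0], side="left"))
    i1 = int(np.searchsorted(time, window[1], side="right"))
    return slice(i0, i1)


def extract_fnorm(trace: MstTrace, auto_width: float = 1.0) -> float:
    """Fnorm = mean(F in F0 window) / mean(F in F1 window).

    With ``f1_window="auto"`` a window of width ``auto_width`` seconds is
    slid sample-by-sample over the region after the F0 window and the
    position maximising |mean - F0 mean| / pooled SD is chosen (earliest
    window wins ties).
    """
    t = trace.time
    f = trace.rel_fluorescence
    s0 = _window_slice(t, trace.f0_window)
    if s0.stop - s0.start < 3:
        raise ValueError("f0_window must contain at least 3 samples")
    f0 = f[s0]
    f0_mean = float(np.mean(f0))

    if trace.f1_window == "auto":
        start_t = trace.f0_window[1]
        first = int(np.searchsorted(t, start_t, side="right"))
        best_score, best_mean = -np.inf, np.nan
        n = len(t)
        for i in range(first, n):
            j = int(np.searchsorted(t, t[i] + auto_width, side="right"))
            if j > n:
                break
            if j - i < 3:
                continue
            if t[j - 1] - t[i] < auto_width * 0.5:  # ran off the end
                break
            w = f[i:j]
            sd0 = np.var(f0, ddof=1)
            sd1 = np.var(w, ddof=1)
            pooled = np.sqrt(
                ((len(f0) - 1) * sd0 + (len(w) - 1) * sd1) / (len(f0) + len(w) - 2)
            )
            delta = abs(float(np.mean(w)) - f0_mean)
            score = np.inf if pooled == 0 and delta > 0 else (
                0.0 if pooled == 0 else delta / pooled
            )
            if score > best_score:  # strict: earliest window wins ties
                best_score, best_mean = score, float(np.mean(w))
        if not np.isfinite(best_score) and np.isnan(best_mean):
            raise ValueError("no valid f1 window found after the f0 window")
        f1_mean = best_mean
    else:
        s1 = _window_slice(t, trace.f1_window)
        if s1.stop - s1.start < 3:
            raise ValueError("f1_window must contain at least 3 samples")
        f1_mean = float(np.mean(f[s1]))

    if f1_mean == 0:
        raise ZeroDivisionError("mean fluorescence in f1_window is zero")
    return f0_mean / f1_mean


# ---------------------------------------------------------------------------
# binding model


def free_ligand(l_tot, p_tot, kd):
    """Free titrant concentration under 1:1 binding with depletion.

    Exact root of the mass-balance quadratic; reduces to ``l_tot`` when
    ``p_tot`` is 0 and to ``max(0, l_tot - p_tot)`` as ``kd`` → 0.
    All concentrations share one unit (μM throughout this package).
    """
    l_tot = np.asarray(l_tot, dtype=float)
    if np.any(l_tot < 0) or p_tot < 0 or kd < 0:
        raise ValueError("free_ligand requires non-negative l_tot, p_tot and kd")
    disc = 0.25 * (kd + p_tot - l_tot) ** 2 + l_tot * kd
    out = 0.5 * (l_tot - p_tot - kd) + np.sqrt(disc)
    # guard tiny negative round-off at stoichiometric depletion
    out = np.clip(out, 0.0, l_tot)
    return out if out.ndim else float(out)


def binding_signal(l_free, s1: float, s2: float, kd: float):
    """Signal of a 1:1 isotherm: S1 + (S2 - S1) * L_free / (L_free + Kd)."""
    l_free = np.asarray(l_free, dtype=float)
    if kd <= 0:
        raise ValueError("kd must be positive")
    out = s1 + (s2 - s1) * (l_free / (l_free + kd))
    return out if out.ndim else float(out)


def _binding_model(l_tot, p_tot, s1, s2, kd):
    return binding_signal(free_ligand(l_tot, p_tot, kd), s1, s2, kd)


def _cov_se(res, n: int, n_par: int) -> np.ndarray:
    """Parameter SEs from the Jacobian of a scipy least_squares result."""
    dof = max(n - n_par, 1)
    s2 = 2.0 * res.cost / dof
    try:
        jtj = res.jac.T @ res.jac
        cov = np.linalg.inv(jtj) * s2
        return np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        return np.full(n_par, np.nan)


def fit_binding(
    series: TitrationSeries,
    pool_replicates: bool = True,
    alpha: float = 0.05,
) -> BindingFit | list[BindingFit]:
    """Fit the depletion-corrected one-to-one isotherm to a titration.

    Nonlinear least squares over (S1, S2, Kd) with Kd bounded in
    ``KD_BOUNDS`` and multi-started from five log-spaced Kd guesses —
    the likelihood is flat in Kd once Kd exceeds the largest titrant
    concentration, so a single start is unreliable. ``binding_detected``
    is False when the isotherm does not beat a constant model in an
    extra-sum-of-squares F-test at ``alpha``, or when the fit runs into
    the upper Kd bound.

    With ``pool_replicates=False`` and a ``replicate_id`` column, each
    replicate series is fitted separately and a list is returned.
    """
    if not pool_replicates and series.replicate_id is not None:
        fits = []
        for rep in np.unique(series.replicate_id):
            m = series.replicate_id == rep
            sub = TitrationSeries(series.l_tot[m], series.signal[m], series.p_tot)
            fits.append(fit_binding(sub, alpha=alpha))
        return fits

    l, y, p_tot = series.l_tot, series.signal, series.p_tot
    n_conc = len(np.unique(l))
    if n_conc < 5:
        raise ValueError("fit_binding needs at least 5 distinct concentrations")
    if np.max(l) / np.min(l) < 10:
        raise ValueError("titration must span at least one decade in concentration")

    order = np.argsort(l)
    s1_0 = float(np.mean(y[order][: max(2, len(y) // 6)]))
    s2_0 = float(np.mean(y[order][-max(2, len(y) // 6):]))

    def resid(theta):
        s1, s2, lkd = theta
        return _binding_model(l, p_tot, s1, s2, 10.0 ** lkd) - y

    lo = np.array([-np.inf, -np.inf, np.log10(KD_BOUNDS[0])])
    hi = np.array([np.inf, np.inf, np.log10(KD_BOUNDS[1])])
    kd_starts = np.geomspace(
        max(np.min(l) / 10, KD_BOUNDS[0]), min(np.max(l) * 10, KD_BOUNDS[1]), 5
    )
    best = None
    for kd0 in kd_starts:
        try:
            res = optimize.least_squares(
                resid, x0=[s1_0, s2_0, np.log10(kd0)], bounds=(lo, hi),
                method="trf", xtol=1e-12, ftol=1e-12,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res

    n = len(y)
    if best is None:
        return BindingFit(np.nan, np.nan, np.nan, converged=False,
                          binding_detected=False, n_points=n)

    s1, s2, lkd = best.x
    kd = 10.0 ** lkd
    se = _cov_se(best, n, 3)
    se_kd = se[2] * kd * np.log(10)  # delta method from log10 Kd

    ss_fit = float(np.sum(resid(best.x) ** 2))
    ss_const = float(np.sum((y - np.mean(y)) ** 2))
    detected = _beats_constant(ss_const, ss_fit, n, 3, alpha)
    if kd >= KD_BOUNDS[1] * 0.99:
        detected = False

    return BindingFit(
        s1=float(s1), s2=float(s2), kd=float(kd),
        se_s1=float(se[0]), se_s2=float(se[1]), se_kd=float(se_kd),
        residual_norm=np.sqrt(ss_fit),
        converged=bool(best.success), binding_detected=bool(detected),
        n_points=n,
    )


def _beats_constant(ss0: float, ss1: float, n: int, n_par: int, alpha: float) -> bool:
    """Extra-sum-of-squares F-test of an ``n_par``-parameter model vs a constant."""
    df1, df2 = n_par - 1, n - n_par
    if df2 <= 0 or ss1 <= 0:
        return ss1 < ss0
    f = ((ss0 - ss1) / df1) / (ss1 / df2)
    return bool(stats.f.sf(f, df1, df2) < alpha) and ss1 < ss0


# ---------------------------------------------------------------------------
# dose response


def dose_response_signal(x, a1: float, a2: float, x0: float, p: float):
    """Log-logistic response: A1 + (A2 - A1) / (1 + 10^((x0 - x) p)).

    ``x`` is log10 concentration. At ``x = x0`` the value is (A1 + A2)/2;
    the slope there is (A2 - A1) * p * ln(10) / 4.
    """
    if p == 0 or not np.isfinite(p):
        raise ValueError("Hill coefficient p must be finite and nonzero")
    x = np.asarray(x, dtype=float)
    out = a1 + (a2 - a1) / (1.0 + 10.0 ** ((x0 - x) * p))
    return out if out.ndim else float(out)


def fit_dose_response(series: TitrationSeries, alpha: float = 0.05) -> DoseResponseFit:
    """Fit the four-parameter dose-response curve to an inhibitor titration.

    ``series.l_tot`` holds the inhibitor concentrations (any consistent
    unit); the fit works on x = log10(concentration). IC50 is reported as
    10**x0 in the input unit. A curve that does not beat a constant model
    (e.g. A1 ≈ A2) is returned with ``converged=False``.
    """
    conc, y = series.l_tot, series.signal
    if len(np.unique(conc)) < 6:
        raise ValueError("fit_dose_response needs at least 6 distinct concentrations")
    x = np.log10(conc)

    order = np.argsort(x)
    a1_0 = float(np.mean(y[order][: max(2, len(y) // 6)]))
    a2_0 = float(np.mean(y[order][-max(2, len(y) // 6):]))

    def resid(theta):
        a1, a2, x0, p = theta
        return a1 + (a2 - a1) / (1.0 + 10.0 ** ((x0 - x) * p)) - y

    span = x.max() - x.min()
    best = None
    for x0_0 in np.linspace(x.min() + 0.2 * span, x.max() - 0.2 * span, 3):
        for p0 in (0.5, 1.0, 2.0):
            res = optimize.least_squares(
                resid, x0=[a1_0, a2_0, x0_0, p0],
                bounds=([-np.inf, -np.inf, x.min() - 2 * span, -50],
                        [np.inf, np.inf, x.max() + 2 * span, 50]),
                method="trf", xtol=1e-12, ftol=1e-12,
            )
            if best is None or res.cost < best.cost:
                best = res

    a1, a2, x0, p = best.x
    n = len(y)
    se = _cov_se(best, n, 4)
    ic50 = 10.0 ** x0
    se_ic50 = se[2] * ic50 * np.log(10)

    ss_fit = float(np.sum(resid(best.x) ** 2))
    ss_const = float(np.sum((y - np.mean(y)) ** 2))
    ok = (
        bool(best.success)
        and _beats_constant(ss_const, ss_fit, n, 4, alpha)
        and abs(a2 - a1) > 1e-12
        and abs(p) > 1e-6
    )
    return DoseResponseFit(
        a1=float(a1), a2=float(a2), x0=float(x0), p=float(p),
        ic50=float(ic50), se_x0=float(se[2]), se_ic50=float(se_ic50),
        se_p=float(se[3]), residual_norm=np.sqrt(ss_fit), converged=ok,
    )
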