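"""Seeded synthetic-data generators for every assay.

Each generator is a deterministic function of its parameters and a
mandatory integer seed, and inverts the corresponding analysis model:
titrations are sampled from the depletion-corrected isotherm, dose-response
series from the log-logistic curve, shrinkage traces from the
double-exponential approach to plateau, quench traces from a
single-exponential decay, tissue weights from the water-content formula
run backwards, and ROI tables from a fixed peri/non-peri enrichment.

Noise conventions: additive Gaussian on fluorescence-derived signals;
multiplicative lognormal on weights and intensities, which must stay
positive.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from aquakin.binding import TitrationSeries, binding_signal, free_ligand, \
    dose_response_signal
from aquakin.permeability import QuenchTrace, StopFlowTrace

__all__ = [
    "MstDesign",
    "StopFlowDesign",
    "GroupSpec",
    "gen_mst_titration",
    "gen_dose_response",
    "gen_stopflow_trace",
    "gen_quench_trace",
    "gen_tissue_weights",
    "gen_roi_intensities",
]


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean lognormal multiplier with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# designs


@dataclasses.dataclass
class MstDesign:
    """Design of an MST titration: 12-16 points, fixed partner concentration.

    Defaults mirror a typical experiment: a geometric titration from 0.4 to
    160 μM of the varied protein at 17 μM total fluorescent partner. With
    ``dilution_series=True`` the concentrations are a strict 2:1 (or
    ``dilution_factor``:1) series descending from ``l_max`` instead of a
    geometric interpolation between the bounds. ``concentrations`` overrides
    both.
    """

    n_points: int = 12
    l_min: float = 0.4  # μM
    l_max: float = 160.0  # μM
    dilution_factor: float = 2.0
    p_tot: float = 17.0  # μM
    noise_sd: float = 0.0
    dilution_series: bool = False
    concentrations: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("n_points must be at least 3")
        if self.l_min <= 0:
            raise ValueError("l_min must be positive")
        if self.l_max <= self.l_min:
            raise ValueError("l_max must exceed l_min")
        if self.p_tot < 0:
            raise ValueError("p_tot must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must exceed 1")
        if self.concentrations is not None:
            c = np.asarray(self.concentrations, dtype=float)
            if np.any(c <= 0):
                raise ValueError("concentrations must be positive")

    def ligand_concentrations(self) -> np.ndarray:
        if self.concentrations is not None:
            return np.sort(np.asarray(self.concentrations, dtype=float))
        if self.dilution_series:
            c = self.l_max / self.dilution_factor ** np.arange(self.n_points)
            return np.sort(c)
        return np.geomspace(self.l_min, self.l_max, self.n_points)


@dataclasses.dataclass
class StopFlowDesign:
    """Design of a stopped-flow shrinkage acquisition.

    Two seconds of data, ten averaged readings and a fast/slow rate pair
    are the standard acquisition; amplitudes are in detector units.
    """

    k_fast: float = 63.7  # s^-1
    k_slow: float = 5.0  # s^-1
    a_fast: float = 0.7
    a_slow: float = 0.3
    baseline: float = 1.0
    duration: float = 2.0  # s
    dt: float = 0.002  # s
    noise_sd: float = 0.0
    n_reads: int = 10

    def __post_init__(self) -> None:
        if not (self.k_fast > self.k_slow >= 0):
            raise ValueError("require k_fast > k_slow >= 0")
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")
        if self.n_reads < 1:
            raise ValueError("n_reads must be at least 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclasses.dataclass
class GroupSpec:
    """A treatment group for group-structured generators."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


# ---------------------------------------------------------------------------
# generators


def gen_mst_titration(
    s1: float,
    s2: float,
    kd: float,
    design: MstDesign,
    seed: int,
    no_binding: bool = False,
) -> TitrationSeries:
    """Titration sampled from the depletion-corrected one-to-one isotherm.

    ``no_binding=True`` emulates a control series (chelated calcium or a
    non-binding construct): the signal is flat at S1 plus noise.
    """
    if not no_binding and kd <= 0:
        raise ValueError("kd must be positive unless no_binding is requested")
    rng = np.random.default_rng(seed)
    l_tot = design.ligand_concentrations()
    if no_binding:
        clean = np.full_like(l_tot, s1)
    else:
        clean = binding_signal(free_ligand(l_tot, design.p_tot, kd), s1, s2, kd)
    signal = clean + rng.normal(0.0, design.noise_sd, size=len(l_tot))
    return TitrationSeries(l_tot=l_tot, signal=signal, p_tot=design.p_tot)


def gen_dose_response(
    a1: float,
    a2: float,
    x0: float,
    p: float,
    concentrations: Sequence[float],
    seed: int,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
) -> TitrationSeries:
    """Inhibitor titration sampled from the log-logistic dose-response curve.

    ``x0`` is the midpoint on the log10-concentration axis; concentrations
    are given explicitly (the inhibitor series in practice is a short
    two-fold dilution whose exact spacing varies between experiments).
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    x = np.log10(conc)
    clean = dose_response_signal(x, a1, a2, x0, p)
    conc_all = np.tile(conc, n_replicates)
    clean_all = np.tile(clean, n_replicates)
    signal = clean_all + rng.normal(0.0, noise_sd, size=len(clean_all))
    rep = np.repeat(np.arange(n_replicates), len(conc))
    return TitrationSeries(l_tot=conc_all, signal=signal, p_tot=0.0,
                           replicate_id=rep)


def gen_stopflow_trace(design: StopFlowDesign, seed: int) -> StopFlowTrace:
    """Shrinkage trace: rising double exponential averaged over n_reads.

    Each of the ``n_reads`` replicates carries independent Gaussian noise
    of ``noise_sd``; the returned trace is their mean, so its residual SD
    scales as noise_sd / sqrt(n_reads).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, design.duration + design.dt / 2, design.dt)
    clean = (
        design.baseline
        + design.a_fast * (1.0 - np.exp(-design.k_fast * t))
        + design.a_slow * (1.0 - np.exp(-design.k_slow * t))
    )
    reads = clean + rng.normal(0.0, design.noise_sd, size=(design.n_reads, len(t)))
    return StopFlowTrace(time=t, fluorescence=reads.mean(axis=0))


def gen_quench_trace(
    k: float,
    seed: int,
    f0: float = 1.0,
    f_inf: float = 0.6,
    injection_time: float = 5.0,
    duration: float = 55.0,
    dt: float = 0.05,
    noise_sd: float = 0.0,
) -> QuenchTrace:
    """Calcein quench trace: flat baseline, then exponential decay.

    Mirrors the plate-reader protocol of a 5-s pre-injection read followed
    by the osmotic challenge and a 50-s decay read at 50-ms sampling.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + dt / 2, dt)
    clean = np.where(
        t < injection_time,
        f0,
        f_inf + (f0 - f_inf) * np.exp(-k * np.maximum(t - injection_time, 0.0)),
    )
    return QuenchTrace(
        time=t, fluorescence=clean + rng.normal(0.0, noise_sd, size=len(t))
    )


def gen_tissue_weights(
    groups: Sequence[GroupSpec],
    seed: int,
    wet_scale: float = 0.1,
    wet_cv: float = 0.2,
) -> pd.DataFrame:
    """Wet/dry weight table inverted from target water percentages.

    Each GroupSpec's ``mean``/``sd`` are the target water content in percent.
    Wet weights are lognormal around ``wet_scale`` grams (a ~100 mg tissue
    block); dry = wet * (1 - water%/100), so dry < wet always.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in groups:
        if not (0 < g.mean < 100):
            raise ValueError(
                f"group {g.label!r}: target water % must lie in (0, 100)"
            )
        wet = wet_scale * _lognormal_factor(rng, wet_cv, g.n)
        water = np.clip(rng.normal(g.mean, g.sd, size=g.n), 0.5, 99.5)
        dry = wet * (1.0 - water / 100.0)
        for w, d in zip(wet, dry):
            rows.append({"group": g.label, "wet_g": float(w), "dry_g": float(d)})
    return pd.DataFrame(rows)


def gen_roi_intensities(
    enrichment: float,
    n_animals: int,
    seed: int,
    images_per_animal: tuple[int, int] = (4, 9),
    rois_per_image: tuple[int, int] = (3, 10),
    noise_cv: float = 0.0,
    base_intensity: float = 80.0,
    group: str | None = None,
) -> pd.DataFrame:
    """Tidy ROI-intensity table with a fixed peri/non-peri enrichment.

    Per image, non-peri ROI means scatter (lognormal, ``noise_cv``) around
    an image-level baseline and peri ROI means around ``enrichment`` times
    that baseline, so the noiseless per-image ratio is exactly
    ``enrichment``. Image and ROI counts are drawn uniformly from the given
    inclusive ranges, emulating fields of view with varying numbers of
    endothelial cells.
    """
    if enrichment <= 0:
        raise ValueError("enrichment must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_animals):
        n_img = int(rng.integers(images_per_animal[0], images_per_animal[1] + 1))
        for im in range(n_img):
            level = base_intensity * _lognormal_factor(rng, 0.15, None)
            n_roi = int(rng.integers(rois_per_image[0], rois_per_image[1] + 1))
            for cls, mu in (("nonperi", level), ("peri", enrichment * level)):
                vals = mu * _lognormal_factor(rng, noise_cv, n_roi)
                for v in vals:
                    row = {
                        "animal": f"animal{a:02d}",
                        "image": f"img{im:02d}",
                        "roi_class": cls,
                        "mean_intensity": float(v),
                    }
                    if group is not None:
                        row["group"] = group
                    rows.append(row)
    return pd.DataFrame(rows)
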