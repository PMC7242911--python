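"""Tissue- and image-level summary metrics.

Covers four quantifications used in CNS-edema studies: gravimetric tissue
water content from wet/dry weights; perivascular enrichment of a membrane
protein from peri- vs non-peri-endothelial ROI intensities with hierarchical
(image -> animal -> group) averaging; thresholded positive-pixel counting
for immunostaining, with the threshold anchored so antibody-control images
count zero pixels; and compound-action-potential amplitude and rectified
negative area from voltage traces.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "TissueSample",
    "CapTrace",
    "water_content",
    "perivascular_ratio",
    "positive_pixel_count",
    "cap_metrics",
]


@dataclasses.dataclass
class TissueSample:
    group: str
    wet_weight: float  # g
    dry_weight: float  # g

    def __post_init__(self) -> None:
        if not (0 < self.dry_weight < self.wet_weight):
            raise ValueError(
                f"require 0 < dry_weight < wet_weight, got "
                f"dry={self.dry_weight}, wet={self.wet_weight}"
            )


@dataclasses.dataclass
class CapTrace:
    """Compound action potential voltage trace."""

    time: np.ndarray  # ms
    voltage: np.ndarray  # a.u.
    stimulus_artifact_end: float  # ms

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


def water_content(sample: TissueSample | None = None, *,
                  wet: float | None = None, dry: float | None = None) -> float:
    """Percent water: (wet - dry) / wet * 100.

    Accepts either a TissueSample or explicit ``wet=``/``dry=`` weights in
    grams. Scale-invariant: multiplying both weights by any constant leaves
    the result unchanged.
    """
    if sample is not None:
        wet, dry = sample.wet_weight, sample.dry_weight
    if wet is None or dry is None:
        raise ValueError("provide a TissueSample or wet= and dry= weights")
    if not (0 < dry < wet):
        raise ValueError(f"require 0 < dry < wet, got dry={dry}, wet={wet}")
    return (wet - dry) / wet * 100.0


def perivascular_ratio(roi_table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Peri-/non-peri-endothelial intensity ratios with hierarchical pooling.

    ``roi_table`` is tidy with columns ``animal``, ``image``, ``roi_class``
    (``"peri"`` or ``"nonperi"``) and ``mean_intensity``; an optional
    ``group`` column enables group summaries. Per image, the ratio is
    mean(peri ROI means) / mean(non-peri ROI means); per animal, the mean
    of its image ratios; group summaries average over animals so that
    image-rich animals carry no extra weight. Images whose non-peri mean is
    zero are excluded with a warning.

    Returns dict with ``per_image``, ``per_animal`` and (when a ``group``
    column is present) ``per_group`` DataFrames.
    """
    required = {"animal", "image", "roi_class", "mean_intensity"}
    missing = required - set(roi_table.columns)
    if missing:
        raise ValueError(f"roi_table missing columns: {sorted(missing)}")
    if np.any(roi_table["mean_intensity"] < 0):
        raise ValueError("ROI intensities must be non-negative")

    has_group = "group" in roi_table.columns
    rows = []
    for (animal, image), sub in roi_table.groupby(["animal", "image"], sort=True):
        peri = sub.loc[sub.roi_class == "peri", "mean_intensity"]
        nonperi = sub.loc[sub.roi_class == "nonperi", "mean_intensity"]
        if peri.empty or nonperi.empty:
            raise ValueError(
                f"image {image!r} of animal {animal!r} lacks a ROI class"
            )
        denom = float(nonperi.mean())
        if denom == 0:
            warnings.warn(
                f"image {image!r} of animal {animal!r} has zero non-peri mean; "
                "excluded", stacklevel=2,
            )
            continue
        row = {"animal": animal, "image": image,
               "ratio": float(peri.mean()) / denom}
        if has_group:
            row["group"] = sub["group"].iloc[0]
        rows.append(row)
    per_image = pd.DataFrame(rows)
    if per_image.empty:
        raise ValueError("no usable images")

    keys = ["group", "animal"] if has_group else ["animal"]
    per_animal = (
        per_image.groupby(keys, sort=True)["ratio"].mean().reset_index()
    )
    out = {"per_image": per_image, "per_animal": per_animal}
    if has_group:
        out["per_group"] = (
            per_animal.groupby("group", sort=True)["ratio"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )
    return out


def positive_pixel_count(
    image: np.ndarray,
    threshold: float | str = "auto",
    control_images: Sequence[np.ndarray] | None = None,
) -> tuple[int, float]:
    """Count pixels strictly above a background threshold.

    ``threshold="auto"`` sets the threshold to the maximum pixel value over
    the antibody-control images — the smallest level at which every control
    pixel is counted negative, so controls count exactly 0. Returns
    ``(count, threshold_used)``.
    """
    image = np.asarray(image)
    if threshold == "auto":
        if not control_images:
            raise ValueError("auto threshold requires control images")
        threshold = max(float(np.max(np.asarray(c))) for c in control_images)
    return int(np.count_nonzero(image > threshold)), float(threshold)


def cap_metrics(
    trace: CapTrace, min_prominence_frac: float = 0.05
) -> dict[str, float | bool]:
    """CAP amplitude and rectified negative area after the stimulus artifact.

    Amplitude is the vertical distance from the first local minimum after
    the artifact to the next local maximum; local extrema need a prominence
    of at least ``min_prominence_frac`` of the trace range, which rejects
    noise wiggles without smoothing the trace. Area is the trapezoidal
    integral of the full-wave-rectified negative component,
    ∫ |min(V, 0)| dt, over the post-artifact window.

    Returns ``{"amplitude", "area", "deflection_found"}``; a trace with no
    negative deflection yields amplitude 0 and ``deflection_found=False``.
    """
    m = trace.time >= trace.stimulus_artifact_end
    t, v = trace.time[m], trace.voltage[m]
    if len(t) < 3:
        raise ValueError("no samples after the stimulus artifact")

    rng = float(np.ptp(v))
    area = float(np.trapezoid(np.abs(np.minimum(v, 0.0)), t))
    if rng == 0:
        return {"amplitude": 0.0, "area": area, "deflection_found": False}

    prom = min_prominence_frac * rng
    minima, _ = find_peaks(-v, prominence=prom)
    minima = [i for i in minima if v[i] < 0]
    if not minima:
        return {"amplitude": 0.0, "area": area, "deflection_found": False}
    i_min = minima[0]

    maxima, _ = find_peaks(v, prominence=prom)
    maxima = [j for j in maxima if j > i_min]
    # plateau/end-of-trace fallback: use the global max after the trough
    i_max = maxima[0] if maxima else i_min + int(np.argmax(v[i_min:]))

    return {
        "amplitude": float(v[i_max] - v[i_min]),
        "area": area,
        "deflection_found": True,
    }
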