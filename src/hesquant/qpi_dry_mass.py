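"""Quantitative-phase-imaging dry mass and pre-event trend classification.

A background-corrected phase map φ (radians) converts to dry mass through
the optical path difference: ``OPD = φ·λ/(2π)`` per pixel, and

    mass [pg] = (1/α) · Σ_mask OPD · pixel_area = λ/(2πα) · Σ_mask φ · A_px

with λ the illumination wavelength (0.623 µm red LED default) and α the
specific refractive increment (0.185 µm³/pg ≡ 0.185 mL/g default).
Background is removed by subtracting the mean phase of the empty space from
the whole field.  Mass trajectories are classified as increasing / flat /
decreasing from the least-squares slope over a trailing window relative to
``flat_tolerance`` (fraction of the mean mass per hour): cells about to
divide gain mass, cells about to extrude do not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ImageStack

__all__ = ["DryMassParams", "DryMassTrace", "background_correct",
           "phase_to_mass", "mass_trace", "classify_trend"]


@dataclass
class DryMassParams:
    """Physical constants of the phase → dry-mass conversion."""

    wavelength: float = 0.623            # µm
    alpha: float = 0.185                 # µm³/pg, specific refractive increment
    pixel_area: float = 0.25             # µm²

    def __post_init__(self) -> None:
        if min(self.wavelength, self.alpha, self.pixel_area) <= 0:
            raise ValueError("all dry-mass parameters must be positive")

    @property
    def mass_per_phase_sum(self) -> float:
        """pg per unit of Σφ·pixel_area."""
        return self.wavelength / (2 * np.pi * self.alpha)


@dataclass
class DryMassTrace:
    region_id: int
    mass_series: np.ndarray              # pg per frame
    slope: float                         # pg/h over the trailing window
    trend_class: str                     # increasing | flat | decreasing


def background_correct(phase: np.ndarray,
                       empty_mask: np.ndarray) -> np.ndarray:
    """Subtract the mean phase of empty space from the whole field."""
    phase = np.asarray(phase, dtype=float)
    if empty_mask.shape != phase.shape[-2:]:
        raise ValueError("empty mask shape does not match the phase map")
    if not empty_mask.any():
        raise ValueError("empty-space mask has zero pixels")
    if phase.ndim == 2:
        return phase - phase[empty_mask].mean()
    means = phase[:, empty_mask].mean(axis=1)
    return phase - means[:, None, None]


def phase_to_mass(phase: np.ndarray, mask: np.ndarray,
                  params: DryMassParams) -> float:
    """Dry mass (pg) of a region from a corrected phase map (radians)."""
    phase = np.asarray(phase, dtype=float)
    if phase.ndim != 2:
        raise ValueError("phase_to_mass expects a single 2-D phase map")
    if mask.shape != phase.shape:
        raise ValueError("region mask lies outside the image")
    return float(params.mass_per_phase_sum * phase[mask].sum()
                 * params.pixel_area)


def mass_trace(stack: ImageStack, mask: np.ndarray, params: DryMassParams,
               empty_mask: np.ndarray | None = None, region_id: int = -1,
               window_frames: int | None = None,
               flat_tolerance: float = 0.05) -> DryMassTrace:
    """Per-frame dry mass of a region, background-corrected per frame.

    ``window_frames`` defaults to the trailing 2 h (or the whole trace when
    shorter).
    """
    data = stack.data
    if empty_mask is not None:
        data = background_correct(data, empty_mask)
    masses = np.array([phase_to_mass(data[t], mask, params)
                       for t in range(stack.n_frames)])
    if window_frames is None:
        window_frames = min(stack.n_frames,
                            max(3, int(round(120.0 / stack.frame_interval))))
    trend, slope = classify_trend(masses, window=window_frames,
                                  flat_tolerance=flat_tolerance,
                                  frame_interval=stack.frame_interval)
    return DryMassTrace(region_id=region_id, mass_series=masses,
                        slope=slope, trend_class=trend)


def classify_trend(mass_series: np.ndarray, window: int,
                   flat_tolerance: float = 0.05,
                   frame_interval: float = 1.0) -> tuple[str, float]:
    """Classify the trailing mass trend by its least-squares slope.

    Increasing if the slope exceeds ``+flat_tolerance × mean mass`` per
    hour, decreasing below the negative of that, flat otherwise.  Returns
    ``(trend_class, slope_pg_per_hour)``.
    """
    mass_series = np.asarray(mass_series, dtype=float)
    if window < 3:
        raise ValueError("trend window must span at least 3 frames")
    if window > len(mass_series):
        raise ValueError("trend window longer than the series")
    tail = mass_series[-window:]
    hours = np.arange(window) * frame_interval / 60.0
    slope = float(np.polyfit(hours, tail, 1)[0])
    bound = flat_tolerance * abs(tail.mean())
    if slope > bound:
        return "increasing", slope
    if slope < -bound:
        return "decreasing", slope
    return "flat", slope
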