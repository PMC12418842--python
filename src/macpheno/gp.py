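"""Ratiometric generalized-polarization (GP) membrane-order analysis.

Di-4-ANEPPDHQ emission blue-shifts in ordered (liquid-ordered) membrane and
red-shifts in disordered membrane, so two emission windows — 500-580 nm
("ordered" channel, I_o) and 620-750 nm ("disordered" channel, I_d) — give a
pixel-wise order statistic

    GP = (I_o - G * I_d) / (I_o + G * I_d)

where G is an instrument calibration factor that equalizes the detection
efficiency of the two channels. G is derived from a reference sample (LUVs of
defined lipid composition) with a known literature GP value ``gp_ref``: the
raw GP measured for that sample with G = 1 is ``gp_mes``, and

    G = (gp_ref + gp_ref*gp_mes - gp_mes - 1) / (gp_mes + gp_ref*gp_mes - gp_ref - 1)
      = (1 - gp_ref)(1 + gp_mes) / ((1 - gp_mes)(1 + gp_ref))

which makes the calibrated GP of the reference sample equal gp_ref exactly
(round-trip identity).

Per-cell summaries are reported on a x100 scale (GP 0.5698 -> 56.98), the
scale used when quoting group means for macrophage phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from matplotlib.colors import hsv_to_rgb

__all__ = [
    "ChannelPair",
    "CalibrationReference",
    "GPMap",
    "GPSummary",
    "raw_reference_gp",
    "calibration_g",
    "gp_pixelwise",
    "summarize_roi",
    "render_gp_map",
    "m1_m2_intensity_ratio",
    "read_channel_pair",
    "write_channel_pair",
    "summaries_to_frame",
]

REPORTED_SCALE = 100.0  # reported GP = 100 x internal GP, exactly


@dataclass(frozen=True)
class ChannelPair:
    """Registered dual-channel intensity image.

    ``ordered_channel`` is the 500-580 nm emission window, ``disordered_channel``
    the 620-750 nm window; both are nonnegative detector units on the same
    pixel grid (0-based, row-major).
    """

    ordered_channel: np.ndarray
    disordered_channel: np.ndarray

    def __post_init__(self) -> None:
        io = np.asarray(self.ordered_channel, dtype=float)
        id_ = np.asarray(self.disordered_channel, dtype=float)
        if io.ndim != 2 or id_.ndim != 2:
            raise ValueError("channels must be 2-D intensity grids")
        if io.shape != id_.shape:
            raise ValueError(f"channel shape mismatch: {io.shape} vs {id_.shape}")
        if not (np.all(np.isfinite(io)) and np.all(np.isfinite(id_))):
            raise ValueError("channels contain non-finite values")
        if io.min() < 0 or id_.min() < 0:
            raise ValueError("channel intensities must be >= 0")
        object.__setattr__(self, "ordered_channel", io)
        object.__setattr__(self, "disordered_channel", id_)

    @property
    def shape(self) -> tuple[int, int]:
        return self.ordered_channel.shape

    def shifted(self, drow: int = 0, dcol: int = 0) -> "ChannelPair":
        """Integer-pixel registration: shift the disordered channel by (drow, dcol).

        Vacated pixels are zero-filled. No registration is applied by default
        anywhere in the pipeline (simultaneous two-channel acquisition is
        assumed); this exists for data acquired sequentially.
        """
        shifted = np.zeros_like(self.disordered_channel)
        src = self.disordered_channel
        h, w = src.shape
        rs, re = max(drow, 0), min(h + drow, h)
        cs, ce = max(dcol, 0), min(w + dcol, w)
        shifted[rs:re, cs:ce] = src[rs - drow:re - drow, cs - dcol:ce - dcol]
        return ChannelPair(self.ordered_channel, shifted)


def raw_reference_gp(ordered: float | np.ndarray, disordered: float | np.ndarray) -> float | np.ndarray:
    """Uncalibrated GP, (I_o - I_d) / (I_o + I_d)."""
    io = np.asarray(ordered, dtype=float)
    id_ = np.asarray(disordered, dtype=float)
    total = io + id_
    if np.any(total <= 0):
        raise ValueError("undefined ratio: total intensity must be positive")
    out = (io - id_) / total
    return float(out) if out.ndim == 0 else out


def calibration_g(gp_ref: float, gp_mes: float) -> float:
    """Calibration factor from the reference GP and its raw measured GP.

    Both arguments must lie strictly in (-1, 1). Returns G > 0 such that
    applying the calibrated GP estimator to intensities whose raw GP equals
    ``gp_mes`` yields ``gp_ref``.
    """
    if not (-1 < gp_ref < 1):
        raise ValueError(f"gp_ref must be in (-1, 1), got {gp_ref}")
    if not (-1 < gp_mes < 1):
        raise ValueError(f"gp_mes must be in (-1, 1), got {gp_mes}")
    return ((1 - gp_ref) * (1 + gp_mes)) / ((1 - gp_mes) * (1 + gp_ref))


@dataclass(frozen=True)
class CalibrationReference:
    """Reference-sample calibration: literature GP, raw measured GP, derived G."""

    gp_ref: float
    gp_mes: float
    g_factor: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "g_factor", calibration_g(self.gp_ref, self.gp_mes))

    @classmethod
    def from_intensity_pairs(cls, pairs: Iterable[tuple[float, float]],
                             gp_ref: float) -> "CalibrationReference":
        """Estimate gp_mes as the mean raw GP of per-vesicle intensity pairs."""
        arr = np.asarray(list(pairs), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
            raise ValueError("need a nonempty sequence of (ordered, disordered) pairs")
        gp_mes = float(np.mean(raw_reference_gp(arr[:, 0], arr[:, 1])))
        return cls(gp_ref=gp_ref, gp_mes=gp_mes)


@dataclass(frozen=True)
class GPMap:
    """Pixel-wise GP image with a validity mask.

    Pixels whose calibrated total intensity ``I_o + G*I_d`` does not exceed
    ``intensity_floor`` are invalid: they are excluded from all statistics,
    never clamped, and their gp entry is NaN.
    """

    gp: np.ndarray
    valid_mask: np.ndarray
    intensity_floor: float
    g_factor_used: float

    def __post_init__(self) -> None:
        if self.gp.shape != self.valid_mask.shape:
            raise ValueError("gp / valid_mask shape mismatch")
        valid = self.gp[self.valid_mask]
        if valid.size and (not np.all(np.isfinite(valid)) or
                           np.any(np.abs(valid) > 1)):
            raise ValueError("valid GP pixels must be finite and within [-1, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.gp.shape


def gp_pixelwise(channels: ChannelPair, g_factor: float,
                 intensity_floor: float = 0.0) -> GPMap:
    """Calibrated pixel-wise GP map.

    ``intensity_floor`` is in detector units; validity requires
    ``I_o + G*I_d > intensity_floor`` (strictly), so the default floor of 0
    already masks empty pixels.
    """
    if g_factor <= 0:
        raise ValueError(f"g_factor must be positive, got {g_factor}")
    if intensity_floor < 0:
        raise ValueError("intensity_floor must be >= 0")
    io = channels.ordered_channel
    id_ = channels.disordered_channel
    denom = io + g_factor * id_
    valid = denom > intensity_floor
    gp = np.full(io.shape, np.nan)
    np.divide(io - g_factor * id_, denom, out=gp, where=valid)
    return GPMap(gp=gp, valid_mask=valid, intensity_floor=float(intensity_floor),
                 g_factor_used=float(g_factor))


@dataclass(frozen=True)
class GPSummary:
    """Mean GP of one cell's membrane ROI, on internal and reported scales."""

    cell_id: str
    phenotype: str
    mean_gp_internal: float
    n_pixels: int

    @property
    def mean_gp_reported(self) -> float:
        return REPORTED_SCALE * self.mean_gp_internal


def summarize_roi(gp_map: GPMap, roi: np.ndarray, cell_id: str,
                  phenotype: str = "unknown") -> GPSummary:
    """Mean GP over the valid pixels of a membrane ROI.

    The mean runs over ``roi & valid_mask`` only; ``n_pixels`` counts the
    pixels actually averaged.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != gp_map.shape:
        raise ValueError("ROI shape does not match GP map")
    sel = roi & gp_map.valid_mask
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"cell {cell_id!r}: ROI contains no valid GP pixels")
    return GPSummary(cell_id=cell_id, phenotype=phenotype,
                     mean_gp_internal=float(gp_map.gp[sel].mean()), n_pixels=n)


def render_gp_map(gp_map: GPMap, channels: ChannelPair,
                  gp_range: tuple[float, float] = (-1.0, 1.0),
                  brightness_percentile: float = 99.0) -> np.ndarray:
    """HSB merge of a GP map with mean fluorescence intensity.

    Hue encodes GP linearly across ``gp_range`` with blue at the high-GP
    (ordered) end and red at the low-GP (disordered) end; saturation is 1;
    brightness is the two-channel mean intensity normalized to [0, 1] by the
    given percentile over valid pixels. Invalid pixels render black. Returns
    a float RGB array in [0, 1] of shape (H, W, 3).
    """
    lo, hi = gp_range
    if not hi > lo:
        raise ValueError("degenerate GP range: max must exceed min")
    if channels.shape != gp_map.shape:
        raise ValueError("channel shape does not match GP map")
    frac = np.clip((gp_map.gp - lo) / (hi - lo), 0.0, 1.0)
    hue = np.nan_to_num(frac * (2.0 / 3.0))  # 0 = red (disordered) .. 2/3 = blue (ordered)
    mean_int = 0.5 * (channels.ordered_channel + channels.disordered_channel)
    if gp_map.valid_mask.any():
        scale = np.percentile(mean_int[gp_map.valid_mask], brightness_percentile)
    else:
        scale = 0.0
    value = np.clip(mean_int / scale, 0.0, 1.0) if scale > 0 else np.zeros_like(mean_int)
    value = np.where(gp_map.valid_mask, value, 0.0)
    hsv = np.stack([hue, np.ones_like(hue), value], axis=-1)
    return hsv_to_rgb(hsv)


def m1_m2_intensity_ratio(summaries: Sequence[GPSummary] | pd.DataFrame,
                          measure: str = "mean_gp_reported") -> dict:
    """Ratio of the M1 group mean to the M2 group mean for a chosen measure.

    ``summaries`` may be GPSummary objects or a data frame with a
    ``phenotype`` column plus the measure column. Returns a dict naming the
    measure, the two group means, and their ratio M1/M2.
    """
    if isinstance(summaries, pd.DataFrame):
        frame = summaries
    else:
        frame = summaries_to_frame(summaries)
    if measure not in frame.columns:
        raise ValueError(f"measure {measure!r} not present")
    m1 = frame.loc[frame["phenotype"] == "M1", measure]
    m2 = frame.loc[frame["phenotype"] == "M2", measure]
    if m1.empty or m2.empty:
        raise ValueError("need at least one M1 and one M2 entry")
    m1_mean, m2_mean = float(m1.mean()), float(m2.mean())
    if m2_mean == 0:
        raise ValueError("undefined ratio: M2 group mean is zero")
    return {"measure": measure, "m1_mean": m1_mean, "m2_mean": m2_mean,
            "ratio_m1_m2": m1_mean / m2_mean}


def summaries_to_frame(summaries: Sequence[GPSummary]) -> pd.DataFrame:
    """Tidy per-cell summary table with the fixed output column order."""
    return pd.DataFrame(
        [{"cell_id": s.cell_id, "phenotype": s.phenotype, "n_pixels": s.n_pixels,
          "mean_gp_internal": s.mean_gp_internal,
          "mean_gp_reported": s.mean_gp_reported} for s in summaries],
        columns=["cell_id", "phenotype", "n_pixels",
                 "mean_gp_internal", "mean_gp_reported"],
    )


def read_channel_pair(path: str | Path, second: str | Path | None = None) -> ChannelPair:
    """Read a two-page TIFF (page 1 = ordered, page 2 = disordered), or two
    single-page TIFFs when ``second`` is given."""
    if second is not None:
        return ChannelPair(tifffile.imread(str(path)), tifffile.imread(str(second)))
    stack = tifffile.imread(str(path))
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ValueError(f"{path}: expected a two-page TIFF, got shape {stack.shape}")
    return ChannelPair(stack[0], stack[1])


def write_channel_pair(path: str | Path, channels: ChannelPair) -> None:
    """Write as a two-page float32 grayscale TIFF (ordered page first)."""
    stack = np.stack([channels.ordered_channel, channels.disordered_channel])
    tifffile.imwrite(str(path), stack.astype(np.float32))
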