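"""Pulsed-field gel lane analysis.

Chromosome XII of *S. cerevisiae* carries the rDNA tandem array, so its
apparent size on a PFGE gel is a direct readout of rDNA copy number:

    copies = (size_kb - backbone_kb) / unit_kb

where ``backbone_kb`` is the non-rDNA portion of the chromosome and
``unit_kb`` the length of one repeat unit.  This module turns 1-D lane
densitometry profiles into sizes, copy numbers, copy-number shifts relative
to a reference lane (typically generation 0 of a long-term culture), and
band-intensity proportions for competition and ERC gels.

Migration distance is calibrated against a chromosomal size ladder
(e.g. *Hansenula wingei* markers) by piecewise-linear interpolation of
log10(size) against distance — the standard empirical treatment for gel
ladders; no mobility physics is modelled.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import minimum_filter1d


class CalibrationError(ValueError):
    """Marker ladder is unusable (too few bands, non-monotone sizes)."""


class WindowError(ValueError):
    """Band windows overlap or fall outside the profile support."""


class NegativeCopyError(ValueError):
    """Estimated chromosome size fell below the non-rDNA backbone length."""


@dataclass
class LaneProfile:
    """A single gel lane reduced to a 1-D densitometry trace.

    distances are in mm from the well, strictly increasing; intensities are
    arbitrary non-negative densitometry units.
    """

    distances: np.ndarray
    intensities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.distances.shape != self.intensities.shape:
            raise ValueError("distances and intensities must have equal length")
        if self.distances.size == 0:
            raise ValueError("empty lane profile")
        if np.any(np.diff(self.distances) <= 0):
            raise ValueError("distances must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"distance_mm": self.distances, "intensity": self.intensities}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, label: str = "") -> "LaneProfile":
        df = pd.read_csv(path, sep="\t")
        return cls(df["distance_mm"].to_numpy(), df["intensity"].to_numpy(), label)


@dataclass
class MigrationCalibration:
    """Monotone distance↔size map fitted from marker-lane bands.

    Interpolates log10(size_kb) linearly between knots; outside the knot
    range the terminal segment is extrapolated (with a warning).  Size is
    strictly decreasing in distance, so the map is invertible.
    """

    knots: list[tuple[float, float]]  # (distance_mm, size_kb), sorted by distance
    method: str = "loglinear"

    def __post_init__(self) -> None:
        if len(self.knots) < 2:
            raise CalibrationError("need at least 2 marker bands")
        self.knots = sorted((float(d), float(s)) for d, s in self.knots)
        d = np.array([k[0] for k in self.knots])
        s = np.array([k[1] for k in self.knots])
        if np.any(np.diff(d) <= 0):
            raise CalibrationError("marker distances must be distinct")
        if np.any(np.diff(s) >= 0):
            raise CalibrationError("marker sizes must strictly decrease with distance")
        if np.any(s <= 0):
            raise CalibrationError("marker sizes must be positive")
        self._d = d
        self._logs = np.log10(s)

    @classmethod
    def from_markers(cls, marker_peaks) -> "MigrationCalibration":
        """Fit a calibration from (distance_mm, size_kb) marker bands."""
        return cls(knots=[(d, s) for d, s in marker_peaks])

    def size_at(self, distance) -> float | np.ndarray:
        """Size (kb) at a migration distance (mm); extrapolates with warning."""
        distance = np.asarray(distance, dtype=float)
        if np.any(distance < self._d[0]) or np.any(distance > self._d[-1]):
            warnings.warn(
                "distance outside ladder range; extrapolating terminal segment",
                stacklevel=2,
            )
        # np.interp clamps, so extrapolate the terminal segments explicitly
        logs = np.interp(distance, self._d, self._logs)
        lo = distance < self._d[0]
        hi = distance > self._d[-1]
        if np.any(lo):
            slope = (self._logs[1] - self._logs[0]) / (self._d[1] - self._d[0])
            logs = np.where(lo, self._logs[0] + slope * (distance - self._d[0]), logs)
        if np.any(hi):
            slope = (self._logs[-1] - self._logs[-2]) / (self._d[-1] - self._d[-2])
            logs = np.where(hi, self._logs[-1] + slope * (distance - self._d[-1]), logs)
        out = 10.0 ** logs
        return float(out) if out.ndim == 0 else out

    def distance_at(self, size_kb) -> float | np.ndarray:
        """Inverse map: migration distance (mm) of a fragment of given size."""
        size_kb = np.asarray(size_kb, dtype=float)
        logs = np.log10(size_kb)
        # distances increase as log-size decreases
        d = np.interp(-logs, -self._logs, self._d)
        lo = logs > self._logs[0]  # larger than largest marker -> before first knot
        hi = logs < self._logs[-1]
        slope0 = (self._d[1] - self._d[0]) / (self._logs[1] - self._logs[0])
        slope1 = (self._d[-1] - self._d[-2]) / (self._logs[-1] - self._logs[-2])
        if np.any(lo):
            d = np.where(lo, self._d[0] + slope0 * (logs - self._logs[0]), d)
        if np.any(hi):
            d = np.where(hi, self._d[-1] + slope1 * (logs - self._logs[-1]), d)
        return float(d) if d.ndim == 0 else d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"method": self.method, "knots": self.knots}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MigrationCalibration":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(knots=[tuple(k) for k in obj["knots"]], method=obj.get("method", "loglinear"))


@dataclass
class Peak:
    """A detected band: apex position/intensity, prominence, FWHM and area."""

    distance: float
    intensity: float
    prominence: float
    fwhm: float
    area: float
    centroid: float = field(default=np.nan)


fit_ladder = MigrationCalibration.from_markers


def _baseline(lane: LaneProfile, window_mm: float) -> np.ndarray:
    """Lower-envelope baseline: rolling minimum over a ``window_mm``-wide
    window (kept much wider than a band so apex positions are not skewed)."""
    if window_mm <= 0:
        return np.zeros_like(lane.intensities)
    step = float(np.median(np.diff(lane.distances)))
    size = max(3, int(round(window_mm / step)))
    return minimum_filter1d(lane.intensities, size=size, mode="nearest")


def find_peaks(
    lane: LaneProfile,
    min_prominence: float = 0.05,
    baseline_window_mm: float = 10.0,
) -> list[Peak]:
    """Detect bands in a lane profile.

    ``min_prominence`` is a fraction of the maximum baseline-subtracted
    intensity.  Returns peaks ordered by migration distance; a flat profile
    yields an empty list.
    """
    y = lane.intensities - _baseline(lane, baseline_window_mm)
    ymax = float(np.max(y))
    if ymax <= 0:
        return []
    idx, props = signal.find_peaks(y, prominence=min_prominence * ymax)
    if idx.size == 0:
        return []
    widths, _, lips, rips = signal.peak_widths(y, idx, rel_height=0.5)
    step = float(np.median(np.diff(lane.distances)))
    peaks = []
    for j, i in enumerate(idx):
        lo = int(np.floor(lips[j]))
        hi = int(np.ceil(rips[j])) + 1
        seg_x = lane.distances[lo:hi]
        seg_y = y[lo:hi]
        area = float(np.trapezoid(seg_y, seg_x))
        centroid = (
            float(np.sum(seg_x * seg_y) / np.sum(seg_y)) if np.sum(seg_y) > 0 else lane.distances[i]
        )
        peaks.append(
            Peak(
                distance=float(lane.distances[i]),
                intensity=float(y[i]),
                prominence=float(props["prominences"][j]),
                fwhm=float(widths[j]) * step,
                area=area,
                centroid=centroid,
            )
        )
    return sorted(peaks, key=lambda p: p.distance)


def estimate_copy_number(
    peak: Peak,
    cal: MigrationCalibration,
    unit_kb: float = 9.1,
    backbone_kb: float = 1050.0,
    round_to_int: bool = False,
    use_centroid: bool = False,
) -> float:
    """rDNA copies implied by a chromosome XII band.

    copies = (size(apex) - backbone_kb) / unit_kb.  ``use_centroid``
    summarizes a smeared band by its intensity centroid instead of the apex.
    """
    if unit_kb <= 0:
        raise ValueError("unit_kb must be positive")
    pos = peak.centroid if use_centroid and np.isfinite(peak.centroid) else peak.distance
    size = cal.size_at(pos)
    copies = (size - backbone_kb) / unit_kb
    if copies < 0:
        raise NegativeCopyError(
            f"estimated size {size:.1f} kb < backbone {backbone_kb} kb; check calibration"
        )
    return float(round(copies)) if round_to_int else float(copies)


def _select_peak(peaks: list[Peak], anchor: float | None) -> Peak:
    """Pick the chromosome XII peak: nearest the anchor (tie -> larger area),
    or the largest-area peak when no anchor is given."""
    if anchor is None:
        return max(peaks, key=lambda p: p.area)
    best = min(peaks, key=lambda p: (abs(p.distance - anchor), -p.area))
    return best


def copy_shift(
    lane_t: LaneProfile,
    lane_0: LaneProfile,
    cal: MigrationCalibration,
    unit_kb: float = 9.1,
    backbone_kb: float = 1050.0,
    min_prominence: float = 0.05,
    baseline_window_mm: float = 10.0,
    anchor: float | None = None,
    use_centroid: bool = False,
) -> float:
    """Copy-number shift of ``lane_t`` relative to the reference ``lane_0``.

    The chromosome XII peak in the reference lane is the largest-area peak
    (or the one nearest ``anchor`` when supplied); in ``lane_t`` it is the
    peak nearest the reference peak.  Both lanes are sized with the same
    calibration, so ladder error largely cancels in the difference.
    """
    peaks_0 = find_peaks(lane_0, min_prominence, baseline_window_mm)
    peaks_t = find_peaks(lane_t, min_prominence, baseline_window_mm)
    if not peaks_0 or not peaks_t:
        raise ValueError("both lanes must contain at least one detectable peak")
    p0 = _select_peak(peaks_0, anchor)
    pt = _select_peak(peaks_t, p0.distance)
    c0 = estimate_copy_number(p0, cal, unit_kb, backbone_kb, use_centroid=use_centroid)
    ct = estimate_copy_number(pt, cal, unit_kb, backbone_kb, use_centroid=use_centroid)
    return ct - c0


@dataclass
class BandProportions:
    """Per-window intensity fractions; ``defined`` is False when the lane
    carries no signal in any window (proportions are then meaningless)."""

    fractions: np.ndarray
    areas: np.ndarray
    defined: bool


def band_proportions(
    lane: LaneProfile,
    bands: list[tuple[float, float]],
    baseline_window_mm: float = 10.0,
) -> BandProportions:
    """Fraction of (baseline-subtracted) signal in each distance window.

    Used for competition gels — the relative intensity of two chromosome XII
    bands of different sizes tracks the strain proportions — and for
    ERC-vs-genomic quantification.  A band whose strain has gone extinct
    reports 0.
    """
    for lo, hi in bands:
        if hi <= lo:
            raise WindowError(f"window ({lo}, {hi}) is empty")
        if lo < lane.distances[0] or hi > lane.distances[-1]:
            raise WindowError(f"window ({lo}, {hi}) outside profile support")
    ordered = sorted(bands)
    for (_, hi), (lo, _) in zip(ordered, ordered[1:]):
        if lo < hi:
            raise WindowError("band windows overlap")
    y = lane.intensities - _baseline(lane, baseline_window_mm)
    y = np.clip(y, 0.0, None)
    areas = []
    for lo, hi in bands:
        mask = (lane.distances >= lo) & (lane.distances <= hi)
        areas.append(float(np.trapezoid(y[mask], lane.distances[mask])))
    areas = np.array(areas)
    total = areas.sum()
    if total <= 0:
        return BandProportions(np.full(len(bands), np.nan), areas, defined=False)
    return BandProportions(areas / total, areas, defined=True)
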