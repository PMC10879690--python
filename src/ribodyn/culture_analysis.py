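"""Generation accounting, copy-number drift, and ploidy classification.

Serial passage converts transfers into generations by doublings: a
1,000-fold dilution regrown to saturation is log2(1000) ≈ 9.97 ≈ 10
generations; a colony of N cells grown from a single founder is log2(N)
doublings.  Drift of rDNA copy number over a long-term culture is
summarized by a per-replicate ordinary-least-squares slope of copies on
generation, with a sign tally across replicates (a zero band ±ε absorbs
numerically flat slopes).  Ploidy changes that arise during long-term
culture (diploidization) are detected as the ratio of dominant DNA-content
modes between a sample and a reference histogram.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .refgen import CopyTrajectory, FACSHistogram


@dataclass
class PassageScheme:
    """A serial-passage design: liquid dilution or colony transfer."""

    mode: str  # "liquid-dilution" | "colony-transfer"
    factor: float  # dilution factor, or cells per colony
    transfers: int

    def __post_init__(self) -> None:
        if self.mode not in ("liquid-dilution", "colony-transfer"):
            raise ValueError("mode must be 'liquid-dilution' or 'colony-transfer'")
        if self.factor <= 1:
            raise ValueError("dilution factor / cells-per-colony must exceed 1")
        if self.transfers < 1:
            raise ValueError("transfers must be >= 1")

    def generations_per_transfer(self) -> float:
        if self.mode == "liquid-dilution":
            return generations_per_transfer(self.factor)
        return colony_generations(self.factor)

    def total_generations(self) -> float:
        return self.transfers * self.generations_per_transfer()


def generations_per_transfer(dilution_factor: float, rounded: bool = False) -> float:
    """Doublings needed to regrow a ``dilution_factor``-fold dilution to the
    same density: log2(dilution_factor).  1,000-fold ≈ 9.97 ≈ 10."""
    if dilution_factor <= 1:
        raise ValueError("dilution factor must exceed 1 (no growth implied)")
    g = math.log2(dilution_factor)
    return float(round(g)) if rounded else g


def colony_generations(cells_per_colony: float) -> float:
    """Doublings from one founder cell to a colony of N cells: log2(N)."""
    if cells_per_colony < 1:
        raise ValueError("cells_per_colony must be >= 1")
    return math.log2(cells_per_colony)


@dataclass
class DriftSummary:
    """Per-replicate copy-number slopes and their sign tally."""

    slopes: np.ndarray  # copies per generation, one per replicate
    n_negative: int
    n_zero: int
    n_positive: int
    zero_band: float
    group: str = ""

    @property
    def n_replicates(self) -> int:
        return self.slopes.size

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "n_replicates": self.n_replicates,
            "mean_slope": float(self.slopes.mean()),
            "n_negative": self.n_negative,
            "n_zero": self.n_zero,
            "n_positive": self.n_positive,
            "zero_band": self.zero_band,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def estimate_drift(
    traj: CopyTrajectory,
    zero_band: float = 0.005,
    method: str = "ols",
    use_total: bool = True,
) -> DriftSummary:
    """Directional drift of copy number across replicates.

    Each replicate contributes the OLS slope of (total) copies on
    generation (``method='endpoints'`` uses (last − first)/Δgenerations
    instead).  Slopes within ±``zero_band`` copies/generation are tallied
    as zero.  Requires at least 3 time points for the OLS fit.
    """
    if traj.generations.size < 3 and method == "ols":
        raise ValueError("need >= 3 time points per replicate for OLS drift")
    series = traj.total() if use_total else traj.copies.reshape(-1, traj.generations.size)
    g = traj.generations.astype(float)
    slopes = []
    for row in series:
        if method == "ols":
            slopes.append(stats.linregress(g, row).slope)
        elif method == "endpoints":
            slopes.append((row[-1] - row[0]) / (g[-1] - g[0]))
        else:
            raise ValueError("method must be 'ols' or 'endpoints'")
    slopes = np.array(slopes)
    neg = int(np.sum(slopes < -zero_band))
    posi = int(np.sum(slopes > zero_band))
    zero = slopes.size - neg - posi
    return DriftSummary(
        slopes=slopes,
        n_negative=neg,
        n_zero=zero,
        n_positive=posi,
        zero_band=zero_band,
        group=traj.mode,
    )


def _dominant_mode(hist: FACSHistogram, smooth: int = 3) -> float:
    """Fluorescence of the dominant peak (counts lightly smoothed)."""
    counts = hist.counts.astype(float)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        counts = np.convolve(counts, kernel, mode="same")
    if counts.max() <= 0:
        raise ValueError("histogram has no detectable peak")
    return float(hist.fluorescence[int(np.argmax(counts))])


@dataclass
class PloidyCall:
    ratio: float
    call: str  # "doubled" | "unchanged" | "ambiguous"
    sample_mode: float
    reference_mode: float

    def to_dict(self) -> dict:
        return {
            "ratio": self.ratio,
            "call": self.call,
            "sample_mode": self.sample_mode,
            "reference_mode": self.reference_mode,
        }


def classify_ploidy(
    sample: FACSHistogram,
    reference: FACSHistogram,
    delta: float = 0.2,
) -> PloidyCall:
    """DNA-content doubling check by dominant-mode ratio.

    ratio = dominant mode of sample / dominant mode of reference;
    "doubled" within [2−δ, 2+δ], "unchanged" within [1−δ, 1+δ], else
    "ambiguous".
    """
    ms = _dominant_mode(sample)
    mr = _dominant_mode(reference)
    ratio = ms / mr
    if 2 - delta <= ratio <= 2 + delta:
        call = "doubled"
    elif 1 - delta <= ratio <= 1 + delta:
        call = "unchanged"
    else:
        call = "ambiguous"
    return PloidyCall(ratio=float(ratio), call=call, sample_mode=ms, reference_mode=mr)
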