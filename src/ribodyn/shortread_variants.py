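"""Naive variant tallying over the collapsed rDNA unit.

Short reads from a PCR-amplified rDNA pool are mapped to a single repeat
unit, so all array copies collapse onto one coordinate system: a variant
carried by k of n copies appears at allele frequency ≈ k/n.  This module
tallies per-position base counts (A/C/G/T/deletion) from SAM alignments or
a simulated pileup table, converts them to non-reference frequencies, and
compares two frequency spectra (e.g. wild type vs a fork-barrier mutant)
by their paired per-position differences with a seeded position bootstrap.
No genotyping model is applied — the output is descriptive frequencies,
which is what a naive caller produces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .refgen import ReferenceUnit

_STATES = ["A", "C", "G", "T", "del"]


@dataclass
class PileupColumn:
    pos: int
    ref: str
    counts: dict[str, int]

    @property
    def coverage(self) -> int:
        return sum(self.counts.values())

    @property
    def nonref(self) -> int:
        return self.coverage - self.counts.get(self.ref, 0)


def tally(
    source,
    unit: ReferenceUnit,
    min_base_quality: int = 0,
) -> list[PileupColumn]:
    """Per-position base counts over the unit.

    ``source`` is either a path to a SAM file of reads mapped to the unit,
    or a simulated pileup DataFrame (columns pos, ref, A, C, G, T, del).
    ``min_base_quality`` optionally drops low-quality base calls (default
    off — a naive tally counts everything).  Counts at each position sum to
    that position's coverage by construction.
    """
    if isinstance(source, pd.DataFrame):
        cols = {s: source[s].to_numpy() for s in _STATES}
        positions = source["pos"].to_numpy()
        refs = source["ref"].to_numpy()
        return [
            PileupColumn(
                pos=int(positions[i]),
                ref=str(refs[i]),
                counts={s: int(cols[s][i]) for s in _STATES},
            )
            for i in range(len(source))
        ]
    return _tally_sam(source, unit, min_base_quality)


def _tally_sam(path, unit: ReferenceUnit, min_base_quality: int) -> list[PileupColumn]:
    L = len(unit)
    counts = np.zeros((L, 5), dtype=int)
    idx = {b: i for i, b in enumerate("ACGT")}
    n_skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.query_sequence is None:
                continue
            if seg.reference_start >= L:
                n_skipped += 1
                continue
            quals = seg.query_qualities
            for qpos, rpos in seg.get_aligned_pairs():
                if rpos is None or rpos >= L:
                    continue
                if qpos is None:
                    counts[rpos, 4] += 1  # deletion in the read
                    continue
                if quals is not None and quals[qpos] < min_base_quality:
                    continue
                b = seg.query_sequence[qpos].upper()
                if b in idx:
                    counts[rpos, idx[b]] += 1
    return [
        PileupColumn(pos=i, ref=unit.sequence[i], counts={s: int(counts[i, j]) for j, s in enumerate(_STATES)})
        for i in range(L)
    ]


def columns_to_frame(columns: list[PileupColumn]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"pos": c.pos, "ref": c.ref, **{s: c.counts[s] for s in _STATES}}
            for c in columns
        ]
    )


@dataclass
class VariantSpectrum:
    """Per-position non-reference allele frequencies over the unit.

    Positions with coverage below the floor are NaN (missing, not zero).
    """

    pos: np.ndarray
    ref: np.ndarray
    coverage: np.ndarray
    freq: np.ndarray

    @property
    def mean_freq(self) -> float:
        covered = self.freq[~np.isnan(self.freq)]
        return float(covered.mean()) if covered.size else float("nan")

    def n_above(self, floor: float) -> int:
        return int(np.nansum(self.freq > floor))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pos": self.pos, "ref": self.ref, "coverage": self.coverage, "freq": self.freq}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "VariantSpectrum":
        df = pd.read_csv(path, sep="\t", keep_default_na=True, dtype={"ref": str})
        return cls(
            pos=df["pos"].to_numpy(),
            ref=df["ref"].to_numpy(),
            coverage=df["coverage"].to_numpy(),
            freq=df["freq"].to_numpy(),
        )


def frequencies(columns: list[PileupColumn], min_coverage: int = 1) -> VariantSpectrum:
    """Non-reference frequency per position: (coverage - ref count)/coverage."""
    pos = np.array([c.pos for c in columns])
    ref = np.array([c.ref for c in columns])
    cov = np.array([c.coverage for c in columns], dtype=float)
    nonref = np.array([c.nonref for c in columns], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(cov >= max(min_coverage, 1), nonref / cov, np.nan)
    return VariantSpectrum(pos=pos, ref=ref, coverage=cov, freq=freq)


@dataclass
class SpectrumComparison:
    """Paired comparison of two spectra over jointly covered positions.

    ``mean_diff`` is mean(freq_b − freq_a); the bootstrap interval
    resamples positions.  ``n_exceeding`` counts positions where
    |freq_b − freq_a| exceeds the reporting floor.
    """

    n_positions: int
    mean_diff: float
    ci_low: float
    ci_high: float
    n_exceeding: int
    exceeding_pos: list[int]

    def to_dict(self) -> dict:
        return {
            "n_positions": self.n_positions,
            "mean_diff": self.mean_diff,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_exceeding": self.n_exceeding,
            "exceeding_pos": self.exceeding_pos,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def compare_spectra(
    a: VariantSpectrum,
    b: VariantSpectrum,
    n_boot: int = 1000,
    ci: float = 0.95,
    floor: float = 0.05,
    seed: int = 0,
) -> SpectrumComparison:
    """Per-position frequency differences (b − a) with a position bootstrap.

    Only positions covered in both spectra enter; the comparison is
    antisymmetric (swapping a and b flips the sign of the mean difference).
    """
    if a.pos.size != b.pos.size or np.any(a.pos != b.pos):
        raise ValueError("spectra must cover the same unit coordinates")
    joint = ~np.isnan(a.freq) & ~np.isnan(b.freq)
    diff = (b.freq - a.freq)[joint]
    pos = a.pos[joint]
    if diff.size == 0:
        return SpectrumComparison(0, float("nan"), float("nan"), float("nan"), 0, [])
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    n = diff.size
    for i in range(n_boot):
        boot[i] = diff[rng.integers(0, n, size=n)].mean()
    alpha = (1 - ci) / 2
    lo, hi = np.quantile(boot, [alpha, 1 - alpha])
    exceed = np.abs(diff) > floor
    return SpectrumComparison(
        n_positions=int(n),
        mean_diff=float(diff.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_exceeding=int(exceed.sum()),
        exceeding_pos=[int(p) for p in pos[exceed]],
    )
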