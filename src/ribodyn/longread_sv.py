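"""Bin-split structural-variant detection over a tandem-repeat unit.

Long reads from a tandem array are quality-filtered (length > 8000 nt,
mean Phred > 18, both strict), split into 300-nt bins, and each bin is
mapped independently to the single repeat unit treated as circular.  In an
intact array, consecutive bins land 300 nt apart on the unit (modulo the
unit length — crossing a unit junction is the common case and is
deviation-free by construction).  A structural variant inside the read
shifts that spacing: if the observed inter-bin reference distance deviates
from the expected one by more than 100 nt, a call is emitted — a deletion
when the observed distance is too large, an insertion/duplication when too
small.  Downstream summaries focus on deletions of at least 50 nt;
insertion calls are reported but excluded from headline rates, since they
are harder to distinguish from sequencing error.

The internal mapper is deliberately minimal (exact k-mer seeding plus
Hamming verification on the circularly extended unit); pre-computed
external mappings can be supplied as SAM or PAF instead.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .refgen import LongRead, ReferenceUnit, SimParams, revcomp

_BIN_RE = re.compile(r"^(?P<read>.+):bin(?P<idx>\d+)$")


@dataclass
class QCResult:
    passed: bool
    reason: str = ""


def qc_filter(read: LongRead, params: SimParams, quality_domain: str = "phred") -> QCResult:
    """Strict length/quality filter.

    Pass iff length > ``min_read_len`` AND mean quality > ``min_mean_q``
    (both strict, so a read of exactly 8000 nt or mean Q exactly 18 fails).
    ``quality_domain='phred'`` averages Phred scores arithmetically (the
    usual basecaller summary); ``'error_prob'`` averages error
    probabilities and converts back.
    """
    if len(read.sequence) == 0:
        return QCResult(False, "empty")
    if not len(read.sequence) > params.min_read_len:
        return QCResult(False, "short")
    if quality_domain == "phred":
        mean_q = read.mean_q
    elif quality_domain == "error_prob":
        mean_q = -10.0 * np.log10(np.mean(10.0 ** (-read.qualities / 10.0)))
    else:
        raise ValueError("quality_domain must be 'phred' or 'error_prob'")
    if not mean_q > params.min_mean_q:
        return QCResult(False, "low_quality")
    return QCResult(True, "")


def split_bins(read: LongRead | str, bin_len: int = 300) -> list[str]:
    """Cut a read into consecutive ``bin_len``-nt bins; the short tail is
    discarded, so exactly floor(len/bin_len) bins are returned."""
    seq = read if isinstance(read, str) else read.sequence
    n = len(seq) // bin_len
    return [seq[i * bin_len : (i + 1) * bin_len] for i in range(n)]


@dataclass
class BinAlignment:
    """One read bin placed on the (circular) unit.

    ``unit_pos`` is the bin's start in forward unit coordinates; for
    reverse-strand hits the position is reflected (L - bin_len - p mod L)
    so that consecutive bins of a reverse-strand read still advance by
    +bin_len along the unit.
    """

    bin_index: int
    read_offset: int
    unit_pos: int
    strand: str
    mismatches: int
    mapped: bool


class UnitIndex:
    """Exact k-mer index of the unit extended circularly by one bin length."""

    def __init__(self, unit: ReferenceUnit, k: int = 15, bin_len: int = 300):
        self.unit = unit
        self.k = k
        self.bin_len = bin_len
        self.L = len(unit)
        ext = unit.sequence + unit.sequence[: bin_len]
        self.ext = ext
        self.ext_arr = np.frombuffer(ext.encode(), dtype="S1")
        kmap: dict[str, list[int]] = {}
        for p in range(self.L):
            kmap.setdefault(ext[p : p + k], []).append(p)
        self.kmap = kmap

    def _candidates(self, q: str) -> list[int]:
        cands = set()
        for o in range(0, len(q) - self.k + 1):
            for p in self.kmap.get(q[o : o + self.k], ()):
                cands.add((p - o) % self.L)
        return sorted(cands)

    def _verify(self, q_arr: np.ndarray, offset: int) -> int:
        return int(np.count_nonzero(self.ext_arr[offset : offset + len(q_arr)] != q_arr))


def map_bin(
    bin_seq: str,
    index: UnitIndex | ReferenceUnit,
    bin_index: int = 0,
    max_mismatch: int = 60,
    k: int = 15,
) -> BinAlignment:
    """Seed-and-verify placement of one bin on the circular unit.

    Exact k-mer seeds from the bin vote for candidate offsets; each
    candidate is verified by Hamming distance over the wrapped window.
    Fewest mismatches wins; ties break to the lowest offset within a
    strand, and to the forward strand between strands.  A bin with no
    candidate within ``max_mismatch`` is returned unmapped.
    """
    if isinstance(index, ReferenceUnit):
        index = UnitIndex(index, k=k, bin_len=len(bin_seq))
    bin_len = len(bin_seq)
    best: tuple[int, int, int] | None = None  # (mismatches, strand_rank, offset)
    for strand_rank, strand in enumerate("+-"):
        q = bin_seq if strand == "+" else revcomp(bin_seq)
        q_arr = np.frombuffer(q.encode(), dtype="S1")
        for c in index._candidates(q):
            mm = index._verify(q_arr, c)
            if mm <= max_mismatch:
                cand = (mm, strand_rank, c)
                if best is None or cand < best:
                    best = cand
    if best is None:
        return BinAlignment(bin_index, bin_index * bin_len, -1, ".", -1, mapped=False)
    mm, strand_rank, c = best
    strand = "+-"[strand_rank]
    pos = c if strand == "+" else (index.L - bin_len - c) % index.L
    return BinAlignment(bin_index, bin_index * bin_len, pos, strand, mm, mapped=True)


def map_read_bins(
    read: LongRead,
    index: UnitIndex,
    max_mismatch: int = 60,
) -> list[BinAlignment]:
    """Split a read and map every bin (unmapped bins retained, flagged)."""
    return [
        map_bin(b, index, bin_index=i, max_mismatch=max_mismatch)
        for i, b in enumerate(split_bins(read, index.bin_len))
    ]


@dataclass
class SVCall:
    read_id: str
    bin_i: int
    bin_j: int
    observed: int
    expected: int
    deviation: int
    type: str  # "deletion" | "insertion"
    size: int


@dataclass
class ReadSVResult:
    read_id: str
    calls: list[SVCall]
    informative: bool          # False when < 2 mapped bins
    n_inversion_pairs: int = 0  # mixed-strand consecutive pairs (excluded)


def call_read_sv(
    alignments: list[BinAlignment],
    params: SimParams,
    read_id: str = "",
    unit_len: int | None = None,
) -> ReadSVResult:
    """Deviation rule over consecutive mapped bins.

    For consecutive mapped bins i < j (skipping unmapped bins in between),
    expected distance = (j - i) × bin_len; the observed distance is the
    representative of (pos_j - pos_i) mod L_unit nearest the expected value,
    so that unit-junction crossings are deviation-free while signed
    deviations survive.  A call is emitted iff |observed - expected|
    strictly exceeds ``dev_tol``: positive deviations are deletions,
    negative ones insertions/duplications.  Mixed-strand pairs are
    inversion-like and excluded from the rule.
    """
    mapped = sorted((a for a in alignments if a.mapped), key=lambda a: a.bin_index)
    if len(mapped) < 2:
        return ReadSVResult(read_id, [], informative=False)
    L = unit_len if unit_len is not None else params.unit_bp
    calls: list[SVCall] = []
    n_inv = 0
    for a, b in zip(mapped, mapped[1:]):
        if a.strand != b.strand:
            n_inv += 1
            continue
        expected = (b.bin_index - a.bin_index) * params.bin_len
        raw = (b.unit_pos - a.unit_pos) % L
        m = round((expected - raw) / L)
        observed = raw + m * L
        deviation = observed - expected
        if abs(deviation) > params.dev_tol:
            calls.append(
                SVCall(
                    read_id=read_id,
                    bin_i=a.bin_index,
                    bin_j=b.bin_index,
                    observed=observed,
                    expected=expected,
                    deviation=deviation,
                    type="deletion" if deviation > 0 else "insertion",
                    size=abs(deviation),
                )
            )
    return ReadSVResult(read_id, calls, informative=True, n_inversion_pairs=n_inv)


# ---------------------------------------------------------------------------
# SAM / PAF import & export of per-bin alignments


def write_sam(per_read: dict[str, list[BinAlignment]], reads: dict[str, LongRead],
              unit: ReferenceUnit, params: SimParams, path) -> None:
    """Write per-bin alignments as SAM records named ``<read>:bin<i>``.

    The reference is declared one bin longer than the unit so that
    origin-wrapping bins fit on a linear coordinate; import folds positions
    back modulo the unit length.
    """
    L = len(unit)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": unit.id, "LN": L + params.bin_len}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read_id, alns in per_read.items():
            bins = split_bins(reads[read_id], params.bin_len)
            for a in alns:
                if not a.mapped:
                    continue
                seg = pysam.AlignedSegment(out.header)
                seg.query_name = f"{read_id}:bin{a.bin_index}"
                seg.reference_id = 0
                seg.is_reverse = a.strand == "-"
                fwd = a.unit_pos if a.strand == "+" else (L - params.bin_len - a.unit_pos) % L
                seg.reference_start = fwd
                b = bins[a.bin_index]
                seg.query_sequence = b if a.strand == "+" else revcomp(b)
                seg.cigarstring = f"{params.bin_len}M"
                seg.mapping_quality = 60
                seg.set_tag("NM", a.mismatches)
                out.write(seg)


def bin_alignments_from_sam(path, unit: ReferenceUnit, params: SimParams
                            ) -> dict[str, list[BinAlignment]]:
    """Read pre-mapped 300-nt bins from SAM (1-based, per the SAM spec)."""
    L = len(unit)
    out: dict[str, list[BinAlignment]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            m = _BIN_RE.match(seg.query_name)
            if not m:
                raise ValueError(f"query name {seg.query_name!r} lacks ':bin<i>' suffix")
            read_id, idx = m.group("read"), int(m.group("idx"))
            fwd = seg.reference_start % L
            strand = "-" if seg.is_reverse else "+"
            pos = fwd if strand == "+" else (L - params.bin_len - fwd) % L
            nm = seg.get_tag("NM") if seg.has_tag("NM") else 0
            out.setdefault(read_id, []).append(
                BinAlignment(idx, idx * params.bin_len, pos, strand, int(nm), mapped=True)
            )
    for alns in out.values():
        alns.sort(key=lambda a: a.bin_index)
    return out


def bin_alignments_from_paf(path, unit: ReferenceUnit, params: SimParams
                            ) -> dict[str, list[BinAlignment]]:
    """Read pre-mapped bins from PAF (0-based target start, column 8)."""
    L = len(unit)
    out: dict[str, list[BinAlignment]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            m = _BIN_RE.match(f[0])
            if not m:
                raise ValueError(f"query name {f[0]!r} lacks ':bin<i>' suffix")
            read_id, idx = m.group("read"), int(m.group("idx"))
            strand = f[4]
            fwd = int(f[7]) % L
            pos = fwd if strand == "+" else (L - params.bin_len - fwd) % L
            nm = max(0, int(f[10]) - int(f[9]))  # alignment block len - matches
            out.setdefault(read_id, []).append(
                BinAlignment(idx, idx * params.bin_len, pos, strand, nm, mapped=True)
            )
    for alns in out.values():
        alns.sort(key=lambda a: a.bin_index)
    return out


def write_paf(per_read: dict[str, list[BinAlignment]], reads: dict[str, LongRead],
              unit: ReferenceUnit, params: SimParams, path) -> None:
    L = len(unit)
    bl = params.bin_len
    with open(path, "w") as fh:
        for read_id, alns in per_read.items():
            qlen = len(reads[read_id].sequence)
            for a in alns:
                if not a.mapped:
                    continue
                fwd = a.unit_pos if a.strand == "+" else (L - bl - a.unit_pos) % L
                fh.write(
                    "\t".join(
                        map(
                            str,
                            [
                                f"{read_id}:bin{a.bin_index}", qlen,
                                a.read_offset, a.read_offset + bl, a.strand,
                                unit.id, L + bl, fwd, fwd + bl,
                                bl - a.mismatches, bl, 60,
                            ],
                        )
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# sample-level summary


@dataclass
class SVSampleSummary:
    """Filter-chain tallies for one sample.

    Counts are weakly decreasing along the chain: reads in → QC pass →
    analyzable (≥ 2 mapped bins, i.e. attributable to the repeat unit) →
    reads carrying at least one SV call.
    """

    n_input: int
    n_pass_qc: int
    n_analyzed: int
    n_sv_reads: int
    sv_read_fraction: float
    n_deletion_reads: int
    deletion_read_fraction: float
    calls: list[SVCall] = field(default_factory=list)
    deletion_calls: list[SVCall] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_pass_qc": self.n_pass_qc,
            "n_analyzed": self.n_analyzed,
            "n_sv_reads": self.n_sv_reads,
            "sv_read_fraction": self.sv_read_fraction,
            "n_deletion_reads": self.n_deletion_reads,
            "deletion_read_fraction": self.deletion_read_fraction,
            "n_calls": len(self.calls),
            "n_deletion_calls": len(self.deletion_calls),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def calls_to_frame(calls: list[SVCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.read_id, c.bin_i, c.bin_j, c.observed, c.expected, c.deviation, c.type, c.size)
            for c in calls
        ],
        columns=["read_id", "bin_i", "bin_j", "observed", "expected", "deviation", "type", "size"],
    )


def summarize_sample(
    reads: list[LongRead] | None,
    unit: ReferenceUnit,
    params: SimParams | None = None,
    alignments: dict[str, list[BinAlignment]] | None = None,
    max_mismatch: int = 60,
    k: int = 15,
) -> SVSampleSummary:
    """Full chain: QC → bin split → map → deviation calls → tallies.

    When ``alignments`` (from SAM/PAF import) is given, QC and mapping are
    assumed to have been performed upstream and the chain starts at the
    calling step.  Headline deletion rates count reads with at least one
    deletion call of size ≥ ``min_del``; insertion calls are retained in
    ``calls`` but excluded from the headline fraction.
    """
    params = params or SimParams()
    results: list[ReadSVResult] = []
    if alignments is not None:
        n_input = n_pass = len(alignments)
        for read_id, alns in alignments.items():
            results.append(call_read_sv(alns, params, read_id=read_id, unit_len=len(unit)))
    else:
        if reads is None:
            raise ValueError("supply reads or alignments")
        n_input = len(reads)
        index = UnitIndex(unit, k=k, bin_len=params.bin_len)
        passing = [r for r in reads if qc_filter(r, params).passed]
        n_pass = len(passing)
        for r in passing:
            alns = map_read_bins(r, index, max_mismatch=max_mismatch)
            results.append(call_read_sv(alns, params, read_id=r.id, unit_len=len(unit)))
    informative = [r for r in results if r.informative]
    n_analyzed = len(informative)
    all_calls = [c for r in informative for c in r.calls]
    del_calls = [c for c in all_calls if c.type == "deletion" and c.size >= params.min_del]
    sv_reads = {c.read_id for r in informative for c in r.calls}
    del_reads = {c.read_id for c in del_calls}
    return SVSampleSummary(
        n_input=n_input,
        n_pass_qc=n_pass,
        n_analyzed=n_analyzed,
        n_sv_reads=len(sv_reads),
        sv_read_fraction=len(sv_reads) / n_analyzed if n_analyzed else 0.0,
        n_deletion_reads=len(del_reads),
        deletion_read_fraction=len(del_reads) / n_analyzed if n_analyzed else 0.0,
        calls=all_calls,
        deletion_calls=del_calls,
    )
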