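"""Synthetic data generation for rDNA copy-number analyses.

Everything downstream of wet lab is driven from here: a single rDNA repeat
unit with its annotated elements (35S, 5S, rARS, E-pro, RFB), tandem arrays
of that unit with planted SNVs and internal deletions, long reads with
configurable length/quality/error laws, collapsed-unit short-read pileups,
PFGE lane profiles with a marker ladder, DNA-content (flow cytometry)
histograms, and replicate copy-number trajectories whose statistical
structure mirrors a long-term evolution experiment: symmetric,
setpoint-recovering variation when the replication-fork barrier pathway is
intact (WT mode), and suppressed, deletion-biased variation without
recovery when it is absent (fob1Δ mode).

The unit sequence is random uniform ACGT by default — none of the analyses
depend on real sequence content — and a real unit can be supplied via
FASTA.  Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .gel_quant import LaneProfile, MigrationCalibration

logger = logging.getLogger(__name__)

BASES = np.array(["A", "C", "G", "T"])
_BASE_IDX = {b: i for i, b in enumerate(BASES)}

#: Default element layout for a 9.1-kb unit (0-based half-open intervals).
#: Positions are schematic: the 35S gene occupies most of the unit; the
#: intergenic spacer carries 5S, the replication origin (rARS), the
#: non-coding promoter (E-pro) and the replication fork barrier (RFB).
DEFAULT_LAYOUT = {
    "35S": (0, 6600),
    "5S": (6900, 7020),
    "rARS": (7300, 7500),
    "E-pro": (7600, 7750),
    "RFB": (7850, 7950),
}

REQUIRED_ELEMENTS = {"35S", "5S", "rARS", "E-pro", "RFB"}


class LayoutError(ValueError):
    """Element intervals overlap or extend beyond the unit."""


class EditError(ValueError):
    """A planted SNV or deletion does not fit its addressed copy."""


@dataclass
class SimParams:
    """All numeric knobs of the simulation and the analysis filters.

    QC / SV-calling thresholds (strict inequalities throughout):
      min_read_len  — reads longer than this pass QC (nt)
      min_mean_q    — mean Phred above this passes QC
      bin_len       — long reads are split into bins of this many nt
      dev_tol       — inter-bin reference-distance deviation above this is an SV (nt)
      min_del       — headline summaries count deletions of at least this size (nt)

    Gel geometry:
      unit_kb       — length of one rDNA repeat unit (kb)
      backbone_kb   — non-rDNA length of chromosome XII (kb)

    Trajectory model:
      dilution      — serial-transfer dilution factor (log2 of it = generations/transfer)
      setpoint      — copy number the recovery term pulls the total toward
      recomb_rate   — per-generation event probability at setpoint copies
                      (scaled linearly by current copy count)
      step_sd       — SD of the copy-number change per recombination event
      deletion_bias — mean copies LOST per event in fob1Δ mode (> 0)
      recovery_rate — per-generation recovery-event probability per unit of
                      fractional total-copy deviation from the setpoint (WT only)
      min_viable    — hard floor on copies per chromosome
    """

    min_read_len: int = 8000
    min_mean_q: float = 18.0
    bin_len: int = 300
    dev_tol: int = 100
    min_del: int = 50
    unit_kb: float = 9.1
    backbone_kb: float = 1050.0
    dilution: float = 1000.0
    setpoint: int = 150
    recomb_rate: float = 0.02
    step_sd: float = 6.0
    deletion_bias: float = 3.0
    recovery_rate: float = 0.05
    min_viable: int = 2

    def __post_init__(self) -> None:
        for name in (
            "min_read_len", "min_mean_q", "bin_len", "dev_tol", "min_del",
            "unit_kb", "backbone_kb", "step_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.recomb_rate < 0 or self.recovery_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.dilution <= 1:
            raise ValueError("dilution factor must exceed 1")
        if not (self.setpoint >= self.min_viable >= 1):
            raise ValueError("require setpoint >= min_viable >= 1")

    @property
    def unit_bp(self) -> int:
        return int(round(self.unit_kb * 1000))

    def replace(self, **kw) -> "SimParams":
        return replace(self, **kw)


@dataclass
class ReferenceUnit:
    """One rDNA repeat unit: sequence plus named element intervals."""

    id: str
    sequence: str
    elements: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        L = len(self.sequence)
        ivs = sorted(self.elements.values())
        for (start, end) in ivs:
            if not (0 <= start < end <= L):
                raise LayoutError(f"interval [{start}, {end}) outside unit of length {L}")
        for (_, e0), (s1, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise LayoutError("element intervals overlap")
        missing = REQUIRED_ELEMENTS - set(self.elements)
        if missing:
            raise LayoutError(f"missing elements: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def to_fasta(self, path) -> None:
        desc = ";".join(f"{k}:{s}-{e}" for k, (s, e) in sorted(self.elements.items()))
        SeqIO.write([SeqRecord(Seq(self.sequence), id=self.id, description=desc)], path, "fasta")

    @classmethod
    def from_fasta(cls, path, elements: dict | None = None) -> "ReferenceUnit":
        rec = next(SeqIO.parse(path, "fasta"))
        if elements is None:
            elements = {}
            for tok in rec.description.split(None, 1)[-1].split(";"):
                if ":" in tok:
                    name, iv = tok.rsplit(":", 1)
                    s, e = iv.split("-")
                    elements[name] = (int(s), int(e))
        return cls(id=rec.id, sequence=str(rec.seq).upper(), elements=elements)


def make_reference_unit(
    L_unit: int = 9100,
    element_layout: dict[str, tuple[int, int]] | None = None,
    seed: int = 0,
) -> ReferenceUnit:
    """Random-sequence repeat unit with the standard element annotation."""
    layout = dict(DEFAULT_LAYOUT if element_layout is None else element_layout)
    rng = np.random.default_rng(seed)
    seq = "".join(BASES[rng.integers(0, 4, size=L_unit)])
    return ReferenceUnit(id=f"rDNA_unit_L{L_unit}", sequence=seq, elements=layout)


@dataclass
class CopyEdits:
    """Edits carried by one copy of the array: SNVs and internal deletions."""

    snvs: list[tuple[int, str]] = field(default_factory=list)  # (unit pos, alt base)
    deletions: list[tuple[int, int]] = field(default_factory=list)  # [start, end)


@dataclass
class TandemArray:
    """Ground-truth genome: left arm + n_c edited unit copies + right arm."""

    unit_ref: ReferenceUnit
    copies: list[CopyEdits]
    left_arm: str
    right_arm: str

    @property
    def n_c(self) -> int:
        return len(self.copies)

    def copy_length(self, i: int) -> int:
        return len(self.unit_ref) - sum(e - s for s, e in self.copies[i].deletions)

    def __len__(self) -> int:
        return (
            len(self.left_arm)
            + len(self.right_arm)
            + sum(self.copy_length(i) for i in range(self.n_c))
        )

    def copy_sequence(self, i: int) -> str:
        seq = list(self.unit_ref.sequence)
        for pos, alt in self.copies[i].snvs:
            seq[pos] = alt
        keep = np.ones(len(seq), dtype=bool)
        for s, e in self.copies[i].deletions:
            keep[s:e] = False
        return "".join(c for c, k in zip(seq, keep) if k)

    @property
    def sequence(self) -> str:
        if not hasattr(self, "_seq"):
            parts = [self.left_arm]
            parts += [self.copy_sequence(i) for i in range(self.n_c)]
            parts.append(self.right_arm)
            self._seq = "".join(parts)
        return self._seq

    def copy_start(self, i: int) -> int:
        """Array coordinate at which copy ``i`` begins."""
        return len(self.left_arm) + sum(self.copy_length(j) for j in range(i))

    def deletion_junctions(self) -> list[tuple[int, int]]:
        """(array position of each deletion junction, deleted length)."""
        out = []
        for i, edits in enumerate(self.copies):
            start = self.copy_start(i)
            for s, e in sorted(edits.deletions):
                # junction sits where the deleted interval collapsed; earlier
                # deletions in the same copy shift coordinates leftward
                shift = sum(e0 - s0 for s0, e0 in edits.deletions if e0 <= s)
                out.append((start + s - shift, e - s))
        return sorted(out)

    def to_fasta(self, path, id: str = "array") -> None:
        SeqIO.write([SeqRecord(Seq(self.sequence), id=id, description="")], path, "fasta")


def build_array(
    unit: ReferenceUnit,
    n_c: int,
    snvs: list[tuple[int, int, str]] | None = None,       # (copy index, pos, alt)
    deletions: list[tuple[int, int, int]] | None = None,  # (copy index, start, end)
    arms: tuple[str, str] | None = None,
    arm_len: int = 1000,
    seed: int = 0,
) -> TandemArray:
    """Assemble a tandem array with planted per-copy edits.

    Arms default to random non-repetitive flanks of ``arm_len`` bp each.
    Every edit must address an existing copy and lie inside the unit.
    """
    if n_c < 1:
        raise ValueError("n_c must be >= 1")
    L = len(unit)
    copies = [CopyEdits() for _ in range(n_c)]
    for ci, pos, alt in snvs or []:
        if not (0 <= ci < n_c):
            raise EditError(f"SNV addressed to copy {ci} of a {n_c}-copy array")
        if not (0 <= pos < L):
            raise EditError(f"SNV position {pos} outside unit of length {L}")
        alt = alt.upper()
        if alt not in _BASE_IDX:
            raise EditError(f"invalid alt base {alt!r}")
        copies[ci].snvs.append((pos, alt))
    for ci, s, e in deletions or []:
        if not (0 <= ci < n_c):
            raise EditError(f"deletion addressed to copy {ci} of a {n_c}-copy array")
        if not (0 <= s < e <= L):
            raise EditError(f"deletion [{s}, {e}) outside unit of length {L}")
        copies[ci].deletions.append((s, e))
    for ci, ce in enumerate(copies):
        ivs = sorted(ce.deletions)
        for (_, e0), (s1, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise EditError(f"overlapping deletions in copy {ci}")
    if arms is None:
        # distinct stream from make_reference_unit so that arms never
        # duplicate unit sequence when the same seed is reused
        rng = np.random.default_rng([seed, 1])
        arms = (
            "".join(BASES[rng.integers(0, 4, size=arm_len)]),
            "".join(BASES[rng.integers(0, 4, size=arm_len)]),
        )
    return TandemArray(unit_ref=unit, copies=copies, left_arm=arms[0], right_arm=arms[1])


# ---------------------------------------------------------------------------
# long reads


@dataclass
class ReadTruth:
    """Provenance of a simulated read (simulation only)."""

    start: int          # array coordinate of the read's first base
    end: int            # half-open end on the array
    strand: str         # '+' or '-'
    svs: list[tuple[int, int]]  # (junction array position, deleted length) spanned


@dataclass
class LongRead:
    id: str
    sequence: str
    qualities: np.ndarray  # per-base Phred, ints in [0, 60]
    truth: ReadTruth | None = None

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=int)
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities must have equal length")
        if self.qualities.size and (self.qualities.min() < 0 or self.qualities.max() > 60):
            raise ValueError("Phred scores must lie in [0, 60]")

    @property
    def mean_q(self) -> float:
        return float(self.qualities.mean()) if self.qualities.size else 0.0


DEFAULT_LENGTH_LAW = {"law": "lognormal", "mean_log": 9.2, "sd_log": 0.55,
                      "min": 1000, "max": 50000}
DEFAULT_Q_LAW = {"mean": 22.0, "sd": 4.0, "base_sd": 3.0}

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _draw_lengths(law: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = law.get("law", "lognormal")
    if kind == "lognormal":
        x = rng.lognormal(law["mean_log"], law["sd_log"], size=n)
    elif kind == "fixed":
        x = np.full(n, float(law["length"]))
    elif kind == "uniform":
        x = rng.uniform(law["min"], law["max"], size=n)
    else:
        raise ValueError(f"unknown length law {kind!r}")
    return np.clip(x, law.get("min", 1), law.get("max", np.inf)).astype(int)


def simulate_long_reads(
    array: TandemArray,
    n_reads: int = 100,
    length_law: dict | None = None,
    error_rate: float = 0.0,
    q_law: dict | None = None,
    seed: int = 0,
    rc_fraction: float = 0.5,
) -> list[LongRead]:
    """Draw reads from the array with substitution errors and Phred scores.

    Read starts are uniform over the array; lengths follow ``length_law``
    (log-normal by default, producing reads on both sides of the QC length
    filter).  Reads running past the array end are truncated (logged).
    Each read records its true origin interval and the planted deletion
    junctions it spans.
    """
    if not (0.0 <= error_rate <= 0.3):
        raise ValueError("error_rate must lie in [0, 0.3]")
    length_law = length_law or DEFAULT_LENGTH_LAW
    q_law = q_law or DEFAULT_Q_LAW
    rng = np.random.default_rng(seed)
    genome = np.frombuffer(array.sequence.encode(), dtype="S1")
    G = len(genome)
    junctions = array.deletion_junctions()
    lengths = _draw_lengths(length_law, n_reads, rng)
    starts = rng.integers(0, G, size=n_reads)
    n_trunc = 0
    reads = []
    for r in range(n_reads):
        start, length = int(starts[r]), int(lengths[r])
        end = start + length
        if end > G:
            end = G
            n_trunc += 1
        seq = genome[start:end].astype("U1")
        n = end - start
        if error_rate > 0:
            errs = np.nonzero(rng.random(n) < error_rate)[0]
            for i in errs:
                alts = [b for b in BASES if b != seq[i]]
                seq[i] = alts[rng.integers(0, 3)]
        mean_q = rng.normal(q_law["mean"], q_law["sd"])
        quals = np.clip(
            np.rint(rng.normal(mean_q, q_law.get("base_sd", 3.0), size=n)), 0, 60
        ).astype(int)
        svs = [(p, d) for p, d in junctions if start < p < end]
        strand = "-" if rng.random() < rc_fraction else "+"
        s = "".join(seq)
        if strand == "-":
            s = revcomp(s)
            quals = quals[::-1]
        reads.append(
            LongRead(
                id=f"read_{r:05d}",
                sequence=s,
                qualities=quals,
                truth=ReadTruth(start=start, end=end, strand=strand, svs=svs),
            )
        )
    if n_trunc:
        logger.info("%d/%d reads truncated at the array end", n_trunc, n_reads)
    return reads


def write_fastq(reads: list[LongRead], path) -> None:
    """Sanger-encoded FASTQ (Phred+33)."""
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def read_fastq(path) -> list[LongRead]:
    reads = []
    for rec in SeqIO.parse(path, "fastq"):
        reads.append(
            LongRead(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=np.array(rec.letter_annotations["phred_quality"]),
            )
        )
    return reads


# ---------------------------------------------------------------------------
# short-read pileup


def simulate_pileup(
    array: TandemArray,
    coverage: int = 1000,
    error_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Collapsed-unit pileup: all array copies pile onto one unit coordinate.

    At each unit position the read pool mixes the n_c copies equally, so a
    variant carried by k copies appears at frequency k/n_c (the detection
    geometry of population sequencing of a tandem array).  Sequencing error
    redistributes a fraction ``error_rate`` of calls uniformly over the
    three other bases.  Columns: pos, ref, A, C, G, T, del; counts at every
    position sum to ``coverage``.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    unit = array.unit_ref
    L = len(unit)
    ref_idx = np.array([_BASE_IDX[b] for b in unit.sequence])
    # per-position probabilities over states A, C, G, T, del
    probs = np.zeros((L, 5))
    n_c = array.n_c
    for edits in array.copies:
        base = ref_idx.copy()
        for pos, alt in edits.snvs:
            base[pos] = _BASE_IDX[alt]
        deleted = np.zeros(L, dtype=bool)
        for s, e in edits.deletions:
            deleted[s:e] = True
        w = 1.0 / n_c
        rows = np.arange(L)
        probs[rows[~deleted], base[~deleted]] += w
        probs[rows[deleted], 4] += w
    if error_rate > 0:
        # substitution error only affects base calls, not deleted positions:
        # a true base is read as each of the other three w.p. error_rate/3
        new = np.zeros((L, 4))
        for b in range(4):
            new[:, b] += probs[:, b] * (1 - error_rate)
            for o in range(4):
                if o != b:
                    new[:, o] += probs[:, b] * error_rate / 3.0
        probs = np.column_stack([new, probs[:, 4]])
    probs /= probs.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(coverage, probs[i]) for i in range(L)])
    return pd.DataFrame(
        {
            "pos": np.arange(L),
            "ref": list(unit.sequence),
            "A": counts[:, 0],
            "C": counts[:, 1],
            "G": counts[:, 2],
            "T": counts[:, 3],
            "del": counts[:, 4],
        }
    )


def write_pileup(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_pileup(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       dtype={"ref": str})


# ---------------------------------------------------------------------------
# gel lanes


def simulate_gel_lanes(
    samples: list[dict],
    truth_calibration: MigrationCalibration,
    params: SimParams | None = None,
    band_width: float = 0.6,
    noise_sd: float = 0.0,
    grid_step: float = 0.02,
    seed: int = 0,
    extra_bands: list[dict] | None = None,
) -> tuple[LaneProfile, list[LaneProfile]]:
    """Marker lane plus one lane per sample.

    Each sample is ``{"label": str, "copies": array-like of copy numbers
    [, "weights": array-like]}``; its lane is a non-negative mixture of
    Gaussian bands (SD ``band_width`` mm) centered where the calibration
    places chromosome XII for each copy number, plus half-normal baseline
    noise.  A wide copy distribution therefore smears into a broader band
    than a clonal sample.  ``extra_bands`` (e.g. an ERC band) are
    ``{"size_kb": float, "weight": float}`` added to every sample lane.
    """
    params = params or SimParams()
    rng = np.random.default_rng(seed)
    knots_d = [d for d, _ in truth_calibration.knots]
    lo, hi = min(knots_d), max(knots_d)
    pad = 0.15 * (hi - lo)
    grid = np.arange(lo - pad, hi + pad, grid_step)

    def gaussians(centers, weights):
        out = np.zeros_like(grid)
        for c, w in zip(centers, weights):
            if c < grid[0] or c > grid[-1]:
                logger.warning("band center %.2f mm outside profile support; clipped", c)
            out += w * np.exp(-0.5 * ((grid - c) / band_width) ** 2)
        return out

    marker_sizes = np.array([s for _, s in truth_calibration.knots])
    marker = LaneProfile(
        grid,
        np.clip(
            gaussians(truth_calibration.distance_at(marker_sizes), np.ones(marker_sizes.size))
            + np.abs(rng.normal(0, noise_sd, size=grid.size)),
            0, None,
        ),
        label="marker",
    )
    lanes = []
    for sample in samples:
        copies = np.atleast_1d(np.asarray(sample["copies"], dtype=float))
        if copies.size == 0:
            raise ValueError("sample copy distribution is empty")
        weights = np.asarray(sample.get("weights", np.ones(copies.size)), dtype=float)
        weights = weights / weights.sum()
        sizes = params.backbone_kb + copies * params.unit_kb
        centers = np.atleast_1d(truth_calibration.distance_at(sizes))
        y = gaussians(centers, weights)
        for band in extra_bands or []:
            y += gaussians([truth_calibration.distance_at(band["size_kb"])], [band["weight"]])
        y = np.clip(y + np.abs(rng.normal(0, noise_sd, size=grid.size)), 0, None)
        lanes.append(LaneProfile(grid, y, label=sample.get("label", "")))
    return marker, lanes


# ---------------------------------------------------------------------------
# copy-number trajectories


@dataclass
class CopyTrajectory:
    """Replicate × time-point copy-number matrix (per homolog for diploids).

    ``copies`` has shape (n_replicates, ploidy, n_timepoints); generations
    starts at 0 and is strictly increasing.
    """

    generations: np.ndarray
    copies: np.ndarray
    mode: str  # "WT" or "fob1" (fork-barrier-deficient)
    ploidy: int
    seed: int

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations, dtype=int)
        self.copies = np.asarray(self.copies, dtype=float)
        if self.generations[0] != 0 or np.any(np.diff(self.generations) <= 0):
            raise ValueError("generations must strictly increase from 0")
        if self.copies.ndim != 3 or self.copies.shape[1] != self.ploidy:
            raise ValueError("copies must have shape (replicates, ploidy, timepoints)")

    @property
    def n_replicates(self) -> int:
        return self.copies.shape[0]

    def total(self) -> np.ndarray:
        """Total copies per replicate per time point (summed over homologs)."""
        return self.copies.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in range(self.n_replicates):
            for h in range(self.ploidy):
                for t, g in enumerate(self.generations):
                    recs.append((r, h, int(g), self.copies[r, h, t]))
        return pd.DataFrame(recs, columns=["replicate", "homolog", "generation", "copies"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, mode: str = "", seed: int = 0) -> "CopyTrajectory":
        if "homolog" not in df.columns:
            df = df.assign(homolog=0)
        reps = np.sort(df["replicate"].unique())
        homs = np.sort(df["homolog"].unique())
        gens = np.sort(df["generation"].unique())
        wide = df.set_index(["replicate", "homolog", "generation"])["copies"]
        copies = np.array(
            [[[wide[r, h, g] for g in gens] for h in homs] for r in reps]
        )
        return cls(generations=gens, copies=copies, mode=mode, ploidy=len(homs), seed=seed)

    @classmethod
    def from_tsv(cls, path, mode: str = "") -> "CopyTrajectory":
        return cls.from_frame(pd.read_csv(path, sep="\t"), mode=mode)


def simulate_trajectory(
    params: SimParams | None = None,
    mode: str = "WT",
    ploidy: int = 1,
    n_replicates: int = 24,
    n_generations: int = 900,
    record_every: int = 100,
    start_copies: list[int] | int | None = None,
    seed: int = 0,
) -> CopyTrajectory:
    """Copy-count-scaled random walk with optional setpoint recovery.

    Per generation and per chromosome, a recombination event fires with
    probability ``recomb_rate × copies/setpoint`` (more repeats, more
    recombination substrate).  In WT mode the event step is symmetric
    Normal(0, step_sd) and an additional recovery term — a restoring step
    whose probability scales with the *total* deviation from
    ``ploidy × setpoint``, applied to a homolog chosen in proportion to
    its copy count — models fork-barrier-dependent copy-number
    restoration based on total copy number.  In fob1 mode steps are
    deletion-biased
    (Normal(-deletion_bias, step_sd)) and there is no recovery.  Copies
    never fall below ``min_viable``.
    """
    params = params or SimParams()
    if mode not in ("WT", "fob1"):
        raise ValueError("mode must be 'WT' or 'fob1'")
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    rng = np.random.default_rng(seed)
    if start_copies is None:
        start = np.full(ploidy, float(params.setpoint))
    else:
        start = np.atleast_1d(np.asarray(start_copies, dtype=float))
        if start.size != ploidy:
            raise ValueError("start_copies must supply one value per homolog")
    state = np.tile(start, (n_replicates, 1))  # (reps, ploidy)
    rec_gens = [0]
    records = [state.copy()]
    target_total = params.setpoint * ploidy
    for g in range(1, n_generations + 1):
        p_event = np.clip(params.recomb_rate * state / params.setpoint, 0, 1)
        fire = rng.random(state.shape) < p_event
        if mode == "WT":
            steps = rng.normal(0.0, params.step_sd, size=state.shape)
        else:
            steps = rng.normal(-params.deletion_bias, params.step_sd, size=state.shape)
        state = state + np.where(fire, steps, 0.0)
        if mode == "WT":
            # restoring force on TOTAL copy number: recombination-mediated
            # amplification below the setpoint, contraction above it; the
            # changing homolog is drawn in proportion to its copy count
            total = state.sum(axis=1)
            excess = total - target_total
            p_rec = np.clip(params.recovery_rate * np.abs(excess) / params.setpoint, 0, 1)
            rec = rng.random(n_replicates) < p_rec
            for r in np.nonzero(rec)[0]:
                w = np.clip(state[r], params.min_viable, None)
                h = rng.choice(ploidy, p=w / w.sum())
                step = np.abs(rng.normal(params.step_sd, params.step_sd))
                state[r, h] -= np.sign(excess[r]) * step
        state = np.clip(state, params.min_viable, None)
        if g % record_every == 0 or g == n_generations:
            rec_gens.append(g)
            records.append(state.copy())
    copies = np.stack(records, axis=-1)  # (reps, ploidy, timepoints)
    return CopyTrajectory(
        generations=np.array(sorted(set(rec_gens))),
        copies=copies,
        mode=mode,
        ploidy=ploidy,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# flow cytometry


@dataclass
class FACSHistogram:
    """DNA-content histogram: fluorescence bin centers and cell counts."""

    fluorescence: np.ndarray
    counts: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(np.diff(self.fluorescence) <= 0):
            raise ValueError("fluorescence bins must strictly increase")
        if self.counts.sum() <= 0:
            raise ValueError("histogram must contain cells")

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"fluorescence": self.fluorescence, "count": self.counts}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, label: str = "") -> "FACSHistogram":
        df = pd.read_csv(path, sep="\t")
        return cls(df["fluorescence"].to_numpy(), df["count"].to_numpy(), label)


UNIT_FLUORESCENCE = 100.0  # arbitrary units per 1C genome content


def simulate_facs(
    ploidy: int = 1,
    n_cells: int = 10_000,
    peak_cv: float = 0.05,
    g1_fraction: float = 0.6,
    n_bins: int = 256,
    seed: int = 0,
) -> FACSHistogram:
    """Two-peak DNA-content histogram (1C and 2C of the given ploidy).

    An asynchronous culture mixes G1 (1C) and G2/M (2C) cells; both peaks
    are Gaussian with coefficient of variation ``peak_cv``.
    """
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    if peak_cv <= 0:
        raise ValueError("peak_cv must be positive")
    rng = np.random.default_rng(seed)
    mode1 = ploidy * UNIT_FLUORESCENCE
    is_g1 = rng.random(n_cells) < g1_fraction
    content = np.where(is_g1, mode1, 2 * mode1)
    signal = rng.normal(content, peak_cv * content)
    edges = np.linspace(0, 5 * UNIT_FLUORESCENCE, n_bins + 1)
    counts, _ = np.histogram(np.clip(signal, edges[0], edges[-1] - 1e-9), bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return FACSHistogram(centers, counts, label=f"{ploidy}n")
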