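import numpy as np
import pytest

from ribodyn import refgen
from ribodyn.gel_quant import MigrationCalibration


@pytest.fixture(scope="session")
def unit():
    return refgen.make_reference_unit(L_unit=9100, seed=1)


@pytest.fixture(scope="session")
def params():
    return refgen.SimParams()


@pytest.fixture(scope="session")
def ladder():
    """Megabase-range calibration spanning the chromosome XII sizes."""
    sizes = np.array([3200, 2700, 2350, 1810, 1660, 1370, 1050, 600, 90], dtype=float)
    distances = np.linspace(12, 70, sizes.size)
    return MigrationCalibration(knots=list(zip(distances, sizes)))


@pytest.fixture(scope="session")
def clean_array(unit):
    """Edit-free 20-copy array (enough copies for reads to stay internal)."""
    return refgen.build_array(unit, n_c=20, seed=2)


def exhaustive_map(bin_seq, unit, max_mismatch=60):
    """Independent mapping oracle: full Hamming scan over every offset of the
    circularly extended unit and both strands, with the same tie-breaks as
    the seeded mapper (fewest mismatches, then forward strand, then lowest
    offset)."""
    from ribodyn.refgen import revcomp

    L = len(unit)
    bl = len(bin_seq)
    ext = np.frombuffer((unit.sequence + unit.sequence[:bl]).encode(), dtype="S1")
    windows = np.lib.stride_tricks.sliding_window_view(ext, bl)[:L]
    best = None
    for strand_rank, strand in enumerate("+-"):
        q = bin_seq if strand == "+" else revcomp(bin_seq)
        q_arr = np.frombuffer(q.encode(), dtype="S1")
        mm = (windows != q_arr).sum(axis=1)
        c = int(np.argmin(mm))
        if mm[c] <= max_mismatch:
            cand = (int(mm[c]), strand_rank, c)
            if best is None or cand < best:
                best = cand
    if best is None:
        return None
    mmc, strand_rank, c = best
    strand = "+-"[strand_rank]
    pos = c if strand == "+" else (L - bl - c) % L
    return (pos, strand, mmc)
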