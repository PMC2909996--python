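"""Shared fixtures and the independent brute-force amplification oracle.

The oracle deliberately re-derives everything from first principles —
its own IUPAC sets, complement map and position-by-position loops — so
that agreement with the vectorized engine is a genuine two-route check.
"""

from __future__ import annotations

import numpy as np
import pytest

# ---------------------------------------------------------------- oracle

ORACLE_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}
_ORACLE_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "R": "Y", "Y": "R",
                "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
                "D": "H", "H": "D", "N": "N"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_ORACLE_COMP[c] for c in reversed(seq))


def oracle_count(primer: str, window: str, max_mm: int, tail: int):
    """Mismatch count of a primer against a primer-oriented window, or
    None when the 3' tail mismatches or the ceiling is exceeded."""
    n = len(primer)
    for i in range(n - tail, n):
        if not (ORACLE_SETS[primer[i]] & ORACLE_SETS[window[i]]):
            return None
    count = sum(1 for i in range(n - tail)
                if not (ORACLE_SETS[primer[i]] & ORACLE_SETS[window[i]]))
    return count if count <= max_mm else None


def oracle_sites(seq: str, primer: str, max_mm: int, tail: int = 2):
    """All (start, strand, mismatches) sites, brute force, both strands."""
    hits = []
    L = len(primer)
    for start in range(len(seq) - L + 1):
        window = seq[start:start + L]
        c = oracle_count(primer, window, max_mm, tail)
        if c is not None:
            hits.append((start, "+", c))
        c = oracle_count(primer, oracle_revcomp(window), max_mm, tail)
        if c is not None:
            hits.append((start, "-", c))
    return hits


def oracle_amplicons(seq: str, fwd: str, rev: str, max_mm: int,
                     min_len: int, max_len: int, tail: int = 2):
    """Brute-force amplicon enumeration in both orientations.

    Returns tuples (strand, span_start, span_end, insert, fwd_mm, rev_mm).
    """
    f_sites = oracle_sites(seq, fwd, max_mm, tail)
    r_sites = oracle_sites(seq, rev, max_mm, tail)
    Lf, Lr = len(fwd), len(rev)
    out = []
    for fs, fstrand, fmm in f_sites:
        for rs, rstrand, rmm in r_sites:
            if fstrand == "+" and rstrand == "-":
                insert = rs - (fs + Lf)
                if insert >= 0 and min_len <= insert <= max_len:
                    out.append(("+", fs, rs + Lr, insert, fmm, rmm))
            elif fstrand == "-" and rstrand == "+":
                insert = fs - (rs + Lr)
                if insert >= 0 and min_len <= insert <= max_len:
                    out.append(("-", rs, fs + Lf, insert, fmm, rmm))
    return sorted(out)


def random_concrete_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def random_primer(rng: np.random.Generator, length: int,
                  degenerate: bool = False) -> str:
    bases = list("ACGT")
    seq = [str(rng.choice(bases)) for _ in range(length)]
    if degenerate:
        n_amb = int(rng.integers(1, 3))
        for i in rng.choice(length - 2, size=n_amb, replace=False):
            seq[int(i)] = str(rng.choice(list("RYSWKMN")))
    return "".join(seq)


# --------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def nn_params():
    from itspcr.thermo import load_nn_params
    return load_nn_params()


@pytest.fixture(scope="session")
def calibrated_model():
    """The shipped model (constants calibrated on the packaged anchors)."""
    from itspcr.thermo import default_model
    return default_model()


@pytest.fixture(scope="session")
def small_db():
    """A small deterministic synthetic database with its truth table."""
    from itspcr.synthetic_data import SimulationConfig, simulate_reference_db
    cfg = SimulationConfig(seed=42, per_group_counts={
        "ascomycete": 12, "basidiomycete": 12, "non_dikarya": 6, "plant": 6})
    return simulate_reference_db(cfg)
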