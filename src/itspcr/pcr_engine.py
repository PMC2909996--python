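"""The in silico PCR core.

Both strands of every record are scanned for primer binding sites under a
per-primer mismatch ceiling. Matching is IUPAC set-intersection
(agrep-style approximate matching), with one hard rule simulating the
chemistry of 3'-OH extension: the last ``protected_tail`` bases (default
2) of each primer must match exactly — a mismatch there rejects the site
at every ceiling rather than counting toward it. A forward site paired
with any downstream reverse site in convergent orientation yields an
amplicon, subject to insert-length bounds.

Site scanning is numpy-vectorized (per-position boolean compatibility
rows accumulated across primer offsets); the test suite checks it against
an independent brute-force enumerator.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple

import numpy as np
import pandas as pd

from ._iupac import COMPAT, encode, iupac_compatible, reverse_complement, validate_iupac
from .refdb_io import AMPLICON_COLUMNS, Group, ReferenceDB, ReferenceRecord

__all__ = [
    "REJECT", "Primer", "PrimerPair", "AmplifyOptions", "Amplicon", "Site",
    "iupac_compatible", "count_mismatches", "scan_sites", "amplify_record",
    "run_insilico_pcr", "load_primer_registry", "get_primer", "PCRResult",
]


class _Reject:
    """Sentinel: site rejected by the protected 3'-tail rule or ceiling."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "REJECT"

    def __bool__(self) -> bool:
        return False


REJECT = _Reject()


@dataclass(frozen=True)
class Primer:
    """A named 5'→3' IUPAC oligonucleotide."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if len(self.sequence) < 8:
            raise ValueError(f"primer {self.name}: length < 8")
        if not validate_iupac(self.sequence):
            raise ValueError(f"primer {self.name}: non-IUPAC characters")

    def __len__(self) -> int:
        return len(self.sequence)


class PrimerPair(NamedTuple):
    fwd: Primer
    rev: Primer


@dataclass(frozen=True)
class AmplifyOptions:
    """Amplification stringency and length bounds.

    ``max_mismatch`` applies independently to each primer. The protected
    3' tail must match exactly regardless of the ceiling. Insert length
    is counted between the two primer 3' ends (primers excluded); the
    default bounds are generous around the typical 450–700 bp span of a
    full fungal ITS region. With ``strict_target_acgt`` an ambiguity code
    in the *target* is only compatible with an identical primer symbol's
    superset — i.e. target non-ACGT bases count as mismatches unless the
    primer base covers every base the target code could be.
    """

    max_mismatch: int = 1
    protected_tail: int = 2
    min_length: int = 20
    max_length: int = 2000
    count_record_once: bool = True
    strict_target_acgt: bool = False

    def __post_init__(self) -> None:
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if self.protected_tail < 0:
            raise ValueError("protected_tail must be >= 0")
        if self.min_length > self.max_length:
            raise ValueError("min_length > max_length")


@dataclass(frozen=True)
class Amplicon:
    """One in silico amplification event on a record.

    ``fwd_start``/``rev_end`` delimit the full amplified span (both
    primer sites included) as 0-based half-open coordinates on the stored
    strand; ``strand`` is the strand carrying the forward-primer match.
    """

    record_id: str
    taxid: int
    group: Group
    strand: str
    fwd_start: int
    rev_end: int
    insert_length: int
    total_length: int
    fwd_mismatches: int
    rev_mismatches: int
    fwd_tm: float = float("nan")
    rev_tm: float = float("nan")

    def as_row(self) -> dict:
        return {
            "record_id": self.record_id, "taxid": self.taxid,
            "group": str(self.group), "strand": self.strand,
            "fwd_start": self.fwd_start, "rev_end": self.rev_end,
            "insert_length": self.insert_length, "total_length": self.total_length,
            "fwd_mismatches": self.fwd_mismatches, "rev_mismatches": self.rev_mismatches,
            "fwd_tm": self.fwd_tm, "rev_tm": self.rev_tm,
        }


class Site(NamedTuple):
    """A primer binding site on the stored strand.

    ``start`` is the leftmost stored-strand coordinate of the site;
    ``strand`` is '+' when the primer reads along the stored strand and
    '-' when it reads along the reverse complement.
    """

    start: int
    strand: str
    mismatches: int


def count_mismatches(primer: Primer | str, window: str,
                     options: AmplifyOptions) -> int | _Reject:
    """Count incompatible positions between a primer and a site window.

    The window must be in primer orientation (position i of the window
    pairs position i of the primer). Any incompatibility within the
    protected 3' tail, or a count above the ceiling, returns REJECT.
    """
    seq = primer.sequence if isinstance(primer, Primer) else primer.upper()
    window = window.upper()
    if len(seq) != len(window):
        raise ValueError("window length must equal primer length")
    n = len(seq)
    tail_start = n - options.protected_tail
    compat = _compatible_strict if options.strict_target_acgt else iupac_compatible
    for i in range(tail_start, n):
        if not compat(seq[i], window[i]):
            return REJECT
    count = 0
    for i in range(tail_start):
        if not compat(seq[i], window[i]):
            count += 1
            if count > options.max_mismatch:
                return REJECT
    return count


def _compatible_strict(primer_base: str, target_base: str) -> bool:
    """Strict semantics: target ambiguity must be fully covered by the primer."""
    from ._iupac import IUPAC_SETS
    return IUPAC_SETS[target_base.upper()] <= IUPAC_SETS[primer_base.upper()]


def _scan_oriented(code: np.ndarray, primer_code: np.ndarray,
                   tail_positions: np.ndarray, options: AmplifyOptions,
                   strict: bool) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized scan of one primer orientation along the coded sequence.

    Returns (positions, mismatch counts) for windows passing tail rule
    and ceiling. ``tail_positions`` are the primer offsets (within the
    oriented pattern) that must match exactly.
    """
    n, L = len(code), len(primer_code)
    if n < L:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    n_win = n - L + 1
    counts = np.zeros(n_win, dtype=np.int16)
    tail_bad = np.zeros(n_win, dtype=bool)
    compat = _STRICT_COMPAT if strict else COMPAT
    tailset = set(tail_positions.tolist())
    for i in range(L):
        incompat = ~compat[primer_code[i], code[i:i + n_win]]
        if i in tailset:
            tail_bad |= incompat
        else:
            counts += incompat
    ok = ~tail_bad & (counts <= options.max_mismatch)
    pos = np.nonzero(ok)[0]
    return pos, counts[pos].astype(int)


def _build_strict_compat() -> np.ndarray:
    from ._iupac import IUPAC_SETS, SYMBOLS
    return np.array([[IUPAC_SETS[b] <= IUPAC_SETS[a] for b in SYMBOLS]
                     for a in SYMBOLS], dtype=bool)


_STRICT_COMPAT = _build_strict_compat()


def scan_sites(record: ReferenceRecord | str, primer: Primer,
               options: AmplifyOptions) -> list[Site]:
    """All primer binding sites on both strands of a record.

    Coordinates are on the stored strand. On the '+' strand the primer
    3' tail is the window's last bases; on the '-' strand the primer is
    matched as its reverse complement, so the tail maps to the window's
    first bases.
    """
    seq = record.sequence if isinstance(record, ReferenceRecord) else record
    code = encode(seq)
    L = len(primer)
    strict = options.strict_target_acgt
    fwd_code = encode(primer.sequence)
    tail_fwd = np.arange(L - options.protected_tail, L)
    pos, counts = _scan_oriented(code, fwd_code, tail_fwd, options, strict)
    sites = [Site(int(p), "+", int(c)) for p, c in zip(pos, counts)]
    rc_code = encode(reverse_complement(primer.sequence))
    tail_rev = np.arange(0, options.protected_tail)
    pos, counts = _scan_oriented(code, rc_code, tail_rev, options, strict)
    sites += [Site(int(p), "-", int(c)) for p, c in zip(pos, counts)]
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def _site_window(seq: str, site: Site, length: int) -> str:
    """Site sequence in primer orientation."""
    text = seq[site.start:site.start + length]
    return text if site.strand == "+" else reverse_complement(text)


def amplify_record(record: ReferenceRecord, pair: PrimerPair | tuple,
                   options: AmplifyOptions, tm_model=None) -> list[Amplicon]:
    """Enumerate amplicons from one record.

    Every forward-primer site is paired with every reverse-primer site in
    convergent orientation (the reverse primer matching as its reverse
    complement on the same strand), on both strands, subject to the
    insert-length bounds. Per-primer Tm is attached when a
    :class:`~itspcr.thermo.TmModel` is supplied.
    """
    fwd, rev = pair
    seq = record.sequence
    fwd_sites = scan_sites(record, fwd, options)
    rev_sites = scan_sites(record, rev, options)
    Lf, Lr = len(fwd), len(rev)
    amplicons: list[Amplicon] = []

    def tm_for(primer: Primer, site: Site, length: int) -> float:
        if tm_model is None:
            return float("nan")
        from .thermo import duplex_tm
        window = reverse_complement(_site_window(seq, site, length))
        return duplex_tm(primer.sequence, window, tm_model)

    # '+' orientation: forward on plus strand, reverse primer's rc downstream
    plus_fwd = [s for s in fwd_sites if s.strand == "+"]
    minus_rev = [s for s in rev_sites if s.strand == "-"]
    for fs in plus_fwd:
        for rs in minus_rev:
            insert = rs.start - (fs.start + Lf)
            if insert < 0 or not (options.min_length <= insert <= options.max_length):
                continue
            amplicons.append(Amplicon(
                record_id=record.id, taxid=record.taxid, group=record.group,
                strand="+", fwd_start=fs.start, rev_end=rs.start + Lr,
                insert_length=insert, total_length=insert + Lf + Lr,
                fwd_mismatches=fs.mismatches, rev_mismatches=rs.mismatches,
                fwd_tm=tm_for(fwd, fs, Lf), rev_tm=tm_for(rev, rs, Lr),
            ))
    # '-' orientation: forward on minus strand, reverse primer upstream on plus
    minus_fwd = [s for s in fwd_sites if s.strand == "-"]
    plus_rev = [s for s in rev_sites if s.strand == "+"]
    for fs in minus_fwd:
        for rs in plus_rev:
            insert = fs.start - (rs.start + Lr)
            if insert < 0 or not (options.min_length <= insert <= options.max_length):
                continue
            amplicons.append(Amplicon(
                record_id=record.id, taxid=record.taxid, group=record.group,
                strand="-", fwd_start=rs.start, rev_end=fs.start + Lf,
                insert_length=insert, total_length=insert + Lf + Lr,
                fwd_mismatches=fs.mismatches, rev_mismatches=rs.mismatches,
                fwd_tm=tm_for(fwd, fs, Lf), rev_tm=tm_for(rev, rs, Lr),
            ))
    amplicons.sort(key=lambda a: (a.fwd_start, a.insert_length, a.strand))
    return amplicons


@dataclass
class PCRResult:
    """Full amplicon list plus the per-record amplified flag."""

    amplicons: list[Amplicon]
    amplified: dict[str, bool]
    options: AmplifyOptions

    @property
    def record_count(self) -> int:
        """Number of records with at least one amplicon (the headline
        'sequences amplified' count when counting each record once)."""
        return sum(self.amplified.values())

    @property
    def amplicon_count(self) -> int:
        return len(self.amplicons)

    def count(self) -> int:
        return self.record_count if self.options.count_record_once else self.amplicon_count

    def to_frame(self) -> pd.DataFrame:
        rows = [a.as_row() for a in self.amplicons]
        frame = pd.DataFrame(rows, columns=AMPLICON_COLUMNS)
        return frame.sort_values(["record_id", "fwd_start", "insert_length"],
                                 kind="mergesort").reset_index(drop=True)


def run_insilico_pcr(db: ReferenceDB, pair: PrimerPair | tuple,
                     options: AmplifyOptions, tm_model=None) -> PCRResult:
    """Amplify every record of a database with one primer pair."""
    amplicons: list[Amplicon] = []
    amplified: dict[str, bool] = {}
    for record in db:
        hits = amplify_record(record, pair, options, tm_model=tm_model)
        amplicons.extend(hits)
        amplified[record.id] = bool(hits)
    amplicons.sort(key=lambda a: (a.record_id, a.fwd_start, a.insert_length))
    return PCRResult(amplicons, amplified, options)


def load_primer_registry() -> dict[str, Primer]:
    """Built-in registry of the nine rDNA/ITS primers shipped as an asset."""
    registry: dict[str, Primer] = {}
    path = resources.files("itspcr.data") / "primers.tsv"
    with path.open() as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("name\t"):
                continue
            name, sequence = line.rstrip("\n").split("\t")[:2]
            registry[name] = Primer(name, sequence)
    return registry


_REGISTRY: dict[str, Primer] | None = None


def get_primer(name_or_sequence: str) -> Primer:
    """Look up a registry primer by name, or wrap a raw sequence."""
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = load_primer_registry()
    if name_or_sequence in _REGISTRY:
        return _REGISTRY[name_or_sequence]
    if validate_iupac(name_or_sequence.upper()) and len(name_or_sequence) >= 8:
        return Primer(name_or_sequence.upper(), name_or_sequence.upper())
    raise KeyError(f"unknown primer {name_or_sequence!r} "
                   f"(registry: {sorted(_REGISTRY)})")
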