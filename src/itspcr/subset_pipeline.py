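"""Hierarchical subset-database construction and internal-primer evaluation.

Because few public entries span the whole rDNA repeat, evaluation is
two-stage: first, *subset* databases are built by in silico amplification
with an outer primer pair at a single-mismatch ceiling (NS7–ITS2 around
ITS1; ITS5–ITS4 around ITS1+ITS2; ITS3–LR3 around ITS2); then internal
primers are evaluated against each subset. Subset records retain both
outer primer binding sites, so (a) re-amplifying a subset with the same
pair reproduces it (idempotence) and (b) pairs reusing an outer primer
(e.g. ITS5–ITS2 on subset 1) still find their sites. Since outer sites
are perfect-or-one-mismatch by construction, any additional failure in a
subset evaluation is attributable to the internal primer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._iupac import reverse_complement
from .pcr_engine import (AmplifyOptions, PrimerPair, get_primer,
                        run_insilico_pcr)
from .refdb_io import Group, ReferenceDB, ReferenceRecord

BUILD_MAX_MISMATCH = 1

_SUBSET_PAIRS = {
    "subset1": ("NS7", "ITS2"),   # ITS1 region
    "subset2": ("ITS5", "ITS4"),  # ITS1 + ITS2
    "subset3": ("ITS3", "LR3"),   # ITS2 region
}


@dataclass(frozen=True)
class SubsetSpec:
    """One of the three fixed outer-pair subset designs."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in _SUBSET_PAIRS:
            raise ValueError(f"unknown subset {self.name!r}; "
                             f"choose from {sorted(_SUBSET_PAIRS)}")

    @property
    def outer_pair(self) -> PrimerPair:
        f, r = _SUBSET_PAIRS[self.name]
        return PrimerPair(get_primer(f), get_primer(r))

    @property
    def build_max_mismatch(self) -> int:
        return BUILD_MAX_MISMATCH


@dataclass
class InternalEvaluation:
    """Per-ceiling amplified proportions for one internal primer."""

    subset: str
    pair: tuple[str, str]
    internal: str
    n_records: int
    amplified: dict[int, int]                 # ceiling -> record count
    proportions: dict[int, float]             # ceiling -> amplified fraction
    group_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    # group -> (amplified at ceiling 1, denominator)

    @property
    def group_proportions(self) -> dict[str, float]:
        return {g: a / d for g, (a, d) in self.group_counts.items() if d > 0}


def build_subset(db: ReferenceDB, spec: SubsetSpec,
                 options: AmplifyOptions | None = None) -> ReferenceDB:
    """Build a subset database by outer-pair amplification at ceiling 1.

    One record per amplified source record; when a source yields several
    amplicons only the longest is kept (documented choice). The subset
    sequence is the amplified span *including* both primer sites,
    normalized to primer orientation (forward primer at the 5' end), with
    taxonomy inherited.
    """
    options = options or AmplifyOptions(max_mismatch=spec.build_max_mismatch)
    result = run_insilico_pcr(db, spec.outer_pair, options)
    best: dict[str, object] = {}
    for amp in result.amplicons:
        cur = best.get(amp.record_id)
        if cur is None or (amp.total_length, -amp.fwd_start) > (cur.total_length, -cur.fwd_start):
            best[amp.record_id] = amp
    records = []
    for rec in db:  # preserve source order
        amp = best.get(rec.id)
        if amp is None:
            continue
        span = rec.sequence[amp.fwd_start:amp.rev_end]
        if amp.strand == "-":
            span = reverse_complement(span)
        records.append(ReferenceRecord(
            id=rec.id, sequence=span, taxid=rec.taxid,
            lineage=rec.lineage, group=rec.group))
    return ReferenceDB(records, label=f"{db.label}:{spec.name}")


def evaluate_internal(subset: ReferenceDB, pair: PrimerPair | tuple,
                      internal_name: str,
                      ceilings: tuple[int, ...] = (0, 1, 2, 3),
                      options: AmplifyOptions | None = None) -> InternalEvaluation:
    """Amplified proportion of a subset per mismatch ceiling.

    At ceiling 1 the per-group proportions are also recorded (groups with
    zero denominator are absent, not 0 %). Proportions are non-decreasing
    in the ceiling by construction.
    """
    fwd, rev = (get_primer(p) if isinstance(p, str) else p for p in pair)
    if internal_name not in (fwd.name, rev.name):
        raise ValueError(f"internal primer {internal_name!r} not in pair "
                         f"({fwd.name}, {rev.name})")
    base = options or AmplifyOptions()
    amplified: dict[int, int] = {}
    proportions: dict[int, float] = {}
    group_counts: dict[str, tuple[int, int]] = {}
    n = len(subset)
    for ceiling in ceilings:
        opts = AmplifyOptions(
            max_mismatch=ceiling, protected_tail=base.protected_tail,
            min_length=base.min_length, max_length=base.max_length,
            count_record_once=True, strict_target_acgt=base.strict_target_acgt)
        result = run_insilico_pcr(subset, PrimerPair(fwd, rev), opts)
        amplified[ceiling] = result.record_count
        proportions[ceiling] = result.record_count / n if n else float("nan")
        if ceiling == 1:
            for group in Group:
                members = [r.id for r in subset if r.group is group]
                if not members:
                    continue
                hit = sum(result.amplified[i] for i in members)
                group_counts[str(group)] = (hit, len(members))
    return InternalEvaluation(
        subset=subset.label, pair=(fwd.name, rev.name), internal=internal_name,
        n_records=n, amplified=amplified, proportions=proportions,
        group_counts=group_counts)


def internal_pair_schedule() -> list[tuple[str, tuple[str, str], str]]:
    """The eight (subset, pair, internal-primer) evaluations.

    ITS5–ITS2 is evaluated on subsets 1 and 2 with the focus on ITS5 and
    ITS2 respectively; ITS3–ITS4 on subsets 2 and 3 focusing ITS3 and
    ITS4; ITS1 is internal in both subsets 1 and 2.
    """
    return [
        ("subset1", ("ITS1-F", "ITS2"), "ITS1-F"),
        ("subset1", ("ITS5", "ITS2"), "ITS5"),
        ("subset1", ("ITS1", "ITS2"), "ITS1"),
        ("subset2", ("ITS1", "ITS4"), "ITS1"),
        ("subset2", ("ITS3", "ITS4"), "ITS3"),
        ("subset2", ("ITS5", "ITS2"), "ITS2"),
        ("subset3", ("ITS3", "ITS4"), "ITS4"),
        ("subset3", ("ITS3", "ITS4-B"), "ITS4-B"),
    ]
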