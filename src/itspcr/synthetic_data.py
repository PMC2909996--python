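"""Seeded generator of synthetic rDNA reference databases with planted
primer sites and exact truth tables.

Each record emulates one nuclear rDNA repeat read on the plus strand:

    flank — [NS7>] — SSU tail — [ITS1-F>] [ITS5>] [ITS1>] — ITS1 region —
    5.8S (containing the shared [ITS3>/<ITS2] locus) — ITS2 region —
    [<ITS4] [<ITS4-B] — LSU head — [<LR3] — flank

Forward-primer sites are planted as the primer text; reverse-primer
sites as its reverse complement. Every planted site is mutated to a
*planned* mismatch category: an exact count of incompatible positions
outside the protected 3' tail, a ``reject_tail`` mutation inside the
tail, or ``absent`` (the slot is random background). Mutations always
substitute a base incompatible with the primer's IUPAC set, so planted
counts are exact truth, and the truth table closes the loop with the
amplification engine with zero estimation error.

Group-specific region-length distributions encode the systematic length
structure of real fungal ITS data: basidiomycetes carry an ITS2 region
about 95 bp longer than ascomycetes, and full-ITS inserts average about
635 vs 551 bp; 'non-dikarya' fungi have markedly shorter ITS1 regions.
Background composition is uniform A/C/G/T by default — composition
affects only Tm dispersion, never matching logic.

ITS2 and ITS3 are exact reverse complements and share one 5.8S locus;
internal mutations there are restricted to positions outside *both*
primers' protected tails, so each primer's planted count stays exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._iupac import IUPAC_SETS, reverse_complement
from .pcr_engine import Primer, get_primer
from .refdb_io import Group, ReferenceDB, ReferenceRecord, classify_group

BASES = "ACGT"

#: region-length defaults per group: (mean bp, sd bp, min bp)
DEFAULT_REGION_LENGTHS: dict[str, dict[str, tuple[float, float, int]]] = {
    "common": {
        "flank5": (30, 5, 10),
        "ssu_tail": (100, 10, 40),
        "s58_pre": (70, 3, 50),
        "s58_post": (68, 3, 50),
        "lsu_head": (200, 20, 80),
        "flank3": (30, 5, 10),
    },
    "ascomycete": {"its1": (230, 45, 60), "its2": (163, 35, 60)},
    "basidiomycete": {"its1": (219, 65, 60), "its2": (258, 55, 60)},
    "non_dikarya": {"its1": (150, 50, 60), "its2": (170, 60, 60)},
    "plant": {"its1": (230, 50, 60), "its2": (180, 40, 60)},
    "other": {"its1": (200, 50, 60), "its2": (200, 50, 60)},
}

_LINEAGES: dict[str, list[tuple[str, ...]]] = {
    "ascomycete": [
        ("Eukaryota", "Fungi", "Dikarya", "Ascomycota", "Sordariomycetes", "Hypocreales"),
        ("Eukaryota", "Fungi", "Dikarya", "Ascomycota", "Dothideomycetes", "Pleosporales"),
        ("Eukaryota", "Fungi", "Dikarya", "Ascomycota", "Leotiomycetes", "Helotiales"),
    ],
    "basidiomycete": [
        ("Eukaryota", "Fungi", "Dikarya", "Basidiomycota", "Agaricomycetes", "Agaricales"),
        ("Eukaryota", "Fungi", "Dikarya", "Basidiomycota", "Agaricomycetes", "Russulales"),
        ("Eukaryota", "Fungi", "Dikarya", "Basidiomycota", "Agaricomycetes", "Boletales"),
    ],
    "non_dikarya": [
        ("Eukaryota", "Fungi", "Chytridiomycota", "Chytridiomycetes", "Chytridiales"),
        ("Eukaryota", "Fungi", "Glomeromycota", "Glomeromycetes", "Glomerales"),
        ("Eukaryota", "Fungi", "Mucoromycota", "Mucorales"),
    ],
    "plant": [
        ("Eukaryota", "Viridiplantae", "Streptophyta", "Magnoliopsida", "Poales"),
        ("Eukaryota", "Viridiplantae", "Streptophyta", "Magnoliopsida", "Fabales"),
        ("Eukaryota", "Viridiplantae", "Streptophyta", "Magnoliopsida", "Asterales"),
    ],
}

PROTECTED_TAIL = 2
_SPACER = 5  # bp between clustered primer sites

#: site slots in plus-strand order: (primer name, orientation)
_SITE_ORDER = [
    ("NS7", "+"), ("ITS1-F", "+"), ("ITS5", "+"), ("ITS1", "+"),
    ("ITS3", "+"),  # shared 5.8S locus, doubles as the ITS2 '-' site
    ("ITS4", "-"), ("ITS4-B", "-"), ("LR3", "-"),
]

MismatchPlan = dict  # category -> count (int) or proportion (float)
_CATEGORIES = (0, 1, 2, 3, "reject_tail", "absent")


@dataclass
class Cohort:
    """A block of records sharing group, lineage and mismatch plans."""

    name: str
    group: str
    n: int
    lineage: tuple[str, ...] | None = None  # default: cycle group templates
    plans: dict[str, MismatchPlan] = field(default_factory=dict)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic database."""

    seed: int = 0
    cohorts: list[Cohort] = field(default_factory=list)
    per_group_counts: dict[str, int] = field(default_factory=lambda: {
        "ascomycete": 30, "basidiomycete": 30, "non_dikarya": 15, "plant": 15})
    region_lengths: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_REGION_LENGTHS.items()})
    mismatch_plan: dict[str, MismatchPlan] = field(default_factory=dict)
    plant_missing: frozenset = frozenset({"ITS1-F", "ITS4-B"})
    gc_content: float = 0.5
    label: str = "synthetic"

    def effective_cohorts(self) -> list[Cohort]:
        if self.cohorts:
            return self.cohorts
        return [Cohort(name=g, group=g, n=n)
                for g, n in self.per_group_counts.items() if n > 0]


@dataclass
class TruthTable:
    """Planted truth: per-record metadata and per-site mismatch plan."""

    records: pd.DataFrame  # record_id, taxid, group, lineage, region lengths
    sites: pd.DataFrame    # record_id, primer, category, mismatches, start, end, strand

    def site(self, record_id: str, primer: str) -> pd.Series:
        hit = self.sites[(self.sites.record_id == record_id)
                         & (self.sites.primer == primer)]
        if hit.empty:
            raise KeyError(f"no planted site for {primer} on {record_id}")
        return hit.iloc[0]

    def amplified_ids(self, fwd: str, rev: str, ceiling: int) -> set[str]:
        """Records whose planted sites allow amplification at a ceiling."""
        ok_f = self._ok(fwd, ceiling)
        ok_r = self._ok(rev, ceiling)
        return ok_f & ok_r

    def _ok(self, primer: str, ceiling: int) -> set[str]:
        s = self.sites[self.sites.primer == primer]
        s = s[(s.mismatches >= 0) & (s.mismatches <= ceiling)]
        return set(s.record_id)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])


def _realize(primer: Primer, rng: np.random.Generator) -> str:
    """A concrete site compatible with the primer at every position."""
    return "".join(b if b in BASES else rng.choice(sorted(IUPAC_SETS[b]))
                   for b in primer.sequence)


def plant_site_mutations(site: str, k: int, protected_tail: int,
                         rng: np.random.Generator, *, primer: str | None = None,
                         forbidden: frozenset[int] = frozenset(),
                         reject_tail: bool = False) -> str:
    """Mutate a planted site to an exact mismatch count.

    Exactly ``k`` positions outside the protected 3' tail (and outside
    ``forbidden``) are changed to a base *incompatible* with the primer's
    IUPAC set at that position — never a silent compatible substitution.
    With ``reject_tail`` one additional tail position is made
    incompatible, which the engine rejects at every ceiling.
    """
    primer = (primer or site).upper()
    n = len(site)
    internal = [i for i in range(n - protected_tail) if i not in forbidden]
    if k > len(internal):
        raise ValueError(f"cannot plant {k} mismatches in {len(internal)} "
                         "mutable positions")
    out = list(site)
    for pos in rng.choice(len(internal), size=k, replace=False):
        i = internal[int(pos)]
        out[i] = rng.choice(sorted(set(BASES) - IUPAC_SETS[primer[i]]))
    if reject_tail:
        i = int(rng.integers(n - protected_tail, n))
        out[i] = rng.choice(sorted(set(BASES) - IUPAC_SETS[primer[i]]))
    return "".join(out)


def _absent_slot(primer: Primer, rng: np.random.Generator, gc: float) -> str:
    """Random background guaranteed incompatible with the primer: several
    internal positions and one tail position are forced incompatible."""
    text = list(_random_seq(rng, len(primer), gc))
    n = len(text)
    internal = rng.choice(n - PROTECTED_TAIL, size=min(6, n - PROTECTED_TAIL),
                          replace=False)
    for i in [int(j) for j in internal] + [n - 1]:
        text[i] = rng.choice(sorted(set(BASES) - IUPAC_SETS[primer.sequence[i]]))
    return "".join(text)


def _allocate(plan: MismatchPlan, n: int, rng: np.random.Generator) -> list:
    """Turn a plan into an exact per-record category list of length n.

    Integer values are exact counts (shortfall tops up category 0);
    float values are proportions converted by largest-remainder rounding.
    The list is shuffled so categories mix across lineages.
    """
    for cat in plan:
        if cat not in _CATEGORIES:
            raise ValueError(f"unknown mismatch category {cat!r}")
    values = list(plan.values())
    if values and all(isinstance(v, int) for v in values):
        counts = dict(plan)
        total = sum(counts.values())
        if total > n:
            raise ValueError(f"plan allocates {total} records but cohort has {n}")
        counts[0] = counts.get(0, 0) + (n - total)
    else:
        raw = {c: float(v) * n for c, v in plan.items()}
        counts = {c: int(math.floor(x)) for c, x in raw.items()}
        shortfall = n - sum(counts.values())
        for c in sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)[:shortfall]:
            counts[c] += 1
    out: list = []
    for cat, cnt in counts.items():
        out.extend([cat] * cnt)
    rng.shuffle(out)
    return out


def simulate_reference_db(config: SimulationConfig) -> tuple[ReferenceDB, TruthTable]:
    """Generate a reference database and its exact truth table.

    Deterministic under ``config.seed``: the same config yields a
    byte-identical database.
    """
    rng = np.random.default_rng(config.seed)
    primers = {name: get_primer(name) for name, _ in _SITE_ORDER}
    primers["ITS2"] = get_primer("ITS2")
    cohorts = config.effective_cohorts()

    # exact category allocation, pooled across cohorts sharing a plan source
    allocations: dict[tuple[int, str], list] = {}
    for ci, cohort in enumerate(cohorts):
        for pname, _ in _SITE_ORDER:
            if pname not in cohort.plans and pname in config.mismatch_plan:
                continue  # pooled allocation below
            plan = cohort.plans.get(pname) or {0: cohort.n}
            allocations[(ci, pname)] = _allocate(plan, cohort.n, rng)

    # pooled allocation for global plans: re-allocate across all records so
    # proportions are exact over the whole database, not per cohort
    for pname, plan in config.mismatch_plan.items():
        pooled_cohorts = [ci for ci, c in enumerate(cohorts) if pname not in c.plans]
        n_total = sum(cohorts[ci].n for ci in pooled_cohorts)
        if n_total == 0:
            continue
        pooled = _allocate(plan, n_total, rng)
        offset = 0
        for ci in pooled_cohorts:
            allocations[(ci, pname)] = pooled[offset:offset + cohorts[ci].n]
            offset += cohorts[ci].n

    rec_rows, site_rows, records = [], [], []
    taxid = 1000
    idx = 0
    for ci, cohort in enumerate(cohorts):
        group = Group(cohort.group)
        lengths = {**config.region_lengths["common"],
                   **config.region_lengths[cohort.group]}
        templates = _LINEAGES.get(cohort.group, [("Eukaryota", "unclassified")])
        for j in range(cohort.n):
            idx += 1
            taxid += 1
            base_lin = cohort.lineage or templates[j % len(templates)]
            lineage = base_lin + (f"{base_lin[-1]}_sp{j + 1}",)
            rec_id = f"{cohort.name}-{j + 1:04d}"

            def draw(region: str) -> int:
                mean, sd, lo = lengths[region]
                return max(lo, int(round(rng.normal(mean, sd))))

            gc = config.gc_content
            parts: list[str] = []
            pos = 0
            sites_here: dict[str, tuple] = {}

            def add(text: str) -> None:
                nonlocal pos
                parts.append(text)
                pos += len(text)

            def add_site(pname: str, orient: str) -> None:
                primer = primers[pname]
                category = allocations[(ci, pname)][j]
                if group is Group.PLANT and pname in config.plant_missing:
                    category = "absent"
                shared = pname == "ITS3"
                forbidden = frozenset({0, 1}) if shared else frozenset()
                if category == "absent":
                    text, mm = _absent_slot(primer, rng, gc), -1
                elif category == "reject_tail":
                    text = plant_site_mutations(
                        _realize(primer, rng), 0, PROTECTED_TAIL, rng,
                        primer=primer.sequence, forbidden=forbidden, reject_tail=True)
                    mm = -1
                else:
                    text = plant_site_mutations(
                        _realize(primer, rng), int(category), PROTECTED_TAIL, rng,
                        primer=primer.sequence, forbidden=forbidden)
                    mm = int(category)
                start = pos
                site_text = text if orient == "+" else reverse_complement(text)
                add(site_text)
                sites_here[pname] = (category, mm, start, pos, orient)
                if shared:
                    # the same locus read as the ITS2 reverse site; tails of
                    # both primers were excluded from internal mutations, and
                    # a tail-reject for ITS3 is one internal mismatch for ITS2
                    if category == "reject_tail":
                        cat2, mm2 = 1, 1
                    elif category == "absent":
                        cat2, mm2 = "absent", -1
                    else:
                        cat2, mm2 = category, mm
                    sites_here["ITS2"] = (cat2, mm2, start, pos, "-")

            add(_random_seq(rng, draw("flank5"), gc))
            add_site("NS7", "+")
            add(_random_seq(rng, draw("ssu_tail"), gc))
            add_site("ITS1-F", "+")
            add(_random_seq(rng, _SPACER, gc))
            add_site("ITS5", "+")
            add(_random_seq(rng, _SPACER, gc))
            add_site("ITS1", "+")
            its1_len = draw("its1")
            add(_random_seq(rng, its1_len, gc))
            add(_random_seq(rng, draw("s58_pre"), gc))
            add_site("ITS3", "+")
            add(_random_seq(rng, draw("s58_post"), gc))
            its2_len = draw("its2")
            add(_random_seq(rng, its2_len, gc))
            add_site("ITS4", "-")
            add(_random_seq(rng, _SPACER, gc))
            add_site("ITS4-B", "-")
            add(_random_seq(rng, draw("lsu_head"), gc))
            add_site("LR3", "-")
            add(_random_seq(rng, draw("flank3"), gc))

            sequence = "".join(parts)
            records.append(ReferenceRecord(
                id=rec_id, sequence=sequence, taxid=taxid,
                lineage=lineage, group=classify_group(lineage)))
            rec_rows.append({"record_id": rec_id, "taxid": taxid,
                             "group": str(group), "lineage": ";".join(lineage),
                             "its1_len": its1_len, "its2_len": its2_len,
                             "seq_len": len(sequence)})
            for pname, (cat, mm, start, end, orient) in sites_here.items():
                site_rows.append({"record_id": rec_id, "primer": pname,
                                  "category": str(cat), "mismatches": mm,
                                  "start": start, "end": end, "strand": orient})

    db = ReferenceDB(records, label=config.label)
    truth = TruthTable(records=pd.DataFrame(rec_rows),
                       sites=pd.DataFrame(site_rows))
    return db, truth


def paper_scenario_config(name: str, seed: int = 0) -> SimulationConfig:
    """Named desk-scale scenarios with planted truth patterns.

    ``its1f_mismatch_profile``
        1000 fungal records whose ITS1-F sites are 36.0 % perfect and
        55.6 % single-mismatch, so the amplified proportion rises from
        0.360 at ceiling 0 to 0.916 at ceiling 1 exactly.
    ``taxonomic_bias``
        Per-group ITS1 amplifiabilities at ceiling 1 planted at exactly
        62 % (ascomycetes), 86 % (basidiomycetes), 89 % (non-dikarya).
    ``order_breakdown``
        Basidiomycete orders with planted ITS4-B site categories, led by
        a Boletales-style row: 18 records, 17 amplifiable within 3
        mismatches, 15 perfect.
    ``length_bias``
        500 ascomycete + 500 basidiomycete + 200 non-dikarya records,
        all sites perfect, group length structure from the defaults
        (planted basidiomycete − ascomycete ITS2 difference: 95 bp).
    """
    if name == "its1f_mismatch_profile":
        return SimulationConfig(
            seed=seed, label=name,
            cohorts=[Cohort("asc", "ascomycete", 500),
                     Cohort("bas", "basidiomycete", 300),
                     Cohort("nda", "non_dikarya", 200)],
            mismatch_plan={"ITS1-F": {0: 360, 1: 556, 2: 40, 3: 24,
                                      "reject_tail": 20}},
        )
    if name == "taxonomic_bias":
        return SimulationConfig(
            seed=seed, label=name,
            cohorts=[
                Cohort("asc", "ascomycete", 300,
                       plans={"ITS1": {0: 93, 1: 93, 2: 60, "reject_tail": 54}}),
                Cohort("bas", "basidiomycete", 200,
                       plans={"ITS1": {0: 86, 1: 86, 2: 14, "reject_tail": 14}}),
                Cohort("nda", "non_dikarya", 100,
                       plans={"ITS1": {0: 45, 1: 44, 2: 6, "reject_tail": 5}}),
            ],
        )
    if name == "order_breakdown":
        orders = [
            # (order/clade name, n, perfect, >=3mm-only, reject)
            ("Boletales", 18, 15, 2, 1),
            ("Cantharellales", 33, 0, 31, 2),
            ("Hymenochaetales", 10, 0, 7, 3),
            ("Russulales", 97, 0, 64, 33),
            ("Tremellomycetes", 38, 0, 13, 25),
            ("Pucciniomycotina", 8, 0, 0, 8),
            ("Ustilaginomycotina", 21, 0, 0, 21),
        ]
        cohorts = []
        for clade, n, perfect, relaxed, reject in orders:
            lineage = ("Eukaryota", "Fungi", "Dikarya", "Basidiomycota",
                       "Agaricomycetes", clade) if clade.endswith("ales") else (
                       "Eukaryota", "Fungi", "Dikarya", "Basidiomycota", clade)
            cohorts.append(Cohort(
                clade.lower()[:6], "basidiomycete", n, lineage=lineage,
                plans={"ITS4-B": {0: perfect, 2: relaxed, "reject_tail": reject}}))
        return SimulationConfig(seed=seed, label=name, cohorts=cohorts)
    if name == "length_bias":
        return SimulationConfig(
            seed=seed, label=name,
            cohorts=[Cohort("asc", "ascomycete", 500),
                     Cohort("bas", "basidiomycete", 500),
                     Cohort("nda", "non_dikarya", 200)],
        )
    raise ValueError(f"unknown scenario {name!r}")
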