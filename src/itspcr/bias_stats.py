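"""Summary statistics for primer bias: specificity, taxonomic and length bias.

All tables carry explicit denominators next to counts so every proportion
is recomputable; nothing here estimates — on databases with known planted
truth each cell equals the planted value exactly. Length comparisons use
Welch's unequal-variance two-tailed t-test by default (a pooled-variance
option exists); p-values are reported raw, without multiple-testing
correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pcr_engine import Amplicon, AmplifyOptions, PrimerPair, get_primer, run_insilico_pcr
from .refdb_io import ReferenceDB
from .subset_pipeline import InternalEvaluation


@dataclass
class BiasTable:
    """A counts/proportions table with explicit denominators."""

    table: pd.DataFrame
    denominators: dict = field(default_factory=dict)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return repr(self.table)


def specificity_table(fungi_db: ReferenceDB, plant_db: ReferenceDB,
                      pairs: list[tuple[str, str]],
                      ceilings: tuple[int, ...] = (0, 1, 2, 3),
                      options: AmplifyOptions | None = None) -> BiasTable:
    """Records amplified per database × primer pair × mismatch ceiling.

    The cross-kingdom specificity table: each cell is the number of
    records (each counted once) amplified from the fungal or plant
    database by the pair at that ceiling.
    """
    base = options or AmplifyOptions()
    rows = []
    for fwd_name, rev_name in pairs:
        pair = PrimerPair(get_primer(fwd_name), get_primer(rev_name))
        row: dict = {"pair": f"{fwd_name}-{rev_name}"}
        for label, db in (("fungi", fungi_db), ("plant", plant_db)):
            for ceiling in ceilings:
                opts = AmplifyOptions(
                    max_mismatch=ceiling, protected_tail=base.protected_tail,
                    min_length=base.min_length, max_length=base.max_length,
                    strict_target_acgt=base.strict_target_acgt)
                row[f"{label}_{ceiling}"] = run_insilico_pcr(db, pair, opts).record_count
        rows.append(row)
    table = pd.DataFrame(rows).set_index("pair")
    return BiasTable(table, denominators={"fungi": len(fungi_db),
                                          "plant": len(plant_db)})


def taxonomic_bias_table(evaluations: list[InternalEvaluation]) -> BiasTable:
    """Percentage of subset records amplified per group at ceiling 1.

    Rows are (subset, pair) evaluations; columns the taxonomic groups.
    Groups absent from a subset yield missing cells rather than 0 %.
    """
    rows = []
    denoms: dict = {}
    for ev in evaluations:
        row: dict = {"subset": ev.subset, "pair": "-".join(ev.pair),
                     "internal": ev.internal}
        for group, (hit, denom) in ev.group_counts.items():
            row[group] = 100.0 * hit / denom
            denoms[(ev.subset, "-".join(ev.pair), group)] = denom
        rows.append(row)
    table = pd.DataFrame(rows).set_index(["subset", "pair"])
    return BiasTable(table, denominators=denoms)


def order_breakdown(subset: ReferenceDB, pair: tuple[str, str],
                    orders: list[str],
                    ceilings: tuple[int, ...] = (0, 3),
                    options: AmplifyOptions | None = None) -> BiasTable:
    """Per-clade subset counts and amplified counts/percentages.

    A clade (order, class or subphylum name) is matched case-insensitively
    against each record's lineage. Clades absent from the subset are
    omitted. Percentages at a higher ceiling are >= those at a lower one.
    """
    base = options or AmplifyOptions()
    primers = PrimerPair(get_primer(pair[0]), get_primer(pair[1]))
    amplified_at: dict[int, dict[str, bool]] = {}
    for ceiling in ceilings:
        opts = AmplifyOptions(
            max_mismatch=ceiling, protected_tail=base.protected_tail,
            min_length=base.min_length, max_length=base.max_length,
            strict_target_acgt=base.strict_target_acgt)
        amplified_at[ceiling] = run_insilico_pcr(subset, primers, opts).amplified
    rows = []
    denoms: dict = {}
    for order in orders:
        members = [r.id for r in subset
                   if any(rank.lower() == order.lower() for rank in r.lineage)]
        if not members:
            continue
        row: dict = {"clade": order, "n": len(members)}
        denoms[order] = len(members)
        for ceiling in ceilings:
            hits = sum(amplified_at[ceiling][i] for i in members)
            row[f"amplified_{ceiling}"] = hits
            row[f"pct_{ceiling}"] = 100.0 * hits / len(members)
        rows.append(row)
    return BiasTable(pd.DataFrame(rows).set_index("clade"), denominators=denoms)


@dataclass
class LengthComparison:
    """Group length summaries and pairwise Welch t-tests."""

    summary: pd.DataFrame     # per group: n, mean bp, sd bp
    pairwise: pd.DataFrame    # group_a, group_b, mean_diff, t, df, p
    degenerate: bool = False  # all lengths equal in both groups of a pair


def length_comparison(amplicons: list[Amplicon] | pd.DataFrame,
                      groups: list[str], *, use_total_length: bool = False,
                      pooled: bool = False) -> LengthComparison:
    """Compare amplicon insert lengths across taxonomic groups.

    Lengths are insert lengths (primers excluded) unless
    ``use_total_length``. For each ordered group pair (a, b) the mean
    difference is reported signed as mean(b) − mean(a) — with groups
    ``["ascomycete", "basidiomycete"]`` a positive difference means
    longer basidiomycete fragments — together with the two-tailed t-test
    (Welch by default, pooled with ``pooled=True``). Degenerate variance
    (all lengths equal in both groups) flags p as undefined.
    """
    if isinstance(amplicons, pd.DataFrame):
        frame = amplicons
    else:
        frame = pd.DataFrame([a.as_row() for a in amplicons])
    col = "total_length" if use_total_length else "insert_length"
    lengths = {g: frame.loc[frame["group"] == g, col].to_numpy(float)
               for g in groups}
    for g, vals in lengths.items():
        if len(vals) < 2:
            raise ValueError(f"need >=2 amplicons in group {g!r}")
    summary = pd.DataFrame(
        [{"group": g, "n": len(v), "mean_bp": v.mean(),
          "sd_bp": v.std(ddof=1)} for g, v in lengths.items()]
    ).set_index("group")
    rows = []
    degenerate = False
    for a, b in itertools.combinations(groups, 2):
        va, vb = lengths[a], lengths[b]
        diff = vb.mean() - va.mean()
        if va.std(ddof=1) == 0 and vb.std(ddof=1) == 0:
            degenerate = True
            t, df, p = float("nan"), float("nan"), float("nan")
        else:
            res = stats.ttest_ind(vb, va, equal_var=pooled)
            t, p = float(res.statistic), float(res.pvalue)
            df = float(res.df)
        rows.append({"group_a": a, "group_b": b, "mean_diff_bp": diff,
                     "t": t, "df": df, "p": p})
    return LengthComparison(summary=summary, pairwise=pd.DataFrame(rows),
                            degenerate=degenerate)


def mismatch_share(evaluation: InternalEvaluation) -> float:
    """Share of amplified records whose internal site has exactly one
    mismatch: (P1 − P0) / P1 from the ceiling-0/1 proportions.

    Undefined (ValueError) when nothing amplifies at ceiling 1.
    """
    try:
        p0 = evaluation.proportions[0]
        p1 = evaluation.proportions[1]
    except KeyError as exc:
        raise ValueError("evaluation must include ceilings 0 and 1") from exc
    if p1 == 0:
        raise ValueError("undefined: no records amplified at ceiling 1")
    return (p1 - p0) / p1
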