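"""The amplification engine against examples and the brute-force oracle."""

import itertools

import numpy as np
import pytest

from conftest import (ORACLE_SETS, oracle_amplicons, oracle_revcomp,
                      oracle_sites, random_concrete_seq, random_primer)
from itspcr._iupac import reverse_complement
from itspcr.pcr_engine import (REJECT, AmplifyOptions, Primer, PrimerPair,
                               amplify_record, count_mismatches, get_primer,
                               iupac_compatible, load_primer_registry,
                               run_insilico_pcr, scan_sites)
from itspcr.refdb_io import Group, ReferenceDB, ReferenceRecord

_LINEAGE = ("Eukaryota", "Fungi", "Dikarya", "Ascomycota", "test")


def _rec(seq, rid="r1"):
    return ReferenceRecord(rid, seq, 1, _LINEAGE, Group.ASCOMYCETE)


def test_iupac_compatible_matches_set_intersection():
    symbols = "ACGTRYSWKMBDHVN"
    for a, b in itertools.product(symbols, repeat=2):
        assert iupac_compatible(a, b) == bool(ORACLE_SETS[a] & ORACLE_SETS[b])
        assert iupac_compatible(a, b) == iupac_compatible(b, a)


def test_iupac_compatible_rejects_non_iupac():
    with pytest.raises(ValueError):
        iupac_compatible("A", "X")


@pytest.mark.parametrize("window, expected", [
    ("ACGTACGT", 0),
    ("TCGTACGT", 1),          # position 0
    ("TCGAACGT", 2),
    ("ACGTACGA", REJECT),     # 3'-terminal mismatch
    ("ACGTACAT", REJECT),     # penultimate (within protected tail)
])
def test_count_mismatches_examples(window, expected):
    opts = AmplifyOptions(max_mismatch=2)
    p = Primer("t", "ACGTACGT")
    assert count_mismatches(p, window, opts) == expected \
        or count_mismatches(p, window, opts) is expected


def test_count_mismatches_over_ceiling_rejected():
    opts = AmplifyOptions(max_mismatch=1)
    assert count_mismatches(Primer("t", "ACGTACGT"), "TCGAACGT", opts) is REJECT


def test_count_mismatches_length_check():
    with pytest.raises(ValueError):
        count_mismatches(Primer("t", "ACGTACGT"), "ACGT", AmplifyOptions())


def test_registry_has_the_nine_primers():
    reg = load_primer_registry()
    assert set(reg) == {"ITS1", "ITS1-F", "ITS2", "ITS3", "ITS4", "ITS4-B",
                        "ITS5", "NS7", "LR3"}
    # ITS2 and ITS3 target the same 5.8S locus from opposite strands
    assert reg["ITS2"].sequence == reverse_complement(reg["ITS3"].sequence)


def test_scan_finds_embedded_reverse_complement_once():
    p = get_primer("ITS3")
    seq = "A" * 50 + reverse_complement(p.sequence) + "A" * 50
    sites = scan_sites(_rec(seq), p, AmplifyOptions(max_mismatch=0))
    assert sites == [(50, "-", 0)]


def test_all_n_primer_hits_everywhere_at_ceiling_zero():
    p = Primer("n", "N" * 10)
    seq = random_concrete_seq(np.random.default_rng(0), 40)
    sites = scan_sites(_rec(seq), p, AmplifyOptions(max_mismatch=0))
    plus = [s for s in sites if s.strand == "+"]
    assert [s.start for s in plus] == list(range(31))


def test_scan_sites_equals_oracle_on_random_instances():
    rng = np.random.default_rng(123)
    for trial in range(30):
        seq = random_concrete_seq(rng, 300)
        primer = Primer("p", random_primer(rng, int(rng.integers(12, 22)),
                                           degenerate=trial % 3 == 0))
        ceiling = int(rng.integers(0, 4))
        opts = AmplifyOptions(max_mismatch=ceiling)
        got = {(s.start, s.strand, s.mismatches)
               for s in scan_sites(_rec(seq), primer, opts)}
        want = set(oracle_sites(seq, primer.sequence, ceiling))
        assert got == want


def _constructed_record(fwd, rev, insert_len=300, pad=25, fwd_mm_site=None):
    ins = random_concrete_seq(np.random.default_rng(5), insert_len)
    fsite = fwd_mm_site or fwd.sequence
    seq = ("T" * pad + fsite + ins + reverse_complement(rev.sequence)
           + "T" * pad)
    return _rec(seq), pad


def test_amplify_constructed_record():
    fwd, rev = get_primer("ITS3"), get_primer("ITS4")
    rec, pad = _constructed_record(fwd, rev)
    amps = amplify_record(rec, (fwd, rev), AmplifyOptions(max_mismatch=0))
    assert len(amps) == 1
    a = amps[0]
    assert (a.strand, a.insert_length, a.fwd_mismatches, a.rev_mismatches) \
        == ("+", 300, 0, 0)
    assert a.fwd_start == pad
    assert a.total_length == 300 + len(fwd) + len(rev)
    assert a.insert_length == a.total_length - len(fwd) - len(rev)


def test_strand_symmetry_of_amplification():
    """Reverse-complementing the record flips the strand flag but leaves
    lengths and mismatch counts unchanged."""
    fwd, rev = get_primer("ITS3"), get_primer("ITS4")
    rec, _ = _constructed_record(fwd, rev)
    flipped = _rec(reverse_complement(rec.sequence), "r2")
    opts = AmplifyOptions(max_mismatch=1)
    a1 = amplify_record(rec, (fwd, rev), opts)
    a2 = amplify_record(flipped, (fwd, rev), opts)
    assert len(a1) == len(a2) == 1
    assert a1[0].strand == "+" and a2[0].strand == "-"
    for field in ("insert_length", "total_length", "fwd_mismatches",
                  "rev_mismatches"):
        assert getattr(a1[0], field) == getattr(a2[0], field)
    assert a2[0].rev_end - a2[0].fwd_start == a1[0].rev_end - a1[0].fwd_start


def test_two_forward_sites_give_two_amplicons():
    fwd, rev = get_primer("ITS3"), get_primer("ITS4")
    rng = np.random.default_rng(9)
    seq = ("A" * 10 + fwd.sequence + random_concrete_seq(rng, 80)
           + fwd.sequence + random_concrete_seq(rng, 120)
           + reverse_complement(rev.sequence) + "A" * 10)
    amps = amplify_record(_rec(seq), (fwd, rev), AmplifyOptions(max_mismatch=0))
    assert len(amps) == 2
    assert sorted(a.insert_length for a in amps) == [120, 220]


def test_overlapping_sites_discarded():
    """A reverse site upstream of the forward 3' end is unamplifiable."""
    fwd, rev = get_primer("ITS3"), get_primer("ITS4")
    seq = "A" * 10 + reverse_complement(rev.sequence) + fwd.sequence + "A" * 10
    amps = amplify_record(_rec(seq), (fwd, rev),
                          AmplifyOptions(max_mismatch=0, min_length=0))
    assert amps == []


def test_amplicons_equal_oracle_on_random_instances():
    rng = np.random.default_rng(77)
    for _ in range(20):
        seq = random_concrete_seq(rng, 600)
        fwd = Primer("f", random_primer(rng, 16))
        rev = Primer("r", random_primer(rng, 16))
        # plant sites so some instances actually amplify
        fs, rs = int(rng.integers(20, 200)), int(rng.integers(300, 500))
        seq = (seq[:fs] + fwd.sequence + seq[fs + 16:rs]
               + oracle_revcomp(rev.sequence) + seq[rs + 16:])
        ceiling = int(rng.integers(0, 4))
        opts = AmplifyOptions(max_mismatch=ceiling, min_length=0,
                              max_length=600)
        got = sorted((a.strand, a.fwd_start, a.rev_end, a.insert_length,
                      a.fwd_mismatches, a.rev_mismatches)
                     for a in amplify_record(_rec(seq), (fwd, rev), opts))
        want = oracle_amplicons(seq, fwd.sequence, rev.sequence, ceiling,
                                0, 600)
        assert got == want


def test_record_counts_monotone_in_ceiling_and_length_bounds(small_db):
    db, _ = small_db
    pair = PrimerPair(get_primer("ITS5"), get_primer("ITS4"))
    counts = [run_insilico_pcr(db, pair, AmplifyOptions(max_mismatch=m)).record_count
              for m in range(4)]
    assert counts == sorted(counts)
    narrow = run_insilico_pcr(db, pair, AmplifyOptions(
        max_mismatch=1, min_length=400, max_length=700)).record_count
    wide = run_insilico_pcr(db, pair, AmplifyOptions(
        max_mismatch=1, min_length=20, max_length=2000)).record_count
    assert narrow <= wide


def test_empty_db_gives_empty_table():
    res = run_insilico_pcr(ReferenceDB([], label="empty"),
                           (get_primer("ITS3"), get_primer("ITS4")),
                           AmplifyOptions())
    assert res.amplicons == [] and res.record_count == 0
    assert res.to_frame().empty


def test_count_record_once_vs_amplicon_count():
    fwd, rev = get_primer("ITS3"), get_primer("ITS4")
    rng = np.random.default_rng(2)
    seq = ("A" * 10 + fwd.sequence + random_concrete_seq(rng, 60)
           + fwd.sequence + random_concrete_seq(rng, 60)
           + reverse_complement(rev.sequence) + "A" * 10)
    db = ReferenceDB([_rec(seq)], label="multi")
    res = run_insilico_pcr(db, (fwd, rev), AmplifyOptions(max_mismatch=0))
    assert res.record_count == 1
    assert res.amplicon_count == 2


def test_strict_target_acgt_counts_target_ambiguity_as_mismatch():
    p = Primer("t", "ACGTACGTAC")
    win_n = "ACGTNCGTAC"
    relaxed = AmplifyOptions(max_mismatch=0)
    strict = AmplifyOptions(max_mismatch=0, strict_target_acgt=True)
    assert count_mismatches(p, win_n, relaxed) == 0
    assert count_mismatches(p, win_n, strict) is REJECT

    strict1 = AmplifyOptions(max_mismatch=1, strict_target_acgt=True)
    assert count_mismatches(p, win_n, strict1) == 1
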