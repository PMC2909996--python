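# Methods

## Approximate primer matching

A primer binds a site when every position is *compatible*: the IUPAC
base sets of the primer symbol and the target symbol intersect. A
degenerate primer base therefore matches any member of its pool, and an
N in the target never counts as a mismatch under the default semantics.
This is deliberately permissive — an N-rich record can only gain
amplifications — and the `strict_target_acgt` option inverts the
treatment (a target ambiguity code counts as a mismatch unless the
primer symbol covers every base the code could be), so users can bound
the N-driven optimism of their database.

Stringency is a per-primer mismatch ceiling *m* ∈ {0..3} applied
independently to each primer of the pair, never summed. The last
`protected_tail` bases (default 2) of each primer's 3′ end must match
exactly: a mismatch there *rejects* the site at every ceiling, rather
than merely not counting, because polymerase extension from a mismatched
3′-OH is the step real PCR stringency suppresses.

Both strands are scanned; a forward site paired with any downstream
reverse-complemented reverse-primer site yields an amplicon when the
insert (the bases between the two 3′ ends) lies within [20, 2000] bp by
default — generous bounds around the 450–700 bp span typical of a full
fungal ITS region. Overlapping site pairs (negative insert) are
physically unamplifiable and discarded. Amplicons are reported with
0-based half-open span coordinates on the stored strand and sorted by
(record id, span start, insert length). The headline count is records
with ≥ 1 amplicon (`count_record_once`), since one database entry
corresponds to one template sequence; the full amplicon list is always
retained.

The scanner is numpy-vectorized: sequences are encoded as 15-symbol
indices and per-offset boolean compatibility rows are accumulated into
window mismatch counts. The test suite holds it to exact agreement with
an independent pure-Python brute-force enumerator on hundreds of random
(sequence, primer pair, ceiling) instances.

## Melting temperatures

Duplex stability uses the two-state nearest-neighbor model

    Tm(K) = ΔH° / (ΔS° + R·ln(cT/4))

with ΔH°, ΔS° summed over dinucleotide stacks and initiation terms, R =
1.987 cal/(mol·K), and cT the total strand concentration (the /4 term is
the non-self-complementary case). The parameter asset
(`data/nn_params.tsv`, versioned) carries the SantaLucia (1998) unified
Watson–Crick set, the Allawi & SantaLucia / Peyret single-internal-
mismatch sets, and the terminal-mismatch compilation; stacks with no
published parameters (tandem mismatches) contribute zero, an
approximation that only matters beyond the single-mismatch regime the
package reasons about. Degenerate primer positions are resolved to the
concrete pool member with the fewest mismatches against the target, ties
broken toward higher Tm, because the best-matching oligo of a degenerate
pool dominates annealing.

Monovalent-salt correction defaults to Owczarzy et al. (2004),

    1/Tm(Na⁺) = 1/Tm(1 M) + (4.29·f_GC − 3.95)·10⁻⁵·ln[Na⁺]
                + 9.40·10⁻⁶·ln²[Na⁺],

chosen over the Schildkraut–Lifson (16.6·log₁₀[Na⁺]) and SantaLucia
entropic (0.368·N·ln[Na⁺]) forms — both available as options — because
in a model-selection pass against the reference zero-mismatch Tm panel
used for calibration it reproduced the non-anchor values markedly
better, and it is the form modern oligo-design services use.

### Calibration

The two environmental constants are not hard-coded. `calibrate_model`
fits (monovalent salt, strand concentration) by bounded least squares
(log-space, multi-started) to user-supplied anchor (primer, Tm) pairs,
constrained to physically plausible PCR conditions (salt 1 mM–1 M,
strand 1 pM–100 µM). Anchor residuals are stored on the model, and a
worst residual ≥ 1 °C raises rather than silently returning a poor fit.
The shipped constants (`data/tm_calibration.yaml`: Na⁺ ≈ 0.128 M, cT ≈
2.2 nM) were calibrated on the reference zero-mismatch values of ITS1
(58.64 °C) and ITS4 (50.9 °C); both anchors are reproduced to machine
precision.

**Known limitation.** Under that two-constant calibration the model
reproduces ITS2/ITS3 (56.68 °C) to within 0.02 °C and ITS4-B (59.33 °C)
to within 0.36 °C, but computes ITS5 about 0.8 °C and ITS1-F about
2.2 °C below their reference values. A systematic search across the
published nearest-neighbor tables (Breslauer 1986, SantaLucia 1996 and
1998, Sugimoto 1996) and salt-correction forms found *no*
parameterization whose two environmental constants reproduce the whole
panel to ±0.5 °C; the residual structure suggests the reference values
included template-context contributions (e.g. dangling-end stabilization
from conserved rDNA flanks) that a primer-only duplex computation cannot
recover. The two failing worked-example tests are left failing rather
than widened.

Temperatures are reported in °C, rounded to 2 decimals in output files
only. The Tm of an amplicon's primer is computed against the actual
(possibly mismatched) target window, so `tm_mismatch_profile` gives the
mean ± sd per mismatch count; one internal mismatch costs about 3–10 °C
on the shipped primer panel, which is why mismatch ceilings map onto
annealing-temperature stringency.

## Subset pipeline

Public databases rarely contain the whole rDNA repeat, so evaluation is
hierarchical: subsets are built by outer-pair amplification (NS7–ITS2
for ITS1, ITS5–ITS4 for ITS1+ITS2, ITS3–LR3 for ITS2) at a 1-mismatch
ceiling, and internal primers are then evaluated per subset across
ceilings 0–3. Subset records keep both outer primer sites (normalized to
forward-primer orientation) — required both for idempotence and because
the evaluation schedule reuses outer primers (ITS5–ITS2 on subset 1,
ITS3–ITS4 on subsets 2 and 3). When a source record yields several outer
amplicons only the longest is kept: one subset entry per sequence; this
is a package choice, configurable in principle via the engine's full
amplicon list. Because outer sites are perfect-or-one-mismatch by
construction, a record that enters the subset but fails an internal
evaluation fails on the internal primer — which is what
`mismatch_share` = (P₁ − P₀)/P₁ quantifies.

## Bias statistics

All tables store counts next to explicit denominators; groups or clades
with zero denominator are omitted, never reported as 0 %. Length
comparisons use insert length (primers excluded; `use_total_length`
switches) and Welch's unequal-variance two-tailed t-test — the paper
trail for "two-tailed t-test" rarely states pooled vs Welch, and Welch
is the robust default; a pooled option exists. Differences are signed as
mean(second group) − mean(first group), so the conventional ordering
(ascomycete, basidiomycete) makes a positive difference mean longer
basidiomycete fragments. p-values are raw; no multiple-testing
correction is applied. An alternative analysis — binning lengths into
size classes and testing class proportions — would answer a slightly
different question and is not implemented.

## Synthetic data

Each record is random flanks plus the plus-strand cassette
NS7 · SSU tail · ITS1-F · ITS5 · ITS1 · ITS1 region · 5.8S (with the
shared ITS3/ITS2 locus) · ITS2 region · ITS4 · ITS4-B · LSU head · LR3,
reverse-primer sites planted as reverse complements. Planted mismatches
always substitute a base *incompatible* with the primer's IUPAC set at
that position, outside the protected tail (except in explicit
reject-tail plans), so mismatch counts are exact truth, not
expectations; category allocation uses exact integer counts
(largest-remainder rounding for proportion plans), pooled across cohorts
for database-wide plans. ITS2/ITS3 are exact reverse complements sharing
one 5.8S locus; internal mutations there avoid both primers' tails, and
a tail-reject for one primer is recorded as one internal mismatch for
the other. Plant records carry the universal primer sites but no ITS1-F
or ITS4-B site by default, mirroring the fungal specificity of those
primers.

Default region lengths (mean ± sd bp, minimum-clipped normals) encode
the field's observed structure: ascomycete ITS1/ITS2 230/163 vs
basidiomycete 219/258 — so full-ITS (ITS1–ITS4) inserts average ≈ 551 vs
≈ 635 bp and the ITS2-region difference is ≈ 95 bp — and shorter
non-dikarya ITS1 regions (150). The 5.8S is ≈ 158 bp including the
20 bp shared locus. Background composition is uniform A/C/G/T
(configurable GC skew): composition affects only Tm dispersion, never
matching. A spurious primer site arising by chance in background
sequence would need ≥ 18 specific bases and is vanishingly improbable at
these scales.

What the generator does *not* emulate: phylogenetically realistic
sequence evolution (sites are planted, not evolved), chimeras,
sequencing error, copy-number variation, or the redundancy and
annotation noise of real public databases. Tests passing on synthetic
truth therefore validate the *logic* of the engine and statistics
exactly, but say nothing about absolute amplification counts on real
repositories, which depend on database composition.

Named scenarios (`paper_scenario_config`) plant desk-scale patterns with
exact truth: `its1f_mismatch_profile` (1000 records; ITS1-F sites 36.0 %
perfect, 55.6 % one-mismatch → amplified proportions exactly 0.360/0.916
at ceilings 0/1), `taxonomic_bias` (per-group ITS1 amplifiability
62/86/89 % at ceiling 1 over 300/200/100 records), `order_breakdown`
(basidiomycete clades with planted ITS4-B categories, led by an 18/17/15
Boletales-style row), and `length_bias` (500+500+200 records, perfect
sites, default length structure). Scenario sizes were chosen so the
whole suite runs in well under a minute per scenario while keeping
integer-exact planted proportions and tight sampling error on the
length contrast.

## Numerical and degenerate-input choices

- Mismatch counting aborts early once the ceiling is exceeded; REJECT is
  a sentinel, not an error.
- Amplicon and site orderings are fully specified (stable sorts on
  explicit keys) so outputs are byte-reproducible.
- The generator is deterministic under its seed: one `default_rng`
  drives every draw in a fixed iteration order.
- Degenerate variance in a length comparison (all lengths equal in both
  groups) flags p as undefined rather than producing a spurious 0 or 1.
- A calibration with fewer than two distinct anchors, a primer shorter
  than 8 nt, a gapped target window, or a non-IUPAC character in a
  reference sequence each raise immediately with the offending item
  named.
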