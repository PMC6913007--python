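# Methods

This note records the models, algorithms, parameter choices and known
limitations behind `tekit`. Coordinates are 0-based half-open throughout
the package; GFF3's 1-based closed convention exists only at the I/O
boundary. The class taxonomy is a fixed five-way top level — LTR, nonLTR
(LINE/SINE), TIR (with a MITE flag), Helitron, nonTE — and unknown labels
fold to nonTE/Unknown. IUPAC ambiguity codes other than N are folded to N
with a warning rather than rejected, to tolerate real assemblies.

## Homology masker

The masker is a deliberate desk-scale stand-in for a full repeat masker,
not a reimplementation of one: exact k-mer seeds (k = 13) against an
indexed genome, single-linkage chaining of collinear seeds (gap ≤ 60 bp,
diagonal drift ≤ 15 between consecutive seeds, which tolerates the
cumulative drift of single-base indels), ungapped X-drop extension at
both chain ends (match +1, mismatch −2, drop 12), identity verification
of each chained region by edit distance (edlib), merging of collinear
hits to the same entry separated by ≤ 50 bp in both genome and entry
coordinates, and greedy overlap resolution (higher score wins; ties go to
the longer hit, then the lexicographically smaller entry name; losers are
trimmed to their non-overlapping remainder and kept if still ≥ 80 bp).
Sub-minimum fragments are kept through the merge step and only then
length-filtered — dropping them early loses the ends of diverged copies.

Hits require identity ≥ 1 − `max_divergence` (default 0.40, the
conventional divergence ceiling for whole-genome TE masking), length
≥ `min_hit_length` (80 bp), and score ≥ `min_score`. Score is defined as
aligned length × identity with default threshold 64 — the score of the
weakest hit the 80-80-80 rule recognizes (80 bp at 80% identity) — which
preserves the intent of a masker score cutoff (reject short/noisy hits)
without reproducing any particular scoring matrix. Whitelisted intervals
are subtracted from hits before resolution, which makes masking
idempotent with respect to its own output. The merge distance of 50 bp
is a package choice, exposed in `MaskParams`, and is reused as the
fragment-merging distance in copy classification for cross-module
consistency.

Copy-number counting reuses the masker on one query: non-overlapping
genomic hits covering ≥ 95% of the query at ≥ 80% identity count as
full-length copies. The 80-80-80 test accumulates coverage over
collinear non-overlapping local alignments (fragments ≥ 30 bp) to the
same subject, because fragmented homology is the norm for diverged TEs;
the 80-bp minimum applies to the accumulated aligned total.

## Tandem and SSR detection

`tandem_fraction` detects candidate periods from the distance spectrum
of repeated 4-mers (plus all periods ≤ 6), then scans the lag-p match
profile with tandem-finder-style weights (match +2, mismatch −7,
X-drop): a qualifying array needs score ≥ 80 (so pure arrays of ~40 bp
or more), identity ≥ 80%, and at least two copies. Periods up to 500 bp
are considered. `ssr_span` is an exact scan for perfect repeats of
motif length 1–6 with ≥ 3 copies and ≥ 6 bp, merged over overlaps; the
terminal trimmer removes such arrays only when anchored at a terminus
(e.g. poly-A tails).

## Filtering cascade

Stage 0, per sublibrary: drop candidates shorter than 80 bp (TIR/MITE)
or 100 bp (LTR, Helitron); drop candidates with more than 50,000 Ns or
with > 90% of their bases in tandem arrays; reclassify TIR candidates of
≤ 600 bp as MITEs; keep only Helitron candidates with 5′-TC…CTRR-3′
termini (R = A/G), an A or T immediately left of the insertion and a T
immediately right (the AT/TT target site), and prediction score ≥ 12
when a score is present.

Stage 1: the 60-bp terminal windows of each TIR/Helitron candidate
(30 bp inside + 30 bp outside each boundary) are counted in the genome;
≥ 20 full-length window copies on exactly one side marks a false
positive, on both sides the candidate is rescued as nested unless its
termini are ≥ 20,000-fold more abundant than the joined 60-bp flank
window (the denominator is clamped to 1 when the target site is unique).
Candidates whose terminal 20 bp are more than 15 bp SSR are dropped;
terminal SSR arrays are trimmed from the rest. LTR candidates pass these
class filters unchanged — they are assumed pre-validated upstream.

Reciprocal richness purification: the richness of a candidate in a
sublibrary is its total aligned bp against the sublibrary's other
entries, so many homologous relatives outweigh one. Alignments here are
whole-entry infix alignments (edlib, both strands) at a permissive
identity floor of 0.6 — richness is an abundance estimate and must see
relatives near the 80%-identity edge, exactly as whole-genome masking at
the 40% divergence ceiling would; fragmentary local alignments at a
strict 0.8 floor systematically underestimate borderline-divergent
copies. A candidate is discarded when some other sublibrary covers
≥ 80% of it (the cascade-wide homology-significance floor — partial
homology such as an unexcised nested remnant must not condemn a whole
entry) and the home richness is less than `richness_ratio` (default 2.0)
times the foreign richness. "Not significantly higher" is thus a
deterministic ratio test, not a statistical one. All decisions are
evaluated on the frozen input and applied simultaneously, making the
step order-independent.

Nested/redundancy removal iterates up to five times with early stop.
Each iteration first excises, from any entry, the merged union of
≥ 80%-identity, ≥ 80%-coverage internal copies of shorter entries
(guarded: the union must leave ≥ 80 bp and cover < 95% of the host —
full-length containment is redundancy, not nesting), rejoining the
flanks; then deletes any entry 80-80-80-covered by a longer entry
(ties: the lexicographically smaller name survives). Excision precedes
deletion because a nested element is itself fully covered by its host
and would otherwise be deleted instead of excised. Span totals use the
union of donor spans — many homologous donors align the same interior,
and summing raw spans would overshoot the guard. The output contains no
pair satisfying the 80-80-80 rule.

The optional CDS filter excises spans matching provided coding
sequences at ≥ 80% identity over ≥ 80 bp and drops entries whose
remainder falls under the class length floor.

Every removal is logged with (entry, stage, rule, detail); identical
inputs and configuration give identical outputs, including log order.
Entries are stage-tagged (raw → stage0 → stage1), and each entry passes
a stage once: re-running stage 1 on a stage-1 library is the identity
by construction. An emergent fixed point is not attainable — permissive
richness homology can see cross-class remnants the 0.8-identity
excision rule cannot remove, and once redundancy has collapsed each
family to one exemplar, every home sublibrary looks empty to a
self-excluding abundance measure.

## Benchmarking

Confusion counts are computed strand-insensitively by interval
arithmetic over merged unions: T is the union of curated bases whose
class is in the target set, P the union of all test-annotated bases;
TP = |T∩P|, FN = |T∖P|, FP = |P∖T|, TN = rest, and the four counts sum
to the genome length by construction. Double-covered bases count once.
Undefined (0/0) metrics propagate as None and serialize as "NA" —
absent predictions are not the same as bad predictions. A region
covering exactly 80% of its exemplar is fragmented: "more than 80%" is
strict. Misclassification rates come in two modes: against a reference
(a base annotated in both is inconsistent when the class labels differ)
and self-consistency (overlapping records of different classes mark
their overlap inconsistent), since conventions for the metric differ
between pipelines; outputs label the mode.

## Simulator

The simulator is the package's source of ground truth. Exemplars carry
the class-defining structure: LTR exemplars are LTR–internal–LTR with
identical terminal repeats ≥ 100 bp starting TG and ending CA and a
5-bp TSD; TIR exemplars have exact 12–28-bp terminal inverted repeats
with superfamily-specific TSD lengths (hAT 8, Tc1/Mariner 2, Mutator 9,
PIF/Harbinger 3, CACTA 3); MITEs are TIR-structured under 600 bp;
Helitron exemplars run TC … stem-loop(≥ 6 bp GC-rich stem within the
final 30 bp) … CTRR with no TSD; LINEs/SINEs end in ≥ 8 bp poly-A with
variable 5–15-bp TSDs. Internal sequence is i.i.d. at the configured GC
content.

Insertions are placed sequentially. Each copy is substituted at
`divergence_rate` per base, indel-mutated at `indel_rate` (single-base,
ins/del 50:50, applied before truncation), truncated with
`fragmentation_probability` (removing a uniform 20–80% from one end,
floored so ≥ 80 bp remain), and planted with a class-specific TSD: the
host target site is duplicated and the trailing copy undergoes the same
substitution process as the element. Helitrons insert with no TSD
between an A|T or T|T host dinucleotide, created in background sequence
if absent (never inside a planted TE); Helitron copies are planted
forward-strand only so candidate sequences retain the terminal
signature orientation, other classes insert on either strand. With
`nesting_probability` an insertion lands inside a previously placed
copy (default depth ≤ 2), splitting the host's truth record; the
duplicated target-site copy belongs to neither record, so excising
[element + duplicate site] and rejoining the host records reconstructs
the diverged host copy exactly. Genome growth equals planted element
plus TSD plus tandem-array bases, which the tests verify against the
recorded per-insertion metadata. All randomness flows from one seed;
each operation draws from its own stream derived from it, so the three
operations are independently reproducible.

Default study conditions: one 500-kb chromosome at GC 0.43, five
families per class, ~5–10 copies per family (richness purification is
an abundance test and needs families, not singletons; LINEs are rarer
at 3–6), divergence 0.10, indel rate 0.005, nesting 0.10, fragmentation
0.10. This yields a ~750-kb genome that is ~34% TE — plant-genome-like
density at a size that keeps every test seconds-scale.

Corrupted candidates emulate detector failure modes: pure tandem arrays
(2–6-mers repeated to 200–400 bp, planted in background), sub-80-bp
fragments of real copies, boundary-shifted duplicates, background
intervals labeled Helitron that violate the terminal motif, candidates
spanning a nested pair, and cross-class mislabels. A mislabel replaces
the true candidate for its copy (a detector reports a locus once; an
exact-duplicate twin would tie the richness ratio and remove both
twins), at most one copy per family, only in families with enough
detectable siblings, and only from LTR/TIR/MITE sources — detector
contamination flows into the Helitron candidate set, not out of it, and
the stage-0 terminal-motif filter already thins diverged Helitron
families to few copies, which any foreign full-length twin would then
out-rich.

What the simulator does not emulate — and hence what passing tests do
not show about real data: substitution-model structure (transition
bias, rate heterogeneity, CpG effects), solo-LTR formation,
transduplication of host sequence, low-complexity and satellite
landscapes beyond planted arrays, and realistic family age structure.
Recovery rates on simulated data are upper bounds on real-genome
performance.

## Numerical and degenerate-input choices

Ties in overlap resolution break score → length → name for determinism.
Terminal windows that would extend past a contig leave the candidate
"unevaluated" and kept, with a warning, rather than silently judged.
Empty candidate classes warn and propagate empty. The `-nr`/`-nc`
cleaning thresholds (0.9 tandem fraction, 50,000 Ns) and the literal
20,000-fold terminal ratio are kept as configured defaults even where
they rarely bind at desk scale. Genome sequences must be non-empty;
zero-length intervals are rejected at construction.

## Known limitations

The masker's greedy extension has no affine gaps, so boundary precision
degrades beyond ~20% divergence and structured indels; pairwise copies
at ~0.80 identity sit at the homology threshold and individual pair
decisions there are unstable by construction (the cascade compensates
with abundance, not sharper alignment). Protein-space exclusion is out
of scope: the CDS filter is nucleotide homology only. The terminal
copy-number test needs the genome; coordinate-less candidates pass it
unevaluated. Richness purification assumes multi-copy families — true
single-copy families with a cross-class homolog will be discarded.
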