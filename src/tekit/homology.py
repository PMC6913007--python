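"""Self-contained sequence-comparison engine.

A k-mer seeded, greedily extended homology masker (a desk-scale stand-in
for RepeatMasker-style library masking), genomic copy-number counting,
the 80-80-80 redundancy test, and tandem / SSR detectors.

The masker seeds on shared k-mers, chains collinear seeds, extends
chain ends with an ungapped X-drop walk, verifies identity of each
chained region by edit distance, merges collinear hits to the same
entry, and resolves overlaps by score (ties: longer hit, then
lexicographically smaller entry name). Hits below ``min_hit_length``
or below ``1 - max_divergence`` identity are discarded, mirroring the
cutoff semantics of homology maskers run with a 40% divergence ceiling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
from intervaltree import IntervalTree

from .model import (
    Annotation,
    AnnotationRecord,
    ConfigError,
    Genome,
    LibraryEntry,
    revcomp,
)

logger = logging.getLogger(__name__)

_XDROP = 12          # ungapped extension drop-off (match +1, mismatch -2)
_CHAIN_GAP = 60      # max bp between chained seeds
_CHAIN_BAND = 15     # max diagonal drift between consecutive seeds


@dataclass
class MaskParams:
    """Parameters of the homology masker.

    ``min_score`` is an aligned-length x identity threshold; the default
    64 corresponds to an 80 bp hit at 80% identity, the weakest hit the
    80-80-80 rule recognizes.
    """

    kmer_size: int = 13
    max_divergence: float = 0.40
    min_hit_length: int = 80
    min_score: float = 64.0
    search_both_strands: bool = True
    merge_distance: int = 50
    whitelist: Optional[dict[str, list[tuple[int, int]]]] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.max_divergence < 1.0):
            raise ConfigError("max_divergence must be in (0, 1)")
        if self.kmer_size < 8:
            raise ConfigError("kmer_size must be >= 8")


@dataclass
class Hit:
    """A verified homology hit on the forward genome strand."""

    seq_id: str
    start: int
    end: int
    entry_name: str
    te_class: object
    strand: str
    identity: float
    e_start: int = 0
    e_end: int = 0

    @property
    def score(self) -> float:
        return (self.end - self.start) * self.identity

    def __len__(self) -> int:
        return self.end - self.start


class GenomeIndex:
    """Exact k-mer index of a genome, reusable across queries."""

    def __init__(self, genome: Genome, kmer_size: int = 13):
        self.genome = genome
        self.k = kmer_size
        self.seq_ids = list(genome.sequences)
        self.kmers: dict[str, list[tuple[int, int]]] = {}
        for si, seq_id in enumerate(self.seq_ids):
            seq = genome[seq_id]
            for pos in range(len(seq) - kmer_size + 1):
                kmer = seq[pos:pos + kmer_size]
                if "N" in kmer:
                    continue
                self.kmers.setdefault(kmer, []).append((si, pos))


def _extend_ungapped(gseq: str, eseq: str, gs: int, ge: int,
                     es: int, ee: int) -> tuple[int, int, int, int]:
    """X-drop ungapped extension of [gs,ge) vs [es,ee) at both ends."""
    # right
    score = best = 0
    i = bi = 0
    while ge + i < len(gseq) and ee + i < len(eseq):
        score += 1 if gseq[ge + i] == eseq[ee + i] else -2
        i += 1
        if score > best:
            best, bi = score, i
        elif best - score > _XDROP:
            break
    ge += bi
    ee += bi
    # left
    score = best = 0
    i = bi = 0
    while gs - i > 0 and es - i > 0:
        i += 1
        score += 1 if gseq[gs - i] == eseq[es - i] else -2
        if score > best:
            best, bi = score, i
        elif best - score > _XDROP:
            break
    return gs - bi, ge, es - bi, ee


def _identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def _chain_seeds(seeds: list[tuple[int, int]]) -> list[tuple[int, int, int, int]]:
    """Group (g, e) seeds into collinear chains; returns (gs, ge, es, ee)
    spans not yet including the k-mer width at the right end."""
    seeds.sort()
    chains: list[list[int]] = []  # [gs, g_last, es, e_last]
    active: list[list[int]] = []
    for g, e in seeds:
        placed = False
        still_active = []
        for ch in active:
            if g - ch[1] > _CHAIN_GAP:
                chains.append(ch)
                continue
            still_active.append(ch)
            if placed:
                continue
            diag_drift = abs((g - e) - (ch[1] - ch[3]))
            if e >= ch[3] - 5 and diag_drift <= _CHAIN_BAND:
                ch[1], ch[3] = g, e
                placed = True
        active = still_active
        if not placed:
            active.append([g, g, e, e])
    chains.extend(active)
    return [(c[0], c[1], c[2], c[3]) for c in chains]


def _entry_hits(index: GenomeIndex, entry: LibraryEntry,
                params: MaskParams) -> list[Hit]:
    """All verified, merged hits of one entry against the indexed genome."""
    k = index.k
    hits: list[Hit] = []
    strands = ["+", "-"] if params.search_both_strands else ["+"]
    for strand in strands:
        eseq = entry.sequence if strand == "+" else revcomp(entry.sequence)
        if len(eseq) < k:
            continue
        seeds_by_seq: dict[int, list[tuple[int, int]]] = {}
        for e in range(len(eseq) - k + 1):
            positions = index.kmers.get(eseq[e:e + k])
            if not positions:
                continue
            for si, g in positions:
                seeds_by_seq.setdefault(si, []).append((g, e))
        for si, seeds in seeds_by_seq.items():
            seq_id = index.seq_ids[si]
            gseq = index.genome[seq_id]
            raw = []
            seen: set[tuple[int, int, int, int]] = set()
            for gs, g_last, es, e_last in _chain_seeds(seeds):
                ge, ee = g_last + k, e_last + k
                gs, ge, es, ee = _extend_ungapped(gseq, eseq, gs, ge, es, ee)
                if (gs, ge, es, ee) in seen:
                    continue
                seen.add((gs, ge, es, ee))
                ident = _identity(gseq[gs:ge], eseq[es:ee])
                if ident < 1.0 - params.max_divergence:
                    continue
                # short fragments are kept here: they may merge with
                # collinear neighbours before the length filter applies
                raw.append(Hit(seq_id, gs, ge, entry.name, entry.te_class,
                               strand, ident, es, ee))
            hits.extend(_merge_collinear(raw, gseq, eseq, params))
    return hits


def _merge_collinear(raw: list[Hit], gseq: str, eseq: str,
                     params: MaskParams) -> list[Hit]:
    """Merge collinear hits of the same entry separated by <= merge_distance
    in both genome and entry coordinates."""
    raw.sort(key=lambda h: (h.start, h.end))
    merged: list[Hit] = []
    for h in raw:
        if merged:
            prev = merged[-1]
            g_gap = h.start - prev.end
            e_gap = h.e_start - prev.e_end
            if (-20 <= g_gap <= params.merge_distance
                    and -20 <= e_gap <= params.merge_distance + _CHAIN_BAND
                    and h.e_end > prev.e_end):
                ident = _identity(gseq[prev.start:h.end],
                                  eseq[prev.e_start:h.e_end])
                if ident >= 1.0 - params.max_divergence:
                    merged[-1] = Hit(prev.seq_id, prev.start, h.end,
                                     prev.entry_name, prev.te_class,
                                     prev.strand, ident,
                                     prev.e_start, h.e_end)
                    continue
        merged.append(h)
    return [h for h in merged
            if len(h) >= params.min_hit_length and h.score >= params.min_score]


def _subtract(start: int, end: int,
              tree: IntervalTree) -> list[tuple[int, int]]:
    """Sub-intervals of [start, end) not covered by ``tree``."""
    covered = sorted((max(iv.begin, start), min(iv.end, end))
                     for iv in tree.overlap(start, end))
    pieces = []
    cursor = start
    for s, e in covered:
        if s > cursor:
            pieces.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < end:
        pieces.append((cursor, end))
    return pieces


def resolve_hits(hits: Iterable[Hit], params: MaskParams) -> list[Hit]:
    """Overlap resolution: higher score wins, ties break to the longer hit
    and then the lexicographically smaller entry name; losers are trimmed
    to their non-overlapping remainder and kept if still long enough."""
    ordered = sorted(
        hits, key=lambda h: (-h.score, -(len(h)), h.entry_name,
                             h.seq_id, h.start))
    claimed: dict[str, IntervalTree] = {}
    out: list[Hit] = []
    for h in ordered:
        tree = claimed.setdefault(h.seq_id, IntervalTree())
        for s, e in _subtract(h.start, h.end, tree):
            if e - s < params.min_hit_length:
                continue
            out.append(Hit(h.seq_id, s, e, h.entry_name, h.te_class,
                           h.strand, h.identity, h.e_start, h.e_end))
            tree.addi(s, e)
    out.sort(key=lambda h: (h.seq_id, h.start))
    return out


def _apply_whitelist(hits: list[Hit], params: MaskParams) -> list[Hit]:
    if not params.whitelist:
        return hits
    trees = {seq_id: IntervalTree.from_tuples(ivs)
             for seq_id, ivs in params.whitelist.items() if ivs}
    out = []
    for h in hits:
        tree = trees.get(h.seq_id)
        if tree is None:
            out.append(h)
            continue
        for s, e in _subtract(h.start, h.end, tree):
            if e - s >= params.min_hit_length:
                out.append(Hit(h.seq_id, s, e, h.entry_name, h.te_class,
                               h.strand, h.identity, h.e_start, h.e_end))
    return out


def collect_hits(genome: Genome, library: Sequence[LibraryEntry],
                 params: MaskParams | None = None,
                 index: GenomeIndex | None = None) -> list[Hit]:
    """Verified merged hits for every library entry (pre-resolution)."""
    params = params or MaskParams()
    if not library:
        raise ConfigError("library is empty")
    shortest = min(len(e) for e in library)
    if params.kmer_size > shortest:
        raise ConfigError(
            f"kmer_size {params.kmer_size} exceeds shortest library entry "
            f"({shortest} bp)")
    if index is None:
        index = GenomeIndex(genome, params.kmer_size)
    hits: list[Hit] = []
    for entry in library:
        hits.extend(_entry_hits(index, entry, params))
    return _apply_whitelist(hits, params)


def mask_genome(genome: Genome, library: Sequence[LibraryEntry],
                params: MaskParams | None = None,
                index: GenomeIndex | None = None,
                resolve: bool = True) -> Annotation:
    """Annotate a genome with homology hits to a TE library.

    Returns a resolved (mutually non-overlapping) annotation unless
    ``resolve=False``, in which case the raw overlapping hit set is
    returned (useful for self-consistency analysis).
    """
    params = params or MaskParams()
    hits = collect_hits(genome, library, params, index)
    if resolve:
        hits = resolve_hits(hits, params)
    records = [
        AnnotationRecord(h.seq_id, h.start, h.end, h.strand, h.entry_name,
                         h.te_class, divergence=1.0 - h.identity,
                         score=h.score)
        for h in hits
    ]
    return Annotation(records, resolved=resolve)


def copy_number(genome: Genome, query: str, min_identity: float = 0.8,
                min_coverage: float = 0.95,
                index: GenomeIndex | None = None,
                kmer_size: int = 13) -> int:
    """Number of non-overlapping genomic copies covering >= ``min_coverage``
    of the query at >= ``min_identity``."""
    query = query.upper()
    if len(query) < kmer_size:
        raise ConfigError(
            f"query ({len(query)} bp) shorter than k-mer size {kmer_size}")
    need = int(np.ceil(min_coverage * len(query)))
    params = MaskParams(
        kmer_size=kmer_size,
        max_divergence=1.0 - min_identity,
        min_hit_length=min(need, len(query)),
        min_score=0.0,
    )
    entry = LibraryEntry("__query__", _neutral_class(), query)
    hits = resolve_hits(collect_hits(genome, [entry], params, index), params)
    return sum(1 for h in hits
               if len(h) >= need and h.identity >= min_identity)


def _neutral_class():
    from .model import TEClass
    return TEClass("nonTE", subclass="Unknown")


def subject_coverage(query: LibraryEntry, subject: LibraryEntry,
                     min_identity: float = 0.8,
                     min_fragment: int = 30) -> tuple[int, list[tuple[int, int]]]:
    """bp of ``query`` covered by local alignments to ``subject`` at
    >= ``min_identity``, accumulated over collinear non-overlapping
    fragments of >= ``min_fragment`` bp; also returns the covered spans."""
    params = MaskParams(
        kmer_size=13,
        max_divergence=1.0 - min_identity,
        min_hit_length=min_fragment,
        min_score=min_fragment * min_identity,
    )
    if len(subject) < params.kmer_size or len(query) < params.kmer_size:
        return 0, []
    genome = Genome({"__q__": query.sequence})
    hits = collect_hits(genome, [subject], params)
    spans = _union_spans([(h.start, h.end) for h in hits])
    return sum(e - s for s, e in spans), spans


def _union_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    spans = sorted(spans)
    out: list[tuple[int, int]] = []
    for s, e in spans:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def match_808080(query: LibraryEntry,
                 subject_library: Sequence[LibraryEntry]) -> bool:
    """The 80-80-80 homology rule: true iff some subject aligns >= 80% of
    the query at >= 80% identity over >= 80 aligned bp.

    Coverage may accumulate over collinear non-overlapping local
    alignments to the same subject.
    """
    n = len(query)
    for subject in subject_library:
        if subject.name == query.name:
            continue
        aligned, _ = subject_coverage(query, subject)
        if aligned >= 80 and aligned >= 0.8 * n:
            return True
    return False


def _kmer_partners(queries: Sequence[LibraryEntry],
                   subjects: Sequence[LibraryEntry],
                   min_shared: int = 3, k: int = 13,
                   ) -> dict[str, list[LibraryEntry]]:
    """Shared-k-mer prefilter (either strand): for each query, the
    subjects worth aligning against. Skips self-pairs by name."""
    kmer_subjects: dict[str, set[int]] = {}
    for si, s in enumerate(subjects):
        seen = set()
        for seq in (s.sequence, revcomp(s.sequence)):
            for i in range(0, len(seq) - k + 1, 2):
                seen.add(seq[i:i + k])
        for kmer in seen:
            kmer_subjects.setdefault(kmer, set()).add(si)
    out: dict[str, list[LibraryEntry]] = {}
    for q in queries:
        counts: dict[int, int] = {}
        for i in range(len(q.sequence) - k + 1):
            for si in kmer_subjects.get(q.sequence[i:i + k], ()):
                counts[si] = counts.get(si, 0) + 1
        out[q.name] = [subjects[si] for si, c in counts.items()
                       if c >= min_shared and subjects[si].name != q.name]
    return out


def whole_entry_coverage(query: LibraryEntry, subject: LibraryEntry,
                         min_identity: float = 0.8,
                         ) -> tuple[int, Optional[tuple[int, int]]]:
    """Coverage of ``query`` by one whole-entry alignment to ``subject``.

    The shorter of the two sequences is placed as an infix of the longer
    (both strands); the pair counts only when the overall alignment
    identity reaches ``min_identity``. Returns (aligned bp on the query,
    covered query span), or (0, None). This whole-entry granularity
    suits entry-level decisions (is this candidate a homologous copy of
    that one?) where fragmentary local alignments underestimate
    borderline-divergent copies."""
    a, b = query.sequence, subject.sequence
    if len(b) <= len(a):
        for seq in (b, revcomp(b)):
            res = edlib.align(seq, a, mode="HW", task="locations")
            if res["editDistance"] < 0:
                continue
            if 1.0 - res["editDistance"] / len(seq) >= min_identity:
                s, e = res["locations"][0]
                return e + 1 - s, (s, e + 1)
    else:
        for seq in (a, revcomp(a)):
            res = edlib.align(seq, b, mode="HW", task="distance")
            if res["editDistance"] < 0:
                continue
            if 1.0 - res["editDistance"] / len(seq) >= min_identity:
                return len(a), (0, len(a))
    return 0, None


def whole_coverage_map(entries: Sequence[LibraryEntry],
                       min_identity: float = 0.8,
                       ) -> dict[tuple[str, str], tuple[int, tuple[int, int]]]:
    """All-vs-all whole-entry coverage within one entry set."""
    partners = _kmer_partners(entries, entries)
    out: dict[tuple[str, str], tuple[int, tuple[int, int]]] = {}
    for q in entries:
        for s in partners.get(q.name, []):
            aligned, span = whole_entry_coverage(q, s, min_identity)
            if aligned:
                out[(q.name, s.name)] = (aligned, span)
    return out


def coverage_map(queries: Sequence[LibraryEntry],
                 subjects: Sequence[LibraryEntry],
                 min_identity: float = 0.8,
                 min_fragment: int = 80,
                 min_shared_kmers: int = 3,
                 ) -> dict[tuple[str, str], tuple[int, list[tuple[int, int]]]]:
    """All-vs-all query coverage by subject alignments.

    Returns ``(query_name, subject_name) -> (aligned_bp, spans)`` for pairs
    with any qualifying alignment. A shared-k-mer prefilter (either strand)
    skips unrelated pairs, which dominates real libraries.
    """
    k = 13
    all_partners = _kmer_partners(queries, subjects, min_shared_kmers, k)
    out: dict[tuple[str, str], tuple[int, list[tuple[int, int]]]] = {}
    for q in queries:
        partners = all_partners.get(q.name, [])
        if not partners:
            continue
        params = MaskParams(
            kmer_size=k,
            max_divergence=1.0 - min_identity,
            min_hit_length=min_fragment,
            min_score=min_fragment * min_identity,
        )
        genome = Genome({"__q__": q.sequence})
        index = GenomeIndex(genome, k)
        for subject in partners:
            if len(subject) < k:
                continue
            hits = _entry_hits(index, subject, params)
            spans = _union_spans([(h.start, h.end) for h in hits])
            aligned = sum(e - s for s, e in spans)
            if aligned:
                out[(q.name, subject.name)] = (aligned, spans)
    return out


def richness(entry: LibraryEntry, sublibrary: Sequence[LibraryEntry],
             min_identity: float = 0.8) -> int:
    """Homology-based richness of ``entry`` within a sublibrary: total
    aligned bp summed over subject entries (self excluded by name), so
    that many homologous relatives score higher than one."""
    total = 0
    for subject in sublibrary:
        if subject.name == entry.name:
            continue
        aligned, _ = subject_coverage(entry, subject, min_identity,
                                      min_fragment=80)
        total += aligned
    return total


# ---------------------------------------------------------------------------
# tandem / SSR detection


def _candidate_periods(seq: str, max_period: int = 500) -> list[int]:
    """Periods suggested by distances between repeated 4-mers, plus all
    short periods; capped for desk-scale running time."""
    periods = set(range(1, 7))
    k = 4
    positions: dict[str, int] = {}
    counts: dict[int, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if kmer in positions:
            d = i - positions[kmer]
            if d <= max_period:
                counts[d] = counts.get(d, 0) + 1
        positions[kmer] = i
    frequent = sorted(counts, key=lambda d: -counts[d])
    for d in frequent[:40]:
        if counts[d] >= 3:
            periods.add(d)
    return sorted(p for p in periods if p <= max(1, len(seq) // 2))


def _tandem_runs(match: np.ndarray, period: int,
                 min_identity: float = 0.8,
                 min_score: int = 80) -> list[tuple[int, int]]:
    """Maximal qualifying segments of the lag-``period`` match profile.

    Scoring is match +2 / mismatch -7 with X-drop, echoing classic tandem
    finder weights; a segment qualifies when its score reaches
    ``min_score`` (so pure arrays must be ~40 bp or longer), its identity
    is >= ``min_identity``, and the matched-lag length is >= ``period``
    (i.e., the array holds at least two copies)."""
    runs = []
    n = len(match)
    i = 0
    while i < n:
        if not match[i]:
            i += 1
            continue
        score = best = 0
        best_j = i
        m = mm = best_m = best_mm = 0
        j = i
        while j < n:
            if match[j]:
                score += 2
                m += 1
            else:
                score -= 7
                mm += 1
            j += 1
            if score > best:
                best, best_j, best_m, best_mm = score, j, m, mm
            elif best - score > 28:
                break
        if (best_j - i >= period and best >= min_score
                and best_m / max(best_m + best_mm, 1) >= min_identity):
            runs.append((i, best_j))
        i = max(best_j, i + 1)
    return runs


def tandem_fraction(seq: str, max_period: int = 500) -> float:
    """Fraction of bases covered by tandem arrays (period 1-500, >= 2
    copies, array identity >= 80%)."""
    seq = seq.upper()
    n = len(seq)
    if n < 2:
        return 0.0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    covered = np.zeros(n, dtype=bool)
    for p in _candidate_periods(seq, max_period):
        if p >= n:
            continue
        match = arr[p:] == arr[:-p]
        for s, e in _tandem_runs(match, p):
            covered[s:e + p] = True
    return float(covered.sum()) / n


def ssr_span(window: str, max_period: int = 6) -> int:
    """bp of ``window`` covered by perfect simple sequence repeats of
    motif length 1..max_period with >= 3 copies and >= 6 bp total."""
    window = window.upper()
    n = len(window)
    if n < 6:
        return 0
    covered = np.zeros(n, dtype=bool)
    for p in range(1, max_period + 1):
        i = 0
        while i + p < n:
            if window[i + p] != window[i]:
                i += 1
                continue
            j = i
            while j + p < n and window[j + p] == window[j]:
                j += 1
            array_len = (j - i) + p  # perfect array [i, i+array_len)
            if array_len >= max(3 * p, 6):
                covered[i:i + array_len] = True
            i = j + 1
    return int(covered.sum())


def trim_terminal_ssr(seq: str, max_period: int = 6) -> str:
    """Remove perfect SSR arrays anchored at either terminus (>= 3 copies,
    >= 6 bp), e.g. terminal poly-A runs."""
    def leading_array(s: str) -> int:
        best = 0
        for p in range(1, max_period + 1):
            j = 0
            while j + p < len(s) and s[j + p] == s[j]:
                j += 1
            if j == 0:
                continue
            array_len = j + p
            if array_len >= max(3 * p, 6):
                best = max(best, array_len)
        return best

    seq = seq.upper()
    lead = leading_array(seq)
    seq = seq[lead:]
    trail = leading_array(seq[::-1])
    if trail:
        seq = seq[:-trail]
    return seq
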