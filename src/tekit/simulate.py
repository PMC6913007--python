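"""TE genome simulator.

Generates exemplar libraries with class-specific structural features
(LTR termini and 5-bp TSDs, superfamily-specific TIRs and TSDs, sub-600-bp
MITEs, Helitron TC...CTRR termini with a 3' GC-rich hairpin and AT/TT
target sites, poly-A tailed LINEs/SINEs), genomes with planted -- possibly
nested, truncated, diverged -- insertions, the matching ground-truth
annotation, and deliberately corrupted raw candidate sets.

All randomness flows from a single integer seed; each operation draws
from its own stream derived from that seed so the three operations are
independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .model import (
    Annotation,
    AnnotationRecord,
    CandidateOccurrence,
    ConfigError,
    Genome,
    LibraryEntry,
    TEClass,
    extract_flanks,
    revcomp,
)

logger = logging.getLogger(__name__)

_BASES = "ACGT"

#: TIR superfamilies cycled over TIR/MITE families: (name, TSD length)
TIR_SUPERFAMILIES = (
    ("hAT", 8), ("Tc1_Mariner", 2), ("Mutator", 9),
    ("PIF_Harbinger", 3), ("CACTA", 3),
)
LTR_SUPERFAMILIES = ("Gypsy", "Copia")

#: simulated family kinds and their benchmark classes
KIND_CLASS = {
    "LTR": TEClass("LTR"),
    "TIR": TEClass("TIR"),
    "MITE": TEClass("TIR", subclass="MITE"),
    "Helitron": TEClass("Helitron"),
    "LINE": TEClass("nonLTR", subclass="LINE"),
    "SINE": TEClass("nonLTR", subclass="SINE"),
}


@dataclass
class CorruptionSpec:
    """Counts of deliberately corrupted candidates to emit."""

    tandem: int = 0
    short: int = 0
    mislabel: int = 0
    bad_helitron: int = 0
    boundary_shift: int = 0
    boundary_shift_bp: int = 10
    nested_span: int = 0


@dataclass
class SimulationConfig:
    seed: int = 1
    n_chromosomes: int = 1
    chrom_length: int = 500_000
    gc_content: float = 0.43
    family_counts: dict = field(default_factory=lambda: {
        "LTR": 5, "TIR": 5, "MITE": 5, "Helitron": 5, "LINE": 5, "SINE": 5})
    copy_range: dict = field(default_factory=lambda: {
        "LTR": (6, 9), "TIR": (6, 9), "MITE": (6, 10), "Helitron": (5, 8),
        "LINE": (3, 6), "SINE": (6, 10)})
    length_range: dict = field(default_factory=lambda: {
        "LTR": (1500, 3000), "TIR": (800, 1500), "MITE": (250, 500),
        "Helitron": (1000, 2000), "LINE": (1500, 3000), "SINE": (200, 400)})
    ltr_length_range: tuple = (100, 300)
    divergence_rate: float = 0.10
    indel_rate: float = 0.005
    nesting_probability: float = 0.10
    fragmentation_probability: float = 0.10
    max_nesting_depth: int = 2
    corruption: CorruptionSpec = field(default_factory=CorruptionSpec)

    def __post_init__(self) -> None:
        if isinstance(self.corruption, dict):
            self.corruption = CorruptionSpec(**self.corruption)
        for name in ("nesting_probability", "fragmentation_probability",
                     "gc_content"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 <= self.divergence_rate <= 0.4):
            raise ConfigError("divergence_rate must be in [0, 0.4] "
                              "(the masker's 40% divergence ceiling)")
        if not (0.0 <= self.indel_rate <= 1.0):
            raise ConfigError("indel_rate must be in [0, 1]")
        lo, hi = self.length_range.get("MITE", (250, 500))
        if "MITE" in self.family_counts and self.family_counts["MITE"] and lo >= 600:
            raise ConfigError("MITE minimum length must be < 600 bp")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("copy_range", "length_range", "ltr_length_range"):
            if key in d and isinstance(d[key], dict):
                d[key] = {k: tuple(v) for k, v in d[key].items()}
            elif key in d and isinstance(d[key], (list, tuple)):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class InsertionMeta:
    """Per-insertion ground-truth metadata."""

    copy_id: str
    family: str
    te_class: TEClass
    seq_id: str
    strand: str
    intact: bool
    depth: int
    parent: Optional[str]  # copy_id of the host for nested inserts
    element_len: int
    tsd_len: int
    element_seq: str       # planted (diverged) element sequence


@dataclass
class GroundTruth:
    exemplar_library: list
    truth_annotation: Annotation
    insertions: list
    copy_records: dict          # copy_id -> list[(seq_id, start, end)]
    background_length: int
    tandem_regions: list        # [(seq_id, start, end)]

    def meta_of(self, copy_id: str) -> InsertionMeta:
        return next(m for m in self.insertions if m.copy_id == copy_id)


def _rand_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=p)
    return codes.tobytes().decode()


def _mutate(seq: str, rng: np.random.Generator, sub_rate: float,
            indel_rate: float = 0.0) -> str:
    """i.i.d. substitutions plus single-base indels (ins/del 50:50)."""
    if not seq or (sub_rate == 0 and indel_rate == 0):
        return seq
    n = len(seq)
    subs = rng.random(n) < sub_rate
    indels = rng.random(n) < indel_rate if indel_rate else np.zeros(n, bool)
    is_ins = rng.random(n) < 0.5
    alt_idx = rng.integers(0, 3, n)
    ins_idx = rng.integers(0, 4, n)
    out: list[str] = []
    for i, ch in enumerate(seq):
        c = ch
        if subs[i] and ch in _BASES:
            alts = _BASES.replace(ch, "")
            c = alts[alt_idx[i]]
        if indels[i]:
            if is_ins[i]:
                out.append(_BASES[ins_idx[i]])
                out.append(c)
            # else: deletion, drop c
        else:
            out.append(c)
    return "".join(out) or seq[:1]


# ---------------------------------------------------------------------------
# exemplar construction


def _gc_rich_stem(rng: np.random.Generator, n: int = 8) -> str:
    return _rand_seq(rng, n, 0.95)


def make_exemplars(config: SimulationConfig) -> list[LibraryEntry]:
    """Build one structurally canonical exemplar per configured family."""
    rng = np.random.default_rng([config.seed, 11])
    gc = config.gc_content
    exemplars: list[LibraryEntry] = []
    for kind, n_families in config.family_counts.items():
        if kind not in KIND_CLASS:
            raise ConfigError(f"unknown family kind {kind!r}")
        lo, hi = config.length_range[kind]
        if kind == "MITE" and lo >= 600:
            raise ConfigError("MITE exemplars must be shorter than 600 bp")
        for i in range(n_families):
            total = int(rng.integers(lo, hi + 1))
            name = f"{kind}_f{i + 1}"
            meta: dict = {}
            if kind == "LTR":
                ltr_lo, ltr_hi = config.ltr_length_range
                ltr_len = int(rng.integers(ltr_lo, min(ltr_hi, total // 3) + 1))
                ltr = "TG" + _rand_seq(rng, ltr_len - 4, gc) + "CA"
                internal = _rand_seq(rng, total - 2 * ltr_len, gc)
                seq = ltr + internal + ltr
                superfam = LTR_SUPERFAMILIES[i % len(LTR_SUPERFAMILIES)]
                meta = {"tsd_length": 5, "ltr_length": ltr_len,
                        "terminal_motif": "TG..CA"}
            elif kind in ("TIR", "MITE"):
                superfam, tsd = TIR_SUPERFAMILIES[i % len(TIR_SUPERFAMILIES)]
                tir_len = int(rng.integers(12, 29))
                tir = _rand_seq(rng, tir_len, gc)
                internal = _rand_seq(rng, total - 2 * tir_len, gc)
                seq = tir + internal + revcomp(tir)
                meta = {"tsd_length": tsd, "tir_length": tir_len}
            elif kind == "Helitron":
                stem = _gc_rich_stem(rng, 8)
                loop = _rand_seq(rng, 4, gc)
                rr = "".join(rng.choice(["A", "G"], size=2))
                tail = stem + loop + revcomp(stem) + "CT" + rr
                seq = "TC" + _rand_seq(rng, total - 2 - len(tail), gc) + tail
                superfam = "Helitron"
                meta = {"tsd_length": 0, "terminal_motif": "TC..CTRR",
                        "hairpin_stem": stem}
            else:  # LINE / SINE
                polya = int(rng.integers(8, 16))
                seq = _rand_seq(rng, total - polya, gc) + "A" * polya
                superfam = "L1" if kind == "LINE" else "tRNA"
                meta = {"tsd_length": int(rng.integers(5, 16)),
                        "polya_length": polya}
            te_class = replace(KIND_CLASS[kind], superfamily=superfam)
            exemplars.append(LibraryEntry(name, te_class, seq, stage="final",
                                          structural_meta=meta))
    if not exemplars:
        raise ConfigError("no families configured")
    return exemplars


# ---------------------------------------------------------------------------
# genome construction


@dataclass
class _Block:
    start: int
    end: int
    kind: str            # "te" | "tandem"
    copy_id: Optional[str] = None


def _free_intervals(length: int, blocks: list[_Block],
                    margin: int) -> list[tuple[int, int]]:
    occupied = sorted((b.start, b.end) for b in blocks)
    free = []
    cursor = margin
    for s, e in occupied:
        if s - cursor > 0:
            free.append((cursor, s))
        cursor = max(cursor, e)
    if length - margin > cursor:
        free.append((cursor, length - margin))
    return free


def _pick_free_position(rng, length, blocks, margin, need) -> Optional[int]:
    free = [(s, e) for s, e in _free_intervals(length, blocks, margin)
            if e - s >= need]
    if not free:
        return None
    weights = np.array([e - s - need + 1 for s, e in free], dtype=float)
    idx = int(rng.choice(len(free), p=weights / weights.sum()))
    s, e = free[idx]
    return int(rng.integers(s, e - need + 1))


def _shift_blocks(blocks: list[_Block], at: int, delta: int) -> None:
    for b in blocks:
        if b.start >= at:
            b.start += delta
            b.end += delta
        elif b.end > at:  # host block being split is handled by the caller
            b.end += delta


def simulate_genome(exemplars: list[LibraryEntry],
                    config: SimulationConfig) -> tuple[Genome, GroundTruth]:
    """Plant diverged, possibly truncated and nested TE copies into random
    background sequence; return the genome plus complete ground truth."""
    if not exemplars:
        raise ConfigError("exemplar list is empty")
    rng = np.random.default_rng([config.seed, 23])
    gc = config.gc_content
    by_name = {e.name: e for e in exemplars}

    # per-chromosome background
    chrom_ids = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    seqs = {cid: _rand_seq(rng, config.chrom_length, gc) for cid in chrom_ids}
    background_length = sum(len(s) for s in seqs.values())
    blocks: dict[str, list[_Block]] = {cid: [] for cid in chrom_ids}
    insertions: list[InsertionMeta] = []
    meta_by_id: dict[str, InsertionMeta] = {}
    tandem_regions: list[tuple[str, int, int]] = []

    # planted tandem arrays (background features used as corrupted candidates)
    for t in range(config.corruption.tandem):
        cid = chrom_ids[t % len(chrom_ids)]
        motif = _rand_seq(rng, int(rng.integers(2, 7)), 0.5)
        reps = int(np.ceil(int(rng.integers(200, 401)) / len(motif)))
        array = (motif * reps)
        p = _pick_free_position(rng, len(seqs[cid]), blocks[cid], 100, 1)
        if p is None:
            break
        seqs[cid] = seqs[cid][:p] + array + seqs[cid][p:]
        _shift_blocks(blocks[cid], p, len(array))
        blocks[cid].append(_Block(p, p + len(array), "tandem"))

    # insertion plan: every copy of every family, in a shuffled order so
    # nesting layers arbitrarily across families
    plan: list[str] = []
    for fam in exemplars:
        kind = fam.name.rsplit("_f", 1)[0]
        lo, hi = config.copy_range.get(kind, (3, 6))
        plan.extend([fam.name] * int(rng.integers(lo, hi + 1)))
    plan = [plan[i] for i in rng.permutation(len(plan))]

    required = sum(len(by_name[f]) + 20 for f in plan) + 200 * len(chrom_ids)
    if required > background_length:
        raise ConfigError(
            f"genome too small for requested copies: need >= {required} bp "
            f"of background, have {background_length}")

    copy_counter: dict[str, int] = {}
    for fam_name in plan:
        fam = by_name[fam_name]
        kind = fam_name.rsplit("_f", 1)[0]
        copy_counter[fam_name] = copy_counter.get(fam_name, 0) + 1
        copy_id = f"{fam_name}_c{copy_counter[fam_name]}"
        cid = chrom_ids[int(rng.integers(len(chrom_ids)))]
        seq = seqs[cid]

        strand = "+" if kind == "Helitron" else ("+" if rng.random() < 0.5 else "-")
        element = fam.sequence if strand == "+" else revcomp(fam.sequence)
        element = _mutate(element, rng, config.divergence_rate,
                          config.indel_rate)
        intact = True
        if rng.random() < config.fragmentation_probability:
            cut = int(len(element) * rng.uniform(0.2, 0.8))
            if len(element) - cut >= 80:
                element = element[cut:] if rng.random() < 0.5 else element[:-cut]
                intact = False
        tsd_len = 0 if kind == "Helitron" else int(
            fam.structural_meta.get("tsd_length", 0))

        # choose host (nested) or background position
        parent: Optional[str] = None
        depth = 1
        p: Optional[int] = None
        te_blocks = [b for b in blocks[cid]
                     if b.kind == "te" and b.end - b.start >= 160 + 2 * tsd_len
                     and meta_by_id[b.copy_id].depth < config.max_nesting_depth]
        if te_blocks and rng.random() < config.nesting_probability:
            host = te_blocks[int(rng.integers(len(te_blocks)))]
            lo_p, hi_p = host.start + 50, host.end - 50 - tsd_len
            if kind == "Helitron":
                cands = [q for q in range(lo_p, hi_p)
                         if seq[q - 1] in "AT" and seq[q] == "T"]
                if cands:
                    p = cands[int(rng.integers(len(cands)))]
            else:
                p = int(rng.integers(lo_p, hi_p + 1))
            if p is not None:
                parent = host.copy_id
                depth = meta_by_id[parent].depth + 1
        if p is None:
            p = _pick_free_position(rng, len(seq), blocks[cid], 100,
                                    tsd_len + 3)
            if p is None:
                raise ConfigError(
                    "genome too small: no free interval left for insertion")
            p += 1  # keep p-1 inside the free span (Helitron site rewrite)
            if kind == "Helitron":
                # ensure an AT or TT target site straddles the breakpoint
                if not (seq[p - 1] in "AT" and seq[p] == "T"):
                    left = "A" if rng.random() < 0.5 else "T"
                    seq = seq[:p - 1] + left + "T" + seq[p + 1:]
            parent = None
            depth = 1

        site = seq[p:p + tsd_len]
        site_dup = _mutate(site, rng, config.divergence_rate, 0.0)
        inserted = element + site_dup
        seqs[cid] = seq[:p + tsd_len] + inserted + seq[p + tsd_len:]
        delta = len(inserted)

        host_block = None
        if parent is not None:
            host_block = next(b for b in blocks[cid]
                              if b.copy_id == parent and b.start < p < b.end)
        _shift_blocks([b for b in blocks[cid] if b is not host_block],
                      p, delta)
        if host_block is not None:
            # split host: left part keeps the original target site; the
            # duplicated site copy belongs to neither record
            right = _Block(p + tsd_len + len(element) + tsd_len,
                           host_block.end + delta, "te", host_block.copy_id)
            host_block.end = p + tsd_len
            if right.end > right.start:
                blocks[cid].append(right)
        blocks[cid].append(
            _Block(p + tsd_len, p + tsd_len + len(element), "te", copy_id))

        meta = InsertionMeta(copy_id, fam_name, fam.te_class, cid, strand,
                             intact, depth, parent, len(element), tsd_len,
                             element)
        insertions.append(meta)
        meta_by_id[copy_id] = meta

    # assemble truth
    records = []
    copy_records: dict[str, list[tuple[str, int, int]]] = {}
    for cid in chrom_ids:
        for b in sorted(blocks[cid], key=lambda b: b.start):
            if b.kind == "tandem":
                tandem_regions.append((cid, b.start, b.end))
                continue
            m = meta_by_id[b.copy_id]
            records.append(AnnotationRecord(
                cid, b.start, b.end, m.strand, m.family, m.te_class,
                divergence=config.divergence_rate))
            copy_records.setdefault(b.copy_id, []).append((cid, b.start, b.end))

    genome = Genome(seqs)
    truth = GroundTruth(
        exemplar_library=exemplars,
        truth_annotation=Annotation(records).sorted(),
        insertions=insertions,
        copy_records=copy_records,
        background_length=background_length,
        tandem_regions=tandem_regions,
    )
    assert truth.truth_annotation.resolved
    return genome, truth


# ---------------------------------------------------------------------------
# corrupted candidate sets


_CANDIDATE_KINDS = ("LTR", "TIR", "MITE", "Helitron")
#: cross-class mislabeling emulates detector contamination, which flows
#: from the abundant classes into foreign sublibraries; Helitron copies
#: are not mislabel sources (their sublibrary receives, not donates)
_MISLABEL_TARGETS = {"LTR": "TIR", "TIR": "LTR", "MITE": "LTR"}
_MISLABEL_CLASS = {"LTR": TEClass("LTR", superfamily="Gypsy"),
                   "TIR": TEClass("TIR", superfamily="hAT"),
                   "Helitron": TEClass("Helitron")}


def _occurrence(genome: Genome, name: str,
                te_class: TEClass, cid: str, start: int, end: int,
                corruption: Optional[str] = None,
                score: Optional[int] = None) -> CandidateOccurrence:
    left, right = extract_flanks(genome, cid, start, end, 60)
    meta = {} if score is None else {"prediction_score": int(score)}
    entry = LibraryEntry(name, te_class, genome.fetch(cid, start, end),
                         stage="raw", structural_meta=meta)
    return CandidateOccurrence(entry, cid, start, end, left, right,
                               corruption=corruption)


def make_noisy_candidates(genome: Genome, truth: GroundTruth,
                          config: SimulationConfig) -> list[CandidateOccurrence]:
    """Emit raw candidates: one per detectable planted copy, plus the
    configured corrupted candidates, each tagged with its corruption type."""
    rng = np.random.default_rng([config.seed, 37])
    spec = config.corruption

    detectable: dict[str, list[InsertionMeta]] = {}
    for m in truth.insertions:
        kind = m.family.rsplit("_f", 1)[0]
        if kind not in _CANDIDATE_KINDS:
            continue
        if m.intact and len(truth.copy_records.get(m.copy_id, [])) == 1:
            detectable.setdefault(m.family, []).append(m)

    # mislabel replaces the true candidate for its copy, at most one copy
    # per family; families need enough detectable siblings that richness
    # purification keeps the correctly-labeled rest
    mislabeled: dict[str, InsertionMeta] = {}
    sources = [f for f in sorted(detectable)
               if f.rsplit("_f", 1)[0] in _MISLABEL_TARGETS]
    eligible = ([f for f in sources if len(detectable[f]) >= 5]
                + [f for f in sources if len(detectable[f]) == 4])
    for fam in eligible:
        if len(mislabeled) >= spec.mislabel:
            break
        copies = detectable[fam]
        mislabeled[fam] = copies[int(rng.integers(len(copies)))]
    if len(mislabeled) < spec.mislabel:
        logger.warning("only %d of %d requested mislabeled candidates placed",
                       len(mislabeled), spec.mislabel)

    candidates: list[CandidateOccurrence] = []
    for fam in sorted(detectable):
        kind = fam.rsplit("_f", 1)[0]
        for m in detectable[fam]:
            cid, start, end = truth.copy_records[m.copy_id][0]
            if mislabeled.get(fam) is m:
                wrong_kind = _MISLABEL_TARGETS[kind]
                candidates.append(_occurrence(
                    genome, f"{m.copy_id}_as_{wrong_kind}",
                    _MISLABEL_CLASS[wrong_kind], cid, start, end,
                    corruption="mislabel"))
                continue
            score = int(rng.integers(12, 31)) if kind == "Helitron" else None
            candidates.append(_occurrence(
                genome, m.copy_id, m.te_class, cid, start, end,
                score=score))

    # boundary-shifted extra copies of true candidates (non-Helitron)
    shiftable = [c for c in candidates
                 if c.corruption is None
                 and c.entry.te_class.class_name != "Helitron"]
    for i in range(min(spec.boundary_shift, len(shiftable))):
        c = shiftable[i]
        d = spec.boundary_shift_bp * (1 if rng.random() < 0.5 else -1)
        start, end = c.start, c.end
        if rng.random() < 0.5:
            start = max(60, start + d)
        else:
            end = min(genome.length_of(c.seq_id) - 60, end + d)
        candidates.append(_occurrence(
            genome, f"{c.entry.name}_shift", c.entry.te_class,
            c.seq_id, start, end, corruption="shifted"))

    # planted tandem arrays wrapped as candidates
    for i, (cid, start, end) in enumerate(truth.tandem_regions):
        kind = _CANDIDATE_KINDS[i % 3]  # cycle LTR / TIR / MITE labels
        candidates.append(_occurrence(
            genome, f"tandem_{i + 1}", KIND_CLASS[kind], cid, start,
            end, corruption="tandem"))

    # short fragments of real copies
    te_records = truth.truth_annotation.records
    for i in range(spec.short):
        r = te_records[int(rng.integers(len(te_records)))]
        frag = int(rng.integers(30, 80))
        if len(r) <= frag + 2:
            frag = len(r) - 2
        off = int(rng.integers(0, len(r) - frag))
        candidates.append(_occurrence(
            genome, f"short_{i + 1}", r.te_class, r.seq_id,
            r.start + off, r.start + off + frag, corruption="short"))

    # background intervals mislabeled as Helitrons (terminal motif violated)
    for i in range(spec.bad_helitron):
        for _ in range(200):
            cid = list(genome.sequences)[int(rng.integers(len(genome.sequences)))]
            length = int(rng.integers(300, 801))
            start = int(rng.integers(100, genome.length_of(cid) - length - 100))
            seq = genome.fetch(cid, start, start + length)
            if not seq.startswith("TC"):
                candidates.append(_occurrence(
                    genome, f"badhel_{i + 1}", TEClass("Helitron"),
                    cid, start, start + length, corruption="bad_helitron",
                    score=int(rng.integers(12, 21))))
                break

    # candidates spanning nested pairs (outer span of a split host copy)
    nested_hosts = [cid for cid, recs in truth.copy_records.items()
                    if len(recs) > 1]
    for i, host_id in enumerate(sorted(nested_hosts)[:spec.nested_span]):
        recs = sorted(truth.copy_records[host_id], key=lambda r: r[1])
        cid, start = recs[0][0], recs[0][1]
        end = recs[-1][2]
        m = truth.meta_of(host_id)
        candidates.append(_occurrence(
            genome, f"span_{host_id}", m.te_class, cid, start, end,
            corruption="nested_span"))

    return candidates
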