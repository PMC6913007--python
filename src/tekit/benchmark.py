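"""Base-pair-level benchmarking of TE annotations.

A test annotation is compared against a curated annotation by interval
arithmetic over the genome: every base is a true positive (curated
target and annotated), false negative (target missed), false positive
(annotated but not target), or true negative (neither). Six metrics
derive from the counts. Also: complete/fragmented copy classification
(> 80% of the exemplar length covered counts as complete) and
misclassification-consistency rates between or within annotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .model import (
    Annotation,
    AnnotationRecord,
    BoundsError,
    Genome,
    LibraryEntry,
)


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    intervals = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in intervals:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _intersect_len(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            total += e - s
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


def union_length(records: Iterable[AnnotationRecord]) -> int:
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for r in records:
        by_seq.setdefault(r.seq_id, []).append((r.start, r.end))
    return sum(e - s for ivs in by_seq.values() for s, e in _merge(ivs))


@dataclass(frozen=True)
class ConfusionCounts:
    tp_bp: int
    fp_bp: int
    fn_bp: int
    tn_bp: int

    def __post_init__(self) -> None:
        if min(self.tp_bp, self.fp_bp, self.fn_bp, self.tn_bp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp_bp + self.fp_bp + self.fn_bp + self.tn_bp


@dataclass(frozen=True)
class MetricSet:
    """The six bp-level metrics; None encodes an undefined (0/0) value,
    serialized as "NA"."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]
    precision: Optional[float]
    fdr: Optional[float]
    f1: Optional[float]

    def to_dict(self) -> dict[str, object]:
        return {k: ("NA" if v is None else round(v, 6))
                for k, v in self.__dict__.items()}


def _class_intervals(ann: Annotation, classes: Optional[set[str]]
                     ) -> dict[str, list[tuple[int, int]]]:
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for r in ann:
        if classes is None or r.te_class.class_name in classes:
            by_seq.setdefault(r.seq_id, []).append((r.start, r.end))
    return {k: _merge(v) for k, v in by_seq.items()}


def confusion_counts(curated: Annotation, test: Annotation,
                     target_classes: Optional[set[str]],
                     genome: Genome) -> ConfusionCounts:
    """bp-level confusion counts of ``test`` against the target subset of
    ``curated`` (records whose class is in ``target_classes``; None means
    all classes). Strand-insensitive; double-covered bases count once."""
    for ann in (curated, test):
        ann.validate(genome)
    T = _class_intervals(curated, target_classes)
    P = _class_intervals(test, None)
    t_len = sum(e - s for ivs in T.values() for s, e in ivs)
    p_len = sum(e - s for ivs in P.values() for s, e in ivs)
    tp = sum(_intersect_len(T.get(sid, []), P.get(sid, []))
             for sid in set(T) | set(P))
    fn = t_len - tp
    fp = p_len - tp
    tn = genome.total_length - (t_len + p_len - tp)
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: float, den: float) -> Optional[float]:
    return None if den == 0 else num / den


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Sensitivity, specificity, accuracy, precision, FDR and F1 from
    bp-level confusion counts; 0/0 yields None ("NA")."""
    tp, fp, fn, tn = counts.tp_bp, counts.fp_bp, counts.fn_bp, counts.tn_bp
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    acc = _ratio(tp + tn, counts.total)
    prec = _ratio(tp, tp + fp)
    fdr = None if prec is None else 1.0 - prec
    if prec is None or sens is None or prec + sens == 0:
        f1 = None
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return MetricSet(sens, spec, acc, prec, fdr, f1)


def benchmark_annotation(curated: Annotation, test: Annotation,
                         target_classes: Optional[set[str]],
                         genome: Genome) -> tuple[ConfusionCounts, MetricSet]:
    counts = confusion_counts(curated, test, target_classes, genome)
    return counts, compute_metrics(counts)


def classify_copies(curated_library: Sequence[LibraryEntry],
                    annotation: Annotation,
                    merge_distance: int = 50,
                    complete_threshold: float = 0.80,
                    ) -> dict[str, tuple[int, int]]:
    """Per-entry (complete, fragmented) copy counts.

    Adjacent records of the same entry separated by <= ``merge_distance``
    form one region; a region whose aligned bp exceed ``complete_threshold``
    of the exemplar length (strict >) is a complete copy, anything less a
    fragment."""
    lengths = {e.name: len(e) for e in curated_library}
    by_entry: dict[str, dict[str, list[AnnotationRecord]]] = {}
    for r in annotation:
        if r.entry_name not in lengths:
            raise ValueError(f"record references unknown entry {r.entry_name!r}")
        by_entry.setdefault(r.entry_name, {}).setdefault(r.seq_id, []).append(r)
    out: dict[str, tuple[int, int]] = {name: (0, 0) for name in lengths}
    for name, by_seq in by_entry.items():
        complete = fragmented = 0
        need = complete_threshold * lengths[name]
        for recs in by_seq.values():
            recs.sort(key=lambda r: r.start)
            region_bp = 0
            region_end = None
            def flush(bp: int) -> None:
                nonlocal complete, fragmented
                if bp > need:
                    complete += 1
                elif bp > 0:
                    fragmented += 1
            for r in recs:
                if region_end is not None and r.start - region_end > merge_distance:
                    flush(region_bp)
                    region_bp = 0
                region_bp += len(r)
                region_end = r.end if region_end is None else max(region_end, r.end)
            flush(region_bp)
        out[name] = (complete, fragmented)
    return out


def _labeled_intervals(ann: Annotation) -> dict[str, list[tuple[int, int, str]]]:
    by_seq: dict[str, list[tuple[int, int, str]]] = {}
    for r in ann:
        by_seq.setdefault(r.seq_id, []).append(
            (r.start, r.end, r.te_class.class_name))
    for v in by_seq.values():
        v.sort()
    return by_seq


def misclassification_rate(annotation: Annotation,
                           reference: Optional[Annotation] = None
                           ) -> dict[str, float]:
    """Classification-consistency rates.

    Reference mode: a base annotated in both is inconsistent when the
    two class labels differ; per-class rates are inconsistent bp over
    total reference bp of that class, overall is inconsistent bp over
    co-annotated bp. Self mode (no reference): overlapping records with
    different classes mark their overlap inconsistent; overall is
    inconsistent bp over all annotated bp.
    """
    rates: dict[str, float] = {}
    if reference is not None:
        ref = _labeled_intervals(reference)
        test = _labeled_intervals(annotation)
        incons_by_class: dict[str, int] = {}
        ref_bp: dict[str, int] = {}
        overlap_bp = 0
        inconsistent = 0
        for sid, ref_ivs in ref.items():
            for s, e, cls in ref_ivs:
                ref_bp[cls] = ref_bp.get(cls, 0) + (e - s)
            test_ivs = test.get(sid, [])
            for rs, re_, rcls in ref_ivs:
                for ts, te, tcls in test_ivs:
                    s, e = max(rs, ts), min(re_, te)
                    if s >= e:
                        continue
                    overlap_bp += e - s
                    if tcls != rcls:
                        inconsistent += e - s
                        incons_by_class[rcls] = (
                            incons_by_class.get(rcls, 0) + (e - s))
        for cls, total in ref_bp.items():
            rates[cls] = incons_by_class.get(cls, 0) / total if total else 0.0
        rates["overall"] = inconsistent / overlap_bp if overlap_bp else 0.0
        return rates

    # self mode: conflicts among overlapping records of one annotation
    by_seq = _labeled_intervals(annotation)
    annotated = 0
    inconsistent = 0
    incons_by_class: dict[str, int] = {}
    bp_by_class: dict[str, int] = {}
    for sid, ivs in by_seq.items():
        bounds = sorted({x for s, e, _ in ivs for x in (s, e)})
        for a, b in zip(bounds, bounds[1:]):
            classes = {cls for s, e, cls in ivs if s < b and e > a}
            if not classes:
                continue
            annotated += b - a
            for cls in classes:
                bp_by_class[cls] = bp_by_class.get(cls, 0) + (b - a)
            if len(classes) > 1:
                inconsistent += b - a
                for cls in classes:
                    incons_by_class[cls] = incons_by_class.get(cls, 0) + (b - a)
    for cls, total in bp_by_class.items():
        rates[cls] = incons_by_class.get(cls, 0) / total if total else 0.0
    rates["overall"] = inconsistent / annotated if annotated else 0.0
    return rates
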