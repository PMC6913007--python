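"""Domain model for TE library construction and annotation benchmarking.

Coordinates are 0-based half-open everywhere inside the package; 1-based
closed GFF3 coordinates exist only at the I/O boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: top-level benchmark categories
TE_CLASSES = ("LTR", "nonLTR", "TIR", "Helitron", "nonTE")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


class FormatError(ValueError):
    """Malformed input file content."""


class BoundsError(ValueError):
    """Interval outside the coordinate space of its sequence."""


class ConfigError(ValueError):
    """Infeasible or inconsistent configuration."""


@dataclass(frozen=True)
class TEClass:
    """Hierarchical TE classification.

    ``class_name`` is one of the five benchmark categories (LTR, nonLTR,
    TIR, Helitron, nonTE). ``subclass`` refines it (LINE/SINE under nonLTR,
    MITE under TIR); ``superfamily`` is free text (hAT, Gypsy, ...).
    """

    class_name: str
    subclass: Optional[str] = None
    superfamily: Optional[str] = None

    def __post_init__(self) -> None:
        if self.class_name not in TE_CLASSES:
            raise ValueError(f"unknown TE class {self.class_name!r}")
        if self.subclass == "MITE" and self.class_name != "TIR":
            raise ValueError("MITE subclass requires class TIR")
        if self.subclass in ("LINE", "SINE") and self.class_name != "nonLTR":
            raise ValueError(f"{self.subclass} subclass requires class nonLTR")

    @property
    def is_mite(self) -> bool:
        return self.subclass == "MITE"

    def rm_name(self) -> str:
        """Serialize to the RepeatMasker ``Class/Superfamily`` convention."""
        if self.class_name == "LTR":
            return f"LTR/{self.superfamily or 'unknown'}"
        if self.class_name == "nonLTR":
            if self.subclass in ("LINE", "SINE"):
                return f"{self.subclass}/{self.superfamily or 'unknown'}"
            return "nonLTR/unknown"
        if self.class_name == "TIR":
            prefix = "MITE" if self.is_mite else "DNA"
            return f"{prefix}/{self.superfamily or 'unknown'}"
        if self.class_name == "Helitron":
            return "DNA/Helitron"
        return "Unknown"


def parse_rm_name(header: str) -> tuple[str, TEClass]:
    """Parse a ``name#Class/Superfamily`` FASTA header into (name, TEClass).

    Lenient by design: anything unrecognized maps to nonTE/Unknown.
    """
    header = header.strip()
    if not header:
        raise ValueError("empty header")
    if "#" not in header:
        return header, TEClass("nonTE", subclass="Unknown")
    name, _, label = header.partition("#")
    cls, _, superfam = label.partition("/")
    cls_l = cls.strip()
    superfam = superfam.strip() or None
    if cls_l == "LTR":
        return name, TEClass("LTR", superfamily=superfam)
    if cls_l == "LINE":
        return name, TEClass("nonLTR", subclass="LINE", superfamily=superfam)
    if cls_l == "SINE":
        return name, TEClass("nonLTR", subclass="SINE", superfamily=superfam)
    if cls_l in ("DNA", "RC"):
        if superfam and superfam.lower() == "helitron":
            return name, TEClass("Helitron")
        if cls_l == "RC":
            return name, TEClass("Helitron")
        return name, TEClass("TIR", superfamily=superfam)
    if cls_l == "MITE":
        return name, TEClass("TIR", subclass="MITE", superfamily=superfam)
    if cls_l == "Helitron":
        return name, TEClass("Helitron")
    if cls_l == "nonLTR":
        return name, TEClass("nonLTR", superfamily=superfam)
    return name, TEClass("nonTE", subclass="Unknown")


class Genome:
    """Ordered, named DNA sequences over {A,C,G,T,N}."""

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("genome must contain at least one sequence")
        norm: dict[str, str] = {}
        for seq_id, seq in sequences.items():
            if not seq:
                raise ValueError(f"sequence {seq_id!r} is empty")
            norm[seq_id] = seq.upper()
        self.sequences = norm

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __getitem__(self, seq_id: str) -> str:
        return self.sequences[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.sequences

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def length_of(self, seq_id: str) -> int:
        return len(self.sequences[seq_id])

    def fetch(self, seq_id: str, start: int, end: int) -> str:
        self.check_interval(seq_id, start, end)
        return self.sequences[seq_id][start:end]

    def check_interval(self, seq_id: str, start: int, end: int) -> None:
        if seq_id not in self.sequences:
            raise BoundsError(f"unknown sequence {seq_id!r}")
        if not (0 <= start < end <= len(self.sequences[seq_id])):
            raise BoundsError(
                f"interval [{start},{end}) outside {seq_id!r} "
                f"(length {len(self.sequences[seq_id])})"
            )

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Genome) and self.sequences == other.sequences


@dataclass
class LibraryEntry:
    """A named TE exemplar sequence with classification and stage tag."""

    name: str
    te_class: TEClass
    sequence: str
    stage: str = "raw"  # raw | stage0 | stage1 | final
    structural_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"entry {self.name!r} has empty sequence")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)

    def header(self) -> str:
        return f"{self.name}#{self.te_class.rm_name()}"


@dataclass
class AnnotationRecord:
    """A genomic interval attributed to a library entry."""

    seq_id: str
    start: int
    end: int
    strand: str
    entry_name: str
    te_class: TEClass
    divergence: float = 0.0
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"bad interval [{self.start},{self.end}) for {self.entry_name}"
            )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def key(self) -> tuple:
        return (
            self.seq_id, self.start, self.end, self.strand, self.entry_name,
            self.te_class, round(self.divergence, 6),
        )


class Annotation:
    """An ordered collection of annotation records.

    ``resolved`` is True when no two records on the same sequence overlap.
    """

    def __init__(self, records: Iterable[AnnotationRecord] = (),
                 resolved: bool | None = None):
        self.records: list[AnnotationRecord] = list(records)
        self.resolved = self._check_resolved() if resolved is None else resolved

    def _check_resolved(self) -> bool:
        by_seq: dict[str, list[AnnotationRecord]] = {}
        for r in self.records:
            by_seq.setdefault(r.seq_id, []).append(r)
        for recs in by_seq.values():
            recs = sorted(recs, key=lambda r: r.start)
            for a, b in zip(recs, recs[1:]):
                if b.start < a.end:
                    return False
        return True

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AnnotationRecord]:
        return iter(self.records)

    def sorted(self) -> "Annotation":
        recs = sorted(self.records, key=lambda r: (r.seq_id, r.start, r.end))
        return Annotation(recs, resolved=self.resolved)

    def filter(self, pred) -> "Annotation":
        return Annotation([r for r in self.records if pred(r)])

    def total_bp(self) -> int:
        """bp covered by the union of all records."""
        from .benchmark import union_length  # local import avoids a cycle
        return union_length(self.records)

    def validate(self, genome: Genome) -> None:
        for r in self.records:
            try:
                genome.check_interval(r.seq_id, r.start, r.end)
            except BoundsError as exc:
                raise BoundsError(f"record {r.entry_name}: {exc}") from exc


@dataclass
class CandidateOccurrence:
    """A raw TE candidate anchored to genomic coordinates.

    Flanks hold up to 60 bp of host sequence on each side (shorter at
    contig edges) so terminal-structure and target-site filters can run.
    ``corruption`` tags simulator-planted defects (None for clean
    candidates); real input has None throughout.
    """

    entry: LibraryEntry
    seq_id: str
    start: int
    end: int
    left_flank: str = ""
    right_flank: str = ""
    corruption: Optional[str] = None

    def __len__(self) -> int:
        return self.end - self.start


def extract_flanks(genome: Genome, seq_id: str, start: int, end: int,
                   flank_bp: int) -> tuple[str, str]:
    """Up-to-``flank_bp`` host bases on each side of [start, end).

    Truncated at sequence edges; never includes the element itself.
    """
    genome.check_interval(seq_id, start, end)
    seq = genome[seq_id]
    left = seq[max(0, start - flank_bp):start]
    right = seq[end:end + flank_bp]
    return left, right
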