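"""Readers and writers: FASTA, BED6, GFF3, RepeatMasker-style naming.

All readers accept gzip-compressed files (by ``.gz`` suffix). BED is
0-based half-open; GFF3 is 1-based closed and converted at this boundary
only. IUPAC ambiguity codes other than N are folded to N with a warning.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    Annotation,
    AnnotationRecord,
    BoundsError,
    FormatError,
    Genome,
    LibraryEntry,
    TEClass,
    VALID_BASES,
    parse_rm_name,
)

logger = logging.getLogger(__name__)

_AMBIGUITY = set("RYSWKMBDHV")


def _open_text(path: Union[str, Path], mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _normalize_sequence(raw: str, path, record_name: str) -> str:
    """Uppercase; fold non-N ambiguity codes to N; reject anything else."""
    seq = raw.upper()
    bad = set(seq) - VALID_BASES
    if not bad:
        return seq
    ambiguous = bad & _AMBIGUITY
    illegal = bad - _AMBIGUITY
    if illegal:
        residue = sorted(illegal)[0]
        raise FormatError(
            f"{path}: illegal residue {residue!r} in record {record_name!r} "
            f"(line {_find_residue_line(path, residue)})"
        )
    logger.warning(
        "%s: folding ambiguity codes %s to N in record %s",
        path, "".join(sorted(ambiguous)), record_name,
    )
    table = str.maketrans({c: "N" for c in ambiguous})
    return seq.translate(table)


def _find_residue_line(path, residue: str) -> int:
    """Locate the first sequence line containing ``residue`` (error path)."""
    try:
        with _open_text(path) as fh:
            for i, line in enumerate(fh, 1):
                if line.startswith(">"):
                    continue
                if residue in line.upper():
                    return i
    except OSError:
        pass
    return -1


def read_fasta_genome(path: Union[str, Path]) -> Genome:
    """Read a FASTA file as a genome (uppercase-normalized, order kept)."""
    sequences: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in sequences:
                raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
            sequences[rec.id] = _normalize_sequence(str(rec.seq), path, rec.id)
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found")
    return Genome(sequences)


def read_fasta_library(path: Union[str, Path],
                       stage: str = "raw") -> list[LibraryEntry]:
    """Read a FASTA library; headers parsed via the ``name#Class/Superfamily``
    RepeatMasker convention."""
    entries: list[LibraryEntry] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            name, te_class = parse_rm_name(rec.id)
            if name in seen:
                raise FormatError(f"{path}: duplicate entry name {name!r}")
            seen.add(name)
            seq = _normalize_sequence(str(rec.seq), path, name)
            entries.append(LibraryEntry(name, te_class, seq, stage=stage))
    if not entries:
        raise FormatError(f"{path}: no FASTA records found")
    return entries


def write_fasta(items: Union[Genome, Iterable[LibraryEntry]],
                path: Union[str, Path]) -> None:
    """Write a genome or a library to FASTA, wrapped at 60 columns."""
    if isinstance(items, Genome):
        records = [SeqRecord(Seq(seq), id=seq_id, description="")
                   for seq_id, seq in items.sequences.items()]
    else:
        records = [SeqRecord(Seq(e.sequence), id=e.header(), description="")
                   for e in items]
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def _record_to_bed(r: AnnotationRecord) -> str:
    name = f"{r.entry_name}#{r.te_class.rm_name()}"
    return "\t".join([
        r.seq_id, str(r.start), str(r.end), name,
        f"{r.score:g}", r.strand, f"{r.divergence:.6g}",
    ])


def _record_to_gff3(r: AnnotationRecord) -> str:
    attrs = (
        f"Name={r.entry_name};"
        f"Classification={r.te_class.rm_name()};"
        f"Identity={1.0 - r.divergence:.6g}"
    )
    return "\t".join([
        r.seq_id, "tekit", "dispersed_repeat",
        str(r.start + 1), str(r.end), f"{r.score:g}", r.strand, ".", attrs,
    ])


def write_annotation(ann: Annotation, path: Union[str, Path],
                     format: str = "BED") -> None:
    fmt = format.upper()
    with _open_text(path, "wt") as fh:
        if fmt == "GFF3":
            fh.write("##gff-version 3\n")
            for r in ann.sorted():
                fh.write(_record_to_gff3(r) + "\n")
        elif fmt == "BED":
            for r in ann.sorted():
                fh.write(_record_to_bed(r) + "\n")
        else:
            raise ValueError(f"unknown annotation format {format!r}")


def _parse_bed_line(line: str, path, lineno: int) -> AnnotationRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 4:
        raise FormatError(f"{path}:{lineno}: BED line has <4 columns")
    seq_id, start, end = fields[0], int(fields[1]), int(fields[2])
    name, te_class = parse_rm_name(fields[3])
    score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
    strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
    divergence = 0.0
    if len(fields) > 6:  # optional extension column; ignore non-numeric
        try:
            divergence = float(fields[6])
        except ValueError:
            pass
    return AnnotationRecord(seq_id, start, end, strand, name, te_class,
                            divergence=divergence, score=score)


def _parse_gff3_line(line: str, path, lineno: int) -> AnnotationRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 9:
        raise FormatError(f"{path}:{lineno}: GFF3 line has {len(fields)} columns")
    seq_id = fields[0]
    start = int(fields[3]) - 1  # to 0-based half-open
    end = int(fields[4])
    score = 0.0 if fields[5] == "." else float(fields[5])
    strand = fields[6] if fields[6] in "+-" else "+"
    attrs = dict(
        kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
    )
    name = attrs.get("Name", "unknown")
    classification = attrs.get("Classification", "Unknown")
    _, te_class = parse_rm_name(f"x#{classification}")
    identity = float(attrs.get("Identity", 1.0))
    return AnnotationRecord(seq_id, start, end, strand, name, te_class,
                            divergence=1.0 - identity, score=score)


def read_annotation(path: Union[str, Path], format: str = "BED",
                    genome: Genome | None = None) -> Annotation:
    """Read BED or GFF3 into an Annotation (internal 0-based half-open).

    When a genome is supplied, out-of-bounds records raise BoundsError.
    """
    fmt = format.upper()
    parse = {"BED": _parse_bed_line, "GFF3": _parse_gff3_line}.get(fmt)
    if parse is None:
        raise ValueError(f"unknown annotation format {format!r}")
    records = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            records.append(parse(line, path, lineno))
    ann = Annotation(records)
    if genome is not None:
        ann.validate(genome)
    return ann
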