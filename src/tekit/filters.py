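"""The TE library filtering cascade.

Stage 0 applies per-sublibrary basic cleaning: tandem/short/N removal,
MITE reclassification of short TIR candidates, and the Helitron
terminal-structure + target-site + score filter. Stage 1 applies
advanced false-positive removal: the 60-bp terminal copy-number test,
terminal SSR screening, reciprocal richness purification between
sublibraries, aggregation, iterative nested-insertion/redundancy
removal, and an optional CDS homology filter. LTR candidates are assumed
pre-validated and pass the stage-1 class filters unchanged.

Every removal is logged as ``(entry, stage, rule, detail)``; the cascade
is deterministic for identical inputs and configuration.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

from .homology import (
    GenomeIndex,
    coverage_map,
    copy_number,
    ssr_span,
    tandem_fraction,
    trim_terminal_ssr,
    whole_coverage_map,
)
from .model import (
    CandidateOccurrence,
    Genome,
    LibraryEntry,
    TEClass,
)

logger = logging.getLogger(__name__)

_HELITRON_END = re.compile(r"CT[AG][AG]$")

RemovalLog = list  # of dicts {entry, stage, rule, detail}


@dataclass
class FilterConfig:
    min_len_tir: int = 80
    min_len_other: int = 100
    max_missing: int = 50_000          # max N count per candidate
    max_tandem_fraction: float = 0.9
    mite_max_len: int = 600
    helitron_min_score: int = 12
    terminal_window: int = 60
    terminal_copy_threshold: int = 20
    target_ratio_threshold: int = 20_000
    ssr_window: int = 20
    ssr_max_bp: int = 15
    nested_iterations: int = 5
    richness_ratio: float = 2.0
    # richness homology is permissive (like whole-genome masking at the
    # 40% divergence ceiling): abundance estimation must see relatives
    # that sit near the 80% identity edge
    richness_min_identity: float = 0.6
    complete_copy_threshold: float = 0.80

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if isinstance(v, (int, float)) and v <= 0:
                raise ValueError(f"{name} must be positive")

    def min_length(self, te_class: TEClass) -> int:
        return (self.min_len_tir if te_class.class_name == "TIR"
                else self.min_len_other)

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown filter config keys: {sorted(unknown)}")
        return cls(**d)


def _log(log: Optional[RemovalLog], entry: str, stage: str, rule: str,
         detail: str = "") -> None:
    if log is not None:
        log.append({"entry": entry, "stage": stage, "rule": rule,
                    "detail": detail})
    logger.info("removed %s at %s by %s %s", entry, stage, rule, detail)


Candidate = Union[LibraryEntry, CandidateOccurrence]


def _entry(c: Candidate) -> LibraryEntry:
    return c.entry if isinstance(c, CandidateOccurrence) else c


# ---------------------------------------------------------------------------
# stage 0


def basic_clean(candidates: Sequence[Candidate], te_class: TEClass | None,
                config: FilterConfig | None = None,
                log: Optional[RemovalLog] = None) -> list[Candidate]:
    """Drop short, N-riddled, and tandem-dominated candidates.

    Minimum length is 80 bp for TIR (incl. MITE) candidates and 100 bp
    for everything else; candidates with more Ns than ``max_missing`` or
    with > 90% of their bases in tandem arrays are removed.
    """
    config = config or FilterConfig()
    kept: list[Candidate] = []
    for c in candidates:
        e = _entry(c)
        min_len = config.min_length(te_class or e.te_class)
        if len(e) < min_len:
            _log(log, e.name, "stage0", "min_length",
                 f"{len(e)} < {min_len}")
            continue
        n_count = e.sequence.count("N")
        if n_count > config.max_missing:
            _log(log, e.name, "stage0", "missing_data",
                 f"{n_count} Ns > {config.max_missing}")
            continue
        tf = tandem_fraction(e.sequence)
        if tf > config.max_tandem_fraction:
            _log(log, e.name, "stage0", "tandem",
                 f"tandem fraction {tf:.2f} > {config.max_tandem_fraction}")
            continue
        kept.append(c)
    return kept


def reclassify_mites(tir_candidates: Sequence[Candidate],
                     config: FilterConfig | None = None) -> list[Candidate]:
    """Flag TIR candidates of <= 600 bp as MITEs; nothing is dropped."""
    config = config or FilterConfig()
    out: list[Candidate] = []
    for c in tir_candidates:
        e = _entry(c)
        if e.te_class.class_name != "TIR":
            raise ValueError(f"{e.name}: reclassify_mites expects TIR input")
        if len(e) <= config.mite_max_len and not e.te_class.is_mite:
            new_class = replace(e.te_class, subclass="MITE")
            new_entry = replace(e, te_class=new_class)
            if isinstance(c, CandidateOccurrence):
                c = replace(c, entry=new_entry)
            else:
                c = new_entry
        out.append(c)
    return out


def helitron_structural_filter(candidates: Sequence[CandidateOccurrence],
                               config: FilterConfig | None = None,
                               log: Optional[RemovalLog] = None,
                               ) -> list[CandidateOccurrence]:
    """Keep only candidates with the 5'-TC...CTRR-3' terminal signature,
    an AT or TT host target site, and prediction score >= 12 (if given)."""
    config = config or FilterConfig()
    kept = []
    for c in candidates:
        e = c.entry
        seq = e.sequence
        if not c.left_flank or not c.right_flank:
            _log(log, e.name, "stage0", "no_flank", "contig edge")
            continue
        if not seq.startswith("TC"):
            _log(log, e.name, "stage0", "helitron_5p", seq[:2])
            continue
        if not _HELITRON_END.search(seq):
            _log(log, e.name, "stage0", "helitron_3p", seq[-4:])
            continue
        if not (c.left_flank[-1] in "AT" and c.right_flank[0] == "T"):
            _log(log, e.name, "stage0", "target_site",
                 c.left_flank[-1] + "|" + c.right_flank[0])
            continue
        score = e.structural_meta.get("prediction_score")
        if score is not None and score < config.helitron_min_score:
            _log(log, e.name, "stage0", "helitron_score",
                 f"{score} < {config.helitron_min_score}")
            continue
        kept.append(c)
    return kept


def run_stage0(candidates: dict[str, list[CandidateOccurrence]],
               genome: Genome | None = None,
               config: FilterConfig | None = None,
               log: Optional[RemovalLog] = None,
               ) -> dict[str, list[CandidateOccurrence]]:
    """Basic cleaning per sublibrary: length/N/tandem filters, MITE
    reclassification (TIR), terminal-structure filter (Helitron)."""
    config = config or FilterConfig()
    out: dict[str, list[CandidateOccurrence]] = {}
    for cls in ("LTR", "TIR", "Helitron"):
        subs = candidates.get(cls, [])
        if not subs:
            logger.warning("stage0: empty %s candidate set", cls)
            out[cls] = []
            continue
        class_hint = TEClass(cls) if cls != "Helitron" else TEClass("Helitron")
        kept = basic_clean(subs, class_hint, config, log)
        if cls == "TIR":
            kept = reclassify_mites(kept, config)
        if cls == "Helitron":
            kept = helitron_structural_filter(kept, config, log)
        for c in kept:
            c.entry.stage = "stage0"
        out[cls] = kept
    return out


# ---------------------------------------------------------------------------
# stage 1


def terminal_copy_filter(candidates: Sequence[CandidateOccurrence],
                         genome: Genome,
                         config: FilterConfig | None = None,
                         index: GenomeIndex | None = None,
                         log: Optional[RemovalLog] = None,
                         ) -> tuple[list[CandidateOccurrence], dict[str, str]]:
    """Terminal copy-number test for falsely extended elements.

    60-bp windows centered on each boundary are counted in the genome;
    abundant full-length window copies (>= 20) on one side mark a false
    positive, abundance on both sides triggers the target-site rescue:
    the candidate survives as a nested true candidate unless its termini
    are >= 20,000-fold more abundant than the joined 60-bp flank window.
    """
    config = config or FilterConfig()
    if index is None:
        index = GenomeIndex(genome, 13)
    half = config.terminal_window // 2
    thr = config.terminal_copy_threshold
    kept: list[CandidateOccurrence] = []
    verdicts: dict[str, str] = {}
    for c in candidates:
        name = c.entry.name
        L = genome.length_of(c.seq_id)
        if c.start - half < 0 or c.end + half > L:
            logger.warning("terminal windows beyond contig for %s", name)
            verdicts[name] = "unevaluated"
            kept.append(c)
            continue
        seq = genome[c.seq_id]
        w_start = seq[c.start - half:c.start + half]
        w_end = seq[c.end - half:c.end + half]
        c_start = copy_number(genome, w_start, index=index)
        c_end = copy_number(genome, w_end, index=index)
        if c_start < thr and c_end < thr:
            verdicts[name] = "true_candidate"
            kept.append(c)
            continue
        if c_start >= thr and c_end >= thr:
            w_tsd = seq[c.start - half:c.start] + seq[c.end:c.end + half]
            c_tsd = copy_number(genome, w_tsd, index=index)
            if max(c_start, c_end) < config.target_ratio_threshold * max(c_tsd, 1):
                verdicts[name] = "nested_true_candidate"
                kept.append(c)
                continue
            verdicts[name] = "false_positive"
            _log(log, name, "stage1", "terminal_copy",
                 f"start={c_start} end={c_end} tsd={c_tsd}")
            continue
        verdicts[name] = "false_positive"
        _log(log, name, "stage1", "terminal_copy",
             f"start={c_start} end={c_end}")
    return kept, verdicts


def ssr_terminal_filter(candidates: Sequence[Candidate],
                        config: FilterConfig | None = None,
                        log: Optional[RemovalLog] = None) -> list[Candidate]:
    """Drop elements whose terminal 20 bp are > 15 bp SSR; trim terminal
    SSR arrays from retained elements and re-check the length floor."""
    config = config or FilterConfig()
    w, cap = config.ssr_window, config.ssr_max_bp
    kept: list[Candidate] = []
    for c in candidates:
        e = _entry(c)
        seq = e.sequence
        head, tail = ssr_span(seq[:w]), ssr_span(seq[-w:])
        if head > cap or tail > cap:
            _log(log, e.name, "stage1", "ssr_terminal",
                 f"head={head} tail={tail} > {cap}/{w}")
            continue
        trimmed = trim_terminal_ssr(seq)
        if trimmed != seq:
            if len(trimmed) < config.min_length(e.te_class):
                _log(log, e.name, "stage1", "ssr_trim_short",
                     f"{len(trimmed)} bp after trim")
                continue
            e = replace(e, sequence=trimmed)
            c = replace(c, entry=e) if isinstance(c, CandidateOccurrence) else e
        kept.append(c)
    return kept


def richness_purify(sublibraries: dict[str, list[LibraryEntry]],
                    config: FilterConfig | None = None,
                    log: Optional[RemovalLog] = None,
                    ) -> dict[str, list[LibraryEntry]]:
    """Reciprocal cross-sublibrary purification.

    The richness of a candidate in a sublibrary is its total aligned bp
    against the sublibrary's other entries, so many homologous relatives
    score higher than one. A candidate is discarded from its home
    sublibrary when some other sublibrary covers at least 80% of it
    (the cascade's homology-significance floor) and is at least half as
    rich (home < ratio x other): abundance that is not clearly
    concentrated in the home class marks a misclassified entry.
    Decisions are evaluated on the frozen input state and applied
    simultaneously, so the result is order-independent.
    """
    config = config or FilterConfig()
    if len(sublibraries) < 2:
        return {k: list(v) for k, v in sublibraries.items()}
    all_entries = [e for lib in sublibraries.values() for e in lib]
    cov = whole_coverage_map(all_entries,
                             min_identity=config.richness_min_identity)

    def rich(entry: LibraryEntry, lib: list[LibraryEntry]) -> int:
        return sum(cov.get((entry.name, s.name), (0, None))[0]
                   for s in lib if s.name != entry.name)

    def union_coverage(entry: LibraryEntry, lib: list[LibraryEntry]) -> int:
        spans = [cov[(entry.name, s.name)][1] for s in lib
                 if s.name != entry.name and (entry.name, s.name) in cov]
        from .homology import _union_spans
        return sum(e - s for s, e in _union_spans(spans))

    out: dict[str, list[LibraryEntry]] = {}
    for home, lib in sublibraries.items():
        kept = []
        for e in lib:
            r_home = rich(e, lib)
            contaminant = False
            for other, other_lib in sublibraries.items():
                if other == home:
                    continue
                r_other = rich(e, other_lib)
                if (r_other > 0
                        and union_coverage(e, other_lib) >= 0.8 * len(e)
                        and r_home < config.richness_ratio * r_other):
                    _log(log, e.name, "stage1", "richness",
                         f"{home}={r_home} < {config.richness_ratio}x"
                         f"{other}={r_other}")
                    contaminant = True
                    break
            if not contaminant:
                kept.append(e)
        out[home] = kept
    return out


def _excise(sequence: str, spans: list[tuple[int, int]]) -> str:
    """Remove spans (merged, sorted) and rejoin the flanks."""
    merged: list[list[int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out = []
    cursor = 0
    for s, e in merged:
        out.append(sequence[cursor:s])
        cursor = e
    out.append(sequence[cursor:])
    return "".join(out)


def remove_nested_redundancy(library: Sequence[LibraryEntry],
                             config: FilterConfig | None = None,
                             log: Optional[RemovalLog] = None,
                             ) -> tuple[list[LibraryEntry], int]:
    """Iteratively excise nested insertions and delete redundant entries.

    Per iteration: (a) any >= 80%-identity, >= 80%-coverage internal copy
    of a shorter entry is excised from its host and the flanks rejoined
    (guarded so the host keeps >= 80 bp); (b) any entry 80-80-80-matched
    by a longer (or equal-length, smaller-name) entry is deleted. Up to
    ``nested_iterations`` rounds with early stop; returns the library and
    the number of iterations run. The output is non-redundant under the
    80-80-80 rule.
    """
    config = config or FilterConfig()
    entries = list(library)
    iterations = 0
    for _ in range(config.nested_iterations):
        if len(entries) <= 1:
            break
        iterations += 1
        changed = False
        cov = coverage_map(entries, entries, min_identity=0.8,
                           min_fragment=64)
        by_name = {e.name: e for e in entries}

        # (a) excise internal copies of shorter entries
        from .homology import _union_spans
        new_entries: list[LibraryEntry] = []
        for host in entries:
            spans: list[tuple[int, int]] = []
            for donor in entries:
                if donor.name == host.name or len(donor) >= len(host):
                    continue
                aligned, d_spans = cov.get((host.name, donor.name), (0, []))
                if aligned >= 0.8 * len(donor) and aligned >= 64:
                    spans.extend(d_spans)
            if spans:
                spans = _union_spans(spans)
                total = sum(e - s for s, e in spans)
                remainder = len(host) - total
                if total < 0.95 * len(host) and remainder >= 80:
                    new_seq = _excise(host.sequence, spans)
                    _log(log, host.name, "stage1", "nested_excision",
                         f"removed {len(host) - len(new_seq)} bp "
                         f"({len(spans)} spans)")
                    new_entries.append(replace(host, sequence=new_seq))
                    changed = True
                    continue
            new_entries.append(host)
        entries = new_entries

        # (b) delete entries covered by a longer entry (simultaneous)
        if changed:
            cov = coverage_map(entries, entries, min_identity=0.8,
                               min_fragment=64)
        doomed: set[str] = set()
        for e in entries:
            for f in entries:
                if f.name == e.name:
                    continue
                longer = (len(f) > len(e)
                          or (len(f) == len(e) and f.name < e.name))
                if not longer:
                    continue
                aligned, _ = cov.get((e.name, f.name), (0, []))
                if aligned >= 80 and aligned >= 0.8 * len(e):
                    doomed.add(e.name)
                    _log(log, e.name, "stage1", "redundant",
                         f"covered by {f.name}")
                    break
        if doomed:
            entries = [e for e in entries if e.name not in doomed]
            changed = True
        if not changed:
            break
    logger.info("nested/redundancy removal converged after %d iterations",
                iterations)
    return entries, iterations


def cds_filter(library: Sequence[LibraryEntry],
               cds_sequences: Sequence[LibraryEntry] | None,
               config: FilterConfig | None = None,
               log: Optional[RemovalLog] = None) -> list[LibraryEntry]:
    """Excise spans matching coding sequence at >= 80% identity over
    >= 80 bp; drop entries whose remainder falls below the class length
    floor. No-op when no CDS is provided."""
    config = config or FilterConfig()
    if not cds_sequences:
        return list(library)
    cov = coverage_map(library, cds_sequences, min_identity=0.8,
                       min_fragment=80)
    out: list[LibraryEntry] = []
    for e in library:
        spans: list[tuple[int, int]] = []
        for cds in cds_sequences:
            _, c_spans = cov.get((e.name, cds.name), (0, []))
            spans.extend(c_spans)
        if not spans:
            out.append(e)
            continue
        new_seq = _excise(e.sequence, spans)
        if len(new_seq) < config.min_length(e.te_class):
            _log(log, e.name, "stage1", "cds",
                 f"{len(new_seq)} bp after CDS removal")
            continue
        if len(new_seq) != len(e):
            _log(log, e.name, "stage1", "cds_trim",
                 f"excised {len(e) - len(new_seq)} bp")
            e = replace(e, sequence=new_seq)
        out.append(e)
    return out


def run_stage1(stage0: dict[str, list[CandidateOccurrence]],
               genome: Genome | None = None,
               config: FilterConfig | None = None,
               cds_sequences: Sequence[LibraryEntry] | None = None,
               log: Optional[RemovalLog] = None) -> list[LibraryEntry]:
    """Advanced filtering: terminal copy-number and SSR screens for TIR
    and Helitron sublibraries (LTR passes unchanged), reciprocal richness
    purification, aggregation, iterative nested/redundancy removal, and
    the optional CDS filter.

    Each entry passes stage 1 once: a library already tagged stage1 is
    returned unchanged, so re-running the stage is a fixed point."""
    config = config or FilterConfig()
    all_in = [_entry(c) for cands in stage0.values() for c in cands]
    if all_in and all(e.stage == "stage1" for e in all_in):
        return all_in
    index = GenomeIndex(genome, 13) if genome is not None else None
    filtered: dict[str, list[LibraryEntry]] = {}
    for cls, cands in stage0.items():
        if not cands:
            filtered[cls] = []
            continue
        if cls == "LTR":
            filtered[cls] = [_entry(c) for c in cands]
            continue
        kept: Sequence[Candidate] = cands
        if genome is not None:
            occ = [c for c in kept if isinstance(c, CandidateOccurrence)]
            bare = [c for c in kept if not isinstance(c, CandidateOccurrence)]
            occ_kept, _ = terminal_copy_filter(occ, genome, config, index, log)
            kept = list(occ_kept) + bare
        kept = ssr_terminal_filter(kept, config, log)
        filtered[cls] = [_entry(c) for c in kept]

    purified = richness_purify(filtered, config, log)
    aggregated = [e for cls in ("LTR", "TIR", "Helitron")
                  for e in purified.get(cls, [])]
    aggregated.extend(e for cls in purified
                      if cls not in ("LTR", "TIR", "Helitron")
                      for e in purified[cls])
    library, _ = remove_nested_redundancy(aggregated, config, log)
    library = cds_filter(library, cds_sequences, config, log)
    out = []
    for e in library:
        e = replace(e, stage="stage1")
        out.append(e)
    return out


def annotate_known(library: Sequence[LibraryEntry],
                   curated: Sequence[LibraryEntry]) -> list[LibraryEntry]:
    """Mark entries 80-80-80-matching a prior curated library as known
    (``structural_meta['known'] = True``); the rest are novel."""
    from .homology import match_808080
    out = []
    for e in library:
        meta = dict(e.structural_meta)
        meta["known"] = match_808080(e, curated)
        out.append(replace(e, structural_meta=meta))
    return out
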