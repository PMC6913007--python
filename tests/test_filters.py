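"""Unit tests of every rule in the library-filtering cascade."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import mutate_positions, random_dna
from tekit.filters import (
    FilterConfig,
    basic_clean,
    cds_filter,
    helitron_structural_filter,
    reclassify_mites,
    remove_nested_redundancy,
    richness_purify,
    run_stage1,
    ssr_terminal_filter,
    terminal_copy_filter,
)
from tekit.model import (
    CandidateOccurrence,
    Genome,
    LibraryEntry,
    TEClass,
)


def _names(items):
    out = []
    for x in items:
        out.append(x.entry.name if isinstance(x, CandidateOccurrence) else x.name)
    return out


class TestBasicClean:
    @pytest.mark.parametrize("length,cls,kept", [
        (79, "TIR", False), (80, "TIR", True),
        (99, "LTR", False), (100, "LTR", True),
        (99, "Helitron", False), (100, "Helitron", True),
    ])
    def test_length_floor(self, rng, entry_factory, length, cls, kept):
        e = entry_factory("x", random_dna(rng, length), cls)
        result = basic_clean([e], TEClass(cls))
        assert bool(result) is kept

    def test_tandem_candidate_dropped(self, entry_factory):
        e = entry_factory("t", "TA" * 200, "TIR")
        assert basic_clean([e], TEClass("TIR")) == []

    def test_n_rich_candidate_dropped(self, rng, entry_factory):
        cfg = FilterConfig(max_missing=50)
        ok = entry_factory("ok", random_dna(rng, 200) + "N" * 50, "LTR")
        bad = entry_factory("bad", random_dna(rng, 200) + "N" * 51, "LTR")
        kept = basic_clean([ok, bad], TEClass("LTR"), cfg)
        assert _names(kept) == ["ok"]

    def test_survivors_unchanged(self, rng, entry_factory):
        e = entry_factory("x", random_dna(rng, 500), "LTR")
        [kept] = basic_clean([e], TEClass("LTR"))
        assert kept.sequence == e.sequence


class TestReclassifyMites:
    @pytest.mark.parametrize("length,is_mite", [
        (600, True), (601, False), (80, True)])
    def test_boundary(self, rng, entry_factory, length, is_mite):
        e = entry_factory("x", random_dna(rng, length), "TIR")
        [out] = reclassify_mites([e])
        assert out.te_class.is_mite is is_mite

    def test_nothing_dropped(self, rng, entry_factory):
        entries = [entry_factory(f"x{i}", random_dna(rng, 100 + 200 * i), "TIR")
                   for i in range(5)]
        assert len(reclassify_mites(entries)) == 5


def _helitron_occ(rng, name="h1", seq=None, left="G" * 59 + "A",
                  right="T" + "G" * 59, score=14):
    if seq is None:
        seq = "TC" + random_dna(rng, 300) + "CTAG"
    meta = {} if score is None else {"prediction_score": score}
    entry = LibraryEntry(name, TEClass("Helitron"), seq, structural_meta=meta)
    return CandidateOccurrence(entry, "chr1", 1000, 1000 + len(seq),
                               left, right)


class TestHelitronStructuralFilter:
    def test_canonical_candidate_kept(self, rng):
        assert len(helitron_structural_filter([_helitron_occ(rng)])) == 1

    def test_wrong_5p_terminal_rejected(self, rng):
        occ = _helitron_occ(rng, seq="GC" + random_dna(rng, 300) + "CTAG")
        assert helitron_structural_filter([occ]) == []

    def test_wrong_3p_terminal_rejected(self, rng):
        occ = _helitron_occ(rng, seq="TC" + random_dna(rng, 300) + "CTTC")
        assert helitron_structural_filter([occ]) == []

    @pytest.mark.parametrize("score,kept", [(11, False), (12, True),
                                            (None, True)])
    def test_score_threshold(self, rng, score, kept):
        occ = _helitron_occ(rng, score=score)
        assert bool(helitron_structural_filter([occ])) is kept

    def test_bad_target_site_rejected(self, rng):
        occ = _helitron_occ(rng, left="G" * 60)
        assert helitron_structural_filter([occ]) == []
        occ = _helitron_occ(rng, right="G" * 60)
        assert helitron_structural_filter([occ]) == []

    def test_missing_flank_rejected_with_reason(self, rng):
        log = []
        occ = _helitron_occ(rng, left="")
        assert helitron_structural_filter([occ], None, log) == []
        assert log[0]["rule"] == "no_flank"


class TestTerminalCopyFilter:
    """Genomes are assembled so the 60-bp terminal windows of a candidate
    have controlled copy numbers."""

    def _build(self, rng, n_start, n_end, n_tsd=0):
        left = random_dna(rng, 200)
        element = random_dna(rng, 400)
        right = random_dna(rng, 200)
        w_start = left[-30:] + element[:30]
        w_end = element[-30:] + right[:30]
        w_tsd = left[-30:] + right[:30]
        pieces = [random_dna(rng, 120)]
        for _ in range(n_start - 1):
            pieces += [w_start, random_dna(rng, 90)]
        for _ in range(n_end - 1):
            pieces += [w_end, random_dna(rng, 90)]
        for _ in range(n_tsd):
            pieces += [w_tsd, random_dna(rng, 90)]
        pieces += [left, element, right, random_dna(rng, 120)]
        genome = Genome({"c": "".join(pieces)})
        start = genome.total_length - 120 - 200 - 400
        occ = CandidateOccurrence(
            LibraryEntry("cand", TEClass("TIR"), element),
            "c", start, start + 400, left[-60:], right[:60])
        return genome, occ

    def test_both_termini_rare_is_true_candidate(self, rng):
        genome, occ = self._build(rng, 5, 5)
        kept, verdicts = terminal_copy_filter([occ], genome)
        assert verdicts["cand"] == "true_candidate"
        assert _names(kept) == ["cand"]

    def test_one_abundant_terminus_is_false_positive(self, rng):
        genome, occ = self._build(rng, 25, 3)
        kept, verdicts = terminal_copy_filter([occ], genome)
        assert verdicts["cand"] == "false_positive"
        assert kept == []

    def test_both_abundant_rescued_as_nested(self, rng):
        genome, occ = self._build(rng, 25, 30, n_tsd=28)
        kept, verdicts = terminal_copy_filter([occ], genome)
        assert verdicts["cand"] == "nested_true_candidate"
        assert _names(kept) == ["cand"]

    def test_window_beyond_contig_unevaluated(self, rng):
        element = random_dna(rng, 200)
        genome = Genome({"c": element + random_dna(rng, 500)})
        occ = CandidateOccurrence(
            LibraryEntry("edge", TEClass("TIR"), element), "c", 0, 200)
        kept, verdicts = terminal_copy_filter([occ], genome)
        assert verdicts["edge"] == "unevaluated"
        assert _names(kept) == ["edge"]


class TestSsrTerminalFilter:
    def test_full_ssr_terminus_dropped(self, rng, entry_factory):
        e = entry_factory("x", "AT" * 10 + random_dna(rng, 300), "TIR")
        assert ssr_terminal_filter([e]) == []

    def test_boundary_15_vs_16(self, rng, entry_factory):
        body = "GTCAGGCATGCGTACGGTAC" + random_dna(rng, 260)
        keep = entry_factory("keep", "A" * 15 + "GCGTA" + body, "TIR")
        drop = entry_factory("drop", "A" * 16 + "GCTA" + body, "TIR")
        kept = ssr_terminal_filter([keep, drop])
        assert _names(kept) == ["keep"]

    def test_short_polya_trimmed_not_dropped(self, rng, entry_factory):
        body = random_dna(np.random.default_rng(77), 290)
        e = entry_factory("x", body + "A" * 10, "TIR")
        [out] = ssr_terminal_filter([e])
        assert len(out) == 290
        assert out.sequence == body

    def test_internal_ssr_untouched(self, rng, entry_factory):
        seq = ("GTCAGGCATG" + random_dna(rng, 100) + "AT" * 30
               + random_dna(rng, 100) + "CATGCGGTCA")
        e = entry_factory("x", seq, "TIR")
        [out] = ssr_terminal_filter([e])
        assert out.sequence == seq


class TestRichnessPurify:
    def _family(self, rng, name, n, length=500):
        base = random_dna(rng, length)
        out = [LibraryEntry(f"{name}0", TEClass("LTR"), base)]
        for i in range(1, n):
            pos = sorted(rng.choice(length, 25, replace=False).tolist())
            out.append(LibraryEntry(f"{name}{i}", TEClass("LTR"),
                                    mutate_positions(base, pos)))
        return out

    def test_verbatim_contaminant_removed_from_foreign_sublibrary(self, rng):
        ltr = self._family(rng, "ltr", 4)  # original + 3 relatives
        dup = LibraryEntry("dup", TEClass("TIR"), ltr[0].sequence)
        other_tir = LibraryEntry("tir1", TEClass("TIR"), random_dna(rng, 400))
        out = richness_purify({"LTR": ltr, "TIR": [dup, other_tir]})
        assert "dup" not in _names(out["TIR"])
        assert _names(out["LTR"]) == _names(ltr)
        assert "tir1" in _names(out["TIR"])

    def test_no_cross_homology_retained(self, rng):
        a = [LibraryEntry("a", TEClass("LTR"), random_dna(rng, 400))]
        b = [LibraryEntry("b", TEClass("TIR"), random_dna(rng, 400))]
        out = richness_purify({"LTR": a, "TIR": b})
        assert _names(out["LTR"]) == ["a"] and _names(out["TIR"]) == ["b"]

    def test_equal_richness_removed_from_target(self, rng):
        seq = random_dna(rng, 400)
        cand = LibraryEntry("cand", TEClass("LTR"), seq)
        twin_home = LibraryEntry("home_twin", TEClass("LTR"), seq)
        twin_away = LibraryEntry("away_twin", TEClass("TIR"), seq)
        out = richness_purify({"LTR": [cand, twin_home],
                               "TIR": [twin_away]})
        assert "cand" not in _names(out["LTR"])


class TestRemoveNestedRedundancy:
    def test_exact_nesting_excised(self, rng):
        x, a, y = random_dna(rng, 300), random_dna(rng, 200), random_dna(rng, 300)
        lib = [LibraryEntry("B", TEClass("LTR"), x + a + y),
               LibraryEntry("A", TEClass("TIR"), a)]
        out, iters = remove_nested_redundancy(lib)
        seqs = {e.name: e.sequence for e in out}
        assert seqs == {"B": x + y, "A": a}
        assert iters <= 5

    def test_duplicate_collapses_to_smaller_name(self, rng):
        q = random_dna(rng, 250)
        lib = [LibraryEntry("zz", TEClass("LTR"), q),
               LibraryEntry("aa", TEClass("LTR"), q)]
        out, _ = remove_nested_redundancy(lib)
        assert _names(out) == ["aa"]

    def test_longer_survivor_on_containment(self, rng):
        q = random_dna(rng, 300)
        lib = [LibraryEntry("long", TEClass("LTR"), q),
               LibraryEntry("short", TEClass("LTR"), q[10:])]
        out, _ = remove_nested_redundancy(lib)
        assert _names(out) == ["long"]

    def test_doubly_nested_converges_quickly(self, rng):
        x, z, y = random_dna(rng, 250), random_dna(rng, 250), random_dna(rng, 250)
        a = random_dna(rng, 150)
        lib = [LibraryEntry("B", TEClass("LTR"), x + a + z + a + y),
               LibraryEntry("A", TEClass("TIR"), a)]
        out, iters = remove_nested_redundancy(lib)
        seqs = {e.name: e.sequence for e in out}
        assert seqs["B"] == x + z + y
        assert iters <= 2

    def test_output_non_redundant(self, rng):
        from tekit.homology import match_808080
        seqs = [random_dna(rng, 400) for _ in range(3)]
        lib = ([LibraryEntry(f"u{i}", TEClass("LTR"), s)
                for i, s in enumerate(seqs)]
               + [LibraryEntry("dup0", TEClass("LTR"), seqs[0]),
                  LibraryEntry("nest", TEClass("TIR"),
                               seqs[1][:200] + seqs[2] + seqs[1][200:])])
        out, _ = remove_nested_redundancy(lib)
        for e in out:
            assert not match_808080(e, [f for f in out if f.name != e.name])


class TestCdsFilter:
    def test_internal_cds_excised_and_rejoined(self, rng):
        te1, te2 = random_dna(rng, 200), random_dna(rng, 200)
        cds = random_dna(rng, 300)
        lib = [LibraryEntry("e", TEClass("LTR"), te1 + cds + te2)]
        cds_lib = [LibraryEntry("cds1", TEClass("nonTE", subclass="Unknown"),
                                cds)]
        [out] = cds_filter(lib, cds_lib)
        assert out.sequence == te1 + te2

    def test_pure_cds_entry_dropped(self, rng):
        cds = random_dna(rng, 300)
        lib = [LibraryEntry("e", TEClass("LTR"), cds)]
        cds_lib = [LibraryEntry("cds1", TEClass("nonTE", subclass="Unknown"),
                                cds)]
        assert cds_filter(lib, cds_lib) == []

    def test_no_cds_is_identity(self, rng):
        lib = [LibraryEntry("e", TEClass("LTR"), random_dna(rng, 300))]
        assert cds_filter(lib, None) == lib


class TestStagePipeline:
    def test_ltr_sublibrary_passes_stage1_class_filters(self, rng):
        """Clean LTR candidates are sequence-identical through stage 1."""
        entries = [LibraryEntry(f"ltr{i}", TEClass("LTR"), random_dna(rng, 600))
                   for i in range(3)]
        occs = [CandidateOccurrence(e, "c", 0, len(e)) for e in entries]
        lib = run_stage1({"LTR": occs, "TIR": [], "Helitron": []})
        assert sorted(_names(lib)) == ["ltr0", "ltr1", "ltr2"]
        seqs = {e.name: e.sequence for e in lib}
        for e in entries:
            assert seqs[e.name] == e.sequence

    def test_stage1_is_idempotent(self, cascade_result):
        _, stage1, _ = cascade_result
        by_class: dict[str, list] = {"LTR": [], "TIR": [], "Helitron": []}
        for e in stage1:
            by_class.setdefault(e.te_class.class_name, []).append(e)
        again = run_stage1(by_class)
        assert sorted((e.name, e.sequence) for e in again) == \
               sorted((e.name, e.sequence) for e in stage1)

    def test_removals_are_logged_per_rule(self, cascade_result):
        _, _, log = cascade_result
        rules = {row["rule"] for row in log}
        assert {"tandem", "min_length", "richness"} <= rules
        for row in log:
            assert set(row) == {"entry", "stage", "rule", "detail"}
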