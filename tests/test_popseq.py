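"""Indel-event detection, recoding, diagnostic sites, haplotype panels."""

import random

import pytest

from conftest import consensus_row, hap_row, make_alignment
from fernhybrid.errors import AlignmentError, DataError, RoleError
from fernhybrid.popseq import (
    collapse_haplotypes,
    detect_indel_events,
    diagnostic_sites,
    polymorphism_summary,
    recode_matrix,
)
from fernhybrid.seqio import Role, Taxon


class TestIndelEvents:
    def test_five_bp_indel_is_one_event(self):
        aln = make_alignment(
            [hap_row("a", "AC-----T"), hap_row("b", "ACGGGGGT")]
        )
        events = detect_indel_events(aln)
        assert len(events) == 1
        assert (events[0].start, events[0].end) == (2, 7)
        assert events[0].length == 5
        assert events[0].presence == {"a": False, "b": True}

    def test_gapless_alignment_has_no_events(self):
        aln = make_alignment([hap_row("a", "ACGT"), hap_row("b", "ACGA")])
        assert detect_indel_events(aln) == []

    def test_adjacent_columns_with_different_patterns_split(self):
        aln = make_alignment(
            [hap_row("a", "A--T"), hap_row("b", "AG-T"), hap_row("c", "A-CT")]
        )
        events = detect_indel_events(aln)
        assert [(e.start, e.end) for e in events] == [(1, 2), (2, 3)]

    def test_all_gap_column_rejected(self):
        aln = make_alignment([hap_row("a", "A-T"), hap_row("b", "A-T")])
        with pytest.raises(AlignmentError, match="all-gap"):
            detect_indel_events(aln)

    def test_matches_bruteforce_column_grouping(self):
        """Events == maximal runs of gapped columns with equal presence
        pattern, checked against a direct per-column oracle."""
        rng = random.Random(11)
        for _ in range(30):
            n, L = rng.randint(2, 5), rng.randint(5, 25)
            rows = []
            for i in range(n):
                rows.append(
                    "".join(rng.choice("AC-") for _ in range(L))
                )
            # avoid all-gap columns
            rows = [
                "".join(
                    "A" if all(r[c] == "-" for r in rows) and i == 0 else r[c]
                    for c in range(L)
                )
                for i, r in enumerate(rows)
            ]
            aln = make_alignment([hap_row(f"s{i}", r) for i, r in enumerate(rows)])
            events = detect_indel_events(aln)
            # oracle: per-column patterns, grouped greedily
            expected = []
            prev = None
            for c in range(L):
                col = [r[c] for r in rows]
                if "-" in col:
                    pat = tuple(ch != "-" for ch in col)
                    if prev is not None and prev[1] == pat and prev[0][-1] == c - 1:
                        prev[0].append(c)
                    else:
                        prev = ([c], pat)
                        expected.append(prev)
                else:
                    prev = None
            assert [(e.start, e.end) for e in events] == [
                (cols[0], cols[-1] + 1) for cols, _ in expected
            ]


class TestRecode:
    def test_indel_becomes_single_binary_character(self):
        aln = make_alignment(
            [hap_row("a", "AC-----T"), hap_row("b", "ACGGGGGT")]
        )
        cm = recode_matrix(aln, detect_indel_events(aln))
        subs = [c for c in cm.characters if c.kind == "substitution"]
        indels = [c for c in cm.characters if c.kind == "indel"]
        assert len(subs) == 3 and len(indels) == 1
        assert cm.states["a"][cm.characters.index(indels[0])] == "0"
        assert cm.states["b"][cm.characters.index(indels[0])] == "1"

    def test_no_events_keeps_one_character_per_column(self):
        aln = make_alignment([hap_row("a", "ACGT"), hap_row("b", "ACGA")])
        cm = recode_matrix(aln, [])
        assert cm.n_characters == 4
        assert all(c.kind == "substitution" for c in cm.characters)

    def test_consensus_keeps_iupac_and_truncation_gives_n(self):
        aln = make_alignment(
            [
                hap_row("a", "AC-----T"),
                hap_row("b", "ACGGGGGT"),
                consensus_row("h", "ARNNNNNN", prefix=2),
            ]
        )
        cm = recode_matrix(aln, detect_indel_events(aln))
        states = cm.states["h"]
        assert states[1] == "R"
        # the indel character and the trailing substitution are unreadable
        assert states[2:] == ("N", "N")

    def test_invariant_characters_flagged(self):
        aln = make_alignment([hap_row("a", "ACGT"), hap_row("b", "ACGA")])
        cm = recode_matrix(aln, [])
        flags = ["invariant" in c.flags for c in cm.characters]
        assert flags == [True, True, True, False]


class TestDiagnosticSites:
    def test_single_fixed_difference(self):
        aln = make_alignment(
            [
                hap_row("a1", "ACG"), hap_row("a2", "ACG"),
                hap_row("b1", "ATG", Taxon.SPECIES_B),
                hap_row("b2", "ATG", Taxon.SPECIES_B),
            ]
        )
        cm = recode_matrix(aln, [])
        table = diagnostic_sites(cm, ["a1", "a2"], ["b1", "b2"])
        assert len(table.rows) == 1
        row = table.rows[0]
        assert (row.allele_a, row.allele_b) == ("C", "T")
        assert row.character_id == "s0001"

    def test_within_species_polymorphism_disqualifies(self):
        aln = make_alignment(
            [
                hap_row("a1", "ACG"), hap_row("a2", "ATG"),
                hap_row("b1", "ATG", Taxon.SPECIES_B),
            ]
        )
        cm = recode_matrix(aln, [])
        assert diagnostic_sites(cm, ["a1", "a2"], ["b1"]).rows == ()

    def test_consensus_rows_cannot_define_alleles(self):
        aln = make_alignment(
            [hap_row("a1", "ACG"), consensus_row("h1", "AYG")]
        )
        cm = recode_matrix(aln, [])
        with pytest.raises(RoleError):
            diagnostic_sites(cm, ["a1"], ["h1"])

    @staticmethod
    def _random_matrix(rng, n_a, n_b, n_char):
        rows = []
        for i in range(n_a + n_b):
            rows.append("".join(rng.choice("ACGN") for _ in range(n_char)))
        ids_a = [f"a{i}" for i in range(n_a)]
        ids_b = [f"b{i}" for i in range(n_b)]
        aln = make_alignment(
            [hap_row(s, r) for s, r in zip(ids_a, rows[:n_a])]
            + [
                hap_row(s, r, Taxon.SPECIES_B)
                for s, r in zip(ids_b, rows[n_a:])
            ]
        )
        return recode_matrix(aln, []), ids_a, ids_b

    def test_matches_per_character_bruteforce(self):
        """Diagnostic calls equal an exhaustive per-character oracle on
        random 10-haplotype, 30-character matrices."""
        rng = random.Random(3)
        for _ in range(40):
            cm, ids_a, ids_b = self._random_matrix(rng, 5, 5, 30)
            table = diagnostic_sites(cm, ids_a, ids_b)
            got = {r.character_id for r in table.rows}
            expected = set()
            for k, ch in enumerate(cm.characters):
                sa = {cm.states[s][k] for s in ids_a} - {"N"}
                sb = {cm.states[s][k] for s in ids_b} - {"N"}
                if len(sa) == 1 and len(sb) == 1 and sa != sb:
                    expected.add(ch.id)
            assert got == expected

    def test_symmetry_swaps_alleles(self):
        rng = random.Random(5)
        cm, ids_a, ids_b = self._random_matrix(rng, 4, 4, 20)
        ab = diagnostic_sites(cm, ids_a, ids_b)
        ba = diagnostic_sites(cm, ids_b, ids_a)
        assert [(r.character_id, r.allele_a, r.allele_b) for r in ab.rows] == [
            (r.character_id, r.allele_b, r.allele_a) for r in ba.rows
        ]

    def test_duplicating_a_haplotype_changes_nothing(self):
        aln = make_alignment(
            [
                hap_row("a1", "ACG"), hap_row("a2", "ACG"),
                hap_row("b1", "ATG", Taxon.SPECIES_B),
            ]
        )
        cm = recode_matrix(aln, [])
        base = diagnostic_sites(cm, ["a1"], ["b1"])
        dup = diagnostic_sites(cm, ["a1", "a2"], ["b1"])
        assert base.rows == dup.rows

    def test_diagnostic_subset_of_segregating(self, study_result):
        for r in study_result.loci.values():
            seg = sum(
                1 for c in r.matrix.characters if "invariant" not in c.flags
            )
            assert len(r.dtable.rows) <= seg


class TestPanels:
    def test_identical_rows_collapse_with_count(self):
        aln = make_alignment([hap_row(f"a{i}", "ACG") for i in range(4)])
        cm = recode_matrix(aln, [])
        panel = collapse_haplotypes(cm, Taxon.SPECIES_A, "a", "A")
        assert panel.names() == ["aA1"]
        assert panel.total_count("aA1") == 4

    def test_population_counts_and_rank_naming(self):
        aln = make_alignment(
            [
                hap_row("a1", "ACG", pop="P1"),
                hap_row("a2", "ACG", pop="P1"),
                hap_row("a3", "ATG", pop="P2"),
            ]
        )
        cm = recode_matrix(aln, [])
        panel = collapse_haplotypes(cm, Taxon.SPECIES_A, "a", "A")
        assert panel.names() == ["aA1", "aA2"]  # commonest first
        assert panel.counts == {("P1", "aA1"): 2, ("P2", "aA2"): 1}

    def test_iupac_in_haplotype_rows_rejected(self):
        aln = make_alignment(
            [hap_row("a1", "ACG"), consensus_row("a2", "AYG", Taxon.SPECIES_A)]
        )
        # force the consensus row through as if it were haplotype-role
        cm = recode_matrix(aln, [])
        object.__setattr__(cm.samples[1], "role", Role.HAPLOTYPE)
        with pytest.raises(RoleError):
            collapse_haplotypes(cm, Taxon.SPECIES_A, "a", "A")

    def test_study_panel_sizes_match_design(self, study_result):
        sizes = {
            name: (len(r.panel_a.haplotypes), len(r.panel_b.haplotypes))
            for name, r in study_result.loci.items()
        }
        assert sizes == {"cam": (2, 2), "gapCp1": (6, 2), "gapCp2": (6, 3)}

    def test_polymorphism_summary_frequencies(self):
        aln = make_alignment(
            [hap_row(f"a{i}", "ACG") for i in range(7)]
            + [hap_row(f"b{i}", "ATG") for i in range(3)]
        )
        cm = recode_matrix(aln, [])
        panel = collapse_haplotypes(cm, Taxon.SPECIES_A, "a", "A")
        summary = polymorphism_summary(panel)
        total = summary[summary.population == "TOTAL"].iloc[0]
        assert total.n == 10 and total.n_haplotypes == 2
        assert total.n_segregating == 1
        assert total.freq_aA1 == pytest.approx(0.7)
        assert total.freq_aA2 == pytest.approx(0.3)

    def test_single_haplotype_population(self):
        aln = make_alignment([hap_row(f"a{i}", "ACG") for i in range(10)])
        cm = recode_matrix(aln, [])
        summary = polymorphism_summary(
            collapse_haplotypes(cm, Taxon.SPECIES_A, "a", "A")
        )
        total = summary[summary.population == "TOTAL"].iloc[0]
        assert total.n_haplotypes == 1 and total.n_segregating == 0
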