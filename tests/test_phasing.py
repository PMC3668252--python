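"""EM haplotype frequencies and panel-constrained phasing."""

import math
import random

import numpy as np
import pytest

from conftest import consensus_row, hap_row, make_alignment
from fernhybrid.errors import ComplexityError, DataError
from fernhybrid.phasing import (
    DiploidGenotype,
    consensus_from_pair,
    em_haplotype_frequencies,
    genotype_from_matrix,
    phase_genotype,
)
from fernhybrid.popseq import (
    Character,
    collapse_haplotypes,
    detect_indel_events,
    merge_panels,
    recode_matrix,
)
from fernhybrid.seqio import Role, Taxon

CHARS2 = (
    Character("s0000", "substitution", (0,)),
    Character("s0001", "substitution", (1,)),
)


def g(sid, states):
    return DiploidGenotype(sid, tuple(states))


class TestEM:
    def test_counting_case(self):
        """50 h1/h1 homozygotes + 50 h1/h2 single-site heterozygotes: phase
        is forced, so EM must return the gene-counting answer 0.75/0.25."""
        chars = CHARS2[:1]
        genotypes = [g(f"hom{i}", "A") for i in range(50)]
        genotypes += [g(f"het{i}", "R") for i in range(50)]
        freqs, loglik = em_haplotype_frequencies(genotypes, chars)
        assert freqs[("A",)] == pytest.approx(0.75, abs=1e-9)
        assert freqs[("G",)] == pytest.approx(0.25, abs=1e-9)
        assert loglik < 0

    def test_identical_homozygotes_single_haplotype(self):
        genotypes = [g(f"s{i}", "AC") for i in range(10)]
        freqs, _, trace = em_haplotype_frequencies(
            genotypes, CHARS2, return_trace=True
        )
        assert freqs == {("A", "C"): 1.0}
        assert len(trace) == 1  # converged after one iteration

    def test_frequencies_sum_to_one_and_loglik_monotone(self):
        rng = random.Random(2)
        haps = [("A", "C"), ("G", "C"), ("G", "T")]
        genotypes = []
        for i in range(60):
            h1, h2 = rng.choice(haps), rng.choice(haps)
            states = []
            for a, b in zip(h1, h2):
                states.append(a if a == b else {"AG": "R", "CT": "Y"}[
                    "".join(sorted(a + b))])
            genotypes.append(g(f"s{i}", states))
        freqs, _, trace = em_haplotype_frequencies(
            genotypes, CHARS2, return_trace=True
        )
        assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_recovers_simulation_truth(self):
        """Two-site system with truth frequencies (0.6, 0.3, 0.1) at n=500:
        the double heterozygote is genuinely ambiguous, yet EM recovers the
        haplotype frequencies within ±0.05."""
        rng = np.random.default_rng(42)
        haps = [("A", "C"), ("A", "T"), ("G", "T")]
        truth = [0.6, 0.3, 0.1]
        genotypes = []
        for i in range(500):
            i1, i2 = rng.choice(3, size=2, p=truth)
            states = []
            for a, b in zip(haps[i1], haps[i2]):
                states.append(
                    a if a == b
                    else {"AG": "R", "CT": "Y", "AT": "W"}["".join(sorted(a + b))]
                )
            genotypes.append(g(f"s{i}", states))
        freqs, _ = em_haplotype_frequencies(genotypes, CHARS2)
        for hap, p in zip(haps, truth):
            assert freqs.get(hap, 0.0) == pytest.approx(p, abs=0.05)

    def test_phase_unambiguous_equals_direct_counting(self):
        """Every genotype has ≤1 heterozygous site, so each has exactly one
        resolution and EM must equal allele counting exactly."""
        rng = random.Random(9)
        genotypes = []
        tally: dict[tuple, float] = {}
        for i in range(80):
            h = (rng.choice("AG"), rng.choice("CT"))
            het_at = rng.choice([None, 0, 1])
            states = list(h)
            other = dict(h2=list(h))
            if het_at is not None:
                alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[h[het_at]]
                states[het_at] = {"AG": "R", "CT": "Y"}[
                    "".join(sorted(h[het_at] + alt))
                ]
                other["h2"][het_at] = alt
            genotypes.append(g(f"s{i}", states))
            tally[h] = tally.get(h, 0) + 1
            h2 = tuple(other["h2"])
            tally[h2] = tally.get(h2, 0) + 1
        freqs, _ = em_haplotype_frequencies(genotypes, CHARS2)
        for hap, count in tally.items():
            assert freqs[hap] == pytest.approx(count / 160, abs=1e-12)

    def test_complexity_bound(self):
        states = ["R"] * 25
        chars = tuple(
            Character(f"s{k:04d}", "substitution", (k,)) for k in range(25)
        )
        with pytest.raises(ComplexityError):
            em_haplotype_frequencies([g("s", states)], chars)


def _cam_like_fixture():
    """Two species, 9 fixed differences, 2 haplotypes each; one F1."""
    rng = random.Random(1)
    L = 30
    core_a = [rng.choice("ACGT") for _ in range(L)]
    diag = sorted(rng.sample(range(L), 9))
    core_b = list(core_a)
    for p in diag:
        core_b[p] = {"A": "G", "G": "A", "C": "T", "T": "C"}[core_a[p]]
    a2 = list(core_a)
    p_a2 = next(p for p in range(L) if p not in diag)
    a2[p_a2] = {"A": "C", "C": "A", "G": "T", "T": "G"}[core_a[p_a2]]
    b2 = list(core_b)
    p_b2 = next(p for p in range(L - 1, -1, -1) if p not in diag and p != p_a2)
    b2[p_b2] = {"A": "C", "C": "A", "G": "T", "T": "G"}[core_b[p_b2]]
    from fernhybrid.seqio import iupac_union

    f1 = [
        a if a == b else iupac_union(a, b)
        for a, b in zip(core_a, core_b)
    ]
    aln = make_alignment(
        [
            hap_row("pa1", "".join(core_a)),
            hap_row("pa2", "".join(a2)),
            hap_row("pb1", "".join(core_b), Taxon.SPECIES_B),
            hap_row("pb2", "".join(b2), Taxon.SPECIES_B),
            consensus_row("hyb", "".join(f1)),
        ],
        locus="camlike",
    )
    cm = recode_matrix(aln, detect_indel_events(aln))
    panel_a = collapse_haplotypes(cm, Taxon.SPECIES_A, "a", "A")
    panel_b = collapse_haplotypes(cm, Taxon.SPECIES_B, "s", "A")
    return cm, panel_a, panel_b


class TestPhase:
    def test_f1_names_one_haplotype_per_species(self):
        cm, panel_a, panel_b = _cam_like_fixture()
        merged = merge_panels(panel_a, panel_b)
        geno = genotype_from_matrix(cm, "hyb")
        pg = phase_genotype(geno, merged, cm.characters)
        assert pg.named_pair == ("aA1", "sA1")
        assert pg.confidence == pytest.approx(1.0)

    def test_homozygote_is_unambiguous(self):
        cm, panel_a, panel_b = _cam_like_fixture()
        merged = merge_panels(panel_a, panel_b)
        geno = DiploidGenotype("hom", panel_a.get("aA1").states)
        pg = phase_genotype(geno, merged, cm.characters)
        assert pg.method == "unambiguous"
        assert pg.named_pair == ("aA1", "aA1")
        assert pg.confidence == 1.0

    def test_single_het_site_has_one_resolution(self):
        chars = CHARS2
        from fernhybrid.popseq import Haplotype, HaplotypePanel

        panel = HaplotypePanel(
            "x",
            (
                Haplotype("aA1", ("A", "C"), Taxon.SPECIES_A),
                Haplotype("sA1", ("G", "C"), Taxon.SPECIES_B),
            ),
        )
        pg = phase_genotype(g("s", "RC"), panel, chars)
        assert pg.method == "unambiguous"
        assert pg.n_resolutions == 1
        assert pg.confidence == 1.0
        assert pg.named_pair == ("aA1", "sA1")

    def test_novel_haplotype_labelled_un(self):
        from fernhybrid.popseq import Haplotype, HaplotypePanel

        panel = HaplotypePanel(
            "x",
            (
                Haplotype("aA1", ("A", "C"), Taxon.SPECIES_A),
                Haplotype("sA1", ("G", "T"), Taxon.SPECIES_B),
            ),
        )
        # het at site 0 only: must be (A,*)/(G,*) with site 1 homozygous C —
        # the C/C pair is not (aA1, sA1), so one side is novel
        pg = phase_genotype(g("s", "RC"), panel, CHARS2)
        assert "UN-1" in pg.named_pair
        assert "aA1" in pg.named_pair

    def test_panel_incompatible_homozygote_reported_novel(self):
        from fernhybrid.popseq import Haplotype, HaplotypePanel

        chars = (Character("i0000", "indel", (0, 1)),)
        panel = HaplotypePanel(
            "x", (Haplotype("aA1", ("1",), Taxon.SPECIES_A),)
        )
        # hom indel-absent genotype against an indel-present panel: the only
        # resolution is the novel absent/absent pair
        pg = phase_genotype(g("s", ["0"]), panel, chars)
        assert pg.named_pair == ("UN-1", "UN-1")
        assert pg.hap_pair == ((("0",)), (("0",)))


class TestConsensusFromPair:
    def test_f1_consensus_is_additive_everywhere(self):
        cm, panel_a, panel_b = _cam_like_fixture()
        states, prefix = consensus_from_pair(
            panel_a.get("aA1").states, panel_b.get("sA1").states, cm.characters
        )
        from fernhybrid.seqio import CODE_TO_PAIR

        assert sum(1 for s in states if s in CODE_TO_PAIR) == 9
        assert prefix == cm.n_columns

    def test_identical_pair_round_trips(self):
        cm, panel_a, _ = _cam_like_fixture()
        vec = panel_a.get("aA2").states
        states, prefix = consensus_from_pair(vec, vec, cm.characters)
        assert states == vec
        assert prefix == cm.n_columns

    def test_heterozygous_indel_truncates(self):
        chars = (
            Character("s0000", "substitution", (0,)),
            Character("i0001", "indel", (1, 2, 3, 4, 5)),
            Character("s0006", "substitution", (6,)),
        )
        h1 = ("A", "1", "C")
        h2 = ("G", "0", "T")
        states, prefix = consensus_from_pair(h1, h2, chars)
        assert prefix == 1  # the 5-bp event starts at column 1
        assert states == ("R", "N", "N")

    def test_round_trip_through_phasing(self):
        """consensus_from_pair → phase_genotype recovers the pair whenever
        it is panel-resolvable and nothing was truncated."""
        cm, panel_a, panel_b = _cam_like_fixture()
        merged = merge_panels(panel_a, panel_b)
        import itertools

        for h1, h2 in itertools.combinations_with_replacement(
            merged.haplotypes, 2
        ):
            states, prefix = consensus_from_pair(
                h1.states, h2.states, cm.characters
            )
            assert prefix == cm.n_columns  # no indels in this fixture
            pg = phase_genotype(
                DiploidGenotype("rt", states), merged, cm.characters
            )
            assert set(pg.named_pair) == {h1.name, h2.name}
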