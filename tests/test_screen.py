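"""Motif finding, operon structure, pathway completeness and genome classes."""

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soasr import simulate
from soasr.screen import (
    AMINO_ACIDS,
    DEFAULT_SOX_MODULE,
    GeneRecord,
    GenomeAnnotation,
    ScreenConfig,
    assign_families_from_hits,
    check_arr_operon,
    classify_dsr,
    default_dsr_references,
    find_motif,
    pathway_completeness,
    screen_genome,
)


def brute_force_motif(seq):
    """Independent oracle: scan every 4-mer."""
    return [
        i + 1
        for i in range(len(seq) - 3)
        if seq[i] in "RK" and seq[i + 1] == "G" and seq[i + 2] == "R" and seq[i + 3] == "Y"
    ]


class TestFindMotif:
    @pytest.mark.parametrize(
        "seq,expected",
        [("AAKGRYAA", [3]), ("AAQGRYAA", []), ("RGRYKGRY", [1, 5]),
         ("", []), ("KGR", []), ("XGRY", [])],
    )
    def test_examples(self, seq, expected):
        assert find_motif(seq) == expected

    @given(st.text(alphabet=AMINO_ACIDS + "X", min_size=0, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_brute_force(self, seq):
        assert find_motif(seq) == brute_force_motif(seq)

    def test_thousand_random_proteins_against_oracle(self, rng):
        aa = np.array(list(AMINO_ACIDS))
        for _ in range(1000):
            seq = "".join(aa[rng.integers(0, 20, size=rng.integers(4, 120))])
            assert find_motif(seq) == brute_force_motif(seq)


def gene(gid, contig, order, family=None, strand="+", protein=None):
    start = 1 + order * 1000
    return GeneRecord(gid, "G1", contig, start, start + 899, strand, family, None, protein)


class TestArrOperon:
    def test_full_operon_found(self):
        genes = [
            gene("g1", "c1", 0, "arrD"), gene("g2", "c1", 1, "arrA"),
            gene("g3", "c1", 2, "arrB"), gene("g4", "c1", 3, "arrE"),
        ]
        chk = check_arr_operon(GenomeAnnotation("G1", genes))
        assert chk.arrab_pair and chk.arrde_flank
        assert set(chk.operon_gene_ids) == {"g1", "g2", "g3", "g4"}

    def test_arrA_alone(self):
        chk = check_arr_operon(GenomeAnnotation("G1", [gene("g1", "c1", 0, "arrA")]))
        assert not chk.arrab_pair and not chk.arrde_flank

    def test_opposite_strands_break_pair(self):
        genes = [gene("g1", "c1", 0, "arrA"), gene("g2", "c1", 1, "arrB", strand="-")]
        chk = check_arr_operon(GenomeAnnotation("G1", genes))
        assert not chk.arrab_pair

    def test_one_intervening_gene_tolerated(self):
        genes = [
            gene("g1", "c1", 0, "arrA"), gene("g2", "c1", 1, "other"),
            gene("g3", "c1", 2, "arrB"),
        ]
        assert check_arr_operon(GenomeAnnotation("G1", genes)).arrab_pair

    def test_two_intervening_genes_break_pair(self):
        genes = [
            gene("g1", "c1", 0, "arrA"), gene("g2", "c1", 1, "other"),
            gene("g3", "c1", 2, "other"), gene("g4", "c1", 3, "arrB"),
        ]
        assert not check_arr_operon(GenomeAnnotation("G1", genes)).arrab_pair

    def test_distant_flank_rejected(self):
        genes = [gene("g1", "c1", 0, "arrD")] + [
            gene(f"b{i}", "c1", i, "other") for i in range(1, 5)
        ] + [
            gene("g2", "c1", 5, "arrA"), gene("g3", "c1", 6, "arrB"),
            gene("g4", "c1", 7, "arrE"),
        ]
        chk = check_arr_operon(GenomeAnnotation("G1", genes))
        assert chk.arrab_pair and not chk.arrde_flank

    def test_different_contigs_never_pair(self):
        genes = [gene("g1", "c1", 0, "arrA"), gene("g2", "c2", 0, "arrB")]
        assert not check_arr_operon(GenomeAnnotation("G1", genes)).arrab_pair


class TestPathwayCompleteness:
    @pytest.mark.parametrize(
        "n_present,expected", [(7, 1.0), (0, 0.0), (5, 5 / 7)]
    )
    def test_sox_module_fractions(self, n_present, expected):
        kos = set(DEFAULT_SOX_MODULE[:n_present])
        assert pathway_completeness(kos, DEFAULT_SOX_MODULE) == pytest.approx(expected)

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError):
            pathway_completeness({"K00001"}, [])


class TestClassifyDsr:
    def test_identity_with_reverse_reference(self):
        refs = default_dsr_references()
        assert classify_dsr(refs["reverse_or_oxidative"][0]) == "reverse_or_oxidative"

    def test_random_query_unknown(self, rng):
        aa = np.array(list(AMINO_ACIDS))
        query = "".join(aa[rng.integers(0, 20, size=300)])
        # random sequences sit near the ~6% identity floor of unrelated proteins
        assert classify_dsr(query) == "unknown"

    def test_mutant_closer_to_reverse_wins(self, rng):
        refs = default_dsr_references()
        seq = list(refs["reverse_or_oxidative"][0])
        aa = list(AMINO_ACIDS)
        for pos in rng.choice(len(seq), size=60, replace=False):  # 80% identity
            seq[pos] = aa[(aa.index(seq[pos]) + 1) % 20]
        assert classify_dsr("".join(seq)) == "reverse_or_oxidative"

    def test_exact_tie_is_unknown(self):
        refs = {"a": ("AAAA",), "b": ("AAAA",)}
        assert classify_dsr("AAAA", refs) == "unknown"

    def test_empty_references_rejected(self):
        with pytest.raises(ValueError):
            classify_dsr("AAAA", {})


class TestScreenGenome:
    def _genome(self, spec, seed=11):
        cfg = simulate.GenomeSimConfig(genomes=(spec,))
        return simulate.simulate_genomes(cfg, seed)[0]

    def test_rule_conjunction_soasrb(self):
        spec = simulate.GenomeSpec("G1", motif=True, flank=True, sox="full")
        assert screen_genome(self._genome(spec)).screen_class == "SOAsRB"

    def test_reducer_without_sulfur_genes(self):
        spec = simulate.GenomeSpec("G1", motif=True, flank=True, sox="none")
        assert screen_genome(self._genome(spec)).screen_class == "nonSox_AsR"

    def test_motifless_arrA_removed_from_reducers(self):
        spec = simulate.GenomeSpec("G1", motif=False, flank=True, sox="full")
        res = screen_genome(self._genome(spec))
        assert res.screen_class == "sulfur_oxidizer_only"
        assert res.evidence.arrA_present and not res.evidence.motif_ok

    def test_partial_sox_without_soxB_is_not_oxidizer(self):
        spec = simulate.GenomeSpec("G1", motif=True, flank=True, sox="partial")
        res = screen_genome(self._genome(spec))
        assert res.screen_class == "nonSox_AsR"
        assert res.evidence.sox_completeness == pytest.approx(5 / 7)

    def test_arrA_without_protein_is_unevaluable_neither(self):
        genes = [
            gene("g1", "c1", 0, "arrD"), gene("g2", "c1", 1, "arrA", protein=None),
            gene("g3", "c1", 2, "arrB"), gene("g4", "c1", 3, "arrE"),
        ]
        with pytest.warns(UserWarning, match="unevaluable"):
            res = screen_genome(GenomeAnnotation("G1", genes))
        assert res.screen_class == "neither"
        assert res.evidence.motif_ok is None

    def test_truth_table_on_all_combinations_fixture(self):
        cfg = simulate.GenomeSimConfig(genomes=simulate.all_combinations_genome_specs())
        genomes = simulate.simulate_genomes(cfg, 1)
        for g, spec in zip(genomes, cfg.genomes):
            assert screen_genome(g).screen_class == simulate.expected_screen_class(spec), g.genome_id

    def test_permutation_invariance_and_idempotence(self):
        cfg = simulate.GenomeSimConfig(genomes=simulate.all_combinations_genome_specs())
        genomes = simulate.simulate_genomes(cfg, 2)
        rnd = random.Random(5)
        for g in genomes:
            first = screen_genome(g)
            shuffled_genes = list(g.genes)
            rnd.shuffle(shuffled_genes)
            shuffled = GenomeAnnotation(g.genome_id, shuffled_genes, g.taxonomy)
            assert screen_genome(shuffled) == first
            assert screen_genome(g) == first  # idempotent

    def test_monotonicity_adding_sulfur_genes(self):
        spec = simulate.GenomeSpec("G1", motif=True, flank=True, sox="none")
        genome = self._genome(spec)
        assert screen_genome(genome).screen_class == "nonSox_AsR"
        extra = gene("soxb_new", "c_extra", 0, "soxB")
        augmented = GenomeAnnotation(genome.genome_id, genome.genes + [extra], genome.taxonomy)
        assert screen_genome(augmented).screen_class == "SOAsRB"

    def test_relaxed_arrb_requirement(self):
        spec = simulate.GenomeSpec("G1", motif=True, has_arrB=False, flank=True)
        genome = self._genome(spec)
        assert screen_genome(genome).screen_class == "neither"
        relaxed = screen_genome(genome, ScreenConfig(require_arrb=False))
        assert relaxed.screen_class == "nonSox_AsR"


class TestHmmAssignment:
    def test_best_hit_with_evalue_ceiling_and_tiebreak(self):
        hits = [
            {"gene_id": "g1", "family": "soxB", "evalue": 1e-30, "score": 200.0},
            {"gene_id": "g1", "family": "soxA", "evalue": 1e-40, "score": 150.0},
            {"gene_id": "g2", "family": "arrA", "evalue": 1e-5, "score": 500.0},  # fails ceiling
            {"gene_id": "g3", "family": "dsrB", "evalue": 1e-20, "score": 90.0},
            {"gene_id": "g3", "family": "dsrA", "evalue": 1e-20, "score": 90.0},  # tie -> alphabetical
        ]
        fams = assign_families_from_hits(hits)
        assert fams == {"g1": "soxB", "g3": "dsrA"}
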