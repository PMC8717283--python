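"""Gene-model extraction, disruption detection, TM screen, classification."""

import numpy as np
import pytest

from tastemine import annotate, simdata
from tastemine._codons import revcomp
from tastemine.align import Disruption
from tastemine.annotate import classify_gene, count_tm_segments


@pytest.fixture()
def planted_locus(template_orf):
    """Template ORF embedded in random flanks (like an extended locus)."""
    orf, prot = template_orf
    rng = np.random.default_rng(1)
    flank = lambda n: "".join("ACGT"[i] for i in rng.integers(0, 4, n))
    left, right = flank(500), flank(500)
    return left + orf + right, orf, prot, len(left)


class TestExtractGeneModel:
    def test_planted_orf_interval_recovered_exactly(self, planted_locus):
        locus, orf, prot, offset = planted_locus
        (cs, ce), protein, raw = annotate.extract_gene_model(locus, prot)
        assert (cs, ce) == (offset, offset + len(orf))
        assert protein == prot

    def test_random_locus_dropped(self):
        rng = np.random.default_rng(2)
        locus = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        guide = "".join(
            "ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 300)
        )
        assert annotate.extract_gene_model(locus, guide) is None

    def test_reverse_strand_plant_gives_identical_protein(self, planted_locus):
        from tastemine.search import CandidateLocus

        locus, orf, prot, _ = planted_locus
        queries = {"q": prot}
        fwd = annotate.build_gene_model(
            {"c": locus},
            CandidateLocus("c", "+", 0, len(locus), best_query="q"),
            queries,
        )
        rev = annotate.build_gene_model(
            {"c": revcomp(locus)},
            CandidateLocus("c", "-", 0, len(locus), best_query="q"),
            queries,
        )
        assert fwd is not None and rev is not None
        assert rev.protein == fwd.protein == prot
        assert rev.category == fwd.category


class TestDetectDisruptions:
    def test_clean_plant_has_no_disruptions(self, planted_locus):
        locus, _, prot, _ = planted_locus
        assert annotate.detect_disruptions(locus, prot) == []

    def test_engineered_stop_found_at_its_codon(self, template_orf):
        orf, prot = template_orf
        mutated = orf[:450] + "TAA" + orf[453:]
        found = annotate.detect_disruptions("A" * 300 + mutated, prot)
        assert [(d.kind, d.position) for d in found] == [
            ("PREMATURE_STOP", 150)
        ]

    def test_single_nt_deletion_reports_one_frameshift(self, template_orf):
        orf, prot = template_orf
        mutated = orf[:500] + orf[501:]
        found = annotate.detect_disruptions("A" * 300 + mutated, prot)
        assert [d.kind for d in found] == ["FRAMESHIFT"]
        assert found[0].length_mod3 == 1

    def test_two_nt_insertion_reports_one_frameshift(self, template_orf):
        orf, prot = template_orf
        mutated = orf[:500] + "GT" + orf[500:]
        found = annotate.detect_disruptions(mutated, prot)
        assert [d.kind for d in found] == ["FRAMESHIFT"]
        assert found[0].length_mod3 == 2

    def test_pseudogene_mutations_round_trip(self, template_orf):
        orf, prot = template_orf
        for seed in range(10):
            mutated, recorded = simdata.mutate_to_pseudogene(orf, 1, seed)
            found = annotate.detect_disruptions("C" * 120 + mutated, prot)
            assert sorted(d.kind for d in found) == sorted(
                k for k, _ in recorded
            )


class TestTMScreen:
    def test_hydrophilic_protein_has_no_segments(self):
        assert count_tm_segments("D" * 300) == 0

    def test_seven_blocks_counted_as_seven(self):
        prot = "M" + ("L" * 21 + "D" * 15) * 7
        assert count_tm_segments(prot) == 7

    def test_short_protein_scores_zero(self):
        assert count_tm_segments("MLLVF") == 0

    def test_agrees_with_independent_hydropathy_oracle(self):
        # independent oracle: direct per-window loop over the published
        # Kyte-Doolittle values, no convolution
        kd = {
            "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
            "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
            "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
            "Y": -1.3, "V": 4.2,
        }

        def oracle(prot, window=19, thr=1.6, min_gap=3):
            above = []
            for i in range(len(prot) - window + 1):
                mean = sum(kd[a] for a in prot[i : i + window]) / window
                above.append(mean > thr)
            segs, gap, in_run = 0, min_gap, False
            for a in above:
                if a:
                    if not in_run and gap >= min_gap:
                        segs += 1
                    in_run, gap = True, 0
                else:
                    in_run = False
                    gap += 1
            return segs

        rng = np.random.default_rng(7)
        aas = list(kd)
        for _ in range(25):
            prot = "".join(
                aas[i] for i in rng.integers(0, 20, int(rng.integers(10, 400)))
            )
            assert count_tm_segments(prot) == oracle(prot)


class TestClassifyGene:
    def test_intact_rule(self):
        assert classify_gene("M" + "A" * 299, True, True, [], 7) == "INTACT"

    def test_missing_stop_at_contig_edge_is_partial(self):
        assert (
            classify_gene("M" + "A" * 200, True, False, [], 7, True)
            == "PARTIAL"
        )

    def test_complete_orf_failing_tm_screen_is_pseudo(self):
        assert classify_gene("M" + "A" * 299, True, True, [], 5) == "PSEUDO"

    def test_270_aa_boundary_is_short_not_intact(self):
        assert classify_gene("M" + "A" * 269, True, True, [], 7) == "SHORT"
        assert classify_gene("M" + "A" * 270, True, True, [], 7) == "INTACT"

    def test_disruption_outranks_truncation(self):
        d = [Disruption("FRAMESHIFT", 10, 1)]
        assert classify_gene("MAA", True, False, d, 0, True) == "PSEUDO"

    def test_missing_start_away_from_edge_is_pseudo(self):
        assert (
            classify_gene("M" + "A" * 300, False, True, [], 7, False)
            == "PSEUDO"
        )


class TestAgainstTruthTable:
    def test_presence_and_category_recovery(self, genome7, mined7):
        from tastemine.report import score_against_truth

        _, truth, _ = genome7
        metrics = score_against_truth(mined7["models"], truth)
        assert metrics.recall >= 0.95
        assert metrics.precision >= 0.95
        assert metrics.category_accuracy >= 0.9

    def test_pseudogenised_intact_plant_flips_to_pseudo(self, genome7):
        genome, truth, queries = genome7
        rec = truth.by_category("INTACT")[0]
        seq = genome.contigs[rec.contig_id][rec.start : rec.end]
        if rec.strand == "-":
            seq = revcomp(seq)
        guide = None
        best = -1.0
        from tastemine.align import guided_align

        for name, q in queries.items():
            a = guided_align(seq, q)
            if a and a.score > best:
                best, guide = a.score, q
        mutated, _ = simdata.mutate_to_pseudogene(seq, 1, seed=3)
        found = annotate.detect_disruptions(mutated, guide)
        assert found
        assert classify_gene("M" * 300, True, True, found, 7) == "PSEUDO"

    def test_truncating_contig_flips_intact_to_partial(self, genome7):
        genome, truth, queries = genome7
        rec = truth.by_category("INTACT")[0]
        # cut the contig through the middle of the plant
        cut = (rec.start + rec.end) // 2
        contigs = {rec.contig_id: genome.contigs[rec.contig_id][:cut]}
        from tastemine import search

        params = search.SearchParams()
        hits = search.search_genome(queries, contigs, params)
        loci = search.merge_hits(search.filter_hits(hits, params), params)
        loci = [search.extend_locus(l, params, cut) for l in loci]
        models = annotate.annotate_loci(contigs, loci, queries)
        overlapping = [
            m for m in models
            if m.coding_start < rec.end and rec.start < m.coding_end
        ]
        assert overlapping
        assert max(overlapping, key=lambda m: m.score).category == "PARTIAL"


class TestDeduplicatePartials:
    def _frag(self, qs, qe):
        from tastemine.annotate import GeneModel

        return GeneModel(
            contig_id="c", strand="+", locus_start=0, locus_end=0,
            coding_start=0, coding_end=0, protein="", raw_translation="",
            category="PARTIAL", guide_interval=(qs, qe),
        )

    def test_overlapping_fragments_are_distinct_loci(self):
        groups = annotate.deduplicate_partials(
            [self._frag(0, 120), self._frag(80, 290)]
        )
        assert len(groups) == 2

    def test_disjoint_fragments_fuse_into_one_locus(self):
        groups = annotate.deduplicate_partials(
            [self._frag(0, 120), self._frag(150, 290)]
        )
        assert len(groups) == 1
        assert len(groups[0]) == 2

    def test_single_fragment_single_locus(self):
        assert len(annotate.deduplicate_partials([self._frag(5, 100)])) == 1


class TestReciprocalVerify:
    @pytest.fixture()
    def panel(self, spec7):
        queries = simdata.simulate_queries(spec7)
        decoys = simdata.simulate_decoys(spec7)
        panel = {n: ("Tas2r", s) for n, s in queries.items()}
        panel.update({n: ("V2R", s) for n, s in decoys.items()})
        return panel, queries, decoys

    def test_panel_member_hits_its_own_family(self, panel):
        p, queries, _ = panel
        name, seq = next(iter(queries.items()))
        assert annotate.reciprocal_verify(seq, p) == "Tas2r"

    def test_diverged_plant_assigned_to_target_family(self, panel, spec7):
        p, queries, _ = panel
        rng = np.random.default_rng(4)
        plant = simdata.diverge_protein(
            next(iter(queries.values())), 0.1, rng
        )
        assert annotate.reciprocal_verify(plant, p) == "Tas2r"

    def test_decoy_derived_protein_rejected(self, panel):
        p, _, decoys = panel
        rng = np.random.default_rng(5)
        impostor = simdata.diverge_protein(
            next(iter(decoys.values())), 0.1, rng
        )
        assert annotate.reciprocal_verify(impostor, p) == "REJECTED"

    def test_empty_panel_is_an_error(self):
        with pytest.raises(ValueError):
            annotate.reciprocal_verify("MKL", {})


class TestGeneNames:
    def test_nomenclature_prefix_and_numbering(self):
        from tastemine.annotate import GeneModel

        mk = lambda c, s: GeneModel(
            contig_id=c, strand="+", locus_start=0, locus_end=0,
            coding_start=s, coding_end=s + 900, protein="", raw_translation="",
            category="INTACT",
        )
        models = [mk("chr2", 100), mk("chr1", 5000), mk("chr1", 100)]
        named = annotate.assign_gene_names(
            models, "Leptobrachium leishanense", "Tas2r"
        )
        assert [m.gene_name for m in named] == [
            "Lele_Tas2r1", "Lele_Tas2r2", "Lele_Tas2r3"
        ]
        named2 = annotate.assign_gene_names(
            [mk("c", 1), mk("c", 2), mk("c", 3)], "Bufo gargarizans", "Tas2r"
        )
        assert named2[2].gene_name == "Buga_Tas2r3"

    def test_zero_genes_zero_names(self):
        assert annotate.assign_gene_names([], "Bufo gargarizans", "Tas2r") == []

    def test_collision_detection(self):
        taken = {"Buga_Tas2r1"}
        from tastemine.annotate import GeneModel

        m = GeneModel(
            contig_id="c", strand="+", locus_start=0, locus_end=0,
            coding_start=0, coding_end=9, protein="", raw_translation="",
            category="INTACT",
        )
        with pytest.raises(ValueError):
            annotate.assign_gene_names(
                [m], "Bufo gargarizans", "Tas2r", _taken=taken
            )

    def test_non_binomial_rejected(self):
        with pytest.raises(ValueError):
            annotate.species_prefix("Bufo")
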