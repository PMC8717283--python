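"""Six-frame translation, seeded search, and hit filter/merge/extend rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tastemine import search, simdata
from tastemine._codons import revcomp, translate
from tastemine.search import CandidateLocus, SearchHit, SearchParams


def _hit(contig="c", strand="+", frame=0, start=0, end=300, score=100.0,
         query="q"):
    return SearchHit(
        query_id=query, contig_id=contig, strand=strand, frame=frame,
        start=start, end=end, score=score, aln_len=end - start,
    )


class TestSixFrame:
    def test_forward_frame_zero_codon_table(self):
        frames = search.sixframe_translate("ATGAAA")
        fwd0 = next(f for f in frames if f.strand == "+" and f.frame == 0)
        assert fwd0.protein == "MK"

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        fr = search.sixframe_translate(seq)
        fr_rc = search.sixframe_translate(revcomp(seq))
        for f in range(3):
            orig_rev = next(
                x for x in fr if x.strand == "-" and x.frame == f
            )
            rc_fwd = next(
                x for x in fr_rc if x.strand == "+" and x.frame == f
            )
            assert orig_rev.protein == rc_fwd.protein

    def test_empty_sequence_gives_six_empty_frames(self):
        frames = search.sixframe_translate("")
        assert len(frames) == 6
        assert all(f.protein == "" for f in frames)

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_coordinate_roundtrip_reproduces_residue(self, draw):
        # protein position -> forward-strand nt interval -> re-translation
        rng = np.random.default_rng(draw)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        frames = search.sixframe_translate(seq)
        fr = frames[int(rng.integers(6))]
        if not fr.protein:
            return
        p = int(rng.integers(len(fr.protein)))
        start, end = fr.nt_interval(p, p + 1)
        assert 0 <= start < end <= len(seq)
        codon = seq[start:end]
        if fr.strand == "-":
            codon = revcomp(codon)
        assert translate(codon) == fr.protein[p]


class TestSearchGenome:
    def test_identical_query_covers_planted_interval(self):
        spec = simdata.SimSpec(
            n_intact=3, n_partial=0, n_pseudo=0, divergence=0.0, seed=11,
            with_markers=False,
        )
        genome, truth = simdata.simulate_genome(spec)
        queries = simdata.simulate_queries(spec)
        hits = search.search_genome(queries, genome)
        for rec in truth.records:
            cover = [
                h for h in hits
                if h.contig_id == rec.contig_id and h.strand == rec.strand
                and h.start < rec.end and rec.start < h.end
            ]
            assert cover
            covered = max(h.end for h in cover) - min(h.start for h in cover)
            assert covered >= 0.95 * (rec.end - rec.start)

    def test_scrambled_query_against_random_genome_scores_above_threshold_only(self):
        rng = np.random.default_rng(3)
        genome = {
            "bg": "".join("ACGT"[i] for i in rng.integers(0, 4, 20_000))
        }
        aas = "ACDEFGHIKLMNPQRSTVWY"
        query = {"scrambled": "".join(
            aas[i] for i in rng.integers(0, 20, 300)
        )}
        params = SearchParams()
        hits = search.search_genome(query, genome, params)
        assert all(h.score >= params.score_threshold for h in hits)
        assert len(hits) == 0  # chance 4-mer seeds never extend this far

    def test_diverged_plants_all_recovered(self, genome7, mined7):
        _, truth, _ = genome7
        hits = mined7["hits"]
        for rec in truth.records:
            assert any(
                h.contig_id == rec.contig_id
                and h.start < rec.end and rec.start < h.end
                for h in hits
            )

    def test_determinism_and_sort_order(self, genome7):
        genome, _, queries = genome7
        h1 = search.search_genome(queries, genome)
        h2 = search.search_genome(queries, genome)
        assert h1 == h2
        keys = [(h.contig_id, h.start, h.query_id) for h in h1]
        assert keys == sorted(keys)

    def test_mostly_n_contig_skipped(self, caplog):
        genome = {"nn": "N" * 5000 + "ACGT" * 10}
        hits = search.search_genome({"q": "MKLVF" * 40}, genome)
        assert hits == []

    def test_agrees_with_tblastn_on_planted_genes(self, tmp_path):
        """External TBLASTN oracle: both searches find every planted gene."""
        import shutil
        import subprocess

        if not (shutil.which("tblastn") and shutil.which("makeblastdb")):
            pytest.skip("BLAST+ not on PATH")
        spec = simdata.SimSpec(
            n_intact=3, n_partial=0, n_pseudo=0, divergence=0.05, seed=13,
            with_markers=False,
        )
        genome, truth = simdata.simulate_genome(spec)
        queries = simdata.simulate_queries(spec)
        gfa = tmp_path / "g.fa"
        qfa = tmp_path / "q.fa"
        gfa.write_text(genome.to_fasta())
        qfa.write_text(
            "".join(f">{n}\n{s}\n" for n, s in queries.items())
        )
        subprocess.run(
            ["makeblastdb", "-in", str(gfa), "-dbtype", "nucl"],
            check=True, capture_output=True,
        )
        out = subprocess.run(
            ["tblastn", "-query", str(qfa), "-db", str(gfa),
             "-evalue", "1e-10", "-outfmt", "6 sseqid sstart send"],
            check=True, capture_output=True, text=True,
        ).stdout
        blast_hits = []
        for line in out.strip().splitlines():
            sid, s, e = line.split("\t")
            s, e = int(s), int(e)
            blast_hits.append((sid, min(s, e) - 1, max(s, e)))
        ours = search.search_genome(queries, genome)
        for rec in truth.records:
            in_blast = any(
                c == rec.contig_id and s < rec.end and rec.start < e
                for c, s, e in blast_hits
            )
            in_ours = any(
                h.contig_id == rec.contig_id
                and h.start < rec.end and rec.start < h.end
                for h in ours
            )
            assert in_blast and in_ours


class TestFilterHits:
    @pytest.mark.parametrize(
        "length,kept", [(99, False), (100, True), (101, True)]
    )
    def test_minimum_span_boundary(self, length, kept):
        hits = [_hit(start=0, end=length)]
        hits[0].aln_len = length
        out = search.filter_hits(hits, SearchParams())
        assert (len(out) == 1) is kept

    def test_empty_list(self):
        assert search.filter_hits([], SearchParams()) == []


class TestMergeHits:
    def test_overlapping_hits_union(self):
        hits = [_hit(start=100, end=400), _hit(start=350, end=700)]
        loci = search.merge_hits(hits)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (100, 700)

    def test_abutting_halfopen_intervals_stay_separate(self):
        hits = [_hit(start=100, end=400), _hit(start=400, end=700)]
        assert len(search.merge_hits(hits)) == 2

    def test_split_frame_hits_within_gap_merge(self):
        # frameshifted pseudogene: adjacent hits in different frames
        hits = [
            _hit(start=100, end=400, frame=0),
            _hit(start=430, end=700, frame=1),
        ]
        loci = search.merge_hits(hits)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (100, 700)

    def test_opposite_strands_never_merge(self):
        hits = [_hit(strand="+", start=0, end=300),
                _hit(strand="-", start=100, end=400)]
        assert len(search.merge_hits(hits)) == 2

    def test_idempotent_and_hits_partitioned(self):
        rng = np.random.default_rng(8)
        hits = [
            _hit(start=s, end=s + int(rng.integers(50, 400)))
            for s in rng.integers(0, 5000, 80)
        ]
        loci = search.merge_hits(hits)
        as_hits = [
            _hit(start=l.start, end=l.end, score=1.0) for l in loci
        ]
        again = search.merge_hits(as_hits)
        assert [(l.start, l.end) for l in again] == [
            (l.start, l.end) for l in loci
        ]
        assigned = sorted(i for l in loci for i in l.hit_indices)
        assert assigned == list(range(len(hits)))

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_interval_union_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 60))
        ivals = []
        for _ in range(n):
            s = int(rng.integers(0, 2000))
            ivals.append((s, s + int(rng.integers(1, 300))))
        hits = [_hit(start=s, end=e) for s, e in ivals]  # all same frame
        got = [(l.start, l.end) for l in search.merge_hits(hits)]
        # oracle: repeated pairwise union until fixpoint
        merged = [list(i) for i in ivals]
        changed = True
        while changed:
            changed = False
            for i in range(len(merged)):
                for j in range(i + 1, len(merged)):
                    a, b = merged[i], merged[j]
                    if a[0] < b[1] and b[0] < a[1]:
                        a[0], a[1] = min(a[0], b[0]), max(a[1], b[1])
                        merged.pop(j)
                        changed = True
                        break
                if changed:
                    break
        assert sorted(got) == sorted((a, b) for a, b in merged)


class TestExtendLocus:
    @pytest.mark.parametrize(
        "interval,contig_len,expected",
        [
            ((600, 1500), 10_000, (100, 2000)),
            ((200, 900), 10_000, (0, 1400)),
            ((0, 500), 500, (0, 500)),
        ],
    )
    def test_flank_extension_clipped_to_contig(
        self, interval, contig_len, expected
    ):
        locus = CandidateLocus("c", "+", *interval)
        out = search.extend_locus(locus, SearchParams(), contig_len)
        assert (out.start, out.end) == expected
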