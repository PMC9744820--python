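"""The caller: dedup, clustering, criteria, scoring, spacer matching."""

from __future__ import annotations

import numpy as np
import pytest

from oracles import brute_force_spacer_scan
from peacseq.io import AlignedRead, GenomicInterval, read_alignments
from peacseq.sites import (
    CallConfig,
    CandidateSite,
    Cluster,
    apply_candidate_filters,
    call_sites,
    cluster_cut_sites,
    compute_peac_score,
    deduplicate,
    match_spacer,
    rank_sites,
)
from peacseq.util import random_dna, spawn_rng


def _read(rid, pos5, strand="+", umi="AAAAAAAAAA", primer="F1", mapq=60,
          length=100, ext=True):
    start = pos5 if strand == "+" else pos5 - length
    side = {"F": "forward", "R": "reverse"}[primer[0]] if primer else "none"
    return AlignedRead(
        read_id=rid, umi=umi, primer_id=primer, side=side,
        interval=GenomicInterval("chrS", start, start + length, strand),
        mapq=mapq, cigar="", extension_ok=ext)


class TestDeduplicate:
    def test_same_key_merged_keeping_best_mapq(self):
        a = _read("a", 100, mapq=30)
        b = _read("b", 100, mapq=60)
        out = deduplicate([a, b])
        assert [r.read_id for r in out] == ["b"]

    def test_different_umi_both_kept(self):
        out = deduplicate([_read("a", 100, umi="A" * 10), _read("b", 100, umi="C" * 10)])
        assert len(out) == 2

    def test_idempotent(self):
        reads = [_read(f"r{i}", 100 + (i % 3), umi="ACGTACGTAC") for i in range(9)]
        once = deduplicate(reads)
        assert deduplicate(once) == once

    def test_duplication_factor_recovered_exactly(self, tag, tmp_path):
        """With PCR duplication factor 3 planted, the deduplicated count
        equals the truth unique-molecule recount."""
        from peacseq.simulate import LibraryParams, generate_reference, plant_sites, simulate_library
        spacer = random_dna(spawn_rng(21, "sp"), 20)
        ref, sites = plant_sites(generate_reference(40_000, 0.45, 21), spacer, 1, [2], 21)
        truth = simulate_library(
            ref, sites, [], tag,
            LibraryParams(n_fragments=9_000, seed=21, pcr_dup_factor=3),
            str(tmp_path / "dup"))
        reads = [r for r in read_alignments(str(tmp_path / "dup_truth.sam")) if r.is_read1]
        dd = deduplicate(reads)
        unique = truth.per_read.drop_duplicates(
            subset=["chrom", "r1_strand", "r1_pos5", "umi", "primer_id"])
        assert len(dd) == len(unique)
        assert len(deduplicate(dd)) == len(dd)


class TestClustering:
    def test_nearby_reads_merge(self):
        reads = [_read("a", 100), _read("b", 105, umi="C" * 10)]
        assert len(cluster_cut_sites(reads, window=25)) == 1

    def test_distant_reads_split(self):
        reads = [_read("a", 100), _read("b", 600, umi="C" * 10)]
        assert len(cluster_cut_sites(reads, window=25)) == 2

    def test_cut_is_modal_junction(self):
        reads = [_read(f"r{i}", 100, umi=f"{i:010d}".replace("0", "A").replace("1", "C")
                       .replace("2", "G").replace("3", "T").replace("4", "A")
                       .replace("5", "C").replace("6", "G").replace("7", "T")
                       .replace("8", "A").replace("9", "C"))
                 for i in range(3)] + [_read("x", 103, umi="G" * 10)]
        cl = cluster_cut_sites(reads, window=25)
        assert len(cl) == 1
        assert cl[0].cut_pos == 100

    def test_planted_sites_one_cluster_each_within_2bp(self, default_bundle):
        all_sites, called = call_sites(
            default_bundle.sam, default_bundle.wt_sam, default_bundle.ref.seq,
            default_bundle.spacer, default_bundle.tag)
        truth_cuts = sorted(s.cut for s in default_bundle.sites)
        called_cuts = sorted(s.cut_pos for s in called)
        assert len(called_cuts) == len(truth_cuts)
        assert all(abs(a - b) <= 2 for a, b in zip(called_cuts, truth_cuts))


class TestCandidateFilters:
    def _cluster(self, ext_f=3, ext_r=2):
        reads = (
            [_read(f"f{i}", 100, "+", umi=random_dna(spawn_rng(i, "f"), 10),
                   primer="F1") for i in range(ext_f)]
            + [_read(f"r{i}", 100, "-", umi=random_dna(spawn_rng(i, "r"), 10),
                     primer="R2") for i in range(ext_r)]
        )
        return Cluster(chrom="chrS", cut_pos=100, reads=reads)

    def test_all_criteria_pass(self):
        verdicts, wt, strand = apply_candidate_filters(
            self._cluster(), {}, CallConfig())
        assert verdicts == {"wt": True, "extension": True, "strand": True}
        assert wt == 0 and strand == "+"

    def test_wt_signal_fails_criterion(self):
        wt_idx = {"chrS": np.array([95, 96, 99, 104, 110], dtype=np.int64)}
        verdicts, wt, _ = apply_candidate_filters(self._cluster(), wt_idx, CallConfig())
        assert wt == 5
        assert verdicts["wt"] is False
        # raising max_wt relaxes the criterion monotonically
        verdicts2, _, _ = apply_candidate_filters(
            self._cluster(), wt_idx, CallConfig(max_wt=5))
        assert verdicts2["wt"] is True

    def test_unidirectional_fails_strict_geometric_mean(self):
        verdicts, _, _ = apply_candidate_filters(
            self._cluster(ext_f=4, ext_r=0), {}, CallConfig())
        assert verdicts["extension"] is False
        loose, _, _ = apply_candidate_filters(
            self._cluster(ext_f=4, ext_r=0), {},
            CallConfig(bidirectional_required=False))
        assert loose["extension"] is True

    def test_wrong_strand_fails_criterion(self):
        # reverse-side reads placed downstream on the wrong strand
        reads = [_read("f0", 100, "+", primer="F1"),
                 _read("r0", 100, "+", primer="R2", umi="C" * 10)]
        verdicts, _, _ = apply_candidate_filters(
            Cluster("chrS", 100, reads), {}, CallConfig())
        assert verdicts["strand"] is False


class TestPeacScore:
    def test_rpm_sum(self):
        rf, rr, score = compute_peac_score(5, 0, 1_000_000, 1_000_000)
        assert (rf, rr, score) == (5.0, 0.0, 5.0)
        assert compute_peac_score(0, 0, 10, 10)[2] == 0.0

    def test_zero_library_with_count_is_error(self):
        with pytest.raises(ValueError):
            compute_peac_score(1, 0, 0, 100)

    def test_scores_rank_sites_like_truth_counts(self, default_bundle):
        all_sites, called = call_sites(
            default_bundle.sam, default_bundle.wt_sam, default_bundle.ref.seq,
            default_bundle.spacer, default_bundle.tag)
        truth = default_bundle.truth
        order_by_score = [s.cut_pos for s in sorted(called, key=lambda s: -s.peac_score)]
        # truth ext-intact tag-read counts per site, same ordering
        tr = truth.per_read
        tagged = tr[tr["origin"].str.startswith("site") & tr["ext_intact"]]
        counts = tagged.groupby("cut").size().sort_values(ascending=False)
        assert order_by_score == [int(c) for c in counts.index]

    def test_rank_ids_descending_with_coordinate_ties(self):
        sites = [
            CandidateSite("chrS", 500, "+", 1, 1, 1, 1, peac_score=2.0),
            CandidateSite("chrS", 100, "+", 1, 1, 1, 1, peac_score=2.0),
            CandidateSite("chrS", 300, "+", 1, 1, 1, 1, peac_score=9.0),
        ]
        ranked = rank_sites(sites)
        assert [(s.peac_id, s.cut_pos) for s in ranked] == [(1, 300), (2, 100), (3, 500)]


class TestMatchSpacer:
    def test_planted_on_target_zero_mismatches(self, default_bundle):
        on = default_bundle.sites[0]
        m = match_spacer(default_bundle.ref.seq, on.cut, default_bundle.spacer)
        assert m is not None and m.n_mismatch == 0
        assert m.strand == on.strand

    def test_planted_mismatch_positions_recovered(self, default_bundle):
        for site in default_bundle.sites[1:]:
            m = match_spacer(default_bundle.ref.seq, site.cut, default_bundle.spacer)
            assert m is not None
            assert m.mismatch_positions == site.mismatch_positions

    def test_scrambled_region_returns_none(self):
        rng = spawn_rng(33, "scram")
        ref = random_dna(rng, 400)
        spacer = random_dna(rng, 20)
        assert match_spacer(ref, 200, spacer, max_mm=2) is None

    def test_oracle_equivalence_200_random_cases(self):
        """The windowed search equals an independent brute-force Hamming scan
        on 200 randomized cases, exactly."""
        rng = spawn_rng(99, "oracle")
        agree = 0
        for case in range(200):
            ref = list(random_dna(rng, 360))
            spacer = random_dna(rng, 20)
            # plant a mutated copy near the middle half the time
            if case % 2 == 0:
                s = int(rng.integers(140, 190))
                proto = list(spacer)
                for p in rng.choice(20, size=int(rng.integers(0, 5)), replace=False):
                    proto[p] = "ACGT"[int(rng.integers(4))]
                ref[s : s + 20] = proto
                ref[s + 20 : s + 23] = ["A", "G", "G"]
            ref = "".join(ref)
            cut = 180
            got = match_spacer(ref, cut, spacer, search_window=25, max_mm=7)
            want = brute_force_spacer_scan(ref, cut, spacer, window=25, max_mm=7)
            if want is None:
                assert got is None
            else:
                assert got is not None
                assert (got.n_mismatch, got.mismatch_positions, got.strand) == want[:3]
            agree += 1
        assert agree == 200


class TestEndToEnd:
    def test_recovery_sensitivity_and_fdr(self, default_bundle):
        """All planted edited sites called, nothing else; the WT library
        yields zero calls."""
        all_sites, called = call_sites(
            default_bundle.sam, default_bundle.wt_sam, default_bundle.ref.seq,
            default_bundle.spacer, default_bundle.tag)
        truth_cuts = {s.cut for s in default_bundle.sites}
        called_cuts = {s.cut_pos for s in called}
        assert all(min(abs(c - t) for t in truth_cuts) <= 2 for c in called_cuts)
        assert len(called) == len(truth_cuts)
        # WT as sample: zero calls
        _, wt_called = call_sites(
            default_bundle.wt_sam, default_bundle.wt_sam, default_bundle.ref.seq,
            default_bundle.spacer, default_bundle.tag)
        assert wt_called == []

    def test_spacer_matches_annotated_with_truth_mismatches(self, default_bundle):
        _, called = call_sites(
            default_bundle.sam, default_bundle.wt_sam, default_bundle.ref.seq,
            default_bundle.spacer, default_bundle.tag)
        by_cut = {s.cut: s for s in default_bundle.sites}
        for c in called:
            site = min(by_cut.values(), key=lambda s: abs(s.cut - c.cut_pos))
            assert c.spacer_match is not None
            assert c.spacer_match.mismatch_positions == site.mismatch_positions
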