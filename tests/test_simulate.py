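"""Simulator: determinism, composition recounts, and geometry realizability."""

from __future__ import annotations

import math

import numpy as np
import pytest

from peacseq.io import read_alignments
from peacseq.simulate import (
    JunctionSpec,
    LibraryParams,
    generate_reference,
    plant_sites,
    simulate_library,
    simulate_wt_control,
)
from peacseq.util import hamming, revcomp, random_dna, spawn_rng


class TestGenerateReference:
    def test_deterministic_and_seed_sensitive(self):
        a = generate_reference(10_000, 0.5, 7)
        b = generate_reference(10_000, 0.5, 7)
        c = generate_reference(10_000, 0.5, 8)
        assert a.seq == b.seq
        assert a.seq != c.seq
        assert len(a.seq) == 10_000

    def test_gc_fraction_recount(self):
        ref = generate_reference(100_000, 0.40, 1)
        gc = sum(b in "GC" for b in ref.seq) / ref.length
        assert 0.38 <= gc <= 0.42

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            generate_reference(0, 0.5, 1)
        with pytest.raises(ValueError):
            generate_reference(100, 1.5, 1)


class TestPlantSites:
    def test_on_target_only_single_exact_match(self):
        spacer = random_dna(spawn_rng(3, "sp"), 20)
        ref, sites = plant_sites(generate_reference(30_000, 0.5, 3), spacer, 0, [], 3)
        hits = ref.seq.count(spacer) + revcomp(ref.seq).count(spacer)
        assert hits == 1
        assert sites[0].mismatch_positions == ()

    def test_planted_mismatches_hamming_recount(self):
        spacer = random_dna(spawn_rng(4, "sp"), 20)
        ref, sites = plant_sites(generate_reference(30_000, 0.5, 4), spacer, 1, [3], 4)
        off = sites[1]
        s, e = off.interval.start, off.interval.end
        written = ref.seq[s:e] if off.strand == "+" else revcomp(ref.seq[s:e])
        assert hamming(written, spacer) == 3
        assert [i + 1 for i in range(20) if written[i] != spacer[i]] == list(off.mismatch_positions)
        # the PAM really follows the protospacer
        pam = ref.seq[e : e + 3] if off.strand == "+" else revcomp(ref.seq[s - 3 : s])
        assert pam[1:] == "GG"

    def test_same_seed_same_coordinates(self):
        spacer = random_dna(spawn_rng(5, "sp"), 20)
        ref0 = generate_reference(30_000, 0.5, 5)
        _, a = plant_sites(ref0, spacer, 2, [1, 2], 9)
        _, b = plant_sites(ref0, spacer, 2, [1, 2], 9)
        assert [s.interval for s in a] == [s.interval for s in b]

    def test_capacity_error(self):
        spacer = random_dna(spawn_rng(6, "sp"), 20)
        with pytest.raises(ValueError, match="cannot host"):
            plant_sites(generate_reference(10_000, 0.5, 6), spacer, 10,
                        [1] * 10, 6)


class TestSimulateLibrary:
    def test_conservation_and_truth_sam(self, default_bundle):
        tr = default_bundle.truth.per_read
        assert len(tr) == 50_000
        assert set(tr["origin"]).issubset(
            {f"site:{i}" for i in range(7)} | {"random_priming", "background"})
        # per-site read counts in the sites table equal per_read recounts
        for row in default_bundle.truth.sites.itertuples(index=False):
            assert row.n_read_pairs == (tr["site_idx"] == row.site_idx).sum()
        # truth SAM holds both mates of every pair
        reads = list(read_alignments(default_bundle.sam))
        assert len(reads) == 2 * 50_000

    def test_zero_insertion_rate_yields_no_tag_reads(self, tag, tmp_path):
        spacer = random_dna(spawn_rng(8, "sp"), 20)
        ref, sites = plant_sites(
            generate_reference(30_000, 0.5, 8), spacer, 1, [2], 8,
            insertion_rates=[0.0, 0.0])
        truth = simulate_library(
            ref, sites, [], tag, LibraryParams(n_fragments=2_000, seed=8),
            str(tmp_path / "zi"))
        assert not truth.per_read["origin"].str.startswith("site").any()
        assert not truth.per_read["ext_intact"].any()

    def test_full_length_tags_contain_whole_tag(self, tag, tmp_path):
        dist = np.zeros(22)
        dist[21] = 1.0
        spacer = random_dna(spawn_rng(9, "sp"), 20)
        ref, sites = plant_sites(generate_reference(30_000, 0.5, 9), spacer, 0, [], 9)
        truth = simulate_library(
            ref, sites, [], tag,
            LibraryParams(n_fragments=1_000, seed=9, seq_error_rate=0.0,
                          tag_truncation_dist=tuple(dist),
                          random_priming_rate=0.0, background_rate=0.0),
            str(tmp_path / "fl"))
        tagged = truth.per_read[truth.per_read["origin"] == "site:0"]
        assert len(tagged) == 1_000
        assert (tagged["tag_len"] == 21).all()
        assert tagged["ext_intact"].all()
        # every read 1 contains the expected full tag continuation
        import pysam
        with pysam.FastxFile(str(tmp_path / "fl_R1.fastq")) as fh:
            for entry, row in zip(fh, tagged.itertuples(index=False)):
                p = tag.primer(row.primer_id)
                cont = tag.full_tag_continuation(row.primer_id)
                assert entry.sequence.startswith(p.seq + cont)

    def test_junction_spec_must_reference_sites(self, tag, tmp_path):
        spacer = random_dna(spawn_rng(10, "sp"), 20)
        ref, sites = plant_sites(generate_reference(30_000, 0.5, 10), spacer, 2, [1, 2], 10)
        stray = JunctionSpec(sites[0], sites[2], "v", True, 0.1)
        with pytest.raises(ValueError, match="receiver not in the site list"):
            simulate_library(ref, [sites[1]], [stray], tag,
                             LibraryParams(n_fragments=100, seed=1),
                             str(tmp_path / "x"))


class TestWtControl:
    def test_no_extension_verified_reads_and_determinism(self, tag, tmp_path):
        from peacseq.readprep import verify_extension
        ref = generate_reference(50_000, 0.45, 12)
        params = LibraryParams(n_fragments=10_000, seed=12, random_priming_rate=0.01)
        t1 = simulate_wt_control(ref, tag, params, str(tmp_path / "a"))
        simulate_wt_control(ref, tag, params, str(tmp_path / "b"))
        assert (tmp_path / "a_R1.fastq").read_bytes() == (tmp_path / "b_R1.fastq").read_bytes()
        assert not t1.per_read["ext_intact"].any()
        # ~n*rate misprimed pairs (binomial +-3 sigma), all failing extension
        n_mp = (t1.per_read["origin"] == "random_priming").sum()
        mu, sd = 10_000 * 0.01, math.sqrt(10_000 * 0.01 * 0.99)
        assert abs(n_mp - mu) <= 3 * sd
        n_ok = 0
        for r in read_alignments(str(tmp_path / "a_truth.sam")):
            if r.is_read1 and r.primer_id is not None:
                n_ok += verify_extension(r.seq, r.primer_id, tag)
        assert n_ok == 0


class TestJunctionRealizability:
    def test_every_model_realized_with_specified_geometry(self, junction_bundle):
        """Each planted junction yields at least one fragment whose two
        segments map to the specified receiver/donor ends in the specified
        orientation (checked against the truth SAM)."""
        bundle, jx_prefix, jx_truth, jx = junction_bundle
        recv_cut = jx[0].receiver.cut
        donor_cut = jx[0].donor.cut
        split = [r for r in read_alignments(jx_prefix + "_truth.sam")
                 if r.is_read1 and r.is_split]
        by_geometry = set()
        for r in split:
            s1, s2 = r.segments[0], r.segments[1]
            by_geometry.add((
                s1.interval.end, s2.interval.strand,
                s2.interval.start if s2.interval.strand == "+" else s2.interval.end,
            ))
        # model i: seg1 ends at receiver cut, seg2 resumes there on '+'
        assert (recv_cut, "+", recv_cut) in by_geometry
        # model ii: resected rejoin downstream of the cut
        assert any(g[0] < recv_cut and g[1] == "+" and recv_cut < g[2] <= recv_cut + 50
                   for g in by_geometry)
        # model iii/v: donor upstream end, inverted
        assert (recv_cut, "-", donor_cut) in by_geometry
        # model iv: donor downstream end, same orientation
        assert (recv_cut, "+", donor_cut) in by_geometry
        # conservation of the junction library ledger
        assert len(jx_truth.per_read) == 3_000
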