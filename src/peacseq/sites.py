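"""Cut-site calling from tag-enrichment alignments.

The caller consumes annotated alignments of the enriched sample and a matched
wild-type control, deduplicates by UMI, clusters tag/genome junction
positions into candidate cut sites, applies three candidate criteria
(no wild-type signal; extension-verified reads with positive geometric mean
across directions; correct read strandedness on both sides of the inferred
cut), scores each site by the RPM-normalized sum of extension-verified reads
(the PEAC score), and locates the best spacer+PAM match near the cut.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import AlignedRead, GenomicInterval, read_alignments
from .readprep import TagDesign, verify_extension
from .util import mismatch_positions as _mm_positions
from .util import revcomp


@dataclass
class CallConfig:
    """Thresholds for candidate calling; defaults follow the pipeline's
    standard analysis settings."""

    window: int = 25            # junction clustering / WT lookup window (bp)
    search_window: int = 25     # spacer scan half-width around the cut (bp)
    max_mm_spacer: int = 7      # max spacer mismatches reported
    max_wt: int = 0             # criterion 1: max deduplicated WT evidence
    min_ext: int = 8            # extension verification window cap (bp)
    bidirectional_required: bool = True  # criterion 2 geometric-mean reading
    min_reads: int = 1          # minimum deduplicated reads to form a cluster


@dataclass(frozen=True)
class SpacerMatch:
    """Best protospacer+PAM match near a cut site.

    ``interval`` spans the full 23 nt (protospacer + PAM); positions in
    ``mismatch_positions`` are 1-based along the spacer 5'->3'.
    """

    interval: GenomicInterval
    strand: str
    matched_seq: str
    pam: str
    mismatch_positions: tuple[int, ...]

    @property
    def n_mismatch(self) -> int:
        return len(self.mismatch_positions)


@dataclass
class CandidateSite:
    chrom: str
    cut_pos: int
    site_strand: str
    fwd_count: int
    rev_count: int
    ext_fwd: int
    ext_rev: int
    rpm_fwd: float = 0.0
    rpm_rev: float = 0.0
    peac_score: float = 0.0
    wt_count: int = 0
    spacer_match: SpacerMatch | None = None
    verdicts: dict = field(default_factory=dict)
    peac_id: int = 0
    reads: list[AlignedRead] = field(default_factory=list)

    @property
    def called(self) -> bool:
        return bool(self.verdicts) and all(self.verdicts.values())


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def _dedup_key(read: AlignedRead) -> tuple:
    return (
        read.interval.chrom,
        read.interval.strand,
        read.five_prime,
        read.umi,
        read.primer_id,
    )


def deduplicate(reads: Iterable[AlignedRead]) -> list[AlignedRead]:
    """Merge PCR duplicates: one representative per
    (chrom, strand, 5'-position, UMI, primer) key.

    The representative is the highest-mapq read, ties broken by input order,
    so the operation is idempotent and deterministic.
    """
    best: dict[tuple, AlignedRead] = {}
    for r in reads:
        k = _dedup_key(r)
        cur = best.get(k)
        if cur is None or r.mapq > cur.mapq:
            best[k] = r
    return list(best.values())


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    chrom: str
    cut_pos: int
    reads: list[AlignedRead]

    def side_reads(self, side: str, ext_only: bool = False) -> list[AlignedRead]:
        return [
            r for r in self.reads
            if r.side == side and (not ext_only or getattr(r, "extension_ok", False))
        ]


def cluster_cut_sites(reads: Sequence[AlignedRead], window: int = 25) -> list[Cluster]:
    """Group junction positions (read 5' ends) within ``window`` bases on the
    same chromosome into clusters; forward- and reverse-side evidence merges
    into the same cluster when their junctions agree.

    The cluster cut position is the modal junction among extension-verified
    reads (falling back to all reads), ties broken toward the smallest
    coordinate.
    """
    items = sorted(reads, key=lambda r: (r.interval.chrom, r.five_prime, r.read_id))
    clusters: list[Cluster] = []
    cur: list[AlignedRead] = []
    last_pos = None
    last_chrom = None
    for r in items:
        pos = r.five_prime
        if cur and (r.interval.chrom != last_chrom or pos - last_pos > window):
            clusters.append(_finish_cluster(cur))
            cur = []
        cur.append(r)
        last_pos = pos
        last_chrom = r.interval.chrom
    if cur:
        clusters.append(_finish_cluster(cur))
    return clusters


def _finish_cluster(reads: list[AlignedRead]) -> Cluster:
    ext = [r for r in reads if getattr(r, "extension_ok", False)]
    basis = ext if ext else reads
    counts: dict[int, int] = {}
    for r in basis:
        counts[r.five_prime] = counts.get(r.five_prime, 0) + 1
    cut = min(sorted(counts), key=lambda p: (-counts[p], p))
    return Cluster(chrom=reads[0].interval.chrom, cut_pos=cut, reads=reads)


# ---------------------------------------------------------------------------
# candidate criteria
# ---------------------------------------------------------------------------

def _infer_strand(cluster: Cluster) -> str:
    """Site orientation from the amplicon geometry: forward-primer reads run
    with the protospacer (plus strand alignments for a plus-strand site)."""
    votes = {"+": 0, "-": 0}
    for r in cluster.side_reads("forward", ext_only=True) or cluster.side_reads("forward"):
        votes[r.interval.strand] += 1
    if votes["+"] == votes["-"]:
        for r in cluster.side_reads("reverse", ext_only=True) or cluster.side_reads("reverse"):
            votes["-" if r.interval.strand == "+" else "+"] += 1
    return "+" if votes["+"] >= votes["-"] else "-"


def _read_correctly_placed(r: AlignedRead, cut: int, site_strand: str, slop: int = 2) -> bool:
    """Whether a read lies on the side of the cut its primer implies, with
    the implied alignment strand."""
    want_fwd_strand = "+" if site_strand == "+" else "-"
    if r.side == "forward":
        if r.interval.strand != want_fwd_strand:
            return False
        if site_strand == "+":
            return r.interval.start >= cut - slop
        return r.interval.end <= cut + slop
    if r.side == "reverse":
        if r.interval.strand == want_fwd_strand:
            return False
        if site_strand == "+":
            return r.interval.end <= cut + slop
        return r.interval.start >= cut - slop
    return False


def apply_candidate_filters(
    cluster: Cluster,
    wt_positions: dict[str, np.ndarray],
    config: CallConfig,
) -> tuple[dict, int, str]:
    """Evaluate the three candidate criteria for one cluster.

    Returns (verdicts, wt_count, site_strand).  Criterion 1: deduplicated
    wild-type evidence within the window does not exceed ``max_wt``.
    Criterion 2: extension-verified reads in at least one direction and a
    positive geometric mean across directions (strict bidirectional reading
    by default).  Criterion 3: extension-verified reads present on both
    sides of the cut with the orientation the amplicon design implies.
    """
    ext_f = len(cluster.side_reads("forward", ext_only=True))
    ext_r = len(cluster.side_reads("reverse", ext_only=True))
    wt = wt_positions.get(cluster.chrom, np.empty(0, dtype=np.int64))
    lo = np.searchsorted(wt, cluster.cut_pos - config.window, side="left")
    hi = np.searchsorted(wt, cluster.cut_pos + config.window, side="right")
    wt_count = int(hi - lo)
    strand = _infer_strand(cluster)
    if config.bidirectional_required:
        c2 = (ext_f >= 1 or ext_r >= 1) and math.sqrt(ext_f * ext_r) > 0
    else:
        c2 = ext_f >= 1 or ext_r >= 1
    has_f = any(
        _read_correctly_placed(r, cluster.cut_pos, strand)
        for r in cluster.side_reads("forward", ext_only=True)
    )
    has_r = any(
        _read_correctly_placed(r, cluster.cut_pos, strand)
        for r in cluster.side_reads("reverse", ext_only=True)
    )
    verdicts = {
        "wt": wt_count <= config.max_wt,
        "extension": bool(c2),
        "strand": has_f and has_r,
    }
    return verdicts, wt_count, strand


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def compute_peac_score(
    ext_fwd: int, ext_rev: int, lib_fwd: int, lib_rev: int
) -> tuple[float, float, float]:
    """PEAC score: reads-per-million-normalized extension-verified counts
    summed over the two amplicon directions.

    Returns (rpm_fwd, rpm_rev, score).  Library sizes are per-side
    deduplicated read totals; a zero library size with a nonzero count is an
    error, with a zero count it contributes zero.
    """
    def rpm(x: int, n: int) -> float:
        if x == 0:
            return 0.0
        if n <= 0:
            raise ValueError("nonzero count with zero library size")
        return 1e6 * x / n

    rf, rr = rpm(ext_fwd, lib_fwd), rpm(ext_rev, lib_rev)
    return rf, rr, rf + rr


def rank_sites(sites: list[CandidateSite]) -> list[CandidateSite]:
    """Assign PEAC-IDs 1..N in descending PEAC-score order (stable; ties by
    coordinate)."""
    ordered = sorted(sites, key=lambda s: (-s.peac_score, s.chrom, s.cut_pos))
    for i, s in enumerate(ordered, start=1):
        s.peac_id = i
    return ordered


# ---------------------------------------------------------------------------
# spacer matching
# ---------------------------------------------------------------------------

_PAM_RANK = {"GG": 0, "AG": 1}


def match_spacer(
    ref_seq: str,
    cut_pos: int,
    spacer: str,
    search_window: int = 25,
    max_mm: int = 7,
    chrom: str = "",
) -> SpacerMatch | None:
    """Exhaustive scan of both strands for the best 20-mer + NGG/NAG whose
    implied cut lies within ``search_window`` of ``cut_pos``.

    Minimal-mismatch match wins; ties break NGG before NAG, then smallest
    implied-cut distance, then plus strand, then coordinate.  Returns None if
    nothing has <= ``max_mm`` spacer mismatches.  Windows beyond the sequence
    bounds are clipped.
    """
    if len(spacer) != 20:
        raise ValueError("spacer must be 20 nt")
    L = len(ref_seq)
    candidates = []
    for c in range(cut_pos - search_window, cut_pos + search_window + 1):
        # plus strand: protospacer [s, s+20), PAM [s+20, s+23), cut = s+17
        s = c - 17
        if 0 <= s and s + 23 <= L:
            pam = ref_seq[s + 20 : s + 23]
            if pam[1:] in _PAM_RANK:
                proto = ref_seq[s : s + 20]
                mm = tuple(_mm_positions(spacer, proto))
                if len(mm) <= max_mm:
                    candidates.append(
                        (len(mm), _PAM_RANK[pam[1:]], abs(c - cut_pos), 0, s,
                         proto, pam, mm, "+", s, s + 23)
                    )
        # minus strand: protospacer [s, s+20) read 5'->3' on '-', PAM at
        # [s-3, s) on the plus strand (revcomp), cut = s+3
        s = c - 3
        if s - 3 >= 0 and s + 20 <= L:
            pam = revcomp(ref_seq[s - 3 : s])
            if pam[1:] in _PAM_RANK:
                proto = revcomp(ref_seq[s : s + 20])
                mm = tuple(_mm_positions(spacer, proto))
                if len(mm) <= max_mm:
                    candidates.append(
                        (len(mm), _PAM_RANK[pam[1:]], abs(c - cut_pos), 1, s,
                         proto, pam, mm, "-", s - 3, s + 20)
                    )
    if not candidates:
        return None
    best = min(candidates)
    _, _, _, _, _, proto, pam, mm, strand, start, end = best
    return SpacerMatch(
        interval=GenomicInterval(chrom or "ref", start, end, strand),
        strand=strand,
        matched_seq=proto,
        pam=pam,
        mismatch_positions=mm,
    )


# ---------------------------------------------------------------------------
# end-to-end calling
# ---------------------------------------------------------------------------

def _load_primary_read1(sam_path: str, tag: TagDesign, config: CallConfig,
                        annotations=None) -> list[AlignedRead]:
    out = []
    for r in read_alignments(sam_path, annotations=annotations):
        if not r.is_read1:
            continue
        if r.primer_id is not None and r.seq:
            r.extension_ok = verify_extension(r.seq, r.primer_id, tag, min_ext=config.min_ext)
        out.append(r)
    return out


def call_sites(
    sample_sam: str,
    wt_sam: str,
    ref_seq: str,
    spacer: str,
    tag: TagDesign,
    config: CallConfig | None = None,
    annotations=None,
    wt_annotations=None,
) -> tuple[list[CandidateSite], list[CandidateSite]]:
    """Run the full caller: returns (all candidate clusters with verdicts,
    the called subset), both carrying PEAC-IDs.

    Called sites are ranked 1..K by descending PEAC score; rejected clusters
    continue the numbering (the site table doubles as the audit log via the
    per-criterion verdict columns).
    """
    config = config or CallConfig()
    sample = _load_primary_read1(sample_sam, tag, config, annotations)
    wt = _load_primary_read1(wt_sam, tag, config, wt_annotations)
    sample_dd = deduplicate(sample)
    wt_dd = deduplicate(wt)
    lib_f = sum(1 for r in sample_dd if r.side == "forward")
    lib_r = sum(1 for r in sample_dd if r.side == "reverse")
    wt_pos: dict[str, list[int]] = {}
    for r in wt_dd:
        if r.primer_id is not None:
            wt_pos.setdefault(r.interval.chrom, []).append(r.five_prime)
    wt_idx = {c: np.array(sorted(v), dtype=np.int64) for c, v in wt_pos.items()}
    evidence = [r for r in sample_dd if r.primer_id is not None]
    clusters = cluster_cut_sites(evidence, window=config.window)
    sites: list[CandidateSite] = []
    for cl in clusters:
        if len(cl.reads) < config.min_reads:
            continue
        verdicts, wt_count, strand = apply_candidate_filters(cl, wt_idx, config)
        ext_f = len(cl.side_reads("forward", ext_only=True))
        ext_r = len(cl.side_reads("reverse", ext_only=True))
        rpm_f, rpm_r, score = compute_peac_score(ext_f, ext_r, lib_f, lib_r)
        match = match_spacer(
            ref_seq, cl.cut_pos, spacer,
            search_window=config.search_window, max_mm=config.max_mm_spacer,
            chrom=cl.chrom,
        )
        sites.append(CandidateSite(
            chrom=cl.chrom, cut_pos=cl.cut_pos, site_strand=strand,
            fwd_count=len(cl.side_reads("forward")),
            rev_count=len(cl.side_reads("reverse")),
            ext_fwd=ext_f, ext_rev=ext_r,
            rpm_fwd=rpm_f, rpm_rev=rpm_r, peac_score=score,
            wt_count=wt_count, spacer_match=match, verdicts=verdicts,
            reads=cl.reads,
        ))
    called = [s for s in sites if s.called]
    rejected = [s for s in sites if not s.called]
    called = rank_sites(called)
    rejected = rank_sites(rejected)
    for s in rejected:
        s.peac_id += len(called)
    return called + rejected, called
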