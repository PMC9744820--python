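"""Readers/writers for the standard formats the pipeline touches.

Coordinate convention: everything in memory is 0-based half-open; 1-based
coordinates appear only in human-readable report columns and are labelled as
such.  All writers are byte-stable for fixed input (no timestamps, no
unordered iteration).

UMI and primer annotations travel in SAM optional tags (``RX`` for the UMI,
``XP`` for the primer id) so an external aligner can be slotted in without
losing them; alternatively they can be re-joined from a read-prep annotation
table by read id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam

from .util import revcomp

UMI_TAG = "RX"
PRIMER_TAG = "XP"


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SegmentAln:
    """One aligned segment of a (possibly split) read.

    ``qstart``/``qend`` are 0-based half-open offsets in the original read
    orientation (as sequenced), regardless of the alignment strand.
    """

    interval: GenomicInterval
    qstart: int
    qend: int


@dataclass
class AlignedRead:
    """One primary alignment with its pair-level annotations.

    ``segments`` lists all aligned segments (primary + supplementary) in
    read-coordinate order when the read is split.
    """

    read_id: str
    umi: str
    primer_id: str | None
    side: str  # forward | reverse | none
    interval: GenomicInterval
    mapq: int
    cigar: str
    is_split: bool = False
    segments: list[SegmentAln] = field(default_factory=list)
    is_read1: bool = True
    seq: str = ""
    extension_ok: bool = False

    @property
    def five_prime(self) -> int:
        """Reference coordinate of the read's 5' end (the tag/genome junction
        for enrichment reads whose tag portion is soft-clipped)."""
        return self.interval.start if self.interval.strand == "+" else self.interval.end


_SIDE_BY_PREFIX = {"F": "forward", "R": "reverse"}


def _segment_from_record(rec: pysam.AlignedSegment, chrom: str) -> SegmentAln:
    qstart = rec.query_alignment_start
    qend = rec.query_alignment_end
    total = rec.infer_read_length() or (qend + (rec.cigartuples[-1][1] if rec.cigartuples and rec.cigartuples[-1][0] in (4, 5) else 0))
    if rec.is_reverse:
        qstart, qend = total - qend, total - qstart
    strand = "-" if rec.is_reverse else "+"
    return SegmentAln(
        interval=GenomicInterval(chrom, rec.reference_start, rec.reference_end, strand),
        qstart=qstart,
        qend=qend,
    )


def read_alignments(
    path: str,
    annotations: dict[str, tuple[str, str | None, str, bool]] | None = None,
) -> Iterator[AlignedRead]:
    """Stream primary alignments as :class:`AlignedRead`.

    Supplementary alignments are folded into ``segments`` of their primary
    record.  Annotations (umi, primer_id, side, extension_ok) come from SAM
    tags when present, else from the ``annotations`` map keyed by read id;
    reads with neither are yielded with ``primer_id=None`` / ``side='none'``
    (background reads are legitimate input).
    """
    supp: dict[tuple[str, bool], list] = {}
    primaries: list[pysam.AlignedSegment] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        chroms = list(fh.references)
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            if rec.is_supplementary:
                supp.setdefault((rec.query_name, rec.is_read1), []).append(
                    _segment_from_record(rec, chroms[rec.reference_id])
                )
            else:
                primaries.append(rec)
    for rec in primaries:
        chrom = chroms[rec.reference_id]
        umi, primer_id, side = "", None, "none"
        if rec.has_tag(UMI_TAG):
            umi = rec.get_tag(UMI_TAG)
        if rec.has_tag(PRIMER_TAG):
            primer_id = rec.get_tag(PRIMER_TAG) or None
            if primer_id:
                side = _SIDE_BY_PREFIX.get(primer_id[0], "none")
        ext_ok = False
        if annotations is not None and rec.query_name in annotations:
            a_umi, a_primer, a_side, a_ext = annotations[rec.query_name]
            umi = umi or a_umi
            ext_ok = a_ext
            if primer_id is None and a_primer:
                primer_id, side = a_primer, a_side
        primary_seg = _segment_from_record(rec, chrom)
        segs = [primary_seg] + supp.get((rec.query_name, rec.is_read1), [])
        segs.sort(key=lambda s: s.qstart)
        is_split = len(segs) > 1
        seq = rec.query_sequence or ""
        if rec.is_reverse and seq:
            seq = revcomp(seq)
        yield AlignedRead(
            read_id=rec.query_name,
            umi=umi,
            primer_id=primer_id,
            side=side,
            interval=primary_seg.interval,
            mapq=rec.mapping_quality,
            cigar=rec.cigarstring or "",
            is_split=is_split,
            segments=segs if is_split else [primary_seg],
            is_read1=not rec.is_read2,
            seq=seq,
            extension_ok=ext_ok,
        )


def read_annotations(path: str) -> dict[str, tuple[str, str | None, str, bool]]:
    """Load a read-prep annotation TSV into the map ``read_alignments`` joins."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = {}
    for row in df.itertuples(index=False):
        pid = None if row.primer_id in ("", "None", None) else row.primer_id
        out[row.read_id] = (row.umi, pid, row.side, row.extension_ok == "1")
    return out


SITE_COLUMNS = [
    "peac_id", "chrom", "cut_pos", "site_strand",
    "fwd_count", "rev_count", "ext_fwd", "ext_rev",
    "rpm_fwd", "rpm_rev", "peac_score", "wt_count",
    "pass_wt", "pass_extension", "pass_strand", "called",
    "spacer_start", "spacer_end", "spacer_strand", "matched_seq", "pam",
    "n_mismatch", "mismatch_positions",
]


def write_sites(sites: Iterable, tsv_path: str, bed_path: str) -> None:
    """Write candidate sites as a TSV (all scores/verdicts) and a BED of the
    23-nt protospacer+PAM spans, ordered by PEAC-ID.

    Sites without a spacer match get a cut-centred 23-base BED interval with
    strand '.'.
    """
    rows = []
    bed_lines = []
    for s in sorted(sites, key=lambda s: s.peac_id if s.peac_id else 10**9):
        m = s.spacer_match
        if m is not None:
            start, end, strand = m.interval.start, m.interval.end, m.interval.strand
            matched, pam = m.matched_seq, m.pam
            n_mm = m.n_mismatch
            mm_pos = ",".join(map(str, m.mismatch_positions))
        else:
            start, end, strand = max(0, s.cut_pos - 11), s.cut_pos + 12, "."
            matched, pam, n_mm, mm_pos = "", "", "", ""
        rows.append([
            s.peac_id, s.chrom, s.cut_pos, s.site_strand,
            s.fwd_count, s.rev_count, s.ext_fwd, s.ext_rev,
            f"{s.rpm_fwd:.6f}", f"{s.rpm_rev:.6f}", f"{s.peac_score:.6f}", s.wt_count,
            int(s.verdicts["wt"]), int(s.verdicts["extension"]), int(s.verdicts["strand"]),
            int(s.called), start, end, strand, matched, pam, n_mm, mm_pos,
        ])
        bed_lines.append(
            f"{s.chrom}\t{start}\t{end}\tPEAC-{s.peac_id}\t{s.peac_score:.4f}\t{strand}\n"
        )
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(SITE_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
    with open(bed_path, "w") as fh:
        fh.writelines(bed_lines)


def read_sites(path: str) -> pd.DataFrame:
    """Read back a site TSV written by :func:`write_sites`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site table {path} is missing columns: {missing}")
    return df


def write_signal_track(
    reads: Iterable[AlignedRead],
    chrom_sizes: dict[str, int],
    path: str,
) -> None:
    """Write per-base coverage of the given (already deduplicated) reads as a
    bedGraph; zero-coverage runs are omitted."""
    cov: dict[str, np.ndarray] = {}
    for r in reads:
        c = r.interval.chrom
        if c not in cov:
            cov[c] = np.zeros(chrom_sizes[c] + 1, dtype=np.int64)
        cov[c][r.interval.start] += 1
        cov[c][r.interval.end] -= 1
    with open(path, "w") as fh:
        for c in sorted(cov):
            depth = np.cumsum(cov[c][:-1])
            if not depth.any():
                continue
            edges = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate([[0], edges])
            ends = np.concatenate([edges, [len(depth)]])
            for s, e in zip(starts, ends):
                v = depth[s]
                if v > 0:
                    fh.write(f"{c}\t{s}\t{e}\t{v}\n")


def write_fasta(seqs: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
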