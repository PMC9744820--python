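"""Synthetic tag-insertion enrichment libraries with a ground-truth ledger.

The generator emulates the structure of a prime-editor tag-insertion library:

* a reference sequence carrying one on-target protospacer and a configurable
  set of off-target variants (each followed by an NGG PAM);
* Cas9 cuts bluntly 3 bp upstream of the PAM (between protospacer positions
  17/18); edited molecules carry a 21-nt tag reverse-transcribed into the cut,
  full-length or 3'-truncated;
* Tn5 tagmentation fragments the molecules; enrichment PCR pairs one primer
  inside the tag with the Tn5 adapter.  Forward-primer amplicons read
  tag -> downstream genome; reverse-primer amplicons read tag -> upstream
  genome.  The Tn5-side read starts with a 10-nt UMI and a fixed 4-nt spacer;
* random-priming pairs arise where the genome matches the primer's
  3'-terminal 8 bases: the read contains the primer followed by genomic
  sequence, so it carries no tag continuation;
* translocation junction molecules join double-strand-break ends between a
  receiver and a donor site in five geometries (models i-v).

Every emitted read pair is recorded in the truth ledger with its origin, UMI,
intended alignment, and whether its primer-extension window was intact, so
every downstream stage can be checked against an exact recount.  A truth SAM
carries the error-free intended alignment of every genomic segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .io import GenomicInterval, PRIMER_TAG, UMI_TAG
from .readprep import TagDesign, UMI_SPACER
from .util import apply_errors, random_dna, revcomp, spawn_rng

#: extension window used when recording ``ext_intact`` in the truth ledger
#: (matches the read-prep default)
DEFAULT_MIN_EXT = 8

MODELS = ("i", "ii", "iii", "iv", "v")


@dataclass
class ReferenceSequence:
    name: str
    seq: str

    def __post_init__(self) -> None:
        if set(self.seq) - set("ACGT"):
            raise ValueError("reference alphabet must be A/C/G/T")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PlantedSite:
    """One planted protospacer (0-based half-open 20-nt interval) + PAM."""

    interval: GenomicInterval
    strand: str
    pam: str
    mismatch_positions: tuple[int, ...]
    insertion_rate: float
    edit_rate: float

    def __post_init__(self) -> None:
        if len(self.pam) != 3 or self.pam[1:] not in ("GG", "AG"):
            raise ValueError(f"PAM must match NGG/NAG, got {self.pam}")
        mp = self.mismatch_positions
        if list(mp) != sorted(set(mp)) or any(not 1 <= p <= 20 for p in mp):
            raise ValueError("mismatch_positions must be sorted, unique, in 1..20")
        for r in (self.insertion_rate, self.edit_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")

    @property
    def cut(self) -> int:
        """Blunt cut coordinate, 3 bp upstream of the PAM (between
        protospacer positions 17/18)."""
        if self.strand == "+":
            return self.interval.start + 17
        return self.interval.start + 3


@dataclass
class LibraryParams:
    n_fragments: int = 50_000
    frag_len_mean: float = 350.0
    frag_len_sd: float = 80.0
    frag_len_min: int = 80
    read_len: int = 150
    umi_len: int = 10
    seq_error_rate: float = 0.0
    #: P(retained tag length = k), k = 0..21; default 60% full-length with
    #: the remainder uniform over 6..20 retained bases
    tag_truncation_dist: tuple[float, ...] = ()
    random_priming_rate: float = 0.02
    background_rate: float = 0.05
    pcr_dup_factor: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tag_truncation_dist:
            d = np.zeros(22)
            d[21] = 0.6
            d[6:21] = 0.4 / 15
            self.tag_truncation_dist = tuple(d)
        d = np.asarray(self.tag_truncation_dist, dtype=float)
        if len(d) != 22 or abs(d.sum() - 1.0) > 1e-9 or (d < 0).any():
            raise ValueError("tag_truncation_dist must be a length-22 probability vector")
        for r in (self.seq_error_rate, self.random_priming_rate, self.background_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.read_len < self.umi_len + len(UMI_SPACER) + 25:
            raise ValueError("read_len too short for UMI + primer + extension")
        if self.pcr_dup_factor < 1:
            raise ValueError("pcr_dup_factor must be >= 1")


@dataclass(frozen=True)
class JunctionSpec:
    """A donor->receiver DSB-end join.

    Models: (i) receiver ends religated with tag (the intended edit);
    (ii) receiver ends religated without tag (resected rejoin); (iii) donor
    upstream end joined, no tag; (iv) donor downstream end joined; (v) donor
    upstream end joined with its tag, reverse-oriented relative to the
    receiver.
    """

    receiver: PlantedSite
    donor: PlantedSite
    model: str
    tag_present: bool
    rate: float

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if self.model in ("iii", "iv") and self.tag_present:
            raise ValueError(f"model {self.model} joins a tag-free donor end")
        if self.model == "v" and not self.tag_present:
            raise ValueError("model v carries the donor tag by definition")
        if self.model == "i" and not self.tag_present:
            raise ValueError("model i is the tag religation")
        if self.model == "ii" and self.tag_present:
            raise ValueError("model ii is the tag-free religation")
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rate must be in [0, 1]")
        if self.receiver.strand != "+" or self.donor.strand != "+":
            raise ValueError("junction simulation supports plus-strand sites")
        if self.model in ("iii", "iv", "v") and self.donor.cut == self.receiver.cut:
            raise ValueError("inter-site models need distinct donor/receiver cuts")


PER_READ_COLUMNS = [
    "read_id", "molecule_id", "origin", "site_idx", "junction_idx",
    "side", "primer_id", "umi", "tag_len", "ext_intact",
    "chrom", "cut", "r1_strand", "r1_pos5", "r1_start", "r1_end",
    "r2_start", "r2_end",
]


@dataclass
class SimTruth:
    """Ground-truth ledger: planted sites, junction specs, and one row per
    emitted read pair."""

    sites: pd.DataFrame
    junctions: pd.DataFrame
    per_read: pd.DataFrame

    def check_conservation(self, n_emitted: int) -> None:
        if len(self.per_read) != n_emitted:
            raise AssertionError(
                f"conservation violated: {len(self.per_read)} ledger rows, "
                f"{n_emitted} emitted pairs"
            )

    def write(self, prefix: str) -> None:
        self.sites.to_csv(prefix + "_truth_sites.tsv", sep="\t", index=False)
        self.junctions.to_csv(prefix + "_truth_junctions.tsv", sep="\t", index=False)
        self.per_read.to_csv(prefix + "_truth_reads.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, prefix: str) -> "SimTruth":
        return cls(
            sites=pd.read_csv(prefix + "_truth_sites.tsv", sep="\t"),
            junctions=pd.read_csv(prefix + "_truth_junctions.tsv", sep="\t"),
            per_read=pd.read_csv(prefix + "_truth_reads.tsv", sep="\t"),
        )


# ---------------------------------------------------------------------------
# reference + site planting
# ---------------------------------------------------------------------------

def generate_reference(length: int, gc: float, seed: int, name: str = "chrS") -> ReferenceSequence:
    """Random reference sequence with the requested GC fraction."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = spawn_rng(seed, "reference")
    return ReferenceSequence(name=name, seq=random_dna(rng, length, gc))


def plant_sites(
    ref: ReferenceSequence,
    spacer: str,
    n_offtargets: int,
    mismatch_counts: list[int],
    seed: int,
    edit_rates: list[float] | None = None,
    insertion_rates: list[float] | None = None,
    min_gap: int = 2_000,
    margin: int = 1_500,
) -> tuple[ReferenceSequence, list[PlantedSite]]:
    """Write the on-target protospacer plus ``n_offtargets`` mismatched
    variants (each followed by an NGG PAM) into the reference.

    Sites alternate strands, are spaced >= ``min_gap`` apart, and stay
    ``margin`` bases clear of the reference edges.  Returns the edited
    reference and the planted sites; the on-target site is first with
    ``mismatch_positions = ()``.
    """
    if len(spacer) != 20 or set(spacer) - set("ACGT"):
        raise ValueError("spacer must be a 20-nt ACGT string")
    if len(mismatch_counts) != n_offtargets:
        raise ValueError("mismatch_counts must have one entry per off-target")
    if any(not 0 <= m <= 8 for m in mismatch_counts):
        raise ValueError("mismatch counts must be in 0..8")
    n_sites = n_offtargets + 1
    usable = ref.length - 2 * margin
    if usable < n_sites * min_gap:
        raise ValueError(
            f"reference of {ref.length} bases cannot host {n_sites} sites "
            f"{min_gap} bases apart with {margin}-base margins"
        )
    rng = spawn_rng(seed, "plant")
    # default per-site rates: on-target edits most, off-targets taper
    if edit_rates is None:
        taper = [0.5, 0.4, 0.3, 0.2, 0.15, 0.1]
        edit_rates = [0.8] + [taper[i % len(taper)] for i in range(n_offtargets)]
    if insertion_rates is None:
        insertion_rates = [0.2] * n_sites
    # evenly spaced slots with jitter keeps sites non-overlapping by design
    slot = usable // n_sites
    positions = []
    for i in range(n_sites):
        lo = margin + i * slot
        hi = lo + slot - min_gap // 2 - 30
        positions.append(int(rng.integers(lo, max(lo + 1, hi))))
    seq = list(ref.seq)
    sites: list[PlantedSite] = []
    pams = ["AGG", "TGG", "CGG", "GGG"]
    for i, s in enumerate(positions):
        n_mm = 0 if i == 0 else mismatch_counts[i - 1]
        proto = list(spacer)
        mm_pos: list[int] = []
        if n_mm:
            mm_pos = sorted(rng.choice(np.arange(1, 21), size=n_mm, replace=False).tolist())
            for p in mm_pos:
                alt = [b for b in "ACGT" if b != proto[p - 1]]
                proto[p - 1] = alt[rng.integers(3)]
        proto_seq = "".join(proto)
        pam = pams[int(rng.integers(len(pams)))]
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            seq[s : s + 20] = proto_seq
            seq[s + 20 : s + 23] = pam
        else:
            seq[s : s + 20] = revcomp(proto_seq)
            seq[s - 3 : s] = revcomp(pam)
        sites.append(
            PlantedSite(
                interval=GenomicInterval(ref.name, s, s + 20, strand),
                strand=strand,
                pam=pam,
                mismatch_positions=tuple(mm_pos),
                insertion_rate=insertion_rates[i],
                edit_rate=edit_rates[i],
            )
        )
    return ReferenceSequence(ref.name, "".join(seq)), sites


# ---------------------------------------------------------------------------
# SAM plumbing
# ---------------------------------------------------------------------------

def _sam_header(ref: ReferenceSequence) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "unsorted"},
         "SQ": [{"SN": ref.name, "LN": ref.length}]}
    )


def _make_record(
    header: pysam.AlignmentHeader,
    qname: str,
    read_no: int,
    seq: str,
    seg: tuple[int, int, str, int, int],
    supplementary: bool,
    umi: str,
    primer_id: str | None,
    mate: tuple[int, str],
) -> pysam.AlignedSegment:
    start, end, strand, qs, qe = seg
    a = pysam.AlignedSegment(header)
    a.query_name = qname
    a.reference_id = 0
    a.reference_start = start
    a.mapping_quality = 60
    flag = 0x1 | 0x2 | (0x40 if read_no == 1 else 0x80)
    if strand == "-":
        flag |= 0x10
    if mate[1] == "-":
        flag |= 0x20
    if supplementary:
        flag |= 0x800
    a.flag = flag
    n = len(seq)
    if strand == "+":
        cig = [(4, qs)] if qs else []
        cig.append((0, qe - qs))
        if n - qe:
            cig.append((4, n - qe))
        a.query_sequence = seq
    else:
        cig = [(4, n - qe)] if n - qe else []
        cig.append((0, qe - qs))
        if qs:
            cig.append((4, qs))
        a.query_sequence = revcomp(seq)
    a.cigartuples = cig
    a.query_qualities = pysam.qualitystring_to_array("I" * n)
    a.next_reference_id = 0
    a.next_reference_start = mate[0]
    a.template_length = 0
    tags = [(UMI_TAG, umi)]
    if primer_id is not None:
        tags.append((PRIMER_TAG, primer_id))
    a.set_tags(tags)
    return a


class _Emitter:
    """Accumulates FASTQ lines, SAM records and truth rows for one library."""

    def __init__(self, ref: ReferenceSequence, params: LibraryParams, rng: np.random.Generator):
        self.ref = ref
        self.params = params
        self.rng = rng
        self.header = _sam_header(ref)
        self.fq1: list[str] = []
        self.fq2: list[str] = []
        self.sam: list[pysam.AlignedSegment] = []
        self.rows: list[dict] = []
        self.n = 0

    def new_umi(self) -> str:
        return random_dna(self.rng, self.params.umi_len)

    def frag_len(self) -> int:
        d = self.rng.normal(self.params.frag_len_mean, self.params.frag_len_sd)
        return max(self.params.frag_len_min, int(round(d)))

    def emit(
        self,
        molecule_id: int,
        seq1: str,
        segs1: list[tuple[int, int, str, int, int]],
        seq2: str,
        segs2: list[tuple[int, int, str, int, int]],
        row: dict,
        copies: int = 1,
    ) -> None:
        """Emit ``copies`` read pairs (PCR duplicates share everything but the
        read id)."""
        p = self.params
        for _ in range(copies):
            rid = f"sim{self.n:07d}"
            self.n += 1
            e1 = apply_errors(self.rng, seq1, p.seq_error_rate)
            e2 = apply_errors(self.rng, seq2, p.seq_error_rate)
            self.fq1.append(f"@{rid}\n{e1}\n+\n{'I' * len(e1)}\n")
            self.fq2.append(f"@{rid}\n{e2}\n+\n{'I' * len(e2)}\n")
            mate1 = (segs2[0][0], segs2[0][2]) if segs2 else (segs1[0][0], segs1[0][2])
            mate2 = (segs1[0][0], segs1[0][2]) if segs1 else (0, "+")
            for k, seg in enumerate(segs1):
                self.sam.append(_make_record(
                    self.header, rid, 1, e1, seg, k > 0, row["umi"], row["primer_id"], mate1))
            for k, seg in enumerate(segs2):
                self.sam.append(_make_record(
                    self.header, rid, 2, e2, seg, k > 0, row["umi"], row["primer_id"], mate2))
            r1 = segs1[0]
            self.rows.append({
                "read_id": rid,
                "molecule_id": molecule_id,
                "chrom": self.ref.name,
                "r1_strand": r1[2],
                "r1_pos5": r1[0] if r1[2] == "+" else r1[1],
                "r1_start": r1[0],
                "r1_end": r1[1],
                "r2_start": segs2[0][0] if segs2 else -1,
                "r2_end": segs2[0][1] if segs2 else -1,
                **row,
            })

    def write(self, prefix: str) -> tuple[str, str, str]:
        fq1, fq2, sam = prefix + "_R1.fastq", prefix + "_R2.fastq", prefix + "_truth.sam"
        with open(fq1, "w") as fh:
            fh.writelines(self.fq1)
        with open(fq2, "w") as fh:
            fh.writelines(self.fq2)
        with pysam.AlignmentFile(sam, "w", header=self.header) as fh:
            for rec in self.sam:
                fh.write(rec)
        return fq1, fq2, sam


# ---------------------------------------------------------------------------
# molecule geometry (protospacer frame)
# ---------------------------------------------------------------------------
# All tag-molecule reads are constructed in the protospacer frame (the
# reference for plus-strand sites, its reverse complement for minus-strand
# sites) and segment coordinates are mapped back afterwards.

def _map_frame_segs(segs, site_strand: str, ref_len: int):
    if site_strand == "+":
        return segs
    flip = {"+": "-", "-": "+"}
    return [(ref_len - e, ref_len - s, flip[st], qs, qe) for (s, e, st, qs, qe) in segs]


def _tag_pair_frame(
    frame: str,
    cf: int,
    tag: TagDesign,
    primer_id: str,
    tag_len: int,
    d: int,
    read_len: int,
    umi: str,
):
    """Reads for a tagged molecule in the protospacer frame.

    Returns (seq1, segs1, seq2, segs2) with segments as frame coordinates
    (start, end, strand, qstart, qend).
    """
    p = tag.primer(primer_id)
    t = tag.tag_seq
    sp = UMI_SPACER
    if p.side == "forward":
        ps = len(t) - p.boundary_offset - len(p.seq)
        tag_part = t[ps:tag_len]
        d = min(d, len(frame) - cf)
        amp = tag_part + frame[cf : cf + d]
        seq1 = amp[: read_len]
        q0 = len(tag_part)
        g1 = max(0, min(read_len - q0, d))
        segs1 = [(cf, cf + g1, "+", q0, q0 + g1)]
        m = min(d, read_len - len(umi) - len(sp))
        seq2 = umi + sp + revcomp(amp)[: read_len - len(umi) - len(sp)]
        segs2 = [(cf + d - m, cf + d, "-", len(umi) + len(sp), len(umi) + len(sp) + m)]
    else:
        pe = p.boundary_offset + len(p.seq)
        d = min(d, cf)
        amp = revcomp(t[:pe]) + revcomp(frame[cf - d : cf])
        seq1 = amp[: read_len]
        q0 = pe
        g1 = max(0, min(read_len - q0, d))
        segs1 = [(cf - g1, cf, "-", q0, q0 + g1)]
        m = min(d, read_len - len(umi) - len(sp))
        seq2 = umi + sp + (frame[cf - d : cf] + t[:pe])[: read_len - len(umi) - len(sp)]
        segs2 = [(cf - d, cf - d + m, "+", len(umi) + len(sp), len(umi) + len(sp) + m)]
    return seq1, segs1, seq2, segs2


def _model_v_pair(
    ref_seq: str,
    r_cut: int,
    d_cut: int,
    tag: TagDesign,
    primer_id: str,
    tag_len: int,
    d: int,
    read_len: int,
    umi: str,
):
    """Reads from a model-(v) junction molecule (donor upstream end with its
    tag joined, inverted, to the receiver upstream end).

    The tag sits reverse-oriented at the receiver junction, so the forward
    primer reads *upstream* of the receiver cut on the minus strand (the
    unexpected-signal geometry), while the reverse primer reads the donor
    upstream flank.
    """
    p = tag.primer(primer_id)
    t = tag.tag_seq
    sp = UMI_SPACER
    u = len(umi) + len(sp)
    if p.side == "forward":
        ps = len(t) - p.boundary_offset - len(p.seq)
        tag_part = t[ps:tag_len]
        d = min(d, r_cut)
        amp = tag_part + revcomp(ref_seq[r_cut - d : r_cut])
        seq1 = amp[: read_len]
        q0 = len(tag_part)
        g1 = max(0, min(read_len - q0, d))
        segs1 = [(r_cut - g1, r_cut, "-", q0, q0 + g1)]
        m = min(d, read_len - u)
        seq2 = umi + sp + (ref_seq[r_cut - d : r_cut] + revcomp(tag_part))[: read_len - u]
        segs2 = [(r_cut - d, r_cut - d + m, "+", u, u + m)]
    else:
        pe = p.boundary_offset + len(p.seq)
        d = min(d, d_cut)
        amp = revcomp(t[:pe]) + revcomp(ref_seq[d_cut - d : d_cut])
        seq1 = amp[: read_len]
        q0 = pe
        g1 = max(0, min(read_len - q0, d))
        segs1 = [(d_cut - g1, d_cut, "-", q0, q0 + g1)]
        m = min(d, read_len - u)
        seq2 = umi + sp + (ref_seq[d_cut - d : d_cut] + t[:pe])[: read_len - u]
        segs2 = [(d_cut - d, d_cut - d + m, "+", u, u + m)]
    return seq1, segs1, seq2, segs2


def _misprime_pair(ref_seq, pos, strand, primer_seq, d, read_len, umi):
    sp = UMI_SPACER
    u = len(umi) + len(sp)
    if strand == "+":
        d = min(d, len(ref_seq) - pos)
        g = ref_seq[pos : pos + d]
        seq1 = (primer_seq + g)[: read_len]
        q0 = len(primer_seq)
        g1 = max(0, min(read_len - q0, d))
        segs1 = [(pos, pos + g1, "+", q0, q0 + g1)]
        m = min(d, read_len - u)
        seq2 = umi + sp + (revcomp(g) + revcomp(primer_seq))[: read_len - u]
        segs2 = [(pos + d - m, pos + d, "-", u, u + m)]
    else:
        d = min(d, pos)
        g = revcomp(ref_seq[pos - d : pos])
        seq1 = (primer_seq + g)[: read_len]
        q0 = len(primer_seq)
        g1 = max(0, min(read_len - q0, d))
        segs1 = [(pos - g1, pos, "-", q0, q0 + g1)]
        m = min(d, read_len - u)
        seq2 = umi + sp + (ref_seq[pos - d : pos] + revcomp(primer_seq))[: read_len - u]
        segs2 = [(pos - d, pos - d + m, "+", u, u + m)]
    return seq1, segs1, seq2, segs2


def _background_pair(ref_seq, a, d, read_len, umi):
    sp = UMI_SPACER
    u = len(umi) + len(sp)
    d = min(d, len(ref_seq) - a)
    g1 = min(read_len, d)
    seq1 = ref_seq[a : a + g1]
    segs1 = [(a, a + g1, "+", 0, g1)]
    m = min(d, read_len - u)
    seq2 = umi + sp + revcomp(ref_seq[a : a + d])[: read_len - u]
    segs2 = [(a + d - m, a + d, "-", u, u + m)]
    return seq1, segs1, seq2, segs2


def find_misprime_loci(ref: ReferenceSequence, tag: TagDesign, primer_ids) -> list[tuple[str, int, str]]:
    """Genomic loci whose sequence matches a primer's 3'-terminal 8 bases
    exactly (either strand) — the places random priming can initiate.

    Returns (primer_id, extension_start, strand): on '+' the misprimed
    product continues with ``ref[pos:]``, on '-' with ``revcomp(ref[:pos])``.
    """
    loci = []
    for pid in primer_ids:
        p = tag.primer(pid)
        tail = p.seq[-8:]
        for probe, strand in ((tail, "+"), (revcomp(tail), "-")):
            i = ref.seq.find(probe)
            while i != -1:
                loci.append((pid, i + 8 if strand == "+" else i, strand))
                i = ref.seq.find(probe, i + 1)
    loci.sort(key=lambda x: (x[1], x[0], x[2]))
    return loci


def _read_ext_ok(tag: TagDesign, primer_id: str, seq1: str,
                 min_ext: int = DEFAULT_MIN_EXT) -> bool:
    """Whether the constructed (pre-error) read passes extension
    verification.

    Checked on the emitted read rather than derived from the retained tag
    length: a 3'-truncated tag usually breaks the window, but the genomic
    base that replaces it can coincidentally continue the tag, and the truth
    ledger must record what a verifier will actually see.
    """
    p = tag.primer(primer_id)
    expected = tag.expected_extension(primer_id, min_ext)
    return seq1[len(p.seq) : len(p.seq) + len(expected)] == expected


def _anneals(tag: TagDesign, primer_id: str, tag_len: int) -> bool:
    p = tag.primer(primer_id)
    if p.side == "forward":
        return tag_len >= len(tag.tag_seq) - p.boundary_offset
    return tag_len >= p.boundary_offset + len(p.seq)


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

def _sites_frame(ref: ReferenceSequence, site: PlantedSite) -> tuple[str, int]:
    if site.strand == "+":
        return ref.seq, site.cut
    return revcomp(ref.seq), ref.length - site.cut


def simulate_library(
    ref: ReferenceSequence,
    sites: list[PlantedSite],
    junctions: list[JunctionSpec],
    tag: TagDesign,
    params: LibraryParams,
    out_prefix: str,
    enrichment_primers: tuple[str, str] = ("F1", "R2"),
) -> SimTruth:
    """Simulate the tag-enriched (edited-sample) library.

    Emits exactly ``n_fragments`` read pairs (rounded down to a multiple of
    ``pcr_dup_factor``): tag-derived pairs allocated across sites in
    proportion to ``edit_rate * insertion_rate``, random-priming pairs at
    ``random_priming_rate``, and unenriched background pairs at
    ``background_rate``.  Tag-carrying junction molecules (models i and v)
    are drawn from their receiver's allocation at the specified rates;
    tag-free joins (ii/iii/iv) leave nothing for the enrichment primers to
    anneal to and are interrogated by :func:`simulate_junction_library`.
    """
    for j in junctions:
        if j.receiver not in sites:
            raise ValueError("junction references a receiver not in the site list")
    rng = spawn_rng(params.seed, "library")
    em = _Emitter(ref, params, rng)
    fwd_id, rev_id = enrichment_primers
    if tag.primer(fwd_id).side != "forward" or tag.primer(rev_id).side != "reverse":
        raise ValueError("enrichment_primers must be (forward, reverse)")
    loci = find_misprime_loci(ref, tag, enrichment_primers)
    weights = np.array([s.edit_rate * s.insertion_rate for s in sites], dtype=float)
    total_w = weights.sum()
    rp = params.random_priming_rate if loci else 0.0
    bg = params.background_rate
    site_mass = (1.0 - rp - bg) if total_w > 0 else 0.0
    probs = np.concatenate([weights / total_w * site_mass if total_w > 0 else weights * 0,
                            [rp, bg + (0.0 if total_w > 0 else 1.0 - rp - bg)]])
    probs = probs / probs.sum()
    trunc = np.asarray(params.tag_truncation_dist)
    jx_by_receiver: dict[int, list[tuple[int, JunctionSpec]]] = {}
    for jidx, j in enumerate(junctions):
        if j.tag_present:  # only tag-carrying joins are amplifiable here
            jx_by_receiver.setdefault(sites.index(j.receiver), []).append((jidx, j))
    frames = [_sites_frame(ref, s) for s in sites]
    k = params.pcr_dup_factor
    n_mol = params.n_fragments // k
    mol = 0
    guard = 0
    while mol < n_mol:
        guard += 1
        if guard > 50 * n_mol + 1000:
            raise RuntimeError("library composition cannot be realized (all draws discarded)")
        choice = int(rng.choice(len(sites) + 2, p=probs))
        umi = em.new_umi()
        d = em.frag_len()
        if choice < len(sites):
            site = sites[choice]
            tag_len = int(rng.choice(22, p=trunc))
            side_fwd = bool(rng.random() < 0.5)
            primer_id = fwd_id if side_fwd else rev_id
            if not _anneals(tag, primer_id, tag_len):
                continue  # no product: this molecule never enters the library
            jidx = -1
            model = ""
            jlist = jx_by_receiver.get(choice, [])
            u = rng.random()
            acc = 0.0
            picked = None
            for ji, js in jlist:
                acc += js.rate
                if u < acc:
                    picked = (ji, js)
                    break
            frame, cf = frames[choice]
            if picked is not None and picked[1].model == "v":
                jidx, js = picked
                model = "v"
                seq1, s1, seq2, s2 = _model_v_pair(
                    ref.seq, js.receiver.cut, js.donor.cut, tag, primer_id,
                    tag_len, d, params.read_len, umi)
                segs1, segs2 = s1, s2  # already reference coordinates
            else:
                if picked is not None:  # model i: geometry of the intended edit
                    jidx, model = picked[0], "i"
                seq1, s1, seq2, s2 = _tag_pair_frame(
                    frame, cf, tag, primer_id, tag_len, d, params.read_len, umi)
                segs1 = _map_frame_segs(s1, site.strand, ref.length)
                segs2 = _map_frame_segs(s2, site.strand, ref.length)
            row = {
                "origin": f"junction:{jidx}" if jidx >= 0 else f"site:{choice}",
                "site_idx": choice, "junction_idx": jidx,
                "side": "forward" if side_fwd else "reverse",
                "primer_id": primer_id, "umi": umi, "tag_len": tag_len,
                "ext_intact": _read_ext_ok(tag, primer_id, seq1),
                "cut": site.cut,
            }
            em.emit(mol, seq1, segs1, seq2, segs2, row, copies=k)
        elif choice == len(sites):
            pid, pos, strand = loci[int(rng.integers(len(loci)))]
            p = tag.primer(pid)
            seq1, segs1, seq2, segs2 = _misprime_pair(
                ref.seq, pos, strand, p.seq, d, params.read_len, umi)
            row = {
                "origin": "random_priming", "site_idx": -1, "junction_idx": -1,
                "side": p.side, "primer_id": pid, "umi": umi,
                "tag_len": 0, "ext_intact": _read_ext_ok(tag, pid, seq1), "cut": -1,
            }
            em.emit(mol, seq1, segs1, seq2, segs2, row, copies=k)
        else:
            a = int(rng.integers(0, max(1, ref.length - d)))
            seq1, segs1, seq2, segs2 = _background_pair(ref.seq, a, d, params.read_len, umi)
            row = {
                "origin": "background", "site_idx": -1, "junction_idx": -1,
                "side": "none", "primer_id": None, "umi": umi,
                "tag_len": 0, "ext_intact": False, "cut": -1,
            }
            em.emit(mol, seq1, segs1, seq2, segs2, row, copies=k)
        mol += 1
    em.write(out_prefix)
    truth = _build_truth(ref, sites, junctions, em)
    truth.check_conservation(em.n)
    truth.write(out_prefix)
    return truth


def simulate_wt_control(
    ref: ReferenceSequence,
    tag: TagDesign,
    params: LibraryParams,
    out_prefix: str,
    enrichment_primers: tuple[str, str] = ("F1", "R2"),
) -> SimTruth:
    """Wild-type control library: no tag insertions anywhere; random-priming
    pairs at ``random_priming_rate`` plus unenriched background."""
    rng = spawn_rng(params.seed, "wt-control")
    em = _Emitter(ref, params, rng)
    loci = find_misprime_loci(ref, tag, enrichment_primers)
    rp = params.random_priming_rate if loci else 0.0
    for mol in range(params.n_fragments):
        umi = em.new_umi()
        d = em.frag_len()
        if rng.random() < rp:
            pid, pos, strand = loci[int(rng.integers(len(loci)))]
            p = tag.primer(pid)
            seq1, segs1, seq2, segs2 = _misprime_pair(
                ref.seq, pos, strand, p.seq, d, params.read_len, umi)
            row = {
                "origin": "random_priming", "site_idx": -1, "junction_idx": -1,
                "side": p.side, "primer_id": pid, "umi": umi,
                "tag_len": 0, "ext_intact": _read_ext_ok(tag, pid, seq1), "cut": -1,
            }
        else:
            a = int(rng.integers(0, max(1, ref.length - d)))
            seq1, segs1, seq2, segs2 = _background_pair(ref.seq, a, d, params.read_len, umi)
            row = {
                "origin": "background", "site_idx": -1, "junction_idx": -1,
                "side": "none", "primer_id": None, "umi": umi,
                "tag_len": 0, "ext_intact": False, "cut": -1,
            }
        em.emit(mol, seq1, segs1, seq2, segs2, row)
    em.write(out_prefix)
    truth = _build_truth(ref, [], [], em)
    truth.check_conservation(em.n)
    truth.write(out_prefix)
    return truth


def simulate_junction_library(
    ref: ReferenceSequence,
    receiver: PlantedSite,
    junctions: list[JunctionSpec],
    tag: TagDesign,
    params: LibraryParams,
    out_prefix: str,
    nested_flank: int = 60,
    resection: int = 35,
) -> SimTruth:
    """Nested-PCR / unidirectional targeted sequencing style library anchored
    in the receiver's upstream flank.

    Each read pair starts ``nested_flank`` bases upstream of the receiver cut
    and reads through whatever joined: a clean or tagged religation (normal
    joins), a resected tag-free rejoin (model ii), or a donor end
    (models iii/iv/v).  Junction reads appear as split alignments in the
    truth SAM (primary = receiver flank, supplementary = the joined segment).
    """
    if receiver.strand != "+":
        raise ValueError("junction library requires a plus-strand receiver")
    for j in junctions:
        if j.receiver != receiver:
            raise ValueError("all junction specs must share the receiver")
    if sum(j.rate for j in junctions) > 1.0:
        raise ValueError("junction rates sum to more than 1")
    rng = spawn_rng(params.seed, "junction-library")
    em = _Emitter(ref, params, rng)
    trunc = np.asarray(params.tag_truncation_dist)
    r = receiver.cut
    A = nested_flank
    rl = params.read_len
    sp = UMI_SPACER

    def tn5_read2(amp: str, locus_start: int, strand: str, umi: str):
        """Tn5-side read fully inside the distal segment (frag length is
        floored at read length so it never re-crosses the junction)."""
        u = len(umi) + len(sp)
        m = rl - u
        seq2 = umi + sp + revcomp(amp)[:m]
        if strand == "+":
            segs2 = [(locus_start + len(amp) - m, locus_start + len(amp), "-", u, u + m)]
        else:
            segs2 = [(locus_start, locus_start + m, "+", u, u + m)]
        return seq2, segs2

    for mol in range(params.n_fragments):
        umi = em.new_umi()
        d2 = max(em.frag_len(), rl + 25)  # distal extent beyond the junction
        u = rng.random()
        acc = 0.0
        picked: tuple[int, JunctionSpec] | None = None
        for jidx, j in enumerate(junctions):
            acc += j.rate
            if u < acc:
                picked = (jidx, j)
                break
        flank = ref.seq[r - A : r]
        if picked is None:
            # normal join at the receiver: tagged religation at the
            # insertion rate, otherwise clean (sequence-identical to WT)
            if rng.random() < receiver.insertion_rate:
                tag_len = int(rng.choice(22, p=trunc))
                gap = tag.tag_seq[:tag_len]
                origin = "normal_tag" if tag_len else "normal"
            else:
                gap, tag_len, origin = "", 0, "normal"
            down = ref.seq[r : r + d2]
            seq1 = (flank + gap + down)[:rl]
            if gap:
                q1 = A + len(gap)
                segs1 = [(r - A, r, "+", 0, A), (r, r + (rl - q1), "+", q1, rl)]
            else:
                segs1 = [(r - A, r - A + rl, "+", 0, rl)]
            seq2, segs2 = tn5_read2(down, r, "+", umi)
            row = {"origin": origin, "site_idx": -1, "junction_idx": -1,
                   "side": "none", "primer_id": None, "umi": umi,
                   "tag_len": tag_len, "ext_intact": False, "cut": r}
            em.emit(mol, seq1, segs1, seq2, segs2, row)
            continue
        jidx, j = picked
        dcut = j.donor.cut
        if j.model == "i":
            tag_len = max(6, int(rng.choice(22, p=trunc)))
            gap = tag.tag_seq[:tag_len]
            down = ref.seq[r : r + d2]
            seq1 = (flank + gap + down)[:rl]
            q1 = A + tag_len
            segs1 = [(r - A, r, "+", 0, A), (r, r + (rl - q1), "+", q1, rl)]
            seq2, segs2 = tn5_read2(down, r, "+", umi)
        elif j.model == "ii":
            up_end = r - resection
            flank2 = ref.seq[up_end - A : up_end]
            down = ref.seq[r + resection : r + resection + d2]
            seq1 = (flank2 + down)[:rl]
            segs1 = [(up_end - A, up_end, "+", 0, A),
                     (r + resection, r + resection + (rl - A), "+", A, rl)]
            seq2, segs2 = tn5_read2(down, r + resection, "+", umi)
            tag_len, gap = 0, ""
        elif j.model == "iii":
            donor_seg = revcomp(ref.seq[dcut - d2 : dcut])
            seq1 = (flank + donor_seg)[:rl]
            segs1 = [(r - A, r, "+", 0, A), (dcut - (rl - A), dcut, "-", A, rl)]
            seq2, segs2 = tn5_read2(donor_seg, dcut - d2, "-", umi)
            tag_len, gap = 0, ""
        elif j.model == "iv":
            donor_seg = ref.seq[dcut : dcut + d2]
            seq1 = (flank + donor_seg)[:rl]
            segs1 = [(r - A, r, "+", 0, A), (dcut, dcut + (rl - A), "+", A, rl)]
            seq2, segs2 = tn5_read2(donor_seg, dcut, "+", umi)
            tag_len, gap = 0, ""
        else:  # model v: donor upstream end with reverse-oriented tag
            tag_len = max(6, int(rng.choice(22, p=trunc)))
            gap = revcomp(tag.tag_seq[:tag_len])
            donor_seg = revcomp(ref.seq[dcut - d2 : dcut])
            seq1 = (flank + gap + donor_seg)[:rl]
            q1 = A + tag_len
            segs1 = [(r - A, r, "+", 0, A), (dcut - (rl - q1), dcut, "-", q1, rl)]
            seq2, segs2 = tn5_read2(donor_seg, dcut - d2, "-", umi)
        row = {"origin": f"junction:{jidx}", "site_idx": -1, "junction_idx": jidx,
               "side": "none", "primer_id": None, "umi": umi,
               "tag_len": tag_len, "ext_intact": False, "cut": r}
        em.emit(mol, seq1, segs1, seq2, segs2, row)
    em.write(out_prefix)
    truth = _build_truth(ref, [], junctions, em)
    truth.check_conservation(em.n)
    truth.write(out_prefix)
    return truth


def _build_truth(
    ref: ReferenceSequence,
    sites: list[PlantedSite],
    junctions: list[JunctionSpec],
    em: _Emitter,
) -> SimTruth:
    per_read = pd.DataFrame(em.rows, columns=PER_READ_COLUMNS)
    site_rows = []
    for i, s in enumerate(sites):
        n_reads = int((per_read["site_idx"] == i).sum())
        site_rows.append({
            "site_idx": i, "chrom": s.interval.chrom,
            "proto_start": s.interval.start, "proto_end": s.interval.end,
            "strand": s.strand, "cut": s.cut, "pam": s.pam,
            "mismatch_positions": ",".join(map(str, s.mismatch_positions)),
            "n_mismatch": len(s.mismatch_positions),
            "insertion_rate": s.insertion_rate, "edit_rate": s.edit_rate,
            "n_read_pairs": n_reads,
        })
    jx_rows = []
    for jidx, j in enumerate(junctions):
        n_reads = int((per_read["junction_idx"] == jidx).sum())
        jx_rows.append({
            "junction_idx": jidx, "model": j.model,
            "receiver_cut": j.receiver.cut, "donor_cut": j.donor.cut,
            "tag_present": j.tag_present, "rate": j.rate,
            "n_read_pairs": n_reads,
        })
    return SimTruth(
        sites=pd.DataFrame(site_rows, columns=[
            "site_idx", "chrom", "proto_start", "proto_end", "strand", "cut",
            "pam", "mismatch_positions", "n_mismatch", "insertion_rate",
            "edit_rate", "n_read_pairs"]),
        junctions=pd.DataFrame(jx_rows, columns=[
            "junction_idx", "model", "receiver_cut", "donor_cut",
            "tag_present", "rate", "n_read_pairs"]),
        per_read=per_read,
    )
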