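"""Read preparation: UMI extraction, enrichment-primer identification, and
primer-extension verification.

The enrichment library is built from two amplicon families: forward primers
anneal inside the inserted tag and read through its 3' boundary into the
downstream genome; reverse primers anneal to the opposite strand and read
through the tag 5' boundary into the upstream genome.  Every primer's 3' end
sits at least two bases away from its tag/genome boundary, so the bases a
genuine tag template contributes immediately after the primer are known in
advance.  Comparing them is the random-priming filter: a primer that annealed
at a partially homologous genomic locus is extended with genomic sequence,
which matches the expected tag continuation only by coincidence
(probability 4^-offset per read).
"""

from __future__ import annotations

from dataclasses import dataclass

import pysam

from .util import revcomp

#: fixed spacer between the UMI and the genomic part of the Tn5-side read
UMI_SPACER = "CAGT"

#: default 21-nt insertion tag (unique vs the synthetic references used here)
DEFAULT_TAG = "GTCATCGCAGATGCTTCAACG"


@dataclass(frozen=True)
class Primer:
    """One enrichment primer.

    ``boundary_offset`` is the number of tag bases between the primer's 3'
    end and the tag/genome insertion boundary (>= 2 by design).
    """

    primer_id: str
    seq: str
    side: str  # "forward" | "reverse"
    boundary_offset: int

    def __post_init__(self) -> None:
        if self.side not in ("forward", "reverse"):
            raise ValueError(f"primer side must be forward/reverse, got {self.side!r}")
        if self.boundary_offset < 2:
            raise ValueError(
                f"primer {self.primer_id}: boundary_offset must be >= 2 "
                f"(got {self.boundary_offset}); the extension filter needs it"
            )


@dataclass(frozen=True)
class TagDesign:
    """The inserted tag, the PBS length it was reverse-transcribed from, and
    the enrichment primers defined on it."""

    tag_seq: str = DEFAULT_TAG
    pbs_len: int = 13
    primers: tuple[Primer, ...] = ()

    def __post_init__(self) -> None:
        if len(self.tag_seq) != 21:
            raise ValueError(f"tag_seq must be 21 nt, got {len(self.tag_seq)}")
        if set(self.tag_seq) - set("ACGT"):
            raise ValueError("tag_seq must be A/C/G/T only")
        for p in self.primers:
            self._check_primer(p)

    def _check_primer(self, p: Primer) -> None:
        t = self.tag_seq
        if p.side == "forward":
            end = len(t) - p.boundary_offset
            if t[end - len(p.seq) : end] != p.seq:
                raise ValueError(
                    f"forward primer {p.primer_id} does not match the tag at "
                    f"its declared boundary offset"
                )
        else:
            start = p.boundary_offset
            if revcomp(t[start : start + len(p.seq)]) != p.seq:
                raise ValueError(
                    f"reverse primer {p.primer_id} does not match the tag at "
                    f"its declared boundary offset"
                )

    def primer(self, primer_id: str) -> Primer:
        for p in self.primers:
            if p.primer_id == primer_id:
                return p
        raise KeyError(primer_id)

    def expected_extension(self, primer_id: str, min_ext: int) -> str:
        """Tag bases expected immediately 3' of the primer in a genuine read.

        The comparison window is ``min(min_ext, boundary_offset)`` bases, so
        raising ``min_ext`` is monotonically stricter and caps at the design
        boundary.
        """
        p = self.primer(primer_id)
        w = min(min_ext, p.boundary_offset)
        t = self.tag_seq
        if p.side == "forward":
            e = len(t) - p.boundary_offset
            return t[e : e + w]
        a = p.boundary_offset
        return revcomp(t[a - w : a])

    def full_tag_continuation(self, primer_id: str) -> str:
        """All remaining tag bases between the primer 3' end and the genome."""
        p = self.primer(primer_id)
        t = self.tag_seq
        if p.side == "forward":
            return t[len(t) - p.boundary_offset :]
        return revcomp(t[: p.boundary_offset])


def default_tag_design(tag_seq: str = DEFAULT_TAG) -> TagDesign:
    """The default three-forward / two-reverse primer panel.

    Forward primers share a 5' anchor near the genome-attached tag end and
    stagger their 3' ends (boundary offsets 6/4/2); reverse primers read
    toward the tag 5' boundary (offsets 2 and 5).  Forward offsets descend so
    shorter reverse-transcription products remain amplifiable by at least one
    primer; the default enrichment pair is F1 + R2.
    """
    t = tag_seq
    primers = (
        Primer("F1", t[0:15], "forward", 6),
        Primer("F2", t[0:17], "forward", 4),
        Primer("F3", t[2:19], "forward", 2),
        Primer("R1", revcomp(t[2:17]), "reverse", 2),
        Primer("R2", revcomp(t[5:20]), "reverse", 5),
    )
    return TagDesign(tag_seq=t, pbs_len=13, primers=primers)


@dataclass
class PrimedRead:
    """Per-pair annotation produced by read preparation."""

    read_id: str
    umi: str
    primer_id: str | None
    side: str  # forward | reverse | none
    extension_ok: bool
    trimmed_seq: str
    mate_seq: str

    def __post_init__(self) -> None:
        if self.primer_id is None and self.extension_ok:
            raise ValueError("extension_ok requires a matched primer")


def extract_umi(read_pair: tuple[str, str], umi_len: int) -> tuple[str, tuple[str, str]] | None:
    """Pull the UMI off the Tn5-side read (read 2).

    The UMI is the first ``umi_len`` bases of read 2, followed by a fixed
    4-nt spacer; both are clipped.  Returns ``None`` (caller logs/discards)
    when read 2 is too short to contain them.
    """
    r1, r2 = read_pair
    need = umi_len + len(UMI_SPACER)
    if len(r2) < need + 1:
        return None
    umi = r2[:umi_len]
    return umi, (r1, r2[need:])


def match_primer(
    read_seq: str,
    tag: TagDesign,
    max_mm: int = 1,
    primer_ids: tuple[str, ...] | None = None,
) -> tuple[str, str] | None:
    """Identify which enrichment primer the read starts with.

    Returns ``(primer_id, side)`` for the best match with <= ``max_mm``
    mismatches over the primer length, or ``None``.  Ties are broken by
    fewest mismatches, then longest primer, then declared primer order.

    ``primer_ids`` restricts matching to the primers actually used in the
    enrichment reaction (each primer runs in its own reaction, and nested
    panel primers share 5' anchors, so an unrestricted match can only report
    read-compatibility, not reaction identity).
    """
    best: tuple[int, int, int] | None = None  # (mm, -len, order)
    best_primer: Primer | None = None
    for order, p in enumerate(tag.primers):
        if primer_ids is not None and p.primer_id not in primer_ids:
            continue
        prefix = read_seq[: len(p.seq)]
        if len(prefix) < len(p.seq):
            continue
        mm = sum(a != b for a, b in zip(prefix, p.seq))
        if mm > max_mm:
            continue
        key = (mm, -len(p.seq), order)
        if best is None or key < best:
            best = key
            best_primer = p
    if best_primer is None:
        return None
    return best_primer.primer_id, best_primer.side


def verify_extension(
    read_seq: str, primer_id: str, tag: TagDesign, min_ext: int = 8
) -> bool:
    """True iff the bases immediately 3' of the primer exactly equal the
    expected tag continuation over a ``min(min_ext, boundary_offset)`` window.

    The comparison is exact-match: the window is only 2-6 bases, so allowing
    a mismatch would defeat the filter.  A read too short to contain the
    window fails.
    """
    p = tag.primer(primer_id)
    expected = tag.expected_extension(primer_id, min_ext)
    got = read_seq[len(p.seq) : len(p.seq) + len(expected)]
    return len(got) == len(expected) and got == expected


def trim_to_genome(read_seq: str, primer_id: str, tag: TagDesign) -> str:
    """Strip the primer plus any following tag bases, returning the genomic
    portion of the read.

    Tag stripping is greedy along the full expected continuation, so reads
    from truncated insertion products (tag ending early) are trimmed at the
    point where the read stops matching the tag.
    """
    p = tag.primer(primer_id)
    rest = read_seq[len(p.seq) :]
    cont = tag.full_tag_continuation(primer_id)
    k = 0
    while k < len(cont) and k < len(rest) and rest[k] == cont[k]:
        k += 1
    return rest[k:]


def annotate_pair(
    read_id: str,
    seq1: str,
    seq2: str,
    tag: TagDesign,
    umi_len: int = 10,
    max_mm: int = 1,
    min_ext: int = 8,
    primer_ids: tuple[str, ...] | None = None,
) -> PrimedRead | str:
    """Annotate one read pair; returns a :class:`PrimedRead` or a rejection
    reason string."""
    got = extract_umi((seq1, seq2), umi_len)
    if got is None:
        return "tn5_read_too_short"
    umi, (r1, r2) = got
    hit = match_primer(r1, tag, max_mm=max_mm, primer_ids=primer_ids)
    if hit is None:
        return "no_primer_match"
    primer_id, side = hit
    ok = verify_extension(r1, primer_id, tag, min_ext=min_ext)
    trimmed = trim_to_genome(r1, primer_id, tag) if ok else ""
    if ok and not trimmed:
        return "no_genomic_sequence_after_tag"
    return PrimedRead(
        read_id=read_id,
        umi=umi,
        primer_id=primer_id,
        side=side,
        extension_ok=ok,
        trimmed_seq=trimmed,
        mate_seq=r2,
    )


def process_fastq(
    fq1: str,
    fq2: str,
    tag: TagDesign,
    out_tsv: str,
    reject_tsv: str,
    umi_len: int = 10,
    max_mm: int = 1,
    min_ext: int = 8,
    primer_ids: tuple[str, ...] | None = None,
    out_fq1: str | None = None,
    out_fq2: str | None = None,
) -> dict:
    """Run read preparation over a paired FASTQ library.

    Writes one annotation row per retained pair (read_id, umi, primer_id,
    side, extension_ok) to ``out_tsv`` and one row per rejected pair to
    ``reject_tsv``.  Optionally writes trimmed FASTQ (genomic portion of read
    1, UMI-clipped read 2) for downstream alignment.  Returns summary counts.
    """
    counts = {"pairs": 0, "annotated": 0, "extension_ok": 0, "rejected": 0}
    f1 = open(out_fq1, "w") if out_fq1 else None
    f2 = open(out_fq2, "w") if out_fq2 else None
    with pysam.FastxFile(fq1) as h1, pysam.FastxFile(fq2) as h2, open(
        out_tsv, "w"
    ) as out, open(reject_tsv, "w") as rej:
        out.write("read_id\tumi\tprimer_id\tside\textension_ok\n")
        rej.write("read_id\treason\n")
        for e1, e2 in zip(h1, h2):
            counts["pairs"] += 1
            res = annotate_pair(
                e1.name, e1.sequence, e2.sequence, tag,
                umi_len=umi_len, max_mm=max_mm, min_ext=min_ext,
                primer_ids=primer_ids,
            )
            if isinstance(res, str):
                counts["rejected"] += 1
                rej.write(f"{e1.name}\t{res}\n")
                continue
            counts["annotated"] += 1
            counts["extension_ok"] += int(res.extension_ok)
            out.write(
                f"{res.read_id}\t{res.umi}\t{res.primer_id}\t{res.side}\t"
                f"{int(res.extension_ok)}\n"
            )
            if f1 is not None and res.extension_ok:
                f1.write(f"@{res.read_id}\n{res.trimmed_seq}\n+\n{'I' * len(res.trimmed_seq)}\n")
                f2.write(f"@{res.read_id}\n{res.mate_seq}\n+\n{'I' * len(res.mate_seq)}\n")
    if f1 is not None:
        f1.close()
        f2.close()
    return counts
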