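"""Translocation detection and classification.

A cut produces three double-strand-break ends: the receiver upstream end with
the inserted tag, the receiver upstream end without it, and the downstream
end.  When breaks at two loci coexist, ends can join across loci.  Five join
geometries are distinguished: (i) intra-site religation with the tag (the
intended edit), (ii) intra-site religation without the tag, (iii) a donor
upstream end joined without its tag, (iv) a donor downstream end joined, and
(v) a donor upstream end joined with its tag, which then sits reverse-
oriented at the receiver and produces forward-primer signal upstream of the
receiver cut — the tell-tale "unexpected upstream signal" in the enrichment
library.

Junctions are read out from split alignments of nested-PCR / unidirectional
targeted sequencing reads anchored in the receiver upstream flank.  Each
inter-site event is scored t / (n + t + c): t junction-supporting reads,
n normal-join reads at the receiver, pseudocount c (default 10).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import AlignedRead
from .readprep import TagDesign
from .sites import CandidateSite, deduplicate
from .util import revcomp

MODELS = ("i", "ii", "iii", "iv", "v")


@dataclass
class TranslocConfig:
    min_seg: int = 20          # minimum aligned segment length (bp)
    receiver_window: int = 50  # seg-1 end to receiver cut tolerance (bp)
    site_window: int = 50      # donor-within-receiver distance => intra-site
    breakpoint_tol: int = 5    # merge tolerance for donor breakpoints (bp)
    pseudocount: float = 10.0
    min_tag_match: int = 6     # shortest partial tag detected between segments
    min_upstream: int = 2      # reads needed to flag unexpected upstream signal
    dedup: bool = True


@dataclass
class TranslocationEvent:
    receiver_cut: int
    donor_chrom: str
    donor_cut: int | None
    donor_end: str            # upstream | downstream | receiver
    model: str                # i..v or "unassigned"
    tag_present: bool
    t_reads: int = 0
    n_reads: int = 0
    score: float = 0.0
    low_confidence: bool = False
    same_site: bool = False


def translocation_score(t: int, n: int, c: float = 10.0) -> float:
    """t / (n + t + c): junction reads over all reads at the receiver plus a
    pseudocount damping low-coverage sites."""
    if t < 0 or n < 0 or c < 0:
        raise ValueError("t, n, c must be non-negative")
    denom = n + t + c
    if denom == 0:
        raise ValueError("score undefined for t = n = c = 0")
    return t / denom


def classify_junction(same_site: bool, donor_end: str, tag_present: bool) -> str:
    """Map a resolved junction geometry onto the five join models.

    Intra-site joins are (i) with the tag, (ii) without; inter-site joins are
    (iii) donor upstream end without tag, (iv) donor downstream end, (v) donor
    upstream end with its (reverse-oriented) tag.  Geometries outside the five
    (e.g. a tagged downstream end) return "unassigned" rather than being
    dropped.
    """
    if same_site:
        if donor_end == "downstream":
            return "i" if tag_present else "ii"
        return "unassigned"
    if donor_end == "upstream":
        return "v" if tag_present else "iii"
    if donor_end == "downstream":
        return "iv" if not tag_present else "unassigned"
    return "unassigned"


def _gap_has_tag(gap: str, tag_seq: str, k: int) -> bool:
    if len(gap) < k:
        return False
    rc = revcomp(tag_seq)
    return any(
        gap[i : i + k] in tag_seq or gap[i : i + k] in rc
        for i in range(len(gap) - k + 1)
    )


def call_junctions(
    reads: Iterable[AlignedRead],
    receiver_cuts: Sequence[int],
    tag: TagDesign,
    config: TranslocConfig | None = None,
) -> tuple[list[TranslocationEvent], dict]:
    """Call and classify donor-receiver junctions from (split) alignments.

    A read contributes when its 5' segment (>= ``min_seg`` bases, plus
    strand) ends within ``receiver_window`` of a receiver cut.  Its 3'
    segment resolves the joined end: plus-strand segments join a downstream end at
    their start, minus-strand segments an inverted upstream end at their end;
    tag bases (full or partial, either orientation) between the segments mark
    tag-carrying joins.  Contiguous reads through the cut and intra-site
    joins count as normal joins (n); inter-site events are scored
    t/(n+t+c) per receiver.  Returns (events, audit counts).
    """
    config = config or TranslocConfig()
    audit = {"reads": 0, "short_segment": 0, "unanchored": 0, "normal": 0, "junction": 0}
    items = [r for r in reads if r.is_read1]
    if config.dedup:
        items = deduplicate(items)
    events: list[TranslocationEvent] = []
    n_by_receiver: dict[int, int] = {r: 0 for r in receiver_cuts}

    def match_receiver(end_pos: int) -> int | None:
        best = None
        for rc_ in receiver_cuts:
            d = abs(end_pos - rc_)
            if d <= config.receiver_window and (best is None or d < abs(best - end_pos)):
                best = rc_
        return best

    for r in sorted(items, key=lambda x: x.read_id):
        audit["reads"] += 1
        if not r.is_split:
            # contiguous through a cut => clean normal join
            if r.interval.strand == "+":
                for rc_ in receiver_cuts:
                    if (r.interval.start <= rc_ - config.min_seg
                            and r.interval.end >= rc_ + config.min_seg):
                        n_by_receiver[rc_] += 1
                        audit["normal"] += 1
                        break
                else:
                    audit["unanchored"] += 1
            else:
                audit["unanchored"] += 1
            continue
        seg1, seg2 = r.segments[0], r.segments[1]
        if (seg1.qend - seg1.qstart) < config.min_seg or (seg2.qend - seg2.qstart) < config.min_seg:
            audit["short_segment"] += 1
            continue
        if seg1.interval.strand != "+":
            audit["unanchored"] += 1
            continue
        rc_ = match_receiver(seg1.interval.end)
        if rc_ is None:
            audit["unanchored"] += 1
            continue
        gap = r.seq[seg1.qend : seg2.qstart] if r.seq else ""
        tag_present = _gap_has_tag(gap, tag.tag_seq, config.min_tag_match)
        if seg2.interval.strand == "+":
            donor_end, donor_cut = "downstream", seg2.interval.start
        else:
            donor_end, donor_cut = "upstream", seg2.interval.end
        same_site = abs(donor_cut - rc_) <= config.site_window
        if same_site:
            n_by_receiver[rc_] += 1
            audit["normal"] += 1
        else:
            audit["junction"] += 1
        # merge into an existing event at the same breakpoint
        hit = None
        for ev in events:
            if (ev.receiver_cut == rc_ and ev.donor_end == donor_end
                    and ev.tag_present == tag_present
                    and ev.donor_chrom == seg2.interval.chrom
                    and ev.donor_cut is not None
                    and abs(ev.donor_cut - donor_cut) <= config.breakpoint_tol):
                hit = ev
                break
        if hit is None:
            hit = TranslocationEvent(
                receiver_cut=rc_, donor_chrom=seg2.interval.chrom,
                donor_cut=donor_cut, donor_end=donor_end,
                model=classify_junction(same_site, donor_end, tag_present),
                tag_present=tag_present, same_site=same_site,
            )
            events.append(hit)
        hit.t_reads += 1
    for ev in events:
        ev.n_reads = n_by_receiver.get(ev.receiver_cut, 0)
        ev.score = translocation_score(ev.t_reads, ev.n_reads, config.pseudocount)
        ev.low_confidence = ev.t_reads < 2
    events.sort(key=lambda e: (e.receiver_cut, -e.t_reads, e.donor_cut or 0))
    return events, audit


def detect_unexpected_signals(
    sites: list[CandidateSite],
    min_upstream: int = 2,
    slop: int = 2,
) -> list[tuple[CandidateSite, int]]:
    """Flag candidate sites whose forward-primer reads map upstream of the
    cut — the side a forward+Tn5 amplicon cannot reach under normal joining,
    so signal there indicates a reverse-oriented tag from a donor break
    (model v).

    Returns (site, upstream read count) for every flagged site.
    """
    flagged = []
    for s in sites:
        want = "-" if s.site_strand == "+" else "+"
        n_up = 0
        for r in s.reads:
            if r.side != "forward" or not getattr(r, "extension_ok", False):
                continue
            if r.interval.strand != want:
                continue
            if s.site_strand == "+" and r.interval.end <= s.cut_pos + slop:
                n_up += 1
            elif s.site_strand == "-" and r.interval.start >= s.cut_pos - slop:
                n_up += 1
        if n_up >= min_upstream:
            flagged.append((s, n_up))
    return flagged


EVENT_COLUMNS = [
    "receiver_cut", "donor_chrom", "donor_cut", "donor_end", "model",
    "tag_present", "t_reads", "n_reads", "score", "low_confidence",
]


def write_events(events: list[TranslocationEvent], tsv_path: str,
                 bedpe_path: str, receiver_chrom: str) -> None:
    """Events TSV plus a BEDPE (receiver breakpoint vs donor breakpoint) for
    genome browsers."""
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(EVENT_COLUMNS) + "\n")
        for e in events:
            fh.write("\t".join(map(str, [
                e.receiver_cut, e.donor_chrom,
                e.donor_cut if e.donor_cut is not None else "",
                e.donor_end, e.model, int(e.tag_present),
                e.t_reads, e.n_reads, f"{e.score:.6f}", int(e.low_confidence),
            ])) + "\n")
    with open(bedpe_path, "w") as fh:
        for e in events:
            if e.donor_cut is None or e.same_site:
                continue
            fh.write("\t".join(map(str, [
                receiver_chrom, e.receiver_cut, e.receiver_cut + 1,
                e.donor_chrom, e.donor_cut, e.donor_cut + 1,
                f"model_{e.model}", f"{e.score:.6f}", "+",
                "-" if e.donor_end == "upstream" else "+",
            ])) + "\n")
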