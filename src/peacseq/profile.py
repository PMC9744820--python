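"""Sequence-context analytics over called sites.

Positions are numbered 1-20 along the spacer 5'->3'; the PAM occupies
positions 21-23.  The PBS (primer binding site) region maps onto the spacer
3' terminus — the segment the pegRNA anneals to when priming reverse
transcription — so a ``pbs_len`` of 13 covers spacer positions 8-20.
Mismatches there can depress tag insertion at an off-target, which is why
they are annotated separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sites import SpacerMatch


@dataclass(frozen=True)
class MismatchProfile:
    """Per-position mismatch frequencies over a group of sites.

    ``freq`` has length 23: spacer positions 1-20 then PAM positions 21-23.
    Position 21 is the degenerate N and is always 0; 22/23 count PAM bases
    deviating from GG.
    """

    group_label: str
    n_sites: int
    freq: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.freq) != 23:
            raise ValueError("profile must have exactly 23 positions")
        if any(not 0.0 <= f <= 1.0 for f in self.freq):
            raise ValueError("frequencies must lie in [0, 1]")


def count_mismatches(match: SpacerMatch) -> int:
    """Number of spacer mismatches (positions 1-20 only; the degenerate PAM
    N is never counted and non-GG PAM bases are reported separately via
    :func:`pam_variant`)."""
    return match.n_mismatch


def pam_variant(match: SpacerMatch) -> int:
    """Count of PAM second/third bases deviating from GG (0 for NGG,
    1 for NAG)."""
    return sum(b != "G" for b in match.pam[1:])


def mismatch_frequency_profile(
    sites: list[SpacerMatch], group_label: str
) -> MismatchProfile:
    """Position-wise mismatch frequency across a group of matched sites."""
    if not sites:
        raise ValueError("cannot profile an empty group")
    counts = np.zeros(23)
    for m in sites:
        for p in m.mismatch_positions:
            counts[p - 1] += 1
        for k, b in enumerate(m.pam[1:], start=22):
            if b != "G":
                counts[k - 1] += 1
    freq = counts / len(sites)
    return MismatchProfile(group_label=group_label, n_sites=len(sites),
                           freq=tuple(freq.tolist()))


def annotate_pbs_mismatches(match: SpacerMatch, pbs_len: int) -> list[int]:
    """Spacer mismatch positions falling inside the PBS region
    (positions ``21 - pbs_len`` .. 20)."""
    if not 1 <= pbs_len <= 20:
        raise ValueError("pbs_len must be in 1..20")
    lo = 21 - pbs_len
    return [p for p in match.mismatch_positions if p >= lo]


def write_profile(profiles: list[MismatchProfile], path: str) -> None:
    """Profile TSV: one row per (group, position)."""
    with open(path, "w") as fh:
        fh.write("group\tn_sites\tposition\tregion\tfrequency\n")
        for pr in profiles:
            for i, f in enumerate(pr.freq, start=1):
                region = "spacer" if i <= 20 else "pam"
                fh.write(f"{pr.group_label}\t{pr.n_sites}\t{i}\t{region}\t{f:.6f}\n")
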