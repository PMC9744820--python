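"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def brute_force_spacer_scan(ref: str, cut: int, spacer: str, window: int, max_mm: int):
    """Enumerate every 20-mer + NGG/NAG on either strand whose implied cut is
    within ``window`` of ``cut``; return the winner under the
    (mismatches, NGG<NAG, cut distance, '+' first, coordinate) order, as
    (n_mm, mismatch_positions, strand, proto_start) or None.

    Written as a plain full scan over all reference positions, independent of
    the package's windowed search.
    """
    hits = []
    for s in range(len(ref) - 22):
        proto = ref[s : s + 20]
        pam = ref[s + 20 : s + 23]
        if pam[1:] in ("GG", "AG"):
            icut = s + 17
            if abs(icut - cut) <= window:
                mm = [i + 1 for i in range(20) if proto[i] != spacer[i]]
                if len(mm) <= max_mm:
                    hits.append((len(mm), 0 if pam[1:] == "GG" else 1,
                                 abs(icut - cut), 0, s, tuple(mm), "+"))
    for s in range(3, len(ref) - 19):
        proto = rc(ref[s : s + 20])
        pam = rc(ref[s - 3 : s])
        if pam[1:] in ("GG", "AG"):
            icut = s + 3
            if abs(icut - cut) <= window:
                mm = [i + 1 for i in range(20) if proto[i] != spacer[i]]
                if len(mm) <= max_mm:
                    hits.append((len(mm), 0 if pam[1:] == "GG" else 1,
                                 abs(icut - cut), 1, s, tuple(mm), "-"))
    if not hits:
        return None
    best = min(hits)
    return best[0], best[5], best[6], best[4]
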