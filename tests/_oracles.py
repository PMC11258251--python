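"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: IR finding enumerates all
(arm-start, arm-length, loop) placements; folding enumerates nested pairings
by explicit recursion on the first position; alignment scans every offset,
orientation and collapse mode with plain string comparison.
"""

from __future__ import annotations

COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}
WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def _ir_valid(s: str, i: int, a: int, g: int, min_arm: int, max_loop: int,
              max_mismatch: int, min_loop: int = 3):
    """Mismatch count of the candidate IR, or None if invalid.

    Candidate: left arm s[i..i+a-1] (0-based), loop length g, right arm
    s[i+a+g..i+a+g+a-1].  Arm position t (inside-out) pairs s[i+a-1-t]
    against s[j+t]; innermost and outermost pairs must match.
    """
    j = i + a + g
    if i < 0 or j + a > len(s) or a < min_arm or not (min_loop <= g <= max_loop):
        return None
    mm = 0
    for t in range(a):
        left, right = s[i + a - 1 - t], s[j + t]
        paired = COMP.get(right) == left
        if (t == 0 or t == a - 1) and not paired:
            return None
        mm += not paired
    return mm if mm <= max_mismatch else None


def brute_find_irs(s: str, min_arm: int, max_loop: int, max_mismatch: int,
                   min_loop: int = 3):
    """All maximal IRs as (left_start_1based, arm, loop, mismatches), sorted."""
    n = len(s)
    out = []
    for i in range(n):
        for a in range(min_arm, n):
            for g in range(min_loop, max_loop + 1):
                mm = _ir_valid(s, i, a, g, min_arm, max_loop, max_mismatch, min_loop)
                if mm is None:
                    continue
                outward = _ir_valid(s, i - 1, a + 1, g, min_arm, max_loop,
                                    max_mismatch, min_loop)
                inward = _ir_valid(s, i, a + 1, g - 2, min_arm, max_loop,
                                   max_mismatch, min_loop)
                if outward is None and inward is None:
                    out.append((i + 1, a, g, mm))
    out.sort(key=lambda r: (r[0], -r[1], r[2]))
    return out


def brute_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum nested pairing by recursion on the leftmost position."""

    def rec(i: int, j: int) -> int:
        if i >= j:
            return 0
        best = rec(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in WC:
                best = max(best, 1 + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    return rec(0, len(seq) - 1)


def revcomp(s: str) -> str:
    return "".join(COMP[c] for c in reversed(s))


def brute_align(read: str, ref: str):
    """Best bisulfite placements of a read.

    Returns (best_mismatches, placements) where each placement is
    (offset0, reverse_complemented, mode); a mode tie at one placement
    resolves to the orientation-consistent mode (fwd->top, rc->bottom).
    """

    def collapse(x: str, mode: str) -> str:
        return x.replace("C", "T") if mode == "top" else x.replace("G", "A")

    placements = []
    for oriented, is_rc in ((read, False), (revcomp(read), True)):
        consistent = "bottom" if is_rc else "top"
        other = "top" if is_rc else "bottom"
        for off in range(len(ref) - len(read) + 1):
            window = ref[off : off + len(read)]
            mm = {
                m: sum(a != b for a, b in zip(collapse(oriented, m), collapse(window, m)))
                for m in ("top", "bottom")
            }
            best_mode = consistent if mm[consistent] <= mm[other] else other
            placements.append((mm[best_mode], off, is_rc, best_mode))
    best = min(p[0] for p in placements)
    return best, [(off, rc, mode) for s, off, rc, mode in placements if s == best]
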