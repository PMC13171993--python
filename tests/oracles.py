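"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive the expected behavior from first principles
(exhaustive window scans, explicit automata) rather than reusing any code
path from the package under test.
"""

from __future__ import annotations

from typing import Optional, Sequence


def median_period(times: Sequence[float]) -> float:
    if len(times) < 2:
        return 0.0
    diffs = sorted(b - a for a, b in zip(times, times[1:]))
    mid = len(diffs) // 2
    return diffs[mid] if len(diffs) % 2 else 0.5 * (diffs[mid - 1] + diffs[mid])


def idt_oracle(samples, max_dispersion, min_duration, max_gap):
    """Greedy-left maximal-window fixation parse, recomputing every window
    predicate from scratch. Returns (onset, offset) pairs, offset = last
    sample time + one sampling period."""
    period = median_period([s.t for s in samples])
    valid = [s for s in samples if s.valid]
    out = []
    i = 0
    n = len(valid)
    while i < n:
        best = None
        for j in range(i, n):
            win = valid[i : j + 1]
            if any(b.t - a.t > max_gap for a, b in zip(win, win[1:])):
                break
            xs = [s.x for s in win]
            ys = [s.y for s in win]
            if (max(xs) - min(xs)) + (max(ys) - min(ys)) > max_dispersion:
                break
            best = j
        if best is not None and valid[best].t + period - valid[i].t >= min_duration > 0:
            out.append((valid[i].t, valid[best].t + period))
            i = best + 1
        else:
            i += 1
    return out


def alternation_oracle(labels: Sequence[Optional[str]], face="Face", target="Target") -> Optional[int]:
    """Two-state automaton: face arms; target fires when armed; any other
    label (including off-ROI None) resets. Returns the index of the firing
    fixation, or None."""
    armed = False
    for i, lab in enumerate(labels):
        if lab == face:
            armed = True
        elif lab == target:
            if armed:
                return i
            armed = False
        else:
            armed = False
    return None


def rja_oracle(labels: Sequence[Optional[str]], cued: str, opposite: str) -> str:
    """Outcome of the cue window given the participant was on the face at cue
    onset and ``labels`` are the subsequent fixation labels, in order: the
    first non-face label decides."""
    for lab in labels:
        if lab == "Face":
            continue
        if lab == cued:
            return "correct"
        if lab == opposite:
            return "incorrect"
        return "none"
    return "none"
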