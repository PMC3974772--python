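"""Independent brute-force oracles used to cross-check the implementation.

These deliberately take a different computational route from the library:
pairing by repeated first-on/first-off scanning, and window-clipped poke
time by per-millisecond membership counting.
"""


def brute_force_pairing(seq, log_end):
    """Pairing oracle: repeatedly take the first remaining 'on' and the
    first 'off' after it, discarding everything skipped over.

    ``seq`` is a time-ordered list of (time_ms, event_type) at one
    location; returns (intervals, n_discarded).
    """
    intervals, discarded = [], 0
    remaining = list(seq)
    while remaining:
        ons = [i for i, (_, t) in enumerate(remaining) if t == "on"]
        if not ons:
            discarded += len(remaining)  # leftover offs
            break
        first_on = ons[0]
        discarded += first_on  # offs before any on
        start = remaining[first_on][0]
        offs = [i for i, (_, t) in enumerate(remaining) if t == "off" and i > first_on]
        if not offs:
            discarded += len(remaining) - first_on - 1  # duplicate ons at the tail
            intervals.append((start, max(log_end, start)))
            break
        end_i = offs[0]
        discarded += end_i - first_on - 1  # duplicate ons inside the bout
        intervals.append((start, remaining[end_i][0]))
        remaining = remaining[end_i + 1 :]
    return intervals, discarded


def grid_count(pokes, window):
    """Millisecond-grid counting oracle for window-clipped poke time."""
    onset, offset = window
    return sum(
        1
        for m in range(onset, offset)
        if any(p.start_ms <= m < p.end_ms for p in pokes)
    )
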