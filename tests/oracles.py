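"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plainly as possible (python loops, math.dist)
and shares no code with the package's vectorized implementations.
"""

import math


def oracle_step_toward(p_from, p_to, pellet) -> bool:
    return math.dist(p_to, pellet) < math.dist(p_from, pellet)


def oracle_find_reaches(frames, xy, pellet, window=5, consensus=4, min_points=6, max_gap=5):
    """Enumerate every candidate window index and keep the earliest valid
    start/end pairs, alternating direction until the track is exhausted.

    Returns a list of (start_index, end_index) sample-index pairs.
    """
    n = len(frames)

    def window_valid(i, want_toward):
        if i + window > n - 1:
            return False
        hits = 0
        for j in range(i, i + window):
            if frames[j + 1] - frames[j] > max_gap:
                return False
            d0 = math.dist(xy[j], pellet)
            d1 = math.dist(xy[j + 1], pellet)
            if (d1 < d0) if want_toward else (d1 > d0):
                hits += 1
        return hits >= consensus

    pairs = []
    i = 0
    while True:
        start = None
        for j in range(i, n):
            if window_valid(j, True):
                start = j
                break
        if start is None:
            break
        anchor = None
        for j in range(start + 1, n):
            if window_valid(j, False):
                anchor = j
                break
        if anchor is None:
            break
        # retraction onset = closest approach within the qualifying window
        best = anchor
        for j in range(anchor, anchor + window + 1):
            if math.dist(xy[j], pellet) < math.dist(xy[best], pellet):
                best = j
        end = best
        if end - start + 1 >= min_points:
            pairs.append((start, end))
        i = end + 1
    return pairs


def oracle_path_length(xy) -> float:
    total = 0.0
    for a, b in zip(xy, xy[1:]):
        total += math.dist(a, b)
    return total


def oracle_delta_y(xy) -> float:
    ys = [p[1] for p in xy]
    return max(ys) - min(ys)


def oracle_delta_x(xy, slit_x, toward_sign) -> float:
    best = 0.0
    for p in xy:
        ext = toward_sign * (p[0] - slit_x)
        if ext > best:
            best = ext
    return best


def oracle_assign(reach_starts, windows):
    """windows: list of (trial, start, end_exclusive). Returns trial or None
    per reach by exhaustive containment."""
    out = []
    for s in reach_starts:
        hit = None
        for t, lo, hi in windows:
            if lo <= s < hi:
                hit = t
        out.append(hit)
    return out
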