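"""Independent brute-force oracles for the digital-topology operations.

These are deliberately naive (breadth-first flood fills over explicit
neighbor lists) and share no code with the package implementation; the test
suite requires exact agreement between the two on random masks.
"""

from collections import deque

import numpy as np

N4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
N8 = N4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def flood_components(fg: np.ndarray, neighbors=N4) -> np.ndarray:
    """Label connected regions of a boolean grid by flood fill.

    Labels are 1..k in row-major order of each region's first pixel;
    0 marks pixels outside the region set.
    """
    n, m = fg.shape
    labels = np.zeros((n, m), dtype=int)
    nxt = 0
    for r in range(n):
        for c in range(m):
            if fg[r, c] and labels[r, c] == 0:
                nxt += 1
                queue = deque([(r, c)])
                labels[r, c] = nxt
                while queue:
                    rr, cc = queue.popleft()
                    for dr, dc in neighbors:
                        a, b = rr + dr, cc + dc
                        if (0 <= a < n and 0 <= b < m and fg[a, b]
                                and labels[a, b] == 0):
                            labels[a, b] = nxt
                            queue.append((a, b))
    return labels


def flood_holes(fg: np.ndarray):
    """Hole regions by border flood fill.

    Background (8-connectivity) is flooded from every border pixel; the
    remaining background regions are the holes.  Returns (hole_labels,
    n_holes) with holes numbered 1..h row-major.
    """
    n, m = fg.shape
    bg = ~fg
    reach = np.zeros((n, m), dtype=bool)
    queue = deque()
    for r in range(n):
        for c in range(m):
            if (r in (0, n - 1) or c in (0, m - 1)) and bg[r, c]:
                reach[r, c] = True
                queue.append((r, c))
    while queue:
        rr, cc = queue.popleft()
        for dr, dc in N8:
            a, b = rr + dr, cc + dc
            if 0 <= a < n and 0 <= b < m and bg[a, b] and not reach[a, b]:
                reach[a, b] = True
                queue.append((a, b))
    hole_mask = bg & ~reach
    hole_labels = flood_components(hole_mask, N8)
    return hole_labels, int(hole_labels.max())


def holes_per_component(fg: np.ndarray):
    """Per-component hole counts with plurality 4-adjacency assignment.

    Mirrors the documented reporting rule: each hole goes to the foreground
    component with the most 4-adjacent pixels along the hole boundary, ties
    to the smallest component id.
    """
    comp = flood_components(fg, N4)
    hole_labels, nholes = flood_holes(fg)
    counts = {cid: 0 for cid in range(1, comp.max() + 1)}
    n, m = fg.shape
    for h in range(1, nholes + 1):
        votes = {}
        for r in range(n):
            for c in range(m):
                if hole_labels[r, c] == h:
                    for dr, dc in N4:
                        a, b = r + dr, c + dc
                        if 0 <= a < n and 0 <= b < m and comp[a, b] > 0:
                            votes[comp[a, b]] = votes.get(comp[a, b], 0) + 1
        if votes:
            best = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))[0]
            counts[best] += 1
    return counts, nholes
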