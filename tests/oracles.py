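"""Independent reference implementations used only by the test suite.

These deliberately avoid the code paths (and the scipy labeling machinery)
used by the package: connected components come from a hand-written BFS
flood fill, and the Euler number from local 2x2 bit-quad pattern counting
(Gray's formula).  Agreement between the package and both oracles, which
are themselves mutually consistent only under the 8-connected-foreground /
4-connected-background pairing, pins down the topology conventions.
"""

from collections import deque

import numpy as np

_N8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_N4 = [(-1, 0), (0, -1), (0, 1), (1, 0)]


def _flood_count(mask: np.ndarray, neighbors) -> tuple[int, np.ndarray]:
    """Label True pixels by BFS; returns (component count, label array)."""
    H, W = mask.shape
    labels = np.zeros((H, W), dtype=np.int64)
    current = 0
    for sr in range(H):
        for sc in range(W):
            if mask[sr, sc] and labels[sr, sc] == 0:
                current += 1
                queue = deque([(sr, sc)])
                labels[sr, sc] = current
                while queue:
                    r, c = queue.popleft()
                    for dr, dc in neighbors:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < H and 0 <= cc < W and mask[rr, cc] and labels[rr, cc] == 0:
                            labels[rr, cc] = current
                            queue.append((rr, cc))
    return current, labels


def betti_flood_fill(mask: np.ndarray) -> tuple[int, int]:
    """(b0, b1) by BFS: 8-connected foreground, 4-connected background.

    Background components that touch the (padded) border are not holes.
    """
    mask = np.asarray(mask, dtype=bool)
    b0, _ = _flood_count(mask, _N8)
    padded = np.pad(mask, 1, constant_values=False)
    n_bg, bg_labels = _flood_count(~padded, _N4)
    border_label = bg_labels[0, 0]  # the frame is one 4-connected component
    b1 = n_bg - (1 if border_label else 0)
    return b0, b1


def euler_bit_quads(mask: np.ndarray) -> int:
    """Euler number b0 - b1 under 8-connectivity by 2x2 bit-quad counting.

    Gray's formula: E8 = (Q1 - Q3 - 2*QD) / 4, counting the 2x2 windows of
    the zero-padded image with one foreground pixel (Q1), three (Q3), and
    the two diagonal patterns (QD).
    """
    padded = np.pad(np.asarray(mask, dtype=np.int64), 1, constant_values=0)
    a = padded[:-1, :-1]
    b = padded[:-1, 1:]
    c = padded[1:, :-1]
    d = padded[1:, 1:]
    total = a + b + c + d
    q1 = int((total == 1).sum())
    q3 = int((total == 3).sum())
    qd = int(((total == 2) & (a == d) & (b == c) & (a != b)).sum())
    quad = q1 - q3 - 2 * qd
    assert quad % 4 == 0
    return quad // 4
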