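"""Independent brute-force oracles used by the test suite.

Each oracle implements the mathematical set definition of an operation
directly, in plain Python loops, without reference to the library code it
checks.
"""

from __future__ import annotations

import numpy as np


def dilate_oracle(mask: np.ndarray, se_side: int) -> np.ndarray:
    """Set-definition dilation with a square SE; outside the frame is 0."""
    h, w = mask.shape
    r = se_side // 2
    out = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            hit = False
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < h and 0 <= jj < w and mask[ii, jj]:
                        hit = True
            out[i, j] = 1 if hit else 0
    return out


def erode_oracle(mask: np.ndarray, se_side: int) -> np.ndarray:
    """Set-definition erosion; out-of-frame pixels count as background."""
    h, w = mask.shape
    r = se_side // 2
    out = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            ok = True
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii, jj = i + di, j + dj
                    if not (0 <= ii < h and 0 <= jj < w and mask[ii, jj]):
                        ok = False
            out[i, j] = 1 if ok else 0
    return out


def close_oracle(mask: np.ndarray, se_side: int) -> np.ndarray:
    """Closing on the zero-padded plane, cropped back to the frame."""
    r = se_side // 2
    padded = np.pad(mask, r)
    closed = erode_oracle(dilate_oracle(padded, se_side), se_side)
    return closed[r:-r, r:-r] if r else closed


def open_oracle(mask: np.ndarray, se_side: int) -> np.ndarray:
    return dilate_oracle(erode_oracle(mask, se_side), se_side)


def fill_holes_oracle(mask: np.ndarray) -> np.ndarray:
    """Flood fill the background from the border; unreached zeros are holes."""
    h, w = mask.shape
    reached = np.zeros((h, w), dtype=bool)
    stack = [
        (i, j)
        for i in range(h)
        for j in range(w)
        if (i in (0, h - 1) or j in (0, w - 1)) and not mask[i, j]
    ]
    for p in stack:
        reached[p] = True
    while stack:
        i, j = stack.pop()
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ii, jj = i + di, j + dj
            if 0 <= ii < h and 0 <= jj < w and not mask[ii, jj] and not reached[ii, jj]:
                reached[ii, jj] = True
                stack.append((ii, jj))
    out = mask.copy()
    out[(mask == 0) & ~reached] = 1
    return out


def pointwise_loss_oracle(p, y, alpha_w, beta_w, eta, eps=1e-7):
    """Scalar piecewise loss, written out case by case."""
    p = min(max(p, eps), 1.0 - eps)
    if y == 0:
        return -alpha_w * np.log(1.0 - p)
    if 0 < y < eta:
        return 0.0
    return -beta_w * np.log(p)


def image_loss_oracle(maps, consensus, alpha_w, beta_w, eta):
    """Exhaustive per-pixel, per-map summation."""
    total = 0.0
    for prob in maps:
        for i in range(consensus.shape[0]):
            for j in range(consensus.shape[1]):
                total += pointwise_loss_oracle(
                    prob[i, j], consensus[i, j], alpha_w, beta_w, eta
                )
    return total


def max_matching_oracle(pred_mask, gt_mask, tol_px):
    """Optimal bipartite edge-pixel matching via Hopcroft-Karp (networkx)."""
    import networkx as nx

    p_coords = np.argwhere(np.asarray(pred_mask) > 0)
    g_coords = np.argwhere(np.asarray(gt_mask) > 0)
    graph = nx.Graph()
    pn = [("p", i) for i in range(len(p_coords))]
    gn = [("g", j) for j in range(len(g_coords))]
    graph.add_nodes_from(pn, bipartite=0)
    graph.add_nodes_from(gn, bipartite=1)
    for i, pc in enumerate(p_coords):
        for j, gc in enumerate(g_coords):
            if np.hypot(*(pc - gc)) <= tol_px + 1e-9:
                graph.add_edge(("p", i), ("g", j))
    matching = nx.bipartite.maximum_matching(graph, top_nodes=pn)
    return sum(1 for k in matching if k[0] == "p"), len(p_coords), len(g_coords)
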