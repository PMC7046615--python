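"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the library code paths they check: path costs by
exhaustive simple-path enumeration, interaction flux by a double loop over
all patch pairs, AUC by pairwise concordance counting.
"""

import math

import numpy as np

_MOVES = [
    (dr, dc)
    for dr in (-1, 0, 1)
    for dc in (-1, 0, 1)
    if (dr, dc) != (0, 0)
]


def exhaustive_least_cost(
    resistance: np.ndarray, cell_size: float, start: tuple, goal: tuple
) -> float:
    """Cheapest 8-connected path cost by depth-first enumeration of simple
    paths (with cost-based pruning); move cost = cell_size x mean incident
    resistance, x sqrt(2) for diagonals."""
    n_rows, n_cols = resistance.shape
    best = [math.inf]

    def walk(cell, cost, visited):
        if cost >= best[0]:
            return
        if cell == goal:
            best[0] = cost
            return
        r, c = cell
        for dr, dc in _MOVES:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < n_rows and 0 <= cc < n_cols):
                continue
            if (rr, cc) in visited:
                continue
            length = cell_size * (math.sqrt(2.0) if dr and dc else 1.0)
            step = length * (resistance[r, c] + resistance[rr, cc]) / 2.0
            visited.add((rr, cc))
            walk((rr, cc), cost + step, visited)
            visited.discard((rr, cc))

    walk(tuple(start), 0.0, {tuple(start)})
    return best[0]


def double_loop_interaction_flux(
    capacities: np.ndarray, dist: np.ndarray, alpha: float, d_max: float
) -> np.ndarray:
    """IF per patch as a literal double loop over all ordered pairs; pairs
    beyond d_max interact with probability 0."""
    n = len(capacities)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j or dist[i, j] > d_max:
                continue
            out[i] += capacities[i] * capacities[j] * math.exp(-alpha * dist[i, j])
    return out


def concordance_auc(scores, labels) -> float:
    """AUC as the fraction of concordant presence/absence pairs (ties half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else 0.5 if p == q else 0.0
    return total / (len(pos) * len(neg))


def flood_fill_components(mask: np.ndarray) -> int:
    """Count 8-connected components of a boolean grid by explicit flood fill."""
    seen = np.zeros_like(mask, dtype=bool)
    n_rows, n_cols = mask.shape
    count = 0
    for r0 in range(n_rows):
        for c0 in range(n_cols):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            count += 1
            stack = [(r0, c0)]
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                for dr, dc in _MOVES:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < n_rows and 0 <= cc < n_cols:
                        if mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
    return count
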