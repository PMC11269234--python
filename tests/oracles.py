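"""Independent oracles used by several test modules.

These deliberately avoid the implementation paths they check.
"""

import numpy as np


def peel_fronts_brute_force(objectives):
    """Dominance peeling: repeatedly remove the maximal non-dominated set.

    O(n^2 * fronts) reference for fast non-dominated sorting.
    """

    def dominated(a, b):
        # b dominates a (minimization)
        return all(y <= x for x, y in zip(a, b)) and any(y < x for x, y in zip(a, b))

    remaining = list(range(len(objectives)))
    fronts = []
    while remaining:
        front = [
            i
            for i in remaining
            if not any(dominated(objectives[i], objectives[j]) for j in remaining if j != i)
        ]
        fronts.append(front)
        remaining = [i for i in remaining if i not in front]
    return fronts


def nearest_neighbor_labels(train_x, train_y, queries):
    """Exhaustive 1-NN prediction in the given space."""
    out = np.empty(len(queries), dtype=np.intp)
    for k, q in enumerate(np.asarray(queries)):
        d2 = ((np.asarray(train_x) - q) ** 2).sum(axis=1)
        out[k] = train_y[int(np.argmin(d2))]
    return out
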