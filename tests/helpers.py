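"""Independent oracles used by the test suite.

These are deliberately coded against the raw data structures (bit sets,
coordinate arrays) rather than through the library's own code paths, so
they can serve as cross-checks.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def brute_force_symmetry_rmsd(elements_a, coords_a, elements_b, coords_b) -> float:
    """Exhaustive minimum RMSD over all same-element atom permutations."""
    coords_a = np.asarray(coords_a, float)
    coords_b = np.asarray(coords_b, float)
    classes = sorted(set(elements_a))
    idx_a = {el: [i for i, e in enumerate(elements_a) if e == el] for el in classes}
    idx_b = {el: [i for i, e in enumerate(elements_b) if e == el] for el in classes}
    best_per_class = []
    for el in classes:
        ia, ib = idx_a[el], idx_b[el]
        assert len(ia) == len(ib)
        best = min(
            sum(
                float(np.sum((coords_a[i] - coords_b[j]) ** 2))
                for i, j in zip(ia, perm)
            )
            for perm in permutations(ib)
        )
        best_per_class.append(best)
    n = len(elements_a)
    return float(np.sqrt(sum(best_per_class) / n))


def brute_force_leader_partition(ids, bitsets, scores, threshold) -> list[list[str]]:
    """Single-pass leader clustering coded directly on bit sets.

    Items are visited best score (lowest) first; each joins the earliest
    leader with Tanimoto >= threshold, else becomes a new leader.
    """
    order = sorted(range(len(ids)), key=lambda i: (scores[i], ids[i]))
    leaders: list[int] = []
    clusters: list[list[str]] = []
    for i in order:
        for k, lead in enumerate(leaders):
            a, b = bitsets[i], bitsets[lead]
            if not a and not b:
                tc = 0.0
            else:
                tc = len(a & b) / len(a | b)
            if tc >= threshold:
                clusters[k].append(ids[i])
                break
        else:
            leaders.append(i)
            clusters.append([ids[i]])
    return clusters
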