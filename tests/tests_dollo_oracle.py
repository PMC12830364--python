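"""Independent brute-force oracle for single-gain (Dollo) reconstruction.

Enumerates every (gain node, loss-branch subset) assignment and returns the
minimal number of losses reproducing a presence pattern; exponential in
tree size, intended for trees with <= 6 leaves only.
"""

from __future__ import annotations

import itertools


def brute_force_min_losses(tree, present) -> int:
    present = set(present)
    if not present:
        return 0
    best = None
    for gain in tree.preorder_node_iter():
        below = {l.taxon.label for l in gain.leaf_iter()}
        if not present <= below:
            continue
        edges = [n for n in gain.preorder_iter() if n is not gain]
        found = False
        for r in range(len(edges) + 1):
            if best is not None and r >= best:
                break
            for losses in itertools.combinations(edges, r):
                if _consistent(gain, set(losses), present):
                    best = r if best is None else min(best, r)
                    found = True
                    break
            if found:
                break
    assert best is not None
    return best


def _consistent(gain, lost, present) -> bool:
    for leaf in gain.leaf_iter():
        node, hit = leaf, False
        while node is not gain and node is not None:
            if node in lost:
                hit = True
                break
            node = node.parent_node
        if (leaf.taxon.label in present) != (not hit):
            return False
    return True
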