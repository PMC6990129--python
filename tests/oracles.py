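"""Independent brute-force oracles shared across test modules."""

import numpy as np
import pandas as pd
from skbio import TreeNode


def brute_force_weighted_unifrac(tree: TreeNode, counts: pd.DataFrame, normalized=False):
    """Independent oracle: explicit enumeration of every branch.

    For each non-root node, sum the counts of its descendant leaves in
    each sample, convert to proportions and accumulate
    length * |p_A - p_B| (normalizer: length * (p_A + p_B)).
    """
    samples = list(counts.columns)
    totals = counts.sum(axis=0)
    n = len(samples)
    d = np.zeros((n, n))
    norm = np.zeros((n, n))
    for node in tree.traverse(include_self=False):
        length = node.length or 0.0
        leaves = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        sub = counts.loc[[l for l in leaves if l in counts.index]].sum(axis=0)
        p = (sub / totals).to_numpy()
        d += length * np.abs(p[:, None] - p[None, :])
        norm += length * (p[:, None] + p[None, :])
    if normalized:
        with np.errstate(invalid="ignore"):
            d = np.where(norm > 0, d / norm, 0.0)
        np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=samples, columns=samples)
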