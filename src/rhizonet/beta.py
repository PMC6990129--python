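"""Beta diversity: weighted UniFrac, PCoA and PERMANOVA (ADONIS).

Weighted UniFrac sums branch lengths weighted by the absolute
difference in the proportion of reads descending from each branch in
the two samples; the raw (non-normalized) form is the default, with the
abundance-weighted normalizer selectable. Ordination is classical PCoA
(eigendecomposition of the Gower-centered squared-distance matrix).
PERMANOVA partitions the distance matrix by a single factor; a
categorical factor uses the standard one-way pseudo-F, a continuous
covariate enters through the distance-based linear model (McArdle &
Anderson), and significance comes from free permutation of sample
labels with the (exceedances + 1) / (permutations + 1) estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.stats.ordination import OrdinationResults
from skbio.stats.ordination import pcoa as _skbio_pcoa

from rhizonet.tables_io import CountTable


def read_tree(path) -> TreeNode:
    """Read a rooted newick tree."""
    return TreeNode.read(str(path), format="newick")


def _branch_proportion_matrix(
    table: CountTable, tree: TreeNode
) -> tuple[np.ndarray, np.ndarray]:
    """Postorder accumulation of per-branch descendant read proportions.

    Returns (lengths, P) where row b of P holds, for every sample, the
    proportion of its reads descending through branch b (one row per
    non-root node). Leaves absent from the table count zero reads.
    """
    otu_index = {o: i for i, o in enumerate(table.otu_ids)}
    prop = table.counts / table.sample_totals().to_numpy()[None, :]
    n_samples = table.shape[1]
    lengths, rows = [], []
    node_acc: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            i = otu_index.get(node.name)
            acc = prop[i].astype(float) if i is not None else np.zeros(n_samples)
        else:
            acc = np.zeros(n_samples)
            for child in node.children:
                acc = acc + node_acc.pop(id(child))
        node_acc[id(node)] = acc
        if node.parent is not None:
            lengths.append(float(node.length or 0.0))
            rows.append(acc)
    return np.asarray(lengths), np.asarray(rows)


def weighted_unifrac(
    table: CountTable, tree: TreeNode, normalized: bool = False
) -> DistanceMatrix:
    """Weighted UniFrac distances between all sample pairs.

    Raw form (default): sum over branches of length * |p_A - p_B|,
    where p is the proportion of a sample's reads descending through
    the branch. ``normalized=True`` divides by the abundance-weighted
    tree depth sum(length * (p_A + p_B)), bounding distances in [0, 1].
    Every OTU in the table must match a leaf of ``tree``; per-sample
    totals must be positive. Multifurcations are allowed.
    """
    leaves = {n.name for n in tree.tips()}
    missing = [o for o in table.otu_ids if o not in leaves]
    if missing:
        raise ValueError(f"OTUs missing from tree: {missing}")
    totals = table.sample_totals()
    empty = list(totals.index[totals == 0])
    if empty:
        raise ValueError(f"zero-total sample(s): {empty}")
    lengths, p = _branch_proportion_matrix(table, tree)
    lp = lengths[:, None] * p
    diff = np.abs(lp[:, :, None] - lp[:, None, :]).sum(axis=0)
    if normalized:
        denom = (lp[:, :, None] + lp[:, None, :]).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            diff = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
        np.fill_diagonal(diff, 0.0)
    diff = 0.5 * (diff + diff.T)  # exact symmetry against float jitter
    return DistanceMatrix(diff, ids=table.sample_ids)


def pcoa(dm: DistanceMatrix, dimensions: int = 0) -> OrdinationResults:
    """Classical principal coordinates analysis.

    Negative eigenvalues are reported but excluded from the explained
    proportions. Requires at least 3 samples.
    """
    if dm.shape[0] < 3:
        raise ValueError("PCoA requires at least 3 samples")
    return _skbio_pcoa(dm, method="eigh", dimensions=dimensions, warn_neg_eigval=False)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])


@dataclass
class AdonisResult:
    """One-factor PERMANOVA outcome."""

    factor: str
    r2: float
    pseudo_f: float
    p_value: float
    n_permutations: int
    df_model: int
    df_residual: int

    def __str__(self) -> str:
        return (
            f"ADONIS[{self.factor}] R2={self.r2:.3f} "
            f"F={self.pseudo_f:.3f} p={self.p_value:.4g} "
            f"({self.n_permutations} permutations)"
        )


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


def _design_matrix(values: pd.Series, continuous: bool) -> np.ndarray:
    n = len(values)
    if continuous:
        z = values.to_numpy(dtype=float)
        if np.allclose(z, z[0]):
            raise ValueError("constant covariate")
        return np.column_stack([np.ones(n), z - z.mean()])
    levels = pd.unique(values.astype(str))
    if len(levels) < 2:
        raise ValueError(f"factor needs >= 2 levels, got {list(levels)}")
    dummies = pd.get_dummies(values.astype(str), drop_first=True).to_numpy(dtype=float)
    return np.column_stack([np.ones(n), dummies])


def adonis(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    factor: str,
    n_permutations: int = 999,
    seed: int = 0,
    continuous: bool | None = None,
) -> AdonisResult:
    """One-factor PERMANOVA on a distance matrix.

    ``continuous=None`` auto-detects: a numeric, non-integer-coded
    factor with many distinct values is treated as a covariate in a
    distance-based regression; otherwise levels are dummy-coded.
    The p-value uses ``(exceedances + 1) / (n_permutations + 1)``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    ids = list(dm.ids)
    values = metadata.loc[ids, factor]
    if continuous is None:
        continuous = (
            pd.api.types.is_float_dtype(values) and pd.Series(values).nunique() > 2
        )
    x = _design_matrix(values, continuous)
    n, k = x.shape
    g = _gower_center(dm.data)
    h = x @ np.linalg.solve(x.T @ x, x.T)
    ss_total = float(np.trace(g))
    ss_model = float(np.sum(h * g))  # tr(HG), H symmetric idempotent
    ss_res = ss_total - ss_model
    df_model = k - 1
    df_res = n - k
    if df_res == 0:
        # saturated design: every point is its own group, no residual
        return AdonisResult(
            factor=factor, r2=ss_model / ss_total, pseudo_f=float("inf"),
            p_value=float("nan"), n_permutations=0, df_model=df_model, df_residual=0,
        )
    f_obs = (ss_model / df_model) / (ss_res / df_res)
    rng = np.random.default_rng(seed)
    exceed = 0
    # strict exceedance (with float tolerance): permutations that merely
    # reproduce the observed partition tie F exactly and carry no
    # evidence against H0; under a continuous null ties have measure
    # zero so this matches the usual >= convention in calibration
    tol = 1e-10 * abs(f_obs) + 1e-12
    for _ in range(n_permutations):
        idx = rng.permutation(n)
        gp = g[np.ix_(idx, idx)]
        ssm = float(np.sum(h * gp))
        ssr = ss_total - ssm
        fp = (ssm / df_model) / (ssr / df_res)
        if fp > f_obs + tol:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return AdonisResult(
        factor=factor,
        r2=ss_model / ss_total,
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=n_permutations,
        df_model=df_model,
        df_residual=df_res,
    )
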