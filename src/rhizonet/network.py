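"""Ensemble co-occurrence network inference for merged fungal-bacterial
OTU tables.

The pipeline scores every OTU pair under four similarity measures
(Bray-Curtis, symmetrized Kullback-Leibler, Pearson, Spearman),
selects an initial candidate edge set per measure (strongest
co-presence plus strongest mutual exclusion), assigns each candidate a
per-measure p-value from a permutation null with per-sample
renormalization for the correlation measures (the ReBoot scheme, which
counteracts the spurious negative correlation induced by
compositionality), removes measure-edges whose observed score falls
outside the central percentile interval of a bootstrap distribution,
merges the per-measure p-values with Brown's method (Fisher's
combined test extended to dependent p-values by moment matching a
scaled chi-square), applies Benjamini-Hochberg FDR, and retains edges
supported by a minimum number of direction-consistent measures.
Consortia are the connected components of the retained edge graph.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from rhizonet.diversity import GroupComparison, compare_groups
from rhizonet.tables_io import CountTable

logger = logging.getLogger(__name__)

MEASURES = ("bray_curtis", "kullback_leibler", "pearson", "spearman")
_CORRELATION_MEASURES = frozenset({"pearson", "spearman"})
_KL_EPS = 1e-6


@dataclass
class NetworkConfig:
    """Tuning knobs of the ensemble network pipeline.

    ``n_initial_edges`` is interpreted per measure and split evenly
    between the strongest co-presence and strongest mutual-exclusion
    candidates; the candidate set is the union across measures.
    """

    min_otu_reads: int = 500
    n_initial_edges: int = 2000
    measures: tuple[str, ...] = MEASURES
    n_permutations: int = 100
    n_bootstraps: int = 100
    stability_percentiles: tuple[float, float] = (2.5, 97.5)
    alpha: float = 0.05
    min_support: int = 3
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.measures) - set(MEASURES)
        if unknown:
            raise ValueError(f"unknown measures: {sorted(unknown)}")
        if self.min_support > len(self.measures):
            raise ValueError("min_support cannot exceed the number of measures")
        lo, hi = self.stability_percentiles
        if not 0 <= lo < hi <= 100:
            raise ValueError("stability percentiles must satisfy 0 <= lo < hi <= 100")


def merge_kingdom_tables(
    fungal: CountTable, bacterial: CountTable, min_otu_reads: int = 500
) -> tuple[CountTable, pd.Series]:
    """Row-concatenate the fungal and bacterial tables and drop OTUs with
    total reads strictly below ``min_otu_reads``.

    Sample sets must be identical. Colliding OTU ids are disambiguated
    with ``F_``/``B_`` prefixes. Returns the merged table and a Series
    mapping OTU id to kingdom ("fungal" / "bacterial").
    """
    fs, bs = set(fungal.sample_ids), set(bacterial.sample_ids)
    if fs != bs:
        raise ValueError(
            f"sample sets differ; only-fungal={sorted(fs - bs)} only-bacterial={sorted(bs - fs)}"
        )
    fdf = fungal.df
    bdf = bacterial.df[fungal.sample_ids]
    collisions = set(fdf.index) & set(bdf.index)
    if collisions:
        fdf = fdf.rename(index={o: f"F_{o}" for o in collisions})
        bdf = bdf.rename(index={o: f"B_{o}" for o in collisions})
    merged = pd.concat([fdf, bdf], axis=0)
    kingdom = pd.Series(
        ["fungal"] * len(fdf) + ["bacterial"] * len(bdf), index=merged.index, name="kingdom"
    )
    keep = merged.sum(axis=1) >= min_otu_reads
    return CountTable(merged.loc[keep]), kingdom.loc[keep]


# ---------------------------------------------------------------------------
# pairwise scoring
# ---------------------------------------------------------------------------


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=-1)


def _corrcoef_rows(x: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        c = np.corrcoef(x)
    return c


def score_matrix(rel: np.ndarray, measure: str) -> np.ndarray:
    """All-pairs score matrix over OTU relative-abundance rows.

    Bray-Curtis is reported as similarity (1 - dissimilarity);
    Kullback-Leibler as the negated symmetrized (Jeffreys) divergence of
    the pseudocounted row profiles; Pearson/Spearman as the correlation
    coefficient. Pairs that are undefined under a measure (constant row
    under a correlation) are NaN.
    """
    rel = np.asarray(rel, dtype=float)
    if measure == "pearson":
        return _corrcoef_rows(rel)
    if measure == "spearman":
        return _corrcoef_rows(_rank_rows(rel))
    if measure == "bray_curtis":
        from scipy.spatial.distance import pdist, squareform

        return 1.0 - squareform(pdist(rel, "braycurtis"))
    if measure == "kullback_leibler":
        p = rel + _KL_EPS
        p = p / p.sum(axis=1, keepdims=True)
        logp = np.log(p)
        s = (p * logp).sum(axis=1)
        kl = s[:, None] - p @ logp.T
        return -(kl + kl.T)
    raise ValueError(f"unknown measure {measure!r}")


def _rowwise_scores(x: np.ndarray, y: np.ndarray, measure: str) -> np.ndarray:
    """Score paired rows of two equal-shape 2-D arrays under a measure."""
    if measure == "spearman":
        x, y = _rank_rows(x), _rank_rows(y)
        measure = "pearson"
    if measure == "pearson":
        xc = x - x.mean(axis=-1, keepdims=True)
        yc = y - y.mean(axis=-1, keepdims=True)
        num = (xc * yc).sum(axis=-1)
        den = np.sqrt((xc**2).sum(axis=-1) * (yc**2).sum(axis=-1))
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    if measure == "bray_curtis":
        denom = (x + y).sum(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, 1.0 - np.abs(x - y).sum(axis=-1) / denom, np.nan)
    if measure == "kullback_leibler":
        p = x + _KL_EPS
        p = p / p.sum(axis=-1, keepdims=True)
        q = y + _KL_EPS
        q = q / q.sum(axis=-1, keepdims=True)
        return -((p - q) * (np.log(p) - np.log(q))).sum(axis=-1)
    raise ValueError(f"unknown measure {measure!r}")


def score_all_pairs(table: CountTable, measure: str) -> pd.DataFrame:
    """Tidy all-pairs scores for one measure.

    Requires >= 4 samples. Returns columns otu_a, otu_b, score with the
    lexicographically smaller OTU first; undefined pairs (e.g. a
    constant profile under a correlation measure) are omitted.
    """
    if table.shape[1] < 4:
        raise ValueError("need at least 4 samples to score co-occurrence")
    rel = table.relative_abundance().to_numpy()
    mat = score_matrix(rel, measure)
    ids = table.otu_ids
    iu, ju = np.triu_indices(len(ids), k=1)
    scores = mat[iu, ju]
    ok = np.isfinite(scores)
    return pd.DataFrame(
        {
            "otu_a": [ids[i] for i in iu[ok]],
            "otu_b": [ids[j] for j in ju[ok]],
            "score": scores[ok],
        }
    )


def select_initial_edges(
    score_mats: dict[str, np.ndarray], otu_ids: list[str], config: NetworkConfig
) -> list[tuple[int, int]]:
    """Per measure, keep the ``n_initial_edges/2`` strongest co-presence
    and strongest mutual-exclusion pairs; return the union.

    Ranking ties at the cutoff are broken by pair id order
    (lexicographically smaller pair wins).
    """
    n = len(otu_ids)
    iu, ju = np.triu_indices(n, k=1)
    pair_keys = [(otu_ids[i], otu_ids[j]) for i, j in zip(iu, ju)]
    half = config.n_initial_edges // 2
    chosen: set[tuple[int, int]] = set()
    for measure in config.measures:
        flat = score_mats[measure][iu, ju]
        ok = np.where(np.isfinite(flat))[0]
        if ok.size <= config.n_initial_edges:
            if ok.size < config.n_initial_edges:
                logger.warning(
                    "%s: only %d scored pairs for %d requested edges; keeping all",
                    measure, ok.size, config.n_initial_edges,
                )
            chosen.update((int(iu[k]), int(ju[k])) for k in ok)
            continue
        order_top = sorted(ok, key=lambda k: (-flat[k], pair_keys[k]))
        order_bot = sorted(ok, key=lambda k: (flat[k], pair_keys[k]))
        for k in order_top[:half]:
            chosen.add((int(iu[k]), int(ju[k])))
        for k in order_bot[:half]:
            chosen.add((int(iu[k]), int(ju[k])))
    return sorted(chosen)


# ---------------------------------------------------------------------------
# permutation null (ReBoot) and bootstrap stability
# ---------------------------------------------------------------------------


def _permuted_rows(rows: np.ndarray, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """(c, n) -> (c, n_draws, n), each draw an independent permutation."""
    c, n = rows.shape
    tiled = np.broadcast_to(rows[:, None, :], (c, n_draws, n))
    return rng.permuted(tiled, axis=-1)


def _null_scores_batch(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    rel_a: np.ndarray,
    rel_b: np.ndarray,
    totals: np.ndarray,
    measure: str,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """ReBoot null scores for a batch of edges: (c, n_permutations).

    One OTU of each pair is shuffled across samples. For correlation
    measures the shuffled table is renormalized per sample (column
    totals are recomputed with the shuffled row) before converting to
    relative abundances, which restores the compositional coupling the
    null must preserve. Distance-type measures shuffle the relative
    abundance profile directly.
    """
    c, n = counts_a.shape
    if measure in _CORRELATION_MEASURES:
        a_perm = _permuted_rows(counts_a.astype(float), n_permutations, rng)
        t_new = totals[None, None, :] - counts_a[:, None, :] + a_perm
        t_new = np.where(t_new <= 0, 1.0, t_new)
        x = a_perm / t_new
        y = counts_b[:, None, :] / t_new
    else:
        x = _permuted_rows(rel_a, n_permutations, rng)
        y = np.broadcast_to(rel_b[:, None, :], (c, n_permutations, n))
    return _rowwise_scores(
        x.reshape(-1, n), np.ascontiguousarray(y).reshape(-1, n), measure
    ).reshape(c, n_permutations)


def _bootstrap_scores_batch(
    rel_a: np.ndarray,
    rel_b: np.ndarray,
    measure: str,
    n_bootstraps: int,
    rng: np.random.Generator,
    max_retries: int = 10,
) -> np.ndarray:
    """Bootstrap scores for a batch of edges: (c, n_bootstraps).

    Samples are resampled with replacement; degenerate draws consisting
    of a single distinct sample are redrawn (bounded retries).
    """
    c, n = rel_a.shape
    idx = rng.integers(0, n, size=(c, n_bootstraps, n))
    for _ in range(max_retries):
        degen = idx.max(axis=-1) == idx.min(axis=-1)
        if not degen.any():
            break
        idx[degen] = rng.integers(0, n, size=(int(degen.sum()), n))
    x = np.take_along_axis(rel_a[:, None, :], idx, axis=-1)
    y = np.take_along_axis(rel_b[:, None, :], idx, axis=-1)
    return _rowwise_scores(x.reshape(-1, n), y.reshape(-1, n), measure).reshape(c, n_bootstraps)


def _gaussian_two_sided_p(observed: np.ndarray, null_scores: np.ndarray) -> np.ndarray:
    """Two-sided p from a Gaussian fit (mean, sd) to the null scores.

    A hundred permutations cannot resolve empirical p below 0.01, so
    the null is summarised by its first two moments. Zero null variance
    yields p = 1.
    """
    mean = np.nanmean(null_scores, axis=-1)
    sd = np.nanstd(null_scores, axis=-1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, np.abs(observed - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(z)
    return np.minimum(p, 1.0)


def reboot_pvalue(
    table: CountTable,
    pair: tuple[str, str],
    measure: str,
    n_permutations: int = 100,
    seed: int = 0,
) -> tuple[float, str]:
    """Permutation p-value and direction for one OTU pair under one
    measure (single-edge convenience wrapper over the batched engine)."""
    rng = np.random.default_rng(seed)
    ia, ib = table.otu_ids.index(pair[0]), table.otu_ids.index(pair[1])
    counts = table.counts.astype(float)
    totals = counts.sum(axis=0)
    rel = counts / np.where(totals > 0, totals, 1.0)
    observed = _rowwise_scores(rel[[ia]], rel[[ib]], measure)[0]
    null = _null_scores_batch(
        counts[[ia]], counts[[ib]], rel[[ia]], rel[[ib]], totals, measure, n_permutations, rng
    )
    sd = float(np.nanstd(null, ddof=1))
    if sd == 0:
        logger.warning("zero null variance for %s under %s; p = 1", pair, measure)
        p = 1.0
    else:
        p = float(_gaussian_two_sided_p(np.array([observed]), null)[0])
    direction = _edge_direction(rel[ia], rel[ib], measure, observed)
    return p, direction


def _edge_direction(rel_a: np.ndarray, rel_b: np.ndarray, measure: str, score: float) -> str:
    """Co-presence vs mutual exclusion.

    Correlation measures carry their own sign; distance-type measures
    are unsigned, so the direction comes from the sign of the pair's
    Spearman correlation.
    """
    if measure in _CORRELATION_MEASURES:
        return "copresence" if score >= 0 else "exclusion"
    rho = _rowwise_scores(rel_a[None, :], rel_b[None, :], "spearman")[0]
    return "copresence" if (not np.isfinite(rho)) or rho >= 0 else "exclusion"


def bootstrap_stability(
    table: CountTable,
    pair: tuple[str, str],
    measure: str,
    n_bootstraps: int = 100,
    percentiles: tuple[float, float] = (2.5, 97.5),
    seed: int = 0,
) -> tuple[bool, tuple[float, float]]:
    """Whether the observed score lies inside the central bootstrap
    percentile interval for one OTU pair under one measure."""
    rng = np.random.default_rng(seed)
    ia, ib = table.otu_ids.index(pair[0]), table.otu_ids.index(pair[1])
    rel = table.relative_abundance().to_numpy()
    observed = _rowwise_scores(rel[[ia]], rel[[ib]], measure)[0]
    boot = _bootstrap_scores_batch(rel[[ia]], rel[[ib]], measure, n_bootstraps, rng)
    lo, hi = np.nanpercentile(boot[0], list(percentiles))
    return bool(lo <= observed <= hi), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Brown's method
# ---------------------------------------------------------------------------


def empirical_log_p_covariance(p_matrix: np.ndarray) -> np.ndarray:
    """Covariance of the -2 ln p transforms across measures, estimated
    empirically over candidate edges (pairwise-complete observations).

    Entries are clipped to [-4, 4], the theoretical range for
    chi-square(2) margins.
    """
    w = -2.0 * np.log(np.clip(p_matrix, 1e-300, 1.0))
    w = np.ma.masked_invalid(w)
    cov = np.ma.cov(w, rowvar=False, allow_masked=True)
    cov = np.asarray(cov.filled(0.0), dtype=float)
    return np.clip(cov, -4.0, 4.0)


def merge_pvalues_brown(
    pvalues, covariance: np.ndarray | None = None
) -> float:
    """Combine dependent p-values with Brown's method.

    Fisher's statistic X = -2 sum(ln p_i) is compared to a scaled
    chi-square c * chi2(df) with moments matched to E[X] = 2k and
    Var[X] = 4k + 2 sum_{i<j} cov(-2 ln p_i, -2 ln p_j). With zero
    covariance this reduces exactly to Fisher's method. NaN entries are
    ignored; a single valid p is returned unchanged.
    """
    p = np.asarray(pvalues, dtype=float)
    valid = np.where(np.isfinite(p))[0]
    if valid.size == 0:
        return float("nan")
    if valid.size == 1:
        return float(p[valid[0]])
    k = valid.size
    x = float(-2.0 * np.log(np.clip(p[valid], 1e-300, 1.0)).sum())
    expected = 2.0 * k
    var = 4.0 * k
    if covariance is not None:
        cov = np.asarray(covariance, dtype=float)
        for a in range(k):
            for b in range(a + 1, k):
                var += 2.0 * cov[valid[a], valid[b]]
    var = max(var, 1e-8)
    c = var / (2.0 * expected)
    df = 2.0 * expected**2 / var
    return float(stats.chi2.sf(x / c, df))


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


@dataclass
class MicrobialNetwork:
    """Result of the ensemble pipeline: retained graph and consortia."""

    graph: nx.Graph
    edges: pd.DataFrame
    clusters: list[set[str]] = field(default_factory=list)
    n_candidates: int = 0
    config: NetworkConfig | None = None

    @property
    def retained_edges(self) -> pd.DataFrame:
        if self.edges.empty:
            return self.edges
        return self.edges[self.edges["retained"]]

    def cluster_membership(self) -> pd.Series:
        out = {}
        for i, members in enumerate(self.clusters, start=1):
            for otu in members:
                out[otu] = f"cluster_{i}"
        return pd.Series(out, name="cluster")


def build_network(
    table: CountTable,
    kingdom: pd.Series | None = None,
    config: NetworkConfig | None = None,
) -> MicrobialNetwork:
    """Run the full ensemble co-occurrence pipeline on a merged table.

    Steps: low-count filter -> all-pairs scoring per measure -> initial
    candidate selection -> per measure-edge ReBoot permutation p and
    bootstrap stability (unstable measure-edges dropped) -> Brown merge
    with empirically estimated covariance -> BH-FDR -> retain edges with
    q < alpha and direction-consistent support >= min_support. Clusters
    are connected components of the retained graph. An empty network is
    a valid outcome.
    """
    config = config or NetworkConfig()
    rng = np.random.default_rng(config.seed)
    keep = table.otu_totals() >= config.min_otu_reads
    table = CountTable(table.df.loc[keep])
    ids = table.otu_ids
    if table.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    counts = table.counts.astype(float)
    totals = counts.sum(axis=0)
    rel = counts / np.where(totals > 0, totals, 1.0)

    score_mats = {m: score_matrix(rel, m) for m in config.measures}
    candidates = select_initial_edges(score_mats, ids, config)
    if not candidates:
        return MicrobialNetwork(nx.Graph(), pd.DataFrame(), [], 0, config)
    ai = np.array([a for a, _ in candidates])
    bi = np.array([b for _, b in candidates])
    n_edges = len(candidates)
    lo, hi = config.stability_percentiles

    p_mat = np.full((n_edges, len(config.measures)), np.nan)
    stable_mat = np.zeros((n_edges, len(config.measures)), dtype=bool)
    dir_mat = np.full((n_edges, len(config.measures)), "", dtype=object)
    spearman_sign = score_mats.get("spearman")
    if spearman_sign is None:
        spearman_sign = score_matrix(rel, "spearman")

    chunk = 256
    for mi, measure in enumerate(config.measures):
        observed_all = score_mats[measure][ai, bi]
        for start in range(0, n_edges, chunk):
            sl = slice(start, min(start + chunk, n_edges))
            ca, cb = ai[sl], bi[sl]
            obs = observed_all[sl]
            ok = np.isfinite(obs)
            if not ok.any():
                continue
            null = _null_scores_batch(
                counts[ca], counts[cb], rel[ca], rel[cb], totals,
                measure, config.n_permutations, rng,
            )
            pvals = _gaussian_two_sided_p(obs, null)
            sd = np.nanstd(null, axis=-1, ddof=1)
            pvals = np.where(sd > 0, pvals, 1.0)
            boot = _bootstrap_scores_batch(
                rel[ca], rel[cb], measure, config.n_bootstraps, rng
            )
            if np.isnan(boot).any():
                blo = np.nanpercentile(boot, lo, axis=-1)
                bhi = np.nanpercentile(boot, hi, axis=-1)
            else:
                blo, bhi = np.percentile(boot, [lo, hi], axis=-1)
            stable = (blo <= obs) & (obs <= bhi)
            rows = np.arange(sl.start, sl.stop)
            p_mat[rows[ok], mi] = pvals[ok]
            stable_mat[rows[ok], mi] = stable[ok]
            if measure in _CORRELATION_MEASURES:
                d = np.where(obs >= 0, "copresence", "exclusion")
            else:
                rho = spearman_sign[ca, cb]
                d = np.where(np.isnan(rho) | (rho >= 0), "copresence", "exclusion")
            dir_mat[rows[ok], mi] = d[ok]

    # unstable measure-edges carry no evidence forward
    p_use = np.where(stable_mat, p_mat, np.nan)
    cov = empirical_log_p_covariance(p_use)
    merged = np.array([merge_pvalues_brown(p_use[e], cov) for e in range(n_edges)])

    q = np.full(n_edges, np.nan)
    has_p = np.isfinite(merged)
    if has_p.any():
        q[has_p] = multipletests(merged[has_p], method="fdr_bh")[1]

    support = np.zeros(n_edges, dtype=int)
    consensus = np.full(n_edges, "", dtype=object)
    for e in range(n_edges):
        dirs = [dir_mat[e, m] for m in range(len(config.measures))
                if stable_mat[e, m] and np.isfinite(p_mat[e, m]) and dir_mat[e, m]]
        if not dirs:
            continue
        n_co = dirs.count("copresence")
        n_ex = dirs.count("exclusion")
        if n_co == n_ex:
            consensus[e] = "tie"
            continue
        consensus[e] = "copresence" if n_co > n_ex else "exclusion"
        support[e] = max(n_co, n_ex)

    retained = (
        has_p
        & (q < config.alpha)
        & (support >= config.min_support)
        & (consensus != "tie")
        & (consensus != "")
    )

    edge_rows = {
        "otu_a": [ids[a] for a in ai],
        "otu_b": [ids[b] for b in bi],
    }
    for mi, measure in enumerate(config.measures):
        edge_rows[f"score_{measure}"] = score_mats[measure][ai, bi]
        edge_rows[f"p_{measure}"] = p_mat[:, mi]
        edge_rows[f"stable_{measure}"] = stable_mat[:, mi]
    edge_rows["p_merged"] = merged
    edge_rows["q"] = q
    edge_rows["support"] = support
    edge_rows["direction"] = consensus
    edge_rows["retained"] = retained
    edges = pd.DataFrame(edge_rows)

    graph = nx.Graph()
    for otu in ids:
        graph.add_node(otu, kingdom=(kingdom.get(otu, "unknown") if kingdom is not None else "unknown"))
    for e in np.where(retained)[0]:
        graph.add_edge(
            ids[ai[e]], ids[bi[e]],
            direction=str(consensus[e]), q=float(q[e]), support=int(support[e]),
        )
    non_isolated = graph.edge_subgraph(graph.edges()).copy() if graph.number_of_edges() else nx.Graph()
    clusters = sorted(
        (set(c) for c in nx.connected_components(non_isolated)),
        key=lambda c: (-len(c), sorted(c)),
    )
    return MicrobialNetwork(graph, edges, clusters, n_edges, config)


def write_edge_list(network: MicrobialNetwork, path) -> None:
    network.edges.to_csv(path, sep="\t", index=False)


def write_gml(network: MicrobialNetwork, path) -> None:
    nx.write_gml(network.graph, str(path))


def cluster_abundance_profile(
    network: MicrobialNetwork,
    table: CountTable,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, GroupComparison | None]]:
    """Per-sample summed relative abundance of each cluster, compared
    across site x habitat groups with ANOVA + Tukey letters.

    Returns (profile, comparisons): profile is clusters x samples;
    comparisons maps cluster name to its GroupComparison (None when a
    group has too few replicates).
    """
    if not network.clusters:
        raise ValueError("network has no clusters")
    rel = table.relative_abundance()
    rows = {}
    for i, members in enumerate(network.clusters, start=1):
        present = [o for o in members if o in rel.index]
        rows[f"cluster_{i}"] = rel.loc[present].sum(axis=0)
    profile = pd.DataFrame(rows).T
    samples = [s for s in profile.columns if s in metadata.index]
    md = metadata.loc[samples]
    group = (md["site"].astype(str) + ":" + md["habitat"].astype(str)).rename("group")
    comparisons: dict[str, GroupComparison | None] = {}
    for cluster in profile.index:
        comparisons[cluster] = compare_groups(
            profile.loc[cluster, samples], group, "site:habitat", alpha=alpha
        )
    return profile, comparisons
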