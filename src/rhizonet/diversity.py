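"""Taxa aggregation, alpha diversity and grouped comparisons.

Alpha diversity follows the classic amplicon-survey pairing of the
Shannon index (here in bits, i.e. log base 2, with base e selectable)
and the Chao1 richness estimator (bias-corrected by default, classic
form selectable). Group comparisons use one-way ANOVA with a Tukey HSD
post hoc test summarised as a compact letter display, and two-group
habitat contrasts use Student's t-test with Benjamini-Hochberg FDR
correction across taxa.
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

from rhizonet.tables_io import RANKS, CountTable

logger = logging.getLogger(__name__)


def shannon(counts, base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log_base p_i over nonzero counts.

    Defaults to bits (base 2). Raises on an all-zero vector.
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("shannon requires at least one positive count")
    p = c / c.sum()
    return float(-(p * (np.log(p) / np.log(base))).sum())


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton/doubleton counts.

    Bias-corrected form (default): S_obs + F1 (F1 - 1) / (2 (F2 + 1)).
    Classic form: S_obs + F1^2 / (2 F2); when F2 = 0 the classic form
    falls back to the bias-corrected value, as is conventional.
    """
    c = np.asarray(counts)
    if not np.allclose(c, np.round(c)):
        raise ValueError("chao1 requires integer counts")
    c = c[c > 0].astype(np.int64)
    s_obs = c.size
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if bias_corrected or f2 == 0:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return s_obs + f1 * f1 / (2.0 * f2)


def observed_otus(counts) -> int:
    return int((np.asarray(counts) > 0).sum())


def alpha_diversity_table(table: CountTable, base: float = 2.0) -> pd.DataFrame:
    """Per-sample alpha metrics: shannon (bits by default), chao1
    (bias-corrected) and observed OTU richness."""
    rows = {}
    for sample in table.sample_ids:
        col = table.df[sample].to_numpy()
        rows[sample] = {
            "shannon": shannon(col, base=base),
            "chao1": chao1(col),
            "observed_otus": observed_otus(col),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def aggregate_by_rank(table: CountTable, taxonomy: pd.Series, rank: str) -> pd.DataFrame:
    """Sum counts by taxon label at ``rank`` and convert to per-sample
    proportions (columns sum to 1).

    OTUs lacking a label at the rank fall into an ``unidentified``
    bucket. Zero-total samples yield NaN proportions.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    level = RANKS.index(rank)
    labels = []
    for otu in table.otu_ids:
        lineage = taxonomy.get(otu, ())
        label = lineage[level] if len(lineage) > level and lineage[level] else "unidentified"
        labels.append(label)
    summed = table.df.groupby(pd.Series(labels, index=table.df.index)).sum()
    totals = summed.sum(axis=0)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        logger.warning("aggregate_by_rank: zero-total sample(s) %s -> NaN proportions", empty)
    return summed / totals.replace(0, np.nan)


@dataclass
class GroupComparison:
    """One-way ANOVA + Tukey HSD summary for a factor.

    ``letters`` is a compact letter display: two levels sharing at
    least one letter are *not* separated by Tukey HSD at ``alpha``.
    """

    factor: str
    levels: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    f_stat: float
    p_value: float
    letters: dict[str, str]
    alpha: float = 0.05
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)


def tukey_letters(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> tuple[dict[str, str], dict[tuple[str, str], float]]:
    """Compact letter display from Tukey HSD on the given groups.

    Builds the graph of level pairs Tukey does not separate at
    ``alpha`` and assigns one letter per maximal clique, ordered by
    descending clique mean (ties broken by level name).
    """
    levels = sorted(groups, key=lambda k: (-float(np.mean(groups[k])), k))
    if len(levels) == 1:
        return {levels[0]: "a"}, {}
    res = stats.tukey_hsd(*[np.asarray(groups[k], dtype=float) for k in levels])
    pairwise: dict[tuple[str, str], float] = {}
    g = nx.Graph()
    g.add_nodes_from(levels)
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            p = float(res.pvalue[i, j])
            pairwise[(levels[i], levels[j])] = p
            if not np.isfinite(p) or p >= alpha:
                g.add_edge(levels[i], levels[j])
    cliques = list(nx.find_cliques(g))
    cliques.sort(key=lambda c: (-float(np.mean([np.mean(groups[k]) for k in c])), sorted(c)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assigned: dict[str, list[str]] = {lv: [] for lv in levels}
    for idx, clique in enumerate(cliques):
        letter = alphabet[idx % len(alphabet)]
        for lv in clique:
            assigned[lv].append(letter)
    return {lv: "".join(sorted(set(ls))) for lv, ls in assigned.items()}, pairwise


def compare_groups(
    values: pd.Series, grouping: pd.Series, factor: str, alpha: float = 0.05
) -> GroupComparison | None:
    """ANOVA + Tukey letters for one response across factor levels.

    Returns None (with a warning) when any level has fewer than two
    replicates. Identical groups yield F = 0 and p = 1.
    """
    grouping = grouping.loc[values.index]
    groups = {str(lv): values[grouping == lv].to_numpy(dtype=float) for lv in grouping.unique()}
    small = [lv for lv, v in groups.items() if v.size < 2]
    if small:
        logger.warning("compare_groups(%s): levels with <2 replicates skipped: %s", factor, small)
        return None
    arrays = list(groups.values())
    if len(groups) < 2:
        lv = next(iter(groups))
        return GroupComparison(
            factor, [lv], {lv: float(np.mean(arrays[0]))}, {lv: float(np.std(arrays[0], ddof=1))},
            float("nan"), float("nan"), {lv: "a"}, alpha,
        )
    if all(np.allclose(a, arrays[0].mean()) for a in arrays):
        f_stat, p = 0.0, 1.0
        letters = {lv: "a" for lv in groups}
        pairwise = {}
    else:
        f_stat, p = stats.f_oneway(*arrays)
        letters, pairwise = tukey_letters(groups, alpha=alpha)
    return GroupComparison(
        factor=factor,
        levels=sorted(groups),
        means={lv: float(np.mean(v)) for lv, v in groups.items()},
        sds={lv: float(np.std(v, ddof=1)) for lv, v in groups.items()},
        f_stat=float(f_stat),
        p_value=float(p),
        letters=letters,
        alpha=alpha,
        pairwise_p=pairwise,
    )


def test_taxa_between_groups(
    rel_table: pd.DataFrame,
    metadata: pd.DataFrame,
    factor: str = "site",
    habitat_contrast: tuple[str, str] = ("rhizosphere", "bulk"),
    alpha: float = 0.05,
) -> tuple[dict[str, GroupComparison], pd.DataFrame]:
    """Per-taxon group tests on a relative-abundance table.

    For each taxon: one-way ANOVA + Tukey across ``factor`` levels, and
    within each site a two-sample Student's t-test between the two
    habitats of ``habitat_contrast``, with Benjamini-Hochberg FDR
    correction applied across taxa within each site.

    Returns
    -------
    (anova, ttests)
        ``anova`` maps taxon -> GroupComparison; ``ttests`` is a tidy
        frame with columns taxon, site, mean_<target>, mean_<reference>,
        t, p, q.
    """
    samples = [s for s in rel_table.columns if s in metadata.index]
    rel = rel_table[samples]
    md = metadata.loc[samples]
    anova: dict[str, GroupComparison] = {}
    for taxon in rel.index:
        cmp = compare_groups(rel.loc[taxon], md[factor].astype(str), factor, alpha=alpha)
        if cmp is not None:
            anova[taxon] = cmp
    rows = []
    target, reference = habitat_contrast
    if "habitat" in md.columns and "site" in md.columns:
        for site in sorted(md["site"].astype(str).unique()):
            in_site = md["site"].astype(str) == site
            a_ids = md.index[in_site & (md["habitat"] == target)]
            b_ids = md.index[in_site & (md["habitat"] == reference)]
            if len(a_ids) < 2 or len(b_ids) < 2:
                logger.warning("t-test skipped for site %s: <2 replicates in a habitat", site)
                continue
            site_rows = []
            for taxon in rel.index:
                a = rel.loc[taxon, a_ids].to_numpy(dtype=float)
                b = rel.loc[taxon, b_ids].to_numpy(dtype=float)
                if np.allclose(a, a.mean()) and np.allclose(b, b.mean()) and np.isclose(
                    a.mean(), b.mean()
                ):
                    t, p = 0.0, 1.0
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        t, p = stats.ttest_ind(a, b, equal_var=True)
                site_rows.append(
                    {
                        "taxon": taxon,
                        "site": site,
                        f"mean_{target}": float(a.mean()),
                        f"mean_{reference}": float(b.mean()),
                        "t": float(t),
                        "p": float(p),
                    }
                )
            pvals = np.array([r["p"] for r in site_rows])
            qvals = multipletests(pvals, method="fdr_bh")[1]
            for r, q in zip(site_rows, qvals):
                r["q"] = float(q)
            rows.extend(site_rows)
    ttests = pd.DataFrame(rows)
    return anova, ttests


def alpha_by_group(
    table: CountTable,
    metadata: pd.DataFrame,
    factor: str = "habitat",
    base: float = 2.0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, GroupComparison | None]]:
    """Per-sample alpha metrics plus ANOVA/Tukey across factor levels.

    An uneven-depth table is flagged (rarefy first for comparable
    richness estimates). With a single factor level the comparison is
    skipped and metrics are still returned.
    """
    totals = table.sample_totals()
    if totals.nunique() > 1:
        logger.info("alpha_by_group: sample totals unequal (%d..%d); consider rarefying",
                    totals.min(), totals.max())
    alpha_df = alpha_diversity_table(table, base=base)
    samples = [s for s in alpha_df.index if s in metadata.index]
    grouping = metadata.loc[samples, factor].astype(str)
    comparisons: dict[str, GroupComparison | None] = {}
    for metric in alpha_df.columns:
        if grouping.nunique() < 2:
            comparisons[metric] = None
            continue
        comparisons[metric] = compare_groups(
            alpha_df.loc[samples, metric], grouping, factor, alpha=alpha
        )
    return alpha_df, comparisons
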