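"""Rhizosphere-specific OTU detection and core-microbiome intersection.

An OTU is called *rhizosphere-specific* for a site when (1) it is
present in every rhizosphere replicate, (2) its summed count across the
rhizosphere replicates exceeds a read threshold, (3) its mean abundance
in the rhizosphere is at least ``fold_threshold`` times the reference
(bulk soil, or bulk + bare in the temporal design), and (4) a
two-sample Student's t-test between the habitats is significant.
OTUs entirely absent from the reference replicates are additionally
flagged *exclusive*; their fold change is computed against a small
pseudo-reference so it stays finite. The *core microbiome* is the
intersection of per-site specific sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from rhizonet.tables_io import CountTable

logger = logging.getLogger(__name__)


@dataclass
class SpecificityConfig:
    """Criteria for calling an OTU rhizosphere-specific.

    ``reference_mode`` selects the comparison baseline: ``"bulk"`` for
    the spatial (gradient) design, ``"bulk_plus_bare"`` for the
    temporal design where the reference is the pooled bulk and bare
    soil. ``strict_fold`` switches the fold criterion from ``>=`` to
    the strict ``>`` variant. ``fdr`` applies Benjamini-Hochberg
    correction to the per-OTU t-test p-values (off by default: the
    criterion is a per-OTU p < alpha).
    """

    min_replicates_present: int = 3
    min_group_total_reads: int = 20
    fold_threshold: float = 3.0
    alpha: float = 0.05
    reference_mode: str = "bulk"
    pseudo_reference: float = 0.5
    strict_fold: bool = False
    fdr: bool = False

    def __post_init__(self):
        if self.fold_threshold <= 0:
            raise ValueError("fold_threshold must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.reference_mode not in ("bulk", "bulk_plus_bare"):
            raise ValueError(f"unknown reference_mode {self.reference_mode!r}")
        if self.pseudo_reference <= 0:
            raise ValueError("pseudo_reference must be > 0")


def _reference_samples(md: pd.DataFrame, config: SpecificityConfig) -> pd.Index:
    if config.reference_mode == "bulk_plus_bare":
        ref = md.index[md["habitat"].isin(["bulk", "bare"])]
        if not (md["habitat"] == "bare").any():
            logger.warning("no bare-soil samples; reference falls back to bulk only")
        return ref
    return md.index[md["habitat"] == "bulk"]


def specificity_records(
    table: CountTable,
    metadata: pd.DataFrame,
    site: str,
    config: SpecificityConfig | None = None,
) -> pd.DataFrame:
    """Per-OTU specificity report for one site.

    Only OTUs detected in the site (any count in rhizosphere or
    reference samples) are reported. Columns: mean_target,
    mean_reference, fold_change, t_p (q when FDR is enabled),
    n_present, group_total, specific, exclusive.
    """
    config = config or SpecificityConfig()
    md = metadata.loc[[s for s in table.sample_ids if s in metadata.index]]
    md = md[md["site"].astype(str) == str(site)]
    target_ids = md.index[md["habitat"] == "rhizosphere"]
    ref_ids = _reference_samples(md, config)
    if len(target_ids) == 0 or len(ref_ids) == 0:
        raise ValueError(f"site {site!r} lacks rhizosphere or reference samples")
    t_ok = len(target_ids) >= 2 and len(ref_ids) >= 2
    if not t_ok:
        logger.warning(
            "site %s: <2 replicates in a habitat; t-test undefined, no OTU can be "
            "flagged specific", site,
        )
    tgt = table.df[list(target_ids)]
    ref = table.df[list(ref_ids)]
    rows = []
    for otu in table.otu_ids:
        a = tgt.loc[otu].to_numpy(dtype=float)
        b = ref.loc[otu].to_numpy(dtype=float)
        if a.sum() == 0 and b.sum() == 0:
            continue
        mean_t, mean_r = float(a.mean()), float(b.mean())
        denom = mean_r if mean_r > 0 else config.pseudo_reference
        fold = mean_t / denom
        n_present = int((a > 0).sum())
        group_total = int(a.sum())
        exclusive = bool(b.sum() == 0) and group_total > 0
        if t_ok and not (np.allclose(a, a.mean()) and np.allclose(b, b.mean())
                         and np.isclose(a.mean(), b.mean())):
            with warnings.catch_warnings():
                # near-constant replicate vectors trip scipy's precision
                # warning; the resulting p is still the right contract
                warnings.simplefilter("ignore", RuntimeWarning)
                _, t_p = stats.ttest_ind(a, b, equal_var=True)
            t_p = float(t_p)
        elif t_ok:
            t_p = 1.0
        else:
            t_p = float("nan")
        rows.append(
            {
                "otu_id": otu,
                "mean_target": mean_t,
                "mean_reference": mean_r,
                "fold_change": fold,
                "t_p": t_p,
                "n_present": n_present,
                "group_total": group_total,
                "exclusive": exclusive,
            }
        )
    rec = pd.DataFrame(rows).set_index("otu_id") if rows else pd.DataFrame(
        columns=["mean_target", "mean_reference", "fold_change", "t_p",
                 "n_present", "group_total", "exclusive"]
    )
    if rec.empty:
        rec["specific"] = pd.Series(dtype=bool)
        return rec
    pcol = rec["t_p"].to_numpy()
    if config.fdr and t_ok:
        finite = np.isfinite(pcol)
        q = np.full_like(pcol, np.nan)
        q[finite] = multipletests(pcol[finite], method="fdr_bh")[1]
        rec["q"] = q
        pcol = q
    n_reps = min(config.min_replicates_present, len(target_ids))
    fold_ok = (
        rec["fold_change"] > config.fold_threshold
        if config.strict_fold
        else rec["fold_change"] >= config.fold_threshold
    )
    rec["specific"] = (
        (rec["n_present"] >= n_reps)
        & (rec["group_total"] > config.min_group_total_reads)
        & fold_ok
        & (pcol < config.alpha)
    )
    return rec


@dataclass
class CoreMicrobiomeResult:
    """Per-site specific sets, their global intersection and Venn regions."""

    per_site: dict[str, set[str]]
    core: set[str]
    venn_regions: dict[frozenset[str], int]

    def venn_table(self) -> pd.DataFrame:
        rows = [
            {"sites": "&".join(sorted(k)), "n_otus": v}
            for k, v in sorted(self.venn_regions.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows)


def venn_region_counts(sets: dict[str, set[str]]) -> dict[frozenset[str], int]:
    """Exclusive region sizes of the Venn diagram over the given sets.

    The region keyed by a site combination counts elements in *all* of
    those sets and in *none* of the others (2^k - 1 regions).
    """
    names = sorted(sets)
    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set.union(set(), *(sets[c] for c in names if c not in combo))
            regions[frozenset(combo)] = len(inside - outside)
    return regions


def core_microbiome(per_site_specific: dict[str, set[str]]) -> CoreMicrobiomeResult:
    """Intersect per-site specific OTU sets into the core microbiome."""
    if not per_site_specific:
        raise ValueError("need at least one site")
    sets = {str(k): set(v) for k, v in per_site_specific.items()}
    core = set.intersection(*sets.values())
    return CoreMicrobiomeResult(
        per_site=sets, core=core, venn_regions=venn_region_counts(sets)
    )


def temporal_overlap(
    active_specific: set[str],
    active_table: CountTable,
    dormant_table: CountTable,
) -> pd.DataFrame:
    """Overlap between the active-rhizosphere specific OTUs and the full
    dormant-rhizosphere community, with percent abundance change.

    The active side contributes only its specifically enriched OTUs;
    the dormant side contributes every OTU present. Percent change is
    computed on mean relative abundances (dormant vs active), so -99
    means the OTU fell to 1% of its active relative abundance.
    """
    dormant_present = set(
        dormant_table.df.index[dormant_table.df.sum(axis=1) > 0]
    )
    shared = sorted(active_specific & dormant_present)
    act_rel = active_table.relative_abundance()
    dor_rel = dormant_table.relative_abundance()
    rows = []
    for otu in shared:
        a = float(act_rel.loc[otu].mean()) if otu in act_rel.index else 0.0
        d = float(dor_rel.loc[otu].mean())
        change = (d - a) / a * 100.0 if a > 0 else float("nan")
        rows.append(
            {"otu_id": otu, "active_mean_rel": a, "dormant_mean_rel": d,
             "pct_change": change}
        )
    return pd.DataFrame(rows).set_index("otu_id") if rows else pd.DataFrame(
        columns=["active_mean_rel", "dormant_mean_rel", "pct_change"]
    )
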