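"""Synthetic OTU tables with planted, recoverable structure.

The generator emulates the sampling design of a multi-site
rhizosphere/soil survey: a handful of sites, two to three habitats per
site (rhizosphere, bulk soil, bare soil), three replicates per cell.
Counts follow a compositional model: each OTU has a log-normal latent
abundance with per-site offsets and per-sample noise, sequencing depth
is log-normal, and reads are drawn multinomially, so every artifact of
compositionality the analysis must cope with is present. Two kinds of
structure can be planted and are reported as ground truth:
rhizosphere-enriched OTUs (latent abundance multiplied by a fold in
rhizosphere samples) and correlated consortia (members share a latent
Gaussian factor scaled to a target correlation; mutual exclusion is
planted by negating the factor for half of the members).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from rhizonet.tables_io import CountTable

#: consortium spec: (size, latent correlation, direction, kingdom-kind)
ConsortiumSpec = tuple


@dataclass
class SyntheticConfig:
    """Study-design and noise parameters of the generator.

    Scales are log-natural: ``base_log_sd`` spreads OTU mean abundances
    over roughly two orders of magnitude at the default 1.0;
    ``site_effect_sd`` (per OTU x site) and ``noise_sd`` (per OTU x
    sample) control between-site structure and replicate scatter. The
    default ``noise_sd`` of 0.10 reflects composite field replicates
    (each replicate pooling many individual plants averages out
    plant-to-plant variation); ``depth_log_mean`` = ln(10^4) with a
    0.10 log-sd matches a depth-balanced amplicon run after quality
    filtering. Enriched OTUs are drawn from a sub-dominant abundance
    band (see :func:`_draw_enriched`): specifically rhizosphere-
    enriched taxa are modest community members, which keeps the
    compositional squeeze of the realized fold (enrichment inflates
    rhizosphere totals, deflating everyone's relative abundance) small. ``planted_consortia`` entries are
    ``(size, rho, direction[, kind])`` with direction ``"copresence"``
    or ``"exclusion"`` and kind ``"fungal"``, ``"bacterial"`` or
    ``"mixed"``.
    """

    sites: tuple[str, ...] = ("QS", "EA", "PA")
    habitats: tuple[str, ...] = ("rhizosphere", "bulk")
    replicates: int = 3
    n_fungal_otus: int = 100
    n_bacterial_otus: int = 300
    depth_log_mean: float = float(np.log(10_000))
    depth_log_sd: float = 0.10
    base_log_sd: float = 0.8
    site_effect_sd: float = 1.0
    noise_sd: float = 0.10
    consortium_sd: float = 1.0
    planted_enriched: int = 20
    enrichment_fold: float = 5.0
    planted_consortia: tuple[ConsortiumSpec, ...] = (
        (8, 0.9, "copresence", "bacterial"),
        (8, 0.9, "copresence", "fungal"),
        (8, 0.9, "copresence", "mixed"),
    )
    year: int = 2015
    year_effect_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1 or self.n_fungal_otus < 1 or self.n_bacterial_otus < 1:
            raise ValueError("counts must be positive")
        if self.enrichment_fold <= 0:
            raise ValueError("enrichment_fold must be > 0")
        for spec in self.planted_consortia:
            size, rho = spec[0], spec[1]
            if abs(rho) > 1:
                raise ValueError(f"|latent correlation| must be <= 1, got {rho}")
            if size < 2:
                raise ValueError("consortium size must be >= 2")


@dataclass
class GroundTruth:
    """Planted structure of a generated dataset."""

    enriched: dict[str, float]  # otu id -> fold
    consortia: list[dict] = field(default_factory=list)

    def edges(self) -> list[tuple[str, str, str]]:
        """All planted pairs: within-sign pairs are co-presence, pairs
        across the sign split of an exclusion consortium are
        exclusions."""
        out = []
        for cons in self.consortia:
            members = cons["members"]
            signs = cons["signs"]
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    a, b = sorted((members[i], members[j]))
                    d = "copresence" if signs[i] == signs[j] else "exclusion"
                    out.append((a, b, d))
        return out


def _draw_enriched(
    all_ids: list[str], mu: np.ndarray, n: int, rng: np.random.Generator
) -> list[str]:
    """Pick enrichment targets from a sub-dominant abundance band.

    Enriched OTUs are drawn from the 25th-55th percentile of base
    abundance: abundant enough to be detected at realistic depth, but
    small enough that multiplying them leaves the composition of the
    rest of the community nearly unchanged.
    """
    if n == 0:
        return []
    lo, hi = np.quantile(mu, [0.25, 0.55])
    pool = [o for o, m in zip(all_ids, mu) if lo <= m <= hi]
    if len(pool) < n:
        pool = list(all_ids)
    return sorted(rng.choice(pool, size=min(n, len(pool)), replace=False).tolist())


def _assign_consortia(
    config: SyntheticConfig,
    fungal_ids: list[str],
    bacterial_ids: list[str],
    taken: set[str],
    rng: np.random.Generator,
) -> list[dict]:
    consortia = []
    for spec in config.planted_consortia:
        size, rho, direction = spec[0], float(spec[1]), spec[2]
        kind = spec[3] if len(spec) > 3 else "mixed"
        if kind == "fungal":
            pool = [o for o in fungal_ids if o not in taken]
        elif kind == "bacterial":
            pool = [o for o in bacterial_ids if o not in taken]
        else:
            pool = [o for o in fungal_ids + bacterial_ids if o not in taken]
        if len(pool) < size:
            raise ValueError(f"not enough free OTUs for a {kind} consortium of {size}")
        members = sorted(rng.choice(pool, size=size, replace=False).tolist())
        taken.update(members)
        if direction == "exclusion":
            signs = [1] * (size // 2) + [-1] * (size - size // 2)
        else:
            signs = [1] * size
        consortia.append(
            {"members": members, "rho": rho, "direction": direction,
             "kind": kind, "signs": signs}
        )
    return consortia


def generate_dataset(
    config: SyntheticConfig | None = None,
) -> tuple[CountTable, CountTable, pd.DataFrame, GroundTruth]:
    """Draw one synthetic survey.

    Returns (fungal table, bacterial table, metadata, ground truth).
    Sample ids are ``{site}.{habitat}.{replicate}``; metadata carries
    site, habitat, year and replicate. Fully reproducible under
    ``config.seed``.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    fungal_ids = [f"F_otu{i:04d}" for i in range(config.n_fungal_otus)]
    bacterial_ids = [f"B_otu{i:04d}" for i in range(config.n_bacterial_otus)]
    all_ids = fungal_ids + bacterial_ids
    n_otus = len(all_ids)
    n_sites = len(config.sites)

    mu = rng.normal(0.0, config.base_log_sd, n_otus)
    site_eff = rng.normal(0.0, config.site_effect_sd, (n_otus, n_sites))

    taken: set[str] = set()
    enriched_ids = _draw_enriched(
        all_ids, mu, min(config.planted_enriched, n_otus), rng
    )
    taken.update(enriched_ids)
    consortia = _assign_consortia(config, fungal_ids, bacterial_ids, taken, rng)

    idx = {o: i for i, o in enumerate(all_ids)}
    enriched_idx = np.array([idx[o] for o in enriched_ids], dtype=int)
    cons_idx = [np.array([idx[o] for o in c["members"]], dtype=int) for c in consortia]
    cons_signs = [np.array(c["signs"], dtype=float) for c in consortia]
    is_member = np.zeros(n_otus, dtype=bool)
    for ci in cons_idx:
        is_member[ci] = True

    log_fold = np.log(config.enrichment_fold)
    samples, columns = [], {}
    meta_rows = []
    for s, site in enumerate(config.sites):
        for habitat in config.habitats:
            for rep in range(1, config.replicates + 1):
                sid = f"{site}.{habitat}.{rep}"
                latent = mu + site_eff[:, s] + rng.normal(0.0, config.noise_sd, n_otus)
                # consortium members: shared factor replaces the
                # independent site/noise variation so the pairwise latent
                # correlation hits the target exactly
                for ci, signs, cons in zip(cons_idx, cons_signs, consortia):
                    g = rng.normal()
                    e = rng.normal(size=ci.size)
                    rho = cons["rho"]
                    latent[ci] = mu[ci] + config.consortium_sd * signs * (
                        np.sqrt(rho) * g + np.sqrt(1.0 - rho) * e
                    )
                if habitat == "rhizosphere":
                    latent[enriched_idx] += log_fold
                weights = np.exp(latent)
                p = weights / weights.sum()
                depth = int(np.round(rng.lognormal(config.depth_log_mean, config.depth_log_sd)))
                columns[sid] = rng.multinomial(depth, p)
                samples.append(sid)
                meta_rows.append(
                    {"sample_id": sid, "site": site, "habitat": habitat,
                     "year": config.year, "replicate": rep}
                )

    table = pd.DataFrame(columns, index=all_ids)
    fungal = CountTable(table.loc[fungal_ids])
    bacterial = CountTable(table.loc[bacterial_ids])
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = GroundTruth(
        enriched={o: config.enrichment_fold for o in enriched_ids},
        consortia=consortia,
    )
    return fungal, bacterial, metadata, truth


def generate_temporal_dataset(
    config: SyntheticConfig | None = None,
) -> tuple[CountTable, CountTable, pd.DataFrame, GroundTruth]:
    """Two-year variant at a single site: a rainy year with an active,
    enriched rhizosphere and a dry year where the dormant rhizosphere
    reverts to the bulk-soil profile and every OTU receives a random
    year offset of sd ``year_effect_sd``.

    The site is ``config.sites[0]``; habitats default to rhizosphere,
    bulk and bare soil.
    """
    if config is None:
        config = SyntheticConfig(habitats=("rhizosphere", "bulk", "bare"))
    site = config.sites[0]
    rng = np.random.default_rng(config.seed)
    fungal_ids = [f"F_otu{i:04d}" for i in range(config.n_fungal_otus)]
    bacterial_ids = [f"B_otu{i:04d}" for i in range(config.n_bacterial_otus)]
    all_ids = fungal_ids + bacterial_ids
    n_otus = len(all_ids)

    mu = rng.normal(0.0, config.base_log_sd, n_otus)
    year_off = rng.normal(0.0, config.year_effect_sd, n_otus)
    taken: set[str] = set()
    enriched_ids = _draw_enriched(
        all_ids, mu, min(config.planted_enriched, n_otus), rng
    )
    taken.update(enriched_ids)
    consortia = _assign_consortia(config, fungal_ids, bacterial_ids, taken, rng)
    idx = {o: i for i, o in enumerate(all_ids)}
    enriched_idx = np.array([idx[o] for o in enriched_ids], dtype=int)
    cons_idx = [np.array([idx[o] for o in c["members"]], dtype=int) for c in consortia]
    cons_signs = [np.array(c["signs"], dtype=float) for c in consortia]

    log_fold = np.log(config.enrichment_fold)
    columns, meta_rows = {}, []
    for year, is_dry in ((config.year, False), (config.year + 1, True)):
        for habitat in config.habitats:
            for rep in range(1, config.replicates + 1):
                sid = f"Y{year}.{site}.{habitat}.{rep}"
                latent = mu + rng.normal(0.0, config.noise_sd, n_otus)
                for ci, signs, cons in zip(cons_idx, cons_signs, consortia):
                    g = rng.normal()
                    e = rng.normal(size=ci.size)
                    rho = cons["rho"]
                    latent[ci] = mu[ci] + config.consortium_sd * signs * (
                        np.sqrt(rho) * g + np.sqrt(1.0 - rho) * e
                    )
                if is_dry:
                    # dormant rhizosphere: no plant-driven enrichment,
                    # community shifted by the per-OTU year offset
                    latent += year_off
                elif habitat == "rhizosphere":
                    latent[enriched_idx] += log_fold
                weights = np.exp(latent)
                depth = int(np.round(rng.lognormal(config.depth_log_mean, config.depth_log_sd)))
                columns[sid] = rng.multinomial(depth, weights / weights.sum())
                meta_rows.append(
                    {"sample_id": sid, "site": site, "habitat": habitat,
                     "year": year, "replicate": rep}
                )

    table = pd.DataFrame(columns, index=all_ids)
    fungal = CountTable(table.loc[fungal_ids])
    bacterial = CountTable(table.loc[bacterial_ids])
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = GroundTruth(
        enriched={o: config.enrichment_fold for o in enriched_ids},
        consortia=consortia,
    )
    return fungal, bacterial, metadata, truth


def generate_tree(otu_ids, seed: int = 0, branch_scale: float = 0.5) -> TreeNode:
    """Random rooted bifurcating tree over the given ids with
    exponential branch lengths; deterministic under ``seed``."""
    ids = list(otu_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate OTU ids")
    if len(ids) < 2:
        raise ValueError("need at least 2 ids")
    rng = np.random.default_rng(seed)
    nodes = []
    for name in ids:
        leaf = TreeNode(name=name)
        leaf.length = float(rng.exponential(branch_scale))
        nodes.append(leaf)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.exponential(branch_scale))
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root
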