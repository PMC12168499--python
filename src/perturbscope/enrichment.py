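"""Credible-set overlap, sampled overlap nulls, partitioned heritability
ratios, constraint ECDFs, and a simplified trait-relevance score.

A variant "overlaps" a region by point containment of its position in a
0-based half-open interval; PIPs are not used for overlap.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from perturbscope.errors import ValidationError
from perturbscope.io import FeatureMatrix

logger = logging.getLogger(__name__)


def _positions_in_regions(pos: np.ndarray, regions: pd.DataFrame) -> np.ndarray:
    """Boolean mask: position falls inside some region (single chromosome
    or pre-filtered; regions must be sorted, non-overlapping)."""
    if len(regions) == 0:
        return np.zeros(len(pos), dtype=bool)
    starts = regions["start"].to_numpy()
    ends = regions["end"].to_numpy()
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    # running max of ends handles overlapping regions correctly
    cummax_end = np.maximum.accumulate(ends)
    j = np.searchsorted(starts, pos, side="right") - 1
    ok = j >= 0
    out = np.zeros(len(pos), dtype=bool)
    out[ok] = pos[ok] < cummax_end[j[ok]]
    return out


def credible_set_overlap(cs: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Percent of credible sets with >= 1 variant inside >= 1 region, per trait."""
    if len(cs) == 0:
        raise ValidationError("empty credible set table")
    hits = np.zeros(len(cs), dtype=bool)
    for chrom, idx in cs.groupby("chrom").groups.items():
        sub = regions[regions["chrom"] == chrom] if "chrom" in regions.columns else regions
        loc = cs.index.get_indexer(idx)
        hits[loc] = _positions_in_regions(cs.loc[idx, "pos"].to_numpy(), sub)
    tmp = cs.assign(_hit=hits)
    per_set = tmp.groupby(["trait", "set_id"])["_hit"].any()
    per_trait = per_set.groupby("trait").agg(["sum", "size"])
    per_trait["pct_overlap"] = 100.0 * per_trait["sum"] / per_trait["size"]
    out = per_trait.reset_index().rename(columns={"sum": "n_overlapping", "size": "n_sets"})
    return out[["trait", "n_overlapping", "n_sets", "pct_overlap"]]


def sampled_overlap_null(cs: pd.DataFrame, n_regions: int, n_samples: int = 100,
                         matching: str = "length", pool: pd.DataFrame | None = None,
                         target_lengths=None, genome_length_bp: int | None = None,
                         seed: int = 0) -> dict:
    """Null distribution of the mean per-trait overlap percent.

    matching="length": sample ``n_regions`` intervals from ``pool`` whose
    lengths are within +/-20% of the target lengths. matching="pool":
    sample uniformly from the pool. matching="random": place intervals of
    the target lengths uniformly on the genome.
    """
    rng = np.random.default_rng(seed)
    if matching in ("length", "pool"):
        if pool is None or len(pool) < n_regions:
            raise ValidationError("candidate pool smaller than n_regions")
        pool_lengths = (pool["end"] - pool["start"]).to_numpy()
    if matching == "random" and genome_length_bp is None:
        raise ValidationError("matching='random' requires genome_length_bp")
    if matching in ("length", "random"):
        if target_lengths is None:
            raise ValidationError(f"matching={matching!r} requires target_lengths")
        target_lengths = np.asarray(target_lengths)

    vals = []
    for _ in range(n_samples):
        if matching == "pool":
            idx = rng.choice(len(pool), size=n_regions, replace=False)
            sampled = pool.iloc[idx]
        elif matching == "length":
            lens = rng.choice(target_lengths, size=n_regions, replace=True)
            rows = []
            for L in lens:
                ok = np.flatnonzero(np.abs(pool_lengths - L) <= 0.2 * L)
                if len(ok) == 0:
                    ok = np.arange(len(pool))
                rows.append(int(rng.choice(ok)))
            sampled = pool.iloc[rows]
        else:  # random genomic placement
            lens = rng.choice(target_lengths, size=n_regions, replace=True)
            starts = rng.integers(0, np.maximum(genome_length_bp - lens, 1))
            sampled = pd.DataFrame({
                "chrom": "chrS", "start": starts, "end": starts + lens,
            })
        ov = credible_set_overlap(cs, sampled)
        vals.append(float(ov["pct_overlap"].mean()))
    vals = np.asarray(vals)
    sd = float(vals.std(ddof=1)) if n_samples > 1 else float("nan")
    return {"null_mean": float(vals.mean()), "null_sd": sd, "samples": vals}


def heritability_enrichment(h2: pd.DataFrame, category_mask) -> dict:
    """Enrichment = (share of h2 in category) / (share of SNPs in category)."""
    mask = np.asarray(category_mask, dtype=bool)
    if mask.shape[0] != len(h2):
        raise ValidationError("category mask length != number of SNPs")
    if not mask.any():
        raise ValidationError("empty SNP category")
    total = float(h2["h2_contribution"].sum())
    if total <= 0:
        raise ValidationError("total heritability must be positive")
    prop_h2 = float(h2.loc[mask, "h2_contribution"].sum()) / total
    prop_snps = float(mask.sum()) / len(h2)
    return {
        "enrichment": prop_h2 / prop_snps,
        "pct_snps": 100.0 * prop_snps,
        "pct_h2": 100.0 * prop_h2,
    }


def constraint_ecdf(records: pd.DataFrame, min_records: int = 10) -> dict:
    """Per-category ECDF on the pooled score grid plus pairwise KS tests.

    ``records`` needs columns ``score`` and ``category``. Categories with
    fewer than 2 records are excluded with a log message.
    """
    cats = {}
    for cat, grp in records.groupby("category"):
        if len(grp) < 2:
            logger.info("constraint_ecdf: category %r has <2 records; excluded", cat)
            continue
        cats[cat] = np.sort(grp["score"].to_numpy(dtype=float))
    if len(cats) < 2 or any(len(v) < min_records for v in cats.values()):
        raise ValidationError(f"need >= 2 categories with >= {min_records} records each")
    grid = np.unique(np.concatenate(list(cats.values())))
    ecdf = {cat: np.searchsorted(v, grid, side="right") / len(v) for cat, v in cats.items()}
    names = sorted(cats)
    ks_rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = stats.ks_2samp(cats[a], cats[b])
            ks_rows.append({"cat_a": a, "cat_b": b,
                            "ks_stat": float(res.statistic), "p": float(res.pvalue)})
    return {"grid": grid, "ecdf": ecdf, "ks": pd.DataFrame(ks_rows)}


def trait_relevance_score(atac: FeatureMatrix, trait_peaks, n_background: int = 50,
                          seed: int = 0, n_deciles: int = 10) -> pd.DataFrame:
    """Simplified deviation-style trait relevance score.

    Per cell: observed fraction of counts in trait peaks, minus the mean
    over ``n_background`` accessibility-matched random peak sets of equal
    size, divided by their SD. Matching is by decile of total peak counts.
    """
    trait_peaks = list(trait_peaks)
    if not trait_peaks:
        raise ValidationError("empty trait peak set")
    if n_background <= 0:
        raise ValidationError("n_background must be positive")
    fidx = atac.feature_index()
    missing = [p for p in trait_peaks if p not in fidx]
    if missing:
        raise ValidationError(f"trait peaks absent from matrix: {missing[:5]}")
    rng = np.random.default_rng(seed)
    counts = np.asarray(atac.counts.todense(), dtype=float)
    cell_tot = counts.sum(axis=1)
    cell_tot[cell_tot == 0] = 1.0
    peak_tot = counts.sum(axis=0)
    dec = pd.qcut(peak_tot, n_deciles, labels=False, duplicates="drop")
    dec = np.asarray(dec)
    cols = np.array([fidx[p] for p in trait_peaks])
    obs = counts[:, cols].sum(axis=1) / cell_tot

    pools = {d: np.flatnonzero(dec == d) for d in np.unique(dec)}
    trait_dec = dec[cols]
    bg = np.empty((n_background, atac.n_cells))
    for s in range(n_background):
        drawn = np.concatenate([
            rng.choice(pools[d], size=int((trait_dec == d).sum()), replace=True)
            for d in np.unique(trait_dec)
        ])
        bg[s] = counts[:, drawn].sum(axis=1) / cell_tot
    mu = bg.mean(axis=0)
    sd = bg.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return pd.DataFrame({"cell": atac.barcodes, "trs": (obs - mu) / sd})
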