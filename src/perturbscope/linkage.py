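"""ACR-gene pair enumeration, single-cell correlation, and enrichment
against CRISPRi-validated links, TADs, and ChIP-seq peak proximity.

Peak "position" is the integer midpoint floor((start+end)/2). A pair is
"in TAD" when the peak center and the gene TSS fall strictly inside the
same TAD interval (half-open containment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from perturbscope.errors import ValidationError
from perturbscope.io import FeatureMatrix
from perturbscope.scoring import normalize

logger = logging.getLogger(__name__)


@dataclass
class OddsResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    table: tuple          # (a, b, c, d)
    degenerate: bool = False


def peak_centers(peaks: pd.DataFrame) -> np.ndarray:
    return ((peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2).astype(np.int64)


def enumerate_pairs(peaks: pd.DataFrame, genes: pd.DataFrame,
                    max_distance: int = 50_000) -> pd.DataFrame:
    """All (acr, gene) pairs with |peak center - TSS| <= max_distance.

    Distance is signed by gene strand: upstream of the TSS is negative.
    """
    if len(peaks) == 0 or len(genes) == 0:
        raise ValidationError("peaks and genes must be non-empty")
    rows = []
    for chrom, pk in peaks.groupby("chrom"):
        gn = genes[genes["chrom"] == chrom]
        if gn.empty:
            continue
        centers = peak_centers(pk)
        order = np.argsort(centers)
        centers_s = centers[order]
        names_s = pk["name"].to_numpy()[order]
        tss = gn["tss"].to_numpy()
        strand = gn["strand"].to_numpy()
        gids = gn["gene_id"].to_numpy()
        lo = np.searchsorted(centers_s, tss - max_distance, side="left")
        hi = np.searchsorted(centers_s, tss + max_distance, side="right")
        for g in range(len(gn)):
            for j in range(lo[g], hi[g]):
                rel = int(centers_s[j] - tss[g])
                if strand[g] == "-":
                    rel = -rel
                rows.append((names_s[j], gids[g], rel))
    out = pd.DataFrame(rows, columns=["acr", "gene", "distance"])
    return out.sort_values(["gene", "distance"], kind="stable").reset_index(drop=True)


def pair_correlation(rna: FeatureMatrix, atac: FeatureMatrix, guides: pd.DataFrame,
                     pairs: pd.DataFrame, min_nt_cells: int = 20) -> pd.DataFrame:
    """Spearman rho between normalized accessibility and expression across
    NT control cells, for each pair. Zero-variance members give NaN."""
    nt = (guides["target_class"] == "NT").to_numpy()
    if nt.sum() < min_nt_cells:
        raise ValidationError(f"need >= {min_nt_cells} NT cells, have {int(nt.sum())}")
    Xr = normalize(rna)[nt]
    Xa = normalize(atac)[nt]
    g_idx = rna.feature_index()
    p_idx = atac.feature_index()
    # rank once per feature actually used
    used_genes = {g: stats.rankdata(Xr[:, g_idx[g]]) for g in pairs["gene"].unique()}
    used_acrs = {p: stats.rankdata(Xa[:, p_idx[p]]) for p in pairs["acr"].unique()}
    n = int(nt.sum())
    rhos = np.empty(len(pairs))
    for i, (acr, gene) in enumerate(zip(pairs["acr"], pairs["gene"])):
        ra, rg = used_acrs[acr], used_genes[gene]
        if np.ptp(ra) == 0 or np.ptp(rg) == 0:
            rhos[i] = np.nan
            continue
        rhos[i] = np.corrcoef(ra, rg)[0, 1]
    out = pairs.copy()
    out["rho"] = rhos
    n_missing = int(np.isnan(rhos).sum())
    if n_missing:
        logger.info("pair_correlation: %d pairs with zero-variance member (rho missing)", n_missing)
    return out


def flag_pair_sensitivity(pairs: pd.DataFrame, st: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Mark pairs where both the ACR and the gene are sensitive to the
    same TF (q < alpha in the ATAC and RNA strata respectively)."""
    sens_acr = st[(st["modality"] == "ATAC") & st["sensitive"]].groupby("feature")["tf"].agg(set)
    sens_gene = st[(st["modality"] == "RNA") & st["sensitive"]].groupby("feature")["tf"].agg(set)
    out = pairs.copy()
    acr_tfs = out["acr"].map(sens_acr)
    gene_tfs = out["gene"].map(sens_gene)
    shared = [
        (a & g) if isinstance(a, set) and isinstance(g, set) else set()
        for a, g in zip(acr_tfs, gene_tfs)
    ]
    out["acr_sensitive"] = [isinstance(a, set) and len(a) > 0 for a in acr_tfs]
    out["gene_sensitive"] = [isinstance(g, set) and len(g) > 0 for g in gene_tfs]
    out["pair_sensitive"] = [len(s) > 0 for s in shared]
    out["shared_tfs"] = [",".join(sorted(s)) for s in shared]
    return out


def _sample_or(a: int, b: int, c: int, d: int) -> tuple:
    """Sample odds ratio with Haldane-Anscombe correction for the CI when
    any cell is zero. Returns (or, ci_low, ci_high, degenerate)."""
    degenerate = min(a, b, c, d) == 0
    if b * c == 0:
        or_point = np.inf if a * d > 0 else (0.0 if (a == 0 or d == 0) else np.nan)
    else:
        or_point = (a * d) / (b * c)
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if degenerate else (a, b, c, d)
    log_or = np.log((aa * dd) / (bb * cc))
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    lo, hi = np.exp(log_or - 1.96 * se), np.exp(log_or + 1.96 * se)
    return float(or_point), float(lo), float(hi), degenerate


def crispri_overlap_or(pairs: pd.DataFrame, validated_links: set) -> OddsResult:
    """Fisher's exact test: {pair TF-sensitive} x {pair CRISPRi-validated}
    over the enumerated pair universe."""
    if not validated_links:
        raise ValidationError("empty validated link set")
    key = list(zip(pairs["acr"], pairs["gene"]))
    in_val = np.array([k in validated_links for k in key])
    sens = pairs["pair_sensitive"].to_numpy(dtype=bool)
    a = int((sens & in_val).sum())
    b = int((sens & ~in_val).sum())
    c = int((~sens & in_val).sum())
    d = int((~sens & ~in_val).sum())
    p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue
    or_point, lo, hi, degenerate = _sample_or(a, b, c, d)
    return OddsResult(or_point, lo, hi, float(p), (a, b, c, d), degenerate)


def _in_tad(positions: np.ndarray, tads: pd.DataFrame) -> np.ndarray:
    """TAD index containing each position (strict half-open), -1 if none.

    Assumes tads are non-overlapping and sorted by start (single genome).
    """
    starts = tads["start"].to_numpy()
    ends = tads["end"].to_numpy()
    j = np.searchsorted(starts, positions, side="right") - 1
    out = np.where((j >= 0) & (positions < ends[np.clip(j, 0, None)]), j, -1)
    return out


def annotate_pairs_for_tads(pairs: pd.DataFrame, peaks: pd.DataFrame, genes: pd.DataFrame,
                            tads: pd.DataFrame, rna: FeatureMatrix, atac: FeatureMatrix) -> pd.DataFrame:
    """Attach in-TAD status and mean accessibility/expression levels
    (matching covariates) to a pair table."""
    centers = dict(zip(peaks["name"], peak_centers(peaks)))
    tss = dict(zip(genes["gene_id"], genes["tss"]))
    pc = np.array([centers[a] for a in pairs["acr"]], dtype=np.int64)
    gt = np.array([tss[g] for g in pairs["gene"]], dtype=np.int64)
    tad_p = _in_tad(pc, tads)
    tad_g = _in_tad(gt, tads)
    out = pairs.copy()
    out["in_tad"] = (tad_p >= 0) & (tad_p == tad_g)
    acc_mean = dict(zip(atac.features, normalize(atac).mean(axis=0)))
    expr_mean = dict(zip(rna.features, normalize(rna).mean(axis=0)))
    out["acr_level"] = out["acr"].map(acc_mean)
    out["gene_level"] = out["gene"].map(expr_mean)
    return out


def tad_cooccupancy_odds(pairs: pd.DataFrame, bins, n_resamples: int = 100,
                         seed: int = 0, n_quantiles: int = 10) -> pd.DataFrame:
    """Per-distance-bin odds of TF-sensitive pairs being in a TAD, versus a
    resampled null of non-sensitive pairs matched on accessibility and
    expression quantiles (same count per bin, ``n_resamples`` draws).

    ``pairs`` must carry columns distance, in_tad, pair_sensitive,
    acr_level, gene_level (see :func:`annotate_pairs_for_tads`).
    """
    rng = np.random.default_rng(seed)
    d = np.abs(pairs["distance"].to_numpy())
    bins = np.asarray(bins, dtype=float)
    bin_idx = np.digitize(d, bins) - 1
    q_a = pd.qcut(pairs["acr_level"], n_quantiles, labels=False, duplicates="drop")
    q_g = pd.qcut(pairs["gene_level"], n_quantiles, labels=False, duplicates="drop")
    cell = q_a.to_numpy() * 100 + q_g.to_numpy()
    sens = pairs["pair_sensitive"].to_numpy(dtype=bool)
    in_tad = pairs["in_tad"].to_numpy(dtype=bool)

    rows = []
    for bi in range(len(bins) - 1):
        in_bin = bin_idx == bi
        s = in_bin & sens
        ns = in_bin & ~sens
        n_s = int(s.sum())
        if n_s == 0:
            logger.info("distance bin %d has no sensitive pairs; skipped", bi)
            continue
        n_in = int(in_tad[s].sum())
        n_out = n_s - n_in
        degenerate = n_out == 0 or n_in == 0
        odds_s = n_in / n_out if n_out else np.inf

        # matched null: for each sensitive pair draw a non-sensitive pair
        # from the same (accessibility, expression) quantile cell in-bin
        ns_idx = np.flatnonzero(ns)
        null_odds = []
        if len(ns_idx):
            ns_cells = cell[ns_idx]
            cell_to_pool = {}
            for cval in np.unique(cell[s]):
                pool = ns_idx[ns_cells == cval]
                cell_to_pool[cval] = pool if len(pool) else ns_idx
            sens_cells = cell[s]
            for _ in range(n_resamples):
                drawn = np.concatenate([
                    rng.choice(cell_to_pool[cv], size=int((sens_cells == cv).sum()), replace=True)
                    for cv in np.unique(sens_cells)
                ])
                k_in = int(in_tad[drawn].sum())
                k_out = len(drawn) - k_in
                null_odds.append(k_in / k_out if k_out else np.nan)
        null_odds = np.asarray(null_odds, dtype=float)
        finite = null_odds[np.isfinite(null_odds)]
        null_mean = float(finite.mean()) if finite.size else np.nan
        null_sd = float(finite.std(ddof=1)) if finite.size > 1 else np.nan
        rows.append({
            "bin_low": bins[bi], "bin_high": bins[bi + 1], "n_sensitive": n_s,
            "odds_sensitive": float(odds_s), "null_mean": null_mean,
            "null_sd": null_sd, "degenerate": degenerate,
        })
    return pd.DataFrame(rows)


def chip_proximity_profile(st_atac: pd.DataFrame, peaks: pd.DataFrame,
                           chip_peaks: pd.DataFrame, window_bp: int = 10_000,
                           n_bins: int = 20, tf: str | None = None) -> pd.DataFrame:
    """Mean -log10(p) of ACR sensitivity as a function of signed distance
    from the nearest ChIP-seq peak center."""
    if window_bp <= 0:
        raise ValidationError("window_bp must be positive")
    st = st_atac
    if tf is not None:
        st = st[st["tf"] == tf]
    if st["tf"].nunique() > 1:
        raise ValidationError("profile requires a single TF; pass tf=")
    centers = dict(zip(peaks["name"], peak_centers(peaks)))
    acr_pos = np.array([centers[f] for f in st["feature"]], dtype=np.int64)
    chip_pos = np.sort(peak_centers(chip_peaks))
    j = np.clip(np.searchsorted(chip_pos, acr_pos), 0, len(chip_pos) - 1)
    jm = np.clip(j - 1, 0, None)
    d_right = chip_pos[j] - acr_pos
    d_left = chip_pos[jm] - acr_pos
    dist = np.where(np.abs(d_left) <= np.abs(d_right), d_left, d_right)
    keep = np.abs(dist) <= window_bp
    if not keep.any():
        raise ValidationError(f"no ACR within {window_bp} bp of a ChIP peak")
    edges = np.linspace(-window_bp, window_bp, n_bins + 1)
    bi = np.clip(np.digitize(dist[keep], edges) - 1, 0, n_bins - 1)
    neglog = -np.log10(np.clip(st["p"].to_numpy()[keep], 1e-300, None))
    out = []
    for bidx in range(n_bins):
        sel = bi == bidx
        out.append({
            "bin_center": float((edges[bidx] + edges[bidx + 1]) / 2),
            "mean_neglog10_p": float(neglog[sel].mean()) if sel.any() else np.nan,
            "n": int(sel.sum()),
        })
    return pd.DataFrame(out)
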