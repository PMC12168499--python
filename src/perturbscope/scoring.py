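"""Per-cell perturbation scores against nearest-neighbor control cells.

The score for a cell is the projection of its "signature" (normalized
profile minus the mean profile of its k nearest control cells in a
low-dimensional embedding) onto the mean signature of all cells carrying
the same target's guides. Scores are z-scored against the control-cell
distribution per target and modality, so a control population has mean 0
and unit variance by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.decomposition import PCA, TruncatedSVD
from sklearn.neighbors import NearestNeighbors

from perturbscope.errors import ConfigError, ValidationError
from perturbscope.io import CONTROL_CLASSES, FeatureMatrix

logger = logging.getLogger(__name__)

DEFAULT_K = 20
DEFAULT_DIMS = 30
RNA_TARGET_DEPTH = 10_000.0
RNA_TOP_FEATURES = 2_000
NORM_SCALE = 10_000.0


@dataclass
class Embedding:
    modality: str
    coords: np.ndarray     # cells x d
    method: str

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] < 2:
            raise ValidationError("embedding must be cells x d with d >= 2")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("embedding contains non-finite values")


def normalize(m: FeatureMatrix) -> np.ndarray:
    """Dense normalized profiles on a log scale.

    RNA: counts scaled to a fixed depth, log1p. ATAC: TF-IDF weighting
    followed by log1p scaling, the standard LSI input.

    The result is cached on the matrix object (counts are never mutated
    once constructed).
    """
    cached = getattr(m, "_normalized", None)
    if cached is not None:
        return cached
    counts = np.asarray(m.counts.todense(), dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    if m.modality == "RNA":
        X = np.log1p(counts / totals * RNA_TARGET_DEPTH)
    else:
        tf = counts / totals
        df = (counts > 0).sum(axis=0)
        idf = np.log1p(m.n_cells / (1.0 + df))
        X = np.log1p(tf * idf * NORM_SCALE)
    object.__setattr__(m, "_normalized", X)
    return X


def embed(m: FeatureMatrix, n_components: int = DEFAULT_DIMS,
          n_top_features: int = RNA_TOP_FEATURES, seed: int = 0) -> Embedding:
    """Reduce a count matrix to an embedding for neighbor search.

    RNA: depth-normalize, log1p, top-variable-feature selection, PCA.
    ATAC: log-scaled TF-IDF, truncated SVD with the first (depth-
    correlated) component dropped.
    """
    if m.n_cells == 0:
        raise ValidationError("cannot embed an empty matrix")
    if n_components >= m.n_cells:
        raise ConfigError(
            f"n_components ({n_components}) must be smaller than the number of cells ({m.n_cells})"
        )
    X = normalize(m)
    if m.modality == "RNA":
        variances = X.var(axis=0)
        keep = np.argsort(variances)[::-1][: min(n_top_features, X.shape[1])]
        X = X[:, np.sort(keep)]
        d = min(n_components, X.shape[1], m.n_cells - 1)
        if X.std() == 0:
            # degenerate: identical rows; any fixed embedding works
            coords = np.zeros((m.n_cells, max(d, 2)))
        else:
            coords = PCA(n_components=d, random_state=seed).fit_transform(X)
        return Embedding("RNA", coords, "pca")
    d = min(n_components + 1, X.shape[1] - 1, m.n_cells - 1)
    if X.std() == 0:
        coords = np.zeros((m.n_cells, max(d - 1, 2)))
    else:
        svd = TruncatedSVD(n_components=d, random_state=seed)
        coords = svd.fit_transform(X)[:, 1:]
    return Embedding("ATAC", coords, "lsi")


def perturbation_signature(m: FeatureMatrix, emb: Embedding, guides: pd.DataFrame,
                           k: int = DEFAULT_K, passes: int = 2,
                           center: bool = True) -> np.ndarray:
    """Signature = normalized profile minus mean profile of the k nearest
    control cells in the embedding; controls are compared to other
    controls, excluding self.

    With ``passes=2`` (default) the neighbor-residual operator is applied
    twice, i.e. each cell's neighbor-mean *signature* is subtracted as
    well; this cancels the systematic bias the first pass leaves near the
    boundary of the cell-state manifold. ``center`` additionally removes
    each cell's mean signature across features (a per-cell common mode
    the embedding does not capture). Both corrections are needed for
    calibrated downstream per-feature tests; ``passes=1, center=False``
    gives the plain one-pass signature.
    """
    if list(guides["cell"]) != list(m.barcodes):
        raise ValidationError("guide table must be aligned to matrix barcodes (see align_guides)")
    is_ctrl = guides["target_class"].isin(CONTROL_CLASSES).to_numpy()
    n_ctrl = int(is_ctrl.sum())
    if k > n_ctrl - 1:
        raise ConfigError(f"k={k} exceeds the number of usable control cells ({n_ctrl - 1})")
    X = normalize(m)
    ctrl_idx = np.flatnonzero(is_ctrl)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb.coords[ctrl_idx])
    _, nbr = nn.kneighbors(emb.coords)
    # map back to global indices; controls drop themselves
    nbr_global = ctrl_idx[nbr]
    chosen = np.empty((m.n_cells, k), dtype=int)
    for i in range(m.n_cells):
        row = nbr_global[i]
        if is_ctrl[i]:
            row = row[row != i]
        chosen[i] = row[:k]
    # sparse averaging matrix avoids a cells x k x features temporary
    import scipy.sparse as sp
    rows = np.repeat(np.arange(m.n_cells), k)
    W = sp.csr_matrix(
        (np.full(m.n_cells * k, 1.0 / k), (rows, chosen.ravel())),
        shape=(m.n_cells, m.n_cells),
    )
    S = X - W @ X
    for _ in range(passes - 1):
        S = S - W @ S
    if center:
        S = S - S.mean(axis=1, keepdims=True)
    return S


@dataclass
class ModalityScores:
    """Perturbation scores for one modality, plus the pieces needed to
    orthogonalize per-feature downstream."""

    modality: str
    table: pd.DataFrame          # cell, guide_id, target_class, target, raw, z
    signatures: np.ndarray       # cells x features
    directions: np.ndarray       # targets x features, unit norm
    targets: list
    barcodes: np.ndarray
    features: np.ndarray
    raw: np.ndarray              # cells x targets
    ctrl_mu: np.ndarray          # per target
    ctrl_sd: np.ndarray


def perturbation_score(signatures: np.ndarray, m: FeatureMatrix,
                       guides: pd.DataFrame) -> ModalityScores:
    """Project signatures onto per-target mean-signature directions.

    Control cells are scored against every target (for calibration); each
    TF cell is scored against its own target. z-scores are standardized
    against the control distribution per target.
    """
    is_ctrl = guides["target_class"].isin(CONTROL_CLASSES).to_numpy()
    cell_target = guides["target"].to_numpy()
    targets = sorted(set(cell_target[~is_ctrl]))
    if not targets:
        raise ValidationError("no TF-targeted cells to score")
    dirs = []
    kept_targets = []
    for t in targets:
        rows = signatures[cell_target == t]
        if rows.shape[0] == 0:
            logger.warning("target %s has zero cells; skipped", t)
            continue
        d = rows.mean(axis=0)
        nrm = np.linalg.norm(d)
        dirs.append(d / nrm if nrm > 0 else d)
        kept_targets.append(t)
    D = np.vstack(dirs)
    raw = signatures @ D.T                        # cells x targets
    ctrl_mu = raw[is_ctrl].mean(axis=0)
    ctrl_sd = raw[is_ctrl].std(axis=0, ddof=1)
    ctrl_sd[ctrl_sd == 0] = 1.0
    z = (raw - ctrl_mu) / ctrl_sd

    rows = []
    t_index = {t: j for j, t in enumerate(kept_targets)}
    for i in range(signatures.shape[0]):
        if is_ctrl[i]:
            for t, j in t_index.items():
                rows.append((guides["cell"].iat[i], guides["guide_id"].iat[i],
                             guides["target_class"].iat[i], t, raw[i, j], z[i, j]))
        else:
            j = t_index.get(cell_target[i])
            if j is None:
                continue
            rows.append((guides["cell"].iat[i], guides["guide_id"].iat[i],
                         "TF", cell_target[i], raw[i, j], z[i, j]))
    table = pd.DataFrame(rows, columns=["cell", "guide_id", "target_class", "target", "raw", "z"])
    table.insert(1, "modality", m.modality)
    return ModalityScores(
        modality=m.modality, table=table, signatures=signatures, directions=D,
        targets=kept_targets, barcodes=m.barcodes, features=m.features,
        raw=raw, ctrl_mu=ctrl_mu, ctrl_sd=ctrl_sd,
    )


def score_modality(m: FeatureMatrix, guides: pd.DataFrame, k: int = DEFAULT_K,
                   n_components: int = DEFAULT_DIMS, seed: int = 0) -> ModalityScores:
    """Convenience: embed -> signature -> score for one modality."""
    emb = embed(m, n_components=n_components, seed=seed)
    sig = perturbation_signature(m, emb, guides, k=k)
    return perturbation_score(sig, m, guides)


def efficiency_correlation(score_table: pd.DataFrame, genotypes: pd.DataFrame) -> dict:
    """Per-guide percent edited vs per-guide median perturbation z-score.

    Returns a dict with a per-guide table and the Spearman rank
    correlation per modality (NaN when undefined, e.g. zero variance).
    """
    if len(genotypes) == 0:
        raise ValidationError("empty genotype table")
    geno = genotypes.groupby("guide_id").agg(
        n_genotyped=("edited", "size"), pct_edited=("edited", lambda s: 100.0 * s.mean()),
    )
    tf_scores = score_table[score_table["target_class"] == "TF"]
    med = tf_scores.groupby(["guide_id", "modality"])["z"].median().rename("median_z").reset_index()
    merged = med.merge(geno, left_on="guide_id", right_index=True, how="inner")
    dropped = set(med["guide_id"]) - set(merged["guide_id"])
    if dropped:
        logger.info("guides without genotype data excluded: %s", sorted(dropped))
    if merged["guide_id"].nunique() < 3:
        raise ValidationError("need >= 3 guides with both genotype and score data")
    corr = {}
    for mod, grp in merged.groupby("modality"):
        if grp["pct_edited"].nunique() < 2 or grp["median_z"].nunique() < 2:
            corr[mod] = float("nan")
        else:
            corr[mod] = float(spearmanr(grp["pct_edited"], grp["median_z"]).statistic)
    return {"per_guide": merged, "spearman": corr}
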