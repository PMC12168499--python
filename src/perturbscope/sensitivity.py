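"""TF-sensitive gene and ACR calling via a linear model on the
continuous per-cell perturbation score.

For each TF, each feature's normalized value is regressed on the cell's
perturbation z-score (plus log total counts and control-fit cell-state
PCs), over that TF's cells and all control cells. The Wald p-value on
the score coefficient is BH-corrected within the (TF, modality) stratum.
The reported effect is ``log2FC = beta_IV * (mean z of TF cells - mean z
of controls) / ln 2`` with the slope estimated by instrumental variables
(guide assignment as instrument), equal to the covariate-residualized
group difference; the plain OLS slope is attenuated by within-group
score noise and would systematically underestimate the fold change.

To keep the per-feature test calibrated, the score used in each
feature's regression is orthogonalized against that feature: the
feature's own contribution to the projection score is subtracted before
re-standardizing against controls. Without this, the score is partly a
linear function of the tested feature and null p-values are
anti-conservative.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from perturbscope.errors import ValidationError
from perturbscope.io import CONTROL_CLASSES, FeatureMatrix
from perturbscope.scoring import ModalityScores, normalize

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)
MIN_CELLS = 50


def _bh(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def state_covariates(m: FeatureMatrix, guides: pd.DataFrame, n_state: int = 10,
                     seed: int = 0) -> np.ndarray:
    """Cell-state covariates: principal-component scores of the normalized
    profiles with loadings fit on control cells only.

    Fitting on controls means the components cannot absorb perturbation
    effects, while still tracking differentiation state and technical
    structure that would otherwise leak into the per-feature test.
    """
    from sklearn.decomposition import PCA

    is_ctrl = guides["target_class"].isin(CONTROL_CLASSES).to_numpy()
    X = normalize(m)
    n_state = min(n_state, int(is_ctrl.sum()) - 1, X.shape[1] - 1)
    pca = PCA(n_components=n_state, random_state=seed).fit(X[is_ctrl])
    return pca.transform(X)


def fit_sensitivity(m: FeatureMatrix, scores: ModalityScores, guides: pd.DataFrame,
                    tf: str, alpha: float = 0.05, orthogonalize: bool = True,
                    depth_covariate: bool = True, n_state: int = 10,
                    state: np.ndarray | None = None,
                    min_cells: int = MIN_CELLS) -> pd.DataFrame:
    """Per-feature sensitivity calls for one TF on one modality.

    The p-value is the Wald test on the score slope in
    ``value ~ score + log_depth + state_PCs``; the reported log2FC is the
    instrumental-variables estimate of the same slope times the score
    gap (guide assignment as instrument), which collapses to the
    covariate-residualized group difference and is not attenuated by
    within-group score noise.
    """
    if tf not in scores.targets:
        raise ValidationError(f"no cells carry guides for target {tf!r}")
    cell_target = guides["target"].to_numpy()
    is_ctrl = guides["target_class"].isin(CONTROL_CLASSES).to_numpy()
    is_tf = cell_target == tf
    if not is_tf.any():
        raise ValidationError(f"no cells carry guides for target {tf!r}")
    idx = np.flatnonzero(is_tf | is_ctrl)
    if len(idx) < min_cells:
        raise ValidationError(
            f"only {len(idx)} cells available for {tf} (+controls); need >= {min_cells}"
        )
    n = len(idx)
    Y = normalize(m)[idx]
    t_j = scores.targets.index(tf)
    d = scores.directions[t_j]
    ctrl_sel = is_ctrl[idx]
    tf_sel = is_tf[idx]

    if orthogonalize:
        # remove the tested feature's own contribution to the projection
        # score, then re-standardize against controls; without this the
        # score is partly a linear function of the tested feature
        A = scores.raw[idx, t_j][:, None] - scores.signatures[idx] * d[None, :]
        mu = A[ctrl_sel].mean(axis=0)
        sd = A[ctrl_sel].std(axis=0, ddof=1)
        sd_ok = sd > 0
        sd = np.where(sd_ok, sd, 1.0)
        Z = (A - mu) / sd
        Z[:, ~sd_ok] = 0.0
    else:
        raw = scores.raw[idx, t_j]
        mu = raw[ctrl_sel].mean()
        sd = raw[ctrl_sel].std(ddof=1) or 1.0
        Z = np.tile(((raw - mu) / sd)[:, None], (1, Y.shape[1]))

    def _informative(cols):
        # constant covariates (e.g. depth or state PCs of a degenerate
        # matrix) carry no information and would make the design singular
        if not cols:
            return np.empty((n, 0))
        arr = np.column_stack(cols)
        return arr[:, arr.std(axis=0) > 0]

    base = []
    if depth_covariate:
        base.append(np.log1p(np.asarray(m.counts[idx].sum(axis=1)).ravel().astype(float)))
    C_base = np.column_stack([np.ones((n, 1)), _informative(base)])
    extra = []
    if n_state > 0:
        if state is None:
            state = state_covariates(m, guides, n_state=n_state)
        extra.append(state[idx])
    C = np.column_stack([C_base, _informative(extra)])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValidationError("singular design matrix")

    # Frisch-Waugh-Lovell: residualize response and score on covariates
    Q, _ = np.linalg.qr(C)
    Yr = Y - Q @ (Q.T @ Y)
    Zr = Z - Q @ (Q.T @ Z)

    y_var = Y.var(axis=0)
    z_var = Zr.var(axis=0)
    degenerate = (y_var == 0) | (z_var <= 1e-12)

    szz = np.einsum("ij,ij->j", Zr, Zr)
    szy = np.einsum("ij,ij->j", Zr, Yr)
    denom = np.where(szz > 0, szz, 1.0)
    beta = szy / denom
    rss = np.einsum("ij,ij->j", Yr, Yr) - beta * szy
    df = n - C.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.clip(rss, 0, None) / df / denom)
        tstat = np.where(se > 0, beta / se, 0.0)
    p_val = 2 * stats.t.sf(np.abs(tstat), df)
    p_val[degenerate] = 1.0

    # IV effect: residualized group difference, on the log2 scale.
    # Guide assignment is randomized, so the effect needs no state
    # adjustment; residualizing on state PCs would absorb part of the
    # planted signal (high-variance features load on the control PCs).
    Qe, _ = np.linalg.qr(C_base)
    Ye = Y - Qe @ (Qe.T @ Y)
    log2fc = (Ye[tf_sel].mean(axis=0) - Ye[ctrl_sel].mean(axis=0)) / LN2
    log2fc[degenerate] = 0.0
    q = _bh(p_val)
    sensitive = q < alpha

    out = pd.DataFrame({
        "feature": scores.features,
        "modality": m.modality,
        "tf": tf,
        "log2fc": log2fc,
        "p": p_val,
        "q": q,
        "sensitive": sensitive,
    })
    sig = out.loc[out["sensitive"], "log2fc"]
    if len(sig) >= 2 and sig.std(ddof=1) > 0:
        out["z_log2fc"] = (out["log2fc"] - sig.mean()) / sig.std(ddof=1)
    else:
        out["z_log2fc"] = np.nan
    return out[["feature", "modality", "tf", "log2fc", "z_log2fc", "p", "q", "sensitive"]]


def fit_all(m: FeatureMatrix, scores: ModalityScores, guides: pd.DataFrame,
            alpha: float = 0.05, n_state: int = 10, **kwargs) -> pd.DataFrame:
    """fit_sensitivity for every scored target, concatenated.

    The state covariates are computed once and shared across TFs.
    """
    state = state_covariates(m, guides, n_state=n_state) if n_state > 0 else None
    frames = [fit_sensitivity(m, scores, guides, tf, alpha=alpha, n_state=n_state,
                              state=state, **kwargs)
              for tf in scores.targets]
    return pd.concat(frames, ignore_index=True)


def summarize_sensitive(st: pd.DataFrame) -> pd.DataFrame:
    """Counts/percentages of features sensitive to at least one TF.

    Percent is ``round(100 * sensitive / total, 1)``; also reports the
    fraction of sensitive features responding to exactly one TF.
    """
    if len(st) == 0:
        raise ValidationError("empty sensitivity table")
    rows = []
    for mod, grp in st.groupby("modality"):
        per_feature = grp.groupby("feature")["sensitive"].sum()
        total = len(per_feature)
        n_sens = int((per_feature >= 1).sum())
        n_single = int((per_feature == 1).sum())
        rows.append({
            "modality": mod,
            "n_features": total,
            "n_sensitive": n_sens,
            "pct_sensitive": round(100.0 * n_sens / total, 1),
            "frac_single_tf": (n_single / n_sens) if n_sens else 0.0,
        })
    return pd.DataFrame(rows)


def group_contrast(m: FeatureMatrix, guides: pd.DataFrame, score_table: pd.DataFrame,
                   target: str, feature_subset=None, score_threshold: float = 2.0) -> pd.DataFrame:
    """Wilcoxon rank-sum contrast: perturbed (z > threshold) vs SAFE controls."""
    zs = score_table[(score_table["modality"] == m.modality) & (score_table["target"] == target)]
    z_by_cell = dict(zip(zs["cell"], zs["z"]))
    bc = guides["cell"].to_numpy()
    is_target = (guides["target"] == target).to_numpy()
    z_arr = np.array([z_by_cell.get(c, -np.inf) for c in bc])
    pert = is_target & (z_arr > score_threshold)
    ctrl = (guides["target_class"] == "SAFE").to_numpy()
    if not pert.any():
        raise ValidationError(
            f"no perturbed cells for {target} at z > {score_threshold}; try a lower threshold"
        )
    if not ctrl.any():
        raise ValidationError("no SAFE control cells")
    X = normalize(m)
    features = np.asarray(m.features, dtype=object)
    if feature_subset is not None:
        fidx = m.feature_index()
        cols = np.array([fidx[f] for f in feature_subset])
        X = X[:, cols]
        features = features[cols]
    a, b_ = X[pert], X[ctrl]
    res = stats.mannwhitneyu(a, b_, axis=0, method="auto")
    p = np.atleast_1d(np.asarray(res.pvalue, dtype=float))
    # fully tied feature (zero spread in both groups): no evidence, p = 1
    flat = np.ptp(np.vstack([a, b_]), axis=0) == 0
    p[flat | ~np.isfinite(p)] = 1.0
    log2fc = (a.mean(axis=0) - b_.mean(axis=0)) / LN2
    return pd.DataFrame({
        "feature": features,
        "modality": m.modality,
        "target": target,
        "log2fc": log2fc,
        "p": p,
        "p_adj": _bh(p),
        "n_perturbed": int(pert.sum()),
        "n_control": int(ctrl.sum()),
    })


def replicate_concordance(st_a: pd.DataFrame, st_b: pd.DataFrame, tf: str,
                          min_shared: int = 10) -> pd.DataFrame:
    """Spearman rho of z-scored log2FC over features significant in both
    replicates, per modality."""
    rows = []
    for mod in sorted(set(st_a["modality"]) & set(st_b["modality"])):
        a = st_a[(st_a["tf"] == tf) & (st_a["modality"] == mod) & st_a["sensitive"]]
        b = st_b[(st_b["tf"] == tf) & (st_b["modality"] == mod) & st_b["sensitive"]]
        merged = a.merge(b, on="feature", suffixes=("_a", "_b"))
        if len(merged) < min_shared:
            logger.warning("replicate_concordance %s/%s: only %d shared significant features",
                           tf, mod, len(merged))
            rows.append({"tf": tf, "modality": mod, "rho": np.nan, "n": len(merged)})
            continue
        rho = stats.spearmanr(merged["z_log2fc_a"], merged["z_log2fc_b"]).statistic
        rows.append({"tf": tf, "modality": mod, "rho": float(rho), "n": len(merged)})
    return pd.DataFrame(rows)


def module_score(m: FeatureMatrix, gene_set) -> pd.DataFrame:
    """Per-cell z-scored mean normalized expression over a gene set."""
    gene_set = list(gene_set)
    if not gene_set:
        raise ValidationError("empty gene set")
    fidx = m.feature_index()
    missing = [g for g in gene_set if g not in fidx]
    if missing:
        raise ValidationError(f"gene set members absent from matrix: {missing[:5]}")
    cols = np.array([fidx[g] for g in gene_set])
    X = normalize(m)[:, cols]
    mean = X.mean(axis=1)
    sd = mean.std(ddof=1) if len(mean) > 1 else 0.0
    score = (mean - mean.mean()) / sd if sd > 0 else np.zeros_like(mean)
    return pd.DataFrame({"cell": m.barcodes, "module": "+".join(gene_set[:1]) + f"_n{len(gene_set)}",
                         "score": score})
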