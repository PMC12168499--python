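"""Synthetic paired RNA/ATAC perturbation-screen generator with ground truth.

One synthetic chromosome (``chrS``), 0-based half-open coordinates.
Peaks are fixed-width and non-overlapping on a regular grid. Each cell
carries exactly one guide. RNA counts are negative binomial with
lognormal size factors and pseudotime-modulated programs; ATAC counts
are Poisson with per-peak open probabilities on the logit scale. Edited
cells have their TF's sensitive genes scaled by 2**delta and sensitive
peak logits shifted. A configurable fraction of sensitive peaks is
"linked" to a sensitive gene: the gene TSS is placed within 50 kb of the
peak center inside a shared TAD, and the two features share a latent
activity so they correlate across unperturbed cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from perturbscope.errors import ConfigError
from perturbscope.io import FeatureMatrix, validate_guides

CHROM = "chrS"
LINK_WINDOW_BP = 50_000
LD_WINDOW_BP = 25_000
CAUSAL_PIP = 0.6


@dataclass
class SimConfig:
    n_cells: int = 2000
    n_genes: int = 1000
    n_peaks: int = 2000
    n_tfs: int = 19
    guides_per_tf: int = 3
    n_control_guides: int = 6
    editing_efficiency_range: tuple = (0.5, 0.95)
    n_sensitive_genes_per_tf: int = 25
    n_sensitive_peaks_per_tf: int = 50
    effect_size_log2fc: float = 1.0
    effect_jitter: float = 0.25
    frac_linked_pairs: float = 0.3
    tad_width_bp: int = 1_000_000
    genome_length_bp: int = 20_000_000
    peak_width_bp: int = 500
    nb_dispersion: float = 0.3
    mean_rna_depth: float = 10_000.0
    mean_atac_depth: float = 5_000.0
    frac_program_features: float = 0.3
    depth_sd_log: float = 0.3
    seed: int = 0
    noise_seed: int | None = None

    def n_guides(self) -> int:
        return self.n_tfs * self.guides_per_tf + self.n_control_guides

    def validate(self) -> None:
        for name in ("n_cells", "n_genes", "n_peaks", "n_tfs", "guides_per_tf",
                     "n_control_guides", "tad_width_bp", "genome_length_bp",
                     "peak_width_bp"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        for name in ("effect_size_log2fc", "nb_dispersion", "mean_rna_depth",
                     "mean_atac_depth", "depth_sd_log"):
            v = getattr(self, name)
            if v < 0:
                raise ConfigError(f"{name} must be non-negative, got {v!r}")
        lo, hi = self.editing_efficiency_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigError(
                f"editing_efficiency_range must be ordered probabilities in [0,1], got {self.editing_efficiency_range!r}"
            )
        if not 0 <= self.effect_jitter <= 1:
            raise ConfigError(f"effect_jitter must be in [0,1], got {self.effect_jitter!r}")
        if not 0 <= self.frac_linked_pairs <= 1:
            raise ConfigError(f"frac_linked_pairs must be in [0,1], got {self.frac_linked_pairs!r}")
        if not 0 <= self.frac_program_features <= 1:
            raise ConfigError(f"frac_program_features must be in [0,1], got {self.frac_program_features!r}")
        if self.n_sensitive_genes_per_tf < 0 or self.n_sensitive_genes_per_tf > self.n_genes:
            raise ConfigError("n_sensitive_genes_per_tf must be in [0, n_genes]")
        if self.n_sensitive_peaks_per_tf < 0 or self.n_sensitive_peaks_per_tf > self.n_peaks:
            raise ConfigError("n_sensitive_peaks_per_tf must be in [0, n_peaks]")
        if self.genome_length_bp < self.n_peaks * 2 * self.peak_width_bp:
            raise ConfigError(
                "genome_length_bp too small: need at least n_peaks * 2 * peak_width_bp"
            )
        if self.n_cells < self.n_guides():
            raise ConfigError(
                f"n_cells ({self.n_cells}) smaller than the number of guides ({self.n_guides()}); every guide must be assignable"
            )


@dataclass
class GroundTruth:
    """Everything planted by the generator, for validation downstream."""

    guide_efficiency: dict            # guide_id -> editing probability
    cell_edited: dict                 # cell barcode -> bool
    cell_pseudotime: dict             # cell barcode -> float in [0,1]
    tf_sensitive_genes: dict          # tf -> {gene_id: signed log2 delta}
    tf_sensitive_peaks: dict          # tf -> {peak_id: signed logit shift}
    linked_pairs: list                # [(peak_id, gene_id, tf), ...]
    tads: pd.DataFrame                # chrom/start/end/name
    snp_h2: pd.DataFrame | None = None   # filled by simulate_gwas
    snp_category: dict = field(default_factory=dict)

    def sensitive_peak_ids(self) -> set:
        out: set = set()
        for d in self.tf_sensitive_peaks.values():
            out |= set(d)
        return out

    def sensitive_gene_ids(self) -> set:
        out: set = set()
        for d in self.tf_sensitive_genes.values():
            out |= set(d)
        return out

    def to_json(self, path: str) -> None:
        payload = {
            "guide_efficiency": self.guide_efficiency,
            "cell_edited": {k: bool(v) for k, v in self.cell_edited.items()},
            "cell_pseudotime": self.cell_pseudotime,
            "tf_sensitive_genes": self.tf_sensitive_genes,
            "tf_sensitive_peaks": self.tf_sensitive_peaks,
            "linked_pairs": [list(p) for p in self.linked_pairs],
            "tads": self.tads.to_dict(orient="list"),
            "snp_category": self.snp_category,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        payload["tads"] = pd.DataFrame(payload["tads"])
        payload["linked_pairs"] = [tuple(p) for p in payload["linked_pairs"]]
        return cls(**payload)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _make_guides(config: SimConfig) -> pd.DataFrame:
    rows = []
    for t in range(config.n_tfs):
        tf = f"TF{t + 1:02d}"
        for g in range(config.guides_per_tf):
            rows.append((f"{tf}_g{g + 1}", tf, "TF"))
    n_nt = (config.n_control_guides + 1) // 2
    n_safe = config.n_control_guides - n_nt
    for g in range(n_nt):
        rows.append((f"NT_g{g + 1}", "NT", "NT"))
    for g in range(n_safe):
        rows.append((f"SAFE_g{g + 1}", "AAVS1", "SAFE"))
    return pd.DataFrame(rows, columns=["guide_id", "target", "target_class"])


def simulate_dataset(config: SimConfig):
    """Generate one synthetic perturbation-screen dataset.

    Returns
    -------
    (rna, atac, guides, genes, peaks, truth)
        ``rna``/``atac`` are :class:`FeatureMatrix`; ``guides`` a guide
        assignment table; ``genes`` a gene annotation table (gene_id,
        chrom, tss, strand); ``peaks`` an interval table; ``truth`` the
        planted :class:`GroundTruth`.
    """
    config.validate()
    # two independent streams: "structure" fixes the planted architecture
    # (genome layout, effect sets, guide efficiencies); "noise" draws the
    # cells and counts. Two configs differing only in noise_seed share
    # their GroundTruth effects and act as biological replicates.
    rng = np.random.default_rng([config.seed, 0])
    noise_seed = config.seed if config.noise_seed is None else config.noise_seed
    rng_n = np.random.default_rng([noise_seed, 1])

    n_cells, n_genes, n_peaks = config.n_cells, config.n_genes, config.n_peaks
    barcodes = np.array([f"cell_{i:06d}" for i in range(n_cells)], dtype=object)
    gene_ids = np.array([f"gene_{i:05d}" for i in range(n_genes)], dtype=object)
    peak_ids = np.array([f"peak_{i:05d}" for i in range(n_peaks)], dtype=object)
    tfs = [f"TF{t + 1:02d}" for t in range(config.n_tfs)]

    # --- guides and cells -------------------------------------------------
    guide_defs = _make_guides(config)
    # every guide gets at least one cell; the rest are uniform multinomial
    n_guides = len(guide_defs)
    assignment = np.concatenate([
        np.arange(n_guides),
        rng_n.integers(0, n_guides, size=n_cells - n_guides),
    ])
    rng_n.shuffle(assignment)
    guides = guide_defs.iloc[assignment].reset_index(drop=True)
    guides.insert(0, "cell", barcodes)
    validate_guides(guides)

    pseudotime = rng_n.uniform(0.0, 1.0, size=n_cells)

    lo, hi = config.editing_efficiency_range
    guide_eff = {
        row.guide_id: (float(rng.uniform(lo, hi)) if row.target_class == "TF" else 0.0)
        for row in guide_defs.itertuples()
    }
    eff_per_cell = guides["guide_id"].map(guide_eff).to_numpy(dtype=float)
    is_tf_cell = (guides["target_class"] == "TF").to_numpy()
    edited = is_tf_cell & (rng_n.uniform(size=n_cells) < eff_per_cell)

    # --- genome layout ----------------------------------------------------
    spacing = config.genome_length_bp // n_peaks
    peak_start = np.arange(n_peaks, dtype=np.int64) * spacing + (spacing - config.peak_width_bp) // 2
    peak_end = peak_start + config.peak_width_bp
    peak_center = (peak_start + peak_end) // 2
    peaks = pd.DataFrame({
        "chrom": CHROM, "start": peak_start, "end": peak_end, "name": peak_ids,
    })

    tss = rng.integers(0, config.genome_length_bp, size=n_genes).astype(np.int64)
    strand = rng.choice(["+", "-"], size=n_genes)

    n_tads = max(1, config.genome_length_bp // config.tad_width_bp)
    tad_start = np.arange(n_tads, dtype=np.int64) * config.tad_width_bp
    tad_end = np.minimum(tad_start + config.tad_width_bp, config.genome_length_bp)
    tads = pd.DataFrame({
        "chrom": CHROM, "start": tad_start, "end": tad_end,
        "name": [f"tad_{i:04d}" for i in range(n_tads)],
    })

    # --- baseline parameters ---------------------------------------------
    gene_logmean = rng.normal(0.0, 1.0, size=n_genes)
    peak_logit = rng.normal(-2.5, 0.8, size=n_peaks)

    # pseudotime programs: a subset of features respond smoothly to pseudotime
    prog_genes = rng.uniform(size=n_genes) < config.frac_program_features
    prog_peaks = rng.uniform(size=n_peaks) < config.frac_program_features
    gene_pt_coef = np.where(prog_genes, rng.normal(0.0, 0.8, size=n_genes), 0.0)
    peak_pt_coef = np.where(prog_peaks, rng.normal(0.0, 0.8, size=n_peaks), 0.0)

    # --- planted sensitive sets -------------------------------------------
    # sensitive genes are drawn from the upper half of baseline expression so
    # planted fold changes remain measurable after depth normalisation
    eligible_genes = np.flatnonzero(gene_logmean >= np.median(gene_logmean))
    eff = config.effect_size_log2fc
    tf_genes: dict = {}
    tf_peaks: dict = {}
    for tf in tfs:
        g_idx = rng.choice(eligible_genes, size=config.n_sensitive_genes_per_tf, replace=False)
        signs = rng.choice([-1.0, 1.0], size=len(g_idx))
        mags = rng.uniform(1 - config.effect_jitter, 1 + config.effect_jitter, size=len(g_idx)) * eff
        tf_genes[tf] = {str(gene_ids[i]): float(s * m) for i, s, m in zip(g_idx, signs, mags)}
        p_idx = rng.choice(n_peaks, size=config.n_sensitive_peaks_per_tf, replace=False)
        psigns = rng.choice([-1.0, 1.0], size=len(p_idx))
        pmags = rng.uniform(1 - config.effect_jitter, 1 + config.effect_jitter, size=len(p_idx)) * eff * np.log(2.0)
        tf_peaks[tf] = {str(peak_ids[i]): float(s * m) for i, s, m in zip(p_idx, psigns, pmags)}

    # --- linked ACR-gene pairs ---------------------------------------------
    # for a fraction of each TF's sensitive peaks, relocate one of its
    # sensitive genes' TSS near the peak (inside the shared TAD) and couple
    # the two features through a per-pair latent activity
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    peak_index = {p: i for i, p in enumerate(peak_ids)}
    linked_pairs: list = []
    link_gene_rows: list = []
    link_peak_rows: list = []
    used_genes: set = set()
    used_peaks: set = set()
    for tf in tfs:
        # a gene or peak joins at most one linked pair; relocating a TSS
        # twice would break the earlier pair's distance guarantee
        sens_peaks = [p for p in tf_peaks[tf] if p not in used_peaks]
        sens_genes = [g for g in tf_genes[tf] if g not in used_genes]
        n_link = min(int(round(config.frac_linked_pairs * len(tf_peaks[tf]))),
                     len(sens_genes), len(sens_peaks))
        if n_link == 0:
            continue
        chosen_peaks = rng.choice(len(sens_peaks), size=n_link, replace=False)
        chosen_genes = rng.choice(len(sens_genes), size=n_link, replace=False)
        for pi, gi in zip(chosen_peaks, chosen_genes):
            pid, gid = sens_peaks[pi], sens_genes[gi]
            used_genes.add(gid)
            used_peaks.add(pid)
            p_idx2, g_idx2 = peak_index[pid], gene_index[gid]
            center = int(peak_center[p_idx2])
            tad_i = min(center // config.tad_width_bp, n_tads - 1)
            lo_b = max(int(tad_start[tad_i]), center - (LINK_WINDOW_BP - 10_000))
            hi_b = min(int(tad_end[tad_i]) - 1, center + (LINK_WINDOW_BP - 10_000))
            tss[g_idx2] = rng.integers(lo_b, hi_b + 1)
            # same-sign planted effects so the pair co-varies under editing too
            tf_genes[tf][gid] = abs(tf_genes[tf][gid]) * np.sign(tf_peaks[tf][pid])
            linked_pairs.append((pid, gid, tf))
            link_gene_rows.append(g_idx2)
            link_peak_rows.append(p_idx2)

    genes = pd.DataFrame({
        "gene_id": gene_ids, "chrom": CHROM, "tss": tss, "strand": strand,
    })

    # --- expression / accessibility means ----------------------------------
    pt_c = (pseudotime - 0.5) * 2.0                      # in [-1, 1]
    log_mu = gene_logmean[None, :] + np.outer(pt_c, gene_pt_coef)
    logit_open = peak_logit[None, :] + np.outer(pt_c, peak_pt_coef)

    if linked_pairs:
        # shared latent per linked pair: smooth pseudotime component + noise
        n_link_tot = len(linked_pairs)
        phase = rng.uniform(0, 2 * np.pi, size=n_link_tot)
        latent = np.sin(np.pi * pseudotime[:, None] + phase[None, :])
        latent = latent + rng_n.normal(0.0, 0.5, size=latent.shape)
        coupling = 0.8
        np.add.at(log_mu.T, link_gene_rows, coupling * latent.T)
        np.add.at(logit_open.T, link_peak_rows, coupling * latent.T)

    # planted effects in edited cells
    edited_idx = np.flatnonzero(edited)
    cell_target = guides["target"].to_numpy()
    ln2 = np.log(2.0)
    for tf in tfs:
        cells_t = edited_idx[cell_target[edited_idx] == tf]
        if len(cells_t) == 0:
            continue
        for gid, delta in tf_genes[tf].items():
            log_mu[cells_t, gene_index[gid]] += delta * ln2
        for pid, shift in tf_peaks[tf].items():
            logit_open[cells_t, peak_index[pid]] += shift

    # --- draw counts --------------------------------------------------------
    rna_depth = np.exp(rng_n.normal(np.log(config.mean_rna_depth), config.depth_sd_log, size=n_cells))
    atac_depth = np.exp(rng_n.normal(np.log(config.mean_atac_depth), config.depth_sd_log, size=n_cells))

    w = np.exp(log_mu)
    mu_rna = w / w.sum(axis=1, keepdims=True) * rna_depth[:, None]
    if config.nb_dispersion > 0:
        size = 1.0 / config.nb_dispersion
        rna_counts = rng_n.negative_binomial(size, size / (size + mu_rna))
    else:
        rna_counts = rng_n.poisson(mu_rna)

    open_p = _sigmoid(logit_open)
    mu_atac = open_p / open_p.sum(axis=1, keepdims=True) * atac_depth[:, None]
    atac_counts = rng_n.poisson(mu_atac)

    rna = FeatureMatrix("RNA", sp.csr_matrix(rna_counts.astype(np.int64)), barcodes, gene_ids)
    atac = FeatureMatrix("ATAC", sp.csr_matrix(atac_counts.astype(np.int64)), barcodes, peak_ids)

    truth = GroundTruth(
        guide_efficiency=guide_eff,
        cell_edited={bc: bool(e) for bc, e in zip(barcodes, edited)},
        cell_pseudotime={bc: float(t) for bc, t in zip(barcodes, pseudotime)},
        tf_sensitive_genes=tf_genes,
        tf_sensitive_peaks=tf_peaks,
        linked_pairs=linked_pairs,
        tads=tads,
    )
    return rna, atac, guides, genes, peaks, truth


def simulate_genotypes(truth: GroundTruth, guides: pd.DataFrame,
                       call_error: float = 0.0, coverage: float = 1.0,
                       seed: int = 0) -> pd.DataFrame:
    """Simulate pooled single-cell genotyping of the guide target sites.

    Each TF-targeted cell is covered with probability ``coverage``; a
    covered call equals the true edited flag with probability
    ``1 - call_error``. Control-guide cells have no target site and are
    absent from the output (missing data).
    """
    if not 0 <= call_error <= 1:
        raise ConfigError(f"call_error must be in [0,1], got {call_error!r}")
    if not 0 <= coverage <= 1:
        raise ConfigError(f"coverage must be in [0,1], got {coverage!r}")
    rng = np.random.default_rng(seed)
    tf_rows = guides[guides["target_class"] == "TF"]
    covered = rng.uniform(size=len(tf_rows)) < coverage
    sub = tf_rows[covered].copy()
    true_flag = sub["cell"].map(truth.cell_edited).to_numpy(dtype=bool)
    flip = rng.uniform(size=len(sub)) < call_error
    sub["edited"] = np.where(flip, ~true_flag, true_flag)
    sub["amplicon"] = sub["target"].astype(str) + "_site"
    return sub[["cell", "guide_id", "edited", "amplicon"]].reset_index(drop=True)


def simulate_gwas(truth: GroundTruth, peaks: pd.DataFrame,
                  n_traits: int = 3, n_sets_per_trait: int = 40,
                  snps_per_set: int = 5, enrichment_factor: float = 1.0,
                  seed: int = 0, n_snps: int = 20_000,
                  frac_snps_in_peaks: float = 0.25,
                  genome_length_bp: int | None = None):
    """Simulate fine-mapped credible sets and per-SNP heritability.

    SNP effect sizes are drawn N(0, v) with v multiplied by
    ``enrichment_factor`` inside TF-sensitive peaks; per-SNP h2
    contributions are the squared effects normalised to sum to 1.
    Credible-set causal SNPs are drawn with probability proportional to
    their h2 contribution; LD companions come from a +/-25 kb window with
    PIP 0.6 on the causal SNP and the remainder split uniformly.
    """
    if enrichment_factor <= 0:
        raise ConfigError(f"enrichment_factor must be > 0, got {enrichment_factor!r}")
    if len(peaks) == 0 and enrichment_factor != 1.0:
        raise ConfigError("cannot plant peak-level enrichment with zero peaks")
    rng = np.random.default_rng(seed)
    if genome_length_bp is None:
        genome_length_bp = int(peaks["end"].max() * 1.02) if len(peaks) else 1_000_000

    n_in = int(round(n_snps * frac_snps_in_peaks)) if len(peaks) else 0
    pos_uniform = rng.integers(0, genome_length_bp, size=n_snps - n_in)
    if n_in:
        pk = peaks.iloc[rng.integers(0, len(peaks), size=n_in)]
        offs = rng.integers(0, (pk["end"] - pk["start"]).to_numpy())
        pos_in = pk["start"].to_numpy() + offs
        pos = np.concatenate([pos_uniform, pos_in])
    else:
        pos = pos_uniform
    pos = np.sort(pos.astype(np.int64))
    snp_ids = np.array([f"rs{i:07d}" for i in range(len(pos))], dtype=object)

    sens_ids = truth.sensitive_peak_ids()
    sens = peaks[peaks["name"].isin(sens_ids)] if len(peaks) else peaks
    in_sens = np.zeros(len(pos), dtype=bool)
    if len(sens):
        starts = sens["start"].to_numpy()
        ends = sens["end"].to_numpy()
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = j >= 0
        in_sens[ok] = pos[ok] < ends[j[ok]]

    var = np.where(in_sens, enrichment_factor, 1.0)
    beta = rng.normal(0.0, 1.0, size=len(pos)) * np.sqrt(var)
    h2 = beta ** 2
    h2 = h2 / h2.sum()

    snp_h2 = pd.DataFrame({
        "snp_id": snp_ids, "chrom": CHROM, "pos": pos, "h2_contribution": h2,
    })
    truth.snp_h2 = snp_h2
    truth.snp_category = {str(s): ("sensitive_peak" if f else "background")
                          for s, f in zip(snp_ids, in_sens)}

    # --- credible sets -----------------------------------------------------
    rows = []
    p_causal = h2 / h2.sum()
    for t in range(n_traits):
        trait = f"trait_{t + 1}"
        causal = rng.choice(len(pos), size=n_sets_per_trait, replace=False, p=p_causal)
        for s, ci in enumerate(causal):
            set_id = f"{trait}_cs{s + 1:03d}"
            lo = np.searchsorted(pos, pos[ci] - LD_WINDOW_BP, side="left")
            hi = np.searchsorted(pos, pos[ci] + LD_WINDOW_BP, side="right")
            companions = [i for i in range(lo, hi) if i != ci]
            k = min(snps_per_set - 1, len(companions))
            comp = rng.choice(companions, size=k, replace=False) if k else np.array([], dtype=int)
            members = [ci] + list(comp)
            pips = [CAUSAL_PIP] + ([(1.0 - CAUSAL_PIP) / k] * k if k else [])
            if not k:
                pips = [1.0]
            for i, pip in zip(members, pips):
                rows.append((trait, set_id, snp_ids[i], CHROM, int(pos[i]), float(pip)))
    credible = pd.DataFrame(rows, columns=["trait", "set_id", "snp_id", "chrom", "pos", "pip"])
    return credible, snp_h2
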