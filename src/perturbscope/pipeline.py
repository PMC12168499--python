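"""End-to-end orchestration: simulate -> score -> sensitivity -> link ->
enrich, with deterministic per-stage seeds and a JSON summary."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from perturbscope import io as pio
from perturbscope import linkage, enrichment, sensitivity
from perturbscope.errors import ConfigError, PipelineError
from perturbscope.scoring import score_modality
from perturbscope.simulate import SimConfig, simulate_dataset, simulate_gwas

logger = logging.getLogger(__name__)

STAGES = ("simulate", "score", "sensitivity", "link", "enrich")


def stage_seed(stage: str, global_seed: int) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).hexdigest()
    return int(digest[:8], 16)


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    # fixture mode: simulate inputs instead of reading them
    sim: SimConfig | None = None
    rna_path: str | None = None
    atac_path: str | None = None
    guides_path: str | None = None
    genes_path: str | None = None
    peaks_path: str | None = None
    tads_path: str | None = None
    # stage parameters
    k_neighbors: int = 20
    n_components: int = 30
    alpha: float = 0.05
    pair_window_bp: int = 50_000
    n_resamples: int = 100
    gwas_enrichment_factor: float = 4.0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = SimConfig(**{**sim, "seed": sim.get("seed", cfg.seed)})
        return cfg

    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")
        if self.sim is None:
            for name in ("rna_path", "atac_path", "guides_path", "genes_path", "peaks_path"):
                p = getattr(self, name)
                if p is None:
                    raise ConfigError(f"non-fixture mode requires {name}")
                if not os.path.exists(p):
                    raise ConfigError(f"{name}: path does not exist: {p}")


def validate_inputs(rna, atac, guides, genes, peaks) -> dict:
    """Cross-check barcodes, coordinates, and schemas. Report-only."""
    issues = []
    rna_bc, atac_bc = set(rna.barcodes), set(atac.barcodes)
    if rna_bc != atac_bc:
        issues.append(
            f"RNA/ATAC barcode mismatch: {len(rna_bc - atac_bc)} RNA-only, {len(atac_bc - rna_bc)} ATAC-only"
        )
    guide_bc = set(guides["cell"])
    n_unassigned = len(rna_bc - guide_bc)
    if n_unassigned:
        issues.append(f"{n_unassigned} cells lack a guide assignment (will be dropped)")
    try:
        pio.validate_intervals(peaks, "peaks")
    except Exception as exc:
        issues.append(str(exc))
    if (genes["tss"] < 0).any():
        issues.append("negative TSS coordinate in gene annotation")
    blocking = [i for i in issues if "mismatch" in i or "interval" in i or "negative" in i]
    return {"ok": not blocking, "issues": issues}


def run_all(config: PipelineConfig) -> dict:
    """Execute all stages, writing TSVs plus summary.json and a MANIFEST.

    Re-running with the same config reproduces all outputs bit-identically.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest_path = os.path.join(config.out_dir, "MANIFEST")
    completed: list = []

    def _write_manifest(status: str) -> None:
        with open(manifest_path, "w", encoding="utf-8") as fh:
            fh.write(f"status\t{status}\n")
            for st in completed:
                fh.write(f"stage_complete\t{st}\n")

    summary: dict = {"seed": config.seed, "stages": {}}
    current = "simulate"
    try:
        # ------------------------------------------------ simulate / load
        if config.sim is not None:
            sim_cfg = config.sim
            sim_cfg.seed = stage_seed("simulate", config.seed)
            rna, atac, guides, genes, peaks, truth = simulate_dataset(sim_cfg)
            credible, snp_h2 = simulate_gwas(
                truth, peaks, enrichment_factor=config.gwas_enrichment_factor,
                seed=stage_seed("gwas", config.seed),
            )
            tads = truth.tads
            pio.write_matrix(rna, os.path.join(config.out_dir, "rna"))
            pio.write_matrix(atac, os.path.join(config.out_dir, "atac"))
            pio.write_table(guides, os.path.join(config.out_dir, "guides.tsv"))
            pio.write_table(genes, os.path.join(config.out_dir, "genes.tsv"))
            pio.write_bed(peaks, os.path.join(config.out_dir, "peaks.bed"))
            pio.write_bed(tads, os.path.join(config.out_dir, "tads.bed"))
            pio.write_table(credible, os.path.join(config.out_dir, "credible_sets.tsv"))
            pio.write_table(snp_h2, os.path.join(config.out_dir, "snp_h2.tsv"))
            truth.to_json(os.path.join(config.out_dir, "truth.json"))
        else:
            rna = pio.read_matrix(config.rna_path, "RNA")
            atac = pio.read_matrix(config.atac_path, "ATAC")
            guides = pio.read_guides(config.guides_path)
            genes = pio.read_genes(config.genes_path)
            peaks = pio.read_bed(config.peaks_path)
            tads = pio.read_bed(config.tads_path) if config.tads_path else None
            truth = None
            credible = snp_h2 = None
        report = validate_inputs(rna, atac, guides, genes, peaks)
        if not report["ok"]:
            raise PipelineError(f"input validation failed: {report['issues']}")
        rna, guides_r = pio.align_guides(rna, guides)
        atac, guides_a = pio.align_guides(atac, guides)
        completed.append("simulate")

        # ------------------------------------------------ score
        current = "score"
        sseed = stage_seed("score", config.seed)
        rna_scores = score_modality(rna, guides_r, k=config.k_neighbors,
                                    n_components=config.n_components, seed=sseed)
        atac_scores = score_modality(atac, guides_a, k=config.k_neighbors,
                                     n_components=config.n_components, seed=sseed)
        score_table = pd.concat([rna_scores.table, atac_scores.table], ignore_index=True)
        pio.write_table(score_table, os.path.join(config.out_dir, "scores.tsv"))
        completed.append("score")

        # ------------------------------------------------ sensitivity
        current = "sensitivity"
        st = pd.concat([
            sensitivity.fit_all(rna, rna_scores, guides_r, alpha=config.alpha),
            sensitivity.fit_all(atac, atac_scores, guides_a, alpha=config.alpha),
        ], ignore_index=True)
        pio.write_table(st, os.path.join(config.out_dir, "sensitivity.tsv"))
        summ = sensitivity.summarize_sensitive(st)
        summary["stages"]["sensitivity"] = summ.to_dict(orient="records")
        completed.append("sensitivity")

        # ------------------------------------------------ link
        current = "link"
        pairs = linkage.enumerate_pairs(peaks, genes, max_distance=config.pair_window_bp)
        pairs = linkage.pair_correlation(rna, atac, guides_r, pairs)
        pairs = linkage.flag_pair_sensitivity(pairs, st, alpha=config.alpha)
        if tads is not None:
            pairs2 = linkage.enumerate_pairs(peaks, genes, max_distance=2_000_000)
            pairs2 = linkage.flag_pair_sensitivity(pairs2, st, alpha=config.alpha)
            pairs2 = linkage.annotate_pairs_for_tads(pairs2, peaks, genes, tads, rna, atac)
            bins = np.geomspace(10_000, 2_000_000, 6)
            tad_odds = linkage.tad_cooccupancy_odds(
                pairs2, bins, n_resamples=config.n_resamples,
                seed=stage_seed("link", config.seed))
            pio.write_table(tad_odds, os.path.join(config.out_dir, "tad_odds.tsv"))
            summary["stages"]["tad_odds"] = tad_odds.to_dict(orient="records")
        pio.write_table(pairs, os.path.join(config.out_dir, "pairs.tsv"))
        summary["stages"]["link"] = {
            "n_pairs": int(len(pairs)),
            "n_pair_sensitive": int(pairs["pair_sensitive"].sum()),
        }
        completed.append("link")

        # ------------------------------------------------ enrich
        current = "enrich"
        if credible is not None:
            sens_acrs = set(st[(st["modality"] == "ATAC") & st["sensitive"]]["feature"])
            regions = peaks[peaks["name"].isin(sens_acrs)]
            if len(regions):
                ov = enrichment.credible_set_overlap(credible, regions)
                pio.write_table(ov, os.path.join(config.out_dir, "overlap.tsv"))
                pool = peaks[~peaks["name"].isin(sens_acrs)]
                null = enrichment.sampled_overlap_null(
                    credible, n_regions=len(regions), n_samples=config.n_resamples,
                    matching="length", pool=pool,
                    target_lengths=(regions["end"] - regions["start"]).to_numpy(),
                    seed=stage_seed("enrich", config.seed))
                mask = enrichment._positions_in_regions(snp_h2["pos"].to_numpy(), regions)
                her = enrichment.heritability_enrichment(snp_h2, mask)
                summary["stages"]["enrich"] = {
                    "observed_pct_overlap": float(ov["pct_overlap"].mean()),
                    "null_mean": null["null_mean"],
                    "null_sd": null["null_sd"],
                    "h2_enrichment": her["enrichment"],
                    "pct_snps": her["pct_snps"],
                    "pct_h2": her["pct_h2"],
                }
        completed.append("enrich")
    except PipelineError:
        _write_manifest(f"failed:{current}")
        raise
    except Exception as exc:
        _write_manifest(f"failed:{current}")
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc

    summary["parameters"] = {
        "k_neighbors": config.k_neighbors, "n_components": config.n_components,
        "alpha": config.alpha, "pair_window_bp": config.pair_window_bp,
        "n_resamples": config.n_resamples,
    }
    with open(os.path.join(config.out_dir, "summary.json"), "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    _write_manifest("complete")
    return summary
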