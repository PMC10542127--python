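"""Configuration-driven orchestration of the full analysis pipeline.

Runs the stages in dependency order on a simulated (or loaded) study:
simulate -> qc -> normalize -> pseudobulk -> abundance -> markers -> de
-> tcr -> sharing -> serum -> report, writing each stage's result table
as TSV plus a JSON run manifest (config hash, seed, package version).
Reruns with an identical configuration are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abundance, de, io, markers, preprocess, repertoire, serum, sharing
from .simulate import SimConfig, simulate_study

__all__ = ["PipelineConfig", "run_pipeline"]

ALL_STAGES = (
    "simulate",
    "qc",
    "abundance",
    "markers",
    "de",
    "tcr",
    "sharing",
    "interactions",
    "serum",
    "report",
)


@dataclass
class PipelineConfig:
    """Pipeline thresholds (printed defaults) and run parameters."""

    outdir: str = "results"
    seed: int = 0
    stages: tuple = ALL_STAGES
    sim: dict = field(default_factory=dict)
    # printed defaults
    auroc_threshold: float = 0.75
    marker_fdr: float = 0.05
    de_fdr: float = 0.1
    abundance_fdr: float = 0.10
    enrichment_fdr: float = 0.05
    sharing_fdr: float = 0.05
    diversity_min_sequences: int = 100
    troponin_max_offset_days: float = 2.0
    n_permutations: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _config_hash(config: PipelineConfig) -> str:
    """Hash of the analysis configuration (output location excluded)."""
    blob = json.dumps(
        {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
            if k != "outdir"
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages; returns the in-memory result dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = tuple(config.stages)
    results: dict = {}

    sim_cfg = SimConfig(seed=config.seed, **config.sim)
    study = simulate_study(sim_cfg)
    results["study"] = study

    cells, counts = study.cell_table, study.counts
    if "qc" in stages:
        cells, counts, qc_report = preprocess.qc_filter(cells, counts)
        qc_report.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        results["qc_report"] = qc_report
    logcpm = preprocess.log_normalize(counts)
    pb, units = preprocess.pseudobulk_sum(counts, cells)

    if "abundance" in stages:
        ab = abundance.diff_abundance(
            cells, study.sample_meta, fdr_threshold=config.abundance_fdr
        )
        io.write_result_table(ab, outdir / "abundance.tsv")
        results["abundance"] = ab
        fractions = (
            cells.groupby(["sample", "cluster"]).size()
            / cells.groupby("sample").size()
        ).rename("fraction").reset_index()
        trop = study.sample_meta.rename(
            columns={"troponin_offset_days": "offset_days"}
        )[["sample", "troponin", "offset_days"]]
        sev = abundance.severity_regression(
            fractions, trop, max_offset_days=config.troponin_max_offset_days
        )
        io.write_result_table(sev, outdir / "severity.tsv")
        results["severity"] = sev

    if "markers" in stages:
        mk = markers.find_markers(
            logcpm, cells, pb, units, genes=study.genes,
            auroc_threshold=config.auroc_threshold, fdr_threshold=config.marker_fdr,
        )
        io.write_result_table(mk, outdir / "markers.tsv")
        results["markers"] = mk

    if "de" in stages:
        donor_of_sample = study.sample_meta.set_index("sample")["group"]
        de_frames = []
        for cl in sorted(cells["cluster"].unique()):
            sel = (units["cluster"] == cl).to_numpy()
            case = (donor_of_sample.loc[units.loc[sel, "sample"]] == "case").to_numpy()
            if case.sum() < 2 or (~case).sum() < 2:
                continue
            de_frames.append(
                de.nb_wald_de(
                    pb[sel], case.astype(float), genes=study.genes,
                    fdr_threshold=config.de_fdr, subset_label=str(cl),
                )
            )
        de_table = pd.concat(de_frames, ignore_index=True) if de_frames else pd.DataFrame()
        io.write_result_table(de_table, outdir / "de.tsv")
        results["de"] = de_table

    if "tcr" in stages:
        enr_frames, div_frames = [], []
        for donor, control in study.control_tissue_clones.items():
            heart = study.heart_bulk_clones[donor]
            enr = repertoire.tissue_enrichment(
                heart, control, tissue="heart", fdr_threshold=config.enrichment_fdr
            )
            enr["donor"] = donor
            enr_frames.append(enr)
            tum = repertoire.tissue_enrichment(
                study.tumor_clones[donor], control, tissue="tumor",
                fdr_threshold=config.enrichment_fdr,
            )
            tum["donor"] = donor
            enr_frames.append(tum)
            if heart["count"].sum() >= config.diversity_min_sequences:
                div = repertoire.hill_diversity(
                    heart, min_sequences=config.diversity_min_sequences
                )
                div["donor"] = donor
                div_frames.append(div)
        enrichment = pd.concat(enr_frames, ignore_index=True)
        diversity = pd.concat(div_frames, ignore_index=True)
        io.write_result_table(enrichment, outdir / "tcr_enrichment.tsv")
        io.write_result_table(diversity, outdir / "tcr_diversity.tsv")
        heart_enr = enrichment.loc[(enrichment["tissue"] == "heart") & enrichment["enriched"]]
        tumor_enr = enrichment.loc[(enrichment["tissue"] == "tumor") & enrichment["enriched"]]
        overlap = repertoire.heart_tumor_overlap(heart_enr, tumor_enr)
        (Path(outdir) / "heart_tumor_overlap.json").write_text(
            json.dumps({k: v for k, v in overlap.items() if k != "shared_keys"}, indent=2)
        )
        results["enrichment"] = enrichment
        results["diversity"] = diversity
        results["overlap"] = overlap

    if "sharing" in stages:
        expanded = {
            donor: set(
                repertoire.call_expanded(table).query("expanded")["clone_key"]
            )
            for donor, table in study.heart_bulk_clones.items()
        }
        flagged, _ = sharing.mark_heart_expanded_in_blood(expanded, study.blood_cells)
        share_frames = [
            sharing.subset_sharing_test(flagged, donor, fdr_threshold=config.sharing_fdr)
            for donor in flagged["donor"].unique()
        ]
        share = pd.concat(share_frames, ignore_index=True)
        io.write_result_table(share, outdir / "sharing.tsv")
        results["sharing"] = share
        designated = sim_cfg.fatal_sharing_subset
        per_donor = share.loc[share["blood_subset"] == designated].set_index("donor")
        fatal = study.sample_meta.set_index("donor")["fatal"]
        table, p = sharing.fatal_association_test(per_donor["significant"], fatal)
        results["fatal_association"] = {"table": table.tolist(), "p": p}

    if "interactions" in stages:
        from . import interactions as ia

        # synthetic curated pair list: marker genes of distinct clusters
        # stand in for a literature-curated ligand-receptor panel
        clusters = sorted(cells["cluster"].unique())
        genes = list(study.genes)
        mpc = sim_cfg.markers_per_cluster
        pair_rows = []
        for i, snd in enumerate(clusters[: min(3, len(clusters))]):
            for rcv in clusters[: min(3, len(clusters))]:
                if snd == rcv:
                    continue
                lig = genes[int(snd) * mpc] if int(snd) * mpc < len(genes) else genes[0]
                rec = genes[int(rcv) * mpc] if int(rcv) * mpc < len(genes) else genes[-1]
                pair_rows.append(
                    {"ligand": lig, "receptor": rec, "sender": snd, "receiver": rcv}
                )
        pairs = pd.DataFrame(pair_rows)
        cells_ia = cells.copy()
        cells_ia.attrs["genes"] = genes
        scored = ia.permutation_test(
            logcpm, cells_ia, pairs, n_perm=config.n_permutations, seed=config.seed
        )
        de_tables = {}
        if "de" in stages and not results.get("de", pd.DataFrame()).empty:
            de_tables = {
                cl: sub for cl, sub in results["de"].groupby("subset")
            }
            de_tables = {type(clusters[0])(k) if str(k).isdigit() else k: v
                         for k, v in de_tables.items()}
        enriched = set()
        if "abundance" in stages and not results.get("abundance", pd.DataFrame()).empty:
            ab = results["abundance"]
            enriched = set(ab.loc[ab["significant"], "cluster"])
        final = ia.filter_interactions(
            scored, de_tables, enriched, pairs[["ligand", "receptor"]], de_fdr=config.de_fdr
        )
        io.write_result_table(final, outdir / "interactions.tsv")
        results["interactions"] = final

    if "serum" in stages:
        groups = study.sample_meta.set_index("donor")["group"]
        sr = serum.serum_compare(study.serum_table, groups)
        io.write_result_table(sr, outdir / "serum.tsv")
        results["serum"] = sr

    if "report" in stages:
        manifest = {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "stages": list(stages),
            "version": __import__("importlib.metadata", fromlist=["version"]).version("myoimmune"),
            "thresholds": {
                "auroc": config.auroc_threshold,
                "marker_fdr": config.marker_fdr,
                "de_fdr": config.de_fdr,
                "abundance_fdr": config.abundance_fdr,
                "enrichment_fdr": config.enrichment_fdr,
                "sharing_fdr": config.sharing_fdr,
            },
        }
        io.write_manifest(manifest, outdir / "manifest.json")
        results["manifest"] = manifest
    return results
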