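"""End-to-end orchestration: quantify -> DE -> classify -> heterosis ->
targets/enrichment -> network, driven by one PipelineConfig.

Stages run in dependency order; each stage's outputs are written as TSV
under the configured output directory and checksummed into a run
manifest, so an unchanged config and seed reproduce identical files.
A failing stage aborts the run with the stage named; its partial outputs
keep a ``.partial`` suffix.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import diffexpr, downstream, io, modes, phenotype, quantify
from .config import PipelineConfig, log

__all__ = ["run_pipeline", "validate_inputs", "StageError", "de_status_table"]

#: the five pairwise contrasts plus the two mid-parent contrasts
CONTRASTS = (
    ("P1", "P2"),
    ("H12", "P1"), ("H12", "P2"),
    ("H21", "P1"), ("H21", "P2"),
    ("H12", "A"), ("H21", "A"),
)

_CONTRAST_KEY = {
    ("P1", "P2"): "p1_vs_p2",
    ("H12", "P1"): "h12_vs_p1", ("H12", "P2"): "h12_vs_p2",
    ("H21", "P1"): "h21_vs_p1", ("H21", "P2"): "h21_vs_p2",
    ("H12", "A"): "h12_vs_a", ("H21", "A"): "h21_vs_a",
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def de_status_table(de_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pivot per-contrast DE calls into one status row per miRNA."""
    any_key = next(iter(de_tables))
    out = pd.DataFrame({"mirna_id": de_tables[any_key]["mirna_id"]})
    for key, table in de_tables.items():
        out[key] = table.set_index("mirna_id").loc[out["mirna_id"], "status"].values
    return out


def run_de_stage(
    counts: pd.DataFrame, samples: pd.DataFrame, thresholds
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Filter low expression, add mid-parent pseudo-libraries, run all contrasts."""
    norm = diffexpr.cpm(counts)
    kept, dropped = diffexpr.filter_low_expression(norm, thresholds.filter_cpm)
    counts = counts.loc[kept]
    aug_counts, aug_samples, totals = diffexpr.with_midparent(counts, samples)
    tables = {}
    for g1, g2 in CONTRASTS:
        tables[_CONTRAST_KEY[(g1, g2)]] = diffexpr.de_contrast(
            aug_counts, aug_samples, g1, g2, thresholds, totals=totals
        )
    return tables, dropped


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Schema checks for every configured input; returns violation messages."""
    issues: list[str] = []

    def need(path, stage):
        if path is None:
            issues.append(f"{stage}: input path not set")
            return None
        if not Path(path).exists():
            issues.append(f"{stage}: missing file {path}")
            return None
        return path

    if config.run_de or config.run_classify:
        cpath = need(config.counts_path, "de")
        spath = need(config.samples_path, "de")
        if cpath and spath:
            try:
                counts = io.read_counts(cpath)
                samples = io.read_samples(spath, config.genotype_map)
            except Exception as err:  # noqa: BLE001 - report, don't raise
                issues.append(f"de: unreadable input ({err})")
            else:
                if (counts.values < 0).any():
                    issues.append("de: count matrix has negative cells")
                missing = set(counts.columns) - set(samples["sample_id"])
                if missing:
                    issues.append(f"de: samples absent from sample table: {sorted(missing)}")
                for role in ("P1", "P2", "H12", "H21"):
                    n = (samples["genotype"] == role).sum()
                    if n < 2:
                        issues.append(f"de: genotype {role} has {n} replicates (<2)")
    if config.run_heterosis:
        lpath = need(config.lay_records_path, "heterosis")
        if lpath:
            lay = io.read_lay_records(lpath)
            day_cols = [c for c in lay.columns if c.startswith("day_")]
            if not day_cols:
                issues.append("heterosis: lay table has no day_* columns")
            elif not lay[day_cols].isin((0, 1)).all().all():
                issues.append("heterosis: lay table has non-binary entries")
    if config.run_targets:
        need(config.targets_path, "targets")
        need(config.expressed_genes_path, "targets")
    if config.run_network:
        need(config.mrna_expr_path, "network")
    if config.run_quantify:
        need(config.mature_fasta, "quantify")
        for sid, fq in config.fastq_paths.items():
            if not Path(fq).exists():
                issues.append(f"quantify: missing FASTQ for {sid}: {fq}")
    return issues


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "hetmir 0.1.0",
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    def record(stage: str, outputs: dict[str, Path], counts: dict[str, int]) -> None:
        manifest["stages"][stage] = {
            "outputs": {name: _sha256(p) for name, p in outputs.items()},
            "rows": counts,
        }

    counts = samples = None
    current_stage = "init"
    try:
        if config.run_quantify:
            current_stage = "quantify"
            mature = quantify.read_mature_fasta(config.mature_fasta)
            cols, qc_frames = {}, []
            for sid, fq in sorted(config.fastq_paths.items()):
                vec, stats = quantify.quantify_library(fq, mature, config.qc)
                cols[sid] = vec
                sf = stats.as_frame()
                sf.insert(0, "sample_id", sid)
                qc_frames.append(sf)
            counts = pd.DataFrame(cols)
            counts.index.name = "mirna_id"
            cpath = out_dir / "counts.tsv"
            io.write_counts(counts, cpath)
            qpath = out_dir / "qc_report.tsv"
            pd.concat(qc_frames, ignore_index=True).to_csv(qpath, sep="\t", index=False)
            record("quantify", {"counts": cpath, "qc_report": qpath},
                   {"mirnas": len(counts)})

        if config.run_de or config.run_classify or config.run_network:
            current_stage = "load_counts"
            if counts is None:
                if config.counts_path is None:
                    raise FileNotFoundError("counts_path not set and quantify disabled")
                counts = io.read_counts(config.counts_path)
            if config.samples_path is None:
                raise FileNotFoundError("samples_path not set")
            samples = io.read_samples(config.samples_path, config.genotype_map)

        de_tables = None
        if config.run_de:
            current_stage = "de"
            de_tables, dropped = run_de_stage(counts, samples, config.de)
            outputs = {}
            for key, table in de_tables.items():
                p = out_dir / f"de_{key}.tsv"
                table.to_csv(p, sep="\t", index=False)
                outputs[key] = p
            fpath = out_dir / "filter_report.tsv"
            pd.DataFrame({"dropped_mirna": dropped}).to_csv(fpath, sep="\t", index=False)
            outputs["filter_report"] = fpath
            record("de", outputs,
                   {"tested": len(next(iter(de_tables.values()))), "dropped": len(dropped)})

        mode_table = None
        if config.run_classify:
            current_stage = "classify"
            if de_tables is None:
                raise RuntimeError("classify requires the de stage")
            status = de_status_table(de_tables)
            mode_table = modes.classify_all(status)
            summary = modes.summarize_modes(mode_table)
            mpath = out_dir / "modes.tsv"
            spath = out_dir / "mode_summary.tsv"
            mode_table.to_csv(mpath, sep="\t", index=False)
            summary.to_csv(spath, sep="\t", index=False)
            record("classify", {"modes": mpath, "summary": spath},
                   {"mode_calls": len(mode_table)})

        if config.run_heterosis:
            current_stage = "heterosis"
            lay = io.read_lay_records(config.lay_records_path)
            summary = phenotype.trait_summary(lay)
            het = phenotype.heterosis_table(summary)
            tpath = out_dir / "trait_summary.tsv"
            hpath = out_dir / "heterosis.tsv"
            summary.to_csv(tpath, sep="\t", index=False)
            het.to_csv(hpath, sep="\t", index=False)
            record("heterosis", {"traits": tpath, "heterosis": hpath},
                   {"genotypes": len(summary)})

        filtered_targets = None
        if config.run_targets:
            current_stage = "targets"
            targets = io.read_targets(config.targets_path)
            expressed = io.read_gene_list(config.expressed_genes_path)
            filtered_targets = downstream.filter_targets(
                targets, expressed, config.target_min_score
            )
            tpath = out_dir / "targets_filtered.tsv"
            filtered_targets.to_csv(tpath, sep="\t", index=False)
            outputs = {"targets_filtered": tpath}
            if config.gene_sets_path:
                sets = downstream.read_gmt(config.gene_sets_path)
                enr = downstream.hypergeom_enrich(
                    set(filtered_targets["gene_id"]), sets, expressed,
                    config.enrich_q_max,
                )
                epath = out_dir / "enrichment.tsv"
                enr.to_csv(epath, sep="\t", index=False)
                outputs["enrichment"] = epath
            record("targets", outputs, {"target_rows": len(filtered_targets)})

        if config.run_network:
            current_stage = "network"
            if filtered_targets is None:
                raise RuntimeError("network requires the targets stage")
            mrna = io.read_expression(config.mrna_expr_path)
            norm = diffexpr.cpm(counts)
            shared = [s for s in norm.columns if s in mrna.columns]
            pairs = list(
                filtered_targets[["mirna_id", "gene_id"]].itertuples(index=False)
            )
            edges = downstream.correlation_edges(
                norm[shared], mrna[shared], pairs, config.network_r_max
            )
            sif = out_dir / "network.sif"
            attrs = out_dir / "node_attributes.tsv"
            gml = out_dir / "network.graphml"
            downstream.export_network(edges, mode_table, sif, attrs, gml)
            epath = out_dir / "edges.tsv"
            pd.DataFrame([vars(e) for e in edges],
                         columns=["mirna_id", "gene_id", "r"]).to_csv(
                epath, sep="\t", index=False
            )
            record("network", {"sif": sif, "attributes": attrs, "edges": epath},
                   {"edges": len(edges)})
    except StageError:
        raise
    except Exception as err:
        # tag partial outputs of the failing stage
        for p in out_dir.glob("*.tmp"):
            p.rename(p.with_suffix(".partial"))
        raise StageError(current_stage, err) from err

    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("pipeline complete: %d stages, manifest at %s",
             len(manifest["stages"]), mpath)
    return manifest
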