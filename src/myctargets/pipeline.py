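"""End-to-end orchestration: binding -> expression -> integration -> enrichment.

``run_pipeline`` executes the full analysis on either simulated data or
files on disk, with every stage threshold carried in :class:`RunConfig` at
the study's defaults (FDR < 10%, one-million-read normalization, >= 10
reads and >= 125 nt detection, p < 0.05, one-third fold rule, 100/300-nt
pruning, 100-nt E-box window). The report echoes every parameter and seed
so a run is auditable, and each stage's output is also re-derivable through
the corresponding CLI subcommand.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import pandas as pd

from . import annotation as ann_mod
from . import chip, expression, targets as targets_mod, enrichment as enr_mod
from .simulate import SimConfig, simulate_all


@dataclass
class RunConfig:
    """All stage parameters, at the study's defaults."""

    seed: int = 0
    fdr_max_percent: float = 10.0
    normalization_target: int = 1_000_000
    min_reads: int = 10
    min_length: int = 125
    alpha: float = 0.05
    fold_fraction: float = 1.0 / 3.0
    near: int = 100
    far: int = 300
    ebox_window: int = 100
    ratio_max: float = 1.2
    step: int = 50
    window: int = 200
    shift: int = 50
    excluded_chroms: tuple[str, ...] = ()
    simulate: bool = True
    sim: SimConfig | None = None
    # file inputs, used when simulate is False
    annotation_path: str | None = None
    host_links_path: str | None = None
    genome_fasta: str | None = None
    counts_path: str | None = None
    tag_paths: dict | None = None  # condition -> BED path
    out_dir: str | None = None


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_inputs(cfg: RunConfig):
    if cfg.simulate:
        sim = cfg.sim or SimConfig(seed=cfg.seed)
        return simulate_all(sim)
    if cfg.annotation_path is None:
        ann = ann_mod.GenomeAnnotation([], {})
    else:
        ann = ann_mod.read_annotation(cfg.annotation_path, cfg.host_links_path)
    genome = ann_mod.read_fasta(cfg.genome_fasta) if cfg.genome_fasta else None
    tags = {
        cond: chip.read_tags(path, condition=cond)
        for cond, path in (cfg.tag_paths or {}).items()
    }
    counts = expression.read_counts(cfg.counts_path) if cfg.counts_path else None
    return ann, genome, None, tags, counts


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and return the report dict (also written to disk
    as report.json / report.md when ``cfg.out_dir`` is set)."""
    report: dict = {"parameters": _echo_params(cfg)}
    stage = "load_inputs"
    try:
        ann, genome, truth, tags, counts = _load_inputs(cfg)
        report["n_genes"] = len(ann)

        stage = "subsample"
        if tags:
            depth = min(len(t) for t in tags.values())
            tags = {
                cond: chip.subsample_tags(t, depth, seed=cfg.seed + i)
                for i, (cond, t) in enumerate(sorted(tags.items()))
            }
            report["tag_depth"] = depth

        stage = "call_peaks"
        peak_sets: dict[str, chip.PeakSet] = {}
        for cond, t in sorted(tags.items()):
            peak_sets[cond] = chip.call_peaks_naive(
                t, None, ann.chrom_sizes, window=cfg.window, shift=cfg.shift,
                fdr_max_percent=cfg.fdr_max_percent, experiment_id=cond,
            )
        report["peak_counts"] = {c: len(ps) for c, ps in peak_sets.items()}

        stage = "filter_specific"
        myc = peak_sets.get("specific_naive", chip.PeakSet("specific_naive", "specific_naive", []))
        controls = [ps for c, ps in peak_sets.items() if c != "specific_naive"]
        specific = chip.filter_specific_peaks(myc, controls, cfg.excluded_chroms)
        report["specific_peak_count"] = len(specific)

        stage = "consensus"
        sites = chip.build_consensus_sites([specific])
        sig_sites = [s for s in sites if s.significant]
        report["consensus_sites"] = len(sites)
        report["significant_sites"] = len(sig_sites)

        stage = "ebox_scan"
        ebox_flags = None
        if genome is not None and sites:
            ebox_flags = [
                chip.scan_ebox(genome[s.chrom], s.representative_summit, cfg.ebox_window)
                for s in sites
            ]
            report["ebox_positive_sites"] = int(sum(ebox_flags))

        stage = "tss_profile"
        if sites:
            profile = chip.tss_distance_profile(sites, ann, ebox_flags=ebox_flags)
            report["tss_profile"] = profile.to_dict(orient="list")
            report["tss_share_within_100"] = profile.attrs["share_within_100_all"]
            report["tss_share_within_1000"] = profile.attrs["share_within_1000_all"]
        else:
            report["tss_profile"] = None

        diff = None
        detected: list[str] = []
        if counts is not None:
            stage = "diffexp"
            cm = expression.normalize_counts(counts, cfg.normalization_target)
            detected = expression.filter_detected(cm, ann, cfg.min_reads, cfg.min_length)
            diff = expression.differential_test(cm, detected, alpha=cfg.alpha)
            fold = expression.classify_regulation(diff, cfg.fold_fraction)
            report["detected_genes"] = len(detected)
            report["regulation_counts"] = (
                diff["regulation"].value_counts().sort_index().to_dict()
            )
            report["fold_class_counts"] = fold.value_counts().sort_index().to_dict()

        target_table = None
        if diff is not None:
            stage = "integrate"
            assignment = targets_mod.assign_sites_to_genes(
                sig_sites, ann, diff, near=cfg.near, far=cfg.far, alpha=cfg.alpha
            )
            target_table = targets_mod.classify_direct_targets(
                sig_sites, assignment, diff, alpha=cfg.alpha
            )
            direct = target_table.index[target_table["direct_activated"]]
            categories = {
                g.gene_id: g.category for g in ann.genes if g.category is not None
            }
            report["direct_activated"] = int(target_table["direct_activated"].sum())
            report["direct_repressed"] = int(target_table["direct_repressed"].sum())
            report["bound_genes"] = int(target_table["bound"].sum())
            report["category_table"] = targets_mod.tabulate_categories(list(direct), categories)

        if diff is not None:
            stage = "gsea"
            sno_set = {
                g.gene_id
                for g in ann.genes
                if g.gene_class == "snoRNA" and g.gene_id in detected
            }
            det_diff = diff.loc[detected]
            if 0 < len(sno_set) < len(det_diff):
                ranked = enr_mod.rank_by_metric(det_diff["log2_ratio"])
                res = enr_mod.permutation_significance(
                    ranked, sno_set, n_perm=1000, seed=cfg.seed
                )
                report["snorna_gsea"] = res.to_dict()
            else:
                report["snorna_gsea"] = None
    except Exception as exc:  # noqa: BLE001 - name the failing stage
        raise StageError(stage, exc) from exc

    if cfg.out_dir:
        os.makedirs(cfg.out_dir, exist_ok=True)
        with open(os.path.join(cfg.out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=1, default=str)
        _write_markdown(report, os.path.join(cfg.out_dir, "report.md"))
        for cond, ps in peak_sets.items():
            chip.write_peaks(ps, os.path.join(cfg.out_dir, f"peaks_{cond}.bed"))
        chip.write_peaks(specific, os.path.join(cfg.out_dir, "peaks_specific.bed"))
        if diff is not None:
            expression.write_diff_result(diff, os.path.join(cfg.out_dir, "diffexp.tsv"))
        if target_table is not None:
            targets_mod.write_target_table(
                target_table, os.path.join(cfg.out_dir, "targets.tsv")
            )
    return report


def _echo_params(cfg: RunConfig) -> dict:
    params = dataclasses.asdict(cfg)
    if params.get("sim") is not None:
        params["sim"] = dataclasses.asdict(cfg.sim)
    params["excluded_chroms"] = list(cfg.excluded_chroms)
    return params


def _write_markdown(report: dict, path: str) -> None:
    lines = ["# Pipeline report", ""]
    for key, value in report.items():
        if key == "parameters":
            continue
        if isinstance(value, dict):
            lines.append(f"## {key}")
            for k, v in value.items():
                lines.append(f"- {k}: {v}")
            lines.append("")
        else:
            lines.append(f"- **{key}**: {value}")
    lines += ["", "## parameters", "```json",
              json.dumps(report["parameters"], indent=1, default=str), "```", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
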