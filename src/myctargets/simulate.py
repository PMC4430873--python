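"""Seeded generator of a toy genome with snoRNA/host architecture, ChIP tag
sets and replicated knockdown count matrices, with exported ground truth.

The generator emulates the experimental design the pipeline analyzes:

* a random genome with non-overlapping genes, including dedicated snoRNA
  host genes ("uhg" class) whose introns each carry one snoRNA record
  (host-linked), and a transcript-length distribution straddling the 125-nt
  detection cutoff;
* four ChIP tag sets — specific antibody and non-immune IgG, each in naive
  and Myc-depleted cells — with uniform background everywhere, enriched
  tags at planted true binding sites only in the specific/naive condition,
  and "sticky" background regions enriched in all four conditions (these
  must be eliminated by control subtraction downstream);
* true binding sites centered on planted canonical E-boxes near TSSs of
  designated target genes;
* negative-binomial RNA-seq counts (3 knockdown + 3 control replicates)
  where target genes drop by a planted log2 effect upon knockdown and
  intronic snoRNAs inherit their host's effect through a coupling factor.

All randomness flows from a single seed through named ``numpy``
``SeedSequence`` children, so each stage is individually reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, GeneRecord
from .chip import TagSet, CONDITIONS
from .expression import CountMatrix, CONDITION_KD, CONDITION_CTRL

#: a gene is a true direct-activated target when it is bound and its planted
#: effect reaches at least a one-third reduction
ONE_THIRD_LOG2 = math.log2(2.0 / 3.0)


@dataclass
class SimConfig:
    seed: int = 0
    # genome
    n_chroms: int = 1
    chrom_length: int = 2_000_000
    # genes
    n_genes: int = 300          # top-level genes (snoRNA records come on top)
    n_uhg: int = 6              # dedicated snoRNA host genes
    uhg_introns_min: int = 2
    uhg_introns_max: int = 16
    frac_other: float = 0.15    # non-coding/other fraction of non-uhg genes
    length_log_mean: float = 6.6   # transcript lengths ~ lognormal, straddling 125 nt
    length_log_sd: float = 1.0
    # binding
    n_true_sites: int = 40
    frac_promoter: float = 0.9
    frac_ebox: float = 0.8
    n_sticky_regions: int = 10
    site_halfwidth: int = 150
    # chip
    tags_per_condition: int = 200_000
    enrichment_fold: float = 20.0
    tag_spread: int = 100
    # expression: unaffected genes carry most of the library mass, so that
    # total-count normalization is only mildly perturbed by the knockdown
    # (as in the real design, where affected genes are a few percent of
    # detected genes); dispersion is that of tight cultured-cell triplicates
    base_mean_log_mean: float = 8.0
    base_mean_log_sd: float = 0.6
    target_mean_log_mean: float = 5.8  # targets & snoRNAs: well measured, but
    target_mean_log_sd: float = 0.5    # a small slice of the library mass
    dispersion: float = 0.002
    effect_mean: float = -1.0
    effect_sd: float = 0.3
    sno_coupling: float = 1.0
    replicates: int = 3
    library_jitter: float = 0.2

    def __post_init__(self):
        for name in ("n_chroms", "chrom_length", "n_genes", "n_uhg", "n_true_sites",
                     "tags_per_condition", "replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("frac_promoter", "frac_ebox", "frac_other"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class TruthSet:
    """Simulator ground truth, exported alongside the synthetic data."""

    true_sites: pd.DataFrame   # chrom, start, end, summit, ebox, gene_id
    sticky_regions: pd.DataFrame  # chrom, start, end
    gene_truth: pd.DataFrame   # gene_id, is_snoRNA, host_gene_id, planted_effect,
    #                            base_mean, is_bound, is_direct_target

    def to_json(self, path: str) -> None:
        payload = {
            "true_sites": self.true_sites.to_dict(orient="list"),
            "sticky_regions": self.sticky_regions.to_dict(orient="list"),
            "gene_truth": self.gene_truth.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "TruthSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            true_sites=pd.DataFrame(payload["true_sites"]),
            sticky_regions=pd.DataFrame(payload["sticky_regions"]),
            gene_truth=pd.DataFrame(payload["gene_truth"]),
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TruthSet)
            and self.true_sites.equals(other.true_sites)
            and self.sticky_regions.equals(other.sticky_regions)
            and self.gene_truth.equals(other.gene_truth)
        )


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(stream,)))


def simulate_genome_annotation(cfg: SimConfig):
    """Build the toy genome: returns (annotation, genome dict, truth).

    Genes are placed left-to-right per chromosome with random gaps (integer
    arithmetic); uhg genes get one snoRNA record per intron, host-linked.
    True binding sites are planted at promoters of designated target genes
    (the remainder intergenic), with a CACGTG hexamer written at the summit
    for the E-box-flagged fraction. Fixed seed gives byte-identical output.
    """
    rng = _rng(cfg, 1)

    # ---- gene skeletons ------------------------------------------------
    n_plain = cfg.n_genes - cfg.n_uhg
    if n_plain <= 0:
        raise ValueError("n_genes must exceed n_uhg")
    n_other = int(round(cfg.frac_other * n_plain))
    classes = ["other"] * n_other + ["protein_coding"] * (n_plain - n_other)
    rng.shuffle(classes)

    blocks = []  # (span, kind, payload)
    for ci, cls in enumerate(classes):
        length = int(np.clip(rng.lognormal(cfg.length_log_mean, cfg.length_log_sd), 60, 20_000))
        blocks.append({"kind": cls, "span": length, "tx_len": length})
    for ui in range(cfg.n_uhg):
        k = int(rng.integers(cfg.uhg_introns_min, cfg.uhg_introns_max + 1))
        # exon(100) + k * (intron hosting one snoRNA + exon(100))
        sno_lens = []
        for _ in range(k):
            if rng.random() < 0.5:
                sno_lens.append(int(rng.integers(60, 101)))    # box C/D-like
            else:
                sno_lens.append(int(rng.integers(130, 161)))   # box H/ACA-like
        span = 100 * (k + 1) + sum(sl + 100 for sl in sno_lens)
        blocks.append({"kind": "uhg", "span": span, "tx_len": 100 * (k + 1),
                       "sno_lens": sno_lens})
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    # ---- placement -----------------------------------------------------
    chrom_sizes = {f"chr{c + 1}": cfg.chrom_length for c in range(cfg.n_chroms)}
    chrom_names = list(chrom_sizes)
    per_chrom: dict[str, list[dict]] = {c: [] for c in chrom_names}
    for i, b in enumerate(blocks):
        per_chrom[chrom_names[i % cfg.n_chroms]].append(b)
    min_gap = 500
    genes: list[GeneRecord] = []
    gid = 0
    sno_id = 0
    for chrom in chrom_names:
        chrom_blocks = per_chrom[chrom]
        span_total = sum(b["span"] for b in chrom_blocks)
        free = cfg.chrom_length - span_total - min_gap * (len(chrom_blocks) + 1)
        if free < 0:
            raise ValueError("genome too small to place genes without overlap")
        # random gap allocation via sorted uniform cut points (integer)
        cuts = np.sort(rng.integers(0, free + 1, size=len(chrom_blocks)))
        gaps = np.diff(np.concatenate(([0], cuts, [free]))) + min_gap
        pos = 0
        for b, gap in zip(chrom_blocks, gaps[:-1]):
            pos += int(gap)
            start = pos
            strand = "+" if rng.random() < 0.5 else "-"
            if b["kind"] == "uhg":
                gid += 1
                host_id = f"uhg{gid}"
                genes.append(GeneRecord(host_id, chrom, start, start + b["span"], strand,
                                        "uhg", transcript_length=b["tx_len"]))
                cursor = start + 100  # first exon
                for sl in b["sno_lens"]:
                    sno_start = cursor + 50
                    sno_id += 1
                    genes.append(
                        GeneRecord(f"sno{sno_id}", chrom, sno_start, sno_start + sl,
                                   strand, "snoRNA", transcript_length=sl,
                                   host_gene_id=host_id)
                    )
                    cursor += sl + 100 + 100  # intron (sno + 100 padding) + exon
            else:
                gid += 1
                genes.append(GeneRecord(f"g{gid}", chrom, start, start + b["span"],
                                        strand, b["kind"], transcript_length=b["tx_len"]))
            pos = start + b["span"]
    ann = GenomeAnnotation(genes, chrom_sizes)

    # ---- true binding sites & sticky regions ---------------------------
    top_level = [g for g in ann.genes if g.host_gene_id is None]
    uhg_genes = [g for g in top_level if g.gene_class == "uhg"]
    coding = [g for g in top_level if g.gene_class != "uhg"]
    n_promoter = min(int(round(cfg.frac_promoter * cfg.n_true_sites)), cfg.n_true_sites)
    # all uhg genes are bound targets (their snoRNAs must respond), the rest
    # of the promoter sites go to well-expressed coding genes
    n_fill = max(n_promoter - len(uhg_genes), 0)
    eligible = [g for g in coding if g.transcript_length >= 200]
    fill_idx = rng.choice(len(eligible), size=min(n_fill, len(eligible)), replace=False)
    target_genes = uhg_genes + [eligible[i] for i in sorted(fill_idx)]
    target_genes = target_genes[:n_promoter]

    site_rows = []
    hw = cfg.site_halfwidth
    for g in target_genes:
        summit = int(g.tss + rng.integers(-30, 31))
        summit = int(np.clip(summit, hw, cfg.chrom_length - hw - 1))
        site_rows.append((g.chrom, summit - hw, summit + hw, summit, g.gene_id))

    # intergenic (distal) sites: keep clear of genes and other sites
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    for g in top_level:
        occupied[g.chrom].append((g.start - 2000, g.end + 2000))
    for chrom, s, e, *_ in site_rows:
        occupied[chrom].append((s - 2000, e + 2000))

    def place_clear(width: int) -> tuple[str, int]:
        for _ in range(1000):
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            s = int(rng.integers(0, cfg.chrom_length - width))
            if not any(s < oe and os_ < s + width for os_, oe in occupied[chrom]):
                occupied[chrom].append((s - 2000, s + width + 2000))
                return chrom, s
        raise ValueError("genome too crowded to place intergenic features")

    for _ in range(cfg.n_true_sites - len(site_rows)):
        chrom, s = place_clear(2 * hw)
        site_rows.append((chrom, s, s + 2 * hw, s + hw, ""))

    ebox_flags = rng.random(len(site_rows)) < cfg.frac_ebox
    true_sites = pd.DataFrame(
        site_rows, columns=["chrom", "start", "end", "summit", "gene_id"]
    )
    true_sites["ebox"] = ebox_flags

    sticky_rows = []
    for _ in range(cfg.n_sticky_regions):
        chrom, s = place_clear(300)
        sticky_rows.append((chrom, s, s + 300))
    sticky = pd.DataFrame(sticky_rows, columns=["chrom", "start", "end"])

    # ---- genome sequence ------------------------------------------------
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome: dict[str, str] = {}
    for chrom in chrom_names:
        arr = alphabet[rng.integers(0, 4, size=cfg.chrom_length)]
        genome[chrom] = arr.tobytes().decode("ascii")
    for _, row in true_sites[true_sites["ebox"]].iterrows():
        s = int(row["summit"])
        seq = genome[row["chrom"]]
        genome[row["chrom"]] = seq[:s] + "CACGTG" + seq[s + 6 :]

    # ---- expression truth ----------------------------------------------
    bound_ids = {g.gene_id for g in target_genes}
    effects = {}
    base_means = {}
    for g in ann.genes:
        if g.gene_id in bound_ids:
            eff = float(rng.normal(cfg.effect_mean, cfg.effect_sd))
            if g.gene_class == "uhg":
                # snoRNA host genes emulate the study condition that every
                # assayed snoRNA is strongly downregulated: their effects are
                # drawn from the same distribution truncated to at least a
                # one-third reduction
                while eff > ONE_THIRD_LOG2:
                    eff = float(rng.normal(cfg.effect_mean, cfg.effect_sd))
            effects[g.gene_id] = eff
            base_means[g.gene_id] = float(
                rng.lognormal(cfg.target_mean_log_mean, cfg.target_mean_log_sd)
            )
        else:
            effects[g.gene_id] = 0.0
            base_means[g.gene_id] = float(
                rng.lognormal(cfg.base_mean_log_mean, cfg.base_mean_log_sd)
            )
    # snoRNAs inherit the host effect through the coupling factor, and are
    # abundant transcripts in their own right
    for g in ann.genes:
        if g.host_gene_id is not None:
            effects[g.gene_id] = cfg.sno_coupling * effects[g.host_gene_id]
            base_means[g.gene_id] = float(
                rng.lognormal(cfg.target_mean_log_mean, cfg.target_mean_log_sd)
            )

    gene_truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in ann.genes],
            "is_snoRNA": [g.gene_class == "snoRNA" for g in ann.genes],
            "host_gene_id": [g.host_gene_id or "" for g in ann.genes],
            "planted_effect": [effects[g.gene_id] for g in ann.genes],
            "base_mean": [base_means[g.gene_id] for g in ann.genes],
            "is_bound": [g.gene_id in bound_ids for g in ann.genes],
        }
    )
    gene_truth["is_direct_target"] = gene_truth["is_bound"] & (
        gene_truth["planted_effect"] <= ONE_THIRD_LOG2
    )
    truth = TruthSet(true_sites, sticky, gene_truth)
    return ann, genome, truth


def simulate_chip_tags(cfg: SimConfig, truth: TruthSet) -> dict[str, TagSet]:
    """Four ChIP tag sets emulating the study's conditions.

    Uniform background everywhere; planted enrichment (``enrichment_fold``
    times the background rate over a ``2 * tag_spread`` window) at true
    sites only in ``specific_naive``; the same enrichment at sticky regions
    in all four conditions. Each condition totals exactly
    ``tags_per_condition`` tags.
    """
    rng = _rng(cfg, 2)
    genome_len = cfg.n_chroms * cfg.chrom_length
    chrom_names = [f"chr{c + 1}" for c in range(cfg.n_chroms)]
    lam_bg = cfg.tags_per_condition / genome_len

    def enriched_block(regions: pd.DataFrame, rng: np.random.Generator):
        chroms, positions = [], []
        for _, row in regions.iterrows():
            summit = int(row.get("summit", (row["start"] + row["end"]) // 2))
            n_extra = rng.poisson((cfg.enrichment_fold - 1.0) * lam_bg * 2 * cfg.tag_spread)
            offs = rng.normal(0.0, cfg.tag_spread / 2.0, size=n_extra)
            pos = np.clip(np.rint(summit + offs), 0, cfg.chrom_length - 1).astype(np.int64)
            chroms.extend([row["chrom"]] * n_extra)
            positions.append(pos)
        if positions:
            return np.array(chroms, dtype=object), np.concatenate(positions)
        return np.empty(0, dtype=object), np.empty(0, dtype=np.int64)

    out: dict[str, TagSet] = {}
    for cond in CONDITIONS:
        c_extra, p_extra = enriched_block(truth.sticky_regions, rng)
        if cond == "specific_naive":
            c2, p2 = enriched_block(truth.true_sites, rng)
            c_extra = np.concatenate((c_extra, c2))
            p_extra = np.concatenate((p_extra, p2))
        n_bg = cfg.tags_per_condition - len(p_extra)
        if n_bg < 0:
            raise ValueError("tags_per_condition too small for the planted enrichment")
        flat = rng.integers(0, genome_len, size=n_bg)
        bg_chrom_idx, bg_pos = np.divmod(flat, cfg.chrom_length)
        c_bg = np.array([chrom_names[i] for i in bg_chrom_idx], dtype=object)
        chroms = np.concatenate((c_bg, c_extra))
        positions = np.concatenate((bg_pos.astype(np.int64), p_extra))
        strands = np.array(
            ["+" if b else "-" for b in rng.random(len(positions)) < 0.5], dtype=object
        )
        order = np.lexsort((positions, chroms.astype(str)))
        out[cond] = TagSet(cond, chroms[order], positions[order], strands[order])
    return out


def simulate_counts(cfg: SimConfig, truth: TruthSet) -> CountMatrix:
    """Replicated NB counts; knockdown means scaled by 2**planted_effect.

    Library sizes are jittered by up to +/- ``library_jitter`` per sample.
    """
    rng = _rng(cfg, 3)
    gt = truth.gene_truth
    base = gt["base_mean"].to_numpy(dtype=float)
    effect = gt["planted_effect"].to_numpy(dtype=float)

    samples = [f"{CONDITION_KD}_{r + 1}" for r in range(cfg.replicates)] + [
        f"{CONDITION_CTRL}_{r + 1}" for r in range(cfg.replicates)
    ]
    conditions = pd.Series(
        [CONDITION_KD] * cfg.replicates + [CONDITION_CTRL] * cfg.replicates,
        index=samples,
    )
    lib = 1.0 + rng.uniform(-cfg.library_jitter, cfg.library_jitter, size=len(samples))
    n_nb = 1.0 / cfg.dispersion
    data = {}
    for s, cond, l in zip(samples, conditions, lib):
        mu = base * (2.0 ** effect if cond == CONDITION_KD else 1.0) * l
        p = n_nb / (n_nb + mu)
        data[s] = rng.negative_binomial(n_nb, p)
    counts = pd.DataFrame(data, index=pd.Index(gt["gene_id"], name="gene_id"))
    return CountMatrix(counts, conditions)


def simulate_null_counts(cfg: SimConfig, n_genes: int) -> CountMatrix:
    """Counts for ``n_genes`` with no condition effect (type-I calibration)."""
    rng = _rng(cfg, 4)
    gene_truth = pd.DataFrame(
        {
            "gene_id": [f"g{i + 1}" for i in range(n_genes)],
            "is_snoRNA": False,
            "host_gene_id": "",
            "planted_effect": 0.0,
            "base_mean": rng.lognormal(cfg.base_mean_log_mean, cfg.base_mean_log_sd,
                                       size=n_genes),
            "is_bound": False,
            "is_direct_target": False,
        }
    )
    truth = TruthSet(pd.DataFrame(), pd.DataFrame(), gene_truth)
    return simulate_counts(cfg, truth)


def simulate_all(cfg: SimConfig):
    """Convenience: (annotation, genome, truth, tag sets, count matrix)."""
    ann, genome, truth = simulate_genome_annotation(cfg)
    tags = simulate_chip_tags(cfg, truth)
    counts = simulate_counts(cfg, truth)
    return ann, genome, truth, tags, counts
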