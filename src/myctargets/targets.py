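"""Peak-to-gene assignment, direct-target classification, category tables.

This is the integration step that combines the binding sites (consensus
ChIP-seq sites) with the knockdown expression data to produce the core set
of directly Myc-activated genes: genes assigned to a significant binding
site whose expression drops by at least one third upon Myc knockdown.

Assignment codifies the pruning rules applied to the candidate gene lists:

1. intronic snoRNAs are replaced by their host genes (with deduplication);
2. if at least one candidate gene changes expression significantly
   (p < 0.05), all transcriptionally unaffected candidates are dropped;
3. otherwise, if an unaffected candidate's TSS lies within 100 nt of the
   site, unaffected candidates with TSS farther than 300 nt are dropped.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .annotation import GenomeAnnotation, closest_tss, interval_tss_distance
from .chip import ConsensusSite
from .expression import ALPHA, classify_regulation

#: The ten functional labels whose direct-target counts make up the
#: "ribosome biogenesis and translation" subtotal.
RIBI_TRANSLATION_LABELS = (
    "RNA Pol I activity",
    "snoRNP function",
    "40S subunit assembly, processing, maturation",
    "60S subunit assembly, processing, maturation",
    "processing of both subunits",
    "40S ribosomal subunit",
    "60S ribosomal subunit",
    "Mitochondrial ribosome",
    "Translation factors",
    "tRNA processing, maturation",
)

OTHER_LABEL = "Other, unknown"


def _overlapping_genes(site: ConsensusSite, ann: GenomeAnnotation) -> list[str]:
    return [
        g.gene_id
        for g in ann.genes
        if g.chrom == site.chrom and g.start < site.end and site.start < g.end
    ]


def assign_sites_to_genes(
    sites: Sequence[ConsensusSite],
    ann: GenomeAnnotation,
    diff: pd.DataFrame,
    near: int = 100,
    far: int = 300,
    alpha: float = ALPHA,
    candidates: str = "union",
) -> dict[str, list[str]]:
    """Assign each consensus site a pruned list of candidate target genes.

    Candidates are the genes overlapped by the site plus all nearest-TSS
    genes (ties included); ``candidates='overlap'`` restricts to overlap
    only. The pruning rules (host substitution, significant-candidate
    priority, 100/300-nt proximity rule) are applied in order; pruning never
    removes a significantly changed candidate. Returns a mapping
    ``site_id -> sorted gene list`` (possibly empty), deterministic and
    order-independent.
    """
    if candidates not in ("union", "overlap"):
        raise ValueError("candidates must be 'union' or 'overlap'")
    nearest = closest_tss([(s.chrom, s.start, s.end) for s in sites], ann)

    def significant(gene_id: str) -> bool:
        if gene_id not in diff.index:
            return False
        p = diff.at[gene_id, "p_value"]
        return bool(pd.notna(p) and p < alpha)

    out: dict[str, list[str]] = {}
    for site, hit in zip(sites, nearest):
        cand = set(_overlapping_genes(site, ann))
        if candidates == "union":
            cand |= set(hit.gene_ids)
        # rule 1: intronic snoRNA -> host gene, deduplicated
        cand = {ann.host_of(g) for g in cand}
        sig = {g for g in cand if significant(g)}
        if sig:
            # rule 2: transcriptionally affected candidates win
            cand = sig
        else:
            # rule 3: 100/300-nt proximity pruning among unaffected genes
            dist = {
                g: interval_tss_distance(site.start, site.end, ann[g].tss)
                for g in cand
            }
            if any(d <= near for d in dist.values()):
                cand = {g for g in cand if dist[g] <= far}
        out[site.site_id] = sorted(cand)
    return out


def classify_direct_targets(
    sites: Sequence[ConsensusSite],
    assignment: Mapping[str, list[str]],
    diff: pd.DataFrame,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Per-gene target calls from site assignment plus differential results.

    A gene is ``bound`` when assigned to at least one significant consensus
    site. ``direct_activated`` = bound and down by at least one third;
    ``direct_repressed`` = bound and up by at least one third; remaining
    bound genes are ``bound_only``; unbound genes with a significant
    expression change are ``indirect``. The frame covers every assigned or
    significantly changed gene.
    """
    site_by_id = {s.site_id: s for s in sites}
    assigned_sites: dict[str, list[str]] = {}
    bound: set[str] = set()
    for sid, genes in assignment.items():
        for g in genes:
            assigned_sites.setdefault(g, []).append(sid)
            if site_by_id[sid].significant:
                bound.add(g)

    fold = classify_regulation(diff)
    sig_change = diff["p_value"].notna() & (diff["p_value"] < alpha)
    genes = sorted(set(assigned_sites) | set(diff.index[sig_change]))
    rows = []
    for g in genes:
        is_bound = g in bound
        fc = fold.get(g, "undetected")
        reg = diff.at[g, "regulation"] if g in diff.index else "undetected"
        direct_act = is_bound and fc == "down_by_third"
        direct_rep = is_bound and fc == "up_by_third"
        if direct_act:
            status = "direct_activated"
        elif direct_rep:
            status = "direct_repressed"
        elif is_bound:
            status = "bound_only"
        elif g in diff.index and sig_change.get(g, False):
            status = "indirect"
        else:
            status = "unassigned"
        rows.append(
            {
                "gene_id": g,
                "bound": is_bound,
                "n_sites": len(assigned_sites.get(g, [])),
                "assigned_sites": ",".join(sorted(assigned_sites.get(g, []))),
                "regulation": reg,
                "fold_class": fc,
                "direct_activated": direct_act,
                "direct_repressed": direct_rep,
                "status": status,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def tabulate_categories(
    target_genes: Sequence[str],
    categories: Mapping[str, str],
    group: Sequence[str] = RIBI_TRANSLATION_LABELS,
) -> dict:
    """Category table over the directly activated gene set.

    Counts genes per functional-category label (uncategorized genes fall
    into ``Other, unknown``), the subtotal over the named label group
    (defaults to the ten ribosome-biogenesis/translation labels), the total,
    and the subtotal as a rounded percent of the total. Order-invariant.
    """
    counts: dict[str, int] = {}
    for g in target_genes:
        label = categories.get(g) or OTHER_LABEL
        counts[label] = counts.get(label, 0) + 1
    subtotal = sum(counts.get(label, 0) for label in group)
    total = len(target_genes)
    percent = int(round(100.0 * subtotal / total)) if total else 0
    return {
        "counts": dict(sorted(counts.items())),
        "group_labels": list(group),
        "subtotal": subtotal,
        "total": total,
        "percent": percent,
    }


def write_target_table(targets: pd.DataFrame, path: str) -> None:
    targets.rename_axis("gene_id").to_csv(path, sep="\t")


def read_category_map(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
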