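"""Genome annotation model, coordinate conventions and interval queries.

All coordinates inside the package are 0-based, half-open (BED convention).
GTF input/output converts to/from the 1-based inclusive convention at the
boundary. Each gene carries a single transcription start site (TSS): the
``start`` coordinate on the + strand, ``end - 1`` on the - strand.

Intronic snoRNAs are modelled as genes of class ``snoRNA`` whose
``host_gene_id`` names the containing host gene; downstream target-assignment
substitutes the host for the snoRNA, mirroring how intron-encoded snoRNAs
inherit the transcriptional regulation of their host.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np

GENE_CLASSES = ("protein_coding", "snoRNA", "uhg", "tRNA", "other")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneRecord:
    """A single-TSS gene model with a class label and optional host link."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_class: str = "other"
    transcript_length: int | None = None
    host_gene_id: str | None = None
    category: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(
                f"gene {self.gene_id}: unknown gene_class {self.gene_class!r}"
            )
        if self.transcript_length is None:
            object.__setattr__(self, "transcript_length", self.end - self.start)
        if self.transcript_length < 1:
            raise ValueError(f"gene {self.gene_id}: transcript_length must be >= 1")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


class GenomeAnnotation:
    """Collection of :class:`GeneRecord` plus chromosome sizes.

    Validates unique gene ids, interval containment within chromosomes, and
    host links (a host must be a different gene whose interval contains the
    linked snoRNA's interval).
    """

    def __init__(self, genes: Iterable[GeneRecord], chrom_sizes: dict[str, int] | None = None):
        self.genes: list[GeneRecord] = list(genes)
        by_id: dict[str, GeneRecord] = {}
        for g in self.genes:
            if g.gene_id in by_id:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            by_id[g.gene_id] = g
        self._by_id = by_id
        if chrom_sizes is None:
            chrom_sizes = {}
            for g in self.genes:
                chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.end)
        self.chrom_sizes = dict(chrom_sizes)
        for g in self.genes:
            size = self.chrom_sizes.get(g.chrom)
            if size is None or g.end > size:
                raise ValueError(
                    f"gene {g.gene_id} exceeds chromosome {g.chrom} bounds"
                )
            if g.host_gene_id is not None:
                host = by_id.get(g.host_gene_id)
                if host is None:
                    raise ValueError(
                        f"gene {g.gene_id}: host link to unknown gene {g.host_gene_id!r}"
                    )
                if host.gene_id == g.gene_id:
                    raise ValueError(f"gene {g.gene_id}: self host link")
                if not (host.chrom == g.chrom and host.start <= g.start and g.end <= host.end):
                    raise ValueError(
                        f"gene {g.gene_id}: host {host.gene_id} interval does not "
                        f"contain the snoRNA interval"
                    )
        self._tss_index: dict[str, tuple[np.ndarray, list[str]]] | None = None

    def __len__(self) -> int:
        return len(self.genes)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenomeAnnotation)
            and self.genes == other.genes
            and self.chrom_sizes == other.chrom_sizes
        )

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def host_of(self, gene_id: str) -> str:
        """Resolve a gene to itself, or to its host if it is an intronic snoRNA."""
        g = self._by_id[gene_id]
        return g.host_gene_id if g.host_gene_id is not None else g.gene_id

    def _tss_arrays(self) -> dict[str, tuple[np.ndarray, list[str]]]:
        # sorted TSS positions per chromosome, gene ids in the same order
        if self._tss_index is None:
            index: dict[str, tuple[np.ndarray, list[str]]] = {}
            per_chrom: dict[str, list[tuple[int, str]]] = {}
            for g in self.genes:
                per_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
            for chrom, pairs in per_chrom.items():
                pairs.sort()
                index[chrom] = (
                    np.array([p for p, _ in pairs], dtype=np.int64),
                    [gid for _, gid in pairs],
                )
            self._tss_index = index
        return self._tss_index


class TssHit(NamedTuple):
    """Closest-TSS result for one query interval.

    ``distance`` is ``None`` when the query chromosome is absent from the
    annotation ('not available' rather than silently dropped); ``gene_ids``
    then is empty. All genes tied at the minimal distance are reported.
    """

    gene_ids: tuple[str, ...]
    distance: int | None


def interval_tss_distance(start: int, end: int, tss: int) -> int:
    """Unsigned gap between a TSS and a half-open interval (0 if contained).

    The TSS is treated as the 1-nt interval ``[tss, tss + 1)``, so the gap is
    the number of bases strictly between it and the peak — symmetric under
    coordinate mirroring, and 0 for a bookended TSS.
    """
    if start <= tss < end:
        return 0
    return start - tss - 1 if tss < start else tss - end


def closest_tss(intervals: Sequence, ann: GenomeAnnotation) -> list[TssHit]:
    """Nearest annotated TSS for each query interval, ties kept.

    ``intervals`` may be any sequence of objects with ``chrom``/``start``/
    ``end`` attributes, or ``(chrom, start, end)`` tuples. Distance is 0 if a
    TSS falls inside ``[start, end)``, otherwise the gap to the nearest
    interval edge.
    """
    index = ann._tss_arrays()
    hits: list[TssHit] = []
    for iv in intervals:
        if hasattr(iv, "chrom"):
            chrom, start, end = iv.chrom, iv.start, iv.end
        else:
            chrom, start, end = iv[0], iv[1], iv[2]
        entry = index.get(chrom)
        if entry is None:
            hits.append(TssHit((), None))
            continue
        pos, gids = entry
        lo = int(np.searchsorted(pos, start, side="left"))
        hi = int(np.searchsorted(pos, end, side="left"))
        if hi > lo:  # at least one TSS inside the interval
            hits.append(TssHit(tuple(sorted(gids[lo:hi])), 0))
            continue
        # candidates: nearest TSS on each side (lo == hi here)
        best = None
        if lo > 0:
            best = start - int(pos[lo - 1]) - 1
        if lo < len(pos):
            d = int(pos[lo]) - end
            best = d if best is None else min(best, d)
        # only the two flanking TSS values can attain the minimum
        left_val = int(pos[lo - 1]) if lo > 0 else None
        right_val = int(pos[lo]) if lo < len(pos) else None
        tied = []
        for val in {left_val, right_val} - {None}:
            if interval_tss_distance(start, end, val) == best:
                a = int(np.searchsorted(pos, val, side="left"))
                b = int(np.searchsorted(pos, val, side="right"))
                tied.extend(gids[a:b])
        hits.append(TssHit(tuple(sorted(set(tied))), best))
    return hits


def remove_rrna_reads(reads: Sequence[str], rrna_refs: Sequence[str]) -> list[str]:
    """Drop reads that match an rRNA reference perfectly.

    A read is removed iff it occurs as an exact substring of any reference or
    of its reverse complement; survivors keep their input order. With an empty
    reference list the input is returned unchanged.
    """
    refs = [r.upper() for r in rrna_refs]
    refs += [reverse_complement(r) for r in refs]
    if not refs:
        return list(reads)
    return [rd for rd in reads if not any(rd.upper() in ref for ref in refs)]


# ---------------------------------------------------------------------------
# I/O: GTF (1-based inclusive), host-link TSV, FASTA


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_annotation(path: str, host_links: str | None = None) -> GenomeAnnotation:
    """Read gene records from a GTF file (``gene`` feature lines).

    Coordinates are converted from GTF's 1-based inclusive to internal 0-based
    half-open. Recognized attributes: ``gene_id`` (required), ``gene_class``
    (defaults to ``other``), ``transcript_length``, ``category``,
    ``host_gene_id``. Chromosome sizes are taken from ``##sequence-region``
    pragmas when present, else inferred from gene extents. ``host_links``
    optionally names a TSV with columns ``sno_gene_id`` and ``host_gene_id``.
    """
    genes: list[GeneRecord] = []
    chrom_sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    chrom_sizes[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GTF line {lineno}: expected 9 fields")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed GTF line {lineno}: {exc}") from None
            attr = dict(_ATTR_RE.findall(attrs))
            if "gene_id" not in attr:
                raise ValueError(f"{path}: malformed GTF line {lineno}: missing gene_id")
            genes.append(
                GeneRecord(
                    gene_id=attr["gene_id"],
                    chrom=chrom,
                    start=start_i - 1,
                    end=end_i,
                    strand=strand,
                    gene_class=attr.get("gene_class", "other"),
                    transcript_length=(
                        int(attr["transcript_length"])
                        if "transcript_length" in attr
                        else None
                    ),
                    host_gene_id=attr.get("host_gene_id") or None,
                    category=attr.get("category") or None,
                )
            )
    if host_links is not None:
        links: dict[str, str] = {}
        with open(host_links) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["sno_gene_id", "host_gene_id"]:
                raise ValueError(f"{host_links}: expected columns sno_gene_id, host_gene_id")
            for line in fh:
                if line.strip():
                    sno, host = line.rstrip("\n").split("\t")[:2]
                    links[sno] = host
        genes = [
            replace(g, host_gene_id=links[g.gene_id]) if g.gene_id in links else g
            for g in genes
        ]
    return GenomeAnnotation(genes, chrom_sizes or None)


def write_annotation(ann: GenomeAnnotation, path: str) -> None:
    """Write a GenomeAnnotation as GTF; round-trips through read_annotation."""
    with open(path, "w") as fh:
        for chrom in sorted(ann.chrom_sizes):
            fh.write(f"##sequence-region {chrom} 1 {ann.chrom_sizes[chrom]}\n")
        for g in ann.genes:
            attrs = [f'gene_id "{g.gene_id}"', f'gene_class "{g.gene_class}"',
                     f'transcript_length "{g.transcript_length}"']
            if g.host_gene_id is not None:
                attrs.append(f'host_gene_id "{g.host_gene_id}"')
            if g.category is not None:
                attrs.append(f'category "{g.category}"')
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        "myctargets",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        "; ".join(attrs) + ";",
                    ]
                )
                + "\n"
            )


def write_host_links(ann: GenomeAnnotation, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sno_gene_id\thost_gene_id\n")
        for g in ann.genes:
            if g.host_gene_id is not None:
                fh.write(f"{g.gene_id}\t{g.host_gene_id}\n")


def read_fasta(path: str) -> dict[str, str]:
    """Read a genome FASTA into a chrom -> sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")
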