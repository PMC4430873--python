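"""Peak-level ChIP-seq computations.

Covers the binding half of the pipeline: tag subsampling to equal depth, a
naive sliding-window Poisson peak caller (plumbing for synthetic end-to-end
runs; peak tables from an external caller can be ingested instead),
specificity filtering against negative controls (non-immune IgG and
knockdown ChIPs), cross-experiment consensus sites with FDR rescue, Venn
overlap counts, TSS-distance profiling, E-box scanning around summits, and
the read-ratio selector used for comparative re-analysis of an external
peak list.

Significance convention: each peak carries ``fdr_percent`` in [0, 100]; a
peak is significant when ``fdr_percent < 10`` (the study's FDR < 10% rule).
A consensus site is significant when any member peak is, and non-significant
member peaks are rescued into the site by overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GenomeAnnotation, closest_tss, interval_tss_distance

CONDITIONS = ("specific_naive", "specific_depleted", "igg_naive", "igg_depleted")

FDR_SIGNIFICANT_PERCENT = 10.0

EBOX = "CACGTG"


@dataclass(frozen=True)
class PeakRecord:
    chrom: str
    start: int
    end: int
    summit: int
    fdr_percent: float
    score: float = 0.0
    experiment_id: str = ""

    def __post_init__(self):
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"peak {self.chrom}:{self.start}-{self.end}: summit outside interval"
            )
        if not (0.0 <= self.fdr_percent <= 100.0):
            raise ValueError("fdr_percent must lie in [0, 100]")

    @property
    def significant(self) -> bool:
        return self.fdr_percent < FDR_SIGNIFICANT_PERCENT


@dataclass
class PeakSet:
    experiment_id: str
    condition: str
    peaks: list[PeakRecord] = field(default_factory=list)

    def __post_init__(self):
        self.peaks = [
            p if p.experiment_id == self.experiment_id
            else replace(p, experiment_id=self.experiment_id)
            for p in self.peaks
        ]

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class ConsensusSite:
    """Single-linkage cluster of overlapping peaks across experiments."""

    chrom: str
    start: int
    end: int
    member_peaks: list[PeakRecord]
    significant: bool
    representative_summit: int

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def experiments(self) -> frozenset[str]:
        return frozenset(p.experiment_id for p in self.member_peaks)


@dataclass
class TagSet:
    """Aligned ChIP tags: 5' positions with strand, one condition."""

    condition: str
    chroms: np.ndarray  # array of str
    positions: np.ndarray  # int64
    strands: np.ndarray  # '+'/'-'

    def __post_init__(self):
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.strands = np.asarray(self.strands, dtype=object)

    def __len__(self) -> int:
        return len(self.positions)

    def positions_by_chrom(self) -> dict[str, np.ndarray]:
        """Sorted 5' positions per chromosome."""
        out: dict[str, np.ndarray] = {}
        for chrom in pd.unique(self.chroms):
            out[chrom] = np.sort(self.positions[self.chroms == chrom])
        return out


def subsample_tags(tags: TagSet, k: int, seed: int) -> TagSet:
    """Uniform sample of exactly ``k`` tags without replacement (fixed seed).

    Mirrors the study's depth equalization: every condition is analyzed at
    the same number of singly-aligned reads.
    """
    n = len(tags)
    if k > n:
        raise ValueError(f"cannot subsample {k} tags from {n}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return TagSet(tags.condition, tags.chroms[idx], tags.positions[idx], tags.strands[idx])


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> list[tuple[int, int]]:
    order = np.argsort(starts, kind="stable")
    merged: list[tuple[int, int]] = []
    for s, e in zip(starts[order], ends[order]):
        if merged and s < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((int(s), int(e)))
    return merged


def call_peaks_naive(
    treatment: TagSet,
    background: TagSet | None,
    chrom_sizes: dict[str, int],
    window: int = 200,
    shift: int = 50,
    fdr_max_percent: float = FDR_SIGNIFICANT_PERCENT,
    local_halfwidth: int = 5000,
    candidate_p: float = 1e-2,
    experiment_id: str = "naive_caller",
) -> PeakSet:
    """Sliding-window Poisson peak caller (plumbing, not a MACS reimplementation).

    Windows of ``window`` nt advanced by ``shift`` nt are scored by the
    Poisson upper-tail probability of the treatment tag count given a
    background rate, the maximum of the genome-wide rate and a local rate
    estimated in +/- ``local_halfwidth`` nt (from the background tags when
    given, else from the treatment's genome-wide rate only). Overlapping
    candidate windows (window p-value < ``candidate_p``) are merged into
    candidate peaks; each peak is then re-scored by the Poisson upper tail
    of its total tag count over the merged interval and Benjamini-Hochberg
    across candidate peaks yields the per-peak ``fdr_percent`` — so the FDR
    is controlled at the peak level, where isolated single-window
    fluctuations cannot ride along with strong true peaks. Each peak's
    summit is the position of maximal treatment tag count (leftmost on
    ties).
    """
    if len(treatment) == 0:
        return PeakSet(experiment_id, treatment.condition, [])
    genome_len = sum(chrom_sizes.values())
    treat_by_chrom = treatment.positions_by_chrom()
    bg_by_chrom = background.positions_by_chrom() if background is not None else {}
    n_bg = len(background) if background is not None else 0
    depth_scale = len(treatment) / n_bg if n_bg else 1.0
    gw_rate = len(treatment) / genome_len  # expected treatment tags per base

    win_chrom: list[str] = []
    win_start: list[np.ndarray] = []
    win_count: list[np.ndarray] = []
    win_lam: list[np.ndarray] = []
    for chrom, size in chrom_sizes.items():
        tpos = treat_by_chrom.get(chrom, np.empty(0, dtype=np.int64))
        starts = np.arange(0, max(size - window, 0) + 1, shift, dtype=np.int64)
        counts = np.searchsorted(tpos, starts + window) - np.searchsorted(tpos, starts)
        lam = np.full(len(starts), gw_rate * window)
        if n_bg:
            bpos = bg_by_chrom.get(chrom, np.empty(0, dtype=np.int64))
            centers = starts + window // 2
            local = np.searchsorted(bpos, centers + local_halfwidth) - np.searchsorted(
                bpos, centers - local_halfwidth
            )
            local_rate = local / (2 * local_halfwidth) * depth_scale
            lam = np.maximum(lam, local_rate * window)
        win_chrom.append(chrom)
        win_start.append(starts)
        win_count.append(counts)
        win_lam.append(lam)

    # stage 1: permissive window scan -> candidate peaks
    candidates: list[tuple[str, int, int]] = []
    for chrom, starts, counts, lam in zip(win_chrom, win_start, win_count, win_lam):
        pvals = stats.poisson.sf(counts - 1, lam)
        cand = pvals < candidate_p
        if cand.any():
            candidates.extend(
                (chrom, s, e) for s, e in _merge_intervals(starts[cand], starts[cand] + window)
            )
    if not candidates:
        return PeakSet(experiment_id, treatment.condition, [])

    # stage 2: peak-level Poisson score over the merged interval, BH across peaks
    peak_counts = np.empty(len(candidates))
    peak_lam = np.empty(len(candidates))
    for i, (chrom, s, e) in enumerate(candidates):
        tpos = treat_by_chrom.get(chrom, np.empty(0, dtype=np.int64))
        peak_counts[i] = np.searchsorted(tpos, e) - np.searchsorted(tpos, s)
        lam = gw_rate * (e - s)
        if n_bg:
            bpos = bg_by_chrom.get(chrom, np.empty(0, dtype=np.int64))
            center = (s + e) // 2
            local = np.searchsorted(bpos, center + local_halfwidth) - np.searchsorted(
                bpos, center - local_halfwidth
            )
            lam = max(lam, local / (2 * local_halfwidth) * depth_scale * (e - s))
        peak_lam[i] = lam
    peak_p = stats.poisson.sf(peak_counts - 1, peak_lam)
    # BH over the full scan: the correction universe is every window position
    # tested, not just the pre-selected candidates (whose p-values are small
    # by construction), so pad with unit p-values up to the window count
    n_windows = sum(len(s) for s in win_start)
    padded = np.concatenate((peak_p, np.ones(max(n_windows - len(peak_p), 0))))
    peak_q = multipletests(padded, method="fdr_bh")[1][: len(peak_p)]

    peaks: list[PeakRecord] = []
    for (chrom, s, e), p, q in zip(candidates, peak_p, peak_q):
        if q * 100.0 >= fdr_max_percent:
            continue
        tpos = treat_by_chrom.get(chrom, np.empty(0, dtype=np.int64))
        cov = np.bincount(tpos[(tpos >= s) & (tpos < e)] - s, minlength=e - s)
        summit = s + int(np.argmax(cov)) if cov.any() else (s + e) // 2
        score = float(-np.log10(max(p, 1e-300)))
        peaks.append(PeakRecord(chrom, s, e, summit, float(q * 100.0), score, experiment_id))
    peaks.sort(key=lambda pk: (pk.chrom, pk.start))
    return PeakSet(experiment_id, treatment.condition, peaks)


def _interval_index(peaks: Iterable[PeakRecord]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome merged-interval arrays for fast overlap membership."""
    per: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        per.setdefault(p.chrom, []).append((p.start, p.end))
    out = {}
    for chrom, ivs in per.items():
        merged = _merge_intervals(
            np.array([s for s, _ in ivs]), np.array([e for _, e in ivs])
        )
        out[chrom] = (
            np.array([s for s, _ in merged], dtype=np.int64),
            np.array([e for _, e in merged], dtype=np.int64),
        )
    return out


def _overlaps_any(chrom: str, start: int, end: int,
                  index: dict[str, tuple[np.ndarray, np.ndarray]]) -> bool:
    entry = index.get(chrom)
    if entry is None:
        return False
    starts, ends = entry
    i = int(np.searchsorted(starts, end, side="left"))  # first interval starting >= end
    return i > 0 and ends[i - 1] > start


def filter_specific_peaks(
    myc_peaks: PeakSet,
    control_sets: Sequence[PeakSet],
    excluded_chroms: Sequence[str] = (),
) -> PeakSet:
    """Retain only specifically Myc-bound peaks.

    A peak is removed iff it lies on an excluded chromosome (unmapped/
    'Uextra'-like contigs) or overlaps (>= 1 bp) any peak called in a
    control ChIP (non-immune IgG, or the specific antibody in knockdown
    cells). Idempotent; with empty controls only the chromosome filter
    applies.
    """
    excluded = set(excluded_chroms)
    index = _interval_index(p for cs in control_sets for p in cs.peaks)
    kept = [
        p
        for p in myc_peaks.peaks
        if p.chrom not in excluded and not _overlaps_any(p.chrom, p.start, p.end, index)
    ]
    return PeakSet(myc_peaks.experiment_id, myc_peaks.condition, kept)


def build_consensus_sites(peak_sets: Sequence[PeakSet]) -> list[ConsensusSite]:
    """Single-linkage clustering of peaks across experiments by overlap.

    Site interval is the union of its members; a site is significant iff any
    member has FDR < 10% — non-significant peaks are thereby rescued into
    significant sites by overlap. Representative summit: the member with
    minimal FDR (ties: highest score, then leftmost summit).
    """
    all_peaks = sorted(
        (p for ps in peak_sets for p in ps.peaks), key=lambda p: (p.chrom, p.start, p.end)
    )
    sites: list[ConsensusSite] = []
    cluster: list[PeakRecord] = []

    def flush():
        if not cluster:
            return
        rep = min(cluster, key=lambda p: (p.fdr_percent, -p.score, p.summit))
        sites.append(
            ConsensusSite(
                chrom=cluster[0].chrom,
                start=min(p.start for p in cluster),
                end=max(p.end for p in cluster),
                member_peaks=list(cluster),
                significant=any(p.significant for p in cluster),
                representative_summit=rep.summit,
            )
        )

    cur_chrom, cur_end = None, -1
    for p in all_peaks:
        if p.chrom == cur_chrom and p.start < cur_end:
            cluster.append(p)
            cur_end = max(cur_end, p.end)
        else:
            flush()
            cluster = [p]
            cur_chrom, cur_end = p.chrom, p.end
    flush()
    sites.sort(key=lambda s: (s.chrom, s.start))
    return sites


def overlap_counts(peak_sets: Sequence[PeakSet]) -> dict[tuple[str, ...], int]:
    """Venn-cell counts of consensus sites by exact member-experiment subset.

    Supports 2 or 3 peak sets; keys are sorted tuples of experiment ids and
    every non-empty subset is present (possibly with count 0). Cells sum to
    the total number of consensus sites.
    """
    if not (2 <= len(peak_sets) <= 3):
        raise ValueError("overlap_counts supports 2 or 3 peak sets")
    ids = [ps.experiment_id for ps in peak_sets]
    if len(set(ids)) != len(ids):
        raise ValueError("experiment ids must be distinct")
    sites = build_consensus_sites(peak_sets)
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(ids) + 1):
        from itertools import combinations

        for combo in combinations(sorted(ids), r):
            counts[combo] = 0
    for s in sites:
        key = tuple(sorted(s.experiments))
        counts[key] += 1
    return counts


TSS_PROFILE_EDGES = list(range(0, 1000, 100)) + list(range(1000, 10001, 1000))


def tss_distance_profile(
    sites: Sequence[ConsensusSite],
    ann: GenomeAnnotation,
    ebox_flags: Sequence[bool] | None = None,
    use_summit: bool = False,
) -> pd.DataFrame:
    """Binned TSS-distance profile of binding sites (percent per bin).

    Bins: 100-nt bins up to 1,000 nt, 1,000-nt bins up to 10,000 nt, plus an
    overflow bin. Distances are interval-based by default (0 when the site
    contains a TSS); ``use_summit`` measures from the 1-nt summit instead.
    Returned frame has a row per bin with percent of all sites and, when
    ``ebox_flags`` is given, percent of the E-box-positive subset; attrs
    carry the cumulative shares within 100 nt and 1,000 nt of a TSS.
    """
    if use_summit:
        queries = [(s.chrom, s.representative_summit, s.representative_summit + 1) for s in sites]
    else:
        queries = [(s.chrom, s.start, s.end) for s in sites]
    hits = closest_tss(queries, ann)
    dists = np.array([h.distance if h.distance is not None else -1 for h in hits])
    valid = dists >= 0

    edges = np.array(TSS_PROFILE_EDGES + [np.inf])
    labels = [
        f"[{int(lo)},{int(hi)})" if np.isfinite(hi) else f">={int(lo)}"
        for lo, hi in zip(edges[:-1], edges[1:])
    ]

    def binned_percent(mask: np.ndarray) -> np.ndarray:
        n = int(mask.sum())
        if n == 0:
            return np.zeros(len(labels))
        counts, _ = np.histogram(dists[mask], bins=np.append(edges[:-1], np.inf))
        return counts / n * 100.0

    def share(mask: np.ndarray, within: int) -> float:
        n = int(mask.sum())
        return float((dists[mask] <= within).sum() / n * 100.0) if n else 0.0

    out = pd.DataFrame({"bin": labels, "all_percent": binned_percent(valid)})
    out.attrs["share_within_100_all"] = share(valid, 100)
    out.attrs["share_within_1000_all"] = share(valid, 1000)
    if ebox_flags is not None:
        emask = valid & np.asarray(ebox_flags, dtype=bool)
        out["ebox_percent"] = binned_percent(emask)
        out.attrs["share_within_100_ebox"] = share(emask, 100)
        out.attrs["share_within_1000_ebox"] = share(emask, 1000)
    return out


def scan_ebox(sequence: str, summit: int, window: int = 100) -> bool:
    """True iff a canonical E-box (CACGTG) starts within the summit window.

    Start positions considered: ``[summit - window//2, summit + window//2)``,
    clipped at the sequence ends. The motif is palindromic, so scanning the
    forward strand suffices.
    """
    if not (0 <= summit < len(sequence)):
        raise ValueError(f"summit {summit} outside sequence of length {len(sequence)}")
    half = window // 2
    lo = max(0, summit - half)
    hi = min(len(sequence), summit + half)  # exclusive bound on start positions
    region = sequence[lo : hi + len(EBOX) - 1].upper()
    i = region.find(EBOX)
    while i != -1:
        if lo + i < hi:
            return True
        i = region.find(EBOX, i + 1)
    return False


def region_read_ratio(
    regions: Sequence[tuple[str, int, int]],
    naive: TagSet,
    depleted: TagSet,
) -> pd.DataFrame:
    """Per-region naive vs depleted tag counts and their ratio.

    A tag counts toward a region when its 5' position lies in the half-open
    interval. The ratio uses a unit pseudocount in the denominator
    (``n_naive / max(n_depleted, 1)``) so zero-count regions stay finite.
    Both tag sets should be subsampled to equal depth first.
    """
    n_by = naive.positions_by_chrom()
    d_by = depleted.positions_by_chrom()
    rows = []
    for chrom, start, end in regions:
        npos = n_by.get(chrom, np.empty(0, dtype=np.int64))
        dpos = d_by.get(chrom, np.empty(0, dtype=np.int64))
        n_n = int(np.searchsorted(npos, end) - np.searchsorted(npos, start))
        n_d = int(np.searchsorted(dpos, end) - np.searchsorted(dpos, start))
        rows.append((chrom, start, end, n_n, n_d, n_n / max(n_d, 1)))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_naive", "n_depleted", "ratio"]
    )


def select_validation_regions(
    regions: pd.DataFrame,
    own_sites: Sequence[ConsensusSite] = (),
    ratio_max: float = 1.2,
    step: int = 50,
    count_col: str = "n_naive",
) -> pd.DataFrame:
    """Pick every ``step``-th region for validation from a read-ratio table.

    Retains regions with ratio <= ``ratio_max`` that do not overlap any of
    our own consensus sites, sorts by read count descending (ties by
    chromosome then start ascending) and selects ranks 1, 1+step, 1+2*step...
    Deterministic.
    """
    index = _interval_index(
        PeakRecord(s.chrom, s.start, s.end, s.start, 100.0) for s in own_sites
    )
    keep = regions[
        (regions["ratio"] <= ratio_max)
        & ~regions.apply(
            lambda r: _overlaps_any(r["chrom"], int(r["start"]), int(r["end"]), index),
            axis=1,
        )
    ]
    ranked = keep.sort_values(
        [count_col, "chrom", "start"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    return ranked.iloc[::step].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Peak / tag I/O (BED-based plain-text formats)


def write_peaks(ps: PeakSet, path: str) -> None:
    """BED6+3: name=experiment_id, score, strand '.', then summit offset,
    fdr_percent, condition."""
    with open(path, "w") as fh:
        for p in ps.peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.experiment_id}\t{p.score:.6g}\t.\t"
                f"{p.summit - p.start}\t{p.fdr_percent:.6g}\t{ps.condition}\n"
            )


def read_peaks(path: str, experiment_id: str | None = None, condition: str = "") -> PeakSet:
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name, score = f[0], int(f[1]), int(f[2]), f[3], float(f[4])
            summit = start + int(f[6]) if len(f) > 6 else (start + end) // 2
            fdr = float(f[7]) if len(f) > 7 else 0.0
            cond = f[8] if len(f) > 8 else condition
            peaks.append(PeakRecord(chrom, start, end, summit, fdr, score, name))
            condition = condition or cond
    eid = experiment_id or (peaks[0].experiment_id if peaks else "")
    return PeakSet(eid, condition, peaks)


def write_tags(ts: TagSet, path: str) -> None:
    """BED6 with 1-nt intervals at tag 5' positions."""
    with open(path, "w") as fh:
        for c, p, s in zip(ts.chroms, ts.positions, ts.strands):
            fh.write(f"{c}\t{p}\t{p + 1}\ttag\t0\t{s}\n")


def read_tags(path: str, condition: str = "") -> TagSet:
    chroms, positions, strands = [], [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            chroms.append(f[0])
            positions.append(int(f[1]))
            strands.append(f[5] if len(f) > 5 else "+")
    return TagSet(condition, np.array(chroms, dtype=object),
                  np.array(positions, dtype=np.int64), np.array(strands, dtype=object))
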