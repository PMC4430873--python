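import numpy as np
import pytest

from myctargets import chip, expression, targets as targets_mod
from myctargets.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def sim_bundle():
    """Simulator-default dataset shared across tests (fixed seed)."""
    cfg = SimConfig(seed=1)
    ann, genome, truth, tags, counts = simulate_all(cfg)
    return {
        "cfg": cfg,
        "ann": ann,
        "genome": genome,
        "truth": truth,
        "tags": tags,
        "counts": counts,
    }


@pytest.fixture(scope="session")
def e2e_results(sim_bundle):
    """Full pipeline products on the simulated dataset."""
    cfg = sim_bundle["cfg"]
    ann, truth = sim_bundle["ann"], sim_bundle["truth"]
    tags, counts = sim_bundle["tags"], sim_bundle["counts"]

    cm = expression.normalize_counts(counts)
    detected = expression.filter_detected(cm, ann)
    diff = expression.differential_test(cm, detected)

    depth = min(len(t) for t in tags.values())
    sub = {
        cond: chip.subsample_tags(t, depth, cfg.seed + i)
        for i, (cond, t) in enumerate(sorted(tags.items()))
    }
    peak_sets = {
        cond: chip.call_peaks_naive(t, None, ann.chrom_sizes, experiment_id=cond)
        for cond, t in sub.items()
    }
    specific = chip.filter_specific_peaks(
        peak_sets["specific_naive"],
        [ps for c, ps in peak_sets.items() if c != "specific_naive"],
    )
    sites = chip.build_consensus_sites([specific])
    sig_sites = [s for s in sites if s.significant]
    assignment = targets_mod.assign_sites_to_genes(sig_sites, ann, diff)
    table = targets_mod.classify_direct_targets(sig_sites, assignment, diff)
    return {
        "cm": cm,
        "detected": detected,
        "diff": diff,
        "peak_sets": peak_sets,
        "specific": specific,
        "sites": sites,
        "sig_sites": sig_sites,
        "assignment": assignment,
        "table": table,
    }


def make_peak(chrom, start, end, fdr=5.0, summit=None, score=1.0, exp="e1"):
    if summit is None:
        summit = (start + end) // 2
    return chip.PeakRecord(chrom, start, end, summit, fdr, score, exp)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
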