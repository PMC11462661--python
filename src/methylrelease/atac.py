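"""ATAC peak post-processing, fragment-length comparison and the
promoter-overlap permutation test.

All genomic intervals use 0-based half-open (BED) coordinates.  The module
starts downstream of peak calling: inputs are per-sample peak summits with
scores, chromosome sizes, a blacklist, fragment-length arrays and gene
lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .association import AssociationResult


def _blacklist_trees(blacklist: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, group in blacklist.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            zip(group["start"].astype(int), group["end"].astype(int))
        )
    return trees


def extend_and_filter_peaks(
    peaks: pd.DataFrame,
    chrom_sizes: dict[str, int],
    blacklist: pd.DataFrame | None = None,
    flank: int = 250,
) -> pd.DataFrame:
    """Extend peak summits to fixed-width intervals and filter them.

    Each summit becomes ``[summit - flank, summit + flank + 1)`` — width
    ``2 * flank + 1`` (501 bp at the default flank).  Peaks overlapping a
    blacklist interval, or extending beyond ``[0, chrom_size)``, are
    removed outright rather than clipped.
    """
    unknown = set(peaks["chrom"]) - set(chrom_sizes)
    if unknown:
        raise ValueError(f"chromosomes missing from chrom_sizes: {sorted(unknown)}")
    out = peaks.copy()
    summit = out["summit"].astype(int)
    out["start"] = summit - flank
    out["end"] = summit + flank + 1

    in_bounds = (out["start"] >= 0) & (
        out["end"] <= out["chrom"].map(chrom_sizes).astype(int)
    )
    out = out[in_bounds]

    if blacklist is not None and len(blacklist) > 0:
        trees = _blacklist_trees(blacklist)
        keep = [
            not (row.chrom in trees and trees[row.chrom].overlap(row.start, row.end))
            for row in out.itertuples()
        ]
        out = out[keep]
    return out.reset_index(drop=True)


def score_per_million(peaks: pd.DataFrame) -> pd.DataFrame:
    """Normalize peak scores to a 'score per million': scores are scaled so
    that they sum to 1e6, removing read-depth differences between samples.
    Rank order is conserved and re-application is a fixed point."""
    total = float(peaks["score"].sum())
    if not total > 0:
        raise ValueError("total peak score must be positive")
    out = peaks.copy()
    out["score"] = out["score"] * 1e6 / total
    return out


def build_consensus(peak_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Iterative-overlap consensus across peak sets.

    Among overlapping peaks the highest-scoring one is kept and every peak
    it overlaps is discarded; the procedure repeats on the remainder until
    no overlaps are left (equivalently: sweep peaks in decreasing score
    order, keeping each peak that overlaps no already-kept peak).  Ties
    break on (chrom, start, sample) for determinism.  The output is sorted
    by (chrom, start), non-overlapping, with the displaced peaks' samples
    recorded as provenance.
    """
    if not peak_sets:
        raise ValueError("need at least one peak set")
    pool = pd.concat(peak_sets, ignore_index=True)
    if "sample_id" not in pool.columns:
        pool["sample_id"] = "NA"
    pool = pool.sort_values(
        ["score", "chrom", "start", "sample_id"],
        ascending=[False, True, True, True],
        kind="stable",
    )
    kept_trees: dict[str, IntervalTree] = {}
    kept_rows = []
    for row in pool.itertuples():
        tree = kept_trees.setdefault(row.chrom, IntervalTree())
        hits = tree.overlap(row.start, row.end)
        if hits:
            for hit in hits:
                kept_rows[hit.data]["contributing_samples"].add(row.sample_id)
            continue
        idx = len(kept_rows)
        tree.addi(row.start, row.end, idx)
        kept_rows.append(
            {
                "chrom": row.chrom,
                "start": int(row.start),
                "end": int(row.end),
                "score": float(row.score),
                "sample_id": row.sample_id,
                "contributing_samples": {row.sample_id},
            }
        )
    out = pd.DataFrame(kept_rows)
    out["contributing_samples"] = out["contributing_samples"].map(
        lambda s: ",".join(sorted(map(str, s)))
    )
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def compare_fragment_lengths(
    a: np.ndarray, b: np.ndarray, alternative: str = "two-sided"
) -> AssociationResult:
    """Wilcoxon rank-sum comparison of two fragment-length samples.

    ``alternative="less"`` tests for enrichment of shorter fragments in
    ``b`` relative to ``a`` (i.e. b stochastically smaller).  Medians of
    both samples are reported in the direction field.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size == 0 or b.size == 0:
        raise ValueError("fragment-length arrays must be non-empty")
    method = "exact" if min(a.size, b.size) <= 8 else "asymptotic"
    res = stats.mannwhitneyu(b, a, alternative=alternative, method=method)
    med_a, med_b = float(np.median(a)), float(np.median(b))
    return AssociationResult(
        "fragment_length",
        "mannwhitney",
        float(res.statistic),
        float(res.pvalue),
        a.size + b.size,
        f"median_a={med_a:g} median_b={med_b:g}"
        + (" (b shorter)" if med_b < med_a else ""),
    )


@dataclass(frozen=True)
class OverlapEnrichment:
    observed_pct: float
    null_mean_pct: float
    null_sd_pct: float
    null_se_pct: float
    expected_pct: float  # closed-form hypergeometric expectation
    z: float
    enriched: bool
    n_iterations: int


def promoter_overlap_enrichment(
    universe: list[str],
    upregulated: list[str],
    promoter_accessible: list[str],
    n_iterations: int = 10,
    seed: int = 0,
) -> OverlapEnrichment:
    """Permutation test for the overlap between upregulated genes and genes
    with increased promoter accessibility.

    The observed statistic is ``|upregulated ∩ accessible| / |upregulated|``
    as a percentage.  The null redraws ``|accessible|`` genes uniformly
    without replacement from the universe ``n_iterations`` times.  The
    closed-form expectation ``100 * |accessible| / |universe|`` is reported
    for cross-checking; note the default of 10 iterations gives an unstable
    SD — use >= 1000 for a stable null spread.
    """
    universe_set = set(universe)
    up = set(upregulated)
    acc = set(promoter_accessible)
    if not up:
        raise ValueError("upregulated gene set is empty")
    if not up <= universe_set or not acc <= universe_set:
        raise ValueError("gene sets must be subsets of the universe")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")

    observed = 100.0 * len(up & acc) / len(up)
    rng = np.random.default_rng(seed)
    genes = np.array(sorted(universe_set))
    up_mask = np.isin(genes, sorted(up))
    draws = np.empty(n_iterations)
    for i in range(n_iterations):
        pick = rng.choice(genes.size, size=len(acc), replace=False)
        draws[i] = 100.0 * up_mask[pick].sum() / len(up)
    null_mean = float(draws.mean())
    null_sd = float(draws.std(ddof=1)) if n_iterations > 1 else 0.0
    expected = 100.0 * len(acc) / len(universe_set)
    z = (observed - null_mean) / null_sd if null_sd > 0 else np.inf
    return OverlapEnrichment(
        observed_pct=observed,
        null_mean_pct=null_mean,
        null_sd_pct=null_sd,
        null_se_pct=null_sd / np.sqrt(n_iterations),
        expected_pct=expected,
        z=float(z),
        enriched=bool(observed - null_mean > 2.0 * null_sd),
        n_iterations=n_iterations,
    )
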