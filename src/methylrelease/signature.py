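"""Release-quartile stratification and methylation-signature derivation.

Samples are ranked by supernatant cfDNA and split into four quartile groups;
per-probe differential methylation between the extreme quartiles (ordinary
least squares on a binary group indicator, equivalent to an equal-variance
two-sample t-test) yields a probe signature after Benjamini–Hochberg
correction.  The effect size is the mean beta of the low-release group
minus the mean beta of the high-release group, so a positive effect encodes
the observed direction "higher methylation, lower release".
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def assign_quartiles(measurements: pd.DataFrame) -> pd.DataFrame:
    """Partition samples into four cfDNA-release quartile groups.

    ``measurements`` is indexed by sample with a ``cfdna_ng_ul`` column.
    Samples are rank-ordered by cfDNA (ascending — quartile 1 holds the
    lowest releasers) with a stable secondary sort on sample identifier for
    determinism under ties.  The first ``n mod 4`` groups take the extra
    sample when n is not divisible by 4 (sizes differ by at most one).
    Returns a copy with an integer ``quartile`` column.
    """
    n = len(measurements)
    if n < 4:
        raise ValueError(f"need at least 4 samples to form quartiles, got {n}")
    ordered = measurements.sort_index(kind="stable").sort_values(
        "cfdna_ng_ul", kind="stable"
    )
    base, extra = divmod(n, 4)
    sizes = [base + (1 if q < extra else 0) for q in range(4)]
    labels = np.repeat(np.arange(1, 5), sizes)
    out = measurements.copy()
    out.loc[ordered.index, "quartile"] = labels
    out["quartile"] = out["quartile"].astype(int)
    return out


def derive_signature(
    beta: pd.DataFrame,
    measurements: pd.DataFrame,
    fdr_threshold: float = 0.01,
    min_available: float = 0.5,
) -> pd.DataFrame:
    """Derive the differentially methylated probe signature from the
    extreme release quartiles.

    For every probe an OLS fit of beta on the binary low-vs-high indicator
    is performed over quartile-1 (low release) and quartile-4 (high
    release) samples only; the slope's two-sided p-value — identical to the
    pooled-variance two-sample t-test — is BH-corrected across all tested
    probes, and probes at FDR <= ``fdr_threshold`` are returned.

    Probes are analysed complete-case; a probe with fewer than
    ``min_available`` of the extreme-quartile samples observed (or fewer
    than two values per group) is skipped and logged.

    Returns a DataFrame indexed by probe_id with columns ``effect_size``
    (mean beta low − mean beta high), ``p_value`` and ``fdr``, sorted by
    p-value.
    """
    if "quartile" not in measurements.columns:
        raise ValueError("quartiles not assigned; run assign_quartiles first")
    low_ids = measurements.index[measurements["quartile"] == 1]
    high_ids = measurements.index[measurements["quartile"] == 4]
    missing = low_ids.union(high_ids).difference(beta.index)
    if len(missing) > 0:
        raise ValueError(f"beta matrix lacks extreme-quartile samples: {list(missing)}")

    low = beta.loc[low_ids].to_numpy(dtype=float)
    high = beta.loc[high_ids].to_numpy(dtype=float)
    n_extreme = low.shape[0] + high.shape[0]

    n_low = np.sum(~np.isnan(low), axis=0)
    n_high = np.sum(~np.isnan(high), axis=0)
    usable = (
        ((n_low + n_high) >= min_available * n_extreme) & (n_low >= 2) & (n_high >= 2)
    )
    if not usable.any():
        raise ValueError("no probe has enough non-missing extreme-quartile values")
    skipped = beta.columns[~usable]
    if len(skipped) > 0:
        log.warning(
            "skipping %d probes with insufficient non-missing values", len(skipped)
        )

    mean_low = np.nanmean(low[:, usable], axis=0)
    mean_high = np.nanmean(high[:, usable], axis=0)
    # pooled-variance t-test == OLS slope test on the group indicator
    res = stats.ttest_ind(
        low[:, usable], high[:, usable], axis=0, equal_var=True, nan_policy="omit"
    )
    pvals = np.asarray(res.pvalue, dtype=float)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)

    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    table = pd.DataFrame(
        {
            "effect_size": mean_low - mean_high,
            "p_value": pvals,
            "fdr": fdr,
        },
        index=pd.Index(beta.columns[usable], name="probe_id"),
    )
    passed = table[table["fdr"] <= fdr_threshold].sort_values(
        ["p_value", "fdr"], kind="stable"
    )
    passed.attrs["fdr_threshold"] = fdr_threshold
    passed.attrs["n_tested"] = int(usable.sum())
    return passed


def signature_heatmap_order(
    beta: pd.DataFrame, signature: pd.DataFrame, measurements: pd.DataFrame
) -> tuple[list[str], list[str]]:
    """Row/column orderings for the signature heatmap.

    Samples are sorted by cfDNA release descending; signature probes by
    mean beta across samples ascending.  Ties break on identifier, so the
    ordering is deterministic.
    """
    if len(signature) == 0:
        raise ValueError("signature is empty")
    samples = (
        measurements.loc[measurements.index.intersection(beta.index)]
        .sort_index(kind="stable")
        .sort_values("cfdna_ng_ul", ascending=False, kind="stable")
        .index.tolist()
    )
    probes = beta.loc[samples, signature.index]
    mean_beta = probes.mean(axis=0, skipna=True).sort_index(kind="stable")
    probe_order = mean_beta.sort_values(kind="stable").index.tolist()
    return samples, probe_order
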