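"""Association statistics between cfDNA release and cell features.

Spearman correlations for quantitative parameters (doubling time, cycle
fractions, cell loss, aneuploidy score), Mann–Whitney tests for grouped
molecular features (MSI/MSS, CIMP positive/negative), one-sided
hypergeometric over-representation, and the arm-level aneuploidy score.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import stats

#: Canonical chromosome-arm set for the aneuploidy score: p and q arms of
#: every non-acrocentric autosome, q arms only for the acrocentric
#: chromosomes 13, 14, 15, 21 and 22 — 39 arms in total.
_ACROCENTRIC = {13, 14, 15, 21, 22}
CANONICAL_ARMS: tuple[str, ...] = tuple(
    f"{chrom}{arm}"
    for chrom in range(1, 23)
    for arm in (("q",) if chrom in _ACROCENTRIC else ("p", "q"))
)

#: Significance symbols at the screen's thresholds (note the unconventional
#: 0.005 level for three stars).
SIGNIFICANCE_LEVELS = (
    (0.001, "****"),
    (0.005, "***"),
    (0.01, "**"),
    (0.05, "*"),
)


def significance_symbol(p: float) -> str:
    for cutoff, symbol in SIGNIFICANCE_LEVELS:
        if p < cutoff:
            return symbol
    return "ns"


@dataclass(frozen=True)
class AssociationResult:
    variable: str
    test: str  # "spearman" | "mannwhitney" | "hypergeometric"
    statistic: float
    p_value: float
    n: int
    direction: str
    symbol: str = ""

    def __post_init__(self):
        object.__setattr__(self, "symbol", significance_symbol(self.p_value))


def spearman_assoc(x, y, variable: str = "") -> AssociationResult:
    """Tie-corrected Spearman rank correlation with a two-sided p-value.

    Pairs with a missing member are dropped; at least four complete pairs
    are required and constant vectors are rejected (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError(f"constant vector: Spearman rho undefined for {variable!r}")
    res = stats.spearmanr(x, y)
    direction = "positive" if res.statistic > 0 else "negative"
    return AssociationResult(
        variable, "spearman", float(res.statistic), float(res.pvalue), x.size, direction
    )


def mannwhitney_assoc(
    values, groups, variable: str = "", alternative: str = "two-sided"
) -> AssociationResult:
    """Mann–Whitney U test between two groups of per-sample values.

    The exact null distribution is used when the smaller group has at most
    8 observations; otherwise the normal approximation with tie correction
    applies.  Direction is the sign of the median difference
    (group1 − group0).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {list(labels)}")
    g0 = values[groups == labels[0]]
    g1 = values[groups == labels[1]]
    if g0.size == 0 or g1.size == 0:
        raise ValueError("one group is empty")
    method = "exact" if min(g0.size, g1.size) <= 8 else "asymptotic"
    res = stats.mannwhitneyu(g1, g0, alternative=alternative, method=method)
    med_diff = np.median(g1) - np.median(g0)
    direction = f"{labels[1]} {'higher' if med_diff > 0 else 'lower'} than {labels[0]}"
    return AssociationResult(
        variable,
        "mannwhitney",
        float(res.statistic),
        float(res.pvalue),
        g0.size + g1.size,
        direction,
    )


def hypergeometric_enrichment(
    hits_in_set: int,
    set_size: int,
    hits_total: int,
    universe: int,
    variable: str = "",
) -> AssociationResult:
    """One-sided over-representation p-value P(X >= hits_in_set) for drawing
    ``set_size`` items from a universe containing ``hits_total`` hits."""
    if not (
        0 <= hits_in_set <= min(set_size, hits_total)
        and max(set_size, hits_total) <= universe
    ):
        raise ValueError(
            "inconsistent counts: need hits_in_set <= min(set_size, hits_total) "
            "<= universe"
        )
    p = float(stats.hypergeom.sf(hits_in_set - 1, universe, hits_total, set_size))
    return AssociationResult(
        variable, "hypergeometric", float(hits_in_set), p, universe, "over"
    )


def aneuploidy_score(profile: Mapping[str, int] | pd.Series) -> int:
    """Count of chromosome arms with copy number different from 2.

    The profile must cover the canonical 39-arm set; the magnitude of the
    deviation is irrelevant (copy 0 and copy 5 both add 1).
    """
    if isinstance(profile, pd.Series):
        profile = profile.to_dict()
    missing = [arm for arm in CANONICAL_ARMS if arm not in profile]
    if missing:
        raise ValueError(f"arm profile is missing arms: {missing}")
    return int(sum(1 for arm in CANONICAL_ARMS if int(profile[arm]) != 2))


_SPEARMAN_VARIABLES = (
    "doubling_time_h",
    "frac_2N",
    "frac_S",
    "frac_4N",
    "frac_M",
    "cell_loss",
)

CIMP_POSITIVE = {"CIMP-H", "CIMP-L"}
CIMP_NEGATIVE = {"CIMP3", "CIMP4"}


def association_panel(
    samples: pd.DataFrame, arm_profiles: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Run the full association panel of a release screen.

    Spearman correlations of cfDNA against doubling time, each cell-cycle
    fraction, cell-loss index and (when arm profiles are given) the
    aneuploidy score; Mann–Whitney comparisons of cfDNA across MSI/MSS and
    CIMP-positive (H/L) vs CIMP-negative (3/4) groups.  Variables whose
    test cannot run (e.g. a constant vector) are reported with an error
    message instead of aborting the panel.
    """
    cfdna = samples["cfdna_ng_ul"].to_numpy(dtype=float)
    rows = []

    def record(result: AssociationResult):
        rows.append(
            {
                "variable": result.variable,
                "test": result.test,
                "statistic": result.statistic,
                "p_value": result.p_value,
                "n": result.n,
                "direction": result.direction,
                "symbol": result.symbol,
                "error": "",
            }
        )

    def record_error(variable: str, test: str, err: Exception):
        rows.append(
            {
                "variable": variable,
                "test": test,
                "statistic": np.nan,
                "p_value": np.nan,
                "n": 0,
                "direction": "",
                "symbol": "",
                "error": str(err),
            }
        )

    for var in _SPEARMAN_VARIABLES:
        if var not in samples.columns:
            continue
        try:
            record(spearman_assoc(cfdna, samples[var], variable=var))
        except ValueError as err:
            record_error(var, "spearman", err)

    if arm_profiles is not None:
        shared = samples.index.intersection(arm_profiles.index)
        scores = arm_profiles.loc[shared].apply(aneuploidy_score, axis=1)
        try:
            record(
                spearman_assoc(
                    samples.loc[shared, "cfdna_ng_ul"],
                    scores,
                    variable="aneuploidy_score",
                )
            )
        except ValueError as err:
            record_error("aneuploidy_score", "spearman", err)

    if "msi" in samples.columns:
        try:
            record(mannwhitney_assoc(cfdna, samples["msi"], variable="msi_vs_mss"))
        except ValueError as err:
            record_error("msi_vs_mss", "mannwhitney", err)

    if "cimp" in samples.columns:
        cimp_group = np.where(
            samples["cimp"].isin(CIMP_POSITIVE), "CIMP-positive", "CIMP-negative"
        )
        try:
            record(
                mannwhitney_assoc(
                    cfdna, cimp_group, variable="cimp_positive_vs_negative"
                )
            )
        except ValueError as err:
            record_error("cimp_positive_vs_negative", "mannwhitney", err)

    return pd.DataFrame(rows)
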