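"""SNP-fingerprint identity matching between DNA profiles.

A profile maps SNP positions to allele fractional abundances.  Alleles are
called at a fractional abundance strictly above 30%; two profiles match when
strictly more than 95% of their shared called positions carry identical
allele sets.  This mirrors cell-line authentication between nuclear DNA and
the cell-free DNA recovered from the culture supernatant.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

ALLELE_CALL_MIN_FRACTION = 0.30
MATCH_THRESHOLD = 0.95


@dataclass(frozen=True)
class IdentityMatch:
    sample_a: str
    sample_b: str
    concordance: float
    matched: bool
    n_compared: int


def call_alleles(
    profile: pd.DataFrame, min_fraction: float = ALLELE_CALL_MIN_FRACTION
) -> dict[str, frozenset[str]]:
    """Called allele set per SNP from a long-format profile
    (sample_id, snp_id, allele, fraction).

    Alleles at fraction strictly greater than ``min_fraction`` are retained;
    positions left with no surviving allele are dropped.
    """
    called = profile[profile["fraction"] > min_fraction]
    return {
        snp: frozenset(group["allele"])
        for snp, group in called.groupby("snp_id", sort=True)
    }


def profile_similarity(
    a: pd.DataFrame,
    b: pd.DataFrame,
    match_threshold: float = MATCH_THRESHOLD,
    min_fraction: float = ALLELE_CALL_MIN_FRACTION,
) -> IdentityMatch:
    """Position-level concordance between two SNP profiles.

    Concordance is the fraction of positions called in both profiles whose
    allele sets are identical; the pair is matched when concordance is
    strictly above ``match_threshold``.
    """
    calls_a = call_alleles(a, min_fraction)
    calls_b = call_alleles(b, min_fraction)
    shared = sorted(set(calls_a) & set(calls_b))
    if not shared:
        raise ValueError("profiles share no positions with called alleles")
    agree = sum(1 for snp in shared if calls_a[snp] == calls_b[snp])
    concordance = agree / len(shared)
    return IdentityMatch(
        sample_a=str(a["sample_id"].iloc[0]),
        sample_b=str(b["sample_id"].iloc[0]),
        concordance=concordance,
        matched=concordance > match_threshold,
        n_compared=len(shared),
    )
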