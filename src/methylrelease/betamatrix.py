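"""Beta-value matrix model and probe-level preprocessing.

A beta matrix is a :class:`pandas.DataFrame` with samples as rows and CpG
probes as columns; entries are methylation fractions in [0, 1] and missing
values are ``NaN`` (explicit missingness, never a sentinel number).  All
preprocessing here happens downstream of normalization: the pipeline starts
from beta values, not raw array intensities.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_EXCLUDED_CHROMOSOMES = frozenset({"chrX", "chrY", "chrM"})

ANNOTATION_COLUMNS = (
    "probe_id",
    "chrom",
    "pos",
    "cross_reactive",
    "snp_at_target",
    "gene",
    "is_promoter",
)


class BetaMatrixError(ValueError):
    """Structural problem with a beta matrix or its companions."""


def validate_beta(beta: pd.DataFrame) -> pd.DataFrame:
    """Check beta-matrix invariants and return the input unchanged.

    Raises
    ------
    BetaMatrixError
        On duplicate sample/probe identifiers or values outside [0, 1].
    """
    if beta.index.has_duplicates:
        dups = beta.index[beta.index.duplicated()].unique().tolist()
        raise BetaMatrixError(f"duplicate sample identifiers: {dups}")
    if beta.columns.has_duplicates:
        dups = beta.columns[beta.columns.duplicated()].unique().tolist()
        raise BetaMatrixError(f"duplicate probe identifiers: {dups}")
    vals = beta.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (vals < 0) | (vals > 1)
    if np.any(bad & ~np.isnan(vals)):
        raise BetaMatrixError("beta values outside [0, 1]")
    return beta


def normalize_chromosome(name: str) -> str:
    """Normalize a chromosome name to the ``chr``-prefixed form.

    ``"X"`` and ``"chrX"`` both map to ``"chrX"``; ``"MT"`` maps to
    ``"chrM"`` (the array-manifest convention).
    """
    name = str(name).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if name.upper() == "MT":
        name = "M"
    return f"chr{name}"


def mask_low_detection(
    beta: pd.DataFrame, detp: pd.DataFrame, threshold: float = 0.05
) -> pd.DataFrame:
    """Mask entries whose detection p-value exceeds ``threshold``.

    The inequality is strict: an entry with detection p exactly equal to the
    threshold is retained.  Entries that fail become missing (NaN); all
    retained entries pass through bit-identically.
    """
    if not beta.index.equals(detp.index) or not beta.columns.equals(detp.columns):
        raise BetaMatrixError(
            "beta matrix and detection p-value matrix have incongruent axes"
        )
    return beta.mask(detp > threshold)


def filter_probes(
    beta: pd.DataFrame,
    annot: pd.DataFrame,
    exclude_chromosomes: Iterable[str] = DEFAULT_EXCLUDED_CHROMOSOMES,
) -> pd.DataFrame:
    """Drop cross-reactive probes, probes with a SNP at the target CpG, and
    probes on excluded chromosomes (sex chromosomes and chrM by default).

    ``annot`` is indexed (or indexable) by ``probe_id`` with boolean columns
    ``cross_reactive`` and ``snp_at_target`` and a ``chrom`` column.  Column
    order of the surviving probes is preserved, and retained values pass
    through unchanged, so the operation is idempotent.
    """
    if "probe_id" in annot.columns:
        annot = annot.set_index("probe_id")
    missing = beta.columns.difference(annot.index)
    if len(missing) > 0:
        raise BetaMatrixError(
            f"probes without annotation records: {sorted(missing.tolist())}"
        )
    excluded = {normalize_chromosome(c) for c in exclude_chromosomes}
    ann = annot.loc[beta.columns]
    chroms = ann["chrom"].map(normalize_chromosome)
    drop = (
        ann["cross_reactive"].astype(bool)
        | ann["snp_at_target"].astype(bool)
        | chroms.isin(excluded)
    )
    keep = beta.columns[~drop.to_numpy()]
    return beta.loc[:, keep]


def intersect_platforms(
    a: pd.DataFrame, b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict two beta matrices to their shared probe set.

    Both outputs carry the shared probes in the same (lexicographic) order;
    sample axes are untouched.  An empty intersection is an error: the two
    platforms have no common CpG sites to merge on.
    """
    shared = a.columns.intersection(b.columns).sort_values()
    if len(shared) == 0:
        raise BetaMatrixError("platforms share no probes")
    return a.loc[:, shared], b.loc[:, shared]


def merge_beta_matrices(matrices: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate beta matrices sample-wise over their probe intersection.

    Sample identifiers must be pairwise disjoint.  The probe axis of the
    result is the intersection of all inputs, in lexicographic order.
    """
    matrices = list(matrices)
    if not matrices:
        raise BetaMatrixError("no matrices to merge")
    shared = matrices[0].columns
    for m in matrices[1:]:
        shared = shared.intersection(m.columns)
    if len(shared) == 0:
        raise BetaMatrixError("matrices share no probes")
    shared = shared.sort_values()
    merged = pd.concat([m.loc[:, shared] for m in matrices], axis=0)
    if merged.index.has_duplicates:
        dups = merged.index[merged.index.duplicated()].unique().tolist()
        raise BetaMatrixError(f"duplicate sample identifiers across matrices: {dups}")
    return merged
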