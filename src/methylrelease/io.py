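"""Plain-text readers and writers for every table the pipeline exchanges.

All tables are TSV with a header row.  Beta matrices are written with the
sample identifier in the first column and probe identifiers as the remaining
headers; missing entries are ``NA``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .betamatrix import validate_beta

SAMPLE_SHEET_COLUMNS = [
    "sample",
    "cfdna_ng_ul",
    "doubling_time_h",
    "frac_2N",
    "frac_S",
    "frac_4N",
    "frac_M",
    "cell_loss",
    "msi",
    "cimp",
    "truth_class",
]


def read_beta_tsv(path: str | Path) -> pd.DataFrame:
    beta = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    beta.index = beta.index.astype(str)
    beta.index.name = "sample"
    return validate_beta(beta)


def write_beta_tsv(beta: pd.DataFrame, path: str | Path) -> None:
    validate_beta(beta)
    out = beta.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    """Probe annotation: probe_id, chrom, pos, cross_reactive, snp_at_target,
    gene, is_promoter."""
    annot = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    for col in ("cross_reactive", "snp_at_target", "is_promoter"):
        if col in annot.columns:
            annot[col] = annot[col].astype(bool)
    return annot


def write_annotation_tsv(annot: pd.DataFrame, path: str | Path) -> None:
    annot.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample": str})
    return sheet.set_index("sample")


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    out = sheet.reset_index() if sheet.index.name == "sample" else sheet
    out.to_csv(path, sep="\t", index=False)


def read_arm_profiles(path: str | Path) -> pd.DataFrame:
    """Long-format arm copy numbers: sample, arm, copy_number."""
    return pd.read_csv(path, sep="\t", dtype={"sample": str, "arm": str})


def write_arm_profiles(profiles: pd.DataFrame, path: str | Path) -> None:
    profiles.to_csv(path, sep="\t", index=False)


def read_signature_tsv(path: str | Path) -> pd.DataFrame:
    sig = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    return sig.set_index("probe_id")


def write_signature_tsv(signature: pd.DataFrame, path: str | Path) -> None:
    out = signature.reset_index() if signature.index.name == "probe_id" else signature
    out.to_csv(path, sep="\t", index=False)


def read_probe_list(path: str | Path) -> list[str]:
    """One-column text file of probe identifiers (e.g. a CIMP panel)."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_probe_list(probes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f"{p}\n")


def read_gene_list(path: str | Path) -> list[str]:
    return read_probe_list(path)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                sizes[chrom] = int(size)
    return sizes


BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "summit_offset"]


def read_peaks_bed(path: str | Path) -> pd.DataFrame:
    """BED 6+1 peaks: chrom, start, end, name, score, strand, summit offset
    relative to start (column 7).  Coordinates are 0-based half-open."""
    peaks = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS, comment="#")
    peaks["summit"] = peaks["start"] + peaks["summit_offset"]
    return peaks


def write_peaks_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    out = peaks.copy()
    if "summit_offset" not in out.columns:
        out["summit_offset"] = out["summit"] - out["start"]
    out[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_snp_profile(path: str | Path) -> pd.DataFrame:
    """SNP allele fractions: sample_id, snp_id, allele, fraction."""
    return pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "snp_id": str, "allele": str}
    )


def write_snp_profile(profile: pd.DataFrame, path: str | Path) -> None:
    profile.to_csv(path, sep="\t", index=False)
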