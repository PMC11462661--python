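"""Preprocess the beta matrix: detection-p masking and probe filtering.

Entries with detection p > 0.05 become missing; cross-reactive probes,
probes with a SNP at the target CpG, and probes on chrX/chrY/chrM are
dropped.  Writes results/screen/beta_preprocessed.tsv.
"""

from pathlib import Path

from methylrelease import filter_probes, io, mask_low_detection

OUT = Path(__file__).resolve().parents[1] / "results" / "screen"


def main() -> None:
    beta = io.read_beta_tsv(OUT / "beta.tsv")
    detp = io.read_beta_tsv(OUT / "detection_p.tsv")
    annot = io.read_annotation_tsv(OUT / "annotation.tsv")

    masked = mask_low_detection(beta, detp)
    n_masked = int(masked.isna().sum().sum() - beta.isna().sum().sum())
    filtered = filter_probes(masked, annot)

    io.write_beta_tsv(filtered, OUT / "beta_preprocessed.tsv")
    print(f"masked {n_masked} entries at detection p > 0.05")
    print(f"probes: {beta.shape[1]} -> {filtered.shape[1]} after filtering")


if __name__ == "__main__":
    main()
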