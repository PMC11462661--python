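"""Association panel: cfDNA release vs biology and molecular features.

Spearman correlations for doubling time, cycle fractions, cell loss and
aneuploidy score; Mann-Whitney tests for MSI/MSS and CIMP-positive vs
CIMP-negative; significance symbols at * <0.05, ** <0.01, *** <0.005,
**** <0.001.
"""

from pathlib import Path

from methylrelease import association_panel, io

OUT = Path(__file__).resolve().parents[1] / "results" / "screen"


def main() -> None:
    samples = io.read_sample_sheet(OUT / "samples.tsv")
    arms_long = io.read_arm_profiles(OUT / "arm_profiles.tsv")
    arms = arms_long.pivot(index="sample", columns="arm", values="copy_number")

    panel = association_panel(samples, arm_profiles=arms)
    panel.to_csv(OUT / "association_panel.tsv", sep="\t", index=False)

    for row in panel.itertuples():
        if row.error:
            print(f"{row.variable:28s} error: {row.error}")
        else:
            print(
                f"{row.variable:28s} {row.test:12s} stat={row.statistic:8.3f} "
                f"p={row.p_value:9.3g} {row.symbol}"
            )


if __name__ == "__main__":
    main()
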