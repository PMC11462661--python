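"""End-to-end pipeline: simulate -> preprocess -> derive -> predict -> cimp
-> assoc, with a run manifest and a plain-text report.

Each stage writes TSV tables into the output directory; a JSON manifest
records the configuration hash, per-file checksums, seeds and stage
runtimes.  Any prefix of the stage sequence is runnable; dependencies are
validated before any computation starts.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .association import association_panel
from .betamatrix import filter_probes, mask_low_detection
from .rpmm import assign_release_class, classify_cimp, rpmm_cluster, silhouette_rank
from .signature import assign_quartiles, derive_signature
from .synthetic import SimulationConfig, generate_arm_profiles, generate_cohort

STAGES = ("simulate", "preprocess", "derive", "predict", "cimp", "assoc")


class PipelineConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


@dataclass(frozen=True)
class PipelineConfig:
    output_dir: str
    seed: int = 17
    stages: tuple[str, ...] = STAGES
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    fdr_threshold: float = 0.01
    release_max_level: int = 1
    cimp_max_level: int = 2
    arm_alteration_rate: float = 0.4
    beta_path: str | None = None
    samples_path: str | None = None
    signature_path: str | None = None
    cimp_panel_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(simulation=sim, **raw)

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineConfigError(f"unknown stages: {sorted(unknown)}")
        have_simulate = "simulate" in self.stages
        if not have_simulate and ("preprocess" in self.stages or "derive" in self.stages):
            if self.beta_path is None or self.samples_path is None:
                raise PipelineConfigError(
                    "preprocess/derive without the simulate stage require "
                    "beta_path and samples_path"
                )
        if "predict" in self.stages and "derive" not in self.stages:
            if self.signature_path is None:
                raise PipelineConfigError(
                    "predict without the derive stage requires signature_path"
                )
        if "cimp" in self.stages and not have_simulate and self.cimp_panel_path is None:
            raise PipelineConfigError(
                "cimp without the simulate stage requires cimp_panel_path"
            )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def synthetic_companions(beta, protected_probes, seed: int):
    """Detection-p matrix and probe annotation for a synthetic beta matrix.

    A small fraction of entries fail detection, a few background probes are
    flagged or placed on sex chromosomes; ``protected_probes`` (the planted
    signature and CIMP panel) stay autosomal and unflagged so the planted
    structure survives preprocessing.
    """
    rng = np.random.default_rng(seed)
    detp = pd.DataFrame(
        np.where(rng.random(beta.shape) < 0.005, rng.uniform(0.06, 1.0, beta.shape), 0.0),
        index=beta.index,
        columns=beta.columns,
    )
    planted = set(protected_probes)
    background = [p for p in beta.columns if p not in planted]
    chroms = np.array([f"chr{c}" for c in range(1, 23)])
    annot = pd.DataFrame(
        {
            "probe_id": list(beta.columns),
            "chrom": rng.choice(chroms, size=beta.shape[1]),
            "pos": rng.integers(1, 2_000_000, size=beta.shape[1]),
            "cross_reactive": False,
            "snp_at_target": False,
            "gene": "",
            "is_promoter": False,
        }
    ).set_index("probe_id")
    n_bg = len(background)
    flagged = rng.choice(background, size=max(1, n_bg // 100), replace=False)
    sexed = rng.choice(
        [p for p in background if p not in set(flagged)],
        size=max(1, n_bg // 50),
        replace=False,
    )
    annot.loc[flagged, "cross_reactive"] = True
    annot.loc[sexed, "chrom"] = "chrX"
    return detp, annot.reset_index()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "methylrelease",
        "version": "0.1.0",
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": list(config.stages),
        "runtimes_s": {},
        "checksums": {},
    }
    written: list[Path] = []

    def emit(name: str, writer, obj) -> Path:
        path = outdir / name
        writer(obj, path)
        written.append(path)
        return path

    cohort = None
    beta = samples = signature = cimp_panel = arms = None

    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        if stage == "simulate":
            cohort = generate_cohort(replace(config.simulation, seed=config.seed))
            beta, samples = cohort.beta, cohort.samples
            cimp_panel = cohort.cimp_probes
            arms_wide = generate_arm_profiles(
                len(samples), config.arm_alteration_rate, config.seed + 1
            )
            arms_wide.index = samples.index
            arms = arms_wide
            emit("beta.tsv", io.write_beta_tsv, beta)
            emit("samples.tsv", io.write_sample_sheet, samples)
            emit("truth_probes.txt", io.write_probe_list, cohort.truth_probes)
            emit("cimp_panel.txt", io.write_probe_list, cohort.cimp_probes)
            arms_long = (
                arms_wide.reset_index()
                .melt(id_vars="sample", var_name="arm", value_name="copy_number")
                .sort_values(["sample", "arm"], kind="stable")
            )
            emit("arm_profiles.tsv", io.write_arm_profiles, arms_long)
        elif stage == "preprocess":
            if beta is None:
                beta = io.read_beta_tsv(config.beta_path)
                samples = io.read_sample_sheet(config.samples_path)
            if cohort is not None:
                protected = set(cohort.truth_probes) | set(cohort.cimp_probes)
                detp, annot = synthetic_companions(beta, protected, config.seed + 2)
                beta = mask_low_detection(beta, detp)
                beta = filter_probes(beta, annot)
            emit("beta_preprocessed.tsv", io.write_beta_tsv, beta)
        elif stage == "derive":
            samples = assign_quartiles(samples)
            signature = derive_signature(beta, samples, config.fdr_threshold)
            emit("samples_quartiled.tsv", io.write_sample_sheet, samples)
            emit("signature.tsv", io.write_signature_tsv, signature)
        elif stage == "predict":
            if signature is None:
                signature = io.read_signature_tsv(config.signature_path)
            probes = [p for p in signature.index if p in beta.columns]
            sub = beta.loc[:, probes].dropna(axis=1, how="any")
            tree = rpmm_cluster(sub, max_level=config.release_max_level, seed=config.seed)
            preds = assign_release_class(tree, sub, signature)
            preds = silhouette_rank(sub, preds)
            emit(
                "predictions.tsv",
                lambda df, p: df.reset_index().to_csv(p, sep="\t", index=False),
                preds,
            )
        elif stage == "cimp":
            if cimp_panel is None:
                cimp_panel = io.read_probe_list(config.cimp_panel_path)
            cimp_calls = classify_cimp(
                beta, cimp_panel, seed=config.seed, max_level=config.cimp_max_level
            )
            emit(
                "cimp_calls.tsv",
                lambda df, p: df.reset_index().to_csv(p, sep="\t", index=False),
                cimp_calls,
            )
        elif stage == "assoc":
            panel = association_panel(samples, arm_profiles=arms)
            emit(
                "association_panel.tsv",
                lambda df, p: df.to_csv(p, sep="\t", index=False),
                panel,
            )
        manifest["runtimes_s"][stage] = round(time.perf_counter() - t0, 3)

    for path in written:
        manifest["checksums"][path.name] = _sha256(path)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def render_report(output_dir: str | Path) -> str:
    """Human-readable summary of whatever stage outputs are present."""
    outdir = Path(output_dir)
    lines = ["methylrelease run summary", "=" * 25]
    found = False

    sq = outdir / "samples_quartiled.tsv"
    if sq.exists():
        found = True
        samples = io.read_sample_sheet(sq)
        counts = samples["quartile"].value_counts().sort_index()
        lines.append(
            "cfDNA quartile groups: "
            + ", ".join(f"Q{q}={c}" for q, c in counts.items())
        )
    sig = outdir / "signature.tsv"
    if sig.exists():
        found = True
        signature = io.read_signature_tsv(sig)
        if len(signature) == 0:
            lines.append("signature: 0 probes passed FDR")
        else:
            lines.append(f"signature: {len(signature)} probes passed FDR")
    preds = outdir / "predictions.tsv"
    if preds.exists():
        found = True
        table = pd.read_csv(preds, sep="\t")
        counts = table["prediction"].value_counts().sort_index()
        lines.append(
            "predicted release classes: "
            + ", ".join(f"{k}={v}" for k, v in counts.items())
        )
    cimp = outdir / "cimp_calls.tsv"
    if cimp.exists():
        found = True
        table = pd.read_csv(cimp, sep="\t")
        counts = table["cimp_class"].value_counts().sort_index()
        lines.append(
            "CIMP classes: " + ", ".join(f"{k}={v}" for k, v in counts.items())
        )
    panel = outdir / "association_panel.tsv"
    if panel.exists():
        found = True
        table = pd.read_csv(panel, sep="\t").fillna("")
        lines.append("association panel:")
        for row in table.itertuples():
            if row.error:
                lines.append(f"  {row.variable}: error ({row.error})")
            else:
                lines.append(
                    f"  {row.variable}: {row.test} stat={row.statistic:.3f} "
                    f"p={row.p_value:.3g} {row.symbol}"
                )
    if not found:
        raise FileNotFoundError(f"no stage outputs found in {outdir}")
    return "\n".join(lines) + "\n"
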