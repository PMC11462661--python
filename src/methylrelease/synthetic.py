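"""Synthetic cohorts with the statistical structure of a cfDNA-release screen.

The generator emulates a colorectal-cancer cell-line screen in which each
line is scored for supernatant cell-free DNA (cfDNA), basic cell-biology
parameters (doubling time, cell-cycle fractions, cell-loss index) and
molecular labels (MSI status, CIMP methylation class), alongside a
methylation beta matrix carrying a planted release signature:

* cfDNA concentrations are log-uniform over a ~2-log dynamic range
  (defaults 7.8–540.8 ng/µl), rank-coupled through a Gaussian copula to a
  latent release propensity;
* biology parameters are coupled to the same latent so that Spearman
  correlations with cfDNA hit stated targets in expectation (doubling time
  positive, 2N fraction negative, S/4N/M positive, cell loss positive);
* signature probes have class-dependent beta means: low releasers are
  *hyper*-methylated by ``delta_beta`` relative to high releasers;
* MSI and CIMP-positive labels are enriched among low releasers with a
  configurable odds ratio;
* an optional panel of CIMP-informative probes carries four ordered class
  means so the recursive mixture-model stage has recoverable structure.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtr

from .association import CANONICAL_ARMS

#: Spearman targets between cfDNA and each cell-cycle fraction, as observed
#: in the screen this generator emulates (2N anti-correlated; S, 4N and
#: especially M positively correlated).
CYCLE_RHO_TARGETS = {"frac_2N": -0.31, "frac_S": 0.24, "frac_4N": 0.27, "frac_M": 0.42}

#: Baseline cell-cycle composition (2N, S, 4N, M) around which per-sample
#: fractions fluctuate.
CYCLE_BASE_FRACTIONS = np.array([0.55, 0.20, 0.18, 0.07])

_CIMP_CLASSES = ("CIMP-H", "CIMP-L", "CIMP3", "CIMP4")


def _spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula latent correlation that yields Spearman ``rho_s``."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic release-screen cohort.

    Defaults reproduce the screen's conditions: 76 lines, a 7.8–540.8 ng/µl
    cfDNA range, Spearman targets of 0.72 (doubling time) and 0.55 (cell
    loss), and a planted hyper-methylation effect of 0.3 beta units at the
    signature probes of low releasers.
    """

    n_samples: int = 76
    n_probes: int = 2000
    n_signature_probes: int = 145
    delta_beta: float = 0.3
    beta_precision: float = 30.0
    class_fraction_low: float = 0.5
    cfdna_range: tuple[float, float] = (7.8, 540.8)
    target_rho_doubling: float = 0.72
    target_rho_cellloss: float = 0.55
    msi_enrichment_odds: float = 8.0
    n_cimp_probes: int = 60
    cimp_separation: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        def fail(name: str, why: str):
            raise ValueError(f"invalid SimulationConfig field {name!r}: {why}")

        if self.n_samples < 4:
            fail("n_samples", "need at least 4 samples")
        if self.n_probes < 1:
            fail("n_probes", "must be positive")
        if not 0 <= self.n_signature_probes <= self.n_probes:
            fail("n_signature_probes", "must lie in [0, n_probes]")
        if not 0.0 <= self.delta_beta <= 1.0:
            fail("delta_beta", "must lie in [0, 1]")
        if self.beta_precision <= 0:
            fail("beta_precision", "must be positive")
        if not 0.0 < self.class_fraction_low < 1.0:
            fail("class_fraction_low", "must lie in (0, 1)")
        lo, hi = self.cfdna_range
        if not (0 < lo < hi):
            fail("cfdna_range", "requires 0 < min < max")
        for name in ("target_rho_doubling", "target_rho_cellloss"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                fail(name, "must lie in [-1, 1]")
        if self.msi_enrichment_odds <= 0:
            fail("msi_enrichment_odds", "must be positive")
        if self.n_cimp_probes < 0:
            fail("n_cimp_probes", "must be non-negative")
        if not 0.0 <= self.cimp_separation <= 1.0 / 3.0:
            fail("cimp_separation", "must lie in [0, 1/3]")


@dataclass
class SyntheticCohort:
    """A generated cohort with its ground truth.

    ``beta`` holds the signature/background probes plus the CIMP panel;
    ``samples`` is the per-sample sheet (cfDNA, biology, labels, truth
    class); ``truth_probes`` are the planted signature probes and
    ``cimp_probes`` the planted CIMP panel.
    """

    beta: pd.DataFrame
    samples: pd.DataFrame
    truth_probes: list[str]
    cimp_probes: list[str]
    config: SimulationConfig = field(repr=False)


def _coupled_latent(
    rng: np.random.Generator, z: np.ndarray, rho_s: float
) -> np.ndarray:
    r = _spearman_to_pearson(rho_s)
    eps = rng.standard_normal(z.shape)
    return r * z + np.sqrt(max(0.0, 1.0 - r * r)) * eps


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort under ``config``.

    Low-releaser samples carry signature-probe beta means higher by
    ``delta_beta`` than high releasers; background probes share
    class-independent means; cfDNA is log-uniform over ``cfdna_range`` with
    its ranks tied to the latent class and biology parameters.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    # latent release propensity: high z -> high cfDNA
    z = rng.standard_normal(n)
    lo, hi = config.cfdna_range
    cfdna = np.exp(np.log(lo) + ndtr(z) * (np.log(hi) - np.log(lo)))

    n_low = int(round(config.class_fraction_low * n))
    n_low = min(max(n_low, 1), n - 1)
    order = np.argsort(z, kind="stable")
    is_low = np.zeros(n, dtype=bool)
    is_low[order[:n_low]] = True

    w_doub = _coupled_latent(rng, z, config.target_rho_doubling)
    doubling_h = 20.0 + 100.0 * ndtr(w_doub)
    w_loss = _coupled_latent(rng, z, config.target_rho_cellloss)
    cell_loss = 0.02 + 0.38 * ndtr(w_loss)

    # cell-cycle fractions through a softmax of jittered log-fractions, so
    # they sum to 1 exactly while staying rank-coupled to the latent
    raw = np.empty((n, 4))
    for j, phase in enumerate(CYCLE_RHO_TARGETS):
        w = _coupled_latent(rng, z, CYCLE_RHO_TARGETS[phase])
        raw[:, j] = np.log(CYCLE_BASE_FRACTIONS[j]) + 0.4 * w
    fracs = np.exp(raw)
    fracs /= fracs.sum(axis=1, keepdims=True)

    # molecular labels with logistic enrichment among low releasers
    log_odds = np.log(config.msi_enrichment_odds)
    p_msi = expit(logit(0.12) + log_odds * is_low)
    msi = np.where(rng.random(n) < p_msi, "MSI", "MSS")
    p_cimp_pos = expit(logit(0.25) + log_odds * is_low)
    cimp_pos = rng.random(n) < p_cimp_pos
    sub = rng.random(n) < 0.5
    cimp = np.where(
        cimp_pos,
        np.where(sub, "CIMP-H", "CIMP-L"),
        np.where(sub, "CIMP3", "CIMP4"),
    )

    # beta matrix: background probes share means; signature probes shift by
    # delta_beta in low releasers
    probe_ids = [f"cg{i:07d}" for i in range(config.n_probes)]
    sig_idx = rng.choice(config.n_probes, size=config.n_signature_probes, replace=False)
    sig_idx = np.sort(sig_idx)
    truth_probes = [probe_ids[i] for i in sig_idx]

    means = np.tile(rng.uniform(0.05, 0.95, size=config.n_probes), (n, 1))
    base_sig = rng.uniform(0.05, 0.95 - config.delta_beta, size=config.n_signature_probes)
    means[:, sig_idx] = base_sig
    means[np.ix_(is_low, sig_idx)] = base_sig + config.delta_beta

    prec = config.beta_precision
    values = rng.beta(means * prec, (1.0 - means) * prec)

    # CIMP panel: four ordered class means, spaced by cimp_separation
    cimp_probes = [f"cgCIMP{i:05d}" for i in range(config.n_cimp_probes)]
    if config.n_cimp_probes:
        offsets = {"CIMP-H": 1.5, "CIMP-L": 0.5, "CIMP3": -0.5, "CIMP4": -1.5}
        class_mean = np.array([0.5 + offsets[c] * config.cimp_separation for c in cimp])
        cimp_means = np.tile(class_mean[:, None], (1, config.n_cimp_probes))
        cimp_values = rng.beta(cimp_means * prec, (1.0 - cimp_means) * prec)
        values = np.hstack([values, cimp_values])

    beta = pd.DataFrame(values, index=sample_ids, columns=probe_ids + cimp_probes)
    beta.index.name = "sample"

    samples = pd.DataFrame(
        {
            "cfdna_ng_ul": cfdna,
            "doubling_time_h": doubling_h,
            "frac_2N": fracs[:, 0],
            "frac_S": fracs[:, 1],
            "frac_4N": fracs[:, 2],
            "frac_M": fracs[:, 3],
            "cell_loss": cell_loss,
            "msi": msi,
            "cimp": cimp,
            "truth_class": np.where(is_low, "low", "high"),
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    return SyntheticCohort(beta, samples, truth_probes, cimp_probes, config)


def generate_arm_profiles(
    n_samples: int, alteration_rate: float, seed: int
) -> pd.DataFrame:
    """Arm-level copy numbers over the canonical 39-arm set.

    Each arm is independently non-diploid with probability
    ``alteration_rate``; altered arms draw a copy number from {0, 1, 3, 4}.
    Returns a samples × arms integer DataFrame.
    """
    if not 0.0 <= alteration_rate <= 1.0:
        raise ValueError("alteration_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_arms = len(CANONICAL_ARMS)
    altered = rng.random((n_samples, n_arms)) < alteration_rate
    alt_copies = rng.choice([0, 1, 3, 4], size=(n_samples, n_arms))
    copies = np.where(altered, alt_copies, 2)
    return pd.DataFrame(
        copies,
        index=pd.Index([f"S{i + 1:03d}" for i in range(n_samples)], name="sample"),
        columns=list(CANONICAL_ARMS),
    )


def generate_snp_profiles(
    n_positions: int, concordance: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two SNP fractional-abundance profiles sharing exactly
    ``round(concordance * n_positions)`` allele calls.

    Profiles are long-format (sample_id, snp_id, allele, fraction).
    Concordant positions carry the same called genotype in both profiles;
    discordant positions carry a different major allele in the second.
    Minor alleles are emitted below the 30% calling threshold.
    """
    if not 0.0 <= concordance <= 1.0:
        raise ValueError("concordance must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    alleles = np.array(list("ACGT"))
    n_discord = n_positions - int(round(concordance * n_positions))
    discordant = set(rng.choice(n_positions, size=n_discord, replace=False))

    rows_a, rows_b = [], []
    for i in range(n_positions):
        snp = f"rs{i + 1:06d}"
        major, alt = rng.choice(4, size=2, replace=False)
        if rng.random() < 0.35:  # heterozygous
            geno_a = [(alleles[major], 0.52), (alleles[alt], 0.45)]
        else:
            geno_a = [(alleles[major], 0.97), (alleles[alt], 0.03)]
        if i in discordant:
            other = (major + 1 + rng.integers(3)) % 4
            if other == major:
                other = (major + 1) % 4
            geno_b = [(alleles[other], 0.97), (alleles[major], 0.03)]
        else:
            geno_b = geno_a
        rows_a += [("nuclear", snp, a, f) for a, f in geno_a]
        rows_b += [("supernatant", snp, a, f) for a, f in geno_b]

    cols = ["sample_id", "snp_id", "allele", "fraction"]
    return pd.DataFrame(rows_a, columns=cols), pd.DataFrame(rows_b, columns=cols)


def generate_fragment_lengths(
    n: int, median_shift: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two fragment-length samples from a common distribution, the second
    shifted shorter by ``median_shift`` base pairs.

    The base distribution is log-normal around ~180 bp, mimicking the
    mononucleosomal mode of accessible-chromatin fragment profiles.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    base_a = rng.lognormal(mean=np.log(180.0), sigma=0.35, size=n)
    base_b = rng.lognormal(mean=np.log(180.0), sigma=0.35, size=n)
    a = np.maximum(1, np.rint(base_a)).astype(int)
    b = np.maximum(1, np.rint(base_b - median_shift)).astype(int)
    return a, b
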