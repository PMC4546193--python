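"""Forward simulation of MSRE qPCR cohorts with the study's statistical structure.

The generator draws a true methylation fraction per sample x gene, converts
it to four digest Ct values through the assay's physical model, and emits
tidy Ct records, sample metadata, mutation calls, and the hidden truth for
parameter-recovery tests.

Per gene x group the true fraction follows a Beta distribution matched to
the reported mean +/- SD.  Where the study also reports the fraction of
methylated cases at the 15% threshold, the cell is *prevalence-anchored*:
exactly the reconstructed number of samples is assigned methylated status
(levels drawn from the moment-matched Beta truncated above/below the
threshold), because a two-parameter Beta matched to mean and SD alone
systematically misstates tail mass at the call threshold.  Synchronous
LGD-CRC lesion pairs share a patient-level Gaussian latent (copula) in both
methylated status and methylation level.

Forward model per assay, with true fraction ``m``, refractory fraction
``r`` and base cycle ``b``::

    ct_mo  = b                           + e
    ct_ms  = b - log2(m (1-r) + r)       + e
    ct_md  = b - log2((1-m)(1-r) + r)    + e
    ct_msd = b - log2(r)                 + e

with independent Gaussian cycle noise ``e`` per reaction; relative amounts
below 2^-40 of the mock (the 40-cycle PCR detection floor) are emitted as
no-amplification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._tables import (
    GROUP_MOMENTS,
    GROUP_SIZES,
    GROUPS,
    MUTATION_COUNTS,
    PANEL_GENES,
    SIGNATURE_GENES,
    TOP10_NORMAL_PREVALENCE,
    TOP10_PREVALENCE,
    TOP17_PREVALENCE,
)
from .calls_signature import reconstruct_counts
from .mutations import ASSAYS

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "beta_from_moments",
    "default_anchor_fractions",
    "default_mutation_rates",
    "simulate_cohort",
    "simulate_pairs",
]

logger = logging.getLogger(__name__)

#: Relative-amount detection floor (40 PCR cycles below the mock digest).
DETECTION_FLOOR = 2.0 ** -40


def beta_from_moments(mean_pct: float, sd_pct: float) -> tuple[float, float]:
    """Beta(alpha, beta) with the requested mean and SD on the percent scale.

    An SD at or beyond the Bernoulli bound ``sqrt(mean (100 - mean))`` is
    infeasible for a Beta; it is shrunk to 0.95x the bound and logged.
    """
    if not 0.0 < mean_pct < 100.0:
        raise ValueError(f"mean must lie strictly in (0, 100), got {mean_pct}")
    mu = mean_pct / 100.0
    sigma = sd_pct / 100.0
    bound = np.sqrt(mu * (1.0 - mu))
    if sigma >= bound:
        logger.warning(
            "sd %.4g infeasible for mean %.4g; shrunk to 0.95x bound", sd_pct, mean_pct
        )
        sigma = 0.95 * bound
    nu = mu * (1.0 - mu) / sigma**2 - 1.0
    return mu * nu, (1.0 - mu) * nu


class _Margin:
    """Per-cell level distribution: Beta(a, b) or a point mass."""

    def __init__(self, mean_pct: float, sd_pct: float):
        if mean_pct <= 0.0:
            self.const: float | None = 0.0
        elif mean_pct >= 100.0:
            self.const = 1.0
        elif sd_pct <= 0.0:
            self.const = mean_pct / 100.0
        else:
            self.const = None
            self.a, self.b = beta_from_moments(mean_pct, sd_pct)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.const is not None:
            return np.full_like(u, self.const)
        return stats.beta.ppf(u, self.a, self.b)

    def cdf(self, x: float) -> float:
        if self.const is not None:
            return 1.0 if self.const <= x else 0.0
        return float(stats.beta.cdf(x, self.a, self.b))


def default_anchor_fractions() -> dict[tuple[str, str], float]:
    """Prevalence anchors (gene, group) -> methylated fraction of cases.

    Built by inverting every printed per-group "methylated cases (%)" value
    to its integer count: all ten groups for the ten signature genes, and
    the three non-metastatic tumor groups for the seven further genes of
    the single-gene comparison table.
    """
    anchors: dict[tuple[str, str], float] = {}
    for gene, row in TOP10_PREVALENCE.items():
        for grp in ("LGD", "HGD", "CRC", "MCRC"):
            n = GROUP_SIZES[grp]
            anchors[(gene, grp)] = reconstruct_counts(row[grp], n) / n
    for gene, row in TOP10_NORMAL_PREVALENCE.items():
        for grp in ("Y", "N", "CN", "F", "UCi", "UCa"):
            n = GROUP_SIZES[grp]
            anchors[(gene, grp)] = reconstruct_counts(row[grp], n) / n
    for gene, row in TOP17_PREVALENCE.items():
        if gene in TOP10_PREVALENCE:
            continue
        for grp in ("LGD", "HGD", "CRC"):
            n = GROUP_SIZES[grp]
            anchors[(gene, grp)] = reconstruct_counts(row[grp], n) / n
    return anchors


def default_mutation_rates() -> dict[str, dict[str, float]]:
    """Per assay x group Bernoulli mutation rates from the study's counts."""
    rates: dict[str, dict[str, float]] = {a: {g: 0.0 for g in GROUPS} for a in ASSAYS}
    for grp in ("LGD", "HGD", "CRC"):
        row = MUTATION_COUNTS[grp]
        for assay in ASSAYS:
            rates[assay][grp] = row[assay] / row["n"]
    return rates


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults reproduce the study: group sizes, per-gene x group methylation
    moments, printed prevalence anchors at the 15% threshold, seven
    synchronous LGD-CRC pairs, and the observed mutation rates.  Ct noise
    (0.15 cycles, typical qPCR replicate scatter), the base cycle
    distribution (24 +/- 1 cycles for 500 ng input), and the mean
    digestion-refractory fraction (1%) are assay-level choices.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(GROUP_SIZES))
    gene_moments: dict[str, tuple[tuple[float, float], ...]] = field(
        default_factory=lambda: dict(GROUP_MOMENTS)
    )
    anchor_fractions: dict[tuple[str, str], float] | None = None  # None -> defaults
    anchor_exact_counts: bool = True  # exact counts vs Bernoulli per sample
    threshold_tau: float = 0.15
    ct_noise_sd: float = 0.15
    base_ct_mean: float = 24.0
    base_ct_sd: float = 1.0
    refractory_mean: float = 0.01
    n_pairs: int = 7
    pair_rho: float = 0.7
    mutation_rates: dict[str, dict[str, float]] | None = None  # None -> defaults

    def resolved_anchors(self) -> dict[tuple[str, str], float]:
        if self.anchor_fractions is not None:
            return self.anchor_fractions
        return default_anchor_fractions()

    def resolved_mutation_rates(self) -> dict[str, dict[str, float]]:
        if self.mutation_rates is not None:
            return self.mutation_rates
        return default_mutation_rates()

    def zero_noise(self) -> "SimulationConfig":
        """Noise-free variant: no cycle noise and no refractory DNA, so the
        fraction formulas invert the forward model exactly."""
        return replace(self, ct_noise_sd=0.0, refractory_mean=0.0)


@dataclass
class SyntheticCohort:
    """Simulated cohort: emitted tables plus the hidden truth.

    ``ct`` is a tidy Ct record table (sample_id, gene, digest, ct), ``meta``
    the sample metadata indexed by sample_id, ``mutations`` per-sample
    mutation statuses, and ``truth`` the generating fractions aligned 1:1
    with the emitted assays.
    """

    ct: pd.DataFrame
    meta: pd.DataFrame
    mutations: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig
    seed: int


def _build_meta(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for grp in GROUPS:
        n = config.group_sizes.get(grp, 0)
        for i in range(n):
            sid = f"{grp}{i + 1:02d}"
            rows.append({"sample_id": sid, "patient_id": f"P_{sid}", "group": grp,
                         "pair_id": None})
    meta = pd.DataFrame(rows).set_index("sample_id", drop=False)
    # synchronous pairs: first n_pairs LGD and CRC samples come from the
    # same patients
    n_pairs = min(config.n_pairs, config.group_sizes.get("LGD", 0),
                  config.group_sizes.get("CRC", 0))
    for i in range(n_pairs):
        lgd, crc = f"LGD{i + 1:02d}", f"CRC{i + 1:02d}"
        pid = f"P_pair{i + 1:02d}"
        meta.loc[[lgd, crc], "patient_id"] = pid
        meta.loc[[lgd, crc], "pair_id"] = f"pr{i + 1}"
    return meta


def _pair_latents(rng: np.random.Generator, meta: pd.DataFrame, n_genes: int,
                  rho: float) -> np.ndarray:
    """Sample x gene standard-normal latents; pair members share a patient
    component with correlation ``rho``."""
    n = len(meta)
    eps = rng.standard_normal((n, n_genes))
    paired = meta["pair_id"].notna().to_numpy()
    if not paired.any() or rho <= 0:
        return eps
    z = eps.copy()
    patients = meta["patient_id"].to_numpy()
    for pid in np.unique(patients[paired]):
        idx = np.flatnonzero(patients == pid)
        w = rng.standard_normal(n_genes)
        z[idx] = np.sqrt(rho) * w + np.sqrt(1.0 - rho) * eps[idx]
    return z


def _truncated_ppf(margin: _Margin, u: np.ndarray, tau: float, above: bool) -> np.ndarray:
    """Quantiles of the margin truncated above (methylated) or below ``tau``."""
    if margin.const is not None:
        return np.full_like(u, margin.const)
    c = margin.cdf(tau)
    if above:
        if c >= 1.0:  # no mass above threshold; degenerate guard
            return np.full_like(u, tau)
        return stats.beta.ppf(c + (1.0 - c) * u, margin.a, margin.b)
    if c <= 0.0:
        return np.full_like(u, tau)
    return stats.beta.ppf(c * u, margin.a, margin.b)


def _draw_levels(
    rng: np.random.Generator,
    config: SimulationConfig,
    meta: pd.DataFrame,
    genes: list[str],
) -> pd.DataFrame:
    """True methylation fractions per sample x gene (samples as index)."""
    anchors = config.resolved_anchors()
    tau = config.threshold_tau
    n_genes = len(genes)
    z_status = _pair_latents(rng, meta, n_genes, config.pair_rho)
    z_level = _pair_latents(rng, meta, n_genes, config.pair_rho)
    u_status = stats.norm.cdf(z_status)
    u_level = stats.norm.cdf(z_level)

    m = np.empty((len(meta), n_genes))
    group_arr = meta["group"].to_numpy()
    for j, gene in enumerate(genes):
        moments = config.gene_moments[gene]
        for gi, grp in enumerate(GROUPS):
            idx = np.flatnonzero(group_arr == grp)
            if idx.size == 0:
                continue
            margin = _Margin(*moments[gi])
            uj, vj = u_status[idx, j], u_level[idx, j]
            pi = anchors.get((gene, grp))
            if pi is None or margin.const is not None:
                m[idx, j] = margin.ppf(vj)
                continue
            if config.anchor_exact_counts:
                k = int(round(pi * idx.size))
                order = np.argsort(uj)
                methylated = np.zeros(idx.size, dtype=bool)
                if k > 0:
                    methylated[order[-k:]] = True
            else:
                methylated = uj > 1.0 - pi
            vals = np.empty(idx.size)
            vals[methylated] = _truncated_ppf(margin, vj[methylated], tau, above=True)
            vals[~methylated] = _truncated_ppf(margin, vj[~methylated], tau, above=False)
            m[idx, j] = vals
    return pd.DataFrame(m, index=meta.index, columns=genes)


def _emit_ct(
    rng: np.random.Generator,
    config: SimulationConfig,
    levels: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward model: true fractions -> tidy Ct table + truth table."""
    n, g = levels.shape
    m = levels.to_numpy()
    if config.refractory_mean > 0:
        mu_r = config.refractory_mean
        r = rng.beta(1.0, (1.0 - mu_r) / mu_r, size=(n, g))
    else:
        r = np.zeros((n, g))
    b = rng.normal(config.base_ct_mean, config.base_ct_sd, size=(n, g))

    rel = {
        "Mo": np.ones((n, g)),
        "Ms": m * (1.0 - r) + r,
        "Md": (1.0 - m) * (1.0 - r) + r,
        "Msd": r,
    }
    frames = []
    for digest, amount in rel.items():
        with np.errstate(divide="ignore"):
            ct = b - np.log2(amount)
        if config.ct_noise_sd > 0:
            ct = ct + rng.normal(0.0, config.ct_noise_sd, size=(n, g))
        ct = np.where(amount < DETECTION_FLOOR, np.nan, ct)
        df = pd.DataFrame(ct, index=levels.index, columns=levels.columns)
        tidy = df.stack(future_stack=True).rename("ct").reset_index()
        tidy.columns = ["sample_id", "gene", "ct"]
        tidy["digest"] = digest
        frames.append(tidy[["sample_id", "gene", "digest", "ct"]])
    ct_table = pd.concat(frames, ignore_index=True)

    truth = levels.stack(future_stack=True).rename("true_m").reset_index()
    truth.columns = ["sample_id", "gene", "true_m"]
    truth["refractory"] = pd.DataFrame(r, index=levels.index, columns=levels.columns) \
        .stack(future_stack=True).to_numpy()
    return ct_table, truth


def _draw_mutations(
    rng: np.random.Generator, config: SimulationConfig, meta: pd.DataFrame
) -> pd.DataFrame:
    rates = config.resolved_mutation_rates()
    rows = []
    for sid, grp in zip(meta["sample_id"], meta["group"]):
        for assay in ASSAYS:
            p = rates.get(assay, {}).get(grp, 0.0)
            status = "MUT" if rng.random() < p else "WT"
            rows.append({"sample_id": sid, "assay": assay, "status": status})
    return pd.DataFrame(rows)


def simulate_cohort(config: SimulationConfig = SimulationConfig(),
                    seed: int = 0) -> SyntheticCohort:
    """Simulate one full cohort, reproducibly from ``seed``."""
    rng = np.random.default_rng(seed)
    meta = _build_meta(config)
    genes = [g for g in PANEL_GENES if g in config.gene_moments]
    levels = _draw_levels(rng, config, meta, genes)
    ct, truth = _emit_ct(rng, config, levels)
    muts = _draw_mutations(rng, config, meta)
    return SyntheticCohort(ct, meta, muts, truth, config, seed)


def simulate_pairs(
    n_pairs: int = 7,
    shift_pct: float = 15.0,
    genes: tuple[str, ...] = SIGNATURE_GENES,
    rho: float = 0.7,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synchronous LGD-CRC pairs with a configured LGD-minus-CRC mean shift.

    LGD lesions draw from each gene's LGD Beta margin; the synchronous CRC
    lesion draws from a Beta with the mean lowered by ``shift_pct``
    percentage points (same SD, floored at 0.5%), coupled to its partner
    through a Gaussian copula with correlation ``rho``.  Returns a
    (fractions, meta) pair ready for
    :func:`methylprofiler.cohort_stats.paired_comparison`.
    """
    rng = np.random.default_rng(seed)
    lgd_idx = GROUPS.index("LGD")
    rows_meta = []
    frac = {}
    for i in range(n_pairs):
        pid, pr = f"P{i + 1:02d}", f"pr{i + 1}"
        for grp in ("LGD", "CRC"):
            sid = f"{grp}{i + 1:02d}"
            rows_meta.append({"sample_id": sid, "patient_id": pid, "group": grp,
                              "pair_id": pr})
            frac[sid] = np.empty(len(genes))
    meta = pd.DataFrame(rows_meta).set_index("sample_id", drop=False)

    for j, gene in enumerate(genes):
        mean_lgd, sd = GROUP_MOMENTS[gene][lgd_idx]
        m_lgd = _Margin(mean_lgd, sd)
        m_crc = _Margin(max(mean_lgd - shift_pct, 0.5), sd)
        for i in range(n_pairs):
            w = rng.standard_normal()
            z = np.sqrt(rho) * w + np.sqrt(1.0 - rho) * rng.standard_normal(2)
            u = stats.norm.cdf(z)
            frac[f"LGD{i + 1:02d}"][j] = m_lgd.ppf(np.array([u[0]]))[0]
            frac[f"CRC{i + 1:02d}"][j] = m_crc.ppf(np.array([u[1]]))[0]
    fractions = pd.DataFrame.from_dict(frac, orient="index", columns=list(genes))
    fractions.index.name = "sample_id"
    return fractions, meta
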