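"""Synthetic-data generators with known ground truth.

Two generators cover the inputs of the full inference chain:

* :func:`gen_two_sample_gwas` produces per-gene two-sample GWAS summary
  statistics (SNP-transcript and SNP-CRP associations with a block LD
  structure) under configurable pleiotropy regimes, for exercising the
  Mendelian-randomization engine.

* :func:`gen_cohort` produces an individual-level cohort: a 3-level ordinal
  early-life exposure, confounders (age, sex, centre, BMI), a lognormal
  C-reactive protein outcome left-censored at centre-specific detection
  limits, a transcription matrix in which a designated gene block mediates
  part of the exposure effect, and per-CpG methylation/transcription
  triplets drawn from known causal groups A-E.

Every generated quantity with downstream relevance is recorded in a
:class:`TruthRecord`, enabling recovery-based testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream

CAUSAL_GROUPS = ("A", "B", "C", "D", "E")


# ---------------------------------------------------------------------------
# configs and truth record
# ---------------------------------------------------------------------------

@dataclass
class GwasSimConfig:
    """Configuration of the two-sample GWAS summary-statistic generator.

    ``theta`` is the true causal effect of each gene's transcription on the
    (log-scale) outcome; a scalar applies to every gene. ``mean_f`` sets the
    expected instrument F-statistic (the emulated eQTL study is strongly
    powered, F around 97). Sample sizes default to the emulated consortium
    scales (~31.7k for the expression GWAS, ~148k for the outcome GWAS).
    """

    n_genes: int = 10
    J: int = 39
    theta: float | np.ndarray = 0.0
    pleiotropy_mode: str = "none"  # none | balanced | directional | inside_violating
    pleiotropy_sd: float = 0.0
    ld_block_rho: float = 0.3
    ld_block_size: int = 5
    mean_f: float = 97.0
    n_exp: int = 31_684
    n_out: int = 148_164
    seed: int = 0

    def validate(self) -> None:
        if self.J < 2:
            raise ValueError("J must be >= 2")
        if not (0.0 <= self.ld_block_rho < 1.0):
            raise ValueError("ld_block_rho must be in [0, 1)")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "inside_violating"):
            raise ValueError(f"invalid pleiotropy_mode: {self.pleiotropy_mode!r}")
        if self.mean_f <= 1:
            raise ValueError("mean_f must exceed 1")

    def theta_vector(self) -> np.ndarray:
        th = np.asarray(self.theta, dtype=float)
        if th.ndim == 0:
            return np.full(self.n_genes, float(th))
        if th.shape != (self.n_genes,):
            raise ValueError("theta must be scalar or length n_genes")
        return th


@dataclass
class CohortSimConfig:
    """Configuration of the cohort generator.

    Defaults emulate the study conditions: exposure prevalences 17.8 / 55.9 /
    26.3 % for high / intermediate / low parental occupational position, a
    2-unit (low vs high) total effect of +22.6 % on the geometric mean of
    CRP of which 69 % is mediated by a 10-gene transcription block, and
    centre-specific CRP detection limits of 1, 2 and 3 mg/L that censor
    about 60 % of individuals.
    """

    n: int = 2000
    exposure_probs: tuple[float, float, float] = (0.178, 0.559, 0.263)
    n_genes: int = 120
    n_cpgs: int = 50
    n_mediator_genes: int = 10
    mediated_fraction: float = 0.69
    total_effect_pct: float = 22.6
    group_assignment: dict[str, str] | None = None
    censor_limits: dict[int, float] = field(default_factory=lambda: {0: 1.0, 1: 2.0, 2: 3.0})
    centre_probs: tuple[float, ...] | None = None
    path_coef: float = 0.3
    mediator_x_coef: float = 0.4
    mediator_block_rho: float = 0.5
    noise_sds: dict[str, float] = field(
        default_factory=lambda: {"crp": 1.15, "transcript": 1.0, "meth": 1.0}
    )
    crp_log_mean: float = 0.28
    bmi_coef: float = 0.05
    age_coef: float = 0.008
    sex_coef: float = 0.15
    centre_coefs: tuple[float, ...] = (0.0, 0.05, -0.05)
    background_block_size: int = 10
    background_block_rho: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        p = np.asarray(self.exposure_probs, dtype=float)
        if p.shape != (3,) or abs(p.sum() - 1.0) > 1e-12 or (p < 0).any():
            raise ValueError("exposure_probs must be a 3-vector of probabilities summing to 1")
        if not (0.0 <= self.mediated_fraction <= 1.0):
            raise ValueError("mediated_fraction must lie in [0, 1]")
        if self.n_genes < self.n_mediator_genes + self.n_cpgs:
            raise ValueError("n_genes must be >= n_mediator_genes + n_cpgs")
        for lim in self.censor_limits.values():
            if lim <= 0:
                raise ValueError("detection limits must be positive")
        if self.group_assignment is not None:
            bad = set(self.group_assignment.values()) - set(CAUSAL_GROUPS)
            if bad:
                raise ValueError(f"unknown causal groups: {sorted(bad)}")

    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def cpg_names(self) -> list[str]:
        return [f"cg{i:07d}" for i in range(self.n_cpgs)]


@dataclass
class TruthRecord:
    """Ground truth of a synthetic dataset (the acceptance oracle).

    ``true_pm`` always satisfies the log-ratio identity
    ``ln(1 + nie_pct/100) / ln(1 + te_pct/100)`` exactly.
    """

    theta_g: dict[str, float] | None = None
    true_te_pct: float | None = None
    true_nie_pct: float | None = None
    true_pm: float | None = None
    mediator_genes: list[str] = field(default_factory=list)
    cpg_group: dict[str, str] = field(default_factory=dict)
    triplet_coefs: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CensoredView:
    """Left-censored view of a positive-valued vector."""

    value: np.ndarray      # observed value, NaN where censored
    censored: np.ndarray   # boolean indicator
    limit: np.ndarray      # per-record detection limit (mg/L)

    @property
    def censored_fraction(self) -> float:
        return float(np.mean(self.censored))


@dataclass
class Cohort:
    """Individual-level substrate of the mediation and BN analyses."""

    data: pd.DataFrame           # exposure, age, sex, centre, bmi, crp_true, crp, censored, limit
    expression: pd.DataFrame     # genes x individuals
    methylation: pd.DataFrame    # cpgs x individuals
    annotation: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# two-sample GWAS
# ---------------------------------------------------------------------------

def _block_corr_chol(J: int, rho: float, block: int) -> tuple[np.ndarray, np.ndarray]:
    """Exchangeable block correlation matrix over J SNPs and its Cholesky."""
    C = np.eye(J)
    for start in range(0, J, block):
        stop = min(start + block, J)
        C[start:stop, start:stop] = rho
        np.fill_diagonal(C[start:stop, start:stop], 1.0)
    return C, np.linalg.cholesky(C)


def _wald_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(beta) / se)


def gen_two_sample_gwas(config: GwasSimConfig):
    """Simulate per-gene two-sample GWAS summary statistics.

    Returns ``(tables, truth)`` where ``tables`` maps gene name to an
    :class:`~medchain.mr.InstrumentTable` and ``truth`` records the per-gene
    causal effects. For each gene, J instruments receive true SNP-exposure
    effects sized so the expected F-statistic matches ``mean_f``; the true
    SNP-outcome effect is ``theta_g`` times the SNP-exposure effect plus a
    pleiotropy term; both studies add SE-consistent sampling noise,
    correlated within LD blocks, and p-values follow the Wald normal
    approximation.
    """
    from .mr import InstrumentTable  # local import to avoid a cycle

    config.validate()
    thetas = config.theta_vector()
    J = config.J
    se_exp = 1.0 / math.sqrt(config.n_exp)
    se_out = 1.0 / math.sqrt(config.n_out)
    gamma_sd = se_exp * math.sqrt(config.mean_f - 1.0)
    _, L = _block_corr_chol(J, config.ld_block_rho, config.ld_block_size)
    r2 = (_block_corr_chol(J, config.ld_block_rho, config.ld_block_size)[0]) ** 2

    tables: dict[str, InstrumentTable] = {}
    truth = TruthRecord(theta_g={})
    for g in range(config.n_genes):
        gene = f"G{g:04d}"
        rng = substream(config.seed, f"gwas/{gene}")
        gamma = rng.normal(0.0, gamma_sd, size=J)
        mode = config.pleiotropy_mode
        if mode == "none" or config.pleiotropy_sd == 0.0:
            alpha = np.zeros(J)
        elif mode == "balanced":
            alpha = rng.normal(0.0, config.pleiotropy_sd, size=J)
        elif mode == "directional":
            alpha = rng.normal(config.pleiotropy_sd, config.pleiotropy_sd, size=J)
        else:  # inside_violating: pleiotropy correlated with instrument strength
            z_new = rng.standard_normal(J)
            z_gam = gamma / gamma_sd
            alpha = config.pleiotropy_sd * (0.7 * z_gam + math.sqrt(1 - 0.49) * z_new)
        beta_exp = gamma + se_exp * (L @ rng.standard_normal(J))
        beta_out = thetas[g] * gamma + alpha + se_out * (L @ rng.standard_normal(J))
        snps = pd.DataFrame(
            {
                "snp": [f"{gene}_rs{j}" for j in range(J)],
                "beta_exp": beta_exp,
                "se_exp": np.full(J, se_exp),
                "p_exp": _wald_p(beta_exp, np.full(J, se_exp)),
                "beta_out": beta_out,
                "se_out": np.full(J, se_out),
                "p_out": _wald_p(beta_out, np.full(J, se_out)),
            }
        )
        tables[gene] = InstrumentTable(snps=snps, ld_r2=r2.copy(), gene=gene)
        truth.theta_g[gene] = float(thetas[g])
    return tables, truth


# ---------------------------------------------------------------------------
# left censoring
# ---------------------------------------------------------------------------

def apply_left_censoring(values: np.ndarray, limits: np.ndarray | float) -> CensoredView:
    """Censor ``values`` below their per-record detection ``limits``.

    A value strictly below its limit is flagged censored and masked (NaN);
    values at or above the limit are kept as observed.
    """
    values = np.asarray(values, dtype=float)
    limits = np.broadcast_to(np.asarray(limits, dtype=float), values.shape).copy()
    if (limits <= 0).any():
        raise ValueError("detection limits must be positive")
    censored = values < limits
    masked = values.copy()
    masked[censored] = np.nan
    return CensoredView(value=masked, censored=censored, limit=limits)


# ---------------------------------------------------------------------------
# CpG annotation
# ---------------------------------------------------------------------------

ISLAND_STATUSES = ("island", "shore", "shelf", "open_sea")


def gen_cpg_annotation(
    n_cpgs: int,
    genes: list[str],
    seed: int = 0,
    distance_range: tuple[float, float] = (0.0, 6000.0),
    cross_reactive_rate: float = 0.05,
    snp_in_probe_rate: float = 0.10,
    tss_utr_rate: float = 0.45,
) -> pd.DataFrame:
    """Generate a CpG annotation table.

    Each CpG links to one gene, with a distance drawn uniformly over a range
    spanning both the 1,500 bp and 5,000 bp cis windows, an island-context
    label, a TSS/UTR flag, a cross-reactivity flag and a SNP-in-probe minor
    allele frequency (zero for most probes).
    """
    if len(genes) < n_cpgs:
        raise ValueError("need at least one gene per CpG")
    rng = substream(seed, "annotation")
    lo, hi = distance_range
    maf = np.where(
        rng.random(n_cpgs) < snp_in_probe_rate, rng.uniform(0.0, 0.05, n_cpgs), 0.0
    )
    return pd.DataFrame(
        {
            "cpg": [f"cg{i:07d}" for i in range(n_cpgs)],
            "gene": list(genes[:n_cpgs]),
            "distance_bp": rng.uniform(lo, hi, n_cpgs),
            "island_status": rng.choice(ISLAND_STATUSES, size=n_cpgs, p=(0.30, 0.25, 0.10, 0.35)),
            "tss_utr": rng.random(n_cpgs) < tss_utr_rate,
            "cross_reactive": rng.random(n_cpgs) < cross_reactive_rate,
            "snp_in_probe_maf": maf,
        }
    )


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _default_groups(cpgs: list[str]) -> dict[str, str]:
    return {c: CAUSAL_GROUPS[i % 5] for i, c in enumerate(cpgs)}


def gen_cohort(config: CohortSimConfig):
    """Simulate a cohort with known mediation and per-CpG causal structure.

    Returns ``(cohort, annotation, truth)``. The exposure is an ordinal dose
    0 (high) / 1 (intermediate) / 2 (low); a designated block of
    ``n_mediator_genes`` transcripts carries the exposure-to-log-CRP
    indirect path, sized so the true proportion mediated equals
    ``mediated_fraction`` and the 2-unit total effect equals
    ``total_effect_pct``. Each CpG is generated as an
    (exposure, methylation, transcription) triplet according to its causal
    group label:

    ``A``
        no exposure edge (methylation feeds transcription);
    ``B``
        exposure -> methylation -> transcription, plus a direct
        exposure -> transcription edge;
    ``C``
        exposure -> transcription, methylation independent;
    ``D``
        exposure -> transcription -> methylation;
    ``E``
        exposure -> methylation only.

    CRP is stored uncensored (``crp_true``) alongside the censored view
    implied by centre-specific detection limits.
    """
    config.validate()
    n = config.n
    genes = config.gene_names()
    cpgs = config.cpg_names()
    groups = config.group_assignment or _default_groups(cpgs)
    if set(groups) != set(cpgs):
        raise ValueError("group_assignment must label every CpG exactly once")

    # --- individuals -------------------------------------------------------
    rng_x = substream(config.seed, "exposure")
    x = rng_x.choice(3, size=n, p=np.asarray(config.exposure_probs, dtype=float))
    rng_c = substream(config.seed, "covariates")
    n_centres = len(config.censor_limits)
    centre_probs = config.centre_probs or tuple([1.0 / n_centres] * n_centres)
    centre = rng_c.choice(n_centres, size=n, p=np.asarray(centre_probs))
    age = np.clip(rng_c.normal(50.0, 12.0, n), 25.0, 88.0)
    sex = (rng_c.random(n) < 0.5).astype(int)  # 1 = woman
    bmi = rng_c.normal(26.0, 4.0, n)

    # --- mediation wiring --------------------------------------------------
    beta_total = math.log1p(config.total_effect_pct / 100.0) / 2.0
    beta_ie = config.mediated_fraction * beta_total
    beta_de = beta_total - beta_ie
    med_genes = genes[: config.n_mediator_genes]
    a = config.mediator_x_coef
    b = beta_ie / (config.n_mediator_genes * a) if config.n_mediator_genes else 0.0

    sd_t = config.noise_sds.get("transcript", 1.0)
    rng_e = substream(config.seed, "expression")
    expr = np.empty((config.n_genes, n))
    x_mean = float(np.dot(config.exposure_probs, [0, 1, 2]))
    # a shared factor makes the mediator block a co-regulated program, so its
    # top principal component carries the block-level (exposure -> CRP) path
    rho_med = config.mediator_block_rho
    shared_med = rng_e.standard_normal(n)
    for i in range(config.n_mediator_genes):
        noise = math.sqrt(rho_med) * shared_med + math.sqrt(1 - rho_med) * rng_e.standard_normal(n)
        expr[i] = a * x + sd_t * noise

    # --- CpG triplets ------------------------------------------------------
    sd_m = config.noise_sds.get("meth", 1.0)
    c0 = config.path_coef
    xs = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
    meth = np.empty((config.n_cpgs, n))
    truth_triplets: dict[str, dict[str, float]] = {}
    rng_tr = substream(config.seed, "triplets")
    for i, cpg in enumerate(cpgs):
        g = groups[cpg]
        em = rng_tr.normal(0.0, sd_m, n)
        et = rng_tr.normal(0.0, sd_t, n)
        if g == "A":
            m = em
            t = c0 * m + et
            coefs = {"x_m": 0.0, "x_t": 0.0, "m_t": c0, "t_m": 0.0}
        elif g == "B":
            m = c0 * xs + em
            t = c0 * xs + c0 * m + et
            coefs = {"x_m": c0, "x_t": c0, "m_t": c0, "t_m": 0.0}
        elif g == "C":
            t = c0 * xs + et
            m = em
            coefs = {"x_m": 0.0, "x_t": c0, "m_t": 0.0, "t_m": 0.0}
        elif g == "D":
            t = c0 * xs + et
            m = c0 * t + em
            coefs = {"x_m": 0.0, "x_t": c0, "m_t": 0.0, "t_m": c0}
        else:  # E
            m = c0 * xs + em
            t = et
            coefs = {"x_m": c0, "x_t": 0.0, "m_t": 0.0, "t_m": 0.0}
        meth[i] = m
        expr[config.n_mediator_genes + i] = t
        truth_triplets[cpg] = coefs

    # --- background genes (block-correlated noise) -------------------------
    n_bg = config.n_genes - config.n_mediator_genes - config.n_cpgs
    if n_bg > 0:
        rho = config.background_block_rho
        bs = config.background_block_size
        bg = np.empty((n_bg, n))
        for start in range(0, n_bg, bs):
            stop = min(start + bs, n_bg)
            shared = rng_e.standard_normal(n)
            own = rng_e.standard_normal((stop - start, n))
            bg[start:stop] = math.sqrt(rho) * shared + math.sqrt(1 - rho) * own
        expr[config.n_mediator_genes + config.n_cpgs:] = bg * sd_t

    # --- CRP ---------------------------------------------------------------
    rng_y = substream(config.seed, "crp")
    centre_eff = np.asarray(config.centre_coefs)[centre] - float(
        np.dot(centre_probs, config.centre_coefs[:n_centres])
    )
    med_contrib = b * (expr[: config.n_mediator_genes].sum(axis=0) - config.n_mediator_genes * a * x_mean)
    log_crp = (
        config.crp_log_mean
        + beta_de * (x - x_mean)
        + med_contrib
        + config.bmi_coef * (bmi - 26.0)
        + config.age_coef * (age - 50.0)
        + config.sex_coef * (sex - 0.5)
        + centre_eff
        + rng_y.normal(0.0, config.noise_sds.get("crp", 1.0), n)
    )
    crp_true = np.exp(log_crp)
    limits = np.asarray([config.censor_limits[c] for c in centre], dtype=float)
    view = apply_left_censoring(crp_true, limits)

    data = pd.DataFrame(
        {
            "exposure": x,
            "age": age,
            "sex": sex,
            "centre": centre,
            "bmi": bmi,
            "crp_true": crp_true,
            "crp": view.value,
            "censored": view.censored,
            "limit": view.limit,
        }
    )
    expression = pd.DataFrame(expr, index=genes, columns=range(n))
    methylation = pd.DataFrame(meth, index=cpgs, columns=range(n))
    annotation = gen_cpg_annotation(
        config.n_cpgs,
        genes[config.n_mediator_genes : config.n_mediator_genes + config.n_cpgs],
        seed=config.seed,
    )

    te_pct = float(config.total_effect_pct)
    nie_pct = 100.0 * math.expm1(2.0 * beta_ie)
    truth = TruthRecord(
        theta_g=None,
        true_te_pct=te_pct,
        true_nie_pct=nie_pct,
        true_pm=math.log1p(nie_pct / 100.0) / math.log1p(te_pct / 100.0),
        mediator_genes=list(med_genes),
        cpg_group=dict(groups),
        triplet_coefs=truth_triplets,
    )
    cohort = Cohort(data=data, expression=expression, methylation=methylation, annotation=annotation)
    return cohort, annotation, truth
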