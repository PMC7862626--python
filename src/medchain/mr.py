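"""Two-sample Mendelian randomization engine.

Per gene: instrument selection (exposure-association and reverse-causation
p-value filters, greedy LD pruning at r^2 <= 0.25, minimum 10 instruments),
three complementary causal estimators (random-effects inverse-variance
weighting, Egger regression, penalized weighted median), Storey q-values
across genes per method, and triple-concordance gene calling with a union
against the fixed CTRA indicator list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .ctra import CTRA_GENES


class NotEnoughInstruments(Exception):
    """Raised when a gene retains fewer instruments than the required minimum."""


@dataclass
class InstrumentTable:
    """SNP-level two-sample summary statistics for one gene, plus LD.

    ``snps`` columns: snp, beta_exp, se_exp, p_exp, beta_out, se_out, p_out.
    ``ld_r2`` is the symmetric, unit-diagonal squared-correlation matrix over
    the same SNPs (row order matches ``snps``).
    """

    snps: pd.DataFrame
    ld_r2: np.ndarray
    gene: str = ""

    def __post_init__(self):
        J = len(self.snps)
        if self.ld_r2.shape != (J, J):
            raise ValueError("LD matrix shape must match the SNP table")

    @property
    def J(self) -> int:
        return len(self.snps)


@dataclass
class MREstimate:
    method: str
    theta_hat: float
    se: float
    p: float
    J: int
    Q: float = np.nan
    phi: float = 1.0
    F_bar: float = np.nan
    egger_intercept: float = np.nan
    q: float = np.nan


@dataclass
class GeneCallSet:
    """Genes called causal by triple concordance, the CTRA list, and their union."""

    mr_genes: list[str]
    ctra_genes: list[str] = field(default_factory=lambda: list(CTRA_GENES))

    @property
    def union(self) -> list[str]:
        return sorted(set(self.mr_genes) | set(self.ctra_genes))


# ---------------------------------------------------------------------------
# instrument selection
# ---------------------------------------------------------------------------

def select_instruments(
    table: InstrumentTable,
    p_exp_max: float = 1.9e-5,
    p_out_reverse: float = 1.9e-5,
    ld_r2_max: float = 0.25,
    min_instruments: int = 10,
) -> tuple[InstrumentTable, float]:
    """Filter and LD-prune instruments; return the pruned table and mean F.

    SNPs must associate with the exposure (p_exp < ``p_exp_max``) and must
    not associate strongly with the outcome (p_out >= ``p_out_reverse``, a
    reverse-causation guard). Greedy pruning scans SNPs by ascending
    exposure p-value and retains a SNP iff its r^2 with every
    already-retained SNP is at most ``ld_r2_max``. Raises
    :class:`NotEnoughInstruments` when fewer than ``min_instruments``
    survive.
    """
    if table.J == 0:
        raise ValueError("empty instrument table")
    snps = table.snps.reset_index(drop=True)
    keep = (snps["p_exp"] < p_exp_max) & (snps["p_out"] >= p_out_reverse)
    idx = np.flatnonzero(keep.to_numpy())
    order = idx[np.argsort(snps.loc[idx, "p_exp"].to_numpy(), kind="stable")]
    retained: list[int] = []
    for j in order:
        if all(table.ld_r2[j, k] <= ld_r2_max for k in retained):
            retained.append(j)
    if len(retained) < min_instruments:
        raise NotEnoughInstruments(
            f"gene {table.gene!r}: {len(retained)} instruments after filtering (< {min_instruments})"
        )
    retained_sorted = sorted(retained)
    sub = snps.loc[retained_sorted].reset_index(drop=True)
    f_bar = float(np.mean((sub["beta_exp"] / sub["se_exp"]) ** 2))
    pruned = InstrumentTable(
        snps=sub, ld_r2=table.ld_r2[np.ix_(retained_sorted, retained_sorted)], gene=table.gene
    )
    return pruned, f_bar


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _ratios(table: InstrumentTable) -> tuple[np.ndarray, np.ndarray]:
    """Wald ratios and their first-order variances, dropping zero-beta_exp SNPs."""
    be = table.snps["beta_exp"].to_numpy(dtype=float)
    bo = table.snps["beta_out"].to_numpy(dtype=float)
    so = table.snps["se_out"].to_numpy(dtype=float)
    nz = be != 0.0
    if not nz.all():
        warnings.warn(f"gene {table.gene!r}: dropping {np.sum(~nz)} SNPs with beta_exp = 0")
    r = bo[nz] / be[nz]
    v = so[nz] ** 2 / be[nz] ** 2
    return r, v


def ivw_random_effects(table: InstrumentTable) -> MREstimate:
    """Multiplicative random-effects inverse-variance-weighted estimate.

    The per-SNP Wald ratios are meta-analysed with weights 1/v_j; Cochran's
    Q yields the overdispersion phi = max(1, Q/(J-1)), which inflates the
    fixed-effect standard error.
    """
    r, v = _ratios(table)
    J = len(r)
    if J < 2:
        raise ValueError("IVW requires at least 2 usable instruments")
    w = 1.0 / v
    theta = float(np.sum(w * r) / np.sum(w))
    Q = float(np.sum(w * (r - theta) ** 2))
    phi = max(1.0, Q / (J - 1))
    se = float(np.sqrt(phi / np.sum(w)))
    p = float(2.0 * stats.norm.sf(abs(theta) / se))
    return MREstimate("ivw", theta, se, p, J, Q=Q, phi=phi)


def harmonize_orientation(table: InstrumentTable) -> InstrumentTable:
    """Flip SNPs so every exposure association is positive (Egger convention)."""
    snps = table.snps.copy()
    flip = snps["beta_exp"] < 0
    snps.loc[flip, ["beta_exp", "beta_out"]] *= -1.0
    return InstrumentTable(snps=snps, ld_r2=table.ld_r2, gene=table.gene)


def egger_regression(table: InstrumentTable) -> MREstimate:
    """Egger regression: weighted fit of beta_out on beta_exp with intercept.

    Instruments are orientation-harmonized first; weights are 1/se_out^2.
    The slope estimates the causal effect, the intercept the average
    pleiotropic effect. Residual overdispersion phi = max(1, RSS/(J-2))
    scales both standard errors.
    """
    if table.J < 3:
        raise ValueError("Egger regression requires at least 3 instruments")
    table = harmonize_orientation(table)
    be = table.snps["beta_exp"].to_numpy(dtype=float)
    bo = table.snps["beta_out"].to_numpy(dtype=float)
    so = table.snps["se_out"].to_numpy(dtype=float)
    if np.ptp(be) == 0.0:
        raise ValueError("zero variance in exposure associations: slope unidentifiable")
    w = 1.0 / so**2
    X = np.column_stack([np.ones_like(be), be])
    sw = np.sqrt(w)
    coef, _, _, _ = np.linalg.lstsq(X * sw[:, None], bo * sw, rcond=None)
    alpha, theta = float(coef[0]), float(coef[1])
    resid = bo - X @ coef
    J = len(be)
    rss = float(np.sum(w * resid**2))
    phi = max(1.0, rss / (J - 2))
    xtwx_inv = np.linalg.inv(X.T @ (X * w[:, None]))
    se_alpha = float(np.sqrt(phi * xtwx_inv[0, 0]))
    se_theta = float(np.sqrt(phi * xtwx_inv[1, 1]))
    p = float(2.0 * stats.norm.sf(abs(theta) / se_theta)) if se_theta > 0 else 0.0
    est = MREstimate("egger", theta, se_theta, p, J, Q=rss, phi=phi, egger_intercept=alpha)
    est.egger_intercept_se = se_alpha  # type: ignore[attr-defined]
    return est


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted median via cumulative-weight interpolation at 50%.

    Exactly tied values are collapsed (weights summed) in the 1-D path, so
    splitting an instrument into duplicates with shared weight is a no-op.
    Vectorized over leading axes: ``ratios``/``weights`` may be (B, J),
    where ties are not collapsed (they occur with probability zero in the
    bootstrap resamples this path serves).
    """
    if ratios.ndim == 1:
        uniq, inv = np.unique(ratios, return_inverse=True)
        w_sum = np.zeros(uniq.size)
        np.add.at(w_sum, inv, weights)
        ratios, weights = uniq, w_sum
        if uniq.size == 1:
            return float(uniq[0])
        r = ratios[None, :]
        w = weights[None, :]
        cw = (np.cumsum(w, axis=1) - 0.5 * w) / np.sum(w)
        return float(np.interp(0.5, cw[0], r[0]))
    r = np.atleast_2d(ratios)
    w = np.atleast_2d(weights)
    order = np.argsort(r, axis=1)
    r_s = np.take_along_axis(r, order, axis=1)
    w_s = np.take_along_axis(w, order, axis=1)
    cw = np.cumsum(w_s, axis=1) - 0.5 * w_s
    cw /= np.sum(w_s, axis=1, keepdims=True)
    out = np.empty(r.shape[0])
    for i in range(r.shape[0]):
        out[i] = np.interp(0.5, cw[i], r_s[i])
    return out if ratios.ndim > 1 else out[0]


def _penalized_weights(r: np.ndarray, v: np.ndarray, penalty_scale: float) -> np.ndarray:
    w = 1.0 / v
    theta0 = _weighted_median(r, w)
    Qj = w * (r - theta0) ** 2
    factor = np.minimum(1.0, penalty_scale * stats.chi2.sf(Qj, df=1))
    return w * factor


def penalized_weighted_median(
    table: InstrumentTable,
    penalty_scale: float = 20.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Penalized weighted median of the Wald ratios.

    Inverse-variance weights are down-weighted by a one-df chi-square
    penalty on each SNP's heterogeneity contribution about an initial
    (unpenalized) weighted-median estimate; the causal estimate is the
    weighted median under the penalized weights. The standard error comes
    from a seeded parametric bootstrap of the summary statistics.
    """
    if table.J < 3:
        raise ValueError("penalized weighted median requires at least 3 instruments")
    r, v = _ratios(table)
    w_pen = _penalized_weights(r, v, penalty_scale)
    if np.sum(w_pen) <= 0:
        raise ValueError("all penalized weights are zero")
    theta = float(_weighted_median(r, w_pen))

    be = table.snps["beta_exp"].to_numpy(dtype=float)
    se_e = table.snps["se_exp"].to_numpy(dtype=float)
    bo = table.snps["beta_out"].to_numpy(dtype=float)
    se_o = table.snps["se_out"].to_numpy(dtype=float)
    rng = substream(seed, f"pwm/{table.gene}")
    be_b = rng.normal(be, se_e, size=(n_boot, len(be)))
    bo_b = rng.normal(bo, se_o, size=(n_boot, len(bo)))
    be_b[be_b == 0.0] = np.finfo(float).tiny
    r_b = bo_b / be_b
    v_b = se_o**2 / be_b**2
    w_b = 1.0 / v_b
    theta0_b = _weighted_median(r_b, w_b)
    Qj_b = w_b * (r_b - theta0_b[:, None]) ** 2
    w_pen_b = w_b * np.minimum(1.0, penalty_scale * stats.chi2.sf(Qj_b, df=1))
    theta_b = _weighted_median(r_b, w_pen_b)
    se = float(np.std(theta_b, ddof=1))
    p = float(2.0 * stats.norm.sf(abs(theta) / se)) if se > 0 else 0.0
    return MREstimate("pwm", theta, se, p, len(r))


# ---------------------------------------------------------------------------
# q-values and gene calling
# ---------------------------------------------------------------------------

def compute_qvalues(p: np.ndarray, method: str = "storey", pi0: float | None = None) -> np.ndarray:
    """Storey q-values with a smoother-based pi0 estimate.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on the grid
    0.05..0.95 and smoothed with a cubic polynomial evaluated at the largest
    lambda. For m < 100 the smoother is unstable and pi0 falls back to 1,
    in which case the q-values reduce to Benjamini-Hochberg step-up values.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if method not in ("storey", "bh"):
        raise ValueError(f"unknown method {method!r}")
    m = p.size
    if pi0 is None:
        if method == "bh" or m < 100:
            pi0 = 1.0
        else:
            lam = np.arange(0.05, 0.96, 0.05)
            pi0_lam = np.array([np.mean(p > l) / (1.0 - l) for l in lam])
            coef = np.polyfit(lam, pi0_lam, deg=3)
            pi0 = float(np.clip(np.polyval(coef, lam[-1]), 1.0 / m, 1.0))
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_gene_mr(
    tables: dict[str, InstrumentTable],
    p_exp_max: float = 1.9e-5,
    p_out_reverse: float = 1.9e-5,
    ld_r2_max: float = 0.25,
    min_instruments: int = 10,
    penalty_scale: float = 20.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run all three estimators on every gene; attach per-method q-values.

    Genes failing instrument selection are skipped (recorded with method
    'skipped'). Returns a long-format frame: gene, method, theta, se, p, q,
    J, F_bar, egger_intercept, phi.
    """
    rows = []
    for gene, table in tables.items():
        try:
            pruned, f_bar = select_instruments(
                table, p_exp_max, p_out_reverse, ld_r2_max, min_instruments
            )
        except NotEnoughInstruments:
            rows.append({"gene": gene, "method": "skipped"})
            continue
        for est in (
            ivw_random_effects(pruned),
            egger_regression(pruned),
            penalized_weighted_median(pruned, penalty_scale, n_boot, seed),
        ):
            est.F_bar = f_bar
            rows.append(
                {
                    "gene": gene,
                    "method": est.method,
                    "theta": est.theta_hat,
                    "se": est.se,
                    "p": est.p,
                    "J": est.J,
                    "F_bar": f_bar,
                    "egger_intercept": est.egger_intercept,
                    "phi": est.phi,
                }
            )
    df = pd.DataFrame(rows)
    df["q"] = np.nan
    for method in ("ivw", "egger", "pwm"):
        mask = df["method"] == method
        if mask.any():
            df.loc[mask, "q"] = compute_qvalues(df.loc[mask, "p"].to_numpy())
    return df


def select_causal_genes(
    estimates: pd.DataFrame,
    q_max: float = 0.05,
    ctra_genes: list[str] | tuple[str, ...] = CTRA_GENES,
) -> GeneCallSet:
    """Call a gene causal iff q <= q_max for IVW, Egger and the weighted median.

    Genes missing any of the three methods are not callable. The returned
    set also carries the fixed CTRA list and their duplicate-collapsed
    union.
    """
    called = []
    for gene, sub in estimates[estimates["method"] != "skipped"].groupby("gene"):
        methods = set(sub["method"])
        if not {"ivw", "egger", "pwm"} <= methods:
            continue
        if (sub.set_index("method").loc[["ivw", "egger", "pwm"], "q"] <= q_max).all():
            called.append(gene)
    return GeneCallSet(mr_genes=sorted(called), ctra_genes=list(ctra_genes))
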