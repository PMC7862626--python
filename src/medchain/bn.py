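"""Bayesian-network selection of exposure-methylation-transcription structures.

For each cis CpG-gene pair, the triplet (exposure dose X, methylation
residual M, transcription residual T) is scored under eleven candidate
DAGs with the Bayesian Gaussian equivalent (BGe) marginal likelihood.
Model posteriors (uniform model prior) are aggregated into five causal
groups:

* A - the exposure influences neither methylation nor transcription;
* B - the exposure drives both, and methylation also drives transcription;
* C - the exposure drives transcription; methylation is unrelated to it;
* D - the exposure drives transcription, which in turn drives methylation;
* E - the exposure influences methylation only.

An optional negative-control group (NC) adds reverse structures in which
methylation and/or transcription drive the exposure. A group wins a CpG
only when the natural log of the Bayes factor between the two
highest-posterior groups exceeds 1 (posterior at least about three times
larger than any rival's).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp, multigammaln

NODES = ("X", "M", "T")

Edge = tuple[str, str]


@dataclass(frozen=True)
class DagModel:
    edges: frozenset[Edge]
    group: str

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(a for a, b in self.edges if b == node))

    def label(self) -> str:
        return "{" + ", ".join(f"{a}->{b}" for a, b in sorted(self.edges)) + "}"


@dataclass
class GroupPosterior:
    log_posteriors: dict[str, float]   # per group, normalized
    winner: str | None
    ln_bf: float

    @property
    def posteriors(self) -> dict[str, float]:
        return {g: float(np.exp(lp)) for g, lp in self.log_posteriors.items()}


def enumerate_dags(include_negative_controls: bool = False) -> list[DagModel]:
    """The eleven candidate DAGs with their group labels.

    The edge options are {X->M in 0/1} x {X->T in 0/1} x {M-T in none,
    M->T, T->M}, minus the collider {X->T, M->T without X->M}; the
    negative-control set adds the three reverse structures {M->X},
    {T->X}, {M->X, T->X}.
    """
    XM: Edge = ("X", "M")
    XT: Edge = ("X", "T")
    MT: Edge = ("M", "T")
    TM: Edge = ("T", "M")
    spec: list[tuple[set[Edge], str]] = [
        (set(), "A"), ({MT}, "A"), ({TM}, "A"),
        ({XM, MT}, "B"), ({XM, XT, MT}, "B"),
        ({XT}, "C"), ({XM, XT}, "C"),
        ({XT, TM}, "D"), ({XM, XT, TM}, "D"),
        ({XM}, "E"), ({XM, TM}, "E"),
    ]
    if include_negative_controls:
        MX: Edge = ("M", "X")
        TX: Edge = ("T", "X")
        spec += [({MX}, "NC"), ({TX}, "NC"), ({MX, TX}, "NC")]
    return [DagModel(frozenset(e), g) for e, g in spec]


# ---------------------------------------------------------------------------
# residualization
# ---------------------------------------------------------------------------

def residualize(values: np.ndarray, confounders: np.ndarray) -> np.ndarray:
    """OLS residuals of ``values`` on a full-rank confounder design."""
    y = np.asarray(values, dtype=float)
    C = np.asarray(confounders, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("rank-deficient confounder design")
    coef, _, _, _ = np.linalg.lstsq(C, y, rcond=None)
    return y - C @ coef


@dataclass
class Triplet:
    """Scored variables for one CpG: exposure dose and residualized M, T."""

    x: np.ndarray
    m_res: np.ndarray
    t_res: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.m_res = np.asarray(self.m_res, dtype=float)
        self.t_res = np.asarray(self.t_res, dtype=float)

    @property
    def n(self) -> int:
        return len(self.x)

    def matrix(self, standardize: bool = True) -> np.ndarray:
        """Columns (X, M, T); M and T unit-scaled when ``standardize``."""
        cols = [self.x]
        for v in (self.m_res, self.t_res):
            sd = np.std(v, ddof=1)
            if sd == 0:
                raise ValueError("degenerate (zero-variance) variable in triplet")
            cols.append(v / sd if standardize else v)
        if np.std(self.x, ddof=1) == 0:
            raise ValueError("degenerate (zero-variance) exposure")
        return np.column_stack(cols)


# ---------------------------------------------------------------------------
# BGe score
# ---------------------------------------------------------------------------

@dataclass
class BgeHyper:
    """Normal-Wishart reference hyperparameters.

    alpha_mu weights the prior mean (set to the sample mean, so the mean
    correction term vanishes); alpha_w = d + 2 degrees of freedom; the
    prior scale matrix is t * I with t = alpha_mu (alpha_w - d - 1) /
    (alpha_mu + 1), which gives unit prior marginal variances on
    unit-standardized data.
    """

    alpha_mu: float = 1.0
    alpha_w: float | None = None
    t_scale: float | None = None

    def resolved(self, d: int) -> tuple[float, float, float]:
        aw = self.alpha_w if self.alpha_w is not None else d + 2.0
        t = (
            self.t_scale
            if self.t_scale is not None
            else self.alpha_mu * (aw - d - 1.0) / (self.alpha_mu + 1.0)
        )
        return self.alpha_mu, aw, t


class BgeScorer:
    """Caches subset marginal likelihoods of one triplet's data matrix.

    The BGe score of a DAG decomposes over node families:
    score = sum_i [ log p(D_{Pa(i) + i}) - log p(D_{Pa(i)}) ], with each
    subset marginal likelihood available in closed form under the
    normal-Wishart prior. Because the subset terms depend only on the
    subset, Markov-equivalent DAGs obtain identical scores.
    """

    def __init__(self, data: np.ndarray, hyper: BgeHyper | None = None):
        data = np.asarray(data, dtype=float)
        n, d = data.shape
        if n <= d + 2:
            raise ValueError("need n > d + 2 observations")
        if (np.std(data, axis=0, ddof=1) == 0).any():
            raise ValueError("degenerate (zero-variance) variable")
        self.n, self.d = n, d
        self.alpha_mu, self.alpha_w, self.t = (hyper or BgeHyper()).resolved(d)
        xbar = data.mean(axis=0)
        centred = data - xbar
        S = centred.T @ centred
        # prior mean = sample mean -> the (xbar - nu) correction vanishes
        self.R = self.t * np.eye(d) + S
        self._cache: dict[tuple[int, ...], float] = {0: 0.0}
        self._index = {name: i for i, name in enumerate(NODES[:d])}

    def _subset_logml(self, cols: tuple[int, ...]) -> float:
        key = tuple(sorted(cols))
        if key in self._cache:
            return self._cache[key]
        l = len(key)
        n, d = self.n, self.d
        aw_l = self.alpha_w - d + l
        idx = np.asarray(key)
        T_A = self.t * np.eye(l)
        R_A = self.R[np.ix_(idx, idx)]
        val = (
            -0.5 * n * l * np.log(2.0 * np.pi)
            + 0.5 * l * np.log(self.alpha_mu / (self.alpha_mu + n))
            + multigammaln(0.5 * (aw_l + n), l)
            - multigammaln(0.5 * aw_l, l)
            + 0.5 * aw_l * np.linalg.slogdet(T_A)[1]
            - 0.5 * (aw_l + n) * np.linalg.slogdet(R_A)[1]
        )
        self._cache[key] = float(val)
        return float(val)

    def family_score(self, node: str, parents: tuple[str, ...]) -> float:
        pa = tuple(self._index[p] for p in parents)
        fam = tuple(sorted(pa + (self._index[node],)))
        top = self._subset_logml(fam)
        bottom = self._subset_logml(tuple(sorted(pa))) if pa else 0.0
        return top - bottom

    def score(self, dag: DagModel) -> float:
        return sum(self.family_score(node, dag.parents(node)) for node in NODES[: self.d])


def bge_score(dag: DagModel, triplet: Triplet, hyper: BgeHyper | None = None) -> float:
    """BGe log marginal likelihood of one DAG for one triplet."""
    return BgeScorer(triplet.matrix(), hyper).score(dag)


def score_triplet(
    triplet: Triplet,
    dags: list[DagModel] | None = None,
    hyper: BgeHyper | None = None,
) -> tuple[list[DagModel], np.ndarray]:
    dags = dags if dags is not None else enumerate_dags()
    scorer = BgeScorer(triplet.matrix(), hyper)
    return dags, np.array([scorer.score(d) for d in dags])


# ---------------------------------------------------------------------------
# posteriors and selection
# ---------------------------------------------------------------------------

def group_posteriors(scores: np.ndarray, dags: list[DagModel]) -> dict[str, float]:
    """Log posterior probability per group under a uniform model prior."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(dags):
        raise ValueError("one score per enumerated model is required")
    total = logsumexp(scores)
    out: dict[str, float] = {}
    for g in sorted({d.group for d in dags}):
        member = np.array([s for s, d in zip(scores, dags) if d.group == g])
        out[g] = float(logsumexp(member) - total)
    return out


def select_group(log_posteriors: dict[str, float], ln_bf_min: float = 1.0) -> GroupPosterior:
    """Pick the winning group iff ln BF over the runner-up strictly exceeds the threshold."""
    if len(log_posteriors) < 2:
        raise ValueError("need at least two groups")
    ranked = sorted(log_posteriors.items(), key=lambda kv: kv[1], reverse=True)
    ln_bf = ranked[0][1] - ranked[1][1]
    winner = ranked[0][0] if ln_bf > ln_bf_min else None
    return GroupPosterior(log_posteriors=dict(log_posteriors), winner=winner, ln_bf=float(ln_bf))


# ---------------------------------------------------------------------------
# cis filtering, cohort-level orchestration, enrichment
# ---------------------------------------------------------------------------

def filter_cis_cpgs(
    annotation: pd.DataFrame,
    window_bp: float = 1500.0,
    maf_max: float = 0.01,
) -> pd.DataFrame:
    """Keep CpGs strictly within the cis window, non-cross-reactive, low MAF."""
    if (annotation["distance_bp"] < 0).any():
        raise ValueError("negative CpG-gene distance")
    keep = (
        (annotation["distance_bp"] < window_bp)
        & (~annotation["cross_reactive"].astype(bool))
        & (annotation["snp_in_probe_maf"] <= maf_max)
    )
    return annotation.loc[keep].reset_index(drop=True)


def assign_cpg_groups(
    methylation: pd.DataFrame,
    expression: pd.DataFrame,
    exposure: np.ndarray,
    confounders: np.ndarray,
    annotation: pd.DataFrame,
    window_bp: float = 1500.0,
    maf_max: float = 0.01,
    ln_bf_min: float = 1.0,
    include_negative_controls: bool = False,
    hyper: BgeHyper | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Score every cis CpG and tabulate winning groups.

    Returns (assignments, counts). CpGs whose linked gene lacks a
    transcription measurement are reported as unscored; counts include
    'none' (no group reached winning evidence) and 'unscored'.
    """
    kept = filter_cis_cpgs(annotation, window_bp, maf_max)
    dags = enumerate_dags(include_negative_controls)
    x = np.asarray(exposure, dtype=float)
    rows = []
    counts: dict[str, int] = {g: 0 for g in sorted({d.group for d in dags})}
    counts["none"] = 0
    counts["unscored"] = 0
    resid_cache: dict[str, np.ndarray] = {}
    for _, rec in kept.iterrows():
        cpg, gene = rec["cpg"], rec["gene"]
        if cpg not in methylation.index or gene not in expression.index:
            counts["unscored"] += 1
            rows.append({"cpg": cpg, "gene": gene, "winner": "unscored", "ln_bf": np.nan})
            continue
        m_res = residualize(methylation.loc[cpg].to_numpy(dtype=float), confounders)
        if gene not in resid_cache:
            resid_cache[gene] = residualize(expression.loc[gene].to_numpy(dtype=float), confounders)
        trip = Triplet(x=x, m_res=m_res, t_res=resid_cache[gene])
        _, scores = score_triplet(trip, dags, hyper)
        gp = select_group(group_posteriors(scores, dags), ln_bf_min)
        label = gp.winner or "none"
        counts[label] += 1
        row = {"cpg": cpg, "gene": gene, "winner": label, "ln_bf": gp.ln_bf}
        row.update({f"post_{g}": p for g, p in gp.posteriors.items()})
        rows.append(row)
    return pd.DataFrame(rows), counts


def annotation_enrichment(
    assignments: pd.DataFrame,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """2x2 chi-square (no continuity correction) of groups C+D vs A.

    Compares (i) island/shore/shelf vs open sea and (ii) TSS/UTR vs other
    between CpGs assigned to C or D and CpGs assigned to A.
    """
    merged = assignments.merge(annotation, on=["cpg", "gene"])
    in_cd = merged["winner"].isin(["C", "D"])
    in_a = merged["winner"] == "A"
    if not (in_cd.any() and in_a.any()):
        raise ValueError("need non-empty C+D and A groups")
    results = []
    for name, flag in (
        ("island_context", merged["island_status"] != "open_sea"),
        ("tss_utr", merged["tss_utr"].astype(bool)),
    ):
        table = np.array(
            [
                [int((flag & in_cd).sum()), int((~flag & in_cd).sum())],
                [int((flag & in_a).sum()), int((~flag & in_a).sum())],
            ]
        )
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            raise ValueError(f"empty margin in {name} contingency table")
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        results.append({"feature": name, "chi2": float(chi2), "p": float(p),
                        "pct_cd": 100.0 * table[0, 0] / table[0].sum(),
                        "pct_a": 100.0 * table[1, 0] / table[1].sum()})
    return pd.DataFrame(results)
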