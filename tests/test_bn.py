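"""DAG enumeration, BGe scoring, group posteriors, cis filtering, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

import medchain as mc
from medchain.bn import (
    BgeHyper,
    BgeScorer,
    DagModel,
    Triplet,
    enumerate_dags,
    filter_cis_cpgs,
    group_posteriors,
    score_triplet,
    select_group,
)


def toy_triplet(n=200, seed=0, coupled=True):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 3, n).astype(float)
    m = (0.3 * x if coupled else 0.0) + rng.standard_normal(n)
    t = 0.3 * m + rng.standard_normal(n)
    return Triplet(x, m - m.mean(), t - t.mean())


# ---------------------------------------------------------------------------
# residualization
# ---------------------------------------------------------------------------

def test_residualize_intercept_only_demeans():
    v = np.array([1.0, 2.0, 6.0])
    r = mc.residualize(v, np.ones((3, 1)))
    np.testing.assert_allclose(r, v - v.mean())


def test_residualize_exact_linear_data():
    rng = np.random.default_rng(1)
    C = np.column_stack([np.ones(100), rng.standard_normal(100)])
    v = C @ np.array([2.0, -1.0])
    np.testing.assert_allclose(mc.residualize(v, C), 0.0, atol=1e-10)


def test_residuals_orthogonal_to_design():
    rng = np.random.default_rng(2)
    C = np.column_stack([np.ones(200), rng.standard_normal((200, 3))])
    r = mc.residualize(rng.standard_normal(200), C)
    assert np.abs(C.T @ r).max() < 1e-8


def test_residualize_rank_deficiency_rejected():
    C = np.column_stack([np.ones(50), np.ones(50)])
    with pytest.raises(ValueError):
        mc.residualize(np.random.default_rng(3).standard_normal(50), C)


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def test_main_set_has_eleven_dags_with_stated_group_sizes():
    dags = enumerate_dags()
    assert len(dags) == 11
    sizes = {g: sum(d.group == g for d in dags) for g in "ABCDE"}
    assert sizes == {"A": 3, "B": 2, "C": 2, "D": 2, "E": 2}
    # the excluded 12th structure is the collider X->T <- M without X->M
    assert frozenset({("X", "T"), ("M", "T")}) not in {d.edges for d in dags}


def test_transcription_drives_methylation_is_group_d():
    dags = {d.edges: d.group for d in enumerate_dags()}
    assert dags[frozenset({("X", "T"), ("T", "M")})] == "D"


def test_negative_controls_add_three_reverse_models():
    dags = enumerate_dags(include_negative_controls=True)
    assert len(dags) == 14
    nc = [d for d in dags if d.group == "NC"]
    assert len(nc) == 3
    assert all(all(b == "X" for _, b in d.edges) for d in nc)


# ---------------------------------------------------------------------------
# BGe score
# ---------------------------------------------------------------------------

def test_markov_equivalent_dags_score_identically():
    trip = toy_triplet(n=300, seed=4)
    s1 = mc.bge_score(DagModel(frozenset({("M", "T")}), "A"), trip)
    s2 = mc.bge_score(DagModel(frozenset({("T", "M")}), "A"), trip)
    assert abs(s1 - s2) < 1e-8


def test_score_decomposes_and_ignores_row_order():
    trip = toy_triplet(n=150, seed=5)
    dag = DagModel(frozenset({("X", "M"), ("M", "T")}), "B")
    scorer = BgeScorer(trip.matrix())
    total = scorer.score(dag)
    parts = sum(scorer.family_score(node, dag.parents(node)) for node in ("X", "M", "T"))
    assert abs(total - parts) < 1e-12
    perm = np.random.default_rng(6).permutation(trip.n)
    scorer_p = BgeScorer(trip.matrix()[perm])
    assert abs(scorer_p.score(dag) - total) < 1e-8


def reference_bge(data, dag, alpha_mu=1.0):
    """Independent textbook implementation: per-family ratio of normal-Wishart
    marginal likelihoods, determinants and multivariate gammas written out
    directly (no caching, explicit loops)."""
    n, d = data.shape
    alpha_w = d + 2.0
    t = alpha_mu * (alpha_w - d - 1.0) / (alpha_mu + 1.0)
    xbar = data.mean(axis=0)
    S = (data - xbar).T @ (data - xbar)
    R = t * np.eye(d) + S
    names = {"X": 0, "M": 1, "T": 2}

    def mvgamma(a, p):
        return (p * (p - 1) / 4.0) * np.log(np.pi) + sum(
            gammaln(a - i / 2.0) for i in range(p)
        )

    def subset_ml(cols):
        if not cols:
            return 0.0
        l = len(cols)
        aw = alpha_w - d + l
        idx = np.array(sorted(cols))
        TA = t * np.eye(l)
        RA = R[np.ix_(idx, idx)]
        return (
            -0.5 * n * l * np.log(2 * np.pi)
            + 0.5 * l * np.log(alpha_mu / (alpha_mu + n))
            + mvgamma(0.5 * (aw + n), l)
            - mvgamma(0.5 * aw, l)
            + 0.5 * aw * np.log(np.linalg.det(TA))
            - 0.5 * (aw + n) * np.log(np.linalg.det(RA))
        )

    score = 0.0
    for node in ("X", "M", "T"):
        pa = [names[p] for p in dag.parents(node)]
        score += subset_ml(pa + [names[node]]) - subset_ml(pa)
    return score


def test_bge_matches_reference_formula_on_toy_data():
    trip = toy_triplet(n=50, seed=7)
    data = trip.matrix()
    for dag in enumerate_dags(include_negative_controls=True):
        mine = BgeScorer(data).score(dag)
        ref = reference_bge(data, dag)
        assert abs(mine - ref) < 1e-6


def test_degenerate_variable_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        Triplet(np.ones(50), np.random.default_rng(8).standard_normal(50),
                np.random.default_rng(9).standard_normal(50)).matrix()


# ---------------------------------------------------------------------------
# posteriors and selection
# ---------------------------------------------------------------------------

def test_equal_scores_give_group_size_posteriors():
    dags = enumerate_dags()
    gp = group_posteriors(np.zeros(11), dags)
    expect = {"A": 3 / 11, "B": 2 / 11, "C": 2 / 11, "D": 2 / 11, "E": 2 / 11}
    for g, v in expect.items():
        assert abs(np.exp(gp[g]) - v) < 1e-12


def test_dominating_model_concentrates_posterior():
    dags = enumerate_dags()
    scores = np.zeros(11)
    scores[5] += 50.0  # a group-C member
    gp = group_posteriors(scores, dags)
    assert np.exp(gp["C"]) > 0.999


def test_posteriors_normalized():
    dags = enumerate_dags()
    rng = np.random.default_rng(10)
    gp = group_posteriors(rng.normal(0, 30, 11), dags)
    assert abs(sum(np.exp(v) for v in gp.values()) - 1.0) < 1e-12


def test_select_group_clear_winner():
    lp = {g: np.log(p) for g, p in
          zip("ABCDE", (0.97, 0.01, 0.01, 0.005, 0.005))}
    gp = select_group(lp)
    assert gp.winner == "A"
    assert abs(gp.ln_bf - np.log(97)) < 1e-12


def test_select_group_tie_gives_none():
    gp = select_group({"A": np.log(0.5), "B": np.log(0.5)})
    assert gp.winner is None and gp.ln_bf == 0.0


def test_select_group_boundary_is_strict():
    gp = select_group({"A": 1.0, "B": 0.0, "C": -50.0})  # ln BF exactly 1
    assert gp.winner is None


# ---------------------------------------------------------------------------
# cis filtering and enrichment
# ---------------------------------------------------------------------------

def annotation_frame(**over):
    base = dict(cpg=["c1", "c2", "c3"], gene=["g", "g", "g"],
                distance_bp=[1499.0, 1500.0, 200.0],
                island_status=["island"] * 3, tss_utr=[True] * 3,
                cross_reactive=[False, False, False],
                snp_in_probe_maf=[0.0, 0.0, 0.0])
    base.update(over)
    return pd.DataFrame(base)


def test_cis_window_boundary_strict():
    kept = filter_cis_cpgs(annotation_frame())
    assert kept["cpg"].tolist() == ["c1", "c3"]


def test_cross_reactive_and_maf_filters():
    ann = annotation_frame(cross_reactive=[True, False, False],
                           distance_bp=[100.0, 100.0, 100.0],
                           snp_in_probe_maf=[0.0, 0.02, 0.0])
    assert filter_cis_cpgs(ann)["cpg"].tolist() == ["c3"]


def test_wider_window_keeps_superset():
    ann = mc.gen_cpg_annotation(200, [f"G{i}" for i in range(200)], seed=11)
    narrow = set(filter_cis_cpgs(ann, 1500)["cpg"])
    wide = set(filter_cis_cpgs(ann, 5000)["cpg"])
    assert narrow <= wide and len(wide) > len(narrow)


def test_negative_distance_rejected():
    with pytest.raises(ValueError):
        filter_cis_cpgs(annotation_frame(distance_bp=[-1.0, 10.0, 20.0]))


def test_enrichment_chi_square_matches_hand_formula():
    obs = np.array([[30.0, 70.0], [44.0, 56.0]])
    expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    chi2_hand = ((obs - expected) ** 2 / expected).sum()
    assign = pd.DataFrame({
        "cpg": [f"c{i}" for i in range(200)],
        "gene": ["g"] * 200,
        "winner": ["C"] * 100 + ["A"] * 100,
    })
    ann = pd.DataFrame({
        "cpg": assign["cpg"], "gene": "g",
        "island_status": ["island"] * 30 + ["open_sea"] * 70 + ["island"] * 44 + ["open_sea"] * 56,
        "tss_utr": [True] * 30 + [False] * 70 + [True] * 44 + [False] * 56,
        "distance_bp": 100.0, "cross_reactive": False, "snp_in_probe_maf": 0.0,
    })
    res = mc.annotation_enrichment(assign, ann).set_index("feature")
    assert abs(res.loc["island_context", "chi2"] - chi2_hand) < 1e-10
    # symmetry: swapping the group rows leaves chi-square unchanged
    assign_sw = assign.copy()
    assign_sw["winner"] = ["A"] * 100 + ["C"] * 100
    res_sw = mc.annotation_enrichment(assign_sw, ann).set_index("feature")
    assert abs(res_sw.loc["island_context", "chi2"] - chi2_hand) < 1e-10


def test_enrichment_identical_proportions_zero():
    assign = pd.DataFrame({"cpg": [f"c{i}" for i in range(80)], "gene": "g",
                           "winner": ["C"] * 40 + ["A"] * 40})
    ann = pd.DataFrame({"cpg": assign["cpg"], "gene": "g",
                        "island_status": (["island"] * 20 + ["open_sea"] * 20) * 2,
                        "tss_utr": ([True] * 20 + [False] * 20) * 2,
                        "distance_bp": 10.0, "cross_reactive": False,
                        "snp_in_probe_maf": 0.0})
    res = mc.annotation_enrichment(assign, ann)
    assert (res["chi2"] < 1e-12).all()


# ---------------------------------------------------------------------------
# null-exposure property
# ---------------------------------------------------------------------------

def test_permuted_exposure_rarely_wins_exposure_groups():
    rng = np.random.default_rng(12)
    n = 1500
    x = rng.integers(0, 3, n).astype(float)
    dags = enumerate_dags()
    hits = 0
    n_cpg = 100
    for _ in range(n_cpg):
        m = 0.3 * (x - x.mean()) / x.std() + rng.standard_normal(n)
        t = 0.3 * m + rng.standard_normal(n)
        xp = rng.permutation(x)
        trip = Triplet(xp, m - m.mean(), t - t.mean())
        _, scores = score_triplet(trip, dags)
        gp = select_group(group_posteriors(scores, dags))
        hits += gp.winner in {"B", "C", "D", "E"}
    assert hits / n_cpg <= 0.05
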