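"""Relatedness estimators: worked examples, oracles, calibration, invariances."""

import numpy as np
import pytest

from kinmate._ibd import em_simplex, triad_pair_links
from kinmate.evaluation import simulate_dyads
from kinmate.io import MISSING, AlleleFrequencySet, GenotypeTable, Individual
from kinmate.relatedness import (
    IBDCoefficients,
    _Coded,
    dyadml_estimator,
    estimate_pairs,
    pairwise_matrix,
    qg_estimator,
    trioml_estimator,
    wang_estimator,
)


def _simple_freqs(mapping, n_typed=100):
    return AlleleFrequencySet(
        list(mapping), {l: dict(v) for l, v in mapping.items()},
        {l: n_typed for l in mapping},
    )


# ---------------------------------------------------------------------------
# oracles


def dyad_grid_search(g1, g2, freqs, step=0.001):
    """Brute-force ML over the (k0, k1, k2) simplex on a regular grid."""
    coded = _Coded(freqs)
    usable = np.ones(len(freqs.loci), dtype=bool)
    P = np.array([coded.dyad_probs(j, g1[j], g2[j]) for j in range(len(freqs.loci))])
    best_ll, best_r, best_k0 = -np.inf, np.nan, -1.0
    for k1 in np.arange(0.0, 1.0 + step / 2, step):
        k2s = np.arange(0.0, 1.0 - k1 + step / 2, step)
        k0s = 1.0 - k1 - k2s
        K = np.stack([k0s, np.full_like(k2s, k1), k2s], axis=1)
        ll = np.sum(np.log(np.maximum(P @ K.T, 1e-300)), axis=0)
        i = int(np.argmax(ll))
        if ll[i] > best_ll + 1e-12 or (
            abs(ll[i] - best_ll) <= 1e-12 and k0s[i] > best_k0
        ):
            best_ll, best_r, best_k0 = ll[i], k2s[i] + k1 / 2, k0s[i]
    return best_r, best_ll


def trio_grid_search(g1, g2, g3, freqs, step=0.001, ridge_tol=1e-6):
    """Brute-force ML over the 16-state simplex for one reference triad.

    With one or two loci the optimum is supported on at most two states, so
    the grid enumerates all state pairs with a fine mixing weight.  Returns
    (r at the optimum, optimal log-likelihood, r-spread among grid points
    within ``ridge_tol`` of the optimum); a large spread flags a likelihood
    ridge on which r is not identified.
    """
    coded = _Coded(freqs)
    L = len(freqs.loci)
    P = np.array([coded.triad_probs(j, g1[j], g2[j], g3[j]) for j in range(L)])
    links12 = triad_pair_links()[:, 0]
    S = P.shape[1]
    lams = np.arange(0.0, 1.0 + step / 2, step)
    lls = np.empty((S, S, len(lams)))
    rs = np.empty((S, S, len(lams)))
    for a in range(S):
        for b in range(S):
            mix = np.outer(P[:, a], 1 - lams) + np.outer(P[:, b], lams)  # (L, n_lam)
            lls[a, b] = np.sum(np.log(np.maximum(mix, 1e-300)), axis=0)
            rs[a, b] = ((1 - lams) * links12[a] + lams * links12[b]) / 2.0
    best_ll = float(lls.max())
    near = lls >= best_ll - ridge_tol
    r_near = rs[near]
    best_r = float(rs[np.unravel_index(np.argmax(lls), lls.shape)])
    return best_r, best_ll, float(r_near.max() - r_near.min())


# ---------------------------------------------------------------------------
# Queller-Goodnight


def test_qg_single_locus_worked_example():
    # genotypes (A,B) vs (A,C) with p_A = 0.5, p_B = p_C = 0.25:
    # S = 1 shared-allele indicator sum; both directions give
    # (0.5 - 0.75) / (1 - 0.75) = -1, hand-evaluated from the moment formula
    freqs = _simple_freqs({"l": {1: 0.5, 2: 0.25, 3: 0.25}})
    r = qg_estimator(np.array([[1, 2]]), np.array([[1, 3]]), freqs)
    assert r == pytest.approx(-1.0)


def test_qg_null_and_po_calibration(equifreq_panel):
    sim = simulate_dyads(equifreq_panel, 1000, seed=5)
    cats = np.array(sim.categories)
    vals = estimate_pairs(sim.geno1, sim.geno2, equifreq_panel, "qg")
    assert abs(vals[cats == "UR"].mean()) < 0.02
    assert abs(vals[cats == "PO"].mean() - 0.5) < 0.02


def test_qg_skips_missing_and_monomorphic_loci():
    freqs = _simple_freqs({"mono": {9: 1.0}, "poly": {1: 0.5, 2: 0.25, 3: 0.25}})
    g1 = np.array([[9, 9], [1, 2]])
    g2 = np.array([[9, 9], [1, 3]])
    r_full = qg_estimator(g1, g2, freqs)
    assert r_full == pytest.approx(-1.0)  # monomorphic locus contributes nothing
    g2_missing = np.array([[9, 9], [MISSING, MISSING]])
    assert np.isnan(qg_estimator(g1, g2_missing, freqs))


# ---------------------------------------------------------------------------
# Wang moment estimator


def test_wang_identical_equifrequent_genotypes_near_one(equifreq_panel):
    g = np.array([[100, 102]] * 12)
    assert wang_estimator(g, g, equifreq_panel) > 0.9


def test_wang_calibration_ur_fs(equifreq_panel):
    sim = simulate_dyads(equifreq_panel, 1000, seed=6)
    cats = np.array(sim.categories)
    vals = estimate_pairs(sim.geno1, sim.geno2, equifreq_panel, "wang")
    assert abs(vals[cats == "UR"].mean()) < 0.02
    assert abs(vals[cats == "FS"].mean() - 0.5) < 0.02


def test_wang_clip_retains_raw(equifreq_panel):
    sim = simulate_dyads(equifreq_panel, 50, seed=8)
    mat_table = GenotypeTable(
        [Individual(f"i{k}", "unknown") for k in range(20)],
        equifreq_panel.loci,
        np.concatenate([sim.geno1[:10], sim.geno2[:10]]),
    )
    mat = pairwise_matrix(mat_table, ["wang"], freqs=equifreq_panel)
    assert np.all(mat.frame["wang"].to_numpy() >= -1.0)
    assert np.all(mat.frame["wang"].to_numpy() <= 1.0)
    clipped = mat.frame["wang"] != mat.frame["wang_raw"]
    inside = ~clipped
    assert np.allclose(
        mat.frame.loc[inside, "wang"], mat.frame.loc[inside, "wang_raw"]
    )


# ---------------------------------------------------------------------------
# dyadic ML


def test_dyadml_unrelated_boundary_reproduces_independence_likelihood():
    """With k fixed at (1,0,0) the per-locus likelihood must equal the plain
    product of genotype probabilities under independence."""
    freqs = _simple_freqs({"l1": {1: 0.5, 2: 0.3, 3: 0.2}, "l2": {1: 0.6, 2: 0.4}})
    coded = _Coded(freqs)
    g1, g2 = np.array([[1, 2], [1, 1]]), np.array([[2, 3], [1, 2]])
    for j, (locus, pair) in enumerate(zip(freqs.loci, zip(g1, g2))):
        p0 = coded.dyad_probs(j, pair[0], pair[1])[0]
        pr = 1.0
        for g in pair:
            pa, pb = freqs.freqs[locus][g[0]], freqs.freqs[locus][g[1]]
            pr *= pa * pa if g[0] == g[1] else 2 * pa * pb
        assert p0 == pytest.approx(pr)


def test_dyadml_matches_grid_oracle_on_one_locus_instances():
    freqs = _simple_freqs({"l": {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1}})
    rng = np.random.default_rng(0)
    codes = np.array([1, 2, 3, 4])
    p = np.array([0.4, 0.3, 0.2, 0.1])
    for _ in range(20):
        g1 = codes[rng.choice(4, 2, p=p)][None, :]
        g2 = codes[rng.choice(4, 2, p=p)][None, :]
        r_grid, _ = dyad_grid_search(g1, g2, freqs, step=0.001)
        r_em, _ = dyadml_estimator(g1, g2, freqs)
        assert abs(r_em - r_grid) <= 1e-3


def test_dyadml_po_calibration(equifreq_panel):
    sim = simulate_dyads(equifreq_panel, 400, seed=9)
    cats = np.array(sim.categories)
    vals = estimate_pairs(sim.geno1, sim.geno2, equifreq_panel, "dyadml")
    assert abs(vals[cats == "PO"].mean() - 0.5) < 0.03
    assert np.all(vals >= 0) and np.all(vals <= 1)


# ---------------------------------------------------------------------------
# triadic ML


def test_trioml_identical_rare_allele_genotypes_high(equifreq_panel):
    """A dyad with identical genotypes carrying only rare alleles must be
    inferred as closely related regardless of the reference draws."""
    loci = [f"L{j}" for j in range(12)]
    freqs = _simple_freqs(
        {l: {1: 0.05, 2: 0.05, 3: 0.45, 4: 0.45} for l in loci}
    )
    g = np.array([[1, 2]] * 12)
    from conftest import random_genotypes

    pool = random_genotypes(freqs, 50, seed=3)
    r, coeff = trioml_estimator(g, g, freqs, pool, n_reference=10, seed=4)
    assert r >= 0.9
    assert coeff.k2 > 0.8


def test_trioml_never_negative_and_ur_small(equifreq_panel):
    sim = simulate_dyads(equifreq_panel, 150, seed=10)
    cats = np.array(sim.categories)
    from conftest import random_genotypes

    pool = random_genotypes(equifreq_panel, 100, seed=11)
    vals = estimate_pairs(
        sim.geno1, sim.geno2, equifreq_panel, "trioml",
        reference_pool=pool, n_reference=10, seed=12,
    )
    assert np.all(vals >= 0.0)
    assert vals[cats == "UR"].mean() < 0.1


def test_trioml_matches_grid_oracle_single_reference():
    """Joint/average modes coincide at one reference.  The optimizer must
    always attain the grid-search likelihood; where the grid optimum is
    r-unique (no likelihood ridge) the r values must agree to 1e-3."""
    freqs = _simple_freqs(
        {"l1": {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1}, "l2": {1: 0.25, 2: 0.25, 3: 0.5}}
    )
    coded = _Coded(freqs)
    links12 = triad_pair_links()[:, 0]
    rng = np.random.default_rng(13)
    unique_checked = 0
    for _ in range(30):
        gs = []
        for locus in freqs.loci:
            codes, p = freqs.codes(locus), freqs.probs(locus)
            gs.append(codes[rng.choice(len(codes), (3, 2), p=p)])
        g1, g2, g3 = (np.stack([gs[0][i], gs[1][i]]) for i in range(3))
        r_grid, ll_grid, spread = trio_grid_search(g1, g2, g3, freqs, step=0.001)
        P = np.array([coded.triad_probs(j, g1[j], g2[j], g3[j]) for j in range(2)])
        w, ll_ml = em_simplex(
            P,
            np.vstack([np.eye(16) * 0.9 + 0.1 / 16, np.full((1, 16), 1 / 16)]),
            tol=1e-12,
            max_iter=200_000,
        )
        r_ml = float(np.sum(w * links12) / 2)
        assert ll_ml >= ll_grid - 1e-6  # never worse than the brute force
        if spread <= 1e-3:
            assert abs(r_ml - r_grid) <= 2e-3
            unique_checked += 1
    assert unique_checked >= 10


def test_trioml_variance_shrinks_with_more_references(equifreq_panel):
    from conftest import random_genotypes

    sim = simulate_dyads(equifreq_panel, 1, seed=20)
    g1, g2 = sim.geno1[1], sim.geno2[1]  # one FS dyad
    pool = random_genotypes(equifreq_panel, 300, seed=21)

    def spread(n_ref):
        vals = [
            trioml_estimator(g1, g2, equifreq_panel, pool, n_ref, seed=s)[0]
            for s in range(30)
        ]
        return np.var(vals)

    assert spread(25) <= spread(1)


# ---------------------------------------------------------------------------
# matrix-level behavior


def test_pairwise_matrix_counts_and_symmetry(equifreq_panel):
    from conftest import random_genotypes

    geno = random_genotypes(equifreq_panel, 3, seed=30)
    table = GenotypeTable(
        [Individual(i, "unknown") for i in "abc"], equifreq_panel.loci, geno
    )
    mat = pairwise_matrix(table, ["qg", "dyadml"])
    assert mat.n_dyads == 3
    assert mat.value("a", "b", "qg") == mat.value("b", "a", "qg")
    # permuting individual order leaves dyad values unchanged
    table_rev = table.subset(["c", "b", "a"])
    mat_rev = pairwise_matrix(table_rev, ["qg", "dyadml"])
    for x, y in (("a", "b"), ("a", "c"), ("b", "c")):
        assert mat.value(x, y, "qg") == pytest.approx(mat_rev.value(x, y, "qg"))
        assert mat.value(x, y, "dyadml") == pytest.approx(
            mat_rev.value(x, y, "dyadml"), abs=1e-9
        )


def test_dyad_count_formula():
    # n individuals -> n (n - 1) / 2 unordered dyads
    assert 183 * 182 // 2 == 16_653


def test_estimators_invariant_to_allele_relabeling(equifreq_panel):
    sim = simulate_dyads(equifreq_panel, 5, seed=31)
    relabel = {100 + 2 * i: 300 + 7 * i for i in range(6)}
    loci = equifreq_panel.loci
    freqs2 = AlleleFrequencySet(
        loci,
        {l: {relabel[c]: p for c, p in equifreq_panel.freqs[l].items()} for l in loci},
        {l: 500 for l in loci},
    )
    remap = np.vectorize(relabel.get)
    g1b, g2b = remap(sim.geno1), remap(sim.geno2)
    for est in ("qg", "wang", "dyadml"):
        a = estimate_pairs(sim.geno1, sim.geno2, equifreq_panel, est)
        b = estimate_pairs(g1b, g2b, freqs2, est)
        assert np.allclose(a, b, atol=1e-9, equal_nan=True)


def test_low_confidence_flag_and_loci_used(equifreq_panel):
    from conftest import random_genotypes

    geno = random_genotypes(equifreq_panel, 2, seed=32)
    geno[0, :8] = MISSING  # only 4 complete loci remain for dyads with ind 0
    table = GenotypeTable(
        [Individual(i, "unknown") for i in "ab"], equifreq_panel.loci, geno
    )
    mat = pairwise_matrix(table, ["qg"])
    row = mat.frame.iloc[0]
    assert row["loci_used"] == 4
    assert bool(row["low_confidence"])


def test_ibd_coefficient_invariants():
    c = IBDCoefficients(0.25, 0.5, 0.25)
    assert c.r == pytest.approx(0.5)
    with pytest.raises(ValueError):
        IBDCoefficients(0.5, 0.1, 0.1)
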