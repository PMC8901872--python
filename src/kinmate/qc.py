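"""Marker quality control for a microsatellite panel.

Covers the pre-analysis checks a relatedness study runs before trusting its
markers: per-locus Hardy–Weinberg exact tests (Monte-Carlo, Guo–Thompson
style allele shuffling) with Bonferroni correction across loci, the
standardized multilocus index of association r̄d as a linkage-disequilibrium
screen, heterozygote-deficit null-allele frequency estimates, and the
probability of identity of the panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import gammaln

from .io import MISSING, GenotypeTable, AlleleFrequencySet, allele_frequencies

__all__ = [
    "LocusSummary",
    "MultilocusLD",
    "hwe_exact_test",
    "multilocus_rbar_d",
    "null_allele_frequency",
    "probability_of_identity",
    "locus_summaries",
    "qc_report",
]


@dataclass
class LocusSummary:
    locus: str
    n_typed: int
    n_alleles: int
    H_O: float
    H_E: float
    hwe_p: float
    hwe_p_bonferroni: float
    null_allele_chakraborty: float
    null_allele_brookfield1: float


@dataclass
class MultilocusLD:
    rbar_d: float
    p_value: float
    n_perm: int
    seed: int


# ---------------------------------------------------------------------------
# Hardy–Weinberg


def _genotype_log_prob_terms(pairs: np.ndarray) -> float:
    """log of the table-dependent part of P(genotype table | allele counts).

    The conditional probability of a genotype table given its allele counts is
    proportional to ``2^h * n! / prod(n_ij!)`` (h = number of heterozygotes);
    the allele-count factorials are invariant under shuffling and dropped.
    """
    a = np.minimum(pairs[:, 0], pairs[:, 1])
    b = np.maximum(pairs[:, 0], pairs[:, 1])
    h = int(np.sum(a != b))
    key = a.astype(np.int64) * (b.max() + 1) + b
    _, counts = np.unique(key, return_counts=True)
    return h * np.log(2.0) - float(np.sum(gammaln(counts + 1.0)))


def hwe_exact_test(
    genotypes: np.ndarray, n_mc: int = 10_000, seed: int = 0
) -> float:
    """Monte-Carlo exact test for Hardy–Weinberg equilibrium at one locus.

    ``genotypes`` is an ``(n, 2)`` array of allele codes (``MISSING`` rows are
    dropped).  Allele copies are shuffled and re-paired into genotypes; the
    p-value is ``(1 + #{shuffled tables with conditional probability <= the
    observed table's}) / (n_mc + 1)``, so it is never exactly zero.

    A monomorphic locus cannot depart from equilibrium: returns 1.0 with a
    warning.
    """
    genotypes = np.asarray(genotypes)
    keep = genotypes[:, 0] != MISSING
    pairs = genotypes[keep]
    if len(pairs) < 2:
        raise ValueError("need at least 2 non-missing genotypes for the HWE test")
    pool = pairs.ravel()
    if len(np.unique(pool)) < 2:
        warnings.warn("monomorphic locus: HWE departure undefined, returning p = 1")
        return 1.0
    obs = _genotype_log_prob_terms(pairs)
    rng = np.random.default_rng(seed)
    n = len(pairs)
    hits = 0
    for _ in range(n_mc):
        shuffled = rng.permutation(pool).reshape(n, 2)
        if _genotype_log_prob_terms(shuffled) <= obs + 1e-12:
            hits += 1
    return (1 + hits) / (n_mc + 1)


# ---------------------------------------------------------------------------
# multilocus linkage disequilibrium (standardized index of association)


def _locus_pair_distances(column: np.ndarray) -> np.ndarray:
    """Pairwise allele-difference distances (0, 1, 2) at one locus.

    Returns a condensed vector over individual pairs (i < j); NaN where either
    genotype is missing.  The distance is 2 minus the multiset intersection of
    the two genotypes.
    """
    g = np.sort(column, axis=1).astype(float)
    g[column[:, 0] == MISSING] = np.nan
    a1, a2 = g[:, 0], g[:, 1]
    n = len(g)
    iu, ju = np.triu_indices(n, k=1)
    m1 = (a1[iu] == a1[ju]).astype(float) + (a2[iu] == a2[ju]).astype(float)
    m2 = (a1[iu] == a2[ju]).astype(float) + (a2[iu] == a1[ju]).astype(float)
    shared = np.maximum(m1, m2)
    d = 2.0 - shared
    bad = np.isnan(a1[iu]) | np.isnan(a1[ju])
    d[bad] = np.nan
    return d


def _rbar_d_from_distances(dists: np.ndarray) -> float:
    """Agapow–Burt standardization: cov of per-locus distances over the sum of
    pairwise products of their standard deviations.  ``dists`` is (L, n_pairs)
    with NaN for pairs unusable at a locus."""
    L = dists.shape[0]
    cov_sum = 0.0
    sd_sum = 0.0
    var = np.empty(L)
    for l in range(L):
        x = dists[l]
        var[l] = np.nanvar(x)
    for l in range(L):
        for m in range(l + 1, L):
            both = ~np.isnan(dists[l]) & ~np.isnan(dists[m])
            if both.sum() < 2:
                continue
            x, y = dists[l][both], dists[m][both]
            cov_sum += float(np.mean(x * y) - np.mean(x) * np.mean(y))
            sd_sum += float(np.sqrt(var[l] * var[m]))
    if sd_sum == 0.0:
        return 0.0
    return min(1.0, cov_sum / sd_sum)  # float error can push perfect association past 1


def multilocus_rbar_d(
    table: GenotypeTable, n_perm: int = 999, seed: int = 0
) -> MultilocusLD:
    """Standardized index of association r̄d with a permutation p-value.

    The statistic is computed from per-locus inter-individual distances
    (number of allele differences, 0–2); the null permutes allele copies among
    individuals independently at each locus, which destroys any multilocus
    association while preserving allele frequencies.  p uses the +1-corrected
    upper-tail count.
    """
    if table.n_loci < 2:
        raise ValueError("r̄d requires at least 2 loci")
    if table.n_individuals < 3:
        raise ValueError("r̄d requires at least 3 individuals")
    dists = np.array(
        [_locus_pair_distances(table.genotypes[:, j, :]) for j in range(table.n_loci)]
    )
    observed = _rbar_d_from_distances(dists)
    rng = np.random.default_rng(seed)
    hits = 0
    geno = table.genotypes
    for _ in range(n_perm):
        perm_cols = []
        for j in range(table.n_loci):
            col = geno[:, j, :].copy()
            present = col[:, 0] != MISSING
            alleles = col[present].ravel()
            col[present] = rng.permutation(alleles).reshape(-1, 2)
            perm_cols.append(_locus_pair_distances(col))
        if _rbar_d_from_distances(np.array(perm_cols)) >= observed - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return MultilocusLD(rbar_d=float(observed), p_value=p, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# null alleles and probability of identity


def _het_obs_exp(genotypes: np.ndarray) -> tuple[float, float, int]:
    genotypes = np.asarray(genotypes)
    pairs = genotypes[genotypes[:, 0] != MISSING]
    if len(pairs) == 0:
        raise ValueError("no non-missing genotypes")
    h_o = float(np.mean(pairs[:, 0] != pairs[:, 1]))
    alleles = pairs.ravel()
    _, counts = np.unique(alleles, return_counts=True)
    p = counts / alleles.size
    h_e = float(1.0 - np.sum(p**2))
    return h_o, h_e, len(pairs)


def null_allele_frequency(genotypes: np.ndarray, method: str = "chakraborty") -> float:
    """Null-allele frequency from the heterozygote deficit at one locus.

    ``chakraborty``: (H_E - H_O) / (H_E + H_O); ``brookfield1``:
    (H_E - H_O) / (1 + H_E).  Both clipped at 0 from below; 0 when H_E = 0.
    """
    h_o, h_e, _ = _het_obs_exp(genotypes)
    if h_e == 0.0:
        return 0.0
    if method == "chakraborty":
        est = (h_e - h_o) / (h_e + h_o) if (h_e + h_o) > 0 else 0.0
    elif method == "brookfield1":
        est = (h_e - h_o) / (1.0 + h_e)
    else:
        raise ValueError(f"unknown null-allele method {method!r}")
    return max(0.0, float(est))


def probability_of_identity(freqs: AlleleFrequencySet) -> float:
    """Probability that two random individuals share an identical multilocus genotype.

    Per locus ``PID_l = 2 (sum p_i^2)^2 - sum p_i^4``; across loci the product.
    """
    if not freqs.loci:
        raise ValueError("need at least one locus")
    pid = 1.0
    for locus in freqs.loci:
        p = freqs.probs(locus)
        a2 = float(np.sum(p**2))
        a4 = float(np.sum(p**4))
        pid *= 2.0 * a2**2 - a4
    return pid


# ---------------------------------------------------------------------------
# report


def locus_summaries(
    table: GenotypeTable, n_mc: int = 10_000, seed: int = 0
) -> list[LocusSummary]:
    """Per-locus QC block; Bonferroni-adjusted HWE p uses the number of loci tested."""
    L = table.n_loci
    out = []
    rng = np.random.default_rng(seed)
    for j, locus in enumerate(table.loci):
        col = table.genotypes[:, j, :]
        h_o, h_e, n = _het_obs_exp(col)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = hwe_exact_test(col, n_mc=n_mc, seed=int(rng.integers(2**31 - 1)))
        pairs = col[col[:, 0] != MISSING]
        out.append(
            LocusSummary(
                locus=locus,
                n_typed=n,
                n_alleles=len(np.unique(pairs.ravel())),
                H_O=h_o,
                H_E=h_e,
                hwe_p=p,
                hwe_p_bonferroni=min(1.0, p * L),
                null_allele_chakraborty=null_allele_frequency(col, "chakraborty"),
                null_allele_brookfield1=null_allele_frequency(col, "brookfield1"),
            )
        )
    return out


def qc_report(
    table: GenotypeTable, n_mc: int = 10_000, n_perm: int = 999, seed: int = 0
) -> dict:
    """Full QC report as a JSON-serializable dict."""
    freqs = allele_frequencies(table)
    ld = multilocus_rbar_d(table, n_perm=n_perm, seed=seed)
    return {
        "loci": [asdict(s) for s in locus_summaries(table, n_mc=n_mc, seed=seed)],
        "multilocus_ld": asdict(ld),
        "probability_of_identity": probability_of_identity(freqs),
        "n_individuals": table.n_individuals,
    }
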