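"""Simulation-based estimator selection.

Mirrors the familiar workflow for choosing a relatedness estimator before an
analysis: generate dyads of known kinship (parent-offspring, full sibs, half
sibs, unrelated) from the observed allele frequencies, estimate r for each
dyad with each candidate estimator, and rank estimators by the Pearson
correlation between estimates and the category's expected r
(PO 0.5, FS 0.5, HS 0.25, UR 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AlleleFrequencySet, GenotypeTable
from .relatedness import ESTIMATORS, estimate_pairs

__all__ = [
    "CATEGORIES",
    "EXPECTED_R",
    "SimulatedDyadSet",
    "simulate_dyads",
    "estimator_correlation",
    "select_estimator",
    "evaluate_estimators",
]

CATEGORIES = ("PO", "FS", "HS", "UR")
EXPECTED_R = {"PO": 0.5, "FS": 0.5, "HS": 0.25, "UR": 0.0}

#: tie-break priority for estimator selection (argmax ties go to the earlier name)
SELECTION_ORDER = ("trioml", "dyadml", "wang", "qg")


@dataclass
class SimulatedDyadSet:
    """Dyads of known kinship category drawn from a set of allele frequencies.

    ``geno1``/``geno2`` are (n_dyads, n_loci, 2) allele-code arrays;
    ``categories`` holds one of PO/FS/HS/UR per dyad.
    """

    geno1: np.ndarray
    geno2: np.ndarray
    categories: list[str]
    freqs: AlleleFrequencySet
    seed: int
    expected_r: dict[str, float] = field(default_factory=lambda: dict(EXPECTED_R))

    @property
    def n_dyads(self) -> int:
        return len(self.categories)

    def expected_values(self) -> np.ndarray:
        return np.array([self.expected_r[c] for c in self.categories])


def _draw_alleles(rng: np.random.Generator, codes: np.ndarray, p: np.ndarray, size) -> np.ndarray:
    return codes[rng.choice(len(codes), size=size, p=p)]


def simulate_dyads(
    freqs: AlleleFrequencySet, n_per_category: int, seed: int = 0
) -> SimulatedDyadSet:
    """Generate ``n_per_category`` dyads of each kinship category.

    UR: both genotypes drawn independently from the frequencies.  PO: the
    offspring inherits one uniformly chosen parental allele, the other allele
    is drawn from the frequencies.  FS: two parents are drawn and each sib
    receives one uniformly chosen allele from each parent.  HS: as FS but the
    sibs share only their first parent.  No mutation and no genotyping error,
    so PO dyads share an allele identical in state at every locus.
    """
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_per_category
    L = len(freqs.loci)
    total = 4 * n
    geno1 = np.empty((total, L, 2), dtype=np.int64)
    geno2 = np.empty((total, L, 2), dtype=np.int64)
    categories: list[str] = []
    for ci, cat in enumerate(CATEGORIES):
        categories.extend([cat] * n)
    for j, locus in enumerate(freqs.loci):
        codes, p = freqs.codes(locus), freqs.probs(locus)
        draw = lambda size: _draw_alleles(rng, codes, p, size)
        pick = lambda pair: pair[np.arange(len(pair)), rng.integers(2, size=len(pair))]
        block = 0
        # PO
        parent = draw((n, 2))
        geno1[block : block + n, j] = parent
        geno2[block : block + n, j, 0] = pick(parent)
        geno2[block : block + n, j, 1] = draw(n)
        block += n
        # FS
        pa, pb = draw((n, 2)), draw((n, 2))
        geno1[block : block + n, j, 0] = pick(pa)
        geno1[block : block + n, j, 1] = pick(pb)
        geno2[block : block + n, j, 0] = pick(pa)
        geno2[block : block + n, j, 1] = pick(pb)
        block += n
        # HS (shared first parent)
        shared, pb, pc = draw((n, 2)), draw((n, 2)), draw((n, 2))
        geno1[block : block + n, j, 0] = pick(shared)
        geno1[block : block + n, j, 1] = pick(pb)
        geno2[block : block + n, j, 0] = pick(shared)
        geno2[block : block + n, j, 1] = pick(pc)
        block += n
        # UR
        geno1[block : block + n, j] = draw((n, 2))
        geno2[block : block + n, j] = draw((n, 2))
    return SimulatedDyadSet(geno1, geno2, categories, freqs, seed)


def estimator_correlation(
    sim: SimulatedDyadSet,
    estimator: str,
    n_reference: int = 100,
    seed: int = 0,
    reference_pool: GenotypeTable | np.ndarray | None = None,
) -> float:
    """Pearson correlation between estimated r and category expected r.

    For ``trioml``, reference individuals default to synthetic genotypes drawn
    from the generating allele frequencies (seeded) when no observed pool is
    supplied.
    """
    if sim.n_dyads == 0:
        raise ValueError("empty dyad set")
    if estimator == "trioml" and reference_pool is None:
        reference_pool = _synthetic_pool(sim.freqs, n=200, seed=seed + 1)
    est = estimate_pairs(
        sim.geno1, sim.geno2, sim.freqs, estimator,
        reference_pool=reference_pool, n_reference=n_reference, seed=seed,
    )
    expected = sim.expected_values()
    ok = np.isfinite(est)
    if np.std(est[ok]) == 0 or np.std(expected[ok]) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(est[ok], expected[ok])[0, 1])


def _synthetic_pool(freqs: AlleleFrequencySet, n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    L = len(freqs.loci)
    pool = np.empty((n, L, 2), dtype=np.int64)
    for j, locus in enumerate(freqs.loci):
        pool[:, j, :] = _draw_alleles(rng, freqs.codes(locus), freqs.probs(locus), (n, 2))
    return pool


def select_estimator(correlations: dict[str, float]) -> str:
    """Argmax of the observed-vs-expected correlations.

    Exact ties break by the fixed priority trioml > dyadml > wang > qg.
    """
    if not correlations:
        raise ValueError("no correlations supplied")
    order = {name: i for i, name in enumerate(SELECTION_ORDER)}
    return max(
        correlations,
        key=lambda name: (correlations[name], -order.get(name, len(order))),
    )


def evaluate_estimators(
    freqs: AlleleFrequencySet,
    n_per_category: int = 100,
    estimators: tuple[str, ...] = ESTIMATORS,
    n_reference: int = 100,
    seed: int = 0,
    reference_pool: GenotypeTable | np.ndarray | None = None,
) -> dict:
    """Run the full selection loop; returns correlations and the chosen estimator."""
    sim = simulate_dyads(freqs, n_per_category, seed=seed)
    correlations = {
        est: estimator_correlation(
            sim, est, n_reference=n_reference, seed=seed + 17 + i,
            reference_pool=reference_pool,
        )
        for i, est in enumerate(estimators)
    }
    return {
        "n_per_category": n_per_category,
        "seed": seed,
        "correlations": correlations,
        "selected": select_estimator(correlations),
    }
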