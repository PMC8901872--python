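"""Pairwise relatedness estimators for microsatellite panels.

Four estimators of the relatedness coefficient r between a dyad, all assuming
non-inbred individuals and a genotyping error rate of zero:

- ``qg``: Queller–Goodnight moment estimator (allele sharing corrected by
  population frequencies; numerators and denominators pooled across loci,
  averaged over the two reference directions).
- ``wang``: Wang-type moment estimator from the dyad's genotype-similarity
  category at each locus.  The three category proportions have expectations
  affine in the two- and four-gene IBD coefficients (phi, Delta); the
  estimator solves those moment equations by least squares after weighting
  loci by 1/u (u = 2 a2 - a3) and applying unbiased small-sample corrections
  to the allele-frequency moments a2, a3, a4.
- ``dyadml``: dyadic maximum-likelihood estimate of (k0, k1, k2) on the
  2-simplex from the non-inbred genotype-pair likelihood.
- ``trioml``: triadic maximum-likelihood estimate using a third individual as
  a control; the triad likelihood mixes the 16 condensed non-inbred identity
  states of three individuals, and r is averaged over seeded reference draws.

Moment estimators can fall outside [0, 1] (raw values are retained alongside
clipped ones); both likelihood estimators are bounded in [0, 1] by
construction, with r = k2 + k1/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._ibd import em_simplex, triad_locus_probs, triad_pair_links
from .io import MISSING, AlleleFrequencySet, GenotypeTable

__all__ = [
    "IBDCoefficients",
    "RelatednessMatrix",
    "ESTIMATORS",
    "qg_estimator",
    "wang_estimator",
    "dyadml_estimator",
    "trioml_estimator",
    "pairwise_matrix",
    "qg_pairs",
    "estimate_pairs",
]

ESTIMATORS = ("qg", "wang", "dyadml", "trioml")

#: dyads with fewer usable loci than this are flagged low-confidence
LOW_CONFIDENCE_LOCI = 6


@dataclass(frozen=True)
class IBDCoefficients:
    """Probabilities that a non-inbred dyad shares 0, 1 or 2 alleles IBD."""

    k0: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        if abs(self.k0 + self.k1 + self.k2 - 1.0) > 1e-9:
            raise ValueError("IBD coefficients must sum to 1")
        for v in (self.k0, self.k1, self.k2):
            if not (-1e-12 <= v <= 1.0 + 1e-12):
                raise ValueError("IBD coefficients must lie in [0, 1]")

    @property
    def r(self) -> float:
        return self.k2 + 0.5 * self.k1


# ---------------------------------------------------------------------------
# shared per-table precomputation


class _Coded:
    """Frequency lookups and usability masks derived once per frequency set."""

    def __init__(self, freqs: AlleleFrequencySet):
        self.freqs = freqs
        self.loci = freqs.loci
        self.maps: list[dict[int, float]] = [dict(freqs.freqs[l]) for l in self.loci]
        self.polymorphic = np.array([freqs.n_alleles(l) > 1 for l in self.loci])
        # Wang-style moments with unbiased small-sample corrections when counts known
        a2 = np.empty(len(self.loci))
        a3 = np.empty(len(self.loci))
        a4 = np.empty(len(self.loci))
        for j, locus in enumerate(self.loci):
            if freqs.counts is not None and sum(freqs.counts[locus].values()) >= 8:
                x = np.array(list(freqs.counts[locus].values()), dtype=float)
                n = x.sum()
                a2[j] = np.sum(x * (x - 1)) / (n * (n - 1))
                a3[j] = np.sum(x * (x - 1) * (x - 2)) / (n * (n - 1) * (n - 2))
                a4[j] = np.sum(x * (x - 1) * (x - 2) * (x - 3)) / (
                    n * (n - 1) * (n - 2) * (n - 3)
                )
            else:
                p = freqs.probs(locus)
                a2[j], a3[j], a4[j] = np.sum(p**2), np.sum(p**3), np.sum(p**4)
        self.b = 2 * a2**2 - a4
        self.c = a2 - self.b
        self.d = 4 * (a3 - a4)
        self.e = 2 * (a2 - 3 * a3 + 2 * a4)
        self.f = 4 * (a2 - a2**2 - 2 * a3 + 2 * a4)
        self.g = 1 - 7 * a2 + 4 * a2**2 + 10 * a3 - 8 * a4
        self.u = 2 * a2 - a3
        # per-locus memoization of genotype-conditional probabilities; genotype
        # patterns recur heavily across dyads so this dominates ML throughput.
        # Loci with identical frequency maps share one cache group.
        groups: dict[tuple, int] = {}
        self._cache_group = []
        for j, locus in enumerate(self.loci):
            sig = tuple(sorted(self.maps[j].items()))
            self._cache_group.append(groups.setdefault(sig, j))
        self._dyad_cache: dict[tuple, tuple[float, float, float]] = {}
        self._triad_cache: dict[tuple, np.ndarray] = {}

    def dyad_probs(self, j: int, g1: np.ndarray, g2: np.ndarray) -> tuple[float, float, float]:
        key = (
            self._cache_group[j],
            min(g1[0], g1[1]), max(g1[0], g1[1]),
            min(g2[0], g2[1]), max(g2[0], g2[1]),
        )
        out = self._dyad_cache.get(key)
        if out is None:
            from ._ibd import dyad_mode_probs

            out = dyad_mode_probs(g1, g2, self.maps[j])
            self._dyad_cache[key] = out
        return out

    def triad_probs(self, j: int, g1: np.ndarray, g2: np.ndarray, g3: np.ndarray) -> np.ndarray:
        key = (
            self._cache_group[j],
            min(g1[0], g1[1]), max(g1[0], g1[1]),
            min(g2[0], g2[1]), max(g2[0], g2[1]),
            min(g3[0], g3[1]), max(g3[0], g3[1]),
        )
        out = self._triad_cache.get(key)
        if out is None:
            out = triad_locus_probs(g1, g2, g3, self.maps[j])
            self._triad_cache[key] = out
        return out


def _usable_loci(g1: np.ndarray, g2: np.ndarray, coded: _Coded) -> np.ndarray:
    typed = (g1[:, 0] != MISSING) & (g2[:, 0] != MISSING)
    return typed & coded.polymorphic


# ---------------------------------------------------------------------------
# Queller–Goodnight


def qg_estimator(g1: np.ndarray, g2: np.ndarray, freqs: AlleleFrequencySet) -> float:
    """Queller–Goodnight moment estimator for one dyad.

    Per reference direction, the locus numerator is half the allele-sharing
    count minus the reference's summed allele frequencies, and the denominator
    is ``1 + homozygosity - summed frequencies``; loci are pooled by summing
    numerators and denominators before dividing, and the two directions are
    averaged.  Returns NaN when no usable locus exists.
    """
    coded = _Coded(freqs)
    return float(_qg_from_coded(g1[None], g2[None], coded, np.array([0]), np.array([0]))[0])


def _per_individual_qg_terms(geno: np.ndarray, coded: _Coded) -> tuple[np.ndarray, np.ndarray]:
    """(psum, hom) arrays of shape (n, L) for all individuals."""
    n, L, _ = geno.shape
    psum = np.zeros((n, L))
    for j, locus in enumerate(coded.loci):
        typed = geno[:, j, 0] != MISSING
        if typed.any():
            psum[typed, j] = coded.freqs.lookup(locus, geno[typed, j, 0]) + coded.freqs.lookup(
                locus, geno[typed, j, 1]
            )
    hom = (geno[:, :, 0] == geno[:, :, 1]).astype(float)
    return psum, hom


def _qg_from_coded(
    geno_a: np.ndarray, geno_b: np.ndarray, coded: _Coded, ia: np.ndarray, ib: np.ndarray
) -> np.ndarray:
    """Vectorized QG over dyads (ia[k], ib[k]) with genotypes taken from two stacks."""
    psum_a, hom_a = _per_individual_qg_terms(geno_a, coded)
    psum_b, hom_b = _per_individual_qg_terms(geno_b, coded)
    g_a, g_b = geno_a[ia], geno_b[ib]  # (m, L, 2)
    share = np.zeros(g_a.shape[:2])
    for s in (0, 1):
        for t in (0, 1):
            share += g_a[:, :, s] == g_b[:, :, t]
    usable = (
        (g_a[:, :, 0] != MISSING) & (g_b[:, :, 0] != MISSING) & coded.polymorphic[None, :]
    )
    num_a = np.where(usable, 0.5 * share - psum_a[ia], 0.0)
    den_a = np.where(usable, 1.0 + hom_a[ia] - psum_a[ia], 0.0)
    num_b = np.where(usable, 0.5 * share - psum_b[ib], 0.0)
    den_b = np.where(usable, 1.0 + hom_b[ib] - psum_b[ib], 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = 0.5 * (num_a.sum(1) / den_a.sum(1) + num_b.sum(1) / den_b.sum(1))
    r[~usable.any(axis=1)] = np.nan
    return r


def qg_pairs(
    geno: np.ndarray, freqs: AlleleFrequencySet, ia: Sequence[int], ib: Sequence[int]
) -> np.ndarray:
    """Batch QG over dyads indexed into a single genotype stack ``geno`` (n, L, 2)."""
    coded = _Coded(freqs)
    return _qg_from_coded(geno, geno, coded, np.asarray(ia), np.asarray(ib))


# ---------------------------------------------------------------------------
# Wang-type moment estimator


def _wang_category(g1: np.ndarray, g2: np.ndarray) -> int:
    """Genotype-similarity category: 1 identical, 2 homozygote/heterozygote
    sharing an allele, 3 heterozygotes sharing exactly one allele, 4 no share."""
    a, b = int(g1[0]), int(g1[1])
    c, d = int(g2[0]), int(g2[1])
    s1, s2 = frozenset((a, b)), frozenset((c, d))
    if s1 == s2 and (a == b) == (c == d):
        return 1
    shared = len({a, b} & {c, d})
    if shared == 0:
        return 4
    if a == b or c == d:
        return 2 if (a in (c, d) if a == b else c in (a, b)) else 4
    return 3


def wang_estimator(
    g1: np.ndarray, g2: np.ndarray, freqs: AlleleFrequencySet, clip: bool = False
) -> float:
    """Wang-type moment estimator of r for one dyad (see module docstring).

    With ``clip=True`` the estimate is truncated to [-1, 1].  Returns NaN when
    no usable locus exists.
    """
    coded = _Coded(freqs)
    r = _wang_one(g1, g2, coded)
    if clip and np.isfinite(r):
        r = float(np.clip(r, -1.0, 1.0))
    return r


def _wang_one(g1: np.ndarray, g2: np.ndarray, coded: _Coded) -> float:
    usable = _usable_loci(g1, g2, coded)
    if not usable.any():
        return np.nan
    idx = np.flatnonzero(usable)
    w = 1.0 / coded.u[idx]
    w /= w.sum()
    cats = np.array([_wang_category(g1[j], g2[j]) for j in idx])
    P1 = float(np.sum(w[cats == 1]))
    P2 = float(np.sum(w[cats == 2]))
    P3 = float(np.sum(w[cats == 3]))
    b = float(np.sum(w * coded.b[idx]))
    c = float(np.sum(w * coded.c[idx]))
    d = float(np.sum(w * coded.d[idx]))
    e = float(np.sum(w * coded.e[idx]))
    f = float(np.sum(w * coded.f[idx]))
    g = float(np.sum(w * coded.g[idx]))
    A = np.array([[c, 1.0 - b], [e, -d], [g, -f]])
    y = np.array([P1 - b, P2 - d, P3 - f])
    (phi, delta), *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(delta + 0.5 * phi)


# ---------------------------------------------------------------------------
# dyadic maximum likelihood


def _dyad_starts() -> np.ndarray:
    eps = 0.02
    corners = np.eye(3) * (1 - 2 * eps) + eps
    center = np.full((1, 3), 1 / 3)
    edges = np.array([[0.49, 0.49, 0.02], [0.02, 0.49, 0.49]])
    return np.vstack([center, corners, edges])


def dyadml_estimator(
    g1: np.ndarray, g2: np.ndarray, freqs: AlleleFrequencySet, tol: float = 1e-8
) -> tuple[float, IBDCoefficients]:
    """Dyadic ML estimate of r and (k0, k1, k2) for one dyad.

    Maximizes the product over usable loci of
    ``k0 P(G|0 IBD) + k1 P(G|1 IBD) + k2 P(G|2 IBD)`` over the 2-simplex by EM
    with restarts from the simplex corners and center; ties within the
    log-likelihood tolerance break toward the larger-k0 solution.
    """
    return _dyadml_one(g1, g2, _Coded(freqs), tol)


def _dyadml_one(
    g1: np.ndarray, g2: np.ndarray, coded: _Coded, tol: float = 1e-8
) -> tuple[float, IBDCoefficients]:
    usable = _usable_loci(g1, g2, coded)
    if not usable.any():
        return np.nan, IBDCoefficients(1.0, 0.0, 0.0)
    P = np.array([coded.dyad_probs(j, g1[j], g2[j]) for j in np.flatnonzero(usable)])
    k, _ = em_simplex(P, _dyad_starts(), tol=tol)
    coeff = IBDCoefficients(float(k[0]), float(k[1]), float(k[2]))
    return coeff.r, coeff


# ---------------------------------------------------------------------------
# triadic maximum likelihood


def _triad_starts() -> np.ndarray:
    links = triad_pair_links()
    n_states = len(links)
    picks = [0]
    for want in ((2, 0, 0), (1, 0, 0), (1, 1, 1), (2, 2, 2)):
        match = np.flatnonzero((links == want).all(axis=1))
        if match.size:
            picks.append(int(match[0]))
    eps = 0.05
    starts = [np.full(n_states, 1.0 / n_states)]
    for s in picks:
        w = np.full(n_states, eps / (n_states - 1))
        w[s] = 1.0 - eps
        starts.append(w)
    return np.array(starts)


def trioml_estimator(
    g1: np.ndarray,
    g2: np.ndarray,
    freqs: AlleleFrequencySet,
    reference_pool: GenotypeTable | np.ndarray,
    n_reference: int = 100,
    seed: int = 0,
    tol: float = 1e-8,
    mode: str = "joint",
) -> tuple[float, IBDCoefficients]:
    """Triadic ML estimate of r for one dyad using reference controls.

    ``n_reference`` reference individuals are sampled with replacement from
    ``reference_pool`` (seeded).  The likelihood of each triad (dyad +
    reference) mixes the 16 condensed non-inbred identity states; the dyad's
    (k0, k1, k2) are the state-marginal probabilities and r = k2 + k1/2,
    bounded in [0, 1] by construction.

    ``mode="joint"`` (default) maximizes one shared state distribution over
    all reference triads: reference-linked states must then be supported by
    every control, which squeezes out identity-in-state noise and keeps the
    dyad margin clean.  ``mode="average"`` instead maximizes each triad
    separately and averages r over the draws.  References sharing no usable
    locus with the dyad are rejected and redrawn.
    """
    return _trioml_one(g1, g2, _Coded(freqs), reference_pool, n_reference, seed, tol, mode)


def _trioml_one(
    g1: np.ndarray,
    g2: np.ndarray,
    coded: _Coded,
    reference_pool: GenotypeTable | np.ndarray,
    n_reference: int,
    seed: int,
    tol: float = 1e-8,
    mode: str = "joint",
) -> tuple[float, IBDCoefficients]:
    pool = reference_pool.genotypes if isinstance(reference_pool, GenotypeTable) else np.asarray(
        reference_pool
    )
    if pool.ndim != 3 or len(pool) == 0:
        raise ValueError("reference pool must be a non-empty (n, L, 2) genotype stack")
    if n_reference < 1:
        raise ValueError("n_reference must be >= 1")
    if mode not in ("joint", "average"):
        raise ValueError(f"unknown trioml mode {mode!r}")
    rng = np.random.default_rng(seed)
    links12 = triad_pair_links()[:, 0]
    blocks: list[np.ndarray] = []
    rs: list[float] = []
    ks: list[np.ndarray] = []
    attempts = 0
    while len(blocks) < n_reference:
        attempts += 1
        if attempts > 50 * n_reference:
            raise RuntimeError("could not draw usable reference individuals")
        gref = pool[rng.integers(len(pool))]
        usable = (
            (g1[:, 0] != MISSING)
            & (g2[:, 0] != MISSING)
            & (gref[:, 0] != MISSING)
            & coded.polymorphic
        )
        if not usable.any():
            continue
        P = np.asarray(
            [coded.triad_probs(j, g1[j], g2[j], gref[j]) for j in np.flatnonzero(usable)]
        )
        blocks.append(P)
        if mode == "average":
            w, _ = em_simplex(P, _triad_starts(), tol=tol)
            k = np.array([float(np.sum(w[links12 == n])) for n in (0, 1, 2)])
            rs.append(float(k[2] + 0.5 * k[1]))
            ks.append(k)
    if mode == "average":
        k_mean = np.clip(np.mean(ks, axis=0), 0.0, 1.0)
        k_mean /= k_mean.sum()
        return float(np.mean(rs)), IBDCoefficients(*k_mean)
    w, _ = em_simplex(np.vstack(blocks), _triad_starts(), tol=tol)
    k = np.array([float(np.sum(w[links12 == n])) for n in (0, 1, 2)])
    k = np.clip(k, 0.0, 1.0)
    k /= k.sum()
    return float(k[2] + 0.5 * k[1]), IBDCoefficients(*k)


# ---------------------------------------------------------------------------
# matrices


class RelatednessMatrix:
    """Symmetric dyad -> r lookup over one or more estimators.

    Backed by a dataframe with one row per unordered dyad: ``id_a``, ``id_b``,
    ``loci_used``, ``low_confidence``, one column per estimator (clipped for
    the moment estimators, whose raw values are kept in ``<name>_raw``).
    """

    def __init__(self, frame: pd.DataFrame, estimators: Sequence[str]):
        self.frame = frame.reset_index(drop=True)
        self.estimators = tuple(estimators)
        self._lookup: dict[tuple[str, str], int] = {}
        for i, row in self.frame.iterrows():
            key = tuple(sorted((row["id_a"], row["id_b"])))
            self._lookup[key] = i

    def value(self, id_a: str, id_b: str, estimator: str) -> float:
        if estimator not in self.estimators:
            raise KeyError(f"estimator {estimator!r} not in matrix ({self.estimators})")
        key = tuple(sorted((id_a, id_b)))
        if key not in self._lookup:
            raise KeyError(f"dyad {key} not present in matrix")
        return float(self.frame.loc[self._lookup[key], estimator])

    def has_dyad(self, id_a: str, id_b: str) -> bool:
        return tuple(sorted((id_a, id_b))) in self._lookup

    @property
    def n_dyads(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def estimate_pairs(
    geno1: np.ndarray,
    geno2: np.ndarray,
    freqs: AlleleFrequencySet,
    estimator: str,
    reference_pool: GenotypeTable | np.ndarray | None = None,
    n_reference: int = 100,
    seed: int = 0,
    trioml_mode: str = "joint",
) -> np.ndarray:
    """Estimates for dyads formed row-wise from two genotype stacks (m, L, 2)."""
    geno1, geno2 = np.asarray(geno1), np.asarray(geno2)
    m = len(geno1)
    if estimator == "qg":
        coded = _Coded(freqs)
        idx = np.arange(m)
        return _qg_from_coded(geno1, geno2, coded, idx, idx)
    out = np.empty(m)
    if estimator == "wang":
        coded = _Coded(freqs)
        for k in range(m):
            out[k] = _wang_one(geno1[k], geno2[k], coded)
        return out
    if estimator == "dyadml":
        coded = _Coded(freqs)
        for k in range(m):
            out[k] = _dyadml_one(geno1[k], geno2[k], coded)[0]
        return out
    if estimator == "trioml":
        if reference_pool is None:
            raise ValueError("trioml requires a reference pool")
        coded = _Coded(freqs)
        seeds = np.random.SeedSequence(seed).generate_state(m) % (2**31 - 1)
        for k in range(m):
            out[k] = _trioml_one(
                geno1[k], geno2[k], coded, reference_pool, n_reference, int(seeds[k]),
                mode=trioml_mode,
            )[0]
        return out
    raise ValueError(f"unknown estimator {estimator!r}")


def pairwise_matrix(
    table: GenotypeTable,
    estimators: Iterable[str] = ESTIMATORS,
    n_reference: int = 100,
    seed: int = 0,
    freqs: AlleleFrequencySet | None = None,
    dyads: Sequence[tuple[str, str]] | None = None,
    trioml_mode: str = "joint",
) -> RelatednessMatrix:
    """Relatedness for all unordered dyads of ``table`` (or a chosen subset).

    Allele frequencies default to the full sample including each focal dyad.
    For ``trioml`` the reference pool is the table itself minus the focal
    dyad.  Deterministic given ``seed``; per-dyad failures (no usable loci)
    yield NaN values rather than aborting the matrix.
    """
    estimators = list(estimators)
    unknown = set(estimators) - set(ESTIMATORS)
    if unknown:
        raise ValueError(f"unknown estimators: {sorted(unknown)}")
    if table.n_individuals < 2:
        raise ValueError("need at least two individuals")
    from .io import allele_frequencies

    if freqs is None:
        freqs = allele_frequencies(table)
    coded = _Coded(freqs)
    ids = table.ids
    if dyads is None:
        pairs = [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]
    else:
        pairs = [tuple(sorted(p)) for p in dyads]
    ia = np.array([table.index_of(a) for a, _ in pairs], dtype=int)
    ib = np.array([table.index_of(b) for _, b in pairs], dtype=int)
    geno = table.genotypes
    typed = geno[:, :, 0] != MISSING
    loci_used = (typed[ia] & typed[ib] & coded.polymorphic[None, :]).sum(axis=1)

    data: dict[str, np.ndarray | list] = {
        "id_a": [p[0] for p in pairs],
        "id_b": [p[1] for p in pairs],
        "loci_used": loci_used,
        "low_confidence": loci_used < LOW_CONFIDENCE_LOCI,
    }
    seeds = np.random.SeedSequence(seed).generate_state(max(len(pairs), 1)) % (2**31 - 1)
    for est in estimators:
        if est == "qg":
            raw = _qg_from_coded(geno, geno, coded, ia, ib)
            data["qg_raw"] = raw
            data["qg"] = np.clip(raw, -1.0, 1.0)
        elif est == "wang":
            raw = np.array([_wang_one(geno[i], geno[j], coded) for i, j in zip(ia, ib)])
            data["wang_raw"] = raw
            data["wang"] = np.clip(raw, -1.0, 1.0)
        elif est == "dyadml":
            data["dyadml"] = np.array(
                [_dyadml_one(geno[i], geno[j], coded)[0] for i, j in zip(ia, ib)]
            )
        elif est == "trioml":
            vals = np.empty(len(pairs))
            for k, (i, j) in enumerate(zip(ia, ib)):
                others = np.array([t for t in range(len(ids)) if t not in (i, j)])
                pool = geno[others] if len(others) else geno
                vals[k] = _trioml_one(
                    geno[i], geno[j], coded, pool, n_reference, int(seeds[k]),
                    mode=trioml_mode,
                )[0]
            data["trioml"] = vals
    return RelatednessMatrix(pd.DataFrame(data), estimators)
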