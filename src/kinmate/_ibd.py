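"""Identity-by-descent likelihood machinery shared by the ML relatedness estimators.

Everything here assumes non-inbred individuals and a genotyping error rate of
zero.  For a dyad the IBD state space is the familiar (k0, k1, k2) simplex.
For a triad (two focal individuals plus a reference/control) the state space
is the set of condensed identity states: set partitions of the six genes in
which no individual's own two genes are IBD.  These are enumerated
programmatically below (there are 16 of them) rather than transcribed from a
table.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

import numpy as np

try:  # numba accelerates the per-triad EM by ~50x; pure numpy fallback below
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

# gene slot layout for a triad: individual 0 -> slots (0, 1), 1 -> (2, 3), 2 -> (4, 5)
_SLOT_PAIRS = ((0, 1), (2, 3), (4, 5))


# ---------------------------------------------------------------------------
# dyadic genotype-pair probabilities


def dyad_mode_probs(g1: np.ndarray, g2: np.ndarray, p: dict[int, float]) -> tuple[float, float, float]:
    """P(observed genotype pair | 0, 1, 2 alleles IBD) at one locus.

    ``g1``/``g2`` are length-2 allele-code arrays (unordered genotypes), ``p``
    maps allele code -> population frequency.  Standard non-inbred conditional
    probabilities; e.g. for (AiAj, AiAk): k1 term p_i p_j p_k, k0 term
    4 p_i^2 p_j p_k.
    """
    a, b = int(g1[0]), int(g1[1])
    c, d = int(g2[0]), int(g2[1])
    pa, pb = p[a], p[b]
    pc, pd = p[c], p[d]

    # P(G) under independence
    prob1 = pa * pa if a == b else 2 * pa * pb
    prob2 = pc * pc if c == d else 2 * pc * pd
    p0 = prob1 * prob2

    # two IBD pairs: genotypes must be identical
    if a == b:
        p2 = pa * pa if (c == d and c == a) else 0.0
    else:
        same = (c == a and d == b) or (c == b and d == a)
        p2 = 2 * pa * pb if same else 0.0

    # one IBD pair: sum over which allele of each genotype is the shared one
    p1 = 0.0
    for s1, o1 in ((a, b), (b, a)):
        for s2, o2 in ((c, d), (d, c)):
            if s1 == s2:
                p1 += p[s1] * p[o1] * p[o2]
    # each unordered heterozygote was enumerated twice per shared-slot choice;
    # correct for double counting of identical (shared, other) splits
    if a == b:
        p1 /= 2.0
    if c == d:
        p1 /= 2.0
    return p0, p1, p2


def dyad_locus_matrix(
    geno1: np.ndarray, geno2: np.ndarray, freq_maps: list[dict[int, float]],
    usable: np.ndarray,
) -> np.ndarray:
    """(n_usable_loci, 3) matrix of (P0, P1, P2) per locus for a dyad."""
    rows = []
    for j in np.flatnonzero(usable):
        rows.append(dyad_mode_probs(geno1[j], geno2[j], freq_maps[j]))
    return np.asarray(rows, dtype=float)


# ---------------------------------------------------------------------------
# triadic condensed identity states


def _set_partitions(items: tuple[int, ...]):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] | {first}] + part[i + 1 :]
        yield part + [{first}]


def _canonical(partition: list[frozenset]) -> frozenset:
    return frozenset(frozenset(c) for c in partition)


@lru_cache(maxsize=1)
def triad_states() -> tuple[tuple[tuple[int, ...], ...], ...]:
    """Condensed non-inbred identity states of a triad.

    Each state is a partition of gene slots 0..5 into IBD classes, with no
    class containing both slots of one individual.  States equivalent under
    within-individual slot swaps are collapsed to one representative.  Classes
    of size 1 are kept explicitly.
    """
    seen: dict[frozenset, tuple] = {}
    for part in _set_partitions(tuple(range(6))):
        classes = [frozenset(c) for c in part]
        if any(len(c & set(sp)) == 2 for c in classes for sp in _SLOT_PAIRS):
            continue
        # canonical representative under the 8 within-individual swaps
        best = None
        for swaps in product((False, True), repeat=3):
            mapping = {}
            for k, (x, y) in enumerate(_SLOT_PAIRS):
                mapping[x], mapping[y] = ((y, x) if swaps[k] else (x, y))
            mapped = _canonical([frozenset(mapping[s] for s in c) for c in classes])
            key = tuple(sorted(tuple(sorted(c)) for c in mapped))
            if best is None or key < best:
                best = key
        if best not in seen:
            seen[best] = tuple(tuple(sorted(c)) for c in sorted(classes, key=lambda c: sorted(c)))
    # stable order: by number of classes descending (unrelated state first), then lexical
    states = sorted(seen.values(), key=lambda s: (-len(s), s))
    return tuple(states)


@lru_cache(maxsize=1)
def triad_pair_links() -> np.ndarray:
    """(n_states, 3) matrix: per state, the number of IBD-linked gene pairs
    between individuals (0,1), (0,2) and (1,2) — 0, 1 or 2 each."""
    states = triad_states()
    pairs = ((0, 1), (0, 2), (1, 2))
    out = np.zeros((len(states), 3), dtype=int)
    for s_idx, state in enumerate(states):
        for c in state:
            members = {slot // 2 for slot in c}
            for p_idx, (i, j) in enumerate(pairs):
                if i in members and j in members:
                    out[s_idx, p_idx] += 1
    return out


def triad_locus_probs(
    g1: np.ndarray, g2: np.ndarray, g3: np.ndarray, p: dict[int, float]
) -> np.ndarray:
    """P(observed triad genotypes | state) for every condensed state, one locus.

    Sums over the orderings of each heterozygous genotype; a class contributes
    the frequency of its (necessarily common) allele, so the probability of an
    ordered gene assignment is the product of one frequency per class.
    """
    states = triad_states()
    genos = (g1, g2, g3)
    orderings = []
    for g in genos:
        a, b = int(g[0]), int(g[1])
        orderings.append([(a, b)] if a == b else [(a, b), (b, a)])
    out = np.zeros(len(states))
    for combo in product(*orderings):
        alleles = [combo[0][0], combo[0][1], combo[1][0], combo[1][1], combo[2][0], combo[2][1]]
        for s_idx, state in enumerate(states):
            prob = 1.0
            for c in state:
                vals = {alleles[slot] for slot in c}
                if len(vals) > 1:
                    prob = 0.0
                    break
                prob *= p[alleles[c[0]]]
            out[s_idx] += prob
    return out


# ---------------------------------------------------------------------------
# EM maximization of mixture likelihoods over a probability simplex


def _em_kernel_py(P: np.ndarray, W: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    S = len(W)
    ll_out = np.full(S, -np.inf)
    L = P.shape[0]
    for s in range(S):
        w = W[s]
        ll_prev = -np.inf
        for _ in range(max_iter):
            mix = P @ w
            if np.any(mix <= 0):
                ll_prev = -np.inf
                break
            ll = float(np.sum(np.log(mix)))
            w = (P * w / mix[:, None]).sum(axis=0) / L
            if ll - ll_prev < tol:
                ll_prev = ll
                break
            ll_prev = ll
        ll_out[s] = ll_prev
        W[s] = w
    return ll_out


if _HAVE_NUMBA:

    @_njit(cache=False)
    def _em_kernel_nb(P, W, tol, max_iter):  # pragma: no cover - numba-compiled
        S, K = W.shape
        L = P.shape[0]
        ll_out = np.full(S, -1e308)
        for s in range(S):
            w = W[s].copy()
            ll_prev = -1e308
            for _ in range(max_iter):
                ll = 0.0
                wnew = np.zeros(K)
                dead = False
                for l in range(L):
                    mix = 0.0
                    for k in range(K):
                        mix += P[l, k] * w[k]
                    if mix <= 0.0:
                        dead = True
                        break
                    ll += np.log(mix)
                    for k in range(K):
                        wnew[k] += P[l, k] * w[k] / mix
                if dead:
                    ll_prev = -1e308
                    break
                for k in range(K):
                    w[k] = wnew[k] / L
                if ll - ll_prev < tol:
                    ll_prev = ll
                    break
                ll_prev = ll
            if ll_prev > -1e308:
                ll_out[s] = ll_prev
            W[s] = w
        return ll_out


def em_simplex(
    P: np.ndarray,
    starts: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[np.ndarray, float]:
    """Maximize  sum_l log( P[l] @ w )  over the simplex by EM, with restarts.

    ``P`` is (n_loci, n_states) of per-locus state-conditional probabilities,
    ``starts`` is (n_starts, n_states); all restarts are iterated in parallel.
    Returns (weights, log-likelihood).  Among restarts whose final
    log-likelihoods agree within ``tol``, the solution with the largest
    weight on the first state is preferred (the state ordering puts the
    all-unrelated state first, so ties break toward the least-related
    solution).
    """
    W = np.clip(np.asarray(starts, dtype=float), 1e-12, None)
    W /= W.sum(axis=1, keepdims=True)  # (S, K)
    P = np.ascontiguousarray(P, dtype=float)
    if _HAVE_NUMBA:
        ll = _em_kernel_nb(P, W, tol, max_iter)
        ll = np.where(ll <= -1e307, -np.inf, ll)
    else:
        ll = _em_kernel_py(P, W, tol, max_iter)
    finite = np.isfinite(ll)
    if not finite.any():
        raise RuntimeError("likelihood is zero for every start (inconsistent genotypes?)")
    best_ll = float(ll[finite].max())
    near = np.flatnonzero(finite & (best_ll - ll <= tol))
    best = near[np.argmax(W[near, 0])]  # tie-break toward the least-related solution
    w = np.clip(W[best], 0.0, None)
    return w / w.sum(), float(ll[best])
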