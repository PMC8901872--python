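"""Random-mating permutation test for within-pair relatedness.

The null model: within each breeding season, the observed males are
re-assigned to the observed females uniformly at random without replacement
(a random one-to-one matching), so every simulated pairing is between birds
that bred in the same season and no bird is used twice.  Pairs that remated
in a season can be frozen (forced to remain together) so the null only
randomizes newly formed pairs.  The test statistic is the mean or the median
within-pair relatedness; two-sided p-values come from the +1-corrected
replicate counts.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .io import PairRecord
from .relatedness import RelatednessMatrix

__all__ = [
    "ObservedPairStats",
    "RandomizationResult",
    "unique_pairs",
    "observed_stats",
    "two_sided_p",
    "randomize_pairings",
    "run_full_analysis",
]


@dataclass
class ObservedPairStats:
    n_pairs: int
    mean_r: float
    sd_r: float
    median_r: float
    iqr_r: float
    prop_gt_0125: float
    prop_gt_025: float
    count_gt_0125: int
    count_gt_025: int


@dataclass
class RandomizationResult:
    statistic: str  # "mean" | "median"
    observed: float
    null_values: np.ndarray
    B: int
    seed: int
    expected: float
    p_two_sided: float
    p_extremity: float
    scope: str  # "pooled" | "year=Y"

    def to_dict(self, keep_null: bool = False) -> dict:
        d = asdict(self)
        if keep_null:
            d["null_values"] = np.asarray(self.null_values).tolist()
        else:
            d.pop("null_values")
        return d


def unique_pairs(records: list[PairRecord]) -> list[PairRecord]:
    """First observation of each female-male combination, ordered by (year, female)."""
    kept = [r for r in records if r.first_observation]
    return sorted(kept, key=lambda r: (r.year, r.female_id))


def _pair_values(
    pairs: list[PairRecord], r: RelatednessMatrix, estimator: str
) -> np.ndarray:
    missing = [
        (p.female_id, p.male_id) for p in pairs if not r.has_dyad(p.female_id, p.male_id)
    ]
    if missing:
        raise ValueError(f"no relatedness value for pairs: {missing}")
    vals = np.array([r.value(p.female_id, p.male_id, estimator) for p in pairs])
    bad = [
        (p.female_id, p.male_id) for p, v in zip(pairs, vals) if not np.isfinite(v)
    ]
    if bad:
        raise ValueError(f"non-finite relatedness value for pairs: {bad}")
    return vals


def observed_stats(
    pairs: list[PairRecord], r: RelatednessMatrix, estimator: str
) -> ObservedPairStats:
    """Summary of within-pair relatedness over the supplied pair records.

    The median is the midpoint average for even counts; the IQR is Q3 - Q1
    with linear-interpolation quantiles; SD is the sample (n-1) standard
    deviation.  Kinship thresholds 0.125 and 0.25 correspond to third- and
    second-degree relatives.
    """
    vals = _pair_values(pairs, r, estimator)
    n = len(vals)
    q1, q3 = np.percentile(vals, [25, 75])
    count_0125 = int(np.sum(vals > 0.125))
    count_025 = int(np.sum(vals > 0.25))
    return ObservedPairStats(
        n_pairs=n,
        mean_r=float(np.mean(vals)),
        sd_r=float(np.std(vals, ddof=1)) if n > 1 else 0.0,
        median_r=float(np.median(vals)),
        iqr_r=float(q3 - q1),
        prop_gt_0125=count_0125 / n,
        prop_gt_025=count_025 / n,
        count_gt_0125=count_0125,
        count_gt_025=count_025,
    )


def two_sided_p(observed: float, null_values: np.ndarray, method: str = "double_tail") -> float:
    """Two-sided Monte-Carlo p-value with the +1 correction.

    ``double_tail``: twice the smaller of the two one-sided +1-corrected tail
    probabilities, capped at 1.  ``extremity``: the probability of a null
    value at least as far from the null mean as the observed value.
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValueError("empty null distribution")
    B = null_values.size
    if method == "double_tail":
        lo = (1 + np.sum(null_values <= observed + 1e-12)) / (B + 1)
        hi = (1 + np.sum(null_values >= observed - 1e-12)) / (B + 1)
        return float(min(1.0, 2.0 * min(lo, hi)))
    if method == "extremity":
        center = float(np.mean(null_values))
        dist = abs(observed - center)
        return float(
            (1 + np.sum(np.abs(null_values - center) >= dist - 1e-12)) / (B + 1)
        )
    raise ValueError(f"unknown method {method!r}")


def _strata(pairs: list[PairRecord], respect_remated: bool):
    """Group pair indices by year; split each year into frozen and free sets."""
    by_year: dict[int, list[int]] = {}
    for i, p in enumerate(pairs):
        by_year.setdefault(p.year, []).append(i)
    strata = []
    for year in sorted(by_year):
        idx = by_year[year]
        frozen = [i for i in idx if respect_remated and pairs[i].remated]
        free = [i for i in idx if i not in frozen]
        strata.append((year, frozen, free))
    return strata


def randomize_pairings(
    pairs: list[PairRecord],
    r: RelatednessMatrix,
    estimator: str,
    B: int = 10_000,
    seed: int = 0,
    scope: str = "pooled",
    respect_remated: bool = False,
    return_assignments: bool = False,
) -> tuple[RandomizationResult, RandomizationResult]:
    """Monte-Carlo random-mating null for the mean and median pair relatedness.

    Each replicate permutes, independently within every year, the year's males
    uniformly at random among the year's females (sampling without
    replacement).  With ``respect_remated`` the pairs flagged as remated are
    frozen and excluded from the permutation.  ``scope`` is ``"pooled"`` (all
    supplied pairs, each anchored to its own year stratum) or ``"year=Y"``.
    A single top-level seed derives one RNG substream per replicate, so
    results do not depend on execution order.  Returns the (mean, median)
    result pair; optionally also the per-replicate male assignments (used by
    conservation checks).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if scope != "pooled":
        if not scope.startswith("year="):
            raise ValueError(f"scope must be 'pooled' or 'year=Y', got {scope!r}")
        year = int(scope.split("=", 1)[1])
        pairs = [p for p in pairs if p.year == year]
        if not pairs:
            raise ValueError(f"no pairs in scope {scope!r}")
    vals_obs = _pair_values(pairs, r, estimator)
    strata = _strata(pairs, respect_remated)

    # pre-resolve relatedness lookups: per stratum an (n_free x n_free) matrix
    # of r(female_i, male_j) over the stratum's free pairs
    stratum_mats = []
    for year, frozen, free in strata:
        females = [pairs[i].female_id for i in free]
        males = [pairs[i].male_id for i in free]
        mat = np.array(
            [[r.value(f, m, estimator) for m in males] for f in females]
        )
        stratum_mats.append(mat)
    frozen_vals = np.array(
        [vals_obs[i] for _, frozen, _ in strata for i in frozen]
    )

    children = np.random.SeedSequence(seed).spawn(B)
    null_mean = np.empty(B)
    null_median = np.empty(B)
    assignments = [] if return_assignments else None
    for b in range(B):
        rng = np.random.default_rng(children[b])
        reps = [frozen_vals] if frozen_vals.size else []
        rep_assign = [] if return_assignments else None
        for (year, frozen, free), mat in zip(strata, stratum_mats):
            if not free:
                continue
            perm = rng.permutation(len(free))
            reps.append(mat[np.arange(len(free)), perm])
            if return_assignments:
                rep_assign.append((year, [pairs[i].female_id for i in free],
                                   [pairs[free[j]].male_id for j in perm]))
        rep_vals = np.concatenate(reps)
        null_mean[b] = np.mean(rep_vals)
        null_median[b] = np.median(rep_vals)
        if return_assignments:
            assignments.append(rep_assign)

    def _result(stat_name: str, obs: float, nulls: np.ndarray) -> RandomizationResult:
        return RandomizationResult(
            statistic=stat_name,
            observed=float(obs),
            null_values=nulls,
            B=B,
            seed=seed,
            expected=float(np.mean(nulls)),
            p_two_sided=two_sided_p(obs, nulls, "double_tail"),
            p_extremity=two_sided_p(obs, nulls, "extremity"),
            scope=scope,
        )

    res = (
        _result("mean", np.mean(vals_obs), null_mean),
        _result("median", np.median(vals_obs), null_median),
    )
    if return_assignments:
        return res, assignments
    return res


def run_full_analysis(
    records: list[PairRecord],
    r: RelatednessMatrix,
    estimator: str,
    b_pooled: int = 10_000,
    b_yearly: int = 1_000,
    seed: int = 0,
    freeze_remated_pooled: bool = False,
) -> dict:
    """Pooled and per-year random-mating tests, mirroring the full study design.

    The pooled analysis uses the first observation of each unique pair
    (anchored to the year of first observation) with ``b_pooled`` replicates;
    the yearly analyses use all pairs captured in each year with ``b_yearly``
    replicates and remated pairs frozen.  Returns a JSON-serializable report.
    """
    uniq = unique_pairs(records)
    stats = observed_stats(uniq, r, estimator)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(1 + len({p.year for p in records})) % (2**31 - 1)
    pooled_mean, pooled_median = randomize_pairings(
        uniq, r, estimator, B=b_pooled, seed=int(seeds[0]),
        scope="pooled", respect_remated=freeze_remated_pooled,
    )
    yearly = {}
    years = sorted({p.year for p in records})
    for k, year in enumerate(years):
        ymean, ymedian = randomize_pairings(
            records, r, estimator, B=b_yearly, seed=int(seeds[1 + k]),
            scope=f"year={year}", respect_remated=True,
        )
        yearly[year] = {
            "n": sum(1 for p in records if p.year == year),
            "mean": ymean.to_dict(),
            "median": ymedian.to_dict(),
        }
    return {
        "estimator": estimator,
        "seed": seed,
        "n_records": len(records),
        "n_unique_pairs": len(uniq),
        "observed": asdict(stats),
        "pooled": {"mean": pooled_mean.to_dict(), "median": pooled_median.to_dict()},
        "yearly": yearly,
    }
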