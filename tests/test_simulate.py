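"""Synthetic pedigreed population: Mendelian consistency, kinship oracle,
demography, kin-avoidance bias."""

import numpy as np
import pytest

from kinmate.io import allele_frequencies
from kinmate.qc import probability_of_identity
from kinmate.randomization import unique_pairs
from kinmate.simulate import (
    Pedigree,
    PopulationConfig,
    pedigree_relatedness,
    simulate_population,
)


@pytest.fixture(scope="module")
def default_sim():
    return simulate_population(PopulationConfig(seed=42))


def test_offspring_alleles_come_from_parents(default_sim):
    table, pedigree = default_sim.table, default_sim.pedigree
    checked = 0
    for ind in table.individuals:
        sire, dam = pedigree.parents(ind.id)
        if sire is None or sire not in table._index or dam not in table._index:
            continue
        child = table.genotype(ind.id)
        sg, dg = table.genotype(sire), table.genotype(dam)
        for j in range(table.n_loci):
            a, b = child[j]
            from_sire = a in sg[j] and b in dg[j]
            from_dam = b in sg[j] and a in dg[j]
            assert from_sire or from_dam
        checked += 1
    assert checked >= 20


def test_pedigree_relatedness_oracle_values():
    ped = Pedigree()
    for ident in ("gpa", "gma", "gpb", "gmb"):
        ped.add(ident, None, None, "male" if "p" in ident else "female", 0)
    ped.add("father", "gpa", "gma", "male", 1)
    ped.add("uncle", "gpa", "gma", "male", 1)
    ped.add("aunt_unrel", None, None, "female", 1)
    ped.add("mother", "gpb", "gmb", "female", 1)
    ped.add("child", "father", "mother", "female", 2)
    ped.add("cousin", "uncle", "aunt_unrel", "male", 2)
    assert pedigree_relatedness(ped, "father", "child") == pytest.approx(0.5)
    assert pedigree_relatedness(ped, "gpa", "gpb") == 0.0
    assert pedigree_relatedness(ped, "father", "uncle") == pytest.approx(0.5)
    # first cousins through shared unrelated grandparents
    assert pedigree_relatedness(ped, "child", "cousin") == pytest.approx(0.125)
    with pytest.raises(KeyError):
        pedigree_relatedness(ped, "child", "stranger")


def test_demography_matches_study_scale(default_sim):
    table, pairs = default_sim.table, default_sim.pairs
    assert 120 <= table.n_individuals <= 260  # ~180 breeding adults
    by_year = {}
    for p in pairs:
        by_year[p.year] = by_year.get(p.year, 0) + 1
    assert len(by_year) == 8
    assert all(12 <= n <= 32 for n in by_year.values())
    assert len(unique_pairs(pairs)) < len(pairs)  # some remating occurred


def test_generated_data_pass_io_and_qc_validations(default_sim):
    table = default_sim.table
    freqs = allele_frequencies(table)  # validates the frequency invariants
    assert len(freqs.loci) == 12
    pid = probability_of_identity(freqs)
    assert 0 < pid < 1e-6  # informative multilocus panel
    # pair records validate against the table (sexes, one pair per year)
    from kinmate.io import write_genotypes, read_genotypes

    # round trip of the generated table
    import tempfile, pathlib

    with tempfile.TemporaryDirectory() as td:
        path = pathlib.Path(td) / "g.csv"
        write_genotypes(table, path)
        assert read_genotypes(path) == table


def test_reproducible_and_seed_sensitive():
    a = simulate_population(PopulationConfig(seed=7, n_years=3, n_founders=30))
    b = simulate_population(PopulationConfig(seed=7, n_years=3, n_founders=30))
    c = simulate_population(PopulationConfig(seed=8, n_years=3, n_founders=30))
    assert a.table == b.table
    assert a.pairs == b.pairs
    assert a.table != c.table


def test_kin_avoidance_lowers_within_pair_pedigree_relatedness():
    """Strong avoidance (large s) must strictly lower the mean pedigree
    relatedness of realized pairs relative to random mating."""

    def mean_pair_rho(s, seed):
        sim = simulate_population(
            PopulationConfig(seed=seed, kin_avoidance_strength=s)
        )
        rhos = [
            pedigree_relatedness(sim.pedigree, p.female_id, p.male_id)
            for p in sim.pairs
            if p.year >= 4  # relatives only accumulate after a few seasons
        ]
        return float(np.mean(rhos))

    random_mating = np.mean([mean_pair_rho(0.0, s) for s in range(3)])
    avoided = np.mean([mean_pair_rho(25.0, s) for s in range(3)])
    assert avoided < random_mating


def test_female_biased_dispersal_elevates_local_male_relatedness():
    """With female-biased dispersal and fragment-local pairing, males breeding
    in the same fragment should be more related than the population at large
    (males are philopatric, females move)."""
    same_frag, diff_frag = [], []
    for seed in range(4):
        sim = simulate_population(
            PopulationConfig(seed=100 + seed, dispersal_bias="female_biased")
        )
        males = [i.id for i in sim.table.individuals if i.sex == "male"]
        for i, a in enumerate(males):
            for b in males[i + 1 :]:
                rho = pedigree_relatedness(sim.pedigree, a, b)
                if sim.fragments[a] == sim.fragments[b]:
                    same_frag.append(rho)
                else:
                    diff_frag.append(rho)
    assert np.mean(same_frag) > np.mean(diff_frag)


def test_trioml_tracks_pedigree_relatedness():
    """Marker-based triadic ML must correlate strongly (Pearson >= 0.7) with
    the pedigree oracle on dyads spanning the relatedness range."""
    from kinmate.io import allele_frequencies
    from kinmate.relatedness import estimate_pairs

    sim = simulate_population(
        PopulationConfig(seed=9, n_founders=30, n_years=8, burn_in_years=6)
    )
    ids = sim.table.ids
    rng = np.random.default_rng(1)
    order = rng.permutation(len(ids))
    bins: dict[int, list] = {0: [], 1: [], 2: []}
    for i in order:
        for j in order:
            if i >= j:
                continue
            rho = pedigree_relatedness(sim.pedigree, ids[i], ids[j])
            b = 0 if rho == 0 else (1 if rho < 0.2 else 2)
            if len(bins[b]) < 150:
                bins[b].append((i, j, rho))
    pick = bins[0] + bins[1] + bins[2]
    ia = np.array([p[0] for p in pick])
    ib = np.array([p[1] for p in pick])
    rho = np.array([p[2] for p in pick])
    geno = sim.table.genotypes
    est = estimate_pairs(
        geno[ia], geno[ib], allele_frequencies(sim.table), "trioml",
        reference_pool=sim.table, n_reference=10, seed=3,
    )
    assert np.corrcoef(est, rho)[0, 1] >= 0.7


def test_stronger_kin_avoidance_lowers_median_test_p():
    """Mean p of the pooled median test decreases monotonically along a
    3-point grid of the avoidance strength s."""
    from kinmate.relatedness import pairwise_matrix
    from kinmate.randomization import randomize_pairings

    def med_p(seed, s):
        kw = dict(n_founders=24, n_years=12, burn_in_years=10, juvenile_recruitment=0.40)
        sim = simulate_population(
            PopulationConfig(seed=seed, kin_avoidance_strength=s, **kw)
        )
        needed = set()
        by_year: dict[int, tuple[list, list]] = {}
        for p in sim.pairs:
            fs, ms = by_year.setdefault(p.year, ([], []))
            fs.append(p.female_id)
            ms.append(p.male_id)
        for fs, ms in by_year.values():
            needed.update((f, m) for f in fs for m in ms)
        mat = pairwise_matrix(sim.table, ["qg"], dyads=sorted(needed))
        _, med = randomize_pairings(
            unique_pairs(sim.pairs), mat, "qg", B=299, seed=seed + 10_000
        )
        return med.p_two_sided

    mean_ps = [
        np.mean([med_p(900 + k, s) for k in range(25)]) for s in (0.0, 8.0, 40.0)
    ]
    assert mean_ps[0] > mean_ps[1] > mean_ps[2]


def test_infeasible_config_raises():
    with pytest.raises((RuntimeError, ValueError)):
        # no males can ever exist: single founder
        simulate_population(PopulationConfig(n_founders=1, n_years=2, seed=0))


def test_config_validation():
    with pytest.raises(ValueError):
        PopulationConfig(adult_survival=1.2)
    with pytest.raises(ValueError):
        PopulationConfig(kin_avoidance_strength=-1)
    with pytest.raises(ValueError):
        PopulationConfig(age_at_first_breeding={1: 0.5, 2: 0.4})


def test_pedigree_graph_is_acyclic(default_sim):
    g = default_sim.pedigree.graph()
    assert g.number_of_nodes() == len(default_sim.pedigree)
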