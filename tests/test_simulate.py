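"""Stochastic cage cycle and its deterministic mean-field recursion."""

import numpy as np
import pytest

from drivecage.genetics import DD, DW, WW, DriveParams, Sex
from drivecage.simulate import (
    CageConfig,
    CageTrajectory,
    DegenerateStateError,
    Population,
    advance_generation,
    carrier_frequency,
    expected_phenotype_trajectory,
    seed_cage,
    simulate_cage,
)


def test_seed_cage_study_composition():
    pop = seed_cage(15, 15, 45, 45)
    assert pop.total == 120
    assert pop.n_dsred_positive == 30
    assert pop.count(DW, Sex.MALE) == 15
    assert pop.count(DW, Sex.FEMALE) == 15
    assert pop.count(WW, Sex.FEMALE) == 45


def test_seed_cage_edge_cases():
    assert seed_cage(0, 0, 10, 10).total == 20
    assert seed_cage(0, 0, 10, 10).n_dsred_positive == 0
    with pytest.raises(ValueError):
        seed_cage(-1, 0, 0, 0)


def test_no_females_leads_to_extinction(rng, study_params):
    pop = seed_cage(1, 0, 0, 0)  # one male, no mothers
    nxt = advance_generation(pop, study_params, census=50, rng=rng)
    assert nxt.total == 0


def test_all_sterile_females_leads_to_extinction(rng, study_params):
    pop = Population.from_dict({(DD, Sex.FEMALE): 10, (WW, Sex.MALE): 10})
    nxt = advance_generation(pop, study_params, census=50, rng=rng)
    assert nxt.total == 0


def test_wild_type_population_is_closed(rng, study_params):
    pop = seed_cage(0, 0, 20, 20)
    nxt = advance_generation(pop, study_params, census=77, rng=rng)
    assert nxt.total == 77
    assert nxt.count(WW, Sex.FEMALE) + nxt.count(WW, Sex.MALE) == 77


def test_census_is_conserved_exactly(rng, study_params):
    pop = seed_cage(15, 15, 45, 45)
    for census in (120, 37, 400):
        nxt = advance_generation(pop, study_params, census=census, rng=rng)
        assert nxt.total == census


def test_one_step_carrier_frequency_matches_hardy_weinberg(rng, mendelian_params):
    # 25% heterozygotes in both sexes with Mendelian transmission: the
    # expected carrier frequency after one round of random mating is
    # 1 - (1 - 0.125)^2 = 0.234375.  With only 60 founder females the
    # realized frequency of a single cage also carries mate-pairing noise,
    # so the check averages replicate cages and uses the empirical SE.
    expected = 0.234375
    pop = seed_cage(15, 15, 45, 45)
    n_rep, census = 400, 10**4
    fracs = np.array([
        advance_generation(pop, mendelian_params, census=census,
                           rng=rng).n_dsred_positive / census
        for _ in range(n_rep)
    ])
    se_mean = fracs.std(ddof=1) / np.sqrt(n_rep)
    assert abs(fracs.mean() - expected) < 4 * se_mean
    # with founders scaled up alongside the census, a single draw lands
    # within Monte-Carlo distance of the closed-form value
    big = seed_cage(25_000, 25_000, 75_000, 75_000)
    census = 10**6
    one = advance_generation(big, mendelian_params, census=census, rng=rng)
    assert abs(one.n_dsred_positive / census - expected) < 4 * np.sqrt(
        expected * (1 - expected) / census + expected * (1 - expected) / 100_000
    )


def test_simulate_cage_deterministic_under_seed(study_params):
    config = CageConfig(census=120, n_generations=8, seed=42)
    t1 = simulate_cage(config, study_params)
    t2 = simulate_cage(CageConfig(census=120, n_generations=8, seed=42),
                       study_params)
    assert t1.n_dsred_pos == t2.n_dsred_pos
    assert t1.n_total == t2.n_total
    assert t1.truth == t2.truth


def test_simulate_cage_generation_zero_is_the_seed(study_params):
    traj = simulate_cage(CageConfig(seed=1, n_generations=3), study_params)
    assert traj.n_dsred_pos[0] == 30
    assert traj.n_total[0] == 120
    assert traj.n_generations == 4  # founders + 3


def test_mendelian_transmission_cage_mean_follows_recursion():
    # With c = r = 0 and f = 1 transmission is Mendelian, but homozygous
    # female sterility remains part of the model, so the carrier frequency
    # still erodes slowly; the correct oracle for the replicate mean is the
    # deterministic recursion, not a flat neutral line.
    params = DriveParams(c_f=0, c_m=0, r_f=0, r_m=0, f_het=1.0)
    expected = carrier_frequency(
        expected_phenotype_trajectory({DW: 0.25, WW: 0.75}, params, 12)
    )
    rng = np.random.default_rng(7)
    n_rep, gens = 200, 12
    freqs = np.empty((n_rep, gens + 1))
    for i in range(n_rep):
        config = CageConfig(census=120, n_generations=gens)
        traj = simulate_cage(config, params, rng=rng)
        freqs[i] = traj.carrier_frequency
    mean = freqs.mean(axis=0)
    se = freqs[:, 1:].std(axis=0, ddof=1) / np.sqrt(n_rep)
    assert np.all(np.abs(mean[1:] - expected[1:]) < 4 * np.maximum(se, 1e-3))


def test_drive_with_cost_declines_on_average(study_params):
    params = study_params.replace(f_het=0.53)
    rng = np.random.default_rng(11)
    n_rep, gens = 100, 10
    freqs = np.empty((n_rep, gens + 1))
    for i in range(n_rep):
        traj = simulate_cage(CageConfig(census=120, n_generations=gens),
                             params, rng=rng)
        freqs[i] = traj.carrier_frequency
    mean = freqs.mean(axis=0)
    assert np.all(np.diff(mean) < 0), "replicate-mean carrier frequency must fall"


def test_expected_trajectory_mendelian_generation_one(mendelian_params):
    traj = expected_phenotype_trajectory({DW: 0.25, WW: 0.75},
                                         mendelian_params, 5)
    cf = carrier_frequency(traj)
    assert cf[0] == pytest.approx(0.25)
    assert cf[1] == pytest.approx(0.234375, abs=1e-12)
    # homozygous-female sterility still removes drive alleles slowly, so
    # after generation 1 the carrier frequency is strictly decreasing
    assert np.all(np.diff(cf[1:]) < 0)


def test_expected_trajectory_all_wild_type(study_params):
    traj = expected_phenotype_trajectory({WW: 1.0}, study_params, 6)
    assert np.allclose(carrier_frequency(traj), 0.0)


def test_expected_trajectory_degenerate_when_all_females_sterile(study_params):
    with pytest.raises(DegenerateStateError):
        expected_phenotype_trajectory({DD: 1.0}, study_params, 2)


def test_large_census_simulation_converges_to_recursion(study_params):
    params = study_params.replace(f_het=0.53)
    expected = carrier_frequency(
        expected_phenotype_trajectory({DW: 0.25, WW: 0.75}, params, 5)
    )
    rng = np.random.default_rng(3)
    census = 10**5
    config = CageConfig(
        census=census, n_generations=5,
        initial=seed_cage(12500, 12500, 37500, 37500),
    )
    traj = simulate_cage(config, params, rng=rng)
    obs = traj.carrier_frequency
    se = np.sqrt(expected[1:] * (1 - expected[1:]) / census)
    assert np.all(np.abs(obs[1:] - expected[1:]) < 4 * se)


def test_expected_trajectory_monotone_in_fitness(study_params):
    # lowering heterozygous-female fitness can only depress the carrier curve
    grid = [1.0, 0.8, 0.53, 0.3, 0.1]
    curves = [
        carrier_frequency(
            expected_phenotype_trajectory(
                {DW: 0.25, WW: 0.75}, study_params.replace(f_het=f), 8
            )
        )
        for f in grid
    ]
    for hi, lo in zip(curves, curves[1:]):
        assert np.all(lo[1:] <= hi[1:] + 1e-12)


def test_trajectory_validation():
    with pytest.raises(ValueError):
        CageTrajectory(cage_id="x", n_dsred_pos=[5], n_total=[4])
    with pytest.raises(ValueError):
        CageTrajectory(cage_id="x", n_dsred_pos=[1, 2], n_total=[10])
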