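"""Likelihood construction and ML recovery of the heterozygous-female fitness."""

import numpy as np
import pytest

from drivecage.genetics import DriveParams
from drivecage.inference import (
    CageFitnessModel,
    ImpossibleObservationError,
    condition_on_observation,
    fit_fitness,
    trajectory_log_likelihood,
)
from drivecage.simulate import (
    CageConfig,
    CageTrajectory,
    _GIDX,
    carrier_frequency,
    expected_phenotype_trajectory,
    seed_cage,
    simulate_cage,
)
from drivecage.genetics import DD, DW, WR, WW
from drivecage.synthetic import SyntheticSpec, generate_cage_data


def test_conditioning_rescales_within_phenotype_classes():
    predicted = {DW: 0.20, DD: 0.05, WW: 0.70, WR: 0.05}
    out = condition_on_observation(predicted, 30, 100)
    assert out[_GIDX[DW]] == pytest.approx(0.24)
    assert out[_GIDX[DD]] == pytest.approx(0.06)
    assert out[_GIDX[WW]] == pytest.approx(0.7 * 0.7 / 0.75)
    assert out[_GIDX[WR]] == pytest.approx(0.05 * 0.7 / 0.75)
    assert out.sum() == pytest.approx(1.0, abs=1e-12)


def test_conditioning_is_identity_when_observation_matches():
    predicted = {DW: 0.25, WW: 0.75}
    out = condition_on_observation(predicted, 25, 100)
    assert out[_GIDX[DW]] == pytest.approx(0.25, abs=1e-12)
    assert out[_GIDX[WW]] == pytest.approx(0.75, abs=1e-12)
    # all wild-type predicted and observed: unchanged
    out2 = condition_on_observation({WW: 1.0}, 0, 50)
    assert out2[_GIDX[WW]] == pytest.approx(1.0)


def test_conditioning_flags_impossible_observation():
    with pytest.raises(ImpossibleObservationError):
        condition_on_observation({WW: 1.0}, 3, 50)


@pytest.mark.parametrize("norm", [1e-12])
def test_conditioned_state_normalizes(norm, rng):
    for _ in range(50):
        v = rng.dirichlet(np.ones(6))
        n = int(rng.integers(10, 200))
        k = int(rng.integers(1, n))
        out = condition_on_observation(v, k, n)
        assert abs(out.sum() - 1.0) < norm
        assert (out >= 0).all()


def test_single_transition_kernel_drops_constants(study_params):
    # one transition predicted at carrier frequency ~0.5 observed as 10/20:
    # the kernel contribution is 20 * ln(0.5) = -13.8629 when the predicted
    # frequency is exactly one half (engineered via symmetric parameters)
    # -- here checked directly on the kernel used by the likelihood
    from drivecage.inference import _binom_kernel

    assert _binom_kernel(10, 20, 0.5) == pytest.approx(20 * np.log(0.5), abs=1e-10)
    assert _binom_kernel(0, 20, 0.0) == 0.0
    assert _binom_kernel(1, 20, 0.0) == -np.inf


def test_two_identical_cages_double_the_log_likelihood(study_params):
    traj = simulate_cage(CageConfig(seed=5, n_generations=8),
                         study_params.replace(f_het=0.53))
    single = trajectory_log_likelihood(traj, study_params, 0.6)
    model = CageFitnessModel([traj, traj], params=study_params)
    assert model.loglike(0.6) == pytest.approx(2 * single, rel=1e-12)


def test_likelihood_finite_for_simulator_output(study_params):
    # anything the simulator can emit under the same parameters must score
    # with finite likelihood for f in (0, 1.5]
    rng = np.random.default_rng(99)
    for f in (0.2, 0.53, 1.0, 1.5):
        traj = simulate_cage(CageConfig(n_generations=10),
                             study_params.replace(f_het=f), rng=rng)
        for f_eval in (0.05, 0.53, 1.0, 1.5):
            ll = trajectory_log_likelihood(traj, study_params, f_eval)
            assert np.isfinite(ll)


def test_self_consistency_deterministic_data_maximal_at_truth(study_params):
    # build data from the deterministic recursion itself (large rounded
    # counts) at f = 1: the grid maximum must sit at f = 1
    cf = carrier_frequency(
        expected_phenotype_trajectory({DW: 0.25, WW: 0.75},
                                      study_params.replace(f_het=1.0), 10)
    )
    n = 100_000
    traj = CageTrajectory(
        cage_id="det",
        n_dsred_pos=[int(round(n * f)) for f in cf],
        n_total=[n] * len(cf),
    )
    model = CageFitnessModel(traj, params=study_params, grid_step=0.01)
    grid = np.arange(0.0, 1.5001, 0.01)
    lls = [model.loglike(f) for f in grid]
    assert grid[int(np.argmax(lls))] == pytest.approx(1.0, abs=0.011)


def test_fit_recovers_moderate_cost_from_synthetic_cages(study_params):
    # small parameter-recovery experiment with the simulator as oracle
    costs = []
    for i in range(12):
        spec = SyntheticSpec(seed=300 + i)
        trajs, _ = generate_cage_data(spec, f_het_true=0.53)
        costs.append(fit_fitness(trajs, params=study_params).cost_hat)
    assert abs(np.mean(costs) - 0.47) < 0.10


def test_high_census_recovery_is_tight(study_params):
    # census 10^4, 12 generations: single-cage errors average below 0.03
    # for a spread of true costs
    rng = np.random.default_rng(17)
    for true_cost in (0.2, 0.47, 0.7):
        errors = []
        for _ in range(8):
            config = CageConfig(
                census=10_000, n_generations=12,
                initial=seed_cage(1250, 1250, 3750, 3750),
            )
            traj = simulate_cage(config,
                                 study_params.replace(f_het=1 - true_cost),
                                 rng=rng)
            fit = fit_fitness(traj, params=study_params)
            errors.append(fit.cost_hat - true_cost)
        assert abs(np.mean(errors)) < 0.03


def test_no_drive_data_is_flagged_unidentifiable(study_params):
    traj = CageTrajectory(cage_id="wt", n_dsred_pos=[0] * 8, n_total=[120] * 8)
    res = fit_fitness(traj, params=study_params)
    assert not res.identifiable
    assert res.ci95 == res.bounds


def test_doubling_counts_moves_argmax_at_most_one_grid_step(study_params):
    traj = simulate_cage(CageConfig(seed=21, n_generations=10),
                         study_params.replace(f_het=0.53))
    doubled = CageTrajectory(
        cage_id="x2",
        n_dsred_pos=[2 * k for k in traj.n_dsred_pos],
        n_total=[2 * n for n in traj.n_total],
    )
    f1 = fit_fitness(traj, params=study_params).f_het_hat
    f2 = fit_fitness(doubled, params=study_params).f_het_hat
    assert abs(f1 - f2) <= 0.005 + 1e-9


def test_profile_maximum_matches_reported_loglik(study_params):
    trajs, _ = generate_cage_data(SyntheticSpec(seed=4), f_het_true=0.53)
    res = fit_fitness(trajs, params=study_params)
    finite = np.isfinite(res.profile[:, 1])
    assert res.profile[finite, 1].max() == pytest.approx(res.log_likelihood)
    assert res.bounds[0] <= res.f_het_hat <= res.bounds[1]
    assert res.ci95[0] <= res.f_het_hat <= res.ci95[1]
    assert res.cost_hat == pytest.approx(1 - res.f_het_hat)


def test_ci_covers_truth_reasonably_often(study_params):
    hits = 0
    n_rep = 12
    for i in range(n_rep):
        trajs, _ = generate_cage_data(SyntheticSpec(seed=600 + i),
                                      f_het_true=0.53)
        res = fit_fitness(trajs, params=study_params)
        if res.ci95[0] <= 0.53 <= res.ci95[1]:
            hits += 1
    assert hits >= n_rep // 2  # loose sanity bound for a 95% interval


def test_model_from_dataframe_roundtrip(study_params):
    trajs, _ = generate_cage_data(SyntheticSpec(seed=8, n_generations=6),
                                  f_het_true=0.7)
    import pandas as pd

    df = pd.concat([t.to_frame() for t in trajs], ignore_index=True)
    m1 = CageFitnessModel(trajs, params=study_params)
    m2 = CageFitnessModel.from_dataframe(df, params=study_params)
    assert m1.loglike(0.7) == pytest.approx(m2.loglike(0.7), rel=1e-12)


def test_summary_mentions_key_quantities(study_params):
    trajs, _ = generate_cage_data(SyntheticSpec(seed=9, n_generations=6),
                                  f_het_true=0.6)
    res = fit_fitness(trajs, params=study_params)
    text = res.summary()
    assert "fitness cost" in text
    assert f"{res.cost_hat:.4f}" in text
    assert "95% CI" in text
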