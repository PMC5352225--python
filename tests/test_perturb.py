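import numpy as np
import pytest

from statefate import perturb
from statefate.errors import PreconditionError, ValidationError
from statefate.grn import CouplingEnsemble, ModelConfig
from statefate.modules import BinaryStateMatrix
from statefate.perturb import (
    classify_distribution,
    ensemble_markov,
    overexpression_scan,
    step_state,
)


class TestStepState:
    def test_fixed_point_unchanged(self, grn_instance):
        cfg = ModelConfig(phi0=grn_instance.phi0)
        for k in range(grn_instance.states.n_states):
            s = grn_instance.states.values[:, k].astype(float)
            np.testing.assert_array_equal(
                step_state(grn_instance.J_true, s, config=cfg), s
            )

    def test_zero_state_absorbing(self):
        rng = np.random.default_rng(0)
        J = rng.uniform(-1, 1, (7, 7))
        out = step_state(J, np.zeros(7), config=ModelConfig(phi0=0.1))
        assert (out == 0).all()

    def test_two_module_hand_case(self):
        # J12 = 0.5, J21 = -0.5, phi0 = 0.1, state (1, 1):
        # drive on 1 = J11*1 + J12*1 = 0.5 -> on; drive on 2 = -0.5 -> off
        J = np.array([[0.0, 0.5], [-0.5, 0.0]])
        out = step_state(J, np.array([1.0, 1.0]), config=ModelConfig(phi0=0.1))
        np.testing.assert_array_equal(out, [1.0, 0.0])

    def test_clamp_enters_drive_but_not_update(self):
        J = np.array([[0.0, 0.5], [0.0, 0.0]])
        # module 1 would go off (no drive), but clamp holds it at 1.5 and
        # its level feeds module 0's drive
        out = step_state(J, np.array([0.0, 1.0]), clamps={1: 1.5},
                         config=ModelConfig(phi0=0.1))
        np.testing.assert_array_equal(out, [1.0, 1.5])


def constructed_ensemble(n_models=50, seed=0):
    """Two modules: a self-sustaining driver and a target whose coupling
    from the driver is uniformly negative. State (1, 1) is fixed for all."""
    rng = np.random.default_rng(seed)
    phi0 = 0.1
    J = np.zeros((n_models, 2, 2))
    J[:, 0, 0] = 0.5
    j10 = rng.uniform(-0.9, -0.1, n_models)
    eta = rng.uniform(0.0, 0.5, n_models)
    J[:, 1, 0] = j10
    J[:, 1, 1] = phi0 - j10 + eta  # base drive on target = phi0 + eta >= phi0
    states = BinaryStateMatrix(
        np.array([[1], [1]]), ["driver", "target"], ["S"]
    )
    return CouplingEnsemble(J, ModelConfig(phi0=phi0), states,
                            np.zeros(n_models, dtype=int))


class TestOverexpressionScan:
    def test_zero_delta_zero_fraction(self):
        ens = constructed_ensemble()
        out = overexpression_scan(ens, "S", "driver", "target",
                                  delta_grid=[0.0, 0.5])
        assert out.loc[out.delta_s == 0.0, "fraction_down"].item() == 0.0

    def test_monotone_under_negative_coupling(self):
        ens = constructed_ensemble()
        grid = np.round(np.arange(0, 2.01, 0.1), 10)
        out = overexpression_scan(ens, "S", "driver", "target", delta_grid=grid)
        fractions = out["fraction_down"].to_numpy()
        assert fractions[0] == 0.0
        assert (np.diff(fractions) >= -1e-12).all()
        assert fractions[-1] > fractions[0]  # some models do flip

    def test_fraction_matches_threshold_prediction(self):
        # model m flips exactly when delta > eta_m / |J10_m|
        ens = constructed_ensemble(n_models=200, seed=3)
        eta = ens.samples[:, 1, 1] + ens.samples[:, 1, 0] - 0.1
        thresh = eta / (-ens.samples[:, 1, 0])
        for ds in (0.3, 0.7, 1.5):
            out = overexpression_scan(ens, "S", "driver", "target",
                                      delta_grid=[0.0, ds])
            expect = float(np.mean(thresh < ds - 1e-12))
            got = out.loc[out.delta_s == ds, "fraction_down"].item()
            assert got == pytest.approx(expect, abs=1 / 200)

    def test_non_fixed_initial_state_rejected(self):
        ens = constructed_ensemble()
        # break the target's self-coupling in one model so (1,1) is no
        # longer a common fixed point
        ens.samples[0, 1, 1] = 0.0
        with pytest.raises(PreconditionError):
            overexpression_scan(ens, np.array([1.0, 1.0]), 0, 1,
                                delta_grid=[0.0])

    def test_module_must_be_expressed(self):
        ens = constructed_ensemble()
        with pytest.raises(PreconditionError):
            overexpression_scan(ens, np.array([0.0, 0.0]), "driver", "target",
                                delta_grid=[0.0])

    def test_bad_grid_rejected(self):
        ens = constructed_ensemble()
        with pytest.raises(ValidationError):
            overexpression_scan(ens, "S", "driver", "target",
                                delta_grid=[0.5, 0.1])


def dense_propagation(ensemble, init, clamps, n_steps):
    """Oracle: full 2^N transition-matrix propagation."""
    n_mod = ensemble.samples.shape[1]
    n_states = 2 ** n_mod
    grid = ((np.arange(n_states)[:, None] >> np.arange(n_mod)[None, :]) & 1).astype(float)
    clamp_idx = sorted(clamps or {})
    lvl = np.array([clamps[i] for i in clamp_idx]) if clamp_idx else None

    def encode(v):
        return int(sum(int(v[i]) << i for i in range(n_mod)))

    T = np.zeros((n_states, n_states))
    for J in ensemble.samples:
        for a in range(n_states):
            s = grid[a].copy()
            if clamp_idx:
                s[clamp_idx] = lvl
            img = (J @ s - ensemble.config.phi0 >= 0).astype(float)
            if clamp_idx:
                img[clamp_idx] = lvl
            T[encode(img), a] += 1.0 / ensemble.n_samples
    p = np.zeros(n_states)
    s0 = init.copy()
    if clamp_idx:
        s0[clamp_idx] = lvl
    p[encode(s0)] = 1.0
    for _ in range(n_steps):
        p = T @ p
    return grid, p


class TestEnsembleMarkov:
    def test_common_fixed_point_stationary(self, grn_instance, small_ensemble):
        init = grn_instance.states.values[:, 0].astype(float)
        dist = ensemble_markov(small_ensemble, init, n_steps=50)
        assert dist.mass(init) == pytest.approx(1.0)
        assert dist.truncated_mass == 0.0

    def test_clamped_expressed_modules_stay_stationary(self, grn_instance, small_ensemble):
        init = grn_instance.states.values[:, 0].astype(float)
        on_modules = [i for i, v in enumerate(init) if v == 1][:2]
        dist = ensemble_markov(small_ensemble, init,
                              clamps={i: 1.0 for i in on_modules}, n_steps=20)
        assert dist.mass(init) == pytest.approx(1.0)

    @pytest.mark.parametrize("clamp_level", [None, 1.0])
    def test_lazy_equals_dense_oracle(self, clamp_level):
        # clamping one module ON destabilizes states: compare lazy sparse
        # propagation against the dense 2^N matrix power at 100 steps
        rng = np.random.default_rng(7)
        n_mod, n_models = 8, 30
        J = rng.uniform(-1, 1, size=(n_models, n_mod, n_mod))
        states = BinaryStateMatrix(
            np.zeros((n_mod, 0), dtype=int), [f"M{i}" for i in range(n_mod)], []
        )
        ens = CouplingEnsemble(J, ModelConfig(), states, np.zeros(n_models, dtype=int))
        init = rng.integers(0, 2, n_mod).astype(float)
        clamps = {} if clamp_level is None else {0: clamp_level}
        dist = ensemble_markov(ens, init, clamps=clamps, n_steps=100, prob_floor=0.0)
        grid, p = dense_propagation(ens, init, clamps, 100)
        for row, prob in zip(grid, p):
            if clamps and row[0] != 1.0:
                # clamped-off twin states never carry mass in the oracle
                assert prob == pytest.approx(0.0, abs=1e-12)
                continue
            key = row.copy()
            if clamps:
                key[0] = clamp_level
            assert dist.probs.get(tuple(key), 0.0) == pytest.approx(prob, abs=1e-9)

    def test_probability_conserved_without_floor(self, small_ensemble, grn_instance):
        init = np.ones(grn_instance.states.n_modules)
        dist = ensemble_markov(small_ensemble, init, n_steps=30, prob_floor=0.0)
        assert dist.total() == pytest.approx(1.0, abs=1e-9)
        assert dist.truncated_mass == 0.0


class TestClassifyDistribution:
    def test_concentrated_mass(self, grn_instance, small_ensemble):
        init = grn_instance.states.values[:, 0].astype(float)
        dist = ensemble_markov(small_ensemble, init, n_steps=10)
        masses = classify_distribution(dist, grn_instance.states)
        assert masses[grn_instance.states.states[0]] == pytest.approx(1.0)
        assert masses["other"] == pytest.approx(0.0)

    def test_masses_sum_to_one(self, small_ensemble, grn_instance):
        init = np.ones(grn_instance.states.n_modules)
        dist = ensemble_markov(small_ensemble, init, n_steps=30, prob_floor=0.0)
        masses = classify_distribution(dist, grn_instance.states)
        assert sum(masses.values()) == pytest.approx(1.0, abs=1e-9)

    def test_matches_dense_oracle_tally(self):
        rng = np.random.default_rng(11)
        n_mod, n_models = 6, 20
        J = rng.uniform(-1, 1, size=(n_models, n_mod, n_mod))
        named = BinaryStateMatrix(
            rng.integers(0, 2, size=(n_mod, 3)),
            [f"M{i}" for i in range(n_mod)],
            ["A", "B", "C"],
        )
        ens = CouplingEnsemble(J, ModelConfig(), named, np.zeros(n_models, dtype=int))
        init = named.values[:, 0].astype(float)
        dist = ensemble_markov(ens, init, n_steps=40, prob_floor=0.0)
        grid, p = dense_propagation(ens, init, {}, 40)
        masses = classify_distribution(dist, named)
        for k, label in enumerate(named.states):
            target = named.values[:, k].astype(float)
            idx = next(
                i for i, row in enumerate(grid) if np.array_equal(row, target)
            )
            assert masses[label] == pytest.approx(p[idx], abs=1e-9)
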