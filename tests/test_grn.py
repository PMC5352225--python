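import itertools

import numpy as np
import pytest

from statefate import grn
from statefate.errors import (
    FeasibilityError,
    PreconditionError,
    SamplingError,
    ValidationError,
)
from statefate.grn import (
    CouplingEnsemble,
    ModelConfig,
    ensemble_summary,
    fixed_point_constraints,
    mutual_sign_fraction,
    sample_couplings,
    verify_fixed_point,
)
from statefate.modules import BinaryStateMatrix


class TestConstraints:
    def test_paper_scale_bookkeeping(self):
        rng = np.random.default_rng(0)
        states = rng.integers(0, 2, size=(29, 9))
        system = fixed_point_constraints(states)
        assert system.n_inequalities == 29 * 9 == 261
        assert system.n_variables == 29 ** 2 == 841

    def test_single_module_zero_state(self):
        system = fixed_point_constraints(np.array([[0]]), ModelConfig(phi0=0.1))
        assert system.n_inequalities == 1
        # 0 <= phi0 - eps holds for any J
        assert (system.a_ub @ np.array([0.7]) <= system.b_ub).all()
        assert (system.a_ub @ np.array([-0.7]) <= system.b_ub).all()

    def test_non_binary_rejected(self):
        with pytest.raises(ValidationError):
            fixed_point_constraints(np.array([[0.5]]))

    def test_feasible_region_matches_grid_oracle(self):
        # N = 3, S = 2: constraints factor by row of J, so scan each row's
        # grid in [-1, 1]^3 at step 0.25 and compare with direct evaluation
        rng = np.random.default_rng(1)
        states = np.array([[1, 0], [0, 1], [1, 1]])
        cfg = ModelConfig(margin=1e-9)
        system = fixed_point_constraints(states, cfg)
        axis = np.arange(-1, 1.01, 0.25)
        n = 3
        for i in range(n):
            rows = [r for r, (a, m, s) in enumerate(system.row_meta) if m == i]
            for combo in itertools.product(axis, repeat=n):
                x = np.zeros(n * n)
                x[i * n:(i + 1) * n] = combo
                sys_ok = (system.a_ub[rows] @ x <= system.b_ub[rows]).all()
                direct_ok = True
                for a in range(states.shape[1]):
                    drive = sum(combo[j] * states[j, a] for j in range(n))
                    if states[i, a] == 1:
                        direct_ok &= drive >= cfg.phi0 + cfg.margin
                    else:
                        direct_ok &= drive <= cfg.phi0 - cfg.margin
                assert sys_ok == direct_ok


class TestSampling:
    def test_zero_state_always_feasible(self):
        states = np.zeros((4, 1), dtype=int)
        system = fixed_point_constraints(states)
        ens = sample_couplings(system, n_samples=25, seed=0)
        assert ens.n_samples == 25
        assert (ens.retry_counts == 0).all()

    def test_planted_instance_all_verified(self, grn_instance, small_ensemble):
        cfg = small_ensemble.config
        for J in small_ensemble.samples:
            for k in range(grn_instance.states.n_states):
                assert verify_fixed_point(J, grn_instance.states.values[:, k], cfg)
            assert np.abs(J).max() <= cfg.j_bound + 1e-9

    def test_all_inequalities_satisfied_post_hoc(self, grn_instance, small_ensemble):
        system = fixed_point_constraints(grn_instance.states, small_ensemble.config)
        for J in small_ensemble.samples:
            assert (system.a_ub @ J.reshape(-1) <= system.b_ub + 1e-7).all()

    def test_reproducible(self, grn_instance):
        system = fixed_point_constraints(grn_instance.states)
        a = sample_couplings(system, n_samples=5, seed=42)
        b = sample_couplings(system, n_samples=5, seed=42)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_infeasible_system_reports_subset(self):
        # a single on-module whose required drive exceeds the coupling bound
        states = np.array([[1]])
        system = fixed_point_constraints(states, ModelConfig(phi0=1.5))
        with pytest.raises(FeasibilityError, match="irreducible"):
            sample_couplings(system, n_samples=2, seed=0)

    def test_phi0_scan_preserves_forced_signs(self, grn_instance):
        # forced-sign couplings (via LP min/max over the polytope) keep
        # their sign across the critical-drive scan wherever feasible
        from scipy.optimize import linprog

        feasible_count = 0
        for phi0 in (-2.0, -1.0, 0.1, 1.0, 2.0):
            cfg = ModelConfig(phi0=phi0)
            system = fixed_point_constraints(grn_instance.states, cfg)
            probe = linprog(
                np.zeros(system.n_variables), A_ub=system.a_ub, b_ub=system.b_ub,
                bounds=(-1, 1), method="highs",
            )
            if probe.status != 0:
                continue
            feasible_count += 1
            ens = sample_couplings(system, n_samples=20, seed=3,
                                   states=grn_instance.states)
            for J in ens.samples:
                for k in range(grn_instance.states.n_states):
                    assert verify_fixed_point(J, grn_instance.states.values[:, k], cfg)
        assert feasible_count >= 1  # phi0 = 0.1 at minimum


class TestVerifyFixedPoint:
    def test_zero_state_with_positive_phi0(self):
        rng = np.random.default_rng(3)
        J = rng.uniform(-1, 1, (6, 6))
        assert verify_fixed_point(J, np.zeros(6), ModelConfig(phi0=0.1))

    def test_flipped_bit_generally_not_fixed(self, grn_instance):
        J = grn_instance.J_true
        cfg = ModelConfig(phi0=grn_instance.phi0)
        flips_broken = 0
        total = 0
        for k in range(grn_instance.states.n_states):
            state = grn_instance.states.values[:, k].astype(float)
            for i in range(len(state)):
                flipped = state.copy()
                flipped[i] = 1 - flipped[i]
                total += 1
                expected = bool(
                    np.array_equal(
                        (J @ flipped - cfg.phi0 >= 0).astype(float), flipped
                    )
                )
                assert verify_fixed_point(J, flipped, cfg) == expected
                flips_broken += not expected
        assert flips_broken > total // 2  # generic case: most flips break it

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            verify_fixed_point(np.zeros((2, 2)), np.zeros(3))


def _forced_signs_by_grid(states, cfg, step=0.25):
    """Grid oracle (rows independent): sign of each coupling over the
    feasible grid; returns dict (i, j) -> sign if all feasible grid points
    agree and are nonzero."""
    n = states.shape[0]
    axis = np.arange(-1, 1.0 + 1e-9, step)
    forced = {}
    for i in range(n):
        feas = []
        for combo in itertools.product(axis, repeat=n):
            ok = True
            for a in range(states.shape[1]):
                drive = float(np.dot(combo, states[:, a]))
                if states[i, a] == 1:
                    ok &= drive >= cfg.phi0 + cfg.margin
                else:
                    ok &= drive <= cfg.phi0 - cfg.margin
            if ok:
                feas.append(combo)
        feas = np.array(feas)
        if not len(feas):
            continue
        for j in range(n):
            col = feas[:, j]
            if (col > 0).all():
                forced[(i, j)] = 1
            elif (col < 0).all():
                forced[(i, j)] = -1
    return forced


class TestSummary:
    def test_identical_matrices_cv_zero(self):
        J = np.full((2, 2, 2), 0.5)
        states = BinaryStateMatrix(np.zeros((2, 0), dtype=int), ["a", "b"], [])
        ens = CouplingEnsemble(J, ModelConfig(), states, np.zeros(2, dtype=int))
        summary = ensemble_summary(ens)
        assert (summary["cv"] == 0).all()

    def test_sign_fractions_partition(self, small_ensemble):
        s = ensemble_summary(small_ensemble)
        total = s["frac_negative"] + s["frac_zero"] + s["frac_positive"]
        np.testing.assert_allclose(total, 1.0)

    def test_single_sample_rejected(self):
        states = BinaryStateMatrix(np.zeros((1, 0), dtype=int), ["a"], [])
        ens = CouplingEnsemble(
            np.zeros((1, 1, 1)), ModelConfig(), states, np.zeros(1, dtype=int)
        )
        with pytest.raises(PreconditionError):
            ensemble_summary(ens)

    def test_forced_signs_match_grid_oracle(self):
        # modules a and c are each alone in one state, so their self
        # couplings must exceed phi0: forced positive
        states = np.array([[1, 0], [0, 0], [0, 1]])
        cfg = ModelConfig()
        forced = _forced_signs_by_grid(states, cfg)
        bsm = BinaryStateMatrix(states, ["a", "b", "c"], ["s0", "s1"])
        system = fixed_point_constraints(bsm, cfg)
        ens = sample_couplings(system, n_samples=200, seed=5, states=bsm)
        summary = ensemble_summary(ens)
        assert forced, "oracle found no forced coupling; instance too loose"
        for (i, j), sign in forced.items():
            frac = (
                summary["frac_positive"][i, j]
                if sign > 0
                else summary["frac_negative"][i, j]
            )
            assert frac >= 0.99


class TestMutualSignFraction:
    @staticmethod
    def toy_ensemble():
        J = np.zeros((4, 2, 2))
        J[:, 0, 1] = [-0.5, -0.2, -0.1, -0.4]   # b drives a, all negative
        J[:, 1, 0] = [-0.3, 0.2, -0.6, 0.1]     # a drives b, half negative
        states = BinaryStateMatrix(np.zeros((2, 0), dtype=int), ["a", "b"], [])
        return CouplingEnsemble(J, ModelConfig(), states, np.zeros(4, dtype=int))

    def test_all_negative_directed(self):
        assert mutual_sign_fraction(self.toy_ensemble(), "b", "a", "a_to_b_negative") == 1.0

    def test_both_negative_bounded_by_directed(self):
        ens = self.toy_ensemble()
        both = mutual_sign_fraction(ens, "a", "b", "both_negative")
        assert both <= mutual_sign_fraction(ens, "a", "b", "a_to_b_negative")
        assert both <= mutual_sign_fraction(ens, "a", "b", "b_to_a_negative")
        assert both == 0.5

    def test_recount_against_stored_samples(self, small_ensemble):
        ids = small_ensemble.states.module_ids
        a, b = ids[0], ids[1]
        ia, ib = 0, 1
        frac = mutual_sign_fraction(small_ensemble, a, b, "both_negative")
        manual = np.mean(
            (small_ensemble.samples[:, ib, ia] < 0)
            & (small_ensemble.samples[:, ia, ib] < 0)
        )
        assert frac == pytest.approx(manual)

    def test_unknown_module(self, small_ensemble):
        with pytest.raises(KeyError):
            mutual_sign_fraction(small_ensemble, "nope", "M0")


class TestEnsembleIO:
    def test_hdf5_roundtrip(self, small_ensemble, tmp_path):
        grn.write_ensemble(small_ensemble, tmp_path / "e.h5")
        back = grn.read_ensemble(tmp_path / "e.h5")
        np.testing.assert_array_equal(back.samples, small_ensemble.samples)
        assert back.states.module_ids == small_ensemble.states.module_ids
        assert back.config.phi0 == small_ensemble.config.phi0

    def test_constraint_csv_export(self, grn_instance, tmp_path):
        system = fixed_point_constraints(grn_instance.states)
        grn.export_constraints_csv(system, tmp_path / "c.csv")
        import pandas as pd

        tab = pd.read_csv(tmp_path / "c.csv")
        assert set(tab.columns) == {"row", "col", "coef"}
        assert tab["row"].max() == system.n_inequalities - 1
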