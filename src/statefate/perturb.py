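"""Ensemble perturbation predictions.

Two prediction modes over a sampled coupling ensemble:

* :func:`overexpression_scan` -- clamp one module at level 1 + delta and,
  per model, iterate the synchronous threshold dynamics until the
  trajectory revisits a state; report the fraction of models in which a
  target module ends (and stays) off.
* :func:`ensemble_markov` -- the ensemble-averaged state-to-state Markov
  chain. The full transition matrix over 2^N states is never materialized;
  probability mass is propagated lazily over the visited support, which is
  exact on that support.

Clamped modules contribute their clamp level to the drives of the others
but are excluded from the update themselves.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from statefate.errors import PreconditionError, ResourceError, ValidationError
from statefate.grn import CouplingEnsemble, ModelConfig, verify_fixed_point
from statefate.modules import BinaryStateMatrix


@dataclasses.dataclass
class StateDistribution:
    """Sparse probability distribution over network states."""

    probs: dict  # tuple(float levels) -> probability
    step: int
    truncated_mass: float = 0.0

    def mass(self, state) -> float:
        return self.probs.get(tuple(np.asarray(state, dtype=float)), 0.0)

    def total(self) -> float:
        return float(sum(self.probs.values()))


def step_state(
    J: np.ndarray,
    state: np.ndarray,
    clamps: Mapping | None = None,
    config: ModelConfig | None = None,
) -> np.ndarray:
    """One synchronous Heaviside update with clamped modules held fixed."""
    config = config or ModelConfig()
    s = np.asarray(state, dtype=float).copy()
    clamps = dict(clamps or {})
    for idx, level in clamps.items():
        s[idx] = level
    drive = np.asarray(J, dtype=float) @ s
    new = (drive - config.phi0 >= 0).astype(float)
    for idx, level in clamps.items():
        new[idx] = level
    return new


def _resolve_clamps(clamps, states: BinaryStateMatrix | None):
    """Accept {module_name_or_index: level} or a list of names (level 1)."""
    if clamps is None:
        return {}
    if not isinstance(clamps, Mapping):
        clamps = {m: 1.0 for m in clamps}
    out = {}
    for key, level in clamps.items():
        if isinstance(key, str):
            if states is None:
                raise ValidationError("module names need a state matrix")
            out[states.module_index(key)] = float(level)
        else:
            out[int(key)] = float(level)
    return out


def _run_to_cycle(J, state, clamps, config, max_steps):
    """Iterate until a state repeats; returns the cycle's states."""
    seen = {}
    trajectory = []
    s = np.asarray(state, dtype=float)
    for t in range(max_steps + 1):
        key = s.tobytes()
        if key in seen:
            return trajectory[seen[key]:]
        seen[key] = t
        trajectory.append(s)
        s = step_state(J, s, clamps, config)
    return [trajectory[-1]]  # horizon hit; report the last state


def overexpression_scan(
    ensemble: CouplingEnsemble,
    initial_state: np.ndarray | str,
    module: str | int,
    target: str | int,
    delta_grid: Sequence[float] | None = None,
    max_steps: int = 200,
) -> pd.DataFrame:
    """Fraction of models in which ``target`` shuts off as ``module`` is
    overexpressed at level 1 + delta from a common fixed point.

    A model counts as "down" when the target is 0 in every state of the
    terminal cycle (fixed points are 1-cycles).
    """
    states = ensemble.states
    if isinstance(initial_state, str):
        init = states.state_vector(initial_state).astype(float)
    else:
        init = np.asarray(initial_state, dtype=float)
    midx = states.module_index(module) if isinstance(module, str) else int(module)
    tidx = states.module_index(target) if isinstance(target, str) else int(target)
    if init[midx] != 1:
        raise PreconditionError("overexpressed module must be expressed in the initial state")
    for J in ensemble.samples:
        if not verify_fixed_point(J, init, ensemble.config):
            raise PreconditionError("initial state is not a fixed point of every model")
    if delta_grid is None:
        delta_grid = np.round(np.arange(0.0, 2.0 + 1e-9, 0.1), 10)
    delta_grid = np.asarray(list(delta_grid), dtype=float)
    if np.any(np.diff(delta_grid) <= 0) or np.any(delta_grid < 0):
        raise ValidationError("delta grid must be nonnegative and increasing")

    rows = []
    for ds in delta_grid:
        clamps = {midx: 1.0 + ds}
        down = 0
        for J in ensemble.samples:
            cycle = _run_to_cycle(J, init, clamps, ensemble.config, max_steps)
            if all(st[tidx] == 0 for st in cycle):
                down += 1
        rows.append(
            {
                "delta_s": float(ds),
                "fraction_down": down / ensemble.n_samples,
                "n_models": ensemble.n_samples,
            }
        )
    return pd.DataFrame(rows)


def ensemble_markov(
    ensemble: CouplingEnsemble,
    initial_state: np.ndarray | str,
    clamps=None,
    n_steps: int = 1000,
    prob_floor: float = 1e-8,
    support_cap: int = 200000,
) -> StateDistribution:
    """Propagate state probabilities under the ensemble-averaged chain.

    Each model maps a state deterministically to its one-step image (with
    clamps applied); the ensemble assigns weight 1/n_samples to each model.
    Mass below ``prob_floor`` is truncated (tracked and renormalized).
    Transition rows are memoized, so cost scales with the number of
    distinct states visited rather than with 2^N.
    """
    states = ensemble.states
    if isinstance(initial_state, str):
        init = states.state_vector(initial_state).astype(float)
    else:
        init = np.asarray(initial_state, dtype=float)
    clamp_map = _resolve_clamps(clamps, states)
    clamp_idx = np.array(sorted(clamp_map), dtype=int)
    clamp_lvl = np.array([clamp_map[i] for i in clamp_idx], dtype=float)
    J_all = ensemble.samples  # (n, N, N)
    n = ensemble.n_samples
    phi0 = ensemble.config.phi0

    transition_cache: dict = {}

    def transitions(key: bytes, vec: np.ndarray):
        if key in transition_cache:
            return transition_cache[key]
        s = vec.copy()
        if clamp_idx.size:
            s[clamp_idx] = clamp_lvl
        drives = J_all @ s  # (n, N)
        images = (drives - phi0 >= 0).astype(float)
        if clamp_idx.size:
            images[:, clamp_idx] = clamp_lvl
        uniq, counts = np.unique(images, axis=0, return_counts=True)
        entries = [(u.tobytes(), u, c / n) for u, c in zip(uniq, counts)]
        transition_cache[key] = entries
        return entries

    init = init.astype(float)
    if clamp_idx.size:
        init[clamp_idx] = clamp_lvl
    dist = {init.tobytes(): (init, 1.0)}
    truncated = 0.0
    for _ in range(n_steps):
        new: dict = {}
        for key, (vec, p) in dist.items():
            for ikey, ivec, w in transitions(key, vec):
                if ikey in new:
                    new[ikey] = (ivec, new[ikey][1] + p * w)
                else:
                    new[ikey] = (ivec, p * w)
        pruned = {k: v for k, v in new.items() if v[1] >= prob_floor}
        truncated += sum(v[1] for k, v in new.items() if v[1] < prob_floor)
        if not pruned:
            raise ResourceError("all probability mass fell below the floor")
        if len(pruned) > support_cap:
            raise ResourceError(
                f"support exceeded {support_cap} states; raise prob_floor"
            )
        total = sum(v[1] for v in pruned.values())
        dist = {k: (v[0], v[1] / total) for k, v in pruned.items()}
    return StateDistribution(
        probs={tuple(v[0]): v[1] for v in dist.values()},
        step=n_steps,
        truncated_mass=truncated,
    )


def classify_distribution(
    dist: StateDistribution, states: BinaryStateMatrix
) -> dict:
    """Exact-match probability mass per named state; residual under 'other'."""
    named = {
        tuple(states.values[:, k].astype(float)): states.states[k]
        for k in range(states.n_states)
    }
    out = {label: 0.0 for label in states.states}
    other = 0.0
    for state, p in dist.probs.items():
        label = named.get(state)
        if label is None:
            other += p
        else:
            out[label] += p
    out["other"] = other
    return out


def distribution_to_frame(dist: StateDistribution) -> pd.DataFrame:
    rows = [
        {"state": "".join(str(int(v)) if v == int(v) else f"({v})" for v in state),
         "probability": p, "step": dist.step}
        for state, p in sorted(dist.probs.items(), key=lambda kv: -kv[1])
    ]
    return pd.DataFrame(rows)
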