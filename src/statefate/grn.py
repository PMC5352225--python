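"""Fixed-point inequality systems and LP sampling of coupling ensembles.

Every observed binary state ``m^a`` must be a fixed point of the synchronous
threshold update: for each module i, the drive ``sum_j J_ij m_j^a`` must be
at least ``phi0`` when ``m_i^a = 1`` and below ``phi0`` when ``m_i^a = 0``.
With N modules and S states that is N*S linear inequalities over the N^2
couplings. The ensemble is drawn by repeatedly (i) picking random binary
objective coefficients a_ij, (ii) slicing the polytope with the fictitious
cut ``sum a_ij J_ij <= 0`` through the origin, and (iii) maximizing
``sum a_ij J_ij`` -- so each solve lands on an interior plane of the
original polytope; draws whose cut misses the polytope are redrawn.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse
from scipy.optimize import linprog

from statefate.errors import (
    FeasibilityError,
    PreconditionError,
    SamplingError,
    ValidationError,
)
from statefate.modules import BinaryStateMatrix


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Threshold-network model settings (hard-threshold limit)."""

    phi0: float = 0.1
    j_bound: float = 1.0
    margin: float = 1e-6
    tau: float = 1.0
    r0: float = 0.0

    def __post_init__(self):
        if self.j_bound <= 0:
            raise ValidationError("j_bound must be positive")
        if self.margin <= 0:
            raise ValidationError("margin must be positive")
        if not np.isfinite(self.phi0):
            raise ValidationError("phi0 must be finite")


@dataclasses.dataclass
class ConstraintSystem:
    """A_ub x <= b_ub over the flattened couplings x = vec(J), row-major."""

    a_ub: scipy.sparse.csr_matrix
    b_ub: np.ndarray
    n_modules: int
    n_states: int
    config: ModelConfig
    row_meta: list  # (state_index, module_index, sense) per inequality

    @property
    def n_inequalities(self) -> int:
        return self.a_ub.shape[0]

    @property
    def n_variables(self) -> int:
        return self.a_ub.shape[1]


@dataclasses.dataclass
class CouplingEnsemble:
    samples: np.ndarray  # (n_samples, N, N)
    config: ModelConfig
    states: BinaryStateMatrix
    retry_counts: np.ndarray
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def module_index(self, module_id: str) -> int:
        return self.states.module_index(module_id)


def fixed_point_constraints(
    states: BinaryStateMatrix | np.ndarray,
    config: ModelConfig | None = None,
) -> ConstraintSystem:
    """Build the N*S fixed-point inequalities over the N^2 couplings.

    Strict inequalities become closed ones with the config margin (LPs
    cannot express strictness).
    """
    config = config or ModelConfig()
    values = states.values if isinstance(states, BinaryStateMatrix) else np.asarray(states)
    if not np.isin(values, (0, 1)).all():
        raise ValidationError("state matrix entries must be 0/1")
    n, s = values.shape
    if isinstance(states, BinaryStateMatrix):
        dup = len({values[:, a].tobytes() for a in range(s)}) < s
        if dup:
            warnings.warn("duplicate state columns: redundant constraints", stacklevel=2)
    rows, cols, data, b, meta = [], [], [], [], []
    r = 0
    for a in range(s):
        m = values[:, a].astype(float)
        for i in range(n):
            nz = np.flatnonzero(m)
            sign = -1.0 if values[i, a] == 1 else 1.0
            for j in nz:
                rows.append(r)
                cols.append(i * n + j)
                data.append(sign)
            if values[i, a] == 1:
                # sum_j J_ij m_j >= phi0 + margin  ->  -sum <= -(phi0+margin)
                b.append(-(config.phi0 + config.margin))
                meta.append((a, i, "on"))
            else:
                b.append(config.phi0 - config.margin)
                meta.append((a, i, "off"))
            r += 1
    a_ub = scipy.sparse.csr_matrix(
        (data, (rows, cols)), shape=(n * s, n * n), dtype=float
    )
    return ConstraintSystem(
        a_ub=a_ub,
        b_ub=np.array(b),
        n_modules=n,
        n_states=s,
        config=config,
        row_meta=meta,
    )


def _solve(system: ConstraintSystem, c: np.ndarray | None, extra_row=None, extra_b=0.0):
    a_ub, b_ub = system.a_ub, system.b_ub
    if extra_row is not None:
        a_ub = scipy.sparse.vstack([a_ub, scipy.sparse.csr_matrix(extra_row[None, :])])
        b_ub = np.append(b_ub, extra_b)
    bound = system.config.j_bound
    return linprog(
        c if c is not None else np.zeros(system.n_variables),
        A_ub=a_ub,
        b_ub=b_ub,
        bounds=(-bound, bound),
        method="highs",
    )


def _irreducible_infeasible_rows(system: ConstraintSystem) -> list:
    """Deletion filter: drop rows whose removal keeps the system infeasible."""
    keep = list(range(system.n_inequalities))
    bound = system.config.j_bound

    def feasible(rows):
        res = linprog(
            np.zeros(system.n_variables),
            A_ub=system.a_ub[rows],
            b_ub=system.b_ub[rows],
            bounds=(-bound, bound),
            method="highs",
        )
        return res.status == 0
    for r in list(keep):
        trial = [x for x in keep if x != r]
        if trial and not feasible(trial):
            keep = trial
    return keep


def sample_couplings(
    system: ConstraintSystem,
    n_samples: int = 10000,
    seed: int = 0,
    max_retries: int = 50,
    states: BinaryStateMatrix | None = None,
) -> CouplingEnsemble:
    """Random-hyperplane LP sampling of the solution polytope.

    Per sample: a_ij ~ iid Bernoulli(0.5); maximize sum a_ij J_ij subject to
    the fixed-point system, the cut sum a_ij J_ij <= 0 and |J_ij| <= bound.
    Cuts that miss the polytope are redrawn up to ``max_retries`` times, so
    the returned ensemble always holds ``n_samples`` members.
    """
    base = _solve(system, None)
    if base.status != 0:
        rows = _irreducible_infeasible_rows(system)
        detail = [system.row_meta[r] for r in rows[:20]]
        raise FeasibilityError(
            f"fixed-point system infeasible; irreducible subset "
            f"(state, module, sense): {detail}"
        )
    rng = np.random.default_rng(seed)
    nv = system.n_variables
    n = system.n_modules
    samples = np.empty((n_samples, n, n))
    retries = np.zeros(n_samples, dtype=int)
    for s in range(n_samples):
        for attempt in range(max_retries + 1):
            a = rng.integers(0, 2, size=nv).astype(float)
            res = _solve(system, -a, extra_row=a, extra_b=0.0)
            if res.status == 0:
                samples[s] = res.x.reshape(n, n)
                retries[s] = attempt
                break
        else:
            raise SamplingError(
                f"sample {s}: no feasible cut in {max_retries} retries"
            )
    if states is None:
        states = BinaryStateMatrix(
            values=np.zeros((n, 0), dtype=int),
            module_ids=[f"M{i}" for i in range(n)],
            states=[],
        )
    return CouplingEnsemble(
        samples=samples, config=system.config, states=states,
        retry_counts=retries, seed=seed,
    )


def verify_fixed_point(
    J: np.ndarray, state: np.ndarray, config: ModelConfig | None = None
) -> bool:
    """True iff one synchronous Heaviside update leaves the state unchanged."""
    config = config or ModelConfig()
    state = np.asarray(state, dtype=float)
    J = np.asarray(J, dtype=float)
    if J.shape[0] != J.shape[1] or J.shape[0] != state.size:
        raise ValidationError("dimension mismatch")
    updated = (J @ state - config.phi0 >= 0).astype(float)
    return bool(np.array_equal(updated, state))


def ensemble_summary(ensemble: CouplingEnsemble) -> dict:
    """Elementwise mean, coefficient of variation and sign fractions.

    cv is NaN (missing) where the mean is zero. Sign fractions use the
    config margin as the zero band and sum to 1 per entry.
    """
    if ensemble.n_samples < 2:
        raise PreconditionError("ensemble summary needs at least 2 samples")
    J = ensemble.samples
    mean = J.mean(axis=0)
    sd = J.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / np.abs(mean), np.nan)
    eps = ensemble.config.margin
    return {
        "mean": mean,
        "cv": cv,
        "frac_negative": (J < -eps).mean(axis=0),
        "frac_zero": (np.abs(J) <= eps).mean(axis=0),
        "frac_positive": (J > eps).mean(axis=0),
    }


_SENSES = (
    "both_negative",
    "both_positive",
    "a_to_b_negative",
    "a_to_b_positive",
    "b_to_a_negative",
    "b_to_a_positive",
)


def mutual_sign_fraction(
    ensemble: CouplingEnsemble,
    module_a: str,
    module_b: str,
    sense: str = "both_negative",
) -> float:
    """Fraction of samples meeting a sign predicate on the (a, b) couplings.

    The coupling "a_to_b" is the drive module a exerts on module b, i.e.
    ``J[b, a]``.
    """
    if sense not in _SENSES:
        raise ValidationError(f"unknown sense {sense!r}; one of {_SENSES}")
    ia = ensemble.module_index(module_a)
    ib = ensemble.module_index(module_b)
    a_to_b = ensemble.samples[:, ib, ia]
    b_to_a = ensemble.samples[:, ia, ib]
    if sense == "both_negative":
        hit = (a_to_b < 0) & (b_to_a < 0)
    elif sense == "both_positive":
        hit = (a_to_b > 0) & (b_to_a > 0)
    elif sense == "a_to_b_negative":
        hit = a_to_b < 0
    elif sense == "a_to_b_positive":
        hit = a_to_b > 0
    elif sense == "b_to_a_negative":
        hit = b_to_a < 0
    else:
        hit = b_to_a > 0
    return float(hit.mean())


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_ensemble(ensemble: CouplingEnsemble, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("samples", data=ensemble.samples)
        fh.create_dataset("retry_counts", data=ensemble.retry_counts)
        fh.create_dataset("states", data=ensemble.states.values)
        fh.create_dataset(
            "module_ids", data=np.array(ensemble.states.module_ids, dtype="S")
        )
        fh.create_dataset(
            "state_ids", data=np.array(ensemble.states.states, dtype="S")
        )
        for key in ("phi0", "j_bound", "margin"):
            fh.attrs[key] = getattr(ensemble.config, key)
        fh.attrs["seed"] = ensemble.seed


def read_ensemble(path: str | Path) -> CouplingEnsemble:
    import h5py

    with h5py.File(path, "r") as fh:
        config = ModelConfig(
            phi0=float(fh.attrs["phi0"]),
            j_bound=float(fh.attrs["j_bound"]),
            margin=float(fh.attrs["margin"]),
        )
        states = BinaryStateMatrix(
            values=fh["states"][...],
            module_ids=[s.decode() for s in fh["module_ids"][...]],
            states=[s.decode() for s in fh["state_ids"][...]],
        )
        return CouplingEnsemble(
            samples=fh["samples"][...],
            config=config,
            states=states,
            retry_counts=fh["retry_counts"][...],
            seed=int(fh.attrs["seed"]),
        )


def export_constraints_csv(system: ConstraintSystem, path: str | Path) -> None:
    """Sparse triplet export (row, variable, coefficient) plus bounds."""
    import pandas as pd

    coo = system.a_ub.tocoo()
    pd.DataFrame(
        {"row": coo.row, "col": coo.col, "coef": coo.data}
    ).to_csv(path, index=False)
    Path(str(path) + ".rhs").write_text(
        "\n".join(str(v) for v in system.b_ub) + "\n"
    )
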