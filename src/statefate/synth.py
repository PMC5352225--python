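"""Planted synthetic datasets for every pipeline stage.

Two generators:

* :func:`generate_lineage_dataset` -- UMI count matrices for cells spread
  over a planted bifurcating state tree, with planted marker and transition
  genes, heterogeneous library sizes and gamma-Poisson (negative binomial)
  count noise.
* :func:`generate_grn_instance` -- a random coupling matrix together with
  the complete set of its nonzero threshold-network fixed points, giving a
  feasible ground truth for the LP sampler.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import networkx as nx
import numpy as np

from statefate.errors import ResourceError, ValidationError
from statefate.io_prep import ExpressionMatrix
from statefate.modules import BinaryStateMatrix

# state tree used by the default configuration: a root, a first split,
# and a second split on each branch of the ectoderm/mesendoderm arms
DEFAULT_TREE_EDGES = [
    ("S0", "S1"),
    ("S1", "S2"),
    ("S1", "S3"),
    ("S2", "S4"),
    ("S4", "S7"),
    ("S4", "S8"),
    ("S3", "S5"),
    ("S3", "S6"),
]


@dataclasses.dataclass
class PlantedLineage:
    """Ground-truth plan for a synthetic lineage dataset.

    ``means`` holds the planted per-gene, per-state mean log2 expression.
    ``gene_classes`` records, per gene, one of ``("marker", state)``,
    ``("transition", (intermediate, retained, low_state))`` or
    ``("background", None)``.
    """

    tree: nx.Graph
    states: list
    gene_ids: list
    means: np.ndarray  # (n_genes, n_states) log2 scale
    gene_classes: list
    n_cells_per_state: np.ndarray
    dispersion: float = 10.0
    depth_range: tuple = (20000, 40000)

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.n_cells_per_state = np.asarray(self.n_cells_per_state, dtype=int)
        if self.means.shape != (len(self.gene_ids), len(self.states)):
            raise ValidationError("means shape must be (n_genes, n_states)")
        if len(self.n_cells_per_state) != len(self.states):
            raise ValidationError("n_cells_per_state must match states")
        if np.any(self.n_cells_per_state <= 0):
            raise ValidationError("every state needs at least one cell")
        if self.depth_range[0] < 20000:
            raise ValidationError("depth_range minimum must be >= 20000")
        if self.depth_range[0] > self.depth_range[1]:
            raise ValidationError("invalid depth_range")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive (np.inf = Poisson)")
        state_idx = {s: k for k, s in enumerate(self.states)}
        for g, (kind, info) in enumerate(self.gene_classes):
            if kind == "marker":
                k = state_idx[info]
                rest = np.delete(self.means[g], k)
                if not np.all(self.means[g, k] > rest):
                    raise ValidationError(
                        f"marker gene {self.gene_ids[g]} not strictly highest in {info}"
                    )
            elif kind == "transition":
                trip = [state_idx[s] for s in info]
                low = trip[2]
                others = trip[:2]
                if not np.all(self.means[g, low] < self.means[g, others]):
                    raise ValidationError(
                        f"transition gene {self.gene_ids[g]} not lowest in {info[2]}"
                    )


def direct_tree_triplets(tree: nx.Graph) -> list:
    """All (intermediate, end_a, end_b) triplets whose pairwise paths stay
    inside the triplet -- i.e. pairs of neighbors of each internal node."""
    out = []
    for m in tree.nodes:
        for a, b in itertools.combinations(sorted(tree.neighbors(m)), 2):
            out.append((m, a, b))
    return out


def default_lineage_config(
    n_states: int = 9,
    n_cells_per_state: int = 32,
    n_marker_per_state: int = 8,
    n_transition_per_branch: int = 4,
    n_background: int = 60,
    high: float = 5.0,
    low: float = 0.0,
    background_level: float = 2.0,
    dispersion: float = 10.0,
    depth_range: tuple = (20000, 40000),
    tree_edges: Sequence[tuple] | None = None,
) -> PlantedLineage:
    """Paper-scale default: 9 states on a bifurcating tree, ~288 cells."""
    if tree_edges is None:
        tree_edges = DEFAULT_TREE_EDGES
    tree = nx.Graph(tree_edges)
    states = sorted(tree.nodes)
    if len(states) != n_states:
        raise ValidationError("tree does not match n_states")
    sidx = {s: k for k, s in enumerate(states)}

    gene_ids, classes, rows = [], [], []
    for s in states:
        for r in range(n_marker_per_state):
            mu = np.full(len(states), low)
            mu[sidx[s]] = high
            gene_ids.append(f"MK_{s}_{r}")
            classes.append(("marker", s))
            rows.append(mu)
    for (m, a, b) in direct_tree_triplets(tree):
        for lo, keep in ((b, a), (a, b)):
            for r in range(n_transition_per_branch):
                mu = np.full(len(states), low)
                mu[sidx[m]] = high
                mu[sidx[keep]] = high
                gene_ids.append(f"TR_{m}_{keep}_not_{lo}_{r}")
                classes.append(("transition", (m, keep, lo)))
                rows.append(mu)
    # equalize the number of planted-high genes per state with filler
    # markers: counts are compositional (every cell is sampled to a fixed
    # depth), so unequal per-state planted totals would leak genuine
    # "lowest in the busiest state" signal into the background genes
    high_count = (np.array(rows) == high).sum(axis=0)
    for k, s in enumerate(states):
        for r in range(int(high_count.max() - high_count[k])):
            mu = np.full(len(states), low)
            mu[k] = high
            gene_ids.append(f"MK_{s}_fill{r}")
            classes.append(("marker", s))
            rows.append(mu)
    for r in range(n_background):
        gene_ids.append(f"BG_{r}")
        classes.append(("background", None))
        rows.append(np.full(len(states), background_level))

    return PlantedLineage(
        tree=tree,
        states=states,
        gene_ids=gene_ids,
        means=np.array(rows),
        gene_classes=classes,
        n_cells_per_state=np.full(len(states), n_cells_per_state),
        dispersion=dispersion,
        depth_range=depth_range,
    )


def generate_lineage_dataset(config: PlantedLineage, seed: int = 0):
    """Draw a UMI count matrix from a planted lineage plan.

    Per cell, gene rates are 2**mean - 1 perturbed by gamma noise with shape
    ``dispersion`` (gamma-Poisson = negative binomial marginals; dispersion
    = inf is the noise-free Poisson limit), and counts are a multinomial
    draw of a library size sampled uniformly from ``depth_range`` -- so
    every cell total lands inside the planted depth interval exactly.

    Returns ``(ExpressionMatrix, labels)`` with ``labels`` the per-cell
    ground-truth state array.
    """
    rng = np.random.default_rng(seed)
    lam = np.maximum(2.0 ** config.means - 1.0, 0.0)  # (G, S)
    counts, labels, cell_ids = [], [], []
    for k, state in enumerate(config.states):
        n_cells = config.n_cells_per_state[k]
        base = lam[:, k]
        for c in range(n_cells):
            if np.isinf(config.dispersion):
                rate = base
            else:
                d = config.dispersion
                rate = np.where(
                    base > 0, rng.gamma(d, 1.0 / d, size=base.size) * base, 0.0
                )
            total = int(rng.integers(config.depth_range[0], config.depth_range[1] + 1))
            p = rate / rate.sum()
            counts.append(rng.multinomial(total, p))
            labels.append(state)
            cell_ids.append(f"{state}_cell{c}")
    mat = ExpressionMatrix(
        np.array(counts, dtype=np.int64), cell_ids, list(config.gene_ids), layer="raw"
    )
    return mat, np.array(labels)


# ---------------------------------------------------------------------------
# planted threshold networks
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PlantedGRN:
    """Random coupling matrix plus the complete set of its fixed points."""

    J_true: np.ndarray
    phi0: float
    states: BinaryStateMatrix


def _heaviside_update(J: np.ndarray, states: np.ndarray, phi0: float) -> np.ndarray:
    """Synchronous threshold update applied to rows of ``states``."""
    return (states @ J.T - phi0 >= 0).astype(np.int8)


def find_fixed_points(
    J: np.ndarray,
    phi0: float,
    exhaustive_limit: int = 16,
    n_starts: int = 2000,
    max_steps: int = 200,
    seed: int = 0,
    include_zero: bool = False,
) -> np.ndarray:
    """All (or all discoverable) fixed points of the threshold network.

    Exhaustive enumeration for N <= ``exhaustive_limit``; otherwise
    synchronous iteration from ``n_starts`` random binary states.
    """
    n = J.shape[0]
    if n <= exhaustive_limit:
        grid = ((np.arange(2 ** n)[:, None] >> np.arange(n)[None, :]) & 1).astype(np.int8)
        fixed = grid[np.all(_heaviside_update(J, grid, phi0) == grid, axis=1)]
    else:
        rng = np.random.default_rng(seed)
        starts = rng.integers(0, 2, size=(n_starts, n)).astype(np.int8)
        found = set()
        for s in starts:
            state = s
            seen = set()
            for _ in range(max_steps):
                key = state.tobytes()
                if key in seen:
                    break
                seen.add(key)
                nxt = _heaviside_update(J, state[None, :], phi0)[0]
                if np.array_equal(nxt, state):
                    found.add(key)
                    break
                state = nxt
        fixed = (
            np.array([np.frombuffer(k, dtype=np.int8) for k in sorted(found)])
            if found
            else np.zeros((0, n), dtype=np.int8)
        )
    if not include_zero and fixed.size:
        fixed = fixed[fixed.sum(axis=1) > 0]
    return fixed


def generate_grn_instance(
    n_modules: int,
    phi0: float = 0.1,
    target_n_states: int = 3,
    seed: int = 0,
    j_bound: float = 1.0,
    max_retries: int = 500,
    include_zero: bool = False,
) -> PlantedGRN:
    """Sample random couplings until the network has enough nonzero fixed points."""
    if n_modules > 20:
        raise ValidationError("n_modules must be <= 20")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        J = rng.uniform(-j_bound, j_bound, size=(n_modules, n_modules))
        fixed = find_fixed_points(J, phi0, include_zero=include_zero, seed=seed)
        if len(fixed) >= target_n_states:
            states = BinaryStateMatrix(
                values=fixed.T.astype(int),
                module_ids=[f"M{i}" for i in range(n_modules)],
                states=[f"S{a}" for a in range(fixed.shape[0])],
            )
            return PlantedGRN(J_true=J, phi0=phi0, states=states)
    raise ResourceError(
        f"no coupling matrix with >= {target_n_states} fixed points "
        f"found in {max_retries} draws"
    )


def write_grn_instance(grn: PlantedGRN, path) -> None:
    """Store a planted network as an HDF5 group (J_true, phi0, states)."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("J_true", data=grn.J_true)
        fh.attrs["phi0"] = grn.phi0
        fh.create_dataset("states", data=grn.states.values)
        fh.create_dataset(
            "module_ids", data=np.array(grn.states.module_ids, dtype="S")
        )
        fh.create_dataset("state_ids", data=np.array(grn.states.states, dtype="S"))


def read_grn_instance(path) -> PlantedGRN:
    import h5py

    with h5py.File(path, "r") as fh:
        states = BinaryStateMatrix(
            values=fh["states"][...],
            module_ids=[s.decode() for s in fh["module_ids"][...]],
            states=[s.decode() for s in fh["state_ids"][...]],
        )
        return PlantedGRN(
            J_true=fh["J_true"][...], phi0=float(fh.attrs["phi0"]), states=states
        )
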