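"""Binarization of gene expression across states into gene modules.

A gene's binary profile over the final states is fixed first by its *local*
high/low calls from direct triplets (marker: high in one cluster, low in
the other two; transition: low in one cluster, high in the intermediate
and retained clusters). Local calls are combined through a dominance
relation so that genes with three expression levels map medium and high
to 1. States without a local call are filled by a threshold rule: a state
is 1 when its mean expression is comparable (within the tolerance,
default ~10%) to, or higher than, the lowest mean among the locally-high
states. Genes sharing a binary pattern form one module; signaling-pathway
modules are appended as named rows binarized from the pathway's mean
profile with the same threshold rule.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from statefate.errors import ConflictError, EmptyResultError, ValidationError


@dataclasses.dataclass
class BinaryStateMatrix:
    """Modules x states binary profiles.

    ``module_ids`` are representative gene names; ``member_genes`` lists the
    genes grouped into each module (defaults to the representative itself).
    ``aliases`` records appended rows that duplicate an existing pattern.
    """

    values: np.ndarray
    module_ids: list
    states: list
    member_genes: list | None = None
    aliases: list = dataclasses.field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("binary state matrix must be 2-D")
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("state matrix entries must be 0/1")
        self.values = self.values.astype(np.int8)
        if self.values.shape != (len(self.module_ids), len(self.states)):
            raise ValidationError("shape does not match module/state labels")
        if self.member_genes is None:
            self.member_genes = [[m] for m in self.module_ids]

    @property
    def n_modules(self) -> int:
        return self.values.shape[0]

    @property
    def n_states(self) -> int:
        return self.values.shape[1]

    def module_index(self, module_id: str) -> int:
        try:
            return self.module_ids.index(module_id)
        except ValueError:
            raise KeyError(f"unknown module {module_id!r}") from None

    def state_vector(self, state: str) -> np.ndarray:
        try:
            k = self.states.index(state)
        except ValueError:
            raise KeyError(f"unknown state {state!r}") from None
        return self.values[:, k].copy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.module_ids, columns=self.states)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BinaryStateMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(
            values=frame.to_numpy(),
            module_ids=[str(i) for i in frame.index],
            states=[str(c) for c in frame.columns],
        )


def collapse_aliases(matrix: BinaryStateMatrix):
    """Collapse duplicate module rows to one modeling variable.

    Returns ``(collapsed, groups)`` where ``groups`` maps each kept module
    id to the list of module ids sharing its pattern (itself first).
    Duplicate rows would make their couplings unidentifiable in the network
    model.
    """
    seen: dict = {}
    keep_idx, groups = [], {}
    for i, mid in enumerate(matrix.module_ids):
        key = matrix.values[i].tobytes()
        if key in seen:
            groups[seen[key]].append(mid)
        else:
            seen[key] = mid
            keep_idx.append(i)
            groups[mid] = [mid]
    collapsed = BinaryStateMatrix(
        values=matrix.values[keep_idx],
        module_ids=[matrix.module_ids[i] for i in keep_idx],
        states=list(matrix.states),
        member_genes=[matrix.member_genes[i] for i in keep_idx],
    )
    return collapsed, groups


# ---------------------------------------------------------------------------
# direct triplets along the tree
# ---------------------------------------------------------------------------

def is_direct_triplet(cluster_ids: Sequence, tree: nx.Graph) -> bool:
    """True when every pairwise tree path stays inside the triplet."""
    trip = set(cluster_ids)
    for a, b in itertools.combinations(cluster_ids, 2):
        path = nx.shortest_path(tree, a, b)
        if any(node not in trip for node in path):
            return False
    return True


def direct_triplet_genes(
    triplet_results: Sequence,
    tree: nx.Graph,
    gene_cutoff: float = 0.5,
) -> set:
    """Genes that are high-probability marker/transition genes in at least
    one triplet lying directly along the tree (no skipped state)."""
    from statefate.triplet import classify_genes

    genes: set = set()
    for result in triplet_results:
        if not is_direct_triplet(result.triplet.cluster_ids, tree):
            continue
        for gid, (kind, _) in classify_genes(result, gene_cutoff).items():
            if kind != "none":
                genes.add(gid)
    return genes


def local_calls_for_gene(
    triplet_results: Sequence,
    tree: nx.Graph,
    gene_cutoff: float = 0.5,
) -> dict:
    """Per-gene local high/low calls from direct triplets.

    Returns ``{gene_id: [(kind, cluster_ids, cluster), ...]}`` where kind is
    'marker' (high in ``cluster``) or 'transition' (low in ``cluster``).
    """
    from statefate.triplet import classify_genes

    calls: dict = {}
    for result in triplet_results:
        if not is_direct_triplet(result.triplet.cluster_ids, tree):
            continue
        for gid, (kind, cluster) in classify_genes(result, gene_cutoff).items():
            if kind == "none":
                continue
            calls.setdefault(gid, []).append(
                (kind, tuple(result.triplet.cluster_ids), cluster)
            )
    return calls


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

def binarize_gene(
    local_calls: Sequence,
    state_means: Mapping,
    states: Sequence,
    tolerance: float = 0.10,
    gene_id: str = "",
) -> np.ndarray:
    """Binary profile over ``states`` from local calls plus the threshold rule.

    Local calls induce dominance relations between states: a marker call in
    triplet (k, a, b) says k is above a and b; a transition call low-in-k
    says the other two are above k. States dominating at least one other
    state (high or medium level) map to 1; states only ever dominated map
    to 0. Contradictory calls (a dominance cycle) raise ConflictError.
    Remaining states get 1 when their mean is >= (1 - tolerance) times the
    lowest mean among locally-1 states (inclusive boundary).
    """
    if not local_calls:
        raise ValidationError(f"gene {gene_id!r} has no local call")
    above: dict = {}
    for kind, cluster_ids, cluster in local_calls:
        others = [c for c in cluster_ids if c != cluster]
        if kind == "marker":
            for o in others:
                above.setdefault(cluster, set()).add(o)
        elif kind == "transition":
            for o in others:
                above.setdefault(o, set()).add(cluster)
        else:
            raise ValidationError(f"unknown call kind {kind!r}")

    dg = nx.DiGraph()
    for s, lows in above.items():
        for t in lows:
            dg.add_edge(s, t)
    for comp in nx.strongly_connected_components(dg):
        if len(comp) > 1:
            raise ConflictError(
                f"gene {gene_id!r}: conflicting local calls among states {sorted(comp)} "
                f"(triplets: {[c[1] for c in local_calls]})"
            )

    called = set(dg.nodes)
    values = {}
    for s in called:
        # dominated-only states are the local lows; anything that sits above
        # some other state (top or medium level) is expressed
        values[s] = 1 if dg.out_degree(s) > 0 else 0

    high_means = [state_means[s] for s, v in values.items() if v == 1]
    if not high_means:
        raise ConflictError(f"gene {gene_id!r}: local calls leave no expressed state")
    reference = min(high_means) * (1.0 - tolerance)
    out = np.zeros(len(states), dtype=np.int8)
    for k, s in enumerate(states):
        if s in values:
            out[k] = values[s]
        else:
            out[k] = 1 if state_means[s] >= reference else 0
    return out


def state_mean_profiles(values: np.ndarray, labels: Sequence, states: Sequence) -> np.ndarray:
    """Per-gene mean expression per state; values is cells x genes."""
    labels = np.asarray(labels)
    return np.stack(
        [values[labels == s].mean(axis=0) for s in states], axis=1
    )  # (genes, states)


def binarize_genes(
    calls: Mapping,
    mean_profiles: pd.DataFrame,
    states: Sequence,
    tolerance: float = 0.10,
) -> dict:
    """Binary profiles for every gene with local calls.

    ``mean_profiles`` is a genes x states frame of mean log expression.
    """
    out = {}
    for gid, gene_calls in calls.items():
        means = mean_profiles.loc[gid]
        out[gid] = binarize_gene(
            gene_calls, means.to_dict(), states, tolerance=tolerance, gene_id=gid
        )
    return out


def group_modules(binary_vectors: Mapping, states: Sequence) -> BinaryStateMatrix:
    """One module per distinct binary pattern; representative is the
    lexicographically first member gene. All-zero patterns are dropped."""
    if not binary_vectors:
        raise EmptyResultError("no binary gene profiles to group")
    patterns: dict = {}
    for gid in sorted(binary_vectors):
        vec = np.asarray(binary_vectors[gid], dtype=np.int8)
        if vec.sum() == 0:
            warnings.warn(f"gene {gid} expressed nowhere; dropped", stacklevel=2)
            continue
        patterns.setdefault(vec.tobytes(), []).append(gid)
    if not patterns:
        raise EmptyResultError("all gene profiles were zero")
    module_ids, rows, members = [], [], []
    for key, genes in sorted(patterns.items(), key=lambda kv: kv[1][0]):
        module_ids.append(genes[0])
        rows.append(np.frombuffer(key, dtype=np.int8))
        members.append(genes)
    return BinaryStateMatrix(
        values=np.array(rows),
        module_ids=module_ids,
        states=list(states),
        member_genes=members,
    )


def binarize_mean_profile(profile: np.ndarray, tolerance: float = 0.10) -> np.ndarray:
    """Threshold rule anchored at the maximum of a mean state profile."""
    profile = np.asarray(profile, dtype=float)
    reference = profile.max() * (1.0 - tolerance)
    return (profile >= reference).astype(np.int8)


def signaling_modules(
    matrix: BinaryStateMatrix,
    mean_profiles: pd.DataFrame,
    pathways: Mapping,
    tolerance: float = 0.10,
) -> BinaryStateMatrix:
    """Append one named row per signaling pathway.

    Each pathway's member genes are averaged into one state profile which is
    binarized with the same threshold rule. Rows are appended even when the
    pattern duplicates an existing module; such pairs are recorded in
    ``aliases``.
    """
    rows = [matrix.values]
    module_ids = list(matrix.module_ids)
    members = [list(m) for m in matrix.member_genes]
    aliases = list(matrix.aliases)
    existing = {matrix.values[i].tobytes(): matrix.module_ids[i] for i in range(matrix.n_modules)}
    for name in sorted(pathways):
        genes = [g for g in pathways[name] if g in mean_profiles.index]
        if not genes:
            warnings.warn(f"pathway {name}: no detected genes; row omitted", stacklevel=2)
            continue
        profile = mean_profiles.loc[genes].mean(axis=0).to_numpy()
        vec = binarize_mean_profile(profile, tolerance)
        key = vec.tobytes()
        if key in existing:
            aliases.append((name, existing[key]))
        else:
            existing[key] = name
        rows.append(vec[None, :])
        module_ids.append(name)
        members.append(list(genes))
    return BinaryStateMatrix(
        values=np.vstack(rows),
        module_ids=module_ids,
        states=list(matrix.states),
        member_genes=members,
        aliases=aliases,
    )


def write_members(matrix: BinaryStateMatrix, path: str | Path) -> None:
    rows = [
        {"module_id": mid, "gene_id": g}
        for mid, genes in zip(matrix.module_ids, matrix.member_genes)
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
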