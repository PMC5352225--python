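"""End-to-end orchestration: prep -> lineage -> modules -> grn -> perturb.

Each stage writes its artifacts under the output directory together with a
manifest (seeds, parameters, config hash) so that reruns with the same
config are bit-identical. A user-supplied module x state CSV (same shape as
the modules stage's output) can replace the data-analysis half, in which
case only the network stages run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from statefate import grn, io_prep, lineage, modules, perturb, synth
from statefate.errors import ValidationError


@dataclasses.dataclass
class PipelineConfig:
    """All stage parameters with the published defaults."""

    out_dir: str = "statefate_out"
    counts_path: str | None = None     # None -> synthetic default dataset
    annot_path: str | None = None
    states_csv: str | None = None      # drop-in module x state matrix
    depth: int = 20000
    gene_cutoff: float = 0.5
    triplet_cutoff: float = 0.6
    prior_odds: float = 5e-2
    phi0: float = 0.1
    j_bound: float = 1.0
    n_samples: int = 10000
    n_steps: int = 1000
    delta_max: float = 2.0
    delta_step: float = 0.1
    cluster_method: str = "kmeans_gap"
    seed: int = 0
    run_perturb: bool = False
    perturb_state: str | None = None
    perturb_module: str | None = None
    perturb_target: str | None = None
    clamp_modules: tuple = ()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "clamp_modules" in data:
            data["clamp_modules"] = tuple(data["clamp_modules"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Master seed expanded per stage via a stable counter scheme."""
        order = ["synth", "prep", "seed_clusters", "iterate", "grn", "perturb"]
        return int(self.seed) * 1000 + order.index(stage)


def write_prep_h5(mat: io_prep.ExpressionMatrix, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("counts", data=mat.counts)
        fh.create_dataset("cell_ids", data=np.array(mat.cell_ids, dtype="S"))
        fh.create_dataset("gene_ids", data=np.array(mat.gene_ids, dtype="S"))
        fh.attrs["layer"] = mat.layer


def read_prep_h5(path) -> io_prep.ExpressionMatrix:
    import h5py

    with h5py.File(path, "r") as fh:
        return io_prep.ExpressionMatrix(
            counts=fh["counts"][...],
            cell_ids=[s.decode() for s in fh["cell_ids"][...]],
            gene_ids=[s.decode() for s in fh["gene_ids"][...]],
            layer=str(fh.attrs["layer"]),
        )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns a manifest of artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "artifacts": {},
    }
    art = manifest["artifacts"]

    state_matrix = None
    if config.states_csv:
        state_matrix = modules.BinaryStateMatrix.from_csv(config.states_csv)
    else:
        # ---- prep ----------------------------------------------------
        if config.counts_path:
            mat = io_prep.load_expression(config.counts_path)
            if config.annot_path:
                annot = io_prep.load_annotation(config.annot_path)
                mat = io_prep.restrict_to_tfs(mat, annot)
            truth = None
            plan = None
        else:
            plan = synth.default_lineage_config()
            mat, truth = synth.generate_lineage_dataset(
                plan, seed=config.stage_seed("synth")
            )
        mat = io_prep.filter_cells_min_depth(mat, config.depth)
        mat = io_prep.subsample_umis(mat, config.depth, seed=config.stage_seed("prep"))
        prep_path = out / "prep.h5"
        write_prep_h5(mat, prep_path)
        art["prep"] = str(prep_path)

        # ---- lineage -------------------------------------------------
        logmat = io_prep.lognorm(mat)
        seed_assign = lineage.seed_clusters(
            logmat, method=config.cluster_method, seed=config.stage_seed("seed_clusters")
        )
        from statefate.triplet import TripletPriors

        priors = TripletPriors(
            prior_odds_transition=config.prior_odds,
            prior_odds_marker=config.prior_odds,
        )
        state = lineage.run_iterations(
            logmat,
            seed_assign,
            gene_cutoff=config.gene_cutoff,
            triplet_cutoff=config.triplet_cutoff,
            method=config.cluster_method,
            seed=config.stage_seed("iterate"),
            priors=priors,
        )
        tree = lineage.assemble_tree(state.triplet_results)
        state.assignment.to_tsv(out / "assignment.tsv")
        lineage.write_history(state, out / "iterations.jsonl")
        pd.DataFrame(tree.edges(), columns=["parent", "child"]).to_csv(
            out / "tree_edges.tsv", sep="\t", index=False
        )
        (out / "tree.nwk").write_text(tree.newick() + "\n")
        art["assignment"] = str(out / "assignment.tsv")
        art["tree"] = str(out / "tree_edges.tsv")
        if truth is not None:
            from sklearn.metrics import adjusted_rand_score

            manifest["ari_vs_truth"] = float(
                adjusted_rand_score(truth, state.assignment.labels)
            )

        # ---- modules -------------------------------------------------
        labels = [f"C{k}" for k in state.assignment.labels]
        named_tree = _relabel_tree(tree, state.assignment)
        calls = modules.local_calls_for_gene(
            _with_named_clusters(state.triplet_results), named_tree, config.gene_cutoff
        )
        states_order = sorted(set(labels))
        profiles = pd.DataFrame(
            modules.state_mean_profiles(logmat.counts, labels, states_order),
            index=logmat.gene_ids,
            columns=states_order,
        )
        binary = modules.binarize_genes(calls, profiles, states_order)
        state_matrix = modules.group_modules(binary, states_order)
        state_matrix.to_csv(out / "modules.csv")
        modules.write_members(state_matrix, out / "module_members.tsv")
        art["modules"] = str(out / "modules.csv")

    # ---- grn ---------------------------------------------------------
    model_cfg = grn.ModelConfig(phi0=config.phi0, j_bound=config.j_bound)
    collapsed, groups = modules.collapse_aliases(state_matrix)
    system = grn.fixed_point_constraints(collapsed, model_cfg)
    ensemble = grn.sample_couplings(
        system,
        n_samples=config.n_samples,
        seed=config.stage_seed("grn"),
        states=collapsed,
    )
    grn.write_ensemble(ensemble, out / "ensemble.h5")
    summary = grn.ensemble_summary(ensemble)
    pd.DataFrame(
        summary["mean"], index=collapsed.module_ids, columns=collapsed.module_ids
    ).to_csv(out / "coupling_mean.csv")
    art["ensemble"] = str(out / "ensemble.h5")
    manifest["alias_groups"] = groups

    # ---- perturb -----------------------------------------------------
    if config.run_perturb:
        if config.perturb_module and config.perturb_target and config.perturb_state:
            grid = np.round(
                np.arange(0.0, config.delta_max + 1e-9, config.delta_step), 10
            )
            scan = perturb.overexpression_scan(
                ensemble,
                config.perturb_state,
                config.perturb_module,
                config.perturb_target,
                delta_grid=grid,
            )
            scan.to_csv(out / "overexpression_scan.csv", index=False)
            art["scan"] = str(out / "overexpression_scan.csv")
        if config.clamp_modules and config.perturb_state:
            dist = perturb.ensemble_markov(
                ensemble,
                config.perturb_state,
                clamps=list(config.clamp_modules),
                n_steps=config.n_steps,
            )
            masses = perturb.classify_distribution(dist, collapsed)
            pd.Series(masses).to_csv(out / "signal_response.csv", header=False)
            art["signal"] = str(out / "signal_response.csv")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _with_named_clusters(triplet_results):
    """Rename integer cluster ids to C<k> labels in triplet results."""
    import copy

    out = []
    for r in triplet_results:
        r2 = copy.copy(r)
        trip = copy.copy(r.triplet)
        object.__setattr__(
            trip, "cluster_ids", tuple(f"C{c}" for c in r.triplet.cluster_ids)
        )
        r2.triplet = trip
        out.append(r2)
    return out


def _relabel_tree(tree: lineage.LineageTree, assignment) -> "lineage.nx.Graph":
    import networkx as nx

    g = nx.relabel_nodes(tree.graph, {k: f"C{k}" for k in tree.graph.nodes})
    return g
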