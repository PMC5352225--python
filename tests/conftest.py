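"""Shared fixtures: synthetic datasets are generated once per session."""

import numpy as np
import pytest

from statefate import grn, io_prep, lineage, synth


@pytest.fixture(scope="session")
def planted_plan():
    return synth.default_lineage_config()


@pytest.fixture(scope="session")
def lineage_dataset(planted_plan):
    """Paper-scale planted dataset: (lognorm matrix, truth labels, plan)."""
    mat, truth = synth.generate_lineage_dataset(planted_plan, seed=3)
    mat = io_prep.subsample_umis(io_prep.filter_cells_min_depth(mat), seed=4)
    return io_prep.lognorm(mat), truth, planted_plan


@pytest.fixture(scope="session")
def truth_assignment(lineage_dataset):
    log, truth, _ = lineage_dataset
    sidx = {s: i for i, s in enumerate(sorted(set(truth)))}
    return lineage.ClusterAssignment(
        np.array([sidx[t] for t in truth]), log.cell_ids
    )


@pytest.fixture(scope="session")
def truth_triplet_results(lineage_dataset, truth_assignment):
    from statefate.lineage import _analyze_all_triplets
    from statefate.triplet import TripletPriors

    log, _, _ = lineage_dataset
    return _analyze_all_triplets(
        log.counts.astype(float), truth_assignment, log.gene_ids, TripletPriors(), 5
    )


@pytest.fixture(scope="session")
def grn_instance():
    """Planted threshold network with 10 modules and >= 4 fixed points."""
    return synth.generate_grn_instance(10, target_n_states=4, seed=11)


@pytest.fixture(scope="session")
def small_ensemble(grn_instance):
    system = grn.fixed_point_constraints(grn_instance.states, grn.ModelConfig())
    return grn.sample_couplings(
        system, n_samples=60, seed=7, states=grn_instance.states
    )
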