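# statefate

Inference of discrete cell states and their lineage tree from single-cell
UMI counts, followed by ensemble modeling of the gene regulatory network
that stabilizes those states.

The pipeline:

1. **prep** (`statefate.io_prep`) — count-matrix IO (MTX/CSV/TSV), depth
   filtering (default ≥ 20,000 UMIs/cell), exact per-cell downsampling to a
   common depth (multivariate hypergeometric), log2(x+1) normalization,
   restriction to transcription factors.
2. **lineage** (`statefate.triplet`, `statefate.lineage`) — for every
   triplet of cell clusters, per-gene posteriors of being a *marker*
   (highest in one cluster) or *transition* gene (lowest in one cluster)
   and a posterior over which cluster is the intermediate node; iterative
   re-clustering in the inferred marker/transition gene subspace until
   convergence; most-parsimonious tree assembly; a per-cluster PCA
   discreteness test against per-gene permutation nulls.
3. **modules** (`statefate.modules`) — binarization of each gene's
   expression across the final states (local triplet calls first, then a
   ~10% comparability threshold), grouping of identical patterns into gene
   modules, and appended signaling-pathway modules (LIF/BMP/WNT/FGF).
4. **grn** (`statefate.grn`) — the fixed-point inequality system (for N
   modules and S states: N·S inequalities over N² couplings, |J| ≤ 1,
   critical drive φ0 = 0.1) and LP sampling of a coupling ensemble with
   random binary objectives cut by a hyperplane through the origin.
5. **perturb** (`statefate.perturb`) — ensemble predictions:
   overexpression scans (fraction of models in which a target module shuts
   off as a clamped module is raised in steps of 0.1) and signal-clamped
   ensemble Markov dynamics propagated lazily over the visited state
   support (mathematically identical to the full 2^N transition matrix on
   that support).

`statefate.synth` generates planted datasets for both halves: UMI count
matrices on a planted bifurcating 9-state tree, and random threshold
networks together with the complete set of their fixed points (a feasible
ground truth for the LP sampler). Everything is testable offline.

## CLI

```bash
# synthetic data
statefate simulate lineage --seed 7 --out sim/
statefate simulate grn --n-modules 10 --target-states 4 --seed 7 --out grn.h5

# pipeline stages
statefate prep --counts sim/counts.mtx --depth 20000 --seed 7 --out prep.h5
statefate lineage --in prep.h5 --method kmeans_gap --seed 7 --out lineage/
statefate grn sample --states modules.csv --n 10000 --phi0 0.1 --seed 7 --out ensemble.h5
statefate perturb overexpress --ensemble ensemble.h5 --state C1 --module Sox2 --target Oct4 --out scan.csv
statefate perturb signal --ensemble ensemble.h5 --state C3 --clamp LIF,BMP --steps 1000 --out dist.csv

# everything at once (YAML config optional; defaults to synthetic data)
statefate run --config cfg.yaml --seed 7 --out out/
```

A user-supplied module × state CSV (binary; modules in rows, states in
columns — the same shape `statefate modules`/the pipeline writes) can
replace the data-analysis half: pass it to `statefate grn sample
--states`, or set `states_csv` in the pipeline config.

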