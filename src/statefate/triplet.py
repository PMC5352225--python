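"""Per-triplet gene-class posteriors and triplet topology posteriors.

For a triplet of clusters each gene is scored as a *marker* (distribution
highest in one cluster), a *transition* gene (lowest in one cluster), or
neither. The concrete likelihood is a two-component (low/high) Gaussian
mixture on log expression fitted on the pooled cells of the triplet:
cluster-level "high" probabilities q_k are products of per-cell component
posteriors renormalized within the cluster, and the eight joint high/low
configurations of the three clusters partition into 3 marker, 3 transition
and 2 null hypotheses. A gene whose pooled distribution does not support
two components (by BIC) is declared null outright.

Each transition gene votes against its lowest cluster being the
intermediate node of the triplet: under topology ``T = k`` a gene's
transition-low-in-k mass is incompatible and contributes nothing, so

    P(T = k | data)  proportional to  prior_k * prod_i (1 - p_transition_{i,k}).

The EM is run batched over all genes of a triplet so that the iterative
re-clustering loop stays fast.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from statefate.errors import PreconditionError, ValidationError

DEFAULT_PRIOR_ODDS = 5e-2
MIN_CELLS = 5

_VAR_FLOOR = 1e-4
_LOG_TINY = -745.0  # log of smallest positive double


@dataclasses.dataclass(frozen=True)
class Triplet:
    """Three disjoint clusters, each given as a tuple of cell indices."""

    cluster_ids: tuple
    cells: tuple  # tuple of three index sequences

    def __post_init__(self):
        if len(self.cluster_ids) != 3 or len(self.cells) != 3:
            raise ValidationError("a triplet has exactly three clusters")
        object.__setattr__(
            self, "cells", tuple(tuple(int(i) for i in c) for c in self.cells)
        )
        sets = [set(c) for c in self.cells]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValidationError("triplet clusters must be disjoint")

    def sizes(self) -> tuple:
        return tuple(len(c) for c in self.cells)


@dataclasses.dataclass(frozen=True)
class TripletPriors:
    prior_odds_transition: float = DEFAULT_PRIOR_ODDS
    prior_odds_marker: float = DEFAULT_PRIOR_ODDS
    topology_prior: tuple = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self):
        if self.prior_odds_transition <= 0 or self.prior_odds_marker <= 0:
            raise ValidationError("prior odds must be positive")
        if any(p <= 0 for p in self.topology_prior):
            raise ValidationError("topology prior must be positive")


@dataclasses.dataclass
class GeneTripletPosterior:
    gene_id: str
    p_marker: np.ndarray      # P(marker for cluster k), k = 0..2
    p_transition: np.ndarray  # P(transition, lowest in cluster k)
    p_null: float

    @property
    def odds_transition(self) -> np.ndarray:
        p = np.clip(self.p_transition, 0.0, 1.0 - 1e-12)
        return p / (1.0 - p)

    def total(self) -> float:
        return float(self.p_null + self.p_marker.sum() + self.p_transition.sum())


@dataclasses.dataclass
class TripletResult:
    triplet: Triplet
    gene_posteriors: list
    p_topology: np.ndarray  # P(cluster k is the intermediate node)
    priors: TripletPriors


# ---------------------------------------------------------------------------
# batched one-dimensional two-component Gaussian mixtures (deterministic EM)
# ---------------------------------------------------------------------------

def _norm_logpdf(x, mu, var):
    return -0.5 * (np.log(2 * np.pi * var) + (x - mu) ** 2 / var)


def _fit_two_component_batch(X, max_iter=120, tol=1e-7):
    """EM for G independent 1-D two-component mixtures, X of shape (G, n).

    Deterministic quartile initialization. Returns (loglik, resp_high) with
    resp_high the per-point posterior of the higher-mean component,
    shape (G, n).
    """
    G, n = X.shape
    q = np.quantile(X, [0.25, 0.75], axis=1).T  # (G, 2)
    mu = q.copy()
    flat = mu[:, 0] == mu[:, 1]
    if flat.any():
        mu[flat, 0] = X[flat].min(axis=1)
        mu[flat, 1] = X[flat].max(axis=1)
    var = np.maximum(X.var(axis=1) / 4.0, _VAR_FLOOR)[:, None].repeat(2, axis=1)
    w = np.full((G, 2), 0.5)
    ll = np.full(G, -np.inf)
    for _ in range(max_iter):
        log_comp = np.log(w)[:, :, None] + _norm_logpdf(
            X[:, None, :], mu[:, :, None], var[:, :, None]
        )  # (G, 2, n)
        log_norm = np.logaddexp(log_comp[:, 0, :], log_comp[:, 1, :])  # (G, n)
        ll_new = log_norm.sum(axis=1)
        resp = np.exp(log_comp - log_norm[:, None, :])  # (G, 2, n)
        nk = resp.sum(axis=2) + 1e-12  # (G, 2)
        w = nk / n
        mu = (resp * X[:, None, :]).sum(axis=2) / nk
        var = np.maximum(
            (resp * (X[:, None, :] - mu[:, :, None]) ** 2).sum(axis=2) / nk, _VAR_FLOOR
        )
        done = np.max(ll_new - ll) < tol
        ll = ll_new
        if done:
            break
    hi = np.argmax(mu, axis=1)  # (G,)
    resp_high = resp[np.arange(G), hi, :]
    return ll, resp_high


def _single_component_loglik(X):
    var = np.maximum(X.var(axis=1), _VAR_FLOOR)
    return _norm_logpdf(X, X.mean(axis=1)[:, None], var[:, None]).sum(axis=1)


def _batch_class_posteriors(groups: list, priors: TripletPriors) -> np.ndarray:
    """Posterior table of shape (G, 7): [null, marker_0..2, transition_0..2].

    ``groups`` holds three arrays of shape (G, n_k) of log expression values.
    """
    X = np.concatenate(groups, axis=1)  # (G, n)
    G, n = X.shape
    out = np.zeros((G, 7))
    out[:, 0] = 1.0

    active = (np.ptp(X, axis=1) > 0) & (X.var(axis=1) >= _VAR_FLOOR)
    if not active.any():
        return out
    Xa = X[active]
    ll2, resp_high = _fit_two_component_batch(Xa)
    # BIC model check: one adequate component means no marker/transition signal
    bic1 = -2 * _single_component_loglik(Xa) + 2 * np.log(n)
    bic2 = -2 * ll2 + 5 * np.log(n)
    bimodal = bic2 < bic1
    if not bimodal.any():
        return out

    eps = 1e-12
    rh = np.clip(resp_high[bimodal], eps, 1 - eps)
    log_hi = np.log(rh)
    log_lo = np.log1p(-rh)
    sizes = [g.shape[1] for g in groups]
    offs = np.cumsum([0] + sizes)
    logit_q = np.stack(
        [
            (log_hi[:, offs[k]:offs[k + 1]] - log_lo[:, offs[k]:offs[k + 1]]).sum(axis=1)
            for k in range(3)
        ],
        axis=1,
    )  # (g, 3)
    log_q = -np.logaddexp(0.0, -logit_q)
    log_1mq = -np.logaddexp(0.0, logit_q)

    others = [(1, 2), (0, 2), (0, 1)]
    log_l_marker = np.stack(
        [log_q[:, k] + log_1mq[:, a] + log_1mq[:, b] for k, (a, b) in enumerate(others)],
        axis=1,
    )
    log_l_trans = np.stack(
        [log_1mq[:, k] + log_q[:, a] + log_q[:, b] for k, (a, b) in enumerate(others)],
        axis=1,
    )
    log_l_null = np.logaddexp(log_q.sum(axis=1), log_1mq.sum(axis=1))

    log_w = np.concatenate(
        (
            [0.0],
            np.full(3, np.log(priors.prior_odds_marker)),
            np.full(3, np.log(priors.prior_odds_transition)),
        )
    )
    log_post = log_w[None, :] + np.concatenate(
        (log_l_null[:, None], log_l_marker, log_l_trans), axis=1
    )
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)

    idx = np.flatnonzero(active)[bimodal]
    out[idx] = post
    return out


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def gene_class_posterior(
    expr,
    triplet: Triplet | None = None,
    priors: TripletPriors | None = None,
    gene_id: str = "",
    min_cells: int = MIN_CELLS,
) -> GeneTripletPosterior:
    """Posterior over {marker-for-k, transition-low-in-k, null} for one gene.

    ``expr`` is either a full per-cell vector (indexed by ``triplet.cells``)
    or a sequence of three per-cluster value arrays.
    """
    priors = priors or TripletPriors()
    if triplet is not None and not isinstance(expr, (list, tuple)):
        expr = np.asarray(expr, dtype=float)
        groups = [expr[np.asarray(c)] for c in triplet.cells]
    else:
        groups = [np.asarray(g, dtype=float) for g in expr]
    if len(groups) != 3:
        raise ValidationError("expected expression values for three clusters")
    if any(g.size < min_cells for g in groups):
        raise PreconditionError(f"each cluster needs at least {min_cells} cells")
    table = _batch_class_posteriors([g[None, :] for g in groups], priors)[0]
    return GeneTripletPosterior(gene_id, table[1:4], table[4:7], float(table[0]))


def topology_posterior(
    gene_posteriors: Sequence[GeneTripletPosterior],
    priors: TripletPriors | None = None,
) -> np.ndarray:
    """P(T = k | data): each gene's transition mass against cluster k is
    incompatible with k being the intermediate node."""
    priors = priors or TripletPriors()
    if len(gene_posteriors) == 0:
        raise PreconditionError("topology posterior needs at least one gene")
    log_p = np.log(np.asarray(priors.topology_prior, dtype=float))
    for gp in gene_posteriors:
        surv = np.clip(1.0 - np.asarray(gp.p_transition, dtype=float), np.exp(_LOG_TINY), 1.0)
        log_p = log_p + np.log(surv)
    log_p -= log_p.max()
    p = np.exp(log_p)
    return p / p.sum()


def analyze_triplet(
    values: np.ndarray,
    triplet: Triplet,
    gene_ids: Sequence[str],
    priors: TripletPriors | None = None,
    min_cells: int = MIN_CELLS,
) -> TripletResult:
    """Score every gene (columns of ``values``, cells in rows) for one triplet."""
    priors = priors or TripletPriors()
    if any(len(c) < min_cells for c in triplet.cells):
        raise PreconditionError(f"each cluster needs at least {min_cells} cells")
    groups = [values[np.asarray(c), :].T.astype(float) for c in triplet.cells]  # (G, n_k)
    table = _batch_class_posteriors(groups, priors)
    posteriors = [
        GeneTripletPosterior(gid, table[j, 1:4], table[j, 4:7], float(table[j, 0]))
        for j, gid in enumerate(gene_ids)
    ]
    p_topo = topology_posterior(posteriors, priors)
    return TripletResult(triplet, posteriors, p_topo, priors)


def classify_genes(result: TripletResult, gene_cutoff: float = 0.5) -> dict:
    """Label each gene marker/transition (with its cluster) when the
    corresponding posterior strictly exceeds the cutoff."""
    labels = {}
    for gp in result.gene_posteriors:
        label = ("none", None)
        k_m = int(np.argmax(gp.p_marker))
        k_t = int(np.argmax(gp.p_transition))
        if gp.p_marker[k_m] > gene_cutoff:
            label = ("marker", result.triplet.cluster_ids[k_m])
        elif gp.p_transition[k_t] > gene_cutoff:
            label = ("transition", result.triplet.cluster_ids[k_t])
        labels[gp.gene_id] = label
    return labels


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_triplet_result(result: TripletResult, tsv_path: str | Path) -> None:
    """TSV of per-gene posteriors plus a JSON sidecar with the topology posterior."""
    tsv_path = Path(tsv_path)
    rows = []
    for gp in result.gene_posteriors:
        row = {"gene_id": gp.gene_id}
        for k, c in enumerate(result.triplet.cluster_ids):
            row[f"p_marker_{c}"] = gp.p_marker[k]
        for k, c in enumerate(result.triplet.cluster_ids):
            row[f"p_transition_{c}"] = gp.p_transition[k]
        row["p_null"] = gp.p_null
        rows.append(row)
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    header = {
        "cluster_ids": list(result.triplet.cluster_ids),
        "p_topology": [float(p) for p in result.p_topology],
        "priors": {
            "prior_odds_transition": result.priors.prior_odds_transition,
            "prior_odds_marker": result.priors.prior_odds_marker,
            "topology_prior": list(result.priors.topology_prior),
        },
    }
    tsv_path.with_suffix(".json").write_text(json.dumps(header, indent=2))
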