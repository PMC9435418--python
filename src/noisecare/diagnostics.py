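"""Evidence-sensitivity (delta-p) scenarios and arc influence values.

Delta-p sets an evidence assignment with probability 100% and reports, for
every other node and state, the change between the prior marginal and the
posterior, in percentage points.  The influence value of an arc summarizes
how far the child's conditional distribution moves across the parent's
states, averaged over co-parent configurations — by default the mean
Euclidean distance between CPT rows (so a maximal binary flip scores
sqrt(2)); a Hellinger variant is selectable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .bayes_net import BayesNetError, DiscreteBayesNet, infer_posterior

__all__ = [
    "DeltaPResult",
    "InfluenceValue",
    "delta_p",
    "influence_value",
    "rank_influences",
]


@dataclass(frozen=True)
class DeltaPResult:
    """Prior vs posterior marginals under one evidence assignment."""

    evidence: dict[str, str]
    frame: pd.DataFrame  # columns: node, state, prior_pct, posterior_pct, delta_pct
    rounding: int = 0

    def rounded(self) -> pd.DataFrame:
        """Presentation copy with deltas as signed whole-percent strings."""
        out = self.frame.copy()
        nd = self.rounding
        for col in ("prior_pct", "posterior_pct"):
            out[col] = out[col].round(nd)
        out["delta_pct"] = [
            f"{d:+.{nd}f}%" for d in self.frame["delta_pct"].round(nd)
        ]
        return out


@dataclass(frozen=True)
class InfluenceValue:
    parent: str
    child: str
    value: float
    metric: str = "euclidean"


def delta_p(
    net: DiscreteBayesNet,
    evidence: Mapping[str, str],
    targets: Iterable[str] | None = None,
) -> DeltaPResult:
    """Posterior-minus-prior change per node state, in percentage points.

    ``targets`` defaults to every node (evidence nodes included, whose
    evidenced state then shows posterior 100).  Explicit targets must be
    disjoint from the evidence.
    """
    evidence = dict(evidence)
    if not evidence:
        raise BayesNetError("delta_p requires non-empty evidence")
    for node, state in evidence.items():
        net.state_index(node, state)
    if targets is None:
        target_list = list(net.names)
    else:
        target_list = list(targets)
        overlap = set(target_list) & set(evidence)
        if overlap:
            raise BayesNetError(
                f"targets must be disjoint from evidence: {sorted(overlap)}"
            )

    rows = []
    for node in target_list:
        states = net.states(node)
        prior = infer_posterior(net, node, {})
        if node in evidence:
            post = np.zeros(len(states))
            post[net.state_index(node, evidence[node])] = 1.0
        else:
            post = infer_posterior(net, node, evidence)
        for i, state in enumerate(states):
            rows.append(
                (
                    node,
                    state,
                    100.0 * prior[i],
                    100.0 * post[i],
                    100.0 * (post[i] - prior[i]),
                )
            )
    frame = pd.DataFrame(
        rows, columns=["node", "state", "prior_pct", "posterior_pct", "delta_pct"]
    )
    return DeltaPResult(evidence=evidence, frame=frame)


def _row_distance(p: np.ndarray, q: np.ndarray, metric: str) -> float:
    if metric == "euclidean":
        return float(np.linalg.norm(p - q))
    if metric == "hellinger":
        return float(np.linalg.norm(np.sqrt(p) - np.sqrt(q)) / np.sqrt(2.0))
    raise ValueError(f"unknown metric {metric!r}")


def influence_value(
    net: DiscreteBayesNet,
    parent: str,
    child: str,
    metric: str = "euclidean",
) -> InfluenceValue:
    """Mean pairwise distance between the child's conditional distributions
    across the parent's states, uniformly averaged over co-parent configs."""
    parents = net.parents(child)
    if parent not in parents:
        raise BayesNetError(f"{parent!r} -> {child!r} is not an arc")
    cpt = net.cpts[child]
    if cpt is None:
        raise BayesNetError(f"CPT unset for {child!r}")
    axis = parents.index(parent)
    table = np.moveaxis(cpt.table, axis, 0)  # parent states first
    k = table.shape[0]
    co_shape = table.shape[1:-1]
    dists = []
    for co in np.ndindex(*co_shape) if co_shape else [()]:
        for a, b in itertools.combinations(range(k), 2):
            dists.append(_row_distance(table[(a, *co)], table[(b, *co)], metric))
    return InfluenceValue(parent, child, float(np.mean(dists)), metric)


def rank_influences(
    net: DiscreteBayesNet, metric: str = "euclidean"
) -> pd.DataFrame:
    """All arcs ordered by influence value, descending; ties break by
    (parent, child) name order."""
    rows = [
        influence_value(net, p, c, metric=metric) for p, c in net.arcs()
    ]
    frame = pd.DataFrame(
        [(r.parent, r.child, r.value) for r in rows],
        columns=["parent", "child", "influence_value"],
    )
    frame = frame.sort_values(
        by=["influence_value", "parent", "child"],
        ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    return frame
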