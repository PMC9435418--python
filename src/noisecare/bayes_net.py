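"""Discrete Bayesian networks: data model, exact inference, and EM learning.

The network model is deliberately small and self-contained: variables carry an
*ordered* list of categorical states, each variable owns one conditional
probability table (CPT) indexed by its parents' states, and inference is exact
variable elimination (verified against full-joint enumeration in the test
suite).  EM learning handles incomplete categorical records by computing each
record's exact posterior over its missing cells.

The default seven-node structure links a nurse's occupational noise exposure,
noise sensitivity and annoyance to the three aspects of quality of patient
care (psychosocial, communicational, physical) and, through them, to the
overall quality-of-care rating.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "NetworkVariable",
    "Cpt",
    "DiscreteBayesNet",
    "BayesNetError",
    "ImpossibleEvidenceError",
    "EMConvergenceError",
    "build_study_network",
    "build_table3_network",
    "joint_probability",
    "infer_posterior",
    "evidence_probability",
    "em_learn",
    "map_predict",
    "read_network",
    "write_network",
    "TABLE3_FIXTURE",
]

_ROW_TOL = 1e-9

#: ordered states shared by the three noise variables
NOISE_STATES = ("low", "moderate", "high")
#: ordered states shared by quality-of-care variables
QUALITY_STATES = ("undesirable", "partly_desirable", "desirable")

TABLE3_FIXTURE = Path(__file__).parent / "data" / "table3_network.json"


class BayesNetError(ValueError):
    """Invalid network specification or query."""


class ImpossibleEvidenceError(BayesNetError):
    """The supplied evidence has zero probability under the network."""


class EMConvergenceError(RuntimeError):
    """EM observed-data log-likelihood decreased — indicates a bug."""


@dataclass(frozen=True)
class NetworkVariable:
    """A categorical network node with an ordered set of states."""

    name: str
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if len(self.states) < 2:
            raise BayesNetError(f"variable {self.name!r} needs >= 2 states")
        if len(set(self.states)) != len(self.states):
            raise BayesNetError(f"variable {self.name!r} has duplicate states")


class Cpt:
    """One conditional probability table.

    ``table`` has one axis per parent (in ``parents`` order) plus a trailing
    axis over the child's states; every row along that trailing axis is a
    probability vector.
    """

    def __init__(
        self,
        child: str,
        parents: Sequence[str],
        table: np.ndarray,
    ) -> None:
        self.child = child
        self.parents = tuple(parents)
        table = np.asarray(table, dtype=float)
        if table.ndim != len(self.parents) + 1:
            raise BayesNetError(
                f"CPT for {child!r}: table has {table.ndim} axes, expected "
                f"{len(self.parents) + 1}"
            )
        if np.any(table < 0):
            raise BayesNetError(f"CPT for {child!r}: negative probability")
        sums = table.sum(axis=-1)
        if not np.allclose(sums, 1.0, rtol=0, atol=_ROW_TOL):
            raise BayesNetError(
                f"CPT for {child!r}: rows must sum to 1 within {_ROW_TOL}"
                f" (worst deviation {np.abs(sums - 1).max():.3g})"
            )
        self.table = table

    def row(self, parent_states: Mapping[str, int] | Sequence[int]) -> np.ndarray:
        """Probability vector over the child's states for one parent config."""
        if isinstance(parent_states, Mapping):
            idx = tuple(parent_states[p] for p in self.parents)
        else:
            idx = tuple(parent_states)
        return self.table[idx]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Cpt)
            and self.child == other.child
            and self.parents == other.parents
            and self.table.shape == other.table.shape
            and np.allclose(self.table, other.table, rtol=0, atol=1e-12)
        )


class DiscreteBayesNet:
    """A directed acyclic model over categorical variables.

    CPTs may be left unset (``None``) to describe structure only, e.g. as the
    input to :func:`em_learn`.
    """

    def __init__(
        self,
        variables: Sequence[NetworkVariable],
        cpts: Mapping[str, Cpt | None] | None = None,
        parents: Mapping[str, Sequence[str]] | None = None,
    ) -> None:
        self.variables = list(variables)
        self._vars = {v.name: v for v in self.variables}
        if len(self._vars) != len(self.variables):
            raise BayesNetError("duplicate variable names")

        cpts = dict(cpts or {})
        if parents is not None:
            # structure-only construction
            self._parents = {n: tuple(parents.get(n, ())) for n in self._vars}
        else:
            self._parents = {
                n: (cpts[n].parents if cpts.get(n) is not None else ())
                for n in self._vars
            }
        self.cpts: dict[str, Cpt | None] = {n: cpts.get(n) for n in self._vars}
        self._validate()

    # -- construction helpers -------------------------------------------------
    def _validate(self) -> None:
        g = self.graph()
        for child, ps in self._parents.items():
            for p in ps:
                if p not in self._vars:
                    raise BayesNetError(f"undeclared parent {p!r} of {child!r}")
        if not nx.is_directed_acyclic_graph(g):
            raise BayesNetError("parent structure contains a cycle")
        for name, cpt in self.cpts.items():
            if cpt is None:
                continue
            if cpt.parents != self._parents[name]:
                raise BayesNetError(f"CPT parents mismatch for {name!r}")
            expect = tuple(len(self._vars[p].states) for p in cpt.parents) + (
                len(self._vars[name].states),
            )
            if cpt.table.shape != expect:
                raise BayesNetError(
                    f"CPT for {name!r}: shape {cpt.table.shape}, expected {expect}"
                )

    # -- introspection --------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def var(self, name: str) -> NetworkVariable:
        try:
            return self._vars[name]
        except KeyError:
            raise BayesNetError(f"unknown variable {name!r}") from None

    def states(self, name: str) -> tuple[str, ...]:
        return self.var(name).states

    def state_index(self, name: str, state: str) -> int:
        try:
            return self.var(name).states.index(state)
        except ValueError:
            raise BayesNetError(
                f"state {state!r} is not legal for variable {name!r}"
            ) from None

    def parents(self, name: str) -> tuple[str, ...]:
        self.var(name)
        return self._parents[name]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self._vars)
        for child, ps in self._parents.items():
            g.add_edges_from((p, child) for p in ps)
        return g

    def arcs(self) -> list[tuple[str, str]]:
        return [(p, c) for c in self.names for p in self._parents[c]]

    def topological_order(self) -> list[str]:
        order = list(nx.topological_sort(self.graph()))
        # stable w.r.t. declaration order among independent nodes
        rank = {n: i for i, n in enumerate(self.names)}
        return sorted(order, key=lambda n: (order.index(n), rank[n]))

    def is_parameterized(self) -> bool:
        return all(c is not None for c in self.cpts.values())

    def structure_copy(self) -> "DiscreteBayesNet":
        return DiscreteBayesNet(self.variables, parents=self._parents)

    def set_cpt(self, cpt: Cpt) -> None:
        if cpt.parents != self._parents[cpt.child]:
            raise BayesNetError(f"CPT parents mismatch for {cpt.child!r}")
        self.cpts[cpt.child] = cpt
        self._validate()

    def _require_params(self) -> None:
        missing = [n for n, c in self.cpts.items() if c is None]
        if missing:
            raise BayesNetError(f"CPTs unset for variables: {missing}")

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, DiscreteBayesNet)
            and self.variables == other.variables
            and self._parents == other._parents
            and self.cpts == other.cpts
        )


# ---------------------------------------------------------------------------
# study structure
# ---------------------------------------------------------------------------

def build_study_network() -> DiscreteBayesNet:
    """The seven-node expert structure, CPTs unset.

    exposure -> sensitivity; {exposure, sensitivity} -> annoyance;
    {exposure, sensitivity, annoyance} -> each quality aspect;
    {psychosocial, communicational, physical} -> quality.  15 arcs.
    """
    noise_vars = ["exposure", "sensitivity", "annoyance"]
    aspect_vars = ["psychosocial", "communicational", "physical"]
    variables = [NetworkVariable(n, NOISE_STATES) for n in noise_vars] + [
        NetworkVariable(n, QUALITY_STATES) for n in aspect_vars + ["quality"]
    ]
    parents = {
        "exposure": (),
        "sensitivity": ("exposure",),
        "annoyance": ("exposure", "sensitivity"),
        "psychosocial": ("exposure", "sensitivity", "annoyance"),
        "communicational": ("exposure", "sensitivity", "annoyance"),
        "physical": ("exposure", "sensitivity", "annoyance"),
        "quality": ("psychosocial", "communicational", "physical"),
    }
    return DiscreteBayesNet(variables, parents=parents)


def build_table3_network() -> DiscreteBayesNet:
    """The packaged four-node fixture: quality conditioned directly on
    exposure, sensitivity and annoyance, with the published quality CPT."""
    return read_network(TABLE3_FIXTURE)


# ---------------------------------------------------------------------------
# exact inference
# ---------------------------------------------------------------------------

def _normalize_evidence(
    net: DiscreteBayesNet, evidence: Mapping[str, str] | None
) -> dict[str, int]:
    out: dict[str, int] = {}
    for name, state in (evidence or {}).items():
        out[name] = net.state_index(name, state)
    return out


class _Factor:
    __slots__ = ("vars", "array")

    def __init__(self, vars: tuple[str, ...], array: np.ndarray) -> None:
        self.vars = vars
        self.array = array


def _reduce(f: _Factor, ev: Mapping[str, int]) -> _Factor:
    vars_, arr = f.vars, f.array
    for name in [v for v in vars_ if v in ev]:
        axis = vars_.index(name)
        arr = np.take(arr, ev[name], axis=axis)
        vars_ = vars_[:axis] + vars_[axis + 1 :]
    return _Factor(vars_, arr)


def _multiply(f1: _Factor, f2: _Factor) -> _Factor:
    union = f1.vars + tuple(v for v in f2.vars if v not in f1.vars)

    def aligned(f: _Factor) -> np.ndarray:
        src = [f.vars.index(v) for v in union if v in f.vars]
        arr = np.transpose(f.array, src) if f.vars else f.array
        shape = [f.array.shape[f.vars.index(v)] if v in f.vars else 1 for v in union]
        return arr.reshape(shape)

    return _Factor(union, aligned(f1) * aligned(f2))


def _sum_out(f: _Factor, name: str) -> _Factor:
    axis = f.vars.index(name)
    return _Factor(
        f.vars[:axis] + f.vars[axis + 1 :], f.array.sum(axis=axis)
    )


def _eliminate(factors: list[_Factor], elim: Iterable[str]) -> _Factor:
    factors = list(factors)
    for name in elim:
        touching = [f for f in factors if name in f.vars]
        if not touching:
            continue
        rest = [f for f in factors if name not in f.vars]
        prod = touching[0]
        for f in touching[1:]:
            prod = _multiply(prod, f)
        factors = rest + [_sum_out(prod, name)]
    result = _Factor((), np.asarray(1.0))
    for f in factors:
        result = _multiply(result, f)
    return result


def _elimination_order(net: DiscreteBayesNet, keep: set[str]) -> list[str]:
    # greedy min-fill over the moralized graph; more than adequate at this scale
    g = nx.moral_graph(net.graph())
    order: list[str] = []
    remaining = [n for n in net.names if n not in keep]
    while remaining:
        def fill(n: str) -> int:
            nbrs = [m for m in g.neighbors(n) if m != n]
            return sum(
                1
                for a, b in itertools.combinations(nbrs, 2)
                if not g.has_edge(a, b)
            )

        nxt = min(remaining, key=lambda n: (fill(n), net.names.index(n)))
        nbrs = [m for m in g.neighbors(nxt) if m != nxt]
        g.add_edges_from(itertools.combinations(nbrs, 2))
        g.remove_node(nxt)
        remaining.remove(nxt)
        order.append(nxt)
    return order


def _cpt_factors(net: DiscreteBayesNet, ev: Mapping[str, int]) -> list[_Factor]:
    factors = []
    for name in net.names:
        cpt = net.cpts[name]
        f = _Factor(cpt.parents + (name,), cpt.table)
        factors.append(_reduce(f, ev))
    return factors


def evidence_probability(
    net: DiscreteBayesNet, evidence: Mapping[str, str]
) -> float:
    """Marginal probability of an evidence assignment."""
    net._require_params()
    ev = _normalize_evidence(net, evidence)
    factors = _cpt_factors(net, ev)
    order = _elimination_order(net, keep=set(ev))
    return float(_eliminate(factors, order).array)


def joint_probability(
    net: DiscreteBayesNet, assignment: Mapping[str, str]
) -> float:
    """Probability of a *full* assignment: the product of CPT entries."""
    net._require_params()
    missing = set(net.names) - set(assignment)
    if missing:
        raise BayesNetError(f"assignment misses variables: {sorted(missing)}")
    ev = _normalize_evidence(net, assignment)
    p = 1.0
    for name in net.names:
        cpt = net.cpts[name]
        idx = tuple(ev[par] for par in cpt.parents) + (ev[name],)
        p *= float(cpt.table[idx])
    return p


def infer_posterior(
    net: DiscreteBayesNet,
    query: str,
    evidence: Mapping[str, str] | None = None,
) -> np.ndarray:
    """Exact posterior P(query | evidence) by variable elimination."""
    net._require_params()
    evidence = evidence or {}
    if query in evidence:
        raise BayesNetError(f"query {query!r} is part of the evidence")
    net.var(query)
    ev = _normalize_evidence(net, evidence)
    factors = _cpt_factors(net, ev)
    order = _elimination_order(net, keep=set(ev) | {query})
    result = _eliminate(factors, order)
    arr = result.array
    if result.vars != (query,):
        axis = result.vars.index(query)
        arr = np.moveaxis(arr, axis, 0).reshape(arr.shape[axis], -1).sum(axis=1)
    total = arr.sum()
    if total <= 0.0:
        raise ImpossibleEvidenceError(
            f"evidence {evidence!r} has zero probability"
        )
    return arr / total


def map_predict(
    net: DiscreteBayesNet,
    target: str,
    evidence: Mapping[str, str] | None = None,
) -> str:
    """Most probable state of ``target``; ties break by declared state order."""
    post = infer_posterior(net, target, evidence)
    return net.states(target)[int(np.argmax(post))]


# ---------------------------------------------------------------------------
# EM parameter learning
# ---------------------------------------------------------------------------

def _init_cpts(
    structure: DiscreteBayesNet,
    rng: np.random.Generator,
    concentration: float,
) -> DiscreteBayesNet:
    net = structure.structure_copy()
    for name in net.names:
        parents = net.parents(name)
        shape = tuple(len(net.states(p)) for p in parents) + (
            len(net.states(name)),
        )
        k = shape[-1]
        rows = rng.dirichlet(np.full(k, concentration), size=shape[:-1] or (1,))
        table = rows.reshape(shape)
        net.set_cpt(Cpt(name, parents, table))
    return net


def em_learn(
    structure: DiscreteBayesNet,
    data: pd.DataFrame,
    *,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int = 0,
    jitter_concentration: float = 50.0,
    laplace: float = 0.0,
) -> DiscreteBayesNet:
    """Learn CPTs from (possibly incomplete) categorical records.

    Missing cells (NaN / None / empty string) are handled by exact EM: the
    E-step computes each record's posterior over its missing variables under
    the current parameters, the M-step normalizes expected family counts.
    Parent configurations with zero expected count receive the uniform row.

    The returned network exposes the per-iteration observed-data
    log-likelihoods as ``em_log_likelihoods_``; a decrease raises
    :class:`EMConvergenceError`.
    """
    names = structure.names
    missing_cols = [n for n in names if n not in data.columns]
    if missing_cols:
        raise BayesNetError(f"data misses columns: {missing_cols}")

    frame = data[names].copy()
    frame = frame.replace("", np.nan)
    for n in names:
        observed = frame[n].dropna()
        if observed.empty:
            raise BayesNetError(f"no non-missing value for variable {n!r}")
        bad = set(observed) - set(structure.states(n))
        if bad:
            raise BayesNetError(f"illegal states {sorted(bad)} for {n!r}")

    # integer-encode; -1 marks missing
    codes = np.full((len(frame), len(names)), -1, dtype=int)
    for j, n in enumerate(names):
        states = structure.states(n)
        lut = {s: i for i, s in enumerate(states)}
        col = frame[n]
        mask = col.notna().to_numpy()
        codes[mask, j] = [lut[s] for s in col[mask]]

    complete_mask = (codes >= 0).all(axis=1)
    complete, counts = np.unique(codes[complete_mask], axis=0, return_counts=True)
    incomplete = codes[~complete_mask]

    families = {
        n: tuple(names.index(p) for p in structure.parents(n)) + (names.index(n),)
        for n in names
    }
    card = {n: len(structure.states(n)) for n in names}

    rng = np.random.default_rng(seed)
    net = _init_cpts(structure, rng, jitter_concentration)

    def log_joint_rows(rows: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            out = np.zeros(len(rows))
            for n in names:
                cpt = net.cpts[n]
                idx = tuple(rows[:, j] for j in families[n])
                out += np.log(cpt.table[idx])
        return out

    def completions(row: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All consistent full assignments and their joint probabilities."""
        miss = np.flatnonzero(row < 0)
        grids = [range(card[names[j]]) for j in miss]
        combos = np.array(list(itertools.product(*grids)), dtype=int)
        rows = np.tile(row, (len(combos), 1))
        rows[:, miss] = combos
        probs = np.exp(log_joint_rows(rows))
        return rows, probs

    prev_ll = -np.inf
    history: list[float] = []
    for _ in range(max_iter):
        # observed-data log-likelihood under current parameters, and E-step
        ll = float((counts * log_joint_rows(complete)).sum()) if len(complete) else 0.0
        expected = {
            n: np.zeros(
                tuple(card[names[j]] for j in families[n]), dtype=float
            )
            for n in names
        }
        for row, c in zip(complete, counts):
            for n in names:
                expected[n][tuple(row[j] for j in families[n])] += c
        for row in incomplete:
            rows, probs = completions(row)
            total = probs.sum()
            if total <= 0.0:
                raise ImpossibleEvidenceError(
                    "a record's observed states have zero probability"
                )
            ll += float(np.log(total))
            w = probs / total
            for n in names:
                idx = tuple(rows[:, j] for j in families[n])
                np.add.at(expected[n], idx, w)

        history.append(ll)
        if ll < prev_ll - 1e-8 * (1.0 + abs(prev_ll)):
            raise EMConvergenceError(
                f"log-likelihood decreased: {prev_ll} -> {ll}"
            )
        improved = ll - prev_ll
        prev_ll = ll

        # M-step
        for n in names:
            tab = expected[n] + laplace
            sums = tab.sum(axis=-1, keepdims=True)
            k = tab.shape[-1]
            with np.errstate(invalid="ignore", divide="ignore"):
                rows_ = np.where(sums > 0, tab / np.where(sums == 0, 1, sums), 1.0 / k)
            net.set_cpt(Cpt(n, structure.parents(n), rows_))

        if improved < tol:
            break

    net.em_log_likelihoods_ = history  # type: ignore[attr-defined]
    return net


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def write_network(net: DiscreteBayesNet, path: str | Path) -> None:
    """Serialize to the JSON network-spec format."""
    doc = {
        "variables": [
            {"name": v.name, "states": list(v.states)} for v in net.variables
        ],
        "cpts": [],
    }
    for name in net.names:
        cpt = net.cpts[name]
        if cpt is None:
            doc["cpts"].append({"child": name, "parents": list(net.parents(name))})
            continue
        rows = []
        parent_cards = cpt.table.shape[:-1]
        for idx in itertools.product(*(range(c) for c in parent_cards)):
            given = [net.states(p)[i] for p, i in zip(cpt.parents, idx)]
            rows.append({"given": given, "probs": [float(x) for x in cpt.table[idx]]})
        doc["cpts"].append(
            {"child": name, "parents": list(cpt.parents), "rows": rows}
        )
    Path(path).write_text(json.dumps(doc, indent=1))


def read_network(path: str | Path) -> DiscreteBayesNet:
    """Read a network from the JSON network-spec format."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise BayesNetError(f"{path}: not valid JSON ({e})") from e
    if not isinstance(doc, dict) or "variables" not in doc:
        raise BayesNetError(f"{path}: missing 'variables'")
    variables = []
    for i, v in enumerate(doc["variables"]):
        try:
            variables.append(NetworkVariable(v["name"], tuple(v["states"])))
        except (KeyError, TypeError) as e:
            raise BayesNetError(f"{path}: variables[{i}] malformed ({e})") from e
    by_name = {v.name: v for v in variables}
    parents: dict[str, tuple[str, ...]] = {}
    tables: dict[str, Cpt | None] = {}
    for i, c in enumerate(doc.get("cpts", [])):
        where = f"{path}: cpts[{i}]"
        child = c.get("child")
        if child not in by_name:
            raise BayesNetError(f"{where}: unknown child {child!r}")
        ps = tuple(c.get("parents", ()))
        parents[child] = ps
        if "rows" not in c:
            tables[child] = None
            continue
        parent_cards = tuple(len(by_name[p].states) for p in ps)
        shape = parent_cards + (len(by_name[child].states),)
        table = np.full(shape, np.nan)
        seen = set()
        for r in c["rows"]:
            given = tuple(r.get("given", ()))
            if len(given) != len(ps):
                raise BayesNetError(f"{where}: row 'given' length mismatch")
            idx = tuple(
                by_name[p].states.index(g) if g in by_name[p].states else -1
                for p, g in zip(ps, given)
            )
            if -1 in idx:
                raise BayesNetError(f"{where}: illegal parent state in {given}")
            if idx in seen:
                raise BayesNetError(f"{where}: duplicate row for {given}")
            seen.add(idx)
            table[idx] = r["probs"]
        if np.isnan(table).any():
            raise BayesNetError(f"{where}: missing parent configurations")
        try:
            tables[child] = Cpt(child, ps, table)
        except BayesNetError as e:
            raise BayesNetError(f"{where}: {e}") from e
    for name in by_name:
        parents.setdefault(name, ())
        tables.setdefault(name, None)
    return DiscreteBayesNet(variables, cpts=tables, parents=parents)
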