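"""Synthetic cohorts with the dependency structure the analysis assumes.

Because the study's raw data are not deposited, every downstream stage is
exercised on generated data: a ground-truth Bayesian network over the seven
categorical variables, ancestral sampling of category-level cohorts,
expansion of categories into item-level questionnaire responses, a simulated
hospital noise grid with per-nurse workstation assignments, and MCAR
missingness injection.

The default ground-truth CPTs are documented constants calibrated so that
sampled marginals approximate the published category frequencies; they are
not the study's (unpublished) fitted parameters.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bayes_net import (
    NOISE_STATES,
    QUALITY_STATES,
    BayesNetError,
    Cpt,
    DiscreteBayesNet,
    build_study_network,
    build_table3_network,
)
from .questionnaire import (
    QPCS_CUTOFFS,
    QPCS_SUBSCALES,
    qpcs_columns,
    weinstein_columns,
)

__all__ = [
    "CohortConfig",
    "TruthNetwork",
    "make_truth_network",
    "sample_cohort",
    "expand_to_items",
    "simulate_noise_environment",
    "inject_missing",
    "study_marginals",
    "BN_COLUMNS",
]

_MARGINALS_FILE = Path(__file__).parent / "data" / "study_marginals.json"

#: cohort-table columns holding Bayesian-network states
BN_COLUMNS = (
    "exposure",
    "sensitivity",
    "annoyance",
    "psychosocial",
    "communicational",
    "physical",
    "quality",
)

#: association strength of each parent on each child in the default truth
#: network (log-linear tilt per parent level); signs encode direction: more
#: noise/sensitivity/annoyance pushes the quality aspects toward undesirable
_TILT = {
    "sensitivity": {"exposure": 0.35},
    "annoyance": {"exposure": 0.95, "sensitivity": 0.55},
    "psychosocial": {"exposure": -0.30, "sensitivity": -0.25, "annoyance": -0.50},
    "communicational": {"exposure": -0.30, "sensitivity": -0.30, "annoyance": -0.40},
    "physical": {"exposure": -0.28, "sensitivity": -0.25, "annoyance": -0.55},
    "quality": {"psychosocial": 0.80, "communicational": 0.75, "physical": 0.85},
}


def study_marginals() -> dict:
    """Published per-category frequencies, means and SDs (n = 209)."""
    return json.loads(_MARGINALS_FILE.read_text())


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the synthetic data-generating process."""

    n_nurses: int = 209
    missing_rate: float = 0.05
    seed: int = 0
    target_marginals: Mapping[str, Sequence[float]] | None = None
    #: "calibrated" = default 7-node truth CPTs; "table3" = the packaged
    #: 4-node network with the published quality CPT
    fixture: str = "calibrated"

    def __post_init__(self) -> None:
        if self.n_nurses < 1:
            raise ValueError("n_nurses must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.fixture not in ("calibrated", "table3"):
            raise ValueError(f"unknown fixture {self.fixture!r}")
        for node, vec in (self.target_marginals or {}).items():
            v = np.asarray(vec, dtype=float)
            if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-9:
                raise BayesNetError(
                    f"target marginal for node {node!r} is not a probability "
                    "vector (non-negative, summing to 1 within 1e-9)"
                )


@dataclass(frozen=True)
class TruthNetwork:
    """A fully parameterized ground-truth network plus its seed."""

    network: DiscreteBayesNet
    seed: int = 0


def _default_marginals() -> dict[str, np.ndarray]:
    doc = study_marginals()
    out = {}
    for node, info in doc["variables"].items():
        c = np.asarray(info["counts"], dtype=float)
        p = c / c.sum()
        p[-1] = 1.0 - p[:-1].sum()
        out[node] = p
    return out


def _tilted_cpt(
    net: DiscreteBayesNet,
    child: str,
    marginal: np.ndarray,
    tilt: Mapping[str, float],
) -> Cpt:
    """CPT rows proportional to ``marginal * exp(sum_p kappa_p*level_p*u)``.

    ``level`` and ``u`` run over (-1, 0, +1) for the ordered ternary states,
    so a positive kappa pushes the child toward its upper states when the
    parent sits in its upper state.
    """
    parents = net.parents(child)
    u = np.array([-1.0, 0.0, 1.0])
    shape = tuple(3 for _ in parents) + (3,)
    table = np.empty(shape)
    for idx in np.ndindex(*shape[:-1]):
        kappa = sum(
            tilt.get(p, 0.0) * u[i] for p, i in zip(parents, idx)
        )
        row = marginal * np.exp(kappa * u)
        table[idx] = row / row.sum()
    return Cpt(child, parents, table)


def make_truth_network(config: CohortConfig | None = None) -> TruthNetwork:
    """Build the ground-truth network the generator samples from."""
    config = config or CohortConfig()
    marg = _default_marginals()
    for node, vec in (config.target_marginals or {}).items():
        marg[node] = np.asarray(vec, dtype=float)

    if config.fixture == "table3":
        net = build_table3_network()
        # parent priors are configurable; the quality CPT is the fixture
        for node in ("exposure", "sensitivity", "annoyance"):
            if config.target_marginals and node in config.target_marginals:
                net.set_cpt(Cpt(node, (), marg[node]))
        return TruthNetwork(net, config.seed)

    net = build_study_network()
    net.set_cpt(Cpt("exposure", (), marg["exposure"]))
    for child in ("sensitivity", "annoyance", *QUALITY_COLS, "quality"):
        net.set_cpt(_tilted_cpt(net, child, marg[child], _TILT[child]))
    return TruthNetwork(net, config.seed)


QUALITY_COLS = ("psychosocial", "communicational", "physical")


def sample_cohort(
    truth: TruthNetwork, n: int, seed: int | None = None
) -> pd.DataFrame:
    """Ancestral sampling of ``n`` category-level records."""
    if n < 1:
        raise ValueError("n must be >= 1")
    net = truth.network
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    codes: dict[str, np.ndarray] = {}
    for name in net.topological_order():
        cpt = net.cpts[name]
        if cpt.parents:
            idx = tuple(codes[p] for p in cpt.parents)
            rows = cpt.table[idx]
        else:
            rows = np.broadcast_to(cpt.table.reshape(-1), (n, cpt.table.shape[-1]))
        u = rng.random(n)
        codes[name] = (u[:, None] > np.cumsum(rows, axis=1)).sum(axis=1)
    out = pd.DataFrame(
        {
            name: np.asarray(net.states(name))[codes[name]]
            for name in net.names
        }
    )
    out.index.name = "nurse_id"
    return out


# ---------------------------------------------------------------------------
# item-level expansion
# ---------------------------------------------------------------------------

# score bands used when drawing a percentile-categorized total: disjoint so
# the sample quartiles can separate the categories exactly
_SENS_BANDS = ((8, 30), (45, 70), (80, 100))
_ANNOY_BANDS = ((5, 25), (35, 60), (70, 95))

_QPCS_BANDS = {
    "total": ((65, 129), (130, 195), (196, 260)),
    "psychosocial": ((28, 55), (56, 84), (85, 112)),
    "communicational": ((13, 25), (26, 39), (40, 52)),
    "physical": ((24, 47), (48, 72), (73, 96)),
}


def _percentile_consistent_scores(
    cats: np.ndarray,
    bands: tuple[tuple[int, int], ...],
    rng: np.random.Generator,
    label: str,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Integer scores whose sample-quartile categorization equals ``cats``.

    At most ``ceil(0.25*(n-1))`` values can lie strictly below the sample's
    25th percentile (linear-interpolation definition), so category vectors
    with a surplus of 'low' or 'high' records cannot be realized exactly;
    the minimal number of surplus records is relabeled to 'moderate'.
    Returns ``(scores, final_categories, n_relabeled)``.
    """
    cats = np.asarray(cats, dtype=object).copy()
    n = len(cats)
    if n < 4:
        raise ValueError("need at least 4 records for percentile categories")
    h25, h75 = 0.25 * (n - 1), 0.75 * (n - 1)
    i0, i1 = math.floor(h25), math.ceil(h25)
    j0, j1 = math.floor(h75), math.ceil(h75)
    l_max = i0 + (1 if i1 != i0 else 0)
    h_max = n - 1 - j0

    relabeled = 0
    for state, cap in (("low", l_max), ("high", h_max)):
        idx = np.flatnonzero(cats == state)
        if len(idx) > cap:
            surplus = rng.choice(idx, size=len(idx) - cap, replace=False)
            cats[surplus] = "moderate"
            relabeled += len(surplus)
    if relabeled:
        warnings.warn(
            f"{label}: {relabeled} record(s) relabeled to 'moderate' — their "
            "category share cannot sit strictly beyond a sample quartile",
            stacklevel=3,
        )

    low_i = np.flatnonzero(cats == "low")
    mid_i = np.flatnonzero(cats == "moderate")
    high_i = np.flatnonzero(cats == "high")
    L, M = len(low_i), len(mid_i)
    (lo_b, mid_b, hi_b) = bands

    scores = np.empty(n, dtype=int)
    scores[low_i] = rng.integers(lo_b[0], lo_b[1] + 1, size=L)
    scores[mid_i] = rng.integers(mid_b[0], mid_b[1] + 1, size=M)
    scores[high_i] = rng.integers(hi_b[0], hi_b[1] + 1, size=len(high_i))

    # pin the quartile anchors: when an anchor index falls inside the
    # moderate block, tie the corresponding extreme moderate values to the
    # band edge so the interpolated quartile equals that edge exactly
    forced_min = i1 - L + 1 if L <= i0 else 0
    forced_max = L + M - j0 if len(high_i) <= n - 1 - j1 else 0
    if forced_min + forced_max > M:
        raise ValueError(
            f"{label}: cohort too small to realize percentile categories"
        )
    if forced_min > 0:
        scores[mid_i[:forced_min]] = mid_b[0]
    if forced_max > 0:
        scores[mid_i[M - forced_max :]] = mid_b[1]
    return scores, cats, relabeled


def _bounded_composition(
    total: int,
    k: int,
    low: int,
    high: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """k integers in [low, high] summing to ``total`` (uniform-ish)."""
    if not k * low <= total <= k * high:
        raise ValueError(f"sum {total} infeasible for {k} items in [{low},{high}]")
    extras = total - k * low
    cap = high - low
    parts = rng.multinomial(extras, np.full(k, 1.0 / k))
    # repair any overflow above the per-item cap
    over = parts - cap
    while (over > 0).any():
        surplus = int(over[over > 0].sum())
        parts = np.minimum(parts, cap)
        room = np.flatnonzero(parts < cap)
        add = rng.choice(room, size=surplus, replace=True)
        np.add.at(parts, add, 1)
        over = parts - cap
    return parts + low


def _qpcs_targets(
    quality_cat: str,
    aspect_cats: dict[str, str],
    rng: np.random.Generator,
    max_attempts: int = 50,
) -> tuple[int, dict[str, int], dict[str, str], bool]:
    """Subscale target sums compatible with the assigned categories.

    Returns ``(total, per-subscale sums, possibly-resampled aspect
    categories, resampled?)``.
    """
    cat_idx = {c: i for i, c in enumerate(QUALITY_STATES)}
    t_lo, t_hi = _QPCS_BANDS["total"][cat_idx[quality_cat]]
    cats = dict(aspect_cats)
    resampled = False
    for _ in range(max_attempts):
        lo = sum(_QPCS_BANDS[a][cat_idx[cats[a]]][0] for a in QUALITY_COLS)
        hi = sum(_QPCS_BANDS[a][cat_idx[cats[a]]][1] for a in QUALITY_COLS)
        lo_t, hi_t = max(t_lo, lo), min(t_hi, hi)
        if lo_t <= hi_t:
            total = int(rng.integers(lo_t, hi_t + 1))
            subs: dict[str, int] = {}
            rem = total
            names = list(QUALITY_COLS)
            for pos, a in enumerate(names):
                a_lo, a_hi = _QPCS_BANDS[a][cat_idx[cats[a]]]
                rest_lo = sum(
                    _QPCS_BANDS[b][cat_idx[cats[b]]][0] for b in names[pos + 1 :]
                )
                rest_hi = sum(
                    _QPCS_BANDS[b][cat_idx[cats[b]]][1] for b in names[pos + 1 :]
                )
                pick_lo, pick_hi = max(a_lo, rem - rest_hi), min(a_hi, rem - rest_lo)
                subs[a] = int(rng.integers(pick_lo, pick_hi + 1))
                rem -= subs[a]
            return total, subs, cats, resampled
        # infeasible joint assignment: resample the aspect categories
        resampled = True
        cats = {
            a: QUALITY_STATES[int(rng.integers(0, 3))] for a in QUALITY_COLS
        }
    raise ValueError(
        f"no feasible subscale assignment for quality={quality_cat!r} "
        f"after {max_attempts} attempts"
    )


def expand_to_items(cohort: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Expand category-level records into item-level responses.

    Emits 21 sensitivity items (0..5), one annoyance VAS value (0..100) and
    65 quality items (1..4) per record such that re-scoring the returned
    table reproduces its category columns (which may have been minimally
    adjusted; see the warnings this function emits).
    """
    need = [c for c in BN_COLUMNS if c != "exposure"]
    absent = [c for c in need if c not in cohort.columns]
    if absent:
        raise ValueError(f"cohort misses category columns: {absent}")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    n = len(out)

    sens_scores, sens_cats, _ = _percentile_consistent_scores(
        out["sensitivity"].to_numpy(), _SENS_BANDS, rng, "sensitivity"
    )
    out["sensitivity"] = sens_cats
    ann_scores, ann_cats, _ = _percentile_consistent_scores(
        out["annoyance"].to_numpy(), _ANNOY_BANDS, rng, "annoyance"
    )
    out["annoyance"] = ann_cats
    out["annoyance_vas"] = ann_scores

    ws = np.empty((n, 21), dtype=int)
    for i, total in enumerate(sens_scores):
        ws[i] = _bounded_composition(int(total), 21, 0, 5, rng)
    for c, col in enumerate(weinstein_columns()):
        out[col] = ws[:, c]

    qp = np.empty((n, 65), dtype=int)
    n_resampled = 0
    records = out[["quality", *QUALITY_COLS]].to_numpy(dtype=object)
    for i, (qcat, *acats) in enumerate(records):
        try:
            total, subs, cats, resampled = _qpcs_targets(
                qcat, dict(zip(QUALITY_COLS, acats)), rng
            )
        except ValueError as e:
            raise ValueError(f"record {out.index[i]}: {e}") from e
        n_resampled += resampled
        for a, idx in QPCS_SUBSCALES.items():
            qp[i, list(idx)] = _bounded_composition(subs[a], len(idx), 1, 4, rng)
        for a in QUALITY_COLS:
            records[i][QUALITY_COLS.index(a) + 1] = cats[a]
    if n_resampled:
        warnings.warn(
            f"{n_resampled} record(s) had infeasible subscale/total category "
            "combinations; subscale categories were resampled",
            stacklevel=2,
        )
    for k, a in enumerate(QUALITY_COLS):
        out[a] = [r[k + 1] for r in records]
    for c, col in enumerate(qpcs_columns()):
        out[col] = qp[:, c]
    return out


# ---------------------------------------------------------------------------
# noise environment
# ---------------------------------------------------------------------------

#: department base sound levels (dBA) used by the simulated hospital; chosen
#: so each exposure category has workstations available
_DEPARTMENTS = (
    ("ICU", 62.5),
    ("Emergency", 58.0),
    ("Surgery", 55.0),
    ("Internal medicine", 52.0),
    ("Blood transfusion", 46.5),
    ("Others", 64.0),
)

#: safe LEP,d intervals per category, strictly inside the boundaries so the
#: energetic mix of two workstations in the same interval stays in category
_SAFE_INTERVALS = {
    "low": (44.0, 49.4),
    "moderate": (50.3, 59.7),
    "high": (60.3, 67.0),
}

N_REPEATS = 10


def simulate_noise_environment(
    cohort: pd.DataFrame,
    n_points: int = 1510,
    seed: int = 0,
    noise_sd: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A measurement grid plus per-nurse workstation assignments.

    Returns ``(grid, stations)``: the grid holds ``n_points * 10`` rows
    (point_id, department, x, y, repeat_index, leq_db) on a 5 m lattice;
    stations assigns each nurse two workstations with durations summing to
    an 8 h shift such that the recomputed LEP,d reproduces the nurse's
    assigned exposure category.
    """
    if "exposure" not in cohort.columns:
        raise ValueError("cohort misses the 'exposure' column")
    from .noise_exposure import build_noise_map, log_mean

    rng = np.random.default_rng(seed)
    n_dep = len(_DEPARTMENTS)
    deps = [_DEPARTMENTS[i % n_dep] for i in range(n_points)]
    ncols = max(1, int(math.isqrt(n_points)))
    rows = []
    for i, (dep, base) in enumerate(deps):
        pid = f"P{i + 1:05d}"
        levels = base + rng.normal(0.0, noise_sd, size=N_REPEATS)
        for r, lv in enumerate(levels):
            rows.append(
                (pid, dep, 5.0 * (i % ncols), 5.0 * (i // ncols), r, float(lv))
            )
    grid = pd.DataFrame(
        rows,
        columns=["point_id", "department", "x", "y", "repeat_index", "leq_db"],
    )

    noise_map = build_noise_map(grid)
    eligible = {
        cat: noise_map[
            noise_map["mapped_level_db"].between(*_SAFE_INTERVALS[cat])
        ]["point_id"].to_numpy()
        for cat in _SAFE_INTERVALS
    }
    for cat, pts in eligible.items():
        if len(pts) == 0:
            raise ValueError(
                f"no grid point available for exposure category {cat!r}; "
                "increase n_points"
            )

    srows = []
    for nurse_id, cat in cohort["exposure"].items():
        pts = rng.choice(eligible[cat], size=2, replace=True)
        d1 = float(rng.uniform(2.0, 6.0))
        srows.append((nurse_id, pts[0], d1))
        srows.append((nurse_id, pts[1], 8.0 - d1))
    stations = pd.DataFrame(srows, columns=["nurse_id", "point_id", "duration_h"])
    return grid, stations


def inject_missing(
    cohort: pd.DataFrame,
    rate: float,
    seed: int = 0,
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Blank cells completely at random at the given expected rate."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("missing rate must be in [0, 1)")
    out = cohort.copy()
    if rate == 0.0:
        return out
    cols = list(columns) if columns is not None else [
        c for c in BN_COLUMNS if c in out.columns
    ]
    rng = np.random.default_rng(seed)
    mask = rng.random((len(out), len(cols))) < rate
    for j, c in enumerate(cols):
        col = out[c].astype(object)
        col[mask[:, j]] = np.nan
        out[c] = col
    return out
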