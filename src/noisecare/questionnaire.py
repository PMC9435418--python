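"""Scoring of the three self-report instruments and item-level imputation.

* Weinstein noise-sensitivity scale: 21 items, 6-point (0..5), total 0..105,
  categorized by the cohort's 25th/75th percentiles.
* Noise annoyance: a single 0..100 visual-analogue value, categorized the
  same way.
* Quality patient care scale: 65 four-point items (1..4) in three subscales
  (psychosocial 28, communicational 13, physical 24), total 65..260,
  categorized by fixed published cut-offs.

Missing item values are imputed by expectation-maximization under a
multivariate-normal working model, then rounded and clipped back into the
item's legal range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WeinsteinResponse",
    "QpcsResponse",
    "score_weinstein",
    "score_qpcs",
    "percentile_categorize",
    "cronbach_alpha",
    "impute_items",
    "score_cohort",
    "QPCS_SUBSCALES",
    "QPCS_CUTOFFS",
    "weinstein_columns",
    "qpcs_columns",
]

N_WEINSTEIN_ITEMS = 21
N_QPCS_ITEMS = 65

#: contiguous default layout of the three subscales within the 65 items
QPCS_SUBSCALES: dict[str, tuple[int, ...]] = {
    "psychosocial": tuple(range(0, 28)),
    "communicational": tuple(range(28, 41)),
    "physical": tuple(range(41, 65)),
}

#: fixed cut-offs: scores below the first bound are undesirable, scores of at
#: least the second bound are desirable, anything between is partly desirable
QPCS_CUTOFFS: dict[str, tuple[int, int]] = {
    "total": (130, 196),
    "psychosocial": (56, 85),
    "communicational": (26, 40),
    "physical": (48, 73),
}

QUALITY_CATEGORIES = ("undesirable", "partly_desirable", "desirable")
PERCENTILE_CATEGORIES = ("low", "moderate", "high")


def weinstein_columns() -> list[str]:
    return [f"ws_{i:02d}" for i in range(1, N_WEINSTEIN_ITEMS + 1)]


def qpcs_columns() -> list[str]:
    return [f"qpc_{i:02d}" for i in range(1, N_QPCS_ITEMS + 1)]


@dataclass(frozen=True)
class WeinsteinResponse:
    """One nurse's 21 noise-sensitivity items (0..5 each, before reversal)."""

    items: tuple[int, ...]
    reverse_key: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(int(v) for v in self.items))
        object.__setattr__(self, "reverse_key", frozenset(self.reverse_key))
        if len(self.items) != N_WEINSTEIN_ITEMS:
            raise ValueError(
                f"expected {N_WEINSTEIN_ITEMS} items, got {len(self.items)}"
            )
        for i, v in enumerate(self.items):
            if not 0 <= v <= 5:
                raise ValueError(f"item {i + 1}: value {v} outside 0..5")
        bad = [i for i in self.reverse_key if not 0 <= i < N_WEINSTEIN_ITEMS]
        if bad:
            raise ValueError(f"reverse_key indices out of range: {bad}")


@dataclass(frozen=True)
class QpcsResponse:
    """One nurse's 65 quality-of-patient-care items (1..4 each)."""

    items: tuple[int, ...]
    subscale_map: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(QPCS_SUBSCALES)
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(int(v) for v in self.items))
        if len(self.items) != N_QPCS_ITEMS:
            raise ValueError(
                f"expected {N_QPCS_ITEMS} items, got {len(self.items)}"
            )
        for i, v in enumerate(self.items):
            if not 1 <= v <= 4:
                raise ValueError(f"item {i + 1}: value {v} outside 1..4")
        sizes = {k: len(v) for k, v in self.subscale_map.items()}
        if sizes != {"psychosocial": 28, "communicational": 13, "physical": 24}:
            raise ValueError(f"subscale sizes must be 28/13/24, got {sizes}")
        covered = sorted(i for v in self.subscale_map.values() for i in v)
        if covered != list(range(N_QPCS_ITEMS)):
            raise ValueError("subscale_map must partition the 65 items")


def score_weinstein(resp: WeinsteinResponse) -> int:
    """Total 0..105 after reverse-keying (reversed value = 5 - raw)."""
    return sum(
        (5 - v) if i in resp.reverse_key else v for i, v in enumerate(resp.items)
    )


def _band_categorize(score: float, cutoffs: tuple[int, int]) -> str:
    lo, hi = cutoffs
    if score < lo:
        return "undesirable"
    if score < hi:
        return "partly_desirable"
    return "desirable"


def score_qpcs(resp: QpcsResponse) -> dict[str, object]:
    """Total, subscale totals, and their band categories."""
    items = np.asarray(resp.items)
    out: dict[str, object] = {}
    total = int(items.sum())
    out["qpcs_total"] = total
    out["quality"] = _band_categorize(total, QPCS_CUTOFFS["total"])
    for name, idx in resp.subscale_map.items():
        sub = int(items[list(idx)].sum())
        out[f"{name}_score"] = sub
        out[name] = _band_categorize(sub, QPCS_CUTOFFS[name])
    return out


def percentile_categorize(scores: Sequence[float]) -> list[str]:
    """Category per score from the sample's own quartiles.

    Percentiles use linear interpolation between order statistics (numpy's
    default, Hyndman–Fan type 7).  Strictly below Q25 -> low, strictly above
    Q75 -> high, ties and everything between -> moderate.
    """
    arr = np.asarray(list(scores), dtype=float)
    if arr.size < 4:
        raise ValueError("percentile categorization needs at least 4 scores")
    q25, q75 = np.percentile(arr, [25.0, 75.0])
    return [
        "low" if s < q25 else ("high" if s > q75 else "moderate") for s in arr
    ]


def cronbach_alpha(item_matrix: np.ndarray | pd.DataFrame) -> float:
    """alpha = k/(k-1) * (1 - sum(item variances)/variance(totals))."""
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 records and >= 2 items")
    if np.isnan(x).any():
        raise ValueError("item matrix contains missing cells")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1).sum()
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero variance of total scores")
    return float(k / (k - 1) * (1.0 - item_var / total_var))


# ---------------------------------------------------------------------------
# EM imputation under a multivariate-normal working model
# ---------------------------------------------------------------------------

def _mvn_em(x: np.ndarray, max_iter: int, tol: float, ridge: float):
    n, p = x.shape
    miss = np.isnan(x)
    filled = np.where(miss, np.nanmean(x, axis=0), x)
    mu = filled.mean(axis=0)
    sigma = np.cov(filled, rowvar=False, ddof=0) + ridge * np.eye(p)

    for _ in range(max_iter):
        ex = np.array(filled)
        exx = np.zeros((p, p))
        patterns: dict[bytes, list[int]] = {}
        for i in range(n):
            patterns.setdefault(miss[i].tobytes(), []).append(i)
        for key, rows in patterns.items():
            m = np.frombuffer(key, dtype=bool)
            if not m.any():
                continue
            o = ~m
            soo = sigma[np.ix_(o, o)] + ridge * np.eye(o.sum())
            smo = sigma[np.ix_(m, o)]
            coef = np.linalg.solve(soo, smo.T).T
            cond_cov = sigma[np.ix_(m, m)] - coef @ smo.T
            for i in rows:
                ex[i, m] = mu[m] + coef @ (x[i, o] - mu[o])
                # second-moment correction from the conditional covariance
                exx[np.ix_(m, m)] += cond_cov
        mu_new = ex.mean(axis=0)
        sigma_new = (ex - mu_new).T @ (ex - mu_new) / n + exx / n
        sigma_new += ridge * np.eye(p)
        shift = max(
            np.abs(mu_new - mu).max(), np.abs(sigma_new - sigma).max()
        )
        mu, sigma, filled = mu_new, sigma_new, ex
        if shift < tol:
            break
    return filled


def impute_items(
    item_matrix: pd.DataFrame,
    *,
    value_range: tuple[float, float] | None = None,
    max_missing_fraction: float = 0.2,
    max_iter: int = 100,
    tol: float = 1e-5,
) -> tuple[pd.DataFrame, list]:
    """Complete an item matrix; returns ``(completed, excluded_index)``.

    Records whose missing fraction exceeds ``max_missing_fraction`` are
    excluded (their index labels returned) rather than imputed.  Imputed
    values are rounded to integers and clipped into ``value_range``
    (inferred from the observed data when not given).
    """
    df = pd.DataFrame(item_matrix).astype(float)
    if df.isna().all(axis=0).any():
        bad = df.columns[df.isna().all(axis=0)].tolist()
        raise ValueError(f"all-missing column(s): {bad}")
    frac = df.isna().mean(axis=1)
    excluded = df.index[frac > max_missing_fraction].tolist()
    if excluded:
        warnings.warn(
            f"{len(excluded)} record(s) above the missing-fraction ceiling "
            f"{max_missing_fraction:.0%} were excluded",
            stacklevel=2,
        )
    kept = df.drop(index=excluded)
    if not kept.isna().any().any():
        return kept.astype(int), excluded
    if value_range is None:
        value_range = (float(np.nanmin(df.values)), float(np.nanmax(df.values)))
    completed = _mvn_em(kept.to_numpy(), max_iter=max_iter, tol=tol, ridge=1e-6)
    completed = np.clip(np.rint(completed), value_range[0], value_range[1])
    return pd.DataFrame(
        completed.astype(int), index=kept.index, columns=kept.columns
    ), excluded


# ---------------------------------------------------------------------------
# cohort-level scoring
# ---------------------------------------------------------------------------

def score_cohort(
    items: pd.DataFrame,
    *,
    reverse_key: frozenset[int] = frozenset(),
    impute: bool = False,
) -> pd.DataFrame:
    """Score an item-level cohort table into totals and categories.

    Expects columns ``ws_01..ws_21``, ``annoyance_vas`` and
    ``qpc_01..qpc_65``; extra columns pass through unchanged.  Sensitivity
    and annoyance categories come from this cohort's own quartiles; quality
    categories from the fixed cut-offs.
    """
    ws_cols, qp_cols = weinstein_columns(), qpcs_columns()
    need = ws_cols + ["annoyance_vas"] + qp_cols
    absent = [c for c in need if c not in items.columns]
    if absent:
        raise ValueError(f"item table misses columns: {absent[:5]} ...")
    df = items.copy()
    if impute:
        ws, excl_ws = impute_items(df[ws_cols], value_range=(0, 5))
        qp, excl_qp = impute_items(df[qp_cols], value_range=(1, 4))
        keep = ws.index.intersection(qp.index)
        df = df.loc[keep]
        df[ws_cols] = ws.loc[keep]
        df[qp_cols] = qp.loc[keep]

    sens = [
        score_weinstein(WeinsteinResponse(tuple(row), reverse_key))
        for row in df[ws_cols].to_numpy(dtype=int)
    ]
    df["sensitivity_score"] = sens
    df["sensitivity"] = percentile_categorize(sens)
    ann = df["annoyance_vas"].astype(float)
    df["annoyance_score"] = ann
    df["annoyance"] = percentile_categorize(ann)
    qpcs = [
        score_qpcs(QpcsResponse(tuple(row)))
        for row in df[qp_cols].to_numpy(dtype=int)
    ]
    for key in (
        "qpcs_total",
        "quality",
        "psychosocial_score",
        "psychosocial",
        "communicational_score",
        "communicational",
        "physical_score",
        "physical",
    ):
        df[key] = [r[key] for r in qpcs]
    return df
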