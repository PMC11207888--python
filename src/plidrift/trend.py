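"""Edge-wise linear trend regression and significance gating.

Each edge's PLI trajectory across epochs is fit with ordinary least
squares, y = b0 + b1 x + e, with x the epoch index.  The coefficient of
determination R^2 = 1 - SS_res/SS_tot and the two-sided test of b1 = 0
via F(1, n-2) (identical to the t-test for simple regression) gate the
edges: an edge is significant when R^2 > r2_min AND p < alpha, both
strict.  No multiple-testing correction is applied across the 1891 edges
(the stated thresholds are the whole gate); the expected family-wise
null pass count is reported alongside so readers can judge the implied
false-positive load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .connectivity import PLINetworkStack
from .montage import Edge

#: R^2 below which a series is treated as exactly constant.
_CONST_TOL = 1e-14


@dataclass(frozen=True)
class ThresholdConfig:
    """Joint significance gate for edge trends (both inequalities strict)."""

    r2_min: float = 0.25
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.r2_min < 1:
            raise ValueError(f"r2_min must be in [0, 1), got {self.r2_min}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass(frozen=True)
class EdgeTrend:
    """OLS fit of one edge's PLI trajectory."""

    edge: Edge
    n_epochs: int
    intercept: float
    slope: float
    r_squared: float
    p_value: float


@dataclass
class EdgeSet:
    """Significant edges of one (subject, band) with their slope signs."""

    band: str
    edges: set[Edge] = field(default_factory=set)
    slopes: dict[Edge, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.edges)

    def slope_sign(self, edge: Edge) -> int:
        return int(np.sign(self.slopes[edge]))


def _ols_line(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float, float]:
    """Closed-form simple OLS: (intercept, slope, R^2, two-sided p)."""
    n = y.size
    xm = x - x.mean()
    ym = y - y.mean()
    sxx = float(xm @ xm)
    sst = float(ym @ ym)
    if sst <= _CONST_TOL * max(1.0, float(y @ y)):
        # degenerate all-constant response: flat line, no explained variance
        return float(y.mean()), 0.0, 0.0, 1.0
    slope = float(xm @ ym) / sxx
    intercept = float(y.mean() - slope * x.mean())
    r2 = slope * slope * sxx / sst
    r2 = min(max(r2, 0.0), 1.0)
    if r2 >= 1.0 - 1e-15:
        return intercept, slope, 1.0, 0.0
    f_stat = r2 * (n - 2) / (1.0 - r2)
    p = float(special.fdtrc(1.0, float(n - 2), f_stat))
    return intercept, slope, r2, p


def fit_edge_trend(
    weights: Sequence[float],
    times: Sequence[float] | None = None,
    edge: Edge = ("a", "b"),
) -> EdgeTrend:
    """Fit one edge's PLI series against epoch index (or given times).

    Requires at least 3 points (one residual degree of freedom).  Times
    default to the epoch indices 0..n-1; any affine recoding of time
    leaves R^2, p and the slope sign unchanged.
    """
    y = np.asarray(weights, dtype=np.float64)
    n = y.size
    if n < 3:
        raise ValueError(f"trend regression needs >= 3 epochs, got {n}")
    if times is None:
        x = np.arange(n, dtype=np.float64)
    else:
        x = np.asarray(times, dtype=np.float64)
        if x.size != n:
            raise ValueError("times and weights must have equal length")
        if np.any(np.diff(x) <= 0):
            raise ValueError("times must be strictly increasing")
    intercept, slope, r2, p = _ols_line(y, x)
    return EdgeTrend(
        edge=edge, n_epochs=n, intercept=intercept, slope=slope,
        r_squared=r2, p_value=p,
    )


def fit_edge_trends_matrix(
    weights: np.ndarray, times: np.ndarray | None = None
) -> pd.DataFrame:
    """Vectorized OLS over an ``n_epochs x n_edges`` matrix.

    Returns a DataFrame with one row per edge (columns ``intercept``,
    ``slope``, ``r2``, ``p``, ``n``); numerically identical to
    :func:`fit_edge_trend` applied column-wise.
    """
    y = np.asarray(weights, dtype=np.float64)
    n, n_edges = y.shape
    if n < 3:
        raise ValueError(f"trend regression needs >= 3 epochs, got {n}")
    x = np.arange(n, dtype=np.float64) if times is None else np.asarray(times, dtype=np.float64)
    xm = x - x.mean()
    ym = y - y.mean(axis=0)
    sxx = float(xm @ xm)
    sst = np.einsum("ij,ij->j", ym, ym)
    sxy = xm @ ym
    const = sst <= _CONST_TOL * np.maximum(1.0, np.einsum("ij,ij->j", y, y))
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(const, 0.0, sxy / sxx)
        r2 = np.where(const, 0.0, slope * slope * sxx / np.where(const, 1.0, sst))
    r2 = np.clip(r2, 0.0, 1.0)
    intercept = y.mean(axis=0) - slope * x.mean()
    exact = r2 >= 1.0 - 1e-15
    with np.errstate(divide="ignore"):
        f_stat = r2 * (n - 2) / (1.0 - r2)
    p = np.ones(n_edges)
    free = ~const
    fit_mask = free & ~exact
    p[fit_mask] = special.fdtrc(1.0, float(n - 2), f_stat[fit_mask])
    p[free & exact] = 0.0
    r2[free & exact] = 1.0
    return pd.DataFrame(
        {"intercept": intercept, "slope": slope, "r2": r2, "p": p, "n": n}
    )


def significant_edges(
    trends: Iterable[EdgeTrend] | pd.DataFrame,
    cfg: ThresholdConfig = ThresholdConfig(),
    band: str = "",
) -> EdgeSet:
    """Edges passing the joint gate r2 > r2_min and p < alpha (strict)."""
    out = EdgeSet(band=band)
    if isinstance(trends, pd.DataFrame):
        hit = trends[(trends["r2"] > cfg.r2_min) & (trends["p"] < cfg.alpha)]
        for row in hit.itertuples():
            e = (row.chan_a, row.chan_b)
            out.edges.add(e)
            out.slopes[e] = float(row.slope)
        return out
    for t in trends:
        if t.r_squared > cfg.r2_min and t.p_value < cfg.alpha:
            out.edges.add(t.edge)
            out.slopes[t.edge] = t.slope
    return out


def expected_null_hits(n_tests: int, n_epochs: int, cfg: ThresholdConfig) -> float:
    """Expected number of null edges passing the joint gate.

    Under i.i.d. Gaussian noise the gate's null pass probability is the
    tail of F(1, n-2) at the R^2 threshold (or alpha if that binds), so
    the family-wise expectation over ``n_tests`` edges follows directly.
    """
    dfd = n_epochs - 2
    f_at_r2 = cfg.r2_min * dfd / (1.0 - cfg.r2_min)
    p_r2_gate = float(special.fdtrc(1.0, float(dfd), f_at_r2))
    return n_tests * min(p_r2_gate, cfg.alpha)


def per_subject_trends(
    stack: PLINetworkStack,
    cfg: ThresholdConfig = ThresholdConfig(),
) -> tuple[pd.DataFrame, EdgeSet]:
    """All edge trends of one (subject, band) stack, plus the gated EdgeSet.

    The returned table has one row per edge with channel labels, fit
    statistics and the significance flag.
    """
    if stack.n_epochs < 3:
        raise ValueError("stack must contain at least 3 epochs")
    table = fit_edge_trends_matrix(stack.weights, times=stack.epoch_indices.astype(float))
    pairs = list(stack.montage.edges())
    table.insert(0, "chan_a", [a for a, _ in pairs])
    table.insert(1, "chan_b", [b for _, b in pairs])
    table.insert(0, "band", stack.band)
    table.insert(0, "subject", stack.subject_id)
    table["significant"] = (table["r2"] > cfg.r2_min) & (table["p"] < cfg.alpha)
    edge_set = significant_edges(table, cfg, band=stack.band)
    return table, edge_set
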