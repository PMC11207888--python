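"""Group-level analysis: individual-network prevalence, shared edges,
global-network averaging and IN/GN overlap statistics.

Two complementary views of the cohort:

* the *individual network* (IN) analysis keeps each subject's gated edge
  set separate and asks which connections recur across subjects
  (prevalence, the >= 40 % shared-edge rule, slope-sign consensus,
  topographic classification);
* the *global network* (GN) averages the PLI weight of every edge across
  subjects per epoch and applies the same trend gate to the averaged
  trajectories.

The overlap statistic ties the two together: per subject,
100 * |IN_s intersect GN| / |GN| — the denominator is the GN edge count,
so every reported percentage times |GN|/100 is an integer edge count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import PLINetworkStack
from .montage import Edge, MontageSpec, classify_edge, unique_nodes
from .trend import EdgeSet, ThresholdConfig, fit_edge_trends_matrix, significant_edges

__all__ = [
    "PrevalenceTable", "SharedEdgeSet", "GlobalNetworkStack", "OverlapSummary",
    "prevalence", "shared_edges", "slope_tally", "classify_edges",
    "unique_nodes", "gn_average", "gn_significant", "in_gn_overlap",
    "band_report",
]


@dataclass
class PrevalenceTable:
    """Per-edge subject counts for one band."""

    band: str
    n_subjects: int
    counts: dict[Edge, int] = field(default_factory=dict)
    contributors: dict[Edge, list[tuple[str, float]]] = field(default_factory=dict)

    def fraction(self, edge: Edge) -> float:
        return self.counts.get(edge, 0) / self.n_subjects

    def max_shared_fraction(self) -> float:
        if not self.counts:
            return 0.0
        return max(self.counts.values()) / self.n_subjects

    def histogram(self, bin_edges: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Histogram of shared-subject fractions over edges with count >= 1.

        Bin edges are explicit (default deciles of the fraction scale).
        """
        if bin_edges is None:
            bin_edges = np.linspace(0.0, 1.0, 11)
        fracs = [c / self.n_subjects for c in self.counts.values()]
        hist, edges = np.histogram(fracs, bins=bin_edges)
        return hist, edges


@dataclass
class SharedEdgeSet:
    """Edges significant in at least ``threshold_fraction`` of subjects.

    ``consensus_signs`` maps each edge to the sign of the mean slope over
    contributing subjects (+1 / -1, or 0 for an exact tie, reported
    separately).
    """

    band: str
    threshold_fraction: float
    edges: set[Edge] = field(default_factory=set)
    consensus_signs: dict[Edge, int] = field(default_factory=dict)
    fractions: dict[Edge, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class GlobalNetworkStack:
    """Edge-wise mean of all subjects' PLI networks, per epoch."""

    band: str
    epoch_indices: np.ndarray
    weights: np.ndarray  # n_epochs x n_edges
    montage: MontageSpec
    n_subjects: int = 0


@dataclass
class OverlapSummary:
    """Per-band IN/GN shared-edge percentages across subjects."""

    band: str
    gn_size: int
    per_subject: dict[str, float | None]
    mean: float | None
    sd: float | None  # population convention (divide by n)
    min: float | None
    max: float | None
    sd_convention: str = "population"


def prevalence(in_sets: dict[str, EdgeSet], n_subjects: int, band: str = "") -> PrevalenceTable:
    """Count, per edge, the subjects in which it is significant."""
    if n_subjects < len(in_sets):
        raise ValueError("n_subjects smaller than the number of provided edge sets")
    bands = {s.band for s in in_sets.values()}
    if band == "" and len(bands) == 1:
        band = bands.pop()
    table = PrevalenceTable(band=band, n_subjects=n_subjects)
    for subject, edge_set in in_sets.items():
        for edge in edge_set.edges:
            table.counts[edge] = table.counts.get(edge, 0) + 1
            table.contributors.setdefault(edge, []).append(
                (subject, edge_set.slopes[edge])
            )
    return table


def shared_edges(prev: PrevalenceTable, threshold_fraction: float = 0.40) -> SharedEdgeSet:
    """Edges present in at least ``threshold_fraction`` of subjects.

    The consensus direction of each shared edge is the sign of the mean
    slope over its contributing subjects; exact ties get sign 0.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError(f"threshold_fraction must be in (0, 1], got {threshold_fraction}")
    out = SharedEdgeSet(band=prev.band, threshold_fraction=threshold_fraction)
    for edge, count in prev.counts.items():
        frac = count / prev.n_subjects
        if frac >= threshold_fraction:
            out.edges.add(edge)
            out.fractions[edge] = frac
            mean_slope = float(np.mean([s for _, s in prev.contributors[edge]]))
            out.consensus_signs[edge] = int(np.sign(mean_slope))
    return out


def slope_tally(shared: SharedEdgeSet) -> tuple[int, int]:
    """Counts of consensus-positive and consensus-negative shared edges.

    Ties (sign 0) are excluded from both tallies, so
    ``n_pos + n_neg + n_tied == len(shared)``.
    """
    signs = list(shared.consensus_signs.values())
    return signs.count(1), signs.count(-1)


def classify_edges(edges: set[Edge]) -> dict[Edge, str]:
    """Topographic class per edge (intra-left / intra-right /
    interhemispheric / midline-involving)."""
    return {e: classify_edge(*e) for e in edges}


def gn_average(stacks: list[PLINetworkStack]) -> GlobalNetworkStack:
    """Edge-wise arithmetic mean across subjects, per epoch, for one band."""
    if not stacks:
        raise ValueError("no stacks to average")
    bands = {s.band for s in stacks}
    if len(bands) != 1:
        raise ValueError(f"gn_average expects a single band, got {bands}")
    grid = stacks[0].epoch_indices
    for s in stacks[1:]:
        if not np.array_equal(s.epoch_indices, grid):
            raise ValueError(
                f"epoch grids are not aligned across subjects "
                f"({s.subject_id} differs); cannot build the global network"
            )
    weights = np.mean([s.weights for s in stacks], axis=0)
    return GlobalNetworkStack(
        band=bands.pop(),
        epoch_indices=grid.copy(),
        weights=weights,
        montage=stacks[0].montage,
        n_subjects=len(stacks),
    )


def gn_significant(
    gn: GlobalNetworkStack, cfg: ThresholdConfig = ThresholdConfig()
) -> EdgeSet:
    """Apply the edge-trend gate to the averaged (global) edge series."""
    if gn.epoch_indices.size < 3:
        raise ValueError("global network needs at least 3 epochs")
    table = fit_edge_trends_matrix(gn.weights, times=gn.epoch_indices.astype(float))
    pairs = list(gn.montage.edges())
    table.insert(0, "chan_a", [a for a, _ in pairs])
    table.insert(1, "chan_b", [b for _, b in pairs])
    return significant_edges(table, cfg, band=gn.band)


def in_gn_overlap(in_sets: dict[str, EdgeSet], gn_set: EdgeSet) -> OverlapSummary:
    """Per-subject percentage of GN edges also present in the subject's IN.

    percent_s = 100 * |IN_s intersect GN| / |GN|.  With an empty GN the
    percentages are undefined and reported as missing.
    """
    gn_size = len(gn_set.edges)
    if gn_size == 0:
        warnings.warn(
            f"global network for band {gn_set.band!r} has no significant "
            "edges; IN/GN overlap is undefined",
            stacklevel=2,
        )
        per = {s: None for s in in_sets}
        return OverlapSummary(
            band=gn_set.band, gn_size=0, per_subject=per,
            mean=None, sd=None, min=None, max=None,
        )
    per: dict[str, float | None] = {}
    for subject, edge_set in in_sets.items():
        per[subject] = 100.0 * len(edge_set.edges & gn_set.edges) / gn_size
    vals = np.asarray([v for v in per.values()], dtype=np.float64)
    return OverlapSummary(
        band=gn_set.band,
        gn_size=gn_size,
        per_subject=per,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=0)),
        min=float(vals.min()),
        max=float(vals.max()),
    )


def band_report(
    band: str,
    in_sets: dict[str, EdgeSet],
    n_subjects: int,
    gn_set: EdgeSet,
    overlap: OverlapSummary,
    shared: SharedEdgeSet,
) -> dict:
    """Assemble the per-band summary tables as a JSON-serializable dict."""
    n_pos, n_neg = slope_tally(shared)
    classes = classify_edges(shared.edges)
    prev = prevalence(in_sets, n_subjects, band=band)
    hist, edges = prev.histogram()
    return {
        "band": band,
        "gn_significant_count": len(gn_set.edges),
        "overlap": {
            "gn_size": overlap.gn_size,
            "mean_percent": overlap.mean,
            "sd_percent": overlap.sd,
            "sd_convention": overlap.sd_convention,
            "min_percent": overlap.min,
            "max_percent": overlap.max,
            "per_subject_percent": overlap.per_subject,
        },
        "shared_edges": {
            "threshold_fraction": shared.threshold_fraction,
            "count": len(shared.edges),
            "unique_nodes": unique_nodes(sorted(shared.edges)),
            "n_positive": n_pos,
            "n_negative": n_neg,
            "n_tied": len(shared.edges) - n_pos - n_neg,
            "edges": [
                {
                    "chan_a": a,
                    "chan_b": b,
                    "fraction": shared.fractions[(a, b)],
                    "consensus_sign": shared.consensus_signs[(a, b)],
                    "topography": classes[(a, b)],
                }
                for a, b in sorted(shared.edges)
            ],
        },
        "prevalence_histogram": {
            "bin_edges_fraction": edges.tolist(),
            "edge_counts": hist.tolist(),
            "max_shared_fraction": prev.max_shared_fraction(),
        },
    }


def shared_edges_frame(shared: SharedEdgeSet) -> pd.DataFrame:
    """Long-format table of a shared edge set (one row per edge)."""
    classes = classify_edges(shared.edges)
    rows = [
        {
            "band": shared.band,
            "chan_a": a,
            "chan_b": b,
            "fraction": shared.fractions[(a, b)],
            "consensus_sign": shared.consensus_signs[(a, b)],
            "topography": classes[(a, b)],
        }
        for a, b in sorted(shared.edges)
    ]
    return pd.DataFrame(rows, columns=["band", "chan_a", "chan_b", "fraction",
                                       "consensus_sign", "topography"])
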