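"""Phase Lag Index (PLI) networks from band-limited epochs.

For a real signal x(t) the analytic signal w(t) = x(t) + i x_H(t)
(Hilbert transform x_H) yields the instantaneous phase phi(t).  For two
channels a, b the PLI is

    PLI_ab = | (1/N) sum_n sign(phi_a(n) - phi_b(n)) |

with phase differences wrapped to (-pi, pi] and sign(0) = 0.  PLI is 0
for couplings whose phase difference is symmetric around zero (including
the zero-lag correlations produced by volume conduction) and 1 for
perfect phase locking at a non-zero lag.

The sign-sum over samples is accumulated as an exact integer, so the
vectorized kernel, the optional numba kernel and a naive per-sample loop
agree bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .montage import MontageSpec
from .preprocess import EpochSet

try:  # fast path for the 1891-pair workloads
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class AnalyticSignal:
    """Instantaneous amplitude and wrapped phase of a real signal."""

    amplitude: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude and phase must have equal length")


def analytic_signal(x: np.ndarray) -> AnalyticSignal:
    """Discrete analytic signal via the frequency-domain construction.

    Returns the instantaneous amplitude A(t) >= 0 and the phase
    phi(t) in (-pi, pi] (four-quadrant arctangent of (x_H, x)).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("analytic_signal expects a 1-D series of length >= 2")
    if not np.any(x):
        raise ValueError("all-zero input: instantaneous phase is undefined")
    z = signal.hilbert(x)
    return AnalyticSignal(amplitude=np.abs(z), phase=np.angle(z))


def wrap_phase(d: np.ndarray) -> np.ndarray:
    """Wrap angles in (-2*pi, 2*pi] to (-pi, pi].

    Single-step wrap: exact (one add/subtract, no modulo rounding) for
    differences of two already-wrapped phases, which is the only input
    the pipeline produces.
    """
    d = np.asarray(d, dtype=np.float64)
    return d - 2.0 * np.pi * (d > np.pi) + 2.0 * np.pi * (d <= -np.pi)


def phase_difference(a: AnalyticSignal, b: AnalyticSignal) -> np.ndarray:
    """Element-wise phase difference phi_a - phi_b wrapped to (-pi, pi]."""
    if a.phase.shape != b.phase.shape:
        raise ValueError(
            f"phase series lengths differ: {a.phase.shape} vs {b.phase.shape}"
        )
    return wrap_phase(a.phase - b.phase)


def pli(phase_diff: np.ndarray) -> float:
    """PLI of a wrapped phase-difference series; sign(0) contributes 0."""
    d = np.asarray(phase_diff, dtype=np.float64)
    if d.size == 0:
        raise ValueError("PLI of an empty phase-difference series is undefined")
    s = np.sign(d).astype(np.int64)
    return abs(int(s.sum())) / d.size


if _HAVE_NUMBA:

    @numba.njit(cache=True)
    def _pli_pairs_kernel(phases: np.ndarray) -> np.ndarray:  # pragma: no cover
        n_ch, n = phases.shape
        out = np.zeros(n_ch * (n_ch - 1) // 2)
        k = 0
        for a in range(n_ch - 1):
            for b in range(a + 1, n_ch):
                s = 0
                for i in range(n):
                    d = phases[a, i] - phases[b, i]
                    if d > np.pi:
                        d -= 2.0 * np.pi
                    elif d <= -np.pi:
                        d += 2.0 * np.pi
                    if d > 0.0:
                        s += 1
                    elif d < 0.0:
                        s -= 1
                out[k] = abs(s) / n
                k += 1
        return out


def _pli_pairs_numpy(phases: np.ndarray) -> np.ndarray:
    n_ch, n = phases.shape
    out = np.empty(n_ch * (n_ch - 1) // 2)
    k = 0
    for a in range(n_ch - 1):
        d = wrap_phase(phases[a] - phases[a + 1:])
        s = np.sign(d).astype(np.int64).sum(axis=-1)
        m = n_ch - a - 1
        out[k:k + m] = np.abs(s) / n
        k += m
    return out


def pairwise_pli(data: np.ndarray, trim_samples: int = 0) -> np.ndarray:
    """Condensed upper-triangular PLI vector for ``channels x samples`` data.

    ``trim_samples`` discards that many samples at each end of the phase
    series before the sign average (filter-edge guard; default 0, as
    multi-minute epochs make boundary effects negligible).
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ValueError("expected a 2-D channels x samples array")
    z = signal.hilbert(data, axis=-1)
    phases = np.angle(z)
    if trim_samples:
        if 2 * trim_samples >= phases.shape[1]:
            raise ValueError("trim_samples removes the whole epoch")
        phases = phases[:, trim_samples:phases.shape[1] - trim_samples]
    phases = np.ascontiguousarray(phases)
    if _HAVE_NUMBA:
        return _pli_pairs_kernel(phases)
    return _pli_pairs_numpy(phases)


@dataclass
class PLINetwork:
    """One weighted undirected network: 62 channels -> 1891 edge weights.

    ``weights`` is the condensed upper-triangular vector in montage edge
    order (see :meth:`MontageSpec.edge_index`).
    """

    subject_id: str
    band: str
    epoch_index: int
    weights: np.ndarray
    montage: MontageSpec

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != (self.montage.n_edges,):
            raise ValueError(
                f"expected {self.montage.n_edges} edge weights, got {self.weights.shape}"
            )
        if np.any((self.weights < 0) | (self.weights > 1)):
            raise ValueError("PLI weights must lie in [0, 1]")

    def weight(self, a: str, b: str) -> float:
        return float(self.weights[self.montage.edge_index(a, b)])

    def dense(self) -> np.ndarray:
        """Symmetric dense adjacency matrix (zero diagonal)."""
        n = self.montage.n_channels
        mat = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        mat[iu] = self.weights
        return mat + mat.T


@dataclass
class PLINetworkStack:
    """Per-(subject, band) sequence of PLI networks across epochs."""

    subject_id: str
    band: str
    epoch_indices: np.ndarray
    weights: np.ndarray  # n_epochs x n_edges
    montage: MontageSpec

    def __post_init__(self) -> None:
        self.epoch_indices = np.asarray(self.epoch_indices, dtype=np.int64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if np.any(np.diff(self.epoch_indices) <= 0):
            raise ValueError("epoch indices must be strictly increasing")
        if self.weights.shape != (self.epoch_indices.size, self.montage.n_edges):
            raise ValueError("weights shape must be (n_epochs, n_edges)")

    @property
    def n_epochs(self) -> int:
        return self.epoch_indices.size

    def network(self, i: int) -> PLINetwork:
        return PLINetwork(
            subject_id=self.subject_id,
            band=self.band,
            epoch_index=int(self.epoch_indices[i]),
            weights=self.weights[i],
            montage=self.montage,
        )


def epoch_network(
    band_epoch: np.ndarray,
    montage: MontageSpec,
    subject_id: str = "subject-0",
    band: str = "",
    epoch_index: int = 0,
    trim_samples: int = 0,
) -> PLINetwork:
    """PLI network over all unordered channel pairs of one band-limited epoch."""
    band_epoch = np.asarray(band_epoch, dtype=np.float64)
    if band_epoch.shape[0] != montage.n_channels:
        raise ValueError(
            f"epoch has {band_epoch.shape[0]} channels but montage defines "
            f"{montage.n_channels}"
        )
    weights = pairwise_pli(band_epoch, trim_samples=trim_samples)
    return PLINetwork(
        subject_id=subject_id,
        band=band,
        epoch_index=epoch_index,
        weights=weights,
        montage=montage,
    )


def build_stacks(
    band_epoch_sets: dict[str, dict[str, EpochSet]],
    montage: MontageSpec,
    trim_samples: int = 0,
) -> list[PLINetworkStack]:
    """PLI network stacks for all (subject, band) pairs.

    ``band_epoch_sets`` maps subject id -> band name -> band-filtered
    :class:`EpochSet`.  Epochs flagged by QC in *any* subject are dropped
    for *all* subjects so the group epoch grids stay aligned (documented
    drop-with-record policy).
    """
    subjects = list(band_epoch_sets)
    if not subjects:
        return []
    bands = list(band_epoch_sets[subjects[0]])
    n_epochs = {
        s: band_epoch_sets[s][b].n_epochs for s in subjects for b in bands
    }
    if len(set(n_epochs.values())) != 1:
        raise ValueError(f"subjects have mismatched epoch grids: {n_epochs}")
    joint_mask = np.ones(next(iter(n_epochs.values())), dtype=bool)
    for s in subjects:
        for b in bands:
            joint_mask &= band_epoch_sets[s][b].retained_mask
    kept = np.flatnonzero(joint_mask)
    stacks = []
    for s in subjects:
        for b in bands:
            es = band_epoch_sets[s][b]
            weights = np.stack(
                [pairwise_pli(es.epochs[i], trim_samples=trim_samples) for i in kept]
            )
            stacks.append(
                PLINetworkStack(
                    subject_id=s,
                    band=b,
                    epoch_indices=kept,
                    weights=weights,
                    montage=montage,
                )
            )
    return stacks
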