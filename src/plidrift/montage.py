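"""Electrode montage handling for 10-20 / 10-10 style channel labels.

The analysis operates on a fixed scalp montage: a set of network channels
(62 by default) plus reference channels (the mastoids) that are excluded
from the connectivity space.  Hemisphere membership is encoded in the
label suffix following the 10-20 convention: an odd final digit marks the
left hemisphere, an even digit the right, and a trailing ``z`` the
midline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence, Tuple

Edge = Tuple[str, str]

#: 62 scalp electrodes of a 64-channel 10-10 cap, mastoids excluded.
DEFAULT_LABELS: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2",
)

DEFAULT_REFERENCES: tuple[str, ...] = ("M1", "M2")


def hemisphere(label: str) -> str:
    """Classify a 10-20 style label as ``left``, ``right`` or ``midline``.

    Raises
    ------
    ValueError
        If the label does not end in a digit or ``z``.
    """
    suffix = label[-1].lower()
    if suffix == "z":
        return "midline"
    if suffix.isdigit():
        return "left" if int(suffix) % 2 == 1 else "right"
    raise ValueError(
        f"channel label {label!r} does not follow the 10-20 suffix "
        "convention (odd digit = left, even digit = right, 'z' = midline)"
    )


@dataclass(frozen=True)
class MontageSpec:
    """Ordered channel labels defining the network space.

    Parameters
    ----------
    labels : sequence of str
        Network channel names in montage order.
    reference_labels : sequence of str
        Reference channels (mastoids) present in raw recordings but
        excluded from the connectivity space.
    """

    labels: tuple[str, ...]
    reference_labels: tuple[str, ...] = ()
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        refs = tuple(self.reference_labels)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "reference_labels", refs)
        all_labels = labels + refs
        if len(set(all_labels)) != len(all_labels):
            raise ValueError("montage labels must be unique")
        for lab in labels:
            hemisphere(lab)  # raises on malformed labels
        object.__setattr__(self, "_index", {lab: i for i, lab in enumerate(labels)})

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        n = self.n_channels
        return n * (n - 1) // 2

    @property
    def all_labels(self) -> tuple[str, ...]:
        """Network labels followed by reference labels (raw-recording order)."""
        return self.labels + self.reference_labels

    def index(self, label: str) -> int:
        return self._index[label]

    def canonical_edge(self, a: str, b: str) -> Edge:
        """Return the unordered pair ``(a, b)`` in montage order."""
        if a == b:
            raise ValueError(f"self-edge ({a!r}, {a!r}) is not a valid connection")
        ia, ib = self._index[a], self._index[b]
        return (a, b) if ia < ib else (b, a)

    def edges(self) -> Iterator[Edge]:
        """All unordered channel pairs in upper-triangular order."""
        labs = self.labels
        for i in range(len(labs) - 1):
            for j in range(i + 1, len(labs)):
                yield (labs[i], labs[j])

    def edge_index(self, a: str, b: str) -> int:
        """Position of edge ``(a, b)`` in the condensed upper-triangular order."""
        i, j = sorted((self._index[a], self._index[b]))
        if i == j:
            raise ValueError("self-edge has no index")
        n = self.n_channels
        # offset of row i in the condensed ordering, then column offset
        return i * n - i * (i + 1) // 2 + (j - i - 1)


def make_default_montage() -> MontageSpec:
    """The default 62-channel network montage with mastoid references."""
    return MontageSpec(labels=DEFAULT_LABELS, reference_labels=DEFAULT_REFERENCES)


def classify_edge(a: str, b: str) -> str:
    """Topographic class of an edge.

    Any midline endpoint makes the edge ``midline-involving``; otherwise
    two left endpoints are ``intra-left``, two right are ``intra-right``
    and one of each is ``interhemispheric``.  The four classes partition
    every edge set.
    """
    ha, hb = hemisphere(a), hemisphere(b)
    if "midline" in (ha, hb):
        return "midline-involving"
    if ha == hb:
        return f"intra-{ha}"
    return "interhemispheric"


def unique_nodes(edges: Sequence[Edge]) -> int:
    """Number of distinct channel labels among the edge endpoints."""
    nodes: set[str] = set()
    for a, b in edges:
        nodes.add(a)
        nodes.add(b)
    return len(nodes)
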