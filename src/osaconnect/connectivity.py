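"""Channel-to-channel functional connectivity and graph summaries.

Connectivity is the Pearson correlation between channels' absolute
wavelet-packet coefficients within a band, computed per epoch and averaged
over epochs.  Edges are the strictly positive correlations; the degree of a
node is the number of incident edges.  Graphs are exported in the BrainNet
Viewer plain-text ``.node`` / ``.edge`` formats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ConstantInputError",
    "pearson",
    "ConnectivityMatrix",
    "band_connectivity",
    "BrainGraph",
    "positive_edges",
    "GroupBandSummary",
    "group_min_max",
    "export_brainnet",
    "read_brainnet",
    "DEFAULT_NODE_COORDS",
]


class ConstantInputError(ValueError):
    """Pearson correlation is undefined for a constant vector."""


#: approximate MNI coordinates of the 10-20 scalp positions used by the four
#: ISRUC derivations (frontal F3/F4, occipital O1/O2); configurable.
DEFAULT_NODE_COORDS: dict[str, tuple[float, float, float]] = {
    "F3": (-37.0, 48.0, 32.0),
    "F4": (38.0, 48.0, 32.0),
    "O1": (-27.0, -100.0, 13.0),
    "O2": (24.0, -100.0, 14.0),
}


def node_coordinates(label: str, table: Mapping[str, tuple] | None = None) -> tuple:
    """Coordinate lookup tolerant of derivation suffixes ("F4-A1" -> "F4")."""
    table = DEFAULT_NODE_COORDS if table is None else table
    key = label.split("-")[0].split("_")[0].strip().upper()
    if label in table:
        return tuple(table[label])
    if key in table:
        return tuple(table[key])
    raise KeyError(f"no coordinates for node {label!r}")


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation coefficient of two equal-length vectors.

    Raises :class:`ConstantInputError` for a constant input rather than
    silently returning 0 or NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    xm = x - x.mean()
    ym = y - y.mean()
    ssx = float(np.sum(xm**2))
    ssy = float(np.sum(ym**2))
    if ssx == 0.0 or ssy == 0.0:
        raise ConstantInputError("correlation undefined for a constant vector")
    r = float(np.dot(xm, ym) / np.sqrt(ssx * ssy))
    return min(1.0, max(-1.0, r))


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel Pearson matrix for one band."""

    band: str
    channel_labels: list[str]
    r: np.ndarray
    n_obs: int

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.channel_labels)
        if self.r.shape != (k, k):
            raise ValueError(f"r must be {k}x{k}")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("r must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-12):
            raise ValueError("diagonal of r must be 1")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValueError("entries of r must lie in [-1, 1]")

    def offdiag(self) -> np.ndarray:
        """Upper-triangle off-diagonal entries, row-major order."""
        iu = np.triu_indices(len(self.channel_labels), k=1)
        return self.r[iu]

    def mean_positive_r(self) -> float:
        """Mean of strictly positive off-diagonal correlations (0 if none)."""
        off = self.offdiag()
        pos = off[off > 0]
        return float(pos.mean()) if pos.size else 0.0


def band_connectivity(
    epoch_features: Sequence[Sequence[np.ndarray]],
    channel_labels: Sequence[str],
    band: str,
    fisher_z: bool = False,
) -> ConnectivityMatrix:
    """Per-band connectivity from per-epoch absolute-coefficient vectors.

    Parameters
    ----------
    epoch_features : sequence over epochs of sequences over channels of
        equal-length 1-D feature vectors (the band's ``abs_coeffs``).
    fisher_z : average correlations on the Fisher z scale instead of the
        plain mean.

    Epochs containing a constant channel vector are excluded with a warning;
    an error is raised only if every epoch is excluded.
    """
    k = len(channel_labels)
    mats = []
    for e, chans in enumerate(epoch_features):
        if len(chans) != k:
            raise ValueError(f"epoch {e}: expected {k} channels, got {len(chans)}")
        lengths = {len(c) for c in chans}
        if len(lengths) != 1:
            raise ValueError(f"epoch {e}: channels have unequal feature lengths")
        m = np.eye(k)
        try:
            for i in range(k):
                for j in range(i + 1, k):
                    m[i, j] = m[j, i] = pearson(chans[i], chans[j])
        except ConstantInputError:
            warnings.warn(
                f"epoch {e} excluded: constant feature vector", stacklevel=2
            )
            continue
        mats.append(m)
    if not mats:
        raise ValueError("all epochs excluded (constant feature vectors)")
    stack = np.stack(mats)
    if fisher_z:
        z = np.arctanh(np.clip(stack, -1 + 1e-15, 1 - 1e-15))
        r = np.tanh(z.mean(axis=0))
        np.fill_diagonal(r, 1.0)
    else:
        r = stack.mean(axis=0)
    n_obs = len(epoch_features[0][0]) * len(mats)
    return ConnectivityMatrix(
        band=band, channel_labels=list(channel_labels), r=r, n_obs=n_obs
    )


@dataclass
class BrainGraph:
    """Undirected weighted graph over the EEG channels.

    ``edges`` are (i, j, weight) with i < j; ``degrees[i]`` is the number of
    edges incident to node i.
    """

    labels: list[str]
    edges: list[tuple[int, int, float]]
    coords: list[tuple[float, float, float]] | None = None
    degrees: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.labels)
        for i, j, _ in self.edges:
            if not (0 <= i < j < n):
                raise ValueError(f"invalid edge ({i}, {j}) for {n} nodes")
        deg = np.zeros(n, dtype=int)
        for i, j, _ in self.edges:
            deg[i] += 1
            deg[j] += 1
        if self.degrees is None:
            self.degrees = deg
        elif not np.array_equal(np.asarray(self.degrees), deg):
            raise ValueError("degrees inconsistent with edge list")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def weight_matrix(self) -> np.ndarray:
        w = np.zeros((len(self.labels), len(self.labels)))
        for i, j, v in self.edges:
            w[i, j] = w[j, i] = v
        return w

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for i, lbl in enumerate(self.labels):
            g.add_node(lbl, index=i)
        for i, j, v in self.edges:
            g.add_edge(self.labels[i], self.labels[j], weight=v)
        return g


def positive_edges(
    m: ConnectivityMatrix,
    threshold: float = 0.0,
    coords: Mapping[str, tuple] | None = None,
) -> BrainGraph:
    """Graph of channel pairs whose correlation exceeds ``threshold``.

    The default threshold 0 keeps exactly the strictly positive
    correlations; self-loops are never emitted.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    k = len(m.channel_labels)
    edges = [
        (i, j, float(m.r[i, j]))
        for i in range(k)
        for j in range(i + 1, k)
        if m.r[i, j] > threshold
    ]
    try:
        xyz = [node_coordinates(lbl, coords) for lbl in m.channel_labels]
    except KeyError:
        xyz = None
    return BrainGraph(labels=list(m.channel_labels), edges=edges, coords=xyz)


@dataclass
class GroupBandSummary:
    """Extremes of positive correlation for one band within one group."""

    band: str
    group: str
    min_pos_r: float | None
    max_pos_r: float | None

    @property
    def empty(self) -> bool:
        return self.min_pos_r is None

    def __post_init__(self) -> None:
        if self.min_pos_r is not None:
            if not (0 < self.min_pos_r <= self.max_pos_r <= 1):
                raise ValueError(
                    f"need 0 < min <= max <= 1, got "
                    f"({self.min_pos_r}, {self.max_pos_r})"
                )


def group_min_max(
    matrices: Sequence[ConnectivityMatrix], group: str = "UNKNOWN"
) -> GroupBandSummary:
    """Min and max positive off-diagonal correlation across subjects.

    A summary with no positive entries at all is flagged empty rather than
    raising.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    band = matrices[0].band
    if any(m.band != band for m in matrices):
        raise ValueError("matrices mix bands")
    pos = np.concatenate([m.offdiag() for m in matrices])
    pos = pos[pos > 0]
    if pos.size == 0:
        return GroupBandSummary(band=band, group=group, min_pos_r=None, max_pos_r=None)
    return GroupBandSummary(
        band=band, group=group,
        min_pos_r=float(pos.min()), max_pos_r=float(pos.max()),
    )


# ---------------------------------------------------------------------------
# BrainNet Viewer export
# ---------------------------------------------------------------------------

def export_brainnet(
    g: BrainGraph, node_path: str | Path, edge_path: str | Path
) -> tuple[Path, Path]:
    """Write BrainNet Viewer ``.node`` and ``.edge`` files.

    ``.node``: one row per node, 6 whitespace-separated columns
    (x, y, z, color, size = degree, label).  ``.edge``: the full symmetric
    weight matrix, zero where no edge.
    """
    if g.coords is None:
        raise ValueError(
            f"missing coordinates for nodes {g.labels}; supply a coordinate table"
        )
    node_path, edge_path = Path(node_path), Path(edge_path)
    with open(node_path, "w") as fh:
        for (x, y, z), deg, lbl in zip(g.coords, g.degrees, g.labels):
            fh.write(f"{x:g}\t{y:g}\t{z:g}\t1\t{deg:d}\t{lbl}\n")
    w = g.weight_matrix()
    with open(edge_path, "w") as fh:
        for row in w:
            fh.write("\t".join(format(v, ".17g") for v in row) + "\n")
    return node_path, edge_path


def read_brainnet(node_path: str | Path, edge_path: str | Path) -> BrainGraph:
    """Parse BrainNet Viewer files back into a :class:`BrainGraph`."""
    labels, coords, sizes = [], [], []
    with open(node_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(f"malformed .node row: {line!r}")
            x, y, z, _color, size, lbl = parts
            labels.append(lbl)
            coords.append((float(x), float(y), float(z)))
            sizes.append(int(size))
    w = np.loadtxt(edge_path, ndmin=2)
    if w.shape != (len(labels), len(labels)):
        raise ValueError(".edge matrix size does not match .node rows")
    edges = [
        (i, j, float(w[i, j]))
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
        if w[i, j] != 0.0
    ]
    g = BrainGraph(labels=labels, edges=edges, coords=coords)
    if not np.array_equal(g.degrees, np.array(sizes)):
        raise ValueError(".node sizes disagree with edge-derived degrees")
    return g
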