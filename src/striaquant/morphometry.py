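"""Dendritic-tree morphometry: SWC I/O, reconstruction eligibility,
per-neuron and per-dendrite metrics, Sholl analysis and dendrograms.

A reconstructed neuron is a rooted tree: the root node is the soma
(modeled as a point) and every maximal subtree hanging off a root child
is one dendrite. Metrics reported per neuron:

* total dendritic length (sum of Euclidean edge lengths, μm);
* number of primary dendrites (children of the soma);
* per dendrite: length, number of end points, and a ``complete`` flag —
  true when all of that dendrite's end points lie within the section,
  the condition under which single-dendrite values are trustworthy;
* path distance from soma to each end point (arc length along the tree,
  always ≥ the straight-line distance);
* terminal length percentage — the share of total dendritic length in
  terminal branches, a terminal branch running from the most distal
  branch point (or the soma, for an unbranched dendrite) to an end
  point.

A neuron is eligible for reconstruction when at least half of its end
points lie within the section (z in [0, thickness]); single-dendrite
metrics additionally require the dendrite itself to be complete. This
two-tier criterion mirrors standard camera-lucida charting practice.

Sholl analysis counts crossings of the dendritic polylines, projected
onto the section plane (x, y), with soma-centered circles (default
radii 10, 20, 30 μm). A segment crossing a circle twice contributes 2;
tangency contributes 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_SHOLL_RADII = (10.0, 20.0, 30.0)


class SWCParseError(ValueError):
    """Malformed SWC content; message carries the 1-based line number."""


@dataclass(frozen=True)
class ReconstructedNeuron:
    """Rooted dendritic tree in topological (parent-before-child) order.

    ``coords`` is (n, 3) in μm, ``parents`` holds the index of each
    node's parent (−1 for the root, which is node 0). ``radii`` and
    ``node_types`` preserve the SWC columns but no metric uses them.
    """

    coords: np.ndarray
    parents: np.ndarray
    radii: np.ndarray | None = None
    node_types: np.ndarray | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        parents = np.asarray(self.parents, dtype=int)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "parents", parents)
        n = len(coords)
        if n == 0:
            raise ValueError("empty neuron")
        if len(parents) != n:
            raise ValueError("coords and parents length mismatch")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        roots = np.flatnonzero(parents == -1)
        if len(roots) != 1 or roots[0] != 0:
            raise ValueError("exactly one root required, at index 0")
        if np.any(parents[1:] >= np.arange(1, n)) or np.any(parents[1:] < 0):
            raise ValueError("parents must precede children (topological order)")
        radii = self.radii
        if radii is None:
            radii = np.ones(n)
        object.__setattr__(self, "radii", np.asarray(radii, dtype=float))
        types = self.node_types
        if types is None:
            types = np.full(n, 3, dtype=int)
            types[0] = 1
        object.__setattr__(self, "node_types", np.asarray(types, dtype=int))

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def n_children(self) -> np.ndarray:
        counts = np.zeros(self.n_nodes, dtype=int)
        np.add.at(counts, self.parents[1:], 1)
        return counts

    @property
    def edge_lengths(self) -> np.ndarray:
        """Length of the edge ending at each node (0 for the root)."""
        out = np.zeros(self.n_nodes)
        out[1:] = np.linalg.norm(
            self.coords[1:] - self.coords[self.parents[1:]], axis=1
        )
        return out

    def endpoints(self) -> np.ndarray:
        """Indices of end points: non-root nodes with no children."""
        return np.flatnonzero((self.n_children == 0) & (np.arange(self.n_nodes) != 0))

    def endpoints_in_section(self, thickness_um: float) -> np.ndarray:
        z = self.coords[self.endpoints(), 2]
        return (z >= 0) & (z <= thickness_um)

    def primary_dendrite_roots(self) -> np.ndarray:
        return np.flatnonzero(self.parents == 0)

    def dendrite_of(self) -> np.ndarray:
        """For each node, the index of the root child whose subtree it
        belongs to (−1 for the soma)."""
        dend = np.full(self.n_nodes, -1, dtype=int)
        for i in range(1, self.n_nodes):
            p = self.parents[i]
            dend[i] = i if p == 0 else dend[p]
        return dend


# ---------------------------------------------------------------------------
# SWC I/O


def read_swc(source: str | Path | IO[str]) -> ReconstructedNeuron:
    """Parse an SWC reconstruction (7 whitespace-separated columns:
    id, type, x, y, z, radius, parent; '#' comments; parent −1 = root).

    Node ids may appear in any order; the tree is re-indexed into
    topological order with consecutive ids. Orphan parents, multiple
    roots and cyclic parent chains raise :class:`SWCParseError` naming
    the offending line.
    """
    if isinstance(source, Path):
        stream: IO[str] = StringIO(source.read_text())
    elif isinstance(source, str):
        if "\n" in source:  # raw SWC content
            stream = StringIO(source)
        else:
            stream = StringIO(Path(source).read_text())
    else:
        stream = source

    rows: dict[int, tuple[int, int, float, float, float, float, int]] = {}
    line_of: dict[int, int] = {}
    for lineno, line in enumerate(stream, start=1):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        parts = body.split()
        if len(parts) != 7:
            raise SWCParseError(f"line {lineno}: expected 7 columns, got {len(parts)}")
        try:
            nid = int(parts[0])
            ntype = int(parts[1])
            x, y, z, r = (float(v) for v in parts[2:6])
            parent = int(parts[6])
        except ValueError as exc:
            raise SWCParseError(f"line {lineno}: {exc}") from exc
        if nid in rows:
            raise SWCParseError(f"line {lineno}: duplicate node id {nid}")
        rows[nid] = (lineno, ntype, x, y, z, r, parent)
        line_of[nid] = lineno
    if not rows:
        raise SWCParseError("line 0: no nodes")

    roots = [nid for nid, row in rows.items() if row[6] == -1]
    if len(roots) == 0:
        raise SWCParseError(
            f"line {min(line_of.values())}: no root node (parent -1)"
        )
    if len(roots) > 1:
        raise SWCParseError(
            f"line {line_of[roots[1]]}: multiple roots (ids {roots})"
        )
    for nid, row in rows.items():
        parent = row[6]
        if parent != -1 and parent not in rows:
            raise SWCParseError(
                f"line {row[0]}: parent {parent} of node {nid} does not exist"
            )

    # children adjacency; DFS from the root gives topological order and
    # leaves cyclic components unvisited
    children: dict[int, list[int]] = {nid: [] for nid in rows}
    for nid, row in rows.items():
        if row[6] != -1:
            children[row[6]].append(nid)
    order: list[int] = []
    stack = [roots[0]]
    seen = set()
    while stack:
        nid = stack.pop()
        if nid in seen:  # pragma: no cover - defensive, cycles caught below
            continue
        seen.add(nid)
        order.append(nid)
        stack.extend(reversed(children[nid]))
    if len(order) != len(rows):
        orphan = min(set(rows) - seen, key=lambda nid: line_of[nid])
        raise SWCParseError(
            f"line {line_of[orphan]}: node {orphan} unreachable from root "
            "(cyclic or detached parent chain)"
        )

    # keep declaration order when it is already topological, so that
    # write → read round-trips node for node; otherwise use DFS order
    file_order = sorted(rows, key=lambda nid: line_of[nid])
    pos = {nid: i for i, nid in enumerate(file_order)}
    if all(
        rows[nid][6] == -1 or pos[rows[nid][6]] < pos[nid] for nid in file_order
    ):
        order = file_order

    new_index = {nid: i for i, nid in enumerate(order)}
    coords = np.array([[rows[nid][2], rows[nid][3], rows[nid][4]] for nid in order])
    radii = np.array([rows[nid][5] for nid in order])
    types = np.array([rows[nid][1] for nid in order])
    parents = np.array(
        [-1 if rows[nid][6] == -1 else new_index[rows[nid][6]] for nid in order]
    )
    return ReconstructedNeuron(coords, parents, radii, types)


def write_swc(neuron: ReconstructedNeuron, target: str | Path | IO[str]) -> None:
    """Write a neuron in SWC format with ids numbered consecutively from 1."""
    lines = []
    for i in range(neuron.n_nodes):
        parent = -1 if neuron.parents[i] == -1 else int(neuron.parents[i]) + 1
        x, y, z = neuron.coords[i]
        lines.append(
            f"{i + 1} {int(neuron.node_types[i])} {x:.6f} {y:.6f} {z:.6f} "
            f"{neuron.radii[i]:.6f} {parent}"
        )
    text = "\n".join(lines) + "\n"
    if isinstance(target, (str, Path)):
        Path(target).write_text(text)
    else:
        target.write(text)


# ---------------------------------------------------------------------------
# Eligibility and metrics


def reconstruction_eligible(
    neuron: ReconstructedNeuron, section_thickness_um: float
) -> bool:
    """True when at least 50% of the neuron's end points lie within the
    section (end-point z within [0, thickness])."""
    eps = neuron.endpoints()
    if len(eps) == 0:
        raise ValueError("neuron has no end points")
    inside = neuron.endpoints_in_section(section_thickness_um)
    return float(np.mean(inside)) >= 0.5


@dataclass(frozen=True)
class DendriteMetrics:
    length_um: float
    n_endpoints: int
    complete: bool


@dataclass(frozen=True)
class MorphometrySummary:
    total_length_um: float
    n_primary_dendrites: int
    per_dendrite: tuple[DendriteMetrics, ...]
    path_distances_um: np.ndarray
    terminal_length_pct: float

    @property
    def n_endpoints(self) -> int:
        return len(self.path_distances_um)


def tree_metrics(
    neuron: ReconstructedNeuron, section_thickness_um: float | None = None
) -> MorphometrySummary:
    """All per-neuron and per-dendrite metrics of one reconstruction.

    When ``section_thickness_um`` is given, each dendrite's ``complete``
    flag reflects whether all of its end points lie within the section;
    without it every dendrite is treated as complete.
    """
    edge_len = neuron.edge_lengths
    total = float(edge_len.sum())
    n_children = neuron.n_children
    primaries = neuron.primary_dendrite_roots()
    endpoints = neuron.endpoints()
    dend_of = neuron.dendrite_of()

    # path distance: cumulative edge length from the root, in topological order
    cumdist = np.zeros(neuron.n_nodes)
    for i in range(1, neuron.n_nodes):
        cumdist[i] = cumdist[neuron.parents[i]] + edge_len[i]
    path_distances = cumdist[endpoints]

    if section_thickness_um is None:
        ep_inside = np.ones(len(endpoints), dtype=bool)
    else:
        ep_inside = neuron.endpoints_in_section(section_thickness_um)

    per_dendrite = []
    for d in primaries:
        mask = dend_of == d
        length = float(edge_len[mask].sum())
        ep_mask = dend_of[endpoints] == d
        per_dendrite.append(
            DendriteMetrics(
                length_um=length,
                n_endpoints=int(ep_mask.sum()),
                complete=bool(np.all(ep_inside[ep_mask])),
            )
        )

    # terminal branches: walk from each end point toward the soma until a
    # branch point (>= 2 children); the soma itself never terminates a branch
    # early, so an unbranched dendrite is terminal over its full length
    terminal = 0.0
    for e in endpoints:
        cur = int(e)
        while True:
            terminal += edge_len[cur]
            cur = int(neuron.parents[cur])
            if cur == 0 or n_children[cur] >= 2:
                break
    terminal_pct = 100.0 * terminal / total if total > 0 else 0.0

    return MorphometrySummary(
        total_length_um=total,
        n_primary_dendrites=len(primaries),
        per_dendrite=tuple(per_dendrite),
        path_distances_um=path_distances,
        terminal_length_pct=terminal_pct,
    )


# ---------------------------------------------------------------------------
# Sholl analysis


def _segment_circle_crossings(
    p: np.ndarray, q: np.ndarray, center: np.ndarray, r: float, eps: float = 1e-12
) -> int:
    """Crossings of segment p→q with the circle |x − center| = r, counting
    parameter values t in [0, 1) so a polyline vertex on the circle is
    attributed to exactly one segment. Tangency contributes 0."""
    d = q - p
    f = p - center
    a = float(d @ d)
    if a <= eps:
        return 0
    b = 2.0 * float(f @ d)
    c = float(f @ f) - r * r
    disc = b * b - 4 * a * c
    scale = max(a, abs(b), abs(c), 1.0)
    if disc <= eps * scale * scale:
        return 0  # no intersection, or tangency
    sq = np.sqrt(disc)
    count = 0
    for t in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
        if -eps <= t < 1.0 - eps:
            count += 1
    return count


@dataclass(frozen=True)
class ShollProfile:
    radii_um: tuple[float, ...]
    intersections: tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"radius_um": self.radii_um, "intersections": self.intersections}
        )


def sholl(
    neuron: ReconstructedNeuron,
    radii_um: Sequence[float] = DEFAULT_SHOLL_RADII,
) -> ShollProfile:
    """Count crossings of the dendritic arbor with soma-centered circles,
    in the 2D projection onto the section plane."""
    radii = tuple(float(r) for r in radii_um)
    if any(r <= 0 for r in radii) or any(
        b <= a for a, b in zip(radii, radii[1:])
    ):
        raise ValueError("radii must be strictly increasing and positive")
    center = neuron.coords[0, :2]
    xy = neuron.coords[:, :2]
    counts = []
    for r in radii:
        n = 0
        for i in range(1, neuron.n_nodes):
            n += _segment_circle_crossings(xy[neuron.parents[i]], xy[i], center, r)
        counts.append(n)
    return ShollProfile(radii_um=radii, intersections=tuple(counts))


def sholl_brute_force(
    neuron: ReconstructedNeuron,
    radii_um: Sequence[float] = DEFAULT_SHOLL_RADII,
    step_um: float = 0.01,
) -> ShollProfile:
    """Independent crossing counter by dense polyline resampling: each
    edge is sampled every ``step_um`` and sign changes of (distance − r)
    are counted. Slow; intended as a cross-check for :func:`sholl`."""
    radii = tuple(float(r) for r in radii_um)
    center = neuron.coords[0, :2]
    counts = [0 for _ in radii]
    for i in range(1, neuron.n_nodes):
        p = neuron.coords[neuron.parents[i], :2]
        q = neuron.coords[i, :2]
        seg_len = float(np.linalg.norm(q - p))
        n_steps = max(int(np.ceil(seg_len / step_um)), 1)
        # half-open [0, 1): the end vertex belongs to the next segment
        t = np.arange(n_steps) / n_steps
        pts = p + t[:, None] * (q - p)
        dist = np.linalg.norm(pts - center, axis=1)
        # append the segment end to close the last interval
        dist = np.append(dist, np.linalg.norm(q - center))
        for j, r in enumerate(radii):
            sign = np.sign(dist - r)
            nz = sign != 0
            s = sign[nz]
            counts[j] += int(np.sum(s[:-1] * s[1:] < 0))
    return ShollProfile(radii_um=radii, intersections=tuple(counts))


# ---------------------------------------------------------------------------
# Dendrogram


@dataclass
class DendrogramNode:
    """One bar of a dendrogram: a branch (chain between branch points)
    with its summed length and the branches continuing from its tip."""

    length_um: float
    children: list["DendrogramNode"] = field(default_factory=list)

    def total_length(self) -> float:
        return self.length_um + sum(c.total_length() for c in self.children)


def dendrogram(neuron: ReconstructedNeuron) -> DendrogramNode:
    """Collapse the tree into a branch-order diagram: each node is a
    chain between branch points with its total length; topology is
    preserved and the bar lengths sum to the total dendritic length."""
    edge_len = neuron.edge_lengths
    n_children = neuron.n_children
    children: list[list[int]] = [[] for _ in range(neuron.n_nodes)]
    for i in range(1, neuron.n_nodes):
        children[neuron.parents[i]].append(i)

    def build_branch(start: int) -> DendrogramNode:
        length = edge_len[start]
        cur = start
        while n_children[cur] == 1:
            cur = children[cur][0]
            length += edge_len[cur]
        return DendrogramNode(
            length_um=float(length),
            children=[build_branch(c) for c in children[cur]],
        )

    root = DendrogramNode(length_um=0.0)
    root.children = [build_branch(c) for c in children[0]]
    return root


def metrics_frame(
    neurons: Iterable[tuple[dict, ReconstructedNeuron]],
    section_thickness_um: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy per-neuron and per-dendrite tables.

    ``neurons`` yields (labels, neuron) pairs; labels (e.g. group, case,
    section, neuron id) are copied onto every output row.
    """
    neuron_rows, dendrite_rows = [], []
    for labels, neuron in neurons:
        m = tree_metrics(neuron, section_thickness_um)
        neuron_rows.append(
            {
                **labels,
                "total_length_um": m.total_length_um,
                "n_primary_dendrites": m.n_primary_dendrites,
                "n_endpoints": m.n_endpoints,
                "mean_path_distance_um": float(np.mean(m.path_distances_um))
                if m.n_endpoints
                else np.nan,
                "terminal_length_pct": m.terminal_length_pct,
            }
        )
        for j, d in enumerate(m.per_dendrite):
            dendrite_rows.append(
                {
                    **labels,
                    "dendrite": j,
                    "length_um": d.length_um,
                    "n_endpoints": d.n_endpoints,
                    "complete": d.complete,
                }
            )
    return pd.DataFrame(neuron_rows), pd.DataFrame(dendrite_rows)
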