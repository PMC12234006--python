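"""Water-wire connectivity via weighted shortest paths over water oxygens.

Every water oxygen in a frame is a graph node; an edge between two
oxygens carries a weight that is close to 1 when they sit within
hydrogen-bonding distance (r0 ≈ 3 Å, the typical O–O separation of
hydrogen-bonded waters) and grows rapidly beyond it. A virtual SOURCE
node attaches to the donor-side atoms (e.g. the two carboxylate oxygens
of the catalytic glutamate) and a virtual SINK to a destination point
(e.g. the midpoint of two backbone CAs at the channel mouth). The summed
weight S of the minimum-weight SOURCE→SINK route measures how well the
wire is connected — small S means a continuous, hoppable water chain —
and log(S) separates 'leak' (wet) from dry frames bimodally.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .frames import Frame, pair_distance

__all__ = [
    "EdgeWeightParams",
    "WaterGraph",
    "PathResult",
    "edge_weight",
    "EDGE_WEIGHT_FORMS",
    "build_graph",
    "shortest_path",
    "wire_profile",
    "wet_fraction",
    "DEFAULT_WATER_QUERY",
]

DEFAULT_WATER_QUERY = "water"

SOURCE = "SOURCE"
SINK = "SINK"


def _exp_barrier(r: np.ndarray, r0: float, alpha: float) -> np.ndarray:
    return 1.0 + np.exp(alpha * (np.asarray(r, dtype=float) - r0))


#: registry of edge-weight functional forms, all mapping (r, r0, alpha) -> w
EDGE_WEIGHT_FORMS: dict[str, Callable] = {
    "exp_barrier": _exp_barrier,
}


@dataclass
class EdgeWeightParams:
    """Edge-weight function parameters.

    r0 is the hydrogen-bond O–O distance (Å) below which an edge costs ≈ 1;
    alpha (1/Å) sets how fast the cost grows past r0; r_cut (Å) caps which
    pairs get an edge at all.
    """

    r0: float = 3.0
    alpha: float = 5.0
    r_cut: float = 8.0
    use_pbc: bool = True
    form: str = "exp_barrier"

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError(f"r0 must be > 0 (got {self.r0})")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0 (got {self.alpha})")
        if self.r_cut <= self.r0:
            raise ValueError(f"r_cut must exceed r0 (got r_cut={self.r_cut}, r0={self.r0})")
        if self.form not in EDGE_WEIGHT_FORMS:
            raise ValueError(
                f"unknown edge-weight form {self.form!r}; available: {sorted(EDGE_WEIGHT_FORMS)}"
            )


def edge_weight(r, params: EdgeWeightParams | None = None):
    """Weight of a graph edge between oxygens separated by r (Å).

    Default form: w(r) = 1 + exp(alpha·(r − r0)); ≈ 1 for hydrogen-bonded
    pairs, steeply increasing past r0. Monotone non-decreasing in r.
    """
    params = params or EdgeWeightParams()
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise ValueError(f"distance must be ≥ 0 (got {r})")
    w = EDGE_WEIGHT_FORMS[params.form](r_arr, params.r0, params.alpha)
    return float(w) if np.isscalar(r) or r_arr.ndim == 0 else w


@dataclass
class WaterGraph:
    """Undirected weighted graph over water oxygens plus SOURCE and SINK.

    ``nodes`` are atom indices (ints) plus the two virtual labels;
    ``edges`` maps a node to a list of (neighbor, weight) pairs.
    """

    adjacency: dict = field(default_factory=dict)
    frame_index: int = 0

    def add_edge(self, a, b, w: float) -> None:
        self.adjacency.setdefault(a, []).append((b, float(w)))
        self.adjacency.setdefault(b, []).append((a, float(w)))

    @property
    def nodes(self) -> list:
        return list(self.adjacency)

    @property
    def n_edges(self) -> int:
        return sum(len(v) for v in self.adjacency.values()) // 2

    def validate(self) -> None:
        for virtual in (SOURCE, SINK):
            if virtual not in self.adjacency:
                raise ValueError(f"malformed water graph: missing virtual node {virtual}")


@dataclass
class PathResult:
    """Shortest-route result for one frame: S, log S and the route taken."""

    S: float
    logS: float
    route: list
    frame_index: int
    connected: bool


def build_graph(
    frame: Frame,
    source_selection: str,
    sink_selection: str,
    params: EdgeWeightParams | None = None,
    water_query: str = DEFAULT_WATER_QUERY,
) -> WaterGraph:
    """Build the weighted water graph of one frame.

    SOURCE connects to every water with the weight of its minimum distance
    to any source atom; SINK connects with the distance to the sink
    midpoint (two sink atoms) or position (one atom). Water–water pairs
    within r_cut get an edge. A direct SOURCE–SINK edge is included when
    within r_cut, and always added as a fallback if the graph would
    otherwise leave SOURCE and SINK disconnected, so S stays finite.
    """
    params = params or EdgeWeightParams()
    src_idx = frame.select(source_selection)
    if len(src_idx) == 0:
        raise ValueError(f"source selection matched no atoms: {source_selection!r}")
    snk_idx = frame.select(sink_selection)
    if len(snk_idx) not in (1, 2):
        raise ValueError(
            f"sink selection must resolve to 1 or 2 atoms (midpoint), got "
            f"{len(snk_idx)}: {sink_selection!r}"
        )
    box = frame.box if (params.use_pbc and frame.box is not None) else None

    src_pos = frame.positions[src_idx]
    sink_point = frame.positions[snk_idx].mean(axis=0)
    waters = frame.select(water_query)

    graph = WaterGraph(frame_index=frame.index)
    graph.adjacency.setdefault(SOURCE, [])
    graph.adjacency.setdefault(SINK, [])

    def dist(a: np.ndarray, b: np.ndarray) -> float:
        return pair_distance(a, b, box)

    for wi in waters:
        pos = frame.positions[wi]
        d_src = min(dist(sp, pos) for sp in src_pos)
        if d_src <= params.r_cut:
            graph.add_edge(SOURCE, int(wi), edge_weight(d_src, params))
        d_snk = dist(pos, sink_point)
        if d_snk <= params.r_cut:
            graph.add_edge(int(wi), SINK, edge_weight(d_snk, params))
    for i, wi in enumerate(waters):
        for wj in waters[i + 1 :]:
            d = dist(frame.positions[wi], frame.positions[wj])
            if d <= params.r_cut:
                graph.add_edge(int(wi), int(wj), edge_weight(d, params))

    d_direct = min(dist(sp, sink_point) for sp in src_pos)
    if d_direct <= params.r_cut:
        graph.add_edge(SOURCE, SINK, edge_weight(d_direct, params))
    elif not _reachable(graph, SOURCE, SINK):
        # guaranteed fallback: keep S finite and frames comparable
        graph.add_edge(SOURCE, SINK, edge_weight(d_direct, params))
    return graph


def _reachable(graph: WaterGraph, a, b) -> bool:
    seen = {a}
    stack = [a]
    while stack:
        node = stack.pop()
        if node == b:
            return True
        for nbr, _ in graph.adjacency.get(node, []):
            if nbr not in seen:
                seen.add(nbr)
                stack.append(nbr)
    return False


def _node_key(node) -> tuple:
    # SOURCE sorts first, SINK last, waters by index: deterministic ties
    if node == SOURCE:
        return (0, 0)
    if node == SINK:
        return (2, 0)
    return (1, int(node))


def shortest_path(graph: WaterGraph) -> PathResult:
    """Minimum-total-weight SOURCE→SINK route (Dijkstra, positive weights).

    Ties between equal-weight routes are broken toward the
    lexicographically smallest node sequence. Returns S = +inf with
    ``connected=False`` if no route exists (cannot occur when the direct
    SOURCE–SINK fallback edge is in place).
    """
    graph.validate()
    dist: dict = {}
    best_route: dict = {}
    heap = [(0.0, (_node_key(SOURCE),), SOURCE, (SOURCE,))]
    while heap:
        d, _, node, route = heapq.heappop(heap)
        if node in dist:
            continue
        dist[node] = d
        best_route[node] = route
        if node == SINK:
            break
        for nbr, w in graph.adjacency.get(node, []):
            if nbr not in dist:
                nroute = route + (nbr,)
                heapq.heappush(
                    heap, (d + w, tuple(_node_key(n) for n in nroute), nbr, nroute)
                )
    if SINK not in dist:
        return PathResult(
            S=np.inf, logS=np.inf, route=[], frame_index=graph.frame_index, connected=False
        )
    s = dist[SINK]
    return PathResult(
        S=s,
        logS=float(np.log(s)),
        route=list(best_route[SINK]),
        frame_index=graph.frame_index,
        connected=True,
    )


def wire_profile(
    frames: Sequence[Frame],
    source_selection: str,
    sink_selection: str,
    params: EdgeWeightParams | None = None,
    water_query: str = DEFAULT_WATER_QUERY,
    bin_width: float = 0.25,
):
    """Per-frame shortest-path table, log S histogram and summary.

    Returns ``(table, histogram, summary)``: a DataFrame with one row per
    frame (frame, S, logS, route length), a (bin_edges, counts) histogram
    of log S (natural log, stated in the summary), and a summary dict with
    min/max/mean log S and the best-/worst-hydrated frame indices (lowest
    and highest S).
    """
    if len(frames) == 0:
        raise ValueError("wire_profile requires at least one frame")
    results = []
    for frame in frames:
        try:
            graph = build_graph(frame, source_selection, sink_selection, params, water_query)
            results.append(shortest_path(graph))
        except ValueError as exc:
            raise ValueError(f"frame {frame.index}: {exc}") from exc
    table = pd.DataFrame(
        {
            "frame": [r.frame_index for r in results],
            "S": [r.S for r in results],
            "logS": [r.logS for r in results],
            "route_length": [len(r.route) for r in results],
        }
    )
    logs = table["logS"].to_numpy()
    lo, hi = float(logs.min()), float(logs.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width))) if hi > lo else 1
    counts, edges = np.histogram(logs, bins=n_bins, range=(lo, hi) if hi > lo else (lo - bin_width / 2, lo + bin_width / 2))
    summary = {
        "n_frames": len(frames),
        "logS_min": lo,
        "logS_max": hi,
        "logS_mean": float(logs.mean()),
        "best_hydrated_frame": int(table.loc[table["S"].idxmin(), "frame"]),
        "worst_hydrated_frame": int(table.loc[table["S"].idxmax(), "frame"]),
        "log_base": "natural",
    }
    return table, (edges, counts), summary


def wet_fraction(logS_series: Sequence[float], threshold: float) -> float:
    """Fraction of frames whose log S falls below a wet/dry threshold."""
    arr = np.asarray(logS_series, dtype=float)
    if arr.size == 0:
        raise ValueError("logS series is empty")
    return float(np.mean(arr < threshold))
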