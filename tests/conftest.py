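import numpy as np
import pytest

from protongate import synth
from protongate.frames import Frame


@pytest.fixture
def chain_frame():
    """Jitter-free 5-water chain at hydrogen-bond spacing."""
    return synth.make_water_chain(5, 2.8, 0.0)


@pytest.fixture
def two_residue_frame():
    """Two small 'side chains' with hydrogens at known distances."""
    names = ["HB1", "HB2", "HB3", "HD1", "HD2", "HD3", "HD4", "CA", "CA"]
    resnames = ["ALA"] * 3 + ["ILE"] * 4 + ["ALA", "ILE"]
    resids = [61] * 3 + [68] * 4 + [61, 68]
    subunits = ["A"] * 3 + ["B"] * 4 + ["A", "B"]
    positions = np.array(
        [
            [0.0, 0.0, 0.0],
            [0.5, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [3.5, 0.0, 0.0],   # closest pair: 2.5 Å from HB3
            [4.0, 0.0, 0.0],
            [4.5, 0.0, 0.0],
            [5.0, 0.0, 0.0],
            [0.0, 2.0, 0.0],
            [4.0, 2.0, 0.0],
        ]
    )
    return Frame(
        names=names, resnames=resnames, resids=resids, subunits=subunits, positions=positions
    )


def random_water_frame(rng, n_waters, box_side=10.0):
    """Random water positions plus anchors, for shortest-path oracle tests."""
    names = ["OE1", "OE2"] + ["O"] * n_waters + ["CA", "CA"]
    resnames = ["GLU", "GLU"] + ["HOH"] * n_waters + ["ARG", "GLY"]
    resids = [14, 14] + list(range(101, 101 + n_waters)) + [102, 57]
    subunits = ["B", "B"] + ["W"] * n_waters + ["A", "A"]
    waters = rng.uniform(0.0, box_side, size=(n_waters, 3))
    positions = np.vstack(
        [
            [0.0, 0.0, 0.0],
            [-1.1, 1.9, 0.0],
            waters,
            [box_side, 3.0, 0.0],
            [box_side, -3.0, 0.0],
        ]
    )
    return Frame(
        names=names, resnames=resnames, resids=resids, subunits=subunits, positions=positions
    )


def enumerate_min_path(graph, source="SOURCE", sink="SINK"):
    """Independent exhaustive-enumeration oracle for the minimum-weight route.

    Depth-first enumeration of all simple routes with branch-and-bound
    pruning (prune when the partial sum already exceeds the incumbent);
    exact because every surviving complete route is evaluated in full.
    """
    best = [np.inf, None]

    def dfs(node, visited, total, route):
        if total >= best[0]:
            return
        if node == sink:
            best[0] = total
            best[1] = route
            return
        for nbr, w in sorted(graph.adjacency.get(node, []), key=lambda e: e[1]):
            if nbr not in visited:
                dfs(nbr, visited | {nbr}, total + w, route + (nbr,))

    dfs(source, {source}, 0.0, (source,))
    return best[0], best[1]
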