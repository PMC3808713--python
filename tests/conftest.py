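"""Shared fixtures: tiny hand-checkable networks and an independent oracle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from npa.diffexpr import ContrastData
from npa.network import TwoLayerNetwork, parse_network

TOY_ROWS = [
    {"source": "b1", "relation": "increases", "target": "g1", "layer": "evidence"},
    {"source": "b1", "relation": "decreases", "target": "g2", "layer": "evidence"},
    {"source": "b2", "relation": "increases", "target": "g3", "layer": "evidence"},
    {"source": "b1", "relation": "increases", "target": "b2", "layer": "backbone"},
]


@pytest.fixture
def toy_rows() -> pd.DataFrame:
    return pd.DataFrame(TOY_ROWS)


@pytest.fixture
def toy_net(toy_rows) -> TwoLayerNetwork:
    """Two backbone nodes, three genes, one positive backbone edge."""
    return parse_network(toy_rows, name="toy")


@pytest.fixture
def toy_contrast() -> ContrastData:
    return ContrastData(
        genes=("g1", "g2", "g3"),
        log2fc=np.array([1.0, -1.0, 0.5]),
        var_log2fc=np.full(3, 0.01),
        label="toy",
    )


@pytest.fixture
def star_net() -> TwoLayerNetwork:
    """Single backbone node with one up- and one down-regulated gene."""
    return TwoLayerNetwork(
        backbone_nodes=("b1",),
        gene_nodes=("g1", "g2"),
        backbone_edges=(),
        evidence_edges=(("b1", "g1", 1), ("b1", "g2", -1)),
        name="star",
    )


def oracle_fit(net: TwoLayerNetwork, beta_map: dict[str, float]) -> dict[str, float]:
    """Independent energy minimizer: least squares on the residual matrix.

    Builds one residual row per energy term — (f_x - s f_y) for backbone
    edges, (s f_b - beta_g) for evidence edges with a measured gene — and
    solves with QR-based ``numpy.linalg.lstsq``, a different route from the
    normal-equations solve used by the implementation.
    """
    nodes = sorted(net.backbone_nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    rows, rhs = [], []
    for x, y, s in net.backbone_edges:
        row = np.zeros(len(nodes))
        row[idx[x]] += 1.0
        row[idx[y]] -= s
        rows.append(row)
        rhs.append(0.0)
    for b, g, s in net.evidence_edges:
        if g not in beta_map:
            continue
        row = np.zeros(len(nodes))
        row[idx[b]] = s
        rows.append(row)
        rhs.append(beta_map[g])
    sol = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)[0]
    return dict(zip(nodes, sol))


def random_small_network(rng: np.random.Generator) -> TwoLayerNetwork:
    """A random identifiable network with <= 6 backbone nodes, <= 12 genes."""
    nb = int(rng.integers(2, 7))
    ng = int(rng.integers(nb, 13))
    nodes = [f"b{i}" for i in range(nb)]
    genes = [f"g{i}" for i in range(ng)]
    backbone = []
    for i in range(1, nb):  # random spanning tree keeps one component
        j = int(rng.integers(i))
        sign = -1 if rng.random() < 0.3 else 1
        backbone.append((nodes[j], nodes[i], sign))
    for _ in range(int(rng.integers(0, nb))):
        i, j = rng.choice(nb, size=2, replace=False)
        pair = (nodes[int(i)], nodes[int(j)])
        if not any((s, t) == pair for s, t, _ in backbone):
            backbone.append((*pair, -1 if rng.random() < 0.3 else 1))
    evidence = []
    for k, g in enumerate(genes):
        b = nodes[k % nb]
        evidence.append((b, g, -1 if rng.random() < 0.3 else 1))
    return TwoLayerNetwork(
        backbone_nodes=tuple(nodes),
        gene_nodes=tuple(genes),
        backbone_edges=tuple(backbone),
        evidence_edges=tuple(evidence),
        name="random-small",
    )
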