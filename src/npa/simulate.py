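"""Synthetic two-layer networks and expression data with known ground truth.

The generator emulates the study design the scoring method targets: a
signed backbone graph whose node activities change between two conditions,
genes each regulated by one or more backbone nodes with signs, and
two-group replicate log2 expression with Gaussian noise. Because the true
backbone-activity vector is known (including the all-zero null), every
pipeline stage — fit, score, CI, permutation tests, profile comparison —
can be tested end to end without any external dataset.

The generative rule mirrors the least-squares geometry of the fit: a
gene's expected log2 fold change is the *mean* of its regulators' signed
activities, so the noiseless contrast equals the signed truth exactly (the
fit itself is additionally shrunk toward backbone smoothness).

Defaults describe the reference simulation used throughout the test suite:
a 10-node backbone with 200 genes (about 20 genes per backbone node),
standard-normal true activities, log2 noise sd 0.1, and 3 replicates per
group (a typical exposed-vs-control triplicate design).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .core import NPAResult, BackboneProfile, score_network
from .diffexpr import ContrastData, ExpressionMatrix, compute_contrast
from .network import TwoLayerNetwork, validate_network

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "RecoveryReport",
    "generate_network",
    "simulate_contrast",
    "recovery_experiment",
    "toy_xenobiotic_network",
]

TrueValues = Union[str, Sequence[float], np.ndarray]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    ``true_backbone_values`` accepts an explicit vector, ``"zero"`` (the
    null), or ``"gaussian(sd)"`` for i.i.d. Normal(0, sd^2) activities.
    ``genes_per_backbone`` sets ``n_genes`` when the latter is omitted;
    ``extra_parent_rate`` is the Poisson mean of additional regulators per
    gene beyond the guaranteed one.
    """

    n_backbone: int = 10
    genes_per_backbone: int = 20
    n_genes: int | None = None
    backbone_edge_prob: float = 0.25
    negative_sign_prob: float = 0.3
    extra_parent_rate: float = 0.3
    true_backbone_values: TrueValues = "gaussian(1)"
    noise_sd: float = 0.1
    n_replicates_per_group: int = 3
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_backbone < 2:
            raise ValueError("n_backbone must be >= 2")
        if self.genes_per_backbone < 1:
            raise ValueError("genes_per_backbone must be >= 1")
        if self.n_genes is None:
            object.__setattr__(self, "n_genes", self.n_backbone * self.genes_per_backbone)
        if self.n_genes < self.n_backbone:
            raise ValueError("n_genes must be >= n_backbone")
        for name in ("backbone_edge_prob", "negative_sign_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_replicates_per_group < 2:
            raise ValueError("n_replicates_per_group must be >= 2")

    def resolve_true_values(self, rng: np.random.Generator) -> np.ndarray:
        spec = self.true_backbone_values
        if isinstance(spec, str):
            if spec == "zero":
                return np.zeros(self.n_backbone)
            m = re.fullmatch(r"gaussian\(([0-9.eE+-]+)\)", spec.strip())
            if m:
                return rng.normal(0.0, float(m.group(1)), size=self.n_backbone)
            raise ValueError(
                f"unknown true_backbone_values spec {spec!r} "
                "(expected 'zero', 'gaussian(sd)', or a vector)"
            )
        vec = np.asarray(spec, dtype=float)
        if vec.shape != (self.n_backbone,):
            raise ValueError(
                f"true_backbone_values has length {vec.size}, expected {self.n_backbone}"
            )
        return vec


@dataclass(frozen=True)
class SimulationTruth:
    """One simulated dataset together with everything that generated it."""

    network: TwoLayerNetwork
    true_backbone_values: np.ndarray
    expected_gene_fc: np.ndarray  # aligned with network.gene_nodes
    expression: ExpressionMatrix
    contrast: ContrastData
    config: SimulationConfig


@dataclass(frozen=True)
class RecoveryReport:
    """Outcome of a full generate -> simulate -> fit -> score run."""

    pearson_true_fitted: float
    profile: BackboneProfile
    npa: NPAResult
    truth: SimulationTruth
    config: SimulationConfig


def _node_names(prefix: str, n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def generate_network(config: SimulationConfig) -> TwoLayerNetwork:
    """Sample a connected, identifiable two-layer network.

    The backbone is a directed Erdos-Renyi graph over unordered pairs
    (random orientation) patched to connectivity with spanning edges; edge
    signs are -1 with probability ``negative_sign_prob``. Every backbone
    node receives at least one gene, every gene at least one regulator;
    extra regulators are Poisson. Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    nb, ng = config.n_backbone, config.n_genes
    nodes = _node_names("B", nb)
    genes = _node_names("G", ng)

    def draw_sign() -> int:
        return -1 if rng.random() < config.negative_sign_prob else 1

    edges: dict[tuple[str, str], int] = {}
    for i in range(nb):
        for j in range(i + 1, nb):
            if rng.random() < config.backbone_edge_prob:
                src, tgt = (nodes[i], nodes[j]) if rng.random() < 0.5 else (nodes[j], nodes[i])
                edges[(src, tgt)] = draw_sign()

    # patch to a single connected component (union-find over unordered edges)
    parent = list(range(nb))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    index = {n: i for i, n in enumerate(nodes)}
    for (s, t) in edges:
        ri, rj = find(index[s]), find(index[t])
        if ri != rj:
            parent[ri] = rj
    roots = sorted({find(i) for i in range(nb)})
    while len(roots) > 1:
        a = int(rng.choice(np.flatnonzero([find(i) == roots[0] for i in range(nb)])))
        b = int(rng.choice(np.flatnonzero([find(i) == roots[1] for i in range(nb)])))
        src, tgt = (nodes[a], nodes[b]) if rng.random() < 0.5 else (nodes[b], nodes[a])
        edges[(src, tgt)] = draw_sign()
        parent[find(a)] = find(b)
        roots = sorted({find(i) for i in range(nb)})

    # evidence layer: first nb genes pin one gene per backbone node, the
    # rest draw a random primary regulator; extra regulators ~ Poisson
    evidence: dict[tuple[str, str], int] = {}
    for gi, gene in enumerate(genes):
        primary = nodes[gi] if gi < nb else nodes[int(rng.integers(nb))]
        evidence[(primary, gene)] = draw_sign()
        for _ in range(int(rng.poisson(config.extra_parent_rate))):
            extra = nodes[int(rng.integers(nb))]
            if (extra, gene) not in evidence:
                evidence[(extra, gene)] = draw_sign()

    net = TwoLayerNetwork(
        backbone_nodes=tuple(nodes),
        gene_nodes=tuple(genes),
        backbone_edges=tuple((s, t, sign) for (s, t), sign in edges.items()),
        evidence_edges=tuple((b, g, sign) for (b, g), sign in evidence.items()),
        name=f"synthetic-{config.seed}",
    )
    report = validate_network(net)
    assert report.is_valid, "generator produced an unidentifiable network"
    return net


def expected_gene_fold_changes(
    net: TwoLayerNetwork, true_values: dict[str, float]
) -> np.ndarray:
    """Expected log2 fold change per gene: mean of signed parent activities."""
    out = np.empty(len(net.gene_nodes))
    for i, gene in enumerate(net.gene_nodes):
        terms = [s * true_values[b] for b, s in net.evidence_for_gene(gene)]
        out[i] = float(np.mean(terms))
    return out


def simulate_contrast(
    net: TwoLayerNetwork,
    true_values: Union[Sequence[float], np.ndarray],
    noise_sd: float,
    n_replicates: int = 3,
    seed: int | None = None,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.0,
    config: SimulationConfig | None = None,
    label: str = "simulated",
) -> SimulationTruth:
    """Two-group replicate expression for a network with known truth.

    Per gene: control samples are ``baseline + noise`` and treated samples
    ``baseline + expected_fc + noise`` with i.i.d. Normal(0, noise_sd^2)
    noise on the log2 scale; baselines are drawn once per gene from
    Normal(baseline_mean, baseline_sd^2), microarray-like, and cancel in
    the contrast. The contrast is computed with
    :func:`npa.diffexpr.compute_contrast`.
    """
    f_star = np.asarray(true_values, dtype=float)
    if f_star.shape != (len(net.backbone_nodes),):
        raise ValueError(
            f"true value vector has length {f_star.size}, expected "
            f"{len(net.backbone_nodes)} (one per backbone node)"
        )
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    rng = np.random.default_rng(seed)
    fmap = dict(zip(net.backbone_nodes, f_star))
    expected_fc = expected_gene_fold_changes(net, fmap)

    ng = len(net.gene_nodes)
    baseline = rng.normal(baseline_mean, baseline_sd, size=ng)
    control = baseline[:, None] + rng.normal(0.0, noise_sd, size=(ng, n_replicates))
    treated = (
        baseline[:, None]
        + expected_fc[:, None]
        + rng.normal(0.0, noise_sd, size=(ng, n_replicates))
    )
    samples = [f"ctrl_{i+1}" for i in range(n_replicates)] + [
        f"trt_{i+1}" for i in range(n_replicates)
    ]
    values = pd.DataFrame(
        np.hstack([control, treated]), index=list(net.gene_nodes), columns=samples
    )
    groups = pd.Series(
        ["control"] * n_replicates + ["treated"] * n_replicates, index=samples
    )
    expr = ExpressionMatrix(values=values, groups=groups)
    contrast = compute_contrast(expr, label=label)
    if config is None:
        config = SimulationConfig(
            n_backbone=len(net.backbone_nodes),
            genes_per_backbone=max(1, ng // len(net.backbone_nodes)),
            n_genes=ng,
            true_backbone_values=tuple(f_star),
            noise_sd=noise_sd,
            n_replicates_per_group=n_replicates,
            seed=seed if seed is not None else 0,
        )
    return SimulationTruth(
        network=net,
        true_backbone_values=f_star,
        expected_gene_fc=expected_fc,
        expression=expr,
        contrast=contrast,
        config=config,
    )


def simulate_study(config: SimulationConfig, label: str = "simulated") -> SimulationTruth:
    """Generate a network and a dataset from one config (single seed)."""
    net = generate_network(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).generate_state(1)[0] % (2**31))
    f_star = config.resolve_true_values(rng)
    data_seed = int(np.random.SeedSequence(config.seed + 1).generate_state(1)[0] % (2**31))
    return simulate_contrast(
        net,
        f_star,
        noise_sd=config.noise_sd,
        n_replicates=config.n_replicates_per_group,
        seed=data_seed,
        baseline_mean=config.baseline_mean,
        baseline_sd=config.baseline_sd,
        config=config,
        label=label,
    )


def recovery_experiment(
    config: SimulationConfig | None = None, n_perm: int = 200
) -> RecoveryReport:
    """Generate, simulate, fit, score; report recovery of the known truth.

    ``pearson_true_fitted`` is the Pearson correlation between the true and
    fitted backbone values (NaN for a constant truth such as the all-zero
    null, where no correlation is defined).
    """
    if config is None:
        config = SimulationConfig(seed=7)
    truth = simulate_study(config)
    perm_seed = int(np.random.SeedSequence(config.seed + 2).generate_state(1)[0] % (2**31))
    profile, npa = score_network(
        truth.network, truth.contrast, n_perm=n_perm, seed=perm_seed
    )
    f_star = truth.true_backbone_values
    f_hat = profile.values
    if np.ptp(f_star) == 0 or np.ptp(f_hat) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(f_star, f_hat)[0, 1])
    return RecoveryReport(
        pearson_true_fitted=r, profile=profile, npa=npa, truth=truth, config=config
    )


def toy_xenobiotic_network(n_genes: int = 150) -> TwoLayerNetwork:
    """A small fixed two-layer network shaped like a xenobiotic-response model.

    Synthetic stand-in for a curated model: a receptor-activity hub
    (``taof_AHR``-like) driving phase I/II enzyme activities, a repressor
    node attached by negative edges, and ``n_genes`` genes assigned
    deterministically (seeded) to the 12 backbone nodes. Byte-identical on
    every call; used in docs and golden tests.
    """
    backbone = [
        "chem_stress",
        "taof_AHR",
        "AHRR_activity",
        "taof_NFE2L2",
        "CYP1A1_act",
        "CYP1B1_act",
        "phaseII_conj",
        "phaseIII_transport",
        "oxidative_stress",
        "taof_NR1I2",
        "CYP3A_act",
        "GST_act",
    ]
    backbone_edges = [
        ("chem_stress", "taof_AHR", 1),
        ("chem_stress", "taof_NFE2L2", 1),
        ("chem_stress", "taof_NR1I2", 1),
        ("taof_AHR", "CYP1A1_act", 1),
        ("taof_AHR", "CYP1B1_act", 1),
        ("taof_AHR", "AHRR_activity", 1),
        ("AHRR_activity", "taof_AHR", -1),
        ("AHRR_activity", "CYP1A1_act", -1),
        ("taof_NFE2L2", "phaseII_conj", 1),
        ("taof_NFE2L2", "GST_act", 1),
        ("taof_NR1I2", "CYP3A_act", 1),
        ("taof_NR1I2", "phaseIII_transport", 1),
        ("CYP1A1_act", "oxidative_stress", 1),
        ("phaseII_conj", "oxidative_stress", -1),
    ]
    rng = np.random.default_rng(20130512)
    genes = _node_names("TG", n_genes)
    evidence: dict[tuple[str, str], int] = {}
    for gi, gene in enumerate(genes):
        primary = backbone[gi % len(backbone)]
        sign = -1 if rng.random() < 0.25 else 1
        evidence[(primary, gene)] = sign
        if rng.random() < 0.25:
            extra = backbone[int(rng.integers(len(backbone)))]
            if (extra, gene) not in evidence:
                evidence[(extra, gene)] = -1 if rng.random() < 0.25 else 1
    return TwoLayerNetwork(
        backbone_nodes=tuple(backbone),
        gene_nodes=tuple(genes),
        backbone_edges=tuple(backbone_edges),
        evidence_edges=tuple((b, g, s) for (b, g), s in evidence.items()),
        name="toy-xenobiotic",
    )
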