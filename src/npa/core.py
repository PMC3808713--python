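"""Network perturbation amplitude: backbone fit, score, CI, permutation tests.

Model
-----
Gene log2 fold changes ``beta`` are treated as boundary values on the
transcriptional layer; differential backbone values ``f`` are the smoothest
signed-graph extension of that boundary, i.e. the minimizer of the energy

    E(f) =   sum over backbone edges (x, y, s):   (f_x - s * f_y)^2
           + sum over evidence edges (b, g, s):   (beta_g - s * f_b)^2

with unit edge weights. Stationarity gives a sparse symmetric positive
definite system ``L3 f = -L2 beta`` (``L3`` the signed backbone Laplacian
plus the diagonal of evidence degrees, ``L2`` holding ``-s`` for each
evidence edge), so ``f = M beta`` with ``M = -L3^{-1} L2`` — the fit is
linear in the fold changes.

The network perturbation amplitude (NPA) summarizes ``f`` as a Sobolev-type
semi-norm on the signed backbone graph,

    NPA(f) = (1/|E_bb|) * sum over backbone edges (f_x - s * f_y)^2
             + alpha * (1/|V_bb|) * sum over nodes f_v^2,

a quadratic form ``f' Q f`` (hence ``beta' A beta`` with ``A = M' Q M``).
With the default ``alpha = 0`` this is the pure Dirichlet semi-norm,
normalized by the backbone edge count so scores are comparable across
network sizes.

Uncertainty propagates from the per-gene fold-change variances
``Sigma = diag(var_log2fc)``: backbone value variances are the diagonal of
``M Sigma M'``, and the NPA variance uses the Gaussian quadratic-form
moments ``Var = 4 beta' A Sigma A beta + 2 tr((A Sigma)^2)``, from which a
central-limit-theorem confidence interval is built.

Two permutation tests accompany the score: *O* shuffles the assignment of
measured fold-change values to gene labels (is the amplitude specific to
the observed evidence?), and K* rewires the backbone cause-and-effect layer
(does the network wiring itself contribute?).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from .diffexpr import ContrastData
from .network import TwoLayerNetwork, validate_network

__all__ = [
    "BackboneProfile",
    "NPAResult",
    "PermutationResult",
    "EnergyModel",
    "fit_backbone_values",
    "npa_score",
    "npa_confidence_interval",
    "permutation_test_O",
    "permutation_test_K",
    "significance_call",
    "score_network",
    "MissingVarianceError",
    "SingularSystemError",
    "DegenerateNormError",
]

VERDICTS = ("significant_and_specific", "significant_not_specific", "not_significant")


class SingularSystemError(ValueError):
    """The boundary-value system is singular (unidentifiable component)."""


class MissingVarianceError(ValueError):
    """The contrast carries no fold-change variances."""


class DegenerateNormError(ValueError):
    """NPA semi-norm undefined (no backbone edges and alpha == 0)."""


@dataclass(frozen=True)
class BackboneProfile:
    """Differential network backbone values for one contrast.

    ``variances`` (and the CI bounds) are ``None`` when the contrast carried
    no fold-change variances.
    """

    nodes: tuple[str, ...]
    values: np.ndarray
    variances: np.ndarray | None
    ci_low: np.ndarray | None
    ci_high: np.ndarray | None
    contrast_label: str = ""
    level: float = 0.95

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if not np.all(np.isfinite(vals)):
            raise ValueError("backbone values must be finite")
        if self.variances is not None:
            var = np.asarray(self.variances, dtype=float)
            object.__setattr__(self, "variances", var)
            if np.any(var < 0):
                raise ValueError("backbone variances must be >= 0")

    def value_map(self) -> dict[str, float]:
        return dict(zip(self.nodes, self.values))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"node": self.nodes, "value": self.values})
        if self.variances is not None:
            df["variance"] = self.variances
            df["ci_low"] = self.ci_low
            df["ci_high"] = self.ci_high
        return df


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of one permutation test (one-sided on score magnitude)."""

    p_value: float
    observed: float
    scores: np.ndarray
    n_permutations: int
    seed: int | None

    def __float__(self) -> float:
        return self.p_value


@dataclass(frozen=True)
class NPAResult:
    """Whole-network perturbation amplitude with its companion statistics."""

    score: float
    ci95: tuple[float, float]
    p_O: float
    p_K: float
    n_permutations: int
    verdict: str
    seed: int | None
    alpha: float = 0.0
    level: float = 0.95


class EnergyModel:
    """Linear-algebra workhorse for one (network, measured-gene-set) pair.

    Assembles the signed backbone Laplacian plus evidence-degree diagonal
    ``L3``, the backbone-gene coupling ``L2``, the scoring quadratic form
    ``Q(alpha)``, and the linear fit map ``M`` with ``f = M beta``.
    """

    def __init__(self, net: TwoLayerNetwork, genes: Sequence[str]):
        self.net = net
        self.nodes: tuple[str, ...] = tuple(net.backbone_nodes)
        self.genes: tuple[str, ...] = tuple(genes)
        self._node_idx = {n: i for i, n in enumerate(self.nodes)}
        self._gene_idx = {g: i for i, g in enumerate(self.genes)}
        nb, ng = len(self.nodes), len(self.genes)

        K = np.zeros((nb, nb))
        for src, tgt, s in net.backbone_edges:
            i, j = self._node_idx[src], self._node_idx[tgt]
            K[i, i] += 1.0
            K[j, j] += 1.0
            K[i, j] -= s
            K[j, i] -= s
        self.K = K

        L2 = np.zeros((nb, ng))
        evid_degree = np.zeros(nb)
        for b, g, s in net.evidence_edges:
            j = self._gene_idx.get(g)
            if j is None:  # gene not measured; edge dropped upstream
                continue
            i = self._node_idx[b]
            L2[i, j] -= s
            evid_degree[i] += 1.0
        self.L2 = L2
        self.L3 = K + np.diag(evid_degree)
        self._M: np.ndarray | None = None

    @property
    def n_backbone_edges(self) -> int:
        return len(self.net.backbone_edges)

    @property
    def M(self) -> np.ndarray:
        """Fit map, one row per backbone node, one column per measured gene."""
        if self._M is None:
            try:
                self._M = sla.solve(self.L3, -self.L2, assume_a="pos")
            except (sla.LinAlgError, np.linalg.LinAlgError) as exc:
                raise SingularSystemError(
                    "backbone system is singular; run validate_network to "
                    "locate unidentifiable components"
                ) from exc
        return self._M

    def Q(self, alpha: float = 0.0) -> np.ndarray:
        """Scoring quadratic form: NPA = f' Q f."""
        nb = len(self.nodes)
        if self.n_backbone_edges == 0 and alpha == 0.0:
            raise DegenerateNormError(
                "network has no backbone edges: the Dirichlet semi-norm is "
                "identically zero; use alpha > 0"
            )
        Q = np.zeros((nb, nb))
        if self.n_backbone_edges:
            Q = self.K / self.n_backbone_edges
        if alpha:
            Q = Q + (alpha / nb) * np.eye(nb)
        return Q

    def A(self, alpha: float = 0.0) -> np.ndarray:
        """Gene-space quadratic form: NPA = beta' A beta."""
        QM = self.Q(alpha) @ self.M
        return self.M.T @ QM

    def fit(self, beta: np.ndarray) -> np.ndarray:
        return self.M @ beta

    def score_values(self, f: np.ndarray, alpha: float = 0.0) -> float:
        return float(f @ self.Q(alpha) @ f)


# -- helpers ---------------------------------------------------------------


def _measured_model(net: TwoLayerNetwork, contrast: ContrastData) -> EnergyModel:
    """Restrict the network to measured genes and check identifiability.

    Genes in the contrast absent from the network are ignored (the network
    defines scope); network genes absent from the contrast drop their
    evidence edges with a warning. If the drop leaves a backbone component
    without boundary data the system is singular and an error names the
    component.
    """
    measured = set(contrast.genes)
    kept = [g for g in net.gene_nodes if g in measured]
    dropped = sorted(set(net.gene_nodes) - measured)
    if dropped:
        warnings.warn(
            f"{len(dropped)} network gene(s) not measured in contrast "
            f"{contrast.label!r}; their evidence edges are dropped",
            stacklevel=3,
        )
    kept_set = set(kept)
    restricted = TwoLayerNetwork(
        backbone_nodes=net.backbone_nodes,
        gene_nodes=tuple(kept),
        backbone_edges=net.backbone_edges,
        evidence_edges=tuple(
            (b, g, s) for b, g, s in net.evidence_edges if g in kept_set
        ),
        name=net.name,
    )
    report = validate_network(restricted)
    if not report.is_valid:
        raise SingularSystemError(
            "after dropping unmeasured genes, backbone component(s) "
            f"{report.unidentifiable_components} have no evidence; "
            "the fit is not identifiable"
        )
    return EnergyModel(net, kept)


def _beta_vector(model: EnergyModel, contrast: ContrastData) -> np.ndarray:
    vmap = contrast.value_map()
    return np.array([vmap[g] for g in model.genes])


def _var_vector(model: EnergyModel, contrast: ContrastData) -> np.ndarray:
    if not contrast.has_variance:
        raise MissingVarianceError(
            f"contrast {contrast.label!r} carries no fold-change variances"
        )
    vmap = dict(zip(contrast.genes, contrast.var_log2fc))
    return np.array([vmap[g] for g in model.genes])


def _z(level: float) -> float:
    return float(stats.norm.ppf(0.5 + level / 2.0))


# -- public operations -----------------------------------------------------


def fit_backbone_values(
    net: TwoLayerNetwork, contrast: ContrastData, level: float = 0.95
) -> BackboneProfile:
    """Differential network backbone values for one contrast.

    Solves the boundary-value problem described in the module docstring.
    Per-node variances are the diagonal of ``M Sigma M'`` with
    ``Sigma = diag(var_log2fc)``; the CI uses the exact Normal quantile of
    the requested level. Without variances, values are returned and the
    uncertainty fields are ``None``.
    """
    model = _measured_model(net, contrast)
    beta = _beta_vector(model, contrast)
    values = model.fit(beta)
    if contrast.has_variance:
        var_beta = _var_vector(model, contrast)
        node_var = np.einsum("ij,j,ij->i", model.M, var_beta, model.M)
        node_var = np.maximum(node_var, 0.0)
        half = _z(level) * np.sqrt(node_var)
        ci_low, ci_high = values - half, values + half
    else:
        node_var = ci_low = ci_high = None
    return BackboneProfile(
        nodes=model.nodes,
        values=values,
        variances=node_var,
        ci_low=ci_low,
        ci_high=ci_high,
        contrast_label=contrast.label,
        level=level,
    )


def npa_score(
    net: TwoLayerNetwork, profile: BackboneProfile, alpha: float = 0.0
) -> float:
    """NPA score of a fitted profile: edge-averaged signed Dirichlet energy.

    ``alpha`` adds a node-averaged ridge term ``alpha * mean(f^2)``; the
    default 0 keeps the pure semi-norm (zero iff ``f_x = s f_y`` on every
    backbone edge).
    """
    if set(profile.nodes) != set(net.backbone_nodes):
        raise ValueError("profile node set does not match network backbone")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if not net.backbone_edges and alpha == 0.0:
        raise DegenerateNormError(
            "network has no backbone edges: the Dirichlet semi-norm is "
            "identically zero; use alpha > 0"
        )
    fmap = profile.value_map()
    score = 0.0
    if net.backbone_edges:
        score = sum(
            (fmap[x] - s * fmap[y]) ** 2 for x, y, s in net.backbone_edges
        ) / len(net.backbone_edges)
    if alpha:
        f = np.array([fmap[n] for n in net.backbone_nodes])
        score += alpha * float(np.mean(f**2))
    return float(score)


def _npa_moments(
    model: EnergyModel, beta: np.ndarray, var_beta: np.ndarray, alpha: float
) -> tuple[float, float]:
    """Score and its delta-method variance under beta ~ N(beta_hat, Sigma)."""
    A = model.A(alpha)
    score = float(beta @ A @ beta)
    ASb = A @ (var_beta * (A @ beta))
    ASigma = A * var_beta[np.newaxis, :]
    var = 4.0 * float(beta @ ASb) + 2.0 * float(np.sum(ASigma * ASigma.T))
    return score, max(var, 0.0)


def npa_confidence_interval(
    net: TwoLayerNetwork,
    contrast: ContrastData,
    level: float = 0.95,
    alpha: float = 0.0,
) -> tuple[float, float]:
    """Central-limit-theorem CI for the NPA score.

    Uses the first two moments of the quadratic form ``beta' A beta`` with
    ``beta ~ N(beta_hat, Sigma)``; the lower bound is truncated at 0 since
    the amplitude is non-negative.
    """
    model = _measured_model(net, contrast)
    beta = _beta_vector(model, contrast)
    var_beta = _var_vector(model, contrast)
    score, var = _npa_moments(model, beta, var_beta, alpha)
    half = _z(level) * np.sqrt(var)
    return (max(0.0, score - half), score + half)


def _upper_tail_p(scores: np.ndarray, observed: float) -> float:
    """(k+1)/(n+1) counting; ties count as >= up to a relative tolerance."""
    tol = 1e-9 * max(1.0, abs(observed))
    k = float(np.sum(scores >= observed - tol))
    return (k + 1.0) / (scores.size + 1.0)


def permutation_test_O(
    net: TwoLayerNetwork,
    contrast: ContrastData,
    n_perm: int = 500,
    seed: int | None = None,
    alpha: float = 0.0,
) -> PermutationResult:
    """Evidence-specificity permutation test (the *O statistic).

    The assignment of measured fold-change values to gene labels is
    shuffled uniformly at random across the whole contrast; fit and score
    are recomputed each time (via the precomputed linear map, which is
    exact). One-sided p = (#{score_perm >= score_obs} + 1) / (n_perm + 1),
    never zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    model = _measured_model(net, contrast)
    beta_all = np.asarray(contrast.log2fc, dtype=float)
    pos = {g: i for i, g in enumerate(contrast.genes)}
    gene_pos = np.array([pos[g] for g in model.genes])
    Q = model.Q(alpha)
    M = model.M
    observed = model.score_values(M @ beta_all[gene_pos], alpha)
    if np.unique(beta_all).size < 2:
        warnings.warn(
            "fewer than 2 distinct fold-change values; permutation null is "
            "degenerate, p = 1",
            stacklevel=2,
        )
        return PermutationResult(1.0, observed, np.array([]), 0, seed)
    rng = np.random.default_rng(seed)
    scores = np.empty(n_perm)
    for k in range(n_perm):
        beta_perm = rng.permutation(beta_all)[gene_pos]
        f = M @ beta_perm
        scores[k] = f @ Q @ f
    p = _upper_tail_p(scores, observed)
    return PermutationResult(p, observed, scores, n_perm, seed)


def permutation_test_K(
    net: TwoLayerNetwork,
    contrast: ContrastData,
    n_perm: int = 500,
    seed: int | None = None,
    alpha: float = 0.0,
) -> PermutationResult:
    """Backbone-wiring permutation test (the K* statistic).

    Each permutation redraws the backbone edge endpoints uniformly among
    distinct ordered backbone node pairs (no self-loops, no duplicate
    (source, target)) and permutes the original multiset of edge signs, so
    sign frequencies are preserved exactly; the evidence layer is left
    untouched. The fit and score are recomputed on the rewired network;
    rewirings that strand a backbone component away from all evidence are
    solved in the minimum-norm least-squares sense.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not net.backbone_edges:
        raise DegenerateNormError("K* permutation needs at least one backbone edge")
    model = _measured_model(net, contrast)
    nb = len(model.nodes)
    n_e = model.n_backbone_edges
    beta = _beta_vector(model, contrast)
    b_vec = -model.L2 @ beta  # evidence side of the system; fixed across perms
    evid_degree = np.diag(model.L3 - model.K)
    observed = model.score_values(model.fit(beta), alpha)

    signs = np.array([s for _, _, s in net.backbone_edges], dtype=float)
    n_pairs = nb * (nb - 1)
    single_config = n_pairs == n_e and np.unique(signs).size == 1
    if nb < 2 or single_config:
        warnings.warn(
            "backbone graph too small to rewire (one possible configuration); "
            "p = 1",
            stacklevel=2,
        )
        return PermutationResult(1.0, observed, np.array([]), 0, seed)

    rng = np.random.default_rng(seed)
    # enumerate ordered pairs (i, j), i != j, as flat codes
    codes = np.arange(nb * nb)
    codes = codes[codes // nb != codes % nb]
    scores = np.empty(n_perm)
    for k in range(n_perm):
        chosen = rng.choice(codes, size=n_e, replace=False)
        s_perm = rng.permutation(signs)
        K = np.zeros((nb, nb))
        for code, s in zip(chosen, s_perm):
            i, j = divmod(int(code), nb)
            K[i, i] += 1.0
            K[j, j] += 1.0
            K[i, j] -= s
            K[j, i] -= s
        L3 = K + np.diag(evid_degree)
        try:
            f = sla.solve(L3, b_vec, assume_a="pos")
        except (sla.LinAlgError, np.linalg.LinAlgError):
            f = np.linalg.lstsq(L3, b_vec, rcond=None)[0]
        score = float(f @ K @ f) / n_e
        if alpha:
            score += alpha * float(np.mean(f**2))
        scores[k] = score
    p = _upper_tail_p(scores, observed)
    return PermutationResult(p, observed, scores, n_perm, seed)


def significance_call(
    score_ci: tuple[float, float],
    p_O: float,
    p_K: float,
    alpha_level: float = 0.05,
) -> str:
    """Combine CI and companion statistics into a verdict.

    The perturbation is *significant* when the CI lower bound is strictly
    above 0, and *specific* when both permutation p-values are below
    ``alpha_level``.
    """
    low, high = score_ci
    if not (np.isfinite(low) and np.isfinite(high) and np.isfinite(p_O) and np.isfinite(p_K)):
        raise ValueError("significance_call requires finite inputs")
    if low <= 0:
        return "not_significant"
    if p_O < alpha_level and p_K < alpha_level:
        return "significant_and_specific"
    return "significant_not_specific"


def score_network(
    net: TwoLayerNetwork,
    contrast: ContrastData,
    n_perm: int = 500,
    seed: int | None = None,
    alpha: float = 0.0,
    level: float = 0.95,
) -> tuple[BackboneProfile, NPAResult]:
    """End-to-end scoring: fit, NPA, CI, both permutation tests, verdict.

    The two permutation tests use independent streams derived from ``seed``
    so results are bit-reproducible given ``(seed, n_perm)``.
    """
    profile = fit_backbone_values(net, contrast, level=level)
    score = npa_score(net, profile, alpha=alpha)
    ci = npa_confidence_interval(net, contrast, level=level, alpha=alpha)
    if seed is None:
        seed_o = seed_k = None
    else:
        children = np.random.SeedSequence(seed).generate_state(2) % (2**31)
        seed_o, seed_k = int(children[0]), int(children[1])
    res_o = permutation_test_O(net, contrast, n_perm=n_perm, seed=seed_o, alpha=alpha)
    res_k = permutation_test_K(net, contrast, n_perm=n_perm, seed=seed_k, alpha=alpha)
    verdict = significance_call(ci, res_o.p_value, res_k.p_value)
    result = NPAResult(
        score=score,
        ci95=ci,
        p_O=res_o.p_value,
        p_K=res_k.p_value,
        n_permutations=n_perm,
        verdict=verdict,
        seed=seed,
        alpha=alpha,
        level=level,
    )
    return profile, result
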