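"""Comparing backbone profiles between contrasts.

Two fitted backbone profiles (e.g., nasal vs bronchial, in vivo vs in
vitro) are compared with Pearson and Spearman correlations, R-squared, and
a least-squares regression line, each with its p-value. Because the fit is
a strong dimension reduction (hundreds of genes onto a few backbone
nodes), correlation between profiles could arise from the reduction alone;
a gene-label permutation negative control quantifies that effect.

Caveat: the reported correlation p-values treat backbone values as
independent draws, which they are not (they share the network smoothing);
the permutation control is the honest null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import BackboneProfile, EnergyModel, _measured_model, fit_backbone_values
from .diffexpr import ContrastData
from .network import TwoLayerNetwork

__all__ = [
    "ComparisonStats",
    "NegativeControlResult",
    "ComparisonError",
    "compare_profiles",
    "compare_contrasts",
    "negative_control_permutation",
]


class ComparisonError(ValueError):
    """Profiles/contrasts cannot be compared (too few common items, etc.)."""


@dataclass(frozen=True)
class ComparisonStats:
    """Correlation and regression summary between two aligned value vectors.

    The regression is of the second profile on the first (B ~ A); axes in
    published scatter plots vary, so the direction is fixed here and
    documented. ``r_squared`` is the square of the Pearson correlation,
    which for simple linear regression equals the coefficient of
    determination.
    """

    pearson_r: float
    spearman_rho: float
    r_squared: float
    slope: float
    intercept: float
    p_pearson: float
    p_spearman: float
    p_regression: float
    n: int
    labels: tuple[str, str] = ("A", "B")


@dataclass(frozen=True)
class NegativeControlResult:
    """Gene-permutation null for the between-profile correlation."""

    observed_r: float
    permuted_r: np.ndarray
    p_two_sided: float
    n_perm: int
    seed: int | None


def _corr_stats(
    x: np.ndarray, y: np.ndarray, labels: tuple[str, str], n_min: int = 3
) -> ComparisonStats:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < n_min:
        raise ComparisonError(
            f"need at least {n_min} paired values, got {x.size} "
            f"({labels[0]!r} vs {labels[1]!r})"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ComparisonError(
            "zero variance in one of the value vectors; correlation undefined"
        )
    pear = stats.pearsonr(x, y)
    spear = stats.spearmanr(x, y)
    reg = stats.linregress(x, y)
    return ComparisonStats(
        pearson_r=float(pear.statistic),
        spearman_rho=float(spear.statistic),
        r_squared=float(pear.statistic) ** 2,
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        p_pearson=float(pear.pvalue),
        p_spearman=float(spear.pvalue),
        p_regression=float(reg.pvalue),
        n=int(x.size),
        labels=labels,
    )


def compare_profiles(a: BackboneProfile, b: BackboneProfile) -> ComparisonStats:
    """Correlation/regression statistics on the common backbone nodes.

    The comparison is restricted to the (sorted) intersection of node sets;
    at least 3 common nodes are required.
    """
    common = sorted(set(a.nodes) & set(b.nodes))
    if len(common) < 3:
        raise ComparisonError(
            f"profiles share only {len(common)} node(s); need >= 3"
        )
    amap, bmap = a.value_map(), b.value_map()
    x = np.array([amap[n] for n in common])
    y = np.array([bmap[n] for n in common])
    return _corr_stats(x, y, (a.contrast_label or "A", b.contrast_label or "B"))


def compare_contrasts(
    net: TwoLayerNetwork,
    contrast_a: ContrastData,
    contrast_b: ContrastData,
) -> tuple[ComparisonStats, ComparisonStats | None]:
    """Compare two contrasts at the functional and transcriptional layers.

    Returns ``(backbone_stats, gene_stats)``: the first correlates the two
    fitted backbone profiles; the second correlates the raw log2 fold
    changes of genes present in both contrasts and in the network. If the
    gene layer cannot be compared (e.g., disjoint gene sets) it is returned
    as ``None`` with a warning, so the functional-layer result survives.
    """
    prof_a = fit_backbone_values(net, contrast_a)
    prof_b = fit_backbone_values(net, contrast_b)
    backbone_stats = compare_profiles(prof_a, prof_b)

    net_genes = set(net.gene_nodes)
    shared = sorted(net_genes & set(contrast_a.genes) & set(contrast_b.genes))
    gene_stats: ComparisonStats | None
    try:
        va, vb = contrast_a.value_map(), contrast_b.value_map()
        gene_stats = _corr_stats(
            np.array([va[g] for g in shared]),
            np.array([vb[g] for g in shared]),
            (contrast_a.label or "A", contrast_b.label or "B"),
        )
    except ComparisonError as exc:
        warnings.warn(f"gene-layer comparison unavailable: {exc}", stacklevel=2)
        gene_stats = None
    return backbone_stats, gene_stats


def negative_control_permutation(
    net: TwoLayerNetwork,
    contrast_a: ContrastData,
    contrast_b: ContrastData,
    n_perm: int = 1000,
    seed: int | None = None,
    statistic: str = "pearson",
) -> NegativeControlResult:
    """Gene-permutation null for the between-profile correlation.

    The gene labels underlying each contrast are shuffled independently
    (decorrelating the fold changes of the two comparison groups), profiles
    are refitted through the linear map, and the correlation recorded;
    two-sided p = (#{|r_perm| >= |r_obs|} + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if statistic not in ("pearson", "spearman"):
        raise ValueError("statistic must be 'pearson' or 'spearman'")
    corr = stats.pearsonr if statistic == "pearson" else stats.spearmanr

    def _prep(contrast: ContrastData) -> tuple[EnergyModel, np.ndarray, np.ndarray]:
        model = _measured_model(net, contrast)
        beta_all = np.asarray(contrast.log2fc, dtype=float)
        pos = {g: i for i, g in enumerate(contrast.genes)}
        gene_pos = np.array([pos[g] for g in model.genes])
        return model, beta_all, gene_pos

    model_a, beta_a, pos_a = _prep(contrast_a)
    model_b, beta_b, pos_b = _prep(contrast_b)
    f_a = model_a.M @ beta_a[pos_a]
    f_b = model_b.M @ beta_b[pos_b]
    observed = float(corr(f_a, f_b).statistic)

    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    for k in range(n_perm):
        pa = model_a.M @ rng.permutation(beta_a)[pos_a]
        pb = model_b.M @ rng.permutation(beta_b)[pos_b]
        permuted[k] = corr(pa, pb).statistic
    p = (float(np.sum(np.abs(permuted) >= abs(observed))) + 1.0) / (n_perm + 1.0)
    return NegativeControlResult(
        observed_r=observed,
        permuted_r=permuted,
        p_two_sided=p,
        n_perm=n_perm,
        seed=seed,
    )
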