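"""Per-gene contrasts: loading, and a simple two-group log2 contrast.

The network scoring layer only consumes per-gene log2 fold changes and
their estimated variances. Contrasts produced by any upstream pipeline can
be loaded from TSV; for fully synthetic end-to-end runs a plain pooled-
variance two-group contrast (equal-variance t test, Benjamini-Hochberg
adjustment) is computed from a log2 expression matrix.

The ``var_log2fc`` column is a *variance* (squared standard error of the
log2 fold change), not a standard error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContrastData",
    "ExpressionMatrix",
    "load_contrast",
    "write_contrast",
    "compute_contrast",
    "benjamini_hochberg",
    "read_expression",
    "write_expression",
]


class ContrastFormatError(ValueError):
    """Malformed contrast or expression input."""


@dataclass(frozen=True)
class ContrastData:
    """Per-gene log2 fold changes (treated minus control) for one comparison.

    ``var_log2fc`` may be ``None`` when the source table carries no variance
    column; operations that propagate uncertainty (confidence intervals)
    refuse such contrasts.
    """

    genes: tuple[str, ...]
    log2fc: np.ndarray
    var_log2fc: np.ndarray | None = None
    pvalue: np.ndarray | None = None
    adj_pvalue: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        genes = tuple(str(g) for g in self.genes)
        object.__setattr__(self, "genes", genes)
        fc = np.asarray(self.log2fc, dtype=float)
        object.__setattr__(self, "log2fc", fc)
        if len(set(genes)) != len(genes):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise ContrastFormatError(f"duplicate gene id(s): {dupes}")
        if fc.shape != (len(genes),):
            raise ContrastFormatError("log2fc length does not match gene ids")
        if not np.all(np.isfinite(fc)):
            bad = [genes[i] for i in np.flatnonzero(~np.isfinite(fc))]
            raise ContrastFormatError(f"non-finite log2fc for gene(s): {bad}")
        if self.var_log2fc is not None:
            v = np.asarray(self.var_log2fc, dtype=float)
            object.__setattr__(self, "var_log2fc", v)
            if v.shape != fc.shape:
                raise ContrastFormatError("var_log2fc length mismatch")
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ContrastFormatError("var_log2fc must be finite and >= 0")
        for attr in ("pvalue", "adj_pvalue"):
            p = getattr(self, attr)
            if p is not None:
                p = np.asarray(p, dtype=float)
                object.__setattr__(self, attr, p)
                if p.shape != fc.shape:
                    raise ContrastFormatError(f"{attr} length mismatch")
                if np.any((p < 0) | (p > 1)):
                    raise ContrastFormatError(f"{attr} outside [0, 1]")
        if self.pvalue is not None and self.adj_pvalue is not None:
            if np.any(self.adj_pvalue < self.pvalue - 1e-12):
                raise ContrastFormatError("adj_pvalue below pvalue")

    @property
    def has_variance(self) -> bool:
        return self.var_log2fc is not None

    def value_map(self) -> Mapping[str, float]:
        return dict(zip(self.genes, self.log2fc))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"gene_id": self.genes, "log2fc": self.log2fc})
        if self.var_log2fc is not None:
            df["var_log2fc"] = self.var_log2fc
        if self.pvalue is not None:
            df["pvalue"] = self.pvalue
        if self.adj_pvalue is not None:
            df["adj_pvalue"] = self.adj_pvalue
        return df


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples log2 intensities with a control/treated group label."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    groups: pd.Series  # index: sample ids, values in {"control", "treated"}

    def __post_init__(self) -> None:
        vals = self.values
        groups = self.groups.astype(str)
        object.__setattr__(self, "groups", groups)
        if not np.all(np.isfinite(vals.to_numpy())):
            raise ContrastFormatError("expression matrix has non-finite entries")
        if set(groups.index) != set(vals.columns):
            raise ContrastFormatError("sample sheet does not match matrix columns")
        bad = set(groups.unique()) - {"control", "treated"}
        if bad:
            raise ContrastFormatError(f"unknown group label(s): {sorted(bad)}")
        for grp in ("control", "treated"):
            if (groups == grp).sum() < 2:
                raise ContrastFormatError(
                    f"group {grp!r} has fewer than 2 samples; variance "
                    "cannot be estimated"
                )

    def samples(self, group: str) -> pd.DataFrame:
        return self.values.loc[:, self.groups.index[self.groups == group]]


def load_contrast(
    table: Union[str, Path, pd.DataFrame], label: str | None = None
) -> ContrastData:
    """Load and validate a contrast from TSV (or an equivalent DataFrame).

    Required columns: ``gene_id``, ``log2fc``; optional: ``var_log2fc``,
    ``pvalue``, ``adj_pvalue``.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
        src = label or ""
    else:
        path = Path(table)
        df = pd.read_csv(path, sep="\t", comment="#")
        src = label or path.stem
    for col in ("gene_id", "log2fc"):
        if col not in df.columns:
            raise ContrastFormatError(f"contrast table missing column {col!r}")
    fc = pd.to_numeric(df["log2fc"], errors="coerce")
    if fc.isna().any():
        rows = df.loc[fc.isna(), "gene_id"].tolist()
        raise ContrastFormatError(f"non-finite log2fc in row(s) for gene(s) {rows}")
    kwargs = {}
    for col in ("var_log2fc", "pvalue", "adj_pvalue"):
        if col in df.columns:
            kwargs[col] = pd.to_numeric(df[col]).to_numpy()
    return ContrastData(
        genes=tuple(df["gene_id"].astype(str)),
        log2fc=fc.to_numpy(),
        label=src,
        **kwargs,
    )


def write_contrast(contrast: ContrastData, path: Union[str, Path]) -> None:
    contrast.to_frame().to_csv(path, sep="\t", index=False)


def compute_contrast(expr: ExpressionMatrix, label: str = "") -> ContrastData:
    """Two-group pooled-variance contrast on a log2 expression matrix.

    log2fc = mean(treated) - mean(control); the variance of the fold change
    uses the pooled within-group variance times (1/n_t + 1/n_c); the p-value
    is a two-sided equal-variance t test with n_t + n_c - 2 degrees of
    freedom, adjusted by Benjamini-Hochberg. Invariant to sample order
    within groups.
    """
    treated = expr.samples("treated").to_numpy()
    control = expr.samples("control").to_numpy()
    n_t, n_c = treated.shape[1], control.shape[1]
    log2fc = treated.mean(axis=1) - control.mean(axis=1)
    s2_t = treated.var(axis=1, ddof=1)
    s2_c = control.var(axis=1, ddof=1)
    dof = n_t + n_c - 2
    s2_pooled = ((n_t - 1) * s2_t + (n_c - 1) * s2_c) / dof
    var_fc = s2_pooled * (1.0 / n_t + 1.0 / n_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = log2fc / np.sqrt(var_fc)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
    # zero within-group variance: t is 0/0 or +/-inf
    degenerate = var_fc == 0
    pvals[degenerate] = np.where(log2fc[degenerate] == 0, 1.0, 0.0)
    return ContrastData(
        genes=tuple(expr.values.index.astype(str)),
        log2fc=log2fc,
        var_log2fc=var_fc,
        pvalue=pvals,
        adj_pvalue=benjamini_hochberg(pvals),
        label=label,
    )


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# -- expression I/O --------------------------------------------------------


def read_expression(
    matrix_path: Union[str, Path], samples_path: Union[str, Path]
) -> ExpressionMatrix:
    """Read an expression TSV (first column gene_id) and a sample sheet.

    The sample sheet is a two-column TSV ``sample\tgroup`` with groups in
    {control, treated}.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sheet = pd.read_csv(samples_path, sep="\t", dtype=str)
    if list(sheet.columns[:2]) != ["sample", "group"]:
        raise ContrastFormatError("sample sheet must have columns sample, group")
    groups = pd.Series(sheet["group"].values, index=sheet["sample"].values)
    return ExpressionMatrix(values=values, groups=groups)


def write_expression(
    expr: ExpressionMatrix, matrix_path: Union[str, Path], samples_path: Union[str, Path]
) -> None:
    out = expr.values.copy()
    out.index.name = "gene_id"
    out.to_csv(matrix_path, sep="\t")
    pd.DataFrame({"sample": expr.groups.index, "group": expr.groups.values}).to_csv(
        samples_path, sep="\t", index=False
    )
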