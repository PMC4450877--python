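"""Normalization, per-contrast fold change, and the empirical differential probability.

The differential probability :math:`P_{DE}` is a NOISeq-style empirical
score: replicate pairs *within* the same condition provide a null cloud of
(|log-ratio|, |difference|) points describing pure technical+biological
noise, and a gene's probability of differential expression is the fraction
of that cloud it strictly dominates.  The statistic is deterministic (full
enumeration of within-group replicate pairs, no sampling) and lives on
[0, 1], thresholded downstream at 0.5 (ranking filter) and 0.9 (class
calls).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import ExpressionMatrix


@dataclass(frozen=True)
class ContrastSpec:
    """A two-group contrast within one cell line.

    ``group_a`` and ``group_b`` are (perturbation, stimulus) pairs; the
    log2 fold change is oriented A over B, with A the treated/stimulated
    arm.
    """

    cell_line: str
    group_a: tuple[str, str]
    group_b: tuple[str, str]

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("contrast groups must differ")


@dataclass
class ContrastResult:
    """Per-gene means, M = log2 ratio, D = absolute difference, P_DE."""

    spec: ContrastSpec
    table: pd.DataFrame  # index gene; columns mean_a, mean_b, M, D, P_DE

    def to_tsv(self) -> str:
        df = self.table
        lines = ["gene\tmean_a\tmean_b\tM\tD\tP_DE"]
        for gene, row in df.iterrows():
            lines.append(
                f"{gene}\t{row['mean_a']:.8g}\t{row['mean_b']:.8g}"
                f"\t{row['M']:.8g}\t{row['D']:.8g}\t{row['P_DE']:.8g}"
            )
        return "\n".join(lines) + "\n"


def _group_matrix(matrix: ExpressionMatrix, cell_line: str, group: tuple[str, str]) -> pd.DataFrame:
    cols = matrix.group_columns(cell_line, *group)
    if len(cols) < 2:
        raise ValueError(
            f"group {group} in cell line {cell_line!r} has {len(cols)} replicates; need >= 2"
        )
    return matrix.values[cols]


def normalize(matrix: ExpressionMatrix, method: str | None = None) -> ExpressionMatrix:
    """Scale samples to a common depth; rank order within a sample is preserved.

    ``library_size`` (default for counts): each sample is scaled so its
    total equals the across-sample mean total.  ``average`` (the BeadStudio
    convention, default for intensities): each sample is scaled so its mean
    equals the grand mean of sample means.  With a fixed gene panel the two
    coincide; both names are kept because they are the idioms of their
    respective platforms.
    """
    if method is None:
        method = "library_size" if matrix.mode == "counts" else "average"
    if method not in ("library_size", "average"):
        raise ValueError(f"unknown normalization method {method!r}")
    values = matrix.values
    totals = values.sum(axis=0)
    if (totals == 0).any():
        zeros = list(totals.index[totals == 0])
        raise ValueError(f"sample(s) with zero total signal: {zeros}")
    if method == "library_size":
        target = totals.mean()
        factors = target / totals
    else:
        means = values.mean(axis=0)
        factors = means.mean() / means
    scaled = values * factors
    return ExpressionMatrix(
        values=scaled, samples=matrix.samples, mode=matrix.mode, normalized=True
    )


def differential_probability(
    matrix: ExpressionMatrix, spec: ContrastSpec, pseudocount: float = 1.0
) -> pd.Series:
    """Empirical P_DE for every gene under one contrast.

    The null cloud collects, for every gene and every unordered pair of
    replicates within the same group (both groups), the point
    ``(|M0|, D0)`` with ``M0 = log2((x_i + c)/(x_j + c))`` and
    ``D0 = |x_i - x_j|``.  Then ``P_DE(g)`` is the fraction of null points
    strictly dominated by gene g: ``|M0| < |M(g)|`` and ``D0 < D(g)``.
    Strict dominance makes an exactly-null gene (M = 0, D = 0) score 0.
    """
    c = float(pseudocount)
    a = _group_matrix(matrix, spec.cell_line, spec.group_a).to_numpy()
    b = _group_matrix(matrix, spec.cell_line, spec.group_b).to_numpy()

    null_m: list[np.ndarray] = []
    null_d: list[np.ndarray] = []
    for grp in (a, b):
        for i, j in combinations(range(grp.shape[1]), 2):
            x, y = grp[:, i], grp[:, j]
            null_m.append(np.abs(np.log2((x + c) / (y + c))))
            null_d.append(np.abs(x - y))
    if not null_m:
        raise ValueError("empty null cloud: no within-group replicate pairs")
    m0 = np.concatenate(null_m)
    d0 = np.concatenate(null_d)

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    m_obs = np.abs(np.log2((mean_a + c) / (mean_b + c)))
    d_obs = np.abs(mean_a - mean_b)

    n_null = len(m0)
    probs = np.empty(len(m_obs))
    chunk = 512  # keep the boolean broadcast under ~25 MB
    for lo in range(0, len(m_obs), chunk):
        hi = lo + chunk
        dom = (m0[None, :] < m_obs[lo:hi, None]) & (d0[None, :] < d_obs[lo:hi, None])
        probs[lo:hi] = dom.sum(axis=1) / n_null
    return pd.Series(probs, index=matrix.values.index, name="P_DE")


def contrast(
    matrix: ExpressionMatrix, spec: ContrastSpec, pseudocount: float = 1.0
) -> ContrastResult:
    """Compute means, M, D and P_DE for one contrast on a normalized matrix."""
    if not matrix.normalized:
        raise ValueError("contrast requires a normalized matrix; call normalize() first")
    c = float(pseudocount)
    a = _group_matrix(matrix, spec.cell_line, spec.group_a)
    b = _group_matrix(matrix, spec.cell_line, spec.group_b)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    m = np.log2((mean_a + c) / (mean_b + c))
    d = (mean_a - mean_b).abs()
    p = differential_probability(matrix, spec, pseudocount=c)
    table = pd.DataFrame(
        {"mean_a": mean_a, "mean_b": mean_b, "M": m, "D": d, "P_DE": p}
    )
    table.index.name = "gene"
    return ContrastResult(spec=spec, table=table)
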