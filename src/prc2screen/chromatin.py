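"""TSS-centred signal binning, the H3K27me3 positivity rule, and class statistics.

The promoter signal matrix holds, per gene, the mean ChIP signal in
fixed-width bins (default 100 bp) across a window around the TSS (default
+/-5 kb), strand-oriented so that index 0 is always the most-upstream bin.
A promoter is called H3K27me3-positive when at least one bin reaches 1.5x
the control level (inclusive).  Class comparisons use Fisher's exact test
on positivity counts and Mann-Whitney on signal levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ParamConfig, SignalTrack, TssAnnotation


@dataclass
class PromoterSignalMatrix:
    """Gene x bin mean signal around the TSS for one mark.

    ``offsets`` are promoter-relative bin start coordinates (negative =
    upstream of the TSS in the gene's orientation).  ``clipped`` flags
    genes whose window ran below coordinate 0 (clipped bases contribute 0).
    """

    mark: str
    values: pd.DataFrame          # index gene, columns = bin index
    offsets: np.ndarray           # bin start offsets, length = n bins
    bin_width: int
    clipped: pd.Series            # bool per gene

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def subwindow(self, half_width: int) -> "PromoterSignalMatrix":
        """Restrict to the central +/-half_width window (index arithmetic)."""
        keep = (self.offsets >= -half_width) & (self.offsets + self.bin_width <= half_width)
        return PromoterSignalMatrix(
            mark=self.mark,
            values=self.values.loc[:, keep],
            offsets=self.offsets[keep],
            bin_width=self.bin_width,
            clipped=self.clipped,
        )


@dataclass
class PositivityCall:
    gene: str
    positive: bool
    max_ratio: float
    control_level: float


def bin_promoter_signal(
    track: SignalTrack,
    tss: TssAnnotation,
    half_width: int = 5000,
    bin_width: int = 100,
    mark: str = "signal",
) -> PromoterSignalMatrix:
    """Coverage-weighted mean signal per bin in a strand-oriented TSS window.

    Each bin value is the integral of the track over the bin divided by the
    bin width; uncovered bases contribute 0 (sparse bedGraph semantics).
    Minus-strand rows are reversed so bin 0 is most-upstream for every
    gene.  Windows extending below coordinate 0 are clipped and flagged.
    """
    if half_width % bin_width != 0:
        raise ValueError("half_width must be divisible by bin_width")
    n_bins = 2 * half_width // bin_width
    offsets = np.arange(-half_width, half_width, bin_width)
    rows = np.empty((len(tss.table), n_bins))
    clipped = np.zeros(len(tss.table), dtype=bool)
    for i, (gene, rec) in enumerate(tss.table.iterrows()):
        t = int(rec["tss"])
        edges = t + np.arange(-half_width, half_width + bin_width, bin_width)
        clipped[i] = edges[0] < 0
        ed = np.clip(edges, 0, None)
        integ = track.integral(rec["chrom"], ed)
        binned = (integ[1:] - integ[:-1]) / bin_width
        if rec["strand"] == "-":
            binned = binned[::-1]
        rows[i] = binned
    values = pd.DataFrame(rows, index=tss.table.index, columns=range(n_bins))
    return PromoterSignalMatrix(
        mark=mark,
        values=values,
        offsets=offsets,
        bin_width=bin_width,
        clipped=pd.Series(clipped, index=tss.table.index),
    )


def h3k27me3_positive(
    bins: np.ndarray | pd.Series,
    control_level: float,
    ratio: float = 1.5,
    gene: str = "",
) -> PositivityCall:
    """Positive iff at least one bin reaches ``ratio`` x control (inclusive)."""
    if control_level <= 0:
        raise ValueError("control_level must be > 0")
    arr = np.asarray(bins, dtype=float)
    max_ratio = float(arr.max() / control_level)
    return PositivityCall(
        gene=gene,
        positive=max_ratio >= ratio,
        max_ratio=max_ratio,
        control_level=control_level,
    )


def control_levels(
    control: SignalTrack | None,
    tss: TssAnnotation,
    signal: SignalTrack | None = None,
    half_width: int = 5000,
    bin_width: int = 100,
) -> pd.Series:
    """Per-gene control level for the positivity rule.

    With a matched control track: mean of the control over the same window
    bins.  Without one: genome-wide 5%-trimmed mean of the signal track
    itself, applied to every gene.
    """
    if control is not None:
        mat = bin_promoter_signal(control, tss, half_width, bin_width, mark="control")
        return mat.values.mean(axis=1)
    if signal is None:
        raise ValueError("need a control track or the signal track for the fallback")
    level = signal.trimmed_mean(trim=0.05)
    return pd.Series(level, index=tss.table.index)


def call_positivity(
    matrix: PromoterSignalMatrix,
    controls: pd.Series,
    ratio: float = 1.5,
) -> pd.DataFrame:
    """Vectorised positivity calls for a whole matrix; returns a tidy table."""
    ctrl = controls.reindex(matrix.values.index)
    if ctrl.isna().any():
        raise ValueError("control level missing for some genes")
    if (ctrl <= 0).any():
        raise ValueError("control_level must be > 0")
    max_ratio = matrix.values.max(axis=1) / ctrl
    return pd.DataFrame(
        {
            "max_ratio": max_ratio,
            "control_level": ctrl,
            "positive": max_ratio >= ratio,
        }
    )


def meta_profile(
    matrix: PromoterSignalMatrix, groups: dict[str, list[str]]
) -> pd.DataFrame:
    """Per-group mean curve (+ SD) across bins; tidy long-format table."""
    records = []
    for name, genes in groups.items():
        if len(genes) == 0:
            raise ValueError(f"empty gene group {name!r}")
        sub = matrix.values.loc[genes]
        mean = sub.mean(axis=0).to_numpy()
        sd = sub.std(axis=0, ddof=0).to_numpy()
        for off, m, s in zip(matrix.offsets, mean, sd):
            records.append({"group": name, "offset": int(off), "mean": m, "sd": s})
    return pd.DataFrame.from_records(records)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact p and sample odds ratio for a 2x2 table.

    p sums the point probabilities of all tables (at fixed margins) whose
    hypergeometric probability does not exceed the observed table's; the
    odds ratio is (a*d)/(b*c) with division by zero yielding inf/nan.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any():
        raise ValueError("table entries must be non-negative")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == arr.astype(np.int64)):
            raise ValueError("table entries must be integers")
        arr = arr.astype(np.int64)
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    a, b = arr[0]
    c, d = arr[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.float64(a * d) / np.float64(b * c)
    return float(p), float(odds)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U (of x) and two-sided p.

    Exact enumeration when n+m <= 12 and there are no ties; otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def expression_strata(
    basal: pd.Series, silent_threshold: float
) -> pd.Series:
    """Stratify genes into silent / low / medium / high basal expression.

    Silent: basal < tau.  Expressed genes are split into tertiles by rank
    (stable tie-break by gene id); partition sizes differ by at most one,
    with the remainder going to the lower strata.
    """
    if (basal < 0).any():
        raise ValueError("basal means must be >= 0")
    strata = pd.Series("silent", index=basal.index, dtype=object)
    expressed = basal[basal >= silent_threshold]
    n = len(expressed)
    if n == 0:
        return strata
    order = expressed.to_frame("v").assign(g=expressed.index)
    order = order.sort_values(["v", "g"], kind="stable").index
    sizes = [n // 3 + (1 if i < n % 3 else 0) for i in range(3)]
    names = ["low", "medium", "high"]
    pos = 0
    for size, name in zip(sizes, names):
        strata.loc[order[pos : pos + size]] = name
        pos += size
    return strata


def positivity_class_association(
    positivity: pd.DataFrame, group_a: list[str], group_b: list[str]
) -> tuple[float, float, np.ndarray]:
    """Fisher test of positivity frequency between two gene groups.

    Returns (p, odds ratio, 2x2 table [[pos_a, neg_a], [pos_b, neg_b]]).
    """
    pos = positivity["positive"]
    a_pos = int(pos.loc[group_a].sum())
    b_pos = int(pos.loc[group_b].sum())
    table = np.array(
        [[a_pos, len(group_a) - a_pos], [b_pos, len(group_b) - b_pos]], dtype=np.int64
    )
    p, odds = fisher_exact_2x2(table)
    return p, odds, table
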