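"""Domain types and strict readers/writers for the formats the pipeline touches.

Coordinate convention
---------------------
All genomic coordinates in this package are **0-based, half-open**
(the native convention of BED and bedGraph).  A minus-strand TSS is
``end - 1`` because the BED ``end`` column is exclusive.

Readers are strict: malformed input is rejected with the offending line
number rather than coerced, because silent coercion hides simulation bugs.
Gene identity is the raw string token, case-sensitive; no symbol aliasing.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PERTURBATIONS = ("ctrl", "suz12_kd", "brg1", "gfp")
STIMULI = ("none", "ifng")
MODES = ("counts", "intensity")

FLOAT_FMT = "%.8g"  # >= 6 significant digits on all emitted tables


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    cell_line: str
    perturbation: str
    stimulus: str
    replicate: int

    def __post_init__(self) -> None:
        if self.perturbation not in PERTURBATIONS:
            raise ValueError(
                f"unknown perturbation {self.perturbation!r} for sample "
                f"{self.sample_id!r}; expected one of {PERTURBATIONS}"
            )
        if self.stimulus not in STIMULI:
            raise ValueError(
                f"unknown stimulus {self.stimulus!r} for sample "
                f"{self.sample_id!r}; expected one of {STIMULI}"
            )


@dataclass
class ExpressionMatrix:
    """Gene x sample quantification plus per-sample design factors.

    ``values`` is a genes x samples DataFrame (index = gene ids, columns =
    sample ids, order following the sample sheet); ``samples`` the parallel
    design records; ``mode`` is ``counts`` (sequencing) or ``intensity``
    (arrays).
    """

    values: pd.DataFrame
    samples: list[SampleInfo]
    mode: str = "counts"
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        ids = [s.sample_id for s in self.samples]
        if list(self.values.columns) != ids:
            raise ValueError("matrix columns do not match sample sheet order")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def group_columns(self, cell_line: str, perturbation: str, stimulus: str) -> list[str]:
        """Sample ids of one (cell_line, perturbation, stimulus) design cell."""
        return [
            s.sample_id
            for s in self.samples
            if s.cell_line == cell_line
            and s.perturbation == perturbation
            and s.stimulus == stimulus
        ]


@dataclass
class TssAnnotation:
    """One TSS per gene: chromosome, 0-based coordinate, strand."""

    table: pd.DataFrame  # index = gene id; columns chrom, tss, strand

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicate gene ids in TSS annotation")
        if (self.table["tss"] < 0).any():
            raise ValueError("TSS coordinates must be >= 0")
        bad = set(self.table["strand"]) - {"+", "-"}
        if bad:
            raise ValueError(f"invalid strand values: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)


class SignalTrack:
    """Per-chromosome sorted, non-overlapping intervals with a real signal.

    Stored as arrays ``(starts, ends, values)`` per chromosome plus a prefix
    integral enabling O(log n) windowed integration (uncovered bases carry
    signal 0, the sparse bedGraph semantics).
    """

    def __init__(self, intervals: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in intervals.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if (ends <= starts).any():
                raise ValueError(f"{chrom}: interval with end <= start")
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"{chrom}: overlapping intervals")
            if (values < 0).any():
                raise ValueError(f"{chrom}: negative signal value")
            # prefix[i] = integral of signal over all intervals < i
            prefix = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
            self._chroms[chrom] = (starts, ends, values, prefix)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._chroms)

    def intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        starts, ends, values, _ = self._chroms[chrom]
        return starts, ends, values

    def integral(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Integral of the signal over [0, pos) for each position."""
        if chrom not in self._chroms:
            return np.zeros(len(pos), dtype=float)
        starts, ends, values, prefix = self._chroms[chrom]
        pos = np.asarray(pos, dtype=np.int64)
        # number of intervals entirely left of pos
        i = np.searchsorted(ends, pos, side="left")
        full = prefix[i]
        # partial overlap of interval i, if pos falls inside it
        inside = (i < len(starts)) & (pos > starts[np.minimum(i, len(starts) - 1)])
        j = np.minimum(i, len(starts) - 1)
        partial = np.where(
            inside, values[j] * (np.minimum(pos, ends[j]) - starts[j]), 0.0
        )
        return full + partial

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base signal over [start, end), uncovered bases = 0."""
        if end <= start:
            raise ValueError("empty window")
        lo = max(start, 0)
        total = float(self.integral(chrom, np.array([end]))[0] - self.integral(chrom, np.array([lo]))[0])
        return total / (end - start)

    def trimmed_mean(self, trim: float = 0.05) -> float:
        """Length-weighted trimmed mean of the signal over covered bases."""
        vals, lens = [], []
        for starts, ends, values, _ in self._chroms.values():
            vals.append(values)
            lens.append(ends - starts)
        if not vals:
            raise ValueError("empty track")
        values = np.concatenate(vals)
        weights = np.concatenate(lens).astype(float)
        order = np.argsort(values, kind="stable")
        values, weights = values[order], weights[order]
        cum = np.cumsum(weights)
        total = cum[-1]
        lo, hi = trim * total, (1 - trim) * total
        # weight of each value clipped to the [lo, hi] mass window
        left = np.concatenate([[0.0], cum[:-1]])
        w = np.clip(np.minimum(cum, hi) - np.maximum(left, lo), 0.0, None)
        if w.sum() == 0:
            return float(values[np.searchsorted(cum, total / 2)])
        return float(np.average(values, weights=w))


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError(f"gene set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")


@dataclass
class ParamConfig:
    """All tunable analysis constants in one place.

    Defaults follow the published analysis: 2-fold induction cutoff,
    differential-probability cutoffs 0.9 (class calls) and 0.5 (ranking
    filter), the 1.5x H3K27me3 bin positivity ratio on 100-bp bins within
    +/-5 kb of the TSS, k = 10 promoter-chromatin clusters split 1-4 vs
    5-10, GSEA significance at nominal p < 0.01 and FDR q < 0.05, and
    1000-fold resampling defaults.
    """

    fc_cutoff: float = 2.0          # theta_FC, inclusive >=
    prob_cutoff: float = 0.9        # theta_P, strict >
    rank_prob_cutoff: float = 0.5   # theta_rank, strict >
    positivity_ratio: float = 1.5   # rho_pos, inclusive >=
    bin_width: int = 100            # b (bp)
    window_half_width: int = 5000   # W5 (bp)
    narrow_half_width: int = 1000   # W1 (bp)
    n_clusters: int = 10            # k
    cid_split: int = 4              # CIDs 1..4 vs 5..k
    alpha_nom: float = 0.01
    alpha_fdr: float = 0.05
    n_perm: int = 1000
    n_random_sets: int = 1000
    pseudocount: float = 1.0        # c, on the normalized scale
    silent_threshold: float = 1.0   # tau, normalized units
    gsea_exponent: float = 1.0      # weight exponent p
    kmeans_restarts: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fc_cutoff", "prob_cutoff", "rank_prob_cutoff", "positivity_ratio",
            "bin_width", "window_half_width", "narrow_half_width",
            "n_clusters", "alpha_nom", "alpha_fdr", "n_perm",
            "n_random_sets", "pseudocount", "silent_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.window_half_width % self.bin_width != 0:
            raise ValueError("window_half_width must be divisible by bin_width")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _lines(text: str) -> Iterable[tuple[int, str]]:
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if line.strip():
            yield lineno, line


def read_sample_sheet(text: str) -> list[SampleInfo]:
    """Parse a TSV sample sheet: sample_id, cell_line, perturbation, stimulus, replicate."""
    rows = []
    header: list[str] | None = None
    for lineno, line in _lines(text):
        fields = line.split("\t")
        if header is None:
            header = fields
            expected = ["sample_id", "cell_line", "perturbation", "stimulus", "replicate"]
            if fields != expected:
                raise FormatError(
                    f"sample sheet line {lineno}: header must be {expected}, got {fields}"
                )
            continue
        if len(fields) != 5:
            raise FormatError(f"sample sheet line {lineno}: expected 5 fields, got {len(fields)}")
        sid, line_, pert, stim, rep = fields
        try:
            info = SampleInfo(sid, line_, pert, stim, int(rep))
        except ValueError as exc:
            raise FormatError(f"sample sheet line {lineno}: {exc}") from exc
        rows.append(info)
    if header is None:
        raise FormatError("empty sample sheet")
    ids = [s.sample_id for s in rows]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate sample ids in sample sheet")
    return rows


def read_expression_table(text: str, sample_sheet_text: str, mode: str = "counts") -> ExpressionMatrix:
    """Parse a gene x sample TSV against its sample sheet.

    The first column is the gene id; remaining column names must all appear
    in the sample sheet.  Column order of the result follows the sheet.
    """
    samples = read_sample_sheet(sample_sheet_text)
    by_id = {s.sample_id: s for s in samples}
    header: list[str] | None = None
    gene_ids: list[str] = []
    data: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in _lines(text):
        fields = line.split("\t")
        if header is None:
            header = fields[1:]
            unknown = [c for c in header if c not in by_id]
            if unknown:
                raise FormatError(
                    f"expression table line {lineno}: sample {unknown[0]!r} absent from sample sheet"
                )
            continue
        gene = fields[0]
        if gene in seen:
            raise FormatError(f"expression table line {lineno}: duplicate gene id {gene!r}")
        seen.add(gene)
        if len(fields) != len(header) + 1:
            raise FormatError(f"expression table line {lineno}: wrong field count")
        row = []
        for col, tok in zip(header, fields[1:]):
            try:
                v = float(tok)
            except ValueError as exc:
                raise FormatError(
                    f"expression table line {lineno}: non-numeric value {tok!r} in {col}"
                ) from exc
            if v < 0:
                raise FormatError(
                    f"expression table line {lineno}: negative value {tok} in {col}"
                )
            row.append(v)
        gene_ids.append(gene)
        data.append(row)
    if header is None:
        raise FormatError("empty expression table")
    df = pd.DataFrame(data, index=gene_ids, columns=header)
    # restrict the sheet to samples present, preserving sheet order
    used = [s for s in samples if s.sample_id in set(header)]
    df = df[[s.sample_id for s in used]]
    return ExpressionMatrix(values=df, samples=used, mode=mode)


def read_tss_bed(text: str) -> TssAnnotation:
    """Parse BED6 into one TSS per gene (start for +, end-1 for -)."""
    recs: dict[str, tuple[str, int, str]] = {}
    for lineno, line in _lines(text):
        if line.startswith(("track", "browser", "#")):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise FormatError(f"BED line {lineno}: expected 6 fields, got {len(fields)}")
        chrom, start, end, name, _score, strand = fields[:6]
        if strand not in ("+", "-"):
            raise FormatError(f"BED line {lineno}: missing or invalid strand {strand!r}")
        try:
            s, e = int(start), int(end)
        except ValueError as exc:
            raise FormatError(f"BED line {lineno}: non-integer coordinates") from exc
        if s < 0 or e <= s:
            raise FormatError(f"BED line {lineno}: invalid interval [{s}, {e})")
        if name in recs:
            raise FormatError(f"BED line {lineno}: duplicate gene name {name!r}")
        tss = s if strand == "+" else e - 1
        recs[name] = (chrom, tss, strand)
    table = pd.DataFrame.from_dict(recs, orient="index", columns=["chrom", "tss", "strand"])
    table.index.name = "gene"
    return TssAnnotation(table)


def read_bedgraph(text: str) -> SignalTrack:
    """Parse bedGraph text into a SignalTrack (track/header lines skipped)."""
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, line in _lines(text):
        if line.startswith(("track", "browser", "#")):
            continue
        fields = line.split()
        if len(fields) != 4:
            raise FormatError(f"bedGraph line {lineno}: expected 4 fields, got {len(fields)}")
        chrom, start, end, value = fields
        try:
            s, e, v = int(start), int(end), float(value)
        except ValueError as exc:
            raise FormatError(f"bedGraph line {lineno}: bad numeric field") from exc
        if e <= s:
            raise FormatError(f"bedGraph line {lineno}: end <= start")
        per_chrom.setdefault(chrom, []).append((s, e, v))
    intervals = {}
    for chrom, triples in per_chrom.items():
        arr = np.array(triples, dtype=float)
        intervals[chrom] = (arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])
    return SignalTrack(intervals)


def read_gmt(text: str) -> list[GeneSet]:
    """Parse GMT: name <TAB> description <TAB> member...; duplicates within a set collapse."""
    sets: list[GeneSet] = []
    names: set[str] = set()
    for lineno, line in _lines(text):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"GMT line {lineno}: expected >= 3 fields, got {len(fields)}")
        name, desc, *members = fields
        if name in names:
            raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
        names.add(name)
        uniq = list(dict.fromkeys(m for m in members if m))
        if not uniq:
            raise FormatError(f"GMT line {lineno}: set {name!r} has no members")
        sets.append(GeneSet(name=name, description=desc, members=tuple(uniq)))
    return sets


# ---------------------------------------------------------------------------
# writers (lossless round-trip with the readers above)
# ---------------------------------------------------------------------------


def write_expression_table(matrix: ExpressionMatrix) -> str:
    buf = _io.StringIO()
    buf.write("gene\t" + "\t".join(matrix.values.columns) + "\n")
    for gene, row in matrix.values.iterrows():
        buf.write(gene + "\t" + "\t".join(FLOAT_FMT % v for v in row) + "\n")
    return buf.getvalue()


def write_sample_sheet(samples: Sequence[SampleInfo]) -> str:
    lines = ["sample_id\tcell_line\tperturbation\tstimulus\treplicate"]
    for s in samples:
        lines.append(f"{s.sample_id}\t{s.cell_line}\t{s.perturbation}\t{s.stimulus}\t{s.replicate}")
    return "\n".join(lines) + "\n"


def write_tss_bed(tss: TssAnnotation) -> str:
    """Emit BED6; for '-' strand the record spans [tss, tss+1) so end-1 recovers the TSS."""
    lines = []
    for gene, rec in tss.table.iterrows():
        start = int(rec["tss"]) if rec["strand"] == "+" else int(rec["tss"])
        end = start + 1
        lines.append(f"{rec['chrom']}\t{start}\t{end}\t{gene}\t0\t{rec['strand']}")
    return "\n".join(lines) + "\n"


def write_bedgraph(track: SignalTrack) -> str:
    lines = []
    for chrom in track.chromosomes:
        starts, ends, values = track.intervals(chrom)
        for s, e, v in zip(starts, ends, values):
            lines.append(f"{chrom}\t{s}\t{e}\t{FLOAT_FMT % v}")
    return "\n".join(lines) + "\n"


def write_gmt(sets: Sequence[GeneSet]) -> str:
    lines = []
    for gs in sets:
        lines.append("\t".join([gs.name, gs.description, *gs.members]))
    return "\n".join(lines) + "\n"
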