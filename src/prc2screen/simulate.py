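"""Synthetic experiments with planted ground truth.

The generator emulates the study design the pipeline assumes: a 2x2
factorial (control vs SUZ12-knockdown crossed with unstimulated vs
interferon-gamma, three biological replicates per cell), negative-binomial
counts (variance mu + phi*mu^2) or log-normal intensities, with planted
gene classes:

* ``N-ISG`` — induced by IFN in both arms (induction fold);
* ``ZR-ISG`` — induced by IFN only after SUZ12 knockdown (the PRC2-
  repressed responders at the heart of the analysis);
* ``ZRG`` — basally derepressed by SUZ12 knockdown (derepression fold);
* ``silent`` — near-zero baseline; remaining genes are unregulated.

Planted promoter chromatin states (bivalent / K27-only / K4-only / none)
are linked to the classes: ZR-ISGs are bivalent with probability
``p_link``, encoding the hypothesis that PRC2-repressed responders carry
both H3K27me3 and H3K4me3.  Chromatin tracks are Gaussian-bump
enrichments over a flat background on a synthetic chromosome with
non-overlapping promoter windows, plus a flat control track.  Everything
is a pure function of config + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneSet,
    SampleInfo,
    SignalTrack,
    TssAnnotation,
    write_gmt,
)

CLASS_LABELS = ("N-ISG", "ZR-ISG", "ZRG", "silent", "none")
CHROM_STATES = ("bivalent", "k27_only", "k4_only", "none")


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 2000
    n_replicates: int = 3
    mean_range: tuple[float, float] = (10.0, 1000.0)   # log-uniform baseline
    dispersion: float = 0.05                           # phi: var = mu + phi mu^2
    frac_isg: float = 0.05
    frac_zr_isg: float = 0.05
    frac_zrg: float = 0.05
    frac_silent: float = 0.10
    induction_fold: float = 8.0
    derepression_fold: float = 4.0
    libsize_cv: float = 0.10        # log-normal sigma of library-size jitter
    silent_mean: float = 0.1
    p_link: float = 0.9             # P(ZR-ISG promoter is bivalent)
    mode: str = "counts"
    cell_line: str = "SIM1"
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.frac_isg + self.frac_zr_isg + self.frac_zrg + self.frac_silent
        if total > 1.0 + 1e-12:
            raise ValueError("class fractions sum above 1")
        for name in ("induction_fold", "derepression_fold"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates")


@dataclass(frozen=True)
class ChromConfig:
    background: float = 1.0         # B
    amplitude: float = 3.0          # A, peak/background ratio
    peak_sigma: float = 500.0       # bp
    noise_sigma: float = 0.0        # log-normal multiplicative noise scale
    bin_width: int = 100
    half_width: int = 5000
    spacing: int = 12000            # promoter spacing; no window overlap at +/-5 kb
    chrom: str = "chrSim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 1:
            raise ValueError("amplitude must be >= 1")
        if self.background <= 0:
            raise ValueError("background must be > 0")
        if self.spacing < 2 * self.half_width + self.bin_width:
            raise ValueError("windows overlap: spacing too small for the window")


@dataclass
class SyntheticTruth:
    table: pd.DataFrame  # index gene; columns: class_label, chrom_state, focal

    def genes_of_class(self, label: str) -> list[str]:
        return list(self.table.index[self.table["class_label"] == label])

    def to_tsv(self) -> str:
        lines = ["gene\tclass_label\tchrom_state\tfocal"]
        for gene, row in self.table.iterrows():
            lines.append(
                f"{gene}\t{row['class_label']}\t{row['chrom_state']}\t{int(row['focal'])}"
            )
        return "\n".join(lines) + "\n"


def _plant_classes(config: SimConfig, rng: np.random.Generator) -> list[str]:
    n = config.n_genes
    counts = {
        "N-ISG": round(config.frac_isg * n),
        "ZR-ISG": round(config.frac_zr_isg * n),
        "ZRG": round(config.frac_zrg * n),
        "silent": round(config.frac_silent * n),
    }
    labels = []
    for label, k in counts.items():
        labels.extend([label] * k)
    labels.extend(["none"] * (n - len(labels)))
    labels = np.array(labels, dtype=object)
    rng.shuffle(labels)
    return list(labels)


def _chrom_state(label: str, p_link: float, rng: np.random.Generator) -> str:
    if label == "ZR-ISG":
        return "bivalent" if rng.random() < p_link else "k4_only"
    if label == "N-ISG":
        return "k4_only"
    if label == "ZRG":
        return "k27_only" if rng.random() < p_link else "none"
    if label == "silent":
        return "k27_only" if rng.random() < 0.3 else "none"
    return "k4_only" if rng.random() < 0.5 else "none"


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, phi: float
) -> np.ndarray:
    """Negative binomial with variance mu + phi*mu^2 (Poisson when phi = 0)."""
    mu = np.clip(mu, 1e-9, None)
    if phi == 0:
        return rng.poisson(mu).astype(float)
    size = 1.0 / phi
    p = size / (size + mu)
    return rng.negative_binomial(size, p).astype(float)


def simulate_experiment(config: SimConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw a 2x2 factorial expression matrix with planted class structure."""
    rng = np.random.default_rng(config.seed)
    labels = _plant_classes(config, rng)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]

    lo, hi = config.mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes))
    base = np.where([l == "silent" for l in labels], config.silent_mean, base)

    conditions = [
        ("ctrl", "none"),
        ("ctrl", "ifng"),
        ("suz12_kd", "none"),
        ("suz12_kd", "ifng"),
    ]
    fold = np.ones((config.n_genes, len(conditions)))
    for gi, label in enumerate(labels):
        if label == "N-ISG":
            fold[gi, 1] = config.induction_fold       # ctrl + IFN
            fold[gi, 3] = config.induction_fold       # kd + IFN
        elif label == "ZR-ISG":
            fold[gi, 3] = config.induction_fold       # responsive only after kd
        elif label == "ZRG":
            fold[gi, 2] = config.derepression_fold    # basal derepression
            fold[gi, 3] = config.derepression_fold

    samples: list[SampleInfo] = []
    columns: dict[str, np.ndarray] = {}
    for ci, (pert, stim) in enumerate(conditions):
        for rep in range(1, config.n_replicates + 1):
            sid = f"{config.cell_line}_{pert}_{stim}_r{rep}"
            libfactor = float(np.exp(rng.normal(0.0, config.libsize_cv)))
            mu = base * fold[:, ci] * libfactor
            if config.mode == "counts":
                col = _nb_draw(rng, mu, config.dispersion)
            else:
                sigma = np.sqrt(np.log1p(config.dispersion + 1.0 / np.clip(mu, 1e-9, None)))
                col = mu * np.exp(rng.normal(0.0, sigma, size=len(mu)) - sigma**2 / 2)
            columns[sid] = col
            samples.append(SampleInfo(sid, config.cell_line, pert, stim, rep))

    values = pd.DataFrame(columns, index=genes)
    matrix = ExpressionMatrix(values=values, samples=samples, mode=config.mode)

    states = [_chrom_state(l, config.p_link, rng) for l in labels]
    truth = SyntheticTruth(
        pd.DataFrame(
            {
                "class_label": labels,
                "chrom_state": states,
                "focal": [l == "ZR-ISG" for l in labels],
            },
            index=genes,
        )
    )
    truth.table.index.name = "gene"
    return matrix, truth


def simulate_chromatin(
    truth: SyntheticTruth, config: ChromConfig
) -> tuple[dict[str, SignalTrack], TssAnnotation]:
    """Build H3K27me3/H3K4me3/control tracks and a TSS layout from the truth.

    Genes sit on one synthetic chromosome at ``spacing`` intervals on
    alternating strands.  Each mark implied by a gene's chromatin state
    gets a Gaussian bump of amplitude A over background B; the bump value
    is evaluated at distance max(0, |bin center - TSS| - b/2), a plateau
    at the two TSS-flanking bins, so the noise-free max bin/control ratio
    equals A exactly.  The control track is flat at B; the mark tracks
    carry multiplicative log-normal noise of scale ``noise_sigma``.
    """
    genes = list(truth.table.index)
    rng = np.random.default_rng(config.seed)
    b, w = config.bin_width, config.half_width
    first = config.half_width + config.bin_width  # keep windows clear of coord 0
    tss_pos = first + config.spacing * np.arange(len(genes))
    strands = np.where(np.arange(len(genes)) % 2 == 0, "+", "-")
    tss = TssAnnotation(
        pd.DataFrame(
            {"chrom": config.chrom, "tss": tss_pos, "strand": strands}, index=genes
        )
    )
    chrom_end = int(tss_pos[-1] + config.spacing)

    mark_of_state = {
        "h3k27me3": {"bivalent", "k27_only"},
        "h3k4me3": {"bivalent", "k4_only"},
    }
    offsets = np.arange(-w, w, b)
    centers = offsets + b / 2.0
    dist = np.maximum(np.abs(centers) - b / 2.0, 0.0)
    bump = 1.0 + (config.amplitude - 1.0) * np.exp(-(dist**2) / (2 * config.peak_sigma**2))

    tracks: dict[str, SignalTrack] = {}
    for mark, states in mark_of_state.items():
        starts: list[np.ndarray] = []
        ends: list[np.ndarray] = []
        values: list[np.ndarray] = []
        prev_end = 0
        for gi, gene in enumerate(genes):
            t = int(tss_pos[gi])
            win_start = t - w
            if win_start > prev_end:
                starts.append(np.array([prev_end]))
                ends.append(np.array([win_start]))
                values.append(np.array([config.background]))
            bin_starts = t + offsets
            level = (
                config.background * bump
                if truth.table.at[gene, "chrom_state"] in states
                else np.full(len(offsets), config.background)
            )
            if config.noise_sigma > 0:
                level = level * np.exp(rng.normal(0.0, config.noise_sigma, len(level)))
            starts.append(bin_starts)
            ends.append(bin_starts + b)
            values.append(level)
            prev_end = t + w
        if chrom_end > prev_end:
            starts.append(np.array([prev_end]))
            ends.append(np.array([chrom_end]))
            values.append(np.array([config.background]))
        tracks[mark] = SignalTrack(
            {
                config.chrom: (
                    np.concatenate(starts),
                    np.concatenate(ends),
                    np.concatenate(values),
                )
            }
        )
    tracks["control"] = SignalTrack(
        {
            config.chrom: (
                np.array([0]),
                np.array([chrom_end]),
                np.array([config.background]),
            )
        }
    )
    return tracks, tss


def simulate_panel(
    base: SimConfig,
    n_lines: int,
    unique_fraction: float = 0.7,
    master_seed: int | None = None,
) -> tuple[dict[str, ExpressionMatrix], dict[str, SyntheticTruth]]:
    """Per-line experiments sharing a core ZR-ISG set plus line-private sets.

    ``unique_fraction`` of each line's planted ZR-ISGs are private to that
    line; the rest come from a shared core, emulating a core interferon
    program plus line-specific PRC2 targets.  Line seeds derive from the
    master seed.
    """
    if n_lines < 2:
        raise ValueError("panel needs >= 2 lines")
    if not 0.0 <= unique_fraction <= 1.0:
        raise ValueError("unique_fraction must be in [0, 1]")
    if master_seed is None:
        master_seed = base.seed
    ss = np.random.SeedSequence(master_seed)
    layout_rng = np.random.default_rng(ss.spawn(1)[0])

    n_zr = round(base.frac_zr_isg * base.n_genes)
    n_private = round(unique_fraction * n_zr)
    n_core = n_zr - n_private
    all_idx = np.arange(base.n_genes)
    layout_rng.shuffle(all_idx)
    core = set(all_idx[:n_core])
    pool = list(all_idx[n_core:])
    private: dict[int, set[int]] = {}
    pos = 0
    for li in range(n_lines):
        private[li] = set(pool[pos : pos + n_private])
        pos += n_private
        if pos + n_private > len(pool):
            raise ValueError("not enough genes for disjoint private ZR-ISG sets")

    matrices: dict[str, ExpressionMatrix] = {}
    truths: dict[str, SyntheticTruth] = {}
    genes = [f"G{i:05d}" for i in range(base.n_genes)]
    for li in range(n_lines):
        line = f"LINE{li + 1}"
        seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        # silent genes are excluded from panel lines: a ZR-ISG re-planted on
        # a silent baseline would be undetectable by construction
        cfg = replace(base, cell_line=line, seed=seed, frac_zr_isg=0.0, frac_silent=0.0)
        matrix, truth = simulate_experiment(cfg)
        # re-plant the line's ZR-ISGs deterministically over the shared layout
        zr_genes = [genes[i] for i in sorted(core | private[li])]
        line_rng = np.random.default_rng(seed + 1)
        tt = truth.table
        cols_kd_ifng = matrix.group_columns(line, "suz12_kd", "ifng")
        for g in zr_genes:
            tt.at[g, "class_label"] = "ZR-ISG"
            tt.at[g, "focal"] = True
            tt.at[g, "chrom_state"] = (
                "bivalent" if line_rng.random() < base.p_link else "k4_only"
            )
            matrix.values.loc[g, cols_kd_ifng] *= base.induction_fold
        matrices[line] = matrix
        truths[line] = truth
    return matrices, truths


def make_genesets(
    truth: SyntheticTruth,
    decoy_count: int = 25,
    decoy_size_range: tuple[int, int] = (20, 100),
    contamination: int = 0,
    focal_name: str = "CCRI_LIKE",
    seed: int = 0,
) -> list[GeneSet]:
    """Focal set = planted ZR-ISGs (+ optional contamination) plus uniform decoys."""
    rng = np.random.default_rng(seed)
    genes = list(truth.table.index)
    focal_members = truth.genes_of_class("ZR-ISG")
    if contamination > 0:
        others = [g for g in genes if g not in set(focal_members)]
        extra = rng.choice(len(others), size=contamination, replace=False)
        focal_members = focal_members + [others[i] for i in extra]
    sets = []
    if focal_members:
        sets.append(
            GeneSet(focal_name, "planted PRC2-repressed responders", tuple(focal_members))
        )
    lo, hi = decoy_size_range
    for d in range(decoy_count):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(genes), size=size, replace=False)
        sets.append(
            GeneSet(f"DECOY_{d:03d}", "uniform random set", tuple(genes[i] for i in sorted(idx)))
        )
    return sets
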