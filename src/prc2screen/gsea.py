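"""Preranked gene-set enrichment on probability-ranked gene lists.

Genes up-regulated by SUZ12 knockdown (log2FC > 0, differential
probability > 0.5) are ranked by decreasing probability and scored
against gene sets with the weighted Kolmogorov-Smirnov-like running sum:
a hit at rank i adds w_i^p / sum(w^p over hits), a miss subtracts
1/(N - N_hits); the enrichment score (ES) is the running-sum value of
greatest absolute deviation from zero.  Significance comes from a
gene-tag permutation null (random same-size subsets of the ranked list),
with sign-matched NES normalization and a GSEA-style pooled FDR q.  The
leading edge is the set members at ranks up to (ES > 0) or from (ES < 0)
the running-sum peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import ContrastResult
from .io import GeneSet, ParamConfig


@dataclass
class RankedList:
    """Genes ordered by decreasing weight (w = P_DE), after the ranking filter."""

    genes: list[str]
    weights: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.weights):
            raise ValueError("genes and weights differ in length")
        if len(self.genes) == 0:
            raise ValueError("empty ranked list")
        if (np.diff(self.weights) > 0).any():
            raise ValueError("weights must be non-increasing")
        self._index = {g: i for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)

    def hit_positions(self, gene_set: GeneSet) -> np.ndarray:
        pos = sorted(self._index[g] for g in gene_set.members if g in self._index)
        return np.asarray(pos, dtype=np.int64)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p: float
    q: float | None
    peak_index: int
    leading_edge: list[str]
    n_hits: int
    n_perm: int
    seed: int
    null_flagged: bool = False
    null_nes: np.ndarray | None = field(default=None, repr=False)


def build_ranked_list(
    contrast: ContrastResult, rank_prob_cutoff: float = 0.5
) -> RankedList:
    """Keep genes with M > 0 and P_DE > cutoff; sort by P_DE desc, M desc, id."""
    t = contrast.table
    keep = t[(t["M"] > 0) & (t["P_DE"] > rank_prob_cutoff)]
    if keep.empty:
        raise ValueError("empty ranked list after the M > 0 / P_DE filter")
    keep = keep.assign(_gene=keep.index)
    keep = keep.sort_values(
        ["P_DE", "M", "_gene"], ascending=[False, False, True], kind="stable"
    )
    return RankedList(
        genes=list(keep.index),
        weights=keep["P_DE"].to_numpy(dtype=float),
        provenance=f"{contrast.spec.cell_line}: M>0 & P_DE>{rank_prob_cutoff}",
    )


def _running_sum(weights: np.ndarray, hits: np.ndarray, exponent: float) -> np.ndarray:
    n = len(weights)
    is_hit = np.zeros(n, dtype=bool)
    is_hit[hits] = True
    wp = np.abs(weights) ** exponent
    hit_total = wp[is_hit].sum()
    step = np.where(is_hit, wp / hit_total, -1.0 / (n - len(hits)))
    return np.cumsum(step)


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, exponent: float = 1.0
) -> tuple[float, np.ndarray, int]:
    """ES, the full running sum, and the 0-based peak index.

    The peak is the running-sum value of greatest absolute deviation from
    zero; on an exact magnitude tie a positive peak is preferred over a
    negative one, then the earliest index wins.  A set covering the whole
    list has ES 1 by convention.
    """
    hits = ranked.hit_positions(gene_set)
    if len(hits) == 0:
        raise ValueError(f"gene set {gene_set.name!r} does not overlap the ranked list")
    n = len(ranked)
    if len(hits) == n:
        return 1.0, np.ones(n), 0
    rs = _running_sum(ranked.weights, hits, exponent)
    peak = _peak_index(rs)
    # cumsum round-off can leave the extremum epsilon outside [-1, 1]
    return float(np.clip(rs[peak], -1.0, 1.0)), rs, int(peak)


def _peak_index(rs: np.ndarray) -> int:
    pos_max = rs.max()
    neg_min = rs.min()
    # magnitude ties (within float tolerance) prefer the positive peak
    tol = 1e-12 * max(pos_max, -neg_min, 1.0)
    if pos_max >= -neg_min - tol and pos_max > 0:
        return int(np.argmax(rs))
    if -neg_min > pos_max:
        return int(np.argmin(rs))
    # all-zero running sum (degenerate): earliest index
    return 0


def _null_es(
    weights_p: np.ndarray, n_hits: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised ES of random same-size hit subsets of the ranked list.

    Running-sum extrema occur only immediately after a hit (candidate
    maxima) or immediately before one (candidate minima), so each
    permutation needs just the sorted hit positions.
    """
    n = len(weights_p)
    miss_step = 1.0 / (n - n_hits)
    perm = np.empty((n_perm, n_hits), dtype=np.int64)
    for r in range(n_perm):
        perm[r] = rng.choice(n, size=n_hits, replace=False)
    perm.sort(axis=1)
    w = weights_p[perm]
    cum = np.cumsum(w, axis=1)
    cum /= cum[:, -1][:, None]
    j = np.arange(1, n_hits + 1)
    # value right after hit j: cum_j - (pos_j + 1 - j) * miss
    after = cum - (perm + 1 - j) * miss_step
    # value right before hit j: cum_{j-1} - (pos_j - (j-1)) * miss
    before = np.concatenate([np.zeros((n_perm, 1)), cum[:, :-1]], axis=1) - (
        perm - (j - 1)
    ) * miss_step
    pos_max = after.max(axis=1)
    neg_min = np.minimum(before.min(axis=1), 0.0)
    tol = 1e-12 * np.maximum(np.maximum(pos_max, -neg_min), 1.0)
    return np.clip(np.where(pos_max >= -neg_min - tol, pos_max, neg_min), -1.0, 1.0)


def permutation_test(
    ranked: RankedList,
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int = 0,
    exponent: float = 1.0,
) -> EnrichmentResult:
    """Gene-tag permutation significance for one set.

    Nominal p uses the add-one rule on same-sign null scores:
    ``p = (1 + #{|null| >= |ES|, same sign}) / (1 + #{same sign})``;
    NES = ES / mean(|null ES| of the same sign).  If no null score shares
    the observed sign the result is flagged and p = 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    es, _, peak = enrichment_score(ranked, gene_set, exponent)
    hits = ranked.hit_positions(gene_set)
    if len(hits) == len(ranked):
        # set covers the whole list: every permutation reproduces it exactly
        return EnrichmentResult(
            set_name=gene_set.name, es=es, nes=1.0, p=1.0, q=None,
            peak_index=peak, leading_edge=list(ranked.genes), n_hits=len(hits),
            n_perm=n_perm, seed=seed, null_flagged=False,
            null_nes=np.ones(n_perm),
        )
    rng = np.random.default_rng(seed)
    wp = np.abs(ranked.weights) ** exponent
    null = _null_es(wp, len(hits), n_perm, rng)
    same_sign = null > 0 if es >= 0 else null < 0
    n_sign = int(same_sign.sum())
    flagged = n_sign == 0
    if flagged:
        p, nes = 1.0, float("nan")
        null_nes = np.array([])
    else:
        extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
        p = (1 + extreme) / (1 + n_sign)
        denom = np.abs(null[same_sign]).mean()
        nes = es / denom
        null_nes = null[same_sign] / denom
    le = leading_edge(ranked, gene_set, es, peak)
    return EnrichmentResult(
        set_name=gene_set.name,
        es=es,
        nes=nes,
        p=p,
        q=None,
        peak_index=peak,
        leading_edge=le,
        n_hits=len(hits),
        n_perm=n_perm,
        seed=seed,
        null_flagged=flagged,
        null_nes=null_nes,
    )


def leading_edge(
    ranked: RankedList, gene_set: GeneSet, es: float, peak_index: int
) -> list[str]:
    """Set members at ranks <= peak (ES > 0) or >= peak (ES < 0), list order."""
    hits = ranked.hit_positions(gene_set)
    if es >= 0:
        sel = hits[hits <= peak_index]
    else:
        sel = hits[hits >= peak_index]
    return [ranked.genes[i] for i in sel]


def fdr_q(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """GSEA-style pooled FDR q per set, computed separately by ES sign.

    q(S) = [fraction of pooled same-sign null NES at least as extreme as
    NES(S)] / [fraction of observed same-sign NES at least as extreme],
    clipped to [0, 1] and monotonized so q never decreases as |NES|
    shrinks.  Results are returned with ``q`` filled in.
    """
    if not results:
        raise ValueError("empty result collection")
    for sign in (1, -1):
        group = [
            r
            for r in results
            if not r.null_flagged and np.isfinite(r.nes) and np.sign(r.es) == sign
        ]
        if not group:
            continue
        pooled = np.concatenate([r.null_nes for r in group])
        obs = np.array([r.nes for r in group])
        for r in group:
            if sign > 0:
                null_frac = (pooled >= r.nes).mean() if len(pooled) else 1.0
                obs_frac = (obs >= r.nes).mean()
            else:
                null_frac = (pooled <= r.nes).mean() if len(pooled) else 1.0
                obs_frac = (obs <= r.nes).mean()
            r.q = float(np.clip(null_frac / obs_frac, 0.0, 1.0))
        # monotonize: sort by decreasing |NES|; q non-decreasing down the list
        group.sort(key=lambda r: -abs(r.nes))
        best = 0.0
        for r in group:
            best = max(best, r.q)
            r.q = best
    for r in results:
        if r.q is None:
            r.q = 1.0
    return results


@dataclass
class ScreenReport:
    """Per-line enrichment calls plus the focal-set induced-gene matrix."""

    enrichments: dict[str, list[EnrichmentResult]]   # line -> results
    significant: dict[str, list[str]]                # line -> set names passing cuts
    skipped_lines: list[str]                         # lines with no computable ranking
    focal_set: str | None
    induced_matrix: pd.DataFrame | None              # focal genes x lines, bool


def pathway_screen(
    contrasts: dict[str, ContrastResult],
    collection: list[GeneSet],
    params: ParamConfig,
    focal_set: str | None = None,
    master_seed: int | None = None,
) -> ScreenReport:
    """Run the preranked enrichment screen across cell lines.

    Per line: build the ranked list (lines whose filter empties are
    recorded as not computable), score every set, compute FDR q across the
    collection, and call sets significant at p < alpha_nom and
    q < alpha_fdr.  For the focal set, a gene x line boolean matrix marks
    genes significantly induced by the perturbation (P_DE > prob_cutoff
    and M > 0).  Per-(line, set) seeds derive from the master seed.
    """
    if master_seed is None:
        master_seed = params.seed
    enrichments: dict[str, list[EnrichmentResult]] = {}
    significant: dict[str, list[str]] = {}
    skipped: list[str] = []
    lines = sorted(contrasts)
    for li, line in enumerate(lines):
        try:
            ranked = build_ranked_list(contrasts[line], params.rank_prob_cutoff)
        except ValueError:
            skipped.append(line)
            continue
        results = []
        for si, gs in enumerate(collection):
            seed = int(
                np.random.SeedSequence(master_seed, spawn_key=(li, si)).generate_state(1)[0]
                % (2**31)
            )
            try:
                res = permutation_test(
                    ranked, gs, n_perm=params.n_perm, seed=seed,
                    exponent=params.gsea_exponent,
                )
            except ValueError:
                continue  # no overlap with this line's ranking
            results.append(res)
        if results:
            fdr_q(results)
        enrichments[line] = results
        significant[line] = [
            r.set_name
            for r in results
            if r.es > 0 and r.p < params.alpha_nom and r.q < params.alpha_fdr
        ]
    induced = None
    if focal_set is not None:
        focal = next((gs for gs in collection if gs.name == focal_set), None)
        if focal is None:
            raise ValueError(f"focal set {focal_set!r} not in the collection")
        cols = {}
        for line in lines:
            t = contrasts[line].table
            present = [g for g in focal.members if g in t.index]
            flags = (t.loc[present, "P_DE"] > params.prob_cutoff) & (
                t.loc[present, "M"] > 0
            )
            cols[line] = flags
        induced = pd.DataFrame(cols).reindex(list(focal.members)).fillna(False)
        induced.index.name = "gene"
    return ScreenReport(
        enrichments=enrichments,
        significant=significant,
        skipped_lines=skipped,
        focal_set=focal_set,
        induced_matrix=induced,
    )
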