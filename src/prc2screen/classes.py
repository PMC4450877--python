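"""Factorial gene-class grammar and cross-cell-line specificity.

A gene is an ISG (interferon-gamma stimulated gene) if IFN induces it
>= 2-fold with high differential probability in at least one arm — control
or perturbed — because responsiveness can be unmasked only after
perturbation (e.g. BRG1 reconstitution in BRG1-deficient cells, or PRC2
depletion).  On top of that, SUZ12-knockdown and BRG1-reconstitution
contrasts flag basal repression/stimulation (``z_basal``, ``br_basal``)
and enhanced induction (``z_induction``, ``br_induction``), and the flag
combination maps to a canonical grammar label such as ``ZR-ISG``
(SUZ12-Repressed ISG), ``N-ISG`` (ISG not PRC2-regulated), ``ZRG``
(SUZ12-repressed basal) or ``BrS/ZRG`` (co-regulated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .diffexpr import ContrastResult
from .io import ParamConfig

FLAG_NAMES = ("isg", "z_basal", "z_induction", "br_basal", "br_induction")


@dataclass
class GeneClassTable:
    """Per-gene boolean regulation flags plus the canonical grammar label."""

    cell_line: str
    table: pd.DataFrame  # index gene; bool columns FLAG_NAMES + str column label

    def genes_with_label(self, label: str) -> set[str]:
        return set(self.table.index[self.table["label"] == label])

    def to_tsv(self) -> str:
        lines = ["gene\t" + "\t".join(FLAG_NAMES) + "\tlabel"]
        for gene, row in self.table.iterrows():
            flags = "\t".join(str(int(row[f])) for f in FLAG_NAMES)
            lines.append(f"{gene}\t{flags}\t{row['label']}")
        return "\n".join(lines) + "\n"


@dataclass
class SpecificityResult:
    label: str
    line_counts: pd.Series          # per gene: number of lines carrying (gene, label)
    fraction_unique: float          # fraction of genes in exactly 1 line
    fraction_le2: float             # fraction of genes in <= 2 lines


def label_grammar(flags: dict[str, bool]) -> str:
    """Map a flag combination to the canonical grammar label.

    Br part ("BrS") if any BRG1 flag, Z part ("ZR") if any SUZ12 flag,
    joined by "/" in Br-then-Z order; suffix "-ISG" for responders, "G"
    otherwise; no parts at all gives "N-ISG" / "N".
    """
    unknown = set(flags) - set(FLAG_NAMES)
    if unknown:
        raise ValueError(f"unknown flags: {sorted(unknown)}")
    f = {name: bool(flags.get(name, False)) for name in FLAG_NAMES}
    if (f["z_induction"] or f["br_induction"]) and not f["isg"]:
        raise ValueError("induction flag requires isg")
    parts = []
    if f["br_basal"] or f["br_induction"]:
        parts.append("BrS")
    if f["z_basal"] or f["z_induction"]:
        parts.append("ZR")
    stem = "/".join(parts)
    if f["isg"]:
        return (stem + "-ISG") if stem else "N-ISG"
    return (stem + "G") if stem else "N"


def _passes(m: float, p: float, params: ParamConfig) -> bool:
    """Fold >= theta_FC (inclusive) and probability > theta_P (strict)."""
    return (2.0 ** m >= params.fc_cutoff) and (p > params.prob_cutoff)


def classify_factorial(
    i_ctrl: ContrastResult,
    params: ParamConfig,
    i_suz12: ContrastResult | None = None,
    b_suz12: ContrastResult | None = None,
    i_brg1: ContrastResult | None = None,
    b_brg1: ContrastResult | None = None,
    cell_line: str | None = None,
) -> GeneClassTable:
    """Assign regulation flags and grammar labels from per-arm contrasts.

    ``i_ctrl``: IFN induction in the control arm (+IFN vs -IFN | ctrl).
    ``i_suz12`` / ``i_brg1``: IFN induction in the perturbed arm.
    ``b_suz12`` / ``b_brg1``: basal perturbation effect (pert -IFN vs
    ctrl -IFN).  At least one perturbation axis must be supplied.

    Rules (fold cutoffs inclusive >=, probability cutoffs strict >):
    ``isg`` — induction passes in the control OR any perturbed arm;
    ``z_basal``/``br_basal`` — the basal contrast passes;
    ``z_induction``/``br_induction`` — isg AND the induction-fold ratio
    2^(M_pert - M_ctrl) >= theta_FC AND P_DE of the perturbed-arm
    induction > theta_P.
    """
    if i_suz12 is None and i_brg1 is None:
        raise ValueError("missing contrast arm: need i_suz12 and/or i_brg1")
    if cell_line is None:
        cell_line = i_ctrl.spec.cell_line
    genes = i_ctrl.table.index
    for other in (i_suz12, b_suz12, i_brg1, b_brg1):
        if other is not None and not other.table.index.equals(genes):
            raise ValueError("contrast arms cover different gene sets")

    def col(res: ContrastResult | None, name: str) -> np.ndarray | None:
        return None if res is None else res.table[name].to_numpy()

    m_ic, p_ic = col(i_ctrl, "M"), col(i_ctrl, "P_DE")
    isg = (2.0 ** m_ic >= params.fc_cutoff) & (p_ic > params.prob_cutoff)

    flags = {name: np.zeros(len(genes), dtype=bool) for name in FLAG_NAMES}

    def induction_arm(i_pert: ContrastResult | None) -> tuple[np.ndarray, np.ndarray]:
        """(passes-as-isg, enhanced-induction) vectors for one perturbed arm."""
        if i_pert is None:
            z = np.zeros(len(genes), dtype=bool)
            return z, z
        m_ip, p_ip = col(i_pert, "M"), col(i_pert, "P_DE")
        arm_isg = (2.0 ** m_ip >= params.fc_cutoff) & (p_ip > params.prob_cutoff)
        enhanced = (2.0 ** (m_ip - m_ic) >= params.fc_cutoff) & (p_ip > params.prob_cutoff)
        return arm_isg, enhanced

    z_arm_isg, z_enh = induction_arm(i_suz12)
    br_arm_isg, br_enh = induction_arm(i_brg1)
    flags["isg"] = isg | z_arm_isg | br_arm_isg
    flags["z_induction"] = flags["isg"] & z_enh
    flags["br_induction"] = flags["isg"] & br_enh
    if b_suz12 is not None:
        flags["z_basal"] = (2.0 ** col(b_suz12, "M") >= params.fc_cutoff) & (
            col(b_suz12, "P_DE") > params.prob_cutoff
        )
    if b_brg1 is not None:
        flags["br_basal"] = (2.0 ** col(b_brg1, "M") >= params.fc_cutoff) & (
            col(b_brg1, "P_DE") > params.prob_cutoff
        )

    table = pd.DataFrame(flags, index=genes)
    table["label"] = [
        label_grammar({name: bool(table.at[g, name]) for name in FLAG_NAMES})
        for g in genes
    ]
    table.index.name = "gene"
    return GeneClassTable(cell_line=cell_line, table=table)


def cross_line_specificity(
    tables: dict[str, GeneClassTable], label: str
) -> SpecificityResult:
    """How private a class label is to individual cell lines.

    Over the union of genes carrying ``label`` in any line, counts carrying
    lines per gene and reports the fraction seen in exactly one line and in
    at most two.  An absent label yields an empty (NaN-fraction) result.
    """
    if len(tables) < 2:
        raise ValueError("specificity needs >= 2 cell lines")
    carriers: dict[str, int] = {}
    for tab in tables.values():
        for gene in tab.genes_with_label(label):
            carriers[gene] = carriers.get(gene, 0) + 1
    counts = pd.Series(carriers, dtype=int).sort_index()
    if counts.empty:
        return SpecificityResult(label, counts, float("nan"), float("nan"))
    frac1 = float((counts == 1).mean())
    frac2 = float((counts <= 2).mean())
    return SpecificityResult(label, counts, frac1, frac2)


def cluster_by_probability(
    prob_table: pd.DataFrame, n_clusters: int | None = None
) -> tuple[list[str], pd.Series, np.ndarray]:
    """Agglomerative clustering of genes by their P_DE profile across lines.

    Euclidean distance, average linkage; genes are pre-sorted by id so leaf
    order is deterministic with ties broken by gene id.  Returns the leaf
    ordering, flat cluster labels (``maxclust`` cut when ``n_clusters`` is
    given, else all ones), and the linkage matrix.
    """
    if len(prob_table) < 2:
        if len(prob_table) == 1:
            g = list(prob_table.index)
            return g, pd.Series([1], index=prob_table.index), np.empty((0, 4))
        raise ValueError("need >= 1 gene")
    if not np.isfinite(prob_table.to_numpy()).all():
        raise ValueError("non-finite values in probability table")
    ordered = prob_table.sort_index(kind="stable")
    z = hierarchy.linkage(pdist(ordered.to_numpy()), method="average")
    leaves = hierarchy.leaves_list(z)
    leaf_genes = [ordered.index[i] for i in leaves]
    if n_clusters is None:
        labels = pd.Series(1, index=ordered.index)
    else:
        flat = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
        labels = pd.Series(flat, index=ordered.index)
    return leaf_genes, labels, z
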