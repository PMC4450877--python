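"""End-to-end orchestration: simulate -> classify -> chromatin -> screen.

The pipeline wires the stages together in the order the analysis runs on
real data: normalization and per-contrast differential probabilities; the
factorial response-class grammar; promoter H3K27me3 positivity and its
class association; K-means bivalency states with CID ordering; the
preranked enrichment screen across cell lines; and cross-line class
specificity.  Every stage writes a TSV and every number in the summary is
recomputable from those TSVs.  All randomness flows from one master seed
through named substreams, so one seed yields a byte-identical bundle.

The "siSUZ12 response" contrast used for CID ordering, induced flags and
the enrichment ranking is knockdown-vs-control under interferon: that arm
exposes both basally derepressed genes and responders whose induction
PRC2 had silenced.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import bivalency as bv
from . import chromatin as ch
from . import classes as cl
from . import diffexpr as dx
from . import gsea
from . import simulate as synth
from .io import (
    ExpressionMatrix,
    ParamConfig,
    write_bedgraph,
    write_expression_table,
    write_gmt,
    write_sample_sheet,
    write_tss_bed,
)


@dataclass
class RunConfig:
    out_dir: Path
    params: ParamConfig = field(default_factory=ParamConfig)
    sim: synth.SimConfig = field(default_factory=synth.SimConfig)
    chrom: synth.ChromConfig = field(default_factory=synth.ChromConfig)
    n_lines: int = 3
    unique_fraction: float = 0.7
    decoy_count: int = 25
    seed: int = 0


def _log(msg: str, t0: float) -> None:
    print(f"[prc2screen +{time.perf_counter() - t0:7.2f}s] {msg}", file=sys.stderr)


def standard_contrasts(
    matrix: ExpressionMatrix, cell_line: str, pseudocount: float
) -> dict[str, dx.ContrastResult]:
    """The three contrasts of the 2x2 design used throughout.

    ``i_ctrl``: IFN induction in the control arm; ``i_kd``: IFN induction
    after SUZ12 knockdown; ``b_kd``: basal knockdown effect; ``kd_ifng``:
    knockdown vs control under IFN (the siSUZ12-response contrast).
    """
    norm = dx.normalize(matrix)
    specs = {
        "i_ctrl": dx.ContrastSpec(cell_line, ("ctrl", "ifng"), ("ctrl", "none")),
        "i_kd": dx.ContrastSpec(cell_line, ("suz12_kd", "ifng"), ("suz12_kd", "none")),
        "b_kd": dx.ContrastSpec(cell_line, ("suz12_kd", "none"), ("ctrl", "none")),
        "kd_ifng": dx.ContrastSpec(cell_line, ("suz12_kd", "ifng"), ("ctrl", "ifng")),
    }
    return {name: dx.contrast(norm, spec, pseudocount) for name, spec in specs.items()}


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Execute the full simulate-first pipeline; returns the summary dict.

    Stage failures abort with the failing stage named; partial outputs
    written before the failure are retained.
    """
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.params
    ss = np.random.SeedSequence(config.seed)
    sub = {name: int(s.generate_state(1)[0] % (2**31))
           for name, s in zip(("panel", "chrom", "sets", "kmeans", "screen"), ss.spawn(5))}
    summary: dict[str, object] = {"seed": config.seed}

    stage = "simulate"
    try:
        base = replace(config.sim, seed=sub["panel"])
        matrices, truths = synth.simulate_panel(
            base, config.n_lines, config.unique_fraction, master_seed=sub["panel"]
        )
        lines = sorted(matrices)
        for line in lines:
            (out / f"expression_{line}.tsv").write_text(write_expression_table(matrices[line]))
            (out / f"samples_{line}.tsv").write_text(write_sample_sheet(matrices[line].samples))
            (out / f"truth_{line}.tsv").write_text(truths[line].to_tsv())
        _log(f"simulated {config.n_lines} lines x {base.n_genes} genes", t0)

        stage = "diffexpr+classify"
        class_tables: dict[str, cl.GeneClassTable] = {}
        kd_contrasts: dict[str, dx.ContrastResult] = {}
        for line in lines:
            con = standard_contrasts(matrices[line], line, params.pseudocount)
            kd_contrasts[line] = con["kd_ifng"]
            (out / f"contrast_kd_ifng_{line}.tsv").write_text(con["kd_ifng"].to_tsv())
            table = cl.classify_factorial(
                con["i_ctrl"], params, i_suz12=con["i_kd"], b_suz12=con["b_kd"],
                cell_line=line,
            )
            class_tables[line] = table
            (out / f"classes_{line}.tsv").write_text(table.to_tsv())
        zr_counts = {line: len(class_tables[line].genes_with_label("ZR-ISG")) for line in lines}
        summary["zr_isg_counts"] = zr_counts
        _log(f"classified; ZR-ISG counts {zr_counts}", t0)

        stage = "chromatin"
        line0 = lines[0]
        truth0 = truths[line0]
        chrom_cfg = replace(config.chrom, seed=sub["chrom"])
        tracks, tss = synth.simulate_chromatin(truth0, chrom_cfg)
        for mark, track in tracks.items():
            (out / f"{mark}.bedgraph").write_text(write_bedgraph(track))
        (out / "tss.bed").write_text(write_tss_bed(tss))
        k27 = ch.bin_promoter_signal(
            tracks["h3k27me3"], tss, params.window_half_width, params.bin_width, "h3k27me3"
        )
        k4 = ch.bin_promoter_signal(
            tracks["h3k4me3"], tss, params.window_half_width, params.bin_width, "h3k4me3"
        )
        ctrl_levels = ch.control_levels(
            tracks["control"], tss, half_width=params.window_half_width,
            bin_width=params.bin_width,
        )
        positivity = ch.call_positivity(k27, ctrl_levels, params.positivity_ratio)
        pos_out = positivity.copy()
        pos_out.insert(0, "gene", pos_out.index)
        pos_out.to_csv(out / f"positivity_{line0}.tsv", sep="\t", index=False,
                       float_format="%.8g")
        zr = class_tables[line0].genes_with_label("ZR-ISG")
        nisg = class_tables[line0].genes_with_label("N-ISG")
        if zr and nisg:
            p_assoc, odds, table2 = ch.positivity_class_association(
                positivity, sorted(zr), sorted(nisg)
            )
            summary["positivity_fisher"] = {
                "p": p_assoc, "odds_ratio": odds, "table": table2.tolist(),
            }
        _log("chromatin positivity done", t0)

        stage = "bivalency"
        features = bv.bivalency_features(k27, k4)
        raw = bv.kmeans_cluster(
            features, params.n_clusters, seed=sub["kmeans"],
            n_restarts=params.kmeans_restarts,
        )
        kd = kd_contrasts[line0].table
        clustering = bv.assign_cids(raw, kd["M"])
        (out / f"bivalency_{line0}.tsv").write_text(clustering.to_tsv())
        induced = (kd["P_DE"] > params.prob_cutoff) & (kd["M"] > 0)
        props = bv.induced_proportion_by_cid(clustering, induced, params.cid_split)
        summary["cid_induced_proportions"] = props
        _log(f"bivalency CID proportions {props}", t0)

        stage = "screen"
        # the focal pathway is the union of planted responders across lines
        # (a shared pathway whose line-specific members drive per-line hits)
        union_truth = truths[line0].table.copy()
        in_union = union_truth.index.isin(
            set().union(*(t.genes_of_class("ZR-ISG") for t in truths.values()))
        )
        union_truth["class_label"] = np.where(in_union, "ZR-ISG", "none")
        genesets = synth.make_genesets(
            synth.SyntheticTruth(union_truth),
            decoy_count=config.decoy_count, seed=sub["sets"],
        )
        (out / "genesets.gmt").write_text(write_gmt(genesets))
        report = gsea.pathway_screen(
            kd_contrasts, genesets, params, focal_set="CCRI_LIKE",
            master_seed=sub["screen"],
        )
        sig = {line: sorted(names) for line, names in report.significant.items()}
        summary["significant_sets"] = sig
        summary["focal_hit_lines"] = sorted(
            line for line, names in sig.items() if "CCRI_LIKE" in names
        )
        enr_lines = ["line\tset\tes\tnes\tp\tq\tn_leading_edge"]
        for line in lines:
            for r in report.enrichments.get(line, []):
                enr_lines.append(
                    f"{line}\t{r.set_name}\t{r.es:.8g}\t{r.nes:.8g}"
                    f"\t{r.p:.8g}\t{r.q:.8g}\t{len(r.leading_edge)}"
                )
        (out / "enrichment.tsv").write_text("\n".join(enr_lines) + "\n")
        if report.induced_matrix is not None:
            im = report.induced_matrix.astype(int)
            im.to_csv(out / "focal_induced_matrix.tsv", sep="\t")
        _log(f"screen significant {sig}", t0)

        stage = "specificity"
        spec_res = cl.cross_line_specificity(class_tables, "ZR-ISG")
        summary["zr_isg_specificity"] = {
            "fraction_unique": spec_res.fraction_unique,
            "fraction_le2": spec_res.fraction_le2,
        }
        _log("specificity done", t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "summary.tsv").write_text(_summary_tsv(summary))
    _log("summary written", t0)
    return summary


def _summary_tsv(summary: dict[str, object]) -> str:
    """Flatten the summary into a deterministic two-column TSV."""
    lines = ["key\tvalue"]

    def emit(key: str, value) -> None:
        if isinstance(value, dict):
            for k in sorted(value, key=str):
                emit(f"{key}.{k}", value[k])
        elif isinstance(value, (list, tuple)):
            lines.append(f"{key}\t{','.join(str(v) for v in value)}")
        elif isinstance(value, float):
            lines.append(f"{key}\t{value:.8g}")
        elif value is None:
            lines.append(f"{key}\tNA")
        else:
            lines.append(f"{key}\t{value}")

    for key in sorted(summary, key=str):
        emit(key, summary[key])
    return "\n".join(lines) + "\n"
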