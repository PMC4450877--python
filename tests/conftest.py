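import numpy as np
import pandas as pd
import pytest

from prc2screen import (
    ContrastResult,
    ContrastSpec,
    ExpressionMatrix,
    ParamConfig,
    SampleInfo,
    SimConfig,
    simulate_experiment,
    standard_contrasts,
)


@pytest.fixture(scope="session")
def params() -> ParamConfig:
    return ParamConfig()


def make_matrix(values: dict[str, list[float]], genes: list[str],
                design: list[tuple[str, str, str]], mode: str = "counts",
                normalized: bool = False) -> ExpressionMatrix:
    """Build an ExpressionMatrix from explicit columns and a compact design.

    ``design`` pairs each column (in dict order) with
    (cell_line, perturbation, stimulus); replicate indices are assigned in
    order within each design cell.
    """
    samples = []
    seen: dict[tuple, int] = {}
    for sid, cell in zip(values, design):
        seen[cell] = seen.get(cell, 0) + 1
        samples.append(SampleInfo(sid, cell[0], cell[1], cell[2], seen[cell]))
    df = pd.DataFrame(values, index=genes)
    return ExpressionMatrix(values=df, samples=samples, mode=mode,
                            normalized=normalized)


def make_contrast(genes: list[str], m: list[float], p: list[float],
                  cell_line: str = "L1", d: list[float] | None = None) -> ContrastResult:
    """ContrastResult with prescribed M and P_DE (means backfilled)."""
    m_arr = np.asarray(m, dtype=float)
    mean_b = np.full(len(genes), 10.0)
    mean_a = (mean_b + 1.0) * 2.0**m_arr - 1.0
    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "M": m_arr,
            "D": np.abs(mean_a - mean_b) if d is None else np.asarray(d, float),
            "P_DE": np.asarray(p, dtype=float),
        },
        index=genes,
    )
    table.index.name = "gene"
    spec = ContrastSpec(cell_line, ("suz12_kd", "ifng"), ("ctrl", "ifng"))
    return ContrastResult(spec=spec, table=table)


@pytest.fixture(scope="session")
def default_experiment():
    """One simulated experiment at study conditions, shared across tests."""
    matrix, truth = simulate_experiment(SimConfig(seed=11))
    return matrix, truth


@pytest.fixture(scope="session")
def default_contrasts(default_experiment):
    matrix, _ = default_experiment
    return standard_contrasts(matrix, "SIM1", 1.0)
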