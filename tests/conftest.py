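"""Shared fixtures.

Protocol runs are session-scoped and reused by the emergence, ordering and
acceptance tests so the whole suite stays well inside its time budget.
"""

from __future__ import annotations

import numpy as np
import pytest

from epiwave.model import ModelParams, PhaseProgram, run_protocol

EMERGENCE_SEEDS = (0, 1, 2, 3, 4)
ORDERING_SEEDS = (0, 1, 2)
ORDERING_GENOTYPES = (
    "WT",
    "Rac1DN_weak",
    "Rac1DN_strong",
    "Rho1DN",
    "PaxOE",
    "TalinRNAi",
    "DumpingInhibited",
)


def run_combined(genotype: str, seed: int):
    """One combined-factor protocol run on the default 3x3 patch."""
    _, per_frame, tissue, sim = run_protocol(genotype, mode="combined_factor", seed=seed)
    return per_frame, tissue, sim


@pytest.fixture(scope="session")
def wt_tissues():
    """Tissue summary tables for WT over the emergence seeds."""
    return {s: run_combined("WT", s)[1] for s in EMERGENCE_SEEDS}


@pytest.fixture(scope="session")
def rac_weak_tissues():
    """Rac1-inhibition combined-factor runs (40-min ruffling override)."""
    return {s: run_combined("Rac1DN_weak", s)[1] for s in EMERGENCE_SEEDS}


@pytest.fixture(scope="session")
def combined_runs(wt_tissues):
    """Final migration and ruffling circularity drop per genotype per seed."""
    out = {}
    for geno in ORDERING_GENOTYPES:
        rows = []
        for seed in ORDERING_SEEDS:
            if geno == "WT":
                tissue = wt_tissues[seed]
                ruff_end = 60.0
            else:
                _, tissue, sim = run_combined(geno, seed)
                ruff_end = sim.program.ruffling_end
            circ = tissue["mean_circularity"].to_numpy()
            n_ruff = int(ruff_end) + 1
            rows.append(
                {
                    "migration": float(tissue["mean_pa_displacement_um"].iloc[-1]),
                    "ruffling_circ_drop": float(circ[0] - circ[:n_ruff].min()),
                }
            )
        out[geno] = rows
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def quiet_params():
    """Noise-free parameters for deterministic force/step checks."""
    return ModelParams(noise_strength=0.0)


@pytest.fixture()
def default_program():
    return PhaseProgram()
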