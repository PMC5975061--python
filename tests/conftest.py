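"""Shared fixtures: QTL definitions, simulated populations, trial helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from masbreed.classify import QTLDefinition, classify_lines
from masbreed.simulate import (
    EffectModel,
    TrialDesign,
    advance,
    build_map,
    f1_line,
    grow_to_size,
    genotype_codes,
    simulate_trial,
)


def make_qtl(name: str, chromosome: str) -> QTLDefinition:
    return QTLDefinition(
        name=name,
        chromosome=chromosome,
        peak_marker=f"{name}_PK",
        left_flanks=(f"{name}_L1", f"{name}_L2"),
        right_flanks=(f"{name}_R1", f"{name}_R2"),
    )


@pytest.fixture
def two_qtls() -> list[QTLDefinition]:
    """A two-QTL pyramid on separate chromosomes (Samba Mahsuri-like)."""
    return [make_qtl("qDTY2.2", "2"), make_qtl("qDTY4.1", "4")]


@pytest.fixture
def three_qtls() -> list[QTLDefinition]:
    """Submergence locus plus two drought-yield QTLs (Swarna-Sub1-like)."""
    return [make_qtl("Sub1", "9"), make_qtl("qDTY2.1", "2"), make_qtl("qDTY3.1", "3")]


def simulate_f3_trial(
    qtl_defs,
    seed: int,
    n_f2: int = 250,
    spacing: float = 5.0,
    effects: EffectModel | None = None,
    design: TrialDesign | None = None,
):
    """Simulate F2 -> F3, genotype, classify, and phenotype one F3 trial.

    Returns (population, genotype codes, assignments, phenotype records, map).
    """
    gmap = build_map(qtl_defs, spacing)
    ss = np.random.SeedSequence(seed)
    rng_breed, rng_trial = (np.random.default_rng(s) for s in ss.spawn(2))
    f2 = grow_to_size([f1_line(gmap)], "selfing", n_f2, gmap, rng_breed)
    f3 = advance(f2, "selfing", 1, 1, gmap, rng_breed)
    genos = genotype_codes(f3, gmap)
    assignments = classify_lines(genos, qtl_defs)
    effects = effects or EffectModel.default([q.name for q in qtl_defs], np.random.default_rng(seed))
    design = design or TrialDesign()
    phenos = simulate_trial(f3, qtl_defs, effects, design, gmap, rng_trial)
    return f3, genos, assignments, phenos, gmap


@pytest.fixture
def f3_trial_factory():
    return simulate_f3_trial


def balanced_records(
    class_sizes: dict[str, int],
    class_means: dict[str, float],
    n_reps: int = 2,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hand-built balanced trial records with known class means.

    Returns (records, assignments); the line value is exactly its class
    mean plus optional Gaussian noise per plot.
    """
    rng = np.random.default_rng(seed)
    rows, assigns = [], []
    i = 0
    for label, n in class_sizes.items():
        for _ in range(n):
            line = f"L{i}"
            i += 1
            assigns.append((line, label))
            for rep in range(1, n_reps + 1):
                y = class_means[label] + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
                rows.append((line, "F3", "RS", rep, 1, y))
    records = pd.DataFrame(
        rows, columns=["line_id", "generation", "environment", "replicate", "block", "grain_yield_kg_ha"]
    )
    assignments = pd.DataFrame(assigns, columns=["line_id", "class_label"])
    return records, assignments


@pytest.fixture
def balanced_records_factory():
    return balanced_records
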