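"""Calibration and validation studies for the early-generation class analysis.

Reusable simulation experiments that quantify how well the pipeline behaves
under its own assumptions: type-I error of the class F test under the null,
recovery of a truly superior pyramided class at F3, persistence of the
F3-selected classes through F5/F7, and the Mendelian sanity checks of the
breeding simulator.  Each study is fully determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import analyze_trial, fit_class_model
from .classify import QTLDefinition, class_label, classify_lines
from .selection import SelectionRule, select_superior_classes
from .simulate import (
    EffectModel,
    TrialDesign,
    advance,
    build_map,
    f1_line,
    genotype_codes,
    grow_to_size,
    haldane,
    make_gamete,
    simulate_trial,
)


def _qtl(name: str, chromosome: str) -> QTLDefinition:
    return QTLDefinition(
        name=name,
        chromosome=chromosome,
        peak_marker=f"{name}_PK",
        left_flanks=(f"{name}_L1", f"{name}_L2"),
        right_flanks=(f"{name}_R1", f"{name}_R2"),
    )


TWO_QTL_STUDY = [_qtl("qDTY2.2", "2"), _qtl("qDTY4.1", "4")]

# a two-QTL pyramid whose additive effects clear twice the plot residual SD,
# the regime in which early-generation class selection is expected to work
STUDY_EFFECTS = dict(
    additive={"qDTY2.2": (120.0, 400.0), "qDTY4.1": (100.0, 350.0)},
    line_effect_sd=100.0,
    residual_sd=150.0,
    replicate_sd=50.0,
    block_sd=0.0,
)


def null_type_i_error(
    n_datasets: int = 1000,
    seed: int = 0,
    n_classes: int = 4,
    lines_per_class: int = 15,
    n_reps: int = 2,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the class F test on pure-noise trials.

    Gaussian plot noise, no class effect: the p values should be uniform
    and the rejection rate at ``alpha`` should sit in its binomial band.
    """
    rng = np.random.default_rng(seed)
    lines = [f"L{i}" for i in range(n_classes * lines_per_class)]
    assignments = pd.DataFrame(
        {"line_id": lines, "class_label": [f"C{i % n_classes}" for i in range(len(lines))]}
    )
    base = pd.DataFrame(
        {
            "line_id": lines * n_reps,
            "replicate": np.repeat(np.arange(1, n_reps + 1), len(lines)),
            "block": 1,
        }
    )
    rejections = 0
    for _ in range(n_datasets):
        recs = base.assign(grain_yield_kg_ha=rng.normal(0.0, 1.0, len(base)))
        fit = fit_class_model(recs, assignments, vc_method="none")
        rejections += fit.p_value < alpha
    return rejections / n_datasets


def _simulate_study_f3(seed_seq: np.random.SeedSequence, n_f2: int = 300):
    """One F3 population of the two-QTL study with its trial data."""
    gmap = build_map(TWO_QTL_STUDY, spacing_cM=5.0)
    rng_breed, rng_trial = (np.random.default_rng(s) for s in seed_seq.spawn(2))
    f2 = grow_to_size([f1_line(gmap)], "selfing", n_f2, gmap, rng_breed)
    f3 = advance(f2, "selfing", 1, 1, gmap, rng_breed)
    effects = EffectModel(**STUDY_EFFECTS)
    phenos = simulate_trial(f3, TWO_QTL_STUDY, effects, TrialDesign(), gmap, rng_trial)
    genos = genotype_codes(f3, gmap)
    assignments = classify_lines(genos, TWO_QTL_STUDY)
    return f3, gmap, assignments, phenos, rng_breed, rng_trial


def _env_result(phenos, assignments, env, alpha=0.05):
    kept = assignments.dropna(subset=["class_label"])
    recs = phenos[(phenos.environment == env) & phenos.line_id.isin(kept.line_id)]
    return analyze_trial(recs, kept, alpha=alpha, vc_method="none")


def top_class_recovery(n_runs: int = 200, seed: int = 0, n_f2: int = 300) -> float:
    """Fraction of F3 trials whose top-mean RS class is the true best class."""
    best = class_label(["qDTY2.2", "qDTY4.1"])
    root = np.random.SeedSequence(seed)
    hits = 0
    for child in root.spawn(n_runs):
        _, _, assignments, phenos, _, _ = _simulate_study_f3(child, n_f2)
        rs = _env_result(phenos, assignments, "RS")
        hits += str(rs.table.iloc[0]["class_label"]) == best
    return hits / n_runs


def selection_persistence(n_runs: int = 200, seed: int = 0, n_f2: int = 300) -> float:
    """Fraction of runs where the F3-selected class set still contains the
    top-mean RS class at F5 and at F7 (generation-stable effects)."""
    gmap = build_map(TWO_QTL_STUDY, spacing_cM=5.0)
    effects = EffectModel(**STUDY_EFFECTS)
    rule = SelectionRule()
    root = np.random.SeedSequence(seed)
    hits = 0
    for child in root.spawn(n_runs):
        pop, gmap, assignments, phenos, rng_breed, rng_trial = _simulate_study_f3(child, n_f2)
        ns = _env_result(phenos, assignments, "NS")
        rs = _env_result(phenos, assignments, "RS")
        selected = select_superior_classes(ns, rs, rule)
        ok = bool(selected)
        for _ in range(2):  # two further selfing steps at a time: F5 then F7
            if not ok:
                break
            pop = advance(pop, "selfing", 2, 1, gmap, rng_breed)
            genos = genotype_codes(pop, gmap)
            assigns = classify_lines(genos, TWO_QTL_STUDY)
            phen = simulate_trial(pop, TWO_QTL_STUDY, effects, TrialDesign(), gmap, rng_trial)
            rs_adv = _env_result(phen, assigns, "RS")
            ok = str(rs_adv.table.iloc[0]["class_label"]) in selected
        hits += ok
    return hits / n_runs


@dataclass
class MendelianChecks:
    """Observed vs expected Mendelian statistics of the simulator."""

    f2_chi2_p: float
    het_by_generation: dict[int, tuple[float, float]]  # t -> (observed, expected)
    recombinant_fraction: tuple[float, float]  # (observed, Haldane expected)

    def all_within_3se(self, n_het: int, n_gametes: int) -> bool:
        ok = self.f2_chi2_p > 0.001
        for t, (obs, exp) in self.het_by_generation.items():
            se = np.sqrt(exp * (1 - exp) / n_het)
            ok &= abs(obs - exp) < 3 * se
        obs, exp = self.recombinant_fraction
        se = np.sqrt(exp * (1 - exp) / n_gametes)
        ok &= abs(obs - exp) < 3 * se
        return bool(ok)


def mendelian_checks(
    seed: int = 0, n_f2: int = 10_000, n_lines: int = 5000, n_gametes: int = 20_000
) -> MendelianChecks:
    """F2 1:2:1 segregation, (1/2)^t selfing heterozygosity decay, and the
    Haldane recombinant fraction at 10 cM, all from fresh simulation."""
    from scipy.stats import chisquare

    gmap = build_map(TWO_QTL_STUDY, spacing_cM=10.0)
    locus = gmap.index["qDTY2.2_PK"]
    ss = np.random.SeedSequence(seed)
    rng_f2, rng_self, rng_gam = (np.random.default_rng(s) for s in ss.spawn(3))

    f2 = advance([f1_line(gmap)], "selfing", 1, n_f2, gmap, rng_f2)
    totals = np.array([l.maternal[locus] + l.paternal[locus] for l in f2])
    observed = [(totals == 2).sum(), (totals == 1).sum(), (totals == 0).sum()]
    _, chi2_p = chisquare(observed, f_exp=[n_f2 / 4, n_f2 / 2, n_f2 / 4])

    pop = [f1_line(gmap, f"F1-{i}") for i in range(n_lines)]
    het_by_gen: dict[int, tuple[float, float]] = {}
    for t in range(1, 6):
        pop = advance(pop, "selfing", 1, 1, gmap, rng_self)
        obs = float(np.mean([l.maternal[locus] != l.paternal[locus] for l in pop]))
        het_by_gen[t] = (obs, 0.5**t)

    i, j = gmap.index["qDTY2.2_PK"], gmap.index["qDTY2.2_R1"]
    parent = f1_line(gmap)
    rec = 0
    for _ in range(n_gametes):
        g = make_gamete(parent, gmap, rng_gam)
        rec += g[i] != g[j]
    r_obs = rec / n_gametes
    r_exp = float(haldane(10.0))

    return MendelianChecks(
        f2_chi2_p=float(chi2_p),
        het_by_generation=het_by_gen,
        recombinant_fraction=(r_obs, r_exp),
    )
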