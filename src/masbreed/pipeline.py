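"""End-to-end pipeline: simulate → classify → analyze → select → cost ledger.

Emulates a QTL-pyramiding program: an F1 from donor × recipient is advanced
(optionally through backcrosses) to F3, where every line is genotyped at
the QTL-tracking markers, assigned to a QTL class, and phenotyped under NS
and RS.  The class analysis picks the superior classes; from F4 on, the
"selected" strategy carries only lines descending from those classes while
the "all" strategy carries everything.  The two tracks feed the
genotyping/phenotyping cost comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .analysis import ClassAnalysisResult, analyze_trial
from .classify import CallingRule, QTLDefinition, classify_lines
from .costs import CostComparison, CostParams, GenerationPlan, GenerationPlanRow, cost_comparison
from .selection import SelectionRule, select_superior_classes
from .simulate import (
    RECIPIENT,
    EffectModel,
    TrialDesign,
    advance,
    build_map,
    f1_line,
    founder,
    genotype_codes,
    grow_to_size,
    parse_generation,
    simulate_trial,
)


def qtl_defs_from_config(cfg: dict[str, Any]) -> list[QTLDefinition]:
    """Build QTL definitions from config; marker names derive from QTL names."""
    entries = cfg.get("qtls") or [
        {"name": "Sub1", "chromosome": "9"},
        {"name": "qDTY2.1", "chromosome": "2"},
        {"name": "qDTY3.1", "chromosome": "3"},
    ]
    defs = []
    for e in entries:
        name = e["name"]
        defs.append(
            QTLDefinition(
                name=name,
                chromosome=str(e["chromosome"]),
                peak_marker=e.get("peak_marker", f"{name}_PK"),
                left_flanks=tuple(e.get("left_flanks", (f"{name}_L1", f"{name}_L2"))),
                right_flanks=tuple(e.get("right_flanks", (f"{name}_R1", f"{name}_R2"))),
            )
        )
    return defs


def effect_model_from_config(cfg: dict[str, Any], qtl_names: Sequence[str], rng: np.random.Generator) -> EffectModel:
    e = cfg["effects"]
    additive = {}
    configured = e.get("additive") or {}
    for name in qtl_names:
        if name in configured:
            additive[name] = tuple(configured[name])
        else:
            rs = float(rng.uniform(300.0, 500.0))
            additive[name] = (e.get("ns_fraction", 0.3) * rs, rs)
    interaction = {
        frozenset(k.split("*")): tuple(v) for k, v in (e.get("interaction") or {}).items()
    }
    return EffectModel(
        baseline_ns=e["baseline_ns"],
        baseline_rs=e["baseline_rs"],
        additive=additive,
        interaction=interaction,
        line_effect_sd=e["line_effect_sd"],
        residual_sd=e["residual_sd"],
        replicate_sd=e["replicate_sd"],
        block_sd=e["block_sd"],
    )


@dataclass
class GenerationOutput:
    generation: str
    genotypes: pd.DataFrame
    assignments: pd.DataFrame
    phenotypes: pd.DataFrame
    results: dict[str, ClassAnalysisResult]
    n_all: int
    n_selected: int


@dataclass
class PipelineResult:
    config: dict[str, Any]
    seed: int
    qtl_defs: list[QTLDefinition]
    effects: EffectModel
    selected_classes: set[str]
    generations: list[GenerationOutput]
    plan: GenerationPlan
    costs: CostComparison


def _analyze_both_envs(
    phenotypes: pd.DataFrame,
    assignments: pd.DataFrame,
    alpha: float,
) -> dict[str, ClassAnalysisResult]:
    """Per-environment class analysis restricted to class-assigned lines."""
    assigned = assignments.dropna(subset=["class_label"])
    results: dict[str, ClassAnalysisResult] = {}
    for env in sorted(phenotypes["environment"].unique()):
        recs = phenotypes[
            (phenotypes["environment"] == env)
            & (phenotypes["line_id"].isin(assigned["line_id"]))
        ]
        results[env] = analyze_trial(recs, assigned, alpha=alpha)
    return results


def run_pipeline(cfg: dict[str, Any], seed: int, out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full pipeline deterministically from (config, seed)."""
    ss = np.random.SeedSequence(seed)
    rng_effects, rng_breed, rng_trial = (np.random.default_rng(s) for s in ss.spawn(3))

    qtl_defs = qtl_defs_from_config(cfg)
    gmap = build_map(qtl_defs, cfg["map"]["spacing_cM"], cfg["map"]["qtl_gap_cM"])
    effects = effect_model_from_config(cfg, [q.name for q in qtl_defs], rng_effects)
    design = TrialDesign(
        environments=tuple(cfg["trial"]["environments"]),
        n_replicates=cfg["trial"]["n_replicates"],
        n_blocks_per_replicate=cfg["trial"]["n_blocks_per_replicate"],
    )
    rule = CallingRule(**cfg["calling"])
    policy = cfg["assignment_policy"]
    sel_rule = SelectionRule(**cfg["selection"])
    params = CostParams(**cfg["costs"])

    # breed to F2 (after any backcrosses), then self to the final generation
    pop = [f1_line(gmap)]
    if int(cfg.get("n_backcrosses", 0)) > 0:
        recurrent = founder("recipient", gmap, RECIPIENT, "F1")
        for _ in range(int(cfg["n_backcrosses"])):
            pop = grow_to_size(pop, "backcross", cfg["population"]["f2_size"], gmap, rng_breed, recurrent=recurrent)
    pop = grow_to_size(pop, "selfing", cfg["population"]["f2_size"], gmap, rng_breed)

    final_filial = parse_generation(cfg["population"]["final_generation"])[1]
    if final_filial < 3:
        raise ValueError("final_generation must be F3 or later")

    selected_classes: set[str] = set()
    selected_f3_ids: set[str] = set()
    generations: list[GenerationOutput] = []
    plan_rows: list[GenerationPlanRow] = []

    current = pop
    while True:
        filial = parse_generation(current[0].generation)[1]
        current = advance(current, "selfing", 1, 1, gmap, rng_breed)
        filial += 1
        if filial < 3:
            continue
        label = current[0].generation
        genos = genotype_codes(current, gmap)
        assignments = classify_lines(genos, qtl_defs, rule, policy)
        phenos = simulate_trial(current, qtl_defs, effects, design, gmap, rng_trial)
        results = _analyze_both_envs(phenos, assignments, sel_rule.alpha)

        if filial == 3:
            ns = results.get("NS")
            rs = results.get("RS")
            if rs is None:
                raise ValueError("selection requires an RS trial at F3")
            selected_classes = select_superior_classes(ns, rs, sel_rule)
            amap = assignments.dropna(subset=["class_label"])
            selected_f3_ids = set(
                amap.loc[amap["class_label"].isin(selected_classes), "line_id"]
            )
            n_selected = len(current)  # selection happens after F3 data are in
        else:
            n_selected = sum(
                1
                for l in current
                if any(l.line_id == fid or l.line_id.startswith(fid + ".") for fid in selected_f3_ids)
            )

        generations.append(
            GenerationOutput(
                generation=label,
                genotypes=genos,
                assignments=assignments,
                phenotypes=phenos,
                results=results,
                n_all=len(current),
                n_selected=n_selected,
            )
        )
        plan_rows.append(GenerationPlanRow(label, len(current), n_selected))
        if filial >= final_filial:
            break

    plan = GenerationPlan(background=cfg.get("background", "simulated"), n_qtls=len(qtl_defs), rows=plan_rows)
    costs = cost_comparison(plan, params)

    result = PipelineResult(
        config=cfg,
        seed=seed,
        qtl_defs=qtl_defs,
        effects=effects,
        selected_classes=selected_classes,
        generations=generations,
        plan=plan,
        costs=costs,
    )
    if out_dir is not None:
        write_pipeline_outputs(result, out_dir)
    return result


def result_table(result: ClassAnalysisResult) -> pd.DataFrame:
    """One trial's class table in the published layout (mean + letters etc.)."""
    t = result.table.copy()
    t["mean_letter"] = t["mean"].round(0).astype(int).astype(str) + " " + t["letters"]
    t.loc[len(t)] = {
        "class_label": "Trial mean",
        "mean": result.trial_mean,
        "mean_letter": f"{result.trial_mean:.0f}",
    }
    t.loc[len(t)] = {"class_label": "F-value", "mean_letter": f"{result.f_value:.2f}"}
    t.loc[len(t)] = {"class_label": "p-value", "mean_letter": f"{result.p_value:.4f}"}
    return t


def write_pipeline_outputs(result: PipelineResult, out_dir: str | Path) -> mio.RunManifest:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = mio.RunManifest(config_hash=mio.config_hash(result.config), seed=result.seed)
    for gen in result.generations:
        stem = out / gen.generation
        mio.write_genotypes(gen.genotypes, f"{stem}_genotypes.csv")
        mio.write_phenotypes(gen.phenotypes, f"{stem}_phenotypes.csv")
        mio.write_assignments(gen.assignments, f"{stem}_assignments.csv")
        for env, res in gen.results.items():
            result_table(res).to_csv(f"{stem}_{env}_class_table.csv", index=False)
            manifest.add(f"{stem}_{env}_class_table.csv")
        for p in (f"{stem}_genotypes.csv", f"{stem}_phenotypes.csv", f"{stem}_assignments.csv"):
            manifest.add(p)
    (out / "selected_classes.txt").write_text(
        "\n".join(sorted(result.selected_classes)) + "\n", encoding="utf-8"
    )
    manifest.add(out / "selected_classes.txt")
    result.costs.display().to_csv(out / "cost_comparison.csv", index=False)
    manifest.add(out / "cost_comparison.csv")
    manifest.write(out / "manifest.json")
    return manifest
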