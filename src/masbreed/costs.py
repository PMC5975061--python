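"""Genotyping and phenotyping cost comparison: all classes vs selected classes.

Quantifies the savings of advancing only the superior F3 QTL classes.
Genotyping is priced per marker data point over five markers per QTL;
phenotyping per trial entry (covering two replications under NS and RS).
Costs accumulate unrounded; displayed dollar figures are rounded half-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd


def round_half_up(x: float) -> int:
    """Round to the nearest dollar with ties going up (ledger convention)."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass
class CostParams:
    """Unit prices: USD 0.50 per marker data point over five markers per QTL,
    USD 36.18 per phenotyping entry."""

    markers_per_qtl: int = 5
    genotyping_unit: float = 0.50
    phenotyping_unit: float = 36.18

    def __post_init__(self) -> None:
        if self.markers_per_qtl <= 0 or self.genotyping_unit <= 0 or self.phenotyping_unit <= 0:
            raise ValueError("all cost parameters must be strictly positive")


def genotyping_cost(n_lines: int, n_qtls: int, params: CostParams | None = None) -> float:
    """USD to genotype ``n_lines`` at 5 markers per QTL (unrounded)."""
    params = params or CostParams()
    if n_lines < 0 or n_qtls < 0:
        raise ValueError("n_lines and n_qtls must be >= 0")
    return n_lines * n_qtls * params.markers_per_qtl * params.genotyping_unit


def phenotyping_cost(n_entries: int, params: CostParams | None = None) -> float:
    """USD to phenotype ``n_entries`` trial entries (unrounded)."""
    params = params or CostParams()
    if n_entries < 0:
        raise ValueError("n_entries must be >= 0")
    return n_entries * params.phenotyping_unit


@dataclass
class GenerationPlanRow:
    """Population sizes of one generation under the two strategies."""

    generation: str
    n_all: int
    n_selected: int
    n_classes_all: int | None = None
    n_classes_selected: int | None = None


@dataclass
class GenerationPlan:
    """Per-generation population sizes for one genetic background.

    The first generation is where the class analysis happens, so both
    strategies genotype and phenotype the full population there
    (n_selected == n_all); selection bites from the next generation on.
    """

    background: str
    n_qtls: int
    rows: list[GenerationPlanRow]

    def __post_init__(self) -> None:
        if self.n_qtls < 1:
            raise ValueError("n_qtls must be >= 1")
        if not self.rows:
            raise ValueError("plan must have at least one generation")
        for r in self.rows:
            if r.n_all < 0 or r.n_selected < 0:
                raise ValueError(f"{self.background} {r.generation}: sizes must be >= 0")
            if r.n_selected > r.n_all:
                raise ValueError(
                    f"{self.background} {r.generation}: n_selected ({r.n_selected}) "
                    f"exceeds n_all ({r.n_all})"
                )
        first = self.rows[0]
        if first.n_selected != first.n_all:
            raise ValueError(
                f"{self.background}: first generation must have n_selected == n_all "
                "(selection happens only after its data are in)"
            )


@dataclass
class CostComparison:
    """Cost ledger of one background: per-generation table plus totals.

    Totals and savings are accumulated unrounded; use ``display()`` for the
    rounded presentation table.
    """

    background: str
    per_generation: pd.DataFrame
    genotyping_total_all: float
    genotyping_total_selected: float
    phenotyping_total_all: float
    phenotyping_total_selected: float

    @property
    def genotyping_savings(self) -> float:
        return self.genotyping_total_all - self.genotyping_total_selected

    @property
    def phenotyping_savings(self) -> float:
        return self.phenotyping_total_all - self.phenotyping_total_selected

    @property
    def genotyping_savings_percent(self) -> float:
        return 100.0 * self.genotyping_savings / self.genotyping_total_all

    @property
    def phenotyping_savings_percent(self) -> float:
        return 100.0 * self.phenotyping_savings / self.phenotyping_total_all

    def display(self) -> pd.DataFrame:
        """Presentation table with all dollar figures rounded half-up."""
        out = self.per_generation.copy()
        for col in (
            "genotyping_all",
            "genotyping_selected",
            "phenotyping_all",
            "phenotyping_selected",
        ):
            out[col] = out[col].map(round_half_up)
        return out


def cost_comparison(plan: GenerationPlan, params: CostParams | None = None) -> CostComparison:
    """Build the all-vs-selected cost ledger for one background."""
    params = params or CostParams()
    rows = []
    for r in plan.rows:
        rows.append(
            {
                "generation": r.generation,
                "n_all": r.n_all,
                "n_selected": r.n_selected,
                "genotyping_all": genotyping_cost(r.n_all, plan.n_qtls, params),
                "genotyping_selected": genotyping_cost(r.n_selected, plan.n_qtls, params),
                "phenotyping_all": phenotyping_cost(r.n_all, params),
                "phenotyping_selected": phenotyping_cost(r.n_selected, params),
            }
        )
    per_gen = pd.DataFrame(rows)
    return CostComparison(
        background=plan.background,
        per_generation=per_gen,
        genotyping_total_all=float(per_gen["genotyping_all"].sum()),
        genotyping_total_selected=float(per_gen["genotyping_selected"].sum()),
        phenotyping_total_all=float(per_gen["phenotyping_all"].sum()),
        phenotyping_total_selected=float(per_gen["phenotyping_selected"].sum()),
    )


def savings_summary(comparisons: Iterable[CostComparison]) -> dict[str, tuple[float, float]]:
    """Min/max savings percent over backgrounds, genotyping and phenotyping."""
    comparisons = list(comparisons)
    if not comparisons:
        raise ValueError("need at least one cost comparison")
    geno = [c.genotyping_savings_percent for c in comparisons]
    pheno = [c.phenotyping_savings_percent for c in comparisons]
    return {
        "genotyping": (min(geno), max(geno)),
        "phenotyping": (min(pheno), max(pheno)),
    }
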