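"""masbreed: marker-assisted QTL-pyramiding breeding simulation and analysis.

Tools for the combined early-generation marker-assisted selection strategy:
simulate selfing/backcross populations pyramiding drought-yield QTLs,
assign lines to QTL classes from their marker genotypes, run the nested
class analysis with compact letter display, select the superior classes,
and quantify the genotyping/phenotyping cost savings of advancing only
those classes.
"""

from .analysis import (
    ClassAnalysisResult,
    analyze_trial,
    fit_class_model,
    letter_display,
    stress_reduction,
    yield_advantage,
)
from .classify import (
    CallingRule,
    QTLCall,
    QTLClass,
    QTLDefinition,
    assign_class,
    call_qtl,
    class_census,
    class_label,
    classify_lines,
)
from .costs import (
    CostComparison,
    CostParams,
    GenerationPlan,
    GenerationPlanRow,
    cost_comparison,
    genotyping_cost,
    phenotyping_cost,
    round_half_up,
    savings_summary,
)
from .plans import published_plan, published_plans
from .selection import SelectionRule, select_superior_classes
from .simulate import (
    EffectModel,
    GeneticMap,
    LineGenotype,
    MarkerLocus,
    TrialDesign,
    advance,
    build_map,
    f1_line,
    founder,
    genotype_codes,
    grow_to_size,
    haldane,
    make_gamete,
    parse_generation,
    qtl_dosages,
    simulate_trial,
)

__version__ = "0.1.0"
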