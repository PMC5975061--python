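"""Superior-class selection from the early-generation class analysis.

After the F3 / BC1F3 / BC2F3 class analysis, only the QTL classes with high
mean grain yield are advanced.  The reconstructed default rule selects a
class when it (i) shares a compact-letter-display letter with the top-mean
class under reproductive-stage drought stress (RS), (ii) is not
significantly below the top class under non-stress (NS) when an NS trial
exists, (iii) has enough member lines for its mean to be trusted, and
(iv) does not yield below the recipient-parent class ``X`` under RS.
"""

from __future__ import annotations

from dataclasses import dataclass

from .analysis import ClassAnalysisResult
from .classify import PARENT_CLASS_LABEL


@dataclass
class SelectionRule:
    """Parameters of the superior-class rule.

    alpha is the significance level the letter displays were built at;
    require_both_envs demands an NS result in addition to RS;
    min_lines_per_class guards against means estimated from too few lines.
    """

    alpha: float = 0.05
    require_both_envs: bool = True
    min_lines_per_class: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_lines_per_class < 1:
            raise ValueError("min_lines_per_class must be >= 1")


def _shares_letter(a: str, b: str) -> bool:
    return bool(set(a) & set(b))


def _top_class(result: ClassAnalysisResult) -> str:
    # table is sorted by descending mean
    return str(result.table.iloc[0]["class_label"])


def select_superior_classes(
    ns_result: ClassAnalysisResult | None,
    rs_result: ClassAnalysisResult,
    rule: SelectionRule | None = None,
) -> set[str]:
    """Apply the superior-class rule; returns the selected class labels.

    ``ns_result`` may be None (stress-only screening) unless the rule
    demands both environments.  Both results must cover the same classes.
    """
    rule = rule or SelectionRule()
    if rs_result is None or not len(rs_result.table):
        raise ValueError("RS class-analysis result with at least one class is required")
    if rule.require_both_envs and ns_result is None:
        raise ValueError("rule requires both environments but no NS result was given")
    rs_classes = set(rs_result.classes)
    if ns_result is not None and set(ns_result.classes) != rs_classes:
        raise ValueError("NS and RS results must cover the same class set")

    rs_letters = rs_result.letters()
    rs_n = rs_result.n_lines()
    top_rs = _top_class(rs_result)
    parent_rs = (
        rs_result.mean(PARENT_CLASS_LABEL) if PARENT_CLASS_LABEL in rs_classes else None
    )
    ns_letters = ns_result.letters() if ns_result is not None else None
    top_ns = _top_class(ns_result) if ns_result is not None else None

    selected: set[str] = set()
    for label in rs_result.classes:
        if not _shares_letter(rs_letters[label], rs_letters[top_rs]):
            continue
        if ns_letters is not None and not _shares_letter(ns_letters[label], ns_letters[top_ns]):
            continue
        if rs_n[label] < rule.min_lines_per_class:
            continue
        if parent_rs is not None and rs_result.mean(label) < parent_rs:
            continue
        selected.add(label)
    return selected
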