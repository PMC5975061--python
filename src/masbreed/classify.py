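"""QTL calling from marker genotypes and assignment of lines to QTL classes.

Each target QTL is tracked by five markers: a peak (or near-peak) marker
plus two flanking markers on each side.  A line's QTL status is called from
the observed marker codes (``A`` donor homozygote, ``B`` recipient
homozygote, ``H`` heterozygote, ``-`` missing), and the set of QTLs called
*present* defines the line's QTL class — the grouping factor of the
early-generation class analysis.  Lines carrying no target QTL form the
recipient-parent class ``X``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

VALID_CODES = frozenset({"A", "B", "H", "-"})
MISSING = "-"

PARENT_CLASS_LABEL = "X"

_QDTY_RE = re.compile(r"^qDTY(\d+)\.(\d+)$")


@dataclass(frozen=True)
class QTLDefinition:
    """One target QTL and the five markers used to track it.

    ``left_flanks`` and ``right_flanks`` are ordered inner-to-outer: the
    first element is the marker immediately adjacent to the peak, the
    second the outer flank.
    """

    name: str
    chromosome: str
    peak_marker: str
    left_flanks: tuple[str, str]
    right_flanks: tuple[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "left_flanks", tuple(self.left_flanks))
        object.__setattr__(self, "right_flanks", tuple(self.right_flanks))
        markers = self.markers
        if len(set(markers)) != 5:
            raise ValueError(
                f"QTL {self.name!r} must have 5 distinct markers, got {markers}"
            )

    @property
    def markers(self) -> tuple[str, ...]:
        """All five marker names, in map order (outer-left ... outer-right)."""
        return (
            self.left_flanks[1],
            self.left_flanks[0],
            self.peak_marker,
            self.right_flanks[0],
            self.right_flanks[1],
        )

    @property
    def inner_markers(self) -> tuple[str, str, str]:
        return (self.left_flanks[0], self.peak_marker, self.right_flanks[0])

    @property
    def outer_markers(self) -> tuple[str, str]:
        return (self.left_flanks[1], self.right_flanks[1])


@dataclass
class CallingRule:
    """Configuration of the marker-to-QTL call.

    mode
        ``"flanked"`` (default): a QTL is *present* when the peak and both
        immediate flanks are donor homozygous, *absent* when all three are
        recipient homozygous, *segregating* otherwise.  ``"peak_only"``:
        the call is read off the peak marker alone.
    max_missing_outer
        Number of missing outer-flank genotypes tolerated before the call
        degrades to *segregating* (outer flanks otherwise do not enter the
        call).
    """

    mode: str = "flanked"
    max_missing_outer: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("flanked", "peak_only"):
            raise ValueError(f"unknown calling mode {self.mode!r}")
        if self.max_missing_outer < 0:
            raise ValueError("max_missing_outer must be >= 0")


@dataclass(frozen=True)
class QTLCall:
    """Status of one QTL in one line.

    ``status`` follows the configured rule; ``peak_status`` is the call
    from the peak marker alone, kept so the segregant-handling policy can
    be switched without re-reading the genotype matrix.
    """

    line_id: str
    qtl_name: str
    status: str  # present | absent | segregating
    peak_status: str


@dataclass(frozen=True)
class QTLClass:
    """A set of pyramided QTLs and its canonical display label."""

    label: str
    members: frozenset[str]


def _label_sort_key(name: str):
    # Sub1 leads; qDTY loci follow ordered by chromosome then sub-index.
    if name == "Sub1":
        return (0, 0, 0, "")
    m = _QDTY_RE.match(name)
    if m:
        return (1, int(m.group(1)), int(m.group(2)), name)
    return (2, 0, 0, name)


def class_label(members: Iterable[str]) -> str:
    """Canonical label for a member set; the empty set is the parent class."""
    members = sorted(set(members), key=_label_sort_key)
    if not members:
        return PARENT_CLASS_LABEL
    return " + ".join(members)


def make_class(members: Iterable[str]) -> QTLClass:
    members = frozenset(members)
    return QTLClass(label=class_label(members), members=members)


def _peak_status(code: str) -> str:
    if code == "A":
        return "present"
    if code == "B":
        return "absent"
    return "segregating"


def call_qtl(
    row: Mapping[str, str],
    qtl: QTLDefinition,
    rule: CallingRule | None = None,
    line_id: str = "",
) -> QTLCall:
    """Call one QTL's status for one line from its marker codes.

    ``row`` maps marker name -> genotype code.  Raises ``KeyError`` naming
    the first marker absent from the row.
    """
    rule = rule or CallingRule()
    for marker in qtl.markers:
        if marker not in row:
            raise KeyError(f"marker {marker!r} (QTL {qtl.name}) absent from genotype row")
    peak = row[qtl.peak_marker]
    peak_status = _peak_status(peak)
    if rule.mode == "peak_only":
        return QTLCall(line_id, qtl.name, peak_status, peak_status)

    inner = (row[qtl.left_flanks[0]], peak, row[qtl.right_flanks[0]])
    n_missing_outer = sum(row[m] == MISSING for m in qtl.outer_markers)
    if peak == MISSING or MISSING in inner or n_missing_outer > rule.max_missing_outer:
        status = "segregating"
    elif all(c == "A" for c in inner):
        status = "present"
    elif all(c == "B" for c in inner):
        status = "absent"
    else:
        status = "segregating"
    return QTLCall(line_id, qtl.name, status, peak_status)


def assign_class(
    calls: Sequence[QTLCall], policy: str = "drop_segregating"
) -> Optional[QTLClass]:
    """Map a line's QTL calls to its class, or ``None`` if excluded.

    ``drop_segregating`` excludes lines with any segregating call (the
    fixed-class interpretation used for the class analysis);
    ``peak_only`` re-reads each call from the peak marker alone before
    applying the same exclusion.
    """
    if policy == "drop_segregating":
        statuses = {c.qtl_name: c.status for c in calls}
    elif policy == "peak_only":
        statuses = {c.qtl_name: c.peak_status for c in calls}
    else:
        raise ValueError(f"unknown assignment policy {policy!r}")
    if any(s == "segregating" for s in statuses.values()):
        return None
    return make_class(name for name, s in statuses.items() if s == "present")


def classify_lines(
    genotypes: pd.DataFrame,
    qtl_defs: Sequence[QTLDefinition],
    rule: CallingRule | None = None,
    policy: str = "drop_segregating",
) -> pd.DataFrame:
    """Assign every line in a genotype matrix to a QTL class.

    ``genotypes`` is indexed by line_id with one column per marker.
    Returns a DataFrame with columns ``line_id`` and ``class_label``;
    excluded (segregating) lines carry a null label.
    """
    rule = rule or CallingRule()
    records = []
    for line_id, row in genotypes.iterrows():
        calls = [call_qtl(row, q, rule, line_id=str(line_id)) for q in qtl_defs]
        cls = assign_class(calls, policy=policy)
        records.append((str(line_id), cls.label if cls is not None else pd.NA))
    return pd.DataFrame(records, columns=["line_id", "class_label"])


def class_census(
    assignments: pd.DataFrame, generations: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Count non-excluded lines per class (optionally per generation).

    ``generations`` maps line_id -> generation label; when given, the
    census is a class × generation table.
    """
    kept = assignments.dropna(subset=["class_label"])
    if generations is None:
        counts = kept.groupby("class_label").size().rename("n_lines")
        return counts.reset_index()
    gen = kept["line_id"].map(dict(generations))
    out = (
        kept.assign(generation=gen.values)
        .groupby(["class_label", "generation"])
        .size()
        .rename("n_lines")
        .reset_index()
    )
    return out
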