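"""Published case-study generation plans for five rice introgression programs.

Population sizes per generation under the two strategies (advance all QTL
classes vs only the superior F3-selected classes), as reported for the
Swarna-Sub1, IR64-Sub1, Samba Mahsuri, TDK1-Sub1 and MR219 backgrounds.
These are inputs to the cost comparison, not outputs of it: the per-class
advancement decisions behind the selected-strategy sizes were made in the
field and are not derivable from the counts alone.
"""

from __future__ import annotations

from .costs import GenerationPlan, GenerationPlanRow

# background -> (n_qtls, [(generation, n_all, n_selected, n_classes_all), ...])
_PLAN_DATA: dict[str, tuple[int, list[tuple[str, int, int, int]]]] = {
    "Swarna-Sub1": (
        3,
        [
            ("F3", 754, 754, 15),
            ("F4", 754, 106, 15),
            ("F5", 432, 106, 10),
            ("F6", 432, 106, 10),
            ("F7", 432, 108, 6),
            ("F8", 52, 17, 5),
        ],
    ),
    "IR64-Sub1": (
        6,
        [
            ("F3", 467, 467, 20),
            ("F4", 194, 46, 19),
            ("F5", 64, 18, 19),
            ("F6", 64, 18, 13),
            ("F7", 18, 10, 7),
        ],
    ),
    "Samba Mahsuri": (
        2,
        [
            ("BC1F3", 42, 42, 3),
            ("BC1F4", 3000, 640, 3),
            ("BC1F5", 1200, 640, 3),
            ("BC1F6", 70, 44, 3),
            ("BC1F7", 20, 15, 2),
            ("BC1F8", 20, 15, 2),
        ],
    ),
    "TDK1-Sub1": (
        3,
        [
            ("BC2F3", 843, 843, 14),
            ("BC2F4", 231, 43, 7),
            ("BC2F5", 48, 14, 7),
            ("BC2F6", 48, 14, 7),
            ("BC2F7", 60, 13, 5),
        ],
    ),
    "MR219": (
        3,
        [
            ("BC1F3", 214, 214, 7),
            ("BC1F4", 620, 240, 7),
            ("BC1F5", 620, 240, 7),
            ("BC1F6", 70, 35, 7),
            ("BC1F7", 70, 35, 7),
        ],
    ),
}

BACKGROUNDS = tuple(_PLAN_DATA)


def published_plan(background: str) -> GenerationPlan:
    """The published generation plan for one background."""
    try:
        n_qtls, rows = _PLAN_DATA[background]
    except KeyError:
        raise KeyError(
            f"unknown background {background!r}; available: {', '.join(BACKGROUNDS)}"
        ) from None
    return GenerationPlan(
        background=background,
        n_qtls=n_qtls,
        rows=[
            GenerationPlanRow(gen, n_all, n_sel, n_classes_all=n_cls)
            for gen, n_all, n_sel, n_cls in rows
        ],
    )


def published_plans() -> dict[str, GenerationPlan]:
    """All five published plans, keyed by background."""
    return {bg: published_plan(bg) for bg in BACKGROUNDS}
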