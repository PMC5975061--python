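"""Synthetic breeding-population generator for QTL-pyramiding studies.

Simulates selfing (F2 → F8) and backcross (BC1/BC2) pedigrees segregating
for 1–6 yield QTLs tracked by five linked markers each, then phenotypes the
resulting lines in replicated yield trials under irrigated non-stress (NS)
and reproductive-stage drought stress (RS) environments.  Meiosis uses the
Haldane mapping function (no crossover interference); trait values are
additive per-QTL effects (expressed mainly under RS), optional QTL×QTL
interactions, a line-level genetic background effect, replicate and
block-within-replicate effects, and plot residual noise.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import QTLDefinition

DONOR = 1
RECIPIENT = 0

_GENERATION_RE = re.compile(r"^(?:BC([1-9]\d*))?F([1-9]\d*)$")


def parse_generation(label: str) -> tuple[int, int]:
    """Parse a pedigree label ``F{m}`` or ``BC{n}F{m}`` -> (n_backcross, m_filial).

    Case-sensitive; ``m >= 1`` required.
    """
    m = _GENERATION_RE.match(label)
    if not m:
        raise ValueError(f"invalid generation label {label!r} (expected F<m> or BC<n>F<m>)")
    return (int(m.group(1) or 0), int(m.group(2)))


def format_generation(n_backcross: int, m_filial: int) -> str:
    if n_backcross < 0 or m_filial < 1:
        raise ValueError("need n_backcross >= 0 and m_filial >= 1")
    prefix = f"BC{n_backcross}" if n_backcross else ""
    return f"{prefix}F{m_filial}"


def haldane(d_cM: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction for a map distance in cM: r = (1 - e^(-2d/100))/2."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


@dataclass(frozen=True)
class MarkerLocus:
    name: str
    chromosome: str
    position_cM: float

    def __post_init__(self) -> None:
        if self.position_cM < 0:
            raise ValueError(f"marker {self.name!r}: position_cM must be >= 0")


class GeneticMap:
    """An ordered set of marker loci grouped by chromosome.

    Chromosomes assort independently; within a chromosome the loci are kept
    in non-decreasing map-position order and adjacent-locus recombination
    fractions are precomputed with the Haldane function.
    """

    def __init__(self, loci: Sequence[MarkerLocus]):
        names = [loc.name for loc in loci]
        seen: set[str] = set()
        for n in names:
            if n in seen:
                raise ValueError(f"duplicate marker name {n!r} in map")
            seen.add(n)
        self.loci: list[MarkerLocus] = list(loci)
        self.names: list[str] = names
        self.index: dict[str, int] = {n: i for i, n in enumerate(names)}
        self._chrom_slices: list[slice] = []
        self._rec_fracs: list[np.ndarray] = []
        start = 0
        for _, group in itertools.groupby(self.loci, key=lambda l: l.chromosome):
            block = list(group)
            stop = start + len(block)
            pos = np.array([l.position_cM for l in block])
            if np.any(np.diff(pos) < 0):
                raise ValueError(
                    f"positions on chromosome {block[0].chromosome!r} must be non-decreasing"
                )
            self._chrom_slices.append(slice(start, stop))
            self._rec_fracs.append(haldane(np.diff(pos)))
            start = stop
        chroms = [l.chromosome for l in self.loci]
        if len(set(chroms)) != len(self._chrom_slices):
            raise ValueError("loci of one chromosome must be contiguous in the map")

    def __len__(self) -> int:
        return len(self.loci)


def build_map(
    qtl_defs: Sequence[QTLDefinition],
    spacing_cM: float = 5.0,
    qtl_gap_cM: float = 50.0,
) -> GeneticMap:
    """Lay out the five tracking markers of each QTL on a genetic map.

    Per QTL the peak marker is flanked at ±spacing and ±2·spacing cM.
    QTLs sharing a chromosome are placed sequentially with ``qtl_gap_cM``
    between the outer flanks of consecutive QTLs, so their marker sets
    never interleave.  Duplicate marker names are rejected by name.
    """
    if not qtl_defs:
        raise ValueError("qtl_defs must be non-empty")
    if spacing_cM < 0:
        raise ValueError("spacing_cM must be >= 0")
    seen: set[str] = set()
    for q in qtl_defs:
        for m in q.markers:
            if m in seen:
                raise ValueError(f"duplicate marker name {m!r} across QTL definitions")
            seen.add(m)
    loci: list[MarkerLocus] = []
    next_start: dict[str, float] = {}
    for q in qtl_defs:
        left_edge = next_start.get(q.chromosome, 0.0)
        peak_pos = left_edge + 2.0 * spacing_cM
        offsets = (-2.0, -1.0, 0.0, 1.0, 2.0)
        for name, k in zip(q.markers, offsets):
            loci.append(MarkerLocus(name, q.chromosome, peak_pos + k * spacing_cM))
        next_start[q.chromosome] = peak_pos + 2.0 * spacing_cM + qtl_gap_cM
    loci.sort(key=lambda l: (list(next_start).index(l.chromosome), l.position_cM))
    return GeneticMap(loci)


@dataclass
class LineGenotype:
    """One line: two haplotypes over the map plus its pedigree label."""

    line_id: str
    maternal: np.ndarray
    paternal: np.ndarray
    generation: str

    def __post_init__(self) -> None:
        self.maternal = np.asarray(self.maternal, dtype=np.int8)
        self.paternal = np.asarray(self.paternal, dtype=np.int8)
        if self.maternal.shape != self.paternal.shape:
            raise ValueError("haplotypes must have equal length")
        for hap in (self.maternal, self.paternal):
            if not np.isin(hap, (DONOR, RECIPIENT)).all():
                raise ValueError("allele states must be donor (1) or recipient (0)")
        parse_generation(self.generation)

    @property
    def dosage(self) -> np.ndarray:
        """Donor-allele dosage per locus in {0, 0.5, 1}."""
        return (self.maternal + self.paternal) / 2.0

    def is_homozygous(self) -> bool:
        return bool(np.array_equal(self.maternal, self.paternal))


def founder(line_id: str, gmap: GeneticMap, allele: int, generation: str = "F1") -> LineGenotype:
    hap = np.full(len(gmap), allele, dtype=np.int8)
    return LineGenotype(line_id, hap.copy(), hap.copy(), generation)


def f1_line(gmap: GeneticMap, line_id: str = "F1-1") -> LineGenotype:
    """The fully heterozygous donor × recipient F1."""
    return LineGenotype(
        line_id,
        np.full(len(gmap), DONOR, dtype=np.int8),
        np.full(len(gmap), RECIPIENT, dtype=np.int8),
        "F1",
    )


def make_gamete(
    parent: LineGenotype, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """Sample one meiotic product of ``parent``.

    Chromosomes assort independently; within a chromosome, recombination
    between adjacent loci occurs with the Haldane probability of their map
    distance.  The result is a mosaic of the two parental haplotypes.
    """
    if len(parent.maternal) != len(gmap):
        raise ValueError("parent haplotype length does not match map")
    gamete = np.empty(len(gmap), dtype=np.int8)
    for sl, rf in zip(gmap._chrom_slices, gmap._rec_fracs):
        n = sl.stop - sl.start
        switch = np.empty(n, dtype=bool)
        switch[0] = rng.random() < 0.5
        if n > 1:
            switch[1:] = rng.random(n - 1) < rf
        use_paternal = np.logical_xor.accumulate(switch)
        seg = np.where(use_paternal, parent.paternal[sl], parent.maternal[sl])
        gamete[sl] = seg
    return gamete


def _next_label(generation: str, scheme: str) -> str:
    n, m = parse_generation(generation)
    if scheme == "selfing":
        return format_generation(n, m + 1)
    return format_generation(n + 1, 1)


def advance(
    pop: Sequence[LineGenotype],
    scheme: str,
    n_generations: int,
    per_line_progeny: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
    recurrent: Optional[LineGenotype] = None,
) -> list[LineGenotype]:
    """Advance a population by selfing or backcrossing.

    Selfing crosses every line to itself (F_m → F_{m+1}); backcrossing
    crosses every line to the recurrent parent (BC count increments, the
    filial count resets to 1).  Each line leaves ``per_line_progeny``
    offspring per generation.
    """
    if not pop:
        raise ValueError("population must be non-empty")
    if scheme not in ("selfing", "backcross"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "backcross" and recurrent is None:
        raise ValueError("backcross scheme requires a recurrent parent")
    if n_generations < 1 or per_line_progeny < 1:
        raise ValueError("n_generations and per_line_progeny must be >= 1")
    current = list(pop)
    for _ in range(n_generations):
        label = _next_label(current[0].generation, scheme)
        nxt: list[LineGenotype] = []
        for parent in current:
            for i in range(per_line_progeny):
                egg = make_gamete(parent, gmap, rng)
                if scheme == "selfing":
                    sperm = make_gamete(parent, gmap, rng)
                else:
                    sperm = make_gamete(recurrent, gmap, rng)
                nxt.append(
                    LineGenotype(f"{parent.line_id}.{i + 1}", egg, sperm, label)
                )
        current = nxt
    return current


def grow_to_size(
    pop: Sequence[LineGenotype],
    scheme: str,
    target_size: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
    recurrent: Optional[LineGenotype] = None,
) -> list[LineGenotype]:
    """Advance one generation to an exact population size.

    Parents are cycled in order so each contributes as evenly as possible.
    """
    if not pop:
        raise ValueError("population must be non-empty")
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    label = _next_label(pop[0].generation, scheme)
    out: list[LineGenotype] = []
    for i in range(target_size):
        parent = pop[i % len(pop)]
        egg = make_gamete(parent, gmap, rng)
        if scheme == "selfing":
            sperm = make_gamete(parent, gmap, rng)
        else:
            if recurrent is None:
                raise ValueError("backcross scheme requires a recurrent parent")
            sperm = make_gamete(recurrent, gmap, rng)
        out.append(LineGenotype(f"{label}-{i + 1}", egg, sperm, label))
    return out


@dataclass
class EffectModel:
    """Genetic and trial effect structure for simulated grain yield (kg/ha).

    ``additive`` maps QTL name -> (NS effect, RS effect) per donor-allele
    dose of 1 (homozygous donor); heterozygotes receive half.
    ``interaction`` maps a frozenset QTL pair -> (NS, RS) adjustment applied
    to the product of the two dosages (negative values model antagonistic
    pyramiding).  The drought baselines calibrate the stress-induced trial
    mean reduction.
    """

    baseline_ns: float = 5077.0
    baseline_rs: float = 2691.0
    additive: dict[str, tuple[float, float]] = field(default_factory=dict)
    interaction: dict[frozenset, tuple[float, float]] = field(default_factory=dict)
    line_effect_sd: float = 300.0
    residual_sd: float = 500.0
    replicate_sd: float = 150.0
    block_sd: float = 100.0

    def __post_init__(self) -> None:
        if self.baseline_ns <= 0 or self.baseline_rs <= 0:
            raise ValueError("baselines must be > 0")
        if self.baseline_rs > self.baseline_ns:
            raise ValueError("stress baseline must not exceed the non-stress baseline")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        for sd in (self.line_effect_sd, self.replicate_sd, self.block_sd):
            if sd < 0:
                raise ValueError("effect SDs must be >= 0")
        self.interaction = {frozenset(k): tuple(v) for k, v in self.interaction.items()}

    @classmethod
    def default(
        cls, qtl_names: Iterable[str], rng: np.random.Generator, **overrides
    ) -> "EffectModel":
        """Default calibration: per-QTL RS effect uniform on [300, 500] kg/ha,
        NS effect 0.3× the RS effect, no QTL×QTL interaction."""
        additive = {}
        for name in qtl_names:
            rs = float(rng.uniform(300.0, 500.0))
            additive[name] = (0.3 * rs, rs)
        return cls(additive=additive, **overrides)

    def effect(self, qtl: str, env: str) -> float:
        ns, rs = self.additive.get(qtl, (0.0, 0.0))
        return ns if env == "NS" else rs

    def pair_effect(self, pair: frozenset, env: str) -> float:
        ns, rs = self.interaction.get(pair, (0.0, 0.0))
        return ns if env == "NS" else rs

    def baseline(self, env: str) -> float:
        return self.baseline_ns if env == "NS" else self.baseline_rs


@dataclass
class TrialDesign:
    """Replicated yield-trial layout (each line appears once per replicate)."""

    environments: tuple[str, ...] = ("NS", "RS")
    n_replicates: int = 2
    n_blocks_per_replicate: int = 1
    plot_size_m2: float = 1.54

    def __post_init__(self) -> None:
        self.environments = tuple(self.environments)
        for env in self.environments:
            if env not in ("NS", "RS"):
                raise ValueError(f"environment must be NS or RS, got {env!r}")
        if self.n_replicates < 1 or self.n_blocks_per_replicate < 1:
            raise ValueError("replicate and block counts must be >= 1")


def qtl_dosages(
    pop: Sequence[LineGenotype], qtl_defs: Sequence[QTLDefinition], gmap: GeneticMap
) -> pd.DataFrame:
    """True donor-QTL dosage per line from the simulated peak-locus genotype."""
    idx = [gmap.index[q.peak_marker] for q in qtl_defs]
    data = np.array([line.dosage[idx] for line in pop])
    return pd.DataFrame(
        data, index=[l.line_id for l in pop], columns=[q.name for q in qtl_defs]
    )


def simulate_trial(
    pop: Sequence[LineGenotype],
    qtl_defs: Sequence[QTLDefinition],
    effects: EffectModel,
    design: TrialDesign,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Phenotype a population in a replicated NS/RS yield trial.

    yield = env baseline + Σ_j a_j(env)·x_j + Σ_{j<k} γ_jk(env)·x_j·x_k
            + line + replicate + block(replicate) + residual,
    with x_j the true donor dosage at QTL j's peak locus.  Blocks within a
    replicate partition the lines into contiguous, equal-sized groups.
    Returns one record per line × environment × replicate.
    """
    if not pop:
        raise ValueError("population must be non-empty")
    dos = qtl_dosages(pop, qtl_defs, gmap)
    n = len(pop)
    qtl_names = [q.name for q in qtl_defs]
    line_effects = rng.normal(0.0, effects.line_effect_sd, size=n) if effects.line_effect_sd else np.zeros(n)
    # block membership is a property of the line (same blocks in every replicate)
    block_of = np.minimum(
        (np.arange(n) * design.n_blocks_per_replicate) // max(n, 1),
        design.n_blocks_per_replicate - 1,
    ) + 1

    genetic = {}
    for env in design.environments:
        g = np.full(n, effects.baseline(env))
        for name in qtl_names:
            g = g + effects.effect(name, env) * dos[name].to_numpy()
        for pair, _ in effects.interaction.items():
            a, b = sorted(pair)
            if a in dos.columns and b in dos.columns:
                g = g + effects.pair_effect(pair, env) * dos[a].to_numpy() * dos[b].to_numpy()
        genetic[env] = g

    records = []
    for env in design.environments:
        for rep in range(1, design.n_replicates + 1):
            rep_eff = rng.normal(0.0, effects.replicate_sd) if effects.replicate_sd else 0.0
            n_blocks = design.n_blocks_per_replicate
            blk_eff = (
                rng.normal(0.0, effects.block_sd, size=n_blocks)
                if effects.block_sd
                else np.zeros(n_blocks)
            )
            resid = rng.normal(0.0, effects.residual_sd, size=n)
            y = genetic[env] + line_effects + rep_eff + blk_eff[block_of - 1] + resid
            for i, line in enumerate(pop):
                records.append(
                    (line.line_id, line.generation, env, rep, int(block_of[i]), y[i])
                )
    return pd.DataFrame(
        records,
        columns=["line_id", "generation", "environment", "replicate", "block", "grain_yield_kg_ha"],
    )


def genotype_codes(pop: Sequence[LineGenotype], gmap: GeneticMap) -> pd.DataFrame:
    """Marker-code matrix (A/H/B) indexed by line_id, one column per marker."""
    total = np.array([line.maternal + line.paternal for line in pop], dtype=np.int8)
    codes = np.full(total.shape, "H", dtype="<U1")
    codes[total == 2] = "A"
    codes[total == 0] = "B"
    df = pd.DataFrame(codes, index=[l.line_id for l in pop], columns=gmap.names)
    df.index.name = "line_id"
    return df
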