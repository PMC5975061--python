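"""Delimited-text readers/writers, pipeline configuration, and run manifests.

All tabular formats are comma-separated UTF-8 with a required header row.
Genotype codes are A (donor homozygote), B (recipient homozygote),
H (heterozygote) and "-" (missing); "." is deliberately not accepted as
missing to avoid ambiguity with decimal points.
"""

from __future__ import annotations

import csv
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from .classify import VALID_CODES, QTLDefinition
from .costs import GenerationPlan, GenerationPlanRow
from .simulate import parse_generation

ENVIRONMENTS = ("NS", "RS")

PHENOTYPE_COLUMNS = [
    "line_id",
    "generation",
    "environment",
    "replicate",
    "block",
    "grain_yield_kg_ha",
]


def _check_header(path: Path, expected_first: str) -> list[str]:
    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh))
    if not header or header[0] != expected_first:
        raise ValueError(f"{path}: first column must be {expected_first!r}, got {header[:1]}")
    dupes = {c for c in header if header.count(c) > 1}
    if dupes:
        raise ValueError(f"{path}: duplicate column(s) {sorted(dupes)}")
    return header


def write_genotypes(genotypes: pd.DataFrame, path: str | Path) -> None:
    """Write a line × marker code matrix (first column line_id)."""
    df = genotypes.copy()
    df.index.name = "line_id"
    df.to_csv(path)


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Read and validate a genotype matrix; returns it indexed by line_id."""
    path = Path(path)
    _check_header(path, "line_id")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.set_index("line_id")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate line_id(s) {dupes[:10]}")
    for col in df.columns:
        bad = ~df[col].isin(VALID_CODES)
        if bad.any():
            line = df.index[bad.to_numpy().argmax()]
            val = df.loc[line, col]
            raise ValueError(
                f"{path}: invalid genotype code {val!r} at line {line!r}, marker {col!r} "
                "(expected A, B, H or -)"
            )
    return df


def write_phenotypes(records: pd.DataFrame, path: str | Path) -> None:
    records[PHENOTYPE_COLUMNS].to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read and validate plot records (yields finite and >= 0, env NS/RS)."""
    path = Path(path)
    _check_header(path, "line_id")
    df = pd.read_csv(path)
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    bad_env = ~df["environment"].isin(ENVIRONMENTS)
    if bad_env.any():
        raise ValueError(
            f"{path}: environment must be one of {ENVIRONMENTS}, "
            f"got {df.loc[bad_env, 'environment'].unique().tolist()[:5]}"
        )
    for label in df["generation"].unique():
        parse_generation(str(label))
    y = pd.to_numeric(df["grain_yield_kg_ha"], errors="coerce")
    if not ((y >= 0) & (y < float("inf"))).all() or y.isna().any():
        raise ValueError(f"{path}: grain_yield_kg_ha must be finite numbers >= 0")
    df["grain_yield_kg_ha"] = y
    df["line_id"] = df["line_id"].astype(str)
    return df


def write_qtl_definitions(qtl_defs: Sequence[QTLDefinition], path: str | Path) -> None:
    rows = [
        {
            "name": q.name,
            "chromosome": q.chromosome,
            "peak_marker": q.peak_marker,
            "left_flank1": q.left_flanks[0],
            "left_flank2": q.left_flanks[1],
            "right_flank1": q.right_flanks[0],
            "right_flank2": q.right_flanks[1],
        }
        for q in qtl_defs
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_qtl_definitions(path: str | Path) -> list[QTLDefinition]:
    df = pd.read_csv(path, dtype=str)
    required = {
        "name",
        "chromosome",
        "peak_marker",
        "left_flank1",
        "left_flank2",
        "right_flank1",
        "right_flank2",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        QTLDefinition(
            name=r["name"],
            chromosome=r["chromosome"],
            peak_marker=r["peak_marker"],
            left_flanks=(r["left_flank1"], r["left_flank2"]),
            right_flanks=(r["right_flank1"], r["right_flank2"]),
        )
        for _, r in df.iterrows()
    ]


def write_assignments(assignments: pd.DataFrame, path: str | Path) -> None:
    assignments.to_csv(path, index=False)


def read_assignments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"line_id": str, "class_label": str})
    missing = {"line_id", "class_label"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def write_plans(plans: Sequence[GenerationPlan], path: str | Path) -> None:
    rows = []
    for p in plans:
        for r in p.rows:
            rows.append(
                {
                    "background": p.background,
                    "generation": r.generation,
                    "n_qtls": p.n_qtls,
                    "n_all": r.n_all,
                    "n_selected": r.n_selected,
                    "n_classes_all": r.n_classes_all,
                    "n_classes_selected": r.n_classes_selected,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plans(path: str | Path) -> list[GenerationPlan]:
    df = pd.read_csv(path)
    required = {"background", "generation", "n_qtls", "n_all", "n_selected"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    plans = []
    for bg, grp in df.groupby("background", sort=False):
        n_qtls = int(grp["n_qtls"].iloc[0])
        rows = [
            GenerationPlanRow(
                generation=str(r["generation"]),
                n_all=int(r["n_all"]),
                n_selected=int(r["n_selected"]),
                n_classes_all=int(r["n_classes_all"]) if "n_classes_all" in grp.columns and pd.notna(r.get("n_classes_all")) else None,
                n_classes_selected=int(r["n_classes_selected"]) if "n_classes_selected" in grp.columns and pd.notna(r.get("n_classes_selected")) else None,
            )
            for _, r in grp.iterrows()
        ]
        plans.append(GenerationPlan(background=str(bg), n_qtls=n_qtls, rows=rows))
    return plans


# ---------------------------------------------------------------------------
# configuration and manifests


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "map": {"spacing_cM": 5.0, "qtl_gap_cM": 50.0},
    "scheme": "selfing",  # or "backcross"
    "n_backcrosses": 0,
    "population": {"f2_size": 400, "final_generation": "F7"},
    "effects": {
        "baseline_ns": 5077.0,
        "baseline_rs": 2691.0,
        "ns_fraction": 0.3,
        "line_effect_sd": 300.0,
        "residual_sd": 500.0,
        "replicate_sd": 150.0,
        "block_sd": 100.0,
    },
    "trial": {"environments": ["NS", "RS"], "n_replicates": 2, "n_blocks_per_replicate": 1},
    "calling": {"mode": "flanked", "max_missing_outer": 1},
    "assignment_policy": "drop_segregating",
    "selection": {"alpha": 0.05, "require_both_envs": True, "min_lines_per_class": 3},
    "costs": {"markers_per_qtl": 5, "genotyping_unit": 0.50, "phenotyping_unit": 36.18},
}


def _deep_update(base: dict, other: dict) -> dict:
    out = dict(base)
    for k, v in other.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load a YAML pipeline config, filling unspecified keys with defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: config must be a mapping")
        cfg = _deep_update(cfg, user)
    return cfg


def config_hash(cfg: dict[str, Any]) -> str:
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline run: config hash, seed, and output checksums."""

    config_hash: str
    seed: int
    started: float = field(default_factory=time.time)
    files: dict[str, str] = field(default_factory=dict)

    def add(self, path: str | Path) -> None:
        self.files[str(path)] = file_sha256(path)

    def write(self, path: str | Path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "started": self.started,
            "finished": time.time(),
            "files": self.files,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
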