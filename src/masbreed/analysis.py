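"""Per-trial QTL-class analysis: nested linear model, mean separation, letters.

The model for a single trial (one generation × one environment) is

    y_ijkl = mu + r_k + b(r)_kl + q_i + g(q)_ij + e_ijkl

with q_i the QTL-class effect, g(q)_ij the genotype (line) nested within
class, r_k the replicate and b(r)_kl the block within replicate.  Replicate
and block enter the estimation skeleton as fixed adjustment terms while
their variance components are reported separately (balanced-ANOVA estimator
by default, REML via statsmodels on request).  Class least-squares means
are unweighted averages of the member genotypes' adjusted means, so on
balanced data they equal arithmetic class means.  The class F test and all
pairwise comparisons use genotype-within-class as the error stratum — the
containment denominator for a factor whose replicates are the lines — so
with a single plot per line the test collapses exactly to one-way ANOVA
across lines.

Pairwise class comparisons use Fisher's protected LSD by default (Tukey HSD
optional); letter groups are the compact letter display in which two
classes share a letter iff they are not significantly different.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .classify import PARENT_CLASS_LABEL

__all__ = [
    "ClassModelFit",
    "ClassAnalysisResult",
    "fit_class_model",
    "letter_display",
    "analyze_trial",
    "yield_advantage",
    "stress_reduction",
]


@dataclass
class ClassModelFit:
    """Fitted nested class model for one trial."""

    class_means: pd.Series
    class_se: pd.Series
    n_lines: pd.Series
    trial_mean: float
    f_value: float
    p_value: float
    df_num: int
    df_den: int
    sigma2: float
    pairwise_p: pd.DataFrame
    variance_components: dict[str, float] = field(default_factory=dict)
    comparison: str = "lsd"

    @property
    def classes(self) -> list[str]:
        return list(self.class_means.index)


@dataclass
class ClassAnalysisResult:
    """Class means with letter groups, the class F test, and the parent contrast."""

    table: pd.DataFrame  # columns: class_label, n_lines, mean, se, letters, flagged
    trial_mean: float
    f_value: float
    p_value: float
    parent_mean: float
    alpha: float
    comparison: str
    protected: bool

    @property
    def classes(self) -> list[str]:
        return list(self.table["class_label"])

    def mean(self, label: str) -> float:
        return float(self.table.set_index("class_label").loc[label, "mean"])

    def letters(self) -> dict[str, str]:
        return dict(zip(self.table["class_label"], self.table["letters"]))

    def n_lines(self) -> dict[str, int]:
        return dict(zip(self.table["class_label"], self.table["n_lines"]))


def _dummies(levels: pd.Series, drop_first: bool) -> tuple[np.ndarray, list]:
    cats = sorted(levels.unique())
    use = cats[1:] if drop_first else cats
    cols = np.column_stack([(levels == c).to_numpy(float) for c in use]) if use else np.empty((len(levels), 0))
    return cols, use


def _anova_variance_components(df: pd.DataFrame, sigma2: float) -> dict[str, float]:
    """Method-of-moments replicate/block components, truncated at zero.

    Balanced-design estimator: var(rep) from the between-replicate mean
    square of replicate means, var(block) analogously within replicates.
    Coincides with REML in expectation for the balanced layouts the
    simulator produces; purely descriptive (tests use the fixed skeleton).
    """
    out: dict[str, float] = {"residual": sigma2}
    reps = df.groupby("replicate")["grain_yield_kg_ha"]
    if reps.ngroups > 1:
        m = reps.mean()
        n_per = df.groupby("replicate").size().mean()
        out["replicate"] = max(float(m.var(ddof=1) - sigma2 / n_per), 0.0)
    else:
        out["replicate"] = 0.0
    blocks = df.groupby(["replicate", "block"])["grain_yield_kg_ha"]
    if blocks.ngroups > df["replicate"].nunique():
        dev = blocks.mean() - df.groupby("replicate")["grain_yield_kg_ha"].mean()
        n_per = df.groupby(["replicate", "block"]).size().mean()
        out["block"] = max(float((dev**2).mean() - sigma2 / n_per), 0.0)
    else:
        out["block"] = 0.0
    return out


def _reml_variance_components(df: pd.DataFrame) -> dict[str, float]:
    import statsmodels.formula.api as smf

    d = df.assign(one=1, rb=df["replicate"].astype(str) + ":" + df["block"].astype(str))
    vcf = {"replicate": "0 + C(replicate)"}
    if d["rb"].nunique() > d["replicate"].nunique():
        vcf["block"] = "0 + C(rb)"
    model = smf.mixedlm(
        "grain_yield_kg_ha ~ C(class_label) + C(class_label):C(line_id)",
        data=d,
        groups="one",
        vc_formula=vcf,
    )
    fit = model.fit(reml=True)
    comps = {name: float(v) for name, v in zip(model.exog_vc.names, fit.vcomp)}
    comps.setdefault("block", 0.0)
    comps["residual"] = float(fit.scale)
    return comps


def fit_class_model(
    records: pd.DataFrame,
    assignments: pd.DataFrame,
    comparison: str = "lsd",
    vc_method: str = "anova",
) -> ClassModelFit:
    """Fit the nested class model to one trial's plot records.

    ``records`` needs columns line_id, replicate, block, grain_yield_kg_ha
    (a single environment); ``assignments`` maps line_id -> class_label.
    Raises on unassigned records and on fewer than two classes.
    """
    if comparison not in ("lsd", "tukey"):
        raise ValueError(f"unknown comparison {comparison!r}")
    amap = assignments.dropna(subset=["class_label"]).set_index("line_id")["class_label"]
    if amap.index.has_duplicates:
        raise ValueError("duplicate line_id in assignments")
    if "environment" in records.columns and records["environment"].nunique() > 1:
        raise ValueError("records span multiple environments; fit one trial at a time")
    orphans = sorted(set(records["line_id"]) - set(amap.index))
    if orphans:
        raise ValueError(f"records with no class assignment: {orphans[:10]}")
    df = records.copy()
    df["class_label"] = df["line_id"].map(amap)
    classes = sorted(df["class_label"].unique())
    if len(classes) < 2:
        raise ValueError("need >= 2 QTL classes with data; F test undefined for one class")

    y = df["grain_yield_kg_ha"].to_numpy(float)
    n_obs = len(y)
    ones = np.ones((n_obs, 1))
    rep_cols, rep_levels = _dummies(df["replicate"], drop_first=True)
    # block within replicate: one dummy per (rep, block) beyond the first block of each rep
    rb = list(zip(df["replicate"], df["block"]))
    rb_ser = pd.Series(rb, index=df.index)
    blk_parts: list[np.ndarray] = []
    blk_levels: list[tuple] = []
    for rep in sorted(df["replicate"].unique()):
        blocks = sorted(df.loc[df["replicate"] == rep, "block"].unique())
        for b in blocks[1:]:
            blk_parts.append((rb_ser == (rep, b)).to_numpy(float)[:, None])
            blk_levels.append((rep, b))
    blk_cols = np.hstack(blk_parts) if blk_parts else np.empty((n_obs, 0))
    lines = sorted(df["line_id"].unique())
    line_idx = {l: i for i, l in enumerate(lines)}
    line_cols = np.zeros((n_obs, len(lines)))
    line_cols[np.arange(n_obs), [line_idx[l] for l in df["line_id"]]] = 1.0

    X = np.hstack([ones, rep_cols, blk_cols, line_cols])
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps
    keep = s > tol
    rank = int(keep.sum())
    Xp = (Vt[keep].T / s[keep]) @ U[:, keep].T  # pseudoinverse of X
    beta = Xp @ y
    fitted = X @ beta
    rss = float(((y - fitted) ** 2).sum())
    df_resid = n_obs - rank
    sigma2 = rss / df_resid if df_resid > 0 else np.nan
    H = Vt[keep].T @ np.diag(1.0 / s[keep] ** 2) @ Vt[keep]  # pinv(X'X)

    # LS-mean row vectors: averages over the replicate × block grid
    n_rep_levels = len(rep_levels) + 1
    rep_part = np.full(len(rep_levels), 1.0 / n_rep_levels)
    blk_part = np.zeros(len(blk_levels))
    for j, (rep, _) in enumerate(blk_levels):
        n_blocks_rep = df.loc[df["replicate"] == rep, "block"].nunique()
        blk_part[j] = 1.0 / (n_rep_levels * n_blocks_rep)
    rows_by_line = {}
    for l, i in line_idx.items():
        z = np.zeros(X.shape[1])
        z[0] = 1.0
        z[1 : 1 + len(rep_levels)] = rep_part
        z[1 + len(rep_levels) : 1 + len(rep_levels) + len(blk_levels)] = blk_part
        z[1 + len(rep_levels) + len(blk_levels) + i] = 1.0
        rows_by_line[l] = z

    members = {c: [l for l in lines if amap[l] == c] for c in classes}
    line_means = pd.Series({l: float(rows_by_line[l] @ beta) for l in lines})
    means = pd.Series(
        {c: float(np.mean([line_means[l] for l in members[c]])) for c in classes}
    )
    n_lines = pd.Series({c: len(members[c]) for c in classes})

    # inference at the line level: genotype-within-class is the error stratum
    # for class comparisons (contained by the class term), so with one plot
    # per line the class test collapses to the ordinary one-way ANOVA
    k = len(classes)
    n_total = len(lines)
    df_within = n_total - k
    grand = float(np.mean([line_means[l] for l in lines]))
    ss_between = float(sum(n_lines[c] * (means[c] - grand) ** 2 for c in classes))
    ss_within = float(
        sum((line_means[l] - means[c]) ** 2 for c in classes for l in members[c])
    )
    if df_within > 0:
        ms_within = ss_within / df_within
        ms_between = ss_between / (k - 1)
        if ms_within > 0:
            f_value = ms_between / ms_within
            p_value = float(stats.f.sf(f_value, k - 1, df_within))
        else:
            f_value = np.inf if ms_between > 0 else np.nan
            p_value = 0.0 if ms_between > 0 else np.nan
    else:
        ms_within = np.nan
        f_value, p_value = np.nan, np.nan

    se = pd.Series(
        {
            c: float(np.sqrt(ms_within / n_lines[c])) if df_within > 0 else np.nan
            for c in classes
        }
    )

    pp = np.ones((k, k))
    if df_within > 0 and ms_within > 0:
        for i in range(k):
            for j in range(i + 1, k):
                ci, cj = classes[i], classes[j]
                sed = np.sqrt(ms_within * (1.0 / n_lines[ci] + 1.0 / n_lines[cj]))
                if comparison == "lsd":
                    t = (means[ci] - means[cj]) / sed
                    p = 2.0 * stats.t.sf(abs(t), df_within)
                else:
                    q = abs(means[ci] - means[cj]) / (sed / np.sqrt(2.0))
                    p = float(stats.studentized_range.sf(q, k, df_within))
                pp[i, j] = pp[j, i] = p
    pairwise_p = pd.DataFrame(pp, index=classes, columns=classes)

    if vc_method == "reml":
        try:
            vc = _reml_variance_components(df)
        except Exception:
            vc = _anova_variance_components(df, sigma2)
    elif vc_method == "anova":
        vc = _anova_variance_components(df, sigma2) if np.isfinite(sigma2) else {}
    elif vc_method == "none":
        vc = {}
    else:
        raise ValueError(f"unknown vc_method {vc_method!r}")

    return ClassModelFit(
        class_means=means,
        class_se=se,
        n_lines=n_lines,
        trial_mean=float(np.mean(y)),
        f_value=f_value,
        p_value=p_value,
        df_num=k - 1,
        df_den=max(df_within, 0),
        sigma2=sigma2,
        pairwise_p=pairwise_p,
        variance_components=vc,
        comparison=comparison,
    )


def letter_display(
    class_means: pd.Series, pairwise_p: pd.DataFrame, alpha: float = 0.05
) -> pd.Series:
    """Compact letter display: classes share a letter iff not significantly different.

    Classes are ranked by descending mean; letter groups are the maximal
    cliques of the non-significance graph (p >= alpha), lettered a, b, c, …
    in order of their best member's mean.  This is the fixed point of the
    insert-and-absorb construction.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    classes = list(class_means.sort_values(ascending=False).index)
    g = nx.Graph()
    g.add_nodes_from(classes)
    for i, a in enumerate(classes):
        for j in range(i + 1, len(classes)):
            b = classes[j]
            if float(pairwise_p.loc[a, b]) >= alpha:
                g.add_edge(a, b)
    cliques = [frozenset(c) for c in nx.find_cliques(g)]
    rank = {c: i for i, c in enumerate(classes)}
    cliques.sort(key=lambda cl: min(rank[c] for c in cl))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {c: "" for c in classes}
    for i, cl in enumerate(cliques):
        sym = alphabet[i] if i < len(alphabet) else f"({i + 1})"
        for c in cl:
            letters[c] += sym
    return pd.Series({c: "".join(sorted(letters[c])) for c in classes}).reindex(
        class_means.index
    )


def analyze_trial(
    records: pd.DataFrame,
    assignments: pd.DataFrame,
    alpha: float = 0.05,
    comparison: str = "lsd",
    protected: bool = True,
    min_lines_flag: int = 3,
    vc_method: str = "anova",
) -> ClassAnalysisResult:
    """Full per-trial class analysis: fit, letters, parent contrast.

    With ``protected`` (Fisher's protected LSD) the pairwise separation is
    only interpreted when the class F test is significant at ``alpha``;
    otherwise every class shares the letter ``a``.  Classes with fewer than
    ``min_lines_flag`` lines are reported but flagged.
    """
    fit = fit_class_model(records, assignments, comparison=comparison, vc_method=vc_method)
    if protected and not (np.isfinite(fit.p_value) and fit.p_value < alpha):
        letters = pd.Series("a", index=fit.class_means.index)
    else:
        letters = letter_display(fit.class_means, fit.pairwise_p, alpha=alpha)
    order = fit.class_means.sort_values(ascending=False).index
    table = pd.DataFrame(
        {
            "class_label": order,
            "n_lines": fit.n_lines.reindex(order).to_numpy(),
            "mean": fit.class_means.reindex(order).to_numpy(),
            "se": fit.class_se.reindex(order).to_numpy(),
            "letters": letters.reindex(order).to_numpy(),
            "flagged": (fit.n_lines.reindex(order) < min_lines_flag).to_numpy(),
        }
    ).reset_index(drop=True)
    parent_mean = (
        float(fit.class_means[PARENT_CLASS_LABEL])
        if PARENT_CLASS_LABEL in fit.class_means.index
        else float("nan")
    )
    return ClassAnalysisResult(
        table=table,
        trial_mean=fit.trial_mean,
        f_value=fit.f_value,
        p_value=fit.p_value,
        parent_mean=parent_mean,
        alpha=alpha,
        comparison=comparison,
        protected=protected,
    )


def yield_advantage(class_mean: float, parent_mean: float) -> float:
    """Grain-yield advantage of a QTL class over the recipient parent (kg/ha)."""
    return class_mean - parent_mean


def stress_reduction(ns_trial_mean: float, rs_trial_mean: float) -> float:
    """Percent reduction of the trial mean under stress: 100 × (1 − RS/NS)."""
    if ns_trial_mean <= 0:
        raise ValueError("non-stress trial mean must be > 0")
    return 100.0 * (1.0 - rs_trial_mean / ns_trial_mean)
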