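"""Effect of normalizer choice on target-gene expression.

Relative expression of a target gene in a sample is quantified against a
chosen reference (housekeeping) gene as

    q = 2^-(Ct_target − Ct_normalizer),

the standard ΔCt quantification at 100 % amplification efficiency.  From
these, three views of normalizer impact are built:

- a pairwise sample ratio matrix (column sample vs row sample) with two-fold
  flags: ``up`` for ratios > 2, ``down`` for < 0.5, else ``unchanged``;
- an apparent-modulation ("artifact") matrix: the cell-wise quotient of the
  worst-normalizer ratios over the best-normalizer ratios, flagging cells
  outside [0.5, 2] as normalization artifacts;
- group-level comparisons: per-group mean relative expression, fold change
  of means, a Shapiro–Wilk normality gate (α = 0.01), an unpaired t-test
  for two groups or a repeated-measures one-way ANOVA with Tukey's post-hoc
  test for three, and a dual-threshold significance verdict
  (p < 0.05 *and* fold change > 2).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .qpcr_data import CtMatrix, DatasetSlice, ValidationError

ALPHA_NORMALITY = 0.01
ALPHA_SIGNIF = 0.05
FOLD_THRESHOLD = 2.0

FLAG_UP = "up"
FLAG_DOWN = "down"
FLAG_UNCHANGED = "unchanged"


@dataclasses.dataclass
class RelExprTable:
    """Per-sample relative expression (2^-ΔCt) of target genes."""

    normalizer: str
    q: pd.DataFrame            # samples × targets, strictly positive
    meta: pd.DataFrame         # donor/group per sample

    @property
    def targets(self) -> list[str]:
        return list(self.q.columns)

    def to_frame(self) -> pd.DataFrame:
        out = self.q.copy()
        out.insert(0, "normalizer", self.normalizer)
        return out


@dataclasses.dataclass
class RatioMatrix:
    """Pairwise sample expression ratios for one target under one normalizer.

    ``ratios.loc[b, a]`` is q_a / q_b: the column sample against the row
    sample.  Antisymmetry r_ab · r_ba = 1 holds by construction.
    """

    target: str
    normalizer: str
    ratios: pd.DataFrame       # samples × samples
    flags: pd.DataFrame        # same shape, categorical strings

    def flag_count(self, off_diagonal_only: bool = True) -> int:
        mask = self.flags.isin([FLAG_UP, FLAG_DOWN]).to_numpy()
        if off_diagonal_only:
            np.fill_diagonal(mask, False)
        return int(mask.sum())

    def to_frame(self) -> pd.DataFrame:
        return self.ratios


@dataclasses.dataclass
class ArtifactMatrix:
    """Apparent ratio modulation: worst-normalizer over best-normalizer."""

    target: str
    best_normalizer: str
    worst_normalizer: str
    modulation: pd.DataFrame
    flags: pd.DataFrame        # boolean: outside [0.5, 2]

    def flag_count(self) -> int:
        mask = self.flags.to_numpy().copy()
        np.fill_diagonal(mask, False)
        return int(mask.sum())

    def to_frame(self) -> pd.DataFrame:
        return self.modulation


@dataclasses.dataclass
class GroupComparison:
    """Group-level test of a target gene's relative expression."""

    target: str
    normalizer: str
    groups: list[str]
    group_means: pd.Series
    normality_p: pd.Series        # Shapiro–Wilk p per group
    normality_ok: bool            # every group passes at α = 0.01
    test: str                     # "t-test" | "RM-ANOVA+Tukey" | "ANOVA+Tukey"
    p_value: float                # overall test p (t-test or ANOVA F)
    pairwise: pd.DataFrame        # per-pair p (Tukey-adjusted for 3 groups),
                                  # fold change of means, and verdict

    @property
    def significant_pairs(self) -> list[tuple[str, str]]:
        return [
            (r["group_a"], r["group_b"])
            for _, r in self.pairwise.iterrows()
            if r["significant"]
        ]

    def to_frame(self) -> pd.DataFrame:
        return self.pairwise


def relative_expression(
    d: CtMatrix | DatasetSlice,
    targets: Sequence[str],
    normalizer: str,
) -> RelExprTable:
    """Relative expression q = 2^-(Ct_target − Ct_normalizer) per sample."""
    all_genes = set(d.genes)
    unknown = [g for g in [*targets, normalizer] if g not in all_genes]
    if unknown:
        raise ValidationError(f"unknown gene(s) {unknown}")
    if normalizer in targets:
        warnings.warn(
            f"normalizer {normalizer!r} is also a target; its relative "
            "expression is identically 1",
            stacklevel=2,
        )
    cols = d.values[[*targets]]
    norm = d.values[normalizer]
    block = pd.concat([cols, norm], axis=1)
    if block.isna().to_numpy().any():
        raise ValidationError("missing Ct values in targets or normalizer")
    q = 2.0 ** -(cols.sub(norm, axis=0))
    return RelExprTable(normalizer=normalizer, q=q, meta=d.meta)


def ratio_matrix(
    e: RelExprTable,
    target: str,
    samples: Sequence[str] | None = None,
) -> RatioMatrix:
    """Full pairwise ratio matrix with two-fold flags for one target."""
    if target not in e.q.columns:
        raise ValidationError(f"unknown target {target!r}")
    q = e.q[target]
    if samples is not None:
        q = q.loc[list(samples)]
    if len(q) < 2:
        raise ValidationError("ratio matrix needs at least 2 samples")
    vals = q.to_numpy(dtype=float)
    r = vals[None, :] / vals[:, None]      # row b, col a -> q_a / q_b
    ratios = pd.DataFrame(r, index=q.index, columns=q.index)
    flags = pd.DataFrame(FLAG_UNCHANGED, index=q.index, columns=q.index)
    flags = flags.mask(ratios > FOLD_THRESHOLD, FLAG_UP)
    flags = flags.mask(ratios < 1.0 / FOLD_THRESHOLD, FLAG_DOWN)
    np.fill_diagonal(flags.values, FLAG_UNCHANGED)
    return RatioMatrix(target=target, normalizer=e.normalizer, ratios=ratios, flags=flags)


def artifact_matrix(best: RatioMatrix, worst: RatioMatrix) -> ArtifactMatrix:
    """Apparent modulation: worst-normalizer ratios over best-normalizer.

    Cells with modulation outside [0.5, 2] are flagged as artifacts: the
    normalizer choice alone moves the apparent ratio by more than two-fold.
    """
    if best.target != worst.target:
        raise ValidationError(
            f"target mismatch: {best.target!r} vs {worst.target!r}"
        )
    if list(best.ratios.index) != list(worst.ratios.index):
        raise ValidationError("sample sets of the two ratio matrices differ")
    m = worst.ratios / best.ratios
    flags = (m > FOLD_THRESHOLD) | (m < 1.0 / FOLD_THRESHOLD)
    return ArtifactMatrix(
        target=best.target,
        best_normalizer=best.normalizer,
        worst_normalizer=worst.normalizer,
        modulation=m,
        flags=flags,
    )


def compare_groups(
    e: RelExprTable,
    target: str,
    grouping: str = "group",
    paired: bool = True,
) -> GroupComparison:
    """Group-level comparison of relative expression for one target.

    Two groups → unpaired t-test; three groups → repeated-measures one-way
    ANOVA (donor position as the repeated factor) with Tukey's post-hoc
    test, or an ordinary one-way ANOVA when ``paired=False``.  Significance
    per pair requires both p < 0.05 and a fold change of means > 2.
    """
    if target not in e.q.columns:
        raise ValidationError(f"unknown target {target!r}")
    labels = list(dict.fromkeys(e.meta[grouping]))
    if len(labels) < 2:
        raise ValidationError("compare_groups needs at least 2 groups")
    values = {g: e.q.loc[e.meta[grouping] == g, target].to_numpy() for g in labels}
    sizes = {g: len(v) for g, v in values.items()}
    if min(sizes.values()) < 2:
        raise ValidationError(f"group sizes too small: {sizes}")
    if min(sizes.values()) < 3:
        raise ValidationError(
            f"need at least 3 samples per group for testing: {sizes}"
        )

    normality_p = pd.Series(
        {g: float(stats.shapiro(v).pvalue) for g, v in values.items()}
    )
    normality_ok = bool((normality_p >= ALPHA_NORMALITY).all())
    if not normality_ok:
        warnings.warn(
            f"{target}: Shapiro-Wilk normality rejected at α={ALPHA_NORMALITY} "
            f"for group(s) {normality_p[normality_p < ALPHA_NORMALITY].index.tolist()}; "
            "parametric test reported regardless",
            stacklevel=2,
        )

    means = pd.Series({g: float(v.mean()) for g, v in values.items()})

    if len(labels) == 2:
        test_name = "t-test"
        a, b = labels
        res = stats.ttest_ind(values[a], values[b])
        overall_p = float(res.pvalue)
        pair_p = {(a, b): overall_p}
    else:
        if paired:
            test_name = "RM-ANOVA+Tukey"
            overall_p = _rm_anova_p(values, labels)
        else:
            test_name = "ANOVA+Tukey"
            overall_p = float(stats.f_oneway(*[values[g] for g in labels]).pvalue)
        pair_p = _tukey_pairwise(values, labels)

    rows = []
    for (a, b), p in pair_p.items():
        fc = _fold_change(means[a], means[b])
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_a": means[a],
                "mean_b": means[b],
                "fold_change": fc,
                "p_value": p,
                "significant": bool(p < ALPHA_SIGNIF and fc > FOLD_THRESHOLD),
            }
        )
    return GroupComparison(
        target=target,
        normalizer=e.normalizer,
        groups=labels,
        group_means=means,
        normality_p=normality_p,
        normality_ok=normality_ok,
        test=test_name,
        p_value=overall_p,
        pairwise=pd.DataFrame(rows),
    )


def _fold_change(a: float, b: float) -> float:
    """Fold change of means on the linear scale, reported as ≥ 1."""
    lo, hi = sorted([a, b])
    return hi / lo if lo > 0 else np.inf


def _rm_anova_p(values: dict[str, np.ndarray], labels: list[str]) -> float:
    """Repeated-measures one-way ANOVA, subject = position within group."""
    from statsmodels.stats.anova import AnovaRM

    sizes = {len(v) for v in values.values()}
    if len(sizes) != 1:
        raise ValidationError("repeated-measures ANOVA needs equal group sizes")
    n = sizes.pop()
    long = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), len(labels)),
            "group": np.repeat(labels, n),
            "value": np.concatenate([values[g] for g in labels]),
        }
    )
    res = AnovaRM(long, depvar="value", subject="subject", within=["group"]).fit()
    return float(res.anova_table["Pr > F"].iloc[0])


def _tukey_pairwise(
    values: dict[str, np.ndarray], labels: list[str]
) -> dict[tuple[str, str], float]:
    """Tukey-HSD adjusted p-values for all group pairs."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    data = np.concatenate([values[g] for g in labels])
    grp = np.concatenate([[g] * len(values[g]) for g in labels])
    res = pairwise_tukeyhsd(data, grp, alpha=ALPHA_SIGNIF)
    out = {}
    for row in res.summary().data[1:]:
        a, b, p = str(row[0]), str(row[1]), float(row[3])
        key = (a, b) if labels.index(a) < labels.index(b) else (b, a)
        out[key] = p
    return out
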