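"""The four reference-gene stability statistics.

All four methods score candidate housekeeping genes so that a *lower* value
means a *more stable* gene:

geNorm
    For gene j, the M-value is the mean over partner genes k of the standard
    deviation across samples of the pairwise log2 expression ratio.  With
    amplification efficiency fixed at 2, the log2 ratio of gene j to gene k
    in a sample is simply ``Ct_k − Ct_j``, so the whole computation runs on
    Ct differences directly.  The worst gene (highest M) is iteratively
    removed and M recomputed until the best pair remains.  Genes with
    M ≥ 1.5 are conventionally flagged as unstable.

Comparative ΔCt method
    The mean over partner genes of the SD of pairwise Ct differences — i.e.
    the geNorm M of the full panel without any iterative exclusion.  The two
    definitions coincide algebraically before the first exclusion step.

BestKeeper
    The SD of a gene's raw Ct values about their arithmetic mean (divisor-n
    convention), plus descriptive extras: the coefficient of variation and
    the Pearson correlation of the gene against the BestKeeper index (the
    per-sample geometric mean of all candidate Cts).  The ranking key is the
    SD alone.  Unlike geNorm/ΔCt, this statistic is *not* invariant to a
    global per-sample Ct offset.

NormFinder
    A model-based variance decomposition (Andersen et al. 2004).  Per-sample
    gene residuals (gene Ct minus the sample's mean Ct over candidates) are
    split into intra-group variance and inter-group bias; the stability
    value averages, over groups, the magnitude of the shrunken group
    difference plus its standard error.  With a single group the value
    reduces to the bias-corrected intra-group SD.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .qpcr_data import CtMatrix, DatasetSlice, ValidationError

GENORM_M_THRESHOLD = 1.5  # conventional instability flag

METHOD_ORDER = ("DeltaCt", "BestKeeper", "NormFinder", "geNorm")


@dataclasses.dataclass
class StabilityTable:
    """Per-gene stability values of one method on one condition.

    ``values`` maps gene → stability (lower = more stable); ``extras`` holds
    method-specific side outputs (geNorm best pair and exclusion order,
    BestKeeper CV and Pearson r, NormFinder variance components).
    """

    method: str
    condition: str
    values: pd.Series
    extras: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        vals = self.values.to_numpy(dtype=float)
        if (vals < -1e-12).any():
            raise ValidationError(f"{self.method}: negative stability value")
        self.values = self.values.clip(lower=0.0)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"stability": self.values})
        out.index.name = "gene"
        out.insert(0, "method", self.method)
        out.insert(1, "condition", self.condition)
        for key in ("cv", "pearson_r", "stepwise_m"):
            if key in self.extras:
                out[key] = self.extras[key]
        return out


def _ct_submatrix(d: CtMatrix | DatasetSlice, hkgs: Sequence[str] | None) -> pd.DataFrame:
    genes = list(hkgs) if hkgs is not None else [
        g for g in d.genes if getattr(d, "parent", d).gene_role[g] == "candidate_hkg"
    ]
    missing = [g for g in genes if g not in d.genes]
    if missing:
        raise ValidationError(f"unknown gene(s) {missing}")
    x = d.values[genes]
    if x.isna().to_numpy().any():
        bad = x.columns[x.isna().any()].tolist()
        raise ValidationError(
            f"missing Ct values in gene(s) {bad}; stability methods require complete data"
        )
    return x


def _check_dims(x: pd.DataFrame, min_genes: int = 2, min_samples: int = 3) -> None:
    if x.shape[1] < min_genes:
        raise ValidationError(f"need at least {min_genes} candidate genes, got {x.shape[1]}")
    if x.shape[0] < min_samples:
        raise ValidationError(f"need at least {min_samples} samples, got {x.shape[0]}")


def _pairwise_m(x: pd.DataFrame, ddof: int = 1) -> pd.Series:
    """Mean over partners of SD(Ct_k − Ct_j): geNorm M / comparative ΔCt."""
    genes = list(x.columns)
    arr = x.to_numpy(dtype=float)
    n = len(genes)
    sd = np.zeros((n, n))
    for j, k in itertools.combinations(range(n), 2):
        s = np.std(arr[:, k] - arr[:, j], ddof=ddof)
        sd[j, k] = sd[k, j] = s
    m = sd.sum(axis=1) / (n - 1)
    return pd.Series(m, index=genes)


def genorm(
    d: CtMatrix | DatasetSlice,
    hkgs: Sequence[str] | None = None,
    ddof: int = 1,
) -> StabilityTable:
    """geNorm M-values with iterative exclusion down to the best pair.

    ``values`` holds each gene's M on the full candidate panel (identical to
    the comparative ΔCt statistic); ``extras`` carries:

    - ``best_pair``: the two genes surviving iterative exclusion;
    - ``exclusion_order``: genes in the order they were removed;
    - ``stepwise_m``: each gene's M at the step it was excluded (the value
      conventionally reported by geNorm, shared by the final pair);
    - ``flagged``: genes with full-panel M ≥ 1.5.

    Ties on the maximal M during exclusion remove the later gene in input
    order (deterministic; recorded in ``tie_log``).
    """
    x = _ct_submatrix(d, hkgs)
    _check_dims(x)
    m_full = _pairwise_m(x, ddof=ddof)

    remaining = list(x.columns)
    exclusion_order: list[str] = []
    stepwise: dict[str, float] = {}
    tie_log: list[str] = []
    while len(remaining) > 2:
        m = _pairwise_m(x[remaining], ddof=ddof)
        worst_val = m.max()
        ties = [g for g in remaining if m[g] == worst_val]
        worst = ties[-1]  # later in input order on exact ties
        if len(ties) > 1:
            tie_log.append(f"exclusion tie at M={worst_val:.6g} among {ties}; removed {worst!r}")
        stepwise[worst] = float(m[worst])
        exclusion_order.append(worst)
        remaining.remove(worst)
    pair_m = float(_pairwise_m(x[remaining], ddof=ddof).iloc[0])
    for g in remaining:
        stepwise[g] = pair_m

    return StabilityTable(
        method="geNorm",
        condition=getattr(d, "condition", "ALL"),
        values=m_full,
        extras={
            "best_pair": tuple(remaining),
            "exclusion_order": exclusion_order,
            "stepwise_m": pd.Series({g: stepwise[g] for g in x.columns}),
            "flagged": [g for g in x.columns if m_full[g] >= GENORM_M_THRESHOLD],
            "tie_log": tie_log,
        },
    )


def delta_ct_method(
    d: CtMatrix | DatasetSlice,
    hkgs: Sequence[str] | None = None,
    ddof: int = 1,
) -> StabilityTable:
    """Comparative ΔCt stability: mean pairwise SD of Ct differences."""
    x = _ct_submatrix(d, hkgs)
    _check_dims(x)
    return StabilityTable(
        method="DeltaCt",
        condition=getattr(d, "condition", "ALL"),
        values=_pairwise_m(x, ddof=ddof),
    )


def bestkeeper(
    d: CtMatrix | DatasetSlice,
    hkgs: Sequence[str] | None = None,
    ddof: int = 0,
) -> StabilityTable:
    """BestKeeper descriptors: per-gene Ct SD (ranking key), CV, and Pearson
    r against the per-sample geometric mean of candidate Cts."""
    x = _ct_submatrix(d, hkgs)
    _check_dims(x, min_genes=1)
    arr = x.to_numpy(dtype=float)
    sd = pd.Series(np.std(arr, axis=0, ddof=ddof), index=x.columns)
    mean = pd.Series(arr.mean(axis=0), index=x.columns)
    cv = 100.0 * sd / mean

    # BestKeeper index: geometric mean of the candidates' Cts per sample.
    index = np.exp(np.log(arr).mean(axis=1))
    r = {}
    for g in x.columns:
        col = x[g].to_numpy()
        if np.std(col) == 0 or np.std(index) == 0:
            r[g] = np.nan  # correlation undefined for a constant series
        else:
            r[g] = float(np.corrcoef(col, index)[0, 1])

    return StabilityTable(
        method="BestKeeper",
        condition=getattr(d, "condition", "ALL"),
        values=sd,
        extras={"cv": cv, "pearson_r": pd.Series(r), "index": pd.Series(index, index=x.index)},
    )


def normfinder(
    d: CtMatrix | DatasetSlice,
    hkgs: Sequence[str] | None = None,
    groups: Sequence[str] | None = None,
) -> StabilityTable:
    """NormFinder model-based stability values.

    When the slice spans more than one tissue-source group (or an explicit
    per-sample ``groups`` vector is supplied), the grouped estimator is used:
    per-gene, per-group intra-group variances (bias-corrected by the
    k/(k−2) factor, k = number of genes) and inter-group differences shrunk
    toward zero by their sampling variance; stability is the mean over
    groups of |shrunken difference| + its standard error.  With one group
    the value is the bias-corrected intra-group SD.
    """
    x = _ct_submatrix(d, hkgs)
    _check_dims(x)
    k = x.shape[1]
    if k < 3:
        warnings.warn(
            "NormFinder with fewer than 3 genes: variance bias-correction "
            "is unavailable; using uncorrected residual variances",
            stacklevel=2,
        )
    if groups is None:
        grp = d.meta["group"] if hasattr(d, "meta") else pd.Series("all", index=x.index)
    else:
        grp = pd.Series(list(groups), index=x.index)

    labels = list(dict.fromkeys(grp))
    counts = grp.value_counts()
    if len(labels) > 1 and (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValidationError(f"NormFinder groups of size 1: {small}")

    arr = x.to_numpy(dtype=float)
    z = arr - arr.mean(axis=1, keepdims=True)  # remove per-sample loading

    if len(labels) == 1:
        sigma2 = _intra_group_var(z)
        vals = pd.Series(np.sqrt(sigma2), index=x.columns)
        return StabilityTable(
            method="NormFinder",
            condition=getattr(d, "condition", "ALL"),
            values=vals,
            extras={"grouped": False, "sigma2": pd.Series(sigma2, index=x.columns)},
        )

    G = len(labels)
    n_g = np.array([int(counts[g]) for g in labels], dtype=float)
    d_ig = np.zeros((G, k))
    sigma2_ig = np.zeros((G, k))
    for gi, lab in enumerate(labels):
        zg = z[(grp == lab).to_numpy()]
        d_ig[gi] = zg.mean(axis=0)
        sigma2_ig[gi] = _intra_group_var(zg)
    d_ig -= d_ig.mean(axis=0, keepdims=True)  # gene's grand mean over groups

    # Between-group variance of the true differences, moment estimate.
    samp_var = sigma2_ig / n_g[:, None]
    gamma2 = max(
        0.0,
        float((d_ig**2).sum() / ((G - 1) * (k - 1)) - samp_var.mean()),
    )
    denom = gamma2 + samp_var
    with np.errstate(invalid="ignore", divide="ignore"):
        d_shrunk = np.where(denom > 0, d_ig * gamma2 / denom, 0.0)
        se = np.sqrt(np.where(denom > 0, gamma2 * samp_var / denom, 0.0))
    rho = (np.abs(d_shrunk) + se).mean(axis=0)
    vals = pd.Series(rho, index=x.columns)
    return StabilityTable(
        method="NormFinder",
        condition=getattr(d, "condition", "ALL"),
        values=vals,
        extras={
            "grouped": True,
            "gamma2": gamma2,
            "sigma2": pd.DataFrame(sigma2_ig, index=labels, columns=x.columns),
            "group_diff": pd.DataFrame(d_ig, index=labels, columns=x.columns),
        },
    )


def _intra_group_var(z: np.ndarray) -> np.ndarray:
    """Bias-corrected per-gene variance of sample-centered residuals.

    Centering each sample over k genes deflates a gene's apparent variance
    and leaks the other genes' variance in; solving the moment equations
    gives sigma2_i = k/(k−2) · (s2_i − S/k²) with S = k/(k−1) · Σ s2.  For
    k = 2 the correction is undefined and the raw s2 is returned.
    """
    k = z.shape[1]
    s2 = np.var(z, axis=0, ddof=1)
    if k < 3:
        return s2
    S = s2.sum() * k / (k - 1)
    return np.clip(k / (k - 2) * (s2 - S / k**2), 0.0, None)


def run_all_methods(
    d: CtMatrix | DatasetSlice,
    hkgs: Sequence[str] | None = None,
) -> list[StabilityTable]:
    """All four stability statistics, in fixed reporting order
    (ΔCt, BestKeeper, NormFinder, geNorm).

    NormFinder runs grouped when the slice spans several tissue sources and
    ungrouped for a single-source slice; the other methods are unaffected by
    grouping.
    """
    return [
        delta_ct_method(d, hkgs),
        bestkeeper(d, hkgs),
        normfinder(d, hkgs),
        genorm(d, hkgs),
    ]
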