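"""Synthetic qRT-PCR Ct data with known ground-truth stability structure.

The generator draws Ct values from an additive Gaussian model on the Ct
(log2-expression) scale,

    Ct[i, g] = base_ct[g] + source_shift[g](group_i) + donor_effect[i, g]
               + sample_shift[i] + eps[i, g],

where the donor effect is drawn once per (donor, gene) and held constant for
that donor (creating donor-specific expression fingerprints), the sample
shift is a global per-sample loading/efficiency offset shared by all genes of
a sample, and eps is residual measurement noise.  Gaussian noise on the Ct
scale corresponds to log-normal noise on the expression scale, which is the
standard error structure of real-time PCR, and makes analytic means and SDs
available for tests.

A perfectly stable reference gene is expressible (all shifts and SDs zero).
All randomness flows through explicit seeds; there is no global random state.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .qpcr_data import CANDIDATE_HKG, TARGET, CtMatrix, SampleMeta, ValidationError

DEFAULT_GROUPS = ("BMSC", "ASC", "hAMSC")


@dataclasses.dataclass(frozen=True)
class GeneSpec:
    """Generating parameters of one gene.

    Parameters
    ----------
    name
        Gene symbol.
    base_ct
        Baseline Ct in cycles (expression level; lower = more abundant).
    source_shift
        Systematic Ct offset per tissue-source group, in cycles.  Groups not
        listed get offset 0.  A negative shift means *higher* expression in
        that group (one cycle = one doubling).
    donor_sd
        SD (cycles) of the donor effect, drawn once per donor.
    noise_sd
        SD (cycles) of the residual per-measurement noise.
    role
        ``"candidate_hkg"`` or ``"target"``.
    """

    name: str
    base_ct: float
    source_shift: Mapping[str, float] = dataclasses.field(default_factory=dict)
    donor_sd: float = 0.0
    noise_sd: float = 0.0
    role: str = CANDIDATE_HKG

    def __post_init__(self):
        if self.donor_sd < 0 or self.noise_sd < 0:
            raise ValidationError(f"negative SD in gene spec {self.name!r}")


@dataclasses.dataclass(frozen=True)
class StudyDesign:
    """Layout of a simulated study: groups × donors, plus global noise.

    The default design (3 tissue sources × 4 donors) matches the MSC study
    structure this package emulates.
    """

    groups: Sequence[str] = DEFAULT_GROUPS
    donors_per_group: int = 4
    sample_shift_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sample_shift_sd < 0:
            raise ValidationError("sample_shift_sd must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.groups) * self.donors_per_group


def generate_ct(design: StudyDesign, genes: Sequence[GeneSpec]) -> CtMatrix:
    """Draw one Ct matrix from the generative model.

    Identical ``design`` (including seed) and gene specs give bit-identical
    output.  The ground-truth specs are retained on the returned matrix as
    ``.truth`` for recovery tests.
    """
    if len(design.groups) < 2 and design.n_samples < 3:
        raise ValidationError("need at least 2 groups or 3 samples")
    names = [g.name for g in genes]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate gene names in spec list")

    rng = np.random.default_rng(design.seed)
    samples = [
        SampleMeta(f"{grp}{d + 1}", f"d{d + 1}", grp)
        for grp in design.groups
        for d in range(design.donors_per_group)
    ]
    n = len(samples)

    # Donor effects: one draw per (sample, gene) — each donor appears once
    # per group in this design, so per-sample draws realise per-donor draws.
    donor_eff = rng.standard_normal((n, len(genes)))
    sample_shift = rng.standard_normal(n) * design.sample_shift_sd
    eps = rng.standard_normal((n, len(genes)))

    values = np.empty((n, len(genes)))
    for j, spec in enumerate(genes):
        shifts = np.array([spec.source_shift.get(s.group, 0.0) for s in samples])
        values[:, j] = (
            spec.base_ct
            + shifts
            + donor_eff[:, j] * spec.donor_sd
            + sample_shift
            + eps[:, j] * spec.noise_sd
        )

    frame = pd.DataFrame(values, columns=names)
    m = CtMatrix(frame, samples, gene_role={g.name: g.role for g in genes})
    m.truth = {"design": design, "genes": list(genes)}  # type: ignore[attr-defined]
    return m


# ---------------------------------------------------------------------------
# Study-calibrated fixture
# ---------------------------------------------------------------------------

# Per-group mean Cts of the five housekeeping candidates, as published for
# bone-marrow, adipose and amniotic-membrane MSCs (4 donors per source).
# base_ct is the BMSC mean; source shifts are the printed group-mean offsets.
_HKG_GROUP_MEANS: dict[str, dict[str, float]] = {
    "ACTB": {"BMSC": 12.06, "ASC": 12.10, "hAMSC": 11.53},
    "EF1A": {"BMSC": 10.63, "ASC": 10.24, "hAMSC": 10.84},
    "GAPDH": {"BMSC": 11.57, "ASC": 11.41, "hAMSC": 11.12},
    "RPLP0": {"BMSC": 11.87, "ASC": 11.09, "hAMSC": 11.68},
    "TBP": {"BMSC": 20.64, "ASC": 20.67, "hAMSC": 20.35},
}

# Donor and residual SDs chosen so the implied group SEM over 4 donors,
# sqrt(0.25² + 0.15²)/2 ≈ 0.15 cycles, sits mid-range of the published
# per-group SEMs (0.07–0.33).
_HKG_DONOR_SD = 0.25
_HKG_NOISE_SD = 0.15


def msc_study_fixture(seed: int, sample_shift_sd: float = 0.0) -> CtMatrix:
    """A 12-sample × 7-gene Ct matrix calibrated to the MSC study conditions.

    Five housekeeping candidates (ACTB, EF1A, GAPDH, RPLP0, TBP) with group
    means matching the published per-source means to within sampling noise,
    plus two osteoarthritis-related target genes: an ICAM1-like gene with
    donor-dominated variation, and an IL8-like gene strongly upregulated in
    amniotic-membrane MSCs (−9-cycle source shift, ≈512-fold).
    """
    genes = [
        GeneSpec(
            name,
            base_ct=means["BMSC"],
            source_shift={g: mu - means["BMSC"] for g, mu in means.items()},
            donor_sd=_HKG_DONOR_SD,
            noise_sd=_HKG_NOISE_SD,
        )
        for name, means in _HKG_GROUP_MEANS.items()
    ]
    genes.append(
        GeneSpec(
            "ICAM1",
            base_ct=18.0,
            source_shift={"ASC": -1.0, "hAMSC": 0.5},
            donor_sd=1.5,
            noise_sd=0.3,
            role=TARGET,
        )
    )
    genes.append(
        GeneSpec(
            "IL8",
            base_ct=22.0,
            source_shift={"ASC": -2.0, "hAMSC": -9.0},
            donor_sd=1.5,
            noise_sd=0.3,
            role=TARGET,
        )
    )
    design = StudyDesign(sample_shift_sd=sample_shift_sd, seed=seed)
    return generate_ct(design, genes)


def ground_truth_panel(seed: int) -> CtMatrix:
    """A 5-HKG panel with designed stability extremes, for recovery tests.

    ``STABLE`` is perfectly stable (zero shifts and SDs); ``SHIFTED`` carries
    a +1.5-cycle source shift in one group; the three fillers have the
    study-calibrated donor/noise SDs and no shift.
    """
    genes = [
        GeneSpec("STABLE", 15.0),
        GeneSpec("FILL1", 12.0, donor_sd=_HKG_DONOR_SD, noise_sd=_HKG_NOISE_SD),
        GeneSpec("FILL2", 14.0, donor_sd=_HKG_DONOR_SD, noise_sd=_HKG_NOISE_SD),
        GeneSpec("FILL3", 18.0, donor_sd=_HKG_DONOR_SD, noise_sd=_HKG_NOISE_SD),
        GeneSpec(
            "SHIFTED",
            16.0,
            source_shift={"hAMSC": 1.5},
            donor_sd=_HKG_DONOR_SD,
            noise_sd=_HKG_NOISE_SD,
        ),
    ]
    return generate_ct(StudyDesign(seed=seed), genes)
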