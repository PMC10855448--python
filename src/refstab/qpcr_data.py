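"""Data model, validation, and file I/O for qRT-PCR Ct matrices.

The central container is :class:`CtMatrix`: a rectangular table of raw Ct
(cycle-threshold) values, samples in rows and genes in columns, with
per-sample metadata (donor label, tissue-source group).  Ct values live on a
log2 scale by construction of real-time PCR: one cycle is one doubling, so a
difference of one Ct corresponds to a two-fold difference in template amount
(at 100 % amplification efficiency).

Missing Ct entries are representable (NaN) and countable, but any stability
computation that would consume a missing value fails loudly rather than
silently imputing — see :mod:`refstab.stability`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("refstab")

#: Ct values at or above this are rejected as out of range (cycles).
DEFAULT_CT_CEILING = 40.0
#: Ct values above this trigger a warning (late amplification, unreliable).
CT_WARN_THRESHOLD = 35.0

CANDIDATE_HKG = "candidate_hkg"
TARGET = "target"

#: Default names of the leading metadata columns in a wide Ct table.
META_COLUMNS = ("sample", "donor", "group")


class RefstabError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(RefstabError):
    """Input data violated a structural or numeric constraint."""


@dataclasses.dataclass(frozen=True)
class SampleMeta:
    """Identity and grouping of one biological sample.

    Parameters
    ----------
    sample_id
        Unique sample label within a dataset.
    donor
        Donor label (e.g. ``"d1"``).  The (donor, group) pair must be unique
        within a dataset: one sample per donor per tissue source.
    group
        Tissue-source label, e.g. ``"BMSC"``, ``"ASC"`` or ``"hAMSC"``.
    """

    sample_id: str
    donor: str
    group: str


class CtMatrix:
    """Validated table of Ct values with sample metadata and gene roles.

    Parameters
    ----------
    values
        DataFrame of Ct values, index = sample ids, columns = gene symbols.
        NaN marks a missing measurement.
    samples
        Sequence of :class:`SampleMeta`, one per row of ``values`` in order.
    gene_role
        Optional mapping gene → ``"candidate_hkg"`` or ``"target"``.  Genes
        not listed default to ``candidate_hkg``.
    ct_ceiling
        Upper bound on admissible Ct values (cycles).
    """

    def __init__(
        self,
        values: pd.DataFrame,
        samples: Sequence[SampleMeta],
        gene_role: dict[str, str] | None = None,
        ct_ceiling: float = DEFAULT_CT_CEILING,
    ):
        values = values.astype(float)
        if values.shape[1] == 0:
            raise ValidationError("empty gene set: the table contains no gene columns")
        if len(samples) != values.shape[0]:
            raise ValidationError(
                f"{len(samples)} metadata rows for {values.shape[0]} value rows"
            )
        ids = [s.sample_id for s in samples]
        dup = _first_duplicate(ids)
        if dup is not None:
            raise ValidationError(f"duplicate sample_id {dup!r}")
        pairs = [(s.donor, s.group) for s in samples]
        dup = _first_duplicate(pairs)
        if dup is not None:
            raise ValidationError(f"duplicate (donor, group) pair {dup!r}")
        values.index = pd.Index(ids, name="sample")

        arr = values.to_numpy()
        finite = arr[np.isfinite(arr)]
        if finite.size and finite.min() < 0:
            raise ValidationError("negative Ct value encountered")
        if finite.size and finite.max() >= ct_ceiling:
            raise ValidationError(
                f"Ct value {finite.max():.2f} at or above ceiling {ct_ceiling}"
            )
        if finite.size and finite.max() > CT_WARN_THRESHOLD:
            warnings.warn(
                f"Ct values above {CT_WARN_THRESHOLD} cycles present "
                "(late amplification; treat with caution)",
                stacklevel=2,
            )

        role = dict.fromkeys(values.columns, CANDIDATE_HKG)
        if gene_role:
            for g, r in gene_role.items():
                if g not in role:
                    raise ValidationError(f"gene_role refers to unknown gene {g!r}")
                if r not in (CANDIDATE_HKG, TARGET):
                    raise ValidationError(f"unknown gene role {r!r} for gene {g!r}")
                role[g] = r

        self.values = values
        self.samples = list(samples)
        self.gene_role = role
        self.ct_ceiling = float(ct_ceiling)

    # -- introspection -----------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.group, None)
        return list(seen)

    @property
    def hkgs(self) -> list[str]:
        return [g for g in self.genes if self.gene_role[g] == CANDIDATE_HKG]

    @property
    def targets(self) -> list[str]:
        return [g for g in self.genes if self.gene_role[g] == TARGET]

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    @property
    def meta(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "donor": [s.donor for s in self.samples],
                "group": [s.group for s in self.samples],
            },
            index=self.values.index,
        )

    def group_of(self) -> pd.Series:
        return self.meta["group"]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CtMatrix({len(self.samples)} samples × {len(self.genes)} genes, "
            f"{len(self.groups)} groups, {self.n_missing} missing)"
        )


class DatasetSlice:
    """A by-group view of a :class:`CtMatrix`.

    Preserves gene order and the parent's sample order.  The study's seven
    analysis conditions (three single-source, three pairwise, one with all
    sources pooled) are all expressible as slices.
    """

    def __init__(self, parent: CtMatrix, group_filter: Iterable[str]):
        requested = list(dict.fromkeys(group_filter))
        known = set(parent.groups)
        for g in requested:
            if g not in known:
                raise ValidationError(
                    f"unknown group label {g!r}; known groups: {sorted(known)}"
                )
        self.parent = parent
        self.group_filter = requested
        keep = [s.group in set(requested) for s in parent.samples]
        self.samples = [s for s, k in zip(parent.samples, keep) if k]
        self.values = parent.values.loc[keep]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return self.parent.genes

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.group, None)
        return list(seen)

    @property
    def meta(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "donor": [s.donor for s in self.samples],
                "group": [s.group for s in self.samples],
            },
            index=self.values.index,
        )

    @property
    def condition(self) -> str:
        """Human-readable condition label, e.g. ``"BMSC/ASC"``."""
        return "/".join(self.group_filter)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DatasetSlice({self.condition!r}, {len(self.samples)} samples)"


def slice_groups(m: CtMatrix | DatasetSlice, groups: Iterable[str]) -> DatasetSlice:
    """Restrict a Ct matrix to the samples whose group is in ``groups``.

    Slicing a slice re-slices the parent matrix, so slicing twice with the
    same filter is idempotent.
    """
    parent = m.parent if isinstance(m, DatasetSlice) else m
    return DatasetSlice(parent, groups)


def read_ct_table(
    path: str | Path,
    format: str | None = None,
    metadata_columns: Sequence[str] = META_COLUMNS,
    gene_role: dict[str, str] | None = None,
    ct_ceiling: float = DEFAULT_CT_CEILING,
) -> CtMatrix:
    """Read a wide Ct table (samples as rows, genes as columns) from CSV/TSV.

    The first columns hold sample metadata (by default ``sample``, ``donor``,
    ``group``); every remaining column is a gene whose cells are Ct values or
    blank (missing).

    Raises
    ------
    ValidationError
        On duplicate sample ids, non-numeric Ct cells (the offending row and
        column are named), missing metadata columns, or an empty gene set.
    """
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix.lower() in (".tsv", ".txt") else "csv"
    if format not in ("csv", "tsv"):
        raise ValidationError(f"unsupported format {format!r}")
    sep = "\t" if format == "tsv" else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)
    missing_meta = [c for c in metadata_columns if c not in raw.columns]
    if missing_meta:
        raise ValidationError(f"metadata columns missing from {path}: {missing_meta}")

    gene_cols = [c for c in raw.columns if c not in metadata_columns]
    if not gene_cols:
        raise ValidationError(f"empty gene set in {path}")

    values = pd.DataFrame(index=raw.index, columns=gene_cols, dtype=float)
    for col in gene_cols:
        for i, cell in raw[col].items():
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
                values.at[i, col] = np.nan
                continue
            try:
                values.at[i, col] = float(cell)
            except ValueError:
                sid = raw.iloc[i][metadata_columns[0]]
                raise ValidationError(
                    f"non-numeric Ct value {cell!r} in row {sid!r}, column {col!r}"
                ) from None

    sample_col, donor_col, group_col = metadata_columns[:3]
    samples = [
        SampleMeta(str(r[sample_col]), str(r[donor_col]), str(r[group_col]))
        for _, r in raw.iterrows()
    ]
    m = CtMatrix(values, samples, gene_role=gene_role, ct_ceiling=ct_ceiling)
    logger.info(
        "read %s: %d samples × %d genes (%d missing cells)",
        path, len(m.samples), len(m.genes), m.n_missing,
    )
    return m


def write_ct_table(m: CtMatrix, path: str | Path, format: str = "csv") -> None:
    """Write a :class:`CtMatrix` as a wide CSV/TSV table (round-trippable)."""
    sep = "\t" if format == "tsv" else ","
    out = pd.DataFrame(
        {
            "sample": [s.sample_id for s in m.samples],
            "donor": [s.donor for s in m.samples],
            "group": [s.group for s in m.samples],
        }
    )
    for g in m.genes:
        out[g] = m.values[g].to_numpy()
    out.to_csv(path, sep=sep, index=False)


def write_results(obj, path: str | Path, format: str = "csv") -> None:
    """Serialize a result object (stability table, consensus ranking, ratio
    matrix, …) to ``path`` in CSV, TSV or JSON form.

    Any object exposing ``to_frame()`` (returning a DataFrame) is supported.
    Values round-trip at full stored precision.
    """
    if format not in ("csv", "tsv", "json"):
        raise ValidationError(f"unsupported output format {format!r}")
    frame = obj.to_frame() if hasattr(obj, "to_frame") else obj
    if not isinstance(frame, pd.DataFrame):
        raise ValidationError(f"cannot serialize object of type {type(obj).__name__}")
    path = Path(path)
    try:
        if format == "json":
            payload = json.loads(frame.to_json(orient="table", double_precision=15))
            path.write_text(json.dumps(payload, indent=1))
        else:
            frame.to_csv(path, sep="\t" if format == "tsv" else ",")
    except OSError as exc:
        raise RefstabError(f"cannot write results to {path}: {exc}") from exc


def _first_duplicate(items):
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None
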