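"""Data model, validation and TSV/GMT readers for the trio screen.

The screen operates on three kinds of tables:

* a gene x sample expression matrix (genes as rows, samples as columns,
  non-negative values — raw counts or already-normalized units);
* a sample annotation table mapping every sample to a patient (``case_id``)
  and a tissue site: adjacent non-tumor (``N``), primary tumor (``T``) or
  metastatic lymph node (``LN``);
* optional clinical tables: immunohistochemistry scores, survival records
  and positive-lymph-node counts.

All on-disk formats are plain TSV (tab-separated, UTF-8, ``.`` decimal,
first expression column headed ``gene_id``); gene sets use the GMT format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

SITES = ("N", "T", "LN")

CPM_SCALE = 1e6


class ValidationError(ValueError):
    """An input table violates a structural invariant."""


class ParseError(ValueError):
    """An input file cannot be parsed into the expected table."""


def _find_duplicates(items: Iterable) -> list:
    seen: set = set()
    dups: list = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample table of non-negative, finite expression values.

    ``data`` is a float DataFrame whose index holds unique gene IDs and whose
    columns hold unique sample IDs; row and column order is preserved by all
    readers and writers.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        dup_genes = _find_duplicates(df.index)
        if dup_genes:
            raise ValidationError(f"duplicate gene IDs: {dup_genes}")
        dup_samples = _find_duplicates(df.columns)
        if dup_samples:
            raise ValidationError(f"duplicate sample IDs: {dup_samples}")
        values = df.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.number):
                raise ParseError("expression values must be numeric")
            bad = ~np.isfinite(values)
            if bad.any():
                g, s = np.argwhere(bad)[0]
                raise ValidationError(
                    f"non-finite value at gene {df.index[g]!r}, sample {df.columns[s]!r}"
                )
            neg = values < 0
            if neg.any():
                g, s = np.argwhere(neg)[0]
                raise ValidationError(
                    f"negative value {values[g, s]} at gene {df.index[g]!r}, "
                    f"sample {df.columns[s]!r}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"unknown sample IDs: {missing}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample TSV into a validated :class:`ExpressionMatrix`.

    The first column holds gene IDs (header ``gene_id``); remaining columns
    are samples.  Duplicated gene or sample IDs raise :class:`ValidationError`
    naming the offenders; a negative or non-numeric cell raises with the
    offending row/column coordinates.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 1:
        raise ParseError(f"{path}: empty header")
    sample_ids = header[1:]
    dup_samples = _find_duplicates(sample_ids)
    if dup_samples:
        raise ValidationError(f"{path}: duplicate sample IDs: {dup_samples}")

    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    dup_genes = _find_duplicates(df.index)
    if dup_genes:
        raise ValidationError(f"{path}: duplicate gene IDs: {dup_genes}")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: non-numeric value {df.iat[g, s]!r} at gene "
            f"{df.index[g]!r}, sample {df.columns[s]!r}"
        )
    neg = (numeric.to_numpy() < 0)
    if neg.any():
        g, s = np.argwhere(neg)[0]
        raise ParseError(
            f"{path}: negative value {numeric.iat[g, s]} at gene "
            f"{df.index[g]!r}, sample {df.columns[s]!r}"
        )
    return ExpressionMatrix(numeric.astype(float))


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as TSV with a ``gene_id`` first column.

    Uses :func:`repr`-faithful float formatting so a write/read round trip
    reproduces values to full precision.
    """
    df = matrix.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def cpm_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million: scale each sample column to sum to 1e6.

    Raises :class:`ValidationError` for an all-zero sample column, which has
    no defined library size.
    """
    totals = matrix.data.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"all-zero sample column(s): {list(zero.index)}")
    return ExpressionMatrix(matrix.data * (CPM_SCALE / totals))


# ---------------------------------------------------------------------------
# Sample annotation and trios
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ("sample_id", "case_id", "site")


def validate_annotation(annot: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in annot.columns]
    if missing:
        raise ValidationError(f"annotation missing column(s): {missing}")
    annot = annot.loc[:, list(ANNOTATION_COLUMNS)].astype(str)
    dup = _find_duplicates(annot["sample_id"])
    if dup:
        raise ValidationError(f"duplicate sample_id in annotation: {dup}")
    bad_sites = sorted(set(annot["site"]) - set(SITES))
    if bad_sites:
        raise ValidationError(
            f"unknown site value(s) {bad_sites}; expected one of {SITES}"
        )
    return annot


def read_sample_annotation(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample annotation TSV (sample_id, case_id, site)."""
    annot = pd.read_csv(path, sep="\t", dtype=str)
    return validate_annotation(annot)


def write_sample_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    validate_annotation(annot).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True, order=True)
class CaseTrio:
    """One patient's matched (N, T, LN) sample triple."""

    case_id: str
    n_sample: str
    t_sample: str
    ln_sample: str

    def __post_init__(self) -> None:
        ids = (self.n_sample, self.t_sample, self.ln_sample)
        if len(set(ids)) != 3:
            raise ValidationError(
                f"case {self.case_id!r}: trio samples must be distinct, got {ids}"
            )

    @property
    def samples(self) -> tuple[str, str, str]:
        return (self.n_sample, self.t_sample, self.ln_sample)


def assemble_trios(
    matrix: ExpressionMatrix, annot: pd.DataFrame
) -> list[CaseTrio]:
    """Group annotated samples into matched (N, T, LN) trios, one per case.

    Cases missing any of the three sites are excluded with a warning; a case
    with two samples of the same site is ambiguous and raises.  The result is
    sorted by ``case_id`` and is independent of annotation row order.
    """
    annot = validate_annotation(annot)
    known = set(matrix.sample_ids)
    unknown = sorted(set(annot["sample_id"]) - known)
    if unknown:
        raise ValidationError(
            f"annotation references samples absent from the matrix: {unknown}"
        )
    trios: list[CaseTrio] = []
    for case_id in sorted(annot["case_id"].unique()):
        rows = annot[annot["case_id"] == case_id]
        by_site: dict[str, str] = {}
        for site, sub in rows.groupby("site"):
            if len(sub) > 1:
                raise ValidationError(
                    f"case {case_id!r} has {len(sub)} samples with site {site!r}: "
                    f"{sorted(sub['sample_id'])}"
                )
            by_site[str(site)] = str(sub["sample_id"].iloc[0])
        missing = [s for s in SITES if s not in by_site]
        if missing:
            warnings.warn(
                f"case {case_id!r} lacks site(s) {missing}; excluded from trios",
                stacklevel=2,
            )
            continue
        trios.append(
            CaseTrio(case_id, by_site["N"], by_site["T"], by_site["LN"])
        )
    return trios


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets with preserved order and deduplicated members."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, members: Iterable[str], description: str = "") -> None:
        if name in self.sets:
            raise ValidationError(f"duplicate gene-set name: {name!r}")
        self.sets[name] = list(dict.fromkeys(members))
        self.descriptions[name] = description

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then members."""
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs at least name and description"
                )
            name, description, *members = parts
            if name in coll.sets:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate gene-set name {name!r}"
                )
            coll.add(name, [m for m in members if m], description)
    return coll


def write_gene_sets(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in coll.names:
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *coll.sets[name]]) + "\n")


# ---------------------------------------------------------------------------
# Clinical records
# ---------------------------------------------------------------------------

TISSUES = ("primary", "ln_met")

#: valid immunostaining scores: half-point grid from 0 to 4
IHC_GRID = tuple(x / 2 for x in range(9))


def _check_grid(score: float) -> float:
    score = float(score)
    if not (0.0 <= score <= 4.0) or abs(score * 2 - round(score * 2)) > 1e-9:
        raise ValidationError(
            f"IHC score {score} is not on the half-point grid 0, 0.5, ..., 4"
        )
    return score


@dataclass(frozen=True)
class IHCRecord:
    """Ordinal immunostaining score for one tissue core."""

    specimen_id: str
    tissue: str  # "primary" or "ln_met"
    score: float

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValidationError(
                f"tissue must be one of {TISSUES}, got {self.tissue!r}"
            )
        object.__setattr__(self, "score", _check_grid(self.score))


@dataclass(frozen=True)
class SurvivalRecord:
    """Right-censored survival observation with a comparison-group label."""

    patient_id: str
    time: float
    event: bool
    group: str

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError(f"negative survival time: {self.time}")


@dataclass(frozen=True)
class LNCountRecord:
    """Positive vs examined lymph-node counts for one patient."""

    patient_id: str
    positive_ln: int
    examined_ln: int

    def __post_init__(self) -> None:
        if self.examined_ln < 1:
            raise ValidationError("examined_ln must be >= 1")
        if not (0 <= self.positive_ln <= self.examined_ln):
            raise ValidationError(
                f"positive_ln must be in [0, examined_ln], got "
                f"{self.positive_ln}/{self.examined_ln}"
            )


def read_ihc_table(path: str | Path) -> list[IHCRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        IHCRecord(str(r.specimen_id), str(r.tissue), float(r.score))
        for r in df.itertuples()
    ]


def write_ihc_table(records: Sequence[IHCRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "specimen_id": [r.specimen_id for r in records],
            "tissue": [r.tissue for r in records],
            "score": [r.score for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_survival_table(path: str | Path) -> list[SurvivalRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        SurvivalRecord(
            str(r.patient_id), float(r.time), bool(int(r.event)), str(r.group)
        )
        for r in df.itertuples()
    ]


def write_survival_table(records: Sequence[SurvivalRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "time": [r.time for r in records],
            "event": [int(r.event) for r in records],
            "group": [r.group for r in records],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_ln_table(path: str | Path) -> list[LNCountRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        LNCountRecord(str(r.patient_id), int(r.positive_ln), int(r.examined_ln))
        for r in df.itertuples()
    ]


def write_ln_table(records: Sequence[LNCountRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "positive_ln": [r.positive_ln for r in records],
            "examined_ln": [r.examined_ln for r in records],
        }
    ).to_csv(path, sep="\t", index=False)
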