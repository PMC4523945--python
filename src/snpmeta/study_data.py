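"""Domain types and delimited-text I/O for case-control genotype-count datasets.

A dataset is a panel of independent case-control studies genotyped at one
biallelic SNP. Each study contributes three genotype counts per arm, ordered
risk-allele homozygote, heterozygote, reference-allele homozygote; the risk
allele is declared once per dataset so every downstream contrast is
orientation-unambiguous.

Three bundled datasets cover the TOX3 breast-cancer SNPs rs3803662,
rs12443621 and rs8051542, transcribed from the published case-control
literature; the reported control Hardy-Weinberg P-values travel along as
reference metadata (``extra_labels['hwe_p_reported']``), never as inputs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "GenotypeCounts",
    "StudyRecord",
    "Dataset",
    "DatasetSummary",
    "SchemaError",
    "ValidationError",
    "DEFAULT_SCHEMA",
    "FIXTURE_SNPS",
    "read_dataset",
    "write_dataset",
    "summarize",
    "load_fixture",
]

#: SNP id -> (risk allele, reference allele) for the bundled datasets.
FIXTURE_SNPS: dict[str, tuple[str, str]] = {
    "rs3803662": ("T", "C"),
    "rs12443621": ("G", "A"),
    "rs8051542": ("T", "C"),
}

#: Logical field -> column name used by the bundled files and by default I/O.
DEFAULT_SCHEMA: dict[str, str] = {
    "study_id": "study_id",
    "ethnicity": "ethnicity",
    "cases_hom_risk": "cases_hom_risk",
    "cases_het": "cases_het",
    "cases_hom_ref": "cases_hom_ref",
    "controls_hom_risk": "controls_hom_risk",
    "controls_het": "controls_het",
    "controls_hom_ref": "controls_hom_ref",
}

_COUNT_FIELDS = (
    "cases_hom_risk",
    "cases_het",
    "cases_hom_ref",
    "controls_hom_risk",
    "controls_het",
    "controls_hom_ref",
)


class SchemaError(ValueError):
    """The column-mapping config does not match the input file."""


class ValidationError(ValueError):
    """A row violates a dataset invariant (named in the message)."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one study arm.

    Attributes
    ----------
    n_hom_risk, n_het, n_hom_ref
        Counts of risk-allele homozygotes, heterozygotes and reference-allele
        homozygotes. All non-negative integers.
    """

    n_hom_risk: int
    n_het: int
    n_hom_ref: int

    def __post_init__(self) -> None:
        for name in ("n_hom_risk", "n_het", "n_hom_ref"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.n_hom_risk + self.n_het + self.n_hom_ref

    @property
    def allele_counts(self) -> tuple[int, int]:
        """(risk, reference) allele counts; 2 alleles per subject."""
        return (2 * self.n_hom_risk + self.n_het, 2 * self.n_hom_ref + self.n_het)

    @property
    def risk_allele_freq(self) -> float:
        risk, ref = self.allele_counts
        return risk / (risk + ref)


@dataclass(frozen=True)
class StudyRecord:
    """One study's metadata plus case and control genotype counts."""

    study_id: str
    ethnicity: str
    snp_id: str
    cases: GenotypeCounts
    controls: GenotypeCounts
    extra_labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cases.total <= 0:
            raise ValidationError(f"study {self.study_id!r}: no cases")
        if self.controls.total <= 0:
            raise ValidationError(f"study {self.study_id!r}: no controls")


@dataclass(frozen=True)
class Dataset:
    """An ordered panel of studies at one SNP, with declared allele orientation."""

    snp_id: str
    risk_allele: str
    ref_allele: str
    studies: tuple[StudyRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "studies", tuple(self.studies))
        seen: set[str] = set()
        for s in self.studies:
            if s.snp_id != self.snp_id:
                raise ValidationError(
                    f"study {s.study_id!r} is for {s.snp_id}, dataset is {self.snp_id}"
                )
            if s.study_id in seen:
                raise ValidationError(f"duplicate study_id {s.study_id!r}")
            seen.add(s.study_id)

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self):
        return iter(self.studies)

    def subset(self, study_ids: Iterable[str]) -> "Dataset":
        keep = set(study_ids)
        return Dataset(
            self.snp_id,
            self.risk_allele,
            self.ref_allele,
            tuple(s for s in self.studies if s.study_id in keep),
        )


@dataclass(frozen=True)
class DatasetSummary:
    n_datasets: int
    total_cases: int
    total_controls: int


def summarize(ds: Dataset) -> DatasetSummary:
    """Exact integer totals over all studies of a dataset."""
    return DatasetSummary(
        n_datasets=len(ds.studies),
        total_cases=sum(s.cases.total for s in ds.studies),
        total_controls=sum(s.controls.total for s in ds.studies),
    )


def _resolve_schema(schema: Mapping[str, str] | str | Path | None) -> dict[str, str]:
    if schema is None:
        return dict(DEFAULT_SCHEMA)
    if isinstance(schema, (str, Path)):
        with open(schema) as fh:
            schema = yaml.safe_load(fh)
    out = dict(DEFAULT_SCHEMA)
    out.update(schema)
    missing = set(DEFAULT_SCHEMA) - set(out)
    if missing:
        raise SchemaError(f"schema is missing mappings for {sorted(missing)}")
    return out


def read_dataset(
    path: str | Path,
    snp_id: str,
    risk_allele: str,
    ref_allele: str,
    schema: Mapping[str, str] | str | Path | None = None,
    sep: str | None = None,
) -> Dataset:
    """Read a delimited-text study table into a validated :class:`Dataset`.

    Parameters
    ----------
    path
        Comma- or tab-delimited UTF-8 file with a header row, one row per study.
    schema
        Mapping from logical field names (keys of :data:`DEFAULT_SCHEMA`) to
        the file's column names, or a path to a YAML file holding that mapping.
        Omitted fields fall back to the default column names.
    sep
        Field delimiter; sniffed from the header line when ``None``.

    Raises
    ------
    SchemaError
        A mapped column is absent from the file.
    ValidationError
        A row carries a negative or non-integer count (the row is named).
    """
    cols = _resolve_schema(schema)
    path = Path(path)
    if sep is None:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: columns {missing} not found in header {list(df.columns)}")

    mapped = set(cols.values())
    studies = []
    for idx, row in df.iterrows():
        counts = {}
        for f in _COUNT_FIELDS:
            raw = row[cols[f]].strip()
            try:
                v = int(raw)
            except ValueError:
                raise ValidationError(
                    f"{path.name} row {idx + 2} ({row[cols['study_id']]!r}): "
                    f"column {cols[f]!r} value {raw!r} is not an integer"
                ) from None
            if v < 0:
                raise ValidationError(
                    f"{path.name} row {idx + 2} ({row[cols['study_id']]!r}): "
                    f"column {cols[f]!r} is negative ({v})"
                )
            counts[f] = v
        extra = {c: row[c] for c in df.columns if c not in mapped and row[c] != ""}
        studies.append(
            StudyRecord(
                study_id=row[cols["study_id"]].strip(),
                ethnicity=row[cols["ethnicity"]].strip(),
                snp_id=snp_id,
                cases=GenotypeCounts(
                    counts["cases_hom_risk"], counts["cases_het"], counts["cases_hom_ref"]
                ),
                controls=GenotypeCounts(
                    counts["controls_hom_risk"], counts["controls_het"], counts["controls_hom_ref"]
                ),
                extra_labels=extra,
            )
        )
    return Dataset(snp_id, risk_allele, ref_allele, tuple(studies))


def write_dataset(ds: Dataset, path: str | Path, sep: str = "\t") -> None:
    """Write a dataset in the same layout :func:`read_dataset` accepts by default."""
    extra_keys = sorted({k for s in ds.studies for k in s.extra_labels})
    rows = []
    for s in ds.studies:
        row = {
            "study_id": s.study_id,
            "ethnicity": s.ethnicity,
            "cases_hom_risk": s.cases.n_hom_risk,
            "cases_het": s.cases.n_het,
            "cases_hom_ref": s.cases.n_hom_ref,
            "controls_hom_risk": s.controls.n_hom_risk,
            "controls_het": s.controls.n_het,
            "controls_hom_ref": s.controls.n_hom_ref,
        }
        for k in extra_keys:
            row[k] = s.extra_labels.get(k, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def load_fixture(snp_id: str) -> Dataset:
    """Load one of the bundled TOX3 breast-cancer datasets.

    ``snp_id`` must be one of rs3803662 (42 studies), rs12443621 (15) or
    rs8051542 (15). Studies reported separately per ethnic group in the source
    appear as separate records.
    """
    if snp_id not in FIXTURE_SNPS:
        raise KeyError(f"no bundled dataset for {snp_id!r}; have {sorted(FIXTURE_SNPS)}")
    risk, ref = FIXTURE_SNPS[snp_id]
    res = importlib.resources.files("snpmeta.data").joinpath(f"{snp_id}.tsv")
    with importlib.resources.as_file(res) as p:
        return read_dataset(p, snp_id=snp_id, risk_allele=risk, ref_allele=ref)
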