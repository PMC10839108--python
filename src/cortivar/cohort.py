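"""Data model and I/O for pig-level hair-cortisol cohorts.

A cohort is a long-format table of pig observations, each identified by a
(farm, batch, pig) triple and carrying one hair-cortisol concentration (HCC)
in pg/mg. Farm metadata holds per-farm management-practice and herd-health
variables used downstream as supplementary typology variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PigRecord",
    "Cohort",
    "BatchSummary",
    "FarmMetadata",
    "CohortValidationError",
    "SchemaError",
    "DEFAULT_SCHEMA",
    "METADATA_VARIABLES",
    "read_cohort",
    "write_cohort",
    "read_farm_metadata",
    "batch_summaries",
]

#: Default column-name mapping for cohort CSV files.
DEFAULT_SCHEMA = {
    "farm_id": "farm_id",
    "batch_id": "batch_id",
    "pig_id": "pig_id",
    "hcc": "hcc_pg_mg",
}

#: Assay detection floor in pg/mg; values below it are accepted with a warning.
DETECTION_LIMIT = 0.13

#: The farm-level practice/health variables and their declared category levels.
#: ``None`` means free ordinal/categorical classes are accepted as printed.
METADATA_VARIABLES: dict[str, list[str] | None] = {
    "castration": ["yes", "no"],
    "tail_docking": ["yes", "no"],
    "teeth_grinding": ["yes", "no"],
    "iron_administration": ["yes", "no"],
    "early_socialization": ["yes", "no"],
    "age_at_weaning": None,
    "age_at_fattening_regrouping": None,
    "regrouping_modality_suckling": None,
    "regrouping_modality_weaning": None,
    "regrouping_modality_fattening": None,
    "housing_suckling": ["indoors", "indoors_outdoor_access", "outdoors"],
    "housing_post_weaning": ["indoors", "indoors_outdoor_access", "outdoors"],
    "housing_fattening": ["indoors", "indoors_outdoor_access", "outdoors"],
    "floor_space_post_weaning": None,
    "floor_space_fattening": None,
    "health_disorder_batch1": ["yes", "no"],
    "health_disorder_batch2": ["yes", "no"],
}


class SchemaError(ValueError):
    """A required column is missing or misdeclared in an input file."""


class CohortValidationError(ValueError):
    """An input row violates a cohort invariant."""


@dataclass(frozen=True)
class PigRecord:
    """One pig's HCC observation.

    Parameters
    ----------
    farm_id, batch_id, pig_id :
        Opaque string identifiers; (farm_id, batch_id, pig_id) is unique
        within a cohort.
    hcc :
        Hair-cortisol concentration in pg/mg; strictly positive and finite.
    """

    farm_id: str
    batch_id: str
    pig_id: str
    hcc: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.hcc) or self.hcc <= 0:
            raise CohortValidationError(
                f"hcc must be positive and finite, got {self.hcc!r} for pig "
                f"({self.farm_id}, {self.batch_id}, {self.pig_id})"
            )


@dataclass(frozen=True)
class BatchSummary:
    """Per-(farm, batch) descriptive statistics (sample SD, denominator n-1)."""

    farm_id: str
    batch_id: str
    n: int
    mean: float
    sd: float

    @property
    def cv(self) -> float:
        """Coefficient of variation, SD / mean."""
        return self.sd / self.mean


@dataclass
class FarmMetadata:
    """Per-farm management-practice and health variables.

    ``values`` maps variable name -> category level (string) or None when
    missing; ``notes`` collects validation remarks (missing variables,
    unknown levels kept verbatim).
    """

    farm_id: str
    values: dict[str, str | None] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


class Cohort:
    """A validated collection of :class:`PigRecord`.

    Row order is preserved as read; ``farm_ids`` and ``batch_ids`` are
    sorted, deduplicated identifier lists. Every (farm, batch) cell must
    hold at least two records so an SD is computable.
    """

    def __init__(self, records: list[PigRecord], *, min_cell_size: int = 2):
        if not records:
            raise CohortValidationError("cohort holds no records")
        seen: set[tuple[str, str, str]] = set()
        for i, r in enumerate(records):
            key = (r.farm_id, r.batch_id, r.pig_id)
            if key in seen:
                raise CohortValidationError(
                    f"duplicate (farm,batch,pig) identifier {key} at record {i}"
                )
            seen.add(key)
        self.records: list[PigRecord] = list(records)
        self.farm_ids: list[str] = sorted({r.farm_id for r in records})
        self.batch_ids: list[str] = sorted({r.batch_id for r in records})
        cells = self.cell_sizes()
        small = {c: n for c, n in cells.items() if n < min_cell_size}
        if small:
            raise CohortValidationError(
                f"cells with fewer than {min_cell_size} records: {sorted(small)}"
            )
        below = [r for r in records if r.hcc < DETECTION_LIMIT]
        if below:
            warnings.warn(
                f"{len(below)} HCC value(s) below the assay detection limit "
                f"({DETECTION_LIMIT} pg/mg) were kept uncensored",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return self.records == other.records

    def cell_sizes(self) -> dict[tuple[str, str], int]:
        """Record count per (farm_id, batch_id) cell."""
        out: dict[tuple[str, str], int] = {}
        for r in self.records:
            k = (r.farm_id, r.batch_id)
            out[k] = out.get(k, 0) + 1
        return out

    def cell_values(self) -> dict[tuple[str, str], np.ndarray]:
        """HCC vectors per (farm_id, batch_id) cell, in row order."""
        out: dict[tuple[str, str], list[float]] = {}
        for r in self.records:
            out.setdefault((r.farm_id, r.batch_id), []).append(r.hcc)
        return {k: np.asarray(v, dtype=float) for k, v in out.items()}

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame with canonical column names."""
        return pd.DataFrame(
            {
                "farm_id": [r.farm_id for r in self.records],
                "batch_id": [r.batch_id for r in self.records],
                "pig_id": [r.pig_id for r in self.records],
                "hcc_pg_mg": [r.hcc for r in self.records],
            }
        )

    @property
    def hcc(self) -> np.ndarray:
        return np.asarray([r.hcc for r in self.records], dtype=float)


def read_cohort(
    path,
    schema: dict[str, str] | None = None,
    *,
    delimiter: str = ",",
) -> Cohort:
    """Read a pig-level CSV into a validated :class:`Cohort`.

    Parameters
    ----------
    path :
        CSV file with a header row.
    schema :
        Maps the canonical keys ``farm_id``, ``batch_id``, ``pig_id``,
        ``hcc`` to the file's column names. Defaults to
        :data:`DEFAULT_SCHEMA`.
    delimiter :
        Field delimiter, comma by default.

    Raises
    ------
    SchemaError
        If a mapped column is absent from the file.
    CohortValidationError
        On non-positive/non-numeric HCC (with the offending row index) or
        duplicate identifiers.
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    missing = [schema[k] for k in ("farm_id", "batch_id", "pig_id", "hcc") if schema[k] not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}; found {list(df.columns)}")
    records: list[PigRecord] = []
    farms = df[schema["farm_id"]].astype(str).str.strip()
    batches = df[schema["batch_id"]].astype(str).str.strip()
    pigs = df[schema["pig_id"]].astype(str).str.strip()
    for idx, raw in enumerate(df[schema["hcc"]]):
        try:
            value = float(raw)
        except (TypeError, ValueError):
            raise CohortValidationError(f"non-numeric HCC {raw!r} at row {idx}") from None
        if not np.isfinite(value) or value <= 0:
            raise CohortValidationError(f"non-positive HCC {value} at row {idx}")
        records.append(
            PigRecord(
                farm_id=farms.iloc[idx],
                batch_id=batches.iloc[idx],
                pig_id=pigs.iloc[idx],
                hcc=value,
            )
        )
    return Cohort(records)


def write_cohort(cohort: Cohort, path, *, delimiter: str = ",") -> None:
    """Write a cohort to canonical CSV (round-trips through :func:`read_cohort`)."""
    cohort.to_frame().to_csv(path, sep=delimiter, index=False)


def read_farm_metadata(path, *, delimiter: str = ",") -> list[FarmMetadata]:
    """Read the per-farm practice/health table.

    One row per farm, keyed by ``farm_id``, with the columns of
    :data:`METADATA_VARIABLES`. Missing columns and unknown category levels
    are tolerated: values are kept verbatim and a note is attached to the
    farm's validation report.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if "farm_id" not in df.columns:
        raise SchemaError(f"missing column(s) ['farm_id'] in {path}")
    absent = [v for v in METADATA_VARIABLES if v not in df.columns]
    out: list[FarmMetadata] = []
    for _, row in df.iterrows():
        meta = FarmMetadata(farm_id=str(row["farm_id"]).strip())
        for var in absent:
            meta.values[var] = None
            meta.notes.append(f"missing variable: {var}")
        for var, levels in METADATA_VARIABLES.items():
            if var in absent:
                continue
            raw = row[var]
            if pd.isna(raw) or str(raw).strip() == "":
                meta.values[var] = None
                meta.notes.append(f"missing value: {var}")
                continue
            value = str(raw).strip()
            meta.values[var] = value
            if levels is not None and value not in levels:
                meta.notes.append(f"unknown level for {var}: {value!r}")
        out.append(meta)
    return out


def batch_summaries(cohort: Cohort) -> list[BatchSummary]:
    """Per-(farm, batch) n, mean, sample SD and CV, ordered by (farm, batch).

    Raises
    ------
    CohortValidationError
        For any cell with fewer than two records (SD undefined).
    """
    out: list[BatchSummary] = []
    for (farm, batch), values in sorted(cohort.cell_values().items()):
        if len(values) < 2:
            raise CohortValidationError(f"cell ({farm}, {batch}) has n={len(values)} < 2")
        out.append(
            BatchSummary(
                farm_id=farm,
                batch_id=batch,
                n=len(values),
                mean=float(np.mean(values)),
                sd=float(np.std(values, ddof=1)),
            )
        )
    return out
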