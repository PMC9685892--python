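"""Mapping of raw coded diagnoses to subcategorized binary indicators.

Each diagnosis code carried by a transfer episode is mapped, through a
user-supplied code -> concept table, into one of six diagnosis
subcategories — primary/admitting diagnosis (``pdx``), problem list
(``pl``), unassigned/general diagnosis (``dx``), comorbidity (``cm``),
past history (``hx``) and discharge diagnosis (``ddx``) — and flagged as
a present/absent (0/1) indicator named ``<subcategory>_<Concept>``.
The same clinical concept may legitimately appear under several
subcategories (e.g. atrial fibrillation both as an acute problem and as
an existing comorbidity); those are distinct items.

The mapping table itself is an input: this package does not bundle a
real ICD -> concept dictionary.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("ihtminer")

#: The six diagnosis subcategories, used as item-name prefixes.
SUBCATEGORIES: tuple[str, ...] = ("pdx", "pl", "dx", "cm", "hx", "ddx")

#: Closed vocabularies for record provenance fields.
CODE_SYSTEMS: tuple[str, ...] = ("icd9", "icd10")
SOURCES: tuple[str, ...] = ("clinical", "administrative")
PHASES: tuple[str, ...] = ("referring", "receiving")

_MAPPING_COLUMNS = ("code", "code_system", "concept", "subcategory")


class MappingError(ValueError):
    """Raised for malformed mapping tables or inconsistent inputs."""


class ConsistencyError(ValueError):
    """Raised when patient identifiers disagree between inputs."""


def item_name(subcategory: str, concept: str) -> str:
    """Return the prefix-named indicator for a (subcategory, concept) pair."""
    return f"{subcategory}_{concept}"


@dataclass(frozen=True)
class DiagnosisRecord:
    """One raw coded diagnosis with its source and encounter phase."""

    patient_id: str
    code: str
    code_system: str
    source: str
    phase: str

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("diagnosis code must be non-empty")
        if self.code_system not in CODE_SYSTEMS:
            raise ValueError(f"unknown code_system {self.code_system!r}; allowed: {CODE_SYSTEMS}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}; allowed: {SOURCES}")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}; allowed: {PHASES}")


@dataclass
class MappingTable:
    """Validated code -> (concept, subcategory) lookup table.

    The frame has columns ``code``, ``code_system``, ``concept``,
    ``subcategory`` and optionally ``precedence`` (smaller = higher
    priority, used only in single-category mode).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _MAPPING_COLUMNS if c not in self.frame.columns]
        if missing:
            raise MappingError(f"mapping table missing required columns: {missing}")
        bad = self.frame.loc[~self.frame["subcategory"].isin(SUBCATEGORIES)]
        if len(bad):
            row = bad.index[0]
            raise MappingError(
                f"row {row}: unknown subcategory {bad['subcategory'].iloc[0]!r}; "
                f"allowed vocabulary: {SUBCATEGORIES}"
            )
        bad = self.frame.loc[~self.frame["code_system"].isin(CODE_SYSTEMS)]
        if len(bad):
            row = bad.index[0]
            raise MappingError(
                f"row {row}: unknown code_system {bad['code_system'].iloc[0]!r}; "
                f"allowed vocabulary: {CODE_SYSTEMS}"
            )
        dup = self.frame.duplicated(subset=["code", "code_system", "subcategory"])
        if dup.any():
            rows = list(self.frame.index[dup][:5])
            raise MappingError(
                f"duplicate (code, code_system, subcategory) triples at rows {rows}"
            )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def concepts(self) -> set[str]:
        return set(self.frame["concept"])

    def items(self) -> list[str]:
        """All indicator names the table can produce, sorted."""
        names = {
            item_name(s, c) for s, c in zip(self.frame["subcategory"], self.frame["concept"])
        }
        return sorted(names)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def load_mapping(path: str | Path) -> MappingTable:
    """Load and validate a mapping CSV (UTF-8, header required)."""
    frame = pd.read_csv(path, dtype=str).fillna("")
    if "precedence" in frame.columns:
        frame["precedence"] = pd.to_numeric(frame["precedence"], errors="coerce")
    return MappingTable(frame)


@dataclass
class MappingReport:
    """Bookkeeping for a ``map_records`` pass; nothing is silently dropped."""

    n_records: int = 0
    n_mapped: int = 0
    n_unmapped: int = 0
    unmapped_codes: Counter = field(default_factory=Counter)

    @property
    def unmapped_rate(self) -> float:
        return self.n_unmapped / self.n_records if self.n_records else 0.0


def _normalize_codes(codes: pd.Series, uppercase: bool, strip_dots: bool) -> pd.Series:
    out = codes.astype(str).str.strip()
    if uppercase:
        out = out.str.upper()
    if strip_dots:
        out = out.str.replace(".", "", regex=False)
    return out


def records_to_frame(records: Iterable[DiagnosisRecord]) -> pd.DataFrame:
    """Materialize a record stream into the long-format CSV layout."""
    return pd.DataFrame(
        [(r.patient_id, r.code, r.code_system, r.source, r.phase) for r in records],
        columns=["patient_id", "code", "code_system", "source", "phase"],
    )


def map_records(
    records: pd.DataFrame | Iterable[DiagnosisRecord],
    mapping: MappingTable,
    *,
    uppercase: bool = True,
    strip_dots: bool = False,
    single_category: bool = False,
    unmapped_warn_threshold: float = 0.05,
) -> tuple[dict[str, set[str]], MappingReport]:
    """Map a stream of coded records to per-patient sets of prefixed items.

    A record contributes one item per mapping row matching its
    ``(code, code_system)``; a code mapped to several subcategories emits
    all of them unless ``single_category`` is set, in which case the row
    with the smallest precedence wins. Duplicate contributions collapse
    (set semantics). Records matching no row are counted in the report
    and a warning is logged when their rate exceeds
    ``unmapped_warn_threshold``.
    """
    if not isinstance(records, pd.DataFrame):
        records = records_to_frame(records)
    report = MappingReport(n_records=len(records))
    if len(records) == 0:
        return {}, report

    required = {"patient_id", "code", "code_system"}
    missing = required - set(records.columns)
    if missing:
        raise MappingError(f"records table missing columns: {sorted(missing)}")

    recs = records[["patient_id", "code", "code_system"]].copy()
    recs["code"] = _normalize_codes(recs["code"], uppercase, strip_dots)

    table = mapping.frame.copy()
    table["code"] = _normalize_codes(table["code"], uppercase, strip_dots)
    if single_category:
        prec = table["precedence"] if "precedence" in table.columns else pd.Series(
            np.zeros(len(table)), index=table.index
        )
        table = (
            table.assign(_prec=prec.fillna(np.inf))
            .sort_values("_prec", kind="stable")
            .drop_duplicates(subset=["code", "code_system"], keep="first")
            .drop(columns="_prec")
        )

    # Conservation is counted per input record (one record may emit several
    # items but is still one mapped record); keep the original row id around.
    recs = recs.reset_index(drop=True)
    merged = recs.reset_index().merge(
        table, on=["code", "code_system"], how="left", indicator=True
    )
    matched = merged["_merge"] == "both"
    per_record = merged.groupby("index")["_merge"].agg(lambda s: (s == "both").any())
    report.n_mapped = int(per_record.sum())
    report.n_unmapped = report.n_records - report.n_mapped

    unmatched_rows = merged.loc[~matched].drop_duplicates(subset="index")
    for code, system in zip(unmatched_rows["code"], unmatched_rows["code_system"]):
        report.unmapped_codes[(code, system)] += 1

    hits = merged.loc[matched]
    items = hits["subcategory"].str.cat(hits["concept"], sep="_")
    item_sets: dict[str, set[str]] = {
        pid: set(vals) for pid, vals in items.groupby(hits["patient_id"])
    }
    # Patients whose every record is unmapped still appear, with empty sets.
    for pid in recs["patient_id"].unique():
        item_sets.setdefault(pid, set())

    if report.unmapped_rate > unmapped_warn_threshold:
        logger.warning(
            "unmapped record rate %.1f%% exceeds threshold %.1f%% (%d of %d records)",
            100 * report.unmapped_rate,
            100 * unmapped_warn_threshold,
            report.n_unmapped,
            report.n_records,
        )
    return item_sets, report


@dataclass
class IndicatorMatrix:
    """Patients x prefix-named binary items, plus outcome and covariates.

    ``items`` is indexed by patient id with one int8 0/1 column per item
    (lexicographic column order); ``died`` / ``age`` / ``sex`` / ``race``
    are aligned per-patient arrays. ``N`` (patients) and ``D`` (deaths)
    are cached totals.
    """

    items: pd.DataFrame
    died: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    race: np.ndarray

    def __post_init__(self) -> None:
        self.items = self.items.astype(np.int8)
        vals = self.items.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("indicator cells must be 0/1")
        if self.items.columns.has_duplicates:
            raise ValueError("duplicate item names")
        self.died = np.asarray(self.died, dtype=np.int8)
        if len(self.died) != len(self.items):
            raise ValueError("outcome vector length does not match patient count")
        self._N = len(self.items)
        self._D = int(self.died.sum())

    @property
    def N(self) -> int:
        return self._N

    @property
    def D(self) -> int:
        return self._D

    @property
    def baseline_mortality(self) -> float:
        """Cohort death proportion D/N."""
        return self._D / self._N if self._N else float("nan")

    @property
    def patient_ids(self) -> pd.Index:
        return self.items.index

    @property
    def item_names(self) -> list[str]:
        return list(self.items.columns)

    def carriers(self, items: Iterable[str]) -> np.ndarray:
        """Boolean mask of patients carrying every item in ``items``."""
        names = list(items)
        unknown = [i for i in names if i not in self.items.columns]
        if unknown:
            raise KeyError(f"unknown item name(s): {unknown}")
        mask = np.ones(self._N, dtype=bool)
        for name in names:
            mask &= self.items[name].to_numpy(dtype=bool)
        return mask

    def to_frame(self) -> pd.DataFrame:
        """Single wide frame: patient_id index, items, then died/age/sex/race."""
        out = self.items.copy()
        out["died"] = self.died
        out["age"] = self.age
        out["sex"] = self.sex
        out["race"] = self.race
        return out

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="patient_id")

    @classmethod
    def read_csv(cls, path: str | Path) -> "IndicatorMatrix":
        frame = pd.read_csv(path, index_col="patient_id")
        meta = ["died", "age", "sex", "race"]
        missing = [c for c in meta if c not in frame.columns]
        if missing:
            raise MappingError(f"indicator CSV missing columns: {missing}")
        item_cols = [c for c in frame.columns if c not in meta]
        return cls(
            items=frame[item_cols],
            died=frame["died"].to_numpy(),
            age=frame["age"].to_numpy(),
            sex=frame["sex"].to_numpy(),
            race=frame["race"].to_numpy(),
        )


def build_indicators(
    item_sets: Mapping[str, set[str]],
    demographics: pd.DataFrame,
) -> IndicatorMatrix:
    """Assemble the indicator matrix over the union of observed items.

    Every patient in ``demographics`` is retained — patients with zero
    mapped diagnoses still contribute to N and to baseline mortality.
    Patients present in ``item_sets`` but absent from ``demographics``
    are a consistency error.
    """
    required = {"patient_id", "died", "age", "sex", "race"}
    missing = required - set(demographics.columns)
    if missing:
        raise MappingError(f"demographics table missing columns: {sorted(missing)}")
    demo = demographics.set_index("patient_id")
    if demo.index.has_duplicates:
        raise ConsistencyError("duplicate patient_id in demographics")
    unknown = sorted(set(item_sets) - set(demo.index))
    if unknown:
        raise ConsistencyError(
            f"{len(unknown)} patient(s) with diagnoses missing from demographics: "
            f"{unknown[:10]}"
        )

    columns = sorted(set().union(*item_sets.values())) if item_sets else []
    data = np.zeros((len(demo), len(columns)), dtype=np.int8)
    col_pos = {c: j for j, c in enumerate(columns)}
    row_pos = {p: i for i, p in enumerate(demo.index)}
    for pid, items in item_sets.items():
        i = row_pos[pid]
        for it in items:
            data[i, col_pos[it]] = 1
    return IndicatorMatrix(
        items=pd.DataFrame(data, index=demo.index, columns=columns),
        died=demo["died"].to_numpy(),
        age=demo["age"].to_numpy(),
        sex=demo["sex"].to_numpy(),
        race=demo["race"].to_numpy(),
    )
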