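"""Cohort containers and plumbing: modality tables, severity scores, splits.

A cohort is a set of patients observed in several feature *modalities*
(clinical scores, DTI regional mean diffusivity, DAT striatal uptake, ...),
each stored as an aligned patients x features table, plus a binary
progression outcome derived from the change in Hoehn-and-Yahr stage (HYS)
between baseline and the 5-year follow-up.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HysRecord",
    "ModalityTable",
    "MultimodalCohort",
    "CohortSplit",
    "hys_group",
    "read_modality_table",
    "write_modality_table",
    "read_hys_records",
    "write_hys_records",
    "align_cohort",
    "split_cohort",
    "load_cohort_manifest",
]


@dataclass(frozen=True)
class HysRecord:
    """Baseline and 5-year follow-up Hoehn-and-Yahr stage for one patient."""

    patient_id: str
    baseline: float
    followup: float

    def __post_init__(self) -> None:
        for name, v in (("baseline", self.baseline), ("followup", self.followup)):
            if not math.isfinite(v):
                raise ValueError(
                    f"HYS {name} for patient {self.patient_id!r} is not finite: {v!r}"
                )


def hys_group(record: HysRecord) -> int:
    """Binary progression label from the two-timepoint HYS rule.

    Returns 1 (progression) iff the follow-up stage is strictly above
    baseline; patients whose stage is unchanged or lower are labelled 0
    (stable).
    """
    return 1 if record.followup > record.baseline else 0


@dataclass
class ModalityTable:
    """One modality's aligned patients x features matrix.

    ``values`` is a float ndarray with one row per entry of ``patient_ids``
    and one column per entry of ``feature_names``. Missing values are
    rejected at construction (cohorts with incomplete data are excluded,
    not imputed).
    """

    modality: str
    patient_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.patient_ids), len(self.feature_names)):
            raise ValueError(
                f"{self.modality}: values shape {self.values.shape} does not match "
                f"{len(self.patient_ids)} patients x {len(self.feature_names)} features"
            )
        if len(set(self.patient_ids)) != len(self.patient_ids):
            dupes = sorted({p for p in self.patient_ids if self.patient_ids.count(p) > 1})
            raise ValueError(f"{self.modality}: duplicate patient_id(s): {dupes}")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError(f"{self.modality}: duplicated feature names")
        bad = np.argwhere(~np.isfinite(self.values))
        if bad.size:
            r, c = bad[0]
            raise ValueError(
                f"{self.modality}: non-finite value at patient "
                f"{self.patient_ids[int(r)]!r}, feature {self.feature_names[int(c)]!r}"
            )

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.patient_ids, name="patient_id"),
            columns=self.feature_names,
        )

    def subset(self, patient_ids: Sequence[str]) -> "ModalityTable":
        """Rows restricted to ``patient_ids``, in the given order."""
        pos = {p: i for i, p in enumerate(self.patient_ids)}
        missing = [p for p in patient_ids if p not in pos]
        if missing:
            raise KeyError(f"{self.modality}: unknown patient_id(s): {missing[:5]}")
        idx = [pos[p] for p in patient_ids]
        return ModalityTable(
            self.modality, list(patient_ids), list(self.feature_names),
            self.values[idx],
        )


@dataclass
class MultimodalCohort:
    """Aligned modality tables plus per-patient binary progression labels."""

    tables: dict[str, ModalityTable]
    labels: np.ndarray
    hys: list[HysRecord] | None = None

    def __post_init__(self) -> None:
        if not self.tables:
            raise ValueError("cohort needs at least one modality table")
        ids = self.patient_ids
        for tag, t in self.tables.items():
            if t.patient_ids != ids:
                raise ValueError(f"modality {tag!r} patient ordering differs from cohort")
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(ids),):
            raise ValueError("labels length must equal patient count")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary 0/1")
        if self.hys is not None and len(self.hys) != len(ids):
            raise ValueError("hys records length must equal patient count")

    @property
    def patient_ids(self) -> list[str]:
        return next(iter(self.tables.values())).patient_ids

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def subset(self, patient_ids: Sequence[str]) -> "MultimodalCohort":
        pos = {p: i for i, p in enumerate(self.patient_ids)}
        idx = [pos[p] for p in patient_ids]
        return MultimodalCohort(
            tables={tag: t.subset(patient_ids) for tag, t in self.tables.items()},
            labels=self.labels[idx],
            hys=None if self.hys is None else [self.hys[i] for i in idx],
        )


@dataclass(frozen=True)
class CohortSplit:
    """Disjoint train/validation/test patient-id partition."""

    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    fractions: tuple[float, float, float] = (0.6, 0.3, 0.1)

    def __post_init__(self) -> None:
        parts = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError("split sets are not pairwise disjoint")


def read_modality_table(path: str | Path, modality: str) -> ModalityTable:
    """Read a modality CSV (header ``patient_id,<f1>,<f2>,...``).

    Every data cell must be numeric and present; an empty or non-numeric
    cell is rejected with the offending patient and column named.
    """
    df = pd.read_csv(path, dtype={0: str})
    if df.columns[0] != "patient_id":
        raise ValueError(f"{path}: first column must be 'patient_id', got {df.columns[0]!r}")
    df = df.set_index("patient_id")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            pid = numeric.index[numeric.isna().to_numpy().argmax()]
            raise ValueError(
                f"{path}: missing or non-numeric cell at patient {pid!r}, column {col!r}"
            )
        values[:, j] = numeric.to_numpy()
    return ModalityTable(modality, list(df.index), list(df.columns), values)


def write_modality_table(table: ModalityTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, float_format="%.17g")


def read_hys_records(path: str | Path) -> list[HysRecord]:
    """Read a severity-score CSV ``patient_id,baseline_hys,followup_hys``."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    expected = ["patient_id", "baseline_hys", "followup_hys"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return [
        HysRecord(row.patient_id, float(row.baseline_hys), float(row.followup_hys))
        for row in df.itertuples(index=False)
    ]


def write_hys_records(records: Sequence[HysRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "baseline_hys": [r.baseline for r in records],
            "followup_hys": [r.followup for r in records],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def align_cohort(
    tables: Sequence[ModalityTable], hys_records: Sequence[HysRecord]
) -> MultimodalCohort:
    """Restrict to patients present in every table and in the HYS records.

    The canonical patient ordering is the first table's row order filtered
    to the common id set; labels come from :func:`hys_group`.
    """
    if not tables:
        raise ValueError("align_cohort needs at least one table")
    hys_by_id = {r.patient_id: r for r in hys_records}
    common = set(tables[0].patient_ids) & set(hys_by_id)
    for t in tables[1:]:
        common &= set(t.patient_ids)
    if not common:
        raise ValueError("no patient is present in every table and the HYS records")
    order = [p for p in tables[0].patient_ids if p in common]
    hys = [hys_by_id[p] for p in order]
    return MultimodalCohort(
        tables={t.modality: t.subset(order) for t in tables},
        labels=np.array([hys_group(r) for r in hys], dtype=int),
        hys=hys,
    )


def split_cohort(
    cohort: MultimodalCohort,
    fractions: tuple[float, float, float] = (0.6, 0.3, 0.1),
    seed: int = 0,
    stratify: bool = False,
) -> CohortSplit:
    """Uniform random train/val/test partition of the cohort's patients.

    Sizes are ``floor(n * f)`` per fraction with leftover patients assigned
    to train, then val, then test. ``stratify=True`` applies the same rule
    within each label class (off by default — the protocol partitions
    purely at random).
    """
    if any(f <= 0 for f in fractions) or not math.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions must be positive and sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    ids = np.asarray(cohort.patient_ids, dtype=object)

    def _partition(pool: np.ndarray) -> list[list[str]]:
        perm = pool[rng.permutation(len(pool))]
        n = len(perm)
        sizes = [int(n * f) for f in fractions]
        leftover = n - sum(sizes)
        for i in range(leftover):
            sizes[i % 3] += 1
        out, start = [], 0
        for s in sizes:
            out.append(list(perm[start : start + s]))
            start += s
        return out

    if stratify:
        parts = [[], [], []]
        for cls in (1, 0):
            for part, chunk in zip(parts, _partition(ids[cohort.labels == cls])):
                part.extend(chunk)
    else:
        parts = _partition(ids)
    if any(len(p) == 0 for p in parts):
        raise ValueError(
            f"split of n={cohort.n_patients} with fractions {fractions} "
            "leaves an empty set"
        )
    return CohortSplit(tuple(parts[0]), tuple(parts[1]), tuple(parts[2]), tuple(fractions))


def load_cohort_manifest(path: str | Path) -> MultimodalCohort:
    """Build an aligned cohort from a JSON manifest.

    The manifest maps modality tags to CSV paths and names the severity
    score CSV::

        {"modalities": {"clinical": "clin.csv", "dti": "dti.csv"},
         "hys": "hys.csv"}

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    spec: Mapping = json.loads(path.read_text())
    base = path.parent
    tables = [
        read_modality_table(base / p, tag) for tag, p in spec["modalities"].items()
    ]
    hys = read_hys_records(base / spec["hys"])
    return align_cohort(tables, hys)
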