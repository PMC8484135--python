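"""Event-record datasets: one row per dose or observation, NONMEM-style.

Canonical CSV columns (in order): ID, TIME (days), EVID (1 = dose,
0 = observation), AMT (mg), DUR (infusion duration, days), DV (ug/mL),
MDV (1 = missing DV), followed by any covariate columns present.  Baseline
covariates are constant within a subject.  A ``dialect`` mapping lets files
with other headers (e.g. RATE instead of DUR) parse to the same canonical
form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .population import CovariateRecord

__all__ = [
    "EventRecord",
    "Dataset",
    "DatasetFormatError",
    "DatasetValidationError",
    "read_dataset",
    "write_dataset",
    "apply_lloq_filter",
    "CANONICAL_COLUMNS",
    "COVARIATE_COLUMNS",
]

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ("ID", "TIME", "EVID", "AMT", "DUR", "DV", "MDV")

#: recognised covariate columns, in canonical output order
COVARIATE_COLUMNS = (
    "WT",
    "ALB",
    "SEX",
    "THERAPY",
    "AGE",
    "ALP",
    "AST",
    "ALT",
    "TBIL",
    "EGFR",
    "LDH",
    "TPROT",
    "TUMSIZE",
    "TUMTYPE",
    "ECOG",
    "REGION",
    "RACE",
    "GASTREC",
    "FGFR2B",
    "PRIORFOLFOX",
)

_CONTINUOUS_COVARIATES = {
    "WT", "ALB", "AGE", "ALP", "AST", "ALT", "TBIL", "EGFR", "LDH", "TPROT", "TUMSIZE",
}


class DatasetFormatError(ValueError):
    """A file does not conform to the expected column layout."""


class DatasetValidationError(ValueError):
    """Rows violate event-record invariants."""


@dataclass(frozen=True)
class EventRecord:
    """One dosing or observation event."""

    subject_id: str
    time: float
    event_kind: str  # "dose" | "observation"
    amount: float = 0.0  # mg, doses only
    infusion_duration: float = 0.0  # days, doses only
    dv: float = float("nan")  # ug/mL, observations only
    mdv_flag: bool = False
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.event_kind not in ("dose", "observation"):
            raise DatasetValidationError(f"unknown event kind {self.event_kind!r}")
        if self.time < 0:
            raise DatasetValidationError("event times must be non-negative")
        if self.event_kind == "dose":
            if self.amount <= 0 or self.infusion_duration <= 0:
                raise DatasetValidationError(
                    "dose rows need amount > 0 and infusion_duration > 0"
                )
        elif not self.mdv_flag and not (self.dv >= 0):
            raise DatasetValidationError("observation rows need dv >= 0 or mdv_flag")


class Dataset:
    """Validated longitudinal event-record table.

    Thin wrapper over a canonical :class:`pandas.DataFrame`; all analysis
    modules consume this type.
    """

    def __init__(self, frame: pd.DataFrame):
        self._frame = _validate_frame(frame)

    # -- construction ---------------------------------------------------
    @classmethod
    def from_records(cls, records: Sequence[EventRecord]) -> "Dataset":
        rows = []
        for r in records:
            row = {
                "ID": r.subject_id,
                "TIME": r.time,
                "EVID": 1 if r.event_kind == "dose" else 0,
                "AMT": r.amount if r.event_kind == "dose" else 0.0,
                "DUR": r.infusion_duration if r.event_kind == "dose" else 0.0,
                "DV": r.dv if r.event_kind == "observation" else np.nan,
                "MDV": int(r.mdv_flag or r.event_kind == "dose"),
            }
            row.update(r.covariates)
            rows.append(row)
        cols = list(CANONICAL_COLUMNS) + [
            c for c in COVARIATE_COLUMNS if any(c in r.covariates for r in records)
        ]
        return cls(pd.DataFrame(rows, columns=cols))

    # -- basic accessors ------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def subject_ids(self) -> list:
        return list(self._frame["ID"].drop_duplicates())

    @property
    def n_subjects(self) -> int:
        return self._frame["ID"].nunique()

    @property
    def n_observations(self) -> int:
        obs = (self._frame["EVID"] == 0) & (self._frame["MDV"] == 0)
        return int(obs.sum())

    def __len__(self) -> int:
        return len(self._frame)

    def observations(self) -> pd.DataFrame:
        f = self._frame
        return f[(f["EVID"] == 0) & (f["MDV"] == 0)]

    def doses(self) -> pd.DataFrame:
        return self._frame[self._frame["EVID"] == 1]

    def covariate_columns(self) -> list[str]:
        return [c for c in self._frame.columns if c not in CANONICAL_COLUMNS]

    def covariates_frame(self) -> pd.DataFrame:
        """One row per subject (baseline covariates), indexed by ID."""
        cols = self.covariate_columns()
        return self._frame.groupby("ID", sort=False)[cols].first()

    def covariate_record(self, subject_id) -> CovariateRecord:
        return self.covariate_records()[subject_id]

    def covariate_records(self) -> dict:
        """Subject ID -> :class:`CovariateRecord` (computed once, cached)."""
        if getattr(self, "_cov_cache", None) is None:
            out = {}
            for sid, row in self.covariates_frame().iterrows():
                extra = {
                    c: row[c]
                    for c in row.index
                    if c not in ("WT", "ALB", "SEX", "THERAPY") and pd.notna(row[c])
                }
                out[sid] = CovariateRecord(
                    wt=float(row["WT"]),
                    alb=float(row.get("ALB", 38.0)),
                    sex=str(row.get("SEX", "M")),
                    therapy=str(row.get("THERAPY", "mono")),
                    extra=extra,
                )
            self._cov_cache = out
        return self._cov_cache

    def subset_subjects(self, subject_ids: Sequence) -> "Dataset":
        keep = self._frame["ID"].isin(set(subject_ids))
        return Dataset(self._frame[keep].reset_index(drop=True))

    def equals(self, other: "Dataset") -> bool:
        a, b = self._frame, other._frame
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            if a[c].dtype.kind in "fc":
                if not np.allclose(
                    a[c].to_numpy(float), b[c].to_numpy(float), equal_nan=True, rtol=1e-10
                ):
                    return False
            elif not (a[c].astype(str) == b[c].astype(str)).all():
                return False
        return True


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    for col in CANONICAL_COLUMNS:
        if col not in frame.columns:
            raise DatasetFormatError(f"missing mandatory column {col!r}")
    f = frame.copy()
    for col in ("TIME", "AMT", "DUR", "DV"):
        f[col] = pd.to_numeric(f[col], errors="coerce")
    f["EVID"] = f["EVID"].astype(int)
    f["MDV"] = f["MDV"].astype(int)

    doses = f["EVID"] == 1
    bad = doses & ~((f["AMT"] > 0) & (f["DUR"] > 0))
    if bad.any():
        sid = f.loc[bad, "ID"].iloc[0]
        raise DatasetValidationError(
            f"dose rows must have AMT > 0 and DUR > 0 (subject {sid!r})"
        )
    obs = f["EVID"] == 0
    bad = obs & (f["MDV"] == 0) & ~(f["DV"] >= 0)
    if bad.any():
        sid = f.loc[bad, "ID"].iloc[0]
        raise DatasetValidationError(
            f"observation rows must have DV >= 0 or MDV = 1 (subject {sid!r})"
        )
    for sid, grp in f.groupby("ID", sort=False):
        t = grp["TIME"].to_numpy(float)
        if np.any(np.diff(t) < 0):
            raise DatasetValidationError(f"times not non-decreasing for subject {sid!r}")
        for c in f.columns:
            if c in CANONICAL_COLUMNS:
                continue
            vals = grp[c].dropna()
            if vals.nunique() > 1:
                raise DatasetValidationError(
                    f"covariate {c!r} varies within subject {sid!r}; baseline only"
                )
    extra = [c for c in f.columns if c not in CANONICAL_COLUMNS]
    ordered = (
        list(CANONICAL_COLUMNS)
        + [c for c in COVARIATE_COLUMNS if c in extra]
        + [c for c in extra if c not in COVARIATE_COLUMNS]
    )
    return f[ordered].reset_index(drop=True)


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def read_dataset(path, dialect: Mapping[str, str] | None = None) -> Dataset:
    """Read an event-record CSV.

    ``dialect`` maps canonical names to the file's column headers, e.g.
    ``{"ID": "USUBJID", "DUR": "RATE"}``; mapping ``DUR`` to a rate column
    converts via ``DUR = AMT / RATE``.  Without a dialect the canonical
    headers are expected, with ``RATE`` accepted in place of ``DUR``.
    """
    raw = pd.read_csv(path)
    dialect = dict(dialect or {})
    rename = {v: k for k, v in dialect.items() if v in raw.columns}
    raw = raw.rename(columns=rename)

    rate_source = dialect.get("DUR", "RATE")
    if "DUR" not in raw.columns and (rate_source in raw.columns or "RATE" in raw.columns):
        rate_col = "DUR" if rate_source in raw.columns and rate_source != "RATE" else "RATE"
        if rate_col in raw.columns:
            rate = pd.to_numeric(raw[rate_col], errors="coerce")
            amt = pd.to_numeric(raw["AMT"], errors="coerce")
            with np.errstate(divide="ignore", invalid="ignore"):
                raw["DUR"] = np.where(rate > 0, amt / rate, 0.0)
            raw = raw.drop(columns=[rate_col], errors="ignore")
    if "EVID" not in raw.columns and "AMT" in raw.columns:
        raw["EVID"] = (pd.to_numeric(raw["AMT"], errors="coerce").fillna(0) > 0).astype(int)
    if "MDV" not in raw.columns:
        dv = pd.to_numeric(raw.get("DV"), errors="coerce")
        raw["MDV"] = ((raw.get("EVID", 0) == 1) | dv.isna()).astype(int)
    for col in CANONICAL_COLUMNS:
        if col not in raw.columns:
            raise DatasetFormatError(f"missing mandatory column {col!r} in {path}")
    keep = list(CANONICAL_COLUMNS) + [c for c in COVARIATE_COLUMNS if c in raw.columns]
    return Dataset(raw[keep])


def write_dataset(ds: Dataset, path) -> None:
    """Write the canonical CSV (stable column order)."""
    cols = list(CANONICAL_COLUMNS) + [
        c for c in COVARIATE_COLUMNS if c in ds.frame.columns
    ] + [
        c for c in ds.covariate_columns() if c not in COVARIATE_COLUMNS
    ]
    ds.frame[cols].to_csv(path, index=False)


def apply_lloq_filter(ds: Dataset, lloq: float) -> tuple[Dataset, int]:
    """Drop observations with DV strictly below the LLOQ.

    Returns the filtered dataset and the number of rows removed.  Values
    exactly at the LLOQ are retained.  Idempotent.
    """
    if lloq <= 0:
        raise ValueError("lloq must be positive")
    f = ds.frame
    below = (f["EVID"] == 0) & (f["MDV"] == 0) & (f["DV"] < lloq)
    removed = int(below.sum())
    if removed:
        logger.info("LLOQ filter removed %d of %d observations", removed, ds.n_observations)
    return Dataset(f[~below].reset_index(drop=True)), removed
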