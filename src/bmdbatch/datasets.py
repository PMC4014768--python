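"""Dose-response dataset containers and CSV / JSON input-output.

A :class:`DoseResponseDataset` holds one study endpoint as group-level summary
data: doses, group sizes, and either affected counts (dichotomous /
dichotomous-cancer endpoints, binomial sampling) or group means and standard
deviations (continuous endpoints, normal sampling).  Datasets are read from
long-format CSV (one row per dose group, keyed by ``dataset_id``) and batch run
outputs are serialized as JSON session records.

Only summary data are supported; individual-animal responses, litter-nested
designs and time-to-tumor data are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

DICHOTOMOUS = "dichotomous"
CONTINUOUS = "continuous"
DICHOTOMOUS_CANCER = "dichotomous_cancer"
DTYPES = (DICHOTOMOUS, CONTINUOUS, DICHOTOMOUS_CANCER)

#: Minimum number of dose groups (including control) for a dataset to be
#: modelable at all.
MIN_MODELABLE_GROUPS = 3


class DatasetError(ValueError):
    """Raised when a dataset violates a structural invariant."""


@dataclass
class ReportedPod:
    """A point of departure reported in an existing assessment."""

    pod_type: str  # NOAEL | LOAEL | BMDL
    value: float

    def __post_init__(self) -> None:
        if self.pod_type not in ("NOAEL", "LOAEL", "BMDL"):
            raise DatasetError(f"unknown POD type {self.pod_type!r}")
        if not self.value > 0:
            raise DatasetError("reported POD must be positive")


@dataclass
class DoseResponseDataset:
    """Group-level summary dose-response data for one endpoint.

    Parameters
    ----------
    dataset_id : str
        Unique identifier of the dataset.
    dtype : str
        One of ``dichotomous``, ``continuous``, ``dichotomous_cancer``.
    doses : sequence of float
        Strictly increasing, non-negative; ``doses[0]`` may be 0 (control).
    n : sequence of int
        Subjects per dose group (positive).
    incidence : sequence of int, optional
        Affected counts per group (dichotomous types only).
    mean, sd : sequence of float, optional
        Group means and standard deviations (continuous only).
    chemical_id, endpoint : str, optional
        Metadata carried through to summaries.
    reported_pod : ReportedPod, optional
        NOAEL/LOAEL/BMDL from an existing assessment, for comparisons.
    dose_units : str
        Opaque unit label; never converted.
    """

    dataset_id: str
    dtype: str
    doses: np.ndarray
    n: np.ndarray
    incidence: Optional[np.ndarray] = None
    mean: Optional[np.ndarray] = None
    sd: Optional[np.ndarray] = None
    chemical_id: Optional[str] = None
    endpoint: Optional[str] = None
    reported_pod: Optional[ReportedPod] = None
    dose_units: str = ""

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if self.incidence is not None:
            self.incidence = np.asarray(self.incidence, dtype=int)
        if self.mean is not None:
            self.mean = np.asarray(self.mean, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.dtype not in DTYPES:
            raise DatasetError(f"unknown dtype {self.dtype!r}")
        g = len(self.doses)
        if g < 2:
            raise DatasetError("need at least 2 dose groups")
        if np.any(self.doses < 0):
            raise DatasetError("doses must be non-negative")
        if np.any(np.diff(self.doses) <= 0):
            raise DatasetError("doses must be strictly increasing (no duplicates)")
        if len(self.n) != g:
            raise DatasetError("n must have one entry per dose group")
        if np.any(self.n < 1):
            raise DatasetError("group sizes must be positive integers")
        if self.is_dichotomous:
            if self.incidence is None or len(self.incidence) != g:
                raise DatasetError("dichotomous data need incidence per group")
            if np.any(self.incidence < 0) or np.any(self.incidence > self.n):
                raise DatasetError("incidence must satisfy 0 <= incidence <= n")
        else:
            if self.mean is None or len(self.mean) != g:
                raise DatasetError("continuous data need a mean per group")
            if self.sd is None or len(self.sd) != g:
                raise DatasetError("continuous data need an SD per group")
            if np.any(self.sd < 0):
                raise DatasetError("SDs must be non-negative")

    # ------------------------------------------------------------------
    @property
    def is_dichotomous(self) -> bool:
        return self.dtype in (DICHOTOMOUS, DICHOTOMOUS_CANCER)

    @property
    def n_groups(self) -> int:
        return len(self.doses)

    @property
    def modelable(self) -> bool:
        """Whether the dataset has enough dose groups to fit at all."""
        return self.n_groups >= MIN_MODELABLE_GROUPS

    @property
    def max_dose(self) -> float:
        return float(self.doses[-1])

    @property
    def lowest_nonzero_dose(self) -> float:
        nz = self.doses[self.doses > 0]
        return float(nz[0]) if nz.size else float("nan")

    def drop_highest_dose(self) -> "DoseResponseDataset":
        """Return a copy with the highest dose group removed."""
        sl = slice(0, self.n_groups - 1)
        return DoseResponseDataset(
            dataset_id=self.dataset_id,
            dtype=self.dtype,
            doses=self.doses[sl].copy(),
            n=self.n[sl].copy(),
            incidence=None if self.incidence is None else self.incidence[sl].copy(),
            mean=None if self.mean is None else self.mean[sl].copy(),
            sd=None if self.sd is None else self.sd[sl].copy(),
            chemical_id=self.chemical_id,
            endpoint=self.endpoint,
            reported_pod=self.reported_pod,
            dose_units=self.dose_units,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format representation (one row per dose group)."""
        df = pd.DataFrame(
            {
                "dataset_id": self.dataset_id,
                "chemical_id": self.chemical_id or "",
                "endpoint": self.endpoint or "",
                "dtype": self.dtype,
                "dose": self.doses,
                "n": self.n,
            }
        )
        if self.is_dichotomous:
            df["incidence"] = self.incidence
            df["mean"] = np.nan
            df["sd"] = np.nan
        else:
            df["incidence"] = np.nan
            df["mean"] = self.mean
            df["sd"] = self.sd
        return df


# ----------------------------------------------------------------------
# CSV reading / writing

REQUIRED_COLUMNS = ("dataset_id", "dose", "n")


def read_datasets(
    path,
    dtype_default: str = DICHOTOMOUS,
    errors: Optional[list] = None,
) -> list[DoseResponseDataset]:
    """Read long-format CSV into validated datasets.

    One row per dose group; groups of rows are keyed by ``dataset_id``.
    Rows within a dataset are sorted by dose.  A dataset violating an
    invariant is rejected with a diagnostic naming the offending rows;
    remaining datasets are still returned.  Missing required columns are a
    hard error.

    Parameters
    ----------
    path : path-like or file-like
    dtype_default : str
        dtype to assume when the CSV has no ``dtype`` column or leaves it blank.
    errors : list, optional
        If given, per-dataset rejection diagnostics are appended to it.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"input CSV is missing required column(s): {missing}")
    if dtype_default not in DTYPES:
        raise DatasetError(f"unknown dtype_default {dtype_default!r}")

    collected = [] if errors is None else errors
    out: list[DoseResponseDataset] = []
    # keep first-appearance order of dataset ids
    for ds_id, grp in df.groupby("dataset_id", sort=False):
        rows = grp.sort_values("dose")
        first = rows.iloc[0]
        dtype = dtype_default
        if "dtype" in rows.columns and isinstance(first.get("dtype"), str) and first["dtype"]:
            dtype = str(first["dtype"])
        kwargs = dict(
            dataset_id=str(ds_id),
            dtype=dtype,
            doses=rows["dose"].to_numpy(float),
            n=rows["n"].to_numpy(),
            chemical_id=_opt_str(first, "chemical_id"),
            endpoint=_opt_str(first, "endpoint"),
        )
        try:
            if dtype in (DICHOTOMOUS, DICHOTOMOUS_CANCER):
                if "incidence" not in rows.columns:
                    raise DatasetError("missing 'incidence' column for dichotomous data")
                kwargs["incidence"] = rows["incidence"].to_numpy()
            else:
                for c in ("mean", "sd"):
                    if c not in rows.columns:
                        raise DatasetError(f"missing {c!r} column for continuous data")
                kwargs["mean"] = rows["mean"].to_numpy(float)
                kwargs["sd"] = rows["sd"].to_numpy(float)
            if "pod_type" in rows.columns and isinstance(first.get("pod_type"), str) and first["pod_type"]:
                kwargs["reported_pod"] = ReportedPod(str(first["pod_type"]), float(first["pod_value"]))
            out.append(DoseResponseDataset(**kwargs))
        except (DatasetError, ValueError, TypeError) as exc:
            row_numbers = [int(i) + 2 for i in rows.index]  # 1-based, + header
            collected.append(
                f"dataset {ds_id!r} rejected (CSV rows {row_numbers}): {exc}"
            )
    return out


def _opt_str(row, col) -> Optional[str]:
    if col in row.index:
        v = row[col]
        if isinstance(v, str) and v:
            return v
    return None


def write_datasets(datasets: Sequence[DoseResponseDataset], path) -> None:
    """Write datasets back to long-format CSV (inverse of :func:`read_datasets`)."""
    frames = [d.to_frame() for d in datasets]
    df = pd.concat(frames, ignore_index=True)
    pods = {d.dataset_id: d.reported_pod for d in datasets if d.reported_pod}
    if pods:
        df["pod_type"] = [
            pods[i].pod_type if i in pods else "" for i in df["dataset_id"]
        ]
        df["pod_value"] = [
            pods[i].value if i in pods else np.nan for i in df["dataset_id"]
        ]
    df.to_csv(path, index=False)


# ----------------------------------------------------------------------
# Session records (batch-run audit trail)


@dataclass
class FitRecord:
    """Serializable summary of one model fit within a session."""

    model: str
    params: list
    param_names: list
    loglik: float
    aic: float
    converged: bool
    gof_pvalue: Optional[float]
    bmd: Optional[float]
    bmdl: Optional[float]
    viability: str  # Unusable | Questionable | Viable
    reasons: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    variance_mode: Optional[str] = None
    degree: Optional[int] = None
    tests: Optional[dict] = None


@dataclass
class AttemptRecord:
    """One pass over the (possibly dose-dropped) dataset with the full suite."""

    doses_used: int
    fits: list  # list[FitRecord]


@dataclass
class Selection:
    """The recommended model(s) and BMD/BMDL for a dataset."""

    model_names: list
    bmd: float
    bmdl: float
    selection_rule: str  # lowest_aic | lowest_bmdl | aic_tie_average
    warnings: list = field(default_factory=list)


@dataclass
class SessionRecord:
    """Full audit of one dataset's batch run."""

    dataset_id: str
    outcome: str  # modeled | failed_modeling | too_few_doses
    attempts: list = field(default_factory=list)  # list[AttemptRecord]
    dropped_doses: int = 0
    selected: Optional[Selection] = None
    chemical_id: Optional[str] = None
    endpoint: Optional[str] = None
    reason: Optional[str] = None

    def to_dict(self) -> dict:
        return asdict(self)


def write_session_record(record: SessionRecord, path) -> None:
    """Serialize a session record to JSON (lossless for every recorded field)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(record.to_dict(), fh, indent=2, default=_json_default)


def read_session_record(path) -> SessionRecord:
    """Load a session record written by :func:`write_session_record`."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return session_record_from_dict(raw)


def session_record_from_dict(raw: dict) -> SessionRecord:
    attempts = [
        AttemptRecord(
            doses_used=a["doses_used"],
            fits=[FitRecord(**f) for f in a["fits"]],
        )
        for a in raw.get("attempts", [])
    ]
    sel = raw.get("selected")
    return SessionRecord(
        dataset_id=raw["dataset_id"],
        outcome=raw["outcome"],
        attempts=attempts,
        dropped_doses=raw.get("dropped_doses", 0),
        selected=None if sel is None else Selection(**sel),
        chemical_id=raw.get("chemical_id"),
        endpoint=raw.get("endpoint"),
        reason=raw.get("reason"),
    )


def _json_default(obj):
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
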