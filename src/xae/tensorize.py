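"""Temporal event matrix representation (TEMR) of patient pathways.

Each patient becomes an activities x time-windows grid: cell (i, j) counts
occurrences of activity i during window j, with windows counted backwards
from the patient's index date (window j = w is the most recent). Counts are
rescaled to [0, 1] by a single factor learned on training data, so grids are
directly consumable by the autoencoders. Flat LOF (list-of-features) and TW
(blocked time-window) exports feed conventional tabular models.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import h5py

from .errors import ValidationError
from .eventlog import EventLog

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """Contiguous, non-overlapping half-open windows ending at the index date.

    Window ``j`` (1-based, ``j = w`` most recent) covers the half-open day
    interval ``[index - (w-j+1)*delta, index - (w-j)*delta)``; the index date
    itself is excluded (history is strictly prior to it).
    """

    n_windows: int = 24
    window_days: float = 30.44

    def __post_init__(self) -> None:
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1 day")

    @property
    def span_days(self) -> float:
        return self.n_windows * self.window_days

    def window_of(self, days_before: np.ndarray) -> np.ndarray:
        """Map days-before-index (>=1) to 1-based window index; 0 = too old."""
        j = self.n_windows - np.ceil(days_before / self.window_days).astype(int) + 1
        return np.where((days_before >= 1) & (j >= 1), j, 0)


#: Two years of history in 24 monthly windows (case-study geometry).
MONTHLY_2Y = WindowSpec(24, 30.44)
#: Two years in 26 four-week windows (worked-example geometry).
FOUR_WEEKLY_2Y = WindowSpec(26, 28.0)


@dataclasses.dataclass
class MatrixDataset:
    """A stack of pathway matrices sharing label order and window geometry."""

    values: np.ndarray            # (n, l, w) float in [0, 1]
    row_labels: list[str]
    patient_ids: np.ndarray
    classes: np.ndarray           # (n,) in {0, 1}
    rescale_factor: float
    spec: WindowSpec

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("values must be (n, l, w)")
        if self.values.shape[1] != len(self.row_labels):
            raise ValueError("row count must match row_labels")
        if self.rescale_factor < 1:
            raise ValueError("rescale_factor must be >= 1")

    def __len__(self) -> int:
        return self.values.shape[0]

    def by_class(self, c: int) -> np.ndarray:
        return self.values[self.classes == c]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values.astype(np.float32))
            f.create_dataset(
                "row_labels", data=np.array(self.row_labels, dtype=h5py.string_dtype())
            )
            f.create_dataset(
                "patient_ids",
                data=np.array(self.patient_ids, dtype=h5py.string_dtype()),
            )
            f.create_dataset("classes", data=self.classes.astype(np.int8))
            f.attrs["rescale_factor"] = self.rescale_factor
            f.attrs["window_days"] = self.spec.window_days
            f.attrs["n_windows"] = self.spec.n_windows

    @classmethod
    def from_hdf5(cls, path) -> "MatrixDataset":
        with h5py.File(path, "r") as f:
            return cls(
                values=f["values"][...].astype(np.float64),
                row_labels=[s.decode() for s in f["row_labels"][...]],
                patient_ids=np.array([s.decode() for s in f["patient_ids"][...]]),
                classes=f["classes"][...].astype(int),
                rescale_factor=float(f.attrs["rescale_factor"]),
                spec=WindowSpec(int(f.attrs["n_windows"]), float(f.attrs["window_days"])),
            )


def _window_table(log: EventLog, spec: WindowSpec) -> pd.DataFrame:
    """Events annotated with their 1-based window; rows outside history dropped."""
    ev = log.events
    idx = log.index_dates.loc[ev["patient_id"]].values
    days_before = (pd.to_datetime(idx) - pd.to_datetime(ev["date"].values)).days
    if np.any(days_before < 0):
        bad = ev.loc[np.asarray(days_before) < 0, "patient_id"].unique()
        raise ValidationError(
            "event(s) dated after index date for patient(s): "
            + ", ".join(map(str, bad[:5]))
        )
    win = spec.window_of(np.asarray(days_before, dtype=float))
    dropped = int(ev.loc[win == 0, "count"].sum())
    if dropped:
        logger.info("dropped %d activity occurrence(s) older than the window span", dropped)
    out = ev.assign(window=win)
    return out[out["window"] > 0]


def count_matrix(log: EventLog, patient: str, spec: WindowSpec) -> np.ndarray:
    """Integer l x w occurrence grid for one patient."""
    counts, _, _ = count_tensor(log.subset([patient]), spec)
    return counts[0]

def count_tensor(
    log: EventLog, spec: WindowSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integer (n, l, w) occurrence tensor for every patient in the log.

    Patients follow the outcome-table order; rows follow ``log.labels``.
    Activities whose label is outside the label set are ignored.
    """
    labels = log.labels
    label_pos = {c: i for i, c in enumerate(labels)}
    patients = np.asarray(log.patients)
    patient_pos = {p: i for i, p in enumerate(patients)}
    tab = _window_table(log, spec)
    tab = tab[tab["code"].isin(label_pos)]
    counts = np.zeros((len(patients), len(labels), spec.n_windows), dtype=np.int64)
    if len(tab):
        pi = tab["patient_id"].map(patient_pos).to_numpy()
        li = tab["code"].map(label_pos).to_numpy()
        wi = tab["window"].to_numpy() - 1
        np.add.at(counts, (pi, li, wi), tab["count"].to_numpy())
    classes = log.outcomes.loc[patients].to_numpy()
    return counts, patients, classes


def rescale_counts(
    counts: np.ndarray, rescale_factor: float | None = None
) -> tuple[np.ndarray, float]:
    """Map integer counts into [0, 1] by one global factor (the training max).

    With ``rescale_factor`` given (test time), cells exceeding it clip to 1.
    """
    if counts.size == 0:
        raise ValueError("empty dataset")
    if rescale_factor is None:
        rescale_factor = max(float(counts.max()), 1.0)
    return np.clip(counts / rescale_factor, 0.0, 1.0), rescale_factor


class PathwayTensorizer:
    """Event log -> :class:`MatrixDataset` transformer.

    ``fit`` learns the global rescale factor (the maximum cell count over the
    training log); ``transform`` builds rescaled [0, 1] matrix stacks, clipping
    test-time cells that exceed the training maximum.

    Parameters
    ----------
    spec : window geometry (count, length of the backward-looking windows).
    """

    def __init__(self, spec: WindowSpec = MONTHLY_2Y):
        self.spec = spec

    def get_params(self, deep: bool = True) -> dict:
        return {"spec": self.spec}

    def set_params(self, **params) -> "PathwayTensorizer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, log: EventLog) -> "PathwayTensorizer":
        counts, _, _ = count_tensor(log, self.spec)
        _, self.rescale_factor_ = rescale_counts(counts)
        self.row_labels_ = log.labels
        return self

    def transform(self, log: EventLog) -> MatrixDataset:
        if not hasattr(self, "rescale_factor_"):
            raise ValidationError("PathwayTensorizer is not fitted")
        if log.labels != self.row_labels_:
            raise ValidationError("label set differs from the fitted one")
        counts, patients, classes = count_tensor(log, self.spec)
        values, _ = rescale_counts(counts, self.rescale_factor_)
        return MatrixDataset(
            values, list(self.row_labels_), patients, classes,
            self.rescale_factor_, self.spec,
        )

    def fit_transform(self, log: EventLog) -> MatrixDataset:
        return self.fit(log).transform(log)


def features_lof(log: EventLog, spec: WindowSpec = MONTHLY_2Y) -> pd.DataFrame:
    """List-of-features export: per patient, total appearances of each label."""
    counts, patients, _ = count_tensor(log, spec)
    return pd.DataFrame(
        counts.sum(axis=2), index=pd.Index(patients, name="patient_id"),
        columns=log.labels,
    )


def features_tw(
    log: EventLog, spec: WindowSpec = MONTHLY_2Y, n_blocks: int = 4
) -> pd.DataFrame:
    """Blocked time-window export: one LOF vector per block, earliest first.

    Window count not divisible by ``n_blocks`` pads the earliest block.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    counts, patients, _ = count_tensor(log, spec)
    w = spec.n_windows
    base = w // n_blocks
    sizes = [base + w % n_blocks] + [base] * (n_blocks - 1)
    bounds = np.cumsum([0] + sizes)
    blocks = [
        counts[:, :, bounds[k]:bounds[k + 1]].sum(axis=2) for k in range(n_blocks)
    ]
    cols = [f"{lab}__tw{k + 1}" for k in range(n_blocks) for lab in log.labels]
    return pd.DataFrame(
        np.concatenate(blocks, axis=1),
        index=pd.Index(patients, name="patient_id"),
        columns=cols,
    )
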