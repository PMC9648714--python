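"""Coded medical event logs: reading, hierarchy enrichment, filtering, splitting.

An event log stores, per patient, dated events where each event is a multiset
of medical codes (diagnoses, procedures, devices, biology, consultations).
Codes live in single-parent hierarchies (ICD-10 chapters, CCAM/ATC-style
trees); enrichment adds every ancestor of every recorded code so that all
aggregation levels coexist as activities. Internally the log is a long-format
:class:`pandas.DataFrame` with one row per (patient, date, code) and a
multiplicity column, which keeps group-by operations vectorised.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .errors import FormatError, ValidationError

EVENT_COLUMNS = ["patient_id", "date", "code", "system"]
OUTCOME_COLUMNS = ["patient_id", "outcome", "index_date"]
HIERARCHY_COLUMNS = ["code", "parent", "system"]

#: Maximum ancestor-chain length tolerated when validating a hierarchy.
MAX_DEPTH = 10


class CodeHierarchy:
    """Directed forest of medical codes (one parent per code, per system).

    Parameters
    ----------
    parent : mapping code -> parent code. Codes absent from the mapping, or
        mapping to ``""``/``None``, are roots.
    system : mapping code -> code-system tag (e.g. ``DIAG``, ``PROC``).
    """

    def __init__(self, parent: Mapping[str, str], system: Mapping[str, str] | None = None):
        self.parent = {c: p for c, p in parent.items() if p not in ("", None)}
        self.system = dict(system or {})
        self._validate()
        self._chain_cache: dict[str, tuple[str, ...]] = {}

    def _validate(self) -> None:
        for code in self.parent:
            seen = [code]
            cur = code
            for _ in range(MAX_DEPTH + 1):
                cur = self.parent.get(cur)
                if cur is None:
                    break
                if cur in seen:
                    raise ValidationError(f"hierarchy cycle through code {cur!r}")
                seen.append(cur)
            else:
                raise ValidationError(
                    f"ancestor chain of {code!r} exceeds {MAX_DEPTH} steps"
                )

    @property
    def roots(self) -> set[str]:
        codes = set(self.parent) | set(self.parent.values())
        return codes - set(self.parent)

    def ancestors(self, code: str) -> tuple[str, ...]:
        """Proper ancestors of ``code``, nearest parent first."""
        cached = self._chain_cache.get(code)
        if cached is not None:
            return cached
        chain = []
        cur = self.parent.get(code)
        while cur is not None:
            chain.append(cur)
            cur = self.parent.get(cur)
        self._chain_cache[code] = tuple(chain)
        return self._chain_cache[code]

    def __contains__(self, code: str) -> bool:
        return code in self.parent or code in self.roots

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CodeHierarchy":
        missing = [c for c in HIERARCHY_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"hierarchy file missing column(s): {', '.join(missing)}")
        frame = frame.fillna({"parent": ""})
        dup = frame.loc[frame.duplicated("code", keep=False), "code"]
        if not dup.empty:
            bad = sorted(set(dup.astype(str)))[:5]
            raise ValidationError(
                "poly-hierarchy rejected: code(s) with more than one parent row: "
                + ", ".join(bad)
            )
        parent = dict(zip(frame["code"].astype(str), frame["parent"].astype(str)))
        system = dict(zip(frame["code"].astype(str), frame["system"].astype(str)))
        return cls(parent, system)


@dataclasses.dataclass
class EventLog:
    """Per-patient dated events with binary outcomes and index dates.

    ``events`` has columns ``patient_id, date, code, system, count`` with one
    row per distinct (patient, date, code); ``count`` is the multiset
    multiplicity of that code within the event. ``label_set`` is the ordered
    list of retained activity labels (codes); ``None`` means "all observed".
    """

    events: pd.DataFrame
    outcomes: pd.Series
    index_dates: pd.Series
    label_set: list[str] | None = None

    def __post_init__(self) -> None:
        unknown = set(self.events["patient_id"]) - set(self.outcomes.index)
        if unknown:
            ids = ", ".join(sorted(map(str, unknown))[:5])
            raise ValidationError(
                f"{len(unknown)} patient(s) in events but absent from outcomes: {ids}"
            )
        bad = set(self.outcomes.unique()) - {0, 1}
        if bad:
            raise ValidationError(f"outcome values outside {{0,1}}: {sorted(bad)}")

    @property
    def patients(self) -> list[str]:
        return list(self.outcomes.index)

    @property
    def labels(self) -> list[str]:
        """Effective ordered label set (sorted observed codes if not fixed)."""
        if self.label_set is not None:
            return list(self.label_set)
        return sorted(self.events["code"].unique())

    def label_systems(self) -> dict[str, str]:
        return dict(zip(self.events["code"], self.events["system"]))

    def n_events(self) -> int:
        return len(self.events.groupby(["patient_id", "date"]).size())

    def n_activities(self) -> int:
        return int(self.events["count"].sum())

    def subset(self, patients: Iterable[str]) -> "EventLog":
        patients = list(patients)
        keep = self.events["patient_id"].isin(patients)
        return EventLog(
            self.events.loc[keep].reset_index(drop=True),
            self.outcomes.loc[patients],
            self.index_dates.loc[patients],
            None if self.label_set is None else list(self.label_set),
        )


def _read_table(path, required: list[str]) -> pd.DataFrame:
    # sep=None sniffs comma/semicolon/tab; python engine required for sniffing
    frame = pd.read_csv(path, sep=None, engine="python", dtype=str, encoding="utf-8")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    return frame


def read_event_log(events_path, outcomes_path) -> EventLog:
    """Read delimited events + outcomes files into an :class:`EventLog`.

    Rows sharing (patient, date) form one event; a code repeated on the same
    date is kept as multiset multiplicity.
    """
    raw = _read_table(events_path, EVENT_COLUMNS)
    raw["date"] = pd.to_datetime(raw["date"])
    events = (
        raw.groupby(["patient_id", "date", "code", "system"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    out = _read_table(outcomes_path, OUTCOME_COLUMNS)
    try:
        outcome_vals = out["outcome"].astype(int)
    except ValueError as exc:
        raise FormatError(f"{outcomes_path}: non-integer outcome values") from exc
    outcomes = pd.Series(outcome_vals.values, index=out["patient_id"].values)
    index_dates = pd.Series(
        pd.to_datetime(out["index_date"]).values, index=out["patient_id"].values
    )
    if outcomes.index.duplicated().any():
        raise ValidationError(f"{outcomes_path}: duplicated patient_id rows")
    return EventLog(events, outcomes, index_dates)


def read_hierarchy(path) -> CodeHierarchy:
    """Read a child->parent hierarchy table (empty parent = root)."""
    return CodeHierarchy.from_frame(_read_table(path, HIERARCHY_COLUMNS))


def write_event_log(log: EventLog, events_path, outcomes_path) -> None:
    """Write the canonical long format back to CSV (multiplicity expanded)."""
    expanded = log.events.loc[log.events.index.repeat(log.events["count"])]
    expanded = expanded.drop(columns="count")
    expanded = expanded.assign(date=expanded["date"].dt.strftime("%Y-%m-%d"))
    expanded.to_csv(events_path, index=False)
    pd.DataFrame(
        {
            "patient_id": log.outcomes.index,
            "outcome": log.outcomes.values,
            "index_date": pd.to_datetime(log.index_dates.values).strftime("%Y-%m-%d"),
        }
    ).to_csv(outcomes_path, index=False)


def enrich_with_hierarchy(
    log: EventLog, hierarchy: CodeHierarchy, on_missing: str = "error"
) -> EventLog:
    """Add one occurrence of each ancestor per recorded code occurrence.

    Ancestor multiplicity within an event therefore equals the sum of the
    multiplicities of its recorded descendants in that event (plus its own
    recorded occurrences, if any). Original occurrences are preserved.

    Parameters
    ----------
    on_missing : ``"error"`` (default) raises if a code is absent from the
        hierarchy and not a declared root; ``"root"`` treats it as a root.
    """
    if on_missing not in ("error", "root"):
        raise ValueError("on_missing must be 'error' or 'root'")
    codes = log.events["code"].unique()
    missing = [c for c in codes if c not in hierarchy]
    if missing and on_missing == "error":
        raise ValidationError(
            "codes absent from hierarchy: " + ", ".join(sorted(missing)[:5])
        )
    frames = [log.events]
    systems = log.label_systems()
    for depth in range(1, MAX_DEPTH + 1):
        lifted = {c: hierarchy.ancestors(c)[depth - 1]
                  for c in codes if len(hierarchy.ancestors(c)) >= depth}
        if not lifted:
            break
        sub = log.events[log.events["code"].isin(lifted)].copy()
        sub["code"] = sub["code"].map(lifted)
        sub["system"] = sub["code"].map(
            lambda c: hierarchy.system.get(c, systems.get(c, "NA"))
        )
        frames.append(sub)
    merged = (
        pd.concat(frames, ignore_index=True)
        .groupby(["patient_id", "date", "code", "system"], sort=True)["count"]
        .sum()
        .reset_index()
    )
    return EventLog(merged, log.outcomes, log.index_dates, None)


def filter_infrequent(
    log: EventLog, min_occurrences: int
) -> tuple[EventLog, list[str]]:
    """Drop labels with total occurrence count below ``min_occurrences``.

    Counting is over occurrences (multiplicities), not distinct patients.
    Returns the filtered log and the retained labels in sorted order.
    """
    if min_occurrences < 0:
        raise ValueError("min_occurrences must be >= 0")
    totals = log.events.groupby("code")["count"].sum()
    retained = sorted(totals.index[totals >= min_occurrences])
    filtered = apply_label_set(log, retained)
    return filtered, retained


def apply_label_set(log: EventLog, labels: list[str]) -> EventLog:
    """Keep only activities whose label is in ``labels``; fix the label order."""
    if len(labels) == 0:
        raise ValueError("labels must be non-empty")
    if len(set(labels)) != len(labels):
        raise ValidationError("label_set contains duplicates")
    keep = log.events["code"].isin(set(labels))
    return EventLog(
        log.events.loc[keep].reset_index(drop=True),
        log.outcomes,
        log.index_dates,
        list(labels),
    )


def split_train_test(
    log: EventLog, test_fraction: float, seed: int
) -> tuple[EventLog, EventLog]:
    """Patient-level stratified split preserving the class ratio.

    Deterministic for a fixed seed; no patient appears in both halves.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    counts = log.outcomes.value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValidationError("each class needs at least 2 patients to stratify")
    patients = np.asarray(log.outcomes.index)
    train_ids, test_ids = train_test_split(
        patients,
        test_size=test_fraction,
        stratify=log.outcomes.values,
        random_state=seed,
    )
    return log.subset(sorted(train_ids)), log.subset(sorted(test_ids))
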