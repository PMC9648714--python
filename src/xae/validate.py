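"""Relative-risk validation of ranked predictive activities.

For each candidate activity, patients split into exposed (activity intensity
at or above the population mean, over either all-but-the-last windows or the
last window only) versus unexposed, and the relative risk of the outcome is
computed on the resulting 2x2 table with a 95% Katz log-normal confidence
interval. Activities whose CI excludes 1 with RR > 1 are retained as
validated risk factors.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .explain import RankedActivities
from .tensorize import MatrixDataset

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclasses.dataclass
class ExposureGrouping:
    """Binary exposure per patient, thresholded at the population mean."""

    label: str
    scope: str                       # "frequent" or "last-window"
    exposed: np.ndarray              # (n,) bool, aligned with patient_ids
    patient_ids: np.ndarray
    threshold: float


@dataclasses.dataclass
class RiskRecord:
    """2x2 outcome-by-exposure table with relative risk and 95% CI."""

    label: str
    scope: str
    a: int   # exposed, positive outcome
    b: int   # exposed, negative outcome
    c: int   # unexposed, positive outcome
    d: int   # unexposed, negative outcome
    rr: float
    ci_low: float
    ci_high: float
    significant: bool
    corrected: bool = False


def _intensity(dataset: MatrixDataset, label: str, scope: str) -> np.ndarray:
    try:
        i = dataset.row_labels.index(label)
    except ValueError:
        raise ValueError(f"activity {label!r} not in row_labels") from None
    if scope == "frequent":
        return dataset.values[:, i, :-1].sum(axis=1)
    if scope == "last-window":
        return dataset.values[:, i, -1]
    raise ValueError("scope must be 'frequent' or 'last-window'")


def exposure_frequent(dataset: MatrixDataset, label: str) -> ExposureGrouping:
    """Exposed iff the row sum over windows 1..w-1 reaches the population mean."""
    vals = _intensity(dataset, label, "frequent")
    thr = float(vals.mean())
    return ExposureGrouping(label, "frequent", vals >= thr, dataset.patient_ids, thr)


def exposure_last_window(dataset: MatrixDataset, label: str) -> ExposureGrouping:
    """Exposed iff the last-window value reaches the population mean."""
    vals = _intensity(dataset, label, "last-window")
    thr = float(vals.mean())
    return ExposureGrouping(label, "last-window", vals >= thr, dataset.patient_ids, thr)


def relative_risk(grouping: ExposureGrouping, outcomes: np.ndarray) -> RiskRecord:
    """RR of the outcome for exposed vs unexposed, Katz log-normal 95% CI.

    A zero cell triggers the +0.5 continuity correction on all four cells
    (flagged in the record). Both exposure groups must be non-empty.
    """
    outcomes = np.asarray(outcomes, dtype=int)
    exp_mask = np.asarray(grouping.exposed, dtype=bool)
    if exp_mask.all() or (~exp_mask).all():
        raise ValueError(f"empty exposure group for {grouping.label!r}: RR undefined")
    a = int(np.sum(exp_mask & (outcomes == 1)))
    b = int(np.sum(exp_mask & (outcomes == 0)))
    c = int(np.sum(~exp_mask & (outcomes == 1)))
    d = int(np.sum(~exp_mask & (outcomes == 0)))
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (
        (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if corrected else (a, b, c, d)
    )
    rr = (aa / (aa + bb)) / (cc / (cc + dd))
    se = math.sqrt(1.0 / aa - 1.0 / (aa + bb) + 1.0 / cc - 1.0 / (cc + dd))
    ci_low = rr * math.exp(-Z_95 * se)
    ci_high = rr * math.exp(Z_95 * se)
    return RiskRecord(
        grouping.label, grouping.scope, a, b, c, d,
        float(rr), float(ci_low), float(ci_high),
        significant=bool(ci_low > 1.0 or ci_high < 1.0),
        corrected=corrected,
    )


def risk_records(
    dataset: MatrixDataset, outcomes: np.ndarray, ranking: RankedActivities
) -> list[RiskRecord]:
    """One RiskRecord per ranked activity, scope-matched; degenerate ones skipped."""
    build = exposure_frequent if ranking.scope == "frequent" else exposure_last_window
    records = []
    for label in ranking.labels():
        try:
            records.append(relative_risk(build(dataset, label), outcomes))
        except ValueError:
            continue
    return records


def select_risk_factors(
    records: list[RiskRecord], k_final: int = 15
) -> list[RiskRecord]:
    """Significant records (CI excludes 1, RR > 1) ordered by RR, top k.

    May return fewer than ``k_final``.
    """
    kept = [r for r in records if r.significant and r.rr > 1.0]
    kept.sort(key=lambda r: (-r.rr, r.label))
    return kept[:k_final]


def records_frame(
    records: list[RiskRecord], systems: dict[str, str] | None = None
) -> pd.DataFrame:
    systems = systems or {}
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "system": systems.get(r.label, "NA"),
                "scope": r.scope,
                "a": r.a, "b": r.b, "c": r.c, "d": r.d,
                "rr": r.rr, "ci_low": r.ci_low, "ci_high": r.ci_high,
                "significant": r.significant, "corrected": r.corrected,
            }
            for r in records
        ]
    )


def forest_plot(records: list[RiskRecord], path, title: str = "Relative risks") -> None:
    """One row per factor, RR point + 95% CI whiskers on a log axis."""
    if not records:
        raise ValueError("no records to plot")
    fig, ax = plt.subplots(figsize=(6, max(2.0, 0.35 * len(records))))
    ys = np.arange(len(records))[::-1]
    for y, r in zip(ys, records):
        ax.plot([r.ci_low, r.ci_high], [y, y], color="black", lw=1)
        ax.plot([r.rr], [y], "s", color="tab:blue")
    ax.axvline(1.0, color="grey", ls="--", lw=1)
    ax.set_xscale("log")
    ax.set_yticks(ys)
    ax.set_yticklabels([f"{r.label} ({r.scope})" for r in records], fontsize=7)
    ax.set_xlabel("relative risk (95% CI)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
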