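"""Synthetic patient-pathway event logs with plantable class structure.

The generator emulates the structure of a claims extract: per-patient dated
events carrying hierarchical medical codes over a two-year pre-index window,
plus a binary outcome. Background activity is independent Bernoulli noise per
(patient, window, activity); a temporal motif — an ordered list of
(activity, window-offset) cells — is planted into a configurable fraction of
positive patients, giving ground truth for predictive-factor recovery. A
small fully worked single-patient example (four leaf codes under two
parents, nine daily windows) is also provided for end-to-end illustration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .eventlog import CodeHierarchy, EventLog
from .tensorize import WindowSpec

_SYSTEM_TAGS = ["DIAG", "PROC", "DEV", "BIO", "CONSULT"]

#: Default planted motif: activity index per step, at window offsets 6..1
#: (offset 1 = the last window before the index date).
DEFAULT_MOTIF = [(1, 6), (0, 5), (4, 4), (2, 3), (1, 2), (5, 1)]


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Defaults give a 2,000-patient cohort at 40% outcome prevalence (the
    realistic device-cohort ballpark), 20 background leaf activities under
    2 code systems of depth 2, 26 four-week windows over two years, a 6-step
    planted motif carried by 90% of positives, and 5% of negatives carrying
    the first half of the motif as confounding noise.
    """

    n_patients: int = 2000
    positive_fraction: float = 0.4
    l_background: int = 20
    n_systems: int = 2
    branching: int = 5
    depth: int = 2
    n_windows: int = 26
    window_days: int = 28
    background_rate: float = 0.05
    pattern: list[tuple[int, int]] = dataclasses.field(
        default_factory=lambda: list(DEFAULT_MOTIF)
    )
    pattern_penetrance: float = 0.9
    noise_in_negatives: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must be in (0, 1)")
        for _, off in self.pattern:
            if not 1 <= off <= self.n_windows:
                raise ValueError("pattern window offsets must lie in [1, n_windows]")
        for p in (self.background_rate, self.pattern_penetrance, self.noise_in_negatives):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def window_spec(self) -> WindowSpec:
        return WindowSpec(self.n_windows, float(self.window_days))


@dataclasses.dataclass
class GroundTruth:
    """What was planted: motif cells (code, 1-based window) and carriers."""

    planted_cells: list[tuple[str, int]]
    carriers: dict[str, bool]
    partial_carriers: dict[str, bool]
    motif_codes: list[str]

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(
                {
                    "planted_cells": [[c, int(w)] for c, w in self.planted_cells],
                    "carriers": self.carriers,
                    "partial_carriers": self.partial_carriers,
                    "motif_codes": self.motif_codes,
                },
                f, indent=2, sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as f:
            d = json.load(f)
        return cls(
            [(c, int(w)) for c, w in d["planted_cells"]],
            d["carriers"], d["partial_carriers"], d["motif_codes"],
        )


def generate_hierarchy(config: SimulationConfig) -> CodeHierarchy:
    """Deterministic code forest: one rooted tree per system.

    Codes are named ``TAG``, ``TAG.i``, ``TAG.i.j`` ... down to ``depth``
    levels below the root, with ``branching`` children per node.
    """
    if config.branching < 1 or config.depth < 1:
        raise ValueError("branching and depth must be >= 1")
    n_leaves = config.n_systems * config.branching ** config.depth
    if n_leaves < config.l_background:
        raise ValueError(
            f"hierarchy yields {n_leaves} leaves < l_background={config.l_background}"
        )
    parent: dict[str, str] = {}
    system: dict[str, str] = {}
    for s in range(config.n_systems):
        tag = _SYSTEM_TAGS[s % len(_SYSTEM_TAGS)]
        level = [tag]
        system[tag] = tag
        for _ in range(config.depth):
            nxt = []
            for node in level:
                for i in range(config.branching):
                    child = f"{node}.{i}"
                    parent[child] = node
                    system[child] = system[node]
                    nxt.append(child)
            level = nxt
    return CodeHierarchy(parent, system)


def hierarchy_frame(h: CodeHierarchy) -> pd.DataFrame:
    codes = sorted(set(h.parent) | h.roots)
    return pd.DataFrame(
        {
            "code": codes,
            "parent": [h.parent.get(c, "") for c in codes],
            "system": [h.system.get(c, "NA") for c in codes],
        }
    )


def _leaves(h: CodeHierarchy) -> list[str]:
    return sorted(set(h.parent) - set(h.parent.values()))


def _background_activities(h: CodeHierarchy, k: int) -> list[str]:
    """First k leaves taken round-robin across systems, keeping sort order."""
    by_system: dict[str, list[str]] = {}
    for leaf in _leaves(h):
        by_system.setdefault(h.system.get(leaf, "NA"), []).append(leaf)
    pools = [by_system[s] for s in sorted(by_system)]
    picked: list[str] = []
    i = 0
    while len(picked) < k:
        pool = pools[i % len(pools)]
        if pool:
            picked.append(pool.pop(0))
        i += 1
    return picked


def generate_event_log(config: SimulationConfig) -> tuple[EventLog, GroundTruth]:
    """Draw a synthetic event log and its ground truth.

    Background occurrences are independent Bernoulli per (patient, window,
    activity); motif cells add one occurrence each for carriers. Event dates
    sit on the most recent day of their window, so the tensorization windows
    recover the planted layout exactly. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    h = generate_hierarchy(config)
    activities = _background_activities(h, config.l_background)
    w, delta = config.n_windows, config.window_days
    n = config.n_patients
    patients = np.array([f"P{i:05d}" for i in range(n)])

    n_pos = int(round(n * config.positive_fraction))
    outcome = np.zeros(n, dtype=int)
    outcome[rng.choice(n, size=n_pos, replace=False)] = 1

    base = np.datetime64("2020-01-01")
    index_dates = base + rng.integers(0, 365, size=n).astype("timedelta64[D]")

    # background: (patient, activity, window) Bernoulli draws
    draws = rng.random((n, len(activities), w)) < config.background_rate
    pi, ai, wi = np.nonzero(draws)

    # carriers: exact planted fractions among each class
    pos_idx = np.flatnonzero(outcome == 1)
    neg_idx = np.flatnonzero(outcome == 0)
    carriers = rng.permutation(pos_idx)[: int(round(len(pos_idx) * config.pattern_penetrance))]
    partial = rng.permutation(neg_idx)[: int(round(len(neg_idx) * config.noise_in_negatives))]
    half = config.pattern[: max(1, len(config.pattern) // 2)]

    extra_p, extra_a, extra_w = [], [], []
    for carrier_set, cells in ((carriers, config.pattern), (partial, half)):
        for act_i, off in cells:
            extra_p.extend(carrier_set)
            extra_a.extend([act_i] * len(carrier_set))
            extra_w.extend([w - off] * len(carrier_set))  # 0-based window index
    pi = np.concatenate([pi, np.array(extra_p, dtype=int)])
    ai = np.concatenate([ai, np.array(extra_a, dtype=int)])
    wi = np.concatenate([wi, np.array(extra_w, dtype=int)])

    # most recent day of 0-based window k lies (w - 1 - k) * delta + 1 days back
    days_back = ((w - 1 - wi) * delta + 1).astype("timedelta64[D]")
    codes = np.array(activities)[ai]
    frame = pd.DataFrame(
        {
            "patient_id": patients[pi],
            "date": index_dates[pi] - days_back,
            "code": codes,
            "system": [h.system[c] for c in codes],
        }
    )
    events = (
        frame.groupby(["patient_id", "date", "code", "system"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    events["date"] = pd.to_datetime(events["date"])
    log = EventLog(
        events,
        pd.Series(outcome, index=patients),
        pd.Series(pd.to_datetime(index_dates), index=patients),
    )
    carrier_set, partial_set = set(carriers.tolist()), set(partial.tolist())
    truth = GroundTruth(
        planted_cells=[(activities[a], w - off + 1) for a, off in config.pattern],
        carriers={p: i in carrier_set for i, p in enumerate(patients)},
        partial_carriers={p: i in partial_set for i, p in enumerate(patients)},
        motif_codes=sorted({activities[a] for a, _ in config.pattern}),
    )
    return log, truth


# ----------------------------------------------------------------------
def worked_example() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Single-patient worked example: 4 leaf codes under 2 parents, 9 daily windows.

    One patient with six dated activities; after hierarchy enrichment the
    pathway matrix has 6 rows (A, A0, A1, B, B0, B1) and 9 daily columns,
    every cell binary.
    """
    index = pd.Timestamp("2020-01-10")
    # (days before index, leaf code); daily windows: days_before k -> window 10-k
    steps = [(9, "A0"), (8, "B0"), (6, "A1"), (4, "B1"), (3, "A0"), (1, "B0")]
    events = pd.DataFrame(
        {
            "patient_id": "P1",
            "date": [(index - pd.Timedelta(days=k)).strftime("%Y-%m-%d") for k, _ in steps],
            "code": [c for _, c in steps],
            "system": ["DIAG"] * len(steps),
        }
    )
    hierarchy = pd.DataFrame(
        {
            "code": ["A", "A0", "A1", "B", "B0", "B1"],
            "parent": ["", "A", "A", "", "B", "B"],
            "system": ["DIAG"] * 6,
        }
    )
    outcomes = pd.DataFrame(
        {"patient_id": ["P1"], "outcome": [1], "index_date": [index.strftime("%Y-%m-%d")]}
    )
    return events, hierarchy, outcomes


TOY_CONFIG = dataclasses.replace(SimulationConfig(), n_patients=200, seed=7)
BENCHMARK_CONFIG = SimulationConfig(seed=11)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_simulation(config: SimulationConfig, outdir) -> dict[str, str]:
    """Write events/hierarchy/outcomes CSVs + ground_truth.json; return checksums."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log, truth = generate_event_log(config)
    h = generate_hierarchy(config)
    expanded = log.events.loc[log.events.index.repeat(log.events["count"])]
    expanded = expanded.drop(columns="count").assign(
        date=lambda d: pd.to_datetime(d["date"]).dt.strftime("%Y-%m-%d")
    )
    expanded.to_csv(outdir / "events.csv", index=False)
    hierarchy_frame(h).to_csv(outdir / "hierarchy.csv", index=False)
    pd.DataFrame(
        {
            "patient_id": log.outcomes.index,
            "outcome": log.outcomes.values,
            "index_date": pd.to_datetime(log.index_dates.values).strftime("%Y-%m-%d"),
        }
    ).to_csv(outdir / "outcomes.csv", index=False)
    truth.to_json(outdir / "ground_truth.json")
    return {
        name: _sha256(outdir / name)
        for name in ["events.csv", "hierarchy.csv", "outcomes.csv", "ground_truth.json"]
    }


def generate_fixture_suite(outdir, seed: int = 0) -> dict:
    """Write the worked example, a 200-patient toy and the 2,000-patient benchmark.

    Returns the manifest (also written as ``manifest.json``) with per-file
    checksums; byte-identical across runs with the same seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "fixtures": {}}

    fig_dir = outdir / "worked_example"
    fig_dir.mkdir(exist_ok=True)
    events, hierarchy, outcomes = worked_example()
    events.to_csv(fig_dir / "events.csv", index=False)
    hierarchy.to_csv(fig_dir / "hierarchy.csv", index=False)
    outcomes.to_csv(fig_dir / "outcomes.csv", index=False)
    manifest["fixtures"]["worked_example"] = {
        name: _sha256(fig_dir / name)
        for name in ["events.csv", "hierarchy.csv", "outcomes.csv"]
    }

    toy = dataclasses.replace(TOY_CONFIG, seed=(TOY_CONFIG.seed + seed) % 2**31)
    bench = dataclasses.replace(
        BENCHMARK_CONFIG, seed=(BENCHMARK_CONFIG.seed + seed) % 2**31
    )
    manifest["fixtures"]["toy200"] = write_simulation(toy, outdir / "toy200")
    manifest["fixtures"]["benchmark2000"] = write_simulation(bench, outdir / "benchmark2000")
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return manifest
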