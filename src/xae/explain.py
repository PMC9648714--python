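"""Global explanation of autoencoder predictions.

The explanation element E is the cell-wise difference between the mean
decoding of positive patients and the mean decoding of negative patients.
Cells that the model decodes more strongly for positives stand out, giving a
global activities x time map of predictive factors. Activities are ranked
either by their E row sum over all but the last window ("frequent" scope) or
by their E value in the last window before the index date ("last-window"
scope), and a minimal masked rendering keeps only selected rows.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import h5py

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib import colors as mcolors


@dataclasses.dataclass
class ExplanationElement:
    """E = mean decoded positive - mean decoded negative, with provenance."""

    values: np.ndarray          # (l, w) in [-1, 1]
    row_labels: list[str]
    mean_negative: np.ndarray
    mean_positive: np.ndarray
    model_id: str = ""

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("E", data=self.values)
            f.create_dataset("mean_negative", data=self.mean_negative)
            f.create_dataset("mean_positive", data=self.mean_positive)
            f.create_dataset(
                "row_labels", data=np.array(self.row_labels, dtype=h5py.string_dtype())
            )
            f.attrs["model_id"] = self.model_id

    @classmethod
    def from_hdf5(cls, path) -> "ExplanationElement":
        with h5py.File(path, "r") as f:
            return cls(
                values=f["E"][...],
                row_labels=[s.decode() for s in f["row_labels"][...]],
                mean_negative=f["mean_negative"][...],
                mean_positive=f["mean_positive"][...],
                model_id=str(f.attrs.get("model_id", "")),
            )


@dataclasses.dataclass
class RankedActivities:
    """Activities ordered by a non-increasing aggregate E score."""

    entries: list[tuple[str, float]]       # (label, score), scores non-increasing
    scope: str                             # "frequent" or "last-window"

    def labels(self) -> list[str]:
        return [lab for lab, _ in self.entries]

    def to_frame(self, systems: dict[str, str] | None = None) -> pd.DataFrame:
        systems = systems or {}
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.entries) + 1),
                "label": [lab for lab, _ in self.entries],
                "system": [systems.get(lab, "NA") for lab, _ in self.entries],
                "score": [s for _, s in self.entries],
                "scope": self.scope,
            }
        )


def mean_element(model, X_c: np.ndarray) -> np.ndarray:
    """Cell-wise mean decoding g(f(x)) over a single-class dataset."""
    X_c = np.asarray(X_c, dtype=float)
    if X_c.shape[0] == 0:
        raise ValueError("empty class dataset")
    return model.reconstruct(X_c).mean(axis=0)


def explanation_element(
    model, negatives: np.ndarray, positives: np.ndarray,
    row_labels: list[str] | None = None, model_id: str = "",
) -> ExplanationElement:
    """Build E from the two class subsets (training split by convention)."""
    if np.asarray(negatives).shape[0] == 0 or np.asarray(positives).shape[0] == 0:
        raise ValueError("both classes must be non-empty")
    m0 = mean_element(model, negatives)
    m1 = mean_element(model, positives)
    labels = row_labels if row_labels is not None else [str(i) for i in range(m0.shape[0])]
    return ExplanationElement(m1 - m0, list(labels), m0, m1, model_id)


def _ranked(scores: np.ndarray, labels: list[str], k: int, scope: str) -> RankedActivities:
    if k < 1:
        raise ValueError("k must be >= 1")
    # sort by score descending, ties lexicographic by label
    order = sorted(range(len(labels)), key=lambda i: (-scores[i], labels[i]))
    top = order[: min(k, len(labels))]
    return RankedActivities([(labels[i], float(scores[i])) for i in top], scope)


def rank_frequent(element: ExplanationElement, k: int = 100) -> RankedActivities:
    """Top-k activities by E row sum over windows 1..w-1 (all but the last)."""
    if element.values.shape[1] < 2:
        raise ValueError("need at least 2 windows")
    return _ranked(
        element.values[:, :-1].sum(axis=1), element.row_labels, k, "frequent"
    )


def rank_last_window(element: ExplanationElement, k: int = 100) -> RankedActivities:
    """Top-k activities by E in the last window before the index date."""
    if element.values.shape[1] < 2:
        raise ValueError("need at least 2 windows")
    return _ranked(element.values[:, -1], element.row_labels, k, "last-window")


def minimal_representation(
    element: ExplanationElement, selected: list[str]
) -> np.ndarray:
    """E with every non-selected row zeroed."""
    unknown = set(selected) - set(element.row_labels)
    if unknown:
        raise ValueError(f"unknown label(s): {sorted(unknown)}")
    mask = np.array([lab in set(selected) for lab in element.row_labels])
    return element.values * mask[:, None]


_DEFAULT_PALETTE = {
    "DIAG": "tab:red", "COM": "tab:orange", "PROC": "tab:blue",
    "DEV": "tab:green", "BIO": "tab:purple", "CONSULT": "tab:brown",
}


def render_element(
    element: ExplanationElement, path, selected: list[str] | None = None,
    systems: dict[str, str] | None = None, palette: dict[str, str] | None = None,
    title: str = "Explanation element",
) -> None:
    """Render E (optionally masked to selected rows) as a PNG image.

    Grayscale encodes |E| magnitude; selected rows get a per-code-system
    colour tint. Rows are ordered by descending frequent-scope score,
    columns run oldest (left) to most recent (right).
    """
    systems = systems or {}
    palette = {**_DEFAULT_PALETTE, **(palette or {})}
    values = (
        minimal_representation(element, selected) if selected is not None
        else element.values
    )
    order = np.argsort(-values[:, :-1].sum(axis=1), kind="stable")
    values = values[order]
    labels = [element.row_labels[i] for i in order]
    vmax = max(float(np.abs(values).max()), 1e-12)
    rgb = np.ones(values.shape + (3,))
    for i, lab in enumerate(labels):
        colour = np.array(
            mcolors.to_rgb(palette.get(systems.get(lab, ""), "black"))
        )
        inten = np.clip(np.abs(values[i]) / vmax, 0, 1)[:, None]
        rgb[i] = 1.0 - inten * (1.0 - colour)
    height = max(2.0, 0.22 * len(labels))
    fig, ax = plt.subplots(figsize=(8, height))
    ax.imshow(rgb, aspect="auto", interpolation="nearest")
    ax.set_xlabel("time window (oldest → index date)")
    ax.set_yticks(range(len(labels)))
    ax.set_yticklabels(labels, fontsize=6)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
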