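"""Binary per-second movie content labels aligned to the TR grid.

A :class:`LabelTrack` assigns each 1-second movie bin ``b`` (covering
movie seconds ``[b, b+1)``, 0-based) a binary content label, e.g. drug
vs. non-drug.  Continuous per-bin features (loudness, brightness) are
turned into binary control tracks by a median split.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LabelTrack:
    """Binary labels over consecutive 1-second movie bins."""

    labels: np.ndarray
    label_name: str = "drug"

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int8)
        if labels.ndim != 1 or labels.size < 1:
            raise ValueError("labels must be a non-empty 1-D vector")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        object.__setattr__(self, "labels", labels)

    @property
    def n_bins(self) -> int:
        return int(self.labels.size)

    @property
    def fraction(self) -> float:
        """Fraction of bins carrying the label."""
        return float(self.labels.mean())

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"bin_start_second": np.arange(self.n_bins), "label": self.labels.astype(int)}
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, label_name: str = "drug") -> "LabelTrack":
        df = pd.read_csv(path, sep="\t")
        required = {"bin_start_second", "label"}
        if not required.issubset(df.columns):
            raise ValueError(f"label track {path} must have columns {sorted(required)}")
        df = df.sort_values("bin_start_second")
        expected = np.arange(len(df))
        if not np.array_equal(df["bin_start_second"].to_numpy(), expected):
            raise ValueError("bin_start_second must be consecutive integers from 0")
        return cls(labels=df["label"].to_numpy(), label_name=label_name)


def median_split_track(values: np.ndarray, label_name: str) -> LabelTrack:
    """Binarize a per-bin scalar feature by a median split over all bins.

    Bins strictly above the median are labeled 1 (high), the rest 0, so
    ties at the median fall into the low class.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 1:
        raise ValueError("feature track must be a non-empty 1-D vector")
    if not np.isfinite(values).all():
        raise ValueError("feature track contains non-finite values")
    labels = (values > np.median(values)).astype(np.int8)
    return LabelTrack(labels=labels, label_name=label_name)


def read_feature_track(path: str | Path) -> np.ndarray:
    """Read a per-bin scalar feature track (TSV: bin_start_second, value)."""
    df = pd.read_csv(path, sep="\t")
    if "value" not in df.columns:
        raise ValueError(f"feature track {path} must have a 'value' column")
    return df.sort_values("bin_start_second")["value"].to_numpy(dtype=float)


def write_feature_track(values: np.ndarray, path: str | Path) -> None:
    values = np.asarray(values, dtype=float)
    pd.DataFrame({"bin_start_second": np.arange(values.size), "value": values}).to_csv(
        path, sep="\t", index=False
    )
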