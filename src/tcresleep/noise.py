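"""Noisy-epoch characterisation across recording modalities.

A 5-s epoch is "noisy" when its maximum band power exceeds a
modality-specific threshold.  The conventional-EEG threshold is a fixed
amplitude criterion (400 μV² by default); the focal-modality equivalent
is derived by quantile matching: per modality, max powers are mapped
through ``log10(x + c)`` (c = 0.01 μV² guards against zeros), robust-scaled
by subtracting the median and dividing by the interquartile range, and the
conventional threshold's position in that standardised space is inverted
through the focal modality's scaler.  Because the transform is strictly
monotone, flagging in raw or scaled space is equivalent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "NoiseModel",
    "DegenerateScaleError",
    "fit_noise_model",
    "equivalent_threshold",
    "flag_noisy_epochs",
    "DEFAULT_OFFSET",
    "DEFAULT_EEG_THRESHOLD",
]

#: Small constant added before the log10 transform (μV²).
DEFAULT_OFFSET: float = 0.01

#: Conventional-EEG noisy-epoch criterion: maximum band power in a 5-s
#: epoch (μV²), a published amplitude cut-off for sleep EEG.
DEFAULT_EEG_THRESHOLD: float = 400.0


class DegenerateScaleError(ValueError):
    """Robust scaling is undefined: the transformed data have zero IQR."""


@dataclass
class NoiseModel:
    """Robust-scaler parameters of one modality's log-max-power distribution.

    ``scaled_threshold`` is the raw threshold's position in standardised
    space: ``(log10(raw_threshold + offset) - median) / iqr``.
    """

    modality: str
    offset_constant: float
    median: float
    iqr: float
    raw_threshold: float | None = None
    scaled_threshold: float | None = None

    def transform(self, x: np.ndarray | float) -> np.ndarray | float:
        """Raw μV² -> robust-scaled log space."""
        return (np.log10(np.asarray(x, dtype=float) + self.offset_constant)
                - self.median) / self.iqr

    def inverse_transform(self, z: np.ndarray | float) -> np.ndarray | float:
        """Robust-scaled log space -> raw μV²."""
        return 10.0 ** (np.asarray(z, dtype=float) * self.iqr + self.median) \
            - self.offset_constant

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "NoiseModel":
        return cls(**json.loads(Path(path).read_text()))


def fit_noise_model(max_powers: Iterable[float],
                    offset: float = DEFAULT_OFFSET,
                    raw_threshold: float | None = None,
                    modality: str = "EEG") -> NoiseModel:
    """Fit the log-offset robust scaler to one modality's epoch max powers.

    Median and IQR (Q3 − Q1, linear-interpolation quantiles, matching the
    reference robust-scaler implementation) are computed over
    ``log10(x + offset)``.  If ``raw_threshold`` is given, its standardised
    position is stored for cross-modality mapping.

    Raises
    ------
    DegenerateScaleError
        If the transformed values have zero IQR (constant data).
    ValueError
        On negative inputs, non-positive offset, or fewer than 4 values.
    """
    x = np.asarray(list(max_powers), dtype=float)
    if offset <= 0:
        raise ValueError("offset must be positive")
    if x.size < 4:
        raise ValueError("need at least 4 values to fit quartiles")
    if not np.all(np.isfinite(x)):
        raise ValueError("max powers must be finite")
    if np.any(x < 0):
        raise ValueError("negative power input")
    z = np.log10(x + offset)
    med = float(np.median(z))
    q1, q3 = np.percentile(z, [25.0, 75.0], method="linear")
    iqr = float(q3 - q1)
    if iqr <= 0.0:
        raise DegenerateScaleError("zero interquartile range (constant data)")
    model = NoiseModel(modality=modality, offset_constant=float(offset),
                       median=med, iqr=iqr)
    if raw_threshold is not None:
        if raw_threshold <= 0:
            raise ValueError("raw_threshold must be positive")
        model.raw_threshold = float(raw_threshold)
        model.scaled_threshold = float(
            (np.log10(raw_threshold + offset) - med) / iqr)
    return model


def equivalent_threshold(reference_model: NoiseModel,
                         target_model: NoiseModel) -> float:
    """Map the reference modality's raw threshold onto the target modality.

    The reference threshold's robust-scaled position ``z`` is inverted
    through the target scaler:
    ``10 ** (z * iqr_target + median_target) - offset_target``.
    Strictly increasing in the reference raw threshold; identical models
    return the reference threshold unchanged.
    """
    for m in (reference_model, target_model):
        if m.iqr is None or m.iqr <= 0:
            raise RuntimeError(f"model for {m.modality} is not fitted")
    if reference_model.raw_threshold is None:
        raise RuntimeError("reference model has no raw threshold")
    z = reference_model.scaled_threshold
    if z is None:
        z = (np.log10(reference_model.raw_threshold
                      + reference_model.offset_constant)
             - reference_model.median) / reference_model.iqr
    return float(target_model.inverse_transform(z))


def flag_noisy_epochs(records: pd.DataFrame, model: NoiseModel,
                      ) -> tuple[pd.Series, pd.DataFrame]:
    """Flag epochs whose max band power strictly exceeds the raw threshold.

    Parameters
    ----------
    records
        Band-power table with ``modality``, ``channel`` and ``max_power``
        columns, all rows of the model's modality.
    model
        Fitted model with ``raw_threshold`` set (directly or via
        :func:`equivalent_threshold`).

    Returns
    -------
    flags, summary
        A boolean Series aligned to ``records`` (True = noisy), and a
        per-channel summary (n_epochs, n_noisy, pct_noisy) with an
        ``ALL`` total row.
    """
    if model.raw_threshold is None:
        raise RuntimeError("model has no raw threshold to flag against")
    mods = set(records["modality"].unique())
    if mods != {model.modality}:
        raise ValueError(
            f"records modality {sorted(mods)} does not match model "
            f"{model.modality!r}")
    flags = records["max_power"] > model.raw_threshold
    grp = records.assign(noisy=flags).groupby("channel", sort=True)["noisy"]
    summary = pd.DataFrame({
        "channel": grp.size().index,
        "n_epochs": grp.size().to_numpy(),
        "n_noisy": grp.sum().to_numpy().astype(int),
    })
    total = pd.DataFrame({
        "channel": ["ALL"],
        "n_epochs": [len(records)],
        "n_noisy": [int(flags.sum())],
    })
    summary = pd.concat([summary, total], ignore_index=True)
    summary["pct_noisy"] = 100.0 * summary["n_noisy"] / summary["n_epochs"]
    return flags, summary
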