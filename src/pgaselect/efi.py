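"""Deficit-accumulation electronic frailty index (eFI).

The frailty index of a record is the proportion of assessed health deficits
that are present, ``fi = n_present / n_assessed``; a record is classed frail
when ``fi`` strictly exceeds a threshold (default 0.21).  Missing deficits
reduce the denominator, the standard convention for accumulation-of-deficits
indices; a record with too few assessed deficits is flagged uncomputable
rather than scored.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .data import FeatureTable

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.21


@dataclass(frozen=True)
class EFIConfig:
    """Deficit panel and classification rule for the eFI.

    Parameters
    ----------
    deficit_names:
        Ordered, unique names of the binary deficit features.
    threshold:
        Frailty cut-point; a record is frail iff ``fi > threshold`` (strict).
    min_assessed_fraction:
        Minimum fraction of the panel that must be non-missing for the
        index to be computable for a record.
    """

    deficit_names: tuple[str, ...]
    threshold: float = DEFAULT_THRESHOLD
    min_assessed_fraction: float = 0.8

    def __post_init__(self) -> None:
        names = tuple(self.deficit_names)
        object.__setattr__(self, "deficit_names", names)
        if not names:
            raise ValueError("deficit_names must be non-empty")
        if len(set(names)) != len(names):
            raise ValueError("deficit_names must be unique")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must lie in (0, 1), got {self.threshold}")
        if not 0.0 <= self.min_assessed_fraction <= 1.0:
            raise ValueError("min_assessed_fraction must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "deficit_names": list(self.deficit_names),
            "threshold": self.threshold,
            "min_assessed_fraction": self.min_assessed_fraction,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "EFIConfig":
        return cls(
            deficit_names=tuple(payload["deficit_names"]),
            threshold=float(payload.get("threshold", DEFAULT_THRESHOLD)),
            min_assessed_fraction=float(payload.get("min_assessed_fraction", 0.8)),
        )


@dataclass(frozen=True)
class EFIResult:
    """Index value for one record; ``fi`` is NaN when not computable."""

    fi: float
    n_present: int
    n_assessed: int
    frail: bool
    computable: bool


def _validate_binary(values: np.ndarray) -> None:
    observed = values[~np.isnan(values)]
    bad = observed[(observed != 0.0) & (observed != 1.0)]
    if bad.size:
        raise ValueError(f"deficit values must be binary 0/1, found {sorted(set(bad))}")


def compute_efi(record: Mapping[str, float] | pd.Series, config: EFIConfig) -> EFIResult:
    """Score a single record's deficit vector.

    ``record`` maps deficit name to 0 (absent), 1 (present), or NaN (not
    assessed).  The index is taken over assessed deficits only.
    """
    values = np.asarray([float(record[name]) for name in config.deficit_names])
    _validate_binary(values)
    assessed = ~np.isnan(values)
    n_assessed = int(assessed.sum())
    n_present = int(np.nansum(values))
    required = config.min_assessed_fraction * len(config.deficit_names)
    if n_assessed == 0 or n_assessed < required:
        return EFIResult(float("nan"), n_present, n_assessed, frail=False, computable=False)
    fi = n_present / n_assessed
    return EFIResult(fi, n_present, n_assessed, frail=fi > config.threshold, computable=True)


def efi_scores(values: pd.DataFrame, config: EFIConfig) -> pd.DataFrame:
    """Vectorised eFI over a record×feature frame.

    Returns a frame indexed like ``values`` with columns
    ``fi, n_present, n_assessed, frail, computable``.
    """
    missing = [n for n in config.deficit_names if n not in values.columns]
    if missing:
        raise KeyError(f"deficit feature(s) absent from table: {missing}")
    block = values[list(config.deficit_names)].to_numpy(dtype=float)
    _validate_binary(block)
    assessed = ~np.isnan(block)
    n_assessed = assessed.sum(axis=1)
    n_present = np.nansum(block, axis=1)
    required = config.min_assessed_fraction * len(config.deficit_names)
    computable = (n_assessed > 0) & (n_assessed >= required)
    with np.errstate(invalid="ignore", divide="ignore"):
        fi = np.where(computable, n_present / np.maximum(n_assessed, 1), np.nan)
    return pd.DataFrame(
        {
            "fi": fi,
            "n_present": n_present.astype(int),
            "n_assessed": n_assessed.astype(int),
            "frail": computable & (fi > config.threshold),
            "computable": computable,
        },
        index=values.index,
    )


def label_table(table: "FeatureTable", config: EFIConfig) -> "FeatureTable":
    """Attach the binary frailty label derived from the table's deficit columns.

    Records whose index is uncomputable (too many missing deficits) are
    dropped; the count is logged.
    """
    scores = efi_scores(table.values, config)
    keep = scores["computable"]
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("label_table: excluded %d uncomputable record(s)", n_dropped)
    values = table.values.loc[keep]
    label = scores.loc[keep, "frail"].astype(int)
    label.name = "frail"
    return dataclasses.replace(table, values=values, label=label)
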