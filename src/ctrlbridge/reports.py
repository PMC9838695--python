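"""Result containers: per-ROI input maps and bootstrap cost reports."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError, SchemaError

__all__ = ["InputMap", "CostReport"]


@dataclass(frozen=True)
class InputMap:
    """Per-ROI expected squared control input, split into mean and covariance parts.

    ``I_total = I_mean + I_cov`` holds elementwise by construction.
    """

    roi_names: tuple[str, ...]
    I_mean: np.ndarray
    I_cov: np.ndarray

    def __post_init__(self) -> None:
        Im = np.asarray(self.I_mean, dtype=float)
        Ic = np.asarray(self.I_cov, dtype=float)
        names = tuple(str(s) for s in self.roi_names)
        if Im.shape != (len(names),) or Ic.shape != (len(names),):
            raise SchemaError("input-map vectors must match the ROI name list")
        if (Im < -1e-12).any() or (Ic < -1e-12).any():
            raise InvalidArgumentError("input maps must be nonnegative")
        object.__setattr__(self, "roi_names", names)
        object.__setattr__(self, "I_mean", np.clip(Im, 0.0, None))
        object.__setattr__(self, "I_cov", np.clip(Ic, 0.0, None))

    @property
    def I_total(self) -> np.ndarray:
        return self.I_mean + self.I_cov

    @property
    def n(self) -> int:
        return len(self.roi_names)

    def normalized(self) -> "InputMap":
        """Divide both components by the summed total input (for cross-task averaging)."""
        s = float(self.I_total.sum())
        if s <= 0:
            raise InvalidArgumentError("cannot normalize an all-zero input map")
        return InputMap(self.roi_names, self.I_mean / s, self.I_cov / s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi": self.roi_names,
                "I_mean": self.I_mean,
                "I_cov": self.I_cov,
                "I_total": self.I_total,
            }
        )


@dataclass
class CostReport:
    """Bridge costs per task and bootstrap replicate.

    ``records`` rows: (task, replicate, J_mean, J_cov, J_total, ratio) with
    ratio = J_cov / J_mean computed within each replicate and only then
    averaged, so the summary statistic is the mean +/- SD of per-replicate
    ratios.
    """

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["task", "replicate", "J_mean", "J_cov", "J_total", "ratio"]
        )
    )

    def add(self, task: str, replicate: int, J_mean: float, J_cov: float) -> None:
        ratio = J_cov / J_mean if J_mean > 0 else np.inf
        row = pd.DataFrame(
            [
                {
                    "task": task,
                    "replicate": int(replicate),
                    "J_mean": float(J_mean),
                    "J_cov": float(J_cov),
                    "J_total": float(J_mean + J_cov),
                    "ratio": float(ratio),
                }
            ]
        )
        self.records = row if self.records.empty else pd.concat(
            [self.records, row], ignore_index=True
        )

    def summary(self) -> pd.DataFrame:
        """Mean +/- SD across replicates, per task."""
        g = self.records.groupby("task")[["J_mean", "J_cov", "J_total", "ratio"]]
        out = g.agg(["mean", "std"])
        out.columns = ["_".join(c) for c in out.columns]
        return out.reset_index()
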