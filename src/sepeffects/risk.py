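"""Counterfactual risk curves: the package's common result container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class RiskCurve:
    """Estimated cumulative incidence nu_k = Pr(Y_{k+1} = 1) for k = 0..K under
    an assignment (a_Y, a_D) of the two treatment components."""

    values: np.ndarray
    a_Y: int
    a_D: int
    method: str
    se: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def K(self) -> int:
        return len(self.values) - 1

    def __getitem__(self, k: int) -> float:
        return float(self.values[k])

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "method": self.method, "a_Y": self.a_Y, "a_D": self.a_D,
            "k": np.arange(len(self.values)), "estimate": self.values,
        })
        if self.se is not None:
            df["se"] = self.se
        if self.ci_low is not None:
            df["ci_low"] = self.ci_low
            df["ci_high"] = self.ci_high
        return df
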