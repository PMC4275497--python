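"""Survey sample containers.

A :class:`SurveySample` is a participant table (one row per person, with a
``weight`` column) plus provenance: whether it came from the probability
survey or from a quota-sampled web panel.  :class:`WeightedSample` is a
sample whose weights were set by poststratification (or raking) and records
the margins used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class SurveySample:
    data: pd.DataFrame
    provenance: str = "unknown"  # "probability" | "panel-quota" | ...
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if "weight" not in self.data.columns:
            self.data = self.data.copy()
            self.data["weight"] = 1.0

    def __len__(self) -> int:
        return len(self.data)

    @property
    def weights(self) -> np.ndarray:
        return self.data["weight"].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.data.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(
            {"provenance": self.provenance, "label": self.label,
             "n": len(self.data), **{k: v for k, v in self.meta.items()
                                     if isinstance(v, (str, int, float))}},
            indent=2))

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "unknown",
                 label: str = "") -> "SurveySample":
        path = Path(path)
        data = pd.read_csv(path)
        meta = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            provenance = meta.get("provenance", provenance)
            label = meta.get("label", label)
        return cls(data, provenance=provenance, label=label, meta=meta)


@dataclass
class WeightedSample(SurveySample):
    """A sample carrying poststratification weights (mean 1)."""

    margin_variables: tuple = ()

    def __post_init__(self):
        super().__post_init__()
        w = self.weights
        if (w <= 0).any():
            raise ValueError("weights must be strictly positive")
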