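"""External benchmark distributions (census / large-survey analogs).

A :class:`BenchmarkSet` maps a variable — or a cross of variables such as
age group within sex — to the population proportion of each category.
Crossed variables are keyed ``"sex*agegrp"`` with categories joined as
``"Male|18-24"``.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Mapping
from pathlib import Path

import yaml

VAR_SEP = "*"
CAT_SEP = "|"

_NORM_TOL = 1e-12


def cross_key(variables: Iterable[str]) -> str:
    """Canonical key for a (possibly crossed) variable grouping."""
    if isinstance(variables, str):
        return variables
    return VAR_SEP.join(variables)


def cross_label(categories: Iterable[str]) -> str:
    if isinstance(categories, str):
        return categories
    return CAT_SEP.join(str(c) for c in categories)


class BenchmarkSet(Mapping):
    """Variable -> category -> population proportion.

    Each per-variable distribution must sum to 1 (within 1e-12 after
    normalisation); proportions must lie in [0, 1].
    """

    def __init__(self, tables: Mapping[str, Mapping[str, float]]):
        clean: dict[str, dict[str, float]] = {}
        for var, dist in tables.items():
            if not dist:
                raise ValueError(f"benchmark for {var!r} has no categories")
            total = float(sum(dist.values()))
            if total <= 0:
                raise ValueError(f"benchmark for {var!r} sums to {total}")
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"benchmark for {var!r} sums to {total:.8f}, expected 1"
                )
            d = {str(k): float(v) / total for k, v in dist.items()}
            for k, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"benchmark {var!r}/{k!r} proportion {v}")
            clean[str(var)] = d
        self._tables = clean

    def __getitem__(self, key: str) -> dict[str, float]:
        return self._tables[cross_key(key)]

    def __iter__(self):
        return iter(self._tables)

    def __len__(self) -> int:
        return len(self._tables)

    def variables(self) -> list[str]:
        return list(self._tables)

    def proportion(self, variable, category) -> float:
        return self._tables[cross_key(variable)][cross_label(category)]

    # ---- serialisation -------------------------------------------------

    def to_dict(self) -> dict[str, dict[str, float]]:
        return {v: dict(d) for v, d in self._tables.items()}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "BenchmarkSet":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            return cls(yaml.safe_load(text))
        return cls(json.loads(text))

    def __repr__(self) -> str:  # pragma: no cover
        return f"BenchmarkSet({list(self._tables)})"
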