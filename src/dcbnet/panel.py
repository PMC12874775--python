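"""Long-format longitudinal panel container with a declarative variable schema.

A :class:`PanelDataset` holds household × wave records (unit id, community id,
wave label, categorical/ordinal outcome codes, optional weights) plus a
schema stating each variable's scale and orientation.  Orientation
harmonization (e.g. "higher = better" for food security, "higher = more
undernutrition" for child nutritional status) is applied once at load time
via :meth:`PanelDataset.harmonize`, never inside dependence computations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

UNIT, COMMUNITY, WAVE, WEIGHT = "unit", "community", "wave", "weight"


@dataclass(frozen=True)
class VariableSchema:
    name: str
    scale: str  # binary | ordinal | categorical | continuous
    levels: tuple = ()  # ordered category codes for discrete scales
    orientation: int = 1  # +1 as recorded, -1 flip so "higher" is harmonized

    def to_dict(self):
        return {
            "name": self.name,
            "scale": self.scale,
            "levels": list(self.levels),
            "orientation": self.orientation,
        }


@dataclass
class PanelDataset:
    """Long-format panel: one row per (unit, wave)."""

    df: pd.DataFrame
    schema: dict[str, VariableSchema]
    waves: list[str] = field(default_factory=list)

    def __post_init__(self):
        required = {UNIT, COMMUNITY, WAVE}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        if self.df.duplicated([UNIT, WAVE]).any():
            raise ValueError("duplicate (unit, wave) rows in panel")
        if not self.waves:
            self.waves = sorted(self.df[WAVE].unique())

    @property
    def variables(self) -> list[str]:
        return list(self.schema)

    def wave_frame(self, wave) -> pd.DataFrame:
        if wave not in set(self.df[WAVE]):
            raise KeyError(f"wave {wave!r} not present; have {self.waves}")
        return self.df[self.df[WAVE] == wave]

    def values(self, var: str, wave) -> pd.Series:
        return self.wave_frame(wave).set_index(UNIT)[var]

    def pairs(self, x: str, y: str, wave_x, wave_y):
        """Aligned complete-case (x, y, weight_or_None, units) for units
        observed in both waves."""
        sx = self.values(x, wave_x)
        sy = self.values(y, wave_y)
        joined = pd.concat([sx.rename("x"), sy.rename("y")], axis=1, join="inner")
        if WEIGHT in self.df.columns:
            w = self.wave_frame(wave_y).set_index(UNIT)[WEIGHT]
            joined = joined.join(w.rename("w"), how="inner")
        joined = joined.dropna()
        w = joined["w"].to_numpy() if "w" in joined else None
        return (joined["x"].to_numpy(), joined["y"].to_numpy(), w,
                joined.index.to_numpy())

    def harmonize(self) -> "PanelDataset":
        """Apply per-variable orientation flags by reversing ordinal codes."""
        df = self.df.copy()
        schema = {}
        for name, vs in self.schema.items():
            if vs.orientation == -1 and vs.scale != "continuous":
                levels = list(vs.levels)
                mapping = {lev: levels[len(levels) - 1 - i] for i, lev in enumerate(levels)}
                df[name] = df[name].map(lambda x: mapping.get(x, x))
                schema[name] = VariableSchema(name, vs.scale, tuple(levels), 1)
            else:
                schema[name] = vs
        return PanelDataset(df, schema, list(self.waves))

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path, header_comment: str | None = None) -> None:
        """CSV panel plus a JSON sidecar schema (<path>.schema.json)."""
        path = Path(path)
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.df.to_csv(fh, index=False)
        sidecar = {
            "waves": list(self.waves),
            "variables": [vs.to_dict() for vs in self.schema.values()],
        }
        Path(str(path) + ".schema.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path) -> "PanelDataset":
        path = Path(path)
        df = pd.read_csv(path, dtype={WAVE: str}, comment="#")
        sidecar = json.loads(Path(str(path) + ".schema.json").read_text())
        schema = {
            d["name"]: VariableSchema(
                d["name"], d["scale"], tuple(d["levels"]), d.get("orientation", 1)
            )
            for d in sidecar["variables"]
        }
        return cls(df, schema, [str(w) for w in sidecar["waves"]])
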