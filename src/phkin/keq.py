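"""pH-dependent equilibrium constants.

Reactions that produce or consume protons have equilibrium constants that
depend on pH.  Keq values are shipped as frozen per-reaction tables on a
pH grid (the package never queries a thermodynamics service at run time)
and interpolated log-linearly: standard transformed reaction energies are
near-linear in pH over narrow ranges, so log Keq is interpolated linearly
between knots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd


@dataclass
class KeqTable:
    """Tabulated Keq(pH) for one reaction, with log-linear interpolation."""

    reaction_id: str
    ph: np.ndarray
    keq: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.ph = np.asarray(self.ph, dtype=float)
        self.keq = np.asarray(self.keq, dtype=float)
        if len(self.ph) < 2:
            raise ValueError(f"{self.reaction_id}: need >= 2 (pH, Keq) points")
        if np.any(np.diff(self.ph) <= 0):
            raise ValueError(f"{self.reaction_id}: pH values must be strictly increasing")
        if np.any(self.keq <= 0):
            raise ValueError(f"{self.reaction_id}: Keq values must be > 0")

    def at_ph(self, ph: float) -> float:
        """Interpolated Keq; exact at knots; errors outside the table range."""
        if ph < self.ph[0] or ph > self.ph[-1]:
            raise ValueError(
                f"pH {ph} outside Keq table range [{self.ph[0]}, {self.ph[-1]}] "
                f"for reaction {self.reaction_id}"
            )
        return float(np.exp(np.interp(ph, self.ph, np.log(self.keq))))

    def fold_change(self, ph_lo: float, ph_hi: float, n_grid: int = 512) -> float:
        """max/min of the interpolated Keq over [ph_lo, ph_hi] (always >= 1)."""
        if ph_hi < ph_lo:
            ph_lo, ph_hi = ph_hi, ph_lo
        grid = np.linspace(ph_lo, ph_hi, n_grid)
        knots = self.ph[(self.ph >= ph_lo) & (self.ph <= ph_hi)]
        grid = np.union1d(grid, knots)
        values = np.exp(np.interp(grid, self.ph, np.log(self.keq)))
        return float(values.max() / values.min())


def keq_at_ph(table: KeqTable, ph: float) -> float:
    return table.at_ph(ph)


def fold_change(table: KeqTable, ph_lo: float, ph_hi: float) -> float:
    return table.fold_change(ph_lo, ph_hi)


def tables_from_frame(df: pd.DataFrame, source: str = "") -> dict[str, KeqTable]:
    """Build per-reaction tables from a tidy frame (reaction, ph, keq)."""
    out = {}
    for rxn, grp in df.groupby("reaction"):
        grp = grp.sort_values("ph")
        out[rxn] = KeqTable(str(rxn), grp["ph"].to_numpy(),
                            grp["keq"].to_numpy(), source=source)
    return out


def load_packaged_tables() -> dict[str, KeqTable]:
    """The frozen Keq(pH) fixture shipped with the package (pH 6.0-8.0)."""
    ref = resources.files("phkin.data") / "keq_ph.csv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return tables_from_frame(df, source="packaged synthetic fixture")
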