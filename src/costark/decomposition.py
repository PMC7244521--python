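"""Extracting electrostatic QM/MM interaction energies from energy tables.

A QM calculation of the probe embedded in the environment point charges
yields E_total; the same calculation in gas phase at the identical geometry
yields E_self.  Their difference E_EI = E_total − E_self is the
electrostatic interaction energy between the probe and its surroundings —
the quantity every downstream fit consumes.  E_EI is always recomputed from
the two inputs, never trusted from a file.

Also here: optional ordinary-least-squares removal of the linear
bond-length component from an energy or charge series (the bond-length
fluctuation of the probe weakly couples into both).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class EnergyRecord:
    """Per-frame, per-method energy bookkeeping (kcal/mol)."""

    frame_index: int
    method_label: str
    e_total: float
    e_self: float

    def __post_init__(self):
        if not (np.isfinite(self.e_total) and np.isfinite(self.e_self)):
            raise ValueError(
                f"non-finite energy for frame {self.frame_index} "
                f"({self.method_label}): data-file fault"
            )

    @property
    def e_ei(self) -> float:
        return self.e_total - self.e_self


@dataclass(frozen=True)
class DetrendedSeries:
    """Result of removing the linear bond-length component from a series."""

    frame_index: np.ndarray
    values: np.ndarray          # residuals, mean-preserving
    regressor: np.ndarray       # the bond lengths used
    detrend_slope: float        # fitted linear coefficient, units of values per Å


def interaction_energy(e_total, e_self):
    """E_EI = E_total − E_self (kcal/mol); scalar or elementwise on arrays."""
    e_total = np.asarray(e_total, dtype=float)
    e_self = np.asarray(e_self, dtype=float)
    if not (np.all(np.isfinite(e_total)) and np.all(np.isfinite(e_self))):
        raise ValueError("non-finite energy input: data-file fault")
    out = e_total - e_self
    return float(out) if out.ndim == 0 else out


def add_interaction_energy(table: pd.DataFrame) -> pd.DataFrame:
    """Append an E_EI column to an energy table with E_total/E_self columns."""
    required = {"frame", "method", "E_total", "E_self"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"energy table missing columns: {sorted(missing)}")
    out = table.copy()
    out["E_EI"] = interaction_energy(
        out["E_total"].to_numpy(), out["E_self"].to_numpy()
    )
    return out


def detrend_on_bond_length(
    values,
    bond_lengths,
    frame_index=None,
) -> DetrendedSeries:
    """Remove the linear bond-length component from a series by OLS.

    Regresses `values` on the centered bond length and returns the
    residuals plus the fitted mean, so the series mean is preserved and the
    residuals are exactly uncorrelated with the regressor.  The fitted
    slope (units of `values` per Å) is reported for logging.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(bond_lengths, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("values and bond_lengths must be 1-D of equal length")
    if len(y) < 3:
        raise ValueError("need at least 3 samples to detrend")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise ValueError("degenerate regressor: bond_length has zero variance")
    slope = float(xc @ (y - y.mean())) / sxx
    residuals = y - slope * xc
    if frame_index is None:
        frame_index = np.arange(len(y))
    return DetrendedSeries(
        frame_index=np.asarray(frame_index),
        values=residuals,
        regressor=x,
        detrend_slope=slope,
    )
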