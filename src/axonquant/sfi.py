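"""Sciatic functional index (SFI) from walking-track print measurements.

The SFI is the standard behavioural measure of hind-limb function after
sciatic nerve injury in the rat.  Three consecutive ink prints of the
injured (experimental) side are measured for print length (PL), toe spread
between digits 1 and 5 (TS) and intermediary toe spread between digits 2
and 4 (IT), each compared with the non-injured (normal) side, and combined
with the Bain-Mackinnon-Hunter coefficients:

    SFI = -38.3 * (EPL - NPL)/NPL + 109.5 * (ETS - NTS)/NTS
          + 13.3 * (EIT - NIT)/NIT - 8.8

A value near 0 indicates normal function and -100 complete transection.
Note the formula's constant term: identical experimental and normal prints
give exactly -8.8, not 0; the raw formula value is reported and no
re-zeroing is applied unless the caller supplies an explicit offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("axonquant")

#: (print-length, toe-spread, intermediary-toe-spread, constant) coefficients.
BAIN_COEFFICIENTS = (-38.3, 109.5, 13.3, -8.8)


@dataclass
class TrackMeasurements:
    """Walking-track prints for one timepoint (>= 3 consecutive prints)."""
    epl_mm: np.ndarray      # experimental print length, per print
    ets_mm: np.ndarray      # experimental toe spread (digits 1-5)
    eit_mm: np.ndarray      # experimental intermediary toe spread (digits 2-4)
    npl_mm: float           # matched normal-side values
    nts_mm: float
    nit_mm: float
    timepoint_weeks: float = 0.0

    def __post_init__(self) -> None:
        self.epl_mm = np.atleast_1d(np.asarray(self.epl_mm, float))
        self.ets_mm = np.atleast_1d(np.asarray(self.ets_mm, float))
        self.eit_mm = np.atleast_1d(np.asarray(self.eit_mm, float))
        n = len(self.epl_mm)
        if not (len(self.ets_mm) == len(self.eit_mm) == n):
            raise ValueError("print measurement arrays must have equal length")
        for name in ("epl_mm", "ets_mm", "eit_mm"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name}: all print lengths must be positive")
        for name in ("npl_mm", "nts_mm", "nit_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive (division by the normal side)")

    @property
    def n_prints(self) -> int:
        return len(self.epl_mm)


@dataclass
class SFIResult:
    """Per-print SFI values and their mean for one timepoint."""
    timepoint_weeks: float
    sfi_per_print: np.ndarray
    mean_sfi: float
    factors: pd.DataFrame    # per print: print-length / toe-spread / intermediary factors
    n_prints: int


def compute_sfi(m: TrackMeasurements,
                coefficients: tuple[float, float, float, float] = BAIN_COEFFICIENTS
                ) -> SFIResult:
    """Evaluate the SFI formula per print; the timepoint value is the mean.

    Fewer than three prints is tolerated with a warning (the protocol
    measures three clear consecutive prints).
    """
    if m.n_prints < 3:
        log.warning("only %d print(s) at week %s; SFI computed anyway",
                    m.n_prints, m.timepoint_weeks)
    c_pl, c_ts, c_it, c0 = coefficients
    plf = (m.epl_mm - m.npl_mm) / m.npl_mm
    tsf = (m.ets_mm - m.nts_mm) / m.nts_mm
    itf = (m.eit_mm - m.nit_mm) / m.nit_mm
    sfi = c_pl * plf + c_ts * tsf + c_it * itf + c0
    factors = pd.DataFrame({
        "print_length_factor": plf,
        "toe_spread_factor": tsf,
        "intermediary_factor": itf,
        "sfi": sfi,
    })
    return SFIResult(
        timepoint_weeks=m.timepoint_weeks,
        sfi_per_print=sfi,
        mean_sfi=float(sfi.mean()),
        factors=factors,
        n_prints=m.n_prints,
    )


def sfi_time_course(results: list[SFIResult],
                    baseline_week: float | None = None) -> pd.DataFrame:
    """Tabulate SFI over post-operative weeks with percent recovery.

    Percent recovery anchors complete transection (-100) at zero function:
    ``100 * (SFI + 100) / (SFI_baseline + 100)``.  When no baseline row is
    available the column is omitted with a warning.
    """
    rows = [
        dict(week=r.timepoint_weeks, mean_sfi=r.mean_sfi, n_prints=r.n_prints)
        for r in results
    ]
    table = pd.DataFrame(rows).sort_values("week", ignore_index=True)
    if baseline_week is None and len(table):
        baseline_week = float(table["week"].iloc[0]) if 0.0 not in table["week"].values else 0.0
    base = table.loc[table["week"] == baseline_week, "mean_sfi"]
    if base.empty:
        log.warning("no baseline week %s in the series; percent-recovery column omitted",
                    baseline_week)
        return table
    base_sfi = float(base.iloc[0])
    table["percent_recovery"] = 100.0 * (table["mean_sfi"] + 100.0) / (base_sfi + 100.0)
    return table
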