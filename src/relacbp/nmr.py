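"""Chemical-shift-based helicity and het-NOE flexibility classification.

Secondary chemical-shift deviations (CSDs: observed minus sequence-corrected
random-coil shifts) of Cα and C′ scale linearly with fractional helical
population; a fully formed α-helix gives 2.8 ppm (Cα) and 2.1 ppm (C′).  The
helical population of a segment is estimated by averaging the CSDs over its
residues, dividing by the full-helix reference per nucleus, and averaging the
two per-nucleus estimates.  [¹H]-¹⁵N heteronuclear NOEs classify backbone
dynamics: ≤ 0 dynamically disordered, intermediate flexible (the ~0.3–0.5
range typical of a fraying terminal helix), high rigid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: full-helix secondary chemical shifts (ppm)
FULL_HELIX_CSD_CA = 2.8
FULL_HELIX_CSD_CO = 2.1


@dataclass(frozen=True)
class ReferenceShifts:
    ca_ppm: float = FULL_HELIX_CSD_CA
    co_ppm: float = FULL_HELIX_CSD_CO

    def __post_init__(self) -> None:
        if self.ca_ppm <= 0 or self.co_ppm <= 0:
            raise ValueError("reference CSDs must be > 0")


@dataclass(frozen=True)
class HelicityEstimate:
    """Fractional helical population with clamping bookkeeping."""
    population: float            # clamped to [0, 1]
    raw: float                   # unclamped linear estimate
    clamped: bool
    window: tuple[int, int]
    n_residues: int
    partial_nuclei: tuple[int, ...] = ()   # residues with only one nucleus

    @property
    def percent(self) -> float:
        return 100.0 * self.population


def load_shift_table(path: str | Path) -> pd.DataFrame:
    """Read ``residue_index, residue_name, csd_ca_ppm, csd_co_ppm`` text."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df["residue_index"].duplicated().any():
        raise ValueError("duplicate residue indices")
    return df.sort_values("residue_index").reset_index(drop=True)


def helix_population(table: pd.DataFrame, window: tuple[int, int],
                     refs: ReferenceShifts = ReferenceShifts()) -> HelicityEstimate:
    """Helical population of the residues in ``window`` (inclusive bounds).

    Per nucleus, the CSDs are averaged over the window and divided by the
    full-helix reference; the Cα and C′ estimates are then averaged.  Residues
    missing one nucleus (NaN) contribute to the other's mean only and are
    flagged.  The estimate is clamped to [0, 1] (negative CSDs indicate
    extended propensity, not negative helicity).
    """
    lo, hi = window
    if hi < lo:
        raise ValueError("window bounds out of order")
    sub = table[(table["residue_index"] >= lo) & (table["residue_index"] <= hi)]
    if sub.empty:
        raise ValueError(f"window {window} not covered by the shift table")
    ca = sub["csd_ca_ppm"].to_numpy(dtype=float)
    co = sub["csd_co_ppm"].to_numpy(dtype=float)
    partial = tuple(int(i) for i, a, c in
                    zip(sub["residue_index"], ca, co)
                    if np.isnan(a) != np.isnan(c))
    estimates = []
    for vals, ref in ((ca, refs.ca_ppm), (co, refs.co_ppm)):
        ok = ~np.isnan(vals)
        if ok.any():
            estimates.append(float(np.mean(vals[ok])) / ref)
    if not estimates:
        raise ValueError("no usable CSDs in window")
    raw = float(np.mean(estimates))
    pop = min(max(raw, 0.0), 1.0)
    return HelicityEstimate(population=pop, raw=raw, clamped=(pop != raw),
                            window=(lo, hi), n_residues=len(sub),
                            partial_nuclei=partial)


#: default het-NOE class boundaries: disordered ≤ 0 < flexible < 0.6 ≤ rigid
DEFAULT_NOE_THRESHOLDS = (0.0, 0.6)


def classify_dynamics(noes: pd.DataFrame,
                      thresholds: tuple[float, float] = DEFAULT_NOE_THRESHOLDS
                      ) -> pd.DataFrame:
    """Per-residue backbone dynamics class from heteronuclear NOE values.

    ``noes`` needs columns ``residue_index`` and ``noe``.  Classes:
    ``disordered`` (NOE ≤ t1), ``flexible`` (t1 < NOE < t2), ``rigid``
    (NOE ≥ t2); default thresholds (0, 0.6).
    """
    t1, t2 = thresholds
    if not t1 < t2:
        raise ValueError("thresholds must satisfy t1 < t2")
    if noes["residue_index"].duplicated().any():
        raise ValueError("duplicate residue indices")
    v = noes["noe"].to_numpy(dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("NOE values must be finite")
    cls = np.where(v <= t1, "disordered", np.where(v < t2, "flexible", "rigid"))
    out = noes[["residue_index"]].copy()
    out["noe"] = v
    out["dynamics_class"] = cls
    return out
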