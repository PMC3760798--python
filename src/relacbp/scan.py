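"""Simulation experiments and model–data agreement scoring.

Two scans are defined over the feedback module: an NF-κB (RelA) abundance scan
(expression levels 2×, 1.5×, 1×, 0.5×, 0.2× of wild type) and a suppression
scan of the NF-κB-dependent IκBα mRNA production rate k_mRNA (100%, 25%,
12.5%, 6.25%).  Model and experimental curves are compared on a common
normalized scale — nuclear NF-κB by the activation convention (resting level
→ 0, peak → 1), total IκBα by the depletion convention (resting level → 1,
post-stimulus minimum → 0) — and agreement is scored by a single RMSD pooled
over the points of both observables.  The scan member with the lowest combined
RMSD is selected as the best-fitting scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ikk import IKKCurve
from .ode import Trajectory, simulate
from .params import ModelParameters

NFKB_SCALES = (2.0, 1.5, 1.0, 0.5, 0.2)
KMRNA_SCALES = (1.0, 0.25, 0.125, 0.0625)

OBSERVABLES = ("nuclear_nfkb", "total_ikba")
#: normalization convention per observable
CONVENTIONS = {"nuclear_nfkb": "activation", "total_ikba": "depletion"}


def normalize_activation(values: Sequence[float]) -> np.ndarray:
    """Activation convention: (x − x(0)) / (max x − x(0)).

    The value at the earliest time is the resting baseline (maps to 0); the
    peak maps to 1.  A flat series is degenerate and rejected.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    span = x.max() - x[0]
    if span <= 0:
        raise ValueError("degenerate activation series: no rise above baseline")
    return (x - x[0]) / span


def normalize_depletion(values: Sequence[float]) -> np.ndarray:
    """Depletion convention: (x − min x) / (x(0) − min x).

    The resting (t = 0) level maps to 1, the post-stimulus minimum to 0.
    Overshoot above the resting level is allowed (values > 1).  A series whose
    minimum is at t = 0 shows no depletion and is rejected.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    span = x[0] - x.min()
    if span <= 0:
        raise ValueError("degenerate depletion series: no drop below resting level")
    return (x - x.min()) / span


@dataclass(frozen=True)
class TimeCourseData:
    """One normalized experimental time course of a single observable."""
    observable: str              # 'nuclear_nfkb' | 'total_ikba'
    times: np.ndarray            # minutes, strictly increasing
    values: np.ndarray           # normalized units

    def __post_init__(self) -> None:
        if self.observable not in OBSERVABLES:
            raise ValueError(f"unknown observable {self.observable!r}")
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size == 0 or t.size != v.size:
            raise ValueError("times/values must be non-empty and equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("normalized values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def convention(self) -> str:
        return CONVENTIONS[self.observable]


def load_timecourse_data(path) -> list[TimeCourseData]:
    """Read ``observable<TAB>time_min<TAB>value_normalized`` delimited text."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for obs, g in df.groupby("observable", sort=False):
        g = g.sort_values("time_min")
        out.append(TimeCourseData(observable=str(obs),
                                  times=g["time_min"].to_numpy(),
                                  values=g["value_normalized"].to_numpy()))
    return out


def save_timecourse_data(data: Iterable[TimeCourseData], path) -> None:
    rows = [(d.observable, t, v) for d in data for t, v in zip(d.times, d.values)]
    pd.DataFrame(rows, columns=["observable", "time_min", "value_normalized"]) \
        .to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ScanResult:
    """Trajectories from one scan, keyed by scale value."""
    trajectories: Mapping[float, Trajectory]
    kind: str                                   # 'nfkb_scale' | 'kmrna_scale'

    def __post_init__(self) -> None:
        if self.kind not in ("nfkb_scale", "kmrna_scale"):
            raise ValueError(f"unknown scan kind {self.kind!r}")
        if any(s <= 0 for s in self.trajectories):
            raise ValueError("scale values must be positive")

    @property
    def scales(self) -> tuple[float, ...]:
        return tuple(self.trajectories)


def scan_total_nfkb(params: ModelParameters, curve: IKKCurve,
                    scales: Sequence[float] = NFKB_SCALES,
                    t_end: float = 360.0, dt_out: float = 1.0) -> ScanResult:
    """Abundance scan: one independently equilibrated trajectory per scale."""
    trajs = {}
    for s in scales:
        try:
            trajs[float(s)] = simulate(params.with_scales(nfkb_scale=s), curve,
                                       t_end=t_end, dt_out=dt_out)
        except Exception as exc:
            raise RuntimeError(f"abundance scan failed at scale {s}") from exc
    return ScanResult(trajectories=trajs, kind="nfkb_scale")


def scan_kmrna(params: ModelParameters, curve: IKKCurve,
               scales: Sequence[float] = KMRNA_SCALES,
               t_end: float = 360.0, dt_out: float = 1.0) -> ScanResult:
    """k_mRNA suppression scan over the IκBα induced-production term only."""
    trajs = {}
    for s in scales:
        if not (0 < s <= 1):
            raise ValueError(f"kmrna scale {s} outside (0, 1]")
        try:
            trajs[float(s)] = simulate(params.with_scales(kmrna_scale=s), curve,
                                       t_end=t_end, dt_out=dt_out)
        except Exception as exc:
            raise RuntimeError(f"k_mRNA scan failed at scale {s}") from exc
    return ScanResult(trajectories=trajs, kind="kmrna_scale")


def _normalized_model_series(traj: Trajectory, observable: str) -> np.ndarray:
    series = getattr(traj, observable)
    if CONVENTIONS[observable] == "activation":
        return normalize_activation(series)
    return normalize_depletion(series)


def combined_rmsd(trajectory: Trajectory, data: Iterable[TimeCourseData]) -> float:
    """RMSD between normalized model curves and data, pooled over all points.

    The model observables are normalized with the same conventions as the data
    (baseline at stimulation onset), linearly interpolated at the data times,
    and all squared residuals from both observables are pooled with equal
    weight per point before taking the root mean.
    """
    sq, n = 0.0, 0
    for d in data:
        if d.times.min() < trajectory.times[0] or d.times.max() > trajectory.times[-1]:
            raise ValueError(f"data times for {d.observable} outside trajectory span")
        model = _normalized_model_series(trajectory, d.observable)
        at_data = np.interp(d.times, trajectory.times, model)
        sq += float(np.sum((at_data - d.values) ** 2))
        n += d.times.size
    if n == 0:
        raise ValueError("no data points")
    return float(np.sqrt(sq / n))


@dataclass(frozen=True)
class FitResult:
    """Per-scale combined RMSD and the selected best scale."""
    rmsd: Mapping[float, float]
    best_scale: float
    tie: bool = False
    kind: str = "kmrna_scale"

    def __post_init__(self) -> None:
        if abs(min(self.rmsd.values()) - self.rmsd[self.best_scale]) > 1e-12:
            raise ValueError("best_scale does not attain the minimum RMSD")


def select_best_scale(scan: ScanResult, data: Iterable[TimeCourseData]) -> FitResult:
    """Score every scan member by combined RMSD and return the argmin.

    Ties (identical RMSD to within 1e-12) are broken toward the larger scale —
    the conservative, less-suppressed attribution — and flagged.
    """
    data = list(data)
    if not scan.trajectories:
        raise ValueError("empty scan")
    rmsd = {s: combined_rmsd(traj, data) for s, traj in scan.trajectories.items()}
    best = min(rmsd)
    tie = False
    lo = min(rmsd.values())
    candidates = [s for s, r in rmsd.items() if abs(r - lo) <= 1e-12]
    best = max(candidates)
    tie = len(candidates) > 1
    return FitResult(rmsd=rmsd, best_scale=best, tie=tie, kind=scan.kind)


class ScaleSelectionModel:
    """Discrete-scan model–data fit for the feedback module.

    Wraps the scan + combined-RMSD selection in a model object: the exogenous
    design is the parameter set, IKK input and scale grid; the endogenous data
    are normalized experimental time courses of the two observables.

    Parameters
    ----------
    data : iterable of TimeCourseData
        Normalized nuclear NF-κB and/or total IκBα time courses.
    params, curve :
        Module parameters (adaptation applied) and IKK input.
    kind : str
        'kmrna_scale' (default) or 'nfkb_scale'.
    scales : sequence of float
        Scan grid; defaults to the grid the scan kind defines.
    """

    def __init__(self, data: Iterable[TimeCourseData], params: ModelParameters,
                 curve: IKKCurve, kind: str = "kmrna_scale",
                 scales: Sequence[float] | None = None,
                 t_end: float | None = None, dt_out: float = 1.0):
        self.data = list(data)
        if not self.data:
            raise ValueError("no data series")
        self.params = params
        self.curve = curve
        self.kind = kind
        if scales is None:
            scales = KMRNA_SCALES if kind == "kmrna_scale" else NFKB_SCALES
        self.scales = tuple(float(s) for s in scales)
        if t_end is None:
            t_end = max(d.times.max() for d in self.data)
        self.t_end = float(t_end)
        self.dt_out = float(dt_out)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, params: ModelParameters,
                       curve: IKKCurve, **kwargs) -> "ScaleSelectionModel":
        """Build from a long table with observable/time_min/value_normalized."""
        data = []
        for obs, g in frame.groupby("observable", sort=False):
            g = g.sort_values("time_min")
            data.append(TimeCourseData(observable=str(obs),
                                       times=g["time_min"].to_numpy(),
                                       values=g["value_normalized"].to_numpy()))
        return cls(data, params, curve, **kwargs)

    def run_scan(self) -> ScanResult:
        fn = scan_kmrna if self.kind == "kmrna_scale" else scan_total_nfkb
        return fn(self.params, self.curve, self.scales,
                  t_end=self.t_end, dt_out=self.dt_out)

    def fit(self, scan: ScanResult | None = None) -> "ScaleSelectionResults":
        if scan is None:
            scan = self.run_scan()
        fr = select_best_scale(scan, self.data)
        return ScaleSelectionResults(model=self, scan=scan, fitres=fr)


@dataclass
class ScaleSelectionResults:
    """Results of a :class:`ScaleSelectionModel` fit."""
    model: ScaleSelectionModel
    scan: ScanResult
    fitres: FitResult

    @property
    def best_scale(self) -> float:
        return self.fitres.best_scale

    @property
    def rmsd(self) -> dict[float, float]:
        return dict(self.fitres.rmsd)

    @property
    def best_trajectory(self) -> Trajectory:
        return self.scan.trajectories[self.best_scale]

    def summary(self) -> str:
        lines = [f"Scale selection ({self.fitres.kind}) by combined RMSD",
                 f"{'scale':>10}  {'rmsd':>10}"]
        for s in sorted(self.rmsd, reverse=True):
            mark = "  <- best" if s == self.best_scale else ""
            lines.append(f"{s:>10g}  {self.rmsd[s]:>10.4f}{mark}")
        if self.fitres.tie:
            lines.append("note: RMSD tie broken toward the larger scale")
        n = sum(d.times.size for d in self.model.data)
        lines.append(f"n data points: {n} (pooled over "
                     f"{len(self.model.data)} observable series)")
        return "\n".join(lines)

    def to_report(self) -> dict:
        return {"kind": self.fitres.kind,
                "rmsd": {str(k): v for k, v in self.rmsd.items()},
                "best_scale": self.best_scale,
                "tie": self.fitres.tie}

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        traj = self.best_trajectory
        for d in self.model.data:
            ax.plot(d.times, d.values, "o", label=f"data: {d.observable}")
            ax.plot(traj.times, _normalized_model_series(traj, d.observable),
                    "-", label=f"model ({self.best_scale:g}×): {d.observable}")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("normalized level")
        ax.legend()
        return ax
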