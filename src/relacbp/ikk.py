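"""Numerically defined IKK activity input.

IKK kinase activity after TNFα exposure is not modelled mechanistically; it is
an input curve given as (time, activity-fraction) points.  Evaluation is by
linear interpolation, returning the basal (pre-stimulus) level before the first
point and holding the last tabulated value afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class IKKCurve:
    times: np.ndarray      # minutes, strictly increasing
    activities: np.ndarray # fraction of maximal IKK activity, >= 0
    basal: float           # pre-stimulus activity

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.activities, dtype=float)
        if t.size == 0:
            raise ValueError("IKK curve needs at least one point")
        if t.size != a.size:
            raise ValueError("times and activities must have equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("IKK curve times must be strictly increasing")
        if np.any(a < 0) or self.basal < 0:
            raise ValueError("IKK activities must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "activities", a)

    def __call__(self, t):
        return ikk_activity(self, t)

    def constant(self, level: float | None = None) -> "IKKCurve":
        """A flat curve at ``level`` (defaults to this curve's basal)."""
        lv = self.basal if level is None else float(level)
        return IKKCurve(times=np.array([0.0]), activities=np.array([lv]), basal=lv)


def ikk_activity(curve: IKKCurve, t):
    """Evaluate IKK activity at time(s) ``t`` (minutes).

    Linear interpolation between tabulated points; ``basal`` before the first
    point; the final value is held beyond the last point.
    """
    t = np.asarray(t, dtype=float)
    out = np.interp(t, curve.times, curve.activities,
                    left=curve.basal, right=curve.activities[-1])
    return float(out) if out.ndim == 0 else out


def load_ikk_curve(path: str | Path) -> IKKCurve:
    """Read a two-column ``time_min<TAB>ikk_activity`` file.

    The basal level is taken from a ``# basal=<value>`` header comment and
    defaults to the first tabulated activity.
    """
    basal = None
    times, acts = [], []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "basal=" in line:
                basal = float(line.split("basal=")[1].strip())
            continue
        if line.lower().startswith("time"):
            continue
        a, b = line.split("\t") if "\t" in line else line.split()
        times.append(float(a))
        acts.append(float(b))
    if not times:
        raise ValueError(f"no IKK points found in {path}")
    if basal is None:
        basal = acts[0]
    return IKKCurve(times=np.array(times), activities=np.array(acts), basal=basal)


def save_ikk_curve(curve: IKKCurve, path: str | Path) -> None:
    lines = [f"# basal={float(curve.basal)!r}", "time_min\tikk_activity"]
    lines += [f"{float(t)!r}\t{float(a)!r}"
              for t, a in zip(curve.times, curve.activities)]
    Path(path).write_text("\n".join(lines) + "\n")


def default_tnf_curve() -> IKKCurve:
    """Shipped TNFα-induced IKK activity profile (reconstruction)."""
    with resources.as_file(resources.files("relacbp.data") / "ikk_tnf.tsv") as p:
        return load_ikk_curve(p)
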