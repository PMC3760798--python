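"""Seeded synthetic-data generators for every analysis stage.

Each generator emulates the statistical structure of one measurement type so
the full pipeline is testable without external data:

* densitometry-style normalized time courses sampled from the feedback model
  (additive Gaussian noise on the normalized scale),
* one-site ITC isotherms (multiplicative, instrument-like Gaussian noise),
* gene-expression fold-induction tables with planted Group A–D structure
  (log-normal replicate noise, i.e. Gaussian in log2),
* secondary-chemical-shift tables with a planted fractional helicity
  (additive Gaussian noise in ppm).

Every generator takes an integer seed and is bit-for-bit reproducible for a
fixed seed and package version.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ikk import IKKCurve
from .itc import ITCParams, ITCSchedule, predict_heats
from .nmr import ReferenceShifts
from .ode import Trajectory, simulate
from .params import ModelParameters
from .scan import (TimeCourseData, normalize_activation, normalize_depletion)

#: planted group sizes matching the published classification (99 genes total)
DEFAULT_GROUP_SIZES = {"A": 20, "B": 25, "C": 6, "D": 48}

DEFAULT_SAMPLE_TIMES = (0.0, 10.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Default study conditions for the generators."""
    seed: int = 0
    timecourse_sigma: float = 0.05     # normalized units
    itc_rel_sigma: float = 0.02        # relative
    csd_sigma_ppm: float = 0.05
    expression_sigma_log2: float = 0.25
    true_kmrna_scale: float = 0.0625
    true_nfkb_scale: float = 1.0
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    helicity: float = 0.32
    helicity_window: tuple[int, int] = (434, 439)


def gen_timecourse(params: ModelParameters, curve: IKKCurve, true_scale: float,
                   times: Sequence[float] = DEFAULT_SAMPLE_TIMES,
                   sigma: float = 0.05, seed: int = 0,
                   kind: str = "kmrna_scale",
                   trajectory: Trajectory | None = None) -> list[TimeCourseData]:
    """Noisy normalized time courses of both observables at a true scale.

    Simulates the module at ``true_scale`` (of the given scan ``kind``),
    normalizes nuclear NF-κB by the activation convention and total IκBα by
    the depletion convention, samples at ``times`` and adds independent
    Gaussian noise of SD ``sigma`` on the normalized scale.  A precomputed
    ``trajectory`` (already at the true scale) can be supplied to avoid
    re-integration across noise replicates.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    times = np.asarray(times, dtype=float)
    if trajectory is None:
        kw = {"kmrna_scale": true_scale} if kind == "kmrna_scale" \
            else {"nfkb_scale": true_scale}
        trajectory = simulate(params.with_scales(**kw), curve,
                              t_end=float(times.max()), dt_out=1.0)
    if times.max() > trajectory.times[-1] or times.min() < trajectory.times[0]:
        raise ValueError("sample times outside the simulated span")
    rng = np.random.default_rng(seed)
    out = []
    for observable, series, norm in (
            ("nuclear_nfkb", trajectory.nuclear_nfkb, normalize_activation),
            ("total_ikba", trajectory.total_ikba, normalize_depletion)):
        clean = np.interp(times, trajectory.times, norm(series))
        noisy = clean + rng.normal(0.0, sigma, size=times.size) if sigma > 0 else clean
        out.append(TimeCourseData(observable=observable, times=times, values=noisy))
    return out


def gen_itc(params: ITCParams, schedule: ITCSchedule,
            rel_sigma: float = 0.02, seed: int = 0) -> np.ndarray:
    """Per-injection heats with multiplicative Gaussian noise.

    heat_i = predicted_i · (1 + ε_i), ε_i ~ N(0, rel_sigma²) — instrument-like
    noise proportional to the signal.
    """
    if rel_sigma < 0:
        raise ValueError("rel_sigma must be >= 0")
    clean = predict_heats(params, schedule)
    if rel_sigma == 0:
        return clean
    rng = np.random.default_rng(seed)
    return clean * (1.0 + rng.normal(0.0, rel_sigma, size=clean.size))


def gen_expression(group_sizes: Mapping[str, int] | None = None,
                   effect_log2: float = 2.5, replicates: int = 3,
                   sigma_log2: float = 0.25, seed: int = 0,
                   base_log2_range: tuple[float, float] = (1.3, 4.5),
                   time: float = 60.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fold-induction table with planted Group A–D structure.

    Each planted gene gets a wild-type log2 fold induction drawn uniformly
    from ``base_log2_range`` (all at or above the 2-fold activation threshold);
    mutant means are attenuated by ``effect_log2`` according to group
    membership (A: both mutants, B: TA2 only, C: S276A only, D: neither).
    Replicate values carry independent Gaussian noise of SD ``sigma_log2`` in
    log2, i.e. log-normal noise on the fold scale.  Empty-vector rows and
    t = 0 calibrator rows (fold 1, noise only) are included for realism.

    Returns the long-format table and a gene → true-group truth frame.
    """
    sizes = dict(DEFAULT_GROUP_SIZES if group_sizes is None else group_sizes)
    if any(v < 0 for v in sizes.values()):
        raise ValueError("group sizes must be >= 0")
    if replicates < 2:
        raise ValueError("need >= 2 replicates for confidence calls")
    rng = np.random.default_rng(seed)
    attenuated = {"A": ("TA2", "S276A"), "B": ("TA2",), "C": ("S276A",), "D": ()}

    rows, truth = [], []
    for group in ("A", "B", "C", "D"):
        for i in range(sizes.get(group, 0)):
            gene = f"gene_{group}{i:03d}"
            truth.append({"gene": gene, "true_group": group})
            mu_wt = rng.uniform(*base_log2_range)
            for genotype in ("wt", "TA2", "S276A", "vector"):
                if genotype == "vector":
                    mu = 0.0
                else:
                    mu = mu_wt - (effect_log2 if genotype in attenuated[group] else 0.0)
                for rep in range(1, replicates + 1):
                    noise0 = rng.normal(0.0, sigma_log2)
                    noise_t = rng.normal(0.0, sigma_log2)
                    rows.append({"gene": gene, "genotype": genotype,
                                 "time_min": 0.0, "replicate": rep,
                                 "fold_induction": 2.0 ** noise0})
                    rows.append({"gene": gene, "genotype": genotype,
                                 "time_min": time, "replicate": rep,
                                 "fold_induction": 2.0 ** (mu + noise_t)})
    return pd.DataFrame(rows), pd.DataFrame(truth)


def gen_csd_table(helicity: float, window: tuple[int, int] = (434, 439),
                  sigma_ppm: float = 0.05, seed: int = 0,
                  refs: ReferenceShifts = ReferenceShifts()) -> pd.DataFrame:
    """Secondary-chemical-shift table with a planted helical population.

    Per-residue Cα and C′ CSDs are drawn around ``helicity`` times the
    full-helix reference values with Gaussian noise ``sigma_ppm``.
    """
    if not 0.0 <= helicity <= 1.0:
        raise ValueError("helicity must lie in [0, 1]")
    if sigma_ppm < 0:
        raise ValueError("sigma_ppm must be >= 0")
    lo, hi = window
    if hi < lo:
        raise ValueError("window bounds out of order")
    rng = np.random.default_rng(seed)
    idx = np.arange(lo, hi + 1)
    return pd.DataFrame({
        "residue_index": idx,
        "residue_name": ["X"] * idx.size,
        "csd_ca_ppm": helicity * refs.ca_ppm + rng.normal(0, sigma_ppm, idx.size),
        "csd_co_ppm": helicity * refs.co_ppm + rng.normal(0, sigma_ppm, idx.size),
    })
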