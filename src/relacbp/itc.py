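"""One-site ITC binding thermodynamics.

Implements the standard single-binding-site isotherm for a titration of
ligand (syringe) into macromolecule (cell): the bound fraction follows the
closed-form quadratic solution in the running total concentrations, per-
injection heats are differences of cumulative heats with the usual perfusion
(displaced-volume) correction, and parameters (stoichiometry n, dissociation
constant Kd, binding enthalpy ΔH) are recovered by nonlinear least squares.

Thermodynamic linkage: ΔG = RT·ln(Kd/1 M), TΔS = ΔH − ΔG.  Units follow
calorimetric convention — Kd in nM, ΔH/TΔS/ΔG in kcal/mol, temperature in K,
heats in µcal, volumes in mL (cell) and µL (injections), concentrations in µM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

R_KCAL = 1.9872e-3   # gas constant, kcal/(mol·K)
T_STANDARD = 298.15  # K (25 °C, the temperature of every tabulated record)


def delta_g(kd_nm: float, temperature: float = T_STANDARD) -> float:
    """Binding free energy ΔG = RT·ln(Kd / 1 M) in kcal/mol (Kd given in nM)."""
    if kd_nm <= 0:
        raise ValueError("kd must be > 0")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    return R_KCAL * temperature * np.log(kd_nm * 1e-9)


def tds_from(kd_nm: float, dh_kcal: float, temperature: float = T_STANDARD) -> float:
    """Entropic term TΔS = ΔH − ΔG (kcal/mol)."""
    return dh_kcal - delta_g(kd_nm, temperature)


def fold_change(kd_num: float, kd_den: float,
                rounding: str = "nearest-integer") -> float:
    """Affinity fold change as the ratio of two dissociation constants.

    ``rounding``: 'nearest-integer' (e.g. the 4-fold salt effect), 'one-decimal'
    (e.g. the 1.6-fold N-terminal truncation effect), or 'none'.
    """
    if kd_den == 0:
        raise ValueError("zero denominator Kd")
    if kd_num <= 0 or kd_den <= 0:
        raise ValueError("Kd values must be positive")
    ratio = kd_num / kd_den
    if rounding == "nearest-integer":
        return float(round(ratio))
    if rounding == "one-decimal":
        return float(round(ratio, 1))
    if rounding == "none":
        return float(ratio)
    raise ValueError(f"unknown rounding {rounding!r}")


@dataclass(frozen=True)
class BindingRecord:
    """One tabulated construct: Kd, ΔH and TΔS with uncertainties."""
    label: str
    salt_mm: float
    kd_nm: float
    kd_err: float
    dh_kcal: float
    dh_err: float
    tds_kcal: float
    tds_err: float
    temperature: float = T_STANDARD

    def __post_init__(self) -> None:
        if self.kd_nm <= 0:
            raise ValueError("kd must be > 0")
        if self.kd_err < 0 or self.dh_err < 0 or self.tds_err < 0:
            raise ValueError("uncertainties must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    def tds_residual(self) -> float:
        """|TΔS from linkage − tabulated TΔS| (kcal/mol)."""
        return abs(tds_from(self.kd_nm, self.dh_kcal, self.temperature)
                   - self.tds_kcal)


def load_binding_table(path: str | Path | None = None) -> list[BindingRecord]:
    """Read a delimited binding table; defaults to the packaged fixture.

    The fixture transcribes the published summary of dissociation constants and
    thermodynamic parameters for RelA–TA2 constructs binding CBP–TAZ1 (rows
    with no measurable binding are not tabulated).
    """
    if path is None:
        with resources.as_file(resources.files("relacbp.data") / "binding_table.tsv") as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    required = {"label", "salt_mM", "kd_nM", "kd_err", "dh_kcal", "dh_err",
                "tds_kcal", "tds_err"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"binding table missing columns {sorted(missing)}")
    return [BindingRecord(label=r.label, salt_mm=r.salt_mM, kd_nm=r.kd_nM,
                          kd_err=r.kd_err, dh_kcal=r.dh_kcal, dh_err=r.dh_err,
                          tds_kcal=r.tds_kcal, tds_err=r.tds_err)
            for r in df.itertuples()]


def check_table_consistency(records: Iterable[BindingRecord],
                            tolerance: float = 0.1) -> pd.DataFrame:
    """Thermodynamic-linkage consistency of a binding table.

    For every record, recomputes TΔS = ΔH − RT·ln(Kd) and compares with the
    tabulated value.  Returns a frame with per-record residuals and pass flags;
    an empty input passes vacuously (with a warning attribute on the frame).
    """
    rows = []
    for rec in records:
        res = rec.tds_residual()
        rows.append({"label": rec.label, "salt_mM": rec.salt_mm,
                     "kd_nM": rec.kd_nm, "dh_kcal": rec.dh_kcal,
                     "tds_tabulated": rec.tds_kcal,
                     "tds_computed": tds_from(rec.kd_nm, rec.dh_kcal, rec.temperature),
                     "residual": res, "passed": res <= tolerance})
    df = pd.DataFrame(rows, columns=["label", "salt_mM", "kd_nM", "dh_kcal",
                                     "tds_tabulated", "tds_computed",
                                     "residual", "passed"])
    df.attrs["tolerance"] = tolerance
    df.attrs["all_passed"] = bool(df["passed"].all()) if len(df) else True
    if not len(df):
        df.attrs["warning"] = "empty record set: vacuous pass"
    return df


# ---------------------------------------------------------------------------
# forward model and fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ITCSchedule:
    """Instrument schedule: cell volume/concentrations and injection volumes."""
    cell_volume_ml: float
    cell_conc_um: float      # macromolecule (binder) in the cell
    syringe_conc_um: float   # titrant
    injection_volumes_ul: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.injection_volumes_ul, dtype=float)
        if v.size < 2:
            raise ValueError("need at least 2 injections")
        if np.any(v <= 0):
            raise ValueError("injection volumes must be positive")
        for name in ("cell_volume_ml", "cell_conc_um", "syringe_conc_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        object.__setattr__(self, "injection_volumes_ul", v)

    @property
    def n_injections(self) -> int:
        return int(self.injection_volumes_ul.size)


def default_schedule(cell_conc_um: float = 15.0, syringe_conc_um: float = 175.0,
                     cell_volume_ml: float = 1.4) -> ITCSchedule:
    """The titration schedule used throughout: 25 injections, a small 6 µL
    first injection followed by 24 injections of 12 µL, with cell and syringe
    concentrations in the experimental ranges (10–18 µM binder in the cell,
    169–185 µM titrant)."""
    vols = np.concatenate([[6.0], np.full(24, 12.0)])
    return ITCSchedule(cell_volume_ml=cell_volume_ml, cell_conc_um=cell_conc_um,
                       syringe_conc_um=syringe_conc_um, injection_volumes_ul=vols)


@dataclass(frozen=True)
class ITCParams:
    """One-site model parameters."""
    n: float        # stoichiometry (sites per macromolecule)
    kd_nm: float    # dissociation constant
    dh_kcal: float  # binding enthalpy
    n_err: float = np.nan
    kd_err: float = np.nan
    dh_err: float = np.nan

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("stoichiometry must be > 0")
        if self.kd_nm <= 0:
            raise ValueError("kd must be > 0")


def _running_concentrations(schedule: ITCSchedule):
    """Total macromolecule and titrant concentrations in the cell after each
    injection, with the standard perfusion (displaced volume) correction."""
    v0 = schedule.cell_volume_ml * 1e3  # µL
    vcum = np.cumsum(schedule.injection_volumes_ul)
    dil = vcum / (2.0 * v0)
    mt = schedule.cell_conc_um * (1.0 - dil) / (1.0 + dil)
    xt = schedule.syringe_conc_um * (vcum / v0) / (1.0 + dil)
    return mt, xt


def _cumulative_heat(n: float, kd_um: float, dh_kcal: float,
                     schedule: ITCSchedule) -> np.ndarray:
    """Cumulative heat content of the cell after each injection (µcal).

    Bound-ligand concentration is the closed-form root of the one-site
    quadratic  [MX] = ((A − sqrt(A² − 4·Mt·n·Xt)) / 2  with
    A = n·Mt + Xt + Kd.
    """
    mt, xt = _running_concentrations(schedule)
    a = n * mt + xt + kd_um
    bound = 0.5 * (a - np.sqrt(a * a - 4.0 * n * mt * xt))
    # µM · mL · kcal/mol = µcal
    return bound * schedule.cell_volume_ml * dh_kcal


def predict_heats(params: ITCParams, schedule: ITCSchedule) -> np.ndarray:
    """Per-injection heats (µcal) for a one-site titration.

    The i-th observed heat is the increment of the cell's cumulative heat,
    corrected for the heat content carried out with the displaced volume:
    ΔQ_i = Q_i − Q_{i−1} + (dV_i/V0)·(Q_i + Q_{i−1})/2.
    """
    q = _cumulative_heat(params.n, params.kd_nm * 1e-3, params.dh_kcal, schedule)
    qprev = np.concatenate([[0.0], q[:-1]])
    dv = schedule.injection_volumes_ul / (schedule.cell_volume_ml * 1e3)
    return q - qprev + dv * (q + qprev) / 2.0


class OneSiteBindingModel:
    """One-site ITC model for observed per-injection heats.

    statsmodels-style usage::

        model = OneSiteBindingModel(heats, schedule)
        res = model.fit()
        print(res.summary())
        res.params.kd_nm, res.bse

    Parameters
    ----------
    heats : sequence of float
        Observed per-injection heats (µcal), one per scheduled injection.
    schedule : ITCSchedule
    exclude_first : bool
        Drop the first (small, diffusion-corrupted) injection from the fit.
        Default True, the universal calorimetric practice.
    """

    def __init__(self, heats: Sequence[float], schedule: ITCSchedule,
                 exclude_first: bool = True):
        self.heats = np.asarray(heats, dtype=float)
        if self.heats.size != schedule.n_injections:
            raise ValueError("one heat per scheduled injection required")
        self.schedule = schedule
        self.exclude_first = exclude_first
        self._mask = np.ones(self.heats.size, dtype=bool)
        if exclude_first:
            self._mask[0] = False
        if self._mask.sum() < 5:
            raise ValueError("need at least 5 informative injections")

    def fit(self, start: ITCParams | None = None) -> "OneSiteBindingResults":
        import lmfit

        y = self.heats[self._mask]
        if np.allclose(y, y[0], atol=1e-12) or np.allclose(y, 0.0, atol=1e-12):
            raise ValueError("degenerate (flat) heats: isotherm carries no "
                             "binding information")
        if start is None:
            # crude initialisation: total heat ~ n·M0·V0·ΔH, mid-range Kd
            total = float(self.heats.sum())
            dh0 = total / (self.schedule.cell_conc_um * self.schedule.cell_volume_ml)
            start = ITCParams(n=1.0, kd_nm=100.0, dh_kcal=dh0 if dh0 != 0 else -5.0)

        pars = lmfit.Parameters()
        pars.add("n", value=start.n, min=1e-3)
        pars.add("log10_kd_nm", value=np.log10(start.kd_nm), min=-3.0, max=9.0)
        pars.add("dh_kcal", value=start.dh_kcal)

        def resid(p):
            model = predict_heats(
                ITCParams(n=p["n"].value, kd_nm=10.0 ** p["log10_kd_nm"].value,
                          dh_kcal=p["dh_kcal"].value), self.schedule)
            return model[self._mask] - y

        out = lmfit.minimize(resid, pars, method="leastsq")
        if not out.success:
            raise RuntimeError(f"one-site fit failed to converge "
                               f"(final residual {np.sum(out.residual**2):.3g})")
        kd = 10.0 ** out.params["log10_kd_nm"].value
        kd_err = np.nan
        if out.params["log10_kd_nm"].stderr is not None:
            kd_err = kd * np.log(10.0) * out.params["log10_kd_nm"].stderr
        fitted = ITCParams(
            n=out.params["n"].value, kd_nm=kd, dh_kcal=out.params["dh_kcal"].value,
            n_err=out.params["n"].stderr if out.params["n"].stderr is not None else np.nan,
            kd_err=kd_err,
            dh_err=out.params["dh_kcal"].stderr
            if out.params["dh_kcal"].stderr is not None else np.nan)
        return OneSiteBindingResults(model=self, params=fitted, minimizer_result=out)


@dataclass
class OneSiteBindingResults:
    """Fit results: parameters, asymptotic standard errors, diagnostics."""
    model: OneSiteBindingModel
    params: ITCParams
    minimizer_result: object

    @property
    def bse(self) -> dict[str, float]:
        return {"n": self.params.n_err, "kd_nm": self.params.kd_err,
                "dh_kcal": self.params.dh_err}

    @property
    def fittedvalues(self) -> np.ndarray:
        return predict_heats(self.params, self.model.schedule)

    @property
    def resid(self) -> np.ndarray:
        return self.model.heats - self.fittedvalues

    @property
    def c_parameter(self) -> float:
        """Wiseman c = n·[cell]/Kd (dimensionless isotherm-shape parameter)."""
        return self.params.n * self.model.schedule.cell_conc_um / (self.params.kd_nm * 1e-3)

    def thermodynamics(self, temperature: float = T_STANDARD) -> dict[str, float]:
        dg = delta_g(self.params.kd_nm, temperature)
        return {"dg_kcal": dg, "dh_kcal": self.params.dh_kcal,
                "tds_kcal": self.params.dh_kcal - dg}

    def summary(self) -> str:
        t = self.thermodynamics()
        lines = ["One-site ITC binding fit",
                 f"  n        = {self.params.n:8.3f} ± {self.params.n_err:.3f}",
                 f"  Kd (nM)  = {self.params.kd_nm:8.1f} ± {self.params.kd_err:.1f}",
                 f"  ΔH (kcal/mol) = {self.params.dh_kcal:6.2f} ± {self.params.dh_err:.2f}",
                 f"  ΔG (kcal/mol) = {t['dg_kcal']:6.2f}",
                 f"  TΔS (kcal/mol) = {t['tds_kcal']:6.2f}",
                 f"  Wiseman c = {self.c_parameter:.1f}",
                 f"  injections used = {int(self.model._mask.sum())}"
                 f" / {self.model.schedule.n_injections}"]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        idx = np.arange(1, self.model.heats.size + 1)
        ax.plot(idx, self.model.heats, "o", label="observed")
        ax.plot(idx, self.fittedvalues, "-", label="one-site fit")
        ax.set_xlabel("injection")
        ax.set_ylabel("heat (µcal)")
        ax.legend()
        return ax


def fit_one_site(heats: Sequence[float], schedule: ITCSchedule,
                 init: ITCParams | None = None,
                 exclude_first: bool = True) -> ITCParams:
    """Functional wrapper: fit and return the parameters with uncertainties."""
    return OneSiteBindingModel(heats, schedule, exclude_first=exclude_first) \
        .fit(start=init).params
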