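"""Integration of the IKK–IκB–NF-κB negative-feedback ODE module.

State vector (17 species, all concentrations in µM; nuclear species in nuclear
volume units, cytoplasmic in cytoplasmic units):

====  =========================================================
idx   species
====  =========================================================
0     cytoplasmic NF-κB (free)
1     nuclear NF-κB (free)
2+5k  free cytoplasmic IκB, isoform k ∈ (α, β, ε)
3+5k  free nuclear IκB
4+5k  cytoplasmic IκB:NF-κB complex
5+5k  nuclear IκB:NF-κB complex
6+5k  IκB mRNA
====  =========================================================

Processes: mass-action NF-κB:IκB association/dissociation in both compartments,
first-order nuclear transport (free NF-κB in/out, free IκB in/out, complex
export only), IκB synthesis from its mRNA, transcription via the additive
Pol-II-recruitment term driven by free nuclear NF-κB, constitutive and
IKK-activity-scaled IκB degradation (NF-κB is released when complexed IκB is
degraded), and first-order mRNA turnover.

Volume bookkeeping uses the cytoplasmic:nuclear volume ratio ``kv``: a nuclear
concentration ``x`` contributes ``x / kv`` on the cytoplasmic scale, and the
volume-weighted total NF-κB

    NFc + NFn/kv + Σ_iso (Cc + Cn/kv)

is conserved analytically by the flux scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .ikk import IKKCurve, ikk_activity
from .params import ISOFORMS, ModelParameters

N_SPECIES = 2 + 5 * len(ISOFORMS)

SPECIES_NAMES = ["nfkb_c", "nfkb_n"]
for _iso in ISOFORMS:
    SPECIES_NAMES += [f"ikb{_iso}_c", f"ikb{_iso}_n",
                      f"complex{_iso}_c", f"complex{_iso}_n", f"mrna{_iso}"]

# solver contract
RTOL = 1e-6
ATOL = 1e-9
STEADY_STATE_TOL = 1e-8       # µM/min, max |dx/dt| at steady state
EQUILIBRATION_HORIZON = 4000.0  # minutes
CLIP_TOL = 1e-9               # negative excursions below -CLIP_TOL are errors


class IntegrationError(RuntimeError):
    pass


class EquilibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class _Rates:
    """Per-isoform parameters packed into arrays for the RHS."""
    tr: np.ndarray
    dm: np.ndarray
    dfb: np.ndarray
    dfi: np.ndarray
    dbb: np.ndarray
    dbi: np.ndarray
    ka: np.ndarray
    kd: np.ndarray
    kiin: np.ndarray
    kiout: np.ndarray
    kcout: np.ndarray


def _pack(params: ModelParameters) -> _Rates:
    g = lambda name: np.array([getattr(params, name)[i] for i in ISOFORMS])
    return _Rates(tr=g("translation_rate"), dm=g("mrna_degradation"),
                  dfb=g("deg_free_basal"), dfi=g("deg_free_ikk"),
                  dbb=g("deg_bound_basal"), dbi=g("deg_bound_ikk"),
                  ka=g("assoc"), kd=g("dissoc"), kiin=g("ikb_import"),
                  kiout=g("ikb_export"), kcout=g("complex_export"))


def derivatives(state: np.ndarray, t: float, params: ModelParameters,
                curve: IKKCurve, _rates: _Rates | None = None) -> np.ndarray:
    """Right-hand side dstate/dt at time ``t`` (µM/min).

    Requires parameters with the adaptation applied (``modified`` flag set).
    """
    if not params.modified:
        raise ValueError("parameters must have the model adaptations applied "
                         "(use apply_model_adaptations or default_parameters)")
    r = _pack(params) if _rates is None else _rates
    kv = params.volume_ratio
    ikk = ikk_activity(curve, t)

    x = np.asarray(state, dtype=float)
    nfc, nfn = x[0], x[1]
    iso = x[2:].reshape(len(ISOFORMS), 5)
    ic, inn, cc, cn, im = iso[:, 0], iso[:, 1], iso[:, 2], iso[:, 3], iso[:, 4]

    bind_c = r.ka * nfc * ic - r.kd * cc          # net cytoplasmic association
    bind_n = r.ka * nfn * inn - r.kd * cn
    degb_c = (r.dbb + r.dbi * ikk) * cc           # bound-IκB degradation (cyt)
    degb_n = r.dbb * cn                           # no IKK activity in nucleus
    degf_c = (r.dfb + r.dfi * ikk) * ic
    degf_n = r.dfb * inn

    dx = np.empty_like(x)
    dx[0] = (-params.nfkb_import * nfc + params.nfkb_export * nfn / kv
             - bind_c.sum() + degb_c.sum())
    dx[1] = (params.nfkb_import * nfc * kv - params.nfkb_export * nfn
             - bind_n.sum() + degb_n.sum())

    tx = np.array([
        params.transcription[name].rate(
            nfn, induced_scale=(params.kmrna_scale if name == "a" else 1.0))
        for name in ISOFORMS])

    d_ic = (r.tr * im - bind_c - degf_c
            - r.kiin * ic + r.kiout * inn / kv)
    d_in = (r.kiin * ic * kv - r.kiout * inn - bind_n - degf_n)
    d_cc = bind_c - degb_c + r.kcout * cn / kv
    d_cn = bind_n - degb_n - r.kcout * cn
    d_im = tx - r.dm * im

    dx[2:] = np.stack([d_ic, d_in, d_cc, d_cn, d_im], axis=1).ravel()
    return dx


def weighted_nfkb_total(state: np.ndarray, volume_ratio: float) -> float:
    """Volume-weighted (cytoplasm-referenced) total NF-κB in a state (µM)."""
    x = np.asarray(state, dtype=float)
    kv = volume_ratio
    iso = x[..., 2:].reshape(*x.shape[:-1], len(ISOFORMS), 5)
    return (x[..., 0] + x[..., 1] / kv
            + iso[..., 2].sum(axis=-1) + (iso[..., 3] / kv).sum(axis=-1))


def total_ikb(state: np.ndarray, volume_ratio: float, isoform: str = "a"):
    """Volume-weighted total IκB protein (free + bound, both compartments)."""
    k = ISOFORMS.index(isoform)
    x = np.asarray(state, dtype=float)
    o = 2 + 5 * k
    kv = volume_ratio
    return x[..., o] + x[..., o + 1] / kv + x[..., o + 2] + x[..., o + 3] / kv


@dataclass(frozen=True)
class Trajectory:
    """Integrated time courses plus the two derived observables."""
    times: np.ndarray        # minutes
    states: np.ndarray       # (n_times, N_SPECIES)
    params: ModelParameters

    @property
    def nuclear_nfkb(self) -> np.ndarray:
        """Free nuclear NF-κB (µM) — the EMSA-type activity observable."""
        return self.states[:, 1]

    @property
    def total_ikba(self) -> np.ndarray:
        """Volume-weighted total IκBα protein (µM) — the immunoblot observable."""
        return total_ikb(self.states, self.params.volume_ratio, "a")

    def conservation_error(self) -> float:
        """Max relative drift of volume-weighted total NF-κB along the path."""
        w = weighted_nfkb_total(self.states, self.params.volume_ratio)
        target = self.params.effective_total_nfkb
        return float(np.max(np.abs(w - target)) / target)

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.states, columns=SPECIES_NAMES)
        df.insert(0, "time_min", self.times)
        df["nuclear_nfkb"] = self.nuclear_nfkb
        df["total_ikba"] = self.total_ikba
        return df

    def plot(self, ax=None):
        """Quick look at the two observables (normalized per convention)."""
        import matplotlib.pyplot as plt
        from .scan import normalize_activation, normalize_depletion
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times, normalize_activation(self.nuclear_nfkb),
                label="nuclear NF-κB (activation-normalized)")
        ax.plot(self.times, normalize_depletion(self.total_ikba),
                label="total IκBα (depletion-normalized)")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("normalized level")
        ax.legend()
        return ax


def _clip(states: np.ndarray) -> np.ndarray:
    worst = states.min()
    if worst < -CLIP_TOL * 100:  # gross negativity => genuine solver failure
        raise IntegrationError(f"negative concentration {worst:.3e} beyond tolerance")
    return np.clip(states, 0.0, None)


def _initial_guess(params: ModelParameters) -> np.ndarray:
    x0 = np.zeros(N_SPECIES)
    x0[0] = params.effective_total_nfkb          # all NF-κB free, cytoplasmic
    for k, name in enumerate(ISOFORMS):
        t = params.transcription[name]
        x0[6 + 5 * k] = t.k_basal / params.mrna_degradation[name]
    return x0


def _polish_steady_state(x: np.ndarray, rhs, params: ModelParameters) -> np.ndarray:
    """Newton-polish a near-steady state on the NF-κB conservation manifold.

    The RHS has a zero eigenvalue along the conserved direction, so the plain
    root problem is singular; the NF-κB flux-balance equation is replaced by
    the conservation constraint to pin the manifold.
    """
    from scipy.optimize import root
    target = params.effective_total_nfkb

    def constrained(z):
        f = rhs(0.0, z)
        f = np.asarray(f, dtype=float).copy()
        f[0] = weighted_nfkb_total(z, params.volume_ratio) - target
        return f

    sol = root(constrained, x, method="hybr", tol=1e-13)
    if sol.success and sol.x.min() > -CLIP_TOL:
        return np.clip(sol.x, 0.0, None)
    return x


def equilibrate(params: ModelParameters, curve: IKKCurve,
                horizon: float = EQUILIBRATION_HORIZON,
                tol: float = STEADY_STATE_TOL) -> np.ndarray:
    """Resting-cell state: integrate under basal IKK until max|dx/dt| < tol.

    Integrates in chunks up to ``horizon`` minutes, Newton-polishing the state
    on the conservation manifold once the integration is near-stationary;
    raises :class:`EquilibrationError` with the residual norm on failure.
    """
    basal = curve.constant()
    rates = _pack(params)
    rhs = lambda t, x: derivatives(x, t, params, basal, rates)
    x = _initial_guess(params)
    elapsed, chunk = 0.0, horizon / 4
    residual = np.inf
    while elapsed < horizon:
        sol = solve_ivp(rhs, (0.0, chunk), x, method="LSODA",
                        rtol=RTOL, atol=ATOL, dense_output=False)
        if not sol.success:
            raise EquilibrationError(f"equilibration solver failed: {sol.message}")
        x = _clip(sol.y[:, -1])
        elapsed += chunk
        residual = float(np.max(np.abs(rhs(0.0, x))))
        if residual < tol:
            return x
        if residual < 1e-3:  # near-stationary: finish with Newton
            x = _polish_steady_state(x, rhs, params)
            residual = float(np.max(np.abs(rhs(0.0, x))))
            if residual < tol:
                return x
    raise EquilibrationError(
        f"no steady state within {horizon} min (max residual {residual:.3e} µM/min)")


def simulate(params: ModelParameters, curve: IKKCurve, t_end: float = 360.0,
             dt_out: float = 1.0, x0: np.ndarray | None = None) -> Trajectory:
    """Integrate the module from the equilibrated resting state.

    Stimulation (the IKK curve) starts at t = 0; output on a uniform grid of
    spacing ``dt_out``.  Uses LSODA (adaptive, automatic stiff/non-stiff
    switching) at rtol 1e-6 / atol 1e-9.  Conservation of volume-weighted
    NF-κB is checked on the output and drift beyond 1e-6 relative is an error.
    """
    if x0 is None:
        x0 = equilibrate(params, curve)
    rates = _pack(params)
    rhs = lambda t, x: derivatives(x, t, params, curve, rates)
    times = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    sol = solve_ivp(rhs, (0.0, float(times[-1])), x0, t_eval=times,
                    method="LSODA", rtol=RTOL, atol=ATOL)
    if not sol.success:
        raise IntegrationError(f"integration failed at t≈{sol.t[-1]:.1f} min: {sol.message}")
    traj = Trajectory(times=sol.t, states=_clip(sol.y.T), params=params)
    drift = traj.conservation_error()
    if drift > 1e-6:
        raise IntegrationError(f"NF-κB conservation drift {drift:.2e} beyond 1e-6")
    return traj
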