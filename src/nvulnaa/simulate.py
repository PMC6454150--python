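"""The 8-state NVU ODE system: assembly, steady states and transients.

State layout: concentrations (uM) of (Phe, CL) in (MBEC, ISF, Ast, Neu),
stored as a (4, 2) array.  Mass balance per species ``s``:

    dMBEC/dt = 1e6 (J_lum,s - J_abl,s) / V_MBEC
    dISF/dt  = 1e6 (J_abl,s - J_LAT2,s - J_B0AT2,s) / V_ISF
    dAst/dt  = 1e6 J_LAT2,s / V_Ast
    dNeu/dt  = 1e6 J_B0AT2,s / V_Neu

with fluxes in umol/min, volumes in ul, and hence derivatives in uM/min.
Plasma is an infinite reservoir (boundary condition), so there is no
closed-system conservation across the plasma interface; the obligatory
1:1 antiporters do, however, conserve the summed Phe+CL content of the
compartments they couple, which is why the prescribed initial condition
(the physiologic steady state reported for the underlying NVU model)
is part of the model definition and not a numerical convenience.

The system is stiff: endothelial volume (3.5 ul) is two orders of
magnitude below the cellular volumes, so MBEC/ISF dynamics relax within
minutes while astrocytes and neurons take hours to days.  Implicit
integrators are therefore mandatory and explicit ones are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from nvulnaa.fluxes import MembraneFlux, b0at2_flux, lat1_flux, lat2_flux
from nvulnaa.forcing import PlasmaForcing
from nvulnaa.params import COMPARTMENTS, SPECIES, Compartment, ParameterSet, Species

MINUTES_PER_DAY = 1440.0

_IMPLICIT_METHODS = ("Radau", "BDF", "LSODA")


@dataclass(frozen=True)
class NVUState:
    """Phe and CL concentrations (uM) in the four NVU compartments."""

    conc: np.ndarray  # shape (4, 2): compartments x species

    def __post_init__(self):
        arr = np.asarray(self.conc, dtype=float)
        if arr.shape != (4, 2):
            raise ValueError(f"state must have shape (4, 2), got {arr.shape}")
        object.__setattr__(self, "conc", arr)

    def __getitem__(self, key: Tuple[Compartment, Species]) -> float:
        comp, sp = key
        return float(self.conc[COMPARTMENTS.index(comp), SPECIES.index(sp)])

    def as_array(self) -> np.ndarray:
        return self.conc.copy()

    def as_flat(self) -> np.ndarray:
        return self.conc.reshape(-1).copy()

    @staticmethod
    def from_flat(x) -> "NVUState":
        return NVUState(np.asarray(x, dtype=float).reshape(4, 2))

    def to_dict(self) -> Dict[str, float]:
        return {
            f"{comp.value}_{sp.value}": float(self.conc[i, j])
            for i, comp in enumerate(COMPARTMENTS)
            for j, sp in enumerate(SPECIES)
        }


#: Physiologic steady-state concentrations (uM) reported for the underlying
#: adult-rat NVU model: the prescribed initial condition of every solve and
#: the reference for baseline normalisation.  Rows MBEC, ISF, Ast, Neu;
#: columns Phe, CL.
PHYSIOLOGIC_REFERENCE_UM = np.array(
    [
        [24.6, 235.7],
        [0.03, 0.3],
        [4.8, 46.0],
        [7.0, 46.9],
    ]
)


def reference_initial_state() -> NVUState:
    """The literature physiologic steady state used to initialise solves."""
    return NVUState(PHYSIOLOGIC_REFERENCE_UM.copy())


def _fluxes(
    x: np.ndarray, phe_p: float, cl_p: float, p: ParameterSet
) -> Tuple[MembraneFlux, MembraneFlux, MembraneFlux, MembraneFlux]:
    """All four membrane fluxes at one instant (umol/min)."""
    mbec = (x[0], x[1])
    isf = (x[2], x[3])
    ast = (x[4], x[5])
    neu = (x[6], x[7])
    lum = lat1_flux((phe_p, cl_p), mbec, "luminal", p.lat1)
    abl = lat1_flux(isf, mbec, "abluminal", p.lat1)
    j2 = lat2_flux(isf, ast, p.lat2)
    jb = b0at2_flux(isf, neu, p.b0at2)
    return lum, abl, j2, jb


def _rhs_flat(x: np.ndarray, phe_p: float, cl_p: float, p: ParameterSet,
              vols: np.ndarray) -> np.ndarray:
    # Fluxes vanish with vanishing substrate, so clipping infinitesimal
    # integrator undershoot at zero preserves continuity.
    x = np.maximum(x, 0.0)
    lum, abl, j2, jb = _fluxes(x, phe_p, cl_p, p)
    out = np.empty(8)
    for j, (l, a, t2, tb) in enumerate(
        ((lum.phe, abl.phe, j2.phe, jb.phe), (lum.cl, abl.cl, j2.cl, jb.cl))
    ):
        out[0 + j] = 1e6 * (l - a) / vols[0]
        out[2 + j] = 1e6 * (a - t2 - tb) / vols[1]
        out[4 + j] = 1e6 * t2 / vols[2]
        out[6 + j] = 1e6 * tb / vols[3]
    return out


def _volume_vector(p: ParameterSet) -> np.ndarray:
    return np.array([p.volumes[c] for c in COMPARTMENTS])


def membrane_fluxes(
    x: NVUState, f: PlasmaForcing, p: ParameterSet, t: float = 0.0
) -> Dict[str, MembraneFlux]:
    """Instantaneous fluxes (umol/min) through the four membranes."""
    lum, abl, j2, jb = _fluxes(
        x.as_flat(), float(f.phe(t)), f.cl_input, p
    )
    return {"lat1_luminal": lum, "lat1_abluminal": abl, "lat2": j2, "b0at2": jb}


def state_derivative(
    t: float, x: NVUState, f: PlasmaForcing, p: ParameterSet
) -> np.ndarray:
    """Time derivative of the state at time ``t`` (days), in uM/min.

    Returns a (4, 2) array aligned with the state layout.  Negative state
    entries are rejected.
    """
    arr = x.as_flat()
    if np.any(arr < 0):
        raise ValueError("state concentrations must be non-negative")
    phe_p = float(f.phe(t))
    dx = _rhs_flat(arr, phe_p, f.cl_input, p, _volume_vector(p))
    return dx.reshape(4, 2)


def residual(x: NVUState, f: PlasmaForcing, p: ParameterSet, t: float = 0.0) -> float:
    """Largest absolute derivative entry, uM/min."""
    return float(np.max(np.abs(state_derivative(t, x, f, p))))


class SteadyStateError(RuntimeError):
    """Raised when the steady-state residual criterion is not met."""

    def __init__(self, residual_value: float, tol: float, minutes: float):
        self.residual = residual_value
        super().__init__(
            f"steady state not reached: residual {residual_value:.3e} uM/min "
            f"> {tol:.1e} after {minutes:.0f} min of model time"
        )


def solve_steady_state(
    f: PlasmaForcing,
    p: ParameterSet,
    x0: Optional[NVUState] = None,
    residual_tol: float = 1e-6,
    max_minutes: float = 1e6,
    rtol: float = 1e-10,
    atol: float = 1e-10,
    method: str = "Radau",
) -> NVUState:
    """Steady state under constant forcing, by stiff relaxation.

    Integrates from ``x0`` (default: the physiologic reference state) over
    geometrically growing spans of model time until the residual
    max |dC/dt| drops below ``residual_tol`` (uM/min), and raises
    :class:`SteadyStateError` with the final residual otherwise.
    """
    if f.cf != 0.0:
        raise ValueError("steady-state solve requires constant forcing (cf = 0)")
    if method not in _IMPLICIT_METHODS:
        raise ValueError(
            f"stiff system: method must be one of {_IMPLICIT_METHODS}, got {method!r}"
        )
    x = (x0 or reference_initial_state()).as_flat()
    phe_p, cl_p = float(f.phe_ss), float(f.cl_input)
    vols = _volume_vector(p)

    def rhs(t, y):
        return _rhs_flat(y, phe_p, cl_p, p, vols)

    span = 100.0
    while True:
        sol = solve_ivp(rhs, (0.0, span), x, method=method, rtol=rtol, atol=atol)
        if not sol.success:
            raise SteadyStateError(np.inf, residual_tol, span)
        x = np.maximum(sol.y[:, -1], 0.0)
        res = float(np.max(np.abs(rhs(0.0, x))))
        if res < residual_tol:
            return NVUState.from_flat(x)
        if span >= max_minutes:
            raise SteadyStateError(res, residual_tol, span)
        span = min(span * 10.0, max_minutes)


@dataclass
class Trajectory:
    """Simulated time course on a regular output grid.

    ``conc`` has shape (n_times, 4, 2) in uM.  ``baseline`` (the
    physiologic steady state) enables the percent-of-baseline view;
    ``transition_days`` flags the initial window excluded from summary
    statistics.
    """

    times_days: np.ndarray
    conc: np.ndarray
    forcing: PlasmaForcing
    transition_days: float = 0.0
    baseline: Optional[NVUState] = None
    initial_state: Optional[NVUState] = None
    solver_stats: Optional[Dict[str, float]] = None

    def state_at(self, i: int) -> NVUState:
        return NVUState(self.conc[i])

    @property
    def post_transition(self) -> np.ndarray:
        """Boolean mask of output times after the transition window."""
        return self.times_days >= self.transition_days

    def percent_of_baseline(self) -> np.ndarray:
        """Concentrations as percent of the physiologic baseline."""
        if self.baseline is None:
            raise ValueError("trajectory has no baseline attached")
        return 100.0 * self.conc / self.baseline.as_array()[None, :, :]

    def to_frame(self) -> pd.DataFrame:
        """Tidy view: time_day, compartment, species, conc_uM, pct_baseline."""
        pct = (
            self.percent_of_baseline()
            if self.baseline is not None
            else np.full_like(self.conc, np.nan)
        )
        rows = []
        for i, comp in enumerate(COMPARTMENTS):
            for j, sp in enumerate(SPECIES):
                rows.append(
                    pd.DataFrame(
                        {
                            "time_day": self.times_days,
                            "compartment": comp.value,
                            "species": sp.value,
                            "conc_uM": self.conc[:, i, j],
                            "pct_baseline": pct[:, i, j],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def simulate(
    f: PlasmaForcing,
    p: ParameterSet,
    span_days: float,
    output_step_days: float = 0.01,
    x0: Optional[NVUState] = None,
    transition_days: Optional[float] = None,
    baseline: Optional[NVUState] = None,
    rtol: float = 1e-8,
    atol: float = 1e-8,
    method: str = "LSODA",
) -> Trajectory:
    """Transient simulation under (possibly fluctuating) plasma forcing.

    Starts from the steady state of the matching constant (cf = 0)
    forcing unless ``x0`` is given, mirroring the study protocol.  The
    default transition window flagged for exclusion from summaries is one
    forcing period (zero for constant forcing).
    """
    if span_days <= 0:
        raise ValueError("span_days must be > 0")
    if method not in _IMPLICIT_METHODS:
        raise ValueError(
            f"stiff system: method must be one of {_IMPLICIT_METHODS}, got {method!r}"
        )
    if x0 is None:
        x0 = solve_steady_state(replace(f, cf=0.0), p)
    if transition_days is None:
        transition_days = f.period_days if f.cf > 0 else 0.0

    vols = _volume_vector(p)
    cl_p = float(f.cl_input)

    def rhs(t_min, y):
        return _rhs_flat(y, float(f.phe(t_min / MINUTES_PER_DAY)), cl_p, p, vols)

    n_steps = int(np.floor(span_days / output_step_days + 1e-9))
    t_grid_days = np.arange(n_steps + 1) * output_step_days
    sol = solve_ivp(
        rhs,
        (0.0, span_days * MINUTES_PER_DAY),
        x0.as_flat(),
        method=method,
        rtol=rtol,
        atol=atol,
        t_eval=t_grid_days * MINUTES_PER_DAY,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed: {sol.message} "
            f"(accepted steps: {sol.t.size}, final time {sol.t[-1] / MINUTES_PER_DAY:.3f} d)"
        )
    conc = sol.y.T.reshape(-1, 4, 2)
    undershoot = float(conc.min())
    if undershoot < -100.0 * atol:
        raise RuntimeError(
            f"integrator produced negative concentrations ({undershoot:.3e} uM); "
            "tighten rtol/atol"
        )
    conc = np.maximum(conc, 0.0)
    stats = {"n_output": float(sol.t.size), "nfev": float(sol.nfev),
             "njev": float(getattr(sol, "njev", 0) or 0)}
    return Trajectory(
        times_days=t_grid_days,
        conc=conc,
        forcing=f,
        transition_days=float(transition_days),
        baseline=baseline,
        initial_state=x0,
        solver_stats=stats,
    )


def brain_average(x: NVUState, p: ParameterSet) -> Dict[Species, float]:
    """Volume-weighted whole-brain mean concentration per species (uM)."""
    vols = _volume_vector(p)
    weighted = vols @ x.as_array() / vols.sum()
    return {Species.PHE: float(weighted[0]), Species.CL: float(weighted[1])}


def physiologic_baseline(p: ParameterSet, **kwargs) -> NVUState:
    """The model's own physiologic baseline: steady state at plasma
    Phe = 77 uM, CL = 739 uM.  Normalisation reference for all analyses."""
    from nvulnaa.forcing import PLASMA_CL_UM, PLASMA_PHE_UM

    f = PlasmaForcing(phe_ss=PLASMA_PHE_UM, cl_ss=PLASMA_CL_UM, cf=0.0)
    return solve_steady_state(f, p, **kwargs)
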