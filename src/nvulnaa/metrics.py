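"""Derived analyses: RMS excursion maps, parameter-sensitivity ensembles
and LNAA-supplementation scenarios.

The excursion metric summarises how far a fluctuating response strays from
its own steady state, expressed as a fraction of the physiologic baseline:

    excursion = sqrt( mean_t [ (c_f(t) - c_ss) / c_baseline ]^2 )

with the time mean taken over the post-transition window by trapezoidal
quadrature on the output grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from nvulnaa.forcing import (
    PlasmaForcing,
    check_sweep_bounds,
    pure_sinusoid,
    with_supplement,
)
from nvulnaa.params import COMPARTMENTS, KINETIC_KEYS, SPECIES, ParameterSet
from nvulnaa.simulate import (
    NVUState,
    SteadyStateError,
    Trajectory,
    physiologic_baseline,
    simulate,
    solve_steady_state,
)

logger = logging.getLogger(__name__)


def rms_excursion(
    traj: Trajectory,
    ss: NVUState,
    baseline: NVUState,
    window: Optional[Tuple[float, float]] = None,
) -> np.ndarray:
    """Baseline-normalised RMS deviation of a trajectory from its steady
    state, per compartment and species.

    ``window`` is a (start, end) pair in days; it defaults to the
    trajectory's post-transition span.  Returns a (4, 2) array of
    dimensionless excursions.
    """
    base = baseline.as_array()
    if np.any(base <= 0):
        raise ValueError("baseline entries must be strictly positive")
    if window is None:
        window = (traj.transition_days, float(traj.times_days[-1]))
    t0, t1 = window
    mask = (traj.times_days >= t0) & (traj.times_days <= t1)
    if mask.sum() < 2:
        raise ValueError(f"window {window} contains fewer than two output points")
    t = traj.times_days[mask]
    dev = (traj.conc[mask] - ss.as_array()[None, :, :]) / base[None, :, :]
    mean_sq = np.trapezoid(dev**2, t, axis=0) / (t[-1] - t[0])
    return np.sqrt(mean_sq)


@dataclass
class ExcursionMap:
    """RMS excursions on an (f0, cf) grid; values shape (nf, nc, 4, 2)."""

    f0_grid: np.ndarray
    cf_grid: np.ndarray
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, f0 in enumerate(self.f0_grid):
            for j, cf in enumerate(self.cf_grid):
                for k, comp in enumerate(COMPARTMENTS):
                    for m, sp in enumerate(SPECIES):
                        rows.append(
                            (f0, cf, comp.value, sp.value, self.values[i, j, k, m])
                        )
        return pd.DataFrame(
            rows, columns=["f0_cpd", "cf", "compartment", "species", "rms_excursion"]
        )


DEFAULT_F0_GRID = tuple(np.geomspace(0.14, 7.0, 8))
DEFAULT_CF_GRID = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


def frequency_amplitude_sweep(
    p: ParameterSet,
    phe_ss: float = 1600.0,
    f0_grid: Sequence[float] = DEFAULT_F0_GRID,
    cf_grid: Sequence[float] = DEFAULT_CF_GRID,
    span_days: float = 14.0,
    post_transition_days: Optional[float] = None,
    output_step_days: float = 0.01,
    baseline: Optional[NVUState] = None,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> ExcursionMap:
    """RMS excursion over a grid of fluctuation frequency and amplitude.

    Each grid point runs a pure-sinusoid simulation started from the shared
    constant-forcing steady state, excludes one forcing period as
    transition, and summarises the remainder with :func:`rms_excursion`.
    If ``post_transition_days`` is given, the span of each run is one
    forcing period plus that window (scaled-down protocol); otherwise
    every run covers ``span_days``.

    The RMS of a periodic deviation is only phase-independent when taken
    over whole periods, so the measurement window is always rounded up to
    an integer number of forcing periods (at least one); the run span
    grows accordingly at low frequencies.
    """
    f0_grid = np.asarray(sorted(f0_grid), dtype=float)
    cf_grid = np.asarray(sorted(cf_grid), dtype=float)
    for f0 in f0_grid:
        check_sweep_bounds(f0, 0.0)
    if baseline is None:
        baseline = physiologic_baseline(p)
    constant = PlasmaForcing(phe_ss=phe_ss, cf=0.0)
    ss = solve_steady_state(constant, p)
    values = np.zeros((len(f0_grid), len(cf_grid), 4, 2))
    for i, f0 in enumerate(f0_grid):
        period = 1.0 / f0
        requested = (
            span_days - period if post_transition_days is None else post_transition_days
        )
        window = period * max(1, int(np.ceil(requested / period - 1e-9)))
        span = period + window
        for j, cf in enumerate(cf_grid):
            if cf == 0.0:
                continue  # constant forcing: zero excursion by definition
            forcing = PlasmaForcing(phe_ss=phe_ss, cf=cf, shape=pure_sinusoid(f0))
            traj = simulate(
                forcing,
                p,
                span_days=span,
                output_step_days=output_step_days,
                x0=ss,
                transition_days=period,
                rtol=rtol,
                atol=atol,
            )
            values[i, j] = rms_excursion(traj, ss, baseline)
    return ExcursionMap(f0_grid=f0_grid, cf_grid=cf_grid, values=values)


# ---------------------------------------------------------------------------
# sensitivity ensemble
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """A reproducible model run whose outputs the ensemble perturbs.

    ``kind`` is 'steady' (outputs: the 8 steady concentrations) or
    'transient' (outputs: the full trajectory on the output grid).
    """

    forcing: PlasmaForcing
    kind: str = "steady"
    span_days: float = 14.0
    output_step_days: float = 0.01

    def __post_init__(self):
        if self.kind not in ("steady", "transient"):
            raise ValueError(f"kind must be 'steady' or 'transient', got {self.kind!r}")


@dataclass
class SensitivityEnsemble:
    """Monte-Carlo parameter-perturbation ensemble.

    Kinetic parameters (maximal rates, Michaelis constants) and the
    baseline concentrations used for normalisation are each multiplied by
    independent uniform factors in [1 - fraction, 1 + fraction] per draw.
    ``lower``/``upper`` bracket the nominal normalised output by its RMS
    deviation across draws, so they contain the nominal curve by
    construction.  Fully reproducible from ``seed``.
    """

    n: int
    fraction: float
    seed: int
    keys: Tuple[str, ...]
    param_factors: np.ndarray  # (n, n_keys)
    baseline_factors: np.ndarray  # (n, 4, 2)
    times_days: Optional[np.ndarray]  # None for steady scenarios
    nominal: np.ndarray  # normalised (% baseline); (4,2) or (nt,4,2)
    draws: np.ndarray  # (n_ok, ...) normalised outputs
    lower: np.ndarray
    upper: np.ndarray
    failed_draws: List[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        if self.times_days is None:
            for k, comp in enumerate(COMPARTMENTS):
                for m, sp in enumerate(SPECIES):
                    rows.append(
                        (comp.value, sp.value, self.nominal[k, m],
                         self.lower[k, m], self.upper[k, m])
                    )
            return pd.DataFrame(
                rows, columns=["compartment", "species", "nominal", "lower", "upper"]
            )
        for it, t in enumerate(self.times_days):
            for k, comp in enumerate(COMPARTMENTS):
                for m, sp in enumerate(SPECIES):
                    rows.append(
                        (t, comp.value, sp.value, self.nominal[it, k, m],
                         self.lower[it, k, m], self.upper[it, k, m])
                    )
        return pd.DataFrame(
            rows,
            columns=["time_day", "compartment", "species", "nominal", "lower", "upper"],
        )


def _scenario_output(p: ParameterSet, scenario: Scenario) -> Tuple[Optional[np.ndarray], np.ndarray]:
    """(times or None, raw concentration output) for one parameter draw."""
    if scenario.kind == "steady":
        ss = solve_steady_state(replace(scenario.forcing, cf=0.0), p)
        return None, ss.as_array()
    traj = simulate(
        scenario.forcing,
        p,
        span_days=scenario.span_days,
        output_step_days=scenario.output_step_days,
    )
    return traj.times_days, traj.conc


def sensitivity_ensemble(
    p: ParameterSet,
    scenario: Scenario,
    n: int = 100,
    fraction: float = 0.20,
    seed: int = 0,
    baseline: Optional[NVUState] = None,
) -> SensitivityEnsemble:
    """Run the +/-20%-style random-perturbation ensemble for one scenario."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must lie in [0, 1)")
    if baseline is None:
        baseline = physiologic_baseline(p)
    base = baseline.as_array()

    rng = np.random.default_rng(seed)
    keys = KINETIC_KEYS
    param_factors = rng.uniform(1.0 - fraction, 1.0 + fraction, size=(n, len(keys)))
    baseline_factors = rng.uniform(1.0 - fraction, 1.0 + fraction, size=(n, 4, 2))

    times, nominal_raw = _scenario_output(p, scenario)
    nominal = 100.0 * nominal_raw / base

    draws = []
    failed: List[int] = []
    for i in range(n):
        p_i = p.perturbed(dict(zip(keys, param_factors[i])))
        try:
            _, raw = _scenario_output(p_i, scenario)
        except (SteadyStateError, RuntimeError) as exc:  # pragma: no cover
            warnings.warn(f"draw {i} failed and is excluded: {exc}")
            failed.append(i)
            continue
        draws.append(100.0 * raw / (base * baseline_factors[i]))
    if failed:
        logger.warning("%d of %d draws failed to converge", len(failed), n)
    draws_arr = np.asarray(draws)
    dev = np.sqrt(np.mean((draws_arr - nominal[None]) ** 2, axis=0))
    return SensitivityEnsemble(
        n=n,
        fraction=fraction,
        seed=seed,
        keys=keys,
        param_factors=param_factors,
        baseline_factors=baseline_factors,
        times_days=times,
        nominal=nominal,
        draws=draws_arr,
        lower=nominal - dev,
        upper=nominal + dev,
        failed_draws=failed,
    )


# ---------------------------------------------------------------------------
# supplementation
# ---------------------------------------------------------------------------


@dataclass
class SupplementationResult:
    """Paired runs with and without supplemented LNAAs.

    Trajectories are present only for the fluctuating protocol;
    ``amplitude_*`` hold post-transition peak-to-trough spans (uM) per
    compartment/species, shape (4, 2).
    """

    sl: float
    steady_without: NVUState
    steady_with: NVUState
    traj_without: Optional[Trajectory] = None
    traj_with: Optional[Trajectory] = None
    amplitude_without: Optional[np.ndarray] = None
    amplitude_with: Optional[np.ndarray] = None


def fluctuation_amplitude(traj: Trajectory) -> np.ndarray:
    """Peak-to-trough concentration span after the transition window."""
    sel = traj.conc[traj.post_transition]
    return sel.max(axis=0) - sel.min(axis=0)


def supplementation_scenario(
    p: ParameterSet,
    sl: float,
    fluctuating: bool = False,
    phe_ss: float = 1000.0,
    cf: float = 0.5,
    f0: float = 1.0,
    span_days: float = 14.0,
    output_step_days: float = 0.01,
    baseline: Optional[NVUState] = None,
) -> SupplementationResult:
    """The LNAA-supplementation protocol at one supplement level.

    Steady protocol: constant plasma Phe (default 1000 uM).  Fluctuating
    protocol: pure sinusoid with cf = 0.5 and f0 = 1 cycle/day.  The
    supplement enters as additional constant plasma CL.
    """
    if sl < 0:
        raise ValueError("supplement level must be >= 0")
    shape = pure_sinusoid(f0)
    f_plain = PlasmaForcing(phe_ss=phe_ss, cf=cf if fluctuating else 0.0, shape=shape)
    f_suppl = with_supplement(f_plain, sl)
    ss_plain = solve_steady_state(replace(f_plain, cf=0.0), p)
    ss_suppl = solve_steady_state(replace(f_suppl, cf=0.0), p)
    result = SupplementationResult(sl=sl, steady_without=ss_plain, steady_with=ss_suppl)
    if fluctuating:
        for name, f, ss in (("without", f_plain, ss_plain), ("with", f_suppl, ss_suppl)):
            traj = simulate(
                f, p, span_days=span_days, output_step_days=output_step_days,
                x0=ss, baseline=baseline,
            )
            setattr(result, f"traj_{name}", traj)
            setattr(result, f"amplitude_{name}", fluctuation_amplitude(traj))
    return result
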