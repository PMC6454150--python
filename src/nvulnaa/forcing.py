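"""Plasma boundary conditions: the synthetic-data generator of the study.

Plasma Phe is either constant or fluctuates periodically around its mean

    Phe(t) = Phe_ss * (1 + c_f * delta(t) / max|delta|),

where ``delta`` is a zero-mean trigonometric Fourier series with fundamental
frequency ``f0`` (cycles/day) and ``c_f`` in [0, 1] is the amplitude-to-mean
ratio.  Plasma CL is constant (739 uM physiologic), and therapeutically
supplemented LNAAs (SL) enter as additional constant plasma CL with
identical kinetics.

Realistic study ranges emulated here: steady plasma Phe 77 uM (physiologic)
to 1600 uM (severe classic PKU); f0 in [0.14, 7] cycles/day; c_f in [0, 1];
supplementation levels 0.5, 2 and 5 mM.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

#: Physiologic plasma CL concentration, uM
PLASMA_CL_UM = 739.0
#: Physiologic plasma Phe concentration, uM
PLASMA_PHE_UM = 77.0
#: Realistic fluctuation-frequency bounds, cycles/day
F0_BOUNDS = (0.14, 7.0)

#: grid density used to normalise the fluctuation shape to unit peak
_PEAK_GRID = 10_000


@dataclass(frozen=True)
class FourierSpec:
    """Zero-mean periodic fluctuation shape.

    delta(t) = sum_n a_n sin(2 pi n f0 t) + b_n cos(2 pi n f0 t),
    n = 1..N, t in days, f0 in cycles/day.  There is no constant term, so
    the signal averages to zero over one period 1/f0.
    """

    f0: float
    a: Tuple[float, ...] = (1.0,)
    b: Tuple[float, ...] = (0.0,)

    def __post_init__(self):
        if self.f0 <= 0:
            raise ValueError(f"f0 must be > 0, got {self.f0}")
        a, b = tuple(self.a), tuple(self.b)
        n = max(len(a), len(b))
        if n == 0:
            raise ValueError("empty Fourier series (no harmonics)")
        a = a + (0.0,) * (n - len(a))
        b = b + (0.0,) * (n - len(b))
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def n_harmonics(self) -> int:
        return len(self.a)

    @property
    def period_days(self) -> float:
        return 1.0 / self.f0


def pure_sinusoid(f0: float) -> FourierSpec:
    """delta(t) = sin(2 pi f0 t): the study's sweep/supplementation shape."""
    return FourierSpec(f0=f0, a=(1.0,), b=(0.0,))


def fourier_value(shape: FourierSpec, t) -> np.ndarray | float:
    """Evaluate the dimensionless fluctuation at time ``t`` (days)."""
    t = np.asarray(t, dtype=float)
    n = np.arange(1, shape.n_harmonics + 1)
    phase = 2.0 * np.pi * shape.f0 * np.multiply.outer(t, n)
    out = phase * 0.0
    out = np.sin(phase) @ np.asarray(shape.a) + np.cos(phase) @ np.asarray(shape.b)
    return out if out.shape else float(out)


@functools.lru_cache(maxsize=256)
def _peak(shape: FourierSpec) -> float:
    """max |delta| over one period, on a dense grid (cached).

    With ``_PEAK_GRID`` points per period the relative error stays below
    1e-5 for up to ~20 harmonics.
    """
    tt = np.linspace(0.0, shape.period_days, _PEAK_GRID, endpoint=False)
    return float(np.max(np.abs(fourier_value(shape, tt))))


def zero_start_shift(shape: FourierSpec) -> float:
    """Time shift t0 (days) with delta(t0) = 0 and delta'(t0) > 0.

    Implements the convention that the fluctuating component starts at
    zero and rising; the default pure sinusoid satisfies it at t0 = 0.
    """
    tt = np.linspace(0.0, shape.period_days, _PEAK_GRID, endpoint=False)
    vals = fourier_value(shape, tt)
    nxt = np.roll(vals, -1)
    crossing = np.nonzero((vals <= 0.0) & (nxt > 0.0))[0]
    if crossing.size == 0:
        raise ValueError("fluctuation shape has no upward zero crossing")
    i = crossing[0]
    # linear interpolation inside the bracketing grid cell
    t0, t1 = tt[i], tt[i] + (tt[1] - tt[0])
    v0, v1 = vals[i], nxt[i]
    return float(t0 if v1 == v0 else t0 + (t1 - t0) * (-v0) / (v1 - v0))


@dataclass(frozen=True)
class PlasmaForcing:
    """Complete plasma boundary condition for one simulation.

    ``phe_ss``: mean plasma Phe (uM); ``cl_ss``: constant plasma CL (uM);
    ``cf``: amplitude-to-mean ratio in [0, 1]; ``shape``: fluctuation
    shape; ``sl``: supplemented-LNAA level (uM), delivered to the model as
    additional constant CL; ``phase_shift_days`` shifts the fluctuation in
    time (used to impose a zero initial value for multi-harmonic shapes).
    """

    phe_ss: float
    cl_ss: float = PLASMA_CL_UM
    cf: float = 0.0
    shape: FourierSpec = FourierSpec(f0=1.0)
    sl: float = 0.0
    phase_shift_days: float = 0.0

    def __post_init__(self):
        if self.phe_ss <= 0:
            raise ValueError("phe_ss must be > 0")
        if self.cl_ss <= 0:
            raise ValueError("cl_ss must be > 0")
        if not (0.0 <= self.cf <= 1.0):
            raise ValueError(f"cf must lie in [0, 1], got {self.cf}")
        if self.sl < 0:
            raise ValueError("supplemented LNAA level must be >= 0")

    @property
    def f0(self) -> float:
        return self.shape.f0

    @property
    def period_days(self) -> float:
        return self.shape.period_days

    @property
    def cl_input(self) -> float:
        """Constant CL delivered to the model: plasma CL plus supplement."""
        return self.cl_ss + self.sl

    def phe(self, t) -> np.ndarray | float:
        return phe_profile(self, t)

    def with_zero_start(self) -> "PlasmaForcing":
        """Copy whose fluctuating component starts at zero and rising."""
        return replace(self, phase_shift_days=zero_start_shift(self.shape))


def phe_profile(f: PlasmaForcing, t) -> np.ndarray | float:
    """Plasma Phe concentration (uM) at time ``t`` (days).

    ``cf = 0`` returns the constant mean.  The fluctuation shape is
    normalised to unit peak magnitude over one period, which guarantees
    ``max Phe = phe_ss (1 + cf)``, ``min Phe = phe_ss (1 - cf)`` and
    non-negativity for any ``cf <= 1``.
    """
    if f.cf == 0.0:
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, f.phe_ss)
        return out if out.shape else float(f.phe_ss)
    peak = _peak(f.shape)
    if peak == 0.0:
        raise ValueError("all-zero fluctuation shape with cf > 0: "
                         "unit-peak normalization undefined")
    delta = fourier_value(f.shape, np.asarray(t, dtype=float) - f.phase_shift_days)
    return f.phe_ss * (1.0 + f.cf * delta / peak)


_PRESETS = {
    "c1": (300.0, 1.0, 0.99),
    "c2": (800.0, 3.0, 0.3),
    "c3": (1600.0, 0.14, 0.6),
}


def preset_case(name: str) -> PlasmaForcing:
    """The three exemplary plasma Phe fluctuation profiles c1-c3.

    (phe_ss, f0, cf) = (300, 1, 0.99), (800, 3, 0.3) and (1600, 0.14, 0.6),
    with physiologic CL.  The multi-harmonic waveforms used for display in
    the study are unpublished, so the shape defaults to a pure unit
    sinusoid; override ``shape`` for custom waveforms.
    """
    try:
        phe_ss, f0, cf = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None
    return PlasmaForcing(phe_ss=phe_ss, cf=cf, shape=pure_sinusoid(f0))


def with_supplement(f: PlasmaForcing, sl: float) -> PlasmaForcing:
    """Copy of ``f`` with supplemented-LNAA plasma level ``sl`` (uM >= 0)."""
    if sl < 0:
        raise ValueError("supplemented LNAA level must be >= 0")
    return replace(f, sl=sl)


def check_sweep_bounds(f0: float, cf: float) -> None:
    """Warn (but allow) requests outside the study's realistic ranges."""
    lo, hi = F0_BOUNDS
    if not (lo <= f0 <= hi):
        warnings.warn(
            f"f0={f0} cycles/day outside the realistic range [{lo}, {hi}]",
            stacklevel=2,
        )
    if not (0.0 <= cf <= 1.0):
        warnings.warn(f"cf={cf} outside [0, 1]", stacklevel=2)


def forcing_from_config(d) -> PlasmaForcing:
    """Build a :class:`PlasmaForcing` from a config mapping.

    Recognised keys: ``Phe_ss_P``, ``CL_ss_P``, ``cf``, ``f0``, ``a``,
    ``b`` (harmonic coefficient lists), ``SL_P``, ``preset``,
    ``zero_start``.  A ``preset`` provides defaults that explicit keys
    override.
    """
    d = dict(d or {})
    preset = d.pop("preset", None)
    base = preset_case(preset) if preset else PlasmaForcing(phe_ss=PLASMA_PHE_UM)
    f0 = float(d.pop("f0", base.shape.f0))
    a = tuple(float(x) for x in d.pop("a", base.shape.a))
    b = tuple(float(x) for x in d.pop("b", base.shape.b))
    zero_start = bool(d.pop("zero_start", False))
    fields = {
        "phe_ss": float(d.pop("Phe_ss_P", base.phe_ss)),
        "cl_ss": float(d.pop("CL_ss_P", base.cl_ss)),
        "cf": float(d.pop("cf", base.cf)),
        "sl": float(d.pop("SL_P", base.sl)),
        "shape": FourierSpec(f0=f0, a=a, b=b),
    }
    if d:
        raise KeyError(f"unknown forcing keys: {sorted(d)}")
    out = PlasmaForcing(**fields)
    return out.with_zero_start() if zero_start else out


def forcing_to_config(f: PlasmaForcing) -> dict:
    return {
        "Phe_ss_P": f.phe_ss,
        "CL_ss_P": f.cl_ss,
        "cf": f.cf,
        "f0": f.shape.f0,
        "a": list(f.shape.a),
        "b": list(f.shape.b),
        "SL_P": f.sl,
    }
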