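"""Carrier rate laws for LAT1, LAT2 and B0AT2, and the 1:1 antiport coupling.

All functions here are pure.  Net fluxes are in umol/min and signed toward
the second-named compartment of each membrane (MBEC for luminal LAT1, ISF
for abluminal LAT1, astrocyte for LAT2, neuron for B0AT2).

Rate-law algebra
----------------
Both species bind a single carrier site competitively, so the fractional
occupancy of the carrier by species ``s`` in a compartment with
concentrations (c_Phe, c_CL) and face constants (Km_Phe, Km_CL) is

    theta_s = (c_s / Km_s) / (1 + c_Phe / Km_Phe + c_CL / Km_CL).

LAT1 and LAT2 are obligatory 1:1 exchangers: translocation only happens as
a full exchange cycle that carries one amino acid in each direction.  The
net exchange rate between faces A and B is therefore driven by the
difference of the two cycle orientations,

    X = theta_Phe(A) * theta_CL(B) - theta_Phe(B) * theta_CL(A),

each species' candidate net flux is its own maximal rate times X (Phe
A->B positive, CL the exact opposite sign), and the two candidates are
reconciled by capping both at the smaller magnitude
(:func:`couple_exchange`), which enforces J_Phe = -J_CL exactly.  The
carrier-asymmetry ratio RK of LAT1 enters the MBEC-face occupancies only;
note that it cancels from the equilibrium condition X = 0, which reduces
to equality of the Phe:CL concentration ratios on the two sides.

B0AT2 co-transports one Na+ per amino acid into neurons and is electrogenic:
the negative neuronal membrane potential biases the forward (inward) and
backward rates by the Eyring factors eps and eps'.  Its two substrate
fluxes are independent (no antiport coupling):

    J_s = Vmax_s * [eps * theta_s(ISF) * phi(Na_ISF)
                    - eps' * theta_s(Neu) * phi(Na_Neu)],

with phi(Na) = (Na/Km_Na) / (1 + Na/Km_Na) the Na+-site occupancy.
"""

from __future__ import annotations

import math
from typing import NamedTuple, Tuple

from nvulnaa.params import AntiporterParams, Species, SymporterParams


class MembraneFlux(NamedTuple):
    """Signed per-species net flux through one membrane, umol/min."""

    phe: float
    cl: float


def occupancy(c_s: float, c_other: float, km_s: float, km_other: float) -> float:
    """Fractional carrier occupancy by the substrate under competition."""
    if c_s < 0 or c_other < 0:
        raise ValueError("concentrations must be non-negative")
    return (c_s / km_s) / (1.0 + c_s / km_s + c_other / km_other)


def competitive_unidirectional_rate(
    c_s: float, c_other: float, km_s: float, km_other: float, vmax_s: float
) -> float:
    """Unidirectional carrier rate Vmax_s * theta_s, umol/min.

    Saturates at ``vmax_s`` as c_s grows and decreases with the
    competitor's concentration.
    """
    return vmax_s * occupancy(c_s, c_other, km_s, km_other)


def couple_exchange(j_a: float, j_b: float) -> Tuple[float, float]:
    """Reconcile two candidate antiporter fluxes into a 1:1 exchange.

    Opposite-signed candidates are rescaled to the smaller magnitude,
    keeping their signs; same-signed (or vanishing) candidates cannot form
    an exchange cycle and yield (0, 0).  Output satisfies
    ``out_a == -out_b`` exactly.
    """
    if j_a == 0.0 or j_b == 0.0 or (j_a > 0) == (j_b > 0):
        return (0.0, 0.0)
    m = min(abs(j_a), abs(j_b))
    return (math.copysign(m, j_a), math.copysign(m, j_b))


def _exchange(
    conc_a: Tuple[float, float],
    conc_b: Tuple[float, float],
    km_a: Tuple[float, float],
    km_b: Tuple[float, float],
    vmax: Tuple[float, float],
) -> MembraneFlux:
    """Obligatory-exchange net flux from face A to face B (Phe positive A->B)."""
    tp_a = occupancy(conc_a[0], conc_a[1], km_a[0], km_a[1])
    tc_a = occupancy(conc_a[1], conc_a[0], km_a[1], km_a[0])
    tp_b = occupancy(conc_b[0], conc_b[1], km_b[0], km_b[1])
    tc_b = occupancy(conc_b[1], conc_b[0], km_b[1], km_b[0])
    x = tp_a * tc_b - tp_b * tc_a
    j_phe, j_cl = couple_exchange(vmax[0] * x, -vmax[1] * x)
    return MembraneFlux(j_phe, j_cl)


def _pair(mapping) -> Tuple[float, float]:
    return (mapping[Species.PHE], mapping[Species.CL])


def lat1_flux(
    outer: Tuple[float, float],
    mbec: Tuple[float, float],
    face: str,
    p: AntiporterParams,
) -> MembraneFlux:
    """Net LAT1 flux at one endothelial membrane.

    ``outer`` is (Phe, CL) in plasma (luminal face) or ISF (abluminal
    face); ``mbec`` is (Phe, CL) inside the endothelial cell.  Sign
    convention: positive Phe flux is toward MBEC at the luminal face and
    toward ISF at the abluminal face.  The asymmetry ratio RK multiplies
    the Michaelis constants on the MBEC face only.
    """
    km_out = _pair(p.km_cis(intracellular=False))
    km_in = _pair(p.km_cis(intracellular=True))
    if face == "luminal":
        return _exchange(outer, mbec, km_out, km_in, _pair(p.vmax))
    if face == "abluminal":
        return _exchange(mbec, outer, km_in, km_out, _pair(p.vmax_abluminal))
    raise ValueError(f"face must be 'luminal' or 'abluminal', got {face!r}")


def lat2_flux(
    isf: Tuple[float, float],
    ast: Tuple[float, float],
    p: AntiporterParams,
) -> MembraneFlux:
    """Net LAT2 flux across the astrocyte membrane, positive toward the
    astrocyte.  LAT2 is symmetric (RK = 1): the same absolute Michaelis
    constants apply on both faces."""
    km = _pair(p.km_abs)
    km_in = _pair(p.km_cis(intracellular=True))
    return _exchange(isf, ast, km, km_in, _pair(p.vmax))


def symporter_bias(p: SymporterParams) -> Tuple[float, float]:
    """Voltage-bias factors (eps, eps') of the neuronal symporter.

    eps = exp(-beta Z F dPsi / RT), eps' = exp((1-beta) Z F dPsi / RT);
    dPsi in volts.  They satisfy eps * eps' = exp((1-2 beta) Z F dPsi / RT)
    identically, and eps > 1 > eps' whenever dPsi < 0 and Z > 0.
    """
    return p.bias()


def na_site_occupancy(na: float, km_na: float) -> float:
    """Saturable Na+-site occupancy phi = (Na/Km) / (1 + Na/Km)."""
    x = na / km_na
    return x / (1.0 + x)


def b0at2_flux(
    isf: Tuple[float, float],
    neu: Tuple[float, float],
    p: SymporterParams,
) -> MembraneFlux:
    """Net B0AT2 flux, positive into the neuron; species are independent."""
    km = _pair(p.km)
    eps, eps_b = p.bias()
    phi_i = na_site_occupancy(p.na_isf_uM, p.km_na)
    phi_n = na_site_occupancy(p.na_neu_uM, p.km_na)
    out = []
    for idx, s in enumerate((Species.PHE, Species.CL)):
        th_i = occupancy(isf[idx], isf[1 - idx], km[idx], km[1 - idx])
        th_n = occupancy(neu[idx], neu[1 - idx], km[idx], km[1 - idx])
        out.append(p.vmax[s] * (eps * th_i * phi_i - eps_b * th_n * phi_n))
    return MembraneFlux(out[0], out[1])
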