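# Methods note

This note records the model equations, the conventions chosen where the
kinetic scheme admits more than one reading, the synthetic-forcing
generator, the numerical methods, and the known limitations.

## 1. State and mass balance

The state is the concentration (µM) of two species — Phe and the lumped
competing-LNAA pool CL — in four well-mixed compartments: microvascular
brain endothelial cells (MBEC, V = 3.5 µl), brain interstitial fluid
(ISF, 352.6 µl), astrocytes (742 µl) and neurons (441.7 µl). Plasma is an
infinite reservoir whose Phe and CL concentrations are inputs. With
membrane fluxes J in µmol/min (positive directions: luminal LAT1 → MBEC,
abluminal LAT1 → ISF, LAT2 → astrocyte, B⁰AT2 → neuron), mass balance per
species s is

```
dMBEC_s/dt = 1e6 (J_lum,s − J_abl,s) / V_MBEC
dISF_s/dt  = 1e6 (J_abl,s − J_LAT2,s − J_B0AT2,s) / V_ISF
dAst_s/dt  = 1e6 J_LAT2,s / V_Ast
dNeu_s/dt  = 1e6 J_B0AT2,s / V_Neu        [µM/min]
```

There is no metabolic consumption, protein incorporation, or CSF
clearance; transport is the only process.

## 2. Carrier rate laws

Both species compete for a single carrier site, so the fractional
occupancy of species s at concentrations (c_Phe, c_CL) with face constants
(Km_Phe, Km_CL) is

```
theta_s = (c_s/Km_s) / (1 + c_Phe/Km_Phe + c_CL/Km_CL).
```

**Obligatory antiporters (LAT1, LAT2).** Translocation occurs only as a
complete exchange cycle carrying one amino acid each way. The net cycle
drive between faces A and B is

```
X = theta_Phe(A)·theta_CL(B) − theta_Phe(B)·theta_CL(A),
```

each species' candidate flux is its maximal rate times X (Phe A→B
positive, CL opposite), and the pair is reconciled to the smaller
magnitude, enforcing J_Phe = −J_CL exactly. Equilibrium (X = 0) reduces to
equality of the Phe:CL concentration ratios on the two faces; the LAT1
asymmetry ratio RK = 80, which multiplies the Michaelis constants on the
MBEC face only, cancels from that condition. LAT2 is symmetric (RK = 1).
The abluminal LAT1 maximal rates are not independently constrained and
default to the luminal values (configurable keys `Vmax_LAT1_abl_*`).

**Electrogenic symporter (B⁰AT2).** One Na⁺ is co-transported per amino
acid into neurons. With Na-site occupancy φ(Na) = (Na/Km_Na)/(1 + Na/Km_Na)
and Eyring voltage-bias factors

```
eps  = exp(−β Z F ΔΨ / RT) ≈ 4.814,   eps' = exp((1−β) Z F ΔΨ / RT) ≈ 0.3507
```

(ΔΨ = −70 mV, β = 0.6, Z = 1, T = 310.15 K), the per-species net flux is

```
J_s = Vmax_s [ eps·theta_s(ISF)·φ(Na_ISF) − eps'·theta_s(Neu)·φ(Na_Neu) ].
```

Na⁺ levels (141 mM ISF, 40 mM neuron) are fixed parameters, not states.
The two species do not exchange-couple on this carrier.

## 3. Parameters

All kinetic constants, volumes and electrochemical parameters are stored
in a single flat registry (`nvulnaa.params._NOMINAL_FLAT`), tagged by
provenance (`literature` / `assumed`), and overridable through the YAML
config. Unknown keys are hard errors; every override is logged. Notable
conventions: Km_B⁰AT2_Na = 1050 µM as printed; body temperature 310.15 K.

## 4. Conservation structure and the initial condition

Because the antiporters move Phe and CL 1:1 in opposite directions, the
summed Phe+CL concentration of the MBEC (initially 260.3 µM) and of the
astrocyte (50.8 µM), and the summed ISF+neuron *amount*
(V_ISF·(ISF_Phe+ISF_CL) + V_Neu·(Neu_Phe+Neu_CL) ≈ 23 924 µM·µl), are
exact invariants of the dynamics. The steady state is therefore a
function of the initial condition, and the published physiologic state
(MBEC 24.6/235.7, ISF 0.03/0.3, Ast 4.8/46.0, Neu 7.0/46.9 µM) is part of
the model definition: every solve starts there
(`reference_initial_state()`).

## 5. Synthetic plasma forcing

Plasma Phe is `Phe(t) = Phe_ss · (1 + cf · δ(t)/max|δ|)` where δ is a
finite Fourier series `Σ aₙ sin(2πn f₀ t) + bₙ cos(2πn f₀ t)` and the
peak is taken on a 10⁴-point grid over one period, so `cf ∈ [0, 1]` is an
exact fractional excursion and Phe(t) ≥ 0. Plasma CL is constant
(739 µM); an LNAA supplement SL adds to the CL input. Exemplary cases:
c1 (300 µM, 1/day, cf 0.99), c2 (800 µM, 3/day, cf 0.3), c3 (1600 µM,
0.14/day, cf 0.6). Frequencies outside [0.14, 7] cycles/day trigger a
warning (extrapolation beyond the studied range).

## 6. Numerics

The system is stiff (volume ratio MBEC:Ast ≈ 1:212 gives minute-scale
endothelial and day-scale cellular dynamics), so only implicit
integrators are accepted (Radau, BDF, LSODA); requesting an explicit
method raises an error.

- **Steady states**: Radau relaxation over geometrically growing spans
  (100 min → ×10 → 10⁶ min cap) at rtol = atol = 10⁻¹⁰ until
  max|dC/dt| < 10⁻⁶ µM/min; failure raises with the achieved residual.
- **Transients**: LSODA at rtol = atol = 10⁻⁸ on a regular output grid;
  trajectories start from the matching constant-forcing steady state and
  flag one forcing period as transition. Infinitesimal negative
  undershoot (≤ 100·atol) is clipped at zero; anything larger is an error.
- **RMS excursion**: `sqrt(mean_t[((c(t) − c_ss)/c_baseline)²])` by
  trapezoidal quadrature. The measurement window is rounded up to a whole
  number of forcing periods (at least one) so the metric is
  phase-independent; the run span grows accordingly at low frequencies.
- **Sensitivity ensembles**: n independent draws of uniform multiplicative
  factors in [1−f, 1+f] on the 15 kinetic keys (Vmax, Km) and on the
  baseline normalisation values, from `numpy.random.default_rng(seed)`;
  bounds are nominal ± RMS deviation across draws.

## 7. Limitations

- **ISF and neuronal Phe at baseline.** The exchange-cycle antiport law
  conserves the ISF+neuron amount (Section 4), so relaxing from the
  published initial state redistributes it: the model's baseline settles
  at ISF 0.26/2.49 µM and neuronal Phe 4.90 µM rather than the published
  0.03/0.3 and 7.0 µM, while MBEC and astrocyte values match to < 0.4 %.
  Reproducing the published sub-µM ISF values would require either a
  qualitatively stronger neuronal uptake bias or additional clearance
  processes not present in the transport-only scheme. All trend analyses
  (dose–response, fluctuation propagation, supplementation) are unaffected
  in direction.
- The CL pool is a single kinetic species; intra-pool competition between
  individual LNAAs is not resolved, and supplements inherit the pool's
  kinetics.
- No protein synthesis, metabolism, CSF turnover, or blood-flow
  limitation; plasma is unaffected by brain exchange.
- Na⁺ gradients and membrane potential are static parameters.
- The rat-scale volumes and rates mean absolute fluxes should not be
  read as human predictions.

All quantitative claims in this note are computed by the test suite
(`tests/`) or the reproduction script (`scripts/acceptance.py`).
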