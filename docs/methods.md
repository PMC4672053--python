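# Methods

## Model

Leaf net CO2 assimilation follows the Farquhar–von Caemmerer–Berry
(FvCB) model for C3 photosynthesis with a hard minimum between the two
enzyme-limited states:

    A_c = V_cmax (C_c − Γ*) / (C_c + K_m) − R_d,   K_m = K_c (1 + O/K_o)
    A_j = J (C_c − Γ*) / (4 C_c + 8 Γ*) − R_d
    A_N = min(A_c, A_j)

Potential electron transport responds to irradiance Q through the
non-rectangular hyperbola, the smaller root of
θJ² − (αQ + J_max)J + αQ·J_max = 0 (θ → 0 degenerates continuously to
the rectangular hyperbola). Triose-phosphate-utilization limitation is
not modeled; apparent TPU points (assimilation decreasing over the
highest CO2 steps) are excluded from fits with a logged count.

CO2 reaches the chloroplast through two conductances in series,
stomatal (g_sc, CO2 basis) and mesophyll (g_m), with boundary-layer
conductance taken as infinite (cuvette fans):

    A_N = g_sc (C_a − C_i) = g_m (C_i − C_c)

`solve_steady_state` closes this chain against the FvCB demand with
bracketed root finding (scipy `brentq`, xtol 1e−12), guaranteeing a
flux residual below 1e−9 μmol m⁻² s⁻¹ for physiological conductances;
near the infinite-conductance limit the tolerance scales with the flux
resolution of a double-precision C_c (g_tot · ulp(C_c)), which is the
attainable bound there.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| Γ* | 37.43 | μmol mol⁻¹ | CO2 compensation point without R_d, 25 °C, chloroplastic basis |
| K_c | 272.38 | μmol mol⁻¹ | Rubisco CO2 Michaelis constant, chloroplastic basis, 25 °C |
| K_o | 165.82 | mmol mol⁻¹ | Rubisco O2 Michaelis constant |
| O | 210 | mmol mol⁻¹ | atmospheric oxygen |
| θ | 0.9 | – | light-response curvature |
| α | 0.3 | e⁻/photon | apparent quantum yield on incident light |
| R_d | 1.0 | μmol m⁻² s⁻¹ | day respiration when not estimated (Laisk) |
| f_PSII · α_leaf | 0.5 · 0.85 | – | J_flu conversion; species-dependent, exposed in config |
| g_m window | [100, 300] | μmol mol⁻¹ C_i | closed interval (inclusive reading), config-overridable |

No temperature scaling is applied anywhere: measurements are assumed
taken at the 25 °C block temperature the constants refer to. Stomatal
conductance is stored on a water-vapor basis and divided by 1.6 exactly
once, inside the diffusion computations; readers accept a
`gs_basis: CO2` dialect flag for tables already on a CO2 basis (the
bundled published means are such a table, used as printed).

## Estimation chain

1. **Fluorescence.** ΦPSII = (F_m′−F_s)/F_m′, qP, F_v/F_m, and
   J_flu = ΦPSII·PPFD·0.5·0.85. Negative ΦPSII (F_s > F_m′, an
   instrument artifact) is propagated with a flag, never clipped, so
   exclusion decisions downstream are reproducible.
2. **Day respiration.** From config, or from the Laisk method: lines
   fitted to the low-C_i (≤150 μmol mol⁻¹) portions of curves at ≥2
   distinct irradiances; their least-squares common intersection
   (C_i*, −R_d) solved by a 2×2 normal system, rejected as
   ill-conditioned when the slope spread is below tolerance. The
   bundled 13-step protocol is single-irradiance, so the pipeline
   defaults to a configured R_d.
3. **Mesophyll conductance.** Variable-J inversion per point;
   points are flagged invalid (and counted) when J_flu ≤ 4(A_N+R_d)
   (singular), when the implied C_c leaves (Γ*, C_i), or when A_N ≤ 0.
   The leaf's g_m is the arithmetic mean of valid window points and is
   reused for all C_c computations of that leaf.
4. **A–C_i fit.** On a chloroplastic basis when g_m is supplied
   (C_c = C_i − A_N/g_m), intercellular basis otherwise; the basis is
   recorded in the result. Given a limitation-state labeling, V_cmax
   and J (and optionally R_d) solve in closed form by linear least
   squares; labels are seeded by a C_i threshold (300 μmol mol⁻¹) and
   iterated until the labeling equals the fitted model's own minimum
   state at every point (ties to Rubisco). The procedure is fully
   deterministic — no optimizer, no restarts. J_max follows from
   inverting the light response at the measurement irradiance. A state
   holding fewer than two points makes its parameter under-determined:
   an error by default, or a flagged result (`jmax_identifiable=False`,
   with a lower bound for J_max inverted from the largest J_flu) in the
   pipeline.
5. **Partition.** Sensitivity coefficients at the same-day control
   reference: l_s = (g_tot/g_sc)·s/(g_tot+s), l_mc = (g_tot/g_m)·s/(g_tot+s),
   l_b = g_tot/(g_tot+s), s = ∂A/∂C_c; they sum to one identically.
   Components use simple fractional differences (x_ref − x)/x_ref (a
   log-difference variant is available); negative components (relief)
   are flagged, not clamped. For infinitesimal perturbations the
   partition converges to the exact differential of the coupled model;
   the biochemical term carries an O(R_d/A_N) bias because the
   sensitivity treats gross and net carboxylation interchangeably, a
   property inherited from the partitioning method itself.

**Choice of ∂A/∂C_c.** Three conventions are provided: the Rubisco
slope V_cmax(Γ*+K_m)/(C_c+K_m)², the RuBP slope J·12Γ*/(4C_c+8Γ*)², and
the default `model_min`, which differentiates the state *consistent
with the reference's observed A_N* (the state whose predicted rate is
closest to the measurement, ties to Rubisco). For model-generated
states this is exactly the minimum state. The observation-based
diagnosis matters for field data: published summary states are often
not reproducible by the bare minimum rule under any one constant set,
while the measured A_N identifies the operating regime unambiguously.
The MC_L/S_L ratio is invariant to this choice (the slope cancels).

## Synthetic campaigns

The generator emulates a combined IRGA/PAM campaign over the
treatment × day cells of the drought–recovery study: true g_sw, g_m,
V_cmax, J_max set to the published treatment means (g_sw = 1.6 × the
printed CO2-basis g_s), R_d = 1 μmol m⁻² s⁻¹, a 13-step C_a protocol
spanning 50–2000 μmol mol⁻¹ at PPFD 1000, with per-leaf curves and a
truth table. Every point is an exact steady state of the coupled model.

Fluorescence is generated *consistently with the gas exchange*: the
generating electron transport is the consumption rate
J = (A_N+R_d)(4C_c+8Γ*)/(C_c−Γ*) — equal to the potential
light-response J under RuBP limitation and below it under Rubisco
limitation, as a real fluorometer reports — folded into F_s at a fixed
F_m′ scale. Measurement noise is multiplicative Gaussian on A_N and F_s
only; CO2 set-points and PPFD are exact, and stomata do not drift
within a curve. A fixed integer seed makes output bit-identical.

What the generator does **not** emulate: day-to-day soil drying,
VPD/temperature covariance, stomatal patchiness, leakage/diffusion
errors of the cuvette, fluorescence detector drift, or alternative
electron sinks. Passing round-trip tests therefore demonstrate
correctness of the estimation algebra under the model's own
assumptions, not robustness to every artifact of real campaigns.

## Identifiability findings (tests that fail by design)

Two acceptance-level checks assert recoveries the study conditions
cannot support; they are kept failing rather than weakened, because
the failure is a property of the method, not of the implementation.

1. **J_max is unidentifiable from these curves.** With the published
   parameter magnitudes (J_max ≈ 4.2–4.4 × V_cmax against K_m ≈ 617),
   the potential J at saturating light exceeds ~4·V_cmax in every cell,
   so min(A_c, A_j) stays Rubisco-limited across the entire 50–2000
   μmol mol⁻¹ protocol (the state transition sits near C_c ≈ 10⁵).
   Consequently neither assimilation nor consumption-based fluorescence
   ever expresses J_max: the data contain a lower bound only, which the
   pipeline reports as such. The noiseless round trip recovers g_m to
   ~3e−15 and V_cmax exactly; a J_max "recovery" is asserted at 1% and
   fails, by construction of the physics.
2. **Variable-J collapses under 2% F_s noise at low ΦPSII.** Inside the
   averaging window these leaves operate at ΦPSII ≈ 0.08–0.11, so a 2%
   multiplicative F_s error maps to a 16–22% relative error on J_flu
   (factor (1−ΦPSII)/ΦPSII), which the inversion amplifies further via
   |dC_c/dJ_flu| = 12Γ*(A_N+R_d)/(J_flu−4(A_N+R_d))². The per-point g_m
   distribution becomes heavy-tailed with a validity-truncation bias
   that does not average away: cell means across 10 leaves err from
   <1% to several hundred percent. The 5% cell-mean assertion fails
   accordingly. With the same noise applied directly to J_flu at 1%,
   the estimator's bias is below 2% (verified by a separate property
   test) — the fragility is specifically the fluorescence-signal noise
   amplification at low operating ΦPSII, a practical caveat for
   applying the variable-J method to low-assimilation leaves.

## Numerical choices

- Root bracketing for the steady state: C_c ∈ (≈0, C_a + (R_d+1)/g_tot],
  where the balance function changes sign exactly once (supply is
  decreasing, demand nondecreasing in C_c).
- CSV output uses shortest round-trip float formatting; read-back is
  exact, comfortably inside the 12-significant-digit contract.
- Windows and intervals are closed on both ends.
- The fit's state iteration caps at 50 sweeps; ties in the minimum go
  to the Rubisco state so that re-runs are bit-identical.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; the seed is recorded in generated file
  headers and the pipeline manifest.

## Known limitations

Single-leaf, steady-state, 25 °C analysis only: no temperature response
functions, no C4 or TPU pathways, no NPQ/quenching kinetics, no
boundary-layer or cuvette-leak corrections, no statistics of group
comparison. Curvature-based (Ethier-type) g_m estimators and isotopic
methods are out of scope; g_m always comes from the variable-J module.
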