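# cuticle

Analysis pipeline for the **cuticular transpiration barrier** of plant
leaves: how much water a leaf loses after its stomata have fully closed,
and how that residual loss responds to temperature and to the chemistry
and phase state of the cuticular waxes.

The package targets ecophysiologists running gravimetric leaf-drying
assays. Its four analysis stages correspond to the four measurement kinds
of such a study:

1. **Drying curves → minimum conductance.** A detached, petiole-sealed
   leaf drying over silica gel yields a fresh-weight time series. From it,
   the relative water deficit

   RWD = 1 − (FW − DW)/(SW − DW),

   the transpiration flux *J* = ΔFW/(Δt·A) and the conductance
   *g* = *J*/(α_apo·C_wv,sat(T_leaf) − α_air·C_wv,sat(T_air)) are computed
   (over silica gel α_air ≈ 0, so the driving force is the saturation
   vapour concentration at leaf temperature, from a Magnus-type closed
   form). A two-segment fit of *g*(RWD) — linear decline plus constant
   plateau, breakpoint by exhaustive grid search — gives the minimum
   conductance **g_min** (plateau level) and **RWD_SC** (RWD at maximum
   stomatal closure, the segment intersection).
2. **Temperature response.** Per-temperature g_min values are transformed
   to Arrhenius coordinates (ln g_min vs 1/T_K). Single-line and
   two-segment fits are compared by an F-test with Bonferroni correction
   over the candidate breakpoints; a biphasic response yields a transition
   temperature (segment intersection) and an activation energy
   E_p = −slope·R from the high-temperature segment. Spearman trend tests
   and Shapiro–Wilk-gated Welch-t / Mann–Whitney comparisons accompany it.
3. **Wax chemistry.** GC-derived coverage tables are aggregated per
   compound class, converted to mole-based carbon chain-length
   distributions, and summarised by the weighted median chain length
   (MCL, the 50 % weighted percentile, satisfying
   Σ_{i<k} w_i ≤ ½ and Σ_{i>k} w_i ≤ ½) and by the <C40 / ≥C40 partition
   that isolates very-long-chain alkyl esters. Cutin depolymerisates are
   summarised by aliphatic/aromatic percentages and the C16:C18 acid ratio.
4. **Wax melting (ATR-FTIR).** The CH₂ asymmetric stretching band maximum
   (~2916–2924 cm⁻¹) is tracked over a heating ladder; melting onset,
   midpoint and completion are the 5/50/95 % crossings of the normalised
   band shift.

A seeded synthetic-data module generates all three input kinds with known
ground truth (two-phase conductance decline, Arrhenius-law replicate
studies, sigmoidal band shifts, species-template wax profiles), so every
stage is validated closed-loop without external data. Published summary
statistics for a water-spender (*Citrullus colocynthis*) and a water-saver
(*Phoenix dactylifera*) desert species are bundled in `cuticle.data` as
worked-example inputs.

## Worked example

```python
import cuticle as c
from cuticle.drying import interval_driving_forces

specimen, obs, truth = c.simulate_drying(
    c.DryingSimConfig(seed=7, balance_noise_sd=5e-4))
points = c.conductance_series(
    c.transpiration_series(obs, specimen),
    interval_driving_forces(obs), specimen)
print(c.fit_drying_curve(points))
```

```
GminResult(g_min=6.897e-05, rwd_sc=0.140, plateau_points=22, ...)
```

The fitted plateau (6.90×10⁻⁵ m s⁻¹) recovers the generator's true g_min
within 0.1 %, and the breakpoint (0.140) the configured stomatal-closure
deficit. Running `python examples/02_thermal_response.py` on the bundled
reference means prints the water-spender's biphasic Arrhenius fit —
high-temperature line ln g = 20.3 − 9.3×10³/T (p = 0.017), transition at
39.5 °C, E_p = 77.1 kJ mol⁻¹ — against the water-saver's flat response
(slope p = 0.087). The other `examples/` scripts exercise wax composition
and FTIR melting the same way, each printing the numbers it computes and a
line on what they mean.

A thin CLI mirrors the library for shell use:
`cuticle simulate|gmin|arrhenius|wax|ftir|all` (see `cuticle --help`).

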