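# osteobeam

Strength and deformation analysis of cancellous (femoral-neck) bone screws
modelled as beams on an elastic (Winkler) foundation under 2nd-order
theory, with a finite-difference verification oracle and a Monte-Carlo
(SBRA-style) reliability extension.

A screw of length `L` rests along its whole length on a foundation of
stiffness `k` [N/m²]. Stance loading yields a per-screw transverse force
`F1` (applied at the fracture-plane abscissae `L1`, `L2` with opposite
signs) and a constant axial compression `N = -F2`. Each of the three
segments obeys

```
EJ·v'''' - N·v'' + k·v = 0
```

and the twelve integration constants follow from free-end, continuity
and shear-jump conditions assembled into a 12x12 linear system. Field
extrema feed extreme-fiber normal stress, peak shear stress and the
yield-based safety factor `S_Re = Re / max(|sigma_MAX1|, |sigma_MAX2|)`.

## Layout

| module | contents |
| --- | --- |
| `osteobeam.sections` | solid/cannulated cross-sections, `A`, `J_ZT`, `W_o`, shear factor, catalog |
| `osteobeam.loading` | stance parameters → total and per-screw forces |
| `osteobeam.solver` | characteristic roots, 12x12 assembly (re-centered segment basis), fields, extrema; batched engine for Monte-Carlo |
| `osteobeam.stress` | stress extremes, peak shear, safety factor |
| `osteobeam.fdiff` | independent central-difference oracle (mixed `v`/`M` second-order form) |
| `osteobeam.sbra` | input distributions, seeded sampling, reliability function `RF = Re - |sigma_MAX|`, Wilson CI |
| `osteobeam.pipeline` / `config` / `report` / `fixtures` / `cli` | end-to-end runs, YAML config with unit-suffixed keys, CSV/JSON reports, seeded fixture generation |

Units: SI internally (m, N, Pa); configs and reports use mm / N / MPa /
N·mm. Conversion happens only in `osteobeam.config`.

## CLI

```sh
osteobeam solve examples/full_steel.yaml            # fields.csv + summary.json
osteobeam solve examples/full_steel.yaml --verify   # + analytic-vs-FD disagreement
osteobeam verify examples/full_steel.yaml
osteobeam sbra examples/cannulated_ti_sbra.yaml     # Monte-Carlo reliability
osteobeam fixtures --seed 1                         # seeded admissible parameter sets
```

The example configs use documented placeholder load/foundation values
(marked in the files); the published worked-example input sets are not
reproduced here.

## Notes on numerics

* Each segment's growing exponential basis function is referenced to the
  segment's right end and the decaying one to its left end; this exact
  reparametrization keeps the 12x12 block well conditioned for stiff,
  long screws (the plain global basis overflows its condition budget and
  is retained only for an equivalence test).
* The finite-difference oracle discretizes the mixed second-order system
  (`M_b = -EJ v''`; `-M_b'' - N v'' + k v = q`) rather than collocating
  the raw 4th-order operator: on fine grids `EJ/h⁴` and `k` share matrix
  entries and double precision rounds the foundation term away. A
  mixed-precision iterative-refinement step keeps the solve
  discretization-limited; observed convergence is cleanly 2nd order.
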