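# extruderquant

Quantitative-imaging analysis and stochastic simulation of SMC
loop-extruder dynamics during mitotic exit.

After cell division, the genome switches from a Condensin-based mitotic
organization to a Cohesin/CTCF-based interphase organization. Measuring
that transition in single cells takes a chain of quantitative microscopy
methods: FCS-calibrated imaging for absolute protein copy numbers,
photobleaching assays (FRAP, spot-bleach) for chromatin-bound fractions and
residence times, STED super-resolution for single-complex counting and
colocalization, and sequential-hybridization DNA tracing for 3D genome
structure. `extruderquant` implements the full downstream analysis chain
for these measurements, the per-megabase occupancy bookkeeping that ties
them together, and a two-species 1D loop-extrusion simulator for the
hierarchical nested-loop picture the numbers imply — in which a sparse,
long-lived extruder (Cohesin-STAG1 with CTCF) first builds TAD-scale loops
that a dense, short-lived extruder (Cohesin-STAG2) then fills with nested
sub-loops, pairing up on chromatin once its occupancy makes encounters
frequent.

The models at the core, in standard notation:

- FRAP normalized difference, fitted with
  `D(t) = a + (1 - a) exp(-koff t)` — `a` the stably bound fraction,
  `1/koff` the residence time of the exchanging pool;
- FCS autocorrelation
  `G(tau) = (1/N)(1 + tau/tauD)^-1 (1 + tau/(kappa^2 tauD))^-1/2`, with
  `V_eff = N/(C N_A)` and an intensity-to-concentration calibration line;
- occupancy arithmetic: bound copies = nuclear copies x bound fraction,
  per-Mb density = bound copies / genome Mb, loop size = `v / koff`,
  encounter probability `1 - exp(-density x loop_kb / 1000)`;
- a fixed-timestep 1D lattice loop-extrusion model with two-arm growth,
  CTCF boundary stalling at oriented sites, mutual blocking and optional
  pairing on encounter;
- median pairwise 3D distance matrices, 120 nm contact maps, difference
  matrices and distance-vs-separation scaling curves for chromatin traces.

Every module has a synthetic-data twin in `extruderquant.synthetic` that
generates its inputs with known ground truth, so the whole pipeline is
testable end to end without any imaging data. See `docs/methods.md` for
models, assumptions, defaults and limitations.

## Worked example

```python
from extruderquant import occupancy as occ
from extruderquant.simulation import SpeciesParams, simulate

table = occ.build_occupancy_table(occ.load_table_fixture())
g1 = table.query("stage == 'G1' and protein in ['CTCF','RAD21','STAG1','STAG2']")
print(g1[["protein", "nuclear_copies", "bound_fraction_used",
          "bound_copies", "per_mb_display", "longterm_per_mb_display"]]
      .to_string(index=False))

print(f"loop size at 1 kb/s for 120 s: {occ.loop_size(1.0, 120.0):.0f} kb")
for d in (3.0, 8.0):
    print(f"encounter probability at {d:.0f}/Mb: "
          f"{occ.encounter_probability(d, 120.0):.3f}")

sp = SpeciesParams("stag2", loading_rate=8/120, koff=1/120, speed=1.0,
                   pair_on_encounter=True)
res = simulate(lattice_mb=25.0, species=[sp], duration=1200.0, seed=1)
print(f"simulated STAG2-like occupancy: {res.steady_state_density('stag2'):.2f}/Mb, "
      f"mean completed loop {res.loop_sizes.mean():.0f} kb, "
      f"paired fraction {res.paired_fraction:.2f}")
```

prints

```
protein  nuclear_copies  bound_fraction_used  bound_copies  per_mb_display  longterm_per_mb_display
   CTCF          124000                 0.72       89280.0             5.7                      2.8
  RAD21          238000                 0.77      183260.0            11.6                      3.2
  STAG1           53500                 0.76       40660.0             2.6                      1.0
  STAG2          183000                 0.71      129930.0             8.2                      0.9

loop size at 1 kb/s for 120 s: 120 kb
encounter probability at 3/Mb: 0.302
encounter probability at 8/Mb: 0.617

simulated STAG2-like occupancy: 6.78/Mb, mean completed loop 75 kb, paired fraction 0.65
```

The table rows are the G1 occupancy summary derived from the packaged raw
measurements: e.g. 183,000 nuclear STAG2 copies at a 71% bound fraction put
~130,000 complexes (8.2 per Mb) on chromatin, of which ~11% are long-term
bound. At that density an extruder making 120 kb loops has a ~62% chance of
overlapping a neighbour, versus ~30% at the early-G1 density of 3 per Mb —
the closed-form version of the concentration-dependent pairing the
simulator reproduces (paired fraction 0.65 at high density). In the
crowded regime the mean completed loop (75 kb) falls below the free-space
`v/koff` = 120 kb because neighbouring extruders block each other; the
single-run occupancy readout (6.78/Mb over a 20-minute window) fluctuates
around the loading/unloading balance of 8/Mb.

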