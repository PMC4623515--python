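# rootflux

A two-dimensional, grid-based simulator of auxin and cytokinin transport and
cross-regulation in a transverse *Arabidopsis* root cross-section, with
explicit cells, cell walls and hormonally regulated membrane transporters.

The package covers:

* idealized (geometric) and segmented-image cross-section geometries,
  rasterized onto a square lattice with an explicit apoplast;
* membrane transport with background permeabilities plus PIN-family efflux
  carriers and an auxin importer, whose activities are Hill functions of the
  local hormone state (cytokinin-up / auxin-down for PIN1/PIN7, auxin-up for
  PIN3 and the lateral-root importer);
* an alternating-direction-implicit (ADI) time stepper and a direct sparse
  steady-state solver over the identical discretization;
* transporter-layout variants (knockouts, apolar rewiring, lateral-root
  context), cytokinin-gradient feasibility scans, steady-flux decomposition
  into radial/angular components, DR5-style heat-map rendering, and a pulse
  competition protocol for importer bistability;
* a config-driven scenario catalogue (`rootflux.scenarios.PRESETS`) exposing
  every study scenario as a named preset, runnable from Python or the CLI.

See [docs/methods.md](docs/methods.md) for the model equations, numerics,
measured behaviour and known limitations.

## Quickstart

```python
from rootflux.scenarios import get_preset, run_scenario

cfg = get_preset("fig4f_wildtype_dynamic", desk_scale=True)
res = run_scenario(cfg)

print(res.cell_table().head())      # per-cell means and transporter activities
res.write("out/wildtype")           # cells.csv, heat maps, state.npz, provenance.yaml
```

Pulse competition in the lateral-root context:

```python
from rootflux.scenarios import get_preset, pulse_competition

cfg = get_preset("fig11_pulse_xylempole", desk_scale=True)
comp = pulse_competition(cfg, ["pericycle@0"], delay=0.0)
print(comp.winner, comp.final_E)
```

## Command line

```bash
rootflux list-presets                     # catalogue with descriptions
rootflux run fig4f_wildtype_dynamic --desk-scale --out out/wt
rootflux run fig7_p0.01_d0.6 --set dx=0.5 --set wall_thickness=1.0
rootflux fixtures out/fixtures            # regenerate tiny test geometries
```

Exit codes: 2 for configuration errors, 3 for numerical failures.

## Resolution and desk scale

Full scale is `dx = 0.3 µm` (wall 0.6 µm).  `desk_scale=True` coarsens to
0.75/1.5 µm for steady runs and 1.0/2.0 µm for pulse runs — our own
documented choice so full-anatomy scenarios complete in minutes on one CPU;
qualitative outcomes were checked across the ladder (docs/methods.md §2).

## Tests and headline targets

```bash
python -m pytest -o addopts= -p no:cacheprovider -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes five headline targets from scratch and
writes them as JSON.  Two acceptance tests fail honestly at the published
parameter set — the dynamic importer-knockout axis ratio and the delayed
two-pulse winner — with quantified analyses in docs/methods.md
("Known limitations"); all other tests are green.  The model is fully
deterministic; `--seed` is accepted and logged for protocol compatibility
only.

## Layout

```
src/rootflux/
  geometry.py    templates, rasterization, face classification, label IO
  regulation.py  Hill functions, transporter activity, auxin-driven synthesis
  layouts.py     transporter placements, condition rewiring, grid binding
  dynamics.py    simulator: ADI stepper, direct steady solver, pulses
  analysis.py    flux decomposition, profiles, gradient classifier, heat maps
  scenarios.py   configs, preset catalogue, scenario runner, pulse competition
  cli.py         click-based CLI
scripts/acceptance.py   headline-target recomputation
docs/methods.md         model description and measured behaviour
```
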