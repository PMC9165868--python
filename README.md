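# hepatolip

A kinetic simulator of in vitro hepatocyte cholesterol and lipoprotein
metabolism.  The model is a 21-state ODE system coupling:

- SREBP-2-mediated transcription of HMGCR, LDLR and PCSK9 with Hill-type
  cholesterol feedback;
- receptor-mediated endocytosis of LDL and VLDL with partial receptor
  recycling, VLDL→LDL delipidation and a constant VLDL source;
- PCSK9 secretion, PCSK9-LDLR binding and degradation of internalised
  PCSK9-bound receptors (no recycling);
- three therapy mechanisms: statins (cell uptake + HMGCR sequestration),
  anti-PCSK9 antibodies and small-molecule inhibitors (1:1 binding of
  extracellular PCSK9).

Both the dimensional system (molecules/mL, seconds) and the rescaled
dimensionless system are implemented; the simulator integrates the
dimensionless form and the test suite verifies trajectory equivalence of the
two under the packaged reference scales.

## Library quick start

```python
import hepatolip as hl
from hepatolip.scenarios import baseline_scenario
from hepatolip.simulate import integrate, find_steady_state

params = hl.default_parameters()                      # packaged defaults
s = baseline_scenario(params, p_E0=1e12, horizon_h=200.0)
run = integrate(s)                                    # stiff LSODA, event-aware
run.write_csv("trajectory.csv")                       # dimensional units
ss = find_steady_state(s)                             # residual + stability
```

Scenario presets (`hepatolip.scenarios`) reproduce the published in-silico
experiments: baseline kinetics, the PCSK9 concentration scan
(`pcsk9_threshold_scan`), a timed PCSK9 influx pulse, single-dose statin
therapy, anti-PCSK9 antibody vs small-molecule therapy, combined therapy, and
the recycling-fraction matching analysis.  `hepatolip.sensitivity` provides
local (central finite-difference, log-log) sensitivity of steady-state
outputs to the PCSK9-pathway and therapy parameters.

## CLI

```bash
hepatolip simulate --config run.yaml          # inline scenario from YAML
hepatolip scenario fig2_baseline              # packaged figure presets
hepatolip scenario fig5_statin --param CL_S=0.02
hepatolip scenario fig3_threshold             # PCSK9 scan analysis
hepatolip scan --spec sweep.yaml              # 1-D sweep (CSV out)
hepatolip sensitivity --targets pcsk9         # sensitivity table (CSV out)
hepatolip convert 1e12 molec./mL ng/mL        # ~100 at the 60 kDa convention
```

Presets: `fig2_baseline`, `fig4_pcsk9_pulse`, `fig5_statin`, `fig6_antibody`,
`fig7_small_molecule` (trajectory runs, shipped as diffable YAML configs
under `hepatolip/data/presets/`), plus the `fig3_threshold` and
`fig8_combined` analyses.  Every run writes a trajectory/metrics CSV, a
`metadata.json` sidecar (config hash, package version, parameter provenance,
solver diagnostics, event log, seed) and a `run.log`.

## Parameters

Defaults ship in `src/hepatolip/data/parameters.tsv` as flat
name/value/units/provenance records.  Published values carry the `table1`
tag and load exactly as printed; values inherited from the parent
endocytosis model are tagged `parent_model`; everything else is tagged
`assumed`, chosen so that all steady-state concentrations are positive and
finite, and can be overridden from any config or via
`default_parameters(name=value)`.

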