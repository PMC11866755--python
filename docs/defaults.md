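# Configuration defaults

Generated from the configuration schema (`cphlab.io.KNOWN_KEYS`); the test suite keeps this file in sync.

| key | default | description |
| --- | --- | --- |
| `lambda-dynamics` | yes | enable lambda dynamics |
| `simulation-ph` | 7 | simulation pH (single-run commands) |
| `lambda-mass` | 60 | lambda particle mass (u) |
| `lambda-dt` | 0.002 | lambda integration step (ps) |
| `lambda-save-interval` | 0.5 | protonation state save interval (ps) |
| `lambda-thermostat-tau` | 1 | CSVR thermostat coupling time (ps) |
| `lambda-thermostat-temperature` | 300 | lambda thermostat temperature (K) |
| `lambda-equilibration-time` | 50 | low-barrier equilibration run (ps) |
| `double-well-barrier` | 6 | starting central barrier (kJ/mol) |
| `dbo-adjust-wells` | no | enable dynamic well-position optimization |
| `dbo-adjust-barrier` | no | enable dynamic barrier optimization |
| `dbo-well-block` | 40 | well statistics block (ps) |
| `dbo-occupancy-threshold` | 0.7 | well occupancy gate (fraction) |
| `dbo-mean-tolerance` | 0.03 | well mean-lambda tolerance |
| `dbo-shift-gain` | 0.5 | well shift gain |
| `dbo-max-shift` | 0.08 | maximum cumulative well shift |
| `dbo-barrier-block` | 1000 | barrier statistics block (ps) |
| `dbo-barrier-increment` | 1 | barrier adjustment increment (kJ/mol) |
| `dbo-barrier-min` | 1 | barrier lower clamp (kJ/mol) |
| `dbo-barrier-max` | 20 | barrier upper clamp (kJ/mol) |
| `dbo-target-fraction` | 0.25 | target in-transition frame fraction |
| `dbo-fraction-tolerance` | 0.05 | in-transition fraction tolerance |
| `dbo-censor-duration` | 10 | censoring window after adjustments (ps) |
| `buffer-charge-deprot` | -0.834 | buffer oxygen charge, deprotonated (e) |
| `buffer-charge-prot` | 0.166 | buffer oxygen charge, protonated (e) |
| `scenario` | 'single' | scenario tag (single | tautomer | coupled_pair | conformation_coupled | spread_replica) |
| `reference-pka` | 4.4 | reference pKa of the (first) site |
| `micro-pka-delta` | 6.53 | microscopic delta-tautomer reference pKa |
| `micro-pka-epsilon` | 6.92 | microscopic epsilon-tautomer reference pKa |
| `second-site-pka` | 4 | reference pKa of the second site |
| `coupling-w` | 0 | bilinear site-site coupling (kJ/mol) |
| `conf-delta-pka` | 2 | pKa shift between conformational basins |
| `conf-barrier` | 6 | conformational double-well barrier (kJ/mol) |
| `conf-diffusion` | 0.05 | conformational diffusion coefficient (1/ps) |
| `n-replicas` | 10 | replicas per pH point |
| `replica-duration` | 2000 | sampling time per replica (ps) |
| `ph-grid-step` | 0.5 | titration pH grid step |
| `ph-grid-margin` | 1 | pH grid margin beyond extreme pKa values |
| `seed` | 0 | global random seed |
| `bootstrap-samples` | 5000 | bootstrap resamples for confidence intervals |
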