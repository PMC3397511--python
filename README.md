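# gridqsar

Grid-based 3D-QSAR in Python: CoMFA-style steric/electrostatic and
CoMSIA-style similarity fields on a shared lattice, PLS regression with
leave-one-out model selection, a full external-validation battery
(r²_pred, through-origin diagnostics, Roy's r²_m, the five-condition
acceptability gate, y-randomization, bootstrap, repeated k-fold CV) and
Stdev*Coeff contour-map export (OpenDX + PyMOL scripts).

The package ships a 71-compound thiourea MK-2 inhibitor series as a worked
fixture: a series definition (scaffold SMILES + R-group lookup), the
experimental and model-predicted pIC50 table with its 53/18 train/test
split, and a common-scaffold SMARTS for template alignment.

## Layout

| module | role |
|---|---|
| `gridqsar.chem_dataset` | molecule/activity IO, Gasteiger charges, packaged series, train/test splitting |
| `gridqsar.alignment` | Kabsch superposition, common-substructure template alignment |
| `gridqsar.fields` | grid construction, LJ/Coulomb/Gaussian field kernels, column filtering + block scaling |
| `gridqsar.pls_engine` | NIPALS PLS1, LOO q²/SEP, component selection, training stats, field contributions, Stdev*Coeff grids |
| `gridqsar.model_validation` | external metrics, acceptability gate, y-randomization, bootstrap, repeated k-fold |
| `gridqsar.contour_maps` | favored/disfavored voxel extraction, OpenDX round-trip, viewer scripts |
| `gridqsar.synthetic_data` | aligned pseudo-molecule generator with planted field→activity signal |
| `gridqsar.cli_pipeline` | end-to-end orchestration + `gridqsar` CLI |

## CLI

```sh
gridqsar run --mode metrics_only --output-dir out/   # metric layer on the packaged predictions
gridqsar run --mode full --output-dir out/           # structures -> fields -> PLS -> validation -> contours
gridqsar synth --n 60 --seed 0 --out-prefix toy      # synthetic benchmark set
gridqsar align --template 70 --in set.sdf --out aligned.sdf --report rmsd.csv
gridqsar fields --aligned aligned.sdf --model comfa --out-prefix fields
gridqsar train --matrix fields_matrix.csv --activity activity.csv
gridqsar validate --obs-pred predictions.csv
```

`run` also accepts `--config config.yaml`; every run writes its resolved
configuration, a JSON report, logs and (in full mode) per-compound
predictions and contour exports into the output directory.

Two pipeline modes exist because conformer generation and charge models
differ between toolkits: `metrics_only` feeds the packaged per-compound
predicted values through the metric layer (tight, deterministic
reproduction), while `full` rebuilds everything from structures (the
training-set statistics are then approximate by construction).

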