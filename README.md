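# modlys

Structure-based triage of lysine chemical-modification sites and
enzyme-stability statistics, packaged as a reusable, tested pipeline.

Given a protein structure (PDB), a per-residue pKa table (as produced by
PROPKA-class tools) and activity assay tables, `modlys` computes:

- **Surface analysis** — atomistic solvent-accessible surface area
  (Shrake–Rupley quadrature, 1.4 Å probe by default), per-residue relative
  exposure against Gly-X-Gly reference maxima (exposed ⇔ relative SASA
  ≥ 20%), and the hydrophobic (C,S) vs hydrophilic (N,O) surface partition.
- **Lysine triage** — reactivity index `10^(pH − pKa)` with low/semi/high
  classes (boundaries 0.1 and 1.0, inclusive to semi), salt-bridge
  detection (charged side-chain N to carboxylate O within 4.0 Å),
  NZ–NZ/Cα–Cα crosslinker span feasibility, and an integrated ranked
  candidate list (candidate ⇔ exposed and not salt-bridged).
- **Stability kinetics** — TNBS standard curves and degree of modification,
  first-order thermal-inactivation fits (`kd`, half-life `ln 2/kd`, fit
  diagnostics, stabilization ratio `R`), pH/temperature optimum summaries
  and inhibitor residual-activity tables.
- **Synthetic data** — deterministic generators for toy structures with
  controlled exposure/bridge/crosslink geometry, exponential decay series
  and standard-curve absorbances, used as ground truth throughout the
  test suite.

## Command line

```sh
# lysine triage on a structure + pKa table, at the agent's modification pH
modlys profile --structure model.pdb --pka pka.tsv --agent CA --out-dir out/

# per-variant inactivation kinetics vs a control (long TSV: variant, time_min, activity)
modlys stability --assay decay.tsv --control EM_control --out-dir out/

# degree of modification from TNBS-derived free-lysine concentrations
modlys dm --sample 0.37 --control 1.0

# synthetic fixtures from a JSON spec
modlys simulate --spec spec.json --out-dir fixtures/
```

`profile` writes `triage.tsv` (per-lysine exposure, pKa, reactivity,
bridge partners, candidate verdict, rank) and `profile.json` (bridges,
crosslink pairs, surface partition, resolved configuration). `stability`
writes a table of raw and rounded `kd`/`t½`/`R` per variant. All reports
embed the resolved configuration; re-runs on identical inputs are
byte-identical.

## Package layout

| module | contents |
| --- | --- |
| `modlys.structure_io` | PDB parsing/writing, pKa and assay TSV readers, sequence extraction |
| `modlys.surface_analysis` | Shrake–Rupley SASA, residue exposure, surface partition |
| `modlys.lysine_triage` | reactivity scoring, salt bridges, crosslink pairs, site triage |
| `modlys.stability_kinetics` | standard curves, DM, inactivation fits, profile summaries |
| `modlys.synthetic_data` | ground-truth structure/decay/absorbance generators |
| `modlys.pipeline_cli` | `modlys` CLI and report writers |
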