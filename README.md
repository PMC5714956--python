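# confsel

NMR analysis toolkit for detecting **conformational selection** in the binding
of partially disordered helical peptides to globular domains. It implements,
as a reusable pipeline:

- **Chemical-shift analysis** — secondary shifts against packaged random-coil
  references, windowed secondary-structure propensity (SSP) scores,
  chemical-shift-index (CSI) consensus, helix populations from 3J(HN-HA)
  couplings, sequential-NOE intensity-ratio classification
  (`confsel.shifts`).
- **Chemical shift perturbation (CSP) mapping** — weighted-average amide
  shift changes between free and bound states (`confsel.shifts.csp`).
- **RDC analysis** — amide N-H bond vectors, Saupe alignment-tensor fitting
  by SVD least squares, RDC back-calculation, Q factor, Pearson correlation,
  and tensor comparison via the normalized scalar product (`confsel.rdc`).
- **Structure machinery** — multi-model PDB I/O, helix-axis fitting,
  interhelical angles, rigid-body helix rotations, Kabsch superposition and
  ensemble backbone RMSD (`confsel.structure`).
- **Ensemble preorganization test** — a rigid-helix/flexible-linker pivot
  sampler with hard-sphere clash checks, average-linkage RMSD clustering with
  an automatic spread-vs-count penalty cut, interhelical-angle filtering and
  per-conformer Q evaluation against free-state RDCs (`confsel.ensemble`).
- **Synthetic data** — ideal-geometry peptide builders (two-helix topology at
  a target interhelical angle) and seeded simulators for every observable the
  pipeline consumes (`confsel.synthetic`).

## Command-line pipeline

```sh
confsel fixtures     --out run/fixtures --seed 0      # synthetic input set
confsel free-peptide --shifts run/fixtures/free_shifts.tsv \
                     --j run/fixtures/free_j.tsv --out run/free
confsel csp          --free run/fixtures/csp_free_shifts.tsv \
                     --bound run/fixtures/csp_bound_shifts.tsv --out run/csp
confsel rdc-fit      --structure run/fixtures/bound_peptide.pdb \
                     --rdcs run/fixtures/bound_rdcs.tsv --out run/rdc
confsel preorg       --structure run/fixtures/bound_peptide.pdb \
                     --free-rdcs run/fixtures/free_rdcs.tsv \
                     --bound-rdcs run/fixtures/bound_rdcs.tsv \
                     --out run/preorg --seed 0 --n-conformers 300
confsel all          --out run --seed 0               # everything in sequence
```

Every stage writes TSV/JSON results plus a `manifest.json` with all inputs,
parameters and seeds. Plots (`--plot`) are optional artifacts.

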