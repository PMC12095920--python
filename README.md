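# apichap

Analysis pipeline for chaperone inhibition of amyloid aggregation, in two
halves:

1. **Aggregation kinetics** — plate-reader ThT time courses are averaged,
   control-subtracted, normalized and fitted to a sigmoidal transition
   between two straight lines (parameters `m1, n1, m2, n2, k, t05`).
   Half-times are compared via two-sample Z statistics, and log-log
   half-time vs monomer-concentration slopes discriminate aggregation
   mechanisms. Moment-equation forward models (nucleation-elongation,
   secondary nucleation, fragmentation, saturating elongation +
   fragmentation) can be fitted globally across a concentration series and
   ranked by mean residual error.
2. **Coarse-grained binding simulation** — one-bead-per-residue Langevin
   dynamics of a folded domain (native-topology 12-10 contacts, harmonic
   bonds/angles, cosine dihedrals extracted from a reference PDB) plus a
   disordered chain (bonds only), interacting through excluded volume,
   Debye-Hückel electrostatics (±1e on Lys/Arg/Asp/Glu, screening length
   from the ionic strength) and hydrophobicity-scaled attraction.
   Trajectories are reduced to residue-residue interaction-probability heat
   maps (6 Å cutoff, optional 3-residue binning) and contiguous interface
   segments.

A `synth` module generates every input the pipeline needs (sigmoid plates
with Gaussian noise, kinetic-model concentration series, Cα-only mini-domain
PDB fixtures, disordered sequences including the built-in 129-residue
four-repeat tau fragment), each with a ground-truth JSON sidecar.

## CLI

```bash
# generate a synthetic plate, fit every condition, run the scaling analysis
apichap synth plate --spec plate.yaml --out data/
apichap kinetics fit --plate data/plate.csv --meta data/meta.csv --out fits.csv
apichap kinetics scaling --fits fits.csv --out scaling.csv

# mechanism fitting / selection on a concentration series
apichap mech fit --curves curves.csv --model fragmentation --out fit.json
apichap mech compare --curves curves.csv --models all --out mre_table.csv

# coarse-grained run and contact analysis
apichap cg run --structure api.pdb --range 223:383 --idp tau4R.fasta \
    --config cg.yaml --out runs/
apichap contacts --trajs runs/ --cutoff 6 --bin 3 --out heatmap.tsv
```

`cg run` writes per-replica XYZ trajectories, per-frame energy CSVs and a
`topology.json`; `contacts` consumes that directory and emits a TSV heat map
plus a BED-like segments file. All runs are deterministic for a fixed seed.

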