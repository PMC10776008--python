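# scwforge

Rule-based construction of atomistic hardwood secondary-cell-wall (SCW)
models — cellulose elementary fibrils, decorated glucuronoxylan, and
syringyl/guaiacyl lignin — together with the analysis stack used to score
such models against solid-state NMR spin-diffusion observables:

- **polymer builders** — 18-chain cellulose I&beta; fibrils (234432
  cross-section, DP 40), &beta;(1&rarr;4) xylan with acetyl decorations on
  every other residue and glucuronate every eighth, and lignin 20-mers
  (13 S : 7 G, 80 % &beta;-O-4) in extended or globular shapes;
- **scenario assembly** — periodic whole-wall models under ten named
  packing scenarios (letters `a`–`h`, `b.8`, `b.10`, equivalently Roman
  numerals i–x), plus density compression and moisture solvation with
  charge neutralization;
- **proximity analysis** — percentage of sink carbons within 1 nm of
  source carbons (acetyl methyls, lignin ring carbons) under periodic
  boundaries, cell-list accelerated and oracle-checked against a
  brute-force scan;
- **conformation analysis** — glycosidic &phi;+&psi; sums, the
  acetate-face dihedral &theta;<sup>2f</sup>(O&#8322;–C&#8325;–C&#8325;–O&#8322;),
  and cellulose-bound/unbound chain classification;
- **spin-diffusion quantification** — pseudo-Voigt deconvolution of
  assigned 1D spectra, selective/nonselective recovery fractions with
  error propagation, saturating-exponential T_SD fits, and distance-range
  classification;
- **synthetic data** — spectra, recovery series and jittered coordinate
  frames with serialized ground truth, so the full pipeline is testable
  offline.

## CLI

A single entry point `scwforge` with subcommands:

```sh
# assemble scenario b.8, compress to 1.5 g/cm3, solvate to 3 % moisture
scwforge build --scenario b.8 --density 1.5 --moisture 3 --seed 42 \
    -o model.pdb --report report.json

# the four source->sink proximity percentages at 1 nm
scwforge proximity model.pdb --cutoff-nm 1.0 --out profile.json

# torsion metrics for one chain
scwforge torsions model.pdb --chain 72 --metric theta2f --hist hist.csv

# synthetic recovery dataset + T_SD fit
scwforge synth recovery --seed 5 --outdir rec/
scwforge nmr fit-recovery --selective rec/sel_00_tau0.001ms.csv \
    --nonselective rec/ref_00_tau0.001ms.csv --tau 0.001 ... --out fit.json

# rank models against the ssNMR reference percentages
scwforge scorecard a.pdb b8.pdb --out scores.csv
```

All subcommands honor `--seed`; reports are stamped with the seed, a
configuration hash and the package version.

## File conventions

- Coordinates are Angstrom everywhere; nanometres appear only at the CLI
  boundary (1 nm cutoff = 10 &Aring;).
- PDB: the polymer class is encoded in the chainID column and the first
  segid character (`C` cellulose, `X` xylan, `L` lignin, `W` water, `I`
  ion); the remaining segid digits carry the chain number modulo 1000, and
  an orthorhombic box is written as CRYST1. This makes write&rarr;read
  round-trips bit-faithful for class, labels and topology.
- XYZ: element + coordinates with a `box=a b c` comment line.
- Residues are numbered from the reducing end; decoration residues (ACE,
  GLCA) follow the backbone indices and are tied to their parent xylose
  geometrically (acetyl carbonyl bonded to the parent O2/O3).
- Builders emit heavy atoms only; masses include per-residue implicit
  hydrogens so that densities are comparable to all-atom bookkeeping.

## Notes on fidelity

Compression is a deterministic seeded scale-and-relax loop, not molecular
dynamics; built models represent initial packings (the proximity ordering
across scenarios, not equilibrated ensembles). The experimental reference
percentages (80/40/60/20) and the T_SD distance anchors are configurable
constants, not derived quantities.
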