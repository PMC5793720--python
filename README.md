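# mutstab

Knowledge-based prediction of the effect of point mutations on protein
stability, for structural biologists and protein engineers who have a PDB
file and want a fast, interpretable stability-difference score — no
training data, no energy minimisation.

## The method

Amino-acid substitution patterns in protein families depend strongly on
the local structural environment of a residue: buried, tightly packed
positions conserve bulky hydrophobics, while exposed positions exchange
freely. `mutstab` captures this with **environment-specific substitution
tables (ESSTs)**: conditional probability tables *P(k | j, env)* estimated
from structure-annotated family alignments, one 20×20 table per discrete
environment class.

Each residue's environment is described by five descriptors computed from
heavy-atom geometry:

* **mainchain conformation** — nine Ramachandran classes (α, near-α, β,
  polyproline, coil, left-handed α, other positive φ, cis-peptide,
  undefined);
* **RSA** — relative sidechain solvent accessibility (%; Shrake–Rupley
  dot SASA over an extended Gly-X-Gly reference); residues with RSA < 17%
  count as buried;
* **OSP** — occluded surface packing, the ray-length-weighted fraction of
  the residue's van der Waals surface occluded by non-bonded atoms within
  a 2.8 Å (water-diameter) shell;
* **residue depth** — mean distance of the residue's atoms from the
  solvent-accessible surface (Å);
* **sidechain hydrogen bonding** — a 3-bit class: bonds to mainchain
  amide N, to mainchain carbonyl O, to other sidechain/hetero partners.

The default scheme combines 9 mainchain × 3 OSP × 8 H-bond classes = 216
environments; alternatives use depth (216), RSA (legacy 54) or a
combination (648).

For a mutation *j → k* the pseudo-ΔΔG is

```
ΔΔs = Δs_U − Δs_F − (Δs_Disrupt + Δs_Cavity)
```

where `Δs_F = ½[ln(P(j|j,e_wt)/P(k|j,e_wt)) + ln(P(k|k,e_mut)/P(j|k,e_mut))]`
is the symmetrized conservation log-odds in the wildtype structure's
environment `e_wt` and the mutant model's environment `e_mut`, `Δs_U` is
the same quantity on the environment-marginal ("unfolded state") table,
`Δs_Disrupt = ln(1 + |ΔA_sc|/100 Å²)` penalises net changes in sidechain
accessible area, and `Δs_Cavity = w·ln(1 + |ΔOSP|/0.33)` penalises buried
(RSA < 17%) Phe/Leu/Ile → Ala/Val substitutions that carve voids into the
core (0.33 is the mean OSP of solvent-exposed regions). Positive ΔΔs is
read as stabilising, negative as destabilising. Scores are log-odds
units, not calibrated kcal/mol.

Mutant structures are modelled deterministically: sidechain atoms shared
between wildtype and mutant stay at wildtype coordinates; new atoms come
from ideal residue templates at a fixed most-common rotamer. No repacking.

## Worked example

Generate the synthetic fixture world, then score the buried core leucine
of the bundle fixture:

```
$ mutstab make-fixtures --seed 1 --out fixtures/
fixtures written to fixtures

$ mutstab predict --pdb fixtures/cluster.pdb --chain A --mutation L6A \
    --essts fixtures/fixture.esst
mutation chain direction     dds  ds_unfolded  ds_folded  ds_disrupt  ds_cavity classification wt_mainchain  wt_rsa  wt_osp  wt_depth ...
     L6A     A   forward -0.6447       3.6323      4.153      0.0063     0.1177  destabilising        alpha     0.0  0.4721     5.739 ...
```

Reading the row: the site is an α-helical, fully buried (RSA = 0%),
densely packed (OSP = 0.47) leucine. The family statistics conserve
leucine more strongly in this folded environment than on average
(`ds_folded` = 4.15 > `ds_unfolded` = 3.63), and the penalties add the
structural cost of the area change (`ds_disrupt`) and of the packing lost
around the site (`ds_cavity` fires because a buried Leu became Ala). The
total ΔΔs = −0.64 classifies the mutation as destabilising, as expected
for hollowing out a hydrophobic core.

Per-residue annotations and batch predictions (up to 20 mutations per
list, mirroring the method's service interface) work the same way:

```
$ mutstab annotate --pdb fixtures/cluster.pdb --out annotations.csv
$ mutstab predict-list --pdb fixtures/cluster.pdb --chain A \
    --mutations muts.txt --essts fixtures/fixture.esst --out preds.csv
$ mutstab evaluate --benchmark fixtures/benchmark.csv \
    --structures fixtures/ --essts fixtures/fixture.esst \
    --reverse-structures fixtures/mutants/
```

## The acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole pipeline from scratch at the given seed: it builds
the synthetic structures, samples a family alignment from a known
environment-dependent substitution process, derives ESSTs from it,
verifies parameter recovery, scores the synthetic benchmark forward and
reverse, and runs the cavity-penalty ablation, printing each stage's
metrics. The JSON output records the (empty) set of externally anchored
target values; the printed log carries the computed numbers.

## Layout

```
src/mutstab/
  structure.py    PDB parsing/writing, mutation specs
  sidechain.py    mutant models, ideal-geometry peptides
  environment.py  RSA / OSP / depth / H-bond / mainchain descriptors
  esst.py         substitution-table derivation and I/O
  scoring.py      the pseudo-ΔΔG score and penalties
  benchmark.py    metrics (r, accuracy, MCC, σ) and evaluation
  fixtures.py     the seeded synthetic world
  cli.py          command-line interface
docs/methods.md   modelling assumptions, parameters, limitations
```
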