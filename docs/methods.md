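# Methods

This note documents the model, its parameters and the judgement calls
behind `mutstab`, in the spirit of a statistical-software methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model overview

The predictor is knowledge-based: it scores a point mutation *j → k* by
how compatible each residue type is with the local structural
environment, as measured by substitution statistics of protein families,
plus two structural penalty terms. The score,

    ΔΔs = Δs_U − Δs_F − (Δs_Disrupt + Δs_Cavity),

is a log-odds quantity ("pseudo-ΔΔG"): positive = stabilising, negative
= destabilising. It is *not* calibrated to kcal/mol; no conversion
factor is applied anywhere.

### Conservation log-odds

With *P(k | j, env)* the probability that a structure residue *j* in
environment class *env* is observed as *k* in a homologue,

    Δs_F = ½ [ ln P(j|j,e_wt)/P(k|j,e_wt) + ln P(k|k,e_mut)/P(j|k,e_mut) ]

averages the forward log-odds (conserve *j* versus accept *k*) in the
wildtype structure's environment with the reverse log-odds in the mutant
model's environment. Δs_U is the same expression on the
environment-marginal table, which stands in for the unfolded state.

A property worth knowing: this form is **invariant**, not antisymmetric,
under exchanging (wildtype, wildtype environment) with (mutant, mutant
environment). Consequently a penalty-free reverse prediction computed on
an exactly rebuilt mutant reproduces the forward table terms rather than
negating them; direction sensitivity comes from the penalties (the
cavity term only fires bulky → small) and from real environment changes.
This mirrors the empirical behaviour of knowledge-based stability
predictors, whose reverse-mutation performance is known to degrade
rather than mirror the forward one. An exactly antisymmetric score would
be a one-function change in `scoring.delta_s_folded`, but cannot
reproduce this form's worked values (ln 16 / ln 5 on the canonical
inputs) — the two properties are mutually exclusive.

### Penalties

* **Disruption**: `w_d · ln(1 + |ΔA_sc| / 100 Å²)` with `w_d = 1`;
  `A_sc` is the absolute sidechain solvent-accessible area. Zero when
  areas are equal; monotone in the change.
* **Cavity**: `w_c · ln(1 + |ΔOSP| / 0.33)` with `w_c = 2`, applied only
  when wildtype ∈ {Phe, Leu, Ile}, mutant ∈ {Ala, Val} and wildtype RSA
  < 17% (the buried cutoff). 0.33 is the mean packing of solvent-exposed
  regions, making |ΔOSP|/0.33 a dimensionless void-creation measure.
  `w_c` is the calibration knob of the method; 2.0 puts the penalty on
  the order of the score's other terms for typical |ΔOSP| ≈ 0.2.

## Environment descriptors

All geometry is heavy-atom only; hydrogens in the input are ignored.
Descriptor integrals use a deterministic golden-spiral dot lattice whose
density is a config value, so convergence is testable.

| descriptor | definition | classes (default bounds) |
|---|---|---|
| mainchain | φ/ψ/ω partition (below) | 9 |
| RSA | sidechain dot-SASA (1.4 Å probe, 960 dots/atom) ÷ extended Gly-X-Gly maximum × 100, capped at 100; Gly uses CA | buried < 17 ≤ intermediate ≤ 50 < exposed |
| OSP | Σ over occluded surface dots of patch × (1 − ray/2.8 Å) ÷ total vdW area; occluders are non-bonded atoms of other residues | low < 0.33 ≤ medium ≤ 0.56 < high |
| depth | mean atom distance to the solvent-accessible surface dot cloud | shallow < 4 Å ≤ medium ≤ 8 Å < deep |
| H-bond | 3-bit: sidechain ↔ mainchain N / mainchain O / other, at donor–acceptor ≤ 3.5 Å and donor–acceptor–antecedent angle ≥ 90° | 8 |

Mainchain partition (evaluated in order; degenerate cases fall to 9):
cis-peptide when |ω| ≤ 30° (class 8); α (φ ∈ [−120,−30), ψ ∈ [−80,−5));
near-α/3₁₀ (ψ ∈ [−5,40)); β (φ ∈ [−180,−45), ψ ∈ [85,180) ∪ [−180,−170));
polyproline/extended (φ ∈ [−120,−45), ψ ∈ [40,85)); other negative φ
(5); left-handed α (φ ∈ [5,120), ψ ∈ [−45,75)) (6); other positive φ
(7); terminal or missing neighbours (9). These nine bins are a declared
stand-in for the environment partition of the original tables, which is
not public; they cover the canonical secondary-structure basins.

Schemes: `216_OSP` (default) = 9 mainchain × 3 OSP × 8 H-bond;
`216_depth` replaces OSP by depth; `54_RSA` (legacy) = 9 × 3 RSA × 2
H-bond (any/none); `648_RSA_OSP_depth` = 9 × 3 RSA × 3 packing × 8
H-bond. The 648 scheme's packing factor is defined as the majority vote
of the OSP and depth classes with ties going to OSP — note that with two
voters this degenerates to the OSP class; it is kept for interface
completeness.

Numerical choices worth noting:

* The RSA reference maxima were computed once with this package's own
  SASA engine on extended (φ=−139°, ψ=135°) Gly-X-Gly ideal-geometry
  tripeptides and frozen into `constants.py`. Self-consistency
  guarantees an isolated residue caps at RSA = 100.
* "Non-bonded" in the OSP definition means: atoms of other residues
  farther than 2.1 Å from the originating atom (excludes the
  peptide-bond partner and disulfide partners). A residue in isolation
  therefore has OSP exactly 0.
* Depth uses solvent-accessible-surface dots as deterministic proxies
  for "nearest surface water"; an isolated atom's depth is r_vdW + 1.4 Å.
* Descriptors are exactly invariant under translation. Under rotation
  they are invariant only up to dot-lattice discretisation (≈2 RSA
  points, ≈0.02 OSP, ≈0.15 Å depth at default densities), because the
  dot lattice is fixed in space; the discrete classes are stable in
  practice and the angular descriptors are exact.

## Substitution-table estimation

Counting runs from each structure-linked alignment member to every other
member: for each unmasked, non-gap column the cell (env of the structure
residue, j = structure residue, k = observed residue) gains the
observer's weight. Gaps never count; functional-site columns (an input
mask; site detection itself is out of scope) contribute nothing.
Observing sequences are weighted 1/(cluster size) after single-linkage
clustering at 60% identity, a simple redundancy guard.

Smoothing is additive: P(k|j,env) = (c + pc·B(j,k)) / (Σc + pc) with a
uniform background B = 1/20 and pseudocount 1 by default. (env, j) rows
with fewer than `min_counts` = 100 observations fall back to the
environment-marginal row, which doubles as the unfolded-state table.
After smoothing every probability is strictly positive and every row
sums to 1 within 1e-9.

## Mutant models

Minimal deterministic sidechain replacement: atoms shared by the two
sidechain topologies keep wildtype coordinates; new atoms come from an
ideal residue template (CCD ideal coordinates) superposed on the site's
N/CA/C, with χ angles set to a single fixed most-common rotamer per
residue type (proline keeps its template ring). No repacking, no
minimisation: the structural perturbation is confined to the mutated
residue and models are bit-reproducible. This is a deliberate stand-in
for whatever modelling the original service performs, which is not
documented; it is recorded in each model's metadata.

## Synthetic world and what green tests mean

No experimental benchmark ships with the package. The fixture generator
states a small world instead:

* an ideal α-helix (φ=−57°, ψ=−47°) and a seven-helix bundle (one
  central helix ringed by six poly-leucine helices at 9 Å) whose central
  leucines are genuinely buried under the package's own descriptors
  (core RSA = 0%, OSP ≈ 0.47, depth ≈ 5.7 Å);
* family alignments sampled from a known process P*(k|j,env): packed
  environments conserve with P(j|j) = 0.9, exposed ones with 0.4,
  off-diagonal mass uniform — an idealisation of the real observation
  that conservation rises with burial and packing;
* a benchmark assigning ΔΔG = −2.5 kcal/mol to buried F/L/I → A/V
  mutations and 0 to conservative substitutions at exposed sites
  (conservative partners: L↔I, A→S, V→I, S↔T).

All randomness flows from one integer seed. The world is idealised — no
backbone relaxation, no ΔΔG noise, two-level effect sizes, a sequence
alphabet dominated by Ala/Leu — so green tests establish that the
machinery is correct (tables recover the generating process; scoring
separates the constructed classes; the cavity ablation moves correlation
in the right direction), **not** that the method attains any particular
accuracy on experimental data.

## Evaluation conventions

* Experimental label: stabilising iff ΔΔG ≥ 0; predicted: stabilising
  iff ΔΔs > 0, with exactly 0 counted destabilising.
* MCC with a zero row/column in the confusion matrix is reported as 0
  with a degeneracy flag.
* σ is the population (ddof = 0) standard deviation of (prediction −
  experiment) residuals; other definitions of a benchmark "standard
  error" exist, so comparisons across tools should check conventions.
* Reverse evaluation scores the inverted mutation on a supplied mutant
  structure against the negated experimental ΔΔG; records without a
  mutant structure are skipped and counted.

## Known limitations

* Scores are uncalibrated log-odds; σ against kcal/mol values mixes
  units and is only meaningful for ranking.
* Mutant environments come from an unrelaxed model, so large
  substitutions that would reorganise packing are scored against a
  fictitious unrelaxed structure.
* The conservation log-odds is symmetric under state exchange (see
  above): reverse predictions differ from forward ones only through the
  penalties and modelling asymmetries.
* The mainchain partition and class boundaries are stand-ins; tables
  built with them are internally consistent but not numerically
  comparable to any external table set.
* No mmCIF input, no network fetching, no repacking, and no
  protein–protein or protein–ligand affinity terms.
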