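# Methods

This package implements the comparative-evolution analysis used to ask
which features of far-red-light photosystem I (FRL-PSI) — chlorophyll-f
binding sites and the rotated A0B electron-transfer chlorophyll — were
already present in the ancestral FRL complex. The pipeline runs in stages:
classify paralog-group-specific residues from a grouped alignment,
reconstruct the ancestral sequence at the most recent common ancestor
(MRCA) of the FRL paralogs, score which specific residues the ancestor
retains, map and cluster them on structures, measure cofactor rotation and
hydrogen-bond geometry between superposed structures, and integrate the
evidence into per-site ancestral Y/N calls.

## Group-specific residue classification

A column of a grouped alignment (FRL paralogs vs visible-light isoforms)
is **group-specific** when, after ignoring rare within-group residues, the
FRL residue set is conserved and disjoint from the VL set. The rule is
explicit and fully configurable (`SpecificityRule`):

| parameter | default | meaning |
|---|---|---|
| `min_frl_dominance` | 0.90 | minimum frequency of the FRL consensus residue (or similarity class) |
| `max_noise_freq` | 0.05 | within-group residues at or below this frequency are ignored |
| `max_gap_fraction` | 0.50 | columns with more gaps than this in either group are GAP_DOMINATED |
| `allow_similarity_class` | on | {ILVM}, {FYW}, {ST}, {DE}, {KR}, {NQ} count as one conserved state |

The dominance default of 0.90 with similarity classes enabled is chosen so
that the canonical worked substitutions of the system (a Val/Ile mixture
replacing a conserved Thr; a fixed Ser replacing Gly; a fixed Thr
replacing Ser) classify as FRL-specific while columns with genuine
within-FRL variation do not. Frequencies are raw sequence counts with no
phylogenetic down-weighting: the rule is meant to be auditable against a
by-eye alignment reading, at the cost of sensitivity to duplicated
sequences (asserted in the tests). `X` is treated as missing, never as a
match. Columns where one group is mostly gaps (e.g. group-specific
insertions) are reported GAP_DOMINATED rather than specific; insertion
regions reach the ancestral scoring through the column-map "unmapped"
pathway instead, counting as specific-but-not-scorable when they are
planted as substitution columns.

## Ancestral sequence reconstruction

Marginal ASR on a fixed rooted tree with fixed branch lengths under a
reversible empirical model. The rate matrix is `Q_ij = s_ij * pi_j`,
scaled to one expected substitution per site at equilibrium; `P(t) =
exp(Qt)` is computed by symmetric eigendecomposition of
`diag(sqrt(pi)) Q diag(1/sqrt(pi))`, which keeps `P(t)` stochastic to
machine precision. The default model is LG with its published
exchangeabilities and frequencies (`_lg_data.py`); a Poisson model is
provided for closed-form checks. Among-site rate variation, off by
default, uses a discrete gamma with equal-probability mean-rate
categories. The default is off because the conservation scoring consumes
only the MAP state, which is robust to moderate rate mis-specification;
the shape is a fixed input, never optimised.

Site likelihoods come from Felsenstein pruning with per-node scaling;
per-node posteriors from an inside/outside pass (the outside weight of the
rest of the tree through the node times the conditional likelihood below
it), with per-site category weights proportional to the category
likelihood. Gaps and `X` are missing data (all-ones conditional vectors),
not a 21st state. MAP ties break alphabetically. The "FRL ancestor" node
is located as the MRCA of the FRL-labelled leaves, by label, not by name.

Correctness is pinned by exhaustive-enumeration oracles on three-leaf
trees (1e-10), Chapman–Kolmogorov and detailed-balance identities (1e-9),
and invariance of the total likelihood under re-rooting (pulley
principle, 1e-8).

## Structures and geometry

Structures are read with gemmi (PDB or mmCIF, first model,
highest-occupancy altloc, author residue numbering authoritative).
Chlorophyll cofactors are recognised by component id (CLA by default;
deposited FRL-PSI models build chlorophyll f as CLA) and must expose the
four pyrrole nitrogens NA–ND. Ring definitions follow
chemical-component-dictionary naming: pyrrole rings A–D, and the isocyclic
ring E (C3C, C4C, CHD, CAD, CBD) carrying the 13(1)-keto oxygen OBD.
Alignment rows are bound to chains by global alignment of the chain's
modelled sequence to the ungapped row, requiring at least 95% identity;
unmodelled loops are simply absent from the column↔residue map.

Cofactor rotation between two structures is measured after a *local*
superposition: backbone atoms (N, CA, C, O) of residues whose C-alpha lies
within 12 Å of the reference cofactor are matched by (chain, residue,
atom) and superposed by Kabsch/SVD with reflections excluded. Local rather
than whole-complex superposition isolates the cofactor's motion from
global lattice differences; the radius is configurable. Three quantities
are reported: the in-plane rotation angle, the angle between the two
macrocycle plane normals, and per-ring centroid shifts, with the pivot
ring defined as the ring whose centroid moves least.

The in-plane angle is the least-squares (2D Procrustes) rotation of the
shared macrocycle atoms after projecting both structures into the
bisecting plane of the two normals. A two-atom NA→NC axis was evaluated
first and rejected: at 0.05 Å coordinate noise it carries ~1° of error
per measurement, which would swamp a ~5° signal; the Procrustes estimate
over ~20 atoms reduces this to ~0.2° and is exact on noise-free
constructions. The NA→NC axis angle is still reported
(`nanc_axis_angle_deg`) as a diagnostic.

Hydrogen bonds are inferred from heavy atoms only (deposited models carry
no hydrogens): donor/acceptor N, O, S pairs within 3.5 Å, excluding
covalently bonded and 1–3 pairs (bonds assigned by distance, <1.85 Å, or
<2.1 Å with sulfur), with the antecedent–acceptor···donor angle required
to fall in 90–180°. Between O and N the oxygen is taken as the acceptor;
otherwise the assignment giving an angle closer to the 120° carbonyl
optimum wins. Bond quality is |acceptor angle − 120°|, the statistic used
to compare FRL against VL keto H-bonds.

## Clustering

Specific residues mapped to C-alpha positions are clustered by single
linkage at a 15 Å cutoff; the partition provably equals the connected
components of the ≤cutoff distance graph (checked against a brute-force
BFS oracle on every randomised test). Single linkage is the right shape
assumption here because the observed residue patches span the membrane —
elongated clusters that centroid-based methods split. Components below 5
members are reported as sparse/unclustered.

## Ancestral site calls

Each candidate chlorophyll-f site carries supporting residues with roles:
`hbond_donor`, `cavity`, `stabilizer`. The ancestral call is **Y** exactly
when every donor and cavity residue is group-specific *and* retained by
the reconstructed ancestor, and at least `required_fraction` (default
0.5) of the stabilizers are retained; otherwise **N**, with the failing
residues listed in the rationale. Per-structure extant evidence is an
input table (shipped for the three FRL structures as
`data/table2_extant_evidence.tsv`); only the Ancestral row is computed.
A site with no configured support is called N ("no evidence").

## Synthetic study conditions

The generators produce every input with known ground truth:

- **Planted alignments** (defaults: 30 FRL + 30 VL sequences, 200 columns,
  10 planted specific columns, i.i.d. background from LG equilibrium
  frequencies shared across groups; 30% of planted columns use a
  similarity-class pair such as Val/Ile vs Thr). Planted columns satisfy
  the default rule by construction.
- **The case study** adds a two-clade phylogeny: sequences are simulated
  down the tree under LG, then planted columns are fixed across the FRL
  clade. "Ancestrally retained" columns are uniform in FRL;
  "not retained" columns keep the ancestral residue in one basal FRL
  lineage sitting on a very short branch off the FRL MRCA, so the
  classifier (which filters one leaf in thirty as noise) still calls the
  column specific while the reconstruction correctly assigns the ancestor
  the basal state — the same signature as a substitution fixed after the
  group's origin. Background columns that happen to fix disjointly in the
  two clades (an expected consequence of shared ancestry) are perturbed so
  the planted truth table is exact.
- **The recovery benchmark** is a fixed 12-leaf, 300-site LG simulation
  with branch lengths uniform in 0.05–0.3 on a shallow topology
  (three-leaf clades hanging off the root, an early-radiation shape that
  keeps every leaf informative about the root). Root-state recovery is
  95–100% across seeds.
- **Cofactor pairs** are built from an idealized planar chlorin template
  with CCD-style atom names, rotated by a known angle about the macrocycle
  normal through a chosen ring centroid, optionally noised (Gaussian,
  per-atom) and given a random rigid motion so the local superposition
  stage does real work.

What the generators deliberately do not emulate: real PSI coordinates
beyond local geometry, indel processes (planted alignments are gap-free),
compositional heterogeneity across sites or lineages, and correlated
(non-isotropic) coordinate error in cryo-EM models. Passing tests
demonstrate the machinery is correct under its stated model, not that the
biological conclusions are insensitive to alignment or model error in
real data.

## Numerical choices and degenerate inputs

Transition matrices are clipped at zero and row-renormalised (deviations
are at rounding level). Pruning uses per-node max scaling; posteriors
normalise per site, so scale factors cancel. Superposition requires three
non-collinear pairs; plane fits require three non-collinear atoms; the
identity fraction is an error on zero compared positions. Greedy
redundancy reduction visits sequences longest-first (ties by id) and uses
global alignment identity (match +1, mismatch 0, linear gap −1) normalised
by the shorter ungapped length; argument order is canonicalised before
aligning because co-optimal alignments can differ in match count.
Consensus and MAP ties break alphabetically. Fragment removal drops
sequences shorter than 70% of the median ungapped length.

## Limitations

- The specificity thresholds approximate an informal by-eye criterion;
  they are exposed in configuration precisely because no authoritative
  operational definition exists.
- ASR assumes the fixed tree and branch lengths are correct and shares one
  model across sites; no model selection or branch-length optimisation.
- H-bond donor/acceptor assignment without hydrogens is heuristic and can
  misassign O···O pairs.
- Chain-to-subunit correspondence for deposited PSI entries must be
  supplied by the user from the entries themselves; no table is bundled.
- Cluster counts depend on the 15 Å cutoff; the partition-vs-components
  identity holds at any cutoff, but the biological grouping is
  scale-dependent.
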