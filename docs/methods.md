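# Methods

This note documents the models, geometric criteria, numerical choices and
known limitations of pharmflow. Units are Å and degrees throughout.

## Feature perception (rule table v1)

Ligand pharmacophore features are perceived with an explicit rule table on
the molecular graph rather than an opaque third-party typer, because the
perception rules of commercial pharmacophore software are proprietary; ours
are therefore a declared approximation, chosen to match standard medicinal
chemistry conventions:

* **HBA** — N/O with an available lone pair. Excluded: positively charged
  N, amide/sulfonamide N (N bonded to C or S carrying a double-bonded O),
  aniline-type N, pyrrole-type ring N–H. Pyridine-type ring N and all
  neutral O (including sulfonyl oxygens) accept.
* **HBD** — N/O carrying ≥ 1 hydrogen (explicit neighbour, RDKit-recorded,
  or implied by standard valence: effective valence = default + formal
  charge, aromatic bonds counting 1.5).
* **ARO** — centroid of each aromatic ring (smallest cycle basis of the
  aromatic-bond subgraph), with the plane normal as direction.
* **HYD** — every aromatic ring centroid (so a model hydrophobic sphere
  can match a ring; the ARO duplicate is ignored by matchers), every
  maximal connected set of ≥ 2 non-ring apolar heavy atoms, and every
  halogen bonded to carbon. Apolar = C/S/halogen with no bonded N/O.

Perception is conformer-independent in kinds and source atoms and its
output order is deterministic for a fixed atom order. Directionality is
perceived (ring normals) but deliberately **ignored in matching**: features
are distance-only spheres and no angular tolerances are part of the
contract.

## Pharmacophore model and matching

Model features carry a tolerance radius (default 1.5 Å for all kinds) and
excluded volumes a radius of 1.2 Å. These defaults are near common
pharmacophore-software values; they are stored in the model JSON so they
are explicit data, not code. An excluded-volume clash is a ligand heavy
atom strictly inside a sphere — atom center vs sphere, no van der Waals
inflation, the simplest testable contract.

**Receptor-based construction** places one HBA feature on each ligand
acceptor H-bonded (≤ 3.5 Å to a donor-capable protein atom, or to a listed
structural water) and one HYD feature on each ligand hydrophobic centroid
with ≥ 2 apolar protein heavy atoms within 4.5 Å. Excluded volumes sit on
every protein heavy atom within 6.0 Å of the ligand except H-bond partner
atoms. The mandatory flag is a heuristic — all HBA plus the best-contacted
HYD — reproducing the canonical 5-mandatory/3-optional split of the MAGL
model; an explicit override is the supported path for other systems.

**In-place matching** solves maximum-cardinality, minimum-total-distance
assignment via a rectangular linear sum assignment with a large per-pair
bonus (cardinality dominates distance; scipy's Hungarian solver makes the
result deterministic). Verified against exhaustive assignment enumeration
on every instance with ≤ 8 model features.

**Alignment matching** enumerates injective correspondences between
mandatory features and kind-compatible ligand features by backtracking,
pruned by pairwise-distance compatibility (|d_model − d_ligand| ≤ sum of
tolerance radii), with a default cap of 10⁵ visited nodes (warning +
best-so-far beyond it). Each surviving correspondence is placed by Kabsch
superposition of the matched centers; optional features are then extended
greedily (nearest unused compatible feature within tolerance) rather than
globally optimally — a bounded-cost choice whose gap the brute-force test
oracle bounds at zero on the planted fixtures. Placements that violate an
excluded volume are discarded. The result maximizes
(mandatory_satisfied, n_matched, −RMS of matched centers).

## Interaction geometry

The source workflow names its interactions but never publishes geometric
cutoffs, so ours are explicit, configurable defaults: H-bond heavy-atom
distance ≤ 3.5 Å (donor angle ≥ 120° applied only when the donor hydrogen
is present, so un-protonated structures work); hydrophobic contact ≤ 4.5 Å
between apolar heavy atoms, aggregated per residue; π-stacking at ring
centroid distance ≤ 4.5 Å and interplanar angle ≤ 30°. Protein-side
connectivity (for apolar typing) is inferred within each residue by a
1.8 Å distance criterion. A water bridge requires the ligand–water H-bond
plus **at least one** partner arm (glutamate or histidine) — the two arms'
occupancies differ in practice and nothing requires both per frame.

The pose filter evaluates "hydrophobic feature respected" as an in-place
pharmacophore match restricted to the model's HYD spheres (≥ 2 of 4 by
default), not raw contact counting, so the filter and the screen share one
definition of a satisfied feature.

## Pose RMSD, consensus, clustering

Pose RMSD is in place (no superposition), heavy atoms only, minimized over
molecular-graph automorphisms (element/charge/bond-order preserving,
capped at 10⁴) — symmetry correction is on by default, with an off switch
used by the test oracles. Thresholds are strict: "below 2.0 Å" means
boundary values fail.

Complete-linkage clustering is agglomerative with inter-cluster distance =
maximum pairwise member distance; merging stops when the smallest linkage
distance reaches the threshold. Equal-distance ties merge the pair whose
smallest member labels are lexicographically first, which makes the
partition label-order invariant. Full consensus (all reciprocal RMSDs
below threshold) is equivalent to a single complete-linkage cluster: the
final merge's linkage distance always equals the global maximum pairwise
distance, since the extremal pair stays split until the last merge.

## Trajectory analytics

Ligand RMSD is measured per frame against frame 0 after least-squares
superposition of protein α-carbons (default). Trajectories produced with
restrained α-carbons make this a near-no-op, but it keeps the analysis
valid for unrestrained inputs; `superpose_on="none"` recovers raw
coordinates. "Average RMSD" is the arithmetic mean of the series — the
phrase taken literally, not a median. Structural-water tracking follows
the same water molecule by default (`identity`); `nearest` mode follows
whichever water oxygen is closest to the frame-0 site, for engines that
exchange waters. Occupancy counts all frames provided (no striding
assumptions) and the MD filter applies strict inequalities at 2.0 Å and
70 %.

## Synthetic fixtures: what they emulate, and what not

The generators plant ground truth geometrically:

* The reference complex realizes the canonical binding-site inventory
  exactly: four ligand acceptor oxygens (two carbonyls and a sulfonyl
  pair, the latter mirroring the sulfonamide binding mode of known hits)
  H-bonded to two backbone-N donors, an arginine side chain and a
  structural water bridging a glutamate/histidine pair; two aromatic
  rings, an aliphatic bridge and a chlorine providing four hydrophobic
  sites with distinct contact counts (6/5/2/2, making the mandatory-flag
  choice unambiguous); and one π-stack. The generator asserts its own
  planted inventory on every call. Seeds apply only a rigid motion, so
  coordinates differ across seeds while all internal geometry is fixed.
* Library variants disable optional features structurally (Cl→H, bridge
  C→ether O, distal ring displaced 3.2 Å — more than twice the tolerance
  radius, so no rigid placement can rescue it while keeping the mandatory
  features satisfied).
* Pose ensembles realize target pairwise-RMSD matrices by rigid
  translations (classical MDS embedding plus least-squares refinement);
  translations make identity-mapping RMSD exact, and the realized
  symmetry-aware matrix is verified to 0.05 Å.
* Trajectories place each H-bond partner along its fixed bond direction
  relative to the *jittered* acceptor: at bond length when "present",
  0.3 Å beyond the cutoff when "absent" — occupancy recovery is therefore
  exact by construction, immune to noise at the boundary. Ligand jitter is
  isotropic Gaussian per atom (E[per-frame RMSD] ≈ σ√3); drift is linear.

Fixtures are geometric, not energetic: no force field would accept the
bond lengths or packing, waters are single oxygens, and protonation is
never modeled. Passing tests therefore demonstrate correctness of the
geometric contracts, not robustness to real structural noise, induced fit,
tautomers or water exchange.

Default study conditions: funnel libraries of 30 molecules at level
weights 10/20/30/40 % (levels 8→5), 6 docking-method labels, trajectories
of 50–200 frames at jitter σ = 0.1 Å, occupancy profile
R57 = 0.98 / water = 0.94 / A51 = 0.82 / M123 = 0.30 (a typical surviving
hit). These sizes keep the full suite and the acceptance script in the
tens of seconds while exercising every code path; the planted-recovery
guarantees are size-independent.

## File-format choices

PDB I/O is backed by gemmi (altloc policy: keep blank or 'A'; occupancy
and B-factors read but ignored), SDF/MOL2/SMILES by RDKit (Tripos atom
types used for element inference only). Trajectories are multi-model PDB
only — an explicit limitation that keeps the toolkit dependency-light; no
binary DCD/XTC, no mmCIF, no protonation-state prediction. Ligands
extracted from PDB get connectivity by covalent-radius distance inference
and bond orders by a documented geometric heuristic (terminal C=O ≤ 1.30 Å,
S=O ≤ 1.50 Å, planar 5/6-rings of C/N with bonds 1.30–1.45 Å aromatic);
structures are otherwise read as given, with no tautomer or charge
assignment.

## Novelty check

2-D similarity uses hashed path-based RDKit fingerprints (2048 bits) and
Tanimoto similarity scaled to 0–100 (100 = identical). This is an explicit
stand-in for proprietary 2-D comparison engines, so the novelty bound
(default ≤ 80 = novel) is configurable rather than calibrated.

## Known limitations

* Feature directionality and projected donor/acceptor points are not used
  in matching; models with tight angular constraints cannot be expressed.
* The greedy optional-feature extension can in principle under-count
  optional matches for pathological feature crowding; the brute-force
  oracle in the tests bounds this on small instances.
* H-bond detection without hydrogens is distance-only; strongly bent
  interactions are over-counted on un-protonated inputs.
* Automorphism-aware RMSD enumerates at most 10⁴ graph automorphisms;
  beyond the cap the value is an upper bound.
* The MOL2 reader handles the Tripos dialect via RDKit only.
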