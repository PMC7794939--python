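# pharmflow

A toolkit for pharmacophore-guided structure-based virtual screening,
built around the workflow used to discover reversible inhibitors of
monoacylglycerol lipase (MAGL): a receptor-based pharmacophore model is
derived from a protein–ligand X-ray complex (e.g. PDB 5ZUN), a compound
library is screened against it, docking poses from multiple engines are
filtered by the interactions they actually form, surviving binding modes
are cross-validated by pose-consensus clustering, and MD trajectories
provide the final stability filter. Docking engines and MD engines are
*out of scope*: their outputs (poses as SDF, trajectories as multi-model
PDB) are inputs here.

It is written for computational medicinal chemists who want an auditable,
scriptable re-implementation of this cascade — every rejection at every
stage is recorded with a reason — and for method developers who need a
testbed: a synthetic-fixture generator plants ground truth (match sizes,
pairwise RMSDs, per-frame interaction occupancies) so that every stage can
be verified without external downloads.

## The model

**Pharmacophore.** A model is a set of typed tolerance spheres
F = {(kind_i, c_i, r_i, mandatory_i)} — here hydrogen-bond acceptor (HBA)
and hydrophobic (HYD, ring-compatible) features — plus excluded-volume
spheres marking receptor-occupied space. A conformer matches feature i
when a ligand feature point of the same kind lies within ‖x − c_i‖ ≤ r_i;
a hit must match **all mandatory features** and touch no excluded volume,
and hits are ranked by the number n of matched features. In-place matching
(for docking poses, which are already in the receptor frame) solves a
maximum-cardinality one-to-one assignment; alignment matching (for
conformer libraries) enumerates mandatory-feature correspondences, prunes
them by pairwise-distance compatibility |d_model − d_ligand| ≤ r_i + r_j,
and places each candidate by least-squares (Kabsch) superposition.

**Pose consensus.** For each compound, the top pose from each docking
method is compared by in-place heavy-atom RMSD (minimized over graph
automorphisms, the docking-community convention). *Full consensus* holds
when every reciprocal RMSD is below 2.0 Å — provably equivalent to the
in-house complete-linkage clustering yielding a single cluster at that
threshold.

**MD filter.** Per-frame interaction presence (H-bonds, water-bridged
H-bond networks) uses the same geometric criteria as the static pose
analysis; occupancy is the fraction of frames present. A complex passes
when mean ligand RMSD < 2.0 Å and the required interactions — the
arginine H-bond, the structural-water bridge, and at least one
oxyanion-hole contact — are maintained for **more than** 70 % of frames
(strict inequalities throughout).

## Worked example

The synthetic reference complex mimics the canonical MAGL binding-site
inventory (oxyanion-hole backbone donors A51/M123, the R57 side chain, the
structural water bridging E53/H272, four hydrophobic clusters, a stacking
tyrosine). Running the full cascade on a 30-compound planted library:

```text
$ pharmflow run --seed 1
stage                 in     out  note
screen                30       9
pose_filter            9       7
consensus              7       5
md_filter              5       3
```

30 compounds carry planted best-match sizes 8/7/6/5 in proportions
10/20/30/40 %; screening at ≥ 7 features keeps the 3 + 6 = 9 planted
hits; two compounds whose pose breaks its H-bonds under one docking method
fall at the interaction filter/intersection; two whose distal arm swings
away in one method lose pose consensus; and of the five simulated
compounds, one fails the 70 % occupancy clause and one drifts past 2.0 Å
mean RMSD, leaving 3 — each number equal to its planted ground truth.

Validating docking protocols against the shipped 5ZUN self-docking
benchmark:

```text
$ pharmflow selfdock-validate
        method  rmsd  passed
         Dock6   0.5    True
      Glide SP   0.6    True
Gold Goldscore   0.6    True
...
          Vina   9.4   False
passing: 9/13
```

Nine of the thirteen protocols re-dock the co-crystallized inhibitor
within 2.0 Å of the crystallographic pose.

Other entry points: `pharmflow build-model` (model JSON from a complex
PDB), `pharmflow screen`, `pharmflow traj-filter`, `pharmflow novelty`
(2-D Tanimoto novelty scores, 100 = identical), and `pharmflow fixtures`
(write a fixture bundle with its ground-truth JSON).

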