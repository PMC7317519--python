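# Methods

## Model

`aquaphore` treats the water molecules of an apo binding-pocket MD
trajectory as probes of ligand-interaction opportunity. The underlying
assumption is that a water oxygen samples, over the trajectory, the
positions a polar or apolar ligand atom could occupy, and that the protein
chemistry it sees there — donors, acceptors, charges, apolar surfaces,
aromatic rings — predicts which pharmacophoric feature a ligand should
present at that position. The analysis requires a trajectory that is
already wrapped and aligned on the protein; no fitting is performed
internally.

### Grid and binning

All fields live on a cubic grid (center, edge length, spacing), point
`(i,j,k)` at `center − edge/2 + (i,j,k)·spacing`. The edge must be an
integer multiple of the spacing so both faces carry grid points. Waters
are assigned to their **nearest** grid point, ties broken to the lower
index; the cube is closed on all faces. Binning is therefore deterministic
and independent of storage order. The default spacing is 0.5 Å with a
30 Å edge — large enough to span an orthosteric GPCR-class pocket; the
spacing is a resolution/cost trade-off (each halving multiplies grid
points by 8), not a fitted constant.

### Frame schedule and windows

Saved frames exclude the t=0 configuration: a 30 ns run saved every 10 ps
yields 3000 frames, and `expected_frame_count` is `floor(duration/interval)`
under that convention. `slice_frames` keeps `t_start < t ≤ t_end`, so
"the last 10 ns" of a 30 ns / 10 ps trajectory is exactly 1000 frames,
excluding the frame at 20 ns itself.

### Interaction counting

Per frame, per in-grid water oxygen, partners are counted per feature
class:

| class | partner | criterion (defaults) |
|---|---|---|
| HBD | protein acceptor heavy atom | 2.5 ≤ d ≤ 3.6 Å (+ water donor angle ≥ 130° when water H present) |
| HBA | protein donor heavy atom | 2.5 ≤ d ≤ 3.6 Å (+ donor angle ≥ 130° when protein H present) |
| PI | anionic group centroid (Asp/Glu carboxylate, C-terminus) | d ≤ 4.0 Å |
| NI | cationic group centroid (Lys NZ, Arg guanidinium, His⁺ ring) | d ≤ 4.0 Å |
| H | apolar C/S atom (no bonded N/O) | d ≤ 4.1 Å |
| AR | aromatic ring centroid (Phe/Tyr/Trp/His) | 3.1 ≤ d ≤ 6.0 Å |

The class label is the feature a **ligand** would present: a protein donor
pointing at the water marks a ligand-acceptor (HBA) site, and vice versa.
Distance windows and the angle threshold are conventional hydrogen-bond
and contact definitions; they are parameters of `GeometryParams`, not
fitted values. `heavy_atom_only` drops all angle terms — hydrogen
positions in classical water models are rotationally noisy, and the
synthetic fixtures do not model them at all, so fixture-driven validation
runs in this mode while the angle logic is unit-tested on hand-placed
single frames. When hydrogens are simply absent from a topology the angle
check degrades to the distance window rather than failing.

Role typing is dictionary-driven over standard residue/atom names (PDB v3,
plus CHARMM/AMBER histidine variants). An atom may carry several roles.
Residues without rules are returned in an exclusion list with a warning —
never silently dropped.

### Field normalisation

Accumulated counts are scaled by `100/n_frames`: scores are per-frame
percentages, independent of trajectory length (duplicating every frame
changes nothing). A site with one qualifying partner occupied in a
fraction *p* of frames converges to 100·p, with binomial sampling noise
√(p(1−p)/n)·100. Hydrophobic scores can exceed 100 because several apolar
contacts per water are summed — which is why hydrophobic display cutoffs
(half the field maximum, the convention used throughout) sit numerically
above those of the other classes. Counts go to the single nearest grid
point; no smoothing is applied, so positional jitter of the water spreads
weight over neighbouring points instead of biasing the peak position.

## Pharmacophore construction

Extraction is greedy per-class peak picking: take the global maximum above
the class threshold (default half-max), place a feature (default tolerance
1.5 Å), suppress a `merge_radius` sphere (default 2.0 Å), repeat. Ties go
to the lowest flat grid index, making extraction deterministic and
storage-order-independent. Hydrogen-bond features can be given projection
points at the centroid of time-averaged partner atoms within H-bond range
(`add_hb_projections`); projection checking during matching is off by
default since both sides rarely define directions in practice here.

Exclusion volumes (default radius 1.0 Å) are placed on time-averaged
protein heavy atoms within 8 Å of any feature, excluding atoms closer than
1.5 Å to a feature position (they would forbid the interaction the feature
demands), deduplicated greedily at twice the radius.

The enumerator generates all feature subsets satisfying total-count and
per-type bounds; hydrogen bonds are counted jointly over donors and
acceptors (the "1–3 hydrogen bonds" convention over a mixed inventory).
No exclusivity metadata is modelled by default; an optional list of
never-co-selected id pairs is accepted. Output order is deterministic
(size, then lexicographic id tuple). All features of a model are required
for a match; optional features are not modelled, mirroring the
combinatorial design in which each sub-model is screened independently.

## Matching and evaluation

Ligand feature perception is rule-based on RDKit molecules: PI at
positively charged N and neutral amidine/guanidine N; HBD at H-bearing
N/O; HBA at O/N acceptors excluding amide and pyrrole-type N; NI at
negatively charged O/S/N; AR at aromatic ring centroids; H at centroids of
maximal connected groups of ≥2 carbons bonded only to C/H.

Matching searches injective type-compatible assignments depth-first,
pruning a partial assignment when any ligand pairwise distance deviates
from the corresponding feature distance by more than the two tolerances
combined — a necessary condition for any rigid superposition to succeed.
Complete assignments are superposed by least-squares rotation
(quaternion-based Kabsch via `scipy.spatial.transform.Rotation`); a pose
is accepted iff every matched point lies within its feature tolerance and
no ligand heavy atom falls strictly inside an exclusion volume. The fit
score `Σ 10·(1 − d_i/tol_i)` rewards tight geometry; the best conformer
and assignment win. The search is exact: at the intended scale (≤ ~6
features, tens of points, 25 conformers) branch-and-bound remains
tractable, and equivalence with an exhaustive oracle is asserted in tests
on small instances.

Screens rank hits by fit score, ties by id (reproducibility). The early
enrichment factor at fraction f selects the top `ceil(f·(A+D))` of the
ranked hit list — or the whole list if shorter — so a short, all-active
hit list attains the ceiling (A+D)/A exactly: 64.5 for the 100/6350
composition at 1%. This capped-selection convention is the one under
which the ceiling is attainable by a sparse, precise pharmacophore; an
empty selection scores 0. Retrieval is the percentage of actives anywhere
in the hit list, and is monotone non-increasing as features are added to a
model (constraint tightening).

## Synthetic fixtures

`build_pocket` emulates occupancy statistics only: per frame each planted
site emits a water oxygen with probability p (plus optional Gaussian
jitter), in front of a static scaffold group presenting exactly one
partner of the site's class and none of any other class — the scaffold
distances are chosen against the default criteria in heavy-atom-only mode
(e.g. carboxylate centroid at 3.8 Å with its oxygens pushed outside the
3.6 Å H-bond window). Absent waters are parked hundreds of Å away so every
model has the same atom count. A single seeded generator drives all
randomness; identical specs give byte-identical files, and the truth
document records planted positions, occupancies and expected scores 100·p.

What the fixtures deliberately do not model: water hydrogens and their
orientational statistics, protein motion, correlated site occupancy, and
realistic water density outside the planted sites. Passing fixture tests
therefore validates the counting, binning, normalisation and geometry
machinery — not force-field-level realism of any particular system.

`build_library` plants actives whose fragments (methylammonium, methanol,
formaldehyde, carboxylate, ethane, benzene) realize every target feature
at its exact position, each molecule under its own random rigid motion.
Decoys break exactly one requirement: either a fragment displaced by a
fixed amount (default 6.0 Å) **radially away from the centroid of the
remaining features** — the radial direction matters, because it grows the
ligand's pairwise distances beyond the matcher's tolerance slack, which no
rigid motion can absorb, whereas a tangentially displaced point on a
3-feature model can be chased by a rotation about the axis through the
other two features — or, when the model carries exclusion volumes, an
otherwise perfect geometry with one extra carbon parked at an
exclusion-volume center. By construction retrieval on planted actives is
100% and on planted decoys 0%, making the EF ceiling an end-to-end
invariant of the whole pipeline at the 100/6350 composition.

## Numerical and design choices

- Ångström everywhere; right-handed coordinates; 0-based grid indices.
- Ties: grid binning to the lower index; extraction to the lowest flat
  index; hit ranking by ascending id. All paths are deterministic for
  fixed input.
- Water identity: residue-name whitelist {HOH, WAT, TIP3, TIP4, SOL, T4P}
  (configurable); only the oxygen defines the water position.
- OpenDX export/import via GridDataFormats; grid metadata round-trips
  exactly, values to ≤1e-5 (text format precision).
- The native pharmacophore format is JSON (lossless round-trip); PML
  export is a best-effort dialect for external visualisation and does not
  round-trip scores.
- Degenerate inputs are rejected with named values (non-integral
  edge/spacing ratio, empty selections, empty time windows, empty
  pharmacophores, overlapping scaffold atoms).
- Problem sizes in tests and the acceptance script: 1000-frame pockets,
  ≤6-feature models, and a full 100-active/6350-decoy planted screen —
  the composition whose EF1% ceiling is 64.5. These run end-to-end in
  seconds to a few minutes on one CPU.

## Known limitations

- Geometric criteria are fixed per run; no aggregation of multiple
  criteria sets or score weighting beyond raw counts.
- No solvation thermodynamics: scores are occupancy-weighted contact
  frequencies, not free energies.
- Feature extraction is greedy; two genuinely overlapping hotspots closer
  than the merge radius collapse into one feature.
- The matcher's exhaustive search is exponential in feature count; it is
  intended for the ≤6-feature sub-models produced by the enumerator, not
  for dense super-pharmacophores.
- PML export targets a common dialect but is not validated against any
  external tool's schema.
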