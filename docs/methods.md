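# Methods

This note records the models, parameters and numerical choices behind
`znsite`, and what the synthetic test conditions do and do not
demonstrate.

## Candidate search

Coordinating atoms are Cys Sγ and the four His ring atoms Nδ1, Nε2, Cε1,
Cδ2; the ring carbons are admitted because deposited imidazoles are
frequently flipped or mislabelled. Backbone N/O donors are not searched
— sites coordinated through backbone atoms are a documented blind spot.
Hydrogens are read but ignored everywhere; waters never seed a site but
can appear as auxiliary ligands.

Residues form a compatibility graph with an edge whenever *any* allowed
atom pair lies in the 2.4–4.5 Å window and is not a disulfide
(Sγ–Sγ < 2.400 Å; the cutoff is the μ + 2.575 σ upper confidence bound
of the covalent S–S distance peak, μ = 2.058 Å, σ = 0.133 Å). Candidate
sites are the maximal cliques of size 2–4 plus every 4-subset of larger
cliques; emitted subsets of a larger emitted set are suppressed. One
coordinating atom is then chosen per residue — Sγ for Cys; for His the
ring atom minimizing the summed distance to the other chosen atoms,
iterated to a fixed point (at most 3 passes, initialized at Nε2, the
most common coordinating atom) — and the site is kept only if the
*chosen* atoms satisfy the window pairwise (the stricter all-pairs
reading). Where a clique larger than four residues occurs, all its
4-subsets are scored downstream and the redundancy rule keeps the best;
this realizes "keep the highest-certainty 4-subset" without a separate
selection pass.

## Zinc placement

Six strategies, keyed to the subgroup:

* **a (CC)** and **b (CH)** — the zinc locus is a circle of radius
  1.2 Å around the midpoint of the two coordinating atoms, in the plane
  perpendicular to their segment. The printed 1.2 Å constant is kept
  as-is even though √(2.1² − 1.8²) = 1.08 Å; it is configurable, and
  for tetrahedral inter-ligand separations (3.43 Å) it is nearly exact.
  Each circle point is scored by the summed squared deviation (degrees²)
  of the Zn–ligand–Cβ angles from per-role targets: Sγ 109°, Nδ1 100°,
  Nε2 155°, and 128° (the nitrogen midpoint) for the ring carbons.
  Points on the Cβ side of either ligand, (p − L)·(Cβ − L) > 0, are
  rejected to avoid clashes; if that empties the circle the rejection
  becomes a large additive penalty. The scan uses 3600 points (0.1°)
  plus one golden-section refinement (40 iterations in the bracketing
  interval), bounding the discretization error around 10⁻³ Å. A missing
  Cβ degrades gracefully to the midpoint with a low-confidence flag.
* **c (HH)** — per ring, four candidates sit on the centroid→atom rays
  at the 2.1 Å coordination-bond distance *beyond* the ring atom (the
  direction a ring nitrogen's lone pair points); the closest cross-ring
  pair is averaged. Placing candidates a full bond length beyond the
  atom, rather than a 2.1 Å segment from the centroid (which would land
  only ~0.9 Å past the atom), is the chemically consistent reading of
  the construction.
* **d (HHH)** — mean of the three pairwise HH placements.
* **e (mixed CH3)** — three pairwise candidates via a/b/c; the two
  mutually closest vote 2-of-3 (cysteine rotamers stray more readily
  than histidine) and their midpoint wins.
* **f (CH4)** — centroid of the four coordinating atoms.

All placements are equivariant under rigid motions (tested to 10⁻⁶ Å).
The 109.47° ideal tetrahedral angle is used for internal geometry; the
printed 109° only as the scoring target.

## Bond-valence validation

V = exp((R₀ − d)/b) with b = 0.37 Å and the standard R₀ tabulation
(Zn–O 1.704, Zn–N 1.77, Zn–S 2.09 Å), configurable per metal–donor
pair. Donors are N/O/S atoms within the 2.5 Å first coordination
sphere, at most one per residue (the closest). Q_c uses the literal
valence-sum normalization for 3+ ligands and the oxidation-state
normalization for 2 ligands — the latter reproduces the two-ligand
optimum 0.71 (resultant 0.58 of two valence-0.5 bonds at the
tetrahedral angle, divided by V_ox = 2) and its half-threshold 0.355.
Q_e's second factor is the ratio of products
min((B_m·O_m)/(B_e·O_e), inverse); for a bare predicted position (no
modelled ion) unit occupancy and the environment B-factor are assumed,
making that factor neutral. Sites with fewer than two ligands never
pass. Vector direction is metal→donor; any consistent convention leaves
|Σv⃗| unchanged.

## Hydrophobicity profiles

Per-atom solvation parameters (cal mol⁻¹ Å⁻²): carbon +16, neutral N/O
−6, charged O −24 (Asp/Glu carboxylate, OXT), charged N −50 (Lys NZ,
Arg NE/NH1/NH2), sulfur +21; hydrogens 0, metals excluded, unknown
elements 0 with a logged warning. The contrast C(R) is the outer-shell
sum (R/2 < r ≤ R) minus the inner-ball sum (r ≤ R/2) — positive for the
buried-metal signature — and is isolated in one function so an
alternative analytic form can be swapped without touching callers.
Curves are evaluated at 21 radii, 2.00–7.00 Å in 0.25 Å steps. Atoms of
the site's own residues are included. The CH3/CH4 certainty is the mean
of the Pearson correlations of the C and Δσ curves against group-mean
reference curves, clamped to [0, 1]; constant curves correlate 0.
Reference curves ship as a small JSON artifact (grid, per-group curves,
provenance) and are rebuilt from any collection of validated sites.

## CH2 ensemble

Features (61): per ligand in canonical (chain, resseq, icode) order, a
Cys/His flag and a 5-way one-hot of the coordinating atom (12); the
coordinating-atom, Cα–Cα and Cβ–Cβ distances (3); the four angles
Cα1–lig1–Zn, Cα2–lig2–Zn, Cβ1–lig1–Zn, Cβ2–lig2–Zn in degrees (4); and
the two 21-point curves (42). The exact angle definitions are a
reconstruction (kept behind the encoder so they can be swapped).

Learners: logistic regression, decision tree, single-hidden-layer MLP
(32), RBF-kernel SVC (Platt-calibrated to probabilities), and a deeper
feed-forward network (64, 32) — the last is a two-hidden-layer choice
made here, as no architecture is prescribed. Each learner sits behind a
standardizer and is tuned by 10-fold cross-validation over a small
grid (LR C ∈ {0.1, 1, 10}; tree depth ∈ {3, 6, ∞}; MLP α ∈ {10⁻⁴,
10⁻²}; SVC C ∈ {0.5, 2}). Data are split 70/30 stratified jointly on
class and CC/CH/HH subgroup (class-only when a stratum has fewer than
two members). The decision is a 3-of-5 majority of per-learner
probability > 0.5; the certainty is the clamped mean probability (a
probability, not a vote fraction). All randomness flows from one seed
recorded in the model metadata; the serialized model carries the fitted
pipelines, a JSON metadata manifest, CV results and held-out metrics.

Training negatives are CH2 candidates with no modelled metal within
4 Å of the predicted zinc that additionally fail the two-ligand
validation (Q_c < 0.355 or Q_v < 0.25).

## Pipeline

Alternate conformations are collapsed to the highest-occupancy conformer
(ties → lowest altloc character) and affected residues flagged;
prediction still uses them, training-set extraction excludes them.
Verified sites (certainty > 0.5) pass redundancy removal: greedy in
descending (ligand count, certainty, then lowest chain/resseq) order,
dropping any zinc within 2.5 Å of a kept one — dinuclear sites at
3–4 Å survive. Auxiliary non-Cys/His N/O/S ligands (acidic side chains,
waters) are annotated as first-sphere (≤ 2.5 Å) or second-sphere
(≤ 4.0 Å). Metals already modelled in the input are validated and
matched to predictions by residue IoUR ≥ 0.5; coinciding predictions
are reported as confirmations, not suppressed. Predicted zincs are
written as HETATM records on a dedicated chain (`Z`) with the certainty
in the occupancy field, plus one LINK (PDB) or struct_conn (mmCIF)
entry per coordination bond.

## Evaluation

IoUR matching is greedy by descending score with a one-to-one
constraint (ties toward the lowest-keyed actual site); it is checked
against exhaustive assignment on small instances. Distance matching
counts a prediction within 5 Å of an actual site as a true positive
(nearest-actual assignment); leftover predictions mutually closer than
the threshold cluster into a single false positive. True negatives are
defined only in the classifier context. Undefined metric denominators
report as absent, never as zero.

## Synthetic fixtures and what they show

The generator builds chemically plausible coordination spheres around a
known zinc: 2.1 Å coordination bonds; the surveyed 3.6 Å inter-ligand
separation for pairs and tetrahedral directions for triples/quadruples;
idealized imidazoles (regular pentagon, 1.37 Å bonds) oriented so the
coordinating atom's lone-pair ray points at the zinc — an orientation
that also reproduces the surveyed Zn–Nδ1–Cβ ≈ 100° and
Zn–Nε2–Cβ ≈ 155° angles without further tuning. Optional shells (water
oxygens at ~3.1 Å, carbons at ~5.8 Å) give profiles the buried-metal
signature; decoys cover the disulfide pair (~2.05 Å), an inverted
shell, and a lone cysteine. The labelled 61-feature Gaussian sets
centre positives on coordinating geometry (distance 3.6 ± 0.15 Å,
angles at the per-role targets ± 4–5°, rising contrast curve) and
disperse negatives (distance 4.1 ± 0.3 Å, uniform angles, flat-to-
inverted curves); CC/CH/HH are drawn 0.2/0.3/0.5, approximating their
relative abundance among deposited two-ligand sites.

Passing these tests shows the geometric machinery is correct and that
the verification layers separate well-formed buried sites from
geometric and physicochemical decoys. It does **not** show
field-realistic accuracy: the fixtures have no backbone context beyond
stubs, no crystallographic noise model, idealized ring symmetry, and
class-conditional feature distributions far cleaner than
PDB-derived training data. Classifier checks run at 400 examples per
class; structure-level checks use single-site fixtures — sizes chosen
so the full suite runs in minutes on one CPU while still exercising
every code path.

## Known limitations

* Zinc only in v1; other metals are validated against the Zn parameters
  unless R₀/oxidation-state entries are added to the config.
* No backbone-donor sites, no electron-density checks, no energy
  minimization or clash detection beyond the distal-side rule.
* The exact analytic contrast form and the CH2 angle/feature definitions
  are reconstructions, isolated behind single functions.
* The deposited-structure check (PDB 7lyt) requires a download; it is
  not bundled.
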