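# Methods

This note documents the model, the conventions, and the numerical choices
behind `poseranker`, in the order data flows through the package. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Atom representation (`io_model`, `sybyl`)

Only heavy atoms are represented; input protonation is accepted implicitly
and hydrogens are dropped on ingestion. Every atom carries a SYBYL
chemical-environment type. Ligand types come from the Mol2 atom block when
the file provides them, from a `sybyl_types` SDF property on round trips,
or are derived from element/aromaticity/hybridization via RDKit. Receptor
types are assigned from a fixed residue-template table (standard amino
acids plus single-atom pseudo-residues used by the generator); unknown
residues fall back to generic per-element types. A template table was
chosen over an external converter to keep typing deterministic and
dependency-light — the sub-typing of protein atoms is this package's
convention, not a community standard.

Waters and a fixed list of common buffer/cryoprotectant molecules are
removed when reading a receptor PDB; metal ions of types Na, Fe, Mg, K, Mn,
Zn and Ca are retained and collapsed to a single `Met` type; all other
hetero groups are dropped. Alternate locations keep the highest-occupancy
conformer. Coordinates are Å everywhere; no unit conversion exists
anywhere in the package.

One-hot encoding places ligand and receptor types in disjoint index
blocks: a ligand sp3 carbon and a receptor sp3 carbon are different
features. An optional reserved `other` slot per block absorbs
out-of-vocabulary types when enabled; by default unknown types raise.

**Pocket truncation.** Network input keeps receptor atoms within 8 Å
(configurable) of any ligand-pose atom. A distance criterion rather than a
bounding box is used deliberately: the retained atom set is then invariant
under rigid motion of the complex, which the logit inherits. 8 Å is a
superset of every possible interface edge at the default 5 Å cross-entity
cutoff, so truncation never changes the message-passing graph.

## Layer routing and neighborhoods (`posegraph`)

A routing string (`l→l→r→l→r→l`; ASCII `->` accepted) with k+1 tokens
defines k layers; the source set of each layer equals the target set of the
previous one by construction. Edges are directed source→target pairs with
d < R_c (strict; the radial basis vanishes at R_c anyway, so the boundary
convention is numerically irrelevant). Self-edges are excluded even when an
atom belongs to both sets: d = 0 would make every basis function equal and
identity information flows through the skip connection instead. Default
cutoffs are 4.0 Å for same-entity layers and 5.0 Å whenever
ligand–receptor pairs can form edges — typical contact-shell radii,
overridable per layer. A k-d tree accelerates construction; the contract
(tested) is equality with the brute-force all-pairs result.

## The network (`graphite`)

Radial basis: b_n(d) = √(2/R_c)·j₀(z_{0n}·d/R_c) with z_{0n} = nπ the zeros
of j₀(x) = sin(x)/x. d = 0 uses the analytic limit j₀(0) = 1 and d = R_c
is set to exactly zero. The basis count is a free hyperparameter here
(default N_b = 16 per layer): no published value was available to adopt.
Because only a score is needed — never forces — no smoothing of the cutoff
is applied.

Feature bookkeeping: slot 0 is the one-hot embedding, slot ℓ the output of
interaction layer ℓ. The embedding exists for *every* atom, since any atom
may enter a bottleneck as a source or a target in a later layer; slot ℓ
exists only for that layer's target atoms. The source bottleneck h_j
projects the concatenation of all of atom j's existing feature slots to the
layer width; the target bottleneck does the same for the skip term, which
is added to the convolution sum *before* the Linear–LeakyReLU–Linear–
LayerNorm block (the written order of the architecture suggests the skip
joins before the MLP, and we follow it). Atoms with no incoming edges
receive only the skip path.

Readout pools ligand and receptor features independently at each slot —
but slot 0 is read out only for the entities of the *initial* token, and
slot ℓ only for the entities of its target token. Hence a ligand-only
configuration contributes nothing to z_R and its logit provably ignores
the receptor entirely. Sum pooling is the default (it preserves the
linearity property that doubling coincident atoms doubles the pooled
features, which the tests exploit); mean pooling is available and is the
*training* default (see below). The head is Linear–LeakyReLU–Linear to a
scalar.

Defaults: 64 channels per layer, bottleneck width = channel width, final
hidden width 128, LeakyReLU slope 0.01, LayerNorm over channels per atom
(ε = 1e-5). Initialization is uniform Kaiming-style fan-in scaling from a
recorded seed; forward passes are bit-reproducible given (params, input) on
one platform. Checkpoints are a single `.npz` map {config, vocabulary,
params, seed, version} and round-trip bit-exactly.

The forward pass, all gradients (including through LayerNorm and the
scatter/gather of the convolution), and the Adam optimizer are implemented
directly on numpy arrays and verified against finite differences in the
test suite. Minibatches are processed as one disjoint batch graph
(concatenated atom/edge arrays with index offsets); batched logits and
gradients are tested to match the per-example path exactly.

Reranking one docking attempt sorts poses by descending logit with exact
ties broken by the original docking rank (stable).

## Pose labeling (`poselabel`)

Symmetry-corrected RMSD is the minimum over all element- and
bond-order-preserving graph automorphisms of the ligand (aromatic bonds are
their own bond class) of the heavy-atom RMSD between pose and native
coordinates, with **no** re-superposition of the ligand — the docked frame
is the thing being judged. Automorphisms are enumerated with VF2 and capped
at 10,000 mappings with a warning; drug-like ligands rarely exceed
hundreds. Full-graph isomorphism is required; mismatched graphs raise
rather than guess a partial match. For cross-docking, the native pose is
first mapped through the receptor superposition into the docked receptor's
frame.

Labels: RMSD ≤ 2.5 Å → hit ("within" read as closed), > 4 Å → miss
(strictly greater), otherwise gap. The three classes partition [0, ∞).

## Cross-docking curation and splits (`crossdock`)

Structures sharing a target identifier are superposed onto the first
member by least-squares rigid fit (SVD with reflection correction) on CA
atoms matched by (chain, residue number); structures without CA atoms —
the generator's pseudo-receptors — fall back to all atoms matched by
(chain, residue number, atom name). Members fitting worse than 5 Å are
dropped and recorded. Binding sites are DBSCAN clusters (eps = 5 Å,
min_samples = 1) of the superposed native-ligand centers of mass; the COM
is the unweighted mean of heavy-atom coordinates (mass weighting is not
used, and with min_samples = 1 DBSCAN reduces to single-linkage components
at eps, which is the testable contract). Clusters are capped at five
uniformly sampled representatives (seeded). Docking attempts with no hit
pose are removed entirely; labels are never modified.

Splits: the `uniprot` kind co-locates targets sharing an identifier. The
similarity kinds (`seqsim70`/`seqsim50`) connect targets whose pairwise
sequence identity reaches the threshold and assign whole connected
components to one side, greedily packing toward the requested train
fraction (seeded component order; default 0.7, reflecting the roughly 2:1
train:test proportions of the curated crystal-structure corpus this
pipeline emulates). Identity is computed by global alignment
with match +1, mismatch 0, gap −0.5, identity = matches / shorter-sequence
length — no standard tool is implied by the construction, so the convention
is recorded in the split metadata. A single giant component triggers a
warning and best effort. The tested invariant: no train/test pair exceeds
the threshold, checked exhaustively at fixture scale.

## Training and evaluation (`traineval`)

Binary cross-entropy on the logit, hit = 1 / miss = 0. Gap poses are
dropped from training and retained in test sets (the only supported
policy). Imbalance is handled by per-epoch balanced sampling: every hit
plus an equal-size uniform sample of misses (a weighted-loss alternative
exists). Optimizer: Adam, constant lr 1e-3 (a cosine decay is available),
batch 32, 100 epochs by default — the original training schedule is not
published, so these are this package's defaults. The training default for
readout pooling is *mean*: sum-pooled readouts scale with ligand and pocket
size, which lets the model absorb target-specific offsets and mis-calibrates
logits across targets; mean pooling keeps the pooled features size-invariant
and markedly improves test-set (cross-target) AUC while leaving
within-target ranking unchanged in character. Validation holds out 10% of
training targets by id (seeded);
history records per-epoch mean loss and validation ROC AUC. Training is
deterministic given the config seed.

Metrics: ROC AUC is the probability a random positive outranks a random
negative with ties counting ½; PR AUC is reported as average precision
(step integration — whether the original figures used interpolated PR
integration is unknown, so the choice is labeled). Both delegate to
scikit-learn; the test suite checks the ROC AUC against a brute-force
pairwise estimator. Top-n pose enrichment is the fraction of attempts whose
best pose among the n highest-ranked is within 2.5 Å, for n = 1..16.
Compound enrichment is ef(ν) = ap⁻¹·a(ν)/n(ν) with n(ν) = ⌈ν·N⌉ and
score ties broken by stable input order; ef(1) = 1 and ef ≤ 1/ap
identically. AUCs are computed over hit-vs-miss poses (gaps, which have no
binary label, are excluded from AUC but participate in ranking curves).

## The synthetic generator (`synthetic`)

What it emulates: typed heavy-atom receptors lining a pocket, small
connected ligand graphs (8–30 heavy atoms, ~1.5 Å bonds), per-attempt pose
sets at the 5.0/15.5/79.5% hit/gap/miss mixture (multinomial per attempt),
docking scores correlated with pose quality plus noise, multi-conformation
receptor ensembles with a requested mean pairwise spread (default 1.6 Å,
matching reported crystal/modelled ensemble spreads), target groups with
shared identifiers, and sequence families (~88% identity within a family)
so both split kinds are exercisable.

The planted signal: k = 4 ligand atoms are assigned types complementary to
k receptor anchor atoms placed 3.0 Å away in the native pose; all other
ligand atoms are carbon scaffold types (C.3/C.ar), so the designated
contact atoms are the only ligand atoms that can complement an anchor and
the signal is not diluted by impostor contacts in mis-docked poses
(contact rule = complementary pair within 3.5 Å — resolvable by the 5 Å
cross-entity cutoff); no receptor atom comes closer than 2.2 Å. Hits are
small rigid jitters of the native pose, misses random rigid re-placements
inside the pocket, gaps rejection-sampled into the (2.5, 4] window by
combining a rotation about the centroid with a translation whose length is
solved from the quadrature identity RMSD² = RMSD²_rot + ‖t‖². Every label
is *recomputed* through `poselabel`; construction is never trusted. Poses
of one attempt are mutually ≥ 1 Å RMSD apart (the docking engine's default
minimum difference) and clash-checked. All poses of a compound are rigid
transforms of one conformer — deliberately, so that ligand-internal
features carry exactly zero pose information and a ligand-only network
must score at chance.

What it does **not** emulate: real chemistry or energetics (no force
field, no torsional flexibility, no realistic docking score distribution),
receptor side-chain rearrangement, or partial-match ligand series. Passing
tests therefore demonstrate that the architecture can extract interfacial
signal when it exists and that the pipeline's contracts hold — not that
the model reaches any particular accuracy on real docked complexes.

Ensembles: member 0 is the input structure; others are displaced by
low-frequency random sinusoidal fields (3 components, |k| ∈ [0.05, 0.2]
rad/Å) normalized per member so the expected mean pairwise RMSD equals the
requested scale (pairs with the reference contribute s, independent
perturbed pairs s√2; s is solved per ensemble size).

Generation is a pure function of (spec, seed); all sub-streams are derived
from the spec seed with fixed salts.

## Problem sizes

The default study — 20 targets × 4 receptor conformations × 64 poses
(~5,120 poses, ~100-atom pockets, 8–30-atom ligands) — is the scale at
which the package's own evaluation (test suite and acceptance script)
trains and evaluates; it is large enough for the ablation contrast
(interface vs ligand-only routing) and the top-1 recovery statistic to be
stable, while a full training run of both configurations completes in
minutes on one CPU core. Reported AUCs at this scale are qualitative
analogs of a PDBbind-scale study, not reproductions of its absolute
values.

## Known limitations

- Per-layer cutoffs, basis counts and hidden widths of the original model
  are unpublished; defaults here are conventions and the qualitative
  ablation ordering is the reproducible claim.
- The automorphism cap (10,000) silently truncates the search for
  pathological highly-symmetric graphs (a warning is emitted).
- Sequence identity uses one fixed global-alignment convention; different
  tools would draw slightly different seqsim boundaries.
- The numpy implementation is single-core and sized for desk-scale
  studies, not PDBbind-scale training.
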