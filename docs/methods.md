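# Methods

## Scope and model

`covbench` evaluates *covalent* docking tools: programs that sample ligand
poses under the constraint of a predefined chemical bond between the
ligand's electrophilic warhead and a nucleophilic receptor residue (Cys-SG
or Ser-OG). The package does not dock; it curates benchmarks, classifies
warheads, measures pose accuracy against crystallographic references, and
aggregates the measurements into selection criteria. Runs produced by any
engine (MOE, GOLD, CovDock, ICM-Pro, or others) are consumed as ordered,
scored pose lists in SDF.

## Benchmark curation

Candidate co-crystal complexes pass an ordered filter pipeline:

1. **Resolution** strictly below 3.0 Å (missing resolution fails with its
   own reason).
2. **Context** — complexes containing nucleic-acid chains are excluded, as
   are complexes with any cofactor heavy atom within 8.0 Å of a ligand
   heavy atom. The proximity scan runs on the structure *as deposited*,
   before waters/metals/cofactors are stripped from the retained target;
   running it after stripping would make the rule vacuous. The dictionary
   separating buffers/crystallization agents from cofactors ships as
   editable config (`data/buffers.yaml`).
3. **Anchor** — exactly one covalent linkage, to CYS-SG or SER-OG, as a
   single bond. Linkages are taken from LINK/struct_conn records; when a
   file lacks them, a distance rule declares a bond for a ligand heavy
   atom within 2.0 Å of an SG or 1.8 Å of an OG (covalent S–C ≈ 1.8 Å,
   O–C ≈ 1.4 Å, plus tolerance).
4. **Ligand size** — at least 5 heavy atoms and strictly fewer than 30
   rotatable bonds, counted on the pre-reaction ligand (the species the
   engine actually docks). A rotatable bond is a single, acyclic bond
   between two heavy atoms each bearing at least one further heavy
   neighbor, excluding amide C–N; the convention is configurable and
   declared rather than inherited, since different toolkits disagree at
   the margins.

Exclusions are attributed to the first filter that fires, making the
report an audit trail; the retained *set* is independent of filter order
(each filter is a pointwise predicate), which the tests assert.

## Warhead taxonomy

Fifteen warhead classes grouped under four reaction classes (nucleophilic
addition, nucleophilic substitution, ring opening, disulfide formation)
and two anchors. The class definitions are SMARTS patterns in a versioned
data file (`data/taxonomy.yaml`), not code: the canonical chemotypes
(nitrile, Michael-acceptor alkene, aldehyde/ketone carbonyl, alkyne,
guanidine, boronic acid, alkyl halide, phosphonate, epoxide/aziridine,
β/γ-lactam, lactone, thiol/disulfide, SNAr "Others") each carry one or
more interchangeable core-pattern variants. Classification picks the
highest-priority rule whose anchor and core both match; priorities form a
total order in which specific patterns outrank generic ones (nitrile
before alkyne, lactam before carbonyl) and the Cys-substitution catch-all
ranks last. Ambiguity among several matches of one rule is resolved by
topological proximity of the matched core to the known covalent link
atom. An unmatched ligand yields an explicit `Unclassified` result, not
an exception.

Reaction templates interconvert the pre-reaction ligand and the covalent
adduct. The anchor side chain is modeled as a minimal nucleophile
(methanethiol for Cys, methanol for Ser) whose S/O maps onto the link
atom. Templates are written heavy-atom conserving on both sides — leaving
groups (halide, fluoride) are kept as product fragments — so every
template has a well-defined reverse, and forward-then-reverse application
recovers a ligand graph isomorphic to the input. Templates are stored as
reaction SMARTS (authoritative) and exported as MDL RXN files for
interchange; V2000 cannot express every query feature (ring-membership,
recursive environments), so file-loaded templates can be broader than the
SMARTS originals and support an explicit `allow_ambiguous` mode.

## Pose accuracy

RMSD is **no-fit** (in-place) over ligand heavy atoms: docked and
reference poses live in the same receptor frame and are never
superposed, because docking accuracy is positional. Hydrogens are
excluded. Topologically equivalent atoms are handled by minimizing over
graph automorphisms (all isomorphisms of the heavy-atom graph,
element + bond order), enumerated via substructure matching with a cap of
10,000 mappings; past the cap the canonical-rank correspondence is used
with a warning. Symmetry handling is on by default and can be disabled.
When one input carries no bond orders (PDB het records), correspondence
falls back to the order-collapsed skeleton.

Per complex and tool: S1 = RMSD of the rank-1 (best-scored) pose, S2 =
minimum over all retained poses (best-sampled), Smax = maximum (maximal
deviated pose), P-deviation = S1 − S2 ≥ 0. With the near-native threshold
τ = 2.0 Å (inclusive): *success* iff S1 ≤ τ; *failure* iff S1 > τ and
S2 > τ. The two flags are deliberately non-complementary — a run whose
scorer misses but whose sampler found a near-native pose is neither — and
that asymmetry is kept exactly as defined.

## Selection criteria

* **Precision** P(i, x) = median over classes of the within-class median
  RMSD, for tool *i* and measurement *x* ∈ {best-scored, best-sampled};
  classes are warhead classes (15) or receptor types (9). Even-length
  medians use the midpoint rule. Lower is better.
* **Generality** — within every (class, subgroup) cell (subgroups:
  UniProt accession or warhead core) each tool's median RMSD is computed
  and all minimizers receive a mark; ties are not fractionally split, so
  marks stay integers. Reported both as the raw mark count and as the
  normalized score Σ_j (marks_j / N_ij) × 100 with N_ij the number of
  structures of class j evaluated by tool i. Requires all tools to cover
  the same entry set; anything else raises.
* **Robustness** — sample standard deviation (ddof = 1) of a tool's RMSDs
  over the whole benchmark; undefined below two results.

Profiling counts (S-Only, F-Only, S≥2, F≥2) classify each entry by how
many tools succeeded/failed on it. Pairwise significance uses the
two-sided, tie-corrected Mann–Whitney U-test; identical degenerate
samples return p = 1 by convention with a warning, and families of
pairwise tests are reported raw plus Holm-adjusted. Heat-map export
linearly interpolates deep green (≤ 1 Å) to deep red (≥ 5 Å), clamped at
the anchors.

## Site descriptors

Anchor-residue SASA uses an in-package Shrake–Rupley implementation
(golden-spiral test points, 960/atom by default), computed on the
ligand-free receptor so the value describes apo-like exposure of the
nucleophile. The atomic radius table (Chothia-style values) and the
1.4 Å water probe are editable config; absolute areas depend on that
choice, so cross-study comparisons should use the same table. Tests
cross-check against analytic sphere/two-sphere closed forms, a
10,000-point dense evaluation, and Biopython's independent implementation.
The side-chain torsion N–CA–CB–SG/OG is the signed IUPAC dihedral in
(−180°, 180°], matching Biopython's sign convention; the −180° boundary
reports as +180°. Accuracy-vs-feature tables bin median S1 per tool with
10 Å² SASA bins and 30° dihedral bins by default; empty bins are reported
missing, never zero.

## Synthetic benchmarks

The generator fabricates Gly-X-Gly receptor stubs with the anchor residue
in the middle, embeds each warhead class's example chemotype in 3D
(seeded ETKDG), and places the ligand's electrophilic atom one covalent
bond length from the anchor atom (S–C 1.81 Å, O–C 1.43 Å). Mock runs are
pure rigid translations of the reference: the no-fit RMSD of a
translation equals the shift norm exactly, and no automorphism can
reduce it (for a permutation P of one coordinate set,
mean‖x_P(i)+t−x_i‖² = ‖t‖² + mean‖x_P(i)−x_i‖²), so planted per-pose
RMSDs are recovered to machine precision under either symmetry setting.
Per-atom jitter and rotations exist as opt-in stress modes where recovery
is only approximate. Scores are rank-consistent with a configurable
score–RMSD correlation ρ, letting tests create the regime where the
best-scored pose is not the best-sampled one. Default study conditions:
10 poses per run, warhead mix proportional to the curated benchmark's
class frequencies, per-tool accuracy profiles as (μ, σ) of folded-normal
RMSD draws.

What the generator does *not* emulate: real binding-site geometry,
scoring energetics, engine-specific failure modes, or conformational
change on binding. Passing tests therefore demonstrate correctness of the
measurement and aggregation machinery, not anything about real docking
accuracy.

## Numerical and design choices

* Strict inequalities at curation boundaries (resolution < 3.0, rotors
  < 30) and an inclusive success threshold (S1 ≤ 2.0 Å) follow the metric
  definitions exactly.
* Median of an even-length list = mean of the two central values.
* Empty classes are omitted from the outer median with a warning rather
  than imputed.
* Alternate locations: altloc A kept, occupancy ignored. Coordinates stay
  in the deposited frame; residue numbering is as-deposited.
* Score orientation is declared per tool ("lower_better"/"higher_better");
  pose rank 1 always means best by the tool's own convention, and scores
  pass through unmodified.
* Problem sizes in the shipped acceptance computation (200 entries × 4
  mock tools for closure; 60 entries for planted-ranking; 200 replicates
  at n = 100/arm for the rank-test power simulation) were chosen as the
  smallest sizes at which the checked properties are unambiguous.

## Known limitations

* The SMARTS library reproduces class labels and canonical chemotypes;
  exotic warheads fall to `Unclassified` or the catch-all class and the
  library is expected to be extended as data, not code.
* Kinase-domain labels are consumed from metadata; no structural
  assignment is attempted.
* Bond-order-insensitive correspondence (the PDB fallback) can, for
  contrived resonance-symmetric ligands, admit mappings a strict matcher
  would reject.
* MOL2 reading handles single-molecule files only; multi-record pose
  lists should use SDF.
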