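# Methods

## Standardization

Every library (analyte, NP reference, fragment set) passes the same
preprocessing so that downstream identity and signature comparisons are
well-defined:

1. RDKit cleanup, then the largest organic component is kept (salt/solvent
   stripping; ties resolved by RDKit's largest-fragment chooser).
2. Charges are neutralized where chemically valid.
3. All stereochemistry — tetrahedral centers and double-bond stereo — is
   removed ("full racemization"). Deduplication and NP identity therefore
   operate on racemic InChIKeys, so enantiomers and unassigned stereoisomers
   collapse to one record.
4. Optionally, terminal sugar rings are removed (deglycosylation) so that
   glycosides are analyzed as their aglycones.
5. The structure is re-rendered to canonical SMILES; results are independent
   of input atom order.

Structural filters: a molecule enters fragment analysis only with at least
one ring and MW < 1000 g/mol. Filtered and failed records are retained with
a `failure_reason` and end as NonPNP after merge-back.

**Deglycosylation rule set.** A terminal sugar is a non-aromatic 5- or
6-membered ring with exactly one ring oxygen and carbon ring atoms, not
fused to another ring, decorated exclusively with hydroxyls and/or CH2OH
groups (at least two such hydroxyls), and attached to the rest of the
molecule through exactly one exocyclic O-glycosidic single bond. Matching
rings are removed iteratively (so oligosaccharides peel from the terminal
sugar inward); the bridging oxygen stays on the aglycone as a hydroxyl. If
removal would leave an (almost) empty structure or an unsanitizable one, the
input is returned unchanged and the event logged. These criteria are this
package's own fixed approximation of "remove the sugars before fragment
analysis"; substituted sugars (esterified, aminated) are deliberately not
removed.

## Fragment catalog

Catalog entries are the Murcko scaffolds (ring systems plus connecting
linkers) of an input fragment set, standardized and racemized as above,
deduplicated by InChIKey, with benzene excluded — benzene matches a large
share of organic molecules and carries no NP information. `frag_id` follows
first-seen input order, so a given input file always yields the same ids.
Building the catalog from its own output is a no-op (idempotence), which the
tests pin.

## Combination taxonomy

Fragment hits are all substructure matches of all catalog entries
(symmetry-equivalent atom sets collapsed; multiple placements of one
fragment are separate hits with an `occurrence` index). A hit wholly
contained in a hit of a different fragment is a matching artifact (`ffs`)
and is discarded globally before any edge is formed; ties on identical atom
sets keep the lower `frag_id`.

For a hit pair with atom sets A, B and k = |A ∩ B|:

* k = 1 → spiro fusion `fs`; k = 2 with the shared atoms bonded → edge
  fusion `fe`; k = 3…5 → bridge fusion `fb`.
* k = 2 non-bonded, or k > 5 without containment, is an overlap artifact
  (`ffo`): such pairs arise from incidental matches, not from a chemically
  meaningful fusion, and are dropped rather than typed.
* k = 0 → connection family. Bridging paths are breadth-first searches from
  each atom of A through atoms *external to both hits* into B, depth-limited
  by the connection cutoff (default 3 bonds; a direct bond is a path of
  length 1). Each reachable (a, b) atom pair is one attachment-point pair.
  No pair within the cutoff → `cfc`, no edge. One pair → monopodal `cm`.
  Two pairs → bipodal, subtyped by the attachment atoms within each
  fragment: a shared atom on either side → `cbs`; attachment atoms bonded
  within both fragments → `cbe`; otherwise `cbb`. Three or more pairs →
  `ct`. The cutoff of 3 bonds is configurable; it encodes "the fragments are
  joined by a short linker, not merely co-resident in a large molecule".

The taxonomy is exhaustive and mutually exclusive over (k, containment,
path counts), and symmetric in the pair by construction. Typed edges over a
molecule's hits form fragment-combination graphs: connected components with
at least one edge. The canonical signature renders each edge as
`min(frag_id):max(frag_id):ctype`, drops occurrence indices (repeated
identical combinations count once), sorts edge strings and joins them with
`|`; it is invariant to atom numbering and SMILES rendering.

## Status assignment

The NP reference holds (a) the racemic InChIKeys of the NP library and
(b) the union of its combination signatures. Comparison granularity is
configurable: at the default `edge` level the novelty test uses individual
pairwise combination strings (combination frequency analyses operate on
pairwise combinations, and edge-level comparison makes "novel combination"
mean exactly that); `graph` level compares whole-FCG signatures and is
strictly more permissive towards PNP. Precedence: identity (NP) first, then
any novel signature → PNP even when known signatures are also present, then
all-known → NPL, else NonPNP. Enlarging the signature set can only move
molecules PNP → NPL, never the reverse.

## Chunked execution

Large libraries are processed in chunks. The runner's contract, pinned by
tests at several chunk sizes, is that results are element-for-element
identical to a single-chunk run: every operation passed to it is pure and
per-record, and no global decision (deduplication, signature collection,
statistics) is ever taken within a chunk. Deduplication of FCGs and records
happens once, globally, by molecule identity + signature. A per-record
wall-clock timeout (default 50 s, SIGALRM-based, main thread only) converts
a stuck record into an explicit failure marker — the record becomes NonPNP
with a reason — without aborting the run.

## Spatial score

Each heavy atom contributes h·s·r·n²: hybridization h (sp 1, sp2 2, sp3 3,
other 4), stereo s (2 for potential or assigned tetrahedral stereocenters
and atoms of stereo double bonds, else 1), ring r (2 for non-aromatic ring
atoms; aromatic rings are not promoted), n = number of heavy-atom neighbors.
SPS is the sum, nSPS divides by the heavy-atom count. Counting *potential*
stereocenters makes the score invariant under the racemization used
throughout the pipeline. The constants are the published ones; a test pins
parity with the independent RDKit implementation to < 1e-9 on a fixed
25-molecule panel covering aromatics, saturated rings, stereocenters,
bridged systems and heteroatoms.

## Screening-subset selection

PNP records are grouped by the racemic InChIKey of their Murcko scaffold.
Only groups whose scaffold has exactly 17 heavy atoms (the median scaffold
size of approved/experimental drugs, used as a drug-likeness anchor) and at
least 4 members qualify. Selection draws 250 groups, then 4 members per
group, uniformly without replacement from a single seeded generator; group
keys and members are pre-sorted (by InChIKey and source id) so a seed maps
to one selection on any platform. Fewer than 250 qualifying groups is a
hard error reporting the count. PAINS triage uses the public RDKit PAINS
filter catalog.

## Cell-painting triage

Profiles are vectors of 579 modified-Z-scored image features. Induction is
100 × (count of features with |z| ≥ threshold)/579; the significance
threshold defaults to |z| ≥ 3 and is a config knob (the underlying assay
pipeline defines it upstream of this package). Activity is induction ≥ 5%.
Cluster assignment computes 100 × Pearson correlation between the profile
restricted to each reference cluster's feature subset and that cluster's
reference vector; the argmax cluster is assigned if its similarity is ≥
80%, ties break lexicographically on cluster name, and a constant restricted
vector (undefined correlation) counts as below threshold. Pearson similarity
was fixed as the single supported metric for testability. Reference
subprofiles are input data (JSON schema: name, feature indices, values);
the repository ships only synthetic subprofiles generated at test time, not
any proprietary reference set. Unassigned actives can be embedded in 2-D
with seeded UMAP together with cluster-marker profiles.

## Synthetic data

The generators exist because the real inputs (vendor catalogs, commercial NP
dictionaries, assay data) are external and license-bound; they emulate the
*structure* of those inputs, not their chemistry or biology.

* The toy catalog holds 10 distinct non-benzene ring scaffolds (plus a
  benzene input that the builder must drop).
* `compose_molecule` realizes a requested combination type by explicit
  atom-index surgery on kekulized fragments (bond addition for cm/cbe, atom
  merging for fs/fe/fb), then sanitizes and verifies that both fragments
  still match at their intended atom positions. Requests that fail these
  checks are skipped explicitly — never emitted with a wrong label — so the
  intended type is certain ground truth for every emitted molecule.
  `enumerate_composites` additionally drops constructs with incidental extra
  catalog hits, making each library molecule's combination content exactly
  one known edge.
* `make_synthetic_library` cycles the composite pool with alkyl decorations
  up to the requested size, designates a random subset of signatures as
  "natural" (first carrier copied into the NP library → NP; further carriers
  → NPL; the rest → PNP) and appends fixed decoys (benzene-only, no-hit
  ring, acyclic, MW ≥ 1000, beyond-cutoff) that must end NonPNP. Defaults —
  500 molecules, np_fraction 0.2 — keep full-pipeline runs at a few seconds
  while exercising every status.
* `make_scaffold_library` builds ≥300 scaffold groups with exactly
  17-heavy-atom two-ring scaffolds (ring templates × linker heteroatom
  patterns) and 4–6 alkyl-decorated members each, plus deliberately
  disqualified groups (3 members; 16-atom scaffolds) that a correct
  selection must never pick.
* `make_profiles` plants disjoint 40-feature blocks per cluster with strong
  (|z| 4.5–8) reference vectors; members reproduce their block scaled with
  small noise (subset correlation ≳ 0.98, induction ≥ 5% by construction),
  and "novel" profiles put their signal on a reserved block orthogonal to
  every cluster subset.

Passing tests on these worlds demonstrate the correctness of the logic —
taxonomy, precedence, invariance, arithmetic — not chemical or biological
realism: synthetic molecules are small two-fragment composites, the NP
"dictionary" is a subset of the library itself, and profiles have idealized
block covariance without the correlated noise of real imaging features.

## Numerical and degenerate-input choices

* Substructure matching caps at 4096 placements per fragment (far above
  anything the composers produce).
* Record order is preserved by all set-like operations; no sorting by
  structure is needed for reproducibility.
* Empty inputs: empty record list → empty result; all-acyclic fragment set
  or empty NP library → hard error; a molecule with hits but only discarded
  pairs is NonPNP.
* All randomness flows through explicit integer seeds into numpy
  generators; UMAP runs single-threaded under a fixed `random_state`.

## Known limitations

* The deglycosylation and connection-cutoff rules are documented
  approximations of conventions defined in external tooling; both are
  configurable.
* Graph-level vs edge-level signature comparison changes PNP/NPL balance on
  molecules with multi-edge FCGs; edge level is the default.
* The per-record timeout uses SIGALRM and is inactive off the main thread
  (results are then computed without a timeout guard).
* Tautomer canonicalization is out of scope; tautomers may carry distinct
  InChIKeys and signatures.
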