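# pnpkit

Pseudo-natural-product (PNP) classification of compound libraries via
natural-product fragment-combination graphs.

Natural products (NPs) remain the richest source of biologically validated
chemical matter, but biosynthesis explores only part of NP-like chemical
space. *Pseudo-natural products* are synthetic compounds that combine
NP-derived fragments in arrangements nature does not produce: they keep the
biological relevance of NP fragments while escaping the structural limits of
biosynthetic pathways, and they are strongly enriched among clinical
compounds. `pnpkit` is a library + CLI for finding them in large screening
collections, for chemists and chemical biologists who want to triage vendor
catalogs or in-house libraries by NP-fragment content, spatial complexity
and (optionally) cell-painting bioactivity.

## What it computes

**Fragment-combination graphs (FCGs).** Every molecule is standardized
(largest organic component, charge neutralization, racemization, optional
deglycosylation), filtered (rings > 0, MW < 1000 g/mol) and matched against a
catalog of NP fragment scaffolds. Each pair of matched fragments is typed by
the overlap of their atom sets A, B (k = |A ∩ B|):

| k | situation | type |
|---|-----------|------|
| ≥1 | one hit inside the other | ffs (artifact, discarded) |
| 1 | spiro fusion | fs |
| 2, bonded | edge fusion | fe |
| 3–5 | bridge fusion | fb |
| 2 non-bonded or >5 | overlap artifact | ffo (discarded) |
| 0, one bridge ≤ cutoff | monopodal connection | cm |
| 0, two bridges | bipodal: shared / adjacent / other attachment atoms | cbs / cbe / cbb |
| 0, ≥3 bridges | tripodal+ | ct |
| 0, nothing within cutoff | too far apart | cfc (no edge) |

Typed edges over one molecule's hits form FCGs (connected components), each
with a canonical text signature such as `3:9:cm|5:9:fe`.

**Status.** Against an NP reference (the InChIKeys of an NP library plus all
FCG signatures observed in it), a molecule is **NP** if structurally
identical to a reference NP, **PNP** if it carries at least one fragment
combination unseen in NPs (a novel combination wins over known ones),
**NPL** (NP-like) if all its combinations occur in NPs, and **NonPNP**
otherwise.

**Complexity.** The spatial score SPS sums, over heavy atoms,
hybridization × stereo × non-aromatic-ring × (heavy neighbors)² terms;
nSPS = SPS / heavy-atom count is a size-independent complexity density.

**Screening selection & profile triage.** PNPs are grouped by the racemic
InChIKey of their Murcko scaffold; groups with 17-heavy-atom scaffolds and
≥4 members enter a seeded 250 × 4 random selection (a PAINS filter is
available for triage). Cell-painting profiles (579 modified-Z-scored
features) get an induction value (% features with |z| above threshold,
active at ≥5%), a bioactivity-cluster assignment by Pearson similarity ≥80%
on cluster-specific feature subsets, and a seeded UMAP embedding of
unassigned actives.

## Worked example

```python
from pnpkit import analyze_molecule, build_catalog, nsps
from pnpkit.standardize import MoleculeRecord, PipelineConfig, standardize_record
from pnpkit.status import build_np_reference, classify_molecule

catalog = build_catalog(["c1ccccc1", "c1ccncc1", "C1CCNCC1", "C1CCNC1"])
# benzene is excluded -> [(0, 'c1ccncc1'), (1, 'C1CCNCC1'), (2, 'C1CCNC1')]

np_rec = standardize_record(MoleculeRecord("np_1", "c1ccncc1C1CCNC1"))
reference = build_np_reference([np_rec], catalog, PipelineConfig())
# reference.np_signatures == {'0:2:cm'}  (pyridine-pyrrolidine, monopodal)

query = standardize_record(MoleculeRecord("q_1", "C[C@H]1CCCN1c1ccncc1"))
# stereo stripped: query.smiles_std == 'CC1CCCN1c1ccncc1'
analysis = analyze_molecule(query.smiles_std, catalog)
print(analysis.edge_strings)                           # ['0:2:cm']
print(classify_molecule(query, analysis.fcgs, reference))  # NPL
print(nsps(query.smiles_std))  # ComplexityScore(sps=277.0, nsps=23.08...)
```

The query contains pyridine (fragment 0) and pyrrolidine (fragment 2) joined
by a single bond — the monopodal combination `0:2:cm`. That combination is
present in the NP reference, and the query is not itself a reference NP, so
it is NP-like (NPL); its complexity density nSPS ≈ 23.1 sits in the range
typical of bioactivity-enriched compound classes.

The same analysis runs from the shell: `pnpkit run --config config.yaml`
executes standardize → catalog → classify → NP reference → status →
merge-back and writes a run manifest; each stage is also its own subcommand
(`pnpkit standardize|build-catalog|classify|np-ref|status|nsps|summarize|
select-subset|cpa|make-fixtures`). Outputs are byte-identical for any
`chunk_size`.

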