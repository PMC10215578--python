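# gemcurate

Automated curation, expansion, construction and merging of genome-scale
metabolic models (GEMs).

GEM reconstructions accumulate annotation errors that manual curation cannot
keep up with: metabolite names with typos or unofficial synonyms, wrong or
missing cross-references (KEGG, ChEBI, PubChem, HMDB, LipidMaps, InChI),
reactions with no database identity, elementally imbalanced reactions, and
gene–protein–reaction (GPR) rules that drift out of sync with enzyme
databases. `gemcurate` implements an algorithm-aided curation pipeline that
repairs all of these against reference catalogs, expands a model with
compartment-specific isoenzyme reactions, builds a network from pathway maps,
and merges networks under a stoichiometric-consistency gate. Everything runs
offline from tabular catalogs and SBML/KGML files; a seeded fixture generator
provides realistic inputs with known ground truth.

## The algorithms

**Metabolite identification.** A model metabolite is compared with every
catalog name and synonym by the longest common substring (LCS):

    score(a, b) = LCS(a, b) / max(|a|, |b|)  ∈ [0, 1]

after case-folding and whitespace collapse, so the score is 1 exactly for
equal names and degrades gracefully under typos. If the best name score falls
below the threshold (default 0.82), the *neutralized* molecular formula is
compared instead — charge is folded into the hydrogen count, so protonation
conventions cannot break the match. A match donates the catalog's
cross-references: missing identifiers are added, conflicting ones corrected.

**Reaction identification.** A reaction's fingerprint is the pair of key sets
(Sᵢ, Pᵢ) of its substrates and products (keys taken in priority order
KEGG > ChEBI > HMDB > LipidMaps > name > formula; protons excluded). Two
fingerprints are compared with four Jaccard indices

    JI(S_i,S_j), JI(S_i,P_j), JI(P_i,S_j), JI(P_i,P_j),   JI(A,B) = |A∩B|/|A∪B|

combined into a total JI_T = JI_SS + JI_PP ∈ [0, 2] (the swapped orientation
JI_SP + JI_PS is also considered when either reaction is reversible). A total
of 2 is a perfect match; identification demands a perfect match by default
and donates EC numbers from the reference.

**Mass balancing.** With the reaction written as an atom matrix *M* (rows =
participants, columns = atoms, product rows negated), a positive coefficient
vector *x* balances it iff *Mᵀx = 0*. A four-method cascade tries: (1) the
reaction's own coefficients, (2) the exact rational nullspace of *Mᵀ*,
(3) enumeration over the RREF parameterization, keeping the strictly positive
integer solution with minimal coefficient sum, (4) a linear program that
minimizes the total absolute per-atom imbalance with coefficients bounded
away from zero. If all fail, candidate species (H⁺, H₂O, K⁺, Na⁺, Ca²⁺, Fe, R)
are inserted one or two at a time and the cascade re-runs. Glycan building
blocks (`(Gal)2(GlcNAc)1`) are treated as pseudo-atoms so glycan chemistry
balances with the same machinery.

**S-GPRs and localization.** EC-keyed gene-association records build
stoichiometric GPR trees: complex subunits under AND nodes with protomer
counts, isoenzymes under OR (`(2*G1 and G2) or G3`); stripping the counts
yields the classical GPR. Gene spellings from different sources are unified
by a bounded Levenshtein merge guarded by Ensembl identity. Per-gene GO
cellular-component records localize each catalytic unit (complex = the
intersection of its subunits' locations), and the model is expanded with a
compartment-local copy of every reaction wherever an isoenzyme lives and the
reaction is absent.

**Consistency-gated merging.** Equivalent entities between two networks are
paired (metabolites by shared xref or name similarity within the same
compartment, reactions by perfect fingerprint, genes by Ensembl id), so the
merged size per class is |a| + |b| − |overlap|. Because merging two
stoichiometrically consistent networks does not guarantee a consistent
result, incoming reactions are admitted in batches with a positive-mass-
vector test (find *m ≥ 1* with *Nᵀm = 0* over internal reactions) after each
batch; reactions that break consistency are quarantined.

## Worked example

Generate a 40-reaction fixture with seeded corruption, curate it, and check
the result:

```sh
gemcurate fixtures --seed 7 --n-reactions 40 --out demo/fix
gemcurate curate --model demo/fix/corrupted_model.xml \
    --catalog demo/fix/metabolite_catalog.tsv \
    --reactions demo/fix/reaction_catalog.tsv \
    --threshold 0.82 --out demo/curated
gemcurate check --model demo/curated/curated.xml --out demo/qc
```

The fixture injects 12 name typos, 5 wrong KEGG ids and 6 deleted balancing
species (H₂O/H⁺). `demo/curated/report.json` then shows:

```
matched: 95   unmatched: 0
added:     {ChEBI: 47, HMDB: 95, InChIKey: 95, KEGG: 2, LipidMaps: 27, PubChem: 95}
corrected: {KEGG: 5}
reactions_identified: 35   rebalanced: 6
```

Every metabolite was identified despite the typos (95/95); the 5 corrupted
KEGG ids were corrected and thousands of missing identifiers added; all 6
imbalanced reactions were rebalanced by re-inserting the deleted species. The
QC report (`demo/qc/report.json`) confirms the curated model is
stoichiometrically consistent, with 43 of 46 reactions elementally balanced
and the remainder classified (2 exchange reactions, imbalanced by definition,
and 1 planted pair of coupled half-reactions that cannot be balanced without
decoupling).

The other subcommands follow the same pattern: `expand` (isoenzyme
compartment copies), `build-db` (network from KGML pathway files), `merge`
(consistency-gated merge) and `balance` (cascade report). Options can also be
given in a YAML config file via `--config` (keys: `threshold`, `case_fold`,
`use_formula`, and the fixture rates); command-line flags take precedence.

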