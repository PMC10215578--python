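# Methods

This note documents the models and procedures implemented in `gemcurate`,
the parameters that matter, the numerical choices, what the synthetic
fixtures do and do not emulate, and the design decisions taken where the
problem was genuinely open.

## Text-similarity metabolite identification

Names are normalized (case fold, whitespace-run collapse, strip) and scored
by `LCS(a,b) / max(|a|,|b|)`, where LCS is the longest *contiguous* common
substring. The denominator makes the score 1 only for equal normalized
strings and penalizes length mismatch symmetrically. Two empty strings score
0 (nothing was matched). The name stage runs first; only when its best score
falls below the threshold is the formula stage consulted — the two bases are
kept sequential rather than combined into one number, and the basis of every
match is recorded.

Formulas are compared as canonical strings of the *neutralized* composition:
charge is folded into hydrogens (`H := H − charge`, clamped at zero, charge
set to 0). This is idempotent and reflects that charge differences between
GEMs are almost always protonation-state conventions. Formula matching
cannot distinguish isomers; compounds sharing a neutralized formula are
ambiguous for this fallback, ties break toward the lexicographically
smallest catalog id, and the fixture generator's recoverability labels mark
such cases accordingly.

**Threshold.** Default 0.82 (dimensionless, in [0, 1]). With names of 10–20
characters this tolerates roughly one edit near an end of the string while
rejecting unrelated compounds; identification accuracy is empirically flat
over 0.1–0.82 on the fixture corpus (the threshold-robustness test), because
the argmax is almost always the true entry and the formula fallback catches
name misses.

## Jaccard reaction identification

Fingerprints are *sets* of participant keys; stoichiometric coefficients do
not weight them. Keys use the first available of KEGG, ChEBI, HMDB,
LipidMaps, normalized name, neutralized formula; a participant with none of
these contributes a sentinel key unique to it, so unannotatable metabolites
can never produce spurious matches. Protons are dropped from both sides
(their presence encodes protonation conventions, not chemistry).

The pair score is `JI(S_i,S_j) + JI(P_i,P_j)`, with the swapped-orientation
total `JI(S_i,P_j) + JI(P_i,S_j)` considered only when at least one of the
two reactions is reversible — direction is meaningful for irreversible
reactions. Empty-vs-empty sides score 1 (identical empty sides), so exchange
reactions compare sensibly. The score is computed per reaction pair and
maximized over the catalog; a total of 2 is a perfect match. Identification
accepts only perfect matches by default; relaxed mode returns the argmax
above a floor (default 1.5, exposed in the call signature) and is off by
default because partial fingerprint matches frequently identify neighboring
reactions in a pathway.

## Mass balancing

The atom matrix `M` has one row per participant and one column per atom or
pseudo-atom; product rows are negated, so `Mᵀx = 0` with `x > 0` is the
balance condition. Coefficients are exact rationals end to end; every
solution any method returns is re-verified exactly.

Cascade order and numerical choices:

1. **check** — exact evaluation of the imbalance vector with the reaction's
   own coefficients.
2. **nullspace** — sympy rational nullspace of `Mᵀ`. Accepted only when
   one-dimensional with a strictly positive (or strictly negative, then
   negated) direction, scaled to the smallest positive integers.
   Higher-dimensional nullspaces defer to the next method.
3. **rref** — free variables of the reduced row echelon form are enumerated
   over 1..20 (at most three free variables); pivot values must come out as
   positive integers ≤ 20. Among solutions the minimal coefficient sum wins,
   ties broken lexicographically. The integer cap bounds the search and is
   far above any stoichiometry seen in curated GEMs.
4. **lp** — minimize Σ_atoms |net(atom)| with coefficients ≥ ε = 10⁻³
   (absolute values linearized with one auxiliary variable per atom; HiGHS
   via scipy). Accepted when the optimum is ≤ 10⁻⁶; the float solution is
   rationalized (denominator limit 1000) and must then re-verify exactly.
   This reaches balances the integer enumeration cannot, e.g. fractional
   stoichiometries or nullspaces with more than three dimensions.

**Candidate-species insertion.** On cascade failure, the species H⁺, H₂O,
K⁺, Na⁺, Ca²⁺, Fe, R are tried in that fixed order, on the substrate side,
product side, then both; then pairs of two distinct species (the cap of two
added species bounds the search and keeps the repair conservative). A
candidate is only tried if it supplies at least one imbalanced atom. For
each insertion the cascade runs twice: first with the original coefficients
held fixed and only the added species' coefficients solved (an exact linear
solve), then with all coefficients free. The fixed-originals pass is
preferred because it is the minimal perturbation of the curated reaction —
without it, atom-only balancing happily "repairs" a missing-water reaction
by rescaling O₂ instead (charge is not an objective here; it is handled
upstream by formula neutralization). Fe is inserted as charge-0 `{Fe: 1}`
since no oxidation state can be inferred.

**Classification.** Boundary reactions (exchange, sink, biomass) are
imbalanced by definition and never modified. Reactions mixing glycan-block
and plain molecular formulas cannot be balanced in either unit system and
are reported as `mixed_glycan_molecular`. Missing formulas are fatal for
that reaction (`missing_formula`). Everything else that survives the full
cascade with additions is reported as `coupled` — the signature of two
independent conservation violations written as one reaction, which can only
be fixed by decoupling. Reactions carrying generic R/X groups are reported
but never modified when the model is treated as a curated reference
(`protect_generic_groups=True`): the composition of those groups is
reaction-specific (typically pools) and rewriting their stoichiometry is
unsafe; such outcomes carry a `generic_protected` flag.

Glycan building blocks are pseudo-atoms: `(Gal)2(GlcNAc)1` contributes two
`Gal` and one `GlcNAc` columns, so elongation reactions written in blocks
balance with the ordinary machinery. Because SBML's `chemicalFormula`
cannot carry block tokens, the full formula string lives in a per-species
annotation and the fbc attribute is set only for plain formulas.

## S-GPRs, localization, expansion

Association records sharing a `complex_group` become one AND node whose
leaves carry protomer counts; distinct groups and singletons are isoenzyme
branches under OR. Protomer-count conflicts between sources keep the
maximum (a source reporting a higher count has usually resolved the
stoichiometry; the conflict is logged). The serialization dialect is
`k*GENE` with `and`/`or` and parentheses; `and` binds tighter than `or`.
The classical GPR is the same tree with all counts 1 and is what goes into
the SBML fbc gene-product association; the S-GPR string rides in a reaction
annotation, preserving COBRA compatibility.

Cross-source gene unification uses Levenshtein distance ≤ 1 on normalized
symbols, merging only toward a spelling with strictly more record support,
never across distinct Ensembl ids, and never when two candidate targets are
equally plausible (ambiguity leaves the records unmerged with a warning).
The strict-support rule matters in dense identifier spaces where many valid
ids are one edit apart.

A complex's location is the intersection of its subunits' GO cellular
components (an empty intersection contributes nothing and is logged); a
reaction's locations are the union over its isoenzyme branches. Expansion
adds `<reaction>__<compartment>` copies wherever an isoenzyme lives and no
fingerprint-identical reaction already exists in that compartment,
re-pointing participants to compartment-local metabolite instances
(`<met>@<comp>`, created on demand, reused when a same-named instance
exists) and restricting the copy's GPR to the branches supporting that
compartment. Expansion never alters existing entities and is idempotent.

## Building and merging networks

KGML pathway maps supply reactions (compound references, reversibility) and
EC numbers via enzyme entries; KGML carries no stoichiometric coefficients,
so all participants enter with coefficient 1 and the balancing cascade
restores true coefficients afterwards. Reactions shared between maps are
deduplicated by perfect fingerprint match. Compartment membership is a
metabolite field; id suffixes are applied only at SBML export.

Stoichiometric consistency is the existence of a mass vector `m ≥ 1` with
`Nᵀm = 0` over internal reactions (boundary columns excluded), solved as a
feasibility LP; atomic masses witness any elementally balanced network. On
infeasibility, a MILP maximizes the number of metabolites that can carry a
mass ≥ 1 (binary indicators `z_i ≤ m_i`, mass upper bound 10⁴); the
complement is the inconsistent set. The merge gate admits incoming
reactions in deterministic id-sorted batches of 50, re-tests after each
batch, and on failure re-admits the batch one reaction at a time,
quarantining the culprits; quarantine is per-reaction (the alternative —
removing metabolites — discards more information). Conflicts between the
two networks resolve toward the first argument, which is positioned as the
curated reference being expanded.

## Synthetic fixtures

The generator emulates the curation setting end to end: a glycolysis-like
core with real formulas plus randomly composed balanced reactions (product
compositions partition the substrates' atom totals, so balance and
consistency hold by construction), gene/complex associations with protomer
counts and compartment assignments, matching metabolite and reaction
catalogs, and KGML maps with deliberate cross-map sharing. Optional planted
structures: pure-block glycan elongation, an unbalanceable coupled reaction
(its imbalance involves only C and N, which no candidate species supplies),
and exchange/transport pairs. Default scale is 20–200 reactions — large
enough to exercise every code path, small enough for sub-minute tests.

Corruption injects the error classes curation must repair: single-edit name
typos (synonyms are removed from typo'd metabolites so the typo is a real
obstacle), wrong KEGG ids, deleted H₂O/H⁺ participants, and duplicated
metabolites under synonym names. Every truth-map entry carries a
`recoverable` flag computed at corruption time by re-scoring the corrupted
record against the catalog under the same LCS rules the identifier uses: an
error is recoverable exactly when the true entry is still the unique best
match at the configured threshold. Recovery tests demand 100% of
recoverable errors and require every failure to trace to an entry marked
unrecoverable.

What the fixtures do *not* emulate: real-database ambiguity (many compounds
per formula, promiscuous ECs, reactions differing only in cofactor usage),
incomplete catalogs, multi-compartment reference models with thousands of
entities, or malformed source records. Passing fixture tests therefore
demonstrates correctness of the algorithms under clean-but-corrupted
conditions, not the field accuracy one would measure against live
databases, which is limited by that ambiguity rather than by the algorithms.
Fabricated identifier spaces are offset by seed so that fixtures from
different seeds never share fake database ids (two fixtures sharing an id
would otherwise look like the same compound with different compositions —
a scenario the consistency gate correctly rejects rather than merges).

## Known limitations

- Charge is not balanced as an objective; it enters only through formula
  neutralization. Reactions balanced in atoms but not charge pass.
- Formula-based identification cannot resolve isomers.
- The RREF enumeration is bounded (three free variables, cap 20); beyond
  that the LP takes over and may return non-minimal coefficients.
- The consistency MILP reports *a* maximal consistent set; when several
  maximal sets exist the choice among them follows solver determinism.
- KGML input deliberately covers the reaction/compound/enzyme subset of the
  format needed for network building; layout and relation elements are
  ignored.
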