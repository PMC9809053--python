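# Methods

This note documents the models and procedures implemented in `molfrag`,
their assumptions, the parameters that matter, and the design decisions
taken where the design was genuinely open.

## Structure representation and canonicalisation

Canonical SMILES is the only retained structural representation:
molecule records, fragment keys, settings files and result tables all
work on strings, and RDKit molecule objects are created on demand.  All
deduplication is string equality on one canonical form, produced by
`molfrag.chemio.canonicalise`:

1. parse with full RDKit sanitisation (one fixed aromaticity perception
   model, applied once on import);
2. if the input cannot be kekulised — which is the case for
   functional-group pseudo-fragments that contain aromatic atoms outside
   rings, such as the hydroxy-on-aromatic-carbon group `[H]Oc` — fall
   back to a partial sanitisation that skips kekulisation and folds
   explicit hydrogen atoms into hydrogen counts;
3. write RDKit canonical SMILES.

This makes `canonicalise` idempotent and gives the same key for a parsed
exemplar string and for the same fragment cut out of a real molecule.
Stereochemistry is preserved on import but dropped on atoms whose bonds
are cut during fragment extraction (a cut can invalidate a
stereocentre); the fixture panel is stereochemistry-free.

**Cut-bond convention (framework-wide).**  Whenever a fragment is
extracted, bonds to atoms outside the fragment are cleaved without
preserving any information and open valences are saturated with
hydrogen.  Atoms whose aromatic ring is broken by the cut are
de-aromatised and re-saturated (so the carbon skeleton of pyridine
becomes pentane); aromatic systems wholly inside a fragment stay
aromatic.

## Functional-group extraction (`ertl-fg`)

Atom marking applies five rules, in order, each atom receiving the first
matching rule as its primary reason:

1. every heteroatom (neither C nor H);
2. every carbon in a non-aromatic C=C or C#C bond;
3. every carbon double- or triple-bonded to a heteroatom;
4. every acetal-like carbon: non-aromatic, only single bonds, with at
   least two O/N/S neighbours that themselves bear only single bonds;
5. all atoms of three-membered rings containing a heteroatom.

Each connected component of marked atoms is one functional group; each
connected component of unmarked atoms is one remnant.  Marked and
unmarked atoms therefore partition the heavy atoms; the first-sphere
unmarked carbon neighbours shown with each group are depiction-only
duplicates.

Environment depiction: environment carbons keep their aromatic or
aliphatic typing (an aromatic attachment is written lowercase even
outside a ring).  In **generalized** mode (default) they carry no
hydrogen specification of their own — phenol's group canonicalises equal
to `[H]Oc`.  In **full** mode every atom is written with its real
hydrogen count; counts matching the SMILES valence default normalise
back to bare atoms, so the two modes differ exactly where the real
environment deviates from the default (phenol: `[c]O`; isopropanol:
`[CH]O`).  Remnants may be aromatic (phenol's remnant is benzene): the
framework keeps whatever skeleton the unmarked atoms form and only
saturates the cuts.

Preconditions: the algorithm accepts the organic element subset
{H, C, N, O, S, P, Se, F, Cl, Br, I}; anything else is filtered as a
metal/metalloid.  Charges are neutralised in preprocessing by adding
hydrogens to anions and removing them from hydrogen-bearing cations;
molecules whose charges cannot be neutralised this way (e.g. quaternary
ammonium) are demoted to FILTERED rather than raising.

## Sugar removal (`sugar-removal`)

Circular sugar detection: non-fused rings of size 5 or 6 with exactly
one ring oxygen, all ring carbons sp3, whose number of exocyclic
single-bonded oxygens divided by ring size is at least
`exocyclic_oxygen_ratio_min` (default 0.5, i.e. a pyranose with four
oxygens on six ring atoms qualifies, tetrahydropyran does not).  A hit
comprises the ring plus those exocyclic oxygens.  Seven-membered sugar
rings and fused/spiro sugars are out of scope.

Linear sugar detection (off by default): acyclic chains of 3–7 carbons,
each bearing exactly one oxygen substituent (hydroxy or carbonyl), chain
atoms not in rings and not branched.  Stereochemistry is ignored
entirely, so no anomeric or D/L classification is attempted.

Removal is iterative: detect, delete one removable hit (the one with the
lowest atom index, for determinism), re-detect, until none remains.
With `remove_only_terminal` (default) only hits whose removal leaves at
most one substantial component are deleted, so the aglycone is never
disconnected.  Two conventions:

- the glycosidic bridging oxygen stays with the aglycone — an aryl
  glycoside yields a phenol, an ether to a removed ring becomes a
  hydroxy group;
- disconnected leftovers below `min_aglycone_heavy_atoms` (default 5)
  heavy atoms — typically the hydroxymethyl arm freed from a pyranose —
  are discarded, and the same threshold defines "substantial" in the
  terminality test.

The defaults (circular on, linear off, terminal-only on, ratio 0.5,
threshold 5) are this package's documented choices; they reproduce the
expected behaviour on the fixture panel (salicin → salicyl alcohol, free
glucopyranose → nothing) but are not claimed numerically identical to
any other deglycosylation tool.

## Scaffolds (`scaffold`)

The scaffold atom set is computed by iteratively deleting terminal
acyclic atoms (heavy-atom degree ≤ 1) until a fixed point; what remains
is the ring atoms plus the linkers connecting them.  Exocyclic double-
or triple-bonded atoms attached to retained atoms (ring or linker) are
added to the scaffold, following the standard convention that a ring
carbonyl belongs to the framework.  Ring systems are the connected
components of ring atoms under ring bonds — fused and spiro rings form
one system, biphenyl forms two.  Side chains are the components of the
complement; scaffold atoms and side-chain atoms partition the heavy
atoms exactly.  The implementation is cross-checked in the test suite
against RDKit's independent Murcko-scaffold routine over the whole
panel.

Parent enumeration works on scaffolds (fixed points of scaffold
extraction).  A *terminal ring* is a ring whose exclusive atoms (atoms
in no other ring) can be deleted — together with their exocyclic
double-bond partners — leaving a connected structure after re-pruning
the exposed linkers.  Breadth-first removal of one terminal ring at a
time collects every distinct canonical parent down to single rings,
excluding the input itself; every parent has strictly fewer rings than
its child, so enumeration terminates.  No chemistry-rule prioritisation
of which parent is "the" parent is implemented; for tree-like use,
`tree_path` offers one documented linear path (smallest terminal ring
first, ties by canonical order of the resulting parent).

## Engine: runs, pipelines, aggregation

A run partitions the input into contiguous chunks, processes chunks
independently and recombines results in input order, making the output
independent of the thread count by construction.  Per-molecule outcomes
are isolated: a structure is FILTERED (with a reason), FAILED (logged,
run continues), or contributes a fragment list; preprocessing that
changed the structure is recorded as PREPROCESSED.

Aggregation groups fragments by canonical SMILES: frequency is the total
count, molecule frequency the number of distinct input molecules, and
the sample parent is drawn by a run-level seeded generator (seed is an
explicit parameter and CLI flag, default 0 — reproducibility was chosen
over emulating an unseeded pick).  The fragment table is sorted by
frequency descending, ties by canonical SMILES ascending.  Total
fragment frequency always equals the summed per-molecule counts.

Pipelines: stage 1 consumes the input molecules with the same semantics
as a single run; every later stage consumes the fragments of the stage
before it, with per-fragment results cached per stage.  A fragment a
mid-pipeline stage filters, cannot preprocess, or fails on passes
through unchanged with a logged note — it does not vanish, which keeps
the conservation invariant and lets, e.g., an organometallic survive an
element-restricted stage.  Final frequencies are traced back to the
original input molecules, so molecule frequency counts molecules, not
intermediate fragments.

Settings are persisted as line-based `key=value` text files; on loading,
invalid values and unknown keys warn and fall back to the default, so a
stale file can never make a run abort.

## File formats

SMILES files are whitespace- or tab-separated, first token the
structure, optional second token the name; a single leading header line
is auto-detected by first-token parse failure.  Unparsable lines are
skipped, counted and logged; names default to `Molecule_<index>`.  SD
files and Molfiles (V2000 and V3000) are read through RDKit, with
corrupt blocks skipped.  Results are exported as RFC-4180 CSV
(fragments table and per-molecule items table) and as an SD file with
`frequency`, `molecule_frequency` and `sample_parent_name` properties.

One known representational limit: molfiles cannot carry atom aromaticity
outside rings, so generalized-mode functional-group pseudo-fragments
(like `[H]Oc`) do not survive an SD round trip as structures.  The SD
export therefore also carries the authoritative canonical SMILES in a
`fragment_smiles` property; all molfile-representable fragments
(remnants, scaffolds, side chains, aglycones) round-trip exactly, which
is what the test suite asserts.

## The fixture panel

The built-in panel (`molfrag.fixtures`) holds 22 hand-curated toy
molecules spanning alkanes, the classic functional-group exemplars
(phenol, ethanol, ethene, acetic acid, ester, ether, amide), aromatics
and scaffold cases (benzene, toluene, anisole, diphenylmethane, a
three-ring cyclohexane–benzene–pyridine chain), sugars (glucopyranose,
salicin, glycerol), and the edge cases (a neutralisable anion, a
non-neutralisable cation, an organometallic).  The three-ring chain
deliberately uses three *different* rings so its five contiguous
subchains are five distinct parents.  Expected fragment multisets were
derived by hand application of the stated rules and are cross-checked by
an independent brute-force per-atom marking oracle in the test suite;
they are never produced by running the implementation on itself.

The panel is toy-sized by design: it covers every rule branch but not
the size, stereochemical richness or tautomeric ambiguity of real
compound libraries, so passing tests demonstrate rule correctness and
framework invariants, not field performance on databases of natural
products.  The acceptance script's determinism check uses the panel
repeated to 200 molecules with permuted order — large enough to span
several thread chunks while keeping the whole script in seconds.

## Numerical and degenerate-input choices

- Tie-breaks everywhere are by canonical SMILES order, never by hash or
  insertion order; iteration over detected hits and components starts at
  the lowest atom index.
- Empty structures fragment to an empty list; acyclic molecules have no
  scaffold and dissect to an empty list with a logged warning; an
  all-filtered run completes with an empty fragment table and a warning
  rather than an error.
- Fragment extraction recomputes hydrogen counts explicitly: atoms that
  lost a neighbour gain exactly the lost bond order in hydrogens;
  de-aromatised atoms are refilled to their default valence.

## Known limitations

- The generalized environment depiction is exact for the documented
  exemplars; for multi-atom environments it is this package's own
  convention (bare atoms, hydrogens unspecified).
- Sugar detection does not handle fused or spiro glycosides and offers
  no sugar classification; linear detection rejects branched chains.
- Parent enumeration returns the set of parent scaffolds, not the
  scaffold-network edges between them.
- Recursive re-fragmentation of side chains (feeding a stage's output
  back into itself until fixed point) is not implemented; pipelines are
  strictly feed-forward.
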