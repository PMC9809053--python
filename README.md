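# molfrag

A headless, scriptable molecule-fragmentation framework for
cheminformatics and drug-discovery work: it decomposes sets of organic
molecules into chemically meaningful substructures — functional groups,
glycosidic moieties, scaffolds and their parents — and profiles how
often each fragment occurs across the set.

Looking at a compound library through its fragments is a standard way to
characterise chemical space: which functional groups dominate a natural
product collection, which scaffolds recur in a screening deck, what is
left of a glycoside once its sugars are stripped.  `molfrag` packages
three rule-based fragmentation algorithms behind one plugin contract,
lets them be composed into pipelines, and reports deduplicated
fragment-frequency tables — all from the command line or from Python,
with no GUI and no external databases.

## Algorithms

Every algorithm implements the same contract (`should_filter`,
`preprocess`, `fragment`) and is configured by typed, persistable
settings:

- **`ertl-fg` — functional-group extraction by atom marking.**  Atoms
  are marked by five structural rules (heteroatoms; carbons in
  non-aromatic C=C/C#C bonds; carbons multiple-bonded to heteroatoms;
  acetal-like sp3 carbons; atoms of heteroatom-containing three-rings).
  Each connected component of marked atoms becomes one functional-group
  fragment carrying its first-sphere unmarked carbon neighbours as
  environment — an aromatic attachment stays lowercase, so phenol's
  hydroxy group is reported as `[H]Oc`.  The unmarked complement yields
  hydrogen-saturated carbon-skeleton remnants.
- **`sugar-removal` — glycosidic-moiety detection and removal.**
  Circular sugars are non-fused 5/6-rings with one ring oxygen, sp3 ring
  carbons and an exocyclic-oxygen density ≥ 0.5; linear sugars are 3–7
  carbon polyol/polyketo chains.  Moieties are removed iteratively
  (terminal ones only, by default), the glycosidic oxygen stays with the
  aglycone, and small freed leftovers are discarded.
- **`scaffold` — Murcko scaffold dissection.**  The scaffold is the
  union of ring systems and the linkers connecting them (terminal chains
  pruned, exocyclic double-bonded atoms retained).  Modes:
  `SCAFFOLD_ONLY`, `SIDE_CHAINS_ONLY`, `RINGS_AND_LINKERS`, and
  `ENUMERATIVE_PARENTS`, which enumerates every distinct parent scaffold
  reachable by repeated terminal-ring removal.

Everywhere a bond is cleaved the convention is the same: cut without
preserving any information and saturate the open valence with hydrogen —
so a methoxy side chain, for example, turns into methanol and its
hydroxy group is picked up by a downstream functional-group stage.

Fragments are deduplicated by canonical SMILES.  For each fragment the
**frequency** (total occurrences over the set) and the **molecule
frequency** (number of distinct molecules containing it) are reported,
together with a randomly selected sample parent molecule drawn by a
seeded generator.

## Worked example

The built-in fixture panel (22 hand-curated molecules, from methane to
salicin) exercises every algorithm:

```bash
python -c "from molfrag.fixtures import write_panel_files; write_panel_files('demo')"
molfrag fragment --input demo/panel.smi --algorithm ertl-fg --output demo/run
# 22 imported, 20 fragmented, 2 filtered, 0 failed, 22 distinct fragments -> demo/run
molfrag histogram --run demo/run --top 5 --out demo/hist.csv
```

Two molecules are filtered: the organometallic (mercury) and the
quaternary ammonium whose charge cannot be neutralised.  The top of
`demo/run/fragments.csv` reads:

```
rank,fragment_smiles,frequency,molecule_frequency,sample_parent_name
1,CO,16,6,glycerol
2,C,10,6,acetamide
3,CC,6,5,ethanol
4,c1ccccc1,3,3,anisole
5,CCCCC,2,2,salicin
```

The most frequent fragment is the hydroxy group on an aliphatic carbon
(`CO`): it occurs 16 times but in only 6 molecules, i.e. the panel's
polyols carry several each — exactly the kind of observation
fragment-frequency profiling is for.  Ranked by *molecule* frequency
instead, the ordering changes (`--by molecule-frequency`).

Pipelines chain algorithms; each stage consumes the fragments of the
one before it:

```bash
cat > pipeline.cfg <<EOF
sugar-removal
scaffold fragmentation_type=SIDE_CHAINS_ONLY
ertl-fg
EOF
molfrag pipeline --input demo/panel.smi --config pipeline.cfg --output demo/pipe
```

The same functionality is available as a library
(`molfrag.run_single`, `molfrag.run_pipeline`,
`molfrag.histogram_data`, ...), and new algorithms plug in by
subclassing `molfrag.MoleculeFragmenter` and registering the class.

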