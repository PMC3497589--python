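# cifsem — semantic tools for crystallographic information files

`cifsem` is a Python toolkit for the machinery that makes crystallographic
publishing *semantic*: the Crystallographic Information File (CIF) exchange
format, the machine-readable dictionaries that define its tags, and the
automated services a journal can layer on top — validation alerts with
submission gating, derivation of missing quantities, chemical connectivity
inferred from coordinates, and annotation of free article text.

It is aimed at people who build or study data pipelines for small-molecule
crystal structures: journal tooling, archive curation, teaching the
CIF/dictionary formalism, or prototyping checks over structural models.

## What it does

**CIF syntax** (`cifsem.cif_syntax`) — a reader/writer for the tag-value /
loop format. Values are plain ASCII strings typed lexically ("if it looks
like a number, treat it as a number"): `5.12(3)` parses as the value 5.12
with standard uncertainty 0.03, the trailing parenthesised integer scaled
by the place value of the last mantissa digit. `?` is *unknown*, `.` is
*inapplicable*; white space delimits, so strings containing it are quoted
(or held in `;`-delimited text blocks). `parse ∘ write` is the identity on
the data model.

**Dictionaries** (`cifsem.dictionary`) — CIF dictionaries are themselves
CIF files. A small bootstrap attribute set (`_name`, `_type`, `_units`,
`_enumeration`, `_enumeration_range`, `_list`, `_definition`) is defined
in a shipped dictionary written in its own formalism, which validates
itself with zero findings. Data blocks are validated against a dictionary
for unknown tags, type, enumeration, closed ranges and loop context.

**Geometry** (`cifsem.geometry`) — cell metrics and symmetry. The cell
volume is

    V = abc·√(1 − cos²α − cos²β − cos²γ + 2·cosα·cosβ·cosγ)

and the orthogonalization matrix (a along x, b in the xy plane) maps
fractional to Cartesian coordinates for distances, angles and IUPAC-signed
torsions. Symmetry operators are parsed exactly (rational matrices) from
`-x,y+1/2,-z+1/2`-style triplets; site orbits give multiplicities (a site
on a special position has a reduced orbit), and F(hkl) is summed directly
over the symmetry-expanded, occupancy-weighted cell contents.

**Derivation** (`cifsem.derivation`) — a registry of executable methods
with recursive, *stored-first* dependency resolution: a missing
`_cell_volume` is deduced from the six cell parameters, density from
formula weight / Z / volume, F(000) from the formula sum. A separate
consistency pass reports stored values that disagree with what the
registry would derive.

**Validation alerts** (`cifsem.validation_alerts`) — checkcif-style
checks producing A (extreme), B (significant) and C (minor) alerts,
including the PLAT213-style displacement-ellipsoid elongation check
(axial ratio of the Cartesian-U eigenvalues). The gating rule: a
submission is admitted only when every A/B alert carries a
machine-readable author response (a `_vrf_`-prefixed item in the CIF
itself).

**Connectivity** (`cifsem.connectivity`) — bonds are inferred where the
minimum-image distance is within the summed covalent radii + 0.40 Å;
bonds between different disorder groups of one assembly are suppressed;
moieties, Hill formulas and a round-trippable connection table follow.

**Text semantics** (`cifsem.text_semantics`) — two annotation passes for
article text: a glossary scanner with a shrinking 4→1 word window, stop
words and longest-match-wins; and a geometry-mention scanner
(`C2---C21---C22---C221`) whose hits are resolved against the tabulated
geometry of the data block — unmatched mentions are dropped, multiple
matches are returned as candidates.

**Fixtures** (`cifsem.fixtures`) — a seeded generator of internally
consistent toy structures (an ethanol-like molecule plus a chloride ion,
triclinic P1 or P-1, optional two-group disorder), defect injection with
expected-finding descriptors, and synthetic article fragments with ground
truth.

## Worked example

```sh
$ cifsem fixtures --seed 1 --out fx
$ head -7 fx/clean.cif
data_fixture_1
_cell_length_a                 9.9668(2)
_cell_length_b                 11.0881(3)
_cell_length_c                 11.8000(2)
_cell_angle_alpha              91.6047(8)
_cell_angle_beta               100.2935(9)
_cell_angle_gamma              93.1847(8)
```

Bond perception recovers the molecule and the free ion:

```sh
$ cifsem bonds fx/clean.cif --formula
fixture_1: 8 bond(s)
  C1-C2 1.538
  C1-H11 1.093
  ...
  O1-H1 0.955
  moiety: C2 H6 O
  moiety: Cl
```

The eight bonds are the ethanol skeleton (C–C 1.538 Å, C–O 1.432 Å,
O–H 0.955 Å, five C–H); the chloride is a second, unbonded moiety.

The derivation engine prefers stored values and flags inconsistencies —
here against a file whose stored volume was corrupted by 10 %:

```sh
$ cifsem derive fx/defect_inconsistent-volume.cif --tag _cell_volume --check
fixture_1: _cell_volume = 1408.139512 (stored)
  inconsistent _cell_volume: stored 1408.139512, derived 1280.1268292960922 (rel 1.00e-01)
```

The stored value wins (provenance `stored`), while the consistency pass
reports the 0.1 relative discrepancy against the value derived from the
six cell parameters.

`cifsem check FILE` runs the alert battery and prints the gating verdict;
`cifsem annotate TEXT --cif FILE` emits glossary links and resolved
geometry mentions as JSON.

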