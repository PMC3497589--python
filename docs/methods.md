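# Methods

This note records the models, conventions and numerical choices behind
`cifsem`, and what the synthetic test battery does and does not show.

## The file format and its data model

The CIF data model implemented here is the classic 1.1-era one: ASCII
text, named data blocks, single tag-value items and loops (a tag header
with interleaved rows). Four lexical conventions matter:

* **Lexical typing.** A bare token that matches the number grammar
  (integer, decimal or exponential mantissa with an optional
  parenthesised trailing integer) carries a numeric interpretation; the
  standard uncertainty is the trailing integer times the place value of
  the last mantissa digit. The grammar accepts an exponent combined with
  an su (`1.2e3(4)` → su 400) as an extension; quoted tokens are never
  numeric. `?` and `.` are distinct value kinds (unknown / inapplicable)
  that satisfy every dictionary constraint.
* **Quoting dialect.** Single quotes, double quotes and first-column
  `;` text blocks are accepted; a closing quote terminates only before
  white space. The writer quotes anything containing white space or that
  would otherwise change kind on re-reading (e.g. a quoted `"12"`), and
  emits any value containing a newline as a text block.
* **Text blocks are read exactly**: the value is every character between
  the opening `;` and the closing line. This makes `parse ∘ write` a true
  identity; readers that strip an initial blank line differ only on
  values that deliberately begin with a newline.
* **Tags** are compared case-insensitively, stored as given; a duplicate
  tag in one block is an error (validation being a core purpose, last-wins
  would hide exactly the problems we want surfaced). There is no
  line-length limit on read; the writer wraps near 80 columns where the
  token structure allows.

CIF2/UTF-8 syntax, save frames and STAR extensions are out of scope.

## Dictionaries

Dictionaries use a deliberately minimal, fixed attribute set —
`_name`, `_category`, `_type` (`numb`/`char`), `_units`,
`_enumeration` (looped when several values are allowed),
`_enumeration_range` (`min:max`, **closed** bounds, either open-ended),
`_list` (`yes`/`no`/`both`) and `_definition` — a reduction of DDL1 that
is sufficient for type, unit, enumeration, range and loop-context
semantics. The bootstrap set is defined in `data/ddl_bootstrap.dic`
using itself, and the shipped core dictionary of crystallographic tags
is written in it. Units are declarative: a dictionary asserts the
preferred unit, and no conversion is ever performed. Relational DDL2
features (parent/child keys, category groups) and method-text parsing
are out of scope.

## Geometry and symmetry

* Orthogonalization follows the common crystallographic convention
  (**a** along Cartesian *x*, **b** in the *xy* plane); its determinant
  equals the cell volume, which the tests verify against the independent
  metric-tensor oracle √det G to 1e-9 relative.
* Torsion angles follow the right-hand IUPAC convention, signed in
  (−180°, 180°]. Under this convention the torsion is *invariant* under
  reversing the atom order and changes sign under inversion of the
  structure; the tests assert exactly these properties.
* Symmetry operators are stored as exact rational matrices parsed from
  coordinate triplets, so orbit computations carry no floating-point
  drift from the operators themselves. Orbits are deduplicated under a
  fractional minimum-image metric with a default tolerance of 1e-4 —
  programs genuinely disagree on special-position handling, so the rule
  is fixed and the tolerance exposed. Multiplicities are reported per
  the supplied operator list (one conventional cell); whether to report
  per asymmetric unit instead is left to the caller.
* The structure factor is the plain phased sum over every operator image
  of every site, weighted by occupancy and a constant per-element
  scattering factor. There is no displacement damping and no
  deduplication of special-position images: F(000) is therefore exactly
  the occupancy-weighted scattering-factor sum over the expanded list,
  which is the identity the tests pin down. Resolution-dependent form
  factors and absorption are out of scope.

## Derivation

Methods are registered executable rules (output tag, input tags, pure
function), not parsed method text — an explicit reduction of the
dictionary-methods approach that keeps the same dependency-resolution
semantics. Resolution is recursive, memoised per call and
**stored-first**: file content is never overridden, and a conflict
between a stored and a derivable value is only *reported* (by the
separate consistency pass, default relative tolerance 1e-6). Numeric
inputs resolve to floats, character inputs to their raw strings, which
is how the formula-weight and F(000) methods (Hill-formula parsing,
atomic numbers/weights for H, C, N, O, Cl) share the registry with the
metric methods. Standard uncertainties are not propagated through
derivations — a known limitation.

## Validation alerts and gating

Checks run in a fixed order (completeness, dictionary findings as C
alerts, ellipsoid elongation, bond plausibility, occupancy sums) so
reports are deterministic. Policy defaults, all exposed in
`CheckConfig`:

| parameter | default | meaning |
|---|---|---|
| `adp_ratio_b` / `adp_ratio_a` | 4.0 / 8.0 | Cartesian-U eigenvalue ratio for B / A elongation alerts |
| `bond_dev_c` / `bond_dev_b` | 0.15 / 0.30 Å | deviation from summed covalent radii for C / B bond alerts |
| `bond_search_tol` | 0.40 Å | bond-perception tolerance used by the plausibility check |
| `occupancy_tol` | 0.02 | allowed deviation of a disorder assembly's group-occupancy sum from 1 |
| `required_tags` | cell + volume + formula sum | the journal completeness profile |

The ellipsoid thresholds are journal policy, not physics; they were
chosen to separate a mildly anisotropic atom (ratio < 2) from a
genuinely pathological one (ratio ≈ 10) with a wide margin on both
sides. The CIF-to-Cartesian transform for displacement tensors is
`U_cart = A N U N Aᵀ` with `N = diag(a*, b*, c*)`. Solvent sites that
are deliberately not fully refined are excluded by *explicit
configuration* (`excluded_labels`) — no heuristic attempts to recognise
solvent. Author responses are `_vrf_<ALERTCODE>` items inside the
submission file; admission requires a response for every A/B alert, C
alerts never block, and responses citing unknown codes are warnings.

## Connectivity

Bonding uses the Cordero covalent radii (shipped as package data) with a
0.40 Å tolerance over the summed radii, minimum-image distances (with an
explicit scan over the ±1 shell, since in oblique cells the rounded
image is not always nearest), and optional symmetry expansion limited to
one shell of neighbouring cells. Cross-group bonds within a disorder
assembly are suppressed because the groups are alternative, mutually
exclusive locations. Bond orders are left unassigned by inference —
order assignment is an author editing step, and automatic perception
for metal-organic or polymeric cases is explicitly not attempted. The
connection table uses the core chemical-connectivity loops plus a local
`_chemical_conn_atom_label` extension so the crystallographic labels
round-trip exactly.

## Text annotation

The glossary scanner tokenises on white space, strips edge punctuation
for matching while spans keep original offsets, normalises by
case-folding, and slides a 4→3→2→1 word window left to right; the first
(longest) hit wins and the scan resumes after it, so an indexed
"space group" can never degrade to a bare "group" hit, and stop-listed
single words are never linked alone. The geometry scanner's label
grammar is `[A-Z][a-z]?\d+[A-Z]?[′']*` (element symbol, digits, optional
disorder-suffix letter, optional primes), with `---`, em/en dashes and
`-` as bond separators and `...`/`…` for contacts; a printed
`value (su)` immediately after the chain is captured. Resolution
against the block's geometry tables matches label sequences forwards or
reversed; zero matches drop the mention, several are all returned.

## The synthetic fixtures

The generator emulates a small-molecule structure report: an
ethanol-like C2H6O molecule built on exact tetrahedral geometry with
realistic bond lengths (C–C 1.53, C–O 1.43, C–H 1.09, O–H 0.97 Å),
±0.01 Å coordinate jitter, a chloride counter-ion, a triclinic cell near
10 × 11 × 12 Å (angles 92/101/94° ± 1°), and anisotropic displacement
tensors on the heavy atoms constructed to be mildly anisotropic in
Cartesian space. In P-1 the molecule sits on a general position and the
chloride on the inversion centre, so the two orbit sizes (2 and 1)
exercise the multiplicity machinery. The disorder variant splits the
hydroxyl arm over two groups (occupancies 0.6/0.4) close enough that
exactly the cross-group pairs fall inside bonding distance — the
suppression rule is therefore load-bearing, not vacuous. Stored items
are formatted with enough digits that volume, formula weight and the
geometry tables are consistent with the stored cell and coordinates to
well below the 1e-6 consistency tolerance.

What the fixtures do **not** emulate: thermal-motion physics, diffraction
intensities, realistic packing interactions, hydrogen-bond networks, or
chemically diverse structures (elements are limited to H, C, N, O, Cl).
Passing tests demonstrate the correctness of the algorithms and the
internal consistency contracts, not detector-grade performance on real
archive data.

## Problem sizes

The verification battery uses 200 random documents for the round trip,
1000 random cells for the volume oracle, 1000 random point sets for the
distance/angle/torsion oracle, 300 orbit trials over three operator
sets, and 50 article/table pairs for mention resolution; the whole suite
and the acceptance script each complete in a few seconds on one CPU.
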