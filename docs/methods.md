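# Methods

This note documents the model behind `nasift`, the defaults it ships, the
numerical choices it makes, what the synthetic probe generator does and does
not emulate, and the design decisions taken where the problem was genuinely
open.

## Input model and assumptions

The receptor is a single-model RNA or DNA structure in PDB format. Waters
and inorganic metal cations may travel with it and are routed to dedicated
lists (waters keep only their oxygen positions; the metal set is
Na/K/Mg/Ca/Mn/Fe/Zn/Co/Ni/Cu/Sr/Ba/Cd/Pb and is configurable). Any other
HETATM is treated as an un-removed ligand or buffer molecule and rejected —
deliberate, because silently dropping an organic molecule from the binding
site would corrupt every downstream statistic. Residue numbers must be
unique across all chains, since the fingerprint's residue manifest is keyed
by number. Ligands come from a multi-record SDF with formal charges and
protonation states already assigned; the package performs no pKa
prediction (no reliable method exists for RNA–ligand complexes). Hydrogens
can be added to ligands (RDKit or OpenBabel back ends); receptor hydrogens,
when needed for the D–H···A mode, must be present in the PDB.

PDB files carry no bond orders, so each residue is converted to an RDKit
molecule using hand-written kekulé templates of the canonical nucleotides
(full 5′-phosphate, ribose with/without O2′, and the A/C/G/U/T bases, with
OP2/OP3 carrying the formal −1). Sanitization then yields aromaticity and
implicit-hydrogen counts, and a single SMARTS-based perception path serves
receptor residues, ligands, and plugins alike. Modified nucleotides are
matched to the template with the largest base-atom-name overlap; a residue
with no overlap at all is rejected. The bridging O3′ of an internal residue
is flagged so it does not gain a spurious implicit hydrogen (and hence a
spurious donor) when its ester partner lives in the next residue.

## Feature perception

Perception rules are SMARTS strings in `PerceptionRules`, overridable as a
unit:

- donors: `[#7,#8,#16;!H0]` — N/O/S with at least one (explicit or
  implicit) hydrogen; the D–H···A mode additionally requires *explicit*
  hydrogen coordinates and raises otherwise.
- acceptors: N/O with an available lone pair; positively charged and
  quaternary N, pyrrole-type aromatic NH, amide N and aryl-conjugated
  amines are excluded. The exact typing table of the original tool is not
  public, so these rules are this package's documented defaults.
- halogen-bond donors: `[#6][Cl,Br,I;X1]`; fluorine is excluded (negligible
  sigma-hole).
- charges: formal charge from the input, plus two receptor-specific rules —
  OP1/OP2 (and OP3 when present) are always anions regardless of recorded
  charge, and metal elements always count as cations.
- rings: aromatic 5- and 6-membered rings; fused systems are decomposed, so
  a purine contributes two rings tested independently.
- lipophilic atoms, ligand side: C or S bonded only to C, H, S or halogen
  (`[#6,#16;+0;!$([#6,#16]~[!#6;!#1;!#16;!F;!Cl;!Br;!I])]`), excluding
  charged atoms. Receptor side: *every* carbon counts as a lipophilic
  contact site. The strict rule would leave a canonical nucleotide with no
  lipophilic atom at all (each sugar/base carbon has an N/O neighbour),
  which contradicts the well-documented dominance of nucleobase and ribose
  carbons in apolar contacts; the asymmetric rule reproduces that behaviour
  while keeping the ligand definition conservative.

## Detectors and numerical choices

All detectors evaluate both directions where meaningful (receptor as donor
and as acceptor; phosphate as anion partner toward ligand cations and as
"anion donor" toward ligand rings). Records are deduplicated on
(type, receptor side, ligand side, mediator). Specific conventions:

- Every `≤ cutoff` comparison adds 1e-9 Å/degrees, so a pair constructed at
  exactly the cutoff is detected: a donor–acceptor pair at 3.90 Å is a
  hydrogen bond, at 3.91 Å it is not. Monotonicity in the cutoffs is
  unaffected.
- Ring normals come from the total-least-squares plane (smallest singular
  vector); their sign is arbitrary, so all angles against normals are folded
  onto [0°, 90°].
- π-stacking offset is the smaller of the two centroid projections (the
  criterion is symmetric in the rings). A parallel stack with offset
  ≤ 0.5 Å is labelled "sandwich", otherwise "parallel-displaced"; θ within
  [60°, 90°] is "T-shaped".
- Mediated interactions take their bridging particles only from the
  receptor file. The single `distance` column of a mediated record holds
  the *longer* coordination leg — the binding-limiting one.
- An atom may simultaneously be a hydrogen-bond partner and a water-bridge
  partner to the same ligand atom; the channels are independent.
- Only the 3.9 Å hydrogen-bond cutoff is anchored in the original method
  description; the remaining defaults are reconstructions from the standard
  interaction-profiling literature (donor angle ≥ 100°; halogen windows
  165° ± 30/120° ± 30; stacking 5.5 Å/2.0 Å/30°; π–ion 6.0 Å/30°; water legs
  3.5 Å; metal legs Mg 3.0/K 3.5/Na 3.1/other 3.0 Å; lipophilic and contact
  4.0 Å). They are labelled as such and every one is overridable from a
  flat `key = value` config file.

## Fingerprints, wrappers, plugins

The FULL channel registry is fixed at twelve: HB, HAL, CationAnion,
PiCation, PiAnion, PiStacking, Mg/K/Na/OtherMetal-mediated, Water_mediated,
Lipophilic. Plugin channels append after these in file order and can never
alter the fixed channels' bits. Column names follow
`CHAIN.NUMBER.RESNAME#CHANNEL` — invented here (no header format is
standardized), chosen to be order-stable and parseable, and round-tripping
bit-identically through the TSV reader. T maps onto the U slot of the ACUG
wrapper for DNA receptors. In ion-profile mode each receptor cation becomes
a ligand of its own; for a bare metal only the CationAnion channel (FULL) or
the contact bits (SIMPLE/PBS) can fire.

Plugin criteria are distance, distance + angle, or distance + dihedral, with
anchors written `R<i>`/`L<i>` as 1-based positions in the receptor/ligand
SMARTS match — the schema detail a criterion needs to be unambiguous. The
shipped sample channels (any, polar, weak polar, weak hydrogen bond, n→π*
with a Bürgi–Dunitz angle window of 95–125° at the carbonyl carbon, and
multipolar organofluorine contacts) are reconstructions written for this
package, intended as editable starting points rather than reference values.

A waters/ions-only receptor yields an empty (zero-length) fingerprint rather
than an error; an error is reserved for receptors with nothing usable at
all.

## Similarity metrics

The eight metrics use the standard binary-vector forms over counts A, B, C
(see README). Tversky's first argument is the reference. 0/0 (two all-zero
fingerprints under Tanimoto/Cosine/Tversky/Soergel) is defined as 0 with a
warning — all-zero fingerprints legitimately occur for distant poses, and
silently propagating NaN through a screening matrix would be worse. "Square
Euclidean" and "Half Square Euclidean" differ by exactly the factor 2 their
names imply.

## The probe generator, and what passing tests show

`fixtures.make_probe_complex` emits a PDB/SDF pair realizing one requested
interaction exactly: an idealized nucleotide (regular-polygon base rings at
1.39 Å bond length, planar; ribose and 5′-phosphate built outward from the
glycosidic nitrogen) plus a minimal functional-group ligand (methanol,
ammonium, benzene, chlorobenzene, acetate, methane). The complex is emitted
in a canonical frame — receptor anchor atom at the origin, approach along
+x — so the defining distance survives the fixed-precision coordinate fields
of PDB (3 decimals) and SDF (4 decimals) exactly for atom-anchored probes;
ring-centroid-anchored probes (π channels) are exact to ~1e-3 Å because the
centroid of rounded ring atoms shifts slightly. All randomness (jitter on
non-defining decoy atoms) is seed-controlled and outputs are byte-identical
per (spec, seed).

These probes are geometrically exact but chemically idealized: planar
regular rings, no thermal noise, no crystallographic disorder, no solvent
shell, no conformational strain, single interactions per complex. Passing
the suite therefore demonstrates that the geometric predicates, perception
rules, and bookkeeping are correct — not that the defaults reproduce
interaction statistics of experimental structures, which depend on
resolution, protonation assignment, and the hydrogen-adding algorithm.
`fixtures.random_feature_scene` complements the probes with randomized
feature clouds (uniform in a 9 Å box, which straddles every default cutoff)
for record-level comparison of each detector against an independent
brute-force predicate scan.

## Problem sizes

The shipped test suite and `scripts/acceptance.py` run on single- and
di-nucleotide probes, 200 random scenes per channel for the oracle
comparison, 100 scenes for subsumption, 50 rigid motions, 1000 random
vector pairs for the metric identities, and 100 random fingerprints for
wrapper conservation — sizes chosen so the whole validation runs in seconds
on one CPU while exercising every code path at full depth.

## Known limitations

- Fixed per-channel cutoffs: the hydrogen-bond criterion does not depend on
  donor strength or element pair. Custom per-group channels via plugins are
  the intended workaround.
- Unique residue numbering is required; insertion codes are ignored.
- File formats are fixed (PDB receptor, SDF ligands); no mmCIF.
- Receptor feature perception relies on canonical atom names; heavily
  modified nucleotides degrade to best-overlap template matching.
- Energy scoring, tautomer enumeration and pKa prediction are out of scope.
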