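# nasift

Structural interaction fingerprints (SIFts) for nucleic acid–ligand
complexes.

Most interaction-profiling software targets protein–ligand binding; tools
for RNA and DNA receptors remain scarce. `nasift` detects the non-covalent
interactions formed between a nucleic-acid receptor (RNA or DNA, PDB format)
and ligand poses (multi-record SDF — small molecules, or anything exportable
as SDF), classifies them, and encodes them as binary Structural Interaction
Fingerprints for high-throughput analysis: virtual-screening post-processing,
pose comparison as an alternative to RMSD, clustering of binding modes, and
binding-site hot-spot statistics. It is written for structural
bioinformaticians and medicinal chemists working on RNA-targeted ligands.

## The method

For every residue *r* of the receptor and every ligand pose, nine interaction
classes are evaluated under geometric criteria (distances *d* in Å, angles in
degrees; all thresholds live in a config file):

| channel | criterion (defaults) |
|---|---|
| Hydrogen bond | d(D···A) ≤ 3.9; optional D–H···A mode adds ∠(D,H,A) ≥ 100 |
| Halogen bond | d(X···A) ≤ 4.0, ∠(C–X···A) = 165 ± 30, ∠(X···A–Y) = 120 ± 30 |
| Cation–anion | 0.5 < d ≤ 5.5 between opposite formal charges (OP1/OP2 always anionic) |
| π–cation / π–anion | d(centroid, ion) ≤ 6.0, angle to ring normal ≤ 30 |
| π-stacking | d ≤ 5.5 with θ ≤ 30 ∧ offset ≤ 2.0 (sandwich / parallel-displaced) or θ ∈ [60, 90] (T-shaped) |
| Metal-mediated (Mg / K / Na / other) | both coordination legs ≤ per-element cutoff (Mg 3.0, K 3.5, Na 3.1) |
| Water-mediated | both polar legs ≤ 3.5 to one water oxygen |
| Lipophilic | apolar-atom pair ≤ 4.0 |

The resulting bit vector is ordered (residue × channel). Three resolutions
exist: **FULL** (the 12 typed channels above), **PBS** (three contact bits per
residue — phosphate/sugar/base), and **SIMPLE** (one any-contact bit per
residue). Wrappers condense a fingerprint: **ACUG**/**PuPy** OR-aggregate
residues by nucleotide class, **Counter** counts set bits per channel.
Additional channels are defined in a YAML plugin file by a receptor-side and
a ligand-side SMARTS plus a distance (optionally angle/dihedral) criterion; a
sample file with six extra channels ships with the package
(`nasift.plugins.sample_plugin_text()`).

Fingerprints are compared with eight metrics over bit counts
A = |a|, B = |b|, C = |a ∧ b|: Tanimoto C/(A+B−C), Tversky
C/(C + α(A−C) + β(B−C)) (α = 1, β = 0 gives the fraction of the reference's
interactions recapitulated in a model), Cosine C/√(AB), Manhattan A+B−2C,
Euclidean, Square- and Half-Square-Euclidean, and Soergel 1 − Tanimoto.

## Worked example

The package generates its own probe complexes, so the example needs no
downloads — a guanosine monophosphate receptor with a methanol ligand whose
hydroxyl oxygen sits exactly 3.0 Å from guanine N7:

```sh
python - <<'EOF'
from nasift.fixtures import ProbeSpec, make_probe_complex
pdb, sdf = make_probe_complex(ProbeSpec("HB", 3.0, angle=180.0), seed=0)
open("probe.pdb", "w").write(pdb); open("probe.sdf", "w").write(sdf * 3)
EOF
nasift -r probe.pdb -l probe.sdf -f FULL -detail -wrapper Counter -o out
```

prints

```
INFO receptor: 1 residue(s), 0 water(s), 0 ion(s)
INFO ligands: 3 pose(s) from probe.sdf (addH=none)
INFO fingerprints: out/probe_FULL.tsv (3 row(s), 12 bit column(s))
INFO detected HB                     3
INFO detail listing: out/probe_FULL_detail.tsv (3 record(s))
INFO Counter wrapper: out/probe_FULL_Counter.tsv
```

`out/probe_FULL.tsv` holds one row per pose and one 0/1 column per
(residue, channel), here `A.1.G#HB … A.1.G#Lipophilic`; each pose sets
exactly the hydrogen-bond bit. The detail listing names the partners and
geometry of every contact:

```
ligand_title  pose  interaction_type  ...  receptor_atoms  ligand_atoms  distance
methanol      1     HB                ...  N7              O1            3.000
```

An all-vs-all similarity matrix over those fingerprints:

```sh
nasift-dist -i out/probe_FULL.tsv -m Tanimoto -o out/tanimoto.tsv
```

gives a 3×3 all-ones matrix (the poses are identical, so every pairwise
Tanimoto similarity is 1). Omitting `-l` switches `nasift` to ion-profile
mode, fingerprinting each inorganic cation in the receptor file as a ligand.

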