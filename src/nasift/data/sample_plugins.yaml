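# Sample plugin set: six additional interaction channels.
#
# These definitions are reconstructions written for this package: the SMARTS
# patterns and thresholds are standard literature values (weak C-H donors,
# Burgi-Dunitz approach trajectory for n->pi*, orthogonal multipolar C-F
# contacts), not values copied from any reference implementation.  Edit
# freely; anchors R<i>/L<i> refer to 1-based atom positions in the
# receptor/ligand SMARTS match.

plugins:
  # (x) any contact between receptor and ligand atoms
  - name: any
    receptor_smarts: "[*]"
    ligand_smarts: "[*]"
    distance: {min: 0.0, max: 4.0}

  # (xi) polar contact: any N/O pair, no angle restraint
  - name: polar
    receptor_smarts: "[#7,#8]"
    ligand_smarts: "[#7,#8]"
    distance: {min: 0.0, max: 3.9}

  # (xii) weak polar contact: carbon donor to N/O, no angle restraint
  - name: weak_polar
    receptor_smarts: "[#6]"
    ligand_smarts: "[#7,#8]"
    distance: {min: 0.0, max: 3.6}

  # (xiii) n->pi*: receptor carbonyl accepting lone-pair density from a
  # ligand O/N along the Burgi-Dunitz trajectory (angle at the carbonyl C)
  - name: n_pi_star
    receptor_smarts: "[OX1]=[CX3]"
    ligand_smarts: "[O,N;X1,X2,X3]"
    distance: {min: 0.0, max: 3.6, receptor_atom: 2, ligand_atom: 1}
    angle: {min: 95.0, max: 125.0, atoms: [L1, R2, R1]}

  # (xiv) weak hydrogen bond: C-H donor (with hydrogen) to an N/O acceptor
  - name: weak_hydrogen_bond
    receptor_smarts: "[#7,#8]"
    ligand_smarts: "[#6;!H0]"
    distance: {min: 0.0, max: 3.8}

  # (xv) halogen multipolar: organofluorine approaching a carbonyl carbon
  - name: halogen_multipolar
    receptor_smarts: "[CX3]=[OX1]"
    ligand_smarts: "[F][#6]"
    distance: {min: 0.0, max: 4.0, receptor_atom: 1, ligand_atom: 1}
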