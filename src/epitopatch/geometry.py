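"""Ideal-geometry peptide construction and PDB text emission.

Backbone atoms are placed by natural-extension-reference-frame (NeRF)
chaining from ideal bond lengths/angles and user-supplied phi/psi torsions;
C-beta is placed from the local N/CA/C frame. Only N, CA, C, O and CB are
emitted — enough for solvent accessibility, patch geometry and the
dihedral-based secondary-structure heuristic.
"""

from __future__ import annotations

import numpy as np

# ideal backbone internal coordinates (Engh-Huber-like)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

PHI_PSI = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
}


def nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
         bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given chain a-b-c, |c-d|, angle(b,c,d) and torsion(a,b,c,d)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg + 180.0)  # frame convention correction
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def place_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal C-beta from the backbone frame (chirality-correct for L-residues)."""
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc + ca


def build_backbone(phi_psi: list[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """Build an n-residue backbone from per-residue (phi, psi) torsions.

    phi of the first residue and psi of the last are ignored (undefined).
    Returns one dict per residue with keys N, CA, C, O, CB.
    """
    n_res = len(phi_psi)
    if n_res < 1:
        raise ValueError("need at least one residue")
    residues: list[dict[str, np.ndarray]] = []
    # seed frame for residue 0
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = residues[-1]
        psi_prev = phi_psi[i - 1][1]
        n_i = nerf(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_i = nerf(prev["CA"], prev["C"], n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_i = nerf(prev["C"], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi_psi[i][0])
        residues.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl O: anti to the next N (psi+180); trans-ish placement at the C-terminus
    for i, res in enumerate(residues):
        if i + 1 < n_res:
            tor = phi_psi[i][1] + 180.0
        else:
            tor = 0.0
        res["O"] = nerf(res["N"], res["CA"], res["C"], BOND_C_O, ANGLE_CA_C_O, tor)
        res["CB"] = place_cb(res["N"], res["CA"], res["C"])
    return residues


def format_pdb(residues, chain_ids, res_numbers, res_types,
               include_cb: bool = True) -> str:
    """Emit ATOM records (fixed 3-decimal coordinates) plus TER/END.

    residues: list of dicts name->xyz; GLY residues never get a CB.
    """
    lines = []
    serial = 1
    prev_chain = None
    order = ["N", "CA", "C", "O", "CB"]
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
    for res, chain, num, rtype in zip(residues, chain_ids, res_numbers, res_types):
        if prev_chain is not None and chain != prev_chain:
            lines.append("TER")
        prev_chain = chain
        for name in order:
            if name not in res:
                continue
            if name == "CB" and (not include_cb or rtype == "GLY"):
                continue
            x, y, z = res[name]
            lines.append(
                f"ATOM  {serial:>5} {name:^4} {rtype:>3} {chain}{num:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                f"{elements[name]:>2}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
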