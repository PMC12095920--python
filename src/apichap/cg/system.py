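"""Assemble chains into one simulation system with precomputed topology.

Bond, angle and dihedral reference values are measured from the chains'
input coordinates for folded chains; disordered chains get bonds at the
canonical 3.8 Å and no angle/dihedral restraints.  Native contacts exist
only within folded chains, so inter-chain interactions are repulsion +
Debye-Hueckel + hydrophobic attraction only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chains import BOND_LENGTH, CGChain, NativeContactSet, \
    build_native_contacts


def _angles(pos: np.ndarray) -> np.ndarray:
    v1 = pos[:-2] - pos[1:-1]
    v2 = pos[2:] - pos[1:-1]
    cosang = np.sum(v1 * v2, axis=1) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def _dihedrals(pos: np.ndarray) -> np.ndarray:
    b1 = pos[1:-2] - pos[:-3]
    b2 = pos[2:-1] - pos[1:-2]
    b3 = pos[3:] - pos[2:-1]
    m = np.cross(b1, b2)
    n = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=1)[:, None]
    x = np.sum(m * n, axis=1)
    y = np.sum(np.cross(m, n) * b2n, axis=1)
    return np.arctan2(y, x)


@dataclass
class CGSystem:
    """Concatenated bead arrays plus bonded and nonbonded pair topology."""

    chains: list[CGChain]
    box: float = 250.0
    pbc: bool = True
    contact_cutoff: float = 9.0

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("a system needs at least one chain")
        self.n_beads = sum(len(c) for c in self.chains)
        if self.box <= 0:
            raise ValueError("box must be positive")
        self.positions = np.concatenate([c.positions for c in self.chains])
        self.charges = np.concatenate([c.charges for c in self.chains])
        self.hydrophobicity = np.concatenate(
            [c.hydrophobicity for c in self.chains])
        self.chain_index = np.concatenate(
            [np.full(len(c), ci) for ci, c in enumerate(self.chains)])
        offsets = np.cumsum([0] + [len(c) for c in self.chains])
        self.chain_offsets = offsets

        bonds, bond_r0 = [], []
        angles, angle_th0 = [], []
        dihedrals, dihedral_phi0 = [], []
        native_pairs, native_r0 = [], []
        self.native_contacts: dict[int, NativeContactSet] = {}
        for ci, chain in enumerate(self.chains):
            off = offsets[ci]
            n = len(chain)
            pos = chain.positions
            if n >= 2:
                idx = np.arange(n - 1)
                bonds.append(np.column_stack([idx, idx + 1]) + off)
                if chain.kind == "folded":
                    bond_r0.append(
                        np.linalg.norm(np.diff(pos, axis=0), axis=1))
                else:
                    bond_r0.append(np.full(n - 1, BOND_LENGTH))
            if chain.kind == "folded":
                if n >= 3:
                    idx = np.arange(n - 2)
                    angles.append(
                        np.column_stack([idx, idx + 1, idx + 2]) + off)
                    angle_th0.append(_angles(pos))
                if n >= 4:
                    idx = np.arange(n - 3)
                    dihedrals.append(np.column_stack(
                        [idx, idx + 1, idx + 2, idx + 3]) + off)
                    dihedral_phi0.append(_dihedrals(pos))
                contacts = build_native_contacts(chain, self.contact_cutoff)
                self.native_contacts[ci] = contacts
                if len(contacts):
                    native_pairs.append(contacts.pairs + off)
                    native_r0.append(contacts.r0)

        def _cat(parts, width):
            if parts:
                return np.concatenate(parts).reshape(-1, width)
            return np.empty((0, width), dtype=int)

        self.bonds = _cat(bonds, 2).astype(np.int64)
        self.bond_r0 = (np.concatenate(bond_r0) if bond_r0
                        else np.empty(0))
        self.angles = _cat(angles, 3).astype(np.int64)
        self.angle_th0 = (np.concatenate(angle_th0) if angle_th0
                          else np.empty(0))
        self.dihedrals = _cat(dihedrals, 4).astype(np.int64)
        self.dihedral_phi0 = (np.concatenate(dihedral_phi0)
                              if dihedral_phi0 else np.empty(0))
        self.native_pairs = _cat(native_pairs, 2).astype(np.int64)
        self.native_r0 = (np.concatenate(native_r0) if native_r0
                          else np.empty(0))

        # nonbonded list: all i<j except same-chain |i-j| <= 2 (bond and
        # angle neighbours) and except native pairs
        ii, jj = np.triu_indices(self.n_beads, k=1)
        same = self.chain_index[ii] == self.chain_index[jj]
        close = same & (jj - ii <= 2)
        keep = ~close
        if len(self.native_pairs):
            nat = set(map(tuple, self.native_pairs))
            is_native = np.array([(a, b) in nat
                                  for a, b in zip(ii, jj)])
        else:
            is_native = np.zeros(ii.size, dtype=bool)
        nb = keep & ~is_native
        self.nb_pairs = np.column_stack([ii[nb], jj[nb]]).astype(np.int64)
        self.nb_qq = self.charges[ii[nb]] * self.charges[jj[nb]]
        self.nb_hh = (self.hydrophobicity[ii[nb]]
                      * self.hydrophobicity[jj[nb]])
        # native pairs still feel electrostatics
        if len(self.native_pairs):
            self.native_qq = (self.charges[self.native_pairs[:, 0]]
                              * self.charges[self.native_pairs[:, 1]])
        else:
            self.native_qq = np.empty(0)

    def chain_slice(self, ci: int) -> slice:
        return slice(self.chain_offsets[ci], self.chain_offsets[ci + 1])

    def extent(self) -> float:
        span = np.ptp(self.positions, axis=0)
        return float(np.max(span))

    def topology_summary(self) -> dict:
        """JSON-serializable description of the system layout."""
        return {
            "box": self.box,
            "pbc": self.pbc,
            "contact_cutoff": self.contact_cutoff,
            "n_beads": int(self.n_beads),
            "chains": [
                {
                    "label": c.label,
                    "kind": c.kind,
                    "length": len(c),
                    "sequence": c.sequence,
                    "residue_numbering": c.residue_numbering.tolist(),
                    "net_charge": c.net_charge,
                    "start": int(self.chain_offsets[ci]),
                    "n_native_contacts": len(self.native_contacts.get(ci, ())),
                }
                for ci, c in enumerate(self.chains)
            ],
        }
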