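"""Bead chains: structure loading, native contacts, disordered chains."""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1

BOND_LENGTH = 3.8  # Å, consecutive Cα-Cα

_CHARGES = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


def residue_charge(aa: str) -> float:
    """+1e for Lys/Arg, -1e for Asp/Glu, 0 otherwise."""
    return _CHARGES.get(aa, 0.0)


def load_hydrophobicity_scale(path=None) -> dict[str, float]:
    """Per-residue hydrophobicity values from the packaged (or given) CSV."""
    if path is None:
        ref = importlib.resources.files("apichap") / "data/hydrophobicity.csv"
        with importlib.resources.as_file(ref) as p:
            table = pd.read_csv(p, comment="#")
    else:
        table = pd.read_csv(path, comment="#")
    return dict(zip(table["residue"], table["hydrophobicity"].astype(float)))


@dataclass
class CGChain:
    """One chain of Cα beads with per-bead charge and hydrophobicity."""

    sequence: str
    positions: np.ndarray          # (N, 3) Å
    kind: str                      # "folded" | "disordered"
    charges: np.ndarray = None
    hydrophobicity: np.ndarray = None
    residue_numbering: np.ndarray = None  # author residue indices
    label: str = "chain"

    def __post_init__(self) -> None:
        if self.kind not in ("folded", "disordered"):
            raise ValueError("kind must be 'folded' or 'disordered'")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(f"invalid residue letters: {sorted(bad)}")
        self.positions = np.asarray(self.positions, dtype=float)
        n = len(self.sequence)
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (len(sequence), 3)")
        if self.charges is None:
            self.charges = np.array([residue_charge(a)
                                     for a in self.sequence])
        if self.hydrophobicity is None:
            scale = load_hydrophobicity_scale()
            self.hydrophobicity = np.array([scale[a] for a in self.sequence])
        if self.residue_numbering is None:
            self.residue_numbering = np.arange(1, n + 1)
        self.charges = np.asarray(self.charges, dtype=float)
        self.hydrophobicity = np.asarray(self.hydrophobicity, dtype=float)
        self.residue_numbering = np.asarray(self.residue_numbering,
                                            dtype=int)
        for arr in (self.charges, self.hydrophobicity,
                    self.residue_numbering):
            if arr.shape[0] != n:
                raise ValueError("per-bead arrays must match sequence length")
        if not np.all(np.isin(self.charges, (-1.0, 0.0, 1.0))):
            raise ValueError("bead charges must be -1, 0 or +1")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())


@dataclass
class NativeContactSet:
    """Reference-structure contact pairs (chain-local indices, i < j)."""

    pairs: np.ndarray   # (n, 2) int, |i - j| >= 4
    r0: np.ndarray      # (n,) Å native distances

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.r0 = np.asarray(self.r0, dtype=float).reshape(-1)
        if self.pairs.shape[0] != self.r0.shape[0]:
            raise ValueError("pairs and r0 lengths differ")
        if self.pairs.size:
            if np.any(self.pairs[:, 0] >= self.pairs[:, 1]):
                raise ValueError("pairs must satisfy i < j")
            if np.any(np.diff(self.pairs[:, ::-1], axis=1) > -4):
                raise ValueError("pairs must satisfy |i - j| >= 4")
            if np.any(self.r0 <= 0):
                raise ValueError("native distances must be positive")
            uniq = {tuple(p) for p in self.pairs}
            if len(uniq) != self.pairs.shape[0]:
                raise ValueError("duplicate contact pairs")

    def __len__(self) -> int:
        return self.pairs.shape[0]


def load_structure(pdb_file, chain_id: str = "A",
                   residue_range: tuple[int, int] | None = None,
                   label: str | None = None) -> CGChain:
    """Build a folded chain from the Cα atoms of a PDB file.

    ``residue_range`` is inclusive in author numbering; omitted means all
    residues of the chain.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ref", str(pdb_file))
    model = next(structure.get_models())
    if chain_id not in [c.id for c in model]:
        raise ValueError(f"chain {chain_id!r} not found in {pdb_file}")
    chain = model[chain_id]

    wanted = None
    if residue_range is not None:
        lo, hi = residue_range
        if hi < lo:
            raise ValueError("empty residue range")
        wanted = range(lo, hi + 1)

    numbers, seq, coords, missing = [], [], [], []
    present = {}
    for res in chain:
        het, num, _ = res.id
        if het.strip():
            continue
        present[num] = res
    numbers_iter = wanted if wanted is not None else sorted(present)
    for num in numbers_iter:
        res = present.get(num)
        if res is None or "CA" not in res:
            missing.append(num)
            continue
        numbers.append(num)
        seq.append(seq1(res.get_resname()))
        coords.append(res["CA"].coord.astype(float))
    if missing:
        raise ValueError(f"missing Cα atoms for residues {missing} "
                         f"in chain {chain_id}")
    if not numbers:
        raise ValueError("no residues selected")
    return CGChain(sequence="".join(seq), positions=np.array(coords),
                   kind="folded", residue_numbering=np.array(numbers),
                   label=label or f"pdb_{chain_id}")


def build_native_contacts(chain: CGChain,
                          cutoff: float = 9.0) -> NativeContactSet:
    """All bead pairs with |i-j| >= 4 closer than ``cutoff`` in the
    reference coordinates."""
    if chain.kind != "folded":
        raise ValueError("native contacts are defined for folded chains only")
    pos = chain.positions
    n = len(chain)
    ii, jj = np.triu_indices(n, k=4)
    d = np.linalg.norm(pos[ii] - pos[jj], axis=1)
    keep = d <= cutoff
    return NativeContactSet(pairs=np.column_stack([ii[keep], jj[keep]]),
                            r0=d[keep])


def build_idp_chain(sequence: str, seed: int = 0, box: float = 250.0,
                    bond_length: float = BOND_LENGTH,
                    residue_numbering=None, label: str = "idp",
                    center=None) -> CGChain:
    """Self-avoiding random-walk initial conformation for a disordered chain.

    Bonds are placed at ``bond_length``; no angle or dihedral restraints are
    recorded.  The walk stays inside a cube of side ``box`` centred at
    ``center`` (default: box centre) and rejects steps closer than
    0.8 * bond_length to any previous bead.
    """
    bad = set(sequence) - VALID_RESIDUES
    if bad:
        raise ValueError(f"invalid residue letters: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    n = len(sequence)
    if center is None:
        center = np.full(3, box / 2.0)
    center = np.asarray(center, dtype=float)
    margin = 5.0
    lo = center - (box / 2.0 - margin)
    hi = center + (box / 2.0 - margin)

    pos = np.empty((n, 3))
    pos[0] = center
    min_sep2 = (0.8 * bond_length) ** 2
    for i in range(1, n):
        for _attempt in range(500):
            v = rng.standard_normal(3)
            v *= bond_length / np.linalg.norm(v)
            cand = pos[i - 1] + v
            if np.any(cand < lo) or np.any(cand > hi):
                continue
            d2 = np.sum((pos[:i - 1] - cand) ** 2, axis=1) if i > 1 else None
            if d2 is not None and d2.size and d2.min() < min_sep2:
                continue
            pos[i] = cand
            break
        else:  # pragma: no cover - 500 retries virtually never exhaust
            raise RuntimeError(f"could not place bead {i}; box too small?")
    return CGChain(sequence=sequence, positions=pos, kind="disordered",
                   residue_numbering=residue_numbering, label=label)
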