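"""Synthetic inputs for every pipeline stage.

Each generator both returns in-memory objects and (given ``out_dir``)
writes the exact plain-text formats the analysis modules read, together
with a ground-truth JSON sidecar sufficient to score recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import amyloid, kinetics
from .cg.chains import VALID_RESIDUES, residue_charge

# Four-repeat tau fragment (residues 244-372 of the human protein) with the
# construct's reported position-332 alanine substitution applied.
_TAU4R_WT = (
    "QTAPVPMPDLKNVKSKIGSTENLKHQPGGGKVQIINKKLDLSNVQSKCGSKDNIKHVPGGGSVQIVY"
    "KPVDLSKVTSKCGSLGNIHHKPGGGQVEVKSEKLDFKDRVQSKIGSLDNITHVPGGGNKKIE"
)
TAU4R_START = 244
_MUT_POS = 332
TAU4R_SEQUENCE = (_TAU4R_WT[:_MUT_POS - TAU4R_START] + "A"
                  + _TAU4R_WT[_MUT_POS - TAU4R_START + 1:])
TAU4R_NUMBERING = np.arange(TAU4R_START, TAU4R_START + len(TAU4R_SEQUENCE))

# default plate grid: 0-24 h at 5-minute intervals
DEFAULT_TIMES = np.round(np.arange(0, 24 * 12 + 1) / 12.0, 6)

_NEUTRAL = "ACFGHILMNPQSTVWY"


@dataclass
class SynthSpec:
    """Declarative description of one synthetic artifact."""

    kind: str                     # plate | model_series | structure_fixture
    #                             # | idp_sequence
    parameters: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("plate", "model_series", "structure_fixture",
                             "idp_sequence"):
            raise ValueError(f"unknown synth kind {self.kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


# ---------------------------------------------------------------------------
# sigmoid plates
# ---------------------------------------------------------------------------

def gen_sigmoid_plate(conditions, times=None, noise_sd: float = 0.0,
                      n_replicates: int = 1, seed: int = 0,
                      include_controls: bool = False, out_dir=None):
    """Generate a plate of sigmoid wells plus metadata and a truth sidecar.

    ``conditions`` is a list of dicts with the sigmoid parameters
    (m1, n1, m2, n2, k, t05) and condition metadata (tau_conc, inhibitor_id,
    inhibitor_conc).  Each condition gets ``n_replicates`` wells of the
    sigmoid plus i.i.d. Gaussian noise; ``include_controls`` adds matching
    heparin-free wells carrying only the pre-transition baseline.
    Returns (plate DataFrame, metadata DataFrame, truth dict).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    times = DEFAULT_TIMES if times is None else np.asarray(times, float)
    rng = np.random.default_rng(seed)
    plate = {"time_h": times}
    meta_rows = []
    truth = {"noise_sd": noise_sd, "seed": seed, "conditions": []}
    well_no = 0
    for ci, cond in enumerate(conditions):
        params = {k: float(cond[k]) for k in kinetics.PARAM_NAMES}
        truth["conditions"].append({**params,
                                    "tau_conc": cond.get("tau_conc", 10.0),
                                    "inhibitor_id": cond.get("inhibitor_id"),
                                    "inhibitor_conc":
                                        cond.get("inhibitor_conc", 0.0)})
        clean = kinetics.eval_sigmoid(params, times)
        baseline = params["m1"] * times + params["n1"]
        for rep in range(n_replicates):
            well_no += 1
            well = f"W{well_no:03d}"
            plate[well] = clean + noise_sd * rng.standard_normal(times.size)
            meta_rows.append({
                "well": well,
                "tau_conc_uM": cond.get("tau_conc", 10.0),
                "inhibitor": cond.get("inhibitor_id") or "none",
                "inhibitor_conc_uM": cond.get("inhibitor_conc", 0.0),
                "heparin": True,
                "replicate": f"r{rep + 1}",
            })
        if include_controls:
            well_no += 1
            well = f"W{well_no:03d}"
            plate[well] = baseline + noise_sd * rng.standard_normal(
                times.size)
            meta_rows.append({
                "well": well,
                "tau_conc_uM": cond.get("tau_conc", 10.0),
                "inhibitor": cond.get("inhibitor_id") or "none",
                "inhibitor_conc_uM": cond.get("inhibitor_conc", 0.0),
                "heparin": False,
                "replicate": "control",
            })
    plate_df = pd.DataFrame(plate)
    meta_df = pd.DataFrame(meta_rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        plate_df.to_csv(out / "plate.csv", index=False)
        meta_df.to_csv(out / "meta.csv", index=False)
        (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return plate_df, meta_df, truth


# ---------------------------------------------------------------------------
# kinetic-model concentration series
# ---------------------------------------------------------------------------

def gen_model_series(model: amyloid.KineticModel, m0_values, times,
                     noise_sd: float = 0.0, seed: int = 0, out_dir=None):
    """Forward-simulated normalized mass curves at several concentrations.

    Returns (curves, truth) where curves is a list of (m0, times, y)
    triples in the format global_fit consumes.  ``out_dir`` additionally
    writes a long-format curves.csv (condition, m0_uM, time_h,
    mass_fraction) plus the truth sidecar.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    m0_values = np.asarray(m0_values, dtype=float)
    if m0_values.size < 3:
        raise ValueError("need >= 3 concentrations")
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    curves, rows = [], []
    for m0 in m0_values:
        y = amyloid.simulate_model(model, float(m0), times)
        y = y + noise_sd * rng.standard_normal(times.size)
        curves.append((float(m0), times.copy(), y))
        for t, v in zip(times, y):
            rows.append({"condition": f"m0_{m0:g}", "m0_uM": m0,
                         "time_h": t, "mass_fraction": v})
    truth = {"model": model.name, "seed": seed, "noise_sd": noise_sd,
             "params": {k: v for k, v in vars(model).items()
                        if v is not None and k != "name"},
             "m0_values": m0_values.tolist()}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rows).to_csv(out / "curves.csv", index=False)
        (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return curves, truth


def load_curves_csv(path):
    """Read a long-format curves.csv into global_fit's input triples."""
    table = pd.read_csv(path)
    curves = []
    for m0, grp in table.groupby("m0_uM"):
        grp = grp.sort_values("time_h")
        curves.append((float(m0), grp["time_h"].to_numpy(),
                       grp["mass_fraction"].to_numpy()))
    return curves


# ---------------------------------------------------------------------------
# structure fixtures
# ---------------------------------------------------------------------------

_HELIX_RISE = 1.5      # Å per residue
_HELIX_TURN = 100.0    # degrees per residue
_HELIX_RADIUS = 2.3    # Å


def _helix_coords(n: int, start=np.zeros(3), direction=1.0) -> np.ndarray:
    i = np.arange(n)
    ang = np.deg2rad(_HELIX_TURN) * i
    xyz = np.column_stack([
        _HELIX_RADIUS * np.cos(ang),
        _HELIX_RADIUS * np.sin(ang),
        direction * _HELIX_RISE * i,
    ])
    return xyz + np.asarray(start)


def _fixture_sequence(n: int, seed: int) -> str:
    # deterministic mixed sequence with a known charge pattern: every 5th
    # residue K, every 7th E, the rest drawn from neutral letters
    rng = np.random.default_rng(seed)
    letters = []
    for i in range(n):
        if i % 5 == 0:
            letters.append("K")
        elif i % 7 == 0:
            letters.append("E")
        else:
            letters.append(_NEUTRAL[rng.integers(len(_NEUTRAL))])
    return "".join(letters)


_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def _write_ca_pdb(path, sequence: str, coords: np.ndarray,
                  chain_id: str = "A", start_num: int = 1) -> None:
    lines = []
    for i, (aa, (x, y, z)) in enumerate(zip(sequence, coords)):
        lines.append(
            f"ATOM  {i + 1:5d}  CA  {_AA3[aa]} {chain_id}{start_num + i:4d}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def gen_mini_domain(n_residues: int, geometry: str = "helix",
                    seed: int = 0, out_path=None):
    """Cα-only PDB fixture: a canonical helix or a two-helix hairpin.

    Returns (sequence, coords); ``out_path`` writes the PDB file.  The
    hairpin places two antiparallel helices ~9 Å apart so it carries a
    hand-countable set of inter-helix native contacts.
    """
    if n_residues < 8:
        raise ValueError("need at least 8 residues")
    if geometry not in ("helix", "helix_hairpin"):
        raise ValueError("geometry must be 'helix' or 'helix_hairpin'")
    sequence = _fixture_sequence(n_residues, seed)
    if geometry == "helix":
        coords = _helix_coords(n_residues)
    else:
        n1 = n_residues // 2
        first = _helix_coords(n1)
        # second helix runs back down, offset in x
        second = _helix_coords(n_residues - n1,
                               start=first[-1] + np.array([8.0, 0.0, 1.5]),
                               direction=-1.0)
        coords = np.vstack([first, second])
    if out_path is not None:
        _write_ca_pdb(out_path, sequence, coords)
    return sequence, coords


def gen_idp_sequence(length: int, net_charge: int = 0,
                     seed: int = 0, out_path=None, name: str = "idp") -> str:
    """Random disordered sequence with an exact (K+R) - (D+E) net charge."""
    if abs(net_charge) > length:
        raise ValueError("requested net charge exceeds sequence length")
    rng = np.random.default_rng(seed)
    n_extra = (length - abs(net_charge))
    n_pairs = min(n_extra // 4, 3)  # a few balanced charge pairs for texture
    n_pos = max(net_charge, 0) + n_pairs
    n_neg = max(-net_charge, 0) + n_pairs
    if n_pos + n_neg > length:
        n_pairs = 0
        n_pos, n_neg = max(net_charge, 0), max(-net_charge, 0)
    letters = (["K"] * n_pos + ["E"] * n_neg
               + [_NEUTRAL[i] for i in
                  rng.integers(len(_NEUTRAL), size=length - n_pos - n_neg)])
    order = rng.permutation(length)
    seq = "".join(letters[i] for i in order)
    assert sum(residue_charge(a) for a in seq) == net_charge
    if out_path is not None:
        Path(out_path).write_text(f">{name}\n{seq}\n")
    return seq


def read_fasta_sequence(path) -> str:
    """First record of a plain FASTA file as an upper-case string."""
    seq_lines = []
    with open(path) as fh:
        seen_header = False
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if seen_header:
                    break
                seen_header = True
                continue
            seq_lines.append(line)
    seq = "".join(seq_lines).upper()
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise ValueError(f"invalid residue letters in {path}: {sorted(bad)}")
    return seq


def generate(spec: SynthSpec, out_dir):
    """Dispatch a SynthSpec to the matching generator (CLI entry)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = dict(spec.parameters)
    if spec.kind == "plate":
        return gen_sigmoid_plate(
            p["conditions"], times=p.get("times"),
            noise_sd=spec.noise_sd, n_replicates=spec.n_replicates,
            seed=spec.seed, include_controls=p.get("include_controls",
                                                   False),
            out_dir=out)
    if spec.kind == "model_series":
        model = amyloid.KineticModel(**p["model"])
        times = np.asarray(p.get("times",
                                 np.linspace(0, p.get("t_max", 50.0), 100)))
        return gen_model_series(model, p["m0_values"], times,
                                noise_sd=spec.noise_sd, seed=spec.seed,
                                out_dir=out)
    if spec.kind == "structure_fixture":
        return gen_mini_domain(p.get("n_residues", 20),
                               p.get("geometry", "helix"),
                               seed=spec.seed,
                               out_path=out / "fixture.pdb")
    if spec.kind == "idp_sequence":
        if p.get("tau4r", False):
            seq = TAU4R_SEQUENCE
            (out / "idp.fasta").write_text(f">tau4R\n{seq}\n")
            return seq
        return gen_idp_sequence(p["length"], p.get("net_charge", 0),
                                seed=spec.seed, out_path=out / "idp.fasta")
    raise ValueError(f"unknown synth kind {spec.kind!r}")
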