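"""Interaction-probability maps between a disordered chain and a domain.

An interaction is counted in a frame when two residue centres (the Cα
beads) are closer than the cutoff (default 6 Å).  Probabilities are the
fraction of frames, pooled over replicas, in which a pair interacts; maps
can be binned into groups of three consecutive residues on both axes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass
class ContactMap:
    """Probability matrix (rows: chain A residues/bins, cols: chain B)."""

    matrix: np.ndarray
    row_numbering: np.ndarray       # author residue index of each row start
    col_numbering: np.ndarray
    row_ranges: np.ndarray          # (n, 2) inclusive author-number spans
    col_ranges: np.ndarray
    bin_size: int = 1
    n_frames: int = 0
    n_replicas: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if np.any(self.matrix < 0) or np.any(self.matrix > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        self.row_numbering = np.asarray(self.row_numbering, dtype=int)
        self.col_numbering = np.asarray(self.col_numbering, dtype=int)
        self.row_ranges = np.asarray(self.row_ranges, dtype=int)
        self.col_ranges = np.asarray(self.col_ranges, dtype=int)
        if self.matrix.shape != (self.row_numbering.size,
                                 self.col_numbering.size):
            raise ValueError("matrix shape does not match numbering")
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")


def _unbinned_ranges(numbering: np.ndarray) -> np.ndarray:
    return np.column_stack([numbering, numbering])


def contact_probabilities(trajectories, idx_a, idx_b,
                          numbering_a=None, numbering_b=None,
                          cutoff: float = 6.0,
                          box: float | None = None,
                          equilibration: float = 0.1) -> ContactMap:
    """Unbinned contact probabilities pooled over replica trajectories.

    ``trajectories`` is a list of either Trajectory objects or raw frame
    arrays of shape (n_frames, n_beads, 3).  ``idx_a``/``idx_b`` select the
    beads of the two chains; ``box`` enables minimum-image distances.  The
    first ``equilibration`` fraction of each trajectory's frames is
    discarded (set 0 for exact hand-built checks).
    """
    if not trajectories:
        raise ValueError("no trajectories given")
    if not 0.0 <= equilibration < 1.0:
        raise ValueError("equilibration fraction must be in [0, 1)")
    idx_a = np.asarray(idx_a, dtype=int)
    idx_b = np.asarray(idx_b, dtype=int)
    counts = np.zeros((idx_a.size, idx_b.size))
    n_frames = 0
    for traj in trajectories:
        frames = np.asarray(getattr(traj, "frames", traj), dtype=float)
        start = int(np.floor(equilibration * frames.shape[0]))
        for frame in frames[start:]:
            d = frame[idx_a][:, None, :] - frame[idx_b][None, :, :]
            if box is not None:
                d -= box * np.round(d / box)
            r = np.sqrt(np.sum(d * d, axis=2))
            counts += r < cutoff
            n_frames += 1
    if n_frames == 0:
        raise ValueError("no frames left after equilibration discard")
    numbering_a = (np.arange(1, idx_a.size + 1) if numbering_a is None
                   else np.asarray(numbering_a, dtype=int))
    numbering_b = (np.arange(1, idx_b.size + 1) if numbering_b is None
                   else np.asarray(numbering_b, dtype=int))
    return ContactMap(matrix=counts / n_frames,
                      row_numbering=numbering_a,
                      col_numbering=numbering_b,
                      row_ranges=_unbinned_ranges(numbering_a),
                      col_ranges=_unbinned_ranges(numbering_b),
                      bin_size=1, n_frames=n_frames,
                      n_replicas=len(trajectories))


def _bin_axis(numbering: np.ndarray, bin_size: int):
    n_bins = int(np.ceil(numbering.size / bin_size))
    starts, ranges = [], []
    for b in range(n_bins):
        chunk = numbering[b * bin_size:(b + 1) * bin_size]
        starts.append(chunk[0])
        ranges.append((chunk[0], chunk[-1]))
    return np.array(starts), np.array(ranges)


def bin_contacts(cmap: ContactMap, bin_size: int = 3,
                 agg: str = "max") -> ContactMap:
    """Aggregate an unbinned map into ``bin_size``-residue blocks.

    ``agg`` is "max" (peak-preserving, the default) or "mean".  Trailing
    partial bins are kept.  ``bin_size=1`` is the identity.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if cmap.bin_size != 1:
        raise ValueError("can only bin an unbinned map")
    if agg not in ("max", "mean"):
        raise ValueError("agg must be 'max' or 'mean'")
    if bin_size == 1:
        return replace(cmap)
    reduce = np.max if agg == "max" else np.mean
    n_r = int(np.ceil(cmap.matrix.shape[0] / bin_size))
    n_c = int(np.ceil(cmap.matrix.shape[1] / bin_size))
    out = np.empty((n_r, n_c))
    for bi in range(n_r):
        rows = slice(bi * bin_size, (bi + 1) * bin_size)
        for bj in range(n_c):
            cols = slice(bj * bin_size, (bj + 1) * bin_size)
            out[bi, bj] = reduce(cmap.matrix[rows, cols])
    row_num, row_rng = _bin_axis(cmap.row_numbering, bin_size)
    col_num, col_rng = _bin_axis(cmap.col_numbering, bin_size)
    return ContactMap(matrix=out, row_numbering=row_num,
                      col_numbering=col_num, row_ranges=row_rng,
                      col_ranges=col_rng, bin_size=bin_size,
                      n_frames=cmap.n_frames, n_replicas=cmap.n_replicas)


def interface_segments(cmap: ContactMap,
                       threshold: float) -> list[dict]:
    """Contiguous row segments whose peak probability reaches threshold.

    Returns dicts with keys ``start``, ``end`` (author numbering, inclusive)
    and ``peak``, ranked by descending peak probability.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    row_max = cmap.matrix.max(axis=1) if cmap.matrix.size else \
        np.zeros(cmap.row_numbering.size)
    hot = row_max >= threshold
    segments = []
    i = 0
    n = hot.size
    while i < n:
        if not hot[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and hot[j + 1]:
            j += 1
        segments.append({
            "start": int(cmap.row_ranges[i, 0]),
            "end": int(cmap.row_ranges[j, 1]),
            "peak": float(row_max[i:j + 1].max()),
        })
        i = j + 1
    segments.sort(key=lambda s: -s["peak"])
    return segments


def write_heatmap_tsv(path, cmap: ContactMap) -> None:
    """TSV matrix with author residue numbering on both axes."""
    with open(path, "w") as fh:
        fh.write("residue\t" + "\t".join(map(str, cmap.col_numbering))
                 + "\n")
        for num, row in zip(cmap.row_numbering, cmap.matrix):
            fh.write(str(num) + "\t"
                     + "\t".join(f"{v:.6f}" for v in row) + "\n")


def write_segments_bed(path, segments: list[dict],
                       chain_label: str = "tau") -> None:
    """BED-like text: chain label, start, end (1-based inclusive), peak."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"{chain_label}\t{seg['start']}\t{seg['end']}"
                     f"\t{seg['peak']:.4f}\n")
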