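"""Maximum local amino-acid composition scanning and bin partitioning.

For every protein x residue x window size, slide a fixed-length window along
the sequence, take the maximum count of the residue of interest in any
window, and sort the protein into a 5%-wide maximum-composition bin. With the
default grid (20 residues x window sizes 10..100 in steps of 10) this sorts
the proteome 200 distinct ways.

All composition arithmetic is exact: the stored quantity is the integer pair
(max count, window size) and the bin label is ``bin_width * floor(100*count /
(bin_width*window))``, so no floating-point comparison ever decides a bin.
Maximum composition is NOT monotone in window size (e.g. "AGA" for A: 100% at
window 1, 50% at window 2, 66.7% at window 3), so every window size is
scanned independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from compscan.proteome_io import CANONICAL_AA, ProteinRecord


@dataclass(frozen=True)
class ScanGrid:
    """The (residues, window sizes, bin width) grid of a scan."""

    residues: tuple[str, ...] = tuple(CANONICAL_AA)
    windows: tuple[int, ...] = tuple(range(10, 101, 10))
    bin_width: int = 5

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.windows):
            raise ValueError("window sizes must be positive")
        if list(self.windows) != sorted(set(self.windows)):
            raise ValueError("window sizes must be strictly increasing")
        if 100 % self.bin_width != 0:
            raise ValueError("100 must be divisible by bin_width")

    @property
    def bin_labels(self) -> tuple[int, ...]:
        return tuple(range(0, 101, self.bin_width))


@dataclass
class CompositionPartition:
    """Per (residue, window): each protein's max local composition and bin.

    maxcomp maps (residue, window, protein id) -> (max count, window); bins
    maps (residue, window, bin label) -> protein-id set; eligible maps
    window -> ids of proteins at least that long. For each (residue, window)
    the bins partition the eligible set exactly.
    """

    grid: ScanGrid
    maxcomp: dict[tuple[str, int, str], tuple[int, int]] = field(default_factory=dict)
    bins: dict[tuple[str, int, int], set[str]] = field(default_factory=dict)
    eligible: dict[int, set[str]] = field(default_factory=dict)

    def bin_of(self, residue: str, window: int, protein_id: str) -> int:
        count, w = self.maxcomp[(residue, window, protein_id)]
        return assign_bin(count, w, self.grid.bin_width)


def max_local_count(seq: str, aa: str, window: int) -> int | None:
    """Maximum count of ``aa`` over all contiguous windows of size ``window``.

    Returns None when the sequence is shorter than the window. Computed with
    a rolling count in integer arithmetic.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(seq)
    if n < window:
        return None
    count = seq[:window].count(aa)
    best = count
    for i in range(window, n):
        count += (seq[i] == aa) - (seq[i - window] == aa)
        if count > best:
            best = count
    return best


def assign_bin(count: int, window: int, bin_width: int = 5) -> int:
    """Bin label in {0, bin_width, ..., 100} for a (count, window) pair.

    label = bin_width * floor(100*count / (bin_width*window)), in integer
    arithmetic; a saturated window (count == window) maps to 100.
    """
    if not 0 <= count <= window:
        raise ValueError(f"count {count} out of range for window {window}")
    return bin_width * ((100 * count) // (bin_width * window))


def _residue_index(residues: tuple[str, ...]) -> dict[str, int]:
    return {aa: i for i, aa in enumerate(residues)}


def _encode(seq: str, index: dict[str, int]) -> np.ndarray:
    # unknown/unlisted residues encode as -1: they occupy window positions
    # but never count toward any target residue
    return np.fromiter((index.get(ch, -1) for ch in seq), dtype=np.int64, count=len(seq))


def _max_counts_all_residues(codes: np.ndarray, n_res: int, window: int) -> np.ndarray:
    """Vector of max window counts, one per residue, for a single protein."""
    L = codes.shape[0]
    onehot = np.zeros((L + 1, n_res), dtype=np.int32)
    valid = codes >= 0
    onehot[1:][valid, codes[valid]] = 1
    cum = np.cumsum(onehot, axis=0)
    win_counts = cum[window:] - cum[:-window]  # (L - window + 1, n_res)
    return win_counts.max(axis=0)


def partition_proteome(
    proteome: list[ProteinRecord], grid: ScanGrid | None = None
) -> CompositionPartition:
    """Sort every protein into a maximum-composition bin for every
    (residue, window) pair of the grid.

    Proteins shorter than a window are excluded from that window's partition
    entirely. Unknown residues count toward window length but never toward
    the target residue's count.
    """
    if not proteome:
        raise ValueError("empty proteome")
    grid = grid or ScanGrid()
    index = _residue_index(grid.residues)
    part = CompositionPartition(grid=grid)
    for w in grid.windows:
        part.eligible[w] = {p.id for p in proteome if len(p.seq) >= w}
    for rec in proteome:
        codes = _encode(rec.seq, index)
        for w in grid.windows:
            if len(rec.seq) < w:
                continue
            counts = _max_counts_all_residues(codes, len(grid.residues), w)
            for aa, c in zip(grid.residues, counts):
                c = int(c)
                part.maxcomp[(aa, w, rec.id)] = (c, w)
                label = assign_bin(c, w, grid.bin_width)
                part.bins.setdefault((aa, w, label), set()).add(rec.id)
    return part


def maxcomp_table(part: CompositionPartition) -> pd.DataFrame:
    """Long-format table: protein_id, residue, window, max_count, max_pct, bin."""
    rows = []
    for (aa, w, pid), (count, _) in part.maxcomp.items():
        rows.append(
            {
                "protein_id": pid,
                "residue": aa,
                "window": w,
                "max_count": count,
                "max_pct": 100.0 * count / w,
                "bin": assign_bin(count, w, part.grid.bin_width),
            }
        )
    return pd.DataFrame(rows).sort_values(["residue", "window", "protein_id"]).reset_index(
        drop=True
    )


def distribution_table(part: CompositionPartition) -> pd.DataFrame:
    """Protein counts per (residue, window, bin) — the bin-occupancy profile."""
    rows = [
        {"residue": aa, "window": w, "bin": label, "n_proteins": len(ids)}
        for (aa, w, label), ids in part.bins.items()
    ]
    return pd.DataFrame(rows).sort_values(["residue", "window", "bin"]).reset_index(drop=True)
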