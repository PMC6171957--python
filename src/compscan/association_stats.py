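"""Bin-vs-rest property comparisons and threshold-scanning set enrichment.

Two statistical engines drive the analysis:

* compare_bins — for each (residue, window, composition bin), the property
  values of proteins in the bin are compared against all length-eligible
  proteins outside the bin with a two-sided Mann-Whitney U test; p-values
  are Bonferroni-adjusted within each (residue, window) family and each
  significant bin is labelled by the direction of its median shift.

* threshold_scan — for each (residue, window, minimum composition), all
  proteins whose maximum local composition reaches the threshold are pooled
  and tested for enrichment of a target membership set (e.g. stress-granule
  or P-body proteins) with Fisher's exact test against the length-eligible
  background. Pooling uses exact integer comparison (100*count >= t*window),
  so pools shrink monotonically as the threshold rises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from compscan.composition_scan import CompositionPartition
from compscan.proteome_io import AnnotationMap, PropertyTable


@dataclass(frozen=True)
class BinComparison:
    residue: str
    window: int
    bin: int
    n_in: int
    n_out: int
    median_in: float
    median_out: float
    u_stat: float
    p_raw: float
    p_adj: float
    direction: str  # "higher" | "lower" | "n.s."


@dataclass(frozen=True)
class EnrichmentRecord:
    term: str
    residue: str
    window: int
    min_comp: int
    a: int  # target & pooled
    b: int  # target \ pooled
    c: int  # pooled \ target
    d: int  # neither
    p_raw: float
    p_adj: float


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with the normal approximation.

    Uses midranks for ties, tie-corrected variance and continuity
    correction. Returns (U of x, two-sided p); U_x + U_y = |x|*|y|.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def compare_bins(
    partition: CompositionPartition,
    prop: PropertyTable,
    alpha: float = 0.05,
    family: str = "per_residue_window",
    min_group: int = 1,
) -> pd.DataFrame:
    """Bin-vs-rest Mann-Whitney comparisons over the whole scan grid.

    For every (residue, window, nonempty bin): the in-group is the bin
    intersected with the property's coverage, the out-group is every other
    covered protein of length >= window. Rows are emitted only when both
    groups are nonempty (and reach ``min_group``). Bonferroni families are
    the rows emitted per (residue, window) by default, or per window pooled
    over residues with family="per_window".

    Returns one BinComparison per row as a DataFrame.
    """
    if len(prop) == 0:
        raise ValueError("empty property table")
    if family not in ("per_residue_window", "per_window"):
        raise ValueError(f"unknown family mode {family!r}")
    grid = partition.grid
    values = prop.values
    rows: list[dict] = []
    for w in grid.windows:
        covered = partition.eligible[w] & values.keys()
        if len(covered) < 2:
            continue
        all_vals = {pid: values[pid] for pid in covered}
        for aa in grid.residues:
            for label in grid.bin_labels:
                ids = partition.bins.get((aa, w, label))
                if not ids:
                    continue
                in_ids = ids & covered
                out_ids = covered - ids
                if len(in_ids) < min_group or len(out_ids) < min_group:
                    continue
                x = np.array([all_vals[i] for i in in_ids])
                y = np.array([all_vals[i] for i in out_ids])
                u, p = mann_whitney_u(x, y)
                rows.append(
                    {
                        "residue": aa,
                        "window": w,
                        "bin": label,
                        "n_in": len(in_ids),
                        "n_out": len(out_ids),
                        "median_in": float(np.median(x)),
                        "median_out": float(np.median(y)),
                        "u_stat": u,
                        "p_raw": p,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "residue", "window", "bin", "n_in", "n_out",
            "median_in", "median_out", "u_stat", "p_raw",
        ],
    )
    if df.empty:
        df["p_adj"] = []
        df["direction"] = []
        return df
    fam_cols = ["residue", "window"] if family == "per_residue_window" else ["window"]
    m = df.groupby(fam_cols)["p_raw"].transform("size")
    df["p_adj"] = np.minimum(1.0, m * df["p_raw"])
    sig = df["p_adj"] <= alpha
    df["direction"] = "n.s."
    df.loc[sig & (df["median_in"] > df["median_out"]), "direction"] = "higher"
    df.loc[sig & (df["median_in"] < df["median_out"]), "direction"] = "lower"
    return df


def fisher_exact(a: int, b: int, c: int, d: int, alternative: str = "greater") -> float:
    """Fisher's exact test p-value for the 2x2 table [[a, b], [c, d]]."""
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unsupported alternative {alternative!r}")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])


def threshold_scan(
    partition: CompositionPartition,
    target: set[str],
    term: str = "target",
    alpha: float = 0.05,
    correct: bool = False,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Minimum-threshold-scanning enrichment of a membership set.

    For each (residue, window, minimum composition in {0, 5, ..., 100}) the
    pool is every eligible protein whose maximum local composition reaches
    the threshold; a 2x2 Fisher test contrasts pool membership with target
    membership over the length-eligible background. Records with an empty
    pool are omitted. With ``correct`` set, Bonferroni adjusts within each
    window family; otherwise p_adj equals p_raw (the uncorrected-p
    convention used for organelle composition profiling).
    """
    grid = partition.grid
    rows: list[dict] = []
    any_target = False
    for w in grid.windows:
        background = partition.eligible[w]
        tgt = target & background
        if tgt:
            any_target = True
        for aa in grid.residues:
            counts = {
                pid: partition.maxcomp[(aa, w, pid)][0] for pid in background
            }
            for t in range(0, 101, grid.bin_width):
                pooled = {pid for pid, c in counts.items() if 100 * c >= t * w}
                if not pooled:
                    continue
                a = len(pooled & tgt)
                b = len(tgt) - a
                c = len(pooled) - a
                d = len(background) - len(pooled) - b
                rows.append(
                    {
                        "term": term,
                        "residue": aa,
                        "window": w,
                        "min_comp": t,
                        "a": a,
                        "b": b,
                        "c": c,
                        "d": d,
                        "p_raw": fisher_exact(a, b, c, d, alternative),
                    }
                )
    if not any_target:
        raise ValueError("target set does not intersect any eligible background")
    df = pd.DataFrame(rows)
    if correct:
        m = df.groupby("window")["p_raw"].transform("size")
        df["p_adj"] = np.minimum(1.0, m * df["p_raw"])
    else:
        df["p_adj"] = df["p_raw"]
    return df


def term_enrichment(
    protein_set: set[str],
    annotations: AnnotationMap,
    background: set[str],
    correct_m: int | None = None,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Per-term Fisher enrichment of a protein set against a background.

    Terms annotating nothing in the background are skipped. Bonferroni uses
    the number of terms tested unless ``correct_m`` overrides it.
    """
    if not protein_set <= background:
        raise ValueError("protein set must be a subset of the background")
    rows = []
    for term, ids in annotations.terms.items():
        members = ids & background
        if not members:
            continue
        a = len(protein_set & members)
        b = len(protein_set) - a
        c = len(members) - a
        d = len(background) - len(protein_set) - c
        rows.append(
            {"term": term, "a": a, "b": b, "c": c, "d": d,
             "p_raw": fisher_exact(a, b, c, d, alternative)}
        )
    df = pd.DataFrame(rows, columns=["term", "a", "b", "c", "d", "p_raw"])
    m = correct_m if correct_m is not None else len(df)
    df["p_adj"] = np.minimum(1.0, m * df["p_raw"]) if len(df) else []
    return df


def pool_significant(per_window_results: dict[int, pd.DataFrame], alpha: float = 0.05) -> list[str]:
    """Union of significant terms across window sizes, deduplicated, sorted."""
    pooled: set[str] = set()
    for df in per_window_results.values():
        if len(df):
            pooled.update(df.loc[df["p_adj"] <= alpha, "term"])
    return sorted(pooled)
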