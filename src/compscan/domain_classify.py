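"""Classical domain definitions and the compositionally-enriched-domain sets.

Three classical notions of a degenerate protein region are implemented:

* low-complexity windows — length-12 windows with Shannon entropy <= 2.2
  bits, the first-pass criterion of the SEG algorithm, with each qualifying
  window assigned to every residue tied for the window maximum;
* statistically-biased subsequences — the lowest binomial point probability
  (P_min) of any residue's count over window sizes 25..2500, with a
  proteome-calibrated threshold classifying the most-biased ~15% of proteins;
* homopolymeric repeats — runs of >= 5 identical residues.

On top of these, compositionally-enriched-domain (CED) sets pool, for each
residue, the composition bins whose occupants are predominantly (>= 75%)
SEG-positive for that residue; single-CED proteins are those left after
removing proteins present in more than one residue's CED set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import groupby

import numpy as np
from scipy.special import gammaln

from compscan.composition_scan import CompositionPartition
from compscan.proteome_io import CANONICAL_AA, UNKNOWN_AA, ProteinRecord

LCD_WINDOW = 12
LCD_MAX_ENTROPY = 2.2
BIAS_W_MIN = 25
BIAS_W_MAX = 2500
BIAS_FRACTION = 0.15
MIN_HOMOPOLYMER_RUN = 5
CED_OCCUPANCY = 0.75


@dataclass(frozen=True)
class LCDWindowCall:
    """One low-entropy window with the residues responsible for it."""

    protein_id: str
    start: int  # 1-based inclusive
    end: int  # inclusive
    entropy: float
    assigned_residues: frozenset[str]


@dataclass(frozen=True)
class BiasResult:
    """The lowest-probability subsequence of one protein."""

    protein_id: str
    length: int
    p_min: float
    window: int
    residue: str
    count: int


@dataclass(frozen=True)
class BiasThreshold:
    """Length-dependent line plus length-independent cap on log10 P_min.

    A protein of length L is classified biased iff
    p_min < min(10**(slope*log10(L) + intercept), p_abs).
    """

    slope: float
    intercept: float
    p_abs: float
    fraction: float = BIAS_FRACTION

    def threshold(self, length: int) -> float:
        line = 10.0 ** (self.slope * math.log10(length) + self.intercept)
        return min(line, self.p_abs)

    def is_biased(self, result: BiasResult) -> bool:
        return result.p_min < self.threshold(result.length)


@dataclass(frozen=True)
class HomopolymerCall:
    protein_id: str
    residue: str
    start: int  # 1-based inclusive
    end: int  # inclusive


def shannon_entropy(counts, L: int) -> float:
    """Shannon entropy (bits) of a window of length L with residue counts.

    SE = -sum_i (n_i/L) * log2(n_i/L) over residues with n_i > 0; zero-count
    residues contribute nothing. Unknown residues are excluded from the
    counts but still contribute to L, so sum(n_i) may be < L.
    """
    if L < 1:
        raise ValueError("window length must be >= 1")
    vals = counts.values() if isinstance(counts, dict) else counts
    se = 0.0
    for n in vals:
        if n > 0:
            p = n / L
            se -= p * math.log2(p)
    return se


def find_lcds(
    seq: str,
    protein_id: str = "",
    window: int = LCD_WINDOW,
    max_entropy: float = LCD_MAX_ENTROPY,
    unknown: str = UNKNOWN_AA,
) -> list[LCDWindowCall]:
    """All windows of the sequence with Shannon entropy <= the threshold.

    Each qualifying window is assigned to every canonical residue whose
    count ties the window maximum (n_AAoI >= n_max) — the residues that are
    major contributors to the window's low complexity. Sequences shorter
    than the window yield no calls.
    """
    if window < 2:
        raise ValueError("entropy window must be >= 2")
    n = len(seq)
    if n < window:
        return []
    counts: dict[str, int] = {}
    for ch in seq[:window]:
        if ch != unknown:
            counts[ch] = counts.get(ch, 0) + 1
    calls: list[LCDWindowCall] = []

    def emit(start0: int) -> None:
        se = shannon_entropy(counts, window)
        if se <= max_entropy:
            n_max = max(counts.values(), default=0)
            assigned = frozenset(aa for aa, c in counts.items() if c >= n_max and c > 0)
            calls.append(
                LCDWindowCall(protein_id, start0 + 1, start0 + window, se, assigned)
            )

    emit(0)
    for i in range(window, n):
        out, inc = seq[i - window], seq[i]
        if out != unknown:
            counts[out] -= 1
            if counts[out] == 0:
                del counts[out]
        if inc != unknown:
            counts[inc] = counts.get(inc, 0) + 1
        emit(i - window + 1)
    return calls


def seg_positive_by_residue(
    proteome: list[ProteinRecord],
    window: int = LCD_WINDOW,
    max_entropy: float = LCD_MAX_ENTROPY,
) -> dict[str, set[str]]:
    """Map residue -> ids of proteins with >= 1 low-entropy window assigned
    to that residue ("SEG-positive for the residue")."""
    positive: dict[str, set[str]] = {aa: set() for aa in CANONICAL_AA}
    for rec in proteome:
        for call in find_lcds(rec.seq, rec.id, window, max_entropy):
            for aa in call.assigned_residues:
                positive.setdefault(aa, set()).add(rec.id)
    return positive


def pbias(w: int, n: int, f: float) -> float:
    """Binomial point probability C(w,n) * f^n * (1-f)^(w-n), in log space."""
    if not 0 <= n <= w:
        raise ValueError("need 0 <= n <= w")
    if not 0 < f < 1:
        raise ValueError("need 0 < f < 1")
    logp = (
        gammaln(w + 1)
        - gammaln(n + 1)
        - gammaln(w - n + 1)
        + n * math.log(f)
        + (w - n) * math.log1p(-f)
    )
    return float(np.exp(logp))


def proteome_frequencies(proteome: list[ProteinRecord]) -> dict[str, float]:
    """Canonical-residue frequencies of the proteome (unknowns excluded)."""
    counts = {aa: 0 for aa in CANONICAL_AA}
    for rec in proteome:
        for ch in rec.seq:
            if ch in counts:
                counts[ch] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("proteome contains no canonical residues")
    return {aa: c / total for aa, c in counts.items()}


def min_pbias(
    seq: str,
    freqs: dict[str, float],
    protein_id: str = "",
    w_min: int = BIAS_W_MIN,
    w_max: int = BIAS_W_MAX,
    step: int = 1,
) -> BiasResult | None:
    """The lowest-probability subsequence of one protein.

    Minimises pbias over all residues, all window sizes in
    [w_min, min(w_max, length)] (step 1 = exhaustive) and all window
    positions, with the count n taken as the residue's occurrences in the
    window. Returns None for proteins shorter than w_min.

    The inner loop is vectorised: per window size, rolling counts for all
    residues come from a cumulative one-hot sum and the log-probabilities
    from a precomputed log-factorial (gammaln) lookup, so no combinatorial
    term is recomputed per position.
    """
    L = len(seq)
    if L < w_min:
        return None
    residues = sorted(set(freqs))
    index = {aa: i for i, aa in enumerate(residues)}
    codes = np.fromiter((index.get(ch, -1) for ch in seq), dtype=np.int64, count=L)
    onehot = np.zeros((L + 1, len(residues)), dtype=np.int64)
    valid = codes >= 0
    onehot[1:][valid, codes[valid]] = 1
    cum = np.cumsum(onehot, axis=0)

    lgamma = gammaln(np.arange(L + 2))  # lookup: lgamma[k] = ln((k-1)!)
    logf = np.log([freqs[aa] for aa in residues])
    log1mf = np.log1p([-freqs[aa] for aa in residues])

    best_logp = np.inf
    best = None
    for w in range(w_min, min(w_max, L) + 1, step):
        counts = cum[w:] - cum[:-w]  # (L - w + 1, n_res)
        logp = (
            lgamma[w + 1]
            - lgamma[counts + 1]
            - lgamma[w - counts + 1]
            + counts * logf[None, :]
            + (w - counts) * log1mf[None, :]
        )
        pos, ri = np.unravel_index(np.argmin(logp), logp.shape)
        if logp[pos, ri] < best_logp:
            best_logp = float(logp[pos, ri])
            best = (w, residues[ri], int(counts[pos, ri]))
    w, aa, n = best
    return BiasResult(protein_id, L, float(np.exp(best_logp)), w, aa, n)


def fit_bias_threshold(
    results: list[BiasResult], fraction: float = BIAS_FRACTION
) -> BiasThreshold:
    """Calibrate the bias threshold on a proteome's P_min values.

    An ordinary least-squares line of log10 P_min on log10 length gives the
    slope; the intercept is then lowered so that the number of points
    strictly below the line is the largest count not exceeding
    floor(fraction * n) — i.e. the intercept is the (floor(fraction*n)+1)-th
    smallest residual. The length-independent cap p_abs is the fraction
    lower quantile of the P_min values themselves; the effective threshold
    at any length is the smaller of the two, guarding against unreasonably
    permissive line values for short proteins.
    """
    if len(results) < 10:
        raise ValueError("need >= 10 bias results to calibrate a threshold")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    x = np.log10([r.length for r in results])
    y = np.log10([r.p_min for r in results])
    if np.allclose(x, x[0]):
        raise ValueError("degenerate fit: all protein lengths equal")
    slope, _ = np.polyfit(x, y, 1)
    resid = np.sort(y - slope * x)
    k = math.floor(fraction * len(results))
    intercept = float(resid[k])  # (k+1)-th smallest residual
    p_sorted = np.sort([r.p_min for r in results])
    q_idx = max(math.ceil(fraction * len(results)), 1) - 1
    p_abs = float(p_sorted[q_idx])
    return BiasThreshold(float(slope), intercept, p_abs, fraction)


def find_homopolymers(
    seq: str,
    protein_id: str = "",
    min_run: int = MIN_HOMOPOLYMER_RUN,
    unknown: str = UNKNOWN_AA,
) -> list[HomopolymerCall]:
    """Maximal runs of >= min_run identical residues (unknowns never form
    runs and break any run they interrupt)."""
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    calls = []
    pos = 1
    for ch, group in groupby(seq):
        run = len(list(group))
        if ch != unknown and run >= min_run:
            calls.append(HomopolymerCall(protein_id, ch, pos, pos + run - 1))
        pos += run
    return calls


def define_ced_sets(
    partition: CompositionPartition,
    seg_positive: dict[str, set[str]],
    occupancy: float = CED_OCCUPANCY,
) -> dict[str, set[str]]:
    """Pool composition bins dominated by SEG-positive proteins into one
    CED protein set per residue.

    A (window, bin) cell qualifies for residue X iff at least ``occupancy``
    of its occupants are SEG-positive for X; the X-CED set is the union of
    qualifying cells across all windows and bins.
    """
    sets: dict[str, set[str]] = {}
    for (aa, _w, _label), ids in partition.bins.items():
        if not ids:
            continue
        pos = seg_positive.get(aa, set())
        if len(ids & pos) >= occupancy * len(ids):
            sets.setdefault(aa, set()).update(ids)
    return sets


def single_ced_proteins(ced_sets: dict[str, set[str]]) -> dict[str, set[str]]:
    """Remove proteins appearing in >= 2 residues' CED sets; the remaining
    per-residue sets are pairwise disjoint by construction."""
    membership: dict[str, int] = {}
    for ids in ced_sets.values():
        for pid in ids:
            membership[pid] = membership.get(pid, 0) + 1
    return {
        aa: {pid for pid in ids if membership[pid] == 1} for aa, ids in ced_sets.items()
    }
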