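"""Whole-gene translation efficiency as a geometric mean of codon weights.

A per-codon efficiency scale (e.g. a normalized translation-efficiency or
tRNA-adaptation-index table) is consumed as an input; each gene's value is
the geometric mean of its codons' weights with stop codons excluded from
both the product and the codon count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from compscan.proteome_io import CodingRecord, PropertyTable

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class CodonWeightTable:
    """Mapping codon -> positive efficiency weight, plus the stop-codon set."""

    weights: dict[str, float]
    stop_codons: frozenset[str] = STOP_CODONS

    def __post_init__(self) -> None:
        for codon, w in self.weights.items():
            if len(codon) != 3 or any(c not in "ACGT" for c in codon):
                raise ValueError(f"invalid codon {codon!r}")
            if not w > 0:
                raise ValueError(f"codon {codon!r}: weight must be positive")


@dataclass(frozen=True)
class GeneNTE:
    """One gene's efficiency value and the number of codons it averages."""

    id: str
    value: float
    n_codons: int


def load_codon_weights(path: str | Path) -> CodonWeightTable:
    """Load a two-column TSV (codon, weight) with a header row."""
    df = pd.read_csv(path, sep="\t", dtype={"codon": str, "weight": float}, comment="#")
    if not {"codon", "weight"} <= set(df.columns):
        raise ValueError("codon weight table needs columns (codon, weight)")
    return CodonWeightTable({r.codon.upper(): float(r.weight) for r in df.itertuples()})


def gene_nte(rec: CodingRecord, table: CodonWeightTable) -> GeneNTE:
    """Geometric mean of the gene's codon weights, stop codons excluded.

    value = exp((1/l) * sum(log w)) over the l non-stop codons; the log-space
    form keeps long genes numerically stable. Internal stop codons are
    excluded like terminal ones (callers may treat them as anomalies).

    Raises on a length not divisible by 3, a codon absent from the table, or
    a gene consisting only of stop codons.
    """
    if len(rec.nt) % 3 != 0:
        raise ValueError(f"{rec.id}: length {len(rec.nt)} not divisible by 3")
    log_sum = 0.0
    l_s = 0
    for i in range(0, len(rec.nt), 3):
        codon = rec.nt[i : i + 3]
        if codon in table.stop_codons:
            continue
        if codon not in table.weights:
            raise ValueError(f"{rec.id}: codon {codon!r} missing from weight table")
        log_sum += math.log(table.weights[codon])
        l_s += 1
    if l_s == 0:
        raise ValueError(f"{rec.id}: gene consists only of stop codons")
    return GeneNTE(rec.id, math.exp(log_sum / l_s), l_s)


def internal_stops(rec: CodingRecord, stop_codons: frozenset[str] = STOP_CODONS) -> int:
    """Count stop codons before the final codon (annotation anomalies)."""
    n = 0
    for i in range(0, len(rec.nt) - 3, 3):
        if rec.nt[i : i + 3] in stop_codons:
            n += 1
    return n


def proteome_nte(
    cds_set: Iterable[CodingRecord], table: CodonWeightTable, name: str = "nte"
) -> tuple[PropertyTable, dict[str, str]]:
    """Per-gene efficiency values for a whole coding-sequence set.

    Records that fail (broken frame, unknown codon) are collected in the
    returned error report rather than aborting the batch.
    """
    values: dict[str, float] = {}
    n_codons: dict[str, int] = {}
    errors: dict[str, str] = {}
    for rec in cds_set:
        try:
            res = gene_nte(rec, table)
        except ValueError as exc:
            errors[rec.id] = str(exc)
            continue
        values[rec.id] = res.value
        n_codons[rec.id] = res.n_codons
    if not values and not errors:
        raise ValueError("empty coding-sequence set")
    if not values:
        raise ValueError("no coding record could be evaluated")
    table_out = PropertyTable(name=name, values=values, units="relative efficiency")
    table_out.filter_report = {"failed_records": len(errors)}
    return table_out, errors
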