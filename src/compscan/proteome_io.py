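"""Input/output and validation for sequences, property tables and annotations.

All tabular inputs are plain UTF-8 TSV; sequences are FASTA. Dataset filters
(drop zero values, drop ambiguous multi-identifier rows, drop low-confidence
measurements) are applied at load time and counted in a filter report.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN_AA = "X"
NUCLEOTIDES = "ACGT"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein: identifier plus residue sequence.

    The sequence is over the 20 canonical one-letter symbols plus a single
    "unknown" symbol (default ``X``) standing in for anything else.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein identifier must be nonempty")
        if len(self.seq) < 1:
            raise ValueError(f"protein {self.id!r}: sequence must be nonempty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CodingRecord:
    """A coding sequence: identifier plus nucleotide sequence over {A,C,G,T}."""

    id: str
    nt: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("coding-record identifier must be nonempty")
        if len(self.nt) < 3:
            raise ValueError(f"coding record {self.id!r}: length must be >= 3")

    def __len__(self) -> int:
        return len(self.nt)


@dataclass
class PropertyTable:
    """A named per-protein numeric property (abundance, half-life, nTE, ...).

    All retained values are strictly positive; each identifier appears once.
    ``filter_report`` counts rows removed per filtering rule at load time.
    """

    name: str
    values: dict[str, float]
    units: str = ""
    filter_report: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [k for k, v in self.values.items() if not v > 0]
        if bad:
            raise ValueError(
                f"property table {self.name!r}: non-positive values for {bad[:5]}"
            )

    def __len__(self) -> int:
        return len(self.values)

    def coverage(self, ids: Iterable[str]) -> set[str]:
        """Identifiers present both here and in ``ids``."""
        return set(ids) & self.values.keys()


@dataclass
class AnnotationMap:
    """Mapping of annotation term -> set of protein identifiers.

    Membership of the identifiers in a given proteome is checked at use time,
    not at load time.
    """

    terms: dict[str, set[str]]

    def __post_init__(self) -> None:
        empty = [t for t, ids in self.terms.items() if not ids]
        if empty:
            raise ValueError(f"annotation terms with empty sets: {empty[:5]}")


class FastaResult(NamedTuple):
    """Parsed FASTA records plus the per-file substitution report."""

    records: list
    report: dict[str, int]


def _extract_id(header: str, id_regex: str | None) -> str:
    if id_regex is not None:
        m = re.search(id_regex, header)
        if m is None:
            raise ValueError(f"id_regex matched nothing in header {header!r}")
        return m.group(1) if m.groups() else m.group(0)
    return header.split()[0]


def read_fasta(
    path: str | Path,
    alphabet: str = "protein",
    unknown: str = UNKNOWN_AA,
    on_duplicate: str = "error",
    id_regex: str | None = None,
) -> FastaResult:
    """Read a FASTA file into protein or coding records.

    Parameters
    ----------
    alphabet : {"protein", "nucleotide"}
        Protein sequences are upper-cased and any character outside the 20
        canonical residues is replaced by ``unknown`` and counted in the
        report. Nucleotide sequences are upper-cased and validated over ACGT.
    on_duplicate : {"error", "keep-first"}
        Behaviour when one identifier appears twice.
    id_regex
        Optional regex applied to the full header; group 1 (or the whole
        match) becomes the identifier. Default: first whitespace token.

    Returns
    -------
    FastaResult
        ``(records, report)`` where ``report`` counts residue substitutions
        per original character (protein alphabet only).
    """
    if alphabet not in ("protein", "nucleotide"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    if on_duplicate not in ("error", "keep-first"):
        raise ValueError(f"on_duplicate must be 'error' or 'keep-first'")

    canonical = set(CANONICAL_AA)
    records: list = []
    seen: set[str] = set()
    report: dict[str, int] = {}
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            if not header.strip():
                raise ValueError("FASTA record with empty header")
            rid = _extract_id(header, id_regex)
            if rid in seen:
                if on_duplicate == "error":
                    raise ValueError(f"duplicate identifier {rid!r} in {path}")
                continue
            seen.add(rid)
            seq = seq.upper().replace("*", "")
            if not seq:
                raise ValueError(f"zero-length sequence for {rid!r}")
            if alphabet == "protein":
                cleaned = []
                for ch in seq:
                    if ch in canonical:
                        cleaned.append(ch)
                    else:
                        report[ch] = report.get(ch, 0) + 1
                        cleaned.append(unknown)
                records.append(ProteinRecord(rid, "".join(cleaned)))
            else:
                bad = set(seq) - set(NUCLEOTIDES)
                if bad:
                    raise ValueError(
                        f"coding record {rid!r}: non-ACGT characters {sorted(bad)}"
                    )
                records.append(CodingRecord(rid, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return FastaResult(records, report)


def write_fasta(records: Iterable[ProteinRecord | CodingRecord], path: str | Path) -> None:
    """Write records back to FASTA (60-column wrapped)."""
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.seq if isinstance(rec, ProteinRecord) else rec.nt
            fh.write(f">{rec.id}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def load_property_table(
    path: str | Path,
    name: str | None = None,
    units: str = "",
    drop_zero: bool = True,
    drop_ambiguous: bool = True,
    drop_low_confidence: bool = False,
    delimiters: tuple[str, ...] = (";", ","),
    low_confidence_label: str = "low-confidence",
) -> PropertyTable:
    """Load a per-protein property TSV with the standard dataset filters.

    The TSV must have a header row with columns ``identifier`` and ``value``
    (an optional third ``confidence`` column enables the low-confidence
    filter). An identifier cell containing any of ``delimiters`` is treated
    as ambiguous — the measurement could not be attributed to one protein —
    and dropped when ``drop_ambiguous`` is set. Identical values listed on
    separate lines are retained. Zero or non-numeric values are dropped when
    ``drop_zero`` is set; zero values are unconditionally rejected by the
    positivity invariant and counted in the report either way.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"identifier", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"property table missing columns {required - set(df.columns)}")
    report = {"zero_or_nonnumeric": 0, "ambiguous": 0, "low_confidence": 0, "duplicate": 0}
    values: dict[str, float] = {}
    for _, row in df.iterrows():
        ident = str(row["identifier"]).strip()
        if drop_low_confidence and "confidence" in df.columns:
            conf = str(row.get("confidence", "")).strip().lower()
            if conf == low_confidence_label:
                report["low_confidence"] += 1
                continue
        if any(d in ident for d in delimiters):
            if drop_ambiguous:
                report["ambiguous"] += 1
                continue
        try:
            val = float(row["value"])
        except (TypeError, ValueError):
            report["zero_or_nonnumeric"] += 1
            continue
        if val <= 0 or val != val:
            # rejected by the positivity invariant even with drop_zero off
            report["zero_or_nonnumeric"] += 1
            continue
        if ident in values:
            raise ValueError(f"identifier {ident!r} appears twice in {path}")
        values[ident] = val
    if not values:
        raise ValueError(f"no rows survive filtering in {path}")
    return PropertyTable(
        name=name or Path(path).stem, values=values, units=units, filter_report=report
    )


def load_annotation_map(path: str | Path) -> AnnotationMap:
    """Load a two-column TSV (term, identifier) into an AnnotationMap.

    Duplicate (term, identifier) pairs collapse; blank lines are skipped.
    """
    terms: dict[str, set[str]] = {}
    n_lines = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"annotation line lacks two columns: {line!r}")
            term, ident = parts[0].strip(), parts[1].strip()
            terms.setdefault(term, set()).add(ident)
            n_lines += 1
    if n_lines == 0:
        raise ValueError(f"empty annotation file {path}")
    return AnnotationMap(terms)


def load_membership_list(path: str | Path, term: str | None = None) -> AnnotationMap:
    """Load a flat membership list (one identifier per line) as a single-term map."""
    ids: set[str] = set()
    with open(path) as fh:
        for line in fh:
            ident = line.strip()
            if ident and not ident.startswith("#"):
                ids.add(ident)
    if not ids:
        raise ValueError(f"empty membership list {path}")
    return AnnotationMap({term or Path(path).stem: ids})
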