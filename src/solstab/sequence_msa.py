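"""Sequences, query-anchored alignments and the PSSM mutation-space filters.

The mutational space of the design pipeline is gated by a position-specific
scoring matrix (PSSM) computed from a multiple sequence alignment of
homologues mapped onto the query coordinates.  Enrichment is expressed as a
log-likelihood ratio against a background amino-acid distribution:

    LL(i, a) = ln[ (n(i,a) + κ·b(a)) / (N_i + κ) / b(a) ]

with n(i,a) the residue counts in column i (gaps excluded), N_i the number
of non-gap observations, κ a pseudocount mass distributed by the background
frequencies b(a).  ΔLL(i, a) = LL(i, a) − LL(i, wt_i) measures enrichment
relative to the wild-type residue.  The default "strong" filter admits a
substitution only when LL > 0 and ΔLL > 0; C, M and N are excluded as
substitution targets by default because they carry chemical liabilities
(disulphide scrambling, oxidation, glycosylation/deamidation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}
#: substitution targets excluded by default (chemical liabilities)
DEFAULT_EXCLUDED_SUBSTITUTIONS: frozenset[str] = frozenset("CMN")

GAP_CHARS = "-."


class FastaParseError(ValueError):
    """Raised for malformed FASTA input, naming the offending line."""


class AlignmentConsistencyError(ValueError):
    """Raised when an alignment row cannot be mapped onto the query columns."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named amino-acid sequence, canonical upper-case letters, 1-based sites."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.identifier!r} is empty")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"sequence {self.identifier!r} contains non-canonical letters: "
                f"{''.join(sorted(bad))}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, site: int) -> str:
        """Residue at 1-based ``site``."""
        if not 1 <= site <= len(self.residues):
            raise IndexError(f"site {site} outside 1..{len(self.residues)}")
        return self.residues[site - 1]


@dataclass(frozen=True)
class QueryAlignment:
    """Homologue rows mapped onto query columns (one symbol per query position).

    Rows are strings of length L over the 20 amino acids plus ``-`` for a gap.
    The query maps to itself gap-free.
    """

    query: SequenceRecord
    rows: tuple[str, ...]
    row_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        L = len(self.query)
        if not self.rows:
            raise ValueError("alignment must contain at least one row")
        for k, row in enumerate(self.rows):
            if len(row) != L:
                raise AlignmentConsistencyError(
                    f"row {k} has {len(row)} mapped symbols, expected {L}"
                )
            bad = set(row) - set(AMINO_ACIDS) - {"-"}
            if bad:
                raise AlignmentConsistencyError(
                    f"row {k} contains unexpected symbols: {''.join(sorted(bad))}"
                )

    @property
    def depth(self) -> int:
        return len(self.rows)

    def __len__(self) -> int:
        return len(self.query)


@dataclass(frozen=True)
class PSSM:
    """Log-likelihood enrichment matrix over the 20 amino acids.

    ``ll`` and ``delta_ll`` are (L, 20) arrays indexed by (position-1,
    AA_INDEX[residue]); ``counts`` holds the raw per-column tallies.
    """

    query: SequenceRecord
    ll: np.ndarray
    delta_ll: np.ndarray
    counts: np.ndarray
    pseudocount: float
    background: np.ndarray

    def __post_init__(self) -> None:
        L = len(self.query)
        for name in ("ll", "delta_ll", "counts"):
            arr = getattr(self, name)
            if arr.shape != (L, 20):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({L}, 20)")
        if abs(float(self.background.sum()) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")

    def wt_ll(self, site: int) -> float:
        """LL of the wild-type residue at 1-based ``site``."""
        return float(self.ll[site - 1, AA_INDEX[self.query[site]]])

    def get_ll(self, site: int, residue: str) -> float:
        return float(self.ll[site - 1, AA_INDEX[residue]])

    def get_delta_ll(self, site: int, residue: str) -> float:
        return float(self.delta_ll[site - 1, AA_INDEX[residue]])

    def to_tsv(self, path: str | Path) -> None:
        """Write the LL matrix: rows = positions (with wt residue), cols = residues."""
        with open(path, "w") as fh:
            fh.write("position\twt\t" + "\t".join(AMINO_ACIDS) + "\n")
            for i in range(len(self.query)):
                cells = "\t".join(f"{v:.6f}" for v in self.ll[i])
                fh.write(f"{i + 1}\t{self.query.residues[i]}\t{cells}\n")


# ---------------------------------------------------------------------------
# readers


def _sanitize(identifier: str, seq: str, *, mask_noncanonical: bool) -> str:
    seq = seq.upper()
    if any(c in GAP_CHARS for c in seq):
        raise FastaParseError(
            f"record {identifier!r} contains gap characters; plain FASTA expected"
        )
    if mask_noncanonical:
        seq = "".join(c if c in AMINO_ACIDS else "" for c in seq)
    return seq


def read_fasta(
    path: str | Path, *, mask_noncanonical: bool = False
) -> list[SequenceRecord]:
    """Read plain (unaligned) FASTA into :class:`SequenceRecord` objects.

    Letters are upper-cased.  Non-canonical letters (``X``, ``B``, ``Z`` ...)
    raise :class:`FastaParseError` naming the line, unless
    ``mask_noncanonical`` is set, in which case they are dropped from the
    sequence.  Gap characters are always rejected.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    with open(path) as fh:
        parsed = list(SeqIO.parse(fh, "fasta"))
    if not parsed:
        raise FastaParseError(f"{path}: no FASTA records found (line 1)")
    for rec in parsed:
        try:
            seq = _sanitize(rec.id, str(rec.seq), mask_noncanonical=mask_noncanonical)
            records.append(SequenceRecord(rec.id, seq))
        except ValueError as exc:
            raise FastaParseError(
                f"{path}: {exc} (near line {_locate_record_line(path, rec.id)})"
            ) from exc
    return records


def _locate_record_line(path: Path, identifier: str) -> int:
    """Best-effort line number of a record header, for error messages."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">") and line[1:].split()[:1] == [identifier]:
                return lineno
    return 1


def read_a3m(path: str | Path, query_id: str | None = None) -> QueryAlignment:
    """Read an A3M (or aligned-FASTA) alignment mapped onto query columns.

    A3M dialect: lower-case letters are insertions relative to the query and
    occupy no query column — they are dropped.  ``.`` is likewise dropped.
    Upper-case letters and ``-`` map one-to-one onto query positions.  The
    query row is the record whose id equals ``query_id`` (default: the first
    record); it must be gap-free and canonical.

    Non-canonical upper-case letters in homologue rows are mapped to gaps;
    in the query they are a hard error.
    """
    path = Path(path)
    with open(path) as fh:
        parsed = list(SeqIO.parse(fh, "fasta"))
    if not parsed:
        raise FastaParseError(f"{path}: no alignment records found")

    if query_id is None:
        query_rec = parsed[0]
    else:
        matches = [r for r in parsed if r.id == query_id]
        if not matches:
            raise AlignmentConsistencyError(f"query id {query_id!r} not in {path}")
        query_rec = matches[0]

    query_mapped = _map_a3m_row(str(query_rec.seq))
    if "-" in query_mapped:
        raise AlignmentConsistencyError(
            f"query row {query_rec.id!r} contains gaps; it must map to itself"
        )
    query = SequenceRecord(query_rec.id, query_mapped)
    L = len(query)

    rows: list[str] = []
    row_ids: list[str] = []
    for rec in parsed:
        mapped = _map_a3m_row(str(rec.seq), homologue=rec.id != query_rec.id)
        if len(mapped) != L:
            raise AlignmentConsistencyError(
                f"row {rec.id!r} maps to {len(mapped)} columns, expected {L}"
            )
        rows.append(mapped)
        row_ids.append(rec.id)
    return QueryAlignment(query=query, rows=tuple(rows), row_ids=tuple(row_ids))


def _map_a3m_row(raw: str, *, homologue: bool = False) -> str:
    out = []
    for c in raw:
        if c in GAP_CHARS:
            out.append("-")
        elif c.islower():
            continue  # insertion relative to the query: no query column
        elif c in AMINO_ACIDS:
            out.append(c)
        elif homologue:
            out.append("-")  # non-canonical in a homologue: treat as gap
        else:
            raise AlignmentConsistencyError(
                f"non-canonical residue {c!r} in query row"
            )
    return "".join(out)


# ---------------------------------------------------------------------------
# PSSM


def _background_array(background: Mapping[str, float] | Sequence[float] | None) -> np.ndarray:
    if background is None:
        return np.full(20, 1.0 / 20.0)
    if isinstance(background, Mapping):
        arr = np.array([background[a] for a in AMINO_ACIDS], dtype=float)
    else:
        arr = np.asarray(background, dtype=float)
    if arr.shape != (20,):
        raise ValueError("background must provide one frequency per amino acid")
    if np.any(arr <= 0) or abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError("background frequencies must be positive and sum to 1")
    return arr


def compute_pssm(
    aln: QueryAlignment,
    pseudocount: float = 1.0,
    background: Mapping[str, float] | Sequence[float] | None = None,
) -> PSSM:
    """Compute the log-likelihood enrichment PSSM from a mapped alignment.

    LL(i,a) = ln[(n(i,a) + κ·b(a)) / (N_i + κ) / b(a)] with gaps excluded
    from the column totals N_i; ΔLL is taken against the query residue.
    Natural logarithm; only the sign matters for the downstream filters.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    bg = _background_array(background)
    L = len(aln.query)
    counts = np.zeros((L, 20), dtype=float)
    for row in aln.rows:
        for i, c in enumerate(row):
            if c != "-":
                counts[i, AA_INDEX[c]] += 1.0

    totals = counts.sum(axis=1)
    if pseudocount == 0 and np.any(totals == 0):
        bad = int(np.argmax(totals == 0)) + 1
        raise ValueError(
            f"column {bad} has no non-gap observations and pseudocount is 0"
        )
    with np.errstate(divide="ignore"):
        freq = (counts + pseudocount * bg) / (totals + pseudocount)[:, None]
        ll = np.log(freq / bg)

    wt_idx = np.array([AA_INDEX[c] for c in aln.query.residues])
    delta_ll = ll - ll[np.arange(L), wt_idx][:, None]
    return PSSM(
        query=aln.query,
        ll=ll,
        delta_ll=delta_ll,
        counts=counts,
        pseudocount=float(pseudocount),
        background=bg,
    )


def allowed_substitutions(
    pssm: PSSM,
    mode: str = "strong",
    excluded: Iterable[str] = DEFAULT_EXCLUDED_SUBSTITUTIONS,
) -> dict[int, frozenset[str]]:
    """Per-site sets of substitutions the PSSM permits.

    ``strong`` (default): residues with LL > 0 AND ΔLL > 0 at that position.
    ``enriched-only``: residues with LL > 0, the wild type itself excepted.
    Residues in ``excluded`` (default C, M, N) are removed from every set.
    Empty sets are legal.
    """
    if mode not in ("strong", "enriched-only"):
        raise ValueError(f"unknown mode {mode!r}")
    excluded_set = frozenset(excluded)
    out: dict[int, frozenset[str]] = {}
    for i in range(len(pssm.query)):
        wt = pssm.query.residues[i]
        allowed = set()
        for a in AMINO_ACIDS:
            if a == wt or a in excluded_set:
                continue
            j = AA_INDEX[a]
            if pssm.ll[i, j] <= 0:
                continue
            if mode == "strong" and pssm.delta_ll[i, j] <= 0:
                continue
            allowed.add(a)
        out[i + 1] = frozenset(allowed)
    return out


def flag_mutable_sites(pssm: PSSM) -> frozenset[int]:
    """Sites whose wild-type residue is depleted in the alignment (LL(i, wt) < 0)."""
    flagged = {
        i + 1
        for i in range(len(pssm.query))
        if pssm.ll[i, AA_INDEX[pssm.query.residues[i]]] < 0
    }
    return frozenset(flagged)


def write_fasta(path: str | Path, records: Iterable[SequenceRecord], width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.identifier}\n")
            for k in range(0, len(rec.residues), width):
                fh.write(rec.residues[k : k + width] + "\n")
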