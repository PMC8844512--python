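"""Reading, validating and deduplicating protein sequences.

All downstream descriptor code assumes sequences over the 20 canonical
amino-acid letters, uppercase, length >= 2 (the transition descriptors need
at least one adjacent residue pair).  Records carrying any other character
(B, J, O, U, X, Z, gaps, ...) are rejected whole, not repaired: stripping or
remapping residues would silently change composition and transition
frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 canonical amino-acid one-letter codes, alphabetical.
CANONICAL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_ALPHABET)

#: Minimum accepted sequence length (one adjacent pair for transitions).
MIN_LENGTH = 2


@dataclass(frozen=True)
class ProteinRecord:
    """One identified protein sequence, optionally labelled.

    label is 1 for the positive class (aquaporin), 0 for negative,
    None when unknown (e.g. prediction input).
    """

    id: str
    seq: str
    label: Optional[int] = None

    def with_label(self, label: int) -> "ProteinRecord":
        return ProteinRecord(self.id, self.seq, label)


@dataclass(frozen=True)
class Rejection:
    """Why a raw record was excluded from further processing."""

    id: str
    reason: str


def validate_record(rec: ProteinRecord) -> ProteinRecord | Rejection:
    """Return the uppercased record if it is canonical, else a Rejection.

    Rejection is a value, not an exception: callers batch-report rejected
    ids rather than aborting a whole FASTA file.
    """
    if not rec.id:
        return Rejection(rec.id, "empty-id")
    seq = rec.seq.upper()
    if len(seq) < MIN_LENGTH:
        return Rejection(rec.id, f"too-short (length {len(seq)} < {MIN_LENGTH})")
    offending = sorted(set(seq) - _CANONICAL_SET)
    if offending:
        return Rejection(rec.id, "non-canonical residues: " + ",".join(offending))
    return ProteinRecord(rec.id, seq, rec.label)


def read_fasta(
    path: str | Path,
    label: Optional[int] = None,
    rejections: Optional[list[Rejection]] = None,
) -> list[ProteinRecord]:
    """Read a FASTA file into validated :class:`ProteinRecord` objects.

    Sequence lines may wrap; the id is the first whitespace-delimited token
    of the header.  Records failing validation are excluded and logged; pass
    ``rejections`` (a list) to collect the per-record reasons.

    Raises FileNotFoundError for a missing file and ValueError when the file
    contains no parseable FASTA entry at all.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[ProteinRecord] = []
    n_entries = 0
    n_rejected = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        n_entries += 1
        raw = ProteinRecord(entry.id, str(entry.seq), label)
        result = validate_record(raw)
        if isinstance(result, Rejection):
            n_rejected += 1
            logger.warning("rejected %r from %s: %s", result.id, path.name, result.reason)
            if rejections is not None:
                rejections.append(result)
        else:
            records.append(result)
    if n_entries == 0:
        raise ValueError(f"no FASTA entries found in {path}")
    if n_rejected:
        logger.warning("%s: %d of %d records rejected", path.name, n_rejected, n_entries)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA (ids and sequences round-trip exactly)."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_rejections(rejections: Iterable[Rejection], path: str | Path) -> None:
    """Write a tab-separated rejection report: id <TAB> reason."""
    with Path(path).open("w") as fh:
        fh.write("id\treason\n")
        for r in rejections:
            fh.write(f"{r.id}\t{r.reason}\n")


def dedupe_exact(records: list[ProteinRecord]) -> tuple[list[ProteinRecord], int]:
    """Keep the first occurrence of each distinct sequence string.

    Input order is otherwise preserved.  Returns (kept, n_removed).  This is
    only the exact-identity subset of redundancy removal; similarity-based
    clustering (e.g. CD-HIT at 90% identity) is an upstream, external step.
    """
    seen: set[str] = set()
    kept: list[ProteinRecord] = []
    for rec in records:
        if rec.seq not in seen:
            seen.add(rec.seq)
            kept.append(rec)
    removed = len(records) - len(kept)
    if removed:
        logger.info("dedupe_exact removed %d duplicate records", removed)
    return kept, removed
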