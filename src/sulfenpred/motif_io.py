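"""Reading, extracting and serializing cysteine-centred sequence motifs.

A *motif* is a fixed-length window (2*flank + 1 residues, 21 by default)
centred on a candidate cysteine. Windows that overlap a protein terminus
are padded with the gap residue ``X`` so that every cysteine in a protein
yields a predictable motif. Coordinates are 1-based, matching UniProt
site annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

from .alphabet import AA_INDEX, GAP, MOTIF_ALPHABET, sanitize_residue

logger = logging.getLogger(__name__)

LABELS = ("positive", "negative", "unknown")

#: Default flank width: 10 residues either side of the central cysteine.
DEFAULT_FLANK = 10


class MotifError(ValueError):
    """Raised for malformed motifs or motif tables."""


@dataclass(frozen=True)
class Motif:
    """A cysteine-centred sequence window with provenance and label.

    Attributes
    ----------
    protein_id : str
        Identifier of the source protein.
    position : int
        1-based position of the central cysteine in the full protein.
    sequence : str
        Window of length ``2*flank + 1`` over the 20 amino acids plus ``X``.
    label : str
        One of ``positive`` (sulphenylated), ``negative``, ``unknown``.
    """

    protein_id: str
    position: int
    sequence: str
    label: str = "unknown"

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if n % 2 == 0 or n < 3:
            raise MotifError(
                f"motif length must be odd and >= 3, got {n} "
                f"({self.protein_id}:{self.position})"
            )
        centre = n // 2
        if self.sequence[centre] != "C":
            raise MotifError(
                f"central residue must be 'C', got {self.sequence[centre]!r} "
                f"({self.protein_id}:{self.position})"
            )
        bad = set(self.sequence) - set(MOTIF_ALPHABET)
        if bad:
            raise MotifError(
                f"illegal residue(s) {sorted(bad)} in motif "
                f"{self.protein_id}:{self.position}"
            )
        if self.label not in LABELS:
            raise MotifError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.position < 1:
            raise MotifError(f"position must be 1-based, got {self.position}")

    @property
    def flank(self) -> int:
        return len(self.sequence) // 2


@dataclass
class MotifDataset:
    """Ordered collection of motifs; (protein_id, position) pairs unique."""

    motifs: list[Motif] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for m in self.motifs:
            key = (m.protein_id, m.position)
            if key in seen:
                raise MotifError(f"duplicate motif {key[0]}:{key[1]}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self) -> Iterator[Motif]:
        return iter(self.motifs)

    def __getitem__(self, i: int) -> Motif:
        return self.motifs[i]

    @property
    def sample_ids(self) -> list[str]:
        return [f"{m.protein_id}:{m.position}" for m in self.motifs]

    @property
    def labels(self) -> list[str]:
        return [m.label for m in self.motifs]

    def label_counts(self) -> dict[str, int]:
        counts = {lab: 0 for lab in LABELS}
        for m in self.motifs:
            counts[m.label] += 1
        return counts

    def subset(self, indices: Sequence[int]) -> "MotifDataset":
        return MotifDataset([self.motifs[i] for i in indices])


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a multi-record FASTA into ``(protein_id, sequence)`` pairs.

    Identifiers are the header up to the first whitespace. Sequences are
    uppercased; letters outside the 20-letter alphabet are replaced by
    ``X`` with a logged warning. Duplicate identifiers and empty files are
    errors.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise MotifError(f"duplicate FASTA identifier {pid!r} in {path}")
        seen.add(pid)
        raw = str(rec.seq).upper()
        clean = "".join(sanitize_residue(c) for c in raw)
        subs = sorted({c for c, s in zip(raw, clean) if c != s})
        if subs:
            logger.warning(
                "protein %s: non-standard residue(s) %s mapped to 'X'",
                pid, ",".join(subs),
            )
        records.append((pid, clean))
    if not records:
        raise MotifError(f"no FASTA records found in {path}")
    return records


def extract_cys_motifs(
    protein_id: str, sequence: str, flank: int = DEFAULT_FLANK
) -> list[Motif]:
    """Extract one ``X``-padded window per cysteine in ``sequence``.

    Returns an empty list (not an error) when the protein has no cysteine.
    """
    if flank < 1:
        raise ValueError(f"flank must be >= 1, got {flank}")
    seq = "".join(sanitize_residue(c) for c in sequence)
    pad = GAP * flank
    padded = pad + seq + pad
    motifs = []
    for i, ch in enumerate(seq):
        if ch == "C":
            window = padded[i : i + 2 * flank + 1]
            motifs.append(Motif(protein_id, i + 1, window))
    return motifs


TABLE_COLUMNS = ["protein_id", "position", "sequence", "label"]


def load_motif_table(path: str | Path) -> MotifDataset:
    """Load a labelled motif table (TSV with a fixed 4-column header)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "sequence": str})
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise MotifError(f"{path}: missing column(s) {missing}")
    motifs = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            motifs.append(
                Motif(
                    protein_id=str(row.protein_id),
                    position=int(row.position),
                    sequence=str(row.sequence),
                    label=str(row.label),
                )
            )
        except (MotifError, ValueError) as exc:
            raise MotifError(f"{path}, row {row_no}: {exc}") from exc
    return MotifDataset(motifs)


def write_motif_table(dataset: MotifDataset, path: str | Path) -> None:
    """Write a MotifDataset as TSV; ``load_motif_table`` round-trips it."""
    df = pd.DataFrame(
        [(m.protein_id, m.position, m.sequence, m.label) for m in dataset],
        columns=TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(protein_id, sequence)`` pairs as unwrapped FASTA."""
    with open(path, "w") as fh:
        for pid, seq in records:
            fh.write(f">{pid}\n{seq}\n")
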