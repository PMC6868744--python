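"""Parsers for external structure-predictor outputs and a mock provider.

The feature encoders consume per-residue structural scores produced by
external tools run on the full protein sequence:

* PSI-BLAST ASCII position-specific scoring matrices (``-out_ascii_pssm``,
  the 2.2.x dialect): 20 log-odds integers plus per-position information
  content;
* DISOPRED3 ``.diso`` files: per-residue disorder probability;
* PSIPRED 3.x ``.ss2`` files: predicted class (C/E/H) and three class
  probabilities per residue;
* NetSurfP-1.1 tabular output: buried/exposed class, relative and
  absolute solvent accessibility, Z-fit and three secondary-structure
  probabilities (seven scores per residue, kept in file-column order).

None of these tools is executed here; only their outputs are parsed.
The :func:`mock_provider` synthesises deterministic annotations from a
seeded hash so the whole pipeline can be exercised without any of them.
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabet import AMINO_ACIDS

#: Residue order of log-odds columns in PSI-BLAST ASCII PSSM files.
PSSM_COLUMN_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Names of the seven per-residue surface-accessibility scores, in
#: NetSurfP-1.1 column order (class flag first, then columns 4-9 of the
#: file). The class flag is 0 for buried ('B'), 1 for exposed ('E').
ACC_SCORE_NAMES = ("exposed", "rsa", "asa", "zfit", "p_helix", "p_strand", "p_coil")

SS_CLASSES = "CEH"


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent predictor output files."""


@dataclass
class PSSMProfile:
    """Per-residue sequence-conservation profile from PSI-BLAST.

    ``log_odds`` is (length, 20) in :data:`PSSM_COLUMN_ORDER`;
    ``information`` is the per-position information content.
    """

    protein_id: str
    log_odds: np.ndarray
    information: np.ndarray
    residues: str = ""

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.information = np.asarray(self.information, dtype=float)
        if self.log_odds.shape != (len(self.information), 20):
            raise AnnotationError(
                f"{self.protein_id}: PSSM log-odds shape {self.log_odds.shape} "
                f"inconsistent with {len(self.information)} information values"
            )

    def __len__(self) -> int:
        return self.log_odds.shape[0]


@dataclass
class StructuralAnnotation:
    """Per-residue structural scores for one protein.

    Arrays are aligned to 1-based protein positions (row 0 = position 1):
    ``disorder`` (length,), ``ss_class`` (length,) of ``C``/``E``/``H``,
    ``ss_probs`` (length, 3) ordered (pC, pE, pH), and ``acc_scores``
    (length, 7) ordered as :data:`ACC_SCORE_NAMES`.
    """

    protein_id: str
    disorder: np.ndarray
    ss_class: np.ndarray
    ss_probs: np.ndarray
    acc_scores: np.ndarray

    def __post_init__(self) -> None:
        self.disorder = np.asarray(self.disorder, dtype=float)
        self.ss_probs = np.asarray(self.ss_probs, dtype=float)
        self.acc_scores = np.asarray(self.acc_scores, dtype=float)
        self.ss_class = np.asarray(self.ss_class, dtype="U1")
        n = len(self.disorder)
        if not (len(self.ss_class) == n and self.ss_probs.shape == (n, 3)
                and self.acc_scores.shape == (n, 7)):
            raise AnnotationError(f"{self.protein_id}: ragged annotation arrays")
        if np.any((self.disorder < 0) | (self.disorder > 1)):
            raise AnnotationError(f"{self.protein_id}: disorder score outside [0,1]")
        if np.any((self.ss_probs < 0) | (self.ss_probs > 1)):
            raise AnnotationError(f"{self.protein_id}: ss probability outside [0,1]")
        bad = set(self.ss_class.tolist()) - set(SS_CLASSES)
        if bad:
            raise AnnotationError(f"{self.protein_id}: unknown ss class {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.disorder)


def _check_length(name: str, path, n: int, sequence: str | None) -> None:
    if sequence is not None and n != len(sequence):
        raise AnnotationError(
            f"{path}: {name} has {n} residues but sequence has {len(sequence)}"
        )


def parse_psiblast_pssm(
    path: str | Path, protein_id: str = "", sequence: str | None = None
) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM (``-out_ascii_pssm``, 2.2.x dialect).

    Only the first 20 columns (log-odds) and the information-content
    column are kept. When ``sequence`` is given, the residue column is
    checked against it.
    """
    path = Path(path)
    rows: list[list[float]] = []
    info: list[float] = []
    residues: list[str] = []
    expected_pos = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        parts = line.split()
        # Data rows start with a position integer followed by a residue letter.
        if len(parts) < 22 or not parts[0].isdigit() or len(parts[1]) != 1:
            continue
        expected_pos += 1
        if int(parts[0]) != expected_pos:
            raise AnnotationError(
                f"{path}:{lineno}: position {parts[0]} out of order "
                f"(expected {expected_pos}); truncated or non-2.2.x dialect?"
            )
        try:
            scores = [float(v) for v in parts[2:22]]
            # Information content sits after the 20 weighted-percentage
            # columns when present; fall back to 0 for truncated dialects.
            inf = float(parts[42]) if len(parts) >= 43 else 0.0
        except ValueError as exc:
            raise AnnotationError(f"{path}:{lineno}: non-numeric PSSM entry") from exc
        rows.append(scores)
        info.append(inf)
        residues.append(parts[1])
    if not rows:
        raise AnnotationError(f"{path}: no PSSM rows found (truncated file?)")
    seq_found = "".join(residues)
    if sequence is not None:
        _check_length("PSSM", path, len(rows), sequence)
        mism = [i + 1 for i, (a, b) in enumerate(zip(seq_found, sequence))
                if a != b and b != "X"]
        if mism:
            raise AnnotationError(
                f"{path}: residue mismatch vs FASTA at position(s) {mism[:5]}"
            )
    return PSSMProfile(protein_id or path.stem, np.array(rows), np.array(info),
                       residues=seq_found)


def parse_disopred(
    path: str | Path, sequence: str | None = None
) -> np.ndarray:
    """Parse a DISOPRED3 ``.diso`` file into per-residue disorder scores."""
    path = Path(path)
    scores: list[float] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) < 4:
            raise AnnotationError(
                f"{path}:{lineno}: expected 'position residue state score'; "
                f"got {len(parts)} fields (DISOPRED3 .diso dialect required)"
            )
        try:
            score = float(parts[3])
        except ValueError as exc:
            raise AnnotationError(f"{path}:{lineno}: non-numeric score") from exc
        if not 0.0 <= score <= 1.0:
            raise AnnotationError(f"{path}:{lineno}: score {score} outside [0,1]")
        scores.append(score)
    if not scores:
        raise AnnotationError(f"{path}: no disorder records found")
    _check_length("disorder", path, len(scores), sequence)
    return np.asarray(scores)


def parse_psipred_ss2(
    path: str | Path, sequence: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Parse a PSIPRED ``.ss2`` file.

    Returns ``(classes, probs)`` where ``classes`` is an array of
    ``C``/``E``/``H`` letters and ``probs`` is (length, 3) ordered
    (pC, pE, pH), preserved to file precision.
    """
    path = Path(path)
    classes: list[str] = []
    probs: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) != 6:
            continue  # header line ("VFORMAT ..." has no 6-field layout)
        cls = parts[2]
        if cls not in SS_CLASSES:
            raise AnnotationError(
                f"{path}:{lineno}: unknown secondary-structure class {cls!r}"
            )
        try:
            p = [float(parts[3]), float(parts[4]), float(parts[5])]
        except ValueError as exc:
            raise AnnotationError(f"{path}:{lineno}: non-numeric probability") from exc
        classes.append(cls)
        probs.append(p)
    if not classes:
        raise AnnotationError(f"{path}: no ss2 records found")
    _check_length("ss2", path, len(classes), sequence)
    return np.asarray(classes, dtype="U1"), np.asarray(probs)


def parse_netsurfp(
    path: str | Path, sequence: str | None = None
) -> np.ndarray:
    """Parse NetSurfP-1.1 tabular output into (length, 7) score records.

    Column order of the result follows :data:`ACC_SCORE_NAMES`: the
    buried/exposed class flag ('B' -> 0, 'E' -> 1) followed by the six
    numeric columns (RSA, ASA, Z-fit, p-helix, p-strand, p-coil) kept
    raw; min-max normalization happens later in the encoder.
    """
    path = Path(path)
    rows: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if parts[0] not in ("B", "E"):
            raise AnnotationError(
                f"{path}:{lineno}: class flag must be 'B' or 'E', got {parts[0]!r}"
            )
        if len(parts) != 10:
            raise AnnotationError(
                f"{path}:{lineno}: expected 10 columns (NetSurfP-1.1 dialect), "
                f"got {len(parts)}"
            )
        try:
            vals = [1.0 if parts[0] == "E" else 0.0] + [float(v) for v in parts[4:10]]
        except ValueError as exc:
            raise AnnotationError(f"{path}:{lineno}: non-numeric score") from exc
        rows.append(vals)
    if not rows:
        raise AnnotationError(f"{path}: no NetSurfP records found")
    _check_length("NetSurfP", path, len(rows), sequence)
    return np.asarray(rows)


def load_annotation_dir(
    annot_dir: str | Path, protein_id: str, sequence: str | None = None
) -> tuple[StructuralAnnotation, PSSMProfile]:
    """Load ``<annot_dir>/<protein_id>.{pssm,diso,ss2,nsp}``."""
    annot_dir = Path(annot_dir)
    pssm = parse_psiblast_pssm(annot_dir / f"{protein_id}.pssm", protein_id, sequence)
    disorder = parse_disopred(annot_dir / f"{protein_id}.diso", sequence)
    ss_class, ss_probs = parse_psipred_ss2(annot_dir / f"{protein_id}.ss2", sequence)
    acc = parse_netsurfp(annot_dir / f"{protein_id}.nsp", sequence)
    ann = StructuralAnnotation(protein_id, disorder, ss_class, ss_probs, acc)
    return ann, pssm


# ---------------------------------------------------------------------------
# deterministic mock provider


def _hash_unit(seed: int, *fields: object) -> float:
    """Uniform [0,1) float from a blake2b hash — platform-independent."""
    key = "\x1f".join(str(f) for f in fields).encode()
    h = hashlib.blake2b(key, digest_size=8, salt=struct.pack("<q", seed)).digest()
    return int.from_bytes(h, "little") / 2.0**64


def mock_provider(
    protein_id: str, sequence: str, seed: int = 0
) -> tuple[StructuralAnnotation, PSSMProfile]:
    """Deterministic pseudo-annotations for testing without external tools.

    Every score is a pure function of ``(seed, protein_id, position)``
    through a keyed hash, so outputs are identical across runs and
    platforms (no float RNG state involved).
    """
    n = len(sequence)
    disorder = np.empty(n)
    ss_class = np.empty(n, dtype="U1")
    ss_probs = np.empty((n, 3))
    acc = np.empty((n, 7))
    log_odds = np.empty((n, 20))
    info = np.empty(n)
    for i, res in enumerate(sequence):
        pos = i + 1
        disorder[i] = _hash_unit(seed, protein_id, pos, "diso")
        raw = np.array([_hash_unit(seed, protein_id, pos, "ss", c) for c in SS_CLASSES])
        probs = raw / raw.sum()
        ss_probs[i] = probs
        ss_class[i] = SS_CLASSES[int(np.argmax(probs))]
        acc[i, 0] = 1.0 if _hash_unit(seed, protein_id, pos, "exposed") > 0.5 else 0.0
        acc[i, 1] = _hash_unit(seed, protein_id, pos, "rsa")
        acc[i, 2] = 200.0 * _hash_unit(seed, protein_id, pos, "asa")
        acc[i, 3] = 8.0 * _hash_unit(seed, protein_id, pos, "zfit") - 4.0
        acc[i, 4:7] = probs
        for j, col in enumerate(PSSM_COLUMN_ORDER):
            base = 6.0 if res == col else -2.0
            jitter = round(4.0 * _hash_unit(seed, protein_id, pos, "pssm", col) - 2.0)
            log_odds[i, j] = base + jitter
        info[i] = 2.0 * _hash_unit(seed, protein_id, pos, "info")
    ann = StructuralAnnotation(protein_id, disorder, ss_class, ss_probs, acc)
    profile = PSSMProfile(protein_id, log_odds, info, residues=sequence)
    return ann, profile


class DirectoryStore:
    """Annotation store over ``<annot_dir>/<protein_id>.{pssm,diso,ss2,nsp}``.

    When a ``protein_id -> sequence`` map is given, every parsed file is
    length-checked (and the PSSM residue column cross-checked) against it.
    """

    def __init__(self, annot_dir: str | Path, sequences: dict[str, str] | None = None):
        self._dir = Path(annot_dir)
        self._sequences = dict(sequences) if sequences else None
        self._cache: dict[str, tuple[StructuralAnnotation, PSSMProfile]] = {}

    def get(self, protein_id: str) -> tuple[StructuralAnnotation, PSSMProfile]:
        if protein_id not in self._cache:
            seq = self._sequences.get(protein_id) if self._sequences else None
            self._cache[protein_id] = load_annotation_dir(self._dir, protein_id, seq)
        return self._cache[protein_id]


def write_annotation_dir(annot_dir: str | Path, protein_id: str,
                         annotation: StructuralAnnotation,
                         profile: PSSMProfile) -> None:
    """Write one protein's annotations in the directory-layout convention.

    The files round-trip through the parsers in this module.
    """
    annot_dir = Path(annot_dir)
    annot_dir.mkdir(parents=True, exist_ok=True)
    seq = profile.residues or "X" * len(annotation)
    with open(annot_dir / f"{protein_id}.pssm", "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        for i in range(len(profile)):
            lo = " ".join(f"{int(v):3d}" for v in profile.log_odds[i])
            pct = " ".join("0" for _ in range(20))
            fh.write(f"{i + 1:5d} {seq[i]} {lo} {pct} "
                     f"{profile.information[i]:6.2f} 0.00\n")
    with open(annot_dir / f"{protein_id}.diso", "w") as fh:
        fh.write("# DISOPRED version 3\n")
        for i in range(len(annotation)):
            state = "*" if annotation.disorder[i] >= 0.5 else "."
            fh.write(f"{i + 1:5d} {seq[i]} {state} {annotation.disorder[i]:.3f}\n")
    with open(annot_dir / f"{protein_id}.ss2", "w") as fh:
        fh.write("# PSIPRED VFORMAT\n\n")
        for i in range(len(annotation)):
            pc, pe, ph = annotation.ss_probs[i]
            fh.write(f"{i + 1:4d} {seq[i]} {annotation.ss_class[i]} "
                     f"{pc:6.3f} {pe:6.3f} {ph:6.3f}\n")
    with open(annot_dir / f"{protein_id}.nsp", "w") as fh:
        fh.write("# NetSurfP-1.1 output\n")
        for i in range(len(annotation)):
            a = annotation.acc_scores[i]
            flag = "E" if a[0] >= 0.5 else "B"
            fh.write(
                f"{flag} {seq[i]} {protein_id} {i + 1:5d} "
                f"{a[1]:.3f} {a[2]:.3f} {a[3]:.3f} {a[4]:.3f} {a[5]:.3f} {a[6]:.3f}\n"
            )


class MockProviderStore:
    """Annotation store backed by :func:`mock_provider`, keyed by protein."""

    def __init__(self, sequences: dict[str, str], seed: int = 0):
        self._sequences = dict(sequences)
        self._seed = seed
        self._cache: dict[str, tuple[StructuralAnnotation, PSSMProfile]] = {}

    def get(self, protein_id: str) -> tuple[StructuralAnnotation, PSSMProfile]:
        if protein_id not in self._cache:
            if protein_id not in self._sequences:
                raise AnnotationError(f"no sequence registered for {protein_id!r}")
            self._cache[protein_id] = mock_provider(
                protein_id, self._sequences[protein_id], self._seed
            )
        return self._cache[protein_id]
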