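"""Amino-acid index table: 64 physicochemical scales in 8 clusters.

Each index maps the 20 amino acids to a real value; the gap residue
``X`` is assigned the mean of the 20 values so that padded positions
carry a neutral signal. The default table shipped with the package
(``data/aaindex64_synthetic.txt``) is a curated synthetic stand-in — see
the file header — and can be replaced by any file in the same format.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .alphabet import AMINO_ACIDS, GAP

DEFAULT_RESOURCE = "aaindex64_synthetic.txt"


class AAindexError(ValueError):
    """Raised for malformed index tables."""


@dataclass(frozen=True)
class AAindexTable:
    """Named amino-acid indices grouped into property clusters."""

    index_ids: tuple[str, ...]
    clusters: tuple[str, ...]
    # (n_indices, 21) values: 20 amino acids in alphabetical order + 'X'.
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.index_ids) != len(set(self.index_ids)):
            raise AAindexError("duplicate index identifiers")
        if self.values.shape != (len(self.index_ids), 21):
            raise AAindexError(
                f"values shape {self.values.shape} != ({len(self.index_ids)}, 21)"
            )

    def __len__(self) -> int:
        return len(self.index_ids)

    def value(self, index_id: str, residue: str) -> float:
        i = self.index_ids.index(index_id)
        j = 20 if residue == GAP else AMINO_ACIDS.index(residue)
        return float(self.values[i, j])

    def select(self, index_ids: list[str]) -> "AAindexTable":
        """Restrict the table to a configured subset of index identifiers."""
        missing = [i for i in index_ids if i not in self.index_ids]
        if missing:
            raise AAindexError(f"unknown index identifier(s): {missing}")
        rows = [self.index_ids.index(i) for i in index_ids]
        return AAindexTable(
            tuple(index_ids),
            tuple(self.clusters[r] for r in rows),
            self.values[rows],
        )


def parse_aaindex_table(text: str, source: str = "<string>") -> AAindexTable:
    """Parse the whitespace-separated index table format.

    Each non-comment line: ``index_id cluster v_A v_C ... v_Y`` with the
    20 values in alphabetical residue order. An index missing a residue
    value is rejected here, at load time.
    """
    ids: list[str] = []
    clusters: list[str] = []
    rows: list[np.ndarray] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) != 22:
            raise AAindexError(
                f"{source}:{lineno}: expected id, cluster and 20 values; "
                f"got {len(parts)} fields"
            )
        try:
            vals = np.array([float(v) for v in parts[2:]], dtype=float)
        except ValueError as exc:
            raise AAindexError(f"{source}:{lineno}: non-numeric value") from exc
        ids.append(parts[0])
        clusters.append(parts[1])
        rows.append(np.append(vals, vals.mean()))  # 'X' = mean of the 20
    if not ids:
        raise AAindexError(f"{source}: no index records found")
    return AAindexTable(tuple(ids), tuple(clusters), np.vstack(rows))


def load_aaindex_table(path: str | Path | None = None) -> AAindexTable:
    """Load an index table from ``path``, or the packaged default."""
    if path is None:
        text = (
            resources.files("sulfenpred.data").joinpath(DEFAULT_RESOURCE).read_text()
        )
        return parse_aaindex_table(text, DEFAULT_RESOURCE)
    path = Path(path)
    return parse_aaindex_table(path.read_text(), str(path))
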