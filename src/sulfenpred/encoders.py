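"""Feature encoders for cysteine-centred motifs.

Nine feature blocks are computed per motif and assembled column-wise
into one feature matrix:

==========  =====================================================  ====
cluster     content                                                dim
==========  =====================================================  ====
AAC         amino-acid composition (counts / window length)          20
CKSAAP      composition of k-spaced residue pairs, k = 0..5        2400
BLOSUM62    per-position substitution-score rows (20 aa + ``*``)    441
PSSM        per-position profile rows (20 log-odds + information)   441
AAindex     per-position values of 64 physicochemical indices      1344
BINARY      per-position one-hot over 20 aa + ``X``                 441
DISOPRED    flank disorder scores (10 up + 10 downstream)            20
PSIPRED     per-position (class, pC, pE, pH)                         84
ACC         per-position 7 surface-accessibility scores, min-max    147
==========  =====================================================  ====

The PSSM block width is configurable (see :class:`EncoderConfig`): 441
with the per-position information column, 420 without it, and 400 when
additionally the C-terminal window position is dropped. The last
configuration brings the nine-block total to 5297 columns.

Every encoder is a pure function of (motif, annotation, config):
repeated calls are byte-identical.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .aaindex import AAindexTable, load_aaindex_table
from .alphabet import AA_INDEX, AMINO_ACIDS, GAP, MOTIF_ALPHABET, MOTIF_INDEX
from .motif_io import Motif, MotifDataset
from .structural import (
    ACC_SCORE_NAMES,
    PSSM_COLUMN_ORDER,
    PSSMProfile,
    SS_CLASSES,
    StructuralAnnotation,
)

logger = logging.getLogger(__name__)

#: Fixed assembly order of the nine feature clusters.
CLUSTER_ORDER = (
    "AAC", "CKSAAP", "BLOSUM62", "PSSM", "AAindex", "BINARY",
    "DISOPRED", "PSIPRED", "ACC",
)

SEQUENCE_CLUSTERS = ("AAC", "CKSAAP", "BLOSUM62", "PSSM", "AAindex", "BINARY")
STRUCTURAL_CLUSTERS = ("DISOPRED", "PSIPRED", "ACC")

#: 21-letter substitution row order: 20 amino acids + the terminal signal.
BLOSUM_ROW_ORDER = AMINO_ACIDS + "*"

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum62_matrix() -> pd.DataFrame:
    """The standard BLOSUM62 table restricted to the 21 columns used here.

    Rows are indexed by the motif alphabet (``X`` included), columns by
    the 20 amino acids plus the terminal ``*`` entry.
    """
    rows = list(MOTIF_ALPHABET)
    cols = list(BLOSUM_ROW_ORDER)
    data = [[float(_BLOSUM62[r][c]) for c in cols] for r in rows]
    return pd.DataFrame(data, index=rows, columns=cols)


_BLOSUM_ARRAY = None


def _blosum_array() -> np.ndarray:
    global _BLOSUM_ARRAY
    if _BLOSUM_ARRAY is None:
        _BLOSUM_ARRAY = blosum62_matrix().to_numpy()
    return _BLOSUM_ARRAY


class EncodingError(ValueError):
    """Raised for configuration or annotation problems during encoding."""


@dataclass(frozen=True)
class EncoderConfig:
    """Tunable encoder settings.

    ``k_max``: largest pair spacing for CKSAAP (default 5, giving
    ``(k_max+1) * 400 = 2400`` columns).
    ``pssm_width``: 21 keeps the per-position information-content column
    next to the 20 log-odds; 20 drops it.
    ``pssm_drop_terminal``: drop the C-terminal window position from the
    PSSM block (with ``pssm_width=20`` this yields the 400-column
    variant and a 5297-column nine-block total).
    """

    k_max: int = 5
    pssm_width: int = 21
    pssm_drop_terminal: bool = False
    aaindex_ids: tuple[str, ...] | None = None

    def table2(self) -> "EncoderConfig":
        """The configuration whose nine blocks total 5297 columns."""
        return replace(self, pssm_width=20, pssm_drop_terminal=True)


def _signed_positions(flank: int) -> list[int]:
    """Window positions as signed offsets from the central cysteine."""
    return list(range(-flank, flank + 1))


def _pos_tag(offset: int) -> str:
    return f"p{offset:+d}" if offset else "p0"


# ---------------------------------------------------------------------------
# sequence encoders


def encode_aac(motif: Motif) -> np.ndarray:
    """Amino-acid composition: counts of each residue / window length.

    ``X`` contributes to no dimension, so the vector sums to
    ``(W - #X) / W`` for a window of length W.
    """
    w = len(motif.sequence)
    out = np.zeros(20)
    for ch in motif.sequence:
        if ch != GAP:
            out[AA_INDEX[ch]] += 1.0
    return out / w


def aac_feature_names() -> list[str]:
    return [f"AAC.{aa}" for aa in AMINO_ACIDS]


def encode_cksaap(motif: Motif, k_max: int = 5) -> np.ndarray:
    """Composition of k-spaced amino-acid pairs for k = 0..k_max.

    A k-spaced pair is an ordered residue pair separated by k intervening
    positions. Each count is normalized by the number of such pairs in
    the window, ``W - k - 1``; pairs containing ``X`` are skipped in the
    numerator only, so the denominator stays fixed.
    """
    w = len(motif.sequence)
    if k_max < 0:
        raise EncodingError(f"k_max must be >= 0, got {k_max}")
    if w <= k_max + 1:
        raise EncodingError(f"k_max={k_max} too large for window of length {w}")
    out = np.zeros((k_max + 1) * 400)
    seq = motif.sequence
    for k in range(k_max + 1):
        denom = w - k - 1
        base = k * 400
        for i in range(w - k - 1):
            a, b = seq[i], seq[i + k + 1]
            if a == GAP or b == GAP:
                continue
            out[base + AA_INDEX[a] * 20 + AA_INDEX[b]] += 1.0 / denom
    return out


def cksaap_feature_names(k_max: int = 5) -> list[str]:
    return [
        f"CKSAAP.k{k}.{a}{b}"
        for k in range(k_max + 1)
        for a in AMINO_ACIDS
        for b in AMINO_ACIDS
    ]


def encode_binary(motif: Motif) -> np.ndarray:
    """One-hot encoding: per position a 21-vector over A..Y then ``X``."""
    w = len(motif.sequence)
    out = np.zeros(w * 21)
    for i, ch in enumerate(motif.sequence):
        out[i * 21 + MOTIF_INDEX[ch]] = 1.0
    return out


def binary_feature_names(flank: int = 10) -> list[str]:
    return [
        f"BINARY.{_pos_tag(off)}.{aa}"
        for off in _signed_positions(flank)
        for aa in MOTIF_ALPHABET
    ]


def encode_blosum62(motif: Motif, matrix: pd.DataFrame | None = None) -> np.ndarray:
    """Per-position BLOSUM62 rows: 20 substitution scores + the terminal
    ``*`` entry for each residue; padded ``X`` positions use the X row."""
    arr = matrix.to_numpy() if matrix is not None else _blosum_array()
    idx = [MOTIF_INDEX[ch] for ch in motif.sequence]
    return arr[idx].ravel()


def blosum62_feature_names(flank: int = 10) -> list[str]:
    return [
        f"BLOSUM62.{_pos_tag(off)}.{c}"
        for off in _signed_positions(flank)
        for c in BLOSUM_ROW_ORDER
    ]


def _window_protein_indices(motif: Motif, protein_length: int) -> list[int | None]:
    """0-based protein index for each window position, None when padded."""
    flank = motif.flank
    out: list[int | None] = []
    for off in _signed_positions(flank):
        pos = motif.position + off  # 1-based
        out.append(pos - 1 if 1 <= pos <= protein_length else None)
    return out


# PSSM log-odds are re-ordered from the PSI-BLAST file column order into
# the package's alphabetical residue order.
_PSSM_REORDER = [PSSM_COLUMN_ORDER.index(aa) for aa in AMINO_ACIDS]


def encode_pssm(
    motif: Motif,
    profile: PSSMProfile,
    width: int = 21,
    drop_terminal: bool = False,
) -> np.ndarray:
    """Per-position profile rows: 20 log-odds (alphabetical residue
    order) plus, at width 21, the position's information content.

    Padded window positions contribute zero rows. ``drop_terminal``
    removes the C-terminal window position.
    """
    if width not in (20, 21):
        raise EncodingError(f"pssm width must be 20 or 21, got {width}")
    n = len(profile)
    rows = []
    indices = _window_protein_indices(motif, n)
    if drop_terminal:
        indices = indices[:-1]
    for idx in indices:
        if idx is None:
            rows.append(np.zeros(width))
        else:
            row = profile.log_odds[idx][_PSSM_REORDER]
            if width == 21:
                row = np.append(row, profile.information[idx])
            rows.append(row)
    return np.concatenate(rows)


def pssm_feature_names(
    flank: int = 10, width: int = 21, drop_terminal: bool = False
) -> list[str]:
    cols = list(AMINO_ACIDS) + (["info"] if width == 21 else [])
    offsets = _signed_positions(flank)
    if drop_terminal:
        offsets = offsets[:-1]
    return [f"PSSM.{_pos_tag(off)}.{c}" for off in offsets for c in cols]


def encode_aaindex(motif: Motif, table: AAindexTable) -> np.ndarray:
    """Per-position values of every index in ``table`` (position-major)."""
    idx = [20 if ch == GAP else AA_INDEX[ch] for ch in motif.sequence]
    # values is (n_indices, 21 residues); take per-position columns.
    return table.values[:, idx].T.ravel()


def aaindex_feature_names(table: AAindexTable, flank: int = 10) -> list[str]:
    return [
        f"AAindex.{_pos_tag(off)}.{iid}"
        for off in _signed_positions(flank)
        for iid in table.index_ids
    ]


# ---------------------------------------------------------------------------
# structural encoders


def _require_annotation(motif: Motif, annotation: StructuralAnnotation) -> None:
    if annotation is None:
        raise EncodingError(
            f"missing structural annotation for {motif.protein_id}:{motif.position}"
        )


def encode_disorder(motif: Motif, annotation: StructuralAnnotation) -> np.ndarray:
    """Flank disorder scores: 10 upstream + 10 downstream (centre
    excluded); padded positions score 0."""
    _require_annotation(motif, annotation)
    indices = _window_protein_indices(motif, len(annotation))
    centre = motif.flank
    out = []
    for i, idx in enumerate(indices):
        if i == centre:
            continue
        out.append(0.0 if idx is None else float(annotation.disorder[idx]))
    return np.asarray(out)


def disorder_feature_names(flank: int = 10) -> list[str]:
    return [
        f"DISOPRED.{_pos_tag(off)}" for off in _signed_positions(flank) if off != 0
    ]


_SS_CODE = {c: float(i) for i, c in enumerate(SS_CLASSES)}  # C=0, E=1, H=2


def encode_secondary_structure(
    motif: Motif, annotation: StructuralAnnotation
) -> np.ndarray:
    """Per-position (class code, pC, pE, pH); padded positions (0,0,0,0).

    The class is coded C=0, E=1, H=2.
    """
    _require_annotation(motif, annotation)
    if np.any((annotation.ss_probs < 0) | (annotation.ss_probs > 1)):
        raise EncodingError(f"{motif.protein_id}: ss probabilities outside [0,1]")
    indices = _window_protein_indices(motif, len(annotation))
    out = np.zeros(len(indices) * 4)
    for i, idx in enumerate(indices):
        if idx is None:
            continue
        out[i * 4] = _SS_CODE[str(annotation.ss_class[idx])]
        out[i * 4 + 1 : i * 4 + 4] = annotation.ss_probs[idx]
    return out


def psipred_feature_names(flank: int = 10) -> list[str]:
    return [
        f"PSIPRED.{_pos_tag(off)}.{c}"
        for off in _signed_positions(flank)
        for c in ("class", "pC", "pE", "pH")
    ]


def encode_surface_accessibility_raw(
    motif: Motif, annotation: StructuralAnnotation
) -> np.ndarray:
    """Raw per-position 7-score accessibility vector; padded = NaN.

    NaNs mark positions with no residue; they are excluded from min-max
    fitting and mapped to 0 after normalization.
    """
    _require_annotation(motif, annotation)
    indices = _window_protein_indices(motif, len(annotation))
    out = np.full(len(indices) * 7, np.nan)
    for i, idx in enumerate(indices):
        if idx is not None:
            out[i * 7 : i * 7 + 7] = annotation.acc_scores[idx]
    return out


def acc_feature_names(flank: int = 10) -> list[str]:
    return [
        f"ACC.{_pos_tag(off)}.{name}"
        for off in _signed_positions(flank)
        for name in ACC_SCORE_NAMES
    ]


# ---------------------------------------------------------------------------
# min-max normalization (used for the ACC block)


@dataclass(frozen=True)
class MinMaxParams:
    """Per-group minima and maxima fitted on training data."""

    groups: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray

    def span(self) -> np.ndarray:
        return self.maxs - self.mins


def min_max_fit(values: np.ndarray, groups: Sequence[str]) -> MinMaxParams:
    """Fit per-score-type minima/maxima.

    ``values`` is (n_samples, n_columns); ``groups`` assigns each column
    to a score type and min/max are pooled within a type. NaN entries
    (padded positions) are ignored. A constant type gets span 0 and a
    warning; such columns later normalize to 0.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != len(groups):
        raise EncodingError("values shape inconsistent with column groups")
    names = list(dict.fromkeys(groups))
    mins, maxs = [], []
    for g in names:
        cols = [j for j, gg in enumerate(groups) if gg == g]
        block = values[:, cols]
        finite = block[np.isfinite(block)]
        if finite.size < 2 or np.unique(finite).size < 2:
            warnings.warn(
                f"min-max fit: score type {g!r} is constant; it will map to 0",
                stacklevel=2,
            )
            v = finite[0] if finite.size else 0.0
            mins.append(v)
            maxs.append(v)
        else:
            mins.append(finite.min())
            maxs.append(finite.max())
    return MinMaxParams(tuple(names), np.asarray(mins), np.asarray(maxs))


def min_max_apply(
    values: np.ndarray,
    params: MinMaxParams,
    groups: Sequence[str],
    clip: bool = False,
) -> np.ndarray:
    """Rescale each column to [0,1] using its score type's fitted range.

    ``clip`` bounds out-of-range values (prediction time, when a score
    may exceed the training range). NaN entries map to 0.
    """
    if params is None:
        raise EncodingError("min-max params not fitted; call min_max_fit first")
    values = np.asarray(values, dtype=float)
    out = np.zeros_like(values)
    lookup = {g: i for i, g in enumerate(params.groups)}
    for j, g in enumerate(groups):
        if g not in lookup:
            raise EncodingError(f"score type {g!r} absent from fitted params")
        i = lookup[g]
        span = params.maxs[i] - params.mins[i]
        col = values[:, j]
        if span == 0:
            res = np.zeros_like(col)
        else:
            res = (col - params.mins[i]) / span
            if clip:
                res = np.clip(res, 0.0, 1.0)
        res = np.where(np.isfinite(col), res, 0.0)
        out[:, j] = res
    return out


# ---------------------------------------------------------------------------
# assembly


@dataclass
class FeatureBlock:
    """One named feature cluster over a set of motifs."""

    cluster_name: str
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise EncodingError(
                f"{self.cluster_name}: values shape {self.values.shape} does not "
                f"match {len(self.feature_names)} feature names"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise EncodingError(f"{self.cluster_name}: duplicate feature names")
        prefix = self.cluster_name + "."
        if not all(n.startswith(prefix) for n in self.feature_names):
            raise EncodingError(
                f"{self.cluster_name}: feature names must be prefixed {prefix!r}"
            )

    @property
    def dimension(self) -> int:
        return self.values.shape[1]


@dataclass
class FeatureMatrix:
    """Column-wise assembly of feature blocks over the same motifs."""

    sample_ids: list[str]
    blocks: list[FeatureBlock]
    acc_norm: MinMaxParams | None = None

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        for b in self.blocks:
            if b.values.shape[0] != n:
                raise EncodingError(
                    f"block {b.cluster_name} has {b.values.shape[0]} rows, "
                    f"expected {n}"
                )
        names = self.feature_names
        if len(set(names)) != len(names):
            raise EncodingError("duplicate column names across blocks")

    @property
    def feature_names(self) -> list[str]:
        return [n for b in self.blocks for n in b.feature_names]

    @property
    def values(self) -> np.ndarray:
        return np.hstack([b.values for b in self.blocks])

    @property
    def n_features(self) -> int:
        return sum(b.dimension for b in self.blocks)

    def block(self, cluster_name: str) -> FeatureBlock:
        for b in self.blocks:
            if b.cluster_name == cluster_name:
                return b
        raise KeyError(cluster_name)

    def cluster_names(self) -> list[str]:
        return [b.cluster_name for b in self.blocks]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.feature_names)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")


def assemble_feature_matrix(
    dataset: MotifDataset,
    blocks: Sequence[str] | None = None,
    providers=None,
    config: EncoderConfig | None = None,
    acc_norm: MinMaxParams | None = None,
) -> FeatureMatrix:
    """Encode every motif and assemble the requested blocks.

    ``blocks`` defaults to all nine clusters; order is always the fixed
    :data:`CLUSTER_ORDER`. ``providers`` must supply
    ``get(protein_id) -> (StructuralAnnotation, PSSMProfile)`` for the
    PSSM and structural clusters. When the ACC block is requested and
    ``acc_norm`` is None, min-max parameters are fitted on this dataset
    (training); pass the stored parameters at prediction time.
    """
    config = config or EncoderConfig()
    requested = list(CLUSTER_ORDER) if blocks is None else list(blocks)
    unknown = [b for b in requested if b not in CLUSTER_ORDER]
    if unknown:
        raise EncodingError(f"unknown feature cluster(s): {unknown}")
    ordered = [c for c in CLUSTER_ORDER if c in requested]
    if not len(dataset):
        raise EncodingError("empty dataset")

    needs_profile = "PSSM" in ordered
    needs_annotation = any(c in ordered for c in STRUCTURAL_CLUSTERS)
    ann_cache: dict[str, tuple[StructuralAnnotation, PSSMProfile]] = {}
    if needs_profile or needs_annotation:
        if providers is None:
            raise EncodingError(
                "structural/PSSM clusters requested but no provider given; "
                f"missing for motifs: {dataset.sample_ids[:5]} ..."
            )
        for m in dataset:
            if m.protein_id not in ann_cache:
                ann_cache[m.protein_id] = providers.get(m.protein_id)

    flank = dataset[0].flank
    table = load_aaindex_table() if "AAindex" in ordered else None
    if table is not None and config.aaindex_ids is not None:
        table = table.select(list(config.aaindex_ids))

    encoders: dict[str, Callable[[Motif], np.ndarray]] = {
        "AAC": encode_aac,
        "CKSAAP": lambda m: encode_cksaap(m, config.k_max),
        "BLOSUM62": encode_blosum62,
        "PSSM": lambda m: encode_pssm(
            m, ann_cache[m.protein_id][1], config.pssm_width,
            config.pssm_drop_terminal,
        ),
        "AAindex": lambda m: encode_aaindex(m, table),
        "BINARY": encode_binary,
        "DISOPRED": lambda m: encode_disorder(m, ann_cache[m.protein_id][0]),
        "PSIPRED": lambda m: encode_secondary_structure(
            m, ann_cache[m.protein_id][0]
        ),
        "ACC": lambda m: encode_surface_accessibility_raw(
            m, ann_cache[m.protein_id][0]
        ),
    }
    namers: dict[str, Callable[[], list[str]]] = {
        "AAC": aac_feature_names,
        "CKSAAP": lambda: cksaap_feature_names(config.k_max),
        "BLOSUM62": lambda: blosum62_feature_names(flank),
        "PSSM": lambda: pssm_feature_names(
            flank, config.pssm_width, config.pssm_drop_terminal
        ),
        "AAindex": lambda: aaindex_feature_names(table, flank),
        "BINARY": lambda: binary_feature_names(flank),
        "DISOPRED": lambda: disorder_feature_names(flank),
        "PSIPRED": lambda: psipred_feature_names(flank),
        "ACC": lambda: acc_feature_names(flank),
    }

    out_blocks: list[FeatureBlock] = []
    fitted_norm = acc_norm
    for cluster in ordered:
        rows = np.vstack([encoders[cluster](m) for m in dataset])
        names = namers[cluster]()
        if cluster == "ACC":
            groups = [n.rsplit(".", 1)[1] for n in names]
            if fitted_norm is None:
                fitted_norm = min_max_fit(rows, groups)
                rows = min_max_apply(rows, fitted_norm, groups, clip=False)
            else:
                rows = min_max_apply(rows, fitted_norm, groups, clip=True)
        out_blocks.append(FeatureBlock(cluster, names, rows))
    return FeatureMatrix(dataset.sample_ids, out_blocks, acc_norm=fitted_norm)
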