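"""Synthetic motif datasets with the statistical structure of real
sulphenylation data.

Real sulphenylated cysteines show characteristic flank composition:
leucine, lysine, glutamate and aspartate are over-represented around
the modified cysteine, while cysteine, serine and phenylalanine are
under-represented. The generator reproduces exactly that structure:
negative motifs draw every flank residue from a background distribution
(uniform over the 20 amino acids by default); positive motifs draw from
the background tilted by per-residue log-odds shifts. Class-conditional
pseudo-structural annotations (disorder / accessibility means shifted
for positives) and pseudo conservation profiles derived from the
motif's own residues complete the picture, so the whole pipeline —
encoders, selection, stacking, evaluation — runs end to end with no
external predictor.

What this emulates and what it does not: each synthetic "protein" is a
single 21-residue window, positions are exchangeable within the flank,
and the conservation profile carries class signal only through sequence
composition. Real proteins have positional structure, homology and
annotation noise that this generator deliberately omits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS
from .motif_io import Motif, MotifDataset
from .structural import (
    PSSM_COLUMN_ORDER,
    PSSMProfile,
    SS_CLASSES,
    StructuralAnnotation,
)

#: Default flank enrichment (log-odds shifts, nats) for positive motifs.
DEFAULT_ENRICHMENT: dict[str, float] = {
    "L": 1.0, "K": 1.0, "E": 1.0, "D": 1.0,
    "C": -1.0, "S": -1.0, "F": -1.0,
}


def strong_enrichment() -> dict[str, float]:
    """A strong-signal setting: 2-nat shifts on the same residues."""
    return {r: 2.0 * s for r, s in DEFAULT_ENRICHMENT.items()}


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    ``enrichment`` maps residues to log-odds shifts applied at every
    flank position of positive motifs; ``structural_effect`` shifts the
    disorder / accessibility means of positives (0 = no structural
    signal). ``background`` defaults to uniform over the 20 amino acids.
    """

    n_pos: int = 500
    n_neg: int = 500
    enrichment: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENRICHMENT)
    )
    structural_effect: float = 0.3
    seed: int = 0
    flank: int = 10
    background: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_pos < 10 or self.n_neg < 10:
            raise ValueError("n_pos and n_neg must both be >= 10")
        bad = set(self.enrichment) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"enrichment for unknown residue(s): {sorted(bad)}")
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (20,) or np.any(bg < 0) or bg.sum() <= 0:
                raise ValueError("background must be 20 non-negative weights")

    def background_probs(self) -> np.ndarray:
        if self.background is None:
            return np.full(20, 1.0 / 20.0)
        bg = np.asarray(self.background, dtype=float)
        return bg / bg.sum()

    def positive_probs(self) -> np.ndarray:
        """Background tilted by the enrichment shifts (renormalized)."""
        logp = np.log(np.maximum(self.background_probs(), 1e-300))
        for res, shift in self.enrichment.items():
            logp[AMINO_ACIDS.index(res)] += shift
        p = np.exp(logp - logp.max())
        p /= p.sum()
        if np.any(p == 0) or not np.all(np.isfinite(p)):
            raise ValueError("degenerate tilted residue distribution")
        return p


class DictProviderStore:
    """In-memory annotation store with the provider ``get`` interface."""

    def __init__(self):
        self._data: dict[str, tuple[StructuralAnnotation, PSSMProfile]] = {}

    def put(self, protein_id, annotation, profile) -> None:
        self._data[protein_id] = (annotation, profile)

    def get(self, protein_id: str) -> tuple[StructuralAnnotation, PSSMProfile]:
        if protein_id not in self._data:
            raise KeyError(f"no annotation for {protein_id!r}")
        return self._data[protein_id]

    def protein_ids(self) -> list[str]:
        return list(self._data)


def _pseudo_annotation(
    rng: np.random.Generator, protein_id: str, sequence: str,
    positive: bool, effect: float,
) -> tuple[StructuralAnnotation, PSSMProfile]:
    n = len(sequence)
    shift = effect if positive else 0.0
    disorder = np.clip(rng.normal(0.30 + shift, 0.12, size=n), 0.0, 1.0)
    # Secondary structure carries no class signal.
    raw = rng.gamma(2.0, 1.0, size=(n, 3))
    ss_probs = raw / raw.sum(axis=1, keepdims=True)
    ss_class = np.array([SS_CLASSES[i] for i in np.argmax(ss_probs, axis=1)])
    rsa = np.clip(rng.normal(0.40 + 0.5 * shift, 0.15, size=n), 0.0, 1.0)
    acc = np.column_stack([
        (rsa > 0.5).astype(float),          # buried/exposed flag
        rsa,                                # relative accessibility
        rsa * 200.0,                        # absolute accessibility
        rng.normal(shift, 1.0, size=n),     # Z-fit
        ss_probs,                           # p-helix, p-strand, p-coil
    ])
    # Conservation profile from the motif's own residues plus noise, so
    # the PSSM block carries class signal only through composition.
    log_odds = np.empty((n, 20))
    for i, res in enumerate(sequence):
        for j, col in enumerate(PSSM_COLUMN_ORDER):
            base = 6.0 if res == col else -2.0
            log_odds[i, j] = base + rng.integers(-2, 3)
    info = rng.uniform(0.0, 2.0, size=n)
    ann = StructuralAnnotation(protein_id, disorder, ss_class, ss_probs, acc)
    profile = PSSMProfile(protein_id, log_odds, info, residues=sequence)
    return ann, profile


def generate_dataset(
    config: SynthConfig,
) -> tuple[MotifDataset, DictProviderStore, dict[str, str]]:
    """Draw a labelled synthetic dataset, fully reproducible from seed.

    Each motif is hosted by its own 21-residue synthetic protein
    (central cysteine at position ``flank + 1``). Returns the dataset,
    an annotation store usable as an encoder provider, and the
    ``protein_id -> sequence`` map (for FASTA export).
    """
    rng = np.random.default_rng(config.seed)
    aa = np.array(list(AMINO_ACIDS))
    p_neg = config.background_probs()
    p_pos = config.positive_probs()
    flank = config.flank
    w = 2 * flank + 1

    motifs: list[Motif] = []
    store = DictProviderStore()
    sequences: dict[str, str] = {}
    plan = [("positive", p_pos, config.n_pos), ("negative", p_neg, config.n_neg)]
    for label, probs, count in plan:
        tag = "P" if label == "positive" else "N"
        for i in range(count):
            flanks = rng.choice(aa, size=w - 1, p=probs)
            seq = "".join(flanks[:flank]) + "C" + "".join(flanks[flank:])
            pid = f"SYN{tag}{i + 1:05d}"
            motif = Motif(pid, flank + 1, seq, label)
            motifs.append(motif)
            sequences[pid] = seq
            store.put(
                pid,
                *_pseudo_annotation(
                    rng, pid, seq, label == "positive", config.structural_effect
                ),
            )
    return MotifDataset(motifs), store, sequences


def shuffle_labels(dataset: MotifDataset, seed: int = 0) -> MotifDataset:
    """Reassign labels independently of the motifs (null-signal control).

    The reassignment is a *stratified* (balanced) permutation: each
    original class contributes to the new "positive" label exactly in
    proportion to its size, so the new labels carry zero empirical
    association with the original ones, not merely zero expected
    association. An unrestricted permutation leaves a residual
    association of order ±1/sqrt(n); because rank statistics such as
    AUC are scale-invariant, models trained on such labels amplify that
    residual into held-out AUCs far from 0.5 whenever the features
    separate the original classes well, which would defeat the purpose
    of the control. Label counts per class are preserved exactly.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(dataset.labels)
    classes = sorted(set(labels))
    n = len(labels)
    counts = {c: int((labels == c).sum()) for c in classes}
    # Allocation[orig][new]: a contingency table with row sums equal to
    # the class sizes and column sums equal to the label counts, as
    # close to the independence table counts[o] * counts[c] / n as
    # integer rounding allows (floor, then distribute the remainder by
    # largest fractional part subject to the remaining margins).
    base = {o: {c: 0 for c in classes} for o in classes}
    fracs = []
    for o in classes:
        for c in classes:
            exact = counts[o] * counts[c] / n
            base[o][c] = int(exact)
            fracs.append((exact - int(exact), o, c))
    row_def = {o: counts[o] - sum(base[o].values()) for o in classes}
    col_def = {c: counts[c] - sum(base[o][c] for o in classes)
               for c in classes}
    for _frac, o, c in sorted(fracs, reverse=True):
        if row_def[o] > 0 and col_def[c] > 0:
            base[o][c] += 1
            row_def[o] -= 1
            col_def[c] -= 1
    for o in classes:  # any residue after the greedy pass
        while row_def[o] > 0:
            c = next(c for c in classes if col_def[c] > 0)
            base[o][c] += 1
            row_def[o] -= 1
            col_def[c] -= 1
    new_labels = np.empty(n, dtype=labels.dtype)
    for orig in classes:
        idx = rng.permutation(np.nonzero(labels == orig)[0])
        start = 0
        for new in classes:
            m = base[orig][new]
            new_labels[idx[start:start + m]] = new
            start += m
    return MotifDataset(
        [
            Motif(m.protein_id, m.position, m.sequence, str(new_labels[i]))
            for i, m in enumerate(dataset)
        ]
    )


def position_enrichment_table(dataset: MotifDataset) -> pd.DataFrame:
    """Per-position, per-residue log-odds of positives vs negatives.

    ``log((f_pos + eps_pos) / (f_neg + eps_neg))`` with a 0.5/n
    pseudo-count per class. Rows are signed window offsets; the central
    position (all cysteine by construction) is reported as NaN.
    """
    counts = dataset.label_counts()
    n_pos, n_neg = counts["positive"], counts["negative"]
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    w = len(dataset[0].sequence)
    flank = w // 2
    offsets = list(range(-flank, flank + 1))
    table = np.full((w, 20), np.nan)
    for pi, off in enumerate(offsets):
        if off == 0:
            continue
        fpos = np.zeros(20)
        fneg = np.zeros(20)
        for m in dataset:
            ch = m.sequence[pi]
            if ch not in AMINO_ACIDS:
                continue
            if m.label == "positive":
                fpos[AMINO_ACIDS.index(ch)] += 1
            elif m.label == "negative":
                fneg[AMINO_ACIDS.index(ch)] += 1
        fpos = fpos / n_pos + 0.5 / n_pos
        fneg = fneg / n_neg + 0.5 / n_neg
        table[pi] = np.log(fpos / fneg)
    return pd.DataFrame(table, index=offsets, columns=list(AMINO_ACIDS))
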