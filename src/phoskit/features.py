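"""Feature families for phosphosite classification.

Three families make up the 28-dimensional feature vector of a candidate
site:

* **KNN scores** (5) — for neighborhood fractions 0.25/0.5/1/2/4% of the
  training set, the fraction of phosphorylated peptides among the query
  window's nearest training windows, nearness measured by summed
  BLOSUM62 substitution scores over the aligned window positions.
* **Disorder scores** (3) — mean per-residue intrinsic-disorder score
  over centered windows of 1, 5 and 13 residues.
* **Amino-acid frequencies** (20) — normalized residue counts over the
  13-residue window, pads and X excluded.

Disorder scores may come from an external predictor (imported TSV) or
from the built-in stand-in: a published residue-level disorder
propensity scale, smoothed by a centered moving average and min-max
mapped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .io import AMINO_ACIDS, PAD, PeptideWindow, ProteinRecord

#: neighborhood sizes as fractions of the training set
KNN_FRACTIONS = (0.0025, 0.005, 0.01, 0.02, 0.04)
#: disorder averaging window lengths (residues)
DISORDER_WINDOWS = (1, 5, 13)
N_FEATURES = len(KNN_FRACTIONS) + len(DISORDER_WINDOWS) + 20

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_NULL = 20  # encoding for pad / X / anything unknown: scores 0 everywhere


def _blosum62_matrix() -> np.ndarray:
    """21x21 integer matrix: BLOSUM62 over the 20 amino acids, 0 for pad/X."""
    blosum = substitution_matrices.load("BLOSUM62")
    m = np.zeros((21, 21), dtype=np.int32)
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            m[_AA_INDEX[a], _AA_INDEX[b]] = int(blosum[a, b])
    return m


BLOSUM62 = _blosum62_matrix()


def encode_windows(flanks: Sequence[str]) -> np.ndarray:
    """Encode equal-length windows as an (n, L) int array; pad/X -> 20."""
    lengths = {len(f) for f in flanks}
    if len(lengths) > 1:
        raise ValueError("windows must share a single length")
    n, L = len(flanks), lengths.pop() if lengths else 0
    arr = np.full((n, L), _NULL, dtype=np.int8)
    for i, f in enumerate(flanks):
        for j, c in enumerate(f):
            arr[i, j] = _AA_INDEX.get(c, _NULL)
    return arr


def blosum_similarity(flank_a: str, flank_b: str) -> int:
    """Summed BLOSUM62 score over positions; pad or X contributes 0."""
    if len(flank_a) != len(flank_b):
        raise ValueError("windows must have equal length")
    enc = encode_windows([flank_a, flank_b])
    return int(BLOSUM62[enc[0], enc[1]].sum())


def similarity_matrix(queries: np.ndarray, training: np.ndarray) -> np.ndarray:
    """(n_query, n_train) summed BLOSUM62 similarities for encoded windows."""
    n_q, L = queries.shape
    sim = np.zeros((n_q, training.shape[0]), dtype=np.int32)
    for j in range(L):
        sim += BLOSUM62[np.ix_(queries[:, j], training[:, j])]
    return sim


def neighborhood_sizes(n_training: int,
                       fractions: Sequence[float] = KNN_FRACTIONS) -> list[int]:
    """k = max(1, round-half-up(f * N)) per fraction."""
    return [max(1, int(np.floor(f * n_training + 0.5))) for f in fractions]


def knn_scores(query: PeptideWindow,
               training_windows: Sequence[PeptideWindow],
               fractions: Sequence[float] = KNN_FRACTIONS,
               exclude_self: bool = False) -> np.ndarray:
    """Positive-neighbor fractions for one query window.

    For each fraction f, the k = max(1, round(f*N)) most similar
    training windows are taken (ties broken by training-set order) and
    the score is the fraction of positives among them.  With
    ``exclude_self`` a training window matching the query's
    (protein_id, position) is removed before ranking (leave-one-out).
    """
    return knn_scores_batch([query], training_windows, fractions,
                            exclude_self=exclude_self)[0]


def knn_scores_batch(queries: Sequence[PeptideWindow],
                     training_windows: Sequence[PeptideWindow],
                     fractions: Sequence[float] = KNN_FRACTIONS,
                     exclude_self: bool = False) -> np.ndarray:
    """Vectorized :func:`knn_scores` over many queries -> (n, len(fractions))."""
    if len(training_windows) == 0:
        raise ValueError("training set must be non-empty")
    t_enc = encode_windows([w.flank for w in training_windows])
    q_enc = encode_windows([w.flank for w in queries])
    if q_enc.shape[1] != t_enc.shape[1]:
        raise ValueError("query and training windows differ in length")
    labels = np.array([w.label == "positive" for w in training_windows])
    sim = similarity_matrix(q_enc, t_enc).astype(np.float64)

    if exclude_self:
        t_keys = {w.key: i for i, w in enumerate(training_windows)}
        for qi, q in enumerate(queries):
            ti = t_keys.get(q.key)
            if ti is not None:
                sim[qi, ti] = -np.inf

    out = np.empty((len(queries), len(fractions)))
    # stable argsort on -sim keeps training order among ties
    order = np.argsort(-sim, axis=1, kind="stable")
    pos_sorted = labels[order]
    # excluded self entries sort last; effective N shrinks by 1 for them
    cum = np.cumsum(pos_sorted, axis=1)
    for fi, f in enumerate(fractions):
        for qi in range(len(queries)):
            n_eff = t_enc.shape[0]
            if exclude_self and np.isneginf(sim[qi]).any():
                n_eff -= 1
            if n_eff < 1:
                raise ValueError("training set empty after self-exclusion")
            k = max(1, int(np.floor(f * n_eff + 0.5)))
            out[qi, fi] = cum[qi, k - 1] / k
    return out


# ---------------------------------------------------------------------------
# Disorder

@dataclass
class DisorderProfile:
    """Per-residue disorder scores in [0, 1] for one protein."""

    protein_id: str
    scores: np.ndarray
    source: str = "builtin"  # or "imported"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise ValueError("scores must be 1-D")
        if ((self.scores < 0) | (self.scores > 1)).any():
            raise ValueError("disorder scores must lie in [0, 1]")


def load_disorder_scale(path: str | Path | None = None) -> dict[str, float]:
    """Load a 20-residue disorder propensity table (residue<TAB>value)."""
    if path is None:
        source = resources.files("phoskit.data").joinpath("disorder_scale.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    scale: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, value = line.split("\t")
        scale[aa] = float(value)
    missing = set(AMINO_ACIDS) - scale.keys()
    if missing:
        raise ValueError(f"disorder scale missing residues {sorted(missing)}")
    return scale


def builtin_disorder_profile(sequence: str,
                             scale: dict[str, float] | None = None,
                             smoothing_window: int = 21,
                             protein_id: str = "") -> DisorderProfile:
    """Stand-in disorder predictor: smoothed propensity, min-max to [0, 1].

    Unknown residues take the scale midpoint.  Smoothing is a centered
    moving average truncated at the termini, so the profile is invariant
    under reversing the sequence and the positions together.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if scale is None:
        scale = _DEFAULT_SCALE
    lo, hi = min(scale.values()), max(scale.values())
    mid = (lo + hi) / 2.0
    raw = np.array([scale.get(c, mid) for c in sequence.upper()])
    half = smoothing_window // 2
    n = len(raw)
    csum = np.concatenate([[0.0], np.cumsum(raw)])
    idx = np.arange(n)
    start = np.maximum(0, idx - half)
    stop = np.minimum(n, idx + half + 1)
    smooth = (csum[stop] - csum[start]) / (stop - start)
    scores = np.clip((smooth - lo) / (hi - lo), 0.0, 1.0)
    return DisorderProfile(protein_id=protein_id, scores=scores,
                           source="builtin")


_DEFAULT_SCALE = load_disorder_scale()


def disorder_features(profile: DisorderProfile, position: int,
                      windows: Sequence[int] = DISORDER_WINDOWS) -> np.ndarray:
    """Mean disorder over centered windows clipped to the sequence bounds."""
    n = len(profile.scores)
    if not 1 <= position <= n:
        raise IndexError(f"position {position} out of range (length {n})")
    i = position - 1
    out = np.empty(len(windows))
    for wi, w in enumerate(windows):
        half = w // 2
        out[wi] = profile.scores[max(0, i - half):min(n, i + half + 1)].mean()
    return out


# ---------------------------------------------------------------------------
# Composition

def aa_frequency(window: str | PeptideWindow) -> np.ndarray:
    """20-vector of residue frequencies over real (non-pad, non-X) residues."""
    flank = window.flank if isinstance(window, PeptideWindow) else window
    counts = np.zeros(20)
    total = 0
    for c in flank:
        i = _AA_INDEX.get(c)
        if i is not None:
            counts[i] += 1
            total += 1
    if total == 0:
        raise ValueError("window contains no real residues")
    return counts / total


# ---------------------------------------------------------------------------
# Assembly

def featurize(window: PeptideWindow,
              training_windows: Sequence[PeptideWindow],
              disorder_profile: DisorderProfile,
              fractions: Sequence[float] = KNN_FRACTIONS,
              disorder_windows: Sequence[int] = DISORDER_WINDOWS,
              exclude_self: bool = False) -> np.ndarray:
    """28-vector: KNN (ascending fraction) + disorder (ascending window) + AA freq."""
    return np.concatenate([
        knn_scores(window, training_windows, fractions, exclude_self),
        disorder_features(disorder_profile, window.position, disorder_windows),
        aa_frequency(window),
    ])


def featurize_batch(windows: Sequence[PeptideWindow],
                    training_windows: Sequence[PeptideWindow],
                    profiles: dict[str, DisorderProfile],
                    fractions: Sequence[float] = KNN_FRACTIONS,
                    disorder_windows: Sequence[int] = DISORDER_WINDOWS,
                    exclude_self: bool = False) -> np.ndarray:
    """Feature matrix (n_windows, 28); ``profiles`` keyed by protein id."""
    knn = knn_scores_batch(windows, training_windows, fractions, exclude_self)
    rest = np.empty((len(windows), len(disorder_windows) + 20))
    for i, w in enumerate(windows):
        rest[i, :len(disorder_windows)] = disorder_features(
            profiles[w.protein_id], w.position, disorder_windows)
        rest[i, len(disorder_windows):] = aa_frequency(w)
    return np.hstack([knn, rest])


def profiles_for_records(records, scale: dict[str, float] | None = None,
                         imported: dict[str, dict[int, float]] | None = None,
                         ) -> dict[str, DisorderProfile]:
    """Disorder profiles for every record: imported scores where given,
    the built-in stand-in otherwise."""
    out: dict[str, DisorderProfile] = {}
    for r in records:
        if imported and r.id in imported:
            per_pos = imported[r.id]
            scores = np.array([per_pos.get(p, 0.0)
                               for p in range(1, len(r.sequence) + 1)])
            out[r.id] = DisorderProfile(protein_id=r.id, scores=scores,
                                        source="imported")
        else:
            out[r.id] = builtin_disorder_profile(r.sequence, scale,
                                                 protein_id=r.id)
    return out
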