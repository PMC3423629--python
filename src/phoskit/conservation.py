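"""Ortholog-group conservation statistics for predicted phosphosites.

Each ortholog group is a quartet of globally aligned sequences.  An
aligned S/T/Y column is a *center*; a group enters the analysis when at
least one of its four centers is phosphorylated (predicted or
annotated).  Writing n_i for the number of groups with exactly i
phosphorylated centers (i = 1..4, N = sum n_i):

* the **ground probability** that one of the three non-reference
  centers is phosphorylated is p = (n2 + 2 n3 + 3 n4) / (3 N);
* under the binomial null the expected number of groups with i
  phosphorylated centers is N * C(3, i-1) p^(i-1) (1-p)^(4-i);
* the departure from the null is tested with the chi-square statistic
  sum (O_i - E_i)^2 / E_i on 3 degrees of freedom;
* the **conditional transfer probabilities** are
  p2 = p, p3 = (n3 + 2 n4) / (2 (n2 + n3 + n4)), p4 = n4 / (n3 + n4) —
  the chance of one more phosphorylated center among those remaining,
  given 1, 2 or 3 already phosphorylated.

:class:`OrthologConservation` wraps the tallies in a Model/Results pair
with a ``summary()``; the free functions expose each statistic directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .features import _AA_INDEX  # 20-letter alphabet index
from .io import AMINO_ACIDS, PAD, STY, OrthoGroupRecord


class UndefinedStatisticError(ZeroDivisionError):
    """A conditional probability whose denominator is empty."""


# ---------------------------------------------------------------------------
# Column extraction

@dataclass
class CenterColumn:
    """One aligned S/T/Y column of an ortholog quartet."""

    group_id: str
    column: int  # 0-based alignment column
    residues: tuple[str, str, str, str]
    gap_flags: tuple[bool, bool, bool, bool]
    phospho_flags: tuple[bool, bool, bool, bool]
    center_class: str  # ST_pure | Y_pure | other

    @property
    def n_phospho(self) -> int:
        return sum(self.phospho_flags)

    @property
    def n_serine(self) -> int:
        return sum(r == "S" for r in self.residues)


def _classify(residues: Sequence[str]) -> str:
    if all(r in "ST" for r in residues):
        return "ST_pure"
    if all(r == "Y" for r in residues):
        return "Y_pure"
    return "other"


def extract_center_columns(group: OrthoGroupRecord,
                           predictions: Mapping[tuple[str, int], bool],
                           ) -> list[CenterColumn]:
    """One :class:`CenterColumn` per alignment column holding >= 1 S/T/Y.

    ``predictions`` maps (member protein id, 1-based unaligned position)
    to a phosphorylation call; member ids are ``group_id|organism``.  A
    gapped member is never phosphorylated at that column.
    """
    seqs = [s for _, s in group.members]
    ids = [group.member_id(i) for i in range(4)]
    out: list[CenterColumn] = []
    for col in range(group.alignment_length):
        residues = tuple(s[col] for s in seqs)
        if not any(r in STY for r in residues):
            continue
        gaps = tuple(r == PAD for r in residues)
        flags = []
        for m in range(4):
            if gaps[m] or residues[m] not in STY:
                flags.append(False)
                continue
            pos = group.unaligned_position(m, col)
            flags.append(bool(predictions.get((ids[m], pos), False)))
        out.append(CenterColumn(group_id=group.group_id, column=col,
                                residues=residues, gap_flags=gaps,
                                phospho_flags=tuple(flags),
                                center_class=_classify(residues)))
    return out


# ---------------------------------------------------------------------------
# State counts and derived statistics

@dataclass(frozen=True)
class StateCounts:
    """Groups with exactly 1..4 phosphorylated centers, for one class."""

    residue_class: str  # "ST" or "Y"
    n: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if any(x < 0 for x in self.n):
            raise ValueError("counts must be non-negative")

    @property
    def N(self) -> int:
        return sum(self.n)


def tally_states(columns: Sequence[CenterColumn],
                 residue_class: str) -> StateCounts:
    """Count pure-class columns by number of phosphorylated centers.

    Columns with zero phosphorylated centers are excluded (the analysis
    conditions on at least one phosphorylated center).
    """
    wanted = f"{residue_class}_pure"
    n = [0, 0, 0, 0]
    for c in columns:
        if c.center_class != wanted:
            continue
        k = c.n_phospho
        if k >= 1:
            n[k - 1] += 1
    return StateCounts(residue_class=residue_class, n=tuple(n))


def ground_probability(counts: StateCounts) -> float:
    """Mean fraction of phosphorylated non-reference centers,
    p = (n2 + 2 n3 + 3 n4) / (3 N)."""
    if counts.N == 0:
        raise UndefinedStatisticError("no groups tallied")
    n1, n2, n3, n4 = counts.n
    return (n2 + 2 * n3 + 3 * n4) / (3 * counts.N)


def expected_counts(counts: StateCounts, p: float | None = None) -> np.ndarray:
    """Binomial-null expectations E_i = N C(3, i-1) p^(i-1) (1-p)^(4-i)."""
    if p is None:
        p = ground_probability(counts)
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    i = np.arange(4)
    return counts.N * sps.binom.pmf(i, 3, p)


def chi_square(observed: Sequence[float],
               expected: Sequence[float]) -> tuple[float, float]:
    """Chi-square statistic sum (O-E)^2/E and its upper-tail p on 3 df."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != (4,) or expected.shape != (4,):
        raise ValueError("need the four state counts")
    if (expected <= 0).any():
        raise ValueError("expected counts must all be positive")
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(sps.chi2.sf(chi2, df=3))


def conditional_probabilities(counts: StateCounts,
                              p3_method: str = "remaining",
                              ) -> tuple[float, float, float]:
    """Transfer probabilities (p2, p3, p4) for the 2nd/3rd/4th site.

    ``p3_method="remaining"`` (default) counts additional phosphorylated
    centers among the two remaining after the second:
    p3 = (n3 + 2 n4) / (2 (n2 + n3 + n4)).  ``p3_method="upper"``
    restricts the denominator to groups that did gain a third site:
    p3 = (n3 + 2 n4) / (2 (n3 + n4)).
    """
    n1, n2, n3, n4 = counts.n
    p2 = ground_probability(counts)
    if p3_method == "remaining":
        denom3 = 2 * (n2 + n3 + n4)
    elif p3_method == "upper":
        denom3 = 2 * (n3 + n4)
    else:
        raise ValueError("p3_method must be 'remaining' or 'upper'")
    if denom3 == 0:
        raise UndefinedStatisticError("p3 undefined: no groups with >= 2 sites")
    p3 = (n3 + 2 * n4) / denom3
    if n3 + n4 == 0:
        raise UndefinedStatisticError("p4 undefined: no groups with >= 3 sites")
    p4 = n4 / (n3 + n4)
    return p2, p3, p4


# ---------------------------------------------------------------------------
# Model / Results wrapper

class OrthologConservation:
    """Conservation analysis of one residue class' state counts.

    Construct from a :class:`StateCounts` (or from extracted columns via
    :meth:`from_columns`); :meth:`fit` computes the binomial null, the
    chi-square test and the conditional transfer probabilities.
    """

    def __init__(self, counts: StateCounts):
        if counts.N < 1:
            raise ValueError("need at least one tallied group")
        self.counts = counts

    @classmethod
    def from_columns(cls, columns: Sequence[CenterColumn],
                     residue_class: str) -> "OrthologConservation":
        return cls(tally_states(columns, residue_class))

    def fit(self, p: float | None = None,
            p3_method: str = "remaining") -> "ConservationResults":
        """Derive all statistics; ``p`` overrides the estimated ground
        probability (e.g. a known simulation truth)."""
        ground = ground_probability(self.counts)
        p_used = ground if p is None else float(p)
        expected = expected_counts(self.counts, p_used)
        chi2, pvalue = chi_square(self.counts.n, expected)
        conditional = conditional_probabilities(self.counts, p3_method)
        return ConservationResults(self.counts, p_used, expected,
                                   chi2, pvalue, conditional)


@dataclass
class ConservationResults:
    """Fitted conservation statistics for one residue class."""

    counts: StateCounts
    p: float
    expected: np.ndarray
    chi2: float
    pvalue: float
    conditional: tuple[float, float, float]
    df: int = 3

    def summary(self) -> str:
        n = self.counts.n
        e = self.expected
        lines = [
            f"Ortholog conservation — {self.counts.residue_class} class",
            "=" * 44,
            "phosphorylated centers      1       2       3       4   total",
            "observed groups        " + "".join(f"{x:8d}" for x in n)
            + f"{self.counts.N:8d}",
            "expected (binomial)    " + "".join(f"{x:8.1f}" for x in e)
            + f"{e.sum():8.1f}",
            f"ground probability p   {self.p:.3f}",
            f"chi-square ({self.df} df)      {self.chi2:.3f}   "
            f"p-value {self.pvalue:.3g}",
            "conditional transfer   p2={:.3f}  p3={:.3f}  p4={:.3f}".format(
                *self.conditional),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"residue_class": self.counts.residue_class,
                "observed": list(self.counts.n), "N": self.counts.N,
                "p": self.p, "expected": self.expected.tolist(),
                "chi2": self.chi2, "pvalue": self.pvalue, "df": self.df,
                "conditional": {"p2": self.conditional[0],
                                "p3": self.conditional[1],
                                "p4": self.conditional[2]}}


# ---------------------------------------------------------------------------
# Composition of S/T centers (Table-3 style)

COMPOSITION_CLASSES = ("4T", "1S3T", "2S2T", "3S1T", "4S")


@dataclass
class CompositionTable:
    """S/T make-up of center quartets, stratified by phosphorylation."""

    counts: dict[str, dict[str, int]]       # stratum -> class -> count
    frequencies: dict[str, dict[str, float]]  # percentages

    def __getitem__(self, stratum: str) -> dict[str, float]:
        return self.frequencies[stratum]


def composition_table(columns: Sequence[CenterColumn]) -> CompositionTable:
    """Count 4T/1S3T/2S2T/3S1T/4S among ST-pure columns, split into the
    non-phosphorylated (0 flags) and fully conserved (4 flags) strata."""
    import warnings

    counts = {"non_phosphorylated": dict.fromkeys(COMPOSITION_CLASSES, 0),
              "fully_conserved": dict.fromkeys(COMPOSITION_CLASSES, 0)}
    for c in columns:
        if c.center_class != "ST_pure":
            continue
        if c.n_phospho == 0:
            stratum = "non_phosphorylated"
        elif c.n_phospho == 4:
            stratum = "fully_conserved"
        else:
            continue
        counts[stratum][COMPOSITION_CLASSES[c.n_serine]] += 1
    freqs: dict[str, dict[str, float]] = {}
    for stratum, table in counts.items():
        total = sum(table.values())
        if total == 0:
            warnings.warn(f"empty stratum {stratum!r}", stacklevel=2)
            freqs[stratum] = dict.fromkeys(COMPOSITION_CLASSES, 0.0)
        else:
            freqs[stratum] = {k: 100.0 * v / total for k, v in table.items()}
    return CompositionTable(counts=counts, frequencies=freqs)


def composition_from_counts(non_phospho: Sequence[int],
                            fully_conserved: Sequence[int]) -> CompositionTable:
    """Build the table directly from per-class counts (4T..4S order)."""
    counts = {"non_phosphorylated": dict(zip(COMPOSITION_CLASSES, non_phospho)),
              "fully_conserved": dict(zip(COMPOSITION_CLASSES, fully_conserved))}
    freqs = {}
    for stratum, table in counts.items():
        total = sum(table.values())
        freqs[stratum] = {k: 100.0 * v / total for k, v in table.items()}
    return CompositionTable(counts=counts, frequencies=freqs)


# ---------------------------------------------------------------------------
# Flanking similarity, disorder distributions, PFM

@dataclass
class SimilarityProfile:
    """Pairwise-identity fraction by flanking offset, across groups."""

    offsets: np.ndarray  # -flank..-1, +1..+flank
    mean: np.ndarray
    sd: np.ndarray
    n_groups: int


def similarity_profile(columns: Sequence[CenterColumn],
                       groups: Mapping[str, OrthoGroupRecord],
                       flank: int = 5,
                       stratum: str = "fully_conserved") -> SimilarityProfile:
    """Mean pairwise identity at each flanking alignment offset.

    For each column in the stratum ("fully_conserved": 4 flags,
    "non_phosphorylated": 0 flags) and each offset in ±1..±flank, the
    C(4,2) = 6 member pairs are compared at that alignment column; a
    pair counts 1 when the symbols match and neither is a gap (a gap is
    a mismatch).  Offsets outside the alignment contribute all-mismatch.
    """
    want = {"fully_conserved": 4, "non_phosphorylated": 0}[stratum]
    offsets = np.array([o for o in range(-flank, flank + 1) if o != 0])
    rows = []
    for c in columns:
        if c.n_phospho != want:
            continue
        g = groups[c.group_id]
        seqs = [s for _, s in g.members]
        L = g.alignment_length
        row = np.zeros(len(offsets))
        for oi, off in enumerate(offsets):
            col = c.column + off
            if not 0 <= col < L:
                continue
            symbols = [s[col] for s in seqs]
            matches = sum(1 for a in range(4) for b in range(a + 1, 4)
                          if symbols[a] == symbols[b] and symbols[a] != PAD)
            row[oi] = matches / 6.0
        rows.append(row)
    if not rows:
        arr = np.zeros((0, len(offsets)))
    else:
        arr = np.vstack(rows)
    mean = arr.mean(axis=0) if len(arr) else np.full(len(offsets), np.nan)
    sd = arr.std(axis=0) if len(arr) else np.full(len(offsets), np.nan)
    return SimilarityProfile(offsets=offsets, mean=mean, sd=sd,
                             n_groups=len(rows))


def disorder_histogram(scores: Sequence[float], bins: int = 20,
                       range_: tuple[float, float] = (0.0, 1.0),
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Density-normalized histogram (area 1) of per-site disorder scores."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no scores to histogram")
    density, edges = np.histogram(scores, bins=bins, range=range_,
                                  density=True)
    return density, edges


def disorder_histograms_by_stratum(site_scores: Mapping[str, Sequence[float]],
                                   bins: int = 20) -> dict[str, dict]:
    """Histograms per stratum (e.g. residue type x phospho status)."""
    out = {}
    for name, scores in site_scores.items():
        density, edges = disorder_histogram(scores, bins=bins)
        out[name] = {"density": density, "edges": edges, "n": len(scores)}
    return out


@dataclass
class PositionFrequencyMatrix:
    """Residue counts per flanking position over gap-free quartets."""

    counts: np.ndarray  # (20, 2*flank + 1)
    flank: int
    n_groups: int

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)

    def to_frequencies(self) -> np.ndarray:
        sums = self.counts.sum(axis=0, keepdims=True)
        return np.divide(self.counts, sums, where=sums > 0,
                         out=np.zeros_like(self.counts, dtype=float))


def pfm(columns: Sequence[CenterColumn],
        groups: Mapping[str, OrthoGroupRecord],
        flank: int = 10, gap_free_only: bool = True,
        stratum: str = "fully_conserved") -> PositionFrequencyMatrix:
    """Position frequency matrix over fully conserved centers.

    Groups with any gap (or alignment-boundary overflow) inside the
    ±flank window are excluded entirely when ``gap_free_only``.
    """
    want = {"fully_conserved": 4, "non_phosphorylated": 0}[stratum]
    width = 2 * flank + 1
    counts = np.zeros((20, width), dtype=np.int64)
    n_used = 0
    for c in columns:
        if c.n_phospho != want:
            continue
        g = groups[c.group_id]
        seqs = [s for _, s in g.members]
        L = g.alignment_length
        lo, hi = c.column - flank, c.column + flank
        window_ok = 0 <= lo and hi < L
        if window_ok:
            window = [s[lo:hi + 1] for s in seqs]
            if gap_free_only and any(PAD in w for w in window):
                window_ok = False
        if not window_ok:
            if gap_free_only:
                continue
            window = [("?" * max(0, -lo)) + s[max(0, lo):min(L, hi + 1)]
                      + ("?" * max(0, hi - L + 1)) for s in seqs]
        for w in window:
            for j, aa in enumerate(w):
                idx = _AA_INDEX.get(aa)
                if idx is not None:
                    counts[idx, j] += 1
        n_used += 1
    return PositionFrequencyMatrix(counts=counts, flank=flank, n_groups=n_used)


def pfm_to_tsv(matrix: PositionFrequencyMatrix, path) -> None:
    """Write the PFM as residues x offsets TSV."""
    import pandas as pd

    df = pd.DataFrame(matrix.counts, index=list(AMINO_ACIDS),
                      columns=[str(o) for o in matrix.offsets])
    df.to_csv(path, sep="\t")
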