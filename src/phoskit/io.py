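"""Sequence, annotation and ortholog-group I/O.

Coordinate convention: all site positions are 1-based, inclusive, on the
unaligned protein sequence.  The pad character ``-`` doubles as the
alignment gap character; pads are never counted as residues downstream.
Ambiguous residues (B, Z, U, O, J) are mapped to ``X``; ``X`` is never a
candidate center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "-"
_AMBIGUOUS = str.maketrans({c: "X" for c in "BZUOJ"})

STY = frozenset("STY")
#: residue classes: serine/threonine model vs tyrosine model
RESIDUE_CLASSES = {"ST": frozenset("ST"), "Y": frozenset("Y")}


class FastaParseError(ValueError):
    """Raised on malformed FASTA input, naming the offending line."""


class AnnotationError(ValueError):
    """Raised when site annotation rows contradict the sequences."""


@dataclass
class ProteinRecord:
    """A protein sequence with organism tag and annotated phosphosites.

    ``phosphosites`` holds 1-based positions whose residue must be S, T
    or Y — enforced when annotations are attached.
    """

    id: str
    sequence: str
    organism: str = "unknown"
    phosphosites: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        self.sequence = self.sequence.upper().translate(_AMBIGUOUS)

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"position {position} out of range for {self.id}")
        return self.sequence[position - 1]


@dataclass(frozen=True)
class PeptideWindow:
    """A candidate site: center residue plus symmetric flanking sequence.

    ``flank`` has length ``2h + 1`` with the center at index ``h``
    (0-based); positions beyond the protein termini carry the pad
    character.  ``label`` is one of ``positive`` / ``negative`` /
    ``unknown``.
    """

    protein_id: str
    position: int
    center: str
    flank: str
    label: str = "unknown"

    def __post_init__(self) -> None:
        h = (len(self.flank) - 1) // 2
        if len(self.flank) != 2 * h + 1 or self.flank[h] != self.center:
            raise ValueError("flank must be odd-length and centered on `center`")

    @property
    def half_width(self) -> int:
        return (len(self.flank) - 1) // 2

    @property
    def key(self) -> tuple[str, int]:
        return (self.protein_id, self.position)


@dataclass
class OrthoGroupRecord:
    """Four globally aligned orthologous sequences, one per organism."""

    group_id: str
    members: list[tuple[str, str]]  # (organism, aligned sequence)

    def __post_init__(self) -> None:
        if len(self.members) != 4:
            raise ValueError(f"group {self.group_id}: expected 4 members, "
                             f"got {len(self.members)}")
        lengths = {len(s) for _, s in self.members}
        if len(lengths) != 1:
            raise ValueError(f"group {self.group_id}: aligned lengths differ")
        self.members = [(org, s.upper().translate(_AMBIGUOUS))
                        for org, s in self.members]

    @property
    def alignment_length(self) -> int:
        return len(self.members[0][1])

    def member_id(self, index: int) -> str:
        return f"{self.group_id}|{self.members[index][0]}"

    def unaligned_position(self, member: int, column: int) -> int | None:
        """Map a 0-based alignment column to a 1-based sequence position.

        Returns ``None`` when the member has a gap at the column.
        """
        seq = self.members[member][1]
        if not 0 <= column < len(seq):
            raise IndexError(f"column {column} out of range in {self.group_id}")
        if seq[column] == PAD:
            return None
        return column + 1 - seq.count(PAD, 0, column)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, organism_token: int | None = None,
               token_sep: str = "|") -> list[ProteinRecord]:
    """Read protein FASTA into :class:`ProteinRecord` objects.

    Sequences are uppercased.  When ``organism_token`` is given, the
    organism is parsed as that ``token_sep``-separated field of the
    header id; otherwise the organism is "unknown".
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        first = handle.read(1)
        if first and first not in (">", ";"):
            raise FastaParseError(f"{path}:1: expected '>' header, got {first!r}")
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if rid in seen:
            raise FastaParseError(f"duplicate record id {rid!r} in {path}")
        seen.add(rid)
        organism = "unknown"
        if organism_token is not None:
            parts = rid.split(token_sep)
            if organism_token < len(parts):
                organism = parts[organism_token]
        records.append(ProteinRecord(id=rid, sequence=str(entry.seq),
                                     organism=organism))
    if not records:
        warnings.warn(f"no FASTA records in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path), "fasta")


def read_ortho_groups(path: str | Path) -> list[OrthoGroupRecord]:
    """Read aligned ortholog quartets from FASTA with ``group|organism`` ids."""
    groups: dict[str, list[tuple[str, str]]] = {}
    order: list[str] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        if "|" not in entry.id:
            raise FastaParseError(
                f"ortholog header {entry.id!r} lacks 'group|organism' form")
        gid, organism = entry.id.split("|", 1)
        if gid not in groups:
            groups[gid] = []
            order.append(gid)
        groups[gid].append((organism, str(entry.seq)))
    return [OrthoGroupRecord(group_id=g, members=groups[g]) for g in order]


def write_ortho_groups(groups: Iterable[OrthoGroupRecord],
                       path: str | Path) -> None:
    entries = [SeqRecord(Seq(seq), id=f"{g.group_id}|{org}", description="")
               for g in groups for org, seq in g.members]
    SeqIO.write(entries, str(path), "fasta")


# ---------------------------------------------------------------------------
# Site annotations

def read_site_annotations(path: str | Path,
                          records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Attach phosphosite annotations from a TSV onto ``records``.

    Columns: protein_id, position (1-based), residue, optional source;
    ``#`` comment lines allowed.  Union semantics: a site observed in
    any file is positive, so repeated calls accumulate.  Rows whose
    protein id is unknown are skipped with a warning; positions out of
    range or disagreeing with the sequence raise a single error listing
    all offending rows.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 3:
        raise AnnotationError(f"{path}: expected >= 3 tab-separated columns")
    df = df.iloc[:, :3]
    df.columns = ["protein_id", "position", "residue"]
    by_id = {r.id: r for r in records}
    bad: list[str] = []
    skipped = 0
    for row in df.itertuples(index=False):
        rec = by_id.get(row.protein_id)
        if rec is None:
            skipped += 1
            continue
        pos = int(row.position)
        if not 1 <= pos <= len(rec.sequence):
            bad.append(f"{row.protein_id}:{pos} out of range (len {len(rec.sequence)})")
            continue
        actual = rec.sequence[pos - 1]
        if actual != row.residue.upper():
            bad.append(f"{row.protein_id}:{pos} annotated {row.residue} "
                       f"but sequence has {actual}")
            continue
        if actual not in STY:
            bad.append(f"{row.protein_id}:{pos} residue {actual} is not S/T/Y")
            continue
        rec.phosphosites.add(pos)
    if skipped:
        warnings.warn(f"{skipped} annotation rows for unknown proteins skipped",
                      stacklevel=2)
    if bad:
        raise AnnotationError("bad annotation rows:\n  " + "\n  ".join(bad))
    return list(records)


def write_site_annotations(records: Iterable[ProteinRecord],
                           path: str | Path) -> None:
    rows = [(r.id, p, r.sequence[p - 1])
            for r in records for p in sorted(r.phosphosites)]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_disorder_tsv(path: str | Path) -> dict[str, dict[int, float]]:
    """Read per-residue disorder scores (protein_id, position, score in [0,1])."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["protein_id", "position", "score"],
                     dtype={"protein_id": str})
    out: dict[str, dict[int, float]] = {}
    for row in df.itertuples(index=False):
        s = float(row.score)
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"disorder score {s} outside [0,1] "
                             f"at {row.protein_id}:{row.position}")
        out.setdefault(row.protein_id, {})[int(row.position)] = s
    return out


# ---------------------------------------------------------------------------
# Windows and candidates

def extract_window(record: ProteinRecord, position: int,
                   h: int = 6) -> PeptideWindow:
    """Extract the ``2h+1``-residue window centered at a 1-based S/T/Y position."""
    center = record.residue(position)
    if center not in STY:
        raise ValueError(f"{record.id}:{position} center {center!r} is not S/T/Y")
    seq = record.sequence
    i = position - 1
    left = seq[max(0, i - h):i]
    right = seq[i + 1:i + 1 + h]
    flank = PAD * (h - len(left)) + left + center + right + PAD * (h - len(right))
    label = "positive" if position in record.phosphosites else "negative"
    return PeptideWindow(protein_id=record.id, position=position,
                         center=center, flank=flank, label=label)


def enumerate_candidates(record: ProteinRecord, residue_class: str,
                         h: int = 6) -> list[PeptideWindow]:
    """All windows of the residue class (``ST`` or ``Y``), in sequence order."""
    try:
        accepted = RESIDUE_CLASSES[residue_class]
    except KeyError:
        raise ValueError(f"residue_class must be 'ST' or 'Y', got {residue_class!r}")
    return [extract_window(record, i + 1, h)
            for i, aa in enumerate(record.sequence) if aa in accepted]


# ---------------------------------------------------------------------------
# Redundancy filter

def _global_identity(a: str, b: str) -> float:
    """Identity fraction from a global alignment (match 1 / mismatch 0 / gap -1).

    Identity = exact-match columns divided by min(len(a), len(b)).
    """
    import numpy as np

    n, m = len(a), len(b)
    gap = -1.0
    score = np.zeros((n + 1, m + 1))
    match = np.zeros((n + 1, m + 1), dtype=np.int32)
    score[:, 0] = gap * np.arange(n + 1)
    score[0, :] = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = 1.0 if ai == b[j - 1] else 0.0
            diag = score[i - 1, j - 1] + s
            up = score[i - 1, j] + gap
            left = score[i, j - 1] + gap
            best = max(diag, up, left)
            score[i, j] = best
            if best == diag:
                match[i, j] = match[i - 1, j - 1] + (1 if s == 1.0 else 0)
            elif best == up:
                match[i, j] = match[i - 1, j]
            else:
                match[i, j] = match[i, j - 1]
    return match[n, m] / min(n, m)


def redundancy_filter(records: Sequence[ProteinRecord],
                      identity_threshold: float = 0.5) -> list[ProteinRecord]:
    """Greedy longest-first clustering; keep one representative per cluster.

    Mirrors CD-HIT's 50%-identity redundancy removal: sequences are
    sorted longest first and each is either absorbed by an existing
    representative (pairwise global identity above the threshold) or
    becomes a new representative.  Deterministic; ties in length are
    broken by input order.  Output preserves the original input order.
    """
    if not records:
        raise ValueError("records must be non-empty")
    order = sorted(range(len(records)), key=lambda i: (-len(records[i]), i))
    reps: list[int] = []
    for i in order:
        seq = records[i].sequence
        if not any(_global_identity(seq, records[j].sequence) > identity_threshold
                   for j in reps):
            reps.append(i)
    keep = set(reps)
    return [records[i] for i in range(len(records)) if i in keep]
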