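"""Synthetic phosphoproteomes and ortholog quartets.

The proteome generator emulates the statistical structure the predictor
and the conservation analysis assume about real plant data: protein
sequences whose local composition tracks a smooth latent
intrinsic-disorder process (disorder-prone residues such as S/P/E/K in
high-disorder stretches, aromatics/hydrophobics in ordered ones), with
S/T/Y phosphosites planted through a logistic link whose odds rise with
local disorder and with acidic / proline-directed flanking motifs.

The ortholog generator builds quartets by mutating an ancestor
independently along four branches (no indels by default, so the trivial
alignment is exact).  One reference center is always phosphorylated;
each of the other three centers is phosphorylated with marginal
probability c + (1-c)p via a Bernoulli mixture: with probability c the
whole group is conserved (all centers phosphorylated), otherwise the
three centers are i.i.d. Bernoulli(p).  c = 0 recovers the independent
binomial null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import DisorderProfile
from .io import AMINO_ACIDS, PAD, OrthoGroupRecord, ProteinRecord

# Residue compositions for disordered vs ordered stretches.  Ratios
# follow the familiar ordering of disorder-promoting (P, E, S, K, Q, G)
# vs order-promoting (W, F, Y, I, L, V, M, C) residues.
_DISORDERED_WEIGHTS = {
    "A": 6, "C": 1, "D": 6, "E": 9, "F": 1, "G": 7, "H": 2, "I": 2,
    "K": 8, "L": 3, "M": 1, "N": 4, "P": 9, "Q": 6, "R": 6, "S": 10,
    "T": 6, "V": 3, "W": 0.5, "Y": 1.5,
}
_ORDERED_WEIGHTS = {
    "A": 7, "C": 3, "D": 3, "E": 3, "F": 6, "G": 5, "H": 2, "I": 7,
    "K": 3, "L": 10, "M": 3, "N": 3, "P": 2, "Q": 2, "R": 3, "S": 4,
    "T": 5, "V": 8, "W": 2, "Y": 5,
}


def _normalize(weights: dict[str, float]) -> np.ndarray:
    v = np.array([weights[aa] for aa in AMINO_ACIDS], dtype=float)
    return v / v.sum()


_P_DISORDERED = _normalize(_DISORDERED_WEIGHTS)
_P_ORDERED = _normalize(_ORDERED_WEIGHTS)


@dataclass
class SimulationConfig:
    """Proteome generator settings.

    ``phospho_fraction`` is the marginal phosphorylation probability per
    candidate residue of each type; ``disorder_coupling`` and
    ``motif_log_odds`` act on the logit scale of the planting model.
    """

    seed: int
    n_proteins: int = 120
    length_min: int = 60
    length_mean: int = 300
    length_max: int = 700
    phospho_fraction: dict[str, float] = field(
        default_factory=lambda: {"S": 0.12, "T": 0.08, "Y": 0.05})
    disorder_coupling: float = 10.0
    motif_log_odds: float = 2.5
    disorder_smoothing: int = 15
    organisms: tuple[str, ...] = ("ath",)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for r, f in self.phospho_fraction.items():
            if not 0.0 <= f <= 0.95:
                raise ValueError(
                    f"phospho fraction {f} for {r} infeasible (must be <= 0.95)")
        if not self.length_min <= self.length_mean <= self.length_max:
            raise ValueError("length distribution min <= mean <= max violated")


def _latent_disorder(n: int, smoothing: int, rng: np.random.Generator,
                     ) -> np.ndarray:
    """Smooth latent process on [0,1]: moving-average noise, min-max scaled."""
    raw = rng.uniform(size=n)
    half = smoothing // 2
    csum = np.concatenate([[0.0], np.cumsum(raw)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)
    smooth = (csum[hi] - csum[lo]) / (hi - lo)
    span = smooth.max() - smooth.min()
    if span < 1e-12:
        return np.full(n, 0.5)
    return (smooth - smooth.min()) / span


def _motif_indicator(sequence: str, i: int) -> float:
    """Acidic (D/E at +1..+3) or proline-directed (P at +1) context."""
    right = sequence[i + 1:i + 4]
    if right[:1] == "P":
        return 1.0
    return 1.0 if any(c in "DE" for c in right) else 0.0


def _solve_intercept(raw_logits: np.ndarray, target: float) -> float:
    """Bisection for b0 with mean(sigmoid(b0 + raw)) == target."""
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = (lo + hi) / 2.0
        mean_p = float((1.0 / (1.0 + np.exp(-(mid + raw_logits)))).mean())
        if mean_p < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def simulate_proteome(config: SimulationConfig,
                      ) -> tuple[list[ProteinRecord],
                                 dict[str, DisorderProfile]]:
    """Generate annotated proteins plus their true disorder profiles.

    Returns ``(records, profiles)``; each record's ``phosphosites`` set
    is populated and ``profiles`` maps protein id to the latent disorder
    that actually drove the planting (``source="imported"``, standing in
    for an external disorder predictor that sees the truth).
    """
    rng = np.random.default_rng(config.seed)
    records: list[ProteinRecord] = []
    profiles: dict[str, DisorderProfile] = {}
    aa = np.array(list(AMINO_ACIDS))

    # collect candidates across proteins, then calibrate intercepts per type
    sequences: list[str] = []
    disorders: list[np.ndarray] = []
    for _ in range(config.n_proteins):
        length = int(np.clip(round(rng.normal(config.length_mean,
                                              config.length_mean / 3)),
                             config.length_min, config.length_max))
        d = _latent_disorder(length, config.disorder_smoothing, rng)
        mix = rng.uniform(size=length) < d
        draws_dis = rng.choice(20, size=length, p=_P_DISORDERED)
        draws_ord = rng.choice(20, size=length, p=_P_ORDERED)
        seq = "".join(aa[np.where(mix, draws_dis, draws_ord)])
        sequences.append(seq)
        disorders.append(d)

    cand: dict[str, list[tuple[int, int, float]]] = {"S": [], "T": [], "Y": []}
    for pi, (seq, d) in enumerate(zip(sequences, disorders)):
        for i, c in enumerate(seq):
            if c in "STY":
                raw = (config.disorder_coupling * (d[i] - 0.5)
                       + config.motif_log_odds * _motif_indicator(seq, i))
                cand[c].append((pi, i, raw))

    intercepts = {}
    for r, rows in cand.items():
        if rows:
            raw = np.array([x[2] for x in rows])
            intercepts[r] = _solve_intercept(raw, config.phospho_fraction[r])

    sites: dict[int, set[int]] = {pi: set() for pi in range(len(sequences))}
    for r, rows in cand.items():
        for pi, i, raw in rows:
            prob = 1.0 / (1.0 + np.exp(-(intercepts[r] + raw)))
            if rng.uniform() < prob:
                sites[pi].add(i + 1)

    for pi, (seq, d) in enumerate(zip(sequences, disorders)):
        organism = config.organisms[pi % len(config.organisms)]
        pid = f"syn{config.seed}_{pi:04d}_{organism}"
        rec = ProteinRecord(id=pid, sequence=seq, organism=organism,
                            phosphosites=sites[pi])
        records.append(rec)
        profiles[pid] = DisorderProfile(protein_id=pid, scores=d,
                                        source="imported")
    return records, profiles


# ---------------------------------------------------------------------------
# Ortholog quartets

@dataclass
class OrthoSimConfig:
    """Ortholog-quartet generator settings.

    ``p`` is the ground probability that a non-reference center is
    phosphorylated; ``conservation`` (c) mixes in group-level conserved
    phosphorylation; ``substitution_prob`` applies independently per
    branch and per non-center position.
    """

    seed: int
    n_groups: int = 500
    seq_length: int = 41
    substitution_prob: float = 0.1
    st_fraction: float = 0.75      # share of S/T-centered groups
    serine_bias: float = 0.7       # P(center S | S/T class)
    p: float = 0.331
    conservation: float = 0.0
    gap_prob: float = 0.0
    organisms: tuple[str, ...] = ("ath", "osa", "rco", "ppa")

    def __post_init__(self) -> None:
        for name in ("substitution_prob", "st_fraction", "serine_bias",
                     "p", "conservation", "gap_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.seq_length < 5 or self.seq_length % 2 == 0:
            raise ValueError("seq_length must be odd and >= 5")


def simulate_ortho_groups(config: OrthoSimConfig,
                          ) -> tuple[list[OrthoGroupRecord],
                                     dict[tuple[str, int], bool]]:
    """Generate aligned quartets and their true phosphorylation flags.

    Returns ``(groups, flags)`` where ``flags`` maps
    (``group_id|organism``, 1-based unaligned center position) to True
    for phosphorylated centers — directly consumable by
    :func:`phoskit.conservation.extract_center_columns`.
    """
    rng = np.random.default_rng(config.seed)
    aa = np.array(list(AMINO_ACIDS))
    non_sty = np.array([a for a in AMINO_ACIDS if a not in "STY"])
    center_idx = config.seq_length // 2
    groups: list[OrthoGroupRecord] = []
    flags: dict[tuple[str, int], bool] = {}

    for gi in range(config.n_groups):
        gid = f"og{gi:05d}"
        is_st = rng.uniform() < config.st_fraction
        if is_st:
            center = "S" if rng.uniform() < config.serine_bias else "T"
        else:
            center = "Y"
        # ancestor: STY kept off the flanks so the class of the center
        # column is unambiguous
        ancestor = rng.choice(non_sty, size=config.seq_length)
        ancestor[center_idx] = center

        members: list[tuple[str, str]] = []
        for org in config.organisms:
            seq = ancestor.copy()
            mutate = rng.uniform(size=config.seq_length) < config.substitution_prob
            mutate[center_idx] = False
            n_mut = int(mutate.sum())
            if n_mut:
                seq[mutate] = rng.choice(non_sty, size=n_mut)
            if is_st and rng.uniform() < config.substitution_prob:
                seq[center_idx] = "T" if seq[center_idx] == "S" else "S"
            members.append((org, "".join(seq)))

        if config.gap_prob > 0 and rng.uniform() < config.gap_prob:
            m = int(rng.integers(0, 4))
            side = 1 if rng.uniform() < 0.5 else -1
            off = int(rng.integers(2, min(8, center_idx)))
            col = center_idx + side * off
            org, s = members[m]
            members[m] = (org, s[:col] + PAD + s[col + 1:])

        group = OrthoGroupRecord(group_id=gid, members=members)
        groups.append(group)

        conserved = rng.uniform() < config.conservation
        phospho = [True] + [True if conserved else bool(rng.uniform() < config.p)
                            for _ in range(3)]
        for m, is_p in enumerate(phospho):
            if not is_p:
                continue
            pos = group.unaligned_position(m, center_idx)
            if pos is not None:
                flags[(group.member_id(m), pos)] = True
    return groups, flags
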