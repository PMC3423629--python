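"""Bootstrap-balanced SVM ensemble for phosphosite prediction.

The model follows the statsmodels convention: :class:`PhosphositeModel`
is built from labeled peptide windows (directly or via
:meth:`PhosphositeModel.from_records`), and :meth:`PhosphositeModel.fit`
returns a :class:`PhosphositeResults` object carrying the trained
ensemble, the score -> specificity calibration table, diagnostics and a
``summary()``.

Class imbalance is handled by bootstrap balancing: each of the B base
classifiers is trained on all positives plus an equal-sized random
sample of negatives (drawn without replacement, fresh per classifier).
The aggregated prediction score is the mean of the B decision values.
Stringency thresholds are calibrated on out-of-bag negative scores:
each pool negative is scored only by the classifiers whose bootstrap
sample excluded it, and the stringency-s threshold is the s-quantile
(higher interpolation) of those scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import features as F
from .io import PeptideWindow, ProteinRecord, enumerate_candidates
from .features import DisorderProfile


@dataclass(frozen=True)
class SitePrediction:
    """One scored candidate site at a requested stringency."""

    protein_id: str
    position: int
    residue: str
    score: float
    predicted_specificity: float
    call: bool


class PhosphositeModel:
    """Phosphosite classifier for one residue class (``ST`` or ``Y``).

    Parameters
    ----------
    positives, negatives
        Labeled :class:`~phoskit.io.PeptideWindow` sets.  The negative
        pool may be larger than the positive set; balancing happens per
        bootstrap sample.
    profiles
        Disorder profiles keyed by protein id, covering every window.
    residue_class
        ``"ST"`` or ``"Y"``; all windows must match.
    """

    def __init__(self, positives: Sequence[PeptideWindow],
                 negatives: Sequence[PeptideWindow],
                 profiles: dict[str, DisorderProfile],
                 residue_class: str = "ST",
                 knn_fractions: Sequence[float] = F.KNN_FRACTIONS,
                 disorder_windows: Sequence[int] = F.DISORDER_WINDOWS,
                 C: float = 1.0):
        if residue_class not in ("ST", "Y"):
            raise ValueError("residue_class must be 'ST' or 'Y'")
        allowed = set(residue_class)
        for w in list(positives) + list(negatives):
            if w.center not in allowed:
                raise ValueError(
                    f"window {w.key} center {w.center} outside class {residue_class}")
        if len(positives) < 10 or len(negatives) < 10:
            raise ValueError("need at least 10 positive and 10 negative windows")
        if len(negatives) < len(positives):
            raise ValueError(
                "fewer negatives than positives: supply more negatives or "
                "subsample the positives")
        self.positives = list(positives)
        self.negatives = list(negatives)
        self.profiles = profiles
        self.residue_class = residue_class
        self.knn_fractions = tuple(knn_fractions)
        self.disorder_windows = tuple(disorder_windows)
        self.C = C

    @classmethod
    def from_records(cls, records: Sequence[ProteinRecord],
                     residue_class: str = "ST", h: int = 6,
                     profiles: dict[str, DisorderProfile] | None = None,
                     negative_ratio: float | None = 3.0,
                     seed: int = 0, **kwargs) -> "PhosphositeModel":
        """Build a model from annotated protein records.

        Candidate windows are enumerated per record; annotated sites are
        positives, the rest negatives.  ``negative_ratio`` caps the
        negative pool at that multiple of the positive count (sampled
        deterministically from ``seed``); ``None`` keeps all negatives.
        """
        if profiles is None:
            profiles = F.profiles_for_records(records)
        positives: list[PeptideWindow] = []
        negatives: list[PeptideWindow] = []
        for rec in records:
            for w in enumerate_candidates(rec, residue_class, h):
                (positives if w.label == "positive" else negatives).append(w)
        if negative_ratio is not None:
            cap = int(negative_ratio * len(positives))
            if len(negatives) > cap:
                rng = np.random.default_rng(seed)
                keep = rng.choice(len(negatives), size=cap, replace=False)
                negatives = [negatives[i] for i in sorted(keep)]
        return cls(positives, negatives, profiles, residue_class, **kwargs)

    # -- fitting ------------------------------------------------------------

    def fit(self, B: int = 30, seed: int = 0) -> "PhosphositeResults":
        """Train the B-classifier bootstrap-balanced ensemble."""
        if B < 1:
            raise ValueError("B must be >= 1")
        n_pos, n_neg = len(self.positives), len(self.negatives)
        training = self.positives + self.negatives

        # leave-one-out KNN features for the training pool itself
        X = F.featurize_batch(training, training, self.profiles,
                              self.knn_fractions, self.disorder_windows,
                              exclude_self=True)
        y = np.concatenate([np.ones(n_pos, dtype=bool),
                            np.zeros(n_neg, dtype=bool)])

        classifiers: list[Pipeline] = []
        in_sample = np.zeros((B, n_neg), dtype=bool)
        for b in range(B):
            rng = np.random.default_rng((int(seed), b))
            chosen = rng.choice(n_neg, size=n_pos, replace=False)
            in_sample[b, chosen] = True
            rows = np.concatenate([np.arange(n_pos), n_pos + chosen])
            clf = Pipeline([
                ("scale", StandardScaler()),
                ("svm", SVC(kernel="linear", C=self.C)),
            ])
            clf.fit(X[rows], y[rows])
            classifiers.append(clf)

        # decision values of every classifier on every pool negative
        neg_dec = np.vstack([clf.decision_function(X[n_pos:])
                             for clf in classifiers])
        oob = ~in_sample
        with np.errstate(invalid="ignore"):
            counts = oob.sum(axis=0)
            sums = np.where(oob, neg_dec, 0.0).sum(axis=0)
        # negatives used by every sample fall back to the full-ensemble mean
        calibration = np.where(counts > 0, sums / np.maximum(counts, 1),
                               neg_dec.mean(axis=0))
        return PhosphositeResults(self, classifiers,
                                  np.sort(calibration), B=B, seed=int(seed))


class PhosphositeResults:
    """Fitted ensemble: scoring, calibration, prediction and summary."""

    def __init__(self, model: PhosphositeModel, classifiers: list[Pipeline],
                 calibration: np.ndarray, B: int, seed: int):
        self.model = model
        self.classifiers = classifiers
        #: sorted out-of-bag negative scores; the calibration table
        self.calibration = np.asarray(calibration, dtype=float)
        self.B = B
        self.seed = seed

    # -- scoring ------------------------------------------------------------

    @property
    def training_windows(self) -> list[PeptideWindow]:
        return self.model.positives + self.model.negatives

    def _features(self, windows: Sequence[PeptideWindow],
                  profiles: dict[str, DisorderProfile]) -> np.ndarray:
        return F.featurize_batch(windows, self.training_windows, profiles,
                                 self.model.knn_fractions,
                                 self.model.disorder_windows,
                                 exclude_self=False)

    def score_windows(self, windows: Sequence[PeptideWindow],
                      profiles: dict[str, DisorderProfile] | None = None,
                      ) -> np.ndarray:
        """Aggregated (mean-of-ensemble) decision scores for windows."""
        allowed = set(self.model.residue_class)
        for w in windows:
            if w.center not in allowed:
                raise ValueError(f"window {w.key} center {w.center} does not "
                                 f"match the {self.model.residue_class} model")
        profiles = profiles or self.model.profiles
        X = self._features(windows, profiles)
        dec = np.vstack([clf.decision_function(X) for clf in self.classifiers])
        return dec.mean(axis=0)

    def predict_score(self, window: PeptideWindow,
                      profiles: dict[str, DisorderProfile] | None = None,
                      ) -> float:
        return float(self.score_windows([window], profiles)[0])

    # -- calibration --------------------------------------------------------

    def threshold_for_specificity(self, level: float) -> float:
        """Score threshold at which a ``level`` fraction of calibration
        negatives fall below.

        Returns the order statistic at index floor(level * n) of the
        sorted negative scores (0-based), so with 100 stored scores the
        0.95 threshold is the 96th smallest and level -> 0 approaches
        the minimum.
        """
        if not 0.0 < level < 1.0:
            raise ValueError("level must be in (0, 1)")
        n = len(self.calibration)
        idx = min(n - 1, int(np.floor(level * n)))
        return float(self.calibration[idx])

    def estimated_specificity(self, scores: np.ndarray | float) -> np.ndarray:
        """Fraction of calibration negatives scoring strictly below each score."""
        idx = np.searchsorted(self.calibration, np.atleast_1d(scores), "left")
        return idx / len(self.calibration)

    # -- prediction ---------------------------------------------------------

    def predict_proteome(self, records: Sequence[ProteinRecord],
                         stringency: float = 0.95,
                         profiles: dict[str, DisorderProfile] | None = None,
                         h: int | None = None) -> list[SitePrediction]:
        """Score every candidate of the model's residue class in ``records``."""
        if h is None:
            h = self.model.positives[0].half_width
        if profiles is None:
            profiles = F.profiles_for_records(records)
        windows = [w for rec in records
                   for w in enumerate_candidates(rec, self.model.residue_class, h)]
        if not windows:
            return []
        scores = self.score_windows(windows, profiles)
        spec = self.estimated_specificity(scores)
        return [SitePrediction(w.protein_id, w.position, w.center,
                               float(s), float(sp), bool(sp >= stringency))
                for w, s, sp in zip(windows, scores, spec)]

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        m = self.model
        lines = [
            "Phosphosite ensemble results",
            "=" * 34,
            f"residue class        {m.residue_class}",
            f"positives            {len(m.positives)}",
            f"negative pool        {len(m.negatives)}",
            f"classifiers (B)      {self.B}",
            f"features             {F.N_FEATURES} "
            f"(KNN {len(m.knn_fractions)} + disorder "
            f"{len(m.disorder_windows)} + AA freq 20)",
            f"seed                 {self.seed}",
            "calibration (out-of-bag negative scores)",
            f"  n                  {len(self.calibration)}",
            f"  threshold @0.90    {self.threshold_for_specificity(0.90):+.4f}",
            f"  threshold @0.95    {self.threshold_for_specificity(0.95):+.4f}",
            f"  threshold @0.99    {self.threshold_for_specificity(0.99):+.4f}",
        ]
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Serialize to a versioned archive (JSON metadata + .npz arrays)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": 1,
            "residue_class": self.model.residue_class,
            "B": self.B, "seed": self.seed, "C": self.model.C,
            "knn_fractions": list(self.model.knn_fractions),
            "disorder_windows": list(self.model.disorder_windows),
            "n_positives": len(self.model.positives),
            "windows": [
                {"protein_id": w.protein_id, "position": w.position,
                 "center": w.center, "flank": w.flank, "label": w.label}
                for w in self.training_windows],
            "profiles": {
                pid: {"scores": prof.scores.tolist(), "source": prof.source}
                for pid, prof in self.model.profiles.items()},
        }
        (directory / "model.json").write_text(json.dumps(meta))
        arrays = {"calibration": self.calibration}
        for i, clf in enumerate(self.classifiers):
            scaler: StandardScaler = clf.named_steps["scale"]
            svm: SVC = clf.named_steps["svm"]
            arrays[f"clf{i}_mean"] = scaler.mean_
            arrays[f"clf{i}_scale"] = scaler.scale_
            arrays[f"clf{i}_coef"] = svm.coef_
            arrays[f"clf{i}_intercept"] = svm.intercept_
        np.savez(directory / "arrays.npz", **arrays)

    @classmethod
    def load(cls, directory: str | Path) -> "PhosphositeResults":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        if meta.get("format_version") != 1:
            raise ValueError("unsupported model archive version")
        windows = [PeptideWindow(**w) for w in meta["windows"]]
        n_pos = meta["n_positives"]
        profiles = {pid: DisorderProfile(protein_id=pid,
                                         scores=np.array(p["scores"]),
                                         source=p["source"])
                    for pid, p in meta["profiles"].items()}
        model = PhosphositeModel(windows[:n_pos], windows[n_pos:], profiles,
                                 meta["residue_class"],
                                 knn_fractions=meta["knn_fractions"],
                                 disorder_windows=meta["disorder_windows"],
                                 C=meta["C"])
        arrays = np.load(directory / "arrays.npz")
        classifiers = []
        for i in range(meta["B"]):
            classifiers.append(_LinearScorer(arrays[f"clf{i}_mean"],
                                             arrays[f"clf{i}_scale"],
                                             arrays[f"clf{i}_coef"],
                                             arrays[f"clf{i}_intercept"]))
        return cls(model, classifiers, arrays["calibration"],
                   B=meta["B"], seed=meta["seed"])


class _LinearScorer:
    """Deserialized linear SVM: reproduces Pipeline.decision_function."""

    def __init__(self, mean, scale, coef, intercept):
        self.mean, self.scale = mean, scale
        self.coef, self.intercept = coef, intercept

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.mean) / self.scale
        return (Z @ self.coef.T).ravel() + self.intercept


def train_ensemble(positives, negatives, profiles, B: int = 30, seed: int = 0,
                   residue_class: str = "ST", **kwargs) -> PhosphositeResults:
    """Functional wrapper: build a :class:`PhosphositeModel` and fit it."""
    return PhosphositeModel(positives, negatives, profiles,
                            residue_class, **kwargs).fit(B=B, seed=seed)
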