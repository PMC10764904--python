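"""Linear-SVM ensemble training and (k, C, SOP) grid search.

Each ensemble member sees its own balanced undersampling draw, fits its own
z-score normalization and ANOVA-F feature selection on that draw, and
trains a linear-kernel SVM with cost C. Thirty-one members vote on each
test sample; with an odd member count there are no ties.

Hyperparameters are tuned by leave-one-seizure-out cross-validation over
the three training seizures: two seizures train (balanced), the held-out
seizure validates on its *unbalanced* samples, scored by the geometric mean
of sample sensitivity and specificity, sqrt(SS_sample * SP_sample).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .dataset import (
    EventScheme,
    LabeledSet,
    SOP_CHOICES,
    label_windows,
    select_features_anova,
    undersample,
    zscore_apply,
    zscore_fit,
)

N_MEMBERS = 31
SVM_TOL = 1e-3
SVM_MAX_ITER = 1_000_000


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grid; defaults follow the study conditions."""

    k_grid: tuple[int, ...] = (10, 20, 30, 40)
    c_grid: tuple[float, ...] = tuple(2.0 ** e for e in range(-10, 11, 2))
    sop_grid: tuple[int, ...] = tuple(SOP_CHOICES)

    @property
    def n_kc(self) -> int:
        return len(self.k_grid) * len(self.c_grid)


DEFAULT_GRID = GridSpec()
assert DEFAULT_GRID.n_kc == 44
assert len(DEFAULT_GRID.sop_grid) == 10


class InfeasibleFold(RuntimeError):
    """A CV fold has no positive samples; the scheme/SOP cannot be scored."""


@dataclass
class EnsembleMember:
    mean: np.ndarray
    std: np.ndarray
    feature_idx: np.ndarray
    coef: np.ndarray
    intercept: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = ((X - self.mean) / self.std)[:, self.feature_idx]
        return (Z @ self.coef + self.intercept > 0).astype(int)


@dataclass
class ModelBundle:
    """A trained per-event ensemble plus everything needed to replay it."""

    approach: str
    event_index: int
    k: int
    C: float
    sop: float
    members: list[EnsembleMember]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.members) != N_MEMBERS:
            raise ValueError(f"bundle must contain exactly {N_MEMBERS} members")

    @property
    def n_features_in(self) -> int:
        return self.members[0].mean.size

    def votes(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.n_features_in:
            raise ValueError(
                f"feature count mismatch: bundle expects {self.n_features_in}, "
                f"got {X.shape[1]}"
            )
        return np.sum([m.predict(X) for m in self.members], axis=0)

    def save_json(self, path) -> None:
        doc = {
            "format": "chronofp-model-v1",
            "approach": self.approach,
            "event_index": self.event_index,
            "k": self.k,
            "C": self.C,
            "sop": self.sop,
            "metadata": self.metadata,
            "members": [
                {
                    "mean": m.mean.tolist(),
                    "std": m.std.tolist(),
                    "feature_idx": m.feature_idx.tolist(),
                    "coef": m.coef.tolist(),
                    "intercept": m.intercept,
                }
                for m in self.members
            ],
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load_json(cls, path) -> "ModelBundle":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "chronofp-model-v1":
            raise ValueError("not a chronofp model container")
        members = [
            EnsembleMember(
                mean=np.array(m["mean"]),
                std=np.array(m["std"]),
                feature_idx=np.array(m["feature_idx"], int),
                coef=np.array(m["coef"]),
                intercept=float(m["intercept"]),
            )
            for m in doc["members"]
        ]
        return cls(doc["approach"], doc["event_index"], doc["k"], doc["C"],
                   doc["sop"], members, doc.get("metadata", {}))


def predict_vote(bundle: ModelBundle, X: np.ndarray) -> np.ndarray:
    """Majority vote of the 31 members on raw (unstandardized) features."""
    return (2 * bundle.votes(X) > N_MEMBERS).astype(int)


def fold_metric(ss: float, sp: float) -> float:
    """Geometric mean of sample sensitivity and specificity."""
    return float(np.sqrt(ss * sp))


def _fit_member(X: np.ndarray, y: np.ndarray, k: int, C: float,
                member_tag: str = "") -> EnsembleMember:
    params = zscore_fit(X)
    Z = zscore_apply(params, X)
    idx = select_features_anova(Z, y, k)
    clf = SVC(kernel="linear", C=C, tol=SVM_TOL, max_iter=SVM_MAX_ITER)
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=UserWarning)
        try:
            clf.fit(Z[:, idx], y)
        except UserWarning as exc:  # libsvm convergence warning escalated
            raise RuntimeError(f"SVM failed to converge {member_tag}: {exc}")
    if getattr(clf, "fit_status_", 0) != 0:
        raise RuntimeError(f"SVM failed to converge {member_tag}")
    return EnsembleMember(
        mean=params.mean,
        std=params.std,
        feature_idx=idx,
        coef=clf.coef_.ravel(),
        intercept=float(clf.intercept_[0]),
    )


def _member_seed(seed: int, *tags: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(tags))


def cv_score(labeled: LabeledSet, k: int, C: float, seed: int = 0) -> float:
    """Leave-one-seizure-out CV metric over the three training seizures."""
    sids = np.unique(labeled.seizure_ids)
    if sids.size != 3:
        raise ValueError(f"expected 3 training seizures, got {sids.size}")
    scores = []
    for fold, held in enumerate(sids):
        train = labeled.subset(labeled.seizure_ids != held)
        valid = labeled.subset(labeled.seizure_ids == held)
        if valid.n_pos == 0 or train.n_pos == 0:
            raise InfeasibleFold(f"fold {fold}: no preictal samples")
        balanced = undersample(train, _member_seed(seed, fold))
        member = _fit_member(balanced.X, balanced.y, k, C, f"(fold {fold})")
        pred = member.predict(valid.X)
        pos, neg = valid.y == 1, valid.y == 0
        ss = float(pred[pos].mean())
        sp = float(1.0 - pred[neg].mean()) if neg.any() else 0.0
        scores.append(fold_metric(ss, sp))
    return float(np.mean(scores))


@dataclass
class GridResult:
    k: int
    C: float
    sop: int
    score: float
    scores: dict = field(default_factory=dict)


def grid_search(table, train_onsets, grid: GridSpec, approach: str,
                sph: float = 5.0, exclusion_min: float = 10.0,
                seed: int = 0) -> GridResult:
    """Arg-max of the CV metric over (k, C, SOP).

    For the multi-event approaches one shared triple is tuned; the metric
    is the mean of the three event classifiers' CV scores. Ties are broken
    toward smaller C, then smaller k, then smaller SOP. Grid cells that are
    infeasible for the data geometry are skipped with a warning.
    """
    best: GridResult | None = None
    all_scores: dict[tuple[int, float, int], float] = {}
    for sop in grid.sop_grid:
        scheme = EventScheme(approach, sop, sph)
        try:
            labeled = [
                label_windows(table, train_onsets, scheme, ev, exclusion_min)
                for ev in range(1, scheme.n_events + 1)
            ]
        except ValueError as exc:
            warnings.warn(f"SOP {sop}: labeling infeasible ({exc})", stacklevel=2)
            continue
        for k in grid.k_grid:
            for C in grid.c_grid:
                try:
                    score = float(np.mean(
                        [cv_score(ls, k, C, seed) for ls in labeled]))
                except (InfeasibleFold, ValueError) as exc:
                    warnings.warn(f"cell (k={k}, C={C}, SOP={sop}) skipped: "
                                  f"{exc}", stacklevel=2)
                    continue
                all_scores[(k, C, sop)] = score
                key = (score, -C, -k, -sop)
                if best is None or key > (best.score, -best.C, -best.k, -best.sop):
                    best = GridResult(k=k, C=C, sop=sop, score=score)
    if best is None:
        raise RuntimeError("no evaluable grid cell")
    best.scores = all_scores
    return best


def train_ensemble(labeled: LabeledSet, k: int, C: float, seed: int,
                   approach: str = "control", event_index: int = 1,
                   sop: float = 10.0) -> ModelBundle:
    """Train the 31-member ensemble on the full training set.

    Members differ only by their (seeded) undersampling draw; each draw is
    independently normalized and feature-selected.
    """
    members = []
    for i in range(N_MEMBERS):
        balanced = undersample(labeled, _member_seed(seed, i))
        try:
            members.append(_fit_member(balanced.X, balanced.y, k, C,
                                       f"(member {i})"))
        except RuntimeError:
            raise
    return ModelBundle(
        approach=approach,
        event_index=event_index,
        k=k,
        C=C,
        sop=sop,
        members=members,
        metadata={
            "seed": int(seed),
            "solver": "libsvm linear kernel",
            "tol": SVM_TOL,
            "max_iter": SVM_MAX_ITER,
        },
    )
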