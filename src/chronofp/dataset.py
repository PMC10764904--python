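"""Labeled, balanced, normalized training sets under an event scheme.

The preictal geometry is pure arithmetic on window start times. All event
windows are half-open ``(start, end]`` in seconds before the onset. Three
schemes are supported:

* ``control`` — one preictal event of length SOP ending SPH before onset;
* ``chronological`` — three contiguous non-overlapping events of length SOP
  each, event 3 nearest the onset, tiling ``(onset-SPH-3*SOP, onset-SPH]``;
* ``cumulative`` — three nested events all ending SPH before onset, with
  lengths 3*SOP (event 1, farthest-reaching), 2*SOP, and SOP (event 3).

For a given event classifier, windows inside the scheme's full preictal
span but outside the target event are excluded (they belong to other
putative events), as are windows inside the SPH and a configurable
post-onset exclusion zone standing in for ictal/postictal data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.feature_selection import f_classif

SOP_CHOICES = tuple(range(10, 60, 5))
APPROACHES = ("control", "chronological", "cumulative")
DEFAULT_EXCLUSION_MIN = 10.0


@dataclass(frozen=True)
class EventScheme:
    """SOP/SPH geometry of the preictal events for one approach."""

    approach: str
    sop: float          # minutes
    sph: float = 5.0    # minutes

    def __post_init__(self) -> None:
        if self.approach not in APPROACHES:
            raise ValueError(f"unknown approach {self.approach!r}")
        if self.sop not in SOP_CHOICES:
            raise ValueError(f"sop must be one of {SOP_CHOICES} minutes")

    @property
    def n_events(self) -> int:
        return 1 if self.approach == "control" else 3

    @property
    def events(self) -> list[tuple[int, float, float]]:
        """(index, start_before_min, end_before_min) per event, minutes
        before onset; interval is (start, end] on the time axis."""
        sop, sph = self.sop, self.sph
        if self.approach == "control":
            return [(1, sph + sop, sph)]
        if self.approach == "chronological":
            return [
                (1, sph + 3 * sop, sph + 2 * sop),
                (2, sph + 2 * sop, sph + sop),
                (3, sph + sop, sph),
            ]
        # cumulative: nested, all ending SPH before onset; event 1 longest
        return [
            (1, sph + 3 * sop, sph),
            (2, sph + 2 * sop, sph),
            (3, sph + sop, sph),
        ]

    @property
    def total_span_min(self) -> float:
        """Full preictal footprint before onset, SPH included."""
        return self.sph + self.n_events * self.sop if self.approach != "control" \
            else self.sph + self.sop

    def event_duration_min(self, event_index: int) -> float:
        idx, start, end = self.events[event_index - 1]
        assert idx == event_index
        return start - end


@dataclass
class LabeledSet:
    """Feature samples with binary labels and per-sample seizure assignment."""

    X: np.ndarray
    y: np.ndarray
    times: np.ndarray
    seizure_ids: np.ndarray

    def __post_init__(self) -> None:
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary")

    @property
    def n_pos(self) -> int:
        return int(self.y.sum())

    def subset(self, mask: np.ndarray) -> "LabeledSet":
        return LabeledSet(self.X[mask], self.y[mask], self.times[mask],
                          self.seizure_ids[mask])


def split_train_test(onsets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First three seizures train, remainder test.

    Patients with fewer than four seizures are ineligible.
    """
    onsets = np.asarray(onsets, float)
    if onsets.size < 4:
        raise ValueError(
            f"patient ineligible: {onsets.size} seizures, a minimum of four "
            "lead seizures is required"
        )
    return onsets[:3], onsets[3:]


def label_windows(table, onsets, scheme: EventScheme, event_index: int = 1,
                  exclusion_min: float = DEFAULT_EXCLUSION_MIN) -> LabeledSet:
    """Label feature-table windows for one event classifier.

    Windows whose start time falls in the target event window get label 1;
    interictal windows get 0; windows in the SPH, other events of the same
    scheme, or the post-onset exclusion zone are dropped. Interictal
    windows are assigned to the seizure they precede.
    """
    times = np.asarray(table.window_times, float)
    onsets = np.asarray(onsets, float)
    if not 1 <= event_index <= scheme.n_events:
        raise ValueError(f"event_index must be 1..{scheme.n_events}")

    labels = np.zeros(times.size, dtype=np.int8)
    sid = np.full(times.size, -1, dtype=int)
    span_s = scheme.total_span_min * 60.0
    excl_s = exclusion_min * 60.0
    _, ev_start_min, ev_end_min = scheme.events[event_index - 1]

    prev_end = -np.inf
    for i, onset in enumerate(onsets):
        pre_start = onset - span_s
        if pre_start < 0 and times.size:
            warnings.warn(
                f"preictal span of seizure {i} truncated at record start",
                stacklevel=2,
            )
        inter = (times > prev_end) & (times <= pre_start)
        sid[inter] = i
        labels[inter] = 0

        pre = (times > pre_start) & (times <= onset)
        sid[pre] = i
        labels[pre] = -1  # SPH / non-target events by default
        tgt = (times > onset - ev_start_min * 60.0) & \
              (times <= onset - ev_end_min * 60.0)
        labels[tgt & pre] = 1

        post = (times > onset) & (times <= onset + excl_s)
        sid[post] = i
        labels[post] = -1
        prev_end = onset + excl_s

    keep = (labels >= 0) & (sid >= 0)
    return LabeledSet(
        X=table.values[keep],
        y=labels[keep].astype(int),
        times=times[keep],
        seizure_ids=sid[keep],
    )


def undersample(labeled: LabeledSet, seed) -> LabeledSet:
    """Systematic random undersampling of the interictal class.

    Per seizure, the (time-ordered) interictal samples are partitioned into
    as many contiguous groups as there are preictal samples, and one sample
    is drawn uniformly from each group — keeping temporal coverage of the
    whole interictal period. Class counts are exactly equal afterwards.
    """
    rng = np.random.default_rng(seed)
    keep_idx: list[np.ndarray] = []
    for s in np.unique(labeled.seizure_ids):
        m = labeled.seizure_ids == s
        pos = np.flatnonzero(m & (labeled.y == 1))
        neg = np.flatnonzero(m & (labeled.y == 0))
        neg = neg[np.argsort(labeled.times[neg], kind="stable")]
        n = pos.size
        if n == 0:
            continue
        if neg.size < n:
            raise ValueError(
                f"seizure {s}: {neg.size} interictal < {n} preictal samples; "
                "cannot balance"
            )
        for group in np.array_split(neg, n):
            keep_idx.append(group[rng.integers(group.size)][None])
        keep_idx.append(pos)
    if not keep_idx:
        raise ValueError("no preictal samples present")
    idx = np.sort(np.concatenate(keep_idx))
    return labeled.subset(np.isin(np.arange(labeled.y.size), idx))


@dataclass(frozen=True)
class ZScoreParams:
    mean: np.ndarray
    std: np.ndarray


def zscore_fit(X: np.ndarray) -> ZScoreParams:
    """Column means/SDs of the training set; zero-variance SDs become 1."""
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    if np.any(std == 0):
        warnings.warn("zero-variance feature column(s); sd set to 1",
                      stacklevel=2)
        std = np.where(std == 0, 1.0, std)
    return ZScoreParams(mean=mean, std=std)


def zscore_apply(params: ZScoreParams, X: np.ndarray) -> np.ndarray:
    return (X - params.mean) / params.std


def select_features_anova(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k features with the largest one-way ANOVA F statistic."""
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds {X.shape[1]} features")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present for the ANOVA F-test")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features yield 0/0
        F, _ = f_classif(X, y)
    F = np.nan_to_num(F, nan=0.0, posinf=np.finfo(float).max)
    order = np.argsort(-F, kind="stable")
    return order[:k]
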