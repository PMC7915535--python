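"""One-vs-one binary-classifier panels and their aggregated accuracy.

A k-class one-vs-one (OvO) panel consists of C(k,2) binary classifiers,
one per unordered class pair, each summarised by a single accuracy.  To
compare such a panel with a direct multiclass decoder, the panel's
decisions are combined by majority vote and the resulting multiclass
accuracy is estimated by Monte-Carlo simulation: each relevant classifier
(one whose pair contains the true class) votes for the true class with
probability equal to its accuracy, and for its other class otherwise.

A pairwise accuracy says nothing about how its classifier behaves on
samples from *neither* of its classes, so irrelevant classifiers here vote
uniformly between their two classes — the minimal-assumption choice (an
OvO classifier's output is meaningless off-pair).  Ties in the vote count
are broken by sampling uniformly among the tied classes.

Panels over classes that share an articulation can be collapsed (e.g. the
two elbow variants into "elbow"); the merged pair inherits the *maximum*
accuracy among the original pairs it absorbs.

:func:`exact_aggregate` enumerates all joint vote outcomes and serves as
the exact oracle for the Monte-Carlo estimate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = ["PanelAccuracy", "exact_aggregate", "mc_aggregate", "merge_pairs"]

DEFAULT_MERGE_MAP = {
    "elbow_flexion": "elbow",
    "elbow_extension": "elbow",
    "wrist_pronation": "wrist",
    "wrist_supination": "wrist",
    "hand_open": "hand",
    "hand_close": "hand",
    "rest": "rest",
}


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class PanelAccuracy:
    """Per-pair accuracies of an OvO panel over ``classes``."""

    classes: tuple[str, ...]
    accuracies: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.classes = tuple(self.classes)
        self.accuracies = {_key(*pair): float(p) for pair, p in self.accuracies.items()}
        expected = {_key(a, b) for a, b in itertools.combinations(self.classes, 2)}
        missing = expected - set(self.accuracies)
        extra = set(self.accuracies) - expected
        if missing or extra:
            raise ValueError(
                f"incomplete panel: missing pairs {sorted(missing)}, extra {sorted(extra)}"
            )
        for pair, p in self.accuracies.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"accuracy {p} for pair {pair} outside [0, 1]")

    def __getitem__(self, pair: Sequence[str]) -> float:
        return self.accuracies[_key(*pair)]

    @property
    def n_pairs(self) -> int:
        return len(self.accuracies)

    @classmethod
    def from_uniform(cls, classes: Sequence[str], p: float) -> "PanelAccuracy":
        accs = {_key(a, b): p for a, b in itertools.combinations(classes, 2)}
        return cls(tuple(classes), accs)


def merge_pairs(panel: PanelAccuracy, merge_map: Mapping[str, str] | None = None) -> PanelAccuracy:
    """Collapse classes via ``merge_map``; merged pairs take the max accuracy."""
    merge_map = DEFAULT_MERGE_MAP if merge_map is None else merge_map
    missing = set(panel.classes) - set(merge_map)
    if missing:
        raise ValueError(f"merge map does not cover classes: {sorted(missing)}")
    merged_classes = tuple(dict.fromkeys(merge_map[c] for c in panel.classes))
    accs: dict[tuple[str, str], float] = {}
    for (a, b), p in panel.accuracies.items():
        ma, mb = merge_map[a], merge_map[b]
        if ma == mb:  # pair collapses inside one merged class
            continue
        key = _key(ma, mb)
        accs[key] = max(accs.get(key, 0.0), p)
    return PanelAccuracy(merged_classes, accs)


def _vote_setup(panel: PanelAccuracy):
    classes = list(panel.classes)
    index = {c: i for i, c in enumerate(classes)}
    pairs = [
        (index[a], index[b], panel[(a, b)])
        for a, b in itertools.combinations(classes, 2)
    ]
    return classes, pairs


def mc_aggregate(
    panel: PanelAccuracy,
    n_sims: int = 10_000,
    seed: int | None = None,
    class_prior: Sequence[float] | None = None,
) -> float:
    """Monte-Carlo estimate of the majority-vote multiclass accuracy.

    ``class_prior`` weights the simulated true classes (default uniform).
    The standard error is about sqrt(0.25 / n_sims) at worst.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    classes, pairs = _vote_setup(panel)
    k = len(classes)
    prior = np.full(k, 1.0 / k) if class_prior is None else np.asarray(class_prior, float)
    prior = prior / prior.sum()
    true = rng.choice(k, size=n_sims, p=prior)
    votes = np.zeros((n_sims, k), dtype=np.int64)
    u = rng.random((n_sims, len(pairs)))
    for j, (a, b, p) in enumerate(pairs):
        rel_a = true == a
        rel_b = true == b
        winner = np.where(u[:, j] < 0.5, a, b)  # irrelevant pairs: coin flip
        winner[rel_a] = np.where(u[rel_a, j] < p, a, b)
        winner[rel_b] = np.where(u[rel_b, j] < p, b, a)
        votes[np.arange(n_sims), winner] += 1
    # uniform tie-break among the most-voted classes via random jitter keys
    pick = (votes + rng.random(votes.shape) * 0.5).argmax(axis=1)
    return float(np.mean(pick == true))


def exact_aggregate(
    panel: PanelAccuracy,
    class_prior: Sequence[float] | None = None,
    max_classes: int = 5,
) -> float:
    """Exact majority-vote accuracy by enumerating all joint vote outcomes.

    Ties contribute their probability mass split uniformly over the tied
    classes.  Enumeration is 2^C(k,2) outcomes, so k is capped.
    """
    classes, pairs = _vote_setup(panel)
    k = len(classes)
    if k > max_classes:
        raise ValueError(f"{k} classes need 2^{k * (k - 1) // 2} outcomes; cap is {max_classes}")
    prior = np.full(k, 1.0 / k) if class_prior is None else np.asarray(class_prior, float)
    prior = prior / prior.sum()
    total = 0.0
    for c in range(k):
        # per-pair win probabilities for class c's sample
        win_a = []  # probability the pair votes for its first class
        for a, b, p in pairs:
            if c == a:
                win_a.append(p)
            elif c == b:
                win_a.append(1.0 - p)
            else:
                win_a.append(0.5)
        acc_c = 0.0
        for outcome in itertools.product((0, 1), repeat=len(pairs)):
            prob = 1.0
            votes = np.zeros(k, dtype=np.int64)
            for (a, b, _), first, pa in zip(pairs, outcome, win_a):
                if first == 0:
                    prob *= pa
                    votes[a] += 1
                else:
                    prob *= 1.0 - pa
                    votes[b] += 1
            if prob == 0.0:
                continue
            winners = np.flatnonzero(votes == votes.max())
            if c in winners:
                acc_c += prob / len(winners)
        total += prior[c] * acc_c
    return float(total)
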