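"""Core-hybrid selection by PC1-score interval sampling.

Representative "core" subsets of each hybrid population are chosen from the
first principal component of the combined mid-parent predictor table: PC1
scores are ranked from high to low and the leader of every consecutive
block of N hybrids is kept, yielding ceil(n / N) hybrids that span the full
PC1 range.  N = 2, 3, 4 give the "2N", "3N", "4N" sets; combining core sets
from the two populations produces the named cross-environment training
compositions (e.g. "3N_2012 & 2N_2015").
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import CoreSet, TrainingComposition, validate_pedigree
from .pls import pca
from .preprocess import Autoscaler

__all__ = ["pc1_scores", "select_core", "random_half", "compose_training"]


def pc1_scores(predictors: pd.DataFrame, flip: bool = False) -> pd.Series:
    """PC1 score of each hybrid from PCA of the autoscaled predictor table.

    The component sign follows the fixed convention (largest-magnitude
    loading positive); ``flip=True`` returns the opposite orientation, which
    changes the block leaders and hence which hybrids become core.
    """
    X = Autoscaler().fit_transform(predictors)
    result = pca(X.to_numpy(), n_components=1)
    scores = result.scores[:, 0]
    if flip:
        scores = -scores
    return pd.Series(scores, index=predictors.index, name="pc1")


def select_core(scores: pd.Series, interval: int,
                population: str | None = None) -> CoreSet:
    """Block-leader sampling of the descending PC1 ordering.

    Hybrids are sorted by decreasing score (ties broken by hybrid id) and
    positions 1, N+1, 2N+1, ... are selected, giving ceil(n / N) hybrids
    including the top-ranked one.
    """
    interval = int(interval)
    if interval < 2:
        raise ValueError("interval must be >= 2")
    if not np.isfinite(scores.to_numpy(dtype=float)).all():
        raise ValueError("PC1 scores must be finite")
    if interval > len(scores):
        warnings.warn(f"interval {interval} exceeds population size "
                      f"{len(scores)}; selecting the single top hybrid")
    frame = scores.rename("score").rename_axis("hybrid_id").reset_index()
    frame = frame.sort_values(["score", "hybrid_id"],
                              ascending=[False, True], kind="mergesort")
    selected = frame["hybrid_id"].iloc[::interval].tolist()
    return CoreSet(population=population, interval=interval,
                   selected_ids=selected, pc1_scores=scores)


def random_half(pedigree: pd.DataFrame, population: str, seed: int):
    """Seeded random half of one population, as a (label, ids) part.

    Mirrors training sets built from "randomly selected hybrids" rather
    than PC1-ranked ones; usable wherever a core set is expected in
    :func:`compose_training`.
    """
    validate_pedigree(pedigree)
    members = pedigree.loc[pedigree["population"] == population, "hybrid_id"]
    if members.empty:
        raise ValueError(f"population {population!r} has no hybrids")
    rng = np.random.default_rng(seed)
    take = len(members) // 2
    ids = sorted(rng.choice(members.to_numpy(dtype=object), size=take,
                            replace=False).tolist())
    return ("Random-half", ids)


def _resolve_part(part, population: str, members: list):
    """Normalise one per-population specification to (label, ids) or None."""
    if part is None:
        return None
    if isinstance(part, str):
        if part.lower() == "all":
            return (f"All_{population}", list(members))
        raise ValueError(f"unknown training-part specification {part!r}")
    if isinstance(part, CoreSet):
        if part.population is not None and part.population != population:
            raise ValueError(f"core set labelled {part.population!r} used "
                             f"for population {population!r}")
        ids = list(part.selected_ids)
        label = f"{part.interval}N_{population}"
    elif isinstance(part, tuple) and len(part) == 2:
        label, ids = part
        label = f"{label}_{population}"
        ids = list(ids)
    else:
        raise TypeError("training part must be a CoreSet, 'all', "
                        "a (label, ids) tuple or None")
    stray = set(ids) - set(members)
    if stray:
        raise ValueError(f"hybrid {sorted(stray)[0]!r} is not in "
                         f"population {population!r}")
    return (label, ids)


def compose_training(pedigree: pd.DataFrame, part_pop1, part_pop2,
                     pop1: str = "2012", pop2: str = "2015") -> TrainingComposition:
    """Combine per-population core sets into a named train/validation split.

    Each part is a :class:`CoreSet`, the string ``"all"`` (whole
    population), a ``(label, ids)`` tuple, or ``None`` (contribute no
    training hybrids).  The validation set is every hybrid of both
    populations not in the training set.
    """
    validate_pedigree(pedigree)
    members = {
        pop: pedigree.loc[pedigree["population"] == pop, "hybrid_id"].tolist()
        for pop in (pop1, pop2)
    }
    overlap = set(members[pop1]) & set(members[pop2])
    if overlap:
        raise ValueError(f"hybrid {sorted(overlap)[0]!r} appears in both "
                         "populations")
    parts = [
        _resolve_part(part_pop1, pop1, members[pop1]),
        _resolve_part(part_pop2, pop2, members[pop2]),
    ]
    parts = [p for p in parts if p is not None]
    if not parts:
        raise ValueError("at least one population must contribute training hybrids")
    name = " & ".join(label for label, _ in parts)
    train = [h for _, ids in parts for h in ids]
    if len(train) != len(set(train)):
        raise ValueError("training hybrids overlap across parts")
    train_set = set(train)
    validation = [h for pop in (pop1, pop2) for h in members[pop]
                  if h not in train_set]
    return TrainingComposition(name=name, train_ids=train,
                               validation_ids=validation)
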