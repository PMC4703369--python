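"""Cross-sample sharing of significant genes/variants and its resampling
null.

Observed sharing between samples (patients or cell lines) is compared with
size-matched random draws: per trial, each sample draws as many items as it
actually has significant, uniformly without replacement from its own tested
universe.  The pseudo p-value is the fraction of trials whose shared count
meets or exceeds the observed one, so it is always in {0, 1/n, ..., 1} and
equals 1 whenever nothing is observed shared.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = ["SharedSetResult", "shared_sets", "resample_shared_pvalue"]


@dataclass
class SharedSetResult:
    group: tuple[str, ...]
    level: str
    direction: str
    observed_shared: int
    null_counts: np.ndarray
    pseudo_p: float
    n_trials: int
    seed: int


def shared_sets(
    significant: Mapping[str, set]
) -> tuple[dict[tuple[str, str], int], int]:
    """Pairwise and full-group intersection counts.

    Returns ``(pairs, full)`` where ``pairs[(a, b)] = |S_a & S_b|`` for every
    unordered pair (keys sorted) and ``full`` is the size of the
    intersection of all sets.
    """
    names = sorted(significant)
    pairs = {
        (a, b): len(significant[a] & significant[b])
        for a, b in itertools.combinations(names, 2)
    }
    full = len(set.intersection(*(set(significant[n]) for n in names))) if names else 0
    return pairs, full


def resample_shared_pvalue(
    significant: Mapping[str, set],
    pools: Mapping[str, set],
    n_trials: int = 1000,
    seed: int = 0,
    level: str = "gene",
    direction: str = "negative",
) -> dict[tuple[str, ...], SharedSetResult]:
    """Size-matched resampling significance for every pair and the full group.

    Each sample's null draw comes from its own tested pool (without
    replacement) with the sample's observed significant-set size.  The
    pseudo p-value for a group is ``#{trials: null shared >= observed
    shared} / n_trials``.
    """
    names = sorted(significant)
    if set(names) - set(pools):
        raise ValueError("every sample needs a tested pool")
    for n in names:
        if not significant[n] <= pools[n]:
            raise ValueError(f"significant set of {n!r} is not within its pool")
        if len(significant[n]) > len(pools[n]):
            raise ValueError(f"significant set of {n!r} larger than its pool")

    rng = np.random.default_rng(seed)
    pool_arrays = {n: np.array(sorted(pools[n]), dtype=object) for n in names}
    sizes = {n: len(significant[n]) for n in names}

    groups: list[tuple[str, ...]] = [
        (a, b) for a, b in itertools.combinations(names, 2)
    ]
    if len(names) > 2:
        groups.append(tuple(names))
    elif len(names) == 2:
        pass
    elif len(names) == 1:
        groups.append(tuple(names))

    observed: dict[tuple[str, ...], int] = {}
    for g in groups:
        observed[g] = len(set.intersection(*(set(significant[n]) for n in g)))

    nulls = {g: np.zeros(n_trials, dtype=int) for g in groups}
    for t in range(n_trials):
        draw = {}
        for n in names:
            arr = pool_arrays[n]
            idx = rng.choice(arr.size, size=sizes[n], replace=False)
            draw[n] = set(arr[idx])
        for g in groups:
            nulls[g][t] = len(set.intersection(*(draw[n] for n in g)))

    out = {}
    for g in groups:
        null = nulls[g]
        pseudo_p = float(np.count_nonzero(null >= observed[g]) / n_trials)
        out[g] = SharedSetResult(
            group=g,
            level=level,
            direction=direction,
            observed_shared=observed[g],
            null_counts=null,
            pseudo_p=pseudo_p,
            n_trials=n_trials,
            seed=seed,
        )
    return out
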