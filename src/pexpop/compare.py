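"""Goodness of fit of observed patient genotypes to the equilibrium model.

A diagnosed patient cohort (e.g. a natural-history study) yields observed
counts per genotype class pair; the population model yields expected
genotype proportions among affected births.  A chi-square goodness-of-fit
test asks whether the observed cohort is consistent with the equilibrium
proportions.  Expected proportions come from the population model, not the
sample, so the degrees of freedom are k - 1 after small-cell merging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chisquare

from .popgen import GenotypeClassPrevalence

__all__ = [
    "ObservedGenotypeCounts",
    "GofResult",
    "chi_square_gof",
    "merge_small_cells",
    "type_one_error_rate",
]


@dataclass(frozen=True)
class ObservedGenotypeCounts:
    """Non-negative observed count per genotype class pair."""

    counts: Mapping[tuple[str, str], int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("observed counts must be non-negative")
        if self.n == 0:
            raise ValueError("observed counts sum to zero")

    @property
    def n(self) -> int:
        return int(sum(self.counts.values()))


@dataclass(frozen=True)
class GofResult:
    statistic: float
    df: int
    pvalue: float
    merged: tuple[str, ...]  # labels pooled into the "other" bucket


def merge_small_cells(
    observed: np.ndarray, expected: np.ndarray, min_expected: float = 1.0
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Pool small-expectation categories into a single "other" bucket.

    Categories are merged smallest-expected first until every remaining
    bucket, including the pooled one, has expected count >= ``min_expected``
    (or only two buckets remain).  Merging depends only on the expected
    counts, so the rule is identical across replicate observed draws.
    """
    order = np.argsort(expected, kind="stable")
    merged_idx: list[int] = []
    pooled = 0.0
    for idx in order:
        below = expected[idx] < min_expected
        if not below and (not merged_idx or pooled >= min_expected):
            break
        if len(order) - len(merged_idx) <= 1:
            break  # keep at least two buckets so df >= 1
        merged_idx.append(int(idx))
        pooled += float(expected[idx])
    if not merged_idx:
        return observed, expected, []
    keep = [i for i in range(len(expected)) if i not in merged_idx]
    obs_out = np.append(observed[keep], observed[merged_idx].sum())
    exp_out = np.append(expected[keep], expected[merged_idx].sum())
    return obs_out, exp_out, merged_idx


def chi_square_gof(
    observed: ObservedGenotypeCounts | Mapping[tuple[str, str], int],
    expected_proportions: Mapping[tuple[str, str], float]
    | Sequence[GenotypeClassPrevalence],
    min_expected: float = 1.0,
) -> GofResult:
    """Chi-square goodness of fit of observed genotype counts to the model.

    Expected proportions are renormalised over affected genotypes; expected
    categories absent from the observed table enter with observed count 0,
    and observed categories with zero expected proportion are pooled into
    the merged bucket.  Statistic = sum (O - E)^2 / E with E = n * prop;
    p-value from the upper chi-square tail at df = k - 1 after merging.
    """
    if not isinstance(observed, ObservedGenotypeCounts):
        observed = ObservedGenotypeCounts(dict(observed))
    if not isinstance(expected_proportions, Mapping):
        expected_proportions = {
            g.pair: g.frequency for g in expected_proportions
        }
    norm_keys = {frozenset(k): float(v) for k, v in expected_proportions.items()}
    total_prop = sum(norm_keys.values())
    if total_prop <= 0:
        raise ValueError("expected proportions sum to zero")
    obs_keys = {frozenset(k): int(v) for k, v in observed.counts.items()}

    labels = sorted(
        set(norm_keys) | set(obs_keys), key=lambda fs: tuple(sorted(fs))
    )
    obs = np.array([obs_keys.get(k, 0) for k in labels], dtype=float)
    props = np.array([norm_keys.get(k, 0.0) for k in labels]) / total_prop
    n = obs.sum()
    exp = n * props

    obs_m, exp_m, merged_idx = merge_small_cells(obs, exp, min_expected)
    if np.any(exp_m <= 0):
        raise ValueError(
            "zero expected count with nonzero observed after merging; "
            "check category alignment"
        )
    # renormalise away float drift so scipy's sum check is satisfied
    exp_m = exp_m * (obs_m.sum() / exp_m.sum())
    stat, p = chisquare(obs_m, exp_m)
    df = len(obs_m) - 1
    merged_labels = tuple("/".join(sorted(labels[i])) for i in merged_idx)
    return GofResult(float(stat), df, float(p), merged_labels)


def type_one_error_rate(
    proportions: Sequence[float] | Mapping,
    n: int,
    reps: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    min_expected: float = 1.0,
) -> float:
    """Empirical rejection rate of the GOF test under the null.

    Draws ``reps`` multinomial cohorts of size ``n`` from the expected
    proportions and applies the same cell-merging rule as
    :func:`chi_square_gof` (the merge depends only on the expected counts,
    so it is computed once and applied to every replicate).
    """
    from scipy.stats import chi2

    if isinstance(proportions, Mapping):
        proportions = list(proportions.values())
    p = np.asarray(proportions, dtype=float)
    p = p / p.sum()
    expected = n * p
    _, exp_m, merged_idx = merge_small_cells(
        np.zeros_like(expected), expected, min_expected
    )
    keep = [i for i in range(len(p)) if i not in merged_idx]
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, p, size=reps).astype(float)
    if merged_idx:
        obs = np.column_stack([draws[:, keep], draws[:, merged_idx].sum(axis=1)])
    else:
        obs = draws
    stats = ((obs - exp_m) ** 2 / exp_m).sum(axis=1)
    df = obs.shape[1] - 1
    return float(np.mean(chi2.sf(stats, df) < alpha))
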