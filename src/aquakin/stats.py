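"""Statistics used alongside the assays.

Three procedures: a two-population Z-test on fitted binding constants
(Z = (X1 - X2) / sqrt(s1^2 + s2^2), with each constant treated as an
estimate carrying its own standard error); the Kruskal-Wallis rank test
with an exact permutation p-value at very small n; and the Conover-Iman
rank-based pairwise post hoc comparison, plus Bonferroni-corrected
pairwise t tests.

The Conover-Iman statistic for groups i, j compares mean ranks using the
pooled rank variance S^2 = (sum R^2 - N (N+1)^2 / 4) / (N - 1) and the
Kruskal-Wallis H of the same data:

    t_ij = (Rbar_i - Rbar_j) /
           sqrt(S^2 * (N - 1 - H) / (N - k) * (1/n_i + 1/n_j)),

referred to Student's t with N - k degrees of freedom. This parameterization
handles ties through the mid-rank H.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "EstimateWithError",
    "ZTestResult",
    "KruskalWallisResult",
    "z_test_estimates",
    "kruskal_wallis",
    "conover_inman",
    "bonferroni_ttests",
]

EXACT_N_MAX = 8  # exact permutation null is enumerated up to this total n


@dataclasses.dataclass
class EstimateWithError:
    """An estimate with its standard deviation (e.g. a fitted Kd and SE)."""

    value: float
    sd: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclasses.dataclass
class ZTestResult:
    z: float
    p: float
    tail: str
    flags: list[str] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class KruskalWallisResult:
    h: float
    p: float
    df: int
    method: str  # "chi2" or "exact"
    n_total: int
    group_sizes: tuple[int, ...]


def z_test_estimates(
    a: EstimateWithError, b: EstimateWithError, tail: str = "one"
) -> ZTestResult:
    """Z-test for two estimates: Z = (a - b) / sqrt(sd_a^2 + sd_b^2).

    ``tail="one"`` reports the normal tail beyond |Z| (a directional test of
    the observed difference); ``tail="two"`` doubles it. Two zero-SD
    estimates with different values give an infinite Z, flagged.
    """
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    denom = float(np.hypot(a.sd, b.sd))
    flags: list[str] = []
    if denom == 0:
        if a.value == b.value:
            z = 0.0
        else:
            z = np.inf if a.value > b.value else -np.inf
            flags.append("zero_variance:difference_infinitely_significant")
    else:
        z = (a.value - b.value) / denom
    p_one = float(sps.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    if z == 0:
        p_one = 0.5
    p = p_one if tail == "one" else min(1.0, 2.0 * p_one)
    return ZTestResult(z=float(z), p=p, tail=tail, flags=flags)


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def _as_groups(data) -> list[np.ndarray]:
    groups = [np.asarray(g, dtype=float) for g in data]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    return groups


def _h_statistic(pooled_ranks: np.ndarray, sizes: Sequence[int]) -> float:
    """Tie-corrected H from a pooled mid-rank vector split by ``sizes``."""
    n = len(pooled_ranks)
    h = 0.0
    i = 0
    for sz in sizes:
        r = pooled_ranks[i: i + sz]
        h += r.sum() ** 2 / sz
        i += sz
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled_ranks, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    if tie > 0:
        h /= tie
    return float(h)


def kruskal_wallis(data: Sequence[Sequence[float]]) -> KruskalWallisResult:
    """Kruskal-Wallis one-way rank ANOVA with tie correction.

    The p-value comes from the chi-square approximation (df = k - 1) except
    when the total sample size is at most ``EXACT_N_MAX``, where the exact
    permutation distribution of H is enumerated over all assignments of the
    pooled observations to groups of the observed sizes.
    """
    groups = _as_groups(data)
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    h = _h_statistic(ranks, sizes)
    df = len(groups) - 1

    if np.ptp(pooled) == 0:
        return KruskalWallisResult(0.0, 1.0, df, "degenerate", n, tuple(sizes))

    if n <= EXACT_N_MAX:
        p = _exact_kw_p(ranks, sizes, h)
        method = "exact"
    else:
        p = float(sps.chi2.sf(h, df))
        method = "chi2"
    return KruskalWallisResult(h, p, df, method, n, tuple(sizes))


def _exact_kw_p(ranks: np.ndarray, sizes: Sequence[int], h_obs: float) -> float:
    """P(H >= h_obs) over all distinct assignments of ranks to groups."""
    n = len(ranks)
    count = 0
    total = 0
    idx = list(range(n))
    for assignment in _group_assignments(idx, sizes):
        perm = np.concatenate([ranks[list(g)] for g in assignment])
        h = _h_statistic(perm, sizes)
        total += 1
        if h >= h_obs - 1e-12:
            count += 1
    return count / total


def _group_assignments(indices: list[int], sizes: Sequence[int]):
    """All ways to partition ``indices`` into ordered groups of given sizes."""
    if len(sizes) == 1:
        yield (tuple(indices),)
        return
    first, rest = sizes[0], sizes[1:]
    for combo in itertools.combinations(indices, first):
        remaining = [i for i in indices if i not in combo]
        for tail in _group_assignments(remaining, rest):
            yield (combo,) + tail


# ---------------------------------------------------------------------------
# Conover-Iman post hoc


def conover_inman(
    data: Sequence[Sequence[float]],
    kw: KruskalWallisResult | None = None,
) -> dict[tuple[int, int], dict[str, float]]:
    """Conover-Iman pairwise rank comparisons after Kruskal-Wallis.

    Returns a dict keyed by group-index pair (i, j), each value holding
    ``t``, ``p`` (two-sided, df = N - k) and ``df``. Pairs involving a
    single-observation group are flagged untestable (``p`` = NaN).
    """
    groups = _as_groups(data)
    sizes = [len(g) for g in groups]
    k = len(groups)
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    if kw is None:
        kw = kruskal_wallis(data)
    h = kw.h

    mean_ranks = []
    i0 = 0
    for sz in sizes:
        mean_ranks.append(float(np.mean(ranks[i0: i0 + sz])))
        i0 += sz

    s2 = (np.sum(ranks**2) - n * (n + 1) ** 2 / 4.0) / (n - 1)
    df = n - k
    scale = s2 * (n - 1 - h) / df if df > 0 else np.nan

    out: dict[tuple[int, int], dict[str, float]] = {}
    for i, j in itertools.combinations(range(k), 2):
        if sizes[i] < 2 or sizes[j] < 2:
            out[(i, j)] = {"t": np.nan, "p": np.nan, "df": df,
                           "untestable": True}
            continue
        denom = np.sqrt(max(scale, 0.0) * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if denom == 0:
            t = 0.0 if mean_ranks[i] == mean_ranks[j] else np.inf
        else:
            t = (mean_ranks[i] - mean_ranks[j]) / denom
        p = float(2.0 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
        out[(i, j)] = {"t": float(t), "p": min(p, 1.0), "df": df,
                       "untestable": False}
    return out


# ---------------------------------------------------------------------------
# Bonferroni t tests


def bonferroni_ttests(
    data: Sequence[Sequence[float]],
    reference: int | None = None,
    run_anova: bool = True,
    anova_gatekeeper: bool = False,
    alpha: float = 0.05,
) -> dict:
    """Pairwise (or vs-reference) two-sample t tests with Bonferroni correction.

    Adjusted p = min(1, m * p_raw) where m is the number of comparisons.
    A one-way ANOVA over all groups is reported alongside; by default it is
    informational only, but with ``anova_gatekeeper=True`` all comparisons
    are declared non-significant when the ANOVA p exceeds ``alpha``.
    """
    groups = _as_groups(data)
    k = len(groups)
    if reference is not None and not (0 <= reference < k):
        raise ValueError("reference group index out of range")

    pairs = (
        [(reference, j) for j in range(k) if j != reference]
        if reference is not None
        else list(itertools.combinations(range(k), 2))
    )
    m = len(pairs)

    anova_p = np.nan
    if run_anova and all(len(g) >= 2 for g in groups):
        anova_p = float(sps.f_oneway(*groups).pvalue)
    gate_blocked = anova_gatekeeper and not (anova_p <= alpha)

    comparisons = {}
    for i, j in pairs:
        gi, gj = groups[i], groups[j]
        flags = []
        if np.var(gi) == 0 and np.var(gj) == 0:
            flags.append("zero_variance_in_both_groups")
            p_raw = 0.0 if np.mean(gi) != np.mean(gj) else 1.0
            t = np.inf if p_raw == 0.0 else 0.0
        else:
            t, p_raw = sps.ttest_ind(gi, gj)
            t, p_raw = float(t), float(p_raw)
        p_adj = min(1.0, m * p_raw)
        if gate_blocked:
            flags.append("anova_gate_not_passed")
        comparisons[(i, j)] = {
            "t": t, "p_raw": p_raw, "p_adjusted": p_adj,
            "significant": (p_adj <= alpha) and not gate_blocked,
            "flags": flags,
        }
    return {"comparisons": comparisons, "m": m, "anova_p": anova_p}
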