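"""Courtship-conditioning statistics.

The courtship index (CI) is the fraction of a 10-minute observation a male
spends courting; the memory index

    MI = (mean CI_naive - mean CI_trained) / mean CI_naive

is the fractional suppression of courtship attributable to training.  Naive
and trained CIs within a genotype are compared with a Mann-Whitney test;
memory indices *between* genotypes are compared with a randomization test on
the difference of MIs.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("flymb")

EXACT_MW_CUTOFF = 12  # combined sample size up to which the U null is enumerated


@dataclass
class CourtshipGroup:
    """Per-fly courtship indices for one genotype, split naive / trained."""

    genotype: str
    ci_naive: np.ndarray
    ci_trained: np.ndarray

    def __post_init__(self) -> None:
        self.ci_naive = np.asarray(self.ci_naive, dtype=float)
        self.ci_trained = np.asarray(self.ci_trained, dtype=float)
        for name, arr in (("ci_naive", self.ci_naive), ("ci_trained", self.ci_trained)):
            if arr.ndim != 1:
                raise ValueError(f"{name} must be one-dimensional")
            if len(arr) and ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"{name} values must lie in [0, 1]")


@dataclass(frozen=True)
class MemoryResult:
    mi: float
    mean_ci_naive: float
    mean_ci_trained: float
    n_naive: int
    n_trained: int


@dataclass(frozen=True)
class RandomizationConfig:
    """Settings for the between-genotype MI randomization test.

    ``scheme='permutation'`` reshuffles CI values between the two genotypes
    within each training condition (the exact label-randomization null);
    ``'bootstrap'`` resamples with replacement from the per-condition pools.
    """

    n_replicates: int = 10_000
    seed: int = 0
    scheme: str = "permutation"

    def __post_init__(self) -> None:
        if self.n_replicates < 100:
            raise ValueError("n_replicates must be >= 100")
        if self.scheme not in ("permutation", "bootstrap"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


def memory_index(group: CourtshipGroup) -> MemoryResult:
    """MI = (mean naive CI - mean trained CI) / mean naive CI.

    MI lies in (-inf, 1]: 1 means complete courtship suppression, 0 no
    memory, negative values more courtship after training than before.
    Undefined (raises) when the naive mean is zero.
    """
    if not len(group.ci_naive) or not len(group.ci_trained):
        raise ValueError("both naive and trained samples must be non-empty")
    mean_n = float(np.mean(group.ci_naive))
    mean_t = float(np.mean(group.ci_trained))
    if mean_n == 0:
        raise ZeroDivisionError("memory index undefined: mean naive CI is zero")
    return MemoryResult(mi=(mean_n - mean_t) / mean_n,
                        mean_ci_naive=mean_n, mean_ci_trained=mean_t,
                        n_naive=len(group.ci_naive), n_trained=len(group.ci_trained))


def relative_mi(mi_test: float, mi_control: float) -> float:
    """Memory index of a test genotype relative to its control (MI_test / MI_control)."""
    if mi_control == 0:
        raise ZeroDivisionError("relative MI undefined: control MI is zero")
    return mi_test / mi_control


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of sample a (ties counted as 1/2)."""
    ranks = stats.rankdata(np.concatenate([a, b]))
    r_a = ranks[: len(a)].sum()
    return float(r_a - len(a) * (len(a) + 1) / 2)


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    For combined n <= 12 the null is enumerated exhaustively over all label
    assignments (handles ties exactly); larger samples use the tie-corrected
    normal approximation with continuity correction.  Returns ``(U, p)`` with
    U the statistic of ``sample_a``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if not len(a) or not len(b):
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(a), len(b)
    u_obs = _u_statistic(a, b)
    mu = n1 * n2 / 2.0
    if n1 + n2 <= EXACT_MW_CUTOFF:
        pooled = np.concatenate([a, b])
        idx = range(n1 + n2)
        count = total = 0
        for combo in itertools.combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(combo)] = True
            u_star = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_star - mu) >= abs(u_obs - mu) - 1e-12:
                count += 1
        return u_obs, count / total
    # tie-corrected normal approximation
    pooled = np.concatenate([a, b])
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:  # all values identical
        return u_obs, 1.0
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = min(1.0, 2 * stats.norm.sf(z))
    return u_obs, p


def _group_mis_permutation(naive_pool, trained_pool, n_na, n_ta, rng, n_rep):
    """Vectorized label-permutation replicates of (MI_a - MI_b)."""
    deltas = np.empty(n_rep)
    filled = 0
    n_redrawn = 0
    while filled < n_rep:
        batch = n_rep - filled
        # independent permutations per replicate via random-key argsort
        na_idx = np.argsort(rng.random((batch, len(naive_pool))), axis=1)
        ta_idx = np.argsort(rng.random((batch, len(trained_pool))), axis=1)
        naive_perm = naive_pool[na_idx]
        trained_perm = trained_pool[ta_idx]
        mean_na = naive_perm[:, :n_na].mean(axis=1)
        mean_nb = naive_perm[:, n_na:].mean(axis=1)
        mean_ta = trained_perm[:, :n_ta].mean(axis=1)
        mean_tb = trained_perm[:, n_ta:].mean(axis=1)
        ok = (mean_na > 0) & (mean_nb > 0)
        n_redrawn += int((~ok).sum())
        good = np.nonzero(ok)[0]
        take = good[: n_rep - filled]
        mi_a = (mean_na[take] - mean_ta[take]) / mean_na[take]
        mi_b = (mean_nb[take] - mean_tb[take]) / mean_nb[take]
        deltas[filled: filled + len(take)] = mi_a - mi_b
        filled += len(take)
    return deltas, n_redrawn


def _group_mis_bootstrap(naive_pool, trained_pool, n_na, n_nb, n_ta, n_tb, rng, n_rep):
    deltas = np.empty(n_rep)
    filled = 0
    n_redrawn = 0
    while filled < n_rep:
        batch = n_rep - filled
        mean_na = naive_pool[rng.integers(0, len(naive_pool), (batch, n_na))].mean(axis=1)
        mean_nb = naive_pool[rng.integers(0, len(naive_pool), (batch, n_nb))].mean(axis=1)
        mean_ta = trained_pool[rng.integers(0, len(trained_pool), (batch, n_ta))].mean(axis=1)
        mean_tb = trained_pool[rng.integers(0, len(trained_pool), (batch, n_tb))].mean(axis=1)
        ok = (mean_na > 0) & (mean_nb > 0)
        n_redrawn += int((~ok).sum())
        good = np.nonzero(ok)[0]
        take = good[: n_rep - filled]
        mi_a = (mean_na[take] - mean_ta[take]) / mean_na[take]
        mi_b = (mean_nb[take] - mean_tb[take]) / mean_nb[take]
        deltas[filled: filled + len(take)] = mi_a - mi_b
        filled += len(take)
    return deltas, n_redrawn


def mi_randomization_test(group_a: CourtshipGroup, group_b: CourtshipGroup,
                          cfg: RandomizationConfig | None = None) -> tuple[float, float]:
    """Randomization test for a difference in memory index between genotypes.

    The observed statistic is ΔMI = MI_a - MI_b.  Under the null the CI
    values are exchangeable between genotypes within each training condition:
    naive CIs of both groups are pooled and redealt at the original group
    sizes (likewise trained), and ΔMI* recomputed per replicate.  The
    two-sided p-value uses +1 smoothing,

        p = (1 + #{|ΔMI*| >= |ΔMI_obs|}) / (n_replicates + 1),

    so p is never 0 and never exceeds 1.  Replicates whose resampled naive
    mean is zero cannot yield an MI; they are redrawn and counted in the log.
    """
    cfg = cfg or RandomizationConfig()
    res_a = memory_index(group_a)
    res_b = memory_index(group_b)
    delta_obs = res_a.mi - res_b.mi

    naive_pool = np.concatenate([group_a.ci_naive, group_b.ci_naive])
    trained_pool = np.concatenate([group_a.ci_trained, group_b.ci_trained])
    rng = np.random.default_rng(cfg.seed)
    if cfg.scheme == "permutation":
        deltas, n_redrawn = _group_mis_permutation(
            naive_pool, trained_pool, res_a.n_naive, res_a.n_trained, rng, cfg.n_replicates)
    else:
        deltas, n_redrawn = _group_mis_bootstrap(
            naive_pool, trained_pool, res_a.n_naive, res_b.n_naive,
            res_a.n_trained, res_b.n_trained, rng, cfg.n_replicates)
    if n_redrawn:
        logger.info("mi_randomization_test: redrew %d replicate(s) with zero naive mean",
                    n_redrawn)
    n_extreme = int((np.abs(deltas) >= abs(delta_obs) - 1e-12).sum())
    p = (1 + n_extreme) / (cfg.n_replicates + 1)
    return delta_obs, p


def read_ci_table(path) -> dict[str, CourtshipGroup]:
    """Read a TSV of (fly_id, genotype, condition in {naive, trained}, ci) into groups."""
    df = pd.read_csv(path, sep="\t")
    required = {"fly_id", "genotype", "condition", "ci"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"CI table missing columns: {sorted(missing)}")
    bad = set(df["condition"]) - {"naive", "trained"}
    if bad:
        raise ValueError(f"unknown condition value(s): {sorted(bad)}")
    groups = {}
    for genotype, sub in df.groupby("genotype", sort=True):
        groups[str(genotype)] = CourtshipGroup(
            genotype=str(genotype),
            ci_naive=sub.loc[sub["condition"] == "naive", "ci"].to_numpy(float),
            ci_trained=sub.loc[sub["condition"] == "trained", "ci"].to_numpy(float),
        )
    return groups
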