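"""Exact nonparametric inference for small paired samples.

The study's group unit is the hemisphere (N = 8), so every reported p-value
is a quantile of the exact Wilcoxon signed-rank null: under the null each of
the 2^N sign assignments of the ranked |differences| is equally likely. The
test statistic W is the smaller of the two signed rank sums and the two-sided
p-value is 2 * P(W_null <= W_obs), capped at 1 — at N = 8 this yields the
discrete values {2k/256}. The null CDF is computed by a subset-sum dynamic
program, which is an exact (and fast) equivalent of enumerating all 2^N sign
patterns; ties in |d| receive average ranks.

Effect sizes are reported as r_equivalent: the one-tailed p-value is mapped
to a Student-t quantile with df = N - 1 and converted to the equivalent
correlation sqrt(t^2 / (t^2 + df)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "exact_signed_rank",
    "signed_rank_null_counts",
    "r_equivalent",
    "fdr_correct",
    "trial_label_permutation",
    "distance_decay_fit",
    "interaction_contrast",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float        # W, the smaller signed rank sum (or perm stat)
    p_value: float
    effect_size: float      # r_equivalent
    n: int
    method: str

    def as_row(self, comparison: str) -> dict:
        return {"comparison": comparison, "N": self.n, "W": self.statistic,
                "p": self.p_value, "r_e": self.effect_size,
                "method": self.method}


def signed_rank_null_counts(ranks: np.ndarray) -> tuple[np.ndarray, int]:
    """Null distribution of the positive-rank sum for given |d| ranks.

    Returns ``(counts, denom)`` where ``counts[s]`` is the number of sign
    assignments whose positive-rank sum equals ``s/2`` (ranks are doubled
    internally so average ranks from ties stay integral) and ``denom = 2^N``.
    Identical to brute-force enumeration of all sign patterns.
    """
    doubled = np.round(2 * np.asarray(ranks, float)).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=object)
    counts[0] = 1
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:counts.size - r]
        counts = counts + shifted
    return counts, 2 ** len(doubled)


def exact_signed_rank(values_a: np.ndarray,
                      values_b: np.ndarray | None = None) -> TestResult:
    """Exact two-sided Wilcoxon signed-rank test on paired differences.

    ``values_b`` defaults to zeros (test of the median difference against 0).
    Zero differences are dropped with a warning; tied |d| get average ranks.
    """
    a = np.asarray(values_a, float)
    b = np.zeros_like(a) if values_b is None else np.asarray(values_b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    nz = d != 0
    if not nz.all():
        warnings.warn(f"dropping {int((~nz).sum())} zero difference(s)")
        d = d[nz]
    n = d.size
    if n < 2:
        # all differences zero (or a single pair): no evidence either way
        return TestResult(0.0, 1.0, 0.0, n, "exact_signed_rank")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    counts, denom = signed_rank_null_counts(ranks)
    w2 = int(np.floor(2 * w + 1e-9))
    cdf = float(sum(counts[:w2 + 1])) / denom
    p = min(1.0, 2.0 * cdf)
    r_e = r_equivalent(p, n) if n >= 3 else 0.0
    return TestResult(w, p, r_e, n, "exact_signed_rank")


def r_equivalent(p_two_sided: float, n: int) -> float:
    """Effect size r_e from a two-sided p-value and sample size.

    The one-tailed p (= p/2) is converted to a t quantile with df = n - 1,
    and returned as the equivalent correlation sqrt(t^2/(t^2 + df)).
    """
    if not (0.0 < p_two_sided <= 1.0):
        raise ValueError("p must lie in (0, 1]")
    if n < 3:
        raise ValueError("r_equivalent requires n >= 3")
    df = n - 1
    t = sps.t.ppf(1.0 - p_two_sided / 2.0, df)
    t = max(t, 0.0)
    return float(np.sqrt(t * t / (t * t + df)))


def fdr_correct(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask at level ``q``."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def trial_label_permutation(trial_values_a: np.ndarray,
                            trial_values_b: np.ndarray,
                            n_perm: int = 1000, seed: int = 0) -> float:
    """Permutation p-value for a difference of group means.

    Group labels are shuffled across the pooled trials ``n_perm`` times;
    p = (1 + #{|perm stat| >= |observed|}) / (n_perm + 1).
    """
    a = np.asarray(trial_values_a, float)
    b = np.asarray(trial_values_b, float)
    if a.size < 5 or b.size < 5:
        raise ValueError("need at least 5 trials per group")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("constant data; permutation test is degenerate")
        return 1.0
    obs = abs(a.mean() - b.mean())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = abs(perm[:a.size].mean() - perm[a.size:].mean())
        if stat >= obs - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)


def distance_decay_fit(distances: np.ndarray, hemispheres: np.ndarray,
                       alpha_db: np.ndarray,
                       min_contacts: int = 3):
    """Per-hemisphere linear fit of alpha power (dB) on distance (mm).

    Suppression originating in alHG predicts less-negative alpha change with
    increasing distance from the alHG centroid, i.e. positive slopes. Returns
    ``(fits, group)`` where ``fits`` is a list of dicts (hemisphere, slope,
    intercept, n) and ``group`` the exact signed-rank test of the slopes
    against zero. Hemispheres with fewer than ``min_contacts`` usable
    contacts are excluded with a warning.
    """
    distances = np.asarray(distances, float)
    hemispheres = np.asarray(hemispheres)
    alpha_db = np.asarray(alpha_db, float)
    fits = []
    for h in np.unique(hemispheres):
        m = (hemispheres == h) & np.isfinite(distances) & np.isfinite(alpha_db)
        if m.sum() < min_contacts:
            warnings.warn(f"hemisphere {h}: fewer than {min_contacts} "
                          "contacts; excluded from the distance-decay fit")
            continue
        slope, intercept = np.polyfit(distances[m], alpha_db[m], 1)
        scale = max(np.abs(alpha_db[m]).max(), 1.0)
        if abs(slope) < 1e-10 * scale:  # constant data: exactly-zero slope
            slope = 0.0
        fits.append({"hemisphere": h, "slope": float(slope),
                     "intercept": float(intercept), "n": int(m.sum())})
    slopes = np.array([f["slope"] for f in fits])
    group = exact_signed_rank(slopes)
    return fits, group


def interaction_contrast(cell_means: np.ndarray) -> TestResult:
    """Stimulus-by-region interaction from per-hemisphere 2x2 cell means.

    ``cell_means`` has shape (n_hemispheres, 2, 2) with axis 1 = region
    (pmHG, alHG) and axis 2 = condition (clear, vocoded). The per-hemisphere
    contrast (alHG_clear - alHG_vocoded) - (pmHG_clear - pmHG_vocoded) is
    tested against zero with the exact signed-rank test.
    """
    cm = np.asarray(cell_means, float)
    if cm.ndim != 3 or cm.shape[1:] != (2, 2):
        raise ValueError("cell means must be (n_hemispheres, 2 regions, 2 conditions)")
    ok = np.isfinite(cm).all(axis=(1, 2))
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} hemisphere(s) with "
                      "missing cells")
        cm = cm[ok]
    contrast = (cm[:, 1, 0] - cm[:, 1, 1]) - (cm[:, 0, 0] - cm[:, 0, 1])
    return exact_signed_rank(contrast)
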