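"""Statistical comparison of paired stance trajectories and 0-D summaries.

The modality comparison (radiograph-based vs MRI-based models of the same
subjects) uses:

- classical paired t-tests with two-sided confidence intervals for 0-D
  quantities (anatomical dimensions, per-subject stance means), with
  Shapiro-Wilk normality screening;
- ICC(3,1) (two-way mixed, consistency, single measure) for intra-rater
  reliability of triplicate measurements;
- 1-D statistical parametric mapping (SPM) over the stance grid for whole
  trajectories. The default inference is nonparametric: the critical
  threshold t* is the (1 - alpha) quantile of the maximum-|t| distribution
  over sign-flip permutations of the paired differences (exhaustive when
  2^n does not exceed the permutation budget), which controls the
  family-wise error over the whole trajectory.

Pointwise t statistics are delegated to scipy; the permutation layer and
cluster extraction are the in-house contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedTResult",
    "ICCResult",
    "SPMResult",
    "Cluster",
    "shapiro_wilk",
    "paired_t_ci",
    "icc_intra_rater",
    "spm_paired_t",
    "spm_threshold_permutation",
    "find_clusters",
    "spm_paired_test",
]


class DegenerateSampleError(ValueError):
    """Sample has no variance (or is otherwise degenerate) for this test."""


def shapiro_wilk(sample: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value for 3 <= n <= 5000."""
    x = np.asarray(sample, dtype=float)
    if not (3 <= len(x) <= 5000):
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("constant sample: W undefined")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    mean_difference: float
    ci_low: float
    ci_high: float
    df: int
    alpha: float
    degenerate: bool = False


def paired_t_ci(
    a: np.ndarray, b: np.ndarray, alpha: float = 0.05
) -> PairedTResult:
    """Classical paired t-test on a - b with a two-sided (1-alpha) CI."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0:
        return PairedTResult(
            t=0.0, p=1.0, mean_difference=md, ci_low=md, ci_high=md,
            df=df, alpha=alpha, degenerate=True,
        )
    se = sd / np.sqrt(n)
    t = md / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    tcrit = float(sps.t.ppf(1.0 - alpha / 2.0, df))
    return PairedTResult(
        t=float(t), p=p, mean_difference=md,
        ci_low=md - tcrit * se, ci_high=md + tcrit * se,
        df=df, alpha=alpha,
    )


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ms_rows: float
    ms_error: float
    n_subjects: int
    n_repeats: int
    degenerate: bool = False


def icc_intra_rater(repeats: np.ndarray) -> ICCResult:
    """ICC(3,1): two-way mixed effects, consistency, single measure.

    ``repeats`` is (n_subjects, n_repeats). The repeat occasion is the
    fixed "rater" factor; ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E) from
    the two-way ANOVA decomposition.
    """
    x = np.asarray(repeats, dtype=float)
    if x.ndim != 2:
        raise ValueError("repeats must be (subjects, repeats)")
    n, k = x.shape
    if n < 5 or k < 2:
        raise ValueError("need >= 5 subjects and >= 2 repeats")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err
    if denom <= 0:
        return ICCResult(icc=float("nan"), ms_rows=ms_rows, ms_error=ms_err,
                         n_subjects=n, n_repeats=k, degenerate=True)
    return ICCResult(
        icc=float((ms_rows - ms_err) / denom),
        ms_rows=float(ms_rows), ms_error=float(ms_err),
        n_subjects=n, n_repeats=k,
    )


# ------------------------------------------------------------------ 1-D SPM


@dataclass(frozen=True)
class Cluster:
    start_pct: float
    end_pct: float
    max_abs_t: float


@dataclass(frozen=True)
class SPMResult:
    t: np.ndarray  # pointwise paired t over the stance grid
    t_star: float  # critical threshold
    alpha: float
    clusters: tuple[Cluster, ...]
    method: str  # {"permutation"}
    stance_pct: np.ndarray
    n_permutations: int


def _pointwise_paired_t(d: np.ndarray) -> np.ndarray:
    """Paired t statistic per grid point for differences (subjects, grid)."""
    n = d.shape[0]
    md = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    sd = np.where(sd == 0, np.inf, sd)  # zero-variance points -> t = 0
    return md / (sd / np.sqrt(n))


def spm_paired_t(traj_a: np.ndarray, traj_b: np.ndarray) -> np.ndarray:
    """Pointwise paired t trajectory for (subjects, grid) arrays."""
    a = np.asarray(traj_a, dtype=float)
    b = np.asarray(traj_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("trajectories must be equal-shape (subjects, grid) arrays")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    return _pointwise_paired_t(a - b)


def spm_threshold_permutation(
    differences: np.ndarray,
    alpha: float = 0.05,
    n_permutations: int = 10000,
    seed: int | None = None,
) -> float:
    """Critical max-|t| threshold by sign-flip permutation.

    Exhausts all 2^n sign patterns when feasible within the budget,
    otherwise samples ``n_permutations`` random sign vectors. Returns the
    (1 - alpha) quantile of the permutation distribution of max_q |t(q)|.
    """
    d = np.asarray(differences, dtype=float)
    n = d.shape[0]
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    if 2**n <= n_permutations:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([1.0, -1.0], size=(n_permutations, n))
    # max-|t| over the grid for every sign assignment, vectorized in chunks
    maxt = np.empty(len(signs))
    chunk = max(1, int(2.0e7 // max(1, d.size)))
    for i in range(0, len(signs), chunk):
        s = signs[i : i + chunk]  # (c, n)
        ds = s[:, :, None] * d[None, :, :]  # (c, n, grid)
        md = ds.mean(axis=1)
        sd = ds.std(axis=1, ddof=1)
        sd = np.where(sd == 0, np.inf, sd)
        t = md / (sd / np.sqrt(n))
        maxt[i : i + chunk] = np.abs(t).max(axis=1)
    return float(np.quantile(maxt, 1.0 - alpha))


def find_clusters(
    t: np.ndarray, t_star: float, stance_pct: np.ndarray | None = None
) -> list[Cluster]:
    """Maximal contiguous intervals where |t| exceeds the threshold."""
    t = np.asarray(t, dtype=float)
    if stance_pct is None:
        stance_pct = np.linspace(0.0, 100.0, len(t))
    supra = np.abs(t) > t_star
    clusters = []
    i = 0
    while i < len(t):
        if supra[i]:
            j = i
            while j + 1 < len(t) and supra[j + 1]:
                j += 1
            clusters.append(
                Cluster(
                    start_pct=float(stance_pct[i]),
                    end_pct=float(stance_pct[j]),
                    max_abs_t=float(np.abs(t[i : j + 1]).max()),
                )
            )
            i = j + 1
        else:
            i += 1
    return clusters


def spm_paired_test(
    traj_a: np.ndarray,
    traj_b: np.ndarray,
    stance_pct: np.ndarray | None = None,
    alpha: float = 0.05,
    n_permutations: int = 10000,
    seed: int | None = None,
) -> SPMResult:
    """Full nonparametric paired 1-D SPM: t trajectory, threshold, clusters.

    Grid points that are NaN in any subject (e.g. empty contact region at
    that stance instant) are excluded pairwise; the retained grid is
    reported in the result.
    """
    a = np.asarray(traj_a, dtype=float)
    b = np.asarray(traj_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("trajectories must be equal-shape (subjects, grid) arrays")
    n, m = a.shape
    if stance_pct is None:
        stance_pct = np.linspace(0.0, 100.0, m)
    keep = ~(np.isnan(a).any(axis=0) | np.isnan(b).any(axis=0))
    d = (a - b)[:, keep]
    grid = np.asarray(stance_pct, dtype=float)[keep]
    if d.shape[1] == 0:
        raise ValueError("no grid points with complete data")
    t = _pointwise_paired_t(d)
    t_star = spm_threshold_permutation(d, alpha=alpha, n_permutations=n_permutations, seed=seed)
    clusters = tuple(find_clusters(t, t_star, grid))
    n_perm = min(n_permutations, 2**n) if 2**n <= n_permutations else n_permutations
    return SPMResult(
        t=t, t_star=t_star, alpha=alpha, clusters=clusters,
        method="permutation", stance_pct=grid, n_permutations=n_perm,
    )
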