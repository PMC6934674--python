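"""Monthly-matched subsampling, the estimated forest network, and
randomization comparisons of road vs forest network metrics.

Observation effort differs between contexts: the group spends far more
scans in the forest than along the road.  To compare like with like, the
*estimated* forest network averages dyadic HWI values over repeated random
subsamples of forest scans, each subsample matching the road context's scan
count month by month.  Per-individual differences in a network metric
between the road and estimated-forest networks are then tested against a
randomization null.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import AssociationMatrix
from .metrics import MetricTable
from .scan_data import Roster


def _month_key(d) -> str:
    return f"{d.year:04d}-{d.month:02d}"


@dataclass
class SubsamplePlan:
    """How many forest scans to draw per month, mirroring the road pattern."""

    per_month_quota: dict[str, int]
    n_samples: int = 100
    seed: int = 0


def plan_from_road(scans: pd.DataFrame, n_samples: int = 100, seed: int = 0) -> SubsamplePlan:
    """Quota per month = number of distinct road-context scans that month."""
    road = scans[scans["context"] == "road"]
    months = road["date"].map(_month_key)
    quota = road.groupby(months)["scan_id"].nunique().to_dict()
    return SubsamplePlan(per_month_quota={m: int(q) for m, q in sorted(quota.items())}, n_samples=n_samples, seed=seed)


def monthly_matched_subsamples(scans: pd.DataFrame, plan: SubsamplePlan) -> list[set[int]]:
    """Draw ``plan.n_samples`` sets of forest scan ids matching monthly quotas.

    Sampling is without replacement within month; draws are seeded and
    invariant to the input row order (scan ids are sorted before sampling).
    Raises if a month's quota exceeds the forest scans available there.
    """
    forest = scans[scans["context"] == "forest"]
    months = forest["date"].map(_month_key)
    available = {m: sorted(g.unique()) for m, g in forest.groupby(months)["scan_id"]}
    for month, quota in plan.per_month_quota.items():
        have = len(available.get(month, []))
        if quota > have:
            raise ValueError(
                f"month {month}: quota {quota} exceeds available forest scans ({have})"
            )
    rng = np.random.default_rng(plan.seed)
    samples: list[set[int]] = []
    for _ in range(plan.n_samples):
        chosen: set[int] = set()
        for month in sorted(plan.per_month_quota):
            quota = plan.per_month_quota[month]
            if quota <= 0:
                continue
            pool = available[month]
            chosen.update(rng.choice(pool, size=quota, replace=False).tolist())
        samples.append(chosen)
    return samples


def estimated_network(
    samples: list[set[int]],
    scans: pd.DataFrame,
    roster: Roster,
    data_type: str,
    interactions: pd.DataFrame | None = None,
    context: str = "forest",
    affiliative_states=None,
) -> AssociationMatrix:
    """Mean HWI matrix over subsamples (the 'estimated' network).

    For each sample the sighting counts and joint counts are recomputed on
    that sample's scans only, the HWI matrix formed, and matrices averaged
    entry-wise across samples.
    """
    if not samples:
        raise ValueError("at least one subsample required")
    ids = roster.ids
    idx = {i: k for k, i in enumerate(ids)}
    n = len(ids)

    sub = scans[scans["context"] == context]
    # per-scan building blocks, computed once and masked per sample
    sight_rows = sub[["scan_id", "individual_id"]].drop_duplicates()
    sight_scan = sight_rows["scan_id"].to_numpy()
    sight_ind = sight_rows["individual_id"].map(idx).to_numpy()

    if data_type == "proximity":
        pair_set: set[tuple[int, int, int]] = set()
        for row in sub.itertuples(index=False):
            a = idx.get(row.individual_id)
            if a is None:
                continue
            for nb in row.neighbours:
                b = idx.get(nb)
                if b is not None:
                    pair_set.add((row.scan_id, min(a, b), max(a, b)))
        pairs = np.array(sorted(pair_set), dtype=int).reshape(-1, 3)
    elif data_type == "affiliative":
        if interactions is None:
            raise ValueError("interactions required for affiliative estimated network")
        isub = interactions[interactions["context"] == context]
        if affiliative_states is not None and len(isub):
            states = scans.set_index(["scan_id", "individual_id"])["state"]
            keys = pd.MultiIndex.from_frame(isub[["scan_id", "actor"]])
            st = states.reindex(keys)
            isub = isub[st.isna().to_numpy() | st.isin(affiliative_states).to_numpy()]
        uniq = isub.drop_duplicates(subset=["scan_id", "actor", "recipient"])
        pairs = np.column_stack(
            [
                uniq["scan_id"].to_numpy(dtype=int),
                uniq["actor"].map(idx).to_numpy(dtype=int),
                uniq["recipient"].map(idx).to_numpy(dtype=int),
            ]
        ) if len(uniq) else np.zeros((0, 3), dtype=int)
    else:
        raise ValueError(f"unknown data_type {data_type!r}")

    acc = np.zeros((n, n))
    first: np.ndarray | None = None
    all_same = True
    for sample in samples:
        in_sample = np.isin(sight_scan, list(sample))
        n_vec = np.bincount(sight_ind[in_sample], minlength=n).astype(float)
        joint = np.zeros((n, n))
        if len(pairs):
            mask = np.isin(pairs[:, 0], list(sample))
            np.add.at(joint, (pairs[mask, 1], pairs[mask, 2]), 1.0)
            if data_type == "proximity":
                joint = joint + joint.T
        denom = n_vec[:, None] + n_vec[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            mat = np.where(denom > 0, 2.0 * joint / denom, 0.0)
        np.fill_diagonal(mat, 0.0)
        acc += mat
        if first is None:
            first = mat
        elif all_same and not np.array_equal(first, mat):
            all_same = False
    # degenerate quota (every sample = the full scan pool) must reproduce the
    # comprehensive matrix bit-exactly, so skip the lossy divide when all
    # per-sample matrices coincide
    acc = first if all_same else acc / len(samples)
    return AssociationMatrix(ids=list(ids), context=context, data_type=data_type, hwi=acc)


def spearman_validate(
    metrics_a: MetricTable | pd.Series,
    metrics_b: MetricTable | pd.Series,
    metric: str | None = None,
) -> tuple[float, float]:
    """Spearman rank correlation between two networks' values of one metric.

    Ties take average ranks.  For n ≤ 9 the p-value is exact, computed by
    enumerating all rank permutations; otherwise the t-approximation is used.
    A constant vector makes rho undefined (returned as NaN with a warning).
    """
    a = metrics_a.metric(metric) if isinstance(metrics_a, MetricTable) else metrics_a
    b = metrics_b.metric(metric) if isinstance(metrics_b, MetricTable) else metrics_b
    a, b = a.align(b, join="inner")
    if set(a.index) != set(b.index) or len(a) == 0:
        raise ValueError("metric vectors must share a non-empty node set")
    x, y = a.to_numpy(float), b.to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant metric vector: Spearman rho undefined")
        return float("nan"), float("nan")
    rho = float(stats.spearmanr(x, y).statistic)
    n = len(x)
    if n <= 9:
        ry = stats.rankdata(y)
        rx = stats.rankdata(x)
        perms = np.array(list(itertools.permutations(range(n))))
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        rhos = (rx_c[perms] * ry_c).sum(axis=1) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def metric_differences(road: MetricTable, est_forest: MetricTable, metric: str) -> pd.Series:
    """Per-individual road − estimated-forest differences for one metric.

    Positive values mean the metric is greater along the road.
    """
    r = road.metric(metric)
    f = est_forest.metric(metric)
    if set(r.index) != set(f.index):
        raise ValueError("road and forest metric tables cover different individuals")
    return (r - f.reindex(r.index)).rename(f"diff_{metric}")


@dataclass
class ComparisonResult:
    """Outcome of the randomization test on one metric's paired differences."""

    metric: str
    data_type: str
    observed_mean: float
    observed_sd: float
    null_mean: float
    null_sd: float
    p_value: float
    direction: str  # "greater along road" / "greater in forest" / "no difference"
    mode: str = "sign_flip"
    n_resamples: int = 10_000
    null_means: np.ndarray | None = field(default=None, repr=False)

    def to_row(self) -> dict:
        return {
            "data_type": self.data_type,
            "metric": self.metric,
            "direction": self.direction,
            "observed_mean_diff": self.observed_mean,
            "observed_sd": self.observed_sd,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "p_value": self.p_value,
            "mode": self.mode,
        }


def randomization_test(
    diffs: pd.Series | np.ndarray,
    n_resamples: int = 10_000,
    mode: str = "sign_flip",
    seed: int | None = None,
    metric: str = "",
    data_type: str = "",
    exhaustive: bool = False,
) -> ComparisonResult:
    """Two-tailed randomization test on paired metric differences.

    ``mode='sign_flip'`` (default) draws each resample by flipping the sign
    of every difference independently — the standard paired randomization
    null of symmetry about zero.  ``mode='centered_bootstrap'`` resamples
    with replacement from the mean-centered differences and compares
    resampled means to the observed mean.  ``exhaustive=True`` (sign-flip
    only, n ≤ 20) enumerates all 2^n sign assignments and returns the exact
    p = #{|mean*| ≥ |mean_obs|} / 2^n; Monte-Carlo p-values carry an add-one
    correction so p > 0 always.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("at least two paired differences required")
    obs_mean = float(d.mean())
    obs_sd = float(d.std(ddof=1))
    if np.all(d == 0):
        warnings.warn("all differences are zero; p = 1")
        return ComparisonResult(metric, data_type, 0.0, 0.0, 0.0, 0.0, 1.0, "no difference", mode, 0)

    n = d.size
    tol = 1e-12 * max(1.0, abs(obs_mean))
    if mode == "sign_flip":
        if exhaustive:
            if n > 20:
                raise ValueError("exhaustive sign-flip enumeration limited to n <= 20")
            signs = np.array(list(itertools.product([1.0, -1.0], repeat=n)))
            null = signs @ d / n
            p = float(np.mean(np.abs(null) >= abs(obs_mean) - tol))
            n_used = len(null)
        else:
            rng = np.random.default_rng(seed)
            signs = rng.choice([-1.0, 1.0], size=(n_resamples, n))
            null = signs @ d / n
            p = float((1 + np.sum(np.abs(null) >= abs(obs_mean) - tol)) / (1 + n_resamples))
            n_used = n_resamples
    elif mode == "centered_bootstrap":
        rng = np.random.default_rng(seed)
        centered = d - obs_mean
        draws = rng.choice(centered, size=(n_resamples, n), replace=True)
        null = draws.mean(axis=1)
        p = float((1 + np.sum(np.abs(null) >= abs(obs_mean) - tol)) / (1 + n_resamples))
        n_used = n_resamples
    else:
        raise ValueError(f"unknown mode {mode!r}")

    direction = "greater along road" if obs_mean > 0 else "greater in forest" if obs_mean < 0 else "no difference"
    return ComparisonResult(
        metric=metric,
        data_type=data_type,
        observed_mean=obs_mean,
        observed_sd=obs_sd,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        p_value=p,
        direction=direction,
        mode=mode,
        n_resamples=n_used,
        null_means=null,
    )


def comparison_table(results: list[ComparisonResult]) -> pd.DataFrame:
    """Tidy table of randomization-test outcomes (one row per metric/type)."""
    return pd.DataFrame([r.to_row() for r in results])
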