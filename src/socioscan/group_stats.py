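"""Age-sex-class summaries: risk perception via nearest-neighbour counts,
and per-class mean differences in network metrics across contexts.

Risk perception is probed by comparing, within each age-sex class, the
number of conspecifics within 1 m per behavioural record between road and
forest contexts (closer spacing in a context suggests it is perceived as
riskier).  Records are treated as independent observations in the
Mann-Whitney U test, replicating the field convention; the resulting
pseudo-replication caveat is documented rather than corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import MetricTable, NODE_METRICS
from .resampling import metric_differences
from .scan_data import Roster


@dataclass
class NeighbourSample:
    """Per-record nearest-neighbour counts for one age-sex class × context."""

    age_sex_class: str
    context: str
    values: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.values.mean()) if self.values.size else float("nan")

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1)) if self.values.size > 1 else 0.0


def neighbour_counts(scans: pd.DataFrame, roster: Roster) -> dict[tuple[str, str], NeighbourSample]:
    """One neighbour count per scan record, grouped by class × context."""
    classes = roster.age_sex_classes()
    counts = scans["neighbours"].map(len).to_numpy()
    cls = scans["individual_id"].map(classes)
    out: dict[tuple[str, str], NeighbourSample] = {}
    for (c, ctx), idx in scans.groupby([cls, "context"]).groups.items():
        vals = counts[scans.index.get_indexer(idx)]
        out[(c, ctx)] = NeighbourSample(age_sex_class=c, context=ctx, values=np.sort(vals)[::-1])
    present = {c for c, _ in out}
    for c in set(classes.values()):
        for ctx in ("road", "forest"):
            if (c, ctx) not in out:
                if c in present:
                    warnings.warn(f"class {c!r} has no {ctx} records; empty sample")
                out[(c, ctx)] = NeighbourSample(c, ctx, np.array([], dtype=int))
    return out


def neighbour_summary(samples: dict[tuple[str, str], NeighbourSample]) -> pd.DataFrame:
    """Tidy mean ± sd of neighbour counts per class × context."""
    rows = [
        {
            "age_sex_class": s.age_sex_class,
            "context": s.context,
            "n_records": int(s.values.size),
            "mean": s.mean,
            "sd": s.sd,
        }
        for s in samples.values()
    ]
    return pd.DataFrame(rows).sort_values(["age_sex_class", "context"]).reset_index(drop=True)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U with a two-tailed p-value.

    Midranks handle ties in U.  The p-value is exact (full labeling
    enumeration) when the pooled sample size is ≤ 12 and tie-free, and the
    normal approximation with tie and continuity corrections otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (pooled.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def risk_perception_tests(
    samples: dict[tuple[str, str], NeighbourSample]
) -> pd.DataFrame:
    """Road-vs-forest Mann-Whitney U per age-sex class on neighbour counts."""
    rows = []
    classes = sorted({c for c, _ in samples})
    for c in classes:
        road = samples.get((c, "road"))
        forest = samples.get((c, "forest"))
        if road is None or forest is None or road.values.size == 0 or forest.values.size == 0:
            warnings.warn(f"class {c!r}: missing road or forest records; test skipped")
            continue
        u, p = mann_whitney_u(road.values, forest.values)
        rows.append(
            {
                "age_sex_class": c,
                "road_mean": road.mean, "road_sd": road.sd, "n_road": road.values.size,
                "forest_mean": forest.mean, "forest_sd": forest.sd, "n_forest": forest.values.size,
                "U": u, "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def class_metric_differences(
    road: MetricTable,
    est_forest: MetricTable,
    roster: Roster,
    metrics=NODE_METRICS,
) -> pd.DataFrame:
    """Mean ± sd of per-individual road − forest differences per class.

    Single-member classes get sd = 0 with ``single_member=True`` flagged so
    the table stays deterministic and complete.  Classes absent from the
    roster are simply omitted (with a warning when expected elsewhere).
    """
    classes = roster.age_sex_classes()
    rows = []
    order = []
    for i in roster.ids:
        if classes[i] not in order:
            order.append(classes[i])
    for metric in metrics:
        diffs = metric_differences(road, est_forest, metric)
        cls = pd.Series({i: classes[i] for i in diffs.index})
        for c in order:
            vals = diffs[cls == c]
            if vals.empty:
                warnings.warn(f"class {c!r} absent from metric tables; omitted")
                continue
            rows.append(
                {
                    "age_sex_class": c,
                    "metric": metric,
                    "n": int(vals.size),
                    "mean_diff": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    "single_member": vals.size == 1,
                }
            )
    return pd.DataFrame(rows)
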