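"""Half-weight association indices (HWI) by context and data type.

The HWI for a dyad (A, B) is ``2N / (n_A + n_B)`` where ``2N`` counts the
joint sightings of A and B and ``n_A``, ``n_B`` their total sightings, all
restricted to one context (road or forest).  It estimates the proportion of
time a dyad spends together while correcting for unequal observation effort
per individual.

Two data types are supported:

* ``proximity`` — a joint sighting is one scan in which A and B were within
  1 m of each other.  Reciprocal records (A lists B, B lists A) in the same
  scan count once, so the matrix is symmetric.
* ``affiliative`` — a joint sighting is one scan containing at least one
  directed A→B interaction.  The numerator is directed (A→B and B→A are
  counted separately) over the undirected denominator n_A + n_B, so the
  matrix is generally asymmetric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .scan_data import CONTEXTS, Roster, SightingCounts

DATA_TYPES = ("proximity", "affiliative")

#: Behavioural states whose scan rows mark affiliative engagement; used when
#: filtering interaction records by the actor's recorded state.
DEFAULT_AFFILIATIVE_STATES = frozenset({"affiliative", "grooming", "play"})


@dataclass
class DyadCounts:
    """Joint-sighting counts N(A, B) for one (context, data type) stratum."""

    context: str
    data_type: str
    ids: list[str]
    joint: np.ndarray  # (n, n) int; symmetric for proximity

    def __post_init__(self):
        if self.data_type not in DATA_TYPES:
            raise ValueError(f"unknown data_type {self.data_type!r}")
        if (self.joint < 0).any():
            raise ValueError("negative joint counts")
        if self.data_type == "proximity" and not np.array_equal(self.joint, self.joint.T):
            raise ValueError("proximity joint counts must be symmetric")

    def __getitem__(self, dyad: tuple[str, str]) -> int:
        a, b = dyad
        idx = {i: k for k, i in enumerate(self.ids)}
        return int(self.joint[idx[a], idx[b]])


@dataclass
class AssociationMatrix:
    """Dense per-dyad HWI values for one (context, data type) stratum."""

    ids: list[str]
    context: str
    data_type: str
    hwi: np.ndarray  # (n, n) float in [0, 1], zero diagonal

    @property
    def directed(self) -> bool:
        return self.data_type == "affiliative"

    def __getitem__(self, dyad: tuple[str, str]) -> float:
        idx = {i: k for k, i in enumerate(self.ids)}
        return float(self.hwi[idx[dyad[0]], idx[dyad[1]]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.hwi, index=self.ids, columns=self.ids)

    def to_edgelist(self) -> pd.DataFrame:
        """Nonzero entries as (from, to, weight); each dyad once if undirected."""
        rows = []
        n = len(self.ids)
        for i in range(n):
            cols = range(n) if self.directed else range(i + 1, n)
            for j in cols:
                if i != j and self.hwi[i, j] > 0:
                    rows.append((self.ids[i], self.ids[j], float(self.hwi[i, j])))
        return pd.DataFrame(rows, columns=["from", "to", "weight"])

    def write_csv(self, matrix_path: str | Path, edgelist_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(matrix_path, index_label="id")
        if edgelist_path is not None:
            self.to_edgelist().to_csv(edgelist_path, index=False)


def joint_counts(
    records: pd.DataFrame,
    context: str,
    data_type: str,
    roster: Roster,
    scans: pd.DataFrame | None = None,
    affiliative_states: frozenset[str] | None = None,
    scan_ids: set | None = None,
) -> DyadCounts:
    """Count joint sightings per dyad within one context.

    For ``data_type='proximity'``, ``records`` is the scan table; a dyad's
    count increments once per scan in which either member lists the other as
    a neighbour.  For ``'affiliative'``, ``records`` is the interaction
    table; N(A→B) counts scans containing at least one A→B record.  When
    ``affiliative_states`` is given together with ``scans``, interaction
    records whose actor's recorded state in that scan falls outside the set
    are ignored (actors without a scan row are kept).

    ``scan_ids`` optionally restricts counting to a subset of scans (used by
    the monthly-matched subsampling).
    """
    if context not in CONTEXTS:
        raise ValueError(f"context must be one of {CONTEXTS}, got {context!r}")
    ids = roster.ids
    idx = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    joint = np.zeros((n, n), dtype=int)

    sub = records[records["context"] == context]
    if scan_ids is not None:
        sub = sub[sub["scan_id"].isin(scan_ids)]

    if data_type == "proximity":
        seen: set[tuple[int, int, int]] = set()
        for row in sub.itertuples(index=False):
            a = idx.get(row.individual_id)
            if a is None:
                continue
            for nb in row.neighbours:
                b = idx.get(nb)
                if b is None:
                    continue
                key = (row.scan_id, min(a, b), max(a, b))
                if key not in seen:  # reciprocal listings within a scan count once
                    seen.add(key)
                    joint[a, b] += 1
                    joint[b, a] += 1
    elif data_type == "affiliative":
        if affiliative_states is not None and scans is not None and len(sub):
            states = scans.set_index(["scan_id", "individual_id"])["state"]
            keys = pd.MultiIndex.from_frame(sub[["scan_id", "actor"]])
            actor_state = states.reindex(keys)
            keep = actor_state.isna().to_numpy() | actor_state.isin(affiliative_states).to_numpy()
            sub = sub[keep]
        # one count per (scan, actor, recipient): repeats within a scan collapse
        uniq = sub.drop_duplicates(subset=["scan_id", "actor", "recipient"])
        for row in uniq.itertuples(index=False):
            a, b = idx.get(row.actor), idx.get(row.recipient)
            if a is not None and b is not None:
                joint[a, b] += 1
    else:
        raise ValueError(f"unknown data_type {data_type!r}")
    return DyadCounts(context=context, data_type=data_type, ids=list(ids), joint=joint)


def hwi(dyads: DyadCounts, sightings: SightingCounts) -> AssociationMatrix:
    """Half-weight association matrix: entry (A, B) = 2·N(A,B) / (n_A + n_B).

    Dyads with ``n_A + n_B = 0`` get 0 (never observed, no evidence of
    association).  Values always lie in [0, 1]; 1 means the dyad was together
    in every sighting of either member.
    """
    if dyads.context != sightings.context:
        raise ValueError(
            f"context mismatch: dyad counts are {dyads.context!r}, sightings are {sightings.context!r}"
        )
    n_vec = np.array([sightings.counts[i] for i in dyads.ids], dtype=float)
    denom = n_vec[:, None] + n_vec[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        mat = np.where(denom > 0, 2.0 * dyads.joint / denom, 0.0)
    np.fill_diagonal(mat, 0.0)
    if mat.min() < 0 or mat.max() > 1 + 1e-12:
        raise ValueError("HWI outside [0, 1]; inconsistent counts")
    return AssociationMatrix(ids=list(dyads.ids), context=dyads.context, data_type=dyads.data_type, hwi=mat)


def road_proportion(scans: pd.DataFrame, roster: Roster, percent: bool = True) -> pd.Series:
    """Per-individual proportion of behavioural records along the road.

    Returns ``n_road / (n_road + n_forest)`` per individual, on the
    percentage scale by default (matching the regression response).
    Individuals never observed are excluded with a warning.
    """
    from .scan_data import tally_sightings

    road = tally_sightings(scans, "road", roster).counts
    forest = tally_sightings(scans, "forest", roster).counts
    out = {}
    dropped = []
    for i in roster.ids:
        total = road[i] + forest[i]
        if total == 0:
            dropped.append(i)
            continue
        out[i] = road[i] / total
    if dropped:
        warnings.warn(f"excluded {len(dropped)} individual(s) with zero sightings: {dropped}")
    s = pd.Series(out, name="road_proportion")
    return s * 100.0 if percent else s


def top_associate(matrix: AssociationMatrix, id: str) -> str:
    """The partner with the greatest HWI to ``id`` (ties → smallest id).

    Defined on the undirected (symmetrised) view; raises if the row is all
    zero (no associate definable for an isolated individual).
    """
    idx = {i: k for k, i in enumerate(matrix.ids)}
    if id not in idx:
        raise KeyError(id)
    sym = matrix.hwi if not matrix.directed else (matrix.hwi + matrix.hwi.T) / 2.0
    row = sym[idx[id]].copy()
    row[idx[id]] = -np.inf
    best = row.max()
    if best <= 0:
        raise ValueError(f"individual {id!r} has no nonzero associations; top associate undefined")
    candidates = sorted(matrix.ids[k] for k in np.flatnonzero(row == best))
    return candidates[0]
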