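"""SVQ-based differential expression calling.

The spot volume quotient (SVQ) is the ratio of the mean normalized spot
volume in the P90 reference group to that in the comparison group
(SVQ = P90 / P7 or P90 / P637).  A spot is called differential when its
SVQ is ≤ 0.6 (up-regulated at the comparison stage — more volume there)
or ≥ 1.67 (down-regulated); both boundaries inclusive.  A non-unchanged
call further requires the spot in at least 4 of 6 gels of every group
where it is expressed.  Absence is called when a spot is reproducibly
present on one side (≥ 4 gels) and essentially missing on the other
(≤ 1 gel); intermediate presence patterns are indeterminate and excluded.
Multi-spot proteins are aggregated by the arithmetic mean of their spot
SVQs, with conflicting spot directions flagged "up-down" instead of
averaged away.

Note the two thresholds are reciprocal within rounding (1/0.6 = 1.67);
``validate_thresholds`` warns when a user breaks that symmetry.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gel_analysis import GelSpotTable, MatchedSpotCluster

__all__ = [
    "DEFAULT_LOW", "DEFAULT_HIGH", "DEFAULT_MIN_GELS", "DEFAULT_MAX_ABSENT",
    "STATUSES", "SVQResult", "DifferentialCall", "EmptyClusterError",
    "compute_svq", "call_spot", "call_absence", "call_cluster",
    "aggregate_protein", "summarize", "validate_thresholds",
]

DEFAULT_LOW = 0.6
DEFAULT_HIGH = 1.67
DEFAULT_MIN_GELS = 4
DEFAULT_MAX_ABSENT = 1

UP = "up"
DOWN = "down"
ABSENT_CMP = "absent_cmp"
ABSENT_P90 = "absent_p90"
UNCHANGED = "unchanged"
UP_DOWN = "up_down"
INDETERMINATE = "indeterminate"
STATUSES = (UP, DOWN, ABSENT_CMP, ABSENT_P90, UNCHANGED, UP_DOWN,
            INDETERMINATE)

#: the four classes that count as differentially expressed
DIFFERENTIAL_STATUSES = (UP, DOWN, ABSENT_CMP, ABSENT_P90)


class EmptyClusterError(ValueError):
    """Cluster has no member spot in either gel group."""


@dataclass(frozen=True)
class SVQResult:
    """Per-cluster SVQ with replication bookkeeping.

    ``svq`` is NaN (flagged, not divided) when either group mean is zero
    or the spot is missing from a whole group.
    """

    cluster_id: str
    svq: float
    presence_ref: int   # gels of the P90 group containing the spot
    presence_cmp: int   # gels of the comparison group containing the spot
    mean_ref: float = float("nan")
    mean_cmp: float = float("nan")

    @property
    def defined(self) -> bool:
        return not math.isnan(self.svq)


@dataclass(frozen=True)
class DifferentialCall:
    subject: str
    status: str
    svq_values: tuple[float, ...] = ()
    mean_svq: float = float("nan")
    presence_ref: int = 0
    presence_cmp: int = 0

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


def validate_thresholds(low: float, high: float) -> None:
    """Check 0 < low < 1 < high; warn when they are not reciprocal."""
    if not (0 < low < 1 < high):
        raise ValueError(f"thresholds must satisfy 0 < low < 1 < high, "
                         f"got ({low}, {high})")
    if round(1.0 / low, 2) != round(high, 2):
        warnings.warn(
            f"SVQ thresholds ({low}, {high}) are not reciprocal "
            f"(1/{low} = {1/low:.2f}); up and down calls will be "
            "asymmetric", stacklevel=2)


def compute_svq(
    cluster: MatchedSpotCluster,
    p90_gels: list[GelSpotTable],
    cmp_gels: list[GelSpotTable],
) -> SVQResult:
    """SVQ of one matched cluster: P90 group mean ÷ comparison group mean.

    Means are taken over the normalized volumes of the gels where the
    spot is present.  Zero or undefined means yield a flagged (NaN) SVQ.
    """
    def group_values(gels):
        vals = []
        for gel in gels:
            sid = cluster.members.get(gel.gel_id)
            if sid is None:
                continue
            row = gel.spots.loc[gel.spots["spot_id"] == sid]
            if row.empty:
                raise KeyError(
                    f"cluster {cluster.cluster_id}: spot {sid} not in gel "
                    f"{gel.gel_id}")
            v = float(row["normalized_volume"].iloc[0])
            if math.isnan(v):
                raise ValueError(
                    f"gel {gel.gel_id} has no normalized volumes; run "
                    "normalize_volumes first")
            vals.append(v)
        return vals

    ref_vals = group_values(p90_gels)
    cmp_vals = group_values(cmp_gels)
    if not ref_vals and not cmp_vals:
        raise EmptyClusterError(
            f"cluster {cluster.cluster_id} has no member in either group")
    mean_ref = float(np.mean(ref_vals)) if ref_vals else float("nan")
    mean_cmp = float(np.mean(cmp_vals)) if cmp_vals else float("nan")
    if ref_vals and cmp_vals and mean_ref > 0 and mean_cmp > 0:
        svq = mean_ref / mean_cmp
    else:
        svq = float("nan")
    return SVQResult(cluster_id=cluster.cluster_id, svq=svq,
                     presence_ref=len(ref_vals), presence_cmp=len(cmp_vals),
                     mean_ref=mean_ref, mean_cmp=mean_cmp)


def call_spot(
    result: SVQResult,
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
    min_gels: int = DEFAULT_MIN_GELS,
) -> DifferentialCall:
    """Threshold call for one spot: up iff SVQ ≤ low, down iff SVQ ≥ high.

    Boundaries are inclusive.  Any non-unchanged call additionally
    requires presence in ≥ ``min_gels`` gels of every group where the
    spot is expressed at all; otherwise the spot is indeterminate.
    """
    validate_thresholds(low, high)
    kw = dict(subject=result.cluster_id, svq_values=(result.svq,),
              mean_svq=result.svq, presence_ref=result.presence_ref,
              presence_cmp=result.presence_cmp)
    if not result.defined:
        return DifferentialCall(status=INDETERMINATE, **kw)
    if result.svq <= low:
        candidate = UP
    elif result.svq >= high:
        candidate = DOWN
    else:
        return DifferentialCall(status=UNCHANGED, **kw)
    for presence in (result.presence_ref, result.presence_cmp):
        if 0 < presence < min_gels:
            return DifferentialCall(status=INDETERMINATE, **kw)
    return DifferentialCall(status=candidate, **kw)


def call_absence(
    result: SVQResult,
    min_present: int = DEFAULT_MIN_GELS,
    max_absent: int = DEFAULT_MAX_ABSENT,
) -> DifferentialCall | None:
    """Absence call from the presence pattern alone.

    absent_cmp: present in ≥ ``min_present`` P90 gels and ≤ ``max_absent``
    comparison gels; absent_p90 symmetric.  Returns None when both groups
    meet the presence bound (not an absence case) and an indeterminate
    call for the gray zone in between.
    """
    kw = dict(subject=result.cluster_id, svq_values=(result.svq,),
              mean_svq=result.svq, presence_ref=result.presence_ref,
              presence_cmp=result.presence_cmp)
    if result.presence_ref >= min_present and \
            result.presence_cmp <= max_absent:
        return DifferentialCall(status=ABSENT_CMP, **kw)
    if result.presence_cmp >= min_present and \
            result.presence_ref <= max_absent:
        return DifferentialCall(status=ABSENT_P90, **kw)
    if result.presence_ref >= min_present and \
            result.presence_cmp >= min_present:
        return None
    return DifferentialCall(status=INDETERMINATE, **kw)


def call_cluster(
    result: SVQResult,
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
    min_gels: int = DEFAULT_MIN_GELS,
    max_absent: int = DEFAULT_MAX_ABSENT,
) -> DifferentialCall:
    """Combined per-cluster call: absence rule first, then thresholds.

    An absence-rule gray zone does not pre-empt the threshold rule: only
    non-unchanged threshold calls require replication, so a spot with a
    null-band SVQ and weak presence is still "unchanged".
    """
    absence = call_absence(result, min_present=min_gels,
                           max_absent=max_absent)
    if absence is not None and absence.status != INDETERMINATE:
        return absence
    return call_spot(result, low=low, high=high, min_gels=min_gels)


def aggregate_protein(
    spot_calls: list[DifferentialCall],
    accession: str | None = None,
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
) -> DifferentialCall:
    """Protein-level call from the calls of its individual spots.

    The protein's mean SVQ is the arithmetic mean of the defined per-spot
    SVQs; its status follows the same thresholds — unless individual spot
    directions conflict (one spot ≤ low, another ≥ high), which is marked
    "up_down" rather than averaged away.  Absence propagates only when
    all spots agree.  Indeterminate spots carry no evidence and are
    excluded; a protein with only indeterminate spots is indeterminate.
    """
    if not spot_calls:
        raise ValueError("no spot calls to aggregate")
    if accession is None:
        accession = spot_calls[0].subject
    usable = [c for c in spot_calls if c.status != INDETERMINATE]
    svqs = tuple(v for c in usable for v in c.svq_values
                 if not math.isnan(v))
    mean_svq = float(np.mean(svqs)) if svqs else float("nan")
    pres_ref = max((c.presence_ref for c in spot_calls), default=0)
    pres_cmp = max((c.presence_cmp for c in spot_calls), default=0)
    kw = dict(subject=accession, svq_values=svqs, mean_svq=mean_svq,
              presence_ref=pres_ref, presence_cmp=pres_cmp)
    if not usable:
        return DifferentialCall(status=INDETERMINATE, **kw)
    if any(v <= low for v in svqs) and any(v >= high for v in svqs):
        return DifferentialCall(status=UP_DOWN, **kw)
    statuses = {c.status for c in usable}
    if statuses == {ABSENT_CMP}:
        return DifferentialCall(status=ABSENT_CMP, **kw)
    if statuses == {ABSENT_P90}:
        return DifferentialCall(status=ABSENT_P90, **kw)
    if not svqs:
        # disagreeing absences with no measurable SVQ anywhere
        return DifferentialCall(status=INDETERMINATE, **kw)
    if mean_svq <= low:
        status = UP
    elif mean_svq >= high:
        status = DOWN
    else:
        status = UNCHANGED
    return DifferentialCall(status=status, **kw)


def aggregate_by_accession(
    cluster_calls: dict[str, DifferentialCall],
    cluster_to_accession: dict[str, str],
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
) -> dict[str, DifferentialCall]:
    """Group cluster calls by protein accession and aggregate each."""
    per_protein: dict[str, list[DifferentialCall]] = {}
    for cid, call in cluster_calls.items():
        acc = cluster_to_accession.get(cid)
        if acc is None:
            continue
        per_protein.setdefault(acc, []).append(call)
    return {acc: aggregate_protein(calls, accession=acc, low=low, high=high)
            for acc, calls in sorted(per_protein.items())}


def summarize(
    calls: dict[str, DifferentialCall] | list[DifferentialCall],
    categories: dict[str, str],
) -> pd.DataFrame:
    """Category-by-status summary table of protein-level calls.

    Rows are the 13 functional categories (plus "unknown" for unmapped
    accessions, with a warning) and a trailing "all" row; columns are the
    seven statuses plus ``total_differential`` — the sum of up, down,
    absent_cmp and absent_p90, i.e. the accounting identity of a
    per-comparison overview table.
    """
    from .catalog import CATEGORIES

    if isinstance(calls, dict):
        calls = list(calls.values())
    table = pd.DataFrame(0, index=list(CATEGORIES),
                         columns=list(STATUSES) + ["total_differential"])
    for call in calls:
        cat = categories.get(call.subject)
        if cat is None or cat not in table.index:
            if "unknown" not in table.index:
                table.loc["unknown"] = 0
            warnings.warn(f"accession {call.subject} has no category; "
                          "counted as 'unknown'", stacklevel=2)
            cat = "unknown"
        table.loc[cat, call.status] += 1
        if call.status in DIFFERENTIAL_STATUSES:
            table.loc[cat, "total_differential"] += 1
    table.loc["all"] = table.sum(axis=0)
    return table


def tallies(summary: pd.DataFrame) -> dict[str, int]:
    """Overview-row tallies from a summary table."""
    row = summary.loc["all"]
    return {
        "total": int(row["total_differential"]),
        "up": int(row[UP]),
        "down": int(row[DOWN]),
        "absent_cmp": int(row[ABSENT_CMP]),
        "absent_p90": int(row[ABSENT_P90]),
        "up_down": int(row[UP_DOWN]),
        "unchanged": int(row[UNCHANGED]),
        "indeterminate": int(row[INDETERMINATE]),
    }
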