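"""Indicator-ASV analysis against HB contamination categories.

For each ASV and candidate sample group, two indicator-value components are
computed:

* **specificity** (A): the ASV's mean relative abundance in the group divided
  by the sum of its group-mean relative abundances over all groups (the
  group-size-corrected "IndVal.g" convention; a value of 1 means the ASV is
  found only in that group);
* **sensitivity** (B): the fraction of the group's samples in which the ASV is
  present (count > 0).

An ASV is *strongly associated* with a group when both components are >= 0.8.
The analysis is typically restricted to a sample subset (e.g. urban
catchments) and to a community subset (sewer + stool ASVs, or freshwater
ASVs) so that land-use-driven community differences do not masquerade as
contamination signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .source_partition import ASVTable

__all__ = ["SampleGrouping", "IndicatorScore", "specificity", "sensitivity",
           "find_indicators"]


@dataclass
class SampleGrouping:
    """Per-sample group labels with an optional restriction mask.

    ``labels`` maps sample id -> group (e.g. an HB contamination category);
    ``mask`` optionally restricts the analysis to a sample subset (samples
    where the mask is False are dropped entirely).
    """

    labels: pd.Series
    mask: pd.Series | None = None

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels)
        if self.labels.isna().any():
            raise ValueError("every sample needs exactly one group label")
        if self.mask is not None:
            self.mask = pd.Series(self.mask).reindex(self.labels.index).fillna(False)

    def retained(self) -> pd.Series:
        lab = self.labels if self.mask is None else self.labels[self.mask]
        if lab.nunique() < 2:
            raise ValueError("need >= 2 groups with samples after restriction")
        return lab

    @property
    def groups(self) -> list:
        return sorted(self.retained().unique().tolist())


@dataclass(frozen=True)
class IndicatorScore:
    asv_id: str
    group: str
    specificity: float
    sensitivity: float
    taxonomy: str | None = field(default=None, compare=False)

    @property
    def strong(self) -> bool:
        return self.specificity >= 0.8 and self.sensitivity >= 0.8

    @property
    def score(self) -> float:
        return self.specificity * self.sensitivity


def _group_frames(table: ASVTable, grouping: SampleGrouping):
    labels = grouping.retained()
    missing = set(labels.index) - set(table.counts.index)
    if missing:
        raise ValueError(f"grouped samples absent from table: {sorted(missing)[:5]}")
    rel = table.relative_abundance().loc[labels.index].fillna(0.0)
    counts = table.counts.loc[labels.index]
    return labels, rel, counts


def specificity(asv_id: str, group, table: ASVTable, grouping: SampleGrouping,
                mode: str = "group_mean") -> float:
    """Component A: concentration of the ASV's abundance in the target group.

    ``mode="group_mean"`` (default) uses per-group mean relative abundances,
    robust to unbalanced group sizes; ``mode="pooled"`` uses pooled sums of
    relative abundance per group.  Returns 0 for an ASV absent everywhere.
    """
    if mode not in ("group_mean", "pooled"):
        raise ValueError("mode must be 'group_mean' or 'pooled'")
    labels, rel, _ = _group_frames(table, grouping)
    if group not in set(labels):
        raise ValueError(f"empty or unknown group {group!r}")
    agg = rel[asv_id].groupby(labels).mean() if mode == "group_mean" \
        else rel[asv_id].groupby(labels).sum()
    total = agg.sum()
    if total == 0:
        return 0.0
    return float(agg[group] / total)


def sensitivity(asv_id: str, group, table: ASVTable, grouping: SampleGrouping) -> float:
    """Component B: fraction of the group's samples where the ASV is present."""
    labels, _, counts = _group_frames(table, grouping)
    in_group = labels.index[labels == group]
    if len(in_group) == 0:
        raise ValueError(f"empty group {group!r}")
    present = (counts.loc[in_group, asv_id] > 0).sum()
    return float(present / len(in_group))


def find_indicators(table: ASVTable, grouping: SampleGrouping,
                    min_spec: float = 0.8, min_sens: float = 0.8,
                    community_filter=None, mode: str = "group_mean",
                    strong_only: bool = True) -> pd.DataFrame:
    """Score every (ASV, best group) pair and report strongly associated ASVs.

    Each ASV is assigned its best group — the one maximizing specificity x
    sensitivity — and kept if both components clear their thresholds
    (inclusive).  ``community_filter`` optionally restricts scoring to a
    subset of ASV ids (e.g. the sewer + stool partition, or the freshwater
    partition, run separately).  Results are sorted by group then descending
    score.

    Returns a DataFrame with columns group, asv_id, taxonomy, specificity,
    sensitivity, strong.
    """
    labels, rel, counts = _group_frames(table, grouping)
    groups = sorted(pd.unique(labels))
    asvs = list(table.asv_ids) if community_filter is None else \
        [a for a in table.asv_ids if a in set(community_filter)]

    # vectorised components: per-group mean relabund and presence fraction
    grouped_rel = rel[asvs].groupby(labels)
    mean_rel = grouped_rel.mean() if mode == "group_mean" else grouped_rel.sum()
    totals = mean_rel.sum(axis=0)
    presence = (counts[asvs] > 0).groupby(labels).mean()

    rows = []
    for asv in asvs:
        if totals[asv] == 0:
            continue  # absent from every retained sample: no indicator signal
        spec_by_group = mean_rel[asv] / totals[asv]
        sens_by_group = presence[asv]
        score = spec_by_group * sens_by_group
        best = max(groups, key=lambda g: (score[g], str(g)))
        s_spec, s_sens = float(spec_by_group[best]), float(sens_by_group[best])
        rows.append({
            "group": best, "asv_id": asv,
            "taxonomy": table.taxonomy.get(asv),
            "specificity": s_spec, "sensitivity": s_sens,
            "strong": bool(s_spec >= min_spec and s_sens >= min_sens),
        })
    out = pd.DataFrame(rows, columns=["group", "asv_id", "taxonomy",
                                      "specificity", "sensitivity", "strong"])
    if strong_only:
        out = out[out["strong"]]
    out = out.assign(_score=out["specificity"] * out["sensitivity"])
    out = out.sort_values(["group", "_score", "asv_id"],
                          ascending=[True, False, True]).drop(columns="_score")
    return out.reset_index(drop=True)
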