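"""Dual-threshold concordance between the HB marker and sewage-sequence proportion.

A sample can exceed the qPCR risk threshold (HB >= 7,800 CN/100 ml), the
sequence-based threshold (sewage-sequence proportion >= 18% by default), both,
or neither.  Cross-tabulating samples over these two binary exceedances gives
a four-quadrant concordance table; agreement (below-both plus above-both)
measures how well the sequence proportion could stand in for the established
qPCR indicator.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .hb_quantification import HBResult

__all__ = ["ThresholdPair", "ConcordanceCounts", "QUADRANTS",
           "classify_sample", "tabulate", "classify_table"]

QUADRANTS = ("below_both", "hb_only", "seq_only", "above_both")


@dataclass(frozen=True)
class ThresholdPair:
    hb_threshold: float = 7800.0       # CN/100 ml
    seq_threshold: float = 0.18        # proportion of sewage sequences

    def __post_init__(self) -> None:
        if self.hb_threshold <= 0:
            raise ValueError("hb_threshold must be strictly positive")
        if not 0 < self.seq_threshold < 1:
            raise ValueError("seq_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class ConcordanceCounts:
    below_both: int
    hb_only: int
    seq_only: int
    above_both: int

    @property
    def n_total(self) -> int:
        return self.below_both + self.hb_only + self.seq_only + self.above_both

    @property
    def agreement(self) -> int:
        return self.below_both + self.above_both

    @property
    def agreement_fraction(self) -> float:
        return self.agreement / self.n_total

    def to_dict(self) -> dict:
        return {"below_both": self.below_both, "hb_only": self.hb_only,
                "seq_only": self.seq_only, "above_both": self.above_both,
                "n_total": self.n_total, "agreement": self.agreement,
                "agreement_fraction": self.agreement_fraction}


def classify_sample(hb: HBResult, seq_proportion: float,
                    thresholds: ThresholdPair = ThresholdPair()) -> str:
    """Quadrant for one sample.

    HB exceedance requires a quantified value >= hb_threshold (non-detects and
    below-LOQ detections are non-exceedance: exceedance demands a quantified
    number above threshold).  Sequence exceedance is seq_proportion >=
    seq_threshold, inclusive to mirror the HB side.
    """
    if seq_proportion is None or pd.isna(seq_proportion):
        raise ValueError("missing sequence proportion")
    if not 0 <= seq_proportion <= 1:
        raise ValueError(f"seq_proportion must lie in [0, 1], got {seq_proportion}")
    hb_exceeds = (hb.censor == "quantified"
                  and hb.cn_per_100ml >= thresholds.hb_threshold)
    seq_exceeds = seq_proportion >= thresholds.seq_threshold
    if hb_exceeds and seq_exceeds:
        return "above_both"
    if hb_exceeds:
        return "hb_only"
    if seq_exceeds:
        return "seq_only"
    return "below_both"


def tabulate(classifications) -> ConcordanceCounts:
    """Count quadrant labels into a ConcordanceCounts."""
    labels = list(classifications)
    if not labels:
        raise ValueError("need at least one classified sample")
    bad = set(labels) - set(QUADRANTS)
    if bad:
        raise ValueError(f"unknown quadrant labels: {bad}")
    return ConcordanceCounts(**{q: labels.count(q) for q in QUADRANTS})


def classify_table(hb_results, seq_proportions: pd.Series,
                   thresholds: ThresholdPair = ThresholdPair()):
    """Classify a cohort; returns (per-sample DataFrame, ConcordanceCounts).

    ``hb_results`` is an iterable of HBResult with sample_id set; samples are
    joined to ``seq_proportions`` on sample id and every HB sample must have a
    proportion.
    """
    rows = []
    for hb in hb_results:
        if hb.sample_id is None:
            raise ValueError("HBResult.sample_id required for table classification")
        if hb.sample_id not in seq_proportions.index:
            raise ValueError(f"missing sequence proportion for {hb.sample_id}")
        quadrant = classify_sample(hb, float(seq_proportions[hb.sample_id]), thresholds)
        rows.append({"sample_id": hb.sample_id,
                     "cn_per_100ml": hb.cn_per_100ml,
                     "seq_proportion": float(seq_proportions[hb.sample_id]),
                     "quadrant": quadrant})
    frame = pd.DataFrame(rows)
    return frame, tabulate(frame["quadrant"])
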