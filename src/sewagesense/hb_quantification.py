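"""Human *Bacteroides* (HB) marker quantification from qPCR with censoring.

Converts quantification-cycle (Cq) observations into marker copy number per
100 ml of river water via a log-linear standard curve, applies the assay's
limit of quantification (LOQ, 15 CN per reaction == 180 CN/100 ml under the
default filtration/extraction constants), and assigns each sample one of four
contamination categories:

=============  =============================================
undetectable   no amplification (below limit of detection)
unquantifiable detected but < 180 CN/100 ml (below LOQ)
quantifiable   180 <= CN/100 ml < 7,800
risk           >= 7,800 CN/100 ml (excess illness risk 0.03)
=============  =============================================

Non-detects carry no numeric concentration; arithmetic on them is an error
rather than a silent zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "ConversionConstants",
    "HBResult",
    "CENSOR_STATES",
    "HB_CATEGORIES",
    "LOQ_CN_PER_100ML",
    "RISK_CN_PER_100ML",
    "fit_standard_curve",
    "quantify",
    "categorize",
    "quantify_table",
]

LOQ_CN_PER_100ML = 180.0
RISK_CN_PER_100ML = 7800.0

CENSOR_STATES = ("nondetect", "below_loq", "quantified")
HB_CATEGORIES = ("undetectable", "unquantifiable", "quantifiable", "risk")


class AssayEfficiencyWarning(UserWarning):
    """Standard-curve efficiency outside the acceptable 90-110% window."""


@dataclass(frozen=True)
class StandardCurve:
    """Log-linear qPCR standard curve Cq = slope * log10(CN/reaction) + intercept.

    ``slope`` must be negative (more template -> earlier amplification).  The
    amplification efficiency is ``10**(-1/slope) - 1``; perfect doubling per
    cycle gives slope -3.3219 and efficiency 1.0.
    """

    slope: float
    intercept: float
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if not self.slope < 0:
            raise ValueError(f"standard-curve slope must be negative, got {self.slope}")

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def cn_per_reaction(self, cq: float) -> float:
        """Invert the curve: CN/reaction = 10**((Cq - intercept) / slope)."""
        return 10.0 ** ((cq - self.intercept) / self.slope)

    def cq_of(self, cn_per_reaction: float) -> float:
        """Forward curve evaluation (used to synthesize Cq values)."""
        if cn_per_reaction <= 0:
            raise ValueError("cn_per_reaction must be positive")
        return self.slope * math.log10(cn_per_reaction) + self.intercept


@dataclass(frozen=True)
class ConversionConstants:
    """Volumes and factors converting CN/reaction to CN/100 ml of sample.

    ``volume_filtered_ml``
        water volume captured on the filter (default 250 ml).
    ``extract_to_reactions``
        number of reaction-equivalents one filter extract represents
        (default 30, calibrated so 15 CN/reaction == 180 CN/100 ml).
    ``reporting_basis_ml``
        the reporting volume (default 100 ml).
    """

    volume_filtered_ml: float = 250.0
    extract_to_reactions: float = 30.0
    reporting_basis_ml: float = 100.0

    def __post_init__(self) -> None:
        for name in ("volume_filtered_ml", "extract_to_reactions", "reporting_basis_ml"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def reaction_to_100ml_factor(self) -> float:
        """Multiplier from CN/reaction to CN/100 ml (12 under defaults)."""
        return self.extract_to_reactions * self.reporting_basis_ml / self.volume_filtered_ml


@dataclass(frozen=True)
class HBResult:
    """One sample's HB quantification outcome."""

    cn_per_100ml: float | None
    censor: str
    category: str | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.censor not in CENSOR_STATES:
            raise ValueError(f"censor must be one of {CENSOR_STATES}")
        if self.censor == "nondetect" and self.cn_per_100ml is not None:
            raise ValueError("non-detects carry no numeric concentration")
        if self.censor != "nondetect":
            if self.cn_per_100ml is None or self.cn_per_100ml < 0:
                raise ValueError("detected samples need a nonnegative concentration")
        if self.category is not None and self.category not in HB_CATEGORIES:
            raise ValueError(f"category must be one of {HB_CATEGORIES}")


def fit_standard_curve(points) -> StandardCurve:
    """Ordinary least squares of Cq on log10(CN/reaction).

    Parameters
    ----------
    points : sequence of (log10_cn_per_reaction, cq) pairs
        Replicates may repeat dilution levels; at least 3 distinct levels are
        required for a meaningful curve.

    Warns if the fitted efficiency falls outside [0.9, 1.1].
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (log10 CN, Cq) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct dilution levels")
    fit = stats.linregress(x, y)
    curve = StandardCurve(slope=float(fit.slope), intercept=float(fit.intercept),
                          r_squared=float(fit.rvalue) ** 2)
    if not (0.9 <= curve.efficiency <= 1.1):
        warnings.warn(
            f"assay efficiency {curve.efficiency:.3f} outside [0.9, 1.1]",
            AssayEfficiencyWarning,
            stacklevel=2,
        )
    return curve


def _is_nondetect(cq) -> bool:
    if cq is None:
        return True
    if isinstance(cq, str):
        if cq.strip().upper() in {"ND", "NA", "NONDETECT", "NON-DETECT", ""}:
            return True
        raise ValueError(f"malformed Cq value: {cq!r}")
    cq = float(cq)
    return math.isnan(cq)


def quantify(cq, curve: StandardCurve,
             constants: ConversionConstants = ConversionConstants(),
             sample_id: str | None = None) -> HBResult:
    """Convert one Cq observation to CN/100 ml (censoring applied, uncategorized).

    A non-detect (None, NaN, or the string ``"ND"``) yields censor
    ``nondetect`` and no numeric value.  Detected values below the LOQ are
    flagged ``below_loq`` but keep their back-calculated concentration.
    """
    if _is_nondetect(cq):
        return HBResult(cn_per_100ml=None, censor="nondetect", sample_id=sample_id)
    cq = float(cq)
    if not math.isfinite(cq) or cq <= 0:
        raise ValueError(f"malformed Cq value: {cq!r}")
    cn_rxn = curve.cn_per_reaction(cq)
    cn_100ml = cn_rxn * constants.reaction_to_100ml_factor
    censor = "below_loq" if cn_100ml < LOQ_CN_PER_100ML else "quantified"
    return HBResult(cn_per_100ml=float(cn_100ml), censor=censor, sample_id=sample_id)


def categorize(result: HBResult,
               loq_cn_100ml: float = LOQ_CN_PER_100ML,
               risk_cn_100ml: float = RISK_CN_PER_100ML) -> HBResult:
    """Assign the four-way contamination category (boundaries inclusive upward).

    ``cn == loq`` is quantifiable; ``cn == risk`` is risk.
    """
    if result.censor == "nondetect":
        category = "undetectable"
    elif result.cn_per_100ml < loq_cn_100ml:
        category = "unquantifiable"
        result = HBResult(result.cn_per_100ml, "below_loq", None, result.sample_id)
    elif result.cn_per_100ml < risk_cn_100ml:
        category = "quantifiable"
        result = HBResult(result.cn_per_100ml, "quantified", None, result.sample_id)
    else:
        category = "risk"
        result = HBResult(result.cn_per_100ml, "quantified", None, result.sample_id)
    return HBResult(result.cn_per_100ml, result.censor, category, result.sample_id)


def quantify_table(qpcr: pd.DataFrame, curve: StandardCurve,
                   constants: ConversionConstants = ConversionConstants(),
                   loq_cn_100ml: float = LOQ_CN_PER_100ML,
                   risk_cn_100ml: float = RISK_CN_PER_100ML) -> pd.DataFrame:
    """Quantify and categorize a qPCR observation table.

    ``qpcr`` needs columns ``sample_id`` and ``cq`` (numeric, NaN or ``"ND"``
    for non-detects) and may carry a ``replicate`` column; replicate Cq values
    are averaged on the Cq scale per sample before quantification, and a
    sample whose replicates are all non-detect is a non-detect.

    Returns a tidy frame with columns sample_id, cn_per_100ml, censor, category.
    """
    if not {"sample_id", "cq"} <= set(qpcr.columns):
        raise ValueError("qpcr table needs columns 'sample_id' and 'cq'")
    rows = []
    for sample_id, grp in qpcr.groupby("sample_id", sort=False):
        cqs = [c for c in grp["cq"] if not _is_nondetect(c)]
        mean_cq = float(np.mean([float(c) for c in cqs])) if cqs else None
        res = categorize(quantify(mean_cq, curve, constants, sample_id=str(sample_id)),
                         loq_cn_100ml, risk_cn_100ml)
        rows.append({
            "sample_id": str(sample_id),
            "cn_per_100ml": res.cn_per_100ml if res.cn_per_100ml is not None else np.nan,
            "censor": res.censor,
            "category": res.category,
        })
    return pd.DataFrame(rows)
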