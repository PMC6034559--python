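"""qPCR absolute quantification, positivity calling and detectability.

A standard curve relates quantification cycle (Ct) to template amount:
Ct = intercept + slope * log10(copies), slope < 0, with amplification
efficiency 10^(-1/slope) - 1 (a slope of -1/log10(2) = -3.3219 means
perfect doubling each cycle).  Unknown samples are inverted through the
fitted line, converted from copies per reaction to CFU/ml by a single
user-supplied factor, and called positive at a detection threshold of
10^4 CFU/ml — loads below the threshold are treated as negative, since
that is where the assay stops distinguishing signal from background in
a ~10^11 CFU/ml total microbiota.

Relative gene expression uses the 2^-dCt rule against a reference gene
(actin).  The detectability calculator answers "how abundant must a
taxon be for shotgun sequencing to see it": with Lander-Waterman
coverage, a taxon at relative abundance a in a D-base dataset with
genome length L has expected covered fraction 1 - exp(-a*D/L), so the
minimum abundance yielding covered fraction f is a* = -L*ln(1-f)/D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "QpcrRun",
    "Quantification",
    "QuantResult",
    "fit_standard_curve",
    "quantify",
    "quantify_run",
    "call_positivity",
    "relative_expression",
    "metagenome_detectability",
    "POSITIVITY_THRESHOLD_CFU_PER_ML",
]

POSITIVITY_THRESHOLD_CFU_PER_ML = 1e4
#: the companion constant sometimes quoted as absolute organism count in a
#: ~1e11 total community; exposed, not silently reconciled with the CFU/ml figure
DETECTION_LIMIT_ORGANISMS = 1e5
TOTAL_MICROBIOTA_CFU_PER_ML = 1e11


@dataclass(frozen=True)
class StandardCurve:
    """Fitted log-linear calibration: Ct = intercept + slope*log10(copies)."""

    slope: float
    intercept: float
    r_squared: float = 1.0
    log10_copies_min: float = -math.inf
    log10_copies_max: float = math.inf

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("amplification requires a negative slope")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must be in [0, 1]")

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency, 1.0 = perfect doubling."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass
class QpcrRun:
    """Standard-curve points plus sample Ct measurements.

    curve_points columns: target, copies, ct, replicate.
    samples columns: sample_id, target, ct, replicate.
    target is 'SFB' or 'universal'; conversion_factor maps copies per
    reaction to CFU/ml.
    """

    curve_points: pd.DataFrame
    samples: pd.DataFrame
    conversion_factor: float = 1.0

    def __post_init__(self) -> None:
        if (self.curve_points["copies"] <= 0).any():
            raise ValueError("known copies must be > 0")
        if (self.curve_points["ct"] <= 0).any() or (self.samples["ct"] <= 0).any():
            raise ValueError("Ct values must be > 0")


class Quantification(NamedTuple):
    copies: float
    load: float
    below_range: bool
    above_range: bool


@dataclass
class QuantResult:
    sample_id: str
    sfb_load: float
    total_load: float
    positive: bool
    relative_abundance: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.sfb_load < 0 or self.total_load < 0:
            raise ValueError("loads must be >= 0")


def fit_standard_curve(points) -> StandardCurve:
    """Ordinary least squares of Ct on log10(copies).

    points: iterable of (copies, ct) or a DataFrame with those columns.
    At least two distinct copy levels are required.
    """
    if isinstance(points, pd.DataFrame):
        copies = points["copies"].to_numpy(dtype=float)
        ct = points["ct"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(points), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("points must be (copies, ct) pairs")
        copies, ct = arr[:, 0], arr[:, 1]
    if (copies <= 0).any():
        raise ValueError("copies must be > 0")
    x = np.log10(copies)
    if len(np.unique(x)) < 2:
        raise ValueError("need >= 2 distinct copy levels")
    res = stats.linregress(x, ct)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        log10_copies_min=float(x.min()),
        log10_copies_max=float(x.max()),
    )


def quantify(curve: StandardCurve, ct: float, conversion: float = 1.0) -> Quantification:
    """Invert a Ct through the curve: copies = 10^((ct-intercept)/slope).

    Extrapolation outside the fitted copy range is allowed but flagged.
    """
    if conversion <= 0:
        raise ValueError("conversion factor must be > 0")
    log10_copies = (ct - curve.intercept) / curve.slope
    copies = 10.0 ** log10_copies
    return Quantification(
        copies=copies,
        load=copies * conversion,
        below_range=log10_copies < curve.log10_copies_min,
        above_range=log10_copies > curve.log10_copies_max,
    )


def call_positivity(load: float, threshold: float = POSITIVITY_THRESHOLD_CFU_PER_ML,
                    rel_tol: float = 1e-9) -> bool:
    """Positive iff load >= threshold; the boundary itself is positive.

    A 1e-9 relative guard keeps a load that is exactly at the threshold
    mathematically from flipping negative after the log10/power round
    trip through a standard curve (~1e-13 relative float error).
    """
    if load < 0:
        raise ValueError("load must be >= 0")
    return load >= threshold * (1.0 - rel_tol)


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """2^-dCt fold expression of a target gene relative to a reference gene."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** (-(ct_target - ct_reference))


def quantify_run(
    run: QpcrRun,
    threshold: float = POSITIVITY_THRESHOLD_CFU_PER_ML,
    replicate_agg: str = "mean",
) -> pd.DataFrame:
    """Quantify every sample of a run against its per-target standard curve.

    Replicate Cts are aggregated (mean by default, median optional)
    before inversion.  Returns a DataFrame with one row per sample:
    sample_id, sfb_load, total_load, relative_abundance, positive.
    """
    if replicate_agg not in ("mean", "median"):
        raise ValueError("replicate_agg must be 'mean' or 'median'")
    curves = {
        target: fit_standard_curve(grp[["copies", "ct"]])
        for target, grp in run.curve_points.groupby("target")
    }
    agg = run.samples.groupby(["sample_id", "target"])["ct"].agg(replicate_agg)
    rows = []
    for sample_id in sorted(run.samples["sample_id"].unique()):
        loads = {}
        for target in ("SFB", "universal"):
            if (sample_id, target) in agg.index and target in curves:
                loads[target] = quantify(curves[target], agg.loc[(sample_id, target)],
                                         run.conversion_factor).load
        sfb = loads.get("SFB", 0.0)
        total = loads.get("universal", float("nan"))
        rows.append({
            "sample_id": sample_id,
            "sfb_load": sfb,
            "total_load": total,
            "relative_abundance": sfb / total if total and not math.isnan(total) else float("nan"),
            "positive": call_positivity(sfb, threshold),
        })
    return pd.DataFrame(rows)


def metagenome_detectability(depth_bp: float, genome_length_bp: float,
                             min_cov_fraction: float) -> float:
    """Minimum relative abundance detectable by shotgun sequencing.

    Under Lander-Waterman coverage the expected covered fraction of a
    genome of length L for a taxon at relative abundance a in D
    sequenced bases is 1 - exp(-a*D/L); solving for the abundance that
    reaches min_cov_fraction gives a* = -L*ln(1 - f)/D.
    """
    if depth_bp <= 0 or genome_length_bp <= 0 or min_cov_fraction <= 0:
        raise ValueError("all inputs must be > 0")
    if min_cov_fraction >= 1:
        raise ValueError("min_cov_fraction must be < 1")
    return -genome_length_bp * math.log(1.0 - min_cov_fraction) / depth_bp
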