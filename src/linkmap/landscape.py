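"""Recombination-hotspot detection over the adjacent-rate landscape.

An interval is a putative hotspot when its adjacent recombination fraction
exceeds the genome-wide mean by more than a chosen multiple (default 2.5)
of the genome-wide standard deviation.  The mean and SD are always taken
over all non-missing intervals of the whole genome — also when results are
later displayed for a single chromosome — and the SD uses the sample
(n − 1) denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AdjacentRates

__all__ = ["HotspotResult", "detect_hotspots"]


@dataclass
class HotspotResult:
    threshold_sd_multiplier: float
    genomewide_mean: float
    genomewide_sd: float
    threshold_value: float
    flagged_intervals: pd.DataFrame  # chrom, left_id, right_id, theta
    flagged_markers: frozenset[str] = field(default_factory=frozenset)

    def for_chromosome(self, chrom: str) -> pd.DataFrame:
        """Flag display filtered to one chromosome; the threshold itself
        stays genome-wide."""
        df = self.flagged_intervals
        return df[df["chrom"] == str(chrom)].reset_index(drop=True)


def detect_hotspots(adjacent: AdjacentRates, multiplier: float = 2.5) -> HotspotResult:
    """Flag intervals with θ̂ > mean + multiplier·SD (strict inequality).

    NA intervals are excluded from the mean/SD and are never flagged.
    Raising the multiplier never adds flagged intervals.  The flagged-marker
    set contains both flanking markers of every flagged interval.
    """
    df = adjacent.table
    theta = df["theta"].to_numpy()
    ok = np.isfinite(theta)
    if ok.sum() < 2:
        raise ValueError("hotspot detection needs at least 2 non-NA intervals")
    mean = float(theta[ok].mean())
    sd = float(theta[ok].std(ddof=1))
    threshold = mean + multiplier * sd
    flagged = ok & (theta > threshold)
    intervals = df.loc[flagged, ["chrom", "left_id", "right_id", "theta"]].reset_index(drop=True)
    markers = frozenset(intervals["left_id"]) | frozenset(intervals["right_id"])
    return HotspotResult(multiplier, mean, sd, threshold, intervals, markers)
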