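"""Two-population ("breed") comparison of marker panels, hotspots and
best-fitting genetic-map functions.

Marker identity across populations is by marker id string (panels come
from the same array); physical positions are not used for matching.
Hotspot sets are compared after each population's threshold has been
derived from its own genome-wide mean and SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .mapfun import FAMILIES

__all__ = ["BreedComparison", "venn_counts", "best_function_tally", "compare_panels"]


def venn_counts(markers_a, markers_b) -> tuple[int, int, int]:
    """(only in A, only in B, shared) counts for two marker-id sets."""
    a, b = set(markers_a), set(markers_b)
    shared = len(a & b)
    return len(a) - shared, len(b) - shared, shared


def best_function_tally(best_a: dict[str, str], best_b: dict[str, str],
                        labels=("A", "B")) -> pd.DataFrame:
    """Counts of best map-function families per population.

    ``best_a``/``best_b`` map chromosome → winning family.  Chromosomes
    present in only one population are tallied under ``unavailable`` for
    the other, with a warning.  Row totals equal the number of chromosomes
    considered.
    """
    import warnings

    chroms = sorted(set(best_a) | set(best_b))
    rows = []
    for label, best in zip(labels, (best_a, best_b)):
        counts = {fam: 0 for fam in FAMILIES}
        counts["unavailable"] = 0
        for c in chroms:
            fam = best.get(c)
            if fam is None:
                warnings.warn(f"chromosome {c} missing in population {label}")
                counts["unavailable"] += 1
            else:
                counts[fam] += 1
        rows.append({"population": label, **counts, "total": len(chroms)})
    return pd.DataFrame(rows)


@dataclass
class BreedComparison:
    scope: str
    venn_markers: tuple[int, int, int]
    venn_hotspot_markers: tuple[int, int, int]
    best_function_tally: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "scope": self.scope,
            "venn_markers": dict(zip(("only_A", "only_B", "shared"), self.venn_markers)),
            "venn_hotspot_markers": dict(
                zip(("only_A", "only_B", "shared"), self.venn_hotspot_markers)
            ),
        }
        if self.best_function_tally is not None:
            out["best_function_tally"] = self.best_function_tally.to_dict(orient="records")
        return out


def compare_panels(markers_a, markers_b, hotspot_markers_a=(), hotspot_markers_b=(),
                   best_a: dict[str, str] | None = None,
                   best_b: dict[str, str] | None = None,
                   scope: str = "all") -> BreedComparison:
    """Assemble the full two-population comparison."""
    tally = None
    if best_a is not None and best_b is not None:
        tally = best_function_tally(best_a, best_b)
    return BreedComparison(
        scope=str(scope),
        venn_markers=venn_counts(markers_a, markers_b),
        venn_hotspot_markers=venn_counts(hotspot_markers_a, hotspot_markers_b),
        best_function_tally=tally,
    )
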