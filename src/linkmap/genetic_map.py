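"""Genetic-map construction and per-chromosome summaries.

Two maps are built from the estimated recombination fractions:

* the *cumulative* map — genetic coordinates are the running sum of
  adjacent-marker recombination fractions (non-informative intervals
  contribute zero, their length having been attributed to the end of the
  enclosing gap during rate estimation);
* the *smoothed* map — coordinates minimise the weighted squared
  deviation between low pairwise recombination fractions (θ̂ < 0.05 by
  default) and the implied map distances d_j − d_i, subject to
  monotonicity.  In the small-θ regime recombination fractions are
  additive, so this is a consistent, convex and deterministic placement
  (a non-negative least-squares problem on the inter-marker increments).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, sparse

from .io import AdjacentRates, GeneticMap, HalfSibDataset, MarkerMap, PairwiseRates
from .estimate import OriginMatrix

__all__ = ["cumulative_map", "smoothed_map", "summarize"]


def cumulative_map(adjacent: AdjacentRates, marker_map: MarkerMap) -> GeneticMap:
    """Cumulative-sum genetic map: d₁ = 0, d_{k+1} = d_k + θ̂_k.

    NA intervals add zero length.  Monotone by construction since
    recombination fractions are non-negative.
    """
    rows = []
    df = adjacent.table
    for chrom in marker_map.chromosomes:
        sl = marker_map.chromosome_slice(chrom)
        ids = marker_map.marker_ids[sl]
        bp = marker_map.bp[sl]
        sub = df[df["chrom"] == chrom]
        if list(sub["left_id"]) != ids[:-1] or list(sub["right_id"]) != ids[1:]:
            raise ValueError(
                f"adjacent rates on chromosome {chrom} do not match the marker map"
            )
        theta = np.nan_to_num(sub["theta"].to_numpy(), nan=0.0)
        d = np.concatenate([[0.0], np.cumsum(theta)])
        rows.append(pd.DataFrame({
            "chrom": chrom, "marker_id": ids, "bp": bp,
            "d_morgan": d, "method": "cumulative",
        }))
    return GeneticMap(pd.concat(rows, ignore_index=True))


def _smooth_chromosome(ids: list[str], bp: np.ndarray, pairs: pd.DataFrame,
                       cutoff: float, weighted: bool):
    """Solve the monotone placement for one chromosome.

    Returns (d, interpolated_ids).  Variables are the non-negative
    increments g_k = d_{k+1} − d_k; a pair (i, j, θ̂) contributes the
    residual √w·(θ̂ − Σ_{k=i}^{j−1} g_k).
    """
    p = len(ids)
    index = {m: k for k, m in enumerate(ids)}
    adm = pairs[pairs["theta"] < cutoff]
    if adm.empty:
        raise ValueError(
            f"no pairwise rates below the smoothing cutoff {cutoff}; "
            "cannot place markers"
        )
    i_idx = adm["i_id"].map(index).to_numpy()
    j_idx = adm["j_id"].map(index).to_numpy()
    theta = adm["theta"].to_numpy()
    w = adm["n_inf"].to_numpy(dtype=float) if weighted else np.ones(len(adm))
    sw = np.sqrt(w)

    # sparse incidence matrix over increments
    rows, cols, vals = [], [], []
    for r, (i, j, s) in enumerate(zip(i_idx, j_idx, sw)):
        ks = np.arange(i, j)
        rows.extend([r] * ks.size)
        cols.extend(ks.tolist())
        vals.extend([s] * ks.size)
    a_mat = sparse.csr_matrix((vals, (rows, cols)), shape=(len(adm), p - 1))
    covered = np.asarray((a_mat != 0).sum(axis=0)).ravel() > 0

    g = np.zeros(p - 1)
    if covered.any():
        res = optimize.lsq_linear(
            a_mat[:, covered], sw * theta,
            bounds=(0.0, np.inf), tol=1e-14, max_iter=500,
        )
        g[covered] = res.x
    d = np.concatenate([[0.0], np.cumsum(np.maximum(g, 0.0))])

    # markers appearing in no admitted pair: interpolate linearly in bp
    in_pair = np.zeros(p, dtype=bool)
    in_pair[i_idx] = True
    in_pair[j_idx] = True
    interpolated = [ids[k] for k in np.flatnonzero(~in_pair)]
    if interpolated:
        anchors = np.flatnonzero(in_pair)
        if anchors.size:
            free = np.flatnonzero(~in_pair)
            left = np.searchsorted(anchors, free, side="right") - 1
            for m, li in zip(free, left):
                if li < 0:
                    d[m] = d[anchors[0]]  # before the first anchor: flat
                elif li == anchors.size - 1:
                    d[m] = d[anchors[-1]]
                else:
                    lo, hi = anchors[li], anchors[li + 1]
                    frac = (bp[m] - bp[lo]) / (bp[hi] - bp[lo])
                    d[m] = d[lo] + frac * (d[hi] - d[lo])
            d = np.maximum.accumulate(d)
            d -= d[0]
    return d, interpolated


def smoothed_map(pairwise: PairwiseRates, marker_map: MarkerMap,
                 cutoff: float = 0.05, weighted: bool = True) -> GeneticMap:
    """Monotone least-squares genetic map from low pairwise rates.

    Only pairs with θ̂ strictly below ``cutoff`` are admitted (small
    fractions are nearly additive in map distance).  Residuals are weighted
    by informative-meiosis counts unless ``weighted`` is False.  Markers
    constrained by no admitted pair are interpolated linearly in bp between
    their nearest constrained neighbours and flagged in
    ``GeneticMap.interpolated_ids``.
    """
    rows, flagged = [], set()
    df = pairwise.table
    for chrom in marker_map.chromosomes:
        sl = marker_map.chromosome_slice(chrom)
        ids = marker_map.marker_ids[sl]
        bp = marker_map.bp[sl]
        d, interp = _smooth_chromosome(ids, bp, df[df["chrom"] == chrom],
                                       cutoff, weighted)
        if interp:
            warnings.warn(
                f"chromosome {chrom}: {len(interp)} marker(s) interpolated in "
                "bp (no admitted pairwise rate)"
            )
            flagged.update(interp)
        rows.append(pd.DataFrame({
            "chrom": chrom, "marker_id": ids, "bp": bp,
            "d_morgan": d, "method": "smoothed",
        }))
    return GeneticMap(pd.concat(rows, ignore_index=True), frozenset(flagged))


def summarize(dataset: HalfSibDataset, maps: dict[str, GeneticMap],
              origins: OriginMatrix) -> pd.DataFrame:
    """Per-chromosome summary plus a genome total row.

    Columns: chromosome, n_markers, n_recombination_events,
    physical_length_bp and the genetic length of each supplied map in
    Morgan (``genetic_length_<method>_M``).
    """
    mmap = dataset.marker_map
    rows = []
    for chrom in mmap.chromosomes:
        sl = mmap.chromosome_slice(chrom)
        bp = mmap.bp[sl]
        row = {
            "chromosome": chrom,
            "n_markers": sl.stop - sl.start,
            "n_recombination_events": origins.n_recombination_events(chrom),
            "physical_length_bp": int(bp.max() - bp.min()),
        }
        for method, gmap in maps.items():
            row[f"genetic_length_{method}_M"] = gmap.length_morgan(chrom)
        rows.append(row)
    total = {
        "chromosome": "all",
        "n_markers": sum(r["n_markers"] for r in rows),
        "n_recombination_events": sum(r["n_recombination_events"] for r in rows),
        "physical_length_bp": sum(r["physical_length_bp"] for r in rows),
    }
    for method in maps:
        total[f"genetic_length_{method}_M"] = sum(
            r[f"genetic_length_{method}_M"] for r in rows
        )
    rows.append(total)
    return pd.DataFrame(rows)
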