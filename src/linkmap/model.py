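"""Model/Results facade over the estimation pipeline.

`RecombinationMapModel` is constructed from a half-sib dataset and `fit()`
runs quality control, paternal-origin inference, rate estimation and map
construction, returning a `RecombinationMapResults` object that carries
every intermediate table and exposes hotspot detection, map-function
fitting, scatter thinning and a summary table.  `MapFunctionModel` is the
corresponding object for the curve-fitting stage alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import estimate, genetic_map, landscape, mapfun, qc
from .io import AdjacentRates, GeneticMap, HalfSibDataset, PairwiseRates, read_halfsib


class RecombinationMapModel:
    """Paternal recombination-map model for a half-sib dataset.

    Parameters
    ----------
    dataset : HalfSibDataset
        Families of sire + progeny dosages over a physical marker map.
    maf_threshold : float
        Markers are kept iff their minor-allele frequency strictly exceeds
        this value (default 0.01).
    blocklist : iterable of str, optional
        Marker ids to exclude before estimation (for example markers with
        a suspect assembly position).
    """

    def __init__(self, dataset: HalfSibDataset, maf_threshold: float = 0.01,
                 blocklist=None):
        self.dataset = dataset
        self.maf_threshold = maf_threshold
        self.blocklist = set(blocklist) if blocklist else set()

    @classmethod
    def from_files(cls, ped_path, map_path, pedigree=None, **kwargs
                   ) -> "RecombinationMapModel":
        return cls(read_halfsib(ped_path, map_path, pedigree=pedigree), **kwargs)

    def fit(self, smoothing_cutoff: float = 0.05, max_pairs: int = 2_000_000,
            weighted_smoothing: bool = True) -> "RecombinationMapResults":
        """Run QC, origin inference, rate estimation and map construction."""
        data = self.dataset
        reports = {}
        if self.blocklist:
            data, reports["blocklist"] = qc.apply_blocklist(data, self.blocklist)
        data, reports["maf"] = qc.maf_filter(data, self.maf_threshold)
        data, reports["mendel"] = qc.mendel_check(data)
        origins = estimate.infer_origins(data)
        adjacent = estimate.adjacent_rates(origins)
        pairwise = estimate.pairwise_rates(origins, max_pairs=max_pairs)
        cmap = genetic_map.cumulative_map(adjacent, data.marker_map)
        smap = genetic_map.smoothed_map(pairwise, data.marker_map,
                                        cutoff=smoothing_cutoff,
                                        weighted=weighted_smoothing)
        return RecombinationMapResults(
            model=self, qc_data=data, qc_reports=reports, origins=origins,
            adjacent=adjacent, pairwise=pairwise,
            map_cumulative=cmap, map_smoothed=smap,
        )


@dataclass
class RecombinationMapResults:
    """Fitted recombination maps plus every intermediate product."""

    model: RecombinationMapModel
    qc_data: HalfSibDataset
    qc_reports: dict
    origins: estimate.OriginMatrix
    adjacent: AdjacentRates
    pairwise: PairwiseRates
    map_cumulative: GeneticMap
    map_smoothed: GeneticMap

    def summary(self) -> pd.DataFrame:
        """Per-chromosome marker counts, recombination events and map
        lengths, plus a genome total row."""
        return genetic_map.summarize(
            self.qc_data,
            {"cumulative": self.map_cumulative, "smoothed": self.map_smoothed},
            self.origins,
        )

    def detect_hotspots(self, multiplier: float = 2.5) -> landscape.HotspotResult:
        return landscape.detect_hotspots(self.adjacent, multiplier=multiplier)

    def map_function_pairs(self, which_map: str = "smoothed",
                           chrom: str | None = None) -> pd.DataFrame:
        """(d, θ̂, n_inf) rows joining pairwise rates with map distances."""
        gmap = self.map_smoothed if which_map == "smoothed" else self.map_cumulative
        pos = dict(zip(gmap.table["marker_id"], gmap.table["d_morgan"]))
        df = self.pairwise.table
        if chrom is not None:
            df = df[df["chrom"] == str(chrom)]
        d = df["i_id"].map(pos).to_numpy()
        d2 = df["j_id"].map(pos).to_numpy()
        return pd.DataFrame({
            "chrom": df["chrom"].to_numpy(),
            "d": np.abs(d2 - d),
            "theta": df["theta"].to_numpy(),
            "n_inf": df["n_inf"].to_numpy(),
        })

    def fit_map_functions(self, which_map: str = "smoothed",
                          chrom: str | None = None,
                          families=mapfun.FAMILIES) -> "MapFunctionResults":
        pairs = self.map_function_pairs(which_map=which_map, chrom=chrom)
        return MapFunctionModel(
            pairs["d"].to_numpy(), pairs["theta"].to_numpy(),
            weights=pairs["n_inf"].to_numpy(),
        ).fit(families=families)

    def thin_scatter(self, n_keep: int = 200_000, which_map: str = "smoothed",
                     chrom: str | None = None) -> pd.DataFrame:
        """Visualisation-ready thinned (d, θ̂) scatter in pair order."""
        pairs = self.map_function_pairs(which_map=which_map, chrom=chrom)
        pts, idx = mapfun.thin_scatter(
            pairs[["d", "theta"]].to_numpy(), n_keep=n_keep
        )
        return pairs.iloc[idx].reset_index(drop=True)

    def plot_landscape(self, chrom: str | None = None, multiplier: float = 2.5,
                       ax=None):
        """Adjacent-rate landscape with hotspot intervals highlighted."""
        import matplotlib.pyplot as plt

        hot = self.detect_hotspots(multiplier)
        df = self.adjacent.table
        if chrom is not None:
            df = df[df["chrom"] == str(chrom)]
        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(len(df))
        ax.scatter(x, df["theta"], s=8, label="adjacent rate")
        mask = df.apply(
            lambda r: (r["left_id"] in hot.flagged_markers
                       and r["right_id"] in hot.flagged_markers
                       and r["theta"] > hot.threshold_value), axis=1
        ) if len(df) else pd.Series(dtype=bool)
        if len(df) and mask.any():
            ax.scatter(x[mask.to_numpy()], df.loc[mask, "theta"], s=16,
                       color="crimson", label="hotspot")
        ax.axhline(hot.threshold_value, ls="--", lw=0.8, color="gray")
        ax.set_xlabel("interval (map order)")
        ax.set_ylabel("recombination fraction")
        ax.legend(frameon=False)
        return ax


class MapFunctionModel:
    """Least-squares genetic-map-function model on (d, θ̂) pairs.

    Fitting is unweighted by default, matching the plain sum-of-squares
    objective; pass ``use_weights=True`` to weight residuals by the stored
    informative-meiosis counts.
    """

    def __init__(self, d, theta_hat, weights=None):
        self.d = np.asarray(d, dtype=float)
        self.theta_hat = np.asarray(theta_hat, dtype=float)
        self.weights = None if weights is None else np.asarray(weights, dtype=float)

    def fit(self, families=mapfun.FAMILIES, use_weights: bool = False
            ) -> "MapFunctionResults":
        w = self.weights if use_weights else None
        fits = mapfun.fit_all(self.d, self.theta_hat, families=families, weights=w)
        best, ranked = mapfun.select_best(fits) if len(fits) > 1 else (fits[0].family, fits)
        return MapFunctionResults(model=self, fits=ranked, best_family=best)


@dataclass
class MapFunctionResults:
    model: MapFunctionModel
    fits: list[mapfun.MapFunctionFit]
    best_family: str
    _by_family: dict = field(init=False, repr=False)

    def __post_init__(self):
        self._by_family = {f.family: f for f in self.fits}

    def __getitem__(self, family: str) -> mapfun.MapFunctionFit:
        return self._by_family[family]

    @property
    def best(self) -> mapfun.MapFunctionFit:
        return self._by_family[self.best_family]

    def summary(self) -> pd.DataFrame:
        """One row per family: parameter, SSE, MSE, n_pairs, best flag."""
        rows = [{
            "family": f.family,
            "parameter": f.parameter,
            "sse": f.sse,
            "mse": f.mse,
            "n_pairs": f.n_pairs,
            "converged": f.converged,
            "best": f.family == self.best_family,
        } for f in self.fits]
        return pd.DataFrame(rows)

    def predict(self, d, family: str | None = None) -> np.ndarray:
        f = self._by_family[family or self.best_family]
        return mapfun.theta(f.family, d, f.parameter)

    def plot(self, ax=None, d_grid=None):
        """Fitted curves over the observed scatter."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.model.d, self.model.theta_hat, s=4, alpha=0.3,
                   color="gray", label="pairs")
        if d_grid is None:
            d_grid = np.linspace(0, max(self.model.d.max(), 1e-6), 200)
        for f in self.fits:
            ax.plot(d_grid, mapfun.theta(f.family, d_grid, f.parameter),
                    label=f"{f.family} (param={f.parameter:.3g})")
        ax.set_xlabel("map distance (Morgan)")
        ax.set_ylabel("recombination fraction")
        ax.legend(frameon=False, fontsize=8)
        return ax
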