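"""Half-sib genotype simulator with a known crossover process.

The paternal gamete is a two-state Markov chain along each chromosome:
state = which of the sire's two haplotypes is being copied, and the state
switches between adjacent markers with the interval's recombination
fraction θ_k.  This is a no-interference (Haldane-consistent) model, so
genetic distances implied by the true θs are exactly the Haldane transform
d_k = −½·ln(1 − 2θ_k), and fitting the scaled Haldane function to simulated
data against those true distances must recover a scale parameter close to 1
— the key end-to-end check for the whole estimation chain.

Dams are unobserved (paternal half-sib design): each maternal allele is an
independent draw from the population allele frequency of its marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Family, HalfSibDataset, MarkerMap
from . import mapfun

__all__ = ["SimulationConfig", "simulate_dataset", "theta_from_map", "default_marker_map"]


def default_marker_map(p: int = 100, chrom_length_bp: int = 100_000_000,
                       n_chromosomes: int = 1) -> MarkerMap:
    """Evenly spaced synthetic marker map (ids ``c<chrom>m<k>``)."""
    if p < 2:
        raise ValueError("need at least 2 markers per chromosome")
    rows = []
    positions = np.linspace(1, chrom_length_bp, p).astype(np.int64)
    for c in range(1, n_chromosomes + 1):
        for k, bp in enumerate(positions, start=1):
            rows.append((str(c), f"c{c}m{k}", int(bp)))
    return MarkerMap(pd.DataFrame(rows, columns=["chrom", "marker_id", "bp"]))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic half-sib design.

    Defaults emulate a desk-scale version of a dense cattle pedigree:
    200 paternal half-sib families of 50 progeny on a single 100-Mbp
    chromosome carrying 100 SNPs, with adjacent recombination fractions
    drawn uniformly from (0.002, 0.02) — about 1.1 Morgan per 100 Mbp,
    the ~1 cM/Mbp genome average of cattle.  Intermediate allele
    frequencies (0.3–0.7) keep most sires heterozygous, as on a SNP array
    after MAF filtering.  Genotyping error is off by default; QC tests
    switch it on.
    """

    n_families: int = 200
    n_progeny_per_family: int = 50
    marker_map: MarkerMap | None = None
    p: int = 100
    chrom_length_bp: int = 100_000_000
    true_adjacent_theta: np.ndarray | None = None
    theta_range: tuple[float, float] = (0.002, 0.02)
    true_map: object | None = None          # GeneticMap, with generating_family
    generating_family: str | None = None
    map_parameter: float | None = None
    allele_freq_range: tuple[float, float] = (0.3, 0.7)
    genotyping_error_rate: float = 0.0
    seed: int = 0

    def resolved_map(self) -> MarkerMap:
        return self.marker_map if self.marker_map is not None else default_marker_map(
            self.p, self.chrom_length_bp
        )


def theta_from_map(true_map, family: str, a) -> np.ndarray:
    """Adjacent recombination fractions implied by a genetic map.

    Applies θ_k = f(d_{k+1} − d_k | a) for the chosen map-function family
    to the consecutive differences of the map, per chromosome.
    """
    out = []
    for _, grp in true_map.table.groupby("chrom", sort=False):
        d = grp["d_morgan"].to_numpy()
        dd = np.diff(d)
        if (dd < 0).any():
            raise ValueError("genetic map positions must be monotone non-decreasing")
        out.append(mapfun.theta(family, dd, a))
    return np.concatenate(out) if out else np.empty(0)


def _resolve_theta(config: SimulationConfig, mmap: MarkerMap,
                   rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-chromosome adjacent θ vectors from whichever config channel is set."""
    sizes = {c: mmap.chromosome_slice(c) for c in mmap.chromosomes}
    if config.true_map is not None:
        if config.generating_family is None or config.map_parameter is None:
            raise ValueError("true_map requires generating_family and map_parameter")
        flat = theta_from_map(config.true_map, config.generating_family, config.map_parameter)
    elif config.true_adjacent_theta is not None:
        flat = np.asarray(config.true_adjacent_theta, dtype=float)
    else:
        lo, hi = config.theta_range
        n = sum(s.stop - s.start - 1 for s in sizes.values())
        flat = rng.uniform(lo, hi, size=n)
    if (flat < 0).any() or (flat > 0.5).any():
        raise ValueError("adjacent recombination fractions must lie in [0, 0.5]")
    expected = sum(s.stop - s.start - 1 for s in sizes.values())
    if flat.size != expected:
        raise ValueError(f"expected {expected} adjacent θ values, got {flat.size}")
    per_chrom, offset = {}, 0
    for c, s in sizes.items():
        k = s.stop - s.start - 1
        per_chrom[c] = flat[offset:offset + k]
        offset += k
    return per_chrom


def simulate_dataset(config: SimulationConfig):
    """Simulate a half-sib dataset with known paternal origins.

    Returns ``(dataset, truth, theta)`` where ``truth`` maps sire id to the
    (progeny × markers) matrix of transmitted sire-haplotype labels (1 or 2)
    and ``theta`` is the flat vector of true adjacent recombination
    fractions in map order (p−1 entries per chromosome).  Genotyping errors,
    when enabled, replace a dosage by a uniform draw from the other two
    valid values.  Fully reproducible from ``config.seed``.
    """
    mmap = config.resolved_map()
    if mmap.n_markers < 2:
        raise ValueError("need at least 2 markers")
    rng = np.random.default_rng(config.seed)
    theta = _resolve_theta(config, mmap, rng)

    p = mmap.n_markers
    lo, hi = config.allele_freq_range
    if not (0 < lo <= hi < 1):
        raise ValueError("allele_freq_range must lie inside (0, 1)")
    freqs = rng.uniform(lo, hi, size=p)

    chrom_slices = [mmap.chromosome_slice(c) for c in mmap.chromosomes]
    families, truth = [], {}
    n_prog = config.n_progeny_per_family
    for f in range(config.n_families):
        sire_id = f"sire{f + 1}"
        haps = (rng.random((2, p)) < freqs).astype(np.int8)
        origin = np.empty((n_prog, p), dtype=np.int8)
        for sl, c in zip(chrom_slices, mmap.chromosomes):
            th = theta[c]
            start = rng.integers(0, 2, size=n_prog)
            switches = rng.random((n_prog, th.size)) < th
            cum = np.cumsum(switches, axis=1) % 2
            chain = np.concatenate([np.zeros((n_prog, 1), dtype=np.int64), cum], axis=1)
            origin[:, sl] = ((start[:, None] + chain) % 2).astype(np.int8)
        paternal = haps[origin, np.arange(p)[None, :]]
        maternal = (rng.random((n_prog, p)) < freqs).astype(np.int8)
        dosage = (paternal + maternal).astype(float)

        eps = config.genotyping_error_rate
        if eps > 0:
            err = rng.random((n_prog, p)) < eps
            shift = rng.integers(1, 3, size=(n_prog, p))
            dosage = np.where(err, (dosage + shift) % 3, dosage)

        sire_dosage = haps.sum(axis=0).astype(float)
        if eps > 0:
            err = rng.random(p) < eps
            shift = rng.integers(1, 3, size=p)
            sire_dosage = np.where(err, (sire_dosage + shift) % 3, sire_dosage)

        prog_ids = [f"{sire_id}_p{i + 1}" for i in range(n_prog)]
        families.append(Family(sire_id, sire_dosage, prog_ids, dosage))
        truth[sire_id] = origin + 1  # 1/2 labels to match OriginMatrix
    flat_theta = np.concatenate([theta[c] for c in mmap.chromosomes])
    return HalfSibDataset(mmap, families), truth, flat_theta
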