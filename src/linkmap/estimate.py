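"""Paternal-origin inference, sire phasing and recombination-rate estimation.

The half-sib design turns recombination estimation into direct counting:
at a marker where the sire is heterozygous, a homozygous progeny reveals
which paternal allele it received.  Chaining those revelations across many
progeny phases the sire's two haplotypes; each progeny's gamete is then a
string of haplotype-of-origin labels, and a switch of origin between two
markers is a crossover.  Recombination fractions are the pooled fraction
of recombinant meioses among informative ones.

Phasing is a greedy majority chain over consecutive sire-heterozygous
markers: adjacent markers are linked "in phase" when the progeny that are
informative at both mostly transmit equal alleles, "in repulsion"
otherwise (ties count as "in phase" so output is deterministic).  Links
with no doubly-informative progeny cannot be resolved; the chromosome then
splits into phase blocks and no rate is ever pooled across blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AdjacentRates, Family, HalfSibDataset, MarkerMap, PairwiseRates

__all__ = [
    "FamilyOrigins", "OriginMatrix", "infer_transmitted_alleles", "phase_sire",
    "paternal_origins", "infer_origins", "adjacent_rates", "pairwise_rates",
    "candidate_pair_count",
]

UNKNOWN = -1  # transmitted-allele code; origins use 0 for unknown


def candidate_pair_count(p: int) -> int:
    """Number of intra-chromosomal marker pairs, p(p−1)/2."""
    if p < 0:
        raise ValueError("marker count must be non-negative")
    return p * (p - 1) // 2


def infer_transmitted_alleles(family: Family) -> np.ndarray:
    """Transmitted paternal alleles per progeny and marker.

    Values: 0 or 1 for the revealed paternal allele, −1 for unknown.  Only
    sire-heterozygous markers are informative: a progeny homozygous 0
    received paternal allele 0, homozygous 2 received allele 1; a
    heterozygous or missing progeny genotype reveals nothing.
    """
    n, p = family.progeny.shape if family.n_progeny else (0, family.sire.size)
    t = np.full((n, p), UNKNOWN, dtype=np.int8)
    if n == 0:
        return t
    het = family.sire == 1
    prog = family.progeny
    t[(prog == 0) & het[None, :]] = 0
    t[(prog == 2) & het[None, :]] = 1
    return t


def phase_sire(transmitted: np.ndarray, het_idx: np.ndarray):
    """Phase the sire's haplotypes over its heterozygous markers.

    ``transmitted`` is the (progeny × markers) matrix from
    :func:`infer_transmitted_alleles`; ``het_idx`` the indices of the
    sire-heterozygous markers, in map order.  Returns ``(hap1, hap2,
    blocks)``: two complementary allele vectors over ``het_idx`` (defined
    up to a global flip within each block) and integer phase-block labels.
    A new block starts wherever no progeny is informative at both markers
    of a consecutive pair.
    """
    h = het_idx.size
    if h == 0:
        return (np.empty(0, np.int8), np.empty(0, np.int8), np.empty(0, np.int64))
    t = transmitted[:, het_idx]
    inf = t != UNKNOWN
    hap1 = np.zeros(h, dtype=np.int8)
    blocks = np.zeros(h, dtype=np.int64)
    if h > 1:
        both = inf[:, 1:] & inf[:, :-1]
        eq = (t[:, 1:] == t[:, :-1]) & both
        concord = eq.sum(axis=0) - (both & ~eq).sum(axis=0)
        resolved = both.any(axis=0)
        same = concord >= 0
        for k in range(1, h):
            if not resolved[k - 1]:
                blocks[k:] += 1
                hap1[k] = 0  # fresh block: restart the phase convention
            else:
                blocks[k] = blocks[k - 1]
                hap1[k] = hap1[k - 1] if same[k - 1] else 1 - hap1[k - 1]
    return hap1, (1 - hap1).astype(np.int8), blocks


def paternal_origins(transmitted: np.ndarray, het_idx: np.ndarray,
                     hap1: np.ndarray) -> np.ndarray:
    """Haplotype-of-origin labels from transmitted alleles and sire phase.

    Returns a (progeny × het markers) matrix with 1 where the transmitted
    allele matches haplotype 1, 2 where it matches haplotype 2, and 0 where
    the transmission is unknown.
    """
    t = transmitted[:, het_idx]
    origins = np.zeros(t.shape, dtype=np.int8)
    known = t != UNKNOWN
    origins[known & (t == hap1[None, :])] = 1
    origins[known & (t != hap1[None, :])] = 2
    return origins


@dataclass
class FamilyOrigins:
    """Phasing and origin labels for one family on one chromosome."""

    sire_id: str
    chrom: str
    het_idx: np.ndarray     # indices into the chromosome's marker order
    origins: np.ndarray     # (progeny × het markers), 0 unknown / 1 / 2
    blocks: np.ndarray      # phase-block label per het marker
    hap1: np.ndarray
    hap2: np.ndarray


@dataclass
class OriginMatrix:
    """All per-family, per-chromosome origin labels plus the marker map."""

    marker_map: MarkerMap
    families: list[FamilyOrigins]

    def for_chromosome(self, chrom: str) -> list[FamilyOrigins]:
        return [f for f in self.families if f.chrom == str(chrom)]

    def n_recombination_events(self, chrom: str | None = None) -> int:
        """Total origin switches between consecutive informative markers
        (within phase blocks), over all progeny and families."""
        total = 0
        for fo in self.families:
            if chrom is not None and fo.chrom != str(chrom):
                continue
            for counts in _family_gap_counts(fo):
                total += counts[3]
        return total


def infer_origins(data: HalfSibDataset) -> OriginMatrix:
    """Run transmission inference, phasing and origin labelling per family
    and chromosome."""
    out = []
    mmap = data.marker_map
    for fam in data.families:
        t = infer_transmitted_alleles(fam)
        for chrom in mmap.chromosomes:
            sl = mmap.chromosome_slice(chrom)
            het_global = np.flatnonzero(fam.sire[sl] == 1) + sl.start
            t_chrom = t  # het_idx below are global, relative index handled here
            hap1, hap2, blocks = phase_sire(t_chrom, het_global)
            origins = paternal_origins(t_chrom, het_global, hap1)
            out.append(FamilyOrigins(
                fam.sire_id, str(chrom), het_global - sl.start,
                origins, blocks, hap1, hap2,
            ))
    return OriginMatrix(mmap, out)


def _family_gap_counts(fo: FamilyOrigins):
    """Yield (left_idx, right_idx, n_informative, n_recombinant) for each
    consecutive sire-heterozygous pair inside one phase block."""
    o = fo.origins
    idx = fo.het_idx
    for k in range(idx.size - 1):
        if fo.blocks[k] != fo.blocks[k + 1]:
            continue
        both = (o[:, k] > 0) & (o[:, k + 1] > 0)
        n_inf = int(both.sum())
        if n_inf == 0:
            continue
        n_rec = int(((o[:, k] != o[:, k + 1]) & both).sum())
        yield int(idx[k]), int(idx[k + 1]), n_inf, n_rec


def adjacent_rates(origins: OriginMatrix, marker_map: MarkerMap | None = None
                   ) -> AdjacentRates:
    """Pooled recombination fractions between consecutive markers.

    For every interval of the physical map, counts are pooled over families
    whose consecutive sire-heterozygous pair spans exactly that interval
    (meiosis-weighted pooling: θ̂ = Σ n_rec / Σ n_inf).  Intervals that no
    family covers directly get NA — unless they lie inside a gap that is
    non-informative in *every* family, in which case the pooled gap counts
    are attributed to the gap's last interval so that the cumulative map
    conserves total genetic length across the gap.
    """
    mmap = marker_map or origins.marker_map
    rows = []
    for chrom in mmap.chromosomes:
        sl = mmap.chromosome_slice(chrom)
        ids = mmap.marker_ids[sl]
        p = len(ids)
        n_inf = np.zeros(p - 1, dtype=np.int64)
        n_rec = np.zeros(p - 1, dtype=np.int64)
        gap_counts: dict[tuple[int, int], list[int]] = {}
        for fo in origins.for_chromosome(chrom):
            for i, j, inf, rec in _family_gap_counts(fo):
                if j - i == 1:
                    n_inf[i] += inf
                    n_rec[i] += rec
                else:
                    c = gap_counts.setdefault((i, j), [0, 0])
                    c[0] += inf
                    c[1] += rec
        # gap rule: only where the whole span is globally non-informative
        for (i, j), (inf, rec) in sorted(gap_counts.items()):
            if inf > 0 and (n_inf[i:j] == 0).all():
                n_inf[j - 1] += inf
                n_rec[j - 1] += rec
        if (n_inf == 0).any():
            warnings.warn(
                f"chromosome {chrom}: {int((n_inf == 0).sum())} interval(s) "
                "without informative meioses (theta = NA)"
            )
        with np.errstate(invalid="ignore"):
            theta = np.where(n_inf > 0, n_rec / np.maximum(n_inf, 1), np.nan)
        for k in range(p - 1):
            rows.append((chrom, ids[k], ids[k + 1], theta[k],
                         int(n_inf[k]), int(n_rec[k])))
    return AdjacentRates(pd.DataFrame(rows, columns=[
        "chrom", "left_id", "right_id", "theta", "n_inf", "n_rec"]))


def pairwise_rates(origins: OriginMatrix, marker_map: MarkerMap | None = None,
                   max_pairs: int = 2_000_000) -> PairwiseRates:
    """Pooled recombination fractions between all intra-chromosomal pairs.

    For each ordered pair i < j of markers (map order), θ̂_ij is the pooled
    fraction of progeny whose haplotype of origin differs between i and j,
    among progeny informative at both, over all families in which both
    markers are sire-heterozygous and in the same phase block.  Entries with
    no informative meioses are omitted.  Rows are emitted in the
    column-major order of the upper triangle (j outer, i inner), the
    vectorisation assumed by scatter thinning.

    Raises when the candidate pair count exceeds ``max_pairs`` — raise the
    cap explicitly for large chromosomes.
    """
    mmap = marker_map or origins.marker_map
    total = sum(
        candidate_pair_count(mmap.chromosome_slice(c).stop - mmap.chromosome_slice(c).start)
        for c in mmap.chromosomes
    )
    if total > max_pairs:
        raise ValueError(
            f"{total} candidate marker pairs exceed the cap of {max_pairs}; "
            "pass a larger max_pairs to proceed"
        )
    rows = []
    for chrom in mmap.chromosomes:
        sl = mmap.chromosome_slice(chrom)
        ids = mmap.marker_ids[sl]
        p = len(ids)
        ninf = np.zeros((p, p))
        nrec = np.zeros((p, p))
        for fo in origins.for_chromosome(chrom):
            o = fo.origins
            if o.size == 0:
                continue
            inf = (o > 0).astype(float)
            a = (o == 1).astype(float)
            b = (o == 2).astype(float)
            n_inf_h = inf.T @ inf
            n_eq_h = a.T @ a + b.T @ b
            same_block = fo.blocks[:, None] == fo.blocks[None, :]
            n_inf_h *= same_block
            n_eq_h *= same_block
            ix = np.ix_(fo.het_idx, fo.het_idx)
            ninf[ix] += n_inf_h
            nrec[ix] += n_inf_h - n_eq_h
        # column-major upper triangle: j outer, i inner
        for j in range(1, p):
            for i in range(j):
                if ninf[i, j] > 0:
                    rows.append((chrom, ids[i], ids[j],
                                 nrec[i, j] / ninf[i, j], int(ninf[i, j])))
    return PairwiseRates(pd.DataFrame(rows, columns=[
        "chrom", "i_id", "j_id", "theta", "n_inf"]))
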