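"""Domain containers and file formats.

Coordinate conventions used throughout the package:

* physical positions are 1-based base pairs (PLINK ``.map`` convention);
* genetic positions are Morgan internally; centiMorgan appears only in
  report-layer tables;
* genotypes are dosages of the minor allele in {0, 1, 2}, with ``NaN`` for
  missing.  The minor allele is determined per dataset (not per family),
  ties at frequency 0.5 broken toward the lexicographically smaller allele
  so that dosage coding is deterministic.

Containers are thin wrappers around :class:`pandas.DataFrame` (rate tables,
maps) or NumPy arrays (genotypes) that validate their invariants on
construction and round-trip losslessly through CSV.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: float format used by every CSV writer; 17 significant digits guarantee
#: exact round-trip of IEEE doubles through text.
FLOAT_FMT = "%.17g"

ADJACENT_COLUMNS = ["chrom", "left_id", "right_id", "theta", "n_inf", "n_rec"]
PAIRWISE_COLUMNS = ["chrom", "i_id", "j_id", "theta", "n_inf"]
GENETIC_MAP_COLUMNS = ["chrom", "marker_id", "bp", "d_morgan", "method"]


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


def _chrom_sort_key(label: str):
    """Sort chromosomes numerically when possible, else lexicographically."""
    s = str(label)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


# ---------------------------------------------------------------------------
# MarkerMap
# ---------------------------------------------------------------------------

@dataclass
class MarkerMap:
    """Ordered physical coordinates of SNPs (the physical map).

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``chrom`` (str), ``marker_id`` (str), ``bp`` (int, 1-based).
        Rows are sorted by (chromosome, bp) on construction; within a
        chromosome positions must be strictly increasing after sorting
        (duplicate positions are rejected) and marker ids must be unique
        across the whole map.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in ("chrom", "marker_id", "bp") if c not in df.columns]
        if missing:
            raise FormatError(f"marker map missing column(s): {', '.join(missing)}")
        df = df.loc[:, ["chrom", "marker_id", "bp"]].copy()
        df["chrom"] = df["chrom"].astype(str)
        df["marker_id"] = df["marker_id"].astype(str)
        bp = pd.to_numeric(df["bp"], errors="raise")
        if (bp < 1).any():
            bad = df.loc[bp < 1, "marker_id"].iloc[0]
            raise FormatError(f"bp position < 1 for marker {bad!r} (positions are 1-based)")
        df["bp"] = bp.astype(np.int64)
        dup = df["marker_id"].duplicated()
        if dup.any():
            raise FormatError(f"duplicate marker id {df.loc[dup, 'marker_id'].iloc[0]!r}")
        df = df.sort_values(
            ["chrom", "bp"],
            key=lambda s: s.map(_chrom_sort_key) if s.name == "chrom" else s,
            kind="mergesort",
        ).reset_index(drop=True)
        for chrom, grp in df.groupby("chrom", sort=False):
            if grp["bp"].duplicated().any():
                raise FormatError(f"duplicate bp position on chromosome {chrom}")
        self.table = df

    # -- basic queries ------------------------------------------------------

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> list[str]:
        return self.table["marker_id"].tolist()

    @property
    def bp(self) -> np.ndarray:
        return self.table["bp"].to_numpy()

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def chromosome_slice(self, chrom: str) -> slice:
        """Contiguous row slice of a chromosome in map order."""
        idx = np.flatnonzero(self.table["chrom"].to_numpy() == str(chrom))
        if idx.size == 0:
            raise KeyError(f"chromosome {chrom!r} not in marker map")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def subset(self, keep: np.ndarray) -> "MarkerMap":
        """New map restricted to a boolean mask / index array over rows."""
        return MarkerMap(self.table.iloc[np.asarray(keep)].reset_index(drop=True))

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, MarkerMap) and self.table.equals(other.table)

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def read(cls, path, dialect: str = "plink_map") -> "MarkerMap":
        """Read a physical map.

        ``plink_map``: whitespace-separated 4 columns (chrom, id,
        genetic position — ignored on read —, bp).  ``tsv``: tab-separated
        with a header containing at least chrom, marker_id, bp.
        """
        if dialect == "plink_map":
            rows = []
            with open(path) as fh:
                for lineno, line in enumerate(fh, start=1):
                    parts = line.split()
                    if not parts:
                        continue
                    if len(parts) < 4:
                        raise FormatError(
                            f"{path}: line {lineno}: expected 4 columns, got {len(parts)}"
                        )
                    chrom, marker_id, _cm, bp = parts[:4]
                    try:
                        bp_val = int(bp)
                    except ValueError:
                        raise FormatError(
                            f"{path}: line {lineno}: non-numeric bp {bp!r}"
                        ) from None
                    rows.append((chrom, marker_id, bp_val))
            return cls(pd.DataFrame(rows, columns=["chrom", "marker_id", "bp"]))
        if dialect == "tsv":
            df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "marker_id": str})
            try:
                df["bp"] = pd.to_numeric(df["bp"], errors="raise")
            except (ValueError, KeyError) as exc:
                raise FormatError(f"{path}: bad bp column: {exc}") from None
            return cls(df)
        raise ValueError(f"unknown dialect {dialect!r}")

    def write(self, path, dialect: str = "plink_map") -> None:
        if dialect == "plink_map":
            out = self.table.copy()
            out.insert(2, "cm", 0)  # PLINK's genetic-position column
            out.to_csv(path, sep="\t", header=False, index=False)
        elif dialect == "tsv":
            self.table.to_csv(path, sep="\t", index=False)
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def read_marker_map(path, dialect: str = "plink_map") -> MarkerMap:
    """Functional alias for :meth:`MarkerMap.read`."""
    return MarkerMap.read(path, dialect=dialect)


# ---------------------------------------------------------------------------
# Half-sib genotypes
# ---------------------------------------------------------------------------

@dataclass
class Family:
    """One half-sib family: a sire and its genotyped progeny.

    Dosages are float arrays with values in {0, 1, 2} and NaN for missing;
    ``progeny`` has one row per progeny, columns follow the marker map.
    """

    sire_id: str
    sire: np.ndarray
    progeny_ids: list[str]
    progeny: np.ndarray

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=float)
        self.progeny = np.asarray(self.progeny, dtype=float).reshape(
            len(self.progeny_ids), -1 if len(self.progeny_ids) else self.sire.size
        )
        for arr, what in ((self.sire, "sire"), (self.progeny, "progeny")):
            vals = arr[~np.isnan(arr)]
            if not np.isin(vals, (0.0, 1.0, 2.0)).all():
                raise ValueError(f"{what} dosages outside {{0,1,2,NA}} for sire {self.sire_id}")

    @property
    def n_progeny(self) -> int:
        return len(self.progeny_ids)


@dataclass
class HalfSibDataset:
    """Half-sib families plus the marker map their genotypes follow."""

    marker_map: MarkerMap
    families: list[Family]

    def __post_init__(self) -> None:
        p = self.marker_map.n_markers
        for fam in self.families:
            if fam.sire.size != p or (fam.n_progeny and fam.progeny.shape[1] != p):
                raise ValueError(
                    f"family {fam.sire_id}: genotype length does not match "
                    f"marker map ({p} markers)"
                )

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def n_progeny(self) -> int:
        return sum(f.n_progeny for f in self.families)

    def subset_markers(self, keep: np.ndarray) -> "HalfSibDataset":
        """Dataset restricted to a boolean mask over markers."""
        keep = np.asarray(keep)
        fams = [
            Family(
                f.sire_id,
                f.sire[keep],
                list(f.progeny_ids),
                f.progeny[:, keep] if f.n_progeny else f.progeny.reshape(0, -1)[:, keep],
            )
            for f in self.families
        ]
        return HalfSibDataset(self.marker_map.subset(keep), fams)

    def all_dosages(self) -> np.ndarray:
        """Stacked (individuals × markers) dosage matrix, sires first."""
        blocks = [f.sire[None, :] for f in self.families]
        blocks += [f.progeny for f in self.families if f.n_progeny]
        return np.vstack(blocks)


def read_halfsib(ped_path, map_path, pedigree: dict[str, str] | None = None,
                 map_dialect: str = "plink_map") -> HalfSibDataset:
    """Read a PLINK text ``.ped``/``.map`` pair into half-sib families.

    The ``.ped`` file is whitespace-separated with the 6 standard leading
    columns (family, individual, father, mother, sex, phenotype) followed by
    two allele columns per marker; ``0`` codes a missing allele and ``0 0``
    becomes a NaN dosage.  ``pedigree`` maps progeny id → sire id; when
    omitted, the father column is used.  Every referenced sire must have a
    genotype row, otherwise the orphan progeny are reported in the error.

    Allele pairs are converted to minor-allele dosages; the minor allele is
    determined per marker from allele counts over the whole file.
    """
    mmap = MarkerMap.read(map_path, dialect=map_dialect)
    # .map files are not necessarily bp-sorted; remember the column order of
    # the .ped file so genotypes can be permuted into map order.
    raw_ids = []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if parts:
                raw_ids.append(parts[1])
    order = [raw_ids.index(m) for m in mmap.marker_ids]

    p = mmap.n_markers
    ids: list[str] = []
    fathers: dict[str, str] = {}
    alleles: dict[str, np.ndarray] = {}
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * p:
                raise FormatError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * p} fields "
                    f"for {p} markers, got {len(parts)}"
                )
            iid, pat = parts[1], parts[2]
            a = np.array(parts[6:], dtype=object).reshape(p, 2)[order]
            ids.append(iid)
            fathers[iid] = pat
            alleles[iid] = a

    if pedigree is None:
        pedigree = {iid: pat for iid, pat in fathers.items() if pat not in ("0", "")}
    # a genotyped individual named as a father stays a family even if the
    # pedigree assigns it no progeny
    declared = {pat for pat in fathers.values() if pat in alleles}
    sires = sorted(set(pedigree.values()) | declared, key=str)
    orphans = sorted(i for i, s in pedigree.items() if s not in alleles)
    if orphans:
        raise FormatError(
            "progeny with no genotyped sire: " + ", ".join(orphans)
        )

    # Minor allele per marker from allele counts over the full file.
    minor = np.empty(p, dtype=object)
    stacked = np.stack([alleles[i] for i in ids])  # (n, p, 2)
    for k in range(p):
        col = stacked[:, k, :].ravel()
        col = col[col != "0"]
        uniq, counts = np.unique(col, return_counts=True)
        if uniq.size > 2:
            raise FormatError(
                f"marker {mmap.marker_ids[k]!r} has >2 alleles: {sorted(uniq)}"
            )
        if uniq.size == 0:
            minor[k] = None
            continue
        if uniq.size == 1:
            # only one allele observed: it is the major allele; dosage 0
            minor[k] = "\x00"  # sentinel never matching a real allele
            continue
        c0, c1 = counts
        if c0 == c1:
            minor[k] = min(uniq)  # deterministic tie-break
        else:
            minor[k] = uniq[np.argmin(counts)]

    def to_dosage(a: np.ndarray) -> np.ndarray:
        d = np.empty(p, dtype=float)
        for k in range(p):
            x, y = a[k]
            if x == "0" or y == "0" or minor[k] is None:
                d[k] = np.nan
            else:
                d[k] = (x == minor[k]) + (y == minor[k])
        return d

    dosages = {iid: to_dosage(alleles[iid]) for iid in ids}
    families = []
    for sire in sires:
        prog = sorted(i for i, s in pedigree.items() if s == sire)
        if not prog:
            warnings.warn(f"sire {sire} has no progeny; family retained empty")
        mat = (
            np.vstack([dosages[i] for i in prog])
            if prog else np.empty((0, p), dtype=float)
        )
        families.append(Family(sire, dosages[sire], prog, mat))
    return HalfSibDataset(mmap, families)


_DOSAGE_TO_ALLELES = {0.0: ("A", "A"), 1.0: ("A", "B"), 2.0: ("B", "B")}


def write_halfsib(dataset: HalfSibDataset, ped_path, map_path) -> None:
    """Write a dataset as a PLINK text ``.ped``/``.map`` pair.

    Dosage d is encoded as d copies of allele ``B`` (so ``B`` is minor as
    long as its frequency stays below 0.5); NaN becomes ``0 0``.
    """
    dataset.marker_map.write(map_path, dialect="plink_map")

    def geno_fields(dos: np.ndarray) -> list[str]:
        out = []
        for d in dos:
            a, b = _DOSAGE_TO_ALLELES.get(d, ("0", "0")) if not np.isnan(d) else ("0", "0")
            out.extend((a, b))
        return out

    with open(ped_path, "w") as fh:
        for fam in dataset.families:
            fields = [fam.sire_id, fam.sire_id, "0", "0", "1", "-9"]
            fh.write(" ".join(fields + geno_fields(fam.sire)) + "\n")
        for fam in dataset.families:
            for i, pid in enumerate(fam.progeny_ids):
                fields = [fam.sire_id, pid, fam.sire_id, "0", "0", "-9"]
                fh.write(" ".join(fields + geno_fields(fam.progeny[i])) + "\n")


# ---------------------------------------------------------------------------
# Rate tables and genetic maps
# ---------------------------------------------------------------------------

def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} missing column(s): {', '.join(missing)}")


@dataclass
class AdjacentRates:
    """Recombination-fraction estimates between consecutive markers.

    One row per interval of the physical map, in map order:
    ``chrom, left_id, right_id, theta, n_inf, n_rec``.  ``theta`` is
    ``n_rec / n_inf`` when informative meioses exist and NaN otherwise.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_columns(self.table, ADJACENT_COLUMNS, "adjacent rates")
        df = self.table.loc[:, ADJACENT_COLUMNS].copy()
        df["chrom"] = df["chrom"].astype(str)
        df["n_inf"] = df["n_inf"].astype(np.int64)
        df["n_rec"] = df["n_rec"].astype(np.int64)
        df["theta"] = df["theta"].astype(float)
        inf = df["n_inf"].to_numpy()
        if (df["n_rec"].to_numpy() > inf).any() or (inf < 0).any():
            raise ValueError("n_rec must lie in [0, n_inf]")
        with np.errstate(invalid="ignore", divide="ignore"):
            expect = np.where(inf > 0, df["n_rec"].to_numpy() / np.maximum(inf, 1), np.nan)
        got = df["theta"].to_numpy()
        ok = np.where(inf > 0, np.isclose(got, expect, atol=1e-12), np.isnan(got))
        if not ok.all():
            raise ValueError("theta inconsistent with n_rec / n_inf")
        self.table = df.reset_index(drop=True)

    @property
    def theta(self) -> np.ndarray:
        return self.table["theta"].to_numpy()

    def write(self, path) -> None:
        self.table.to_csv(path, index=False, float_format=FLOAT_FMT)

    @classmethod
    def read(cls, path) -> "AdjacentRates":
        return cls(pd.read_csv(path, dtype={"chrom": str}, float_precision="round_trip"))

    def __eq__(self, other) -> bool:
        return isinstance(other, AdjacentRates) and _frames_equal(self.table, other.table)


@dataclass
class PairwiseRates:
    """Sparse upper-triangular recombination fractions between marker pairs.

    Rows ``chrom, i_id, j_id, theta, n_inf`` with i preceding j in map order.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_columns(self.table, PAIRWISE_COLUMNS, "pairwise rates")
        df = self.table.loc[:, PAIRWISE_COLUMNS].copy()
        df["chrom"] = df["chrom"].astype(str)
        df["n_inf"] = df["n_inf"].astype(np.int64)
        df["theta"] = df["theta"].astype(float)
        th = df["theta"].to_numpy()
        if ((th < 0) | (th > 1)).any():
            raise ValueError("pairwise theta outside [0, 1]")
        self.table = df.reset_index(drop=True)

    def write(self, path) -> None:
        self.table.to_csv(path, index=False, float_format=FLOAT_FMT)

    @classmethod
    def read(cls, path) -> "PairwiseRates":
        return cls(pd.read_csv(path, dtype={"chrom": str}, float_precision="round_trip"))

    def __eq__(self, other) -> bool:
        return isinstance(other, PairwiseRates) and _frames_equal(self.table, other.table)


@dataclass
class GeneticMap:
    """Per-marker genetic coordinates in Morgan.

    ``method`` is ``cumulative`` (running sum of adjacent rates) or
    ``smoothed`` (monotone least-squares placement from pairwise rates).
    Positions start at 0 and are non-decreasing within each chromosome.
    ``interpolated_ids`` flags markers whose position was interpolated in bp
    because no admitted pairwise rate constrained them (not serialised).
    """

    table: pd.DataFrame
    interpolated_ids: frozenset[str] = field(default_factory=frozenset, compare=False)

    def __post_init__(self) -> None:
        _check_columns(self.table, GENETIC_MAP_COLUMNS, "genetic map")
        df = self.table.loc[:, GENETIC_MAP_COLUMNS].copy()
        df["chrom"] = df["chrom"].astype(str)
        df["marker_id"] = df["marker_id"].astype(str)
        df["bp"] = df["bp"].astype(np.int64)
        df["d_morgan"] = df["d_morgan"].astype(float)
        methods = set(df["method"])
        if not methods <= {"cumulative", "smoothed"}:
            raise ValueError(f"unknown map method(s): {sorted(methods - {'cumulative', 'smoothed'})}")
        for chrom, grp in df.groupby("chrom", sort=False):
            d = grp["d_morgan"].to_numpy()
            if d.size and (d[0] != 0 or (np.diff(d) < -1e-12).any()):
                raise ValueError(f"genetic positions on chromosome {chrom} not monotone from 0")
        self.table = df.reset_index(drop=True)

    @property
    def d_morgan(self) -> np.ndarray:
        return self.table["d_morgan"].to_numpy()

    def length_morgan(self, chrom: str | None = None) -> float:
        df = self.table if chrom is None else self.table[self.table["chrom"] == str(chrom)]
        if chrom is None:
            return float(sum(g["d_morgan"].max() for _, g in df.groupby("chrom", sort=False)))
        return float(df["d_morgan"].max())

    def write(self, path) -> None:
        self.table.to_csv(path, index=False, float_format=FLOAT_FMT)

    @classmethod
    def read(cls, path) -> "GeneticMap":
        return cls(pd.read_csv(path, dtype={"chrom": str, "marker_id": str}, float_precision="round_trip"))

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneticMap) and _frames_equal(self.table, other.table)


def _frames_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    for col in a.columns:
        x, y = a[col].to_numpy(), b[col].to_numpy()
        if x.dtype.kind == "f":
            if not np.allclose(x, y, rtol=0, atol=0, equal_nan=True):
                return False
        elif not (x == y).all():
            return False
    return True


def write_rates(rates: AdjacentRates | PairwiseRates, path) -> None:
    rates.write(path)


def write_genetic_map(gmap: GeneticMap, path) -> None:
    gmap.write(path)


def read_rates(path, kind: str = "adjacent") -> AdjacentRates | PairwiseRates:
    """Read a rate CSV; ``kind`` is ``adjacent`` or ``pairwise``."""
    if kind == "adjacent":
        return AdjacentRates.read(path)
    if kind == "pairwise":
        return PairwiseRates.read(path)
    raise ValueError(f"unknown rates kind {kind!r}")
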