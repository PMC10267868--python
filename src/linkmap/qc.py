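"""Genotype quality control: MAF filter, Mendelian checks, marker blocklist.

Only genotype-level rules are applied: markers failing the minor-allele-
frequency threshold are removed, progeny genotypes in opposite-homozygote
conflict with their sire are set to missing, and a user-supplied blocklist
of (for example, putatively misplaced) marker ids is excluded.  Missing
values are never imputed — downstream estimation treats them as
non-informative meioses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .io import Family, HalfSibDataset


@dataclass
class QcReport:
    n_markers_in: int
    n_markers_out: int
    n_mendel_errors_set_na: int = 0
    removed_marker_ids: list[str] = field(default_factory=list)
    blocklist_removed: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_markers_out > self.n_markers_in:
            raise ValueError("n_markers_out cannot exceed n_markers_in")

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def minor_allele_frequencies(data: HalfSibDataset) -> np.ndarray:
    """Per-marker MAF over all non-missing dosages of all individuals.

    Dosages count the dataset's minor allele, but the frequency is folded
    (min(f, 1−f)) so the result is a true MAF even if coding drifted after
    subsetting.
    """
    dos = data.all_dosages()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        f = np.nanmean(dos, axis=0) / 2.0
    f = np.where(np.isnan(f), 0.0, f)
    return np.minimum(f, 1.0 - f)


def maf_filter(data: HalfSibDataset, threshold: float = 0.01):
    """Remove markers with MAF ≤ threshold (markers are kept iff MAF is
    strictly greater than the threshold).

    Returns ``(filtered_dataset, QcReport)``.
    """
    if not (0.0 <= threshold <= 0.5):
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    maf = minor_allele_frequencies(data)
    keep = maf > threshold
    if not keep.any():
        raise ValueError(
            f"MAF filter at threshold {threshold} removed every marker; "
            "lower the threshold"
        )
    removed = [m for m, k in zip(data.marker_map.marker_ids, keep) if not k]
    report = QcReport(
        n_markers_in=data.marker_map.n_markers,
        n_markers_out=int(keep.sum()),
        removed_marker_ids=removed,
    )
    return data.subset_markers(keep), report


def mendel_check(data: HalfSibDataset):
    """Set progeny dosages in opposite-homozygote conflict with the sire to NA.

    A conflict is sire 0 with progeny 2, or sire 2 with progeny 0 — the
    progeny cannot have received a compatible paternal allele.
    Heterozygous or missing sire genotypes never conflict.  Returns
    ``(cleaned_dataset, QcReport)``; marker count is unchanged.
    """
    n_errors = 0
    fams = []
    for fam in data.families:
        prog = fam.progeny.copy()
        if fam.n_progeny:
            sire = fam.sire[None, :]
            conflict = ((sire == 0) & (prog == 2)) | ((sire == 2) & (prog == 0))
            n_errors += int(conflict.sum())
            prog[conflict] = np.nan
        fams.append(Family(fam.sire_id, fam.sire.copy(), list(fam.progeny_ids), prog))
    p = data.marker_map.n_markers
    report = QcReport(n_markers_in=p, n_markers_out=p, n_mendel_errors_set_na=n_errors)
    return HalfSibDataset(data.marker_map, fams), report


def apply_blocklist(data: HalfSibDataset, blocklist):
    """Remove the listed marker ids; unknown ids are ignored with a warning."""
    blocklist = set(blocklist)
    ids = data.marker_map.marker_ids
    present = [m for m in ids if m in blocklist]
    unknown = sorted(blocklist - set(ids))
    if unknown:
        warnings.warn(f"blocklist ids not in marker map (ignored): {', '.join(unknown)}")
    keep = np.array([m not in blocklist for m in ids])
    if not keep.any():
        raise ValueError("blocklist would remove every marker")
    report = QcReport(
        n_markers_in=len(ids),
        n_markers_out=int(keep.sum()),
        removed_marker_ids=list(present),
        blocklist_removed=list(present),
    )
    if not present:
        return data, report
    return data.subset_markers(keep), report
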