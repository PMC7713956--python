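"""Founder-admixture screen: lineage-specific SNP counts in fixed windows.

A Timor founder genome is scanned for segments introgressed from the
Australian population: the genome is tiled into non-overlapping 500-kb
windows ([start, start+500000), 0-based half-open), the number of
Timor-specific SNPs (homozygous non-reference in the focal bird and
absent from the pooled Australian reference data) is counted per
window, and windows with fewer than 100 specific SNPs are flagged as
introgressed.  Adjacent flagged windows merge into regions; the admixed
fraction of the diploid genome weights heterozygous tracts by one
haplotype copy and homozygous tracts by two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SITE_COLUMNS = ["chromosome", "position", "focal_state", "present_in_reference_pool"]


class CoordinateError(ValueError):
    """A SNP position lies beyond its chromosome length."""


@dataclass
class WindowCall:
    chromosome: str
    start: int
    end: int  # half-open
    specific_count: int
    introgressed: bool = False
    zygosity_note: str = "NA"

    @property
    def length(self) -> int:
        return self.end - self.start


def scan_windows(sites: pd.DataFrame, chrom_lengths: dict,
                 window: int = 500_000) -> list:
    """Count qualifying SNPs per non-overlapping window.

    Qualifying sites are ``focal_state == "hom_nonref"`` with
    ``present_in_reference_pool == False``.  Windows tile each chromosome;
    the last window may be short.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    for col in SITE_COLUMNS:
        if col not in sites.columns:
            raise ValueError(f"sites table missing column {col!r}")
    calls: list[WindowCall] = []
    qual = sites[
        (sites["focal_state"] == "hom_nonref")
        & (~sites["present_in_reference_pool"].astype(bool))
    ]
    by_chrom = {c: g["position"].to_numpy() for c, g in qual.groupby("chromosome")}
    for chrom in sites["chromosome"].unique():
        if chrom not in chrom_lengths:
            raise CoordinateError(f"unknown chromosome {chrom!r}")
    for chrom, length in chrom_lengths.items():
        pos = by_chrom.get(chrom, np.array([], dtype=int))
        if len(pos) and (pos.min() < 0 or pos.max() >= length):
            raise CoordinateError(
                f"{chrom}: site position outside [0, {length})"
            )
        n_windows = int(np.ceil(length / window)) if length else 0
        counts = np.bincount(pos // window, minlength=n_windows) if n_windows else []
        for wi in range(n_windows):
            start = wi * window
            calls.append(
                WindowCall(
                    chromosome=chrom,
                    start=start,
                    end=min(length, start + window),
                    specific_count=int(counts[wi]),
                )
            )
    return calls


@dataclass
class Region:
    chromosome: str
    start: int
    end: int
    zygosity: str  # "heterozygous" | "homozygous"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ScanSummary:
    calls: list
    regions: list
    n_regions: int
    admixed_diploid_fraction: float


def flag_introgressed(
    calls: list,
    threshold: int = 100,
    zygosity: str | dict = "heterozygous",
) -> ScanSummary:
    """Flag windows with < threshold specific SNPs (strict) and merge them.

    ``zygosity`` labels regions ("heterozygous" by default, matching a
    scan where no tract is fixed); a dict keyed by (chromosome, start)
    can override per region.  The admixed diploid fraction counts one
    genome copy for heterozygous tracts and two for homozygous ones.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    for c in calls:
        c.introgressed = c.specific_count < threshold

    regions: list[Region] = []
    for c in calls:
        if not c.introgressed:
            continue
        if (
            regions
            and regions[-1].chromosome == c.chromosome
            and regions[-1].end == c.start
        ):
            regions[-1].end = c.end
        else:
            regions.append(Region(c.chromosome, c.start, c.end, "heterozygous"))
    for r in regions:
        if isinstance(zygosity, dict):
            r.zygosity = zygosity.get((r.chromosome, r.start), "heterozygous")
        else:
            r.zygosity = zygosity
    for c in calls:
        if c.introgressed:
            for r in regions:
                if r.chromosome == c.chromosome and r.start <= c.start < r.end:
                    c.zygosity_note = r.zygosity
                    break

    genome = sum(c.length for c in calls)
    weighted = sum(
        r.length * (2 if r.zygosity == "homozygous" else 1) for r in regions
    )
    fraction = weighted / (2 * genome) if genome else float("nan")
    return ScanSummary(
        calls=calls,
        regions=regions,
        n_regions=len(regions),
        admixed_diploid_fraction=fraction,
    )


def windows_to_frame(calls: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.chromosome, c.start, c.end, c.length, c.specific_count,
             c.introgressed, c.zygosity_note)
            for c in calls
        ],
        columns=["chromosome", "start", "end", "length", "specific_count",
                 "introgressed", "zygosity_note"],
    )


def regions_to_frame(regions: list) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.chromosome, r.start, r.end, r.length, r.zygosity) for r in regions],
        columns=["chromosome", "start", "end", "length", "zygosity"],
    )


def read_sites(path) -> pd.DataFrame:
    """Read a SNP site table (TSV, 0-based positions)."""
    sites = pd.read_csv(path, sep="\t")
    missing = [c for c in SITE_COLUMNS if c not in sites.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    sites["present_in_reference_pool"] = sites["present_in_reference_pool"].map(
        lambda v: str(v).lower() in ("true", "1")
    )
    return sites
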