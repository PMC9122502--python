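"""Haplotype-panel data types, VCF/BED/annotation I/O, and site filters.

The central container is :class:`HaplotypeMatrix`: a haploid 0/1 allele
matrix (samples x sites) with 1-based positions, as produced by genotyping a
panel of fully homozygous or haploid-embryo libraries one chromosome arm at a
time.  All downstream statistics (diversity scans, LD, recombination bounds)
operate on this container.

Conventions
-----------
* Coordinates are 1-based inclusive everywhere; BED input (0-based
  half-open) is converted at the reader boundary.
* Missing genotypes are encoded as ``-1`` and are excluded pairwise by the
  statistics, never imputed.
* Multiallelic VCF records are dropped (with a logged count), not
  decomposed: every retained site is biallelic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, EmptyResultError, VcfParseError

logger = logging.getLogger(__name__)

MISSING = -1

#: closed vocabularies for per-site annotations
SITE_CLASSES = ("synonymous", "nonsynonymous", "intronic", "intergenic", "other")
SHARING_LABELS = ("private", "shared", "unassigned")


@dataclass(frozen=True)
class SiteClass:
    """Functional/sharing annotation for one SNP."""

    position: int
    klass: str = "other"
    sharing: str = "unassigned"

    def __post_init__(self) -> None:
        if self.klass not in SITE_CLASSES:
            raise ValueError(f"unknown site class {self.klass!r}")
        if self.sharing not in SHARING_LABELS:
            raise ValueError(f"unknown sharing label {self.sharing!r}")


@dataclass(frozen=True)
class GenomeWindow:
    """A 1-based inclusive genomic interval with a callable-site count."""

    chrom: str
    start: int
    end: int
    n_callable: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"window start {self.start} > end {self.end}")
        if self.n_callable > self.end - self.start + 1:
            raise ValueError("n_callable exceeds window span")

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class HaplotypeMatrix:
    """Haploid allele matrix with positions, sample names and optional depth.

    ``alleles[i, j]`` is sample *i* at site *j*: 0 = reference/ancestral,
    1 = alternate/derived, -1 = missing.  ``depth`` (same shape) carries
    per-call read depth when known.
    """

    chrom: str
    positions: np.ndarray
    samples: list[str]
    alleles: np.ndarray
    depth: np.ndarray | None = None
    group: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (samples x sites)")
        n_samp, n_site = self.alleles.shape
        if len(self.samples) != n_samp:
            raise ValueError("sample count mismatch")
        if self.positions.shape != (n_site,):
            raise ValueError("positions length mismatch")
        if n_site and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=np.int32)
            if self.depth.shape != self.alleles.shape:
                raise ValueError("depth shape mismatch")
            if np.any(self.depth < 0):
                raise ValueError("negative depth")
        if n_site and np.any((self.alleles == MISSING).all(axis=0)):
            raise ValueError("site with zero non-missing calls")

    # -- basic shape -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    # -- per-site summaries ------------------------------------------------

    def called_counts(self) -> np.ndarray:
        """Number of non-missing calls per site."""
        return (self.alleles != MISSING).sum(axis=0)

    def derived_counts(self) -> np.ndarray:
        """Number of derived (1) alleles per site, missing excluded."""
        return (self.alleles == 1).sum(axis=0)

    def minor_counts(self) -> np.ndarray:
        der = self.derived_counts()
        return np.minimum(der, self.called_counts() - der)

    def is_segregating(self) -> np.ndarray:
        der = self.derived_counts()
        return (der > 0) & (der < self.called_counts())

    # -- views -------------------------------------------------------------

    def take_sites(self, index: np.ndarray) -> "HaplotypeMatrix":
        """Subset sites by (sorted) positional index, preserving order."""
        return replace(
            self,
            positions=self.positions[index],
            alleles=self.alleles[:, index],
            depth=None if self.depth is None else self.depth[:, index],
        )

    def in_window(self, window: GenomeWindow) -> "HaplotypeMatrix":
        mask = (self.positions >= window.start) & (self.positions <= window.end)
        return self.take_sites(np.flatnonzero(mask))


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def read_haplotype_vcf(path: str | Path, group: str = "") -> HaplotypeMatrix:
    """Read a haploid (or haplotype-column) single-arm VCF into a matrix.

    Multiallelic records are dropped with a logged count.  Missing GT calls
    become :data:`MISSING`.  Raises :class:`EmptyInputError` when no
    biallelic record survives.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    positions: list[int] = []
    rows: list[np.ndarray] = []
    depths: list[np.ndarray] = []
    have_depth = True
    chrom: str | None = None
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        if chrom is None:
            chrom = rec.CHROM
        elif rec.CHROM != chrom:
            raise VcfParseError(
                f"{path}: expected a single chromosome arm, "
                f"found {chrom} and {rec.CHROM} (POS {rec.POS})"
            )
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=missing.  Haploid "0"/"1"
        # calls surface as hom-ref/hom-alt; a het in haploid input is bad data.
        gt = rec.gt_types
        if np.any(gt == 1):
            raise VcfParseError(
                f"{path}: heterozygous call at {rec.CHROM}:{rec.POS} in haploid panel"
            )
        calls = np.where(gt == 3, MISSING, np.where(gt == 2, 1, 0)).astype(np.int8)
        positions.append(rec.POS)
        rows.append(calls)
        if have_depth:
            try:
                dp = rec.format("DP")
            except KeyError:  # DP absent from the header entirely
                dp = None
            if dp is None:
                have_depth = False
            else:
                depths.append(np.maximum(dp.reshape(-1), 0).astype(np.int32))
    if n_multi:
        logger.info("%s: dropped %d multiallelic record(s)", path, n_multi)
    if not positions:
        raise EmptyInputError(f"{path}: no biallelic records retained")
    alleles = np.stack(rows, axis=1)
    depth = np.stack(depths, axis=1) if have_depth and depths else None
    return HaplotypeMatrix(
        chrom=chrom or "",
        positions=np.asarray(positions),
        samples=samples,
        alleles=alleles,
        depth=depth,
        group=group,
    )


def write_haplotype_vcf(m: HaplotypeMatrix, path: str | Path, *, meta: dict | None = None) -> None:
    """Write a matrix as a minimal haploid VCF 4.2 (GT, plus DP when present).

    Reference/alternate nucleotides are not tracked by the matrix and are
    written as the placeholders A/T; round-tripping preserves positions,
    alleles and sample names.  ``meta`` key/value pairs are embedded as
    ``##sdmal_<key>=`` header lines for provenance.
    """
    has_dp = m.depth is not None
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={m.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for key, val in (meta or {}).items():
            fh.write(f"##sdmal_{key}={val}\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(m.samples) + "\n")
        fmt = "GT:DP" if has_dp else "GT"
        for j in range(m.n_sites):
            cells = []
            for i in range(m.n_samples):
                a = m.alleles[i, j]
                gt = "." if a == MISSING else str(int(a))
                if has_dp:
                    gt += f":{int(m.depth[i, j])}"
                cells.append(gt)
            fh.write(
                f"{m.chrom}\t{m.positions[j]}\t.\tA\tT\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Site filters
# ---------------------------------------------------------------------------


def depth_callable_mask(
    m: HaplotypeMatrix, min_depth: int, dialect: str = "per_sample"
) -> np.ndarray:
    """Boolean mask of sites passing the depth filter.

    ``per_sample``: every sample must have depth >= min_depth (strict
    reading of a 'minimum sample depth' filter).  ``mean``: mean depth over
    samples >= min_depth.  A matrix without depth passes everywhere.
    """
    if m.depth is None:
        return np.ones(m.n_sites, dtype=bool)
    if dialect == "per_sample":
        return (m.depth >= min_depth).all(axis=0)
    if dialect == "mean":
        return m.depth.mean(axis=0) >= min_depth
    raise ValueError(f"unknown depth dialect {dialect!r}")


def filter_sites(
    m: HaplotypeMatrix,
    *,
    biallelic: bool = False,
    require_complete: bool = False,
    drop_singletons: bool = False,
    min_depth: int | None = None,
    depth_dialect: str = "per_sample",
) -> HaplotypeMatrix:
    """Retain sites passing all enabled criteria.

    ``biallelic`` keeps only sites where both alleles are observed among the
    matrix's own non-missing calls; ``drop_singletons`` removes sites with
    minor-allele count 1; ``require_complete`` removes sites with any missing
    call.  Raises :class:`EmptyResultError` (naming the first filter that
    removed more than half the sites) when nothing survives.
    """
    if m.n_sites == 0:
        raise EmptyInputError("cannot filter an empty matrix")
    mask = np.ones(m.n_sites, dtype=bool)
    heavy: str | None = None

    def apply(name: str, crit: np.ndarray) -> None:
        nonlocal heavy
        before = int(mask.sum())
        mask[:] = mask & crit
        if heavy is None and before and (before - int(mask.sum())) > before / 2:
            heavy = name

    if biallelic:
        apply("biallelic", m.is_segregating())
    if require_complete:
        apply("require_complete", m.called_counts() == m.n_samples)
    if drop_singletons:
        apply("drop_singletons", m.minor_counts() != 1)
    if min_depth is not None:
        apply("min_depth", depth_callable_mask(m, min_depth, depth_dialect))
    if not mask.any():
        raise EmptyResultError(
            f"all {m.n_sites} sites removed"
            + (f" (first filter removing >50%: {heavy})" if heavy else "")
        )
    n_drop = m.n_sites - int(mask.sum())
    if n_drop:
        logger.info("filter_sites: removed %d of %d sites", n_drop, m.n_sites)
    return m.take_sites(np.flatnonzero(mask))


# ---------------------------------------------------------------------------
# Annotation table and BED
# ---------------------------------------------------------------------------


def read_site_annotations(path: str | Path) -> list[SiteClass]:
    """Read a tab-separated (position, klass, sharing) annotation table."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"position", "klass", "sharing"}
    if not required.issubset(df.columns):
        raise VcfParseError(f"{path}: annotation table needs columns {sorted(required)}")
    return [
        SiteClass(int(r.position), str(r.klass), str(r.sharing))
        for r in df.itertuples(index=False)
    ]


def write_site_annotations(sites: Iterable[SiteClass], path: str | Path) -> None:
    pd.DataFrame(
        [(s.position, s.klass, s.sharing) for s in sites],
        columns=["position", "klass", "sharing"],
    ).to_csv(path, sep="\t", index=False)


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED (0-based half-open) as 1-based inclusive (chrom, start, end)."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise VcfParseError(f"{path}:{line_no}: need >= 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise VcfParseError(f"{path}:{line_no}: empty BED interval")
            out.append((chrom, start + 1, end))
    return out


def mask_intervals(
    m: HaplotypeMatrix, intervals: Sequence[tuple[str, int, int]]
) -> HaplotypeMatrix:
    """Drop sites falling inside any of the given 1-based inclusive intervals."""
    keep = np.ones(m.n_sites, dtype=bool)
    for chrom, start, end in intervals:
        if chrom != m.chrom:
            continue
        keep &= ~((m.positions >= start) & (m.positions <= end))
    if not keep.any():
        raise EmptyResultError("interval mask removed every site")
    return m.take_sites(np.flatnonzero(keep))
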