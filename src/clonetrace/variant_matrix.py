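"""Multi-sample variant calls -> high-confidence binary marker matrix.

The pipeline treats each called variant as a presence/absence marker per
sample: heterozygous or homozygous non-reference genotypes are coded 1,
homozygous reference 0.  Before binarisation, calls are reduced to a
high-confidence set: site filter passed, genotype called in every sample,
and the called allele supported by a minimum number of reads in every
sample.  Known polymorphic sites (a dbSNP-style VCF) can be excluded so the
remaining markers are individual- and tumour-specific.

Coordinates follow the VCF convention: 1-based, inclusive.  Multi-allelic
rows are split into one biallelic record per alternate allele; a sample is a
carrier of a marker only if its genotype contains that specific allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

NORMAL = "normal"
TUMOUR = "tumour"
REFERENCE_LABEL = "reference"


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant call across all samples of a patient."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: tuple[Optional[int], ...]  # per sample: 1 carrier, 0 hom-ref, None missing
    support: tuple[int, ...]  # reads supporting the called allele, per sample
    passed: bool  # site FILTER status
    annotation: Optional[str] = None  # raw snpEff-style ANN string, if any

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and \
            self.ref in "ACGT" and self.alt in "ACGT"


@dataclass(frozen=True)
class Marker:
    """Metadata for one column of the binary matrix."""

    chrom: str
    pos: int
    ref: str
    alt: str
    annotation: Optional[str] = None

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class BinaryMarkerMatrix:
    """Samples x markers 0/1 matrix with per-marker metadata.

    Invariants: entries are 0/1; a ``reference`` row, if present, is all
    zero; every marker column is non-zero over the real (non-reference)
    samples.
    """

    samples: list[str]
    roles: dict[str, str]  # sample -> "normal" | "tumour" (reference row absent)
    data: np.ndarray  # shape (n_samples, n_markers), dtype int8
    markers: list[Marker] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"matrix shape {self.data.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        if self.data.size and not np.isin(self.data, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def has_reference(self) -> bool:
        return REFERENCE_LABEL in self.samples

    @property
    def normal_sample(self) -> str:
        normals = [s for s, r in self.roles.items() if r == NORMAL]
        if len(normals) != 1:
            raise ValueError(f"expected exactly one normal sample, got {normals}")
        return normals[0]

    @property
    def tumour_samples(self) -> list[str]:
        return [s for s in self.samples if self.roles.get(s) == TUMOUR]

    def row(self, sample: str) -> np.ndarray:
        return self.data[self.samples.index(sample)]

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            [(m.chrom, m.pos, m.ref, m.alt) for m in self.markers],
            columns=["chrom", "pos", "ref", "alt"],
        )
        geno = pd.DataFrame(self.data.T, columns=self.samples)
        return pd.concat([meta, geno], axis=1)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, roles: Mapping[str, str]) -> "BinaryMarkerMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        samples = [c for c in df.columns if c not in ("chrom", "pos", "ref", "alt")]
        markers = [
            Marker(r.chrom, int(r.pos), r.ref, r.alt)
            for r in df.itertuples(index=False)
        ]
        data = df[samples].to_numpy(dtype=np.int8).T
        return cls(samples, dict(roles), data, markers)


class MissingSampleError(ValueError):
    pass


def _split_filter(flt) -> bool:
    names = list(flt)
    return not names or names == ["PASS"]


def read_multisample_vcf(
    path,
    sample_roles: Mapping[str, str],
    depth_mode: str = "called",
) -> list[VariantRecord]:
    """Read a multi-sample VCF into per-alt biallelic :class:`VariantRecord` s.

    ``sample_roles`` maps every expected sample name to ``"normal"`` or
    ``"tumour"``; records carry genotypes in that (VCF header) order for
    exactly these samples.  Multi-allelic rows are split per alternate
    allele.  ``depth_mode`` selects the per-sample supporting-read count:

    ``"called"`` (default)
        reads supporting the called allele — ``AD[alt]`` for carriers,
        ``AD[ref]`` for homozygous-reference samples; falls back to ``DP``
        when ``AD`` is absent.
    ``"dp"``
        total read depth (``DP``; sum of ``AD`` as fallback).

    Malformed rows are skipped with a logged warning; a declared sample
    missing from the header is fatal.
    """
    if depth_mode not in ("called", "dp"):
        raise ValueError(f"unknown depth_mode {depth_mode!r}")
    vcf = pysam.VariantFile(str(path))
    header_samples = list(vcf.header.samples)
    for s in sample_roles:
        if s not in header_samples:
            raise MissingSampleError(f"sample {s!r} not present in {path}")
    samples = [s for s in header_samples if s in sample_roles]

    records: list[VariantRecord] = []
    n_skipped = 0
    for row in vcf:
        try:
            records.extend(_records_from_row(row, samples, depth_mode))
        except Exception as exc:  # malformed row: skip, keep going
            n_skipped += 1
            logger.warning("skipping malformed row %s:%s (%s)", row.chrom, row.pos, exc)
    if n_skipped:
        logger.warning("skipped %d malformed VCF rows", n_skipped)
    return records


def _records_from_row(row, samples: Sequence[str], depth_mode: str) -> list[VariantRecord]:
    if not row.alts:
        return []
    passed = _split_filter(row.filter)
    ann = row.info.get("ANN")
    if isinstance(ann, tuple):
        ann = ",".join(ann)
    out = []
    for alt_index, alt in enumerate(row.alts, start=1):
        genotypes, support = [], []
        for s in samples:
            call = row.samples[s]
            gt = call.get("GT")
            if gt is None or any(a is None for a in gt):
                genotypes.append(None)
                support.append(0)
                continue
            carrier = 1 if alt_index in gt else 0
            genotypes.append(carrier)
            support.append(_support(call, alt_index if carrier else 0, depth_mode))
        out.append(
            VariantRecord(
                chrom=row.chrom,
                pos=row.pos,
                ref=row.ref,
                alt=alt,
                genotypes=tuple(genotypes),
                support=tuple(support),
                passed=passed,
                annotation=ann,
            )
        )
    return out


def _support(call, allele_index: int, depth_mode: str) -> int:
    ad = call.get("AD")
    dp = call.get("DP")
    if depth_mode == "dp":
        if dp is not None:
            return int(dp)
        return int(sum(a or 0 for a in ad)) if ad is not None else 0
    if ad is not None and len(ad) > allele_index and ad[allele_index] is not None:
        return int(ad[allele_index])
    return int(dp) if dp is not None else 0


def filter_high_confidence(
    records: Iterable[VariantRecord],
    min_reads: int = 4,
    stats_out: Optional[dict] = None,
) -> list[VariantRecord]:
    """Keep records with PASS status, no missing genotype, and the called
    allele supported by ``>= min_reads`` reads in every sample.

    Order is preserved; removal counts per reason are logged (and written to
    ``stats_out`` when given).  Idempotent.
    """
    stats = {"input": 0, "fail_filter": 0, "missing_genotype": 0, "low_support": 0, "kept": 0}
    kept = []
    for rec in records:
        stats["input"] += 1
        if not rec.passed:
            stats["fail_filter"] += 1
            continue
        if any(g is None for g in rec.genotypes):
            stats["missing_genotype"] += 1
            continue
        if any(d < min_reads for d in rec.support):
            stats["low_support"] += 1
            continue
        stats["kept"] += 1
        kept.append(rec)
    logger.info(
        "high-confidence filter: %(input)d in, %(kept)d kept "
        "(%(fail_filter)d failed site filter, %(missing_genotype)d missing genotype, "
        "%(low_support)d below read support)",
        stats,
    )
    if stats_out is not None:
        stats_out.update(stats)
    return kept


def exclude_known_sites(
    records: Iterable[VariantRecord],
    known,
    stats_out: Optional[dict] = None,
) -> list[VariantRecord]:
    """Drop records matching a known-sites VCF on (chrom, pos, alt).

    Matching on the specific alternate allele (not position alone) keeps
    somatic alleles that happen to coincide with common-SNP positions.
    """
    known_set: set[tuple] = set()
    vcf = pysam.VariantFile(str(known))
    for row in vcf:
        for alt in row.alts or ():
            known_set.add((row.chrom, row.pos, alt))
    records = list(records)
    kept = [r for r in records if (r.chrom, r.pos, r.alt) not in known_set]
    if stats_out is not None:
        stats_out["known_sites"] = len(known_set)
        stats_out["removed_known"] = len(records) - len(kept)
    logger.info(
        "known-site exclusion: %d known alleles, %d records removed",
        len(known_set), len(records) - len(kept),
    )
    return kept


def binarize(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    roles: Mapping[str, str],
) -> BinaryMarkerMatrix:
    """Binary matrix: entry 1 iff the sample's genotype carries the marker's
    alternate allele.  All-zero columns (every sample homozygous reference)
    carry no signal and are dropped.  A missing genotype here means the
    filtering contract was violated and is fatal.
    """
    cols, markers = [], []
    for rec in records:
        if any(g is None for g in rec.genotypes):
            raise ValueError(
                f"missing genotype at {rec.chrom}:{rec.pos} — "
                "records must pass filter_high_confidence before binarize"
            )
        col = np.array(rec.genotypes, dtype=np.int8)
        if col.any():
            cols.append(col)
            markers.append(Marker(rec.chrom, rec.pos, rec.ref, rec.alt, rec.annotation))
    data = np.column_stack(cols) if cols else np.zeros((len(samples), 0), dtype=np.int8)
    return BinaryMarkerMatrix(list(samples), dict(roles), data, markers)


def add_reference_row(matrix: BinaryMarkerMatrix) -> BinaryMarkerMatrix:
    """Append the all-zero ``reference`` pseudo-sample used to root the tree."""
    if matrix.has_reference:
        raise ValueError("matrix already contains a reference row")
    data = np.vstack([matrix.data, np.zeros((1, matrix.n_markers), dtype=np.int8)])
    return BinaryMarkerMatrix(
        matrix.samples + [REFERENCE_LABEL], dict(matrix.roles), data, list(matrix.markers)
    )
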