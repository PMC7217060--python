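"""Readers and writers for the standard formats the pipeline touches.

All external genomic formats (VCF, SEG) are 1-based inclusive; internally
every interval is 0-based half-open.  Conversion happens here, at the
boundary, and nowhere else.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "PresenceStatus",
    "SomaticVariant",
    "RegionCall",
    "RegionCallMatrix",
    "read_multisample_vcf",
    "write_multisample_vcf",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_segments",
    "write_segments",
    "write_newick",
    "read_loci_bed",
    "read_cohort_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "seg_to_internal",
    "internal_to_seg",
]

_DNA_BASES = frozenset("ACGT")

COHORT_COLUMNS = ["sample_id", "group", "stage", "gene", "protein_change"]
COHORT_GROUPS = {"CSD_high", "CSD_low"}
COHORT_STAGES = {"in_situ", "invasive"}
SAMPLE_KINDS = {"PT", "IT", "normal"}


class PresenceStatus(enum.IntEnum):
    """Call state of one variant in one region."""

    INDETERMINATE = 0
    ABSENT = 1
    PRESENT = 2
    PRESENT_RESCUED = 3

    @property
    def is_present(self) -> bool:
        return self in (PresenceStatus.PRESENT, PresenceStatus.PRESENT_RESCUED)


@dataclass(frozen=True)
class SomaticVariant:
    """A somatic substitution or indel on the forward reference strand.

    ``pos`` is 1-based.  ``tri_context`` is the 3-base reference context
    centred on ``pos`` and is only meaningful for SNVs; its middle base must
    equal ``ref``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    tri_context: str = ""
    gene: str = ""
    protein_change: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        if not self.ref or not self.alt:
            raise ValueError(f"empty allele at {self.chrom}:{self.pos}")
        if self.is_snv and self.tri_context:
            if len(self.tri_context) != 3:
                raise ValueError(f"tri_context must have 3 bases, got {self.tri_context!r}")
            if self.tri_context[1] != self.ref:
                raise ValueError(
                    f"tri_context middle base {self.tri_context[1]!r} does not match "
                    f"ref {self.ref!r} at {self.chrom}:{self.pos}"
                )

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class RegionCall:
    """Depth / alt-count / VAF / status of one variant in one region."""

    depth: int
    alt_count: int
    status: PresenceStatus = PresenceStatus.INDETERMINATE

    def __post_init__(self) -> None:
        if not (0 <= self.alt_count <= self.depth):
            raise ValueError(f"alt_count {self.alt_count} outside [0, depth={self.depth}]")

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth if self.depth > 0 else 0.0


class RegionCallMatrix:
    """Variants x regions grid of read support and presence statuses.

    Backing storage is three integer arrays (depth, alt count, status) so
    downstream operations can vectorise over the grid.
    """

    def __init__(
        self,
        variants: Sequence[SomaticVariant],
        regions: Sequence[str],
        depth: np.ndarray,
        alt: np.ndarray,
        status: np.ndarray | None = None,
    ) -> None:
        self.variants = list(variants)
        self.regions = list(regions)
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("region ids must be unique")
        shape = (len(self.variants), len(self.regions))
        self.depth = np.asarray(depth, dtype=np.int64)
        self.alt = np.asarray(alt, dtype=np.int64)
        if self.depth.shape != shape or self.alt.shape != shape:
            raise ValueError(f"grid shape {self.depth.shape} does not match {shape}")
        if status is None:
            status = np.full(shape, PresenceStatus.INDETERMINATE, dtype=np.int8)
        self.status = np.asarray(status, dtype=np.int8)
        if self.status.shape != shape:
            raise ValueError("status grid shape mismatch")
        if np.any(self.alt > self.depth) or np.any(self.alt < 0):
            raise ValueError("alt counts must satisfy 0 <= alt <= depth")

    # -- basic accessors -------------------------------------------------

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def vaf(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(self.depth > 0, self.alt / np.maximum(self.depth, 1), 0.0)
        return v

    @property
    def present(self) -> np.ndarray:
        """Boolean grid: called present (de novo or rescued)."""
        return (self.status == PresenceStatus.PRESENT) | (
            self.status == PresenceStatus.PRESENT_RESCUED
        )

    def cell(self, i: int, j: int) -> RegionCall:
        return RegionCall(
            depth=int(self.depth[i, j]),
            alt_count=int(self.alt[i, j]),
            status=PresenceStatus(int(self.status[i, j])),
        )

    def region_index(self, region_id: str) -> int:
        return self.regions.index(region_id)

    # -- subsetting ------------------------------------------------------

    def subset_regions(self, keep: Sequence[str]) -> "RegionCallMatrix":
        idx = [self.regions.index(r) for r in keep]
        return RegionCallMatrix(
            self.variants,
            [self.regions[j] for j in idx],
            self.depth[:, idx],
            self.alt[:, idx],
            self.status[:, idx],
        )

    def subset_variants(self, keep: Sequence[int]) -> "RegionCallMatrix":
        keep = list(keep)
        return RegionCallMatrix(
            [self.variants[i] for i in keep],
            self.regions,
            self.depth[keep, :],
            self.alt[keep, :],
            self.status[keep, :],
        )

    def copy(self) -> "RegionCallMatrix":
        return RegionCallMatrix(
            list(self.variants),
            list(self.regions),
            self.depth.copy(),
            self.alt.copy(),
            self.status.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionCallMatrix):
            return NotImplemented
        return (
            self.variants == other.variants
            and self.regions == other.regions
            and np.array_equal(self.depth, other.depth)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.status, other.status)
        )


# ---------------------------------------------------------------------------
# coordinate conversion


def seg_to_internal(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive (SEG) -> 0-based half-open."""
    if end1 < start1:
        raise ValueError(f"SEG interval end {end1} < start {start1}")
    return start1 - 1, end1


def internal_to_seg(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (SEG)."""
    if end0 <= start0:
        raise ValueError(f"empty internal interval [{start0}, {end0})")
    return start0 + 1, end0


# ---------------------------------------------------------------------------
# VCF


def read_multisample_vcf(path: str | Path) -> RegionCallMatrix:
    """Read a multi-sample VCF into a RegionCallMatrix.

    Every sample must carry FORMAT fields DP and AD.  Multi-allelic records
    are split into one matrix row per ALT allele.  A missing genotype in one
    sample becomes (depth 0, alt 0, indeterminate).  All statuses are
    initialised to indeterminate; presence calling is a separate step.
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    if not samples:
        raise ValueError(f"VCF {path} has no sample columns")

    variants: list[SomaticVariant] = []
    depth_rows: list[list[int]] = []
    alt_rows: list[list[int]] = []
    declared = set(vf.header.info)
    with vf:
        for rec in vf:
            alts = rec.alts or ()
            if not alts:
                continue
            gene = str(rec.info.get("GENE", "") or "") if "GENE" in declared else ""
            pchange = str(rec.info.get("PCHANGE", "") or "") if "PCHANGE" in declared else ""
            ctx = str(rec.info.get("TNC", "") or "") if "TNC" in declared else ""
            for ai, alt_allele in enumerate(alts):
                variants.append(
                    SomaticVariant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=str(alt_allele),
                        tri_context=ctx if len(rec.ref) == 1 and len(alt_allele) == 1 else "",
                        gene=gene,
                        protein_change=pchange,
                    )
                )
                drow: list[int] = []
                arow: list[int] = []
                for s in samples:
                    fmt = rec.samples[s]
                    dp = fmt.get("DP")
                    ad = fmt.get("AD")
                    if dp is None and ad is None:
                        # missing genotype: no evidence either way
                        drow.append(0)
                        arow.append(0)
                        continue
                    if dp is None or ad is None:
                        raise ValueError(
                            f"record {rec.chrom}:{rec.pos} sample {s} lacks DP/AD"
                        )
                    ad = tuple(0 if a is None else int(a) for a in ad)
                    alt_reads = ad[ai + 1] if len(ad) > ai + 1 else 0
                    drow.append(int(dp))
                    arow.append(min(alt_reads, int(dp)))
                depth_rows.append(drow)
                alt_rows.append(arow)

    if not variants:
        raise ValueError(f"VCF {path} contains no variant records")
    return RegionCallMatrix(
        variants,
        samples,
        np.array(depth_rows, dtype=np.int64),
        np.array(alt_rows, dtype=np.int64),
    )


def write_multisample_vcf(matrix: RegionCallMatrix, path: str | Path) -> None:
    """Write the matrix as an uncompressed multi-sample VCF 4.2."""
    header = pysam.VariantHeader()
    chrom_max: dict[str, int] = {}
    for v in matrix.variants:
        chrom_max[v.chrom] = max(chrom_max.get(v.chrom, 0), v.pos + len(v.ref) + 1)
    for chrom, length in chrom_max.items():
        header.contigs.add(chrom, length=length + 10_000)
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("PCHANGE", 1, "String", "Protein change")
    header.info.add("TNC", 1, "String", "Trinucleotide reference context")
    for r in matrix.regions:
        header.add_sample(r)

    order = sorted(range(matrix.n_variants), key=lambda i: (matrix.variants[i].chrom,
                                                            matrix.variants[i].pos,
                                                            matrix.variants[i].alt))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in order:
            v = matrix.variants[i]
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            if v.gene:
                rec.info["GENE"] = v.gene
            if v.protein_change:
                rec.info["PCHANGE"] = v.protein_change
            if v.tri_context:
                rec.info["TNC"] = v.tri_context
            for j, r in enumerate(matrix.regions):
                dp = int(matrix.depth[i, j])
                ad = int(matrix.alt[i, j])
                rec.samples[r]["DP"] = dp
                rec.samples[r]["AD"] = (dp - ad, ad)
            out.write(rec)


# ---------------------------------------------------------------------------
# matrix TSV (long form; lossless round-trip)

_STATUS_LABELS = {s: s.name.lower() for s in PresenceStatus}
_STATUS_FROM_LABEL = {v: k for k, v in _STATUS_LABELS.items()}

_MATRIX_COLUMNS = [
    "chrom", "pos", "ref", "alt", "tri_context", "gene", "protein_change",
    "region", "depth", "alt_count", "vaf", "status",
]


def write_matrix_tsv(matrix: RegionCallMatrix, path: str | Path) -> None:
    rows = []
    vaf = matrix.vaf
    for i, v in enumerate(matrix.variants):
        for j, r in enumerate(matrix.regions):
            rows.append(
                (
                    v.chrom, v.pos, v.ref, v.alt, v.tri_context, v.gene,
                    v.protein_change, r, int(matrix.depth[i, j]),
                    int(matrix.alt[i, j]), f"{vaf[i, j]:.6g}",
                    _STATUS_LABELS[PresenceStatus(int(matrix.status[i, j]))],
                )
            )
    pd.DataFrame(rows, columns=_MATRIX_COLUMNS).to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path: str | Path) -> RegionCallMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MATRIX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"matrix TSV missing columns: {missing}")
    regions = list(dict.fromkeys(df["region"]))
    variants: list[SomaticVariant] = []
    var_index: dict[tuple, int] = {}
    for _, row in df.iterrows():
        key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        if key not in var_index:
            var_index[key] = len(variants)
            variants.append(
                SomaticVariant(
                    chrom=row["chrom"], pos=int(row["pos"]), ref=row["ref"],
                    alt=row["alt"], tri_context=row["tri_context"],
                    gene=row["gene"], protein_change=row["protein_change"],
                )
            )
    shape = (len(variants), len(regions))
    depth = np.zeros(shape, dtype=np.int64)
    alt = np.zeros(shape, dtype=np.int64)
    status = np.full(shape, PresenceStatus.INDETERMINATE, dtype=np.int8)
    rj = {r: j for j, r in enumerate(regions)}
    for _, row in df.iterrows():
        i = var_index[(row["chrom"], int(row["pos"]), row["ref"], row["alt"])]
        j = rj[row["region"]]
        depth[i, j] = int(row["depth"])
        alt[i, j] = int(row["alt_count"])
        status[i, j] = _STATUS_FROM_LABEL[row["status"]]
    return RegionCallMatrix(variants, regions, depth, alt, status)


# ---------------------------------------------------------------------------
# SEG


def read_segments(path: str | Path):
    """Read a SEG-like TSV into CNASegment objects (internal coordinates)."""
    from .cnahet import CNASegment  # local import; cnahet imports this module

    df = pd.read_csv(path, sep="\t")
    required = ["sample", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"SEG file missing columns: {missing}")
    seen: set[tuple] = set()
    segments = []
    for _, row in df.iterrows():
        key = (row["sample"], row["chrom"], int(row["loc.start"]), int(row["loc.end"]))
        if key in seen:
            raise ValueError(f"duplicate (sample, interval) row in SEG: {key}")
        seen.add(key)
        start0, end0 = seg_to_internal(int(row["loc.start"]), int(row["loc.end"]))
        if end0 <= start0:
            raise ValueError(f"zero-length SEG interval: {key}")
        call = str(row["call"]) if "call" in df.columns else ""
        segments.append(
            CNASegment(
                region_id=str(row["sample"]), chrom=str(row["chrom"]),
                start=start0, end=end0, n_bins=int(row["num.mark"]),
                log2_ratio=float(row["seg.mean"]), call=call or "neutral",
            )
        )
    return segments


def write_segments(segments: Iterable, path: str | Path) -> None:
    rows = []
    for s in segments:
        start1, end1 = internal_to_seg(s.start, s.end)
        rows.append((s.region_id, s.chrom, start1, end1, s.n_bins,
                     f"{s.log2_ratio:.6g}", s.call))
    pd.DataFrame(
        rows,
        columns=["sample", "chrom", "loc.start", "loc.end", "num.mark",
                 "seg.mean", "call"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree, path: str | Path) -> None:
    """Serialise a phylogeny (clonality.PhyloTree) as Newick with branch lengths."""
    with open(path, "w") as fh:
        fh.write(tree.to_newick())
        fh.write("\n")


def read_loci_bed(path: str | Path) -> pd.DataFrame:
    """Read loci of interest from BED (0-based half-open; name in column 4)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError("BED needs at least chrom, start, end columns")
    out = df.iloc[:, :4].copy() if df.shape[1] >= 4 else df.iloc[:, :3].copy()
    out.columns = ["chrom", "start", "end", "name"][: out.shape[1]]
    if "name" not in out.columns:
        out["name"] = [f"locus_{k}" for k in range(len(out))]
    if (out["end"] <= out["start"]).any():
        raise ValueError("empty BED interval")
    return out


# ---------------------------------------------------------------------------
# cohort table and sample sheet


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the cohort mutation TSV.

    One row per sample x mutated gene; samples with no mutation appear with
    an empty gene field so group/stage/load metadata survive.  An optional
    ``mutational_load`` column carries the per-sample somatic mutation count
    over the panel territory; when absent the load defaults to the number of
    gene rows per sample.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    bad_groups = set(df["group"]) - COHORT_GROUPS
    if bad_groups:
        raise ValueError(f"unknown CSD class labels in group column: {sorted(bad_groups)}")
    bad_stage = set(df["stage"]) - COHORT_STAGES
    if bad_stage:
        raise ValueError(f"unknown stage labels: {sorted(bad_stage)}")
    if "mutational_load" in df.columns:
        loads = pd.to_numeric(df["mutational_load"])
        if (loads < 0).any():
            raise ValueError("negative mutational_load")
        df["mutational_load"] = loads.astype(int)
    return df


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("region_id", "kind"):
        if col not in df.columns:
            raise ValueError(f"sample sheet missing column {col!r}")
    bad = set(df["kind"]) - SAMPLE_KINDS
    if bad:
        raise ValueError(f"unknown specimen kinds: {sorted(bad)}")
    if df["region_id"].duplicated().any():
        raise ValueError("duplicate region ids in sample sheet")
    return df


def write_sample_sheet(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
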