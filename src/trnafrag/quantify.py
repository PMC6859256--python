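"""Read-to-locus assignment and counting with conservative ambiguity removal.

Assignment follows union semantics over interval overlap: a mapped read is
assigned to a fragment locus it overlaps by at least ``min_overlap`` bases
(default 1). Reads are excluded — and tallied separately — when they are
ambiguous in either of two senses:

* multi-mapping: the aligner reported more than one hit for the query;
* feature-ambiguous: the alignment overlaps two or more distinct loci.

Both exclusions implement the conservative policy of dropping every
ambiguously mapped read rather than rescuing or splitting it. Per-sample
diagnostics preserve an exact conservation identity::

    sum(counts) + n_ambiguous_feature + n_multimapped_discarded
                + n_unassigned == total_mapped
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
import pysam
from intervaltree import IntervalTree

from trnafrag.annotation import AnnotationSet

logger = logging.getLogger(__name__)

DIAGNOSTIC_COLUMNS = [
    "total_mapped",
    "n_assigned",
    "n_ambiguous_feature",
    "n_multimapped_discarded",
    "n_unassigned",
    "n_unmapped",
]


class Strandedness(str, enum.Enum):
    SAME = "same"
    OPPOSITE = "opposite"
    IGNORE = "ignore"


class Unassigned(enum.Enum):
    """Sentinel assignment outcomes for reads not counted to any locus."""

    AMBIGUOUS = "ambiguous"
    NONE = "none"
    MULTIMAPPED = "multimapped"


@dataclass(frozen=True)
class ReadAlignment:
    """A mapped small-RNA read, reduced to what assignment needs."""

    query_name: str
    chrom: str
    strand: str
    aligned_blocks: tuple[tuple[int, int], ...]
    n_hits: int = 1
    mapped: bool = True

    def __post_init__(self) -> None:
        prev = -1
        for s, e in self.aligned_blocks:
            if s >= e or s < prev:
                raise ValueError(
                    f"read {self.query_name}: blocks must be sorted, non-overlapping"
                )
            prev = e
        if self.mapped and self.n_hits < 1:
            raise ValueError(f"read {self.query_name}: n_hits must be >= 1")


class LocusIndex:
    """Per-chromosome interval index over the fragment loci of an annotation."""

    def __init__(self, ann: AnnotationSet):
        self.trees: dict[str, IntervalTree] = {}
        for locus in ann.loci:
            tree = self.trees.setdefault(locus.chrom, IntervalTree())
            tree.addi(locus.start, locus.end, (locus.id, locus.strand))
        self._warned_chroms: set[str] = set()

    def overlapping(
        self,
        chrom: str,
        blocks: Sequence[tuple[int, int]],
        read_strand: str,
        strandedness: Strandedness,
        min_overlap: int = 1,
    ) -> set[str]:
        """Ids of loci overlapped by >= min_overlap bases of any block."""
        tree = self.trees.get(chrom)
        if tree is None:
            if chrom not in self._warned_chroms:
                logger.warning("chromosome %s absent from annotation index", chrom)
                self._warned_chroms.add(chrom)
            return set()
        hits: set[str] = set()
        for bstart, bend in blocks:
            for iv in tree.overlap(bstart, bend):
                locus_id, locus_strand = iv.data
                if strandedness is Strandedness.SAME and locus_strand != read_strand:
                    continue
                if strandedness is Strandedness.OPPOSITE and locus_strand == read_strand:
                    continue
                if min(bend, iv.end) - max(bstart, iv.begin) >= min_overlap:
                    hits.add(locus_id)
        return hits


def assign_read(
    read: ReadAlignment,
    ann: AnnotationSet | LocusIndex,
    strandedness: Strandedness | str = Strandedness.SAME,
    min_overlap: int = 1,
) -> str | Unassigned:
    """Assign one mapped read under union-with-ambiguity-removal semantics.

    Returns the single overlapped locus id, or ``Unassigned.MULTIMAPPED``
    (n_hits > 1), ``Unassigned.AMBIGUOUS`` (>= 2 distinct loci overlapped),
    or ``Unassigned.NONE`` (no overlap). Deterministic for fixed inputs.
    """
    if not read.mapped:
        raise ValueError("assign_read requires a mapped read")
    strandedness = Strandedness(strandedness)
    index = ann if isinstance(ann, LocusIndex) else LocusIndex(ann)
    if read.n_hits > 1:
        return Unassigned.MULTIMAPPED
    hits = index.overlapping(
        read.chrom, read.aligned_blocks, read.strand, strandedness, min_overlap
    )
    if not hits:
        return Unassigned.NONE
    if len(hits) > 1:
        return Unassigned.AMBIGUOUS
    return hits.pop()


@dataclass
class SampleCounts:
    """One sample's raw counts plus counting diagnostics."""

    sample_id: str
    counts: pd.Series  # indexed by feature id, int
    total_mapped: int
    n_ambiguous_feature: int
    n_multimapped_discarded: int
    n_unassigned: int
    n_unmapped: int = 0

    @property
    def n_assigned(self) -> int:
        return int(self.counts.sum())

    def validate(self) -> None:
        total = (
            self.n_assigned
            + self.n_ambiguous_feature
            + self.n_multimapped_discarded
            + self.n_unassigned
        )
        if total != self.total_mapped:
            raise AssertionError(
                f"count conservation violated for {self.sample_id}: "
                f"{total} != total_mapped {self.total_mapped}"
            )

    def diagnostics(self) -> dict[str, int]:
        return {
            "total_mapped": self.total_mapped,
            "n_assigned": self.n_assigned,
            "n_ambiguous_feature": self.n_ambiguous_feature,
            "n_multimapped_discarded": self.n_multimapped_discarded,
            "n_unassigned": self.n_unassigned,
            "n_unmapped": self.n_unmapped,
        }


@dataclass
class CountMatrix:
    """Features x samples raw counts with per-sample counting diagnostics."""

    counts: pd.DataFrame  # features x samples, non-negative int
    diagnostics: pd.DataFrame  # samples x DIAGNOSTIC_COLUMNS

    def __post_init__(self) -> None:
        self.validate()

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def total_mapped(self) -> pd.Series:
        """Library-wide mapped-read totals (the RPM denominator)."""
        return self.diagnostics["total_mapped"]

    def validate(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        for sample in self.counts.columns:
            d = self.diagnostics.loc[sample]
            total = (
                int(self.counts[sample].sum())
                + int(d["n_ambiguous_feature"])
                + int(d["n_multimapped_discarded"])
                + int(d["n_unassigned"])
            )
            if total != int(d["total_mapped"]):
                raise ValueError(
                    f"count conservation violated for sample {sample}"
                )


def iter_bam_reads(bam_path: str) -> Iterable[ReadAlignment]:
    """Yield mapped reads from a BAM/SAM file as :class:`ReadAlignment`,
    plus ``None`` for each unmapped read.

    Multi-mapping detection precedence: the NH tag when present, otherwise
    duplicate query names within the file.
    """
    try:
        with pysam.AlignmentFile(bam_path, check_sq=False) as bam:
            raw = list(bam.fetch(until_eof=True))
    except (OSError, ValueError) as exc:
        raise OSError(f"unreadable BAM/SAM file {bam_path}: {exc}") from exc
    name_counts: dict[str, int] = {}
    any_missing_nh = any(a.has_tag("NH") is False for a in raw if not a.is_unmapped)
    if any_missing_nh:
        for a in raw:
            if not a.is_unmapped:
                name_counts[a.query_name] = name_counts.get(a.query_name, 0) + 1
    for a in raw:
        if a.is_unmapped:
            yield None
            continue
        if a.has_tag("NH"):
            n_hits = int(a.get_tag("NH"))
        else:
            n_hits = name_counts.get(a.query_name, 1)
        yield ReadAlignment(
            query_name=a.query_name,
            chrom=a.reference_name,
            strand="-" if a.is_reverse else "+",
            aligned_blocks=tuple(a.get_blocks()),
            n_hits=max(1, n_hits),
        )


def count_bam(
    bam_path: str,
    ann: AnnotationSet,
    sample_id: str,
    strandedness: Strandedness | str = Strandedness.SAME,
    min_overlap: int = 1,
) -> SampleCounts:
    """Count one BAM against the fragment annotation (single pass).

    Unmapped reads are ignored by assignment but tallied in ``n_unmapped``;
    the conservation identity over mapped reads holds exactly.
    """
    strandedness = Strandedness(strandedness)
    index = LocusIndex(ann)
    counts = pd.Series(0, index=ann.feature_ids(), dtype=int)
    n_amb = n_multi = n_none = n_unmapped = total_mapped = 0
    for read in iter_bam_reads(bam_path):
        if read is None:
            n_unmapped += 1
            continue
        total_mapped += 1
        result = assign_read(read, index, strandedness, min_overlap)
        if result is Unassigned.MULTIMAPPED:
            n_multi += 1
        elif result is Unassigned.AMBIGUOUS:
            n_amb += 1
        elif result is Unassigned.NONE:
            n_none += 1
        else:
            counts[result] += 1
    out = SampleCounts(
        sample_id=sample_id,
        counts=counts,
        total_mapped=total_mapped,
        n_ambiguous_feature=n_amb,
        n_multimapped_discarded=n_multi,
        n_unassigned=n_none,
        n_unmapped=n_unmapped,
    )
    out.validate()
    return out


def write_counts_tsv(cm: CountMatrix, counts_path: str, diagnostics_path: str) -> None:
    """Write counts and per-sample diagnostics as TSVs with metadata headers."""
    with open(counts_path, "w") as fh:
        fh.write("# trnafrag raw counts\n")
        cm.counts.to_csv(fh, sep="\t", index_label="feature_id")
    with open(diagnostics_path, "w") as fh:
        fh.write("# trnafrag counting diagnostics\n")
        cm.diagnostics.to_csv(fh, sep="\t", index_label="sample_id")


def read_counts_tsv(counts_path: str, diagnostics_path: str) -> CountMatrix:
    """Read a CountMatrix written by :func:`write_counts_tsv`."""
    counts = pd.read_csv(counts_path, sep="\t", comment="#", index_col="feature_id")
    diagnostics = pd.read_csv(
        diagnostics_path, sep="\t", comment="#", index_col="sample_id"
    )
    return CountMatrix(counts=counts.astype(int), diagnostics=diagnostics)


def merge_counts(columns: Sequence[SampleCounts]) -> CountMatrix:
    """Merge single-sample count columns into a CountMatrix.

    Features are aligned by id (union, zero-filled); sample order is
    preserved as given. Duplicate sample ids are an error.
    """
    if not columns:
        raise ValueError("merge_counts requires at least one sample")
    sample_ids = [c.sample_id for c in columns]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids in merge_counts")
    feature_ids: list[str] = []
    seen: set[str] = set()
    for c in columns:
        for fid in c.counts.index:
            if fid not in seen:
                feature_ids.append(fid)
                seen.add(fid)
    counts = pd.DataFrame(0, index=feature_ids, columns=sample_ids, dtype=int)
    diag_rows = []
    for c in columns:
        counts.loc[c.counts.index, c.sample_id] = c.counts
        diag_rows.append(c.diagnostics())
    diagnostics = pd.DataFrame(diag_rows, index=sample_ids)[DIAGNOSTIC_COLUMNS]
    return CountMatrix(counts=counts, diagnostics=diagnostics)
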