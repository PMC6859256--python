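"""tRNA gene catalogs and tRNA-derived fragment loci.

Internal coordinates are 0-based half-open throughout. GTF output is
1-based inclusive, BED output 0-based half-open; both round-trip losslessly
through the matching reader.

Four fragment classes are modeled in genome space:

* ``TRF5`` / ``TRF3`` — fragments of the mature tRNA 5'/3' ends, lying
  within the parent gene span. The non-templated CCA of tRF-3s is absent
  from the genome and therefore not represented here (see
  :mod:`trnafrag.fragclass`).
* ``TSRNA`` (also called tRF-1) — 3' trailer fragments released by RNase Z;
  the locus begins at or after the parent gene's 3' end.
* ``LEADER5`` — 5' leader RNAs, modeled as the region (default 20 nt)
  immediately upstream of the gene's 5' end, bounded by the RNase P
  cleavage site.
"""

from __future__ import annotations

import enum
import io
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_LEADER_LEN = 20
TRF_MIN_LEN = 14
TRF_MAX_LEN = 30

_VALID_ANTICODON = set("ACGTN")


class FragClass(str, enum.Enum):
    """The four tRNA-derived ncRNA classes stored by this package."""

    TRF5 = "tRF-5"
    TRF3 = "tRF-3"
    TSRNA = "tsRNA"
    LEADER5 = "5p-leader"

    @classmethod
    def parse(cls, label: str) -> "FragClass":
        """Parse a class label, accepting common aliases.

        ``tRF-1`` is an alias for tsRNA: both name the 3' trailer fragment.
        """
        key = label.strip().lower().replace("_", "-").replace("'", "p")
        aliases = {
            "trf5": cls.TRF5,
            "trf-5": cls.TRF5,
            "trf3": cls.TRF3,
            "trf-3": cls.TRF3,
            "tsrna": cls.TSRNA,
            "trf1": cls.TSRNA,
            "trf-1": cls.TSRNA,
            "leader5": cls.LEADER5,
            "leader": cls.LEADER5,
            "5p-leader": cls.LEADER5,
            "5pleader": cls.LEADER5,
            "5p-leader-rna": cls.LEADER5,
        }
        if key not in aliases:
            raise ValueError(f"unknown fragment class label: {label!r}")
        return aliases[key]


class CoordinateDialect(str, enum.Enum):
    """Coordinate conventions accepted by the fragment-record importer."""

    ZERO_HALF_OPEN = "zero_half_open"
    ONE_INCLUSIVE = "one_inclusive"


class AnnotationError(ValueError):
    """Invalid annotation input (bad coordinates, unknown format, ...)."""


class LeaderConstructionError(AnnotationError):
    """A 5' leader locus could not be built (no upstream bases)."""


# Validation / provenance flags attached to loci
FLAG_TRUNCATED = "truncated_at_contig_boundary"
FLAG_LENGTH_OUT_OF_RANGE = "length_out_of_range"
FLAG_OVERLAPS_GENE = "overlaps_neighboring_gene"
FLAG_POLYU_3P = "polyU_3prime"
FLAG_CCA_NOT_TEMPLATED = "cca_not_genome_templated"


@dataclass(frozen=True)
class TRNAGene:
    """A genomic tRNA gene record.

    Coordinates are 0-based half-open. ``amino_acid`` is the 3-letter
    isotype code (``Und`` when undetermined); ``anticodon`` the DNA-space
    anticodon triplet. ``introns`` holds sub-intervals of the gene span
    (tRNA introns are carried for provenance but ignored by locus
    construction: all four fragment classes are defined relative to
    gene/mature ends, not spliced bodies).
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    amino_acid: str = "Und"
    anticodon: str = "NNN"
    introns: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"gene {self.id}: invalid interval [{self.start},{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.id}: strand must be + or -")
        if len(self.anticodon) != 3 or not set(self.anticodon) <= _VALID_ANTICODON:
            raise AnnotationError(f"gene {self.id}: bad anticodon {self.anticodon!r}")
        prev_end = self.start
        for istart, iend in self.introns:
            if not (self.start < istart < iend < self.end):
                raise AnnotationError(
                    f"gene {self.id}: intron [{istart},{iend}) not strictly inside gene"
                )
            if istart < prev_end:
                raise AnnotationError(f"gene {self.id}: overlapping introns")
            prev_end = iend

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the gene's 5' end (strand-aware)."""
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        """Genomic coordinate of the gene's 3' end (strand-aware)."""
        return self.end if self.strand == "+" else self.start


@dataclass
class FragmentLocus:
    """One tRNA-derived ncRNA locus with class label and parent tRNA link."""

    id: str
    frag_class: FragClass
    chrom: str
    start: int
    end: int
    strand: str
    parent_ids: tuple[str, ...] = ()
    subclass: str | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"locus {self.id}: invalid interval [{self.start},{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"locus {self.id}: strand must be + or -")
        self.parent_ids = tuple(self.parent_ids)

    @property
    def length(self) -> int:
        """Locus length in nt; the gene length used as the TPM denominator."""
        return self.end - self.start


@dataclass
class AnnotationSet:
    """A gene catalog plus its fragment loci."""

    genes: list[TRNAGene] = field(default_factory=list)
    loci: list[FragmentLocus] = field(default_factory=list)
    genome_id: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        gene_ids = {g.id for g in self.genes}
        if len(gene_ids) != len(self.genes):
            raise AnnotationError("duplicate gene ids")
        seen: set[str] = set()
        for locus in self.loci:
            if locus.id in seen:
                raise AnnotationError(f"duplicate locus id {locus.id}")
            seen.add(locus.id)
            for pid in locus.parent_ids:
                if pid not in gene_ids:
                    raise AnnotationError(
                        f"locus {locus.id}: unresolved parent gene {pid!r}"
                    )

    def gene_map(self) -> dict[str, TRNAGene]:
        return {g.id: g for g in self.genes}

    def locus_map(self) -> dict[str, FragmentLocus]:
        return {l.id: l for l in self.loci}

    def feature_ids(self) -> list[str]:
        return [l.id for l in self.loci]

    def feature_lengths(self) -> pd.Series:
        """Per-locus lengths in nt, indexed by locus id."""
        return pd.Series({l.id: l.length for l in self.loci}, dtype=int)


def build_leader_locus(
    gene: TRNAGene,
    leader_len: int = DEFAULT_LEADER_LEN,
    contig_len: int | None = None,
) -> FragmentLocus:
    """Construct the 5' leader locus immediately upstream of a tRNA gene.

    The locus covers the ``leader_len`` (default 20) bases 5' of the gene on
    its own strand, ending exactly at the RNase P cleavage site (the gene's
    5' boundary). When the contig boundary leaves fewer than ``leader_len``
    bases, the locus is clipped and flagged ``truncated_at_contig_boundary``.

    Raises
    ------
    LeaderConstructionError
        If zero upstream bases are available (gene abuts the contig edge).
    """
    if leader_len < 1:
        raise AnnotationError("leader_len must be >= 1")
    if gene.strand == "+":
        start = max(0, gene.start - leader_len)
        end = gene.start
    else:
        if contig_len is None:
            raise AnnotationError(
                f"gene {gene.id}: contig length required for minus-strand leader"
            )
        start = gene.end
        end = min(contig_len, gene.end + leader_len)
    if end <= start:
        raise LeaderConstructionError(
            f"gene {gene.id}: no upstream bases available for a 5' leader locus"
        )
    locus = FragmentLocus(
        id=f"{gene.id}_leader5",
        frag_class=FragClass.LEADER5,
        chrom=gene.chrom,
        start=start,
        end=end,
        strand=gene.strand,
        parent_ids=(gene.id,),
    )
    if locus.length < leader_len:
        locus.flags.add(FLAG_TRUNCATED)
    return locus


def build_leader_loci(
    genes: Iterable[TRNAGene],
    contig_lengths: Mapping[str, int],
    leader_len: int = DEFAULT_LEADER_LEN,
) -> tuple[list[FragmentLocus], list[tuple[str, str]]]:
    """Build leader loci for a catalog; failures are collected, not raised.

    Returns ``(loci, rejected)`` where ``rejected`` is a list of
    ``(gene_id, reason)`` pairs. Leader loci overlapping a neighboring gene
    are permitted but flagged ``overlaps_neighboring_gene``.
    """
    genes = list(genes)
    loci: list[FragmentLocus] = []
    rejected: list[tuple[str, str]] = []
    for gene in genes:
        try:
            locus = build_leader_locus(
                gene, leader_len=leader_len, contig_len=contig_lengths.get(gene.chrom)
            )
        except LeaderConstructionError as exc:
            rejected.append((gene.id, str(exc)))
            continue
        loci.append(locus)
    # flag (never resolve) overlaps with neighboring genes
    by_chrom: dict[str, list[TRNAGene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for locus in loci:
        for g in by_chrom.get(locus.chrom, ()):
            if g.id in locus.parent_ids:
                continue
            if g.start < locus.end and locus.start < g.end:
                locus.flags.add(FLAG_OVERLAPS_GENE)
                break
    return loci, rejected


def import_fragment_records(
    records: pd.DataFrame | Iterable[Mapping[str, object]],
    coordinate_dialect: CoordinateDialect | str,
    genes: Iterable[TRNAGene],
) -> tuple[list[FragmentLocus], list[tuple[str, str]]]:
    """Convert external fragment records (tRF-5/tRF-3/tsRNA coordinates)
    into internal loci.

    ``records`` needs columns ``id, chrom, start, end, strand, class,
    parent``; the caller must state the coordinate dialect explicitly.
    Records labeled ``tRF-1`` are imported as tsRNA (the two names denote
    the same 3'-trailer class). Per-record validation failures are
    quarantined with a reason, never thrown; length-range violations for
    tRF-5/tRF-3 are flagged on the locus instead (flag-only policy).

    Returns ``(loci, quarantined)`` with quarantined ``(record_id, reason)``.
    """
    dialect = CoordinateDialect(coordinate_dialect)
    gene_map = {g.id: g for g in genes}
    if isinstance(records, pd.DataFrame):
        rows: Iterator[Mapping[str, object]] = (
            row._asdict() if hasattr(row, "_asdict") else dict(row)
            for row in records.to_dict("records")
        )
    else:
        rows = iter(records)

    loci: list[FragmentLocus] = []
    quarantined: list[tuple[str, str]] = []
    for row in rows:
        rec_id = str(row["id"])
        try:
            frag_class = FragClass.parse(str(row["class"]))
        except ValueError as exc:
            quarantined.append((rec_id, str(exc)))
            continue
        if frag_class is FragClass.LEADER5:
            quarantined.append(
                (rec_id, "5' leader loci are derived from the gene catalog, not imported")
            )
            continue
        start = int(row["start"])  # type: ignore[arg-type]
        end = int(row["end"])  # type: ignore[arg-type]
        if dialect is CoordinateDialect.ONE_INCLUSIVE:
            start -= 1
        parent = str(row["parent"])
        gene = gene_map.get(parent)
        if gene is None:
            quarantined.append((rec_id, f"unresolved parent gene {parent!r}"))
            continue
        strand = str(row["strand"])
        try:
            locus = FragmentLocus(
                id=rec_id,
                frag_class=frag_class,
                chrom=str(row["chrom"]),
                start=start,
                end=end,
                strand=strand,
                parent_ids=(parent,),
            )
        except AnnotationError as exc:
            quarantined.append((rec_id, str(exc)))
            continue
        reason = _positional_violation(locus, gene)
        if reason is not None:
            quarantined.append((rec_id, reason))
            continue
        if frag_class in (FragClass.TRF5, FragClass.TRF3):
            validate_trf_length(locus)
        loci.append(locus)
    return loci, quarantined


def _positional_violation(locus: FragmentLocus, gene: TRNAGene) -> str | None:
    """Check a locus against its class's positional definition."""
    if locus.chrom != gene.chrom:
        return f"locus on {locus.chrom} but parent gene on {gene.chrom}"
    if locus.strand != gene.strand:
        return "locus strand differs from parent gene strand"
    if locus.frag_class in (FragClass.TRF5, FragClass.TRF3):
        if not (gene.start <= locus.start and locus.end <= gene.end):
            return f"{locus.frag_class.value} locus not within parent gene span"
    elif locus.frag_class is FragClass.TSRNA:
        # the 3' trailer begins at/after the mature 3' end (strand-aware)
        if gene.strand == "+":
            if locus.start < gene.end:
                return "tsRNA locus begins upstream of the parent gene 3' end"
        else:
            if locus.end > gene.start:
                return "tsRNA locus begins upstream of the parent gene 3' end"
    elif locus.frag_class is FragClass.LEADER5:
        if gene.strand == "+":
            if locus.end != gene.start:
                return "5' leader locus does not abut the parent gene 5' end"
        else:
            if locus.start != gene.end:
                return "5' leader locus does not abut the parent gene 5' end"
    return None


def validate_trf_length(
    locus: FragmentLocus, min_len: int = TRF_MIN_LEN, max_len: int = TRF_MAX_LEN
) -> set[str]:
    """Flag tRF-5/tRF-3 loci whose length falls outside [min_len, max_len].

    tRFs derived from mature tRNAs range 14–30 nt; out-of-range loci are
    flagged, never deleted (flag-only policy). Returns the flags added.
    """
    if locus.frag_class not in (FragClass.TRF5, FragClass.TRF3):
        raise AnnotationError("length validation applies to tRF-5/tRF-3 loci only")
    added: set[str] = set()
    if not (min_len <= locus.length <= max_len):
        locus.flags.add(FLAG_LENGTH_OUT_OF_RANGE)
        added.add(FLAG_LENGTH_OUT_OF_RANGE)
    return added


# ---------------------------------------------------------------------------
# Readers / writers


def _fmt_introns(introns: Sequence[tuple[int, int]]) -> str:
    return ";".join(f"{s}-{e}" for s, e in introns) or "."


def _parse_introns(text: str) -> tuple[tuple[int, int], ...]:
    if text in (".", ""):
        return ()
    out = []
    for piece in text.split(";"):
        s, e = piece.split("-")
        out.append((int(s), int(e)))
    return tuple(out)


def write_annotation(ann: AnnotationSet, format: str) -> bytes:
    """Serialize an AnnotationSet to GTF (1-based inclusive) or extended
    BED (0-based half-open, BED6+3). Round-trips through
    :func:`read_annotation`.
    """
    fmt = format.upper()
    buf = io.StringIO()
    if fmt == "GTF":
        buf.write(f'##genome-id "{ann.genome_id}"\n')
        for g in ann.genes:
            attrs = (
                f'gene_id "{g.id}"; amino_acid "{g.amino_acid}"; '
                f'anticodon "{g.anticodon}"; introns "{_fmt_introns(g.introns)}";'
            )
            buf.write(
                f"{g.chrom}\ttrnafrag\ttRNA_gene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
        for l in ann.loci:
            attrs = (
                f'locus_id "{l.id}"; frag_class "{l.frag_class.value}"; '
                f'parents "{",".join(l.parent_ids) or "."}"; '
                f'subclass "{l.subclass or "."}"; '
                f'flags "{"|".join(sorted(l.flags)) or "."}";'
            )
            buf.write(
                f"{l.chrom}\ttrnafrag\tfragment\t{l.start + 1}\t{l.end}\t.\t"
                f"{l.strand}\t.\t{attrs}\n"
            )
    elif fmt == "BED":
        buf.write(f"#genome-id={ann.genome_id}\n")
        for g in ann.genes:
            buf.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.id}\t0\t{g.strand}\tgene\t"
                f"{g.amino_acid}:{g.anticodon}\t{_fmt_introns(g.introns)}\n"
            )
        for l in ann.loci:
            info = (
                f"parents={','.join(l.parent_ids) or '.'};"
                f"subclass={l.subclass or '.'};"
                f"flags={'|'.join(sorted(l.flags)) or '.'}"
            )
            buf.write(
                f"{l.chrom}\t{l.start}\t{l.end}\t{l.id}\t0\t{l.strand}\t"
                f"{l.frag_class.value}\t{info}\t.\n"
            )
    else:
        raise AnnotationError(f"unknown annotation format: {format!r}")
    return buf.getvalue().encode()


def _parse_gtf_attrs(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for piece in text.strip().split(";"):
        piece = piece.strip()
        if not piece:
            continue
        key, _, value = piece.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_annotation(data: bytes | str, format: str) -> AnnotationSet:
    """Parse the output of :func:`write_annotation`."""
    fmt = format.upper()
    if isinstance(data, bytes):
        data = data.decode()
    genes: list[TRNAGene] = []
    loci: list[FragmentLocus] = []
    genome_id = ""
    for line in data.splitlines():
        if not line.strip():
            continue
        if fmt == "GTF" and line.startswith("##genome-id"):
            genome_id = line.split('"', 2)[1] if '"' in line else ""
            continue
        if fmt == "BED" and line.startswith("#genome-id="):
            genome_id = line.split("=", 1)[1]
            continue
        if line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if fmt == "GTF":
            chrom, _, feature, start1, end1, _, strand, _, attr_text = fields[:9]
            start, end = int(start1) - 1, int(end1)
            attrs = _parse_gtf_attrs(attr_text)
            if feature == "tRNA_gene":
                genes.append(
                    TRNAGene(
                        id=attrs["gene_id"],
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        amino_acid=attrs.get("amino_acid", "Und"),
                        anticodon=attrs.get("anticodon", "NNN"),
                        introns=_parse_introns(attrs.get("introns", ".")),
                    )
                )
            else:
                parents = attrs.get("parents", ".")
                subclass = attrs.get("subclass", ".")
                flags = attrs.get("flags", ".")
                loci.append(
                    FragmentLocus(
                        id=attrs["locus_id"],
                        frag_class=FragClass(attrs["frag_class"]),
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        parent_ids=tuple(parents.split(",")) if parents != "." else (),
                        subclass=None if subclass == "." else subclass,
                        flags=set() if flags == "." else set(flags.split("|")),
                    )
                )
        elif fmt == "BED":
            chrom, start0, end0, name, _, strand, kind, info1, info2 = fields[:9]
            start, end = int(start0), int(end0)
            if kind == "gene":
                aa, _, anticodon = info1.partition(":")
                genes.append(
                    TRNAGene(
                        id=name,
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        amino_acid=aa,
                        anticodon=anticodon,
                        introns=_parse_introns(info2),
                    )
                )
            else:
                kv = dict(piece.split("=", 1) for piece in info1.split(";"))
                parents = kv.get("parents", ".")
                subclass = kv.get("subclass", ".")
                flags = kv.get("flags", ".")
                loci.append(
                    FragmentLocus(
                        id=name,
                        frag_class=FragClass(kind),
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        parent_ids=tuple(parents.split(",")) if parents != "." else (),
                        subclass=None if subclass == "." else subclass,
                        flags=set() if flags == "." else set(flags.split("|")),
                    )
                )
        else:
            raise AnnotationError(f"unknown annotation format: {format!r}")
    return AnnotationSet(genes=genes, loci=loci, genome_id=genome_id)


def read_gene_bed(path: str) -> list[TRNAGene]:
    """Read tRNA genes from a BED6 track.

    Isotype and anticodon are parsed from GtRNAdb-style names
    (``tRNA-Ala-AGC-1-1``) when present.
    """
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5] if len(fields) > 5 else "+"
            aa, anticodon = "Und", "NNN"
            parts = name.split("-")
            if len(parts) >= 3 and parts[0].lower().startswith("trna"):
                aa, anticodon = parts[1], parts[2]
                if not set(anticodon) <= _VALID_ANTICODON or len(anticodon) != 3:
                    anticodon = "NNN"
            genes.append(
                TRNAGene(
                    id=name, chrom=chrom, start=start, end=end, strand=strand,
                    amino_acid=aa, anticodon=anticodon,
                )
            )
    return genes


def read_gene_gff3(path: str) -> list[TRNAGene]:
    """Read tRNA genes from a GFF3 track (features of type tRNA/tRNA_gene/gene)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] not in ("tRNA", "tRNA_gene", "gene"):
                continue
            attrs = dict(
                piece.split("=", 1) for piece in fields[8].split(";") if "=" in piece
            )
            gid = attrs.get("ID") or attrs.get("Name") or f"{fields[0]}:{fields[3]}"
            genes.append(
                TRNAGene(
                    id=gid,
                    chrom=fields[0],
                    start=int(fields[3]) - 1,
                    end=int(fields[4]),
                    strand=fields[6],
                    amino_acid=attrs.get("amino_acid", "Und"),
                    anticodon=attrs.get("anticodon", "NNN"),
                )
            )
    return genes


def read_gene_table(path: str) -> list[TRNAGene]:
    """Read a GtRNAdb-style tab-delimited gene table.

    Expected header columns: ``id chrom start end strand amino_acid
    anticodon [intron_starts intron_ends]``; coordinates 1-based inclusive
    (the convention of the source tables).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    genes = []
    for row in df.itertuples(index=False):
        introns: tuple[tuple[int, int], ...] = ()
        istarts = getattr(row, "intron_starts", None)
        iends = getattr(row, "intron_ends", None)
        if istarts and iends and str(istarts) not in (".", "nan"):
            starts = [int(x) - 1 for x in str(istarts).split(",")]
            ends = [int(x) for x in str(iends).split(",")]
            introns = tuple(zip(starts, ends))
        genes.append(
            TRNAGene(
                id=str(row.id),
                chrom=str(row.chrom),
                start=int(row.start) - 1,
                end=int(row.end),
                strand=str(row.strand),
                amino_acid=str(getattr(row, "amino_acid", "Und")),
                anticodon=str(getattr(row, "anticodon", "NNN")),
                introns=introns,
            )
        )
    return genes


def read_fragment_table(path: str) -> tuple[pd.DataFrame, CoordinateDialect]:
    """Read a fragment-record TSV whose header line declares the dialect.

    First line must be ``# dialect: zero_half_open`` or
    ``# dialect: one_inclusive``; then a header row ``id chrom start end
    strand class parent``.
    """
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#") or "dialect" not in first:
            raise AnnotationError(
                f"{path}: first line must declare the coordinate dialect "
                "(e.g. '# dialect: zero_half_open')"
            )
        dialect = CoordinateDialect(first.split(":", 1)[1].strip())
        df = pd.read_csv(fh, sep="\t", dtype=str)
    return df, dialect
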