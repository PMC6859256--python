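"""Synthetic genomes, tRNA catalogs and class-faithful small-RNA reads.

The simulator emulates the statistical structure the identification
pipeline assumes: reads of the four tRNA-derived classes have
class-specific 5'/3' end anchors (tRF-5 reads start at the gene 5' end,
tRF-3 reads end at the gene 3' end, tsRNA reads start at the 3' trailer,
5' leader reads end at the RNase P site) and class-specific length laws.
Known per-fragment abundances, a per-base substitution error rate, and
designated fractions of multi-mapping and feature-ambiguous reads allow
every downstream stage to be tested against ground truth without any
external download. Outputs are FASTA/GTF/FASTQ plus a truth-aligned BAM in
which each read's alignment is its generating locus.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from trnafrag.annotation import (
    DEFAULT_LEADER_LEN,
    AnnotationSet,
    FragClass,
    FragmentLocus,
    TRNAGene,
    build_leader_loci,
)
from trnafrag.fragclass import reverse_complement

_BASES = np.array(list("ACGT"))
_AMINO_ACIDS = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr "
    "Trp Tyr Val"
).split()

# placement geometry: one gene per slot, with clearance on both sides large
# enough that leader (20 nt), trailer locus (<=40 nt) and trailer reads
# (<=40 nt past the locus start) never touch a neighboring gene's loci
_SLOT = 250
_MARGIN = 45

TRF5_LENGTHS = tuple(range(14, 17)) + tuple(range(22, 25)) + tuple(range(28, 31))
TRF3_LENGTHS = tuple(range(17, 20)) + tuple(range(21, 24))
TSRNA_READ_LEN = (16, 40)
LEADER_READ_LEN = (14, 20)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset."""

    seed: int = 0
    n_contigs: int = 4
    contig_len: int = 10_000
    n_trna_genes: int = 20
    minus_strand_fraction: float = 0.5
    boundary_fraction: float = 0.05  # genes placed with <leader_len upstream space
    n_reads: int = 20_000
    error_rate: float = 0.001
    fraction_multimapped: float = 0.05
    fraction_feature_ambiguous: float = 0.02
    background_fraction: float = 0.05
    leader_len: int = DEFAULT_LEADER_LEN
    abundances: dict[str, float] | None = None  # fragment id -> expected fraction

    def __post_init__(self) -> None:
        for name in (
            "minus_strand_fraction",
            "boundary_fraction",
            "error_rate",
            "fraction_multimapped",
            "fraction_feature_ambiguous",
            "background_fraction",
        ):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.abundances is not None:
            total = sum(self.abundances.values())
            if any(a < 0 for a in self.abundances.values()) or total > 1 + 1e-9:
                raise ValueError("abundance fractions must be in [0,1] and sum to <= 1")


@dataclass(frozen=True)
class SimRead:
    """One simulated read with its ground truth."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    seq: str  # as sequenced (sense orientation)
    n_hits: int
    category: str  # fragment | background | ambiguous | multimapped
    source_id: str  # fragment id, or "background"/"ambiguous" sentinels
    true_class: str


@dataclass
class SimulatedReads:
    reads: list[SimRead]
    truth: pd.DataFrame  # one row per read
    expected_fractions: pd.Series  # fragment id -> expected read fraction


def _rng(cfg: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stage]))


def simulate_genome_and_catalog(
    cfg: SimulationConfig,
) -> tuple[dict[str, str], list[TRNAGene]]:
    """Generate a random genome and a non-overlapping tRNA gene catalog.

    Genes are placed one per 250-bp slot with >= leader_len upstream and
    >= 40 nt downstream clearance, except for a ``boundary_fraction`` of
    genes deliberately placed at contig edges with fewer than leader_len
    upstream bases (to exercise leader clipping/rejection). Both strands
    are represented according to ``minus_strand_fraction``. Deterministic
    given the seed.
    """
    rng = _rng(cfg, 0)
    genome = {
        f"contig_{i}": "".join(
            _BASES[rng.integers(0, 4, size=cfg.contig_len)]
        )
        for i in range(cfg.n_contigs)
    }
    contig_names = list(genome)

    n_boundary = int(round(cfg.boundary_fraction * cfg.n_trna_genes))
    n_interior = cfg.n_trna_genes - n_boundary
    slots_per_contig = cfg.contig_len // _SLOT - 2  # first/last slot reserved
    capacity = cfg.n_contigs * max(0, slots_per_contig)
    if n_interior > capacity or n_boundary > 2 * cfg.n_contigs:
        needed = ((n_interior + cfg.n_contigs - 1) // cfg.n_contigs + 2) * _SLOT
        raise ValueError(
            f"genes cannot fit: need contig_len >= {needed} "
            f"(or more contigs) for {cfg.n_trna_genes} genes"
        )

    genes: list[TRNAGene] = []

    def _make_gene(idx: int, chrom: str, start: int, end: int, strand: str) -> TRNAGene:
        aa = _AMINO_ACIDS[int(rng.integers(0, len(_AMINO_ACIDS)))]
        anticodon = "".join(_BASES[rng.integers(0, 4, size=3)])
        return TRNAGene(
            id=f"tRNA-{aa}-{anticodon}-{idx}",
            chrom=chrom,
            start=start,
            end=end,
            strand=strand,
            amino_acid=aa,
            anticodon=anticodon,
        )

    # boundary genes: alternate contig 5'/3' edges
    for k in range(n_boundary):
        chrom = contig_names[(k // 2) % cfg.n_contigs]
        gene_len = int(rng.integers(70, 91))
        upstream = int(rng.integers(1, cfg.leader_len))  # < leader_len, > 0
        if k % 2 == 0:  # plus-strand gene near contig start
            genes.append(_make_gene(k, chrom, upstream, upstream + gene_len, "+"))
        else:  # minus-strand gene near contig end
            end = cfg.contig_len - upstream
            genes.append(_make_gene(k, chrom, end - gene_len, end, "-"))

    # interior genes: round-robin over contigs, one per slot
    slot_cursor = {name: 1 for name in contig_names}
    for k in range(n_interior):
        chrom = contig_names[k % cfg.n_contigs]
        slot = slot_cursor[chrom]
        slot_cursor[chrom] += 1
        gene_len = int(rng.integers(70, 91))
        lo = slot * _SLOT + _MARGIN
        hi = (slot + 1) * _SLOT - _MARGIN - gene_len
        start = int(rng.integers(lo, hi + 1))
        strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
        genes.append(_make_gene(n_boundary + k, chrom, start, start + gene_len, strand))

    return genome, genes


def build_fragment_annotation(
    cfg: SimulationConfig,
    genes: Sequence[TRNAGene],
    contig_lengths: Mapping[str, int],
) -> AnnotationSet:
    """Attach one locus of each class to every gene of the catalog.

    tRF-5/tRF-3 locus lengths are drawn from the subclass length windows,
    tsRNA trailer loci are 20-40 nt starting at the gene 3' end, and 5'
    leader loci come from the standard leader construction (clipped or
    rejected at contig boundaries).
    """
    rng = _rng(cfg, 1)
    loci: list[FragmentLocus] = []
    for gene in genes:
        l5 = int(rng.choice(TRF5_LENGTHS))
        l3 = int(rng.choice(TRF3_LENGTHS))
        lt = int(rng.integers(20, 41))
        if gene.strand == "+":
            trf5 = (gene.start, gene.start + l5)
            trf3 = (gene.end - l3, gene.end)
            tsrna = (gene.end, gene.end + lt)
        else:
            trf5 = (gene.end - l5, gene.end)
            trf3 = (gene.start, gene.start + l3)
            tsrna = (gene.start - lt, gene.start)
        for cls, (s, e), suffix in (
            (FragClass.TRF5, trf5, "trf5"),
            (FragClass.TRF3, trf3, "trf3"),
            (FragClass.TSRNA, tsrna, "tsrna"),
        ):
            loci.append(
                FragmentLocus(
                    id=f"{gene.id}_{suffix}",
                    frag_class=cls,
                    chrom=gene.chrom,
                    start=s,
                    end=e,
                    strand=gene.strand,
                    parent_ids=(gene.id,),
                )
            )
    leaders, _rejected = build_leader_loci(genes, contig_lengths, cfg.leader_len)
    loci.extend(leaders)
    return AnnotationSet(genes=list(genes), loci=loci, genome_id=f"sim-seed{cfg.seed}")


def resolve_abundances(cfg: SimulationConfig, ann: AnnotationSet) -> pd.Series:
    """Expected read fraction per fragment locus.

    Uses ``cfg.abundances`` when given (validated against the annotation);
    otherwise fractions are uniform over all loci, with
    ``cfg.background_fraction`` of reads left for background.
    """
    ids = ann.feature_ids()
    if cfg.abundances is not None:
        unknown = set(cfg.abundances) - set(ids)
        if unknown:
            raise ValueError(f"abundance references unknown fragments: {sorted(unknown)[:5]}")
        return pd.Series(cfg.abundances, dtype=float)
    if not ids:
        return pd.Series(dtype=float)
    share = (1.0 - cfg.background_fraction) / len(ids)
    return pd.Series(share, index=ids, dtype=float)


def _read_interval(
    locus: FragmentLocus,
    gene: TRNAGene,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Sample a genomic read interval obeying the class's end-anchor law."""
    cls = locus.frag_class
    if cls is FragClass.TRF5:
        length = int(rng.choice(TRF5_LENGTHS))
        if gene.strand == "+":
            return gene.start, gene.start + length
        return gene.end - length, gene.end
    if cls is FragClass.TRF3:
        length = int(rng.choice(TRF3_LENGTHS))
        if gene.strand == "+":
            return gene.end - length, gene.end
        return gene.start, gene.start + length
    if cls is FragClass.TSRNA:
        length = int(rng.integers(TSRNA_READ_LEN[0], TSRNA_READ_LEN[1] + 1))
        if gene.strand == "+":
            return locus.start, locus.start + length
        return locus.end - length, locus.end
    # LEADER5: read lies inside the leader and ends at the gene 5' boundary
    lo = min(LEADER_READ_LEN[0], locus.length)
    hi = min(LEADER_READ_LEN[1], locus.length)
    length = int(rng.integers(lo, hi + 1))
    if gene.strand == "+":
        return locus.end - length, locus.end
    return locus.start, locus.start + length


def _sequence_with_errors(
    genome: Mapping[str, str],
    chrom: str,
    start: int,
    end: int,
    strand: str,
    error_rate: float,
    rng: np.random.Generator,
) -> str:
    seq = genome[chrom][start:end].upper()
    if strand == "-":
        seq = reverse_complement(seq)
    if error_rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < error_rate
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def simulate_reads(
    cfg: SimulationConfig,
    genome: Mapping[str, str],
    ann: AnnotationSet,
) -> SimulatedReads:
    """Sample reads per the abundance table, with truth bookkeeping.

    Per-read categories are drawn from a single categorical law:
    feature-ambiguous reads (straddling a gene's tRF-3/trailer junction)
    with probability ``fraction_feature_ambiguous``, multi-mapping reads
    (fragment-positioned, n_hits=2) with ``fraction_multimapped``, and the
    rest split between fragments (per abundance) and background reads from
    non-tRNA regions. Substitution errors at ``error_rate`` per base.
    """
    rng = _rng(cfg, 2)
    fractions = resolve_abundances(cfg, ann)
    if cfg.n_reads > 0 and fractions.empty and cfg.background_fraction < 1.0:
        if cfg.abundances is not None or not ann.loci:
            raise ValueError("cannot simulate fragment reads from an empty catalog")
    gene_map = ann.gene_map()
    loci = {l.id: l for l in ann.loci}

    frag_ids = list(fractions.index)
    frag_p = fractions.to_numpy(dtype=float) if frag_ids else np.array([])
    p_amb = cfg.fraction_feature_ambiguous
    p_multi = cfg.fraction_multimapped
    rest = 1.0 - p_amb - p_multi
    frag_total = float(frag_p.sum())
    probs = np.concatenate(
        [[p_amb, p_multi], rest * frag_p, [rest * max(0.0, 1.0 - frag_total)]]
    )
    probs = probs / probs.sum()
    categories = rng.choice(len(probs), size=cfg.n_reads, p=probs)

    # interval tree of locus-or-gene occupied space, for background placement
    occupied: dict[str, list[tuple[int, int]]] = {}
    for l in ann.loci:
        occupied.setdefault(l.chrom, []).append((l.start - 45, l.end + 45))
    for g in ann.genes:
        occupied.setdefault(g.chrom, []).append((g.start - 65, g.end + 65))
    contig_names = list(genome)

    def _background_interval() -> tuple[str, int, int]:
        for _ in range(200):
            chrom = contig_names[int(rng.integers(0, len(contig_names)))]
            length = int(rng.integers(14, 41))
            start = int(rng.integers(0, len(genome[chrom]) - length))
            end = start + length
            if all(
                not (start < oe and os_ < end)
                for os_, oe in occupied.get(chrom, ())
            ):
                return chrom, start, end
        raise RuntimeError("could not place a background read in 200 attempts")

    fragment_loci = [loci[f] for f in frag_ids]
    genes_with_junction = [
        g for g in ann.genes
        if f"{g.id}_trf3" in loci and f"{g.id}_tsrna" in loci
    ]

    reads: list[SimRead] = []
    for i, cat in enumerate(categories):
        read_id = f"read_{i:07d}"
        n_hits = 1
        if cat == 0 and genes_with_junction:  # feature-ambiguous
            g = genes_with_junction[int(rng.integers(0, len(genes_with_junction)))]
            junction = g.three_prime
            k = int(rng.integers(5, 16))
            m = int(rng.integers(5, 16))
            if g.strand == "+":
                start, end = junction - k, junction + m
            else:
                start, end = junction - m, junction + k
            chrom, strand = g.chrom, g.strand
            category, source, true_class = "ambiguous", "ambiguous", "."
        elif cat in (0, 1) and fragment_loci:  # multimapped (or ambiguous fallback)
            pick = rng.random() * frag_total if frag_total > 0 else 0.0
            idx = int(np.searchsorted(np.cumsum(frag_p), pick, side="right"))
            idx = min(idx, len(fragment_loci) - 1)
            locus = fragment_loci[idx]
            g = gene_map[locus.parent_ids[0]]
            start, end = _read_interval(locus, g, rng)
            chrom, strand = locus.chrom, locus.strand
            n_hits = 2
            category, source, true_class = (
                "multimapped",
                locus.id,
                locus.frag_class.value,
            )
        elif 2 <= cat < 2 + len(frag_ids):  # fragment read
            locus = fragment_loci[cat - 2]
            g = gene_map[locus.parent_ids[0]]
            start, end = _read_interval(locus, g, rng)
            chrom, strand = locus.chrom, locus.strand
            category, source, true_class = "fragment", locus.id, locus.frag_class.value
        else:  # background
            chrom, start, end = _background_interval()
            strand = "-" if rng.random() < 0.5 else "+"
            category, source, true_class = "background", "background", "."
        seq = _sequence_with_errors(
            genome, chrom, start, end, strand, cfg.error_rate, rng
        )
        reads.append(
            SimRead(
                read_id=read_id,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                seq=seq,
                n_hits=n_hits,
                category=category,
                source_id=source,
                true_class=true_class,
            )
        )

    truth = pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "category": [r.category for r in reads],
            "source_id": [r.source_id for r in reads],
            "true_class": [r.true_class for r in reads],
            "chrom": [r.chrom for r in reads],
            "start": [r.start for r in reads],
            "end": [r.end for r in reads],
            "strand": [r.strand for r in reads],
            "n_hits": [r.n_hits for r in reads],
        }
    )
    return SimulatedReads(reads=reads, truth=truth, expected_fractions=fractions)


# ---------------------------------------------------------------------------
# Writers


def write_fasta(genome: Mapping[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: Sequence[SimRead], path: str) -> None:
    """Constant-quality FASTQ of the sequenced (sense) reads."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_truth_bam(
    reads: Sequence[SimRead], genome: Mapping[str, str], path: str
) -> None:
    """Write reads as a coordinate-sorted truth-aligned BAM.

    Each read's single alignment is its generating interval; minus-strand
    reads are stored reverse-complemented with the reverse flag, per SAM
    convention. NH carries the designated hit count.
    """
    contigs = list(genome)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": len(genome[name])} for name in contigs],
    }
    tid = {name: i for i, name in enumerate(contigs)}
    ordered = sorted(reads, key=lambda r: (tid[r.chrom], r.start, r.read_id))
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for r in ordered:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = r.read_id
            a.reference_id = tid[r.chrom]
            a.reference_start = r.start
            a.mapping_quality = 255
            a.cigartuples = [(0, r.end - r.start)]
            a.flag = 16 if r.strand == "-" else 0
            seq = reverse_complement(r.seq) if r.strand == "-" else r.seq
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            a.set_tag("NH", r.n_hits)
            bam.write(a)


def write_truth_table(sim: SimulatedReads, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# per-read truth; expected fractions in paired .fractions.tsv\n")
        sim.truth.to_csv(fh, sep="\t", index=False)
    sim.expected_fractions.rename("expected_fraction").to_csv(
        path.replace(".tsv", "") + ".fractions.tsv", sep="\t", index_label="fragment_id"
    )


def simulate_dataset(
    cfg: SimulationConfig, outdir: str, n_samples: int = 1
) -> dict[str, object]:
    """End-to-end convenience: genome, annotation, and per-sample reads.

    Writes genome.fa, annotation.gtf, and per sample sample_<i>.fastq /
    .bam / truth tables under ``outdir``. Samples share the genome and
    annotation; each gets an independent read draw (seed offset by sample
    index). Returns the in-memory objects.
    """
    import os

    from trnafrag.annotation import write_annotation

    os.makedirs(outdir, exist_ok=True)
    genome, genes = simulate_genome_and_catalog(cfg)
    contig_lengths = {name: len(seq) for name, seq in genome.items()}
    ann = build_fragment_annotation(cfg, genes, contig_lengths)
    write_fasta(genome, os.path.join(outdir, "genome.fa"))
    with open(os.path.join(outdir, "annotation.gtf"), "wb") as fh:
        fh.write(write_annotation(ann, "GTF"))
    sims = []
    for i in range(n_samples):
        sample_cfg = SimulationConfig(**{**cfg.__dict__, "seed": cfg.seed + 1000 + i})
        sim = simulate_reads(sample_cfg, genome, ann)
        write_fastq(sim.reads, os.path.join(outdir, f"sample_{i}.fastq"))
        write_truth_bam(sim.reads, genome, os.path.join(outdir, f"sample_{i}.bam"))
        write_truth_table(sim, os.path.join(outdir, f"sample_{i}.truth.tsv"))
        sims.append(sim)
    return {"genome": genome, "annotation": ann, "samples": sims}
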