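from __future__ import annotations

import os

import pysam
import pytest

from trnafrag.annotation import FragClass, FragmentLocus, TRNAGene
from trnafrag.simulate import (
    SimulationConfig,
    build_fragment_annotation,
    simulate_genome_and_catalog,
    simulate_reads,
    write_truth_bam,
)


@pytest.fixture
def plus_gene():
    return TRNAGene(id="g_plus", chrom="chr1", start=100, end=172, strand="+")


@pytest.fixture
def minus_gene():
    return TRNAGene(id="g_minus", chrom="chr1", start=100, end=172, strand="-")


def make_locus(
    id="L1",
    frag_class=FragClass.TRF5,
    chrom="chr1",
    start=100,
    end=120,
    strand="+",
    parents=(),
):
    return FragmentLocus(
        id=id,
        frag_class=frag_class,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        parent_ids=parents,
    )


def write_bam(path, contigs, records):
    """Write a small BAM: records are dicts with qname, chrom, start,
    length, strand ('+'/'-'), and optional nh / unmapped / seq keys."""
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": name, "LN": length} for name, length in contigs.items()],
    }
    tid = {name: i for i, name in enumerate(contigs)}
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for rec in records:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = rec["qname"]
            length = rec.get("length", 20)
            a.query_sequence = rec.get("seq", "A" * length)
            if rec.get("unmapped"):
                a.flag = 4
            else:
                a.reference_id = tid[rec["chrom"]]
                a.reference_start = rec["start"]
                a.cigartuples = [(0, length)]
                a.flag = 16 if rec.get("strand", "+") == "-" else 0
                a.mapping_quality = 60
                if "nh" in rec:
                    a.set_tag("NH", rec["nh"])
            bam.write(a)
    return path


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """A small simulated dataset shared across tests: genome, annotation,
    reads and a truth BAM on disk."""
    cfg = SimulationConfig(seed=11, n_trna_genes=10, n_reads=5000)
    genome, genes = simulate_genome_and_catalog(cfg)
    contig_lengths = {name: len(seq) for name, seq in genome.items()}
    ann = build_fragment_annotation(cfg, genes, contig_lengths)
    sim = simulate_reads(cfg, genome, ann)
    bam_path = str(tmp_path_factory.mktemp("sim") / "truth.bam")
    write_truth_bam(sim.reads, genome, bam_path)
    return {
        "cfg": cfg,
        "genome": genome,
        "annotation": ann,
        "sim": sim,
        "bam": bam_path,
    }
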