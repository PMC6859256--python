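"""Length-based fragment subclassification and sequence-signature flags.

tRF-5s and tRF-3s have well-defined sizes and stratify into subclasses:
tRF-5a (14-16 nt), tRF-5b (22-24 nt), tRF-5c (28-30 nt), tRF-3a (~18 nt)
and tRF-3b (~22 nt). The "about" windows default to +-1 nt ([17,19] and
[21,23]) and are configurable. Lengths between windows are legitimately
unclassified.

Sequence flags annotate, never filter:

* tsRNA loci are checked for the characteristic 3' poly-U tail (>= 3
  consecutive T within the final 6 nt of the sense sequence, both
  parameters configurable);
* tRF-3s carry a non-templated CCA added post-transcriptionally, which by
  construction cannot be confirmed from genomic sequence; a
  ``cca_not_genome_templated`` note records this explicitly instead of
  faking a check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from trnafrag.annotation import (
    FLAG_CCA_NOT_TEMPLATED,
    FLAG_POLYU_3P,
    AnnotationError,
    FragClass,
    FragmentLocus,
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SubclassRule:
    """Inclusive length window defining one subclass of a fragment class."""

    frag_class: FragClass
    subclass: str
    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise AnnotationError(
                f"rule {self.subclass}: min_len > max_len"
            )

    def matches(self, length: int) -> bool:
        return self.min_len <= length <= self.max_len


DEFAULT_RULES: tuple[SubclassRule, ...] = (
    SubclassRule(FragClass.TRF5, "tRF-5a", 14, 16),
    SubclassRule(FragClass.TRF5, "tRF-5b", 22, 24),
    SubclassRule(FragClass.TRF5, "tRF-5c", 28, 30),
    SubclassRule(FragClass.TRF3, "tRF-3a", 17, 19),
    SubclassRule(FragClass.TRF3, "tRF-3b", 21, 23),
)


def validate_rules(rules: Iterable[SubclassRule]) -> tuple[SubclassRule, ...]:
    """Check that rules within one fragment class do not overlap."""
    rules = tuple(rules)
    by_class: dict[FragClass, list[SubclassRule]] = {}
    for rule in rules:
        by_class.setdefault(rule.frag_class, []).append(rule)
    for frag_class, class_rules in by_class.items():
        ordered = sorted(class_rules, key=lambda r: r.min_len)
        for a, b in zip(ordered, ordered[1:]):
            if b.min_len <= a.max_len:
                raise AnnotationError(
                    f"overlapping {frag_class.value} subclass rules: "
                    f"{a.subclass} and {b.subclass}"
                )
    return rules


def load_rules(path: str) -> tuple[SubclassRule, ...]:
    """Load subclass rules from a TSV with columns
    ``frag_class subclass min_len max_len``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    rules = tuple(
        SubclassRule(
            frag_class=FragClass.parse(str(row.frag_class)),
            subclass=str(row.subclass),
            min_len=int(row.min_len),
            max_len=int(row.max_len),
        )
        for row in df.itertuples(index=False)
    )
    return validate_rules(rules)


def assign_subclass(
    locus: FragmentLocus, rules: Iterable[SubclassRule] = DEFAULT_RULES
) -> str | None:
    """Return the unique subclass matching (frag_class, length), or None.

    A pure function of class and length; rule order is irrelevant because
    rules within a class are non-overlapping (validated at load time).
    """
    rules = validate_rules(rules)
    for rule in rules:
        if rule.frag_class is locus.frag_class and rule.matches(locus.length):
            return rule.subclass
    return None


def annotate_subclasses(
    loci: Iterable[FragmentLocus], rules: Iterable[SubclassRule] = DEFAULT_RULES
) -> None:
    """Set ``locus.subclass`` in place for each locus."""
    rules = validate_rules(rules)
    for locus in loci:
        locus.subclass = assign_subclass(locus, rules)


def _fetch_sense_sequence(locus: FragmentLocus, genome) -> str:
    """Strand-aware sense sequence of a locus from a FASTA accessor.

    ``genome`` may be a :class:`pyfaidx.Fasta` or a plain mapping of
    contig name to sequence string.
    """
    if isinstance(genome, Mapping):
        contig = genome[locus.chrom]
        if locus.end > len(contig):
            raise AnnotationError(
                f"locus {locus.id} extends past the end of {locus.chrom}"
            )
        seq = contig[locus.start : locus.end]
    else:  # pyfaidx.Fasta or similar
        record = genome[locus.chrom]
        if locus.end > len(record):
            raise AnnotationError(
                f"locus {locus.id} extends past the end of {locus.chrom}"
            )
        seq = str(record[locus.start : locus.end])
    seq = seq.upper()
    return reverse_complement(seq) if locus.strand == "-" else seq


def _has_polyu_tail(sense_seq: str, min_run: int, window: int) -> bool:
    tail = sense_seq[-window:]
    run = best = 0
    for base in tail:
        run = run + 1 if base == "T" else 0
        best = max(best, run)
    return best >= min_run


def sequence_flags(
    locus: FragmentLocus,
    genome,
    polyU_min_run: int = 3,
    polyU_window: int = 6,
) -> set[str]:
    """Compute sequence-signature flags for a locus and add them in place.

    tsRNA: ``polyU_3prime`` when >= ``polyU_min_run`` consecutive T occur
    within the final ``polyU_window`` nt of the sense sequence (the DNA
    template of the poly-U tail). tRF-3: ``cca_not_genome_templated`` is
    always recorded. Returns the flags added.
    """
    added: set[str] = set()
    if locus.frag_class is FragClass.TSRNA:
        sense = _fetch_sense_sequence(locus, genome)
        if _has_polyu_tail(sense, polyU_min_run, polyU_window):
            added.add(FLAG_POLYU_3P)
    elif locus.frag_class is FragClass.TRF3:
        added.add(FLAG_CCA_NOT_TEMPLATED)
    locus.flags |= added
    return added
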