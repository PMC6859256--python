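"""Normalization (RPM, TPM) and the mean-log2-TPM expression filter.

Two library-size normalizations are provided:

* RPM — reads per million mapped reads::

      RPM(f, s) = counts(f, s) * 1e6 / total_mapped(s)

  where ``total_mapped`` is the library-wide mapped-read total (not the
  within-annotation sum), so RPM column sums over annotation features never
  exceed 1e6.

* TPM — transcripts per million: counts are first divided by feature
  length in bp, then each sample's rates are rescaled to sum to 1e6::

      rate(f, s) = counts(f, s) / length(f)
      TPM(f, s)  = rate(f, s) * 1e6 / sum_f rate(f, s)

Low-expressed features are removed when their mean over samples of
log2(TPM + pseudocount) falls strictly below a threshold (default 1, the
conventional cut at TPM = 1 with pseudocount 1).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from trnafrag.quantify import CountMatrix

logger = logging.getLogger(__name__)

SCALE = 1_000_000.0


class NormMethod(str, enum.Enum):
    TPM = "TPM"
    RPM = "RPM"


@dataclass
class NormalizedMatrix:
    """TPM or RPM values with the normalization method recorded."""

    values: pd.DataFrame  # features x samples, float
    method: NormMethod
    pseudocount_used: float = 0.0
    provenance: CountMatrix | None = None

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("normalized values must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def rpm(counts: CountMatrix) -> NormalizedMatrix:
    """Reads-per-million normalization against library-wide mapped totals.

    Samples with zero mapped reads are emitted as all-zero columns with a
    warning rather than dividing by zero.
    """
    totals = counts.total_mapped.astype(float)
    values = counts.counts.astype(float).copy()
    for sample in values.columns:
        total = totals[sample]
        if total <= 0:
            logger.warning("sample %s has no mapped reads; RPM set to 0", sample)
            values[sample] = 0.0
        else:
            values[sample] = values[sample] * SCALE / total
    return NormalizedMatrix(values=values, method=NormMethod.RPM, provenance=counts)


def tpm(counts: CountMatrix, lengths: pd.Series) -> NormalizedMatrix:
    """Transcripts-per-million normalization using feature lengths in bp.

    ``lengths`` must cover every counted feature; the length-normalized
    rates of each sample are rescaled to sum to 1e6. All-zero columns stay
    all-zero with a warning.
    """
    missing = [f for f in counts.feature_ids if f not in lengths.index]
    if missing:
        raise ValueError(f"missing lengths for counted features: {missing[:5]}")
    lengths = lengths.reindex(counts.feature_ids).astype(float)
    if (lengths < 1).any():
        raise ValueError("feature lengths must be >= 1 bp")
    rates = counts.counts.astype(float).div(lengths, axis=0)
    values = rates.copy()
    for sample in rates.columns:
        denom = rates[sample].sum()
        if denom <= 0:
            logger.warning("sample %s has all-zero counts; TPM set to 0", sample)
            values[sample] = 0.0
        else:
            values[sample] = rates[sample] * SCALE / denom
    return NormalizedMatrix(values=values, method=NormMethod.TPM, provenance=counts)


def filter_by_mean_log2_tpm(
    tpm_matrix: NormalizedMatrix,
    threshold: float = 1.0,
    pseudocount: float = 1.0,
) -> tuple[NormalizedMatrix, pd.Series]:
    """Remove features whose mean log2(TPM + pseudocount) is below threshold.

    A feature is kept iff ``mean_s log2(TPM(f,s) + pseudocount) >= threshold``
    (strict-less removal: a mean of exactly the threshold is kept). Returns
    the filtered matrix and a Series of removed feature means.
    """
    if tpm_matrix.method is not NormMethod.TPM:
        raise ValueError("filter_by_mean_log2_tpm requires a TPM matrix")
    if tpm_matrix.values.shape[1] == 0:
        raise ValueError("cannot filter with zero samples")
    mean_log2 = np.log2(tpm_matrix.values + pseudocount).mean(axis=1)
    keep = mean_log2 >= threshold
    removed = mean_log2[~keep]
    kept = NormalizedMatrix(
        values=tpm_matrix.values.loc[keep],
        method=NormMethod.TPM,
        pseudocount_used=pseudocount,
        provenance=tpm_matrix.provenance,
    )
    return kept, removed


def write_normalized_tsv(matrix: NormalizedMatrix, path: str) -> None:
    """Write a normalized matrix as TSV with a one-line metadata header."""
    with open(path, "w") as fh:
        fh.write(
            f"# method={matrix.method.value}\tpseudocount={matrix.pseudocount_used}\n"
        )
        matrix.values.to_csv(fh, sep="\t", index_label="feature_id")


def read_normalized_tsv(path: str) -> NormalizedMatrix:
    """Read a TSV produced by :func:`write_normalized_tsv`."""
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(
            piece.split("=", 1) for piece in header.lstrip("# ").split("\t")
        )
        values = pd.read_csv(fh, sep="\t", index_col="feature_id")
    return NormalizedMatrix(
        values=values,
        method=NormMethod(meta["method"]),
        pseudocount_used=float(meta.get("pseudocount", 0.0)),
    )
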