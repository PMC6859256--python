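"""Independent brute-force oracles used to check the package's fast paths.

Everything here is deliberately written as plain loops over definitions,
sharing no code with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize, special, stats as sps


def oracle_assign(read, loci, strandedness="same", min_overlap=1):
    """Literal per-read assignment: nested loop over (block, locus) pairs."""
    if read.n_hits > 1:
        return "MULTIMAPPED"
    hits = set()
    for locus in loci:
        if locus.chrom != read.chrom:
            continue
        if strandedness == "same" and locus.strand != read.strand:
            continue
        if strandedness == "opposite" and locus.strand == read.strand:
            continue
        for bstart, bend in read.aligned_blocks:
            if min(bend, locus.end) - max(bstart, locus.start) >= min_overlap:
                hits.add(locus.id)
                break
    if not hits:
        return "NONE"
    if len(hits) > 1:
        return "AMBIGUOUS"
    return hits.pop()


def oracle_counts(reads, loci, strandedness="same", min_overlap=1):
    """All-pairs overlap counting with ambiguity removal; returns
    (counts dict, diagnostics dict)."""
    counts = {locus.id: 0 for locus in loci}
    diag = {"ambiguous": 0, "multimapped": 0, "unassigned": 0, "total": 0}
    for read in reads:
        diag["total"] += 1
        result = oracle_assign(read, loci, strandedness, min_overlap)
        if result == "MULTIMAPPED":
            diag["multimapped"] += 1
        elif result == "AMBIGUOUS":
            diag["ambiguous"] += 1
        elif result == "NONE":
            diag["unassigned"] += 1
        else:
            counts[result] += 1
    return counts, diag


def oracle_rpm(counts, totals):
    """Elementwise recomputation of reads-per-million."""
    out = {}
    for f in counts.index:
        for s in counts.columns:
            total = totals[s]
            out[(f, s)] = counts.loc[f, s] * 1e6 / total if total > 0 else 0.0
    return out


def oracle_bh(p):
    """Literal step-up definition: adj_(i) = min_{j>=i} min(1, (m/j) p_(j))."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    for rank, idx in enumerate(order, start=1):
        best = min(
            min(1.0, (m / j) * p[order[j - 1]]) for j in range(rank, m + 1)
        )
        adjusted[idx] = best
    return adjusted


def oracle_moderated_t(expr, group1_cols, group2_cols, prior_df=None):
    """Per-feature OLS + explicit moment-matching empirical Bayes.

    Root-finds the trigamma equation with brentq (independent of any
    Newton iteration). Returns a dict of lists keyed by statistic.
    """
    n1, n2 = len(group1_cols), len(group2_cols)
    d = n1 + n2 - 2
    logfc, s2 = [], []
    for fid in expr.index:
        a = [expr.loc[fid, c] for c in group1_cols]
        b = [expr.loc[fid, c] for c in group2_cols]
        m1 = sum(a) / n1
        m2 = sum(b) / n2
        logfc.append(m2 - m1)
        ss = sum((x - m1) ** 2 for x in a) + sum((x - m2) ** 2 for x in b)
        s2.append(ss / d)
    s2_arr = np.array(s2)
    pos = s2_arr[s2_arr > 0]
    e = np.log(pos) - special.digamma(d / 2) + math.log(d / 2)
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2))
    if e_var > 0:
        half_d0 = optimize.brentq(
            lambda x: float(special.polygamma(1, x)) - e_var, 1e-8, 1e8
        )
        d0 = 2 * half_d0
        s0_sq = math.exp(
            float(np.mean(e)) + float(special.digamma(d0 / 2)) - math.log(d0 / 2)
        )
    else:
        d0 = 1e6
        s0_sq = math.exp(float(np.mean(e)))
    if prior_df is not None:
        d0 = prior_df
    t_stats, p_vals, s2_post = [], [], []
    for lfc, v in zip(logfc, s2):
        if math.isinf(d0):
            post = s0_sq
            df_total = math.inf
        else:
            post = (d0 * s0_sq + d * v) / (d0 + d)
            df_total = d0 + d
        se = math.sqrt(post * (1 / n1 + 1 / n2))
        t = lfc / se if se > 0 else math.copysign(math.inf, lfc) if lfc else 0.0
        if math.isinf(df_total):
            p = 2 * sps.norm.sf(abs(t))
        else:
            p = 2 * sps.t.sf(abs(t), df=df_total)
        t_stats.append(t)
        p_vals.append(p)
        s2_post.append(post)
    return {
        "logFC": logfc,
        "t_mod": t_stats,
        "p": p_vals,
        "s2_post": s2_post,
        "d0": d0,
        "s0_sq": s0_sq,
    }


def binom_bounds_99(n, p):
    """Central 99% interval for a binomial proportion, as fractions."""
    lo = sps.binom.ppf(0.005, n, p) / n
    hi = sps.binom.ppf(0.995, n, p) / n
    return lo, hi
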