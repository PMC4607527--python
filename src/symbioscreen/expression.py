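"""Transcript quantification and two-library differential expression.

The study design this module serves has one RNA-seq library per condition
(bacteriocyte vs whole body), so differential expression rests on the
Audic-Claverie tag-count statistic: conditional on observing ``x`` fragments
for a transcript in library 1 (total depth N1), the count ``y`` in library 2
(depth N2) follows

    p(y | x) = (N2/N1)^y * (x+y)! / (x! * y! * (1+N2/N1)^(x+y+1)),

the posterior predictive of a Poisson rate under a flat prior.  Calls combine
a Benjamini-Hochberg q-value threshold with a log2 fold-change threshold on
FPKM (fragments per kilobase of transcript per million mapped fragments).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LibraryPair",
    "OrthologPair",
    "ClipResult",
    "compute_fpkm",
    "pair_orthologs",
    "clip_overlap",
    "ac_test",
    "ac_test_many",
    "bh_adjust",
    "log2_ratio",
    "call_differential",
    "round_half_up",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LibraryPair:
    """Total mapped-fragment counts of the two libraries (N1, N2)."""

    total_lib1: int
    total_lib2: int

    def __post_init__(self) -> None:
        if self.total_lib1 <= 0 or self.total_lib2 <= 0:
            raise ValueError("library totals must be positive")


@dataclass(frozen=True)
class OrthologPair:
    """A retained ortholog match between assemblies A and B.

    Coordinates are 1-based inclusive on each transcript.
    """

    id_a: str
    id_b: str
    pident: float
    overlap_bp: int
    interval_a: tuple[int, int]
    interval_b: tuple[int, int]


@dataclass(frozen=True)
class ClipResult:
    """Complement intervals left on each transcript after removing the
    aligned (overlapping) region, with retained-length bookkeeping."""

    intervals_a: tuple[tuple[int, int], ...]
    intervals_b: tuple[tuple[int, int], ...]
    retained_a: int
    retained_b: int


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching report-table presentation."""
    factor = 10**ndigits
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)


def compute_fpkm(
    counts: Sequence[int] | np.ndarray,
    lengths: Sequence[int] | np.ndarray,
    library_total: int,
    ids: Sequence[str] | None = None,
) -> np.ndarray:
    """FPKM_i = counts_i * 1e9 / (lengths_i * library_total).

    ``ids`` is only used to name the offending transcript in errors.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    bad = np.nonzero(lengths <= 0)[0]
    if bad.size:
        name = ids[bad[0]] if ids is not None else f"index {bad[0]}"
        raise ValueError(f"non-positive transcript length for {name}")
    return counts * 1e9 / (lengths * library_total)


def pair_orthologs(
    hits: pd.DataFrame,
    min_ident: float = 99.0,
    min_overlap: int = 200,
) -> list[OrthologPair]:
    """Select one ortholog partner per query from a MegaBLAST-style hit table.

    Retains hits with percent identity strictly above ``min_ident`` and
    alignment length >= ``min_overlap``; picks the best hit per query by
    bitscore (ties: lower E-value, then lexicographic subject id).  Records
    with inverted query coordinates are logged and skipped.
    """
    required = {"qseqid", "sseqid", "pident", "length", "qstart", "qend", "sstart", "send"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")

    malformed = hits["qstart"] > hits["qend"]
    for _, row in hits[malformed].iterrows():
        logger.warning(
            "skipping hit %s->%s with inverted query coordinates %d>%d",
            row["qseqid"], row["sseqid"], row["qstart"], row["qend"],
        )
    ok = hits[~malformed]
    ok = ok[(ok["pident"] > min_ident) & (ok["length"] >= min_overlap)]
    if ok.empty:
        return []

    ok = ok.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    best = ok.groupby("qseqid", sort=True).head(1)
    pairs = []
    for _, row in best.iterrows():
        s1, s2 = int(row["sstart"]), int(row["send"])
        pairs.append(
            OrthologPair(
                id_a=str(row["qseqid"]),
                id_b=str(row["sseqid"]),
                pident=float(row["pident"]),
                overlap_bp=int(row["length"]),
                interval_a=(int(row["qstart"]), int(row["qend"])),
                interval_b=(min(s1, s2), max(s1, s2)),
            )
        )
    return pairs


def _complement(interval: tuple[int, int], length: int) -> tuple[tuple[int, int], ...]:
    start, end = interval
    if start < 1 or end > length or start > end:
        raise ValueError(f"aligned interval {interval} outside transcript of length {length}")
    out = []
    if start > 1:
        out.append((1, start - 1))
    if end < length:
        out.append((end + 1, length))
    return tuple(out)


def clip_overlap(pair: OrthologPair, length_a: int, length_b: int) -> ClipResult:
    """Remove the aligned region of an ortholog pair from both transcripts.

    Returns the complement of the aligned interval on each transcript as
    1-based inclusive intervals, plus retained lengths for downstream FPKM
    on the clipped regions.
    """
    ints_a = _complement(pair.interval_a, length_a)
    ints_b = _complement(pair.interval_b, length_b)
    ret_a = sum(e - s + 1 for s, e in ints_a)
    ret_b = sum(e - s + 1 for s, e in ints_b)
    return ClipResult(ints_a, ints_b, ret_a, ret_b)


def _log_cond_pmf(x: int, ks: np.ndarray, log_ratio: float, log1p_ratio: float) -> np.ndarray:
    # log p(k|x) with ratio = N2/N1, in log-gamma space
    return (
        ks * log_ratio
        + gammaln(x + ks + 1.0)
        - gammaln(x + 1.0)
        - gammaln(ks + 1.0)
        - (x + ks + 1.0) * log1p_ratio
    )


def _upper_tail_direct(x: int, y: int, ratio: float, log_ratio: float,
                       log1p_ratio: float) -> float:
    # sum_{k>=y} p(k|x) by the term recurrence; successive-term ratio tends
    # to ratio/(1+ratio) < 1, so convergence is geometric
    log_t = float(_log_cond_pmf(x, np.array([y], dtype=float), log_ratio, log1p_ratio)[0])
    if log_t < -745.0:  # below double underflow: tail is numerically 0
        return 0.0
    t = math.exp(log_t)
    total = t
    k = y
    step = ratio / (1.0 + ratio)
    while True:
        t *= step * (x + k + 1) / (k + 1)
        total += t
        k += 1
        if t <= total * 1e-18 or k > y + 100_000:
            break
    return total


def _ac_pvalue(x: int, y: int, ratio: float, log_ratio: float,
               log1p_ratio: float) -> float:
    ks = np.arange(y + 1)
    lt = _log_cond_pmf(x, ks, log_ratio, log1p_ratio)
    lower = math.exp(logsumexp(lt))
    below = math.exp(logsumexp(lt[:-1])) if y > 0 else 0.0
    if below < 0.5:
        # complement is well-conditioned here (upper tail > ~0.5)
        upper = max(0.0, 1.0 - below)
    else:
        # 1 - below would lose relative precision on a small tail
        upper = _upper_tail_direct(x, y, ratio, log_ratio, log1p_ratio)
    return min(1.0, 2.0 * min(lower, upper))


def ac_test(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided Audic-Claverie p-value for counts (x, y) at depths (N1, N2).

    Tails are accumulated in log-gamma space and the two-sided value is
    min(1, 2*min(lower tail, upper tail)).  The upper tail is evaluated as
    the complement 1 - sum_{k<y} p(k|x) (clamped at 0) while that is
    well-conditioned, and by direct geometric summation of sum_{k>=y} once
    the complement would lose relative precision.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    ratio = n2 / n1
    return _ac_pvalue(x, y, ratio, math.log(n2) - math.log(n1), math.log1p(ratio))


def ac_test_many(
    xs: Sequence[int] | np.ndarray,
    ys: Sequence[int] | np.ndarray,
    n1: int,
    n2: int,
) -> np.ndarray:
    """Vectorised convenience wrapper over :func:`ac_test`."""
    xs = np.asarray(xs, dtype=np.int64)
    ys = np.asarray(ys, dtype=np.int64)
    if xs.shape != ys.shape:
        raise ValueError("xs and ys must have equal shape")
    if np.any(xs < 0) or np.any(ys < 0):
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    ratio = n2 / n1
    log_ratio = math.log(n2) - math.log(n1)
    log1p_ratio = math.log1p(ratio)
    out = np.empty(xs.shape, dtype=float)
    flat_x, flat_y = xs.ravel(), ys.ravel()
    res = out.ravel()
    for i in range(flat_x.size):
        res[i] = _ac_pvalue(int(flat_x[i]), int(flat_y[i]), ratio, log_ratio, log1p_ratio)
    return out


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_ratio(fpkm_1: float, fpkm_2: float, pseudocount: float = 0.0) -> float:
    """log2((fpkm_1 + pseudocount) / (fpkm_2 + pseudocount)).

    With the default pseudocount of 0 both inputs must be strictly positive.
    """
    if fpkm_1 < 0 or fpkm_2 < 0:
        raise ValueError("FPKM values must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    a, b = fpkm_1 + pseudocount, fpkm_2 + pseudocount
    if b == 0 or a == 0:
        raise ValueError("zero FPKM with zero pseudocount: ratio undefined")
    return math.log2(a / b)


def call_differential(
    records: pd.DataFrame,
    libs: LibraryPair,
    fdr_threshold: float = 0.001,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-transcript FPKM, AC p, BH q and enriched/depleted/unchanged calls.

    ``records`` needs columns transcript_id, length_bp, count_lib1,
    count_lib2.  Library 1 is the bacteriocyte-style focal library, so
    ``enriched`` means higher in library 1.  Transcripts with a zero count in
    one library get a signed-infinite fold change (the direction is known,
    the magnitude is not); both-zero transcripts get 0.
    """
    cols = ["transcript_id", "length_bp", "count_lib1", "count_lib2"]
    missing = set(cols) - set(records.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    out = records[cols].copy().reset_index(drop=True)
    if out.empty:
        for c in ("fpkm_1", "fpkm_2", "log2_ratio", "p_value", "q_value"):
            out[c] = pd.Series(dtype=float)
        out["call"] = pd.Series(dtype=str)
        return out

    out["fpkm_1"] = compute_fpkm(
        out["count_lib1"], out["length_bp"], libs.total_lib1, ids=out["transcript_id"]
    )
    out["fpkm_2"] = compute_fpkm(
        out["count_lib2"], out["length_bp"], libs.total_lib2, ids=out["transcript_id"]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = np.log2(out["fpkm_1"].to_numpy() / out["fpkm_2"].to_numpy())
    lr[np.isnan(lr)] = 0.0  # 0/0: no evidence either way
    out["log2_ratio"] = lr
    out["p_value"] = ac_test_many(
        out["count_lib1"].to_numpy(), out["count_lib2"].to_numpy(),
        libs.total_lib1, libs.total_lib2,
    )
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    sig = out["q_value"] < fdr_threshold
    out["call"] = "unchanged"
    out.loc[sig & (out["log2_ratio"] >= lfc_threshold), "call"] = "enriched"
    out.loc[sig & (out["log2_ratio"] <= -lfc_threshold), "call"] = "depleted"
    return out
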