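"""qPCR quantification arithmetic.

Standard-curve amplification efficiency E = 10^(-1/slope) - 1 (slope of Ct
against log10 template quantity; slope -3.3219 cycles/log10 is perfect
doubling, E = 1), relative expression by the 2^-ddCt method with log2
reporting, and within-pathway transcript abundance by 2^-dCt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

__all__ = [
    "EfficiencyResult",
    "DdctSummary",
    "amplification_efficiency",
    "ddct_replicates",
    "relative_expression_ddct",
    "relative_abundance_dct",
]


@dataclass(frozen=True)
class EfficiencyResult:
    slope: float
    efficiency: float
    r_squared: float


@dataclass(frozen=True)
class DdctSummary:
    """Per-reference-gene summary of 2^-ddCt relative expression."""

    reference_gene: str
    log2_per_replicate: tuple[float, ...]
    mean_log2: float
    se_log2: float
    n: int


def amplification_efficiency(
    log10_quantity: Sequence[float], ct: Sequence[float]
) -> EfficiencyResult:
    """Efficiency from a dilution series via OLS of Ct on log10 quantity."""
    x = np.asarray(log10_quantity, dtype=float)
    y = np.asarray(ct, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >=3 matched (log10 quantity, Ct) points")
    if np.ptp(x) == 0:
        raise ValueError("template quantities must not all be equal")
    fit = linregress(x, y)
    eff = 10.0 ** (-1.0 / fit.slope) - 1.0
    return EfficiencyResult(slope=float(fit.slope), efficiency=float(eff),
                            r_squared=float(fit.rvalue**2))


def ddct_replicates(
    ct_target_sample: Sequence[float],
    ct_ref_sample: Sequence[float],
    ct_target_calibrator: Sequence[float],
    ct_ref_calibrator: Sequence[float],
) -> np.ndarray:
    """Per-replicate ddCt = (Ct_tgt - Ct_ref)_sample - (Ct_tgt - Ct_ref)_calibrator."""
    arrs = [np.asarray(a, dtype=float) for a in (
        ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator)]
    n = arrs[0].size
    if any(a.size != n for a in arrs) or n == 0:
        raise ValueError("replicate vectors must be non-empty and matched")
    return (arrs[0] - arrs[1]) - (arrs[2] - arrs[3])


def relative_expression_ddct(
    ct_records: pd.DataFrame,
    target_gene: str,
    reference_genes: Sequence[str],
    sample: str,
    calibrator: str,
) -> list[DdctSummary]:
    """2^-ddCt relative expression of ``sample`` vs ``calibrator``.

    ``ct_records`` columns: sample, gene, replicate, ct.  Replicates are
    matched on the replicate index; the result is reported separately per
    reference gene (no pooling), as mean +/- SE of the log2-transformed
    relative expression, which equals -ddCt exactly.
    """
    required = {"sample", "gene", "replicate", "ct"}
    if required - set(ct_records.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if (ct_records["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")

    def _cts(cond: str, gene: str) -> pd.Series:
        sel = ct_records[(ct_records["sample"] == cond) & (ct_records["gene"] == gene)]
        return sel.set_index("replicate")["ct"].sort_index()

    out = []
    for ref in reference_genes:
        series = {
            "ts": _cts(sample, target_gene),
            "rs": _cts(sample, ref),
            "tc": _cts(calibrator, target_gene),
            "rc": _cts(calibrator, ref),
        }
        idx = series["ts"].index
        if any(not s.index.equals(idx) or s.empty for s in series.values()):
            raise ValueError(
                f"unmatched replicate structure for target {target_gene!r} / reference {ref!r}"
            )
        ddct = ddct_replicates(series["ts"], series["rs"], series["tc"], series["rc"])
        log2_rel = -ddct  # log2(2^-ddCt) == -ddCt
        n = log2_rel.size
        se = float(np.std(log2_rel, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        out.append(
            DdctSummary(
                reference_gene=ref,
                log2_per_replicate=tuple(float(v) for v in log2_rel),
                mean_log2=float(np.mean(log2_rel)),
                se_log2=se,
                n=int(n),
            )
        )
    return out


def relative_abundance_dct(ct_target: float, ct_reference: float) -> float:
    """Within-condition relative abundance 2^-(Ct_target - Ct_reference)."""
    return 2.0 ** (-(ct_target - ct_reference))
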