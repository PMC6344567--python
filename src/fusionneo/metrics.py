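"""Sample-level metrics: fusion fraction, survival stratification, TIC ratio.

The fusion fraction (FF) summarizes genomic instability from RNA-seq alone:
the supporting read-pair (span) counts of all assembly-validated INTER and
INTRA fusions, normalized per 10 million mapped paired reads.  Read-through
chimeras (TICs) are excluded because they need not reflect rearrangement.
The normalization makes FF approximately invariant to sequencing depth, so
samples sequenced at different depths remain comparable.

A sample counts as high-FF when its fraction exceeds twice that of matched
normal controls; cohorts are stratified for survival at a configurable FF
cutoff (2.7 by default, a top-quartile split) and compared with the standard
two-sample log-rank test, implemented here directly from the
observed-minus-expected formulas.

The TIC read ratio quantifies read-through chimera abundance relative to
total transcription of the downstream gene: mean depth over the first 10 nt
of the retained intron (chimera-only reads) divided by mean depth over the
last 10 nt of the shared exon (chimera + native reads).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    CoverageTrack,
    FusionClass,
    FusionNeoError,
    SampleFusionProfile,
    SurvivalRecord,
    TicRatioResult,
)

__all__ = [
    "fusion_fraction",
    "high_ff",
    "km_curve",
    "logrank_test",
    "km_stratify",
    "StratifiedSurvival",
    "tic_read_ratio",
]

READS_PER_UNIT = 10_000_000
#: Recommended minimum sequencing depth for fusion discovery.
MIN_RECOMMENDED_READS = 40_000_000


def fusion_fraction(
    sample_id: str,
    validated_fusions: Sequence[tuple],
    fusion_classes: Mapping[str, FusionClass],
    mapped_paired_reads: int,
    mode: str = "span_sum",
) -> SampleFusionProfile:
    """Compute the per-sample fusion fraction.

    ``validated_fusions`` holds (candidate, concordance) pairs that already
    passed assembly validation; ``fusion_classes`` maps cluster ids to their
    class so TICs can be excluded.  ``mode="span_sum"`` (default) sums span
    counts; ``mode="fusion_count"`` counts fusions instead.
    """
    if mapped_paired_reads <= 0:
        raise FusionNeoError("mapped_paired_reads must be positive")
    if mode not in ("span_sum", "fusion_count"):
        raise FusionNeoError(f"unknown fusion-fraction mode {mode!r}")
    total = 0
    for cand, _ in validated_fusions:
        cls = fusion_classes.get(cand.cluster_id)
        if cls is None:
            raise FusionNeoError(f"no class recorded for {cand.cluster_id}")
        if cls == FusionClass.TIC:
            continue
        total += cand.span_count if mode == "span_sum" else 1
    ff = total / (mapped_paired_reads / READS_PER_UNIT)
    return SampleFusionProfile(
        sample_id=sample_id,
        validated_fusions=list(validated_fusions),
        mapped_paired_reads=mapped_paired_reads,
        fusion_fraction=ff,
    )


def high_ff(ff: float, control_ff: float, multiplier: float = 2.0) -> bool:
    """High fusion fraction: strictly greater than ``multiplier`` x control."""
    if control_ff < 0:
        raise FusionNeoError("control fusion fraction must be non-negative")
    return ff > multiplier * control_ff


# ---------------------------------------------------------------------------
# Survival


def km_curve(times: Sequence[float], events: Sequence[bool]) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimator.

    Returns one row per distinct event time (plus time 0 with survival 1):
    columns time, n_at_risk, n_events, survival.  Censored observations
    leave the risk set without an event.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(t) != len(e) or len(t) == 0:
        raise FusionNeoError("times and events must be equal-length and non-empty")
    rows = [{"time": 0.0, "n_at_risk": len(t), "n_events": 0, "survival": 1.0}]
    surv = 1.0
    for tj in np.unique(t[e]):
        n_at_risk = int((t >= tj).sum())
        d = int((e & (t == tj)).sum())
        surv *= 1.0 - d / n_at_risk
        rows.append({"time": float(tj), "n_at_risk": n_at_risk, "n_events": d, "survival": surv})
    return pd.DataFrame(rows)


def logrank_test(
    times1: Sequence[float],
    events1: Sequence[bool],
    times2: Sequence[float],
    events2: Sequence[bool],
) -> tuple[float, float]:
    """Two-sample log-rank test from the standard formulas.

    At each pooled event time t_j with d_j events and n_j at risk (n_1j in
    group 1), the observed group-1 events O_1 = sum d_1j are compared with
    the expectation E_1 = sum d_j n_1j / n_j under the null, with
    hypergeometric variance V = sum d_j (n_1j/n_j)(1 - n_1j/n_j)(n_j - d_j)
    / (n_j - 1).  Returns the 1-df chi-square statistic (O-E)^2 / V and its
    p-value; (0, 1) when no variance accumulates.
    """
    t1, e1 = np.asarray(times1, float), np.asarray(events1, bool)
    t2, e2 = np.asarray(times2, float), np.asarray(events2, bool)
    if len(t1) == 0 or len(t2) == 0:
        raise FusionNeoError("both groups must be non-empty")
    pooled = np.unique(np.concatenate([t1[e1], t2[e2]]))
    observed = expected = variance = 0.0
    for tj in pooled:
        n1 = (t1 >= tj).sum()
        n2 = (t2 >= tj).sum()
        d1 = (e1 & (t1 == tj)).sum()
        d2 = (e2 & (t2 == tj)).sum()
        n, d = n1 + n2, d1 + d2
        if n == 0 or d == 0:
            continue
        observed += d1
        expected += d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if variance == 0:
        return 0.0, 1.0
    chi_sq = (observed - expected) ** 2 / variance
    return float(chi_sq), float(stats.chi2.sf(chi_sq, df=1))


@dataclass
class StratifiedSurvival:
    """KM curves per FF group plus the log-rank comparison."""

    curves: dict[str, pd.DataFrame]
    records: dict[str, list[SurvivalRecord]]
    chi_square: float
    p_value: float
    threshold: float


def km_stratify(
    records: Sequence[tuple[str, float, bool, float]],
    threshold: float = 2.7,
) -> StratifiedSurvival:
    """Stratify samples at FF > ``threshold`` and compare survival.

    ``records`` are (sample_id, time, event, fusion_fraction) tuples.
    Samples exactly at the threshold fall in the LOW_FF group (the high
    group is defined by a strict '>').  Raises when either group is empty.
    """
    groups: dict[str, list[SurvivalRecord]] = {"HIGH_FF": [], "LOW_FF": []}
    for sample_id, time, event, ff in records:
        group = "HIGH_FF" if ff > threshold else "LOW_FF"
        groups[group].append(SurvivalRecord(sample_id, float(time), bool(event), group))
    for name, recs in groups.items():
        if not recs:
            raise FusionNeoError(f"stratification leaves group {name} empty")
    curves = {
        name: km_curve([r.time for r in recs], [r.event for r in recs])
        for name, recs in groups.items()
    }
    chi_sq, p = logrank_test(
        [r.time for r in groups["HIGH_FF"]],
        [r.event for r in groups["HIGH_FF"]],
        [r.time for r in groups["LOW_FF"]],
        [r.event for r in groups["LOW_FF"]],
    )
    return StratifiedSurvival(curves=curves, records=groups, chi_square=chi_sq, p_value=p, threshold=threshold)


# ---------------------------------------------------------------------------
# TIC read ratio


def tic_read_ratio(exon_track: CoverageTrack, intron_track: CoverageTrack) -> TicRatioResult:
    """Chimera-to-total transcript ratio at an exon/intron boundary.

    ``exon_track`` covers the terminal 10 nt of the shared exon (all
    transcripts); ``intron_track`` the first 10 nt of the retained intron
    (chimeric transcripts only).
    """
    for name, track in (("exon", exon_track), ("intron", intron_track)):
        if len(track.depths) != 10:
            raise FusionNeoError(f"{name} track must cover exactly 10 nt, got {len(track.depths)}")
    exon_mean = float(np.mean(exon_track.depths))
    intron_mean = float(np.mean(intron_track.depths))
    if exon_mean == 0:
        raise FusionNeoError("exon mean depth is 0; ratio undefined")
    return TicRatioResult(
        exon_mean_depth=exon_mean,
        intron_mean_depth=intron_mean,
        ratio=intron_mean / exon_mean,
    )
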