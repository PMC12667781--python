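"""Poisson peak calling: background rate estimation, exact upper-tail test,
Benjamini-Hochberg FDR, and the cluster decision.

The null model: sequencing and RT errors hit every base independently at a
small per-substitution-type rate.  Pooling the 11 non-T-to-C substitution
types transcriptome-wide gives M background mismatches over N sequenced
bases, so the per-type (hence null T-to-C) rate is

    R = M / (11 * N).

For read group i with n_i sequenced bases, the observed T-to-C count O_i is
compared against Poisson(lambda_i = R * n_i) with the exact one-sided rate
test (the greater-alternative Poisson test); q-values come from BH over all
tested read groups genome-wide, and groups with q <= 0.05 are clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .readgroups import ReadGroup, derive_read_groups
from .tracks import MismatchTrack, build_tracks

#: number of substitution types counted as background (all but T->C)
N_BACKGROUND_TYPES = 11

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class BackgroundModel:
    """Transcriptome-wide background mismatch totals and the null rate R.

    When no background mismatch is observed the rate is floored at
    1/(divisor * n_total) — the smallest non-zero estimate the data could
    have produced — so pristine simulated data does not yield p = 0 for
    every group with a single T-to-C.
    """

    n_total: int
    m_background: int
    divisor: int = N_BACKGROUND_TYPES
    rate: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("no usable coverage: n_total must be positive")
        if self.m_background < 0:
            raise ValueError("m_background must be non-negative")
        m = max(self.m_background, 1)
        object.__setattr__(self, "rate", m / (self.divisor * self.n_total))


@dataclass(frozen=True)
class ClusterCall:
    """Per-read-group test result; ``is_cluster`` iff q_value <= alpha."""

    group: ReadGroup
    expected: float
    p_value: float
    q_value: float
    is_cluster: bool


def estimate_background(
    plus: MismatchTrack, minus: MismatchTrack, divisor: int = N_BACKGROUND_TYPES
) -> BackgroundModel:
    """Pool both strands into one background model.

    n_total = all sequenced bases, m_background = all non-T-to-C mismatches,
    rate = m_background / (divisor * n_total).
    """
    n_total = plus.total("depth") + minus.total("depth")
    m_background = plus.total("other_mm") + minus.total("other_mm")
    return BackgroundModel(n_total=n_total, m_background=m_background, divisor=divisor)


def poisson_upper_tail(observed: int, n_bases: float, rate: float) -> float:
    """Exact one-sided Poisson probability P(X >= observed), X ~ Poisson(rate*n_bases).

    This is the p-value of the exact rate test with time base ``n_bases``
    and null rate ``rate`` against the greater alternative.
    """
    if observed < 0 or n_bases < 0 or rate < 0:
        raise ValueError("observed, n_bases and rate must be non-negative")
    lam = rate * n_bases
    if not np.isfinite(lam):
        raise ValueError("rate * n_bases overflows")
    # sf(k-1) = P(X >= k); exact via the regularised incomplete gamma function
    return float(stats.poisson.sf(observed - 1, lam))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_clusters(
    groups: Sequence[ReadGroup],
    model: BackgroundModel,
    alpha: float = DEFAULT_ALPHA,
) -> list[ClusterCall]:
    """Test every read group against the background model.

    One BH family over all groups (both strands); ordering preserved.  Both
    the accepted clusters and the rejected groups remain in the output so
    downstream code can report both counts.
    """
    if not groups:
        return []
    p = np.array(
        [poisson_upper_tail(g.o_t2c, g.n_bases, model.rate) for g in groups]
    )
    q = bh_adjust(p)
    return [
        ClusterCall(
            group=g,
            expected=model.rate * g.n_bases,
            p_value=float(pi),
            q_value=float(qi),
            is_cluster=bool(qi <= alpha),
        )
        for g, pi, qi in zip(groups, p, q)
    ]


@dataclass
class PeakCallResult:
    """End-to-end result: background model plus all tested read groups."""

    model: BackgroundModel
    calls: list[ClusterCall]
    alpha: float

    @property
    def clusters(self) -> list[ClusterCall]:
        return [c for c in self.calls if c.is_cluster]

    @property
    def rejected(self) -> list[ClusterCall]:
        return [c for c in self.calls if not c.is_cluster]


def call_peaks(
    alignments: str,
    reference: str,
    min_mapq: int = 55,
    min_baseq: int = 20,
    min_depth: int = 3,
    gap: int = 0,
    max_width: int = 50,
    alpha: float = DEFAULT_ALPHA,
    divisor: int = N_BACKGROUND_TYPES,
) -> PeakCallResult:
    """Run the whole caller: pileup tracks -> read groups -> Poisson test."""
    plus, minus = build_tracks(alignments, reference, min_mapq=min_mapq, min_baseq=min_baseq)
    model = estimate_background(plus, minus, divisor=divisor)
    groups = derive_read_groups(plus, minus, min_depth=min_depth, gap=gap, max_width=max_width)
    return PeakCallResult(model=model, calls=call_clusters(groups, model, alpha), alpha=alpha)


def write_clusters_bed(
    calls: Sequence[ClusterCall], out: str, prefix: str = "CL"
) -> None:
    """BED6 + n_bases, o_t2c, other_mm, expected, p_value, q_value."""
    with open(out, "w") as fh:
        for i, c in enumerate(calls, start=1):
            g = c.group
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{prefix}{i}\t{g.o_t2c}\t{g.strand}"
                f"\t{g.n_bases}\t{g.o_t2c}\t{g.other_mm}"
                f"\t{c.expected:.6g}\t{c.p_value:.6g}\t{c.q_value:.6g}\n"
            )
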