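"""Glucan chain-length distribution summaries.

A distribution is a table of (DP, A) pairs where DP is the degree of
polymerization of a linear glucan chain and A its percent peak area.  The
summaries are the number-average DP

    x_n = sum(A * DP) / sum(A),

the mass-average DP

    x_w = sum(A * DP * DP) / sum(A * DP),

and the dispersity (polydispersity index)

    pdi = x_w / x_n,

which is 1 for a monodisperse sample and grows with the breadth of the
distribution.  All three are homogeneous of degree zero in A, so percent
areas never need unit conversion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

log = logging.getLogger("svk")


@dataclass
class ChainLengthDistribution:
    """(DP, percent-area) table for one sample replicate."""

    sample_id: str
    ear: str
    points: list[tuple[int, float]]

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("distribution must have at least one point")
        dps = [dp for dp, _ in self.points]
        if any(dp < 1 for dp in dps):
            raise ValueError("DP values must be >= 1")
        if sorted(set(dps)) != dps:
            raise ValueError("DP values must be unique and sorted")
        if any(a < 0 for _, a in self.points):
            raise ValueError("percent areas must be non-negative")
        if not any(a > 0 for _, a in self.points):
            raise ValueError("distribution must have at least one positive area")

    @property
    def dp(self) -> list[int]:
        return [dp for dp, _ in self.points]

    @property
    def area(self) -> list[float]:
        return [a for _, a in self.points]

    def total_area(self) -> float:
        return sum(self.area)


@dataclass
class DistributionSummary:
    """Moment summaries for one sample (averaged over replicate ears)."""

    sample_id: str
    x_n: float
    x_w: float
    pdi: float
    acl: float
    n_ears: int = 1
    per_ear: dict[str, dict[str, float]] = field(default_factory=dict)


def normalize(dist: ChainLengthDistribution) -> ChainLengthDistribution:
    """Rescale percent areas to sum to 100; DP values untouched."""
    total = dist.total_area()
    if total <= 0:
        raise ValueError("cannot normalize all-zero areas")
    factor = 100.0 / total
    return replace(dist, points=[(dp, a * factor) for dp, a in dist.points])


def restrict_dp_range(
    dist: ChainLengthDistribution, dp_min: int = 6, dp_max: int = 60
) -> ChainLengthDistribution:
    """Drop rows outside [dp_min, dp_max], warning when any are removed."""
    kept = [(dp, a) for dp, a in dist.points if dp_min <= dp <= dp_max]
    dropped = len(dist.points) - len(kept)
    if dropped:
        log.warning(
            "sample %s ear %s: dropped %d rows outside DP range [%d, %d]",
            dist.sample_id,
            dist.ear,
            dropped,
            dp_min,
            dp_max,
        )
    if not kept:
        raise ValueError(
            f"sample {dist.sample_id} ear {dist.ear}: no rows in DP range "
            f"[{dp_min}, {dp_max}]"
        )
    return replace(dist, points=kept)


def number_average_dp(dist: ChainLengthDistribution) -> float:
    """Area-weighted mean DP: sum(A*DP) / sum(A)."""
    num = sum(a * dp for dp, a in dist.points)
    den = dist.total_area()
    return num / den


def mass_average_dp(dist: ChainLengthDistribution) -> float:
    """Mass-weighted mean DP: sum(A*DP*DP) / sum(A*DP)."""
    num = sum(a * dp * dp for dp, a in dist.points)
    den = sum(a * dp for dp, a in dist.points)
    return num / den


def pdi(dist: ChainLengthDistribution) -> float:
    """Dispersity: mass-average over number-average DP (>= 1)."""
    return mass_average_dp(dist) / number_average_dp(dist)


def average_chain_length(dist: ChainLengthDistribution) -> float:
    """Average glucan chain length, computed as the number-average DP.

    The unweighted area mean is the only plain average the moment equations
    define, so it is used for "average chain length"; swap in
    :func:`mass_average_dp` explicitly if a mass-weighted mean is wanted.
    """
    return number_average_dp(dist)


def summarize_distribution(dist: ChainLengthDistribution) -> dict[str, float]:
    return {
        "x_n": number_average_dp(dist),
        "x_w": mass_average_dp(dist),
        "pdi": pdi(dist),
        "acl": average_chain_length(dist),
    }


def summarize_sample(replicates: list[ChainLengthDistribution]) -> DistributionSummary:
    """Summaries per ear, then averaged arithmetically across ears.

    Per-ear summaries are retained for dispersion reporting.  Averaging
    per-ear PDI values is deliberately NOT the same as pooling areas and
    computing one PDI — the per-ear-then-average path is the reported one.
    """
    if not replicates:
        raise ValueError("summarize_sample requires at least one replicate")
    sample_ids = {d.sample_id for d in replicates}
    if len(sample_ids) != 1:
        raise ValueError(f"mixed sample_ids in replicates: {sorted(sample_ids)}")
    per_ear = {d.ear: summarize_distribution(d) for d in replicates}
    n = len(replicates)
    means = {
        key: sum(s[key] for s in per_ear.values()) / n
        for key in ("x_n", "x_w", "pdi", "acl")
    }
    return DistributionSummary(
        sample_id=replicates[0].sample_id,
        x_n=means["x_n"],
        x_w=means["x_w"],
        pdi=means["pdi"],
        acl=means["acl"],
        n_ears=n,
        per_ear=per_ear,
    )


def summarize_table(
    dists: list[ChainLengthDistribution],
    dp_min: int | None = 6,
    dp_max: int | None = 60,
) -> list[DistributionSummary]:
    """Group distributions by sample_id and summarize each sample."""
    by_sample: dict[str, list[ChainLengthDistribution]] = {}
    for dist in dists:
        if dp_min is not None and dp_max is not None:
            dist = restrict_dp_range(dist, dp_min, dp_max)
        by_sample.setdefault(dist.sample_id, []).append(dist)
    return [summarize_sample(reps) for reps in by_sample.values()]
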