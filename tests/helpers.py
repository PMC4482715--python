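"""Shared helpers for the test suite."""

from svk.chains import ChainLengthDistribution, DistributionSummary, summarize_sample


def make_summaries(dists: list[ChainLengthDistribution]) -> list[DistributionSummary]:
    """Group ear-level distributions by sample and summarize each sample."""
    by_sample: dict[str, list[ChainLengthDistribution]] = {}
    for d in dists:
        by_sample.setdefault(d.sample_id, []).append(d)
    return [summarize_sample(reps) for reps in by_sample.values()]
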