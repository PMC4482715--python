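"""Synthetic data generators for the full pipeline.

Three generators mirror the three kinds of input the analysis consumes:

* near-identical allele cDNA pairs with planted SNPs and in-frame deletions
  (ground truth returned for recovery tests);
* FACE-like amylopectin chain-length distributions, modelled as a
  two-component mixture of discretized lognormal densities over integer DP
  (a short A-chain mode plus a long B-chain tail) whose parameters depend on
  the 2x2 Zpu1/SSIII genotype class;
* RIL phenotype panels in which vitreousness follows a * exp(r * PDI) plus
  truncated Gaussian noise and pullulanase activity is an affine function of
  vitreousness with noise calibrated to a target population R-squared.

Everything is driven by a single numpy Generator seeded once per call, so a
fixed seed replays a panel exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from svk.alleles import CODON_MAP, Variant, translate_codon
from svk.chains import ChainLengthDistribution, pdi as compute_pdi, number_average_dp
from svk.io import RilRecord, SequenceRecord

log = logging.getLogger("svk")

GENOTYPE_CLASSES = ("Q-Q", "Q-W", "W-Q", "W-W")

_STOP_CODONS = {c for c, aa in CODON_MAP.items() if aa == "*"}
_SENSE_CODONS = sorted(set(CODON_MAP) - _STOP_CODONS)


@dataclass
class AlleleSimSpec:
    """Specification for one simulated reference/alternate allele pair."""

    length: int = 300
    n_snps: int = 4
    n_silent: int = 3
    indel_lengths: list[int] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length % 3 != 0:
            raise ValueError("length must be divisible by 3 (treated as a CDS)")
        if self.length < 9:
            raise ValueError("length must allow start + one codon + stop")
        if self.n_silent > self.n_snps:
            raise ValueError("n_silent cannot exceed n_snps")
        if self.n_snps < 0 or self.n_silent < 0:
            raise ValueError("variant counts must be non-negative")
        if any(l <= 0 or l % 3 != 0 for l in self.indel_lengths):
            raise ValueError("indel lengths must be positive multiples of 3")


@dataclass
class ChainMixtureParams:
    """Two-component discretized-lognormal mixture over integer DP."""

    short_mode_loc: float = math.log(12.0)  # lognormal mu of the A-chain mode
    short_mode_scale: float = 0.32
    long_tail_loc: float = math.log(31.0)  # lognormal mu of the B-chain tail
    long_tail_scale: float = 0.30
    long_weight: float = 0.22  # mixture weight of the long tail

    def __post_init__(self) -> None:
        if not 0.0 <= self.long_weight <= 1.0:
            raise ValueError("mixture weight must be within [0, 1]")
        if self.short_mode_scale < 0 or self.long_tail_scale < 0:
            raise ValueError("component scales must be non-negative")


#: Default class-specific mixtures.  Chosen only to reproduce the observed
#: ordering of mean chain length (W-Q highest, Q-Q/W-W intermediate, Q-W
#: lowest); magnitudes are not calibrated to any measured values.
DEFAULT_CLASS_PARAMS: dict[str, ChainMixtureParams] = {
    "W-Q": ChainMixtureParams(long_weight=0.30),
    "Q-Q": ChainMixtureParams(long_weight=0.22),
    "W-W": ChainMixtureParams(long_weight=0.20),
    "Q-W": ChainMixtureParams(long_weight=0.17),
}


@dataclass
class PanelSimSpec:
    """Specification for a simulated RIL panel."""

    n_ril: int = 14
    ears_per_ril: int = 3
    class_params: dict[str, ChainMixtureParams] = field(
        default_factory=lambda: {k: replace(v) for k, v in DEFAULT_CLASS_PARAMS.items()}
    )
    dp_min: int = 6
    dp_max: int = 60
    # vitreousness = amplitude * exp(growth_rate * PDI) + N(0, noise_sd), truncated at 0
    vit_amplitude: float = 2.0
    vit_growth_rate: float = 4.0
    vit_noise_sd: float = 25.0
    # per-RIL spread of the long-tail scale (log-sd of a multiplicative jitter);
    # this is what creates between-RIL PDI variation
    ril_scale_jitter: float = 0.16
    # per-ear multiplicative area noise (coefficient of variation)
    ear_area_cv: float = 0.02
    pullulanase_r2: float = 0.38
    pullulanase_intercept: float = 0.15
    pullulanase_slope: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ril < 4:
            raise ValueError("n_ril must be >= 4 so all four genotype classes appear")
        if self.ears_per_ril < 1:
            raise ValueError("ears_per_ril must be >= 1")
        if not 0.0 < self.pullulanase_r2 < 1.0:
            raise ValueError("target R-squared must be in (0, 1)")
        if self.vit_growth_rate <= 0:
            raise ValueError("growth rate must be > 0")
        if self.vit_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.dp_min < 1 or self.dp_max < self.dp_min:
            raise ValueError("invalid DP support")
        missing = set(GENOTYPE_CLASSES) - set(self.class_params)
        if missing:
            raise ValueError(f"class_params missing genotype classes: {sorted(missing)}")


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """Random CDS: ATG start, random sense codons, one stop codon at the end."""
    n_internal = length // 3 - 2
    codons = ["ATG"]
    codons += list(rng.choice(_SENSE_CODONS, size=n_internal))
    codons.append(str(rng.choice(sorted(_STOP_CODONS))))
    return "".join(codons)


def _synonymous_options(codon: str, within: int) -> list[str]:
    """Alternate bases at ``within`` (0..2) that keep the amino acid."""
    aa = translate_codon(codon)
    options = []
    for base in "ACGT":
        if base == codon[within]:
            continue
        alt = codon[:within] + base + codon[within + 1 :]
        if translate_codon(alt) == aa:
            options.append(base)
    return options


def _missense_options(codon: str, within: int) -> list[str]:
    """Alternate bases that change the amino acid without creating a stop."""
    aa = translate_codon(codon)
    options = []
    for base in "ACGT":
        if base == codon[within]:
            continue
        alt = codon[:within] + base + codon[within + 1 :]
        alt_aa = translate_codon(alt)
        if alt_aa not in (aa, "*"):
            options.append(base)
    return options


def simulate_allele_pair(
    spec: AlleleSimSpec, max_retries: int = 50
) -> tuple[SequenceRecord, SequenceRecord, list[Variant]]:
    """Generate a reference CDS, an alternate carrying planted variants, and
    the exact truth set in reference coordinates.

    Silent SNPs are planted only where the codon table guarantees synonymy;
    in-frame deletions are codon-aligned.  Planted positions are kept >= 3 nt
    apart.  Raises after bounded retries if the spec is infeasible.
    """
    rng = np.random.default_rng(spec.seed)
    last_error: Exception | None = None
    for _ in range(max_retries):
        try:
            return _attempt_allele_pair(rng, spec)
        except _Infeasible as exc:
            last_error = exc
    raise ValueError(
        f"could not satisfy allele spec after {max_retries} retries: {last_error}"
    )


class _Infeasible(Exception):
    pass


def _attempt_allele_pair(rng, spec: AlleleSimSpec):
    reference = _random_cds(rng, spec.length)
    n_codons = spec.length // 3
    # editable codons exclude the start and stop codon
    internal = list(range(1, n_codons - 1))
    rng.shuffle(internal)

    used_positions: list[int] = []

    def far_enough(pos: int, span: int = 1) -> bool:
        return all(
            abs(pos - q) >= 3 and abs(pos + span - 1 - q) >= 3 for q in used_positions
        )

    truth: list[Variant] = []
    n_missense = spec.n_snps - spec.n_silent
    wanted = (
        [("silent", None)] * spec.n_silent
        + [("missense", None)] * n_missense
        + [("deletion", l) for l in spec.indel_lengths]
    )
    # plant deletions first (they consume whole codons), then SNPs
    wanted.sort(key=lambda w: 0 if w[0] == "deletion" else 1)

    deleted_codons: set[int] = set()
    codon_iter = iter(internal)
    for kind, del_len in wanted:
        placed = False
        for codon_idx in codon_iter:
            start_nt = codon_idx * 3 + 1
            codon = reference[codon_idx * 3 : codon_idx * 3 + 3]
            if kind == "deletion":
                n_del_codons = del_len // 3
                codon_span = range(codon_idx, codon_idx + n_del_codons)
                if codon_idx + n_del_codons >= n_codons - 1:
                    continue
                if any(c in deleted_codons for c in codon_span):
                    continue
                # canonical (leftmost) placement of the same edit, so the
                # planted truth matches left-normalized variant calls exactly
                norm_start = start_nt
                while (
                    norm_start > 4  # keep clear of the ATG start codon
                    and reference[norm_start - 2] == reference[norm_start + del_len - 2]
                ):
                    norm_start -= 1
                if not far_enough(norm_start, span=start_nt + del_len - norm_start):
                    continue
                ref_bases = reference[norm_start - 1 : norm_start - 1 + del_len]
                truth.append(Variant(norm_start, ref_bases, "", "deletion"))
                deleted_codons.update(codon_span)
                # pad the exclusion zone by the deletion length: a SNP within
                # del_len+3 of a gap can make an alternative alignment
                # score-equivalent, breaking exact truth recovery
                used_positions.extend(
                    range(norm_start - del_len, start_nt + 2 * del_len)
                )
                placed = True
                break
            else:
                if codon_idx in deleted_codons:
                    continue
                offsets = list(range(3))
                rng.shuffle(offsets)
                for within in offsets:
                    pos = start_nt + within
                    if not far_enough(pos):
                        continue
                    options = (
                        _synonymous_options(codon, within)
                        if kind == "silent"
                        else _missense_options(codon, within)
                    )
                    if not options:
                        continue
                    alt_base = str(rng.choice(options))
                    truth.append(Variant(pos, codon[within], alt_base, "SNP"))
                    used_positions.append(pos)
                    placed = True
                    break
                if placed:
                    break
        if not placed:
            raise _Infeasible(f"no remaining site for a {kind} variant")

    truth.sort(key=lambda v: v.ref_pos)

    # build the alternate sequence by applying the truth set
    from svk.alleles import apply_variants

    alternate = apply_variants(reference, truth)
    ref_rec = SequenceRecord("ref", reference, "DNA", "simulated reference CDS")
    alt_rec = SequenceRecord("alt", alternate, "DNA", "simulated alternate CDS")
    return ref_rec, alt_rec, truth


def _mixture_areas(
    params: ChainMixtureParams, dp: np.ndarray
) -> np.ndarray:
    """Unnormalized mixture density over integer DP.

    A zero-scale component collapses to a point mass at round(exp(loc)).
    """

    def component(loc: float, scale: float) -> np.ndarray:
        if scale == 0.0:
            out = np.zeros(dp.size)
            target = int(round(math.exp(loc)))
            out[dp == target] = 1.0
            return out
        logdp = np.log(dp)
        return np.exp(-0.5 * ((logdp - loc) / scale) ** 2) / (dp * scale)

    short = component(params.short_mode_loc, params.short_mode_scale)
    long_ = component(params.long_tail_loc, params.long_tail_scale)
    return (1.0 - params.long_weight) * short + params.long_weight * long_


def simulate_chain_distribution(
    genotype_class: str,
    spec: PanelSimSpec,
    seed: int,
    sample_id: str = "sim",
    ear: str = "1",
    scale_multiplier: float = 1.0,
) -> ChainLengthDistribution:
    """One FACE-like distribution for a genotype class.

    ``scale_multiplier`` widens/narrows both mixture components and is how
    between-RIL dispersity variation is injected by the panel generator.
    Percent areas are normalized to sum to 100.
    """
    if genotype_class not in spec.class_params:
        raise ValueError(f"unknown genotype class {genotype_class!r}")
    dp = np.arange(spec.dp_min, spec.dp_max + 1)
    if dp.size == 0:
        raise ValueError("empty DP support")
    rng = np.random.default_rng(seed)
    params = spec.class_params[genotype_class]
    params = replace(
        params,
        short_mode_scale=params.short_mode_scale * scale_multiplier,
        long_tail_scale=params.long_tail_scale * scale_multiplier,
    )
    areas = _mixture_areas(params, dp)
    if spec.ear_area_cv > 0:
        noise = rng.normal(1.0, spec.ear_area_cv, size=dp.size)
        areas = areas * np.clip(noise, 0.0, None)
    total = areas.sum()
    if total <= 0:
        raise ValueError("mixture produced all-zero areas on the DP support")
    areas = areas * (100.0 / total)
    return ChainLengthDistribution(
        sample_id=sample_id,
        ear=ear,
        points=list(zip(dp.tolist(), areas.tolist())),
    )


def simulate_ril_panel(
    spec: PanelSimSpec,
) -> tuple[list[RilRecord], list[ChainLengthDistribution], dict]:
    """Simulate a full RIL panel: phenotype records, chain distributions, and
    the truth parameters needed for recovery tests.

    Genotype classes are assigned round-robin so all four are always
    represented.  Vitreousness is a * exp(r * PDI) + truncated Gaussian
    noise at the ear level; pullulanase A490 is affine in vitreousness with
    noise variance solved from the target population R-squared.
    """
    rng = np.random.default_rng(spec.seed)
    classes = [GENOTYPE_CLASSES[i % 4] for i in range(spec.n_ril)]
    rng.shuffle(classes)

    records: list[RilRecord] = []
    dists: list[ChainLengthDistribution] = []
    pdis = []
    vits = []
    for i, genotype in enumerate(classes):
        ril_id = f"RIL{i + 1:03d}"
        zpu1, ssiii = genotype.split("-")
        multiplier = float(np.exp(rng.normal(0.0, spec.ril_scale_jitter)))
        for ear_idx in range(spec.ears_per_ril):
            ear = str(ear_idx + 1)
            dist = simulate_chain_distribution(
                genotype,
                spec,
                seed=int(rng.integers(0, 2**63 - 1)),
                sample_id=ril_id,
                ear=ear,
                scale_multiplier=multiplier,
            )
            dists.append(dist)
            ear_pdi = compute_pdi(dist)
            vit = spec.vit_amplitude * math.exp(spec.vit_growth_rate * ear_pdi)
            if spec.vit_noise_sd > 0:
                vit = max(0.0, vit + float(rng.normal(0.0, spec.vit_noise_sd)))
            pdis.append(ear_pdi)
            vits.append(vit)
            records.append(
                RilRecord(
                    ril_id=ril_id,
                    zpu1_allele=zpu1,
                    ssiii_allele=ssiii,
                    ear=ear,
                    vitreousness=vit,
                )
            )

    # calibrate pullulanase noise so the population R^2 hits the target:
    # R^2 = b1^2 Var(V) / (b1^2 Var(V) + sigma^2)
    vit_arr = np.asarray(vits)
    signal_var = spec.pullulanase_slope**2 * float(vit_arr.var())
    noise_var = signal_var * (1.0 - spec.pullulanase_r2) / spec.pullulanase_r2
    noise_sd = math.sqrt(noise_var)
    for rec in records:
        pull = (
            spec.pullulanase_intercept
            + spec.pullulanase_slope * rec.vitreousness
            + float(rng.normal(0.0, noise_sd))
        )
        rec.pullulanase_a490 = pull
        # DSC phenotypes: simple class-shifted Gaussians (consumed as-is by
        # the association stage; no instrument model intended)
        base = {"Q-Q": 0.0, "Q-W": 1.0, "W-Q": 0.6, "W-W": 0.2}[rec.genotype_class]
        rec.onset_c = 66.0 + base + float(rng.normal(0.0, 0.3))
        rec.max_c = 71.0 + base + float(rng.normal(0.0, 0.3))
        rec.enthalpy = 10.0 + 2.0 * (rec.genotype_class in ("W-Q", "Q-Q")) + float(
            rng.normal(0.0, 0.4)
        )

    truth = {
        "vit_amplitude": spec.vit_amplitude,
        "vit_growth_rate": spec.vit_growth_rate,
        "vit_noise_sd": spec.vit_noise_sd,
        "pullulanase_intercept": spec.pullulanase_intercept,
        "pullulanase_slope": spec.pullulanase_slope,
        "pullulanase_noise_sd": noise_sd,
        "pullulanase_r2": spec.pullulanase_r2,
        "classes": dict(zip([f"RIL{i + 1:03d}" for i in range(spec.n_ril)], classes)),
    }
    log.info(
        "simulate_ril_panel: %d RILs x %d ears, seed %d",
        spec.n_ril,
        spec.ears_per_ril,
        spec.seed,
    )
    return records, dists, truth
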