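"""Allele comparison: global alignment, variant calling, coding effects.

Near-identical allele cDNAs are compared by global alignment with affine gap
penalties (Needleman-Wunsch; a length-L gap costs open + L*extend).  Variants
are reported on the reference, 1-based, with indel runs left-normalized so a
gap in a repeat is always placed at its leftmost equivalent position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from Bio.Align import PairwiseAligner
from Bio.Data import CodonTable

from svk.io import SequenceRecord

log = logging.getLogger("svk")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_MAP: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    CODON_MAP[_stop] = "*"

GAP = "-"


@dataclass
class AlignmentResult:
    """A pairwise global alignment of alternate against reference."""

    gapped_ref: str
    gapped_alt: str
    score: float
    ref_coord_map: list[int]

    def __post_init__(self) -> None:
        if len(self.gapped_ref) != len(self.gapped_alt):
            raise ValueError("gapped sequences must have equal length")

    @property
    def ref(self) -> str:
        return self.gapped_ref.replace(GAP, "")

    @property
    def alt(self) -> str:
        return self.gapped_alt.replace(GAP, "")


@dataclass
class Variant:
    """One reference/alternate difference with its coding effect."""

    ref_pos: int
    ref_allele: str
    alt_allele: str
    kind: str  # "SNP" | "deletion" | "insertion"
    effect: str = "unknown"
    aa_change: tuple[str, int, str] | None = None
    domain: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "SNP":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("SNP alleles must both have length 1")
            if self.ref_allele == self.alt_allele:
                raise ValueError("SNP alleles must differ")
        elif self.kind == "deletion":
            if self.alt_allele or not self.ref_allele:
                raise ValueError("deletion must have ref bases and empty alt")
        elif self.kind == "insertion":
            if self.ref_allele or not self.alt_allele:
                raise ValueError("insertion must have alt bases and empty ref")
        else:
            raise ValueError(f"unknown variant kind {self.kind!r}")


@dataclass
class DomainMap:
    """Annotated domains as (name, nt_start, nt_end, aa_start, aa_end), 1-based."""

    entries: list[tuple[str, int, int, int, int]]

    def __post_init__(self) -> None:
        for intervals in (
            [(s, e) for _, s, e, _, _ in self.entries],
            [(s, e) for _, _, _, s, e in self.entries],
        ):
            prev_end = 0
            for start, end in intervals:
                if start > end:
                    raise ValueError(f"domain interval {start}-{end} inverted")
                if start <= prev_end:
                    raise ValueError("domain intervals must be sorted and non-overlapping")
                prev_end = end

    def domain_for_aa(self, aa_pos: int) -> str | None:
        for name, _, _, aa_start, aa_end in self.entries:
            if aa_start <= aa_pos <= aa_end:
                return name
        return None

    def domain_for_nt(self, nt_pos: int) -> str | None:
        for name, nt_start, nt_end, _, _ in self.entries:
            if nt_start <= nt_pos <= nt_end:
                return name
        return None


# Published SSIII domain annotation.  The printed nucleotide bounds of the
# homology/catalytic regions are one base off a perfect 3x correspondence
# with the amino-acid bounds; both are kept as printed.
SSIII_DOMAINS = DomainMap(
    entries=[
        ("N-terminal", 1, 2304, 1, 768),
        ("homology", 2305, 3679, 769, 1226),
        ("catalytic", 3680, 5025, 1227, 1674),
    ]
)


def align_global(
    ref: SequenceRecord,
    alt: SequenceRecord,
    scoring: dict[str, float] | None = None,
) -> AlignmentResult:
    """Optimal global alignment of two DNA records with affine gaps.

    Default scoring: match +1, mismatch -2, gap open -6, gap extend -1
    (a length-L gap costs 6 + L).  Among equal-score alignments, gaps are
    normalized to their leftmost placement so output is deterministic.
    """
    for rec in (ref, alt):
        if rec.alphabet != "DNA":
            raise ValueError(f"align_global requires DNA records, got {rec.alphabet}")
        if not rec.residues:
            raise ValueError("cannot align empty sequence")
    if min(len(ref), len(alt)) < 0.8 * max(len(ref), len(alt)):
        raise ValueError("sequence lengths differ by more than 20%")
    params = {"match": 1.0, "mismatch": -2.0, "gap_open": -6.0, "gap_extend": -1.0}
    if scoring:
        params.update(scoring)

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params["match"]
    aligner.mismatch_score = params["mismatch"]
    # Biopython charges open_gap_score for the first gap column and
    # extend_gap_score for each further column; fold the per-base extend cost
    # into the opening column so a length-L gap costs open + L*extend.
    aligner.open_gap_score = params["gap_open"] + params["gap_extend"]
    aligner.extend_gap_score = params["gap_extend"]

    aln = aligner.align(ref.residues, alt.residues)[0]
    gapped_ref, gapped_alt = _left_normalize(aln[0], aln[1])
    return AlignmentResult(
        gapped_ref=gapped_ref,
        gapped_alt=gapped_alt,
        score=float(aln.score),
        ref_coord_map=_coord_map(gapped_ref),
    )


def _coord_map(gapped_ref: str) -> list[int]:
    """Per-column 1-based reference position (previous base for gap columns)."""
    coords = []
    pos = 0
    for char in gapped_ref:
        if char != GAP:
            pos += 1
        coords.append(pos)
    return coords


def _left_normalize(row_a: str, row_b: str) -> tuple[str, str]:
    """Shift every gap run to its leftmost score-equivalent position."""
    a, b = list(row_a), list(row_b)
    changed = True
    while changed:
        changed = False
        for gapped, other in ((b, a), (a, b)):
            i = 0
            n = len(gapped)
            while i < n:
                if gapped[i] != GAP:
                    i += 1
                    continue
                j = i
                while j < n and gapped[j] == GAP:
                    j += 1
                # shift run [i, j) left while the flanking base repeats
                while i > 0 and gapped[i - 1] != GAP and other[i - 1] == other[j - 1]:
                    gapped[i - 1], gapped[j - 1] = gapped[j - 1], gapped[i - 1]
                    i -= 1
                    j -= 1
                    changed = True
                i = j + 1
    return "".join(a), "".join(b)


def call_variants(aln: AlignmentResult) -> list[Variant]:
    """SNPs and merged indel events from an alignment, sorted by ref_pos.

    Deletions are reported at the first deleted reference base; insertions at
    the reference base after which the new bases sit (0 for an insertion
    before the first base).
    """
    variants: list[Variant] = []
    ref_pos = 0
    cols = list(zip(aln.gapped_ref, aln.gapped_alt))
    i = 0
    n = len(cols)
    while i < n:
        r, a = cols[i]
        if r != GAP and a != GAP:
            ref_pos += 1
            if r != a:
                variants.append(Variant(ref_pos, r, a, "SNP"))
            i += 1
        elif a == GAP:  # run of deleted reference bases
            start_pos = ref_pos + 1
            deleted = []
            while i < n and cols[i][1] == GAP:
                deleted.append(cols[i][0])
                ref_pos += 1
                i += 1
            variants.append(Variant(start_pos, "".join(deleted), "", "deletion"))
        else:  # run of inserted alternate bases
            inserted = []
            while i < n and cols[i][0] == GAP:
                inserted.append(cols[i][1])
                i += 1
            variants.append(Variant(ref_pos, "", "".join(inserted), "insertion"))
    return sorted(variants, key=lambda v: (v.ref_pos, v.kind))


def apply_variants(reference: str, variants: list[Variant]) -> str:
    """Rebuild the alternate sequence from the reference and a variant set.

    This is the round-trip oracle for :func:`call_variants`.
    """
    inserts: dict[int, str] = {}
    subs: dict[int, str] = {}
    deleted: set[int] = set()
    for v in variants:
        if v.kind == "insertion":
            inserts[v.ref_pos] = inserts.get(v.ref_pos, "") + v.alt_allele
        elif v.kind == "SNP":
            if reference[v.ref_pos - 1] != v.ref_allele:
                raise ValueError(f"SNP at {v.ref_pos}: reference base mismatch")
            subs[v.ref_pos] = v.alt_allele
        else:
            seg = reference[v.ref_pos - 1 : v.ref_pos - 1 + len(v.ref_allele)]
            if seg != v.ref_allele:
                raise ValueError(f"deletion at {v.ref_pos}: reference bases mismatch")
            deleted.update(range(v.ref_pos, v.ref_pos + len(v.ref_allele)))
    out = [inserts.get(0, "")]
    for pos in range(1, len(reference) + 1):
        if pos not in deleted:
            out.append(subs.get(pos, reference[pos - 1]))
        out.append(inserts.get(pos, ""))
    return "".join(out)


def translate_codon(codon: str) -> str:
    return CODON_MAP.get(codon.upper(), "X")


def translate_cds(cds: SequenceRecord, table: dict[str, str] | None = None) -> SequenceRecord:
    """Conceptual translation of a CDS; stops render as ``*``, ambiguity as ``X``."""
    if cds.alphabet != "DNA":
        raise ValueError("translate_cds requires a DNA record")
    if len(cds.residues) % 3 != 0:
        raise ValueError(f"CDS length {len(cds.residues)} not divisible by 3")
    table = table or CODON_MAP
    protein = "".join(
        table.get(cds.residues[i : i + 3], "X") for i in range(0, len(cds.residues), 3)
    )
    return SequenceRecord(
        id=cds.id, residues=protein, alphabet="PROTEIN", description=cds.description
    )


def find_longest_orf(record: SequenceRecord) -> tuple[int, int]:
    """Longest ATG..stop open reading frame on the forward strand.

    Returns (cds_offset, cds_length): the number of bases before the ATG and
    the ORF length including the stop codon.  Used to derive the CDS frame of
    an mRNA record when the annotation is not supplied.
    """
    seq = record.residues
    best = (0, 0)
    for frame in range(3):
        i = frame
        while i + 3 <= len(seq):
            if seq[i : i + 3] == "ATG":
                j = i
                while j + 3 <= len(seq):
                    codon = seq[j : j + 3]
                    if CODON_MAP.get(codon) == "*":
                        length = j + 3 - i
                        if length > best[1]:
                            best = (i, length)
                        break
                    j += 3
                # restart the scan after this ATG regardless of outcome
            i += 3
    if best[1] == 0:
        raise ValueError(f"{record.id}: no complete ORF found")
    return best


def classify_effects(
    variants: list[Variant],
    ref_cds: SequenceRecord,
    alt_cds: SequenceRecord,
    cds_offset: int = 0,
) -> list[Variant]:
    """Attach coding effects and amino-acid changes to variants.

    ``cds_offset`` is the number of reference bases before the CDS start
    (0 when the record is the CDS itself).  SNPs are silent iff the codon
    translation is unchanged; in-frame indels report the codon of their first
    affected base; indels of length not divisible by 3 are frameshifts.
    """
    ref = ref_cds.residues
    n_codons = (len(ref) - cds_offset) // 3
    cds_end = cds_offset + 3 * n_codons
    out: list[Variant] = []
    for v in variants:
        if v.kind == "SNP" and ref[v.ref_pos - 1] != v.ref_allele:
            raise ValueError(f"variant at {v.ref_pos}: reference allele mismatch")
        cds_pos = v.ref_pos - cds_offset
        if v.kind == "SNP":
            if cds_pos < 1 or v.ref_pos > cds_end:
                out.append(replace(v, effect="noncoding", aa_change=None))
                continue
            codon_idx = (cds_pos - 1) // 3
            start = cds_offset + codon_idx * 3
            ref_codon = ref[start : start + 3]
            within = (cds_pos - 1) % 3
            alt_codon = ref_codon[:within] + v.alt_allele + ref_codon[within + 1 :]
            ref_aa = translate_codon(ref_codon)
            alt_aa = translate_codon(alt_codon)
            if ref_aa == alt_aa:
                out.append(replace(v, effect="silent", aa_change=None))
            else:
                out.append(
                    replace(v, effect="missense", aa_change=(ref_aa, codon_idx + 1, alt_aa))
                )
        elif v.kind == "deletion":
            if cds_pos < 1 or v.ref_pos > cds_end:
                out.append(replace(v, effect="noncoding", aa_change=None))
            elif len(v.ref_allele) % 3 != 0:
                out.append(replace(v, effect="frameshift", aa_change=None))
            else:
                aa_change = _deletion_aa_change(ref, cds_offset, cds_pos, len(v.ref_allele))
                out.append(replace(v, effect="in_frame_deletion", aa_change=aa_change))
        else:  # insertion
            if cds_pos < 0 or v.ref_pos >= cds_end:
                out.append(replace(v, effect="noncoding", aa_change=None))
            elif len(v.alt_allele) % 3 != 0:
                out.append(replace(v, effect="frameshift", aa_change=None))
            else:
                aa_pos = cds_pos // 3 + 1
                added = "".join(
                    translate_codon(v.alt_allele[k : k + 3])
                    for k in range(0, len(v.alt_allele), 3)
                )
                out.append(
                    replace(v, effect="in_frame_insertion", aa_change=("-", aa_pos, added))
                )
    return out


def _deletion_aa_change(
    ref: str, cds_offset: int, cds_pos: int, del_len: int
) -> tuple[str, int, str]:
    """Protein-level placement of an in-frame deletion.

    A deletion that straddles a codon boundary can remove a *different*
    residue than the codon of its first deleted base suggests, so the fused
    codon is retranslated and compared against the flanking residues.
    """
    m = del_len // 3
    aa1 = (cds_pos - 1) // 3 + 1  # codon of first deleted base
    start0 = cds_offset + (aa1 - 1) * 3
    region = ref[start0 : start0 + 3 * (m + 1)]
    residues = "".join(
        translate_codon(region[k : k + 3]) for k in range(0, len(region) - 2, 3)
    )
    off = (cds_pos - 1) % 3
    fused = region[:off] + region[off + del_len :]
    if len(region) == 3 * (m + 1) and len(fused) == 3:
        fused_aa = translate_codon(fused)
        if off > 0 and fused_aa == residues[0] and fused_aa != residues[-1]:
            # the first affected codon survives; residues aa1+1..aa1+m are gone
            return (residues[1:], aa1 + 1, "-")
        return (residues[:-1], aa1, "-")
    # deletion runs into the end of the CDS; report naively
    return (residues[: max(1, m)], aa1, "-")


def assign_domains(variants: list[Variant], domain_map: DomainMap) -> list[Variant]:
    """Label each variant with its containing domain (amino-acid intervals for
    coding changes, nucleotide intervals otherwise); ``outside`` if none."""
    out = []
    for v in variants:
        if v.aa_change is not None:
            label = domain_map.domain_for_aa(v.aa_change[1])
        else:
            label = domain_map.domain_for_nt(v.ref_pos)
        out.append(replace(v, domain=label if label is not None else "outside"))
    return out


def summarize_alleles(variants: list[Variant]) -> dict[str, int]:
    """Partition counts: SNP total, silent, missense, noncoding SNPs, indels."""
    n_snps = sum(1 for v in variants if v.kind == "SNP")
    n_silent = sum(1 for v in variants if v.kind == "SNP" and v.effect == "silent")
    n_missense = sum(1 for v in variants if v.kind == "SNP" and v.effect == "missense")
    n_noncoding = sum(1 for v in variants if v.kind == "SNP" and v.effect == "noncoding")
    n_indels = sum(1 for v in variants if v.kind in ("deletion", "insertion"))
    return {
        "n_snps": n_snps,
        "n_silent": n_silent,
        "n_missense": n_missense,
        "n_noncoding": n_noncoding,
        "n_indels": n_indels,
    }


def compare_alleles(
    ref: SequenceRecord,
    alt: SequenceRecord,
    cds_offset: int = 0,
    domain_map: DomainMap | None = None,
    scoring: dict[str, float] | None = None,
) -> list[Variant]:
    """Full pairwise pipeline: align, call, classify, (optionally) label."""
    aln = align_global(ref, alt, scoring=scoring)
    variants = call_variants(aln)
    variants = classify_effects(variants, ref, alt, cds_offset=cds_offset)
    if domain_map is not None:
        variants = assign_domains(variants, domain_map)
    return variants
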