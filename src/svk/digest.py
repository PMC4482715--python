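"""IUPAC-degenerate restriction site scanning and linear digest prediction.

Sites are matched on the top strand and on the reverse complement of the
recognition pattern (both orientations of the enzyme), with duplicate start
positions collapsed.  A base with an ambiguity code in the *sequence* matches
a pattern position only if every concrete resolution of that code would
match.  Fragment lengths are top-strand segment lengths, which is what an
agarose gel resolves (double-strand fragments differ only by the overhang).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from svk.io import SequenceRecord

log = logging.getLogger("svk")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A recognition pattern and its top-strand cut offset.

    ``cut_offset_top`` is the number of site bases 5' of the cut on the top
    strand; BslI (CCNNNNN^NNGG) has offset 7.
    """

    name: str
    recognition: str
    cut_offset_top: int

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError("recognition pattern must be non-empty")
        bad = set(self.recognition.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC characters in recognition: {sorted(bad)}")
        if not 0 <= self.cut_offset_top <= len(self.recognition):
            raise ValueError("cut_offset_top must lie within the recognition site")


@dataclass
class DigestResult:
    """Top-strand cut positions (1-based, cut after that base) and fragments."""

    cut_positions: list[int]
    fragment_lengths: list[int]


def load_enzyme_table(path: str | Path | None = None) -> dict[str, RestrictionEnzyme]:
    """Load the enzyme CSV (name, recognition, cut_offset_top).

    Defaults to the table shipped with the package, which includes BslI.
    """
    if path is None:
        source = resources.files("svk").joinpath("data/enzymes.csv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    enzymes = {}
    for row in csv.DictReader(text.splitlines()):
        enzyme = RestrictionEnzyme(
            name=row["name"].strip(),
            recognition=row["recognition"].strip().upper(),
            cut_offset_top=int(row["cut_offset_top"]),
        )
        enzymes[enzyme.name] = enzyme
    return enzymes


def _match_table(pattern: str) -> np.ndarray:
    """(len(pattern), 256) bool table: table[j, ord(c)] = seq char c matches."""
    table = np.zeros((len(pattern), 256), dtype=bool)
    for j, p in enumerate(pattern.upper()):
        allowed = set(IUPAC[p])
        for code, resolutions in IUPAC.items():
            if set(resolutions) <= allowed:
                table[j, ord(code)] = True
    return table


def _scan(seq_bytes: np.ndarray, pattern: str) -> np.ndarray:
    m = len(pattern)
    n = seq_bytes.size
    if n < m:
        return np.array([], dtype=int)
    table = _match_table(pattern)
    ok = np.ones(n - m + 1, dtype=bool)
    for j in range(m):
        ok &= table[j][seq_bytes[j : n - m + 1 + j]]
    return np.flatnonzero(ok) + 1  # 1-based starts


def find_sites(seq: SequenceRecord, enzyme: RestrictionEnzyme) -> list[int]:
    """1-based start positions of recognition sites in either orientation."""
    if seq.alphabet != "DNA":
        raise ValueError("find_sites requires a DNA record")
    seq_bytes = np.frombuffer(seq.residues.upper().encode("ascii"), dtype=np.uint8)
    forward = _scan(seq_bytes, enzyme.recognition)
    rc_pattern = reverse_complement(enzyme.recognition.upper())
    if rc_pattern == enzyme.recognition.upper():
        reverse = np.array([], dtype=int)
    else:
        reverse = _scan(seq_bytes, rc_pattern)
    return sorted(set(forward.tolist()) | set(reverse.tolist()))


def digest(seq: SequenceRecord, enzyme: RestrictionEnzyme) -> DigestResult:
    """Predict linear-digest fragments from top-strand cut positions.

    Cut position = site start - 1 + cut_offset_top (the strand is cleaved
    after that base).  Cuts falling on or beyond the final base produce no
    fragment boundary; such sites are skipped with a warning.
    """
    length = len(seq.residues)
    cuts = set()
    for start in find_sites(seq, enzyme):
        cut = start - 1 + enzyme.cut_offset_top
        if 1 <= cut < length:
            cuts.add(cut)
        else:
            log.warning(
                "%s: site at %d cuts outside the sequence (position %d); skipped",
                seq.id,
                start,
                cut,
            )
    ordered = sorted(cuts)
    bounds = [0] + ordered + [length]
    fragments = [b - a for a, b in zip(bounds, bounds[1:])]
    assert sum(fragments) == length
    return DigestResult(cut_positions=ordered, fragment_lengths=fragments)


def slice_region(seq: SequenceRecord, start: int, end: int) -> SequenceRecord:
    """1-based inclusive sub-record, id suffixed with the region."""
    if not 1 <= start <= end <= len(seq.residues):
        raise ValueError(f"region {start}:{end} outside sequence of length {len(seq.residues)}")
    return SequenceRecord(
        id=f"{seq.id}:{start}-{end}",
        residues=seq.residues[start - 1 : end],
        alphabet=seq.alphabet,
        description=seq.description,
    )


def differential_sites(
    ref: SequenceRecord,
    alt: SequenceRecord,
    enzyme: RestrictionEnzyme,
    scoring: dict[str, float] | None = None,
) -> dict[str, list[int]]:
    """Sites gained/lost in the alternate allele, in reference coordinates.

    Alternate site positions are projected through the global alignment's
    coordinate map before comparison.
    """
    from svk.alleles import align_global

    aln = align_global(ref, alt, scoring=scoring)
    ref_sites = set(find_sites(ref, enzyme))

    # map alt positions -> ref positions via alignment columns
    alt_to_ref: dict[int, int] = {}
    alt_pos = 0
    for col, alt_char in enumerate(aln.gapped_alt):
        if alt_char != "-":
            alt_pos += 1
            alt_to_ref[alt_pos] = aln.ref_coord_map[col]
    alt_sites = {alt_to_ref[p] for p in find_sites(alt, enzyme)}

    return {
        "gained": sorted(alt_sites - ref_sites),
        "lost": sorted(ref_sites - alt_sites),
    }
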