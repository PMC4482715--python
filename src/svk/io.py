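"""Readers and writers for the plain-text formats used by the pipeline.

All coordinates are 1-based and inclusive on the forward strand.  CSV files
are comma-separated with a header row, UTF-8, ``.`` decimal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from svk.chains import ChainLengthDistribution

log = logging.getLogger("svk")

DNA_CHARS = set("ACGTRYSWKMBDHVN")
PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWY*X")

PHENOTYPE_COLUMNS = [
    "ril_id",
    "zpu1_allele",
    "ssiii_allele",
    "ear",
    "vitreousness",
    "pullulanase_a490",
    "onset_c",
    "max_c",
    "enthalpy",
]
# optional extra measurements consumed by the association suite when present
OPTIONAL_PHENOTYPE_COLUMNS = ["density", "hardness"]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SequenceRecord:
    """One nucleotide or protein sequence."""

    id: str
    residues: str
    alphabet: str = "DNA"  # "DNA" | "PROTEIN"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: residues must be non-empty")
        if self.alphabet not in ("DNA", "PROTEIN"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        valid = DNA_CHARS if self.alphabet == "DNA" else PROTEIN_CHARS
        bad = set(self.residues) - valid
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: illegal {self.alphabet} characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class RilRecord:
    """Genotype class plus phenotype measurements for one RIL replicate (ear)."""

    ril_id: str
    zpu1_allele: str  # "Q" | "W"
    ssiii_allele: str  # "Q" | "W"
    ear: str
    vitreousness: float = math.nan
    pullulanase_a490: float = math.nan
    onset_c: float = math.nan
    max_c: float = math.nan
    enthalpy: float = math.nan
    density: float = math.nan
    hardness: float = math.nan

    def __post_init__(self) -> None:
        for name in ("zpu1_allele", "ssiii_allele"):
            value = getattr(self, name)
            if value not in ("Q", "W"):
                raise ValueError(f"{name} must be 'Q' or 'W', got {value!r}")

    @property
    def genotype_class(self) -> str:
        """Two-letter class label, Zpu1 allele first (e.g. ``Q-W``)."""
        return f"{self.zpu1_allele}-{self.ssiii_allele}"

    @property
    def missing_fields(self) -> list[str]:
        return [
            name
            for name in PHENOTYPE_COLUMNS[4:]
            if math.isnan(getattr(self, name))
        ]


@dataclass
class RunConfig:
    """Shared run configuration for all pipeline stages."""

    seed: int = 0
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -6.0
    gap_extend: float = -1.0
    enzyme_table: str | None = None
    alpha: float = 0.05
    dp_min: int = 6
    dp_max: int = 60

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.dp_min < 1:
            raise ValueError(f"dp_min must be >= 1, got {self.dp_min}")
        if self.dp_max < self.dp_min:
            raise ValueError("dp_max must be >= dp_min")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Residues are uppercased and whitespace-stripped; record order is
    preserved.  Malformed headers or illegal characters raise
    :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    _check_fasta_lines(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            fields = title.split(None, 1)
            if not fields:
                raise ParseError(f"{path}: record with empty header")
            rec_id = fields[0]
            description = fields[1] if len(fields) > 1 else ""
            if rec_id in seen:
                raise ParseError(f"{path}: duplicate record id {rec_id!r}")
            seen.add(rec_id)
            residues = "".join(seq.split()).upper()
            try:
                records.append(
                    SequenceRecord(rec_id, residues, alphabet="DNA", description=description)
                )
            except ValueError as exc:
                raise ParseError(f"{path}: {exc}") from exc
    log.info("read_fasta: %s -> %d records", path, len(records))
    return records


def _check_fasta_lines(path: Path) -> None:
    """Line-level sanity check so errors can cite a line number."""
    with open(path) as handle:
        in_record = False
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if len(line) == 1:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                in_record = True
            else:
                if not in_record:
                    raise ParseError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                bad = set(line.upper()) - DNA_CHARS - PROTEIN_CHARS
                if bad:
                    raise ParseError(
                        f"{path}:{lineno}: illegal sequence characters {sorted(bad)!r}"
                    )


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with open(path, "w") as handle:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            handle.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i : i + width] + "\n")


def read_chain_table(path: str | Path) -> list[ChainLengthDistribution]:
    """Read a per-sample (DP, percent_area) CSV into distributions.

    Expects columns ``sample_id, ear, DP, percent_area``; rows are grouped by
    (sample_id, ear).  Duplicate DP rows within a group and negative areas are
    errors.  Percent areas are taken as given — normalization happens
    downstream.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = ["sample_id", "ear", "DP", "percent_area"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if (df["percent_area"] < 0).any():
        bad = df.loc[df["percent_area"] < 0].iloc[0]
        raise ParseError(
            f"{path}: negative percent_area for sample {bad['sample_id']!r} DP {bad['DP']}"
        )
    dup = df.duplicated(subset=["sample_id", "ear", "DP"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise ParseError(
            f"{path}: duplicate (sample_id, ear, DP) row "
            f"({bad['sample_id']!r}, {bad['ear']!r}, {bad['DP']})"
        )
    dists = []
    for (sample_id, ear), grp in df.groupby(["sample_id", "ear"], sort=False):
        grp = grp.sort_values("DP")
        dists.append(
            ChainLengthDistribution(
                sample_id=str(sample_id),
                ear=str(ear),
                points=list(zip(grp["DP"].astype(int), grp["percent_area"].astype(float))),
            )
        )
    log.info("read_chain_table: %s -> %d distributions", path, len(dists))
    return dists


def write_chain_table(dists: list[ChainLengthDistribution], path: str | Path) -> None:
    rows = [
        {"sample_id": d.sample_id, "ear": d.ear, "DP": dp, "percent_area": area}
        for d in dists
        for dp, area in d.points
    ]
    pd.DataFrame(rows, columns=["sample_id", "ear", "DP", "percent_area"]).to_csv(
        path, index=False
    )


def read_phenotypes(path: str | Path) -> list[RilRecord]:
    """Read the RIL phenotype/genotype panel CSV.

    Allele columns are restricted to {Q, W}; missing phenotype cells are
    permitted and surface as NaN (see :attr:`RilRecord.missing_fields`).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        kwargs = {
            "ril_id": str(row["ril_id"]),
            "zpu1_allele": str(row["zpu1_allele"]),
            "ssiii_allele": str(row["ssiii_allele"]),
            "ear": str(row["ear"]),
        }
        for col in PHENOTYPE_COLUMNS[4:] + OPTIONAL_PHENOTYPE_COLUMNS:
            if col in df.columns:
                value = row[col]
                kwargs[col] = float(value) if pd.notna(value) else math.nan
        try:
            records.append(RilRecord(**kwargs))
        except ValueError as exc:
            raise ParseError(f"{path}: row {row['ril_id']!r}: {exc}") from exc
    log.info("read_phenotypes: %s -> %d records", path, len(records))
    return records


def write_phenotypes(records: list[RilRecord], path: str | Path) -> None:
    cols = PHENOTYPE_COLUMNS + OPTIONAL_PHENOTYPE_COLUMNS
    rows = [{c: getattr(r, c) for c in cols} for r in records]
    df = pd.DataFrame(rows, columns=cols)
    if df[OPTIONAL_PHENOTYPE_COLUMNS].isna().all().all():
        df = df[PHENOTYPE_COLUMNS]
    df.to_csv(path, index=False)
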