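"""Peptide-level HDX table I/O, validation, and sequence utilities.

The on-disk format is a DynamX-style "cluster" CSV with one row per
peptide x charge x state x exposure x replicate centroid observation.
Canonical column names (aliases from common exports are accepted on read)::

    Protein, Start, End, Sequence, Charge, State, Exposure, Replicate, Center, RT

Coordinates are 1-based inclusive. Exposure is in seconds; 0 marks the
undeuterated control and ``inf`` the long-incubation out-exchange control.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .constants import CANONICAL_RESIDUES, PROTON_MASS
from .errors import (
    AlphabetError,
    NoDataError,
    ParseError,
    UnknownProteinError,
)

#: canonical internal column order
COLUMNS = [
    "protein",
    "start",
    "end",
    "sequence",
    "charge",
    "state",
    "exposure",
    "replicate",
    "centroid_mz",
    "retention_time",
]

#: header names used when writing (DynamX style), aligned with COLUMNS
_CSV_HEADER = [
    "Protein",
    "Start",
    "End",
    "Sequence",
    "Charge",
    "State",
    "Exposure",
    "Replicate",
    "Center",
    "RT",
]

_ALIASES = {
    "protein": {"protein"},
    "start": {"start"},
    "end": {"end"},
    "sequence": {"sequence"},
    "charge": {"charge", "z"},
    "state": {"state"},
    "exposure": {"exposure", "exposure (s)", "exposure_s"},
    "replicate": {"replicate", "file", "rep"},
    "centroid_mz": {"center", "centroid", "center mz", "centroid_mz"},
    "retention_time": {"rt", "retention time", "retention_time", "rt (min)"},
}

# optional identification-quality columns, applied as filters when present
_OPTIONAL = {
    "intensity": {"intensity", "maxintensity", "max intensity"},
    "score": {"score"},
    "fragments_per_aa": {"fragments_per_aa", "products per amino acid"},
}


@dataclass(frozen=True)
class PeptideRecord:
    """One centroid-mass observation of one peptide in one condition."""

    protein: str
    start: int
    end: int
    sequence: str
    charge: int
    state: str
    exposure: float
    replicate: int
    centroid_mz: float
    retention_time: float = float("nan")

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match "
                f"coordinates {self.start}-{self.end}"
            )
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if not self.centroid_mz > 0:
            raise ValueError("centroid m/z must be positive")


@dataclass
class ExchangeDataset:
    """All centroid observations for one or more proteins.

    Thin wrapper over a DataFrame with the canonical ``COLUMNS``; a
    ``rejected`` frame records per-row validation failures with reasons.
    """

    frame: pd.DataFrame
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["line", "reason"])
    )

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset frame missing columns: {missing}")
        self.frame = self.frame[COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_records(cls, records: Iterable[PeptideRecord]) -> "ExchangeDataset":
        rows = [
            (
                r.protein, r.start, r.end, r.sequence, r.charge, r.state,
                r.exposure, r.replicate, r.centroid_mz, r.retention_time,
            )
            for r in records
        ]
        return cls(pd.DataFrame(rows, columns=COLUMNS))

    def records(self) -> list[PeptideRecord]:
        return [PeptideRecord(**row) for row in self.frame.to_dict("records")]

    def proteins(self) -> list[str]:
        return sorted(self.frame["protein"].unique())

    def subset(self, protein: str) -> "ExchangeDataset":
        sub = self.frame[self.frame["protein"] == protein]
        if sub.empty:
            raise UnknownProteinError(protein)
        return ExchangeDataset(sub.copy())


@dataclass(frozen=True)
class CoverageMap:
    """Per-residue distinct-peptide counts for one protein."""

    protein: str
    length: int
    counts: np.ndarray  # length == protein length, counts[i] covers residue i+1

    @property
    def covered_fraction(self) -> float:
        return float(np.count_nonzero(self.counts) / self.length)


def validate_sequence(sequence: str) -> str:
    """Return ``sequence`` uppercased or raise :class:`AlphabetError`."""
    seq = sequence.upper()
    if not seq:
        raise AlphabetError("empty sequence")
    bad = set(seq) - CANONICAL_RESIDUES
    if bad:
        raise AlphabetError(f"non-canonical residues {sorted(bad)} in {sequence!r}")
    return seq


# ExPASy average residue masses (monomer minus water), Da. Average, not
# monoisotopic: centroids of unresolved isotopic envelopes are analyzed
# downstream, so the average mass is the correct theoretical reference and
# the table must be good to ~1 ppm for the 10 ppm parent-ion rule.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.01524


def average_mass(sequence: str) -> float:
    """Average (not monoisotopic) neutral mass of a peptide, Da."""
    seq = validate_sequence(sequence)
    return sum(AVERAGE_RESIDUE_MASS[a] for a in seq) + WATER_MASS


def max_exchangeable_amides(sequence: str, fast_loss: int = 1) -> int:
    """Number of backbone amides whose deuteration is observable.

    The N-terminal residue has no backbone amide proton retained through
    workup, prolines have none at all, and the first ``fast_loss`` amides
    after the N-terminus back-exchange too fast to observe.
    """
    seq = validate_sequence(sequence)
    if not 0 <= fast_loss <= 2:
        raise ValueError("fast_loss must be in 0..2")
    n = len(seq) - 1 - seq[1:].count("P") - fast_loss
    return max(n, 0)


def exchangeable_positions(sequence: str, start: int, fast_loss: int = 1) -> list[int]:
    """Absolute 1-based residue positions of observable amides.

    Residues 2..len of the peptide excluding prolines, with the first
    ``fast_loss`` of those dropped. Consistent with
    :func:`max_exchangeable_amides` by construction.
    """
    seq = validate_sequence(sequence)
    positions = [
        start + i for i in range(1, len(seq)) if seq[i] != "P"
    ]
    return positions[fast_loss:]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a {name: sequence} mapping."""
    db = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        db[rec.id] = validate_sequence(str(rec.seq))
    if not db:
        raise NoDataError(f"no sequences in {path}")
    return db


def write_fasta(db: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in db.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _canonical_columns(columns: Iterable[str]) -> dict[str, str]:
    """Map raw header names to canonical names using the alias table."""
    mapping = {}
    for raw in columns:
        key = raw.strip().lower()
        for canon, aliases in {**_ALIASES, **_OPTIONAL}.items():
            if key in aliases:
                mapping[raw] = canon
                break
    return mapping


def theoretical_mz(sequence: str, charge: int) -> float:
    """Theoretical average centroid m/z of the undeuterated peptide."""
    return (average_mass(sequence) + charge * PROTON_MASS) / charge


def read_peptide_table(
    path: str | Path,
    sequence_db: Mapping[str, str],
    *,
    max_ppm: float = 10.0,
    min_intensity: float = 3000.0,
    min_score: float = 7.5,
    min_fragments_per_aa: float = 0.3,
) -> ExchangeDataset:
    """Read and validate a cluster CSV into an :class:`ExchangeDataset`.

    Validation follows the identification acceptance rules applied upstream:
    rows are rejected (with per-row reasons, never silently) when the stated
    sequence disagrees with its coordinates, when the undeuterated parent-ion
    mass deviates more than ``max_ppm`` from the theoretical average mass, or
    when optional intensity / score / fragmentation columns fall below their
    thresholds. The ppm rule is only meaningful for undeuterated rows
    (exposure 0); deuterated rows legitimately carry extra mass.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed CSV
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    raw = raw.rename(columns=_canonical_columns(raw.columns))
    missing = [c for c in COLUMNS if c not in raw.columns and c != "retention_time"]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    if "retention_time" not in raw.columns:
        raw["retention_time"] = np.nan

    accepted, rejects = [], []
    for idx, row in raw.iterrows():
        line = idx + 2  # header is line 1
        reason = None
        try:
            protein = str(row["protein"])
            if protein not in sequence_db:
                raise UnknownProteinError(
                    f"unknown protein {protein!r} (line {line})"
                )
            start, end = int(row["start"]), int(row["end"])
            sequence = validate_sequence(str(row["sequence"]))
            charge = int(row["charge"])
            exposure = float(row["exposure"])
            mz = float(row["centroid_mz"])
        except (ValueError, TypeError) as exc:
            raise ParseError(str(exc), line=line) from exc

        ref = sequence_db[protein]
        if end > len(ref) or ref[start - 1 : end] != sequence:
            reason = "sequence-coordinate mismatch"
        elif exposure == 0.0:
            theo = average_mass(sequence)
            observed = charge * (mz - PROTON_MASS)
            if abs(observed - theo) / theo * 1e6 > max_ppm:
                reason = f"parent-ion mass error > {max_ppm} ppm"
        if reason is None and "intensity" in raw.columns:
            if float(row["intensity"]) < min_intensity:
                reason = f"intensity < {min_intensity}"
        if reason is None and "score" in raw.columns:
            if float(row["score"]) < min_score:
                reason = f"score < {min_score}"
        if reason is None and "fragments_per_aa" in raw.columns:
            if float(row["fragments_per_aa"]) < min_fragments_per_aa:
                reason = f"fragmentation products per residue < {min_fragments_per_aa}"

        if reason is None:
            accepted.append(
                (
                    protein, start, end, sequence, charge, str(row["state"]),
                    exposure, int(row["replicate"]), mz,
                    float(row["retention_time"]),
                )
            )
        else:
            rejects.append((line, reason))

    frame = pd.DataFrame(accepted, columns=COLUMNS)
    rejected = pd.DataFrame(rejects, columns=["line", "reason"])
    dataset = ExchangeDataset(frame, rejected)
    # stable grouping order: peptide identity, then condition
    dataset.frame = dataset.frame.sort_values(
        ["protein", "start", "end", "sequence", "state", "exposure", "replicate", "charge"],
        kind="mergesort",
    ).reset_index(drop=True)
    return dataset


def write_peptide_table(
    dataset: ExchangeDataset, path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    """Write a dataset back to cluster CSV (the exact format read back)."""
    buf = io.StringIO()
    for line in header_lines:
        buf.write(f"# {line}\n")
    out = dataset.frame.copy()
    out.columns = _CSV_HEADER
    out.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def write_rejection_log(dataset: ExchangeDataset, path: str | Path) -> None:
    dataset.rejected.to_csv(path, sep="\t", index=False)


def distinct_peptides(dataset: ExchangeDataset, protein: str) -> pd.DataFrame:
    """Distinct (start, end, sequence) peptides for a protein; charge ignored."""
    sub = dataset.frame[dataset.frame["protein"] == protein]
    if sub.empty:
        raise UnknownProteinError(protein)
    return (
        sub[["start", "end", "sequence"]]
        .drop_duplicates()
        .sort_values(["start", "end"], kind="mergesort")
        .reset_index(drop=True)
    )


def coverage_map(
    dataset: ExchangeDataset, protein: str, protein_length: int
) -> CoverageMap:
    """Per-residue count of distinct peptides spanning each residue."""
    peps = distinct_peptides(dataset, protein)
    counts = np.zeros(protein_length, dtype=int)
    for start, end in zip(peps["start"], peps["end"]):
        counts[start - 1 : end] += 1
    return CoverageMap(protein=protein, length=protein_length, counts=counts)
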