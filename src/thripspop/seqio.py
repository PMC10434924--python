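"""Sequence and metadata I/O, primer trimming, and alignment QC.

The barcode analyses downstream all operate on a fixed 434-nt window of the
mitochondrial COI gene.  This module reads FASTA and tab-separated metadata,
trims PCR primers off raw amplicons, cuts the analysis window, and applies the
end-missing QC rule (records missing more than five nucleotides at either end
of the window are discarded; up to five are kept and handled later by
pairwise deletion).
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

#: IUPAC nucleotide codes mapped to the set of bases they stand for.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

#: Characters treated as missing data in distance computations.
MISSING_CHARS = frozenset("-N") | {c for c, s in IUPAC.items() if len(s) > 1}

VALID_CHARS = frozenset(IUPAC) | {"-"}

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")

#: The published analysis window on the COI gene: 1-based, start-inclusive,
#: end-exclusive, so that (341, 775) spans exactly 434 nucleotides.
BARCODE_WINDOW = (341, 775)
BARCODE_LENGTH = 434

METADATA_COLUMNS = ["sample_id", "location", "latitude", "longitude", "date", "host"]


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclasses.dataclass
class SequenceRecord:
    """One individual's COI fragment plus sample passport data."""

    id: str
    nucleotides: str
    location: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    date: str | None = None
    host: str | None = None

    def __post_init__(self) -> None:
        self.nucleotides = self.nucleotides.upper()
        if not self.nucleotides:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.nucleotides) - VALID_CHARS
        if bad:
            raise ValueError(f"record {self.id!r}: non-IUPAC characters {sorted(bad)}")
        if self.latitude is not None and not -90 <= self.latitude <= 90:
            raise ValueError(f"record {self.id!r}: latitude {self.latitude} out of range")
        if self.longitude is not None and not -180 <= self.longitude <= 180:
            raise ValueError(f"record {self.id!r}: longitude {self.longitude} out of range")

    def __len__(self) -> int:
        return len(self.nucleotides)


@dataclasses.dataclass
class Alignment:
    """An ordered set of equal-length records."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.records}
        if len(lengths) > 1:
            raise ValueError(f"records have unequal lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.records[0]) if self.records else 0

    def __len__(self) -> int:
        return len(self.records)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (sequences uppercased).

    Raises ValueError naming the offending line for files whose first
    non-blank content is not a FASTA header, and on duplicate record ids.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}:{lineno}: not FASTA (expected '>' header, got {line[:20]!r})"
                    )
                break
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, nucleotides=str(rec.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.nucleotides
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, location, latitude, longitude,
    date, host); unknown extra columns are preserved."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "location": str})
    missing = [c for c in ("sample_id", "location") if c not in df.columns]
    if missing:
        raise ValueError(f"metadata {path}: missing required columns {missing}")
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def attach_metadata(records: list[SequenceRecord], metadata: pd.DataFrame) -> list[SequenceRecord]:
    """Fill location / coordinate / date / host fields from a metadata table."""
    by_id = metadata.set_index("sample_id")
    out = []
    for rec in records:
        if rec.id in by_id.index:
            row = by_id.loc[rec.id]
            rec = dataclasses.replace(
                rec,
                location=row.get("location"),
                latitude=_opt_float(row.get("latitude")),
                longitude=_opt_float(row.get("longitude")),
                date=_opt_str(row.get("date")),
                host=_opt_str(row.get("host")),
            )
        out.append(rec)
    return out


def _opt_float(x):
    return None if x is None or pd.isna(x) else float(x)


def _opt_str(x):
    return None if x is None or pd.isna(x) else str(x)


def _iupac_match(a: str, b: str) -> bool:
    """True if template base `a` is compatible with primer code `b`."""
    return IUPAC.get(a, frozenset()) <= IUPAC.get(b, frozenset())


def _best_site(template: str, primer: str, max_mismatch: int) -> int | None:
    """Offset of the best primer site within mismatch budget, or None.

    Exhaustive ambiguity-aware sliding-window scan; ties go to the leftmost
    site with the fewest mismatches.
    """
    best, best_mm = None, max_mismatch + 1
    for off in range(len(template) - len(primer) + 1):
        mm = sum(
            not _iupac_match(template[off + k], primer[k]) for k in range(len(primer))
        )
        if mm < best_mm:
            best, best_mm = off, mm
    return best


class TrimResult(NamedTuple):
    record: SequenceRecord
    fwd_found: bool
    rev_found: bool


def trim_primers(
    record: SequenceRecord, fwd_primer: str, rev_primer: str, max_mismatch: int = 1
) -> TrimResult:
    """Remove forward and reverse primer footprints from an amplicon.

    Both primers are given 5'->3'; the reverse primer is matched as its
    reverse complement on the template.  If either primer is not found within
    ``max_mismatch``, the sequence is returned unchanged for that end and the
    corresponding flag is False.
    """
    seq = record.nucleotides
    if len(fwd_primer) > len(seq) or len(rev_primer) > len(seq):
        raise ValueError(f"record {record.id!r}: primer longer than sequence")
    fwd_primer, rev_primer = fwd_primer.upper(), rev_primer.upper()
    fwd_off = _best_site(seq, fwd_primer, max_mismatch)
    rev_rc = reverse_complement(rev_primer)
    rev_off = _best_site(seq, rev_rc, max_mismatch)
    start = fwd_off + len(fwd_primer) if fwd_off is not None else 0
    end = rev_off if rev_off is not None else len(seq)
    if start >= end:  # primers overlap or mis-ordered: leave untouched
        return TrimResult(record, False, False)
    trimmed = dataclasses.replace(record, nucleotides=seq[start:end])
    return TrimResult(trimmed, fwd_off is not None, rev_off is not None)


def window_trim(
    seq: str, start: int, end: int, coordinate_convention: str = "one_based_half_open"
) -> str:
    """Cut a coordinate window out of a sequence.

    ``one_based_half_open`` (the default) means 1-based, start-inclusive,
    end-exclusive: window (341, 775) yields 434 nt.  ``one_based_closed``
    includes both endpoints.
    """
    if coordinate_convention == "one_based_half_open":
        lo, hi = start - 1, end - 1
    elif coordinate_convention == "one_based_closed":
        lo, hi = start - 1, end
    else:
        raise ValueError(f"unknown coordinate convention {coordinate_convention!r}")
    if not lo < hi:
        raise ValueError(f"empty or inverted window ({start}, {end})")
    if lo < 0 or hi > len(seq):
        raise ValueError(f"window ({start}, {end}) outside sequence of length {len(seq)}")
    return seq[lo:hi]


def _end_missing(seq: str) -> tuple[int, int]:
    lead = len(seq) - len(seq.lstrip("-N"))
    trail = len(seq) - len(seq.rstrip("-N"))
    return lead, trail


def qc_filter(
    records: Iterable[SequenceRecord], window_len: int = BARCODE_LENGTH, max_end_missing: int = 5
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Discard records missing more than ``max_end_missing`` nucleotides at
    the beginning or the end of the window; keep everything else."""
    kept, discarded = [], []
    for rec in records:
        if len(rec) != window_len:
            raise ValueError(
                f"record {rec.id!r}: length {len(rec)} != window length {window_len}"
            )
        lead, trail = _end_missing(rec.nucleotides)
        if lead > max_end_missing or trail > max_end_missing:
            discarded.append(rec)
        else:
            kept.append(rec)
    return kept, discarded
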