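"""Haplotype collapsing, naming, and variable-site profiling.

Individuals sharing an identical COI fragment share a haplotype.  Collapsing
turns a set of aligned records into a table of unique sequences with counts
and frequencies; shared haplotypes are named H1, H2, ... in descending
frequency and singletons HU<k> continuing the numbering, mirroring common
barcoding practice.  The variable-site profile is the compact dot-notation
table (one column per polymorphic alignment position, '.' meaning identical
to the reference haplotype) that such surveys publish.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .seqio import MISSING_CHARS, SequenceRecord

RESOLVED = frozenset("ACGT")


@dataclasses.dataclass
class Haplotype:
    name: str
    sequence: str
    member_ids: list[str]
    count: int
    frequency: float

    def __post_init__(self) -> None:
        if self.count != len(self.member_ids) or self.count < 1:
            raise ValueError(f"haplotype {self.name!r}: count/member mismatch")


@dataclasses.dataclass
class HaplotypeTable:
    haplotypes: list[Haplotype]

    def __iter__(self):
        return iter(self.haplotypes)

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __getitem__(self, name: str) -> Haplotype:
        for h in self.haplotypes:
            if h.name == name:
                return h
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [h.name for h in self.haplotypes]

    @property
    def n_records(self) -> int:
        return sum(h.count for h in self.haplotypes)

    def sequences(self) -> dict[str, str]:
        return {h.name: h.sequence for h in self.haplotypes}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [h.name for h in self.haplotypes],
                "count": [h.count for h in self.haplotypes],
                "frequency": [h.frequency for h in self.haplotypes],
                "sequence": [h.sequence for h in self.haplotypes],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _compatible(a: str, b: str) -> bool:
    """True if two sequences agree at every mutually resolved site."""
    return all(
        x == y or x in MISSING_CHARS or y in MISSING_CHARS for x, y in zip(a, b)
    )


def collapse(records: Iterable[SequenceRecord], missing_policy: str = "strict") -> HaplotypeTable:
    """Group aligned records into haplotypes.

    ``strict`` (default): records share a haplotype iff their sequences are
    string-identical.  ``merge``: a record joins the first existing cluster it
    is compatible with (identical at all mutually non-missing sites); the
    cluster keeps the most-resolved sequence seen so far.
    """
    records = list(records)
    if not records:
        return HaplotypeTable([])
    lengths = {len(r) for r in records}
    if len(lengths) > 1:
        raise ValueError(f"unaligned input: lengths {sorted(lengths)}")
    clusters: list[tuple[str, list[str]]] = []  # (representative sequence, member ids)
    if missing_policy == "strict":
        index: dict[str, int] = {}
        for rec in records:
            k = index.get(rec.nucleotides)
            if k is None:
                index[rec.nucleotides] = len(clusters)
                clusters.append((rec.nucleotides, [rec.id]))
            else:
                clusters[k][1].append(rec.id)
    elif missing_policy == "merge":
        for rec in records:
            for k, (rep, ids) in enumerate(clusters):
                if _compatible(rep, rec.nucleotides):
                    merged = "".join(
                        y if x in MISSING_CHARS else x for x, y in zip(rep, rec.nucleotides)
                    )
                    clusters[k] = (merged, ids + [rec.id])
                    break
            else:
                clusters.append((rec.nucleotides, [rec.id]))
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    n = len(records)
    haps = [
        Haplotype(name=f"hap{k+1}", sequence=seq, member_ids=ids, count=len(ids),
                  frequency=len(ids) / n)
        for k, (seq, ids) in enumerate(clusters)
    ]
    return HaplotypeTable(haps)


def name_haplotypes(table: HaplotypeTable) -> HaplotypeTable:
    """Assign H/HU names: shared haplotypes H1..Hm in descending count (ties
    by first occurrence in input order), then singletons HU(m+1).. in input
    order.  Deterministic for a fixed input order."""
    order = list(range(len(table.haplotypes)))
    shared = sorted(
        (k for k in order if table.haplotypes[k].count > 1),
        key=lambda k: (-table.haplotypes[k].count, k),
    )
    singles = [k for k in order if table.haplotypes[k].count == 1]
    renamed: list[Haplotype | None] = [None] * len(order)
    for rank, k in enumerate(shared, start=1):
        renamed[k] = dataclasses.replace(table.haplotypes[k], name=f"H{rank}")
    for rank, k in enumerate(singles, start=len(shared) + 1):
        renamed[k] = dataclasses.replace(table.haplotypes[k], name=f"HU{rank}")
    return HaplotypeTable([h for h in renamed if h is not None])


@dataclasses.dataclass
class VariableSiteTable:
    """Dot-notation profile of the polymorphic alignment columns."""

    reference_name: str
    positions: list[int]  # sorted, 1-based
    states: dict[str, dict[int, str]]  # haplotype -> {position: base}; '.' implied

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for name, sub in self.states.items():
            if name == self.reference_name:
                rows[name] = [sub[p] for p in self.positions]
            else:
                rows[name] = [sub.get(p, ".") for p in self.positions]
        return pd.DataFrame.from_dict(rows, orient="index", columns=self.positions)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "haplotype"
        df.to_csv(path, sep="\t")


def variable_sites(table: HaplotypeTable, reference: str) -> VariableSiteTable:
    """Columns where at least two resolved states occur among haplotypes."""
    seqs = table.sequences()
    if reference not in seqs:
        raise KeyError(f"reference haplotype {reference!r} not in table")
    length = len(seqs[reference])
    positions = []
    for i in range(length):
        col = {s[i] for s in seqs.values()} & RESOLVED
        if len(col) > 1:
            positions.append(i + 1)
    ref_seq = seqs[reference]
    states: dict[str, dict[int, str]] = {}
    for name, seq in seqs.items():
        if name == reference:
            states[name] = {p: ref_seq[p - 1] for p in positions}
        else:
            states[name] = {
                p: seq[p - 1] for p in positions if seq[p - 1] != ref_seq[p - 1]
            }
    return VariableSiteTable(reference_name=reference, positions=positions, states=states)


def reconstruct(vst: VariableSiteTable, reference_sequence: str) -> dict[str, str]:
    """Rebuild full sequences from a variable-site profile and the reference
    haplotype's full sequence; inverse of :func:`variable_sites`."""
    out = {}
    for name, sub in vst.states.items():
        seq = list(reference_sequence)
        for pos, base in sub.items():
            seq[pos - 1] = base
        out[name] = "".join(seq)
    return out


def sequences_from_profile(
    profile: Mapping[str, Mapping[int, str]],
    reference_name: str,
    background: str,
) -> dict[str, str]:
    """Expand a dot-notation profile onto an arbitrary background sequence.

    ``profile[reference_name]`` must give the reference base at every listed
    position; other haplotypes list only their deviations.  Conflicting
    duplicate states raise ValueError.  Pairwise differences between the
    returned sequences depend only on the profile, not on the background.
    """
    ref_states = profile[reference_name]
    seq = list(background)
    for pos, base in ref_states.items():
        seq[pos - 1] = base
    reference_sequence = "".join(seq)
    out = {}
    for name, sub in profile.items():
        seq = list(reference_sequence)
        for pos, base in sub.items():
            if pos not in ref_states:
                raise ValueError(f"{name}: position {pos} not in reference profile")
            seq[pos - 1] = base
        out[name] = "".join(seq)
    return out
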