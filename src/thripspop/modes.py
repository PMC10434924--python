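"""In-silico PCR and reproductive-mode calling.

The wet assay uses one universal reverse primer and two forward primers, one
per mitochondrial lineage: the thelytoky-specific primer yields a 451-nt
product, the arrhenotoky-specific primer a 261-nt product, and heteroplasmic
individuals (carrying both mitotypes) show both bands at once.  The two
products overlap: the arrhenotokous fragment corresponds to the tail of the
thelytokous one, and a T insertion inside the thelytokous lineage destroys
the arrhenotoky primer site there, which is why a pure thelytokous template
can never produce the 261-nt band.

This module emulates that assay: IUPAC-aware primer matching, amplicon
enumeration, fragment-pattern interpretation, and the phylogenetic fallback
for heteroplasmic calls (group 1 = thelytokous, group 2 = arrhenotokous).
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

from .seqio import IUPAC, reverse_complement

THELYTOKOUS_LENGTH = 451
ARRHENOTOKOUS_LENGTH = 261
KNOWN_LENGTHS = (THELYTOKOUS_LENGTH, ARRHENOTOKOUS_LENGTH)


@dataclasses.dataclass(frozen=True)
class Primer:
    name: str
    sequence: str  # 5'->3', IUPAC alphabet
    role: str  # universal_forward / universal_reverse / thelytoky_specific / arrhenotoky_specific

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"primer {self.name!r}: empty sequence")
        bad = set(self.sequence.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"primer {self.name!r}: non-IUPAC characters {sorted(bad)}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


# the published primer set
MTD7_2F = Primer("MTD7.2F", "ATTAGGAGCHCCHGAYATAGCATT", "universal_forward")
MTD9_2R = Primer("MTD9.2R", "CAGGCAAGATTAAAATATAAACTTCTG", "universal_reverse")
TCOR = Primer("TCOR", "ATTGCGTAAATTATTCCTAAAAGTCCA", "universal_reverse")
TCOS = Primer("TCOS", "AACAGCTATTCTCCTTCTTTATCTC", "arrhenotoky_specific")
TCOC = Primer("TCOC", "GAACAGTATATCCACCTTTATCAACG", "thelytoky_specific")

MODE_PRIMERS = (TCOC, TCOS, TCOR)

_ROLE_BY_NAME = {p.name: p.role for p in (MTD7_2F, MTD9_2R, TCOR, TCOS, TCOC)}


def read_primer_file(path: str | Path) -> list[Primer]:
    """Plain-text primer file: name<TAB>sequence(5'->3')<TAB>orientation(F|R)."""
    primers = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3 or parts[2] not in ("F", "R"):
                raise ValueError(f"{path}:{lineno}: expected name<TAB>seq<TAB>F|R")
            name, seq, orient = parts
            role = _ROLE_BY_NAME.get(
                name, "universal_forward" if orient == "F" else "universal_reverse"
            )
            primers.append(Primer(name, seq, role))
    return primers


def write_primer_file(primers: Iterable[Primer], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in primers:
            orient = "R" if "reverse" in p.role else "F"
            fh.write(f"{p.name}\t{p.sequence}\t{orient}\n")


def match_primer(template: str, primer: str | Primer, max_mismatch: int = 0,
                 strand: str = "+") -> list[int]:
    """0-based offsets of primer binding-site 5' footprints on the template.

    Matching is IUPAC-aware (primer code H matches template A, C or T, etc.);
    ``strand='-'`` searches for the primer's reverse complement on the given
    (plus-strand) template, returning footprint start offsets on that strand.
    """
    seq = primer.sequence if isinstance(primer, Primer) else primer.upper()
    template = template.upper()
    if len(seq) >= len(template):
        raise ValueError("primer not shorter than template")
    if strand == "-":
        seq = reverse_complement(seq)
    elif strand != "+":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    hits = []
    for off in range(len(template) - len(seq) + 1):
        mm = 0
        for k, code in enumerate(seq):
            if not IUPAC.get(template[off + k], frozenset("?")) <= IUPAC.get(code, frozenset()):
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            hits.append(off)
    return hits


class Amplicon(NamedTuple):
    fwd_primer: str
    rev_primer: str
    length: int
    start: int  # 0-based offset of the forward primer's 5' end


@dataclasses.dataclass
class AmpliconResult:
    template_id: str
    amplicons: list[Amplicon]

    @property
    def lengths(self) -> frozenset[int]:
        return frozenset(a.length for a in self.amplicons)


def in_silico_pcr(
    template: str,
    fwd_primers: Iterable[Primer],
    rev_primer: Primer,
    max_mismatch: int = 0,
    max_amplicon: int = 2000,
    template_id: str = "",
) -> AmpliconResult:
    """Enumerate products of a multiplex PCR on one template.

    Amplicon length follows the gel-observed convention: from the forward
    primer's 5' end through the reverse primer's 5' end inclusive, i.e. both
    primer footprints are part of the product.
    """
    rev_sites = match_primer(template, rev_primer, max_mismatch, strand="-")
    amplicons = []
    for fwd in fwd_primers:
        for f in match_primer(template, fwd, max_mismatch, strand="+"):
            for r in rev_sites:
                end = r + len(rev_primer)  # 5' end of the reverse primer on its strand
                length = end - f
                if f + len(fwd) <= r and length <= max_amplicon:
                    amplicons.append(Amplicon(fwd.name, rev_primer.name, length, f))
    return AmpliconResult(template_id, amplicons)


def classify_lengths(lengths: Iterable[int], tolerance: int = 0) -> frozenset[int]:
    """Snap observed amplicon lengths to the canonical 451/261 within a
    gel-resolution tolerance; unknown lengths are dropped."""
    pattern = set()
    for ln in lengths:
        for canon in KNOWN_LENGTHS:
            if abs(ln - canon) <= tolerance:
                pattern.add(canon)
    return frozenset(pattern)


@dataclasses.dataclass
class ModeCall:
    haplotype: str
    fragment_pattern: frozenset[int]
    raw_call: str  # thelytokous / arrhenotokous / heteroplasmic / undetermined
    resolved_mode: str  # thelytokous / arrhenotokous / undetermined
    resolution_source: str  # fragment / phylogeny / none


def call_mode(fragment_pattern: Iterable[int], group: str,
              haplotype: str = "") -> ModeCall:
    """Interpret a fragment pattern, resolving heteroplasmy by phylogeny.

    {451} -> thelytokous, {261} -> arrhenotokous (both from the fragment
    itself); {451, 261} -> heteroplasmic, resolved thelytokous for group 1
    and arrhenotokous for group 2 (undetermined if ungrouped); {} ->
    undetermined.
    """
    pattern = frozenset(fragment_pattern)
    unknown = pattern - set(KNOWN_LENGTHS)
    if unknown:
        raise ValueError(f"unknown fragment length(s) {sorted(unknown)} in pattern")
    if pattern == frozenset({THELYTOKOUS_LENGTH}):
        return ModeCall(haplotype, pattern, "thelytokous", "thelytokous", "fragment")
    if pattern == frozenset({ARRHENOTOKOUS_LENGTH}):
        return ModeCall(haplotype, pattern, "arrhenotokous", "arrhenotokous", "fragment")
    if pattern == frozenset(KNOWN_LENGTHS):
        resolved = {"group1": "thelytokous", "group2": "arrhenotokous"}.get(
            group, "undetermined"
        )
        source = "phylogeny" if resolved != "undetermined" else "none"
        return ModeCall(haplotype, pattern, "heteroplasmic", resolved, source)
    return ModeCall(haplotype, pattern, "undetermined", "undetermined", "none")


def type_template_set(
    templates: Iterable[str],
    group: str,
    haplotype: str = "",
    max_mismatch: int = 0,
    tolerance: int = 0,
) -> ModeCall:
    """Run the mode assay over an individual's mitotype templates and call
    the mode from the union of observed fragment lengths."""
    lengths: set[int] = set()
    for k, tmpl in enumerate(templates):
        res = in_silico_pcr(tmpl, (TCOC, TCOS), TCOR, max_mismatch,
                            template_id=f"{haplotype}.{k}")
        lengths |= set(res.lengths)
    return call_mode(classify_lengths(lengths, tolerance), group, haplotype)


def heteroplasmy_summary(
    fragment_patterns: Mapping[str, frozenset[int]], groups: Mapping[str, str]
) -> dict[str, int | None]:
    """Percentage of heteroplasmic haplotypes per group, rounded to integer
    percent; None for empty groups."""
    if set(fragment_patterns) != set(groups):
        raise ValueError("fragment patterns and groups cover different haplotypes")
    tallies: dict[str, list[bool]] = {}
    for hap, grp in groups.items():
        tallies.setdefault(grp, []).append(
            fragment_patterns[hap] == frozenset(KNOWN_LENGTHS)
        )
    return {
        grp: (round(100 * sum(v) / len(v)) if v else None)
        for grp, v in tallies.items()
    }


def mode_calls_frame(calls: Iterable[ModeCall], groups: Mapping[str, str]):
    import pandas as pd

    rows = []
    for c in calls:
        rows.append({
            "haplotype": c.haplotype,
            "fragment_pattern": ",".join(str(x) for x in sorted(c.fragment_pattern)) or "none",
            "raw_call": c.raw_call,
            "group": groups.get(c.haplotype, "ungrouped"),
            "resolved_mode": c.resolved_mode,
        })
    return pd.DataFrame(rows)
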