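"""Bundled reference panel: the 58 published onion-thrips COI haplotypes.

A worldwide survey of Thrips tabaci on Allium crops published its 58 COI
haplotypes as a variable-site table: 52 polymorphic positions over the
434-nt barcode fragment, with each haplotype's frequency among the 545
T. tabaci individuals sequenced, its reproductive-mode PCR fragment pattern
(451 nt = thelytokous assay, 261 nt = arrhenotokous assay, both = heteroplasmic,
none = no amplification), and its mitochondrial lineage (phylogenetic group).
This module reconstructs full-length haplotype sequences from that table on a
seeded invariant background; because haplotypes only differ at the listed
positions, all pairwise distances are independent of the background choice.

Also bundled: the survey's 14 sampling sites with decimal coordinates, and
the two per-location haplotype compositions printed in the survey's main
text (the only ones available without its supplementary material).
"""
from __future__ import annotations

from importlib.resources import files
from typing import NamedTuple

import numpy as np
import pandas as pd

from .haplotypes import Haplotype, HaplotypeTable, sequences_from_profile
from .seqio import BARCODE_LENGTH

N_INDIVIDUALS = 545  # T. tabaci individuals behind the published frequencies
REFERENCE_HAPLOTYPE = "H1"


def _data(name: str):
    return files("thripspop") / "data" / name


def load_variable_sites() -> pd.DataFrame:
    """The raw panel table: dot-notation states, frequency, fragments, group."""
    return pd.read_csv(_data("haplotype_variable_sites.tsv"), sep="\t", dtype=str)


def panel_positions(df: pd.DataFrame | None = None) -> list[int]:
    df = load_variable_sites() if df is None else df
    return [int(c) for c in df.columns if c.isdigit()]


def panel_profile() -> dict[str, dict[int, str]]:
    """Dot-notation profile keyed by haplotype name (reference fully listed)."""
    df = load_variable_sites()
    positions = panel_positions(df)
    profile: dict[str, dict[int, str]] = {}
    for _, row in df.iterrows():
        name = row["haplotype"]
        if name == REFERENCE_HAPLOTYPE:
            profile[name] = {p: row[str(p)] for p in positions}
        else:
            profile[name] = {
                p: row[str(p)] for p in positions if row[str(p)] != "."
            }
    return profile


def fragment_patterns() -> dict[str, frozenset[int]]:
    """Reproductive-mode PCR fragment pattern per haplotype."""
    df = load_variable_sites()
    out = {}
    for _, row in df.iterrows():
        frag = row["fragments"]
        out[row["haplotype"]] = (
            frozenset() if frag == "none"
            else frozenset(int(x) for x in frag.split(","))
        )
    return out


def groups() -> dict[str, str]:
    df = load_variable_sites()
    return dict(zip(df["haplotype"], df["group"]))


def _background(seed: int, length: int = BARCODE_LENGTH, at_fraction: float = 0.7) -> str:
    """Seeded AT-rich invariant background resembling insect mtDNA."""
    rng = np.random.default_rng(seed)
    p_at = at_fraction / 2.0
    p_gc = (1.0 - at_fraction) / 2.0
    return "".join(rng.choice(list("ATGC"), size=length,
                              p=[p_at, p_at, p_gc, p_gc]))


def reconstruct_panel(background_seed: int = 0) -> HaplotypeTable:
    """Rebuild all 58 full 434-nt haplotype sequences with counts/frequencies.

    Counts are the published frequencies resolved against the 545 sequenced
    individuals (they sum to exactly 545); frequencies are recomputed from
    the counts so they sum to 1.
    """
    df = load_variable_sites()
    profile = panel_profile()
    seqs = sequences_from_profile(profile, REFERENCE_HAPLOTYPE,
                                  _background(background_seed))
    haps = []
    counts = {row["haplotype"]: round(float(row["frequency"]) * N_INDIVIDUALS)
              for _, row in df.iterrows()}
    total = sum(counts.values())
    for _, row in df.iterrows():
        name = row["haplotype"]
        c = counts[name]
        haps.append(Haplotype(
            name=name, sequence=seqs[name],
            member_ids=[f"{name}.{k+1}" for k in range(c)],
            count=c, frequency=c / total,
        ))
    return HaplotypeTable(haps)


def sampling_sites() -> pd.DataFrame:
    """The 14 sampling sites: location, country, decimal latitude/longitude."""
    return pd.read_csv(_data("sampling_sites.tsv"), sep="\t")


def population_compositions() -> dict[str, dict[str, int]]:
    """Per-location haplotype counts printed in the survey's main text.

    Only two locations have their full composition in the main text: one
    fixed for H1 (33 individuals) and one with a single-step mutant of H1
    (32 x H1 + 1 x HU40).  The remaining compositions live in supplementary
    material and are not bundled.
    """
    return {
        "Tulancingo de Bravo": {"H1": 33},
        "Huron": {"H1": 32, "HU40": 1},
    }


class ReferenceFixture(NamedTuple):
    haplotypes: HaplotypeTable
    fragment_patterns: dict[str, frozenset[int]]
    groups: dict[str, str]
    populations: dict[str, dict[str, int]]
    sites: pd.DataFrame


def build_reference_fixture(background_seed: int = 0) -> ReferenceFixture:
    """Deterministic in-package fixture reproducing the published panel."""
    return ReferenceFixture(
        haplotypes=reconstruct_panel(background_seed),
        fragment_patterns=fragment_patterns(),
        groups=groups(),
        populations=population_compositions(),
        sites=sampling_sites(),
    )
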