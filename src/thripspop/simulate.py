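"""Synthetic geo-referenced barcode populations.

The generator emulates the statistical structure of a worldwide onion-thrips
COI survey so every analysis stage is testable without downloads:

* two mitochondrial lineage groups whose core sequences differ at a fixed
  number of sites (13 by default) over the 434-nt barcode;
* sparse Poisson private mutations within groups;
* per-location compositions of reproductive modes (thelytokous individuals
  carry group-1 barcodes, arrhenotokous group-2, heteroplasmic individuals a
  template set with both mitotypes);
* a mode-assay region downstream of the barcode carrying the three PCR
  primer sites with the published product geometry: the thelytoky-specific
  product spans 451 nt, the arrhenotoky-specific product the 261-nt tail of
  the same region, and the thelytokous mitotype carries a T insertion inside
  the arrhenotoky primer site, so a pure thelytokous template can never
  yield the 261-nt band;
* sampling sites with decimal coordinates (the bundled survey sites by
  default), 33 individuals per site with one smaller 16-individual sample;
* optionally, isolation by distance: population cores drift along a spatial
  transect so genetic and geographic distances correlate.

All randomness flows from one seeded generator; identical configs give
byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import reference
from .modes import TCOC, TCOR, TCOS
from .seqio import BARCODE_LENGTH, SequenceRecord, reverse_complement, write_fasta

BASES = np.array(list("ACGT"))

ASSAY_LENGTH = 451  # thelytoky-specific product
ARRHENO_OFFSET = 190  # arrhenotoky primer site start within the assay region
SPACER_LENGTH = 20

MODES = ("thelytokous", "arrhenotokous", "heteroplasmic", "undetermined")

#: Default per-location mode fractions: a third of sites carry the
#: thelytokous lineage only (as the survey's five fixed populations did); the
#: rest host both lineages in sympatry with some heteroplasmy.
PURE_THELYTOKOUS = (1.0, 0.0, 0.0, 0.0)
SYMPATRIC = (0.6, 0.25, 0.15, 0.0)


@dataclasses.dataclass
class SimConfig:
    seed: int = 0
    n_locations: int = 14
    n_per_location: int = 33
    #: (location index, n): one smaller sample, mirroring the survey's single
    #: 16-individual collection.
    small_sample: tuple[int, int] | None = (6, 16)
    group_core_divergence: int = 13
    within_group_mutation_rate: float = 0.003  # per site, per individual
    #: per-location (thelytokous, arrhenotokous, heteroplasmic, undetermined)
    #: fractions; None selects the defaults above.
    mode_composition: Mapping[int, tuple] | tuple | None = None
    geography: str = "panmictic"  # or "isolation_by_distance"
    interspecific_contaminant_fraction: float = 0.0
    #: probability a heteroplasmic individual carries a group-2 barcode
    heteroplasmic_group2_prob: float = 0.8
    #: core-sequence drift along the transect under isolation by distance
    ibd_mutations_per_1000km: float = 3.0
    at_fraction: float = 0.7  # insect mtDNA is AT-rich

    def __post_init__(self) -> None:
        if not 0 <= self.within_group_mutation_rate <= 1:
            raise ValueError("mutation rate must be in [0, 1]")
        if not 0 <= self.interspecific_contaminant_fraction <= 1:
            raise ValueError("contaminant fraction must be in [0, 1]")
        if not 0 < self.group_core_divergence <= BARCODE_LENGTH:
            raise ValueError("core divergence must be in (0, 434]")
        if self.geography not in ("panmictic", "isolation_by_distance"):
            raise ValueError(f"unknown geography {self.geography!r}")
        for frac in self._compositions().values():
            arr = np.asarray(frac, dtype=float)
            if arr.shape != (4,) or (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"mode fractions must be 4 non-negatives summing to 1, got {frac}")

    def _compositions(self) -> dict[int, tuple]:
        if isinstance(self.mode_composition, Mapping):
            return {int(k): tuple(v) for k, v in self.mode_composition.items()}
        if self.mode_composition is not None:
            return {k: tuple(self.mode_composition) for k in range(self.n_locations)}
        if self.geography == "isolation_by_distance":
            # a single lineage keeps the between-population signal purely spatial
            return {k: PURE_THELYTOKOUS for k in range(self.n_locations)}
        # pure-thelytokous sites interleaved (every third site, ~5 of 14 as
        # in the survey) so lineage composition carries no spatial gradient
        return {
            k: (PURE_THELYTOKOUS if k % 3 == 0 else SYMPATRIC)
            for k in range(self.n_locations)
        }

    def location_table(self) -> pd.DataFrame:
        if self.geography == "isolation_by_distance":
            # equatorial transect, ~5 degrees (~556 km) between neighbours
            return pd.DataFrame({
                "location": [f"L{k+1:02d}" for k in range(self.n_locations)],
                "latitude": 0.0,
                "longitude": [5.0 * k for k in range(self.n_locations)],
            })
        sites = reference.sampling_sites()
        if self.n_locations <= len(sites):
            return sites.iloc[: self.n_locations][
                ["location", "latitude", "longitude"]
            ].reset_index(drop=True)
        extra = pd.DataFrame({
            "location": [f"X{k+1:02d}" for k in range(self.n_locations - len(sites))],
            "latitude": 0.0,
            "longitude": [10.0 * k - 170.0 for k in range(self.n_locations - len(sites))],
        })
        return pd.concat(
            [sites[["location", "latitude", "longitude"]], extra], ignore_index=True
        )


def _corrupt(site: str, shift_at: int | None = None) -> str:
    """Disable a primer site.  With ``shift_at`` the tail is shifted by a T
    insertion at that index (the published heteroplasmy structure); otherwise
    three bases are substituted."""
    if shift_at is not None:
        return site[:shift_at] + "T" + site[shift_at : len(site) - 1]
    swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
    s = list(site)
    for k in (5, len(s) // 2, len(s) - 6):
        s[k] = swap[s[k]]
    return "".join(s)


def _random_seq(rng: np.random.Generator, length: int, at_fraction: float) -> str:
    p_at = at_fraction / 2.0
    p_gc = (1.0 - at_fraction) / 2.0
    return "".join(rng.choice(BASES, size=length, p=[p_at, p_gc, p_gc, p_at]))


def _mutate(rng: np.random.Generator, seq: str, n_mut: int,
            sites: np.ndarray | None = None) -> str:
    if n_mut == 0:
        return seq
    s = list(seq)
    if sites is None:
        sites = rng.choice(len(s), size=min(n_mut, len(s)), replace=False)
    for pos in sites:
        alts = [b for b in "ACGT" if b != s[pos]]
        s[pos] = alts[rng.integers(3)]
    return "".join(s)


def _assay_region(rng: np.random.Generator, at_fraction: float) -> dict[str, str]:
    """Build the three assay-region variants sharing one backbone."""
    backbone = list(_random_seq(rng, ASSAY_LENGTH, at_fraction))
    tcor_rc = reverse_complement(TCOR.sequence)

    def place(tcoc_ok: bool, tcos_ok: bool) -> str:
        s = backbone.copy()
        tcoc = TCOC.sequence if tcoc_ok else _corrupt(TCOC.sequence)
        # the T insertion at fragment position 212 shifts the arrhenotoky
        # primer site's 3' end out of register on the thelytokous mitotype
        tcos = TCOS.sequence if tcos_ok else _corrupt(TCOS.sequence, shift_at=21)
        s[0 : len(tcoc)] = tcoc
        s[ARRHENO_OFFSET : ARRHENO_OFFSET + len(tcos)] = tcos
        s[ASSAY_LENGTH - len(tcor_rc) :] = tcor_rc
        return "".join(s)

    return {
        "thelytokous": place(tcoc_ok=True, tcos_ok=False),
        "arrhenotokous": place(tcoc_ok=False, tcos_ok=True),
        "undetermined": place(tcoc_ok=False, tcos_ok=False),
    }


@dataclasses.dataclass
class SimResult:
    config: SimConfig
    records: list[SequenceRecord]  # one barcode record per individual
    templates: dict[str, list[str]]  # individual -> mitotype template set
    metadata: pd.DataFrame
    truth: pd.DataFrame
    group_cores: dict[str, str]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "barcodes.fasta",
            "templates": outdir / "templates.fasta",
            "metadata": outdir / "metadata.tsv",
            "truth": outdir / "truth.tsv",
            "config": outdir / "sim_config.json",
        }
        write_fasta(self.records, paths["fasta"])
        tmpl_records = [
            SequenceRecord(id=f"{ind}.m{k+1}", nucleotides=seq)
            for ind, seqs in self.templates.items()
            for k, seq in enumerate(seqs)
        ]
        write_fasta(tmpl_records, paths["templates"])
        self.metadata.to_csv(paths["metadata"], sep="\t", index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        paths["config"].write_text(json.dumps(dataclasses.asdict(self.config),
                                              default=str, indent=1))
        return paths


def expected_pairwise_divergence(config: SimConfig) -> float:
    """Expected within-population p-distance implied by the mutation model.

    Each individual independently mutates a site with probability mu to one
    of the three other bases, so two individuals differ at a site with
    probability 2 mu (1 - mu) + (2/3) mu^2.
    """
    mu = config.within_group_mutation_rate
    return 2.0 * mu * (1.0 - mu) + (2.0 / 3.0) * mu * mu


def simulate(config: SimConfig) -> SimResult:
    rng = np.random.default_rng(config.seed)
    locations = config.location_table()
    compositions = config._compositions()

    core1 = _random_seq(rng, BARCODE_LENGTH, config.at_fraction)
    div_sites = rng.choice(BARCODE_LENGTH, size=config.group_core_divergence,
                           replace=False)
    core2 = _mutate(rng, core1, config.group_core_divergence, sites=div_sites)
    # a heterospecific contaminant core at barcode-gap divergence (~19%)
    n_contam_sites = round(0.19 * BARCODE_LENGTH)
    contam_core = _mutate(
        rng, core1, n_contam_sites,
        sites=rng.choice(BARCODE_LENGTH, size=n_contam_sites, replace=False),
    )
    assay = _assay_region(rng, config.at_fraction)

    # per-location group-1 cores; under isolation by distance they drift
    # along the transect proportionally to the geographic step
    loc_cores = {}
    if config.geography == "isolation_by_distance":
        from .geostats import geo_distance_matrix

        geo = geo_distance_matrix(locations)
        prev = core1
        for k, loc in enumerate(locations["location"]):
            if k > 0:
                step_km = geo.values[k - 1, k]
                n_step = max(1, round(config.ibd_mutations_per_1000km * step_km / 1000.0))
                prev = _mutate(rng, prev, n_step)
            loc_cores[loc] = prev
    else:
        loc_cores = {loc: core1 for loc in locations["location"]}

    records, truth_rows, meta_rows = [], [], []
    templates: dict[str, list[str]] = {}
    hap_ids: dict[str, str] = {}
    counter = 0
    for k, row in locations.iterrows():
        loc = row["location"]
        n = config.n_per_location
        if config.small_sample and k == config.small_sample[0]:
            n = config.small_sample[1]
        fracs = np.asarray(compositions[k], dtype=float)
        for _ in range(n):
            counter += 1
            ind = f"S{counter:04d}"
            contaminant = (
                rng.random() < config.interspecific_contaminant_fraction
            )
            mode = MODES[rng.choice(4, p=fracs)]
            if contaminant:
                species, group, mode = "Thrips_sp_X", "none", "undetermined"
                base = contam_core
            else:
                species = "Thrips_tabaci"
                if mode == "arrhenotokous":
                    group = "group2"
                elif mode == "heteroplasmic":
                    group = ("group2" if rng.random() < config.heteroplasmic_group2_prob
                             else "group1")
                else:
                    group = "group1"
                base = (core2 if group == "group2" else loc_cores[loc])
            n_mut = rng.poisson(config.within_group_mutation_rate * BARCODE_LENGTH)
            barcode = _mutate(rng, base, int(n_mut))
            hap = hap_ids.setdefault(barcode, f"T{len(hap_ids)+1:03d}")
            records.append(SequenceRecord(
                id=ind, nucleotides=barcode, location=loc,
                latitude=float(row["latitude"]), longitude=float(row["longitude"]),
            ))
            spacer = _random_seq(rng, SPACER_LENGTH, config.at_fraction)
            if contaminant or mode == "undetermined":
                own = ["undetermined"]
            elif mode == "heteroplasmic":
                own = (["thelytokous", "arrhenotokous"] if group == "group1"
                       else ["arrhenotokous", "thelytokous"])
            else:
                own = [mode]
            templates[ind] = [barcode + spacer + assay[m] for m in own]
            truth_rows.append({
                "individual": ind, "location": loc, "species": species,
                "haplotype": hap, "group": group, "mode": mode,
                "heteroplasmic": mode == "heteroplasmic",
            })
            meta_rows.append({
                "sample_id": ind, "location": loc,
                "latitude": float(row["latitude"]),
                "longitude": float(row["longitude"]),
                "date": "", "host": "Allium cepa",
            })
    return SimResult(
        config=config,
        records=records,
        templates=templates,
        metadata=pd.DataFrame(meta_rows),
        truth=pd.DataFrame(truth_rows),
        group_cores={"group1": core1, "group2": core2,
                     "contaminant": contam_core},
    )


def build_reference_fixture(background_seed: int = 0):
    """Re-export of the deterministic in-package published-panel fixture."""
    return reference.build_reference_fixture(background_seed)
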