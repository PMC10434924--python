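"""End-to-end analysis: QC -> haplotypes -> distances -> tree/groups ->
mode calls -> diversity -> chi-square -> Mantel, with a structured report.

The pipeline consumes a template FASTA (one or more mitotype records per
individual, ids ``<individual>.m<k>``; plain per-individual ids also work),
a metadata TSV, and optionally a primer file overriding the built-in
reproductive-mode primer trio.  Every stage writes its table into the run
directory and contributes a section to the JSON report; all numbers in the
report are recomputable from the inputs plus the seed.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from . import distances, geostats, haplotypes, modes, nj, reference, seqio

SCHEMA_VERSION = 1


@dataclasses.dataclass
class PipelineConfig:
    barcode_window: tuple[int, int] = (1, 435)  # 1-based half-open, 434 nt
    max_end_missing: int = 5
    missing_policy: str = "strict"
    distance_model: str = "mcl"
    #: group name -> anchor individuals (record ids) of known lineage
    group_anchors: Mapping[str, list[str]] | None = None
    outgroup_id: str | None = None  # record id of an outgroup individual
    pcr_max_mismatch: int = 0
    fragment_tolerance: int = 0
    mantel_permutations: int = 999
    seed: int = 0


@dataclasses.dataclass
class AnalysisReport:
    schema_version: int
    provenance: dict
    qc: dict
    haplotypes: list[dict]
    n_polymorphic_sites: int
    mean_haplotype_distance: float
    group_assignment: dict
    mode_calls: list[dict]
    heteroplasmy_percent: dict
    diversity_by_location: dict
    chi_square: dict | None
    mantel: dict | None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, default=str))


def _individual_of(record_id: str) -> str:
    return record_id.rsplit(".m", 1)[0] if ".m" in record_id else record_id


def run_pipeline(
    templates_fasta: str | Path,
    metadata_tsv: str | Path,
    primers: str | Path | None = None,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> AnalysisReport:
    cfg = config or PipelineConfig()
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # --- load
    raw = _stage("load", seqio.read_fasta, templates_fasta)
    metadata = _stage("load", seqio.read_metadata, metadata_tsv)
    primer_set = {p.name: p for p in modes.MODE_PRIMERS}
    if primers is not None:
        for p in modes.read_primer_file(primers):
            primer_set[p.name] = p

    templates: dict[str, list[str]] = {}
    for rec in raw:
        templates.setdefault(_individual_of(rec.id), []).append(rec.nucleotides)

    # --- barcode extraction + QC
    start, end = cfg.barcode_window
    barcode_records = [
        seqio.SequenceRecord(id=ind, nucleotides=seqio.window_trim(seqs[0], start, end))
        for ind, seqs in templates.items()
    ]
    barcode_records = seqio.attach_metadata(barcode_records, metadata)
    kept, discarded = _stage("qc", seqio.qc_filter, barcode_records,
                             end - start, cfg.max_end_missing)
    qc_info = {"n_input": len(barcode_records), "n_kept": len(kept),
               "n_discarded": len(discarded),
               "discarded_ids": [r.id for r in discarded]}

    # --- haplotypes
    table = _stage("collapse", haplotypes.collapse, kept, cfg.missing_policy)
    table = haplotypes.name_haplotypes(table)
    ref_name = max(table, key=lambda h: (h.count, -table.names.index(h.name))).name
    vst = _stage("variable_sites", haplotypes.variable_sites, table, ref_name)
    hap_of_individual = {m: h.name for h in table for m in h.member_ids}

    # --- distances + tree + groups
    dm = _stage("distances", distances.distance_matrix,
                table.names, [h.sequence for h in table], cfg.distance_model)
    mean_d = _stage("distances", distances.mean_haplotype_distance,
                    table, cfg.distance_model)
    assignment: dict[str, str] = {}
    tree = None
    if len(table) >= 3:
        tree = _stage("nj", nj.neighbor_joining, dm)
        if cfg.outgroup_id and cfg.outgroup_id in hap_of_individual:
            rooted = nj.root_with_outgroup(tree, hap_of_individual[cfg.outgroup_id])
        else:
            rooted = nj.midpoint_root(tree)
        if cfg.group_anchors:
            anchor_haps = {
                g: sorted({hap_of_individual[i] for i in ids if i in hap_of_individual})
                for g, ids in cfg.group_anchors.items()
            }
            assignment = _stage("groups", nj.assign_groups, rooted, anchor_haps)

    # --- reproductive-mode typing
    fwd = (primer_set["TCOC"], primer_set["TCOS"])
    rev = primer_set["TCOR"]
    individual_calls: dict[str, modes.ModeCall] = {}
    hap_patterns: dict[str, set[int]] = {h.name: set() for h in table}
    kept_ids = {r.id for r in kept}
    for ind in templates:
        if ind not in kept_ids:
            continue
        hap = hap_of_individual[ind]
        group = assignment.get(hap, "ungrouped")
        lengths: set[int] = set()
        for tmpl in templates[ind]:
            res = modes.in_silico_pcr(tmpl, fwd, rev, cfg.pcr_max_mismatch,
                                      template_id=ind)
            lengths |= set(res.lengths)
        pattern = modes.classify_lengths(lengths, cfg.fragment_tolerance)
        individual_calls[ind] = modes.call_mode(pattern, group, haplotype=hap)
        hap_patterns[hap] |= set(pattern)
    hap_calls = {
        h: modes.call_mode(frozenset(p), assignment.get(h, "ungrouped"), haplotype=h)
        for h, p in hap_patterns.items()
    }
    het = modes.heteroplasmy_summary(
        {h: frozenset(p) for h, p in hap_patterns.items()},
        {h: assignment.get(h, "ungrouped") for h in hap_patterns},
    ) if assignment else {}

    # --- per-location diversity
    by_location: dict[str, list] = {}
    for rec in kept:
        by_location.setdefault(rec.location or "unknown", []).append(rec)
    diversity = {}
    for loc, recs in sorted(by_location.items()):
        if len(recs) < 2:
            diversity[loc] = None
            continue
        res = distances.within_sample_diversity(
            [r.nucleotides for r in recs], cfg.distance_model, sample_label=loc)
        diversity[loc] = res.mean_pairwise_distance

    # --- chi-square of resolved modes over locations
    chisq = None
    loc_of = {r.id: (r.location or "unknown") for r in kept}
    counts: dict[str, dict[str, int]] = {}
    for ind, call in individual_calls.items():
        if call.resolved_mode == "undetermined":
            continue
        counts.setdefault(call.resolved_mode, {})
        loc = loc_of[ind]
        counts[call.resolved_mode][loc] = counts[call.resolved_mode].get(loc, 0) + 1
    if len(counts) == 2:
        ctab = pd.DataFrame(counts).T.fillna(0).astype(int)
        ctab = ctab.reindex(["thelytokous", "arrhenotokous"])
        if ctab.shape[1] >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = geostats.mode_homogeneity_chisq(ctab)
            chisq = {"statistic": res.statistic, "df": res.df,
                     "p_value": res.p_value, "n": res.n}

    # --- Mantel: genetic vs geographic distance between populations
    mantel = None
    multi = [loc for loc, recs in sorted(by_location.items()) if len(recs) >= 1]
    if len(multi) >= 3 and all(
        r.latitude is not None for recs in by_location.values() for r in recs
    ):
        seqs, labs = [], []
        for loc in multi:
            for r in by_location[loc]:
                seqs.append(r.nucleotides)
                labs.append(loc)
        gen = distances.population_distance_matrix(seqs, labs, model="p")
        coords = [(loc, by_location[loc][0].latitude, by_location[loc][0].longitude)
                  for loc in gen.labels]
        geo = geostats.geo_distance_matrix(coords)
        try:
            res = geostats.mantel_test(geo, gen, cfg.mantel_permutations, cfg.seed)
            mantel = {"r": res.r, "r_squared": res.r_squared, "p_value": res.p_value,
                      "n_permutations": res.n_permutations, "seed": res.seed}
        except ValueError:
            mantel = None  # constant matrix (e.g. a single haplotype everywhere)

    report = AnalysisReport(
        schema_version=SCHEMA_VERSION,
        provenance={"package_version": __version__, "seed": cfg.seed,
                    "config": {k: str(v) for k, v in dataclasses.asdict(cfg).items()},
                    "templates_fasta": str(templates_fasta),
                    "metadata_tsv": str(metadata_tsv)},
        qc=qc_info,
        haplotypes=[{"name": h.name, "count": h.count, "frequency": h.frequency}
                    for h in table],
        n_polymorphic_sites=len(vst.positions),
        mean_haplotype_distance=mean_d,
        group_assignment=assignment,
        mode_calls=[dataclasses.asdict(c) | {"fragment_pattern": sorted(c.fragment_pattern)}
                    for c in hap_calls.values()],
        heteroplasmy_percent=het,
        diversity_by_location=diversity,
        chi_square=chisq,
        mantel=mantel,
    )

    if out:
        report.write_json(out / "report.json")
        table.write_tsv(out / "haplotypes.tsv")
        vst.write_tsv(out / "variable_sites.tsv")
        dm.write_tsv(out / "distances.tsv")
        if tree is not None:
            nj.write_newick(tree, out / "tree.nwk")
        modes.mode_calls_frame(hap_calls.values(),
                               {h: assignment.get(h, "ungrouped") for h in hap_patterns}
                               ).to_csv(out / "mode_calls.tsv", sep="\t", index=False)
        pd.Series(diversity, name="diversity").rename_axis("location").to_csv(
            out / "diversity.tsv", sep="\t")
    return report


def reference_report(background_seed: int = 0) -> dict:
    """Desk-scale summary of the bundled 58-haplotype reference panel.

    Every number is recomputed from the panel: polymorphic-site count, mean
    pairwise haplotype distance under each model, diversity of the two
    populations whose composition is bundled, fragment-pattern tallies, and
    per-group heteroplasmy percentages.
    """
    fix = reference.build_reference_fixture(background_seed)
    table = fix.haplotypes
    vst = haplotypes.variable_sites(table, reference.REFERENCE_HAPLOTYPE)
    seqs = table.sequences()
    diversity = {
        loc: distances.composition_diversity(comp, seqs, model="mcl",
                                             sample_label=loc).mean_pairwise_distance
        for loc, comp in fix.populations.items()
    }
    patterns = fix.fragment_patterns
    tally = {
        "thelytokous_only": sum(p == {modes.THELYTOKOUS_LENGTH} for p in patterns.values()),
        "arrhenotokous_only": sum(p == {modes.ARRHENOTOKOUS_LENGTH} for p in patterns.values()),
        "both": sum(p == set(modes.KNOWN_LENGTHS) for p in patterns.values()),
        "none": sum(not p for p in patterns.values()),
    }
    return {
        "n_haplotypes": len(table),
        "n_polymorphic_sites": len(vst.positions),
        "mean_haplotype_distance": {
            m: distances.mean_haplotype_distance(table, m)
            for m in ("p", "jc69", "mcl")
        },
        "diversity_by_location": diversity,
        "fragment_tally": tally,
        "heteroplasmy_percent": modes.heteroplasmy_summary(patterns, fix.groups),
        "group_sizes": {g: list(fix.groups.values()).count(g)
                        for g in ("group1", "group2", "ungrouped")},
    }
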