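"""End-to-end orchestration: simulate -> select -> ibd -> linkage ->
summary (and optionally power), driven by a single TOML config with
per-stage seeds.  Every stage logs its input/output counts and writes
schema-stable TSVs so that a seeded run is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import ascertainment, ibd, io_formats, linkage, power, synthetic_data
from .models import (
    EdspError,
    IndividualRecord,
    MarkerDef,
    MarkerMap,
    SelectionCriteria,
    SibPairRecord,
    TraitModel,
)

log = logging.getLogger(__name__)

DEFAULT_STAGES = ("simulate", "select", "ibd", "linkage", "summary")


@dataclasses.dataclass
class RunConfig:
    """Parsed pipeline configuration."""

    outdir: Path
    stages: tuple[str, ...] = DEFAULT_STAGES
    n_families: int = 200
    seed: int = 1
    model: TraitModel = dataclasses.field(
        default_factory=synthetic_data.TraitModel)
    markers: list[MarkerDef] = dataclasses.field(default_factory=list)
    criteria: SelectionCriteria = dataclasses.field(
        default_factory=SelectionCriteria)
    phenotypes: tuple[str, ...] = ("sbp", "dbp", "pp")
    lrt: bool = False
    lrt_n_perm: int = 1000
    lrt_seed: int = 0
    ped_path: Optional[Path] = None
    map_path: Optional[Path] = None
    pheno_path: Optional[Path] = None
    power_design: Optional[power.DesignSpec] = None
    power_n_sim: int = 50_000
    power_seed: int = 0

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path = Path(".")) -> "RunConfig":
        run = raw.get("run", {})
        sim = raw.get("simulate", {})
        paths = raw.get("paths", {})
        if "model_fractions" in sim:
            model = TraitModel.from_variance_fractions(
                **sim["model_fractions"])
        else:
            model = TraitModel(**sim.get("model", {}))
        markers = [MarkerDef(**m) if "allele_freqs" not in m
                   else MarkerDef(**{**m, "allele_freqs":
                                     tuple(m["allele_freqs"])})
                   for m in sim.get("markers", [])]
        link = raw.get("linkage", {})
        pw = raw.get("power", {})
        design = None
        if pw:
            design = power.DesignSpec(**{
                k: v for k, v in pw.items()
                if k in ("selection", "lower_pct", "upper_pct", "phenotype",
                         "alpha", "power")})
        return cls(
            # output directory is cwd-relative; input paths are relative
            # to the config file
            outdir=Path(run.get("outdir", "out")),
            stages=tuple(run.get("stages", DEFAULT_STAGES)),
            n_families=sim.get("n_families", 200),
            seed=sim.get("seed", 1),
            model=model,
            markers=markers,
            criteria=SelectionCriteria(**raw.get("select", {})),
            phenotypes=tuple(link.get("phenotypes", ("sbp", "dbp", "pp"))),
            lrt=link.get("lrt", False),
            lrt_n_perm=link.get("lrt_n_perm", 1000),
            lrt_seed=link.get("lrt_seed", 0),
            ped_path=base / paths["ped"] if "ped" in paths else None,
            map_path=base / paths["map"] if "map" in paths else None,
            pheno_path=base / paths["pheno"] if "pheno" in paths else None,
            power_design=design,
            power_n_sim=pw.get("n_sim", 50_000),
            power_seed=pw.get("seed", 0),
        )


def build_sib_pairs(records: Sequence[IndividualRecord]) -> list[SibPairRecord]:
    """Pair up the genotyped offspring of each family (first two sibs,
    ordered by individual id)."""
    by_family: dict[str, list[IndividualRecord]] = {}
    for rec in records:
        if rec.father_id != "0":
            by_family.setdefault(rec.family_id, []).append(rec)
    pairs = []
    for fam in sorted(by_family):
        sibs = sorted(by_family[fam], key=lambda r: r.individual_id)
        if len(sibs) < 2:
            log.warning("family %s has %d genotyped offspring; skipped",
                        fam, len(sibs))
            continue
        if len(sibs) > 2:
            log.warning("family %s has %d offspring; using the first two",
                        fam, len(sibs))
        pairs.append(SibPairRecord(family_id=fam, sib1=sibs[0],
                                   sib2=sibs[1]))
    return pairs


def pairs_table(pairs: Sequence[SibPairRecord]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        cls = p.classification
        rows.append({
            "family_id": p.family_id,
            "sib1": p.sib1.individual_id, "sib2": p.sib2.individual_id,
            "label": cls.label if cls else "",
            "rule": cls.which_rule if cls else "",
            "affected_sib": cls.affected_sib if cls else "",
        })
    return pd.DataFrame(rows)


def sharing_table(pairs: Sequence[SibPairRecord],
                  marker_map: MarkerMap) -> pd.DataFrame:
    rows = []
    for p in pairs:
        for m_idx, marker in enumerate(marker_map):
            post = p.posteriors[m_idx] if p.posteriors else None
            row = {"family_id": p.family_id,
                   "pair": f"{p.sib1.individual_id}-{p.sib2.individual_id}",
                   "marker": marker.name,
                   "informative": post is not None}
            if post is not None:
                row.update(f0=post.f0, f1=post.f1, f2=post.f2,
                           pihat=post.pihat,
                           expected_shared=post.expected_shared)
            else:
                row.update(f0=float("nan"), f1=float("nan"),
                           f2=float("nan"), pihat=float("nan"),
                           expected_shared=float("nan"))
            rows.append(row)
    return pd.DataFrame(rows)


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the result bundle
    (DataFrames and output paths)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"outdir": out}

    if "simulate" in config.stages:
        if not config.markers:
            raise EdspError("simulate stage requires [simulate.markers]")
        cohort = synthetic_data.simulate_families(
            config.n_families, config.model, config.markers, config.seed)
        cohort = synthetic_data.mask_parents(cohort)
        io_formats.write_ped(cohort.individuals, out / "cohort.ped")
        io_formats.write_marker_map(cohort.marker_map, out / "markers.tsv")
        pheno = io_formats.cohort_phenotype_frame(cohort.individuals)
        io_formats.write_phenotypes(pheno, out / "phenotypes.csv")
        records = cohort.offspring()
        marker_map = cohort.marker_map
        pairs = cohort.sib_pairs
        log.info("simulated %d families (seed %d)", config.n_families,
                 config.seed)
    else:
        if not (config.ped_path and config.map_path and config.pheno_path):
            raise EdspError("without the simulate stage, [paths] must give "
                            "ped, map and pheno")
        records_all = io_formats.read_ped(config.ped_path)
        marker_map = io_formats.read_marker_map(config.map_path)
        pheno = io_formats.read_phenotypes(config.pheno_path)
        io_formats.attach_phenotypes(records_all, pheno)
        records = [r for r in records_all if r.father_id != "0"]
        pairs = build_sib_pairs(records_all)

    bundle["n_pairs_total"] = len(pairs)

    if "select" in config.stages:
        selected = ascertainment.select_edsp(pairs, config.criteria)
        table = pairs_table(pairs)
        io_formats.write_results(table, out / "pairs.tsv")
        bundle["pairs"] = table
        bundle["selected"] = selected
        log.info("selected %d extreme discordant pairs of %d",
                 len(selected), len(pairs))
    else:
        selected = list(pairs)

    if "ibd" in config.stages:
        freqs = ibd.estimate_allele_frequencies(records, marker_map)
        for pair in selected:
            ibd.pair_sharing_profile(pair, marker_map, freqs)
        sharing = sharing_table(selected, marker_map)
        io_formats.write_results(sharing, out / "sharing.tsv")
        bundle["sharing"] = sharing
        bundle["freqs"] = freqs

    if "linkage" in config.stages:
        if len(selected) < 4:
            raise EdspError(
                f"linkage needs >= 4 selected pairs, have {len(selected)}")
        results = linkage.linkage_table(selected, marker_map,
                                        config.phenotypes)
        io_formats.write_results(results, out / "results.tsv")
        bundle["results"] = results
        if config.lrt:
            lrt_rows = []
            for m_idx, marker in enumerate(marker_map):
                posts = [p.posteriors[m_idx] for p in selected]
                try:
                    res = linkage.sharing_lrt(
                        posts, direction="deficit",
                        n_perm=config.lrt_n_perm,
                        seed=config.lrt_seed + m_idx)
                except EdspError as exc:
                    log.warning("lrt %s: %s", marker.name, exc)
                    continue
                lrt_rows.append({
                    "marker": marker.name, "z0": res.z_hat[0],
                    "z1": res.z_hat[1], "z2": res.z_hat[2],
                    "lr_stat": res.lr_stat, "p_perm": res.p_perm,
                    "n_perm": res.n_perm, "n_pairs": res.n_pairs})
            lrt_table = pd.DataFrame(lrt_rows)
            io_formats.write_results(lrt_table, out / "lrt.tsv")
            bundle["lrt"] = lrt_table

    if "summary" in config.stages:
        summary = linkage.cohort_summary(selected, criteria=config.criteria)
        io_formats.write_results(summary, out / "summary.tsv")
        bundle["summary"] = summary

    if "power" in config.stages:
        design = config.power_design or power.DesignSpec()
        comparison = power.DesignSpec(selection="unselected",
                                      alpha=design.alpha, power=design.power)
        result = power.power_analysis(config.model, design,
                                      config.power_n_sim, config.power_seed,
                                      comparison=comparison)
        bundle["power"] = result
        io_formats.write_results(
            pd.DataFrame([dataclasses.asdict(result)]), out / "power.tsv")

    return bundle
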