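"""End-to-end orchestration: simulate, ingest, flag, classify, analyze, report.

The pipeline runs the full analysis on a synthetic catchment in dependency
order:

    simulate -> ingest -> gut_flag -> core -> attribution -> fates
             -> diversity -> rain -> biomass

Every stage writes its outputs (TSV/CSV/JSON) into the run directory
together with a manifest recording the configuration hash and seed; on a
rerun, stages whose outputs are present under the same hash are loaded from
disk instead of recomputed (unless forced), so deleting one intermediate
reproduces exactly that intermediate.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    biomass_budget,
    core_communities,
    diversity_stats,
    growth_fate,
    io_formats,
    rain_dynamics,
    source_attribution,
    synthetic_data,
    taxonomy_mapping,
)
from .io_formats import SEWER_HABITATS, CountTable

log = logging.getLogger("sewerflow.pipeline")

STAGES = (
    "simulate",
    "ingest",
    "gut_flag",
    "core",
    "attribution",
    "fates",
    "diversity",
    "rain",
    "biomass",
)


@dataclass
class PipelineConfig:
    """Thresholds, depths and module parameters for one pipeline run."""

    out_dir: str = "sewerflow_run"
    seed: int = 7
    scenario: dict = field(default_factory=dict)
    min_reads: int = 5000
    rarefaction: str | int = "sewer_median"  # or a fixed integer depth
    alpha_depth: int = 7322
    species_abundance_cutoff: float = 1e-4
    genus_abundance_cutoff: float = 5e-4
    gut_identity_cutoff: float = 0.987
    detected_min_samples: int = 3
    srt_days: float = 20.0
    m_daily_fraction: float = 0.05
    n_permutations: int = 999
    rain_days: int = 120
    rain_event_rate: float = 0.25
    network: dict = field(default_factory=dict)
    plant: dict = field(default_factory=dict)
    force: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k not in ("out_dir", "force")}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def median_sewer_depth(table: CountTable, meta: pd.DataFrame) -> int:
    """Median total read count over sewer-habitat samples.

    For an even number of samples the lower of the two middle values is
    used, so the returned depth is always an attained total.
    """
    by_sample = meta.set_index("sample_id")["habitat"]
    totals = sorted(
        int(t)
        for s, t in table.totals().items()
        if by_sample.get(s) in SEWER_HABITATS
    )
    if not totals:
        raise ValueError("no sewer samples")
    return totals[(len(totals) - 1) // 2]


def _species_table(table: CountTable, prefix: str = "s") -> CountTable:
    """Restrict a species-level table to proper species columns (drops the
    unclassified singleton ASV features)."""
    cols = [c for c in table.feature_ids if c.startswith(prefix)]
    return CountTable(table.counts[cols], level=table.level)


class _Run:
    """Mutable pipeline state plus stage bookkeeping."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.out = Path(cfg.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.state: dict = {}
        self.manifest_path = self.out / "manifest.json"
        self.manifest = (
            json.loads(self.manifest_path.read_text())
            if self.manifest_path.exists()
            else {}
        )
        self.chash = cfg.config_hash()

    def path(self, name: str) -> Path:
        return self.out / name

    def fresh(self, stage: str, outputs) -> bool:
        if self.cfg.force:
            return False
        if self.manifest.get(stage) != self.chash:
            return False
        return all(self.path(o).exists() for o in outputs)

    def done(self, stage: str) -> None:
        self.manifest[stage] = self.chash
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report dict (also written to report.json)."""
    run = _Run(config)
    report: dict = {"config_hash": run.chash, "seed": config.seed, "stages": {}}
    for stage in STAGES:
        spec = _STAGE_TABLE[stage]
        if run.fresh(stage, spec["outputs"]):
            log.info("stage %-12s cached -> loading", stage)
            spec["load"](run)
            report["stages"][stage] = {"cached": True}
        else:
            log.info("stage %-12s running", stage)
            summary = spec["run"](run)
            run.done(stage)
            report["stages"][stage] = {"cached": False, **(summary or {})}
    report["summary"] = _final_summary(run)
    with open(run.path("report.json"), "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(run: _Run):
    cfg = run.cfg
    scenario = synthetic_data.CommunityScenario(seed=cfg.seed, **cfg.scenario)
    table, meta, tax = synthetic_data.simulate_habitats(scenario)
    daily, hourly = synthetic_data.simulate_rainfall(
        cfg.rain_days, event_rate=cfg.rain_event_rate, seed=cfg.seed, hourly=True
    )
    sww_rain, sww_meta, weights = synthetic_data.simulate_wastewater_mixing(
        scenario, daily
    )
    refs, gut_refs, ref_truth = synthetic_data.simulate_references(
        scenario.species_ids, scenario.gut_species, seed=cfg.seed
    )
    io_formats.write_count_table(table, run.path("counts.tsv"))
    io_formats.write_metadata(meta, run.path("metadata.csv"))
    io_formats.write_taxonomy(tax, run.path("taxonomy.tsv"))
    io_formats.write_rainfall(daily, run.path("rainfall_daily.csv"))
    io_formats.write_rainfall(hourly, run.path("rainfall_hourly.csv"))
    io_formats.write_count_table(sww_rain, run.path("sww_rain_counts.tsv"))
    io_formats.write_metadata(sww_meta, run.path("sww_rain_metadata.csv"))
    io_formats.write_fasta(refs, run.path("species_refs.fasta"))
    io_formats.write_fasta(gut_refs, run.path("gut_refs.fasta"))
    truth = scenario.planted_truth()
    truth["sww_rain_weights"] = weights.to_dict()
    synthetic_data.write_truth(truth, run.path("truth.json"))
    run.state.update(scenario=scenario, truth=truth)
    _load_simulate(run)
    return {"n_samples": len(table.sample_ids), "n_features": len(table.feature_ids)}


def _load_simulate(run: _Run):
    run.state["table"] = io_formats.read_count_table(run.path("counts.tsv"))
    run.state["meta"] = io_formats.read_metadata(run.path("metadata.csv"))
    run.state["taxonomy"] = io_formats.read_taxonomy(run.path("taxonomy.tsv"))
    run.state["daily_rain"] = io_formats.read_rainfall(run.path("rainfall_daily.csv"))
    run.state["hourly_rain"] = io_formats.read_rainfall(
        run.path("rainfall_hourly.csv"), hourly=True
    )
    sww = io_formats.read_count_table(run.path("sww_rain_counts.tsv"))
    run.state["sww_rain"] = CountTable(sww.counts, level="species")
    run.state["sww_rain_meta"] = io_formats.read_metadata(run.path("sww_rain_metadata.csv"))
    run.state["species_refs"] = io_formats.read_fasta(run.path("species_refs.fasta"))
    run.state["gut_refs"] = io_formats.read_fasta(run.path("gut_refs.fasta"))
    run.state["truth"] = json.loads(run.path("truth.json").read_text())


def _stage_ingest(run: _Run):
    st = run.state
    filtered = io_formats.filter_and_merge(st["table"], st["meta"], run.cfg.min_reads)
    meta = io_formats.collapse_metadata(st["meta"])
    meta = meta[meta["sample_id"].isin(filtered.sample_ids)]
    io_formats.write_count_table(filtered, run.path("filtered_counts.tsv"))
    io_formats.write_metadata(meta, run.path("filtered_metadata.csv"))
    _load_ingest(run)
    return {"n_samples": len(filtered.sample_ids)}


def _load_ingest(run: _Run):
    run.state["filtered"] = io_formats.read_count_table(run.path("filtered_counts.tsv"))
    run.state["filtered_meta"] = io_formats.read_metadata(run.path("filtered_metadata.csv"))


def _stage_gut_flag(run: _Run):
    st = run.state
    flags = taxonomy_mapping.flag_gut_species(
        st["species_refs"], st["gut_refs"], cutoff=run.cfg.gut_identity_cutoff
    )
    flags.to_csv(run.path("gut_flags.tsv"), sep="\t", index=False)
    _load_gut_flag(run)
    return {"n_gut": int(flags["is_gut"].sum())}


def _load_gut_flag(run: _Run):
    flags = pd.read_csv(run.path("gut_flags.tsv"), sep="\t")
    run.state["gut_flags"] = flags
    run.state["gut_species"] = taxonomy_mapping.gut_species_set(flags)


def _stage_core(run: _Run):
    st, cfg = run.state, run.cfg
    table, meta = st["filtered"], st["filtered_meta"]
    depth = (
        median_sewer_depth(table, meta)
        if cfg.rarefaction == "sewer_median"
        else int(cfg.rarefaction)
    )
    rarefied = core_communities.rarefy(table, depth, seed=cfg.seed)
    species = io_formats.aggregate(rarefied, st["taxonomy"], "species")
    genus = io_formats.aggregate(rarefied, st["taxonomy"], "genus")
    core = core_communities.classify_core_species(
        species,
        meta,
        gut_species=st["gut_species"],
        abundance_cutoff=cfg.species_abundance_cutoff,
    )
    genera = core_communities.classify_core_genera(
        genus, meta, abundance_cutoff=cfg.genus_abundance_cutoff
    )
    detected = core_communities.detect_in_sewer(
        species, meta, core, st["gut_species"], min_samples=cfg.detected_min_samples
    )
    unified = core_communities.unify_core(core, detected)
    io_formats.write_count_table(species, run.path("rarefied_species.tsv"))
    io_formats.write_count_table(genus, run.path("rarefied_genus.tsv"))
    core.to_csv(run.path("core_species.tsv"), sep="\t", index=False)
    genera.to_csv(run.path("core_genera.tsv"), sep="\t", index=False)
    unified.to_csv(run.path("unified_core.tsv"), sep="\t", index=False)
    (run.path("detected_species.json")).write_text(json.dumps(sorted(detected)))
    _load_core(run)
    return {"rarefaction_depth": depth, "n_detected": len(detected)}


def _load_core(run: _Run):
    st = run.state
    sp = io_formats.read_count_table(run.path("rarefied_species.tsv"))
    ge = io_formats.read_count_table(run.path("rarefied_genus.tsv"))
    st["species_table"] = CountTable(sp.counts, level="species")
    st["genus_table"] = CountTable(ge.counts, level="genus")
    st["core"] = pd.read_csv(run.path("core_species.tsv"), sep="\t")
    st["core_genera"] = pd.read_csv(run.path("core_genera.tsv"), sep="\t")
    st["unified"] = pd.read_csv(run.path("unified_core.tsv"), sep="\t")
    st["detected"] = frozenset(json.loads(run.path("detected_species.json").read_text()))


def _stage_attribution(run: _Run):
    st = run.state
    labels = source_attribution.assign_sources(
        st["gut_species"],
        st["unified"],
        st["detected"],
        observed_species=st["species_table"].feature_ids,
    )
    summary = source_attribution.summarize_attribution(
        st["species_table"], labels, st["filtered_meta"]
    )
    labels.to_frame().to_csv(run.path("source_labels.tsv"), sep="\t")
    summary.to_csv(run.path("attribution_summary.tsv"), sep="\t", index=False)
    _load_attribution(run)
    return {"n_labeled": len(labels)}


def _load_attribution(run: _Run):
    st = run.state
    st["source_labels"] = pd.read_csv(
        run.path("source_labels.tsv"), sep="\t", index_col=0
    )["source"]
    st["attribution"] = pd.read_csv(run.path("attribution_summary.tsv"), sep="\t")


def _stage_fates(run: _Run):
    st, cfg = run.state, run.cfg
    params = growth_fate.MassBalanceParams(cfg.srt_days, cfg.m_daily_fraction)
    table, meta = st["species_table"], st["filtered_meta"]
    iww = growth_fate.mean_abundance_by_wwtp(table, meta, "IWW")
    a_s = growth_fate.mean_abundance_by_wwtp(table, meta, "AS")
    fates = growth_fate.classify_fates(iww, a_s, params)
    cross = growth_fate.crosstab_fate_source(fates, st["source_labels"], table, meta)
    fates.to_csv(run.path("growth_fates.tsv"), sep="\t")
    cross.to_csv(run.path("fate_source_crosstab.tsv"), sep="\t", index=False)
    _load_fates(run)
    return {"n_growing": int((fates["fate"] == "growing").sum())}


def _load_fates(run: _Run):
    st = run.state
    st["fates"] = pd.read_csv(run.path("growth_fates.tsv"), sep="\t", index_col=0)
    st["fate_crosstab"] = pd.read_csv(run.path("fate_source_crosstab.tsv"), sep="\t")


def _stage_diversity(run: _Run):
    st, cfg = run.state, run.cfg
    table, meta = st["filtered"], st["filtered_meta"]
    alpha_table = core_communities.rarefy(table, cfg.alpha_depth, seed=cfg.seed)
    alpha = pd.DataFrame(
        {
            m: diversity_stats.alpha_diversity(alpha_table, m)
            for m in diversity_stats.ALPHA_METRICS
        }
    )
    dm = diversity_stats.bray_curtis(
        st["species_table"], abundance_floor=cfg.species_abundance_cutoff
    )
    coords, explained = diversity_stats.pcoa(dm)
    habitats = meta.set_index("sample_id")["habitat"].reindex(dm.sample_ids)
    perma = diversity_stats.permanova(
        dm, habitats, n_permutations=cfg.n_permutations, seed=cfg.seed
    )
    alpha.to_csv(run.path("alpha_diversity.tsv"), sep="\t")
    dm.to_dataframe().to_csv(run.path("bray_curtis.tsv"), sep="\t")
    coords.assign(habitat=habitats.to_numpy()).to_csv(run.path("pcoa.tsv"), sep="\t")
    with open(run.path("permanova.json"), "w") as fh:
        json.dump(
            {
                "factor": "habitat",
                "r_squared": perma.r_squared,
                "pseudo_f": perma.pseudo_f,
                "p_value": perma.p_value,
                "n_permutations": perma.n_permutations,
                "explained_axis1": float(explained[0]),
                "explained_axis2": float(explained[1]),
            },
            fh,
            indent=1,
        )
    _load_diversity(run)
    return {"permanova_r2": round(perma.r_squared, 4)}


def _load_diversity(run: _Run):
    st = run.state
    st["alpha"] = pd.read_csv(run.path("alpha_diversity.tsv"), sep="\t", index_col=0)
    bc = pd.read_csv(run.path("bray_curtis.tsv"), sep="\t", index_col=0)
    st["bray_curtis"] = diversity_stats.DistanceMatrix(list(bc.index), bc.to_numpy())
    st["permanova"] = json.loads(run.path("permanova.json").read_text())


def _stage_rain(run: _Run):
    st, cfg = run.state, run.cfg
    tsr = rain_dynamics.compute_tsr(st["daily_rain"])
    sww, sww_meta = st["sww_rain"], st["sww_rain_meta"]
    # water-phase and sewer-surface samples in one species-level matrix
    sewer_meta = st["filtered_meta"]
    sewer_ids = [
        s
        for s in st["species_table"].sample_ids
        if sewer_meta.set_index("sample_id")["habitat"].get(s) in SEWER_HABITATS
    ]
    sewer_counts = st["species_table"].counts.loc[sewer_ids]
    combined = pd.concat([sww.counts, sewer_counts]).fillna(0).astype(np.int64)
    dm = diversity_stats.bray_curtis(
        CountTable(combined, level="species"),
        abundance_floor=cfg.species_abundance_cutoff,
    )
    meta_all = pd.concat([sww_meta, sewer_meta], ignore_index=True)
    flags = rain_dynamics.flag_rain_before_sampling(
        st["hourly_rain"], sww_meta["timestamp"]
    )
    flags.index = sww_meta["sample_id"]
    tsr_of = tsr.set_index(tsr["date"])["tsr"]
    tsr_by_sample = pd.Series(
        [tsr_of.get(pd.Timestamp(t).normalize(), pd.NA) for t in sww_meta["timestamp"]],
        index=sww_meta["sample_id"],
        dtype="Int64",
    )
    analysis = rain_dynamics.rain_bc_analysis(
        dm, meta_all, water_habitat="SWW_g", rain_flags=flags, tsr_by_sample=tsr_by_sample
    )
    tsr.to_csv(run.path("tsr.tsv"), sep="\t", index=False)
    with open(run.path("rain_analysis.json"), "w") as fh:
        json.dump(analysis, fh, indent=1, default=str)
    _load_rain(run)
    return {"n_pairs": analysis["n_pairs"]}


def _load_rain(run: _Run):
    st = run.state
    st["tsr"] = pd.read_csv(run.path("tsr.tsv"), sep="\t")
    st["rain_analysis"] = json.loads(run.path("rain_analysis.json").read_text())


def _stage_biomass(run: _Run):
    cfg = run.cfg
    network = biomass_budget.SewerNetworkSpec(**cfg.network)
    plant = biomass_budget.PlantLoadSpec(**cfg.plant)
    report = biomass_budget.budget_report(network, plant)
    with open(run.path("biomass_budget.json"), "w") as fh:
        json.dump(report, fh, indent=1)
    _load_biomass(run)
    return report


def _load_biomass(run: _Run):
    run.state["biomass"] = json.loads(run.path("biomass_budget.json").read_text())


_STAGE_TABLE = {
    "simulate": {
        "run": _stage_simulate,
        "load": _load_simulate,
        "outputs": [
            "counts.tsv",
            "metadata.csv",
            "taxonomy.tsv",
            "rainfall_daily.csv",
            "rainfall_hourly.csv",
            "sww_rain_counts.tsv",
            "sww_rain_metadata.csv",
            "species_refs.fasta",
            "gut_refs.fasta",
            "truth.json",
        ],
    },
    "ingest": {
        "run": _stage_ingest,
        "load": _load_ingest,
        "outputs": ["filtered_counts.tsv", "filtered_metadata.csv"],
    },
    "gut_flag": {"run": _stage_gut_flag, "load": _load_gut_flag, "outputs": ["gut_flags.tsv"]},
    "core": {
        "run": _stage_core,
        "load": _load_core,
        "outputs": [
            "rarefied_species.tsv",
            "rarefied_genus.tsv",
            "core_species.tsv",
            "core_genera.tsv",
            "unified_core.tsv",
            "detected_species.json",
        ],
    },
    "attribution": {
        "run": _stage_attribution,
        "load": _load_attribution,
        "outputs": ["source_labels.tsv", "attribution_summary.tsv"],
    },
    "fates": {
        "run": _stage_fates,
        "load": _load_fates,
        "outputs": ["growth_fates.tsv", "fate_source_crosstab.tsv"],
    },
    "diversity": {
        "run": _stage_diversity,
        "load": _load_diversity,
        "outputs": ["alpha_diversity.tsv", "bray_curtis.tsv", "pcoa.tsv", "permanova.json"],
    },
    "rain": {"run": _stage_rain, "load": _load_rain, "outputs": ["tsr.tsv", "rain_analysis.json"]},
    "biomass": {"run": _stage_biomass, "load": _load_biomass, "outputs": ["biomass_budget.json"]},
}


def _final_summary(run: _Run) -> dict:
    st = run.state
    att = st["attribution"]
    gut = att[att["source"] == "gut"].set_index("habitat")["abundance_fraction"]
    return {
        "permanova_habitat_r2": st["permanova"]["r_squared"],
        "gut_fraction_by_habitat": {k: round(float(v), 4) for k, v in gut.items()},
        "n_growing_species": int((st["fates"]["fate"] == "growing").sum()),
        "network_cell_biomass_kg_cod": st["biomass"]["network_cell_biomass_kg_cod"],
        "daily_cell_input_kg_cod": st["biomass"]["daily_cell_input_kg_cod"],
    }
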