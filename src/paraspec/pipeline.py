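"""End-to-end pipeline orchestration: config, stages, and the run manifest.

The pipeline runs the stages in dependency order on a self-contained
synthetic study: simulate (duplication dataset + gene table + kinetics
quartet) -> pair -> model selection -> ancestral reconstruction ->
paralog profiling -> kinetics.  Identical config and seed give identical
outputs for every deterministic stage.  Configuration is strict: unknown
keys are rejected before any stage runs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import io as pio
from .ancestors import altall_ancestor, map_ancestor, marginal_posteriors
from .alignment import Alignment
from .kinetics import MatrixDesign, specificity_matrix
from .likelihood import aic_model_selection
from .models import lg_model, poisson_model
from .pairing import match_cognate_pairs
from .profiles import paralog_specific_positions, position_frequencies
from .simulate import (
    DuplicationScenario,
    GenomeLayout,
    KineticParameters,
    duplication_tree,
    plant_duplication,
    simulate_gene_table,
    simulate_phosphotransfer,
)

__version__ = "0.1.0"


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PlantedPosition(_StrictModel):
    column: int
    clade1: list[str]
    clade2: list[str]


class SimulateConfig(_StrictModel):
    n_leaves_per_clade: int = 12
    mean_branch_length: float = 0.1
    stem_length: float = 0.25
    n_sites: int = 300
    gamma_shape: float = 1.0
    n_categories: int = 4
    planted: list[PlantedPosition] = Field(
        default_factory=lambda: [
            PlantedPosition(column=27, clade1=["R"], clade2=["Q", "E", "S"]),
            PlantedPosition(column=29, clade1=["D", "E"], clade2=["A"]),
        ]
    )
    n_genomes: int = 4
    adjacent_pairs: int = 2
    clusters: int = 1
    orphan_hks: int = 1
    orphan_rrs: int = 0
    # kinetics quartet: transfer rate constants, uM^-1 s^-1
    rates: dict[str, float] = Field(
        default_factory=lambda: {
            "HK1:RR1": 9.0e-4,
            "HK1:RR2": 9.0e-4,
            "HK2:RR1": 2.0e-4,
            "HK2:RR2": 5.6e-3,
        }
    )
    phosphatase_ratio: float = 0.1   # k_p = ratio * k_t; order-of-magnitude guess
    noise_sd: float = 0.05
    sample_times: list[float] = Field(
        default_factory=lambda: [0, 10, 30, 60, 120, 300, 600, 1200, 1800]
    )

    @field_validator("rates")
    @classmethod
    def _pairs_wellformed(cls, v: dict[str, float]) -> dict[str, float]:
        for pair in v:
            if ":" not in pair:
                raise ValueError(f"pair label {pair!r} must be '<hk>:<rr>'")
        return v


class StagesConfig(_StrictModel):
    simulate: bool = True
    pair: bool = True
    modelselect: bool = True
    asr: bool = True
    profile: bool = True
    kinetics: bool = True


class AsrConfig(_StrictModel):
    tau: float = 0.2
    altall: bool = True


class ProfileConfig(_StrictModel):
    f_high: float = 0.9
    f_low: float = 0.1


class KineticsConfig(_StrictModel):
    method: str = "loglinear"
    floor: float = 0.1

    @field_validator("method")
    @classmethod
    def _known_method(cls, v: str) -> str:
        if v not in ("window", "loglinear"):
            raise ValueError(f"method must be 'window' or 'loglinear', got {v!r}")
        return v


class PipelineConfig(_StrictModel):
    seed: int = 0
    stages: StagesConfig = Field(default_factory=StagesConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    asr: AsrConfig = Field(default_factory=AsrConfig)
    profile: ProfileConfig = Field(default_factory=ProfileConfig)
    kinetics: KineticsConfig = Field(default_factory=KineticsConfig)


def load_config(path: "str | Path") -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class RunManifest(dict):
    """JSON-serializable record of one pipeline run."""


def run_pipeline(config: PipelineConfig, outdir: "str | Path") -> RunManifest:
    """Execute the enabled stages in dependency order; write a manifest.

    Returns the manifest (also written to ``manifest.json``); any stage
    failure propagates after the partial manifest is flushed.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config.model_dump(), sort_keys=True)
    manifest: RunManifest = RunManifest(
        tool_version=__version__,
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        config=config.model_dump(),
        stages={},
    )

    def finish_stage(name: str, started: float, outputs: dict[str, Path]) -> None:
        manifest["stages"][name] = {
            "outputs": {k: str(p) for k, p in outputs.items()},
            "digests": {k: _digest(p) for k, p in outputs.items()},
            "wall_time_s": round(time.perf_counter() - started, 3),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    sim_cfg = config.simulate
    scenario: DuplicationScenario | None = None
    sim = None
    clades: dict[str, int] = {}

    try:
        if config.stages.simulate:
            t0 = time.perf_counter()
            tree = duplication_tree(
                sim_cfg.n_leaves_per_clade,
                sim_cfg.mean_branch_length,
                sim_cfg.stem_length,
                seed=config.seed,
            )
            scenario = DuplicationScenario.at_root(
                tree,
                [
                    (p.column, set(p.clade1), set(p.clade2))
                    for p in sim_cfg.planted
                ],
            )
            model = lg_model(sim_cfg.gamma_shape, sim_cfg.n_categories)
            sim, clades = plant_duplication(
                scenario, model, sim_cfg.n_sites, seed=config.seed
            )
            gene_records = simulate_gene_table(
                sim_cfg.n_genomes,
                GenomeLayout(
                    adjacent_pairs=sim_cfg.adjacent_pairs,
                    clusters=sim_cfg.clusters,
                    orphan_hks=sim_cfg.orphan_hks,
                    orphan_rrs=sim_cfg.orphan_rrs,
                ),
                seed=config.seed,
            )
            courses = []
            for i, (pair, kt) in enumerate(sorted(sim_cfg.rates.items())):
                params = KineticParameters(
                    transfer_rate_constant=kt,
                    phosphatase_rate_constant=kt * sim_cfg.phosphatase_ratio,
                    noise_sd=sim_cfg.noise_sd,
                    seed=config.seed * 1000 + i,
                )
                courses.append(
                    simulate_phosphotransfer(
                        params, np.asarray(sim_cfg.sample_times, float), pair=pair
                    )
                )
            outputs = {
                "tree": out / "simulated_tree.nwk",
                "alignment": out / "simulated_alignment.fasta",
                "truth": out / "ancestral_truth.tsv",
                "gene_table": out / "gene_table.tsv",
                "timecourses": out / "timecourses.csv",
                "clades": out / "clade_labels.tsv",
            }
            outputs["tree"].write_text(tree.to_newick() + "\n")
            pio.write_fasta(sim.leaf_alignment, outputs["alignment"])
            pio.write_ancestral_truth_tsv(sim.ancestral_truth, outputs["truth"])
            pio.write_gene_table(gene_records, outputs["gene_table"])
            pio.write_timecourse_csv(courses, outputs["timecourses"])
            outputs["clades"].write_text(
                "leaf\tclade\n"
                + "".join(f"{l}\t{c}\n" for l, c in sorted(clades.items()))
            )
            finish_stage("simulate", t0, outputs)

        if config.stages.pair:
            t0 = time.perf_counter()
            records = pio.read_gene_table(out / "gene_table.tsv")
            pairs, dropped = match_cognate_pairs(records)
            outputs = {
                "pairs": out / "matched_pairs.tsv",
                "dropped": out / "dropped_genes.tsv",
            }
            pio.write_pairs_table(pairs, dropped, outputs["pairs"], outputs["dropped"])
            finish_stage("pair", t0, outputs)

        if config.stages.modelselect:
            t0 = time.perf_counter()
            aln = pio.read_fasta(out / "simulated_alignment.fasta")
            tree = _read_tree(out / "simulated_tree.nwk")
            table = aic_model_selection(
                tree,
                aln,
                [poisson_model(), lg_model(None, sim_cfg.n_categories)],
            )
            outputs = {"model_selection": out / "model_selection.tsv"}
            table.to_csv(outputs["model_selection"], sep="\t", index=False)
            finish_stage("modelselect", t0, outputs)

        if config.stages.asr:
            t0 = time.perf_counter()
            aln = pio.read_fasta(out / "simulated_alignment.fasta")
            tree = _read_tree(out / "simulated_tree.nwk")
            model = lg_model(sim_cfg.gamma_shape, sim_cfg.n_categories)
            # the duplication node and the two post-duplication ancestors
            nodes = [tree.root_id] + tree.children_ids(tree.root_id)
            nodes = [n for n in nodes if n in tree.internal_ids]
            posteriors = marginal_posteriors(tree, aln, model, nodes)
            maps = [map_ancestor(p) for p in posteriors]
            outputs = {
                "posteriors": out / "asr_posteriors.tsv",
                "map_fasta": out / "asr_map.fasta",
                "confidence": out / "asr_confidence.tsv",
            }
            pio.write_posteriors_tsv(posteriors, outputs["posteriors"])
            pio.write_fasta(
                Alignment([(m.node_id, m.map_sequence) for m in maps]),
                outputs["map_fasta"],
            )
            pio.write_ancestor_confidence_tsv(maps, outputs["confidence"])
            if config.asr.altall:
                alts = [altall_ancestor(p, config.asr.tau) for p in posteriors]
                outputs["altall_fasta"] = out / "asr_altall.fasta"
                pio.write_fasta(
                    Alignment([(a.node_id, a.sequence) for a in alts]),
                    outputs["altall_fasta"],
                )
            finish_stage("asr", t0, outputs)

        if config.stages.profile:
            t0 = time.perf_counter()
            aln = pio.read_fasta(out / "simulated_alignment.fasta")
            clade_rows = [
                line.split("\t")
                for line in (out / "clade_labels.tsv").read_text().splitlines()[1:]
            ]
            clade1 = [l for l, c in clade_rows if c == "1"]
            clade2 = [l for l, c in clade_rows if c == "2"]
            f1 = position_frequencies(aln, clade1)
            f2 = position_frequencies(aln, clade2)
            calls = paralog_specific_positions(
                f1, f2, config.profile.f_high, config.profile.f_low
            )
            outputs = {"position_calls": out / "position_calls.tsv"}
            import pandas as pd

            pd.DataFrame([vars(c) for c in calls]).to_csv(
                outputs["position_calls"], sep="\t", index=False
            )
            finish_stage("profile", t0, outputs)

        if config.stages.kinetics:
            t0 = time.perf_counter()
            courses = pio.read_timecourse_csv(out / "timecourses.csv")
            hks = sorted({tc.hk for tc in courses})
            cognate = frozenset(
                (hk, rr)
                for hk, rr in ((tc.hk, tc.rr) for tc in courses)
                if hk[-1] == rr[-1]  # matching index convention HKi:RRi
            )
            design = MatrixDesign(cognate_pairs=cognate)
            table = specificity_matrix(
                courses,
                design,
                method=config.kinetics.method,
                floor=config.kinetics.floor,
            )
            outputs = {"specificity_matrix": out / "specificity_matrix.tsv"}
            table.to_csv(outputs["specificity_matrix"], sep="\t", index=False)
            finish_stage("kinetics", t0, outputs)
    except Exception:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    return manifest


def _read_tree(path: Path):
    from .tree import PhylogeneticTree

    return PhylogeneticTree.from_newick(path.read_text())
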