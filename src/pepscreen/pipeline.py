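"""End-to-end orchestration: design → layout → simulate → quantify → analyze → motifs.

A run is described by a YAML config (validated with pydantic); every stage
seed derives deterministically from the master seed, so identical configs
produce byte-identical outputs. Stage outputs are plain text files, each
stamped with the hash of the config that produced it, so any stage can be
re-run standalone from prior outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .array_layout import ArrayLayout, GridSpec, build_layout, serialize_layout
from .constants import BLANK_ID, PARENT_PEPTIDES
from .library_design import (
    LibraryConfig,
    assemble_library,
    library_to_frame,
    read_fasta,
    write_library,
)
from .motif_mapper import export_residue_track, infer_minimal_motifs, window_track
from .quantification import quantifications_from_table, quantify_spots
from .scan_simulator import (
    AdhesionModel,
    RenderParams,
    assign_latent_adhesion,
    random_proteins,
    render_scan_image,
    simulate_intensity_table,
    write_intensity_table,
    write_scan_image,
)
from .screen_analysis import (
    PropertyScales,
    aggregate_replicates,
    blank_floor_threshold,
    compute_property_profile,
    correlate_properties,
    detect_extremes,
    intensity_map,
    measurements_to_frame,
    rank_curve,
)
from .substitution_analysis import build_substitution_matrix, find_critical_substitutions

logger = logging.getLogger("pepscreen")


class ProteinsConfig(BaseModel):
    fasta: Optional[str] = None
    synthetic_lengths: list[int] = [314, 266, 233]


class LibraryBlock(BaseModel):
    k: int = 15
    step: int = 1
    replicates_scan: int = 5
    replicates_substitution: int = 3
    replicates_random: int = 2
    replicates_control: int = 5
    n_random: int = 9818
    include_parents: bool = True
    n_blank: int = 100


class GridBlock(BaseModel):
    s_pixel_um: float = 30.0
    spot_side_spx: int = 4
    grid_rows: Optional[int] = None  # None: auto-size square with ~3% blank fill
    grid_cols: Optional[int] = None


class AdhesionBlock(BaseModel):
    median_intensity: float = 3000.0
    sigma_base: float = 1.0
    sigma_rep: float = 0.1
    background: float = 300.0
    adhesive_margin: float = 4.0
    n_planted_repulsive: int = 0
    n_planted_adhesive: int = 0
    control_adhesive: bool = True  # plant the HA control at the adhesive extreme


class ImageBlock(BaseModel):
    enabled: bool = False
    um_per_pixel: float = 6.0
    cells_per_intensity: float = 0.35
    cell_radius_um: float = 7.0
    cell_brightness: float = 250.0
    noise_sd: float = 20.0
    lawn_cells_per_mm2: float = 0.0


class AnalysisBlock(BaseModel):
    q_low: float = 0.05
    q_high: float = 0.95
    gradient_factor: float = 3.0
    fallback: Literal["none", "quantile"] = "none"
    n_permutations: int = 499
    charge_scale: str = "charge_default"
    mw_scale: str = "residue_mass_average"
    hydrophobicity_scale: str = "kyte_doolittle"
    helix_scale: str = "pace_scholtz"


class RunConfig(BaseModel):
    """Full pipeline configuration; round-trips through YAML."""

    seed: int = 0
    proteins: ProteinsConfig = Field(default_factory=ProteinsConfig)
    parents: list[str] = list(PARENT_PEPTIDES)
    library: LibraryBlock = Field(default_factory=LibraryBlock)
    grid: GridBlock = Field(default_factory=GridBlock)
    adhesion: AdhesionBlock = Field(default_factory=AdhesionBlock)
    image: ImageBlock = Field(default_factory=ImageBlock)
    measurement_source: Literal["table", "image"] = "table"
    analysis: AnalysisBlock = Field(default_factory=AnalysisBlock)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)

    def config_hash(self) -> str:
        canonical = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def demo_config(seed: int = 0) -> RunConfig:
    """A small synthetic end-to-end run (minutes of CPU at most)."""
    return RunConfig(
        seed=seed,
        proteins=ProteinsConfig(synthetic_lengths=[80, 60, 50]),
        parents=["NRWHE", "NGWQG"],
        library=LibraryBlock(n_random=300, n_blank=40),
        adhesion=AdhesionBlock(n_planted_repulsive=15, n_planted_adhesive=5),
        image=ImageBlock(enabled=True, um_per_pixel=6.0),
        measurement_source="table",
    )


def _derive_seeds(master: int, n: int) -> list[int]:
    root = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(n)]


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages, write every artifact under *outdir*, return the report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(outdir / "run.log")
    logger.addHandler(fh)
    chash = config.config_hash()
    stamp = f"config_hash={chash}"
    seeds = _derive_seeds(config.seed, 6)
    (s_proteins, s_library, s_plant, s_layout, s_table, s_image) = seeds
    report: dict = {
        "pepscreen_version": __version__,
        "config_hash": chash,
        "master_seed": config.seed,
        "stage_seeds": {
            "proteins": s_proteins,
            "library": s_library,
            "planting": s_plant,
            "layout": s_layout,
            "intensity_table": s_table,
            "image": s_image,
        },
        "parameters": config.model_dump(),
    }

    current_stage = {"name": "init"}

    def stage(name):
        current_stage["name"] = name
        logger.info("stage: %s", name)

    try:
        stage("design")
        if config.proteins.fasta:
            proteins = read_fasta(config.proteins.fasta)
        else:
            proteins = random_proteins(config.proteins.synthetic_lengths, seed=s_proteins)
        lib_cfg = LibraryConfig(
            k=config.library.k,
            step=config.library.step,
            replicates_scan=config.library.replicates_scan,
            replicates_substitution=config.library.replicates_substitution,
            replicates_random=config.library.replicates_random,
            replicates_control=config.library.replicates_control,
            n_random=config.library.n_random,
            include_parents=config.library.include_parents,
            n_blank=config.library.n_blank,
            seed=s_library,
        )
        library, lib_report = assemble_library(lib_cfg, proteins, config.parents)
        write_library(library, outdir / "library.tsv", header_comment=stamp)
        report["library"] = {
            k: v for k, v in lib_report.items() if k != "duplicate_sequences"
        }
        report["library"]["n_duplicate_sequences"] = lib_report["n_duplicate_sequences"]

        stage("planting")
        rng = np.random.default_rng(s_plant)
        plantable = [
            e.peptide_id for e in library if e.group in ("scan", "substitution", "random")
        ]
        n_rep = config.adhesion.n_planted_repulsive
        n_adh = config.adhesion.n_planted_adhesive
        if n_rep + n_adh > len(plantable):
            raise ValueError("more planted peptides requested than library entries")
        chosen = rng.choice(len(plantable), size=n_rep + n_adh, replace=False)
        planted_repulsive = frozenset(plantable[i] for i in chosen[:n_rep])
        planted_adhesive = set(plantable[i] for i in chosen[n_rep:])
        if config.adhesion.control_adhesive:
            planted_adhesive |= {e.peptide_id for e in library if e.group == "control"}
        report["planted"] = {
            "repulsive": sorted(planted_repulsive),
            "adhesive": sorted(planted_adhesive),
        }

        stage("layout")
        total_spots = sum(e.replicates for e in library)
        rows, cols = config.grid.grid_rows, config.grid.grid_cols
        if rows is None or cols is None:
            side = int(np.ceil(np.sqrt(total_spots / 0.97)))
            rows = rows or side
            cols = cols or side
        grid = GridSpec(
            s_pixel_um=config.grid.s_pixel_um,
            spot_side_spx=config.grid.spot_side_spx,
            grid_rows=rows,
            grid_cols=cols,
            seed=s_layout,
        )
        layout = build_layout(library, grid, seed=s_layout)
        serialize_layout(layout, outdir / "layout.gal.tsv", header_comment=stamp)

        stage("simulate")
        adhesion = assign_latent_adhesion(
            library,
            planted_repulsive=planted_repulsive,
            planted_adhesive=planted_adhesive,
            median_intensity=config.adhesion.median_intensity,
            sigma_base=config.adhesion.sigma_base,
            sigma_rep=config.adhesion.sigma_rep,
            background=config.adhesion.background,
            adhesive_margin=config.adhesion.adhesive_margin,
            seed=s_table,
        )
        truth = library_to_frame(library)[["peptide_id", "group"]]
        truth["latent_adhesion"] = [adhesion.a[p] for p in truth["peptide_id"]]
        with open(outdir / "ground_truth.tsv", "w") as f:
            f.write(f"# {stamp}\n")
            truth.to_csv(f, sep="\t", index=False)
        table = simulate_intensity_table(layout, adhesion, seed=s_table)
        write_intensity_table(table, outdir / "intensities.gpr.tsv", header_comment=stamp)

        blank_lib_ids = frozenset(e.peptide_id for e in library if e.group == "blank")
        if config.image.enabled or config.measurement_source == "image":
            stage("render+quantify")
            params = RenderParams(
                um_per_pixel=config.image.um_per_pixel,
                cells_per_intensity=config.image.cells_per_intensity,
                cell_radius_um=config.image.cell_radius_um,
                cell_brightness=config.image.cell_brightness,
                noise_sd=config.image.noise_sd,
                lawn_cells_per_mm2=config.image.lawn_cells_per_mm2,
            )
            image = render_scan_image(layout, adhesion, params, seed=s_image)
            write_scan_image(image, outdir / "scan.tif", description=stamp)
            image_quants = quantify_spots(image, layout, blank_ids=blank_lib_ids)
        else:
            image_quants = None

        stage("quantify")
        if config.measurement_source == "image":
            quants = image_quants
        else:
            quants = quantifications_from_table(table)

        stage("analyze")
        measurements, dropped = aggregate_replicates(quants, blank_ids=blank_lib_ids)
        mframe = measurements_to_frame(measurements)
        with open(outdir / "measurements.tsv", "w") as f:
            f.write(f"# {stamp}\n")
            mframe.to_csv(f, sep="\t", index=False)
        peptide_meas = [m for m in measurements if m.peptide_id != BLANK_ID]
        curve = rank_curve(peptide_meas)
        calls, det_report = detect_extremes(
            curve,
            q_low=config.analysis.q_low,
            q_high=config.analysis.q_high,
            gradient_factor=config.analysis.gradient_factor,
            fallback=config.analysis.fallback,
        )
        with open(outdir / "extreme_calls.tsv", "w") as f:
            f.write(f"# {stamp}\n")
            f.write("peptide_id\tside\trank\tintensity\n")
            for c in calls:
                f.write(f"{c.peptide_id}\t{c.side}\t{c.rank}\t{c.intensity:.6g}\n")
        report["extreme_detection"] = det_report
        report["extreme_calls"] = {
            "repulsive": sorted(c.peptide_id for c in calls if c.side == "repulsive"),
            "adhesive": sorted(c.peptide_id for c in calls if c.side == "adhesive"),
        }

        scales = PropertyScales(
            charge=config.analysis.charge_scale,
            mw=config.analysis.mw_scale,
            hydrophobicity=config.analysis.hydrophobicity_scale,
            helix=config.analysis.helix_scale,
        )
        seq_by_id = {e.peptide_id: e.sequence for e in library if e.group != "blank"}
        profiles = [
            compute_property_profile(seq_by_id[m.peptide_id], scales, peptide_id=m.peptide_id)
            for m in peptide_meas
            if m.peptide_id in seq_by_id
        ]
        correlations, scatter = correlate_properties(
            peptide_meas,
            profiles,
            n_permutations=config.analysis.n_permutations,
            seed=config.seed,
        )
        for name, frame in (("property_correlations", correlations), ("property_scatter", scatter)):
            with open(outdir / f"{name}.tsv", "w") as f:
                f.write(f"# {stamp}\n")
                frame.to_csv(f, sep="\t", index=False)
        report["property_correlations"] = correlations.to_dict(orient="records")

        stage("substitution")
        blank_m = [m for m in measurements if m.peptide_id == BLANK_ID]
        imap = intensity_map(measurements)
        if blank_m:
            threshold = blank_floor_threshold(blank_m[0].replicate_intensities)
        else:
            threshold = config.adhesion.background
        report["repulsion_threshold"] = threshold
        report["critical_substitutions"] = {}
        for parent in config.parents:
            try:
                smatrix = build_substitution_matrix(parent, library, imap)
            except ValueError:
                continue
            mat_frame = pd.DataFrame(
                smatrix.matrix, columns=list("ACDEFGHIKLMNPQRSTVWY")
            )
            mat_frame.insert(0, "position", range(1, len(smatrix.parent) + 1))
            mat_frame.insert(1, "parent_residue", list(smatrix.parent))
            with open(outdir / f"substitution_{parent}.tsv", "w") as f:
                f.write(f"# {stamp}\n")
                mat_frame.to_csv(f, sep="\t", index=False)
            crit = find_critical_substitutions(smatrix, threshold)
            report["critical_substitutions"][parent] = [
                {"pos": c.pos, "residue": c.residue, "intensity": c.intensity, "specific": c.specific}
                for c in crit
            ]

        stage("motifs")
        report["motif_calls"] = {}
        for protein in proteins:
            track = window_track(protein, imap, library, k=config.library.k)
            track.set_flags(threshold, side="repulsive")
            motif_calls = infer_minimal_motifs(track, protein)
            export_residue_track(
                motif_calls,
                protein,
                outdir / f"motifs_{protein.id}.bed",
                outdir / f"residues_{protein.id}.tsv",
                header_comment=stamp,
            )
            report["motif_calls"][protein.id] = [
                {
                    "motif": c.motif,
                    "start": c.start,
                    "end": c.end,
                    "run_length": c.run_length,
                    "mean_intensity": c.mean_intensity,
                    "empty_core": c.empty_core,
                }
                for c in motif_calls
            ]

        with open(outdir / "report.json", "w") as f:
            json.dump(report, f, indent=2)
        return report
    except Exception as exc:
        logger.error("pipeline aborted in stage %s: %s", current_stage["name"], exc)
        raise RuntimeError(
            f"pipeline stage {current_stage['name']!r} failed: {exc}"
        ) from exc
    finally:
        logger.removeHandler(fh)
        fh.close()
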