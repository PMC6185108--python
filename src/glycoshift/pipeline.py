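"""End-to-end orchestration: simulate/load -> annotate -> differential ->
cross-reference -> enrichment -> report.

``run_pipeline`` executes the stages in order, writes every stage output as a
tab-separated file under ``out_dir`` together with the resolved configuration,
and returns a :class:`PipelineReport` whose counts are all reconstructible
from those files. Logging (with stage timing) goes to standard error and never
into result files, so two runs with the same config and seed produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import core_io, crossref, differential, enrichment, sequons, simulate
from .core_io import QuantMatrix, SiteKey
from .differential import DECREASED, EXCLUSIVE_CONTROL, EXCLUSIVE_MUTANT, INCREASED

logger = logging.getLogger("glycoshift")


class PipelineStageError(RuntimeError):
    """An error in a named pipeline stage (the cause is chained)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything a run needs; written next to the outputs as YAML."""

    out_dir: str = "glycoshift_out"
    seed: int = 0
    # synthetic mode: when set, inputs are generated instead of read
    synthetic: bool = True
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    # file mode inputs (ignored when synthetic=True)
    fasta: str | None = None
    design_table: str | None = None
    protein_table: str | None = None
    glyco_table: str | None = None
    unmodified_table: str | None = None
    known_site_lists: list[str] = field(default_factory=list)
    annotation_table: str | None = None  # two columns: label, protein_id
    # thresholds
    alpha_q: float = 0.05
    alpha_p: float = 0.05
    min_control: int = 3
    min_exclusive: int = 3
    min_control_detections_reference: int = 2
    crossref_k: int = 3
    multiplicity_thresholds: tuple[int, ...] = (1, 2, 3, 4)
    correlation_min_bin_size: int = 3
    correlation_cap: int = 8
    correlation_mode: str = "fraction_of_nxs"
    normalize: bool = False
    equal_var: bool = False

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["multiplicity_thresholds"] = list(self.multiplicity_thresholds)
        # the output location is run metadata, not an analysis parameter:
        # leaving it out keeps resolved configs identical across runs
        data.pop("out_dir")
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        sim_data = data.pop("sim", {})
        cfg = cls(**{**data, "sim": simulate.SimConfig(**sim_data)})
        cfg.multiplicity_thresholds = tuple(cfg.multiplicity_thresholds)
        return cfg


@dataclass
class PipelineReport:
    """Counts and statistics summarizing one run (mirrors the output files)."""

    config: PipelineConfig
    counts: dict[str, Any] = field(default_factory=dict)
    enrichments: dict[str, Any] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    # in-memory handles to the stage outputs
    protein_results: pd.DataFrame | None = None
    glyco_results: pd.DataFrame | None = None
    occupancy_calls: pd.DataFrame | None = None
    profiles: pd.DataFrame | None = None
    reference_sites: list = field(default_factory=list)
    correlation: dict | None = None
    motifs: enrichment.MotifAnalysis | None = None

    def to_json_dict(self) -> dict:
        return {
            "counts": self.counts,
            "enrichments": self.enrichments,
            "skipped": self.skipped,
        }


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                logger.error("stage %s: FAILED (%s)", name, exc)
                raise PipelineStageError(name, exc) from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return result

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(config=config)

    proteins, design, matrices, known_lists, annotations = _acquire_inputs(
        config, out_dir
    )
    protein_matrix, glyco_matrix, unmodified_matrix = matrices
    by_id = core_io.proteins_by_id(proteins)

    reference, profiles, novelty = _annotate(
        config, glyco_matrix, by_id, known_lists, out_dir
    )
    report.reference_sites = reference
    report.profiles = profiles
    report.counts["n_reference_sites"] = len(reference)
    report.counts["n_glycoproteins"] = int((profiles["multiplicity"] >= 1).sum())
    report.counts["novelty"] = dataclasses.asdict(novelty)

    protein_results, glyco_results, partition_counts = _differential(
        config, protein_matrix, glyco_matrix, out_dir
    )
    report.protein_results = protein_results
    report.glyco_results = glyco_results
    report.counts["total_proteome"] = {
        "n_quantified": len(protein_matrix),
        "n_complete_case": int(len(protein_results)),
        "n_filtered_out": len(protein_matrix) - int(len(protein_results)),
        "status": _status_counts(protein_results),
    }
    report.counts["glyco"] = {
        "n_features": len(glyco_matrix),
        "partition": partition_counts,
        "status": _status_counts(glyco_results),
    }

    if unmodified_matrix is not None:
        calls, call_summary = _crossref(
            config, glyco_results, unmodified_matrix, protein_results, out_dir
        )
        report.occupancy_calls = calls
        report.counts["occupancy_calls"] = call_summary
    else:
        report.skipped["crossref"] = "no unmodified-peptide table provided"

    _enrich(config, report, reference, profiles, annotations, out_dir)

    _write_report(report, out_dir)
    config.to_yaml(out_dir / "config_resolved.yaml")
    return report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

@_stage("inputs")
def _acquire_inputs(config: PipelineConfig, out_dir: Path):
    if config.synthetic:
        sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
        data = simulate.simulate_dataset(sim_cfg)
        exp = data.experiment
        core_io.write_fasta(data.proteins, out_dir / "proteins.fasta")
        core_io.write_design_table(exp.design, out_dir / "design.tsv")
        core_io.write_quant_table(exp.protein_matrix, out_dir / "total_quant.tsv")
        core_io.write_quant_table(exp.glyco_matrix, out_dir / "glyco_quant.tsv")
        core_io.write_quant_table(exp.unmodified_matrix, out_dir / "unmodified_quant.tsv")
        truth_sites = data.truth.sites.reset_index()
        core_io.write_results(truth_sites, out_dir / "truth_sites.tsv")
        core_io.write_results(
            data.truth.proteins.reset_index(), out_dir / "truth_proteins.tsv"
        )
        core_io.write_known_sites(data.known_sites, out_dir / "known_sites.tsv")
        return (
            data.proteins,
            exp.design,
            (exp.protein_matrix, exp.glyco_matrix, exp.unmodified_matrix),
            [data.known_sites],
            {},
        )

    for name in ("fasta", "design_table", "protein_table", "glyco_table"):
        if getattr(config, name) is None:
            raise FileNotFoundError(f"input {name!r} is required when simulation is off")
    proteins = core_io.read_fasta(config.fasta)
    design = core_io.read_design_table(config.design_table)
    protein_matrix = core_io.read_quant_table(config.protein_table, design, "protein")
    glyco_matrix = core_io.read_quant_table(config.glyco_table, design, "glycosite")
    unmodified = (
        core_io.read_quant_table(config.unmodified_table, design, "unmodified_peptide")
        if config.unmodified_table
        else None
    )
    known_lists = [core_io.read_known_sites(p) for p in config.known_site_lists]
    annotations = (
        _read_annotations(config.annotation_table) if config.annotation_table else {}
    )
    return proteins, design, (protein_matrix, glyco_matrix, unmodified), known_lists, annotations


def _read_annotations(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise core_io.ParseError(f"{path}: annotation table needs columns label, protein_id")
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row[0]), set()).add(str(row[1]))
    return out


@_stage("annotate")
def _annotate(config, glyco_matrix, by_id, known_lists, out_dir: Path):
    reference = sequons.build_reference_glycoproteome(
        glyco_matrix, by_id, config.min_control_detections_reference
    )
    reference, novelty = sequons.call_novel_sites(reference, known_lists)
    profiles = sequons.multiplicity_profiles(reference, by_id)
    core_io.write_results(sequons.sites_table(reference), out_dir / "reference_sites.tsv")
    core_io.write_results(
        profiles.reset_index(), out_dir / "multiplicity_profiles.tsv"
    )
    return reference, profiles, novelty


@_stage("differential")
def _differential(config, protein_matrix, glyco_matrix, out_dir: Path):
    complete, _dropped = differential.filter_complete_cases(protein_matrix)
    protein_results = differential.paired_protein_test(
        complete, alpha_q=config.alpha_q, normalize=config.normalize
    )
    partition, glyco_results = differential.partition_and_test(
        glyco_matrix,
        min_control=config.min_control,
        min_exclusive=config.min_exclusive,
        alpha_p=config.alpha_p,
        equal_var=config.equal_var,
    )
    core_io.write_results(protein_results, out_dir / "protein_differential.tsv")
    core_io.write_results(glyco_results, out_dir / "glyco_differential.tsv")
    return protein_results, glyco_results, partition.counts()


@_stage("crossref")
def _crossref(config, glyco_results, unmodified_matrix, protein_results, out_dir: Path):
    calls, summary = crossref.crossref_occupancy(
        glyco_results, unmodified_matrix, protein_results, k=config.crossref_k
    )
    core_io.write_results(calls, out_dir / "occupancy_calls.tsv")
    return calls, summary


@_stage("enrich")
def _enrich(config, report: PipelineReport, reference, profiles, annotations, out_dir: Path):
    protein_results = report.protein_results
    glyco_results = report.glyco_results
    rows = []

    def record(name: str, result: enrichment.EnrichmentResult) -> None:
        report.enrichments[name] = result.as_row()
        rows.append({"analysis": name, **result.as_row()})

    glyco_ids = set(profiles.index[profiles["multiplicity"] >= 1])
    tested = protein_results["feature_id"]
    tested_glyco = [p for p in tested if p in glyco_ids]
    decreased_proteins = [
        p
        for p, s in zip(protein_results["feature_id"], protein_results["status"])
        if s == DECREASED
    ]
    decreased_glyco = [p for p in decreased_proteins if p in glyco_ids]

    # glycoprotein enrichment among decreased proteins (total proteome)
    if decreased_proteins:
        record(
            "glycoprotein_in_decreased_proteins",
            enrichment.fisher_enrichment(
                set_hits=len(decreased_glyco),
                set_total=len(decreased_proteins),
                bg_hits=len(tested_glyco),
                bg_total=len(tested),
            ),
        )
    else:
        report.skipped["glycoprotein_in_decreased_proteins"] = "no decreased proteins"

    # multiplicity means and threshold enrichment among decreased glycoproteins
    unchanged_glyco = [
        p
        for p, s in zip(protein_results["feature_id"], protein_results["status"])
        if s not in (DECREASED, INCREASED) and p in glyco_ids
    ]
    if decreased_glyco and unchanged_glyco:
        cmp = enrichment.multiplicity_group_test(
            profiles.loc[decreased_glyco, "multiplicity"],
            profiles.loc[unchanged_glyco, "multiplicity"],
        )
        report.enrichments["protein_multiplicity_comparison"] = dataclasses.asdict(cmp)
        for k, res in enrichment.multiplicity_enrichment(
            decreased_glyco,
            profiles.loc[tested_glyco],
            thresholds=config.multiplicity_thresholds,
        ).items():
            record(f"protein_multiplicity_ge{k}_in_decreased", res)
    else:
        report.skipped["protein_multiplicity"] = "no decreased or no unchanged glycoproteins"

    # glyco-branch site sets (decreased = decreased + exclusive_control)
    status_by_site = dict(zip(glyco_results["feature_id"], glyco_results["status"]))
    decreased_sites = [
        s for s in reference if status_by_site.get(str(s.key)) in (DECREASED, EXCLUSIVE_CONTROL)
    ]
    increased_sites = [
        s for s in reference if status_by_site.get(str(s.key)) in (INCREASED, EXCLUSIVE_MUTANT)
    ]
    dec_keys = {s.key for s in decreased_sites} | {s.key for s in increased_sites}
    unchanged_sites = [s for s in reference if s.key not in dec_keys]

    # per-protein contrast of multiplicity (proteins with a decreased site)
    dec_site_proteins = sorted({s.protein_id for s in decreased_sites})
    other_glyco = sorted(glyco_ids - set(dec_site_proteins))
    if dec_site_proteins and other_glyco:
        cmp = enrichment.multiplicity_group_test(
            profiles.loc[dec_site_proteins, "multiplicity"],
            profiles.loc[other_glyco, "multiplicity"],
        )
        report.enrichments["site_level_multiplicity_comparison"] = dataclasses.asdict(cmp)
    else:
        report.skipped["site_level_multiplicity_comparison"] = "a group is empty"

    # sequon motif enrichment and the NxS/multiplicity correlation
    if decreased_sites and unchanged_sites:
        motifs = enrichment.sequon_position_enrichment(decreased_sites, unchanged_sites)
        report.motifs = motifs
        core_io.write_results(motifs.table(), out_dir / "motif_enrichment.tsv")
        core_io.write_results(
            motifs.logo_decreased.reset_index(), out_dir / "logo_decreased.tsv"
        )
        core_io.write_results(
            motifs.logo_unchanged.reset_index(), out_dir / "logo_unchanged.tsv"
        )
        report.enrichments["motif_headline"] = {
            f"{m.position}:{m.feature}": {
                "fold_enrichment": m.fold_enrichment,
                "p_value": m.p_value,
            }
            for m in motifs.features
            if (m.position, m.feature) in ((-2, "non_aromatic"), (2, "S"))
        }
        try:
            corr = enrichment.nxs_multiplicity_correlation(
                decreased_sites,
                unchanged_sites,
                profiles,
                min_bin_size=config.correlation_min_bin_size,
                cap=config.correlation_cap,
                mode=config.correlation_mode,
            )
            report.correlation = corr
            report.enrichments["nxs_multiplicity_correlation"] = {
                name: {"r": c.r, "p_value": c.p_value, "n_bins": c.n_bins}
                for name, c in corr.items()
            }
            pts = []
            for name, c in corr.items():
                pts.extend(
                    {"series": name, "multiplicity_bin": x, "percentage": y}
                    for x, y in c.points
                )
            core_io.write_results(pd.DataFrame(pts), out_dir / "correlation_points.tsv")
        except ValueError as exc:
            report.skipped["nxs_multiplicity_correlation"] = str(exc)
    else:
        report.skipped["motifs"] = "no decreased or no unchanged glycosites"

    # annotation-set enrichment among decreased glycosites
    all_sites = [str(s.key) for s in reference]
    feature_to_protein = {str(s.key): s.protein_id for s in reference}
    for label, members in sorted(annotations.items()):
        try:
            record(
                f"annotation_{label}_in_decreased_sites",
                enrichment.annotation_set_enrichment(
                    [str(s.key) for s in decreased_sites],
                    all_sites,
                    members,
                    feature_to_protein,
                ),
            )
        except ValueError as exc:
            report.skipped[f"annotation_{label}"] = str(exc)

    if rows:
        core_io.write_results(pd.DataFrame(rows), out_dir / "enrichment_summary.tsv")


def _status_counts(results: pd.DataFrame) -> dict[str, int]:
    return {k: int(v) for k, v in sorted(results["status"].value_counts().items())}


def _write_report(report: PipelineReport, out_dir: Path) -> None:
    payload = report.to_json_dict()
    (out_dir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))
    lines = ["glycoshift pipeline report", "=" * 26, ""]
    lines.append(json.dumps(payload, indent=2, sort_keys=True, default=float))
    (out_dir / "report.txt").write_text("\n".join(lines) + "\n")
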