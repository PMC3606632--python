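"""End-to-end orchestration: simulate -> extract -> map -> annotate -> de ->
enrich -> validate, with a JSON run manifest and stage-level resume.

Each stage reads its inputs from the previous stage's files under the run
directory (never from in-memory state), so a rerun can resume from the last
completed stage: a stage is skipped when the manifest marks it complete and
every recorded output file still exists with its recorded checksum. A single
global seed is fanned out to the stochastic stages by fixed offsets.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from collections import defaultdict
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .genes import GeneModel, read_gff3, write_gff3
from .layout import DitagLayout
from .simulate import (SyntheticGenomeSpec, generate_genome, simulate_truth,
                       simulate_reads, simulate_functional_annotations,
                       write_fasta, write_fastq, write_truth)
from . import ditags as dt
from . import mapping as mp
from . import annotation as an
from . import expression as ex
from . import enrichment as en
from . import validation as va

logger = logging.getLogger(__name__)

STAGES = ("simulate", "extract", "map", "annotate", "de", "enrich", "validate")
STAGE_LABELS = ("Myc", "S1-Pri")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: str = "sagelight_run"
    seed: int = 0
    stage_labels: Tuple[str, str] = STAGE_LABELS
    # synthetic inputs (used when no external paths are given)
    genome: SyntheticGenomeSpec = field(default_factory=SyntheticGenomeSpec)
    deg_fraction: float = 1 / 3
    fold_range: Tuple[float, float] = (3.0, 8.0)
    antisense_fraction: float = 0.15
    n_reads_per_stage: Tuple[int, int] = (3000, 4000)
    error_rate: float = 0.0
    layout: DitagLayout = field(default_factory=DitagLayout)
    # processing parameters
    min_mean_q: float = 20.0
    min_base_q: int = 10
    drop_singletons: bool = True
    de: ex.DeConfig = field(default_factory=ex.DeConfig)
    # optional external inputs (paths); synthetic stand-ins are generated
    # when these are None
    domain_table: Optional[str] = None
    homology_dir: Optional[str] = None
    fruiting_body_species: Tuple[str, ...] = ()
    platform_panel: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "genome" in kwargs:
            kwargs["genome"] = SyntheticGenomeSpec(**_tupled(kwargs["genome"]))
        if "layout" in kwargs:
            kwargs["layout"] = DitagLayout(**_tupled(kwargs["layout"]))
        if "de" in kwargs:
            kwargs["de"] = ex.DeConfig(**kwargs["de"])
        for key in ("stage_labels", "fold_range", "n_reads_per_stage",
                    "fruiting_body_species"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        unknown = set(kwargs) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def validate(self) -> None:
        """Check referenced paths and parameter blocks before any compute."""
        for name in ("domain_table", "homology_dir", "platform_panel"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config {name}: {p} does not exist")
        if self.error_rate < 0 or self.error_rate > 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        if min(self.n_reads_per_stage) <= 0:
            raise ValueError("n_reads_per_stage must be positive")
        # dataclass __post_init__ validation already ran for nested blocks


def _tupled(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        if path.exists():
            with open(path) as fh:
                self.data = json.load(fh)
        else:
            self.data = {"version": __version__, "stages": {}}

    def stage_complete(self, stage: str) -> bool:
        rec = self.data["stages"].get(stage)
        if not rec or rec.get("status") != "complete":
            return False
        for fname, digest in rec.get("outputs", {}).items():
            p = self.path.parent / fname
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    def record(self, stage: str, outputs: List[Path], info: dict) -> None:
        root = self.path.parent
        self.data["stages"][stage] = {
            "status": "complete",
            "outputs": {str(p.relative_to(root)): _sha256(p) for p in outputs},
            "info": info,
            "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self.save()

    def save(self) -> None:
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages in dependency order, resuming from the manifest.

    Returns the manifest dictionary. Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")
    manifest.data["seed"] = config.seed
    manifest.data["parameters"] = _config_summary(config)

    handlers: Dict[str, callable] = {
        "simulate": _stage_simulate, "extract": _stage_extract,
        "map": _stage_map, "annotate": _stage_annotate, "de": _stage_de,
        "enrich": _stage_enrich, "validate": _stage_validate,
    }
    for stage in STAGES:
        if manifest.stage_complete(stage):
            logger.info("stage %s: up to date, skipping", stage)
            continue
        logger.info("stage %s: running", stage)
        try:
            outputs, info = handlers[stage](config, out)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        manifest.record(stage, outputs, info)
    return manifest.data


def _config_summary(config: RunConfig) -> dict:
    d = asdict(config)
    return json.loads(json.dumps(d, default=str))


def _labels(config: RunConfig):
    return config.stage_labels


def _slug(label: str) -> str:
    return label.lower().replace("-", "").replace(" ", "_")


# --- stages ----------------------------------------------------------------

def _stage_simulate(config: RunConfig, out: Path):
    genome, models = generate_genome(config.genome)
    truths = simulate_truth(
        models, deg_fraction=config.deg_fraction, fold_range=config.fold_range,
        seed=config.seed + 1, antisense_fraction=config.antisense_fraction)
    sim = simulate_reads(
        genome, models, truths, layout=config.layout,
        n_reads_per_stage=config.n_reads_per_stage,
        error_rate=config.error_rate, seed=config.seed + 2,
        stage_labels=config.stage_labels)
    d = out / "simulate"
    d.mkdir(exist_ok=True)
    write_fasta(genome, d / "genome.fa")
    with open(d / "models.gff3", "w") as fh:
        write_gff3(models, fh)
    la, lb = (_slug(s) for s in config.stage_labels)
    write_fastq(sim.reads_myc, d / f"reads_{la}.fastq")
    write_fastq(sim.reads_pri, d / f"reads_{lb}.fastq")
    write_truth(sim.truth, d / "truth.tsv")
    truth_rows = len(sim.truth)
    outputs = [d / "genome.fa", d / "models.gff3", d / f"reads_{la}.fastq",
               d / f"reads_{lb}.fastq", d / "truth.tsv"]
    return outputs, {"genes": len(models), "truth_rows": truth_rows,
                     "reads": list(config.n_reads_per_stage)}


def _stage_extract(config: RunConfig, out: Path):
    d = out / "extract"
    d.mkdir(exist_ok=True)
    outputs, info = [], {}
    for label in _labels(config):
        slug = _slug(label)
        stats = dt.ProcessingStats()
        reads = dt.read_fastq(out / "simulate" / f"reads_{slug}.fastq")
        passed = dt.quality_filter(reads, config.min_mean_q, config.min_base_q,
                                   stats=stats)
        tags = dt.extract_library(passed, config.layout, stats=stats)
        table = dt.collapse_and_filter(tags, stage=label,
                                       drop_singletons=config.drop_singletons,
                                       stats=stats)
        dt.write_tag_table(table, d / f"tags_{slug}.tsv")
        with open(d / f"stats_{slug}.json", "w") as fh:
            json.dump(stats.as_dict() | {"total_valid_tags": table.total_valid_tags},
                      fh, indent=2)
        outputs += [d / f"tags_{slug}.tsv", d / f"stats_{slug}.json"]
        info[label] = {"total_valid_tags": table.total_valid_tags}
    return outputs, info


def _load_genome(out: Path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(out / "simulate" / "genome.fa"), "fasta")}


def _stage_map(config: RunConfig, out: Path):
    genome = _load_genome(out)
    d = out / "map"
    d.mkdir(exist_ok=True)
    tables = {
        label: dt.read_tag_table(out / "extract" / f"tags_{_slug(label)}.tsv",
                                 stage=label)
        for label in _labels(config)
    }
    lengths = {len(t) for tbl in tables.values() for t in tbl.entries}
    lengths = lengths or set(range(config.layout.tag_length_range[0],
                                   config.layout.tag_length_range[1] + 1))
    index = mp.build_index(genome, lengths)
    outputs, info = [], {}
    for label, table in tables.items():
        slug = _slug(label)
        hits, summary = mp.map_tags(table, index)
        mp.write_hits(hits, d / f"hits_{slug}.tsv")
        with open(d / f"summary_{slug}.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        outputs += [d / f"hits_{slug}.tsv", d / f"summary_{slug}.json"]
        info[label] = {cls: summary["classes"][cls]["tags"] for cls in mp.CLASSES}
    return outputs, info


def _stage_annotate(config: RunConfig, out: Path):
    genome = _load_genome(out)
    with open(out / "simulate" / "models.gff3") as fh:
        models = read_gff3(fh)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    windows = an.GeneWindows(models, chrom_lengths=chrom_lengths)
    d = out / "annotate"
    d.mkdir(exist_ok=True)
    outputs, info = [], {}
    for label in _labels(config):
        slug = _slug(label)
        hits = mp.read_hits(out / "map" / f"hits_{slug}.tsv")
        unique = mp.unique_hits(hits)
        classified, summary = an.annotate_library(unique, windows)
        catalogs = an.build_tss_catalogs(classified)
        an.write_classifications(classified, d / f"classified_{slug}.tsv")
        an.write_tss_catalogs(catalogs, d / f"tss_{slug}.tsv")
        an.write_tss_bed(catalogs, models, d / f"tss_{slug}.bed")
        with open(d / f"summary_{slug}.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        outputs += [d / f"classified_{slug}.tsv", d / f"tss_{slug}.tsv",
                    d / f"tss_{slug}.bed", d / f"summary_{slug}.json"]
        info[label] = {cat: summary["categories"][cat]["tags"]
                       for cat in an.CATEGORIES}
    return outputs, info


def _stage_de(config: RunConfig, out: Path):
    labels = _labels(config)
    counts: Dict[str, List[int]] = defaultdict(lambda: [0, 0])
    totals = [0, 0]
    for si, label in enumerate(labels):
        slug = _slug(label)
        cls = pd.read_csv(out / "annotate" / f"classified_{slug}.tsv", sep="\t")
        utr5 = cls[cls.category == an.UTR5_SENSE]
        for gid, cnt in utr5.groupby("gene_id")["count"].sum().items():
            counts[gid][si] = int(cnt)
        if config.de.denominator == "unique_mapped":
            with open(out / "map" / f"summary_{slug}.json") as fh:
                summary = json.load(fh)
            totals[si] = summary["classes"][mp.UNIQUE]["tags"]
        else:
            with open(out / "extract" / f"stats_{slug}.json") as fh:
                totals[si] = json.load(fh)["total_valid_tags"]
    expressions = ex.quantify({g: tuple(c) for g, c in counts.items()},
                              (totals[0], totals[1]), config.de)
    expressions, summary = ex.call_degs(expressions, config.de)
    d = out / "de"
    d.mkdir(exist_ok=True)
    ex.write_deg_tables(expressions, d)
    with open(d / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    outputs = [d / "expression.tsv", d / "degs_myc.tsv", d / "degs_pri.tsv",
               d / "summary.json"]
    return outputs, {"assessed_genes": summary["assessed_genes"],
                     "degs_myc": summary["Myc"]["degs"],
                     "degs_pri": summary["S1-Pri"]["degs"]}


def _stage_enrich(config: RunConfig, out: Path):
    with open(out / "simulate" / "models.gff3") as fh:
        universe = [m.gene_id for m in read_gff3(fh)]
    expr = pd.read_csv(out / "de" / "expression.tsv", sep="\t")
    deg_sets = {
        "myc": set(expr[expr.deg_direction == ex.MYC_UP].gene_id),
        "pri": set(expr[expr.deg_direction == ex.PRI_UP].gene_id),
    }
    d = out / "enrich"
    d.mkdir(exist_ok=True)
    if config.domain_table is not None:
        assignments = en.read_domain_table(config.domain_table)
        reports = {}
        fb_species = config.fruiting_body_species
        if config.homology_dir:
            for p in sorted(Path(config.homology_dir).glob("*.tsv")):
                reports[p.stem] = en.read_blast_tabular(p)
    else:
        assignments, reports, fb_species = simulate_functional_annotations(
            universe, seed=config.seed + 3)
        pd.DataFrame([(a.orf_id, a.domain_id, a.e_value) for a in assignments],
                     columns=["orf_id", "domain_id", "e_value"]).to_csv(
            d / "synthetic_domains.tsv", sep="\t", index=False)
    outputs, info = [], {}
    for name, deg in deg_sets.items():
        results = en.domain_enrichment(assignments, deg, universe,
                                       alpha=config.de.alpha)
        en.write_enrichment(results, d / f"domain_enrichment_{name}.tsv")
        calls = en.classify_lineages(sorted(deg), reports, fb_species)
        en.write_lineage(calls, d / f"lineage_{name}.tsv")
        outputs += [d / f"domain_enrichment_{name}.tsv", d / f"lineage_{name}.tsv"]
        info[name] = {
            "enriched_domains": sum(r.enriched for r in results),
            "basidiomycete_unique": sum(
                c.classification == en.BASIDIOMYCETE_UNIQUE for c in calls),
            "species_unique": sum(
                c.classification == en.SPECIES_UNIQUE for c in calls),
        }
    if config.domain_table is None:
        outputs.append(d / "synthetic_domains.tsv")
    return outputs, info


def _stage_validate(config: RunConfig, out: Path):
    if config.platform_panel:
        panel = va.read_panel(config.platform_panel)
    else:
        panel = va.load_reference_panel()
    report = va.validate_report(panel)
    d = out / "validate"
    d.mkdir(exist_ok=True)
    with open(d / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    info = {name: {k: pair[k] for k in ("n", "r") if k in pair}
            for name, pair in report["pairs"].items()}
    return [d / "report.json"], info
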