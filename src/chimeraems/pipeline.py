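"""End-to-end orchestration: simulate/ingest -> partition -> spectrum ->
candidates -> report.

Intermediate files are the contract between stages: every stage writes
plain TSV/VCF/BED/GFF3 into the run directory, so users can substitute
real variant calls from any caller at the partition stage, or re-run a
single downstream stage from the files of a previous run.  A manifest
records the seed, a configuration hash and a SHA-256 per output;
identical configuration and seed reproduce every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as cio
from .caller import call_and_filter
from .chem import pigment_table
from .config import (
    YELLOW,
    FilterThresholds,
    SimulationConfig,
    SpectrumConfig,
)
from .errors import ChimeraEMSError, ConfigurationError, InputError
from .provenance import (
    CLASS_EMS1,
    CLASS_EMS2,
    SampleSheet,
    build_locus_matrix,
    partition,
)
from .simdata import (
    GenomeModel,
    emit_sample_calls,
    generate_genome,
    plant_causal_genes,
    sample_layout,
    simulate_two_round_mutagenesis,
)
from .spectrum import canonical_ems_fraction, spectrum_table
from .twohit import assign_snps_to_genes, candidate_genes

log = logging.getLogger(__name__)

MODES = ("simulate", "vcf", "pileup")


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    outdir: Path
    mode: str = "simulate"
    seed: int = 1
    sim: SimulationConfig | None = None
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    min_callable_depth: int = 8
    focal_sector: str = YELLOW
    sheet: SampleSheet | None = None
    vcfs: dict[str, str] = field(default_factory=dict)
    masks: dict[str, str] = field(default_factory=dict)
    pileups: dict[str, str] = field(default_factory=dict)
    genes_path: str | None = None
    absorbance_path: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}")
        self.outdir = Path(self.outdir)
        if self.mode == "simulate" and self.sim is None:
            self.sim = SimulationConfig(seed=self.seed)
        if self.mode != "simulate" and self.sheet is None:
            raise ConfigurationError(f"{self.mode} mode requires a sample sheet")
        if self.mode != "simulate" and self.genes_path is None:
            raise ConfigurationError(f"{self.mode} mode requires a gene annotation")

    @classmethod
    def from_yaml(
        cls,
        path: str | Path,
        seed: int | None = None,
        outdir: str | Path | None = None,
    ) -> "RunConfig":
        raw = cio.load_yaml(path)
        mode = raw.get("mode", "simulate")
        run_seed = seed if seed is not None else int(raw.get("seed", 1))
        sim = None
        if "simulate" in raw or mode == "simulate":
            sim_raw = dict(raw.get("simulate", {}))
            if "spectrum" in sim_raw:
                sim_raw["spectrum"] = SpectrumConfig.from_percentages(
                    sim_raw["spectrum"]
                )
            sim_raw["seed"] = run_seed
            sim = SimulationConfig(**sim_raw)
        thresholds = FilterThresholds(**raw.get("thresholds", {}))
        sheet = None
        if "sheet" in raw:
            sheet = cio.read_sample_sheet(raw["sheet"])
        return cls(
            outdir=Path(outdir if outdir is not None else raw.get("outdir", "run_out")),
            mode=mode,
            seed=run_seed,
            sim=sim,
            thresholds=thresholds,
            min_callable_depth=int(raw.get("min_callable_depth", 8)),
            focal_sector=raw.get("focal_sector", YELLOW),
            sheet=sheet,
            vcfs=dict(raw.get("vcfs", {})),
            masks=dict(raw.get("masks", {})),
            pileups=dict(raw.get("pileups", {})),
            genes_path=raw.get("genes"),
            absorbance_path=raw.get("absorbances"),
            log_level=raw.get("log_level", "INFO"),
        )


@contextmanager
def _stage(name: str):
    log.info("stage %s: start", name)
    try:
        yield
    except ChimeraEMSError as exc:
        raise type(exc)(f"stage '{name}': {exc}") from exc
    except Exception as exc:  # noqa: BLE001 - annotate with the stage name
        raise ChimeraEMSError(f"stage '{name}': {exc}") from exc
    log.info("stage %s: done", name)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if isinstance(o, SpectrumConfig):
            return dict(o.probabilities)
        if dataclasses.is_dataclass(o):
            return {f.name: getattr(o, f.name) for f in dataclasses.fields(o)}
        if isinstance(o, Path):
            return str(o)
        if isinstance(o, SampleSheet):
            return o.frame.to_dict("records")
        return str(o)

    payload = json.dumps(config, default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def run(config: RunConfig) -> dict:
    """Execute one full analysis run; returns in-memory results.

    The returned dict carries the partition result, venn counts,
    spectrum and candidate tables, the truth table when simulating, and
    the manifest.  All tables are also written as TSV under
    ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("chimeraems")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    outputs: dict[str, Path] = {}
    results: dict = {"outdir": outdir}

    def emit(name: str, writer, *args) -> None:
        path = outdir / name
        writer(*args, path)
        outputs[name] = path

    try:
        genome: GenomeModel | None = None
        truth = None
        if config.mode == "simulate":
            with _stage("simulate"):
                sim = dataclasses.replace(config.sim, seed=config.seed)
                genome = generate_genome(sim)
                truth = simulate_two_round_mutagenesis(sim, genome)
                truth = plant_causal_genes(sim, genome, truth)
                calls, masks = emit_sample_calls(truth, sim, genome)
                sheet = config.sheet or SampleSheet.from_layout(sample_layout(sim))
                genes = genome.genes_frame()
                emit("genes.gff3", cio.write_gff3, genes)
                emit("genes.bed", cio.write_genes_bed, genes)
                emit("truth.tsv", cio.write_table, truth.variants)
                emit("causal_genes.tsv", cio.write_table, truth.causal_genes)
                emit("sheet.tsv", cio.write_sample_sheet, sheet.frame)
                for sample in sheet.samples:
                    path = outdir / f"{sample}.vcf"
                    cio.write_vcf(calls[sample], path, sample, genome.lengths)
                    outputs[f"{sample}.vcf"] = path
                    mpath = outdir / f"{sample}.mask.bed"
                    cio.write_mask_bed(masks[sample], mpath)
                    outputs[f"{sample}.mask.bed"] = mpath
                results["truth"] = truth
        elif config.mode == "vcf":
            with _stage("ingest-vcf"):
                sheet = config.sheet
                calls, masks = {}, {}
                for sample in sheet.samples:
                    if sample not in config.vcfs:
                        raise InputError(f"no VCF provided for sample {sample!r}")
                    calls[sample] = cio.read_vcf(config.vcfs[sample], sample)
                    if sample in config.masks:
                        masks[sample] = cio.read_mask_bed(config.masks[sample])
                genes = cio.read_genes(config.genes_path)
        else:  # pileup
            with _stage("call"):
                sheet = config.sheet
                calls, masks = {}, {}
                for sample in sheet.samples:
                    if sample not in config.pileups:
                        raise InputError(f"no pileup provided for sample {sample!r}")
                    lines = cio.read_pileup(config.pileups[sample])
                    calls[sample] = call_and_filter(
                        lines, config.thresholds, sample=sample
                    )
                    depths = pd.DataFrame(
                        [
                            (l.split("\t")[0], int(l.split("\t")[1]),
                             int(l.split("\t")[3]))
                            for l in lines
                            if l.strip()
                        ],
                        columns=["chrom", "pos", "depth"],
                    )
                    masks[sample] = depths
                    cio.write_vcf(
                        calls[sample].assign(zygosity="het"),
                        outdir / f"{sample}.called.vcf",
                        sample,
                    )
                    outputs[f"{sample}.called.vcf"] = outdir / f"{sample}.called.vcf"
                genes = cio.read_genes(config.genes_path)

        with _stage("partition"):
            matrix = build_locus_matrix(
                calls, masks or None, sheet, config.min_callable_depth
            )
            part = partition(matrix, sheet)
            emit("partition.tsv", cio.write_table, part.loci)
            emit("venn.tsv", cio.write_table, part.venn)
            results["partition"] = part

        with _stage("spectrum"):
            induced = part.loci[
                part.loci["label"].isin([CLASS_EMS1, CLASS_EMS2])
            ].copy()
            induced["group"] = induced.apply(
                lambda r: f"{r['label']}:{r['line']}"
                + (f":{r['sector']}" if r["sector"] else ""),
                axis=1,
            )
            spec = spectrum_table(induced, group_by="group")
            emit("spectrum.tsv", cio.write_table, spec)
            overall = spectrum_table(induced)
            results["spectrum"] = spec
            results["spectrum_overall"] = overall
            frac = canonical_ems_fraction(overall)
            log.info("canonical C/T+G/A fraction of induced SNPs: %.2f%%", frac)

        with _stage("candidates"):
            known = set(genome.chrom_names) if genome is not None else None
            assigned = assign_snps_to_genes(part.loci, genes, known)
            pieces = []
            for line in sheet.lines:
                cand = candidate_genes(assigned, line, config.focal_sector)
                cand.insert(0, "line", line)
                pieces.append(cand)
            candidates = pd.concat(pieces, ignore_index=True)
            emit("candidates.tsv", cio.write_table, candidates)
            results["candidates"] = candidates

        if config.absorbance_path:
            with _stage("pigments"):
                absorbances = cio.read_table(config.absorbance_path)
                pigments = pigment_table(absorbances)
                emit("pigments.tsv", cio.write_table, pigments)
                results["pigments"] = pigments

        with _stage("manifest"):
            manifest = {
                "package": "chimeraems",
                "seed": config.seed,
                "mode": config.mode,
                "config_hash": _config_hash(config),
                "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
            }
            (outdir / "manifest.json").write_text(
                json.dumps(manifest, indent=2, sort_keys=True) + "\n"
            )
            results["manifest"] = manifest
    finally:
        root.removeHandler(handler)
        handler.close()
    return results
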