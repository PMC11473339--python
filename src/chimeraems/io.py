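"""Readers and writers for the pipeline's file contracts.

Per-sample calls travel as VCF v4.2 (INFO DP/AD/PV, sample GT), gene
annotation as GFF3 and BED (both dialects), depth masks as 4-column BED
(chrom, 0-based start, end, depth), tables as TSV, pileup as
samtools-style 6-column text, configs as YAML.  All coordinates are
1-based inclusive in memory; BED converts at the boundary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .errors import InputError

VCF_INFO_HEADER = [
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##INFO=<ID=AD,Number=R,Type=Integer,Description="Ref,alt read counts">',
    '##INFO=<ID=PV,Number=1,Type=Float,Description="Site p-value">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


def write_vcf(
    calls: pd.DataFrame,
    path: str | Path,
    sample: str,
    contigs: Mapping[str, int] | None = None,
) -> None:
    lines = ["##fileformat=VCFv4.2", "##source=chimeraems"]
    if contigs:
        lines += [f"##contig=<ID={c},length={l}>" for c, l in contigs.items()]
    lines += VCF_INFO_HEADER
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    work = calls.sort_values(["chrom", "pos"], kind="mergesort")
    for rec in work.itertuples(index=False):
        depth = int(rec.depth)
        alt_reads = int(rec.alt_reads)
        pv = getattr(rec, "p_value", float("nan"))
        gt = "1/1" if getattr(rec, "zygosity", "het") == "hom" else "0/1"
        info = f"DP={depth};AD={depth - alt_reads},{alt_reads};PV={pv:.6g}"
        lines.append(
            f"{rec.chrom}\t{int(rec.pos)}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t"
            f"{info}\tGT\t{gt}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path, sample: str | None = None) -> pd.DataFrame:
    """Read one single-sample VCF into the internal call-table shape."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if sample is None:
        sample = vcf.samples[0] if vcf.samples else "sample"
    rows = []
    for v in vcf:
        if not v.ALT:
            continue
        depth = v.INFO.get("DP")
        ad = v.INFO.get("AD")
        alt_reads = ad[1] if isinstance(ad, tuple) else None
        if depth is None:
            depth = 0
        if alt_reads is None:
            alt_reads = 0
        pv = v.INFO.get("PV")
        zyg = "het"
        if v.genotypes:
            a, b = v.genotypes[0][:2]
            zyg = "hom" if a == b == 1 else "het"
        rows.append(
            (v.CHROM, v.POS, v.REF, v.ALT[0], sample, int(depth), int(alt_reads),
             float(pv) if pv is not None else float("nan"), zyg)
        )
    vcf.close()
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "sample",
                 "depth", "alt_reads", "p_value", "zygosity"],
    )


def write_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for rec in genes.itertuples(index=False):
        lines.append(
            f"{rec.chrom}\tchimeraems\tgene\t{int(rec.start)}\t{int(rec.end)}\t.\t"
            f"{rec.strand}\t.\tID={rec.gene_id}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "source", "type", "start", "end",
               "score", "strand", "phase", "attributes"],
        dtype={"chrom": str},
    )
    genes = frame[frame["type"] == "gene"].copy()
    ids = genes["attributes"].str.extract(r"ID=([^;]+)")[0]
    if ids.isna().any():
        raise InputError(f"{path}: gene records without an ID attribute")
    out = genes[["chrom", "start", "end", "strand"]].copy()
    out.insert(0, "gene_id", ids.to_numpy())
    return out.reset_index(drop=True)


def write_genes_bed(genes: pd.DataFrame, path: str | Path) -> None:
    lines = [
        f"{r.chrom}\t{int(r.start) - 1}\t{int(r.end)}\t{r.gene_id}\t0\t{r.strand}"
        for r in genes.itertuples(index=False)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start0", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str},
    )
    return pd.DataFrame(
        {
            "gene_id": frame["gene_id"],
            "chrom": frame["chrom"],
            "start": frame["start0"] + 1,
            "end": frame["end"],
            "strand": frame.get("strand", "+"),
        }
    )


def read_genes(path: str | Path) -> pd.DataFrame:
    """Dispatch on extension: .gff/.gff3 vs .bed."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        return read_gff3(path)
    if suffix == ".bed":
        return read_genes_bed(path)
    raise InputError(f"cannot infer gene-annotation format from {path}")


def write_mask_bed(mask: pd.DataFrame, path: str | Path) -> None:
    lines = [
        f"{r.chrom}\t{int(r.pos) - 1}\t{int(r.pos)}\t{int(r.depth)}"
        for r in mask.itertuples(index=False)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_mask_bed(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start0", "end", "depth"],
        dtype={"chrom": str},
    )
    return pd.DataFrame(
        {"chrom": frame["chrom"], "pos": frame["start0"] + 1, "depth": frame["depth"]}
    )


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_sample_sheet(sheet_frame: pd.DataFrame, path: str | Path) -> None:
    write_table(sheet_frame, path)


def read_sample_sheet(path: str | Path):
    from .provenance import SampleSheet

    return SampleSheet(pd.read_csv(path, sep="\t", dtype=str))


def write_pileup(text: str, path: str | Path) -> None:
    Path(path).write_text(text)


def read_pileup(path: str | Path) -> list[str]:
    return Path(path).read_text().splitlines()


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def dump_yaml(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
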