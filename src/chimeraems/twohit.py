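"""Two-hit candidate-gene prediction for the yellow-sector phenotype.

Because the second mutagenesis acted on cells already heterozygous from
the first round, a gene knocked out in the yellow sector is expected to
carry two induced mutations: one private to the focal yellow sample
(second round) and one more, at a distinct position, from either round.
A gene is therefore a candidate for ``(line, sector)`` when its body
contains at least one ``EMS2(line, sector)`` SNP and at least one
additional SNP of class ``EMS1(line)`` or ``EMS2(line, sector)``.

Background (cultivar) SNPs never count toward the pair, and assignment
is to the gene body only — annotation start through end, 1-based
inclusive — with no promoter or UTR flank.
"""

from __future__ import annotations

import pandas as pd
from intervaltree import IntervalTree

from .config import YELLOW
from .errors import InputError
from .provenance import CLASS_EMS1, CLASS_EMS2

CANDIDATE_COLUMNS = ["gene_id", "n_snps", "classes", "positions", "trace"]


def assign_snps_to_genes(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    known_chromosomes: set[str] | None = None,
) -> pd.DataFrame:
    """Attach a ``gene_id`` column to a SNP table by interval lookup.

    A SNP lands in gene g when ``start <= pos <= end``; SNPs in no gene
    get an empty gene_id (intergenic).  Genes are assumed
    non-overlapping; with overlaps the first annotated gene wins.
    Chromosome names present in the SNPs but absent from the annotation
    (or from ``known_chromosomes`` when given) raise an error listing
    the unmatched names.
    """
    valid = known_chromosomes if known_chromosomes is not None else set(genes["chrom"])
    unmatched = sorted(set(snps["chrom"].astype(str)) - set(valid))
    if unmatched:
        raise InputError(
            f"SNP chromosomes not present in the gene annotation: {unmatched}"
        )
    trees: dict[str, IntervalTree] = {}
    for rec in genes.itertuples(index=False):
        trees.setdefault(rec.chrom, IntervalTree()).addi(
            int(rec.start), int(rec.end) + 1, rec.gene_id
        )
    out = snps.copy()
    assigned = []
    for chrom, pos in zip(out["chrom"], out["pos"]):
        tree = trees.get(chrom)
        hits = sorted(iv.data for iv in tree[int(pos)]) if tree is not None else []
        assigned.append(hits[0] if hits else "")
    out["gene_id"] = assigned
    return out


def intergenic(assigned: pd.DataFrame) -> pd.DataFrame:
    return assigned[assigned["gene_id"] == ""]


def candidate_genes(
    assigned: pd.DataFrame,
    focal_line: str,
    focal_sector: str = YELLOW,
) -> pd.DataFrame:
    """Evaluate the two-hit rule over a gene-assigned partition table.

    ``assigned`` is a partition table (columns label, line, sector, pos)
    with ``gene_id`` attached.  Returns candidates sorted by gene id,
    with a trace naming the SNP that satisfied each clause.
    """
    for col in ("gene_id", "label", "line", "sector", "pos"):
        if col not in assigned.columns:
            raise InputError(f"assigned SNP table lacks column {col!r}")
    genic = assigned[assigned["gene_id"] != ""]
    rows = []
    for gene_id, sub in genic.groupby("gene_id", sort=True):
        second = sub[
            (sub["label"] == CLASS_EMS2)
            & (sub["line"] == focal_line)
            & (sub["sector"] == focal_sector)
        ]
        first = sub[(sub["label"] == CLASS_EMS1) & (sub["line"] == focal_line)]
        qualifying = pd.concat([second, first]).drop_duplicates(["chrom", "pos"])
        if second.empty or qualifying["pos"].nunique() < 2:
            continue
        anchor = second.sort_values("pos").iloc[0]
        partner = (
            qualifying[qualifying["pos"] != anchor["pos"]]
            .sort_values("pos")
            .iloc[0]
        )
        rows.append(
            (
                gene_id,
                int(qualifying["pos"].nunique()),
                ",".join(sorted(set(qualifying["label"]))),
                ",".join(str(p) for p in sorted(qualifying["pos"])),
                f"second-round:{CLASS_EMS2}@{anchor['pos']};"
                f"partner:{partner['label']}@{partner['pos']}",
            )
        )
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
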