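"""Synthetic double-mutagenesis experiments with ground truth.

The simulator emulates the design of a sequential two-round EMS
mutagenesis that produced sectored (chimeric) plants:

* a random reference genome with sparse, non-overlapping genes;
* a layer of cultivar-vs-reference *background* variants shared by every
  sample of every line;
* per line, a first-round EMS layer (``EMS1``) heterozygous in both the
  yellow and the green leaf sector;
* per line, a second-round EMS layer concentrated in the yellow sector
  (``EMS2_YELLOW``) with a small configurable leak into the green sector
  (``EMS2_GREEN``) — the green lineage largely escaped the second
  treatment;
* planted causal genes carrying a two-hit pair (one second-round yellow
  mutation plus one earlier induced mutation at a distinct position);
* per-sample observed call sets and pileup text with configurable
  coverage, allele-fraction, base-quality and false-call noise.

Every variant's (ref, alt) pair is realised by sampling a directed
substitution type from the configured spectrum and then consuming an
unused genome position whose reference base matches, so positions never
collide across layers and the empirical spectrum converges to the
configuration.  All randomness flows through per-stage streams derived
from the master seed (see :func:`chimeraems.config.stage_rng`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .caller import score_sites
from .config import (
    BASES,
    SECTORS,
    YELLOW,
    SimulationConfig,
    stage_rng,
)
from .errors import ConfigurationError, SimulationError

CLASS_BACKGROUND = "BACKGROUND"
CLASS_EMS1 = "EMS1"
CLASS_EMS2_YELLOW = "EMS2_YELLOW"
CLASS_EMS2_GREEN = "EMS2_GREEN"
TRUE_CLASSES = (CLASS_BACKGROUND, CLASS_EMS1, CLASS_EMS2_YELLOW, CLASS_EMS2_GREEN)

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "true_class", "line", "zygosity"]
CAUSAL_COLUMNS = ["gene_id", "line", "chrom", "pos_a", "class_a", "pos_b", "class_b"]
CALL_COLUMNS = [
    "chrom", "pos", "ref", "alt", "sample",
    "depth", "alt_reads", "mean_baseq", "p_value", "zygosity",
]


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str


@dataclass
class GenomeModel:
    """Chromosome sequences plus non-overlapping gene annotation."""

    sequences: dict[str, str]
    genes: tuple[GeneRecord, ...]

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def base(self, chrom: str, pos: int) -> str:
        return self.sequences[chrom][pos - 1]

    def genes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in self.genes],
            columns=["gene_id", "chrom", "start", "end", "strand"],
        )

    def reverse_complemented(self) -> "GenomeModel":
        """The same genome viewed from the opposite strand.

        Sequences are reverse-complemented and gene coordinates flipped;
        used for strand-symmetry checks.
        """
        table = str.maketrans("ACGT", "TGCA")
        seqs = {
            name: seq.translate(table)[::-1] for name, seq in self.sequences.items()
        }
        genes = tuple(
            GeneRecord(
                g.gene_id,
                g.chrom,
                len(self.sequences[g.chrom]) - g.end + 1,
                len(self.sequences[g.chrom]) - g.start + 1,
                "-" if g.strand == "+" else "+",
            )
            for g in self.genes
        )
        return GenomeModel(seqs, genes)


@dataclass
class TruthTable:
    """Ground truth: every planted variant plus the causal-gene list.

    ``variants`` has one row per locus (positions are unique across all
    layers): chrom, pos, ref, alt, true_class, line, zygosity.  The
    class is one of BACKGROUND (line empty), EMS1, EMS2_YELLOW or
    EMS2_GREEN; every EMS record is heterozygous.  ``causal_genes``
    records each planted two-hit pair.
    """

    variants: pd.DataFrame
    causal_genes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=CAUSAL_COLUMNS)
    )

    def visible_to(self, line: str, sector: str) -> pd.DataFrame:
        """Variants carried by the sample ``(line, sector)``.

        Background is carried by everyone; EMS1 by both sectors of its
        line; EMS2 only by its own sector of its line.
        """
        v = self.variants
        cls = v["true_class"]
        mask = cls == CLASS_BACKGROUND
        mask |= (cls == CLASS_EMS1) & (v["line"] == line)
        sector_class = CLASS_EMS2_YELLOW if sector == YELLOW else CLASS_EMS2_GREEN
        mask |= (cls == sector_class) & (v["line"] == line)
        return v[mask]


def sample_id(line: str, sector: str) -> str:
    return f"{line}{'Y' if sector == YELLOW else 'G'}"


def sample_layout(config: SimulationConfig) -> list[tuple[str, str, str]]:
    """(sample, line, sector) triplets in canonical order."""
    return [
        (sample_id(line, sector), line, sector)
        for line in config.line_ids
        for sector in SECTORS
    ]


# ---------------------------------------------------------------------------
# genome synthesis


def generate_genome(config: SimulationConfig) -> GenomeModel:
    """Uniform-composition chromosomes with packed non-overlapping genes.

    Genes are spread round-robin over chromosomes; within a chromosome,
    sorted random offsets plus a per-gene shift guarantee
    non-overlapping placement that is uniform over admissible layouts.
    """
    rng = stage_rng(config.seed, "genome")
    if config.n_genes * config.gene_length > config.total_length:
        raise ConfigurationError(
            f"cannot pack {config.n_genes} genes x {config.gene_length} bp "
            f"(= {config.n_genes * config.gene_length} bp) into "
            f"{config.n_chromosomes} chromosome(s) of {config.genome_length} bp"
        )
    letters = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    sequences: dict[str, str] = {}
    per_chrom = [
        config.n_genes // config.n_chromosomes
        + (1 if i < config.n_genes % config.n_chromosomes else 0)
        for i in range(config.n_chromosomes)
    ]
    genes: list[GeneRecord] = []
    counter = 0
    for ci in range(config.n_chromosomes):
        name = f"chr{ci + 1}"
        codes = rng.integers(0, 4, size=config.genome_length)
        sequences[name] = letters[codes].tobytes().decode("ascii")
        k = per_chrom[ci]
        if k == 0:
            continue
        free = config.genome_length - k * config.gene_length
        if free < 0:
            raise ConfigurationError(
                f"cannot pack {k} genes x {config.gene_length} bp into "
                f"chromosome {name} of {config.genome_length} bp"
            )
        offsets = np.sort(rng.integers(0, free + 1, size=k))
        for i in range(k):
            counter += 1
            start = int(offsets[i]) + i * config.gene_length + 1
            genes.append(
                GeneRecord(
                    gene_id=f"gene{counter:05d}",
                    chrom=name,
                    start=start,
                    end=start + config.gene_length - 1,
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
    return GenomeModel(sequences, tuple(genes))


# ---------------------------------------------------------------------------
# mutation layers


class _BasePools:
    """Shuffled, consumable pools of genome positions per reference base.

    Drawing from a shared pool across all mutation layers guarantees
    collision-free positions without rejection sampling.
    """

    def __init__(self, genome: GenomeModel, rng: np.random.Generator) -> None:
        self._names = list(genome.sequences)
        self._chrom_idx: dict[str, np.ndarray] = {}
        self._pos: dict[str, np.ndarray] = {}
        self._ptr: dict[str, int] = {}
        per_base_pos = {b: [] for b in BASES}
        per_base_ci = {b: [] for b in BASES}
        for ci, name in enumerate(self._names):
            arr = np.frombuffer(genome.sequences[name].encode(), dtype=np.uint8)
            for b in BASES:
                pos = np.where(arr == ord(b))[0] + 1
                per_base_pos[b].append(pos)
                per_base_ci[b].append(np.full(len(pos), ci, dtype=np.int64))
        for b in BASES:
            pos = np.concatenate(per_base_pos[b]) if per_base_pos[b] else np.array([], int)
            cis = np.concatenate(per_base_ci[b]) if per_base_ci[b] else np.array([], int)
            perm = rng.permutation(len(pos))
            self._pos[b] = pos[perm]
            self._chrom_idx[b] = cis[perm]
            self._ptr[b] = 0

    def take(self, base: str, k: int, type_label: str) -> tuple[np.ndarray, np.ndarray]:
        ptr = self._ptr[base]
        if ptr + k > len(self._pos[base]):
            raise SimulationError(
                f"reference bases '{base}' exhausted while drawing "
                f"substitution type {type_label} "
                f"({len(self._pos[base]) - ptr} left, {k} requested)"
            )
        self._ptr[base] = ptr + k
        return self._chrom_idx[base][ptr:ptr + k], self._pos[base][ptr:ptr + k]

    def chrom_name(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(self._names, dtype=object)[idx]


def _draw_variants(
    rng: np.random.Generator,
    pools: _BasePools,
    config: SimulationConfig,
    n: int,
) -> pd.DataFrame:
    """Draw ``n`` (chrom, pos, ref, alt) records from the spectrum."""
    types, probs = config.spectrum.as_arrays()
    idx = rng.choice(len(types), size=n, p=probs)
    refs = np.asarray([t[0] for t in types], dtype=object)[idx]
    alts = np.asarray([t[2] for t in types], dtype=object)[idx]
    chroms = np.empty(n, dtype=object)
    positions = np.empty(n, dtype=np.int64)
    for b in BASES:
        mask = refs == b
        k = int(mask.sum())
        if k == 0:
            continue
        requested = [t for t in types if t[0] == b]
        ci, pos = pools.take(b, k, ", ".join(requested) or b)
        chroms[mask] = pools.chrom_name(ci)
        positions[mask] = pos
    return pd.DataFrame({"chrom": chroms, "pos": positions, "ref": refs, "alt": alts})


def simulate_two_round_mutagenesis(
    config: SimulationConfig, genome: GenomeModel
) -> TruthTable:
    """Plant the background and both EMS layers, returning ground truth.

    Background variants (cultivar vs reference, homozygous) are drawn
    Poisson at ``background_snv_rate`` per bp; each line then receives
    ``ems1_count`` heterozygous first-round mutations shared by both
    sectors and ``ems2_count`` second-round mutations, of which a
    ``green_leak_fraction`` lands in the green sector instead of the
    yellow one.
    """
    rng = stage_rng(config.seed, "mutagenesis")
    pools = _BasePools(genome, rng)
    frames: list[pd.DataFrame] = []

    n_bg = int(rng.poisson(config.background_snv_rate * genome.total_length))
    if n_bg:
        bg = _draw_variants(rng, pools, config, n_bg)
        bg["true_class"] = CLASS_BACKGROUND
        bg["line"] = ""
        bg["zygosity"] = "hom"
        frames.append(bg)

    for line in config.line_ids:
        if config.ems1_count:
            e1 = _draw_variants(rng, pools, config, config.ems1_count)
            e1["true_class"] = CLASS_EMS1
            e1["line"] = line
            e1["zygosity"] = "het"
            frames.append(e1)

    for line in config.line_ids:
        if config.ems2_count:
            e2 = _draw_variants(rng, pools, config, config.ems2_count)
            leak = rng.random(config.ems2_count) < config.green_leak_fraction
            e2["true_class"] = np.where(leak, CLASS_EMS2_GREEN, CLASS_EMS2_YELLOW)
            e2["line"] = line
            e2["zygosity"] = "het"
            frames.append(e2)

    if frames:
        variants = pd.concat(frames, ignore_index=True)
        variants = variants.sort_values(
            ["chrom", "pos"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        variants = pd.DataFrame(columns=VARIANT_COLUMNS)
    return TruthTable(variants=variants[VARIANT_COLUMNS])


def plant_causal_genes(
    config: SimulationConfig, genome: GenomeModel, truth: TruthTable
) -> TruthTable:
    """Plant a two-hit pair inside each of ``n_causal_genes`` genes.

    Each selected gene receives one EMS2_YELLOW mutation and one
    additional mutation of class EMS1 or EMS2_YELLOW (coin flip) at a
    distinct position, both with spectrum-sampled substitution types
    realised on matching reference bases inside the gene body.  Genes
    cycle through the lines so every line gets candidates.
    """
    if config.n_causal_genes == 0:
        return TruthTable(truth.variants.copy(), truth.causal_genes.copy())
    rng = stage_rng(config.seed, "plant")
    if config.n_causal_genes > len(genome.genes):
        raise ConfigurationError(
            f"n_causal_genes={config.n_causal_genes} exceeds the "
            f"{len(genome.genes)} annotated genes"
        )
    order = rng.permutation(len(genome.genes))
    chosen = [genome.genes[i] for i in order[: config.n_causal_genes]]
    types, probs = config.spectrum.as_arrays()
    used = set(zip(truth.variants["chrom"], truth.variants["pos"]))
    new_rows = []
    causal_rows = []
    for i, gene in enumerate(chosen):
        line = config.line_ids[i % config.n_lines]
        seq = genome.sequences[gene.chrom]
        eligible = {
            b: [
                p
                for p in range(gene.start, gene.end + 1)
                if seq[p - 1] == b and (gene.chrom, p) not in used
            ]
            for b in BASES
        }
        if sum(len(v) for v in eligible.values()) < 2:
            raise SimulationError(
                f"gene {gene.gene_id} ({gene.chrom}:{gene.start}-{gene.end}) is "
                f"too short to host two distinct mutations of the required "
                f"reference bases"
            )
        pair_classes = [
            CLASS_EMS2_YELLOW,
            str(rng.choice([CLASS_EMS1, CLASS_EMS2_YELLOW])),
        ]
        planted_here: list[tuple[int, str]] = []
        for cls in pair_classes:
            placed = False
            for _ in range(1000):
                t = types[int(rng.choice(len(types), p=probs))]
                b = t[0]
                if not eligible[b]:
                    continue
                pos = eligible[b][int(rng.integers(len(eligible[b])))]
                eligible[b].remove(pos)
                used.add((gene.chrom, pos))
                new_rows.append(
                    (gene.chrom, pos, b, t[2], cls, line, "het")
                )
                planted_here.append((pos, cls))
                placed = True
                break
            if not placed:
                raise SimulationError(
                    f"gene {gene.gene_id} has no remaining reference bases "
                    f"matching the configured spectrum"
                )
        (pos_a, cls_a), (pos_b, cls_b) = planted_here
        causal_rows.append(
            (gene.gene_id, line, gene.chrom, pos_a, cls_a, pos_b, cls_b)
        )
    planted = pd.DataFrame(new_rows, columns=VARIANT_COLUMNS)
    variants = pd.concat([truth.variants, planted], ignore_index=True)
    variants = variants.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
        drop=True
    )
    causal = pd.concat(
        [truth.causal_genes, pd.DataFrame(causal_rows, columns=CAUSAL_COLUMNS)],
        ignore_index=True,
    )
    return TruthTable(variants=variants, causal_genes=causal)


def simulate_spectrum_survey(
    n: int,
    seed: int,
    spectrum=None,
    genome_length: int | None = None,
) -> pd.DataFrame:
    """Simulate ``n`` EMS-induced variants for spectrum estimation.

    A convenience wrapper: one line, no background layer, all ``n``
    mutations in the second round on a genome large enough that no
    reference base runs out.  Returns the truth variant frame.
    """
    config = SimulationConfig(
        genome_length=genome_length or max(200_000, 20 * n),
        n_chromosomes=1,
        n_genes=0,
        n_lines=1,
        background_snv_rate=0.0,
        ems1_count=0,
        ems2_count=n,
        green_leak_fraction=0.0,
        n_causal_genes=0,
        spectrum=spectrum if spectrum is not None else SimulationConfig().spectrum,
        seed=seed,
    )
    genome = generate_genome(config)
    return simulate_two_round_mutagenesis(config, genome).variants


# ---------------------------------------------------------------------------
# observed-data emission


def emit_sample_calls(
    truth: TruthTable, config: SimulationConfig, genome: GenomeModel
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    """Per-sample observed call sets plus per-sample depth masks.

    For each of the ``2 x n_lines`` samples, the visible truth variants
    are thinned at ``false_negative_rate``, spurious calls are added
    Poisson at ``false_positive_rate`` per bp with uniform alleles, and
    each call receives depth ~ Poisson(coverage_mean) (floored at 1),
    alt reads ~ Binomial(depth, 0.5 x sector_purity) for heterozygous
    variants (all reads for homozygous ones, floored at 1), the
    configured mean base quality, and a binomial-tail p-value.

    The masks cover the union of all truth and called loci with that
    sample's read depth, so downstream classification can distinguish a
    confident reference call from missing coverage.
    """
    if truth.variants.empty:
        raise SimulationError("truth table is empty; nothing to emit")
    calls: dict[str, pd.DataFrame] = {}
    truth_used = set(zip(truth.variants["chrom"], truth.variants["pos"]))
    for sample, line, sector in sample_layout(config):
        rng = stage_rng(config.seed, "calls", sample)
        vis = truth.visible_to(line, sector).reset_index(drop=True)
        keep = rng.random(len(vis)) >= config.false_negative_rate
        kept = vis[keep].reset_index(drop=True)
        n = len(kept)
        depth = np.maximum(rng.poisson(config.coverage_mean, size=n), 1)
        p_alt = np.where(kept["zygosity"] == "het", 0.5 * config.sector_purity, 1.0)
        alt_reads = np.clip(rng.binomial(depth, p_alt), 1, depth)
        frame = pd.DataFrame(
            {
                "chrom": kept["chrom"],
                "pos": kept["pos"],
                "ref": kept["ref"],
                "alt": kept["alt"],
                "sample": sample,
                "depth": depth,
                "alt_reads": alt_reads,
                "mean_baseq": float(config.mean_baseq),
                "p_value": score_sites(depth, alt_reads, config.mean_baseq),
                "zygosity": kept["zygosity"],
            }
        )
        n_fp = int(rng.poisson(config.false_positive_rate * genome.total_length))
        fp_rows = []
        own = set(zip(frame["chrom"], frame["pos"]))
        names = genome.chrom_names
        while len(fp_rows) < n_fp:
            ci = int(rng.integers(len(names)))
            chrom = names[ci]
            pos = int(rng.integers(1, len(genome.sequences[chrom]) + 1))
            if (chrom, pos) in truth_used or (chrom, pos) in own:
                continue
            ref = genome.base(chrom, pos)
            alt = str(rng.choice([b for b in BASES if b != ref]))
            d = max(int(rng.poisson(config.coverage_mean)), 1)
            a = int(np.clip(rng.binomial(d, 0.5 * config.sector_purity), 1, d))
            fp_rows.append(
                (chrom, pos, ref, alt, sample, d, a, float(config.mean_baseq),
                 float(score_sites(np.array([d]), np.array([a]), config.mean_baseq)[0]),
                 "het")
            )
            own.add((chrom, pos))
        if fp_rows:
            frame = pd.concat(
                [frame, pd.DataFrame(fp_rows, columns=CALL_COLUMNS)],
                ignore_index=True,
            )
        frame = frame.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
            drop=True
        )
        calls[sample] = frame[CALL_COLUMNS]

    loci = pd.concat(
        [truth.variants[["chrom", "pos"]]]
        + [c[["chrom", "pos"]] for c in calls.values()],
        ignore_index=True,
    ).drop_duplicates().sort_values(["chrom", "pos"], kind="mergesort").reset_index(
        drop=True
    )
    masks: dict[str, pd.DataFrame] = {}
    for sample, line, sector in sample_layout(config):
        rng = stage_rng(config.seed, "mask", sample)
        depth = rng.poisson(config.coverage_mean, size=len(loci))
        mask = loci.copy()
        mask["depth"] = depth
        call_depth = calls[sample].set_index(["chrom", "pos"])["depth"]
        idx = pd.MultiIndex.from_frame(mask[["chrom", "pos"]])
        overlap = idx.isin(call_depth.index)
        mask.loc[overlap, "depth"] = call_depth.loc[idx[overlap]].to_numpy()
        masks[sample] = mask
    return calls, masks


def emit_pileup(
    truth: TruthTable, config: SimulationConfig, genome: GenomeModel
) -> dict[str, str]:
    """Six-column pileup text per sample over every truth locus.

    Reads at a site carry the alternate base with probability 0.5 x
    sector_purity (heterozygous) or 1 (homozygous) when the variant is
    visible to the sample, and the reference base otherwise; each read
    base is then corrupted to a uniformly chosen different base with
    probability ``base_error_rate``.  Base qualities are normal around
    ``mean_baseq`` (sd 2, clipped to [2, 60]).
    """
    sites = truth.variants.sort_values(["chrom", "pos"], kind="mergesort")
    other = {b: [c for c in BASES if c != b] for b in BASES}
    pileups: dict[str, str] = {}
    for sample, line, sector in sample_layout(config):
        rng = stage_rng(config.seed, "pileup", sample)
        vis = truth.visible_to(line, sector)
        vis_map = {
            (c, p): (a, z)
            for c, p, a, z in zip(vis["chrom"], vis["pos"], vis["alt"], vis["zygosity"])
        }
        lines = []
        for chrom, pos, ref in zip(sites["chrom"], sites["pos"], sites["ref"]):
            d = max(int(rng.poisson(config.coverage_mean)), 1)
            hit = vis_map.get((chrom, pos))
            if hit is None:
                reads = [ref] * d
            else:
                alt, zyg = hit
                p_alt = 0.5 * config.sector_purity if zyg == "het" else 1.0
                reads = [
                    alt if rng.random() < p_alt else ref for _ in range(d)
                ]
            if config.base_error_rate > 0:
                reads = [
                    other[b][int(rng.integers(3))]
                    if rng.random() < config.base_error_rate
                    else b
                    for b in reads
                ]
            quals = np.clip(
                np.rint(rng.normal(config.mean_baseq, 2.0, size=d)), 2, 60
            ).astype(int)
            base_str = "".join("." if b == ref else b for b in reads)
            qual_str = "".join(chr(q + 33) for q in quals)
            lines.append(f"{chrom}\t{pos}\t{ref}\t{d}\t{base_str}\t{qual_str}")
        pileups[sample] = "\n".join(lines) + "\n"
    return pileups
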