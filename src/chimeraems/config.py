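"""Shared configuration objects and seeded random-stream helpers.

Every random draw in the package descends from a single master seed.
Each stage (genome synthesis, mutagenesis, causal-gene planting, call
emission, mask emission, pileup emission) pulls an independent stream
derived deterministically from ``(seed, stage label)``, so stages can be
re-run in isolation and still reproduce their output byte for byte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

import numpy as np

from .errors import ConfigurationError

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The 12 directed substitution types on the reference strand, in a fixed
#: lexicographic order.  "C/T" denotes a C->T change.
SUBSTITUTION_TYPES = tuple(f"{r}/{a}" for r in BASES for a in BASES if r != a)

TRANSITIONS = frozenset({"A/G", "G/A", "C/T", "T/C"})

YELLOW = "yellow"
GREEN = "green"
SECTORS = (YELLOW, GREEN)


def stage_rng(seed: int, *labels: object) -> np.random.Generator:
    """Return a Generator for one named stage of a seeded run.

    The stream is keyed on the master seed plus a CRC of each label, so
    distinct stages (and distinct samples within a stage) never share a
    stream, and the mapping is stable across platforms and sessions.
    """
    words = [int(seed) & 0x7FFFFFFF]
    words += [zlib.crc32(str(lab).encode("utf-8")) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(words))


@dataclass(frozen=True)
class SpectrumConfig:
    """Probabilities over the 12 directed substitution types.

    EMS alkylates guanine, so a realistic spectrum concentrates mass on
    C->T and G->A; the default is built from the published per-type
    percentages (C/T 37.8, G/A 36.9, A/G 7.05, remainder spread uniformly
    over the other nine types).
    """

    probabilities: Mapping[str, float]

    def __post_init__(self) -> None:
        probs = dict(self.probabilities)
        if set(probs) != set(SUBSTITUTION_TYPES):
            missing = sorted(set(SUBSTITUTION_TYPES) - set(probs))
            extra = sorted(set(probs) - set(SUBSTITUTION_TYPES))
            raise ConfigurationError(
                f"spectrum must cover exactly the 12 directed types; "
                f"missing={missing} unexpected={extra}"
            )
        if any(p < 0 for p in probs.values()):
            raise ConfigurationError("spectrum probabilities must be non-negative")
        total = float(sum(probs.values()))
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"spectrum probabilities must sum to 1 (got {total!r})"
            )
        object.__setattr__(self, "probabilities", MappingProxyType(probs))

    @classmethod
    def default_ems(cls) -> "SpectrumConfig":
        named = {"C/T": 0.378, "G/A": 0.369, "A/G": 0.0705}
        rest = (1.0 - sum(named.values())) / (len(SUBSTITUTION_TYPES) - len(named))
        return cls({t: named.get(t, rest) for t in SUBSTITUTION_TYPES})

    @classmethod
    def from_percentages(cls, percentages: Mapping[str, float]) -> "SpectrumConfig":
        total = float(sum(percentages.values()))
        if total <= 0:
            raise ConfigurationError("spectrum percentages must have positive total")
        return cls({t: percentages.get(t, 0.0) / total for t in SUBSTITUTION_TYPES})

    def as_arrays(self) -> tuple[tuple[str, ...], np.ndarray]:
        probs = np.array(
            [self.probabilities[t] for t in SUBSTITUTION_TYPES], dtype=float
        )
        return SUBSTITUTION_TYPES, probs / probs.sum()

    def complement_swapped(self) -> "SpectrumConfig":
        """Spectrum seen from the opposite strand (C/T <-> G/A etc.)."""
        swapped = {}
        for t, p in self.probabilities.items():
            r, a = t.split("/")
            swapped[f"{COMPLEMENT[r]}/{COMPLEMENT[a]}"] = p
        return SpectrumConfig(swapped)


@dataclass(frozen=True)
class SimulationConfig:
    """Design of one simulated double-mutagenesis experiment.

    Defaults describe the desk-scale study conditions: one 1 Mb
    chromosome, two independently mutagenized lines, ~200 cultivar
    background variants, 100 first-round and 100 second-round EMS
    mutations per line, a 5% second-round leak into the green sector,
    sparse non-overlapping genes, three planted causal genes, and
    noise-free emission at 30x coverage.
    """

    genome_length: int = 1_000_000        # bp per chromosome
    n_chromosomes: int = 1
    n_genes: int = 20
    gene_length: int = 1_000              # bp
    n_lines: int = 2
    background_snv_rate: float = 2e-4     # variants / bp, cultivar vs reference
    ems1_count: int = 100                 # first-round mutations per line
    ems2_count: int = 100                 # second-round mutations per line
    green_leak_fraction: float = 0.05     # share of round-2 hits landing in green
    spectrum: SpectrumConfig = field(default_factory=SpectrumConfig.default_ems)
    n_causal_genes: int = 3
    sector_purity: float = 1.0            # fraction of sector cells from the lineage
    coverage_mean: float = 30.0           # reads / site
    base_error_rate: float = 0.0          # sequencing errors / base (pileup only)
    mean_baseq: float = 30.0              # Phred
    false_positive_rate: float = 0.0      # spurious calls / bp / sample
    false_negative_rate: float = 0.0      # fraction of true calls dropped
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("genome_length", "n_chromosomes", "gene_length", "n_lines"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("n_genes", "ems1_count", "ems2_count", "n_causal_genes"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in (
            "background_snv_rate",
            "green_leak_fraction",
            "base_error_rate",
            "false_positive_rate",
            "false_negative_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1] (got {v!r})")
        if not 0.0 < self.sector_purity <= 1.0:
            raise ConfigurationError("sector_purity must lie in (0, 1]")
        if self.coverage_mean <= 0:
            raise ConfigurationError("coverage_mean must be positive")
        if self.mean_baseq <= 0:
            raise ConfigurationError("mean_baseq must be positive")
        if self.n_causal_genes > self.n_genes:
            raise ConfigurationError("n_causal_genes cannot exceed n_genes")

    @property
    def line_ids(self) -> tuple[str, ...]:
        return tuple(f"GY{i + 1}" for i in range(self.n_lines))

    @property
    def total_length(self) -> int:
        return self.genome_length * self.n_chromosomes


@dataclass(frozen=True)
class FilterThresholds:
    """SNP filtering criteria.

    A site is reported when all four hold: mean base quality strictly
    above ``min_baseq``, depth strictly above ``min_depth_exclusive``
    ("more than 8 reads"), at least ``min_alt_reads`` reads supporting
    the variant, and a site p-value strictly below ``max_p``.
    """

    min_baseq: float = 20.0
    min_depth_exclusive: int = 8
    min_alt_reads: int = 2
    max_p: float = 0.01

    def __post_init__(self) -> None:
        if self.min_baseq < 0 or self.min_depth_exclusive < 0 or self.min_alt_reads < 0:
            raise ConfigurationError("thresholds must be non-negative")
        if not 0.0 < self.max_p <= 1.0:
            raise ConfigurationError("max_p must lie in (0, 1]")
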