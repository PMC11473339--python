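"""Pileup-based SNP calling with four explicit filtering criteria.

The caller reads samtools-style six-column pileup text, picks the
best-supported non-reference base per site, scores it with a one-sided
binomial tail against the Phred-implied error rate, and reports the
site when all four criteria hold:

1. mean base quality of the supporting reads > ``min_baseq`` (default 20),
2. depth strictly greater than ``min_depth_exclusive`` (default 8,
   i.e. "more than 8 reads"),
3. at least ``min_alt_reads`` supporting reads (default 2),
4. p-value < ``max_p`` (default 0.01).

The p-value is P(X >= alt_reads) for X ~ Binomial(depth, eps) with
eps = 10^(-meanQ/10): the chance that sequencing error alone produced at
least the observed support.  This is a deliberately simple, exactly
specified test; full-featured callers use a Fisher-style read-count
test, which coincides with the binomial tail when reference-read error
is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy.stats import binom

from .config import BASES, FilterThresholds
from .errors import InputError, PileupParseError


def phred_error_rate(mean_baseq: float) -> float:
    return 10.0 ** (-float(mean_baseq) / 10.0)


def score_site(depth: int, alt_reads: int, mean_baseq: float) -> float:
    """One-sided binomial tail p-value for one site.

    Monotonically non-increasing in ``alt_reads`` at fixed depth;
    ``alt_reads == 0`` gives exactly 1.
    """
    depth = int(depth)
    alt_reads = int(alt_reads)
    if depth < 0 or alt_reads < 0 or alt_reads > depth:
        raise InputError(
            f"need 0 <= alt_reads <= depth (got alt_reads={alt_reads}, depth={depth})"
        )
    if mean_baseq <= 0:
        raise InputError("mean_baseq must be positive")
    if alt_reads == 0:
        return 1.0
    eps = phred_error_rate(mean_baseq)
    return float(binom.sf(alt_reads - 1, depth, eps))


def score_sites(depth: np.ndarray, alt_reads: np.ndarray, mean_baseq: float) -> np.ndarray:
    """Vectorised ``score_site`` for equal-quality batches."""
    depth = np.asarray(depth, dtype=int)
    alt_reads = np.asarray(alt_reads, dtype=int)
    eps = phred_error_rate(mean_baseq)
    p = binom.sf(alt_reads - 1, depth, eps)
    return np.where(alt_reads == 0, 1.0, p)


def passes_filters(
    depth: int,
    alt_reads: int,
    mean_baseq: float,
    p_value: float,
    thresholds: FilterThresholds = FilterThresholds(),
) -> bool:
    """The four-criteria predicate, exposed for direct testing."""
    return (
        mean_baseq > thresholds.min_baseq
        and depth > thresholds.min_depth_exclusive
        and alt_reads >= thresholds.min_alt_reads
        and p_value < thresholds.max_p
    )


@dataclass(frozen=True)
class PileupSite:
    chrom: str
    pos: int               # 1-based
    ref: str
    depth: int
    bases: str             # one symbol per read, escapes stripped, '.'=ref
    quals: tuple[int, ...]  # Phred, one per read


def _strip_read_bases(raw: str, line_no: int) -> str:
    """Resolve pileup escapes to one symbol per read.

    Handles ``^Q`` (read start + mapping quality), ``$`` (read end) and
    ``+N.../-N...`` indel insertions; keeps ``*`` placeholders as reads
    that support nothing.
    """
    out = []
    i = 0
    n = len(raw)
    while i < n:
        c = raw[i]
        if c == "^":
            i += 2  # skip the mapping-quality byte too
        elif c == "$":
            i += 1
        elif c in "+-":
            i += 1
            j = i
            while j < n and raw[j].isdigit():
                j += 1
            if j == i:
                raise PileupParseError(f"line {line_no}: malformed indel length")
            length = int(raw[i:j])
            i = j + length
        else:
            out.append(c)
            i += 1
    return "".join(out)


def parse_pileup(lines: Iterable[str]) -> Iterator[PileupSite]:
    """Parse six-column pileup text, yielding one record per site."""
    for line_no, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise PileupParseError(
                f"line {line_no}: expected 6 tab-separated fields, got {len(fields)}"
            )
        chrom, pos_s, ref, depth_s, raw_bases, qual_s = fields[:6]
        try:
            pos = int(pos_s)
            depth = int(depth_s)
        except ValueError as exc:
            raise PileupParseError(f"line {line_no}: non-integer pos/depth") from exc
        ref = ref.upper()
        if ref not in BASES and ref != "N":
            raise PileupParseError(f"line {line_no}: bad reference base {ref!r}")
        bases = _strip_read_bases(raw_bases, line_no)
        if len(bases) != depth or len(qual_s) != depth:
            raise PileupParseError(
                f"line {line_no}: depth {depth} does not match "
                f"{len(bases)} read bases / {len(qual_s)} qualities"
            )
        quals = tuple(ord(q) - 33 for q in qual_s)
        yield PileupSite(chrom, pos, ref, depth, bases, quals)


def call_site(site: PileupSite) -> tuple[str, int, float, bool] | None:
    """Pick the alt allele at one site.

    Returns ``(alt, alt_reads, mean_baseq_of_alt_reads, multiallelic)``
    or None when no read supports a non-reference base.  Ties are broken
    alphabetically; a site with more than one observed non-reference
    base is flagged multiallelic.
    """
    support: dict[str, list[int]] = {}
    for sym, q in zip(site.bases, site.quals):
        b = sym.upper()
        if b in (".", ","):
            continue
        if b in BASES and b != site.ref:
            support.setdefault(b, []).append(q)
    if not support:
        return None
    alt = max(sorted(support), key=lambda b: len(support[b]))
    # sorted() first, max() keeps the first maximum -> alphabetical tie-break
    quals = support[alt]
    return alt, len(quals), float(np.mean(quals)), len(support) > 1


def call_and_filter(
    pileup: Iterable[str] | str,
    thresholds: FilterThresholds = FilterThresholds(),
    sample: str = "sample",
) -> pd.DataFrame:
    """Run the caller over pileup text and apply the four criteria.

    ``pileup`` may be a string of newline-separated lines or an iterable
    of lines.  Returns a frame with columns chrom, pos, ref, alt,
    sample, depth, alt_reads, mean_baseq, p_value, multiallelic.
    """
    if isinstance(pileup, str):
        pileup = pileup.splitlines()
    rows = []
    for site in parse_pileup(pileup):
        if site.ref == "N" or site.depth == 0:
            continue
        picked = call_site(site)
        if picked is None:
            continue
        alt, alt_reads, mean_q, multi = picked
        p = score_site(site.depth, alt_reads, mean_q)
        if passes_filters(site.depth, alt_reads, mean_q, p, thresholds):
            rows.append(
                (site.chrom, site.pos, site.ref, alt, sample,
                 site.depth, alt_reads, mean_q, p, multi)
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "sample",
                 "depth", "alt_reads", "mean_baseq", "p_value", "multiallelic"],
    )
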