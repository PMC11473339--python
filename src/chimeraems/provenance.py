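"""Partition SNP loci into background / first-round / second-round classes.

Given one call set per leaf sector of each mutagenized line, each locus
is classified from the pattern of allele presence and callable absence
across samples:

* ``BACKGROUND`` — every sample of every line carries the same alternate
  allele: a cultivar-vs-reference difference predating mutagenesis.
* ``EMS1(line)`` — both sectors of exactly one line carry the allele and
  every other sample is confidently reference: a first-round mutation,
  fixed before the sectors diverged.
* ``EMS2(line, sector)`` — exactly one sample carries the allele and all
  others are confidently reference: a second-round, sector-private
  mutation.
* ``AMBIGUOUS`` — anything else (conflicting alleles, sharing across
  lines that falls short of all samples, or a required absence resting
  on an uncallable sample), with a machine-readable reason code.

"Same genotype" means same alternate allele; zygosity is ignored, since
pooled sector tissue makes it unreliable.  Absence is only trusted where
the sample's depth mask reaches the callability floor (default 8 reads,
mirroring the caller's coverage criterion) — a locus nobody sequenced is
not evidence of anything.

With a single line the background/first-round distinction is
unidentifiable (no second line to witness the allele); shared-within-
line loci are then labelled ``UNRESOLVED_SHARED`` and a warning is
logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .config import BASES, SECTORS
from .errors import InputError

log = logging.getLogger(__name__)

ALT_STATES = set(BASES)
REF_CALLABLE = "REF_CALLABLE"
UNCALLABLE = "UNCALLABLE"

CLASS_BACKGROUND = "BACKGROUND"
CLASS_EMS1 = "EMS1"
CLASS_EMS2 = "EMS2"
CLASS_AMBIGUOUS = "AMBIGUOUS"
CLASS_UNRESOLVED = "UNRESOLVED_SHARED"

REASON_CONFLICT = "conflicting-alleles"
REASON_CROSS_LINE = "cross-line"
REASON_UNCALLABLE = "uncallable-absence"
REASON_NO_ALT = "no-alt"


class SampleSheet:
    """Sample metadata: one sample per (line, sector), both sectors per line."""

    def __init__(self, frame: pd.DataFrame) -> None:
        required = {"sample", "line", "sector"}
        if not required.issubset(frame.columns):
            raise InputError(f"sample sheet needs columns {sorted(required)}")
        frame = frame[["sample", "line", "sector"]].astype(str).reset_index(drop=True)
        bad = set(frame["sector"]) - set(SECTORS)
        if bad:
            raise InputError(f"unknown sectors {sorted(bad)}; expected {SECTORS}")
        if frame["sample"].duplicated().any():
            raise InputError("duplicate sample ids in sheet")
        if frame.duplicated(["line", "sector"]).any():
            raise InputError("more than one sample for a (line, sector) pair")
        for line, sub in frame.groupby("line"):
            if set(sub["sector"]) != set(SECTORS):
                raise InputError(
                    f"line {line!r} must have exactly one yellow and one "
                    f"green sample"
                )
        if frame.empty:
            raise InputError("sample sheet is empty")
        self.frame = frame
        self._line_of = dict(zip(frame["sample"], frame["line"]))
        self._sector_of = dict(zip(frame["sample"], frame["sector"]))
        self._sample_of = {
            (r.line, r.sector): r.sample for r in frame.itertuples()
        }

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.frame["sample"])

    @property
    def lines(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.frame["line"]))

    def line_of(self, sample: str) -> str:
        return self._line_of[sample]

    def sector_of(self, sample: str) -> str:
        return self._sector_of[sample]

    def sample_for(self, line: str, sector: str) -> str:
        try:
            return self._sample_of[(line, sector)]
        except KeyError:
            raise InputError(f"no sample for line={line!r} sector={sector!r}")

    @classmethod
    def from_layout(cls, layout: list[tuple[str, str, str]]) -> "SampleSheet":
        return cls(pd.DataFrame(layout, columns=["sample", "line", "sector"]))


@dataclass(frozen=True)
class Classification:
    label: str                # BACKGROUND / EMS1 / EMS2 / AMBIGUOUS / UNRESOLVED_SHARED
    line: str = ""
    sector: str = ""
    reason: str = ""


@dataclass
class PartitionResult:
    """Per-locus classes plus the Venn-style summary counts."""

    loci: pd.DataFrame   # chrom,pos,ref,alt,label,line,sector,reason
    venn: pd.DataFrame   # cell,label,line,sector,count

    @property
    def n_loci(self) -> int:
        return len(self.loci)


def build_locus_matrix(
    calls: Mapping[str, pd.DataFrame],
    masks: Mapping[str, pd.DataFrame] | None,
    sheet: SampleSheet,
    min_callable_depth: int = 8,
    missing_mask_policy: str = "callable",
) -> pd.DataFrame:
    """Union all called loci into one per-sample state matrix.

    Each row carries, per sample, either the called alternate allele,
    ``REF_CALLABLE`` (no call, mask depth >= the floor) or
    ``UNCALLABLE``.  When a sample has no mask, absence is treated per
    ``missing_mask_policy``: ``"callable"`` (trust the call set,
    pragmatic default for externally called VCFs) or ``"uncallable"``
    (strict).
    """
    unknown = set(calls) - set(sheet.samples)
    if unknown:
        raise InputError(f"call sets for unknown samples: {sorted(unknown)}")
    if missing_mask_policy not in ("callable", "uncallable"):
        raise InputError("missing_mask_policy must be 'callable' or 'uncallable'")
    pieces = [
        c[["chrom", "pos", "ref"]] for c in calls.values() if not c.empty
    ]
    if not pieces:
        return pd.DataFrame(columns=["chrom", "pos", "ref"])
    loci = (
        pd.concat(pieces, ignore_index=True)
        .drop_duplicates(["chrom", "pos"])
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    idx = pd.MultiIndex.from_frame(loci[["chrom", "pos"]])
    for sample in sheet.samples:
        c = calls.get(sample)
        state = np.full(len(loci), "", dtype=object)
        if c is not None and not c.empty:
            alt = c.drop_duplicates(["chrom", "pos"]).set_index(["chrom", "pos"])["alt"]
            hit = idx.isin(alt.index)
            state[hit] = alt.loc[idx[hit]].to_numpy()
        no_call = state == ""
        mask = masks.get(sample) if masks else None
        if mask is None:
            fallback = REF_CALLABLE if missing_mask_policy == "callable" else UNCALLABLE
            state[no_call] = fallback
        else:
            depth = mask.drop_duplicates(["chrom", "pos"]).set_index(
                ["chrom", "pos"]
            )["depth"]
            covered = idx.isin(depth.index)
            depths = np.zeros(len(loci))
            depths[covered] = depth.loc[idx[covered]].to_numpy()
            state[no_call & (depths >= min_callable_depth)] = REF_CALLABLE
            state[no_call & (depths < min_callable_depth)] = UNCALLABLE
        loci[sample] = state
    return loci


def classify_locus(
    pattern: Mapping[str, str], sheet: SampleSheet
) -> Classification:
    """Classify one locus from its per-sample states.

    ``pattern`` maps every sample to an alternate allele (A/C/G/T),
    ``REF_CALLABLE`` or ``UNCALLABLE``.
    """
    missing = set(sheet.samples) - set(pattern)
    if missing:
        raise InputError(f"pattern lacks states for samples {sorted(missing)}")
    alt_samples = {s: pattern[s] for s in sheet.samples if pattern[s] in ALT_STATES}
    others = [s for s in sheet.samples if s not in alt_samples]

    if not alt_samples:
        return Classification(CLASS_AMBIGUOUS, reason=REASON_NO_ALT)
    if len(set(alt_samples.values())) > 1:
        return Classification(CLASS_AMBIGUOUS, reason=REASON_CONFLICT)

    alt_lines = {sheet.line_of(s) for s in alt_samples}
    all_others_callable = all(pattern[s] == REF_CALLABLE for s in others)

    if len(alt_samples) == len(sheet.samples):
        if len(sheet.lines) == 1:
            return Classification(CLASS_UNRESOLVED, line=next(iter(alt_lines)))
        return Classification(CLASS_BACKGROUND)

    if len(alt_samples) == 1:
        (sample,) = alt_samples
        if all_others_callable:
            return Classification(
                CLASS_EMS2, line=sheet.line_of(sample), sector=sheet.sector_of(sample)
            )
        return Classification(CLASS_AMBIGUOUS, reason=REASON_UNCALLABLE)

    if len(alt_lines) == 1 and len(alt_samples) == 2:
        # both sectors of one line
        line = next(iter(alt_lines))
        if all_others_callable:
            if len(sheet.lines) == 1:
                return Classification(CLASS_UNRESOLVED, line=line)
            return Classification(CLASS_EMS1, line=line)
        return Classification(CLASS_AMBIGUOUS, reason=REASON_UNCALLABLE)

    return Classification(CLASS_AMBIGUOUS, reason=REASON_CROSS_LINE)


def partition(matrix: pd.DataFrame, sheet: SampleSheet) -> PartitionResult:
    """Classify every locus of the matrix and summarise Venn counts."""
    if len(sheet.lines) < 2:
        log.warning(
            "single-line input: background and first-round mutations are "
            "confounded; shared loci will be UNRESOLVED_SHARED"
        )
    rows = []
    for rec in matrix.itertuples(index=False):
        pattern = {s: getattr(rec, s) for s in sheet.samples}
        cl = classify_locus(pattern, sheet)
        alleles = sorted({pattern[s] for s in sheet.samples if pattern[s] in ALT_STATES})
        rows.append(
            (rec.chrom, rec.pos, rec.ref, ",".join(alleles),
             cl.label, cl.line, cl.sector, cl.reason)
        )
    loci = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "label", "line", "sector", "reason"],
    )
    return PartitionResult(loci=loci, venn=venn_counts_frame(loci, sheet))


def venn_counts_frame(loci: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """Venn-style cell counts: shared-by-all, shared-per-line, unique-per-sample.

    Cells appear even when empty, in a deterministic order, so runs are
    directly comparable.
    """
    cells: list[tuple[str, str, str, str]] = [("shared_all", CLASS_BACKGROUND, "", "")]
    for line in sheet.lines:
        cells.append((f"shared_{line}", CLASS_EMS1, line, ""))
    for line in sheet.lines:
        for sector in SECTORS:
            cells.append(
                (f"unique_{sheet.sample_for(line, sector)}", CLASS_EMS2, line, sector)
            )
    cells.append(("unresolved_shared", CLASS_UNRESOLVED, "", ""))
    cells.append(("ambiguous", CLASS_AMBIGUOUS, "", ""))
    rows = []
    for cell, label, line, sector in cells:
        sub = loci[loci["label"] == label]
        if line:
            sub = sub[sub["line"] == line]
        if sector:
            sub = sub[sub["sector"] == sector]
        rows.append((cell, label, line, sector, len(sub)))
    return pd.DataFrame(rows, columns=["cell", "label", "line", "sector", "count"])


def venn_counts(result: PartitionResult) -> pd.DataFrame:
    return result.venn
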