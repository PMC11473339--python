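"""Chlorophyll quantitation from two-wavelength absorbance readings.

Chlorophyll a and b absorb maximally near 663 nm and 645 nm in
ethanol/acetone extracts; the Arnon-style two-wavelength equations
deconvolve the overlapping spectra:

    chlA  = (12.72*A663 - 2.59*A645) * V / (1000*m)   [mg per g fresh weight]
    chlB  = (22.88*A645 - 4.76*A663) * V / (1000*m)
    total = ( 8.75*A663 + 20.29*A645) * V / (1000*m)

with V the extract volume in mL and m the sample mass in g.  Note that
with these coefficients ``total`` is an independent regression, not the
sum chlA + chlB (the two differ by 0.79*A663*V/(1000*m)).  Results are
conventionally reported to three significant digits; raw values are
retained alongside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .errors import InputError

log = logging.getLogger(__name__)

CHLA_COEF = (12.72, -2.59)
CHLB_COEF = (-4.76, 22.88)
TOTAL_COEF = (8.75, 20.29)


@dataclass(frozen=True)
class AbsorbanceRecord:
    """One spectrophotometer reading for one extract.

    ``a663``/``a645`` are the absorbances driving the equations; ``a470``
    (carotenoid region) is carried through for bookkeeping but unused —
    no carotenoid formula is applied.
    """

    a663: float
    a645: float
    volume_ml: float
    mass_g: float
    a470: float | None = None
    sample: str = ""

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise InputError(f"extract volume must be positive (got {self.volume_ml})")
        if self.mass_g <= 0:
            raise InputError(f"sample mass must be positive (got {self.mass_g})")
        if self.a663 < 0 or self.a645 < 0:
            raise InputError("absorbances must be non-negative")


@dataclass(frozen=True)
class PigmentResult:
    """Chlorophyll contents in mg/g fresh weight, raw and rounded."""

    chla_raw: float
    chlb_raw: float
    total_raw: float
    chla: float
    chlb: float
    total: float
    sample: str = ""


def round_significant(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures, half to even.

    0 maps to 0.  Uses decimal rounding on the shortest repr of ``x`` so
    values like 0.10462 round on their decimal digits, not their binary
    representation.
    """
    if digits < 1:
        raise InputError("digits must be >= 1")
    if x == 0 or not math.isfinite(x):
        return float(x)
    from decimal import ROUND_HALF_EVEN, Decimal

    d = Decimal(repr(float(x)))
    exponent = d.adjusted() - (digits - 1)
    return float(d.quantize(Decimal(1).scaleb(exponent), rounding=ROUND_HALF_EVEN))


def chlorophyll_content(rec: AbsorbanceRecord, digits: int = 3) -> PigmentResult:
    """Apply the two-wavelength equations to one absorbance record.

    Negative raw values (possible with a miscalibrated blank) are
    reported as-is with a warning rather than clamped, so the anomaly
    stays visible downstream.
    """
    scale = rec.volume_ml / (1000.0 * rec.mass_g)
    chla = (CHLA_COEF[0] * rec.a663 + CHLA_COEF[1] * rec.a645) * scale
    chlb = (CHLB_COEF[0] * rec.a663 + CHLB_COEF[1] * rec.a645) * scale
    total = (TOTAL_COEF[0] * rec.a663 + TOTAL_COEF[1] * rec.a645) * scale
    if chla < 0 or chlb < 0 or total < 0:
        log.warning(
            "negative pigment content for sample %r (chlA=%.4g chlB=%.4g total=%.4g); "
            "check the blank calibration",
            rec.sample, chla, chlb, total,
        )
    return PigmentResult(
        chla_raw=chla,
        chlb_raw=chlb,
        total_raw=total,
        chla=round_significant(chla, digits),
        chlb=round_significant(chlb, digits),
        total=round_significant(total, digits),
        sample=rec.sample,
    )


def pigment_table(records: pd.DataFrame, digits: int = 3) -> pd.DataFrame:
    """Vectorised convenience over a TSV-shaped frame.

    Expects columns ``sample, a663, a645, volume_ml, mass_g`` (an
    optional ``a470`` is ignored); returns one row per record with raw
    and rounded contents.
    """
    rows = []
    for _, r in records.iterrows():
        res = chlorophyll_content(
            AbsorbanceRecord(
                a663=float(r["a663"]),
                a645=float(r["a645"]),
                volume_ml=float(r["volume_ml"]),
                mass_g=float(r["mass_g"]),
                sample=str(r.get("sample", "")),
            ),
            digits=digits,
        )
        rows.append(
            (res.sample, res.chla, res.chlb, res.total,
             res.chla_raw, res.chlb_raw, res.total_raw)
        )
    return pd.DataFrame(
        rows,
        columns=["sample", "chla", "chlb", "total",
                 "chla_raw", "chlb_raw", "total_raw"],
    )
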