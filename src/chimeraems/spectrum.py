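"""Directed substitution-type classification and spectrum tables.

A substitution is recorded on the reference strand as ``ref/alt``
(``"C/T"`` meaning C->T).  The 12 directed types are kept separate —
complementary pairs such as C/T and G/A are *not* collapsed, because the
two strands of an EMS-mutagenized genome are reported separately in this
analysis.  Transitions are A/G, G/A, C/T and T/C; the other eight types
are transversions.  The canonical EMS signature is the combined C/T +
G/A share.
"""

from __future__ import annotations

import pandas as pd

from .config import BASES, COMPLEMENT, SUBSTITUTION_TYPES, TRANSITIONS
from .errors import InputError

_PURINES = {"A", "G"}


def substitution_type(ref: str, alt: str) -> tuple[str, str]:
    """Classify one substitution.

    Returns ``(label, kind)`` where ``label`` is the directed type (e.g.
    ``"G/A"``) and ``kind`` is ``"transition"`` or ``"transversion"``.
    """
    ref = str(ref).upper()
    alt = str(alt).upper()
    if ref not in BASES or alt not in BASES:
        raise InputError(f"bases must be one of A/C/G/T (got ref={ref!r}, alt={alt!r})")
    if ref == alt:
        raise InputError(f"ref and alt must differ (both {ref!r})")
    label = f"{ref}/{alt}"
    kind = "transition" if label in TRANSITIONS else "transversion"
    return label, kind


def is_transition(label: str) -> bool:
    return label in TRANSITIONS


def complement_type(label: str) -> str:
    """Map a directed type to its opposite-strand equivalent."""
    ref, alt = label.split("/")
    return f"{COMPLEMENT[ref]}/{COMPLEMENT[alt]}"


def spectrum_table(
    records: pd.DataFrame,
    group_by: str | None = None,
) -> pd.DataFrame:
    """Tabulate counts and percentages over the 12 directed types.

    ``records`` needs ``ref`` and ``alt`` columns; with ``group_by`` the
    table carries one block of 12 rows per group (zero counts included),
    otherwise a single block under group ``"all"``.  Percentages are of
    the group total and retain full precision; round only for display.
    An empty input yields an empty table.
    """
    columns = ["group", "type", "count", "percent"]
    if records.empty:
        return pd.DataFrame(columns=columns)
    labels = [
        substitution_type(r, a)[0]
        for r, a in zip(records["ref"], records["alt"])
    ]
    work = pd.DataFrame(
        {
            "group": records[group_by].astype(str).to_numpy()
            if group_by is not None
            else "all",
            "type": labels,
        }
    )
    rows = []
    for group, sub in work.groupby("group", sort=True):
        counts = sub["type"].value_counts()
        total = int(counts.sum())
        for t in SUBSTITUTION_TYPES:
            c = int(counts.get(t, 0))
            rows.append((group, t, c, 100.0 * c / total))
    return pd.DataFrame(rows, columns=columns)


def canonical_ems_fraction(table: pd.DataFrame, group: str | None = None) -> float:
    """Combined C/T + G/A percentage of a spectrum table.

    The two transitions produced by guanine alkylation are the canonical
    EMS signature.  Returns NaN for an empty table.
    """
    if table.empty:
        return float("nan")
    sub = table if group is None else table[table["group"] == group]
    total = sub["count"].sum()
    if total == 0:
        return float("nan")
    canon = sub.loc[sub["type"].isin(["C/T", "G/A"]), "count"].sum()
    return 100.0 * float(canon) / float(total)


def type_percent(table: pd.DataFrame, label: str, group: str | None = None) -> float:
    """Percentage of one directed type in a spectrum table."""
    sub = table if group is None else table[table["group"] == group]
    hit = sub.loc[sub["type"] == label, "percent"]
    return float(hit.iloc[0]) if len(hit) else float("nan")


def empirical_spectrum(records: pd.DataFrame) -> dict[str, float]:
    """Per-type empirical frequencies (fractions summing to 1)."""
    table = spectrum_table(records)
    if table.empty:
        return {t: float("nan") for t in SUBSTITUTION_TYPES}
    return {
        row["type"]: row["percent"] / 100.0 for _, row in table.iterrows()
    }


def plot_spectrum(table: pd.DataFrame, path) -> None:
    """Bar chart of per-type counts, one panel row per group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = sorted(table["group"].unique())
    fig, axes = plt.subplots(
        len(groups), 1, figsize=(8, 2.2 * max(len(groups), 1)), squeeze=False
    )
    for ax, group in zip(axes[:, 0], groups):
        sub = table[table["group"] == group].set_index("type").reindex(
            list(SUBSTITUTION_TYPES)
        )
        ax.bar(range(len(SUBSTITUTION_TYPES)), sub["count"], color="#41683f")
        ax.set_xticks(range(len(SUBSTITUTION_TYPES)))
        ax.set_xticklabels(SUBSTITUTION_TYPES, rotation=45, fontsize=7)
        ax.set_ylabel("SNPs")
        ax.set_title(str(group), fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
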