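"""Parsing and summarizing differential enzyme-abundance tables.

The input is a single delimited text file produced upstream by a
differential-abundance analysis (e.g. an edgeR contrast of two treatments):
one row per EC number with its log2 fold change, raw and adjusted p-value,
and a three-way association label (treatment_1, treatment_2 or
not_associated).  Column headers vary between exporters, so the expected
names are configurable through :class:`TableDialect`.
"""

from __future__ import annotations

import enum
import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "Association",
    "DifferentialEnzymeRecord",
    "DifferentialEnzymeTable",
    "TableDialect",
    "TableSummary",
    "parse_differential_table",
    "write_differential_table",
    "summarize_table",
    "plot_summary",
]

# EC numbers are four dot-separated fields; trailing fields may be "-" for
# partial classifications (e.g. "1.1.1.-").
_EC_PATTERN = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")


class Association(str, enum.Enum):
    """Which treatment (if any) an enzyme is differentially associated with."""

    TREATMENT_1 = "treatment_1"
    TREATMENT_2 = "treatment_2"
    NOT_ASSOCIATED = "not_associated"


@dataclass(frozen=True)
class DifferentialEnzymeRecord:
    """One EC number with its differential-abundance statistics."""

    ec_id: str
    log_fc: float
    p_value: float
    adj_p_value: float
    association: Association

    def __post_init__(self) -> None:
        if not self.ec_id or not _EC_PATTERN.match(self.ec_id):
            raise ValidationError(
                f"invalid EC identifier {self.ec_id!r}: expected dotted "
                "pattern like 1.1.1.1 or 1.1.1.-"
            )
        for name in ("p_value", "adj_p_value"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name}={value} outside [0, 1] for EC {self.ec_id}")


@dataclass
class DifferentialEnzymeTable:
    """Ordered collection of per-EC records plus treatment display names."""

    records: list[DifferentialEnzymeRecord]
    treatment_labels: tuple[str, str] = ("treatment_1", "treatment_2")

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("empty data section: table has no records")
        seen: dict[str, int] = {}
        duplicates = []
        for rec in self.records:
            if rec.ec_id in seen:
                duplicates.append(rec.ec_id)
            seen[rec.ec_id] = seen.get(rec.ec_id, 0) + 1
        if duplicates:
            raise ValidationError(
                "duplicate EC identifiers in table: " + ", ".join(sorted(set(duplicates)))
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ec_ids(self) -> list[str]:
        return [rec.ec_id for rec in self.records]


@dataclass
class TableDialect:
    """Column naming and label mapping for the input file.

    ``association_synonyms`` maps extra labels (case-insensitively) onto the
    canonical enum; the two treatment display names are always accepted as
    synonyms for their class, mirroring inputs that say e.g. "root"/"soil"
    instead of "Treatment_1"/"Treatment_2".
    """

    ec_column: str = "ec"
    log_fc_column: str = "logFC"
    p_value_column: str = "PValue"
    adj_p_value_column: str = "FDR"
    association_column: str = "association"
    association_synonyms: Mapping[str, Association] = field(default_factory=dict)

    def required_columns(self) -> list[str]:
        return [
            self.ec_column,
            self.log_fc_column,
            self.p_value_column,
            self.adj_p_value_column,
            self.association_column,
        ]


_BUILTIN_LABELS: dict[str, Association] = {
    "treatment_1": Association.TREATMENT_1,
    "treatment1": Association.TREATMENT_1,
    "t1": Association.TREATMENT_1,
    "treatment_2": Association.TREATMENT_2,
    "treatment2": Association.TREATMENT_2,
    "t2": Association.TREATMENT_2,
    "not_associated": Association.NOT_ASSOCIATED,
    "not-associated": Association.NOT_ASSOCIATED,
    "notassociated": Association.NOT_ASSOCIATED,
    "none": Association.NOT_ASSOCIATED,
    "ns": Association.NOT_ASSOCIATED,
}


def _association_map(
    dialect: TableDialect, treatment_labels: tuple[str, str]
) -> dict[str, Association]:
    mapping = dict(_BUILTIN_LABELS)
    mapping[treatment_labels[0].lower()] = Association.TREATMENT_1
    mapping[treatment_labels[1].lower()] = Association.TREATMENT_2
    for label, assoc in dialect.association_synonyms.items():
        mapping[label.lower()] = Association(assoc)
    return mapping


def _strip_ec(raw: str) -> str:
    raw = raw.strip()
    if raw.lower().startswith("ec:"):
        raw = raw[3:]
    return raw.strip()


def parse_differential_table(
    source: Union[str, Path, TextIO],
    dialect: TableDialect | None = None,
    treatment_labels: tuple[str, str] = ("treatment_1", "treatment_2"),
) -> DifferentialEnzymeTable:
    """Parse a delimited differential-abundance file into a validated table.

    The delimiter is auto-detected among comma, tab and semicolon.  Rows are
    preserved in file order.  Raises :class:`FormatError` when a required
    column is missing and :class:`ValidationError` for duplicate ECs,
    unmappable association labels or an empty data section.
    """
    dialect = dialect or TableDialect()
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()

    try:
        frame = pd.read_csv(
            io.StringIO(text), sep=None, engine="python", dtype=str,
            skip_blank_lines=True,
        )
    except Exception as exc:  # pragma: no cover - pandas error classes vary
        raise FormatError(f"could not parse delimited input: {exc}") from exc

    frame.columns = [str(c).strip() for c in frame.columns]
    missing = [c for c in dialect.required_columns() if c not in frame.columns]
    if missing:
        raise FormatError(
            "missing required column(s): " + ", ".join(missing)
            + f" (found: {', '.join(frame.columns)})"
        )
    if frame.empty:
        raise ValidationError("empty data section: file contains a header but no rows")

    label_map = _association_map(dialect, treatment_labels)
    records: list[DifferentialEnzymeRecord] = []
    for _, row in frame.iterrows():
        raw_assoc = str(row[dialect.association_column]).strip()
        assoc = label_map.get(raw_assoc.lower())
        if assoc is None:
            raise ValidationError(
                f"unmappable association label {raw_assoc!r} "
                f"(accepted: {sorted(label_map)})"
            )
        try:
            records.append(
                DifferentialEnzymeRecord(
                    ec_id=_strip_ec(str(row[dialect.ec_column])),
                    log_fc=float(row[dialect.log_fc_column]),
                    p_value=float(row[dialect.p_value_column]),
                    adj_p_value=float(row[dialect.adj_p_value_column]),
                    association=assoc,
                )
            )
        except ValueError as exc:
            raise FormatError(f"non-numeric statistic in row for EC "
                              f"{row[dialect.ec_column]!r}: {exc}") from exc
    return DifferentialEnzymeTable(records=records, treatment_labels=treatment_labels)


def write_differential_table(
    table: DifferentialEnzymeTable,
    path: Union[str, Path],
    dialect: TableDialect | None = None,
) -> None:
    """Write a table back to CSV in the given dialect (round-trip partner)."""
    dialect = dialect or TableDialect()
    frame = pd.DataFrame(
        {
            dialect.ec_column: [r.ec_id for r in table.records],
            dialect.log_fc_column: [r.log_fc for r in table.records],
            dialect.p_value_column: [r.p_value for r in table.records],
            dialect.adj_p_value_column: [r.adj_p_value for r in table.records],
            dialect.association_column: [r.association.value for r in table.records],
        }
    )
    frame.to_csv(path, index=False)


@dataclass
class TableSummary:
    """Counts, fractions and plotting vectors per association category."""

    counts: dict[str, int]
    fractions: dict[str, float]
    volcano: dict[str, list[tuple[float, float]]]  # (log_fc, adj_p_value)
    p_values: dict[str, list[float]]
    total: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "total": self.total,
                "counts": self.counts,
                "fractions": self.fractions,
            },
            indent=2,
            sort_keys=True,
        )


def summarize_table(table: DifferentialEnzymeTable) -> TableSummary:
    """Tally records per association class, with vectors for the three
    standard input-overview panels (volcano scatter, pie, p-value histogram)."""
    counts = {a.value: 0 for a in Association}
    volcano: dict[str, list[tuple[float, float]]] = {a.value: [] for a in Association}
    p_values: dict[str, list[float]] = {a.value: [] for a in Association}
    for rec in table.records:
        key = rec.association.value
        counts[key] += 1
        volcano[key].append((rec.log_fc, rec.adj_p_value))
        p_values[key].append(rec.p_value)
    total = len(table.records)
    fractions = {k: v / total for k, v in counts.items()}
    return TableSummary(
        counts=counts, fractions=fractions, volcano=volcano,
        p_values=p_values, total=total,
    )


def plot_summary(
    summary: TableSummary,
    out_dir: Union[str, Path],
    prefix: str = "input",
) -> list[Path]:
    """Render the three overview panels as PNG files; returns written paths."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    import numpy as np

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    colors = {
        Association.TREATMENT_1.value: "#d95f02",
        Association.TREATMENT_2.value: "#1b9e77",
        Association.NOT_ASSOCIATED.value: "#999999",
    }

    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, pairs in summary.volcano.items():
        if not pairs:
            continue
        fc, adj = zip(*pairs)
        adj = np.clip(np.asarray(adj, dtype=float), 1e-300, None)
        ax.scatter(fc, -np.log10(adj), s=10, label=cls, color=colors[cls], alpha=0.7)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 adjusted p-value")
    ax.legend(fontsize=7)
    path = out_dir / f"{prefix}_volcano.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(4, 4))
    labels = [k for k, v in summary.counts.items() if v > 0]
    sizes = [summary.counts[k] for k in labels]
    ax.pie(sizes, labels=labels, colors=[colors[k] for k in labels],
           autopct="%1.1f%%", textprops={"fontsize": 7})
    path = out_dir / f"{prefix}_pie.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(5, 4))
    all_p = [p for ps in summary.p_values.values() for p in ps]
    ax.hist(all_p, bins=20, color="#555555")
    ax.set_xlabel("p-value")
    ax.set_ylabel("count")
    path = out_dir / f"{prefix}_pvalues.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    return written
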