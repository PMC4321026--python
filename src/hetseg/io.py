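"""Readers/writers for the delimited count-table formats, plus the
packaged count fixtures.

Dialect: tab-separated, UTF-8, mandatory header row, "." decimal
separator.  Malformed rows are reported with their line number and the
offending field.  Fixtures store raw counts and footnote-level subsets
only; every percentage is always recomputed by the estimators, never
stored.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Mapping, Tuple

from .estimators import OocyteConfigCounts, ProgenyCountTable

__all__ = [
    "CountTableError",
    "ProgenyRecord",
    "OrientationCounts",
    "load_counts",
    "load_cytology",
    "load_orientation",
    "load_progeny",
    "write_cytology",
    "write_orientation",
    "write_progeny",
    "table1",
    "table2",
    "fixture_path",
    "Table1Fixture",
    "Table2Fixture",
]

CYTOLOGY_COLUMNS = (
    "genotype",
    "stage",
    "single_mass",
    "one_plus_out",
    "compound_out",
    "hs_config",
    "other_config",
)
ORIENTATION_COLUMNS = (
    "genotype",
    "normal_orientation",
    "hs_orientation",
    "other_orientation",
)
PROGENY_COLUMNS = (
    "genotype",
    "normal",
    "hs_exceptional",
    "other",
    "recombinant",
    "paternal_ndj",
    "decimals",
    "correction",
)


class CountTableError(ValueError):
    """A count-table file failed validation; carries the 1-based line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


@dataclass(frozen=True)
class ProgenyRecord:
    """A progeny table plus its presentation/correction metadata."""

    table: ProgenyCountTable
    decimals: int
    correction: str  # "derived" or "raw"


@dataclass(frozen=True)
class OrientationCounts:
    """Metaphase-arrest orientation counts (normal / HS / other)."""

    normal: int
    hs: int
    other: int

    @property
    def total(self) -> int:
        return self.normal + self.hs + self.other


def _read_rows(path, columns):
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise CountTableError(f"{path}: empty file", line=1)
        missing = [c for c in columns if c not in reader.fieldnames]
        if missing:
            raise CountTableError(
                f"{path}: missing column(s) {', '.join(missing)}", line=1
            )
        for row in reader:
            yield reader.line_num, row


def _to_count(value, field, line):
    try:
        n = int(value)
    except (TypeError, ValueError):
        raise CountTableError(f"field {field!r}: {value!r} is not an integer", line)
    if n < 0:
        raise CountTableError(f"field {field!r}: negative count {n}", line)
    return n


def load_cytology(path) -> Dict[Tuple[str, str], OocyteConfigCounts]:
    """Read per-genotype, per-stage oocyte configuration counts."""
    out = {}
    for line, row in _read_rows(path, CYTOLOGY_COLUMNS):
        try:
            counts = OocyteConfigCounts(
                stage=row["stage"],
                single_mass=_to_count(row["single_mass"], "single_mass", line),
                one_plus_out=_to_count(row["one_plus_out"], "one_plus_out", line),
                compound_out=_to_count(row["compound_out"], "compound_out", line),
                hs_config=_to_count(row["hs_config"], "hs_config", line),
                other_config=_to_count(row["other_config"], "other_config", line),
            )
        except ValueError as e:
            raise CountTableError(str(e), line) from None
        out[(row["genotype"], row["stage"])] = counts
    return out


def load_orientation(path) -> Dict[str, OrientationCounts]:
    out = {}
    for line, row in _read_rows(path, ORIENTATION_COLUMNS):
        out[row["genotype"]] = OrientationCounts(
            normal=_to_count(row["normal_orientation"], "normal_orientation", line),
            hs=_to_count(row["hs_orientation"], "hs_orientation", line),
            other=_to_count(row["other_orientation"], "other_orientation", line),
        )
    return out


def load_progeny(path) -> Dict[str, ProgenyRecord]:
    out = {}
    for line, row in _read_rows(path, PROGENY_COLUMNS):
        correction = row["correction"].strip()
        if correction not in ("derived", "raw"):
            raise CountTableError(
                f"field 'correction': {correction!r} is neither 'derived' nor 'raw'",
                line,
            )
        try:
            table = ProgenyCountTable(
                normal=_to_count(row["normal"], "normal", line),
                hs_exceptional=_to_count(row["hs_exceptional"], "hs_exceptional", line),
                other=_to_count(row["other"], "other", line),
                recombinant=_to_count(row["recombinant"], "recombinant", line),
                paternal_ndj=_to_count(row["paternal_ndj"], "paternal_ndj", line),
            )
        except ValueError as e:
            raise CountTableError(str(e), line) from None
        out[row["genotype"]] = ProgenyRecord(
            table=table,
            decimals=_to_count(row["decimals"], "decimals", line),
            correction=correction,
        )
    return out


_SCHEMAS = {
    "cytology": load_cytology,
    "orientation": load_orientation,
    "progeny": load_progeny,
}


def load_counts(path, schema: str):
    """Dispatch to the loader for *schema* ('cytology', 'orientation',
    'progeny')."""
    try:
        loader = _SCHEMAS[schema]
    except KeyError:
        raise ValueError(
            f"unknown schema {schema!r}; expected one of {sorted(_SCHEMAS)}"
        ) from None
    return loader(path)


def _format_tsv(columns, rows) -> str:
    lines = ["\t".join(str(v) for v in columns)]
    lines.extend("\t".join(str(v) for v in row) for row in rows)
    return "\n".join(lines) + "\n"


def format_cytology(counts: Mapping[Tuple[str, str], OocyteConfigCounts]) -> str:
    rows = [
        (g, c.stage, c.single_mass, c.one_plus_out, c.compound_out, c.hs_config, c.other_config)
        for (g, _stage), c in counts.items()
    ]
    return _format_tsv(CYTOLOGY_COLUMNS, rows)


def format_orientation(counts: Mapping[str, OrientationCounts]) -> str:
    rows = [(g, c.normal, c.hs, c.other) for g, c in counts.items()]
    return _format_tsv(ORIENTATION_COLUMNS, rows)


def format_progeny(records: Mapping[str, ProgenyRecord]) -> str:
    rows = [
        (
            g,
            r.table.normal,
            r.table.hs_exceptional,
            r.table.other,
            r.table.recombinant,
            r.table.paternal_ndj,
            r.decimals,
            r.correction,
        )
        for g, r in records.items()
    ]
    return _format_tsv(PROGENY_COLUMNS, rows)


def write_cytology(counts, path) -> None:
    Path(path).write_text(format_cytology(counts), encoding="utf-8")


def write_orientation(counts, path) -> None:
    Path(path).write_text(format_orientation(counts), encoding="utf-8")


def write_progeny(records, path) -> None:
    Path(path).write_text(format_progeny(records), encoding="utf-8")


# ---------------------------------------------------------------------------
# packaged fixtures

_FIXTURE_FILES = (
    "table1_cytology.tsv",
    "table1_progeny.tsv",
    "table2_orientation.tsv",
    "table2_progeny.tsv",
    "table2_progeny_classes.tsv",
)


def fixture_path(name: str) -> Path:
    if name not in _FIXTURE_FILES:
        raise ValueError(f"unknown fixture {name!r}; available: {_FIXTURE_FILES}")
    return Path(resources.files("hetseg.data") / name)


@dataclass(frozen=True)
class Table1Fixture:
    """Monovalent-compound genotypes: cytology at both stages + progeny."""

    cytology: Dict[Tuple[str, str], OocyteConfigCounts]
    progeny: Dict[str, ProgenyRecord]


@dataclass(frozen=True)
class Table2Fixture:
    """Multiple-heterolog genotypes: orientation counts + progeny, with
    the footnote-level phenotype-class breakdown where published."""

    orientation: Dict[str, OrientationCounts]
    progeny: Dict[str, ProgenyRecord]
    progeny_classes: Dict[str, Dict[str, Tuple[str, int]]]


def table1() -> Table1Fixture:
    return Table1Fixture(
        cytology=load_cytology(fixture_path("table1_cytology.tsv")),
        progeny=load_progeny(fixture_path("table1_progeny.tsv")),
    )


def table2() -> Table2Fixture:
    classes: Dict[str, Dict[str, Tuple[str, int]]] = {}
    for line, row in _read_rows(
        fixture_path("table2_progeny_classes.tsv"),
        ("genotype", "class_label", "category", "count"),
    ):
        classes.setdefault(row["genotype"], {})[row["class_label"]] = (
            row["category"],
            _to_count(row["count"], "count", line),
        )
    return Table2Fixture(
        orientation=load_orientation(fixture_path("table2_orientation.tsv")),
        progeny=load_progeny(fixture_path("table2_progeny.tsv")),
        progeny_classes=classes,
    )
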