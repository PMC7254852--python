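"""Domain types and tabular I/O for targeted-metabolomics panel data.

The central container is :class:`MetaboliteTable`, a samples-as-rows matrix of
concentrations (µM by default) backed by a pandas DataFrame. Around it sit the
per-metabolite panel annotation (:class:`PanelAnnotation`), the study design
(:class:`StudyDesign`, one row per *measurement*, so a bridge sample measured
in two batches contributes two rows), and limits of detection (plain
``{metabolite_id: lod}`` mappings validated by :func:`read_lod`).

All files are CSV/TSV with one header row; the delimiter is inferred from the
extension and can be overridden. Missing values are written as ``"NA"`` and
held internally as NaN — never as 0, since 0 is a legal concentration bound
while absence is not. Identifiers are case-sensitive and trimmed of leading /
trailing whitespace only (Biocrates-style ids contain internal spaces and
parentheses).
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DuplicateIdError, FormatError

MISSING_TOKEN = "NA"

KLASSES = frozenset(
    {
        "acylcarnitine",
        "amino_acid",
        "biogenic_amine",
        "glycerophospholipid",
        "sphingolipid",
        "sugar",
    }
)
SUBCLASSES = frozenset({"PC_aa", "PC_ae", "lysoPC", "SM", "SM_OH", "none"})

_GPL_SUBCLASSES = frozenset({"PC_aa", "PC_ae", "lysoPC"})
_SL_SUBCLASSES = frozenset({"SM", "SM_OH"})

#: grammar of the lipid shorthand used on the panel: ``<token> C<carbons>:<double bonds>``
_LIPID_RE = re.compile(r"^(PC aa|PC ae|lysoPC a|SM \(OH\)|SM) C(\d+):(\d+)$")

_SUBCLASS_BY_TOKEN = {
    "PC aa": "PC_aa",
    "PC ae": "PC_ae",
    "lysoPC a": "lysoPC",
    "SM": "SM",
    "SM (OH)": "SM_OH",
}


def _infer_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DuplicateIdError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


class MetaboliteTable:
    """Rectangular sample × metabolite concentration matrix.

    Parameters
    ----------
    values
        DataFrame (index = sample ids, columns = metabolite ids) or a 2-D
        array together with ``sample_ids`` / ``metabolite_ids``.
    unit
        Concentration unit label; purely descriptive.

    Values must be finite non-negative reals; missing measurements are NaN.
    """

    def __init__(
        self,
        values,
        sample_ids: Sequence[str] | None = None,
        metabolite_ids: Sequence[str] | None = None,
        unit: str = "µM",
    ) -> None:
        if isinstance(values, pd.DataFrame):
            frame = values.astype(float)
        else:
            if sample_ids is None or metabolite_ids is None:
                raise FormatError("array input requires sample_ids and metabolite_ids")
            frame = pd.DataFrame(
                np.asarray(values, dtype=float),
                index=list(sample_ids),
                columns=list(metabolite_ids),
            )
        frame.index = [str(i).strip() for i in frame.index]
        frame.columns = [str(c).strip() for c in frame.columns]
        _check_unique(list(frame.index), "sample")
        _check_unique(list(frame.columns), "metabolite")
        arr = frame.to_numpy()
        if np.isinf(arr).any():
            raise FormatError("non-finite concentration value")
        if (arr < 0).any():
            raise FormatError("negative concentration value")
        self.data = frame
        self.unit = unit

    # -- basic introspection ------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    # -- subsetting ---------------------------------------------------------
    def select_samples(self, ids: Sequence[str]) -> "MetaboliteTable":
        return MetaboliteTable(self.data.loc[list(ids)], unit=self.unit)

    def select_metabolites(self, ids: Sequence[str]) -> "MetaboliteTable":
        return MetaboliteTable(self.data[list(ids)], unit=self.unit)

    def copy(self) -> "MetaboliteTable":
        return MetaboliteTable(self.data.copy(), unit=self.unit)

    def equals(self, other: "MetaboliteTable", rtol: float = 1e-11) -> bool:
        if self.sample_ids != other.sample_ids or self.metabolite_ids != other.metabolite_ids:
            return False
        a, b = self.values(), other.values()
        both_nan = np.isnan(a) & np.isnan(b)
        close = np.isclose(a, b, rtol=rtol, atol=0.0, equal_nan=True)
        return bool(np.all(close | both_nan))

    def to_json(self) -> str:
        return json.dumps(
            {
                "unit": self.unit,
                "sample_ids": self.sample_ids,
                "metabolite_ids": self.metabolite_ids,
                "values": [
                    [None if np.isnan(v) else v for v in row] for row in self.values()
                ],
            }
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, j = self.shape
        return f"MetaboliteTable({n} samples × {j} metabolites, unit={self.unit!r})"


def read_table(
    path: str | Path,
    orientation: str = "samples_as_rows",
    *,
    missing: str = MISSING_TOKEN,
    delimiter: str | None = None,
    unit: str = "µM",
) -> MetaboliteTable:
    """Read a concentration matrix from CSV/TSV in either orientation.

    The returned table is always samples-as-rows. Cells other than numbers or
    the missing token raise :class:`FormatError`; ragged rows and duplicate
    identifiers are rejected.
    """
    if orientation not in ("samples_as_rows", "metabolites_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    delim = _infer_delimiter(path, delimiter)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh, delimiter=delim)]
    if not rows:
        raise FormatError(f"{path}: empty file")
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        raise FormatError(f"{path}: ragged rows (widths {sorted(widths)})")
    header = [c.strip() for c in rows[0][1:]]
    ids = [r[0].strip() for r in rows[1:]]
    _check_unique(header, "column")
    _check_unique(ids, "row")

    def _cell(raw: str, i: int, jname: str) -> float:
        raw = raw.strip()
        if raw == missing or raw == "":
            return np.nan
        try:
            return float(raw)
        except ValueError:
            raise FormatError(
                f"{path}: non-numeric cell {raw!r} at row {ids[i]!r}, column {jname!r}"
            ) from None

    data = [
        [_cell(c, i, header[j]) for j, c in enumerate(r[1:])]
        for i, r in enumerate(rows[1:])
    ]
    frame = pd.DataFrame(np.asarray(data, dtype=float).reshape(len(ids), len(header)),
                         index=ids, columns=header)
    if orientation == "metabolites_as_rows":
        frame = frame.T
    return MetaboliteTable(frame, unit=unit)


def write_table(
    table: MetaboliteTable,
    path: str | Path,
    *,
    missing: str = MISSING_TOKEN,
    delimiter: str | None = None,
) -> None:
    """Write a table as CSV/TSV; round-trips through :func:`read_table` to 12
    significant digits."""
    delim = _infer_delimiter(path, delimiter)
    table.data.to_csv(
        path, sep=delim, na_rep=missing, float_format="%.12g", index_label="sample"
    )


# ---------------------------------------------------------------------------
# Panel annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelAnnotation:
    """Class and lipid-structure descriptors for one panel analyte.

    For lipid species ``total_carbons``/``total_double_bonds`` describe the
    *sum composition* of the acyl / acyl-alkyl chains as encoded in the
    shorthand ``PC aa C36:4`` etc.; the panel does not resolve individual
    chains.
    """

    metabolite_id: str
    klass: str
    subclass: str = "none"
    total_carbons: int = 0
    total_double_bonds: int = 0
    hydroxylated: bool = False

    def __post_init__(self) -> None:
        if self.klass not in KLASSES:
            raise FormatError(f"unknown class {self.klass!r}")
        if self.subclass not in SUBCLASSES:
            raise FormatError(f"unknown subclass {self.subclass!r}")
        if self.subclass in _GPL_SUBCLASSES and self.klass != "glycerophospholipid":
            raise FormatError(
                f"{self.metabolite_id}: subclass {self.subclass} requires glycerophospholipid"
            )
        if self.subclass in _SL_SUBCLASSES and self.klass != "sphingolipid":
            raise FormatError(
                f"{self.metabolite_id}: subclass {self.subclass} requires sphingolipid"
            )
        if self.subclass != "none" and self.total_carbons <= 0:
            raise FormatError(f"{self.metabolite_id}: lipid subclass needs total_carbons > 0")
        if self.total_carbons < 0 or self.total_double_bonds < 0:
            raise FormatError(f"{self.metabolite_id}: negative chain descriptor")

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def parse_lipid_id(metabolite_id: str) -> tuple[str, int, int, bool]:
    """Parse lipid shorthand ``<token> C<carbons>:<double bonds>``.

    Returns ``(subclass, total_carbons, total_double_bonds, hydroxylated)``.
    """
    m = _LIPID_RE.match(metabolite_id.strip())
    if m is None:
        raise FormatError(f"unparseable lipid id {metabolite_id!r}")
    token, carbons, dbs = m.group(1), int(m.group(2)), int(m.group(3))
    subclass = _SUBCLASS_BY_TOKEN[token]
    return subclass, carbons, dbs, subclass == "SM_OH"


def annotation_from_id(metabolite_id: str, klass: str) -> PanelAnnotation:
    """Build a :class:`PanelAnnotation`, parsing lipid structure from the id
    for glycerophospholipids and sphingolipids."""
    metabolite_id = metabolite_id.strip()
    if klass in ("glycerophospholipid", "sphingolipid"):
        subclass, carbons, dbs, oh = parse_lipid_id(metabolite_id)
        return PanelAnnotation(metabolite_id, klass, subclass, carbons, dbs, oh)
    return PanelAnnotation(metabolite_id, klass)


class Panel:
    """Ordered collection of :class:`PanelAnnotation` with id lookup."""

    def __init__(self, annotations: Iterable[PanelAnnotation]) -> None:
        self.annotations = list(annotations)
        _check_unique([a.metabolite_id for a in self.annotations], "metabolite")
        self._by_id = {a.metabolite_id: a for a in self.annotations}

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self):
        return iter(self.annotations)

    def __contains__(self, metabolite_id: str) -> bool:
        return metabolite_id in self._by_id

    def __getitem__(self, metabolite_id: str) -> PanelAnnotation:
        return self._by_id[metabolite_id]

    @property
    def ids(self) -> list[str]:
        return [a.metabolite_id for a in self.annotations]

    def ids_by_klass(self, klass: str) -> list[str]:
        return [a.metabolite_id for a in self.annotations if a.klass == klass]

    def ids_by_subclass(self, subclass: str) -> list[str]:
        return [a.metabolite_id for a in self.annotations if a.subclass == subclass]

    def count_by_klass(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for a in self.annotations:
            out[a.klass] = out.get(a.klass, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(a) for a in self.annotations])

    def to_json(self) -> str:
        return json.dumps([asdict(a) for a in self.annotations])


def read_annotations(path: str | Path, *, delimiter: str | None = None) -> Panel:
    """Read panel annotations from CSV with at least ``metabolite_id,klass``.

    The lipid-structure columns are optional; when absent they are parsed from
    the id shorthand for lipid classes.
    """
    delim = _infer_delimiter(path, delimiter)
    frame = pd.read_csv(path, sep=delim, dtype=str, keep_default_na=False)
    for col in ("metabolite_id", "klass"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    has_struct = {"subclass", "total_carbons", "total_double_bonds", "hydroxylated"}.issubset(
        frame.columns
    )
    anns = []
    for _, row in frame.iterrows():
        if has_struct:
            anns.append(
                PanelAnnotation(
                    row["metabolite_id"].strip(),
                    row["klass"].strip(),
                    row["subclass"].strip(),
                    int(row["total_carbons"]),
                    int(row["total_double_bonds"]),
                    str(row["hydroxylated"]).strip().lower() in ("true", "1"),
                )
            )
        else:
            anns.append(annotation_from_id(row["metabolite_id"], row["klass"].strip()))
    return Panel(anns)


def write_annotations(panel: Panel, path: str | Path, *, delimiter: str | None = None) -> None:
    panel.to_frame().to_csv(path, sep=_infer_delimiter(path, delimiter), index=False)


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignRow:
    """One measurement: a sample run in one batch."""

    measurement_id: str
    sample_id: str
    group: str
    batch: int
    replicate: int
    is_bridge: bool
    severity_rank: int

    def __post_init__(self) -> None:
        if self.batch < 1 or self.replicate < 1:
            raise FormatError(f"{self.sample_id}: batch and replicate must be >= 1")
        if self.severity_rank < 0:
            raise FormatError(f"{self.sample_id}: negative severity rank")


class StudyDesign:
    """Measurement-level study design.

    One row per (sample, batch) measurement; bridge samples therefore appear
    once per batch under the same ``sample_id`` but distinct
    ``measurement_id``s, which key the rows of the corresponding
    :class:`MetaboliteTable`.
    """

    def __init__(self, rows: Iterable[DesignRow]) -> None:
        self.rows = list(rows)
        _check_unique([r.measurement_id for r in self.rows], "measurement")
        pairs = [(r.sample_id, r.batch) for r in self.rows]
        if len(set(pairs)) != len(pairs):
            raise FormatError("a sample appears more than once in the same batch")
        # severity rank must be consistent within group
        rank: dict[str, int] = {}
        for r in self.rows:
            if rank.setdefault(r.group, r.severity_rank) != r.severity_rank:
                raise FormatError(f"inconsistent severity rank for group {r.group!r}")
        # bridge samples must span >= 2 batches
        by_sample: dict[str, set[int]] = {}
        for r in self.rows:
            by_sample.setdefault(r.sample_id, set()).add(r.batch)
        for r in self.rows:
            if r.is_bridge and len(by_sample[r.sample_id]) < 2:
                raise FormatError(f"bridge sample {r.sample_id!r} measured in < 2 batches")
        self._by_measurement = {r.measurement_id: r for r in self.rows}

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    @property
    def measurement_ids(self) -> list[str]:
        return [r.measurement_id for r in self.rows]

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for r in self.rows:
            if r.group not in seen:
                seen.append(r.group)
        return seen

    @property
    def batches(self) -> list[int]:
        return sorted({r.batch for r in self.rows})

    @property
    def severity_ranks(self) -> dict[str, int]:
        return {g: r.severity_rank for g in self.groups for r in self.rows if r.group == g}

    def row(self, measurement_id: str) -> DesignRow:
        return self._by_measurement[measurement_id]

    def group_of(self, measurement_id: str) -> str:
        return self._by_measurement[measurement_id].group

    def subset(self, measurement_ids: Sequence[str]) -> "StudyDesign":
        keep = set(measurement_ids)
        return StudyDesign([r for r in self.rows if r.measurement_id in keep])

    def subset_groups(self, groups: Sequence[str]) -> "StudyDesign":
        keep = set(groups)
        return StudyDesign([r for r in self.rows if r.group in keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.rows])

    def to_json(self) -> str:
        return json.dumps([asdict(r) for r in self.rows])


_DESIGN_COLS = ("sample_id", "group", "batch", "replicate", "is_bridge", "severity_rank")


def read_design(path: str | Path, *, delimiter: str | None = None) -> StudyDesign:
    """Read a measurement-level design table.

    Required columns: ``sample_id, group, batch, replicate, is_bridge,
    severity_rank``; ``measurement_id`` is optional and defaults to the sample
    id, suffixed with ``-b<batch>`` for samples run in several batches.
    """
    delim = _infer_delimiter(path, delimiter)
    frame = pd.read_csv(path, sep=delim, dtype=str, keep_default_na=False)
    for col in _DESIGN_COLS:
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    multi = frame["sample_id"].duplicated(keep=False)
    rows = []
    for i, row in frame.iterrows():
        sid = row["sample_id"].strip()
        if "measurement_id" in frame.columns and row["measurement_id"].strip():
            mid = row["measurement_id"].strip()
        else:
            mid = f"{sid}-b{int(row['batch'])}" if multi[i] else sid
        rows.append(
            DesignRow(
                measurement_id=mid,
                sample_id=sid,
                group=row["group"].strip(),
                batch=int(row["batch"]),
                replicate=int(row["replicate"]),
                is_bridge=str(row["is_bridge"]).strip().lower() in ("true", "1"),
                severity_rank=int(row["severity_rank"]),
            )
        )
    return StudyDesign(rows)


def write_design(design: StudyDesign, path: str | Path, *, delimiter: str | None = None) -> None:
    design.to_frame().to_csv(path, sep=_infer_delimiter(path, delimiter), index=False)


# ---------------------------------------------------------------------------
# Limits of detection
# ---------------------------------------------------------------------------

def validate_lods(lods: Mapping[str, float]) -> dict[str, float]:
    out = {}
    for mid, lod in lods.items():
        lod = float(lod)
        if not np.isfinite(lod) or lod <= 0:
            raise FormatError(f"LOD for {mid!r} must be a positive real, got {lod}")
        out[str(mid).strip()] = lod
    return out


def read_lod(path: str | Path, *, delimiter: str | None = None) -> dict[str, float]:
    """Read per-metabolite limits of detection (columns ``metabolite_id,lod``)."""
    delim = _infer_delimiter(path, delimiter)
    frame = pd.read_csv(path, sep=delim, dtype=str, keep_default_na=False)
    for col in ("metabolite_id", "lod"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return validate_lods(dict(zip(frame["metabolite_id"], frame["lod"])))


def write_lod(lods: Mapping[str, float], path: str | Path, *, delimiter: str | None = None) -> None:
    pd.DataFrame(
        {"metabolite_id": list(lods.keys()), "lod": ["%.12g" % v for v in lods.values()]}
    ).to_csv(path, sep=_infer_delimiter(path, delimiter), index=False)
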