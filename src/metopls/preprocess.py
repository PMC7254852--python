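"""Data cleaning and normalization chain.

The stages compose in a fixed order: LOD filter → bridge-sample batch
normalization → (bridge-replicate collapse) → total-sum row normalization →
autoscaling. Each stage returns its transformed table together with a
:class:`PreprocessReport` recording exactly what it did, and each is a pure
function of its inputs.

Censored (sub-LOD) values of *retained* metabolites are kept as reported —
no imputation; the downstream methods are variance and rank based, and
inventing values below the detection limit would only add structure that was
never measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConstantMetaboliteError,
    DegenerateBridgeError,
    DegenerateSampleError,
    MissingLODError,
)
from .tables import MetaboliteTable, StudyDesign


@dataclass
class PreprocessReport:
    """Bookkeeping for one preprocessing stage."""

    stage: str
    n_input_metabolites: int
    n_retained: int
    dropped_ids: list[str] = field(default_factory=list)
    per_batch_factors: dict[tuple[int, str], float] = field(default_factory=dict)
    row_totals: dict[str, float] = field(default_factory=dict)
    centers: dict[str, float] = field(default_factory=dict)
    scales: dict[str, float] = field(default_factory=dict)
    removed_measurements: list[str] = field(default_factory=list)
    notes: str = ""

    def __post_init__(self) -> None:
        if self.n_retained + len(self.dropped_ids) != self.n_input_metabolites:
            raise ValueError("retained + dropped != input metabolites")
        for v in self.per_batch_factors.values():
            if not (v > 0):
                raise ValueError("non-positive batch factor")
        for v in self.scales.values():
            if not (v > 0):
                raise ValueError("non-positive scale")


def filter_by_lod(
    table: MetaboliteTable,
    lods: dict[str, float],
    max_fraction: float = 0.20,
) -> tuple[MetaboliteTable, PreprocessReport]:
    """Drop metabolites with more than ``max_fraction`` of values below LOD.

    The rule is a strict inequality: a metabolite with exactly
    ``max_fraction`` of its values censored is retained. Retained values are
    left untouched. Idempotent by construction.
    """
    if not (0 <= max_fraction < 1):
        raise ValueError("max_fraction must lie in [0, 1)")
    missing = [m for m in table.metabolite_ids if m not in lods]
    if missing:
        raise MissingLODError(f"no LOD for: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    n = table.shape[0]
    dropped = []
    for m in table.metabolite_ids:
        col = table.data[m].to_numpy()
        below = np.sum(col < lods[m])
        if n > 0 and below / n > max_fraction:
            dropped.append(m)
    kept = [m for m in table.metabolite_ids if m not in set(dropped)]
    out = table.select_metabolites(kept)
    report = PreprocessReport(
        stage="lod_filter",
        n_input_metabolites=table.shape[1],
        n_retained=len(kept),
        dropped_ids=dropped,
    )
    return out, report


def bridge_normalize(
    table: MetaboliteTable,
    design: StudyDesign,
    reference_batch: int = 1,
    normalizer: str | None = None,
) -> tuple[MetaboliteTable, PreprocessReport]:
    """Correct between-batch scale differences with one bridge sample.

    For every non-reference batch *b* and metabolite *j* the factor
    ``f_bj = value(bridge, reference batch, j) / value(bridge, b, j)``
    multiplies all batch-*b* values; the reference batch is untouched. The
    bridge measurement that was consumed is removed from the analysis table
    (one run per batch, including the reference batch), leaving the remaining
    bridge replicates available to verify that normalization worked.

    A single-batch table is returned unchanged. By default the normalizer is
    the lexicographically first bridge sample measured in every batch.
    """
    sub = design.subset([m for m in design.measurement_ids if m in set(table.sample_ids)])
    batches = sub.batches
    if len(batches) <= 1:
        report = PreprocessReport(
            stage="bridge_normalize",
            n_input_metabolites=table.shape[1],
            n_retained=table.shape[1],
            notes="single batch; identity",
        )
        return table.copy(), report
    if reference_batch not in batches:
        raise DegenerateBridgeError(f"reference batch {reference_batch} not present")

    # bridge samples measured in every batch
    runs_by_sample: dict[str, dict[int, str]] = {}
    for r in sub:
        if r.is_bridge:
            runs_by_sample.setdefault(r.sample_id, {})[r.batch] = r.measurement_id
    eligible = sorted(s for s, runs in runs_by_sample.items() if set(batches) <= set(runs))
    if normalizer is None:
        if not eligible:
            raise DegenerateBridgeError("no bridge sample measured in every batch")
        normalizer = eligible[0]
    elif normalizer not in eligible:
        raise DegenerateBridgeError(f"{normalizer!r} is not a bridge sample in every batch")
    runs = runs_by_sample[normalizer]

    frame = table.data.copy()
    ref_vals = frame.loc[runs[reference_batch]]
    factors: dict[tuple[int, str], float] = {}
    for b in batches:
        if b == reference_batch:
            continue
        bval = frame.loc[runs[b]]
        bad = ~(np.isfinite(bval.to_numpy()) & (bval.to_numpy() > 0))
        bad |= ~(np.isfinite(ref_vals.to_numpy()) & (ref_vals.to_numpy() > 0))
        if bad.any():
            culprit = frame.columns[np.argmax(bad)]
            raise DegenerateBridgeError(
                f"bridge {normalizer!r} zero/missing for {culprit!r} in batch {b}"
            )
        f = (ref_vals / bval).to_numpy()
        rows = [r.measurement_id for r in sub if r.batch == b]
        frame.loc[rows] = frame.loc[rows].to_numpy() * f
        for m, fj in zip(frame.columns, f):
            factors[(b, m)] = float(fj)

    used = [runs[b] for b in batches]
    frame = frame.drop(index=used)
    report = PreprocessReport(
        stage="bridge_normalize",
        n_input_metabolites=table.shape[1],
        n_retained=table.shape[1],
        per_batch_factors=factors,
        removed_measurements=used,
        notes=f"normalizer={normalizer}",
    )
    return MetaboliteTable(frame, unit=table.unit), report


def collapse_bridge_replicates(
    table: MetaboliteTable,
    design: StudyDesign,
    keep_batch: int = 1,
) -> tuple[MetaboliteTable, PreprocessReport]:
    """Keep one measurement per sample after bridge normalization.

    Bridge samples still present in several batches are reduced to their
    ``keep_batch`` run, and all rows are re-keyed by sample id so the table
    is one-row-per-biological-sample for analysis.
    """
    sub = design.subset([m for m in design.measurement_ids if m in set(table.sample_ids)])
    by_sample: dict[str, list] = {}
    for r in sub:
        by_sample.setdefault(r.sample_id, []).append(r)
    keep_rows: list[str] = []
    new_ids: list[str] = []
    removed: list[str] = []
    for sid in by_sample:
        runs = by_sample[sid]
        if len(runs) == 1:
            chosen = runs[0]
        else:
            in_keep = [r for r in runs if r.batch == keep_batch]
            chosen = in_keep[0] if in_keep else sorted(runs, key=lambda r: r.batch)[0]
        keep_rows.append(chosen.measurement_id)
        new_ids.append(sid)
        removed += [r.measurement_id for r in runs if r is not chosen]
    frame = table.data.loc[keep_rows].copy()
    frame.index = new_ids
    report = PreprocessReport(
        stage="collapse_bridge_replicates",
        n_input_metabolites=table.shape[1],
        n_retained=table.shape[1],
        removed_measurements=removed,
    )
    return MetaboliteTable(frame, unit=table.unit), report


def row_normalize(table: MetaboliteTable) -> tuple[MetaboliteTable, PreprocessReport]:
    """Total-sum normalization per sample, rescaled to the grand-mean total.

    Each row is divided by its total and multiplied by the mean of the
    original row totals, so proportions are equalized while values stay on a
    µM-like scale; afterwards all row totals are equal.
    """
    frame = table.data
    totals = frame.sum(axis=1, skipna=True)
    if not (totals > 0).all():
        bad = totals.index[~(totals > 0)][0]
        raise DegenerateSampleError(f"sample {bad!r} has non-positive total")
    grand = float(totals.mean())
    out = frame.div(totals, axis=0) * grand
    report = PreprocessReport(
        stage="row_normalize",
        n_input_metabolites=table.shape[1],
        n_retained=table.shape[1],
        row_totals={s: float(t) for s, t in totals.items()},
    )
    return MetaboliteTable(out, unit=table.unit), report


def autoscale(table) -> tuple[pd.DataFrame, PreprocessReport]:
    """Center each metabolite to mean 0 and scale to unit variance (ddof=1).

    Accepts a :class:`MetaboliteTable` or a DataFrame; returns a plain
    DataFrame (scaled values may be negative) plus the centers and scales
    needed for the inverse transform.
    """
    frame = table.data if isinstance(table, MetaboliteTable) else table
    centers = frame.mean(axis=0)
    scales = frame.std(axis=0, ddof=1)
    dead = scales.index[~(scales > 0)]
    if len(dead):
        raise ConstantMetaboliteError(f"zero-variance metabolite {dead[0]!r}")
    scaled = (frame - centers) / scales
    report = PreprocessReport(
        stage="autoscale",
        n_input_metabolites=frame.shape[1],
        n_retained=frame.shape[1],
        centers={m: float(c) for m, c in centers.items()},
        scales={m: float(s) for m, s in scales.items()},
        notes="sd with n-1 denominator",
    )
    return scaled, report


def inverse_autoscale(scaled: pd.DataFrame, report: PreprocessReport) -> pd.DataFrame:
    """Undo :func:`autoscale` using its recorded centers and scales."""
    centers = pd.Series(report.centers)
    scales = pd.Series(report.scales)
    return scaled * scales + centers


@dataclass
class PreprocessResult:
    """Cleaned analysis table plus the per-stage reports."""

    clean: MetaboliteTable
    reports: list[PreprocessReport]

    @property
    def n_retained(self) -> int:
        return self.clean.shape[1]

    @property
    def dropped_ids(self) -> list[str]:
        out: list[str] = []
        for r in self.reports:
            out += r.dropped_ids
        return out


def preprocess(
    table: MetaboliteTable,
    design: StudyDesign,
    lods: dict[str, float],
    max_fraction: float = 0.20,
    reference_batch: int = 1,
    normalizer: str | None = None,
) -> PreprocessResult:
    """Run the full cleaning chain; the result is one row per sample, total-sum
    normalized, ready for per-analysis autoscaling."""
    t, rep_lod = filter_by_lod(table, lods, max_fraction)
    t, rep_bridge = bridge_normalize(t, design, reference_batch, normalizer)
    t, rep_collapse = collapse_bridge_replicates(t, design, keep_batch=reference_batch)
    t, rep_row = row_normalize(t)
    return PreprocessResult(clean=t, reports=[rep_lod, rep_bridge, rep_collapse, rep_row])
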