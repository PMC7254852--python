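"""Synthetic study-like data with known ground truth.

Emulates the design of the MEF *OPA1*-variant study: seven groups
(wild type, knock-out, and five transfected human alleles), five replicates
each, two measurement batches with the five wild-type samples run in both
batches as bridges, and a 188-analyte p180-style panel (40 acylcarnitines,
21 amino acids, 21 biogenic amines, 90 glycerophospholipids, 15
sphingolipids, 1 sugar).

Concentrations follow a log-normal model: for sample *i* and metabolite *j*

    log c_ij = mu_j + slope_j * severity(group_i) + tau_j * transfected_i
               + beta_{batch(i), j} + eps_ij + eta_mj

with metabolite baselines mu_j log-uniform over [0.01, 100] µM (fixed by a
panel-level seed so that the panel, not the replicate seed, owns the dynamic
range), a random per-metabolite transfection offset tau_j shared by the five
transfected groups, per-batch per-metabolite effects beta, biological
replicate noise eps (per sample, shared across repeat injections) and
technical injection noise eta (per measurement row). The severity gradient is
planted linearly in the group severity rank on the log scale, concentrated on
amino acids, biogenic amines and phospholipid classes, with per-metabolite
overrides such as spermine (up) versus spermidine/putrescine (down).

Per-metabolite limits of detection are chosen so that a fixed fraction of the
panel fails the downstream "more than 20% of values below LOD" rule; failing
metabolites are drawn from the analytes that carry no planted signal and are
not needed by the derived severity indices, emulating a study in which the
signature analytes were all quantifiable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import SpecError
from .tables import (
    DesignRow,
    MetaboliteTable,
    Panel,
    PanelAnnotation,
    StudyDesign,
    annotation_from_id,
)

GROUP_WT = "Opa1+/+"
GROUP_KO = "Opa1-/-"
TRANSFECTED_GROUPS = ("ISO1", "I382M", "D603H", "G439V", "R445H")

#: severity ranks; lower = closer to wild type
SEVERITY_RANKS = {
    GROUP_WT: 0,
    "ISO1": 0,
    "I382M": 1,
    "D603H": 2,
    "G439V": 3,
    "R445H": 4,
    GROUP_KO: 5,
}

#: planted severity order of the transfected groups, mildest first
PLANTED_ORDER = ("ISO1", "I382M", "D603H", "G439V", "R445H")

#: baselines are fixed by this panel-level seed, independent of the replicate seed
PANEL_SEED = 180

#: analytes required by the derived severity indices; never LOD-censored
INDEX_ANALYTES = (
    "t4-OH-Pro",
    "Spermine",
    "Spermidine",
    "Putrescine",
    "Taurine",
    "Met-SO",
    "SM C16:0",
    "SM C18:0",
    "SM (OH) C22:1",
    "SM (OH) C22:2",
)

_AMINO_ACIDS = (
    "Ala Arg Asn Asp Cit Gln Glu Gly His Ile Leu Lys Met Orn Phe Pro Ser Thr "
    "Trp Tyr Val"
).split()

_BIOGENIC_AMINES = [
    "Ac-Orn", "ADMA", "alpha-AAA", "c4-OH-Pro", "Carnosine", "Creatinine",
    "DOPA", "Dopamine", "Histamine", "Kynurenine", "Met-SO", "Nitro-Tyr",
    "PEA", "Putrescine", "Sarcosine", "SDMA", "Serotonin", "Spermidine",
    "Spermine", "t4-OH-Pro", "Taurine",
]

_ACYLCARNITINES = [
    "C0", "C2", "C3", "C3-DC (C4-OH)", "C3-OH", "C3:1", "C4", "C4:1", "C5",
    "C5-DC (C6-OH)", "C5-M-DC", "C5-OH (C3-DC-M)", "C5:1", "C5:1-DC",
    "C6 (C4:1-DC)", "C6:1", "C7-DC", "C8", "C9", "C10", "C10:1", "C10:2",
    "C12", "C12-DC", "C12:1", "C14", "C14:1", "C14:1-OH", "C14:2",
    "C14:2-OH", "C16", "C16-OH", "C16:1", "C16:1-OH", "C16:2", "C16:2-OH",
    "C18", "C18:1", "C18:1-OH", "C18:2",
]

_LYSOPC = [
    "lysoPC a C14:0", "lysoPC a C16:0", "lysoPC a C16:1", "lysoPC a C17:0",
    "lysoPC a C18:0", "lysoPC a C18:1", "lysoPC a C18:2", "lysoPC a C20:3",
    "lysoPC a C20:4", "lysoPC a C24:0", "lysoPC a C26:0", "lysoPC a C26:1",
    "lysoPC a C28:0", "lysoPC a C28:1",
]

_PC_AA = [
    "PC aa C24:0", "PC aa C26:0", "PC aa C28:1", "PC aa C30:0", "PC aa C30:2",
    "PC aa C32:0", "PC aa C32:1", "PC aa C32:2", "PC aa C32:3", "PC aa C34:1",
    "PC aa C34:2", "PC aa C34:3", "PC aa C34:4", "PC aa C36:0", "PC aa C36:1",
    "PC aa C36:2", "PC aa C36:3", "PC aa C36:4", "PC aa C36:5", "PC aa C36:6",
    "PC aa C38:0", "PC aa C38:3", "PC aa C38:4", "PC aa C38:5", "PC aa C38:6",
    "PC aa C40:1", "PC aa C40:2", "PC aa C40:3", "PC aa C40:4", "PC aa C40:5",
    "PC aa C40:6", "PC aa C42:0", "PC aa C42:1", "PC aa C42:2", "PC aa C42:4",
    "PC aa C42:5", "PC aa C42:6", "PC aa C44:6",
]

_PC_AE = [
    "PC ae C30:0", "PC ae C30:1", "PC ae C30:2", "PC ae C32:1", "PC ae C32:2",
    "PC ae C34:0", "PC ae C34:1", "PC ae C34:2", "PC ae C34:3", "PC ae C36:0",
    "PC ae C36:1", "PC ae C36:2", "PC ae C36:3", "PC ae C36:4", "PC ae C36:5",
    "PC ae C38:0", "PC ae C38:1", "PC ae C38:2", "PC ae C38:3", "PC ae C38:4",
    "PC ae C38:5", "PC ae C38:6", "PC ae C40:1", "PC ae C40:2", "PC ae C40:3",
    "PC ae C40:4", "PC ae C40:5", "PC ae C40:6", "PC ae C42:0", "PC ae C42:1",
    "PC ae C42:2", "PC ae C42:3", "PC ae C42:4", "PC ae C42:5", "PC ae C44:3",
    "PC ae C44:4", "PC ae C44:5", "PC ae C44:6",
]

_SM = [
    "SM C16:0", "SM C16:1", "SM C18:0", "SM C18:1", "SM C20:2", "SM C22:3",
    "SM C24:0", "SM C24:1", "SM C26:0", "SM C26:1",
]

_SM_OH = [
    "SM (OH) C14:1", "SM (OH) C16:1", "SM (OH) C22:1", "SM (OH) C22:2",
    "SM (OH) C24:1",
]

_SUGAR = ["H1"]


def default_panel() -> Panel:
    """The bundled 188-analyte panel, partitioned 40/21/21/90/15/1 by class."""
    anns: list[PanelAnnotation] = []
    anns += [PanelAnnotation(m, "acylcarnitine") for m in _ACYLCARNITINES]
    anns += [PanelAnnotation(m, "amino_acid") for m in _AMINO_ACIDS]
    anns += [PanelAnnotation(m, "biogenic_amine") for m in _BIOGENIC_AMINES]
    anns += [annotation_from_id(m, "glycerophospholipid") for m in _LYSOPC + _PC_AA + _PC_AE]
    anns += [annotation_from_id(m, "sphingolipid") for m in _SM + _SM_OH]
    anns += [PanelAnnotation(m, "sugar") for m in _SUGAR]
    panel = Panel(anns)
    counts = panel.count_by_klass()
    expected = {
        "acylcarnitine": 40,
        "amino_acid": 21,
        "biogenic_amine": 21,
        "glycerophospholipid": 90,
        "sphingolipid": 15,
        "sugar": 1,
    }
    if counts != expected:  # pragma: no cover - construction guard
        raise AssertionError(f"panel partition {counts} != {expected}")
    return panel


def default_design(n_replicates: int = 5) -> StudyDesign:
    """Seven groups × five replicates, two batches, wild type bridging both.

    Replicates 1–3 of every non-bridge group run in batch 1 and replicates
    4–5 in batch 2, so batch composition is identical across groups. The five
    wild-type samples are measured in both batches under the same sample id
    (40 measurement rows in total at the default replicate count).
    """
    prefixes = {
        GROUP_WT: "WT",
        GROUP_KO: "KO",
        **{g: g for g in TRANSFECTED_GROUPS},
    }
    rows: list[DesignRow] = []
    for group in (GROUP_WT, GROUP_KO) + TRANSFECTED_GROUPS:
        rank = SEVERITY_RANKS[group]
        prefix = prefixes[group]
        for rep in range(1, n_replicates + 1):
            sid = f"{prefix}_{rep}"
            if group == GROUP_WT:
                for batch in (1, 2):
                    rows.append(
                        DesignRow(f"{sid}-b{batch}", sid, group, batch, rep, True, rank)
                    )
            else:
                batch = 1 if rep <= (n_replicates + 1) // 2 else 2
                rows.append(DesignRow(sid, sid, group, batch, rep, False, rank))
    return StudyDesign(rows)


def _default_class_slopes() -> dict[str, float]:
    # per severity-rank-unit slopes on log concentration; signs follow the
    # study's signature: amino acids / amines / diacyl & acyl-alkyl PCs fall
    # toward the null-allele phenotype, sphingomyelins (especially
    # hydroxylated) rise
    return {
        "amino_acid": -0.12,
        "biogenic_amine": -0.08,
        "PC_aa": -0.10,
        "PC_ae": -0.08,
        "SM": 0.10,
        "SM_OH": 0.14,
    }


def _default_overrides() -> dict[str, float]:
    return {
        "Spermine": 0.12,      # highest-order polyamine rises with severity
        "Spermidine": -0.12,
        "Putrescine": -0.08,
        "Taurine": -0.10,
        "t4-OH-Pro": -0.14,    # collagen turnover falls
        "Met-SO": -0.10,
        "Gln": 0.10,           # the one amino acid moving against the pool
        "SM C18:0": 0.15,      # differential so the 18:0/16:0 ratio rises
        "SM C16:0": 0.04,
    }


def _default_unsaturation() -> dict[str, float]:
    # extra slope per double bond (centered within subclass) so saturation
    # ratios (PUFA/MUFA aa, MUFA/SFA ae) trend with severity, not only the
    # class totals
    return {"PC_aa": -0.02, "PC_ae": -0.02}


@dataclass
class EffectSpec:
    """Effect sizes and noise levels of the generative model.

    All scales are on log concentration. ``noise_sd`` is the biological
    replicate scatter (shared between repeat injections of the same sample);
    ``technical_sd`` is the per-injection scatter, which is what separates the
    bridge sample's two batch runs beyond the batch effect itself.
    """

    class_slopes: dict[str, float] = field(default_factory=_default_class_slopes)
    metabolite_overrides: dict[str, float] = field(default_factory=_default_overrides)
    unsaturation_slopes: dict[str, float] = field(default_factory=_default_unsaturation)
    transfection_offset_sd: float = 0.30
    batch_sd: float = 0.15
    noise_sd: float = 0.20
    technical_sd: float = 0.05
    lod_quantile: float = 59 / 188
    signal_fraction: float = 0.8
    non_transfected_groups: tuple[str, ...] = (GROUP_WT, GROUP_KO)

    def validate(self) -> None:
        if self.noise_sd <= 0:
            raise SpecError("noise_sd must be > 0")
        for name in ("transfection_offset_sd", "batch_sd", "technical_sd"):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be >= 0")
        if not (0 <= self.lod_quantile < 1):
            raise SpecError("lod_quantile must lie in [0, 1)")
        if not (0 < self.signal_fraction <= 1):
            raise SpecError("signal_fraction must lie in (0, 1]")
        for k, v in self.class_slopes.items():
            if not np.isfinite(v):
                raise SpecError(f"non-finite slope for {k!r}")

    @classmethod
    def null(cls) -> "EffectSpec":
        """Zero effect sizes everywhere; pure replicate noise."""
        return cls(
            class_slopes={},
            metabolite_overrides={},
            unsaturation_slopes={},
            transfection_offset_sd=0.0,
            batch_sd=0.0,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    signal_metabolites: set[str]
    planted_order: list[str]
    per_metabolite_slope: dict[str, float]

    def __post_init__(self) -> None:
        nonzero = {m for m, s in self.per_metabolite_slope.items() if s != 0.0}
        if self.signal_metabolites != nonzero:
            raise SpecError("signal_metabolites inconsistent with per_metabolite_slope")

    def to_json(self) -> str:
        return json.dumps(
            {
                "signal_metabolites": sorted(self.signal_metabolites),
                "planted_order": list(self.planted_order),
                "per_metabolite_slope": self.per_metabolite_slope,
            },
            sort_keys=True,
        )


def _baselines(panel: Panel) -> np.ndarray:
    rng = np.random.default_rng(PANEL_SEED)
    lo, hi = np.log(0.01), np.log(100.0)
    return rng.uniform(lo, hi, size=len(panel))


def _assign_slopes(panel: Panel, effects: EffectSpec, rng: np.random.Generator) -> dict[str, float]:
    slopes = {m: 0.0 for m in panel.ids}
    for key, slope in effects.class_slopes.items():
        if key in SUBCLASSES_WITH_SLOPES:
            members = panel.ids_by_subclass(key)
        else:
            members = panel.ids_by_klass(key)
        if not members:
            continue
        n_carry = max(1, int(round(effects.signal_fraction * len(members))))
        carriers = rng.choice(len(members), size=n_carry, replace=False)
        for idx in carriers:
            slopes[members[idx]] = slope
    # saturation-dependent differential, applied to carriers only and
    # centered within the subclass so the class-total slope is unchanged
    for subclass, coeff in effects.unsaturation_slopes.items():
        members = panel.ids_by_subclass(subclass)
        carriers = [m for m in members if slopes[m] != 0.0]
        if not carriers or coeff == 0.0:
            continue
        mean_db = float(np.mean([panel[m].total_double_bonds for m in carriers]))
        for m in carriers:
            slopes[m] += coeff * (panel[m].total_double_bonds - mean_db)
    for mid, slope in effects.metabolite_overrides.items():
        if mid in slopes:
            slopes[mid] = slope
    return slopes


SUBCLASSES_WITH_SLOPES = frozenset({"PC_aa", "PC_ae", "lysoPC", "SM", "SM_OH"})


def simulate(
    panel: Panel,
    design: StudyDesign,
    effects: EffectSpec,
    seed: int,
) -> tuple[MetaboliteTable, dict[str, float], GroundTruth]:
    """Draw one study-like dataset.

    Returns the measurement-level concentration table (rows keyed by the
    design's measurement ids), per-metabolite LODs and the planted ground
    truth. Identical arguments and seed give bit-identical output.
    """
    effects.validate()
    rng = np.random.default_rng(seed)
    J = len(panel)
    ids = panel.ids
    mu = _baselines(panel)
    slopes = _assign_slopes(panel, effects, rng)
    slope_vec = np.array([slopes[m] for m in ids])

    tau = rng.normal(0.0, effects.transfection_offset_sd, size=J)
    batches = design.batches
    beta = {b: rng.normal(0.0, effects.batch_sd, size=J) for b in batches}

    sample_ids = sorted({r.sample_id for r in design})
    bio = {s: rng.normal(0.0, effects.noise_sd, size=J) for s in sample_ids}

    logv = np.empty((len(design), J))
    for i, row in enumerate(design):
        transfected = row.group not in effects.non_transfected_groups
        logv[i] = (
            mu
            + slope_vec * row.severity_rank
            + (tau if transfected else 0.0)
            + beta[row.batch]
            + bio[row.sample_id]
            + rng.normal(0.0, effects.technical_sd, size=J)
        )
    values = np.exp(logv)
    table = MetaboliteTable(values, design.measurement_ids, ids)

    # LODs: a fixed number of non-signal, non-index analytes get an LOD near
    # the middle of their observed range (they will fail the 20% rule); all
    # others get one safely below their minimum.
    n_fail = int(round(effects.lod_quantile * J))
    protected = set(INDEX_ANALYTES) | {m for m, s in slopes.items() if s != 0.0}
    candidates = [m for m in ids if m not in protected]
    if n_fail > len(candidates):
        n_fail = len(candidates)
    fail_idx = rng.choice(len(candidates), size=n_fail, replace=False)
    failing = {candidates[i] for i in fail_idx}
    lods: dict[str, float] = {}
    for j, mid in enumerate(ids):
        col = values[:, j]
        if mid in failing:
            lods[mid] = float((np.quantile(col, 0.40) + np.quantile(col, 0.45)) / 2.0)
        else:
            lods[mid] = float(col.min() / 2.0)

    truth = GroundTruth(
        signal_metabolites={m for m, s in slopes.items() if s != 0.0},
        planted_order=list(PLANTED_ORDER),
        per_metabolite_slope=slopes,
    )
    return table, lods, truth
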