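"""The two study analyses and everything derived from them.

Analysis A discriminates knock-out from wild type with OPLS-DA; analysis B
ranks the transfected variant lines: PCA of the transfected samples only,
the first score vector t1 taken as a quantitative severity proxy, an OPLS
model regressing the metabolome on t1, per-metabolite Spearman correlations
with t1, and a Mann-Whitney test on t1 between the hypomorphic variant and
the wild-type-allele control. Both analyses yield a VIP-based metabolite
signature and volcano-plot records, and both are validated with
cross-validated Q², a permutation null and CV-ANOVA.

On top of the signatures sit the derived severity indices (amino-acid sum,
trans-4-hydroxyproline, spermine/spermidine, sphingomyelin and
phosphatidylcholine saturation ratios) and their least-squares regressions
on t1. ``run_all`` executes the entire chain from a config (simulated or
file inputs) and writes a deterministic report bundle.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateError, DesignError, RankError
from .latent import OPLS, OPLSDA, PCA, OPLSResults, PCAResults, encode_two_class
from .preprocess import PreprocessResult, autoscale, preprocess
from .simulate import (
    EffectSpec,
    GROUP_KO,
    GROUP_WT,
    default_design,
    default_panel,
    simulate,
)
from .tables import (
    MetaboliteTable,
    Panel,
    StudyDesign,
    read_annotations,
    read_design,
    read_lod,
    read_table,
)
from .validation import ValidationReport, mann_whitney, select_n_orth, spearman_profile, validate_opls


# ---------------------------------------------------------------------------
# Signatures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignatureEntry:
    metabolite_id: str
    vip: float
    loading_or_rho: float
    direction: str  # "up" | "down"


@dataclass
class Signature:
    """Metabolites selected as important, with the rule that selected them."""

    entries: list[SignatureEntry]
    selection_rule: dict

    @property
    def ids(self) -> set[str]:
        return {e.metabolite_id for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def to_records(self) -> list[dict]:
        return [asdict(e) for e in self.entries]


def _build_signature(
    vip: pd.Series,
    association: pd.Series,
    vip_threshold: float,
    top_fraction: float = 1.0,
) -> Signature:
    """VIP >= threshold, ranked by |association| with an optional top cut."""
    selected = vip.index[vip >= vip_threshold]
    ranked = sorted(selected, key=lambda m: -abs(float(association[m])))
    if top_fraction < 1.0:
        ranked = ranked[: max(1, int(round(top_fraction * len(ranked))))]
    entries = []
    for m in ranked:
        a = float(association[m])
        if np.isnan(a):
            continue
        entries.append(
            SignatureEntry(m, float(vip[m]), a, "up" if a >= 0 else "down")
        )
    return Signature(
        entries=entries,
        selection_rule={"vip_threshold": vip_threshold, "top_fraction": top_fraction},
    )


def signature_overlap(a: Signature, b: Signature) -> tuple[int, float, float]:
    """Shared metabolites and the overlap as a fraction of each signature."""
    shared = a.ids & b.ids
    fa = len(shared) / len(a.ids) if a.ids else 0.0
    fb = len(shared) / len(b.ids) if b.ids else 0.0
    return len(shared), fa, fb


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Knobs of the two analyses; defaults follow the study design."""

    wt_group: str = GROUP_WT
    ko_group: str = GROUP_KO
    most_severe: str = "R445H"
    contrast: tuple[str, str] = ("I382M", "ISO1")
    k: int = 7
    n_perm: int = 200
    seed: int = 0
    vip_threshold: float = 1.0
    loading_top_fraction: float = 1.0
    max_orth: int = 5


def _sample_groups(design: StudyDesign) -> dict[str, str]:
    return {r.sample_id: r.group for r in design}


def _fit_feasible(make_model, n_orth: int):
    """Fit with at most ``n_orth`` orthogonal components, backing off when the
    full-data matrix carries fewer y-orthogonal directions than the
    cross-validation suggested (e.g. y exactly aligned with a principal
    component)."""
    while True:
        try:
            return make_model(n_orth).fit(), n_orth
        except RankError:
            if n_orth == 0:
                raise
            n_orth -= 1


# ---------------------------------------------------------------------------
# Analysis A: KO vs WT OPLS-DA
# ---------------------------------------------------------------------------

@dataclass
class KOvsWTResult:
    model: OPLSResults
    validation: ValidationReport | None
    signature: Signature
    volcano: pd.DataFrame


def run_ko_vs_wt(
    clean: MetaboliteTable,
    design: StudyDesign,
    config: AnalysisConfig | None = None,
    validate: bool = True,
) -> KOvsWTResult:
    """OPLS-DA of the two non-transfected genotypes.

    The class encoding fixes wild type at 0 and knock-out at 1, so negative
    predictive loadings mean a metabolite is relatively decreased in the
    knock-out.
    """
    config = config or AnalysisConfig()
    groups = _sample_groups(design)
    wanted = (config.wt_group, config.ko_group)
    ids = [s for s in clean.sample_ids if groups.get(s) in wanted]
    labels = [groups[s] for s in ids]
    for g in wanted:
        if labels.count(g) < 3:
            raise DesignError(f"group {g!r} has fewer than 3 samples in the table")
    sub = clean.select_samples(ids)
    class_map = {config.wt_group: 0.0, config.ko_group: 1.0}
    y = encode_two_class(labels, class_map)

    n_orth = select_n_orth(sub.data, y, max_orth=config.max_orth, k=config.k)
    scaled, _ = autoscale(sub)
    model, n_orth = _fit_feasible(lambda a: OPLSDA(labels, scaled, a, class_map), n_orth)
    validation = (
        validate_opls(
            sub.data, y, k=config.k, n_perm=config.n_perm, seed=config.seed, n_orth=n_orth
        )
        if validate
        else None
    )
    vip = model.vip()
    volcano = pd.DataFrame(
        {
            "metabolite_id": list(vip.index),
            "loading": model.p_pred.to_numpy(),
            "vip": vip.to_numpy(),
        }
    )
    signature = _build_signature(
        vip, model.p_pred, config.vip_threshold, config.loading_top_fraction
    )
    volcano["selected"] = volcano["metabolite_id"].isin(signature.ids)
    return KOvsWTResult(model, validation, signature, volcano)


# ---------------------------------------------------------------------------
# Analysis B: variant ranking via PCA t1 + OPLS
# ---------------------------------------------------------------------------

@dataclass
class SeverityResult:
    """t1-based severity ordering of the transfected groups."""

    t1_scores: dict[str, float]
    group_mean_t1: dict[str, float]
    group_order: list[str]
    per_metabolite_rho: dict[str, float]
    contrast: tuple[str, str]
    contrast_p: float
    contrast_u: float


@dataclass
class VariantRankingResult:
    pca: PCAResults
    model: OPLSResults
    validation: ValidationReport | None
    signature: Signature
    volcano: pd.DataFrame
    severity: SeverityResult


def run_variant_ranking(
    clean: MetaboliteTable,
    design: StudyDesign,
    config: AnalysisConfig | None = None,
    validate: bool = True,
) -> VariantRankingResult:
    """Severity ranking of the transfected lines.

    PCA is fitted to the transfected samples only; t1 is oriented so the
    declared most-severe group has the largest mean score, then used as the
    quantitative response of an OPLS model on the same matrix. Spearman
    correlations against t1 are computed on the cleaned concentrations.
    """
    config = config or AnalysisConfig()
    groups = _sample_groups(design)
    excluded = {config.wt_group, config.ko_group}
    ids = [s for s in clean.sample_ids if groups.get(s) not in excluded and s in groups]
    transfected_groups = sorted({groups[s] for s in ids})
    if len(transfected_groups) < 3:
        raise DesignError(f"need >= 3 transfected groups, got {transfected_groups}")
    if config.most_severe not in transfected_groups:
        raise DesignError(f"most_severe group {config.most_severe!r} absent")
    sub = clean.select_samples(ids)
    scaled, _ = autoscale(sub)
    pca = PCA(scaled).fit(n_components=2)

    t1 = pca.t(1)
    label = np.array([groups[s] for s in ids])
    if t1[label == config.most_severe].mean() < t1[label != config.most_severe].mean():
        pca.flip_component(1)
        t1 = pca.t(1)

    y = t1.to_numpy()
    n_orth = select_n_orth(sub.data, y, max_orth=config.max_orth, k=config.k)
    model, n_orth = _fit_feasible(lambda a: OPLS(y, scaled, a), n_orth)
    validation = (
        validate_opls(
            sub.data, y, k=config.k, n_perm=config.n_perm, seed=config.seed, n_orth=n_orth
        )
        if validate
        else None
    )
    vip = model.vip()
    rho = spearman_profile(sub.data, y)
    volcano = pd.DataFrame(
        {
            "metabolite_id": list(vip.index),
            "rho": rho.reindex(vip.index).to_numpy(),
            "vip": vip.to_numpy(),
        }
    )
    signature = _build_signature(vip, rho, config.vip_threshold, config.loading_top_fraction)
    volcano["selected"] = volcano["metabolite_id"].isin(signature.ids)

    means = {g: float(t1[label == g].mean()) for g in transfected_groups}
    order = sorted(means, key=means.get)
    g1, g2 = config.contrast
    for g in (g1, g2):
        if g not in transfected_groups:
            raise DesignError(f"contrast group {g!r} absent")
    u, p = mann_whitney(t1[label == g1].to_numpy(), t1[label == g2].to_numpy())
    severity = SeverityResult(
        t1_scores={s: float(v) for s, v in t1.items()},
        group_mean_t1=means,
        group_order=order,
        per_metabolite_rho={m: float(v) for m, v in rho.items()},
        contrast=(g1, g2),
        contrast_p=p,
        contrast_u=u,
    )
    return VariantRankingResult(pca, model, validation, signature, volcano, severity)


# ---------------------------------------------------------------------------
# Derived indices and regressions
# ---------------------------------------------------------------------------

INDEX_COLUMNS = (
    "aa_sum",
    "t4_oh_pro",
    "spermine_spermidine_ratio",
    "sm18_sm16_ratio",
    "sm_oh_22_1",
    "sm_oh_22_2",
    "pufa_aa_sum",
    "pufa_mufa_aa_ratio",
    "mufa_sfa_ae_ratio",
)


def _safe_ratio(num: pd.Series, den: pd.Series) -> pd.Series:
    out = num / den
    bad = ~np.isfinite(out.to_numpy())
    if bad.any():
        out = out.copy()
        out[bad] = np.nan
    return out


def derived_indices(clean: MetaboliteTable, panel: Panel) -> pd.DataFrame:
    """Per-sample severity indices from the cleaned (pre-scaling) table.

    Polyunsaturated / monounsaturated / saturated species are defined on the
    total double-bond count of the sum-composition shorthand (>= 2, == 1,
    == 0), within the diacyl (aa) and acyl-alkyl (ae) phosphatidylcholine
    subclasses. Indices whose analytes were dropped upstream come back as
    missing columns with a warning, never as infinities.
    """
    frame = clean.data
    present = set(frame.columns)
    out = pd.DataFrame(index=frame.index)

    def col(mid: str) -> pd.Series | None:
        if mid in present:
            return frame[mid]
        warnings.warn(f"index analyte {mid!r} absent after filtering", stacklevel=2)
        return None

    aa_ids = [m for m in panel.ids_by_klass("amino_acid") if m in present]
    out["aa_sum"] = frame[aa_ids].sum(axis=1) if aa_ids else np.nan

    t4 = col("t4-OH-Pro")
    out["t4_oh_pro"] = t4 if t4 is not None else np.nan

    spm, spd = col("Spermine"), col("Spermidine")
    out["spermine_spermidine_ratio"] = (
        _safe_ratio(spm, spd) if spm is not None and spd is not None else np.nan
    )

    sm18, sm16 = col("SM C18:0"), col("SM C16:0")
    out["sm18_sm16_ratio"] = (
        _safe_ratio(sm18, sm16) if sm18 is not None and sm16 is not None else np.nan
    )
    for key, mid in (("sm_oh_22_1", "SM (OH) C22:1"), ("sm_oh_22_2", "SM (OH) C22:2")):
        c = col(mid)
        out[key] = c if c is not None else np.nan

    def unsat_sum(subclass: str, predicate) -> pd.Series | None:
        ids = [
            m
            for m in panel.ids_by_subclass(subclass)
            if m in present and predicate(panel[m].total_double_bonds)
        ]
        return frame[ids].sum(axis=1) if ids else None

    pufa_aa = unsat_sum("PC_aa", lambda d: d >= 2)
    mufa_aa = unsat_sum("PC_aa", lambda d: d == 1)
    mufa_ae = unsat_sum("PC_ae", lambda d: d == 1)
    sfa_ae = unsat_sum("PC_ae", lambda d: d == 0)
    out["pufa_aa_sum"] = pufa_aa if pufa_aa is not None else np.nan
    out["pufa_mufa_aa_ratio"] = (
        _safe_ratio(pufa_aa, mufa_aa) if pufa_aa is not None and mufa_aa is not None else np.nan
    )
    out["mufa_sfa_ae_ratio"] = (
        _safe_ratio(mufa_ae, sfa_ae) if mufa_ae is not None and sfa_ae is not None else np.nan
    )
    return out[list(INDEX_COLUMNS)]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    n: int


def regress_vs_t1(index_values, t1) -> RegressionResult:
    """Ordinary least squares of one index on t1; R² is the squared Pearson
    correlation."""
    x = np.asarray(t1, dtype=float).ravel()
    y = np.asarray(index_values, dtype=float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise DegenerateError("need >= 3 paired finite values")
    if np.var(x) == 0.0:
        raise DegenerateError("t1 has zero variance")
    res = stats.linregress(x, y)
    return RegressionResult(float(res.slope), float(res.intercept), float(res.rvalue**2), int(x.size))


def batch_score_r2(scores: pd.DataFrame, batches) -> float:
    """Fraction of total PC-score variance explained by the batch label
    (between-batch sum of squares over total, pooled across components)."""
    batches = np.asarray(batches)
    T = scores.to_numpy()
    ss_between = 0.0
    ss_total = 0.0
    for a in range(T.shape[1]):
        t = T[:, a]
        mu = t.mean()
        ss_total += float(np.sum((t - mu) ** 2))
        for b in np.unique(batches):
            sel = t[batches == b]
            ss_between += sel.size * float((sel.mean() - mu) ** 2)
    return ss_between / ss_total if ss_total > 0 else 0.0


# ---------------------------------------------------------------------------
# End-to-end run
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Inputs and knobs for a full pipeline run.

    Either ``table``/``design``/``lod`` paths are given, or the dataset is
    simulated from ``seed`` and ``effects``.
    """

    seed: int = 42
    effects: EffectSpec = field(default_factory=EffectSpec)
    table: str | None = None
    design: str | None = None
    lod: str | None = None
    annotations: str | None = None
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    out_dir: str = "out"
    make_figures: bool = True

    def canonical(self) -> dict:
        d = {
            "seed": self.seed,
            "effects": asdict(self.effects),
            "table": self.table,
            "design": self.design,
            "lod": self.lod,
            "annotations": self.annotations,
            "analysis": {**asdict(self.analysis), "contrast": list(self.analysis.contrast)},
        }
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.canonical(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        sim = raw.get("simulate") or {}
        cfg.seed = int(sim.get("seed", raw.get("seed", cfg.seed)))
        eff = sim.get("effects") or {}
        for k, v in eff.items():
            if not hasattr(cfg.effects, k):
                raise KeyError(f"unknown effects field {k!r}")
            setattr(cfg.effects, k, v)
        inputs = raw.get("inputs") or {}
        cfg.table = inputs.get("table")
        cfg.design = inputs.get("design")
        cfg.lod = inputs.get("lod")
        cfg.annotations = inputs.get("annotations")
        ana = raw.get("analysis") or {}
        for k, v in ana.items():
            if not hasattr(cfg.analysis, k):
                raise KeyError(f"unknown analysis field {k!r}")
            setattr(cfg.analysis, k, tuple(v) if k == "contrast" else v)
        out = raw.get("output") or {}
        cfg.out_dir = out.get("dir", cfg.out_dir)
        cfg.make_figures = bool(out.get("figures", True))
        return cfg


@dataclass
class ReportBundle:
    """Everything one pipeline run produced."""

    config: RunConfig
    design: StudyDesign
    panel: Panel
    preprocessing: PreprocessResult
    pca_all: PCAResults
    ko_vs_wt: KOvsWTResult
    ranking: VariantRankingResult
    indices: pd.DataFrame
    regressions: dict[str, RegressionResult]

    def report_dict(self) -> dict:
        pre = self.preprocessing
        val_a = self.ko_vs_wt.validation
        val_b = self.ranking.validation
        n_shared, frac_a, frac_b = signature_overlap(
            self.ko_vs_wt.signature, self.ranking.signature
        )
        return {
            "config_hash": self.config.hash(),
            "seed": self.config.seed,
            "preprocessing": {
                "n_input_metabolites": pre.reports[0].n_input_metabolites,
                "n_retained": pre.n_retained,
                "retained_fraction": pre.n_retained / pre.reports[0].n_input_metabolites,
                "n_samples": pre.clean.shape[0],
            },
            "pca_all": {
                "r2x_pct": [round(100 * r, 4) for r in self.pca_all.r2x_per_component],
            },
            "ko_vs_wt": {
                "n_orth": self.ko_vs_wt.model.n_orth,
                "r2y": self.ko_vs_wt.model.r2y,
                "validation": val_a.to_dict() if val_a else None,
                "n_signature": len(self.ko_vs_wt.signature),
            },
            "variant_ranking": {
                "n_orth": self.ranking.model.n_orth,
                "r2y": self.ranking.model.r2y,
                "validation": val_b.to_dict() if val_b else None,
                "n_signature": len(self.ranking.signature),
                "group_order": self.ranking.severity.group_order,
                "group_mean_t1": self.ranking.severity.group_mean_t1,
                "contrast": list(self.ranking.severity.contrast),
                "contrast_p": self.ranking.severity.contrast_p,
                "pca_r2x_pct": [
                    round(100 * r, 4) for r in self.ranking.pca.r2x_per_component
                ],
            },
            "signature_overlap": {
                "n_shared": n_shared,
                "fraction_of_ko_vs_wt": frac_a,
                "fraction_of_ranking": frac_b,
            },
            "index_regressions": {
                k: asdict(v) for k, v in self.regressions.items()
            },
        }

    def write(self, out_dir: str | Path | None = None, timestamp: str | None = None) -> Path:
        """Write report.json, CSV tables and figures; returns the directory.

        The report is byte-identical across reruns of the same config and
        seed; the wall-clock timestamp is isolated in the single
        ``generated_at`` field.
        """
        out = Path(out_dir or self.config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report = self.report_dict()
        if timestamp is None:
            import datetime

            timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()
        report["generated_at"] = timestamp
        (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
        self.ko_vs_wt.volcano.to_csv(out / "volcano_A.csv", index=False, float_format="%.10g")
        self.ranking.volcano.to_csv(out / "volcano_B.csv", index=False, float_format="%.10g")
        self.indices.to_csv(out / "indices.csv", index_label="sample", float_format="%.10g")
        groups = _sample_groups(self.design)
        sc = self.pca_all.scores.copy()
        sc.insert(0, "group", [groups.get(s, "") for s in sc.index])
        sc.to_csv(out / "scores.csv", index_label="sample", float_format="%.10g")
        sct = self.ranking.pca.scores.copy()
        sct.insert(0, "group", [groups.get(s, "") for s in sct.index])
        sct.to_csv(out / "scores_transfected.csv", index_label="sample", float_format="%.10g")
        if self.config.make_figures:
            self._figures(out, groups)
        return out

    def _figures(self, out: Path, groups: dict[str, str]) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(10, 4.2))
        self.pca_all.plot_scores(ax=axes[0], groups=groups)
        axes[0].set_title("PCA, all groups")
        self.ranking.pca.plot_scores(ax=axes[1], groups=groups)
        axes[1].set_title("PCA, transfected only")
        fig.tight_layout()
        fig.savefig(out / "fig_scores.png", dpi=120)
        plt.close(fig)

        fig, axes = plt.subplots(1, 2, figsize=(10, 4.2))
        for ax, vol, xcol, title in (
            (axes[0], self.ko_vs_wt.volcano, "loading", "OPLS-DA KO vs WT"),
            (axes[1], self.ranking.volcano, "rho", "OPLS on t1"),
        ):
            sel = vol["selected"]
            ax.scatter(vol.loc[~sel, xcol], vol.loc[~sel, "vip"], s=10, c="lightgray")
            ax.scatter(vol.loc[sel, xcol], vol.loc[sel, "vip"], s=12, c="crimson")
            ax.axhline(1.0, color="k", lw=0.6, ls="--")
            ax.set_xlabel(xcol)
            ax.set_ylabel("VIP")
            ax.set_title(title)
        fig.tight_layout()
        fig.savefig(out / "fig_volcano.png", dpi=120)
        plt.close(fig)

        t1 = pd.Series(self.ranking.severity.t1_scores)
        cols = [c for c in self.indices.columns]
        fig, axes = plt.subplots(3, 3, figsize=(11, 9))
        for ax, name in zip(axes.ravel(), cols):
            vals = self.indices.loc[t1.index, name]
            ax.scatter(t1, vals, s=12)
            try:
                reg = self.regressions[name]
                xs = np.linspace(float(t1.min()), float(t1.max()), 50)
                ax.plot(xs, reg.slope * xs + reg.intercept, "k-", lw=1)
                ax.set_title(f"{name}  R²={reg.r2:.2f}", fontsize=9)
            except KeyError:
                ax.set_title(name, fontsize=9)
            ax.set_xlabel("t1")
        fig.tight_layout()
        fig.savefig(out / "fig_regressions.png", dpi=120)
        plt.close(fig)


def load_inputs(config: RunConfig) -> tuple[MetaboliteTable, StudyDesign, dict, Panel]:
    """Simulate or read the raw inputs named by the config."""
    if config.table:
        table = read_table(config.table)
        design = read_design(config.design)
        lods = read_lod(config.lod)
        panel = (
            read_annotations(config.annotations) if config.annotations else default_panel()
        )
    else:
        panel = default_panel()
        design = default_design()
        table, lods, _ = simulate(panel, design, config.effects, config.seed)
    return table, design, lods, panel


def run_all(config: RunConfig | str | Path, write: bool = True) -> ReportBundle:
    """Execute preprocess → analysis A → analysis B → indices/regressions."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    table, design, lods, panel = load_inputs(config)
    pre = preprocess(table, design, lods)
    clean = pre.clean

    scaled_all, _ = autoscale(clean)
    pca_all = PCA(scaled_all).fit(n_components=2)

    ana = config.analysis
    ko = run_ko_vs_wt(clean, design, ana)
    ranking = run_variant_ranking(clean, design, ana)
    indices = derived_indices(clean, panel)
    t1 = pd.Series(ranking.severity.t1_scores)
    regressions: dict[str, RegressionResult] = {}
    for name in indices.columns:
        vals = indices.loc[t1.index, name]
        try:
            regressions[name] = regress_vs_t1(vals.to_numpy(), t1.to_numpy())
        except DegenerateError:
            continue
    bundle = ReportBundle(
        config=config,
        design=design,
        panel=panel,
        preprocessing=pre,
        pca_all=pca_all,
        ko_vs_wt=ko,
        ranking=ranking,
        indices=indices,
        regressions=regressions,
    )
    if write:
        bundle.write()
    return bundle
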