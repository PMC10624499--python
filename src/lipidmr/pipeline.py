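"""End-to-end analysis orchestration from a declarative run configuration.

A run is a list of analysis arms (e.g. lipid→disease, per-gene
drug-target→disease, disease→lipid reverse arm).  Each arm executes the
selection chain

    p-threshold → (cis extraction | MHC exclusion) → LD clumping →
    harmonization → Steiger filtering → strength metrics → estimators →
    heterogeneity diagnostics

and the run finishes with Benjamini-Hochberg FDR applied to the primary
(Wald/IVW) p-values within each configured FDR family.  Gene-panel arms
expand to one analysis per gene, mirroring per-gene forest plots.

Estimator applicability follows the reporting convention of drug-target
MR forest plots: the Wald ratio when a single variant survives selection,
IVW from two, MR-Egger from three; correlated-instrument (GLS) variants
are used exactly when the arm declares an LD matrix with
``correlated: true``.  Zero instruments after selection is recorded as a
skipped arm, not a crash.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import instruments as instr
from .diagnostics import bh_fdr
from .errors import (
    ConfigurationError,
    EstimationError,
    NoSharedVariantsError,
    ValidationError,
)
from .estimators import MRInput, egger, ivw, ivw_correlated, mvmr_ivw, wald_ratio
from .harmonize import harmonize
from .sumstats import (
    DatasetDialect,
    SummaryDataset,
    read_ld_matrix,
    read_summary_table,
)

RESULT_COLUMNS = [
    "arm",
    "exposure",
    "outcome",
    "gene",
    "pathway",
    "outcome_type",
    "method",
    "primary",
    "n_snps",
    "beta",
    "se",
    "ci_low",
    "ci_high",
    "pvalue",
    "or_",
    "or_ci_low",
    "or_ci_high",
    "Q",
    "Q_dof",
    "Q_p",
    "I2_percent",
    "egger_intercept",
    "egger_intercept_se",
    "egger_intercept_p",
    "re_scale",
    "mean_F",
    "total_r2_x",
    "fdr_family",
    "qvalue",
    "significant",
    "note",
]


@dataclass
class SourceSpec:
    """One summary-statistics source: a path (+dialect) or an in-memory dataset."""

    trait_name: str
    trait_type: str = "continuous"
    path: str | None = None
    dialect: DatasetDialect | None = None
    dataset: SummaryDataset | None = None
    n: float | None = None

    def load(self) -> SummaryDataset:
        if self.dataset is not None:
            return self.dataset
        dialect = self.dialect or DatasetDialect.canonical()
        dataset, _ = read_summary_table(
            self.path, dialect, self.trait_name, self.trait_type
        )
        return dataset

    @classmethod
    def from_dict(cls, d: dict) -> "SourceSpec":
        dialect = None
        if "dialect" in d:
            dd = d["dialect"]
            dialect = DatasetDialect(
                column_map=dd.get("column_map", {c: c for c in ()}),
                delimiter=dd.get("delimiter", "\t"),
                p_floor=float(dd.get("p_floor", 1e-300)),
            )
        return cls(
            trait_name=d["trait_name"],
            trait_type=d.get("trait_type", "continuous"),
            path=d.get("path"),
            dialect=dialect,
            n=d.get("n"),
        )


@dataclass
class AnalysisSpec:
    """One analysis arm of a run."""

    label: str
    exposure: SourceSpec
    outcome: SourceSpec
    p_threshold: float = instr.GENOME_WIDE_P
    clump_r2: float | None = None
    ld_path: str | None = None
    correlated: bool = False
    gene_panel_path: str | None = None
    cis_flank_bp: int = instr.CIS_FLANK_BP
    mhc_exclude: str = "outcome"  # outcome | exposure | both | none
    steiger: bool = True
    estimators: list[str] = dc_field(default_factory=lambda: ["ivw", "egger"])
    effects_model: str = "multiplicative_random"
    fdr_family: str | None = None
    palindromic_eaf_window: float = 0.08
    mv_exposures: list[SourceSpec] = dc_field(default_factory=list)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisSpec":
        return cls(
            label=d["label"],
            exposure=SourceSpec.from_dict(d["exposure"]),
            outcome=SourceSpec.from_dict(d["outcome"]),
            p_threshold=float(d.get("p_threshold", instr.GENOME_WIDE_P)),
            clump_r2=None if d.get("clump_r2") is None else float(d["clump_r2"]),
            ld_path=d.get("ld_path"),
            correlated=bool(d.get("correlated", False)),
            gene_panel_path=d.get("gene_panel"),
            cis_flank_bp=int(d.get("cis_flank_bp", instr.CIS_FLANK_BP)),
            mhc_exclude=d.get("mhc_exclude", "outcome"),
            steiger=bool(d.get("steiger", True)),
            estimators=list(d.get("estimators", ["ivw", "egger"])),
            effects_model=d.get("effects_model", "multiplicative_random"),
            fdr_family=d.get("fdr_family"),
            palindromic_eaf_window=float(d.get("palindromic_eaf_window", 0.08)),
            mv_exposures=[SourceSpec.from_dict(s) for s in d.get("mv_exposures", [])],
        )


@dataclass
class RunConfig:
    analyses: list[AnalysisSpec]
    output_dir: str | None = None
    seed: int = 0
    fdr_q: float = 0.05

    def __post_init__(self):
        labels = [a.label for a in self.analyses]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("analysis arm labels must be unique")
        known = {"wald_ratio", "ivw", "egger", "mvmr_ivw"}
        for a in self.analyses:
            unknown = set(a.estimators) - known
            if unknown:
                raise ConfigurationError(
                    f"{a.label}: unknown estimator(s) {sorted(unknown)}"
                )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        cfg = cls(
            analyses=[AnalysisSpec.from_dict(d) for d in raw["analyses"]],
            output_dir=raw.get("output_dir"),
            seed=int(raw.get("seed", 0)),
            fdr_q=float(raw.get("fdr_q", 0.05)),
        )
        cfg.validate_paths()
        return cfg

    def validate_paths(self) -> None:
        """Fail before any work if a referenced file is missing."""
        for a in self.analyses:
            for p in [
                a.exposure.path,
                a.outcome.path,
                a.ld_path,
                a.gene_panel_path,
                *[s.path for s in a.mv_exposures],
            ]:
                if p is not None and not Path(p).exists():
                    raise ConfigurationError(f"{a.label}: file not found: {p}")


@dataclass
class AnalysisReport:
    """Run output: result rows, per-stage instrument audit, skipped arms."""

    results: pd.DataFrame
    audit: pd.DataFrame  # arm, gene, stage, n_variants
    skipped: pd.DataFrame  # arm, gene, reason

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        _write_fixed(self.results, directory / "results.tsv")
        _write_fixed(self.audit, directory / "instrument_audit.tsv")
        _write_fixed(self.skipped, directory / "skipped.tsv")


def _write_fixed(frame: pd.DataFrame, path) -> None:
    """Deterministic table serialisation (fixed float format, no index)."""
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _estimate_rows(spec, gene, pathway, harmonized, ld, strength, note=""):
    """Run the arm's estimators on one harmonized instrument set."""
    J = len(harmonized)
    rows = []
    base = {
        "arm": spec.label,
        "exposure": harmonized.exposure_name,
        "outcome": harmonized.outcome_name,
        "gene": gene,
        "pathway": pathway,
        "outcome_type": harmonized.outcome_type,
        "mean_F": strength.mean_F,
        "total_r2_x": strength.total_r2_x,
        "fdr_family": spec.fdr_family,
        "note": note,
    }

    def add(est, het, primary):
        binary = harmonized.outcome_type == "binary"
        rows.append(
            {
                **base,
                "method": est.method,
                "primary": primary,
                "n_snps": est.n_snps,
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pvalue": est.pvalue,
                "or_": math.exp(est.beta) if binary else np.nan,
                "or_ci_low": math.exp(est.ci_low) if binary else np.nan,
                "or_ci_high": math.exp(est.ci_high) if binary else np.nan,
                "Q": het.Q if het else np.nan,
                "Q_dof": het.dof if het else np.nan,
                "Q_p": het.pvalue if het else np.nan,
                "I2_percent": het.I2_percent if het else np.nan,
                "egger_intercept": est.intercept,
                "egger_intercept_se": est.intercept_se,
                "egger_intercept_p": est.intercept_p,
                "re_scale": est.re_scale,
            }
        )

    mr_input = MRInput(harmonized=harmonized, ld=ld)
    if J == 1:
        h = harmonized
        est = wald_ratio(h.beta_x[0], h.se_x[0], h.beta_y[0], h.se_y[0])
        add(est, None, primary=True)
        return rows

    if "ivw" in spec.estimators or "wald_ratio" in spec.estimators:
        if spec.correlated and ld is not None:
            est, het = ivw_correlated(mr_input, effects_model=spec.effects_model)
        else:
            est, het = ivw(mr_input, effects_model=spec.effects_model)
        add(est, het, primary=True)
    if "egger" in spec.estimators and J >= 3:
        est, het = egger(
            mr_input,
            correlated=spec.correlated and ld is not None,
            effects_model=spec.effects_model,
        )
        add(est, het, primary=False)
    return rows


def run_analysis(config: RunConfig) -> AnalysisReport:
    """Execute every arm of the run; deterministic given config and inputs."""
    config.validate_paths()
    result_rows: list[dict] = []
    audit_rows: list[dict] = []
    skipped_rows: list[dict] = []

    for spec in config.analyses:
        exposure = spec.exposure.load()
        outcome = spec.outcome.load()
        ld_full = None
        if spec.ld_path is not None:
            ld_full = read_ld_matrix_full(spec.ld_path)

        if spec.mhc_exclude in ("outcome", "both"):
            outcome = instr.exclude_mhc(outcome)
        if spec.mhc_exclude in ("exposure", "both"):
            exposure = instr.exclude_mhc(exposure)

        panels: list[tuple[str, str, SummaryDataset]]
        if spec.gene_panel_path:
            regions = instr.read_gene_regions(spec.gene_panel_path)
            panels = [
                (
                    reg.symbol,
                    reg.pathway_label,
                    instr.extract_cis_window(exposure, reg, spec.cis_flank_bp),
                )
                for reg in regions
            ]
        else:
            panels = [("", "", exposure)]

        for gene, pathway, panel_ds in panels:

            def audit(stage, n):
                audit_rows.append(
                    {"arm": spec.label, "gene": gene, "stage": stage, "n_variants": n}
                )

            audit("input", len(panel_ds))
            ds = instr.threshold_by_pvalue(panel_ds, spec.p_threshold)
            audit("p_threshold", len(ds))

            if spec.clump_r2 is not None and len(ds) > 1:
                if ld_full is None:
                    skipped_rows.append(
                        {
                            "arm": spec.label,
                            "gene": gene,
                            "reason": "clump_r2 set but no LD matrix configured",
                        }
                    )
                    continue
                ds = instr.ld_clump(ds, ld_full, spec.clump_r2)
            audit("clump", len(ds))

            if len(ds) == 0:
                skipped_rows.append(
                    {"arm": spec.label, "gene": gene, "reason": "no instruments after selection"}
                )
                continue

            try:
                harmonized = harmonize(ds, outcome, spec.palindromic_eaf_window)
            except NoSharedVariantsError:
                skipped_rows.append(
                    {"arm": spec.label, "gene": gene, "reason": "no shared variants with outcome"}
                )
                continue
            audit("harmonize", len(harmonized))

            n_x = spec.exposure.n or _median_n(exposure)
            n_y = spec.outcome.n or _median_n(outcome)
            steiger_dropped: list[str] = []
            if spec.steiger:
                if n_x is None or n_y is None:
                    raise ConfigurationError(
                        f"{spec.label}: Steiger filtering needs exposure and outcome sample sizes"
                    )
                harmonized, steiger_dropped = instr.steiger_filter(harmonized, n_x, n_y)
            audit("steiger", len(harmonized))

            if len(harmonized) == 0:
                skipped_rows.append(
                    {"arm": spec.label, "gene": gene, "reason": "no instruments after Steiger filtering"}
                )
                continue

            ld_sub = None
            if ld_full is not None and spec.correlated:
                ld_sub = ld_full.subset(harmonized.variant_ids)

            strength = instr.per_snp_strength(
                harmonized, n_x if n_x else 4, method="t_stat"
            )
            strength.steiger_dropped = steiger_dropped

            note = ""
            if len(harmonized) == 1:
                note = "single instrument: Wald ratio"
            elif len(harmonized) < 3 and "egger" in spec.estimators:
                note = "fewer than 3 instruments: Egger omitted"
            try:
                result_rows.extend(
                    _estimate_rows(spec, gene, pathway, harmonized, ld_sub, strength, note)
                )
            except EstimationError as exc:
                skipped_rows.append(
                    {"arm": spec.label, "gene": gene, "reason": f"estimation failed: {exc}"}
                )
                continue

        if spec.mv_exposures and "mvmr_ivw" in spec.estimators:
            result_rows.extend(_run_mvmr(spec, outcome))

    results = pd.DataFrame(result_rows, columns=RESULT_COLUMNS)
    results = _apply_fdr(results, config.fdr_q)
    report = AnalysisReport(
        results=results,
        audit=pd.DataFrame(audit_rows, columns=["arm", "gene", "stage", "n_variants"]),
        skipped=pd.DataFrame(skipped_rows, columns=["arm", "gene", "reason"]),
    )
    if config.output_dir:
        report.write(config.output_dir)
    return report


def read_ld_matrix_full(path):
    """Read an LD matrix keeping the file's own variant order."""
    import pandas as pd_

    frame = pd_.read_csv(path, sep="\t", index_col=0, nrows=0)
    ids = [str(c) for c in frame.columns]
    return read_ld_matrix(path, ids)


def _median_n(dataset: SummaryDataset) -> float | None:
    n = dataset.table["n"].to_numpy(dtype=float)
    n = n[~np.isnan(n)]
    return float(np.median(n)) if n.size else None


def _run_mvmr(spec: AnalysisSpec, outcome: SummaryDataset) -> list[dict]:
    """Harmonize each exposure to the outcome, intersect, and fit MVMR-IVW."""
    harmonized_list = []
    for src in spec.mv_exposures:
        ds = instr.threshold_by_pvalue(src.load(), spec.p_threshold)
        if len(ds) == 0:
            continue
        harmonized_list.append(harmonize(ds, outcome, spec.palindromic_eaf_window))
    if len(harmonized_list) < 2:
        raise ConfigurationError(
            f"{spec.label}: multivariable analysis needs >= 2 exposures with instruments"
        )
    common = set(harmonized_list[0].variant_ids)
    for h in harmonized_list[1:]:
        common &= set(h.variant_ids)
    if len(common) <= len(harmonized_list):
        raise ValidationError(
            f"{spec.label}: too few shared variants ({len(common)}) for MVMR"
        )
    order = [v for v in harmonized_list[0].variant_ids if v in common]
    cols, names = [], []
    for h in harmonized_list:
        idx = {v: i for i, v in enumerate(h.variant_ids)}
        cols.append(np.array([h.beta_x[idx[v]] for v in order]))
        names.append(h.exposure_name)
    h0 = harmonized_list[0]
    idx0 = {v: i for i, v in enumerate(h0.variant_ids)}
    sel = [idx0[v] for v in order]
    base_h = h0.subset(np.isin(np.arange(len(h0)), sel))
    mr_input = MRInput(
        harmonized=base_h,
        exposure_matrix=np.column_stack(cols),
        exposure_names=names,
    )
    estimates, het = mvmr_ivw(mr_input, effects_model=spec.effects_model)
    binary = base_h.outcome_type == "binary"
    rows = []
    for est in estimates:
        rows.append(
            {
                "arm": spec.label,
                "exposure": est.exposure,
                "outcome": base_h.outcome_name,
                "gene": "",
                "pathway": "",
                "outcome_type": base_h.outcome_type,
                "method": "mvmr_ivw",
                "primary": False,
                "n_snps": est.n_snps,
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pvalue": est.pvalue,
                "or_": math.exp(est.beta) if binary else np.nan,
                "or_ci_low": math.exp(est.ci_low) if binary else np.nan,
                "or_ci_high": math.exp(est.ci_high) if binary else np.nan,
                "Q": het.Q,
                "Q_dof": het.dof,
                "Q_p": het.pvalue,
                "I2_percent": het.I2_percent,
                "egger_intercept": None,
                "egger_intercept_se": None,
                "egger_intercept_p": None,
                "re_scale": est.re_scale,
                "mean_F": np.nan,
                "total_r2_x": np.nan,
                "fdr_family": spec.fdr_family,
                "note": "",
            }
        )
    return rows


def _apply_fdr(results: pd.DataFrame, q_star: float) -> pd.DataFrame:
    """BH adjustment of primary p-values within each declared FDR family."""
    results = results.copy()
    results["qvalue"] = np.nan
    results["significant"] = pd.array([None] * len(results), dtype="boolean")
    if results.empty:
        return results
    mask_primary = results["primary"].fillna(False).astype(bool)
    for family, group in results[mask_primary].groupby("fdr_family", dropna=True):
        if family is None or len(group) == 0:
            continue
        fdr = bh_fdr(group["pvalue"].to_numpy(), q_star=q_star)
        results.loc[group.index, "qvalue"] = fdr.qvalues
        results.loc[group.index, "significant"] = fdr.significant
    return results


def make_forest_table(report: AnalysisReport, scale: str = "beta") -> pd.DataFrame:
    """Plot-ready forest-plot rows: label, n_snps, point, low, high.

    ``scale="or"`` exponentiates beta and CI bounds and is valid only for
    binary outcomes.
    """
    if report.results.empty:
        raise ValidationError("report has no results")
    if scale not in ("beta", "or"):
        raise ValidationError(f"unknown scale {scale!r}")
    res = report.results
    if scale == "or" and (res["outcome_type"] != "binary").any():
        raise ValidationError("odds-ratio scale requested for a continuous outcome")
    labels = [
        " / ".join(filter(None, [r.arm, r.gene, r.method]))
        for r in res.itertuples(index=False)
    ]
    if scale == "beta":
        point, low, high = res["beta"], res["ci_low"], res["ci_high"]
    else:
        point, low, high = (
            np.exp(res["beta"]),
            np.exp(res["ci_low"]),
            np.exp(res["ci_high"]),
        )
    return pd.DataFrame(
        {
            "label": labels,
            "n_snps": res["n_snps"].to_numpy(),
            "point": np.asarray(point, dtype=float),
            "low": np.asarray(low, dtype=float),
            "high": np.asarray(high, dtype=float),
        }
    )
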