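"""End-to-end orchestration: validate -> ordinations -> dispersion tests ->
turnover suite, from a single run configuration."""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io_validation import AnalysisBundle, load_bundle
from .nullmodel import NullModelResult, run_all_trait_tests
from .ordination import (
    axis_variable_correlations,
    pca_correlation,
    select_trait_assemblage,
    vif_eliminate,
    zscore,
)
from .synthetic import SyntheticConfig, generate_dataset
from .turnover import run_turnover_suite

__all__ = ["RunConfig", "run_full", "summarize_figure1", "significance_stars"]


@dataclass
class RunConfig:
    """Analysis-level knobs; either file paths or a simulation config."""

    occurrence_path: str | None = None
    sm_path: str | None = None
    rut_path: str | None = None
    env_path: str | None = None
    simulate: dict | None = None  # SyntheticConfig fields
    alpha: float = 0.05
    reps_within: int = 1000
    perms_mantel: int = 999
    vif_threshold: float = 10.0
    residualize_soil: bool = True
    null_variant: str = "subset"  # or "multiset": literal with-replacement draw
    outlier_control: bool = False
    max_rut_axes: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.reps_within < 1 or self.perms_mantel < 1:
            raise ValueError("replicate and permutation counts must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    coverage: dict
    soil: dict
    rut: dict
    assemblages: dict
    within_plot: dict[str, NullModelResult]
    turnover: dict
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        within = {k: v.summary() for k, v in self.within_plot.items()}
        turn = {}
        for label, entry in self.turnover.items():
            turn[label] = {
                k: v.summary() for k, v in entry.items() if k != "tau"
            }
        return {
            "coverage": self.coverage,
            "soil": self.soil,
            "rut": self.rut,
            "assemblages": self.assemblages,
            "within_plot": within,
            "turnover": turn,
            "provenance": self.provenance,
        }


def _pca_summary(pca, retained_only: bool = False) -> dict:
    mask = pca.retained_axes
    return {
        "eigenvalues": [float(v) for v in pca.eigenvalues],
        "variance_pct": [float(100 * v) for v in pca.variance_proportions],
        "broken_stick_pct": [float(100 * v) for v in pca.broken_stick_expectations],
        "retained_axes": pca.retained_axis_labels(),
        "n_retained": int(mask.sum()),
    }


def _load_or_simulate(config: RunConfig) -> AnalysisBundle:
    if config.simulate is not None:
        sim = dict(config.simulate)
        sim.setdefault("seed", config.seed)
        if sim.get("sigma_filt") in ("inf", ".inf"):
            sim["sigma_filt"] = math.inf
        return generate_dataset(SyntheticConfig(**sim)).bundle
    paths = (config.occurrence_path, config.sm_path, config.rut_path, config.env_path)
    if any(p is None for p in paths):
        raise ValueError("provide either all four table paths or a simulate block")
    return load_bundle(*paths)


def run_full(config: RunConfig, out_dir: str | Path | None = None) -> RunReport:
    """Run the whole analysis; deterministic given ``config.seed``.

    Stage seeds derive from the master seed, so the dispersion tests and
    the turnover suite can be rerun in isolation with the same streams.
    """
    bundle = _load_or_simulate(config)

    ss = np.random.SeedSequence(config.seed)
    seed_within, seed_turnover = (int(s.generate_state(1)[0]) for s in ss.spawn(2))

    # soil ordination: z-score, drop collinear variables, normed PCA
    soil_retained, vif_log = vif_eliminate(bundle.env.data, threshold=config.vif_threshold)
    soil_pca = pca_correlation(bundle.env.data[soil_retained])
    soil_axes = soil_pca.retained_axis_labels() or ["axis1"]
    soil_corr = axis_variable_correlations(
        soil_pca, zscore(bundle.env.data[soil_retained]), alpha=config.alpha,
        axes=soil_axes,
    )
    soil_distance_vars = select_trait_assemblage(soil_corr, "axis1")

    # trait ordination: all traits kept, normed PCA, axis assemblages
    rut_pca = pca_correlation(bundle.rut.data)
    rut_axes = rut_pca.retained_axis_labels()[: config.max_rut_axes]
    rut_corr = axis_variable_correlations(
        rut_pca, zscore(bundle.rut.data), alpha=config.alpha, axes=rut_axes,
    )
    assemblages = {}
    for axis in rut_axes:
        try:
            assemblages[f"rut_{axis}"] = select_trait_assemblage(rut_corr, axis)
        except ValueError:
            continue  # axis with no significant trait is unusable

    within = run_all_trait_tests(
        bundle, assemblages, R=config.reps_within, seed=seed_within,
        variant=config.null_variant,
        outlier_control=config.outlier_control,
    )
    turnover = run_turnover_suite(
        bundle, assemblages, soil_variables=soil_distance_vars,
        permutations=config.perms_mantel, seed=seed_turnover,
        residualize_soil=config.residualize_soil,
    )

    report = RunReport(
        coverage=bundle.coverage,
        soil={
            "vif_retained": soil_retained,
            "vif_eliminated": [v for v in bundle.env.variable_ids if v not in soil_retained],
            "pca": _pca_summary(soil_pca),
            "distance_variables": soil_distance_vars,
        },
        rut={"pca": _pca_summary(rut_pca), "axes_tested": rut_axes},
        assemblages=assemblages,
        within_plot=within,
        turnover=turnover,
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stage_seeds": {"within_plot": seed_within, "turnover": seed_turnover},
            "version": __version__,
        },
    )

    if out_dir is not None:
        _persist(report, config, Path(out_dir))
    return report


def _persist(report: RunReport, config: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    (out / "report.txt").write_text(render_text_report(report))
    for label, res in report.within_plot.items():
        pd.Series(res.replicate_medians, name="median_O_E").to_csv(
            out / f"replicate_medians_{label}.csv", index_label="replicate"
        )
    for label, entry in report.turnover.items():
        entry["tau"].to_frame().to_csv(out / f"tau_{label}.csv", index_label="plot")


def significance_stars(p: float, alpha: float = 0.05) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= alpha:
        return "*"
    return "ns"


def summarize_figure1(report: RunReport, alpha: float = 0.05) -> pd.DataFrame:
    """O-E mean +/- SD with significance stars, one row per trait set."""
    rows = []
    for label, res in report.within_plot.items():
        rows.append(
            {
                "trait_set": label,
                "O_E_mean": res.mean,
                "O_E_sd": res.sd,
                "p": res.p,
                "alternative": res.alternative,
                "stars": significance_stars(res.p, alpha),
            }
        )
    return pd.DataFrame(rows)


def render_text_report(report: RunReport) -> str:
    lines = ["# analysis report", ""]
    lines.append(f"coverage: {json.dumps(report.coverage, default=str)}")
    lines.append("")
    lines.append(f"soil variables retained after VIF: {report.soil['vif_retained']}")
    pct = ", ".join(f"{v:.1f}%" for v in report.soil["pca"]["variance_pct"])
    lines.append(f"soil PCA variance: {pct}; retained {report.soil['pca']['retained_axes']}")
    pct = ", ".join(f"{v:.1f}%" for v in report.rut["pca"]["variance_pct"])
    lines.append(f"trait PCA variance: {pct}; retained {report.rut['pca']['retained_axes']}")
    lines.append("")
    lines.append("within-plot dispersion tests (median of O-E):")
    fig1 = summarize_figure1(report)
    lines.append(fig1.to_string(index=False))
    lines.append("")
    lines.append("turnover Mantel tests:")
    for label, entry in report.turnover.items():
        for key, res in entry.items():
            if key == "tau":
                continue
            lines.append(
                f"  {label} vs {key.removeprefix('mantel_')}: "
                f"r = {res.r:+.3f}, p = {res.p:.4f} "
                f"({significance_stars(res.p)})"
            )
    return "\n".join(lines) + "\n"
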