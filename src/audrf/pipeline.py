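"""End-to-end per-unit and population analysis.

`analyze_unit` runs the FRA and/or RLF chains on each condition of a unit and
derives paired change metrics (modulation index, 20%-criterion change class)
for total spikes, FRA area, threshold, half-maximum level and the
discriminability index.  `analyze_population` assembles the study-level
report: MI distributions split by receptive-field class with a two-sample KS
comparison, the RLF type-transition contingency table with Fisher's exact
test, condition medians with bootstrap CIs plus Friedman and Sidak-corrected
Wilcoxon post hocs for half-max and DI, and the Spearman correlation between
half-max change and threshold change.  `run_repro` is the one-command
demonstration on the default synthetic population, writing deterministic
tables with a provenance sidecar.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from typing import TextIO
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fra as fra_mod
from . import rlf as rlf_mod
from . import stats as st
from .data_io import ConditionTriplet, ValidationError, write_results, _jsonable
from .synth import Population, PopulationConfig, SyntheticUnit, make_population

__all__ = [
    "AnalysisConfig",
    "load_population_config",
    "UnitResult",
    "PopulationReport",
    "analyze_unit",
    "analyze_population",
    "run_repro",
]

log = logging.getLogger("audrf")

CONDITIONS = ("control", "deactivated", "recovery")


@dataclass(frozen=True)
class AnalysisConfig:
    """Named constants of the analysis chain.

    Defaults are the published criteria: a 2-SD excitatory criterion, a
    tenth-order tuning-curve polynomial, the 25% non-monotonicity rule, a 20%
    firing-rate change criterion, and a family alpha of 0.05 Sidak-corrected
    across the two post hoc comparisons.
    """

    sd_multiplier: float = 2.0
    poly_degree: int = 10
    nonmono_fraction: float = 0.25
    change_criterion: float = 0.20
    alpha: float = 0.05
    n_posthoc: int = 2
    di_variant: str = "absdev"  # or "sumauc" (diagnostic)
    fallback_criterion: int = 1
    plateau_tol: float = rlf_mod.PLATEAU_TOL
    r2_straight: float = rlf_mod.R2_STRAIGHT
    flat_floor: float = rlf_mod.FLAT_FLOOR
    bootstrap_n: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 <= self.change_criterion < 1
                and 0 < self.nonmono_fraction < 1):
            raise ValidationError("analysis thresholds out of range")
        if self.di_variant not in ("absdev", "sumauc"):
            raise ValidationError("di_variant must be 'absdev' or 'sumauc'")

    @property
    def posthoc_alpha(self) -> float:
        return st.sidak_alpha(self.alpha, self.n_posthoc)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, source: str | Path | TextIO) -> "AnalysisConfig":
        """Load analysis constants from a YAML (or JSON) mapping."""
        return cls(**_load_mapping(source))


def _load_mapping(source) -> dict:
    import yaml

    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValidationError("config file must contain a mapping")
    return data


def load_population_config(source) -> PopulationConfig:
    """Load a :class:`~audrf.synth.PopulationConfig` from YAML/JSON."""
    return PopulationConfig(**_load_mapping(source))


@dataclass
class UnitResult:
    unit_id: str
    fra_class: str | None
    fra_results: dict  # condition -> FTCResult
    rlf_results: dict  # condition -> RLFMetrics
    changes: list  # ChangeSummary


def _di_value(metrics: rlf_mod.RLFMetrics, config: AnalysisConfig) -> float:
    return metrics.di if config.di_variant == "absdev" else metrics.di_sumauc


def analyze_unit(
    unit: SyntheticUnit | dict,
    config: AnalysisConfig = AnalysisConfig(),
) -> UnitResult:
    """Analyze every condition of one unit and derive its change metrics.

    Accepts a :class:`~audrf.synth.SyntheticUnit` or a mapping with keys
    ``unit_id`` / ``fra`` / ``rlf`` / ``fra_class`` (triplets of recorded
    data go through the same door).  Grid consistency across conditions is
    enforced by :class:`~audrf.data_io.ConditionTriplet`.
    """
    if isinstance(unit, dict):
        unit_id = unit.get("unit_id", "unit")
        fra_trip = unit.get("fra")
        rlf_trip = unit.get("rlf")
        fra_class = unit.get("fra_class")
        use_fallback = unit.get("use_fallback", False)
    else:
        unit_id = unit.record.unit_id
        fra_trip, rlf_trip = unit.fra, unit.rlf
        fra_class = unit.record.fra_class
        use_fallback = False

    fra_results: dict = {}
    rlf_results: dict = {}
    changes: list[st.ChangeSummary] = []

    if fra_trip is not None:
        for cond, grid in fra_trip.conditions().items():
            fra_results[cond] = fra_mod.analyze_fra(
                grid,
                sd_multiplier=config.sd_multiplier,
                degree=config.poly_degree,
                use_fallback=use_fallback,
                fallback_criterion=config.fallback_criterion,
            )
        for measure, getter in (
            ("total_spikes", lambda r: r.total_spikes),
            ("area_bins", lambda r: r.area_bins),
            ("threshold", lambda r: r.threshold_spl if r.threshold_spl is not None
             else r.threshold),
        ):
            ctrl = float(getter(fra_results["control"]))
            deact = fra_results.get("deactivated")
            recov = fra_results.get("recovery")
            mi = cls = None
            if deact is not None and measure in ("total_spikes", "area_bins"):
                mi = st.modulation_index(ctrl, float(getter(deact)))
                cls = st.classify_change(ctrl, float(getter(deact)), config.change_criterion) \
                    if ctrl > 0 or getter(deact) > 0 else None
            changes.append(st.ChangeSummary(
                unit_id=unit_id, measure=measure, control=ctrl,
                deactivated=float(getter(deact)) if deact is not None else None,
                recovery=float(getter(recov)) if recov is not None else None,
                mi=mi, change_class=cls,
            ))

    if rlf_trip is not None:
        for cond, rlf in rlf_trip.conditions().items():
            rlf_results[cond] = rlf_mod.analyze_rlf(
                rlf,
                nonmono_fraction=config.nonmono_fraction,
                plateau_tol=config.plateau_tol,
                r2_straight=config.r2_straight,
                flat_floor=config.flat_floor,
            )
        for measure, getter in (
            ("half_max_level", lambda m: m.half_max_level),
            ("di", lambda m: _di_value(m, config)),
        ):
            ctrl = float(getter(rlf_results["control"]))
            deact = rlf_results.get("deactivated")
            recov = rlf_results.get("recovery")
            mi = cls = None
            if deact is not None and measure == "di":
                mi = st.modulation_index(ctrl, float(getter(deact)))
            changes.append(st.ChangeSummary(
                unit_id=unit_id, measure=measure, control=ctrl,
                deactivated=float(getter(deact)) if deact is not None else None,
                recovery=float(getter(recov)) if recov is not None else None,
                mi=mi, change_class=cls,
            ))

    return UnitResult(
        unit_id=unit_id, fra_class=fra_class,
        fra_results=fra_results, rlf_results=rlf_results, changes=changes,
    )


@dataclass
class PopulationReport:
    """Study-level tables and the nonparametric test battery."""

    unit_table: pd.DataFrame
    stat_results: dict  # name -> StatResult
    medians: dict  # measure -> {condition: (median, lo, hi)}
    transition_table: pd.DataFrame | None  # RLF type x {unchanged, changed}
    transition_table_2x2: pd.DataFrame | None
    config: AnalysisConfig

    def to_dict(self) -> dict:
        return {
            "config": dataclasses.asdict(self.config),
            "config_hash": self.config.hash(),
            "stat_results": {k: _jsonable(v) for k, v in self.stat_results.items()},
            "medians": _jsonable(self.medians),
            "transition_table": None if self.transition_table is None
            else self.transition_table.to_dict(),
        }


def _unit_rows(results: list[UnitResult], config: AnalysisConfig) -> pd.DataFrame:
    rows = []
    for res in results:
        row: dict = {"unit_id": res.unit_id, "fra_class": res.fra_class}
        for cond, r in res.fra_results.items():
            row[f"total_spikes_{cond}"] = r.total_spikes
            row[f"area_bins_{cond}"] = r.area_bins
            row[f"threshold_{cond}"] = (
                r.threshold_spl if r.threshold_spl is not None else r.threshold
            )
            row[f"cf_{cond}"] = r.cf
        for cond, m in res.rlf_results.items():
            row[f"half_max_{cond}"] = m.half_max_level
            row[f"di_{cond}"] = _di_value(m, config)
            row[f"rlf_type_{cond}"] = m.type_label
        for ch in res.changes:
            if ch.mi is not None:
                row[f"mi_{ch.measure}"] = ch.mi
            if ch.change_class is not None:
                row[f"change_{ch.measure}"] = ch.change_class
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_population(
    units: list[SyntheticUnit] | Population,
    config: AnalysisConfig = AnalysisConfig(),
) -> PopulationReport:
    """Assemble the population report over analyzed units."""
    if isinstance(units, Population):
        units = units.units
    if len(units) < 2:
        raise ValidationError("population analysis needs at least two units")
    results = [analyze_unit(u, config) for u in units]
    table = _unit_rows(results, config)
    stat_results: dict[str, st.StatResult] = {}
    medians: dict[str, dict] = {}
    rng = np.random.default_rng(config.seed)

    # --- KS: V vs nonV modulation-index distributions -----------------------
    for measure in ("total_spikes", "area_bins"):
        col = f"mi_{measure}"
        if col not in table or "fra_class" not in table:
            continue
        sub = table.dropna(subset=[col])
        v = sub.loc[sub.fra_class == "V", col].to_numpy()
        nonv = sub.loc[sub.fra_class == "nonV", col].to_numpy()
        if v.size and nonv.size:
            stat_results[f"ks_mi_{measure}"] = st.ks_two_sample(
                v, nonv, alpha=config.alpha
            )

    # --- RLF type transitions + Fisher r x 2 --------------------------------
    transition = transition_2x2 = None
    if {"rlf_type_control", "rlf_type_deactivated"}.issubset(table.columns):
        sub = table.dropna(subset=["rlf_type_control", "rlf_type_deactivated"])
        if len(sub):
            changed = (sub.rlf_type_control != sub.rlf_type_deactivated)
            transition = (
                pd.crosstab(sub.rlf_type_control, changed.map({False: "unchanged", True: "changed"}))
                .reindex(columns=["unchanged", "changed"], fill_value=0)
            )
            nonmono = sub.rlf_type_control == "non-monotonic"
            transition_2x2 = pd.crosstab(
                nonmono.map({True: "non-monotonic", False: "other"}),
                changed.map({False: "unchanged", True: "changed"}),
            ).reindex(columns=["unchanged", "changed"], fill_value=0)
            if transition.shape[0] >= 2:
                stat_results["fisher_rlf_transitions"] = st.fisher_exact_rx2(
                    transition.to_numpy(), alpha=config.alpha
                )

    # --- half-max and DI: medians/CIs, Friedman, Sidak Wilcoxon post hocs ---
    posthoc_alpha = config.posthoc_alpha
    for measure, prefix in (("half_max_level", "half_max"), ("di", "di")):
        cols = [f"{prefix}_{c}" for c in CONDITIONS]
        if not set(cols[:2]).issubset(table.columns):
            continue
        have_all = table.dropna(subset=[c for c in cols if c in table.columns])
        med: dict[str, tuple] = {}
        for cond in CONDITIONS:
            col = f"{prefix}_{cond}"
            if col in table:
                vals = table[col].dropna().to_numpy()
                if vals.size >= 2:
                    if config.bootstrap_n > 0:
                        med[cond] = st.bootstrap_median_ci(
                            vals, n_boot=config.bootstrap_n, seed=rng
                        )
                    else:
                        m = float(np.median(vals))
                        med[cond] = (m, float("nan"), float("nan"))
        medians[measure] = med
        if set(cols).issubset(table.columns):
            mat = have_all[cols].to_numpy(dtype=float)
            if mat.shape[0] >= 3:
                stat_results[f"friedman_{measure}"] = st.friedman_test(
                    mat, alpha=config.alpha
                )
                for other, tag in (("deactivated", "deact"), ("recovery", "recov")):
                    try:
                        stat_results[f"wilcoxon_{measure}_control_vs_{tag}"] = (
                            st.wilcoxon_signed_rank(
                                have_all[f"{prefix}_{other}"].to_numpy(dtype=float),
                                have_all[f"{prefix}_control"].to_numpy(dtype=float),
                                alpha=posthoc_alpha,
                            )
                        )
                    except ValidationError as err:
                        log.warning("wilcoxon %s control-vs-%s skipped: %s",
                                    measure, tag, err)
            else:
                log.warning("friedman on %s skipped: fewer than 3 complete units", measure)

    # --- Spearman: half-max change vs threshold change ----------------------
    need = {"half_max_control", "half_max_deactivated",
            "threshold_control", "threshold_deactivated"}
    if need.issubset(table.columns):
        sub = table.dropna(subset=sorted(need))
        if len(sub) >= 3:
            d_half = (sub.half_max_deactivated - sub.half_max_control).to_numpy()
            d_thr = (sub.threshold_deactivated - sub.threshold_control).to_numpy()
            stat_results["spearman_halfmax_vs_threshold"] = st.spearman_correlation(
                d_half, d_thr, alpha=config.alpha
            )

    return PopulationReport(
        unit_table=table,
        stat_results=stat_results,
        medians=medians,
        transition_table=transition,
        transition_table_2x2=transition_2x2,
        config=config,
    )


def run_repro(
    outdir: str | Path = "repro_out",
    population_config: PopulationConfig | None = None,
    analysis_config: AnalysisConfig | None = None,
    *,
    figures: bool = False,
) -> PopulationReport:
    """One-command demonstration on the default synthetic population.

    Generates the seeded population, runs the full analysis, and writes
    deterministic TSV tables plus a JSON report and provenance block under
    ``outdir``.  Figures (MI CDFs, RLF overlays, DI distributions) are
    optional artifacts; the tables are the authoritative output.
    """
    pop_cfg = population_config or PopulationConfig()
    ana_cfg = analysis_config or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    population = make_population(pop_cfg)
    report = analyze_population(population, ana_cfg)

    provenance = {
        "population_config": dataclasses.asdict(pop_cfg),
        "analysis_config": dataclasses.asdict(ana_cfg),
        "config_hash": _config_hash(pop_cfg, ana_cfg),
        "seed": pop_cfg.seed,
    }
    report.unit_table.to_csv(outdir / "unit_table.tsv", sep="\t", index=False)
    if report.transition_table is not None:
        report.transition_table.to_csv(outdir / "rlf_transitions.tsv", sep="\t")
        report.transition_table_2x2.to_csv(outdir / "rlf_transitions_2x2.tsv", sep="\t")
    payload = report.to_dict()
    payload["provenance"] = _jsonable(provenance)
    (outdir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    write_results(
        list(report.stat_results.values()), outdir / "stat_results.tsv",
        provenance=provenance,
    )
    if figures:
        _write_figures(report, outdir)
    return report


def _config_hash(pop_cfg: PopulationConfig, ana_cfg: AnalysisConfig) -> str:
    payload = json.dumps(
        {"population": dataclasses.asdict(pop_cfg), "analysis": dataclasses.asdict(ana_cfg)},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_figures(report: PopulationReport, outdir: Path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # pragma: no cover - plotting is optional
        log.warning("matplotlib unavailable: skipping figures")
        return
    t = report.unit_table
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for col, ax, title in (
        ("mi_total_spikes", axes[0], "MI: FRA spikes"),
        ("mi_area_bins", axes[1], "MI: FRA area"),
    ):
        if col in t:
            for cls, sub in t.dropna(subset=[col]).groupby("fra_class"):
                vals = np.sort(sub[col].to_numpy())
                ax.step(vals, np.linspace(0, 1, vals.size), label=cls)
            ax.set_xlabel("modulation index")
            ax.set_ylabel("cumulative fraction")
            ax.set_title(title)
            ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "mi_cdfs.png", dpi=120)
    plt.close(fig)
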