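"""End-to-end orchestration: simulate/ingest -> metrics -> spectra ->
pressure -> statistics, with deterministic outputs and a run manifest.

``run_all`` writes long-format metric CSVs, statistical reports, optional
figures, and ``run_manifest.json`` (package version, config hash, seed).
``make_report`` assembles a Markdown summary from a completed output
directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import SEXES, GENOTYPES, recordings_for_phase
from .architecture import (
    bout_statistics,
    hourly_time_in_state,
    nrem_latency_after_sd,
    sd_efficiency,
    time_in_state,
)
from .io import load_cohort, write_cohort, write_metric_table
from .simulate import SimulationConfig, iter_cohort, shank3_like_effects
from .spectral import (
    group_spectrum_ci,
    normalized_sleep_pressure,
    relative_spectra,
    spectral_difference_bins,
)
from .stats import (
    ALPHA,
    StatReport,
    posthoc_gate,
    posthoc_pressure,
    posthoc_ttests,
    rm_anova,
)

log = logging.getLogger("somnarch")

PHASES = ("baseline", "recovery")
PERIODS = ("light", "dark")


@dataclass
class RunConfig:
    """One pipeline run: exactly one input source plus analysis toggles."""

    out_dir: str = "somnarch_out"
    manifest: str | None = None
    simulation: SimulationConfig | None = None
    baseline: bool = True
    recovery: bool = True
    spectra: bool = True
    pressure: bool = True
    bouts: bool = True
    latency: bool = True
    figures: bool = False
    alpha: float = ALPHA
    seed: int | None = None

    def __post_init__(self):
        if (self.manifest is None) == (self.simulation is None):
            raise ValueError("exactly one of manifest or simulation must be given")
        if self.simulation is not None and self.seed is not None:
            object.__setattr__(self, "simulation",
                               SimulationConfig(**{**_cfg_dict(self.simulation),
                                                   "seed": self.seed}))


def _cfg_dict(cfg: SimulationConfig) -> dict:
    d = {f: getattr(cfg, f) for f in cfg.__dataclass_fields__}
    d.pop("protocol")
    return d


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:16]


def _meta_frame(records):
    return pd.DataFrame(
        [(r.animal_id, r.meta.sex, r.meta.genotype, r.meta.excluded) for r in records],
        columns=["animal_id", "sex", "genotype", "excluded"],
    )


def _iter_input(config: RunConfig):
    """Yield recordings one at a time (streaming keeps spectra memory flat)."""
    if config.manifest is not None:
        for rec in load_cohort(config.manifest):
            yield rec
    else:
        need_spectra = config.spectra or config.pressure
        for rec, _ in iter_cohort(config.simulation, with_spectra=need_spectra):
            yield rec


def run_all(config: RunConfig) -> dict:
    """Run every enabled stage; returns the result tables by name.

    Deterministic under a fixed seed; any stage failure aborts with the
    stage named in the raised exception.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, pd.DataFrame] = {}

    stage = "ingest"
    try:
        tis_rows, hourly_rows, bout_rows, lat_rows, sdeff_rows = [], [], [], [], []
        spectra_rows, pressure_rows = [], []
        metas = []
        phases = [p for p, on in zip(PHASES, (config.baseline, config.recovery)) if on]
        for rec in _iter_input(config):
            metas.append(rec)
            rec_phases = [
                p for p in phases
                if not (p == "recovery" and rec.meta.excluded == "recovery")
            ]
            stage = "metrics"
            for phase in rec_phases:
                for period in PERIODS:
                    tis_rows.append(time_in_state(rec, phase, period))
                    if config.bouts:
                        bout_rows.append(bout_statistics(rec, phase, period))
            hourly_rows.append(hourly_time_in_state(rec))
            sdeff_rows.append((rec.animal_id, sd_efficiency(rec)))
            if config.latency and "recovery" in rec_phases:
                lat_rows.append((rec.animal_id, nrem_latency_after_sd(rec)))
            if rec.spectra is not None:
                stage = "spectra"
                if config.spectra:
                    for phase in rec_phases:
                        spectra_rows.append(relative_spectra(rec, phase))
                if config.pressure and "recovery" in rec_phases:
                    pressure_rows.append(normalized_sleep_pressure(rec))

        meta_df = _meta_frame(metas)
        results["animals"] = meta_df
        results["time_in_state"] = pd.concat(tis_rows, ignore_index=True).merge(meta_df)
        results["hourly"] = pd.concat(hourly_rows, ignore_index=True).merge(meta_df)
        results["sd_efficiency"] = pd.DataFrame(
            sdeff_rows, columns=["animal_id", "sd_efficiency_pct"]
        ).merge(meta_df)
        if config.bouts:
            results["bouts"] = pd.concat(bout_rows, ignore_index=True).merge(meta_df)
        if config.latency and lat_rows:
            results["latency"] = pd.DataFrame(
                lat_rows, columns=["animal_id", "latency_min"]
            ).merge(meta_df)
        if spectra_rows:
            results["spectra"] = pd.concat(spectra_rows, ignore_index=True).merge(meta_df)
        if pressure_rows:
            results["pressure"] = pd.concat(pressure_rows, ignore_index=True).merge(meta_df)

        stage = "stats"
        results["stats"] = _run_stats(results, config)
        if "spectra" in results:
            results["spectral_differences"] = _spectral_differences(results["spectra"])
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for name, df in results.items():
        write_metric_table(df, out / f"{name}.csv")
    manifest = {
        "somnarch_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed if config.seed is not None
        else (config.simulation.seed if config.simulation else None),
        "n_animals": len(results["animals"]),
        "tables": sorted(results),
        "alpha": config.alpha,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    if config.figures:
        _make_figures(results, out)
    return results


def _run_stats(results: dict, config: RunConfig) -> pd.DataFrame:
    """Mixed-design ANOVA + gated BH-corrected post hocs per measure."""
    reports = []
    hourly = results["hourly"]
    for phase in PHASES:
        if phase not in hourly_phase_map(config):
            continue
        lo, hi = hourly_phase_map(config)[phase]
        for state in ("WAKE", "NREM", "REM"):
            sub = hourly[(hourly["state"] == state)
                         & (hourly["hour"] >= lo) & (hourly["hour"] < hi)]
            if phase == "recovery":
                sub = sub[sub["excluded"] != "recovery"]
            if sub.empty:
                continue
            dv_name = f"{phase}_{state.lower()}_hourly_pct"
            res = rm_anova(sub, dv="pct_trt")
            comparisons = posthoc_gate(res, config.alpha)
            ph = None
            if comparisons:
                scalar = (
                    sub.groupby(["animal_id", "sex", "genotype"])["pct_trt"]
                    .mean()
                    .reset_index(name="value")
                )
                ph = posthoc_ttests(scalar, comparisons)
            reports.append(StatReport(dv_name, res.table, ph))

    if "latency" in results:
        lat = results["latency"].dropna(subset=["latency_min"])
        scalar = lat.rename(columns={"latency_min": "value"})
        # scalar dv: groups compared directly with the gated t-tests
        from .stats import POSTHOC_COMPARISONS

        ph = posthoc_ttests(scalar, POSTHOC_COMPARISONS)
        reports.append(StatReport("nrem_latency_min", pd.DataFrame(), ph))

    if "pressure" in results:
        pres = results["pressure"].dropna(subset=["norm_delta"])
        res = rm_anova(pres, dv="norm_delta")
        comparisons = posthoc_gate(res, config.alpha)
        ph = posthoc_pressure(pres, comparisons) if comparisons else None
        reports.append(StatReport("sleep_pressure", res.table, ph))

    frames = [r.to_frame() for r in reports]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def hourly_phase_map(config: RunConfig) -> dict:
    proto = (config.simulation.protocol if config.simulation is not None
             else None)
    sd_end = int(proto.sd[1]) if proto is not None else 29
    out = {}
    if config.baseline:
        out["baseline"] = (0, 24)
    if config.recovery:
        out["recovery"] = (sd_end, 48)
    return out


def _spectral_differences(spectra: pd.DataFrame) -> pd.DataFrame:
    """WT-vs-MUT CI-overlap flags per sex, phase, state, and bin."""
    rows = []
    for (phase, state, sex), sub in spectra.groupby(["phase", "state", "sex"]):
        cis = {}
        freqs = None
        for genotype in GENOTYPES:
            g = sub[sub["genotype"] == genotype]
            pivot = g.pivot(index="animal_id", columns="freq_hz", values="rel_power")
            if len(pivot) < 2:
                break
            freqs = pivot.columns.to_numpy(float)
            cis[genotype] = group_spectrum_ci(list(pivot.to_numpy()))
        if len(cis) < 2:
            continue
        flags = spectral_difference_bins(cis["WT"], cis["MUT"])
        rows.append(
            pd.DataFrame(
                {
                    "phase": phase,
                    "state": state,
                    "sex": sex,
                    "freq_hz": freqs,
                    "different": flags.astype(int),
                }
            )
        )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["phase", "state", "sex", "freq_hz", "different"]
    )


def _make_figures(results: dict, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    from .plotting import plot_pressure, plot_time_in_state

    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)
    tis = results.get("time_in_state")
    if tis is not None:
        for phase in tis["phase"].unique():
            for state in ("WAKE", "NREM", "REM"):
                ax = plot_time_in_state(tis, state, phase)
                ax.figure.savefig(figdir / f"time_in_state_{phase}_{state}.png", dpi=120)
                plt.close(ax.figure)
    if "pressure" in results:
        ax = plot_pressure(results["pressure"])
        ax.figure.savefig(figdir / "pressure.png", dpi=120)
        plt.close(ax.figure)


def make_report(out_dir) -> Path:
    """Assemble a Markdown report from a completed run directory."""
    out = Path(out_dir)
    manifest_path = out / "run_manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no run manifest in {out}; run the pipeline first")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    missing = [t for t in manifest["tables"] if not (out / f"{t}.csv").exists()]
    if missing:
        raise FileNotFoundError(f"missing result tables: {missing}")

    lines = [
        "# somnarch run report",
        "",
        f"- package version: {manifest['somnarch_version']}",
        f"- seed: {manifest['seed']}; config hash: {manifest['config_hash']}",
        f"- animals: {manifest['n_animals']}; alpha: {manifest['alpha']}",
        "",
    ]
    tis_path = out / "time_in_state.csv"
    if tis_path.exists():
        tis = pd.read_csv(tis_path)
        lines.append("## Time in state (% TRT, group mean +/- SEM)")
        lines.append("")
        agg = (
            tis.groupby(["phase", "period", "state", "sex", "genotype"])["pct_trt"]
            .agg(["mean", "sem", "count"])
            .reset_index()
        )
        lines.append("| phase | period | state | group | mean +/- SEM (n) |")
        lines.append("|---|---|---|---|---|")
        for _, r in agg.iterrows():
            lines.append(
                f"| {r['phase']} | {r['period']} | {r['state']} | "
                f"{r['sex']}/{r['genotype']} | "
                f"{r['mean']:.1f} +/- {r['sem']:.1f} (n={int(r['count'])}) |"
            )
        lines.append("")
    sd_path = out / "sd_efficiency.csv"
    if sd_path.exists():
        sd = pd.read_csv(sd_path)
        lines.append("## Sleep-deprivation efficiency (% wake during SD)")
        lines.append("")
        for (sex, genotype), g in sd.groupby(["sex", "genotype"]):
            lines.append(
                f"- {sex}/{genotype}: {g['sd_efficiency_pct'].mean():.1f}% "
                f"+/- {g['sd_efficiency_pct'].sem():.1f}%"
            )
        lines.append("")
    lat_path = out / "latency.csv"
    if lat_path.exists():
        lat = pd.read_csv(lat_path).dropna(subset=["latency_min"])
        lines.append("## NREM sleep-onset latency after SD (min)")
        lines.append("")
        for (sex, genotype), g in lat.groupby(["sex", "genotype"]):
            lines.append(
                f"- {sex}/{genotype}: {g['latency_min'].mean():.1f} "
                f"+/- {g['latency_min'].sem():.1f} min"
            )
        lines.append("")
    stats_path = out / "stats.csv"
    if stats_path.exists():
        st = pd.read_csv(stats_path)
        sig = st[(st.get("kind") == "anova") & (st["p"] < manifest["alpha"])]
        lines.append(f"## Significant ANOVA terms (p < {manifest['alpha']})")
        lines.append("")
        if sig.empty:
            lines.append("(none)")
        for _, r in sig.iterrows():
            lines.append(
                f"- {r['dv']} / {r['term']}: F({r['df_num']:g}, {r['df_den']:g}) "
                f"= {r['F']:.3f}, p = {r['p']:.4g}"
            )
        lines.append("")
    report = out / "report.md"
    report.write_text("\n".join(lines))
    return report


def default_simulated_run(out_dir, seed: int = 0, figures: bool = False) -> RunConfig:
    """The package's demonstration configuration: a mutant-phenotype cohort."""
    sim = SimulationConfig(seed=seed, effects=shank3_like_effects())
    return RunConfig(out_dir=str(out_dir), simulation=sim, figures=figures, seed=seed)


__all__ = [
    "RunConfig",
    "run_all",
    "make_report",
    "default_simulated_run",
]
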