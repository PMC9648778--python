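"""End-to-end orchestration: phantom cohorts -> measurements -> report.

``run_pipeline`` generates per-phase cohorts, measures central-zone
statistics, segments plaque under both threshold schemes, computes the
analytic error model, and writes four artifacts to the output directory:

* ``cohort_stats.csv``   — measured per-(scan, vertebra) attenuation table
* ``plaque_cdf.csv``     — the calibrated plaque HU law on a grid
* ``error_curves.csv``   — FP/FN vs uniform T and dynamic N per phase
* ``report.json``        — headline quantities, raw and rounded, plus the
                           phantom pixel-count cross-check

Everything flows from the single config seed; re-running with the same
config is byte-identical.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
from scipy.stats import norm

from . import central_zone as cz
from .cohort_stats import generate_contrast_pairs, plaque_contrast_regression, simple_regression, welch_ttest
from .error_model import (
    PopulationModel,
    error_curves,
    fn_rate,
    fp_rate_population,
    min_threshold_for_fp,
)
from .phantom import DemographicsSpec, PhantomParams, make_cohort
from .threshold import ThresholdScheme, segment_plaque

log = logging.getLogger("aohu.workbench")

__all__ = ["RunConfig", "run_pipeline", "export_figures", "round_to"]


def round_to(value: float, base: float) -> float:
    """Round to the nearest multiple of ``base`` (5 points, 50 HU, ...)."""
    return float(base * round(value / base))


@dataclass(frozen=True)
class RunConfig:
    params: PhantomParams = field(default_factory=PhantomParams)
    n_scans_per_phase: dict = field(
        default_factory=lambda: {"arterial": 60, "venous": 30, "delayed": 30}
    )
    uniform_grid: tuple = tuple(range(130, 601, 10))
    dynamic_grid: tuple = tuple(np.arange(0.5, 5.01, 0.25).round(2))
    sigma_bar: float = 30.0
    fraction: float = 0.5
    out_dir: str = "aohu_run"
    seed: int = 1
    fp_round_base: float = 5.0  # percentage points
    hu_round_base: float = 50.0

    def __post_init__(self) -> None:
        if not self.uniform_grid or not len(self.dynamic_grid):
            raise ValueError("threshold grids must be non-empty")


def _phase_population(config: RunConfig, phase: str) -> PopulationModel:
    p = config.params
    return PopulationModel(
        M=p.phase_mean_HU[phase], S=p.phase_popSD_HU[phase], sigma_bar=config.sigma_bar, phase=phase
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the JSON report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed, 7])
    params = replace(config.params, rng_seed=config.seed)
    plaque = params.plaque_law

    report: dict = {
        "seed": config.seed,
        "sigma_bar_HU": config.sigma_bar,
        "n_scans_per_phase": dict(config.n_scans_per_phase),
    }

    # --- stage 1: phantom cohorts, one per phase, 50/50 sex split -------
    try:
        scans_by_phase, tables = {}, []
        for i, (phase, n) in enumerate(sorted(config.n_scans_per_phase.items())):
            demo = DemographicsSpec(phase_mix={phase: 1.0}, cohort_tag=f"SYN-{phase[:3].upper()}")
            scans, _ = make_cohort(params, n, demo, seed=(config.seed * 13 + i) % (2**31))
            scans_by_phase[phase] = scans
            log.info("phase=%s n_scans=%d seed=%d", phase, n, params.rng_seed)
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"[phantom] cohort generation failed: {exc}") from exc

    # --- stage 2: central-zone measurement ------------------------------
    try:
        stats_by_phase = {}
        for phase, scans in scans_by_phase.items():
            stats_by_scan = {s.meta.scan_id: cz.scan_zone_stats(s, config.fraction) for s in scans}
            metas = {s.meta.scan_id: s.meta for s in scans}
            tbl = cz.stats_table(stats_by_scan, metas)
            tbl.insert(0, "contrast phase", phase)
            tables.append(tbl)
            stats_by_phase[phase] = stats_by_scan
        import pandas as pd

        cohort_table = pd.concat(tables, ignore_index=True)
        cohort_table.to_csv(out / "cohort_stats.csv", index=False)
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"[central_zone] measurement failed: {exc}") from exc

    # --- stage 3: analytic error model ----------------------------------
    pops = {ph: _phase_population(config, ph) for ph in config.n_scans_per_phase}
    curves = error_curves(
        plaque, pops, config.uniform_grid, config.dynamic_grid, n_mc=50_000, rng=rng
    )
    curves.to_csv(out / "error_curves.csv", index=False)

    art = pops.get("arterial") or next(iter(pops.values()))
    fp3sd = float(norm.sf(3.0))
    headline = {
        "dynamic_fp_3sd_raw": fp3sd,
        "dynamic_fp_3sd_pct": round(100 * fp3sd, 2),
        "fn_at_250_raw": float(fn_rate(plaque, 250.0)),
        "fn_at_250_pct_rounded": round_to(100 * float(fn_rate(plaque, 250.0)), config.fp_round_base),
        "min_uniform_T_for_0p00135_raw": min_threshold_for_fp(art, fp3sd),
        "min_uniform_T_for_0p00135_rounded": round_to(
            min_threshold_for_fp(art, fp3sd), config.hu_round_base
        ),
    }
    for T in (200, 300, 400):
        raw = fp_rate_population(art, T)
        headline[f"uniform_fp_{T}_arterial_raw"] = raw
        headline[f"uniform_fp_{T}_arterial_pct_rounded"] = round_to(100 * raw, config.fp_round_base)
    report["headline"] = headline

    # --- stage 4: cohort statistics on measured scan means --------------
    try:
        phase0 = "arterial" if "arterial" in stats_by_phase else next(iter(stats_by_phase))
        scans0 = scans_by_phase[phase0]
        means = {sid: float(np.mean([st.mean_AoHU for st in sts]))
                 for sid, sts in stats_by_phase[phase0].items()}
        f_means = [means[s.meta.scan_id] for s in scans0 if s.meta.sex == "F"]
        m_means = [means[s.meta.scan_id] for s in scans0 if s.meta.sex == "M"]
        if len(f_means) >= 2 and len(m_means) >= 2:
            tt = welch_ttest(f_means, m_means)
            report["sex_difference"] = {
                "phase": phase0,
                "mean_difference_HU": tt.mean_difference,
                "p_value": tt.p_value,
                "n_F": tt.n_a,
                "n_M": tt.n_b,
            }
        weights = [s.meta.weight for s in scans0]
        reg = simple_regression(weights, [means[s.meta.scan_id] for s in scans0],
                                unit_scale=10.0, unit="HU per 10 kg")
        report["weight_slope"] = {"phase": phase0, "slope_HU_per_10kg": reg.slope,
                                  "adj_r2": reg.adj_r2, "n": reg.n}
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"[cohort_stats] failed: {exc}") from exc

    # --- stage 5: phantom pixel-count cross-check -----------------------
    try:
        report["phantom_check"] = _pixel_count_check(
            scans_by_phase, within_sd=params.within_scan_SD_HU
        )
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"[threshold_score] pixel counting failed: {exc}") from exc

    # --- plaque CDF table ------------------------------------------------
    grid = np.arange(130.0, plaque.p99_HU + 1, 10.0)
    import pandas as pd

    pd.DataFrame({"HU": grid, "cdf": plaque.cdf(grid)}).to_csv(out / "plaque_cdf.csv", index=False)

    report_json = json.dumps(report, indent=2, sort_keys=True)
    (out / "report.json").write_text(report_json)
    return report


def _pixel_count_check(scans_by_phase: dict, within_sd: float, N: float = 3.0) -> dict:
    """Measured dynamic-threshold FP on plaque-free pixels vs 1 - Phi(N).

    Counts blood-pool pixels at or above each slice's generative
    mean + N.SD cutoff; generative truth is used so that neither plaque
    contamination nor threshold-estimation noise enters the comparison.
    Lesion-bearing slices are excluded entirely: PSF blur spreads plaque
    intensity into a rim just outside the truth mask, and those
    partial-volume pixels are genuine threshold crossings, not
    blood-pool noise.
    """
    above = total = 0
    for scans in scans_by_phase.values():
        for scan in scans:
            for k in range(scan.image.shape[0]):
                if scan.plaque_truth_mask[k].any():
                    continue
                thr = scan.slice_mean_HU[k] + N * within_sd
                sl = scan.aorta_mask[k]
                above += int((scan.image[k][sl] >= thr).sum())
                total += int(sl.sum())
    measured = above / total if total else float("nan")
    return {
        "dynamic_N": N,
        "measured_fp": measured,
        "predicted_fp": float(norm.sf(N)),
        "n_pixels": total,
    }


def export_figures(report_or_dir, out_dir: str | None = None) -> list[Path]:
    """Render the four summary figures; failures never corrupt numerics."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    run_dir = Path(out_dir or report_or_dir if isinstance(report_or_dir, (str, Path)) else out_dir)
    made: list[Path] = []
    try:
        curves = pd.read_csv(run_dir / "error_curves.csv")
        cdf = pd.read_csv(run_dir / "plaque_cdf.csv")
        table = pd.read_csv(run_dir / "cohort_stats.csv")
    except Exception as exc:
        warnings.warn(f"missing pipeline outputs, no figures rendered: {exc}", stacklevel=2)
        return made

    mean_col = "aortic attenuation mean"
    sd_col = "aortic attenuation standard deviation"

    fig, ax = plt.subplots()
    for phase, grp in table.groupby("contrast phase"):
        ax.hist(grp[mean_col], bins=30, alpha=0.5, label=phase)
    ax.set_xlabel("mean AoHU (HU)"), ax.set_ylabel("vertebra observations"), ax.legend()
    made.append(_save(fig, run_dir / "fig_aohu_distributions.png"))

    fig, ax = plt.subplots()
    for phase, grp in table.groupby("contrast phase"):
        ax.hist(grp[sd_col], bins=30, alpha=0.5, label=phase)
    ax.set_xlabel("SD AoHU (HU)"), ax.set_ylabel("vertebra observations"), ax.legend()
    made.append(_save(fig, run_dir / "fig_aohu_sd_distributions.png"))

    fig, ax = plt.subplots()
    ax.plot(cdf["HU"], cdf["cdf"])
    ax.set_xlim(left=130.0)  # distribution starts at the detection threshold
    ax.set_xlabel("plaque pixel HU"), ax.set_ylabel("cumulative fraction")
    made.append(_save(fig, run_dir / "fig_plaque_cdf.png"))

    if len(curves):
        fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharey="row")
        for j, scheme in enumerate(("uniform", "dynamic")):
            sub = curves[curves["scheme"] == scheme]
            for phase, grp in sub.groupby("phase"):
                axes[0, j].plot(grp["threshold_or_N"], grp["fn"], label=phase)
                axes[1, j].plot(grp["threshold_or_N"], grp["fp"], label=phase)
            axes[0, j].set_title(f"{scheme} scheme")
            axes[1, j].set_xlabel("threshold (HU)" if scheme == "uniform" else "N (SD)")
        axes[0, 0].set_ylabel("false-negative rate"), axes[1, 0].set_ylabel("false-positive rate")
        axes[0, 0].legend()
        made.append(_save(fig, run_dir / "fig_error_curves.png"))
    else:
        warnings.warn("error-curve table empty; curve figure skipped", stacklevel=2)
    return made


def _save(fig, path: Path) -> Path:
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    import matplotlib.pyplot as plt

    plt.close(fig)
    return path
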