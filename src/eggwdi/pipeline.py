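"""End-to-end orchestration: simulate/load -> BLQ policy -> NCA -> augment
-> WDI, with machine-readable outputs and a human-readable report.

A single global seed fans out to per-stage child seeds (seed + stage index)
so stages re-run in isolation reproduce the pipeline's numbers. All output
tables carry units in their headers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .augment import (
    DEFAULT_MIN_N,
    DEFAULT_TARGET_N,
    AugmentedTimepoint,
    TimepointSummary,
    augment as augment_op,
    elimination_phase,
    summarize_timepoints,
)
from . import nca as nca_mod
from .data import (
    BlqPolicy,
    FlockDataset,
    Matrix,
    build_series,
    read_flock,
    summarize_laying,
    write_flock,
)
from .simulate import FlockSimConfig, simulate_flock
from .wdi import (
    LimitBasis,
    ResidueLimit,
    WdiEstimate,
    WdiMethod,
    wdi_ema,
    wdi_fda,
    wdi_hlm,
)

logger = logging.getLogger("eggwdi")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

# stage indices for the seed fan-out
_STAGE_SIMULATE = 0
_STAGE_AUGMENT = 1


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one reproduction run needs.

    Exactly one of ``input_path`` (a flock CSV) or ``sim_config`` drives the
    data stage. ``methods`` lists the WDI estimators to run; the regulatory
    methods are evaluated once per entry in ``limit_bases``.
    """

    seed: int = 42
    input_path: str | None = None
    sim_config: FlockSimConfig | None = None
    matrix: Matrix = Matrix.YOLK
    blq_policy: BlqPolicy = BlqPolicy.EXCLUDE_BELOW_LOD
    min_n: int = DEFAULT_MIN_N
    target_n: int = DEFAULT_TARGET_N
    methods: tuple[WdiMethod, ...] = (
        WdiMethod.HLM,
        WdiMethod.FDA_TOLERANCE,
        WdiMethod.EMA_MRL,
    )
    limit_bases: tuple[LimitBasis, ...] = (
        LimitBasis.LOD,
        LimitBasis.TWO_TIMES_LLOQ,
    )
    explicit_limit: float | None = None
    out_dir: str | None = None
    figures: bool = True

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("at least one WDI method must be requested")


@dataclass(frozen=True)
class PipelineResult:
    """All stage outputs of one run."""

    flock: FlockDataset
    laying: object
    nca_results: tuple[nca_mod.NcaResult, ...]
    nca_summary: nca_mod.FlockNcaSummary
    timepoints: tuple[TimepointSummary, ...]
    augmented: tuple[AugmentedTimepoint, ...]
    wdi_estimates: tuple[WdiEstimate, ...]
    seed: int


def _resolve_limit(basis: LimitBasis, flock: FlockDataset, matrix: Matrix,
                   explicit: float | None) -> ResidueLimit:
    limits = flock.limits[matrix]
    if basis is LimitBasis.LOD:
        return ResidueLimit.from_lod(limits.lod)
    if basis is LimitBasis.TWO_TIMES_LLOQ:
        return ResidueLimit.from_lloq(limits.lloq)
    if explicit is None:
        raise ValueError("explicit_mrl basis requires explicit_limit")
    return ResidueLimit(explicit, LimitBasis.EXPLICIT_MRL)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages in order; deterministic given config and seed."""
    # --- data stage ------------------------------------------------------
    if (config.input_path is None) == (config.sim_config is None):
        raise ValueError("provide exactly one of input_path or sim_config")
    if config.sim_config is not None:
        sim_cfg = dataclasses.replace(
            config.sim_config, seed=config.seed + _STAGE_SIMULATE
        )
        flock, _truth = simulate_flock(sim_cfg)
        logger.info("simulated flock: %d observations", len(flock.observations))
    else:
        flock = read_flock(config.input_path)
        logger.info("loaded flock: %d observations", len(flock.observations))

    laying = summarize_laying(flock)

    # --- NCA stage -------------------------------------------------------
    from .data import apply_blq_policy

    filtered = apply_blq_policy(flock, config.blq_policy)
    results = []
    for hen in filtered.hen_ids:
        series = build_series(filtered, hen, config.matrix).after(0.0)
        if len(series) < 4:
            logger.warning("hen %s: too few points for NCA, skipped", hen)
            continue
        try:
            results.append(nca_mod.run_nca(series))
        except nca_mod.NcaError as exc:
            logger.warning("hen %s: NCA failed (%s)", hen, exc)
    if not results:
        raise RuntimeError("NCA stage produced no results")
    summary = nca_mod.summarize_flock(results)

    # --- augmentation stage ----------------------------------------------
    timepoints = summarize_timepoints(filtered, config.matrix, config.min_n)
    elim = elimination_phase(timepoints)
    lod = flock.limits[config.matrix].lod
    augmented = augment_op(
        elim, config.target_n, lod, seed=config.seed + _STAGE_AUGMENT
    )

    # --- WDI stage --------------------------------------------------------
    estimates: list[WdiEstimate] = []
    for method in config.methods:
        if method is WdiMethod.HLM:
            estimates.append(wdi_hlm(summary.geometric_means["t_half"]))
            continue
        for basis in config.limit_bases:
            limit = _resolve_limit(basis, flock, config.matrix,
                                   config.explicit_limit)
            if method is WdiMethod.FDA_TOLERANCE:
                estimates.append(wdi_fda(augmented, limit))
            else:
                estimates.append(wdi_ema(augmented, limit))

    result = PipelineResult(
        flock=flock,
        laying=laying,
        nca_results=tuple(results),
        nca_summary=summary,
        timepoints=tuple(timepoints),
        augmented=tuple(augmented),
        wdi_estimates=tuple(estimates),
        seed=config.seed,
    )
    if config.out_dir is not None:
        _write_outputs(result, config)
    return result


def nca_table(result: PipelineResult) -> pd.DataFrame:
    """Per-hen NCA rows plus a geometric-mean summary row (hour units)."""
    rows = [
        {
            "hen_id": r.hen_id,
            "cmax_obs_ng_per_g": r.cmax_obs,
            "tmax_obs_h": r.tmax_obs,
            "lambda_z_per_h": r.lambda_z,
            "t_half_h": r.t_half,
            "auc_inf_h_ng_per_g": r.auc_inf,
            "pct_extrapolated": r.pct_extrapolated,
        }
        for r in result.nca_results
    ]
    gm = result.nca_summary.geometric_means
    rows.append(
        {
            "hen_id": "geometric_mean",
            "cmax_obs_ng_per_g": gm.get("cmax_obs"),
            "tmax_obs_h": gm.get("tmax_obs"),
            "lambda_z_per_h": gm.get("lambda_z"),
            "t_half_h": gm.get("t_half"),
            "auc_inf_h_ng_per_g": gm.get("auc_inf"),
            "pct_extrapolated": gm.get("pct_extrapolated"),
        }
    )
    return pd.DataFrame(rows)


def augmented_table(result: PipelineResult) -> pd.DataFrame:
    """Long-format augmented data: time, value, source."""
    rows = []
    for tp in result.augmented:
        for v in tp.observed:
            rows.append({"time_days_since_final_dose": tp.time,
                         "concentration_ng_per_g": v, "source": "observed"})
        for v in tp.simulated:
            rows.append({"time_days_since_final_dose": tp.time,
                         "concentration_ng_per_g": v, "source": "simulated"})
    return pd.DataFrame(rows)


def wdi_records(result: PipelineResult) -> list[dict]:
    recs = []
    for est in result.wdi_estimates:
        recs.append(
            {
                "method": est.method.value,
                "limit_ng_per_g": est.limit.value if est.limit else None,
                "limit_basis": est.limit.basis.value if est.limit else None,
                "raw_wdi_days": round(est.raw_wdi, 2),
                "rounded_wdi_days": est.rounded_wdi,
            }
        )
    return recs


def _report_markdown(result: PipelineResult) -> str:
    gm = result.nca_summary.geometric_means
    rng = result.nca_summary.ranges
    lines = [
        "# Egg residue depletion report",
        "",
        f"Seed: {result.seed}",
        "",
        "## Laying",
        f"- flock mean inter-egg interval: "
        f"{result.laying.flock_mean_interval:.2f} d",
        f"- longest gap: {result.laying.longest_gap:.1f} d "
        f"(hen {result.laying.longest_gap_hen})",
        f"- hens ceased laying: {list(result.laying.ceased_hens) or 'none'}",
        f"- flock max last detection: "
        f"{max(result.laying.last_detection.values()):.0f} d after final dose",
        "",
        "## NCA (geometric mean, range; hour units)",
    ]
    for name in ("cmax_obs", "tmax_obs", "t_half", "auc_inf"):
        if name in gm:
            lo, hi = rng[name]
            lines.append(f"- {name}: {gm[name]:.3g} ({lo:.3g}-{hi:.3g})")
    lines += ["", "## Withdrawal intervals", "",
              "| method | limit (ng/g) | raw (d) | rounded (d) |",
              "|---|---|---|---|"]
    for rec in wdi_records(result):
        lim = "-" if rec["limit_ng_per_g"] is None else rec["limit_ng_per_g"]
        lines.append(
            f"| {rec['method']} | {lim} | {rec['raw_wdi_days']} | "
            f"{rec['rounded_wdi_days']} |"
        )
    lines.append("")
    return "\n".join(lines)


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_flock(result.flock, out / "flock.csv")
    nca_table(result).to_csv(out / "nca.csv", index=False)
    augmented_table(result).to_csv(out / "augmented.csv", index=False)
    payload = {"seed": result.seed, "estimates": wdi_records(result)}
    (out / "wdi.json").write_text(json.dumps(payload, indent=2))
    (out / "report.md").write_text(_report_markdown(result))
    if config.figures:
        _write_figures(result, out)


def _write_figures(result: PipelineResult, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .data import Censor

    for matrix in (Matrix.YOLK, Matrix.WHITE):
        bins: dict[int, list[float]] = {}
        for obs in result.flock.subset(matrix):
            if obs.censor is Censor.BELOW_LOD or obs.concentration is None:
                continue
            if obs.time >= 0:
                bins.setdefault(int(round(obs.time)), []).append(
                    obs.concentration
                )
        if not bins:
            continue
        days = sorted(bins)
        means = [float(pd.Series(bins[d]).mean()) for d in days]
        sds = [float(pd.Series(bins[d]).std(ddof=1)) if len(bins[d]) > 1 else 0.0
               for d in days]
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.errorbar(days, means, yerr=sds, fmt="o-", ms=3, lw=1, capsize=2)
        lod = result.flock.limits[matrix].lod
        ax.axhline(lod, ls="--", color="grey", label=f"LOD {lod} ng/g")
        ax.set_yscale("log")
        ax.set_xlabel("time since final dose (days)")
        ax.set_ylabel("concentration (ng/g)")
        ax.set_title(f"Egg {matrix.value} residue, mean ± SD")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / f"profile_{matrix.value}.png", dpi=120)
        plt.close(fig)
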