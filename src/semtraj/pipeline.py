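"""End-to-end orchestration: score -> model -> report.

Reads an embedding space and a transcript table, builds similarity and
lag records, runs the enabled Bayesian analyses, and writes tidy CSVs
plus JSON summaries with full provenance.  Identical config + seed
reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from . import __version__
from .embeddings import load_embeddings
from .models import (
    MCMCConfig,
    MixedModelSpec,
    PowerLawSpec,
    check_convergence,
    difference_distribution,
    fit_mixed_model,
    fit_power_law,
    leave_one_out_by_subject,
    summarize_draws,
)
from .trajectory import (
    build_lag_records,
    build_position_records,
    group_summary,
    records_to_frame,
    write_records_csv,
)
from .transcript import ExclusionLists, read_trials

__all__ = ["AnalysisConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Flat configuration for one pipeline run; see ``from_dict`` for
    the dotted config-file keys."""

    embeddings_path: str = ""
    embeddings_dims: Optional[int] = None
    embeddings_lowercase: bool = True
    transcripts_path: str = ""
    out_dir: str = "semtraj_out"
    exclusion_profile: str = "extended"
    extra_exclusions: tuple[str, ...] = ()
    max_position: int = 5
    max_lag: int = 4
    lognormal_policy: str = "positive_only"
    powerlaw_data_mode: str = "raw"
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    overall_shift: bool = True
    position_powerlaw: bool = True
    lag_powerlaw: bool = True
    leave_one_out: bool = True
    make_plots: bool = False
    convergence_threshold: float = 1.01

    _KEYS = {
        "embeddings.path": "embeddings_path",
        "embeddings.dims": "embeddings_dims",
        "embeddings.lowercase": "embeddings_lowercase",
        "transcripts.path": "transcripts_path",
        "out_dir": "out_dir",
        "prep.exclusion_profile": "exclusion_profile",
        "prep.extra_exclusions": "extra_exclusions",
        "analysis.max_position": "max_position",
        "analysis.max_lag": "max_lag",
        "model.lognormal_policy": "lognormal_policy",
        "model.powerlaw_data_mode": "powerlaw_data_mode",
        "analysis.overall_shift": "overall_shift",
        "analysis.position_powerlaw": "position_powerlaw",
        "analysis.lag_powerlaw": "lag_powerlaw",
        "analysis.leave_one_out": "leave_one_out",
        "analysis.make_plots": "make_plots",
        "analysis.convergence_threshold": "convergence_threshold",
    }
    _MCMC_KEYS = {
        "mcmc.chains": "chains",
        "mcmc.iterations": "iterations",
        "mcmc.warmup": "warmup",
        "mcmc.seed": "seed",
    }

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "AnalysisConfig":
        """Build from a flat dict of dotted keys (or nested mappings)."""
        flat = _flatten(raw)
        kwargs: dict[str, Any] = {}
        mcmc_kwargs: dict[str, Any] = {}
        for key, value in flat.items():
            if key in cls._KEYS:
                if key == "prep.extra_exclusions":
                    value = tuple(value)
                kwargs[cls._KEYS[key]] = value
            elif key in cls._MCMC_KEYS:
                mcmc_kwargs[cls._MCMC_KEYS[key]] = value
            else:
                raise KeyError(f"unknown config key {key!r}")
        kwargs["mcmc"] = MCMCConfig(**mcmc_kwargs)
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        out = {dotted: getattr(self, attr) for dotted, attr in self._KEYS.items()}
        out["prep.extra_exclusions"] = list(self.extra_exclusions)
        for key, attr in self._MCMC_KEYS.items():
            out[key] = getattr(self.mcmc, attr)
        return out


def _flatten(raw: dict[str, Any], prefix: str = "") -> dict[str, Any]:
    flat: dict[str, Any] = {}
    for key, value in raw.items():
        dotted = f"{prefix}{key}"
        if isinstance(value, dict):
            flat.update(_flatten(value, prefix=f"{dotted}."))
        else:
            flat[dotted] = value
    return flat


def _convergence_dict(report) -> dict[str, Any]:
    return {
        "rhat": report.rhat,
        "ess": report.ess,
        "threshold": report.threshold,
        "passed": report.passed,
    }


def _write_draws_csv(draws: dict[str, np.ndarray], path: Path) -> None:
    cols: dict[str, np.ndarray] = {}
    chains, n_draws = next(iter(draws.values())).shape[:2]
    cols["chain"] = np.repeat(np.arange(chains), n_draws)
    cols["iteration"] = np.tile(np.arange(n_draws), chains)
    for name, arr in draws.items():
        if arr.ndim == 2:
            cols[name] = arr.reshape(-1)
    pd.DataFrame(cols).to_csv(path, index=False)


def run_pipeline(config: AnalysisConfig) -> dict[str, Any]:
    """Execute the enabled analyses and write all outputs under ``out_dir``.

    Returns the report dict (also written to ``report.json``).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    report: dict[str, Any] = {"stages": {}}

    def stage(name):
        log.info("stage %s", name)
        report["stages"][name] = round(time.time() - t0, 3)

    stage("load")
    space = load_embeddings(config.embeddings_path,
                            expected_dims=config.embeddings_dims,
                            lowercase=config.embeddings_lowercase)
    trials = read_trials(config.transcripts_path)
    exclusions = ExclusionLists.from_profile(config.exclusion_profile,
                                             extra=config.extra_exclusions)
    log.info("loaded %d words (%d dims), %d trials", len(space), space.dims, len(trials))

    stage("score")
    overall_records = build_position_records(trials, space, exclusions,
                                             max_position=None)
    position_records = [r for r in overall_records if r.position <= config.max_position]
    lag_records = build_lag_records(trials, space, exclusions, max_lag=config.max_lag)
    write_records_csv(overall_records, out_dir / "position_records.csv")
    if lag_records:
        write_records_csv(lag_records, out_dir / "lag_records.csv")

    report["descriptives"] = {
        "overall": group_summary(overall_records).to_dict(orient="records"),
        "lag": (group_summary(lag_records).to_dict(orient="records")
                if lag_records else None),
        "n_position_records": len(overall_records),
        "n_lag_records": len(lag_records),
    }

    mm_spec = MixedModelSpec(response_family="lognormal",
                             lognormal_policy=config.lognormal_policy)
    pl_kwargs = dict(data_mode=config.powerlaw_data_mode)

    if config.overall_shift:
        stage("overall_shift")
        posterior, conv = fit_mixed_model(
            overall_records, spec=mm_spec, mcmc=config.mcmc,
            convergence_threshold=config.convergence_threshold)
        report["overall_shift"] = {
            "summary": summarize_draws(
                {k: v for k, v in posterior.draws.items() if v.ndim == 2}),
            "n_obs": posterior.n_obs,
            "n_dropped_nonpositive": posterior.n_dropped,
            "convergence": _convergence_dict(conv),
        }
        _write_draws_csv(posterior.draws, out_dir / "overall_shift_draws.csv")
        if config.leave_one_out:
            stage("leave_one_out")
            loo = leave_one_out_by_subject(overall_records, spec=mm_spec,
                                           mcmc=config.mcmc)
            report["leave_one_out"] = [
                {"excluded_subject": r.excluded_subject,
                 "beta_mean": r.beta_mean, "beta_sd": r.beta_sd,
                 "ci95": list(r.ci95), "excludes_zero": r.excludes_zero}
                for r in loo
            ]

    if config.position_powerlaw:
        stage("position_powerlaw")
        spec = PowerLawSpec(x_field="position", **pl_kwargs)
        posterior, conv = fit_power_law(
            position_records, spec=spec, mcmc=config.mcmc,
            convergence_threshold=config.convergence_threshold)
        diffs = {}
        for param in ("a", "b"):
            summary, _ = difference_distribution(posterior, param)
            diffs[param] = asdict(summary)
        report["position_powerlaw"] = {
            "summary": summarize_draws(
                {k: v for k, v in posterior.draws.items() if v.ndim == 2}),
            "differences": diffs,
            "convergence": _convergence_dict(conv),
        }
        _write_draws_csv(posterior.draws, out_dir / "position_powerlaw_draws.csv")
        report["_position_posterior"] = posterior  # in-memory only

    if config.lag_powerlaw and lag_records:
        stage("lag_powerlaw")
        lag_mm_spec = MixedModelSpec(response_family="normal")
        mm_post, mm_conv = fit_mixed_model(
            lag_records, spec=lag_mm_spec, mcmc=config.mcmc,
            convergence_threshold=config.convergence_threshold)
        spec = PowerLawSpec(x_field="lag", **pl_kwargs)
        posterior, conv = fit_power_law(
            lag_records, spec=spec, mcmc=config.mcmc,
            convergence_threshold=config.convergence_threshold)
        diffs = {}
        for param in ("a", "b"):
            summary, _ = difference_distribution(posterior, param)
            diffs[param] = asdict(summary)
        report["lag_powerlaw"] = {
            "mixed_model_summary": summarize_draws(
                {k: v for k, v in mm_post.draws.items() if v.ndim == 2}),
            "mixed_model_convergence": _convergence_dict(mm_conv),
            "summary": summarize_draws(
                {k: v for k, v in posterior.draws.items() if v.ndim == 2}),
            "differences": diffs,
            "convergence": _convergence_dict(conv),
        }
        _write_draws_csv(posterior.draws, out_dir / "lag_powerlaw_draws.csv")
        report["_lag_posterior"] = posterior

    if config.make_plots:
        stage("plot")
        from .plotting import plot_trajectories

        plot_trajectories(
            position_records=position_records,
            lag_records=lag_records,
            position_posterior=report.get("_position_posterior"),
            lag_posterior=report.get("_lag_posterior"),
            out_dir=out_dir,
        )

    stage("done")
    config_dict = config.to_dict()
    report["provenance"] = {
        "package_version": __version__,
        "config": config_dict,
        "config_hash": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()).hexdigest(),
        "seed": config.mcmc.seed,
    }
    serializable = {k: v for k, v in report.items() if not k.startswith("_")}
    (out_dir / "report.json").write_text(json.dumps(serializable, indent=2))
    _write_summary_text(serializable, out_dir / "summary.txt")
    return report


def _write_summary_text(report: dict[str, Any], path: Path) -> None:
    lines = ["semtraj analysis summary", "=" * 24, ""]
    for row in report["descriptives"]["overall"]:
        lines.append(
            f"overall target-similarity {row['group']}: "
            f"mean={row['mean']:.4f} sd={row['sd']:.4f} n={row['n']}"
        )
    if "overall_shift" in report:
        beta = report["overall_shift"]["summary"]["beta_group"]
        lines.append(
            f"group shift beta: mean={beta['mean']:.4f} sd={beta['sd']:.4f} "
            f"95% CI [{beta['q2.5']:.4f}, {beta['q97.5']:.4f}]"
        )
    for key, label in (("position_powerlaw", "position"), ("lag_powerlaw", "lag")):
        if key in report:
            s = report[key]["summary"]
            for g in ("CO", "HP"):
                lines.append(
                    f"{label} power law {g}: a={s[f'mean_a_{g}']['mean']:.4f} "
                    f"b={s[f'mean_b_{g}']['mean']:.4f}"
                )
            d = report[key]["differences"]["b"]
            lines.append(
                f"{label} b difference (HP-CO): mean={d['mean']:.4f} "
                f"P(>0)={d['proportion_positive']:.2f}"
            )
    path.write_text("\n".join(lines) + "\n")
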