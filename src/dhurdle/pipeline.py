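"""End-to-end orchestration: simulate or load, describe, encode, fit, render.

A pipeline run is declared by a small mapping (usually read from YAML):

.. code-block:: yaml

    seed: 7
    simulate: {preset: hies, n: 2000, variant: exponential}
    # or:  data: households.csv
    fit: {variant: exponential, rho: both}

Artifacts are plain text (CSV/JSON/TXT) and byte-identical across re-runs
with the same resolved config and seed; timings live only on the returned
:class:`PipelineRun`, never in the artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from . import descriptives, synthetic
from .design import CATEGORY_LEVELS, CONTINUOUS_FIELDS, DesignSpec, encode_design
from .errors import ConfigurationError, ContractError
from .model import fit_dh
from .params import DHFitResult

logger = logging.getLogger(__name__)

__all__ = ["PipelineRun", "run_pipeline", "render_coefficient_table"]

_Z975 = float(norm.ppf(0.975))


@dataclass
class PipelineRun:
    """Record of one pipeline execution."""

    config_digest: str
    seed: int
    stage_outputs: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    fits: dict = field(default_factory=dict)


def _digest(resolved: dict) -> str:
    payload = yaml.safe_dump(resolved, sort_keys=True).encode("utf-8")
    return hashlib.sha256(payload).hexdigest()


def render_coefficient_table(fit: DHFitResult, spec: DesignSpec | None = None) -> pd.DataFrame:
    """Long-format coefficient table mirroring the published layout.

    One row per parameter with hurdle, term, estimate, SE, normal-theory z,
    two-sided p and a 95% CI; when a :class:`DesignSpec` is given, the
    reference category of each categorical term appears as a ``Reference``
    row with empty numeric cells.
    """
    if fit.se is None:
        raise ContractError("fit carries no standard errors; refit with compute_se=True")
    est = fit.params.as_array() if fit.rho_mode == "free" else np.concatenate(
        [fit.params.theta, fit.params.beta, [fit.params.sigma]]
    )
    if est.size != fit.se.size or est.size != len(fit.param_names):
        raise ContractError("parameter names, estimates and SEs are inconsistent")

    by_name = {}
    for name, e, s in zip(fit.param_names, est, fit.se):
        stat = e / s if s > 0 else np.inf * np.sign(e)
        p = 2.0 * norm.sf(abs(stat))
        by_name[name] = dict(estimate=e, se=s, statistic=stat, p=p,
                             ci_low=e - _Z975 * s, ci_high=e + _Z975 * s)

    rows: list[dict] = []

    def emit(hurdle: str, term: str, key: str | None, note: str = ""):
        base = dict.fromkeys(("estimate", "se", "statistic", "p", "ci_low", "ci_high"), np.nan)
        if key is not None:
            base = by_name[key]
        rows.append({"hurdle": hurdle, "term": term, **base, "note": note})

    for hurdle, prefix in (("first", "participation"), ("second", "expenditure")):
        names = [n.split(":", 1)[1] for n in fit.param_names if n.startswith(prefix + ":")]
        if spec is None:
            for n in names:
                emit(hurdle, n, f"{prefix}:{n}")
            continue
        terms = spec.participation_terms if prefix == "participation" else spec.expenditure_terms
        if spec.include_intercept:
            emit(hurdle, "const", f"{prefix}:const")
        for term in terms:
            if term in CONTINUOUS_FIELDS:
                emit(hurdle, term, f"{prefix}:{term}")
            else:
                ref = spec.reference_levels.get(term, None)
                for lev in CATEGORY_LEVELS[term]:
                    label = f"{term}[{lev}]"
                    if lev == ref:
                        emit(hurdle, label, None, note="Reference")
                    else:
                        emit(hurdle, label, f"{prefix}:{label}")
    emit("", "sigma", "sigma")
    if fit.rho_mode == "free":
        emit("", "rho", "rho")
    return pd.DataFrame(rows)


def _fit_summary(fit: DHFitResult) -> dict:
    wald = None
    if fit.wald_rho is not None:
        wald = {"statistic": fit.wald_rho.statistic, "df": fit.wald_rho.df,
                "p_value": fit.wald_rho.p_value}
    return {
        "variant": fit.params.variant,
        "rho_mode": fit.rho_mode,
        "loglik": fit.loglik,
        "loglik_null": fit.loglik_null,
        "lr_chi2": fit.lr_chi2,
        "lr_df": fit.lr_df,
        "lr_p": fit.lr_p,
        "pseudo_r2": fit.pseudo_r2,
        "wald_rho": wald,
        "sigma": fit.params.sigma,
        "rho": fit.params.rho if fit.rho_mode == "free" else 0.0,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "n_obs": fit.n_obs,
        "n_zero": fit.n_zero,
        "n_floored": fit.n_floored,
    }


def _resolve(config: dict, seed: int | None) -> tuple[dict, synthetic.SyntheticConfig | None]:
    resolved = json.loads(json.dumps(config, sort_keys=True))  # deep copy, canonical types
    if seed is not None:
        resolved["seed"] = int(seed)
    resolved.setdefault("seed", 0)
    if ("simulate" in resolved) == ("data" in resolved):
        raise ConfigurationError("config must name exactly one of 'simulate' or 'data'")
    sim_cfg = None
    if "simulate" in resolved:
        sim = resolved["simulate"]
        if "config" in sim:
            sim_cfg = synthetic.config_from_dict(sim["config"])
        else:
            sim_cfg = synthetic.hies_like_config(
                n_households=int(sim.get("n", 9381)),
                seed=int(resolved["seed"]),
                variant=sim.get("variant", "exponential"),
            )
        sim_cfg.seed = int(resolved["seed"])
        resolved["simulate"] = {"config": synthetic.config_to_dict(sim_cfg)}
    return resolved, sim_cfg


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> PipelineRun:
    """Execute simulate/load -> describe -> encode -> fit -> render.

    Deterministic given the resolved config (which embeds the seed); any
    stage failure is re-raised with the stage name attached.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved, sim_cfg = _resolve(config, seed)
    run = PipelineRun(config_digest=_digest(resolved), seed=int(resolved["seed"]))
    caught: list[warnings.WarningMessage] = []

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                self_inner.ctx = warnings.catch_warnings(record=True)
                self_inner.records = self_inner.ctx.__enter__()
                warnings.simplefilter("always")
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                self_inner.ctx.__exit__(None, None, None)
                run.timings[name] = time.perf_counter() - self_inner.t0
                for w in self_inner.records:
                    run.warnings.append(f"{name}: {w.message}")
                if exc is not None:
                    logger.error("pipeline stage %r failed: %s", name, exc)
                    raise ContractError(f"pipeline stage {name!r} failed: {exc}") from exc
                return False

        return _Stage()

    with stage("input"):
        if sim_cfg is not None:
            table = synthetic.simulate_households(sim_cfg)
            if sim_cfg.emit_rials:
                for col in synthetic.MONETARY_COLUMNS:
                    table[col] = descriptives.convert_rial_to_usd(table[col])
        else:
            table = pd.read_csv(resolved["data"])
        path = out / "households.csv"
        table.to_csv(path, index=False)
        run.stage_outputs["households"] = str(path)

    with stage("describe"):
        frame = descriptives.summary_frame(table)
        path = out / "descriptives.csv"
        frame.to_csv(path, index=False)
        run.stage_outputs["descriptives"] = str(path)
        path = out / "table1.txt"
        path.write_text(descriptives.format_table1(table) + "\n", encoding="utf-8")
        run.stage_outputs["table1"] = str(path)

    with stage("encode"):
        if sim_cfg is not None:
            spec = sim_cfg.design
        else:
            dd = resolved.get("design")
            spec = DesignSpec() if dd is None else synthetic.config_from_dict(
                {"n_households": 1, "design": dd,
                 "true_params": {"theta": [0], "beta": [0], "sigma": 1, "rho": 0,
                                 "variant": "linear"}}
            ).design
        dm = encode_design(table, spec)

    fit_block = resolved.get("fit", {})
    variant = fit_block.get("variant", sim_cfg.outcome_variant if sim_cfg is not None else "linear")
    rho_req = fit_block.get("rho", "free")
    modes = ("free", "fixed_zero") if rho_req == "both" else (rho_req,)
    summaries = {}
    with stage("fit"):
        for mode in modes:
            fit = fit_dh(dm, variant=variant, rho_mode=mode)
            run.fits[mode] = fit
            table_df = render_coefficient_table(fit, spec)
            path = out / f"coefficients_{mode}.csv"
            table_df.to_csv(path, index=False)
            run.stage_outputs[f"coefficients_{mode}"] = str(path)
            summaries[mode] = _fit_summary(fit)
        if len(modes) == 2:
            summaries["lr_free_vs_fixed_zero"] = lr_test_free_fixed(run.fits["free"], run.fits["fixed_zero"])

    with stage("render"):
        path = out / "fit_summary.json"
        path.write_text(json.dumps(summaries, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        run.stage_outputs["fit_summary"] = str(path)
        manifest = {
            "config_digest": run.config_digest,
            "seed": run.seed,
            # file names only, so re-runs in different directories compare equal
            "artifacts": {k: Path(p).name for k, p in sorted(run.stage_outputs.items())},
            "warnings": run.warnings,
        }
        path = out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        run.stage_outputs["manifest"] = str(path)

    missing = [p for p in run.stage_outputs.values() if not Path(p).exists()]
    if missing:
        raise ContractError(f"pipeline exited with missing artifacts: {missing}")
    return run


def lr_test_free_fixed(fit_free: DHFitResult, fit_fixed: DHFitResult) -> dict:
    """LR comparison of the correlated-errors fit against the independent one."""
    from scipy.stats import chi2

    stat = max(0.0, 2.0 * (fit_free.loglik - fit_fixed.loglik))
    return {"chi2": stat, "df": 1, "p": float(chi2.sf(stat, 1))}
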