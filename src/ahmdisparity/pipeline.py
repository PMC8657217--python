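"""Configuration-driven orchestration: simulate -> disparity -> HLM ->
joint model -> report, with a provenance manifest per run.

A run is described by a :class:`RunConfig` (built directly or loaded from a
YAML/JSON file).  Each requested stage writes its outputs into the run
directory and registers them (with SHA-256 hashes) in ``manifest.json``;
rerunning with the same configuration and seed reproduces every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, disparity, hlm, jointmodel, synthdata

__all__ = ["RunConfig", "StageError", "run", "report"]

logger = logging.getLogger("ahmdisparity")

STAGES = ("simulate", "prr", "hlm", "jointmodel", "report")


class StageError(RuntimeError):
    """A pipeline stage failed; the manifest records partial completion."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    outdir: str = "run"
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    csv_path: str | None = None  # if set, load counties instead of simulating
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides
    prr_method: str = "geometric"
    hlm_outcome: str = "prr"
    hlm_reml: bool = False
    jointmodel_options: dict = field(default_factory=dict)
    save_draws: bool = True
    strict: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}")
        if not self.stages:
            raise ValueError("at least one stage must be requested")
        if "report" in self.stages and len(self.stages) == 1 and not Path(
            self.outdir
        ).exists():
            raise ValueError("report stage requires upstream outputs")
        if self.csv_path is None and "simulate" not in self.stages:
            # downstream stages need data from somewhere
            needs_data = set(self.stages) & {"prr", "hlm", "jointmodel"}
            if needs_data and not (Path(self.outdir) / "counties.csv").exists():
                raise ValueError(
                    "no csv_path given and no simulate stage or prior "
                    "counties.csv to supply data"
                )

    @staticmethod
    def from_file(path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        payload = yaml.safe_load(text) or {}
        cfg = RunConfig(**payload)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg

    def to_jsonable(self) -> dict:
        out = dataclasses.asdict(self)
        out["stages"] = list(self.stages)
        return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _register(manifest: dict, stage: str, path: Path) -> None:
    manifest["outputs"][path.name] = {
        "stage": stage,
        "sha256": _sha256(path),
    }


def _load_records(config: RunConfig, outdir: Path) -> pd.DataFrame:
    if config.csv_path is not None:
        return synthdata.read_county_csv(config.csv_path)
    return synthdata.read_county_csv(outdir / "counties.csv")


def run(config: RunConfig) -> dict:
    """Execute the requested stages; returns (and writes) the manifest."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_jsonable(),
        "stages": {},
        "outputs": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    records = None
    truth = None
    convergence_flag = False
    try:
        for stage in config.stages:
            logger.info("stage %s", stage)
            t0 = time.time()
            if stage == "simulate":
                gen_payload = dict(config.generator)
                gen_payload.setdefault("seed", config.seed)
                gcfg = _generator_config(gen_payload)
                records, truth = synthdata.generate_dataset(gcfg)
                synthdata.write_county_csv(records, outdir / "counties.csv")
                truth.to_json(outdir / "truth.json")
                _register(manifest, stage, outdir / "counties.csv")
                _register(manifest, stage, outdir / "truth.json")
            elif stage == "prr":
                if records is None:
                    records = _load_records(config, outdir)
                result = disparity.compute_disparity(
                    records, method=config.prr_method
                )
                result.tidy().to_csv(outdir / "prr_summary.csv", index=False)
                result.per_county.to_csv(
                    outdir / "prr_by_county.csv", index=False
                )
                _register(manifest, stage, outdir / "prr_summary.csv")
                _register(manifest, stage, outdir / "prr_by_county.csv")
            elif stage == "hlm":
                if records is None:
                    records = _load_records(config, outdir)
                table, fits = hlm.model_sequence(
                    records, outcome=config.hlm_outcome, reml=config.hlm_reml
                )
                table.to_csv(outdir / "hlm_table.csv", index=False)
                payload = {
                    "pseudo_r2": table.attrs["pseudo_r2"],
                    "fits": {
                        label: {
                            "fixed_effects": fit.fixed_effects,
                            "sigma2_state": fit.sigma2_state,
                            "sigma2_resid": fit.sigma2_resid,
                            "loglik": fit.loglik,
                            "n_counties": fit.n_counties,
                            "n_states": fit.n_states,
                            "method": fit.method,
                        }
                        for label, fit in fits.items()
                    },
                }
                (outdir / "hlm_fits.json").write_text(
                    json.dumps(payload, indent=2)
                )
                _register(manifest, stage, outdir / "hlm_table.csv")
                _register(manifest, stage, outdir / "hlm_fits.json")
            elif stage == "jointmodel":
                if records is None:
                    records = _load_records(config, outdir)
                opts = dict(config.jointmodel_options)
                opts.setdefault("random_state", config.seed)
                model = jointmodel.SharedComponentFactorModel(**opts).fit(records)
                model.summary_.to_csv(
                    outdir / "posterior_params.csv", index=False
                )
                model.main_effects_().to_csv(
                    outdir / "main_effects.csv", index=False
                )
                if model.interactions:
                    model.interaction_effects_().to_csv(
                        outdir / "interaction_effects.csv", index=False
                    )
                    _register(manifest, stage, outdir / "interaction_effects.csv")
                model.county_factors_.to_csv(
                    outdir / "county_factors.csv", index=False
                )
                if model.county_differences_ is not None:
                    model.county_differences_.to_csv(
                        outdir / "county_differences.csv", index=False
                    )
                    _register(manifest, stage, outdir / "county_differences.csv")
                (outdir / "diagnostics.json").write_text(
                    json.dumps(model.diagnostics_, indent=2)
                )
                if config.save_draws:
                    _write_draws(model.draws_, outdir / "draws.csv")
                    _register(manifest, stage, outdir / "draws.csv")
                for name in (
                    "posterior_params.csv",
                    "main_effects.csv",
                    "county_factors.csv",
                    "diagnostics.json",
                ):
                    _register(manifest, stage, outdir / name)
                convergence_flag = bool(
                    model.diagnostics_.get("nonconverged_flag", False)
                )
            elif stage == "report":
                text = report(outdir)
                (outdir / "report.md").write_text(text)
                _register(manifest, stage, outdir / "report.md")
            manifest["stages"][stage] = {
                "status": "ok",
                "seconds": round(time.time() - t0, 3),
            }
    except Exception as exc:
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        manifest["convergence_flag"] = convergence_flag
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    manifest["convergence_flag"] = convergence_flag
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _generator_config(payload: dict) -> synthdata.GeneratorConfig:
    payload = dict(payload)
    if "nonadh_model" in payload and isinstance(payload["nonadh_model"], dict):
        nm = dict(payload["nonadh_model"])
        for key in ("nhw_coefs", "baa_coefs", "clamp"):
            if key in nm:
                nm[key] = tuple(nm[key])
        payload["nonadh_model"] = synthdata.NonadherenceModel(**nm)
    if "mortality_truth" in payload and isinstance(
        payload["mortality_truth"], dict
    ):
        payload["mortality_truth"] = synthdata.JointModelTruth(
            **payload["mortality_truth"]
        )
    if "domain_score_cov" in payload:
        payload["domain_score_cov"] = np.asarray(payload["domain_score_cov"])
    if "domain_score_mean" in payload:
        payload["domain_score_mean"] = tuple(payload["domain_score_mean"])
    if "demog_params" in payload:
        payload["demog_params"] = {
            k: tuple(v) for k, v in payload["demog_params"].items()
        }
    return synthdata.GeneratorConfig(**payload)


def _write_draws(draws: dict[str, np.ndarray], path: Path) -> None:
    """Columnar draws file: parameter, chain, iteration, value."""
    frames = []
    for name, arr in draws.items():
        chains, iters = arr.shape
        frames.append(
            pd.DataFrame(
                {
                    "parameter": name,
                    "chain": np.repeat(np.arange(chains), iters),
                    "iteration": np.tile(np.arange(iters), chains),
                    "value": arr.reshape(-1),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _fmt_est(mean, lo, hi) -> str:
    return f"{mean:.3f} ({lo:.3f}, {hi:.3f})"


def report(outdir: str | Path) -> str:
    """Assemble a markdown report from whatever stage outputs exist."""
    outdir = Path(outdir)
    sections = ["# County AHM non-adherence disparity analysis\n"]
    found = False

    prr_path = outdir / "prr_summary.csv"
    if prr_path.exists():
        found = True
        prr = pd.read_csv(prr_path)
        sections.append("## Disparity in AHM non-adherence (PRR)\n")
        sections.append(prr.to_markdown(index=False))
        sections.append("")

    hlm_path = outdir / "hlm_table.csv"
    if hlm_path.exists():
        found = True
        table = pd.read_csv(hlm_path)
        sections.append("## Hierarchical linear models (M1-M4)\n")
        sections.append(table.to_markdown(index=False))
        fits_path = outdir / "hlm_fits.json"
        if fits_path.exists():
            payload = json.loads(fits_path.read_text())
            pr2 = payload.get("pseudo_r2", {})
            sections.append(
                "\nPseudo-R^2: "
                + ", ".join(f"{k} = {v:.3f}" for k, v in pr2.items())
            )
        sections.append("")

    me_path = outdir / "main_effects.csv"
    if me_path.exists():
        found = True
        me = pd.read_csv(me_path)
        sections.append("## Joint model: non-adherence main effects\n")
        sections.append(me.to_markdown(index=False))
        sections.append("")

    ie_path = outdir / "interaction_effects.csv"
    if ie_path.exists():
        found = True
        ie = pd.read_csv(ie_path)
        sections.append("## Joint model: moderation (interaction) effects\n")
        sections.append(ie.to_markdown(index=False))
        sections.append("")

    diag_path = outdir / "diagnostics.json"
    if diag_path.exists():
        diag = json.loads(diag_path.read_text())
        sections.append("## MCMC diagnostics\n")
        sections.append(
            f"max split-R-hat = {diag['max_rhat']:.4f}; "
            f"min ESS = {diag['min_ess']:.0f}; "
            f"converged = {diag['converged']}"
        )
        sections.append("")

    truth_path = outdir / "truth.json"
    params_path = outdir / "posterior_params.csv"
    if truth_path.exists() and params_path.exists():
        sections.append("## Truth-vs-estimate recovery (synthetic run)\n")
        truth = synthdata.SyntheticTruth.from_json(truth_path)
        params = pd.read_csv(params_path).set_index("name")
        rows = []
        for name, value in _truth_param_map(truth.config.mortality_truth).items():
            if name not in params.index:
                continue
            s = params.loc[name]
            covered = bool(s["ci_low"] <= value <= s["ci_high"])
            rows.append(
                {
                    "parameter": name,
                    "truth": value,
                    "posterior": _fmt_est(s["mean"], s["ci_low"], s["ci_high"]),
                    "covered": "yes" if covered else "NO",
                }
            )
        sections.append(pd.DataFrame(rows).to_markdown(index=False))
        sections.append("")

    if not found:
        raise ValueError(f"no stage outputs found in {outdir}")
    return "\n".join(sections)


def _truth_param_map(truth: synthdata.JointModelTruth) -> dict[str, float]:
    out: dict[str, float] = {}
    for outc, alpha in truth.alpha.items():
        out[f"{outc}:intercept"] = alpha
    for outc, betas in truth.beta.items():
        for cov, val in betas.items():
            out[f"{outc}:{cov}"] = val
    for outc, gammas in truth.gamma.items():
        for m, val in gammas.items():
            if val != 0.0:
                out[f"{outc}:nonadh_x_{m}"] = val
    for race, val in truth.lambda_st.items():
        out[f"lambda:{race}_st"] = val
    for outc, val in truth.kappa.items():
        out[f"kappa:{outc}"] = val
    for race, val in truth.sigma_f.items():
        out[f"sigma_f:{race}"] = val
    out["rho"] = truth.rho
    out["sigma_g"] = truth.sigma_g
    return out
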