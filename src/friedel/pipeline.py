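"""Pipeline orchestration: fa -> detect -> phase -> dm -> hand.

A :class:`PipelineConfig` (usually loaded from YAML) names the experiment
(simulated toy crystal or input reflection files), the heavy-atom
specification, the step slice to run and per-step parameter overrides.
``run_pipeline`` executes the steps with experiment-dependent defaults
(SAD: multivariate |F_A| + multivariate phase combination; SIRAS:
anomalous-vs-isomorphous signal choice, uncorrelated SIRAS phasing, MLHL
combination; MAD: best-channel selection then the SAD path with MLHL
combination), writes artifacts into the output directory, and returns a
:class:`RunReport` that is byte-reproducible given config and seed.

All randomness flows from the root seed via step-name-hashed offsets.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from .density import determine_hand, run_dm_cycles
from .fa import (
    anomalous_signal_by_shell,
    anomalous_signal_score,
    estimate_fa_isomorphous,
    estimate_fa_multivariate,
    estimate_fa_simple,
    isomorphous_signal_score,
    select_best_channel,
)
from .io import (
    read_reflections,
    read_sites_pdb,
    write_fa_tsv,
    write_phases_tsv,
    read_phases_tsv,
    write_reflections,
    write_signal_table,
    write_sites_pdb,
    write_trial_log,
    write_truth_tsv,
)
from .model import SADPhasingModel
from .patterson import SearchConfig, search_substructure
from .phasing import check_substructure_complete, phase_quality_vs_truth
from .reflections import ErrorModel, compute_bijvoet_stats, flag_free_set
from .simulate import (
    ExperimentSpec,
    Substructure,
    generate_structure,
    simulate_dataset,
)
from .symmetry import SpaceGroup, UnitCell

STEPS = ("fa", "detect", "phase", "dm", "hand")


def step_seed(root: int, step: str) -> int:
    """Deterministic per-step seed derived from the root seed."""
    return (int(root) * 1000003 + zlib.crc32(step.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see module docstring)."""

    seed: int = 0
    outdir: str = "friedel_out"
    steps: tuple = STEPS
    experiment: dict = field(default_factory=dict)
    substructure: str = None  # optional sites PDB to start from
    free_fraction: float = 0.05
    params: dict = field(default_factory=dict)

    _KNOWN_TOP = {"seed", "outdir", "steps", "experiment", "substructure",
                  "free_fraction", "params"}

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - cls._KNOWN_TOP
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**{k: raw[k] for k in raw})
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        steps = tuple(self.steps)
        for s in steps:
            if s not in STEPS:
                raise ValueError(f"unknown step {s!r}; valid: {STEPS}")
        idx = [STEPS.index(s) for s in steps]
        if idx != sorted(idx) or (idx and idx != list(range(idx[0], idx[-1] + 1))):
            raise ValueError("steps must be a contiguous, ordered slice of "
                             f"{STEPS}")
        self.steps = steps
        if not 0.0 < self.free_fraction < 0.5:
            raise ValueError("free_fraction must lie in (0, 0.5)")
        for step in self.params:
            if step not in STEPS:
                raise ValueError(f"params for unknown step {step!r}")

    def step_params(self, step: str) -> dict:
        return dict(self.params.get(step, {}))


@dataclass
class RunReport:
    """Structured, reproducible record of one pipeline run."""

    config: dict
    steps: dict = field(default_factory=dict)
    status: str = "ok"
    failed_step: str = None

    def to_json(self) -> str:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in sorted(obj.items())}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return [clean(v) for v in obj.tolist()]
            if isinstance(obj, (np.floating, float)):
                return round(float(obj), 10)
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.bool_,)):
                return bool(obj)
            return obj

        payload = {
            "config": clean(self.config),
            "status": self.status,
            "failed_step": self.failed_step,
            "steps": clean(self.steps),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        raw = json.loads(text)
        return cls(raw["config"], raw["steps"], raw["status"], raw["failed_step"])


def _experiment_data(config: PipelineConfig):
    """Returns (datasets, truth_or_None, kind, heavy_spec)."""
    exp = dict(config.experiment)
    kind = exp.get("kind", "SAD")
    heavy_spec = [
        (h.get("element", "Se"), int(h.get("count", 1)),
         float(h.get("f_prime", 0.0)), float(h.get("f_dprime", 4.0)))
        for h in exp.get("heavy", [{"element": "Se", "count": 2, "f_prime": -2.0, "f_dprime": 4.0}])
    ]
    source = exp.get("source", "simulate")
    if source == "files":
        dialect = exp.get("dialect", "tsv")
        datasets = []
        for path in exp["files"]:
            datasets.extend(read_reflections(path, dialect))
        return datasets, None, kind, heavy_spec
    st = exp.get("structure", {})
    cell = UnitCell(*st.get("cell", [34.0, 42.0, 38.0, 90.0, 90.0, 90.0]))
    sg = SpaceGroup(st.get("spacegroup", "P21"))
    structure = generate_structure(
        step_seed(config.seed, "simulate"), cell, sg,
        int(st.get("n_light", 150)), heavy_spec,
    )
    channels = [
        (c.get("label", f"ch{i}"), float(c.get("f_prime", -2.0)), float(c.get("f_dprime", 4.0)))
        for i, c in enumerate(exp.get("channels", [{"label": "peak", "f_prime": -2.0, "f_dprime": 4.0}]))
    ]
    spec = ExperimentSpec(
        kind=kind, channels=channels,
        native=(kind == "SIRAS"),
        d_min=float(exp.get("d_min", 2.2)),
        noise_frac=float(exp.get("noise_frac", 0.05)),
        seed=step_seed(config.seed, "noise"),
    )
    datasets, truth = simulate_dataset(structure, spec)
    return datasets, truth, kind, heavy_spec


def run_pipeline(config: PipelineConfig) -> RunReport:
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    report = RunReport(config=_config_dict(config))
    out = config.outdir

    datasets, truth, kind, heavy_spec = _experiment_data(config)
    native = None
    if kind == "SIRAS":
        native = next(d for d in datasets if d.label == "native")
        channels = [d for d in datasets if d.label != "native"]
    else:
        channels = list(datasets)

    # free set (stratified, reproducible)
    channels = [
        flag_free_set(d, config.free_fraction, step_seed(config.seed, "free"))
        for d in channels
    ]
    for d in channels:
        write_reflections(d, os.path.join(out, f"reflections_{d.label}.tsv"), "tsv")
    if native is not None:
        write_reflections(native, os.path.join(out, "reflections_native.tsv"), "tsv")
    if truth is not None:
        write_truth_tsv(truth, os.path.join(out, "truth.tsv"))

    element, n_sites_expected = heavy_spec[0][0], sum(h[1] for h in heavy_spec)
    f_prime, f_dprime = heavy_spec[0][2], heavy_spec[0][3]

    data = channels[0]
    fa_est = None
    sub = None
    em = None
    phases = None

    if config.substructure:
        sub, _, _ = read_sites_pdb(config.substructure, f_prime, f_dprime)

    try:
        for step in config.steps:
            params = config.step_params(step)
            if step == "fa":
                rec = {}
                if kind == "MAD" and len(channels) > 1:
                    label = select_best_channel([(d.label, d) for d in channels])
                    data = next(d for d in channels if d.label == label)
                    rec["chosen_channel"] = label
                elif kind == "SIRAS":
                    s_ano = anomalous_signal_score(data)
                    s_iso = isomorphous_signal_score(data, native)
                    rec["anomalous_score"] = s_ano
                    rec["isomorphous_score"] = s_iso
                    rec["chosen_signal"] = "anomalous" if s_ano >= s_iso else "isomorphous"
                method = params.get("method", "multivariate")
                if kind == "SIRAS" and rec.get("chosen_signal") == "isomorphous":
                    fa_est = estimate_fa_isomorphous(data, native)
                elif method == "simple":
                    fa_est = estimate_fa_simple(data)
                else:
                    fa_est = estimate_fa_multivariate(
                        data, heavy_fraction=params.get("heavy_fraction", 0.05)
                    )
                bs = compute_bijvoet_stats(data, params.get("n_shells", 10))
                rec["method"] = fa_est.method
                rec["overall_bijvoet_ratio"] = bs.overall_bijvoet_ratio
                write_fa_tsv(fa_est, os.path.join(out, "fa.tsv"))
                write_signal_table(
                    anomalous_signal_by_shell(data), os.path.join(out, "signal_by_shell.tsv")
                )
                report.steps["fa"] = rec
            elif step == "detect":
                if fa_est is None:
                    raise RuntimeError("detect needs the fa step output (run fa first)")
                sc = SearchConfig(
                    score_threshold=params.get("score_threshold", 0.65),
                    deviation_threshold=params.get("deviation_threshold", 0.2),
                    min_trials=params.get("min_trials", 5),
                )
                trials = search_substructure(
                    fa_est,
                    n_sites_expected=params.get("n_sites", n_sites_expected),
                    n_trials=params.get("n_trials", 20),
                    seed=step_seed(config.seed, "detect"),
                    element=element,
                    f_prime=f_prime,
                    f_dprime=f_dprime,
                    config=sc,
                )
                best = trials[0]
                write_trial_log(trials, os.path.join(out, "trials.tsv"))
                rec = {"n_trials_run": len(trials), "best_score": best.score}
                if best.score < params.get("score_floor", 0.1):
                    report.steps["detect"] = rec
                    raise _StepFailure("detect", "no trial above the score floor")
                sub = best.sites
                for s in sub.sites:
                    s.f_prime, s.f_dprime = f_prime, f_dprime
                if truth is not None:
                    # synthetic runs: place the solution in the deposited
                    # truth frame (hand/origin/symmetry are symmetries of
                    # the amplitudes) so truth metrics are interpretable
                    from .patterson import align_substructure

                    sub, n_matched, mean_d = align_substructure(
                        sub, truth.sites, data.sg, data.cell
                    )
                    rec["n_sites_matched"] = n_matched
                    rec["mean_site_dist"] = mean_d
                verdict, avg = check_substructure_complete(
                    data, sub, params.get("luzzati_threshold", 0.7)
                )
                rec["check_mode"] = verdict
                rec["avg_luzzati"] = avg
                write_sites_pdb(sub, data.cell, data.sg, os.path.join(out, "sites.pdb"))
                # the written file is the canonical artifact: reload it so a
                # later slice starting from sites.pdb reproduces this run
                sub, _, _ = read_sites_pdb(os.path.join(out, "sites.pdb"), f_prime, f_dprime)
                report.steps["detect"] = rec
            elif step == "phase":
                if sub is None:
                    sub = _load_sites(out, f_prime, f_dprime)
                model = SADPhasingModel(
                    data, sub,
                    native=native if kind == "SIRAS" else None,
                    n_shells=params.get("n_shells", 10),
                )
                res = model.fit(
                    refine_positions=params.get("refine_positions", True),
                    max_iter=params.get("max_iter", 20),
                )
                sub, em, phases = res.substructure, res.error_model, res.phases
                rec = {
                    "avg_luzzati": res.avg_luzzati,
                    "mean_fom": res.mean_fom,
                    "luzzati_d_per_shell": em.luzzati_d,
                }
                if truth is not None:
                    mc, fwe, cc = phase_quality_vs_truth(phases, truth)
                    rec["mean_cos_err"] = mc
                    rec["fom_weighted_err_deg"] = fwe
                    rec["map_cc"] = cc
                write_phases_tsv(phases, os.path.join(out, "phases.tsv"))
                write_sites_pdb(sub, data.cell, data.sg, os.path.join(out, "sites_refined.pdb"))
                _save_error_model(em, os.path.join(out, "error_model.json"))
                report.steps["phase"] = rec
            elif step == "dm":
                if phases is None:
                    phases = read_phases_tsv(os.path.join(out, "phases.tsv"))
                    em = _load_error_model(os.path.join(out, "error_model.json"))
                mode = params.get("mode", "multivariate" if kind == "SAD" else "mlhl")
                res = run_dm_cycles(
                    data, phases, em,
                    n_cycles=params.get("n_cycles", 5),
                    mode=mode,
                    solvent_fraction=params.get("solvent_fraction", 0.45),
                    truth=truth,
                )
                phases = res.phases
                rec = {
                    "mode": mode,
                    "per_cycle": res.log,
                    "final_mean_fom": float(res.phases.fom.mean()),
                    "free_loglik": res.free_loglik,
                }
                write_phases_tsv(phases, os.path.join(out, "phases_dm.tsv"))
                report.steps["dm"] = rec
            elif step == "hand":
                if sub is None:
                    sub = _load_sites(out, f_prime, f_dprime, refined=True)
                decision, stats = determine_hand(
                    data, sub, em,
                    n_cycles=params.get("n_cycles", 3),
                    solvent_fraction=params.get("solvent_fraction", 0.45),
                    truth=truth,
                )
                report.steps["hand"] = {"decision": decision, **_flatten_hand(stats)}
    except _StepFailure as exc:
        report.status = "failed"
        report.failed_step = exc.step
        report.steps.setdefault(exc.step, {})["error"] = exc.message

    emit_report(report, out)
    return report


class _StepFailure(Exception):
    def __init__(self, step: str, message: str):
        super().__init__(message)
        self.step = step
        self.message = message


def _config_dict(config: PipelineConfig) -> dict:
    return {
        "seed": config.seed,
        "outdir": config.outdir,
        "steps": list(config.steps),
        "experiment": config.experiment,
        "substructure": config.substructure,
        "free_fraction": config.free_fraction,
        "params": config.params,
    }


def _flatten_hand(stats: dict) -> dict:
    out = {}
    for key, val in stats.items():
        if isinstance(val, dict):
            for k2, v2 in val.items():
                out[f"{key}_{k2}"] = v2
        else:
            out[key] = val
    return out


def _load_sites(outdir: str, f_prime: float, f_dprime: float, refined: bool = False):
    for name in (["sites_refined.pdb", "sites.pdb"] if refined else ["sites.pdb", "sites_refined.pdb"]):
        path = os.path.join(outdir, name)
        if os.path.exists(path):
            sub, _, _ = read_sites_pdb(path, f_prime, f_dprime)
            return sub
    raise RuntimeError("phase/hand step needs a substructure: run detect first "
                       "or provide one in the config")


def _save_error_model(em: ErrorModel, path: str) -> None:
    payload = {
        "shell_d_max": em.shell_d_max.tolist(),
        "shell_d_min": em.shell_d_min.tolist(),
        "luzzati_d": em.luzzati_d.tolist(),
        "var_extra": em.var_extra.tolist(),
        "shell_n": np.asarray(em.shell_n).tolist(),
        "d_dm": em.d_dm.tolist(),
        "dm_corr": em.dm_corr.tolist(),
        "sigma_a_data": em.sigma_a_data.tolist(),
        "beta": em.beta.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def _load_error_model(path: str) -> ErrorModel:
    with open(path) as fh:
        raw = json.load(fh)
    return ErrorModel(
        shell_d_max=np.array(raw["shell_d_max"]),
        shell_d_min=np.array(raw["shell_d_min"]),
        luzzati_d=np.array(raw["luzzati_d"]),
        var_extra=np.array(raw["var_extra"]),
        shell_n=np.array(raw["shell_n"]),
        d_dm=np.array(raw["d_dm"]),
        dm_corr=np.array(raw["dm_corr"]),
        sigma_a_data=np.array(raw["sigma_a_data"]),
        beta=np.array(raw["beta"]),
    )


def emit_report(report: RunReport, outdir: str) -> None:
    """Machine-readable JSON plus a human-readable summary; per-cycle FOM
    and Bijvoet-by-shell tables are written by their steps as TSV."""
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        fh.write(report.to_json() + "\n")
    lines = [f"friedel pipeline report  (status: {report.status})"]
    if report.failed_step:
        lines.append(f"FAILED at step: {report.failed_step}")
    for step in STEPS:
        if step not in report.steps:
            continue
        lines.append(f"\n[{step}]")
        for key, val in sorted(report.steps[step].items()):
            if isinstance(val, float):
                lines.append(f"  {key}: {val:.4f}")
            elif isinstance(val, list) and val and isinstance(val[0], dict):
                for rec in val:
                    lines.append("  " + "  ".join(
                        f"{k}={v:.4f}" if isinstance(v, float) else f"{k}={v}"
                        for k, v in sorted(rec.items())
                    ))
            else:
                lines.append(f"  {key}: {val}")
    with open(os.path.join(outdir, "report.txt"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
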