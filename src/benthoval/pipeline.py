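"""End-to-end orchestration: simulate -> QC -> link -> validate -> skill -> profiles.

A single :class:`RunConfig` (YAML-serialisable) drives the whole analysis so a
run is reproducible bit-for-bit from its config snapshot and seed.  All random
sub-streams are derived from the master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bottomval, diagnostics, profileval, skillstats, synthdata, telemetry
from .meshfield import save_fields
from .synthdata import BiasSchedule, DetectionModel, TagSpec

log = logging.getLogger("benthoval")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Every knob of the synthetic study and its analysis, in one place.

    Defaults reproduce the default study conditions: a ~15-month record with
    a +0.53 degC model warm bias through 2016 and a -0.045 degC residual bias
    after the new-year model update.
    """

    seed: int = 1
    start: str = "2016-03-15"
    end: str = "2017-06-01"
    # mesh
    extent_m: tuple[float, float] = (20_000.0, 20_000.0)
    n_nodes: int = 150
    depth_range_m: tuple[float, float] = (5.0, 290.0)
    n_layers: int = 10
    # fields
    bias_before: float = 0.53
    bias_after: float = -0.045
    bias_switch: str = "2017-01-01"
    strat_magnitude: float = 1.5
    ar_sd: float = 0.05
    # animals and receivers
    n_individuals: int = 3
    n_receivers: int = 12
    track_step_sd: float = 30.0
    track_home_strength: float = 1e-3
    home_spread_m: float = 500.0
    # angling (events are written into the first individual's record)
    n_angling_events: int = 8
    # detection QC and linking
    filter_window_min: float = 30.0
    filter_min_companions: int = 1
    link_max_gap_min: float = 30.0
    # skill
    skill_floor: int = 5
    skill_n_sample: int = 5
    skill_n_sim: int = 1000
    improvement_months: tuple[int, ...] | None = (3, 4, 5)
    # outputs
    write_fields_nc: bool = False
    make_plots: bool = False

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("extent_m", "depth_range_m", "improvement_months"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PipelineResult:
    """In-memory bundle of every stage's output."""

    config: RunConfig
    mesh: object
    scheme: object
    truth_and_model: object
    receivers: pd.DataFrame
    archival: pd.DataFrame
    detections: pd.DataFrame
    detections_valid: pd.DataFrame
    qc_report: pd.DataFrame
    events: pd.DataFrame
    linked: pd.DataFrame
    validation: pd.DataFrame
    effort: dict
    overall: "skillstats.SkillScores"
    by_period: dict
    ensemble_month: object
    ensemble_node: object
    improvement: object
    profiles: list
    diagnostics: dict
    manifest: dict = field(default_factory=dict)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _seeds(master: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(master).generate_state(n) // 2]


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full synthetic validation study under one config.

    When ``out_dir`` is given, writes the CSV/JSON artefacts, a config
    snapshot and a manifest there; a stage failure leaves a FAILED marker
    beside any partial outputs and re-raises as :class:`StageError`.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        return _run(config, out)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        stage = getattr(exc, "_stage", stage)
        if out is not None:
            (out / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise StageError(f"pipeline failed at stage '{stage}': {exc}") from exc


def _run(config: RunConfig, out: Path | None) -> PipelineResult:
    seeds = _seeds(config.seed, 8 + 3 * config.n_individuals)
    tag = TagSpec()
    det_model = DetectionModel()
    bias = BiasSchedule.two_period(config.bias_switch, config.bias_before, config.bias_after)

    def _stage(name):
        log.info("stage: %s", name)
        return name

    stage = _stage("simulate-fields")
    try:
        mesh, scheme = synthdata.generate_mesh(
            extent=config.extent_m, n_nodes=config.n_nodes,
            depth_range=config.depth_range_m, n_layers=config.n_layers, seed=seeds[0],
        )
        tam = synthdata.generate_fields(
            mesh, scheme, start=config.start, end=config.end,
            strat_magnitude=config.strat_magnitude, ar_sd=config.ar_sd,
            bias=bias, seed=seeds[1],
        )
        centre = (float(mesh.x.mean()), float(mesh.y.mean()))
        receivers = synthdata.place_receivers(mesh, centre, n=config.n_receivers)

        stage = _stage("simulate-animals")
        rng_home = np.random.default_rng(seeds[2])
        archival_frames, det_frames, events, arch_first = [], [], None, None
        for i in range(config.n_individuals):
            ind = f"skate-{i + 1}"
            home = (
                centre[0] + rng_home.normal(0, config.home_spread_m),
                centre[1] + rng_home.normal(0, config.home_spread_m),
            )
            track = synthdata.simulate_track(
                mesh, start=config.start, end=config.end,
                step_sd=config.track_step_sd, home=home,
                home_strength=config.track_home_strength, seed=seeds[8 + 3 * i],
            )
            arch = synthdata.sample_archival(
                track, tam.truth, mesh, tag, individual_id=ind, seed=seeds[9 + 3 * i]
            )
            if i == 0 and config.n_angling_events >= 1:
                events, arch = synthdata.simulate_angling(
                    track, arch, tam.truth, mesh, scheme, tag,
                    n_events=config.n_angling_events, seed=seeds[3],
                )
            archival_frames.append(arch)
            det_frames.append(
                synthdata.simulate_detections(
                    track, receivers, det_model, transmitter_id=ind, seed=seeds[10 + 3 * i]
                )
            )
        archival = pd.concat(archival_frames, ignore_index=True)
        detections = pd.concat(det_frames, ignore_index=True).sort_values(
            "timestamp", ignore_index=True
        )
        if events is None:
            events = pd.DataFrame(
                columns=["individual_id", "event_time", "x", "y", "event_type"]
            )

        stage = _stage("filter-detections")
        valid, qc_report = telemetry.short_interval_filter(
            detections,
            window=pd.Timedelta(minutes=config.filter_window_min),
            min_companions=config.filter_min_companions,
            return_report=True,
        )
        valid = telemetry.assign_nodes(valid, receivers, mesh)
        log.info("detections kept %d / %d", len(valid), len(detections))

        stage = _stage("link-and-build")
        linked = bottomval.link_archival_to_detections(
            archival, valid, max_gap=pd.Timedelta(minutes=config.link_max_gap_min)
        )
        validation = bottomval.build_validation_dataset(linked, tam.model, mesh)
        effort = bottomval.effort_summary(validation)

        stage = _stage("skill")
        overall = skillstats.skill_metrics(validation["mod_temp"], validation["obs_temp"])
        switch = pd.Timestamp(config.bias_switch)
        by_period = {}
        for name, mask in [
            ("baseline", validation["hour"] < switch),
            ("updated", validation["hour"] >= switch),
        ]:
            sub = validation.loc[mask]
            if len(sub) >= 2:
                by_period[name] = skillstats.skill_metrics(sub["mod_temp"], sub["obs_temp"])
        ensemble_month = skillstats.stratified_skill(
            validation, "month", floor=config.skill_floor,
            n_sample=config.skill_n_sample, n_sim=config.skill_n_sim, seed=seeds[4],
        )
        ensemble_node = skillstats.stratified_skill(
            validation, "node", floor=config.skill_floor,
            n_sample=config.skill_n_sample, n_sim=config.skill_n_sim, seed=seeds[5],
        )
        improvement = None
        if config.improvement_months:
            base_vt = validation[validation["hour"] < switch]
            upd_vt = validation[validation["hour"] >= switch]
            if not base_vt.empty and not upd_vt.empty:
                ens_b = skillstats.stratified_skill(
                    base_vt, "month", floor=config.skill_floor,
                    n_sample=config.skill_n_sample, n_sim=config.skill_n_sim, seed=seeds[6],
                )
                ens_u = skillstats.stratified_skill(
                    upd_vt, "month", floor=config.skill_floor,
                    n_sample=config.skill_n_sample, n_sim=config.skill_n_sim, seed=seeds[7],
                )
                improvement = skillstats.percentage_improvement(
                    ens_b, ens_u, months=tuple(config.improvement_months)
                )

        stage = _stage("profiles")
        profiles = []
        first_arch = archival[archival["individual_id"] == "skate-1"]
        for _, ev in events.iterrows():
            event = profileval.extract_ascent(
                first_arch,
                capture_time=ev["event_time"] + pd.Timedelta(minutes=10),
                event_type=ev["event_type"],
                location=(ev["x"], ev["y"]),
            )
            prof, zeta, node = profileval.model_profile(tam.model, mesh, scheme, event)
            event = dataclasses.replace(event, node_id=node)
            profiles.append(profileval.pair_profile(event, first_arch, prof, tag, zeta))

        stage = _stage("diagnostics")
        diag = diagnostics.variability_diagnostics(
            tam.model, mesh, scheme, nodes=np.unique(validation["node_id"])
        )
    except Exception as exc:
        exc._stage = stage
        raise

    result = PipelineResult(
        config=config, mesh=mesh, scheme=scheme, truth_and_model=tam,
        receivers=receivers, archival=archival, detections=detections,
        detections_valid=valid, qc_report=qc_report, events=events, linked=linked,
        validation=validation, effort=effort, overall=overall, by_period=by_period,
        ensemble_month=ensemble_month, ensemble_node=ensemble_node,
        improvement=improvement, profiles=profiles, diagnostics=diag,
    )
    if out is not None:
        result.manifest = _write_outputs(result, out)
    return result


def _write_outputs(res: PipelineResult, out: Path) -> dict:
    cfg = res.config
    artefacts = {}

    def _csv(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, index=False)
        artefacts[name] = str(path)

    cfg.to_yaml(out / "config.yaml")
    artefacts["config.yaml"] = str(out / "config.yaml")
    _csv("receivers.csv", res.receivers)
    _csv("detections_valid.csv", res.detections_valid.drop(columns=["is_false"], errors="ignore"))
    _csv("qc_report.csv", res.qc_report)
    _csv("events.csv", res.events)
    _csv("validation.csv", res.validation)
    _csv("skill_overall.csv", pd.DataFrame([res.overall.as_dict()]))
    _csv(
        "skill_by_period.csv",
        pd.DataFrame([{"period": k, **v.as_dict()} for k, v in res.by_period.items()]),
    )
    _csv("ensemble_month.csv", res.ensemble_month.per_stratum)
    _csv("ensemble_node.csv", res.ensemble_node.per_stratum)
    if res.improvement is not None:
        _csv("improvement_per_month.csv", res.improvement.per_month)
        (out / "improvement.json").write_text(
            json.dumps(
                {
                    "mean_p": res.improvement.mean_p,
                    "error_formula": res.improvement.error_formula,
                    "bounded_formula": res.improvement.bounded_formula,
                },
                indent=2,
            )
        )
        artefacts["improvement.json"] = str(out / "improvement.json")
    for i, pair in enumerate(res.profiles, start=1):
        mod = pair.modelled.assign(role="modelled")
        obs = pair.observed.assign(role="observed")
        _csv(f"profile_{i:02d}.csv", pd.concat([mod, obs], ignore_index=True))
    diag = {k: v for k, v in res.diagnostics.items() if not isinstance(v, dict)}
    (out / "diagnostics.json").write_text(json.dumps(diag, indent=2))
    artefacts["diagnostics.json"] = str(out / "diagnostics.json")
    if cfg.write_fields_nc:
        artefacts["fields.nc"] = save_fields(
            out / "fields.nc", res.mesh, res.scheme, res.truth_and_model.model
        )
    if cfg.make_plots:
        from . import plots

        artefacts["effort.png"] = plots.effort_figure(res.validation, out / "effort.png")
        for i, pair in enumerate(res.profiles, start=1):
            artefacts[f"profile_{i:02d}.png"] = plots.profile_figure(
                pair, out / f"profile_{i:02d}.png"
            )

    manifest = {
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "artefacts": artefacts,
        "n_validation_rows": int(len(res.validation)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
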