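"""End-to-end study pipeline: generate -> maps -> gradients -> events ->
localize -> report, as a configured, seeded, logged run.

A study config is a YAML/JSON document with one section per component
(grid, ionic, lesion, pacing, ectopic, acquisition, analysis, study);
unknown keys are rejected and defaults fill everything omitted.  Each
preparation is generated, analyzed and written under its own directory;
the study directory receives the aggregate tables, the Markdown report and
a manifest listing every artifact with a checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import events as ev
from . import geometry as geo
from . import phase as ph
from . import stats as st
from .core import EcgRecord, OpticalMovie
from .maps import BeatWindow, MapParams, build_maps, condition_movie, windows_from_beats
from .synthetic import (
    AcquisitionModel,
    EctopicSpec,
    IonicParams,
    LesionSpec,
    PacingProtocol,
    PreparationConfig,
    TissueGrid,
    generate_preparation,
)

log = logging.getLogger("vftrig")

CONFIG_SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class AnalysisParams:
    """Analysis-side tunables for a study run."""

    snr_min: float = 5.0
    gradient_sigma_px: float = 1.0
    nontrigger_sites: int = 3
    nontrigger_clearance_mm: float = 10.0
    origin_percentile: float = 1.0
    n_first_cycles: int = 5
    manual_threshold_ms: float | None = None


@dataclass
class StudyConfig:
    """Full study description: generator + analysis + bookkeeping."""

    grid: TissueGrid = field(default_factory=TissueGrid)
    ionic: IonicParams = field(default_factory=IonicParams)
    lesion: LesionSpec = field(default_factory=LesionSpec)
    pacing: PacingProtocol = field(default_factory=PacingProtocol)
    ectopic: EctopicSpec | None = field(default_factory=EctopicSpec)
    acquisition: AcquisitionModel = field(default_factory=AcquisitionModel)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    n_preparations: int = 4
    seed: int = 1
    duration_ms: float | None = None
    dt_ms: float = 0.05
    schema_version: str = CONFIG_SCHEMA_VERSION

    def prep_config(self) -> PreparationConfig:
        return PreparationConfig(
            grid=self.grid, ionic=self.ionic, lesion=self.lesion,
            pacing=self.pacing, ectopic=self.ectopic,
            acquisition=self.acquisition, duration_ms=self.duration_ms,
            dt_ms=self.dt_ms,
        )

    def to_dict(self) -> dict:
        d = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            d[f.name] = dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
        return d


_SECTIONS = {
    "grid": TissueGrid,
    "ionic": IonicParams,
    "lesion": LesionSpec,
    "pacing": PacingProtocol,
    "ectopic": EctopicSpec,
    "acquisition": AcquisitionModel,
    "analysis": AnalysisParams,
}
_SCALARS = {"n_preparations", "seed", "duration_ms", "dt_ms", "schema_version"}


def _build_section(cls, data: dict, errors: list, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    for k in sorted(unknown):
        errors.append(f"{section}: unknown key '{k}'")
    kwargs = {k: v for k, v in data.items() if k in names}
    for key in ("center_px", "site_px", "coupling_clip_ms", "pacing_match_ms"):
        if isinstance(kwargs.get(key), list):
            kwargs[key] = tuple(kwargs[key])
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{section}: {exc}")
        return None


def validate_config(path) -> StudyConfig:
    """Load, schema-check and normalize a YAML/JSON study config.

    Raises ``ValueError`` with a human-readable error list on violations.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> StudyConfig:
    errors: list = []
    unknown = set(raw) - set(_SECTIONS) - _SCALARS
    for k in sorted(unknown):
        errors.append(f"unknown top-level key '{k}'")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            if raw[name] is None and name == "ectopic":
                kwargs[name] = None
                continue
            if not isinstance(raw[name], dict):
                errors.append(f"{name}: expected a mapping")
                continue
            built = _build_section(cls, raw[name], errors, name)
            if built is not None:
                kwargs[name] = built
    for name in _SCALARS & set(raw):
        kwargs[name] = raw[name]
    if errors:
        raise ValueError("invalid study config:\n  " + "\n  ".join(errors))
    return StudyConfig(**kwargs)


# ---------------------------------------------------------------------------
# Per-preparation analysis
# ---------------------------------------------------------------------------


def analyze_preparation(
    movie: OpticalMovie,
    ecg: EcgRecord,
    prep_id: str,
    analysis: AnalysisParams | None = None,
    seed: int = 0,
):
    """Run the full analysis chain on one preparation.

    Returns a dict with beats, episodes, maps, geometry, site measurements
    and the trigger report (fields are None when no trigger was found).
    """
    analysis = analysis or AnalysisParams()
    res: dict = {"prep": prep_id}
    beats = ev.classify_pvc(ev.detect_beats(ecg))
    for k, b in enumerate(beats):
        if b.kind == "pvc" and k > 0:
            prior = beats[k - 2] if k >= 2 else None
            flag, t_end, _ = ev.twave_overlap(ecg, b, beats[k - 1], prior=prior)
            b.r_on_t = flag
            b.t_end_ms = t_end
    episodes = ev.detect_vf(ecg, beats)
    res["beats"] = beats
    res["episodes"] = episodes

    mp = MapParams(snr_min=analysis.snr_min)
    cond = condition_movie(movie, mp)
    windows = windows_from_beats(beats, movie)
    pvc_idx = next((k for k, b in enumerate(beats) if b.kind == "pvc"), None)
    if pvc_idx is None or pvc_idx == 0:
        log.info("%s: no ectopic beat found", prep_id)
        res.update(maps=None, geometry=None, trigger=None, report=None,
                   nontrigger_sites=None)
        return res
    win_by_idx = {w.index: w for w in windows}
    # substrate maps come from the latest pre-trigger beat whose
    # repolarization is complete: the beat before the last one, since the
    # premature complex truncates repolarization around its own origin
    pre_idx = pvc_idx - 2 if pvc_idx >= 2 and (pvc_idx - 2) in win_by_idx else pvc_idx - 1
    if pre_idx not in win_by_idx or pvc_idx not in win_by_idx:
        res.update(maps=None, geometry=None, trigger=None, report=None,
                   nontrigger_sites=None)
        return res

    pre_maps = build_maps(movie, [win_by_idx[pre_idx]], mp, conditioned=cond)[pre_idx]
    apd_grad = geo.local_gradient(pre_maps["APD80"], analysis.gradient_sigma_px)
    rt_grad = geo.local_gradient(pre_maps["RT"], analysis.gradient_sigma_px)
    geometry = geo.delineate_border(
        pre_maps["APD80"], manual_threshold_ms=analysis.manual_threshold_ms
    )
    origin = ph.localize_trigger(
        movie, win_by_idx[pvc_idx], mp,
        percentile=analysis.origin_percentile, conditioned=cond,
    )
    trig_site = geo.measure_trigger_site(origin.site_px, geometry, apd_grad, rt_grad)
    nontrig = geo.sample_nontrigger_sites(
        geometry, apd_grad, rt_grad, n=analysis.nontrigger_sites, seed=seed,
        clearance_mm=analysis.nontrigger_clearance_mm,
    )

    pattern: list = []
    try:
        # cycle boundaries from the ECG-detected post-trigger beats
        bounds = [
            b.onset_ms for b in beats[pvc_idx: pvc_idx + analysis.n_first_cycles + 1]
        ] if analysis.n_first_cycles > 0 else []
        if 0 < len(bounds) < 2:
            bounds = ph.cycle_bounds_from_activity(
                movie, origin.site_px, beats[pvc_idx].onset_ms - 20.0,
                max_cycles=analysis.n_first_cycles,
            )
        if len(bounds) >= 2:
            phase_movie = ph.compute_phase(
                movie,
                window_ms=(max(movie.t0_ms, bounds[0] - 200.0),
                           min(movie.times_ms[-1], bounds[-1] + 100.0)),
                valid=pre_maps["APD80"].valid,
            )
            per_frame = [
                ph.detect_singularities(phase_movie, f)
                for f in range(phase_movie.phase.shape[0])
            ]
            tracks = ph.track_singularities(per_frame)
            pattern = ph.classify_first_cycles(
                phase_movie, tracks, origin.site_px, bounds,
                n_cycles=analysis.n_first_cycles,
            )
    except ValueError as exc:
        log.info("%s: phase analysis skipped (%s)", prep_id, exc)

    report = ph.TriggerReport(
        episode_id=prep_id,
        origin_site_px=origin.site_px,
        origin_time_ms=origin.time_ms,
        distance_to_border_mm=trig_site.distance_to_border_mm,
        border_zone=trig_site.in_border_zone,
        apd_gradient_ms_mm=trig_site.apd_gradient_ms_mm,
        rt_gradient_ms_mm=trig_site.rt_gradient_ms_mm,
        pattern_sequence=pattern,
    )
    res.update(
        maps=pre_maps, geometry=geometry, trigger=trig_site,
        nontrigger_sites=nontrig, report=report, origin=origin,
    )
    return res


# ---------------------------------------------------------------------------
# Study driver
# ---------------------------------------------------------------------------


def run_study(config: StudyConfig, out_dir) -> Path:
    """Generate and analyze every preparation; write tables, report, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(name)s %(message)s")
    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(config.seed).spawn(max(config.n_preparations, 1))
    ]
    prep_cfg = config.prep_config()
    per_prep = {}
    trigger_sites = []
    nontrigger_sites = []
    trigger_reports = []
    beat_rows = []
    episode_rows = []
    for i in range(config.n_preparations):
        prep_id = f"prep{i:03d}"
        pdir = out / prep_id
        pdir.mkdir(exist_ok=True)
        log.info("%s: generating (seed %d)", prep_id, seeds[i])
        try:
            movie, ecg, truth = generate_preparation(prep_cfg, seeds[i])
            movie.save(pdir / "movie.tif")
            ecg.save(pdir / "ecg.csv")
            truth.save(pdir / "truth.json")
            log.info("%s: analyzing", prep_id)
            res = analyze_preparation(
                movie, ecg, prep_id, config.analysis, seed=seeds[i]
            )
        except Exception as exc:
            raise RuntimeError(
                f"stage failure in {prep_id}: {exc}; partial outputs in {pdir}"
            ) from exc
        per_prep[prep_id] = (res["beats"], res["episodes"])
        for b in res["beats"]:
            beat_rows.append(
                {"prep": prep_id, "onset_ms": b.onset_ms, "kind": b.kind,
                 "coupling_ms": b.coupling_ms, "r_on_t": b.r_on_t,
                 "t_end_ms": b.t_end_ms}
            )
        for e in res["episodes"]:
            episode_rows.append(
                {"prep": prep_id, "start_ms": e.start_ms, "end_ms": e.end_ms,
                 "duration_s": e.duration_s, "sustained": e.sustained,
                 "spontaneous": e.spontaneous,
                 "trigger_coupling_ms": e.trigger.coupling_ms if e.trigger else None}
            )
        if res.get("trigger") is not None:
            trigger_sites.append(res["trigger"])
            nontrigger_sites.extend(res["nontrigger_sites"])
            trigger_reports.append(res["report"].to_dict())
            (pdir / "trigger_report.json").write_text(
                json.dumps(res["report"].to_dict(), indent=1)
            )
            for kind, m in res["maps"].items():
                m.save(pdir / f"map_{kind.lower()}.tif")
            res["geometry"].save(pdir / "border")

    pd.DataFrame(beat_rows).to_csv(out / "beats.csv", index=False)
    pd.DataFrame(episode_rows).to_csv(out / "episodes.csv", index=False)
    summary = ev.episode_summary(per_prep)
    summary.to_csv(out / "episode_summary.csv", index=False)
    tables = {
        "config": config.to_dict(),
        "seeds": seeds,
        "episode_summary": summary,
        "trigger_reports": trigger_reports,
        "version": _version(),
    }
    if trigger_sites and nontrigger_sites:
        gc = st.gradient_comparison(trigger_sites, nontrigger_sites)
        tables["gradient_comparison"] = gc
        (out / "gradient_comparison.json").write_text(json.dumps(gc, indent=1))
    st.render_report(tables, out / "report.md")
    _write_manifest(out)
    return out


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("vftrig")
    except Exception:
        return "unknown"


def _write_manifest(out: Path) -> None:
    entries = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            entries[str(p.relative_to(out))] = hashlib.sha256(
                p.read_bytes()
            ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(entries, indent=1))
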