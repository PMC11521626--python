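"""End-to-end orchestration: simulate -> geolocate -> behaviour -> phenology
-> environment -> summary -> infer.

Every stage writes plain CSV artifacts under ``out_dir`` together with a
JSON manifest recording a content key per stage (a hash of the config and
of upstream stage keys).  Re-running with an unchanged config skips stages
whose key matches and whose outputs exist; deleting an artifact recomputes
only that stage and its descendants.  Row counts in and out of each filter
are recorded and must reconcile.
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

from . import environment as env
from . import immersion as imm
from . import inference as inf
from . import io as sio
from . import lightgeo, phenology, solar, synthio

log = logging.getLogger("shearlog")


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    n_birds: int = 8
    n_years: int = 3
    first_year: int = 2008
    colony_name: str = "Skomer"
    colony_lat: float = 51.74
    colony_lon: float = -5.29

    light_threshold: float = 10.0
    angle_candidates: tuple = lightgeo.DEFAULT_ANGLE_CANDIDATES
    equinox_mask_days: float = 15.0
    phenology_min_run_days: int = phenology.DEFAULT_MIN_RUN_DAYS
    phenology_displacement_deg: float = phenology.DEFAULT_DISPLACEMENT_DEG
    min_dry_hours: float = 6.0
    mixture_scope: str = "bird"          # bird | colony-year | pooled
    peak_method: str = "zonal-mean"
    include_burrow_days: bool = True
    january: int = 1
    august: int = 8
    n_boot: int = 1000
    sim_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.light_threshold:
            raise ValueError("light threshold must be positive")
        if self.mixture_scope not in ("bird", "colony-year", "pooled"):
            raise ValueError("mixture_scope must be bird | colony-year | pooled")
        if self.peak_method not in ("zonal-mean", "max-cell"):
            raise ValueError("peak_method must be zonal-mean | max-cell")

    # -- serialisation ----------------------------------------------------
    def to_yaml(self, path=None) -> str:
        d = dataclasses.asdict(self)
        d["angle_candidates"] = list(d["angle_candidates"])
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = yaml.safe_load(text)
        d["angle_candidates"] = tuple(d.get("angle_candidates",
                                            lightgeo.DEFAULT_ANGLE_CANDIDATES))
        return cls(**d)

    def sim_config(self) -> synthio.SimConfig:
        return synthio.SimConfig(
            n_birds=self.n_birds, n_years=self.n_years, first_year=self.first_year,
            colony=synthio.Colony(self.colony_name, self.colony_lat, self.colony_lon),
            seed=self.seed, **self.sim_overrides)

    def key(self, *extra) -> str:
        h = hashlib.sha256(self.to_yaml().encode())
        for e in extra:
            h.update(str(e).encode())
        return h.hexdigest()[:16]


@dataclass
class PipelineResult:
    summary: pd.DataFrame
    reports: dict
    stages_run: list
    out_dir: Path


class _Manifest:
    def __init__(self, out_dir: Path):
        self.path = out_dir / "manifest.json"
        self.data = json.loads(self.path.read_text()) if self.path.exists() else {}

    def fresh(self, stage: str, key: str, outputs: list) -> bool:
        entry = self.data.get(stage)
        return (entry is not None and entry["key"] == key
                and all(Path(p).exists() for p in entry["outputs"])
                and entry["outputs"] == [str(p) for p in outputs])

    def record(self, stage: str, key: str, outputs: list):
        gen = self.data.get(stage, {}).get("gen", 0) + 1
        self.data[stage] = {"key": key, "outputs": [str(p) for p in outputs],
                            "gen": gen}
        self.path.write_text(json.dumps(self.data, indent=1))

    def token(self, stage: str) -> str:
        """Upstream token for descendant keys: changes whenever the stage
        reruns, so descendants rerun too."""
        entry = self.data.get(stage, {})
        return f"{entry.get('key')}:{entry.get('gen', 0)}"


def _night_interval(date, lat, lon):
    """(sunset of ``date``, sunrise of the next day) at a position."""
    _, ss = solar.sunrise_sunset(date, lat, lon, angle=0.0)
    sr, _ = solar.sunrise_sunset(pd.Timestamp(date) + pd.Timedelta(days=1), lat, lon, angle=0.0)
    if ss is None or sr is None:
        return None
    return ss, sr


def _month_slice(trace: pd.DataFrame, col: str, year: int, month: int) -> pd.DataFrame:
    t = pd.DatetimeIndex(trace[col])
    return trace[(t.year == year) & (t.month == month)]


def run_pipeline(config: RunConfig) -> PipelineResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out_dir)
    stages_run = []
    reports = {"filters": {}, "errors": {}}
    cfg = config.sim_config()
    bird_years = [(b, y) for b in range(cfg.n_birds)
                  for y in synthio.deployment_years(cfg, b)]
    index = synthio.simulate_index(cfg)

    # ---- stage: simulate (truth + environment artifacts) -----------------
    key = config.key("simulate")
    truth_files = [out_dir / f for f in
                   ("truth_positions.csv", "truth_phenology.csv", "truth_winter.csv",
                    "index.csv", "chl_peaks.csv")]
    if manifest.fresh("simulate", key, truth_files):
        truth_positions = pd.read_csv(truth_files[0], parse_dates=["date"], float_precision="round_trip")
        truth_phenology = pd.read_csv(
            truth_files[1], parse_dates=["southbound_start", "northbound_start",
                                         "northbound_end"], float_precision="round_trip")
        chl_fields = {y: sio.read_chlorophyll_csv(out_dir / f"chl_{y}.csv", y)
                      for y in range(cfg.first_year, cfg.first_year + cfg.n_years + 1)}
    else:
        stages_run.append("simulate")
        truth = synthio.simulate_dataset(cfg, with_sensors=False)
        truth_positions, truth_phenology = truth.positions, truth.phenology
        chl_fields = truth.chlorophyll
        truth.positions.to_csv(truth_files[0], index=False)
        truth.phenology.to_csv(truth_files[1], index=False)
        truth.winter.to_csv(truth_files[2], index=False)
        sio.write_index_csv(truth.index, truth_files[3])
        truth.chl_peaks.to_csv(truth_files[4], index=False)
        for y, f in chl_fields.items():
            sio.write_chlorophyll_csv(f, out_dir / f"chl_{y}.csv")
        manifest.record("simulate", key, truth_files)

    sensors = {}

    def get_sensors(bird, year):
        if (bird, year) not in sensors:
            sensors[(bird, year)] = synthio.simulate_bird_year(cfg, bird, year, index)
        return sensors[(bird, year)]

    # ---- stage: geolocate ------------------------------------------------
    key = config.key("geolocate", manifest.token("simulate"))
    pos_file = out_dir / "positions.csv"
    if manifest.fresh("geolocate", key, [pos_file]):
        positions = pd.read_csv(pos_file, parse_dates=["date"], float_precision="round_trip")
    else:
        stages_run.append("geolocate")
        frames = []
        for bird, year in bird_years:
            light = get_sensors(bird, year)["light"]
            summer = light[pd.DatetimeIndex(light["timestamp"]).month.isin((6, 7))]
            try:
                angle = lightgeo.calibrate_sun_elevation(
                    summer, config.colony_lat, candidates=config.angle_candidates,
                    threshold=config.light_threshold)
            except ValueError:
                angle = float(np.median(config.angle_candidates))
            pos = lightgeo.estimate_positions(light, angle, config.light_threshold)
            pos = lightgeo.smooth_positions(pos)
            pos.insert(0, "year", year)
            pos.insert(0, "bird", bird)
            pos["angle"] = angle
            frames.append(pos)
        positions = pd.concat(frames, ignore_index=True)
        positions.to_csv(pos_file, index=False)
        manifest.record("geolocate", key, [pos_file])
    reports["filters"]["geolocate"] = {
        "rows_in": int(len(positions)),
        "rows_excluded": int((~positions["valid"]).sum()),
        "rows_out": int(positions["valid"].sum())}
    assert (reports["filters"]["geolocate"]["rows_in"]
            - reports["filters"]["geolocate"]["rows_excluded"]
            == reports["filters"]["geolocate"]["rows_out"])

    # ---- stage: phenology --------------------------------------------------
    key = config.key("phenology", manifest.token("geolocate"))
    phen_file = out_dir / "phenology.csv"
    if manifest.fresh("phenology", key, [phen_file]):
        phen = pd.read_csv(phen_file, parse_dates=["southbound_start", "northbound_start",
                                                   "northbound_end"], float_precision="round_trip")
    else:
        stages_run.append("phenology")
        rows = []
        for bird, year in bird_years:
            sel = positions[(positions["bird"] == bird) & (positions["year"] == year)]
            dates = phenology.detect_migration_dates(
                sel.rename(columns={"longitude": "longitude"})[["date", "longitude"]],
                config.colony_lon, config.phenology_min_run_days,
                config.phenology_displacement_deg)
            rows.append({"bird": bird, "year": year,
                         "southbound_start": dates.southbound_start,
                         "northbound_start": dates.northbound_start,
                         "northbound_end": dates.northbound_end,
                         "confidence": dates.confidence, "reason": dates.reason})
        phen = pd.DataFrame(rows)
        phen.to_csv(phen_file, index=False)
        manifest.record("phenology", key, [phen_file])

    # ---- stage: behaviour --------------------------------------------------
    key = config.key("behaviour", manifest.token("geolocate"))
    beh_file = out_dir / "behaviour.csv"
    nights_file = out_dir / "nights.csv"
    if manifest.fresh("behaviour", key, [beh_file, nights_file]):
        behaviour = pd.read_csv(beh_file, float_precision="round_trip")
    else:
        stages_run.append("behaviour")
        behaviour, night_frames = _behaviour_stage(
            config, cfg, bird_years, positions, get_sensors)
        behaviour.to_csv(beh_file, index=False)
        (pd.concat(night_frames, ignore_index=True) if night_frames else
         pd.DataFrame()).to_csv(nights_file, index=False)
        manifest.record("behaviour", key, [beh_file, nights_file])

    # ---- stage: environment ------------------------------------------------
    key = config.key("environment", manifest.token("simulate"))
    env_file = out_dir / "environment.csv"
    if manifest.fresh("environment", key, [env_file]):
        env_table = pd.read_csv(env_file, float_precision="round_trip")
    else:
        stages_run.append("environment")
        soi = env.soi_ond(index).rename(columns={"value": "soi_ond"})
        naow = env.nao_winter(index).rename(columns={"value": "nao_winter"})
        naos = env.nao_summer(index).rename(columns={"value": "nao_summer"})
        chl_rows = []
        for y, f in chl_fields.items():
            lat, reason = env.chlorophyll_peak_latitude(f, method=config.peak_method)
            chl_rows.append({"year": y, "chl_peak_latitude": lat, "chl_reason": reason})
        env_table = (soi[["year", "soi_ond"]]
                     .merge(naow[["year", "nao_winter"]], on="year", how="outer")
                     .merge(naos[["year", "nao_summer"]], on="year", how="outer")
                     .merge(pd.DataFrame(chl_rows), on="year", how="outer"))
        env_table.to_csv(env_file, index=False)
        manifest.record("environment", key, [env_file])

    # ---- stage: summary (BirdYearSummary) ----------------------------------
    key = config.key("summary", *(manifest.token(s) for s in
                                  ("phenology", "behaviour", "environment")))
    sum_file = out_dir / "bird_year_summary.csv"
    if manifest.fresh("summary", key, [sum_file]):
        summary = pd.read_csv(sum_file, parse_dates=["southbound_start", "northbound_start",
                                                     "northbound_end"], float_precision="round_trip")
    else:
        stages_run.append("summary")
        summary = _summary_stage(config, positions, phen, behaviour, env_table)
        summary.to_csv(sum_file, index=False)
        manifest.record("summary", key, [sum_file])
    rows_complete = int(summary.dropna(subset=["january_latitude"]).shape[0])
    reports["filters"]["summary"] = {
        "rows_in": int(len(summary)),
        "rows_excluded": int(len(summary)) - rows_complete,
        "rows_out": rows_complete}

    # ---- stage: infer -----------------------------------------------------
    reports["inference"] = _inference_stage(config, summary, out_dir)
    return PipelineResult(summary=summary, reports=reports,
                          stages_run=stages_run, out_dir=out_dir)


def _behaviour_stage(config, cfg, bird_years, positions, get_sensors):
    rows, night_frames = [], []
    for bird, year in bird_years:
        sens = get_sensors(bird, year)
        trace = sens["immersion"]
        # January at the estimated mean position
        sel = positions[(positions["bird"] == bird) & (positions["year"] == year)]
        jan = lightgeo.mean_monthly_position(sel, month=config.january,
                                     equinox_mask_days=config.equinox_mask_days)
        jan_foraging = np.nan
        if np.isfinite(jan["latitude"]):
            jan_trace = _month_slice(trace, "bin_start", year + 1, config.january)
            if len(jan_trace):
                mid = pd.DatetimeIndex(jan_trace["bin_start"]) + pd.Timedelta(minutes=5)
                is_day = solar.solar_elevation(mid, jan["latitude"], jan["longitude"]) > 0
                decl = solar.declination_on(f"{year + 1}-01-15")
                dl = solar.day_length(jan["latitude"], decl, 0.0)
                states = imm.classify_states(jan_trace)
                try:
                    eff = imm.foraging_effort(states, is_day, dl, period="january")
                    jan_foraging = eff.proportion
                except ValueError:
                    pass
        # breeding-season nights at the colony (July of year .. August of year)
        night_rows = []
        for day in pd.date_range(f"{year}-07-01", f"{year}-08-31", freq="D"):
            interval = _night_interval(day, config.colony_lat, config.colony_lon)
            if interval is None:
                continue
            cnt = imm.count_night_wet_events(trace, interval)
            if cnt is not None:
                night_rows.append({"bird": bird, "year": year, "night_date": day,
                                   "wet_event_count": cnt,
                                   "sunset": interval[0], "sunrise": interval[1]})
        nights = pd.DataFrame(night_rows)
        # August foraging at the colony day length, colony bins excluded
        aug_trace = _month_slice(trace, "bin_start", year, config.august)
        aug_foraging, aug_visits = np.nan, np.nan
        incub_evidence, _ = imm.detect_incubation(trace)
        if len(nights) >= 20 and nights["wet_event_count"].nunique() > 1:
            try:
                fit = imm.fit_night_mixture(nights["wet_event_count"], seed=config.seed)
            except ValueError as exc:
                log.warning("mixture degenerate for bird %s year %s: %s",
                            bird, year, exc)
                rows.append({"bird": bird, "year": year,
                             "january_latitude": jan["latitude"],
                             "january_longitude": jan["longitude"],
                             "january_foraging": jan_foraging,
                             "august_foraging": np.nan, "august_visits": np.nan,
                             "breeding_evidence": bool(incub_evidence)})
                continue
            nights = imm.classify_night_visits(nights, fit)
            burrow_days = []
            colony_bins = np.zeros(len(aug_trace), dtype=bool)
            tbin = pd.DatetimeIndex(aug_trace["bin_start"])
            for day in pd.date_range(f"{year}-08-01", f"{year}-08-31", freq="D"):
                sr, ss = solar.sunrise_sunset(day, config.colony_lat, config.colony_lon, 0.0)
                if sr is None:
                    continue
                day_trace = aug_trace[(tbin >= day) & (tbin < day + pd.Timedelta(days=1))]
                for a, b in imm.detect_daytime_burrow(day_trace, sr, ss, config.min_dry_hours):
                    burrow_days.append(day)
                    colony_bins |= np.asarray((tbin >= a) & (tbin < b))
            for _, nrow in nights[nights["is_visit"]].iterrows():
                colony_bins |= np.asarray((tbin >= nrow["sunset"]) & (tbin < nrow["sunrise"]))
            aug_visits = imm.count_colony_visits(
                nights, month=config.august, burrow_days=burrow_days,
                include_burrow_days=config.include_burrow_days)
            if len(aug_trace):
                mid = tbin + pd.Timedelta(minutes=5)
                is_day = solar.solar_elevation(mid, config.colony_lat, config.colony_lon) > 0
                decl = solar.declination_on(f"{year}-08-15")
                dl = solar.day_length(config.colony_lat, decl, 0.0)
                states = imm.classify_states(aug_trace, at_sea_mask=~colony_bins)
                try:
                    eff = imm.foraging_effort(states, is_day, dl, period="august")
                    aug_foraging = eff.proportion
                except ValueError:
                    pass
            night_frames.append(nights)
        rows.append({"bird": bird, "year": year,
                     "january_latitude": jan["latitude"],
                     "january_longitude": jan["longitude"],
                     "january_foraging": jan_foraging,
                     "august_foraging": aug_foraging,
                     "august_visits": aug_visits,
                     "breeding_evidence": bool(incub_evidence)})
    return pd.DataFrame(rows), night_frames


def _summary_stage(config, positions, phen, behaviour, env_table):
    """One row per bird-year with same-cycle and next-breeding-season terms.

    A bird-year runs July(y)-June(y+1): August foraging/visits of year y
    are the *previous* breeding season relative to that cycle's January,
    and the following August (bird-year y+1) supplies the carry-over
    response terms.
    """
    summary = behaviour.rename(columns={"august_foraging": "august_foraging_prev",
                                        "august_visits": "august_visits_prev"})
    nxt = behaviour[["bird", "year", "august_foraging", "august_visits"]].copy()
    nxt["year"] -= 1
    summary = summary.merge(nxt, on=["bird", "year"], how="left")
    summary = summary.merge(phen.drop(columns=["confidence", "reason"]),
                            on=["bird", "year"], how="left")
    e = env_table.rename(columns={"year": "jan_year"})
    summary["jan_year"] = summary["year"] + 1
    # OND index of year y sets conditions for January of y+1
    soi = env_table[["year", "soi_ond"]]
    summary = summary.merge(soi, on="year", how="left")
    summary = summary.merge(
        e[["jan_year", "nao_winter", "nao_summer", "chl_peak_latitude"]],
        on="jan_year", how="left").drop(columns=["jan_year"])
    summary["skipped_breeding"] = ~summary["breeding_evidence"].astype(bool)
    for c in ("southbound_start", "northbound_start", "northbound_end"):
        summary[c] = pd.DatetimeIndex(summary[c])
        summary[c + "_doy"] = summary[c].dt.dayofyear.astype(float)
    return summary


def _inference_stage(config, summary, out_dir: Path):
    report = {}
    data = summary.rename(columns={"soi_ond": "soi"}).copy()
    for c in ("southbound_start", "northbound_start", "northbound_end"):
        data[c] = data[c + "_doy"]
    spec = inf.figure_graph_spec()
    try:
        res = inf.fit_path_model(spec, data, standardize=True)
        res.edges.to_csv(out_dir / "path_edges.csv", index=False)
        (out_dir / "fit_indices.json").write_text(json.dumps(res.fit, indent=1))
        k = len(res.edges)
        sub = data[spec.variables].dropna()
        corr = sub.corr().abs().to_numpy()
        mean_r = float(corr[np.triu_indices_from(corr, k=1)].mean())
        report["path"] = {"fit": res.fit, "n": res.n,
                          "alpha_per_test": inf.sem_bonferroni_alpha(k, mean_r)}
    except (ValueError, np.linalg.LinAlgError) as exc:
        report["path"] = {"error": str(exc)}
    try:
        cr = inf.subject_centring(data.dropna(subset=["soi", "january_latitude"]),
                                  "soi", "january_latitude", "bird",
                                  n_boot=config.n_boot, seed=config.seed)
        report["centring"] = {"within": cr.within, "within_ci": cr.within_ci,
                              "between": cr.between, "between_ci": cr.between_ci,
                              "difference_ci": cr.difference_ci,
                              "n": cr.n, "n_birds": cr.n_birds}
    except ValueError as exc:
        report["centring"] = {"error": str(exc)}
    try:
        fit = inf.fit_lmm(data.dropna(subset=["chl_peak_latitude", "january_latitude"]),
                          "january_latitude", ["chl_peak_latitude"], "bird",
                          focal="chl_peak_latitude", n_boot=config.n_boot,
                          seed=config.seed)
        report["chl_tracking"] = {"beta": float(fit.beta["chl_peak_latitude"]),
                                  "lrt": fit.lrt}
    except ValueError as exc:
        report["chl_tracking"] = {"error": str(exc)}
    if data["skipped_breeding"].nunique() > 1 and data["january_foraging"].notna().any():
        try:
            report["skip_glm"] = inf.fit_skip_glm(data)
        except ValueError as exc:
            report["skip_glm"] = {"error": str(exc)}
    (out_dir / "inference_report.json").write_text(
        json.dumps(report, indent=1, default=str))
    return report
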