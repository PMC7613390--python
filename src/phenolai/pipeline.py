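"""End-to-end orchestration: simulate -> retrieve -> collections ->
phenology -> map -> evaluate, with a reproducibility manifest.

Each stage reads and writes plain files under the run directory, so the
stages can be run individually (and a run can start from an external LAI
CSV, skipping simulation and retrieval). One global seed fans out to
stage-specific seeds by fixed offsets, keeping partial re-runs
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .calendar import nile_delta_calendar
from .config import RunConfig
from .evaluation import area_los_regression, crop_stats, detection_accuracy
from .mapping import cropping_frequency, lsp_maps, pixel_phenology, vegetation_mask
from .phenology import extract_seasons, seasons_to_frame
from .raster import SceneStack
from .retrieval import resample_pairs_to_l8, retrieve_lai, train_lai_model
from .series import SampledSeries, read_series_csv, write_series_csv
from .synthetic import (AcquisitionSchedule, build_parcel_set, forward_model,
                        grid_parcels, render_scene, sample_series,
                        spectra_lai_pairs, write_parcels_geojson)
from .timeseries import build_collections

__all__ = ["Pipeline", "StageError", "COLLECTIONS", "METHODS"]

log = logging.getLogger("phenolai.pipeline")

COLLECTIONS = ("S30", "L30", "SL30_SG", "SL30_GPR")
METHODS = ("seasonal", "relative")

# fixed fan-out offsets of the global seed per stochastic stage
SEED_OFFSETS = {"simulate": 0, "retrieval": 1009, "collections": 2003,
                "mapping": 3001}


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class Pipeline:
    def __init__(self, cfg: RunConfig, outdir):
        self.cfg = cfg
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.calendar = nile_delta_calendar()
        self._manifest: dict = {"config": cfg.raw, "version": __version__,
                                "stages": {}}

    def _stage_seed(self, stage: str) -> int:
        return (self.cfg.seed + SEED_OFFSETS[stage]) % (2**31)

    def _run_stage(self, name: str, fn):
        t0 = time.perf_counter()
        log.info("stage %s: start", name)
        try:
            outputs = fn() or []
        except Exception as err:  # noqa: BLE001 - annotate stage context
            raise StageError(name, err) from err
        dt = time.perf_counter() - t0
        self._manifest["stages"][name] = {
            "seconds": round(dt, 3),
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
        log.info("stage %s: done in %.2fs (%d outputs)", name, dt, len(outputs))
        return outputs

    # -- stages -------------------------------------------------------------

    def simulate(self):
        return self._run_stage("simulate", self._simulate)

    def _simulate(self):
        cfg, sc = self.cfg, self.cfg.scenario
        seed = self._stage_seed("simulate")
        years = cfg.years
        # simulate one extra year so winter seasons of the last year close
        end = 365.0 * (len(years) + 1)
        truths, planted = build_parcel_set(
            int(sc["n_parcels"]), years, seed=seed,
            double_frac=float(sc["double_frac"]), calendar=self.calendar,
            epoch_year=cfg.epoch_year, base_lai=float(sc["base_lai"]))
        rng = np.random.default_rng(seed)
        rows_s2, rows_l8 = [], []
        for pid, truth in truths.items():
            s2 = sample_series(
                truth, AcquisitionSchedule("S2", float(sc["s2_revisit"]),
                                           jitter=float(sc["jitter"]),
                                           gap_prob=float(sc["s2_gap_prob"]),
                                           end=end),
                noise_sd=float(sc["noise_sd"]), seed=int(rng.integers(2**31)),
                parcel_id=pid, epoch_year=cfg.epoch_year)
            l8 = sample_series(
                truth, AcquisitionSchedule("L8", float(sc["l8_revisit"]),
                                           jitter=float(sc["jitter"]),
                                           gap_prob=float(sc["l8_gap_prob"]),
                                           end=end),
                noise_sd=float(sc["noise_sd"]), seed=int(rng.integers(2**31)),
                parcel_id=pid, epoch_year=cfg.epoch_year)
            rows_s2.append(s2)
            rows_l8.append(l8)
        self._truths = truths
        p_s2 = self.outdir / "series_s2.csv"
        p_l8 = self.outdir / "series_l8.csv"
        p_pl = self.outdir / "planted.csv"
        write_series_csv(p_s2, rows_s2)
        write_series_csv(p_l8, rows_l8)
        planted.to_csv(p_pl, index=False)
        return [p_s2, p_l8, p_pl]

    def retrieve(self):
        if not self.cfg.retrieval["enabled"]:
            log.info("stage retrieve: disabled, skipping")
            return []
        return self._run_stage("retrieve", self._retrieve)

    def _retrieve(self):
        """Round-trip the simulated LAI through spectra and GPR models.

        The S2-dialect model is trained on synthetic pairs; the L8 model on
        the same pairs resampled to the 6-band dialect. Each sensor's LAI
        series is mapped to reflectance with the forward model and
        retrieved back, replacing the series used downstream.
        """
        rc = self.cfg.retrieval
        seed = self._stage_seed("retrieval")
        pairs10 = spectra_lai_pairs(int(rc["n_train"]), "S2-10band", seed=seed,
                                    noise_sd=float(rc["noise_sd"]))
        model_s2 = train_lai_model(pairs10, "S2-10band", seed=seed)
        model_l8 = train_lai_model(resample_pairs_to_l8(pairs10), "L8-6band",
                                   seed=seed)
        outputs = []
        for tag, model in (("s2", model_s2), ("l8", model_l8)):
            mpath = self.outdir / f"lai_model_{tag}.json"
            model.save(mpath)
            outputs.append(mpath)
            dialect = "S2-10band" if tag == "s2" else "L8-6band"
            series = read_series_csv(self.outdir / f"series_{tag}.csv",
                                     epoch_year=self.cfg.epoch_year)
            out = {}
            for pid, s in series.items():
                refl = forward_model(np.maximum(s.values, 0.0), dialect)
                res = retrieve_lai(model, refl)
                out[pid] = SampledSeries(s.times, res.lai, sd=res.lai_sd,
                                         sensor=s.sensor, parcel_id=pid,
                                         epoch_year=s.epoch_year)
            path = self.outdir / f"series_{tag}.csv"
            write_series_csv(path, out)
            outputs.append(path)
        return outputs

    def build_collections(self):
        return self._run_stage("collections", self._build_collections)

    def _build_collections(self):
        cfg = self.cfg
        if cfg.lai_csv:
            df = pd.read_csv(cfg.lai_csv)
            if "sensor" not in df.columns:
                df["sensor"] = "S2"
            s2_map, l8_map = {}, {}
            for (pid, sensor), grp in df.groupby(["parcel_id", "sensor"]):
                store = s2_map if sensor == "S2" else l8_map
                store[str(pid)] = SampledSeries.from_frame(
                    grp, epoch_year=cfg.epoch_year)
        else:
            s2_map = read_series_csv(self.outdir / "series_s2.csv",
                                     epoch_year=cfg.epoch_year)
            l8_map = read_series_csv(self.outdir / "series_l8.csv",
                                     epoch_year=cfg.epoch_year)
        seed = self._stage_seed("collections")
        per_collection: dict[str, list] = {c: [] for c in COLLECTIONS}
        for pid in sorted(set(s2_map) & set(l8_map)):
            cols = build_collections(s2_map[pid], l8_map[pid],
                                     sg=cfg.sg_config(),
                                     grid_spacing=cfg.grid_spacing, seed=seed)
            for name, series in cols.items():
                per_collection[name].append(series)
        outputs = []
        manifest = {}
        for name, items in per_collection.items():
            path = self.outdir / f"collection_{name}.csv"
            write_series_csv(path, items)
            manifest[name] = {"method": "sg" if "GPR" not in name else "gpr",
                              "n_parcels": len(items)}
            outputs.append(path)
        mpath = self.outdir / "collections_manifest.json"
        mpath.write_text(json.dumps(manifest, indent=1))
        return outputs + [mpath]

    def phenology(self):
        return self._run_stage("phenology", self._phenology)

    def _phenology(self):
        cfg = self.cfg
        planted = self._read_planted()
        frames = []
        for coll in COLLECTIONS:
            series = read_series_csv(self.outdir / f"collection_{coll}.csv",
                                     epoch_year=cfg.epoch_year)
            for method in METHODS:
                dcfg = cfg.detection_config(method)
                for pid in sorted(series):
                    seasons = extract_seasons(series[pid], dcfg,
                                              calendar=self.calendar,
                                              planted=planted)
                    if seasons:
                        frames.append(seasons_to_frame(seasons, collection=coll))
        table = (pd.concat(frames, ignore_index=True) if frames
                 else seasons_to_frame([]))
        path = self.outdir / "seasons.csv"
        table.to_csv(path, index=False)
        return [path]

    def map(self):
        if not self.cfg.mapping["enabled"]:
            log.info("stage map: disabled, skipping")
            return []
        return self._run_stage("map", self._map)

    def _map(self):
        cfg, sc = self.cfg, self.cfg.scenario
        seed = self._stage_seed("mapping")
        if not hasattr(self, "_truths"):
            raise RuntimeError("mapping requires the simulate stage "
                               "(no truth curves available)")
        parcels, shape = grid_parcels(len(self._truths),
                                      parcel_size=int(cfg.mapping["parcel_size"]))
        end = 365.0 * (len(cfg.years) + 1)
        schedule = AcquisitionSchedule("S2", float(sc["s2_revisit"]),
                                       jitter=float(sc["jitter"]),
                                       gap_prob=float(sc["s2_gap_prob"]), end=end)
        stack, truth_maps = render_scene(parcels, self._truths, schedule,
                                         shape, seed=seed,
                                         noise_sd=float(sc["noise_sd"]),
                                         epoch_year=cfg.epoch_year)
        gpath = self.outdir / "parcels.geojson"
        write_parcels_geojson(parcels, gpath)
        mask = vegetation_mask(stack, float(cfg.mapping["mask_threshold"]))
        pix = pixel_phenology(stack, cfg.detection_config("seasonal"),
                              calendar=self.calendar, mask=mask)
        outputs = [gpath]
        scene_dir = self.outdir / "scene"
        outputs.append(stack.save(scene_dir))
        for year in cfg.years:
            freq = cropping_frequency(pix, year, shape, mask)
            maps = lsp_maps(pix, year, shape, mask)
            layers = [freq] + [maps[cls][m] for cls in ("summer", "winter")
                               for m in ("sos_doy", "eos_doy", "los_days", "area")]
            path = self.outdir / f"phenomap_{year}.tif"
            tifffile.imwrite(path, np.stack(layers).astype(np.float32))
            outputs.append(path)
        ppath = self.outdir / "pixel_seasons.csv"
        pix.to_csv(ppath, index=False)
        outputs.append(ppath)
        return outputs

    def evaluate(self):
        return self._run_stage("evaluate", self._evaluate)

    def _evaluate(self):
        seasons = pd.read_csv(self.outdir / "seasons.csv")
        planted = self._read_planted()
        outputs = []
        if len(seasons):
            per_crop, overall = crop_stats(seasons)
            p1 = self.outdir / "crop_stats.csv"
            p2 = self.outdir / "crop_stats_overall.csv"
            per_crop.to_csv(p1, index=False)
            overall.to_csv(p2, index=False)
            outputs += [p1, p2]
        acc_frames = []
        if planted is not None and len(planted):
            for coll in COLLECTIONS:
                for method in METHODS:
                    sel = seasons[(seasons["collection"] == coll)
                                  & (seasons["method"] == method)]
                    tab = detection_accuracy(sel, planted, self.calendar)
                    tab.insert(0, "collection", coll)
                    tab.insert(1, "method", method)
                    acc_frames.append(tab)
            acc = pd.concat(acc_frames, ignore_index=True)
            p3 = self.outdir / "detection_accuracy.csv"
            acc.to_csv(p3, index=False)
            outputs.append(p3)
        summary = {}
        sel = seasons[(seasons["collection"] == "SL30_GPR")
                      & (seasons["method"] == "seasonal")]
        if len(sel) >= 3:
            try:
                slope, intercept, r = area_los_regression(sel)
                summary["area_los"] = {"slope": slope, "intercept": intercept,
                                       "r": r}
            except ValueError as err:
                summary["area_los"] = {"error": str(err)}
        spath = self.outdir / "evaluation_summary.json"
        spath.write_text(json.dumps(summary, indent=1))
        return outputs + [spath]

    # -- orchestration ------------------------------------------------------

    def _read_planted(self):
        src = self.cfg.planted_csv or (self.outdir / "planted.csv")
        p = Path(src)
        return pd.read_csv(p) if p.exists() else None

    def run_all(self) -> dict:
        if self.cfg.lai_csv:
            log.info("lai_csv given: starting from collection building")
        else:
            self.simulate()
            self.retrieve()
        self.build_collections()
        self.phenology()
        if not self.cfg.lai_csv:
            self.map()
        self.evaluate()
        mpath = self.outdir / "manifest.json"
        mpath.write_text(json.dumps(self._manifest, indent=1, sort_keys=True))
        return self._manifest


def setup_logging(verbose: bool = True) -> None:
    logging.basicConfig(stream=sys.stderr,
                        level=logging.INFO if verbose else logging.WARNING,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
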