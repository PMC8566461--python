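"""End-to-end orchestration and group statistics.

:func:`run` executes a set of analyses from a single config (YAML/JSON or
dict) over either a simulated dataset or real inputs (channel TIFF stacks +
ROI JSON, track tables, plate tables), writes one tidy CSV per analysis and
a machine-readable manifest (parameters, versions, input hashes, seed) from
which every table can be re-derived byte-for-byte.

:func:`compare_groups` applies the comparisons used throughout:
unpaired two-tailed Student's t, one-way ANOVA, and Spearman rank
correlation, reporting per-group n, mean and SEM alongside the statistic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sstats

from . import coloc as coloc_mod
from . import dynamics as dyn
from . import geometry as geo
from . import morphometrics as morpho_mod
from . import profiling as prof
from . import scene_sim as sim
from .errors import TraffiqError

__all__ = ["RunConfig", "GroupComparison", "compare_groups", "run", "run_from_manifest"]

log = logging.getLogger("traffiq")

KNOWN_ANALYSES = ("profile", "coloc", "morpho", "polarity", "tracks", "kinetics", "demo")


@dataclass
class RunConfig:
    outdir: str = "traffiq_out"
    seed: int = 0
    analyses: list[str] = field(default_factory=lambda: ["profile"])
    simulate: dict | None = None  # SceneConfig fields
    inputs: dict | None = None  # paths: images (channel->tiff), rois, tracks, plate, densitometry
    params: dict = field(default_factory=dict)  # module parameters

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise TraffiqError("bad-config", f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise TraffiqError(
                "bad-config", "exactly one of 'simulate' or 'inputs' must be given"
            )
        for a in self.analyses:
            if a not in KNOWN_ANALYSES:
                raise TraffiqError("bad-config", f"unknown analysis {a!r}")
        if self.inputs:
            for key, val in self.inputs.items():
                paths = val.values() if isinstance(val, dict) else [val]
                for p in paths:
                    if not Path(p).exists():
                        raise TraffiqError("bad-config", f"missing input file: {p}")


@dataclass
class GroupComparison:
    groups: list[str]
    n: list[int]
    mean: list[float]
    sem: list[float]
    test: str
    statistic: float
    p_value: float
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"group": g, "n": n, "mean": m, "sem": s}
            for g, n, m, s in zip(self.groups, self.n, self.mean, self.sem)
        ]
        df = pd.DataFrame(rows)
        df["test"] = self.test
        df["statistic"] = self.statistic
        df["p_value"] = self.p_value
        return df


def compare_groups(
    values_by_group: dict[str, np.ndarray],
    test: str = "t",
    paired: bool = False,
) -> GroupComparison:
    """Compare per-cell values across conditions.

    ``t``: unpaired (or paired) two-tailed Student's t between two groups.
    ``anova``: one-way ANOVA across two or more groups.
    ``spearman``: rank correlation between exactly two equal-length value
    vectors treated as paired observations (reported as R and two-sided p).
    """
    names = list(values_by_group)
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if test not in ("t", "anova", "spearman"):
        raise TraffiqError("bad-config", f"unknown test {test!r}")
    min_n = 3 if test == "spearman" else 2
    if any(len(a) < min_n for a in arrays):
        raise TraffiqError("insufficient-data")
    flags: list[str] = []
    if test == "t":
        if len(arrays) != 2:
            raise TraffiqError("insufficient-data", "t-test needs exactly 2 groups")
        if np.var(arrays[0]) == 0 and np.var(arrays[1]) == 0:
            flags.append("zero-variance")
            statistic, p = (0.0, 1.0) if np.mean(arrays[0]) == np.mean(arrays[1]) else (np.inf, 0.0)
        else:
            res = (sstats.ttest_rel if paired else sstats.ttest_ind)(arrays[0], arrays[1])
            statistic, p = float(res.statistic), float(res.pvalue)
    elif test == "anova":
        res = sstats.f_oneway(*arrays)
        statistic, p = float(res.statistic), float(res.pvalue)
        if np.isnan(statistic):
            flags.append("zero-variance")
    else:
        if len(arrays) != 2 or len(arrays[0]) != len(arrays[1]):
            raise TraffiqError("insufficient-data", "spearman needs 2 equal-length vectors")
        res = sstats.spearmanr(arrays[0], arrays[1])
        statistic, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        groups=names,
        n=[len(a) for a in arrays],
        mean=[float(a.mean()) for a in arrays],
        sem=[float(sstats.sem(a)) if len(a) > 1 else float("nan") for a in arrays],
        test=test,
        statistic=statistic,
        p_value=p,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# analyses


def _load_scenes(cfg: RunConfig) -> list[sim.Scene]:
    if cfg.simulate is not None:
        scfg = sim.SceneConfig(**{**cfg.simulate, "seed": cfg.simulate.get("seed", cfg.seed)})
        return sim.simulate_scene(scfg)
    import tifffile

    rois = geo.load_rois_json(cfg.inputs["rois"])
    stacks = {ch: tifffile.imread(p) for ch, p in cfg.inputs["images"].items()}
    scenes = []
    for i, roi in enumerate(rois):
        images = {ch: (st[i] if st.ndim == 3 else st) for ch, st in stacks.items()}
        scenes.append(sim.Scene(cell_id=roi.cell_id, images=images, roi=roi))
    return scenes


def _analysis_profile(scenes: list[sim.Scene], params: dict) -> dict[str, pd.DataFrame]:
    band_p = params.get("perinuclear_band", 0.25)
    band_q = params.get("peripheral_band", 0.15)
    margin = params.get("tie_margin", 0.1)
    cargo_ch = params.get("cargo_channel", "cargo")
    rows, prof_rows, skipped = [], [], []
    for s in scenes:
        try:
            shape = s.images[cargo_ch].shape
            masks = geo.build_compartment_masks(s.roi, band_p, band_q, shape=shape)
            score = prof.compartment_max(s.images[cargo_ch], masks, cell_id=s.cell_id)
            label = prof.classify_cell(score, tie_margin=margin)
            rows.append(
                {"cell_id": s.cell_id, "perinuclear_max": score.perinuclear_max,
                 "peripheral_max": score.peripheral_max, "label": label}
            )
            segs = geo.radial_lines(
                s.roi, n_lines=params.get("n_lines", 3),
                length=params.get("line_length", 40), width=params.get("line_width", 3),
            )
            for ch in params.get("profile_channels", [cargo_ch, "dapi"]):
                if ch not in s.images:
                    continue
                profile = prof.linescan_profile(s.images[ch], segs, channel=ch)
                prof_rows.append(profile.to_frame(cell_id=s.cell_id))
        except TraffiqError as e:
            skipped.append({"cell_id": s.cell_id, "reason": e.code})
            log.warning("profile: skipped %s (%s)", s.cell_id, e.code)
    scores = pd.DataFrame(rows)
    out = {"scores": scores}
    if prof_rows:
        out["profiles"] = pd.concat(prof_rows, ignore_index=True)
    if len(scores):
        frac, table = prof.percent_perinuclear(list(scores["label"]))
        table["percent_perinuclear"] = 100 * frac
        out["summary"] = table
    if skipped:
        out["skipped"] = pd.DataFrame(skipped)
    return out


def _analysis_coloc(scenes: list[sim.Scene], params: dict) -> dict[str, pd.DataFrame]:
    ch1 = params.get("cargo_channel", "cargo")
    ch2 = params.get("marker_channel", "marker")
    mode = params.get("mode", "pixel-count")
    rows, skipped = [], []
    for s in scenes:
        try:
            mask = geo.rasterize_polygon(s.roi.cell_polygon, s.images[ch1].shape)
            res = coloc_mod.manders(
                s.images[ch1], s.images[ch2], mask,
                threshold_method=params.get("threshold_method", "otsu"), mode=mode,
            )
            rows.append(
                {"cell_id": s.cell_id, "m1": res.m1, "m2": res.m2,
                 "threshold_1": res.threshold_1, "threshold_2": res.threshold_2,
                 "mode": res.mode}
            )
        except TraffiqError as e:
            skipped.append({"cell_id": s.cell_id, "reason": e.code})
            log.warning("coloc: skipped %s (%s)", s.cell_id, e.code)
    out = {"coloc": pd.DataFrame(rows)}
    if skipped:
        out["skipped"] = pd.DataFrame(skipped)
    return out


def _analysis_morpho(scenes: list[sim.Scene], params: dict) -> dict[str, pd.DataFrame]:
    fa_ch = params.get("fa_channel", "fa")
    golgi_ch = params.get("golgi_channel", "golgi")
    particle_rows, summary_rows, skipped = [], [], []
    for s in scenes:
        try:
            shape = next(iter(s.images.values())).shape
            mask = geo.rasterize_polygon(s.roi.cell_polygon, shape)
            rec: dict = {"cell_id": s.cell_id}
            if fa_ch in s.images:
                table = morpho_mod.segment_puncta(
                    s.images[fa_ch], mask,
                    threshold_method=params.get("threshold_method", "otsu"),
                    min_size=params.get("min_size", 4),
                    pixel_size=s.roi.pixel_size, cell_id=s.cell_id,
                )
                p = table.particles.copy()
                p.insert(0, "cell_id", s.cell_id)
                particle_rows.append(p)
                rec.update(fa_count=table.count, fa_mean_area_px2=table.mean_area_px2)
            if golgi_ch in s.images:
                rec.update({f"golgi_{k}": v for k, v in morpho_mod.golgi_area(
                    s.images[golgi_ch], mask,
                    threshold_method=params.get("threshold_method", "otsu"),
                    pixel_size=s.roi.pixel_size).items()})
            summary_rows.append(rec)
        except TraffiqError as e:
            skipped.append({"cell_id": s.cell_id, "reason": e.code})
            log.warning("morpho: skipped %s (%s)", s.cell_id, e.code)
    out = {"morpho_summary": pd.DataFrame(summary_rows)}
    if particle_rows:
        out["particles"] = pd.concat(particle_rows, ignore_index=True)
    if skipped:
        out["skipped"] = pd.DataFrame(skipped)
    return out


def _analysis_polarity(scenes: list[sim.Scene], params: dict) -> dict[str, pd.DataFrame]:
    fa_ch = params.get("fa_channel", "fa")
    direction = np.deg2rad(params.get("front_direction_deg", 0.0))
    half_width = np.deg2rad(params.get("front_half_width_deg", 60.0))
    basis = params.get("basis", "intensity")
    rows, skipped = [], []
    for s in scenes:
        try:
            sector = geo.front_sector(s.roi, direction=direction, half_width=half_width)
            mask = geo.rasterize_polygon(s.roi.cell_polygon, s.images[fa_ch].shape)
            res = morpho_mod.polarity_score(
                s.images[fa_ch], sector, basis=basis, cell_mask=mask, cell_id=s.cell_id
            )
            rows.append(
                {"cell_id": s.cell_id, "in_sector_fraction": res.in_sector_fraction,
                 "polarized": res.polarized, "basis": res.basis}
            )
        except TraffiqError as e:
            skipped.append({"cell_id": s.cell_id, "reason": e.code})
            log.warning("polarity: skipped %s (%s)", s.cell_id, e.code)
    df = pd.DataFrame(rows)
    out = {"polarity": df}
    if len(df):
        out["polarity_summary"] = pd.DataFrame(
            [{"n": len(df), "percent_polarized": 100 * morpho_mod.percent_polarized(
                list(df["polarized"]))}]
        )
    if skipped:
        out["skipped"] = pd.DataFrame(skipped)
    return out


def _analysis_tracks(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    if cfg.inputs and "tracks" in cfg.inputs:
        table = pd.read_csv(cfg.inputs["tracks"])
    else:
        p = cfg.params.get("tracks", {})
        table, _ = sim.simulate_tracks(
            n_tracks=p.get("n_tracks", 100), motion=p.get("motion", "directed"),
            v=p.get("v", 0.5), jitter=p.get("jitter", 0.05), sigma=p.get("sigma", 0.5),
            n_frames=p.get("n_frames", 50), dt=p.get("dt", 1.0), seed=cfg.seed,
        )
    rows, skipped = [], []
    for tr in dyn.tracks_from_table(table):
        try:
            st = dyn.track_stats(tr)
            rows.append(
                {"track_id": st.track_id, "speed": st.speed,
                 "net_displacement": st.net_displacement,
                 "path_length": st.path_length, "directionality": st.directionality}
            )
        except TraffiqError as e:
            skipped.append({"track_id": tr.track_id, "reason": e.code})
            log.warning("tracks: skipped %s (%s)", tr.track_id, e.code)
    out = {"track_stats": pd.DataFrame(rows)}
    if skipped:
        out["skipped_tracks"] = pd.DataFrame(skipped)
    return out


def _analysis_kinetics(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    out: dict[str, pd.DataFrame] = {}
    if cfg.inputs and "plate" in cfg.inputs:
        plate = pd.read_csv(cfg.inputs["plate"])
    else:
        p = cfg.params.get("plate", {})
        plate, _ = sim.simulate_plate(
            true_uptake=p.get("true_uptake", 0.3),
            true_recycled=p.get("true_recycled", 0.6),
            n_replicates=p.get("n_replicates", 6),
            noise_cv=p.get("noise_cv", 0.05), seed=cfg.seed,
        )
    out["endocytosis"] = dyn.endocytosis_fraction_from_plate(plate)
    rec_rows = []
    for cond, g in plate.groupby("condition", sort=False):
        norm = g["signal"] / g["bca_signal"]
        internal = norm[g["role"] == "sample"].mean()
        remaining = norm[g["role"] == "strip_control"].mean()
        frac, clamped = dyn.recycled_fraction(
            dyn.KineticsRecord(condition=cond, internalized=internal,
                               surface_bound_total=1.0, remaining_after_strip=remaining)
        )
        rec_rows.append({"condition": cond, "recycled_fraction": frac, "clamped": clamped})
    out["recycling"] = pd.DataFrame(rec_rows)
    if cfg.inputs and "densitometry" in cfg.inputs:
        dens = pd.read_csv(cfg.inputs["densitometry"])
    else:
        p = cfg.params.get("decay", {})
        dens, _ = sim.simulate_decay(
            half_life_min=p.get("half_life_min", 30.0),
            times_min=np.asarray(p.get("times_min", [0, 15, 30, 45, 60, 90, 120])),
            noise_cv=p.get("noise_cv", 0.05), seed=cfg.seed,
        )
    curve = dyn.degradation_curve(dens["band"].to_numpy(), dens["control"].to_numpy(),
                                  dens["time_min"].to_numpy())
    out["degradation"] = pd.DataFrame(
        {"time_min": curve.times, "percent_of_t0": curve.normalized_intensity,
         "fitted_half_life_min": curve.fitted_half_life}
    )
    return out


def _analysis_demo(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Two-condition experiment: epithelial-like vs mesenchymal-like scenes."""
    p = cfg.params.get("demo", {})
    n = p.get("n_cells", 30)
    base = {k: v for k, v in (cfg.simulate or {}).items() if k not in ("n_cells", "seed")}
    out: dict[str, pd.DataFrame] = {}
    scores = {}
    for name, weight, seed_off in (("epithelial_like", p.get("p_epithelial", 0.2), 1),
                                   ("mesenchymal_like", p.get("p_mesenchymal", 0.8), 2)):
        scfg = sim.SceneConfig(**{**base, "n_cells": n,
                                  "perinuclear_weight": weight, "seed": cfg.seed + seed_off})
        scenes = sim.simulate_scene(scfg)
        tables = _analysis_profile(scenes, cfg.params)
        df = tables["scores"].copy()
        df.insert(0, "condition", name)
        scores[name] = df
    all_scores = pd.concat(scores.values(), ignore_index=True)
    out["demo_scores"] = all_scores
    comps = []
    for metric in ("perinuclear_max", "peripheral_max"):
        comp = compare_groups(
            {name: df[metric].to_numpy() for name, df in scores.items()}, test="t"
        )
        cdf = comp.to_frame()
        cdf.insert(0, "metric", metric)
        comps.append(cdf)
    out["demo_comparison"] = pd.concat(comps, ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# run


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run(config: RunConfig | dict | str | Path) -> dict:
    """Execute the configured analyses; write tidy CSVs and a run manifest.

    Deterministic given (config, seed). Per-cell failures are logged and
    skipped; missing input files fail fast before any computation.
    """
    if isinstance(config, (str, Path)):
        config = RunConfig.from_file(config)
    elif isinstance(config, dict):
        config = RunConfig(**config)
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    image_analyses = [a for a in config.analyses if a in ("profile", "coloc", "morpho", "polarity")]
    scenes = _load_scenes(config) if image_analyses else []

    tables: dict[str, pd.DataFrame] = {}
    for a in config.analyses:
        if a == "profile":
            tables.update(_analysis_profile(scenes, config.params))
        elif a == "coloc":
            tables.update(_analysis_coloc(scenes, config.params))
        elif a == "morpho":
            tables.update(_analysis_morpho(scenes, config.params))
        elif a == "polarity":
            tables.update(_analysis_polarity(scenes, config.params))
        elif a == "tracks":
            tables.update(_analysis_tracks(config))
        elif a == "kinetics":
            tables.update(_analysis_kinetics(config))
        elif a == "demo":
            tables.update(_analysis_demo(config))

    outputs = {}
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        outputs[name] = str(p)

    import scipy
    import skimage

    from . import __version__

    manifest = {
        "traffiq_version": __version__,
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__, "scikit-image": skimage.__version__},
        "config": {
            "outdir": str(config.outdir), "seed": config.seed,
            "analyses": config.analyses, "simulate": config.simulate,
            "inputs": config.inputs, "params": config.params,
        },
        "input_hashes": {
            key: ( {k: _sha256(v) for k, v in val.items()} if isinstance(val, dict)
                   else _sha256(val) )
            for key, val in (config.inputs or {}).items()
        },
        "outputs": outputs,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {"tables": tables, "outputs": outputs,
            "manifest": str(outdir / "manifest.json")}


def run_from_manifest(manifest_path: str | Path, outdir: str | Path | None = None) -> dict:
    """Re-run an analysis from its manifest; reproduces every CSV exactly."""
    manifest = json.loads(Path(manifest_path).read_text())
    cfg = dict(manifest["config"])
    if outdir is not None:
        cfg["outdir"] = str(outdir)
    return run(cfg)
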