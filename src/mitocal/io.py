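"""File formats, configuration and the end-to-end pipeline driver.

Formats are deliberately plain: traces and tables are UTF-8 comma-separated
CSV with a mandatory header and units embedded in the column names
(``time_s``, ``fluorescence_fau``, ``length_um``, ``sr_distance_nm``);
images are multichannel TIFF with the pixel size recorded in the image
description; configuration is TOML; reports are JSON.  Pixel coordinates
are 0-based (row, col).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import morphometry, simulate, stats
from .kinetics import FluorescenceTrace, KineticsConfig, analyze_batch

__all__ = [
    "PipelineConfig",
    "read_trace_csv",
    "write_trace_csv",
    "write_metrics_csv",
    "read_metrics_csv",
    "read_object_table",
    "write_object_table",
    "read_tiff",
    "write_tiff",
    "load_config",
    "save_config",
    "run_pipeline",
]

logger = logging.getLogger("mitocal")

TRACE_COLUMNS = ["time_s", "fluorescence_fau"]
OBJECT_COLUMNS = ["id", "length_um", "width_um"]
MANIFEST_COLUMNS = ["trace_id", "file", "t_app", "group"]


class SchemaError(ValueError):
    """A file is missing required columns or referenced files."""


@dataclass(frozen=True)
class MorphometryConfig:
    d_max_nm: float = 30.0
    largest_fraction_min: float = 0.5
    length_min_um: float = 5.0
    min_area_px: int = 4
    threshold_method: str = "otsu"

    def __post_init__(self) -> None:
        for name in ("d_max_nm", "largest_fraction_min", "length_min_um",
                     "min_area_px"):
            if not getattr(self, name) > 0:
                raise ValueError(f"MorphometryConfig.{name} must be > 0")


@dataclass(frozen=True)
class PipelineConfig:
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)
    pixel_size: float = 0.1  # µm/px
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("PipelineConfig.pixel_size must be > 0")


# ---------------------------------------------------------------------------
# CSV


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_trace_csv(path, t_app: float | None = None) -> FluorescenceTrace:
    """Read a trace CSV; ``t_app`` falls back to the JSON sidecar."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface file + cause
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc
    _require_columns(df, TRACE_COLUMNS, path)
    if t_app is None:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise SchemaError(f"{path}: no t_app given and no sidecar {sidecar.name}")
        t_app = json.loads(sidecar.read_text())["params"]["t_app"]
    return FluorescenceTrace(
        time=df["time_s"].to_numpy(float),
        fluorescence=df["fluorescence_fau"].to_numpy(float),
        t_app=float(t_app),
    )


def write_trace_csv(
    trace: FluorescenceTrace,
    path,
    params: simulate.TraceParams | None = None,
) -> None:
    """Write a trace CSV plus, when params are known, the JSON sidecar with
    the generating parameters and their analytic ground-truth metrics."""
    path = Path(path)
    pd.DataFrame(
        {"time_s": trace.time, "fluorescence_fau": trace.fluorescence}
    ).to_csv(path, index=False, float_format="%.12g")
    if params is not None:
        sidecar = {
            "params": dataclasses.asdict(params),
            "ground_truth": simulate.trace_ground_truth(params),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def write_metrics_csv(metrics: pd.DataFrame, path) -> None:
    metrics.to_csv(path, index=False, float_format="%.12g")


def read_metrics_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["trace_id", "amplitude"], path)
    return df


def read_object_table(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc
    _require_columns(df, OBJECT_COLUMNS, path)
    return df


def write_object_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# TIFF


def write_tiff(image: np.ndarray, path, pixel_size: float) -> None:
    """Write a (C, H, W) image; pixel size (µm/px) goes in the description."""
    tifffile.imwrite(
        Path(path),
        np.asarray(image, dtype=np.float32),
        description=json.dumps({"pixel_size_um": pixel_size}),
    )


def read_tiff(path, pixel_size: float | None = None) -> tuple[np.ndarray, float]:
    """Read a multichannel TIFF; an explicit ``pixel_size`` flag wins over
    the value stored in the file's description."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        image = tf.asarray()
        if pixel_size is None:
            desc = tf.pages[0].description
            try:
                pixel_size = json.loads(desc)["pixel_size_um"]
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise SchemaError(
                    f"{path}: no pixel size flag and none in TIFF metadata"
                ) from exc
    if image.ndim == 2:
        image = image[None]
    return image.astype(float), float(pixel_size)


# ---------------------------------------------------------------------------
# TOML config round-trip


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"unsupported TOML value {v!r}")


def _toml_dump(d: dict, prefix: str = "") -> str:
    scalars, tables = [], []
    for k, v in d.items():
        if isinstance(v, dict):
            tables.append((k, v))
        else:
            scalars.append(f"{k} = {_toml_value(v)}")
    out = "\n".join(scalars)
    for k, v in tables:
        name = f"{prefix}{k}"
        out += f"\n\n[{name}]\n" + _toml_dump(v, prefix=name + ".")
    return out


def save_config(config: PipelineConfig, path) -> None:
    d = dataclasses.asdict(config)
    Path(path).write_text(_toml_dump(d) + "\n")


def load_config(path) -> PipelineConfig:
    d = tomllib.loads(Path(path).read_text())
    kin = KineticsConfig(**d.pop("kinetics", {}))
    morph = MorphometryConfig(**d.pop("morphometry", {}))
    return PipelineConfig(kinetics=kin, morphometry=morph, **d)


def _stable_hash(s: str) -> int:
    """Process-independent small hash (``hash()`` is salted per run)."""
    return int(hashlib.sha256(s.encode()).hexdigest()[:6], 16)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# End-to-end pipeline

#: The bundled demo study: two transient groups (control vs fission-blocked)
#: and two EM morphometry groups (control vs rapid pacing), matching the
#: group presets in :mod:`mitocal.simulate`.
DEMO_STUDY = {
    "traces": {
        "groups": ["control", "drp1k38e"],
        "n_per_group": 10,
        "noise_frac": 0.01,
        "cell_cv": 0.2,
    },
    "em": {
        "n": 50,
        "groups": {
            "control": {"length": [0.2, 0.4], "width": [0.15, 0.25],
                        "contact_fraction": 0.04},
            "efs_5hz": {"length": [0.8, 1.0], "width": [0.6, 0.8],
                        "contact_fraction": 0.94},
        },
    },
}


def _simulate_trace_set(study: dict, outdir: Path, seed: int) -> pd.DataFrame:
    """Write one trace CSV + sidecar per simulated cell, plus the manifest.

    ``cell_cv`` adds between-cell biological variability: each cell's
    latency, rise slope, rise duration and decay constant are the group
    preset scaled by independent lognormal factors with that coefficient
    of variation.
    """
    cv = study.get("cell_cv", 0.2)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    rows = []
    i = 0
    for group in study["groups"]:
        base = simulate.GROUP_PRESETS[group]
        for _ in range(study["n_per_group"]):
            rng = np.random.default_rng((seed % 2**31) * 100_003 + i)
            f = rng.lognormal(-sigma**2 / 2, sigma, size=4)
            cell = dataclasses.replace(
                base,
                latency=base.latency * f[0],
                rise_slope=base.rise_slope * f[1],
                rise_duration=base.rise_duration * f[2],
                decay_tau=base.decay_tau * f[3],
            )
            params = dataclasses.replace(
                cell,
                noise_sd=study["noise_frac"] * cell.amplitude,
                seed=(seed + i) % 2**31,
            )
            trace = simulate.simulate_trace(params)
            fname = f"trace_{i:03d}.csv"
            write_trace_csv(trace, outdir / fname, params)
            rows.append(
                {"trace_id": f"trace_{i:03d}", "file": fname,
                 "t_app": params.t_app, "group": group}
            )
            i += 1
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def analyze_manifest(
    manifest: pd.DataFrame, tracedir: Path, config: PipelineConfig
) -> pd.DataFrame:
    """Run the kinetics stage over every trace a manifest lists."""
    _require_columns(manifest, MANIFEST_COLUMNS, "manifest")
    traces = []
    for row in manifest.itertuples(index=False):
        fpath = Path(tracedir) / row.file
        if not fpath.exists():
            raise SchemaError(f"manifest references missing file {fpath}")
        traces.append(read_trace_csv(fpath, t_app=float(row.t_app)))
    return analyze_batch(
        traces,
        config.kinetics,
        trace_ids=list(manifest["trace_id"]),
        groups=list(manifest["group"]),
    )


def _summaries_to_json(gs: list[stats.GroupStats]) -> list[dict]:
    return [dataclasses.asdict(g) for g in gs]


def _tests_to_json(ts: list[stats.TestResult]) -> list[dict]:
    return [
        {"test_name": t.test_name, "statistic": t.statistic,
         "df": list(t.df) if t.df is not None else None, "p": t.p}
        for t in ts
    ]


def run_pipeline(
    config: PipelineConfig,
    manifest: pd.DataFrame | None = None,
    study: dict | None = None,
    tracedir=None,
) -> dict:
    """Simulate (unless a manifest points at existing traces), analyze and
    summarize; returns the report dict and writes it to the output
    directory along with the metrics CSV."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = study if study is not None else DEMO_STUDY
    logger.info("pipeline start: config %s seed %d", config_hash(config), config.seed)

    if manifest is None:
        tracedir = outdir
        manifest = _simulate_trace_set(study["traces"], outdir, config.seed)
    elif tracedir is None:
        raise ValueError("an explicit manifest needs a tracedir")

    metrics = analyze_manifest(manifest, tracedir, config)
    write_metrics_csv(metrics, outdir / "trace_metrics.csv")

    report: dict = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "group_summaries": [],
        "tests": [],
        "censored_exclusions": {},
    }

    metrics = metrics.copy()
    gs, ts = stats.summarize_groups(
        metrics, "amplitude", "group", censored_col=None
    )
    for g in gs:
        report["group_summaries"].append({"metric": "amplitude_fau", **dataclasses.asdict(g)})
    report["tests"] += _tests_to_json(ts)

    em = study.get("em")
    if em:
        frames = []
        for gname, spec_ in em["groups"].items():
            tab = simulate.simulate_em_objects(
                em["n"],
                tuple(spec_["length"]),
                tuple(spec_["width"]),
                spec_["contact_fraction"],
                seed=(config.seed * 7919 + _stable_hash(gname)) % 2**31,
            )
            objs = morphometry.objects_from_table(
                tab, d_max_nm=config.morphometry.d_max_nm
            )
            frames.append(pd.DataFrame({
                "group": gname,
                "size2d_um2": [o.size2d for o in objs],
                "contact": [bool(o.contact) for o in objs],
            }))
            tab.to_csv(outdir / f"em_{gname}.csv", index=False)
        em_df = pd.concat(frames, ignore_index=True)
        gs, ts = stats.summarize_groups(em_df, "size2d_um2", "group")
        for g in gs:
            report["group_summaries"].append(
                {"metric": "size2d_um2", **dataclasses.asdict(g)}
            )
        report["tests"] += _tests_to_json(ts)
        _, fisher_ts = stats.summarize_groups(em_df, "contact", "group")
        report["tests"] += _tests_to_json(fisher_ts)

    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    logger.info("pipeline done: %d summaries, %d tests",
                len(report["group_summaries"]), len(report["tests"]))
    return report
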