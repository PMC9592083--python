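"""Batch orchestration: configuration, end-to-end runs, group statistics.

A run turns an input movie (or a phantom specification) into per-cell
metric CSVs plus one summary row of characteristic values per cell.
Group comparison delegates to the standard nonparametric tests used for
these endpoints: Mann-Whitney for two groups, Kruskal-Wallis followed by
Dunn's post test for more.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import kinetics, metrics, nucleus, shape, volume
from .errors import ConfigError
from .phantom import PhantomParams, generate_doublet

logger = logging.getLogger("synapsekin")

__all__ = ["RunConfig", "run_pipeline", "compare_groups"]

# Channel roles each metric needs before any computation starts.
_METRIC_CHANNELS = {
    "antigen_recruitment": ("antigen",),
    "actin_enrichment": ("antigen", "cytoplasm"),
    "centrosome_distance": ("antigen", "cytoplasm", "centrosome"),
    "organelle_distance": ("antigen", "organelle"),
    "theta_n": ("antigen", "cytoplasm", "nucleus"),
    "shape": ("cytoplasm",),
}

# Paper-derived defaults for every tunable constant, single source of truth.
DEFAULTS = {
    "actin_shell_um": 2.0,
    "dag_shell_um": 1.0,
    "peak_window_min": (0.0, 10.0),
    "plateau_window_min": (25.0, 30.0),
    "theta_threshold_deg": 45.0,
    "centrosome_threshold_um": 2.0,
    "centrosome_gate_um": 3.0,
    "golgi_threshold_um": 4.0,
    "golgi_gate_um": 5.0,
    "lysosome_threshold_um": 3.0,
    "lysosome_gate_um": 4.0,
    "migration_net_um": 20.0,
    "migration_start_step_um": 6.0,
    "migration_keep_frames": 30,
    "moving_average_window": 3,
}


@dataclass
class RunConfig:
    """Configuration of one batch run; round-trips losslessly to YAML."""

    out_dir: str = "synapsekin_out"
    seed: int = 0
    cell_id: str = "cell_000"
    metrics: tuple[str, ...] = ("antigen_recruitment", "actin_enrichment",
                                "centrosome_distance", "theta_n", "shape")
    channel_map: dict = field(default_factory=lambda: {
        "antigen": "antigen", "cytoplasm": "cytoplasm", "nucleus": "nucleus",
        "centrosome": "centrosome", "organelle": "organelle",
    })
    phantom: dict = field(default_factory=dict)  # PhantomParams overrides
    input_tiff: str | None = None
    thresholds: dict = field(default_factory=lambda: dict(DEFAULTS))
    log_level: str = "INFO"

    def validate(self) -> None:
        for m in self.metrics:
            if m not in _METRIC_CHANNELS:
                raise ConfigError(f"unknown metric {m!r}")
            missing = [c for c in _METRIC_CHANNELS[m] if c not in self.channel_map]
            if missing:
                raise ConfigError(f"metric {m!r} needs channel roles {missing} in channel_map")

    def to_yaml(self, path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "metrics" in data:
            data["metrics"] = tuple(data["metrics"])
        if "thresholds" in data:
            thr = dict(DEFAULTS)
            thr.update(data["thresholds"])
            data["thresholds"] = thr
        return cls(**data)


def _load_series(config: RunConfig):
    if config.input_tiff:
        import tifffile

        with tifffile.TiffFile(config.input_tiff) as tf:
            arr = tf.asarray()
            axes = tf.series[0].axes
        if axes == "TZCYX":
            arr = arr.swapaxes(1, 2)
        elif axes != "TCZYX":
            raise ConfigError(f"unsupported axis order {axes!r}; need TZCYX or TCZYX")
        meta = config.phantom  # voxel geometry must come from config for plain TIFFs
        from .core import VolumeSeries

        series = VolumeSeries(
            arr,
            tuple(meta.get("voxel_size", (0.7, 0.325, 0.325))),
            float(meta.get("frame_interval", 30.0)),
            tuple(config.channel_map.values())[: arr.shape[1]],
        )
        return series, None
    params = PhantomParams(**{**config.phantom, "seed": config.seed})
    return generate_doublet(params)


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full single-cell run and write the report bundle.

    Returns a dict with the summary row, per-metric traces, and output
    paths.  Identical config + seed reproduce identical outputs.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    series, truth = _load_series(config)
    thr = config.thresholds
    summary: dict = {"cell_id": config.cell_id, "seed": config.seed}
    traces: dict = {}
    rows = []

    droplet = volume.segment_droplet(series, config.channel_map["antigen"], frame=0)
    cell_masks = volume.segment_cell(series, config.channel_map["cytoplasm"])
    dfield = volume.distance_map(droplet)
    d_center = droplet.centroid_um()
    peak_win = tuple(60.0 * m for m in thr["peak_window_min"])
    plateau_win = tuple(60.0 * m for m in thr["plateau_window_min"])

    def _record(name, trace):
        traces[name] = trace
        for t, v in zip(trace.times, trace.values):
            rows.append({"cell_id": config.cell_id, "metric": name, "time_s": t, "value": v})

    for m in config.metrics:
        try:
            if m == "antigen_recruitment":
                tr = metrics.antigen_recruitment(
                    series, droplet, cell_masks[0].centroid_um(), config.channel_map["antigen"]
                ).as_kinetic(config.cell_id)
                _record(m, tr)
                try:
                    summary["antigen_plateau"] = kinetics.plateau_mean(tr, plateau_win)
                except Exception:
                    summary["antigen_plateau"] = np.nan
            elif m == "actin_enrichment":
                tr = metrics.shell_enrichment(
                    series, config.channel_map["cytoplasm"], cell_masks, dfield,
                    metrics.SHELL_PRESETS["actin2um"],
                ).as_kinetic(config.cell_id)
                _record(m, tr)
                t_pk, pk = kinetics.window_extremum(tr, peak_win, "max")
                summary["actin_t_peak_s"], summary["actin_peak"] = t_pk, pk
            elif m == "centrosome_distance":
                dists = []
                for t in range(series.n_frames):
                    pos = volume.detect_punctum(series, config.channel_map["centrosome"], t,
                                                within=cell_masks[t])
                    dists.append(volume.organelle_distance(pos, dfield, "point"))
                from .core import KineticTrace

                tr = KineticTrace(series.times, np.asarray(dists), m, config.cell_id)
                _record(m, tr)
                spec = kinetics.CharacteristicTimeSpec(
                    thr["centrosome_threshold_um"], thr["centrosome_gate_um"]
                )
                summary["t_polarization_s"] = kinetics.polarization_time(tr, spec)
            elif m == "organelle_distance":
                org = series.channel(config.channel_map["organelle"])
                dists = []
                for t in range(series.n_frames):
                    from skimage.filters import threshold_otsu
                    from .core import Mask3D

                    v = org[t]
                    msk = Mask3D(v > threshold_otsu(v), series.voxel_size, "organelle")
                    dists.append(volume.organelle_distance(msk, dfield, "mean"))
                from .core import KineticTrace

                tr = KineticTrace(series.times, np.asarray(dists), m, config.cell_id)
                _record(m, tr)
            elif m == "theta_n":
                from skimage.filters import threshold_otsu
                from .core import KineticTrace, Mask3D

                nuc = series.channel(config.channel_map["nucleus"])
                angles, prev = [], None
                for t in range(series.n_frames):
                    v = nuc[t]
                    msk = Mask3D(v > threshold_otsu(v), series.voxel_size, "nucleus")
                    mesh = nucleus.extract_surface(msk)
                    apex = nucleus.detect_invagination(mesh, previous_point=prev)
                    prev = apex
                    angles.append(nucleus.orientation_angle(
                        apex, cell_masks[t].centroid_um(), d_center))
                tr = KineticTrace(series.times, np.asarray(angles), m, config.cell_id)
                _record(m, tr)
                summary["t_theta45_s"] = kinetics.orientation_time(tr, thr["theta_threshold_deg"])
            elif m == "shape":
                samples = [
                    shape.shape_sample(shape.project_max_z(cm), time=t * series.frame_interval)
                    for t, cm in enumerate(cell_masks)
                ]
                summary["aspect_cv_percent"] = shape.summarize_shape(samples, "cv_percent_aspect")
                summary["median_solidity"] = shape.summarize_shape(samples, "median_solidity")
        except Exception:
            logger.exception("metric %s failed for %s; skipping", m, config.cell_id)

    pd.DataFrame(rows).to_csv(out / "traces.csv", index=False)
    pd.DataFrame([summary]).to_csv(out / "summary.csv", index=False)
    (out / "run.json").write_text(json.dumps(
        {"seed": config.seed, "metrics": list(config.metrics)}, indent=2))
    return {"summary": summary, "traces": traces, "out_dir": str(out), "ground_truth": truth}


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def _dunn_posthoc(groups: dict[str, np.ndarray]) -> list[dict]:
    """Dunn's rank-sum z tests for all pairs after Kruskal-Wallis.

    Pooled mid-ranks with tie correction; two-sided normal p-values,
    Bonferroni-adjusted over the pairs.
    """
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie = (counts ** 3 - counts).sum() / (12.0 * (n_total - 1))
    mean_ranks, sizes = {}, {}
    start = 0
    for g in names:
        k = len(groups[g])
        mean_ranks[g] = ranks[start : start + k].mean()
        sizes[g] = k
        start += k
    rows = []
    pairs = list(combinations(names, 2))
    for a, b in pairs:
        se = np.sqrt((n_total * (n_total + 1) / 12.0 - tie) * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({
            "test": "dunn", "group_a": a, "group_b": b, "statistic": float(z),
            "p_value": float(p), "p_adjusted": float(min(1.0, p * len(pairs))),
        })
    return rows


def compare_groups(summary, group_column: str, value_columns=None) -> pd.DataFrame:
    """Nonparametric comparison of per-cell summary metrics across groups.

    ``summary`` is a DataFrame or CSV path.  Two groups: Mann-Whitney U.
    Three or more: Kruskal-Wallis plus Dunn's pairwise post test.  Groups
    with fewer than 2 cells are excluded with a warning.
    """
    df = pd.read_csv(summary) if not isinstance(summary, pd.DataFrame) else summary
    if group_column not in df.columns:
        raise ConfigError(f"no column {group_column!r} in summary")
    if value_columns is None:
        value_columns = [c for c in df.columns
                         if c != group_column and pd.api.types.is_numeric_dtype(df[c])]
    rows = []
    for col in value_columns:
        groups = {}
        for g, grp in df.groupby(group_column):
            vals = grp[col].dropna().to_numpy(float)
            if len(vals) < 2:
                logger.warning("group %s excluded for %s (n=%d < 2)", g, col, len(vals))
                continue
            groups[str(g)] = vals
        if len(groups) < 2:
            continue
        names = list(groups)
        if len(groups) == 2:
            u, p = stats.mannwhitneyu(groups[names[0]], groups[names[1]], alternative="two-sided")
            rows.append({"metric": col, "test": "mann-whitney", "group_a": names[0],
                         "group_b": names[1], "statistic": float(u), "p_value": float(p)})
        else:
            h, p = stats.kruskal(*groups.values())
            rows.append({"metric": col, "test": "kruskal-wallis", "group_a": "all",
                         "group_b": "all", "statistic": float(h), "p_value": float(p)})
            for r in _dunn_posthoc(groups):
                r["metric"] = col
                rows.append(r)
    return pd.DataFrame(rows)
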