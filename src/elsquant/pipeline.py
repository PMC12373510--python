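"""Pipeline orchestration: simulate -> classify -> quantify -> compare.

Composes the simulator, pixel classification, quantification and statistics
into a configured, logged run that emits figure-ready tables: a per-field
gland-metrics CSV, a per-aggregate CSV, and a group-comparison CSV with the
box-plot summaries (median, quartiles, extremes), test statistics, p values
and significance stars.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .imgio import MultiplexImage, read_tiff
from .pixclass import ThresholdSpec
from .quant import FOCUS_MIN_LYMPHOCYTES, GlandMetrics, quantify_field
from .stats import mann_whitney, significance_stars, wilcoxon_signed_rank
from .synthgland import (
    FieldRecord,
    SimulationConfig,
    cohort_truth_tables,
    simulate_cohort,
)

__all__ = [
    "PipelineConfig",
    "run_quantification",
    "run_comparison",
    "demo",
    "load_config",
    "DEFAULT_ENDPOINTS",
]

#: Endpoints compared between groups, mirroring the quantities shown in the
#: group-comparison figures: focus score, aggregate area fraction, per-field
#: T / B / intersection areas, and the prevalence of segregated aggregates.
DEFAULT_ENDPOINTS = (
    "focus_score",
    "aggregate_area_fraction_pct",
    "t_area_um2",
    "b_area_um2",
    "intersection_area_um2",
    "segregated_prevalence_pct",
)


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run.

    ``groups`` maps group name to a :class:`SimulationConfig` (synthetic
    cohort) — or use :func:`run_quantification` with pre-loaded images.
    Thresholds default to per-channel Otsu, the unattended stand-in for an
    operator-assigned global threshold.
    """

    groups: dict[str, SimulationConfig] = field(default_factory=dict)
    n_fields_per_group: int = 10
    t_threshold: ThresholdSpec | None = None
    b_threshold: ThresholdSpec | None = None
    dapi_channel: str = "DAPI"
    t_channel: str = "CD3"
    b_channel: str = "B220"
    min_aggregate_area_um2: float = 500.0
    min_object_area_um2: float = 0.0
    min_lymphocytes: int = FOCUS_MIN_LYMPHOCYTES
    index_threshold: float = 0.5
    nucleus_radius_um: float = 3.0
    nucleus_method: str = "peaks"
    paired: bool = False
    alpha: float = 0.05
    seed: int = 0
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        # Default thresholds: for a simulated cohort the staining is known, so
        # the stand-in for an operator-assigned global threshold is the
        # midpoint between background and stained intensity (Otsu has no
        # signal class on a marker-free field and would threshold noise);
        # for externally supplied images the default falls back to Otsu.
        if self.t_threshold is None:
            self.t_threshold = self._default_threshold(self.t_channel)
        if self.b_threshold is None:
            self.b_threshold = self._default_threshold(self.b_channel)
        if self.t_threshold.channel != self.t_channel:
            raise ValueError("t_threshold.channel must match t_channel")
        if self.b_threshold.channel != self.b_channel:
            raise ValueError("b_threshold.channel must match b_channel")

    def _default_threshold(self, channel: str) -> ThresholdSpec:
        if self.groups:
            cfg = next(iter(self.groups.values()))
            mid = cfg.background_intensity + cfg.intensity_of(channel) / 2.0
            return ThresholdSpec(channel, threshold=mid, method="manual")
        return ThresholdSpec(channel, method="otsu")


def _metrics_rows(
    group: str, index: int, gm: GlandMetrics
) -> tuple[dict, list[dict]]:
    gland_row = {
        "group": group,
        "field_index": index,
        "gland_area_mm2": gm.gland_area_mm2,
        "n_aggregates": len(gm.aggregates),
        "n_foci": gm.n_foci,
        "focus_score": gm.focus_score,
        "aggregate_area_fraction_pct": gm.aggregate_area_fraction_pct,
        "t_area_um2": gm.t_area_um2,
        "b_area_um2": gm.b_area_um2,
        "intersection_area_um2": gm.intersection_area_um2,
        "segregated_prevalence_pct": gm.segregated_prevalence_pct,
    }
    agg_rows = [
        {
            "group": group,
            "field_index": index,
            "aggregate_id": m.aggregate_id,
            "t_area_um2": m.t_area_um2,
            "b_area_um2": m.b_area_um2,
            "intersection_area_um2": m.intersection_area_um2,
            "nucleus_count": m.nucleus_count,
            "segregation_index": m.segregation_index,
            "segregated": m.segregated,
        }
        for m in gm.aggregates
    ]
    return gland_row, agg_rows


def _quantify_one(config: PipelineConfig, image: MultiplexImage) -> GlandMetrics:
    return quantify_field(
        image,
        t_threshold=config.t_threshold,
        b_threshold=config.b_threshold,
        dapi_channel=config.dapi_channel,
        min_aggregate_area_um2=config.min_aggregate_area_um2,
        min_object_area_um2=config.min_object_area_um2,
        min_lymphocytes=config.min_lymphocytes,
        index_threshold=config.index_threshold,
        nucleus_radius_um=config.nucleus_radius_um,
        nucleus_method=config.nucleus_method,
    )


def run_quantification(
    config: PipelineConfig,
    records: Sequence[FieldRecord] | None = None,
    image_files: Mapping[str, Sequence[str | Path]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify a cohort and return (per-field gland table, per-aggregate
    table).

    Inputs, by precedence: ``records`` (pre-simulated fields),
    ``image_files`` (group -> list of TIFF paths), else a synthetic cohort
    simulated from ``config.groups``.  Deterministic given config and seed.
    When ``config.out_dir`` is set, writes ``gland_metrics.csv``,
    ``aggregate_metrics.csv`` and a JSON run log of every resolved parameter.
    """
    truth_fields = None
    if records is None and image_files is None:
        if not config.groups:
            raise ValueError("config.groups is empty and no images were supplied")
        records = simulate_cohort(config.groups, config.n_fields_per_group, config.seed)
    if records is not None:
        items = [(r.group, r.field_index, r.image) for r in records]
        truth_fields, _ = cohort_truth_tables(records)
    else:
        items = [
            (g, i, read_tiff(p))
            for g, paths in image_files.items()
            for i, p in enumerate(paths)
        ]

    gland_rows, agg_rows = [], []
    for group, idx, image in items:
        try:
            gm = _quantify_one(config, image)
        except Exception as exc:
            raise RuntimeError(f"field {group}/{idx}: {exc}") from exc
        grow, arows = _metrics_rows(group, idx, gm)
        gland_rows.append(grow)
        agg_rows.extend(arows)

    gland_df = pd.DataFrame(gland_rows)
    agg_df = pd.DataFrame(agg_rows)
    if truth_fields is not None and len(truth_fields):
        gland_df = gland_df.merge(
            truth_fields, on=["group", "field_index"], suffixes=("", "_true")
        )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        gland_df.to_csv(out / "gland_metrics.csv", index=False)
        agg_df.to_csv(out / "aggregate_metrics.csv", index=False)
        _write_run_log(config, out, n_fields=len(gland_rows))
    return gland_df, agg_df


def _write_run_log(config: PipelineConfig, out: Path, **extra) -> None:
    def _default(o):
        if isinstance(o, (SimulationConfig, ThresholdSpec)):
            d = asdict(o)
            d.pop("gland_polygon", None)
            return d
        if isinstance(o, Path):
            return str(o)
        if isinstance(o, np.generic):
            return o.item()
        return str(o)

    log = {
        "software": "elsquant",
        "version": __version__,
        "python": sys.version.split()[0],
        "parameters": asdict(config),
        **extra,
    }
    (out / "run_log.json").write_text(json.dumps(log, default=_default, indent=1))


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def run_comparison(
    gland_df: pd.DataFrame,
    endpoints: Sequence[str] = DEFAULT_ENDPOINTS,
    group_col: str = "group",
    paired: bool = False,
    pair_col: str = "field_index",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare every endpoint between every pair of groups.

    Unpaired comparisons use the Mann–Whitney U test; ``paired=True`` aligns
    observations on ``pair_col`` and uses the Wilcoxon signed-rank test.
    Each row carries the statistic, p value, significance stars and the
    box-plot summaries (median, 25th/75th percentiles, min, max) per group.
    """
    missing = [e for e in endpoints if e not in gland_df.columns]
    if missing:
        raise KeyError(
            f"unknown endpoint(s) {missing}; available: "
            f"{sorted(c for c in gland_df.columns if c not in (group_col, pair_col))}"
        )
    groups = list(dict.fromkeys(gland_df[group_col]))
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    rows = []
    for ga, gb in combinations(groups, 2):
        a_df = gland_df[gland_df[group_col] == ga]
        b_df = gland_df[gland_df[group_col] == gb]
        for ep in endpoints:
            if paired:
                merged = a_df.merge(b_df, on=pair_col, suffixes=("_a", "_b"))
                xa = merged[f"{ep}_a"].to_numpy(dtype=float)
                xb = merged[f"{ep}_b"].to_numpy(dtype=float)
                keep = ~(np.isnan(xa) | np.isnan(xb))
                res = wilcoxon_signed_rank(xa[keep], xb[keep])
            else:
                xa = a_df[ep].dropna().to_numpy(dtype=float)
                xb = b_df[ep].dropna().to_numpy(dtype=float)
                res = mann_whitney(xa, xb)
            row = {
                "endpoint": ep,
                "group_1": ga,
                "group_2": gb,
                "test": res.method,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "significance": significance_stars(res.p_value),
                "n_1": len(xa),
                "n_2": len(xb),
            }
            for tag, vals in (("1", xa), ("2", xb)):
                row.update(
                    {
                        f"median_{tag}": float(np.median(vals)),
                        f"q25_{tag}": float(np.percentile(vals, 25)),
                        f"q75_{tag}": float(np.percentile(vals, 75)),
                        f"min_{tag}": float(np.min(vals)),
                        f"max_{tag}": float(np.max(vals)),
                    }
                )
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Demo cohort
# ---------------------------------------------------------------------------

def demo(
    out_dir: str | Path,
    seed: int = 0,
    n_fields_per_group: int = 6,
    noise_sd: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the whole synthetic study: a control-like cohort with a full
    aggregate burden versus a treated-like cohort with the burden halved,
    quantified and compared end to end.  Returns (gland table, aggregate
    table, comparison table) and writes all three plus the run log."""
    control = SimulationConfig(
        n_aggregates=4, nuclei_per_aggregate=(60, 120), noise_sd=noise_sd, seed=seed
    )
    treated = replace(control, n_aggregates=2, nuclei_per_aggregate=(55, 90))
    config = PipelineConfig(
        groups={"control": control, "treated": treated},
        n_fields_per_group=n_fields_per_group,
        seed=seed,
        out_dir=out_dir,
    )
    gland_df, agg_df = run_quantification(config)
    cmp_df = run_comparison(gland_df)
    out = Path(out_dir)
    cmp_df.to_csv(out / "comparison.csv", index=False)
    return gland_df, agg_df, cmp_df


# ---------------------------------------------------------------------------
# TOML configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a TOML file.

    Layout: top-level pipeline keys, plus one ``[simulation.<group>]`` table
    per group whose keys mirror :class:`SimulationConfig`, and optional
    ``[thresholds.<channel>]`` tables with ``threshold``/``comparison``/
    ``method`` keys.
    """
    import tomllib

    raw = tomllib.loads(Path(path).read_text())
    groups = {
        name: SimulationConfig(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in tbl.items()})
        for name, tbl in raw.pop("simulation", {}).items()
    }
    thresholds = raw.pop("thresholds", {})
    kwargs = dict(raw)
    cfg = PipelineConfig(groups=groups, **kwargs)
    for channel, tbl in thresholds.items():
        spec = ThresholdSpec(channel=channel, **tbl)
        if channel == cfg.t_channel:
            cfg.t_threshold = spec
        elif channel == cfg.b_channel:
            cfg.b_threshold = spec
        else:
            raise ValueError(
                f"threshold for unknown channel {channel!r}; "
                f"expected {cfg.t_channel!r} or {cfg.b_channel!r}"
            )
    return cfg
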