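"""File I/O and the end-to-end pipeline runner.

Interchange formats are deliberately plain: multi-page TIFF for image
volumes and masks (one page per B-scan, 32-bit float linear intensity),
YAML/JSON for configuration, CSV for boundaries, quantification tables and
statistics.  ``run_pipeline`` glues simulate → reconstruct → segment →
quantify → report, records a manifest (seed, parameters, version), and is
reproducible: the same config and seed yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .geometry import ScanGeometry
from .reconstruction import OCTVolume
from .segmentation import SENTINEL, WallMask

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "read_volume",
    "write_volume",
    "write_mask",
    "read_mask",
    "write_boundaries",
    "read_boundaries",
    "run_pipeline",
]


def write_volume(vol: OCTVolume, path: str | Path, geom_sidecar: bool = True) -> None:
    """Write a volume as multi-page float32 TIFF plus a geometry sidecar."""
    path = Path(path)
    tifffile.imwrite(path, vol.data.astype(np.float32), photometric="minisblack")
    if geom_sidecar:
        vol.geom.save(path.with_suffix(".geom.yaml"))


def read_volume(
    path: str | Path, geom: ScanGeometry | None = None, scale: str = "linear"
) -> OCTVolume:
    """Read a multi-page TIFF volume, validating it against the geometry.

    With ``geom=None`` the sidecar written by :func:`write_volume` is used.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if geom is None:
        sidecar = path.with_suffix(".geom.yaml")
        if not sidecar.exists():
            raise FileNotFoundError(f"no geometry given and no sidecar {sidecar}")
        geom = ScanGeometry.load(sidecar)
    expected = (geom.n_bscans, geom.a_lines_per_bscan, geom.n_depth_samples)
    if data.shape != expected:
        raise ValueError(
            f"{path}: volume shape {data.shape} does not match geometry {expected}"
        )
    return OCTVolume(data=np.asarray(data, dtype=np.float64), geom=geom, scale=scale)


def write_mask(wall: WallMask, path: str | Path) -> None:
    tifffile.imwrite(Path(path), wall.mask.astype(np.uint8), photometric="minisblack")


def read_mask(path: str | Path, boundaries_csv: str | Path) -> WallMask:
    mask = tifffile.imread(Path(path))
    top, bottom = read_boundaries(boundaries_csv, mask.shape[:-1])
    return WallMask(mask=mask, top_boundary=top, bottom_boundary=bottom)


def write_boundaries(wall: WallMask, path: str | Path) -> None:
    """Boundaries as CSV (bscan, a_line, top, bottom); sentinel −1 = missing."""
    top = np.atleast_2d(wall.top_boundary)
    bottom = np.atleast_2d(wall.bottom_boundary)
    nb, na = top.shape
    b, a = np.meshgrid(np.arange(nb), np.arange(na), indexing="ij")
    pd.DataFrame(
        {
            "bscan": b.ravel(),
            "a_line": a.ravel(),
            "top": top.ravel(),
            "bottom": bottom.ravel(),
        }
    ).to_csv(path, index=False)


def read_boundaries(path: str | Path, shape: tuple[int, int]):
    df = pd.read_csv(path)
    top = np.full(shape, SENTINEL, dtype=int)
    bottom = np.full(shape, SENTINEL, dtype=int)
    top[df["bscan"], df["a_line"]] = df["top"]
    bottom[df["bscan"], df["a_line"]] = df["bottom"]
    return top, bottom


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run.

    ``skip`` lists stage names (subset of simulate/segment/quantify/report)
    to omit; skipped stages expect their outputs to already exist in
    ``out_dir`` from an earlier run.
    """

    out_dir: str = "coloct_out"
    seed: int = 0
    n_per_group: int = 3
    days: tuple[int, ...] = (0, 9, 24)
    n_locations: int = 10
    geometry: dict = field(default_factory=dict)
    phantom: dict = field(default_factory=dict)
    effect: dict | None = None
    segmentation: dict = field(default_factory=dict)
    response: str = "thickness_um"
    unit: str = "mouse_mean"
    skip: tuple[str, ...] = ()
    write_volumes: bool = False
    make_figures: bool = False
    log_level: str = "INFO"

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("days", "skip"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def _build_study_objects(config: PipelineConfig):
    from . import phantom as ph

    geom = ph.default_phantom_geometry(**config.geometry)
    spec_kwargs = dict(config.phantom)
    spec = ph.PhantomSpec(**spec_kwargs) if spec_kwargs else ph.PhantomSpec()
    if config.effect is None:
        effect = ph.ColitisEffect()
    else:
        sched = {int(k): tuple(v) for k, v in config.effect.items()}
        effect = ph.ColitisEffect(day_schedule=sched)
    design = ph.StudyDesign(
        days=tuple(config.days),
        n_per_group=config.n_per_group,
        n_locations=config.n_locations,
        seed=config.seed,
    )
    return design, spec, effect, geom


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full synthetic-study pipeline; returns the artifact directory.

    Artifacts: ``manifest.json``, per-volume TIFFs (optional),
    ``boundaries/*.csv``, ``quant.csv``, ``anova_*.csv``, ``summary.csv``
    and optional box-plot figures.
    """
    from . import phantom as ph
    from . import quantification as qn
    from . import stats as st

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design, spec, effect, geom = _build_study_objects(config)
    seg_params = ph.default_segmentation_params(spec, geom, **config.segmentation)

    manifest = {
        "package": "coloct",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    t0 = time.perf_counter()
    if "simulate" in config.skip:
        if not list(out.glob("vol_*.tif")):
            raise FileNotFoundError(
                f"--skip simulate: no vol_*.tif found in {out}; run once with "
                f"write_volumes=True first"
            )
        records = _load_records(out, geom, design, spec, effect)
    else:
        records = ph.simulate_study(design, spec, effect, geom)
        if config.write_volumes:
            for rec in records:
                write_volume(rec.volume, out / f"vol_{rec.mouse_id}_d{rec.day:02d}.tif")
    manifest["stages"]["simulate"] = {"seconds": round(time.perf_counter() - t0, 3)}
    log.info("simulate: %d volumes in %.1fs", len(records), time.perf_counter() - t0)

    t0 = time.perf_counter()
    quant = qn.quantify_study(
        records,
        geom,
        n_locations=config.n_locations,
        seg_params=seg_params,
    )
    quant = qn.normalize_to_baseline(quant, "mu_A_mm", baseline_day=min(config.days))
    quant.to_csv(out / "quant.csv", index=False, float_format="%.6g")
    manifest["stages"]["quantify"] = {"seconds": round(time.perf_counter() - t0, 3)}
    log.info("quantify: %d rows in %.1fs", len(quant), time.perf_counter() - t0)

    t0 = time.perf_counter()
    results = {}
    anova_t = st.two_way_anova(quant, response="thickness_um", unit=config.unit)
    anova_t.to_csv(out / "anova_thickness.csv")
    results["thickness_interaction_p"] = st.interaction_pvalue(anova_t)
    for layer in quant["layer"].unique():
        at = st.two_way_anova(quant, response="mu_A_mm", unit=config.unit, layer=layer)
        at.to_csv(out / f"anova_mu_{layer}.csv")
        results[f"mu_interaction_p_{layer}"] = st.interaction_pvalue(at)
    st.summarize(quant, "thickness_um").to_csv(out / "summary.csv", index=False)
    if config.make_figures:
        _boxplots(quant, out)
    manifest["stages"]["report"] = {
        "seconds": round(time.perf_counter() - t0, 3),
        "interaction_p": results,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _load_records(out: Path, geom: ScanGeometry, design, spec, effect):
    """Re-attach volumes written by an earlier run to freshly regenerated
    ground truth (same seeds, render=False)."""
    from .phantom import simulate_study

    records = simulate_study(design, spec, effect, geom, render=False)
    for rec in records:
        tif = out / f"vol_{rec.mouse_id}_d{rec.day:02d}.tif"
        if not tif.exists():
            raise FileNotFoundError(f"--skip simulate: missing {tif}")
        rec.volume = read_volume(tif, geom)
    return records


def _boxplots(quant: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for value, fname in (("thickness_um", "thickness_box.png"), ("mu_A_mm", "attenuation_box.png")):
        fig, ax = plt.subplots(figsize=(6, 4))
        groups = sorted(quant["group"].unique())
        days = sorted(quant["day"].unique())
        width = 0.35
        for gi, g in enumerate(groups):
            data = [
                quant[(quant["group"] == g) & (quant["day"] == d)][value].dropna()
                for d in days
            ]
            pos = np.arange(len(days)) + (gi - 0.5) * width
            ax.boxplot(data, positions=pos, widths=width * 0.9)
        ax.set_xticks(np.arange(len(days)))
        ax.set_xticklabels([f"day {d}" for d in days])
        ax.set_ylabel(value)
        fig.tight_layout()
        fig.savefig(out / fname, dpi=100)
        plt.close(fig)
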