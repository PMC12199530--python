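"""Image and table I/O, run configuration, and the composite pipeline.

Images travel as multi-page TIFF (one page per channel or frame) with the
physical pixel size and channel names in a JSON sidecar next to the file
(``X.tif`` ↔ ``X.tif.json``) — TIFF resolution tags are dialect-ridden, a
sidecar is unambiguous. Integer data round-trip bit-exactly.

:class:`RunConfig` gathers every stage parameter (defaults match the module
defaults), rejects unknown keys, and round-trips losslessly through YAML or
JSON. :func:`run_pipeline` executes the seeded section-phantom cohort →
segmentation → ROI quantification → group statistics chain and writes CSV
tables, a JSON summary, and a log recording the fully resolved parameter set.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict

from . import glomquant, stats, synthdata
from .core import ImageStack

logger = logging.getLogger(__name__)

__all__ = ["read_image", "write_image", "RunConfig", "run_pipeline"]


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".json")


def write_image(stack: ImageStack, path: str | Path) -> Path:
    """Write an ImageStack as a multi-page TIFF plus JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # one grayscale page per channel/frame (3-plane stacks must not be RGB)
    tifffile.imwrite(path, stack.data, photometric="minisblack")
    meta = {
        "channel_names": list(stack.channel_names),
        "pixels_per_micron": stack.pixels_per_micron,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_image(path: str | Path, pixels_per_micron: float | None = None) -> ImageStack:
    """Read a TIFF written by :func:`write_image` (or any plain TIFF).

    Without a sidecar, ``pixels_per_micron`` must be supplied explicitly
    (CLI flag ``--pixels-per-micron``); channels are then named ``ch0..chN``.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[np.newaxis]
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        names = meta["channel_names"]
        ppm = pixels_per_micron if pixels_per_micron is not None else meta["pixels_per_micron"]
    else:
        if pixels_per_micron is None:
            raise ValueError(
                f"no pixel-size sidecar found for {path}; "
                "supply --pixels-per-micron (pixels_per_micron=...)"
            )
        names = [f"ch{i}" for i in range(data.shape[0])]
        ppm = pixels_per_micron
    return ImageStack(data, names, float(ppm))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SectionSimConfig(_Strict):
    """Parameters of the simulated section cohort (one image per subject)."""

    n_subjects_per_group: int = 5
    n_glomeruli: int = 20
    image_size_px: tuple[int, int] = (1200, 1200)
    pixels_per_micron: float = 2.64
    glomerulus_radius_um: tuple[float, float] = (18.0, 26.0)
    group_effects: dict[str, float] = {
        "control": 1.0,
        "MCD": 1.3,
        "Prim FSGS": 0.6,
        "Sec FSGS": 1.0,
    }
    subject_base: float = 100.0
    noise_cv: float = 0.2
    subject_cv: float = 0.1


class SegmentationConfig(_Strict):
    sigma_um: float = 5.0
    d_min_um: float = 30.0
    opening_radius_px: int = 2


class StatsConfig(_Strict):
    control_group: str = "control"
    alpha: float = 0.05
    per_subject: bool = True


class RunConfig(_Strict):
    """Full configuration of a composite run; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "results"
    target_channel: str = "target"
    marker_channel: str = "marker"
    section: SectionSimConfig = SectionSimConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    stats: StatsConfig = StatsConfig()

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        payload = yaml.safe_load(text)
        return cls.model_validate(payload)

    def to_file(self, path: str | Path) -> None:
        payload = self.model_dump(mode="json")
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


# ---------------------------------------------------------------------------
# Composite pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Simulate a section cohort, quantify it, compare groups, write a report.

    Outputs in ``config.out_dir``: ``per_glomerulus.csv``, ``per_subject.csv``,
    ``summary.json`` and ``run.log``. Returns the summary dict. Deterministic
    under a fixed config (including seed).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("podoquant")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("resolved config: %s", json.dumps(config.model_dump(mode="json")))
        sec = config.section
        base_spec = synthdata.SectionPhantomSpec(
            image_size_px=tuple(sec.image_size_px),
            pixels_per_micron=sec.pixels_per_micron,
            n_glomeruli=sec.n_glomeruli,
            glomerulus_radius_um=tuple(sec.glomerulus_radius_um),
            group_effects=dict(sec.group_effects),
            group=next(iter(sec.group_effects)),
            subject_base=sec.subject_base,
            noise_cv=sec.noise_cv,
        )
        seg_params = glomquant.SegmentationParams(
            sigma_um=config.segmentation.sigma_um,
            d_min_um=config.segmentation.d_min_um,
            opening_radius_px=config.segmentation.opening_radius_px,
        )
        measurements = []
        for sid, group, stack, _gt in synthdata.gen_section_cohort(
            sec.n_subjects_per_group, base_spec, subject_cv=sec.subject_cv, seed=config.seed
        ):
            mask = glomquant.segment_glomeruli(stack, config.marker_channel, seg_params)
            rois = glomquant.measure_rois(stack, mask, subject_id=sid, group=group)
            logger.info("subject %s (%s): %d glomeruli", sid, group, len(rois))
            measurements.extend(rois)
        per_glom, per_subject = glomquant.aggregate(measurements, channel=config.target_channel)
        per_glom.to_csv(out / "per_glomerulus.csv", index=False)
        per_subject.to_csv(out / "per_subject.csv", index=False)

        table = per_subject if config.stats.per_subject else per_glom
        comparison = stats.compare_groups(
            table, control=config.stats.control_group, alpha=config.stats.alpha
        )
        ctrl = config.stats.control_group
        group_means = per_subject.groupby("group")["value"].mean()
        summary = {
            "seed": config.seed,
            "n_subjects": int(per_subject.shape[0]),
            "n_glomeruli": int(per_glom.shape[0]),
            "group_means": {g: float(v) for g, v in group_means.items()},
            "group_ratios_vs_control": {
                g: float(v / group_means[ctrl]) for g, v in group_means.items()
            },
            "comparison": {
                "test_name": comparison.test_name,
                "statistic": comparison.statistic,
                "p_value": comparison.p_value,
                "records": [
                    {
                        "group": r.group,
                        "p_raw": r.p_raw,
                        "p_adjusted": r.p_adjusted,
                        "significant": r.significant,
                    }
                    for r in comparison.records
                ],
            },
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        logger.info("pipeline finished: %d glomeruli, %d subjects",
                    per_glom.shape[0], per_subject.shape[0])
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read a tidy cohort CSV; requires at least ``group`` and ``value`` columns."""
    df = pd.read_csv(path)
    missing = {"group", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    return df
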