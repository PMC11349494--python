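"""End-to-end analysis pipeline: detect -> fit -> size -> match -> aberration.

Every removal is accounted for: the audit log satisfies
``detected = exported + removed_by_size + removed_by_overlap +
removed_by_border + removed_by_fit + removed_by_user`` per channel, with
match removals tracked separately (matching does not delete records, it
selects rows).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import detect as _detect
from . import fit as _fit
from . import fwhm as _fwhm
from . import register as _register
from .errors import UsageError
from .iolayer import ImageStack
from .records import ParticleRecord

logger = logging.getLogger("speckler")

__all__ = ["PipelineConfig", "ChannelLog", "PipelineResult", "analyze_channel",
           "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`."""

    thresholds: Sequence[float] | None = None  # None -> Otsu auto threshold
    buffer_b: float = 0.3
    size_min_px: int = 1
    size_max_px: int | None = None
    exclude_overlaps: bool = True
    drop_border: bool = True
    roi: tuple | None = None
    fit_dims: int = 3
    fit_theta: bool = False
    local_bg: bool = True
    bg_buffer_p: float = 0.15
    upsample: int = 10
    sort_fwhm: bool = False
    exclude_ids: Sequence[int] = ()
    match: bool = False
    ref_channel: int = 0
    max_match_dist_nm: float = _register.DEFAULT_MAX_DIST_NM
    aberration: str | None = None  # None | "affine" | "poly_surface"
    aberration_degree: int = 2
    channels: Sequence[int] | None = None  # default: all

    def __post_init__(self) -> None:
        if self.fit_dims not in (2, 3):
            raise UsageError("fit_dims must be 2 or 3")
        if self.aberration not in (None, "affine", "poly_surface"):
            raise UsageError(f"unknown aberration model {self.aberration!r}")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Build a config from a plain-text ``key = value`` file.

        Lines starting with ``#`` are comments; keyword overrides win over
        file entries. Values are parsed as Python literals where possible
        (``thresholds = 800, 300`` gives a two-pass threshold list).
        """
        import ast
        from pathlib import Path

        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise UsageError(f"{path}:{lineno}: expected key = value")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in cls.__dataclass_fields__:
                raise UsageError(f"{path}:{lineno}: unknown option {key!r}")
            try:
                kwargs[key] = ast.literal_eval(value.strip())
            except (ValueError, SyntaxError):
                kwargs[key] = value.strip()
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class ChannelLog:
    """Per-channel audit counts; detection equals exported plus removals."""

    channel: int
    threshold_used: list[float] = field(default_factory=list)
    threshold_relative: float = float("nan")  # (T - bg median) / bg MAD
    detected: int = 0
    removed_by_size: int = 0
    removed_by_overlap: int = 0
    removed_by_border: int = 0
    removed_by_fit: int = 0
    removed_by_user: int = 0
    removed_by_match: int = 0
    exported: int = 0

    def conserved(self) -> bool:
        return self.detected == (
            self.exported + self.removed_by_size + self.removed_by_overlap
            + self.removed_by_border + self.removed_by_fit + self.removed_by_user
        )


@dataclass
class PipelineResult:
    per_channel_records: dict[int, list[ParticleRecord]]
    logs: dict[int, ChannelLog]
    matched: "_register.MatchedSet | None" = None
    aberration_stats: dict | None = None
    aberration_model: "_register.AberrationModel | None" = None
    summaries: dict[int, dict] = field(default_factory=dict)


def analyze_channel(
    stack: ImageStack, channel: int, cfg: PipelineConfig
) -> tuple[list[ParticleRecord], ChannelLog]:
    """Run detection, fitting, background and FWHM sizing for one channel."""
    log = ChannelLog(channel=channel)
    det_cfg = _detect.DetectionConfig(
        buffer_b=cfg.buffer_b,
        size_min_px=cfg.size_min_px,
        size_max_px=cfg.size_max_px,
        exclude_overlaps=cfg.exclude_overlaps,
        roi=cfg.roi,
    )
    if cfg.thresholds is None:
        thresholds = [_detect.auto_threshold(stack, channel)]
    else:
        thresholds = list(cfg.thresholds)
    log.threshold_used = [float(t) for t in thresholds]
    volume = np.asarray(stack.channel(channel), dtype=float)
    med = float(np.median(volume))
    mad = float(np.median(np.abs(volume - med)))
    if mad > 0:
        log.threshold_relative = (thresholds[0] - med) / mad
    logger.info(
        "ch%d: threshold %s (relative %.1f MAD above background median)",
        channel, thresholds, log.threshold_relative,
    )

    if len(thresholds) == 1:
        boxes = _detect.detect_particles(stack, channel, thresholds[0], det_cfg)
    else:
        boxes = _detect.multi_threshold_detect(stack, channel, thresholds, det_cfg)
    log.detected = len(boxes)

    sized = _detect.filter_by_size(boxes, det_cfg)
    log.removed_by_size = len(boxes) - len(sized)

    if cfg.exclude_overlaps:
        kept = _detect.exclude_overlapping(sized)
        log.removed_by_overlap = len(sized) - len(kept)
    else:
        kept = sized

    if cfg.drop_border:
        interior = [b for b in kept if not b.border]
        log.removed_by_border = len(kept) - len(interior)
    else:
        interior = kept

    bg_cfg = _fit.BackgroundConfig(enabled=cfg.local_bg, bg_buffer_p=cfg.bg_buffer_p) \
        if cfg.local_bg else None
    records: list[ParticleRecord] = []
    for box in interior:
        fitres = _fit.fit_gaussian(
            stack, box, dims=cfg.fit_dims, bg=bg_cfg, fit_theta=cfg.fit_theta
        )
        if not fitres.ok:
            log.removed_by_fit += 1
            continue
        intensities = _fit.measure_intensities(
            stack, box, fitres, bg=bg_cfg, all_boxes=interior
        )
        triple = _fwhm.measure_fwhm(
            stack, fitres,
            background=intensities["background_used"] if cfg.local_bg else fitres.base,
            upsample=cfg.upsample,
        )
        fitted_axes = [0, 1] + ([2] if cfg.fit_dims == 3 else [])
        unmeasurable = bool(
            np.any(~np.isfinite(triple.tfwhm_nm[fitted_axes]))
            or np.any(~np.isfinite(triple.ifwhm_nm[fitted_axes]))
        )
        records.append(
            ParticleRecord(
                id=0,  # assigned below
                channel=channel,
                wavelength_nm=stack.wavelengths_nm[channel],
                center_nm=np.asarray(fitres.center_nm, dtype=float),
                theta_rad=np.asarray(fitres.theta_rad, dtype=float),
                sigma_nm=np.asarray(fitres.sigma_nm, dtype=float),
                gauss_base=fitres.base,
                gauss_peak=fitres.peak,
                resnorm=fitres.resnorm,
                integrated_intensity=intensities["integrated"],
                max_intensity=intensities["max"],
                tfwhm_nm=triple.tfwhm_nm,
                ifwhm_nm=triple.ifwhm_nm,
                gfwhm_nm=triple.gfwhm_nm,
                border=box.border,
                unmeasurable=unmeasurable,
            )
        )

    for i, rec in enumerate(records, start=1):
        rec.id = i
    if cfg.exclude_ids:
        excl = set(cfg.exclude_ids)
        before = len(records)
        records = [r for r in records if r.id not in excl]
        log.removed_by_user = before - len(records)
        for i, rec in enumerate(records, start=1):
            rec.id = i
    if cfg.sort_fwhm:
        records = [r.sorted_fwhm() for r in records]
    log.exported = len(records)
    logger.info(
        "ch%d: %d detected -> %d exported (size %d, overlap %d, border %d, "
        "fit %d, user %d)",
        channel, log.detected, log.exported, log.removed_by_size,
        log.removed_by_overlap, log.removed_by_border, log.removed_by_fit,
        log.removed_by_user,
    )
    return records, log


def run_pipeline(stack: ImageStack, cfg: PipelineConfig) -> PipelineResult:
    """Analyze every requested channel; optionally match and fit aberrations."""
    channels = list(cfg.channels) if cfg.channels is not None \
        else list(range(stack.n_channels))
    if (cfg.match or cfg.aberration) and len(channels) < 2:
        raise UsageError("matching/aberration needs at least two channels")

    per_channel: dict[int, list[ParticleRecord]] = {}
    logs: dict[int, ChannelLog] = {}
    for c in channels:
        records, log = analyze_channel(stack, c, cfg)
        per_channel[c] = records
        logs[c] = log

    result = PipelineResult(per_channel_records=per_channel, logs=logs)
    for c, records in per_channel.items():
        measurable = [r for r in records if not r.unmeasurable]
        if measurable:
            result.summaries[c] = _fwhm.summarize_sizes(measurable)

    if cfg.match or cfg.aberration:
        matched = _register.match_points(
            per_channel, ref_channel=cfg.ref_channel,
            max_dist_nm=cfg.max_match_dist_nm,
        )
        for c, n in matched.unmatched_removed.items():
            logs[c].removed_by_match = n
        result.matched = matched
        result.aberration_stats = _register.aberration_stats(matched, per_channel)
        if cfg.aberration:
            result.aberration_model = _register.fit_aberration(
                matched, per_channel, kind=cfg.aberration,
                degree=cfg.aberration_degree,
            )
    return result
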