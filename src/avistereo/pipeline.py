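"""End-to-end processing: frames in, archived events out.

Per synchronized stereo frame pair the pipeline runs: motion detection
on each camera, optional CNN screening of the crops, cross-camera
matching, localization, size estimation, size classification, action
selection, and event archiving.  Per-frame failures are logged and the
pipeline continues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from . import decision, detection, stereo
from .config import SystemConfig
from .identification import BirdCnn, classify_crop

__all__ = ["StereoFramePair", "run_pipeline", "frame_pairs_from_dir", "evaluate_archive"]

logger = logging.getLogger("avistereo.pipeline")


@dataclass
class StereoFramePair:
    """Consecutive frames from both cameras at one instant."""

    timestamp: float
    upper_prev: detection.FrameImage
    upper_curr: detection.FrameImage
    lower_prev: detection.FrameImage
    lower_curr: detection.FrameImage


def _messages(
    candidates: list[detection.DetectionCandidate],
    camera: str,
    timestamp: float,
    module_id: str,
) -> list[decision.DetectionMessage]:
    out = []
    for cand in candidates:
        xc, yc = cand.centroid
        out.append(
            decision.DetectionMessage(
                module_id=module_id,
                camera=camera,
                timestamp=timestamp,
                o_s=cand.o_s,
                p_w=cand.p_w,
                p_h=cand.p_h,
                # 0-based image rows -> 1-based stereo axis rows
                centroid=(xc + 1.0, yc + 1.0),
            )
        )
    return out


def run_pipeline(
    cfg: SystemConfig,
    frame_pairs: Iterable[StereoFramePair],
    archive: decision.EventArchive | None = None,
    model: BirdCnn | None = None,
    module_id: str = "module-A",
) -> list[decision.Event]:
    """Run the full chain over a stream of stereo frame pairs.

    With ``model`` given, candidates whose crop scores below 0.5 bird
    probability are discarded before matching.  Returns the events (also
    appended to ``archive`` when provided).
    """
    rig = cfg.rig()
    assembly = cfg.assembly()
    params = cfg.detection_params()
    boundaries = cfg.boundaries()
    policy = cfg.policy()
    matching = cfg.raw["matching"]
    events: list[decision.Event] = []

    for pair in frame_pairs:
        try:
            cands = {}
            crops = {}
            for camera, prev, curr in (
                ("upper", pair.upper_prev, pair.upper_curr),
                ("lower", pair.lower_prev, pair.lower_curr),
            ):
                found = detection.detect(prev, curr, params)
                if model is not None:
                    found = [
                        c for c in found
                        if c.crop is not None and classify_crop(model, c.crop) >= 0.5
                    ]
                msgs = _messages(found, camera, pair.timestamp, module_id)
                cands[camera] = msgs
                crops.update(zip(msgs, (c.crop for c in found)))
            synced = decision.synchronize_streams(
                cands["upper"], cands["lower"],
                tolerance=matching["sync_tolerance_s"],
            )
            matched = []
            for upper_msgs, lower_msgs in synced:
                matched.extend(
                    decision.match_objects(
                        upper_msgs,
                        lower_msgs,
                        max_center_offset=matching["max_center_offset_px"],
                        min_ydiff=matching["min_disparity_px"],
                    )
                )
            for k, mp in enumerate(matched):
                est = decision.estimate_size(mp, rig, assembly)
                loc = stereo.localize(
                    stereo.StereoObservation(y_u=mp.upper.yc, y_d=mp.lower.yc), rig
                )
                label = decision.classify_size(est, boundaries)
                actions = decision.decide_action(label, loc.d, policy)
                crop_path = ""
                crop = crops.get(mp.upper)
                if archive is not None and crop is not None:
                    from PIL import Image

                    media = archive.root / "media"
                    media.mkdir(exist_ok=True)
                    name = f"{pair.timestamp:.3f}_{module_id}_{k}.png"
                    Image.fromarray(crop).save(media / name)
                    crop_path = f"media/{name}"
                event = decision.Event(
                    timestamp=pair.timestamp,
                    module_id=module_id,
                    size_class=label,
                    d=loc.d,
                    h=loc.h,
                    d_b=est.distance_db,
                    delta_db=est.distance_db_delta,
                    wingspan=est.wingspan,
                    body_height=est.body_height,
                    contour_area=est.contour_area,
                    approx_area=est.approx_area,
                    actions=tuple(sorted(actions)),
                    crop_path=crop_path,
                )
                if archive is not None:
                    archive.append(event)
                events.append(event)
        except Exception:  # noqa: BLE001 - keep the stream alive
            logger.exception("frame pair at t=%s failed; continuing", pair.timestamp)
    return events


def frame_pairs_from_dir(root: str | Path) -> Iterator[StereoFramePair]:
    """Read scenes written by the simulator: per scene stem, four PNGs
    ``<stem>_{upper,lower}_{prev,curr}.png``, ordered by stem."""
    from PIL import Image

    root = Path(root)
    stems = sorted(
        p.name[: -len("_upper_curr.png")]
        for p in root.glob("*_upper_curr.png")
    )
    for t, stem in enumerate(stems):
        frames = {}
        for part in ("upper_prev", "upper_curr", "lower_prev", "lower_curr"):
            path = root / f"{stem}_{part}.png"
            frames[part] = detection.FrameImage(
                np.asarray(Image.open(path)), timestamp=float(t)
            )
        yield StereoFramePair(timestamp=float(t), **frames)


def evaluate_archive(
    events: list[decision.Event], truths: list[dict]
) -> dict:
    """Compare archived events against ground-truth sidecars.

    ``truths`` carry one record per scene with a ``detectable`` flag and
    the true class ``label``.  Scenes are matched to events by order of
    timestamp.  Returns detection confusion counts plus per-class
    classification accuracy among detected targets.
    """
    from .identification import ConfusionCounts, compute_metrics

    tp = fp = fn = tn = 0
    class_hits = 0
    class_total = 0
    by_t: dict[float, list[decision.Event]] = {}
    for ev in events:
        by_t.setdefault(ev.timestamp, []).append(ev)
    for t, truth in enumerate(truths):
        got = by_t.get(float(t), [])
        if truth.get("detectable", True):
            if got:
                tp += 1
                class_total += 1
                if any(ev.size_class == truth["label"] for ev in got):
                    class_hits += 1
            else:
                fn += 1
        else:
            if got:
                fp += 1
            else:
                tn += 1
    counts = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
    report = compute_metrics(counts)
    return {
        "counts": counts,
        "metrics": report,
        "class_accuracy": class_hits / class_total if class_total else float("nan"),
    }
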