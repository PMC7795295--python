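"""Fusion of upper/lower camera detections and the avoidance decision.

The decision chain: synchronize the two detection streams by timestamp,
pair objects across cameras by nearest image-centre distance (greedy over
the full distance matrix), drop implausible pairs (centre offsets above
150 px, disparity below 1 px — typically insects close to the rig or
mismatches), convert the pair's disparity to a baseline distance,
translate pixel extents into physical wingspan / body height / area, vote
a size class per parameter against the configured boundaries (the final
class is the *largest* any parameter indicates, a deliberately
conservative rule), and finally select deterrent / turbine-stop actions
from the per-class trigger distances.  Every decision is archived as an
event row (CSV and JSON-lines).
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

logger = logging.getLogger("avistereo.decision")

from .optics import OpticalAssembly
from .stereo import StereoRig, baseline_distance

__all__ = [
    "DetectionMessage",
    "MatchedPair",
    "SizeEstimate",
    "SizeClassBoundaries",
    "ActionPolicy",
    "Event",
    "EventArchive",
    "CLASS_ORDER",
    "synchronize_streams",
    "match_objects",
    "estimate_size",
    "approx_area",
    "classify_size",
    "decide_action",
    "record_event",
]

CLASS_ORDER = ("uncategorized", "small", "medium", "large")
_RANK = {name: i for i, name in enumerate(CLASS_ORDER)}


@dataclass(frozen=True)
class DetectionMessage:
    """One detected object reported by a camera's local processing unit."""

    module_id: str
    camera: str  # "upper" | "lower"
    timestamp: float
    o_s: float
    p_w: float
    p_h: float
    centroid: tuple[float, float]  # (xc, yc), 1-based stereo axis for yc

    @property
    def xc(self) -> float:
        return self.centroid[0]

    @property
    def yc(self) -> float:
        return self.centroid[1]


@dataclass(frozen=True)
class MatchedPair:
    upper: DetectionMessage
    lower: DetectionMessage

    @property
    def center_distance(self) -> float:
        return math.hypot(self.upper.xc - self.lower.xc, self.upper.yc - self.lower.yc)

    @property
    def yc_diff(self) -> float:
        return self.upper.yc - self.lower.yc

    @property
    def xc_diff(self) -> float:
        return self.upper.xc - self.lower.xc


@dataclass(frozen=True)
class SizeEstimate:
    """Physical size of a matched object, with quantization half-widths."""

    wingspan: float
    wingspan_delta: float
    body_height: float
    body_height_delta: float
    contour_area: float
    approx_area: float
    distance_db: float
    distance_db_delta: float


@dataclass(frozen=True)
class SizeClassBoundaries:
    """Lower class boundaries for wingspan [m], height [m], area [m2].

    Each triple is (small, medium, large) lower bounds; intervals are
    half-open ``[lo, next_lo)`` so gaps between listed boundaries
    (e.g. 1.25 -> 1.26) are bridged, and the large class is open above.  Values below the small
    bound on every parameter are *uncategorized*.
    """

    wingspan: tuple[float, float, float] = (0.68, 1.26, 1.505)
    height: tuple[float, float, float] = (0.32, 0.40, 0.555)
    area: tuple[float, float, float] = (0.11, 0.25, 0.415)

    def __post_init__(self) -> None:
        for name in ("wingspan", "height", "area"):
            lo = getattr(self, name)
            if not (lo[0] < lo[1] < lo[2]):
                raise ValueError(f"{name} boundaries must be strictly increasing")

    def classify_value(self, value: float, parameter: str) -> str:
        lo_s, lo_m, lo_l = getattr(self, parameter)
        if value > lo_l or math.isclose(value, lo_l):
            # the large bounds are exclusive (">1.50"); the stored lower
            # bound sits between the medium top and the large bottom
            return "large"
        if value >= lo_m:
            return "medium"
        if value >= lo_s:
            return "small"
        return "uncategorized"


@dataclass(frozen=True)
class ActionPolicy:
    """Per-class trigger distances [m] for each avoidance action.

    An action fires when the object's horizontal distance is at or below
    its trigger (boundary inclusive); ``None`` disables the action for
    that class.  Turbine stopping implies the deterrents are also active.
    Defaults: deterrents at 300 m for all bird classes, turbine stop at
    200 m for large birds only — illustrative and fully configurable.
    """

    strobe: dict = field(
        default_factory=lambda: {"small": 300.0, "medium": 300.0, "large": 300.0}
    )
    audio: dict = field(
        default_factory=lambda: {"small": 300.0, "medium": 300.0, "large": 300.0}
    )
    turbine_stop: dict = field(default_factory=lambda: {"large": 200.0})

    def __post_init__(self) -> None:
        for name in ("strobe", "audio", "turbine_stop"):
            for cls, dist in getattr(self, name).items():
                if cls not in CLASS_ORDER:
                    raise ValueError(f"unknown class {cls!r} in policy.{name}")
                if dist is not None and dist <= 0:
                    raise ValueError("trigger distances must be positive")


@dataclass
class Event:
    """The archival unit: a fused, classified detection with its action."""

    timestamp: float
    module_id: str
    size_class: str
    d: float
    h: float
    d_b: float
    delta_db: float
    wingspan: float
    body_height: float
    contour_area: float
    approx_area: float
    actions: tuple[str, ...]
    crop_path: str = ""

    def to_row(self) -> dict:
        row = asdict(self)
        row["actions"] = "|".join(self.actions)
        return row

    @classmethod
    def from_row(cls, row: dict) -> "Event":
        actions = tuple(a for a in str(row["actions"]).split("|") if a)
        kwargs = {k: row[k] for k in row if k != "actions"}
        for key in ("timestamp", "d", "h", "d_b", "delta_db", "wingspan",
                    "body_height", "contour_area", "approx_area"):
            kwargs[key] = float(kwargs[key])
        kwargs["module_id"] = str(kwargs["module_id"])
        kwargs["size_class"] = str(kwargs["size_class"])
        kwargs["crop_path"] = str(kwargs.get("crop_path", "") or "")
        return cls(actions=actions, **kwargs)


# ---------------------------------------------------------------------------

def synchronize_streams(
    upper: list[DetectionMessage],
    lower: list[DetectionMessage],
    tolerance: float = 0.05,
) -> list[tuple[list[DetectionMessage], list[DetectionMessage]]]:
    """Pair co-timed message sets from the two cameras.

    Messages are grouped into instants by timestamp; instants are matched
    greedily by smallest time offset, accepting a pair only if both
    instants are unused and the offset is within ``tolerance`` seconds.
    Unmatched instants are dropped.
    """
    for name, stream in (("upper", upper), ("lower", lower)):
        ts = [m.timestamp for m in stream]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError(f"{name} stream is not time-sorted")

    def group(stream):
        instants: dict[float, list[DetectionMessage]] = {}
        for m in stream:
            instants.setdefault(m.timestamp, []).append(m)
        return sorted(instants.items())

    gu, gl = group(upper), group(lower)
    offsets = [
        (abs(tu - tl), i, j)
        for i, (tu, _) in enumerate(gu)
        for j, (tl, _) in enumerate(gl)
        if abs(tu - tl) <= tolerance
    ]
    offsets.sort()
    used_u: set[int] = set()
    used_l: set[int] = set()
    pairs = []
    for _, i, j in offsets:
        if i in used_u or j in used_l:
            continue
        used_u.add(i)
        used_l.add(j)
        pairs.append((gu[i][0], gu[i][1], gl[j][1]))
    dropped = (len(gu) - len(used_u)) + (len(gl) - len(used_l))
    if dropped:
        logger.info("synchronize_streams: dropped %d unmatched instant(s)", dropped)
    pairs.sort(key=lambda p: p[0])
    return [(mu, ml) for _, mu, ml in pairs]


def match_objects(
    upper_objs: list[DetectionMessage],
    lower_objs: list[DetectionMessage],
    max_center_offset: float = 150.0,
    min_ydiff: float = 1.0,
) -> list[MatchedPair]:
    """Greedy nearest-centre assignment followed by the false-pair filter.

    All L x M centre distances are sorted ascending; a pair is accepted
    when both members are still unused, yielding ``min(L, M)`` raw pairs.
    The filter then removes pairs whose centre offset exceeds
    ``max_center_offset`` px on either axis or whose disparity is below
    ``min_ydiff`` px.
    """
    if not upper_objs or not lower_objs:
        return []
    dists = [
        (math.hypot(u.xc - l.xc, u.yc - l.yc), i, j)
        for i, u in enumerate(upper_objs)
        for j, l in enumerate(lower_objs)
    ]
    dists.sort(key=lambda t: (t[0], t[1], t[2]))
    used_u: set[int] = set()
    used_l: set[int] = set()
    pairs = []
    for _, i, j in dists:
        if i in used_u or j in used_l:
            continue
        used_u.add(i)
        used_l.add(j)
        pairs.append(MatchedPair(upper=upper_objs[i], lower=lower_objs[j]))
    return [
        p
        for p in pairs
        if abs(p.xc_diff) <= max_center_offset
        and abs(p.upper.yc - p.lower.yc) <= max_center_offset
        and p.yc_diff >= min_ydiff
    ]


def approx_area(wingspan: float, body_height: float) -> float:
    """Isosceles-triangle area approximation: wingspan x height / 2."""
    return wingspan * body_height / 2.0


def estimate_size(
    pair: MatchedPair,
    rig: StereoRig,
    assembly: OpticalAssembly,
    per_axis_ratio: bool = False,
) -> SizeEstimate:
    """Physical size of a matched pair from its disparity.

    Pixel extents from the two cameras are averaged.  Wingspan and body
    height both use the horizontal sensor ratio VSSh / (f VSRh) (the
    sensor's pixels are nearly square); set ``per_axis_ratio`` to use the
    vertical ratio for the height instead.
    """
    ydiff = pair.yc_diff
    d_bc = baseline_distance(ydiff, rig)
    delta_dbc = d_bc / (2.0 * ydiff)
    p_w = (pair.upper.p_w + pair.lower.p_w) / 2.0
    p_h = (pair.upper.p_h + pair.lower.p_h) / 2.0
    o_s = (pair.upper.o_s + pair.lower.o_s) / 2.0
    sensor, f = assembly.sensor, assembly.lens.f
    ratio_w = sensor.vss_h / (f * sensor.vsr_h)  # [m object / (px * m range)]
    ratio_h = sensor.vss_v / (f * sensor.vsr_v) if per_axis_ratio else ratio_w
    wingspan = d_bc * p_w * ratio_w
    body_height = d_bc * p_h * ratio_h
    contour_area = (
        o_s * (d_bc / f) ** 2 * (sensor.vss_h / sensor.vsr_h) * (sensor.vss_v / sensor.vsr_v)
    )
    return SizeEstimate(
        wingspan=wingspan,
        wingspan_delta=delta_dbc * p_w * ratio_w,
        body_height=body_height,
        body_height_delta=delta_dbc * p_h * ratio_h,
        contour_area=contour_area,
        approx_area=approx_area(wingspan, body_height),
        distance_db=d_bc,
        distance_db_delta=delta_dbc,
    )


def classify_size(
    est: SizeEstimate, boundaries: SizeClassBoundaries | None = None
) -> str:
    """Vote a class per parameter (wingspan, height, contour area) and
    return the largest class any parameter indicates."""
    boundaries = boundaries or SizeClassBoundaries()
    votes = (
        boundaries.classify_value(est.wingspan, "wingspan"),
        boundaries.classify_value(est.body_height, "height"),
        boundaries.classify_value(est.contour_area, "area"),
    )
    return max(votes, key=_RANK.__getitem__)


def decide_action(
    size_class: str, distance_d: float, policy: ActionPolicy | None = None
) -> frozenset[str]:
    """Actions triggered for a bird of ``size_class`` at ``distance_d`` m."""
    policy = policy or ActionPolicy()
    actions = set()
    for name in ("strobe", "audio", "turbine_stop"):
        trigger = getattr(policy, name).get(size_class)
        if trigger is not None and distance_d <= trigger:
            actions.add(name)
    if "turbine_stop" in actions:
        actions.update({"strobe", "audio"})
    return frozenset(actions)


class EventArchive:
    """Append-only event log, mirrored as CSV and JSON-lines."""

    FIELDS = [
        "timestamp", "module_id", "size_class", "d", "h", "d_b", "delta_db",
        "wingspan", "body_height", "contour_area", "approx_area", "actions",
        "crop_path",
    ]

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self.csv_path = self.root / "events.csv"
        self.jsonl_path = self.root / "events.jsonl"

    def append(self, event: Event) -> None:
        row = event.to_row()
        new = not self.csv_path.exists()
        try:
            with open(self.csv_path, "a", newline="") as fh:
                writer = csv.DictWriter(fh, fieldnames=self.FIELDS)
                if new:
                    writer.writeheader()
                writer.writerow(row)
            with open(self.jsonl_path, "a") as fh:
                fh.write(json.dumps(row) + "\n")
        except OSError as exc:
            raise IOError(f"cannot write event archive under {self.root}") from exc

    def read(self) -> list[Event]:
        if not self.csv_path.exists():
            return []
        with open(self.csv_path, newline="") as fh:
            return [Event.from_row(row) for row in csv.DictReader(fh)]

    def __len__(self) -> int:
        return len(self.read())


def record_event(archive: EventArchive, event: Event) -> Event:
    archive.append(event)
    return event
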