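"""Run configuration and session records.

A :class:`SessionSpec` captures every choice the original interactive
workflow prompted for — which CMYK cluster to focus on, one outline
polygon per zone, optional exclusion polygons — so runs are scriptable
and reproducible.  A :class:`RunConfig` holds every tunable of the
pipeline.  Both serialize to YAML/JSON with round-trip identity and
hash to a provenance digest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .segmentation import DEFAULT_ZONE_REFS, ZONES

__all__ = ["RunConfig", "SessionSpec"]


def _canonical(obj):
    """JSON-serializable canonical form (tuples/arrays → lists)."""
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _canonical(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _digest(payload: dict) -> str:
    blob = json.dumps(_canonical(payload), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunConfig:
    """All pipeline tunables, with their documented defaults.

    seed drives every stochastic step (k-means initialization and the
    fitting subsample); two runs with equal config and inputs are
    bit-identical.
    """

    k_clusters: int = 8
    n_peaks: int = 8
    hue_bins: int = 64
    peak_min_separation: int = 2
    s_floor: float = 0.05
    norm_low_pct: float = 0.01
    norm_high_pct: float = 0.99
    bg_v_min: float = 0.92
    bg_s_max: float = 0.12
    adjacency_tol: float = math.sqrt(2)
    border_resample_step: int = 5
    ref_min_frac: float = 0.01
    kmeans_max_iter: int = 100
    color_weights: tuple = (2.0, 1.0, 1.0)
    mask_rule: str = "segmentation"  # or "outline"
    zone_refs: dict = field(
        default_factory=lambda: {z: tuple(DEFAULT_ZONE_REFS[z]) for z in ZONES})
    pixel_size: float = 1.0
    seed: int = 0
    output_dir: str = "."
    save_masks: bool = False

    def __post_init__(self) -> None:
        if self.k_clusters < 1 or self.n_peaks < 1 or self.hue_bins < 2:
            raise ValueError("k_clusters, n_peaks >= 1 and hue_bins >= 2")
        if not (0 <= self.norm_low_pct < self.norm_high_pct <= 1):
            raise ValueError("normalization percentiles out of order")
        for name in ("bg_v_min", "bg_s_max", "s_floor", "ref_min_frac"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mask_rule not in ("segmentation", "outline"):
            raise ValueError("mask_rule must be 'segmentation' or 'outline'")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["color_weights"] = list(self.color_weights)
        d["zone_refs"] = {z: list(v) for z, v in self.zone_refs.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "color_weights" in d:
            d["color_weights"] = tuple(d["color_weights"])
        if "zone_refs" in d:
            d["zone_refs"] = {z: tuple(v) for z, v in d["zone_refs"].items()}
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2)
                if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        data = (json.loads(path.read_text()) if path.suffix == ".json"
                else yaml.safe_load(path.read_text()))
        return cls.from_dict(data)

    def digest(self) -> str:
        return _digest(self.to_dict())


@dataclass
class SessionSpec:
    """Record of the formerly interactive choices for one section.

    ``cluster_index`` is an integer (the user's manual pick) or
    ``"auto"``; ``zone_outlines`` maps each zone name to a (V, 2)
    vertex list in pixel (x, y) coordinates; ``exclusions`` is a list
    of polygons to strip from the analysis; ``zone_refs`` optionally
    overrides the per-zone HSV stain colors.
    """

    image_id: str = ""
    cluster_index: int | str = "auto"
    zone_outlines: dict = field(default_factory=dict)
    exclusions: list = field(default_factory=list)
    zone_refs: dict | None = None

    def __post_init__(self) -> None:
        self.zone_outlines = {
            z: np.asarray(p, dtype=float) for z, p in self.zone_outlines.items()
        }
        self.exclusions = [np.asarray(p, dtype=float) for p in self.exclusions]
        if self.zone_refs is not None:
            self.zone_refs = {z: tuple(v) for z, v in self.zone_refs.items()}

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "cluster_index": self.cluster_index,
            "zone_outlines": {z: np.asarray(p).tolist()
                              for z, p in self.zone_outlines.items()},
            "exclusions": [np.asarray(p).tolist() for p in self.exclusions],
            "zone_refs": (None if self.zone_refs is None
                          else {z: list(v) for z, v in self.zone_refs.items()}),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionSpec":
        return cls(
            image_id=d.get("image_id", ""),
            cluster_index=d.get("cluster_index", "auto"),
            zone_outlines=d.get("zone_outlines", {}),
            exclusions=d.get("exclusions", []),
            zone_refs=d.get("zone_refs"),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2)
                if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "SessionSpec":
        path = Path(path)
        data = (json.loads(path.read_text()) if path.suffix == ".json"
                else yaml.safe_load(path.read_text()))
        return cls.from_dict(data)

    def digest(self) -> str:
        return _digest(self.to_dict())
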