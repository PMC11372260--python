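"""The four-stage interactive TMTV measurement protocol.

The benchmark measurement proceeds stepwise from the automated
preselection (SUV >= 4, volume >= 3 cm^3):

* **TMTV1** — single-click removal of physiologic uptake (brain, bladder,
  ...): a click deletes the whole connected component under it.
* **TMTV2** — additional single-click removal of reactive bone-marrow and
  spleen uptake, if required.
* **TMTV3** — manual mask editing to carve out physiologic uptake fused
  with tumor (e.g. a retroperitoneal node merged with kidney/ureter).
  Fragments left behind are kept regardless of size: the 3 cm^3 filter
  applies only at preselection, so re-filtering here would silently delete
  tumor the reader chose to keep.
* **TMTV4** — optional addition of missed lesions by seed click: the full
  connected SUV >= 4 region under the seed is added, with **no** volume
  threshold.

All reader judgement lives in a serializable :class:`Session` (JSON on
disk), which makes every measurement replayable bit-for-bit.  Click
coordinates are world millimetres by default (voxel indices with an
explicit flag); a click must land exactly inside a component — there is no
snapping, because silently grabbing a nearby structure would be worse than
an error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import segmentation as seg
from .errors import (
    GridMismatchError,
    NoComponentAtPointError,
    SeedBelowThresholdError,
    TMTVError,
)
from .pet_io import MaskVolume, PETVolume, read_mask, require_same_grid, write_volume

__all__ = [
    "Interaction",
    "Session",
    "WorkflowResult",
    "remove_component_at",
    "apply_edit_mask",
    "add_lesion_at",
    "run_workflow",
]

#: Stages at which each interaction kind is legal.
VALID_STAGES = {"remove_click": (1, 2), "edit_mask": (3,), "add_seed": (4,)}

STAGE_NAMES = {1: "TMTV1", 2: "TMTV2", 3: "TMTV3", 4: "TMTV4"}


@dataclass
class Interaction:
    """One reader action: a removal click, an edit mask, or an add seed."""

    kind: str
    stage: int
    point_mm: tuple[float, float, float] | None = None
    mask: MaskVolume | None = None
    mask_path: str | None = None
    point_is_index: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in VALID_STAGES:
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        if self.stage not in VALID_STAGES[self.kind]:
            raise ValueError(
                f"{self.kind} is only valid at stage(s) {VALID_STAGES[self.kind]}, "
                f"got stage {self.stage}"
            )
        if self.kind in ("remove_click", "add_seed") and self.point_mm is None:
            raise ValueError(f"{self.kind} requires a point")
        if self.kind == "edit_mask" and self.mask is None and self.mask_path is None:
            raise ValueError("edit_mask requires a mask or mask_path")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "stage": self.stage,
            "point_mm": list(self.point_mm) if self.point_mm is not None else None,
            "mask_path": self.mask_path,
            "point_is_index": self.point_is_index,
            "note": self.note,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Interaction":
        return cls(
            kind=d["kind"],
            stage=int(d["stage"]),
            point_mm=tuple(d["point_mm"]) if d.get("point_mm") is not None else None,
            mask_path=d.get("mask_path"),
            point_is_index=bool(d.get("point_is_index", False)),
            note=d.get("note", ""),
        )


@dataclass
class Session:
    """An ordered, staged list of reader interactions for one case.

    Interactions are applied stage by stage (1..4); within a stage, in list
    order.  Segmentation parameters travel with the session so the whole
    measurement is reproducible from the PET volume plus this file.
    """

    case_id: str = "case"
    reader_id: str = "reader"
    interactions: list[Interaction] = field(default_factory=list)
    suv_min: float = seg.DEFAULT_SUV_MIN
    min_volume_cm3: float = seg.DEFAULT_MIN_VOLUME_CM3
    connectivity: int = seg.DEFAULT_CONNECTIVITY

    def for_stage(self, stage: int) -> list[Interaction]:
        return [i for i in self.interactions if i.stage == stage]

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "reader_id": self.reader_id,
            "params": {
                "suv_min": self.suv_min,
                "min_volume_cm3": self.min_volume_cm3,
                "connectivity": self.connectivity,
            },
            "interactions": [i.to_dict() for i in self.interactions],
        }

    def save(self, path, mask_dir=None) -> Path:
        """Write the session as JSON; in-memory edit masks are materialized
        as NIfTI files under ``mask_dir`` (required if any exist)."""
        path = Path(path)
        out = []
        for n, inter in enumerate(self.interactions):
            if inter.kind == "edit_mask" and inter.mask is not None and inter.mask_path is None:
                if mask_dir is None:
                    raise ValueError(
                        "session holds in-memory edit masks; pass mask_dir to save them"
                    )
                mpath = Path(mask_dir) / f"edit_mask_{n:02d}.nii.gz"
                write_volume(inter.mask, mpath)
                inter = replace(inter, mask_path=str(mpath))
            out.append(inter)
        d = replace(self, interactions=out).to_dict()
        path.write_text(json.dumps(d, indent=2))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "Session":
        params = d.get("params", {})
        return cls(
            case_id=d.get("case_id", "case"),
            reader_id=d.get("reader_id", "reader"),
            interactions=[Interaction.from_dict(i) for i in d.get("interactions", [])],
            suv_min=float(params.get("suv_min", seg.DEFAULT_SUV_MIN)),
            min_volume_cm3=float(params.get("min_volume_cm3", seg.DEFAULT_MIN_VOLUME_CM3)),
            connectivity=int(params.get("connectivity", seg.DEFAULT_CONNECTIVITY)),
        )

    @classmethod
    def load(cls, path) -> "Session":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _resolve_index(cs: seg.ComponentSet, point_mm, point_is_index: bool):
    if point_is_index:
        idx = tuple(int(i) for i in point_mm)
        shape = cs.mask.grid.shape
        if any(i < 0 or i >= n for i, n in zip(idx, shape)):
            raise NoComponentAtPointError(f"index {idx} outside the grid")
        return idx
    return cs.mask.grid.world_to_index(point_mm)


def remove_component_at(
    cs: seg.ComponentSet, point_mm, point_is_index: bool = False
) -> seg.ComponentSet:
    """Delete the entire component containing the clicked voxel.

    Clicking background raises :class:`NoComponentAtPointError` and leaves
    the state unchanged.
    """
    idx = _resolve_index(cs, point_mm, point_is_index)
    label = int(cs.mask.labels[idx])
    if label == 0:
        raise NoComponentAtPointError(f"no component at {tuple(point_mm)}")
    labels = cs.mask.labels.copy()
    labels[labels == label] = 0
    comps = [c for c in cs.components if c.label != label]
    return replace(cs, components=comps, mask=MaskVolume(cs.mask.grid, labels))


def apply_edit_mask(cs: seg.ComponentSet, remove: MaskVolume) -> seg.ComponentSet:
    """Erase the voxels of ``remove`` from the segmentation and relabel.

    A component cut in two becomes two components; fragments below 3 cm^3
    survive (no re-filtering after manual edits).
    """
    require_same_grid(cs.mask, remove, "segmentation and edit mask")
    binary = cs.binary & (remove.labels == 0)
    return seg.components_from_binary(binary, cs.source, cs.threshold_suv, cs.connectivity)


def add_lesion_at(
    cs: seg.ComponentSet,
    pet: PETVolume,
    point_mm,
    point_is_index: bool = False,
) -> seg.ComponentSet:
    """Add the full connected SUV >= threshold region under a seed click.

    No minimum volume applies.  A region overlapping the existing
    segmentation merges with it (idempotent union), so re-seeding an
    included lesion is a no-op.
    """
    require_same_grid(cs.mask, pet, "segmentation and PET volume")
    idx = _resolve_index(cs, point_mm, point_is_index)
    suv = float(pet.values[idx])
    if suv < cs.threshold_suv:
        raise SeedBelowThresholdError(
            f"seed voxel SUV {suv:.2f} is below the threshold {cs.threshold_suv:.2f}"
        )
    structure = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[cs.connectivity])
    above, _ = ndimage.label(pet.values >= cs.threshold_suv, structure=structure)
    region = above == above[idx]
    return seg.components_from_binary(
        region | cs.binary, cs.source, cs.threshold_suv, cs.connectivity
    )


@dataclass
class WorkflowResult:
    """Stage-by-stage TMTVs plus the component sets behind them.

    Invariants guaranteed by the stage semantics: TMTV3 <= TMTV2 <= TMTV1
    (stages 2-3 only remove) and TMTV4 >= TMTV3 (stage 4 only adds).
    """

    tmtv_by_stage: dict[str, float]
    stage_sets: dict[int, seg.ComponentSet]
    log: list[dict]

    @property
    def final_tmtv(self) -> float:
        return self.tmtv_by_stage["TMTV4"]

    def mask(self, stage: int) -> MaskVolume:
        return self.stage_sets[stage].mask


def run_workflow(pet: PETVolume, session: Session, strict: bool = False) -> WorkflowResult:
    """Replay a session against a PET volume and record TMTV1..TMTV4.

    Failed interactions (background click, sub-threshold seed, mismatched
    edit grid) are logged and skipped in lenient mode (the default);
    ``strict=True`` re-raises the first failure.  Replaying the same session
    on the same volume is deterministic.
    """
    cs = seg.preselect(pet, session.suv_min, session.min_volume_cm3, session.connectivity)
    stage_sets = {0: cs}
    tmtv_by_stage: dict[str, float] = {}
    log: list[dict] = []
    for stage in (1, 2, 3, 4):
        for inter in session.for_stage(stage):
            entry = {"kind": inter.kind, "stage": stage, "note": inter.note, "ok": True,
                     "message": ""}
            try:
                if inter.kind == "remove_click":
                    cs = remove_component_at(cs, inter.point_mm, inter.point_is_index)
                elif inter.kind == "edit_mask":
                    mask = inter.mask if inter.mask is not None else read_mask(inter.mask_path)
                    cs = apply_edit_mask(cs, mask)
                elif inter.kind == "add_seed":
                    cs = add_lesion_at(cs, pet, inter.point_mm, inter.point_is_index)
            except TMTVError as exc:
                entry["ok"] = False
                entry["message"] = str(exc)
                if strict:
                    log.append(entry)
                    raise
            log.append(entry)
        stage_sets[stage] = cs
        tmtv_by_stage[STAGE_NAMES[stage]] = cs.tmtv
    return WorkflowResult(tmtv_by_stage, stage_sets, log)
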