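"""Synthetic lymphoma FDG-PET phantoms with exact voxel-level ground truth.

The generator emulates the uptake patterns a baseline lymphoma PET shows:
focal nodal / splenic / bone lesions over a low soft-tissue background,
physiologic high uptake (brain, bladder, myocardium, kidneys), reactive
bone marrow, diffuse splenic uptake above 1.5x liver, and lesions fused to
physiologic structures.  A liver organ is always present as reference
tissue so the spleen-to-liver ratio is well defined.

Geometry is analytic: each organ is a sphere, ellipsoid, box, or capsule
("tube"), painted in ``paint_order`` onto the voxel grid, a voxel belonging
to the highest-order organ whose shape contains the voxel *center* (no
antialiasing, so truth volumes are integer-voxel exact).  Truth masks are
recorded before any degradation.  Scanner physics is emulated afterwards as
a Gaussian point-spread blur plus additive Gaussian SUV noise, fully
determined by a seed.

The :func:`scenario` library ships ready-made cases — each a phantom spec,
a scripted reader session, and the expected stage TMTVs derived purely from
the rasterizer's per-organ voxel counts — so the whole measurement pipeline
is testable without any external image download.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ScenarioNotFoundError
from .pet_io import MaskVolume, PETVolume, VoxelGrid
from .workflow import Interaction, Session

log = logging.getLogger("tmtvbench")

__all__ = [
    "OrganSpec",
    "PhantomSpec",
    "OrganTruth",
    "PhantomTruth",
    "ScenarioCase",
    "rasterize",
    "degrade",
    "generate",
    "scenario",
    "list_scenarios",
    "DEFAULT_GRID",
]

#: Default phantom grid: 128 x 128 x 160 voxels at 4 mm isotropic
#: (512 x 512 x 640 mm field of view), large enough for whole-body-like
#: organ layouts while keeping second-scale rasterization.
DEFAULT_GRID = VoxelGrid((128, 128, 160), (4.0, 4.0, 4.0))

_ROLES = ("lesion", "physiologic", "reference_tissue", "background")
_SHAPES = ("sphere", "ellipsoid", "box", "tube")


@dataclass(frozen=True)
class OrganSpec:
    """One analytic organ/lesion.

    ``radii_mm`` is the sphere radius (scalar), ellipsoid semi-axes or box
    half-widths (triple); tubes are capsules given by two endpoints and a
    radius.  ``paint_order`` resolves overlaps: the higher value wins.
    """

    name: str
    role: str
    shape: str
    suv: float
    center_mm: tuple[float, float, float] | None = None
    radii_mm: float | tuple[float, float, float] | None = None
    end0_mm: tuple[float, float, float] | None = None
    end1_mm: tuple[float, float, float] | None = None
    radius_mm: float | None = None
    paint_order: int = 1

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.suv < 0:
            raise ValueError("organ SUV must be >= 0")
        if self.shape == "tube":
            if self.end0_mm is None or self.end1_mm is None or self.radius_mm is None:
                raise ValueError("tube requires end0_mm, end1_mm and radius_mm")
            if self.radius_mm <= 0:
                raise ValueError("tube radius must be positive")
        else:
            if self.center_mm is None or self.radii_mm is None:
                raise ValueError(f"{self.shape} requires center_mm and radii_mm")
            r = np.atleast_1d(np.asarray(self.radii_mm, dtype=float))
            if np.any(r <= 0):
                raise ValueError("radii must be positive")

    def _triple_radii(self) -> np.ndarray:
        r = np.atleast_1d(np.asarray(self.radii_mm, dtype=float))
        return np.repeat(r, 3) if r.size == 1 else r

    def bounds_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box (lo, hi) of the analytic shape."""
        if self.shape == "tube":
            p0, p1 = np.asarray(self.end0_mm), np.asarray(self.end1_mm)
            return np.minimum(p0, p1) - self.radius_mm, np.maximum(p0, p1) + self.radius_mm
        c = np.asarray(self.center_mm, dtype=float)
        r = self._triple_radii()
        return c - r, c + r

    def contains(self, x, y, z) -> np.ndarray:
        """Boolean containment of (broadcastable) world coordinates."""
        if self.shape == "tube":
            p0 = np.asarray(self.end0_mm, dtype=float)
            d = np.asarray(self.end1_mm, dtype=float) - p0
            dd = float(d @ d)
            if dd == 0.0:
                t = 0.0
            else:
                t = np.clip(((x - p0[0]) * d[0] + (y - p0[1]) * d[1] + (z - p0[2]) * d[2]) / dd,
                            0.0, 1.0)
            qx, qy, qz = p0[0] + t * d[0], p0[1] + t * d[1], p0[2] + t * d[2]
            return (x - qx) ** 2 + (y - qy) ** 2 + (z - qz) ** 2 <= self.radius_mm**2
        c = np.asarray(self.center_mm, dtype=float)
        r = self._triple_radii()
        dx, dy, dz = x - c[0], y - c[1], z - c[2]
        if self.shape == "sphere":
            rad = float(r[0])
            return dx**2 + dy**2 + dz**2 <= rad**2
        if self.shape == "ellipsoid":
            return (dx / r[0]) ** 2 + (dy / r[1]) ** 2 + (dz / r[2]) ** 2 <= 1.0
        # box: half-widths
        return (np.abs(dx) <= r[0]) & (np.abs(dy) <= r[1]) & (np.abs(dz) <= r[2])


@dataclass(frozen=True)
class PhantomSpec:
    grid: VoxelGrid = DEFAULT_GRID
    background_suv: float = 1.0
    organs: tuple[OrganSpec, ...] = ()
    psf_fwhm_mm: float = 0.0
    noise_sd_suv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "organs", tuple(self.organs))
        if self.psf_fwhm_mm < 0 or self.noise_sd_suv < 0:
            raise ValueError("psf_fwhm_mm and noise_sd_suv must be >= 0")


@dataclass(frozen=True)
class OrganTruth:
    name: str
    role: str
    suv: float
    label: int
    voxel_count: int
    volume_cm3: float


@dataclass
class PhantomTruth:
    """Exact per-organ voxel bookkeeping of a rasterized phantom."""

    organs: dict[str, OrganTruth]
    voxel_volume_cm3: float
    liver_mean_suv: float | None = None
    spleen_liver_ratio: float | None = None
    expected_stage_tmtv: dict[str, float] | None = None

    def volume(self, name: str) -> float:
        return self.organs[name].volume_cm3

    def thresholded_volume(self, name: str, suv_min: float = 4.0) -> float:
        """Volume of an organ's voxels at or above a threshold (uniform
        uptake: all of it or none of it)."""
        o = self.organs[name]
        return o.volume_cm3 if o.suv >= suv_min else 0.0


def _world_axes(grid: VoxelGrid):
    ox, oy, oz = grid.origin_mm
    sx, sy, sz = grid.spacing_mm
    nx, ny, nz = grid.shape
    x = (ox + sx * np.arange(nx))[:, None, None]
    y = (oy + sy * np.arange(ny))[None, :, None]
    z = (oz + sz * np.arange(nz))[None, None, :]
    return x, y, z


def rasterize(spec: PhantomSpec) -> tuple[PETVolume, PhantomTruth, MaskVolume]:
    """Paint the phantom onto its grid and record exact ground truth.

    Returns the noise-free PET volume, the truth bookkeeping, and a truth
    label mask whose label for each voxel is the (1-based) index of the
    winning organ in ``spec.organs`` (0 = background).  Organs reaching
    outside the grid are clipped with a warning.
    """
    grid = spec.grid
    x, y, z = _world_axes(grid)
    values = np.full(grid.shape, float(spec.background_suv), dtype=np.float32)
    winner = np.zeros(grid.shape, dtype=np.uint16)

    order = sorted(range(len(spec.organs)), key=lambda i: (spec.organs[i].paint_order, i))
    masks: dict[int, np.ndarray] = {}
    by_paint: dict[int, list[int]] = {}
    lo_grid = np.asarray(grid.origin_mm)
    hi_grid = lo_grid + (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing_mm)
    for i in order:
        organ = spec.organs[i]
        lo, hi = organ.bounds_mm()
        if np.any(lo < lo_grid) or np.any(hi > hi_grid):
            log.warning("organ %r extends outside the grid and is clipped", organ.name)
        m = organ.contains(x, y, z)
        masks[i] = m
        by_paint.setdefault(organ.paint_order, []).append(i)
        values[m] = organ.suv
        winner[m] = i + 1
    # painter's rule must be deterministic: equal paint_order + overlap is a
    # spec error, not a silent ordering accident
    for paint, idxs in by_paint.items():
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                if np.any(masks[idxs[a]] & masks[idxs[b]]):
                    raise ValueError(
                        f"organs {spec.organs[idxs[a]].name!r} and "
                        f"{spec.organs[idxs[b]].name!r} overlap with equal paint_order {paint}"
                    )

    vv = grid.voxel_volume_cm3
    organs: dict[str, OrganTruth] = {}
    for i, organ in enumerate(spec.organs):
        cnt = int(np.count_nonzero(winner == i + 1))
        organs[organ.name] = OrganTruth(organ.name, organ.role, organ.suv, i + 1, cnt, cnt * vv)

    liver = next((o for o in spec.organs if o.name == "liver"), None)
    spleen = next((o for o in spec.organs if o.name == "spleen"), None)
    truth = PhantomTruth(
        organs=organs,
        voxel_volume_cm3=vv,
        liver_mean_suv=liver.suv if liver else None,
        spleen_liver_ratio=(spleen.suv / liver.suv) if (liver and spleen) else None,
    )
    pet = PETVolume(grid, values, meta={"phantom": True})
    return pet, truth, MaskVolume(grid, winner)


def degrade(
    pet: PETVolume, psf_fwhm_mm: float = 0.0, noise_sd_suv: float = 0.0, seed: int = 0
) -> PETVolume:
    """Apply scanner-like degradation: Gaussian PSF blur then Gaussian noise.

    Blur uses sigma = FWHM / 2.355 per axis (converted to voxels by the
    spacing); noise is additive in SUV space and clamped at zero.  The
    result is fully determined by ``seed``.
    """
    if psf_fwhm_mm < 0 or noise_sd_suv < 0:
        raise ValueError("psf_fwhm_mm and noise_sd_suv must be >= 0")
    values = pet.values.astype(np.float32)
    if psf_fwhm_mm > 0:
        sigma_vox = [psf_fwhm_mm / 2.355 / s for s in pet.grid.spacing_mm]
        values = ndimage.gaussian_filter(values, sigma=sigma_vox)
    if noise_sd_suv > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd_suv, size=values.shape)
    return PETVolume(pet.grid, np.maximum(values, 0.0), meta=dict(pet.meta))


def generate(spec: PhantomSpec) -> tuple[PETVolume, PhantomTruth, MaskVolume]:
    """Rasterize then degrade with the spec's own PSF/noise/seed settings."""
    pet, truth, truth_mask = rasterize(spec)
    return degrade(pet, spec.psf_fwhm_mm, spec.noise_sd_suv, spec.seed), truth, truth_mask


# ---------------------------------------------------------------------------
# Scenario library
# ---------------------------------------------------------------------------

@dataclass
class ScenarioCase:
    """A ready-made benchmark-style case with scripted reader session.

    ``expected_tmtv`` maps TMTV1..TMTV4 to the clean-mode (no PSF, no
    noise) values implied by the rasterizer's per-organ voxel counts; the
    workflow must reproduce them exactly in clean mode.
    """

    name: str
    description: str
    spec: PhantomSpec
    session: Session
    expected_tmtv: dict[str, float]
    truth: PhantomTruth
    truth_mask: MaskVolume


# Shared organ geometry (world mm on the default 512 x 512 x 640 mm grid).
# Layout leaves >= 2-voxel gaps between any two organs except the two
# deliberate fusions (kidney_r + node_renal, myocardium + lesion_mediastinum).
def _organ(name, **kw) -> OrganSpec:
    catalog = {
        "liver": dict(role="reference_tissue", shape="ellipsoid",
                      center_mm=(150, 250, 320), radii_mm=(70, 50, 60), paint_order=1),
        "brain": dict(role="physiologic", shape="ellipsoid", suv=10.0,
                      center_mm=(254, 254, 580), radii_mm=(55, 65, 50), paint_order=2),
        "bladder": dict(role="physiologic", shape="sphere", suv=12.0,
                        center_mm=(254, 254, 60), radii_mm=25, paint_order=2),
        "spleen": dict(role="physiologic", shape="ellipsoid",
                       center_mm=(380, 240, 330), radii_mm=(40, 28, 55), paint_order=2),
        "marrow": dict(role="physiologic", shape="tube",
                       end0_mm=(254, 330, 110), end1_mm=(254, 330, 500),
                       radius_mm=10, paint_order=2),
        "myocardium": dict(role="physiologic", shape="ellipsoid", suv=6.0,
                           center_mm=(330, 270, 440), radii_mm=(40, 35, 40), paint_order=2),
        "kidney_l": dict(role="physiologic", shape="sphere", suv=8.0,
                         center_mm=(170, 330, 200), radii_mm=25, paint_order=2),
        "kidney_r": dict(role="physiologic", shape="sphere", suv=8.0,
                         center_mm=(340, 330, 200), radii_mm=25, paint_order=2),
        "node_renal": dict(role="lesion", shape="sphere", suv=8.0,
                           center_mm=(340, 330, 236), radii_mm=16, paint_order=5),
        "lesion_mediastinum": dict(role="lesion", shape="sphere", suv=8.0,
                                   center_mm=(330, 270, 485), radii_mm=18, paint_order=5),
        "neck_l": dict(role="lesion", shape="sphere", suv=7.0,
                       center_mm=(230, 150, 500), radii_mm=12, paint_order=3),
        "neck_r": dict(role="lesion", shape="sphere", suv=9.0,
                       center_mm=(300, 150, 500), radii_mm=10, paint_order=3),
        "ax_l": dict(role="lesion", shape="sphere", suv=6.0,
                     center_mm=(100, 200, 460), radii_mm=14, paint_order=3),
        "ax_r": dict(role="lesion", shape="sphere", suv=12.0,
                     center_mm=(408, 200, 460), radii_mm=14, paint_order=3),
        "abdominal": dict(role="lesion", shape="sphere", suv=10.0,
                          center_mm=(254, 150, 280), radii_mm=15, paint_order=3),
        "groin_l": dict(role="lesion", shape="sphere", suv=8.0,
                        center_mm=(200, 254, 120), radii_mm=7.8, paint_order=3),
        "pelvic_r": dict(role="lesion", shape="sphere", suv=8.0,
                         center_mm=(310, 254, 120), radii_mm=8.0, paint_order=3),
        "bulky_mass": dict(role="lesion", shape="ellipsoid", suv=9.0,
                           center_mm=(254, 160, 330), radii_mm=(70, 60, 90), paint_order=3),
    }
    d = dict(catalog[name])
    d.update(kw)
    return OrganSpec(name=name, **d)


def _organ_center(spec: PhantomSpec, name: str) -> tuple[float, float, float]:
    for o in spec.organs:
        if o.name == name:
            if o.shape == "tube":
                return tuple((np.asarray(o.end0_mm) + np.asarray(o.end1_mm)) / 2.0)
            return tuple(float(v) for v in o.center_mm)
    raise KeyError(name)


def organ_truth_mask(truth: PhantomTruth, truth_mask: MaskVolume, name: str) -> MaskVolume:
    """Binary mask of the voxels an organ actually owns (painter's rule)."""
    label = truth.organs[name].label
    return MaskVolume(truth_mask.grid, (truth_mask.labels == label).astype(np.uint16))


def _assemble(
    name: str,
    description: str,
    organs: list[OrganSpec],
    clicks: list[tuple[int, str]],
    edits: list[str],
    adds: list[str],
    stage_groups: dict[int, list[list[str]]],
    seed: int,
) -> ScenarioCase:
    """Build a ScenarioCase: phantom spec + scripted session + truth-derived
    expected stage TMTVs.

    ``stage_groups[k]`` lists, for stage k, the connected units still in the
    segmentation as lists of organ names; the expected TMTV_k is the plain
    sum of their painter-rule voxel volumes — bookkeeping on the rasterizer
    truth, independent of the segmentation pipeline.
    """
    spec = PhantomSpec(organs=tuple(organs), seed=seed)
    _, truth, truth_mask = rasterize(spec)
    interactions: list[Interaction] = []
    for stage, organ in clicks:
        interactions.append(
            Interaction("remove_click", stage, point_mm=_organ_center(spec, organ),
                        note=f"remove {organ}")
        )
    for organ in edits:
        interactions.append(
            Interaction("edit_mask", 3, mask=organ_truth_mask(truth, truth_mask, organ),
                        note=f"edit out {organ}")
        )
    for organ in adds:
        interactions.append(
            Interaction("add_seed", 4, point_mm=_organ_center(spec, organ),
                        note=f"add {organ}")
        )
    expected = {
        f"TMTV{k}": float(sum(sum(truth.volume(n) for n in grp) for grp in stage_groups[k]))
        for k in (1, 2, 3, 4)
    }
    session = Session(case_id=name, reader_id="script", interactions=interactions)
    truth.expected_stage_tmtv = expected
    return ScenarioCase(name, description, spec, session, expected, truth, truth_mask)


def _sc_multifocal_nodal(seed: int) -> ScenarioCase:
    lesions = ["neck_l", "neck_r", "ax_l", "ax_r", "abdominal", "lesion_mediastinum"]
    groups = [[n] for n in lesions]
    return _assemble(
        "multifocal_nodal",
        "Multifocal nodal disease (neck, axillae, mediastinum, abdomen); "
        "brain and bladder removed with single clicks at stage 1.",
        [_organ("liver", suv=2.5), _organ("brain"), _organ("bladder")]
        + [_organ(n) for n in lesions],
        clicks=[(1, "brain"), (1, "bladder")],
        edits=[], adds=[],
        stage_groups={1: groups, 2: groups, 3: groups, 4: groups},
        seed=seed,
    )


def _sc_physiologic_only(seed: int) -> ScenarioCase:
    groups = [["neck_l"]]
    return _assemble(
        "physiologic_only",
        "A single small cervical lesion; only brain and bladder physiologic "
        "uptake to remove. Small-TMTV end of the suite (~8 cm^3).",
        [_organ("liver", suv=2.5), _organ("brain"), _organ("bladder"),
         _organ("neck_l", radii_mm=12.4, suv=6.0)],
        clicks=[(1, "brain"), (1, "bladder")],
        edits=[], adds=[],
        stage_groups={1: groups, 2: groups, 3: groups, 4: groups},
        seed=seed,
    )


def _sc_reactive_spleen_marrow(seed: int) -> ScenarioCase:
    lesions = [["neck_l"], ["ax_l"], ["abdominal"]]
    return _assemble(
        "reactive_spleen_marrow",
        "Reactive diffuse spleen (SUV 4.6) and bone-marrow (SUV 4.5) uptake "
        "removed with single clicks at stage 2.",
        [_organ("liver", suv=2.5), _organ("brain"), _organ("bladder"),
         _organ("spleen", suv=4.6), _organ("marrow", suv=4.5),
         _organ("neck_l"), _organ("ax_l"), _organ("abdominal")],
        clicks=[(1, "brain"), (1, "bladder"), (2, "spleen"), (2, "marrow")],
        edits=[], adds=[],
        stage_groups={1: lesions + [["spleen"], ["marrow"]],
                      2: lesions, 3: lesions, 4: lesions},
        seed=seed,
    )


def _sc_diffuse_spleen_no_marrow(seed: int) -> ScenarioCase:
    groups = [["neck_l"], ["ax_r"], ["abdominal"], ["spleen"]]
    return _assemble(
        "diffuse_spleen_no_marrow",
        "Diffuse splenic uptake at 1.6x liver without matching marrow "
        "changes: counted as disease, so the spleen stays in the TMTV.",
        [_organ("liver", suv=3.0), _organ("brain"), _organ("bladder"),
         _organ("spleen", suv=4.8, role="lesion"),
         _organ("neck_l"), _organ("ax_r"), _organ("abdominal")],
        clicks=[(1, "brain"), (1, "bladder")],
        edits=[], adds=[],
        stage_groups={1: groups, 2: groups, 3: groups, 4: groups},
        seed=seed,
    )


def _sc_diffuse_spleen_with_marrow(seed: int) -> ScenarioCase:
    lesions = [["neck_l"], ["ax_r"], ["abdominal"]]
    return _assemble(
        "diffuse_spleen_with_marrow",
        "Diffuse splenic uptake at 1.6x liver together with reactive marrow: "
        "interpreted as reactive and click-removed at stage 2.",
        [_organ("liver", suv=3.0), _organ("brain"), _organ("bladder"),
         _organ("spleen", suv=4.8), _organ("marrow", suv=4.4),
         _organ("neck_l"), _organ("ax_r"), _organ("abdominal")],
        clicks=[(1, "brain"), (1, "bladder"), (2, "spleen"), (2, "marrow")],
        edits=[], adds=[],
        stage_groups={1: lesions + [["spleen"], ["marrow"]],
                      2: lesions, 3: lesions, 4: lesions},
        seed=seed,
    )


def _sc_kidney_node_fusion(seed: int) -> ScenarioCase:
    free = [["neck_l"], ["abdominal"]]
    return _assemble(
        "kidney_node_fusion",
        "A retroperitoneal node fused with the right kidney into a single "
        "component: the isolated left kidney is click-removed, the fused "
        "kidney part is carved out with a stage-3 edit mask.",
        [_organ("liver", suv=2.5), _organ("brain"), _organ("bladder"),
         _organ("kidney_l"), _organ("kidney_r"), _organ("node_renal"),
         _organ("neck_l"), _organ("abdominal")],
        clicks=[(1, "brain"), (1, "bladder"), (1, "kidney_l")],
        edits=["kidney_r"], adds=[],
        stage_groups={1: free + [["kidney_r", "node_renal"]],
                      2: free + [["kidney_r", "node_renal"]],
                      3: free + [["node_renal"]],
                      4: free + [["node_renal"]]},
        seed=seed,
    )


def _sc_myocardium_edit(seed: int) -> ScenarioCase:
    free = [["ax_l"], ["ax_r"]]
    return _assemble(
        "myocardium_edit",
        "Intense myocardium fused with a mediastinal lesion; a stage-3 edit "
        "mask removes the myocardial part, the lesion fragment is kept.",
        [_organ("liver", suv=2.5), _organ("brain"), _organ("bladder"),
         _organ("myocardium"), _organ("lesion_mediastinum"),
         _organ("ax_l"), _organ("ax_r")],
        clicks=[(1, "brain"), (1, "bladder")],
        edits=["myocardium"], adds=[],
        stage_groups={1: free + [["myocardium", "lesion_mediastinum"]],
                      2: free + [["myocardium", "lesion_mediastinum"]],
                      3: free + [["lesion_mediastinum"]],
                      4: free + [["lesion_mediastinum"]]},
        seed=seed,
    )


def _sc_small_lesion_addition(seed: int) -> ScenarioCase:
    return _assemble(
        "small_lesion_addition",
        "Two sub-3 cm^3 pelvic/groin lesions excluded by the preselection "
        "volume filter and added back with stage-4 seed clicks.",
        [_organ("liver", suv=2.5), _organ("brain"), _organ("bladder"),
         _organ("abdominal"), _organ("groin_l"), _organ("pelvic_r")],
        clicks=[(1, "brain"), (1, "bladder")],
        edits=[], adds=["groin_l", "pelvic_r"],
        stage_groups={1: [["abdominal"]], 2: [["abdominal"]], 3: [["abdominal"]],
                      4: [["abdominal"], ["groin_l"], ["pelvic_r"]]},
        seed=seed,
    )


def _sc_bulky_disease(seed: int) -> ScenarioCase:
    groups = [["bulky_mass"], ["spleen"], ["ax_l"], ["ax_r"], ["neck_l"]]
    return _assemble(
        "bulky_disease",
        "Bulky abdominal conglomerate (~1,600 cm^3) with diffuse splenic "
        "involvement retained: the bulky end of the suite.",
        [_organ("liver", suv=3.0), _organ("brain"), _organ("bladder"),
         _organ("spleen", suv=4.8, role="lesion"), _organ("bulky_mass"),
         _organ("ax_l"), _organ("ax_r"), _organ("neck_l")],
        clicks=[(1, "brain"), (1, "bladder")],
        edits=[], adds=[],
        stage_groups={1: groups, 2: groups, 3: groups, 4: groups},
        seed=seed,
    )


def _sc_bone_lesions(seed: int) -> ScenarioCase:
    # focal bone lesions sit on the marrow tube axis but the marrow itself is
    # quiescent (below threshold), emulating focal skeletal disease
    organs = [
        _organ("liver", suv=2.5), _organ("brain"), _organ("bladder"),
        _organ("marrow", suv=2.0),
        OrganSpec("bone_focal_1", "lesion", "sphere", 9.0,
                  center_mm=(254, 330, 180), radii_mm=13, paint_order=4),
        OrganSpec("bone_focal_2", "lesion", "sphere", 7.0,
                  center_mm=(254, 330, 420), radii_mm=11, paint_order=4),
        _organ("neck_r"),
    ]
    groups = [["bone_focal_1"], ["bone_focal_2"], ["neck_r"]]
    return _assemble(
        "focal_bone_disease",
        "Focal skeletal lesions on a quiescent marrow background plus one "
        "nodal lesion; clicks remove brain and bladder only.",
        organs,
        clicks=[(1, "brain"), (1, "bladder")],
        edits=[], adds=[],
        stage_groups={1: groups, 2: groups, 3: groups, 4: groups},
        seed=seed,
    )


_SCENARIOS = {
    "multifocal_nodal": _sc_multifocal_nodal,
    "physiologic_only": _sc_physiologic_only,
    "reactive_spleen_marrow": _sc_reactive_spleen_marrow,
    "diffuse_spleen_no_marrow": _sc_diffuse_spleen_no_marrow,
    "diffuse_spleen_with_marrow": _sc_diffuse_spleen_with_marrow,
    "kidney_node_fusion": _sc_kidney_node_fusion,
    "myocardium_edit": _sc_myocardium_edit,
    "small_lesion_addition": _sc_small_lesion_addition,
    "bulky_disease": _sc_bulky_disease,
    "focal_bone_disease": _sc_bone_lesions,
}


def list_scenarios() -> tuple[str, ...]:
    return tuple(_SCENARIOS)


def scenario(name: str, seed: int = 0) -> ScenarioCase:
    """Build a shipped scenario: phantom spec, scripted session, and the
    expected clean-mode stage TMTVs.  ``seed`` feeds any later degradation
    (the clean layout itself is deterministic)."""
    try:
        builder = _SCENARIOS[name]
    except KeyError:
        raise ScenarioNotFoundError(
            f"unknown scenario {name!r}; available: {', '.join(_SCENARIOS)}"
        ) from None
    return builder(int(seed))
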