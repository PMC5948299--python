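"""Synthetic inputs for the whole pipeline.

Real micro-CT scans of cadaver femora and instrumented-prosthesis force
recordings are not shipped with this package. This module generates
desk-scale stand-ins for every input the pipeline needs:

* trabecular-like structures *adapted to a known load history* by a
  forward strain-energy-driven remodelling rule, on a quarter-dome "mini
  joint" (hemispherical articular cap on a support block) so that the
  sphere fit, cone load patches and lateral/distal fixation machinery are
  exercised end to end;
* grayscale renderings of binary structures (two grey levels, Gaussian
  blur, additive noise) for segmentation-threshold studies;
* smooth hip-load time series per subject and activity in the implant
  coordinate frame, with configurable peaks and inclinations;
* the published per-specimen load-scaling/CoV table as a versioned text
  fixture.

The forward remodelling rule is an intermediate-density model: element
modulus E = E0 * rho^p (p = 3 by default), stimulus S = U / rho with U the
cycle-weighted strain energy density of the generating load mix, and the
density update rho <- clip(rho + step * (S - S*) / S*, floor, 1). After
convergence the structure is binarised at rho >= 0.5. Adaptation runs on
an element lattice at twice the voxel pitch and the result is rendered at
the full voxel grid, mirroring the scan-then-resample flow of the inverse
pipeline.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import VoxelImage
from .image_pipeline import AnatomicalFrame, align_crop_cartilage
from .unit_loads import LoadPatchSpec, build_load_case, direction_vector
from .voxel_fe import LABEL_BONE, SolverSettings, build_model, solve_load_case

__all__ = [
    "RemodellingParams",
    "RemodellingConvergenceError",
    "SyntheticSpecimen",
    "Table2Fixture",
    "ActivitySpec",
    "generate_adapted_structure",
    "remodelling_update",
    "synthesize_grayscale",
    "generate_load_traces",
    "default_activity_specs",
    "table2_fixture",
    "synthetic_proximal_femur",
]


class RemodellingConvergenceError(RuntimeError):
    """Forward remodelling failed to reach a converged density field."""


@dataclass
class RemodellingParams:
    """Controls of the forward density-adaptation rule.

    base_modulus is the fully dense bone modulus in MPa; target_stimulus
    (MPa) is the strain-energy-density-per-density level the adaptation
    drives towards, matching the equilibrium stimulus of the inverse
    problem. density_floor keeps resorbed elements weakly elastic so the
    FE operator stays well conditioned.
    """

    base_modulus: float = 10_000.0
    density_exponent: float = 3.0
    density_floor: float = 0.25
    step_size: float = 0.2
    target_stimulus: float = 0.02
    max_iterations: int = 80
    convergence_tol: float = 1.5e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.density_floor < 1:
            raise ValueError("density_floor must be in (0, 1)")
        if not self.step_size > 0:
            raise ValueError("step_size must be > 0")
        if not self.target_stimulus > 0:
            raise ValueError("target_stimulus must be > 0")


@dataclass
class SyntheticSpecimen:
    """A remodelling-adapted binary structure with known load history."""

    binary_structure: VoxelImage  # 0/1 voxel grid
    frame: AnatomicalFrame
    true_load_mix: tuple[tuple[float, float], ...]  # (inclination deg, magnitude N)
    params: RemodellingParams
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.binary_structure.values.any():
            raise ValueError("specimen has no foreground voxels")
        if any(m < 0 for _, m in self.true_load_mix):
            raise ValueError("true load mix magnitudes must be >= 0")


def remodelling_update(rho: np.ndarray, stimulus: np.ndarray, params: RemodellingParams) -> np.ndarray:
    """One density-adaptation step; the fixed point is stimulus == target."""
    step = params.step_size * (stimulus - params.target_stimulus) / params.target_stimulus
    return np.clip(rho + step, params.density_floor, 1.0)


def generate_adapted_structure(
    domain_shape: tuple[int, int, int] = (48, 48, 48),
    voxel_size: float = 0.5,
    load_mix: Sequence[tuple[float, float]] = ((20.0, 1000.0),),
    params: RemodellingParams | None = None,
    cartilage_thickness: float = 2.2,
    crop_factor: float = 1.5,
    solver: SolverSettings | None = None,
) -> SyntheticSpecimen:
    """Forward-remodel a mini-joint structure adapted to ``load_mix``.

    The candidate bone domain is a hemispherical cap (head radius a quarter
    of the domain edge) on a full-width support block; density adapts under
    the cycle-weighted stimulus of the load mix until the mean density
    change per step drops below ``convergence_tol``. Deterministic for a
    fixed ``params.seed``.
    """
    params = params or RemodellingParams()
    solver = solver or SolverSettings(tolerance=1e-5)
    mix = tuple((float(a), float(m)) for a, m in load_mix)
    if not mix or all(m == 0 for _, m in mix):
        raise ValueError("load mix needs at least one positive magnitude")
    if any(m < 0 for _, m in mix):
        raise ValueError("load mix magnitudes must be >= 0")
    shape = tuple(int(s) for s in domain_shape)
    if any(s % 2 or s < 8 for s in shape):
        raise ValueError("domain_shape must be even and >= 8 voxels per axis")
    if max(shape) > 64:
        raise ValueError("domain exceeds desk scale (<= 64^3 voxels)")

    h = float(voxel_size)
    he = 2 * h  # remodelling element pitch
    L = np.array(shape) * h
    radius = 0.25 * float(min(L))
    centre = np.array([0.45 * L[0], 0.5 * L[1], 0.45 * L[2]])
    block_top = centre[2]

    # candidate domain on the element lattice
    ne = tuple(s // 2 for s in shape)
    origin_e = np.full(3, h / 2)  # centre of element (0,0,0)
    egrid = np.stack(
        np.meshgrid(*[origin_e[a] + he * np.arange(ne[a]) for a in range(3)], indexing="ij"),
        axis=-1,
    )
    dist = np.linalg.norm(egrid - centre, axis=-1)
    dome = (dist <= radius) & (egrid[..., 2] >= block_top)
    r_axis = np.linalg.norm(egrid[..., :2] - centre[:2], axis=-1)
    pedestal = (r_axis <= radius) & (egrid[..., 2] < block_top)
    candidate = dome | pedestal

    frame = AnatomicalFrame(
        head_centre=centre,
        head_radius=radius,
        neck_midpoint=centre - np.array([0.0, 0.0, radius]),
        axes=np.eye(3),
    )
    cand_img = VoxelImage(candidate.astype(np.uint8), he, origin_e)
    seg = align_crop_cartilage(
        cand_img, frame, crop_factor=crop_factor, cartilage_thickness=cartilage_thickness
    )
    fe = build_model(seg, bone_modulus=params.base_modulus, poisson=0.3)
    bone = fe.labels == LABEL_BONE
    n_bone = int(bone.sum())
    if n_bone == 0:
        raise ValueError("empty candidate structure")

    cases = []
    weights = []
    active = [(a, m) for a, m in mix if m > 0]
    for i, (angle, mag) in enumerate(active):
        spec = LoadPatchSpec(angle)
        cases.append(build_load_case(seg, spec, resultant_magnitude=1000.0, case_id=i))
        weights.append((mag / 1000.0) ** 2 / len(active))

    rng = np.random.default_rng(params.seed)
    rho = np.clip(0.5 + 0.05 * rng.standard_normal(n_bone), params.density_floor, 1.0)
    warm = [None] * len(cases)
    converged = False
    history = []
    for it in range(params.max_iterations):
        fe.moduli[bone] = params.base_modulus * rho**params.density_exponent
        U = np.zeros(n_bone)
        for i, lc in enumerate(cases):
            f = solve_load_case(fe, lc, solver, x0=warm[i])
            warm[i] = f.u_free
            U += weights[i] * f.sed[bone]
        stimulus = U / rho
        new_rho = remodelling_update(rho, stimulus, params)
        change = float(np.mean(np.abs(new_rho - rho)))
        history.append(change)
        rho = new_rho
        if change < params.convergence_tol:
            converged = True
            break
    if not converged:
        raise RemodellingConvergenceError(
            f"remodelling did not converge in {params.max_iterations} iterations "
            f"(last mean density changes: {[f'{c:.2e}' for c in history[-5:]]})"
        )

    # binarise and paint back onto the full-domain element lattice
    bone_solid = rho >= 0.5
    if not bone_solid.any():
        raise ValueError("adapted structure is empty after binarisation")
    eidx = fe.element_indices[bone]
    world = frame.head_centre + seg.labels.origin + seg.voxel_size * eidx
    m_idx = np.rint((world - origin_e) / he).astype(int)
    full_e = np.zeros(ne, dtype=bool)
    ok = np.all((m_idx >= 0) & (m_idx < np.array(ne)), axis=1)
    full_e[tuple(m_idx[bone_solid & ok].T)] = True

    binary = np.repeat(np.repeat(np.repeat(full_e, 2, axis=0), 2, axis=1), 2, axis=2)
    structure = VoxelImage(binary.astype(np.uint8), h, np.zeros(3))
    meta = {
        "iterations": it + 1,
        "final_density_change": history[-1],
        "stimulus_mean": float(stimulus[bone_solid].mean()),
        "stimulus_cov_pct": float(
            100 * stimulus[bone_solid].std() / stimulus[bone_solid].mean()
        ),
        "density_history": history,
        "n_bone_elements": int(bone_solid.sum()),
    }
    return SyntheticSpecimen(
        binary_structure=structure,
        frame=frame,
        true_load_mix=mix,
        params=params,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# grayscale rendering

def synthesize_grayscale(
    structure: VoxelImage,
    bone_grey: float = 6000.0,
    background_grey: float = 1000.0,
    blur_sigma: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> VoxelImage:
    """Render a binary structure as a two-level grayscale CT-like volume.

    Optional Gaussian blur (sigma in voxels) emulates scanner blur and
    additive Gaussian noise emulates detector noise; with both at zero the
    output takes exactly the two input grey levels. Identical seeds give
    bit-identical volumes.
    """
    if bone_grey <= background_grey:
        raise ValueError("bone_grey must exceed background_grey")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    vals = np.where(structure.values > 0, float(bone_grey), float(background_grey))
    if blur_sigma > 0:
        vals = ndimage.gaussian_filter(vals, sigma=blur_sigma, mode="nearest")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = vals + noise_sd * rng.standard_normal(vals.shape)
    return VoxelImage(vals, structure.voxel_size, structure.origin.copy())


# ---------------------------------------------------------------------------
# in-vivo-style load traces

class ActivitySpec(NamedTuple):
    name: str
    peak_N: float
    inclination_deg: float
    duration_s: float
    sample_rate_hz: float


def default_activity_specs() -> list[ActivitySpec]:
    """Activities of daily living emulated by the trace generator.

    Peaks and frontal-plane inclinations are chosen to reproduce published
    instrumented-prosthesis summary figures: walking carries the largest
    peak (~2.7 kN near 18 deg) and the full direction range spans 3.7 deg
    to 66.6 deg from the vertical axis.
    """
    return [
        ActivitySpec("walking", 2700.0, 18.0, 1.1, 100.0),
        ActivitySpec("stair_climb", 2600.0, 22.0, 1.4, 100.0),
        ActivitySpec("stair_descend", 2550.0, 12.0, 1.3, 100.0),
        ActivitySpec("one_legged_stance", 2300.0, 3.7, 2.0, 100.0),
        ActivitySpec("stand_up", 1900.0, 60.0, 2.0, 100.0),
        ActivitySpec("sit_down", 1700.0, 66.6, 2.0, 100.0),
    ]


def generate_load_traces(
    activity_specs: Sequence[ActivitySpec] | None = None,
    n_subjects: int = 10,
    seed: int = 0,
    magnitude_jitter_sd: float = 0.0,
) -> pd.DataFrame:
    """Half-sine force cycles per subject and activity, implant frame.

    Each activity is one load cycle with a half-sine magnitude profile and
    a fixed frontal-plane direction; the per-subject peak magnitude is the
    configured peak plus Gaussian jitter (SD ``magnitude_jitter_sd`` in N,
    default 0). Columns: subject, activity, time_s, f_ml_N, f_ap_N,
    f_vert_N.
    """
    specs = list(activity_specs) if activity_specs is not None else default_activity_specs()
    if not specs:
        raise ValueError("activity list must not be empty")
    for s in specs:
        if s.peak_N <= 0:
            raise ValueError(f"peak magnitude must be > 0 ({s.name})")
        if s.sample_rate_hz <= 0:
            raise ValueError(f"sample rate must be > 0 ({s.name})")
    rng = np.random.default_rng(seed)
    rows = []
    for subj in range(1, n_subjects + 1):
        for s in specs:
            peak = s.peak_N + (magnitude_jitter_sd * rng.standard_normal()
                               if magnitude_jitter_sd > 0 else 0.0)
            peak = max(peak, 1e-6)
            m = int(round(s.duration_s * s.sample_rate_hz))
            m += m % 2  # even interval count -> the mid-cycle sample hits the peak
            t = np.linspace(0.0, s.duration_s, m + 1)
            mag = peak * np.sin(np.pi * t / s.duration_s)
            d = direction_vector(s.inclination_deg)
            rows.append(pd.DataFrame({
                "subject": subj,
                "activity": s.name,
                "time_s": t,
                "f_ml_N": mag * d[0],
                "f_ap_N": mag * d[1],
                "f_vert_N": mag * d[2],
            }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# published per-specimen results fixture

@dataclass
class Table2Fixture:
    """Published load-scaling factors and CoV values for ten femora."""

    records: pd.DataFrame  # 10 rows: specimen, alpha_1..alpha_4, cov_init, cov_opt
    printed_mean: dict
    printed_sd: dict

    def __post_init__(self) -> None:
        if len(self.records) != 10:
            raise ValueError("fixture must contain exactly 10 specimen records")
        alphas = self.alphas
        if np.any(alphas < 0):
            raise ValueError("alpha values must be >= 0")
        if np.any(self.records[["cov_init", "cov_opt"]].to_numpy() <= 0):
            raise ValueError("CoV values must be > 0")

    @property
    def alphas(self) -> np.ndarray:
        return self.records[["alpha_1", "alpha_2", "alpha_3", "alpha_4"]].to_numpy()

    @property
    def cov_init(self) -> np.ndarray:
        return self.records["cov_init"].to_numpy()

    @property
    def cov_opt(self) -> np.ndarray:
        return self.records["cov_opt"].to_numpy()


def table2_fixture() -> Table2Fixture:
    """Load the packaged per-specimen alpha/CoV table."""
    ref = importlib.resources.files("femload.data") / "specimen_alpha_cov.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, comment="#", dtype={"specimen": str})
    records = df[~df["specimen"].isin(["Mean", "SD"])].reset_index(drop=True)
    records = records.astype({c: float for c in records.columns if c != "specimen"})
    mean = df[df["specimen"] == "Mean"].iloc[0].drop("specimen").astype(float).to_dict()
    sd = df[df["specimen"] == "SD"].iloc[0].drop("specimen").astype(float).to_dict()
    return Table2Fixture(records=records, printed_mean=mean, printed_sd=sd)


# ---------------------------------------------------------------------------
# synthetic whole proximal femur (for frame-construction tests)

def synthetic_proximal_femur(
    voxel_size: float = 1.0,
    shaft_length: float = 60.0,
    shaft_radius: float = 8.0,
    neck_radius: float = 5.0,
    head_radius: float = 12.0,
    neck_angle_deg: float = 50.0,
    rotation: np.ndarray | None = None,
    pad_mm: float = 4.0,
) -> tuple[VoxelImage, dict]:
    """Solid idealised proximal femur: shaft + oblique neck + head sphere.

    Returns the binary image and the generating ground truth (head centre,
    radius, vertical/neck axes), optionally rigidly rotated by ``rotation``
    (3x3). Useful as an oracle for anatomical-frame construction.
    """
    Rm = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    a = np.deg2rad(neck_angle_deg)
    # canonical (unrotated) landmarks: shaft along +z from origin
    shaft_base = np.zeros(3)
    shaft_top = np.array([0.0, 0.0, shaft_length])
    neck_dir = np.array([np.sin(a), 0.0, np.cos(a)])
    neck_len = shaft_radius + 2.5 * neck_radius + head_radius
    head_centre = shaft_top + neck_dir * neck_len

    pts_of_interest = np.stack([shaft_base, shaft_top, head_centre])
    pts_rot = pts_of_interest @ Rm.T
    lo = pts_rot.min(axis=0) - (head_radius + pad_mm)
    hi = pts_rot.max(axis=0) + (head_radius + pad_mm)
    n = np.ceil((hi - lo) / voxel_size).astype(int)
    grid = np.stack(
        np.meshgrid(*[lo[i] + voxel_size * (np.arange(n[i]) + 0.5) for i in range(3)],
                    indexing="ij"),
        axis=-1,
    )
    p = grid.reshape(-1, 3) @ Rm  # back to canonical coordinates

    def seg_param_dist(p, a_pt, b_pt):
        ab = b_pt - a_pt
        t = np.clip(((p - a_pt) @ ab) / (ab @ ab), 0.0, 1.0)
        return t, np.linalg.norm(p - (a_pt + t[:, None] * ab), axis=1)

    _, d_shaft = seg_param_dist(p, shaft_base, shaft_top)
    solid = d_shaft <= shaft_radius
    # hourglass neck: narrowest halfway between shaft top and head centre
    s, d_neck = seg_param_dist(p, shaft_top, head_centre)
    r_neck = neck_radius * (1.0 + 1.6 * (s - 0.5) ** 2)
    solid |= d_neck <= r_neck
    solid |= np.linalg.norm(p - head_centre, axis=1) <= head_radius
    img = VoxelImage(solid.reshape(tuple(n)).astype(np.uint8), voxel_size, lo + voxel_size / 2)
    truth = {
        "head_centre": head_centre @ Rm.T,
        "head_radius": head_radius,
        "vertical": np.array([0.0, 0.0, 1.0]) @ Rm.T,
        "neck_axis": neck_dir @ Rm.T,
        "rotation": Rm,
    }
    return img, truth
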