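"""Inverse-remodelling joint load prediction.

Given the strain energy density fields U_i(x) of n unit load cases, find
the non-negative combined scaling factors s_i that bring the superimposed
stimulus

    U(x) = sum_i s_i * U_i(x)

as close as possible (least squares over the bone region of interest) to
the remodelling equilibrium stimulus U~ (default 0.02 MPa). Assuming an
equal number of load cycles for every unit load case, the force magnitude
multiplier of case i is alpha_i = sqrt(n * s_i), and the predicted joint
load vectors are alpha_i * F_i for the 1000 N unit resultants F_i.

The quality of a load combination is summarised by the coefficient of
variation (CoV, in %) of the stimulus distribution over the region of
interest: the lower the CoV, the more homogeneous the tissue loading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .image_pipeline import LABEL_BONE, SegmentedModel
from .unit_loads import direction_vector
from .voxel_fe import FEModel, SEDField

__all__ = [
    "LoadPredictionConfig",
    "ROIMask",
    "LoadPredictionResult",
    "combined_stimulus",
    "compute_cov",
    "make_roi",
    "predict_loads",
    "vectors_and_angles",
]


@dataclass
class LoadPredictionConfig:
    """Settings of the inverse-remodelling optimisation."""

    equilibrium_stimulus: float = 0.02  # MPa
    roi_reduction: float = 0.0  # mm, retreat from lateral/distal faces

    def __post_init__(self) -> None:
        if not self.equilibrium_stimulus > 0:
            raise ValueError("equilibrium_stimulus must be > 0")
        if self.roi_reduction < 0:
            raise ValueError("roi_reduction must be >= 0")


@dataclass
class ROIMask:
    """Bone elements entering the optimisation objective."""

    element_ids: np.ndarray  # indices into the FE element ordering
    reduction: float  # mm

    def __post_init__(self) -> None:
        self.element_ids = np.asarray(self.element_ids, dtype=int)
        if len(self.element_ids) == 0:
            raise ValueError("ROI is empty")


@dataclass
class LoadPredictionResult:
    s: np.ndarray  # combined scaling factors, >= 0
    alpha: np.ndarray  # load magnitudes, alpha_i = sqrt(n * s_i)
    directions: np.ndarray  # (n, 3) unit vectors +d_i
    resultant_magnitude: float  # N, unit-load resultant (1000 N)
    scaled_vectors: np.ndarray  # (n, 3) alpha_i * F_i, along +d_i
    peak_vector: np.ndarray
    peak_inclination: float  # degrees
    mean_vector: np.ndarray
    mean_inclination: float  # degrees
    cov_init: float  # %, uniformly scaled unit loads
    cov_opt: float  # %, optimised combination
    objective_init: float
    objective_opt: float
    degenerate: bool = False
    meta: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# inverse-remodelling load prediction\n")
            fh.write("# case s alpha fx_N fy_N fz_N inclination_deg\n")
            for i, (s, a, v) in enumerate(zip(self.s, self.alpha, self.scaled_vectors)):
                fh.write(f"{i + 1} {s:.9g} {a:.9g} {v[0]:.6f} {v[1]:.6f} {v[2]:.6f} "
                         f"{frontal_inclination(v):.4f}\n")
            fh.write(f"peak {np.linalg.norm(self.peak_vector):.4f} N at "
                     f"{self.peak_inclination:.4f} deg\n")
            fh.write(f"mean {np.linalg.norm(self.mean_vector):.4f} N at "
                     f"{self.mean_inclination:.4f} deg\n")
            fh.write(f"cov_init {self.cov_init:.6f} %\ncov_opt {self.cov_opt:.6f} %\n")
            fh.write(f"objective_init {self.objective_init:.9g}\n")
            fh.write(f"objective_opt {self.objective_opt:.9g}\n")


def _stack_fields(sed_set: list[SEDField]) -> np.ndarray:
    n_el = {len(f.sed) for f in sed_set}
    if len(n_el) != 1:
        raise ValueError("SED fields have mismatched element sets")
    return np.stack([f.sed for f in sed_set], axis=1)  # (nel, n)


def combined_stimulus(sed_set: list[SEDField], s: np.ndarray) -> np.ndarray:
    """Superimposed stimulus U(x) = sum_i s_i U_i(x), per element."""
    U = _stack_fields(sed_set)
    s = np.asarray(s, dtype=float)
    if len(s) != U.shape[1]:
        raise ValueError("s length must equal the number of load cases")
    if np.any(s < 0):
        raise ValueError("scaling factors must be non-negative")
    return U @ s


def compute_cov(field_values: np.ndarray, roi: ROIMask | None = None) -> float:
    """Coefficient of variation (%) of a stimulus field over the ROI.

    Population standard deviation over mean, in percent.
    """
    v = np.asarray(field_values, dtype=float)
    if roi is not None:
        v = v[roi.element_ids]
    mean = v.mean()
    if mean <= 0:
        raise ValueError("CoV undefined: ROI mean is not positive")
    return float(100.0 * v.std(ddof=0) / mean)


def make_roi(fe: FEModel, reduction: float = 0.0) -> ROIMask:
    """Bone elements farther than ``reduction`` mm from the lateral and
    distal crop faces (cartilage is always excluded)."""
    if reduction < 0:
        raise ValueError("reduction must be >= 0")
    eidx = fe.element_indices
    h = fe.element_size
    # distance of element centres from the low-ml and low-vert grid faces
    d_lat = (eidx[:, 0] + 0.5) * h
    d_dist = (eidx[:, 2] + 0.5) * h
    keep = (fe.labels == LABEL_BONE) & (d_lat > reduction) & (d_dist > reduction)
    ids = np.where(keep)[0]
    if len(ids) == 0:
        raise ValueError(f"ROI empty after {reduction} mm reduction")
    return ROIMask(ids, reduction)


def frontal_inclination(vector: np.ndarray) -> float:
    """Signed frontal-plane angle (deg) from the vertical axis.

    The anterior-posterior component is ignored (projection onto the
    ml-vert plane); positive angles tilt towards medial.
    """
    return float(np.rad2deg(np.arctan2(vector[0], vector[2])))


def vectors_and_angles(
    alpha: np.ndarray,
    inclinations_deg: np.ndarray,
    resultant_magnitude: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled, peak and mean joint load vectors from load magnitudes.

    Returns ``(scaled_vectors, peak_vector, mean_vector)``; the peak is the
    scaled vector of maximal magnitude (ties broken by lowest case index)
    and the mean is the vector sum divided by the number of load cases.
    """
    alpha = np.asarray(alpha, dtype=float)
    inclinations_deg = np.asarray(inclinations_deg, dtype=float)
    if len(alpha) != len(inclinations_deg):
        raise ValueError("alpha and direction lists must have equal length")
    dirs = np.stack([direction_vector(a) for a in inclinations_deg])
    scaled = alpha[:, None] * dirs * resultant_magnitude
    mags = np.linalg.norm(scaled, axis=1)
    peak = scaled[int(np.argmax(mags))]  # argmax returns the first maximum
    mean = scaled.sum(axis=0) / len(alpha)
    return scaled, peak, mean


def predict_loads(
    sed_set: list[SEDField],
    roi: ROIMask,
    config: LoadPredictionConfig | None = None,
    directions_deg: np.ndarray | None = None,
    resultant_magnitude: float = 1000.0,
) -> LoadPredictionResult:
    """Solve the non-negative least-squares load scaling problem.

    ``directions_deg`` are the frontal-plane inclinations of the unit load
    cases; when omitted the joint-load vector outputs are left at zero
    direction bookkeeping is skipped.
    """
    config = config or LoadPredictionConfig()
    U = _stack_fields(sed_set)
    n = U.shape[1]
    A = U[roi.element_ids]
    if not np.any(A > 0):
        raise ValueError("all SED fields are zero over the ROI")
    b = np.full(len(A), config.equilibrium_stimulus)

    s, _ = nnls(A, b)
    degenerate = bool(np.linalg.matrix_rank(A, tol=None) < n)

    alpha = np.sqrt(n * s)
    resid_opt = b - A @ s
    objective_opt = float(resid_opt @ resid_opt)

    # uniformly scaled unit loads: equal s_i; by CoV scale invariance the
    # common level does not matter, 1/n is used
    s_init = np.full(n, 1.0 / n)
    field_init = A @ s_init
    field_opt = A @ s
    resid_init = b - field_init
    objective_init = float(resid_init @ resid_init)
    cov_init = float(100.0 * field_init.std(ddof=0) / field_init.mean())
    cov_opt = float(100.0 * field_opt.std(ddof=0) / field_opt.mean())

    if directions_deg is None:
        directions_deg = np.full(n, np.nan)
        scaled = np.zeros((n, 3))
        peak = np.zeros(3)
        mean = np.zeros(3)
        dirs = np.zeros((n, 3))
        peak_inc = mean_inc = float("nan")
    else:
        directions_deg = np.asarray(directions_deg, dtype=float)
        scaled, peak, mean = vectors_and_angles(alpha, directions_deg, resultant_magnitude)
        dirs = np.stack([direction_vector(a) for a in directions_deg])
        peak_inc = frontal_inclination(peak) if np.any(alpha > 0) else float("nan")
        mean_inc = frontal_inclination(mean)

    meta = {}
    if not np.any(alpha > 0):
        meta["peak_undefined"] = True
    return LoadPredictionResult(
        s=s,
        alpha=alpha,
        directions=dirs,
        resultant_magnitude=resultant_magnitude,
        scaled_vectors=scaled,
        peak_vector=peak,
        peak_inclination=peak_inc,
        mean_vector=mean,
        mean_inclination=mean_inc,
        cov_init=cov_init,
        cov_opt=cov_opt,
        objective_init=objective_init,
        objective_opt=objective_opt,
        degenerate=degenerate,
        meta=meta,
    )
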