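"""B-scan processing: alignment, foveola location, six-layer segmentation and
per-eccentricity feature extraction.

Conventions (stated on every interface):

* depth axis in microns, 0 at the RPE2/Bruch's-membrane (BrM) band after
  alignment, increasing toward the vitreous;
* lateral axis in degrees, eccentricity 0 at the foveola, temporal negative;
* a single A-scan is a longitudinal reflectivity profile (LRP).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .errors import AlignmentError, FoveolaNotFoundError, UnsegmentableScanError

logger = logging.getLogger(__name__)

#: Boundary roles ordered from vitreous down to Bruch's membrane.
BOUNDARIES: tuple[str, ...] = ("OPL", "ELM", "EZ", "COST", "RPE1", "RPE2_BrM")

#: Roles assigned above the RPE2/BrM reference, ascending depth.
_ABOVE_BRM_ROLES: tuple[str, ...] = ("RPE1", "COST", "EZ", "ELM", "OPL")

#: Seven extraction eccentricities relative to the foveola (degrees).
ECCENTRICITY_GRID: tuple[float, ...] = (-0.75, -0.5, -0.25, 0.0, 0.25, 0.5, 0.75)

#: Fixed resampling depths for the reflectivity feature vector (um above BrM).
#: 0-240 um keeps the OPL band inside the window for the whole 24-150 um ONL
#: training range; truncating earlier makes the reflectivity models blind to
#: thick ONLs and over-sensitive to outer-segment band shifts.
DEFAULT_VEC_DEPTHS: np.ndarray = np.arange(0.0, 241.0, 4.0)  # 61 values


@dataclass
class BScan:
    """Depth x lateral reflectivity matrix (a stack of LRPs).

    ``reflectivity`` has shape ``(n_depth, n_lateral)``; ``truth`` optionally
    stores per-A-scan ground-truth boundary depths (same depth coordinates)
    for oracle testing of downstream stages.
    """

    reflectivity: np.ndarray
    depth_axis: np.ndarray  # um, strictly increasing
    lateral_axis: np.ndarray  # deg, strictly increasing
    aligned: bool = False
    foveola: float | None = None
    truth: dict[str, np.ndarray] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.reflectivity = np.asarray(self.reflectivity, dtype=float)
        self.depth_axis = np.asarray(self.depth_axis, dtype=float)
        self.lateral_axis = np.asarray(self.lateral_axis, dtype=float)
        if self.reflectivity.shape != (self.depth_axis.size, self.lateral_axis.size):
            raise ValueError(
                f"reflectivity shape {self.reflectivity.shape} does not match axes "
                f"({self.depth_axis.size}, {self.lateral_axis.size})"
            )
        for name, ax in (("depth", self.depth_axis), ("lateral", self.lateral_axis)):
            if ax.size > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError(f"{name} axis must be strictly increasing")

    @property
    def n_depth(self) -> int:
        return self.depth_axis.size

    @property
    def n_lateral(self) -> int:
        return self.lateral_axis.size

    @property
    def axial_step(self) -> float:
        return float(np.median(np.diff(self.depth_axis)))

    @property
    def lateral_step(self) -> float:
        return float(np.median(np.diff(self.lateral_axis)))


@dataclass
class LayerSegmentation:
    """Per-A-scan boundary depths (um, above BrM) for the six roles.

    ``depths[role]`` is NaN wherever the role is unassigned; ``flags[role]``
    is True for unreliable/missing entries (NaN depths are always flagged).
    """

    depths: dict[str, np.ndarray]
    flags: dict[str, np.ndarray]
    lateral_axis: np.ndarray

    def __post_init__(self) -> None:
        n = self.lateral_axis.size
        for role in BOUNDARIES:
            if role not in self.depths or self.depths[role].size != n:
                raise ValueError(f"missing or mis-sized depths for role {role}")
            if role not in self.flags or self.flags[role].size != n:
                raise ValueError(f"missing or mis-sized flags for role {role}")

    def valid(self, role: str) -> np.ndarray:
        """Boolean mask of A-scans where ``role`` is assigned and unflagged."""
        return ~self.flags[role] & np.isfinite(self.depths[role])


@dataclass
class StructuralSample:
    """Structural + reflectivity features at one (scan, eccentricity).

    Thicknesses are in microns; NaN means flagged (a defining boundary was
    missing), never silently zero.  ``eccentricity`` is relative to the
    foveola on the fixed 0.25-degree grid.
    """

    scan_id: str
    eccentricity: float
    onl: float
    is_len: float
    cos_len: float
    rpe: float
    n_extrema: int
    reflectivity_vec: np.ndarray

    def __post_init__(self) -> None:
        self.reflectivity_vec = np.asarray(self.reflectivity_vec, dtype=float)
        if self.n_extrema < 0:
            raise ValueError("n_extrema must be >= 0")
        for name in ("onl", "is_len", "cos_len", "rpe"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be >= 0 or NaN (flagged), got {v}")


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables for the order-constrained peak-assignment segmentation."""

    smooth_sigma: float = 1.0  # axial samples
    peak_prominence_frac: float = 0.05  # of scan max, band candidate threshold
    strong_height_frac: float = 0.5  # of scan max, "detectable band" for rejection
    rejection_frac: float = 0.5  # scans with < 2 strong bands in > this fraction rejected
    rejection_smooth_sigma: float = 3.0  # heavier smoothing for band detectability
    brm_tol_steps: float = 3.0  # RPE2/BrM must lie within this many steps of depth 0
    max_jump_um: float = 15.0  # lateral smoothness bound between neighbours
    skip_role_cost: float = 0.5
    skip_peak_cost: float = 0.25
    amp_weight: float = 2.0
    window_penalty: float = 5.0
    #: expected relative band amplitudes (vs RPE2/BrM) per above-BrM role
    expected_amps: Mapping[str, float] = field(
        default_factory=lambda: {"RPE1": 0.7, "COST": 0.6, "EZ": 0.8, "ELM": 0.35, "OPL": 0.45}
    )
    #: plausible depth windows (um above BrM) per above-BrM role
    depth_windows: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "RPE1": (4.0, 40.0),
            "COST": (12.0, 70.0),
            "EZ": (18.0, 100.0),
            "ELM": (24.0, 140.0),
            "OPL": (40.0, 300.0),
        }
    )


def _smooth(scan: BScan, sigma: float) -> np.ndarray:
    return gaussian_filter1d(scan.reflectivity, sigma=sigma, axis=0, mode="nearest")


# ---------------------------------------------------------------------------
# downsampling
# ---------------------------------------------------------------------------

def downsample_lrps(scan: BScan, target_per_15deg: int) -> BScan:
    """Average neighbouring LRPs to reduce lateral density.

    ``target_per_15deg`` is the desired A-scan count per 15 degrees of
    lateral extent (the acquisition convention).  Neighbouring columns are
    averaged in non-overlapping, nearly equal blocks; the lateral axis becomes
    the block centres.
    """
    if target_per_15deg < 1:
        raise ValueError("target_per_15deg must be >= 1")
    extent = scan.n_lateral * scan.lateral_step
    n_out = int(round(extent * target_per_15deg / 15.0))
    if n_out < 1:
        raise ValueError("target density too low for scan extent")
    if n_out > scan.n_lateral:
        raise ValueError(
            f"target density ({n_out} A-scans) exceeds input density ({scan.n_lateral})"
        )
    blocks = np.array_split(np.arange(scan.n_lateral), n_out)
    refl = np.column_stack([scan.reflectivity[:, b].mean(axis=1) for b in blocks])
    lat = np.array([scan.lateral_axis[b].mean() for b in blocks])
    truth = None
    if scan.truth is not None:
        truth = {k: np.array([v[b].mean() for b in blocks]) for k, v in scan.truth.items()}
    return BScan(
        reflectivity=refl,
        depth_axis=scan.depth_axis.copy(),
        lateral_axis=lat,
        aligned=scan.aligned,
        foveola=scan.foveola,
        truth=truth,
        meta=dict(scan.meta),
    )


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align_to_brm(
    scan: BScan,
    smooth_sigma: float = 1.0,
    sub_brm_pad_um: float = 40.0,
    strong_frac: float = 0.6,
) -> BScan:
    """Straighten the scan on the major hyperreflective band (RPE2/BrM).

    Per LRP the reference is the *deepest* strong peak of the smoothed
    profile (height >= ``strong_frac`` of the LRP maximum): RPE2/BrM is the
    strongest band and anatomically the bottom-most, which disambiguates it
    from merged photoreceptor-band clusters.  Each LRP is circularly shifted
    so that peak sits at depth 0; the output depth axis starts at
    ``-sub_brm_pad_um`` so the reference peak stays interior to the matrix.
    LRPs whose maximum touches the matrix border are flagged
    (``meta['alignment_flagged']``) and excluded from features downstream.
    """
    sm = _smooth(scan, smooth_sigma)
    if np.any(np.ptp(sm, axis=0) == 0):
        raise AlignmentError("no detectable band: at least one LRP is constant")
    peak_idx = np.empty(scan.n_lateral, dtype=int)
    for j in range(scan.n_lateral):
        col = sm[:, j]
        pk, _ = find_peaks(col, height=strong_frac * col.max())
        peak_idx[j] = pk[0] if pk.size else int(np.argmax(col))
    border = (peak_idx == 0) | (peak_idx == scan.n_depth - 1)
    if np.all(border):
        raise AlignmentError("no detectable band: all LRP maxima at matrix border")
    if border.any():
        logger.warning("alignment: %d/%d LRPs have truncated bands", border.sum(), border.size)

    step = scan.axial_step
    pad_idx = int(round(sub_brm_pad_um / step))
    pad_idx = min(pad_idx, scan.n_depth - 1)
    shifts = pad_idx - peak_idx  # roll so that the peak lands at index pad_idx

    refl = np.empty_like(scan.reflectivity)
    for j in range(scan.n_lateral):
        refl[:, j] = np.roll(scan.reflectivity[:, j], shifts[j])
    depth = step * np.arange(scan.n_depth) - pad_idx * step

    truth = None
    if scan.truth is not None:
        span = step * scan.n_depth
        truth = {}
        for k, v in scan.truth.items():
            d = v - scan.depth_axis[peak_idx]  # depth relative to the aligned peak
            truth[k] = (d - depth[0]) % span + depth[0]

    meta = dict(scan.meta)
    meta["alignment_flagged"] = border
    return BScan(
        reflectivity=refl,
        depth_axis=depth,
        lateral_axis=scan.lateral_axis.copy(),
        aligned=True,
        foveola=scan.foveola,
        truth=truth,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# foveola
# ---------------------------------------------------------------------------

def locate_foveola(
    scan: BScan,
    override: float | None = None,
    surface_frac: float = 0.3,
    lateral_smooth_sigma: float = 3.0,
    smooth_sigma: float = 2.0,
) -> float:
    """Lateral position (deg) of the foveola.

    If ``override`` is given it is returned unchanged, mirroring manual
    identification.  Otherwise the inner-retinal surface is traced as the
    greatest depth where smoothed reflectivity exceeds ``surface_frac`` of the
    scan maximum, smoothed laterally, and the position of maximum depression
    (minimum surface height above BrM) is returned; ties break toward the
    scan centre.
    """
    if override is not None:
        return float(override)
    if not scan.aligned:
        raise ValueError("scan must be aligned before locating the foveola")
    sm = _smooth(scan, smooth_sigma)
    thresh = surface_frac * sm.max()
    above = sm >= thresh
    if not above.any():
        raise FoveolaNotFoundError("no surface signal found; supply an override")
    # greatest depth index with signal, per A-scan
    idx = scan.n_depth - 1 - np.argmax(above[::-1, :], axis=0)
    surface = scan.depth_axis[idx].astype(float)
    surface = gaussian_filter1d(surface, sigma=lateral_smooth_sigma, mode="nearest")

    j_min = int(np.argmin(surface))
    if j_min in (0, scan.n_lateral - 1):
        raise FoveolaNotFoundError(
            "surface is monotone across the scan (no depression); supply an override"
        )
    # tie break toward scan centre among near-minimal positions
    eps = 1e-9 + 1e-6 * np.ptp(surface)
    cand = np.flatnonzero(surface <= surface[j_min] + eps)
    centre = 0.5 * (scan.lateral_axis[0] + scan.lateral_axis[-1])
    j_best = cand[np.argmin(np.abs(scan.lateral_axis[cand] - centre))]
    return float(scan.lateral_axis[j_best])


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _assign_roles(
    peak_depths: np.ndarray,
    peak_amps: np.ndarray,
    params: SegmentationParams,
) -> dict[str, float]:
    """Order-preserving assignment of ascending-depth peaks to the five
    above-BrM roles by dynamic programming (sequence alignment).

    Match cost is |relative amplitude - expected| plus a penalty when the peak
    falls outside the role's plausible depth window; roles may be skipped
    (missing band) and peaks may be skipped (e.g. the vitreoretinal surface).
    """
    roles = _ABOVE_BRM_ROLES
    nr, npk = len(roles), peak_depths.size
    INF = float("inf")
    cost = np.full((nr + 1, npk + 1), INF)
    move = np.zeros((nr + 1, npk + 1), dtype=np.int8)  # 1=match 2=skip-role 3=skip-peak
    cost[0, 0] = 0.0
    for j in range(1, npk + 1):
        cost[0, j] = cost[0, j - 1] + params.skip_peak_cost
        move[0, j] = 3
    for i in range(1, nr + 1):
        role = roles[i - 1]
        lo, hi = params.depth_windows[role]
        amp_exp = params.expected_amps[role]
        cost[i, 0] = cost[i - 1, 0] + params.skip_role_cost
        move[i, 0] = 2
        for j in range(1, npk + 1):
            d, a = peak_depths[j - 1], peak_amps[j - 1]
            c_match = cost[i - 1, j - 1] + params.amp_weight * abs(a - amp_exp)
            if not (lo <= d <= hi):
                c_match += params.window_penalty
            c_skip_role = cost[i - 1, j] + params.skip_role_cost
            c_skip_peak = cost[i, j - 1] + params.skip_peak_cost
            best = min(c_match, c_skip_role, c_skip_peak)
            cost[i, j] = best
            move[i, j] = 1 if best == c_match else (2 if best == c_skip_role else 3)

    out: dict[str, float] = {}
    i, j = nr, npk
    while i > 0 or j > 0:
        m = move[i, j]
        if m == 1:
            out[roles[i - 1]] = float(peak_depths[j - 1])
            i, j = i - 1, j - 1
        elif m == 2:
            i -= 1
        else:
            j -= 1
    return out


def segment_layers(
    scan: BScan,
    params: SegmentationParams | None = None,
    overrides: Mapping[str, Mapping[int, float]] | None = None,
) -> LayerSegmentation:
    """Assign the six boundary roles per A-scan from smoothed-LRP band peaks.

    Candidate boundaries are local maxima of the smoothed LRP; the RPE2/BrM
    role is the peak nearest depth 0 (the alignment reference) and the
    remaining roles are assigned by expected depth order and relative
    amplitude with a lateral-smoothness check.  ``overrides`` maps role ->
    {A-scan index -> depth} for manual correction (computer-assisted mode).
    """
    if params is None:
        params = SegmentationParams()
    if not scan.aligned:
        raise ValueError("scan must be aligned before segmentation")
    sm = _smooth(scan, params.smooth_sigma)
    scan_max = sm.max()
    if scan_max <= 0:
        raise UnsegmentableScanError("scan has no positive reflectivity")
    step = scan.axial_step
    brm_tol = params.brm_tol_steps * step

    n = scan.n_lateral
    depths = {r: np.full(n, np.nan) for r in BOUNDARIES}
    align_flagged = np.asarray(scan.meta.get("alignment_flagged", np.zeros(n, bool)))

    # band detectability on a heavier-smoothed copy: coherent bands survive,
    # speckle-scale peaks collapse
    smr = _smooth(scan, params.rejection_smooth_sigma)
    smr_thresh = params.strong_height_frac * smr.max()

    weak_cols = 0
    for j in range(n):
        col = sm[:, j]
        strong, _ = find_peaks(smr[:, j], height=smr_thresh)
        if strong.size < 2:
            weak_cols += 1
        pk, props = find_peaks(col, prominence=params.peak_prominence_frac * scan_max)
        heights = col[pk]
        if align_flagged[j] or pk.size == 0:
            continue
        pd_ = scan.depth_axis[pk]
        # RPE2/BrM: peak nearest depth 0 within tolerance
        near = np.abs(pd_) <= brm_tol
        if not near.any():
            continue
        k = np.flatnonzero(near)[np.argmax(heights[near])]
        brm_depth = pd_[k]
        brm_amp = heights[k]
        depths["RPE2_BrM"][j] = brm_depth
        above = pd_ > brm_depth + step
        if above.any() and brm_amp > 0:
            assigned = _assign_roles(pd_[above], heights[above] / brm_amp, params)
            for role, d in assigned.items():
                depths[role][j] = d

    if weak_cols > params.rejection_frac * n:
        raise UnsegmentableScanError(
            f"fewer than 2 detectable bands in {weak_cols}/{n} A-scans"
        )

    if overrides:
        for role, fixes in overrides.items():
            if role not in BOUNDARIES:
                raise ValueError(f"unknown boundary role {role!r}")
            for j, d in fixes.items():
                depths[role][int(j)] = float(d)

    flags = {}
    for role in BOUNDARIES:
        d = depths[role]
        f = ~np.isfinite(d) | align_flagged
        # lateral smoothness: compare to local rolling median of assigned depths
        med = pd.Series(d).rolling(9, center=True, min_periods=3).median().to_numpy()
        jumpy = np.isfinite(d) & np.isfinite(med) & (np.abs(d - med) > params.max_jump_um)
        if jumpy.any():
            logger.debug("segmentation: %d lateral-smoothness flags on %s", jumpy.sum(), role)
        f |= jumpy
        depths[role] = np.where(f, np.nan, d)
        flags[role] = f

    return LayerSegmentation(depths=depths, flags=flags, lateral_axis=scan.lateral_axis.copy())


def thicknesses_from_segmentation(seg: LayerSegmentation) -> pd.DataFrame:
    """Per-A-scan layer thicknesses (um) from boundary depths above BrM.

    ONL = OPL - ELM; IS = ELM - EZ; COS = EZ - COST; RPE = RPE1 - RPE2/BrM.
    A thickness whose defining boundary is flagged, or that comes out
    negative, is NaN (flagged) -- never clipped to 0.
    """
    d = seg.depths
    out = pd.DataFrame(
        {
            "onl": d["OPL"] - d["ELM"],
            "is_len": d["ELM"] - d["EZ"],
            "cos_len": d["EZ"] - d["COST"],
            "rpe": d["RPE1"] - d["RPE2_BrM"],
        }
    )
    out[out < 0] = np.nan
    return out


# ---------------------------------------------------------------------------
# extrema counting
# ---------------------------------------------------------------------------

def count_extrema(
    depth_axis: np.ndarray,
    lrp: np.ndarray,
    elm_depth: float,
    brm_depth: float,
    min_prominence: float,
    smooth_sigma: float = 2.0,
) -> int:
    """Count gradient extrema of a smoothed LRP between BrM and ELM.

    Returns the number of positive plus negative peaks of the first
    difference of the smoothed profile restricted to the open interval
    ``(brm_depth, elm_depth)``, each required to exceed ``min_prominence``.
    """
    if not elm_depth > brm_depth:
        raise ValueError("elm_depth must exceed brm_depth")
    depth_axis = np.asarray(depth_axis, dtype=float)
    lrp = np.asarray(lrp, dtype=float)
    mask = (depth_axis > brm_depth) & (depth_axis < elm_depth)
    if mask.sum() < 3:
        raise ValueError("window shorter than 3 samples")
    smoothed = gaussian_filter1d(lrp, sigma=smooth_sigma, mode="nearest")
    g = np.diff(smoothed[mask])
    pos, _ = find_peaks(g, prominence=min_prominence)
    neg, _ = find_peaks(-g, prominence=min_prominence)
    return int(pos.size + neg.size)


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def extract_samples(
    scan: BScan,
    seg: LayerSegmentation,
    foveola: float,
    scan_id: str = "scan",
    vec_depths: np.ndarray | None = None,
    window_deg: float = 0.05,
    min_prominence_frac: float = 0.05,
) -> list[StructuralSample]:
    """Extract the seven per-eccentricity structural samples of a scan.

    At each grid eccentricity (relative to ``foveola``) thicknesses are the
    mean over A-scans within ``+/- window_deg``; the reflectivity vector is
    the window-mean LRP resampled at ``vec_depths`` (um above BrM, default
    0-240 in 4 um steps); the extrema count is taken on the window-mean LRP
    between the local ELM and BrM.
    """
    if not scan.aligned:
        raise ValueError("scan must be aligned before feature extraction")
    if vec_depths is None:
        vec_depths = DEFAULT_VEC_DEPTHS
    thick = thicknesses_from_segmentation(seg)
    lat = scan.lateral_axis
    samples: list[StructuralSample] = []
    min_prom = min_prominence_frac * scan.reflectivity.max()
    for ecc in ECCENTRICITY_GRID:
        pos = foveola + ecc
        if pos < lat[0] - 1e-9 or pos > lat[-1] + 1e-9:
            raise ValueError(f"grid eccentricity {pos:.3f} deg outside scan extent")
        cols = np.flatnonzero(np.abs(lat - pos) <= window_deg)
        if cols.size == 0:
            cols = np.array([int(np.argmin(np.abs(lat - pos)))])
        with np.errstate(invalid="ignore"):
            t = thick.iloc[cols].mean(skipna=True)
        mean_lrp = scan.reflectivity[:, cols].mean(axis=1)
        vec = np.interp(vec_depths, scan.depth_axis, mean_lrp)
        elm = np.nanmean(seg.depths["ELM"][cols])
        if np.isfinite(elm) and elm > 3 * scan.axial_step:
            n_ext = count_extrema(scan.depth_axis, mean_lrp, elm, 0.0, min_prom)
        else:
            n_ext = 0
        samples.append(
            StructuralSample(
                scan_id=scan_id,
                eccentricity=float(ecc),
                onl=float(t["onl"]),
                is_len=float(t["is_len"]),
                cos_len=float(t["cos_len"]),
                rpe=float(t["rpe"]),
                n_extrema=n_ext,
                reflectivity_vec=vec,
            )
        )
    return samples
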