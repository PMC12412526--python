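"""Parametric 2-D vascular phantoms of the zebrafish trunk.

The generator emulates the trunk vasculature seen in en-face angiograms of
larval zebrafish: two roughly horizontal axial vessels (the ventral dorsal
aorta / caudal artery axis and the dorsal longitudinal anastomotic vessel)
joined by evenly spaced, near-vertical intersegmental vessels (ISVs).  The
tumor-like ("RAS+") phenotype is produced by three knobs:

* ``axis_bend_sigma_deg`` — a smooth low-frequency lateral displacement of
  the whole axis whose tangent-angle distribution has the requested standard
  deviation, emulating the bent DA/CA axis;
* ``wiggle_amplitude_px`` / ``wiggle_period_px`` — a sinusoidal transverse
  perturbation of each ISV centerline, the single knob controlling
  tortuosity;
* ``n_hyperbranches`` — extra bridges connecting adjacent ISVs at random
  heights, each carrying flow only with probability ``perfused_fraction``
  (newly formed tumor vessels are often not perfused).

Every vessel is stored as a dense sub-pixel centerline with analytically
known arc and chord length, so downstream skeleton-based estimators can be
validated by parameter recovery.  Rasterization sweeps a disk of the class
radius along each centerline (pixel center within ``radius`` of the
polyline), with optional post-raster Gaussian blur and additive noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .io import ROI, EnFaceMap

__all__ = [
    "PhenotypeParams",
    "Vessel",
    "VesselNetworkTruth",
    "generate_network",
    "single_vessel_truth",
    "rasterize",
    "default_image_shape",
    "ground_truth_metrics",
]

#: vessel classes used for radii and (in the pipeline) flow speeds
KINDS = ("axis_ventral", "axis_dorsal", "isv", "bridge")

DEFAULT_RADII = {"axis_ventral": 3.0, "axis_dorsal": 2.5, "isv": 2.0, "bridge": 2.0}


@dataclass(frozen=True)
class PhenotypeParams:
    """Generator knobs for one phantom; see module docstring for semantics."""

    n_isv: int = 6
    isv_spacing_px: float = 40.0
    axis_bend_sigma_deg: float = 0.0
    wiggle_amplitude_px: float = 0.0
    wiggle_period_px: float = 50.0
    n_hyperbranches: int = 0
    vessel_radius_px: dict = field(default_factory=lambda: dict(DEFAULT_RADII))
    perfused_fraction: float = 1.0
    trunk_height_px: float = 100.0
    margin_px: float = 30.0
    max_bridges_per_gap: int = 2
    bend_corr_len_px: float = 25.0
    pixel_size_um: float = 1.4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_isv < 2:
            raise ValueError("n_isv must be >= 2")
        if not 0.0 <= self.perfused_fraction <= 1.0:
            raise ValueError("perfused_fraction must be in [0, 1]")
        if self.wiggle_amplitude_px < 0:
            raise ValueError("wiggle_amplitude_px must be >= 0")
        if self.wiggle_period_px <= 0:
            raise ValueError("wiggle_period_px must be > 0")
        if self.axis_bend_sigma_deg < 0:
            raise ValueError("axis_bend_sigma_deg must be >= 0")
        rmax = max(self.vessel_radius_px.values())
        if self.isv_spacing_px <= 2 * rmax:
            raise ValueError("isv_spacing_px must exceed twice the largest radius")
        n_slots = (self.n_isv - 1) * self.max_bridges_per_gap
        if self.n_hyperbranches > n_slots:
            raise ValueError(
                f"{self.n_hyperbranches} hyperbranches do not fit in "
                f"{n_slots} slots ({self.n_isv - 1} gaps x "
                f"{self.max_bridges_per_gap})"
            )


@dataclass
class Vessel:
    """One vessel centerline: ordered sub-pixel (row, col) points."""

    name: str
    kind: str
    points: np.ndarray  # (N, 2) float, (row, col)
    radius_px: float
    perfused: bool = True

    @property
    def arc_length_px(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    @property
    def chord_length_px(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))


@dataclass
class VesselNetworkTruth:
    """Exact geometric ground truth for one phantom."""

    vessels: list
    junctions: np.ndarray  # (J, 2) (row, col)
    params: PhenotypeParams
    meta: dict = field(default_factory=dict)

    @property
    def junction_count(self) -> int:
        return len(self.junctions)

    @property
    def total_length_px(self) -> float:
        return float(sum(v.arc_length_px for v in self.vessels))

    def subset(self, which: str) -> list:
        if which == "all":
            return list(self.vessels)
        if which == "perfused_only":
            return [v for v in self.vessels if v.perfused]
        raise ValueError("which must be 'all' or 'perfused_only'")

    def validate(self, tol_px: float = 0.35) -> None:
        """Check the structural invariants (junctions on >=2 centerlines,
        arc >= chord per chain)."""
        for v in self.vessels:
            if v.arc_length_px + 1e-9 < v.chord_length_px:
                raise AssertionError(f"arc < chord for {v.name}")
        for j in self.junctions:
            n_on = sum(
                _min_dist_to_polyline(j, v.points) <= tol_px for v in self.vessels
            )
            if n_on < 2:
                raise AssertionError(f"junction {j} lies on {n_on} centerlines")


def _min_dist_to_polyline(point: np.ndarray, chain: np.ndarray) -> float:
    a, b = chain[:-1], chain[1:]
    d = b - a
    L2 = np.einsum("ij,ij->i", d, d)
    L2 = np.where(L2 == 0, 1.0, L2)
    t = np.clip(np.einsum("ij,ij->i", point - a, d) / L2, 0.0, 1.0)
    proj = a + t[:, None] * d
    return float(np.min(np.linalg.norm(point - proj, axis=1)))


def _bend_displacement(n: int, sigma_deg: float, corr_len: float, rng) -> np.ndarray:
    """Smooth lateral displacement (px) whose tangent-angle sd is sigma_deg.

    Built from Gaussian-smoothed white noise and rescaled so the empirical
    standard deviation of the local heading angle equals the requested
    sigma; bounded in amplitude (unlike an integrated heading walk).
    """
    if sigma_deg == 0 or n < 3:
        return np.zeros(n)
    white = rng.standard_normal(n)
    dev = gaussian_filter1d(white, sigma=corr_len, mode="reflect")
    # band-limit: drop wavelengths much longer than the correlation length,
    # whose lobes would otherwise dominate the excursion after the heading
    # rescale below and push the axis out of frame
    dev = dev - gaussian_filter1d(dev, sigma=4 * corr_len, mode="reflect")
    dev -= dev.mean()
    slope = np.gradient(dev)
    sd = np.degrees(np.arctan(slope)).std()
    if sd == 0:
        return np.zeros(n)
    # arctan is near-linear for the bend regime (< ~10 deg); one Newton
    # correction handles the residual nonlinearity
    dev *= sigma_deg / sd
    sd2 = np.degrees(np.arctan(np.gradient(dev))).std()
    if sd2 > 0:
        dev *= sigma_deg / sd2
    return dev


def generate_network(params: PhenotypeParams) -> VesselNetworkTruth:
    """Build the trunk phantom for ``params`` (deterministic per seed)."""
    rng = np.random.default_rng(params.rng_seed)
    radii = {**DEFAULT_RADII, **params.vessel_radius_px}
    m = params.margin_px
    spacing = params.isv_spacing_px
    x_isv = m + spacing / 2 + spacing * np.arange(params.n_isv)
    x0, x1 = m, x_isv[-1] + spacing / 2 + spacing / 2
    y_dorsal, y_ventral = m, m + params.trunk_height_px

    # axial vessels: shared smooth bend displacement (the spine bends rigidly)
    xs = np.arange(x0, x1 + 0.5, 1.0)
    dev = _bend_displacement(len(xs), params.axis_bend_sigma_deg,
                             params.bend_corr_len_px, rng)
    # keep the bent axis inside the margins: rare realizations whose heading
    # variance sits in one slow lobe are damped to the allowed excursion
    dev_cap = params.margin_px - max(radii.values()) - 6.0
    if dev_cap > 0 and np.abs(dev).max() > dev_cap:
        dev *= dev_cap / np.abs(dev).max()
    ventral = np.column_stack([y_ventral + dev, xs])
    dorsal = np.column_stack([y_dorsal + dev, xs])

    vessels = [
        Vessel("DA_CA", "axis_ventral", ventral, radii["axis_ventral"]),
        Vessel("DLAV", "axis_dorsal", dorsal, radii["axis_dorsal"]),
    ]
    junctions: list[np.ndarray] = []
    wiggle_phases = {}

    def axis_y(axis_pts: np.ndarray, x: float) -> float:
        return float(np.interp(x, axis_pts[:, 1], axis_pts[:, 0]))

    # intersegmental vessels: vertical chains with sinusoidal x-perturbation,
    # spanning the local (bent) axis heights at each ISV position
    step = 0.25
    for i, xi in enumerate(x_isv):
        phase = float(rng.uniform(0, 2 * np.pi))
        wiggle_phases[f"ISV{i}"] = phase
        y_top = axis_y(dorsal, xi)
        y_bot = axis_y(ventral, xi)
        ys = np.arange(y_top, y_bot + step / 2, step)
        xcol = xi + params.wiggle_amplitude_px * np.sin(
            2 * np.pi * (ys - y_top) / params.wiggle_period_px + phase
        )
        pts = np.column_stack([ys, xcol])
        # snap terminal points onto the axial polylines so junctions lie on
        # both centerlines
        pts[0, 0] = axis_y(dorsal, pts[0, 1])
        pts[-1, 0] = axis_y(ventral, pts[-1, 1])
        vessels.append(Vessel(f"ISV{i}", "isv", pts, radii["isv"]))
        junctions.append(pts[0].copy())
        junctions.append(pts[-1].copy())

    # hyperbranches: straight bridges between adjacent ISVs at slot heights
    n_gaps = params.n_isv - 1
    slots = [(g, s) for g in range(n_gaps) for s in range(params.max_bridges_per_gap)]
    chosen = rng.choice(len(slots), size=params.n_hyperbranches, replace=False)
    isv_chains = [v.points for v in vessels if v.kind == "isv"]
    for k, idx in enumerate(sorted(int(c) for c in chosen)):
        g, s = slots[idx]
        # jittered height lattice staggered by slot and gap parity: any two
        # bridges sharing an ISV attach >= ~8 % of its length apart, so their
        # junctions stay resolvable in a finite-resolution raster
        u = float(0.20 + (0.7 / params.max_bridges_per_gap) * s
                  + 0.175 * (g % 2) + rng.uniform(0.0, 0.09))
        p_left = _point_at_fraction(isv_chains[g], u)
        p_right = _point_at_fraction(isv_chains[g + 1], u)
        t = np.linspace(0.0, 1.0, 160)
        pts = p_left[None, :] * (1 - t[:, None]) + p_right[None, :] * t[:, None]
        # mild sinusoidal bow (zero at both endpoints): new tumor vessels are
        # not straight, and a perfectly straight digital chain would put all
        # its orientation samples into a single degenerate histogram bin
        bow = 0.5 * params.wiggle_amplitude_px
        if bow > 0:
            d = p_right - p_left
            L = np.linalg.norm(d)
            if L > 0:
                normal = np.array([-d[1], d[0]]) / L
                pts = pts + bow * np.sin(2 * np.pi * t)[:, None] * normal[None, :]
        perfused = bool(rng.random() < params.perfused_fraction)
        vessels.append(Vessel(f"BR{k}", "bridge", pts, radii["bridge"], perfused))
        junctions.append(p_left.copy())
        junctions.append(p_right.copy())

    truth = VesselNetworkTruth(
        vessels,
        np.array(junctions).reshape(-1, 2),
        params,
        meta={"wiggle_phases": wiggle_phases, "x_isv": x_isv.tolist(),
              "y_dorsal": y_dorsal, "y_ventral": y_ventral},
    )
    return truth


def _point_at_fraction(chain: np.ndarray, u: float) -> np.ndarray:
    """Actual chain sample nearest to arc-length fraction ``u``."""
    seg = np.linalg.norm(np.diff(chain, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    idx = int(np.argmin(np.abs(cum - u * cum[-1])))
    return chain[idx].copy()


def single_vessel_truth(
    length_px: float = 200.0,
    radius_px: float = 2.0,
    orientation_deg: float = 0.0,
    margin_px: float = 10.0,
    pixel_size_um: float = 1.4,
) -> VesselNetworkTruth:
    """Ground truth holding one straight vessel (a calibration phantom)."""
    th = np.radians(orientation_deg)
    t = np.linspace(0.0, length_px, int(length_px * 4) + 1)
    # integer start point: a calibration phantom should sit on the pixel
    # lattice so its rasterized width equals the nominal 2*radius+1 band
    r0 = round(margin_px + radius_px + length_px * max(0.0, -np.sin(th)))
    c0 = round(margin_px + radius_px + length_px * max(0.0, -np.cos(th)))
    pts = np.column_stack([r0 - t * np.sin(th), c0 + t * np.cos(th)])
    params = PhenotypeParams(pixel_size_um=pixel_size_um,
                             vessel_radius_px={"isv": radius_px})
    v = Vessel("V0", "isv", pts, radius_px)
    return VesselNetworkTruth([v], np.empty((0, 2)), params)


def default_image_shape(truth: VesselNetworkTruth, pad_px: float = 2.0) -> tuple[int, int]:
    pts = np.concatenate([v.points for v in truth.vessels])
    rmax = max(v.radius_px for v in truth.vessels)
    h = int(np.ceil(pts[:, 0].max() + truth.params.margin_px))
    w = int(np.ceil(pts[:, 1].max() + rmax + pad_px))
    return h, w


def _sweep_mask(chain: np.ndarray, radius: float, shape: tuple[int, int]) -> np.ndarray:
    """Boolean swept-disk raster: pixel centers within ``radius`` of the
    polyline (exact point-to-segment distance, no anti-aliasing)."""
    h, w = shape
    r_lo = int(np.floor(chain[:, 0].min() - radius - 1))
    r_hi = int(np.ceil(chain[:, 0].max() + radius + 1))
    c_lo = int(np.floor(chain[:, 1].min() - radius - 1))
    c_hi = int(np.ceil(chain[:, 1].max() + radius + 1))
    if r_lo < -1 or c_lo < -1 or r_hi > h or c_hi > w:
        raise ValueError("vessel (with radius) exceeds image bounds")
    r_lo, c_lo = max(r_lo, 0), max(c_lo, 0)
    r_hi, c_hi = min(r_hi, h - 1), min(c_hi, w - 1)
    rr, cc = np.meshgrid(np.arange(r_lo, r_hi + 1), np.arange(c_lo, c_hi + 1),
                         indexing="ij")
    pix = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)

    a, b = chain[:-1], chain[1:]
    d = b - a
    L2 = np.einsum("ij,ij->i", d, d)
    keep = L2 > 0
    a, d, L2 = a[keep], d[keep], L2[keep]
    if len(a) == 0:  # degenerate single-point chain
        a = chain[:1]
        d = np.zeros((1, 2))
        L2 = np.ones(1)
    # process pixels in blocks to bound memory at ~ (block x segments)
    within = np.zeros(len(pix), dtype=bool)
    block = max(1, int(4e6 / max(len(a), 1)))
    for s in range(0, len(pix), block):
        p = pix[s:s + block]
        t = np.clip(
            ((p[:, None, :] - a[None]) * d[None]).sum(-1) / L2[None], 0.0, 1.0
        )
        proj = a[None] + t[..., None] * d[None]
        dist2 = ((p[:, None, :] - proj) ** 2).sum(-1)
        within[s:s + block] = dist2.min(axis=1) <= radius * radius
    out = np.zeros(shape, dtype=bool)
    out[rr.ravel()[within], cc.ravel()[within]] = True
    return out


def rasterize(
    truth: VesselNetworkTruth,
    which: str = "all",
    image_shape: tuple[int, int] | None = None,
    pixel_size_um: float | None = None,
    values: dict | None = None,
    blur_sigma_px: float = 0.0,
    noise_sigma: float = 0.0,
    rng=None,
    channel: str | None = None,
) -> EnFaceMap:
    """Rasterize the network into an en-face map.

    ``which="all"`` emulates the GFP/structure channel (every vessel),
    ``which="perfused_only"`` the OCTA/flow channel.  ``values`` optionally
    maps vessel kind -> pixel value (default 1.0); overlaps take the max, so
    the perfused raster is pixelwise <= the all-vessel raster.
    """
    shape = image_shape or default_image_shape(truth)
    canvas = np.zeros(shape, dtype=float)
    for v in truth.subset(which):
        val = 1.0 if values is None else float(values.get(v.kind, 1.0))
        mask = _sweep_mask(v.points, v.radius_px, shape)
        np.maximum(canvas, val * mask, out=canvas)
    if blur_sigma_px > 0:
        canvas = gaussian_filter(canvas, blur_sigma_px)
    if noise_sigma > 0:
        rng = np.random.default_rng(truth.params.rng_seed) if rng is None else (
            np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
        )
        canvas = canvas + rng.normal(0.0, noise_sigma, size=shape)
    np.clip(canvas, 0.0, None, out=canvas)
    if channel is None:
        channel = "structure" if which == "all" else "flow"
    return EnFaceMap(canvas, pixel_size_um or truth.params.pixel_size_um, channel)


# ---------------------------------------------------------------------------
# analytic ground-truth metrics
# ---------------------------------------------------------------------------

def split_at_junctions(truth: VesselNetworkTruth, tol_px: float = 0.6) -> list[np.ndarray]:
    """Split each centerline at interior junction points, mirroring the
    junction-to-junction edges a skeleton graph produces."""
    out = []
    for v in truth.vessels:
        cuts = [0, len(v.points) - 1]
        for j in truth.junctions:
            d = np.linalg.norm(v.points - j, axis=1)
            i = int(np.argmin(d))
            if d[i] <= tol_px and 0 < i < len(v.points) - 1:
                cuts.append(i)
        cuts = sorted(set(cuts))
        for a, b in zip(cuts[:-1], cuts[1:]):
            seg = v.points[a:b + 1]
            if len(seg) >= 2:
                out.append(seg)
    return out


def windowed_arc_chord(
    chain: np.ndarray, window_px: float = 20.0, step_px: float = 1.0
) -> list[float]:
    """Arc/chord ratios of overlapping fixed-arc-length windows of a polyline.

    The chain is re-parametrized by arc length; each window spans exactly
    ``window_px`` of path, its ratio being ``window_px`` divided by the
    Euclidean distance between the window's end points.  Chains shorter than
    the window contribute their single whole-chain ratio.
    """
    seg = np.linalg.norm(np.diff(chain, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        return []
    if total < window_px:
        chord = float(np.linalg.norm(chain[-1] - chain[0]))
        return [total / chord] if chord > 0 else []
    ratios = []
    s = 0.0
    while s + window_px <= total + 1e-9:
        p0 = _interp_along(chain, cum, s)
        p1 = _interp_along(chain, cum, min(s + window_px, total))
        chord = float(np.linalg.norm(p1 - p0))
        if chord > 0:
            ratios.append(window_px / chord)
        s += step_px
    return ratios


def _interp_along(chain: np.ndarray, cum: np.ndarray, s: float) -> np.ndarray:
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(max(i, 0), len(chain) - 2)
    ds = cum[i + 1] - cum[i]
    t = 0.0 if ds == 0 else (s - cum[i]) / ds
    return chain[i] * (1 - t) + chain[i + 1] * t


def tangent_angles_deg(
    chain: np.ndarray, sample_step_px: float = 1.0, halfspan_px: float = 4.0
) -> np.ndarray:
    """Local orientations (degrees, image convention: 0 = +col direction)
    sampled at fixed arc steps along a polyline.

    Each sample is the central difference over ±``halfspan_px`` of arc — the
    same spatial scale at which skeleton-based orientation is measured, so
    analytic truth and pixel-chain estimates are directly comparable.
    """
    seg = np.linalg.norm(np.diff(chain, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] < 2 * sample_step_px:
        d = chain[-1] - chain[0]
        return np.array([np.degrees(np.arctan2(-d[0], d[1]))])
    h = min(halfspan_px, cum[-1] / 2)
    ss = np.arange(h, cum[-1] - h + 1e-9, sample_step_px)
    p_fwd = np.array([_interp_along(chain, cum, s + h) for s in ss])
    p_bwd = np.array([_interp_along(chain, cum, s - h) for s in ss])
    d = p_fwd - p_bwd
    # rows grow downward: negate the row delta so angles follow math convention
    return np.degrees(np.arctan2(-d[:, 0], d[:, 1]))


def ground_truth_metrics(
    truth: VesselNetworkTruth,
    roi: ROI | None = None,
    image_shape: tuple[int, int] | None = None,
    window_px: float = 20.0,
    step_px: float = 1.0,
):
    """Analytic expectations for the five topological descriptors.

    Tortuosity and orientation statistics are computed on the exact
    centerlines (split at junctions, windowed arc/chord, tangent-angle
    Gaussian fit shared with :mod:`vesselquant.topology`); density comes
    from the clean raster, diameter from the class radii, and the
    bifurcation rate from the exact junction count and centerline length.
    """
    from .topology import TopologyMetrics, fit_orientation_sigma

    shape = image_shape or default_image_shape(truth)
    roi = roi or ROI(0, shape[0], 0, shape[1])
    chains = split_at_junctions(truth)
    chains = [c[roi.contains_points(c)] for c in chains]
    chains = [c for c in chains if len(c) >= 2]
    if not chains:
        raise ValueError("ROI does not intersect the network")

    ratios: list[float] = []
    for c in chains:
        ratios.extend(windowed_arc_chord(c, window_px, step_px))
    tortuosity = float(np.mean(ratios)) if ratios else float("nan")

    angles = np.concatenate([tangent_angles_deg(c) for c in chains])
    sigma = fit_orientation_sigma(angles)

    mask = rasterize(truth, "all", shape).pixels > 0
    density = float(mask[roi.slices].mean())

    lengths = np.array([
        np.sum(np.linalg.norm(np.diff(c, axis=0), axis=1)) for c in chains
    ])
    total_len = float(lengths.sum())
    # length-weighted mean diameter over vessels intersecting the ROI
    per_chain_rad = []
    for c in chains:
        for v in truth.vessels:
            if _min_dist_to_polyline(c[len(c) // 2], v.points) < 0.5:
                per_chain_rad.append(v.radius_px)
                break
        else:
            per_chain_rad.append(np.nan)
    per_chain_rad = np.array(per_chain_rad, dtype=float)
    ok = np.isfinite(per_chain_rad)
    diam_px = float(np.average(2 * per_chain_rad[ok], weights=lengths[ok]))

    n_junc = int(roi.contains_points(truth.junctions).sum()) if len(truth.junctions) else 0
    bif = n_junc / (total_len / roi.area_px) if total_len > 0 else 0.0

    return TopologyMetrics(
        tortuosity=tortuosity,
        orientation_sigma_deg=sigma,
        vessel_density=density,
        mean_vessel_diameter_um=diam_px * truth.params.pixel_size_um,
        bifurcations_per_length=float(bif),
        n_junctions=n_junc,
        n_windows=len(ratios),
        n_angle_samples=len(angles),
        total_length_px=total_len,
        pixel_size_um=truth.params.pixel_size_um,
    )
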