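"""Transverse-profile extraction and cross-section model fitting.

A traced filament is sampled at regular arc-length steps; at every sample a
line perpendicular to the local tangent is interpolated from the image and
all lines are averaged into one :class:`TransverseProfile`.  The averaged
profile is then fitted with one of five cross-section models:

* ``gaussian``       h·exp(−(x−c)²/2w²) + b                    (single ridge)
* ``bigaussian``     two Gaussians + b                         (hollow filament,
                     peak-to-peak = |c2−c1|)
* ``trigaussian``    three Gaussians + b                       (hollow filament
                     over strong background)
* ``cylinder``       projection of a uniform annulus with inner/outer radii
                     r1 < r2, amplitude h: h·(√(r2²−u²) − √(r1²−u²)) inside
                     the bore (u = x−c, |u| < r1), h·√(r2²−u²) in the wall,
                     0 outside
* ``multicylinder``  sum of three annulus projections tied to the microtubule
                     geometry (25 nm tube, fluorophore layer at 42.5·e_x/2)
                     with free shell thickness a and expansion e_x

Fits are deterministic: initial parameters are derived from the profile
(two highest local maxima for the bi-Gaussian centers, half-maximum
crossings for the cylinder radii) unless explicit ``init`` overrides them,
and results are reported canonically with c1 < c2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import ndimage, optimize, signal

from .io_formats import SRImage

__all__ = [
    "TransverseProfile", "ProfileFit", "SegmentStatistics",
    "MODELS", "eval_model", "fit_profile", "extract_profiles",
    "aggregate_segments", "xz_projection", "relative_label_density",
    "FitError",
]


class FitError(RuntimeError):
    """A profile fit failed to converge or collapsed degenerately."""


@dataclass
class TransverseProfile:
    """Averaged perpendicular intensity profile on a centered nm axis."""

    axis: np.ndarray        # nm offsets, uniform, symmetric about 0
    values: np.ndarray      # averaged intensity
    n_lines: int = 1        # number of contributing line profiles
    trace_id: int = 0

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.axis.ndim != 1 or self.axis.shape != self.values.shape:
            raise ValueError("axis and values must be 1D and congruent")
        if len(self.axis) >= 2:
            steps = np.diff(self.axis)
            if (steps <= 0).any():
                raise ValueError("axis must be strictly increasing")
            if abs(self.axis[0] + self.axis[-1]) > steps.mean() + 1e-9:
                raise ValueError("axis must be symmetric about 0 within one step")
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")


@dataclass
class ProfileFit:
    """Result of fitting one cross-section model to an averaged profile."""

    model: str
    params: dict[str, float]
    residual_rms: float
    peak_to_peak: Optional[float] = None
    n_points: int = 0

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return eval_model(self.model, self.params, x)


@dataclass
class SegmentStatistics:
    """Per-segment peak-to-peak statistics as reported in figure legends."""

    per_segment_p2p: list[float]
    mean: float
    sd: float
    n_segments: int
    total_length: float  # µm


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

def _gauss(x: np.ndarray, h: float, c: float, w: float) -> np.ndarray:
    return h * np.exp(-((x - c) ** 2) / (2.0 * w ** 2))


def _cyl(x: np.ndarray, h: float, c: float, r1: float, r2: float) -> np.ndarray:
    """Projection of a uniform annulus; piecewise in u = x − c.

    The bore condition is evaluated on |x − c| so the shape is translation
    invariant (the squared terms already use x − c).
    """
    if r1 < 0 or r1 >= r2:
        raise ValueError("cylinder radii require 0 <= r1 < r2")
    u = np.abs(np.asarray(x, dtype=float) - c)
    y = np.zeros_like(u)
    wall = u < r2
    y[wall] = np.sqrt(r2 ** 2 - u[wall] ** 2)
    bore = u < r1
    y[bore] -= np.sqrt(r1 ** 2 - u[bore] ** 2)
    return h * y


def _multicyl_radii(a: float, e_x: float) -> list[tuple[float, float]]:
    """The three annuli of the multi-cylinder model at expansion e_x.

    Two shells straddle the 25 nm microtubule wall and one sits at the
    fluorophore-layer diameter 42.5·e_x; a is the common shell thickness.
    """
    return [
        (25.0 * e_x / 2.0 - 2.0 * a, 25.0 * e_x / 2.0 - a),
        (42.5 * e_x / 2.0, 42.5 * e_x / 2.0 + a),
        (25.0 * e_x / 2.0 + a, 25.0 * e_x / 2.0 + 2.0 * a),
    ]


#: model name -> ordered free-parameter names
MODELS: dict[str, tuple[str, ...]] = {
    "gaussian": ("h", "c", "w", "b"),
    "bigaussian": ("h1", "c1", "w1", "h2", "c2", "w2", "b"),
    "trigaussian": ("h1", "c1", "w1", "h2", "c2", "w2", "h3", "c3", "w3", "b"),
    "cylinder": ("h", "c", "r1", "r2"),
    "multicylinder": ("i1", "i2", "i3", "c", "a", "e_x", "b"),
}


def eval_model(model: str, params: Mapping[str, float], x: np.ndarray) -> np.ndarray:
    """Evaluate a cross-section model pointwise at offsets ``x`` (nm)."""
    x = np.asarray(x, dtype=float)
    p = params
    if model == "gaussian":
        return _gauss(x, p["h"], p["c"], p["w"]) + p["b"]
    if model == "bigaussian":
        return (_gauss(x, p["h1"], p["c1"], p["w1"])
                + _gauss(x, p["h2"], p["c2"], p["w2"]) + p["b"])
    if model == "trigaussian":
        return (_gauss(x, p["h1"], p["c1"], p["w1"])
                + _gauss(x, p["h2"], p["c2"], p["w2"])
                + _gauss(x, p["h3"], p["c3"], p["w3"]) + p["b"])
    if model == "cylinder":
        return _cyl(x, p["h"], p["c"], p["r1"], p["r2"])
    if model == "multicylinder":
        y = np.zeros_like(x) + p["b"]
        for (r1, r2), h in zip(_multicyl_radii(p["a"], p["e_x"]),
                               (p["i1"], p["i2"], p["i3"])):
            y = y + _cyl(x, h, p["c"], r1, r2)
        return y
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# initial estimates
# ---------------------------------------------------------------------------

#: physical scale (nm) of the pre-fit smoothing and curvature probes, so
#: initial estimates do not depend on the sampling step of the profile
_SEED_SMOOTH_NM = 2.0
_SEED_CURV_NM = 1.5


def _smoothed(values: np.ndarray, step: float = 1.0) -> np.ndarray:
    sigma = max(1.0, _SEED_SMOOTH_NM / step)
    return ndimage.gaussian_filter1d(values, sigma, mode="nearest")


def _two_peaks(axis: np.ndarray,
               values: np.ndarray) -> tuple[float, float, float, float]:
    """Centers and widths of the two highest local maxima of the profile.

    Returns ``(c1, c2, w1, w2)`` with c1 < c2; widths are Gaussian-sigma
    estimates from the half-prominence peak widths.  Falls back to
    symmetric positions around the global maximum when the profile shows no
    resolvable dip.  Equal maxima break ties leftmost first.
    """
    step = float(axis[1] - axis[0]) if len(axis) > 1 else 1.0
    span = float(np.ptp(axis))
    sm = _smoothed(values, step)
    peaks, props = signal.find_peaks(sm, prominence=1e-12 + 0.005 * np.ptp(sm))
    if len(peaks) >= 2:
        order = np.argsort(sm[peaks], kind="stable")[::-1]
        best = np.sort(peaks[order[:2]])
        w = [_local_width(axis, sm, i) for i in best]
        return (float(axis[best[0]]), float(axis[best[1]]),
                float(w[0]), float(w[1]))
    c0 = abs(float(axis[int(np.argmax(sm))]))
    if c0 < span / 50.0:
        c0 = span / 8.0
    return -c0, c0, c0 / 2.0, c0 / 2.0


def _local_width(axis: np.ndarray, sm: np.ndarray, i: int) -> float:
    """Gaussian-sigma seed from the curvature at a local maximum.

    For a Gaussian peak f''(c)/f(c) = −1/w², a purely local measure that is
    insensitive to plateaus or background away from the peak; this keeps
    the subsequent fit locked to the sidewall maxima it was seeded on.
    """
    step = float(axis[1] - axis[0]) if len(axis) > 1 else 1.0
    span = float(np.ptp(axis))
    h = max(1, int(round(_SEED_CURV_NM / step)))
    j0, j1 = max(i - h, 0), min(i + h, len(sm) - 1)
    d2 = (sm[j0] - 2.0 * sm[i] + sm[j1]) / ((j1 - j0) / 2.0 * step) ** 2
    height = sm[i] - sm.min()
    if d2 >= 0 or height <= 0:
        return span / 8.0
    return float(np.clip(np.sqrt(height / -d2), step, span / 4.0))


def _half_max_crossings(axis: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """(inner, outer) radius estimates from the half-maximum crossings."""
    step = float(axis[1] - axis[0]) if len(axis) > 1 else 1.0
    sm = _smoothed(values, step)
    base = sm.min()
    half = base + 0.5 * (sm.max() - base)
    above = sm >= half
    idx = np.flatnonzero(above)
    if len(idx) == 0:
        return 0.25 * axis.max(), 0.75 * axis.max()
    outer = max(abs(axis[idx[0]]), abs(axis[idx[-1]]))
    # inner radius: half-max crossing of the central dip, if any
    mid = len(axis) // 2
    center_val = sm[mid]
    if center_val < half:
        inside = np.flatnonzero(~above[: idx[-1]][idx[0]:])
        inner = abs(axis[idx[0] + inside[-1]]) if len(inside) else 0.3 * outer
    else:
        inner = 0.3 * outer
    inner = min(inner, 0.9 * outer)
    return float(inner), float(outer)


def _initial_params(profile: TransverseProfile, model: str) -> dict[str, float]:
    ax, val = profile.axis, profile.values
    base = float(val.min())
    amp = float(val.max() - base)
    span = float(np.ptp(ax))
    step = span / (len(ax) - 1) if len(ax) > 1 else 1.0
    if model == "gaussian":
        c = float(ax[int(np.argmax(_smoothed(val, step)))])
        return {"h": amp, "c": c, "w": span / 8.0, "b": base}
    if model in ("bigaussian", "trigaussian"):
        c1, c2, w1, w2 = _two_peaks(ax, val)
        p = {"h1": amp, "c1": c1, "w1": w1, "h2": amp, "c2": c2, "w2": w2,
             "b": base}
        if model == "trigaussian":
            p.update({"h3": 0.25 * amp, "c3": 0.5 * (c1 + c2),
                      "w3": 2.0 * max(w1, w2)})
        return p
    if model == "cylinder":
        r1, r2 = _half_max_crossings(ax, val)
        h = amp / max(np.sqrt(max(r2 ** 2 - r1 ** 2, 1e-9)), 1e-9)
        return {"h": h, "c": 0.0, "r1": r1, "r2": r2}
    if model == "multicylinder":
        _, outer = _half_max_crossings(ax, val)
        e_x = max(2.0 * outer / 42.5, 0.2)
        i = amp / max(outer, 1.0)
        return {"i1": 0.3 * i, "i2": i, "i3": 0.3 * i, "c": 0.0,
                "a": 2.0, "e_x": e_x, "b": base}
    raise ValueError(f"unknown model {model!r}")


_BOUNDS: dict[str, dict[str, tuple[float, float]]] = {
    "gaussian": {"h": (0, np.inf), "w": (1e-6, np.inf)},
    "bigaussian": {"h1": (0, np.inf), "h2": (0, np.inf),
                   "w1": (1e-6, np.inf), "w2": (1e-6, np.inf)},
    "trigaussian": {"h1": (0, np.inf), "h2": (0, np.inf), "h3": (0, np.inf),
                    "w1": (1e-6, np.inf), "w2": (1e-6, np.inf),
                    "w3": (1e-6, np.inf)},
    "cylinder": {"h": (0, np.inf), "r1": (0, np.inf), "r2": (1e-6, np.inf)},
    "multicylinder": {"i1": (0, np.inf), "i2": (0, np.inf), "i3": (0, np.inf),
                      "a": (1e-3, np.inf), "e_x": (0.05, np.inf)},
}


def _canonicalize(model: str, p: dict[str, float]) -> dict[str, float]:
    """Report multi-component fits with centers in ascending order."""
    if model == "bigaussian" and p["c1"] > p["c2"]:
        p = dict(p)
        p["h1"], p["c1"], p["w1"], p["h2"], p["c2"], p["w2"] = (
            p["h2"], p["c2"], p["w2"], p["h1"], p["c1"], p["w1"])
    elif model == "trigaussian":
        comps = sorted([(p["c1"], p["h1"], p["w1"]),
                        (p["c2"], p["h2"], p["w2"]),
                        (p["c3"], p["h3"], p["w3"])])
        p = dict(p)
        for k, (c, h, w) in enumerate(comps, start=1):
            p[f"c{k}"], p[f"h{k}"], p[f"w{k}"] = c, h, w
    return p


def _fit_p2p(model: str, p: Mapping[str, float],
             axis: np.ndarray) -> Optional[float]:
    """Peak-to-peak distance implied by a fitted model.

    Gaussian-sum models use the separation of the outermost fitted centers;
    cylinder models locate the two maxima of the fitted curve numerically.
    """
    if model == "gaussian":
        return None
    if model == "bigaussian":
        return abs(p["c2"] - p["c1"])
    if model == "trigaussian":
        cs = sorted([p["c1"], p["c2"], p["c3"]])
        return cs[2] - cs[0]
    # cylinder / multicylinder: numeric maxima of the fitted curve
    lo, hi = float(axis.min()), float(axis.max())
    xx = np.linspace(lo, hi, 4001)
    yy = eval_model(model, p, xx)
    c = p["c"]
    left = xx < c
    if left.sum() < 2 or (~left).sum() < 2:
        return None
    xl = xx[left][int(np.argmax(yy[left]))]
    xr = xx[~left][int(np.argmax(yy[~left]))]
    return float(xr - xl)


def fit_profile(profile: TransverseProfile, model: str = "bigaussian",
                init: Optional[Mapping[str, float]] = None,
                symmetric: bool = False) -> ProfileFit:
    """Nonlinear least-squares fit of a cross-section model to a profile.

    Initial parameters are estimated from the profile itself (the fits are
    sensitive to initialization, especially the cylinder models) unless
    ``init`` provides explicit values for some or all parameters.  Raises
    :class:`FitError` on non-convergence or degenerate collapse (vanishing
    width, or r1 → r2).

    ``symmetric=True`` (bi-Gaussian only) constrains the two components to
    mirror images (equal heights and widths, centers c0 ± d/2).  On an
    ideally symmetric cross-section this has the same optimum as the free
    fit, but on noisy profiles it suppresses a soft mode in which one lobe
    sharpens on a sidewall while the other broadens over the interior,
    biasing the distance low.
    """
    if symmetric:
        if model != "bigaussian":
            raise ValueError("symmetric fitting is defined for the bigaussian model")
        return _fit_bigaussian_symmetric(profile, init)
    names = MODELS.get(model)
    if names is None:
        raise ValueError(f"unknown model {model!r}")
    ax, val = profile.axis, profile.values
    if len(ax) < len(names) + 2:
        raise ValueError(
            f"profile has {len(ax)} points; need >= {len(names) + 2} for {model}")
    p0 = _initial_params(profile, model)
    if init:
        p0.update({k: float(v) for k, v in init.items()})
    bounds_map = dict(_BOUNDS[model])
    # keep centers on the sampled axis and widths/radii at the axis scale
    span = float(np.ptp(ax))
    step = span / (len(ax) - 1)
    for cname in ("c", "c1", "c2", "c3"):
        if cname in names:
            bounds_map[cname] = (float(ax.min()), float(ax.max()))
    for wname in ("w", "w1", "w2", "w3"):
        if wname in names:
            bounds_map[wname] = (step / 4.0, span)
    for rname in ("r1", "r2"):
        if rname in names:
            bounds_map[rname] = (0.0 if rname == "r1" else step / 4.0, span)
    lo = [bounds_map.get(n, (-np.inf, np.inf))[0] for n in names]
    hi = [bounds_map.get(n, (-np.inf, np.inf))[1] for n in names]
    x0 = np.array([np.clip(p0[n], lo[i], hi[i]) for i, n in enumerate(names)])

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = dict(zip(names, theta))
        if model == "cylinder" and p["r1"] >= p["r2"]:
            return np.full_like(val, 1e6)
        if model == "multicylinder":
            for r1, r2 in _multicyl_radii(p["a"], p["e_x"]):
                if r1 < 0 or r1 >= r2:
                    return np.full_like(val, 1e6)
        return eval_model(model, p, ax) - val

    res = optimize.least_squares(residuals, x0, bounds=(lo, hi),
                                 method="trf", max_nfev=10000,
                                 xtol=1e-11, ftol=1e-11, gtol=1e-11)
    # polish: restart once from the optimum; stays in the same basin but
    # tightens nearly-degenerate directions (e.g. multicylinder amplitudes)
    res = optimize.least_squares(residuals, res.x, bounds=(lo, hi),
                                 method="trf", max_nfev=10000,
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    rms = float(np.sqrt(np.mean(res.fun ** 2)))
    if not res.success and rms > 1e-6 * max(1.0, float(np.abs(val).max())):
        raise FitError(f"{model} fit did not converge (residual rms {rms:.3g})")
    p = _canonicalize(model, dict(zip(names, res.x)))
    scale = float(np.ptp(ax))
    for wname in ("w", "w1", "w2", "w3"):
        if wname in p and p[wname] < 1e-6 * scale:
            raise FitError(f"degenerate fit: {wname} collapsed to {p[wname]:.3g}")
    if model == "cylinder" and p["r2"] - p["r1"] < 1e-6 * scale:
        raise FitError("degenerate fit: r1 -> r2")
    return ProfileFit(model=model, params=p, residual_rms=rms,
                      peak_to_peak=_fit_p2p(model, p, ax), n_points=len(ax))


def _fit_bigaussian_symmetric(profile: TransverseProfile,
                              init: Optional[Mapping[str, float]] = None
                              ) -> ProfileFit:
    """Mirror-symmetric bi-Gaussian fit: parameters (h, c0, d, w, b)."""
    ax, val = profile.axis, profile.values
    if len(ax) < 7:
        raise ValueError("profile too short for a symmetric bi-Gaussian fit")
    p0full = _initial_params(profile, "bigaussian")
    if init:
        p0full.update({k: float(v) for k, v in init.items()})
    span = float(np.ptp(ax))
    step = span / (len(ax) - 1)
    h0 = 0.5 * (p0full["h1"] + p0full["h2"])
    c00 = 0.5 * (p0full["c1"] + p0full["c2"])
    d0 = max(p0full["c2"] - p0full["c1"], step)
    w0 = 0.5 * (p0full["w1"] + p0full["w2"])
    lo = [0.0, float(ax.min()), step / 4.0, step / 4.0, -np.inf]
    hi = [np.inf, float(ax.max()), span, span, np.inf]
    x0 = np.clip([h0, c00, d0, w0, p0full["b"]], lo, hi)

    def model_sym(theta):
        h, c0, d, w, b = theta
        return (_gauss(ax, h, c0 - d / 2.0, w)
                + _gauss(ax, h, c0 + d / 2.0, w) + b)

    res = optimize.least_squares(lambda t: model_sym(t) - val, x0,
                                 bounds=(lo, hi), method="trf",
                                 max_nfev=10000,
                                 xtol=1e-11, ftol=1e-11, gtol=1e-11)
    h, c0, d, w, b = res.x
    rms = float(np.sqrt(np.mean(res.fun ** 2)))
    if w < 1e-6 * span:
        raise FitError(f"degenerate fit: w collapsed to {w:.3g}")
    params = {"h1": h, "c1": c0 - d / 2.0, "w1": w,
              "h2": h, "c2": c0 + d / 2.0, "w2": w, "b": b}
    return ProfileFit(model="bigaussian", params=params, residual_rms=rms,
                      peak_to_peak=float(d), n_points=len(ax))


# ---------------------------------------------------------------------------
# profile extraction along traces
# ---------------------------------------------------------------------------

def _sample_lines(plane: np.ndarray, pixel_size: float,
                  points: np.ndarray, normals: np.ndarray,
                  offsets: np.ndarray) -> tuple[np.ndarray, int]:
    """Average bilinear line samples perpendicular to a trace on one plane.

    ``points`` are (x, y) nm positions, ``normals`` unit perpendiculars.
    Lines leaving the image are dropped entirely.  Returns (profile, n_kept).
    """
    nrows, ncols = plane.shape
    # sample positions in nm: point + offset * normal
    px = points[:, None, 0] + offsets[None, :] * normals[:, None, 0]
    py = points[:, None, 1] + offsets[None, :] * normals[:, None, 1]
    rows = py / pixel_size - 0.5
    cols = px / pixel_size - 0.5
    inside = ((rows >= 0) & (rows <= nrows - 1)
              & (cols >= 0) & (cols <= ncols - 1)).all(axis=1)
    if not inside.any():
        return np.zeros_like(offsets), 0
    sampled = ndimage.map_coordinates(
        plane.astype(float),
        [rows[inside].ravel(), cols[inside].ravel()],
        order=1, mode="nearest")
    lines = sampled.reshape(inside.sum(), len(offsets))
    return lines.mean(axis=0), int(inside.sum())


def extract_profiles(image: SRImage, trace, half_width: float = 300.0,
                     step: float = 10.0, trim: float = 0.0) -> TransverseProfile:
    """Average perpendicular line profiles along a trace into one profile.

    The trace spline is evaluated every ``step`` nm of arc length; at each
    point a line of length 2·``half_width`` perpendicular to the tangent is
    sampled by bilinear interpolation on a uniform nm grid (grid step equals
    the image pixel size).  For 3D stacks the maximum-intensity projection
    is used; :func:`xz_projection` keeps the planes separate.

    ``trim`` drops the first and last ``trim`` nm of the trace, where
    skeleton erosion and spline end effects distort the centerline.
    """
    if half_width <= 0 or step <= 0:
        raise ValueError("half_width and step must be > 0")
    plane = image.values.max(axis=0) if image.is_3d else image.values
    dx = image.pixel_size_xy
    n_off = max(3, int(round(half_width / dx)))
    offsets = np.linspace(-half_width, half_width, 2 * n_off + 1)
    points, tangents = trace.sample(step)
    if trim > 0 and len(points) > 2:
        arc = np.linspace(0.0, trace.length, len(points))
        keep = (arc >= trim) & (arc <= trace.length - trim)
        if keep.sum() < 2:
            raise ValueError("trim leaves no usable trace interior")
        points, tangents = points[keep], tangents[keep]
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    prof, n_kept = _sample_lines(plane, dx, points, normals, offsets)
    if n_kept == 0:
        raise ValueError("trace lies entirely outside the image")
    return TransverseProfile(axis=offsets, values=prof, n_lines=n_kept,
                             trace_id=getattr(trace, "trace_id", 0))


def xz_projection(stack: SRImage, trace, half_width: float = 300.0,
                  step: float = 10.0) -> SRImage:
    """Side-view (xz) projection of a 3D stack along a lateral trace.

    Row k of the output is the averaged perpendicular profile extracted from
    plane k along the same spline, so a hollow filament shows up as an
    annulus.  Columns are transverse nm offsets at the lateral pixel size.
    """
    if not stack.is_3d:
        raise ValueError("xz_projection requires a 3D stack")
    dx = stack.pixel_size_xy
    n_off = max(3, int(round(half_width / dx)))
    offsets = np.linspace(-half_width, half_width, 2 * n_off + 1)
    points, tangents = trace.sample(step)
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    rows = []
    for plane in stack.values:
        prof, n_kept = _sample_lines(plane, dx, points, normals, offsets)
        rows.append(prof)
    out = np.array(rows)
    return SRImage(out, pixel_size_xy=2 * half_width / (out.shape[1] - 1),
                   pixel_size_z=None if stack.pixel_size_z is None
                   else stack.pixel_size_z)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_segments(fits: Sequence[ProfileFit],
                       lengths: Sequence[float]) -> SegmentStatistics:
    """Unweighted mean ± sample sd of per-segment peak-to-peak distances.

    Each filament segment counts once regardless of its length, matching how
    segment statistics are reported alongside per-segment histograms; the
    overlaid normal curve of such a histogram uses exactly these moments.
    ``lengths`` are in nm and only enter the reported total length.
    """
    if len(fits) == 0:
        raise ValueError("no fits to aggregate")
    if len(fits) != len(lengths):
        raise ValueError("fits and lengths must have equal length")
    p2p = [f.peak_to_peak for f in fits]
    if any(v is None for v in p2p):
        raise ValueError("all fits must define a peak-to-peak distance")
    arr = np.asarray(p2p, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return SegmentStatistics(per_segment_p2p=[float(v) for v in arr],
                             mean=float(arr.mean()), sd=sd,
                             n_segments=len(arr),
                             total_length=float(np.sum(lengths)) / 1000.0)


def relative_label_density(fit: ProfileFit) -> float:
    """Relative labeling density: the summed fit amplitude(s) h.

    The fitted intensity scales linearly with image intensity, so ratios
    between images taken under identical rendering are label-density ratios.
    """
    p = fit.params
    if fit.model == "gaussian":
        return p["h"]
    if fit.model == "bigaussian":
        return p["h1"] + p["h2"]
    if fit.model == "trigaussian":
        return p["h1"] + p["h2"] + p["h3"]
    if fit.model == "cylinder":
        return p["h"]
    if fit.model == "multicylinder":
        return p["i1"] + p["i2"] + p["i3"]
    raise ValueError(f"unknown model {fit.model!r}")
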