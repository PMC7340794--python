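"""Ground-truth filament simulator for testing the analysis pipeline.

Generates smooth random curves in a field of view, decorates them with
localizations drawn from the cylindrical fluorophore-shell distribution of
a :class:`~exmprofiler.mt_model.LabelingGeometry` (scaled by the expansion
factor according to the pre/post labeling flags), adds localization noise
and uniform background, and renders everything to an image.  A fixture is
fully determined by its parameters and one integer seed, so every pipeline
stage can be tested against known ground truth without external data.

The emulated regime is immunolabeled microtubules in (expanded) dSTORM
images: localization densities of tens to hundreds per micrometer of
filament, a hollow label shell tens of nanometers across, and localization
precisions of a few nanometers on the image scale.  Blinking kinetics,
raw camera frames and drift are out of scope (they are upstream of the
rendered images this package analyzes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import interpolate
from scipy.spatial.distance import cdist

from .io_formats import LocalizationTable, SRImage, render_histogram
from .mt_model import LabelingGeometry

__all__ = ["Curve", "GroundTruth", "generate_curves",
           "sample_localizations", "make_fixture"]


@dataclass
class Curve:
    """A smooth planar parametric curve (cubic spline through control points)."""

    control_points: np.ndarray          # (m, 2) nm
    tck: tuple
    length: float                       # nm

    def sample(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """n points along the curve plus unit tangents."""
        u = np.linspace(0.0, 1.0, n)
        x, y = interpolate.splev(u, self.tck)
        dx, dy = interpolate.splev(u, self.tck, der=1)
        t = np.column_stack([dx, dy])
        norm = np.linalg.norm(t, axis=1)
        norm[norm == 0] = 1.0
        return np.column_stack([x, y]), t / norm[:, None]

    def point_at(self, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x, y = interpolate.splev(u, self.tck)
        dx, dy = interpolate.splev(u, self.tck, der=1)
        t = np.column_stack([dx, dy])
        norm = np.linalg.norm(t, axis=1)
        norm[norm == 0] = 1.0
        return np.column_stack([x, y]), t / norm[:, None]


@dataclass
class GroundTruth:
    """Complete description of a synthetic sample.

    ``density`` is localizations per µm of filament; ``background_density``
    per µm².  ``sigma_loc`` defaults to the geometry's localization
    precision.  The same seed always reproduces the same sample.
    """

    curves: list
    geometry: LabelingGeometry
    expansion: float = 1.0
    density: float = 150.0
    background_density: float = 0.5
    sigma_loc: Optional[float] = None
    seed: int = 0
    field_size: tuple[float, float] = (20000.0, 20000.0)
    three_d: bool = False

    @property
    def effective_sigma(self) -> float:
        return (self.geometry.sigma_loc if self.sigma_loc is None
                else self.sigma_loc)

    @property
    def total_length(self) -> float:
        return float(sum(c.length for c in self.curves))


def _make_curve(rng: np.random.Generator, field: tuple[float, float],
                curvature_scale: float, margin: float,
                base_angle: float) -> Curve:
    """One smooth curve spanning the field with bounded random curvature.

    Curves of one sample share a base orientation (small per-curve angular
    jitter) so several well-separated filaments fit into one field.
    """
    w, h = field
    ang = base_angle + rng.uniform(-0.12, 0.12)
    direction = np.array([np.cos(ang), np.sin(ang)])
    normal = np.array([-direction[1], direction[0]])
    max_offset = max(0.5 * min(w, h) - margin - 300.0, 0.05 * min(w, h))
    offset = rng.uniform(-max_offset, max_offset)
    center = np.array([0.5 * w, 0.5 * h]) + offset * normal
    # largest half-length that keeps both endpoints inside the margin box
    half = 0.5 * min(w, h) - margin
    for comp, lo, hi in ((0, margin, w - margin), (1, margin, h - margin)):
        d = direction[comp]
        if abs(d) > 1e-12:
            half = min(half, (hi - center[comp]) / abs(d),
                       (center[comp] - lo) / abs(d))
    if half < 500.0:
        raise ValueError("chord does not fit inside the field margins")
    m = 9
    s = np.linspace(-half, half, m)
    spacing = s[1] - s[0]
    # lateral jitter bounded so curvature stays ~ curvature_scale
    amp = curvature_scale * spacing ** 2
    lateral = rng.uniform(-amp, amp, size=m) if amp > 0 else np.zeros(m)
    pts = (center[None, :] + s[:, None] * direction[None, :]
           + lateral[:, None] * normal[None, :])
    tck, _ = interpolate.splprep([pts[:, 0], pts[:, 1]], k=3, s=0)
    uu = np.linspace(0.0, 1.0, 400)
    xx, yy = interpolate.splev(uu, tck)
    length = float(np.hypot(np.diff(xx), np.diff(yy)).sum())
    return Curve(control_points=pts, tck=tck, length=length)


def generate_curves(n: int, field: tuple[float, float] = (20000.0, 20000.0),
                    curvature_scale: float = 5e-5, min_separation: float = 1000.0,
                    seed: int = 0, margin: float = 1500.0,
                    max_retries: int = 200) -> list[Curve]:
    """Generate ``n`` smooth random curves with pairwise separation.

    Curves are cubic splines through jittered control points along random
    chords of the field; ``curvature_scale`` (1/nm) bounds how wiggly they
    are (0 gives straight segments).  Curves closer than ``min_separation``
    to an accepted curve are rejected and redrawn; exceeding
    ``max_retries`` raises.
    """
    if n < 1:
        raise ValueError("need n >= 1 curves")
    rng = np.random.default_rng(seed)
    base_angle = rng.uniform(0.0, np.pi)
    curves: list[Curve] = []
    samples: list[np.ndarray] = []
    tries = 0
    while len(curves) < n:
        if tries > max_retries:
            raise RuntimeError(
                f"could not place {n} curves with separation "
                f">= {min_separation} nm in this field")
        try:
            c = _make_curve(rng, field, curvature_scale, margin, base_angle)
        except ValueError:
            tries += 1
            continue
        pts, _ = c.sample(200)
        if all(cdist(pts, other).min() >= min_separation for other in samples):
            curves.append(c)
            samples.append(pts)
        tries += 1
    return curves


def _sample_shell_radii(rng: np.random.Generator, geometry: LabelingGeometry,
                        expansion: float, n: int) -> np.ndarray:
    """Radial fluorophore offsets from the mixture shell density.

    Matches the forward model exactly: a fraction ``ring_weight`` of labels
    in the thin outer ring, the rest volume-uniform over the shell; both
    components volume-uniform in a cylindrical annulus, i.e. pdf(r) ∝ r.
    """
    r_lo, r_hi = geometry.shell_radii(expansion)
    l = expansion if geometry.expands_linker else 1.0
    ring_lo = max(r_hi - geometry.ring_thickness * l, 0.0)
    in_ring = rng.random(n) < geometry.ring_weight
    lo = np.where(in_ring, ring_lo, r_lo)
    u = rng.random(n)
    return np.sqrt(lo ** 2 + u * (r_hi ** 2 - lo ** 2))


def sample_localizations(truth: GroundTruth) -> LocalizationTable:
    """Draw a localization table from the ground truth.

    Filament localizations: Poisson(density x total length) in number, at
    uniform arc positions, with radial offsets from the fluorophore shell
    at a uniform azimuth around the filament axis, plus isotropic Gaussian
    localization noise.  Background: Poisson-uniform over the field.  The
    lateral image coordinates keep only the in-plane component of the
    azimuthal offset; the axial component is kept as z for 3D truths.
    """
    rng = np.random.default_rng(truth.seed)
    sig = truth.effective_sigma
    xs, ys, zs = [], [], []
    n_total = rng.poisson(truth.density * truth.total_length / 1000.0)
    lengths = np.array([c.length for c in truth.curves])
    if n_total > 0 and lengths.sum() > 0:
        which = rng.choice(len(truth.curves), size=n_total,
                           p=lengths / lengths.sum())
        radii = _sample_shell_radii(rng, truth.geometry, truth.expansion,
                                    n_total)
        phi = rng.uniform(0.0, 2.0 * np.pi, n_total)
        for i, c in enumerate(truth.curves):
            sel = which == i
            if not sel.any():
                continue
            u = rng.uniform(0.0, 1.0, int(sel.sum()))
            pts, tang = c.point_at(u)
            normal = np.column_stack([-tang[:, 1], tang[:, 0]])
            r = radii[sel]
            inplane = r * np.cos(phi[sel])
            axial = r * np.sin(phi[sel])
            pos = pts + inplane[:, None] * normal
            xs.append(pos[:, 0])
            ys.append(pos[:, 1])
            zs.append(axial)
    w, h = truth.field_size
    n_bg = rng.poisson(truth.background_density * (w / 1000.0) * (h / 1000.0))
    if n_bg > 0:
        xs.append(rng.uniform(0.0, w, n_bg))
        ys.append(rng.uniform(0.0, h, n_bg))
        zs.append(rng.uniform(-200.0, 200.0, n_bg))
    if not xs:
        return LocalizationTable(frame=np.empty(0, dtype=int),
                                 x=np.empty(0), y=np.empty(0),
                                 z=np.empty(0) if truth.three_d else None)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    z = np.concatenate(zs)
    n = len(x)
    x = x + rng.normal(0.0, sig, n) if sig > 0 else x
    y = y + rng.normal(0.0, sig, n) if sig > 0 else y
    if truth.three_d and sig > 0:
        z = z + rng.normal(0.0, sig, n)
    return LocalizationTable(frame=np.arange(n, dtype=int), x=x, y=y,
                             z=z if truth.three_d else None)


def make_fixture(truth: GroundTruth, pixel_size: float = 4.0
                 ) -> tuple[SRImage, LocalizationTable, dict]:
    """Render a complete test fixture: image, table and truth manifest.

    The image covers exactly the stated field of view so that ground-truth
    curve coordinates and pixel coordinates share one frame.  The manifest
    records every generator parameter (JSON-serializable) for assertions.
    """
    table = sample_localizations(truth)
    if len(table) == 0:
        raise ValueError("nothing to render: ground truth produced no localizations")
    w, h = truth.field_size
    image = render_histogram(table, pixel_size=pixel_size, mode="counts",
                             bounds=(0.0, 0.0, w, h))
    manifest = {
        "seed": truth.seed,
        "expansion": truth.expansion,
        "density_per_um": truth.density,
        "background_per_um2": truth.background_density,
        "sigma_loc": truth.effective_sigma,
        "field_size_nm": list(truth.field_size),
        "pixel_size_nm": pixel_size,
        "three_d": truth.three_d,
        "n_curves": len(truth.curves),
        "curve_lengths_nm": [c.length for c in truth.curves],
        "curve_control_points": [c.control_points.tolist()
                                 for c in truth.curves],
        "geometry": {k: v for k, v in asdict(truth.geometry).items()},
        "n_localizations": len(table),
    }
    json.dumps(manifest)  # guarantee serializability
    return image, table, manifest
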