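"""Cylindrical-distribution forward model of immunolabeled microtubules.

The microtubule is a hollow tube of outer radius 12.5 nm.  Affinity labels
put the fluorophores into a cylindrically symmetric shell at some radial
distance beyond the tube surface: a primary + secondary IgG stack carries
the dye layer about 8.75 nm out (half of the 17.5 nm linkage error, i.e. a
fluorophore-layer diameter of 42.5 nm on a 25 nm tube), and DNA-modified
secondary antibodies add the oligonucleotide length on top.  Projecting
that shell onto the transverse axis yields the characteristic double-peaked
cross-section; convolving with the localization precision and fitting a
bi-Gaussian reproduces the peak-to-peak readout used on measured images.

Expansion enters as a linear scale factor ``e``:

* pre-labeling  — labels are in place before gelation, so both the
  structure radius and the label shell scale with ``e`` (the linkage error
  is magnified);
* post-labeling — labels bind after expansion, so only the structure
  scales and the label shell keeps its physical size.

Because the localization precision is a property of the imaging, it is held
fixed on the image scale rather than scaled with ``e``; this makes the
predicted peak-to-peak distance slightly sub-linear in ``e`` at small
expansion, exactly the regime where measured distances are inverted into
molecular expansion factors.

Geometry presets (IgG pre/post, 42-base DNA linkers in extended and coiled
conformation) ship in ``data/geometries.yaml``; all lengths are nm.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, Optional

import numpy as np
import yaml
from scipy import ndimage, optimize

from .profile_analysis import TransverseProfile, fit_profile

__all__ = [
    "LabelingGeometry", "PredictedProfile",
    "project_shell", "apply_precision", "predict_profile", "predict_p2p",
    "superpose", "infer_expansion_factor", "effective_linkage_error",
    "dna_linker_length", "expanded_diameter", "broadened_diameter",
    "load_geometry", "available_presets",
    "MICROTUBULE_RADIUS", "IGG_LINKAGE_ERROR", "DNA_RISE_PER_BASE",
]

#: Microtubule outer radius (25 nm diameter tube).
MICROTUBULE_RADIUS = 12.5
#: Linkage error of a primary + secondary IgG antibody stack.
IGG_LINKAGE_ERROR = 17.5
#: Helical rise per base of B-form DNA.
DNA_RISE_PER_BASE = 0.34

#: Axis resolution of stand-alone shell projections (nm).
_GRID_STEP = 0.1

#: Points per predicted-profile axis.  The count is fixed (rather than the
#: step) so the sampled profile — and hence the fitted peak-to-peak
#: distance — varies smoothly with the expansion factor; a step-quantized
#: window would make the inversion's objective micro-discontinuous.
_GRID_POINTS = 4001


@dataclass(frozen=True)
class LabelingGeometry:
    """Radial description of a fluorophore shell around a filament.

    ``label_inner``/``label_outer`` bound the fluorophore shell as radial
    offsets beyond the structure surface.  The dye density is a
    two-component mixture: a fraction ``1 − ring_weight`` is uniform over
    the shell volume (conjugation sites along the whole affinity stack) and
    a fraction ``ring_weight`` is concentrated in a thin ring of
    ``ring_thickness`` at the outer shell edge (the terminal dye layer).
    ``expands_linker`` distinguishes pre-labeling (the shell scales with
    expansion) from post-labeling (it does not).  ``sigma_loc`` is the
    localization-precision blur in image-scale nm.
    """

    name: str = "custom"
    structure_radius: float = MICROTUBULE_RADIUS
    label_inner: float = 0.0
    label_outer: float = IGG_LINKAGE_ERROR
    ring_weight: float = 0.0
    ring_thickness: float = 1.0
    expands_structure: bool = True
    expands_linker: bool = True
    sigma_loc: float = 5.0
    linker_conformation: str = "extended"
    dna_bases: int = 0

    def __post_init__(self) -> None:
        if self.structure_radius < 0 or self.label_inner < 0:
            raise ValueError("radial lengths must be >= 0")
        if self.label_outer <= self.label_inner:
            raise ValueError("label_outer must exceed label_inner")
        if not 0.0 <= self.ring_weight <= 1.0:
            raise ValueError("ring_weight must be in [0, 1]")
        if self.ring_thickness <= 0:
            raise ValueError("ring_thickness must be > 0")
        if self.sigma_loc < 0:
            raise ValueError("sigma_loc must be >= 0")

    @property
    def linker_extent(self) -> float:
        """Radial extent of the label shell beyond the structure surface."""
        return self.label_outer

    def shell_radii(self, expansion: float) -> tuple[float, float]:
        """Inner and outer fluorophore-shell radii at a given expansion."""
        s = expansion if self.expands_structure else 1.0
        l = expansion if self.expands_linker else 1.0
        return (self.structure_radius * s + self.label_inner * l,
                self.structure_radius * s + self.label_outer * l)


@dataclass
class PredictedProfile:
    """Predicted transverse intensity profile, normalized to unit area."""

    axis: np.ndarray
    values: np.ndarray
    geometry: Optional[LabelingGeometry] = None
    expansion: float = 1.0

    def as_transverse(self) -> TransverseProfile:
        return TransverseProfile(axis=self.axis, values=self.values)


# ---------------------------------------------------------------------------
# projection and blur
# ---------------------------------------------------------------------------

def project_shell(r_in: float, r_out: float,
                  density: Callable[[np.ndarray], np.ndarray] | None = None,
                  axis: np.ndarray | None = None) -> np.ndarray:
    """Project a cylindrically symmetric label density onto one axis.

    ``P(x) = ∫ ρ(√(x² + u²)) du`` over the line of sight; for uniform
    density this is the annulus projection √(r2²−x²) − √(r1²−x²) (up to
    normalization).  Output is normalized to unit area over ``axis``.
    """
    if not 0 <= r_in < r_out:
        raise ValueError("require 0 <= r_in < r_out")
    if axis is None:
        axis = np.arange(-r_out - 1.0, r_out + 1.0 + _GRID_STEP, _GRID_STEP)
    ax = np.abs(np.asarray(axis, dtype=float))
    if density is None:
        vals = np.zeros_like(ax)
        wall = ax < r_out
        vals[wall] = np.sqrt(r_out ** 2 - ax[wall] ** 2)
        bore = ax < r_in
        vals[bore] -= np.sqrt(r_in ** 2 - ax[bore] ** 2)
    else:
        # line-of-sight quadrature, singularity-free in u
        nodes, weights = np.polynomial.legendre.leggauss(200)
        vals = np.zeros_like(ax)
        visible = ax < r_out
        umax = np.sqrt(r_out ** 2 - ax[visible] ** 2)
        u = 0.5 * umax[:, None] * (nodes[None, :] + 1.0)
        r = np.sqrt(ax[visible, None] ** 2 + u ** 2)
        vals[visible] = 0.5 * umax * np.sum(weights[None, :] * density(r),
                                            axis=1)
    area = np.trapezoid(vals, axis)
    if area <= 0:
        raise ValueError("projected profile has zero area")
    return vals / area


def apply_precision(axis: np.ndarray, values: np.ndarray,
                    sigma_loc: float) -> np.ndarray:
    """Convolve a profile with the localization-precision Gaussian.

    Area is conserved; ``sigma_loc = 0`` is the identity.  The axis must be
    uniform.
    """
    if sigma_loc < 0:
        raise ValueError("sigma_loc must be >= 0")
    if sigma_loc == 0:
        return np.asarray(values, dtype=float)
    step = axis[1] - axis[0]
    return ndimage.gaussian_filter1d(np.asarray(values, dtype=float),
                                     sigma_loc / step, mode="constant",
                                     truncate=8.0)


def profile_half_width(geometry: LabelingGeometry,
                       expansion: float = 1.0) -> float:
    """Transverse window half-width matched to a labeling geometry (nm).

    The profile spans the fluorophore shell plus the blur tails plus a
    20 nm margin.  The window is part of the peak-to-peak readout: a
    bi-Gaussian fitted over a window much wider than the structure trades
    the sidewall peaks against the empty tails and reports systematically
    smaller distances, so measured profiles should be fitted over the same
    window the forward model uses.
    """
    _, r_hi = geometry.shell_radii(expansion)
    return r_hi + 8.0 * geometry.sigma_loc + 20.0


def predict_profile(geometry: LabelingGeometry,
                    expansion: float = 1.0) -> PredictedProfile:
    """Predicted transverse profile of a labeled filament at a given expansion."""
    if expansion < 1.0:
        raise ValueError("expansion must be >= 1")
    r_lo, r_hi = geometry.shell_radii(expansion)
    span = profile_half_width(geometry, expansion)
    axis = np.linspace(-span, span, _GRID_POINTS)
    q = geometry.ring_weight
    l = expansion if geometry.expands_linker else 1.0
    vals = np.zeros_like(axis)
    if q < 1.0:
        vals += (1.0 - q) * project_shell(r_lo, r_hi, axis=axis)
    if q > 0.0:
        ring_lo = max(r_hi - geometry.ring_thickness * l, 0.0)
        vals += q * project_shell(ring_lo, r_hi, axis=axis)
    vals = apply_precision(axis, vals, geometry.sigma_loc)
    vals /= np.trapezoid(vals, axis)
    return PredictedProfile(axis=axis, values=vals, geometry=geometry,
                            expansion=expansion)


def predict_p2p(geometry: LabelingGeometry, expansion: float = 1.0) -> float:
    """Peak-to-peak sidewall distance of the predicted profile (nm).

    Obtained exactly as on measured images: a bi-Gaussian fit to the
    profile, peak-to-peak = |c2 − c1|.  Raises when the predicted profile
    has no central dip (unresolvable sidewalls).
    """
    prof = predict_profile(geometry, expansion)
    mid = len(prof.axis) // 2
    peak = prof.values.max()
    if prof.values[mid] >= peak * (1.0 - 1e-6):
        raise ValueError("no resolvable sidewalls: predicted profile is unimodal")
    fit = fit_profile(prof.as_transverse(), "bigaussian")
    return float(fit.peak_to_peak)


def superpose(pre_profile: PredictedProfile, post_profile: PredictedProfile,
              pre_to_post_ratio: float) -> PredictedProfile:
    """Weighted mixture ``ratio·pre + post``, renormalized to unit area.

    Models a sample labeled both before and after expansion, where the
    pre-expansion signal is diluted (volume dilution plus fluorophore loss)
    relative to the post-expansion signal.
    """
    if pre_to_post_ratio < 0:
        raise ValueError("pre_to_post_ratio must be >= 0")
    if (len(pre_profile.axis) != len(post_profile.axis)
            or not np.allclose(pre_profile.axis, post_profile.axis)):
        raise ValueError("profiles must share an axis; interpolate first")
    vals = pre_to_post_ratio * pre_profile.values + post_profile.values
    vals /= np.trapezoid(vals, pre_profile.axis)
    return PredictedProfile(axis=pre_profile.axis.copy(), values=vals,
                            geometry=post_profile.geometry,
                            expansion=post_profile.expansion)


def align_profiles(a: PredictedProfile,
                   b: PredictedProfile) -> tuple[PredictedProfile, PredictedProfile]:
    """Resample two predicted profiles onto their common (wider) axis."""
    axis = a.axis if a.axis[-1] >= b.axis[-1] else b.axis
    out = []
    for p in (a, b):
        vals = np.interp(axis, p.axis, p.values, left=0.0, right=0.0)
        vals /= np.trapezoid(vals, axis)
        out.append(PredictedProfile(axis=axis.copy(), values=vals,
                                    geometry=p.geometry, expansion=p.expansion))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# expansion-factor inversion and linkage-error arithmetic
# ---------------------------------------------------------------------------

def infer_expansion_factor(measured_p2p: float, geometry: LabelingGeometry,
                           bracket: tuple[float, float] = (1.0, 10.0),
                           tol: float = 1e-9) -> float:
    """Invert a measured peak-to-peak distance into a molecular expansion factor.

    Solves ``predict_p2p(geometry, e) = measured_p2p`` by bracketed root
    finding; valid because the predicted distance increases strictly with
    ``e`` for all shipped geometries.  Round the result to one decimal for
    reporting.
    """
    lo, hi = bracket
    p_lo = predict_p2p(geometry, lo)
    if measured_p2p < p_lo:
        raise ValueError(
            f"sub-unity expansion: measured {measured_p2p:.1f} nm is below the "
            f"unexpanded prediction {p_lo:.1f} nm")
    p_hi = predict_p2p(geometry, hi)
    if measured_p2p > p_hi:
        raise ValueError(
            f"measured {measured_p2p:.1f} nm exceeds the prediction at "
            f"{hi:.0f}x ({p_hi:.1f} nm); widen the bracket")
    return float(optimize.brentq(
        lambda e: predict_p2p(geometry, e) - measured_p2p, lo, hi, xtol=tol))


def effective_linkage_error(label_error: float, expansion: float,
                            mode: str = "post") -> float:
    """Linkage error after expansion.

    ``post`` mode: labels bind after expansion, so on the biological scale
    the error shrinks to ``label_error / expansion``.  ``pre`` mode: labels
    expand with the gel, so on the expanded/image scale the error grows to
    ``label_error × expansion``.
    """
    if expansion < 1:
        raise ValueError("expansion must be >= 1")
    if label_error < 0:
        raise ValueError("label_error must be >= 0")
    if mode == "post":
        return label_error / expansion
    if mode == "pre":
        return label_error * expansion
    raise ValueError(f"mode must be 'pre' or 'post', got {mode!r}")


def dna_linker_length(bases: int, conformation: str = "extended",
                      persistence_length: float = 5.0) -> float:
    """Effective radial extent of a DNA linker of ``bases`` bases (nm).

    ``extended`` assumes B-DNA rise (0.34 nm/base).  ``coiled`` models a
    flexible single strand as a worm-like chain and returns the root mean
    square end-to-end distance ``√(2·lp·L − 2·lp²·(1 − e^(−L/lp)))``, which
    is always below the contour length.
    """
    if bases < 0:
        raise ValueError("bases must be >= 0")
    L = bases * DNA_RISE_PER_BASE
    if conformation == "extended" or L == 0:
        return L
    if conformation == "coiled":
        lp = persistence_length
        return float(np.sqrt(2 * lp * L - 2 * lp ** 2 * (1 - np.exp(-L / lp))))
    raise ValueError(f"conformation must be 'extended' or 'coiled', got {conformation!r}")


def expanded_diameter(core_diameter: float, expansion: float) -> float:
    """Diameter of the bare structure after expansion (simple product)."""
    if expansion < 1:
        raise ValueError("expansion must be >= 1")
    return core_diameter * expansion


def broadened_diameter(core_diameter: float, expansion: float,
                       label_error: float = IGG_LINKAGE_ERROR) -> float:
    """Apparent diameter of a pre-labeled structure after expansion.

    The expanded core plus the (co-expanded) linkage error on both sides:
    ``core·e + 2·label_error·e``.
    """
    return (expanded_diameter(core_diameter, expansion)
            + 2.0 * effective_linkage_error(label_error, expansion, "pre"))


# ---------------------------------------------------------------------------
# geometry catalogue
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=1)
def _catalogue() -> dict:
    text = resources.files("exmprofiler").joinpath("data/geometries.yaml").read_text()
    return yaml.safe_load(text)


def available_presets() -> list[str]:
    return sorted(_catalogue()["geometries"].keys())


def load_geometry(preset: str, **overrides) -> LabelingGeometry:
    """Load a named geometry preset from the catalogue, with overrides."""
    cat = _catalogue()["geometries"]
    if preset not in cat:
        raise KeyError(
            f"unknown geometry preset {preset!r}; available: "
            f"{', '.join(sorted(cat))}")
    params = dict(cat[preset])
    params.pop("description", None)
    params.update(overrides)
    return LabelingGeometry(name=preset, **params)


def predict_mixture_profile(mixture: str, expansion: float) -> PredictedProfile:
    """Predicted profile of a catalogued pre/post labeling mixture."""
    cat = _catalogue().get("mixtures", {})
    if mixture not in cat:
        raise KeyError(
            f"unknown mixture preset {mixture!r}; available: "
            f"{', '.join(sorted(cat))}")
    entry = cat[mixture]
    pre = predict_profile(load_geometry(entry["pre"]), expansion)
    post = predict_profile(load_geometry(entry["post"]), expansion)
    pre, post = align_profiles(pre, post)
    return superpose(pre, post, float(entry["ratio"]))


def predict_mixture_p2p(mixture: str, expansion: float) -> float:
    """Bi-Gaussian peak-to-peak distance of a catalogued labeling mixture."""
    prof = predict_mixture_profile(mixture, expansion)
    fit = fit_profile(prof.as_transverse(), "bigaussian")
    return float(fit.peak_to_peak)
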