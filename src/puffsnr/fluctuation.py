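"""Generative noise model for per-pixel fluorescence of single-wavelength Ca2+ dyes.

The fluorescence collected at one pixel of a photon-counting confocal linescan is
modelled as the outcome of a four-stage stochastic chain:

1. the number of dye molecules contributing to the pixel, ``N ~ Poisson(<N>)``;
2. the number of those molecules that are Ca2+-bound, ``B | N ~ Binomial(N, lam)``,
   where ``lam`` is the probability that a dye molecule is Ca2+-bound (the
   *occupancy*);
3. the detected photon count, Poisson with mean ``eps_b*B + eps_f*(N - B)`` where
   ``eps_b`` and ``eps_f`` are the molecular brightnesses (detected photons per
   molecule per pixel dwell) of the bound and free forms of the dye;
4. the detector, which multiplies the photon count by a gain ``A`` with no offset.

The closed-form pixel moments that follow from this chain are

    <F>      = A <N> (eps_b lam + eps_f (1 - lam))
    sigma_F2 = A^2 <N> [ (eps_b lam + eps_f (1 - lam))
                         + (eps_b^2 lam + eps_f^2 (1 - lam)) ]

i.e. a photon shot-noise term plus a molecule-number / occupancy term.  Three
re-parameterisations of these moments describe the variance-vs-mean curves of the
stationary calibration experiments:

* :func:`type1_slope` -- molecule number varies across points, brightness and
  occupancy fixed: the curve is a line through the origin.
* :func:`type2_coefficients` -- brightness varies (laser power), molecule number
  and occupancy fixed: the curve is a quadratic through the origin.
* :func:`type3_line` -- occupancy varies (added Ca2+): the curve is a line with a
  non-positive intercept.

Each of these is an exact algebraic rearrangement of the moment formulas; the test
suite verifies the identities to 1e-12 relative.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import DegenerateInputError, ParameterError

__all__ = [
    "FluctuationParams",
    "mean_fluorescence",
    "variance_fluorescence",
    "sample_pixel",
    "sample_pixels",
    "type1_slope",
    "type2_coefficients",
    "type3_line",
    "occupancy_from_type3",
]

#: serialization keys for a flat key-value config
_FIELD_KEYS = ("gain", "eps_bound", "eps_free", "occupancy", "mean_molecules")


@dataclass(frozen=True)
class FluctuationParams:
    """The five parameters of the fluorescence fluctuation model.

    Parameters
    ----------
    gain
        Detector amplification factor ``A`` (dimensionless, > 0).
    eps_bound
        Molecular brightness ``eps_b`` of the Ca2+-bound dye: detected photons
        per bound molecule per pixel dwell time (> 0).
    eps_free
        Molecular brightness ``eps_f`` of the Ca2+-free dye (>= 0, <= eps_bound).
    occupancy
        Probability ``lam`` in [0, 1] that a dye molecule is Ca2+-bound.
    mean_molecules
        Mean number ``<N>`` of dye molecules contributing to one pixel (> 0).
    """

    gain: float
    eps_bound: float
    eps_free: float
    occupancy: float
    mean_molecules: float

    def __post_init__(self) -> None:
        vals = (self.gain, self.eps_bound, self.eps_free,
                self.occupancy, self.mean_molecules)
        if not all(math.isfinite(v) for v in vals):
            raise ParameterError(f"non-finite fluctuation parameter in {vals}")
        if self.gain <= 0:
            raise ParameterError(f"gain must be > 0, got {self.gain}")
        if self.eps_bound <= 0:
            raise ParameterError(f"eps_bound must be > 0, got {self.eps_bound}")
        if not 0 <= self.eps_free <= self.eps_bound:
            raise ParameterError(
                f"eps_free must lie in [0, eps_bound], got {self.eps_free}")
        if not 0 <= self.occupancy <= 1:
            raise ParameterError(f"occupancy must be in [0, 1], got {self.occupancy}")
        if self.mean_molecules <= 0:
            raise ParameterError(
                f"mean_molecules must be > 0, got {self.mean_molecules}")

    @property
    def ratio(self) -> float:
        """Brightness ratio r = eps_free / eps_bound, fixed per dye, in [0, 1]."""
        return self.eps_free / self.eps_bound

    def with_occupancy(self, occupancy: float) -> "FluctuationParams":
        """Same parameters at a different bound fraction."""
        return replace(self, occupancy=occupancy)

    def scaled_intensity(self, rel_intensity: float) -> "FluctuationParams":
        """Both brightnesses scaled by a relative laser intensity I/I0 (> 0)."""
        if not rel_intensity > 0:
            raise ParameterError(f"relative intensity must be > 0, got {rel_intensity}")
        return replace(self, eps_bound=self.eps_bound * rel_intensity,
                       eps_free=self.eps_free * rel_intensity)

    # -- flat key-value serialization ------------------------------------
    def to_dict(self) -> dict:
        return {"gain": self.gain, "eps_bound": self.eps_bound,
                "eps_free": self.eps_free, "occupancy": self.occupancy,
                "mean_molecules": self.mean_molecules}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "FluctuationParams":
        missing = [k for k in _FIELD_KEYS if k not in d]
        if missing:
            raise ParameterError(f"missing fluctuation parameter keys: {missing}")
        return cls(**{k: float(d[k]) for k in _FIELD_KEYS})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml
            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_file(cls, path: str | Path) -> "FluctuationParams":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml
            return cls.from_dict(yaml.safe_load(path.read_text()))
        return cls.from_dict(json.loads(path.read_text()))


def _moments(p: FluctuationParams) -> tuple[float, float]:
    lam = p.occupancy
    mu = p.eps_bound * lam + p.eps_free * (1.0 - lam)
    m2 = p.eps_bound ** 2 * lam + p.eps_free ** 2 * (1.0 - lam)
    return mu, m2


def mean_fluorescence(params: FluctuationParams) -> float:
    """Expected pixel fluorescence <F> = A <N> (eps_b lam + eps_f (1-lam))."""
    mu, _ = _moments(params)
    return params.gain * params.mean_molecules * mu


def variance_fluorescence(params: FluctuationParams) -> float:
    """Exact pixel fluorescence variance of the generative chain.

    sigma_F^2 = A^2 <N> [(eps_b lam + eps_f (1-lam)) + (eps_b^2 lam + eps_f^2 (1-lam))]

    The first bracket term is photon shot noise (always >= A <F> after scaling by
    the gain); the second is the contribution of molecule-number and occupancy
    fluctuations.
    """
    mu, m2 = _moments(params)
    return params.gain ** 2 * params.mean_molecules * (mu + m2)


def sample_pixels(params: FluctuationParams, size: int | tuple,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw independent pixel fluorescence values from the generative chain.

    Each draw realises N ~ Poisson(<N>), B ~ Binomial(N, lam), a photon count
    P ~ Poisson(eps_b B + eps_f (N - B)) and reports F = A * P.  The ensemble
    mean and variance converge to :func:`mean_fluorescence` and
    :func:`variance_fluorescence`.
    """
    n = rng.poisson(params.mean_molecules, size=size)
    b = rng.binomial(n, params.occupancy)
    photon_mean = params.eps_bound * b + params.eps_free * (n - b)
    photons = np.asarray(rng.poisson(photon_mean), dtype=np.float64)
    return params.gain * photons


def sample_pixel(params: FluctuationParams, rng: np.random.Generator) -> float:
    """Single draw of the pixel fluorescence (see :func:`sample_pixels`)."""
    return float(sample_pixels(params, size=(), rng=rng))


def sample_pixels_map(occupancy_map: np.ndarray, params: FluctuationParams,
                      rng: np.random.Generator) -> np.ndarray:
    """Vectorised sampling with a per-pixel occupancy array (used for images)."""
    lam = np.asarray(occupancy_map, dtype=np.float64)
    if np.any(lam < 0) or np.any(lam > 1) or not np.all(np.isfinite(lam)):
        raise ParameterError("occupancy map must be finite and within [0, 1]")
    n = rng.poisson(params.mean_molecules, size=lam.shape)
    b = rng.binomial(n, lam)
    photon_mean = params.eps_bound * b + params.eps_free * (n - b)
    return params.gain * rng.poisson(photon_mean).astype(np.float64)


def type1_slope(gain: float, eps_bound: float, ratio: float,
                occupancy: float) -> float:
    """Slope of the variance-vs-mean line when only <N> varies across points.

    sigma_F^2 = slope * <F> with

        slope = A * [1 + eps_b (lam + r^2 (1-lam)) / (lam + r (1-lam))]

    The slope is >= A and tends to A as eps_b -> 0, which is the regime in which
    the Type I fit directly estimates the detector gain.
    """
    denom = occupancy + ratio * (1.0 - occupancy)
    if denom <= 0:
        raise DegenerateInputError(
            "occupancy and brightness ratio cannot both be zero")
    num = occupancy + ratio ** 2 * (1.0 - occupancy)
    return gain * (1.0 + eps_bound * num / denom)


def type2_coefficients(gain: float, mean_molecules: float, occupancy: float,
                       ratio: float) -> tuple[float, float]:
    """Coefficients of sigma_F^2 = a1 <F> + a2 <F>^2 when brightness varies.

    With the laser power (hence eps_b, at fixed r) varying across points and
    A, <N>, lam fixed:

        a1 = A
        a2 = (lam + r^2 (1-lam)) / (<N> (lam + r (1-lam))^2)

    The fluorescence ``<F>* = a1/a2`` is the level above which the quadratic term
    dominates; staying below it makes the curve look purely linear (the signature
    of an experimental setting in which molecule-number fluctuations are invisible).
    """
    denom = occupancy + ratio * (1.0 - occupancy)
    if denom <= 0:
        raise DegenerateInputError(
            "occupancy and brightness ratio cannot both be zero")
    a2 = (occupancy + ratio ** 2 * (1.0 - occupancy)) / (mean_molecules * denom ** 2)
    return gain, a2


def type3_line(gain: float, eps_bound: float, eps_free: float,
               mean_molecules: float) -> tuple[float, float]:
    """(slope, intercept) of the variance-vs-mean line when occupancy varies.

    sigma_F^2 = A (1 + eps_b + eps_f) <F> - A^2 <N> eps_b eps_f

    The intercept is <= 0 and vanishes when eps_f -> 0, in which case the slope
    reduces to A (1 + eps_b) -- the relation used to extract eps_b from Type III
    experiments once A is known.
    """
    slope = gain * (1.0 + eps_bound + eps_free)
    intercept = -(gain ** 2) * mean_molecules * eps_bound * eps_free
    return slope, intercept


def occupancy_from_type3(mean_f: float, var_f: float, gain: float,
                         eps_bound: float, eps_free: float) -> float:
    """Invert the Type III relation for the occupancy of a single data point.

    For a point with moments (<F>, sigma_F^2) and known A, eps_b, eps_f the
    occupancy-varying line gives

        y   = A (1 + eps_b + eps_f) <F> - sigma_F^2     (= A^2 <N> eps_b eps_f)
        lam = (A eps_f <F> / y - r) / (1 - r)

    Raises :class:`DegenerateInputError` when y <= 0 (noise pushed the point
    outside the model manifold) or when eps_f = 0 (the inversion needs the
    free-dye fluorescence).
    """
    if eps_free <= 0:
        raise DegenerateInputError(
            "occupancy inversion requires eps_free > 0")
    if eps_free >= eps_bound:
        raise DegenerateInputError(
            "occupancy inversion requires eps_free < eps_bound")
    r = eps_free / eps_bound
    y = gain * (1.0 + eps_bound + eps_free) * mean_f - var_f
    if y <= 0:
        raise DegenerateInputError(
            f"ordinate y = A(1+eps_b+eps_f)<F> - var = {y:.4g} <= 0")
    return (gain * eps_free * mean_f / y - r) / (1.0 - r)
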