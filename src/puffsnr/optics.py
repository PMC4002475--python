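"""Confocal PSF blurring of simulated dye fields and noisy linescan synthesis.

The confocal observation volume is modelled as a 3-D Gaussian (1/e² half-widths
``w_r`` laterally, ``w_z`` axially).  For a spherically symmetric Ca-bound dye
field CaD(r, t) and a scan line through the source, the signal at scan position
x is the normalised PSF-weighted average of CaD centred at (x, 0, 0).  Dividing
the blurred field by the total dye concentration gives the space- and time-
dependent occupancy map lambda(x, t) that drives the noisy image generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .fluctuation import FluctuationParams, sample_pixels_map
from .linescan import LinescanImage
from .rd import RDSolution

__all__ = [
    "PSFParams",
    "BlurredProfile",
    "blur_radial_field",
    "synthesize_image",
]

#: kernel truncation radius in units of the Gaussian half-width
_TRUNC = 3.0
#: quadrature points per half-width along each axis
_PTS_PER_W = 6


@dataclass(frozen=True)
class PSFParams:
    """Gaussian PSF half-widths (1/e² convention), µm."""

    w_r_um: float = 0.3
    w_z_um: float = 1.0

    def __post_init__(self) -> None:
        if self.w_r_um <= 0 or self.w_z_um <= 0:
            raise ParameterError("PSF half-widths must be > 0")
        if self.w_z_um < self.w_r_um:
            raise ParameterError("axial half-width must be >= lateral half-width")


@dataclass
class BlurredProfile:
    """PSF-blurred Ca-bound dye concentration along the scan line."""

    x_um: np.ndarray             # scan coordinate
    t_ms: np.ndarray
    cad_blur_um: np.ndarray      # (nx, nt) blurred Ca-bound dye, µM
    dye_total_um: float
    psf: PSFParams

    @property
    def occupancy_map(self) -> np.ndarray:
        """lambda(x, t) = CaD_blur / [D]_T, clipped to [0, 1] at round-off."""
        lam = self.cad_blur_um / self.dye_total_um
        return np.clip(lam, 0.0, 1.0)

    def peak_to_basal_ratio(self) -> float:
        """Max of the blurred field over its value at (x, t) = (far, 0)."""
        basal = float(self.cad_blur_um[:, 0].mean())
        return float(self.cad_blur_um.max() / basal)


def _psf_weight_matrix(r_grid: np.ndarray, scan_x: np.ndarray,
                       psf: PSFParams) -> np.ndarray:
    """W[k, j]: normalised weight of radial node j for scan position x_k.

    Direct quadrature of the 3-D Gaussian over a Cartesian grid truncated at
    ``_TRUNC`` half-widths, with the radial field linearly interpolated between
    nodes.  Rows are renormalised so a uniform field is reproduced exactly.
    """
    dr = r_grid[1] - r_grid[0]
    r_max = r_grid[-1]
    nu = int(_TRUNC * _PTS_PER_W)
    # offsets along scan axis (u), lateral (v) and axial (w)
    u = np.linspace(-_TRUNC * psf.w_r_um, _TRUNC * psf.w_r_um, 2 * nu + 1)
    v = u.copy()
    w = np.linspace(-_TRUNC * psf.w_z_um, _TRUNC * psf.w_z_um, 2 * nu + 1)
    uu, vv, ww = np.meshgrid(u, v, w, indexing="ij")
    gauss = np.exp(-2.0 * (uu ** 2 + vv ** 2) / psf.w_r_um ** 2
                   - 2.0 * ww ** 2 / psf.w_z_um ** 2).ravel()

    W = np.zeros((scan_x.size, r_grid.size))
    for k, x in enumerate(scan_x):
        rad = np.sqrt((uu + x) ** 2 + vv ** 2 + ww ** 2).ravel()
        if rad.max() > r_max + 1e-9:
            raise ParameterError(
                f"scan position {x:.3g} µm needs field values beyond the "
                f"simulation radius {r_max:.3g} µm")
        idx = np.minimum((rad / dr).astype(np.int64), r_grid.size - 2)
        frac = rad / dr - idx
        row = np.zeros(r_grid.size)
        np.add.at(row, idx, gauss * (1.0 - frac))
        np.add.at(row, idx + 1, gauss * frac)
        W[k] = row / row.sum()
    return W


def blur_radial_field(solution: RDSolution, dye_name: str, psf: PSFParams,
                      scan_x_um: np.ndarray) -> BlurredProfile:
    """Blur the Ca-bound dye field of a simulation along a scan line.

    ``scan_x_um`` are the scan positions (µm) measured from the source; the
    blur is linear and positivity-preserving, and the blurred maximum never
    exceeds the unblurred maximum (the kernel is a normalised average).
    """
    if dye_name not in solution.bound:
        raise ParameterError(f"species {dye_name!r} not present in the solution")
    scan_x = np.asarray(scan_x_um, dtype=float)
    W = _psf_weight_matrix(solution.r_um, np.abs(scan_x), psf)
    cad = solution.bound[dye_name]                     # (nt, nr)
    blurred = W @ cad.T                                # (nx, nt)
    dye_total = next(s.total_um for s in solution.config.species
                     if s.name == dye_name)
    return BlurredProfile(x_um=scan_x, t_ms=solution.t_ms.copy(),
                          cad_blur_um=blurred, dye_total_um=dye_total, psf=psf)


def synthesize_image(occupancy_map: np.ndarray, params: FluctuationParams,
                     rng: np.random.Generator,
                     pixel_size_um: float = 0.2, line_period_ms: float = 2.0,
                     granule_rows: np.ndarray | None = None,
                     granule_level: float = 0.1,
                     annotations: dict | None = None) -> LinescanImage:
    """Draw a noisy linescan image from a per-pixel occupancy map.

    Every pixel is an independent draw of the fluctuation-model chain with the
    pixel's own occupancy.  ``granule_rows`` (row indices) optionally renders
    dark fringes: those rows get an occupancy chosen so their mean fluorescence
    is ``granule_level`` times the basal cytosolic mean (clipped at zero when
    the free-dye fluorescence alone exceeds that level) — purely cosmetic rows
    for preprocessing tests.
    """
    lam = np.array(occupancy_map, dtype=np.float64)
    if lam.ndim != 2:
        raise ParameterError("occupancy map must be 2-D (space x time)")
    if np.any(lam < 0) or np.any(lam > 1):
        raise ParameterError("occupancy map must lie within [0, 1]")
    if granule_rows is not None and len(granule_rows):
        lam_basal = float(np.median(lam[:, 0]))
        eb, ef = params.eps_bound, params.eps_free
        target = granule_level * (eb * lam_basal + ef * (1 - lam_basal))
        lam_gran = max((target - ef) / (eb - ef), 0.0) if eb > ef else 0.0
        lam[np.asarray(granule_rows, dtype=int), :] = lam_gran
    values = sample_pixels_map(lam, params, rng)
    ann = {"type": "0", "power_rel": 1.0, "region": 0, "ca_added": 0.0}
    ann.update(annotations or {})
    return LinescanImage(values=values, pixel_size_um=pixel_size_um,
                         line_period_ms=line_period_ms, annotations=ann)
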