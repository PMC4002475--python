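"""Seeded generators of synthetic calibration data, images and puff scenarios.

Everything the analysis modules consume can be produced here with a known
ground truth embedded, so the whole pipeline is testable without any external
data.  The three stationary experiment types vary exactly one knob each:

* Type I  — the per-image molecule number (regional dye-concentration jitter);
* Type II — the molecular brightness (laser-power sweep at fixed ratio r);
* Type III — the occupancy (added Ca2+), with molecule-number jitter as well.

The puff scenario presets carry the dye/buffer kinetics of the three
concentration sets studied with Fluo-4 and Rhod-2 (two printed Rhod-2 rate
pairs are exposed as variants ``a`` and ``b`` rather than choosing silently).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import MomentEnsemble
from .errors import ParameterError
from .fluctuation import FluctuationParams, sample_pixels
from .linescan import LinescanImage, MomentSample
from .rd import PuffSource, RDConfig, SpeciesSpec

__all__ = [
    "DYE_KINETICS",
    "DYE_BRIGHTNESS_RATIO",
    "SCENARIO_SETS",
    "FixtureSpec",
    "gen_moment_ensemble",
    "gen_linescan_fixture",
    "gen_puff_scenario",
]

#: dye and buffer kinetics (diffusion µm²/s, k_on µM⁻¹s⁻¹, k_off s⁻¹)
DYE_KINETICS = {
    "fluo4":   {"diffusion_um2_s": 15.0, "k_on": 240.0, "k_off": 180.0},
    "rhod2_a": {"diffusion_um2_s": 15.0, "k_on": 70.0, "k_off": 130.0},
    "rhod2_b": {"diffusion_um2_s": 15.0, "k_on": 85.0, "k_off": 170.0},
}

#: default brightness ratios r = eps_f/eps_b per dye family (free/bound quantum
#: efficiency ratio; ~40x Ca-bound enhancement for Fluo-4, ~14x for Rhod-2)
DYE_BRIGHTNESS_RATIO = {"fluo4": 0.025, "rhod2": 0.07}

_EGTA = {"diffusion_um2_s": 80.0, "k_on": 5.0, "k_off": 0.75}
_IMMOBILE = {"diffusion_um2_s": 0.0, "k_on": 400.0, "k_off": 800.0,
             "total_um": 300.0}
_MOBILE_SLOW = {"diffusion_um2_s": 27.0, "k_on": 20.0, "k_off": 8.6,
                "total_um": 250.0}
_MOBILE_RAPID = {"diffusion_um2_s": 32.0, "k_on": 500.0, "k_off": 750.0,
                 "total_um": 10.0}

#: the three dye/EGTA concentration sets (µM)
SCENARIO_SETS = {
    "i":   {"dye": "fluo4", "dye_total_um": 36.0, "egta_total_um": 90.0},
    "ii":  {"dye": "rhod2", "dye_total_um": 36.0, "egta_total_um": 90.0},
    "iii": {"dye": "rhod2", "dye_total_um": 90.0, "egta_total_um": 45.0},
}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic moment ensemble with embedded ground truth."""

    experiment_type: str                  # "I", "II" or "III"
    truth: FluctuationParams
    n_images: int
    n_pixels: int = 100_000
    # Type I / III: log-uniform molecule-number jitter factors across regions
    n_jitter: tuple[float, float] = (0.5, 2.0)
    # Type II: relative laser-intensity span (log-spaced across images)
    intensity_span: tuple[float, float] = (0.2, 2.0)
    # Type III: occupancy grid endpoints (linear across images) and the
    # fraction of images recorded at basal occupancy (no added Ca2+)
    occupancy_span: tuple[float, float] = (0.1, 0.9)
    basal_fraction: float = 0.2
    dye: str = ""
    set_label: str = ""

    def __post_init__(self) -> None:
        if self.experiment_type not in ("I", "II", "III"):
            raise ParameterError(
                f"unknown experiment type {self.experiment_type!r}")
        if self.n_images < 1 or self.n_pixels < 2:
            raise ParameterError("need >= 1 image and >= 2 pixels per image")


def _image_params(spec: FixtureSpec, rng: np.random.Generator):
    """Per-image ground-truth parameter list realising the type's variation law."""
    t = spec.truth
    out = []
    if spec.experiment_type == "I":
        factors = np.exp(rng.uniform(np.log(spec.n_jitter[0]),
                                     np.log(spec.n_jitter[1]), spec.n_images))
        for i, f in enumerate(factors):
            p = FluctuationParams(gain=t.gain, eps_bound=t.eps_bound,
                                  eps_free=t.eps_free, occupancy=t.occupancy,
                                  mean_molecules=t.mean_molecules * f)
            out.append((p, {"region": i, "power_rel": 1.0, "ca_added": 0.0}))
    elif spec.experiment_type == "II":
        intens = np.geomspace(spec.intensity_span[0], spec.intensity_span[1],
                              spec.n_images)
        for i, s in enumerate(intens):
            out.append((t.scaled_intensity(s),
                        {"region": 0, "power_rel": float(s), "ca_added": 0.0}))
    else:  # Type III: basal cluster + occupancy ramp, molecule-number jitter
        n_basal = int(round(spec.basal_fraction * spec.n_images))
        ramp = np.linspace(spec.occupancy_span[0], spec.occupancy_span[1],
                           spec.n_images - n_basal)
        lams = np.concatenate([np.full(n_basal, spec.occupancy_span[0]), ramp])
        factors = np.exp(rng.uniform(np.log(spec.n_jitter[0]),
                                     np.log(spec.n_jitter[1]), spec.n_images))
        for i, (lam, f) in enumerate(zip(lams, factors)):
            p = FluctuationParams(gain=t.gain, eps_bound=t.eps_bound,
                                  eps_free=t.eps_free, occupancy=float(lam),
                                  mean_molecules=t.mean_molecules * f)
            out.append((p, {"region": i, "power_rel": 1.0,
                            "ca_added": float(lam)}))
    return out


def gen_moment_ensemble(spec: FixtureSpec,
                        rng: np.random.Generator | int) -> MomentEnsemble:
    """Sample one moment ensemble: per-image pooled (mean, variance) pairs.

    Each image's moments come from freshly sampled pixels of the generative
    chain; the per-image ground-truth parameters are embedded in
    ``ensemble.ground_truth`` for recovery scoring.  Deterministic under a
    fixed seed.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    samples, truths = [], []
    for i, (p, ann) in enumerate(_image_params(spec, rng)):
        pix = sample_pixels(p, spec.n_pixels, rng)
        ann = dict(ann, image_id=i)
        samples.append(MomentSample(mean_f=float(pix.mean()),
                                    var_f=float(pix.var(ddof=1)),
                                    n_pixels=pix.size, annotations=ann))
        truths.append(p)
    return MomentEnsemble(samples=samples,
                          experiment_type=spec.experiment_type,
                          dye=spec.dye, set_label=spec.set_label,
                          ground_truth={"spec": spec, "per_image": truths})


def gen_linescan_fixture(params: FluctuationParams, n_rows: int, n_times: int,
                         rng: np.random.Generator | int,
                         granule_fraction: float = 0.3,
                         granule_level: float = 0.1,
                         pixel_size_um: float = 0.2,
                         line_period_ms: float = 2.0) -> tuple[LinescanImage, np.ndarray]:
    """Stationary linescan image with flat dark (granule) rows at known positions.

    Returns the image and the ground-truth dark-row indices.  Granule rows are
    rendered at ``granule_level`` of the cytosolic mean fluorescence by scaling
    the occupancy (clipped at zero), which is all the preprocessing tests need.
    """
    from .optics import synthesize_image

    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    n_dark = int(round(granule_fraction * n_rows))
    dark_rows = rng.choice(n_rows, size=n_dark, replace=False)
    lam = np.full((n_rows, n_times), params.occupancy)
    img = synthesize_image(lam, params, rng, pixel_size_um=pixel_size_um,
                           line_period_ms=line_period_ms,
                           granule_rows=dark_rows, granule_level=granule_level,
                           annotations={"type": "I"})
    return img, np.sort(dark_rows)


def gen_puff_scenario(set_label: str, flux_ions_per_s: float = 3.0e5,
                      dye_variant: str = "a",
                      include_mobile_buffers: bool = False,
                      **numerics) -> RDConfig:
    """Reaction-diffusion preset for one of the concentration sets i/ii/iii.

    ``dye_variant`` selects between the two printed Rhod-2 rate pairs
    (``a``: k_on 70 / k_off 130; ``b``: 85 / 170) and is ignored for Fluo-4.
    Mobile endogenous buffers are off by default in puff scenarios; the
    immobile buffer and the pump are always on.  Extra keyword arguments
    override the numerical fields of :class:`RDConfig` (dr_um, dt_ms,
    t_end_ms, radius_um, save_every_ms, ...).
    """
    if set_label not in SCENARIO_SETS:
        raise ParameterError(
            f"unknown scenario set {set_label!r}; choose from "
            f"{sorted(SCENARIO_SETS)}")
    cfg = SCENARIO_SETS[set_label]
    dye_key = cfg["dye"] if cfg["dye"] == "fluo4" else f"rhod2_{dye_variant}"
    if dye_key not in DYE_KINETICS:
        raise ParameterError(f"unknown dye variant {dye_variant!r}")
    species = [
        SpeciesSpec(name="dye", total_um=cfg["dye_total_um"],
                    **DYE_KINETICS[dye_key]),
        SpeciesSpec(name="egta", total_um=cfg["egta_total_um"], **_EGTA),
        SpeciesSpec(name="immobile", **_IMMOBILE),
    ]
    if include_mobile_buffers:
        species.append(SpeciesSpec(name="mobile_slow", **_MOBILE_SLOW))
        species.append(SpeciesSpec(name="mobile_rapid", **_MOBILE_RAPID))
    return RDConfig(
        species=tuple(species),
        source=PuffSource(flux_ions_per_s=flux_ions_per_s),
        **numerics,
    )
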