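"""Ground-truthed synthetic hyperspectral scenes of an in-vitro wound disc.

The generator emulates the imagery the clustering pipeline targets: a
circular tissue disc on a dark low-reflectance dish, built from a small
number of smooth endmember reflectance spectra over 450-790 nm, with
additive Gaussian sensor noise and a handful of fluid-covered pixels whose
reflectance exceeds 1 (specular overexposure).  Every scene comes with its
ground truth — region labels, true endmembers, background and overexposure
masks — so clustering recovery can be scored with the adjusted Rand index.

The default layout is concentric: an outer disc of tissue periphery, an
annulus of wound margin, and a central disc of wound bed.  A time-course
builder shrinks the wound-bed disc over "days" for untreated series and
leaves it in place for treated ones, mimicking wound closure dynamics.

Scenes are piecewise-constant (no spectral gradient within a region) so the
ground-truth partition is unambiguous, and desk-scale (64 x 64 x 125 bands
by default) rather than megapixel.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError, ParameterError
from .hsi_io import SpectralCube

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "default_wavelengths",
    "make_endmembers",
    "make_wound_cube",
    "make_timecourse",
]

#: label value for background pixels in the ground-truth grid
BACKGROUND_LABEL = 0


def default_wavelengths(lo_nm: float = 450.0, hi_nm: float = 790.0,
                        step_nm: float = 2.73) -> np.ndarray:
    """Band grid at the camera's 2.73 nm spectral resolution (125 bands)."""
    n = int(np.floor((hi_nm - lo_nm) / step_nm)) + 1
    return lo_nm + step_nm * np.arange(n)


@dataclass
class SceneSpec:
    """Parameters of one synthetic wound-disc scene.

    ``region_radii`` are fractions of ``min(spatial_shape)`` for the outer
    tissue disc, the wound-margin annulus and the central wound bed; each
    must fit inside the image.  ``noise_sd`` is the per-band additive noise
    scale in reflectance units; ``background_level`` is the dish
    reflectance; ``n_overexposed`` fluid pixels get values in 1.05-1.5.
    """

    spatial_shape: tuple[int, int] = (64, 64)
    wavelengths: np.ndarray = field(default_factory=default_wavelengths)
    n_endmembers: int = 3
    region_radii: tuple[float, ...] = (0.45, 0.30, 0.15)
    noise_sd: float = 0.01
    n_overexposed: int = 25
    background_level: float = 0.01
    separation_floor: float = 1.0
    seed: int = 0
    endmembers: np.ndarray | None = None  # override; rows are spectra

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if len(self.region_radii) != self.n_endmembers:
            raise ParameterError("need one region radius per endmember")
        if any(r2 >= r1 for r1, r2 in zip(self.region_radii, self.region_radii[1:])):
            raise ParameterError("region radii must be strictly decreasing (concentric)")
        if max(self.region_radii) > 0.5:
            raise ParameterError("outer region radius exceeds the image bounds")
        if self.noise_sd < 0 or self.background_level < 0:
            raise ParameterError("noise_sd and background_level must be non-negative")


@dataclass
class GroundTruth:
    """Per-pixel truth aligned to the generated cube.

    ``labels`` holds 0 for background and 1..g for the tissue regions;
    overexposed pixels keep their region label in ``labels`` but are flagged
    in ``overexposed`` (they are excluded from recovery scoring, as the
    masking stage removes them).
    """

    labels: np.ndarray
    endmembers: np.ndarray
    background: np.ndarray
    overexposed: np.ndarray

    @property
    def tissue(self) -> np.ndarray:
        """Pixels that survive masking: labelled tissue, not overexposed."""
        return (self.labels > 0) & ~self.overexposed


def _gaussian_bumps(wavelengths: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    lo, hi = wavelengths[0], wavelengths[-1]
    n_bumps = int(rng.integers(2, 5))
    spectrum = np.zeros_like(wavelengths)
    for _ in range(n_bumps):
        amp = rng.uniform(0.2, 0.9)
        center = rng.uniform(lo, hi)
        width = rng.uniform(40.0, 120.0)  # nm; keeps band-to-band steps small
        spectrum += amp * np.exp(-0.5 * ((wavelengths - center) / width) ** 2)
    peak_target = rng.uniform(0.5, 0.9)
    return spectrum * (peak_target / spectrum.max())


def make_endmembers(g: int, wavelengths=None, seed=0,
                    separation_floor: float = 1.0, max_tries: int = 500) -> np.ndarray:
    """Draw g smooth endmember spectra with guaranteed pairwise separation.

    Each spectrum is a positive sum of 2-4 Gaussian bumps, rescaled to a
    peak in (0, 0.9].  Candidates closer than ``separation_floor``
    (Euclidean over bands) to an accepted spectrum, or too dark on average,
    are redrawn; a bounded retry budget guards against impossible settings.
    """
    if g < 1:
        raise ParameterError("g must be >= 1")
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths, float)
    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    tries = 0
    while len(accepted) < g:
        if tries >= max_tries:
            raise GenerationError(
                f"could not draw {g} endmembers with separation >= "
                f"{separation_floor} in {max_tries} tries"
            )
        tries += 1
        cand = _gaussian_bumps(wl, rng)
        if cand.mean() < 0.1:  # must stay clearly above the dark background
            continue
        if all(np.linalg.norm(cand - e) >= separation_floor for e in accepted):
            accepted.append(cand)
    return np.vstack(accepted)


def _region_labels(spec: SceneSpec) -> np.ndarray:
    rows, cols = spec.spatial_shape
    rr, cc = np.ogrid[:rows, :cols]
    center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    dist = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
    scale = min(rows, cols)
    labels = np.zeros((rows, cols), dtype=np.int32)
    # regions are nested discs; later (inner) regions overwrite outer ones
    for idx, radius_frac in enumerate(spec.region_radii, start=1):
        labels[dist <= radius_frac * scale] = idx
    return labels


def make_wound_cube(spec: SceneSpec) -> tuple[SpectralCube, GroundTruth]:
    """Render one scene: cube plus aligned ground truth, reproducible from seed."""
    rng = np.random.default_rng(spec.seed)
    wl = spec.wavelengths
    if spec.endmembers is not None:
        endmembers = np.asarray(spec.endmembers, dtype=float)
        if endmembers.shape != (spec.n_endmembers, len(wl)):
            raise ParameterError("endmember override has the wrong shape")
    else:
        endmembers = make_endmembers(spec.n_endmembers, wl, seed=rng.integers(2**31),
                                     separation_floor=spec.separation_floor)

    labels = _region_labels(spec)
    rows, cols = spec.spatial_shape
    values = np.empty((rows, cols, len(wl)))
    values[labels == BACKGROUND_LABEL] = spec.background_level
    for idx in range(1, spec.n_endmembers + 1):
        values[labels == idx] = endmembers[idx - 1]

    overexposed = np.zeros((rows, cols), dtype=bool)
    tissue_flat = np.flatnonzero(labels.ravel() > 0)
    n_over = min(spec.n_overexposed, tissue_flat.size)
    if n_over > 0:
        pick = rng.choice(tissue_flat, size=n_over, replace=False)
        overexposed.ravel()[pick] = True
        # specular fluid: flat bright spectrum clearly beyond reflectance 1
        values[overexposed] = rng.uniform(1.05, 1.5, size=n_over)[:, None]

    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
        np.clip(values, 0.0, None, out=values)

    cube = SpectralCube(values, wl.copy(),
                        meta={"synthetic": True, "seed": int(spec.seed)})
    truth = GroundTruth(labels=labels, endmembers=endmembers,
                        background=labels == BACKGROUND_LABEL,
                        overexposed=overexposed)
    return cube, truth


#: wound-bed radius multiplier per day for closing (control) vs persistent wounds
_CLOSURE = {0: 1.0, 5: 0.6, 10: 0.3}


def make_timecourse(base: SceneSpec | None = None, days=(0, 5, 10),
                    conditions=("control", "AWF", "CWF"), seed: int = 0) -> list[dict]:
    """Build a day x condition series of scenes sharing one endmember set.

    The innermost (wound bed) region shrinks over days for the ``control``
    condition and persists for treated conditions (chronic/artificial wound
    fluid), so downstream per-cluster pixel counts show the closure dynamic.
    Returns records ``{"day", "condition", "cube", "truth"}``; the same seed
    always yields the identical series.
    """
    base = base or SceneSpec()
    endmembers = make_endmembers(base.n_endmembers, base.wavelengths,
                                 seed=seed, separation_floor=base.separation_floor)
    records = []
    for condition in conditions:
        for day in days:
            factor = _CLOSURE.get(day, 1.0) if condition == "control" else 1.0
            radii = list(base.region_radii)
            radii[-1] = radii[-1] * factor
            cond_key = zlib.crc32(condition.encode()) % 97
            scene_seed = (seed * 1000 + cond_key * 10 + day) % (2**31)
            spec = SceneSpec(
                spatial_shape=base.spatial_shape,
                wavelengths=base.wavelengths,
                n_endmembers=base.n_endmembers,
                region_radii=tuple(radii),
                noise_sd=base.noise_sd,
                n_overexposed=base.n_overexposed,
                background_level=base.background_level,
                separation_floor=base.separation_floor,
                seed=scene_seed,
                endmembers=endmembers,
            )
            cube, truth = make_wound_cube(spec)
            cube.meta["image_id"] = f"{condition}_d{day}"
            cube.meta["day"] = day
            cube.meta["condition"] = condition
            records.append({"day": day, "condition": condition,
                            "cube": cube, "truth": truth})
    return records
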