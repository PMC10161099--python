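"""Synthetic-data generators for every stage of the pipeline.

Three generators cover the three kinds of raw data the analysis consumes:

* :func:`generate_micrograph` — multi-channel fluorescence micrographs
  (nucleus stain, mCherry-Gal8, DiD, NBD-PE) with a :class:`SceneTruth`
  sidecar recording every object drawn, so counting accuracy can be
  scored against exact ground truth.
* :func:`generate_titration` — TNS fluorescence-versus-pH curves with the
  sigmoidal shape used for apparent-pKa fitting.
* :func:`generate_mechanism_panel` — per-well (puncta, foci, vesicles)
  tables produced by a two-mechanism disruption model in which Gal8 foci
  arise both from endocytosed colloids (slope term) and from free drug
  entering by passive diffusion (intercept term).  Wells treated with an
  endocytosis blocker have zero colloid uptake and anchor the intercept.

Every generator is a pure function of its parameters and an integer seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

# Channel roles used throughout the package.
CHANNEL_NUCLEI = "nuclei"
CHANNEL_GAL8 = "gal8"      # mCherry-Gal8: diffuse cytosol + disruption foci
CHANNEL_DID = "did"        # DiD: colloid-containing vesicles (puncta)
CHANNEL_NBDPE = "nbd_pe"   # NBD-PE: phospholipidosis vesicles

CHANNEL_ROLES = (CHANNEL_NUCLEI, CHANNEL_GAL8, CHANNEL_DID, CHANNEL_NBDPE)

#: SceneTruth object-list name for each channel role.
ROLE_TO_OBJECTS = {
    CHANNEL_NUCLEI: "nuclei",
    CHANNEL_GAL8: "foci",
    CHANNEL_DID: "puncta",
    CHANNEL_NBDPE: "vesicles",
}

UINT16_MAX = 65535


@dataclass
class SceneTruth:
    """Ground truth for one synthetic micrograph.

    Object tuples are ``(row, col, radius)`` for nuclei and
    ``(row, col, radius, peak_intensity)`` for the punctate channels.
    The list lengths ARE the ground-truth counts.
    """

    nuclei: list[tuple[float, float, float]]
    foci: list[tuple[float, float, float, float]]
    puncta: list[tuple[float, float, float, float]]
    vesicles: list[tuple[float, float, float, float]]
    cytosol_background: float
    camera_offset: float
    noise_sd: float
    image_shape: tuple[int, int]

    def count(self, objects: str) -> int:
        return len(getattr(self, objects))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SceneTruth":
        d = json.loads(text)
        d["image_shape"] = tuple(d["image_shape"])
        for key in ("nuclei", "foci", "puncta", "vesicles"):
            d[key] = [tuple(t) for t in d[key]]
        return cls(**d)


@dataclass
class SceneParams:
    """Distribution parameters for :func:`generate_micrograph`.

    Defaults emulate one stitched wide-field image of ~100 cells: ~100
    Hoechst-stained nuclei, diffuse cytosolic mCherry-Gal8 with a few
    dozen disruption foci, a few hundred DiD puncta, and NBD-PE
    phospholipidosis vesicles.  Intensities are in 16-bit camera counts.
    ``min_separation_radii`` is the minimum center distance between two
    objects of one channel, in units of the object radius.
    """

    n_nuclei: int = 100
    n_foci: int = 40
    n_puncta: int = 250
    n_vesicles: int = 30
    nucleus_radius: float = 12.0
    spot_radius: float = 3.0
    nucleus_peak: float = 20000.0
    spot_peak: float = 15000.0
    cytosol_background: float = 3000.0
    cytosol_halo_sigma: float = 40.0
    camera_offset: float = 500.0
    noise_sd: float = 1500.0
    min_separation_radii: float = 3.0

    def __post_init__(self) -> None:
        for name in ("n_nuclei", "n_foci", "n_puncta", "n_vesicles"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nucleus_radius <= 0 or self.spot_radius <= 0:
            raise ValueError("object radii must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _place_centers(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    radius: float,
    min_sep: float,
    channel: str,
    max_attempts_per_object: int = 2000,
) -> np.ndarray:
    """Rejection-sample ``n`` centers with pairwise distance >= min_sep.

    Centers stay ``2*radius`` away from the image border so objects are
    fully contained.  Raises when the requested density cannot be placed.
    """
    if n == 0:
        return np.empty((0, 2))
    margin = 2.0 * radius
    lo = (margin, margin)
    hi = (shape[0] - margin, shape[1] - margin)
    if hi[0] <= lo[0] or hi[1] <= lo[1]:
        raise ValueError(
            f"channel {channel!r}: image shape {shape} too small for "
            f"objects of radius {radius}"
        )
    centers: list[np.ndarray] = []
    placed = np.empty((0, 2))
    for _ in range(n):
        for attempt in range(max_attempts_per_object):
            c = rng.uniform(lo, hi)
            if placed.size == 0 or np.min(
                np.hypot(*(placed - c).T)
            ) >= min_sep:
                centers.append(c)
                placed = np.asarray(centers)
                break
        else:
            raise ValueError(
                f"channel {channel!r}: could not place {n} objects of "
                f"radius {radius} with separation {min_sep:.1f} px in "
                f"image {shape}; density physically unplaceable"
            )
    return placed


def _render_spots(
    canvas: np.ndarray,
    spots: list[tuple],
    default_amp: float | None = None,
) -> None:
    """Add isotropic Gaussian profiles (radius = 2*sigma) in place."""
    h, w = canvas.shape
    for spot in spots:
        r, c, radius = spot[0], spot[1], spot[2]
        amp = spot[3] if len(spot) > 3 else default_amp
        sigma = radius / 2.0
        ext = int(np.ceil(4 * sigma))
        r0, r1 = max(0, int(r) - ext), min(h, int(r) + ext + 1)
        c0, c1 = max(0, int(c) - ext), min(w, int(c) + ext + 1)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        canvas[r0:r1, c0:c1] += amp * np.exp(
            -((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma**2)
        )


def generate_micrograph(
    params: SceneParams,
    image_shape: tuple[int, int] = (512, 512),
    seed: int = 0,
):
    """Render one multi-channel micrograph and its ground truth.

    Each channel is the additive composition of a constant camera offset,
    the per-cell diffuse cytosolic Gal8 halo (Gal8 channel only — this is
    exactly the background the top-hat stage must remove), Gaussian
    profile objects at the truth locations, and i.i.d. Gaussian pixel
    noise, clipped to the 16-bit range.

    Returns ``(channels, truth)`` where ``channels`` maps channel role to
    a uint16 raster. Deterministic in ``(params, image_shape, seed)``.
    """
    rng = np.random.default_rng(seed)
    sep_n = params.min_separation_radii * params.nucleus_radius
    sep_s = params.min_separation_radii * params.spot_radius

    nuc = _place_centers(
        rng, params.n_nuclei, image_shape, params.nucleus_radius, sep_n,
        CHANNEL_NUCLEI,
    )
    spots = {}
    for role, n in (
        (CHANNEL_GAL8, params.n_foci),
        (CHANNEL_DID, params.n_puncta),
        (CHANNEL_NBDPE, params.n_vesicles),
    ):
        spots[role] = _place_centers(
            rng, n, image_shape, params.spot_radius, sep_s, role
        )

    truth = SceneTruth(
        nuclei=[(r, c, params.nucleus_radius) for r, c in nuc],
        foci=[(r, c, params.spot_radius, params.spot_peak)
              for r, c in spots[CHANNEL_GAL8]],
        puncta=[(r, c, params.spot_radius, params.spot_peak)
                for r, c in spots[CHANNEL_DID]],
        vesicles=[(r, c, params.spot_radius, params.spot_peak)
                  for r, c in spots[CHANNEL_NBDPE]],
        cytosol_background=params.cytosol_background,
        camera_offset=params.camera_offset,
        noise_sd=params.noise_sd,
        image_shape=tuple(image_shape),
    )

    channels: dict[str, np.ndarray] = {}
    for role in CHANNEL_ROLES:
        canvas = np.full(image_shape, params.camera_offset, dtype=np.float64)
        if role == CHANNEL_GAL8 and params.cytosol_background > 0:
            # diffuse cytosolic Gal8: one wide halo per nucleus
            halos = [
                (r, c, 2 * params.cytosol_halo_sigma,
                 params.cytosol_background)
                for r, c, _rad in truth.nuclei
            ]
            _render_spots(canvas, halos)
        if role == CHANNEL_NUCLEI:
            _render_spots(canvas, truth.nuclei, default_amp=params.nucleus_peak)
        else:
            _render_spots(canvas, getattr(truth, ROLE_TO_OBJECTS[role]))
        if params.noise_sd > 0:
            canvas += rng.normal(0.0, params.noise_sd, image_shape)
        channels[role] = np.clip(np.rint(canvas), 0, UINT16_MAX).astype(
            np.uint16
        )
    return channels, truth


def write_micrograph(
    channels: dict[str, np.ndarray],
    truth: SceneTruth | None,
    directory: Path | str,
    stem: str,
) -> list[Path]:
    """Write one 16-bit grayscale TIFF per channel plus a truth sidecar.

    Channel role is encoded as the filename suffix
    (``<stem>_<role>.tif``); ground truth goes to ``<stem>_truth.json``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for role, raster in channels.items():
        path = directory / f"{stem}_{role}.tif"
        tifffile.imwrite(path, raster, software=False)
        written.append(path)
    if truth is not None:
        path = directory / f"{stem}_truth.json"
        path.write_text(truth.to_json())
        written.append(path)
    return written


def read_micrograph_channels(
    directory: Path | str, stem: str
) -> dict[str, np.ndarray]:
    """Read the per-channel TIFFs written by :func:`write_micrograph`."""
    directory = Path(directory)
    channels = {}
    for role in CHANNEL_ROLES:
        path = directory / f"{stem}_{role}.tif"
        if path.exists():
            channels[role] = tifffile.imread(path)
    if not channels:
        raise FileNotFoundError(
            f"no channel TIFFs matching {stem}_<role>.tif in {directory}"
        )
    return channels


# --------------------------------------------------------------------------
# Titration curves (TNS apparent-pKa assay)
# --------------------------------------------------------------------------

def titration_model(
    ph: np.ndarray, background: float, maximum: float, pka: float
) -> np.ndarray:
    """Sigmoidal TNS fluorescence model.

    ``F(pH) = Background + (Maximum - Background) / (1 + 10**(pH - pKa))``

    TNS fluoresces in the presence of the protonated (cationic) species,
    so fluorescence falls from ``Maximum`` at acidic pH to ``Background``
    at basic pH, crossing the midpoint at ``pH = pKa``.
    """
    ph = np.asarray(ph, dtype=float)
    return background + (maximum - background) / (1.0 + 10.0 ** (ph - pka))


def generate_titration(
    pka: float,
    background: float,
    maximum: float,
    ph_grid,
    noise_sd: float = 0.0,
    seed: int = 0,
    relative_noise_sd: float = 0.0,
):
    """Simulate a TNS titration curve over ``ph_grid``.

    ``noise_sd`` adds Gaussian noise in fluorescence units;
    ``relative_noise_sd`` adds multiplicative noise (e.g. 0.02 for 2%).
    Returns ``(ph, fluorescence)`` arrays.
    """
    ph = np.asarray(ph_grid, dtype=float)
    if ph.min() < 3.0 or ph.max() > 10.0:
        raise ValueError("ph_grid must lie within [3, 10]")
    if maximum <= background:
        raise ValueError(
            "maximum must exceed background (direction unidentifiable)"
        )
    rng = np.random.default_rng(seed)
    f = titration_model(ph, background, maximum, pka)
    if relative_noise_sd > 0:
        f = f * (1.0 + rng.normal(0.0, relative_noise_sd, ph.shape))
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, ph.shape)
    return ph, f


# --------------------------------------------------------------------------
# Two-mechanism disruption panel
# --------------------------------------------------------------------------

@dataclass
class CompoundParams:
    """Per-compound rates of the two-mechanism disruption model."""

    compound_id: str
    pka: float
    colloid_efficiency: float      # Gal8 foci per DiD punctum
    free_drug_rate: float          # foci per cell at zero uptake
    phospholipidosis_rate: float   # NBD-PE vesicles per cell

    def __post_init__(self) -> None:
        if min(self.colloid_efficiency, self.free_drug_rate,
               self.phospholipidosis_rate) < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class PanelSpec:
    """Design of a multi-well mechanism panel.

    ``blocker_fraction`` of each compound's wells are pre-treated with an
    endocytosis blocker, forcing colloid uptake (puncta per cell) to zero;
    the remaining wells draw uptake from a log-normal distribution with
    the stated mean and SD.  Foci per cell follow
    ``efficiency * puncta + free_drug_rate + noise`` truncated at zero.
    """

    compounds: list[CompoundParams]
    wells_per_compound: int = 15
    blocker_fraction: float = 1.0 / 3.0
    uptake_mean: float = 5.0
    uptake_sd: float = 2.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.blocker_fraction <= 1.0:
            raise ValueError("blocker_fraction must be in [0, 1]")
        if self.wells_per_compound < 2:
            raise ValueError("wells_per_compound must be >= 2")
        if self.uptake_mean <= 0 or self.uptake_sd < 0 or self.noise_sd < 0:
            raise ValueError("uptake_mean > 0 and SDs >= 0 required")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def generate_mechanism_panel(spec: PanelSpec) -> pd.DataFrame:
    """Simulate per-well counts under the two-mechanism model.

    Returns a tidy table with one row per well and columns
    ``compound``, ``blocker``, ``puncta_per_cell``, ``foci_per_cell``,
    ``vesicles_per_cell``.  Deterministic in the spec (including seed).
    """
    rng = np.random.default_rng(spec.seed)
    n_block = int(round(spec.blocker_fraction * spec.wells_per_compound))
    rows = []
    for comp in spec.compounds:
        uptake = np.zeros(spec.wells_per_compound)
        n_free = spec.wells_per_compound - n_block
        if n_free > 0:
            if spec.uptake_sd > 0:
                mu, sig = _lognormal_params(spec.uptake_mean, spec.uptake_sd)
                uptake[n_block:] = rng.lognormal(mu, sig, n_free)
            else:
                uptake[n_block:] = spec.uptake_mean
        noise = (rng.normal(0.0, spec.noise_sd,
                            (2, spec.wells_per_compound))
                 if spec.noise_sd > 0
                 else np.zeros((2, spec.wells_per_compound)))
        foci = np.maximum(
            comp.colloid_efficiency * uptake + comp.free_drug_rate
            + noise[0], 0.0,
        )
        vesicles = np.maximum(
            comp.phospholipidosis_rate + noise[1], 0.0
        )
        for w in range(spec.wells_per_compound):
            rows.append(
                {
                    "compound": comp.compound_id,
                    "blocker": w < n_block,
                    "puncta_per_cell": uptake[w],
                    "foci_per_cell": foci[w],
                    "vesicles_per_cell": vesicles[w],
                }
            )
    return pd.DataFrame(rows)


def latent_driver_compounds(
    n_compounds: int = 15,
    seed: int = 0,
    free_drug_range: tuple[float, float] = (0.2, 3.0),
    efficiency_range: tuple[float, float] = (0.05, 0.4),
    phospholipidosis_gain: float = 2.0,
) -> list[CompoundParams]:
    """Compound set in which free-drug disruption and phospholipidosis
    share a latent driver while colloid efficiency is independent.

    The latent driver (a stand-in for the lysosomotropic character of the
    free drug) sets both ``free_drug_rate`` and ``phospholipidosis_rate``;
    ``colloid_efficiency`` is drawn independently and then residualized
    against the driver so independence holds in the sampled design, not
    just in expectation.  Apparent pKa is spread over the weakly basic
    range typical of ionizable analogs.
    """
    if n_compounds < 3:
        raise ValueError("need at least 3 compounds")
    rng = np.random.default_rng(seed)
    latent = np.linspace(0.0, 1.0, n_compounds)
    free = free_drug_range[0] + (free_drug_range[1] - free_drug_range[0]) * latent
    phospho = phospholipidosis_gain * free
    eff = rng.uniform(*efficiency_range, n_compounds)
    # residualize so the sampled efficiencies are uncorrelated with the driver
    b = np.polyfit(latent, eff, 1)[0]
    eff = eff - b * (latent - latent.mean())
    eff = np.clip(eff, 1e-3, None)
    pkas = np.linspace(5.0, 7.5, n_compounds)
    return [
        CompoundParams(
            compound_id=f"analog_{i+1:02d}",
            pka=float(pkas[i]),
            colloid_efficiency=float(eff[i]),
            free_drug_rate=float(free[i]),
            phospholipidosis_rate=float(phospho[i]),
        )
        for i in range(n_compounds)
    ]


# --------------------------------------------------------------------------
# Dose-response curves
# --------------------------------------------------------------------------

def generate_dose_response(
    conc_um: np.ndarray,
    params: dict,
    model: str = "monophasic",
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulate % metabolic activity at the given concentrations.

    ``params`` holds the model parameters (see
    :mod:`colloidquant.curves`); noise is additive Gaussian in percent.
    """
    from . import curves  # local import to avoid a cycle

    conc_um = np.asarray(conc_um, dtype=float)
    if model == "monophasic":
        y = curves.monophasic_model(
            conc_um, params["top"], params["bottom"], params["ic50"],
            params["hill"],
        )
    elif model == "biphasic":
        y = curves.biphasic_model(
            conc_um, params["top"], params["plateau"], params["bottom"],
            params["ic50_stat"], params["hill_stat"],
            params["ic50_tox"], params["hill_tox"],
        )
    else:
        raise ValueError(f"unknown model {model!r}")
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, y.shape)
    return y
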