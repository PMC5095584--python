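"""Synthetic data with known ground truth for every pipeline stage.

Emulates the raw inputs of the analysis: diffraction-limited spot image
stacks of two-fluorophore complexes that photobleach in single steps under
EMCCD-like noise, mixtures of complex species at model-defined separations,
2D Brownian or confined single-particle tracks, and FRET efficiency versus
acceptor-density records from the donor-above-acceptor-plane model.  Each
generated artifact carries its ground truth so all recovery tests are
closed-loop.  Every sampling function takes an explicit seed; there is no
hidden global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .fret import FRETRecord, simulate_plane_fret
from .msd import Track

__all__ = [
    "CameraModel",
    "EmitterPairTruth",
    "SpeciesMixtureSpec",
    "default_species_mixture",
    "sample_species_mixture",
    "render_spot_stack",
    "simulate_tracks",
    "simulate_fret_dataset",
    "integrated_gaussian",
]

# Dye-corrected separations of the default five-species scenario
# (dimer, tetramer, hexamer, octamer, decamer): the independent dimer
# constant plus the chain-model predictions with the dye correction applied.
DEFAULT_SPECIES_SEPARATIONS_NM = (12.5, 19.6, 27.1, 34.6, 42.1)
DEFAULT_SPECIES_LABELS = ("dimer", "tetramer", "hexamer", "octamer", "decamer")


@dataclass(frozen=True)
class CameraModel:
    """EMCCD camera and acquisition parameters.

    Noise model: Poisson photon shot noise, multiplicative gain, additive
    Gaussian read noise.  ``excess_noise`` doubles the shot variance (the
    standard EM-register approximation) by drawing the amplified count from
    a Gamma distribution conditional on the photon count.
    """

    pixel_size_nm: float = 100.0
    read_noise_e: float = 1.0
    gain: float = 1.0
    background_photons_per_px: float = 10.0
    frame_interval_s: float = 0.28
    excess_noise: bool = False

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel size and frame interval must be positive")
        if self.read_noise_e < 0 or self.background_photons_per_px < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.gain <= 0:
            raise ValueError("gain must be positive")


@dataclass
class EmitterPairTruth:
    """Ground truth for one two-emitter complex.

    Positions are in nm in the image coordinate frame (origin at the center
    of pixel (0, 0); x along columns, y along rows).  ``bleach_frames`` give,
    per emitter, the first frame index at which the emitter is dark.
    """

    positions_nm: np.ndarray  # shape (2, 2): [(x1, y1), (x2, y2)]
    photons_per_frame: float
    bleach_frames: tuple[int, int]
    psf_fwhm_nm: float = 270.0
    species: str = ""
    complex_id: str = ""

    def __post_init__(self) -> None:
        self.positions_nm = np.asarray(self.positions_nm, dtype=float)
        if self.positions_nm.shape != (2, 2):
            raise ValueError("positions_nm must have shape (2, 2)")
        if min(self.bleach_frames) < 1:
            raise ValueError("bleach frames must be >= 1")
        if self.psf_fwhm_nm <= 0:
            raise ValueError("psf_fwhm_nm must be positive")

    @property
    def separation_nm(self) -> float:
        return float(np.hypot(*(self.positions_nm[0] - self.positions_nm[1])))


@dataclass(frozen=True)
class SpeciesMixtureSpec:
    """A mixture of complex species at fixed separations.

    ``weights`` are species probabilities (must sum to 1); each sampled
    complex is placed at its species separation with a uniformly random
    in-plane orientation.
    """

    labels: tuple[str, ...]
    separations_nm: tuple[float, ...]
    weights: tuple[float, ...]
    n_complexes: int
    photons_per_frame: float = 5000.0
    mean_bleach_frames: float = 25.0
    psf_fwhm_nm: float = 270.0

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.separations_nm) == len(self.weights)):
            raise ValueError("labels, separations and weights must align")
        if len(self.labels) == 0:
            raise ValueError("mixture must contain at least one species")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        if np.any(np.asarray(self.separations_nm) < 0):
            raise ValueError("separations must be non-negative")
        if self.n_complexes < 1:
            raise ValueError("n_complexes must be >= 1")


def default_species_mixture(
    n_complexes: int = 150,
    weights: tuple[float, ...] = (0.35, 0.30, 0.15, 0.12, 0.08),
) -> SpeciesMixtureSpec:
    """The five-species dimer-through-decamer scenario at dye-corrected
    separations, with populations decreasing with oligomer order."""
    return SpeciesMixtureSpec(
        labels=DEFAULT_SPECIES_LABELS,
        separations_nm=DEFAULT_SPECIES_SEPARATIONS_NM,
        weights=weights,
        n_complexes=n_complexes,
    )


def sample_species_mixture(
    spec: SpeciesMixtureSpec,
    seed: int,
    center_nm: tuple[float, float] = (700.0, 700.0),
) -> list[EmitterPairTruth]:
    """Draw complexes i.i.d. from the mixture, each centered near
    ``center_nm`` with random orientation and exponential bleach times."""
    rng = np.random.default_rng(seed)
    k = rng.choice(len(spec.labels), size=spec.n_complexes, p=spec.weights)
    out: list[EmitterPairTruth] = []
    for i, ki in enumerate(k):
        sep = spec.separations_nm[ki]
        theta = rng.uniform(0.0, 2.0 * np.pi)
        half = 0.5 * sep * np.array([np.cos(theta), np.sin(theta)])
        center = np.asarray(center_nm, dtype=float)
        # distinct exponential bleach times so two clean steps exist
        b = np.maximum(
            1, np.ceil(rng.exponential(spec.mean_bleach_frames, size=2)).astype(int)
        )
        if b[0] == b[1]:
            b[1] += 1
        out.append(
            EmitterPairTruth(
                positions_nm=np.array([center + half, center - half]),
                photons_per_frame=spec.photons_per_frame,
                bleach_frames=(int(b[0]), int(b[1])),
                psf_fwhm_nm=spec.psf_fwhm_nm,
                species=spec.labels[ki],
                complex_id=f"c{i:05d}",
            )
        )
    return out


def integrated_gaussian(
    shape: tuple[int, int], x_px: float, y_px: float, fwhm_px: float
) -> np.ndarray:
    """Pixel-area-integrated symmetric 2D Gaussian of unit total intensity.

    The value at pixel (row, col) is the integral of the Gaussian over the
    unit pixel square centered at (col, row); pixel (0, 0) is centered at
    the coordinate origin.
    """
    s = fwhm_px / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    rows = np.arange(shape[0])
    cols = np.arange(shape[1])
    fy = 0.5 * (
        erf((rows + 0.5 - y_px) / (np.sqrt(2) * s))
        - erf((rows - 0.5 - y_px) / (np.sqrt(2) * s))
    )
    fx = 0.5 * (
        erf((cols + 0.5 - x_px) / (np.sqrt(2) * s))
        - erf((cols - 0.5 - x_px) / (np.sqrt(2) * s))
    )
    return np.outer(fy, fx)


def render_spot_stack(
    truth: EmitterPairTruth,
    camera: CameraModel,
    n_frames: int | None = None,
    seed: int = 0,
    shape: tuple[int, int] = (15, 15),
    noise: bool = True,
) -> np.ndarray:
    """Render the image stack of one photobleaching two-emitter complex.

    Per frame, each unbleached emitter contributes an integrated Gaussian of
    its photon rate; shot noise, gain and read noise are applied when
    ``noise`` is on.  Emitters emit in frames [0, bleach_frame) and nothing
    after.  Returns a float array of shape (n_frames, *shape).
    """
    if truth.photons_per_frame <= 0:
        raise ValueError("photon rate must be positive")
    last = max(truth.bleach_frames)
    if n_frames is None:
        n_frames = last + 5
    if n_frames < last:
        raise ValueError("n_frames must cover the last bleach frame")

    rng = np.random.default_rng(seed)
    px = camera.pixel_size_nm
    spots = [
        integrated_gaussian(
            shape, truth.positions_nm[j, 0] / px, truth.positions_nm[j, 1] / px,
            truth.psf_fwhm_nm / px,
        )
        for j in range(2)
    ]
    stack = np.empty((n_frames, *shape), dtype=float)
    for t in range(n_frames):
        photons = np.full(shape, camera.background_photons_per_px, dtype=float)
        for j in range(2):
            if t < truth.bleach_frames[j]:
                photons += truth.photons_per_frame * spots[j]
        if noise:
            n_phot = rng.poisson(photons)
            if camera.excess_noise:
                # EM-register excess noise: Gamma(N, gain) given N photons
                # doubles the shot variance.
                out = np.where(
                    n_phot > 0, rng.gamma(np.maximum(n_phot, 1), camera.gain), 0.0
                )
            else:
                out = n_phot * camera.gain
            stack[t] = out + rng.normal(0.0, camera.read_noise_e, size=shape)
        else:
            stack[t] = photons * camera.gain
    return stack


def simulate_tracks(
    model: str,
    D_um2_per_s: float,
    n_tracks: int,
    n_steps: int,
    dt_s: float = 0.28,
    box_nm: float | None = None,
    seed: int = 0,
    dataset_id: str = "sim",
) -> list[Track]:
    """Simulate 2D single-particle tracks.

    ``model='brownian'``: Gaussian steps with per-axis variance 2 D dt.
    ``model='confined'``: the same steps reflected at the walls of a square
    box of side ``box_nm`` (long-time MSD plateau at box^2 / 3).
    """
    if D_um2_per_s < 0:
        raise ValueError("D must be non-negative")
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if model not in ("brownian", "confined"):
        raise ValueError(f"unknown motion model: {model!r}")
    if model == "confined":
        if box_nm is None or box_nm <= 0:
            raise ValueError("confined motion requires box_nm > 0")

    rng = np.random.default_rng(seed)
    step_sd_nm = np.sqrt(2.0 * D_um2_per_s * dt_s) * 1000.0
    times = np.arange(n_steps + 1) * dt_s
    tracks: list[Track] = []
    for i in range(n_tracks):
        steps = rng.normal(0.0, step_sd_nm, size=(n_steps, 2))
        if model == "brownian":
            pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        else:
            pos = np.empty((n_steps + 1, 2))
            pos[0] = rng.uniform(0.0, box_nm, size=2)
            for t in range(n_steps):
                pos[t + 1] = _reflect(pos[t] + steps[t], box_nm)
        tracks.append(
            Track(track_id=f"t{i:05d}", dataset_id=dataset_id,
                  times_s=times.copy(), positions_nm=pos)
        )
    return tracks


def _reflect(p: np.ndarray, box: float) -> np.ndarray:
    """Reflect a point into [0, box]^2 (billiard boundary)."""
    q = np.mod(p, 2.0 * box)
    return np.where(q > box, 2.0 * box - q, q)


def simulate_fret_dataset(
    h_over_R0: float,
    densities: list[float],
    n_donors_per_density: int = 10,
    lifetime_noise_cv: float = 0.0,
    tau_d_ns: float = 2.6,
    n_mc: int = 2000,
    seed: int = 0,
) -> list[FRETRecord]:
    """FRET records from the donor-above-acceptor-plane model.

    Each record carries the donor-only lifetime, a donor+acceptor lifetime
    set by the plane-model mean efficiency at (h, density) with optional
    multiplicative log-normal noise of the given CV, and the density.
    """
    if h_over_R0 <= 0:
        raise ValueError("h_over_R0 must be positive")
    densities = list(densities)
    if any(d < 0 for d in densities):
        raise ValueError("densities must be non-negative")
    rng = np.random.default_rng(seed)
    records: list[FRETRecord] = []
    for j, rho in enumerate(densities):
        e_model = simulate_plane_fret(
            h_over_R0, rho, n_mc=n_mc, seed=int(rng.integers(2**31))
        )
        for i in range(n_donors_per_density):
            tau_da = tau_d_ns * (1.0 - e_model)
            if lifetime_noise_cv > 0:
                s = np.sqrt(np.log1p(lifetime_noise_cv**2))
                tau_da *= rng.lognormal(-0.5 * s**2, s)
            records.append(
                FRETRecord(
                    tau_d_ns=tau_d_ns,
                    tau_da_ns=float(min(tau_da, tau_d_ns)),
                    density_per_R02=float(rho),
                    cell_id=f"d{j}_{i}",
                )
            )
    return records
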