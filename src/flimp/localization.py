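"""Two-emitter localization from photobleaching image stacks.

The measurement exploits single-step photobleaching: a diffraction-limited
spot containing two fluorophores shows an intensity time course with two
downward steps.  Frames before the first bleach see both emitters; frames
between the two bleaches see only the survivor, whose position pins down
one of the two centers.  A global least-squares seven-parameter fit —
{x1, y1, I1, x2, y2, I2, FWHM} over the mean image of the two-emitter
segment (sum of two pixel-integrated Gaussians, shared FWHM) and the mean
image of the one-emitter segment (the survivor alone) — recovers both
positions, from which the pair separation follows with a precision set by
the localization errors.  Per-emitter errors are estimated by parametric
bootstrap: the fitted model images are re-noised under the camera model and
refitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.special import erf
from skimage.feature import peak_local_max

__all__ = [
    "IntensityTrace",
    "StepSegmentation",
    "TwoEmitterFit",
    "TraceRejected",
    "detect_spots",
    "extract_trace",
    "detect_steps",
    "fit_two_emitters",
    "measured_separation",
    "measure_complex",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class TraceRejected(Exception):
    """Raised when a trace lacks the two-step bleaching structure."""


# ---------------------------------------------------------------------------
# spot detection and trace extraction


def detect_spots(
    frame: np.ndarray, min_snr: float = 5.0, min_sep_px: int = 5
) -> np.ndarray:
    """Candidate spot centers (row, col) in one frame.

    Local maxima of a difference-of-Gaussians band-pass image exceeding
    ``min_snr`` times the robust noise level, non-maximum-suppressed at
    ``min_sep_px``.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        return np.empty((0, 2), dtype=int)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    bp = ndimage.gaussian_filter(frame, 1.0) - ndimage.gaussian_filter(frame, 3.0)
    noise = 1.4826 * np.median(np.abs(bp - np.median(bp)))
    if noise == 0:
        noise = np.finfo(float).tiny
    return peak_local_max(
        bp, min_distance=min_sep_px, threshold_abs=min_snr * noise,
        exclude_border=False,
    )


@dataclass
class IntensityTrace:
    """Per-frame integrated intensity and centroid of one spot."""

    complex_id: str
    frames: np.ndarray
    intensities: np.ndarray
    centroids_px: np.ndarray  # (n, 2) as (x, y); NaN where no signal

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")


def extract_trace(
    stack: np.ndarray,
    spot_rc: tuple[int, int],
    radius_px: int = 5,
    complex_id: str = "",
) -> IntensityTrace:
    """Background-subtracted integrated intensity and centroid per frame.

    The background per frame is the median of the pixels outside the
    extraction disc; the centroid is intensity-weighted over the disc after
    background subtraction (clipped at zero).
    """
    stack = np.asarray(stack, dtype=float)
    n, h, w = stack.shape
    r0, c0 = int(spot_rc[0]), int(spot_rc[1])
    if not (radius_px <= r0 < h - radius_px and radius_px <= c0 < w - radius_px):
        raise ValueError("spot too close to the image edge for this radius")
    rows, cols = np.ogrid[:h, :w]
    disc = (rows - r0) ** 2 + (cols - c0) ** 2 <= radius_px**2
    xs = np.broadcast_to(cols, (h, w))[disc].astype(float)
    ys = np.broadcast_to(rows, (h, w))[disc].astype(float)

    intens = np.empty(n)
    cents = np.full((n, 2), np.nan)
    for t in range(n):
        frame = stack[t]
        bg = np.median(frame[~disc])
        vals = np.clip(frame[disc] - bg, 0.0, None)
        total = vals.sum()
        intens[t] = (frame[disc] - bg).sum()
        if total > 0:
            cents[t] = (vals @ xs / total, vals @ ys / total)
    return IntensityTrace(
        complex_id=complex_id, frames=np.arange(n), intensities=intens,
        centroids_px=cents,
    )


# ---------------------------------------------------------------------------
# change-point detection


def _binary_segmentation(y: np.ndarray, penalty: float) -> list[int]:
    """Change points by recursive binary segmentation on squared-error cost.

    A split is accepted when it lowers the within-segment sum of squares by
    more than ``penalty``.  Returns sorted interior change-point indices
    (each the first index of a new segment).
    """
    def sse(a: int, b: int) -> float:
        seg = y[a:b]
        return float(((seg - seg.mean()) ** 2).sum()) if b > a else 0.0

    def best_split(a: int, b: int) -> tuple[float, int]:
        if b - a < 2:
            return 0.0, -1
        seg = y[a:b]
        csum = np.cumsum(seg)
        csq = np.cumsum(seg**2)
        n = b - a
        k = np.arange(1, n)
        left = csq[:-1] - csum[:-1] ** 2 / k
        rsum = csum[-1] - csum[:-1]
        rsq = csq[-1] - csq[:-1]
        right = rsq - rsum**2 / (n - k)
        total = sse(a, b)
        gains = total - (left + right)
        i = int(np.argmax(gains))
        return float(gains[i]), a + i + 1

    points: list[int] = []
    stack = [(0, len(y))]
    while stack:
        a, b = stack.pop()
        gain, split = best_split(a, b)
        if split >= 0 and gain > penalty:
            points.append(split)
            stack.append((a, split))
            stack.append((split, b))
    return sorted(points)


@dataclass
class StepSegmentation:
    """Retained two-step bleaching structure of an intensity trace.

    ``two_emitter`` and ``one_emitter`` are (start, stop) frame ranges for
    the last two non-zero intensity levels; ``zero`` covers the fully
    bleached tail.  ``n_steps`` counts all downward steps detected before
    trimming to the lowest two.
    """

    change_points: list[int]
    levels: list[float]
    n_steps: int
    two_emitter: tuple[int, int]
    one_emitter: tuple[int, int]
    zero: tuple[int, int]


def detect_steps(
    trace: IntensityTrace, penalty: float | None = None
) -> StepSegmentation:
    """Segment a trace into constant intensity levels and select the
    two-step bleaching portion.

    The penalty defaults to 2 ln(n) times the noise variance estimated from
    first differences (robust MAD).  Traces without at least two downward
    steps ending near zero are rejected — they signal a monomer, incomplete
    bleaching, or no signal.  When more than two downward steps occur, only
    the lowest two non-zero levels are retained.
    """
    y = trace.intensities
    n = len(y)
    if n < 10:
        raise ValueError("trace must have at least 10 frames")
    diffs = np.diff(y)
    noise_sd = 1.4826 * np.median(np.abs(diffs - np.median(diffs))) / np.sqrt(2.0)
    if noise_sd == 0:
        noise_sd = max(1e-12, 1e-9 * np.abs(y).max())
    if penalty is None:
        penalty = 2.0 * np.log(n) * noise_sd**2

    cps = _binary_segmentation(y, penalty)
    bounds = [0, *cps, n]
    levels = [float(y[a:b].mean()) for a, b in zip(bounds[:-1], bounds[1:])]

    # merge spurious splits: adjacent levels closer than the noise scale,
    # or differing by a small fraction of the level itself — a bleaching
    # step removes a whole emitter's intensity, so sub-20% level changes
    # between bright segments are noise, not photophysics
    def _mergeable(l0: float, l1: float) -> bool:
        if abs(l1 - l0) < 3.0 * noise_sd:
            return True
        bright = min(abs(l0), abs(l1)) > 4.0 * noise_sd
        return bright and abs(l1 - l0) < 0.2 * max(abs(l0), abs(l1))

    merged = True
    while merged and len(levels) > 1:
        merged = False
        for i in range(len(levels) - 1):
            if _mergeable(levels[i], levels[i + 1]):
                a, b = bounds[i], bounds[i + 2]
                bounds.pop(i + 1)
                levels[i] = float(y[a:b].mean())
                levels.pop(i + 1)
                merged = True
                break
    cps = bounds[1:-1]

    if len(levels) < 3:
        raise TraceRejected("fewer than two bleaching steps detected")

    # a level is "zero" when consistent with background noise
    zero_tol = max(4.0 * noise_sd, 0.02 * max(levels))
    if abs(levels[-1]) > zero_tol:
        raise TraceRejected("trace does not decay to zero")
    down_steps = sum(
        1 for l0, l1 in zip(levels[:-1], levels[1:]) if l1 < l0 - 2 * noise_sd
    )
    if down_steps < 2:
        raise TraceRejected("fewer than two downward steps")

    # walk back from the zero tail: the last two non-zero, decreasing levels
    i_zero = len(levels) - 1
    while i_zero > 0 and abs(levels[i_zero - 1]) <= zero_tol:
        i_zero -= 1
    if i_zero < 2:
        raise TraceRejected("no two non-zero levels before the zero tail")
    i_one, i_two = i_zero - 1, i_zero - 2
    if not (levels[i_two] > levels[i_one] > zero_tol):
        raise TraceRejected("retained levels are not strictly decreasing")

    return StepSegmentation(
        change_points=cps,
        levels=[levels[i_two], levels[i_one], levels[-1]],
        n_steps=down_steps,
        two_emitter=(bounds[i_two], bounds[i_two + 1]),
        one_emitter=(bounds[i_one], bounds[i_one + 1]),
        zero=(bounds[i_zero], n),
    )


# ---------------------------------------------------------------------------
# the global seven-parameter fit


def _axis_profiles(coords: np.ndarray, x0: float, s: float):
    """Pixel-integrated 1D Gaussian profile and its derivatives.

    Returns (g, dg/dx0, dg/ds) over integer pixel coordinates ``coords``.
    """
    a = (coords + 0.5 - x0) / s
    b = (coords - 0.5 - x0) / s
    g = 0.5 * (erf(a / np.sqrt(2)) - erf(b / np.sqrt(2)))
    ea = np.exp(-0.5 * a**2)
    eb = np.exp(-0.5 * b**2)
    norm = 1.0 / (np.sqrt(2.0 * np.pi) * s)
    dg_dx = -norm * (ea - eb)
    dg_ds = -norm * (a * ea - b * eb)
    return g, dg_dx, dg_ds


def _two_emitter_residuals(theta, A, B, rows, cols, share_intensity=True):
    """Residuals and analytic Jacobian for the joint two-segment fit."""
    x1, y1, I1, x2, y2, I2, fwhm = theta
    s = max(fwhm, 1e-3) / _FWHM_TO_SIGMA
    gx1, dgx1, dsx1 = _axis_profiles(cols, x1, s)
    gy1, dgy1, dsy1 = _axis_profiles(rows, y1, s)
    gx2, dgx2, dsx2 = _axis_profiles(cols, x2, s)
    gy2, dgy2, dsy2 = _axis_profiles(rows, y2, s)

    spot1 = np.outer(gy1, gx1)
    spot2 = np.outer(gy2, gx2)
    rA = (I1 * spot1 + I2 * spot2 - A).ravel()
    rB = (I2 * spot2 - B).ravel()
    resid = np.concatenate([rA, rB])

    nA = A.size
    J = np.zeros((nA + B.size, 7))
    d_spot1_f = (np.outer(dsy1, gx1) + np.outer(gy1, dsx1)) / _FWHM_TO_SIGMA
    d_spot2_f = (np.outer(dsy2, gx2) + np.outer(gy2, dsx2)) / _FWHM_TO_SIGMA
    J[:nA, 0] = (I1 * np.outer(gy1, dgx1)).ravel()
    J[:nA, 1] = (I1 * np.outer(dgy1, gx1)).ravel()
    J[:nA, 2] = spot1.ravel()
    J[:nA, 3] = (I2 * np.outer(gy2, dgx2)).ravel()
    J[:nA, 4] = (I2 * np.outer(dgy2, gx2)).ravel()
    J[:nA, 5] = spot2.ravel()
    J[:nA, 6] = (I1 * d_spot1_f + I2 * d_spot2_f).ravel()
    J[nA:, 3] = (I2 * np.outer(gy2, dgx2)).ravel()
    J[nA:, 4] = (I2 * np.outer(dgy2, gx2)).ravel()
    J[nA:, 5] = spot2.ravel()
    J[nA:, 6] = (I2 * d_spot2_f).ravel()
    return resid, J


@dataclass
class TwoEmitterFit:
    """Result of the global seven-parameter two-emitter fit.

    Emitter 2 is the survivor of the first bleach (its identity is fixed by
    the one-emitter segment, not by intensity ordering).  Positions and
    errors are in nm; ``sigma1_nm``/``sigma2_nm`` are per-axis isotropic
    localization errors of each emitter from the parametric bootstrap, and
    ``sigma_pair_nm`` is the per-axis error of the separation vector taken
    from the joint bootstrap distribution.  Because the two positions are
    fitted jointly their errors are correlated, so the pair error is
    measured directly rather than as sqrt(sigma1^2 + sigma2^2) (the two
    agree when the estimates are uncorrelated).
    """

    x1_nm: float
    y1_nm: float
    x2_nm: float
    y2_nm: float
    I1: float
    I2: float
    fwhm_nm: float
    sigma1_nm: float
    sigma2_nm: float
    sigma_pair_nm: float
    converged: bool
    degenerate: bool
    n_boot: int
    complex_id: str = ""

    @property
    def separation_nm(self) -> float:
        return float(np.hypot(self.x1_nm - self.x2_nm, self.y1_nm - self.y2_nm))


def _solve(theta0, A, B, rows, cols):
    res = least_squares(
        lambda th: _two_emitter_residuals(th, A, B, rows, cols)[0],
        theta0,
        jac=lambda th: _two_emitter_residuals(th, A, B, rows, cols)[1],
        method="lm",
        xtol=1e-10,
        max_nfev=200,
    )
    return res.x, res.status > 0


def _initial_guess(A, B, rows, cols, fwhm0_px):
    """Moment-based starting point: survivor from segment B, partner from
    the photometric centroid surplus of segment A."""
    IB = max(B.sum(), 1e-6)
    x2 = float((B.sum(axis=0) @ cols) / IB)
    y2 = float((B.sum(axis=1) @ rows) / IB)
    IA = max(A.sum(), 1e-6)
    xA = float((A.sum(axis=0) @ cols) / IA)
    yA = float((A.sum(axis=1) @ rows) / IA)
    I1 = max(IA - IB, 0.2 * IA)
    x1 = xA + (xA - x2) * IB / I1
    y1 = yA + (yA - y2) * IB / I1
    return np.array([x1, y1, I1, x2, y2, IB, fwhm0_px])


def fit_two_emitters(
    stack: np.ndarray,
    segmentation: StepSegmentation,
    camera,
    n_boot: int = 100,
    seed: int = 0,
    fwhm0_nm: float = 270.0,
    complex_id: str = "",
    degenerate_sep_px: float = 0.02,
) -> TwoEmitterFit:
    """Global least-squares seven-parameter fit of one bleaching complex.

    Fits the mean image of the two-emitter segment (sum of two integrated
    Gaussians) jointly with the mean image of the one-emitter segment (the
    survivor alone), sharing FWHM and the survivor's intensity between
    segments.  Localization errors come from ``n_boot`` parametric-bootstrap
    refits of re-noised model images.
    """
    stack = np.asarray(stack, dtype=float)
    _, h, w = stack.shape
    rows = np.arange(h, dtype=float)
    cols = np.arange(w, dtype=float)
    px = camera.pixel_size_nm

    a0, a1 = segmentation.two_emitter
    b0, b1 = segmentation.one_emitter
    nA, nB = a1 - a0, b1 - b0
    meanA = stack[a0:a1].mean(axis=0)
    meanB = stack[b0:b1].mean(axis=0)
    # background from the mean of the fully bleached tail (median over px)
    z0, z1 = segmentation.zero
    bg = float(np.median(stack[z0:z1])) if z1 > z0 else float(np.median(meanB))
    A = meanA - bg
    B = meanB - bg

    theta0 = _initial_guess(A, B, rows, cols, fwhm0_nm / px)
    theta, ok = _solve(theta0, A, B, rows, cols)
    x1, y1, I1, x2, y2, I2, fwhm = theta
    sep_px = float(np.hypot(x1 - x2, y1 - y2))
    degenerate = sep_px < degenerate_sep_px or I1 <= 0 or I2 <= 0

    sigma1 = sigma2 = sigma_pair = np.nan
    if ok and not degenerate and n_boot > 0:
        rng = np.random.default_rng(seed)
        resid, _ = _two_emitter_residuals(theta, A, B, rows, cols)
        modelA = (A - resid[: A.size].reshape(A.shape)) + bg
        modelB = (B - resid[A.size:].reshape(B.shape)) + bg
        # Gaussian approximation to the noise of an nA/nB-frame mean image
        shot = 2.0 if getattr(camera, "excess_noise", False) else 1.0
        sdA = np.sqrt(
            shot * camera.gain * np.clip(modelA, 0, None) / nA
            + camera.read_noise_e**2 / nA
        )
        sdB = np.sqrt(
            shot * camera.gain * np.clip(modelB, 0, None) / nB
            + camera.read_noise_e**2 / nB
        )
        boots = np.empty((n_boot, 4))
        for b in range(n_boot):
            Ab = modelA + rng.normal(0.0, sdA) - bg
            Bb = modelB + rng.normal(0.0, sdB) - bg
            tb, _ = _solve(theta, Ab, Bb, rows, cols)
            boots[b] = tb[[0, 1, 3, 4]]
        sigma1 = np.sqrt(0.5 * (boots[:, 0].var() + boots[:, 1].var())) * px
        sigma2 = np.sqrt(0.5 * (boots[:, 2].var() + boots[:, 3].var())) * px
        # pair error from the joint distribution of the separation vector
        dx = boots[:, 0] - boots[:, 2]
        dy = boots[:, 1] - boots[:, 3]
        sigma_pair = np.sqrt(0.5 * (dx.var() + dy.var())) * px

    return TwoEmitterFit(
        x1_nm=x1 * px, y1_nm=y1 * px, x2_nm=x2 * px, y2_nm=y2 * px,
        I1=float(I1), I2=float(I2),
        fwhm_nm=float(fwhm * px),
        sigma1_nm=float(sigma1), sigma2_nm=float(sigma2),
        sigma_pair_nm=float(sigma_pair),
        converged=bool(ok), degenerate=bool(degenerate),
        n_boot=n_boot, complex_id=complex_id,
    )


def measured_separation(fit: TwoEmitterFit) -> tuple[float, float]:
    """(d, sigma_pair) in nm: the Euclidean distance between the fitted
    centers and the combined pair localization error.

    The pair error comes from the joint bootstrap distribution of the
    separation vector; it equals sqrt(sigma1^2 + sigma2^2) when the two
    position estimates are uncorrelated and is used as the Rice scale of
    the measurement."""
    if not fit.converged or fit.degenerate:
        raise ValueError("fit did not converge or is degenerate")
    sig = fit.sigma_pair_nm
    if not np.isfinite(sig):
        sig = float(np.hypot(fit.sigma1_nm, fit.sigma2_nm))
    return fit.separation_nm, sig


def measure_complex(
    stack: np.ndarray,
    camera,
    n_boot: int = 100,
    seed: int = 0,
    radius_px: int = 6,
    complex_id: str = "",
) -> TwoEmitterFit:
    """Convenience path for a single-complex stack: detect the spot in the
    first frame, extract the trace, segment the bleaching steps, and run
    the seven-parameter fit.  Raises :class:`TraceRejected` when the trace
    lacks two clean steps."""
    stack = np.asarray(stack, dtype=float)
    spots = detect_spots(stack[0])
    if len(spots) == 0:
        raise TraceRejected("no spot detected in the first frame")
    # brightest candidate
    order = np.argsort([-stack[0][r, c] for r, c in spots])
    r0, c0 = spots[order[0]]
    h, w = stack.shape[1:]
    radius = min(radius_px, r0, c0, h - 1 - r0, w - 1 - c0)
    trace = extract_trace(stack, (r0, c0), radius_px=radius, complex_id=complex_id)
    seg = detect_steps(trace)
    return fit_two_emitters(
        stack, seg, camera, n_boot=n_boot, seed=seed, complex_id=complex_id
    )
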