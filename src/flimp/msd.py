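"""Mean squared displacement analysis of single-particle tracks.

MSD(dT) = < |r_i(T + dT) - r_i(T)|^2 >, averaged over all (overlapping)
pairs of points separated by dT within each track, then over tracks.  The
average instantaneous diffusion coefficient comes from a straight line
through the first two MSD points: D = m / 4 in 2D, m the fitted gradient.
Errors are bootstrap: the MSD computation is repeated on synthetic data
sets built by resampling, with replacement, the displacement pairs within
each track, the tracks within each data set, and the data sets themselves;
per-lag standard deviations across replicates are the MSD error bars and
the standard deviation of the refitted D is sigma(D).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Track", "MSDResults", "msd_curve", "diffusion_coefficient",
           "MSDAnalysis", "bootstrap_msd"]

NM2_PER_UM2 = 1.0e6


@dataclass
class Track:
    """A 2D single-particle track (positions in nm, times in s)."""

    track_id: str
    dataset_id: str
    times_s: np.ndarray
    positions_nm: np.ndarray  # shape (n, 2)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.positions_nm = np.asarray(self.positions_nm, dtype=float)
        if self.times_s.ndim != 1 or len(self.times_s) < 2:
            raise ValueError("a track needs at least two time points")
        if self.positions_nm.shape != (len(self.times_s), 2):
            raise ValueError("positions must be (n, 2) matching times")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def dt_s(self) -> float:
        return float(self.times_s[1] - self.times_s[0])

    def squared_displacements(self, lag: int) -> np.ndarray:
        """All overlapping squared displacements at integer lag ``lag``."""
        if lag < 1 or lag >= len(self.times_s):
            return np.empty(0)
        diff = self.positions_nm[lag:] - self.positions_nm[:-lag]
        return np.einsum("ij,ij->i", diff, diff)


def msd_curve(tracks: list[Track], max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """MSD over all qualifying pairs across all tracks.

    Returns (lags_s, msd_nm2) for integer lags 1..max_lag.  Requires at
    least one track long enough for every requested lag.
    """
    if not tracks:
        raise ValueError("track list is empty")
    dt = tracks[0].dt_s
    n_max = max(len(t.times_s) for t in tracks)
    if max_lag >= n_max:
        raise ValueError("max_lag exceeds the longest track")
    msd = np.zeros(max_lag)
    for k in range(1, max_lag + 1):
        total, count = 0.0, 0
        for t in tracks:
            sq = t.squared_displacements(k)
            total += sq.sum()
            count += sq.size
        msd[k - 1] = total / count if count else np.nan
    return np.arange(1, max_lag + 1) * dt, msd


def diffusion_coefficient(
    lags_s: np.ndarray, msd_nm2: np.ndarray, through_origin: bool = False
) -> tuple[float, float]:
    """(D in um^2/s, gradient m in nm^2/s) from the first two MSD points.

    Default is an unconstrained straight line through the two points;
    ``through_origin`` instead least-squares fits m through (0, 0).
    """
    if len(lags_s) < 2:
        raise ValueError("need at least two MSD points")
    t1, t2 = float(lags_s[0]), float(lags_s[1])
    y1, y2 = float(msd_nm2[0]), float(msd_nm2[1])
    if t2 == t1:
        raise ValueError("identical lags")
    if through_origin:
        m = (t1 * y1 + t2 * y2) / (t1**2 + t2**2)
    else:
        m = (y2 - y1) / (t2 - t1)
    return m / 4.0 / NM2_PER_UM2, m


class MSDAnalysis:
    """MSD model over one or more data sets of tracks.

    ``fit()`` computes the pooled MSD curve, the two-point diffusion
    coefficient, and triple-bootstrap errors (pairs within tracks, tracks
    within data sets, data sets).
    """

    def __init__(self, tracks: list[Track]):
        if not tracks:
            raise ValueError("track list is empty")
        self.tracks = list(tracks)
        self.datasets: dict[str, list[Track]] = {}
        for t in self.tracks:
            self.datasets.setdefault(t.dataset_id, []).append(t)

    def fit(
        self,
        max_lag: int = 10,
        n_boot: int = 200,
        seed: int = 0,
        through_origin: bool = False,
        resample_pairs: bool = True,
    ) -> "MSDResults":
        lags, msd = msd_curve(self.tracks, max_lag)
        D, m = diffusion_coefficient(lags, msd, through_origin)
        msd_sd = np.full(max_lag, np.nan)
        sigma_D = np.nan
        if n_boot:
            msd_sd, sigma_D = bootstrap_msd(
                self.tracks, max_lag, n_boot=n_boot, seed=seed,
                through_origin=through_origin, resample_pairs=resample_pairs,
            )
        return MSDResults(
            lags_s=lags, msd_nm2=msd, msd_sd_nm2=msd_sd,
            D_um2_per_s=D, sigma_D_um2_per_s=sigma_D, m_nm2_per_s=m,
            n_tracks=len(self.tracks), n_boot=n_boot,
        )


def bootstrap_msd(
    tracks: list[Track],
    max_lag: int,
    n_boot: int = 200,
    seed: int = 0,
    through_origin: bool = False,
    resample_pairs: bool = True,
) -> tuple[np.ndarray, float]:
    """Triple-bootstrap errors for the MSD curve and for D.

    Each replicate resamples with replacement (i) the data sets, (ii) the
    tracks within each sampled data set, and (iii) the displacement pairs
    within each sampled track at every lag ("time points within each
    track", realized at the pair level so the lag structure survives).
    Returns (per-lag sd of MSD, sd of D).
    """
    if len(tracks) < 2:
        raise ValueError("bootstrap needs at least two tracks")
    if n_boot < 10:
        raise ValueError("n_boot must be at least 10")
    rng = np.random.default_rng(seed)
    dt = tracks[0].dt_s

    datasets: dict[str, list[Track]] = {}
    for t in tracks:
        datasets.setdefault(t.dataset_id, []).append(t)
    ds_ids = list(datasets)

    # Precompute squared-displacement arrays per (track, lag).
    pair_values = {
        id(t): [t.squared_displacements(k) for k in range(1, max_lag + 1)]
        for t in tracks
    }

    lags_s = np.arange(1, max_lag + 1) * dt
    msd_b = np.zeros((n_boot, max_lag))
    D_b = np.zeros(n_boot)
    for b in range(n_boot):
        total = np.zeros(max_lag)
        count = np.zeros(max_lag, dtype=int)
        chosen_ds = rng.choice(ds_ids, size=len(ds_ids), replace=True)
        for ds in chosen_ds:
            pool = datasets[ds]
            chosen = rng.integers(0, len(pool), size=len(pool))
            for j in chosen:
                vals = pair_values[id(pool[j])]
                for k in range(max_lag):
                    v = vals[k]
                    if v.size == 0:
                        continue
                    if resample_pairs:
                        idx = rng.integers(0, v.size, size=v.size)
                        total[k] += v[idx].sum()
                    else:
                        total[k] += v.sum()
                    count[k] += v.size
        with np.errstate(invalid="ignore", divide="ignore"):
            msd_b[b] = np.where(count > 0, total / np.maximum(count, 1), np.nan)
        D_b[b], _ = diffusion_coefficient(lags_s, msd_b[b], through_origin)
    return np.nanstd(msd_b, axis=0), float(np.std(D_b))


@dataclass
class MSDResults:
    """MSD curve, diffusion coefficient and bootstrap uncertainties."""

    lags_s: np.ndarray
    msd_nm2: np.ndarray
    msd_sd_nm2: np.ndarray
    D_um2_per_s: float
    sigma_D_um2_per_s: float
    m_nm2_per_s: float
    n_tracks: int
    n_boot: int
    extra: dict = field(default_factory=dict)

    @property
    def msd_um2(self) -> np.ndarray:
        return self.msd_nm2 / NM2_PER_UM2

    def curvature_index(self) -> float:
        """Relative shortfall of the MSD at the largest lag below the line
        through the first two points.  Near 0 for linear (Brownian) curves,
        approaching -1 for the plateauing curves of confined motion."""
        if len(self.msd_nm2) < 3:
            raise ValueError("need >= 3 lags")
        linear = self.msd_nm2[0] + self.m_nm2_per_s * (
            self.lags_s[-1] - self.lags_s[0]
        )
        return float(self.msd_nm2[-1] / linear - 1.0)

    def is_concave_down(self, threshold: float = -0.1) -> bool:
        """Concave-down (confinement signature) when the curvature index
        falls below ``threshold``."""
        return self.curvature_index() < threshold

    def summary(self) -> str:
        rows = "\n".join(
            f"  {t:8.3f}  {m / NM2_PER_UM2:10.5f}  {s / NM2_PER_UM2:10.5f}"
            for t, m, s in zip(self.lags_s, self.msd_nm2, self.msd_sd_nm2)
        )
        return (
            "MSD analysis\n"
            "============\n"
            f"tracks: {self.n_tracks}   bootstrap replicates: {self.n_boot}\n"
            f"D = {self.D_um2_per_s:.4f} +/- {self.sigma_D_um2_per_s:.4f} um^2/s"
            f"  (m = {self.m_nm2_per_s / NM2_PER_UM2:.4f} um^2/s, D = m/4)\n"
            "  lag (s)    MSD (um^2)   sd (um^2)\n" + rows
        )
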