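"""Statistics of 2-D free-flight head tracks.

Consumes plain tabular tracks (frame, x, y) as exported by markerless video
tracking at 100 frames/s: RMS kinematics, a unit-stride sliding-window
tortuosity (40-frame windows), box-counting fractal dimension of the
linearly interpolated path, windowed Fourier power spectra, and the
contingency statistics of flight/roll incidence. A deterministic synthetic
track generator provides fixtures with known geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["Track", "IncidenceTable", "rms_kinematics", "sliding_tortuosity",
           "box_dimension", "segment_spectra", "incidence_chi_squared",
           "incidence_percentages", "rank_sum_compare", "generate_track",
           "DISPLACEMENT_EPS"]

#: windows with net displacement below this (input units) are degenerate
DISPLACEMENT_EPS = 1e-9


@dataclass(frozen=True)
class Track:
    """A planar head trajectory sampled at a fixed frame rate."""

    frames: np.ndarray  # consecutive integer frame indices
    x: np.ndarray
    y: np.ndarray
    fps: float = 100.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=int)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (len(frames) == len(x) == len(y)):
            raise ValueError("frames, x, y must have equal length")
        if len(frames) > 1 and not np.all(np.diff(frames) == 1):
            raise ValueError("frame indices must be consecutive "
                             "(gaps must be made explicit upstream)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.frames)

    @classmethod
    def from_csv(cls, path: str | Path, fps: float = 100.0) -> "Track":
        """Read a (frame, x, y) comma-separated table with header."""
        df = pd.read_csv(path)
        missing = {"frame", "x", "y"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        return cls(frames=df["frame"].to_numpy(), x=df["x"].to_numpy(),
                   y=df["y"].to_numpy(), fps=fps)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"frame": self.frames, "x": self.x,
                      "y": self.y}).to_csv(path, index=False)


@dataclass(frozen=True)
class IncidenceTable:
    """2x2 counts of treatment (rows) by binary outcome (columns)."""

    counts: np.ndarray
    row_labels: tuple[str, str] = ("experimental", "sham")
    col_labels: tuple[str, str] = ("yes", "no")

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (2, 2):
            raise ValueError("counts must be 2x2")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("grand total must be positive")
        object.__setattr__(self, "counts", counts)


def rms_kinematics(track: Track) -> tuple[float, float]:
    """(RMS speed, RMS acceleration magnitude) in input units per s / s^2.

    Central differences interior, one-sided at the ends.
    """
    if len(track) < 3:
        raise ValueError("need at least 3 frames")
    dt = 1.0 / track.fps
    vx = np.gradient(track.x, dt)
    vy = np.gradient(track.y, dt)
    ax = np.gradient(vx, dt)
    ay = np.gradient(vy, dt)
    rms_v = float(np.sqrt(np.mean(vx**2 + vy**2)))
    rms_a = float(np.sqrt(np.mean(ax**2 + ay**2)))
    return rms_v, rms_a


def sliding_tortuosity(track: Track, window: int = 40,
                       eps: float = DISPLACEMENT_EPS):
    """Unit-stride sliding-window tortuosity.

    For each start index i, path length over the ``window``-step segment
    divided by its net displacement. Windows with displacement below
    ``eps`` are degenerate: excluded from the mean and returned as NaN.

    Returns ``(values, mean, n_excluded)``.
    """
    n = len(track)
    if n <= window:
        raise ValueError(f"track length {n} must exceed window {window}")
    steps = np.hypot(np.diff(track.x), np.diff(track.y))
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    starts = np.arange(n - window)
    path = cum[starts + window] - cum[starts]
    disp = np.hypot(track.x[starts + window] - track.x[starts],
                    track.y[starts + window] - track.y[starts])
    values = np.full(len(starts), np.nan)
    ok = disp > eps
    values[ok] = path[ok] / disp[ok]
    n_excluded = int(np.sum(~ok))
    if not np.any(ok):
        raise ValueError("all windows degenerate (no net displacement)")
    return values, float(np.nanmean(values)), n_excluded


def _rasterize(track: Track, grid: int) -> np.ndarray:
    """Binary image of the linearly interpolated path on a grid."""
    from skimage.draw import line

    x, y = track.x, track.y
    span = max(x.max() - x.min(), y.max() - y.min())
    if span <= 0:
        raise ValueError("degenerate bounding box")
    pad = 0.02 * span
    scale = (grid - 1) / (span + 2 * pad)  # isotropic: preserves geometry
    col = np.round((x - x.min() + pad) * scale).astype(int)
    row = np.round((y - y.min() + pad) * scale).astype(int)
    img = np.zeros((grid, grid), dtype=bool)
    for i in range(len(col) - 1):
        rr, cc = line(row[i], col[i], row[i + 1], col[i + 1])
        img[rr, cc] = True
    return img


def box_dimension(track: Track, sizes: Sequence[int] | None = None,
                  grid: int = 1024) -> float:
    """Box-counting dimension of the rasterized, interpolated path.

    Counts occupied boxes over a dyadic ladder of box sizes (default 2..256
    pixels on a 1024-pixel grid) and returns the least-squares slope of
    log N versus log(1/size). Near 1 for smooth curves, approaching 2 for
    plane-filling paths.
    """
    img = _rasterize(track, grid)
    if sizes is None:
        sizes = [2, 4, 8, 16, 32, 64, 128, 256]
    counts = []
    for s in sizes:
        if grid % s:
            raise ValueError(f"box size {s} must divide grid {grid}")
        blocks = img.reshape(grid // s, s, grid // s, s)
        counts.append(int(blocks.any(axis=(1, 3)).sum()))
    slope, _, _, _, _ = stats.linregress(np.log(1.0 / np.asarray(sizes, float)),
                                         np.log(counts))
    return float(slope)


def segment_spectra(track: Track, window: int = 40):
    """Mean one-sided power spectrum over non-overlapping segments.

    Power is normalized so the spectrum of each segment sums to its mean
    squared signal (Parseval); x- and y-components are summed. Returns
    ``(freqs_hz, power)``.
    """
    n = len(track)
    if n <= window:
        raise ValueError(f"track length {n} must exceed window {window}")
    n_seg = n // window
    freqs = np.fft.rfftfreq(window, d=1.0 / track.fps)
    power = np.zeros(len(freqs))
    for comp in (track.x, track.y):
        segs = comp[:n_seg * window].reshape(n_seg, window)
        spec = np.fft.rfft(segs, axis=1)
        p = np.abs(spec)**2 / window**2
        # one-sided doubling (DC and Nyquist appear once)
        p[:, 1:] *= 2.0
        if window % 2 == 0:
            p[:, -1] /= 2.0
        power += p.mean(axis=0)
    return freqs, power


def incidence_chi_squared(table: IncidenceTable) -> tuple[float, int, float]:
    """Pearson chi-squared without continuity correction, df = 1.

    The continuity correction is deliberately off: the printed incidence
    statistics use the uncorrected Pearson form.
    """
    counts = table.counts
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero marginal total")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def incidence_percentages(table: IncidenceTable) -> dict:
    """Row-wise success percentages, rounded to one decimal."""
    counts = table.counts
    if np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero row total")
    out = {}
    for lab, row in zip(table.row_labels, counts):
        out[lab] = round(100.0 * row[0] / row.sum(), 1)
    return out


def rank_sum_compare(group_a: Sequence[float], group_b: Sequence[float],
                     alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon rank-sum test: (W, p).

    Exact null distribution when both samples are free of ties and small
    enough (scipy's exact method); normal approximation with tie correction
    otherwise. W is the rank-sum statistic of the first group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        raise ValueError("degenerate input: all values tied")
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (not has_ties and max(len(a), len(b)) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    w = float(res.statistic + len(a) * (len(a) + 1) / 2)  # U -> rank sum
    return w, float(res.pvalue)


def generate_track(kind: str, n_frames: int = 400, fps: float = 100.0,
                   seed: int = 0, speed: float = 1.0, radius: float = 1.0,
                   freq_hz: float = 5.0, amplitude: float = 1.0,
                   noise_sd: float = 0.0, smoothness: float = 10.0) -> Track:
    """Deterministic synthetic tracks for fixtures.

    Kinds: ``straight`` (constant velocity), ``circle`` (radius, angular
    rate = speed/radius), ``sinusoid`` (drift in x, tone at ``freq_hz`` in
    y), ``smooth-random`` (integrated Gaussian velocity smoothed over
    ``smoothness`` frames). Additive Gaussian position noise ``noise_sd``.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / fps
    if kind == "straight":
        x = speed * t
        y = 0.5 * speed * t
    elif kind == "circle":
        omega = speed / radius
        x = radius * np.cos(omega * t)
        y = radius * np.sin(omega * t)
    elif kind == "sinusoid":
        x = speed * t
        y = amplitude * np.sin(2 * np.pi * freq_hz * t)
    elif kind == "smooth-random":
        from scipy.ndimage import gaussian_filter1d

        vx = gaussian_filter1d(rng.standard_normal(n_frames), smoothness)
        vy = gaussian_filter1d(rng.standard_normal(n_frames), smoothness)
        x = np.cumsum(vx) * speed / fps
        y = np.cumsum(vy) * speed / fps
    else:
        raise ValueError(f"unknown kind {kind!r}")
    if noise_sd > 0:
        x = x + rng.normal(0, noise_sd, n_frames)
        y = y + rng.normal(0, noise_sd, n_frames)
    return Track(frames=np.arange(n_frames), x=x, y=y, fps=fps)
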