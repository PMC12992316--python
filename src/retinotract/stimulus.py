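"""Binary checkerboard white-noise stimulus.

The stimulus is a 32x18-pixel binary checkerboard refreshed at 60 Hz in
which every pixel independently takes the value +1 ("white") or -1
("black"), under the constraint that each frame contains exactly as many
white as black pixels, keeping the overall luminance of every frame at the
mean intensity.  The movie covers 73 deg of azimuth by 44 deg of elevation,
centred on the animal's visual field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: stimulus grid (rows = elevation, cols = azimuth)
N_ROWS = 18
N_COLS = 32
N_PIXELS = N_ROWS * N_COLS

#: visual-field coverage of the stimulation area, degrees (azimuth, elevation)
STIM_EXTENT_DEG = (73.0, 44.0)

DEFAULT_FRAME_RATE = 60.0


@dataclass
class StimulusMovie:
    """A luminance-balanced binary noise movie with its screen geometry.

    Attributes
    ----------
    frames :
        ``(n_frames, 18, 32)`` int8 array with entries in {-1, +1}.
    frame_rate :
        Refresh rate in Hz.
    pixel_size_deg :
        Degrees per pixel along (azimuth, elevation).
    origin_deg :
        (azimuth, elevation) of the lower-left corner of pixel (0, 0);
        the default grid is centred on (0, 0) deg.
    """

    frames: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE
    pixel_size_deg: tuple[float, float] = (
        STIM_EXTENT_DEG[0] / N_COLS,
        STIM_EXTENT_DEG[1] / N_ROWS,
    )
    origin_deg: tuple[float, float] = (
        -STIM_EXTENT_DEG[0] / 2,
        -STIM_EXTENT_DEG[1] / 2,
    )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def dt_s(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def extent_deg(self) -> tuple[float, float, float, float]:
        """(az_min, az_max, el_min, el_max) of the stimulated area."""
        az0, el0 = self.origin_deg
        daz, del_ = self.pixel_size_deg
        return (az0, az0 + N_COLS * daz, el0, el0 + N_ROWS * del_)

    def pixel_centers_deg(self) -> tuple[np.ndarray, np.ndarray]:
        """Azimuth (32,) and elevation (18,) of pixel centres in degrees."""
        az0, el0 = self.origin_deg
        daz, del_ = self.pixel_size_deg
        az = az0 + (np.arange(N_COLS) + 0.5) * daz
        el = el0 + (np.arange(N_ROWS) + 0.5) * del_
        return az, el

    def covers(self, az_deg: float, el_deg: float) -> bool:
        az_min, az_max, el_min, el_max = self.extent_deg
        return (az_min <= az_deg <= az_max) and (el_min <= el_deg <= el_max)


def generate_checkerboard(
    n_frames: int,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    frame_rate: float = DEFAULT_FRAME_RATE,
) -> StimulusMovie:
    """Generate a luminance-balanced binary checkerboard movie.

    Each frame is an independent random permutation of a fixed vector of
    288 white (+1) and 288 black (-1) pixels, which satisfies the
    constant-luminance constraint exactly while keeping the marginal
    distribution of every pixel balanced.

    Parameters
    ----------
    n_frames :
        Number of frames; 15 min at 60 Hz corresponds to 54,000.
    seed :
        Seed for the pseudo-random generator (ignored if ``rng`` given).
    rng :
        Optional generator to draw from, for callers that manage seeding.
    """
    if n_frames < 1:
        raise ValueError(f"n_frames must be >= 1, got {n_frames}")
    if rng is None:
        rng = np.random.default_rng(seed)
    base = np.empty(N_PIXELS, dtype=np.int8)
    base[: N_PIXELS // 2] = 1
    base[N_PIXELS // 2 :] = -1
    flat = np.tile(base, (n_frames, 1))
    flat = rng.permuted(flat, axis=1)
    return StimulusMovie(
        frames=flat.reshape(n_frames, N_ROWS, N_COLS), frame_rate=frame_rate
    )
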