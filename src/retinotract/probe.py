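"""Multishank silicon-probe geometry.

Coordinate convention (micrometres): the first two axes (x, y) span the
cross-section of the recorded structure and map onto (azimuth, elevation)
under the retinotopic gradient; z runs along the fibre bundle / insertion
axis, along which the represented position does not change.  Shanks are
therefore spread along z and recording sites along y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ProbeGeometry:
    """Recording-site layout.

    Attributes
    ----------
    site_positions :
        ``(n_sites, 3)`` float array of site coordinates in micrometres.
    n_shanks, sites_per_shank :
        Layout counts (informational; ``site_positions`` is authoritative).
    """

    site_positions: np.ndarray
    n_shanks: int
    sites_per_shank: int

    def __post_init__(self) -> None:
        pos = np.asarray(self.site_positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("site_positions must have shape (n_sites, 3)")
        uniq = np.unique(pos, axis=0)
        if uniq.shape[0] != pos.shape[0]:
            raise ValueError("recording-site positions must be distinct")
        self.site_positions = pos

    @property
    def n_sites(self) -> int:
        return self.site_positions.shape[0]

    def site_distance_um(self, i: int, j: int) -> float:
        return float(
            np.linalg.norm(self.site_positions[i] - self.site_positions[j])
        )


def default_probe(
    n_shanks: int = 4,
    sites_per_shank: int = 8,
    shank_pitch_um: float = 200.0,
    site_pitch_um: float = 25.0,
) -> ProbeGeometry:
    """Build the default 4-shank x 8-site probe.

    Shanks are spaced ``shank_pitch_um`` apart along z; on each shank the
    sites are spaced ``site_pitch_um`` apart along y, centred on y = 0.
    """
    ys = (np.arange(sites_per_shank) - (sites_per_shank - 1) / 2) * site_pitch_um
    zs = (np.arange(n_shanks) - (n_shanks - 1) / 2) * shank_pitch_um
    pos = np.array([(0.0, y, z) for z in zs for y in ys])
    return ProbeGeometry(pos, n_shanks=n_shanks, sites_per_shank=sites_per_shank)
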