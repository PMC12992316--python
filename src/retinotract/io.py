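"""HDF5 container for one simulated session.

Layout::

    /stimulus/frames                int8 (n_frames, 18, 32)
    /stimulus attrs                 frame_rate, pixel_size_deg, origin_deg
    /probe/site_positions           float (n_sites, 3)
    /units/<id>/spike_times         float (n_spikes,)
    /units/<id>/site_amplitudes     float (n_sites,)
    /units/<id> attrs               dominant_site, rf_outside_stim
    /truth/*                        ground-truth arrays for test oracles

Datasets are written with ``track_times=False`` so identical sessions
serialise to identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .population import GroundTruthPopulation
from .probe import ProbeGeometry
from .simulate import SpikeData
from .stimulus import StimulusMovie


@dataclass
class Recording:
    """One session: stimulus, probe, spikes and (synthetic) ground truth."""

    stimulus: StimulusMovie
    probe: ProbeGeometry
    spikes: SpikeData
    truth: GroundTruthPopulation | None = None

    @property
    def n_units(self) -> int:
        return self.spikes.n_units


def _w(group, name, data):
    group.create_dataset(name, data=data, track_times=False)


def save_recording(path, rec: Recording) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("stimulus")
        _w(g, "frames", rec.stimulus.frames.astype(np.int8))
        g.attrs["frame_rate"] = rec.stimulus.frame_rate
        g.attrs["pixel_size_deg"] = rec.stimulus.pixel_size_deg
        g.attrs["origin_deg"] = rec.stimulus.origin_deg

        g = f.create_group("probe")
        _w(g, "site_positions", rec.probe.site_positions)
        g.attrs["n_shanks"] = rec.probe.n_shanks
        g.attrs["sites_per_shank"] = rec.probe.sites_per_shank

        units = f.create_group("units")
        units.attrs["duration_s"] = rec.spikes.duration_s
        for i in range(rec.n_units):
            u = units.create_group(f"{i:04d}")
            _w(u, "spike_times", rec.spikes.spike_times_s[i])
            _w(u, "site_amplitudes", rec.spikes.site_amplitudes[i])
            u.attrs["dominant_site"] = int(rec.spikes.dominant_site[i])
            u.attrs["rf_outside_stim"] = bool(rec.spikes.rf_outside_stim[i])

        if rec.truth is not None:
            t = f.create_group("truth")
            pop = rec.truth
            _w(t, "position_um", pop.position_um)
            _w(t, "rf_center_deg", pop.rf_center_deg)
            _w(t, "rf_center_ideal_deg", pop.rf_center_ideal_deg)
            _w(t, "rf_sigma_deg", pop.rf_sigma_deg)
            _w(t, "rf_orientation", pop.rf_orientation)
            _w(t, "polarity", pop.polarity)
            _w(t, "temporal_kernel", pop.temporal_kernel)
            _w(t, "baseline_rate", pop.baseline_rate)
            _w(t, "gain", pop.gain)
            t.attrs["mode"] = pop.mode
            t.attrs["jitter_sigma"] = pop.jitter_sigma


def load_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        g = f["stimulus"]
        stim = StimulusMovie(
            frames=g["frames"][()],
            frame_rate=float(g.attrs["frame_rate"]),
            pixel_size_deg=tuple(g.attrs["pixel_size_deg"]),
            origin_deg=tuple(g.attrs["origin_deg"]),
        )
        g = f["probe"]
        probe = ProbeGeometry(
            g["site_positions"][()],
            n_shanks=int(g.attrs["n_shanks"]),
            sites_per_shank=int(g.attrs["sites_per_shank"]),
        )
        units = f["units"]
        ids = sorted(units.keys())
        spikes = SpikeData(
            spike_times_s=[units[i]["spike_times"][()] for i in ids],
            site_amplitudes=np.array(
                [units[i]["site_amplitudes"][()] for i in ids]
            ),
            dominant_site=np.array(
                [int(units[i].attrs["dominant_site"]) for i in ids]
            ),
            rf_outside_stim=np.array(
                [bool(units[i].attrs["rf_outside_stim"]) for i in ids]
            ),
            duration_s=float(units.attrs["duration_s"]),
        )
        truth = None
        if "truth" in f:
            t = f["truth"]
            truth = GroundTruthPopulation(
                position_um=t["position_um"][()],
                rf_center_deg=t["rf_center_deg"][()],
                rf_center_ideal_deg=t["rf_center_ideal_deg"][()],
                rf_sigma_deg=t["rf_sigma_deg"][()],
                rf_orientation=t["rf_orientation"][()],
                polarity=t["polarity"][()],
                temporal_kernel=t["temporal_kernel"][()],
                baseline_rate=t["baseline_rate"][()],
                gain=t["gain"][()],
                mode=str(t.attrs["mode"]),
                jitter_sigma=float(t.attrs["jitter_sigma"]),
            )
    return Recording(stimulus=stim, probe=probe, spikes=spikes, truth=truth)
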