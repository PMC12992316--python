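"""Pairwise RF-distance statistics for simultaneously recorded units.

Nearby pairs are units whose largest spike waveforms fall on the same
recording site (zero electrode distance); distant pairs have their
largest signals on different sites.  Group statistics follow the robust
median +/- median-absolute-deviation convention, with a two-sided
Mann-Whitney U-test for the nearby-vs-distant comparison and a Pearson
correlation of RF distance against electrode distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .probe import ProbeGeometry


def median_mad(x) -> tuple[float, float]:
    """Median and (unscaled) median absolute deviation."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    med = float(np.median(x))
    return med, float(np.median(np.abs(x - med)))


@dataclass
class GroupSummary:
    n_nearby: int
    n_distant: int
    nearby_median: float
    nearby_mad: float
    distant_median: float
    distant_mad: float
    utest_p: float
    pearson_r: float | None
    pearson_p: float | None
    pearson_r_distant_only: float | None
    pearson_p_distant_only: float | None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def enumerate_pairs(
    units: pd.DataFrame,
    geometry: ProbeGeometry,
    session_col: str = "session",
) -> pd.DataFrame:
    """All unordered pairs of QC-passed units within each session.

    Returns one row per pair with the electrode distance between dominant
    sites, the Euclidean RF-centre distance in degrees (stimulus plane
    treated as flat), the absolute RF-size difference and the
    nearby/distant label.  Sessions with fewer than two QC-passed units
    contribute no pairs.
    """
    # astype(bool): a zero-row table read back from CSV has object dtype
    qc = units[units["passed_qc"].astype(bool)].reset_index(drop=True)
    rows = []
    for session, grp in qc.groupby(session_col, sort=True):
        g = grp.reset_index(drop=True)
        n = len(g)
        for a in range(n):
            for b in range(a + 1, n):
                sa, sb = int(g.loc[a, "dominant_site"]), int(g.loc[b, "dominant_site"])
                ed = geometry.site_distance_um(sa, sb)
                rf = float(
                    np.hypot(
                        g.loc[a, "center_az"] - g.loc[b, "center_az"],
                        g.loc[a, "center_el"] - g.loc[b, "center_el"],
                    )
                )
                rows.append(
                    dict(
                        session=session,
                        unit_a=int(g.loc[a, "unit_id"]),
                        unit_b=int(g.loc[b, "unit_id"]),
                        electrode_distance_um=ed,
                        rf_distance_deg=rf,
                        size_diff_deg=float(
                            abs(g.loc[a, "size_deg"] - g.loc[b, "size_deg"])
                        ),
                        label="nearby" if sa == sb else "distant",
                    )
                )
    cols = [
        "session", "unit_a", "unit_b", "electrode_distance_um",
        "rf_distance_deg", "size_diff_deg", "label",
    ]
    return pd.DataFrame(rows, columns=cols)


def summarize_group(distances) -> tuple[float, float, int]:
    """(median, MAD, n) of a set of RF distances in degrees."""
    med, mad = median_mad(distances)
    return med, mad, len(np.asarray(distances))


def compare_groups(pairs: pd.DataFrame) -> GroupSummary:
    """Population-level nearby-vs-distant comparison over pooled pairs.

    The Pearson correlation of RF distance vs electrode distance is
    reported both over all pairs (nearby included, at zero electrode
    distance) and over distant pairs only, since it is ambiguous which
    population a scatter of RF vs electrode distance should include.
    Zero-variance inputs make the correlation undefined (None).
    """
    nearby = pairs.loc[pairs["label"] == "nearby", "rf_distance_deg"].to_numpy()
    distant = pairs.loc[pairs["label"] == "distant", "rf_distance_deg"].to_numpy()
    if nearby.size == 0 or distant.size == 0:
        raise ValueError("both nearby and distant groups must be nonempty")
    n_med, n_mad = median_mad(nearby)
    d_med, d_mad = median_mad(distant)
    # exact U below n=20 per group when tie-free, normal approximation with
    # tie correction otherwise (scipy's 'auto' policy)
    u = stats.mannwhitneyu(nearby, distant, alternative="two-sided", method="auto")

    def _pearson(df):
        x = df["electrode_distance_um"].to_numpy(float)
        y = df["rf_distance_deg"].to_numpy(float)
        if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
            return None, None
        r = stats.pearsonr(x, y)
        return float(r.statistic), float(r.pvalue)

    r_all, p_all = _pearson(pairs)
    r_dist, p_dist = _pearson(pairs[pairs["label"] == "distant"])
    return GroupSummary(
        n_nearby=int(nearby.size),
        n_distant=int(distant.size),
        nearby_median=n_med,
        nearby_mad=n_mad,
        distant_median=d_med,
        distant_mad=d_mad,
        utest_p=float(u.pvalue),
        pearson_r=r_all,
        pearson_p=p_all,
        pearson_r_distant_only=r_dist,
        pearson_p_distant_only=p_dist,
    )
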