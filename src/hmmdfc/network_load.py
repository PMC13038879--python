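"""High / Neutral / Low relative network load per state.

A state's connectivity matrix is summarized at the level of the canonical
networks: for each network, the mean of its within-network edge values
(ROI pairs i < j, both in the network; the diagonal never contributes).
The state-specific baseline is the mean of the (up to seven) network
averages, and each network's relative load is its deviation from that
baseline, (m - b) / |b|, capped to +-50% so a single extreme network
cannot dominate the descriptive categorization.  Networks at least
``neutral_band`` (default 10%) above baseline are High, at least that far
below are Low, and the rest Neutral; the boundary belongs to the
non-neutral side.

Which matrix to summarize is a caller choice: the default pipeline uses
the group-level mean of subjects' state connectivity matrices, and the
fitted model's state covariance (as correlation) is supported as an
alternative input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import AtlasMapping, ValidationError

logger = logging.getLogger(__name__)

LOAD_CAP = 0.5
NEUTRAL_BAND_DEFAULT = 0.10


def network_block_means(state_matrix: np.ndarray,
                        atlas: AtlasMapping) -> np.ndarray:
    """Mean within-network edge value per network (canonical order of the
    networks present in the atlas).  Networks with < 2 ROIs have no
    within-network edge and yield NaN with a warning."""
    m = np.asarray(state_matrix, dtype=float)
    if m.shape != (atlas.n_rois, atlas.n_rois):
        raise ValidationError(
            f"matrix shape {m.shape} does not match atlas N={atlas.n_rois}")
    out = []
    for net in atlas.network_names:
        idx = atlas.rois_in_network(net)
        if idx.size < 2:
            logger.warning("network %s has <2 ROIs; mean undefined", net)
            out.append(np.nan)
            continue
        block = m[np.ix_(idx, idx)]
        tri = np.triu_indices(idx.size, k=1)
        out.append(float(block[tri].mean()))
    return np.array(out)


def relative_load(network_means: np.ndarray,
                  cap: float = LOAD_CAP) -> tuple[np.ndarray, float]:
    """Capped relative deviation of each network from the state baseline.

    Returns ``(loads, baseline)``.  The baseline is the mean over the
    network averages (NaN entries excluded); division by |baseline| keeps
    the sign of a deviation meaningful when the baseline is negative.
    """
    means = np.asarray(network_means, dtype=float)
    b = float(np.nanmean(means))
    if b == 0:
        raise ValidationError(
            "state baseline is zero; relative deviation undefined")
    dev = (means - b) / abs(b)
    return np.clip(dev, -cap, cap), b


def categorize(loads: np.ndarray,
               neutral_band: float = NEUTRAL_BAND_DEFAULT
               ) -> tuple[list[str], int, int]:
    """Label each network High/Neutral/Low; returns (labels, n_high,
    n_low).  NaN loads are labelled Neutral."""
    labels = []
    for d in np.asarray(loads, dtype=float):
        if np.isnan(d) or abs(d) < neutral_band:
            labels.append("Neutral")
        elif d > 0:
            labels.append("High")
        else:
            labels.append("Low")
    return labels, labels.count("High"), labels.count("Low")


@dataclass
class NetworkLoadProfile:
    state: int                      # 0-based
    networks: list[str]
    network_means: np.ndarray
    baseline: float
    relative_load: np.ndarray
    labels: list[str]
    n_high: int
    n_low: int


def state_network_load(state_matrix: np.ndarray, atlas: AtlasMapping,
                       state: int,
                       neutral_band: float = NEUTRAL_BAND_DEFAULT
                       ) -> NetworkLoadProfile:
    means = network_block_means(state_matrix, atlas)
    loads, baseline = relative_load(means)
    labels, n_high, n_low = categorize(loads, neutral_band=neutral_band)
    return NetworkLoadProfile(
        state=state, networks=atlas.network_names, network_means=means,
        baseline=baseline, relative_load=loads, labels=labels,
        n_high=n_high, n_low=n_low)


def network_load_table(profiles: list[NetworkLoadProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for net, mean, dev, lab in zip(p.networks, p.network_means,
                                       p.relative_load, p.labels):
            rows.append({"state": p.state + 1, "network": net,
                         "mean": mean, "baseline": p.baseline,
                         "capped_dev": dev, "label": lab})
    return pd.DataFrame(rows)
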