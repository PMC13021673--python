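"""Network-level convergence metrics over the fingerprint matrix.

For a network ``k`` with region set ``R_k`` (every ROI whose membership
includes ``k``; multi-network ROIs count in full in every network they
belong to):

* total abnormal load         ``L_k = sum_{r in R_k} sum_s |X(r, s)|``
* distinct abnormal regions   ``N_k = |{r in R_k : exists s, X(r, s) != 0}|``
* abnormality per region      ``A_k = L_k / N_k``   (undefined when N_k = 0)
* mean direction              ``D_k = (1 / L_k) sum sum X(r, s)``
                              (undefined when L_k = 0; -1 = pure volume
                              loss, +1 = pure increase, 0 = mixed)

Undefined values are carried as NaN in memory and serialised as the
literal token ``NA`` — never as 0, which would fabricate a "mixed
direction" or "no burden" signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FingerprintMatrix, NetworkScheme

__all__ = [
    "NetworkMetricsRow",
    "total_abnormal_load",
    "distinct_abnormal_regions",
    "abnormality_per_region",
    "mean_direction",
    "metrics_table",
    "METRICS_COLUMNS",
]

METRICS_COLUMNS = (
    "network", "region_count", "load", "distinct_regions",
    "per_region_index", "mean_direction",
)


@dataclass(frozen=True)
class NetworkMetricsRow:
    network: str
    region_count: int
    load: int
    distinct_regions: int
    per_region_index: float  # NaN when distinct_regions == 0
    mean_direction: float    # NaN when load == 0
    rank: int                # rank by per_region_index, 1 = highest


def _network_rows(m: FingerprintMatrix, scheme: NetworkScheme, k: str) -> np.ndarray:
    scheme.require(k)
    return np.array([k in r.networks for r in m.regions], dtype=bool)


def total_abnormal_load(m: FingerprintMatrix, scheme: NetworkScheme, k: str) -> int:
    """Count of non-zero entries over the rows of R_k, all studies."""
    return int(np.abs(m.entries[_network_rows(m, scheme, k), :]).sum())


def distinct_abnormal_regions(m: FingerprintMatrix, scheme: NetworkScheme, k: str) -> int:
    """Number of R_k regions abnormal in at least one study."""
    sub = m.entries[_network_rows(m, scheme, k), :]
    return int((sub != 0).any(axis=1).sum())


def abnormality_per_region(load: int, distinct_regions: int) -> float:
    """The per-region index L_k / N_k; NaN when no region is abnormal."""
    if load < distinct_regions:
        raise ValueError(
            f"load ({load}) cannot be smaller than distinct_regions ({distinct_regions})"
        )
    if distinct_regions == 0:
        return math.nan
    return load / distinct_regions

def mean_direction(m: FingerprintMatrix, scheme: NetworkScheme, k: str) -> float:
    """Signed mean of the non-zero entries over R_k; NaN when L_k = 0."""
    sub = m.entries[_network_rows(m, scheme, k), :]
    load = int(np.abs(sub).sum())
    if load == 0:
        return math.nan
    return float(sub.sum()) / load


def metrics_table(m: FingerprintMatrix, scheme: NetworkScheme) -> pd.DataFrame:
    """Per-network metrics table, one row per scheme network, in scheme order.

    Columns: ``network, region_count, load, distinct_regions,
    per_region_index, mean_direction, rank``.  ``rank`` orders networks by
    descending per-region index (1 = highest); NaN indices rank last and
    ties are broken by scheme order, so the table is deterministic.
    Row sums double-count multi-membership regions by design.

    Raises if any region references a network the scheme does not define.
    """
    known = set(scheme.network_ids)
    for r in m.regions:
        missing = [k for k in r.networks if k not in known]
        if missing:
            raise ValueError(
                f"region {r.roi_id!r} references network(s) {missing} "
                "not covered by the scheme"
            )
    rows = []
    for k in scheme.network_ids:
        members = _network_rows(m, scheme, k)
        load = int(np.abs(m.entries[members, :]).sum())
        distinct = int((m.entries[members, :] != 0).any(axis=1).sum())
        rows.append({
            "network": k,
            "region_count": int(members.sum()),
            "load": load,
            "distinct_regions": distinct,
            "per_region_index": abnormality_per_region(load, distinct),
            "mean_direction": mean_direction(m, scheme, k),
        })
    table = pd.DataFrame(rows, columns=list(METRICS_COLUMNS))
    # stable sort on -index keeps scheme order among ties; NaN ranks last
    key = table["per_region_index"].to_numpy(dtype=float)
    order = np.argsort(-np.where(np.isnan(key), -np.inf, key), kind="stable")
    ranks = np.empty(len(table), dtype=int)
    ranks[order] = np.arange(1, len(table) + 1)
    table["rank"] = ranks
    return table
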