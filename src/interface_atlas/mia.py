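"""Multimodal intersection analysis (MIA).

MIA maps cell states onto tissue regions by asking whether the marker
genes of a cell state overlap the marker genes of a region more (or less)
than chance.  With a background of N genes, a region set of size K, a
state set of size n, and an overlap of k genes, the enrichment p-value is
the hypergeometric upper tail P(X >= k); the paired depletion score is
-log10(1 - p).  Marker sets are intersected with the shared background
(e.g. genes measured in both modalities) before testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .datatypes import GeneSetCollection

__all__ = ["MIAResult", "hypergeom_upper_tail", "mia_map"]

#: smallest positive normal double; p is clamped to [EPS, 1 - EPS] so both
#: -log10 scores stay finite
EPS = np.finfo(float).tiny


def _check_margins(k: int, K: int, n: int, N: int) -> None:
    if N < 1:
        raise ValueError("background size N must be positive")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"infeasible margins: K={K}, n={n}, N={N}")
    if not (max(0, K + n - N) <= k <= min(K, n)):
        raise ValueError(f"infeasible overlap k={k} for K={K}, n={n}, N={N}")


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    The tail includes the observed overlap (the standard
    over-representation convention).  Computed via the survival function,
    which scipy evaluates stably in log space internally.
    """
    _check_margins(k, K, n, N)
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def log10_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """log10 P(X >= k), evaluated in log space for extreme tails."""
    _check_margins(k, K, n, N)
    if k == 0:
        return 0.0
    return float(hypergeom.logsf(k - 1, N, K, n) / np.log(10.0))


def log10_lower_tail(k: int, K: int, n: int, N: int) -> float:
    """log10 P(X < k) = log10 (1 - P(X >= k)), stably in log space."""
    _check_margins(k, K, n, N)
    if k == 0:
        return np.log10(EPS)  # P(X < 0) = 0, clamped
    return float(max(hypergeom.logcdf(k - 1, N, K, n) / np.log(10.0), np.log10(EPS)))


@dataclass
class MIAResult:
    """Enrichment/depletion score matrices, cell states x regions."""

    enrichment: pd.DataFrame  # -log10 P(X >= k)
    depletion: pd.DataFrame  # -log10 (1 - P(X >= k))
    overlap: pd.DataFrame  # k
    state_sizes: pd.Series  # n per state (within background)
    region_sizes: pd.Series  # K per region (within background)
    background_size: int

    def to_long(self) -> pd.DataFrame:
        rows = []
        for state in self.enrichment.index:
            for region in self.enrichment.columns:
                rows.append(
                    {
                        "state": state,
                        "region": region,
                        "k": int(self.overlap.at[state, region]),
                        "K": int(self.region_sizes[region]),
                        "n": int(self.state_sizes[state]),
                        "N": self.background_size,
                        "enrichment": self.enrichment.at[state, region],
                        "depletion": self.depletion.at[state, region],
                    }
                )
        return pd.DataFrame(rows)


def mia_map(
    celltype_markers: GeneSetCollection,
    region_markers: GeneSetCollection,
    background,
) -> MIAResult:
    """Hypergeometric overlap of every (cell state, region) marker pair.

    ``background`` is the shared gene universe (typically the intersection
    of the genes measured in both modalities); all marker sets are
    intersected with it before testing.
    """
    background = list(dict.fromkeys(background))
    if not background:
        raise ValueError("empty gene background")
    bg = set(background)
    N = len(bg)

    states = celltype_markers.names()
    regions = region_markers.names()
    state_sets = {s: set(celltype_markers[s]) & bg for s in states}
    region_sets = {r: set(region_markers[r]) & bg for r in regions}

    enrich = pd.DataFrame(index=states, columns=regions, dtype=float)
    deplete = pd.DataFrame(index=states, columns=regions, dtype=float)
    overlap = pd.DataFrame(index=states, columns=regions, dtype=int)
    for s in states:
        n = len(state_sets[s])
        for r in regions:
            K = len(region_sets[r])
            k = len(state_sets[s] & region_sets[r])
            # both tails evaluated in log space so extreme overlaps keep
            # finite scores (p clamped to [EPS, 1 - EPS] equivalent)
            enrich.at[s, r] = max(0.0, -max(log10_upper_tail(k, K, n, N), np.log10(EPS)))
            deplete.at[s, r] = max(0.0, -log10_lower_tail(k, K, n, N))
            overlap.at[s, r] = k
    return MIAResult(
        enrichment=enrich,
        depletion=deplete,
        overlap=overlap,
        state_sizes=pd.Series({s: len(state_sets[s]) for s in states}),
        region_sizes=pd.Series({r: len(region_sets[r]) for r in regions}),
        background_size=N,
    )
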