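"""Correlation analysis of mean kinetic profiles.

Proteins acting in the same cytokinetic module share a kinetic signature, so
the Pearson correlation between mean accumulation curves over a common time
window ranks candidate partners and predicts module membership for an
uncharacterized protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .align import MeanKinetics
from .kinetics import extract_signature

__all__ = [
    "SimilarityMatrix",
    "ModuleAssignment",
    "correlation_matrix",
    "rank_similarity",
    "assign_module",
    "DEFAULT_WINDOW",
]

DEFAULT_WINDOW = (-20.0, 30.0)  # min; covers the cytokinesis window
MIN_OVERLAP = 15


@dataclass
class SimilarityMatrix:
    ids: list[str]
    r: np.ndarray          # Pearson r, NaN where masked
    n_overlap: np.ndarray  # joint unmasked gridpoints per pair
    window: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.ids, columns=self.ids)

    def loc(self, a: str, b: str) -> float:
        return float(self.r[self.ids.index(a), self.ids.index(b)])


@dataclass
class ModuleAssignment:
    query: str
    ranked_neighbors: list[tuple[str, float]]
    predicted_module: str
    peak_time_module: str
    peak_time_distance: float
    consistent: bool = field(default=True)


def correlation_matrix(mks: Sequence[MeanKinetics],
                       window: tuple[float, float] = DEFAULT_WINDOW,
                       min_overlap: int = MIN_OVERLAP) -> SimilarityMatrix:
    """Pairwise Pearson r between mean curves on jointly unmasked gridpoints.

    Pairs with fewer than ``min_overlap`` joint points, and any curve with
    zero variance inside the window, are masked (NaN) with a warning.
    """
    if len(mks) < 2:
        raise ValueError("correlation_matrix: need at least 2 curves")
    ids = [mk.protein_id for mk in mks]
    if len(set(ids)) != len(ids):
        raise ValueError("correlation_matrix: duplicate protein ids")
    k = len(mks)
    r = np.full((k, k), np.nan)
    n_overlap = np.zeros((k, k), dtype=int)
    grids = [mk.grid for mk in mks]
    sel = [(g >= window[0]) & (g <= window[1]) for g in grids]
    np.fill_diagonal(r, 1.0)
    for i in range(k):
        gi = grids[i][sel[i]]
        yi = mks[i].mean[sel[i]]
        for j in range(i + 1, k):
            gj = grids[j][sel[j]]
            yj = mks[j].mean[sel[j]]
            common, ia, ja = np.intersect1d(gi, gj, return_indices=True)
            a, b = yi[ia], yj[ja]
            okk = np.isfinite(a) & np.isfinite(b)
            n_overlap[i, j] = n_overlap[j, i] = int(okk.sum())
            if okk.sum() < min_overlap:
                continue
            a, b = a[okk], b[okk]
            if np.std(a) == 0 or np.std(b) == 0:
                warnings.warn(f"zero-variance curve in window: "
                              f"{ids[i] if np.std(a) == 0 else ids[j]}")
                continue
            r[i, j] = r[j, i] = float(np.corrcoef(a, b)[0, 1])
    return SimilarityMatrix(ids=ids, r=r, n_overlap=n_overlap, window=window)


def rank_similarity(matrix: SimilarityMatrix, query: str,
                    peak_times: dict[str, float] | None = None,
                    ) -> list[tuple[str, float]]:
    """Neighbors of ``query`` ordered by descending r.

    Ties resolve by ascending peak-time distance (when ``peak_times`` is
    given), then lexicographic id.  Masked neighbors are dropped.
    """
    if query not in matrix.ids:
        raise KeyError(f"query {query!r} not in matrix")
    qi = matrix.ids.index(query)
    row = matrix.r[qi]
    if not np.any(np.isfinite(np.delete(row, qi))):
        raise ValueError(f"query {query!r} is fully masked")
    entries = []
    for j, other in enumerate(matrix.ids):
        if j == qi or not np.isfinite(row[j]):
            continue
        if peak_times and query in peak_times and other in peak_times:
            dist = abs(peak_times[other] - peak_times[query])
        else:
            dist = np.inf
        entries.append((-row[j], dist, other))
    entries.sort()
    return [(name, -negr) for negr, _, name in entries]


def assign_module(query_mk: MeanKinetics,
                  references: Sequence[tuple[MeanKinetics, str]],
                  window: tuple[float, float] = DEFAULT_WINDOW) -> ModuleAssignment:
    """Predict the functional module of a query protein.

    The predicted module maximizes the mean Pearson r between the query curve
    and the module's reference curves; the nearest-peak-time module is
    reported alongside, and disagreement between the two is flagged.
    """
    labels = {label for _, label in references}
    if len(labels) < 2:
        raise ValueError("assign_module: references must span >= 2 modules")
    mks = [query_mk] + [mk for mk, _ in references]
    matrix = correlation_matrix(mks, window=window)
    ranked = rank_similarity(matrix, query_mk.protein_id)
    by_id = {mk.protein_id: label for mk, label in references}

    module_r: dict[str, list[float]] = {}
    for name, rv in ranked:
        module_r.setdefault(by_id[name], []).append(rv)
    if not module_r:
        raise ValueError("assign_module: all references masked")
    predicted = max(module_r, key=lambda m: np.mean(module_r[m]))

    q_peak = extract_signature(query_mk).primary_peak_time
    best_name, best_dist = None, np.inf
    for mk, _ in references:
        try:
            pt = extract_signature(mk).primary_peak_time
        except ValueError:
            continue
        d = abs(pt - q_peak)
        if d < best_dist:
            best_name, best_dist = mk.protein_id, d
    peak_module = by_id[best_name] if best_name is not None else predicted
    return ModuleAssignment(
        query=query_mk.protein_id, ranked_neighbors=ranked,
        predicted_module=predicted, peak_time_module=peak_module,
        peak_time_distance=float(best_dist),
        consistent=(predicted == peak_module))
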