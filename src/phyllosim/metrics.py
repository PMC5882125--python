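"""Spatial-scale indices of 1D concentration patterns (and cluster sizes on
arbitrary lattices).

Two indices summarize a periodic concentration series c_0..c_{N-1}:

* **L1**, the dominant wavelength: after a discrete Fourier transform
  F(k) = (1/N) sum_n c_n exp(-2*pi*i*k*n/N), the wavenumber k1 in [1, N/2]
  with the largest spectral power |F(k)|^2 defines L1 = N/k1 in [2, N].
* **L2**, the mean cluster size: positions with c_n strictly above the
  series mean are "spots"; maximal runs of consecutive spots (with
  periodic wrap-around) are "clusters"; L2 = (#spots)/(#clusters).

Both are undefined for a (numerically) constant series; results carry an
explicit ``defined`` flag rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import Lattice

__all__ = ["PatternMetrics", "wavelength_L1", "cluster_size_L2",
           "pattern_metrics", "graph_cluster_sizes", "neighbor_correlation",
           "count_local_maxima"]


@dataclass(frozen=True)
class PatternMetrics:
    """L1/L2 summary of one series; ``defined`` is False for constant input."""

    defined: bool
    k1: int | None = None
    L1: float | None = None
    L2: float | None = None
    n_spots: int = 0
    n_clusters: int = 0
    spot_mask: np.ndarray | None = None
    tie: bool = False
    series_kind: str = "cells"


def wavelength_L1(series: np.ndarray,
                  min_rel_amplitude: float = 1e-6) -> tuple[int | None, float | None, bool, bool]:
    """Dominant wavenumber and wavelength of a periodic series.

    Returns (k1, L1, defined, tie). Ties in spectral power are broken toward
    the smallest k (longest wavelength) and flagged. A series whose dominant
    mode amplitude is below ``min_rel_amplitude`` relative to its mean level
    is reported undefined (effectively constant).
    """
    c = np.asarray(series, dtype=float)
    N = c.size
    if N < 4:
        raise ValueError("series length must be >= 4")
    F = np.fft.fft(c) / N
    power = np.abs(F) ** 2
    kmax = N // 2
    band = power[1:kmax + 1]
    scale = max(abs(float(F[0].real)), 1.0e-300)
    if np.sqrt(2.0 * band.max()) <= min_rel_amplitude * scale:
        return None, None, False, False
    # near-ties (within DFT rounding) break toward the smallest wavenumber
    top = band >= band.max() * (1.0 - 1e-9)
    k1 = int(np.argmax(top)) + 1
    tie = bool(top.sum() > 1)
    return k1, float(N / k1), True, tie


def cluster_size_L2(series: np.ndarray) -> tuple[float | None, int, int, np.ndarray]:
    """Mean size of contiguous above-mean runs, with periodic wrap-around.

    Returns (L2, n_spots, n_clusters, spot_mask); L2 is None when no
    position exceeds the mean (constant series).
    """
    c = np.asarray(series, dtype=float)
    if c.size < 2:
        raise ValueError("series length must be >= 2")
    mask = c > c.mean()
    n_spots = int(mask.sum())
    if n_spots == 0:
        return None, 0, 0, mask
    if n_spots == c.size:          # cannot happen with strict >, kept defensive
        return float(c.size), n_spots, 1, mask
    # count cluster starts: spot whose predecessor (cyclically) is not a spot
    starts = mask & ~np.roll(mask, 1)
    n_clusters = int(starts.sum())
    return n_spots / n_clusters, n_spots, n_clusters, mask


def pattern_metrics(series: np.ndarray, series_kind: str = "cells",
                    min_rel_amplitude: float = 1e-6) -> PatternMetrics:
    """Combined L1/L2 metrics of one series."""
    k1, L1, defined, tie = wavelength_L1(series, min_rel_amplitude)
    if not defined:
        return PatternMetrics(defined=False, series_kind=series_kind)
    L2, n_spots, n_clusters, mask = cluster_size_L2(series)
    return PatternMetrics(defined=True, k1=k1, L1=L1, L2=L2,
                          n_spots=n_spots, n_clusters=n_clusters,
                          spot_mask=mask, tie=tie, series_kind=series_kind)


def count_local_maxima(values: np.ndarray, lattice: Lattice) -> int:
    """Number of cells strictly above all their neighbors and above the mean.

    Counts isolated concentration maxima on any lattice: a handful of peaks
    signals macroscopic maxima, a peak on the order of every other cell
    signals interface-scale alternation.
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (lattice.n_cells,):
        raise ValueError("values must be one scalar per cell")
    nb = v[lattice.neighbors]
    return int(np.sum((v[:, None] > nb).all(axis=1) & (v > v.mean())))


def neighbor_correlation(values: np.ndarray, lattice: Lattice) -> float:
    """Pearson correlation between each cell's value and its neighbor mean.

    Distinguishes macroscopic maxima (strong positive spatial coherence)
    from interface-scale alternation (zero or negative coherence), which
    cluster counting alone cannot on 6-neighbor lattices where above-mean
    masks percolate.
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (lattice.n_cells,):
        raise ValueError("values must be one scalar per cell")
    nb_mean = v[lattice.neighbors].mean(axis=1)
    sv, sn = v.std(), nb_mean.std()
    if sv == 0 or sn == 0:
        return 0.0
    return float(np.corrcoef(v, nb_mean)[0, 1])


def graph_cluster_sizes(values: np.ndarray, lattice: Lattice) -> list[int]:
    """Sizes of connected above-mean components on the cell adjacency graph
    (the 2D analogue of the cluster index; hex torus included)."""
    v = np.asarray(values, dtype=float)
    if v.shape != (lattice.n_cells,):
        raise ValueError("values must be one scalar per cell")
    mask = v > v.mean()
    seen = np.zeros(lattice.n_cells, dtype=bool)
    sizes = []
    for start in np.nonzero(mask)[0]:
        if seen[start]:
            continue
        size = 0
        stack = [int(start)]
        seen[start] = True
        while stack:
            i = stack.pop()
            size += 1
            for j in lattice.neighbors[i]:
                j = int(j)
                if mask[j] and not seen[j]:
                    seen[j] = True
                    stack.append(j)
        sizes.append(size)
    return sorted(sizes, reverse=True)
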