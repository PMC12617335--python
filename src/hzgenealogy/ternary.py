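"""Ternary representation of topology weights and left–right asymmetry.

Each tree's weight triple ``(w_geo, w_var, w_alt)`` is a point on the
2-simplex, drawn in the unit equilateral triangle with the GEO topology at
the apex, VAR at the bottom-right corner and ALT at the bottom-left.  Under
purely neutral sorting of ancestral variation the two discordant topologies
are exchangeable, so the distribution must be mirror-symmetric about the
vertical (GEO) axis; excess mass on the VAR side is the tree-based analogue
of Patterson's D and signals haplotype sharing between same-variety
populations across zones.

Asymmetry is quantified globally as ``D_lr = (n_right - n_left) /
(n_right + n_left)`` over off-axis trees, and locally by two-sided binomial
tests on mirrored bin pairs of a simplex-lattice grid (Benjamini–Hochberg
adjusted across pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .twisst import TopologyWeights

__all__ = ["TernaryGrid", "AsymmetryResult", "ternary_coordinates", "build_grid", "asymmetry"]

SQRT3_2 = np.sqrt(3.0) / 2.0


def _classified_triples(weights) -> np.ndarray:
    """(n, 3) array of (geo, var, alt) renormalised over classified mass.

    Trees whose quartets are entirely unresolved (u == 1) are dropped.
    Accepts TopologyWeights objects, dicts, or raw triples.
    """
    rows = []
    for w in weights:
        if isinstance(w, TopologyWeights):
            g, v, a = w.w_geo, w.w_var, w.w_alt
        elif isinstance(w, dict):
            g, v, a = w["w_geo"], w["w_var"], w["w_alt"]
        else:
            g, v, a = w
        s = g + v + a
        if s <= 0:
            continue
        if s < 1.0 - 1e-9:  # polytomy residual: renormalise over classified mass
            g, v, a = g / s, v / s, a / s
        rows.append((g, v, a))
    return np.asarray(rows, dtype=float).reshape(-1, 3)


def ternary_coordinates(weights) -> np.ndarray:
    """Map weight triples to (x, y) in the unit equilateral triangle.

    Corners: GEO (1,0,0) → apex (0.5, √3/2); VAR (0,1,0) → (1, 0);
    ALT (0,0,1) → (0, 0).  ``x > 0.5`` iff ``w_var > w_alt``.
    """
    W = _classified_triples(weights)
    if W.size == 0:
        raise ValueError("no classified weights")
    x = W[:, 1] + 0.5 * W[:, 0]
    y = SQRT3_2 * W[:, 0]
    return np.stack([x, y], axis=1)


@dataclass
class TernaryGrid:
    """Simplex-lattice histogram of weight triples.

    The simplex is cut into ``K = 1/g`` rows per axis giving ``K**2`` small
    triangles: "up" triangles indexed by floor coordinates ``(i, j, k)``
    with ``i + j + k = K - 1`` and "down" triangles with ``i + j + k = K - 2``
    (``i`` counts the GEO axis, ``j`` VAR, ``k`` ALT).
    """

    granularity: float
    counts: dict = field(default_factory=dict)  # (i, j, k, orient) -> count
    n_points: int = 0
    n_dropped: int = 0  # u == 1 trees

    @property
    def K(self) -> int:
        return round(1.0 / self.granularity)

    def mirror_key(self, key):
        i, j, k, o = key
        return (i, k, j, o)


def build_grid(weights, g: float = 0.02) -> TernaryGrid:
    """Bin weight triples on the simplex lattice with edge width ``g``."""
    K = round(1.0 / g)
    if abs(K * g - 1.0) > 1e-9:
        raise ValueError(f"granularity {g} does not divide 1 evenly")
    W = _classified_triples(weights)
    n_in = sum(1 for _ in weights)
    grid = TernaryGrid(granularity=g, n_points=W.shape[0], n_dropped=n_in - W.shape[0])
    if np.any(W < -1e-9) or np.any(np.abs(W.sum(axis=1) - 1) > 1e-9):
        raise ValueError("points outside the simplex")
    eps = 1e-12
    for gw, vw, aw in W:
        i = min(int((gw + eps) / g), K - 1)
        j = min(int((vw + eps) / g), K - 1)
        k = min(int((aw + eps) / g), K - 1)
        s = i + j + k
        if s >= K:  # rounding at an upper edge: pull the largest index down
            drop = int(np.argmax([gw - i * g, vw - j * g, aw - k * g]))
            i, j, k = (i - (drop == 0), j - (drop == 1), k - (drop == 2))
            s = i + j + k
        if s == K - 1:
            key = (i, j, k, "up")
        else:  # s == K - 2
            key = (i, j, k, "down")
        grid.counts[key] = grid.counts.get(key, 0) + 1
    return grid


@dataclass
class AsymmetryResult:
    n_right: int
    n_left: int
    n_axis: int
    d_lr: float
    bin_pairs: list  # (key_right, key_left, n_right, n_left, p, q)

    def significant_pairs(self, alpha: float = 0.05):
        return [bp for bp in self.bin_pairs if bp[5] <= alpha]


def asymmetry(weights, g: float = 0.02) -> AsymmetryResult:
    """Left–right asymmetry of the ternary distribution.

    Points with ``w_var == w_alt`` sit on the mirror axis and are excluded
    from both counts.  Per mirrored-bin-pair two-sided binomial tests of
    H0: p = 0.5 are BH-adjusted across pairs.
    """
    W = _classified_triples(weights)
    if W.size == 0:
        raise ValueError("no classified weights")
    diff = W[:, 1] - W[:, 2]
    n_right = int((diff > 0).sum())
    n_left = int((diff < 0).sum())
    n_axis = int((diff == 0).sum())
    if n_right + n_left == 0:
        raise ValueError("all points lie on the mirror axis")
    d_lr = (n_right - n_left) / (n_right + n_left)

    grid = build_grid(weights, g=g)
    seen, pairs = set(), []
    for key in grid.counts:
        mk = grid.mirror_key(key)
        if key == mk or key in seen or mk in seen:
            continue
        seen.add(key)
        seen.add(mk)
        right_key = key if key[1] > key[2] else mk
        left_key = mk if right_key == key else key
        nr = grid.counts.get(right_key, 0)
        nl = grid.counts.get(left_key, 0)
        if nr + nl == 0:
            continue
        p = binomtest(nr, nr + nl, 0.5).pvalue
        pairs.append([right_key, left_key, nr, nl, p])
    if pairs:
        q = multipletests([row[4] for row in pairs], method="fdr_bh")[1]
        pairs = [row + [float(qi)] for row, qi in zip(pairs, q)]
    return AsymmetryResult(n_right, n_left, n_axis, d_lr, pairs)
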