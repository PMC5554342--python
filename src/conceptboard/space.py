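"""Geometric semantics for symbols: seeded Voronoi regions in a conceptual space.

Each symbol of an alphabet owns a seed point; a query point is classified by
nearest seed, with two modifications:

* a **gap** parameter ``g`` shrinks every region by ``g/2`` on each side of
  every separating hyperplane, leaving an explicit GAP zone between regions
  (points landing there are mutually indiscriminable from no stored symbol
  and become seeds for new symbols);
* an **expectation modulation** parameter ``alpha`` shifts each separating
  hyperplane away from the midpoint toward the less likely of the two
  symbols, in proportion to their relative likelihood under the current
  predictive distribution — so an unexpected, imprecisely placed point may
  be captured by a nearby expected region.

Trajectories through a space are abstracted to single points of the space
one level up via a discrete cosine transform on a fixed-length resampling,
which makes the abstraction invariant to uniform time dilation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct

__all__ = ["GAP", "SpaceConfig", "ConceptualSpace", "Trajectory", "abstract"]

#: Sentinel returned by :meth:`ConceptualSpace.classify` for points that fall
#: between regions when the gap parameter is non-zero.
GAP = "<GAP>"


@dataclass
class SpaceConfig:
    """Tunable geometry parameters.

    gap : width (distance units) of the buffer zone between regions.
    alpha : strength of expectation-driven boundary displacement.
    entropy_scaling : if set, alpha is further scaled by
        ``1 - H(D)/log2 |A|`` so that sharper (more informative)
        distributions move boundaries more.
    seed_tolerance : two points closer than this are not mutually
        discriminable; adding the second returns the first's symbol.
    """

    gap: float = 0.0
    alpha: float = 0.5
    entropy_scaling: bool = False
    seed_tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.gap < 0 or not math.isfinite(self.gap):
            raise ValueError("gap must be finite and >= 0")
        if self.alpha < 0 or not math.isfinite(self.alpha):
            raise ValueError("alpha must be finite and >= 0")


@dataclass
class Trajectory:
    """Ordered points through one space, with per-point durations."""

    points: np.ndarray  # (n, dim)
    durations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            raise ValueError("trajectory must be non-empty")
        if self.durations is None:
            self.durations = np.ones(len(self.points))
        else:
            self.durations = np.asarray(self.durations, dtype=float)
            if len(self.durations) != len(self.points):
                raise ValueError("durations must match points")
            if np.any(self.durations <= 0):
                raise ValueError("durations must be positive")


class ConceptualSpace:
    """An alphabet of symbols with one seed point each.

    Symbols are minted in insertion order (``s0, s1, ...`` by default, or
    caller-supplied names); classification is deterministic, breaking exact
    ties in favor of the earliest symbol.
    """

    def __init__(self, dim: int, config: SpaceConfig | None = None, prefix: str = "s"):
        if dim < 1:
            raise ValueError("dimensionality must be >= 1")
        self.dim = dim
        self.config = config or SpaceConfig()
        self.prefix = prefix
        self.symbols: list[str] = []
        self._seeds: list[np.ndarray] = []

    @property
    def alphabet(self) -> list[str]:
        return list(self.symbols)

    def seed(self, symbol: str) -> np.ndarray:
        return self._seeds[self.symbols.index(symbol)]

    def add_seed(self, point, symbol: str | None = None) -> str:
        """Label a new discriminable point with a symbol; grow the alphabet.

        Points within ``seed_tolerance`` of an existing seed return that
        symbol instead of minting a new one.
        """
        p = np.asarray(point, dtype=float)
        if p.shape != (self.dim,):
            raise ValueError(f"point must have dimensionality {self.dim}")
        for s, q in zip(self.symbols, self._seeds):
            if np.linalg.norm(p - q) <= self.config.seed_tolerance:
                return s
        if symbol is None:
            symbol = f"{self.prefix}{len(self.symbols)}"
        if symbol in self.symbols:
            raise ValueError(f"symbol {symbol!r} already present")
        self.symbols.append(symbol)
        self._seeds.append(p)
        return symbol

    def nearest(self, point) -> str:
        """Plain nearest-seed lookup (no gap, no modulation)."""
        p = np.asarray(point, dtype=float)
        dists = [np.linalg.norm(p - q) for q in self._seeds]
        return self.symbols[int(np.argmin(dists))]

    def classify(self, point, distribution: dict[str, float] | None = None) -> str:
        """Assign ``point`` to a symbol, or to GAP.

        For each seed pair (s, s') the separating hyperplane perpendicular
        to the connecting segment is displaced from the midpoint toward the
        less likely symbol by ``alpha * (p(s)-p(s')) / (p(s)+p(s')) *
        ||s-s'|| / 2`` and then withdrawn by ``gap/2`` on each side.  The
        point belongs to the unique symbol all of whose modulated, gapped
        half-spaces contain it; if no symbol qualifies, the point is in a
        gap region.
        """
        q = np.asarray(point, dtype=float)
        if q.shape != (self.dim,):
            raise ValueError(f"point must have dimensionality {self.dim}")
        if not self.symbols:
            return GAP
        n = len(self.symbols)
        if n == 1:
            return self.symbols[0]
        probs = self._probs(distribution)
        alpha = self.config.alpha
        if self.config.entropy_scaling and distribution is not None:
            h = -sum(p * math.log2(p) for p in probs.values() if p > 0)
            hmax = math.log2(n)
            alpha *= (1.0 - h / hmax) if hmax > 0 else 1.0
        g = self.config.gap
        for i, s in enumerate(self.symbols):
            inside = True
            for j, s2 in enumerate(self.symbols):
                if i == j:
                    continue
                a, b = self._seeds[i], self._seeds[j]
                seg = b - a
                d = np.linalg.norm(seg)
                if d == 0:
                    continue
                u = seg / d
                mid = (a + b) / 2.0
                ps, ps2 = probs[s], probs[s2]
                delta = 0.0
                if distribution is not None and ps + ps2 > 0:
                    delta = alpha * (ps - ps2) / (ps + ps2) * (d / 2.0)
                boundary = mid + delta * u
                # signed coordinate of q along u, relative to the boundary;
                # negative side belongs to s
                if float(np.dot(q - boundary, u)) > -g / 2.0:
                    inside = False
                    break
            if inside:
                return s
        return GAP

    def _probs(self, distribution: dict[str, float] | None) -> dict[str, float]:
        if distribution is None:
            return {s: 1.0 / len(self.symbols) for s in self.symbols}
        missing = set(self.symbols) - set(distribution)
        if missing:
            raise ValueError(f"distribution missing symbols {sorted(missing)}")
        return {s: float(distribution[s]) for s in self.symbols}

    # -- serialization -------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "dim": self.dim,
                "prefix": self.prefix,
                "config": {
                    "gap": self.config.gap,
                    "alpha": self.config.alpha,
                    "entropy_scaling": self.config.entropy_scaling,
                    "seed_tolerance": self.config.seed_tolerance,
                },
                "seeds": {s: list(map(float, p)) for s, p in zip(self.symbols, self._seeds)},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ConceptualSpace":
        doc = json.loads(text)
        space = cls(doc["dim"], SpaceConfig(**doc["config"]), doc["prefix"])
        for s, p in doc["seeds"].items():
            space.add_seed(np.array(p), s)
        return space


RESAMPLE_LENGTH = 32


def abstract(trajectory: Trajectory, k: int = 8) -> np.ndarray:
    """Collapse a trajectory into a single point one abstraction level up.

    The trajectory is resampled (respecting per-point durations) to a fixed
    length, a discrete cosine transform is applied per dimension, and the
    magnitudes of the first ``k`` coefficients per dimension are
    concatenated.  Because resampling normalizes total duration, the result
    is invariant to uniform time dilation: the same shape traversed twice
    as slowly maps to the same point.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pts, durs = trajectory.points, trajectory.durations
    if len(pts) == 1:
        resampled = np.repeat(pts, RESAMPLE_LENGTH, axis=0)
    else:
        t = np.concatenate([[0.0], np.cumsum(durs[:-1])])
        t = t / t[-1] if t[-1] > 0 else t
        grid = np.linspace(0.0, 1.0, RESAMPLE_LENGTH)
        resampled = np.column_stack(
            [np.interp(grid, t, pts[:, d]) for d in range(pts.shape[1])]
        )
    # normalized so the 0th coefficient of a constant trajectory is the
    # constant itself
    coeffs = dct(resampled, axis=0, norm="ortho")[:k] / math.sqrt(RESAMPLE_LENGTH)
    return np.abs(coeffs).T.reshape(-1)
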