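"""Mean-function design matrices and the (site, sex) batch registry.

Age enters the mean function through one of three parameterizations:
a linear basis ``[1, age]``, a cubic polynomial ``[1, age, age^2, age^3]``,
or a cubic B-spline expansion with evenly spaced interior knots over the
training age range (plus an explicit intercept column).

Group effects (site and sex) are combined as a cross-product: every
observed (site, sex) cell is one *batch* and receives its own parameter
vector under the shared hierarchical prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

_KIND_ALIASES = {
    "linear": "linear",
    "poly3": "polynomial3",
    "polynomial3": "polynomial3",
    "bspline": "bspline3",
    "bspline3": "bspline3",
}


@dataclass(frozen=True)
class BasisConfig:
    """Configuration of the age basis.

    Parameters
    ----------
    kind : {"linear", "polynomial3", "bspline3"}
        Parameterization of the age effect. ``polynomial3`` is a cubic
        polynomial; ``bspline3`` a cubic B-spline.
    n_knots : int
        Number of evenly spaced *interior* knots for ``bspline3``.
    extrapolation : {"clamp", "linear"}
        How test-time ages outside the training range are handled:
        ``clamp`` evaluates the basis at the nearest range boundary
        (conservative for centile charts); ``linear`` continues the
        basis linearly from the boundary.
    standardize : bool
        When true (the default), the basis is evaluated on age affinely
        rescaled to [-1, 1] over the fit range. This leaves the spline
        basis unchanged (its knots are evenly spaced either way) but
        decorrelates the polynomial columns, which conditions the
        posterior dramatically better; predictions are identical up to
        a linear reparameterization of the coefficients.
    """

    kind: str = "linear"
    n_knots: int = 5
    extrapolation: str = "clamp"
    standardize: bool = True

    def __post_init__(self):
        kind = _KIND_ALIASES.get(self.kind)
        if kind is None:
            raise ValueError(f"unknown basis kind {self.kind!r}; choose from {sorted(set(_KIND_ALIASES))}")
        object.__setattr__(self, "kind", kind)
        if self.extrapolation not in ("clamp", "linear"):
            raise ValueError("extrapolation must be 'clamp' or 'linear'")
        if kind == "bspline3" and self.n_knots < 1:
            raise ValueError("bspline3 requires n_knots >= 1")

    @property
    def n_columns(self) -> int:
        if self.kind == "linear":
            return 2
        if self.kind == "polynomial3":
            return 4
        return 1 + self.n_knots + 4  # intercept + (interior knots + order) spline columns

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "n_knots": self.n_knots,
            "extrapolation": self.extrapolation,
            "standardize": self.standardize,
        }

    @staticmethod
    def from_dict(d) -> "BasisConfig":
        return BasisConfig(**d)


def _spline_knots(lo: float, hi: float, n_interior: int) -> np.ndarray:
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    return np.concatenate([[lo] * 4, interior, [hi] * 4])


def expand_basis(age, config: BasisConfig, fit_range: tuple[float, float]) -> np.ndarray:
    """Expand ages into the mean-function design matrix.

    The first column is always the intercept. Rows are independent:
    permuting the input permutes the output rows identically.
    """
    age = np.asarray(age, dtype=float)
    if age.ndim != 1:
        age = age.ravel()
    if age.size == 0:
        raise ValueError("empty age vector")
    if not np.all(np.isfinite(age)):
        raise ValueError("ages must be finite")
    lo, hi = float(fit_range[0]), float(fit_range[1])
    if not lo < hi:
        raise ValueError(f"degenerate fit_range ({lo}, {hi}): lower bound must be < upper")

    if config.standardize:
        t_age = 2.0 * (age - lo) / (hi - lo) - 1.0
        t_lo, t_hi = -1.0, 1.0
    else:
        t_age, t_lo, t_hi = age, lo, hi

    x = np.clip(t_age, t_lo, t_hi)
    if config.kind == "linear":
        # the linear basis extrapolates linearly by its nature
        base = t_age if config.extrapolation == "linear" else x
        return np.column_stack([np.ones_like(base), base])
    if config.kind == "polynomial3":
        phi = np.column_stack([np.ones_like(x), x, x**2, x**3])
    else:
        t = _spline_knots(t_lo, t_hi, config.n_knots)
        cols = BSpline.design_matrix(x, t, 3).toarray()
        phi = np.column_stack([np.ones(len(x)), cols])
    if config.extrapolation == "linear":
        out = (t_age < t_lo) | (t_age > t_hi)
        if np.any(out):
            clamp_cfg = BasisConfig(config.kind, config.n_knots, "clamp", False)
            delta = t_age[out] - x[out]
            eps = 1e-6 * (t_hi - t_lo)
            inner = np.clip(x[out], t_lo + eps, t_hi - eps)
            d = (
                expand_basis(inner + eps, clamp_cfg, (t_lo, t_hi))
                - expand_basis(inner - eps, clamp_cfg, (t_lo, t_hi))
            ) / (2 * eps)
            phi[out] = phi[out] + d * delta[:, None]
    return phi


def _clean_labels(labels, name: str) -> np.ndarray:
    arr = np.asarray(labels, dtype=object)
    bad = [i for i, v in enumerate(arr) if v is None or (isinstance(v, float) and np.isnan(v)) or str(v) == ""]
    if bad:
        raise ValueError(f"missing {name} labels at rows {bad[:10]}")
    return np.array([str(v) for v in arr], dtype=object)


@dataclass
class BatchRegistry:
    """Ordered mapping from observed (site, sex) label pairs to indices.

    Only combinations actually observed in the training data are
    registered; the ordering is lexicographic and therefore stable under
    serialization. Unseen pairs are reported by :meth:`lookup`, never
    silently added.
    """

    batches: list = field(default_factory=list)
    counts: dict = field(default_factory=dict)

    def __post_init__(self):
        self._index = {b: i for i, b in enumerate(self.batches)}

    @property
    def n_batches(self) -> int:
        return len(self.batches)

    def lookup(self, site_labels, sex_labels, strict: bool = True) -> np.ndarray:
        site = _clean_labels(site_labels, "site")
        sex = _clean_labels(sex_labels, "sex")
        if len(site) != len(sex):
            raise ValueError("site and sex label vectors must have equal length")
        idx = np.empty(len(site), dtype=np.int64)
        unseen = set()
        for i, pair in enumerate(zip(site, sex)):
            j = self._index.get(pair, -1)
            idx[i] = j
            if j < 0:
                unseen.add(pair)
        if unseen and strict:
            raise KeyError(f"unseen (site, sex) batches: {sorted(unseen)}")
        return idx

    def to_dict(self) -> dict:
        return {
            "batches": [list(b) for b in self.batches],
            "counts": {f"{s}|{x}": int(c) for (s, x), c in self.counts.items()},
        }

    @staticmethod
    def from_dict(d) -> "BatchRegistry":
        batches = [tuple(b) for b in d["batches"]]
        counts = {tuple(k.split("|")): v for k, v in d["counts"].items()}
        return BatchRegistry(batches, counts)


def register_batches(site_labels, sex_labels) -> BatchRegistry:
    """Build a :class:`BatchRegistry` over the observed (site, sex) cells."""
    site = _clean_labels(site_labels, "site")
    sex = _clean_labels(sex_labels, "sex")
    if len(site) != len(sex):
        raise ValueError("site and sex label vectors must have equal length")
    counts: dict = {}
    for pair in zip(site, sex):
        counts[pair] = counts.get(pair, 0) + 1
    batches = sorted(counts)
    return BatchRegistry(batches, counts)
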