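"""Synthetic ordinal-data generators for the validation study.

Three families emulate typical response structures on an n-point scale:

* **categorical** — i.i.d. draws from a 5-category distribution with a
  declared probability vector (presets ``p1``..``p30`` sweep a dominant
  category of intensity 1.00, 0.92, 0.84, 0.76, 0.68 or 0.60 across the
  five positions, the remainder spread evenly);
* **rounded normal** — Gaussian draws rounded half-away-from-zero and
  clipped onto the integer scale, emulating responses clustered around a
  central value;
* **Gaussian copula ordinal** — correlated latent standard normals mapped
  through the normal CDF and binned by cumulative cut points, giving
  correlated ordinal items with exactly controlled marginals (presets
  ``m1``..``m5`` for the base marginals, ``c1``..``c6`` for the base 2x2
  correlation templates; both are expanded cyclically / as an
  equicorrelation matrix to the requested dimension).

Every generator is deterministic given its seed, and ``design_grid``
enumerates full Cartesian parameter grids with per-cell derived seeds.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CategoricalDesign",
    "NormalDesign",
    "CopulaDesign",
    "P_VECTORS",
    "MARGINALS",
    "CORRELATIONS",
    "gen_categorical",
    "gen_rounded_normal",
    "expand_marginals",
    "expand_correlation",
    "gen_copula_ordinal",
    "design_grid",
]


def _dominant_presets() -> dict[str, list[float]]:
    out: dict[str, list[float]] = {}
    idx = 1
    for dom, rest in [(1.0, 0.0), (0.92, 0.02), (0.84, 0.04), (0.76, 0.06), (0.68, 0.08), (0.60, 0.10)]:
        for pos in range(5):
            probs = [rest] * 5
            probs[pos] = dom
            out[f"p{idx}"] = probs
            idx += 1
    return out


#: 30 categorical probability presets: dominant score 1..5 at six intensities.
P_VECTORS: dict[str, list[float]] = _dominant_presets()

#: base marginal cut-point presets (two margins each, 3 cuts -> 4 categories).
MARGINALS: dict[str, list[list[float]]] = {
    "m1": [[0.25, 0.5, 0.75], [0.25, 0.5, 0.75]],     # uniform
    "m2": [[0.6, 0.85, 0.95], [0.65, 0.9, 0.98]],     # left-skewed
    "m3": [[0.05, 0.15, 0.4], [0.1, 0.2, 0.5]],       # right-skewed
    "m4": [[0.22, 0.5, 0.78], [0.24, 0.49, 0.74]],    # high entropy
    "m5": [[0.05, 0.06, 0.07], [0.02, 0.04, 0.06]],   # low entropy
}

#: base 2x2 correlation templates keyed by dependence regime.
CORRELATIONS: dict[str, list[list[float]]] = {
    "c1": [[1.0, 0.0], [0.0, 1.0]],     # independent
    "c2": [[1.0, 0.2], [0.2, 1.0]],     # low positive
    "c3": [[1.0, 0.5], [0.5, 1.0]],     # moderate positive
    "c4": [[1.0, 0.9], [0.9, 1.0]],     # high positive
    "c5": [[1.0, -0.6], [-0.6, 1.0]],   # negative
    "c6": [[1.0, 0.35], [0.35, 1.0]],   # noisy symmetric
}


@dataclass(frozen=True)
class CategoricalDesign:
    """i.i.d. categorical responses on a 5-point scale."""

    n_items: int
    probs: tuple
    iterations: int = 1
    seed: int = 0

    def __init__(self, n_items, probs, iterations=1, seed=0):
        if isinstance(probs, str):
            probs = P_VECTORS[probs]
        probs = tuple(float(q) for q in probs)
        if n_items < 2:
            raise ValueError(f"n_items must be >= 2, got {n_items}")
        if any(q < 0 for q in probs):
            raise ValueError("probabilities must be nonnegative")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {sum(probs)}")
        object.__setattr__(self, "n_items", int(n_items))
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "iterations", int(iterations))
        object.__setattr__(self, "seed", int(seed))


@dataclass(frozen=True)
class NormalDesign:
    """Rounded/clipped Gaussian responses on an integer scale."""

    n_items: int
    mu: float
    sigma: float
    scale_min: int = 1
    scale_max: int = 5
    iterations: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_items < 2:
            raise ValueError(f"n_items must be >= 2, got {self.n_items}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be nonnegative, got {self.sigma}")
        if self.scale_min >= self.scale_max:
            raise ValueError("scale_min must be < scale_max")


@dataclass(frozen=True)
class CopulaDesign:
    """Gaussian-copula ordinal responses with expanded marginals/correlation."""

    n_items: int
    base_marginals: tuple
    base_correlation: tuple
    iterations: int = 1
    seed: int = 0
    shrink_correlation: bool = False

    def __init__(self, n_items, base_marginals, base_correlation,
                 iterations=1, seed=0, shrink_correlation=False):
        if isinstance(base_marginals, str):
            base_marginals = MARGINALS[base_marginals]
        if isinstance(base_correlation, str):
            base_correlation = CORRELATIONS[base_correlation]
        if n_items < 2:
            raise ValueError(f"n_items must be >= 2, got {n_items}")
        margins = tuple(tuple(float(c) for c in m) for m in base_marginals)
        for m in margins:
            if not all(0 < a < 1 for a in m) or any(b <= a for a, b in zip(m, m[1:])):
                raise ValueError(f"cut points must be strictly increasing in (0, 1), got {m}")
        corr = tuple(tuple(float(v) for v in row) for row in base_correlation)
        rho = corr[0][1]
        if not abs(rho) < 1:
            raise ValueError(f"|rho| must be < 1, got {rho}")
        object.__setattr__(self, "n_items", int(n_items))
        object.__setattr__(self, "base_marginals", margins)
        object.__setattr__(self, "base_correlation", corr)
        object.__setattr__(self, "iterations", int(iterations))
        object.__setattr__(self, "seed", int(seed))
        object.__setattr__(self, "shrink_correlation", bool(shrink_correlation))

    @property
    def rho(self) -> float:
        return self.base_correlation[0][1]


def gen_categorical(design: CategoricalDesign, rng: np.random.Generator) -> np.ndarray:
    """(iterations x n_items) matrix of i.i.d. draws from {1..5}."""
    cats = np.arange(1, len(design.probs) + 1)
    return rng.choice(cats, size=(design.iterations, design.n_items), p=design.probs)


def gen_rounded_normal(design: NormalDesign, rng: np.random.Generator) -> np.ndarray:
    """Gaussian(mu, sigma) draws rounded half-away-from-zero, clipped to the scale."""
    z = rng.normal(design.mu, design.sigma, size=(design.iterations, design.n_items))
    rounded = np.copysign(np.floor(np.abs(z) + 0.5), z)
    return np.clip(rounded, design.scale_min, design.scale_max).astype(int)


def expand_marginals(base: Sequence[Sequence[float]], d: int) -> list[list[float]]:
    """Cyclic expansion of the base marginal list to d margins: out[i] = base[i mod k]."""
    if d < 2:
        raise ValueError(f"d must be >= 2, got {d}")
    k = len(base)
    return [list(base[i % k]) for i in range(d)]


def expand_correlation(
    base: Sequence[Sequence[float]], d: int, shrink: bool = False
) -> np.ndarray:
    """Equicorrelation expansion of a 2x2 template to d x d.

    The off-diagonal rho is read from the (0, 1) position.  The expansion
    is positive semidefinite only for rho >= -1/(d-1); below that bound an
    error is raised unless ``shrink=True``, which clips rho just inside
    the bound with a warning.
    """
    if d < 2:
        raise ValueError(f"d must be >= 2, got {d}")
    rho = float(base[0][1])
    if not abs(rho) < 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    bound = -1.0 / (d - 1)
    if rho < bound:
        if not shrink:
            raise ValueError(
                f"equicorrelation with rho={rho} is not positive semidefinite for "
                f"d={d}; the PSD bound is rho >= {bound:.6g} "
                "(pass shrink=True to clip rho just inside the bound)"
            )
        new_rho = bound + 1e-6
        warnings.warn(
            f"shrinking rho from {rho} to {new_rho:.6g} to restore positive "
            f"semidefiniteness at d={d}",
            stacklevel=2,
        )
        rho = new_rho
    C = np.full((d, d), rho)
    np.fill_diagonal(C, 1.0)
    return C


def _categories_from_uniform(u: np.ndarray, cuts: Sequence[float]) -> np.ndarray:
    # category j+1 where j = number of cut points strictly below u
    return 1 + np.searchsorted(np.asarray(cuts), u, side="left")


def gen_copula_ordinal(design: CopulaDesign, rng: np.random.Generator) -> np.ndarray:
    """(iterations x d) matrix of correlated ordinal categories 1..(cuts+1).

    Latent standard normals with the expanded equicorrelation are mapped to
    uniforms via the normal CDF and binned by each margin's cut points, so
    the marginal cell probabilities are successive differences of the
    cut-point vector padded with 0 and 1.
    """
    d = design.n_items
    margins = expand_marginals(design.base_marginals, d)
    C = expand_correlation(design.base_correlation, d, shrink=design.shrink_correlation)
    # symmetric PSD factorization (eigh tolerates the semidefinite boundary)
    w, V = np.linalg.eigh(C)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal(size=(design.iterations, d)) @ L.T
    u = stats.norm.cdf(z)
    out = np.empty((design.iterations, d), dtype=int)
    for j in range(d):
        out[:, j] = _categories_from_uniform(u[:, j], margins[j])
    return out


@dataclass(frozen=True)
class _GridCell:
    family: str
    index: int
    params: tuple
    design: object
    seed: int


def design_grid(family: str, config: dict) -> Iterator[_GridCell]:
    """Enumerate the full Cartesian product of a family's parameter lists.

    ``config`` supplies the parameter lists (``n_items``, plus ``probs``
    for categorical, ``mu``/``sigma`` for normal, ``marginals``/
    ``correlations`` for copula), ``iterations`` per cell, and
    ``base_seed``; cell seeds are ``base_seed + cell index`` in a fixed,
    deterministic ordering.
    """
    iterations = int(config.get("iterations", 1))
    base_seed = int(config.get("base_seed", 0))
    n_items = list(config["n_items"])
    if not n_items:
        raise ValueError("empty parameter set: n_items")

    if family == "categorical":
        probs = list(config["probs"])
        axes = [n_items, probs]
    elif family == "normal":
        mus, sigmas = list(config["mu"]), list(config["sigma"])
        axes = [n_items, mus, sigmas]
    elif family == "copula":
        margins = list(config["marginals"])
        corrs = list(config["correlations"])
        axes = [n_items, margins, corrs]
    else:
        raise ValueError(f"unknown family {family!r}")
    if any(not ax for ax in axes):
        raise ValueError("empty parameter set in config")

    for index, combo in enumerate(itertools.product(*axes)):
        seed = base_seed + index
        if family == "categorical":
            n, p = combo
            design = CategoricalDesign(n, p, iterations=iterations, seed=seed)
        elif family == "normal":
            n, mu, sigma = combo
            design = NormalDesign(n, mu, sigma, iterations=iterations, seed=seed)
        else:
            n, m, c = combo
            design = CopulaDesign(
                n, m, c, iterations=iterations, seed=seed,
                shrink_correlation=bool(config.get("shrink_correlation", False)),
            )
        yield _GridCell(family=family, index=index, params=combo, design=design, seed=seed)


def generate(design, rng: np.random.Generator | None = None) -> np.ndarray:
    """Dispatch a design to its generator; a fresh RNG from the design seed by default."""
    if rng is None:
        rng = np.random.default_rng(design.seed)
    if isinstance(design, CategoricalDesign):
        return gen_categorical(design, rng)
    if isinstance(design, NormalDesign):
        return gen_rounded_normal(design, rng)
    if isinstance(design, CopulaDesign):
        return gen_copula_ordinal(design, rng)
    raise TypeError(f"unknown design type {type(design).__name__}")
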