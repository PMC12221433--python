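"""The isoreflective construct and the Kabirian coefficient of proximity.

An individual's whole-encoded scores ``x_1..x_n`` are paired isoreflectively
with a *statistical mirror* — ``n`` copies of the highest positive scale
point ``p`` — about a central element ``delta = 0``.  The concatenated
construct

    d = [x_(1), ..., x_(n), 0, p, ..., p]          (length 2n + 1)

is weighted by the *optiscale* ``R = (1, 2, ..., 2n+1)`` with central value
``r_c = n + 1``.  The Kabirian coefficient of statistical proximity is the
ratio of the center-weighted mass to the position-weighted mass,

    KC1 = r_c * sum(d) / sum(R * d),

which for data in ``[0, p]`` is guaranteed to lie in ``[2/3, 1]``: 1 when
every response sits at the top of the scale, 2/3 when every response sits
at the bottom.  KC1 is translated to a probability of positive assessment

    PSprox = ((2n+1) * KC1 - (n+1)) / ((n+1) - KC1),

monotone in KC1 with PSprox = 1 at KC1 = 1, and PSdev = 1 - PSprox is the
probability of negative assessment.  Both KC1 and the probabilities are
invariant to a common rescaling of the data and the scale top — the
statistic depends only on where the responses sit relative to ``p``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ordinal_encoding import NATURAL, OrdinalScale, ResponseVector, to_whole_encoding

__all__ = [
    "OptinalyticConstruct",
    "OrdinalysisResult",
    "build_construct",
    "kabirian_coefficient",
    "bicoefficient",
    "kc_to_probability",
    "alternative_coefficients",
    "sm_ordinalysis",
]

#: slack for the KC domain check; float pipelines can land at 1 + 1e-16.
KC_DOMAIN_TOL = 1e-9


@dataclass(frozen=True)
class OptinalyticConstruct:
    """The isoreflective sequence d with its optiscale R.

    ``d`` holds the ascending-sorted data in positions 1..n, the center
    ``delta = 0`` at position n+1, and n copies of the principal mirror
    value ``p`` in positions n+2..2n+1.  Head-to-head pairing is realized
    by this arrangement: the lowest data value sits at optiscale position
    1, maximally distant from the mirror's far end.
    """

    d: tuple
    p: float
    n: int

    @property
    def R(self) -> np.ndarray:
        return np.arange(1, 2 * self.n + 2)

    @property
    def r_c(self) -> int:
        return self.n + 1


def build_construct(
    values: Sequence[float], p: float, *, check_bounds: bool = True
) -> OptinalyticConstruct:
    """Assemble the optinalytic construct for whole-encoded ``values``.

    Requires n >= 2, p > 0 and every value in [0, p].  The generalized
    mirroring engine passes ``check_bounds=False``: its transformed data
    (e.g. absolute deviations mirrored against their mean) may legitimately
    exceed the mirror value.
    """
    vals = list(values)
    n = len(vals)
    if n < 2:
        raise ValueError(f"need at least 2 responses, got {n}")
    if not (p > 0):
        raise ValueError(f"principal mirror value p must be positive, got {p}")
    tol = KC_DOMAIN_TOL * max(p, 1.0)
    for i, v in enumerate(vals):
        if not np.isfinite(v):
            raise ValueError(f"non-finite value {v!r} at index {i}")
        if check_bounds and (v < -tol or v > p + tol):
            raise ValueError(f"value {v!r} at index {i} outside [0, p={p}]")
    ordered = sorted(float(v) for v in vals)
    d = tuple(ordered) + (0.0,) + (float(p),) * n
    return OptinalyticConstruct(d=d, p=float(p), n=n)


def _construct_sums(values: Sequence[float], p: float) -> tuple[float, float]:
    """(sum d, sum R*d) of the construct, in closed form.

    Integral inputs are accumulated as exact Python ints/floats term by
    term, so the 6-decimal table values are free of float drift.
    """
    ordered = sorted(values)
    n = len(ordered)
    s = sum(ordered)
    sum_d = s + n * p
    # data side: weights 1..n on the ascending order statistics;
    # mirror side: p * (positions n+2 .. 2n+1) = 3*p*n*(n+1)/2
    weighted = sum(i * x for i, x in enumerate(ordered, start=1))
    sum_rd = weighted + 3 * p * n * (n + 1) / 2
    return sum_d, sum_rd


def kabirian_coefficient(c: OptinalyticConstruct) -> float:
    """KC1 = r_c * sum(d) / sum(R * d), in [2/3, 1] for data in [0, p]."""
    data = c.d[: c.n]
    sum_d, sum_rd = _construct_sums(data, c.p)
    assert sum_rd > 0, "degenerate construct: p > 0 makes sum(R*d) positive"
    kc = c.r_c * sum_d / sum_rd
    return float(kc)


def bicoefficient(kc1: float) -> float:
    """The bi-coefficient of the inverse optinalytic operation: KC2 = 1/KC1."""
    if kc1 <= 0:
        raise ValueError(f"kc1 must be positive, got {kc1}")
    return 1.0 / kc1


def _check_kc_domain(kc: float) -> float:
    lo, hi = 2.0 / 3.0, 1.0
    if kc < lo - KC_DOMAIN_TOL or kc > hi + KC_DOMAIN_TOL:
        raise ValueError(
            f"coefficient {kc} outside the proximity branch [2/3, 1]; "
            "out-of-model coefficient"
        )
    return min(max(kc, lo), hi)


def kc_to_probability(kc: float, n: int) -> float:
    """Translate a Kabirian coefficient to the probability of positive assessment.

    PSprox = ((2n+1)*kc - (n+1)) / ((n+1) - kc); monotone increasing in kc,
    1 at kc = 1 and (n-1)/(3n+1) at the lower bound kc = 2/3.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    kc = _check_kc_domain(kc)
    if kc == 1.0:
        return 1.0
    return ((2 * n + 1) * kc - (n + 1)) / ((n + 1) - kc)


def alternative_coefficients(kc: float, n: int) -> tuple[float, float]:
    """Alternative coefficients on the translation branch (provisional semantics).

    The source module documentation names these outputs without defining
    them; the definitions here are this package's own and are flagged as
    provisional in ``sm_ordinalysis`` metadata.  ``kcalt1`` is the
    coefficient whose translation equals PSprox (the identity, = kc);
    ``kcalt2`` is the coefficient whose translation equals PSdev, obtained
    by inverting the translation: x = (n+1)(1 + PSdev) / ((2n+1) + PSdev).
    """
    kc = _check_kc_domain(kc)
    psdev = 1.0 - kc_to_probability(kc, n)
    kcalt1 = kc
    kcalt2 = (n + 1) * (1.0 + psdev) / ((2 * n + 1) + psdev)
    return kcalt1, kcalt2


_SELECTOR_ALIASES = {
    "print:kc-sprox": "kc", "kc": "kc", "kc-sprox": "kc",
    "print:p-sprox": "pprox", "pprox": "pprox", "p-sprox": "pprox",
    "print:p-sdev": "pdev", "pdev": "pdev", "p-sdev": "pdev",
    "print:kcalt1": "kcalt1", "kcalt1": "kcalt1",
    "print:kcalt2": "kcalt2", "kcalt2": "kcalt2",
    "print:kcalt": "kcalt", "kcalt": "kcalt",
    "print:all_in_list": "all_in_list", "all_in_list": "all_in_list",
    "print:all_in_dict": "all_in_dict", "all_in_dict": "all_in_dict",
}


@dataclass(frozen=True)
class OrdinalysisResult:
    """Full result of SM-based ordinalysis for one individual.

    ``kc1`` lies in [2/3, 1]; ``kc2 = 1/kc1`` in [1, 3/2]; ``psprox`` and
    ``psdev`` are complementary probabilities of positive and negative
    ordinal assessment.
    """

    kc1: float
    kc2: float
    psprox: float
    psdev: float
    n: int
    p: float
    kcalt1: float | None = None
    kcalt2: float | None = None
    kcalt: float | None = None
    meta: tuple = ()

    def as_dict(self) -> dict:
        out = {
            "kc_sprox": self.kc1,
            "kc2_sprox": self.kc2,
            "p_sprox": self.psprox,
            "p_sdev": self.psdev,
            "n": self.n,
            "p": self.p,
        }
        if self.kcalt1 is not None:
            out.update(kcalt1=self.kcalt1, kcalt2=self.kcalt2, kcalt=self.kcalt)
        if self.meta:
            out["meta"] = dict(self.meta)
        return out

    def as_list(self) -> list:
        out = [self.kc1, self.kc2, self.psprox, self.psdev]
        if self.kcalt1 is not None:
            out += [self.kcalt1, self.kcalt2, self.kcalt]
        return out


def sm_ordinalysis(
    data: Sequence[float],
    point_scale: int,
    max_scale: float,
    encoding: str = NATURAL,
    print_result: str = "all_in_dict",
):
    """End-to-end SM-based ordinalysis of one composite score set.

    Pipeline: whole-number recoding -> isoreflective construct with the
    scale top as mirror -> Kabirian coefficient -> bi-coefficient ->
    probability translation -> complement.  ``print_result`` selects the
    output: ``"print:kc-sprox"``/``"kc"``, ``"print:p-sprox"``/``"pprox"``,
    ``"print:p-sdev"``/``"pdev"``, the alternative-coefficient selectors,
    or ``"all_in_list"``/``"all_in_dict"``.

    Raises ``ValueError`` if the input data is not properly formatted for
    the declared scale or the selector is unknown.
    """
    sel = _SELECTOR_ALIASES.get(print_result)
    if sel is None:
        raise ValueError(
            f"unknown print_result {print_result!r}; valid selectors: "
            + ", ".join(sorted(set(_SELECTOR_ALIASES)))
        )
    scale = OrdinalScale(point_scale, max_scale, encoding)
    whole = to_whole_encoding(ResponseVector(data, scale))
    p = whole.scale.top_whole_value
    construct = build_construct(whole.values, p)
    kc1 = kabirian_coefficient(construct)
    kc2 = bicoefficient(kc1)
    psprox = kc_to_probability(kc1, construct.n)
    psdev = 1.0 - psprox

    want_alt = sel in ("kcalt1", "kcalt2", "kcalt", "all_in_list", "all_in_dict")
    kcalt1 = kcalt2 = kcalt = None
    meta = ()
    if want_alt:
        kcalt1, kcalt2 = alternative_coefficients(kc1, construct.n)
        kcalt = 1.0 / kc1
        meta = (("alternative_coefficients", "provisional semantics"),)

    result = OrdinalysisResult(
        kc1=kc1, kc2=kc2, psprox=psprox, psdev=psdev,
        n=construct.n, p=p,
        kcalt1=kcalt1, kcalt2=kcalt2, kcalt=kcalt, meta=meta,
    )
    if sel == "kc":
        return kc1
    if sel == "pprox":
        return psprox
    if sel == "pdev":
        return psdev
    if sel == "kcalt1":
        return kcalt1
    if sel == "kcalt2":
        return kcalt2
    if sel == "kcalt":
        return kcalt
    if sel == "all_in_list":
        return result.as_list()
    return result.as_dict()
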