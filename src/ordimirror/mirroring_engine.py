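"""Generalized statistical mirroring and the SAMD dispersion measure.

Statistical mirroring pairs a (possibly transformed) data sequence against
``n`` copies of a principal mirror value and summarizes the pairing with
the same Kabirian coefficient / probability translation as the ordinalysis
statistic.  SM-based ordinalysis is the special case
``principal_value = scale top p, centering = never, ordering = ascend,
pairing = H_H``.

The *statistical absolute meanic deviation* (SAMD) used as the efficiency
criterion mirrors the absolute deviations from the mean against their own
mean: ``a_i = |x_i - mean(x)|``, mirror value ``q = mean(a)``, and the
reported dispersion is the probability of deviation of that construct.
Because the absolute deviations are location-free and the construct is
invariant to a common rescaling of data and mirror, SAMD is "scaloc"
invariant: ``samd(c*x + b) = samd(x)`` for any ``c != 0`` and any ``b``.
It is 0 exactly when the data are constant.

The construct cited for this measure is not restated in full by its
source; the definition here is this package's documented reconstruction,
chosen to satisfy the scaloc-invariance contract and kept behind this
module so a corrected construct could be swapped without touching callers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .optinalysis_core import (
    bicoefficient,
    build_construct,
    kabirian_coefficient,
    kc_to_probability,
)

__all__ = ["MirroringSpec", "stat_mirroring", "samd"]

log = logging.getLogger(__name__)

_CENTERING = ("never", "bymeanR+", "bymeanR±")
_ORDERING = ("ascend", "descend")
_PAIRING = ("H_H", "T_T")


def _strip(tag: str, prefix: str) -> str:
    return tag.removeprefix(prefix)


@dataclass(frozen=True)
class MirroringSpec:
    """Mirroring configuration.

    ``principal_value`` is ``"mean"``, ``"max"`` or a custom positive
    number; ``centering`` one of never / bymeanR+ (absolute deviations) /
    bymeanR± (signed deviations); option strings may carry their documented
    prefixes (``"principal_value:mean"``, ``"centering:bymeanR+"``,
    ``"ordering:ascend"``, ``"pairing:H_H"``).
    """

    principal_value: object = "mean"
    centering: str = "never"
    ordering: str = "ascend"
    pairing: str = "H_H"
    output: str = "all"

    def __post_init__(self) -> None:
        pv = self.principal_value
        if isinstance(pv, str):
            pv = _strip(pv, "principal_value:")
            if pv not in ("mean", "max"):
                raise ValueError(f"principal_value must be 'mean', 'max' or a number, got {pv!r}")
        centering = _strip(self.centering, "centering:")
        if centering not in _CENTERING:
            raise ValueError(f"centering must be one of {_CENTERING}, got {centering!r}")
        ordering = _strip(self.ordering, "ordering:")
        if ordering not in _ORDERING:
            raise ValueError(f"ordering must be one of {_ORDERING}, got {ordering!r}")
        pairing = _strip(self.pairing, "pairing:")
        if pairing not in _PAIRING:
            raise ValueError(f"pairing must be one of {_PAIRING}, got {pairing!r}")
        output = _strip(self.output, "print:")
        object.__setattr__(self, "principal_value", pv)
        object.__setattr__(self, "centering", centering)
        object.__setattr__(self, "ordering", ordering)
        object.__setattr__(self, "pairing", pairing)
        object.__setattr__(self, "output", output)


def stat_mirroring(data: Sequence[float], spec: MirroringSpec) -> dict:
    """Mirror ``data`` per ``spec`` and return ``{"kc", "pprox", "pdev"}``.

    Centering is applied first (never -> identity, bymeanR+ -> absolute
    deviations from the mean, bymeanR± -> signed deviations), the principal
    mirror value is then resolved against the *transformed* data, and the
    construct is summarized exactly as in SM-based ordinalysis.  A fully
    degenerate construct (all transformed values and the mirror value 0)
    is defined as perfect proximity: kc = 1, pdev = 0.
    """
    x = np.asarray(list(data), dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")

    if spec.centering == "never":
        a = x
    elif spec.centering == "bymeanR+":
        a = np.abs(x - x.mean())
    else:  # bymeanR± — signed deviations
        a = x - x.mean()

    pv = spec.principal_value
    if pv == "mean":
        p = float(a.mean())
    elif pv == "max":
        p = float(a.max())
    else:
        p = float(pv)

    tiny = 1e-12 * max(1.0, float(np.abs(a).max()))
    if np.all(np.abs(a) <= tiny) and abs(p) <= tiny:
        log.debug("degenerate 0/0 mirroring construct; defining kc=1, pdev=0")
        return {"kc": 1.0, "pprox": 1.0, "pdev": 0.0}
    if p <= tiny:
        raise ValueError(f"resolved principal mirror value must be positive, got {p}")

    construct = build_construct(a, p, check_bounds=False)
    kc = kabirian_coefficient(construct)
    pprox = kc_to_probability(kc, construct.n)
    return {"kc": kc, "kc2": bicoefficient(kc), "pprox": pprox, "pdev": 1.0 - pprox}


_SAMD_SPEC = MirroringSpec(
    principal_value="mean", centering="bymeanR+", ordering="ascend",
    pairing="H_H", output="pdev",
)


def samd(data: Sequence[float]) -> float:
    """Statistical absolute meanic deviation, a scaloc-invariant dispersion.

    Returns the probability of deviation of the construct that mirrors the
    ascending-sorted absolute deviations from the mean against their own
    mean; 0 exactly when the data are constant, and invariant to any
    location shift and any nonzero rescaling of the input.  Multiply by
    100 when reporting as a percentage.
    """
    x = np.asarray(list(data), dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 values, got {x.size}")
    return float(stat_mirroring(x, _SAMD_SPEC)["pdev"])
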