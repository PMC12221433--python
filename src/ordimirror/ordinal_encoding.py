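"""Ordinal scales, response vectors and encoding conversions.

Two encoding conventions are supported for an n-point ordinal scale with a
common interval ``k``:

* **natural-number encoding** — admissible values ``{k, 2k, ..., n*k}``
  (the familiar 1..5 Likert coding when ``k = 1``);
* **whole-number encoding** — admissible values ``{0, k, ..., (n-1)*k}``,
  i.e. the same ladder shifted down so the lowest category is exactly 0.

The whole-number form is what the mirroring construct consumes: its top
value ``p = (n-1)*k`` is the principal mirror value, the highest positive
scale point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OrdinalScale",
    "ResponseVector",
    "AlignmentMap",
    "HomogeneityResult",
    "to_whole_encoding",
    "reverse_code",
    "align_scale",
    "validate_homogeneous",
    "read_responses",
]

NATURAL = "natural_numbers"
WHOLE = "whole_numbers"

#: relative tolerance for membership of a value in the admissible set;
#: loose enough to admit decimal ladders such as a 0.01-step scale.
MEMBERSHIP_RTOL = 1e-9


def _normalize_encoding(encoding: str) -> str:
    enc = encoding.removeprefix("encoding:")
    if enc not in (NATURAL, WHOLE):
        raise ValueError(
            f"unknown encoding {encoding!r}; expected "
            f"'{NATURAL}' or '{WHOLE}' (optionally prefixed 'encoding:')"
        )
    return enc


@dataclass(frozen=True)
class OrdinalScale:
    """A declared n-point ordinal scale.

    Parameters
    ----------
    point_scale
        Number of scale points, at least 2.
    max_scale
        The largest encoded value as declared by the user: ``n*k`` under
        natural-number encoding, ``(n-1)*k`` under whole-number encoding.
    encoding
        ``"natural_numbers"`` or ``"whole_numbers"`` (an ``"encoding:"``
        prefix is tolerated).

    The common interval ``k`` and the top whole-number value
    ``p = (point_scale - 1) * k`` are derived.
    """

    point_scale: int
    max_scale: float
    encoding: str = NATURAL

    def __post_init__(self) -> None:
        object.__setattr__(self, "encoding", _normalize_encoding(self.encoding))
        if self.point_scale < 2:
            raise ValueError(f"point_scale must be >= 2, got {self.point_scale}")
        if not np.isfinite(self.max_scale) or self.max_scale <= 0:
            raise ValueError(f"max_scale must be a positive finite number, got {self.max_scale}")

    @property
    def interval(self) -> float:
        """Common step k between adjacent scale points."""
        if self.encoding == NATURAL:
            return self.max_scale / self.point_scale
        return self.max_scale / (self.point_scale - 1)

    @property
    def top_whole_value(self) -> float:
        """Highest positive scale point after whole-number recoding (p)."""
        return (self.point_scale - 1) * self.interval

    @property
    def admissible_values(self) -> np.ndarray:
        k = self.interval
        if self.encoding == NATURAL:
            return k * np.arange(1, self.point_scale + 1)
        return k * np.arange(self.point_scale)

    def is_admissible(self, value: float) -> bool:
        if not np.isfinite(value):
            return False
        ref = max(abs(self.max_scale), 1.0)
        return bool(np.any(np.abs(self.admissible_values - value) <= MEMBERSHIP_RTOL * ref))

    def as_whole(self) -> "OrdinalScale":
        """The same ladder re-declared in whole-number encoding."""
        if self.encoding == WHOLE:
            return self
        return OrdinalScale(self.point_scale, self.top_whole_value, WHOLE)


@dataclass(frozen=True)
class ResponseVector:
    """One individual's composite set of ordinal assessment scores.

    ``values`` must all be members of the scale's admissible set and there
    must be at least two items; ``reversed_polarity`` declares that the
    instrument's wording runs opposite to the scale's positive direction.
    """

    values: tuple
    scale: OrdinalScale
    item_labels: tuple | None = None
    reversed_polarity: bool = False

    def __init__(
        self,
        values: Sequence[float],
        scale: OrdinalScale,
        item_labels: Sequence[str] | None = None,
        reversed_polarity: bool = False,
        drop_na: bool = False,
    ) -> None:
        vals = list(values)
        if drop_na:
            kept = [v for v in vals if v is not None and np.isfinite(v)]
            if len(kept) < len(vals):
                warnings.warn(
                    f"dropped {len(vals) - len(kept)} missing value(s); "
                    f"composite length shrinks to {len(kept)}",
                    stacklevel=2,
                )
            vals = kept
        if len(vals) < 2:
            raise ValueError(f"a response vector needs at least 2 items, got {len(vals)}")
        for i, v in enumerate(vals):
            if v is None or not np.isfinite(v):
                raise ValueError(f"non-finite response at index {i}: {v!r}")
            if not scale.is_admissible(v):
                raise ValueError(
                    f"response {v!r} at index {i} is not an admissible value of the "
                    f"{scale.point_scale}-point {scale.encoding} scale "
                    f"(admissible: {np.round(scale.admissible_values, 12).tolist()})"
                )
        if item_labels is not None and len(item_labels) != len(vals):
            raise ValueError("item_labels length must match values length")
        object.__setattr__(self, "values", tuple(float(v) for v in vals))
        object.__setattr__(self, "scale", scale)
        object.__setattr__(self, "item_labels", tuple(item_labels) if item_labels else None)
        object.__setattr__(self, "reversed_polarity", bool(reversed_polarity))

    def __len__(self) -> int:
        return len(self.values)


def to_whole_encoding(responses: ResponseVector) -> ResponseVector:
    """Convert a response vector to whole-number encoding.

    Natural-encoded values are shifted down by one interval ``k``;
    whole-encoded input passes through unchanged.  Rank order is preserved
    exactly and the output minimum admissible value is 0.
    """
    scale = responses.scale
    if scale.encoding == WHOLE:
        return responses
    k = scale.interval
    shifted = [v - k for v in responses.values]
    # snap tiny float residue (e.g. 0.07 - 0.01) onto the exact ladder
    whole = scale.as_whole()
    grid = whole.admissible_values
    snapped = [float(grid[np.argmin(np.abs(grid - v))]) for v in shifted]
    return ResponseVector(
        snapped,
        whole,
        item_labels=responses.item_labels,
        reversed_polarity=responses.reversed_polarity,
    )


def reverse_code(values: Sequence[float], scale: OrdinalScale) -> list[float]:
    """Reverse-code a whole-encoded sequence: each x becomes ``p - x``.

    Required when an item's polarity runs against the scale's positive
    direction.  Involution: applying twice restores the input exactly.
    """
    if _normalize_encoding(scale.encoding) != WHOLE:
        raise ValueError("reverse_code expects whole-number encoded input")
    p = scale.top_whole_value
    out = []
    for i, v in enumerate(values):
        if not scale.is_admissible(v):
            raise ValueError(f"value {v!r} at index {i} is not on the whole-encoded scale")
        out.append(p - v)
    return out


@dataclass(frozen=True)
class AlignmentMap:
    """Injective, order-preserving map from category labels to whole codes.

    ``mapping`` is read in insertion order, which is taken as the ordinal
    order of the source categories.  With ``direction="same"`` the target
    codes must be strictly increasing; with ``direction="reversed"`` they
    must be strictly decreasing (the declared reversal restores
    order-preservation).
    """

    mapping: Mapping[object, float]
    direction: str = "same"

    def __post_init__(self) -> None:
        if self.direction not in ("same", "reversed"):
            raise ValueError("direction must be 'same' or 'reversed'")
        codes = list(self.mapping.values())
        if len(set(codes)) != len(codes):
            raise ValueError("alignment map must be injective (duplicate target codes)")
        diffs = np.diff(codes)
        ok = np.all(diffs > 0) if self.direction == "same" else np.all(diffs < 0)
        if not ok:
            raise ValueError(
                "alignment map must be strictly order-preserving after any declared "
                f"reversal; got target codes {codes} with direction={self.direction!r}"
            )
        object.__setattr__(self, "mapping", dict(self.mapping))


def align_scale(values: Sequence[object], amap: AlignmentMap) -> list[float]:
    """Replace category labels by their aligned whole-number codes."""
    unknown = [v for v in values if v not in amap.mapping]
    if unknown:
        raise ValueError(f"unknown categories (not in alignment map): {sorted(set(map(str, unknown)))}")
    return [float(amap.mapping[v]) for v in values]


@dataclass
class HomogeneityResult:
    """Truthy iff all response vectors share one scale in magnitude and direction."""

    homogeneous: bool
    mismatches: list[dict] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.homogeneous


def validate_homogeneous(vectors: Iterable[ResponseVector]) -> HomogeneityResult:
    """Check that all vectors come from one homogeneous ordinal scale.

    Heterogeneity arises from incompatible magnitude (point count, interval,
    encoding) or directionality (declared polarity).
    """
    vecs = list(vectors)
    if not vecs:
        raise ValueError("validate_homogeneous needs a non-empty collection")
    ref = vecs[0]
    mismatches: list[dict] = []
    for idx, v in enumerate(vecs[1:], start=1):
        if v.scale.point_scale != ref.scale.point_scale or not np.isclose(
            v.scale.max_scale, ref.scale.max_scale
        ):
            mismatches.append({"index": idx, "reason": "incompatible magnitude"})
        elif v.scale.encoding != ref.scale.encoding:
            mismatches.append({"index": idx, "reason": "incompatible encoding"})
        if v.reversed_polarity != ref.reversed_polarity:
            mismatches.append({"index": idx, "reason": "directionality"})
    return HomogeneityResult(not mismatches, mismatches)


def read_responses(
    path,
    scale: OrdinalScale,
    sep: str | None = None,
    header: bool = True,
    na_tokens: Sequence[str] = ("", "NA", "NaN", "nan"),
    drop_na: bool = False,
    reverse_columns: Sequence[str] = (),
) -> list[ResponseVector]:
    """Read a response matrix (rows = individuals, columns = items) from CSV/TSV.

    ``reverse_columns`` names items whose polarity runs against the scale;
    they are reverse-coded after whole-number conversion, so the returned
    vectors are all whole-encoded and homogeneous.
    """
    df = pd.read_csv(
        path,
        sep=sep,
        engine="python" if sep is None else "c",
        header=0 if header else None,
        na_values=list(na_tokens),
        keep_default_na=False,
    )
    labels = [str(c) for c in df.columns]
    bad = set(reverse_columns) - set(labels)
    if bad:
        raise ValueError(f"reverse columns not present in input: {sorted(bad)}")
    whole = scale.as_whole()
    p = whole.top_whole_value
    out = []
    for _, row in df.iterrows():
        rv = ResponseVector(row.tolist(), scale, item_labels=labels, drop_na=drop_na)
        rv = to_whole_encoding(rv)
        if reverse_columns:
            vals = [
                p - v if lab in reverse_columns else v
                for lab, v in zip(labels, rv.values)
            ]
            rv = ResponseVector(vals, whole, item_labels=labels)
        out.append(rv)
    return out
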