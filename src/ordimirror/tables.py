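"""Published worked-example fixtures and their reproduction.

Three fixture sets pin the implementation:

* **well-structured** — three blocks (A: ten 10-item sets, B and C: ten
  15-item sets each) of 5-point natural-encoded responses whose block sums
  are constant, with the printed classical sum/average/median and the
  mirroring-based KCSprox (6 d.p.) / PSprox / PSdev (4 d.p.) per row;
* **scale-robustness** — eleven 7-item sets sharing one internal pattern
  at different scale units, for which the mirroring statistics are
  identical while the classical statistics scale proportionally;
* **sensitivity** — per block, the percent relative entropy of each
  estimator's column (0 for the classical three, 100 for the proposed
  three).

``reproduce_*`` recompute every cell from scratch and compare with the
printed value at its printed rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .evaluation import classical_estimates, percent_relative_entropy
from .optinalysis_core import sm_ordinalysis

__all__ = [
    "TABLE_WELL_STRUCTURED",
    "TABLE_SCALE_ROBUSTNESS",
    "reproduce_well_structured",
    "reproduce_scale_robustness",
    "reproduce_sensitivity",
]


@dataclass(frozen=True)
class FixtureRow:
    label: str
    data: tuple
    point_scale: int
    max_scale: float
    sum: float
    average: float
    median: float
    kc: float          # printed to 6 d.p.
    psprox: float      # printed to 4 d.p.
    psdev: float       # printed to 4 d.p.


def _row(label, data, ps, ms, s, a, m, kc, pp, pd_):
    return FixtureRow(label, tuple(data), ps, ms, s, a, m, kc, pp, pd_)


#: 31 rows, 5-point natural encoding; block sums constant within A, B, C.
TABLE_WELL_STRUCTURED: tuple = (
    _row("A_1", [2, 3, 3, 3, 3, 3, 3, 3, 3, 4], 5, 5, 30, 3.00, 3.00, 0.847240, 0.6690, 0.3310),
    _row("A_2", [2, 2, 3, 3, 3, 3, 3, 3, 4, 4], 5, 5, 30, 3.00, 3.00, 0.839695, 0.6529, 0.3471),
    _row("A_3", [1, 3, 3, 3, 3, 3, 3, 3, 3, 5], 5, 5, 30, 3.00, 3.00, 0.837563, 0.6484, 0.3516),
    _row("A_4", [2, 2, 2, 3, 3, 3, 3, 4, 4, 4], 5, 5, 30, 3.00, 3.00, 0.834387, 0.6416, 0.3584),
    _row("A_5", [2, 2, 2, 2, 3, 3, 4, 4, 4, 4], 5, 5, 30, 3.00, 3.00, 0.831234, 0.6349, 0.3651),
    _row("A_6", [2, 2, 2, 2, 2, 4, 4, 4, 4, 4], 5, 5, 30, 3.00, 3.00, 0.830189, 0.6327, 0.3673),
    _row("A_7", [1, 1, 3, 3, 3, 3, 3, 3, 5, 5], 5, 5, 30, 3.00, 3.00, 0.822943, 0.6173, 0.3827),
    _row("A_8", [1, 1, 1, 3, 3, 3, 3, 5, 5, 5], 5, 5, 30, 3.00, 3.00, 0.812808, 0.5957, 0.4043),
    _row("A_9", [1, 1, 1, 1, 3, 3, 5, 5, 5, 5], 5, 5, 30, 3.00, 3.00, 0.806846, 0.5831, 0.4169),
    _row("A_10", [1, 1, 1, 1, 1, 5, 5, 5, 5, 5], 5, 5, 30, 3.00, 3.00, 0.804878, 0.5789, 0.4211),
    _row("B_1", [2, 2, 2, 1, 2, 5, 1, 4, 2, 1, 4, 2, 3, 3, 2], 5, 5, 36, 2.40, 2.40, 0.773270, 0.5235, 0.4765),
    _row("B_2", [2, 3, 2, 1, 1, 3, 3, 2, 5, 2, 3, 2, 3, 2, 2], 5, 5, 36, 2.40, 2.40, 0.779783, 0.5370, 0.4630),
    _row("B_3", [2, 1, 1, 4, 5, 4, 2, 3, 1, 2, 2, 1, 5, 1, 2], 5, 5, 36, 2.40, 2.40, 0.765505, 0.5074, 0.4926),
    _row("B_4", [2, 2, 2, 4, 2, 5, 1, 1, 2, 2, 4, 4, 2, 1, 2], 5, 5, 36, 2.40, 2.40, 0.772809, 0.5226, 0.4774),
    _row("B_5", [3, 1, 3, 4, 2, 2, 2, 2, 2, 4, 5, 1, 1, 1, 3], 5, 5, 36, 2.40, 2.40, 0.770511, 0.5178, 0.4822),
    _row("B_6", [2, 2, 2, 2, 3, 1, 5, 3, 2, 2, 3, 2, 3, 2, 2], 5, 5, 36, 2.40, 2.40, 0.783555, 0.5448, 0.4552),
    _row("B_7", [3, 1, 1, 1, 3, 2, 3, 3, 2, 5, 3, 2, 1, 2, 4], 5, 5, 36, 2.40, 2.40, 0.772348, 0.5216, 0.4784),
    _row("B_8", [3, 3, 2, 2, 3, 2, 1, 2, 3, 4, 2, 1, 2, 5, 1], 5, 5, 36, 2.40, 2.40, 0.774656, 0.5264, 0.4736),
    _row("B_9", [2, 2, 2, 1, 3, 3, 5, 2, 1, 1, 2, 2, 4, 1, 5], 5, 5, 36, 2.40, 2.40, 0.768683, 0.5140, 0.4860),
    _row("B_10", [1, 1, 5, 1, 1, 2, 4, 2, 5, 3, 1, 1, 5, 1, 3], 5, 5, 36, 2.40, 2.40, 0.761010, 0.4982, 0.5018),
    _row("C_1", [4, 5, 1, 3, 5, 4, 3, 3, 4, 4, 1, 3, 2, 4, 4], 5, 5, 50, 3.33, 3.33, 0.848214, 0.6794, 0.3206),
    _row("C_2", [1, 5, 5, 3, 4, 3, 1, 4, 2, 3, 4, 2, 4, 5, 4], 5, 5, 50, 3.33, 3.33, 0.843976, 0.6706, 0.3294),
    _row("C_3", [5, 2, 4, 3, 4, 1, 5, 5, 4, 2, 4, 3, 2, 2, 4], 5, 5, 50, 3.33, 3.33, 0.845384, 0.6735, 0.3265),
    _row("C_4", [1, 5, 3, 5, 3, 4, 2, 2, 3, 5, 4, 4, 1, 5, 3], 5, 5, 50, 3.33, 3.33, 0.842105, 0.6667, 0.3333),
    _row("C_5", [2, 3, 5, 5, 3, 2, 5, 2, 1, 2, 4, 5, 5, 3, 3], 5, 5, 50, 3.33, 3.33, 0.842572, 0.6676, 0.3324),
    _row("C_6", [3, 4, 2, 1, 5, 3, 5, 4, 2, 4, 2, 3, 3, 5, 4], 5, 5, 50, 3.33, 3.33, 0.846797, 0.6765, 0.3235),
    _row("C_7", [2, 5, 2, 3, 1, 3, 4, 4, 4, 2, 4, 5, 3, 4, 4], 5, 5, 50, 3.33, 3.33, 0.849162, 0.6814, 0.3186),
    _row("C_8", [2, 3, 3, 3, 3, 1, 5, 4, 3, 4, 3, 3, 4, 5, 4], 5, 5, 50, 3.33, 3.33, 0.853933, 0.6914, 0.3086),
    _row("C_9", [4, 1, 2, 5, 5, 3, 1, 3, 5, 5, 3, 1, 4, 5, 3], 5, 5, 50, 3.33, 3.33, 0.838389, 0.6589, 0.3411),
    _row("C_10", [4, 3, 3, 2, 2, 3, 1, 4, 3, 5, 4, 3, 4, 5, 4], 5, 5, 50, 3.33, 3.33, 0.851064, 0.6854, 0.3146),
)

#: 11 rows, one 7-point pattern at different scale units; mirroring
#: statistics identical throughout, classical statistics proportional.
TABLE_SCALE_ROBUSTNESS: tuple = (
    _row("D_1", [0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07], 7, 0.07, 0.28, 0.04, 0.04, 0.818182, 0.5949, 0.4051),
    _row("D_2", [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7], 7, 0.7, 2.80, 0.40, 0.40, 0.818182, 0.5949, 0.4051),
    _row("D_3", [0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4], 7, 1.4, 5.60, 0.80, 0.80, 0.818182, 0.5949, 0.4051),
    _row("D_4", [0.3, 0.6, 0.9, 1.2, 1.5, 1.8, 2.1], 7, 2.1, 8.40, 1.20, 1.20, 0.818182, 0.5949, 0.4051),
    _row("D_5", [0.4, 0.8, 1.2, 1.6, 2.0, 2.4, 2.8], 7, 2.8, 11.20, 1.60, 1.60, 0.818182, 0.5949, 0.4051),
    _row("D_6", [100, 200, 300, 400, 500, 600, 700], 7, 700, 2800, 400, 400, 0.818182, 0.5949, 0.4051),
    _row("D_7", [10, 20, 30, 40, 50, 60, 70], 7, 70, 280, 40, 40, 0.818182, 0.5949, 0.4051),
    _row("D_8", [1, 2, 3, 4, 5, 6, 7], 7, 7, 28, 4, 4, 0.818182, 0.5949, 0.4051),
    _row("D_9", [2, 4, 6, 8, 10, 12, 14], 7, 14, 56, 8, 8, 0.818182, 0.5949, 0.4051),
    _row("D_10", [3, 6, 9, 12, 15, 18, 21], 7, 21, 84, 12, 12, 0.818182, 0.5949, 0.4051),
    _row("D_11", [4, 8, 12, 16, 20, 24, 28], 7, 28, 112, 16, 16, 0.818182, 0.5949, 0.4051),
)

#: printed percent relative sensitivity per block and estimator column.
SENSITIVITY_EXPECTED = {
    "SS": 0.0, "AS": 0.0, "MS": 0.0,
    "KCSprox": 100.0, "PSprox": 100.0, "PSdev": 100.0,
}


def _recompute(row: FixtureRow) -> dict:
    cls = classical_estimates(row.data)
    res = sm_ordinalysis(list(row.data), row.point_scale, row.max_scale,
                         "natural_numbers", "all_in_dict")
    return {
        "sum": cls["sum"],
        "average": cls["average"],
        "median": cls["median"],
        "kc": res["kc_sprox"],
        "psprox": res["p_sprox"],
        "psdev": res["p_sdev"],
    }


def _compare_rows(rows) -> pd.DataFrame:
    decimals = {"sum": 2, "average": 2, "median": 2, "kc": 6, "psprox": 4, "psdev": 4}
    out = []
    for row in rows:
        got = _recompute(row)
        for col, nd in decimals.items():
            printed = getattr(row, col)
            computed = round(got[col], nd)
            ok = abs(computed - round(printed, nd)) < 10 ** (-nd) / 2
            # The published median cells in the 15-item blocks B and C print
            # the mean instead of the sample median; they are reported but
            # not locked (see the package methods note).
            locked = not (col == "median" and row.label[0] in "BC")
            out.append(
                dict(row=row.label, column=col, printed=printed, computed=got[col],
                     ok=ok, locked=locked)
            )
    return pd.DataFrame(out)


def reproduce_well_structured() -> pd.DataFrame:
    """Recompute all 31 well-structured rows against the printed values."""
    return _compare_rows(TABLE_WELL_STRUCTURED)


def reproduce_scale_robustness() -> pd.DataFrame:
    """Recompute all 11 scale-robustness rows against the printed values."""
    return _compare_rows(TABLE_SCALE_ROBUSTNESS)


def reproduce_sensitivity() -> pd.DataFrame:
    """Percent relative entropy per block and estimator column.

    Classical columns are constant within a block (0%); the mirroring
    columns are all-distinct (100%).
    """
    blocks = {"A": [], "B": [], "C": []}
    for row in TABLE_WELL_STRUCTURED:
        blocks[row.label.split("_")[0]].append(row)
    out = []
    for block, rows in blocks.items():
        cols = {k: [] for k in SENSITIVITY_EXPECTED}
        for row in rows:
            got = _recompute(row)
            cols["SS"].append(got["sum"])
            cols["AS"].append(got["average"])
            cols["MS"].append(got["median"])
            cols["KCSprox"].append(got["kc"])
            cols["PSprox"].append(got["psprox"])
            cols["PSdev"].append(got["psdev"])
        for est, series in cols.items():
            value = percent_relative_entropy(series)
            expected = SENSITIVITY_EXPECTED[est]
            # The printed 0% for the median in block C derives from the
            # defective published median cells (which print the mean); the
            # true block-C medians vary between 3 and 4, so their entropy
            # is honestly nonzero.  Reported, not locked.
            locked = not (block == "C" and est == "MS")
            out.append(
                dict(block=block, estimator=est, printed=expected, computed=value,
                     ok=abs(value - expected) < 1e-9, locked=locked)
            )
    return pd.DataFrame(out)
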