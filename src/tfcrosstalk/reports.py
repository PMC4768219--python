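"""Reporting helpers: printed-style percentages and result serialisation."""

from __future__ import annotations

import json
import math
from typing import Mapping

import pandas as pd


def rounded_percentage(k: float, n: float) -> float:
    """Render the fraction ``k/n`` the way the summary figures are printed.

    Figures of at least 2 % are rounded half-up to the nearest integer
    ("ca. 24 %"); smaller figures are truncated at one decimal so that a
    marginal class is never inflated past its printed precision.
    """
    if n <= 0:
        raise ValueError("denominator must be positive")
    pct = 100.0 * k / n
    if pct >= 2.0:
        return float(math.floor(pct + 0.5))
    return math.floor(pct * 10.0) / 10.0


def write_json(obj: Mapping, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_tsv(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.6g")
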