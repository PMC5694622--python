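"""Result serialization: JSON bundles and summary CSV tables.

CSV summaries round to 4 decimal places; the JSON bundle keeps full
precision. p-values below 1e-4 are displayed as "< 0.0001" in formatted
tables while the raw value is retained in JSON.
"""

from __future__ import annotations

import json
from typing import Iterable

import pandas as pd

from .inference import VUSResult

__all__ = ["estimates_table", "tests_table", "results_json", "write_results"]

ESTIMATE_COLUMNS = [
    "Estimate",
    "Std.Err",
    "Lower.Normal",
    "Upper.Normal",
    "Lower.Logit",
    "Upper.Logit",
]


def estimates_table(results: Iterable[VUSResult]) -> pd.DataFrame:
    """Wide table of estimates and 95% CIs, one row per method."""
    rows = {}
    for r in results:
        lo_l, hi_l = r.ci_logit if r.ci_logit is not None else (float("nan"),) * 2
        rows[r.method.upper()] = [
            r.estimate, r.se, r.ci_normal[0], r.ci_normal[1], lo_l, hi_l,
        ]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=ESTIMATE_COLUMNS)
    return df.round(4)


def tests_table(results: Iterable[VUSResult]) -> pd.DataFrame:
    """Table of the useless-test statistics, one row per method."""
    rows = {r.method.upper(): [round(r.t_stat, 4), r.format_p()] for r in results}
    return pd.DataFrame.from_dict(rows, orient="index", columns=["t-stat", "p-value"])


def results_json(results: Iterable[VUSResult], extra: dict | None = None) -> str:
    bundle = {"results": [r.to_dict() for r in results]}
    if extra:
        bundle.update(extra)
    return json.dumps(bundle, indent=2, sort_keys=True)


def write_results(results: list[VUSResult], outdir, prefix: str = "vus") -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    estimates_table(results).to_csv(outdir / f"{prefix}_estimates.csv")
    tests_table(results).to_csv(outdir / f"{prefix}_tests.csv")
    (outdir / f"{prefix}_results.json").write_text(results_json(results))
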