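"""Trial-to-trial variability: coefficients of variation of edge values and
behavior scores across repeated trials."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["cov", "build_cov_table"]


def cov(values) -> float:
    """Coefficient of variation: sample standard deviation (n-1 denominator)
    divided by the mean.  Requires at least two values and a mean bounded
    away from zero."""
    x = np.asarray(values, float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < 2:
        raise ValueError("CoV needs at least two trial values")
    m = x.mean()
    if abs(m) <= 1e-12:
        raise ValueError("CoV undefined: mean is (numerically) zero")
    return float(x.std(ddof=1) / m)


def build_cov_table(edge_table: pd.DataFrame) -> pd.DataFrame:
    """Per-(subject, condition) CoV of every edge and of the score.

    ``edge_table`` is the long-format output of
    :func:`nirsnet.gc.first_window_networks` (columns subject, group,
    condition, trial, source, target, gc, valid, score).  Edges with invalid
    trials are computed on the remaining valid trials when at least two
    remain, and set to NaN (with a log entry) otherwise; the score CoV uses
    all trials of the cell.
    """
    rows = []
    for (subject, group, condition), cell in edge_table.groupby(
        ["subject", "group", "condition"], sort=True
    ):
        row: dict = dict(subject=subject, group=group, condition=condition)
        scores = cell.drop_duplicates("trial").sort_values("trial")["score"].to_numpy()
        try:
            row["score_cov"] = cov(scores)
        except ValueError:
            logger.warning("score CoV undefined for %s/%s", subject, condition)
            row["score_cov"] = np.nan
        for (src, dst), edge in cell.groupby(["source", "target"], sort=False):
            name = f"{src}->{dst}"
            vals = edge.loc[edge["valid"], "gc"].to_numpy()
            if vals.size < 2:
                logger.warning("edge %s of %s/%s has <2 valid trials; CoV masked",
                               name, subject, condition)
                row[name] = np.nan
                continue
            if vals.size < edge.shape[0]:
                logger.info("edge %s of %s/%s uses %d of %d trials",
                            name, subject, condition, vals.size, edge.shape[0])
            try:
                row[name] = cov(vals)
            except ValueError:
                row[name] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
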