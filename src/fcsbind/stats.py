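"""Group statistics: per-nucleus aggregation and condition comparison.

Measurements (one fitted curve each) are aggregated to per-nucleus means
and conditions are compared per parameter with a two-sided Welch t-test at
alpha = 0.005.  Welch is the default because group sizes are unequal and
no variance homogeneity is assumed; Student's pooled test is available
behind a flag and coincides with Welch for equal-variance, equal-n data.
No multiple-testing correction is applied across the parameters by
default, matching a single-threshold presentation; a Holm-corrected report
is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

#: parameters carried through aggregation and comparison
PARAMETERS = ("N", "D", "kon_uM", "koff", "kd_uM")

_REQUIRED = ("condition", "nucleus", "measurement", "converged")


def measurement_table(rows) -> pd.DataFrame:
    """Build a measurement table from fit-result rows.

    Each row needs condition, nucleus, measurement ids, a ``converged``
    flag and the fitted/derived parameters (N, D, kon_uM, koff, kd_uM).
    (condition, nucleus, measurement) must be unique.
    """
    df = pd.DataFrame(list(rows))
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table lacks columns {missing}")
    dup = df.duplicated(subset=["condition", "nucleus", "measurement"])
    if dup.any():
        raise ValueError("duplicate (condition, nucleus, measurement) rows")
    return df


def aggregate_by_nucleus(table: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of each parameter over a nucleus's converged fits.

    Non-converged measurements are excluded; nuclei with no converged
    measurement are dropped with a warning.  Kd is averaged like every
    other parameter (not re-derived from the aggregated rates).
    """
    if len(table) == 0:
        raise ValueError("empty measurement table")
    ok = table[table["converged"].astype(bool)]
    dropped = set(map(tuple, table[["condition", "nucleus"]].values)) \
        - set(map(tuple, ok[["condition", "nucleus"]].values))
    if dropped:
        warnings.warn(f"dropping {len(dropped)} nuclei with no converged "
                      f"measurement: {sorted(dropped)}", stacklevel=2)
    if len(ok) == 0:
        raise ValueError("no converged measurements to aggregate")
    cols = [p for p in PARAMETERS if p in ok.columns]
    agg = (ok.groupby(["condition", "nucleus"], as_index=False)
             .agg(**{p: (p, "mean") for p in cols},
                  n_measurements=("measurement", "count")))
    flagged = ok.groupby(["condition", "nucleus"])["measurement"].count()
    total = table.groupby(["condition", "nucleus"])["measurement"].count()
    partial = (flagged != total.loc[flagged.index])
    agg["partial"] = partial.values
    return agg


@dataclass
class ConditionSummary:
    """Per-condition parameter summaries and per-parameter comparisons."""

    condition_a: str
    condition_b: str
    alpha: float
    test: str
    unit: str
    summary: pd.DataFrame  # parameter x (mean_a, sd_a, n_a, mean_b, sd_b, n_b, t, df, p, significant)
    meta: dict = field(default_factory=dict)

    def significant(self, parameter: str) -> bool:
        return bool(self.summary.loc[parameter, "significant"])

    def to_text(self) -> str:
        lines = [f"condition comparison: {self.condition_a} vs {self.condition_b} "
                 f"({self.test} t-test, alpha = {self.alpha}, unit = {self.unit})"]
        lines.append(self.summary.to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def _welch(a, b):
    na, nb = len(a), len(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(na + nb - 2), 1.0
        return np.inf, float(na + nb - 2), 0.0
    se2 = va / na + vb / nb
    t = (np.mean(a) - np.mean(b)) / np.sqrt(se2)
    df = se2**2 / (va**2 / (na**2 * (na - 1)) + vb**2 / (nb**2 * (nb - 1)))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _student(a, b):
    na, nb = len(a), len(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(na + nb - 2), 1.0
        return np.inf, float(na + nb - 2), 0.0
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    df = float(na + nb - 2)
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def compare_conditions(a: pd.DataFrame, b: pd.DataFrame, alpha: float = 0.005,
                       test: str = "welch", unit: str = "nucleus",
                       holm: bool = False) -> ConditionSummary:
    """Two-sided t-test per parameter between two condition tables.

    ``a`` and ``b`` are measurement tables (per-measurement rows); with
    ``unit="nucleus"`` (default, matching a means-per-nucleus analysis)
    they are first aggregated by nucleus; ``unit="measurement"`` compares
    raw converged measurements.
    """
    if test not in ("welch", "student"):
        raise ValueError("test must be 'welch' or 'student'")
    if unit not in ("nucleus", "measurement"):
        raise ValueError("unit must be 'nucleus' or 'measurement'")
    ta = aggregate_by_nucleus(a) if unit == "nucleus" else a[a["converged"].astype(bool)]
    tb = aggregate_by_nucleus(b) if unit == "nucleus" else b[b["converged"].astype(bool)]
    if len(ta) < 3 or len(tb) < 3:
        raise ValueError("need at least 3 aggregated units per condition")
    stat = _welch if test == "welch" else _student
    rows = {}
    cols = [p for p in PARAMETERS if p in ta.columns and p in tb.columns]
    for p in cols:
        xa = ta[p].dropna().to_numpy()
        xb = tb[p].dropna().to_numpy()
        t, df, pv = stat(xa, xb)
        rows[p] = {"mean_a": xa.mean(), "sd_a": xa.std(ddof=1), "n_a": len(xa),
                   "mean_b": xb.mean(), "sd_b": xb.std(ddof=1), "n_b": len(xb),
                   "t": t, "df": df, "p": pv}
    summary = pd.DataFrame(rows).T
    if holm:
        order = np.argsort(summary["p"].values)
        m = len(order)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * summary["p"].values[idx])
            adj[idx] = min(running, 1.0)
        summary["p_holm"] = adj
        summary["significant"] = summary["p_holm"] <= alpha
    else:
        summary["significant"] = summary["p"] <= alpha
    conda = a["condition"].iloc[0] if len(a) else "a"
    condb = b["condition"].iloc[0] if len(b) else "b"
    return ConditionSummary(str(conda), str(condb), alpha, test, unit, summary)
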