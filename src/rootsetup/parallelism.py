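"""Adjacent-tooth root parallelism: pair differences, the left/right
pooling gate, and the per-location comparison table.

Root parallelism is summarised as the absolute difference in angulation
between consecutive teeth of a quadrant (locations ``1-2`` through
``6-7``).  Before comparing setups, angular measurements of the initial
scan are tested per tooth position with a paired t-test between the left
and right sides; when no position differs the two sides are pooled and
each side's pair value enters the setup comparison as one observation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .stats import RepeatedBlock, paired_t, rm_anova

log = logging.getLogger(__name__)

SETUP_ORDER = ("crown", "root1", "root2")

LOCATION_LABELS = tuple(f"{i}-{i + 1}" for i in range(1, 7))

_SIDE = {1: "right", 2: "left", 3: "left", 4: "right"}
_JAW = {1: "maxilla", 2: "maxilla", 3: "mandible", 4: "mandible"}


@dataclass(frozen=True)
class PoolingGate:
    """Outcome of the left/right pooling gate on initial-scan angles."""

    report: pd.DataFrame  # jaw, position, n_pairs, t, p, pooled
    pooled: bool

    @property
    def failing(self) -> pd.DataFrame:
        return self.report[~self.report["pooled"]]


def adjacent_differences(measurements: pd.DataFrame) -> pd.DataFrame:
    """Absolute angulation differences between adjacent teeth.

    ``measurements`` is tidy with columns ``patient_id, setup, fdi,
    angulation`` (extra columns are ignored).  Output rows carry
    ``patient_id, setup, jaw, side, location, value``; pairs with a
    missing tooth are omitted.
    """
    df = measurements.copy()
    df["quadrant"] = df["fdi"] // 10
    df["position"] = df["fdi"] % 10
    rows = []
    for (pid, setup, quad), g in df.groupby(["patient_id", "setup", "quadrant"]):
        ang = dict(zip(g["position"], g["angulation"]))
        for pos in range(1, 7):
            if pos in ang and pos + 1 in ang:
                rows.append(
                    {
                        "patient_id": pid,
                        "setup": setup,
                        "jaw": _JAW[quad],
                        "side": _SIDE[quad],
                        "location": f"{pos}-{pos + 1}",
                        "value": abs(ang[pos] - ang[pos + 1]),
                    }
                )
            elif (pos in ang) != (pos + 1 in ang):
                log.info(
                    "patient %s %s quadrant %d: pair %d-%d omitted (missing tooth)",
                    pid, setup, quad, pos, pos + 1,
                )
    return pd.DataFrame(
        rows, columns=["patient_id", "setup", "jaw", "side", "location", "value"]
    )


def pool_left_right(initial: pd.DataFrame, alpha: float = 0.05) -> PoolingGate:
    """Left/right pooling gate from initial-scan angular measurements.

    ``initial`` has columns ``patient_id, fdi, angulation``.  A paired
    t-test is run per (jaw, tooth position) on left-vs-right values
    paired within patient; the sides may be pooled when every location
    has p >= alpha.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    df = initial.copy()
    df["quadrant"] = df["fdi"] // 10
    df["jaw"] = df["quadrant"].map(_JAW)
    df["side"] = df["quadrant"].map(_SIDE)
    df["position"] = df["fdi"] % 10
    rows = []
    for (jaw, pos), g in df.groupby(["jaw", "position"]):
        wide = g.pivot_table(
            index="patient_id", columns="side", values="angulation", aggfunc="first"
        )
        if "left" not in wide or "right" not in wide:
            raise InsufficientDataError(f"{jaw} position {pos}: missing one side")
        wide = wide.dropna()
        if len(wide) < 2:
            raise InsufficientDataError(
                f"{jaw} position {pos}: fewer than 2 complete left/right pairs"
            )
        r = paired_t(wide["left"].to_numpy(), wide["right"].to_numpy())
        rows.append(
            {
                "jaw": jaw,
                "position": pos,
                "n_pairs": len(wide),
                "t": r.statistic,
                "p": r.p_value,
                "pooled": r.p_value >= alpha,
            }
        )
    report = pd.DataFrame(rows)
    return PoolingGate(report, bool(report["pooled"].all()))


def parallelism_table(
    pair_values: pd.DataFrame,
    alpha: float = 0.05,
    *,
    pooled: bool = True,
    setups: tuple[str, ...] = SETUP_ORDER,
) -> pd.DataFrame:
    """Per jaw x location comparison of the three setups.

    Each (patient, side) pair value is one observation; subjects missing
    a setup at a location are excluded there with a warning.  Returns a
    tidy table with per-setup mean/sd/n, the repeated-measures ANOVA p,
    Mauchly's W and p, and Bonferroni post-hoc labels (``a``: crown,
    ``b``: root setup-1, ``c``: root setup-2), or ``"NA"`` when the
    omnibus test is not significant.

    With ``pooled=False`` the left and right sides are kept as separate
    rows (used when the pooling gate fails).
    """
    df = pair_values[pair_values["setup"].isin(setups)].copy()
    group_cols = ["jaw", "location"] if pooled else ["jaw", "location", "side"]
    rows = []
    for key, g in df.groupby(group_cols):
        key = key if isinstance(key, tuple) else (key,)
        wide = g.pivot_table(
            index=["patient_id", "side"], columns="setup", values="value",
            aggfunc="first",
        )
        missing_setups = [s for s in setups if s not in wide.columns]
        if missing_setups:
            raise InsufficientDataError(
                f"{key}: no observations for setups {missing_setups}"
            )
        complete = wide[list(setups)].dropna()
        n_dropped = len(wide) - len(complete)
        if n_dropped:
            log.warning("%s: excluded %d subjects with unbalanced setups", key,
                        n_dropped)
        row = dict(zip(group_cols, key))
        for s in setups:
            row[f"mean_{s}"] = complete[s].mean() if len(complete) else np.nan
            row[f"sd_{s}"] = complete[s].std(ddof=1) if len(complete) > 1 else np.nan
            row[f"n_{s}"] = len(complete)
        try:
            block = RepeatedBlock(
                tuple(complete.index), tuple(setups), complete.to_numpy()
            )
            rep = rm_anova(block, alpha)
            row["p_value"] = rep.omnibus.p_value
            row["mauchly_w"] = rep.sphericity.statistic if rep.sphericity else np.nan
            row["mauchly_p"] = rep.sphericity.p_value if rep.sphericity else np.nan
            row["posthoc"] = ", ".join(rep.labels) if rep.labels else "NA"
        except InsufficientDataError as exc:
            log.warning("%s: %s", key, exc)
            row["p_value"] = np.nan
            row["mauchly_w"] = np.nan
            row["mauchly_p"] = np.nan
            row["posthoc"] = "insufficient-data"
        rows.append(row)
    out = pd.DataFrame(rows)
    order = {loc: i for i, loc in enumerate(LOCATION_LABELS)}
    jaw_order = {"maxilla": 0, "mandible": 1}
    return out.sort_values(
        group_cols, key=lambda s: s.map({**order, **jaw_order}).fillna(0)
    ).reset_index(drop=True)
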