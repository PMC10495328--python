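"""Simulation studies over replicated synthetic cohorts.

Two study designs are provided:

* **type-I calibration** -- cohorts generated under the null (identical
  generative distributions for every setup condition) are pushed through
  the real comparison stages, and the rejection rate of each stage at a
  given alpha is estimated.  One representative maxillary row per stage
  is used per replicate (the adjacent-incisor parallelism ANOVA, the
  incisor buccal-exposure Friedman test, and the incisor-frequency
  McNemar test) so replicate outcomes are independent Bernoulli draws
  and an exact binomial envelope applies.

* **directional power** -- cohorts generated with the study-shaped
  effect structure (crown setup: larger angular dispersion and designed
  exposures; root setup-2: near-zero exposure) are run end to end, and
  each replicate is scored for whether the post-hoc pattern
  "crown worse than both root setups" appears in the parallelism table
  and "both crown-level setups worse than root setup-2" in the exposure
  table.

Both run on the mesh-free path: angles are measured from the generated
landmarks and exposures taken from the generator's analytic ground
truth, which is what the mesh measurement recovers up to sampling error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .parallelism import adjacent_differences, parallelism_table
from .pipeline import measure_cohort_angles, truth_exposure_frame, run_exposure_stats
from .stats import RepeatedBlock, friedman_wilcoxon, mcnemar, rm_anova
from .synthetic import SETUPS, build_cohort, null_effect, study_effect


def _stage_pvalues(cohort) -> tuple[float, float, float]:
    """The three representative stage p-values of one cohort."""
    angles = measure_cohort_angles(cohort)
    pairs = adjacent_differences(angles)
    g = pairs[(pairs["jaw"] == "maxilla") & (pairs["location"] == "1-2")]
    wide = g.pivot_table(index=["patient_id", "side"], columns="setup",
                         values="value", aggfunc="first")[list(SETUPS)].dropna()
    p_anova = rm_anova(
        RepeatedBlock(tuple(wide.index), SETUPS, wide.to_numpy())
    ).omnibus.p_value

    expo = truth_exposure_frame(cohort)
    inc = expo[(expo["jaw"] == "maxilla") & (expo["fdi"] % 10 <= 2)]
    buc = inc[inc["side"] == "buccal"]
    wide2 = buc.pivot_table(index=["patient_id", "fdi"], columns="setup",
                            values="combined", aggfunc="first")[list(SETUPS)].dropna()
    p_friedman = friedman_wilcoxon(
        RepeatedBlock(tuple(wide2.index), SETUPS, wide2.to_numpy())
    ).omnibus.p_value

    crown = inc[inc["setup"] == "crown"].pivot_table(
        index=["patient_id", "fdi"], columns="side", values="combined",
        aggfunc="first",
    )
    over_b = crown["buccal"] > 2.0
    over_l = crown["lingual"] > 2.0
    b = int((over_b & ~over_l).sum())
    c = int((~over_b & over_l).sum())
    p_mcnemar = mcnemar(b, c).p_value
    return p_anova, p_friedman, p_mcnemar


def null_type1_pvalues(
    n_replicates: int, seed: int, n_patients: int = 16
) -> pd.DataFrame:
    """Stage p-values under ``n_replicates`` independent null cohorts."""
    rows = []
    for rep in range(n_replicates):
        cohort = build_cohort(
            n_patients, null_effect(), seed=_subseed(seed, rep),
            include_initial=False, jaws=("maxilla",),
        )
        pa, pf, pm = _stage_pvalues(cohort)
        rows.append({"replicate": rep, "p_rm_anova": pa, "p_friedman": pf,
                     "p_mcnemar": pm})
    return pd.DataFrame(rows)


def rejection_rates(pvalues: pd.DataFrame, alpha: float = 0.05) -> dict[str, float]:
    return {
        col.removeprefix("p_"): float((pvalues[col] < alpha).mean())
        for col in pvalues.columns if col.startswith("p_")
    }


def binomial_envelope(n: int, p: float = 0.05, level: float = 0.99):
    """Exact central binomial envelope for a rejection count out of n."""
    from scipy.stats import binom

    lo = binom.ppf((1 - level) / 2, n, p) / n
    hi = binom.ppf(1 - (1 - level) / 2, n, p) / n
    return float(lo), float(hi)


def directional_outcomes(
    n_replicates: int, seed: int, n_patients: int = 16, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-replicate detection of the study-shaped effect pattern."""
    rows = []
    for rep in range(n_replicates):
        cohort = build_cohort(
            n_patients, study_effect(), seed=_subseed(seed, rep),
            include_initial=False,
        )
        angles = measure_cohort_angles(cohort)
        pairs = adjacent_differences(angles)
        table1 = parallelism_table(pairs, alpha)
        par_hit = bool(
            (table1["posthoc"].str.contains("a > b").fillna(False)
             & table1["posthoc"].str.contains("a > c").fillna(False)).any()
        )
        t2, _ = run_exposure_stats(truth_exposure_frame(cohort), 2.0, alpha)
        exp_hit = bool(
            (t2["posthoc"].str.contains("a > c").fillna(False)
             & t2["posthoc"].str.contains("b > c").fillna(False)).any()
        )
        rows.append({"replicate": rep, "parallelism_pattern": par_hit,
                     "exposure_pattern": exp_hit})
    return pd.DataFrame(rows)


def _subseed(seed: int, rep: int) -> int:
    # distinct, reproducible sub-seeds below 2**31
    return int((seed * 1_000_003 + rep) % 2_147_483_647)
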