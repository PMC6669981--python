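"""Simulation studies: FWER calibration and effect recovery.

These harnesses exercise the whole inference chain (cohort simulation ->
pot aggregation -> weighted block model -> multiplicity-adjusted contrasts)
under a known truth.  ``null_fwer`` estimates the family-wise error rate of
the Dunnett and Tukey procedures on null cohorts; ``effect_recovery``
estimates the power to detect the strongest host effects and how well the
treatment-level survivorship-color coupling is recovered.
"""

from __future__ import annotations

import numpy as np

from .pheno import aggregate_pots
from .stats import BlockDesignModel, pearson_r2
from .synthdata import CohortDesign, EffectModel, simulate_cohort

__all__ = ["null_fwer", "effect_recovery"]


def _fit_pots(design: CohortDesign, effects: EffectModel, seed: int, response: str):
    plants, _ = simulate_cohort(design, effects, seed=seed)
    pots = aggregate_pots(plants)
    model = BlockDesignModel.from_dataframe(pots, response=response)
    return pots, model.fit()


def null_fwer(
    n_reps: int,
    seed: int,
    design: CohortDesign | None = None,
    response: str = "gr_ratio",
    alpha: float = 0.05,
) -> dict:
    """Family-wise error rates of Dunnett and Tukey on null cohorts.

    Each replicate simulates a cohort in which every host equals the
    control, fits the weighted block model and records whether the family's
    smallest adjusted p falls below ``alpha`` (a false rejection).  Returns
    the rejection rates with their binomial standard errors.
    """
    design = design or CohortDesign()
    effects = EffectModel.null(design.treatments)
    seeds = np.random.SeedSequence(seed).generate_state(n_reps)
    dunnett_hits = tukey_hits = 0
    for s in seeds:
        _, res = _fit_pots(design, effects, int(s), response)
        if res.min_adjusted_p("dunnett", control=design.control) < alpha:
            dunnett_hits += 1
        if res.min_adjusted_p("tukey") < alpha:
            tukey_hits += 1
    return {
        "n_reps": n_reps,
        "alpha": alpha,
        "dunnett_fwer": dunnett_hits / n_reps,
        "tukey_fwer": tukey_hits / n_reps,
        "binomial_se": float(np.sqrt(alpha * (1 - alpha) / n_reps)),
    }


def effect_recovery(
    n_reps: int,
    seed: int,
    design: CohortDesign | None = None,
    response: str = "gr_ratio",
    alpha: float = 0.05,
    strong_hosts: tuple[str, ...] = ("zea", "solanum"),
) -> dict:
    """Power and survivorship-color coupling under the default host effects.

    Each replicate simulates a cohort with the default effect model, runs
    the Dunnett comparison against the control and records (a) whether each
    strong host is detected and (b) the treatment-level Pearson r^2 between
    mean survivorship and the estimated color (G/R) level means.
    """
    design = design or CohortDesign()
    effects = EffectModel.default(design.treatments)
    seeds = np.random.SeedSequence(seed).generate_state(n_reps)
    detected = {h: 0 for h in strong_hosts}
    r2s = []
    for s in seeds:
        pots, res = _fit_pots(design, effects, int(s), response)
        for comp in res.dunnett(control=design.control):
            host = comp.contrast[0]
            if host in detected and comp.p_adjusted < alpha:
                detected[host] += 1
        surv = pots.groupby("host")["survivorship"].mean()
        levels = list(res.treatment_levels)
        r2s.append(
            pearson_r2(
                [surv[t] for t in levels],
                [res.estimates[t] for t in levels],
                x_name="survivorship",
                y_name=response,
            ).r_squared
        )
    return {
        "n_reps": n_reps,
        "alpha": alpha,
        "power": {h: detected[h] / n_reps for h in strong_hosts},
        "mean_r_squared": float(np.mean(r2s)),
        "min_r_squared": float(np.min(r2s)),
    }
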