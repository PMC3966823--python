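"""Simulation studies validating the mixed-model machinery.

Both studies run the full generator -> model pipeline on the default field
design (50 quarter sections x 3 wetlands x 4 seasons) with stratified crop
allocation, using the generator's uncensored ground-truth log totals as
the response so the statistical properties of the estimator are isolated
from censoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exposure_models import LmmSpec, fit_lmm, interaction_contrasts
from .residue_pipeline import CROPS, SEASONS
from .synthetic_data import PanelConfig, gen_residue_panel

__all__ = ["RecoveryStudy", "NullContrastStudy",
           "parameter_recovery_study", "null_contrast_study"]

_SIM_SPEC = LmmSpec(
    random="nested", include_baseline=False, include_prev_crop=False
)

_SEASON_BASE = {"spring2012": 1.0, "summer2012": 3.0,
                "fall2012": 0.5, "spring2013": 2.5}


def _truth_frame(truth):
    frame = truth[truth["sampled"]].copy()
    frame["time"] = frame["season"].map({s: float(i) for i, s in enumerate(SEASONS)})
    frame["baseline"] = 0.0
    return frame.reset_index(drop=True)


@dataclass(frozen=True)
class RecoveryStudy:
    """Bias and CI coverage of a known crop effect over replicates."""

    true_effect: float
    mean_estimate: float
    bias: float
    bias_pct_of_truth: float
    ci_coverage: float
    n_replicates: int


def parameter_recovery_study(
    n_replicates: int = 200,
    true_effect: float = 2.0,
    seed: int = 0,
    n_qs: int = 50,
    wetlands_per_qs: int = 3,
) -> RecoveryStudy:
    """Recover a barley effect of ``true_effect`` log units.

    Each replicate simulates a panel with additive cell means (season base
    plus the barley shift), fits the nested-intercept mixed model on the
    uncensored log totals, and records the barley fixed effect and whether
    its Wald 95% CI covers the truth.
    """
    cells = {
        (c, s): _SEASON_BASE[s] + (true_effect if c == "barley" else 0.0)
        for c in CROPS
        for s in SEASONS
    }
    base_seed = int(seed) % (2**20)
    estimates = np.empty(n_replicates)
    covered = 0
    for rep in range(n_replicates):
        cfg = PanelConfig(
            seed=base_seed * 1000 + rep,
            cell_means=cells,
            n_qs=n_qs,
            wetlands_per_qs=wetlands_per_qs,
            stratified_crops=True,
        )
        _, truth = gen_residue_panel(cfg)
        fit = fit_lmm(_truth_frame(truth), _SIM_SPEC)
        b = fit.params["crop[barley]"]
        se = fit.bse["crop[barley]"]
        estimates[rep] = b
        covered += b - 1.96 * se <= true_effect <= b + 1.96 * se
    mean_est = float(estimates.mean())
    bias = mean_est - true_effect
    return RecoveryStudy(
        true_effect=true_effect,
        mean_estimate=mean_est,
        bias=bias,
        bias_pct_of_truth=100.0 * abs(bias) / abs(true_effect),
        ci_coverage=covered / n_replicates,
        n_replicates=n_replicates,
    )


@dataclass(frozen=True)
class NullContrastStudy:
    """Family-wise error of Šidák-corrected contrasts under a global null."""

    fwer: float
    alpha: float
    n_replicates: int
    n_contrasts: int
    ks_distance: float  # raw contrast p-values vs uniform


def null_contrast_study(
    n_replicates: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    n_qs: int = 50,
    wetlands_per_qs: int = 3,
) -> NullContrastStudy:
    """Global null: all (crop, season) cell means equal.

    Each replicate fits the mixed model and tests the full crop-by-season
    contrast family at family-wise ``alpha``; the study reports the
    fraction of replicates with any rejection and the Kolmogorov distance
    of raw p-values from uniform.
    """
    from scipy.stats import kstest

    cells = {(c, s): 2.0 for c in CROPS for s in SEASONS}
    base_seed = int(seed) % (2**20)
    any_reject = 0
    pvals: list[float] = []
    k = 0
    for rep in range(n_replicates):
        cfg = PanelConfig(
            seed=base_seed * 1000 + 500_000 + rep,
            cell_means=cells,
            n_qs=n_qs,
            wetlands_per_qs=wetlands_per_qs,
            stratified_crops=True,
        )
        _, truth = gen_residue_panel(cfg)
        fit = fit_lmm(_truth_frame(truth), _SIM_SPEC)
        contrasts = interaction_contrasts(fit, alpha=alpha)
        k = len(contrasts)
        any_reject += any(c.significant for c in contrasts)
        pvals.extend(c.p for c in contrasts)
    return NullContrastStudy(
        fwer=any_reject / n_replicates,
        alpha=alpha,
        n_replicates=n_replicates,
        n_contrasts=k,
        ks_distance=float(kstest(np.asarray(pvals), "uniform").statistic),
    )
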