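"""End-to-end analysis of static-stimulus trials.

The analysis mirrors the four statistical stages applied to populations
of extended tentacles facing a motionless stripe:

1. per-trial directedness (Moore's modified Rayleigh test, weights are
   tentacle lengths);
2. per-treatment model selection on the trial mean angles phi* (uniform
   vs unimodal von Mises, AICc);
3. homogeneity of the unimodal concentration parameters across stripe
   widths (global equal-kappa test plus optional pairwise comparisons);
4. an omnibus Friedman test on per-animal tentacle counts, and an OLS
   regression of directedness R* on the unit-circle chord distance z
   between phi* and the stimulus direction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import circstats
from .circstats import (
    EqualKappaResult,
    FriedmanResult,
    ModelSelectionResult,
    MooreResult,
    RegressionResult,
    VectorSample,
)
from .errors import InsufficientSampleError
from .geometry import chord_distance
from .landmark_io import Trial, filter_trials

__all__ = [
    "trial_directedness",
    "treatment_summary",
    "width_kappa_comparison",
    "count_table",
    "count_comparison",
    "offset_regression",
    "circular_histogram",
    "plot_circular_histogram",
    "analyze_static_experiment",
    "StaticExperimentResult",
]

logger = logging.getLogger(__name__)

DEFAULT_MC_REPS = 100_000
DEFAULT_MC_SEED = 19800101


def trial_directedness(
    trial: Trial,
    alpha: float = 0.05,
    mc_reps: int = DEFAULT_MC_REPS,
    seed: int = DEFAULT_MC_SEED,
    angle_mode: str = "heading",
    cache_path=None,
) -> MooreResult:
    """Moore's test on the tentacles of one static trial.

    Tentacle vectors use ``angle_mode`` ("heading" = base->tip direction,
    "position" = angular position of the base); vector magnitudes are
    tentacle lengths and enter the statistic through their ranks.
    """
    if not trial.meta.is_static:
        raise ValueError("trial_directedness applies to static trials")
    obs = trial.frame_observations(trial.frames[0])
    sample = VectorSample(
        np.array([o.angle(angle_mode) for o in obs]),
        np.array([o.length for o in obs]),
    )
    return circstats.moore_test(sample, alpha=alpha, reps=mc_reps, seed=seed,
                                cache_path=cache_path,
                                trial_id=trial.meta.trial_id)


def treatment_summary(moore_results) -> ModelSelectionResult:
    """Model-select uniform vs unimodal over one treatment's phi* values.

    Trials whose resultant vanished exactly (phi* undefined) are dropped
    with a warning; at least four usable trials are required for AICc.
    """
    phis = []
    for res in moore_results:
        if np.isnan(res.phi_star_deg):
            logger.warning("dropping trial %s from treatment summary: "
                           "undefined phi* (zero resultant)", res.trial_id)
            continue
        phis.append(res.phi_star_deg)
    if len(phis) < 4:
        raise InsufficientSampleError(
            f"treatment summary needs >= 4 trials with defined phi*, "
            f"got {len(phis)}"
        )
    return circstats.model_select(phis)


def width_kappa_comparison(phi_by_treatment: dict[str, list[float]],
                           pairwise: bool = True,
                           bonferroni: bool = False) -> dict:
    """Concentration homogeneity across treatments.

    Runs the global equal-kappa test over all treatments and, optionally,
    every treatment pair.  Pairwise p-values are raw by default; set
    ``bonferroni`` to correct for the number of pairs.
    """
    labels = list(phi_by_treatment)
    if len(labels) < 2:
        raise ValueError("need at least two treatments to compare kappas")
    global_res = circstats.equal_kappa_test(
        [phi_by_treatment[k] for k in labels]
    )
    out = {"labels": labels, "global": global_res, "pairwise": {}}
    if pairwise:
        pairs = list(itertools.combinations(labels, 2))
        for a, b in pairs:
            res = circstats.equal_kappa_test(
                [phi_by_treatment[a], phi_by_treatment[b]]
            )
            if bonferroni:
                res = EqualKappaResult(
                    statistic=res.statistic, df=res.df,
                    p_value=min(1.0, res.p_value * len(pairs)),
                    kappas=res.kappas, rbar_pooled=res.rbar_pooled,
                    regime=res.regime,
                )
            out["pairwise"][(a, b)] = res
    return out


def count_table(trials) -> pd.DataFrame:
    """Per-animal tentacle counts by treatment (before the >=3 filter).

    Zero-tentacle trials count as zero; animals missing a treatment get NaN.
    """
    rows = []
    for t in trials:
        rows.append({"animal_id": t.meta.animal_id,
                     "treatment": t.meta.treatment_label,
                     "count": t.frames[0].n_tentacles if t.meta.is_static
                     else t.total_tentacles})
    df = pd.DataFrame(rows)
    return df.pivot_table(index="animal_id", columns="treatment",
                          values="count", aggfunc="first")


def count_comparison(trials) -> FriedmanResult:
    """Friedman test of tentacle counts ~ treatment | animal.

    Animals with an incomplete treatment set are dropped with a warning.
    Counting precedes the minimum-tentacle exclusion filter, so trials
    with zero extended tentacles contribute zeros.
    """
    table = count_table(trials)
    complete = table.dropna()
    n_dropped = len(table) - len(complete)
    if n_dropped:
        logger.warning("dropping %d animal(s) with incomplete treatment "
                       "sets from the count comparison", n_dropped)
    if len(complete) < 2:
        raise InsufficientSampleError(
            "count comparison needs >= 2 animals observed in all treatments"
        )
    return circstats.friedman_test(complete)


@dataclass
class OffsetRegressionResult:
    regression: RegressionResult
    table: pd.DataFrame  # per-trial trial_id, R_star, phi_star, stim, dx, dy, z


def offset_regression(trial_results: list[tuple[MooreResult, float]]
                      ) -> OffsetRegressionResult:
    """Regress R* on the chord distance z between phi* and the stimulus.

    ``trial_results`` pairs each analysable stimulus-present trial's Moore
    result with its stimulus direction (body-frame degrees).  Control
    trials must be excluded by the caller; trials with undefined phi* are
    skipped.
    """
    rows = []
    for res, stim in trial_results:
        if np.isnan(res.phi_star_deg):
            continue
        off = chord_distance(stim, res.phi_star_deg)
        rows.append({"trial_id": res.trial_id, "R_star": res.R_star,
                     "phi_star_deg": res.phi_star_deg, "stim_deg": stim,
                     "delta_x": off.delta_x, "delta_y": off.delta_y,
                     "z": off.z})
    df = pd.DataFrame(rows)
    reg = circstats.directedness_regression(df["R_star"], df["z"])
    return OffsetRegressionResult(regression=reg, table=df)


def circular_histogram(angles_deg, bins: int = 16) -> np.ndarray:
    """Bin angles into equal circular bins with bin 0 centred on 0 degrees.

    Bins are half-open [centre - w/2, centre + w/2) with width
    w = 360 / bins, so an angle landing exactly on an edge goes to the
    higher bin.
    """
    if bins < 1:
        raise ValueError("need at least one bin")
    angles = np.asarray(angles_deg, dtype=float)
    width = 360.0 / bins
    idx = np.floor(((angles + width / 2.0) % 360.0) / width).astype(int)
    return np.bincount(idx, minlength=bins)


def plot_circular_histogram(angles_deg, bins: int = 16, ax=None,
                            stimulus_deg: float | None = None,
                            phi1_deg: float | None = None):
    """Polar rose plot of binned mean angles (one wedge per bin)."""
    import matplotlib.pyplot as plt

    counts = circular_histogram(angles_deg, bins)
    width = 2.0 * np.pi / bins
    centres = np.arange(bins) * width
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.bar(centres, counts, width=width, bottom=0.0, edgecolor="black",
           color="0.7")
    if stimulus_deg is not None:
        ax.axvline(np.deg2rad(stimulus_deg), color="black", lw=2)
    if phi1_deg is not None:
        ax.annotate("", xy=(np.deg2rad(phi1_deg), max(counts.max(), 1)),
                    xytext=(0, 0), arrowprops={"arrowstyle": "->"})
    return ax


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class StaticExperimentResult:
    moore: list[MooreResult]
    by_treatment: dict[str, ModelSelectionResult]
    phi_by_treatment: dict[str, list[float]]
    kappa_comparison: dict | None
    counts: FriedmanResult | None
    regression: OffsetRegressionResult | None
    excluded: dict[str, str] = field(default_factory=dict)

    def moore_table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"trial_id": r.trial_id, "n_tentacles": r.n, "R_star": r.R_star,
             "phi_star_deg": r.phi_star_deg, "R_crit": r.R_crit,
             "significant": r.significant}
            for r in self.moore
        ], columns=["trial_id", "n_tentacles", "R_star", "phi_star_deg",
                    "R_crit", "significant"])


def analyze_static_experiment(
    trials: list[Trial],
    min_tentacles: int = 3,
    alpha: float = 0.05,
    mc_reps: int = DEFAULT_MC_REPS,
    seed: int = DEFAULT_MC_SEED,
    angle_mode: str = "heading",
    pairwise_kappa: bool = True,
    cache_path=None,
) -> StaticExperimentResult:
    """Run the full static analysis over a set of assembled trials."""
    counts = None
    try:
        counts = count_comparison(trials)
    except InsufficientSampleError as exc:
        logger.warning("skipping count comparison: %s", exc)

    outcome = filter_trials(trials, min_tentacles=min_tentacles)
    moore_results: list[MooreResult] = []
    stim_by_trial: dict[str, float | None] = {}
    treatment_of: dict[str, str] = {}
    for trial in outcome.kept:
        res = trial_directedness(trial, alpha=alpha, mc_reps=mc_reps,
                                 seed=seed, angle_mode=angle_mode,
                                 cache_path=cache_path)
        moore_results.append(res)
        stim_by_trial[trial.meta.trial_id] = trial.meta.stimulus_angle_body
        treatment_of[trial.meta.trial_id] = trial.meta.treatment_label

    phi_by_treatment: dict[str, list[float]] = {}
    results_by_treatment: dict[str, list[MooreResult]] = {}
    for res in moore_results:
        label = treatment_of[res.trial_id]
        results_by_treatment.setdefault(label, []).append(res)
        if not np.isnan(res.phi_star_deg):
            phi_by_treatment.setdefault(label, []).append(res.phi_star_deg)

    summaries: dict[str, ModelSelectionResult] = {}
    for label, results in results_by_treatment.items():
        try:
            summaries[label] = treatment_summary(results)
        except InsufficientSampleError as exc:
            logger.warning("skipping treatment %s: %s", label, exc)

    kappa_cmp = None
    usable = {k: v for k, v in phi_by_treatment.items() if len(v) >= 2}
    if len(usable) >= 2:
        kappa_cmp = width_kappa_comparison(usable, pairwise=pairwise_kappa)

    regression = None
    with_stim = [
        (res, stim_by_trial[res.trial_id])
        for res in moore_results
        if stim_by_trial[res.trial_id] is not None
    ]
    if sum(1 for r, _ in with_stim if not np.isnan(r.phi_star_deg)) >= 3:
        regression = offset_regression(with_stim)
    else:
        logger.warning("too few stimulus-present trials for the "
                       "directedness regression")

    return StaticExperimentResult(
        moore=moore_results,
        by_treatment=summaries,
        phi_by_treatment=phi_by_treatment,
        kappa_comparison=kappa_cmp,
        counts=counts,
        regression=regression,
        excluded=outcome.reasons,
    )
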