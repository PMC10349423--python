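"""Reusable simulation studies over the timMRD pipeline.

Each study builds its inputs with the synthetic cohort generator, runs
the deconvolution/scoring machinery, and returns a plain dict of summary
numbers. The analysis scripts, the test suite, and the acceptance script
all call these functions so that every reported number comes from one
code path.

Problem sizes are desk-scale: panels of a few hundred to a thousand
blocks and tens to hundreds of replicates, which is where the model's
operating characteristics (bias, calibration, power) are already stable.
"""

from __future__ import annotations

import numpy as np

from .background_prior import fit_panel_prior
from .core import (
    ScoringOptions,
    beta_binomial_logpmf,
    block_marginal_loglik,
    classification_threshold,
    fit_timmrd,
    grid_oracle_fit,
)
from .dmb_selection import PanelBlock, PatientPanel, select_patient_dmbs
from .simulate import (
    LongitudinalSpec,
    SimulationSpec,
    simulate_dilution_series,
    simulate_healthy_plasma,
    simulate_longitudinal_cohort,
    simulate_plasma_mixture,
    simulate_tissue_pair,
)
from .surveillance import (
    PatientTimeline,
    build_timeline,
    horizon_confusion,
    lead_time,
    roc_over_thresholds,
)

# tight-background, deep-coverage panel emulating the assay's low-LoD regime
DEEP_PANEL = dict(p_range=(0.3, 1.0), q_range=(500.0, 2000.0), depth_mean=5000.0)


def _full_panel(tumor, normal, planted) -> PatientPanel:
    return PatientPanel(
        "SIM", [PanelBlock(b, tumor.level(b), normal.level(b)) for b in sorted(planted)]
    )


def closed_form_accuracy(quad_order: int = 128, n_max: int = 30) -> dict:
    """Quadrature vs analytic beta-binomial at alpha = gamma = 0.

    Returns the largest absolute log-pmf deviation over a grid of depths
    N <= ``n_max`` and shapes p, q in {0.5, 1, 2, 8}, plus the largest
    deviation of the marginal pmf sum from 1.
    """
    shapes = (0.5, 1.0, 2.0, 8.0)
    max_err = 0.0
    max_norm_err = 0.0
    for p in shapes:
        for q in shapes:
            for n in range(1, n_max + 1):
                total = 0.0
                for m in range(n + 1):
                    ll = block_marginal_loglik(0.0, 0.0, n, m, 0.8, 0.1, p, q, quad_order)
                    max_err = max(max_err, abs(ll - beta_binomial_logpmf(m, n, p, q)))
                    total += np.exp(ll)
                max_norm_err = max(max_norm_err, abs(total - 1.0))
    return {"max_abs_log_err": max_err, "max_pmf_sum_err": max_norm_err}


def oracle_agreement(
    seed: int, n_samples: int = 20, grid_step: float = 0.005, m: int = 30
) -> dict:
    """Optimizer vs exhaustive-grid MLE on small simulated panels.

    Returns the worst |alpha_hat - alpha_hat_grid| and the largest amount
    by which the grid maximum exceeds the optimizer's log-likelihood.
    """
    spec = SimulationSpec(n_blocks=m, n_dmb_true=m, seed=seed, depth_mean=200.0)
    from .simulate import true_background_prior

    prior = true_background_prior(spec)
    tumor, normal, planted = simulate_tissue_pair(spec, prior)
    panel = _full_panel(tumor, normal, planted)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    alphas = np.tile([0.0, 0.005, 0.02, 0.05, 0.1], n_samples // 5 + 1)[:n_samples]
    max_dev = 0.0
    max_excess = -np.inf
    for i, a_true in enumerate(alphas):
        counts = simulate_plasma_mixture(
            float(a_true), 0.0, tumor, normal, prior, spec, rng, f"oracle{i}"
        )
        fit = fit_timmrd(panel, counts, prior)
        grid = grid_oracle_fit(panel, counts, prior, grid_step=grid_step)
        max_dev = max(max_dev, abs(fit.alpha_hat - grid.alpha_hat))
        max_excess = max(max_excess, grid.loglik_full - fit.loglik_full)
    return {"max_alpha_dev": max_dev, "max_grid_excess": float(max_excess)}


def recovery_study(
    seed: int,
    alphas: tuple[float, ...] = (0.01, 0.05),
    n_rep: int = 100,
    m: int = 500,
    depth: float = 200.0,
) -> dict:
    """Mean MLE of the ctDNA fraction across seeded replicates.

    Data are generated from the model itself (gamma = 0) on a panel where
    every block is a true DMB; reports the mean alpha_hat and its relative
    error per true alpha.
    """
    spec = SimulationSpec(n_blocks=m, n_dmb_true=m, seed=seed, depth_mean=depth)
    from .simulate import true_background_prior

    prior = true_background_prior(spec)
    tumor, normal, planted = simulate_tissue_pair(spec, prior)
    panel = _full_panel(tumor, normal, planted)
    out = {}
    for a_true in alphas:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7, int(a_true * 1e6)]))
        est = [
            fit_timmrd(
                panel,
                simulate_plasma_mixture(a_true, 0.0, tumor, normal, prior, spec, rng, "r"),
                prior,
            ).alpha_hat
            for _ in range(n_rep)
        ]
        mean = float(np.mean(est))
        out[a_true] = {"mean_alpha_hat": mean, "rel_err": mean / a_true - 1.0}
    return out


def null_calibration(
    seed: int, n_rep: int = 500, m: int = 300, depth: float = 200.0,
    percentile: float = 0.98,
) -> dict:
    """Empirical MRD-high rate under alpha = 0 (type-I behaviour).

    The boundary null makes the chi-square threshold conservative: about
    half the null fits land exactly at alpha_hat = 0 and score 0.
    """
    spec = SimulationSpec(n_blocks=m, n_dmb_true=m, seed=seed, depth_mean=depth)
    from .simulate import true_background_prior

    prior = true_background_prior(spec)
    tumor, normal, planted = simulate_tissue_pair(spec, prior)
    panel = _full_panel(tumor, normal, planted)
    opts = ScoringOptions(percentile=percentile)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    n_high = 0
    for _ in range(n_rep):
        counts = simulate_plasma_mixture(0.0, 0.0, tumor, normal, prior, spec, rng, "n")
        n_high += fit_timmrd(panel, counts, prior, opts).call == "high"
    return {"high_rate": n_high / n_rep, "n_rep": n_rep}


def dilution_power(
    seed: int,
    fractions: tuple[float, ...] = (0.1, 0.01, 0.001, 2e-4, 0.0),
    reps: int = 25,
    m: int = 1000,
    depth: float = 200.0,
    **panel_kwargs,
) -> dict:
    """MRD-high detection rate per simulated tumor fraction (gamma = 0)."""
    spec = SimulationSpec(
        n_blocks=m, n_dmb_true=m, seed=seed, depth_mean=depth, **panel_kwargs
    )
    series = simulate_dilution_series(list(fractions), reps, spec)
    panel = _full_panel(series.tumor, series.normal, series.planted)
    rates: dict[float, float] = {}
    hits: dict[float, int] = {f: 0 for f in fractions}
    counts_per = {f: 0 for f in fractions}
    for frac, counts in series.samples:
        fit = fit_timmrd(panel, counts, series.prior)
        hits[frac] += fit.call == "high"
        counts_per[frac] += 1
    for f in fractions:
        rates[f] = hits[f] / counts_per[f]
    return {"rates": rates, "reps": reps}


def deep_lod_check(seed: int, reps: int = 12) -> dict:
    """Detection of tumor fraction 2e-4 on the deep, tight-background panel."""
    kwargs = dict(DEEP_PANEL)
    depth = kwargs.pop("depth_mean")
    return dilution_power(
        seed, fractions=(2e-4, 0.0), reps=reps, m=1000, depth=depth, **kwargs
    )


SURVEIL_SPEC = dict(
    n_blocks=400,
    n_dmb_true=100,
    p_range=(0.3, 1.5),
    q_range=(200.0, 800.0),
    depth_mean=150.0,
)


def surveillance_study(
    seed: int,
    n_patients: int = 200,
    horizon_days: int = 120,
    n_healthy: int = 40,
) -> dict:
    """End-to-end longitudinal comparison of methylation vs mutation MRD.

    Simulates a post-surgical cohort, fits the background prior from
    synthetic healthy plasma, selects each patient's panel from their
    tissue pair, scores every plasma sample, and evaluates both assays at
    the fixed horizon before relapse. Returns sensitivities,
    specificities, NPVs, ROC AUC, and average lead times.
    """
    spec = SimulationSpec(seed=seed, **SURVEIL_SPEC)
    lspec = LongitudinalSpec(n_patients=n_patients, seed=seed)
    healthy, _ = simulate_healthy_plasma(spec, n_healthy)
    block_ids = list(healthy[0].counts)
    prior = fit_panel_prior(healthy, block_ids, min_depth=10)
    patients, _ = simulate_longitudinal_cohort(lspec, spec)

    timelines: list[PatientTimeline] = []
    n_unscoreable = 0
    for patient in patients:
        try:
            panel = select_patient_dmbs(
                patient.tumor, patient.normal, prior, patient_id=patient.patient_id
            )
        except Exception:
            n_unscoreable += 1
            continue
        fits = {}
        for counts in patient.counts:
            fit = fit_timmrd(panel, counts, prior)
            fits[counts.sample_id] = fit
        clinical = {
            "patient_id": patient.patient_id,
            "relapsed": patient.relapsed,
            "relapse_day": patient.relapse_day,
            "dfs_days": patient.relapse_day
            if patient.relapsed
            else max(s.day_from_surgery for s in patient.samples),
        }
        timelines.append(build_timeline(patient.samples, fits, clinical))

    conf_mrd = horizon_confusion(timelines, horizon_days, assay="timmrd")
    conf_mut = horizon_confusion(timelines, horizon_days, assay="mutation")
    _, auc = roc_over_thresholds(timelines, horizon_days)

    leads_mrd, leads_mut = [], []
    for t in timelines:
        if not t.relapsed:
            continue
        lt_m = lead_time(t, assay="timmrd")
        lt_u = lead_time(t, assay="mutation")
        if lt_m is not None:
            leads_mrd.append(lt_m)
        if lt_u is not None:
            leads_mut.append(lt_u)

    return {
        "sens_timmrd": conf_mrd.sensitivity,
        "spec_timmrd": conf_mrd.specificity,
        "npv_timmrd": conf_mrd.npv,
        "sens_mutation": conf_mut.sensitivity,
        "spec_mutation": conf_mut.specificity,
        "npv_mutation": conf_mut.npv,
        "auc_timmrd": auc,
        "mean_lead_timmrd": float(np.mean(leads_mrd)) if leads_mrd else None,
        "mean_lead_mutation": float(np.mean(leads_mut)) if leads_mut else None,
        "n_timelines": len(timelines),
        "n_unscoreable": n_unscoreable,
        "threshold": classification_threshold(),
    }
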