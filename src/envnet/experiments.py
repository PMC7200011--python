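"""Reference experiments on the default synthetic conditions.

Each function runs one of the package's headline analyses end to end on
synthetic data at the reference conditions (100 networks per class,
guild sizes 10–30, connectance 0.1–0.3, null ensembles of R = 100) and
returns the measured quantities.  They are the single source both for
the acceptance checks and for the command-line demo, so the numbers the
package reports are always recomputed, never stored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from envnet.differentiation import (
    FeatureTable,
    assemble_features,
    scalability_report,
    separability,
    specificity_test,
)
from envnet.network_io import NetworkSet
from envnet.null_models import null_corrected_metrics
from envnet.regression import (
    class_fits,
    opposite_sign_check,
    randomized_control,
    stability_table,
)
from envnet.stability import CompetitionSpec
from envnet.synthetic_data import (
    ANTAGONISTIC,
    MUTUALISTIC,
    ConfoundedSetSpec,
    SubClassSpec,
    generate_confounded_set,
)

_SEED_MAX = 2**31 - 1


def _spawn(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % _SEED_MAX]


def compute_metrics(network_set: NetworkSet, R: int = 100, seed: int = 0) -> dict:
    """Null-corrected metrics for every network (suppresses λ2 warnings;
    affected networks are excluded downstream)."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for net, s in zip(network_set, _spawn(seed, len(network_set))):
            out[net.id] = null_corrected_metrics(net, R=R, seed=s)
    return out


# ---------------------------------------------------------------------------
# Separability (Simpson structure)


@dataclass
class SeparabilityExperiment:
    accuracy_metrics_only: float
    accuracy_with_environment: float
    p_metrics_only: float
    p_with_environment: float
    ellipse_overlap_metrics_only: float
    ellipse_overlap_with_environment: float
    n_networks: int
    network_set: NetworkSet = field(repr=False)
    table_with_env: FeatureTable = field(repr=False)


def run_separability_experiment(seed: int, n_per_class: int = 100,
                                R: int = 100) -> SeparabilityExperiment:
    """Metrics-only vs metrics+environment class separability.

    The confounded generator makes the marginal metric distributions
    coincide across classes while coupling them to the environment with
    opposite signs, so accuracy should be near chance without the
    environment and high with it.
    """
    s_gen, s_metrics, s_sep3, s_sep4 = _spawn(seed, 4)
    nets = generate_confounded_set(ConfoundedSetSpec(n_per_class=n_per_class, seed=s_gen))
    metrics = compute_metrics(nets, R=R, seed=s_metrics)
    t3 = assemble_features(nets, metrics, include_environment=False)
    t4 = assemble_features(nets, metrics, include_environment=True)
    rep3 = separability(t3, seed=s_sep3)
    rep4 = separability(t4, seed=s_sep4)
    return SeparabilityExperiment(
        accuracy_metrics_only=rep3.cv_accuracy,
        accuracy_with_environment=rep4.cv_accuracy,
        p_metrics_only=rep3.p_value,
        p_with_environment=rep4.p_value,
        ellipse_overlap_metrics_only=rep3.ellipse_overlap,
        ellipse_overlap_with_environment=rep4.ellipse_overlap,
        n_networks=len(t4.data),
        network_set=nets,
        table_with_env=t4,
    )


# ---------------------------------------------------------------------------
# Specificity (randomized architectures)


@dataclass
class SpecificityExperiment:
    accuracies: list[float]
    p_values: list[float]
    fraction_near_chance: float  # |accuracy − 0.5| <= 0.10
    fraction_p_above_05: float
    n_runs: int


def run_specificity_experiment(seed: int, n_runs: int = 20, n_per_class: int = 100,
                               R: int = 100) -> SpecificityExperiment:
    """Repeated specificity test on one confounded set.

    The set is generated once; each run draws fresh ER randomizations and
    null ensembles, scales on the randomized table, and measures
    separability, which should sit at chance.
    """
    seeds = _spawn(seed, n_runs + 1)
    nets = generate_confounded_set(ConfoundedSetSpec(n_per_class=n_per_class,
                                                     seed=seeds[0]))
    accs, ps = [], []
    for s in seeds[1:]:
        rep = specificity_test(nets, R=R, seed=s)
        accs.append(rep.cv_accuracy)
        ps.append(rep.p_value)
    accs_a = np.asarray(accs)
    return SpecificityExperiment(
        accuracies=accs, p_values=ps,
        fraction_near_chance=float((np.abs(accs_a - 0.5) <= 0.10).mean()),
        fraction_p_above_05=float((np.asarray(ps) > 0.05).mean()),
        n_runs=n_runs,
    )


# ---------------------------------------------------------------------------
# Scalability (planted hierarchy)


def hierarchical_spec(seed: int, n_per_class: int = 99) -> ConfoundedSetSpec:
    """Conditions with a planted class/sub-class hierarchy.

    Classes are separated at the class level (distinct environment means
    and nestedness baselines) and sub-classes are small offsets within
    their class, so the planted geometry is hierarchical by construction.
    """
    return ConfoundedSetSpec(
        n_per_class=n_per_class,
        env_mean={MUTUALISTIC: 2.5, ANTAGONISTIC: 6.5},
        env_sd={MUTUALISTIC: 1.5, ANTAGONISTIC: 1.5},
        coupling={MUTUALISTIC: 0.4, ANTAGONISTIC: -0.4},
        nu0={MUTUALISTIC: 2.7, ANTAGONISTIC: 1.5},
        sub_classes={
            MUTUALISTIC: [
                SubClassSpec("plant-pollinator", env_offset=-0.35),
                SubClassSpec("seed-dispersal", env_offset=0.35),
                SubClassSpec("plant-ant", nu_offset=0.2),
            ],
            ANTAGONISTIC: [
                SubClassSpec("host-parasite", env_offset=-0.35),
                SubClassSpec("plant-herbivore", env_offset=0.35, nu_offset=-0.1),
            ],
        },
        seed=seed,
    )


@dataclass
class ScalabilityExperiment:
    passes: bool
    n_sub_classes: int
    margin: float  # min(other − same) centroid-distance gap
    table: object = field(repr=False)


def run_scalability_experiment(seed: int, n_per_class: int = 99,
                               R: int = 100) -> ScalabilityExperiment:
    s_gen, s_metrics = _spawn(seed, 2)
    nets = generate_confounded_set(hierarchical_spec(s_gen, n_per_class=n_per_class))
    metrics = compute_metrics(nets, R=R, seed=s_metrics)
    table = assemble_features(nets, metrics, include_environment=True)
    rep = scalability_report(table)
    gaps = rep.table["other_class_dist"] - rep.table["same_class_dist"]
    return ScalabilityExperiment(
        passes=rep.passes,
        n_sub_classes=len(rep.table),
        margin=float(gaps.min()),
        table=rep.table,
    )


# ---------------------------------------------------------------------------
# Regression (opposite temperature effects on stability)


@dataclass
class PlantedRegressionExperiment:
    sign_recovery_rate: float  # both classes' signs recovered at >= 2 SE
    n_runs: int


def run_planted_regression_experiment(seed: int, n_runs: int = 200, n: int = 100,
                                      beta_temp: float = 0.4, noise_sd: float = 0.5
                                      ) -> PlantedRegressionExperiment:
    """Sign-recovery calibration with directly planted effects.

    Per run and class, y = ±β_T·x_T − 0.3·x_S + 0.1·x_C + ε on
    standardized predictors; success means both per-class temperature
    coefficients match the planted sign at ≥ 2 SE.
    """
    import pandas as pd

    from envnet.regression import fit_effects

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_runs):
        frames = []
        for cls, sign in ((MUTUALISTIC, 1.0), (ANTAGONISTIC, -1.0)):
            X = rng.standard_normal((n, 3))
            y = sign * beta_temp * X[:, 0] - 0.3 * X[:, 1] + 0.1 * X[:, 2]
            y = y + rng.normal(0, noise_sd, n)
            frames.append(pd.DataFrame({
                "lambda1": y, "temperature_variability": X[:, 0],
                "size_S": X[:, 1], "connectance_C": X[:, 2],
                "interaction_class": cls,
            }))
        data = pd.concat(frames, ignore_index=True)
        ok = True
        for cls, sign in ((MUTUALISTIC, 1.0), (ANTAGONISTIC, -1.0)):
            fit = fit_effects(data, "lambda1", class_filter=cls)
            b, s = fit.coefficient(), fit.se()
            if not (np.sign(b) == sign and abs(b) > 2 * s):
                ok = False
        hits += ok
    return PlantedRegressionExperiment(sign_recovery_rate=hits / n_runs, n_runs=n_runs)


@dataclass
class StabilityRegressionExperiment:
    opposite_sign_lambda1: bool
    opposite_sign_omega: bool
    coef_temp_mut_lambda1: float
    coef_temp_ant_lambda1: float
    coef_temp_mut_omega: float
    coef_temp_ant_omega: float
    adj_r2_lambda1_mut: float
    randomized_opposite_fraction: float  # over seeded randomized controls
    n_randomized_runs: int


def run_stability_regression_experiment(seed: int, n_per_class: int = 60,
                                        n_randomized_runs: int = 10,
                                        n_draws: int = 10_000
                                        ) -> StabilityRegressionExperiment:
    """Opposite per-class temperature effects on stability, and their
    disappearance under ER randomization.

    The confounded generator couples nestedness to temperature with
    opposite signs per class; nestedness raises λ1 and deepens intra-guild
    overlap (lowering Ω), so the fitted temperature coefficients should
    show opposite signs across classes for both responses — and lose the
    pattern when architectures are randomized.
    """
    seeds = _spawn(seed, n_randomized_runs + 2)
    nets = generate_confounded_set(ConfoundedSetSpec(n_per_class=n_per_class,
                                                     seed=seeds[0]))
    spec = CompetitionSpec()
    table = stability_table(nets, spec=spec, n_draws=n_draws, seed=seeds[1])
    fits_l1 = class_fits(table, "lambda1")
    fits_om = class_fits(table, "omega_norm")
    osc_l1 = opposite_sign_check(fits_l1[MUTUALISTIC], fits_l1[ANTAGONISTIC])
    osc_om = opposite_sign_check(fits_om[MUTUALISTIC], fits_om[ANTAGONISTIC])
    n_opposite = 0
    for s in seeds[2:]:
        fits = randomized_control(nets, seed=s, spec=spec, responses=("lambda1",),
                                  n_draws=n_draws)["lambda1"]
        osc = opposite_sign_check(fits[MUTUALISTIC], fits[ANTAGONISTIC])
        n_opposite += osc.opposite
    return StabilityRegressionExperiment(
        opposite_sign_lambda1=osc_l1.opposite,
        opposite_sign_omega=osc_om.opposite,
        coef_temp_mut_lambda1=fits_l1[MUTUALISTIC].coefficient(),
        coef_temp_ant_lambda1=fits_l1[ANTAGONISTIC].coefficient(),
        coef_temp_mut_omega=fits_om[MUTUALISTIC].coefficient(),
        coef_temp_ant_omega=fits_om[ANTAGONISTIC].coefficient(),
        adj_r2_lambda1_mut=fits_l1[MUTUALISTIC].adj_r2,
        randomized_opposite_fraction=n_opposite / max(n_randomized_runs, 1),
        n_randomized_runs=n_randomized_runs,
    )
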