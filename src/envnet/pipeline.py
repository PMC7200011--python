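"""End-to-end pipeline orchestration with a structured configuration.

Stages, in order: simulate-or-ingest → spectral metrics → null-corrected
metrics → stability → differentiation (with and without environment) →
specificity → scalability → per-class regressions → report.  Every stage
writes CSV artifacts into the output directory and the report embeds the
full configuration and seeds, so a rerun with the same configuration is
reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from envnet.differentiation import (
    assemble_features,
    fit_scaler,
    apply_scaler,
    pca,
    scalability_report,
    separability,
    specificity_test,
)
from envnet.errors import ValidationError
from envnet.experiments import compute_metrics
from envnet.network_io import DEFAULT_ENV_VAR, read_network_set, write_network_set
from envnet.regression import RESPONSES, class_fits, opposite_sign_check, stability_table
from envnet.stability import CompetitionSpec
from envnet.synthetic_data import ConfoundedSetSpec, generate_confounded_set

_SEED_MAX = 2**31 - 1


@dataclass
class PipelineConfig:
    """Everything a full run needs; seeds are always explicit."""

    mode: str = "synthetic"  # "synthetic" or "real"
    input_dir: str | None = None  # required for mode="real"
    output_dir: str = "envnet_results"
    seed: int = 0
    n_per_class: int = 100
    null_replicates: int = 100
    env_var: str = DEFAULT_ENV_VAR
    guild: str = "rows"
    rho: float = 0.5
    omega_draws: int = 20_000
    scaling_reference: str = "randomized"  # for the specificity stage
    classifier: str = "qda"
    n_permutations: int = 199

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValidationError("mode must be 'synthetic' or 'real'")
        if self.mode == "real" and not self.input_dir:
            raise ValidationError("mode='real' requires input_dir")
        if self.null_replicates < 2:
            raise ValidationError("null_replicates must be >= 2")
        if not self.env_var:
            raise ValidationError("env_var must be set")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _report_to_dict(rep) -> dict:
    return {
        "cv_accuracy": rep.cv_accuracy,
        "p_value": rep.p_value,
        "ellipse_overlap": rep.ellipse_overlap,
        "classifier": rep.classifier,
        "n_permutations": rep.n_permutations,
        "seed": rep.seed,
        "scaling_reference": rep.scaler_reference,
        "explained_variance_ratio": [float(v) for v in rep.explained_variance_ratio],
    }


def _ellipse_frame(rep) -> pd.DataFrame:
    rows = []
    for cls, e in rep.ellipses.items():
        rows.append({"class": cls, "center_x": e.center[0], "center_y": e.center[1],
                     "semi_major": e.semi_axes[0], "semi_minor": e.semi_axes[1],
                     "angle_rad": e.angle, "level": e.level})
    return pd.DataFrame(rows).set_index("class")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report dict (also written to disk)."""
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    seeds = {name: int(s) for name, s in zip(
        ("generate", "metrics", "sep3", "sep4", "specificity", "stability"),
        rng.integers(_SEED_MAX, size=6))}
    report: dict = {"config": config.to_dict(), "stage_seeds": seeds, "counts": {}}

    # --- stage: simulate or ingest -----------------------------------------
    if config.mode == "synthetic":
        nets = generate_confounded_set(
            ConfoundedSetSpec(n_per_class=config.n_per_class, env_var=config.env_var,
                              seed=seeds["generate"]))
        write_network_set(os.path.join(out, "networks"), nets)
    else:
        nets = read_network_set(config.input_dir)
    report["counts"]["networks"] = len(nets)

    # --- stage: null-corrected metrics -------------------------------------
    metrics = compute_metrics(nets, R=config.null_replicates, seed=seeds["metrics"])
    mrows = []
    for net in nets:
        am = metrics[net.id]
        mrows.append({"id": net.id, "S": am.size_S, "C": am.connectance_C,
                      "lambda1": am.lambda1, "lambda2": am.lambda2,
                      "rel_err_l1_cm": am.rel_err_l1_cm,
                      "rel_err_l1_er": am.rel_err_l1_er,
                      "rel_err_l2_er": am.rel_err_l2_er})
    pd.DataFrame(mrows).set_index("id").to_csv(os.path.join(out, "metrics.csv"))

    # --- stage: differentiation (±environment) -----------------------------
    t3 = assemble_features(nets, metrics, include_environment=False)
    t4 = assemble_features(nets, metrics, include_environment=True,
                           env_var=config.env_var)
    report["counts"]["excluded_undefined_lambda2"] = t4.n_excluded
    rep3 = separability(t3, seed=seeds["sep3"], classifier=config.classifier,
                        n_permutations=config.n_permutations)
    rep4 = separability(t4, seed=seeds["sep4"], classifier=config.classifier,
                        n_permutations=config.n_permutations)
    report["separability_metrics_only"] = _report_to_dict(rep3)
    report["separability_with_environment"] = _report_to_dict(rep4)
    scaler = fit_scaler(t4)
    emb = pca(apply_scaler(scaler, t4), n_components=2)
    scores = emb.scores.copy()
    scores["interaction_class"] = t4.class_labels.to_numpy()
    scores["sub_class"] = t4.sub_class_labels.to_numpy()
    scores.to_csv(os.path.join(out, "pca_scores.csv"))
    _ellipse_frame(rep4).to_csv(os.path.join(out, "ellipses_with_environment.csv"))

    # --- stage: scalability -------------------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scal = scalability_report(t4)
    scal.table.to_csv(os.path.join(out, "scalability.csv"))
    report["scalability"] = {"passes": scal.passes, "degenerate": scal.degenerate}

    # --- stage: specificity --------------------------------------------------
    spec_rep = specificity_test(nets, R=config.null_replicates,
                                seed=seeds["specificity"], env_var=config.env_var,
                                classifier=config.classifier,
                                n_permutations=config.n_permutations,
                                scaling_reference=config.scaling_reference)
    report["specificity"] = _report_to_dict(spec_rep)

    # --- stage: stability + regression --------------------------------------
    stab = stability_table(nets, spec=CompetitionSpec(guild=config.guild, rho=config.rho),
                           n_draws=config.omega_draws, seed=seeds["stability"],
                           env_var=config.env_var)
    stab.to_csv(os.path.join(out, "stability.csv"))
    reg_rows = []
    report["regression"] = {}
    for resp in RESPONSES:
        fits = class_fits(stab, resp)
        osc = opposite_sign_check(fits["mutualistic"], fits["antagonistic"])
        report["regression"][resp] = {
            "opposite_signs": osc.opposite,
            "mutualistic": osc.summary["mutualistic"],
            "antagonistic": osc.summary["antagonistic"],
        }
        for cls, fit in fits.items():
            for term in fit.coefficients:
                reg_rows.append({"response": resp, "class": cls, "term": term,
                                 "estimate": fit.coefficients[term],
                                 "se": fit.standard_errors[term],
                                 "adj_r2": fit.adj_r2, "n": fit.n})
    pd.DataFrame(reg_rows).to_csv(os.path.join(out, "regression.csv"), index=False)

    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
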