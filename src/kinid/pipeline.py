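"""End-to-end estimation + identifiability workflow.

Stage order: initial multi-seed estimation with an uninformed prior →
scaled-sensitivity ranking (aggregated over seeds) → per-parameter profile
likelihoods and classification → linear correlations and ACE/MOTA
functional relations → remedy suggestions → optionally, when any parameter
is non-identifiable, a rank-based informed-prior re-estimation pass.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fixtures as fx
from .filtering import (
    BoxConstraints,
    initial_state,
    estimate,
    multistart_estimate,
)
from .models import ConfigError, NoiseModel, TimeSeries
from .priors import prior_from_ranking
from .profile import SteppingPolicy, run_profiles, trajectory_variability
from .relations import (
    IdentifiabilityReport,
    correlation_from_sqrt,
    mota_detect,
    suggest_remedies,
)
from .sensitivity import aggregate_rankings, compute_sensitivities, rank_parameters

__all__ = ["FrameworkConfig", "FrameworkReport", "run_framework", "load_config"]


@dataclass
class FrameworkConfig:
    """Declarative configuration for a full framework run."""

    model: str = "mm_chain"  # fixture id or path to an SBML file
    observed: list | None = None  # SBML observed species (fixtures observe all)
    data: list = field(default_factory=list)  # CSV paths, ordered for phases
    param_lower: float = 1e-8
    param_upper: float = 100.0
    noise_kind: str = "multiplicative"
    noise_c: float = 0.2
    rank_threshold: float = 0.004
    confidence: float = 0.95
    prior_mode: str = "informed"  # informed | uninformed_only
    repetitions: int = 5
    seed: int = 0
    n_starts: int = 3
    profile_max_steps: int = 60
    sigma_min: float = 0.001
    sigma_max: float = 1.0
    #: relative perturbation of the informed-prior mean across repetitions
    prior_perturb: float = 0.01

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh)


def load_config(path) -> FrameworkConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    known = {k: v for k, v in payload.items() if k in FrameworkConfig().__dict__}
    return FrameworkConfig(**known)


@dataclass
class FrameworkReport:
    config: FrameworkConfig
    theta_estimates: list  # per-seed final theta dicts (uninformed stage)
    ranking: object
    ia: IdentifiabilityReport
    informed_estimates: list  # per-seed theta dicts after informed prior (may be empty)
    merits: list
    profiles: dict

    def to_dict(self) -> dict:
        return {
            "model": self.config.model,
            "seed": self.config.seed,
            "theta_estimates": [
                {k: float(v) for k, v in t.items()} for t in self.theta_estimates
            ],
            "ranking": self.ranking.to_dict() if self.ranking is not None else None,
            "identifiability": self.ia.to_dict(),
            "informed_estimates": [
                {k: float(v) for k, v in t.items()} for t in self.informed_estimates
            ],
            "merits": [float(m) for m in self.merits],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _resolve_model_and_data(config: FrameworkConfig):
    """Build (model, data series, r_fn) from a fixture id or SBML + CSVs."""
    if config.model in fx.FIXTURE_IDS:
        noise = NoiseModel(kind=config.noise_kind, c_mult=config.noise_c, seed=config.seed)
        model, _, noisy = fx.make_fixture(
            fx.FixtureSpec(model_id=config.model, noise=noise, seed=config.seed)
        )
        datasets = [noisy]
    else:
        from .sbml import load_sbml

        model = load_sbml(config.model, observed=config.observed)
        if not config.data:
            raise ConfigError("SBML models need at least one data CSV")
        datasets = [TimeSeries.read_csv(p) for p in config.data]
    if config.data and config.model in fx.FIXTURE_IDS:
        datasets = [TimeSeries.read_csv(p) for p in config.data]
    if config.noise_kind == "multiplicative":
        r_fn = fx.proportional_r_fn(config.noise_c)
    elif config.noise_kind == "mixed":
        r_fn = fx.mixed_r_fn(0.1, config.noise_c)
    else:
        r_fn = None
    return model, datasets, r_fn


def _R_list(data: TimeSeries, r_fn, fallback: float = 0.1):
    if r_fn is None:
        return np.eye(len(data.observed_names)) * fallback**2
    return [
        np.atleast_2d(r_fn(k, y)) @ np.atleast_2d(r_fn(k, y)).T
        for k, y in enumerate(data.values)
    ]


def _estimate_with_prior(model, data, prior, r_fn, *, n_anneal=8, decay=0.5):
    """Annealed estimation starting from a PriorSpec's mean and factors."""
    theta0 = prior.mean0[model.n_states :]
    p_diag = np.diag(prior.sqrt_V0 @ prior.sqrt_V0.T)
    q_diag = np.diag(prior.sqrt_Q0 @ prior.sqrt_Q0.T)
    d = model.n_states
    res = None
    theta = np.clip(theta0, 1e-8, None)
    constraints = BoxConstraints.for_model(model)
    for sweep in range(n_anneal):
        scale = decay**sweep
        init = initial_state(
            model,
            theta,
            constraints=constraints,
            p0_state=np.maximum(p_diag[:d] * scale, 1e-10),
            p0_param=np.maximum(p_diag[d:] * scale, 1e-12),
            q_state=np.maximum(q_diag[:d] * scale, 1e-12),
            q_param=np.maximum(q_diag[d:] * scale, 1e-14),
            sqrt_R=0.1,
        )
        res = estimate(model, data, init, r_fn=r_fn, rtol=1e-6, atol=1e-9)
        theta = res.final_theta_vector
    return res


def run_framework(config: FrameworkConfig, out_dir: str | Path | None = None) -> FrameworkReport:
    """Run the full workflow; optionally write all artifacts under ``out_dir``."""
    log = logging.getLogger("kinid.pipeline")
    model, datasets, r_fn = _resolve_model_and_data(config)
    data = datasets[0]
    R = _R_list(data, r_fn)
    rng = np.random.default_rng(config.seed)

    # stage 1: multi-seed uninformed estimation
    log.info("stage 1: estimation (%d repetitions)", config.repetitions)
    fits = []
    for rep in range(config.repetitions):
        res = multistart_estimate(
            model,
            data,
            n_starts=config.n_starts,
            seed=int(rng.integers(0, 2**31 - 1)),
            r_fn=r_fn,
            R_for_selection=R,
        )
        fits.append(res)
    best = min(fits, key=lambda r: r.merit)
    theta_hat = dict(best.final_theta)

    # stage 2: sensitivities + ranking per fit, aggregated
    log.info("stage 2: sensitivity ranking; best merit %.3g", best.merit)
    rankings = []
    for res in fits:
        Z = compute_sensitivities(model, res.final_theta, data.times)
        rankings.append(rank_parameters(Z, threshold=config.rank_threshold))
    ranking = aggregate_rankings(rankings)

    # stage 3: profiles + classification; the merit is the noise model's
    # −2 log-likelihood (signal-dependent variance keeps its log-det term)
    from .filtering import proportional_nll

    policy = SteppingPolicy(
        max_steps=config.profile_max_steps,
        psi_lower=config.param_lower,
        psi_upper=config.param_upper,
    )
    if config.noise_kind == "multiplicative":
        objective = lambda mdl, th: proportional_nll(mdl, th, data, c=config.noise_c)  # noqa: E731
    elif config.noise_kind == "mixed":
        objective = lambda mdl, th: proportional_nll(  # noqa: E731
            mdl, th, data, c=config.noise_c, a_add=0.1
        )
    else:
        objective = None
    profiles = run_profiles(
        model, data, theta_hat, R, policy=policy, alpha=config.confidence,
        r_fn=r_fn, objective=objective,
    )
    classes = {p: t.klass for p, t in profiles.items()}
    cis = {p: t.ci for p, t in profiles.items()}

    log.info("stage 3 done: classes %s", classes)
    # stage 4: correlations + functional relations
    corr = correlation_from_sqrt(
        best.final_S, model.estimated_params, n_states=model.n_states
    )
    rows = []
    for p, t in profiles.items():
        for pt in t.all_points():
            if pt.ok and pt.eta_opt:
                row = dict(pt.eta_opt)
                row[p] = pt.psi_value
                rows.append([row.get(q, np.nan) for q in model.estimated_params])
    samples = pd.DataFrame(rows, columns=list(model.estimated_params)).dropna()
    relations = []
    if len(samples) >= 30 and model.n_est >= 2:
        relations = mota_detect(samples, seed=config.seed)

    variability = {}
    for p, t in profiles.items():
        if t.klass == "practical":
            variability[p] = trajectory_variability(model, t, data.times)

    ia = IdentifiabilityReport(
        classes=classes,
        cis=cis,
        ranks={p: ranking.rank_of(p) for p in model.estimated_params},
        relations=relations,
        correlations=corr,
        chi2_min=min(t.chi2_min for t in profiles.values()),
        thresholds={
            "pointwise": next(iter(profiles.values())).threshold_pointwise,
            "simultaneous": next(iter(profiles.values())).threshold_simultaneous,
        },
    )
    ia.suggestions = suggest_remedies(ia, ranking, variability)

    # stage 5: informed-prior re-estimation when needed
    log.info("stage 4 done: %d relations, %d suggestions", len(relations), len(ia.suggestions))
    informed_thetas = []
    if config.prior_mode == "informed" and ia.nonidentifiable():
        # the prior mean carries the first-pass estimate (the IA hands the
        # informed prior back to the estimator); repetitions differ by a
        # small multiplicative perturbation of that mean
        base_theta = np.array([theta_hat[p] for p in model.estimated_params])
        for rep in range(config.repetitions):
            perturb = rng.uniform(
                1.0 - config.prior_perturb, 1.0 + config.prior_perturb, size=len(base_theta)
            )
            prior = prior_from_ranking(
                model,
                ranking,
                sigma_min=config.sigma_min,
                sigma_max=config.sigma_max,
                theta0=base_theta * perturb,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            res = _estimate_with_prior(model, data, prior, r_fn)
            informed_thetas.append(dict(res.final_theta))

    report = FrameworkReport(
        config=config,
        theta_estimates=[dict(r.final_theta) for r in fits],
        ranking=ranking,
        ia=ia,
        informed_estimates=informed_thetas,
        merits=[r.merit for r in fits],
        profiles=profiles,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
        for p, t in profiles.items():
            t.to_csv(out / f"profile_{p}.csv")
            try:
                from .profile import plot_profile

                plot_profile(t, out / f"profile_{p}.png")
            except Exception:  # plots are optional side-effects
                pass
        corr.to_frame().to_csv(out / "correlation.csv")
        data.to_csv(out / "data_used.csv")
    return report
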