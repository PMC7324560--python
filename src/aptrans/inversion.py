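"""Inversion: estimate conductance adjustments and drug block from biomarkers.

Given a dose-response dataset (per-dose biomarker sets including a control),
the inversion adjusts per-current multiplicative factors lambda (matching
the individual cell's control AP) and per-channel block parameters
eps = 1/IC50 (the drug effect) by minimizing the weighted sum of squared
relative biomarker residuals

    H(lambda, eps) = sum_d sum_j w_{d,j} * H_j(lambda, eps, D_d)^2,

where H_j = |model_j - data_j| / |data_j| over APD20..APD90, v_max, v_min
and optionally the maximal upstroke velocity.  Weights: 2 for v_max, v_min
and APD50, 5 for APD90, 1 for the remaining terms; control-case weights are
additionally multiplied by the number of doses (control included).

Minimization is a continuation scheme: each round draws random starting
points around the incumbent (lambda components within +-10%, eps components
log-uniform within a factor 5) and polishes each with a fixed, small number
of Nelder-Mead iterations in log-parameter space; the incumbent is the best
point ever evaluated, so its cost trace is non-increasing.  A fixed RNG seed
makes the whole procedure deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .apmodel import CHANNELS, SpeciesParams
from .biomarkers import APD_LEVELS, BiomarkerSet
from .engine import BiomarkerSimulator
from .pharmacology import scale_factor

__all__ = [
    "DoseRecord",
    "DoseResponseDataset",
    "InversionConfig",
    "InversionResult",
    "cost_terms",
    "default_weights",
    "total_cost",
    "invert",
]

log = logging.getLogger(__name__)

#: cost assigned when a candidate's simulation fails (keeps the simplex alive)
PENALTY_COST = 1.0e6

#: currents whose adjustment factors are free by default (every current
#: of the base parameterization; I_CaT joins for species that have it)
DEFAULT_FREE_LAMBDAS = (
    "I_Kr",
    "I_CaL",
    "I_Na",
    "I_Ks",
    "I_KL",
    "I_to",
    "I_NaL",
    "I_NaCa",
    "I_NaK",
    "I_bCl",
    "I_bCa",
    "I_pCa",
)


@dataclass(frozen=True)
class DoseRecord:
    dose: float
    biomarkers: BiomarkerSet


@dataclass(frozen=True)
class DoseResponseDataset:
    """Per-dose biomarker sets, control (dose 0) included."""

    species_name: str
    dose_unit: str
    records: tuple[DoseRecord, ...]

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        doses = [r.dose for r in self.records]
        if 0.0 not in doses:
            raise ValueError("dataset must contain the control case (dose 0)")
        if len(set(doses)) != len(doses):
            raise ValueError(f"doses must be distinct, got {doses}")
        if any(d < 0 for d in doses):
            raise ValueError("doses must be >= 0")
        keysets = {tuple(sorted(r.biomarkers.apd)) for r in self.records}
        if len(keysets) != 1:
            raise ValueError("all records must carry the same biomarker keys")

    @property
    def doses(self) -> tuple[float, ...]:
        return tuple(r.dose for r in self.records)

    @property
    def n_doses(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class InversionConfig:
    """Free parameters, weights and continuation schedule.

    The shipped defaults follow the reference procedure (10 rounds of 100
    guesses, 15 Nelder-Mead iterations each, +-10% lambda windows, factor-5
    epsilon windows); tests and quick runs scale the schedule down.
    """

    free_epsilons: tuple[str, ...]
    free_lambdas: tuple[str, ...] | None = None  # None -> all currents present
    weights: Mapping[str, float] | None = None  # term -> base weight override
    continuation_iterations: int = 10
    guesses_per_iteration: int = 100
    nm_iterations: int = 15
    lambda_jitter: float = 0.10
    epsilon_range_factor: float = 5.0
    include_dvdt_term: bool = False
    rng_seed: int = 0
    eval_beats: int = 30
    warm_beats: int = 50

    def __post_init__(self):
        object.__setattr__(self, "free_epsilons", tuple(self.free_epsilons))
        if self.free_lambdas is not None:
            object.__setattr__(self, "free_lambdas", tuple(self.free_lambdas))
        if min(self.continuation_iterations, self.guesses_per_iteration,
               self.nm_iterations) < 1:
            raise ValueError("schedule counts must be >= 1")
        if not (0 < self.lambda_jitter < 1):
            raise ValueError("lambda_jitter must be in (0, 1)")
        if self.epsilon_range_factor <= 1:
            raise ValueError("epsilon_range_factor must be > 1")

    def resolved_free_lambdas(self, params: SpeciesParams) -> tuple[str, ...]:
        if self.free_lambdas is not None:
            return self.free_lambdas
        lams = list(DEFAULT_FREE_LAMBDAS)
        if params.g_CaT > 0:
            lams.append("I_CaT")
        return tuple(lams)


@dataclass
class InversionResult:
    """Estimated adjustment factors and drug parameters, with audit trail."""

    species_name: str
    dose_unit: str
    lambda_hat: dict[str, float]
    epsilon_hat: dict[str, float]
    final_cost: float
    cost_trace: list[float]  # incumbent cost after each continuation round
    residuals: dict[float, dict[str, float]]  # dose -> term -> H_j
    config: dict
    rng_seed: int

    @property
    def ic50_hat(self) -> dict[str, float]:
        return {
            ch: (float("inf") if e == 0 else 1.0 / e)
            for ch, e in self.epsilon_hat.items()
        }


def _term_names(include_dvdt: bool) -> tuple[str, ...]:
    names = [f"apd{p}" for p in APD_LEVELS] + ["v_max", "v_min"]
    if include_dvdt:
        names.append("dvdt_max")
    return tuple(names)


def cost_terms(
    model: BiomarkerSet, data: BiomarkerSet, include_dvdt: bool = False
) -> dict[str, float]:
    """Relative absolute residual |model - data| / |data| per biomarker."""
    out = {}
    for name in _term_names(include_dvdt):
        d = data.value(name)
        if d == 0:
            raise ValueError(f"relative residual undefined: data {name} is 0")
        out[name] = abs(model.value(name) - d) / abs(d)
    return out


def default_weights(n_doses: int, include_dvdt: bool = False) -> dict:
    """Weight map (dose_index, term) -> weight.

    Base weights: 2 for v_max, v_min and APD50, 5 for APD90, 1 otherwise
    (including the upstroke-velocity term when enabled).  Dose index 0 is
    the control case; its weights are multiplied by ``n_doses``.
    """
    if n_doses < 1:
        raise ValueError("n_doses must be >= 1 (control counted)")
    base = _base_weights(include_dvdt, None)
    out = {}
    for d in range(n_doses):
        mult = n_doses if d == 0 else 1
        for term, w in base.items():
            out[(d, term)] = mult * w
    return out


def _base_weights(include_dvdt: bool, override: Mapping[str, float] | None):
    base = {name: 1.0 for name in _term_names(include_dvdt)}
    base["v_max"] = 2.0
    base["v_min"] = 2.0
    base["apd50"] = 2.0
    base["apd90"] = 5.0
    if override:
        base.update(override)
    return base


def _model_biomarkers(
    sim: BiomarkerSimulator,
    lambdas: Mapping[str, float],
    epsilons: Mapping[str, float],
    dose: float,
) -> BiomarkerSet:
    blocks = {ch: scale_factor(e, dose) for ch, e in epsilons.items()}
    return sim.biomarkers(lambdas=lambdas, blocks=blocks)


def total_cost(
    lambdas: Mapping[str, float],
    epsilons: Mapping[str, float],
    dataset: DoseResponseDataset,
    cfg: InversionConfig,
    sim: BiomarkerSimulator,
    return_residuals: bool = False,
):
    """Weighted sum of squared residuals over all doses and terms.

    A failed simulation (or an unmeasurable action potential) contributes a
    large finite penalty instead of raising, so derivative-free search can
    continue past pathological parameter combinations.
    """
    base = _base_weights(cfg.include_dvdt_term, cfg.weights)
    n = dataset.n_doses
    h = 0.0
    residuals: dict[float, dict[str, float]] = {}
    for rec in dataset.records:
        mult = n if rec.dose == 0 else 1
        try:
            model_bm = _model_biomarkers(sim, lambdas, epsilons, rec.dose)
            terms = cost_terms(model_bm, rec.biomarkers, cfg.include_dvdt_term)
        except (ValueError, RuntimeError) as exc:
            log.debug("penalty at dose %s: %s", rec.dose, exc)
            if return_residuals:
                residuals[rec.dose] = {"penalty": PENALTY_COST}
            h += PENALTY_COST
            continue
        residuals[rec.dose] = terms
        for term, resid in terms.items():
            h += mult * base[term] * resid * resid
    if return_residuals:
        return h, residuals
    return h


def _initial_epsilons(
    dataset: DoseResponseDataset,
    cfg: InversionConfig,
    sim: BiomarkerSimulator,
    lambdas: Mapping[str, float],
) -> dict[str, float]:
    """Coarse per-channel scan replacing hand-picked starting values.

    Channels are scanned one at a time (others held at 1/D_max) over
    {0.1, 0.3, 1, 3, 10}/D_max, keeping the lowest-cost value.
    """
    d_max = max(dataset.doses)
    if d_max <= 0:  # control-only dataset: nothing constrains epsilon
        return {ch: 1.0 for ch in cfg.free_epsilons}
    # the 0.01/D point represents "essentially no block" so a channel the
    # drug does not touch can start near zero effect
    grid = [x / d_max for x in (0.01, 0.1, 0.3, 1.0, 3.0, 10.0)]
    eps = {ch: 1.0 / d_max for ch in cfg.free_epsilons}
    for ch in cfg.free_epsilons:
        best_val, best_cost = eps[ch], np.inf
        for cand in grid:
            trial = dict(eps)
            trial[ch] = cand
            c = total_cost(lambdas, trial, dataset, cfg, sim)
            if c < best_cost:
                best_val, best_cost = cand, c
        eps[ch] = best_val
    return eps


def invert(
    dataset: DoseResponseDataset,
    cfg: InversionConfig,
    params: SpeciesParams,
    simulator: BiomarkerSimulator | None = None,
) -> InversionResult:
    """Run the continuation/Nelder-Mead minimization on a dataset.

    Identical ``cfg.rng_seed`` (and inputs) gives an identical result.  The
    incumbent after each continuation round is logged and recorded in the
    returned cost trace.
    """
    for ch in cfg.free_epsilons:
        if ch not in CHANNELS:
            raise KeyError(f"unknown channel {ch!r} in free_epsilons")
        if params.magnitude(ch) == 0:
            raise ValueError(
                f"free epsilon on {ch}, but species {params.species_name} has "
                "zero conductance for it (drug effect unobservable)"
            )
    free_l = cfg.resolved_free_lambdas(params)
    sim = simulator or BiomarkerSimulator(
        params,
        warm_beats=cfg.warm_beats,
        eval_beats=cfg.eval_beats,
        include_dvdt=cfg.include_dvdt_term,
    )
    rng = np.random.default_rng(cfg.rng_seed)

    nl = len(free_l)

    def unpack(x: np.ndarray):
        lam = {ch: float(np.exp(x[i])) for i, ch in enumerate(free_l)}
        eps = {ch: float(np.exp(x[nl + i])) for i, ch in enumerate(cfg.free_epsilons)}
        return lam, eps

    best = {"x": None, "cost": np.inf}

    def objective(x: np.ndarray) -> float:
        lam, eps = unpack(x)
        c = total_cost(lam, eps, dataset, cfg, sim)
        if c < best["cost"]:
            best["cost"] = c
            best["x"] = x.copy()
        return c

    # incumbent for the first round: lambda = 1, epsilon from a coarse scan
    lam0 = {ch: 1.0 for ch in free_l}
    eps0 = _initial_epsilons(dataset, cfg, sim, lam0)
    x0 = np.log(np.array([lam0[ch] for ch in free_l]
                         + [eps0[ch] for ch in cfg.free_epsilons]))
    objective(x0)

    d_max = max(dataset.doses)
    cost_trace = []
    jit = cfg.lambda_jitter
    fac = cfg.epsilon_range_factor
    ne = len(cfg.free_epsilons)
    for it in range(cfg.continuation_iterations):
        inc = best["x"].copy()
        lam_inc = np.exp(inc[:nl])
        eps_inc = np.exp(inc[nl:])
        starts = []
        # deterministic no-block probes: epsilon estimates can fall into
        # compensation valleys (a spurious block on one channel traded
        # against the others), so each round first asks whether dropping
        # each blocked channel entirely improves the fit
        if d_max > 0:
            for k in range(ne):
                eps_p = eps_inc.copy()
                eps_p[k] = 0.01 / d_max
                starts.append(np.concatenate([np.log(lam_inc), np.log(eps_p)]))
        for _ in range(cfg.guesses_per_iteration):
            lam_g = lam_inc * rng.uniform(1.0 - jit, 1.0 + jit, size=nl)
            eps_g = eps_inc * np.exp(
                rng.uniform(-np.log(fac), np.log(fac), size=ne)
            )
            starts.append(np.concatenate([np.log(lam_g), np.log(eps_g)]))
        for xg in starts:
            # explicit initial simplex: scipy's default collapses at
            # log-parameters near 0 (i.e. lambda or epsilon near 1)
            ndim = xg.size
            simplex = np.tile(xg, (ndim + 1, 1))
            for k in range(ndim):
                simplex[k + 1, k] += jit / 2.0 if k < nl else np.log(fac) / 3.0
            minimize(
                objective,
                xg,
                method="Nelder-Mead",
                options={
                    "maxiter": cfg.nm_iterations,
                    "initial_simplex": simplex,
                    "xatol": 1e-12,
                    "fatol": 1e-14,
                },
            )
        cost_trace.append(best["cost"])
        lam_b, eps_b = unpack(best["x"])
        log.info(
            "continuation %d/%d: incumbent cost %.6g, eps %s",
            it + 1,
            cfg.continuation_iterations,
            best["cost"],
            {ch: f"{e:.4g}" for ch, e in eps_b.items()},
        )

    lam_hat, eps_hat = unpack(best["x"])
    final_cost, residuals = total_cost(
        lam_hat, eps_hat, dataset, cfg, sim, return_residuals=True
    )
    cfg_echo = asdict(cfg)
    cfg_echo["free_lambdas"] = list(free_l)
    cfg_echo["weights"] = dict(cfg.weights) if cfg.weights else None
    return InversionResult(
        species_name=params.species_name,
        dose_unit=dataset.dose_unit,
        lambda_hat=lam_hat,
        epsilon_hat=eps_hat,
        final_cost=final_cost,
        cost_trace=cost_trace,
        residuals=residuals,
        config=cfg_echo,
        rng_seed=cfg.rng_seed,
    )
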