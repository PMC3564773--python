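"""Scoring and Monte-Carlo fitting of the closure model to time courses.

The objective is a (by default inverse-SEM-weighted) sum of squared
residuals between simulated and observed percent-of-control values at the
observed (treatment, variable, time) points.  Records at t = 0 carry zero
residual automatically because every simulation starts at 100.

The fitter is a squeeze-and-breathe scheme: an accelerated Monte-Carlo
search that alternates (i) sampling candidate parameter vectors in
log-space, (ii) keeping an elite subset, (iii) optionally polishing elites
with a bounded local least-squares step, (iv) contracting ("squeezing")
the sampling distribution around the elites, and (v) periodically
re-expanding ("breathing") toward the original bounds to escape premature
collapse.  Rates span decades and must stay positive, hence the log-space
parameterisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import (
    ModelParameters,
    StimulusDose,
    VARIANTS,
    free_parameter_names,
)
from .simulate import IntegrationError, simulate

__all__ = [
    "TimeCourseDataset",
    "FitConfig",
    "FitResult",
    "DEFAULT_BOUNDS",
    "default_bounds",
    "objective",
    "squeeze_and_breathe_fit",
    "compare_variants",
]

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = (
    "treatment_aba_um", "treatment_acc_um", "variable",
    "time_min", "mean_pct", "sem_pct",
)

_VARIABLES = ("ros", "aperture")


class TimeCourseDataset:
    """Records of (treatment, variable, time, mean, sem), percent of control.

    Thin validated wrapper around a tidy DataFrame with columns
    ``treatment_aba_um, treatment_acc_um, variable, time_min, mean_pct,
    sem_pct`` (extra columns such as ``source`` are preserved).
    """

    def __init__(self, records: pd.DataFrame):
        df = records.copy()
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("dataset must contain at least one record")
        bad_var = set(df["variable"]) - set(_VARIABLES)
        if bad_var:
            raise ValueError(f"unknown variables {bad_var}; expected {_VARIABLES}")
        for col in ("treatment_aba_um", "treatment_acc_um", "time_min",
                    "mean_pct", "sem_pct"):
            df[col] = df[col].astype(float)
        if (df["time_min"] < 0).any():
            raise ValueError("times must be >= 0")
        if (df["mean_pct"] <= 0).any():
            raise ValueError("means must be > 0 (percent of control)")
        if (df["sem_pct"] < 0).any():
            raise ValueError("sems must be >= 0")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def treatments(self) -> list:
        """Unique stimulus doses present, as :class:`StimulusDose`."""
        pairs = self.records[["treatment_aba_um", "treatment_acc_um"]]
        return [StimulusDose(a, c) for a, c in
                pairs.drop_duplicates().itertuples(index=False)]

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TimeCourseDataset":
        return cls(pd.read_csv(path))


#: Default fitting box: log-uniform over these (low, high) ranges.
#: Ranges are set by dimensional analysis of the percent-of-control scale:
#: every state sits near 100, so each kinetic term's magnitude should span
#: roughly 0.01-10 %/min within the box.  Bimolecular coefficients that
#: multiply one or two ~100-scale species (beta11, beta50, alpha42) are
#: scaled down accordingly; alpha51 feeds through 1/(k51+NO) and is scaled
#: up.  Cascade lengths span 1..10 and saturation constants 0.01-1000.
_BOUND_RULES: Dict[str, Tuple[float, float]] = {
    "n1": (1.0, 10.0), "n2": (1.0, 10.0),
    "k11": (1e-2, 1e3), "k12": (1e-2, 1e3),
    "k21": (1e-2, 1e3), "k22": (1e-2, 1e3),
    "k31": (1e-2, 1e3), "k51": (1e-2, 1e3),
    "alpha10": (1e-3, 1e2), "alpha11": (1e-2, 1e2), "alpha12": (1e-2, 1e2),
    "beta11": (1e-6, 1e-2), "beta12": (1e-4, 1e1),
    "alpha20": (1e-3, 1e2), "alpha21": (1e-3, 1e2), "alpha22": (1e-3, 1e2),
    "alpha23": (1e-4, 1e0), "beta20": (1e-4, 1e0),
    "beta13": (1e-3, 1e0),
    "alpha31": (1e-2, 1e2), "alpha32": (1e-3, 1e2), "beta30": (1e-4, 1e0),
    "alpha40": (1e-3, 1e2), "alpha41": (1e-3, 1e2), "alpha42": (1e-6, 1e0),
    "beta40": (1e-4, 1e0), "alpha43": (1e-3, 1e2),
    "alpha51": (1e-1, 1e5), "beta50": (1e-7, 1e-2),
}


def default_bounds() -> Dict[str, Tuple[float, float]]:
    return dict(_BOUND_RULES)


DEFAULT_BOUNDS = default_bounds()


@dataclass
class FitConfig:
    """Budget and search-space configuration for the Monte-Carlo fit.

    ``fixed`` pins named parameters to given values (they are excluded from
    the search); ``bounds`` overrides the default per-parameter box.
    """

    bounds: Optional[Dict[str, Tuple[float, float]]] = None
    n_samples: int = 250
    n_elite: int = 15
    n_rounds: int = 10
    contraction: float = 0.7
    breathe_every: int = 5
    local_refine: bool = True
    n_refine: int = 2
    refine_max_nfev: int = 100
    final_polish_max_nfev: int = 500
    weighting: str = "inverse_sem"
    rtol: float = 1e-6
    atol: float = 1e-8
    seed: int = 0
    fixed: Dict[str, float] = field(default_factory=dict)
    #: optional warm starts evaluated alongside the first round's samples
    initial_guesses: Tuple[ModelParameters, ...] = ()

    def __post_init__(self) -> None:
        if self.n_elite > self.n_samples:
            raise ValueError("n_elite must be <= n_samples")
        if not (0.0 < self.contraction < 1.0):
            raise ValueError("contraction must be in (0, 1)")
        if self.weighting not in ("uniform", "inverse_sem"):
            raise ValueError("weighting must be 'uniform' or 'inverse_sem'")

    def resolved_bounds(self) -> Dict[str, Tuple[float, float]]:
        out = default_bounds()
        if self.bounds:
            out.update(self.bounds)
        return out


@dataclass
class FitResult:
    """Outcome of a fit: best parameters, score, and search diagnostics."""

    best_params: ModelParameters
    objective: float
    variant: str
    trace: np.ndarray  # best-ever score after each round (non-increasing)
    seed: int
    n_evaluations: int


class _ResidualModel:
    """Precomputed residual machinery for one dataset/variant/weighting."""

    def __init__(self, dataset: TimeCourseDataset, variant: str,
                 weighting: str, rtol: float, atol: float):
        if variant not in VARIANTS:
            raise ValueError(f"unknown model variant {variant!r}")
        self.variant = variant
        self.rtol, self.atol = rtol, atol
        self.groups = []
        obs_mean, obs_w = [], []
        df = dataset.records
        for (aba, acc), grp in df.groupby(["treatment_aba_um", "treatment_acc_um"],
                                          sort=True):
            times = np.unique(np.concatenate([[0.0], grp["time_min"].to_numpy()]))
            pos = {t: i for i, t in enumerate(times)}
            idx = np.array([pos[t] for t in grp["time_min"]])
            is_ros = (grp["variable"] == "ros").to_numpy()
            self.groups.append((StimulusDose(aba, acc), times, idx, is_ros))
            obs_mean.append(grp["mean_pct"].to_numpy())
            sem = grp["sem_pct"].to_numpy()
            if weighting == "inverse_sem":
                # sem == 0 would give infinite weight; fall back to unit weight
                w = np.where(sem > 0, 1.0 / np.where(sem > 0, sem, 1.0), 1.0)
            else:
                w = np.ones_like(sem)
            obs_w.append(w)
        self.mean = np.concatenate(obs_mean)
        self.weight = np.concatenate(obs_w)
        self.n_residuals = self.mean.size
        self.n_evaluations = 0

    def predictions(self, params: ModelParameters) -> np.ndarray:
        self.n_evaluations += 1
        preds = []
        for dose, times, idx, is_ros in self.groups:
            traj = simulate(params, dose, times, variant=self.variant,
                            rtol=self.rtol, atol=self.atol)
            values = np.where(is_ros, traj.ros[idx], traj.k[idx])
            preds.append(values)
        return np.concatenate(preds)

    def residuals(self, params: ModelParameters) -> np.ndarray:
        return (self.predictions(params) - self.mean) * self.weight

    def score(self, params: ModelParameters) -> float:
        try:
            r = self.residuals(params)
        except IntegrationError as err:
            logger.debug("candidate rejected: %s", err)
            return np.inf
        return float(r @ r)


def objective(params: ModelParameters, dataset: TimeCourseDataset,
              variant: str = "primary", weighting: str = "inverse_sem",
              rtol: float = 1e-6, atol: float = 1e-8) -> float:
    """Weighted sum of squared residuals of the model against a dataset.

    Under ``inverse_sem`` weighting each squared residual is divided by the
    record's sem^2 (records with sem = 0 get unit weight); ``uniform``
    weighting uses raw residuals.  Returns +inf if integration fails for
    any treatment (the candidate is infeasible).
    """
    if weighting not in ("uniform", "inverse_sem"):
        raise ValueError("weighting must be 'uniform' or 'inverse_sem'")
    return _ResidualModel(dataset, variant, weighting, rtol, atol).score(params)


def _build_params(names: Sequence[str], values: np.ndarray,
                  fixed: Dict[str, float], variant: str) -> ModelParameters:
    d = {n: 0.0 for n in ModelParameters.__dataclass_fields__}
    d.update(fixed)
    d.update(zip(names, values))
    return ModelParameters(**d)


def squeeze_and_breathe_fit(dataset: TimeCourseDataset, config: FitConfig,
                            variant: str = "primary") -> FitResult:
    """Fit the model to a dataset with the squeeze-and-breathe search.

    Sampling is log-uniform within bounds on the first round, then
    log-normal centred on the elite mean.  Elites survive between rounds,
    so the best-ever score trace is non-increasing.  Reproducible for a
    fixed ``config.seed``.

    Raises
    ------
    RuntimeError
        if every candidate in a round is infeasible (consider widening
        bounds or loosening integration tolerances).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}")
    rng = np.random.default_rng(config.seed)
    bounds = config.resolved_bounds()
    names = [n for n in free_parameter_names(variant) if n not in config.fixed]
    lo = np.log10([bounds[n][0] for n in names])
    hi = np.log10([bounds[n][1] for n in names])
    rm = _ResidualModel(dataset, variant, config.weighting,
                        config.rtol, config.atol)

    def score_x(x: np.ndarray) -> float:
        return rm.score(_build_params(names, 10.0 ** x, config.fixed, variant))

    def refine(x: np.ndarray, max_nfev: int) -> tuple:
        def fun(z):
            try:
                return rm.residuals(
                    _build_params(names, 10.0 ** z, config.fixed, variant))
            except IntegrationError:
                return np.full(rm.n_residuals, 1e6)
        try:
            sol = least_squares(fun, x, bounds=(lo, hi), max_nfev=max_nfev,
                                method="trf", x_scale="jac")
        except Exception as err:  # keep the search alive on solver hiccups
            logger.debug("local refinement failed: %s", err)
            return x, np.inf
        return sol.x, float(2 * sol.cost)

    sd0 = (hi - lo) / 4.0
    sd = sd0.copy()
    mean = 0.5 * (lo + hi)
    elites_x: list = []
    elites_s: list = []
    best_x, best_s = None, np.inf
    trace = []

    for rnd in range(config.n_rounds):
        if rnd == 0:
            X = rng.uniform(lo, hi, size=(config.n_samples, lo.size))
            for g, guess in enumerate(config.initial_guesses):
                x = np.log10(np.clip(guess.to_array(names),
                                     10.0 ** lo, 10.0 ** hi))
                X[g % len(X)] = x
        else:
            X = rng.normal(mean, sd, size=(config.n_samples, lo.size))
            X = np.clip(X, lo, hi)
        fresh_s = [score_x(x) for x in X]
        if not np.isfinite(np.min(fresh_s + elites_s)):
            raise RuntimeError(
                "all candidates infeasible in a squeeze-and-breathe round; "
                "consider wider bounds or looser integration tolerances"
            )
        if config.local_refine:
            # polish the best *fresh* candidates: novel starting points keep
            # the search from re-refining one basin round after round
            for j in np.argsort(fresh_s)[: config.n_refine]:
                xr, sr = refine(X[j], config.refine_max_nfev)
                if sr < fresh_s[j]:
                    X[j], fresh_s[j] = xr, sr
        pool_x = list(X) + elites_x
        pool_s = fresh_s + elites_s
        elite_idx = np.argsort(pool_s)[: config.n_elite]
        elites_x = [pool_x[i] for i in elite_idx]
        elites_s = [pool_s[i] for i in elite_idx]

        if elites_s[0] < best_s:
            best_s = elites_s[0]
            best_x = elites_x[0].copy()
        trace.append(best_s)

        E = np.array(elites_x)
        mean = E.mean(axis=0)
        elite_sd = E.std(axis=0)
        sd = np.maximum(config.contraction * sd, elite_sd)
        sd = np.maximum(sd, 1e-4)
        if config.breathe_every and (rnd + 1) % config.breathe_every == 0:
            sd = np.sqrt(sd * sd0)  # breathe back toward the original box

    if config.local_refine:
        xr, sr = refine(best_x, config.final_polish_max_nfev)
        if sr < best_s:
            best_x, best_s = xr, sr
            trace[-1] = best_s

    best_params = _build_params(names, 10.0 ** best_x, config.fixed, variant)
    return FitResult(
        best_params=best_params,
        objective=rm.score(best_params),
        variant=variant,
        trace=np.array(trace),
        seed=config.seed,
        n_evaluations=rm.n_evaluations,
    )


#: Parameters pinned to zero for the ethylene-blind control model: with
#: these off, ACC has no route into ROS, AOX1 or NO production.
ETHYLENE_BLIND_FIXED = {"alpha12": 0.0, "alpha22": 0.0, "alpha32": 0.0}


def compare_variants(dataset: TimeCourseDataset, config: FitConfig,
                     variants: Sequence[str] = ("primary", "ph_variant"),
                     ) -> pd.DataFrame:
    """Fit several model variants with identical budget and seed.

    Accepts the two real variants plus ``"ethylene_blind"``, a deliberately
    crippled control (the primary equations with every ACC input removed).
    Returns a DataFrame ordered by objective with an AIC-style score
    2k + n*log(SSE/n) (k = 28 free parameters for either real variant;
    SSE is the unweighted sum of squares at the best fit).  A failed fit is
    reported in the ``error`` column without aborting the other variants.
    """
    rows = []
    n = len(dataset)
    for tag in variants:
        if tag == "ethylene_blind":
            variant, fixed = "primary", dict(ETHYLENE_BLIND_FIXED)
            fixed.update(config.fixed)
        else:
            variant, fixed = tag, dict(config.fixed)
        cfg = dc_replace(config, fixed=fixed)
        try:
            fit = squeeze_and_breathe_fit(dataset, cfg, variant=variant)
            sse = objective(fit.best_params, dataset, variant=variant,
                            weighting="uniform", rtol=config.rtol,
                            atol=config.atol)
            k = 28
            rows.append({
                "label": tag, "variant": variant, "objective": fit.objective,
                "sse": sse, "aic": 2 * k + n * np.log(sse / n),
                "error": "", "fit": fit,
            })
        except Exception as err:
            logger.warning("variant %s failed to fit: %s", tag, err)
            rows.append({
                "label": tag, "variant": variant, "objective": np.inf,
                "sse": np.inf, "aic": np.inf, "error": str(err), "fit": None,
            })
    out = pd.DataFrame(rows).sort_values("objective").reset_index(drop=True)
    return out
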