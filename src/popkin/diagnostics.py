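"""Model qualification: prediction-corrected VPC, numerical predictive check,
nonparametric bootstrap, and goodness-of-fit tables.

The pcVPC simulates replicate trials with the observed designs and
covariates, then normalizes observed and simulated concentrations by the
median population prediction (eta = 0) of each time bin before comparing
percentiles — removing the spread that comes from dose level and covariates
rather than from the random-effect model.  The bootstrap resamples subjects
(whole record blocks) with replacement and refits each replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import Dataset
from .estimation import FitConfig, _Engine, cwres, ebe_estimate, fit, predictions
from .population import PopulationModel
from .structural import conc_linear_batch

__all__ = [
    "VPCResult",
    "BootstrapResult",
    "pcvpc",
    "npc",
    "bootstrap",
    "gof_tables",
    "simulate_observations",
]

logger = logging.getLogger(__name__)

_SIM_CHUNK = 100  # replicates simulated per vectorized batch


def _obs_vectors(ds: Dataset) -> tuple[np.ndarray, np.ndarray]:
    obs = ds.observations()
    return obs["TIME"].to_numpy(float), obs["DV"].to_numpy(float)


def simulate_observations(
    model: PopulationModel,
    ds: Dataset,
    n_sim: int,
    seed: int | np.random.Generator,
    config: FitConfig | None = None,
) -> np.ndarray:
    """Simulate ``n_sim`` replicate datasets under ``model``.

    Uses the observed designs and covariates of ``ds``; returns an array of
    shape (n_sim, n_observations) aligned with ``ds.observations()``.  Etas
    are drawn from Omega and residual noise from sigma; disposition runs
    through the closed-form linear path (the saturable pathway of the fitted
    model is negligible at study concentrations).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    config = config or FitConfig()
    eng = _Engine(model, ds, config)
    d = eng.design
    theta, coeffs, _, _ = eng.unpack(eng.pack(model))
    lp = eng._log_params(theta, coeffs)
    names = model.omega.names
    chol = np.linalg.cholesky(model.omega.matrix + 1e-12 * np.eye(len(names)))
    S, J = d.obs_time.shape
    out = np.empty((n_sim, d.total_obs))
    mask = d.obs_mask
    rows = d.obs_rows[mask]
    for start in range(0, n_sim, _SIM_CHUNK):
        r = min(_SIM_CHUNK, n_sim - start)
        z = rng.standard_normal((r, S, len(names)))
        etas = z @ chol.T  # (r, S, K)
        def with_eta(p):
            base = np.broadcast_to(lp[p][None, :], (r, S))
            if p in names:
                base = base + etas[:, :, names.index(p)]
            return np.exp(base).reshape(r * S)
        conc = conc_linear_batch(
            with_eta("CL"), with_eta("Vc"), with_eta("Q"), with_eta("Vp"),
            np.tile(d.dose_time, (r, 1)),
            np.tile(d.dose_dur, (r, 1)),
            np.tile(d.dose_rate, (r, 1)),
            np.tile(d.obs_time, (r, 1)),
        ).reshape(r, S, J)
        conc = np.maximum(conc, 1e-12)
        noise = rng.standard_normal((r, S, J)) * model.sigma
        sim = conc * np.exp(noise)
        out[start : start + r][:, rows] = sim[:, mask]
    return out


def _make_bins(times: np.ndarray, bins) -> np.ndarray:
    """Bin edges: int -> quantile-based with that many bins; array -> as-is.
    Default targets >= 8 observations per bin."""
    if bins is None:
        bins = max(2, min(10, len(times) // 8))
    if np.isscalar(bins):
        edges = np.unique(np.quantile(times, np.linspace(0, 1, int(bins) + 1)))
    else:
        edges = np.asarray(bins, dtype=float)
    return edges


@dataclass
class VPCResult:
    bin_edges: np.ndarray
    table: pd.DataFrame  # bin, t_mid, percentile, observed, sim_lo, sim_hi, n_obs

    def coverage(self, percentile: float = 50.0) -> float:
        """Fraction of bins whose observed percentile lies inside the CI."""
        t = self.table[self.table["percentile"] == percentile]
        inside = (t["observed"] >= t["sim_lo"]) & (t["observed"] <= t["sim_hi"])
        return float(inside.mean())


def pcvpc(
    model: PopulationModel,
    ds: Dataset,
    n_sim: int = 1000,
    bins=None,
    seed: int | np.random.Generator = 0,
    percentiles: tuple[float, ...] = (2.5, 50.0, 97.5),
    ci: float = 95.0,
    config: FitConfig | None = None,
) -> VPCResult:
    """Prediction-corrected visual predictive check.

    Observed and simulated values are corrected by
    ``y * median(PRED in bin) / PRED`` before percentile comparison; the
    simulated CI of each percentile is the (2.5th, 97.5th) percentile of the
    replicate-level percentiles.
    """
    t_obs, dv = _obs_vectors(ds)
    pred = predictions(model, ds, config=config)
    keep = pred > 0
    if not keep.all():
        logger.warning("%d observations with PRED = 0 excluded from pcVPC", (~keep).sum())
    edges = _make_bins(t_obs[keep], bins)
    idx = np.clip(np.searchsorted(edges, t_obs, side="right") - 1, 0, len(edges) - 2)
    sims = simulate_observations(model, ds, n_sim, seed, config)

    rows = []
    a_lo, a_hi = (100 - ci) / 2.0, 100 - (100 - ci) / 2.0
    for b in range(len(edges) - 1):
        sel = keep & (idx == b)
        if not sel.any():
            continue
        factor = np.median(pred[sel]) / pred[sel]
        pc_obs = dv[sel] * factor
        pc_sim = sims[:, sel] * factor[None, :]
        for q in percentiles:
            obs_q = float(np.percentile(pc_obs, q))
            rep_q = np.percentile(pc_sim, q, axis=1)
            rows.append(
                dict(
                    bin=b,
                    t_mid=float(np.median(t_obs[sel])),
                    percentile=q,
                    observed=obs_q,
                    sim_lo=float(np.percentile(rep_q, a_lo)),
                    sim_hi=float(np.percentile(rep_q, a_hi)),
                    n_obs=int(sel.sum()),
                )
            )
    return VPCResult(edges, pd.DataFrame(rows))


def npc(
    model: PopulationModel,
    ds: Dataset,
    n_sim: int = 1000,
    levels: tuple[float, ...] = (0.5, 0.9, 0.95),
    seed: int | np.random.Generator = 0,
    config: FitConfig | None = None,
) -> pd.DataFrame:
    """Numerical predictive check: observed vs nominal outside-fractions.

    For each prediction-interval level, the per-observation interval is the
    corresponding quantile band of the simulated replicates; rows report the
    fraction of observations outside the band, the nominal fraction, and a
    simulation-based 95% reference range for that fraction.
    """
    _, dv = _obs_vectors(ds)
    sims = simulate_observations(model, ds, n_sim, seed, config)
    rows = []
    for level in levels:
        lo_q, hi_q = 50.0 * (1 - level), 100.0 - 50.0 * (1 - level)
        lo = np.percentile(sims, lo_q, axis=0)
        hi = np.percentile(sims, hi_q, axis=0)
        outside_obs = float(np.mean((dv < lo) | (dv > hi)))
        rep_fracs = np.mean((sims < lo[None, :]) | (sims > hi[None, :]), axis=1)
        rows.append(
            dict(
                level=level,
                nominal_outside=1.0 - level,
                observed_outside=outside_obs,
                sim_lo=float(np.percentile(rep_fracs, 2.5)),
                sim_hi=float(np.percentile(rep_fracs, 97.5)),
            )
        )
    return pd.DataFrame(rows)


@dataclass
class BootstrapResult:
    summary: pd.DataFrame  # index parameter; median, ci_lo, ci_hi
    n_replicates: int
    n_failed: int
    replicates: pd.DataFrame = field(repr=False, default=None)

    @property
    def reliable(self) -> bool:
        return self.n_failed <= 0.2 * self.n_replicates


def _flatten_estimates(model: PopulationModel) -> dict[str, float]:
    out = dict(model.typical_values())
    for e in model.covariate_effects:
        out[e.name] = e.coefficient
    for i, a in enumerate(model.omega.names):
        out[f"omega2_{a}"] = float(model.omega.matrix[i, i])
        for j, b in enumerate(model.omega.names[:i]):
            if model.omega.matrix[i, j] != 0.0:
                out[f"omega_{b}_{a}"] = float(model.omega.matrix[i, j])
    out["sigma"] = model.sigma
    return out


def bootstrap(
    model: PopulationModel,
    ds: Dataset,
    n_replicates: int = 1000,
    seed: int | np.random.Generator = 0,
    config: FitConfig | None = None,
    stratify: str | None = None,
) -> BootstrapResult:
    """Nonparametric bootstrap: resample subjects with replacement, refit.

    ``stratify`` names a covariate column whose level proportions are
    preserved in every resample (e.g. THERAPY).  Replicate fits start from
    the point estimates.  Failed replicates are excluded and counted; more
    than 20% failures flags the result unreliable.
    """
    if ds.n_subjects < 2:
        raise ValueError("bootstrap needs at least 2 subjects")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = np.array(ds.subject_ids, dtype=object)
    if stratify is not None:
        strata_map = ds.covariates_frame()[stratify]
        strata = [ids[(strata_map.loc[ids] == lv).to_numpy()] for lv in strata_map.unique()]
    else:
        strata = [ids]
    by_id = dict(tuple(ds.frame.groupby("ID", sort=False)))
    rows = []
    n_failed = 0
    for _ in range(n_replicates):
        sampled = np.concatenate([rng.choice(s, size=len(s), replace=True) for s in strata])
        blocks = []
        for k, sid in enumerate(sampled):
            block = by_id[sid].copy()
            block["ID"] = f"B{k:04d}"
            blocks.append(block)
        rep_ds = Dataset(pd.concat(blocks, ignore_index=True))
        try:
            res = fit(model, rep_ds, config)
            if not res.converged:
                raise RuntimeError(res.convergence)
            rows.append(_flatten_estimates(res.estimates))
        except Exception as err:
            n_failed += 1
            logger.warning("bootstrap replicate failed: %s", err)
    reps = pd.DataFrame(rows)
    if reps.empty:
        raise RuntimeError("all bootstrap replicates failed")
    summary = pd.DataFrame(
        {
            "median": reps.median(),
            "ci_lo": reps.quantile(0.025),
            "ci_hi": reps.quantile(0.975),
        }
    )
    result = BootstrapResult(summary, n_replicates, n_failed, reps)
    if not result.reliable:
        logger.warning("bootstrap unreliable: %d/%d replicates failed", n_failed, n_replicates)
    return result


def gof_tables(
    model: PopulationModel,
    ds: Dataset,
    config: FitConfig | None = None,
) -> pd.DataFrame:
    """Observed-vs-predicted and residual table for goodness-of-fit plots.

    One row per observation: ID, TIME, DV, PRED (population), IPRED
    (conditional-mode), IWRES and CWRES.
    """
    obs = ds.observations()
    ebes = ebe_estimate(model, ds, config)
    pred = predictions(model, ds, config=config)
    ipred = predictions(model, ds, etas=ebes, config=config)
    iwres = (np.log(obs["DV"].to_numpy(float)) - np.log(np.maximum(ipred, 1e-12))) / model.sigma
    return pd.DataFrame(
        {
            "ID": obs["ID"].to_numpy(),
            "TIME": obs["TIME"].to_numpy(float),
            "DV": obs["DV"].to_numpy(float),
            "PRED": pred,
            "IPRED": ipred,
            "IWRES": iwres,
            "CWRES": cwres(model, ds, config),
        }
    )
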