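"""Stepwise covariate modelling: EBE-based screening, forward inclusion and
backward elimination.

Screening regresses each subject-level random effect (ETA) on the log of the
candidate covariate relative to its median (the covariate enters the model
log-linearly, so the screening regression matches the model form), or runs a
one-way ANOVA across the levels of categorical candidates.  Candidates that
screen in at p < 0.05 go to the stepwise search: forward inclusion adds, at
each step, the candidate with the largest drop in objective function among
those significant at p < 0.01 (chi-squared on the added degrees of freedom);
backward elimination then removes effects whose deletion raises the
objective by less than 10.83 (p < 0.001, 1 df).  Ties in the forward step
break toward fewer added parameters, then lexicographic effect name.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import Dataset
from .estimation import FitConfig, FitResult, fit, lrt
from .population import CovariateEffect, PopulationModel

__all__ = [
    "screen",
    "forward_include",
    "backward_eliminate",
    "weight_base_model_step",
    "SearchStep",
    "SearchTrace",
    "FORWARD_ALPHA",
    "BACKWARD_THRESHOLD",
]

logger = logging.getLogger(__name__)

FORWARD_ALPHA = 0.01
BACKWARD_THRESHOLD = 10.83  # delta-OFV for retention, p < 0.001 at 1 df
SHRINKAGE_WARN = 30.0  # percent; EBE-based screening degrades above this


def screen(
    result: FitResult,
    ds: Dataset,
    parameters: Sequence[str] = ("CL", "Vc"),
    covariates: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test each (parameter, covariate) pair on the EBEs of ``result``.

    Returns a DataFrame sorted by p-value with columns parameter, covariate,
    test, p_value, direction, significant.  Constant covariates are skipped.
    """
    for p in parameters:
        shr = result.eta_shrinkage.get(p)
        if shr is not None and shr > SHRINKAGE_WARN:
            logger.warning(
                "eta shrinkage for %s is %.1f%% (> %.0f%%); EBE-based screening "
                "may be unreliable",
                p, shr, SHRINKAGE_WARN,
            )
    covs = ds.covariates_frame().loc[result.ebes.index]
    names = list(covariates) if covariates is not None else list(covs.columns)
    rows = []
    for param in parameters:
        if param not in result.ebes.columns:
            continue
        eta = result.ebes[param].to_numpy(float)
        for name in names:
            if name not in covs.columns:
                continue
            col = covs[name]
            if col.nunique(dropna=True) < 2:
                logger.info("covariate %s constant across subjects; skipped", name)
                continue
            if pd.api.types.is_numeric_dtype(col):
                x = np.log(col.to_numpy(float) / float(col.median()))
                ok = np.isfinite(x)
                reg = stats.linregress(x[ok], eta[ok])
                rows.append(
                    dict(
                        parameter=param,
                        covariate=name,
                        test="regression",
                        p_value=float(reg.pvalue),
                        direction=float(np.sign(reg.slope)),
                    )
                )
            else:
                groups = [eta[(col == lv).to_numpy()] for lv in col.dropna().unique()]
                groups = [g for g in groups if len(g) >= 2]
                if len(groups) < 2:
                    continue
                f_stat, p = stats.f_oneway(*groups)
                means = [float(np.mean(g)) for g in groups]
                rows.append(
                    dict(
                        parameter=param,
                        covariate=name,
                        test="anova",
                        p_value=float(p),
                        direction=float(np.sign(means[-1] - means[0])),
                    )
                )
    out = pd.DataFrame(rows, columns=["parameter", "covariate", "test", "p_value", "direction"])
    out["significant"] = out["p_value"] < alpha
    return out.sort_values("p_value", ignore_index=True)


@dataclass(frozen=True)
class SearchStep:
    action: str  # "add" | "remove"
    effect: str  # "COV->PARAM" name
    dofv: float
    df: int
    p_value: float
    accepted: bool


@dataclass
class SearchTrace:
    steps: list[SearchStep] = field(default_factory=list)
    final: PopulationModel | None = None
    final_fit: FitResult | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps])

    @property
    def accepted_effects(self) -> list[str]:
        return [s.effect for s in self.steps if s.accepted and s.action == "add"]


def _fit_or_none(model, ds, config) -> FitResult | None:
    try:
        return fit(model, ds, config)
    except Exception as err:  # candidate fits may fail; skip, do not abort
        logger.warning("candidate fit failed: %s", err)
        return None


def forward_include(
    base: PopulationModel,
    candidates: Sequence[CovariateEffect],
    ds: Dataset,
    alpha: float = FORWARD_ALPHA,
    config: FitConfig | None = None,
    base_fit: FitResult | None = None,
) -> SearchTrace:
    """Stepwise forward addition of covariate effects.

    Each remaining candidate is added to the current model one at a time and
    refitted; the candidate with the largest drop in OFV among those with
    p < ``alpha`` is kept.  Stops when no candidate qualifies.
    """
    config = config or FitConfig()
    trace = SearchTrace()
    current_fit = base_fit if base_fit is not None else fit(base, ds, config)
    current = current_fit.estimates
    remaining = list(candidates)
    while remaining:
        results = []
        for cand in remaining:
            cand_fit = _fit_or_none(current.with_effect(cand), ds, config)
            if cand_fit is None:
                continue
            dofv = current_fit.ofv - cand_fit.ofv
            p = lrt(current_fit.ofv, cand_fit.ofv, df=1)
            results.append((cand, cand_fit, dofv, p))
        if not results:
            break
        # largest dOFV wins; ties by fewer parameters (all 1 here) then name
        results.sort(key=lambda r: (-r[2], r[0].name))
        best, best_fit, best_dofv, best_p = results[0]
        for cand, _, dofv, p in results[1:]:
            trace.steps.append(SearchStep("add", cand.name, dofv, 1, p, False))
        accepted = best_p < alpha
        trace.steps.append(SearchStep("add", best.name, best_dofv, 1, best_p, accepted))
        if not accepted:
            break
        current_fit = best_fit
        current = best_fit.estimates
        remaining = [c for c in remaining if c.name != best.name]
    trace.final = current
    trace.final_fit = current_fit
    return trace


def backward_eliminate(
    full: PopulationModel,
    ds: Dataset,
    threshold: float = BACKWARD_THRESHOLD,
    effects: Sequence[str] | None = None,
    config: FitConfig | None = None,
    full_fit: FitResult | None = None,
) -> SearchTrace:
    """Stepwise backward deletion.

    At each step the effect whose removal raises the OFV the least is
    removed, provided that rise is below ``threshold`` (default 10.83,
    p < 0.001 on 1 df); effects whose removal costs more are retained.
    ``effects`` restricts which effect names are eligible for removal.
    """
    config = config or FitConfig()
    trace = SearchTrace()
    current_fit = full_fit if full_fit is not None else fit(full, ds, config)
    current = current_fit.estimates
    removable = list(effects) if effects is not None else [e.name for e in current.covariate_effects]
    while removable:
        results = []
        for name in removable:
            red_fit = _fit_or_none(current.without_effect(name), ds, config)
            if red_fit is None:
                continue
            rise = red_fit.ofv - current_fit.ofv
            p = lrt(red_fit.ofv, current_fit.ofv, df=1)
            results.append((name, red_fit, rise, p))
        if not results:
            break
        results.sort(key=lambda r: (r[2], r[0]))
        name, red_fit, rise, p = results[0]
        remove = rise < threshold
        trace.steps.append(SearchStep("remove", name, rise, 1, p, remove))
        if not remove:
            break
        current_fit = red_fit
        current = red_fit.estimates
        removable = [n for n in removable if n != name]
    trace.final = current
    trace.final_fit = current_fit
    return trace


def weight_base_model_step(
    base: PopulationModel,
    ds: Dataset,
    config: FitConfig | None = None,
    reference_weight: float = 64.0,
    alpha: float = 0.01,
) -> SearchTrace:
    """Body-weight step of base-model development.

    Tests weight on CL, Vc, Q and Vp jointly against the no-weight base
    model (4 df), then prunes weight from Q and Vp if removing both changes
    the OFV non-significantly at ``alpha`` (2 df, chi-squared threshold 9.21
    at p = 0.01).
    """
    config = config or FitConfig()
    trace = SearchTrace()
    fit0 = fit(base, ds, config)
    with_wt = base
    for param, start in (("CL", 0.75), ("Vc", 0.5), ("Q", 0.5), ("Vp", 0.5)):
        with_wt = with_wt.with_effect(
            CovariateEffect(param, "WT", start, "power", reference=reference_weight)
        )
    fit_all = fit(with_wt, ds, config)
    dofv = fit0.ofv - fit_all.ofv
    p_all = lrt(fit0.ofv, fit_all.ofv, df=4)
    add_ok = p_all < alpha
    trace.steps.append(SearchStep("add", "WT->{CL,Vc,Q,Vp}", dofv, 4, p_all, add_ok))
    if not add_ok:
        trace.final, trace.final_fit = fit0.estimates, fit0
        return trace
    pruned_model = fit_all.estimates.without_effect("WT->Q").without_effect("WT->Vp")
    fit_pruned = fit(pruned_model, ds, config)
    rise = fit_pruned.ofv - fit_all.ofv
    p_prune = lrt(fit_pruned.ofv, fit_all.ofv, df=2)
    prune_ok = p_prune >= alpha  # non-significant loss: keep the leaner model
    trace.steps.append(SearchStep("remove", "WT->{Q,Vp}", rise, 2, p_prune, prune_ok))
    if prune_ok:
        trace.final, trace.final_fit = fit_pruned.estimates, fit_pruned
    else:
        trace.final, trace.final_fit = fit_all.estimates, fit_all
    return trace
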