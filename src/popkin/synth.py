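"""Synthetic trial data: virtual populations and simulated PK datasets.

The generator emulates the pooled three-trial dataset the analysis was built
for: 173 patients, ~9 serum samples each (1557 scheduled), IV infusions of
0.3-15 mg/kg every two weeks with an optional additional 7.5 mg/kg dose on
day 8 (combination-therapy design), covariates drawn to match the published
baseline table (median weight 63.9 kg, albumin 38 g/L, 65.3% male, 50.9%
combination therapy, ...), log-normal interindividual variability, log-scale
additive residual error, and an assay LLOQ of 0.125 ug/mL.

Continuous covariates are drawn from truncated log-normals (weight, lab
values; right-skew typical of labs) or truncated normals (albumin, age),
centred on the published medians and truncated to the published ranges.
Covariates are independent by default; an optional knob couples weight and
sex (males heavier), which matters when exercising covariate screening under
confounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import Dataset
from .population import CovariateRecord, PopulationModel, final_model, sample_etas
from .structural import DEFAULT_INFUSION_DAYS, Regimen, solve_profile
from . import population as _pop

__all__ = [
    "ContinuousSpec",
    "PopulationSpec",
    "DesignSpec",
    "Preset",
    "generate_population",
    "generate_dataset",
    "scenario_presets",
    "simulate_preset",
    "DEFAULT_LLOQ",
]

DEFAULT_LLOQ = 0.125  # ug/mL


@dataclass(frozen=True)
class ContinuousSpec:
    """Truncated marginal for one continuous covariate."""

    median: float
    lower: float
    upper: float
    kind: str = "lognormal"  # or "normal"
    spread: float = 0.35  # ln-SD (lognormal) or SD (normal)

    def __post_init__(self) -> None:
        if not (self.lower < self.median < self.upper):
            raise ValueError("need lower < median < upper")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(n)
        todo = np.arange(n)
        while todo.size:
            if self.kind == "lognormal":
                x = np.exp(rng.normal(math.log(self.median), self.spread, todo.size))
            elif self.kind == "normal":
                x = rng.normal(self.median, self.spread, todo.size)
            else:
                raise ValueError(f"unknown marginal kind {self.kind!r}")
            ok = (x >= self.lower) & (x <= self.upper)
            out[todo[ok]] = x[ok]
            todo = todo[~ok]
        return out


#: marginals matching the pooled baseline covariate table (median [min, max])
DEFAULT_CONTINUOUS: dict[str, ContinuousSpec] = {
    "WT": ContinuousSpec(63.9, 35.5, 148.0, "lognormal", 0.20),
    "ALB": ContinuousSpec(38.0, 19.0, 50.2, "normal", 5.0),
    "AGE": ContinuousSpec(60.0, 23.0, 86.0, "normal", 11.0),
    "ALP": ContinuousSpec(103.0, 32.0, 1255.0, "lognormal", 0.55),
    "AST": ContinuousSpec(22.0, 7.0, 113.0, "lognormal", 0.45),
    "ALT": ContinuousSpec(17.0, 5.0, 128.0, "lognormal", 0.50),
    "TBIL": ContinuousSpec(8.04, 1.71, 34.2, "lognormal", 0.45),
    "EGFR": ContinuousSpec(95.1, 29.1, 145.0, "normal", 20.0),
    "LDH": ContinuousSpec(215.0, 91.0, 1041.0, "lognormal", 0.40),
    "TPROT": ContinuousSpec(69.0, 43.0, 93.0, "normal", 7.0),
}

DEFAULT_CATEGORICAL: dict[str, dict[str, float]] = {
    "SEX": {"M": 0.653, "F": 0.347},
    "THERAPY": {"mono": 0.491, "combo": 0.509},
    "RACE": {"White": 0.405, "Asian": 0.561, "Other": 0.034},
    "REGION": {"UEA": 0.451, "CN": 0.081, "ROA": 0.468},
    "ECOG": {"0": 0.324, "ge1": 0.676},
    "TUMTYPE": {"GC": 0.688, "GEJ": 0.093, "Other": 0.219},
    "GASTREC": {"no": 0.72, "yes": 0.28},
    "PRIORFOLFOX": {"no": 0.798, "yes": 0.202},
    "FGFR2B": {"lt10": 0.179, "ge10": 0.254, "missing": 0.567},
}


@dataclass(frozen=True)
class PopulationSpec:
    """Virtual population: size and covariate marginals."""

    n_subjects: int = 173
    continuous: Mapping[str, ContinuousSpec] = field(
        default_factory=lambda: dict(DEFAULT_CONTINUOUS)
    )
    categorical: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORICAL)
    )
    couple_weight_sex: bool = False
    #: force exact level counts, e.g. {"THERAPY": {"mono": 85, "combo": 88}}
    exact_counts: Mapping[str, Mapping[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, probs in self.categorical.items():
            if abs(sum(probs.values()) - 1.0) > 1e-6:
                raise ValueError(f"probabilities for {name} must sum to 1")
        for name, counts in self.exact_counts.items():
            if sum(counts.values()) != self.n_subjects:
                raise ValueError(f"exact counts for {name} must sum to n_subjects")


def generate_population(
    spec: PopulationSpec, seed: int | np.random.Generator
) -> list[CovariateRecord]:
    """Draw a virtual population; reproducible under ``seed``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = spec.n_subjects
    cols: dict[str, np.ndarray] = {}
    for name, cspec in spec.continuous.items():
        cols[name] = cspec.draw(n, rng)
    for name, probs in spec.categorical.items():
        levels = list(probs)
        if name in spec.exact_counts:
            seq = [lv for lv, k in spec.exact_counts[name].items() for _ in range(k)]
            cols[name] = np.array(seq, dtype=object)[rng.permutation(n)]
        else:
            cols[name] = rng.choice(levels, size=n, p=[probs[lv] for lv in levels])
    if spec.couple_weight_sex and "WT" in cols and "SEX" in cols:
        # shift log-weight by +/- 6% keeping the overall median roughly fixed
        shift = np.where(cols["SEX"] == "M", 1.04, 0.93)
        cols["WT"] = np.clip(cols["WT"] * shift, spec.continuous["WT"].lower,
                             spec.continuous["WT"].upper)

    records = []
    for i in range(n):
        extra = {
            k: (float(v[i]) if np.asarray(v).dtype.kind == "f" else str(v[i]))
            for k, v in cols.items()
            if k not in ("WT", "ALB", "SEX", "THERAPY")
        }
        records.append(
            CovariateRecord(
                wt=float(cols["WT"][i]),
                alb=float(cols["ALB"][i]) if "ALB" in cols else 38.0,
                sex=str(cols["SEX"][i]) if "SEX" in cols else "M",
                therapy=str(cols["THERAPY"][i]) if "THERAPY" in cols else "mono",
                extra=extra,
            )
        )
    return records


#: cycle-1 rich sampling plus pre-dose troughs at cycles 2, 3, 5 and 9 — nine
#: samples per subject (1557 for 173 subjects, matching the study's ~1552).
DEFAULT_SAMPLE_TIMES = (
    DEFAULT_INFUSION_DAYS,  # end of first infusion
    4.0 / 24.0,
    1.0,
    2.0,
    7.0,
    14.0,  # pre-dose troughs from here on
    28.0,
    56.0,
    112.0,
)


@dataclass(frozen=True)
class DesignSpec:
    """Dosing and sampling design for one arm."""

    dose_mg_per_kg: float = 15.0
    day8_dose_mg_per_kg: float | None = None  # extra cycle-1 day-8 dose
    n_cycles: int = 9  # Q2W doses at days 0, 14, ..., 14*(n_cycles-1)
    infusion_days: float = DEFAULT_INFUSION_DAYS
    sample_times: tuple[float, ...] = DEFAULT_SAMPLE_TIMES
    lloq: float = DEFAULT_LLOQ

    def __post_init__(self) -> None:
        if self.dose_mg_per_kg <= 0 or self.n_cycles < 1:
            raise ValueError("need a positive dose and at least one cycle")
        if any(t < 0 for t in self.sample_times):
            raise ValueError("sampling times must be non-negative")

    def dose_events(self, weight: float) -> list[tuple[float, float, float]]:
        """(time, amount mg, duration) tuples for a subject of given weight."""
        events = [
            (14.0 * c, self.dose_mg_per_kg * weight, self.infusion_days)
            for c in range(self.n_cycles)
        ]
        if self.day8_dose_mg_per_kg:
            events.append((8.0, self.day8_dose_mg_per_kg * weight, self.infusion_days))
        return sorted(events)

    def regimen(self, weight: float) -> Regimen:
        ev = self.dose_events(weight)
        return Regimen.from_arrays([e[0] for e in ev], [e[1] for e in ev], [e[2] for e in ev])


def generate_dataset(
    population: Sequence[CovariateRecord],
    design: DesignSpec | Sequence[DesignSpec],
    model: PopulationModel,
    seed: int | np.random.Generator,
    *,
    method: str = "auto",
    plant_blq: int = 0,
    plant_outliers: int = 0,
    outlier_magnitude: float = 10.0,
) -> Dataset:
    """Simulate an event-record dataset for ``population`` under ``model``.

    ``design`` may be shared or per-subject.  ``method`` follows
    :func:`popkin.structural.solve_profile` ("auto" integrates the full
    system including the saturable pathway; "analytic" uses the linear
    closed form, which for the fitted model differs by < 0.3%).

    ``plant_blq`` forces that many observations below the LLOQ (placed at the
    latest samples of the lowest-dose subjects); ``plant_outliers`` multiplies
    that many randomly chosen observations by exp(+/- outlier_magnitude *
    sigma).  The returned dataset still contains the BLQ rows — censoring is
    the caller's step (``apply_lloq_filter``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(population)
    designs = list(design) if isinstance(design, (list, tuple)) else [design] * n
    if len(designs) != n:
        raise ValueError("need one design per subject")

    etas = sample_etas(model.omega, n, rng)
    rows: list[dict] = []
    obs_refs: list[tuple[int, float]] = []  # (row index, dose level) for planting
    for i, (cov, des) in enumerate(zip(population, designs)):
        sid = f"S{i + 1:03d}"
        eta = etas.iloc[i].to_dict()
        params = _pop.individual_params(model, cov, eta)
        if method == "analytic":
            params = replace(params, Vmax=0.0)
        reg = des.regimen(cov.wt)
        t_obs = np.asarray(des.sample_times, dtype=float)
        profile = solve_profile(params, reg, t_obs, method="analytic" if method == "analytic" else "auto")
        pred = np.maximum(profile.concentrations, 1e-12)
        dv = pred * np.exp(rng.normal(0.0, model.sigma, size=pred.shape))

        cov_cols = {
            "WT": cov.wt,
            "ALB": cov.alb,
            "SEX": cov.sex,
            "THERAPY": cov.therapy,
            **{k: v for k, v in cov.extra.items()},
        }
        events: list[dict] = []
        for t, amt, dur in des.dose_events(cov.wt):
            events.append(
                dict(ID=sid, TIME=t, EVID=1, AMT=amt, DUR=dur, DV=np.nan, MDV=1, **cov_cols)
            )
        for t, y in zip(t_obs, dv):
            events.append(
                dict(ID=sid, TIME=t, EVID=0, AMT=0.0, DUR=0.0, DV=y, MDV=0, **cov_cols)
            )
        # stable within-subject order: time ascending, observations before the
        # dose given at the same instant (pre-dose troughs)
        events.sort(key=lambda r: (r["TIME"], r["EVID"]))
        for ev in events:
            if ev["EVID"] == 0:
                obs_refs.append((len(rows), des.dose_mg_per_kg))
            rows.append(ev)

    frame = pd.DataFrame(rows)
    if plant_blq:
        # latest observations of the lowest-dose subjects fall below the LLOQ
        lloq = designs[0].lloq
        order = sorted(obs_refs, key=lambda r: (r[1], -frame.loc[r[0], "TIME"]))
        for idx, _ in order[:plant_blq]:
            frame.loc[idx, "DV"] = 0.8 * lloq
    if plant_outliers:
        pick = rng.choice(len(obs_refs), size=plant_outliers, replace=False)
        signs = rng.choice([-1.0, 1.0], size=plant_outliers)
        for j, s in zip(pick, signs):
            idx = obs_refs[int(j)][0]
            frame.loc[idx, "DV"] *= math.exp(s * outlier_magnitude * model.sigma)
    return Dataset(frame)


# --------------------------------------------------------------------------
# Named scenario presets
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Preset:
    name: str
    population: PopulationSpec
    #: (dose mg/kg, day-8 dose or None, weight) -> DesignSpec per subject
    model: PopulationModel
    mono_dose_levels: tuple[tuple[float, int], ...]  # (mg/kg, n subjects)
    plant_blq: int = 0

    def designs_for(self, population: Sequence[CovariateRecord]) -> list[DesignSpec]:
        mono_pool = [lvl for lvl, k in self.mono_dose_levels for _ in range(k)]
        designs, j = [], 0
        for cov in population:
            if cov.therapy == "combo":
                designs.append(DesignSpec(15.0, day8_dose_mg_per_kg=7.5))
            else:
                lvl = mono_pool[j % len(mono_pool)] if mono_pool else 15.0
                j += 1
                designs.append(DesignSpec(lvl))
        return designs


def scenario_presets() -> dict[str, Preset]:
    """Named population/design/model bundles emulating the source trials."""
    final = final_model()
    pooled_pop = PopulationSpec(
        n_subjects=173,
        exact_counts={"THERAPY": {"mono": 85, "combo": 88}},
    )
    escalation = ((0.3, 6), (1.0, 6), (3.0, 10), (6.0, 10), (10.0, 10), (15.0, 43))
    mono_pop = PopulationSpec(
        n_subjects=79,
        categorical={**DEFAULT_CATEGORICAL, "THERAPY": {"mono": 1.0}},
    )
    combo_pop = PopulationSpec(
        n_subjects=88,
        categorical={**DEFAULT_CATEGORICAL, "THERAPY": {"combo": 1.0}},
    )
    return {
        "pooled-study-like": Preset(
            "pooled-study-like", pooled_pop, final, escalation, plant_blq=19
        ),
        "fpa144-001-like": Preset("fpa144-001-like", mono_pop, final, escalation),
        "fight-like": Preset("fight-like", combo_pop, final, ()),
    }


def simulate_preset(
    name: str,
    seed: int | np.random.Generator,
    *,
    n_subjects: int | None = None,
    method: str = "auto",
    plant_blq: int | None = None,
    plant_outliers: int = 0,
) -> Dataset:
    """Generate a full synthetic dataset from a named preset."""
    presets = scenario_presets()
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; have {sorted(presets)}")
    preset = presets[name]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pop_spec = preset.population
    if n_subjects is not None and n_subjects != pop_spec.n_subjects:
        exact = {
            name_: _rescale_counts(counts, n_subjects)
            for name_, counts in pop_spec.exact_counts.items()
        }
        pop_spec = replace(pop_spec, n_subjects=n_subjects, exact_counts=exact)
    population = generate_population(pop_spec, rng)
    designs = preset.designs_for(population)
    blq = preset.plant_blq if plant_blq is None else plant_blq
    if n_subjects is not None and plant_blq is None:
        blq = round(blq * n_subjects / preset.population.n_subjects)
    return generate_dataset(
        population,
        designs,
        preset.model,
        rng,
        method=method,
        plant_blq=blq,
        plant_outliers=plant_outliers,
    )


def _rescale_counts(counts: Mapping[str, int], n: int) -> dict[str, int]:
    total = sum(counts.values())
    scaled = {k: int(round(v * n / total)) for k, v in counts.items()}
    drift = n - sum(scaled.values())
    first = next(iter(scaled))
    scaled[first] += drift
    return scaled
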