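"""Synthetic SCAR16 cohort and biochemistry generator.

Emulates the statistical structure of the real tables — categorical trait
frequencies, biochemical variable locations/scales, and linear effect
structures inducing SARA and age of onset — so every downstream stage can
be exercised with known ground truth.  It makes no attempt at mutation
nomenclature realism beyond the packaged domain map, and none at modelling
nonsense-mediated decay; stop-codon partner alleles are included only so
per-allele expansion has something to drop.

Physical bounds are enforced by clipping (not conditional resampling),
which slightly biases means upward when the bound is within a couple of
SDs of the mean; the documented default K_D (mean 7.8, SD 6.0) carries a
clip bias of about +0.3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    BiochemRecord,
    PatientRecord,
    load_domain_map,
)
from .equations import CategoricalTerm, LinearEquation
from .models import reference_sara_clinical_equation

__all__ = ["GeneratorParams", "generate_cohort", "generate_from_equation"]

_STOP_ALLELES = ("K144*", "Y207*", "E238*", "Y230Cfx*8")


def _default_categorical_freqs() -> dict[str, dict[str, float]]:
    return {
        "sex": {"male": 0.54, "female": 0.46},
        "ancestry": {"AMR": 0.04, "SAS": 0.04, "MENA": 0.25, "EUR": 0.33, "EAS": 0.33},
        "homozygous": {"Y": 0.46, "N": 0.54},
        "tr": {"Y": 0.75, "N": 0.25},
        "hypogonadism": {"Y": 0.17, "N": 0.83},
    }


def _default_biochem_means() -> dict[str, float]:
    return {"pct_hsp70_ub": 43.7, "pct_chain": 69.9, "kd": 7.8, "bmax": 212.0,
            "tm": 45.0, "pct_e": 55.0}


def _default_biochem_sds() -> dict[str, float]:
    return {"pct_hsp70_ub": 15.5, "pct_chain": 39.0, "kd": 6.0, "bmax": 16.6,
            "tm": 4.0, "pct_e": 20.0}


def _default_aoo_equation() -> LinearEquation:
    # homozygous mutations present ~12 years earlier; cohort-level mean ~17.5 y
    return LinearEquation(
        response="aoo",
        intercept=17.0,
        categorical=[CategoricalTerm("homozygous", {"Y": -6.0, "N": 6.0})],
    )


def _default_effect_model() -> dict[str, LinearEquation]:
    return {"sara": reference_sara_clinical_equation(), "aoo": _default_aoo_equation()}


@dataclass
class GeneratorParams:
    """Tunable study conditions for the synthetic cohort.

    Defaults reproduce the documented cohort: trait frequencies, the
    biochemical locations/scales used to standardize the severity models,
    a 94% cognitive-dysfunction rate among Ubox-allele carriers versus 59%
    otherwise, and domain draw weights chosen so the implied overall CD
    frequency is ~71%.  Residual noise SDs are free parameters of the
    generator (no empirical value exists for them).
    """

    n_patients: int = 24
    categorical_freqs: dict[str, dict[str, float]] = field(
        default_factory=_default_categorical_freqs
    )
    biochem_means: dict[str, float] = field(default_factory=_default_biochem_means)
    biochem_sds: dict[str, float] = field(default_factory=_default_biochem_sds)
    effect_model: dict[str, LinearEquation] = field(default_factory=_default_effect_model)
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"sara": 6.0, "aoo": 8.0}
    )
    ubox_cd_prob: float = 0.94
    other_cd_prob: float = 0.59
    domain_weights: dict[str, float] = field(
        default_factory=lambda: {"TPR": 0.40, "CC": 0.30, "Ubox": 0.30}
    )
    stop_allele_prob: float = 0.60
    ubox_chain_mean: float = 25.0
    mutation_pool: dict[str, str] | None = None  # mutation -> domain; default: resource map
    seed: int | None = None

    def __post_init__(self):
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        for var, freqs in self.categorical_freqs.items():
            for level, p in freqs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{var}[{level}]: probability {p} outside [0, 1]")
        for prob in (self.ubox_cd_prob, self.other_cd_prob, self.stop_allele_prob):
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"probability {prob} outside [0, 1]")
        for name, sd in {**self.biochem_sds, **self.noise_sd}.items():
            if sd < 0:
                raise ValueError(f"sd for {name!r} must be >= 0")
        if not self.effect_model:
            raise ValueError("effect_model must define at least one response")

    @classmethod
    def null(cls, **overrides) -> "GeneratorParams":
        """Params with all effect sizes zeroed (intercept-only responses).

        Under these conditions every phenotype is independent of every
        predictor, giving a clean type-I-error testbed.
        """
        model = {
            "sara": LinearEquation("sara", 18.0),
            "aoo": LinearEquation("aoo", 17.0),
        }
        params = cls(effect_model=model, ubox_cd_prob=0.71, other_cd_prob=0.71)
        return replace(params, **overrides) if overrides else params


def _draw_level(rng: np.random.Generator, freqs: Mapping[str, float]) -> str:
    levels = sorted(freqs)
    probs = np.array([freqs[l] for l in levels], dtype=float)
    probs = probs / probs.sum()
    return str(rng.choice(levels, p=probs))


def _draw_mutation(rng, by_domain: Mapping[str, Sequence[str]], weights) -> tuple[str, str]:
    domains = sorted(by_domain)
    w = np.array([weights.get(d, 0.0) for d in domains], dtype=float)
    if w.sum() <= 0:
        raise ValueError("domain_weights sum to zero over available domains")
    dom = str(rng.choice(domains, p=w / w.sum()))
    muts = sorted(by_domain[dom])
    return str(rng.choice(muts)), dom


def generate_cohort(
    params: GeneratorParams, seed: int | None = None
) -> tuple[list[PatientRecord], list[BiochemRecord]]:
    """Draw a patient cohort and matching mutant biochemistry table.

    The same seed and params give identical output.  SARA is the clinical
    effect model's prediction plus Gaussian noise clamped to [0, 40]; AOO
    likewise, clamped positive.  Biochemical variables are Gaussian with
    the configured location/scale, clipped at 0; %chain formation gets a
    domain effect (Ubox deficit) that preserves the marginal mean.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    pool = params.mutation_pool or load_domain_map()
    by_domain: dict[str, list[str]] = {}
    for mut, dom in pool.items():
        by_domain.setdefault(dom, []).append(mut)

    biochem = _generate_biochem(rng, params, pool)

    sara_eq = params.effect_model.get("sara")
    aoo_eq = params.effect_model.get("aoo")
    patients: list[PatientRecord] = []
    for i in range(params.n_patients):
        sex = _draw_level(rng, params.categorical_freqs["sex"])
        ancestry = _draw_level(rng, params.categorical_freqs["ancestry"])
        homozygous = _draw_level(rng, params.categorical_freqs["homozygous"]) == "Y"
        tr = _draw_level(rng, params.categorical_freqs["tr"])
        hypogonadism = _draw_level(rng, params.categorical_freqs["hypogonadism"])

        allele1, dom1 = _draw_mutation(rng, by_domain, params.domain_weights)
        if homozygous:
            allele2, dom2 = allele1, dom1
        elif rng.random() < params.stop_allele_prob:
            allele2, dom2 = str(rng.choice(_STOP_ALLELES)), None
        else:
            allele2, dom2 = _draw_mutation(rng, by_domain, params.domain_weights)

        has_ubox = dom1 == "Ubox" or dom2 == "Ubox"
        cd_p = params.ubox_cd_prob if has_ubox else params.other_cd_prob
        cd = "Y" if rng.random() < cd_p else "N"

        row = {
            "sex": sex,
            "ancestry": ancestry,
            "homozygous": "Y" if homozygous else "N",
            "cd": cd,
            "tr": tr,
            "hypogonadism": hypogonadism,
        }
        sara = float(np.clip(
            sara_eq.evaluate(row) + rng.normal(0.0, params.noise_sd.get("sara", 0.0)),
            0.0, 40.0,
        )) if sara_eq is not None else 0.0
        aoo = float(max(
            aoo_eq.evaluate(row) + rng.normal(0.0, params.noise_sd.get("aoo", 0.0)),
            0.5,
        )) if aoo_eq is not None else 1.0

        patients.append(
            PatientRecord(
                patient_id=f"P{i + 1:04d}",
                sex=sex,
                ancestry=ancestry,
                homozygous=homozygous,
                allele1=allele1,
                allele2=allele2,
                aoo=round(aoo, 2),
                sara=round(sara, 2),
                cd=cd,
                tr=tr,
                hypogonadism=hypogonadism,
            )
        )
    return patients, biochem


def _generate_biochem(
    rng: np.random.Generator, params: GeneratorParams, pool: Mapping[str, str]
) -> list[BiochemRecord]:
    means, sds = params.biochem_means, params.biochem_sds
    n_ubox = sum(1 for d in pool.values() if d == "Ubox")
    n_other = len(pool) - n_ubox
    # Ubox chain deficit with the marginal mean preserved
    if n_other and n_ubox:
        other_chain_mean = (
            means["pct_chain"] * len(pool) - params.ubox_chain_mean * n_ubox
        ) / n_other
    else:
        other_chain_mean = means["pct_chain"]

    records = []
    for mut in sorted(pool):
        dom = pool[mut]
        chain_mean = params.ubox_chain_mean if dom == "Ubox" else other_chain_mean
        kd = max(float(rng.normal(means["kd"], sds["kd"])), 0.05)
        bmax = max(float(rng.normal(means["bmax"], sds["bmax"])), 0.0)
        hsp = max(float(rng.normal(means["pct_hsp70_ub"], sds["pct_hsp70_ub"])), 0.0)
        chain = max(float(rng.normal(chain_mean, sds["pct_chain"])), 0.0)
        tm = float(np.clip(rng.normal(means["tm"], sds["tm"]), 20.0, 100.0))
        pct_e = max(float(rng.normal(means["pct_e"], sds["pct_e"])), 0.0)
        higher_p = 0.8 if dom == "Ubox" else 0.25
        oligomer = "higher_order" if rng.random() < higher_p else "dimer"
        records.append(
            BiochemRecord(
                mutation=mut, domain=dom,
                kd=round(kd, 3), bmax=round(bmax, 1),
                pct_hsp70_ub=round(hsp, 1), pct_chain=round(chain, 1),
                tm=round(tm, 1), oligomer=oligomer, pct_e=round(pct_e, 1),
            )
        )
    # wild-type reference row; the domain label is meaningless for WT and
    # analyses stratifying by domain must drop the mutation == "WT" row
    records.append(
        BiochemRecord(
            mutation="WT", domain="TPR",
            kd=2.9, bmax=204.0, pct_hsp70_ub=73.1, pct_chain=100.0,
            tm=53.0, oligomer="dimer", pct_e=100.0,
        )
    )
    return records


def generate_from_equation(
    equation: LinearEquation | Sequence[LinearEquation],
    input_dists: Mapping[str, tuple[float, float] | Mapping[str, float]],
    n: int,
    noise_sd: float | Mapping[str, float] = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Regression dataset drawn from a known linear model.

    ``input_dists`` maps each input to either ``(mean, sd)`` (continuous
    normal) or a level->probability mapping (categorical).  Responses are
    the equation predictions plus ``N(0, noise_sd)``; with ``noise_sd=0``
    they equal the predictions exactly.  Used as the parameter-recovery
    harness for the regression engine.
    """
    equations = [equation] if isinstance(equation, LinearEquation) else list(equation)
    if not equations:
        raise ValueError("at least one equation required")
    rng = np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {}
    for name in sorted(input_dists):
        dist = input_dists[name]
        if isinstance(dist, Mapping):
            levels = sorted(dist)
            probs = np.array([dist[l] for l in levels], dtype=float)
            data[name] = rng.choice(levels, size=n, p=probs / probs.sum())
        else:
            mean, sd = dist
            data[name] = rng.normal(mean, sd, size=n)
    df = pd.DataFrame(data)
    for eq in equations:
        sd = noise_sd.get(eq.response, 0.0) if isinstance(noise_sd, Mapping) else noise_sd
        pred = np.asarray(eq.evaluate(df), dtype=float)
        df[eq.response] = pred + (rng.normal(0.0, sd, size=n) if sd > 0 else 0.0)
    return df
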