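"""Reference reduced PLS models of SCAR16 severity, as published.

Two companion equations predict age of onset (AOO, years) and ataxia
severity (SARA, 0-40 points) from four biochemical properties of mutant
CHIP: %HSP70 ubiquitination, %ubiquitin-chain formation, K_D and B_max.
Each biochemical input enters standardized by the cohort location/scale
printed with the equations.  A third equation predicts SARA from the
clinical factors cognitive dysfunction (CD), ancestry and increased tendon
reflex (TR).

These constants are data, not fits: they are the published coefficient
sets, kept verbatim so simulations and acceptance checks can reproduce the
published operating points.
"""

from __future__ import annotations

from .equations import CategoricalTerm, ContinuousTerm, LinearEquation

__all__ = [
    "BIOCHEM_INPUT_DISTS",
    "WT_BIOCHEM_INPUTS",
    "BASELINE_BIOCHEM_INPUTS",
    "OPTIMIZED_BIOCHEM_INPUTS",
    "AOO_TARGET_OFFSET",
    "SARA_TARGET_OFFSET",
    "reference_aoo_equation",
    "reference_sara_biochem_equation",
    "reference_sara_clinical_equation",
]

#: Cohort mean/SD of each biochemical input (the standardization constants
#: inside the published equations); also the baseline simulation settings.
BIOCHEM_INPUT_DISTS: dict[str, tuple[float, float]] = {
    "pct_hsp70_ub": (43.7, 15.5),
    "pct_chain": (69.9, 39.0),
    "kd": (7.8, 6.0),
    "bmax": (212.0, 16.6),
}

#: Wild-type CHIP reference biochemistry.
WT_BIOCHEM_INPUTS = {"pct_hsp70_ub": 73.1, "pct_chain": 100.0, "kd": 2.9, "bmax": 204.0}

#: Baseline (cohort-mean) settings used for the published simulation.
BASELINE_BIOCHEM_INPUTS = {k: mu for k, (mu, _) in BIOCHEM_INPUT_DISTS.items()}

#: Published desirability-optimized biochemical settings.
OPTIMIZED_BIOCHEM_INPUTS = {"pct_hsp70_ub": 7.2, "pct_chain": 15.0, "kd": 17.0, "bmax": 217.0}

#: Improvement targets: one response SD from the baseline mean
#: (+11 years AOO, -10 SARA points).
AOO_TARGET_OFFSET = 11.0
SARA_TARGET_OFFSET = 10.0


def reference_aoo_equation() -> LinearEquation:
    """AOO (years) as a function of mutant-CHIP biochemistry."""
    return LinearEquation(
        response="aoo",
        intercept=20.6,
        continuous=[
            ContinuousTerm("pct_hsp70_ub", -3.9, 43.7, 15.5),
            ContinuousTerm("pct_chain", 5.3, 69.9, 39.0),
            ContinuousTerm("kd", 4.9, 7.8, 6.0),
            ContinuousTerm("bmax", -7.1, 212.0, 16.6),
        ],
    )


def reference_sara_biochem_equation() -> LinearEquation:
    """SARA (points) as a function of mutant-CHIP biochemistry."""
    return LinearEquation(
        response="sara",
        intercept=18.8,
        continuous=[
            ContinuousTerm("pct_hsp70_ub", 1.9, 43.7, 15.5),
            ContinuousTerm("pct_chain", 0.2, 69.9, 39.0),
            ContinuousTerm("kd", -2.3, 7.8, 6.0),
            ContinuousTerm("bmax", 0.3, 212.0, 16.6),
        ],
    )


def reference_sara_clinical_equation() -> LinearEquation:
    """SARA (points) as a function of CD, ancestry and TR.

    The published ancestry offsets sum to -0.9 rather than 0 (rounding in
    the printed coefficients); they are kept verbatim.
    """
    return LinearEquation(
        response="sara",
        intercept=17.2,
        categorical=[
            CategoricalTerm("cd", {"Y": 5.6, "N": -5.6}),
            CategoricalTerm(
                "ancestry",
                {"EUR": 4.7, "SAS": 0.9, "MENA": -1.4, "AMR": -1.7, "EAS": -3.4},
            ),
            CategoricalTerm("tr", {"Y": 2.7, "N": -2.7}),
        ],
    )
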