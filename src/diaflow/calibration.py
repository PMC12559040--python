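"""Bland-Altman method comparison and bias-adjusted cutoff derivation.

Bias is defined as mean(echo - 4D flow); a negative bias therefore means
the 4D-flow value exceeds the echo value, and the echo cutoff transfers
to the 4D scale by *subtracting* the bias (50 % - (-5) = 55 %,
34 mL/m^2 - (-13) = 47 mL/m^2). Limits of agreement use the classical
1.96-SD multipliers. The zero-bias test is a one-sample t-test when the
paired differences pass Shapiro-Wilk normality at alpha = 0.05, else the
Wilcoxon signed-rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .core import GradingCutoffs, SubjectRecord, default_cutoffs

__all__ = [
    "BlandAltmanResult",
    "bland_altman",
    "bias_adjust_cutoff",
    "calibrate_cutoffs",
    "PAIRED_PARAMETERS",
    "paired_series",
]


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float             # mean(echo - 4D), parameter units
    loa_low: float          # bias - 1.96 * SD of differences
    loa_high: float         # bias + 1.96 * SD of differences
    bias_p: float           # p of the zero-bias test
    normality_p: float      # Shapiro-Wilk p of the differences (nan if degenerate)
    test_used: str          # "t_test" or "wilcoxon"
    r: float                # Pearson correlation of the paired values (nan if undefined)
    n: int


def bland_altman(echo_values: Sequence[float],
                 flow_values: Sequence[float]) -> BlandAltmanResult:
    """Paired method comparison of echo vs 4D-flow values.

    Raises on unequal lengths, n < 3, or missing values; a constant series
    leaves the correlation undefined (returned as NaN).
    """
    echo = np.asarray(echo_values, dtype=float)
    flow = np.asarray(flow_values, dtype=float)
    if echo.shape != flow.shape or echo.ndim != 1:
        raise ValueError("echo and 4D flow series must be 1-D and equal length")
    if echo.size < 3:
        raise ValueError(f"need n >= 3 pairs, got {echo.size}")
    if np.isnan(echo).any() or np.isnan(flow).any():
        raise ValueError("missing values in paired series")

    diff = echo - flow
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd

    if sd == 0.0:
        # Constant difference: normality and signed-rank tests are undefined.
        normality_p = math.nan
        test_used = "t_test"
        bias_p = 1.0 if bias == 0.0 else 0.0
    else:
        normality_p = float(stats.shapiro(diff).pvalue)
        if normality_p >= 0.05:
            test_used = "t_test"
            bias_p = float(stats.ttest_1samp(diff, 0.0).pvalue)
        else:
            test_used = "wilcoxon"
            bias_p = float(stats.wilcoxon(diff).pvalue)

    if echo.std() == 0.0 or flow.std() == 0.0:
        r = math.nan
    else:
        r = float(stats.pearsonr(echo, flow).statistic)
    return BlandAltmanResult(bias=bias, loa_low=loa_low, loa_high=loa_high,
                             bias_p=bias_p, normality_p=normality_p,
                             test_used=test_used, r=r, n=int(echo.size))


def bias_adjust_cutoff(echo_cutoff: float, bias: float) -> float:
    """Transfer an echo-scale cutoff to the 4D-flow scale.

    With bias = mean(echo - 4D), the 4D value equivalent to an echo value x
    is x - bias, so the transferred threshold is echo_cutoff - bias.
    """
    return echo_cutoff - bias


# Paired parameters: name -> (echo column, flow column). Ratios are derived
# from the velocity columns; E/A rows with absent A are dropped pairwise.
PAIRED_PARAMETERS: dict[str, tuple[str, str]] = {
    "ef": ("echo_ef", "flow_ef"),
    "lavi": ("echo_lavi", "flow_lavi"),
    "e": ("echo_e", "flow_e"),
    "e_over_a": ("echo_e_over_a", "flow_e_over_a"),
    "e_prime_septal": ("echo_e_prime_septal", "flow_e_prime_septal"),
    "e_prime_lateral": ("echo_e_prime_lateral", "flow_e_prime_lateral"),
    "e_over_eprime": ("echo_e_over_eprime", "flow_e_over_eprime"),
}

# Which GradingCutoffs fields each paired parameter governs.
_CUTOFF_FIELDS: dict[str, tuple[str, ...]] = {
    "ef": ("ef_low",),
    "lavi": ("lavi_high",),
    "e": ("e_high",),
    "e_over_a": ("ea_low", "ea_high"),
    "e_prime_septal": ("e_prime_septal_low",),
    "e_prime_lateral": ("e_prime_lateral_low",),
    "e_over_eprime": ("e_over_eprime_high",),
}


def paired_series(records: Sequence[SubjectRecord],
                  parameter: str) -> tuple[np.ndarray, np.ndarray]:
    """Extract the paired echo/4D series for one parameter, dropping
    subjects where either side is undefined (e.g. fused E/A)."""
    if parameter not in PAIRED_PARAMETERS:
        raise KeyError(f"unknown paired parameter: {parameter!r}")
    attr = {"ef": "ef", "lavi": "lavi", "e": "e_peak",
            "e_over_a": "e_over_a",
            "e_prime_septal": "e_prime_septal",
            "e_prime_lateral": "e_prime_lateral",
            "e_over_eprime": "e_over_eprime"}[parameter]
    echo, flow = [], []
    for r in records:
        ev, fv = getattr(r.echo, attr), getattr(r.flow4d, attr)
        if ev is not None and fv is not None:
            echo.append(float(ev))
            flow.append(float(fv))
    return np.asarray(echo), np.asarray(flow)


def calibrate_cutoffs(records: Sequence[SubjectRecord],
                      echo_cutoffs: Optional[GradingCutoffs] = None,
                      policy: str | Mapping[str, str] = "default",
                      tvortex_high: float = 15.0,
                      alpha: float = 0.05,
                      ) -> tuple[GradingCutoffs, dict[str, BlandAltmanResult]]:
    """Derive 4D-flow cutoffs from a paired cohort (cutoff-selection rule 1).

    policy: ``"default"`` adjusts the volumetric parameters (EF, LAVI) only
    and keeps every velocity cutoff at its echo value; ``"auto"`` adjusts
    each parameter whose zero-bias test is significant at ``alpha``; or a
    mapping parameter -> {"adjust", "keep"}. The pulmonary-pressure slot of
    the returned 4D cutoffs is ``tvortex_high`` (derived separately by the
    vortex surrogate model; rule 2).

    Returns the 4D GradingCutoffs and the per-parameter Bland-Altman
    results used to derive them.
    """
    if echo_cutoffs is None:
        echo_cutoffs = default_cutoffs("echo")
    if echo_cutoffs.modality != "echo":
        raise ValueError("echo_cutoffs must carry the echo modality tag")

    # Parameters with too few defined pairs (e.g. E/A when A peaks are
    # absent) get no Bland-Altman entry; they can only be kept, not adjusted.
    ba: dict[str, Optional[BlandAltmanResult]] = {}
    for param in PAIRED_PARAMETERS:
        echo_v, flow_v = paired_series(records, param)
        ba[param] = bland_altman(echo_v, flow_v) if len(echo_v) >= 3 else None

    def decide(param: str) -> str:
        if isinstance(policy, str):
            if policy == "default":
                action = "adjust" if param in ("ef", "lavi") else "keep"
            elif policy == "auto":
                action = ("adjust" if ba[param] is not None
                          and ba[param].bias_p < alpha else "keep")
            else:
                raise ValueError(f"unknown policy: {policy!r}")
        else:
            action = policy.get(param, "keep")
        if action == "adjust" and ba[param] is None:
            raise ValueError(
                f"cannot adjust {param!r}: fewer than 3 defined pairs")
        return action

    new_fields: dict[str, float] = {}
    for param, cut_fields in _CUTOFF_FIELDS.items():
        action = decide(param)
        if action not in ("adjust", "keep"):
            raise ValueError(f"policy for {param!r} must be adjust/keep")
        for cf in cut_fields:
            base = getattr(echo_cutoffs, cf)
            new_fields[cf] = (bias_adjust_cutoff(base, ba[param].bias)
                              if action == "adjust" else base)

    flow_cutoffs = GradingCutoffs(modality="flow4d", tr_high=None,
                                  tvortex_high=tvortex_high, **new_fields)
    return flow_cutoffs, ba
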