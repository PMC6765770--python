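"""Spearman rank-correlation sensitivity of the risk output to its inputs.

For each input variable the Spearman rank correlation rho with the output
draws is computed on exactly the draws the simulation retained.  The
"contribution to variance" of a variable is its squared rank correlation
normalised over all variables, expressed in percent and signed by the
direction of the monotone dependence:

    contribution_v = sign(rho_v) * 100 * rho_v**2 / sum_u rho_u**2

This is the convention commercial Monte Carlo packages print on tornado
plots.  Being rank-based, it is invariant to any strictly monotone
transform of either side.

Concentration variables (one per metal) can be pooled into a single
"C_veg" entry by summing their signed contributions, so the tornado
compares ingestion rate, body weight, exposure frequency/duration and the
contaminant concentrations on the footing a reader expects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import InvalidInputError
from .monte_carlo import RiskResult


@dataclass
class SensitivityResult:
    group: str
    rho: dict[str, float]
    contribution_percent: dict[str, float]


def spearman_sensitivity(
    input_draws: Mapping[str, Sequence[float]],
    output_draws: Sequence[float],
    group: str = "",
) -> SensitivityResult:
    """Rank correlation and normalised contribution of each input variable."""
    out = np.asarray(output_draws, dtype=float)
    if out.size < 10:
        raise InvalidInputError("need at least 10 draws for sensitivity analysis")
    if np.ptp(out) == 0:
        raise InvalidInputError("output has no variance")

    rho: dict[str, float] = {}
    for name, draws in input_draws.items():
        arr = np.asarray(draws, dtype=float)
        if arr.size != out.size:
            raise InvalidInputError(
                f"draw length mismatch for {name!r}: {arr.size} vs {out.size}"
            )
        if np.ptp(arr) == 0:
            rho[name] = 0.0  # a constant input cannot drive the output
            continue
        rho[name] = float(stats.spearmanr(arr, out).statistic)

    total = sum(r * r for r in rho.values())
    if total == 0:
        contribution = {name: 0.0 for name in rho}
    else:
        contribution = {
            name: float(np.sign(r)) * 100.0 * r * r / total for name, r in rho.items()
        }
    return SensitivityResult(group=group, rho=rho, contribution_percent=contribution)


def pool_variables(
    result: SensitivityResult, pools: Mapping[str, Sequence[str]]
) -> SensitivityResult:
    """Merge groups of variables (e.g. all C_<metal>) into aggregate entries.

    The pooled contribution is the sum of the members' signed
    contributions; the pooled rho is reported as the signed root of the
    summed squared correlations, consistent with that sum.
    """
    pooled_members = {m for members in pools.values() for m in members}
    rho = {k: v for k, v in result.rho.items() if k not in pooled_members}
    contribution = {
        k: v
        for k, v in result.contribution_percent.items()
        if k not in pooled_members
    }
    for name, members in pools.items():
        present = [m for m in members if m in result.rho]
        if not present:
            continue
        contrib = sum(result.contribution_percent[m] for m in present)
        rho_sq = sum(result.rho[m] ** 2 for m in present)
        contribution[name] = contrib
        rho[name] = float(np.sign(contrib)) * float(np.sqrt(rho_sq))
    return SensitivityResult(
        group=result.group, rho=rho, contribution_percent=contribution
    )


def sensitivity_for_risk(
    risk: RiskResult, group: str, pool_concentrations: bool = True
) -> SensitivityResult:
    """Tornado inputs for one population, computed against its HI draws."""
    inputs = {
        var: draws
        for (g, var), draws in risk.input_draws.items()
        if g == group
    }
    if not inputs:
        raise InvalidInputError(f"no retained input draws for group {group!r}")
    result = spearman_sensitivity(inputs, risk.hi_draws[group], group=group)
    if pool_concentrations:
        conc_vars = [v for v in inputs if v.startswith("C_")]
        result = pool_variables(result, {"C_veg": conc_vars})
    return result


def tornado_table(result: SensitivityResult) -> pd.DataFrame:
    """Variable, rho and contribution %, sorted by |contribution| descending."""
    rows = [
        {
            "variable": name,
            "rho": result.rho[name],
            "contribution_percent": result.contribution_percent[name],
        }
        for name in result.rho
    ]
    frame = pd.DataFrame(rows)
    return frame.reindex(
        frame["contribution_percent"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)
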