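"""Monte Carlo propagation of input distributions to THQ/HI distributions.

Each iteration draws one value of every input variable (vegetable
concentration per metal, IR, BW, EF, ED) per population group, pushes the
draw through the deterministic EDI -> THQ -> HI chain, and retains both the
input and output draws.  Draws are independent across variables (the
assessment assumes weak correlation or independence between inputs) and
across groups; each (group, variable) pair gets its own named random
stream derived from the root seed, so results are reproducible and
insensitive to the iteration order of the variable dictionary.

Percentiles use linear interpolation between adjacent order statistics
(numpy's default); this convention is fixed so published tables are
reproducible to the last digit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ConfigurationError, InvalidInputError, METALS, ToxTable
from .distributions import DistributionSpec, sample, stream_seed

#: Exposure-factor variable names used in the simulation.
EXPOSURE_VARS = ("IR", "BW", "EF", "ED")


def conc_var(metal: str) -> str:
    """Name of the concentration input variable for one metal."""
    return f"C_{metal}"


@dataclass
class MCConfig:
    seed: int = 0
    n_iter: int = 30_000
    percentiles: tuple[float, ...] = (5.0, 25.0, 50.0, 75.0, 95.0)
    populations: tuple[str, ...] = ("children", "adolescents", "adults")
    metals: tuple[str, ...] = METALS

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ConfigurationError("n_iter must be >= 1")
        ps = list(self.percentiles)
        if ps != sorted(ps) or len(set(ps)) != len(ps):
            raise ConfigurationError("percentiles must be strictly increasing")
        if any(not 0 < p < 100 for p in ps):
            raise ConfigurationError("percentiles must lie in (0, 100)")


@dataclass
class RiskResult:
    config: MCConfig
    thq_draws: dict[tuple[str, str], np.ndarray]
    hi_draws: dict[str, np.ndarray]
    thq_percentiles: dict[tuple[str, str, float], float]
    hi_summary: dict[str, dict[str, float]]
    hi_cdf: dict[str, np.ndarray]  # (n, 2) arrays of (value, cum. probability)
    input_draws: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)


def summarize_percentiles(
    draws: Sequence[float], percentiles: Sequence[float]
) -> dict[float, float]:
    """Percentiles by linear interpolation between order statistics."""
    arr = np.asarray(draws, dtype=float)
    if arr.size == 0:
        raise InvalidInputError("cannot summarise an empty draw list")
    values = np.percentile(arr, list(percentiles), method="linear")
    return {float(p): float(v) for p, v in zip(percentiles, values)}


def empirical_cdf(draws: Sequence[float]) -> np.ndarray:
    """Sorted (value, i/n) pairs — the plot-ready cumulative distribution."""
    arr = np.asarray(draws, dtype=float)
    if arr.size == 0:
        raise InvalidInputError("cannot build a CDF from an empty draw list")
    values = np.sort(arr)
    probs = np.arange(1, arr.size + 1) / arr.size
    return np.column_stack([values, probs])


def _normalize_dists(
    dists: Mapping,
) -> dict[tuple[str, str], DistributionSpec]:
    """Accept either {(group, var): spec} or {group: {var: spec}}."""
    flat: dict[tuple[str, str], DistributionSpec] = {}
    for key, value in dists.items():
        if isinstance(key, tuple):
            flat[key] = value
        else:
            for var, spec in value.items():
                flat[(key, var)] = spec
    return flat


def run_simulation(
    dists: Mapping,
    tox: ToxTable,
    cfg: MCConfig,
) -> RiskResult:
    """Propagate the input distributions through EDI -> THQ -> HI.

    ``dists`` maps (group, variable) to a :class:`DistributionSpec`;
    variables are ``C_<metal>`` for every metal in ``cfg.metals`` plus
    ``IR``, ``BW``, ``EF`` and ``ED``.  Missing specs or reference doses
    are reported before any sampling happens.
    """
    flat = _normalize_dists(dists)

    required = [conc_var(m) for m in cfg.metals] + list(EXPOSURE_VARS)
    missing = [
        (group, var)
        for group in cfg.populations
        for var in required
        if (group, var) not in flat
    ]
    if missing:
        raise ConfigurationError(f"missing distribution spec(s): {missing}")
    for metal in cfg.metals:
        tox.rfd_for(metal)  # raises ConfigurationError if absent

    thq_draws: dict[tuple[str, str], np.ndarray] = {}
    hi_draws: dict[str, np.ndarray] = {}
    input_draws: dict[tuple[str, str], np.ndarray] = {}
    thq_percentiles: dict[tuple[str, str, float], float] = {}
    hi_summary: dict[str, dict[str, float]] = {}
    hi_cdf: dict[str, np.ndarray] = {}

    for group in cfg.populations:
        for var in required:
            spec = flat[(group, var)]
            seq = stream_seed(cfg.seed, f"{group}/{var}")
            input_draws[(group, var)] = sample(spec, cfg.n_iter, seq)

        ir = input_draws[(group, "IR")]
        bw = input_draws[(group, "BW")]
        ef = input_draws[(group, "EF")]
        # ED is drawn and retained for sensitivity, but cancels in the EDI
        # through AT = ED * 365.
        exposure_factor = ir * (ef / 365.0) / bw  # g/(kg*d)

        hi = np.zeros(cfg.n_iter)
        for metal in cfg.metals:
            conc = input_draws[(group, conc_var(metal))]
            edi_draws = conc * exposure_factor  # ug/(kg*d)
            t = edi_draws / tox.rfd_for(metal)
            thq_draws[(group, metal)] = t
            hi += t
            for p, v in summarize_percentiles(t, cfg.percentiles).items():
                thq_percentiles[(group, metal, p)] = v

        hi_draws[group] = hi
        hi_summary[group] = {
            "median": float(np.median(hi)),
            "mean": float(hi.mean()),
            "p95": float(np.percentile(hi, 95, method="linear")),
        }
        hi_cdf[group] = empirical_cdf(hi)

    return RiskResult(
        config=cfg,
        thq_draws=thq_draws,
        hi_draws=hi_draws,
        thq_percentiles=thq_percentiles,
        hi_summary=hi_summary,
        hi_cdf=hi_cdf,
        input_draws=input_draws,
    )


# ---------------------------------------------------------------------------
# Table exports
# ---------------------------------------------------------------------------


def thq_percentile_table(result: RiskResult) -> pd.DataFrame:
    """THQ percentiles per population and metal (one row per percentile)."""
    cfg = result.config
    rows = []
    for group in cfg.populations:
        for p in cfg.percentiles:
            row: dict = {"population": group, "percentile": p}
            for metal in cfg.metals:
                row[metal] = result.thq_percentiles[(group, metal, p)]
            rows.append(row)
    return pd.DataFrame(rows)


def hi_summary_table(result: RiskResult) -> pd.DataFrame:
    rows = [
        {"population": group, **summary}
        for group, summary in result.hi_summary.items()
    ]
    return pd.DataFrame(rows)


def hi_cdf_table(result: RiskResult) -> pd.DataFrame:
    frames = []
    for group, pairs in result.hi_cdf.items():
        frames.append(
            pd.DataFrame(
                {"population": group, "hi": pairs[:, 0], "cum_prob": pairs[:, 1]}
            )
        )
    return pd.concat(frames, ignore_index=True)
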