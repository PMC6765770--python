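"""Default toxicological reference values and YAML (de)serialisation.

The shipped defaults are the regulatory values the assessment is keyed to:

* chronic oral reference doses (RfD, ug/(kg*d)) for As, Cd, Cu, Pb, Zn;
* FAO/WHO provisional tolerable daily intakes (PTDI, ug/(kg*d)); Pb is the
  one metal with an age-dependent PTDI (1.5 adults, 0.5 adolescents; the
  more protective 0.5 is applied to children as well);
* maximum allowable concentrations in vegetables (MAC, mg/kg fresh weight,
  GB 2762-2017) per vegetable category, set only for As, Cd and Pb;
* soil risk screening values (RSV, mg/kg dry weight, GB 15618-2018).
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .core import ConfigurationError, ToxTable
from .distributions import DistributionSpec

DEFAULT_RFD = {"As": 0.3, "Cd": 1.0, "Cu": 40.0, "Pb": 3.57, "Zn": 300.0}

DEFAULT_RSV = {"As": 40.0, "Cd": 0.3, "Cu": 50.0, "Pb": 90.0, "Zn": 200.0}

DEFAULT_MAC = {
    ("As", "leafy"): 0.5, ("As", "rootstalk"): 0.5,
    ("As", "legume"): 0.5, ("As", "fruit"): 0.5,
    ("Cd", "leafy"): 0.2, ("Cd", "rootstalk"): 0.1,
    ("Cd", "legume"): 0.1, ("Cd", "fruit"): 0.05,
    ("Pb", "leafy"): 0.3, ("Pb", "rootstalk"): 0.1,
    ("Pb", "legume"): 0.2, ("Pb", "fruit"): 0.1,
}

_PTDI_FLAT = {"As": 3.0, "Cd": 0.83, "Cu": 50.0, "Zn": 1000.0}
DEFAULT_PTDI = {
    (metal, group): value
    for metal, value in _PTDI_FLAT.items()
    for group in ("children", "adolescents", "adults")
}
DEFAULT_PTDI.update({
    ("Pb", "adults"): 1.5,
    ("Pb", "adolescents"): 0.5,
    ("Pb", "children"): 0.5,
})


def default_tox() -> ToxTable:
    """The shipped toxicology table (RfD/PTDI/MAC/RSV defaults)."""
    return ToxTable(
        rfd=dict(DEFAULT_RFD),
        ptdi=dict(DEFAULT_PTDI),
        mac=dict(DEFAULT_MAC),
        rsv=dict(DEFAULT_RSV),
    )


# ---------------------------------------------------------------------------
# YAML round-trips.  Tuple keys become "metal/group" or "metal/category".
# ---------------------------------------------------------------------------


def tox_to_dict(tox: ToxTable) -> dict:
    return {
        "rfd": dict(tox.rfd),
        "ptdi": {f"{m}/{g}": v for (m, g), v in tox.ptdi.items()},
        "mac": {f"{m}/{c}": v for (m, c), v in tox.mac.items()},
        "rsv": dict(tox.rsv),
    }


def tox_from_dict(d: dict) -> ToxTable:
    def _split(table: dict) -> dict:
        out = {}
        for key, value in table.items():
            try:
                left, right = key.split("/")
            except ValueError:
                raise ConfigurationError(
                    f"expected 'metal/group' style key, got {key!r}"
                ) from None
            out[(left, right)] = float(value)
        return out

    return ToxTable(
        rfd={k: float(v) for k, v in d.get("rfd", {}).items()},
        ptdi=_split(d.get("ptdi", {})),
        mac=_split(d.get("mac", {})),
        rsv={k: float(v) for k, v in d.get("rsv", {}).items()},
    )


def save_tox(tox: ToxTable, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(tox_to_dict(tox), sort_keys=False))


def load_tox(path: str | Path) -> ToxTable:
    return tox_from_dict(yaml.safe_load(Path(path).read_text()))


def dists_to_dict(dists: dict[tuple[str, str], DistributionSpec]) -> dict:
    """Nested {group: {variable: spec}} form for YAML export."""
    out: dict = {}
    for (group, var), spec in dists.items():
        out.setdefault(group, {})[var] = spec.to_dict()
    return out


def dists_from_dict(d: dict) -> dict[tuple[str, str], DistributionSpec]:
    return {
        (group, var): DistributionSpec.from_dict(spec_d)
        for group, table in d.items()
        for var, spec_d in table.items()
    }


def save_dists(dists: dict[tuple[str, str], DistributionSpec], path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dists_to_dict(dists), sort_keys=False))


def load_dists(path: str | Path) -> dict[tuple[str, str], DistributionSpec]:
    return dists_from_dict(yaml.safe_load(Path(path).read_text()))
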