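"""Read and write the delimiter-separated tables the pipeline exchanges.

Sample tables carry one row per paired soil--vegetable observation with
columns ``site_id, village, species, category, soil_ph, soil_som_g_kg,
soil_<M>_mg_kg, veg_fw_<M>_mg_kg [, veg_dw_<M>_mg_kg, fresh_mass_g,
dry_mass_g, water_content]`` for each metal ``<M>``.  Exposure tables carry
``person_id, group, age, bw_kg, ir_g_d, ed_yr, ef_d_yr``.  Tab-separated by
default; any pandas-readable delimiter works.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import METALS, InvalidInputError, ExposureRecord, SampleRecord


def samples_to_frame(samples: Sequence[SampleRecord]) -> pd.DataFrame:
    metals = sorted({m for s in samples for m in s.veg_conc_fw}) or list(METALS)
    rows = []
    for s in samples:
        row: dict = {
            "site_id": s.site_id,
            "village": s.village,
            "species": s.veg_species,
            "category": s.veg_category,
            "soil_ph": s.soil_ph,
            "soil_som_g_kg": s.soil_som,
        }
        for m in metals:
            row[f"soil_{m}_mg_kg"] = s.soil_conc.get(m)
            row[f"veg_fw_{m}_mg_kg"] = s.veg_conc_fw.get(m)
            if s.veg_conc_dw is not None:
                row[f"veg_dw_{m}_mg_kg"] = s.veg_conc_dw.get(m)
        row["fresh_mass_g"] = s.fresh_mass
        row["dry_mass_g"] = s.dry_mass
        row["water_content"] = s.water_content_w
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_samples(frame: pd.DataFrame) -> list[SampleRecord]:
    metals = sorted(
        c.removeprefix("veg_fw_").removesuffix("_mg_kg")
        for c in frame.columns
        if c.startswith("veg_fw_")
    )
    if not metals:
        raise InvalidInputError("no veg_fw_<metal>_mg_kg columns found")
    has_dw = any(c.startswith("veg_dw_") for c in frame.columns)

    def _opt(row, col):
        v = row.get(col)
        return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

    samples = []
    for idx, row in frame.iterrows():
        try:
            samples.append(
                SampleRecord(
                    site_id=str(row["site_id"]),
                    village=str(row.get("village", "?")),
                    veg_species=str(row.get("species", "?")),
                    veg_category=str(row["category"]),
                    soil_ph=_opt(row, "soil_ph"),
                    soil_som=_opt(row, "soil_som_g_kg"),
                    soil_conc={m: float(row[f"soil_{m}_mg_kg"]) for m in metals},
                    veg_conc_fw={m: float(row[f"veg_fw_{m}_mg_kg"]) for m in metals},
                    veg_conc_dw=(
                        {m: float(row[f"veg_dw_{m}_mg_kg"]) for m in metals}
                        if has_dw else None
                    ),
                    fresh_mass=_opt(row, "fresh_mass_g"),
                    dry_mass=_opt(row, "dry_mass_g"),
                    water_content_w=_opt(row, "water_content"),
                )
            )
        except (KeyError, ValueError) as exc:
            raise InvalidInputError(
                f"sample table row {idx}: {exc}"
            ) from exc
    return samples


def people_to_frame(people: Sequence[ExposureRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "person_id": p.person_id,
                "group": p.group,
                "age": p.age,
                "bw_kg": p.bw,
                "ir_g_d": p.ir,
                "ed_yr": p.ed,
                "ef_d_yr": p.ef,
            }
            for p in people
        ]
    )


def frame_to_people(frame: pd.DataFrame) -> list[ExposureRecord]:
    people = []
    for idx, row in frame.iterrows():
        try:
            age = row.get("age")
            people.append(
                ExposureRecord(
                    person_id=str(row["person_id"]),
                    group=str(row["group"]),
                    age=None if age is None or pd.isna(age) else float(age),
                    bw=float(row["bw_kg"]),
                    ir=float(row["ir_g_d"]),
                    ed=float(row["ed_yr"]),
                    ef=float(row["ef_d_yr"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise InvalidInputError(f"exposure table row {idx}: {exc}") from exc
    return people


def write_table(frame: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    frame.to_csv(path, sep=sep, index=False)


def read_samples(path: str | Path, sep: str = "\t") -> list[SampleRecord]:
    return frame_to_samples(pd.read_csv(path, sep=sep))


def read_people(path: str | Path, sep: str = "\t") -> list[ExposureRecord]:
    return frame_to_people(pd.read_csv(path, sep=sep))
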