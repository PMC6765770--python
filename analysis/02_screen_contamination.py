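"""Contamination screening: descriptive statistics and threshold exceedance.

Summarises soil and vegetable metal concentrations (min/max/median/mean/
SD/CV%/Shapiro-Wilk p) and the share of samples above the soil risk
screening values and the category-specific food MACs.
"""

from pathlib import Path

from vegrisk.config import default_tox
from vegrisk.io import read_samples, write_table
from vegrisk.reporting import soil_screening_table, veg_screening_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    samples = read_samples(ROOT / "data" / "samples.tsv")
    tox = default_tox()
    out = ROOT / "screening"
    out.mkdir(parents=True, exist_ok=True)

    soil = soil_screening_table(samples, tox)
    veg = veg_screening_table(samples, tox)
    write_table(soil, out / "soil_screening.tsv")
    write_table(veg, out / "veg_screening.tsv")

    print("soil screening (vs GB 15618-2018 RSVs):")
    print(soil[["name", "mean", "cv_percent", "rsv_mg_kg", "exceeding_percent"]]
          .to_string(index=False))
    print("\nvegetable screening (vs GB 2762-2017 MACs, category-specific):")
    print(veg[["name", "mean", "sd", "exceeding_percent"]].to_string(index=False))


if __name__ == "__main__":
    main()
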