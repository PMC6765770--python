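"""Sensitivity of the hazard index to each input variable (tornado tables).

Spearman rank correlations between the retained input draws and the HI
draws, normalised to contribution-to-variance percentages; the per-metal
concentration inputs are pooled into a single C_veg entry.
"""

from pathlib import Path

from vegrisk.config import default_tox
from vegrisk.io import read_people, read_samples, write_table
from vegrisk.monte_carlo import MCConfig
from vegrisk.pipeline import run_risk_pipeline
from vegrisk.sensitivity import tornado_table

SEED = 2023
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    samples = read_samples(ROOT / "data" / "samples.tsv")
    people = read_people(ROOT / "data" / "exposure.tsv")
    result = run_risk_pipeline(
        samples, people, tox=default_tox(), mc=MCConfig(seed=SEED, n_iter=30_000)
    )
    out = ROOT / "sensitivity"
    out.mkdir(parents=True, exist_ok=True)
    for group, sens in result.sensitivity.items():
        table = tornado_table(sens)
        write_table(table, out / f"tornado_{group}.tsv")
        print(f"\n{group}:")
        print(table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))


if __name__ == "__main__":
    main()
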