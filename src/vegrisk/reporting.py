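"""Screening, BCF and intake summary tables, plus the run manifest.

Everything here is a thin tabular view over the core equations: the
contamination screen (descriptive statistics and regulatory exceedance),
per-metal bioaccumulation summaries, deterministic mean intakes with their
PTDI comparison, and a JSON manifest that records enough (command, config
digest, seed, iterations, version) to reproduce any run exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    CATEGORIES,
    ExposureRecord,
    SampleRecord,
    ToxTable,
    describe,
    edi,
    exceedance_rate,
)
from .synthetic import mean_sample_bcf


def soil_screening_table(
    samples: Sequence[SampleRecord], tox: ToxTable
) -> pd.DataFrame:
    """Descriptives and risk-screening-value exceedance per metal in soil."""
    metals = sorted({m for s in samples for m in s.soil_conc})
    rows = []
    for metal in metals:
        values = [s.soil_conc[metal] for s in samples]
        d = describe(values, name=f"soil_{metal}")
        row = asdict(d)
        rsv = tox.rsv.get(metal)
        row["rsv_mg_kg"] = rsv
        row["exceeding_percent"] = (
            exceedance_rate(values, rsv) if rsv is not None else None
        )
        rows.append(row)
    return pd.DataFrame(rows)


def veg_screening_table(
    samples: Sequence[SampleRecord], tox: ToxTable
) -> pd.DataFrame:
    """MAC exceedance per metal, with each sample screened against the MAC
    of its own vegetable category (limits differ by category)."""
    metals = sorted({m for s in samples for m in s.veg_conc_fw})
    rows = []
    for metal in metals:
        values = [s.veg_conc_fw[metal] for s in samples]
        d = describe(values, name=f"veg_{metal}")
        row = asdict(d)
        macs = {c: tox.mac.get((metal, c)) for c in CATEGORIES}
        if any(v is not None for v in macs.values()):
            n_limit = n_exceed = 0
            for s in samples:
                mac = macs.get(s.veg_category)
                if mac is None:
                    continue
                n_limit += 1
                if s.veg_conc_fw[metal] > mac:
                    n_exceed += 1
            row["exceeding_percent"] = (
                100.0 * n_exceed / n_limit if n_limit else None
            )
        else:
            row["exceeding_percent"] = None
        rows.append(row)
    return pd.DataFrame(rows)


def bcf_table(samples: Sequence[SampleRecord]) -> pd.DataFrame:
    """Mean per-sample BCF (mean of ratios) per metal, overall and by category."""
    metals = sorted({m for s in samples for m in s.veg_conc_fw})
    rows = []
    for metal in metals:
        row: dict = {"metal": metal, "mean_bcf": mean_sample_bcf(list(samples), metal)}
        for cat in CATEGORIES:
            cat_samples = [s for s in samples if s.veg_category == cat]
            row[f"mean_bcf_{cat}"] = (
                mean_sample_bcf(cat_samples, metal) if cat_samples else None
            )
        rows.append(row)
    return pd.DataFrame(rows).sort_values("mean_bcf", ascending=False, ignore_index=True)


def edi_table(
    samples: Sequence[SampleRecord],
    people: Sequence[ExposureRecord],
    tox: ToxTable,
) -> pd.DataFrame:
    """Deterministic mean EDIs per group and metal, against the PTDI.

    Each person's intake uses the survey-mean fresh-weight concentration
    and their own IR/BW/EF; the table reports the group mean.
    """
    metals = sorted({m for s in samples for m in s.veg_conc_fw})
    mean_conc = {
        m: float(np.mean([s.veg_conc_fw[m] for s in samples])) for m in metals
    }
    groups = sorted({p.group for p in people})
    rows = []
    for group in groups:
        members = [p for p in people if p.group == group]
        for metal in metals:
            intakes = [
                edi(mean_conc[metal], p.ir, p.bw, p.ef, p.ed) for p in members
            ]
            mean_edi = float(np.mean(intakes))
            ptdi = tox.ptdi.get((metal, group))
            rows.append(
                {
                    "population": group,
                    "metal": metal,
                    "mean_edi_ug_kg_d": mean_edi,
                    "ptdi_ug_kg_d": ptdi,
                    "exceeds_ptdi": None if ptdi is None else bool(mean_edi > ptdi),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    command: str
    config_digest: str
    seed: int
    n_iter: int
    timestamp: str
    software_version: str


def digest_inputs(paths: Iterable[str | Path] = (), extra: dict | None = None) -> str:
    """SHA-256 over the byte content of every input file plus the literal
    configuration, so the digest changes iff any input byte changes."""
    h = hashlib.sha256()
    for path in sorted(str(p) for p in paths):
        h.update(path.encode())
        h.update(Path(path).read_bytes())
    if extra is not None:
        h.update(json.dumps(extra, sort_keys=True, default=str).encode())
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    seed: int,
    n_iter: int,
    input_paths: Iterable[str | Path] = (),
    extra_config: dict | None = None,
) -> RunManifest:
    manifest = RunManifest(
        command=command,
        config_digest=digest_inputs(input_paths, extra_config),
        seed=seed,
        n_iter=n_iter,
        timestamp=datetime.now(timezone.utc).isoformat(),
        software_version=__version__,
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(asdict(manifest), indent=2) + "\n")
    return manifest
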