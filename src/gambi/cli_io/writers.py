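"""Writers for results tables, FASTA, and run provenance."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

import gambi
from gambi.agreement import ConfusionMatrix, KappaResult
from gambi.core_index import AmbiResult, EcologicalGroupMap, StationSample
from gambi.reference_library import SequenceRecord


def provenance_block(config: Mapping, seed: int | None = None) -> dict:
    """Version + config hash + seed, attached to every CLI output."""
    blob = json.dumps({k: str(v) for k, v in sorted(config.items())}, sort_keys=True)
    return {
        "tool": "gambi",
        "version": gambi.__version__,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "seed": seed,
    }


def write_ambi_results(results: Sequence[AmbiResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "station_id": r.station_id,
                "mode": r.mode,
                "value": r.value,
                "quality_class": r.quality_class,
                "azoic": r.azoic,
                "unassigned_fraction": r.unassigned_fraction,
                "n_taxa_used": r.n_taxa_used,
            }
            for r in results
        ]
    ).to_csv(path, index=False)


def write_class_table(classes: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"station_id": list(classes), "quality_class": list(classes.values())}
    ).to_csv(path, index=False)


def write_confusion_matrix(cm: ConfusionMatrix, path: str | Path) -> None:
    pd.DataFrame(cm.counts, index=list(cm.classes), columns=list(cm.classes)).rename_axis(
        "A\\B"
    ).to_csv(path)


def kappa_report_dict(result: KappaResult) -> dict:
    return {
        "kappa": result.kappa,
        "p_observed": result.p_observed,
        "p_expected": result.p_expected,
        "n": result.n,
        "interpretation": result.interpretation,
    }


def format_kappa_report(result: KappaResult) -> str:
    return (
        f"n = {result.n}\n"
        f"observed agreement p_o = {result.p_observed:.4f}\n"
        f"expected agreement p_e = {result.p_expected:.4f}\n"
        f"Cohen's kappa = {result.kappa:.4f} ({result.interpretation})\n"
    )


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, delimiter: str = "|", width: int = 70
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}{delimiter}{rec.species}{delimiter}{rec.phylum}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_eg_table(eg: EcologicalGroupMap, path: str | Path) -> None:
    rows = []
    for key, rec in eg.entries.items():
        group = rec.group.value if rec.group.value != "UNASSIGNED" else "NA"
        rows.append(
            {"species": eg.display_names[key], "phylum": rec.phylum, "group": group}
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_abundance_matrix(samples: Sequence[StationSample], path: str | Path) -> None:
    species = sorted({sp for s in samples for sp in s.abundances})
    rows = []
    for s in samples:
        row = {"station_id": s.station_id}
        row.update({sp: s.abundances.get(sp, 0) for sp in species})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_json(payload: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if hasattr(obj, "tolist"):
        return obj.tolist()
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
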