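"""Model and data I/O: SBML/JSON metabolic models, abundance tables, results.

Models are `cobra.Model` objects read and written through cobra's SBML Level 3
FBC and BiGG-style JSON codecs. Transcript abundance tables are two-column
gene/abundance text files parsed into plain dictionaries; duplicate gene rows
are summed (with a warning) and negative abundances rejected.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import List, Optional

import cobra
import pandas as pd

from .contextualize import ContextResult
from .weighting import TranscriptAbundanceTable

logger = logging.getLogger(__name__)

_SBML_SUFFIXES = {".xml", ".sbml"}


def _infer_format(path: Path, format: Optional[str]) -> str:
    if format is not None:
        if format not in ("sbml", "json"):
            raise ValueError(f"unknown model format {format!r}; expected sbml or json")
        return format
    if path.suffix.lower() in _SBML_SUFFIXES:
        return "sbml"
    if path.suffix.lower() == ".json":
        return "json"
    raise ValueError(
        f"cannot infer model format from {path.name!r}; pass format='sbml' or 'json'"
    )


def read_model(path, format: Optional[str] = None) -> cobra.Model:
    """Read a genome-scale model from SBML (L3+FBC) or BiGG-style JSON.

    Reversibility is encoded via lower_bound < 0. Raises if the file does not
    parse or if the model declares no objective reaction.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    fmt = _infer_format(path, format)
    try:
        if fmt == "sbml":
            model = cobra.io.read_sbml_model(str(path))
        else:
            model = cobra.io.load_json_model(str(path))
    except Exception as exc:
        raise ValueError(f"failed to parse {fmt.upper()} model {path.name}: {exc}") from exc
    if not any(r.objective_coefficient != 0 for r in model.reactions):
        raise ValueError(f"model {path.name} declares no objective reaction")
    return model


def write_model(model: cobra.Model, path, format: Optional[str] = None) -> None:
    """Write a model as SBML or BiGG-style JSON (inferred from the suffix)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        cobra.io.write_sbml_model(model, str(path))
    else:
        cobra.io.save_json_model(model, str(path))


def read_abundances(path, delimiter: Optional[str] = None) -> TranscriptAbundanceTable:
    """Parse a two-column gene/abundance table (TSV or CSV, optional header).

    Duplicate gene rows are summed with a warning; negative abundances and
    non-numeric rows raise with the offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"abundance file not found: {path}")
    table: TranscriptAbundanceTable = {}
    duplicates = 0
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle]
    rows = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not rows:
        raise ValueError(f"abundance file {path.name} is empty")
    if delimiter is None:
        delimiter = "\t" if "\t" in rows[0][1] else ","
    for position, (line_no, line) in enumerate(rows):
        fields = [f.strip() for f in line.split(delimiter)]
        if len(fields) < 2:
            raise ValueError(
                f"{path.name}:{line_no}: expected two {delimiter!r}-separated columns"
            )
        gene, raw_value = fields[0], fields[1]
        try:
            value = float(raw_value)
        except ValueError:
            if position == 0:  # header row
                continue
            raise ValueError(
                f"{path.name}:{line_no}: non-numeric abundance {raw_value!r}"
            ) from None
        if math.isnan(value) or value < 0:
            raise ValueError(
                f"{path.name}:{line_no}: invalid abundance {raw_value!r} for gene {gene!r}"
            )
        if gene in table:
            duplicates += 1
            table[gene] += value
        else:
            table[gene] = value
    if duplicates:
        logger.warning(
            "%s: %d duplicate gene rows merged by summation", path.name, duplicates
        )
    if not table:
        raise ValueError(f"abundance file {path.name} contains no data rows")
    return table


def write_abundances(table: TranscriptAbundanceTable, path, delimiter: str = "\t") -> None:
    path = Path(path)
    with open(path, "w") as handle:
        handle.write(f"gene{delimiter}abundance\n")
        for gene, value in table.items():
            handle.write(f"{gene}{delimiter}{value:g}\n")


def _concordance_dict(result: ContextResult) -> Optional[dict]:
    if result.concordance is None:
        return None
    c = result.concordance
    return {
        "rho": None if math.isnan(c.rho) else c.rho,
        "p_value": None if math.isnan(c.p_value) else c.p_value,
        "n_reactions": c.n_reactions,
        "undefined": c.undefined,
    }


def write_result(result: ContextResult, out_dir) -> List[Path]:
    """Write a full contextualization result to a directory.

    Produces the pruned model (SBML and JSON), the flux sample matrix and FVA
    ranges as TSV, the reaction-weight audit table, and a JSON report with all
    settings, pruning metrics, objective bounds and concordance.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    sbml_path = out_dir / "pruned_model.xml"
    json_path = out_dir / "pruned_model.json"
    cobra.io.write_sbml_model(result.pruned_model, str(sbml_path))
    cobra.io.save_json_model(result.pruned_model, str(json_path))
    written += [sbml_path, json_path]

    weights_path = out_dir / "reaction_weights.tsv"
    result.weights.to_frame().to_csv(weights_path, sep="\t")
    written.append(weights_path)

    if result.flux_samples is not None:
        samples_path = out_dir / "flux_samples.tsv"
        result.flux_samples.matrix.to_csv(samples_path, sep="\t")
        written.append(samples_path)
    if result.fva is not None:
        fva_path = out_dir / "fva_ranges.tsv"
        result.fva.to_csv(fva_path, sep="\t", index_label="reaction_id")
        written.append(fva_path)

    report = {
        "settings": result.settings.to_dict(),
        "metrics": result.metrics,
        "objective_bounds": list(result.objective_bounds),
        "concordance": _concordance_dict(result),
        "retained_reactions": sorted(result.retained_reactions),
        "pruned_reactions": sorted(result.pruned_reactions),
        "n_samples": None if result.flux_samples is None else result.flux_samples.n_samples,
        "sampling_seed": None if result.flux_samples is None else result.flux_samples.seed,
    }
    report_path = out_dir / "report.json"
    with open(report_path, "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
    written.append(report_path)
    return written


def read_samples(path) -> pd.DataFrame:
    """Read back a flux sample TSV written by :func:`write_result`."""
    return pd.read_csv(path, sep="\t", index_col=0)
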