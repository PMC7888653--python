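"""Readers and writers for the pipeline's on-disk formats.

Plain-text formats throughout: wide CSV for chromatograms (retention_time
first column, one column per sample) and VOC tables, TSV for species count
tables (negative controls flagged by a ``NEG_`` column-name prefix, with
manifest override), JSON for trial records and result summaries.  Result
JSON embeds a config echo so every number is traceable to its settings.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import FormatError, PipelineConfig, SampleRecord, check_unique_ids
from .containers import Chromatogram, TaxaTable, VocTable
from .trial import RunOutcome, SetRecord, TrialRecord

NEG_PREFIX = "NEG_"


# ---------------------------------------------------------------- chromatograms


def write_chromatograms(path, chroms: list[Chromatogram]) -> None:
    grids = [c.retention_times for c in chroms]
    for g in grids[1:]:
        if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
            raise FormatError("all chromatograms must share one retention-time grid")
    df = pd.DataFrame({"retention_time": grids[0]})
    for c in chroms:
        df[c.sample_id] = c.abundances
    df.to_csv(path, index=False)


def write_manifest(path, records: list[SampleRecord]) -> None:
    rows = [
        {"column": r.sample_id, "sample_id": r.sample_id, "cohort": r.cohort}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_chromatograms(
    path, manifest
) -> tuple[list[Chromatogram], list[SampleRecord]]:
    """Read a wide chromatogram CSV using a column→sample manifest.

    ``manifest`` is a CSV path (columns: column, sample_id, cohort) or a
    list of such dicts.
    """
    df = pd.read_csv(path)
    if "retention_time" not in df.columns:
        raise FormatError("chromatogram CSV needs a 'retention_time' column")
    rt = df["retention_time"].to_numpy(dtype=float)
    if not np.all(np.diff(rt) > 0):
        raise FormatError("retention times must be strictly increasing")

    if isinstance(manifest, (str, Path)):
        entries = pd.read_csv(manifest).to_dict("records")
    else:
        entries = list(manifest)

    chroms, records = [], []
    for e in entries:
        col = e["column"]
        if col not in df.columns:
            raise FormatError(
                f"sample {e['sample_id']!r}: column {col!r} absent from CSV"
            )
        ab = df[col].to_numpy(dtype=float)
        if np.any(ab < 0):
            raise FormatError(f"sample {e['sample_id']!r}: negative abundances")
        chroms.append(Chromatogram(rt.copy(), ab, e["sample_id"]))
        records.append(SampleRecord(e["sample_id"], e["cohort"], ("gcms",)))
    check_unique_ids(records)
    return chroms, records


# ---------------------------------------------------------------- taxa tables


def write_taxa_table(path, table: TaxaTable) -> None:
    df = pd.DataFrame(
        table.counts, index=table.species_ids, columns=table.sample_ids
    )
    df.index.name = "species"
    df.to_csv(path, sep="\t")


def read_taxa_table(path, labels: dict[str, str] | None = None) -> TaxaTable:
    """Read a species × samples TSV count table.

    Columns whose name starts with ``NEG_`` are blank extraction negative
    controls.  ``labels`` maps true-sample ids to cohorts; when omitted the
    cohort is inferred from the ``case``/``ctrl`` id prefix convention.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.isna().any() or any(not str(s).strip() for s in df.index):
        raise FormatError("empty species name in taxa table")
    try:
        counts = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric counts in taxa table: {exc}") from exc
    if np.any(counts < 0):
        raise FormatError("negative counts in taxa table")
    if np.any(counts != np.floor(counts)):
        raise FormatError("non-integer counts in taxa table")

    sample_ids = [str(c) for c in df.columns]
    flags = np.array([s.startswith(NEG_PREFIX) for s in sample_ids])
    labs = []
    for s, neg in zip(sample_ids, flags):
        if neg:
            labs.append(None)
        elif labels is not None:
            if s not in labels:
                raise FormatError(f"no cohort label for sample {s!r}")
            labs.append(labels[s])
        elif s.startswith("case"):
            labs.append("cancer")
        elif s.startswith("ctrl"):
            labs.append("control")
        else:
            raise FormatError(
                f"cannot infer cohort for sample {s!r}; pass a labels mapping"
            )
    return TaxaTable(
        species_ids=[str(s) for s in df.index],
        sample_ids=sample_ids,
        counts=counts.astype(np.int64),
        is_negative_control=flags,
        labels=np.array(labs, dtype=object),
    )


# ---------------------------------------------------------------- VOC tables


def write_voc_table(path, table: VocTable) -> None:
    df = pd.DataFrame(table.abundances, columns=table.compound_ids)
    df.insert(0, "sample_id", table.sample_ids)
    df.insert(1, "cohort", table.labels)
    df.to_csv(path, index=False)


def read_voc_table(path) -> VocTable:
    df = pd.read_csv(path)
    for col in ("sample_id", "cohort"):
        if col not in df.columns:
            raise FormatError(f"VOC table needs a {col!r} column")
    compound_ids = [c for c in df.columns if c not in ("sample_id", "cohort")]
    ab = df[compound_ids].to_numpy(dtype=float)
    return VocTable(
        sample_ids=[str(s) for s in df["sample_id"]],
        compound_ids=compound_ids,
        abundances=ab,
        labels=df["cohort"].to_numpy(dtype=object),
    )


# ---------------------------------------------------------------- trial records


def write_trial_record(path, record: TrialRecord) -> None:
    payload = {
        "dog": record.dog,
        "sets": [
            {
                "target_position": s.target_position,
                "reward_scheme": s.reward_scheme,
                "runs": [r.call for r in s.runs],
            }
            for s in record.sets
        ],
    }
    if record.controls_presented_override is not None:
        payload["controls_presented_override"] = record.controls_presented_override
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_trial_record(path) -> TrialRecord:
    payload = json.loads(Path(path).read_text())
    sets = []
    for s in payload["sets"]:
        runs = []
        n_x = 0
        for call in s["runs"]:
            if call == "X":
                n_x += 1
                runs.append(RunOutcome("X", f"ctrl{n_x}"))
            else:
                runs.append(RunOutcome(call))
        sets.append(
            SetRecord(
                target_position=s["target_position"],
                runs=runs,
                reward_scheme=s.get("reward_scheme", "balanced"),
            )
        )
    return TrialRecord(
        dog=payload["dog"],
        sets=sets,
        controls_presented_override=payload.get("controls_presented_override"),
    )


# ---------------------------------------------------------------- results JSON


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_result_json(
    path, payload: dict, config: PipelineConfig | None = None
) -> None:
    """Serialize a result dict with an embedded config echo."""
    out = {"config": config.to_dict() if config else None}
    out.update(_jsonable(payload))
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")
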