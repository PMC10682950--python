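"""File writers and readers for runs: outcomes/trajectory TSVs, summary and
manifest JSON. All floats are written at 12 significant digits so that
re-runs from a manifest reproduce byte-identical files."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

from .ensemble import EnsembleSummary
from .lineage import LineageOutcome
from .params import DiseaseConfig, config_to_dict

__all__ = [
    "format_float",
    "write_outcomes_tsv",
    "write_trajectories_tsv",
    "write_summary_json",
    "read_summary_json",
    "write_manifest",
    "read_manifest",
    "write_comparison_tsv",
]

_FLOAT_FMT = "{:.12g}"


def format_float(x) -> str:
    if x is None:
        return ""
    return _FLOAT_FMT.format(x)


def write_outcomes_tsv(outcomes: Sequence[LineageOutcome], path: Union[str, Path]) -> None:
    cols = (
        "lineage_id\tstatus\tterminal_generation\tfixation_generation\t"
        "repeat_at_event\texpanded_at_horizon\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for i, o in enumerate(outcomes):
            fh.write(
                "\t".join(
                    [
                        str(i),
                        o.status,
                        str(o.terminal_generation),
                        "" if o.fixation_generation is None else str(o.fixation_generation),
                        format_float(o.repeat_at_event),
                        "" if o.expanded_at_horizon is None else str(int(o.expanded_at_horizon)),
                    ]
                )
                + "\n"
            )


def write_trajectories_tsv(
    outcomes: Sequence[LineageOutcome], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        fh.write("lineage_id\tgeneration\tfrequency\trepeat_length\tao\tregime\tfixed\n")
        for i, o in enumerate(outcomes):
            for rec in o.trajectory:
                fh.write(
                    f"{i}\t{rec.generation}\t{format_float(rec.frequency)}\t"
                    f"{format_float(rec.repeat_length)}\t{format_float(rec.ao)}\t"
                    f"{rec.regime}\t{int(rec.fixed)}\n"
                )


def write_summary_json(summary: EnsembleSummary, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2) + "\n")


def read_summary_json(path: Union[str, Path]) -> EnsembleSummary:
    return EnsembleSummary.from_dict(json.loads(Path(path).read_text()))


def write_manifest(
    path: Union[str, Path],
    cfg: DiseaseConfig,
    schedule_source: dict,
    n: int,
    master_seed: int,
    version: str,
) -> None:
    """Write a manifest sufficient to reproduce the run bit-for-bit.

    The timestamp is informational; a replay keys on config, schedule
    source, n and master_seed only.
    """
    from datetime import datetime, timezone

    manifest = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config_to_dict(cfg),
        "schedule_source": schedule_source,
        "n": n,
        "master_seed": master_seed,
        "version": version,
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")


def read_manifest(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text())


def write_comparison_tsv(table, path: Union[str, Path]) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")
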