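"""Tabular I/O, run configuration and the reproducibility contract.

All output files are plain text.  CSV files carry a short metadata header of
``#``-prefixed comment lines (tool version, seed, resolved configuration)
that :func:`pandas.read_csv` skips via ``comment='#'``; JSON outputs embed
the same metadata under a ``meta`` key.  No timestamps are written, so a run
with a fixed seed is byte-identical across invocations.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .fitting import ColonizationRecord, FitResult
from .model import MODEL_VARIANTS
from .niche import NicheObservation, observations_from_frame, observations_to_frame

__all__ = [
    "FormatError",
    "RunConfig",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_niche_csv",
    "write_niche_csv",
    "write_fit_json",
    "read_fit_json",
]

logger = logging.getLogger(__name__)

COHORT_COLUMNS = ["subject_id", "group", "n", "outcome"]
NICHE_COLUMNS = [
    "dtc_id",
    "subject_id",
    "group",
    "distance_to_growth_plate",
    "distance_to_vessel",
    "distance_to_bone",
    "vessel_type",
]


class FormatError(ValueError):
    """Malformed or incomplete input file."""


@dataclass
class RunConfig:
    """Resolved run settings; every output embeds this plus the seed."""

    seed: Optional[int] = None
    birth_rate: float = 1.0
    death_rate: Optional[float] = None
    ratio: Optional[float] = 0.885
    proliferative_fraction: float = 1.0
    model_variant: str = "mixture"
    replicates: int = 100_000
    outgrowth_threshold: int = 1000
    max_events: int = 1_000_000
    f_fixed: float = 1.0
    n_boot: int = 1000
    contact_radius: float = 10.0

    def __post_init__(self) -> None:
        if self.model_variant not in MODEL_VARIANTS:
            raise ValueError(f"model_variant must be one of {MODEL_VARIANTS}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a YAML or JSON scenario file; unknown keys are rejected."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)

    def branching_params(self):
        from .model import BranchingParams

        if self.death_rate is not None:
            return BranchingParams(
                self.birth_rate, self.death_rate, self.proliferative_fraction
            )
        if self.ratio is None:
            raise ValueError("either death_rate or ratio must be set")
        return BranchingParams.from_ratio(
            self.ratio, self.proliferative_fraction, self.birth_rate
        )


def _metadata_lines(seed: Optional[int], config: Optional[dict]) -> list[str]:
    lines = [f"# dtcfate {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config: {json.dumps(config, sort_keys=True)}")
    return lines


def _write_csv(path, df: pd.DataFrame, seed, config) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in _metadata_lines(seed, config):
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def write_cohort_csv(
    path,
    records: Sequence[ColonizationRecord],
    *,
    seed: Optional[int] = None,
    config: Optional[dict] = None,
) -> None:
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "n": [r.n for r in records],
            "outcome": [r.outcome for r in records],
        },
        columns=COHORT_COLUMNS,
    )
    _write_csv(path, df, seed, config)
    logger.info("wrote cohort CSV %s (%d records)", path, len(records))


def _read_table(path, required: list[str]) -> tuple[pd.DataFrame, int]:
    path = Path(path)
    n_comments = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                n_comments += 1
            else:
                break
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file, no header found") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns: {missing}")
    return df, n_comments


def read_cohort_csv(path) -> list[ColonizationRecord]:
    """Read a cohort CSV; malformed rows are reported with line numbers."""
    df, n_comments = _read_table(path, COHORT_COLUMNS)
    if df.empty:
        logger.warning("read_cohort_csv: %s contains a header but no records", path)
        return []
    records = []
    bad: list[str] = []
    header_line = n_comments + 1
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = header_line + 1 + i
        try:
            outcome = int(row.outcome)
            if float(row.outcome) != outcome or outcome not in (0, 1):
                raise ValueError(f"outcome must be 0 or 1, got {row.outcome!r}")
            n = int(row.n)
            if float(row.n) != n:
                raise ValueError(f"n must be an integer, got {row.n!r}")
            records.append(
                ColonizationRecord(
                    subject_id=str(row.subject_id),
                    group=str(row.group),
                    n=n,
                    outcome=outcome,
                )
            )
        except (TypeError, ValueError) as exc:
            bad.append(f"line {line_no}: {exc}")
    if bad:
        raise FormatError(f"{path}: {len(bad)} malformed rows:\n" + "\n".join(bad))
    logger.info("read cohort CSV %s (%d records)", path, len(records))
    return records


def write_niche_csv(
    path,
    observations: Sequence[NicheObservation],
    *,
    seed: Optional[int] = None,
    config: Optional[dict] = None,
) -> None:
    df = observations_to_frame(list(observations))
    if df.empty:
        df = pd.DataFrame(columns=NICHE_COLUMNS)
    _write_csv(path, df[NICHE_COLUMNS] if len(df) else df, seed, config)
    logger.info("wrote niche CSV %s (%d observations)", path, len(observations))


def read_niche_csv(path) -> list[NicheObservation]:
    df, n_comments = _read_table(path, NICHE_COLUMNS)
    if df.empty:
        logger.warning("read_niche_csv: %s contains a header but no records", path)
        return []
    bad = []
    header_line = n_comments + 1
    for i, row in enumerate(df.itertuples(index=False)):
        if row.vessel_type not in ("H", "L", "none"):
            bad.append(f"line {header_line + 1 + i}: vessel_type must be H, L or none, "
                       f"got {row.vessel_type!r}")
    if bad:
        raise FormatError(f"{path}: {len(bad)} malformed rows:\n" + "\n".join(bad))
    logger.info("read niche CSV %s (%d observations)", path, len(df))
    return observations_from_frame(df)


def write_fit_json(
    path,
    fit: FitResult,
    *,
    seed: Optional[int] = None,
    config: Optional[dict] = None,
) -> None:
    payload = {
        "meta": {"tool": "dtcfate", "version": __version__, "seed": seed,
                 "config": config},
        "fit": fit.to_dict(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("wrote fit JSON %s", path)


def read_fit_json(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
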