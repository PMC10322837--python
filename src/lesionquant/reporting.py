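"""Per-group descriptive summaries and run logging helpers.

The pipelines emit one CSV row per image/field; downstream significance
testing (Kruskal-Wallis, ANOVA) is deliberately left to external tools —
this module only aggregates mean / sample SD / min / max per group, the
descriptive statistics a burden or co-localization figure plots.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError

log = logging.getLogger(__name__)

__all__ = ["GroupSummary", "summarize_groups", "write_run_log"]


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float  # sample SD (n-1); 0.0 with sd_flagged=True when n == 1
    min: float
    max: float
    sd_flagged: bool = False


def summarize_groups(
    rows: pd.DataFrame, grouping: str, statistic: str
) -> list[GroupSummary]:
    """Per-group n / mean / sample SD / min / max of one numeric column.

    Undefined statistics (NaN) are excluded with a logged count; a group of
    one reports SD 0 with ``sd_flagged`` set.
    """
    if rows.empty:
        raise InvalidInputError("empty result table")
    for col in (grouping, statistic):
        if col not in rows.columns:
            raise InvalidInputError(f"column {col!r} not in table")
    values = pd.to_numeric(rows[statistic], errors="coerce")
    n_dropped = int(values.isna().sum())
    if n_dropped:
        log.info("excluding %d rows with undefined %s", n_dropped, statistic)
    kept = rows.assign(__stat=values).dropna(subset=["__stat"])
    out = []
    for group, sub in kept.groupby(grouping, sort=True):
        v = sub["__stat"].to_numpy(dtype=float)
        single = len(v) == 1
        out.append(
            GroupSummary(
                group=str(group),
                n=len(v),
                mean=float(np.mean(v)),
                sd=0.0 if single else float(np.std(v, ddof=1)),
                min=float(np.min(v)),
                max=float(np.max(v)),
                sd_flagged=single,
            )
        )
    return out


def summaries_to_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable config dict."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_run_log(path, *, command: str, config: dict, seed=None, files=(), statuses=()):
    """Write a reproducibility log: command, config + hash, seed, per-file status."""
    from pathlib import Path

    import lesionquant

    record = {
        "command": command,
        "package_version": lesionquant.__version__,
        "config": config,
        "config_hash": config_hash(config),
        "seed": seed,
        "files": [
            {"path": str(f), "status": s}
            for f, s in zip(files, statuses)
        ],
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(record, indent=2, default=str) + "\n")
    return record
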