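"""Design reports: JSON serialization and table-style CSV rows.

A :class:`DesignReport` echoes the inputs (hypotheses + configuration),
the selected stopping rules, and the simulated operating characteristics
with their Monte-Carlo standard errors, together with the seed and package
version so any report can be replayed exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .evaluate import DesignHypotheses, OperatingCharacteristics
from .search import DesignResult, design_csr
from .simulate import StoppingRules, TrialConfig

logger = logging.getLogger(__name__)

__all__ = ["DesignReport", "run_design", "run_table", "CSV_COLUMNS"]

#: Column order of the tabular report (the classic design-table layout).
CSV_COLUMNS = [
    "r_nul",
    "r_alt",
    "ttp_nul",
    "ttp_alt",
    "n1",
    "n2",
    "r1_stop",
    "epd_stop",
    "r2_reject",
    "ttp2_reject",
    "power",
    "alpha",
    "en_nul",
    "pes_nul",
    "en_alt",
    "pes_alt",
]


@dataclass(frozen=True)
class DesignReport:
    hypotheses: DesignHypotheses
    config: TrialConfig
    rules: StoppingRules
    oc: OperatingCharacteristics
    info: dict
    seed: Optional[int]
    version: str
    timestamp: str

    def to_dict(self, exclude_timestamp: bool = False) -> dict:
        d = {
            "hypotheses": dataclasses.asdict(self.hypotheses),
            "config": dataclasses.asdict(self.config),
            "rules": dataclasses.asdict(self.rules),
            "oc": dataclasses.asdict(self.oc),
            "info": dict(self.info),
            "seed": self.seed,
            "version": self.version,
            "timestamp": self.timestamp,
        }
        if exclude_timestamp:
            del d["timestamp"]
        return d

    def to_json(self, exclude_timestamp: bool = False) -> str:
        return json.dumps(self.to_dict(exclude_timestamp), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "DesignReport":
        return cls(
            hypotheses=DesignHypotheses(**d["hypotheses"]),
            config=TrialConfig(**d["config"]),
            rules=StoppingRules(**d["rules"]),
            oc=OperatingCharacteristics(**d["oc"]),
            info=dict(d["info"]),
            seed=d["seed"],
            version=d["version"],
            timestamp=d.get("timestamp", ""),
        )

    @classmethod
    def from_json(cls, s: str) -> "DesignReport":
        return cls.from_dict(json.loads(s))

    def to_csv_row(self) -> dict:
        h, c, r, oc = self.hypotheses, self.config, self.rules, self.oc
        return {
            "r_nul": h.r_nul,
            "r_alt": h.r_alt,
            "ttp_nul": h.ttp_nul,
            "ttp_alt": h.ttp_alt,
            "n1": c.n1,
            "n2": c.n2,
            "r1_stop": r.r1_stop,
            "epd_stop": r.epd_stop,
            "r2_reject": r.r2_reject,
            "ttp2_reject": r.ttp2_reject,
            "power": oc.power,
            "alpha": oc.alpha,
            "en_nul": oc.en_nul,
            "pes_nul": oc.pes_nul,
            "en_alt": oc.en_alt,
            "pes_alt": oc.pes_alt,
        }


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


def run_design(hyps: DesignHypotheses, config: TrialConfig) -> DesignReport:
    """Execute the full CSR design search and wrap it in a report."""
    result: DesignResult = design_csr(hyps, config)
    return DesignReport(
        hypotheses=hyps,
        config=config,
        rules=result.rules,
        oc=result.oc,
        info=result.info,
        seed=config.seed,
        version=__version__,
        timestamp=_now(),
    )


def run_table(
    rows: Sequence[dict], defaults: Optional[dict] = None
) -> tuple[pd.DataFrame, list[DesignReport]]:
    """Run one design per hypothesis row; failures are flagged, not fatal.

    Each row is a flat dict of ``DesignHypotheses`` and ``TrialConfig``
    fields; ``defaults`` fills fields missing from a row.  Returns the
    aggregated table (failed rows carry an ``error`` message and NaN
    results) and the successful reports.
    """
    from .cli import split_params  # shared key routing, no CLI involved

    if not rows:
        raise ValueError("row list must contain at least one hypothesis row")
    records = []
    reports = []
    for i, row in enumerate(rows):
        merged = {**(defaults or {}), **row}
        try:
            hyps, config = split_params(merged)
            report = run_design(hyps, config)
        except Exception as exc:  # noqa: BLE001 - per-row failures are data
            logger.warning("table row %d failed: %s", i, exc)
            rec = {k: merged.get(k) for k in CSV_COLUMNS}
            rec["error"] = str(exc)
            records.append(rec)
            continue
        reports.append(report)
        rec = report.to_csv_row()
        rec["error"] = ""
        records.append(rec)
    frame = pd.DataFrame.from_records(records, columns=CSV_COLUMNS + ["error"])
    return frame, reports
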