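"""TSV dialects and the end-to-end scoring pipeline.

Screen TSV (UTF-8, tab-separated, header required)::

    line_id  males  females  [breakpoints]  [replicates]  [control]

``replicates`` holds semicolon-separated ``males,females`` pairs whose sums
must match the pooled counts; ``control`` (0/1) marks baseline outcrosses.
A breakpoints value of ``N/A`` also marks a control line.  The report writer
emits a table in the layout of the published screen table, one row per line
with the computed percentage, fold change and classification.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .screen import (
    CrossTally,
    ScreenConfig,
    ScreenRecord,
    ScreenSummary,
    display_fold,
    display_pct,
    score_screen,
    summarize_screen,
)

__all__ = [
    "ScreenValidationError",
    "read_screen_tsv",
    "write_screen_tsv",
    "write_screen_report",
    "run_pipeline",
    "PipelineResult",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("line_id", "males", "females")


class ScreenValidationError(ValueError):
    """Raised when a screen TSV fails validation; lists offending rows."""


def _parse_replicates(text: str):
    pairs = []
    for chunk in text.split(";"):
        m_text, f_text = chunk.split(",")
        pairs.append((int(m_text), int(f_text)))
    return tuple(pairs)


def read_screen_tsv(path: Union[str, Path]) -> List[CrossTally]:
    """Read and validate a screen TSV; malformed rows are reported together."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ScreenValidationError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    if df.empty:
        raise ScreenValidationError(f"{path}: no records")
    tallies: List[CrossTally] = []
    errors: List[str] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            males = int(row["males"])
            females = int(row["females"])
        except ValueError:
            errors.append(f"line {line_no} ({row['line_id']}): non-integer count")
            continue
        breakpoints = row.get("breakpoints", "") or None
        is_control = str(row.get("control", "")).strip() in ("1", "true", "True")
        if breakpoints in ("N/A", "NA"):
            breakpoints, is_control = None, True
        replicates = None
        if row.get("replicates", ""):
            try:
                replicates = _parse_replicates(row["replicates"])
            except ValueError:
                errors.append(f"line {line_no} ({row['line_id']}): malformed replicates")
                continue
        try:
            tallies.append(
                CrossTally(
                    line_id=row["line_id"],
                    males=males,
                    females=females,
                    breakpoints=breakpoints,
                    replicates=replicates,
                    is_control=is_control,
                )
            )
        except ValueError as exc:
            errors.append(f"line {line_no}: {exc}")
    if errors:
        raise ScreenValidationError(f"{path}: " + "; ".join(errors))
    return tallies


def write_screen_tsv(tallies: Sequence[CrossTally], path: Union[str, Path]) -> None:
    """Write the canonical screen TSV (read/write round-trips byte-for-byte)."""
    rows = ["line_id\tbreakpoints\tmales\tfemales\tcontrol"]
    for t in tallies:
        bp = "N/A" if t.is_control and t.breakpoints is None else (t.breakpoints or "")
        rows.append(f"{t.line_id}\t{bp}\t{t.males}\t{t.females}\t{int(t.is_control)}")
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def write_screen_report(
    records: Sequence[ScreenRecord], path: Union[str, Path]
) -> None:
    """Emit the scored table: counts, %, fold, class, p-value per line."""
    rows = [
        "line_id\tbreakpoints\tmales\tfemales\ttotal\tpct_males\tfold_change"
        "\tclassification\tp_value"
    ]
    for r in records:
        t = r.tally
        p = "" if r.p_value is None else f"{r.p_value:.4g}"
        rows.append(
            f"{t.line_id}\t{t.breakpoints or ''}\t{t.males}\t{t.females}\t{t.total}"
            f"\t{display_pct(r.pct_males)}\t{display_fold(r.fold_change)}"
            f"\t{r.classification}\t{p}"
        )
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class PipelineResult:
    records: List[ScreenRecord]
    summary: ScreenSummary
    report_path: Optional[Path]
    summary_path: Optional[Path]


def _file_checksum(path: Union[str, Path]) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def run_pipeline(
    screen_path: Union[str, Path],
    out_dir: Optional[Union[str, Path]] = None,
    config: ScreenConfig = ScreenConfig(),
) -> PipelineResult:
    """Score -> classify -> summarize one screen TSV, optionally writing files.

    Writes ``screen_report.tsv`` and ``summary.json`` into ``out_dir`` (created
    if absent).  The summary JSON carries the baseline, recomputed mean/SD and
    class counts plus the input checksum for provenance.
    """
    logger.info("scoring %s (sha256 %s)", screen_path, _file_checksum(screen_path))
    tallies = read_screen_tsv(screen_path)
    records = score_screen(tallies, config)
    summary = summarize_screen(records, config)
    report_path = summary_path = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report_path = out / "screen_report.tsv"
        summary_path = out / "summary.json"
        write_screen_report(records, report_path)
        payload: Dict[str, object] = {
            "n_lines": summary.n_lines,
            "baseline_pct": summary.baseline_pct,
            "mean_pct": round(summary.mean_pct, 4),
            "sd_pct": round(summary.sd_pct, 4),
            "n_suppressors": summary.n_suppressors,
            "n_enhancers": summary.n_enhancers,
            "threshold_mode": config.threshold_mode,
            "input_sha256": _file_checksum(screen_path),
        }
        summary_path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    return PipelineResult(
        records=records, summary=summary,
        report_path=report_path, summary_path=summary_path,
    )
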