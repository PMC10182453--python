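"""Plain-text IO for logs, sessions, and synthetic-world artifacts.

Query logs travel as (optionally gzipped) UTF-8 TSV with columns
(user_id, ISO-8601 UTC timestamp, region_id, space-joined query tokens,
semicolon-joined domain:position clicks); sessions are emitted as JSONL.
"""

from __future__ import annotations

import datetime as _dt
import gzip
import json
from pathlib import Path
from typing import Iterable, Sequence

from .intent_labels import INTENT_NAMES
from .sessions import LogRecord, Session

__all__ = [
    "write_logs_tsv",
    "read_logs_tsv",
    "sessions_to_jsonl",
    "write_world",
]


def _open(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t", encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def _format_ts(ts: float) -> str:
    return _dt.datetime.fromtimestamp(int(ts), tz=_dt.timezone.utc).strftime(
        "%Y-%m-%dT%H:%M:%S"
    )


def _parse_ts(text: str) -> float:
    return (
        _dt.datetime.strptime(text, "%Y-%m-%dT%H:%M:%S")
        .replace(tzinfo=_dt.timezone.utc)
        .timestamp()
    )


def write_logs_tsv(records: Iterable[LogRecord], path: str | Path) -> None:
    with _open(path, "w") as fh:
        for r in records:
            clicks = ";".join(f"{dom}:{pos}" for dom, pos in r.clicks)
            fh.write(
                f"{r.user_id}\t{_format_ts(r.timestamp)}\t{r.region_id}\t"
                f"{' '.join(r.tokens)}\t{clicks}\n"
            )


def read_logs_tsv(path: str | Path) -> list[LogRecord]:
    records = []
    with _open(path, "r") as fh:
        for line in fh:
            user, ts, region, query, clicks = line.rstrip("\n").split("\t")
            parsed = tuple(
                (dom, int(pos))
                for dom, _, pos in (c.partition(":") for c in clicks.split(";") if c)
            )
            records.append(
                LogRecord(
                    user_id=user,
                    timestamp=_parse_ts(ts),
                    region_id=int(region),
                    tokens=tuple(query.split()),
                    clicks=parsed,
                )
            )
    return records


def sessions_to_jsonl(sessions: Sequence[Session], path: str | Path) -> None:
    with _open(path, "w") as fh:
        for s in sessions:
            fh.write(
                json.dumps(
                    {
                        "user_id": s.user_id,
                        "record_ids": list(s.record_ids),
                        "key_indices": list(s.key_indices),
                        "disease_ids": sorted(s.disease_ids),
                        "region_id": s.region_id,
                        "period_id": s.period_id,
                        "intent": s.intent,
                    }
                )
                + "\n"
            )


def write_world(world, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic world as logs.tsv, lexicon.tsv, incidence.csv and
    ground_truth.json; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "logs": outdir / "logs.tsv",
        "lexicon": outdir / "lexicon.tsv",
        "incidence": outdir / "incidence.csv",
        "panel": outdir / "panel.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_logs_tsv(world.records, paths["logs"])
    world.lexicon.to_tsv(paths["lexicon"])
    world.incidence.to_csv(paths["incidence"], index=False)
    world.truth.panel.to_csv(paths["panel"], index=False)
    truth = world.truth
    paths["ground_truth"].write_text(
        json.dumps(
            {
                "session_intents": [
                    INTENT_NAMES[c] for c in truth.session_intents
                ],
                "session_record_ids": truth.session_record_ids,
                "key_record_ids": sorted(truth.key_record_ids),
                "coefficients": {
                    k: getattr(truth.coeffs, k).tolist()
                    for k in ("alpha_d", "theta_d", "alpha_n", "theta_n", "beta", "phi")
                },
            }
        )
    )
    return paths
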