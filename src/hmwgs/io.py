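"""Flat-file I/O for pipeline tables (TSV, '#'-prefixed header comments)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import __version__
from .calling import GenotypeCall
from .reference import LOCI
from .simulate import AuxiliaryEvidence

_LOCUS_KEY = {"Glu-A1": "a1", "Glu-B1": "b1", "Glu-D1": "d1"}


def config_hash(obj) -> str:
    """Stable short hash of a (dataclass-like or mapping) configuration."""
    if hasattr(obj, "__dataclass_fields__"):
        payload = {k: getattr(obj, k) for k in obj.__dataclass_fields__}
    else:
        payload = dict(obj)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def header_comments(seed: int | None = None, cfg_hash: str | None = None) -> list[str]:
    out = [f"hmwgs v{__version__}"]
    if seed is not None:
        out.append(f"seed={seed}")
    if cfg_hash is not None:
        out.append(f"config_hash={cfg_hash}")
    return out


def write_table(df: pd.DataFrame, path: str | Path,
                comments: Iterable[str] = ()) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       dtype=str, keep_default_na=False)


def genotype_calls_to_frame(calls: Sequence[GenotypeCall]) -> pd.DataFrame:
    rows = []
    for call in calls:
        row = {"line_id": call.line_id}
        for locus in LOCI:
            key = _LOCUS_KEY[locus]
            subs = sorted(call.subunits[locus])
            pend = ["|".join(sorted(c)) for c in call.unresolved[locus]]
            row[f"{key}_subunits"] = ";".join(subs + pend)
            row[f"{key}_symbol"] = call.symbols[locus]
            row[f"{key}_display"] = call.displays[locus]
        row["flags"] = ";".join(sorted(call.flags))
        row["evidence_notes"] = " | ".join(call.evidence_notes)
        rows.append(row)
    return pd.DataFrame(rows)


def evidence_to_frame(records: Sequence[tuple]) -> pd.DataFrame:
    """``records``: iterable of (line_id, AuxiliaryEvidence)."""
    return pd.DataFrame([
        {"line_id": line_id,
         "gel_confirmed": ";".join(sorted(ev.gel_confirmed)),
         "pcr_7oe": ev.pcr_7oe}
        for line_id, ev in records
    ])


def evidence_from_frame(df: pd.DataFrame) -> dict:
    out = {}
    for row in df.itertuples(index=False):
        gel = frozenset(s for s in row.gel_confirmed.split(";") if s)
        out[row.line_id] = AuxiliaryEvidence(gel_confirmed=gel,
                                             pcr_7oe=row.pcr_7oe)
    return out
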