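"""Per-feature %ID and percent alignment length from BLAST tabular output.

Running BLAST is outside this package's scope; it consumes the standard
12-column tabular dialect (outfmt 6) produced elsewhere, keeps the top hit
per query under an e-value threshold, and converts alignment lengths into
percent of the probe length (which may exceed 100 when insertions inflate
the alignment).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AnalysisError, FormatError
from .synthetic import NO_HIT

BLAST_COLUMNS = [
    "query_id", "subject_id", "pct_identity", "align_length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "evalue", "bitscore",
]


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    pct_identity: float
    align_length: int
    evalue: float
    bitscore: float


def parse_blast_tabular(path: str | Path) -> list[BlastHit]:
    """Parse a 12-column BLAST tabular file into hits.

    Malformed rows (wrong column count, non-numeric fields) raise
    :class:`FormatError` with their line numbers; an empty file yields an
    empty list.
    """
    hits: list[BlastHit] = []
    bad: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{Path(path).name}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                hits.append(
                    BlastHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        align_length=int(fields[3]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError:
                bad.append(lineno)
    if bad:
        raise FormatError(f"{Path(path).name}: malformed numeric fields on line(s) {bad}")
    return hits


def top_hits(
    hits: list[BlastHit],
    probe_lengths: dict[str, float] | pd.Series,
    evalue_max: float = 1e-14,
) -> pd.DataFrame:
    """Best hit per query at the e-value threshold; percent alignment length.

    The top hit minimizes e-value, with ties broken by larger bit score and
    then input order.  pct_align = 100 * alignment_length / probe_length and
    may exceed 100.  Queries with no passing hit are reported with the
    ``NoHit`` sentinel (NaN values, hit=False).
    """
    if isinstance(probe_lengths, pd.Series):
        probe_lengths = probe_lengths.to_dict()
    queries = list(dict.fromkeys(h.query_id for h in hits))
    missing = [q for q in queries if q not in probe_lengths]
    if missing:
        raise AnalysisError(f"probe length unknown for query(ies): {', '.join(missing)}")
    best: dict[str, tuple] = {}
    for idx, h in enumerate(hits):
        if h.evalue > evalue_max:
            continue
        key = (h.evalue, -h.bitscore, idx)
        if h.query_id not in best or key < best[h.query_id][0]:
            best[h.query_id] = (key, h)
    rows = []
    for q in queries:
        if q in best:
            h = best[q][1]
            rows.append(
                {
                    "feature_id": q,
                    "pct_id": h.pct_identity,
                    "pct_align": 100.0 * h.align_length / probe_lengths[q],
                    "hit": True,
                }
            )
        else:
            rows.append({"feature_id": q, "pct_id": np.nan, "pct_align": np.nan, "hit": False})
    return pd.DataFrame(rows)


def write_homology_tsv(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    for col in ("pct_id", "pct_align"):
        out[col] = [NO_HIT if not h else repr(float(v)) for h, v in zip(out["hit"], out[col])]
    out.drop(columns=["hit"]).to_csv(path, sep="\t", index=False)
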