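"""Reading, quality filtering, background correction and loess normalization.

Turns per-array two-channel scans into an oriented, normalized matrix of
M = log2(heterologous/platform) values.  Normalization is anchored on a set
of highly conserved features (>= ~95 %ID) so that genuinely diverged features
do not drag the within-array loess fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import FormatError, NormalizationError, PreprocessingError
from .synthetic import SCAN_COLUMNS, ArrayScan


def read_array_scan(path: str | Path) -> ArrayScan:
    """Parse one GPR-like TSV scan file.

    Header lines are ``# key: value`` (``array_id``, ``dye_swapped``); the
    body is tab-separated with columns feature_id, F635, B635, F532, B532,
    flag.  Unknown columns are ignored; a missing mandatory column raises
    :class:`FormatError` naming it.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, sep="\t", dtype={"feature_id": str}, float_precision="round_trip")
    missing = [c for c in SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"scan file {path.name} missing column(s): {', '.join(missing)}")
    data = df.set_index("feature_id")[["F635", "B635", "F532", "B532", "flag"]]
    if (data[["F635", "B635", "F532", "B532"]] < 0).any().any():
        raise FormatError(f"scan file {path.name} contains negative intensities")
    return ArrayScan(
        array_id=meta.get("array_id", path.stem),
        dye_swapped=meta.get("dye_swapped", "false").lower() in ("true", "1", "yes"),
        data=data,
    )


def quality_filter(scan: ArrayScan, k_sd: float = 2.0) -> pd.Series:
    """Per-feature usability: both channels' foreground at or above
    background + ``k_sd`` * SD(background), and a non-negative flag.

    The background SD is taken per array and channel across features.  The
    boundary is inclusive.  Returns a boolean Series indexed by feature id.
    """
    d = scan.data
    sd635 = float(d["B635"].std(ddof=1))
    sd532 = float(d["B532"].std(ddof=1))
    ok = (
        (d["F635"] >= d["B635"] + k_sd * sd635)
        & (d["F532"] >= d["B532"] + k_sd * sd532)
        & (d["flag"] >= 0)
    )
    if not ok.any():
        warnings.warn(f"array {scan.array_id}: all observations filtered out", stacklevel=2)
    return ok


def background_correct_minimum(scan: ArrayScan) -> pd.DataFrame:
    """Subtract background; rescue non-positive values ("minimum" rule).

    Per channel, corrected = foreground - background; any corrected value
    <= 0 is replaced by half the smallest positive corrected value on that
    array/channel, so every corrected intensity is strictly positive.
    """
    out = {}
    for ch, (f, b) in {"R": ("F635", "B635"), "G": ("F532", "B532")}.items():
        corr = (scan.data[f] - scan.data[b]).astype(float)
        pos = corr[corr > 0]
        if pos.empty:
            raise PreprocessingError(
                f"array {scan.array_id}, channel {f}: no positive background-corrected value"
            )
        corr[corr <= 0] = pos.min() / 2.0
        out[ch] = corr
    return pd.DataFrame(out)


@dataclass
class RatioMatrix:
    """Features x arrays of normalized, oriented M values.

    ``M`` holds log2(het/platform) with NaN in unusable cells, ``usable`` the
    per-cell mask, ``analyzed`` the multi-array survival flag, and ``A`` the
    average log2 intensities (diagnostic).
    """

    M: pd.DataFrame
    usable: pd.DataFrame
    analyzed: pd.Series
    A: pd.DataFrame | None = None

    def subset_arrays(self, columns, min_arrays: int = 2) -> "RatioMatrix":
        cols = list(columns)
        usable = self.usable[cols]
        return RatioMatrix(
            M=self.M[cols],
            usable=usable,
            analyzed=usable.sum(axis=1) >= min_arrays,
            A=self.A[cols] if self.A is not None else None,
        )

    def write_tsv(self, path) -> None:
        out = self.M.copy()
        out["analyzed"] = self.analyzed.astype(int)
        out.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def read_tsv(cls, path) -> "RatioMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        analyzed = df.pop("analyzed").astype(bool)
        return cls(M=df, usable=df.notna(), analyzed=analyzed)


def _loess_curve(x: np.ndarray, y: np.ndarray, x_out: np.ndarray, span: float, it: int) -> np.ndarray:
    fit = lowess(y, x, frac=span, it=it, return_sorted=True)
    return np.interp(x_out, fit[:, 0], fit[:, 1])


def normalize_loess_conserved(
    scans: list[ArrayScan],
    annotations: pd.DataFrame,
    span: float = 0.25,
    iterations: int = 3,
    k_sd: float = 2.0,
    min_arrays: int = 2,
    min_conserved: int = 50,
) -> RatioMatrix:
    """Within-array loess normalization anchored on conserved features.

    Per array: M and A are computed from background-corrected intensities, a
    robust loess curve of M on A is fitted on usable conserved features only
    and subtracted from all features, the conserved-set median is removed,
    and dye-swapped arrays are negated so every column reads
    log2(heterologous/platform).  Features usable on >= ``min_arrays`` arrays
    are flagged as analyzed.
    """
    ann = annotations.set_index("feature_id")
    conserved_ids = set(ann.index[ann["conserved"] == 1])
    m_cols, u_cols, a_cols = {}, {}, {}
    for scan in scans:
        usable = quality_filter(scan, k_sd=k_sd)
        corr = background_correct_minimum(scan)
        m = np.log2(corr["R"].to_numpy() / corr["G"].to_numpy())
        a = 0.5 * np.log2(corr["R"].to_numpy() * corr["G"].to_numpy())
        cons = usable.to_numpy() & scan.data.index.isin(conserved_ids)
        if cons.sum() < min_conserved:
            raise NormalizationError(
                f"array {scan.array_id}: only {int(cons.sum())} usable conserved features "
                f"(need >= {min_conserved})"
            )
        m = m - _loess_curve(a[cons], m[cons], a, span, iterations)
        m = m - np.median(m[cons])
        if scan.dye_swapped:
            m = -m
        m = pd.Series(m, index=scan.data.index)
        m[~usable] = np.nan
        m_cols[scan.array_id] = m
        u_cols[scan.array_id] = usable
        a_cols[scan.array_id] = pd.Series(a, index=scan.data.index)
    M = pd.DataFrame(m_cols)
    usable_df = pd.DataFrame(u_cols)
    return RatioMatrix(
        M=M,
        usable=usable_df,
        analyzed=usable_df.sum(axis=1) >= min_arrays,
        A=pd.DataFrame(a_cols),
    )
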