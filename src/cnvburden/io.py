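"""Readers and writers for every external format the pipeline touches.

Formats
-------
* PennCNV ``rawcnv`` call files — one call per line::

      chr8:25073452-25074806 numsnp=6 length=1,355 state2,cn=1 S001 \
          startsnp=rs123 endsnp=rs456 conf=15.0

  Coordinates on disk are 1-based inclusive.  The trailing snp/conf tokens
  are optional; the ``state`` token is parsed but only ``cn=`` is
  authoritative.
* Sample sheets — CSV or TSV with header ``sample_id, group, lrr_sd,
  baf_drift, waviness[, n_calls]``; ``group`` is ``case`` or ``control``.
* Transcript tables — UCSC refGene-style TSV with at least ``name, chrom,
  txStart, txEnd, name2`` (0-based half-open on disk, as UCSC tables are).
* Gene lists — one symbol per line, ``#`` comments allowed.
* Results tables — TSV with a header and configurable float precision.

Coordinate convention
---------------------
All DataFrames returned by this module carry ``start``/``end`` in the
internal **0-based half-open** convention, so interval arithmetic downstream
is uniform.  Writers convert back to each format's native convention.
Chromosome names are kept verbatim; calls and genes match by exact string
equality.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from cnvburden.errors import ParseError, SchemaError, ValidationError

PathLike = Union[str, Path]

#: DataFrame columns produced by :func:`read_penncnv_calls`.
CALL_COLUMNS = [
    "sample_id",
    "chrom",
    "start",
    "end",
    "copy_number",
    "n_probes",
    "length_bp",
    "confidence",
]

VALID_COPY_NUMBERS = frozenset({0, 1, 3, 4})

_RAWCNV_RE = re.compile(
    r"^(?P<chrom>\S+):(?P<start>\d[\d,]*)-(?P<end>\d[\d,]*)"
    r"\s+numsnp=(?P<numsnp>\d[\d,]*)"
    r"\s+length=(?P<length>\d[\d,]*)"
    r"\s+state(?P<state>\d+),cn=(?P<cn>\d+)"
    r"\s+(?P<sample>\S+)"
    r"(?:\s+startsnp=(?P<startsnp>\S+))?"
    r"(?:\s+endsnp=(?P<endsnp>\S+))?"
    r"(?:\s+conf=(?P<conf>[-+0-9.eE]+))?"
    r"\s*$"
)


def _empty_calls() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": pd.Series(dtype=str),
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "copy_number": pd.Series(dtype=np.int64),
            "n_probes": pd.Series(dtype=np.int64),
            "length_bp": pd.Series(dtype=np.int64),
            "confidence": pd.Series(dtype=float),
        }
    )


def read_penncnv_calls(path: PathLike) -> pd.DataFrame:
    """Parse a PennCNV ``rawcnv`` file into a call table.

    Returns a DataFrame with columns :data:`CALL_COLUMNS`, one row per input
    line in input order, coordinates converted to 0-based half-open.
    ``length_bp`` is derived from the coordinates (``end - start``); a
    mismatching ``length=`` token triggers a warning, not an error.

    Raises
    ------
    ParseError
        If a non-empty line does not match the rawcnv dialect (the message
        names the 1-based line number).
    ValidationError
        If ``cn`` is outside ``{0..4}`` or equals 2 (a call is by definition
        a departure from the diploid state).
    """
    rows = []
    length_mismatches = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            m = _RAWCNV_RE.match(line.strip())
            if m is None:
                raise ParseError(
                    f"{path}: line {lineno}: not a valid rawcnv record: {line.strip()!r}"
                )
            cn = int(m["cn"])
            if cn > 4:
                raise ValidationError(
                    f"{path}: line {lineno}: copy number {cn} outside 0..4"
                )
            if cn == 2:
                raise ValidationError(
                    f"{path}: line {lineno}: cn=2 is diploid, not a CNV call"
                )
            start1 = int(m["start"].replace(",", ""))
            end1 = int(m["end"].replace(",", ""))
            if start1 > end1:
                raise ValidationError(
                    f"{path}: line {lineno}: start {start1} > end {end1}"
                )
            length_bp = end1 - start1 + 1
            if int(m["length"].replace(",", "")) != length_bp:
                length_mismatches += 1
            rows.append(
                (
                    m["sample"],
                    m["chrom"],
                    start1 - 1,  # to 0-based half-open
                    end1,
                    cn,
                    int(m["numsnp"].replace(",", "")),
                    length_bp,
                    float(m["conf"]) if m["conf"] is not None else np.nan,
                )
            )
    if length_mismatches:
        warnings.warn(
            f"{path}: {length_mismatches} call(s) have a length= token that "
            "disagrees with the coordinates; coordinate-derived lengths are used",
            stacklevel=2,
        )
    if not rows:
        return _empty_calls()
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def write_penncnv_calls(calls: pd.DataFrame, path: PathLike) -> None:
    """Write a call table in the rawcnv dialect read by :func:`read_penncnv_calls`.

    The ``state`` token is reconstructed from the copy number with PennCNV's
    state numbering (cn 0,1,3,4 -> state 1,2,5,6).
    """
    state_of_cn = {0: 1, 1: 2, 3: 5, 4: 6}
    with open(path, "w") as fh:
        for row in calls.itertuples(index=False):
            cn = int(row.copy_number)
            if cn not in VALID_COPY_NUMBERS:
                raise ValidationError(f"invalid copy number {cn} in call table")
            start1 = int(row.start) + 1
            end1 = int(row.end)
            line = (
                f"{row.chrom}:{start1}-{end1} numsnp={int(row.n_probes)} "
                f"length={end1 - start1 + 1} state{state_of_cn[cn]},cn={cn} "
                f"{row.sample_id}"
            )
            conf = getattr(row, "confidence", np.nan)
            if conf is not None and np.isfinite(conf):
                line += f" conf={conf:g}"
            fh.write(line + "\n")


SAMPLE_SHEET_COLUMNS = ["sample_id", "group", "lrr_sd", "baf_drift", "waviness"]
VALID_GROUPS = frozenset({"case", "control"})


def read_sample_sheet(path: PathLike) -> pd.DataFrame:
    """Read a case/control sample sheet with per-sample array QC metrics.

    Accepts comma- or tab-separated text with a header.  Required columns:
    ``sample_id, group, lrr_sd, baf_drift, waviness``; an optional
    ``n_calls`` column carries the raw PennCNV call count per sample.

    Raises
    ------
    SchemaError
        If a required column is missing.
    ValidationError
        On duplicate sample ids or a group label outside {case, control}.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype={"sample_id": str})
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: sample sheet missing column(s) {missing}")
    dupes = df["sample_id"][df["sample_id"].duplicated()].unique()
    if len(dupes):
        raise ValidationError(f"{path}: duplicate sample_id(s): {list(dupes)}")
    bad_groups = set(df["group"].unique()) - VALID_GROUPS
    if bad_groups:
        raise ValidationError(
            f"{path}: unknown group label(s) {sorted(bad_groups)}; expected case/control"
        )
    for col in ("lrr_sd", "baf_drift", "waviness"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    if "n_calls" in df.columns:
        df["n_calls"] = pd.to_numeric(df["n_calls"], errors="raise").astype(int)
    return df.reset_index(drop=True)


TRANSCRIPT_COLUMNS = ["transcript_id", "gene_symbol", "chrom", "tx_start", "tx_end"]
_REQUIRED_REFGENE = ["name", "chrom", "txStart", "txEnd", "name2"]


def read_transcript_table(path: PathLike) -> pd.DataFrame:
    """Read a UCSC refGene-style transcript table (TSV with header).

    UCSC coordinates are already 0-based half-open, so no conversion is
    applied; rows with ``txStart >= txEnd`` are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "chrom": str, "name2": str})
    missing = [c for c in _REQUIRED_REFGENE if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: transcript table missing column(s) {missing}")
    out = pd.DataFrame(
        {
            "transcript_id": df["name"].astype(str),
            "gene_symbol": df["name2"].astype(str),
            "chrom": df["chrom"].astype(str),
            "tx_start": pd.to_numeric(df["txStart"], errors="raise").astype(np.int64),
            "tx_end": pd.to_numeric(df["txEnd"], errors="raise").astype(np.int64),
        }
    )
    bad = out["tx_start"] >= out["tx_end"]
    if bad.any():
        first = out.index[bad][0]
        raise ValidationError(
            f"{path}: transcript {out.at[first, 'transcript_id']} has "
            f"tx_start >= tx_end ({out.at[first, 'tx_start']} >= {out.at[first, 'tx_end']})"
        )
    return out


def read_gene_list(path: PathLike) -> list[str]:
    """Read a plain-text gene list: one symbol per line, ``#`` comments skipped."""
    symbols = []
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                symbols.append(sym)
    return symbols


def write_results_table(
    rows: pd.DataFrame, path: PathLike, float_precision: int = 6
) -> None:
    """Write a result table as TSV with explicit floating precision.

    ``float_precision`` is the number of significant digits used for float
    columns (``%.<p>g``), so round-tripping the file reproduces all values at
    the rendered precision.
    """
    rows.to_csv(path, sep="\t", index=False, float_format=f"%.{float_precision}g")


def read_results_table(path: PathLike) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t")


def classify_state(copy_number: Union[int, Sequence[int], np.ndarray]):
    """Map copy number to its state class: {0,1} -> ``loss``, {3,4} -> ``gain``."""
    arr = np.asarray(copy_number)
    if not np.isin(arr, list(VALID_COPY_NUMBERS)).all():
        raise ValidationError(f"copy numbers outside {{0,1,3,4}}: {np.unique(arr)}")
    out = np.where(arr <= 1, "loss", "gain")
    if out.ndim == 0:
        return out.item()
    return out
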