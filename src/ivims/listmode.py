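"""Reader/writer for the list-mode acquisition dialect.

Three plain-TSV stream kinds share one container format:

* ``hits``  (``.imslm.tsv``)  — tracker pixel hits:
  event_id, t, detector_id, iu, iv, x, y, z
* ``spm``   (``.spm.tsv``)    — beam spot-monitor crossings:
  event_id, t, x, y, z
* ``truth`` (``.truth.tsv``)  — generator ground truth:
  event_id, species, origin_class, x, y, z

Files start with a comment-prefixed metadata block::

    # ivims-listmode v1
    # kind: hits
    # seed: 42
    # geometry_hash: ab12...

followed by a tab-separated header line and data rows.  Times are integer
nanoseconds, event ids 64-bit integers.  The acquisition contract is that
rows arrive sorted by (event_id, t); the writer enforces it and the reader
never reorders.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterator

import pandas as pd

__all__ = ["write_listmode", "read_listmode", "ListmodeFormatError", "COLUMNS"]

FORMAT_VERSION = "1"
MAGIC = "# ivims-listmode v"

COLUMNS = {
    "hits": ["event_id", "t", "detector_id", "iu", "iv", "x", "y", "z"],
    "spm": ["event_id", "t", "x", "y", "z"],
    "truth": ["event_id", "species", "origin_class", "x", "y", "z"],
}
_INT_COLS = {"event_id", "t", "detector_id", "iu", "iv"}


class ListmodeFormatError(ValueError):
    """Raised for malformed, truncated or out-of-contract list-mode files."""


def _check_sorted(df: pd.DataFrame, kind: str) -> None:
    if kind == "truth" or df.empty:
        key = df["event_id"] if "event_id" in df else None
        if key is not None and not key.is_monotonic_increasing:
            raise ListmodeFormatError("truth stream must be sorted by event_id")
        return
    if not (
        df["event_id"].is_monotonic_increasing
        and df.groupby("event_id", sort=False)["t"].apply(lambda s: s.is_monotonic_increasing).all()
    ):
        raise ListmodeFormatError(f"{kind} stream must be sorted by (event_id, t)")


def write_listmode(
    df: pd.DataFrame, path: str | Path, kind: str, metadata: dict | None = None
) -> Path:
    """Write one stream to a TSV file with a metadata header block.

    ``df`` must contain the columns for ``kind`` (extra columns are dropped)
    and be sorted by (event_id, t); unsorted input raises, since sortedness
    is the acquisition contract downstream consumers rely on.
    """
    if kind not in COLUMNS:
        raise ValueError(f"unknown stream kind {kind!r}; expected one of {sorted(COLUMNS)}")
    cols = COLUMNS[kind]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ListmodeFormatError(f"{kind} stream missing columns: {missing}")
    df = df[cols]
    if "t" in df.columns and not df.empty and (df["t"] < 0).any():
        raise ListmodeFormatError("timestamps must be non-negative")
    _check_sorted(df, kind)

    path = Path(path)
    buf = io.StringIO()
    buf.write(f"{MAGIC}{FORMAT_VERSION}\n")
    buf.write(f"# kind: {kind}\n")
    for k, v in (metadata or {}).items():
        buf.write(f"# {k}: {v}\n")
    df.to_csv(buf, sep="\t", index=False, float_format="%.6f")
    path.write_text(buf.getvalue())
    return path


def _parse_header(path: Path) -> tuple[dict, str, int]:
    meta: dict[str, str] = {}
    n_meta = 0
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(MAGIC):
            raise ListmodeFormatError(f"{path}: not an ivims list-mode file")
        version = first[len(MAGIC):].strip()
        if version != FORMAT_VERSION:
            raise ListmodeFormatError(f"{path}: unsupported format version {version!r}")
        n_meta = 1
        for line in fh:
            if not line.startswith("#"):
                break
            n_meta += 1
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
    kind = meta.pop("kind", None)
    if kind not in COLUMNS:
        raise ListmodeFormatError(f"{path}: missing or unknown 'kind' in metadata")
    return meta, kind, n_meta


def _validate_chunk(df: pd.DataFrame, kind: str, meta: dict, path: Path, row_offset: int) -> None:
    cols = COLUMNS[kind]
    if list(df.columns) != cols:
        raise ListmodeFormatError(f"{path}: expected columns {cols}, found {list(df.columns)}")
    if df.empty:
        return
    for c in cols:
        if c in _INT_COLS and not pd.api.types.is_integer_dtype(df[c]):
            bad = df.index[df[c].isna() | (df[c] != df[c].round())]
            line = row_offset + (int(bad[0]) if len(bad) else 0)
            raise ListmodeFormatError(f"{path}: malformed integer in column {c!r} near line {line}")
    if "t" in df.columns and not df.empty and (df["t"] < 0).any():
        raise ListmodeFormatError(f"{path}: negative timestamp")
    if kind == "hits" and "n_u" in meta and "n_v" in meta and not df.empty:
        n_u, n_v = int(meta["n_u"]), int(meta["n_v"])
        bad = (df["iu"] < 0) | (df["iu"] >= n_u) | (df["iv"] < 0) | (df["iv"] >= n_v)
        if bad.any():
            line = row_offset + int(df.index[bad][0] - df.index[0])
            raise ListmodeFormatError(
                f"{path}: pixel index outside the {n_u}x{n_v} grid at line {line}"
            )


def read_listmode(
    path: str | Path, chunksize: int | None = None
) -> tuple[pd.DataFrame, dict] | tuple[Iterator[pd.DataFrame], dict]:
    """Read a list-mode TSV; returns ``(frame, metadata)``.

    With ``chunksize`` set, returns a constant-memory iterator of validated
    chunks instead of one frame.  Rows are never reordered.  Validation
    failures raise :class:`ListmodeFormatError` naming the offending line;
    a stored geometry hash is surfaced in the metadata for the caller to
    cross-check.
    """
    path = Path(path)
    meta, kind, n_meta = _parse_header(path)
    meta["kind"] = kind

    def _read(cs):
        try:
            return pd.read_csv(path, sep="\t", skiprows=n_meta, chunksize=cs)
        except pd.errors.ParserError as exc:
            raise ListmodeFormatError(f"{path}: malformed TSV body: {exc}") from exc

    data_start = n_meta + 2  # 1-based line number of the first data row

    if chunksize is None:
        try:
            df = pd.read_csv(path, sep="\t", skiprows=n_meta)
        except pd.errors.ParserError as exc:
            raise ListmodeFormatError(f"{path}: malformed TSV body: {exc}") from exc
        except pd.errors.EmptyDataError as exc:
            raise ListmodeFormatError(f"{path}: truncated file (no header row)") from exc
        _validate_chunk(df, kind, meta, path, data_start)
        return df, meta

    def _iter():
        offset = data_start
        for chunk in _read(chunksize):
            chunk = chunk.reset_index(drop=True)
            _validate_chunk(chunk, kind, meta, path, offset)
            offset += len(chunk)
            yield chunk

    return _iter(), meta
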