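"""CSV ingestion and emission of amplification-curve tables.

Two dialects:

* long — columns ``well_id, cycle, fluorescence`` (+ optional
  ``known_copies``), one row per well per cycle;
* wide — first column ``cycle``, one further column per well.

Cycles are 1-based; within a well they must be complete (no gaps) and free
of duplicates, and every fluorescence value must be present and finite —
instrument exports are complete tables, so a hole is an ingestion error
naming the well and cycle.  Known copy numbers can ride along in the long
dialect or come from a separate metadata CSV (``well_id, known_copies``).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IngestionError
from .preprocess import AmplificationCurve
from .quantify import DilutionSeries

__all__ = ["read_curves", "write_curves", "read_metadata", "curves_to_frame"]

_LONG_REQUIRED = {"well_id", "cycle", "fluorescence"}


def _detect_dialect(df: pd.DataFrame) -> str:
    cols = {c.strip().lower() for c in df.columns}
    if _LONG_REQUIRED <= cols:
        return "long"
    if df.columns[0].strip().lower() == "cycle":
        return "wide"
    raise IngestionError(
        "cannot detect dialect: need columns well_id/cycle/fluorescence (long) "
        "or a leading 'cycle' column (wide)"
    )


def _validate_well(well: str, cycles: np.ndarray, fluo: np.ndarray) -> None:
    order = np.argsort(cycles)
    cycles, fluo = cycles[order], fluo[order]
    dup = pd.Series(cycles).duplicated()
    if dup.any():
        raise IngestionError(f"well {well!r}: duplicate rows for cycle {int(cycles[dup.idxmax()])}")
    for c, v in zip(cycles, fluo):
        if not np.isfinite(v):
            raise IngestionError(f"well {well!r}: missing fluorescence at cycle {int(c)}")
    gaps = np.flatnonzero(np.diff(cycles) != 1)
    if gaps.size:
        missing = int(cycles[gaps[0]]) + 1
        raise IngestionError(f"well {well!r}: gap in cycles at cycle {missing}")


def read_metadata(path) -> dict[str, float]:
    """Read a ``well_id, known_copies`` CSV into a mapping."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"well_id", "known_copies"} <= set(df.columns):
        raise IngestionError("metadata CSV needs columns well_id and known_copies")
    return {str(r.well_id): float(r.known_copies) for r in df.itertuples()}


def read_curves(
    path, dialect: str = "auto", metadata=None
) -> list[AmplificationCurve]:
    """Read and validate amplification curves from a CSV file.

    ``metadata`` may be a path to a metadata CSV or a well->copies mapping;
    wells named there but absent from the data raise a warning, not an
    error.
    """
    df = pd.read_csv(path)
    if dialect == "auto":
        dialect = _detect_dialect(df)
    if dialect not in ("long", "wide"):
        raise IngestionError(f"unknown dialect {dialect!r}")

    known: dict[str, float] = {}
    if metadata is not None:
        known = read_metadata(metadata) if isinstance(metadata, (str, Path)) else dict(metadata)

    curves: list[AmplificationCurve] = []
    if dialect == "long":
        df.columns = [c.strip().lower() for c in df.columns]
        if not _LONG_REQUIRED <= set(df.columns):
            raise IngestionError("long CSV needs columns well_id, cycle, fluorescence")
        has_copies = "known_copies" in df.columns
        for well, grp in df.groupby("well_id", sort=False):
            cycles = grp["cycle"].to_numpy(dtype=int)
            fluo = grp["fluorescence"].to_numpy(dtype=float)
            _validate_well(str(well), cycles, fluo)
            order = np.argsort(cycles)
            kc = known.get(str(well))
            if kc is None and has_copies:
                vals = grp["known_copies"].dropna().unique()
                if len(vals) > 1:
                    raise IngestionError(f"well {well!r}: conflicting known_copies values")
                if len(vals) == 1:
                    kc = float(vals[0])
            curves.append(
                AmplificationCurve(
                    well_id=str(well),
                    cycles=cycles[order],
                    fluorescence=fluo[order],
                    known_copies=kc,
                )
            )
    else:
        cycle_col = df.columns[0]
        cycles_all = df[cycle_col].to_numpy(dtype=int)
        for well in df.columns[1:]:
            fluo = df[well].to_numpy(dtype=float)
            _validate_well(str(well), cycles_all.copy(), fluo)
            order = np.argsort(cycles_all)
            curves.append(
                AmplificationCurve(
                    well_id=str(well),
                    cycles=cycles_all[order],
                    fluorescence=fluo[order],
                    known_copies=known.get(str(well)),
                )
            )

    missing = set(known) - {c.well_id for c in curves}
    if missing:
        warnings.warn(
            f"metadata names wells absent from the data: {sorted(missing)}", stacklevel=2
        )
    return curves


def curves_to_frame(curves, dialect: str = "long") -> pd.DataFrame:
    """Render curves as a long or wide DataFrame (lossless round trip)."""
    if dialect == "long":
        rows = []
        any_copies = any(c.known_copies is not None for c in curves)
        for c in curves:
            for cyc, fl in zip(c.cycles, c.fluorescence):
                row = {"well_id": c.well_id, "cycle": int(cyc), "fluorescence": float(fl)}
                if any_copies:
                    row["known_copies"] = c.known_copies
                rows.append(row)
        return pd.DataFrame(rows)
    if dialect == "wide":
        frames = {
            c.well_id: pd.Series(c.fluorescence, index=c.cycles) for c in curves
        }
        wide = pd.DataFrame(frames)
        wide.index.name = "cycle"
        return wide.reset_index()
    raise IngestionError(f"unknown dialect {dialect!r}")


def write_curves(curves, path, dialect: str = "long") -> None:
    """Write curves to CSV in the requested dialect."""
    curves_to_frame(curves, dialect).to_csv(path, index=False)


def curves_to_series(curves) -> DilutionSeries:
    """Bundle curves into a dilution series container."""
    return DilutionSeries(curves=list(curves))
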