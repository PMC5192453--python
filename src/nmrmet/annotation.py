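"""Chemical-shift annotation: map bucket ppm positions to metabolite names.

The shipped fixture library lists each metabolite's resonance positions as
semicolon-separated points and/or ranges; point shifts are expanded to a
+/- tolerance window, ranges are kept as given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LibraryEntry",
    "MetaboliteLibrary",
    "load_library",
    "default_library_path",
    "assign_buckets",
    "metabolite_bucket_indices",
]

#: Half-width (ppm) of the window around a point chemical shift.
DEFAULT_TOLERANCE = 0.005


@dataclass(frozen=True)
class LibraryEntry:
    name: str
    regions: tuple[tuple[float, float], ...]  # closed ppm intervals
    label: str = ""

    def contains(self, ppm: float) -> bool:
        return any(lo <= ppm <= hi for lo, hi in self.regions)


@dataclass
class MetaboliteLibrary:
    entries: list[LibraryEntry]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("metabolite names must be unique")
        for e in self.entries:
            for lo, hi in e.regions:
                if not (0.0 <= lo <= hi <= 10.0):
                    raise ValueError(f"{e.name}: region [{lo}, {hi}] outside 0-10 ppm")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for e in self.entries:
            parts = []
            for lo, hi in e.regions:
                parts.append(f"{lo:g}" if lo == hi else f"{lo:g}-{hi:g}")
            rows.append({"name": e.name, "regions": "; ".join(parts), "label": e.label})
        pd.DataFrame(rows).to_csv(path, index=False)


def default_library_path() -> Path:
    return Path(str(resources.files("nmrmet").joinpath("data/table1_library.csv")))


def _parse_region(token: str, tolerance: float, row: int) -> tuple[float, float]:
    token = token.strip().replace("–", "-")  # en-dash ranges
    if not token:
        raise ValueError(f"row {row}: empty region token")
    # a range has a '-' that is not a leading sign
    if "-" in token[1:]:
        cut = token.index("-", 1)
        lo_s, hi_s = token[:cut], token[cut + 1 :]
        try:
            lo, hi = float(lo_s), float(hi_s)
        except ValueError:
            raise ValueError(f"row {row}: malformed range {token!r}") from None
        if lo > hi:
            raise ValueError(f"row {row}: range bounds out of order in {token!r}")
        return lo, hi  # ranges kept as given
    try:
        center = float(token)
    except ValueError:
        raise ValueError(f"row {row}: malformed shift {token!r}") from None
    return center - tolerance, center + tolerance


def _merge_overlaps(name: str, regions: list[tuple[float, float]]) -> tuple[tuple[float, float], ...]:
    regions = sorted(regions)
    merged: list[tuple[float, float]] = []
    for lo, hi in regions:
        if merged and lo <= merged[-1][1]:
            warnings.warn(f"{name}: overlapping regions merged")
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return tuple(merged)


def load_library(path: str | Path | None = None, tolerance: float = DEFAULT_TOLERANCE) -> MetaboliteLibrary:
    """Load a CSV library with columns ``name``, ``regions`` and optional
    ``label``.  ``regions`` is semicolon-separated; "2.41" becomes the window
    [2.41 - tol, 2.41 + tol] while "3.23-4.0" stays a closed interval."""
    if path is None:
        path = default_library_path()
    df = pd.read_csv(path)
    if df.empty and {"name", "regions"} - set(df.columns):
        return MetaboliteLibrary(entries=[])
    for col in ("name", "regions"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    entries = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        name = str(row.name).strip()
        if not name or name == "nan":
            raise ValueError(f"row {row_no}: missing metabolite name")
        tokens = str(row.regions).split(";")
        regions = [_parse_region(tok, tolerance, row_no) for tok in tokens if tok.strip()]
        if not regions:
            raise ValueError(f"row {row_no}: no regions for {name!r}")
        label = str(getattr(row, "label", "")) if hasattr(row, "label") else ""
        if label == "nan":
            label = ""
        entries.append(LibraryEntry(name=name, regions=_merge_overlaps(name, regions), label=label))
    return MetaboliteLibrary(entries=entries)


def assign_buckets(
    library: MetaboliteLibrary, bucket_centers: Sequence[float]
) -> dict[float, set[str]]:
    """Map every bucket center to the set of metabolites whose region
    contains it (possibly several; empty set when unassigned)."""
    centers = np.asarray(bucket_centers, dtype=float)
    if centers.size > 1 and np.any(np.diff(centers) < 0):
        raise ValueError("bucket centers must be sorted")
    out: dict[float, set[str]] = {float(c): set() for c in centers}
    for entry in library:
        for lo, hi in entry.regions:
            inside = (centers >= lo) & (centers <= hi)
            for c in centers[inside]:
                out[float(c)].add(entry.name)
    return out


def metabolite_bucket_indices(
    library: MetaboliteLibrary, bucket_centers: Sequence[float]
) -> dict[str, list[int]]:
    """Inverse view of :func:`assign_buckets`: metabolite -> bucket indices."""
    centers = np.asarray(bucket_centers, dtype=float)
    out: dict[str, list[int]] = {}
    for entry in library:
        idx: list[int] = []
        for lo, hi in entry.regions:
            idx.extend(np.nonzero((centers >= lo) & (centers <= hi))[0].tolist())
        out[entry.name] = sorted(set(idx))
    return out
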