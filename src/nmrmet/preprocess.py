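"""Spectral preprocessing: reading, referencing, bucketing, normalization, scaling.

Turns a directory of frequency-domain 1D spectra into the samples x buckets
matrix used by the latent-variable models.  The default parameters are
0.001 ppm buckets with the 4.6-5.0 ppm water region removed, probabilistic
quotient normalization against the cohort median spectrum, and
centering + unit-variance scaling of the bucket columns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "BucketTable",
    "read_spectrum",
    "write_spectrum",
    "reference_to_acetate",
    "bucket",
    "build_table",
    "pqn_normalize",
    "scale",
]

#: Default water-suppression artifact region removed from every bucket table.
WATER_REGION = (4.6, 5.0)

#: Relative intensity floor (fraction of the reference maximum) below which a
#: bucket is excluded from the probabilistic quotient.  At 0.001 ppm
#: resolution most buckets hold baseline noise or inter-peak Lorentzian
#: shoulders; noise ratios swamp the median and shoulder buckets track the
#: total signal rather than any single metabolite, so the quotient is taken
#: over clear peak buckets only.
PQN_EPSILON_REL = 0.05


@dataclass
class Spectrum:
    """One sample's frequency-domain trace on a strictly increasing ppm axis."""

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D")
        if self.ppm.shape != self.intensity.shape:
            raise ValueError(
                f"axis/intensity length mismatch: {self.ppm.size} vs {self.intensity.size}"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite intensities")
        if self.ppm.size > 1 and np.any(np.diff(self.ppm) <= 0):
            raise ValueError("ppm axis must be strictly increasing")

    def __len__(self) -> int:
        return self.ppm.size


@dataclass
class BucketTable:
    """Samples x buckets matrix with its normalization / scaling state.

    ``values`` rows follow ``sample_ids``; columns follow ``bucket_centers``
    (ppm of each bucket midpoint).  ``excluded_regions`` records the ppm
    intervals whose buckets were dropped (water by default).
    """

    sample_ids: list[str]
    bucket_centers: np.ndarray
    values: np.ndarray
    normalization: str = "raw"  # {"raw", "pqn"}
    scaling: str = "none"  # {"none", "center", "center_unit_variance"}
    excluded_regions: list[tuple[float, float]] = field(default_factory=list)
    quotients: np.ndarray | None = None
    empty_buckets: np.ndarray | None = None
    degenerate_columns: np.ndarray | None = None
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bucket_centers = np.asarray(self.bucket_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), self.bucket_centers.size):
            raise ValueError("values shape does not match sample_ids x bucket_centers")
        for lo, hi in self.excluded_regions:
            inside = (self.bucket_centers >= lo) & (self.bucket_centers <= hi)
            if inside.any():
                raise ValueError(f"bucket centers found inside excluded region [{lo}, {hi}]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_buckets(self) -> int:
        return self.bucket_centers.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"{c:.4f}" for c in self.bucket_centers],
        )
        return df

    def to_csv(self, path: str | Path) -> None:
        """Write the matrix as CSV plus a JSON sidecar with the state."""
        path = Path(path)
        self.to_frame().to_csv(path)
        sidecar = {
            "normalization": self.normalization,
            "scaling": self.scaling,
            "excluded_regions": [list(r) for r in self.excluded_regions],
            "bucket_centers": self.bucket_centers.tolist(),
            "quotients": None if self.quotients is None else self.quotients.tolist(),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "BucketTable":
        path = Path(path)
        df = pd.read_csv(path, index_col=0)
        sidecar_path = path.with_suffix(path.suffix + ".json")
        normalization, scaling = "raw", "none"
        excluded: list[tuple[float, float]] = []
        quotients = None
        centers = np.array([float(c) for c in df.columns])
        if sidecar_path.exists():
            meta = json.loads(sidecar_path.read_text())
            normalization = meta.get("normalization", "raw")
            scaling = meta.get("scaling", "none")
            excluded = [tuple(r) for r in meta.get("excluded_regions", [])]
            if meta.get("bucket_centers"):
                centers = np.asarray(meta["bucket_centers"], dtype=float)
            if meta.get("quotients") is not None:
                quotients = np.asarray(meta["quotients"], dtype=float)
        return cls(
            sample_ids=[str(i) for i in df.index],
            bucket_centers=centers,
            values=df.to_numpy(dtype=float),
            normalization=normalization,
            scaling=scaling,
            excluded_regions=excluded,
            quotients=quotients,
        )


def read_spectrum(path: str | Path, sample_id: str | None = None) -> Spectrum:
    """Read a two-column (ppm, intensity) text file.

    Leading non-numeric lines are treated as headers and skipped; a
    non-numeric line after numeric data has started is an error reported
    with its 1-based line number.  The axis is re-sorted ascending if needed.
    """
    path = Path(path)
    ppm: list[float] = []
    intensity: list[float] = []
    seen_data = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.replace(",", " ").split()
            try:
                vals = [float(f) for f in fields[:2]]
                if len(vals) < 2:
                    raise ValueError
            except ValueError:
                if seen_data:
                    raise ValueError(f"{path}: non-numeric row at line {lineno}") from None
                continue  # header
            ppm.append(vals[0])
            intensity.append(vals[1])
            seen_data = True
    if not ppm:
        raise ValueError(f"{path}: no numeric data rows")
    p = np.asarray(ppm)
    y = np.asarray(intensity)
    order = np.argsort(p, kind="stable")
    p, y = p[order], y[order]
    if np.any(np.diff(p) == 0):
        raise ValueError(f"{path}: duplicated ppm values")
    return Spectrum(ppm=p, intensity=y, sample_id=sample_id or path.stem)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write (ppm, intensity) as whitespace-separated text, round-trip exact."""
    np.savetxt(path, np.column_stack([spectrum.ppm, spectrum.intensity]), fmt="%.17g")


def reference_to_acetate(
    s: Spectrum,
    target: float = 1.92,
    search_window: tuple[float, float] = (1.82, 2.02),
    min_snr: float = 5.0,
) -> Spectrum:
    """Shift the ppm axis so the tallest peak in the window sits at ``target``.

    If the window holds no peak clearly above its own baseline (max below
    ``min_snr`` robust sds over the window median) the spectrum is returned
    unshifted with a warning.
    """
    lo, hi = search_window
    mask = (s.ppm >= lo) & (s.ppm <= hi)
    if not mask.any():
        warnings.warn("referencing window contains no data points; spectrum unshifted")
        return s
    win = s.intensity[mask]
    med = np.median(win)
    mad = np.median(np.abs(win - med))
    floor = med + min_snr * 1.4826 * mad
    apex_idx = int(np.argmax(win))
    if win[apex_idx] <= floor and mad > 0:
        warnings.warn("no peak above noise floor in referencing window; spectrum unshifted")
        return s
    apex_ppm = s.ppm[mask][apex_idx]
    shift = target - apex_ppm
    return Spectrum(ppm=s.ppm + shift, intensity=s.intensity.copy(), sample_id=s.sample_id)


def bucket(
    s: Spectrum,
    width: float = 0.001,
    exclude: Sequence[tuple[float, float]] = (WATER_REGION,),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sum grid intensities into fixed-width ppm buckets.

    The bucket grid is anchored at the spectrum's minimum ppm with half-open
    [left, left + width) intervals; each bucket is labelled by its center.
    Buckets whose center lies inside an excluded interval are dropped.

    Returns ``(centers, values, empty)`` where ``empty`` flags buckets that
    contained no grid point (their value is 0).
    """
    if width <= 0:
        raise ValueError("bucket width must be positive")
    if len(s) > 1:
        step = np.diff(s.ppm).max()
        if step >= width:
            raise ValueError(f"grid step {step:g} must be finer than bucket width {width:g}")
    p0 = s.ppm[0]
    # epsilon absorbs float error when grid points sit on bucket boundaries
    idx = np.floor((s.ppm - p0) / width + 1e-9).astype(int)
    n_buckets = int(idx.max()) + 1
    values = np.bincount(idx, weights=s.intensity, minlength=n_buckets)
    counts = np.bincount(idx, minlength=n_buckets)
    centers = p0 + (np.arange(n_buckets) + 0.5) * width
    keep = np.ones(n_buckets, dtype=bool)
    for lo, hi in exclude:
        keep &= ~((centers >= lo) & (centers <= hi))
    return centers[keep], values[keep], counts[keep] == 0


def build_table(
    spectra: Iterable[Spectrum],
    width: float = 0.001,
    exclude: Sequence[tuple[float, float]] = (WATER_REGION,),
) -> BucketTable:
    """Bucket a cohort of same-axis spectra into one raw BucketTable."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra given")
    centers_ref: np.ndarray | None = None
    rows, empties, ids = [], [], []
    for s in spectra:
        centers, values, empty = bucket(s, width=width, exclude=exclude)
        if centers_ref is None:
            centers_ref = centers
        elif centers.size != centers_ref.size or not np.allclose(centers, centers_ref):
            raise ValueError(f"sample {s.sample_id!r} has an incompatible ppm grid")
        rows.append(values)
        empties.append(empty)
        ids.append(s.sample_id)
    assert centers_ref is not None
    return BucketTable(
        sample_ids=ids,
        bucket_centers=centers_ref,
        values=np.vstack(rows),
        excluded_regions=[tuple(r) for r in exclude],
        empty_buckets=np.vstack(empties).any(axis=0),
    )


#: Gaussian kernel width (in log-ratio units, i.e. a relative spread) used to
#: locate the most probable quotient.  Fixed rather than data-driven so that
#: well-separated clusters of genuinely changed buckets cannot widen the
#: kernel and drag the peak.
PQN_MODE_BANDWIDTH = 0.02


def _mode_quotient(ratios: np.ndarray, bandwidth: float = PQN_MODE_BANDWIDTH) -> float:
    """Most probable quotient: fixed-bandwidth KDE peak of the log-ratio
    distribution, refined as the median of the ratios within one bandwidth
    of the peak.

    Falls back to the plain median when the ratios are (near-)constant or
    too few for a density estimate.
    """
    r = np.log(ratios[ratios > 0])
    if r.size < 10 or np.std(r) < 1e-12:
        return float(np.median(ratios))
    grid = np.linspace(r.min(), r.max(), 1024)
    density = np.exp(-0.5 * ((grid[:, None] - r[None, :]) / bandwidth) ** 2).sum(axis=1)
    peak = grid[int(np.argmax(density))]
    near = r[np.abs(r - peak) <= bandwidth]
    return float(np.exp(np.median(near))) if near.size else float(np.exp(peak))


def pqn_normalize(
    X: BucketTable,
    reference: str = "median_spectrum",
    epsilon_rel: float = PQN_EPSILON_REL,
    estimator: str = "mode",
    stable_fraction: float | None = 0.25,
) -> BucketTable:
    """Probabilistic quotient normalization.

    Each sample is divided by its most probable bucket-wise ratio to a
    reference spectrum (the cohort column-median by default, or a named
    sample).  Only buckets where the reference exceeds
    ``epsilon_rel * max(reference)`` enter the quotient.

    ``estimator`` selects how the quotient is located on the ratio
    distribution: ``"mode"`` (default; the density peak, robust when a
    sizeable minority of signal buckets carries real group changes) or
    ``"median"`` (the textbook estimator).  The two coincide whenever the
    ratios are unimodal-symmetric, including every pure-dilution case.

    When ``stable_fraction`` is set, the quotient is further restricted to
    the fraction of included buckets with the lowest cross-sample spread of
    log-ratios.  A per-sample dilution shifts every bucket's log-ratio
    equally, so this ranking is dilution-blind; buckets carrying real group
    changes have inflated spread and drop out of the quotient, which is
    exactly the "majority of unchanged variables" assumption PQN needs.
    """
    if X.scaling != "none":
        raise ValueError("PQN must be applied before scaling")
    if estimator not in ("mode", "median"):
        raise ValueError(f"unknown quotient estimator {estimator!r}")
    V = X.values
    if reference == "median_spectrum":
        ref = np.median(V, axis=0)
    else:
        try:
            ref = V[X.sample_ids.index(reference)]
        except ValueError:
            raise ValueError(f"reference sample {reference!r} not in table") from None
    eps = epsilon_rel * np.max(ref) if np.max(ref) > 0 else 0.0
    mask = ref > eps
    if not mask.any():
        raise ValueError("reference spectrum has no buckets above the quotient floor")
    if stable_fraction is not None and 0 < stable_fraction < 1 and X.n_samples >= 3:
        with np.errstate(divide="ignore", invalid="ignore"):
            logr = np.log(np.where(V[:, mask] > 0, V[:, mask], np.nan) / ref[mask])
        spread = np.nanstd(logr, axis=0)
        spread = np.where(np.isfinite(spread), spread, np.inf)
        n_keep = max(int(round(stable_fraction * mask.sum())), min(50, int(mask.sum())))
        cutoff = np.partition(spread, n_keep - 1)[n_keep - 1]
        stable = np.zeros_like(mask)
        stable[np.flatnonzero(mask)[spread <= cutoff]] = True
        if stable.any():
            mask = stable
    quotients = np.empty(X.n_samples)
    out = np.empty_like(V)
    for i, sid in enumerate(X.sample_ids):
        row = V[i]
        if not np.any(row[mask] != 0):
            raise ValueError(f"sample {sid!r} has all-zero overlap with the PQN reference")
        ratios = row[mask] / ref[mask]
        q = _mode_quotient(ratios) if estimator == "mode" else float(np.median(ratios))
        if not np.isfinite(q) or q <= 0:
            raise ValueError(f"sample {sid!r} yields a non-positive quotient ({q!r})")
        quotients[i] = q
        out[i] = row / q
    return replace(X, values=out, normalization="pqn", quotients=quotients)


def scale(X: BucketTable, method: str = "center_unit_variance") -> BucketTable:
    """Column-wise centering, optionally followed by unit-variance scaling.

    Columns with zero spread are left centered only and flagged in
    ``degenerate_columns``.  Population (ddof=0) standard deviations are used.
    """
    if method not in ("center", "center_unit_variance"):
        raise ValueError(f"unknown scaling method {method!r}")
    if X.n_samples < 2:
        raise ValueError("scaling requires at least 2 samples")
    V = X.values
    means = V.mean(axis=0)
    centered = V - means
    sds = V.std(axis=0)
    degenerate = sds < 1e-12
    if method == "center":
        out = centered
        used_sds = np.ones_like(sds)
    else:
        used_sds = np.where(degenerate, 1.0, sds)
        out = centered / used_sds
    return replace(
        X,
        values=out,
        scaling=method,
        degenerate_columns=degenerate,
        column_means=means,
        column_sds=used_sds,
    )
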