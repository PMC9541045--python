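"""Reading and writing Raman spectra and cohort metadata.

Two plain-CSV dialects are supported as the canonical interchange formats:

* **long** — one row per (acquisition, wavenumber) pair with the metadata
  repeated on every row; header exactly
  ``acquisition_id,subject_id,group,site,covariate,wavenumber,intensity``.
* **wide** — one wavenumber column plus one intensity column per
  acquisition, with a sidecar ``<name>.meta.csv`` table keyed by
  acquisition id.  All spectra must share one wavenumber axis.

Axes are wavenumber shifts in cm^-1.  An empty covariate field means the
covariate (distance run, km) is absent, as for human biopsy samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumMetadata",
    "RamanSpectrum",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "LONG_COLUMNS",
    "META_COLUMNS",
]

LONG_COLUMNS = [
    "acquisition_id",
    "subject_id",
    "group",
    "site",
    "covariate",
    "wavenumber",
    "intensity",
]
META_COLUMNS = ["acquisition_id", "subject_id", "group", "site", "covariate"]


@dataclass(frozen=True)
class SpectrumMetadata:
    """Per-acquisition metadata: who, which group, where, and how far they ran."""

    subject_id: str
    group: str
    site: str = ""
    covariate: float | None = None
    acquisition_id: str = ""

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError("metadata mismatch: empty subject_id")
        if not self.group:
            raise ValueError("metadata mismatch: empty group")
        if self.covariate is not None and not math.isfinite(self.covariate):
            raise ValueError("metadata mismatch: non-finite covariate")


@dataclass
class RamanSpectrum:
    """One acquisition: a wavenumber axis (cm^-1) with intensities (counts)."""

    wavenumber: np.ndarray
    intensity: np.ndarray
    meta: SpectrumMetadata

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumber.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("axis error: wavenumber and intensity must be 1-D")
        if self.wavenumber.size < 2:
            raise ValueError("axis error: need at least 2 points")
        if self.wavenumber.size != self.intensity.size:
            raise ValueError("axis error: wavenumber/intensity length mismatch")
        if not np.all(np.diff(self.wavenumber) > 0):
            raise ValueError("axis error: wavenumber must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("parse error: non-finite intensity")

    def __len__(self) -> int:
        return self.wavenumber.size


@dataclass
class Cohort:
    """An ordered collection of spectra with subject/group structure."""

    spectra: list[RamanSpectrum] = field(default_factory=list)
    name: str = "cohort"

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[RamanSpectrum]:
        return iter(self.spectra)

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.spectra:
            seen.setdefault(s.meta.group, None)
        return list(seen)

    @property
    def subjects(self) -> list[str]:
        """Distinct subject ids in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.spectra:
            seen.setdefault(s.meta.subject_id, None)
        return list(seen)

    def subset(self, groups: Sequence[str]) -> "Cohort":
        keep = set(groups)
        return Cohort(
            [s for s in self.spectra if s.meta.group in keep],
            name=self.name,
        )


def _meta_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.csv")


def _parse_covariate(value: object) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    try:
        return float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError) as exc:
        raise ValueError(f"parse error: bad covariate value {value!r}") from exc


def _format_covariate(value: float | None) -> str:
    return "" if value is None else repr(float(value))


def read_cohort(path: str | Path, layout: str = "long") -> Cohort:
    """Read a cohort from CSV.

    Parameters
    ----------
    path
        CSV file; for ``layout='wide'`` a sidecar ``<stem>.meta.csv`` must
        sit next to it.
    layout
        ``'long'`` or ``'wide'`` (see module docstring).

    Spectrum order follows file appearance; rows within a spectrum are
    sorted by wavenumber.  Duplicate (acquisition, wavenumber) pairs are an
    axis error.
    """
    path = Path(path)
    if layout == "long":
        return _read_long(path)
    if layout == "wide":
        return _read_wide(path)
    raise ValueError(f"unknown layout {layout!r}")


def _read_long(path: Path) -> Cohort:
    df = pd.read_csv(path, dtype={c: str for c in META_COLUMNS[:-1]})
    if list(df.columns) != LONG_COLUMNS:
        raise ValueError(
            f"parse error: expected columns {LONG_COLUMNS}, got {list(df.columns)}"
        )
    for col in ("wavenumber", "intensity"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"parse error: non-numeric {col} column")
    spectra: list[RamanSpectrum] = []
    # groupby(sort=False) preserves file appearance order of acquisitions
    for acq, block in df.groupby("acquisition_id", sort=False):
        block = block.sort_values("wavenumber", kind="stable")
        wn = block["wavenumber"].to_numpy(dtype=float)
        if np.any(np.diff(wn) == 0):
            raise ValueError(f"axis error: duplicate wavenumber in acquisition {acq}")
        cov_vals = {
            _parse_covariate(v) for v in block["covariate"].unique().tolist()
        }
        if len(cov_vals) != 1:
            raise ValueError(f"metadata mismatch: inconsistent covariate for {acq}")
        meta = SpectrumMetadata(
            subject_id=str(block["subject_id"].iloc[0]),
            group=str(block["group"].iloc[0]),
            site="" if pd.isna(block["site"].iloc[0]) else str(block["site"].iloc[0]),
            covariate=cov_vals.pop(),
            acquisition_id=str(acq),
        )
        spectra.append(
            RamanSpectrum(wn, block["intensity"].to_numpy(dtype=float), meta)
        )
    return Cohort(spectra, name=path.stem)


def _read_wide(path: Path) -> Cohort:
    meta_path = _meta_path(path)
    if not meta_path.exists():
        raise ValueError(f"metadata mismatch: sidecar {meta_path.name} not found")
    df = pd.read_csv(path)
    if df.columns[0] != "wavenumber":
        raise ValueError("parse error: first wide-layout column must be 'wavenumber'")
    mdf = pd.read_csv(meta_path, dtype={c: str for c in META_COLUMNS[:-1]})
    if list(mdf.columns) != META_COLUMNS:
        raise ValueError(
            f"parse error: expected metadata columns {META_COLUMNS}, got {list(mdf.columns)}"
        )
    meta_by_acq = {str(r.acquisition_id): r for r in mdf.itertuples(index=False)}
    order = np.argsort(df["wavenumber"].to_numpy(), kind="stable")
    df = df.iloc[order]
    wn = df["wavenumber"].to_numpy(dtype=float)
    if np.any(np.diff(wn) == 0):
        raise ValueError("axis error: duplicate wavenumber rows")
    spectra: list[RamanSpectrum] = []
    for acq in df.columns[1:]:
        if str(acq) not in meta_by_acq:
            raise ValueError(f"metadata mismatch: acquisition {acq!r} not in sidecar")
        row = meta_by_acq[str(acq)]
        if not pd.api.types.is_numeric_dtype(df[acq]):
            raise ValueError(f"parse error: non-numeric intensity column {acq!r}")
        meta = SpectrumMetadata(
            subject_id=str(row.subject_id),
            group=str(row.group),
            site="" if pd.isna(row.site) else str(row.site),
            covariate=_parse_covariate(row.covariate),
            acquisition_id=str(acq),
        )
        spectra.append(RamanSpectrum(wn.copy(), df[acq].to_numpy(dtype=float), meta))
    return Cohort(spectra, name=path.stem)


def write_cohort(cohort: Cohort, path: str | Path, layout: str = "long") -> None:
    """Write a cohort to CSV so that :func:`read_cohort` round-trips it."""
    path = Path(path)
    acq_ids = [s.meta.acquisition_id for s in cohort.spectra]
    if len(set(acq_ids)) != len(acq_ids):
        raise ValueError("metadata mismatch: duplicate acquisition ids")
    if layout == "long":
        frames = []
        for s in cohort.spectra:
            frames.append(
                pd.DataFrame(
                    {
                        "acquisition_id": s.meta.acquisition_id,
                        "subject_id": s.meta.subject_id,
                        "group": s.meta.group,
                        "site": s.meta.site,
                        "covariate": _format_covariate(s.meta.covariate),
                        "wavenumber": s.wavenumber,
                        "intensity": s.intensity,
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        return
    if layout == "wide":
        if not cohort.spectra:
            raise ValueError("axis error: empty cohort")
        wn0 = cohort.spectra[0].wavenumber
        for s in cohort.spectra[1:]:
            if s.wavenumber.shape != wn0.shape or not np.array_equal(s.wavenumber, wn0):
                raise ValueError("axes must match for wide layout")
        columns = {"wavenumber": wn0}
        columns.update(
            {s.meta.acquisition_id: s.intensity for s in cohort.spectra}
        )
        pd.DataFrame(columns).to_csv(path, index=False)
        pd.DataFrame(
            {
                "acquisition_id": [s.meta.acquisition_id for s in cohort.spectra],
                "subject_id": [s.meta.subject_id for s in cohort.spectra],
                "group": [s.meta.group for s in cohort.spectra],
                "site": [s.meta.site for s in cohort.spectra],
                "covariate": [
                    _format_covariate(s.meta.covariate) for s in cohort.spectra
                ],
            }
        ).to_csv(_meta_path(path), index=False)
        return
    raise ValueError(f"unknown layout {layout!r}")


def with_acquisition_ids(cohort: Cohort) -> Cohort:
    """Return a copy where any blank acquisition ids are filled in (a1, a2, ...)."""
    out = []
    for i, s in enumerate(cohort.spectra, start=1):
        meta = s.meta
        if not meta.acquisition_id:
            meta = replace(meta, acquisition_id=f"a{i}")
        out.append(RamanSpectrum(s.wavenumber, s.intensity, meta))
    return Cohort(out, name=cohort.name)
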