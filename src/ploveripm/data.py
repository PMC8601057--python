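"""Data streams for the plover integrated population model.

Five observation streams feed the model: shoreline population counts
(Texas/New Mexico), grid-cell counts and distance-sampling rows (Oklahoma),
nest records (clutch size and fate), and individual encounter histories from
capture-recapture-resight surveys.  Annual breeding-season covariates (Palmer
drought severity index, minimum temperature, wind speed) drive the demographic
regressions.  Streams are only partially aligned across regions and years, so
availability is tracked explicitly with boolean masks rather than imputed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

REGIONS = ("Texas", "New Mexico", "Oklahoma")
COHORTS = ("AF", "AM", "JF", "JM")
STREAMS = ("survey", "grid", "distance", "nest", "cmr")
COVARIATES = ("pdsi", "tmin", "wind")

__all__ = [
    "REGIONS",
    "COHORTS",
    "STREAMS",
    "COVARIATES",
    "SurveyDesign",
    "CountObservation",
    "GridCountObservation",
    "DistanceObservation",
    "NestRecord",
    "EncounterHistory",
    "CovariateRecord",
    "ObservationBundle",
    "read_stream",
    "write_stream",
    "standardize_covariates",
    "build_bundle",
    "load_design",
]


@dataclass(frozen=True)
class SurveyDesign:
    """Spatial/temporal layout of the study.

    The default design is three regions (Texas, New Mexico, Oklahoma)
    observed 1998-2018, with the Oklahoma salt flat divided into 668
    300 m x 300 m grid cells and a 30 m median detection distance for
    transect counts.
    """

    regions: tuple[str, ...] = REGIONS
    first_year: int = 1998
    last_year: int = 2018
    n_grids: int = 668
    median_distance: float = 30.0

    def __post_init__(self) -> None:
        if self.last_year < self.first_year:
            raise ValueError("last_year precedes first_year")
        if self.n_grids <= 0:
            raise ValueError("n_grids must be positive")
        if self.median_distance <= 0:
            raise ValueError("median_distance must be positive")
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("duplicate region identifiers")

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(range(self.first_year, self.last_year + 1))

    @property
    def n_years(self) -> int:
        return self.last_year - self.first_year + 1

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def region_index(self, region: str) -> int:
        try:
            return self.regions.index(region)
        except ValueError:
            raise ValueError(f"unknown region {region!r}") from None

    def year_index(self, year: int) -> int:
        if not (self.first_year <= year <= self.last_year):
            raise ValueError(f"year {year} outside design span "
                             f"{self.first_year}-{self.last_year}")
        return year - self.first_year


@dataclass(frozen=True)
class CountObservation:
    region: str
    year: int
    site: str
    date: int
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be non-negative")


@dataclass(frozen=True)
class GridCountObservation:
    region: str
    year: int
    grid: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be non-negative")


@dataclass(frozen=True)
class DistanceObservation:
    region: str
    year: int
    grid: str
    count: int
    distance: float

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


@dataclass(frozen=True)
class NestRecord:
    region: str
    year: int
    clutch_size: int
    fate: int

    def __post_init__(self) -> None:
        if self.clutch_size not in (1, 2, 3):
            raise ValueError(f"clutch size {self.clutch_size} not in {{1,2,3}}")
        if self.fate not in (0, 1):
            raise ValueError(f"fate {self.fate} not in {{0,1}}")


@dataclass(frozen=True)
class EncounterHistory:
    """One bird's 0/1 detection record, conditioned on first capture.

    ``detections`` spans the full design period; the entry for
    ``first_year`` must be 1 and all earlier entries 0.  ``cohort`` is the
    age-sex class at first capture (AF/AM adult, JF/JM juvenile).
    """

    individual_id: str
    cohort: str
    region: str
    first_year: int
    detections: tuple[int, ...]
    start_year: int

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"cohort {self.cohort!r} not one of {COHORTS}")
        f = self.first_year - self.start_year
        if not (0 <= f < len(self.detections)):
            raise ValueError("first_year outside detection span")
        if self.detections[f] != 1:
            raise ValueError("no detection recorded at first_year")
        if any(self.detections[:f]):
            raise ValueError("detection before first_year")
        if any(d not in (0, 1) for d in self.detections):
            raise ValueError("detections must be 0/1")


@dataclass(frozen=True)
class CovariateRecord:
    region: str
    year: int
    pdsi: float
    tmin: float
    wind: float
    pdsi_z: float | None = None
    tmin_z: float | None = None
    wind_z: float | None = None


# ---------------------------------------------------------------------------
# CSV dialects (column layouts mirroring the archived data files)

_DIALECTS = {
    "survey": ("year", "lake", "date", "count"),
    "grid": ("year", "grid", "count"),
    "distance": ("year", "grid", "count", "distance"),
    "nest": ("year", "region", "clutch", "fate"),
    "covariates": ("year", "palmer", "tmin", "wind"),
}


def _parse_int(value: str, row_no: int, col: str) -> int:
    try:
        return int(value.strip())
    except ValueError:
        raise ValueError(
            f"row {row_no}: cannot parse {col}={value!r} as integer") from None


def _parse_float(value: str, row_no: int, col: str) -> float:
    try:
        return float(value.strip())
    except ValueError:
        raise ValueError(
            f"row {row_no}: cannot parse {col}={value!r} as number") from None


def read_stream(path: str | Path, stream_kind: str, *,
                region: str | None = None,
                design: SurveyDesign | None = None) -> list:
    """Read one data stream from CSV into typed records.

    ``stream_kind`` is one of ``survey``, ``grid``, ``distance``, ``nest``,
    ``cmr`` or ``covariates``.  Files in the archival layout carry no region
    column for region-specific streams (survey/grid/distance/covariates); pass
    ``region`` for those, or include an extra leading ``region`` column.  A
    header-only file yields an empty list.  Malformed rows raise ``ValueError``
    naming the offending row.
    """
    path = Path(path)
    if stream_kind not in ("cmr",) and stream_kind not in _DIALECTS:
        raise ValueError(f"unknown stream kind {stream_kind!r}")
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = [h.strip() for h in next(reader)]
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected a header") from None
        rows = [r for r in reader if any(cell.strip() for cell in r)]

    if stream_kind == "cmr":
        return _parse_cmr(header, rows, design)

    expected = _DIALECTS[stream_kind]
    has_region = header and header[0] == "region"
    base = header[1:] if has_region else header
    # covariate files may carry extra columns (aet/prcp/tmax); keep only
    # the modelled ones
    if stream_kind == "covariates":
        required = set(expected)
        if not required.issubset(base):
            raise ValueError(
                f"{path}: header {base} missing columns {sorted(required - set(base))}")
        idx = {c: base.index(c) + (1 if has_region else 0) for c in expected}
    else:
        if tuple(base) != expected:
            raise ValueError(
                f"{path}: header {base} does not match {list(expected)} "
                f"for stream {stream_kind!r}")
        idx = {c: i + (1 if has_region else 0) for i, c in enumerate(expected)}

    records = []
    for row_no, row in enumerate(rows, start=2):
        if has_region:
            row_region = row[0].strip()
        elif region is not None:
            row_region = region
        elif stream_kind == "nest":
            row_region = None  # the nest dialect names its region per row
        else:
            raise ValueError(
                f"{path}: stream {stream_kind!r} has no region column; "
                "pass region=")
        get = lambda col: row[idx[col]]
        try:
            if stream_kind == "survey":
                rec = CountObservation(row_region,
                                       _parse_int(get("year"), row_no, "year"),
                                       get("lake").strip(),
                                       _parse_int(get("date"), row_no, "date"),
                                       _parse_int(get("count"), row_no, "count"))
            elif stream_kind == "grid":
                rec = GridCountObservation(row_region,
                                           _parse_int(get("year"), row_no, "year"),
                                           get("grid").strip(),
                                           _parse_int(get("count"), row_no, "count"))
            elif stream_kind == "distance":
                rec = DistanceObservation(row_region,
                                          _parse_int(get("year"), row_no, "year"),
                                          get("grid").strip(),
                                          _parse_int(get("count"), row_no, "count"),
                                          _parse_float(get("distance"), row_no,
                                                       "distance"))
            elif stream_kind == "nest":
                rec = NestRecord(get("region").strip(),
                                 _parse_int(get("year"), row_no, "year"),
                                 _parse_int(get("clutch"), row_no, "clutch"),
                                 _parse_int(get("fate"), row_no, "fate"))
            else:  # covariates
                rec = CovariateRecord(row_region,
                                      _parse_int(get("year"), row_no, "year"),
                                      _parse_float(get("palmer"), row_no, "palmer"),
                                      _parse_float(get("tmin"), row_no, "tmin"),
                                      _parse_float(get("wind"), row_no, "wind"))
        except IndexError:
            raise ValueError(f"{path}: row {row_no} has too few fields") from None
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from None
        records.append(rec)
    return records


def _parse_cmr(header: list[str], rows: list[list[str]],
               design: SurveyDesign | None) -> list[EncounterHistory]:
    fixed = ("id", "cohort", "region", "f")
    if tuple(header[:4]) != fixed:
        raise ValueError(f"encounter header must start with {list(fixed)}, "
                         f"got {header[:4]}")
    year_cols = header[4:]
    years = []
    for c in year_cols:
        if not c.startswith("year_"):
            raise ValueError(f"unexpected encounter column {c!r}")
        years.append(int(c[5:]))
    if years != list(range(years[0], years[0] + len(years))):
        raise ValueError("encounter year columns must be consecutive")
    start_year = years[0]
    if design is not None and (start_year != design.first_year
                               or years[-1] != design.last_year):
        raise ValueError("encounter year columns do not match the design span")
    records = []
    for row_no, row in enumerate(rows, start=2):
        if len(row) != 4 + len(years):
            raise ValueError(f"row {row_no}: expected {4 + len(years)} fields, "
                             f"got {len(row)}")
        det = tuple(_parse_int(v, row_no, "detection") for v in row[4:])
        try:
            rec = EncounterHistory(row[0].strip(), row[1].strip(),
                                   row[2].strip(),
                                   _parse_int(row[3], row_no, "f"),
                                   det, start_year)
        except ValueError as exc:
            raise ValueError(f"row {row_no}: {exc}") from None
        records.append(rec)
    return records


def write_stream(path: str | Path, records: Sequence, stream_kind: str,
                 *, design: SurveyDesign | None = None) -> None:
    """Write records to CSV in the matching dialect (with a region column)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if stream_kind == "cmr":
            if design is None:
                if records:
                    start = records[0].start_year
                    span = len(records[0].detections)
                else:
                    raise ValueError("design required to write an empty "
                                     "encounter stream")
            else:
                start, span = design.first_year, design.n_years
            writer.writerow(["id", "cohort", "region", "f"]
                            + [f"year_{start + k}" for k in range(span)])
            for r in records:
                writer.writerow([r.individual_id, r.cohort, r.region,
                                 r.first_year, *r.detections])
            return
        cols = _DIALECTS[stream_kind]
        # the nest dialect already carries its own region column
        header = list(cols) if stream_kind == "nest" else ["region", *cols]
        writer.writerow(header)
        for r in records:
            if stream_kind == "nest":
                writer.writerow([r.year, r.region, r.clutch_size, r.fate])
            elif stream_kind == "survey":
                writer.writerow([r.region, r.year, r.site, r.date, r.count])
            elif stream_kind == "grid":
                writer.writerow([r.region, r.year, r.grid, r.count])
            elif stream_kind == "distance":
                writer.writerow([r.region, r.year, r.grid, r.count,
                                 repr(float(r.distance))])
            elif stream_kind == "covariates":
                writer.writerow([r.region, r.year, repr(float(r.pdsi)),
                                 repr(float(r.tmin)), repr(float(r.wind))])
            else:
                raise ValueError(f"unknown stream kind {stream_kind!r}")


def standardize_covariates(records: Sequence[CovariateRecord],
                           ) -> list[CovariateRecord]:
    """Pooled z-scoring of the three covariates across all region-years.

    Each covariate is centred by its pooled mean and scaled by its pooled
    sample standard deviation (n-1 denominator), so the regression slopes
    of all regions live on one shared scale.  Raw values are retained.
    """
    if not records:
        return []
    out_cols = {}
    for cov in COVARIATES:
        x = np.array([getattr(r, cov) for r in records], dtype=float)
        if len(np.unique(x)) < 2:
            raise ValueError(f"covariate {cov!r} has zero variance; "
                             "cannot standardize")
        sd = x.std(ddof=1)
        out_cols[cov] = (x - x.mean()) / sd
    return [replace(r, pdsi_z=out_cols["pdsi"][k], tmin_z=out_cols["tmin"][k],
                    wind_z=out_cols["wind"][k])
            for k, r in enumerate(records)]


@dataclass
class ObservationBundle:
    """All five data streams aligned to one design, plus availability masks.

    ``availability[stream]`` is a boolean (n_regions, n_years) array marking
    the region-years in which that stream was collected.  Missing region-years
    are never imputed; the state-space model simply receives no likelihood
    contribution there.
    """

    design: SurveyDesign
    counts: list[CountObservation] = field(default_factory=list)
    grid_counts: list[GridCountObservation] = field(default_factory=list)
    distances: list[DistanceObservation] = field(default_factory=list)
    nests: list[NestRecord] = field(default_factory=list)
    encounters: list[EncounterHistory] = field(default_factory=list)
    covariates: list[CovariateRecord] = field(default_factory=list)
    availability: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.availability:
            self.availability = {
                s: np.zeros((self.design.n_regions, self.design.n_years),
                            dtype=bool)
                for s in STREAMS
            }

    def stream_records(self, stream: str) -> list:
        return {
            "survey": self.counts, "grid": self.grid_counts,
            "distance": self.distances, "nest": self.nests,
            "cmr": self.encounters,
        }[stream]

    def covariate_matrix(self) -> np.ndarray:
        """Standardized covariates as an (n_regions, n_years, 3) array."""
        d = self.design
        X = np.zeros((d.n_regions, d.n_years, 3))
        seen = np.zeros((d.n_regions, d.n_years), dtype=bool)
        for r in self.covariates:
            i, t = d.region_index(r.region), d.year_index(r.year)
            if r.pdsi_z is None:
                raise ValueError("covariates must be standardized before use; "
                                 "call standardize_covariates")
            X[i, t] = (r.pdsi_z, r.tmin_z, r.wind_z)
            seen[i, t] = True
        if not seen.all():
            missing = [(d.regions[i], d.years[t])
                       for i, t in zip(*np.where(~seen))]
            raise ValueError(f"missing covariates for region-years {missing[:5]}")
        return X

    def write(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for stream, records in [("survey", self.counts),
                                ("grid", self.grid_counts),
                                ("distance", self.distances),
                                ("nest", self.nests)]:
            p = directory / f"{stream}.csv"
            write_stream(p, records, stream)
            paths[stream] = p
        p = directory / "cmr.csv"
        write_stream(p, self.encounters, "cmr", design=self.design)
        paths["cmr"] = p
        p = directory / "covariates.csv"
        write_stream(p, self.covariates, "covariates")
        paths["covariates"] = p
        return paths


def build_bundle(design: SurveyDesign, *,
                 counts: Iterable[CountObservation] = (),
                 grid_counts: Iterable[GridCountObservation] = (),
                 distances: Iterable[DistanceObservation] = (),
                 nests: Iterable[NestRecord] = (),
                 encounters: Iterable[EncounterHistory] = (),
                 covariates: Iterable[CovariateRecord] = (),
                 standardize: bool = True) -> ObservationBundle:
    """Assemble the streams into a bundle with presence-derived masks.

    Every record must fall inside the design span and name a known region;
    the availability mask for each stream is true exactly at the region-years
    holding at least one record.  Encounter histories mark every year from
    first capture onward as informative for the mark-resight stream.
    """
    bundle = ObservationBundle(design=design,
                               counts=list(counts),
                               grid_counts=list(grid_counts),
                               distances=list(distances),
                               nests=list(nests),
                               encounters=list(encounters),
                               covariates=list(covariates))
    for stream in ("survey", "grid", "distance", "nest"):
        mask = bundle.availability[stream]
        for rec in bundle.stream_records(stream):
            mask[design.region_index(rec.region),
                 design.year_index(rec.year)] = True
    cmr_mask = bundle.availability["cmr"]
    for rec in bundle.encounters:
        i = design.region_index(rec.region)
        if rec.start_year != design.first_year \
                or len(rec.detections) != design.n_years:
            raise ValueError(f"encounter {rec.individual_id}: span does not "
                             "match design")
        design.year_index(rec.first_year)
        for t, det in enumerate(rec.detections):
            if det:
                cmr_mask[i, t] = True
    if standardize and bundle.covariates \
            and bundle.covariates[0].pdsi_z is None:
        bundle.covariates = standardize_covariates(bundle.covariates)
    for rec in bundle.covariates:
        design.region_index(rec.region)
        design.year_index(rec.year)
    return bundle


def load_design(path: str | Path) -> SurveyDesign:
    """Load a design config (YAML or JSON) declaring regions/span/constants."""
    import yaml

    with Path(path).open(encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return SurveyDesign(
        regions=tuple(cfg.get("regions", REGIONS)),
        first_year=int(cfg.get("first_year", 1998)),
        last_year=int(cfg.get("last_year", 2018)),
        n_grids=int(cfg.get("n_grids", 668)),
        median_distance=float(cfg.get("median_distance", 30.0)),
    )
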