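"""Survey tables, detection tensors, covariate preprocessing and design matrices.

The data model mirrors a repeat-visit trap survey: a set of sites (each
burned or unburned, with a site-level canopy-openness measurement), two or
more visits per site (each with floral counts, trap hours and a Julian
day), and a binary detection record per (species, site, visit).

Continuous covariates are z-scored before fitting; floral abundance is
log(x + 1)-transformed first because unburned forest sites can have zero
open flowers.  Every transform is recorded so fitted effects can be mapped
back to the original covariate scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurveyData",
    "DetectionTensor",
    "DesignInputs",
    "StandardizationRecord",
    "CaptureSummary",
    "SurveyDataError",
    "OCC_COVARIATES",
    "DET_COVARIATES",
    "read_survey_csv",
    "write_survey_csv",
    "pool_floral_counts",
    "build_design",
    "tally_captures",
    "load_table1_captures",
]

#: Default occupancy-side covariates (site level).
OCC_COVARIATES = (
    "burn_status",
    "canopy_openness",
    "burn_status:canopy_openness",
    "log_floral_abundance",
    "floral_richness",
)

#: Default detection-side covariates (site or visit level).
DET_COVARIATES = (
    "burn_status",
    "canopy_openness",
    "log_floral_abundance",
    "floral_richness",
    "trap_hours",
    "julian_day",
)

SITE_COLUMNS = ("site_id", "burn_status", "canopy_openness")
VISIT_COLUMNS = (
    "site_id",
    "visit_index",
    "floral_abundance",
    "floral_richness",
    "trap_hours",
    "julian_day",
)
DETECTION_COLUMNS = ("site_id", "visit_index", "species", "detected")


class SurveyDataError(ValueError):
    """Raised for malformed or referentially inconsistent survey inputs."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class DetectionTensor:
    """Binary detections indexed (species, site, visit) plus a visit mask.

    ``values[i, j, k]`` is 1 if species ``i`` was recorded at site ``j`` on
    visit ``k``; ``mask[j, k]`` is True where visit ``k`` to site ``j``
    actually occurred.  Values are forced to 0 outside the mask.
    """

    values: np.ndarray
    mask: np.ndarray
    species_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise SurveyDataError("detection values must be (species, site, visit)")
        if self.mask.shape != self.values.shape[1:]:
            raise SurveyDataError("mask shape must match (site, visit)")
        if not np.isin(self.values, (0, 1)).all():
            raise SurveyDataError("detections must be binary")
        if (self.values[:, ~self.mask] != 0).any():
            raise SurveyDataError("detections recorded for a visit that did not occur")
        if len(self.species_names) != self.values.shape[0]:
            raise SurveyDataError("species_names length mismatch")

    @property
    def n_species(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    @property
    def n_visits(self) -> int:
        return self.values.shape[2]


@dataclass
class SurveyData:
    """Aligned site table, visit table and detection tensor.

    Rows are canonicalized (sites sorted by ``site_id``, visits by
    ``(site_id, visit_index)``) so downstream results do not depend on the
    row order of the input CSVs.
    """

    sites: pd.DataFrame
    visits: pd.DataFrame
    detections: DetectionTensor

    def __post_init__(self) -> None:
        self.sites = _validate_sites(self.sites)
        self.visits = _validate_visits(self.visits, self.sites)
        order = np.argsort(self.sites["site_id"].to_numpy(), kind="stable")
        if not np.array_equal(order, np.arange(len(order))):
            self.detections = DetectionTensor(
                self.detections.values[:, order, :],
                self.detections.mask[order, :],
                self.detections.species_names,
            )
            self.sites = self.sites.iloc[order].reset_index(drop=True)
        self.visits = self.visits.sort_values(
            ["site_id", "visit_index"], kind="stable"
        ).reset_index(drop=True)
        if self.detections.n_sites != len(self.sites):
            raise SurveyDataError("detection tensor site dimension mismatch")
        max_visits = int(self.visits.groupby("site_id")["visit_index"].count().max())
        if self.detections.n_visits < max_visits:
            raise SurveyDataError("detection tensor visit dimension too small")

    @property
    def site_ids(self) -> list:
        return self.sites["site_id"].tolist()

    @property
    def species_names(self) -> list[str]:
        return self.detections.species_names

    def visit_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (site row index, visit column index) for each visit row."""
        site_pos = {s: i for i, s in enumerate(self.site_ids)}
        j = self.visits["site_id"].map(site_pos).to_numpy()
        k = self.visits["visit_index"].to_numpy() - 1
        return j, k


@dataclass(frozen=True)
class StandardizationRecord:
    """(mean, sd, transform) of one design column, for back-conversion."""

    mean: float
    sd: float
    transform: str = "identity"  # "identity" | "log1p"

    def standardize(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.log1p(x) if self.transform == "log1p" else np.asarray(x, float)
        return (x - self.mean) / self.sd

    def original(self, z: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(z, float) * self.sd + self.mean
        return np.expm1(x) if self.transform == "log1p" else x


@dataclass
class DesignInputs:
    """Design matrices for the occupancy and detection linear predictors.

    ``X_occ`` is (site, covariate); the species random intercept is handled
    by the model, not the design.  ``X_det`` is (site, visit, covariate)
    with rows defined only where ``mask`` is True.
    """

    X_occ: np.ndarray
    occ_names: tuple[str, ...]
    X_det: np.ndarray
    det_names: tuple[str, ...]
    mask: np.ndarray
    site_ids: list
    site_burn: np.ndarray
    standardization: dict[str, dict[str, StandardizationRecord]]

    @property
    def n_sites(self) -> int:
        return self.X_occ.shape[0]

    @property
    def n_visits(self) -> int:
        return self.X_det.shape[1]

    def occ_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X_occ, index=self.site_ids, columns=list(self.occ_names))

    def det_frame(self) -> pd.DataFrame:
        j, k = np.nonzero(self.mask)
        idx = pd.MultiIndex.from_arrays(
            [[self.site_ids[a] for a in j], k + 1], names=["site_id", "visit_index"]
        )
        return pd.DataFrame(self.X_det[j, k, :], index=idx, columns=list(self.det_names))


@dataclass
class CaptureSummary:
    """Per-method capture totals derived from a capture table."""

    trap_total: int
    net_total: int
    trap_species: int
    net_species: int
    combined_species: int
    top_k_trap_share: int
    k: int = 3


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------


def _validate_sites(sites: pd.DataFrame) -> pd.DataFrame:
    missing = set(SITE_COLUMNS) - set(sites.columns)
    if missing:
        raise SurveyDataError(f"sites table missing columns: {sorted(missing)}")
    sites = sites[list(SITE_COLUMNS)].copy().reset_index(drop=True)
    if sites["site_id"].duplicated().any():
        dup = sites.loc[sites["site_id"].duplicated(), "site_id"].iloc[0]
        raise SurveyDataError(f"duplicate site_id {dup!r}")
    if not sites["burn_status"].isin([0, 1]).all():
        raise SurveyDataError("burn_status must be 0 (unburned) or 1 (burned)")
    canopy = sites["canopy_openness"].astype(float)
    # percent-scale inputs are converted to fractions at read time
    if (canopy > 1.0).any():
        canopy = canopy / 100.0
    if ((canopy < 0) | (canopy > 1)).any():
        raise SurveyDataError("canopy_openness must lie in [0, 1] (or [0, 100] percent)")
    sites["burn_status"] = sites["burn_status"].astype(int)
    sites["canopy_openness"] = canopy
    return sites


def _validate_visits(visits: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    missing = set(VISIT_COLUMNS) - set(visits.columns)
    if missing:
        raise SurveyDataError(f"visits table missing columns: {sorted(missing)}")
    visits = visits[list(VISIT_COLUMNS)].copy().reset_index(drop=True)
    if visits.duplicated(["site_id", "visit_index"]).any():
        raise SurveyDataError("duplicate (site_id, visit_index) row in visits table")
    unknown = set(visits["site_id"]) - set(sites["site_id"])
    if unknown:
        raise SurveyDataError(f"visits reference unknown site(s): {sorted(map(str, unknown))}")
    lonely = set(sites["site_id"]) - set(visits["site_id"])
    if lonely:
        raise SurveyDataError(f"site(s) with no visits: {sorted(map(str, lonely))}")
    if (visits["visit_index"].astype(int) < 1).any():
        raise SurveyDataError("visit_index must be >= 1")
    for col in ("floral_abundance", "floral_richness"):
        vals = visits[col].to_numpy()
        if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
            raise SurveyDataError(f"{col} must be a non-negative integer count")
    if (visits["trap_hours"].astype(float) <= 0).any():
        raise SurveyDataError("trap_hours must be positive")
    jd = visits["julian_day"].astype(int)
    if ((jd < 1) | (jd > 366)).any():
        raise SurveyDataError("julian_day must lie in [1, 366]")
    visits["visit_index"] = visits["visit_index"].astype(int)
    visits["floral_abundance"] = visits["floral_abundance"].astype(int)
    visits["floral_richness"] = visits["floral_richness"].astype(int)
    visits["trap_hours"] = visits["trap_hours"].astype(float)
    visits["julian_day"] = jd
    return visits


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def read_survey_csv(
    site_path,
    visit_path,
    detection_path,
    species: Sequence[str] | None = None,
) -> SurveyData:
    """Read sites.csv, visits.csv and detections.csv into a :class:`SurveyData`.

    Detection rows are long format (site_id, visit_index, species, detected).
    A species absent from a visit's rows is a recorded nondetection (0), not
    missing data.  ``species`` may fix the species axis explicitly (e.g. to
    retain species never detected); by default it is the sorted set of
    species appearing in the detections file.
    """
    sites = _validate_sites(pd.read_csv(site_path))
    visits = _validate_visits(pd.read_csv(visit_path), sites)
    det = pd.read_csv(detection_path)
    missing = set(DETECTION_COLUMNS) - set(det.columns)
    if missing:
        raise SurveyDataError(f"detections table missing columns: {sorted(missing)}")

    if species is None:
        species_names = sorted(det["species"].astype(str).unique())
    else:
        species_names = list(species)
        unknown_sp = set(det["species"].astype(str)) - set(species_names)
        if unknown_sp:
            raise SurveyDataError(f"detections reference unknown species: {sorted(unknown_sp)}")

    sites_sorted = sites.sort_values("site_id", kind="stable").reset_index(drop=True)
    site_pos = {s: i for i, s in enumerate(sites_sorted["site_id"])}
    n_visits = int(visits["visit_index"].max())
    mask = np.zeros((len(sites_sorted), n_visits), dtype=bool)
    for sid, vi in zip(visits["site_id"], visits["visit_index"]):
        mask[site_pos[sid], vi - 1] = True

    sp_pos = {s: i for i, s in enumerate(species_names)}
    values = np.zeros((len(species_names), len(sites_sorted), n_visits), dtype=np.int8)
    seen: dict[tuple, int] = {}
    for row, rec in enumerate(det.itertuples(index=False)):
        sid, vi, sp, d = rec.site_id, int(rec.visit_index), str(rec.species), int(rec.detected)
        if sid not in site_pos:
            raise SurveyDataError(f"detections row {row}: unknown site {sid!r}")
        if vi < 1 or vi > n_visits or not mask[site_pos[sid], vi - 1]:
            raise SurveyDataError(f"detections row {row}: site {sid!r} has no visit {vi}")
        if d not in (0, 1):
            raise SurveyDataError(f"detections row {row}: detected must be 0/1")
        key = (sp, sid, vi)
        if key in seen and seen[key] != d:
            raise SurveyDataError(f"detections row {row}: conflicting duplicate for {key}")
        seen[key] = d
        values[sp_pos[sp], site_pos[sid], vi - 1] = d

    tensor = DetectionTensor(values, mask, species_names)
    return SurveyData(sites_sorted, visits, tensor)


def write_survey_csv(survey: SurveyData, out_dir) -> dict[str, str]:
    """Write sites.csv, visits.csv and detections.csv; returns the paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {name: os.path.join(out_dir, f"{name}.csv") for name in ("sites", "visits", "detections")}
    survey.sites.to_csv(paths["sites"], index=False)
    survey.visits.to_csv(paths["visits"], index=False)
    det = survey.detections
    rows = []
    j_idx, k_idx = np.nonzero(det.mask)
    for j, k in zip(j_idx, k_idx):
        for i, sp in enumerate(det.species_names):
            rows.append((survey.site_ids[j], k + 1, sp, int(det.values[i, j, k])))
    pd.DataFrame(rows, columns=list(DETECTION_COLUMNS)).to_csv(paths["detections"], index=False)
    return paths


# ---------------------------------------------------------------------------
# covariate preprocessing
# ---------------------------------------------------------------------------


def pool_floral_counts(
    transect_counts: Mapping[str, Sequence[float]],
) -> tuple[int, int]:
    """Pool per-transect open-flower counts into (abundance, richness).

    ``transect_counts`` maps a transect id to a sequence of open-flower
    counts aligned by flowering plant species; shorter sequences are padded
    with zeros.  Abundance is the grand total; richness counts plant species
    with a pooled count > 0 (pooling is across transects, never per
    transect).
    """
    width = max((len(v) for v in transect_counts.values()), default=0)
    pooled = np.zeros(width)
    for tid, counts in transect_counts.items():
        arr = np.asarray(list(counts), dtype=float)
        if (arr < 0).any():
            raise SurveyDataError(f"negative open-flower count in transect {tid!r}")
        pooled[: len(arr)] += arr
    return int(pooled.sum()), int((pooled > 0).sum())


def _zscore(x: np.ndarray, name: str, transform: str = "identity") -> tuple[np.ndarray, StandardizationRecord]:
    y = np.log1p(x) if transform == "log1p" else np.asarray(x, float)
    mean = float(np.mean(y))
    sd = float(np.std(y, ddof=1))
    if not sd > 1e-12:
        raise SurveyDataError(f"covariate {name!r} has zero variance; cannot standardize")
    return (y - mean) / sd, StandardizationRecord(mean, sd, transform)


def build_design(
    survey: SurveyData,
    spec=None,
    *,
    site_floral_aggregation: str = "mean",
) -> DesignInputs:
    """Build standardized occupancy and detection design matrices.

    Occupancy rows are per site (burn status; z-scored canopy openness;
    their product; z-scored site-level log floral abundance and floral
    richness, the site level being the mean over that site's visits of the
    visit-level values, floral abundance log(x+1)-transformed before
    averaging).  Detection rows are per (site, visit) with burn status,
    canopy openness, visit-level log floral abundance and richness, trap
    hours and Julian day.  ``spec`` may restrict either covariate list
    (any object with ``occ_covariates`` / ``det_covariates``).
    """
    occ_wanted = tuple(getattr(spec, "occ_covariates", OCC_COVARIATES) or OCC_COVARIATES)
    det_wanted = tuple(getattr(spec, "det_covariates", DET_COVARIATES) or DET_COVARIATES)
    for name in occ_wanted:
        if name not in OCC_COVARIATES:
            raise SurveyDataError(f"unknown occupancy covariate {name!r}")
    for name in det_wanted:
        if name not in DET_COVARIATES:
            raise SurveyDataError(f"unknown detection covariate {name!r}")
    if "burn_status:canopy_openness" in occ_wanted and not (
        "burn_status" in occ_wanted and "canopy_openness" in occ_wanted
    ):
        raise SurveyDataError("interaction requested without both parent covariates")

    sites, visits = survey.sites, survey.visits
    burn = sites["burn_status"].to_numpy(float)
    rec_occ: dict[str, StandardizationRecord] = {}
    rec_det: dict[str, StandardizationRecord] = {}

    _canopy_cache: list = []

    def canopy() -> tuple[np.ndarray, StandardizationRecord]:
        if not _canopy_cache:
            _canopy_cache.append(_zscore(sites["canopy_openness"].to_numpy(), "canopy_openness"))
        return _canopy_cache[0]

    # site-level floral covariates: mean over visits (log first for abundance)
    def site_floral() -> tuple[np.ndarray, np.ndarray]:
        log_fa_visit = np.log1p(visits["floral_abundance"].to_numpy(float))
        per_site = visits.assign(_log_fa=log_fa_visit).groupby("site_id", sort=True)
        if site_floral_aggregation == "mean":
            return per_site["_log_fa"].mean().to_numpy(), per_site["floral_richness"].mean().to_numpy()
        if site_floral_aggregation == "pooled_sum":
            return (
                np.log1p(per_site["floral_abundance"].sum().to_numpy(float)),
                per_site["floral_richness"].sum().to_numpy(float),
            )
        raise SurveyDataError(f"unknown site_floral_aggregation {site_floral_aggregation!r}")

    occ_cols: dict[str, np.ndarray] = {}
    identity = StandardizationRecord(0.0, 1.0, "identity")
    need_site_floral = {"log_floral_abundance", "floral_richness"} & set(occ_wanted)
    fa_site, fr_site = site_floral() if need_site_floral else (None, None)
    for name in occ_wanted:
        if name == "burn_status":
            occ_cols[name] = burn
            rec_occ[name] = identity
        elif name == "canopy_openness":
            occ_cols[name], rec_occ[name] = canopy()
        elif name == "burn_status:canopy_openness":
            pass  # filled after parents
        elif name == "log_floral_abundance":
            col, r = _zscore(fa_site, "site log_floral_abundance")
            occ_cols[name], rec_occ[name] = col, dataclasses.replace(r, transform="log1p")
        elif name == "floral_richness":
            occ_cols[name], rec_occ[name] = _zscore(fr_site, "site floral_richness")
    if "burn_status:canopy_openness" in occ_wanted:
        occ_cols["burn_status:canopy_openness"] = (
            occ_cols["burn_status"] * occ_cols["canopy_openness"]
        )
        rec_occ["burn_status:canopy_openness"] = identity
    X_occ = np.column_stack([occ_cols[n] for n in occ_wanted]) if occ_wanted else np.empty((len(sites), 0))

    # detection design on the (site, visit) grid
    j_idx, k_idx = survey.visit_grid()
    mask = survey.detections.mask
    det_level: dict[str, np.ndarray] = {}
    for name in det_wanted:
        if name == "burn_status":
            det_level[name] = burn[j_idx]
            rec_det[name] = identity
        elif name == "canopy_openness":
            canopy_z, canopy_rec = canopy()
            det_level[name] = canopy_z[j_idx]
            rec_det[name] = canopy_rec
        elif name == "log_floral_abundance":
            col, r = _zscore(
                visits["floral_abundance"].to_numpy(float), "visit log_floral_abundance", "log1p"
            )
            det_level[name], rec_det[name] = col, r
        elif name == "floral_richness":
            det_level[name], rec_det[name] = _zscore(
                visits["floral_richness"].to_numpy(float), "visit floral_richness"
            )
        elif name == "trap_hours":
            det_level[name], rec_det[name] = _zscore(visits["trap_hours"].to_numpy(float), "trap_hours")
        elif name == "julian_day":
            det_level[name], rec_det[name] = _zscore(visits["julian_day"].to_numpy(float), "julian_day")
    X_det = np.full((len(sites), mask.shape[1], len(det_wanted)), np.nan)
    for p, name in enumerate(det_wanted):
        X_det[j_idx, k_idx, p] = det_level[name]
    X_det[~mask] = 0.0

    return DesignInputs(
        X_occ=X_occ,
        occ_names=occ_wanted,
        X_det=X_det,
        det_names=det_wanted,
        mask=mask,
        site_ids=survey.site_ids,
        site_burn=burn.astype(int),
        standardization={"occ": rec_occ, "det": rec_det},
    )


# ---------------------------------------------------------------------------
# capture tallies
# ---------------------------------------------------------------------------


def tally_captures(table: pd.DataFrame, k: int = 3) -> CaptureSummary:
    """Summarize a per-species capture table (trap vs net methods).

    A species counts toward a method iff its total there is positive; the
    top-k trap share is the sum of the k largest per-species trap totals.
    """
    required = {"species", "trap_unburned", "trap_burned", "net_burned"}
    missing = required - set(table.columns)
    if missing:
        raise SurveyDataError(f"capture table missing columns: {sorted(missing)}")
    counts = table[["trap_unburned", "trap_burned", "net_burned"]].to_numpy()
    if counts.size and ((counts < 0).any() or not np.allclose(counts, np.round(counts))):
        raise SurveyDataError("capture counts must be non-negative integers")
    trap = table["trap_unburned"].to_numpy(int) + table["trap_burned"].to_numpy(int) if len(table) else np.array([], int)
    net = table["net_burned"].to_numpy(int) if len(table) else np.array([], int)
    return CaptureSummary(
        trap_total=int(trap.sum()),
        net_total=int(net.sum()),
        trap_species=int((trap > 0).sum()),
        net_species=int((net > 0).sum()),
        combined_species=int(((trap > 0) | (net > 0)).sum()),
        top_k_trap_share=int(np.sort(trap)[::-1][:k].sum()),
        k=k,
    )


def load_table1_captures() -> pd.DataFrame:
    """Load the packaged per-species capture table for the study."""
    with resources.files("bombus_occupancy.data").joinpath("table1_captures.csv").open() as fh:
        return pd.read_csv(fh)
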