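"""Survey data model, readers, cluster-to-area assignment and design diagnostics.

The central container is :class:`SurveyDataset`: one row per sampled individual
with cluster, stratum, Admin-1/Admin-2 membership, urban/rural flag, a binary
outcome ``y`` and a strictly positive design weight ``w`` (the inverse
inclusion probability, possibly non-response adjusted). Aggregating over
clusters yields a :class:`ClusterTable` with per-cluster positive counts
``Y_c``, sample sizes ``n_c`` and summed weights — the sufficient statistics
for both design-based estimation and the cluster-level models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INDIVIDUAL_COLUMNS = ["cluster", "stratum", "admin1", "admin2", "urban", "y", "weight"]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """Input rows violate the survey-data contract."""


@dataclass(frozen=True)
class AreaHierarchy:
    """Nesting of Admin-2 areas within Admin-1 areas.

    External labels (any hashable) are mapped to dense internal ids
    0..M-1 in sorted label order; ``a_of[i]`` gives the internal Admin-1
    id of internal Admin-2 area ``i``.
    """

    admin1_labels: tuple
    admin2_labels: tuple
    a_of: np.ndarray  # admin2 internal id -> admin1 internal id

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "AreaHierarchy":
        """Build from a table with columns ``admin2, admin1`` (one row per Admin-2)."""
        for col in ("admin2", "admin1"):
            if col not in table.columns:
                raise SchemaError(f"hierarchy table missing column {col!r}")
        tab = table.drop_duplicates(subset="admin2")
        if tab["admin2"].duplicated().any():
            raise ValidationError("admin2 areas mapped to more than one admin1")
        a1 = tuple(sorted(tab["admin1"].unique()))
        a2 = tuple(sorted(tab["admin2"].unique()))
        a1_index = {lab: k for k, lab in enumerate(a1)}
        mapping = dict(zip(tab["admin2"], tab["admin1"]))
        a_of = np.array([a1_index[mapping[lab]] for lab in a2], dtype=int)
        return cls(a1, a2, a_of)

    @property
    def n_admin1(self) -> int:
        return len(self.admin1_labels)

    @property
    def n_admin2(self) -> int:
        return len(self.admin2_labels)

    def admin1_id(self, labels) -> np.ndarray:
        idx = {lab: k for k, lab in enumerate(self.admin1_labels)}
        return np.array([idx[x] for x in np.asarray(labels, dtype=object)])

    def admin2_id(self, labels) -> np.ndarray:
        idx = {lab: k for k, lab in enumerate(self.admin2_labels)}
        return np.array([idx[x] for x in np.asarray(labels, dtype=object)])

    def admin1_of_admin2(self, admin2_labels) -> np.ndarray:
        """Admin-1 labels of the given Admin-2 labels."""
        ids = self.admin2_id(admin2_labels)
        return np.array([self.admin1_labels[self.a_of[i]] for i in ids], dtype=object)


@dataclass
class SurveyDataset:
    """Validated individual-level survey rows plus the area hierarchy."""

    rows: pd.DataFrame
    hierarchy: AreaHierarchy

    def __len__(self) -> int:
        return len(self.rows)

    def to_clusters(self) -> "ClusterTable":
        """Aggregate to per-cluster sufficient statistics (exact sums)."""
        g = self.rows.groupby("cluster", sort=True)
        tab = g.agg(
            Y=("y", "sum"),
            n=("y", "size"),
            sum_w=("weight", "sum"),
            urban=("urban", "first"),
            admin1=("admin1", "first"),
            admin2=("admin2", "first"),
            stratum=("stratum", "first"),
        ).reset_index()
        if "phantom" in self.rows.columns:
            tab["phantom"] = g["phantom"].first().to_numpy()
        return ClusterTable(tab, self.hierarchy)


@dataclass
class ClusterTable:
    """Per-cluster aggregates: (Y_c, n_c, Σw, urban, admin1, admin2, stratum)."""

    table: pd.DataFrame
    hierarchy: AreaHierarchy

    def __len__(self) -> int:
        return len(self.table)


def _check_columns(table: pd.DataFrame, required: Sequence[str]) -> None:
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")


def load_survey(table: pd.DataFrame | str, hierarchy: AreaHierarchy) -> SurveyDataset:
    """Validate an individual-level survey table against the hierarchy.

    Parameters
    ----------
    table
        DataFrame (or CSV path) with columns
        ``cluster, stratum, admin1, admin2, urban, y, weight``.
    hierarchy
        Admin-2 -> Admin-1 nesting used to resolve and cross-check area labels.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ValidationError
        Non-positive weights, non-binary outcomes, unresolvable area ids,
        Admin-2 areas recorded under the wrong Admin-1, or clusters that span
        more than one stratum or area.
    """
    if isinstance(table, str):
        table = pd.read_csv(table)
    _check_columns(table, INDIVIDUAL_COLUMNS)
    rows = table.copy().reset_index(drop=True)

    bad_w = rows.index[~(rows["weight"] > 0)].tolist()
    if bad_w:
        raise ValidationError(f"non-positive design weight in rows {bad_w}")
    if not rows["y"].isin([0, 1]).all():
        bad = rows.index[~rows["y"].isin([0, 1])].tolist()
        raise ValidationError(f"outcome y must be 0/1; offending rows {bad}")

    known2 = set(hierarchy.admin2_labels)
    unknown = sorted(set(rows["admin2"]) - known2)
    if unknown:
        raise ValidationError(f"admin2 label(s) not in hierarchy: {unknown}")
    known1 = set(hierarchy.admin1_labels)
    unknown = sorted(set(rows["admin1"]) - known1)
    if unknown:
        raise ValidationError(f"admin1 label(s) not in hierarchy: {unknown}")

    expected_a1 = hierarchy.admin1_of_admin2(rows["admin2"].to_numpy())
    mismatch = rows.index[expected_a1 != rows["admin1"].to_numpy(dtype=object)]
    if len(mismatch):
        raise ValidationError(
            f"admin2 not nested in recorded admin1 for rows {mismatch.tolist()}"
        )

    for col in ("stratum", "admin1", "admin2", "urban"):
        per_cluster = rows.groupby("cluster")[col].nunique()
        multi = per_cluster.index[per_cluster > 1].tolist()
        if multi:
            raise ValidationError(f"cluster(s) {multi} map to multiple {col} values")

    rows["urban"] = rows["urban"].astype(bool)
    rows["y"] = rows["y"].astype(int)
    rows["weight"] = rows["weight"].astype(float)
    logger.info("loaded %d survey rows in %d clusters", len(rows), rows["cluster"].nunique())
    return SurveyDataset(rows, hierarchy)


def load_cluster_table(table: pd.DataFrame | str, hierarchy: AreaHierarchy) -> ClusterTable:
    """Load a pre-aggregated cluster-level table (columns ``cluster,...,Y,n,sum_w``)."""
    if isinstance(table, str):
        table = pd.read_csv(table)
    _check_columns(table, ["cluster", "stratum", "admin1", "admin2", "urban", "Y", "n", "sum_w"])
    tab = table.copy().reset_index(drop=True)
    if ((tab["Y"] < 0) | (tab["Y"] > tab["n"]) | (tab["n"] < 1)).any():
        raise ValidationError("cluster counts must satisfy 0 <= Y <= n, n >= 1")
    tab["urban"] = tab["urban"].astype(bool)
    return ClusterTable(tab, hierarchy)


def assign_clusters_to_areas(
    cluster_points: pd.DataFrame, area_polygons: Mapping[object, "shapely.Geometry"]
) -> pd.DataFrame:
    """Label each cluster point with the id of the containing polygon.

    ``cluster_points`` has columns ``cluster, lon, lat``. A point lying on a
    shared boundary is assigned deterministically to the lowest area id among
    the covering polygons; points outside every polygon get a null area with
    ``assigned=False``.
    """
    from shapely.geometry import Point

    if len(area_polygons) == 0:
        raise ValueError("empty polygon set")
    ordered = sorted(area_polygons.items(), key=lambda kv: str(kv[0]))
    out = []
    for _, row in cluster_points.iterrows():
        pt = Point(row["lon"], row["lat"])
        hit = None
        for area_id, poly in ordered:
            if poly.covers(pt):  # covers() includes the boundary
                hit = area_id
                break
        out.append((row["cluster"], hit, hit is not None))
    return pd.DataFrame(out, columns=["cluster", "area", "assigned"])


def reconcile_assignments(
    assignment: pd.DataFrame,
    recorded_admin1: Mapping[object, object],
    area_polygons: Mapping[object, "shapely.Geometry"],
    admin1_of_area: Mapping[object, object],
    cluster_points: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-check polygon-derived assignments against recorded Admin-1 labels.

    GPS coordinates of survey clusters are routinely jittered for
    confidentiality, so a point can land across an administrative border.
    Clusters whose polygon-derived Admin-1 disagrees with the Admin-1 label
    recorded in the survey (or that fell outside all polygons) are snapped to
    the nearest Admin-2 polygon *within the recorded Admin-1*, by boundary
    distance.

    Returns the corrected assignment table and a discrepancy report with one
    row per flagged cluster (original area, corrected area, reason).
    """
    from shapely.geometry import Point

    points = {}
    if cluster_points is not None:
        points = {
            r["cluster"]: Point(r["lon"], r["lat"]) for _, r in cluster_points.iterrows()
        }

    corrected = assignment.copy()
    report_rows = []
    for idx, row in assignment.iterrows():
        cl = row["cluster"]
        if cl not in recorded_admin1:
            continue
        rec1 = recorded_admin1[cl]
        derived1 = admin1_of_area.get(row["area"]) if row["assigned"] else None
        if row["assigned"] and derived1 == rec1:
            continue
        reason = "unassigned" if not row["assigned"] else "admin1 mismatch"
        candidates = [a for a, a1 in admin1_of_area.items() if a1 == rec1]
        new_area = None
        if candidates and cl in points:
            dists = [(area_polygons[a].distance(points[cl]), str(a), a) for a in candidates]
            new_area = min(dists)[2]
        if new_area is not None:
            corrected.loc[idx, "area"] = new_area
            corrected.loc[idx, "assigned"] = True
        report_rows.append(
            {
                "cluster": cl,
                "reason": reason,
                "original_area": row["area"],
                "recorded_admin1": rec1,
                "corrected_area": new_area,
            }
        )
        logger.warning("cluster %s %s; snapped to %s", cl, reason, new_area)
    report = pd.DataFrame(
        report_rows,
        columns=["cluster", "reason", "original_area", "recorded_admin1", "corrected_area"],
    )
    return corrected, report


def availability_summary(clusters: ClusterTable, hierarchy: AreaHierarchy) -> dict:
    """Per-level data-availability tabulation.

    Returns a dict with per-Admin-1 and per-Admin-2 tables of cluster and
    individual counts (areas absent from the data appear with zeros), the
    medians across areas, and the lists of areas with 0 or exactly 1 cluster.
    """
    out = {}
    tab = clusters.table
    for level, labels in (("admin1", hierarchy.admin1_labels), ("admin2", hierarchy.admin2_labels)):
        g = tab.groupby(level).agg(n_clusters=("cluster", "nunique"), n_individuals=("n", "sum"))
        g = g.reindex(list(labels), fill_value=0).rename_axis(level).reset_index()
        out[f"{level}_table"] = g
        out[f"{level}_median_clusters"] = float(g["n_clusters"].median())
        out[f"{level}_median_individuals"] = float(g["n_individuals"].median())
        out[f"{level}_zero_cluster_areas"] = g.loc[g["n_clusters"] == 0, level].tolist()
        out[f"{level}_one_cluster_areas"] = g.loc[g["n_clusters"] == 1, level].tolist()
    return out


def urban_sampling_diagnostic(
    clusters: ClusterTable, population_urban_fractions: Mapping[object, float] | pd.Series
) -> pd.DataFrame:
    """Compare the sampled urban-cluster fraction to the population urban fraction.

    Urban strata are commonly over-sampled relative to their population share;
    a positive ``difference`` for most areas is the design signature that makes
    unweighted estimation biased whenever the outcome differs by urbanicity.
    """
    fracs = pd.Series(population_urban_fractions, dtype=float)
    if ((fracs < 0) | (fracs > 1)).any():
        raise ValueError("population urban fractions must lie in [0, 1]")
    tab = clusters.table
    g = tab.groupby("admin1").agg(
        n_clusters=("cluster", "nunique"), n_urban=("urban", "sum")
    )
    out = pd.DataFrame(index=fracs.index)
    out["sampled_urban_fraction"] = g["n_urban"] / g["n_clusters"]
    out["population_urban_fraction"] = fracs
    out["difference"] = out["sampled_urban_fraction"] - out["population_urban_fraction"]
    return out.rename_axis("admin1").reset_index()
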