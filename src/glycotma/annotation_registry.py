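"""Pathology annotations and their transfer onto the MSI pixel grid.

Annotations are labeled polygons drawn on the H&E slide (coordinates in
micrometers).  A least-squares affine transform fitted from fiducial
point pairs maps slide coordinates onto the MSI grid; every pixel center
is then mapped back into slide space and labeled by the containing
polygon (point-in-polygon on the pixel center, closed boundaries, with
overlaps resolved in favour of the smallest-area polygon).

Grid convention: the MSI grid is 0-based with x = column, y = row, and
the center of pixel (x, y) sits at grid coordinate (x + 0.5, y + 0.5);
one grid unit is one pixel pitch (50 um by default).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon, mapping, shape
from shapely.strtree import STRtree

from glycotma.msi_preprocess import MSIDataset

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "BONE_SITES",
    "AnnotationRegion",
    "AffineTransform",
    "parse_annotations",
    "write_annotations",
    "fit_affine",
    "assign_pixels",
    "pool_bone_sites",
    "read_fiducials",
    "write_attribute_table",
    "read_attribute_table",
]

#: Controlled histology-category vocabulary.
CATEGORIES = frozenset(
    {"normal", "stroma", "cancer_associated_stroma", "cancer_mixed_cas",
     "cancer", "necrosis"}
)

#: Tissue sites pooled into a single skeletal "bone" label.
BONE_SITES = frozenset({"bone", "rib", "spine", "vertebra"})


@dataclass
class AnnotationRegion:
    """A labeled polygon in slide coordinates (um)."""

    region_id: str
    tissue_site: str
    category: str
    polygon: Polygon
    tma_id: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown annotation category {self.category!r}")
        if not isinstance(self.polygon, Polygon) or self.polygon.is_empty:
            raise ValueError("polygon must be a non-empty shapely Polygon")
        if len(self.polygon.exterior.coords) - 1 < 3:
            raise ValueError("polygon needs at least 3 vertices")
        if self.polygon.area <= 0:
            raise ValueError("polygon area must be positive")


@dataclass(frozen=True)
class AffineTransform:
    """Affine map grid = A @ slide + b from slide um to MSI grid units."""

    a11: float
    a12: float
    a21: float
    a22: float
    b1: float
    b2: float

    def __post_init__(self) -> None:
        if abs(self.det) < 1e-12:
            raise ValueError("affine transform is not invertible")

    @property
    def det(self) -> float:
        return self.a11 * self.a22 - self.a12 * self.a21

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, float)
        A = np.array([[self.a11, self.a12], [self.a21, self.a22]])
        return xy @ A.T + np.array([self.b1, self.b2])

    def inverse(self) -> "AffineTransform":
        A = np.array([[self.a11, self.a12], [self.a21, self.a22]])
        Ai = np.linalg.inv(A)
        bi = -Ai @ np.array([self.b1, self.b2])
        return AffineTransform(Ai[0, 0], Ai[0, 1], Ai[1, 0], Ai[1, 1],
                               bi[0], bi[1])


# --- annotation I/O ---------------------------------------------------------

def parse_annotations(path) -> tuple[list[AnnotationRegion], list[dict]]:
    """Parse annotation polygons from GeoJSON (primary) or a simple XML
    dialect (best effort).

    Returns (regions, errors); malformed or invalidly labeled features are
    skipped and reported in the error list with a reason.
    """
    path = Path(path)
    if path.suffix.lower() == ".xml":
        return _parse_annotations_xml(path)
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    regions: list[AnnotationRegion] = []
    errors: list[dict] = []
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties", {}) or {}
        rid = str(props.get("region_id", f"feature_{i}"))
        try:
            geom = shape(feat["geometry"])
            if not isinstance(geom, Polygon):
                raise ValueError(f"geometry type {geom.geom_type}, not Polygon")
            region = AnnotationRegion(
                region_id=rid,
                tissue_site=str(props["tissue_site"]),
                category=str(props["category"]),
                polygon=geom,
                tma_id=str(props.get("tma_id", "")),
            )
        except (KeyError, ValueError, TypeError, shapely.errors.GEOSException) as e:
            errors.append({"region_id": rid, "reason": str(e)})
            logger.warning("parse_annotations: skipped %s (%s)", rid, e)
            continue
        regions.append(region)
    return regions, errors


def _parse_annotations_xml(path) -> tuple[list[AnnotationRegion], list[dict]]:
    """Best-effort slide-viewer XML import: any element with a 'points'
    attribute of 'x,y x,y ...' plus region_id/tissue_site/category
    attributes is read as one polygon."""
    from lxml import etree

    tree = etree.parse(str(path))
    regions: list[AnnotationRegion] = []
    errors: list[dict] = []
    for i, el in enumerate(tree.iter()):
        pts = el.get("points")
        if pts is None:
            continue
        rid = el.get("region_id", f"xml_{i}")
        try:
            coords = [tuple(map(float, p.split(","))) for p in pts.split()]
            region = AnnotationRegion(
                region_id=rid,
                tissue_site=el.get("tissue_site", ""),
                category=el.get("category", ""),
                polygon=Polygon(coords),
                tma_id=el.get("tma_id", ""),
            )
        except (ValueError, TypeError, shapely.errors.GEOSException) as e:
            errors.append({"region_id": rid, "reason": str(e)})
            continue
        regions.append(region)
    return regions, errors


def write_annotations(regions: list[AnnotationRegion], path) -> None:
    """Write regions as a GeoJSON FeatureCollection (coordinates in um)."""
    features = [
        {
            "type": "Feature",
            "geometry": mapping(r.polygon),
            "properties": {
                "region_id": r.region_id,
                "tissue_site": r.tissue_site,
                "category": r.category,
                "tma_id": r.tma_id,
            },
        }
        for r in regions
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# --- coregistration ---------------------------------------------------------

def fit_affine(
    slide_points: np.ndarray, grid_points: np.ndarray
) -> tuple[AffineTransform, np.ndarray]:
    """Least-squares affine transform from fiducial pairs.

    Requires >= 3 non-collinear pairs.  Returns the transform together
    with per-pair residuals in grid units.
    """
    slide = np.asarray(slide_points, float)
    grid = np.asarray(grid_points, float)
    if slide.shape != grid.shape or slide.ndim != 2 or slide.shape[1] != 2:
        raise ValueError("point sets must both be (n, 2) arrays")
    if slide.shape[0] < 3:
        raise ValueError("need at least 3 fiducial pairs")
    X = np.column_stack([slide, np.ones(len(slide))])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("fiducial points are collinear")
    coeffs, *_ = np.linalg.lstsq(X, grid, rcond=None)
    t = AffineTransform(
        a11=coeffs[0, 0], a12=coeffs[1, 0],
        a21=coeffs[0, 1], a22=coeffs[1, 1],
        b1=coeffs[2, 0], b2=coeffs[2, 1],
    )
    residuals = np.linalg.norm(t.apply(slide) - grid, axis=1)
    return t, residuals


def read_fiducials(path) -> tuple[np.ndarray, np.ndarray]:
    """Read fiducial pairs from a delimited file with columns
    slide_x_um, slide_y_um, grid_x, grid_y."""
    df = pd.read_csv(path, sep="\t")
    return (df[["slide_x_um", "slide_y_um"]].to_numpy(float),
            df[["grid_x", "grid_y"]].to_numpy(float))


# --- pixel labeling ---------------------------------------------------------

def assign_pixels(
    d: MSIDataset,
    regions: list[AnnotationRegion],
    transform: AffineTransform,
    extra_attrs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Label every MSI pixel with the annotation containing its center.

    Pixel centers (x+0.5, y+0.5) in grid units are mapped through the
    inverse transform into slide space.  Points on a polygon boundary
    count as inside; overlapping polygons are resolved by smallest area
    (ties by lexicographically smallest region_id, with a warning).
    Pixels in no polygon keep null labels.

    Regions carrying a non-empty tma_id label only the pixels of that
    TMA (each TMA is its own slide); regions with an empty tma_id apply
    to every pixel.

    extra_attrs, if given, is joined on tma_id (e.g. BC subtype).
    """
    attrs = d.pixels[["tma_id", "x", "y"]].copy()
    attrs["tissue_site"] = pd.Series([None] * len(attrs), dtype=object)
    attrs["category"] = pd.Series([None] * len(attrs), dtype=object)
    attrs["region_id"] = pd.Series([None] * len(attrs), dtype=object)

    if regions:
        inv = transform.inverse()
        centers_grid = attrs[["x", "y"]].to_numpy(float) + 0.5
        centers_slide = inv.apply(centers_grid)
        pixel_tmas = attrs["tma_id"].astype(str).to_numpy()

        by_tma: dict[str, list[AnnotationRegion]] = {}
        for r in regions:
            by_tma.setdefault(str(r.tma_id), []).append(r)
        tie_warned = False
        for tma, regs in by_tma.items():
            if tma:
                rows = np.flatnonzero(pixel_tmas == tma)
            else:
                rows = np.arange(len(attrs))
            if rows.size == 0:
                continue
            points = shapely.points(centers_slide[rows, 0],
                                    centers_slide[rows, 1])
            order = sorted(range(len(regs)),
                           key=lambda i: (regs[i].polygon.area,
                                          regs[i].region_id))
            areas = np.array([regs[i].polygon.area for i in order])
            tree = STRtree([regs[i].polygon for i in order])
            # covers: boundary points are inside (closed polygons)
            pix_idx, reg_idx = tree.query(points, predicate="covered_by")
            # keep the smallest-area (first in sorted order) region per pixel
            best: dict[int, int] = {}
            for p, r in zip(pix_idx, reg_idx):
                if p not in best:
                    best[p] = r
                elif r < best[p]:
                    if not tie_warned and areas[r] == areas[best[p]]:
                        logger.warning("assign_pixels: overlapping regions "
                                       "with equal areas resolved by "
                                       "region_id order")
                        tie_warned = True
                    best[p] = r
            if best:
                hit = np.fromiter(best.keys(), dtype=int)
                chosen = [regs[order[best[p]]] for p in hit]
                attrs.loc[attrs.index[rows[hit]], "tissue_site"] = [
                    r.tissue_site for r in chosen]
                attrs.loc[attrs.index[rows[hit]], "category"] = [
                    r.category for r in chosen]
                attrs.loc[attrs.index[rows[hit]], "region_id"] = [
                    r.region_id for r in chosen]

    if extra_attrs is not None:
        attrs = attrs.merge(extra_attrs, on="tma_id", how="left")
    return attrs


def pool_bone_sites(attrs: pd.DataFrame) -> pd.DataFrame:
    """Rewrite skeletal tissue-site labels (bone, rib, spine, vertebra)
    to the pooled label 'bone'; all other rows are unchanged."""
    out = attrs.copy()
    mask = out["tissue_site"].isin(BONE_SITES)
    out.loc[mask, "tissue_site"] = "bone"
    return out


def write_attribute_table(attrs: pd.DataFrame, path) -> None:
    attrs.to_csv(path, sep="\t", index=False)


def read_attribute_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
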