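"""Per-chloroplast morphometry of grey-scale micrographs.

Turns an 8-bit image plus a physical scale (and a label mask, or a grey
threshold when no mask exists) into the raw measurements behind all derived
PG attributes: chloroplast cross-section area (CA), starch area, per-PG
pixel areas and mean grey values, the vacuole reference grey, and the count
of grape-like PG clusters.  Also implements the image-selection rules used
in quantitative TEM surveys: chloroplasts with less than 80% of their
surface visible are excluded, and at most four chloroplasts are retained
per image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from skimage.measure import label as sk_label

from .synthetic import MASK_PG_BASE, MASK_STARCH, MASK_STROMA, MASK_VACUOLE

NM2_PER_UM2 = 1e6


# ---------------------------------------------------------------------------
# scale calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PixelScale:
    """Physical pixel size.  ``source='absent'`` restricts downstream
    attributes to the scale-free ones (%PG and nED)."""

    nm_per_pixel: float | None
    source: str = "metadata"  # scale_bar | metadata | absent

    def __post_init__(self) -> None:
        if self.source == "absent":
            if self.nm_per_pixel is not None:
                raise ValueError("absent scale must carry no nm_per_pixel")
        elif self.nm_per_pixel is None or self.nm_per_pixel <= 0:
            raise ValueError("nm_per_pixel must be positive")

    @property
    def known(self) -> bool:
        return self.source != "absent"


ABSENT_SCALE = PixelScale(None, "absent")


def calibrate_scale(scale_bar_length_px: float,
                    stated_length_nm: float) -> PixelScale:
    """Derive nm/pixel from a measured scale bar."""
    if scale_bar_length_px <= 0 or stated_length_nm <= 0:
        raise ValueError("scale bar length and stated length must be > 0")
    return PixelScale(stated_length_nm / scale_bar_length_px, "scale_bar")


# ---------------------------------------------------------------------------
# segmentation & object measurement
# ---------------------------------------------------------------------------

@dataclass
class ObjectMeasurement:
    """One segmented object: role, pixel area, mean grey, centroid."""

    role: str                     # chloroplast | starch | pg | vacuole_ref
    pixel_area: int
    mean_grey: float
    centroid: tuple[float, float]  # (row, col), pixel-centred, 0-based

    @property
    def equivalent_radius(self) -> float:
        return float(np.sqrt(self.pixel_area / np.pi))


def _measure_labelled(image: np.ndarray, labels: np.ndarray,
                      role: str) -> list[ObjectMeasurement]:
    out = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        region = labels == lab
        rr, cc = np.nonzero(region)
        out.append(ObjectMeasurement(
            role=role,
            pixel_area=int(region.sum()),
            mean_grey=float(image[region].mean()),
            centroid=(float(rr.mean()), float(cc.mean())),
        ))
    return out


def segment_scene(image: np.ndarray,
                  mask: np.ndarray | None = None, *,
                  pg_grey_threshold: float = 80.0,
                  chloroplast_grey_threshold: float = 160.0,
                  starch_grey_threshold: float = 220.0,
                  ) -> list[ObjectMeasurement]:
    """Segment a scene into chloroplast, starch, PG and vacuole objects.

    When ``mask`` is given it is authoritative: 0 encodes the vacuole
    reference region, 1 stroma, 2 starch and values >= 10 individual PGs
    (one object per label, so touching PGs stay separate).  Without a mask,
    the chloroplast is the largest hole-filled connected component darker
    than ``chloroplast_grey_threshold``; PGs are connected components inside
    it darker than ``pg_grey_threshold``; starch is brighter than
    ``starch_grey_threshold``; the complement is the vacuole reference.

    Mean greys are always computed on the raw image.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2D grey image")

    objects: list[ObjectMeasurement] = []
    if mask is not None:
        mask = np.asarray(mask)
        chloro = mask >= MASK_STROMA
        if not chloro.any():
            raise ValueError("no chloroplast")
        rr, cc = np.nonzero(chloro)
        objects.append(ObjectMeasurement(
            "chloroplast", int(chloro.sum()),
            float(image[chloro].mean()),
            (float(rr.mean()), float(cc.mean()))))
        starch_labels = sk_label(mask == MASK_STARCH)
        objects += _measure_labelled(image, starch_labels, "starch")
        pg_ids = np.unique(mask[mask >= MASK_PG_BASE])
        for pid in pg_ids:
            region = mask == pid
            rr, cc = np.nonzero(region)
            objects.append(ObjectMeasurement(
                "pg", int(region.sum()), float(image[region].mean()),
                (float(rr.mean()), float(cc.mean()))))
        vac = mask == MASK_VACUOLE
        if vac.any():
            rr, cc = np.nonzero(vac)
            objects.append(ObjectMeasurement(
                "vacuole_ref", int(vac.sum()), float(image[vac].mean()),
                (float(rr.mean()), float(cc.mean()))))
        return objects

    # threshold mode
    dark = ndi.binary_fill_holes(image < chloroplast_grey_threshold)
    labels, n = ndi.label(dark)
    if n == 0:
        raise ValueError("no chloroplast")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    chloro = labels == (1 + int(np.argmax(sizes)))
    rr, cc = np.nonzero(chloro)
    objects.append(ObjectMeasurement(
        "chloroplast", int(chloro.sum()), float(image[chloro].mean()),
        (float(rr.mean()), float(cc.mean()))))
    pg_labels = sk_label((image < pg_grey_threshold) & chloro)
    objects += _measure_labelled(image, pg_labels, "pg")
    starch_labels = sk_label((image > starch_grey_threshold) & chloro)
    objects += _measure_labelled(image, starch_labels, "starch")
    vac = ~chloro
    if vac.any():
        rr, cc = np.nonzero(vac)
        objects.append(ObjectMeasurement(
            "vacuole_ref", int(vac.sum()), float(image[vac].mean()),
            (float(rr.mean()), float(cc.mean()))))
    return objects


# ---------------------------------------------------------------------------
# cluster counting
# ---------------------------------------------------------------------------

def count_clusters(centroids: np.ndarray, radii: np.ndarray, *,
                   contact_gap: float = 1.0,
                   min_size: int = 2) -> int:
    """Count grape-like PG clusters via the contact graph.

    Two PGs are linked when their centre distance is at most
    ``r1 + r2 + contact_gap`` (all in the same units).  A cluster is a
    connected component of at least ``min_size`` PGs.  ``min_size=2`` counts
    a touching pair as a cluster; ``min_size=3`` gives the stricter
    more-than-two reading.
    """
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    radii = np.asarray(radii, dtype=float)
    n = len(radii)
    if n == 0:
        return 0
    diff = centroids[:, None, :] - centroids[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    limit = radii[:, None] + radii[None, :] + contact_gap
    adj = csr_matrix((dist <= limit) & ~np.eye(n, dtype=bool))
    n_comp, comp = connected_components(adj, directed=False)
    sizes = np.bincount(comp, minlength=n_comp)
    return int((sizes >= min_size).sum())


# ---------------------------------------------------------------------------
# chloroplast records
# ---------------------------------------------------------------------------

@dataclass
class ChloroplastRecord:
    """Raw measurements for one chloroplast cross-section.

    Pixel-based quantities are always present; physical areas (um^2) are
    ``None`` in scale-free mode.  PG lists are ordered by decreasing area.
    """

    image_id: str
    chloroplast_id: int
    scale: PixelScale
    ca_px: int
    starch_px: int
    pg_px: list[int]
    pg_greys: list[float]
    vacuole_grey: float | None
    visibility_fraction: float = 1.0
    n_clusters: int = 0
    case_id: str | None = None

    ca_um2: float | None = field(init=False, default=None)
    starch_area_um2: float | None = field(init=False, default=None)
    pg_areas_um2: list[float] | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        if self.ca_px <= 0:
            raise ValueError("chloroplast area must be positive")
        if self.starch_px >= self.ca_px:
            raise ValueError("starch exceeds chloroplast")
        if not 0.0 <= self.visibility_fraction <= 1.0:
            raise ValueError("visibility_fraction must lie in [0, 1]")
        order = np.argsort(self.pg_px)[::-1]
        self.pg_px = [int(self.pg_px[i]) for i in order]
        self.pg_greys = [float(self.pg_greys[i]) for i in order]
        if self.scale.known:
            f = self.scale.nm_per_pixel ** 2 / NM2_PER_UM2
            self.ca_um2 = self.ca_px * f
            self.starch_area_um2 = self.starch_px * f
            self.pg_areas_um2 = [a * f for a in self.pg_px]

    @property
    def npg(self) -> int:
        return len(self.pg_px)


def measure_chloroplast(objects: list[ObjectMeasurement],
                        scale: PixelScale, *,
                        image_id: str = "image",
                        chloroplast_id: int = 0,
                        case_id: str | None = None,
                        visibility_fraction: float = 1.0,
                        contact_gap_nm: float = 10.0,
                        min_cluster_size: int = 2) -> ChloroplastRecord:
    """Assemble segmented objects into a :class:`ChloroplastRecord`.

    Requires exactly one chloroplast object; a missing vacuole reference
    leaves ``vacuole_grey`` as ``None`` (nED will be null downstream).  With
    an absent scale the record stays in scale-free mode: pixel areas only.
    The contact gap for cluster counting is converted from nm to pixels
    when the scale is known, otherwise touching (gap 0) is required.
    """
    chloros = [o for o in objects if o.role == "chloroplast"]
    if len(chloros) != 1:
        raise ValueError(f"expected exactly one chloroplast object, "
                         f"got {len(chloros)}")
    vacs = [o for o in objects if o.role == "vacuole_ref"]
    pgs = [o for o in objects if o.role == "pg"]
    starch_px = sum(o.pixel_area for o in objects if o.role == "starch")

    if pgs:
        centroids = np.array([o.centroid for o in pgs])
        radii = np.array([o.equivalent_radius for o in pgs])
        gap_px = (contact_gap_nm / scale.nm_per_pixel) if scale.known else 0.0
        n_clusters = count_clusters(centroids, radii, contact_gap=gap_px,
                                    min_size=min_cluster_size)
    else:
        n_clusters = 0

    return ChloroplastRecord(
        image_id=image_id, chloroplast_id=chloroplast_id, scale=scale,
        ca_px=chloros[0].pixel_area, starch_px=starch_px,
        pg_px=[o.pixel_area for o in pgs],
        pg_greys=[o.mean_grey for o in pgs],
        vacuole_grey=vacs[0].mean_grey if vacs else None,
        visibility_fraction=visibility_fraction,
        n_clusters=n_clusters, case_id=case_id)


def measure_scene(image: np.ndarray, mask: np.ndarray | None,
                  scale: PixelScale, **kwargs) -> ChloroplastRecord:
    """Convenience: segment a one-chloroplast scene and measure it."""
    return measure_chloroplast(segment_scene(image, mask), scale, **kwargs)


# ---------------------------------------------------------------------------
# image-selection rules
# ---------------------------------------------------------------------------

def select_chloroplasts(records: list[ChloroplastRecord], *,
                        max_per_image: int = 4,
                        min_visibility: float = 0.8,
                        ) -> tuple[list[ChloroplastRecord], pd.DataFrame]:
    """Apply the image-selection rules; return kept records + rejection log.

    Chloroplasts with visibility below ``min_visibility`` (boundary
    inclusive: exactly 80% visible is kept) are dropped; within each image
    at most ``max_per_image`` records are retained, largest CA first with a
    deterministic tie-break on chloroplast id.
    """
    rejections = []
    visible: dict[str, list[ChloroplastRecord]] = {}
    for rec in records:
        if rec.visibility_fraction < min_visibility:
            rejections.append({
                "image_id": rec.image_id,
                "chloroplast_id": rec.chloroplast_id,
                "reason": f"visibility {rec.visibility_fraction:.2f} "
                          f"< {min_visibility:.2f}"})
        else:
            visible.setdefault(rec.image_id, []).append(rec)

    kept: list[ChloroplastRecord] = []
    for image_id, group in visible.items():
        group = sorted(group, key=lambda r: (-r.ca_px, r.chloroplast_id))
        kept.extend(group[:max_per_image])
        for rec in group[max_per_image:]:
            rejections.append({
                "image_id": rec.image_id,
                "chloroplast_id": rec.chloroplast_id,
                "reason": f"more than {max_per_image} chloroplasts in image"})
    log = pd.DataFrame(rejections,
                       columns=["image_id", "chloroplast_id", "reason"])
    return kept, log


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def records_to_frames(records: list[ChloroplastRecord],
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy frames: one row per chloroplast, plus a long per-PG table."""
    chloro_rows, pg_rows = [], []
    for rec in records:
        chloro_rows.append({
            "image_id": rec.image_id,
            "chloroplast_id": rec.chloroplast_id,
            "case_id": rec.case_id,
            "ca_px": rec.ca_px, "starch_px": rec.starch_px,
            "ca_um2": rec.ca_um2, "starch_area_um2": rec.starch_area_um2,
            "npg": rec.npg, "n_clusters": rec.n_clusters,
            "vacuole_grey": rec.vacuole_grey,
            "visibility_fraction": rec.visibility_fraction,
            "nm_per_pixel": rec.scale.nm_per_pixel,
        })
        for k in range(rec.npg):
            pg_rows.append({
                "image_id": rec.image_id,
                "chloroplast_id": rec.chloroplast_id,
                "pg_index": k,
                "pg_px": rec.pg_px[k],
                "pg_area_um2":
                    rec.pg_areas_um2[k] if rec.pg_areas_um2 else None,
                "pg_grey": rec.pg_greys[k],
            })
    return (pd.DataFrame(chloro_rows),
            pd.DataFrame(pg_rows, columns=[
                "image_id", "chloroplast_id", "pg_index", "pg_px",
                "pg_area_um2", "pg_grey"]))


def write_measurements(records: list[ChloroplastRecord],
                       path: str | Path) -> tuple[Path, Path]:
    """Write the per-chloroplast CSV plus the companion per-PG long CSV."""
    path = Path(path)
    chloro, pgs = records_to_frames(records)
    pg_path = path.with_name(path.stem + "_pgs.csv")
    chloro.to_csv(path, index=False)
    pgs.to_csv(pg_path, index=False)
    return path, pg_path
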