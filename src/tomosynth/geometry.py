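"""Linear-sweep acquisition geometry and the sagittal-slice/strip mapping.

The X-ray source travels along a vertical line at distance ``sdd_mm`` from
the detector plane (z = 0), covering an angular range (default -15 deg to
+15 deg as seen from the detector center).  Because the source only moves
vertically, the lateral detector coordinate of any projected point is
independent of the view: all rays through one sagittal plane of the patient
fall into a narrow vertical strip of detector columns.  That strip (31 px
wide at full scale) is the model input for the corresponding sagittal slice.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml


@dataclass(frozen=True)
class AcquisitionGeometry:
    sdd_mm: float = 1800.0                      # source-detector distance along z
    sweep_deg: tuple = (-15.0, 15.0)
    n_views: int = 60
    detector_shape: tuple = (2048, 2048)        # (rows, cols)
    detector_pitch_mm: float = 0.2
    patient_offset_mm: float = 150.0            # depth of the mid-patient plane
    strip_width_px: int = 31

    def __post_init__(self):
        if self.n_views < 2:
            raise ValueError("need at least 2 views")
        if self.strip_width_px < 1 or self.strip_width_px % 2 == 0:
            raise ValueError("strip_width_px must be odd and >= 1")
        if not (0 < self.patient_offset_mm < self.sdd_mm):
            raise ValueError("patient must lie between detector and source")
        if self.sweep_deg[0] >= self.sweep_deg[1]:
            raise ValueError("sweep range must be increasing")

    # -- sweep ---------------------------------------------------------------

    def view_angles_deg(self) -> np.ndarray:
        """View angles, uniformly spaced in angle, endpoints included."""
        return np.linspace(self.sweep_deg[0], self.sweep_deg[1], self.n_views)

    def source_position(self, view: int) -> np.ndarray:
        """Source world position (x, y, z) for one view: (0, sdd*tan(theta), sdd)."""
        if not 0 <= view < self.n_views:
            raise IndexError(f"view {view} out of range [0, {self.n_views})")
        theta = np.deg2rad(self.view_angles_deg()[view])
        return np.array([0.0, self.sdd_mm * np.tan(theta), self.sdd_mm])

    # -- central projection --------------------------------------------------

    def magnification(self, z_mm) -> np.ndarray:
        """M(z) = sdd / (sdd - z); M(0) = 1, strictly increasing in z."""
        return self.sdd_mm / (self.sdd_mm - np.asarray(z_mm, dtype=float))

    def project_point(self, view: int, p) -> tuple:
        """Intersection (row_mm, col_mm) of the ray source -> p with z = 0.

        Detector coordinates are in mm with origin at the detector center;
        the row axis is vertical (sweep direction), the col axis lateral.
        """
        p = np.asarray(p, dtype=float)
        if p[2] >= self.sdd_mm:
            raise ValueError("point must lie between detector and source (z < sdd)")
        y_src = self.source_position(view)[1]
        t = self.sdd_mm / (self.sdd_mm - p[2])
        col = t * p[0]
        row = y_src + t * (p[1] - y_src)
        return (row, col)

    # -- detector pixel grid -------------------------------------------------

    def pixel_centers_mm(self):
        """(row_mm, col_mm) world coordinates of detector pixel centers."""
        nrows, ncols = self.detector_shape
        rows = (np.arange(nrows) - (nrows - 1) / 2.0) * self.detector_pitch_mm
        cols = (np.arange(ncols) - (ncols - 1) / 2.0) * self.detector_pitch_mm
        return rows, cols

    def col_mm_to_px(self, col_mm: float) -> float:
        ncols = self.detector_shape[1]
        return col_mm / self.detector_pitch_mm + (ncols - 1) / 2.0

    # -- strips --------------------------------------------------------------

    @property
    def mid_magnification(self) -> float:
        return float(self.magnification(self.patient_offset_mm))

    def strip_for_slice(self, slice_x_mm: float) -> tuple:
        """Detector column window for one sagittal plane.

        Returns ``(center_col_px, half_width_px)``; the window is the 0-based
        inclusive range [center - half, center + half].  The center uses the
        mid-patient magnification; the configured width absorbs the
        depth-dependent magnification spread.
        """
        ncols = self.detector_shape[1]
        center = int(round(self.col_mm_to_px(slice_x_mm * self.mid_magnification)))
        half = (self.strip_width_px - 1) // 2
        if center + half < 0 or center - half > ncols - 1:
            raise ValueError(
                f"slice at x={slice_x_mm} mm projects outside the detector "
                f"(center column {center} of {ncols})")
        return center, half

    def strip_columns(self, slice_x_mm: float) -> np.ndarray:
        """The strip's column indices (may extend past the detector edge)."""
        center, half = self.strip_for_slice(slice_x_mm)
        return np.arange(center - half, center + half + 1)


def save_geometry(geom: AcquisitionGeometry, path) -> None:
    d = asdict(geom)
    d["sweep_deg"] = list(d["sweep_deg"])
    d["detector_shape"] = list(d["detector_shape"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)


def load_geometry(path) -> AcquisitionGeometry:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["sweep_deg"] = tuple(d["sweep_deg"])
    d["detector_shape"] = tuple(d["detector_shape"])
    return AcquisitionGeometry(**d)
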