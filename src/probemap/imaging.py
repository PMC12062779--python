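"""Map products: analyte heatmaps and z-height surface profiles.

Each sampling spot is one pixel.  A heatmap cell holds the XIC of that
spot's averaged spectrum in a narrow m/z window (e.g. 858.6 +- 1 for a
phosphocholine lipid); a height-profile cell holds the z at which contact
occurred, i.e. the specimen's topography.  Missed spots stay missing —
no interpolation unless explicitly requested at render time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .conductance import ContactEvent
from .motion import SamplingPlan
from .msio import xic
from .registration import SpotSpectrum

__all__ = ["GridMap", "HeatMap", "HeightProfile", "build_heatmap",
           "build_height_profile", "render_maps", "grid_csv", "read_grid_csv"]


@dataclass(frozen=True)
class GridMap:
    """A per-spot value on the sampling grid; NaN marks missing cells.

    ``values`` has shape (n_rows, n_cols); row 0 is the smallest y.
    """

    values: np.ndarray
    pitch: float
    origin: tuple[float, float]
    label: str = ""

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def relief(self) -> float:
        """max - min over non-missing cells."""
        v = self.values[np.isfinite(self.values)]
        if v.size == 0:
            return float("nan")
        return float(v.max() - v.min())


class HeatMap(GridMap):
    pass


class HeightProfile(GridMap):
    pass


def _cell(plan: SamplingPlan, x: float, y: float) -> tuple[int, int]:
    col = round((x - plan.origin_x) / plan.pitch)
    row = round((y - plan.origin_y) / plan.pitch)
    return int(row), int(col)


def _index_to_cell(plan: SamplingPlan) -> dict[int, tuple[int, int]]:
    return {i: _cell(plan, x, y) for i, x, y in plan.spots}


def build_heatmap(
    spot_spectra: list[SpotSpectrum],
    plan: SamplingPlan,
    mz_center: float,
    mz_tol: float,
) -> HeatMap:
    """Grid of per-spot XIC values of the averaged spot spectra."""
    cells = _index_to_cell(plan)
    values = np.full((plan.n_rows, plan.n_cols), np.nan)
    for ss in spot_spectra:
        if ss.spot_index not in cells:
            raise ValueError(f"spot index {ss.spot_index} not in plan")
        if ss.empty:
            continue
        r, c = cells[ss.spot_index]
        values[r, c] = float(xic([ss.spectrum], mz_center, mz_tol).values[0])
    return HeatMap(values, plan.pitch, (plan.origin_x, plan.origin_y),
                   label=f"XIC m/z {mz_center:g} +- {mz_tol:g}")


def build_height_profile(
    events: list[ContactEvent],
    plan: SamplingPlan,
) -> HeightProfile:
    """Grid of contact z-heights; missed spots stay missing."""
    cells = _index_to_cell(plan)
    values = np.full((plan.n_rows, plan.n_cols), np.nan)
    seen: set[int] = set()
    for ev in events:
        if ev.spot_index in seen:
            raise ValueError(f"duplicate contact event for spot {ev.spot_index}")
        seen.add(ev.spot_index)
        if ev.spot_index not in cells:
            raise ValueError(f"spot index {ev.spot_index} not in plan")
        if ev.missed:
            continue
        r, c = cells[ev.spot_index]
        values[r, c] = ev.contact_z
    return HeightProfile(values, plan.pitch, (plan.origin_x, plan.origin_y),
                         label="contact z (mm)")


def grid_csv(gmap: GridMap) -> str:
    """CSV matrix of the map (rows = y, cols = x; missing cells blank).

    Row 0 is the smallest y, stated in the header comment to avoid the
    image-versus-plot vertical flip.
    """
    buf = io.StringIO()
    buf.write(f"# {gmap.label}; origin=({gmap.origin[0]:g},{gmap.origin[1]:g}) mm; "
              f"pitch={gmap.pitch:g} mm; row 0 = smallest y\n")
    for row in gmap.values:
        buf.write(",".join("" if not np.isfinite(v) else repr(float(v))
                           for v in row) + "\n")
    return buf.getvalue()


def read_grid_csv(text: str) -> np.ndarray:
    """Parse a :func:`grid_csv` matrix back into an array (NaN = blank)."""
    rows = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        rows.append([float(v) if v else float("nan") for v in line.split(",")])
    return np.asarray(rows)


def render_maps(
    gmap: GridMap,
    out_prefix,
    cmap: str = "viridis",
    vlim: tuple[float, float] | None = None,
    interpolate: bool = False,
) -> tuple[str, str]:
    """Write a raster image and the gridded CSV for a map.

    The colour scale is perceptually uniform by default and spans the data
    min/max unless fixed limits are given (for cross-run comparison).
    Missing cells render in a distinct colour; interpolation is a
    rendering option only and defaults off.

    Returns the (png_path, csv_path) pair.
    """
    if not np.any(np.isfinite(gmap.values)):
        raise ValueError("map has no finite cells to render")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad("#b0b0b0")
    vmin, vmax = vlim if vlim is not None else (None, None)
    data = np.ma.masked_invalid(gmap.values)
    x0, y0 = gmap.origin
    extent = (
        x0 - gmap.pitch / 2, x0 + (gmap.n_cols - 0.5) * gmap.pitch,
        y0 - gmap.pitch / 2, y0 + (gmap.n_rows - 0.5) * gmap.pitch,
    )
    im = ax.imshow(
        data, cmap=cm, vmin=vmin, vmax=vmax, origin="lower", extent=extent,
        interpolation="bilinear" if interpolate else "nearest",
    )
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title(gmap.label)
    fig.colorbar(im, ax=ax)
    png_path = f"{out_prefix}.png"
    csv_path = f"{out_prefix}.csv"
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
    with open(csv_path, "w") as fh:
        fh.write(grid_csv(gmap))
    return png_path, csv_path
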