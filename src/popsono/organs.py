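"""Organ vocabulary and the healthy midsagittal reference layout.

Coordinates follow the raster convention of a transperineal midsagittal
ultrasound frame: the origin is the top-left corner, the row index increases
caudally (so organ *descent* means an increasing row coordinate) and the
column index increases from the anterior (pubic) side toward the posterior
(anorectal) side.  The layout is expressed in millimetres relative to the
frame origin so that it is independent of the pixel raster; at the default
0.5 mm/px scale it fills a 64 mm x 64 mm field of view (128 x 128 px).

Each organ is modelled as an axis-aligned ellipse: (center_row_mm,
center_col_mm, semi_axis_row_mm, semi_axis_col_mm).  The values are a
stylised but anatomically ordered arrangement: the pubic symphysis is the
fixed bony landmark, the urethra/bladder sit anteriorly, the vagina and
uterus centrally, the anus/rectum posteriorly, and the levator ani forms a
wide sling caudal to everything else.
"""

from __future__ import annotations

# The eight organs segmented per frame, in canonical order.  The order is
# load-bearing: it fixes the integer coding of the organ indicator column.
ORGANS: tuple[str, ...] = (
    "pubis",
    "urethra",
    "bladder",
    "vagina",
    "uterus",
    "anus",
    "rectum",
    "levator_ani",
)

# Virtual measurement region for enterocele assessment (abdominal content
# between vagina and rectum, anterior to the anorectal angle).  It is tracked
# like an organ for ground-truth purposes but is never rendered to a
# confidence map: it is not a structure the segmentation network knows.
ENTEROCELE_REGION = "enterocele_region"

# (center_row_mm, center_col_mm, semi_axis_row_mm, semi_axis_col_mm)
HEALTHY_LAYOUT_MM: dict[str, tuple[float, float, float, float]] = {
    "pubis": (28.0, 15.0, 3.0, 2.0),
    "urethra": (29.5, 21.0, 4.0, 1.5),
    "bladder": (20.0, 24.0, 6.0, 5.0),
    "vagina": (31.0, 30.0, 5.0, 2.0),
    "uterus": (18.0, 31.0, 6.0, 3.5),
    "anus": (37.0, 40.0, 3.0, 2.0),
    "rectum": (29.0, 41.0, 6.0, 3.5),
    "levator_ani": (40.0, 32.0, 2.5, 10.0),
    ENTEROCELE_REGION: (27.0, 36.0, 2.0, 2.0),
}
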