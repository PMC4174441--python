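"""Per-gene coverage figures: replicate depth tracks over the gene model.

Each figure shows up to three IP replicates as depth polylines in the
fixed colour order red, green, blue, above the gene model drawn as exon
rectangles whose opacity is the fraction of annotated isoforms
containing that exonic interval (constitutive exons dark, minor-isoform
exons light), joined by an intron connector line. Output is SVG built
with the stdlib XML tree, so byte output is deterministic for a fixed
input.
"""

from __future__ import annotations

from dataclasses import dataclass
from xml.etree import ElementTree as ET

import numpy as np

from .annotation import GeneModel
from .assignment import FragmentAlignment

TRACK_COLORS = ("red", "green", "blue")


@dataclass
class CoverageProfile:
    """Per-base fragment depth over a gene region."""

    gene_id: str
    library_id: str
    region_start: int
    region_end: int
    depth: np.ndarray  # int array, length region_end - region_start


def coverage_profile(
    fragments: list[FragmentAlignment],
    gene_id: str,
    region_start: int,
    region_end: int,
    library_id: str = "",
) -> CoverageProfile:
    """depth[i] = number of fragments with an aligned block covering
    base region_start+i; bases covered by both mates of one fragment
    count once (fragment blocks are mate-merged upstream)."""
    depth = np.zeros(region_end - region_start, dtype=np.int64)
    for frag in fragments:
        for s, e in frag.blocks:
            lo = max(s, region_start) - region_start
            hi = min(e, region_end) - region_start
            if hi > lo:
                depth[lo:hi] += 1
    return CoverageProfile(gene_id, library_id, region_start, region_end, depth)


def _fmt(x: float) -> str:
    return f"{x:.2f}".rstrip("0").rstrip(".")


def render_coverage_svg(
    gene: GeneModel,
    profiles: dict[int, CoverageProfile],
    occurrence: dict[tuple[int, int], float],
    path: str,
    width: int = 900,
    track_height: int = 70,
    colors: tuple[str, ...] = TRACK_COLORS,
) -> None:
    """Write the coverage figure for one gene as an SVG file.

    ``profiles`` maps replicate number (1-3) to its CoverageProfile;
    replicates share one vertical scale (the max depth across all of
    them) so tracks are visually comparable. ``occurrence`` comes from
    :func:`ripenrich.annotation.exon_occurrence`.
    """
    if not 1 <= len(profiles) <= 3:
        raise ValueError("render_coverage_svg takes 1-3 replicate profiles")
    reps = sorted(profiles)
    region_start = gene.region_start
    region_end = gene.region_end
    span = region_end - region_start
    margin = 50
    plot_w = width - 2 * margin
    model_h = 40
    height = margin + len(reps) * (track_height + 10) + model_h + margin

    ymax = max(1, max(int(profiles[r].depth.max()) for r in reps))

    def x_of(pos: int) -> float:
        return margin + (pos - region_start) * plot_w / span

    svg = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "width": str(width),
            "height": str(height),
            "viewBox": f"0 0 {width} {height}",
        },
    )
    title = ET.SubElement(svg, "text", {"x": str(margin), "y": "30", "font-size": "16"})
    title.text = f"{gene.gene_id}  {gene.chrom}:{region_start + 1:,}-{region_end:,} ({gene.strand})"

    # step for the polyline: cap segments per track so files stay small
    step = max(1, -(-span // 500))

    for i, rep in enumerate(reps):
        prof = profiles[rep]
        top = margin + i * (track_height + 10)
        base = top + track_height
        pts = [f"{_fmt(x_of(region_start))},{_fmt(base)}"]
        for off in range(0, span, step):
            d = int(prof.depth[off : off + step].max())
            y = base - d * track_height / ymax
            pts.append(f"{_fmt(x_of(region_start + off))},{_fmt(y)}")
            pts.append(f"{_fmt(x_of(min(region_start + off + step, region_end)))},{_fmt(y)}")
        pts.append(f"{_fmt(x_of(region_end))},{_fmt(base)}")
        ET.SubElement(
            svg,
            "polyline",
            {
                "class": "coverage-track",
                "id": f"track-rep{rep}",
                "points": " ".join(pts),
                "fill": "none",
                "stroke": colors[i],
                "stroke-width": "1",
            },
        )
        label = ET.SubElement(
            svg,
            "text",
            {"x": "5", "y": _fmt(top + track_height / 2), "font-size": "11", "fill": colors[i]},
        )
        label.text = f"rep {rep} (max {int(prof.depth.max())})"

    # gene model: intron connector + occurrence-shaded exon rectangles
    model_top = margin + len(reps) * (track_height + 10) + 10
    mid = model_top + 10
    ET.SubElement(
        svg,
        "line",
        {
            "class": "intron-connector",
            "x1": _fmt(x_of(region_start)),
            "x2": _fmt(x_of(region_end)),
            "y1": _fmt(mid),
            "y2": _fmt(mid),
            "stroke": "black",
            "stroke-width": "1",
        },
    )
    for (s, e), frac in sorted(occurrence.items()):
        ET.SubElement(
            svg,
            "rect",
            {
                "class": "exon",
                "x": _fmt(x_of(s)),
                "y": _fmt(model_top),
                "width": _fmt(max(0.5, (e - s) * plot_w / span)),
                "height": "20",
                "fill": "black",
                "fill-opacity": f"{frac:.4f}",
                "stroke": "black",
                "stroke-width": "0.5",
            },
        )

    # coordinate axis labels
    for pos, anchor in ((region_start, "start"), (region_end, "end")):
        t = ET.SubElement(
            svg,
            "text",
            {
                "class": "axis-label",
                "x": _fmt(x_of(pos)),
                "y": _fmt(model_top + 38),
                "font-size": "10",
                "text-anchor": "middle",
            },
        )
        t.text = f"{pos + 1:,}" if anchor == "start" else f"{pos:,}"

    tree = ET.ElementTree(svg)
    with open(path, "wb") as fh:
        fh.write(b'<?xml version="1.0" encoding="UTF-8"?>\n')
        tree.write(fh, encoding="utf-8", xml_declaration=False)
        fh.write(b"\n")
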