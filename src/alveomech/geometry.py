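"""Parametric 2-D buccolingual cross-section of an incisor in its alveolar housing.

The cross-section idealizes a maxillary incisor as a rounded tapered root
(parabolic flank) surrounded by a periodontal-ligament (PDL) band, cancellous
bone, and two cortical plates of independent thickness — the buccal plate may
be much thinner than the palatal one (thin phenotype).  An optional softened
corticotomy band sits on the inner face of the buccal plate, running apically
from the alveolar crest.

Coordinate frame: x = buccolingual axis with +x buccal, y = apico-coronal with
+y coronal; the origin is at the cervical line on the root axis; units mm.

The mesher is structured (transfinite): every region boundary is an exact
polyline of the region outlines, so the mesh is conforming by construction and
per-region element areas sum to the polygon areas to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "TOOTH", "PDL", "CORT_BUCCAL", "CORT_PALATAL", "CANCELLOUS",
    "CORTICOTOMY_BAND", "REGION_LABELS", "APICAL_MARGIN_MM",
    "PhenotypeParams", "RegionOutlines", "Mesh", "TrackingNodes",
    "build_outline", "generate_mesh", "locate_tracking_nodes",
]

TOOTH = "TOOTH"
PDL = "PDL"
CORT_BUCCAL = "CORT_BUCCAL"
CORT_PALATAL = "CORT_PALATAL"
CANCELLOUS = "CANCELLOUS"
CORTICOTOMY_BAND = "CORTICOTOMY_BAND"
REGION_LABELS = (TOOTH, PDL, CORT_BUCCAL, CORT_PALATAL, CANCELLOUS,
                 CORTICOTOMY_BAND)

#: Depth of basal bone (mm) modeled below the PDL apex cap down to the fixed
#: basal boundary.  This column supplies the elastic give of the far field
#: (the surrounding jaw), which carries the alveolar segment bodily under
#: load; it is a property of the modeled anatomy, not of the phenotype,
#: hence a module constant.
APICAL_MARGIN_MM = 18.0

#: Depth below the crest (mm) of the skeletal-anchorage (mini-implant) nodes
#: on the buccal plate — mid-root level, where such implants are placed.
ANCHOR_DEPTH_MM = 8.0


class GeometryError(ValueError):
    """Invalid phenotype parameters or degenerate outline."""


@dataclass(frozen=True)
class PhenotypeParams:
    """Parametric description of the buccolingual cross-section (mm).

    ``corticotomy_depth`` is the apical extent of the corticotomy cut below
    the alveolar crest; 0 means no corticotomy.  ``root_apical_taper`` is the
    ratio of apical to cervical root width, in (0, 1].
    """

    root_length: float = 13.0
    crown_height: float = 5.0
    root_cervical_width: float = 6.5
    root_apical_taper: float = 0.60
    pdl_thickness: float = 0.2
    buccal_cortical_thickness: float = 0.4
    palatal_cortical_thickness: float = 1.2
    cancellous_buccolingual_extent: float = 3.5
    corticotomy_depth: float = 0.0
    corticotomy_band_width: float = 0.2

    def __post_init__(self) -> None:
        positive = ("root_length", "crown_height", "root_cervical_width",
                    "pdl_thickness", "buccal_cortical_thickness",
                    "palatal_cortical_thickness",
                    "cancellous_buccolingual_extent", "corticotomy_band_width")
        for name in positive:
            if not getattr(self, name) > 0:
                raise GeometryError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.corticotomy_depth < 0:
            raise GeometryError(
                f"corticotomy_depth must be >= 0, got {self.corticotomy_depth!r}")
        if not 0 < self.root_apical_taper <= 1:
            raise GeometryError(
                f"root_apical_taper must be in (0, 1], got {self.root_apical_taper!r}")
        if not (self.pdl_thickness
                < self.buccal_cortical_thickness + self.cancellous_buccolingual_extent):
            raise GeometryError(
                "pdl_thickness must fit inside the alveolar housing "
                "(pdl_thickness < buccal_cortical_thickness + cancellous extent)")
        if self.corticotomy_depth > self.root_length:
            raise GeometryError(
                "corticotomy_depth must not exceed root_length "
                f"({self.corticotomy_depth} > {self.root_length})")
        if (self.corticotomy_depth > 0
                and self.corticotomy_band_width >= self.buccal_cortical_thickness):
            raise GeometryError(
                "corticotomy_band_width must be smaller than "
                "buccal_cortical_thickness so the band stays inside the plate")

    # -- derived geometry ---------------------------------------------------

    @property
    def cervical_half_width(self) -> float:
        return 0.5 * self.root_cervical_width

    @property
    def apical_half_width(self) -> float:
        return self.cervical_half_width * self.root_apical_taper

    def half_width(self, y):
        """Root half-width at depth y (mm); parabolic flank, clamped outside
        [-root_length, 0] to the apical / cervical value."""
        s = np.clip(-np.asarray(y, dtype=float) / self.root_length, 0.0, 1.0)
        return self.cervical_half_width * (1.0 - (1.0 - self.root_apical_taper) * s**2)

    def mirrored(self) -> "PhenotypeParams":
        """Swap buccal and palatal cortical thicknesses (phenotype reflection)."""
        return PhenotypeParams(
            root_length=self.root_length,
            crown_height=self.crown_height,
            root_cervical_width=self.root_cervical_width,
            root_apical_taper=self.root_apical_taper,
            pdl_thickness=self.pdl_thickness,
            buccal_cortical_thickness=self.palatal_cortical_thickness,
            palatal_cortical_thickness=self.buccal_cortical_thickness,
            cancellous_buccolingual_extent=self.cancellous_buccolingual_extent,
            corticotomy_depth=self.corticotomy_depth,
            corticotomy_band_width=self.corticotomy_band_width,
        )


@dataclass
class RegionOutlines:
    """Closed planar polygon per region label; produced by :func:`build_outline`.

    ``flank_y`` holds the y-stations at which the parabolic root flank was
    sampled; the mesher reuses them so mesh boundaries lie exactly on the
    outline polylines.
    """

    regions: dict
    params: PhenotypeParams
    flank_y: np.ndarray

    def polygon(self, label: str) -> Polygon:
        return Polygon(self.regions[label])

    def area(self, label: str) -> float:
        return self.polygon(label).area

    @property
    def labels(self):
        return tuple(self.regions)


@dataclass
class Mesh:
    """Conforming triangle mesh with region labels and named node sets."""

    nodes: np.ndarray              # (N, 2) mm
    elements: np.ndarray           # (M, 3) CCW node indices
    element_region: np.ndarray     # (M,) region label strings
    node_sets: dict                # name -> np.ndarray of node indices
    characteristic_length: float   # mm
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_areas(self) -> np.ndarray:
        p = self.nodes[self.elements]
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        return 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])

    def region_elements(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.element_region == label)


@dataclass(frozen=True)
class TrackingNodes:
    """Bracket point on the buccal crown surface and the root apex node."""

    crown_node: int
    apex_node: int


# ---------------------------------------------------------------------------
# Outline construction
# ---------------------------------------------------------------------------

def build_outline(params: PhenotypeParams, flank_ds: float = 0.25) -> RegionOutlines:
    """Build one closed polygon per region of the cross-section.

    The corticotomy band polygon is present iff ``corticotomy_depth > 0``.
    ``flank_ds`` controls the sampling step of the parabolic root flank.
    """
    p = params
    L = p.root_length
    t = p.pdl_thickness
    wc = p.cervical_half_width
    wa = p.apical_half_width
    y_bot = -(L + t + APICAL_MARGIN_MM)

    n_fl = max(3, int(math.ceil(L / flank_ds)) + 1)
    flank_y = -np.linspace(0.0, L, n_fl)          # crest -> apex
    hw = p.half_width(flank_y)

    # distances from the root axis to the cancellous/cortex interfaces
    d_canc_out = wc + t + p.cancellous_buccolingual_extent
    d_cb_out = d_canc_out + p.buccal_cortical_thickness
    d_cp_out = d_canc_out + p.palatal_cortical_thickness

    def pts(xs, ys):
        return np.column_stack([np.asarray(xs, float), np.asarray(ys, float)])

    regions: dict = {}

    # TOOTH: crown rectangle on top of the tapered root
    tooth = np.vstack([
        pts([-wc, wc], [p.crown_height, p.crown_height]),
        pts(hw, flank_y),                        # buccal flank down
        pts(-hw[::-1], flank_y[::-1]),           # across apex, palatal flank up
    ])
    regions[TOOTH] = tooth

    # PDL: U-shaped band of thickness t around the root, closed by a cap of
    # thickness t under the (truncated) apex.  `inner` runs buccal-crest ->
    # apex -> palatal-crest along the root surface; `outer` returns
    # palatal-crest -> under the cap -> buccal-crest along the housing
    # surface, closing the band without self-intersection.
    inner = np.vstack([
        pts(hw, flank_y),                                  # buccal crest->apex
        pts(-hw[::-1], flank_y[::-1]),                     # apex->palatal crest
    ])
    outer = np.vstack([
        pts(-(hw + t), flank_y),                           # palatal crest->apex
        pts([-(wa + t), wa + t], [-(L + t), -(L + t)]),    # under the cap
        pts((hw + t)[::-1], flank_y[::-1]),                # apex->buccal crest
    ])
    regions[PDL] = np.vstack([inner, outer])

    # CANCELLOUS: between the PDL outer boundary and the cortical plates,
    # extending APICAL_MARGIN_MM below the PDL cap.
    canc = np.vstack([
        pts([d_canc_out, d_canc_out], [0.0, y_bot]),
        pts([-d_canc_out, -d_canc_out], [y_bot, 0.0]),
        pts([-(wc + t)], [0.0]),
        pts(-(hw + t)[1:], flank_y[1:]),                   # palatal outer down
        pts([-(wa + t), wa + t], [-(L + t), -(L + t)]),
        pts((hw + t)[::-1], flank_y[::-1]),                # buccal outer up
    ])
    regions[CANCELLOUS] = canc

    # Cortical plates (full-height slabs, crest at y = 0)
    regions[CORT_PALATAL] = pts(
        [-d_canc_out, -d_cp_out, -d_cp_out, -d_canc_out],
        [0.0, 0.0, y_bot, y_bot])

    if p.corticotomy_depth > 0:
        d_band = d_canc_out + p.corticotomy_band_width
        regions[CORTICOTOMY_BAND] = pts(
            [d_canc_out, d_band, d_band, d_canc_out],
            [0.0, 0.0, -p.corticotomy_depth, -p.corticotomy_depth])
        # L-shaped remainder of the buccal plate
        regions[CORT_BUCCAL] = pts(
            [d_band, d_cb_out, d_cb_out, d_canc_out, d_canc_out, d_band],
            [0.0, 0.0, y_bot, y_bot, -p.corticotomy_depth, -p.corticotomy_depth])
    else:
        regions[CORT_BUCCAL] = pts(
            [d_canc_out, d_cb_out, d_cb_out, d_canc_out],
            [0.0, 0.0, y_bot, y_bot])

    out = RegionOutlines(regions=regions, params=p, flank_y=flank_y)
    for label, ring in regions.items():
        poly = Polygon(ring)
        if not poly.is_valid or poly.area <= 0:
            raise GeometryError(f"degenerate outline for region {label}")
    return out


# ---------------------------------------------------------------------------
# Structured conforming mesher
# ---------------------------------------------------------------------------

def _subdivide(lo: float, hi: float, target: float) -> np.ndarray:
    """Stations from lo to hi (both endpoint-exact) with spacing <= target."""
    n = max(1, int(math.ceil((hi - lo) / target - 1e-12)))
    f = np.arange(n + 1) / n
    return lo * (1.0 - f) + hi * f


def _band_fractions(n: int) -> np.ndarray:
    return np.arange(n + 1) / n


def generate_mesh(outlines: RegionOutlines, h_pdl: float = 0.1,
                  h_far: float = 0.5) -> Mesh:
    """Mesh the cross-section with a layered structured triangulation.

    ``h_pdl`` bounds the element size in the PDL band (and the layer spacing
    along the socket); ``h_far`` is the target size elsewhere.  Named node
    sets: FIXED_BOUNDARY (basal edge), CROWN_LOAD (bracket point), ANCHOR
    (buccal plate nodes at mini-implant depth, present when a corticotomy
    band exists), CREST_BUCCAL (buccal plate nodes at the crest).
    """
    if not 0 < h_pdl <= h_far:
        raise GeometryError(f"require 0 < h_pdl <= h_far, got {h_pdl}, {h_far}")
    p = outlines.params
    L, t = p.root_length, p.pdl_thickness
    wc, wa = p.cervical_half_width, p.apical_half_width
    y_bot = -(L + t + APICAL_MARGIN_MM)
    d_canc_out = wc + t + p.cancellous_buccolingual_extent
    d_cb_out = d_canc_out + p.buccal_cortical_thickness
    d_cp_out = d_canc_out + p.palatal_cortical_thickness
    depth = p.corticotomy_depth
    split_band = depth > 0

    for label in outlines.labels:
        if outlines.area(label) <= 0:
            raise GeometryError(f"degenerate outline (zero area) in region {label}")

    # ---- layer stations ---------------------------------------------------
    y_anchor_target = -min(ANCHOR_DEPTH_MM, L)
    mandatory = {y_bot, -(L + t), 0.0, p.crown_height}
    mandatory.update(float(y) for y in outlines.flank_y)   # includes 0 and -L
    if split_band:
        mandatory.update({-depth, y_anchor_target})
    mand = np.array(sorted(mandatory))
    layers = [mand[0]]
    for lo, hi in zip(mand[:-1], mand[1:]):
        mid = 0.5 * (lo + hi)
        target = h_pdl if (-(L + t) - 1e-12 <= mid <= 1e-12) else h_far
        seg = _subdivide(lo, hi, target)
        layers.extend(seg[1:])
    ys = np.array(layers)
    n_lay = len(ys)

    # ---- column bands -----------------------------------------------------
    # Half-band descriptors, mirrored exactly: distances from the root axis
    # are computed once and negated for the palatal side so that swapping the
    # plate thicknesses mirrors node coordinates bitwise.
    # root columns also discretize the PDL cap under the apex, whose height
    # is one h_pdl layer; capping their width at 1.8 h_pdl keeps every cap
    # triangle below the h_pdl^2 PDL size bound
    n_root = max(1, int(math.ceil(wc / min(h_far, 1.8 * h_pdl))))
    n_pdl = max(1, int(math.ceil(t / h_pdl)))
    n_canc = max(1, int(math.ceil(p.cancellous_buccolingual_extent / h_far)))
    n_cb_out = max(1, int(math.ceil(
        (p.buccal_cortical_thickness - (p.corticotomy_band_width if split_band else 0.0))
        / h_far)))
    n_cp = max(1, int(math.ceil(p.palatal_cortical_thickness / h_far)))

    # root half-width per layer, linearly interpolated along the outline
    # polyline so mesh boundaries lie exactly on the region polygons
    # (np.interp clamps to the apical / cervical value outside the flank)
    hw_outline = p.half_width(outlines.flank_y)
    hw_l = np.interp(ys, outlines.flank_y[::-1], hw_outline[::-1])
    const = np.full(n_lay, 1.0)

    def lin_edges(lo_arr, hi_arr, n):
        """(n_lay, n+1) station distances between two per-layer edges;
        endpoint-exact so shared band edges coincide bitwise."""
        f = _band_fractions(n)[None, :]
        return lo_arr[:, None] * (1.0 - f) + hi_arr[:, None] * f

    # buccal half, inner to outer (distances >= 0)
    root_b = lin_edges(np.zeros(n_lay), hw_l, n_root)
    pdl_b = lin_edges(hw_l, hw_l + t, n_pdl)
    canc_b = lin_edges(hw_l + t, d_canc_out * const, n_canc)
    cols_b = [("ROOT_B", root_b), ("PDL_B", pdl_b), ("CANC_B", canc_b)]
    if split_band:
        band_b = lin_edges(d_canc_out * const,
                           (d_canc_out + p.corticotomy_band_width) * const, 1)
        cortb = lin_edges((d_canc_out + p.corticotomy_band_width) * const,
                          d_cb_out * const, n_cb_out)
        cols_b += [("BAND_B", band_b), ("CORT_B", cortb)]
    else:
        cortb = lin_edges(d_canc_out * const, d_cb_out * const, n_cb_out)
        cols_b += [("CORT_B", cortb)]

    # palatal half, outer to inner (mirror of the buccal construction)
    pdl_p = lin_edges(hw_l, hw_l + t, n_pdl)
    canc_p = lin_edges(hw_l + t, d_canc_out * const, n_canc)
    cortp = lin_edges(d_canc_out * const, d_cp_out * const, n_cp)
    root_p = lin_edges(np.zeros(n_lay), hw_l, n_root)

    # global x stations per layer: palatal outer ... axis ... buccal outer.
    # Adjacent bands share an edge; the duplicate column is dropped on append.
    x_parts = [(-cortp[:, ::-1], "CORT_P"), (-canc_p[:, ::-1], "CANC_P"),
               (-pdl_p[:, ::-1], "PDL_P"), (-root_p[:, ::-1], "ROOT_P")]
    x_parts += [(arr, name) for name, arr in cols_b]
    x_cols = [x_parts[0][0]]
    cell_band: list = [x_parts[0][1]] * (x_parts[0][0].shape[1] - 1)
    for arr, name in x_parts[1:]:
        x_cols.append(arr[:, 1:])
        cell_band.extend([name] * (arr.shape[1] - 1))
    X = np.hstack(x_cols)                   # (n_lay, n_col)
    n_col = X.shape[1]
    assert len(cell_band) == n_col - 1

    # ---- cells ------------------------------------------------------------
    def cell_region(band: str, ymid: float):
        """Region label for a cell, or None if void (outside the material)."""
        if band in ("ROOT_B", "ROOT_P"):
            if ymid > -L:
                return TOOTH
            if ymid > -(L + t):
                return PDL
            return CANCELLOUS
        if ymid > 0:
            return None                     # only the crown exists above y=0
        if band in ("PDL_B", "PDL_P"):
            return PDL if ymid > -(L + t) else CANCELLOUS
        if band in ("CANC_B", "CANC_P"):
            return CANCELLOUS
        if band == "CORT_P":
            return CORT_PALATAL
        if band == "BAND_B":
            return CORTICOTOMY_BAND if ymid > -depth else CORT_BUCCAL
        if band == "CORT_B":
            return CORT_BUCCAL
        raise AssertionError(band)

    node_id = -np.ones((n_lay, n_col), dtype=np.int64)
    tris = []
    tri_region = []
    quads = []                              # (i, j, region) for node marking
    for i in range(n_lay - 1):
        ymid = 0.5 * (ys[i] + ys[i + 1])
        for j in range(n_col - 1):
            reg = cell_region(cell_band[j], ymid)
            if reg is None:
                continue
            quads.append((i, j, reg))

    # mark used nodes
    for i, j, _ in quads:
        node_id[i, j] = node_id[i, j + 1] = 0
        node_id[i + 1, j] = node_id[i + 1, j + 1] = 0
    used = np.argwhere(node_id == 0)
    for k, (i, j) in enumerate(used):
        node_id[i, j] = k
    nodes = np.column_stack([X[used[:, 0], used[:, 1]], ys[used[:, 0]]])

    for i, j, reg in quads:
        n00 = node_id[i, j]
        n10 = node_id[i, j + 1]
        n11 = node_id[i + 1, j + 1]
        n01 = node_id[i + 1, j]
        # diagonal orientation flips across the root axis so that a mirrored
        # phenotype produces the exactly mirrored triangulation
        if X[i, j] + X[i, j + 1] >= 0:
            cand = [(n00, n10, n11), (n00, n11, n01)]
        else:
            cand = [(n00, n10, n01), (n10, n11, n01)]
        for tri in cand:
            tris.append(tri)
            tri_region.append(reg)
    elements = np.array(tris, dtype=np.int64)
    element_region = np.array(tri_region, dtype=object)

    # fix orientation to CCW (x increases with j, y with i, so these are CCW
    # already; enforce defensively)
    pcoords = nodes[elements]
    v1 = pcoords[:, 1] - pcoords[:, 0]
    v2 = pcoords[:, 2] - pcoords[:, 0]
    area2 = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    flip = area2 < 0
    if np.any(flip):
        elements[flip] = elements[flip][:, [0, 2, 1]]

    # ---- node sets --------------------------------------------------------
    tol = 1e-9
    fixed = np.flatnonzero(np.abs(nodes[:, 1] - y_bot) < tol)
    bracket = np.array([(wc, p.crown_height)])
    crown_load = np.array([int(np.argmin(
        np.sum((nodes - bracket) ** 2, axis=1)))])

    in_buccal_plate = (nodes[:, 0] >= d_canc_out - tol) & \
                      (nodes[:, 0] <= d_cb_out + tol)
    crest_buccal = np.flatnonzero(in_buccal_plate & (np.abs(nodes[:, 1]) < tol))
    if split_band:
        y_anchor = ys[np.argmin(np.abs(ys - y_anchor_target))]
        anchor = np.flatnonzero(in_buccal_plate
                                & (np.abs(nodes[:, 1] - y_anchor) < tol))
    else:
        anchor = np.array([], dtype=np.int64)

    node_sets = {
        "FIXED_BOUNDARY": fixed,
        "CROWN_LOAD": crown_load,
        "ANCHOR": anchor,
        "CREST_BUCCAL": crest_buccal,
    }

    meta = {
        "params": p,
        "flank_y": outlines.flank_y,
        "flank_half_width": p.half_width(outlines.flank_y),
        "h_pdl": h_pdl,
        "h_far": h_far,
        "y_bottom": y_bot,
    }
    return Mesh(nodes=nodes, elements=elements, element_region=element_region,
                node_sets=node_sets, characteristic_length=h_pdl, meta=meta)


def locate_tracking_nodes(mesh: Mesh, params: PhenotypeParams) -> TrackingNodes:
    """Mesh nodes nearest the bracket point and the root apex, restricted to
    nodes of TOOTH elements."""
    tooth_el = mesh.region_elements(TOOTH)
    if mesh.n_nodes == 0 or len(tooth_el) == 0:
        raise GeometryError("mesh has no TOOTH elements")
    tooth_nodes = np.unique(mesh.elements[tooth_el])
    pts = mesh.nodes[tooth_nodes]
    bracket = np.array([params.cervical_half_width, params.crown_height])
    apex = np.array([0.0, -params.root_length])
    crown = tooth_nodes[int(np.argmin(np.sum((pts - bracket) ** 2, axis=1)))]
    apex_n = tooth_nodes[int(np.argmin(np.sum((pts - apex) ** 2, axis=1)))]
    return TrackingNodes(crown_node=int(crown), apex_node=int(apex_n))
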