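"""Neuron morphologies with a movable axon initial segment (AIS).

A morphology is an ordered list of :class:`Section` objects (soma, dendrites,
hillock, AIS, axon) connected into a tree.  The AIS is a contiguous 30-um span
of the proximal axon whose distance from the soma surface, ``d_ais``, is the
quantity this package ultimately detects and estimates.  Three constructors
are provided: a minimal ball-and-stick model, a procedural branched
("synthetic detailed") model, and an SWC loader for user-supplied
reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

AIS_LENGTH_UM = 30.0
D_AIS_MIN = 5.0
D_AIS_MAX = 40.0

#: membrane channel densities in pS/um^2, keyed by section tag
DEFAULT_DENSITIES = {
    "soma": {"g_na": 50.0, "g_k": 100.0, "g_kv7": 1.0},
    "ais": {"g_na": 7000.0, "g_k": 2000.0, "g_kv7": 7.0},
    "dend": {"g_na": 20.0, "g_k": 0.3, "g_kv7": 1.0},
    # the plain axon and hillock densities are package defaults: enough Na/K
    # for active propagation, far below the AIS hot zone
    "axon": {"g_na": 300.0, "g_k": 100.0, "g_kv7": 0.0},
    "hillock": {"g_na": 50.0, "g_k": 100.0, "g_kv7": 1.0},
}

E_NA_MV = 55.0
E_K_MV = -98.0

# passive defaults (standard cortical values)
RA_OHM_CM = 150.0
CM_UF_CM2 = 1.0
G_LEAK_S_CM2 = 1.0 / 30000.0
E_LEAK_MV = -80.0

VALID_TAGS = ("soma", "dend", "hillock", "ais", "axon")


@dataclass
class AISSpec:
    """Position and length of the axon initial segment.

    ``d_ais`` is the path distance (um) from the soma surface to the proximal
    end of the AIS; the modelled range is 5-40 um.  Length is fixed at 30 um.
    """

    d_ais: float
    length: float = AIS_LENGTH_UM

    def __post_init__(self):
        if not (D_AIS_MIN <= self.d_ais <= D_AIS_MAX):
            raise ValueError(
                f"d_ais={self.d_ais} um outside supported range "
                f"[{D_AIS_MIN}, {D_AIS_MAX}] um"
            )
        if self.length != AIS_LENGTH_UM:
            raise ValueError(f"AIS length is fixed at {AIS_LENGTH_UM} um")


@dataclass
class ChannelDistribution:
    """Per-tag maximal conductance densities (pS/um^2) and reversals (mV)."""

    densities: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DENSITIES.items()})
    e_na: float = E_NA_MV
    e_k: float = E_K_MV

    def __post_init__(self):
        for tag, dens in self.densities.items():
            for name, g in dens.items():
                if g < 0:
                    raise ValueError(f"negative density {name}={g} for tag {tag!r}")
        if "soma" in self.densities and "ais" in self.densities:
            soma, ais = self.densities["soma"], self.densities["ais"]
            if not (ais["g_na"] > soma["g_na"] and ais["g_k"] > soma["g_k"]):
                raise ValueError("AIS Na/K densities must exceed somatic densities")


@dataclass
class Section:
    """A cable section: a polyline of 3D points (um) with per-point radii.

    A spherical soma is encoded as a single point plus radius.  ``parent`` is
    the index of the parent section in ``Morphology.sections`` (-1 for the
    root soma); children attach to the distal end of their parent.
    """

    tag: str
    points: np.ndarray  # (n, 3) um
    radii: np.ndarray  # (n,) um
    n_segments: int = 1
    parent: int = -1

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if self.tag not in VALID_TAGS:
            raise ValueError(f"unknown section tag {self.tag!r}")
        if len(self.points) != len(self.radii):
            raise ValueError("points and radii length mismatch")
        if self.tag != "soma" and len(self.points) < 2:
            raise ValueError("cylindrical sections need >= 2 points")
        if np.any(self.radii <= 0):
            raise ValueError("all radii must be > 0 um")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")

    @property
    def length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    def point_at(self, arclen: float) -> np.ndarray:
        """Interpolate a 3D point at a path distance along the section."""
        seglens = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seglens)])
        arclen = float(np.clip(arclen, 0.0, cum[-1]))
        i = int(np.searchsorted(cum, arclen, side="right") - 1)
        i = min(i, len(seglens) - 1)
        frac = 0.0 if seglens[i] == 0 else (arclen - cum[i]) / seglens[i]
        return self.points[i] + frac * (self.points[i + 1] - self.points[i])


@dataclass
class Morphology:
    """A sectioned neuron with one soma and one contiguous AIS."""

    sections: list
    soma_center: np.ndarray
    axon_orientation_deg: float = 0.0
    d_ais: float | None = None
    biophysics: ChannelDistribution | None = None

    def __post_init__(self):
        self.soma_center = np.asarray(self.soma_center, dtype=float)
        tags = [s.tag for s in self.sections]
        if tags.count("soma") != 1:
            raise ValueError("morphology must contain exactly one soma section")
        if tags.count("ais") != 1:
            raise ValueError("morphology must contain exactly one AIS section")

    def section(self, tag: str) -> Section:
        """First section with the given tag."""
        for s in self.sections:
            if s.tag == tag:
                return s
        raise KeyError(tag)

    @property
    def soma_radius(self) -> float:
        return float(self.section("soma").radii[0])

    def total_length(self, tags=("axon", "ais", "hillock")) -> float:
        return sum(s.length for s in self.sections if s.tag in tags)

    def copy(self) -> "Morphology":
        sections = [
            replace(s, points=s.points.copy(), radii=s.radii.copy())
            for s in self.sections
        ]
        return Morphology(
            sections,
            self.soma_center.copy(),
            self.axon_orientation_deg,
            self.d_ais,
            self.biophysics,
        )


def _segmented_cylinder(tag, start, end, radius, parent, max_seg_um):
    start, end = np.asarray(start, float), np.asarray(end, float)
    length = float(np.linalg.norm(end - start))
    n_seg = max(1, int(np.ceil(length / max_seg_um)))
    return Section(
        tag=tag,
        points=np.vstack([start, end]),
        radii=np.array([radius, radius]),
        n_segments=n_seg,
        parent=parent,
    )


def build_ball_and_stick(ais: AISSpec, z_um: float = 10.0) -> Morphology:
    """Minimal model: 1 mm dendrite (2 um diam), 16 um spherical soma, and a
    1 mm axon (1 um diam) carrying a 30 um AIS starting ``ais.d_ais`` um from
    the soma surface.

    The dendrite extends along -x and the axon along +x from the soma surface;
    moving the AIS relabels a sub-span of the axon, it never changes cable
    length or diameters.
    """
    d = float(ais.d_ais)
    r_soma = 8.0
    r_dend, r_axon = 1.0, 0.5
    axon_total = 1000.0
    center = np.array([0.0, 0.0, z_um])

    soma = Section("soma", center[None, :], np.array([r_soma]), n_segments=1, parent=-1)
    dend = _segmented_cylinder(
        "dend",
        center + [-r_soma, 0, 0],
        center + [-r_soma - 1000.0, 0, 0],
        r_dend,
        parent=0,
        max_seg_um=50.0,
    )
    x0 = r_soma  # axon origin at the soma surface; path distance is x - x0
    sections = [soma, dend]

    def add_axon_span(tag, a, b, parent, max_seg):
        sections.append(
            _segmented_cylinder(
                tag, center + [x0 + a, 0, 0], center + [x0 + b, 0, 0], r_axon, parent, max_seg
            )
        )
        return len(sections) - 1

    prox = add_axon_span("axon", 0.0, d, parent=0, max_seg=5.0)
    ais_idx = add_axon_span("ais", d, d + ais.length, parent=prox, max_seg=5.0)
    # keep fine resolution shortly past the AIS, coarsen distally
    mid_end = min(axon_total, d + ais.length + 40.0)
    mid = add_axon_span("axon", d + ais.length, mid_end, parent=ais_idx, max_seg=5.0)
    if mid_end < axon_total:
        add_axon_span("axon", mid_end, axon_total, parent=mid, max_seg=25.0)

    return Morphology(sections, center, axon_orientation_deg=0.0, d_ais=d)


def build_synthetic_detailed(
    seed: int,
    hillock_angle_deg: float,
    ais: AISSpec | None = None,
    z_um: float = 10.0,
    dendrite_rise: float = 0.15,
) -> Morphology:
    """Procedural branched morphology: a polarized multi-branch dendritic
    tree, a 14 um soma, a 5 um tapering hillock, a 30 um AIS, and a 500 um
    straight axon leaving the soma at ``hillock_angle_deg`` in the array
    plane.

    The arbor is polarized like a pyramidal cell: dendrites fan out over the
    hemisphere opposite the axon and climb away from the substrate with slope
    ``dendrite_rise`` (axons grow along the substrate, dendrites stand off
    it), so the proximal-axon field dominates the footprint near the AIS —
    the regime in which AIS tracking from extracellular signals is possible.

    Deterministic given ``seed``; distinct seeds give distinct dendritic
    trees.  The AIS is placed ``ais.d_ais`` um from the soma surface along the
    hillock+axon path (default 15 um).
    """
    if ais is None:
        ais = AISSpec(15.0)
    rng = np.random.default_rng(seed)
    r_soma = 7.0
    center = np.array([0.0, 0.0, z_um])
    sections = [Section("soma", center[None, :], np.array([r_soma]), 1, parent=-1)]

    # dendritic tree: 6 primary branches opposite the axon, some bifurcating
    n_primary = 6
    opposite = hillock_angle_deg + 180.0
    base_angles = opposite + np.linspace(-70, 70, n_primary) + rng.uniform(-10, 10, n_primary)
    for ang in base_angles:
        theta = np.deg2rad(ang)
        direction = np.array([np.cos(theta), np.sin(theta), dendrite_rise])
        direction /= np.linalg.norm(direction)
        length = rng.uniform(120.0, 350.0)
        start = center + r_soma * direction
        end = start + length * direction
        radius = rng.uniform(0.4, 0.8)
        sections.append(
            _segmented_cylinder("dend", start, end, radius, parent=0, max_seg_um=40.0)
        )
        parent_idx = len(sections) - 1
        if rng.random() < 0.6:  # secondary branch
            dtheta = np.deg2rad(ang + rng.uniform(-50, 50))
            d2 = np.array([np.cos(dtheta), np.sin(dtheta), dendrite_rise])
            d2 /= np.linalg.norm(d2)
            end2 = end + rng.uniform(60.0, 180.0) * d2
            sections.append(
                _segmented_cylinder(
                    "dend", end, end2, radius * 0.7, parent=parent_idx, max_seg_um=40.0
                )
            )

    # axonal path: hillock (tapering 2.0 -> 0.6 um) then axon with AIS
    theta = np.deg2rad(hillock_angle_deg)
    u = np.array([np.cos(theta), np.sin(theta), 0.0])
    h_len = 5.0
    h_start = center + r_soma * u
    h_end = h_start + h_len * u
    sections.append(
        Section(
            "hillock",
            np.vstack([h_start, h_end]),
            np.array([2.0, 0.6]),
            n_segments=2,
            parent=0,
        )
    )
    hillock_idx = len(sections) - 1
    r_axon = 0.5
    axon_total = 500.0
    d = float(ais.d_ais)
    if d < h_len:
        raise ValueError(f"d_ais={d} um shorter than the {h_len} um hillock")

    def span(tag, a, b, parent, max_seg):
        sections.append(
            _segmented_cylinder(
                tag, h_start + a * u, h_start + b * u, r_axon, parent, max_seg
            )
        )
        return len(sections) - 1

    prox = span("axon", h_len, d, parent=hillock_idx, max_seg=5.0)
    ais_idx = span("ais", d, d + ais.length, parent=prox, max_seg=5.0)
    mid_end = min(axon_total, d + ais.length + 40.0)
    mid = span("axon", d + ais.length, mid_end, parent=ais_idx, max_seg=5.0)
    if mid_end < axon_total:
        span("axon", mid_end, axon_total, parent=mid, max_seg=25.0)

    return Morphology(
        sections, center, axon_orientation_deg=float(hillock_angle_deg) % 360.0, d_ais=d
    )


def assign_biophysics(m: Morphology, dist: ChannelDistribution | None = None) -> Morphology:
    """Attach channel densities to a morphology (validated); returns ``m``."""
    if dist is None:
        dist = ChannelDistribution()
    try:
        m.section("ais")
    except KeyError:
        raise ValueError("morphology has no AIS section") from None
    m.biophysics = dist
    return m


# ---------------------------------------------------------------------------
# SWC I/O

_SWC_TAGS = {1: "soma", 2: "axon", 3: "dend", 4: "dend"}
_TAG_TO_SWC = {"soma": 1, "axon": 2, "ais": 2, "hillock": 2, "dend": 3}


def _moving_average(x: np.ndarray, window: int = 15) -> np.ndarray:
    """Centered moving average with edge truncation (window shrinks at ends)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    out = np.empty(n)
    half = window // 2
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def _interpolate_small_radii(radii: np.ndarray, floor: float = 0.1) -> np.ndarray:
    """Replace radii <= floor by linear interpolation from valid neighbors."""
    radii = np.asarray(radii, dtype=float).copy()
    bad = radii <= floor
    if bad.all():
        raise ValueError("all radii at or below the interpolation floor")
    if bad.any():
        idx = np.arange(len(radii))
        radii[bad] = np.interp(idx[bad], idx[~bad], radii[~bad])
    return radii


def load_swc(path, smooth: bool = True, ais: AISSpec | None = None) -> Morphology:
    """Load a standard 7-column SWC file.

    Structure ids are mapped 1->soma, 2->axon, 3/4->dend.  Radii at or below
    0.1 um are interpolated from path neighbors and each path's radii are
    smoothed with a 15-sample moving average (disable with ``smooth=False``).
    If the file has no AIS-tagged span, a 30 um AIS is carved out of the
    proximal axon at ``ais.d_ais`` (default 15 um).
    """
    ids, parents, tags, xyz, radii = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"{path}: malformed SWC at line {lineno}: {line!r}")
            try:
                nid, stype = int(parts[0]), int(parts[1])
                x, y, z, r = map(float, parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed SWC at line {lineno}: {exc}") from None
            ids.append(nid)
            tags.append(_SWC_TAGS.get(stype, "dend"))
            xyz.append((x, y, z))
            radii.append(r)
            parents.append(parent)

    if not ids:
        raise ValueError(f"{path}: empty SWC file")
    id_to_row = {nid: i for i, nid in enumerate(ids)}
    xyz = np.asarray(xyz)
    radii = np.asarray(radii)
    parents = [id_to_row.get(p, -1) for p in parents]

    # soma: first type-1 point
    soma_rows = [i for i, t in enumerate(tags) if t == "soma"]
    if not soma_rows:
        raise ValueError(f"{path}: no soma (type 1) point")
    soma_row = soma_rows[0]
    soma_center = xyz[soma_row]
    soma_radius = max(radii[soma_row], 1.0)

    # decompose the tree into unbranched paths of same-tag points
    children: dict[int, list[int]] = {}
    for i, p in enumerate(parents):
        children.setdefault(p, []).append(i)
    n_children = {i: len(children.get(i, [])) for i in range(len(ids))}

    sections = [
        Section("soma", soma_center[None, :], np.array([soma_radius]), 1, parent=-1)
    ]
    row_to_section = {soma_row: 0}

    def walk(start_row, parent_section):
        path = [start_row]
        row = start_row
        while n_children.get(row, 0) == 1:
            nxt = children[row][0]
            if tags[nxt] != tags[start_row]:
                break
            path.append(nxt)
            row = nxt
        prow = parents[start_row]
        ppoint = xyz[prow] if prow >= 0 else soma_center
        pts = np.vstack([ppoint, xyz[path]])
        rr = np.concatenate([[radii[path[0]]], radii[path]])
        rr = _interpolate_small_radii(rr)
        if smooth:
            rr = _moving_average(rr, 15)
        sections.append(
            Section(
                tags[start_row],
                pts,
                rr,
                n_segments=max(1, int(np.ceil(len(pts) / 2))),
                parent=parent_section,
            )
        )
        sec_idx = len(sections) - 1
        row_to_section[row] = sec_idx
        for child in children.get(row, []):
            if child not in path:
                walk(child, sec_idx)

    for child in children.get(soma_row, []):
        walk(child, 0)
    # any roots that are not the soma attach to the soma
    for row, p in enumerate(parents):
        if p == -1 and row != soma_row and row not in row_to_section:
            walk(row, 0)

    # carve the AIS out of the first axon section
    if ais is None:
        ais = AISSpec(15.0)
    axon_secs = [i for i, s in enumerate(sections) if s.tag == "axon"]
    if not axon_secs:
        raise ValueError(f"{path}: no axon (type 2) points; cannot place an AIS")
    # paths parented to the soma start at the soma center: d_ais counts from
    # the soma surface, one radius further along
    surface_offset = soma_radius if sections[axon_secs[0]].parent == 0 else 0.0
    _carve_ais(sections, axon_secs[0], ais, surface_offset)
    return Morphology(sections, soma_center, d_ais=float(ais.d_ais))


def _carve_ais(sections, axon_idx, ais: AISSpec, surface_offset: float = 0.0):
    """Split an axon section into [proximal axon][AIS][distal axon] in place.

    ``surface_offset`` is the path distance from the section's first point to
    the soma surface (nonzero when the path begins at the soma center)."""
    sec = sections[axon_idx]
    d, L = float(ais.d_ais) + surface_offset, float(ais.length)
    if sec.length < d + L:
        raise ValueError(
            f"first axon path ({sec.length:.1f} um) shorter than d_ais+30={d + L} um"
        )
    seglens = np.linalg.norm(np.diff(sec.points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglens)])

    def slice_span(a, b):
        pa, pb = sec.point_at(a), sec.point_at(b)
        inside = (cum > a) & (cum < b)
        pts = np.vstack([pa, sec.points[inside], pb])
        rr = np.interp(
            np.concatenate([[a], cum[inside], [b]]), cum, sec.radii
        )
        return pts, rr

    spans = [("axon", 0.0, d), ("ais", d, d + L), ("axon", d + L, cum[-1])]
    parent = sec.parent
    new_secs = []
    for tag, a, b in spans:
        if b - a <= 0:
            continue
        pts, rr = slice_span(a, b)
        new_secs.append(
            Section(tag, pts, rr, n_segments=max(1, int(np.ceil((b - a) / 5.0))), parent=parent)
        )
        parent = None  # fixed after insertion
    # insert, re-index parents
    offset = len(new_secs) - 1
    for i, s in enumerate(sections):
        if s.parent is not None and s.parent > axon_idx:
            s.parent += offset
    first = axon_idx
    new_secs[0].parent = sec.parent
    for j in range(1, len(new_secs)):
        new_secs[j].parent = first + j - 1
    sections[axon_idx : axon_idx + 1] = new_secs
    # children of the original section now hang off the last new section
    last = first + len(new_secs) - 1
    for i, s in enumerate(sections):
        if i < first or i > last:
            if s.parent == axon_idx and i not in range(first, last + 1):
                s.parent = last


def save_swc(m: Morphology, path) -> None:
    """Write a morphology as standard 7-column SWC (AIS/hillock map to axon).

    A section's first point is written as its own node unless it coincides
    with the parent's tip (contiguous cable), so detached attachment points
    (e.g. the soma surface) survive a round trip.
    """
    rows = []
    nid = 1
    soma = m.section("soma")
    soma_idx = m.sections.index(soma)
    rows.append((nid, 1, *soma.points[0], soma.radii[0], -1))
    section_tip = {soma_idx: 1}
    tip_xyz = {soma_idx: soma.points[0]}
    nid += 1
    for si, sec in enumerate(m.sections):
        if sec.tag == "soma":
            continue
        parent_nid = section_tip.get(sec.parent, 1)
        parent_xyz = tip_xyz.get(sec.parent, soma.points[0])
        swc_type = _TAG_TO_SWC[sec.tag]
        start = 1
        if not np.allclose(sec.points[0], parent_xyz, atol=1e-9):
            start = 0  # write the detached attachment point too
        for pi in range(start, len(sec.points)):
            rows.append((nid, swc_type, *sec.points[pi], sec.radii[pi], parent_nid))
            parent_nid = nid
            nid += 1
        section_tip[si] = parent_nid
        tip_xyz[si] = sec.points[-1]
    with open(path, "w") as fh:
        fh.write("# generated by aistrack\n")
        for r in rows:
            fh.write(
                f"{r[0]} {r[1]} {r[2]:.6f} {r[3]:.6f} {r[4]:.6f} {r[5]:.6f} {r[6]}\n"
            )
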