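"""Stylized compartmental morphologies and SWC input/output.

A morphology is a tree of cylindrical segments labelled ``soma``, ``basal`` or
``apical``.  Geometry is stored in a cell-local frame (micrometres) with the
soma base at the origin and the apical direction along +z; ``soma_depth``
records the absolute vertical position of the soma plane and is applied when
cells are placed in a population.

The stylized generators are stand-ins for reconstructed cortical cells: a
pyramidal template (soma, vertical apical trunk with a tuft, radial basal
dendrites) and a stellate template (isotropically oriented dendrites with no
apical/basal polarity).  They are not claimed to reproduce any particular
reconstruction; their role is to expose the same qualitative geometry (spatial
asymmetry, vertical extent) that shapes extracellular potentials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

REGIONS = ("soma", "basal", "apical")
_SWC_TYPE_TO_REGION = {1: "soma", 3: "basal", 4: "apical"}
_REGION_TO_SWC_TYPE = {v: k for k, v in _SWC_TYPE_TO_REGION.items()}

#: attachment tolerance between a child's start and its parent's end (um)
ATTACH_TOL = 1e-6


class MorphologyError(ValueError):
    """Invalid morphology parameters or inconsistent tree structure."""


class SWCParseError(MorphologyError):
    """Malformed SWC content; message names the offending line."""


@dataclass(frozen=True)
class Segment:
    """One cylindrical neurite section.

    ``start``/``end`` are 3-vectors in micrometres; ``diameter`` in
    micrometres; ``region`` one of soma/basal/apical. ``parent_id`` is -1 for
    the root segment.
    """

    id: int
    parent_id: int
    start: np.ndarray
    end: np.ndarray
    diameter: float
    region: str

    def __post_init__(self):
        object.__setattr__(self, "start", np.asarray(self.start, dtype=float))
        object.__setattr__(self, "end", np.asarray(self.end, dtype=float))

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def lateral_area(self) -> float:
        """Cylinder side area pi*d*L (um^2); end caps are not counted."""
        return math.pi * self.diameter * self.length

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.start + self.end)


@dataclass
class Morphology:
    segments: list[Segment] = field(default_factory=list)
    soma_depth: float = 0.0

    def __post_init__(self):
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if not self.segments:
            raise MorphologyError("morphology has no segments")
        by_id = {}
        roots = 0
        for seg in self.segments:
            if seg.region not in REGIONS:
                raise MorphologyError(f"unknown region {seg.region!r}")
            if seg.length <= 0:
                raise MorphologyError(f"segment {seg.id} has non-positive length")
            if seg.diameter <= 0:
                raise MorphologyError(f"segment {seg.id} has non-positive diameter")
            if seg.id in by_id:
                raise MorphologyError(f"duplicate segment id {seg.id}")
            by_id[seg.id] = seg
            if seg.parent_id == -1:
                roots += 1
        if roots != 1:
            raise MorphologyError(f"expected exactly one root segment, found {roots}")
        # parent links form a tree and children attach at the parent's end
        for seg in self.segments:
            if seg.parent_id == -1:
                continue
            if seg.parent_id not in by_id:
                raise MorphologyError(
                    f"segment {seg.id} references missing parent {seg.parent_id}"
                )
            parent = by_id[seg.parent_id]
            if np.linalg.norm(seg.start - parent.end) > ATTACH_TOL:
                raise MorphologyError(
                    f"segment {seg.id} does not attach to the end of parent {parent.id}"
                )
        # cycle check by walking to the root from every segment
        for seg in self.segments:
            seen = set()
            cur = seg
            while cur.parent_id != -1:
                if cur.id in seen:
                    raise MorphologyError("parent links contain a cycle")
                seen.add(cur.id)
                cur = by_id[cur.parent_id]

    # -- derived quantities -------------------------------------------------
    def total_area(self) -> float:
        """Total lateral membrane area in um^2."""
        return sum(seg.lateral_area for seg in self.segments)

    def regions_present(self) -> set[str]:
        return {seg.region for seg in self.segments}

    def extent_z(self) -> tuple[float, float]:
        zs = np.concatenate(
            [[seg.start[2], seg.end[2]] for seg in self.segments]
        )
        return float(zs.min()), float(zs.max())

    def with_soma_depth(self, soma_depth: float) -> "Morphology":
        m = Morphology.__new__(Morphology)
        m.segments = self.segments
        m.soma_depth = soma_depth
        return m


# ---------------------------------------------------------------------------
# stylized generators
# ---------------------------------------------------------------------------

def _check_positive(**kwargs):
    for name, val in kwargs.items():
        if not (val > 0):
            raise MorphologyError(f"{name} must be positive, got {val}")


def make_stylized_pyramidal(
    soma_diam: float = 20.0,
    trunk_length: float = 600.0,
    trunk_diam: float = 4.0,
    n_basal: int = 6,
    basal_length: float = 200.0,
    basal_diam: float = 2.0,
    n_tuft: int = 6,
    tuft_length: float = 150.0,
    tuft_diam: float = 1.5,
    basal_tilt_deg: float = 20.0,
    soma_depth: float = 0.0,
) -> Morphology:
    """Soma + vertical apical trunk with a horizontal tuft fan + radial basal star.

    The soma is a single cylinder of equal length and diameter spanning
    z in [0, soma_diam]; the trunk rises from the soma top so the apical
    region tops out exactly ``trunk_length`` above the soma top (the tuft
    branches fan out horizontally).  Basal dendrites radiate from the soma,
    tilted ``basal_tilt_deg`` below horizontal.
    """
    _check_positive(
        soma_diam=soma_diam, trunk_length=trunk_length, trunk_diam=trunk_diam,
        basal_length=basal_length, basal_diam=basal_diam,
        tuft_length=tuft_length, tuft_diam=tuft_diam,
    )
    if n_basal < 1 or n_tuft < 1:
        raise MorphologyError("n_basal and n_tuft must be >= 1")

    segs = []
    soma_top = np.array([0.0, 0.0, soma_diam])
    segs.append(Segment(0, -1, np.zeros(3), soma_top, soma_diam, "soma"))
    trunk_top = soma_top + np.array([0.0, 0.0, trunk_length])
    segs.append(Segment(1, 0, soma_top, trunk_top, trunk_diam, "apical"))
    next_id = 2
    for k in range(n_tuft):
        ang = 2 * math.pi * k / n_tuft
        d = np.array([math.cos(ang), math.sin(ang), 0.0])
        segs.append(
            Segment(next_id, 1, trunk_top, trunk_top + tuft_length * d,
                    tuft_diam, "apical")
        )
        next_id += 1
    tilt = math.radians(basal_tilt_deg)
    for k in range(n_basal):
        ang = 2 * math.pi * (k + 0.5) / n_basal
        d = np.array(
            [math.cos(ang) * math.cos(tilt),
             math.sin(ang) * math.cos(tilt),
             -math.sin(tilt)]
        )
        segs.append(
            Segment(next_id, 0, soma_top, soma_top + basal_length * d,
                    basal_diam, "basal")
        )
        next_id += 1
    return Morphology(segs, soma_depth=soma_depth)


def isotropic_directions(n: int) -> np.ndarray:
    """Deterministic set of n unit vectors whose sum vanishes.

    Even n: antipodal pairs taken from a golden-angle spiral over one
    hemisphere (sum exactly zero).  Odd n: a regular planar star (sum zero to
    floating-point roundoff).
    """
    if n % 2 == 0:
        half = n // 2
        golden = math.pi * (3.0 - math.sqrt(5.0))
        dirs = []
        for k in range(half):
            z = (k + 0.5) / half  # upper hemisphere, avoid poles/equator
            r = math.sqrt(max(0.0, 1.0 - z * z))
            phi = golden * k
            v = np.array([r * math.cos(phi), r * math.sin(phi), z])
            dirs.append(v)
            dirs.append(-v)
        return np.array(dirs)
    angles = 2 * math.pi * np.arange(n) / n
    return np.stack(
        [np.cos(angles), np.sin(angles), np.zeros(n)], axis=1
    )


def make_stylized_stellate(
    n_dendrites: int = 10,
    dendrite_length: float = 200.0,
    dendrite_diam: float = 1.5,
    soma_diam: float = 15.0,
    soma_depth: float = 0.0,
) -> Morphology:
    """Star-shaped cell: isotropic straight dendrites, all labelled basal."""
    if n_dendrites < 4:
        raise MorphologyError("a stellate cell needs n_dendrites >= 4")
    _check_positive(
        dendrite_length=dendrite_length, dendrite_diam=dendrite_diam,
        soma_diam=soma_diam,
    )
    segs = []
    soma_top = np.array([0.0, 0.0, soma_diam])
    segs.append(Segment(0, -1, np.zeros(3), soma_top, soma_diam, "soma"))
    for k, d in enumerate(isotropic_directions(n_dendrites)):
        segs.append(
            Segment(k + 1, 0, soma_top, soma_top + dendrite_length * d,
                    dendrite_diam, "basal")
        )
    return Morphology(segs, soma_depth=soma_depth)


# ---------------------------------------------------------------------------
# SWC I/O (standard 7-column, types 1=soma, 3=basal dendrite, 4=apical)
# ---------------------------------------------------------------------------

def write_swc(morphology: Morphology, path) -> None:
    """Write the morphology as a standard 7-column SWC file.

    The root sample is the soma base point; every segment contributes one
    sample at its end with radius = diameter/2.  ``soma_depth`` is preserved
    in a comment so that write/read round-trips are identity.
    """
    lines = ["# SWC export (lfpreach)", f"# soma_depth {morphology.soma_depth!r}"]
    node_of_segment = {}
    root = next(s for s in morphology.segments if s.parent_id == -1)
    x, y, z = root.start
    lines.append(
        f"1 {_REGION_TO_SWC_TYPE[root.region]} {x:.9g} {y:.9g} {z:.9g} "
        f"{root.diameter / 2:.9g} -1"
    )
    next_node = 2
    for seg in morphology.segments:
        parent_node = 1 if seg.parent_id == -1 else node_of_segment[seg.parent_id]
        x, y, z = seg.end
        lines.append(
            f"{next_node} {_REGION_TO_SWC_TYPE[seg.region]} "
            f"{x:.9g} {y:.9g} {z:.9g} {seg.diameter / 2:.9g} {parent_node}"
        )
        node_of_segment[seg.id] = next_node
        next_node += 1
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_swc(path) -> Morphology:
    """Read a single-tree SWC file (types 1, 3, 4) into a Morphology."""
    soma_depth = 0.0
    points = {}  # node id -> (type, xyz, radius, parent)
    order = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 2 and parts[0] == "soma_depth":
                    soma_depth = float(parts[1])
                continue
            if not line:
                continue
            cols = line.split()
            if len(cols) != 7:
                raise SWCParseError(f"line {lineno}: expected 7 columns, got {len(cols)}")
            try:
                nid = int(cols[0]); typ = int(cols[1])
                xyz = np.array([float(c) for c in cols[2:5]])
                radius = float(cols[5]); parent = int(cols[6])
            except ValueError as exc:
                raise SWCParseError(f"line {lineno}: {exc}") from None
            if typ not in _SWC_TYPE_TO_REGION:
                raise SWCParseError(f"line {lineno}: unsupported SWC type {typ}")
            if nid in points:
                raise SWCParseError(f"line {lineno}: duplicate node id {nid}")
            points[nid] = (typ, xyz, radius, parent, lineno)
            order.append(nid)
    roots = [nid for nid in order if points[nid][3] == -1]
    if len(roots) != 1:
        raise SWCParseError(f"expected one root sample, found {len(roots)}")
    root = roots[0]
    segs = []
    node_to_seg = {root: -1}
    seg_id = 0
    for nid in order:
        typ, xyz, radius, parent, lineno = points[nid]
        if parent == -1:
            continue
        if parent not in points:
            raise SWCParseError(f"line {lineno}: parent {parent} does not exist")
        segs.append(
            Segment(seg_id, node_to_seg[parent], points[parent][1], xyz,
                    2 * radius, _SWC_TYPE_TO_REGION[typ])
        )
        node_to_seg[nid] = seg_id
        seg_id += 1
    return Morphology(segs, soma_depth=soma_depth)
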