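"""Synthetic coronary-tree geometry.

A coronary tree is represented at reduced order as a set of centerline
segments, each a 1D profile of lumen radius versus arc length, joined by
a parent/attachment topology rooted at the aortic root.  Two anatomical
variants are generated:

* ``normal`` -- left main (LM) from the left sinus feeding LAD and LCX,
  right coronary artery (RCA) from the right sinus;
* ``aoca_lcx_right_sinus`` -- anomalous origin of the LCX from the right
  coronary sinus with a retroaortic course, represented purely as extra
  path length of the LCX.

A parametric stenosis (percent diameter reduction with a smooth cosine
taper) can be inserted into, removed from, and measured on any segment,
which provides the four anatomical study models (patient with/without
plaque, healthy with/without plaque).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "VARIANT_NORMAL",
    "VARIANT_AOCA",
    "BRANCH_NAMES",
    "GeometryError",
    "GeometryParams",
    "CenterlineSegment",
    "CoronaryTree",
    "StenosisSpec",
    "paper_twin_params",
    "build_tree",
    "insert_stenosis",
    "remove_stenosis",
    "measure_stenosis_degree",
    "tree_to_dict",
    "tree_from_dict",
    "save_tree",
    "load_tree",
]

VARIANT_NORMAL = "normal"
VARIANT_AOCA = "aoca_lcx_right_sinus"
VARIANTS = (VARIANT_NORMAL, VARIANT_AOCA)

BRANCH_NAMES = ("AORTA", "LM", "LAD", "LCX", "RCA")

#: physiological admissible proximal radius ranges (cm)
_CORONARY_RADIUS_RANGE = (0.05, 0.25)
_AORTA_RADIUS_RANGE = (1.0, 1.8)


class GeometryError(ValueError):
    """Raised for invalid geometry parameters or malformed trees."""


@dataclass(frozen=True)
class CenterlineSegment:
    """One vessel segment: radius sampled along arc length.

    Arc length is measured in cm from the segment's proximal end
    (``arc_s[0] == 0``).  ``parent`` names the segment this one branches
    from, ``attach_s`` the arc position on the parent where it attaches.
    """

    id: str
    name: str
    arc_s: np.ndarray
    radius: np.ndarray
    parent: str | None = None
    attach_s: float = 0.0

    def __post_init__(self) -> None:
        arc = np.asarray(self.arc_s, dtype=float)
        rad = np.asarray(self.radius, dtype=float)
        object.__setattr__(self, "arc_s", arc)
        object.__setattr__(self, "radius", rad)
        if self.name not in BRANCH_NAMES:
            raise GeometryError(f"unknown branch name {self.name!r}")
        if arc.ndim != 1 or rad.ndim != 1 or arc.size != rad.size or arc.size < 2:
            raise GeometryError(
                f"segment {self.id!r}: arc_s and radius must be equal-length 1D arrays with >= 2 samples"
            )
        if arc[0] != 0.0 or np.any(np.diff(arc) <= 0.0):
            raise GeometryError(f"segment {self.id!r}: arc_s must be strictly increasing from 0")
        if np.any(rad <= 0.0) or not np.all(np.isfinite(rad)):
            raise GeometryError(f"segment {self.id!r}: radii must be positive and finite")

    @property
    def length(self) -> float:
        """Segment arc length (cm)."""
        return float(self.arc_s[-1])

    def radius_at(self, s) -> np.ndarray | float:
        """Lumen radius (cm) at arc position(s) ``s``, linearly interpolated."""
        return np.interp(s, self.arc_s, self.radius)

    def with_profile(self, arc_s: np.ndarray, radius: np.ndarray) -> "CenterlineSegment":
        return dataclasses.replace(self, arc_s=arc_s, radius=radius)


@dataclass(frozen=True)
class CoronaryTree:
    """A validated coronary tree: segments + topology + sinus of origin."""

    variant: str
    segments: tuple[CenterlineSegment, ...]
    ostia: dict[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        self._validate()

    # -- lookups ---------------------------------------------------------
    def segment(self, key: str) -> CenterlineSegment:
        """Return the segment whose id or branch name equals ``key``."""
        for seg in self.segments:
            if seg.id == key or seg.name == key:
                return seg
        raise KeyError(f"no segment {key!r} in tree")

    def children_of(self, name: str) -> list[CenterlineSegment]:
        return [s for s in self.segments if s.parent == name]

    @property
    def leaves(self) -> list[CenterlineSegment]:
        parents = {s.parent for s in self.segments if s.parent is not None}
        return [s for s in self.segments if s.name not in parents]

    def replace_segment(self, new_seg: CenterlineSegment) -> "CoronaryTree":
        segs = tuple(new_seg if s.id == new_seg.id else s for s in self.segments)
        return dataclasses.replace(self, segments=segs)

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        if self.variant not in VARIANTS:
            raise GeometryError(f"unknown variant {self.variant!r}")
        names = [s.name for s in self.segments]
        for required in ("AORTA", "LAD", "LCX", "RCA"):
            if names.count(required) != 1:
                raise GeometryError(f"tree must contain exactly one {required} segment")
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise GeometryError("segment ids must be unique")
        by_name = {s.name: s for s in self.segments}
        # acyclic parent relation rooted at AORTA
        for seg in self.segments:
            seen = set()
            cur = seg
            while cur.parent is not None:
                if cur.name in seen:
                    raise GeometryError(f"cycle in parent relation at {cur.name}")
                seen.add(cur.name)
                if cur.parent not in by_name:
                    raise GeometryError(f"segment {cur.name}: unknown parent {cur.parent!r}")
                parent = by_name[cur.parent]
                if not (0.0 <= cur.attach_s <= parent.length):
                    raise GeometryError(
                        f"segment {cur.name}: attach_s {cur.attach_s} outside parent arc range"
                    )
                cur = parent
            if cur.name != "AORTA":
                raise GeometryError(f"segment {seg.name} is not rooted at AORTA")
        if by_name["AORTA"].parent is not None:
            raise GeometryError("AORTA must be the root segment")
        # sinus-of-origin rules per variant
        expected_rca = "right"
        if self.ostia.get("RCA") != expected_rca:
            raise GeometryError("RCA must originate from the right sinus")
        if self.ostia.get("LAD") != "left":
            raise GeometryError("LAD must originate from the left sinus")
        lcx_sinus = "right" if self.variant == VARIANT_AOCA else "left"
        if self.ostia.get("LCX") != lcx_sinus:
            raise GeometryError(
                f"variant {self.variant}: LCX ostium must map to the {lcx_sinus} sinus"
            )


@dataclass(frozen=True)
class StenosisSpec:
    """Parametric plaque: smooth focal narrowing of a segment.

    ``degree`` is percent *diameter* reduction at the plaque center
    relative to the local healthy diameter; the narrowing tapers to zero
    at the window edges with a cosine profile.
    """

    segment_id: str
    center_s: float
    length: float
    degree: float
    profile: str = "cosine"

    def __post_init__(self) -> None:
        if not (0.0 <= self.degree < 100.0):
            raise GeometryError("stenosis degree must satisfy 0 <= degree < 100")
        if self.length <= 0.0:
            raise GeometryError("plaque length must be positive")
        if self.profile != "cosine":
            raise GeometryError(f"unsupported taper profile {self.profile!r}")

    @property
    def window(self) -> tuple[float, float]:
        half = self.length / 2.0
        return (self.center_s - half, self.center_s + half)


@dataclass(frozen=True)
class GeometryParams:
    """Per-branch lengths and proximal radii (cm) for tree generation.

    The defaults are the packaged "paper_twin" fixture: a desk-scale
    stand-in with physiological calibres, not measurements of any
    patient.  Distal radii taper linearly to ``distal_taper`` times the
    proximal radius.
    """

    aorta_radius: float = 1.4
    aorta_length: float = 6.0
    lm_length: float = 1.0
    lm_radius: float = 0.185
    lad_length: float = 4.0
    lad_radius: float = 0.16
    lcx_length: float = 4.0
    lcx_radius: float = 0.14
    lcx_length_aoca: float = 7.0
    rca_length: float = 5.0
    rca_radius: float = 0.17
    distal_taper: float = 0.7
    sample_ds: float = 0.05
    left_ostium_s: float = 0.6
    right_ostium_s: float = 0.4

    def __post_init__(self) -> None:
        lo, hi = _AORTA_RADIUS_RANGE
        if not (lo <= self.aorta_radius <= hi):
            raise GeometryError(f"aortic radius must lie in [{lo}, {hi}] cm")
        lo, hi = _CORONARY_RADIUS_RANGE
        for label in ("lm_radius", "lad_radius", "lcx_radius", "rca_radius"):
            r = getattr(self, label)
            if not (lo <= r <= hi):
                raise GeometryError(f"{label} = {r} outside physiological range [{lo}, {hi}] cm")
        for label in (
            "aorta_length",
            "lm_length",
            "lad_length",
            "lcx_length",
            "lcx_length_aoca",
            "rca_length",
            "sample_ds",
        ):
            if getattr(self, label) <= 0.0:
                raise GeometryError(f"{label} must be positive")
        if not (0.0 < self.distal_taper <= 1.0):
            raise GeometryError("distal_taper must lie in (0, 1]")
        if self.lcx_length_aoca <= self.lcx_length:
            raise GeometryError("retroaortic LCX must be strictly longer than the normal LCX")
        if not (0.0 <= self.left_ostium_s <= self.aorta_length):
            raise GeometryError("left ostium outside aorta arc range")
        if not (0.0 <= self.right_ostium_s <= self.aorta_length):
            raise GeometryError("right ostium outside aorta arc range")


def paper_twin_params() -> GeometryParams:
    """The packaged default geometry fixture ("paper_twin")."""
    return GeometryParams()


def _sampled_profile(length: float, r_prox: float, r_dist: float, ds: float):
    n = max(2, int(round(length / ds)) + 1)
    arc = np.linspace(0.0, length, n)
    rad = np.linspace(r_prox, r_dist, n)
    return arc, rad


def build_tree(variant: str, params: GeometryParams | None = None) -> CoronaryTree:
    """Generate a synthetic coronary tree for the requested variant.

    Deterministic for fixed parameters.  In the AOCA variant the LCX
    attaches at the right sinus and its centerline is longer than the
    normal-variant LCX, standing in for the retroaortic course.
    """
    if variant not in VARIANTS:
        raise GeometryError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    p = params if params is not None else paper_twin_params()
    tap = p.distal_taper
    ds = p.sample_ds

    segs = []
    arc, rad = _sampled_profile(p.aorta_length, p.aorta_radius, p.aorta_radius, ds)
    segs.append(CenterlineSegment("AORTA", "AORTA", arc, rad, None, 0.0))

    arc, rad = _sampled_profile(p.lm_length, p.lm_radius, p.lm_radius, ds)
    segs.append(CenterlineSegment("LM", "LM", arc, rad, "AORTA", p.left_ostium_s))

    arc, rad = _sampled_profile(p.lad_length, p.lad_radius, tap * p.lad_radius, ds)
    segs.append(CenterlineSegment("LAD", "LAD", arc, rad, "LM", p.lm_length))

    if variant == VARIANT_AOCA:
        arc, rad = _sampled_profile(p.lcx_length_aoca, p.lcx_radius, tap * p.lcx_radius, ds)
        segs.append(CenterlineSegment("LCX", "LCX", arc, rad, "AORTA", p.right_ostium_s))
        lcx_sinus = "right"
    else:
        arc, rad = _sampled_profile(p.lcx_length, p.lcx_radius, tap * p.lcx_radius, ds)
        segs.append(CenterlineSegment("LCX", "LCX", arc, rad, "LM", p.lm_length))
        lcx_sinus = "left"

    arc, rad = _sampled_profile(p.rca_length, p.rca_radius, tap * p.rca_radius, ds)
    segs.append(CenterlineSegment("RCA", "RCA", arc, rad, "AORTA", p.right_ostium_s))

    ostia = {"LM": "left", "LAD": "left", "LCX": lcx_sinus, "RCA": "right"}
    return CoronaryTree(variant=variant, segments=tuple(segs), ostia=ostia)


# ---------------------------------------------------------------------------
# stenosis editing
# ---------------------------------------------------------------------------

def _refined_window_grid(seg: CenterlineSegment, w0: float, w1: float, n_inner: int = 41):
    """Union of the segment's samples with a fine symmetric grid over the window.

    The refined grid always contains the window center, so the maximum
    narrowing of a cosine plaque lands exactly on a sample.
    """
    win = np.linspace(w0, w1, n_inner)
    arc = np.union1d(seg.arc_s, win)
    return arc


def insert_stenosis(tree: CoronaryTree, spec: StenosisSpec) -> CoronaryTree:
    """Return a new tree with a cosine-tapered plaque applied to one segment.

    Radii inside the plaque window are multiplied by a smooth factor
    reaching ``1 - degree/100`` at the center and 1 at the window edges;
    radii outside the window are untouched.  The input tree is not
    mutated.
    """
    seg = tree.segment(spec.segment_id)  # KeyError if absent
    w0, w1 = spec.window
    if w0 < 0.0 or w1 > seg.length:
        raise GeometryError(
            f"plaque window [{w0:.3f}, {w1:.3f}] cm outside segment {spec.segment_id!r} "
            f"arc range [0, {seg.length:.3f}] cm"
        )
    if spec.degree == 0.0:
        return tree.replace_segment(seg)
    arc = _refined_window_grid(seg, w0, w1)
    base = seg.radius_at(arc)
    factor = np.ones_like(base)
    inside = (arc >= w0) & (arc <= w1)
    phase = 2.0 * np.pi * (arc[inside] - spec.center_s) / spec.length
    factor[inside] = 1.0 - (spec.degree / 100.0) * 0.5 * (1.0 + np.cos(phase))
    return tree.replace_segment(seg.with_profile(arc, base * factor))


def remove_stenosis(
    tree: CoronaryTree, segment_id: str, window: tuple[float, float]
) -> CoronaryTree:
    """Return a new tree with radii in ``window`` replaced by the shoulder chord.

    The radii strictly inside the window are overwritten with the linear
    (hence monotone) interpolation between the radii at the window
    edges, which restores a linearly tapering healthy lumen exactly.
    """
    seg = tree.segment(segment_id)
    w0, w1 = window
    if w0 >= w1:
        raise GeometryError("window must satisfy w0 < w1")
    if w0 < 0.0 or w1 > seg.length:
        raise GeometryError(
            f"window [{w0:.3f}, {w1:.3f}] cm outside segment {segment_id!r} arc range"
        )
    arc = np.union1d(seg.arc_s, np.asarray([w0, w1]))
    rad = seg.radius_at(arc).copy()
    r0 = float(seg.radius_at(w0))
    r1 = float(seg.radius_at(w1))
    inside = (arc > w0) & (arc < w1)
    rad[inside] = r0 + (r1 - r0) * (arc[inside] - w0) / (w1 - w0)
    return tree.replace_segment(seg.with_profile(arc, rad))


def _upper_hull(s: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper convex hull of the radius profile (the healthy envelope)."""
    hull: list[tuple[float, float]] = []
    for point in zip(s, r):
        while len(hull) >= 2:
            (ox, oy), (ax, ay) = hull[-2], hull[-1]
            bx, by = point
            cross = (ax - ox) * (by - oy) - (ay - oy) * (bx - ox)
            if cross >= 0.0:  # middle point lies on/below the chord
                hull.pop()
            else:
                break
        hull.append(point)
    hs = np.asarray([p[0] for p in hull])
    hr = np.asarray([p[1] for p in hull])
    return hs, hr


def measure_stenosis_degree(tree: CoronaryTree, segment_id: str) -> float:
    """Percent diameter reduction of the tightest narrowing of a segment.

    The healthy reference diameter at each arc position is taken from
    the upper convex hull of the radius profile (which reproduces a
    linear baseline taper exactly); the degree is the largest relative
    shortfall ``100 * (1 - d / d_ref)``.  Returns 0 for segments with no
    narrowing.
    """
    seg = tree.segment(segment_id)
    hs, hr = _upper_hull(seg.arc_s, seg.radius)
    ref = np.interp(seg.arc_s, hs, hr)
    ratio = seg.radius / ref
    degree = 100.0 * (1.0 - float(np.min(ratio)))
    return degree if degree > 1e-9 else 0.0


# ---------------------------------------------------------------------------
# JSON geometry interchange
# ---------------------------------------------------------------------------

def tree_to_dict(tree: CoronaryTree) -> dict:
    return {
        "variant": tree.variant,
        "segments": [
            {
                "id": s.id,
                "name": s.name,
                "parent": s.parent,
                "attach_s": s.attach_s,
                "arc_s": s.arc_s.tolist(),
                "radius": s.radius.tolist(),
            }
            for s in tree.segments
        ],
        "ostia": dict(tree.ostia),
    }


def tree_from_dict(doc: dict) -> CoronaryTree:
    """Build (and fully re-validate) a tree from its JSON document form."""
    segs = tuple(
        CenterlineSegment(
            id=d["id"],
            name=d["name"],
            arc_s=np.asarray(d["arc_s"], dtype=float),
            radius=np.asarray(d["radius"], dtype=float),
            parent=d.get("parent"),
            attach_s=float(d.get("attach_s", 0.0) or 0.0),
        )
        for d in doc["segments"]
    )
    return CoronaryTree(variant=doc["variant"], segments=segs, ostia=dict(doc["ostia"]))


def save_tree(tree: CoronaryTree, path) -> None:
    with open(path, "w") as fh:
        json.dump(tree_to_dict(tree), fh, indent=1, sort_keys=True)


def load_tree(path) -> CoronaryTree:
    with open(path) as fh:
        return tree_from_dict(json.load(fh))
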