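"""Parametric 2D root systems with analytic ground truth, rendered as
pouch-style images.

Geometry lives in physical units: lengths in cm, widths in mm, origin at
the root/shoot junction with y increasing downward (image row direction).
The mm/cm split matches how root traits are conventionally tabulated; the
factor 10 is applied once at the render/measure boundary.

Rendered scenes emulate the two failure modes the cleaning pipeline
exists to fix: small bright debris particles (false root tips) and
meniscus halos along root edges that inflate apparent root size.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from PIL import Image, ImageDraw
from scipy.spatial import ConvexHull
from scipy.spatial import cKDTree
from skimage.morphology import dilation as _gray_dilation, disk as disk_footprint
from skimage.draw import disk as draw_disk

from .records import PouchImage, TraitRecord

__all__ = [
    "DistSpec",
    "WidthSpec",
    "RootModelParams",
    "RootSegment",
    "RootSystemModel",
    "SceneParams",
    "GenerationError",
    "generate_model",
    "truth_traits",
    "render_scene",
    "RenderManifest",
]

_DS_CM = 0.1  # polyline sampling step along each root


class GenerationError(RuntimeError):
    """Raised when rejection sampling cannot place a lateral without crossings."""


@dataclass
class DistSpec:
    """Clipped-normal distribution spec; sd == 0 means the constant ``mean``."""

    mean: float
    sd: float = 0.0
    min: float | None = None
    max: float | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative (0 means constant)")

    def sample(self, rng: np.random.Generator, size=None):
        x = self.mean + self.sd * rng.standard_normal(size) if self.sd > 0 \
            else (np.full(size, self.mean) if size is not None else self.mean)
        lo = -np.inf if self.min is None else self.min
        hi = np.inf if self.max is None else self.max
        return np.clip(x, lo, hi)


@dataclass
class WidthSpec:
    tap_mm: float = 0.8
    lateral_mm: float = 0.4

    def __post_init__(self) -> None:
        if self.tap_mm <= 0 or self.lateral_mm <= 0:
            raise ValueError("root widths must be positive")


@dataclass
class RootModelParams:
    tap_length_cm: float = 12.0
    n_laterals: int = 10
    lateral_length_cm: DistSpec = field(default_factory=lambda: DistSpec(1.5, 0.4, min=0.8))
    root_width_mm: WidthSpec = field(default_factory=WidthSpec)
    insertion_angle_deg: DistSpec = field(default_factory=lambda: DistSpec(45.0, 8.0, min=20.0, max=75.0))
    wiggle: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tap_length_cm <= 0:
            raise ValueError("tap_length_cm must be positive")
        if self.n_laterals < 0:
            raise ValueError("n_laterals must be non-negative")
        if self.wiggle < 0:
            raise ValueError("wiggle must be non-negative")


@dataclass
class RootSegment:
    vertices: np.ndarray   # (N, 2) array of (x, y) in cm, y down
    widths_mm: np.ndarray  # (N,) per-vertex width
    order: str             # "tap" | "lateral"


@dataclass
class RootSystemModel:
    segments: list
    junction: tuple = (0.0, 0.0)
    truth: TraitRecord | None = None
    params: RootModelParams | None = None


@dataclass
class SceneParams:
    """Rendering parameters for one pouch-style image."""

    image_size_px: tuple = (1400, 1000)  # (height, width)
    pixels_per_cm: float = 100.0
    background_level: int = 30
    root_brightness: int = 220
    noise_sd: float = 0.0
    debris_count: int = 0
    debris_area_px: tuple = (20, 150)
    meniscus_halo: bool = False
    halo_width_px: int = 3
    halo_droplets: int = 25
    droplet_len_px: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixels_per_cm <= 0:
            raise ValueError("pixels_per_cm must be positive")
        if not self.root_brightness > self.background_level:
            raise ValueError("root_brightness must exceed background_level")
        if self.noise_sd < 0 or self.debris_count < 0:
            raise ValueError("noise_sd and debris_count must be non-negative")


# ---------------------------------------------------------------------------
# model generation
# ---------------------------------------------------------------------------

def _grow_polyline(start, direction_deg, length_cm, wiggle, rng):
    """March from ``start`` at ``direction_deg`` (0 = straight down,
    positive = toward +x), jittering the heading each step."""
    n = max(2, int(round(length_cm / _DS_CM)) + 1)
    theta = np.deg2rad(direction_deg)
    headings = theta + np.cumsum(rng.normal(0.0, wiggle * _DS_CM * 2.0, n - 1))
    steps = np.stack([np.sin(headings), np.cos(headings)], axis=1) * _DS_CM
    verts = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)]) + np.asarray(start)
    return verts


def generate_model(params: RootModelParams) -> RootSystemModel:
    """Build a tap root with non-crossing laterals; deterministic per seed.

    Laterals attach at distinct, depth-sorted positions along the tap.
    Each candidate lateral is rejection-sampled (up to 100 retries) so that
    its body keeps clearance from the tap and all other laterals; tip
    counts of the model are therefore unambiguous.
    """
    rng = np.random.default_rng(params.seed)
    w = params.root_width_mm
    tap = _grow_polyline((0.0, 0.0), 0.0, params.tap_length_cm, params.wiggle, rng)
    segments = [RootSegment(tap, np.full(len(tap), w.tap_mm), "tap")]

    n = params.n_laterals
    if n:
        # stratified attachment depths: even spacing + jitter, alternating sides
        lo, hi = 0.06 * params.tap_length_cm, 0.96 * params.tap_length_cm
        base = np.linspace(lo, hi, n)
        jitter = (hi - lo) / max(n, 1) * 0.25
        depths = np.sort(np.clip(base + rng.uniform(-jitter, jitter, n), lo, hi))
        sides = np.where((np.arange(n) + rng.integers(0, 2)) % 2 == 0, 1.0, -1.0)

        # arclength -> tap vertex interpolation
        tap_s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(tap, axis=0), axis=1))])
        clearance = (w.tap_mm + w.lateral_mm) / 2.0 / 10.0 + 0.05
        accepted_pts = []
        tree = None
        spacing = (hi - lo) / n
        for depth, side in zip(depths, sides):
            placed = False
            for retry in range(100):
                # later retries shrink toward a short straight lateral at the
                # mean insertion angle, which is the easiest shape to place;
                # stubborn conflicts also get a jittered attachment depth
                damp = 1.0 - retry / 99.0
                depth_eff = depth if retry < 30 else float(
                    np.clip(depth + rng.uniform(-0.6, 0.6) * spacing, lo, hi))
                attach = np.array([np.interp(depth_eff, tap_s, tap[:, 0]),
                                   np.interp(depth_eff, tap_s, tap[:, 1])])
                # tap vertices away from the attachment: the lateral must
                # keep clear of these (it may touch the tap only where it
                # inserts)
                far_tap = tap[np.abs(tap_s - depth_eff) > 0.4]
                tap_tree = cKDTree(far_tap) if len(far_tap) else None
                ang = float(params.insertion_angle_deg.sample(rng))
                ang = side * (params.insertion_angle_deg.mean
                              + (ang - params.insertion_angle_deg.mean) * damp)
                length = float(params.lateral_length_cm.sample(rng))
                min_len = params.lateral_length_cm.min or _DS_CM * 3
                # the length floor also relaxes: a squeezed lateral becomes a
                # short stub (>= 0.3 cm, still a countable tip) instead of
                # being forced through an occupied corridor
                length = max(length * (0.3 + 0.7 * damp),
                             min_len * (0.35 + 0.65 * damp), 0.3)
                verts = _grow_polyline(attach, ang, length, params.wiggle * damp, rng)
                body = verts[np.linalg.norm(verts - attach, axis=1) > 0.25]
                if body.size == 0:
                    body = verts[-1:]
                ok = tap_tree is None or tap_tree.query(body, k=1)[0].min() > clearance
                if ok and tree is not None:
                    ok = tree.query(body, k=1)[0].min() > clearance
                if ok:
                    segments.append(RootSegment(verts, np.full(len(verts), w.lateral_mm), "lateral"))
                    accepted_pts.append(body)
                    tree = cKDTree(np.vstack(accepted_pts))
                    placed = True
                    break
            if not placed:
                # last resort: a short stub in the most open direction, on
                # either side, with just enough clearance that strokes stay
                # disjoint (tips remain unambiguous)
                stub_clear = (w.tap_mm + w.lateral_mm) / 2.0 / 10.0 + 0.02
                attach = np.array([np.interp(depth, tap_s, tap[:, 0]),
                                   np.interp(depth, tap_s, tap[:, 1])])
                far_tap = tap[np.abs(tap_s - depth) > 0.4]
                tap_tree = cKDTree(far_tap) if len(far_tap) else None
                a_lo = params.insertion_angle_deg.min or 15.0
                a_hi = params.insertion_angle_deg.max or 80.0
                for sgn in (side, -side):
                    for a in np.arange(a_lo, a_hi + 1e-9, 5.0):
                        verts = _grow_polyline(attach, sgn * a, 0.3, 0.0, rng)
                        body = verts[-2:]
                        ok = tap_tree is None or tap_tree.query(body, k=1)[0].min() > stub_clear
                        if ok and tree is not None:
                            ok = tree.query(body, k=1)[0].min() > stub_clear
                        if ok:
                            segments.append(RootSegment(
                                verts, np.full(len(verts), w.lateral_mm), "lateral"))
                            accepted_pts.append(body)
                            tree = cKDTree(np.vstack(accepted_pts))
                            placed = True
                            break
                    if placed:
                        break
            if not placed:
                raise GenerationError(
                    f"could not place lateral at depth {depth:.2f} cm without crossings")
    model = RootSystemModel(segments=segments, junction=(0.0, 0.0), params=params)
    model.truth = truth_traits(model)
    return model


# ---------------------------------------------------------------------------
# analytic ground truth
# ---------------------------------------------------------------------------

def _element_arrays(model: RootSystemModel):
    """Per-element (polyline edge) midpoints, lengths (cm), widths (cm)."""
    mids, lens, wids = [], [], []
    for seg in model.segments:
        v = np.asarray(seg.vertices, float)
        if len(v) < 2:
            raise ValueError("degenerate (zero-length) polyline")
        d = np.diff(v, axis=0)
        ell = np.linalg.norm(d, axis=1)
        if not np.all(ell > 0):
            raise ValueError("degenerate (zero-length) polyline edge")
        mids.append((v[:-1] + v[1:]) / 2.0)
        lens.append(ell)
        wids.append((seg.widths_mm[:-1] + seg.widths_mm[1:]) / 2.0 / 10.0)
    return np.vstack(mids), np.concatenate(lens), np.concatenate(wids)


def _outline_points(model: RootSystemModel) -> np.ndarray:
    """Stroke outline samples: centerline offset by half-width both sides."""
    pts = []
    for seg in model.segments:
        v = np.asarray(seg.vertices, float)
        t = np.gradient(v, axis=0)
        t /= np.maximum(np.linalg.norm(t, axis=1, keepdims=True), 1e-12)
        nrm = np.stack([-t[:, 1], t[:, 0]], axis=1)
        half = (seg.widths_mm / 20.0)[:, None]
        pts += [v + nrm * half, v - nrm * half]
    return np.vstack(pts)


def truth_traits(model: RootSystemModel) -> TraitRecord:
    """Analytic traits of the model geometry under a cylinder approximation.

    Each polyline element of length l and diameter d contributes l to TRL,
    pi*d*l to TSA and (pi/4)*d^2*l to TRV. Architectural traits come from
    the width-weighted centerline (COPM, RDI) and the stroke outline
    (TRW, TCA, SOL).
    """
    mids, lens, wids_cm = _element_arrays(model)
    wids_mm = wids_cm * 10.0

    trl = float(lens.sum())
    sa = np.pi * wids_cm * lens
    tsa = float(sa.sum())
    trv = float(((np.pi / 4.0) * wids_cm**2 * lens).sum())
    dim = float((wids_mm * lens).sum() / trl)
    tsa1 = float(sa[(wids_mm >= 0.0) & (wids_mm < 0.5)].sum())
    tsa3 = float(sa[(wids_mm >= 1.0) & (wids_mm < 1.5)].sum())
    trt = sum(1 for s in model.segments if s.order == "lateral") + 1

    outline = _outline_points(model)
    tca = float(ConvexHull(outline).volume)
    trw = float(outline[:, 0].max() - outline[:, 0].min())

    # projected area: strokes + half-disk caps at free ends, minus the part
    # of each lateral buried inside the tap stroke near its attachment
    area = float((wids_cm * lens).sum())
    tap_seg = model.segments[0]
    tap_v = np.asarray(tap_seg.vertices, float)
    tap_tan = np.gradient(tap_v, axis=0)
    tap_tan /= np.maximum(np.linalg.norm(tap_tan, axis=1, keepdims=True), 1e-12)
    for seg in model.segments:
        wc = float(seg.widths_mm[-1]) / 10.0
        area += np.pi * wc**2 / 8.0                       # tip cap
        if seg.order != "tap":  # tap top is rendered flat (no start cap)
            # buried length ~ (tap half-width)/sin(insertion angle); the
            # attachment cap is inside the tap too
            v = np.asarray(seg.vertices, float)
            w_lat = float(seg.widths_mm[0]) / 10.0
            tap_w = float(tap_seg.widths_mm[0]) / 10.0
            i = int(np.argmin(np.linalg.norm(tap_v - v[0], axis=1)))
            d0 = v[min(2, len(v) - 1)] - v[0]
            d0 /= max(np.linalg.norm(d0), 1e-12)
            sin_phi = max(abs(d0[0] * tap_tan[i][1] - d0[1] * tap_tan[i][0]), 0.3)
            area -= w_lat * (tap_w / 2.0) / sin_phi + np.pi * w_lat**2 / 8.0
    sol = min(1.0, area / tca)

    jy = model.junction[1]
    copm = float((wids_cm * lens * mids[:, 1]).sum() / (wids_cm * lens).sum()) - jy
    depth = float(max(np.asarray(s.vertices)[:, 1].max() for s in model.segments)) - jy
    below = mids[:, 1] - jy > depth / 3.0
    rdi = float(sa[below].sum() / tsa)

    rec = TraitRecord(TRL=trl, TSA=tsa, DIM=dim, TRV=trv, TRT=int(trt),
                      TSA1=tsa1, TSA3=tsa3, TRW=trw, TCA=tca, RDI=rdi,
                      SOL=sol, COPM=copm)
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class RenderManifest:
    """Ground-truth side channel of a render.

    ``root_mask`` is the debris/halo-free stroke mask at target resolution
    (coverage >= 0.5); it is dropped by :meth:`to_json`.
    """

    debris: list                 # [{"centroid": (row, col), "area_px": int}, ...]
    junction_px: tuple           # (row, col)
    pixels_per_cm: float
    root_mask: np.ndarray | None = None

    def to_json(self) -> str:
        return json.dumps({
            "debris": self.debris,
            "junction_px": list(self.junction_px),
            "pixels_per_cm": self.pixels_per_cm,
        })


_SS = 4  # supersampling factor for anti-aliased strokes


def _draw_strokes(canvas: ImageDraw.ImageDraw, segs_px: list) -> None:
    for verts, w_px, start_cap in segs_px:
        wp = max(1, int(round(w_px * _SS)))
        pts = [tuple(p) for p in (verts * _SS)]
        canvas.line(pts, fill=255, width=wp, joint="curve")
        r = wp / 2.0
        caps = (pts[0], pts[-1]) if start_cap else (pts[-1],)
        for p in caps:
            canvas.ellipse([p[0] - r, p[1] - r, p[0] + r, p[1] + r], fill=255)


def _downsample(arr: np.ndarray, h: int, w: int) -> np.ndarray:
    return arr[:h * _SS, :w * _SS].reshape(h, _SS, w, _SS).mean(axis=(1, 3))


def render_scene(model: RootSystemModel, scene: SceneParams) -> tuple[PouchImage, RenderManifest]:
    """Rasterize the model as bright anti-aliased strokes on a dark pouch.

    The junction is placed near the top center of the frame. Debris blobs
    are placed disjoint from the (dilated) root so each unfiltered particle
    is a guaranteed false tip. With ``meniscus_halo`` on, a bright rim plus
    droplet-shaped protrusions are added along root edges, inflating
    apparent length, surface, volume and tip count the way in-air menisci
    do.
    """
    h, w = scene.image_size_px
    ppc = scene.pixels_per_cm
    rng = np.random.default_rng(scene.seed)

    # cm -> px; junction at row ~0.5 cm, column centered on the tap extent
    allv = np.vstack([np.asarray(s.vertices) for s in model.segments])
    x_mid = (allv[:, 0].min() + allv[:, 0].max()) / 2.0
    off = np.array([w / 2.0 - x_mid * ppc, 0.5 * ppc])
    segs_px = []
    clipped = False
    for seg in model.segments:
        v = np.asarray(seg.vertices) * ppc + off
        if v[:, 0].min() < 0 or v[:, 1].min() < 0 or v[:, 0].max() >= w or v[:, 1].max() >= h:
            clipped = True
        # flat top at the junction so the topmost root pixel IS the junction
        segs_px.append((v, float(seg.widths_mm.mean()) * ppc / 10.0,
                        seg.order != "tap"))
    if clipped:
        warnings.warn("model extends beyond the image frame; strokes clipped")

    big = Image.new("L", (w * _SS, h * _SS), 0)
    _draw_strokes(ImageDraw.Draw(big), segs_px)
    root_cov = _downsample(np.asarray(big, float) / 255.0, h, w)
    root_mask = root_cov >= 0.5

    bg, rb = float(scene.background_level), float(scene.root_brightness)
    img = bg + root_cov * (rb - bg)

    if scene.meniscus_halo:
        halo_level = bg + 0.85 * (rb - bg)
        rim = _gray_dilation(root_mask, disk_footprint(scene.halo_width_px)) & ~root_mask
        drop = Image.new("L", (w * _SS, h * _SS), 0)
        dd = ImageDraw.Draw(drop)
        verts_all = allv * ppc + off
        for _ in range(scene.halo_droplets):
            p = verts_all[rng.integers(0, len(verts_all))]
            ang = rng.uniform(0, 2 * np.pi)
            q = p + scene.droplet_len_px * np.array([np.cos(ang), np.sin(ang)])
            dd.line([tuple(p * _SS), tuple(q * _SS)], fill=255, width=3 * _SS)
        drop_cov = _downsample(np.asarray(drop, float) / 255.0, h, w)
        halo = np.where(rim, 1.0, 0.0)
        halo = np.maximum(halo, drop_cov)
        img = np.maximum(img, bg + halo * (halo_level - bg))

    # debris: bright disks, disjoint from roots/halo and from each other
    occupied = _gray_dilation(img > bg + 1, disk_footprint(3))
    debris = []
    lo_a, hi_a = scene.debris_area_px
    for _ in range(scene.debris_count):
        for _try in range(200):
            r_px = float(np.sqrt(rng.uniform(lo_a, hi_a) / np.pi))
            cy = rng.integers(int(np.ceil(r_px)) + 1, h - int(np.ceil(r_px)) - 1)
            cx = rng.integers(int(np.ceil(r_px)) + 1, w - int(np.ceil(r_px)) - 1)
            rr, cc = draw_disk((cy, cx), max(r_px, 1.0), shape=(h, w))
            if not occupied[rr, cc].any():
                img[rr, cc] = rb
                # a 3-px moat so neighbouring debris never merge
                rr3, cc3 = draw_disk((cy, cx), max(r_px, 1.0) + 3, shape=(h, w))
                occupied[rr3, cc3] = True
                debris.append({"centroid": (float(rr.mean()), float(cc.mean())),
                               "area_px": int(len(rr))})
                break
        else:
            warnings.warn("could not place all debris particles without overlap")
            break

    if scene.noise_sd > 0:
        img = img + rng.normal(0.0, scene.noise_sd, img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    pixels = np.repeat(pixels[:, :, None], 3, axis=2)

    junction_px = (float(off[1]), float(model.junction[0] * ppc + off[0]))
    image = PouchImage(pixels, ppc, id=f"synth-{model.params.seed if model.params else 0}-{scene.seed}")
    manifest = RenderManifest(debris=debris, junction_px=junction_px,
                              pixels_per_cm=ppc, root_mask=root_mask)
    return image, manifest
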