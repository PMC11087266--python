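"""Synthetic organoid-PBMC co-culture fields with exhaustive ground truth.

The generator emulates a 2-D section through an ECM dome in which ring-shaped
epithelial objects (organoids: a thin cytokeratin shell around a lumen;
tumouroids: densely packed disks with little or no lumen) are co-embedded
with point-like immune cells.  Over a 0/24/48/72 h time course, immune cells
infiltrate the epithelium according to a simple Bernoulli jump model and a
caspase-3/7 reporter signal accumulates in the epithelial shell from the
outside in.  Every generated quantity -- object geometry, per-cell position,
phenotype and concentric-zone membership, and the apoptotic pixel fraction --
is recorded in a :class:`GroundTruth` object so that each downstream analysis
stage can be validated exactly.

Geometry is circular by construction so that zone membership has an analytic
oracle (distance to the circle boundary); an optional radial-perturbation
amplitude produces irregular outlines for robustness experiments, at the cost
of that oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd

#: Concentric-zone margin used for ground-truth zone labels (matches the
#: default analysis margin in :mod:`orgzone.zones`).
ZONE_MARGIN_UM = 25.0

#: Channel layout of a generated field, in rendering order.
CHANNELS = ("DAPI", "panCK", "caspase", "CD4", "CD8", "CD14", "CD20")

#: Immune phenotypes carried by the marker channels.
IMMUNE_MARKERS = ("CD4", "CD8", "CD14", "CD20")

#: Default immune composition (free parameters; the assay does not fix one).
DEFAULT_PHENOTYPE_PROPORTIONS = {"CD4": 0.45, "CD8": 0.35, "CD14": 0.15, "CD20": 0.05}

#: Zone code used for cells that fall in no zone (or in deleted overlap).
OUTSIDE = 0


@dataclass
class ImageField:
    """One multi-channel 2-D raster with physical pixel size and metadata."""

    channels: dict
    pixel_size_um: float
    metadata: dict = dc_field(default_factory=dict)

    @property
    def shape(self):
        return next(iter(self.channels.values())).shape

    def channel(self, name):
        return self.channels[name]


@dataclass
class SynthConfig:
    """Parameters of one synthetic co-culture field.

    Distances are in micrometres, rates are per 24 h in [0, 1], and ``seed``
    fixes every source of randomness (placement, kinetics and pixel noise).
    """

    field_size_px: tuple = (1536, 1536)
    pixel_size_um_per_px: float = 0.50
    n_organoids: int = 5
    object_class: str = "organoid"          # "organoid" | "tumouroid"
    radius_range_um: tuple = (50.0, 70.0)
    shell_thickness_um: float = 25.0
    lumen: bool | None = None               # default: organoid True, tumouroid False
    n_immune_cells: int = 200
    infiltration_rate: float = 0.3
    timepoints_h: tuple = (0.0, 24.0, 48.0, 72.0)
    caspase_rate: float = 0.3
    noise_sd: float = 20.0
    seed: int = 0
    # geometry and rendering details
    min_separation_um: float = 110.0        # boundary-to-boundary object spacing
    phenotype_proportions: dict | None = None
    signal_amplitude: float = 3000.0
    caspase_baseline: float = 200.0         # dim reporter signal in live epithelium
    nucleus_radius_um: float = 2.5
    marker_radius_um: float = 3.0
    min_cell_distance_um: float = 7.5
    boundary_clearance_um: float = 2.0      # keep cells off analytic zone boundaries
    outside_clearance_um: float = 5.0       # keep extra-epithelial cells off the shell
    carve_radius_um: float = 4.0            # epithelium displaced around an IEL nucleus
    perturb_amplitude: float = 0.0          # radial perturbation; breaks the circle oracle

    def proportions(self):
        props = self.phenotype_proportions or DEFAULT_PHENOTYPE_PROPORTIONS
        return {m: float(props.get(m, 0.0)) for m in IMMUNE_MARKERS}

    def has_lumen(self):
        if self.lumen is not None:
            return self.lumen
        return self.object_class == "organoid"

    def lumen_radius_um(self, outer_radius_um):
        if not self.has_lumen():
            return 0.0
        return max(outer_radius_um - self.shell_thickness_um, 0.0)

    def validate(self):
        h, w = self.field_size_px
        if h < 8 or w < 8 or self.pixel_size_um_per_px <= 0:
            raise ValueError("invalid field geometry")
        rmin, rmax = self.radius_range_um
        if not (0 < rmin <= rmax):
            raise ValueError("radius_range_um must be positive and ordered")
        if self.n_organoids > 0 and 2 * rmax >= min(h, w) * self.pixel_size_um_per_px:
            raise ValueError("largest object diameter exceeds the field")
        for name in ("infiltration_rate", "caspase_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_organoids < 0 or self.n_immune_cells < 0:
            raise ValueError("counts must be nonnegative")
        if self.object_class not in ("organoid", "tumouroid"):
            raise ValueError("object_class must be 'organoid' or 'tumouroid'")
        tps = list(self.timepoints_h)
        if len(tps) == 0 or any(t < 0 for t in tps) or sorted(tps) != tps:
            raise ValueError("timepoints_h must be sorted and nonnegative")
        if abs(sum(self.proportions().values()) - 1.0) > 1e-9:
            raise ValueError("phenotype proportions must sum to 1")
        if not 0.0 <= self.perturb_amplitude < 0.5:
            raise ValueError("perturb_amplitude must be in [0, 0.5)")


def apoptotic_fraction(rate, t_h):
    """Apoptotic fraction of the epithelial shell, ``1 - (1 - rate)**(t/24)``."""
    return 1.0 - (1.0 - rate) ** (t_h / 24.0)


def true_zone(row_px, col_px, objects, pixel_size_um, margin_um=ZONE_MARGIN_UM):
    """Analytic zone of a point: (object_id, zone 1-4) or (-1, 0) for outside.

    A point inside a circle belongs to zone 2 if it is within ``margin_um`` of
    the boundary, else zone 1.  Outside, the first (proximal) and second
    (distal) margin bands are zones 3 and 4.  A point claimed by the outward
    bands of two or more objects is 'outside': contested pixels are deleted
    during overlap resolution and cells there are counted in no zone.
    """
    if len(objects) == 0:
        return -1, OUTSIDE
    d = np.hypot(objects["row_px"].to_numpy() - row_px,
                 objects["col_px"].to_numpy() - col_px) * pixel_size_um
    g = d - objects["radius_um"].to_numpy()
    inside = np.flatnonzero(g <= 0)
    if inside.size:
        j = inside[np.argmax(g[inside])]      # the containing object (unique)
        zone = 2 if g[j] >= -margin_um else 1
        return int(objects["object_id"].iloc[j]), zone
    claim = np.flatnonzero((g > 0) & (g <= 2 * margin_um))
    if claim.size != 1:
        return -1, OUTSIDE
    j = claim[0]
    zone = 3 if g[j] <= margin_um else 4
    return int(objects["object_id"].iloc[j]), zone


@dataclass
class GroundTruth:
    """Complete ground truth of a synthetic time course.

    ``objects`` has one row per object (centre in px, outer and lumen radius
    in um, class); ``cells`` has one row per cell per timepoint with the true
    phenotype and analytic zone membership (zone 0 encodes 'outside').
    """

    objects: pd.DataFrame
    cells: pd.DataFrame
    config: SynthConfig

    def positions(self, timepoint_h):
        sub = self.cells[self.cells["timepoint_h"] == timepoint_h]
        sub = sub.sort_values("cell_id")
        return sub[["row_px", "col_px"]].to_numpy(float)

    def apoptotic_fraction(self, t_h):
        return apoptotic_fraction(self.config.caspase_rate, t_h)

    def zone_occupancy(self, timepoint_h):
        """Tidy per-object, per-zone, per-phenotype cell counts at one timepoint."""
        sub = self.cells[self.cells["timepoint_h"] == timepoint_h]
        out = (sub.groupby(["object_id", "zone", "phenotype"], sort=True)
                  .size().rename("count").reset_index())
        return out

    def match_objects(self, objects, max_distance_um=25.0):
        """Map measured object labels to ground-truth ids by nearest centroid.

        Measured labels follow raster order, truth ids follow placement
        order; the mapping must be one-to-one within ``max_distance_um`` or
        a ``ValueError`` is raised.
        """
        px = self.config.pixel_size_um_per_px
        ty = self.objects["row_px"].to_numpy()
        tx = self.objects["col_px"].to_numpy()
        tid = self.objects["object_id"].to_numpy()
        mapping = {}
        for obj in objects:
            cy, cx = obj.centroid
            d = np.hypot(ty - cy, tx - cx) * px
            j = int(np.argmin(d))
            if d[j] > max_distance_um:
                raise ValueError(f"object {obj.label} matches no truth object")
            mapping[obj.label] = int(tid[j])
        if len(set(mapping.values())) != len(mapping):
            raise ValueError("object-to-truth matching is not one-to-one")
        return mapping


# ---------------------------------------------------------------------------
# placement

def _placement_border_um(radius_um):
    # object plus both outward margin bands must fit inside the field
    return radius_um + 2 * ZONE_MARGIN_UM + 2.0


def _place_objects(cfg, rng):
    h, w = cfg.field_size_px
    px = cfg.pixel_size_um_per_px
    rmin, rmax = cfg.radius_range_um
    rows, cols, radii = [], [], []
    for _ in range(cfg.n_organoids):
        for _attempt in range(10_000):
            radius = rng.uniform(rmin, rmax)
            border = _placement_border_um(radius) / px
            if 2 * border >= min(h, w):
                continue
            cy = rng.uniform(border, h - 1 - border)
            cx = rng.uniform(border, w - 1 - border)
            if rows:
                d = np.hypot(np.array(rows) - cy, np.array(cols) - cx) * px
                if np.any(d < radius + np.array(radii) + cfg.min_separation_um):
                    continue
            rows.append(cy)
            cols.append(cx)
            radii.append(radius)
            break
        else:
            raise RuntimeError(
                "object placement failed after 10000 attempts: field too crowded "
                f"for {cfg.n_organoids} objects of radius {cfg.radius_range_um} um "
                f"with {cfg.min_separation_um} um separation"
            )
    n = len(rows)
    return pd.DataFrame({
        "object_id": np.arange(n, dtype=int),
        "row_px": np.asarray(rows, float),
        "col_px": np.asarray(cols, float),
        "radius_um": np.asarray(radii, float),
        "lumen_radius_um": [cfg.lumen_radius_um(r) for r in radii],
        "object_class": cfg.object_class,
        "perturb_phase": rng.uniform(0, 2 * np.pi, n),
    })


def _phenotype_labels(cfg, rng):
    props = cfg.proportions()
    n = cfg.n_immune_cells
    base = {m: int(math.floor(props[m] * n)) for m in IMMUNE_MARKERS}
    short = n - sum(base.values())
    frac = sorted(IMMUNE_MARKERS,
                  key=lambda m: (-(props[m] * n - base[m]), IMMUNE_MARKERS.index(m)))
    for m in frac[:short]:
        base[m] += 1
    labels = np.array([m for m in IMMUNE_MARKERS for _ in range(base[m])])
    rng.shuffle(labels)
    return labels


def _cell_position_ok(cy, cx, cfg, objects, placed):
    h, w = cfg.field_size_px
    px = cfg.pixel_size_um_per_px
    edge = cfg.nucleus_radius_um / px + 2
    if not (edge <= cy <= h - 1 - edge and edge <= cx <= w - 1 - edge):
        return False
    if len(objects):
        d = np.hypot(objects["row_px"].to_numpy() - cy,
                     objects["col_px"].to_numpy() - cx) * px
        g = d - objects["radius_um"].to_numpy()
        if np.any(g < cfg.outside_clearance_um):
            return False
        bc = cfg.boundary_clearance_um
        if np.any(np.abs(g - ZONE_MARGIN_UM) < bc):
            return False
        if np.any(np.abs(g - 2 * ZONE_MARGIN_UM) < bc):
            return False
    if len(placed):
        arr = np.asarray(placed)
        if np.min(np.hypot(arr[:, 0] - cy, arr[:, 1] - cx)) * px < cfg.min_cell_distance_um:
            return False
    return True


def _place_cells(cfg, objects, rng):
    """Uniform random placement in the matrix, with clearance buffers.

    Cells start extra-epithelial (co-embedded in the ECM, not inside objects)
    and keep a small clearance from analytic zone boundaries and from each
    other so that zone membership and nuclear detection are unambiguous.
    """
    h, w = cfg.field_size_px
    placed = []
    for _ in range(cfg.n_immune_cells):
        for _attempt in range(10_000):
            cy = rng.uniform(0, h - 1)
            cx = rng.uniform(0, w - 1)
            if _cell_position_ok(cy, cx, cfg, objects, placed):
                placed.append((cy, cx))
                break
        else:
            raise RuntimeError("cell placement failed: field too crowded")
    return np.asarray(placed, float).reshape(cfg.n_immune_cells, 2)


# ---------------------------------------------------------------------------
# infiltration kinetics

def _shell_radius_bounds(cfg, radius_um, lumen_radius_um):
    lo = max(lumen_radius_um + 2.0, 2.0)
    hi = radius_um - (cfg.carve_radius_um + 1.5)
    return lo, hi


def _advance(pos, objects, cfg, rate, dt_h, rng):
    """One infiltration step (in place).

    Each extra-epithelial cell jumps into the shell of its nearest object
    with probability ``rate * dt / 24`` (clipped to 1); intra-epithelial
    cells are stationary.  The landing point lies on the ray from the object
    centre through the cell (falling back to a random angle when crowded)
    and respects the minimum cell spacing; a cell that cannot be placed after
    100 draws stays outside for this step.
    """
    p = min(1.0, max(0.0, rate * dt_h / 24.0))
    if p == 0.0 or len(objects) == 0 or len(pos) == 0:
        return pos
    px = cfg.pixel_size_um_per_px
    ocy = objects["row_px"].to_numpy()
    ocx = objects["col_px"].to_numpy()
    orad = objects["radius_um"].to_numpy()
    olum = objects["lumen_radius_um"].to_numpy()
    h, w = cfg.field_size_px
    edge = cfg.nucleus_radius_um / px + 2
    for i in range(len(pos)):
        d = np.hypot(ocy - pos[i, 0], ocx - pos[i, 1]) * px
        g = d - orad
        if np.min(g) <= 0:
            continue                      # already intra-epithelial
        if rng.random() >= p:
            continue
        j = int(np.argmin(g))
        lo, hi = _shell_radius_bounds(cfg, orad[j], olum[j])
        if hi <= lo:
            lo = hi = 0.5 * (olum[j] + orad[j])
        theta0 = math.atan2(pos[i, 0] - ocy[j], pos[i, 1] - ocx[j])
        for k in range(100):
            u = math.sqrt(rng.uniform(lo * lo, hi * hi)) if hi > lo else lo
            inner_band = orad[j] - ZONE_MARGIN_UM
            if inner_band > lo and abs(u - inner_band) < cfg.boundary_clearance_um:
                continue                  # keep off the zone-1/zone-2 boundary
            theta = theta0 if k < 10 else rng.uniform(0, 2 * np.pi)
            cy = ocy[j] + (u / px) * math.sin(theta)
            cx = ocx[j] + (u / px) * math.cos(theta)
            if not (edge <= cy <= h - 1 - edge and edge <= cx <= w - 1 - edge):
                continue
            others = np.delete(pos, i, axis=0)
            if len(others):
                dmin = np.min(np.hypot(others[:, 0] - cy, others[:, 1] - cx)) * px
                if dmin < cfg.min_cell_distance_um:
                    continue
            pos[i, 0] = cy
            pos[i, 1] = cx
            break
    return pos


def step_infiltration(truth, rate, dt_h, rng):
    """Advance a ground truth by one step of ``dt_h`` hours.

    Returns a new :class:`GroundTruth` with an appended timepoint.  ``rng``
    may be a :class:`numpy.random.Generator` or an integer seed.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cfg = truth.config
    last_t = float(truth.cells["timepoint_h"].max()) if len(truth.cells) else 0.0
    sub = truth.cells[truth.cells["timepoint_h"] == last_t].sort_values("cell_id")
    pos = sub[["row_px", "col_px"]].to_numpy(float).copy()
    phen = sub["phenotype"].to_numpy()
    ids = sub["cell_id"].to_numpy()
    _advance(pos, truth.objects, cfg, rate, dt_h, rng)
    rows = _cell_rows(pos, phen, ids, truth.objects, cfg, last_t + dt_h)
    cells = pd.concat([truth.cells, rows], ignore_index=True)
    return GroundTruth(objects=truth.objects, cells=cells, config=cfg)


def _cell_rows(pos, phenotypes, cell_ids, objects, cfg, t_h):
    recs = []
    for i in range(len(pos)):
        oid, zone = true_zone(pos[i, 0], pos[i, 1], objects, cfg.pixel_size_um_per_px)
        recs.append((float(t_h), int(cell_ids[i]), pos[i, 0], pos[i, 1],
                     phenotypes[i], oid, zone))
    return pd.DataFrame(recs, columns=["timepoint_h", "cell_id", "row_px",
                                       "col_px", "phenotype", "object_id", "zone"])


# ---------------------------------------------------------------------------
# rendering

def _object_window(obj_row, cfg):
    """Crop slices plus the normalized radial coordinate (um) within the crop.

    With radial perturbation the outline is r(theta) = R(1 + a cos(3 theta +
    phase)); distances are divided by the local scale factor so that the
    painted shell can still be expressed by comparisons against the nominal
    radii.
    """
    h, w = cfg.field_size_px
    px = cfg.pixel_size_um_per_px
    a = cfg.perturb_amplitude
    radius_px = obj_row["radius_um"] * (1 + a) / px
    half = int(math.ceil(radius_px)) + 2
    cy, cx = obj_row["row_px"], obj_row["col_px"]
    r0 = max(int(math.floor(cy)) - half, 0)
    r1 = min(int(math.ceil(cy)) + half + 1, h)
    c0 = max(int(math.floor(cx)) - half, 0)
    c1 = min(int(math.ceil(cx)) + half + 1, w)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dr = yy - cy
    dc = xx - cx
    d_um = np.hypot(dr, dc) * px
    if a > 0:
        theta = np.arctan2(dr, dc)
        d_um = d_um / (1.0 + a * np.cos(3 * theta + obj_row["perturb_phase"]))
    return (slice(r0, r1), slice(c0, c1)), d_um


def _paint_epithelium(panck, caspase, truth, rate, t_h, cfg):
    f = apoptotic_fraction(rate, t_h)
    for _, obj in truth.objects.iterrows():
        win, d = _object_window(obj, cfg)
        R = obj["radius_um"]
        rl = obj["lumen_radius_um"]
        shell = (d <= R) & (d >= rl)
        rho = math.sqrt(max(R * R - f * (R * R - rl * rl), 0.0))
        apop = shell & (d >= rho)
        live = shell & ~apop
        panck[win][live] = cfg.signal_amplitude
        caspase[win][apop] = cfg.signal_amplitude
        caspase[win][live] = cfg.caspase_baseline


def _paint_disk(arr, row, col, radius_um, value, cfg):
    h, w = arr.shape
    px = cfg.pixel_size_um_per_px
    rpx = radius_um / px
    half = int(math.ceil(rpx)) + 1
    r0 = max(int(math.floor(row)) - half, 0)
    r1 = min(int(math.ceil(row)) + half + 1, h)
    c0 = max(int(math.floor(col)) - half, 0)
    c1 = min(int(math.ceil(col)) + half + 1, w)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    disk = (yy - row) ** 2 + (xx - col) ** 2 <= rpx * rpx
    sub = arr[r0:r1, c0:c1]
    sub[disk] = np.maximum(sub[disk], value)


def _carve_disk(arrs, row, col, radius_um, cfg):
    for arr in arrs:
        h, w = arr.shape
        px = cfg.pixel_size_um_per_px
        rpx = radius_um / px
        half = int(math.ceil(rpx)) + 1
        r0 = max(int(math.floor(row)) - half, 0)
        r1 = min(int(math.ceil(row)) + half + 1, h)
        c0 = max(int(math.floor(col)) - half, 0)
        c1 = min(int(math.ceil(col)) + half + 1, w)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        disk = (yy - row) ** 2 + (xx - col) ** 2 <= rpx * rpx
        arr[r0:r1, c0:c1][disk] = 0.0


def _render(truth, t_h, cfg, rng, metadata):
    raw = {name: np.zeros(cfg.field_size_px, float) for name in CHANNELS}
    _paint_epithelium(raw["panCK"], raw["caspase"], truth, cfg.caspase_rate, t_h, cfg)
    sub = truth.cells[truth.cells["timepoint_h"] == t_h]
    # intra-epithelial lymphocytes locally displace the epithelium
    intra = sub[sub["zone"].isin([1, 2])]
    for _, c in intra.iterrows():
        _carve_disk((raw["panCK"], raw["caspase"]), c["row_px"], c["col_px"],
                    cfg.carve_radius_um, cfg)
    for _, c in sub.iterrows():
        _paint_disk(raw["DAPI"], c["row_px"], c["col_px"],
                    cfg.nucleus_radius_um, cfg.signal_amplitude, cfg)
        _paint_disk(raw[c["phenotype"]], c["row_px"], c["col_px"],
                    cfg.marker_radius_um, cfg.signal_amplitude, cfg)
    channels = {}
    for name in CHANNELS:
        arr = raw[name]
        if cfg.noise_sd > 0:
            arr = arr + rng.normal(0.0, cfg.noise_sd, arr.shape)
        channels[name] = np.rint(np.clip(arr, 0, 65535)).astype(np.uint16)
    meta = dict(metadata or {})
    meta["timepoint_h"] = float(t_h)
    return ImageField(channels=channels, pixel_size_um=cfg.pixel_size_um_per_px,
                      metadata=meta)


def render_caspase(truth, rate, t_h, rng=None):
    """Render only the caspase-3/7 channel at ``t_h`` for apoptosis ``rate``.

    The apoptotic pixel fraction of each shell is ``1 - (1 - rate)**(t/24)``,
    applied outside-in; apoptotic pixels are bright, live epithelium carries
    the dim baseline.  With ``rng`` given, Gaussian pixel noise is added.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    cfg = truth.config
    caspase = np.zeros(cfg.field_size_px, float)
    panck = np.zeros(cfg.field_size_px, float)
    _paint_epithelium(panck, caspase, truth, rate, t_h, cfg)
    if rng is not None:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        caspase = caspase + rng.normal(0.0, cfg.noise_sd, caspase.shape)
    return np.rint(np.clip(caspase, 0, 65535)).astype(np.uint16)


def generate_field(config, metadata=None):
    """Generate one synthetic co-culture time course.

    Returns ``(fields, truth)`` where ``fields`` is one :class:`ImageField`
    per configured timepoint and ``truth`` the complete :class:`GroundTruth`.
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    objects = _place_objects(config, rng)
    pos = _place_cells(config, objects, rng)
    phen = _phenotype_labels(config, rng)
    ids = np.arange(config.n_immune_cells, dtype=int)
    tps = [float(t) for t in config.timepoints_h]
    frames = []
    for i, t in enumerate(tps):
        if i > 0:
            _advance(pos, objects, config, config.infiltration_rate,
                     tps[i] - tps[i - 1], rng)
        frames.append(_cell_rows(pos, phen, ids, objects, config, t))
    cells = (pd.concat(frames, ignore_index=True) if frames
             else _cell_rows(np.empty((0, 2)), [], [], objects, config, 0.0))
    truth = GroundTruth(objects=objects, cells=cells, config=config)
    fields = [_render(truth, t, config, rng, metadata) for t in tps]
    return fields, truth


def with_seed(config, seed):
    """A copy of ``config`` with a different seed (convenience for sweeps)."""
    return replace(config, seed=seed)
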