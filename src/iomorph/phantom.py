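"""Parametric forearm phantoms and synthetic biphasic tensile curves.

The phantom stands in for the cadaveric data: two capped-cylinder bones
of declared lengths, an interosseous membrane modelled as a thin ruled
solid spanning the gap between them, landmark clips placed exactly at
the analytic attachment-span endpoints, and force-displacement curves
with a toe region, a linear region of known slope, a first fibre-failure
peak and an ultimate peak.  Every quantity the morphometry and tensile
modules measure is analytically known here, which makes parameter
recovery the package's primary validation surface.

Geometry convention (canonical frame, before any rigid re-orientation):
the radius runs along +z with its distal end at z = 0 and its centre
line on the z-axis; the ulna is parallel at centre distance
``radius_radius + gap + ulna_radius`` along +x; the membrane mid-surface
lies in the y = 0 plane, so y is the dorso-palmar (thickness) direction.
Fibre lines connect a radial attachment point to an ulnar attachment
point inside that plane.  The signed fan-out angle of a fibre against
the radius axis is positive when the radial-to-ulnar vector points
distally (CB/AB course) and negative when it points proximally
(DOAC/DOB course).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import ConfigurationError, ValidationError
from .io_core import BoneAxis, LandmarkSet, SurfaceMesh, TensileCurve


def _thickness_pair(t) -> tuple[float, float]:
    if np.isscalar(t):
        return float(t), float(t)
    a, b = t
    return float(a), float(b)


@dataclass
class LigamentSpec:
    """Declared geometry of one ligament in the phantom.

    ``radius_span`` / ``ulna_span`` are [distal%, proximal%] of the
    owning bone's length (a single mid-fibre percentage for the DOAC).
    If ``ulna_span`` is omitted, it is derived from ``fan_out`` (signed
    degrees per fibre) and the membrane gap, so the declared angle holds
    exactly.  ``thickness`` is either a constant (mm) or a
    (radial, ulnar) pair defining a linear ramp across the membrane.
    """

    ligament_id: str
    radius_span: tuple[float, float] | float
    ulna_span: tuple[float, float] | float | None = None
    fan_out: tuple[float, float] | float | None = None
    thickness: float | tuple[float, float] = 3.0

    def __post_init__(self) -> None:
        if self.ulna_span is None and self.fan_out is None:
            raise ConfigurationError(
                f"{self.ligament_id}: need either ulna_span or fan_out"
            )
        tr, tu = _thickness_pair(self.thickness)
        if tr <= 0 or tu <= 0:
            raise ValidationError(f"{self.ligament_id}: thickness must be positive")
        spans = [self.radius_span] if self.is_mid_fibre else [self.radius_span, self.ulna_span]
        for span in spans:
            if span is None or np.isscalar(span):
                continue
            d, p = span
            if not 0 <= d < p <= 100:
                raise ConfigurationError(
                    f"{self.ligament_id}: span must satisfy 0 <= distal < proximal <= 100"
                )

    @property
    def is_mid_fibre(self) -> bool:
        return self.ligament_id == "DOAC"


def default_ligaments() -> list[LigamentSpec]:
    """Ligament set at the magnitudes of the cadaveric study.

    CB and DOB use the published attachment spans verbatim; the DOAC is
    angle-driven at the published -18.7 deg mean.  The published AB span
    overlaps the CB span on the radius (group means of different
    specimens are not a consistent single geometry), so the phantom AB
    is shifted distally while keeping the published widths.
    """
    return [
        LigamentSpec("DOB", radius_span=(10.0, 17.5), ulna_span=(11.0, 19.1),
                     thickness=6.95),
        LigamentSpec("AB", radius_span=(40.0, 47.7), ulna_span=(21.3, 30.3),
                     thickness=3.11),
        LigamentSpec("CB", radius_span=(51.7, 65.1), ulna_span=(32.9, 46.4),
                     thickness=3.52),
        LigamentSpec("DOAC", radius_span=74.0, fan_out=-18.7, thickness=4.65),
    ]


@dataclass
class PhantomTruth:
    """Ground-truth parameters of a synthetic forearm phantom.

    Defaults follow the cadaveric study conditions: mean radius length
    254.4 mm, mean ulna length 271.5 mm, an interosseous gap of 16.4 mm
    (which places the CB fan-out angles in the published 20-35 deg
    range), and ligament spans/thicknesses at the published magnitudes.
    """

    radius_length: float = 254.4
    ulna_length: float = 271.5
    radius_radius: float = 9.0
    ulna_radius: float = 8.0
    gap: float = 16.4
    ulna_distal_offset: float = -5.0
    ligaments: list[LigamentSpec] = field(default_factory=default_ligaments)
    edge_margin: float = 5.0
    doac_band_half_width: float = 4.5  # perpendicular half-width of the DOAC cord
    random_orientation: bool = False

    def __post_init__(self) -> None:
        for v, name in [
            (self.radius_length, "radius_length"),
            (self.ulna_length, "ulna_length"),
            (self.radius_radius, "radius_radius"),
            (self.ulna_radius, "ulna_radius"),
            (self.gap, "gap"),
        ]:
            if not v > 0:
                raise ValidationError(f"{name} must be positive")

    # -- canonical-frame analytic geometry ---------------------------------

    @property
    def x_radial(self) -> float:
        return self.radius_radius

    @property
    def x_ulnar(self) -> float:
        return self.radius_radius + self.gap

    def radius_z(self, pct: float) -> float:
        return pct / 100.0 * self.radius_length

    def ulna_z(self, pct: float) -> float:
        return self.ulna_distal_offset + pct / 100.0 * self.ulna_length

    def ulna_pct_from_z(self, z: float) -> float:
        return 100.0 * (z - self.ulna_distal_offset) / self.ulna_length

    def _derive_ulna_z(self, z_r: float, theta_deg: float) -> float:
        """Ulnar fibre endpoint implied by a signed fan-out angle."""
        if abs(theta_deg) < 1e-9:
            raise ConfigurationError(
                "a 0 deg fibre is parallel to the bone axis and cannot span the gap"
            )
        if abs(abs(theta_deg) - 90.0) < 1e-12:
            return z_r
        dz = -math.copysign(self.gap / math.tan(math.radians(abs(theta_deg))), theta_deg)
        return z_r + dz

    def fibre_endpoints(self, spec: LigamentSpec) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per fibre position -> (radial point, ulnar point), canonical frame."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}

        def pt(x: float, z: float) -> np.ndarray:
            return np.array([x, 0.0, z])

        def check_on_ulna(z_u: float, what: str) -> None:
            pct = self.ulna_pct_from_z(z_u)
            if not 0.0 <= pct <= 100.0:
                raise ConfigurationError(
                    f"{spec.ligament_id} {what}: derived ulnar attachment at "
                    f"{pct:.1f}% lies outside the ulna"
                )

        if spec.is_mid_fibre:
            z_r = self.radius_z(float(spec.radius_span))
            if spec.ulna_span is not None:
                z_u = self.ulna_z(float(spec.ulna_span))
            else:
                z_u = self._derive_ulna_z(z_r, float(spec.fan_out))
                check_on_ulna(z_u, "m")
            out["m"] = (pt(self.x_radial, z_r), pt(self.x_ulnar, z_u))
            return out
        rd, rp = spec.radius_span
        z_rd, z_rp = self.radius_z(rd), self.radius_z(rp)
        if spec.ulna_span is not None:
            ud, up = spec.ulna_span
            z_ud, z_up = self.ulna_z(ud), self.ulna_z(up)
        else:
            th_d, th_p = spec.fan_out
            z_ud = self._derive_ulna_z(z_rd, float(th_d))
            z_up = self._derive_ulna_z(z_rp, float(th_p))
            check_on_ulna(z_ud, "d")
            check_on_ulna(z_up, "p")
        out["d"] = (pt(self.x_radial, z_rd), pt(self.x_ulnar, z_ud))
        out["p"] = (pt(self.x_radial, z_rp), pt(self.x_ulnar, z_up))
        return out

    def signed_angle(self, z_r: float, z_u: float) -> float:
        """Signed fan-out angle (deg) of the fibre (z_r -> z_u) vs the radius axis."""
        dz = z_u - z_r
        acute = math.degrees(math.atan2(self.gap, abs(dz)))
        if dz > 0:
            return -acute
        return acute  # dz < 0 distally-directed -> positive; dz == 0 -> +90

    def expected_record(self, ligament_id: str) -> dict:
        """Analytic truth the morphometry module should recover."""
        spec = next(l for l in self.ligaments if l.ligament_id == ligament_id)
        ends = self.fibre_endpoints(spec)
        tr, tu = _thickness_pair(spec.thickness)
        rec: dict = {
            "ligament_id": ligament_id,
            "mean_thickness": 0.5 * (tr + tu),
            "thickness_radial": tr,
            "thickness_ulnar": tu,
            "radial_pct": {},
            "ulnar_pct": {},
            "fan_out_deg": {},
        }
        for pos, (r, u) in ends.items():
            rec["radial_pct"][pos] = 100.0 * r[2] / self.radius_length
            rec["ulnar_pct"][pos] = self.ulna_pct_from_z(u[2])
            rec["fan_out_deg"][pos] = self.signed_angle(r[2], u[2])
        if not spec.is_mid_fibre:
            rec["width_radial"] = abs(ends["p"][0][2] - ends["d"][0][2])
            rec["width_ulnar"] = abs(ends["p"][1][2] - ends["d"][1][2])
        else:
            rec["width_radial"] = rec["width_ulnar"] = None
        return rec

    # -- rails of the membrane sheet ---------------------------------------

    def rails(self) -> list[dict]:
        """Ordered fibre rails spanning the sheet, distal to proximal.

        Each rail carries the (z_radial, z_ulnar) fibre endpoints and the
        (radial, ulnar) thickness at that fibre.  Edge-margin rails extend
        the sheet slightly beyond the extreme ligaments.
        """
        def z_shift_per_perp(z_r: float, z_u: float) -> float:
            # axial shift that moves a fibre rail by 1 mm perpendicular
            # to its own direction within the membrane plane
            length = math.hypot(self.gap, z_u - z_r)
            return length / self.gap

        rails: list[dict] = []
        for spec in self.ligaments:
            ends = self.fibre_endpoints(spec)
            tr, tu = _thickness_pair(spec.thickness)
            for pos, (r, u) in ends.items():
                rails.append(
                    {"ligament": spec.ligament_id, "pos": pos,
                     "z_r": r[2], "z_u": u[2], "t": (tr, tu)}
                )
                if spec.is_mid_fibre and self.doac_band_half_width > 0:
                    # the DOAC is a discrete cord: give it flanking rails
                    # of the same thickness so the band is uniform
                    dz = self.doac_band_half_width * z_shift_per_perp(r[2], u[2])
                    for sgn, tag in ((-1.0, "band_d"), (+1.0, "band_p")):
                        rails.append(
                            {"ligament": spec.ligament_id, "pos": tag,
                             "z_r": r[2] + sgn * dz, "z_u": u[2] + sgn * dz,
                             "t": (tr, tu)}
                        )
        rails.sort(key=lambda r: r["z_r"])
        z_r = [r["z_r"] for r in rails]
        z_u = [r["z_u"] for r in rails]
        order = [r["ligament"] for r in rails]
        contiguous = all(
            order.index(lig) + order.count(lig) - 1 == len(order) - 1 - order[::-1].index(lig)
            for lig in set(order)
        )
        if np.any(np.diff(z_r) <= 0) or np.any(np.diff(z_u) <= 0) or not contiguous:
            raise ConfigurationError(
                "ligament attachment spans overlap; fibre rails must be "
                "strictly ordered on both bones"
            )
        if self.edge_margin > 0:
            first, last = dict(rails[0]), dict(rails[-1])
            for rail, sgn in ((first, -1.0), (last, +1.0)):
                dz = self.edge_margin * z_shift_per_perp(rail["z_r"], rail["z_u"])
                rail["ligament"] = "_margin"
                rail["pos"] = "edge"
                rail["z_r"] += sgn * dz
                rail["z_u"] += sgn * dz
            rails = [first] + rails + [last]
        return rails

    def analytic_areas(self) -> dict[str, float]:
        """Mid-surface area (mm^2) per ligament patch and of the whole sheet.

        Every patch is a planar quad in the membrane plane, so its area
        is exact (shoelace on the four fibre endpoints).  A ligament's
        patch is the region between its distal and proximal rails; the
        mid-fibre DOAC has zero span and contributes no patch area.
        """
        rails = self.rails()
        xr, xu = self.x_radial, self.x_ulnar

        def quad_area(r0, r1) -> float:
            pts = np.array(
                [[xr, r0["z_r"]], [xu, r0["z_u"]], [xu, r1["z_u"]], [xr, r1["z_r"]]]
            )
            x, z = pts[:, 0], pts[:, 1]
            return 0.5 * abs(np.dot(x, np.roll(z, -1)) - np.dot(z, np.roll(x, -1)))

        areas: dict[str, float] = {"total": 0.0}
        for r0, r1 in zip(rails[:-1], rails[1:]):
            a = quad_area(r0, r1)
            areas["total"] += a
            if r0["ligament"] == r1["ligament"] and r0["ligament"] != "_margin":
                areas[r0["ligament"]] = areas.get(r0["ligament"], 0.0) + a
        return areas


@dataclass
class PhantomResult:
    """Everything make_phantom produces, including the analytic truth echo."""

    radius: SurfaceMesh
    ulna: SurfaceMesh
    membrane: SurfaceMesh
    landmarks: list[LandmarkSet]
    truth: PhantomTruth
    expected: dict[str, dict]
    radius_axis: BoneAxis
    ulna_axis: BoneAxis
    distal_hints: dict[str, np.ndarray]
    rotation: np.ndarray
    translation: np.ndarray
    vertex_counts: dict[str, int]
    analytic_areas: dict[str, float]


def _cylinder(radius: float, length: float, z0: float, x0: float,
              sections: int, name: str) -> SurfaceMesh:
    tm = trimesh.creation.cylinder(radius=radius, height=length, sections=sections)
    tm.apply_translation([x0, 0.0, z0 + length / 2.0])
    return SurfaceMesh.from_trimesh(tm, name=name)


def _membrane_mesh(truth: PhantomTruth, mesh_resolution: float) -> SurfaceMesh:
    """Watertight thin solid around the ruled mid-surface."""
    rails = truth.rails()
    xr, xu = truth.x_radial, truth.x_ulnar
    ns = max(4, int(math.ceil(truth.gap / mesh_resolution)))
    s = np.linspace(0.0, 1.0, ns + 1)

    # rows: rails plus evenly interpolated rows inside each patch
    rows = []
    for r0, r1 in zip(rails[:-1], rails[1:]):
        span = max(abs(r1["z_r"] - r0["z_r"]), abs(r1["z_u"] - r0["z_u"]))
        nu = max(1, int(math.ceil(span / mesh_resolution)))
        for k in range(nu):
            u = k / nu
            rows.append(
                {
                    "z_r": (1 - u) * r0["z_r"] + u * r1["z_r"],
                    "z_u": (1 - u) * r0["z_u"] + u * r1["z_u"],
                    "t": tuple((1 - u) * np.asarray(r0["t"]) + u * np.asarray(r1["t"])),
                }
            )
    rows.append({"z_r": rails[-1]["z_r"], "z_u": rails[-1]["z_u"], "t": rails[-1]["t"]})

    nr, nc = len(rows), len(s)
    x = xr + s * (xu - xr)
    mid = np.empty((nr, nc, 3))
    half = np.empty((nr, nc))
    for i, row in enumerate(rows):
        z = (1 - s) * row["z_r"] + s * row["z_u"]
        t = (1 - s) * row["t"][0] + s * row["t"][1]
        mid[i, :, 0] = x
        mid[i, :, 1] = 0.0
        mid[i, :, 2] = z
        half[i] = 0.5 * t
    top = mid.copy()
    top[:, :, 1] = half
    bot = mid.copy()
    bot[:, :, 1] = -half

    def vid(layer: int, i: int, j: int) -> int:  # layer 0 = top, 1 = bottom
        return layer * nr * nc + i * nc + j

    vertices = np.concatenate([top.reshape(-1, 3), bot.reshape(-1, 3)])
    faces: list[tuple[int, int, int]] = []
    for i in range(nr - 1):
        for j in range(nc - 1):
            a, b = vid(0, i, j), vid(0, i + 1, j)
            c, d = vid(0, i + 1, j + 1), vid(0, i, j + 1)
            faces += [(a, b, c), (a, c, d)]  # top, outward +y
            a, b = vid(1, i, j), vid(1, i + 1, j)
            c, d = vid(1, i + 1, j + 1), vid(1, i, j + 1)
            faces += [(a, c, b), (a, d, c)]  # bottom, outward -y
    for i in range(nr - 1):  # radial (-x) and ulnar (+x) edge walls
        a, b = vid(1, i, 0), vid(1, i + 1, 0)
        c, d = vid(0, i + 1, 0), vid(0, i, 0)
        faces += [(a, b, c), (a, c, d)]
        a, b = vid(1, i, nc - 1), vid(1, i + 1, nc - 1)
        c, d = vid(0, i + 1, nc - 1), vid(0, i, nc - 1)
        faces += [(a, c, b), (a, d, c)]
    for j in range(nc - 1):  # distal (-z) and proximal (+z) edge walls
        a, b = vid(0, 0, j), vid(0, 0, j + 1)
        c, d = vid(1, 0, j + 1), vid(1, 0, j)
        faces += [(a, b, c), (a, c, d)]
        a, b = vid(0, nr - 1, j), vid(0, nr - 1, j + 1)
        c, d = vid(1, nr - 1, j + 1), vid(1, nr - 1, j)
        faces += [(a, c, b), (a, d, c)]
    return SurfaceMesh(vertices, np.asarray(faces), name="membrane")


def _landmarks(truth: PhantomTruth) -> list[LandmarkSet]:
    out = []
    for spec in truth.ligaments:
        ends = truth.fibre_endpoints(spec)
        pts: dict[str, np.ndarray] = {}
        for pos, (r, u) in ends.items():
            pts[f"R_{pos}"] = r
            pts[f"U_{pos}"] = u
        out.append(LandmarkSet(spec.ligament_id, pts))
    return out


def make_phantom(
    truth: PhantomTruth,
    mesh_resolution: float = 2.0,
    seed: int = 0,
    bone_sections: int = 64,
) -> PhantomResult:
    """Generate bone and membrane meshes, landmarks and the truth echo.

    ``mesh_resolution`` is the target in-plane edge length (mm) of the
    membrane grid; fibre lines and attachment endpoints are analytic, so
    landmark-derived quantities are resolution independent.  The *seed*
    only matters when ``truth.random_orientation`` is set, in which case
    the whole phantom is rigidly re-oriented by a seeded random rotation
    and translation (morphometric truth is invariant under this).
    """
    radius = _cylinder(truth.radius_radius, truth.radius_length, 0.0, 0.0,
                       bone_sections, "radius")
    xc_ulna = truth.radius_radius + truth.gap + truth.ulna_radius
    ulna = _cylinder(truth.ulna_radius, truth.ulna_length,
                     truth.ulna_distal_offset, xc_ulna, bone_sections, "ulna")
    membrane = _membrane_mesh(truth, mesh_resolution)
    for mesh in (radius, ulna, membrane):
        if len(mesh.faces) < 200:
            raise ConfigurationError(
                f"{mesh.name}: resolution too coarse ({len(mesh.faces)} faces < 200)"
            )
    landmarks = _landmarks(truth)
    zhat = np.array([0.0, 0.0, 1.0])
    radius_axis = BoneAxis(np.zeros(3), zhat, truth.radius_length)
    ulna_axis = BoneAxis(np.array([xc_ulna, 0.0, truth.ulna_distal_offset]),
                         zhat, truth.ulna_length)
    hints = {"radius": np.array([0.0, 0.0, -1.0]),
             "ulna": np.array([xc_ulna, 0.0, truth.ulna_distal_offset - 1.0])}

    rot = np.eye(3)
    tra = np.zeros(3)
    if truth.random_orientation:
        rng = np.random.default_rng(seed)
        from scipy.spatial.transform import Rotation

        rot = Rotation.random(random_state=rng).as_matrix()
        tra = rng.uniform(-50.0, 50.0, size=3)
        radius = radius.transformed(rot, tra)
        ulna = ulna.transformed(rot, tra)
        membrane = membrane.transformed(rot, tra)
        landmarks = [lm.transformed(rot, tra) for lm in landmarks]
        radius_axis = BoneAxis(rot @ radius_axis.distal_point + tra,
                               rot @ radius_axis.direction, radius_axis.length)
        ulna_axis = BoneAxis(rot @ ulna_axis.distal_point + tra,
                             rot @ ulna_axis.direction, ulna_axis.length)
        hints = {k: rot @ v + tra for k, v in hints.items()}

    expected = {spec.ligament_id: truth.expected_record(spec.ligament_id)
                for spec in truth.ligaments}
    return PhantomResult(
        radius=radius,
        ulna=ulna,
        membrane=membrane,
        landmarks=landmarks,
        truth=truth,
        expected=expected,
        radius_axis=radius_axis,
        ulna_axis=ulna_axis,
        distal_hints=hints,
        rotation=rot,
        translation=tra,
        vertex_counts={m.name: len(m.vertices) for m in (radius, ulna, membrane)},
        analytic_areas=truth.analytic_areas(),
    )


# ---------------------------------------------------------------------------
# synthetic tensile curves


@dataclass
class TensileTruth:
    """Ground truth of one synthetic ramp-to-failure curve.

    The curve is generated in the machine frame that starts at the
    preload: force(0) = preload exactly, so the declared stiffness, peak
    forces, ultimate strain and linear range all live on the same
    displacement origin that preprocessing produces.
    """

    stiffness_true: float       # N/mm, slope of the linear region
    first_peak_force_true: float
    ultimate_force_true: float
    ultimate_strain_true: float  # %, grip-to-grip at the ultimate force
    toe_span: float = 0.5        # mm of residual concave toe after the preload
    linear_span: float | None = None  # mm of truly linear response (derived if None)
    linear_end_fraction: float = 0.9  # linear region ends at this fraction of the first peak
    softening_fraction: float = 0.4   # mean slope of the softening limb, as fraction of k
    noise_sd: float = 0.0        # N, i.i.d. Gaussian on force
    seed: int = 0
    gauge_length: float = 250.0  # mm; grip-to-grip length of the mounted construct
    preload: float = 0.5
    specimen_id: str = ""
    ligament_id: str = ""

    def __post_init__(self) -> None:
        for v, name in [
            (self.stiffness_true, "stiffness_true"),
            (self.first_peak_force_true, "first_peak_force_true"),
            (self.ultimate_force_true, "ultimate_force_true"),
            (self.ultimate_strain_true, "ultimate_strain_true"),
            (self.gauge_length, "gauge_length"),
        ]:
            if not v > 0:
                raise ValidationError(f"{name} must be positive")
        if self.first_peak_force_true > self.ultimate_force_true + 1e-12:
            raise ValidationError("first peak force must not exceed ultimate force")
        if self.toe_span < 0 or self.noise_sd < 0:
            raise ValidationError("toe_span and noise_sd must be non-negative")
        if self.linear_span is not None and not self.linear_span > 0:
            raise ValidationError("linear_span must be positive when given")
        if not 0 < self.linear_end_fraction < 1:
            raise ValidationError("linear_end_fraction must be in (0, 1)")
        if not 0 < self.softening_fraction < 1:
            raise ValidationError("softening_fraction must be in (0, 1)")

    @property
    def is_monophasic(self) -> bool:
        return self.first_peak_force_true >= self.ultimate_force_true - 1e-12

    def resolved_linear_span(self) -> float:
        """Length (mm) of the linear segment.

        When not given explicitly, the linear region is taken to end
        where the force reaches ``linear_end_fraction`` of the first
        peak — micro-failures then soften the curve up to the peak.
        """
        if self.linear_span is not None:
            return self.linear_span
        _, _, f_t = self.toe_parameters()
        k, sf = self.stiffness_true, self.softening_fraction
        span = (self.linear_end_fraction * self.first_peak_force_true - f_t) / k
        if self.is_monophasic:
            # additionally end the linear region early enough that the
            # softening limb can reach the single peak at its declared
            # displacement with mean slope softening_fraction * k
            fu = self.ultimate_force_true
            t = self.toe_span
            du = self.gauge_length * self.ultimate_strain_true / 100.0
            dl_sf = (fu - f_t + k * t - sf * k * du) / (k * (1.0 - sf))
            span = min(span, dl_sf - t)
        if span <= 0:
            raise ConfigurationError(
                "toe-end force already exceeds the linear-region end force; "
                "shorten toe_span or raise the first peak"
            )
        return span

    def toe_parameters(self) -> tuple[float, float, float]:
        """(c, d0, F_toe_end) of the quadratic toe F(d) = c (d + d0)^2.

        The quadratic is anchored so that F(0) equals the preload and its
        slope reaches the true stiffness exactly at the toe end, joining
        the linear segment with continuous value and slope.
        """
        k, p0, t = self.stiffness_true, self.preload, self.toe_span
        if t == 0.0:
            return 0.0, 0.0, p0
        d0 = (p0 + math.sqrt(p0 * p0 + 2.0 * k * p0 * t)) / k
        c = k / (2.0 * (t + d0))
        return c, d0, c * (t + d0) ** 2

    def linear_range_true(self) -> tuple[float, float]:
        """True linear window as (strain_lo %, strain_hi %)."""
        g = self.gauge_length
        return (100.0 * self.toe_span / g,
                100.0 * (self.toe_span + self.resolved_linear_span()) / g)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    return x * x * (3.0 - 2.0 * x)


def _hermite(x: np.ndarray, span: float, f0: float, f1: float,
             m0: float, m1: float) -> np.ndarray:
    """Cubic Hermite on [0, span] with endpoint values and slopes."""
    s = x / span
    h00 = (1 + 2 * s) * (1 - s) ** 2
    h10 = s * (1 - s) ** 2
    h01 = s * s * (3 - 2 * s)
    h11 = s * s * (s - 1)
    return h00 * f0 + h10 * span * m0 + h01 * f1 + h11 * span * m1


def make_tensile_curve(truth: TensileTruth, sample_step_mm: float = 0.005) -> TensileCurve:
    """Sample a biphasic (or degenerate monophasic) failure curve.

    Shape, in displacement order: a concave quadratic toe over
    ``toe_span`` (most of the physiological toe is assumed taken out by
    the preload); a linear segment of slope ``stiffness_true``; a C1
    softening limb (cubic Hermite, slope decaying from the stiffness to
    zero) up to the first fibre-failure peak ``first_peak_force_true``,
    followed by a 20 % drop; a smooth rise to the global maximum
    ``ultimate_force_true`` at ``gauge_length * ultimate_strain_true /
    100``; and a terminal drop well below the 95 %-of-maximum stopping
    level.  When the first peak equals the ultimate force the curve is
    monophasic: one smooth rise to a single peak.  Gaussian noise of sd
    ``noise_sd`` is added to force with the declared seed, so identical
    truths yield identical curves.
    """
    if not sample_step_mm > 0:
        raise ValidationError("sample_step_mm must be positive")
    k = truth.stiffness_true
    fu = truth.ultimate_force_true
    t = truth.toe_span
    c, d0, f_t = truth.toe_parameters()
    du = truth.gauge_length * truth.ultimate_strain_true / 100.0
    if du <= t:
        raise ConfigurationError(
            "ultimate strain places the global peak inside the toe region"
        )
    step = sample_step_mm
    linear_span = truth.resolved_linear_span()
    dl = t + linear_span  # end of the linear segment
    f_l = f_t + k * linear_span
    if du <= dl + 6.0 * step:
        raise ConfigurationError(
            "ultimate strain leaves no room past the linear region"
        )
    if fu <= f_l:
        raise ConfigurationError(
            "peak forces must exceed the force at the end of the linear region"
        )
    f1 = fu if truth.is_monophasic else truth.first_peak_force_true
    if f1 <= f_l:
        raise ConfigurationError(
            "first peak force lies below the end of the linear region"
        )
    if truth.is_monophasic:
        d1 = d2 = du
        f_valley = fu
    else:
        # softening limb reaches the first peak at a mean slope of
        # softening_fraction * stiffness
        d1 = dl + (f1 - f_l) / (truth.softening_fraction * k)
        d2 = d1 + min(3.0 * step, 0.25 * max(du - d1, 0.0))  # fibre-failure drop
        f_valley = 0.8 * f1  # >= 10 % relative drop after the first peak
        if du <= d2 + 3.0 * step:
            raise ConfigurationError(
                "ultimate strain leaves no room for the post-first-peak rise"
            )
    if k * (d1 - dl) > 3.0 * (f1 - f_l):
        # the cubic joining segment would overshoot the declared peak
        raise ConfigurationError(
            "first peak force too close to the linear-region end force"
        )
    d_end = du + max(5.0 * step, 0.05 * du)
    f_end = 0.35 * fu  # far below the 95 % stopping criterion

    d = np.arange(0.0, d_end + 0.5 * step, step)
    f = np.empty_like(d)
    toe = d <= t
    f[toe] = truth.preload if t == 0.0 else c * (d[toe] + d0) ** 2
    lin = (d > t) & (d <= dl)
    f[lin] = f_t + k * (d[lin] - t)
    rise1 = (d > dl) & (d <= d1)
    f[rise1] = _hermite(d[rise1] - dl, d1 - dl, f_l, f1, k, 0.0)
    if not truth.is_monophasic:
        drop = (d > d1) & (d <= d2)
        f[drop] = f1 + (f_valley - f1) * (d[drop] - d1) / (d2 - d1)
        rise2 = (d > d2) & (d <= du)
        # concave re-engagement of the main bundle: steep start, smooth
        # saturation into the ultimate peak
        mean_m = (fu - f_valley) / (du - d2)
        f[rise2] = _hermite(d[rise2] - d2, du - d2, f_valley, fu, 1.2 * mean_m, 0.0)
    tail = d > du
    f[tail] = fu + (f_end - fu) * (d[tail] - du) / (d_end - du)

    # pin the named extremes (and the preload start) to exact sample values
    f[0] = truth.preload
    i1 = int(np.argmin(np.abs(d - d1)))
    iu = int(np.argmin(np.abs(d - du)))
    f[i1] = f1
    f[iu] = fu

    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        f = f + rng.normal(0.0, truth.noise_sd, size=f.shape)
    return TensileCurve(
        displacement=d,
        force=f,
        gauge_length=truth.gauge_length,
        specimen_id=truth.specimen_id,
        ligament_id=truth.ligament_id,
    )


def sample_phantom_truths(n: int, seed: int) -> list[PhantomTruth]:
    """Draw *n* randomized phantom truths at the magnitudes of the
    cadaveric study, in random rigid orientations.

    Bone lengths, interosseous gap, axial offset, attachment spans
    (jittered around the published percentages while keeping the fibre
    rails strictly ordered), thickness fields (constants or ramps in the
    published 2-7 mm range) and the DOAC fan-out angle (around the
    published -18.7 deg) all vary; draws whose rails would overlap or
    whose angle-derived attachments leave the ulna are rejected and
    redrawn.
    """
    rng = np.random.default_rng(seed)
    out: list[PhantomTruth] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 100 * n:
            raise ConfigurationError("phantom truth sampling failed to converge")

        def thickness():
            if rng.random() < 0.5:
                return float(rng.uniform(2.0, 7.0))
            lo, hi = np.sort(rng.uniform(2.0, 7.0, size=2))
            return (float(lo), float(hi))

        def jitter(span, amount=2.0):
            d, p = span
            d = d + rng.uniform(-amount, amount)
            p = p + rng.uniform(-amount, amount)
            if p - d < 3.0:
                p = d + 3.0
            return (float(d), float(p))

        try:
            truth = PhantomTruth(
                radius_length=float(rng.uniform(230.0, 275.0)),
                ulna_length=float(rng.uniform(244.0, 291.0)),
                radius_radius=float(rng.uniform(8.0, 10.0)),
                ulna_radius=float(rng.uniform(7.0, 9.0)),
                gap=float(rng.uniform(14.0, 20.0)),
                ulna_distal_offset=float(rng.uniform(-8.0, 0.0)),
                ligaments=[
                    LigamentSpec("DOB", radius_span=jitter((10.0, 17.5)),
                                 ulna_span=jitter((11.0, 19.1)),
                                 thickness=thickness()),
                    LigamentSpec("AB", radius_span=jitter((40.0, 47.7)),
                                 ulna_span=jitter((21.3, 30.3)),
                                 thickness=thickness()),
                    LigamentSpec("CB", radius_span=jitter((51.7, 65.1)),
                                 ulna_span=jitter((32.9, 46.4)),
                                 thickness=thickness()),
                    LigamentSpec("DOAC",
                                 radius_span=float(rng.uniform(70.0, 76.0)),
                                 fan_out=float(rng.uniform(-25.0, -14.0)),
                                 thickness=thickness()),
                ],
                random_orientation=True,
            )
            truth.rails()  # reject overlapping/unordered configurations
        except (ConfigurationError, ValidationError):
            continue
        out.append(truth)
    return out


def sample_tensile_truths(
    n: int,
    seed: int,
    noise_fraction: float = 0.0,
    gauge_length: float = 250.0,
    monophasic_rate: float = 0.2,
) -> list[TensileTruth]:
    """Draw *n* internally consistent tensile truths spanning the
    magnitudes of the cadaveric study (ultimate forces ~45-330 N,
    ultimate strains ~1.3-6.2 %, stiffness ~20-160 N/mm).

    Real curves couple their parameters — a stiff ligament cannot reach
    a large ultimate strain with a short re-engagement limb — so the
    sampler draws the curve *shape* first (toe, linear, softening and
    re-engagement spans as fractions of the displacement at failure)
    together with target force/strain magnitudes, and derives the
    stiffness from them.  ``noise_fraction`` sets the Gaussian force
    noise as a fraction of each curve's ultimate force.
    """
    rng = np.random.default_rng(seed)
    out: list[TensileTruth] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 50 * n:
            raise ConfigurationError("tensile truth sampling failed to converge")
        eu = rng.uniform(1.3, 6.2)
        fu_target = rng.uniform(45.0, 330.0)
        du = gauge_length * eu / 100.0
        t = 0.5
        avail = du - t
        sf = 0.4
        mono = rng.random() < monophasic_rate
        lin = (rng.uniform(0.35, 0.5) if mono else rng.uniform(0.25, 0.45)) * avail
        try:
            if mono:
                mu = rng.uniform(0.35, 0.5)
                k = (fu_target - 0.5) / (0.25 + lin + mu * (avail - lin))
                probe = TensileTruth(
                    stiffness_true=k, first_peak_force_true=1.0,
                    ultimate_force_true=1.0, ultimate_strain_true=eu,
                    toe_span=t, linear_span=lin, gauge_length=gauge_length,
                )
                _, _, f_t = probe.toe_parameters()
                f1 = fu = f_t + k * lin + mu * k * (avail - lin)
            else:
                soft = rng.uniform(0.10, 0.20) * avail
                rise = avail - lin - soft
                mu = rng.uniform(0.3, 0.55)
                k = (fu_target - 0.4) / (0.8 * (0.25 + lin + sf * soft) + mu * rise)
                probe = TensileTruth(
                    stiffness_true=k, first_peak_force_true=1.0,
                    ultimate_force_true=1.0, ultimate_strain_true=eu,
                    toe_span=t, linear_span=lin, gauge_length=gauge_length,
                )
                _, _, f_t = probe.toe_parameters()
                f1 = f_t + k * lin + sf * k * soft
                fu = 0.8 * f1 + mu * k * rise
                if fu <= f1 * 1.02:
                    continue
            truth = TensileTruth(
                stiffness_true=k,
                first_peak_force_true=f1,
                ultimate_force_true=fu,
                ultimate_strain_true=eu,
                toe_span=t,
                linear_span=lin,
                softening_fraction=sf,
                gauge_length=gauge_length,
                noise_sd=noise_fraction * fu,
                seed=int(rng.integers(2**31)),
            )
            make_tensile_curve(truth)  # reject unbuildable configurations
        except (ConfigurationError, ValidationError):
            continue
        out.append(truth)
    return out
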