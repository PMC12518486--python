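"""Synthetic radius-like mesh populations with known ground truth.

Clinical CT segmentations of the radius are not publicly deposited, so the
package ships a generator that emulates the relevant *statistical* structure
of such a dataset: ~100 tube-like bones dominated by a handful of smooth
shape modes (length, bowing, distal tilt/inclination, distal width, head
size) plus fine Gaussian surface noise, with exact latent coefficients,
landmarks and correspondence known by construction.  Every downstream stage
— correspondence, GPA, PCA, completion, 6-DOF evaluation — is tested
against this ground truth.

The template is a closed, outward-oriented surface of revolution-like grid:
a proximal head bulge at Y=0, a shaft, and a flared distal end, with the
long axis on +Y (the canonical anatomical frame).  Landmarks are actual
template vertices, so they ride along exactly under any deformation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import ValidationError
from .frame import LandmarkSet
from .geometry import SurfaceQuery
from .mesh import TriangleMesh, cut_by_length_fraction, write_mesh


@dataclass(frozen=True)
class ShapeMode:
    """One generative shape mode: a smooth per-vertex displacement field.

    ``displacement`` has unit RMS norm (sqrt of the mean squared vertex
    displacement is 1), so ``sd_mm`` is the population standard deviation of
    per-vertex RMS displacement in mm.
    """

    name: str
    displacement: np.ndarray
    sd_mm: float

    def __post_init__(self) -> None:
        d = np.asarray(self.displacement, dtype=np.float64)
        rms = float(np.sqrt((d ** 2).sum(axis=1).mean()))
        if not np.isclose(rms, 1.0, rtol=1e-9):
            raise ValidationError(f"mode {self.name!r} displacement RMS is {rms}, not 1")
        object.__setattr__(self, "displacement", d)


def _unit_rms(d: np.ndarray) -> np.ndarray:
    rms = np.sqrt((d ** 2).sum(axis=1).mean())
    if rms < 1e-15:
        raise ValidationError("degenerate (zero) mode displacement field")
    return d / rms


@dataclass
class SyntheticPopulation:
    """A generated population of corresponded bone-like meshes."""

    meshes: list[TriangleMesh]
    latents: np.ndarray                      # (n_shapes, n_modes), standard normal
    landmarks: list[LandmarkSet]
    modes: list[ShapeMode]
    template: TriangleMesh
    landmark_indices: dict[str, int]
    noise_sd_mm: float
    seed: int

    @property
    def n_shapes(self) -> int:
        return len(self.meshes)

    def write(self, out_dir: str | Path) -> Path:
        """Write PLY meshes plus latents and landmarks CSV files."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, m in enumerate(self.meshes):
            write_mesh(m, out / f"shape_{i:03d}.ply")
        header = ",".join(mode.name for mode in self.modes)
        np.savetxt(out / "latents.csv", self.latents, delimiter=",",
                   header=header, comments="")
        with open(out / "landmarks.csv", "w") as fh:
            fh.write("shape,name,x,y,z\n")
            for i, lm in enumerate(self.landmarks):
                for name in ("head_center", "ridge_midpoint", "notch_point"):
                    p = getattr(lm, name)
                    fh.write(f"{i},{name},{p[0]!r},{p[1]!r},{p[2]!r}\n")
        return out


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

def _grid_sizes(n_vertices: int, length: float, mean_radius: float) -> tuple[int, int]:
    # near-isotropic grid: row spacing ~ circumferential spacing
    interior = n_vertices - 2
    aspect = length / (2.0 * np.pi * mean_radius)
    n_theta = int(round(np.sqrt(interior / aspect) / 4.0)) * 4
    n_theta = max(8, n_theta)
    n_rows = max(3, interior // n_theta)
    return n_rows, n_theta


def make_template(n_vertices: int = 2000, length_mm: float = 240.0,
                  shaft_radius_mm: float = 8.0, head_radius_mm: float = 11.0,
                  distal_width_mm: float = 30.0
                  ) -> tuple[TriangleMesh, LandmarkSet, dict[str, int]]:
    """Build the canonical bone-like template mesh.

    Returns ``(mesh, landmarks, landmark_vertex_indices)``.  The mesh is a
    closed 2-manifold spanning exactly Y in [0, length_mm], with the head
    bulge proximal (Y=0 end), the distal end flared to ``distal_width_mm``
    across Z, a ridge landmark at the distal pole and a notch-direction
    landmark on the +Z side near the distal end.
    """
    for name, v in (("n_vertices", n_vertices), ("length_mm", length_mm),
                    ("shaft_radius_mm", shaft_radius_mm),
                    ("head_radius_mm", head_radius_mm),
                    ("distal_width_mm", distal_width_mm)):
        if v <= 0:
            raise ValidationError(f"{name} must be positive")
    if n_vertices < 200:
        raise ValidationError("n_vertices must be at least 200")
    if head_radius_mm >= length_mm:
        raise ValidationError("head radius must be smaller than bone length")
    if distal_width_mm >= length_mm:
        raise ValidationError("distal width must be smaller than bone length")

    L = float(length_mm)
    n_rows, n_theta = _grid_sizes(n_vertices, L, shaft_radius_mm)
    y = L * (np.arange(1, n_rows + 1)) / (n_rows + 1)
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta

    # radial profile: shaft + proximal head bulge + distal flare (flare
    # widens the Z half-axis toward distal_width_mm/2 at the distal end)
    y_head = 1.2 * head_radius_mm
    head_w = 1.1 * head_radius_mm
    bulge = (head_radius_mm - shaft_radius_mm) * np.exp(-((y - y_head) / head_w) ** 2)
    s = np.clip((y - 0.80 * L) / (0.20 * L), 0.0, 1.0)
    smooth = s * s * (3.0 - 2.0 * s)
    flare = (0.5 * distal_width_mm - shaft_radius_mm) * smooth
    r_x = shaft_radius_mm + bulge + 0.25 * flare
    r_z = shaft_radius_mm + bulge + flare
    # closed rounded caps: radius tapers to zero at both poles
    u = 2.0 * y / L - 1.0
    cap = np.sqrt(np.clip(1.0 - u ** 16, 0.0, None))
    r_x = r_x * cap
    r_z = r_z * cap

    ct, st = np.cos(theta), np.sin(theta)
    # interosseous crest: a sharp longitudinal ridge on the -X (ulnar)
    # side whose amplitude swells over the mid-shaft; it anchors axial
    # rotation and longitudinal position the way the real border does
    d_theta = np.angle(np.exp(1j * (theta - np.pi)))
    crest_az = np.exp(-(d_theta / 0.45) ** 2)
    crest_y = np.exp(-(((y / L) - 0.55) / 0.28) ** 2)
    crest = 0.35 * shaft_radius_mm * crest_y[:, None] * crest_az[None, :] * cap[:, None]
    # distal asymmetries: a radial styloid bump on the +X side and a
    # shallow sigmoid-notch concavity on the +Z side; they break the
    # two-fold symmetry of the distal end the way the real bone does,
    # which is what makes distal rigid registration unambiguous
    d_theta0 = np.angle(np.exp(1j * theta))
    styloid = 0.15 * distal_width_mm * \
        np.exp(-((y - 0.97 * L) / (0.05 * L)) ** 2)[:, None] * \
        np.exp(-(d_theta0 / 0.55) ** 2)[None, :] * cap[:, None]
    d_theta90 = np.angle(np.exp(1j * (theta - 0.5 * np.pi)))
    notch = -0.06 * distal_width_mm * \
        np.exp(-((y - 0.955 * L) / (0.035 * L)) ** 2)[:, None] * \
        np.exp(-(d_theta90 / 0.4) ** 2)[None, :] * cap[:, None]

    verts = np.empty((n_rows * n_theta + 2, 3))
    verts[0] = (0.0, 0.0, 0.0)            # proximal pole = head center
    verts[-1] = (0.0, L, 0.0)             # distal pole = ridge midpoint
    grid = verts[1:-1].reshape(n_rows, n_theta, 3)
    rad_x = r_x[:, None] + crest + styloid + notch
    rad_z = r_z[:, None] + crest + styloid + notch
    grid[:, :, 0] = rad_x * ct[None, :]
    grid[:, :, 1] = y[:, None]
    grid[:, :, 2] = rad_z * st[None, :]

    def vid(i: int, j: int) -> int:
        return 1 + i * n_theta + (j % n_theta)

    faces = []
    for j in range(n_theta):              # proximal fan
        faces.append((0, vid(0, j), vid(0, j + 1)))
    for i in range(n_rows - 1):           # quad strips
        for j in range(n_theta):
            a, b = vid(i, j), vid(i, j + 1)
            c, d = vid(i + 1, j), vid(i + 1, j + 1)
            faces.append((a, d, b))
            faces.append((a, c, d))
    last = len(verts) - 1
    for j in range(n_theta):              # distal fan
        faces.append((last, vid(n_rows - 1, j + 1), vid(n_rows - 1, j)))
    mesh = TriangleMesh(verts, np.asarray(faces, dtype=np.int64))
    if mesh.signed_volume() < 0:
        mesh = TriangleMesh(mesh.vertices, mesh.faces[:, [0, 2, 1]])

    notch_row = int(np.argmin(np.abs(y - 0.96 * L)))
    notch_col = n_theta // 4              # theta = pi/2 -> +Z side
    lm_idx = {"head_center": 0, "ridge_midpoint": len(verts) - 1,
              "notch_point": vid(notch_row, notch_col)}
    lms = LandmarkSet(verts[lm_idx["head_center"]].copy(),
                      verts[lm_idx["ridge_midpoint"]].copy(),
                      verts[lm_idx["notch_point"]].copy())
    return mesh, lms, lm_idx


# ---------------------------------------------------------------------------
# built-in shape modes
# ---------------------------------------------------------------------------

def _feather_weight(y: np.ndarray, extent: tuple[float, float],
                    cut_fraction: float = 0.88, feather: float = 0.05) -> np.ndarray:
    lo, hi = extent
    span = hi - lo
    cut = lo + cut_fraction * span
    return np.clip((y - (cut - feather * span)) / (feather * span), 0.0, 1.0)


def default_modes(template: TriangleMesh,
                  sd_mm: dict[str, float] | None = None) -> list[ShapeMode]:
    """The six built-in generative modes on a template.

    Distal modes are linearised rotations/scalings of the part beyond the
    88% cut, feathered over 5% of bone length, so 6-DOF ground truth is
    available in closed form.  Default standard deviations (mm, RMS
    displacement scale) reflect the dominant anatomical variation of a
    healthy adult radius population: length first, then bowing, then distal
    orientation and width, then head size.
    """
    v = template.vertices
    y = v[:, 1]
    lo, hi = float(y.min()), float(y.max())
    span = hi - lo
    w = _feather_weight(y, (lo, hi))
    cut_centroid = v[y > lo + 0.88 * span].mean(axis=0)
    rel = v - cut_centroid

    fields = {}
    d = np.zeros_like(v)
    d[:, 1] = (y - lo) / span
    fields["lengthening"] = d
    d = np.zeros_like(v)
    d[:, 0] = np.sin(np.pi * (y - lo) / span)
    fields["bowing"] = d
    # linearised rotation about X through the cut centroid (volar tilt)
    fields["distal_volar_tilt"] = w[:, None] * np.cross(
        np.array([1.0, 0.0, 0.0]), rel)
    # linearised rotation about Z through the cut centroid (radial inclination)
    fields["distal_radial_inclination"] = w[:, None] * np.cross(
        np.array([0.0, 0.0, 1.0]), rel)
    d = np.zeros_like(v)
    d[:, 2] = w * v[:, 2]
    fields["distal_width"] = d
    g = np.exp(-(((y - lo) - 0.05 * span) / (0.08 * span)) ** 2)
    d = np.zeros_like(v)
    radial = np.linalg.norm(v[:, [0, 2]], axis=1)
    safe = np.maximum(radial, 1e-9)
    d[:, 0] = g * v[:, 0] / safe
    d[:, 2] = g * v[:, 2] / safe
    fields["head_radius"] = d

    defaults = {"lengthening": 8.0, "bowing": 3.0, "distal_volar_tilt": 2.0,
                "distal_radial_inclination": 2.0, "distal_width": 2.0,
                "head_radius": 1.5}
    if sd_mm:
        defaults.update(sd_mm)
    return [ShapeMode(name, _unit_rms(fields[name]), defaults[name])
            for name in fields]


def generate_population(template: TriangleMesh, modes: list[ShapeMode],
                        n_shapes: int, noise_sd_mm: float, seed: int,
                        landmark_indices: dict[str, int] | None = None
                        ) -> SyntheticPopulation:
    """Draw a population: template + sum_k c_k sd_k mode_k + Gaussian noise.

    Latents ``c`` are standard normal — the SSM's own generative assumption
    — and are stored for ground-truth checks.  A seed is mandatory; the same
    seed reproduces vertex arrays bit-for-bit.
    """
    if seed is None:
        raise ValidationError("a seed is required: population draws must be reproducible")
    if n_shapes < 2:
        raise ValidationError("need at least 2 shapes")
    if not modes:
        raise ValidationError("need at least one shape mode")
    if noise_sd_mm < 0:
        raise ValidationError("noise_sd_mm must be >= 0")
    rng = np.random.default_rng(seed)
    latents = rng.standard_normal((n_shapes, len(modes)))
    if landmark_indices is None:
        landmark_indices = {}
    meshes, lms = [], []
    for i in range(n_shapes):
        verts = template.vertices.copy()
        for k, mode in enumerate(modes):
            verts += latents[i, k] * mode.sd_mm * mode.displacement
        if noise_sd_mm > 0:
            verts += rng.normal(0.0, noise_sd_mm, size=verts.shape)
        meshes.append(TriangleMesh(verts, template.faces))
        if landmark_indices:
            lms.append(LandmarkSet(verts[landmark_indices["head_center"]].copy(),
                                   verts[landmark_indices["ridge_midpoint"]].copy(),
                                   verts[landmark_indices["notch_point"]].copy()))
        else:
            lms.append(LandmarkSet(verts[0], verts[-1], verts[len(verts) // 2]))
    return SyntheticPopulation(meshes, latents, lms, list(modes), template,
                               dict(landmark_indices), noise_sd_mm, seed)


# ---------------------------------------------------------------------------
# topology-independent copies and exact distal transforms
# ---------------------------------------------------------------------------

def remesh_copy(mesh: TriangleMesh, target_vertex_count: int, seed: int
                ) -> TriangleMesh:
    """Resample a tube-like mesh onto fresh, unrelated connectivity.

    A new cylindrical grid (seed-jittered in angle and row placement) is
    laid over the shape and every new vertex is projected exactly onto the
    input surface, so the one-sided distance to the input is numerically
    zero while the face list shares nothing with the input.  This gives the
    correspondence stage genuinely re-meshed inputs to chew on, mimicking
    independent segmentations.
    """
    rng = np.random.default_rng(seed)
    y = mesh.vertices[:, 1]
    lo, hi = float(y.min()), float(y.max())
    n_rows, n_theta = _grid_sizes(target_vertex_count, hi - lo, 9.0)
    n_theta += 4 * int(rng.integers(0, 2))        # vary the grid shape per seed
    n_rows = max(3, (target_vertex_count - 2) // n_theta)
    offset = rng.uniform(0.0, 2.0 * np.pi)
    jitter = rng.uniform(-0.3, 0.3, size=n_rows)
    rows = (np.arange(1, n_rows + 1) + jitter) / (n_rows + 1)
    yy = lo + (hi - lo) * rows
    theta = offset + 2.0 * np.pi * np.arange(n_theta) / n_theta

    # initial guess: per-row median radial extent, then exact projection
    rad = np.linalg.norm(mesh.vertices[:, [0, 2]], axis=1)
    order = np.argsort(y)
    r_guess = np.interp(yy, y[order], rad[order])
    guess = np.empty((n_rows * n_theta + 2, 3))
    guess[0] = (0.0, lo, 0.0)
    guess[-1] = (0.0, hi, 0.0)
    g = guess[1:-1].reshape(n_rows, n_theta, 3)
    g[:, :, 0] = r_guess[:, None] * np.cos(theta)[None, :]
    g[:, :, 1] = yy[:, None]
    g[:, :, 2] = r_guess[:, None] * np.sin(theta)[None, :]
    projected, _, _ = SurfaceQuery(mesh).query(guess)

    def vid(i: int, j: int) -> int:
        return 1 + i * n_theta + (j % n_theta)

    faces = []
    for j in range(n_theta):
        faces.append((0, vid(0, j), vid(0, j + 1)))
    for i in range(n_rows - 1):
        for j in range(n_theta):
            a, b = vid(i, j), vid(i, j + 1)
            c, d = vid(i + 1, j), vid(i + 1, j + 1)
            faces.append((a, d, b))
            faces.append((a, c, d))
    last = len(projected) - 1
    for j in range(n_theta):
        faces.append((last, vid(n_rows - 1, j + 1), vid(n_rows - 1, j)))
    return TriangleMesh(projected, np.asarray(faces, dtype=np.int64))


def apply_distal_rotation(mesh: TriangleMesh, angle_deg: float, axis: str = "z",
                          fraction: float = 0.88, feather: float = 0.05
                          ) -> TriangleMesh:
    """Rigidly rotate the distal segment by an exact, known angle.

    Vertices beyond the cut rotate by the full ``angle_deg`` about the given
    frame axis through the distal-segment centroid; the rotation angle is
    feathered to zero over ``feather`` of the bone length below the cut.
    Used to manufacture 6-DOF ground truth for the clinical metrics.
    """
    axes = {"x": np.array([1.0, 0.0, 0.0]), "y": np.array([0.0, 1.0, 0.0]),
            "z": np.array([0.0, 0.0, 1.0])}
    if axis not in axes:
        raise ValidationError(f"axis must be one of {sorted(axes)}")
    v = mesh.vertices.copy()
    y = v[:, 1]
    lo, hi = float(y.min()), float(y.max())
    w = _feather_weight(y, (lo, hi), fraction, feather)
    _, dist = cut_by_length_fraction(mesh, fraction)
    pivot = v[dist.indices].mean(axis=0)
    k = axes[axis]
    ang = np.deg2rad(angle_deg) * w
    rel = v - pivot
    # per-vertex Rodrigues rotation by the feathered angle; vertices with
    # zero weight are left bitwise untouched
    cosa, sina = np.cos(ang)[:, None], np.sin(ang)[:, None]
    kxr = np.cross(k, rel)
    kdotr = rel @ k
    rot = rel * cosa + kxr * sina + np.outer(kdotr * (1.0 - cosa.ravel()), k)
    out = np.where((w > 0)[:, None], pivot + rot, v)
    return TriangleMesh(out, mesh.faces.copy())


def apply_distal_translation(mesh: TriangleMesh, delta: np.ndarray,
                             fraction: float = 0.88, feather: float = 0.05
                             ) -> TriangleMesh:
    """Translate the distal segment by an exact, known offset (feathered)."""
    v = mesh.vertices.copy()
    y = v[:, 1]
    w = _feather_weight(y, (float(y.min()), float(y.max())), fraction, feather)
    return TriangleMesh(v + w[:, None] * np.asarray(delta, dtype=np.float64),
                        mesh.faces.copy())
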