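"""Layered-sphere head phantom and labeled tetrahedral mesh handling.

The phantom is a nested-conductor head: concentric spherical shells
(scalp / skull / CSF / brain by default) meshed with linear tetrahedra.
Nodes are laid out on Fibonacci lattices on every tissue interface plus
interior filling shells, tetrahedralised with a Delaunay triangulation,
and labeled by centroid radius.  Sponge electrodes are added as radially
extruded spherical-cap cylinders whose distal faces later carry the
Dirichlet boundary conditions of the forward solver.

All coordinates are millimetres; the forward solver converts to SI.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

from .errors import PlacementError, ResolutionError, ValidationError
from .layouts import ElectrodeLayout

#: Tissue conductivities in S/m for the isotropic quasi-static model.
DEFAULT_CONDUCTIVITIES = {
    "scalp": 0.25,
    "skull": 0.015,
    "csf": 1.79,
    "grey": 0.276,
    "white": 0.126,
    "electrode": 5.21,
}

DEFAULT_LAYER_RADII = (92.0, 88.0, 83.0, 80.0)
DEFAULT_LAYER_LABELS = ("scalp", "skull", "csf", "brain")


@dataclass
class TissueTable:
    """Label -> conductivity (S/m) map."""

    conductivity: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDUCTIVITIES)
    )

    def __post_init__(self) -> None:
        for name, sigma in self.conductivity.items():
            if not sigma > 0:
                raise ValidationError(f"conductivity of {name!r} must be > 0")
        # The single-compartment phantom brain uses grey-matter conductivity.
        self.conductivity.setdefault("brain", self.conductivity.get("grey", 0.276))

    def __getitem__(self, label: str) -> float:
        try:
            return self.conductivity[label]
        except KeyError:
            raise ValidationError(f"no conductivity for tissue {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self.conductivity


@dataclass
class TetrahedralMesh:
    """Labeled tetrahedral volume mesh.

    ``nodes`` are (n, 3) coordinates in mm; ``tets`` are (m, 4) node
    indices with positive signed volume; ``tet_label`` holds an integer
    label per tet resolved through ``label_names``.
    """

    nodes: np.ndarray
    tets: np.ndarray
    tet_label: np.ndarray
    label_names: dict[int, str]
    electrode_nodes: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.tet_label = np.ascontiguousarray(self.tet_label, dtype=np.int64)

    # ------------------------------------------------------------ queries
    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_tets(self) -> int:
        return self.tets.shape[0]

    def label_id(self, name: str) -> int:
        for lid, lname in self.label_names.items():
            if lname == name:
                return lid
        raise ValidationError(f"label {name!r} not present in mesh")

    def labels_present(self) -> set[str]:
        return {self.label_names[i] for i in np.unique(self.tet_label)}

    def tet_volumes(self) -> np.ndarray:
        """Signed volumes in mm^3 (positive under the storage convention)."""
        p = self.nodes[self.tets]
        a, b, c = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def tet_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def label_volume(self, name: str) -> float:
        mask = self.tet_label == self.label_id(name)
        return float(self.tet_volumes()[mask].sum())

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.nodes).tobytes())
        h.update(np.ascontiguousarray(self.tets).tobytes())
        h.update(np.ascontiguousarray(self.tet_label).tobytes())
        return h.hexdigest()[:16]

    def validate(self) -> None:
        """Raise ValidationError on inverted tets, orphan nodes or
        out-of-range indices."""
        if self.tets.min(initial=0) < 0 or self.tets.max(initial=-1) >= self.n_nodes:
            raise ValidationError("tet node index out of range")
        vols = self.tet_volumes()
        if np.any(vols <= 0):
            bad = int(np.argmin(vols))
            raise ValidationError(f"non-positive tet volume at tet {bad}")
        used = np.zeros(self.n_nodes, dtype=bool)
        used[self.tets.ravel()] = True
        if not used.all():
            raise ValidationError(f"{int((~used).sum())} orphan node(s)")
        unknown = set(np.unique(self.tet_label)) - set(self.label_names)
        if unknown:
            raise ValidationError(f"tet labels without names: {sorted(unknown)}")


@dataclass
class CorticalSurface:
    """Triangulated outer boundary of the cortical compartment.

    One "cortical element" per triangle: the forward solver samples the
    owning tet's field on it and projects onto the outward unit normal.
    """

    triangles: np.ndarray  # (t, 3) node indices into the parent mesh
    normals: np.ndarray  # (t, 3) outward unit normals
    areas: np.ndarray  # (t,) mm^2
    centroids: np.ndarray  # (t, 3) mm
    owner_tet: np.ndarray  # (t,) tet index owning each triangle
    mesh_hash: str = ""

    @property
    def n_elements(self) -> int:
        return self.triangles.shape[0]

    def total_area(self) -> float:
        return float(self.areas.sum())


@dataclass
class RoiPatch:
    """Set of cortical elements carrying one amplitude/phase target."""

    name: str
    elements: np.ndarray  # indices into the cortical surface
    definition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.elements = np.unique(np.asarray(self.elements, dtype=np.int64))
        if self.elements.size == 0:
            raise ValidationError(f"ROI {self.name!r} is empty")

    def __len__(self) -> int:
        return self.elements.size


# ----------------------------------------------------------------- phantom
def _fibonacci_sphere(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """n near-uniform points on a sphere, randomly rotated (seeded) to
    avoid symmetric degeneracies in the Delaunay step."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    # random rotation: QR of a seeded Gaussian matrix
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return radius * pts @ q.T


def _shell_node_count(radius: float, edge: float) -> int:
    # area per vertex of an equilateral lattice with spacing `edge`
    return int(round(4.0 * np.pi * radius**2 / (np.sqrt(3.0) / 2.0 * edge**2)))


def build_layered_sphere(
    layer_radii=DEFAULT_LAYER_RADII,
    labels=None,
    target_edge_length: float = 8.0,
    seed: int = 0,
) -> TetrahedralMesh:
    """Concentric labeled sphere phantom.

    ``layer_radii`` are outer radii in mm, strictly decreasing outside-in;
    layer i occupies radii (layer_radii[i+1], layer_radii[i]], the last
    layer fills the innermost ball.  ``target_edge_length`` sets the
    tangential node spacing; every interface receives its own node shell,
    so each layer is resolved radially regardless of its thickness.
    Deterministic for a fixed seed.
    """
    radii = [float(r) for r in np.atleast_1d(np.asarray(layer_radii, dtype=float))]
    if len(radii) < 1:
        raise ValidationError("need at least one layer radius")
    if any(b >= a for a, b in zip(radii, radii[1:])):
        raise ValidationError("layer radii must be strictly decreasing")
    if labels is None:
        labels = list(DEFAULT_LAYER_LABELS[: len(radii)])
        if len(labels) < len(radii):
            labels += [f"layer{i}" for i in range(len(labels), len(radii))]
    labels = list(labels)
    if len(labels) != len(radii):
        raise ValidationError("labels must match layer_radii in length")
    h = float(target_edge_length)
    if h <= 0:
        raise ValidationError("target_edge_length must be positive")
    if _shell_node_count(radii[-1], h) < 32:
        raise ResolutionError(
            f"edge length {h} mm too coarse to resolve a layer of radius "
            f"{radii[-1]} mm"
        )

    rng = np.random.default_rng(seed)
    shells: list[np.ndarray] = []
    # node shells: every interface, intermediate shells in thick layers,
    # and a filling of the innermost ball
    interface_radii: list[float] = []
    for i, r in enumerate(radii):
        interface_radii.append(r)
        nxt = radii[i + 1] if i + 1 < len(radii) else None
        if nxt is not None:
            gap = r - nxt
            k = int(np.floor(gap / h))
            for j in range(1, k + 1):
                interface_radii.append(r - j * gap / (k + 1))
    # interface shells share one direction lattice so that nodes stack
    # into radial columns: thin layers then mesh into clean prism-like
    # tets instead of leaking across layer boundaries
    n_if = max(32, _shell_node_count(radii[0], h))
    dirs = _fibonacci_sphere(n_if, 1.0, rng)
    for sr in interface_radii:
        jitter = 1.0 + 1e-4 * rng.standard_normal(n_if)
        shells.append(dirs * (sr * jitter)[:, None])
    # interior filling of the innermost ball, independent lattices
    r = radii[-1] - h
    while r > 0.6 * h:
        n = max(32, _shell_node_count(r, h))
        pts = _fibonacci_sphere(n, r, rng)
        jitter = 1.0 + 1e-4 * rng.standard_normal(n)
        shells.append(pts * jitter[:, None])
        r -= h
    shells.append(np.zeros((1, 3)))
    nodes = np.vstack(shells)

    tri = Delaunay(nodes)
    tets = np.asarray(tri.simplices, dtype=np.int64)
    mesh = _label_and_clean(nodes, tets, radii, labels)
    mesh.metadata.update(
        {
            "kind": "layered_sphere",
            "layer_radii": radii,
            "layer_labels": labels,
            "target_edge_length": h,
            "seed": int(seed),
        }
    )
    return mesh


def _label_by_radius(centroid_r: np.ndarray, radii: list[float]) -> np.ndarray:
    """Layer index per centroid radius: layer i covers (radii[i+1], radii[i]]."""
    bounds = np.array(radii[1:])  # inner boundaries of layers 0..k-2
    return np.searchsorted(-bounds, -centroid_r, side="left").astype(np.int64)


def _label_and_clean(nodes, tets, radii, labels) -> TetrahedralMesh:
    p = nodes[tets]
    a, b, c = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]
    vols = np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0
    # orient positively
    neg = vols < 0
    tets = tets.copy()
    tets[neg, 0], tets[neg, 1] = tets[neg, 1].copy(), tets[neg, 0].copy()
    vols = np.abs(vols)
    keep = vols > 1e-7 * np.median(vols)
    tets, vols = tets[keep], vols[keep]
    centroids = nodes[tets].mean(axis=1)
    cr = np.linalg.norm(centroids, axis=1)
    lab = _label_by_radius(cr, radii)
    keep = cr <= radii[0]  # defensive: drop anything outside the outer sphere
    tets, lab = tets[keep], lab[keep]
    # drop orphan nodes and remap
    used = np.zeros(nodes.shape[0], dtype=bool)
    used[tets.ravel()] = True
    remap = -np.ones(nodes.shape[0], dtype=np.int64)
    remap[used] = np.arange(int(used.sum()))
    mesh = TetrahedralMesh(
        nodes[used],
        remap[tets],
        lab,
        {i: name for i, name in enumerate(labels)},
    )
    mesh.validate()
    return mesh


# --------------------------------------------------------------- electrodes
def _electrode_points(
    direction: np.ndarray,
    scalp_radius: float,
    disc_radius: float,
    height: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Node cloud of one sponge electrode: spherical-cap discs extruded
    radially from the scalp surface, plus refinement nodes under the
    footprint.  Returns (points, distal-face point indices)."""
    u = direction / np.linalg.norm(direction)
    # orthonormal frame
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    ring_radii = [0.0, 0.5 * disc_radius, disc_radius]
    ring_counts = [1, 6, 12]
    n_levels = max(4, int(np.ceil(height / disc_radius)) + 1)
    levels = scalp_radius + np.linspace(0.0, height, n_levels)

    def cap(R: float, a: float, m: int, az0: float) -> list[np.ndarray]:
        alpha = a / R  # constant lateral extent: true cylinder
        out = []
        for k in range(max(1, m)):
            az = 2.0 * np.pi * k / max(1, m) + az0
            d = np.cos(alpha) * u + np.sin(alpha) * (
                np.cos(az) * e1 + np.sin(az) * e2
            )
            out.append(R * d)
        return out

    pts: list[np.ndarray] = []
    for R in levels:
        for a, m in zip(ring_radii, ring_counts):
            pts.extend(cap(R, a, m, 0.25 if a > 0 else 0.0))
    n_per_level = sum(ring_counts)
    distal = np.arange(len(pts) - n_per_level, len(pts))
    # local refinement under the footprint: the spreading resistance
    # concentrates there, so the scalp lattice alone is too coarse
    for depth, rads, cnts in (
        (0.45 * disc_radius, [0.0, 0.6 * disc_radius, 1.2 * disc_radius], [1, 6, 12]),
        (1.1 * disc_radius, [0.0, 0.9 * disc_radius], [1, 8]),
    ):
        for a, m in zip(rads, cnts):
            pts.extend(cap(scalp_radius - depth, a, m, 0.55))
    # skirt on the scalp surface around the footprint for graded transition
    pts.extend(cap(scalp_radius, 1.7 * disc_radius, 14, 0.1))
    return np.array(pts), distal


def place_electrodes(
    mesh: TetrahedralMesh,
    layout: ElectrodeLayout,
    electrode_label: str = "electrode",
) -> TetrahedralMesh:
    """Attach sponge electrodes to a layered-sphere phantom.

    The electrode bodies are meshed together with the head by a fresh
    Delaunay triangulation over the combined node cloud; tets are labeled
    by centroid (tissue by radius, electrode where the centroid falls in
    an electrode cylinder above the scalp) and air tets between bumps are
    discarded.  The distal-face node set of each electrode is recorded for
    the Dirichlet boundary conditions of the forward solver.
    """
    if len(layout) == 0:
        return mesh
    if "layer_radii" not in mesh.metadata:
        raise PlacementError(
            "electrode placement requires a layered-sphere phantom "
            "(meshes read from file must already contain electrodes)"
        )
    radii = [float(r) for r in mesh.metadata["layer_radii"]]
    r0 = radii[0]

    # overlap check on the scalp sphere (arc distance between footprints)
    dirs = layout.directions
    dots = np.clip(dirs @ dirs.T, -1.0, 1.0)
    arc = r0 * np.arccos(dots)
    rsum = layout.radii_mm[:, None] + layout.radii_mm[None, :]
    bad = (arc < rsum) & ~np.eye(len(layout), dtype=bool)
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise PlacementError(
            f"electrode footprints overlap: {layout.names[i]} / {layout.names[j]}"
        )

    all_pts = [mesh.nodes]
    distal_sets: dict[str, np.ndarray] = {}
    offset = mesh.n_nodes
    specs = []
    for name, u, a, hgt in layout:
        pts, distal = _electrode_points(u, r0, a, hgt)
        all_pts.append(pts)
        distal_sets[name] = offset + distal
        specs.append((u, a, hgt))
        offset += len(pts)
    nodes = np.vstack(all_pts)

    tri = Delaunay(nodes)
    tets = np.asarray(tri.simplices, dtype=np.int64)
    p = nodes[tets]
    aa, bb, cc = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]
    vols = np.einsum("ij,ij->i", aa, np.cross(bb, cc)) / 6.0
    neg = vols < 0
    tets[neg, 0], tets[neg, 1] = tets[neg, 1].copy(), tets[neg, 0].copy()
    vols = np.abs(vols)
    keep = vols > 1e-7 * np.median(vols)
    tets = tets[keep]

    centroids = nodes[tets].mean(axis=1)
    cr = np.linalg.norm(centroids, axis=1)
    lab = _label_by_radius(np.minimum(cr, r0), radii)
    elec_id = max(mesh.label_names) + 1
    outside = cr > r0 + 1e-9
    in_electrode = np.zeros(len(tets), dtype=bool)
    cdir = centroids / cr[:, None]
    for u, a, hgt in specs:
        cosang = cdir @ u
        lateral = cr * np.sqrt(np.maximum(0.0, 1.0 - cosang**2))
        inside = (
            (cosang > 0)
            & (lateral <= a * 1.15)
            & (cr <= r0 + hgt + 1e-6)
        )
        in_electrode |= inside
    lab[outside & in_electrode] = len(radii)  # temporary electrode index
    keep = ~outside | in_electrode
    tets, lab = tets[keep], lab[keep]

    label_names = dict(mesh.label_names)
    # map phantom layer index -> existing label ids (they coincide for the
    # generator, but go through names to stay robust)
    layer_labels = mesh.metadata["layer_labels"]
    id_of_layer = {i: mesh.label_id(name) for i, name in enumerate(layer_labels)}
    id_of_layer[len(radii)] = elec_id
    label_names[elec_id] = electrode_label
    lab = np.vectorize(id_of_layer.get)(lab).astype(np.int64)

    used = np.zeros(nodes.shape[0], dtype=bool)
    used[tets.ravel()] = True
    remap = -np.ones(nodes.shape[0], dtype=np.int64)
    remap[used] = np.arange(int(used.sum()))
    new_distal = {}
    for name, idx in distal_sets.items():
        kept = idx[used[idx]]
        if kept.size == 0:
            raise PlacementError(f"electrode {name!r} lost its distal face")
        new_distal[name] = remap[kept]

    out = TetrahedralMesh(
        nodes[used],
        remap[tets],
        lab,
        label_names,
        electrode_nodes=new_distal,
        metadata=dict(mesh.metadata),
    )
    out.metadata["electrode_order"] = list(layout.names)
    out.validate()
    return out


# ------------------------------------------------------------------ surface
_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


def extract_cortical_surface(
    mesh: TetrahedralMesh,
    cortical_label: str = "brain",
    outer_label: str | None = None,
) -> CorticalSurface:
    """Outer boundary of the cortical compartment with outward normals.

    Triangles are faces of cortical tets whose neighbour is the outer
    tissue (CSF on the phantom) or the mesh boundary.  If ``outer_label``
    is omitted it is taken from the phantom layer ordering, or inferred
    when exactly one neighbouring tissue exists.
    """
    cid = mesh.label_id(cortical_label)
    if outer_label is None and "layer_labels" in mesh.metadata:
        layers = list(mesh.metadata["layer_labels"])
        if cortical_label in layers and layers.index(cortical_label) > 0:
            outer_label = layers[layers.index(cortical_label) - 1]

    tets, labels = mesh.tets, mesh.tet_label
    m = len(tets)
    flat = tets[:, _FACES].reshape(-1, 3)  # 4 faces per tet
    key = np.sort(flat, axis=1)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    skey = key[order]
    new = np.ones(len(skey), dtype=bool)
    new[1:] = np.any(skey[1:] != skey[:-1], axis=1)
    group = np.cumsum(new) - 1
    n_groups = int(group[-1]) + 1
    owner = np.repeat(np.arange(m), 4)[order]
    # each face appears once (boundary) or twice (interior)
    first = np.full(n_groups, -1, dtype=np.int64)
    second = np.full(n_groups, -1, dtype=np.int64)
    rows = np.arange(len(skey))
    first[group[new]] = rows[new]
    second[group[~new]] = rows[~new]
    t1 = owner[first]
    t2 = np.where(second >= 0, owner[np.maximum(second, 0)], -1)
    l1 = labels[t1]
    l2 = np.where(t2 >= 0, labels[np.maximum(t2, 0)], -1)

    side1 = l1 == cid  # cortical tet on side 1
    side2 = (l2 == cid) & (t2 >= 0)
    boundary = side1 ^ side2  # exactly one cortical side
    cort_tet = np.where(side1, t1, t2)
    other_lab = np.where(side1, l2, l1)  # -1 for mesh boundary
    cort_row = np.where(side1, first, second)

    sel = boundary.copy()
    if outer_label is not None:
        oid = mesh.label_id(outer_label)
        sel &= other_lab == oid
    else:
        neigh = set(np.unique(other_lab[boundary])) - {-1}
        if len(neigh) > 1:
            raise ValidationError(
                f"label {cortical_label!r} touches several tissues "
                f"({sorted(mesh.label_names[i] for i in neigh)}); "
                "pass outer_label explicitly"
            )
    if not np.any(sel):
        raise ValidationError(
            f"no boundary between {cortical_label!r} and {outer_label!r}"
        )
    triangles = flat[order][cort_row[sel]]
    owner_tet = cort_tet[sel]

    p = mesh.nodes[triangles]
    raw = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    areas = 0.5 * np.linalg.norm(raw, axis=1)
    normals = raw / (2.0 * areas[:, None])
    centroids = p.mean(axis=1)
    # orient outward: away from the owning cortical tet centroid
    tc = mesh.nodes[mesh.tets[owner_tet]].mean(axis=1)
    flip = np.einsum("ij,ij->i", normals, centroids - tc) < 0
    normals[flip] *= -1
    return CorticalSurface(
        triangles, normals, areas, centroids, owner_tet, mesh.content_hash()
    )


def define_roi_patch(
    surface: CorticalSurface,
    center_direction,
    angular_radius_deg: float,
    name: str,
) -> RoiPatch:
    """Geodesic-cap ROI: cortical elements whose centroid direction lies
    within ``angular_radius_deg`` of ``center_direction``."""
    if not 0.0 < angular_radius_deg <= 90.0:
        raise ValidationError("angular radius must be in (0, 90] degrees")
    u = np.asarray(center_direction, dtype=float)
    nu = np.linalg.norm(u)
    if nu == 0:
        raise ValidationError("zero centre direction")
    u = u / nu
    cdir = surface.centroids / np.linalg.norm(surface.centroids, axis=1)[:, None]
    cosang = cdir @ u
    idx = np.flatnonzero(cosang >= np.cos(np.deg2rad(angular_radius_deg)))
    if idx.size == 0:
        raise ValidationError(f"ROI {name!r} selects no cortical elements")
    return RoiPatch(
        name,
        idx,
        definition={
            "center": u.tolist(),
            "angular_radius_deg": float(angular_radius_deg),
        },
    )
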