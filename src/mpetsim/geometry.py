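"""Two-boundary tetrahedral domains the MPET solver runs on.

A :class:`LabeledMesh` is a tetrahedral volume enclosed between an outer
"cortical" surface and an inner "ventricular" surface, with the cortical
surface partitioned into four arterial perfusion territories (left/right
internal carotid, left/right vertebral supply) and elements labeled by
hemisphere.  Synthetic concentric spherical-shell meshes stand in for
subject geometry; Gmsh MSH 2.2 and legacy-VTK readers accept externally
produced meshes carrying the same labels.

Internal units are metres and indexing is 0-based; the MSH reader/writer
translates to the format's 1-based convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._vtk import VTK_TETRA, VTK_TRIANGLE, read_vtk, write_vtk

# boundary surface tags
CORTICAL = 1
VENTRICULAR = 2
# structured-box face tags (verification geometries)
XMIN, XMAX, YMIN, YMAX, ZMIN, ZMAX = 10, 11, 12, 13, 14, 15

TERRITORIES = ("ICA_L", "ICA_R", "VA_L", "VA_R")
NO_TERRITORY = -1
HEMI_L, HEMI_R, NO_HEMI = 0, 1, -1

_SURFACE_NAMES = {"cortical": CORTICAL, "ventricular": VENTRICULAR}


class MeshError(ValueError):
    """Raised for unreadable, mislabeled or ill-formed meshes."""


class LabelingError(MeshError):
    """Raised when a territory rule leaves cortical facets unlabeled."""


@dataclass
class LabeledMesh:
    """Tetrahedral mesh with tagged boundary facets and region labels."""

    nodes: np.ndarray            # (N, 3) float, metres
    tets: np.ndarray             # (M, 4) int
    boundary_facets: np.ndarray  # (F, 3) int
    facet_tag: np.ndarray        # (F,) int, CORTICAL/VENTRICULAR/...
    territory: np.ndarray = None   # (F,) int in {-1, 0..3}
    hemisphere: np.ndarray = None  # (M,) int in {-1, 0, 1}
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.boundary_facets = np.ascontiguousarray(self.boundary_facets,
                                                    dtype=np.int64)
        self.facet_tag = np.ascontiguousarray(self.facet_tag, dtype=np.int64)
        if self.territory is None:
            self.territory = np.full(len(self.boundary_facets), NO_TERRITORY,
                                     dtype=np.int64)
        else:
            self.territory = np.ascontiguousarray(self.territory,
                                                  dtype=np.int64)
        if self.hemisphere is None:
            self.hemisphere = np.full(len(self.tets), NO_HEMI, dtype=np.int64)
        else:
            self.hemisphere = np.ascontiguousarray(self.hemisphere,
                                                   dtype=np.int64)
        # canonical orientation: positive signed volumes
        vol = self._signed_volumes()
        flip = vol < 0
        if flip.any():
            self.tets[flip] = self.tets[flip][:, [0, 1, 3, 2]]
        self._cache.clear()

    # -- basic measures ----------------------------------------------------

    @property
    def n_nodes(self):
        return len(self.nodes)

    @property
    def n_elements(self):
        return len(self.tets)

    def _signed_volumes(self):
        x = self.nodes[self.tets]
        return np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0

    def tet_volumes(self):
        if "vol" not in self._cache:
            self._cache["vol"] = self._signed_volumes()
        return self._cache["vol"]

    def tet_centroids(self):
        return self.nodes[self.tets].mean(axis=1)

    def facet_areas(self):
        x = self.nodes[self.boundary_facets]
        n = np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
        return 0.5 * np.linalg.norm(n, axis=1)

    def facet_centroids(self):
        return self.nodes[self.boundary_facets].mean(axis=1)

    def facet_normals(self):
        """Unit outward normals of boundary facets."""
        if "normals" in self._cache:
            return self._cache["normals"]
        x = self.nodes[self.boundary_facets]
        n = np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        # orient away from the adjacent tet centroid
        owner = self.facet_owner_tets()
        to_facet = self.facet_centroids() - self.tet_centroids()[owner]
        sign = np.sign(np.einsum("ij,ij->i", n, to_facet))
        sign[sign == 0] = 1.0
        n *= sign[:, None]
        self._cache["normals"] = n
        return n

    def facet_owner_tets(self):
        """Index of the unique tet adjacent to each boundary facet."""
        if "owner" in self._cache:
            return self._cache["owner"]
        lookup = {}
        local = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
        for e, tet in enumerate(self.tets):
            for lf in local:
                key = tuple(sorted(tet[list(lf)]))
                lookup.setdefault(key, []).append(e)
        owner = np.empty(len(self.boundary_facets), dtype=np.int64)
        for f, tri in enumerate(self.boundary_facets):
            key = tuple(sorted(tri))
            owners = lookup.get(key)
            if not owners or len(owners) != 1:
                raise MeshError(f"boundary facet {f} {tuple(tri)} is not a "
                                "boundary face of exactly one tetrahedron")
            owner[f] = owners[0]
        self._cache["owner"] = owner
        return owner

    # -- label queries -----------------------------------------------------

    def facets_where(self, label):
        """Boolean facet mask for a surface tag or territory name/int."""
        if isinstance(label, str):
            if label.lower() in _SURFACE_NAMES:
                return self.facet_tag == _SURFACE_NAMES[label.lower()]
            if label in TERRITORIES:
                return self.territory == TERRITORIES.index(label)
            raise MeshError(f"unknown surface/territory label {label!r}")
        mask = self.facet_tag == int(label)
        if not mask.any():
            raise MeshError(f"unknown facet tag {label!r}")
        return mask

    def hemisphere_elements(self, which):
        code = {"L": HEMI_L, "R": HEMI_R}.get(which, which)
        mask = self.hemisphere == code
        if not mask.any():
            raise MeshError(f"hemisphere {which!r} has no elements")
        return np.where(mask)[0]

    # -- validation --------------------------------------------------------

    def validate(self, require_two_surfaces=True, require_territories=False):
        """Check the structural invariants; raise :class:`MeshError`."""
        if (self.tets >= self.n_nodes).any() or (self.tets < 0).any():
            raise MeshError("tet connectivity references missing nodes")
        vol = self.tet_volumes()
        if (vol <= 0).any():
            raise MeshError(f"non-positive volume in element "
                            f"{int(np.argmin(vol))}")
        # boundary facets of the tet mesh must match the stored ones
        faces = np.sort(np.concatenate([
            self.tets[:, [1, 2, 3]], self.tets[:, [0, 2, 3]],
            self.tets[:, [0, 1, 3]], self.tets[:, [0, 1, 2]]]), axis=1)
        uniq, counts = np.unique(faces, axis=0, return_counts=True)
        if (counts > 2).any():
            raise MeshError("a facet is shared by more than two tets")
        bnd = uniq[counts == 1]
        stored = np.sort(self.boundary_facets, axis=1)
        bnd_set = {tuple(f) for f in bnd}
        stored_set = {tuple(f) for f in stored}
        missing = bnd_set - stored_set
        if missing:
            raise MeshError(f"boundary facet {sorted(missing)[0]} carries "
                            "no tag")
        extra = stored_set - bnd_set
        if extra:
            raise MeshError(f"tagged facet {sorted(extra)[0]} is not on the "
                            "mesh boundary")
        if len(stored_set) != len(stored):
            raise MeshError("duplicate boundary facets")
        # watertight: each boundary edge shared by exactly two boundary facets
        edges = np.sort(np.concatenate([
            stored[:, [0, 1]], stored[:, [1, 2]], stored[:, [0, 2]]]), axis=1)
        _, ecounts = np.unique(edges, axis=0, return_counts=True)
        if (ecounts != 2).any():
            raise MeshError("boundary is not watertight (an edge is not "
                            "shared by exactly two boundary facets)")
        if require_two_surfaces:
            bad = ~np.isin(self.facet_tag, (CORTICAL, VENTRICULAR))
            if bad.any():
                raise MeshError(f"facet {int(np.argmax(bad))} carries tag "
                                f"{int(self.facet_tag[np.argmax(bad)])}, "
                                "expected cortical or ventricular")
            vent_terr = (self.facet_tag == VENTRICULAR) & \
                        (self.territory != NO_TERRITORY)
            if vent_terr.any():
                raise MeshError("a ventricular facet carries a territory "
                                "label")
        if require_territories:
            cort = self.facet_tag == CORTICAL
            if (self.territory[cort] == NO_TERRITORY).any():
                f = int(np.where(cort & (self.territory == NO_TERRITORY))[0][0])
                raise LabelingError(f"cortical facet {f} has no territory "
                                    "label")
        return self


# ---------------------------------------------------------------------------
# measures

def surface_area(mesh: LabeledMesh, label) -> float:
    """Total area (m^2) of a tagged surface or one perfusion territory."""
    mask = mesh.facets_where(label)
    area = float(mesh.facet_areas()[mask].sum())
    if area <= 0:
        raise MeshError(f"label {label!r} selects no facets")
    return area


def domain_volume(mesh: LabeledMesh) -> float:
    return float(mesh.tet_volumes().sum())


# ---------------------------------------------------------------------------
# territory labeling

def label_territories(mesh: LabeledMesh, rule="hemisphere-polar",
                      va_cap_cos=-0.5, require_nonempty=True) -> LabeledMesh:
    """Assign the four perfusion territories to the cortical facets.

    The built-in ``hemisphere-polar`` rule mirrors the anatomical split at
    synthetic-geometry fidelity: the sagittal plane x = 0 separates left
    from right, and a polar cap (facet centroids with z/r below
    ``va_cap_cos``) receives the vertebral (VA) supply, the rest the
    internal carotid (ICA) supply.  Labels are deterministic functions of
    facet centroids.
    """
    if rule != "hemisphere-polar":
        raise MeshError(f"unknown territory labeling rule {rule!r}")
    cort = mesh.facet_tag == CORTICAL
    c = mesh.facet_centroids()
    r = np.linalg.norm(c, axis=1)
    r[r == 0] = 1.0
    lower = (c[:, 2] / r) < va_cap_cos
    left = c[:, 0] < 0.0
    terr = np.full(len(cort), NO_TERRITORY, dtype=np.int64)
    terr[cort & ~lower & left] = TERRITORIES.index("ICA_L")
    terr[cort & ~lower & ~left] = TERRITORIES.index("ICA_R")
    terr[cort & lower & left] = TERRITORIES.index("VA_L")
    terr[cort & lower & ~left] = TERRITORIES.index("VA_R")
    if (terr[cort] == NO_TERRITORY).any():
        raise LabelingError("rule left cortical facets unlabeled")
    if require_nonempty:
        for t, name in enumerate(TERRITORIES):
            if not (terr == t).any():
                raise LabelingError(f"territory {name} is empty under rule "
                                    f"{rule!r}")
    mesh.territory = terr
    return mesh


def label_hemispheres(mesh: LabeledMesh) -> LabeledMesh:
    """Label elements left/right by centroid x-sign."""
    cx = mesh.tet_centroids()[:, 0]
    mesh.hemisphere = np.where(cx < 0.0, HEMI_L, HEMI_R).astype(np.int64)
    return mesh


# ---------------------------------------------------------------------------
# synthetic shell generator

def _icosahedron():
    t = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array([
        [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
        [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
        [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1]], dtype=float)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    f = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1]],
        dtype=np.int64)
    return v, f


def _geodesic_sphere(freq: int):
    """Unit geodesic sphere: each icosahedron face split into freq^2."""
    base_v, base_f = _icosahedron()
    verts = list(base_v)
    index = {}

    def corner_key(vid):
        return ("v", vid)

    def edge_key(a, b, i):
        # i steps from a toward b, 0 < i < freq
        if a < b:
            return ("e", a, b, i)
        return ("e", b, a, freq - i)

    def get_vertex(face_id, A, B, C, i, j):
        # point = (k*A + i*B + j*C) / freq
        k = freq - i - j
        if j == 0 and k == 0:
            key = corner_key(B)
        elif i == 0 and k == 0:
            key = corner_key(C)
        elif i == 0 and j == 0:
            key = corner_key(A)
        elif k == 0:            # edge B->C, j steps from B toward C
            key = edge_key(B, C, j)
        elif j == 0:            # edge A->B, i steps from A toward B
            key = edge_key(A, B, i)
        elif i == 0:            # edge A->C, j steps from A toward C
            key = edge_key(A, C, j)
        else:
            key = ("f", face_id, i, j)
        if key in index:
            return index[key]
        p = (k * base_v[A] + i * base_v[B] + j * base_v[C]) / freq
        p = p / np.linalg.norm(p)
        if key[0] == "v":
            p = base_v[key[1]]
        verts.append(p)
        index[key] = len(verts) - 1
        return index[key]

    # seed corners so they keep their base indices
    for vid in range(len(base_v)):
        index[corner_key(vid)] = vid

    faces = []
    for fid, (A, B, C) in enumerate(base_f):
        # lattice (i, j): point = ((freq-i-j) A + i B + j C)/freq
        ids = {}
        for i in range(freq + 1):
            for j in range(freq + 1 - i):
                ids[(i, j)] = get_vertex(fid, A, B, C, i, j)
        for i in range(freq):
            for j in range(freq - i):
                faces.append([ids[(i, j)], ids[(i + 1, j)], ids[(i, j + 1)]])
                if i + j < freq - 1:
                    faces.append([ids[(i + 1, j)], ids[(i + 1, j + 1)],
                                  ids[(i, j + 1)]])
    return np.array(verts), np.array(faces, dtype=np.int64)


_PRISM_ROT = [
    (0, 1, 2, 3, 4, 5),
    (1, 2, 0, 4, 5, 3),
    (2, 0, 1, 5, 3, 4),
    (3, 5, 4, 0, 2, 1),
    (5, 4, 3, 2, 1, 0),
    (4, 3, 5, 1, 0, 2),
]


def _split_prism(p):
    """Split a prism (bottom p[0:3], top p[3:6]) into three tets.

    Face diagonals are chosen through the globally smallest vertex index of
    each quad face, which makes the split conforming across neighbouring
    prisms that share a quad.
    """
    g = np.asarray(p)
    best = None
    for rot in _PRISM_ROT:
        q = g[list(rot)]
        if q[0] == g.min():
            best = q
            break
    v0, v1, v2, v3, v4, v5 = best
    # quads through v0 get diagonals v0-v4 and v0-v5; third quad (1,2,5,4)
    if min(v1, v5) < min(v2, v4):
        return [(v0, v1, v2, v5), (v0, v1, v5, v4), (v0, v4, v5, v3)]
    return [(v0, v1, v2, v4), (v0, v4, v2, v5), (v0, v4, v5, v3)]


def generate_shell_mesh(r_inner: float, r_outer: float, target_h: float,
                        seed: int = 0, resolution=None) -> LabeledMesh:
    """Concentric spherical-shell mesh with labeled surfaces/territories.

    The inner sphere (radius ``r_inner``) is tagged ventricular, the outer
    (``r_outer``) cortical; cortical facets get the four-territory
    hemisphere/polar labeling and elements are labeled L/R by centroid.
    ``resolution=(freq, layers)`` overrides the ``target_h``-derived
    geodesic frequency and radial layer count.  The construction is
    deterministic; ``seed`` is accepted for interface uniformity.
    """
    if not (0 < r_inner < r_outer):
        raise ValueError(f"need 0 < r_inner < r_outer, got "
                         f"{r_inner}, {r_outer}")
    if resolution is None:
        if not (0 < target_h < (r_outer - r_inner)):
            raise ValueError("target_h must lie in (0, r_outer - r_inner)")
        freq = max(2, int(round(1.05 * r_outer / target_h)))
        layers = max(2, int(round((r_outer - r_inner) / target_h)))
    else:
        freq, layers = resolution
        if freq < 1 or layers < 1:
            raise ValueError("resolution entries must be >= 1")
    sv, sf = _geodesic_sphere(freq)
    nv = len(sv)
    radii = np.linspace(r_inner, r_outer, layers + 1)
    nodes = (radii[:, None, None] * sv[None, :, :]).reshape(-1, 3)
    tets = []
    for s in range(layers):
        lo, hi = s * nv, (s + 1) * nv
        for a, b, c in sf:
            tets.extend(_split_prism((lo + a, lo + b, lo + c,
                                      hi + a, hi + b, hi + c)))
    tets = np.array(tets, dtype=np.int64)
    inner = sf.copy()
    outer = sf + layers * nv
    boundary = np.vstack([inner, outer])
    tags = np.concatenate([np.full(len(inner), VENTRICULAR, dtype=np.int64),
                           np.full(len(outer), CORTICAL, dtype=np.int64)])
    mesh = LabeledMesh(nodes, tets, boundary, tags)
    label_territories(mesh)
    label_hemispheres(mesh)
    return mesh


# ---------------------------------------------------------------------------
# structured boxes (verification geometries)

def generate_box_mesh(nx, ny, nz, lx, ly, lz, origin=(0.0, 0.0, 0.0)):
    """Structured box split into 6 tets per cell (Kuhn), faces tagged
    XMIN..ZMAX.  Used for consolidation benchmarks, not brain runs."""
    ox, oy, oz = origin
    xs = np.linspace(ox, ox + lx, nx + 1)
    ys = np.linspace(oy, oy + ly, ny + 1)
    zs = np.linspace(oz, oz + lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    perms = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]
    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                base = np.array([i, j, k])
                for perm in perms:
                    path = [base.copy()]
                    cur = base.copy()
                    for ax in perm:
                        cur = cur.copy()
                        cur[ax] += 1
                        path.append(cur)
                    tets.append([nid(*p) for p in path])
    tets = np.array(tets, dtype=np.int64)

    boundary, tags = [], []

    def add_face_quads(fixed_axis, fixed_idx, tag):
        axes = [ax for ax in range(3) if ax != fixed_axis]
        n0 = (nx, ny, nz)[axes[0]]
        n1 = (nx, ny, nz)[axes[1]]
        for a in range(n0):
            for b in range(n1):
                idx = [0, 0, 0]
                idx[fixed_axis] = fixed_idx

                def corner(da, db):
                    c = list(idx)
                    c[axes[0]] = a + da
                    c[axes[1]] = b + db
                    return nid(*c)

                q = [corner(0, 0), corner(1, 0), corner(1, 1), corner(0, 1)]
                # split quad consistently with the Kuhn tets: diagonal
                # through the lexicographically smallest corner
                if min(q[0], q[2]) < min(q[1], q[3]):
                    tris = [(q[0], q[1], q[2]), (q[0], q[2], q[3])]
                else:
                    tris = [(q[0], q[1], q[3]), (q[1], q[2], q[3])]
                boundary.extend(tris)
                tags.extend([tag, tag])

    add_face_quads(0, 0, XMIN)
    add_face_quads(0, nx, XMAX)
    add_face_quads(1, 0, YMIN)
    add_face_quads(1, ny, YMAX)
    add_face_quads(2, 0, ZMIN)
    add_face_quads(2, nz, ZMAX)
    return LabeledMesh(nodes, tets, np.array(boundary, dtype=np.int64),
                       np.array(tags, dtype=np.int64))


# ---------------------------------------------------------------------------
# file formats

def read_mesh(path, territory_rule=None, unit_scale=1.0) -> LabeledMesh:
    """Read a labeled mesh from Gmsh MSH 2.2 ASCII or legacy VTK.

    ``unit_scale`` converts file coordinates to metres (1e-3 for meshes
    stored in millimetres).  If the file carries no territory labels a
    ``territory_rule`` (see :func:`label_territories`) must be supplied;
    otherwise loading a two-surface mesh without them is an error only
    when validation demands territories.
    """
    path = str(path)
    if path.endswith(".msh"):
        mesh = _read_msh(path)
    elif path.endswith(".vtk"):
        mesh = _read_vtk_mesh(path)
    else:
        raise MeshError(f"unsupported mesh format: {path}")
    if unit_scale != 1.0:
        mesh.nodes = mesh.nodes * float(unit_scale)
        mesh._cache.clear()
    mesh.validate(require_two_surfaces=set(np.unique(mesh.facet_tag)) <=
                  {CORTICAL, VENTRICULAR})
    has_terr = (mesh.territory != NO_TERRITORY).any()
    if not has_terr and territory_rule is not None:
        label_territories(mesh, rule=territory_rule)
        label_hemispheres(mesh)
    return mesh


def _read_msh(path) -> LabeledMesh:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    try:
        i = lines.index("$Nodes")
        n = int(lines[i + 1])
        nodes = np.empty((n, 3))
        id_map = {}
        for row in range(n):
            parts = lines[i + 2 + row].split()
            id_map[int(parts[0])] = row
            nodes[row] = [float(v) for v in parts[1:4]]
        j = lines.index("$Elements")
        ne = int(lines[j + 1])
    except (ValueError, IndexError) as exc:
        raise MeshError(f"{path}: unreadable MSH file ({exc})") from exc
    tets, hemi, tris, ttags, terr = [], [], [], [], []
    for row in range(ne):
        parts = lines[j + 2 + row].split()
        eid, etype, ntags = int(parts[0]), int(parts[1]), int(parts[2])
        tags = [int(v) for v in parts[3:3 + ntags]]
        conn = [id_map[int(v)] for v in parts[3 + ntags:]]
        if etype == 4:
            tets.append(conn)
            hemi.append((tags[0] - 1) if tags and tags[0] in (1, 2)
                        else NO_HEMI)
        elif etype == 2:
            tris.append(conn)
            ttags.append(tags[0] if tags else 0)
            terr.append((tags[1] - 1) if len(tags) > 1 and
                        1 <= tags[1] <= 4 else NO_TERRITORY)
        elif etype in (15, 1):
            continue
        else:
            raise MeshError(f"{path}: element {eid} has non-tetrahedral "
                            f"volumetric type {etype}")
    if not tets:
        raise MeshError(f"{path}: no tetrahedra found")
    if not tris:
        raise MeshError(f"{path}: boundary facets lack tags (no labeled "
                        "triangles present)")
    if any(t == 0 for t in ttags):
        k = ttags.index(0)
        raise MeshError(f"{path}: boundary facet {k} carries no surface tag")
    return LabeledMesh(nodes, np.array(tets, dtype=np.int64),
                       np.array(tris, dtype=np.int64),
                       np.array(ttags, dtype=np.int64),
                       territory=np.array(terr, dtype=np.int64),
                       hemisphere=np.array(hemi, dtype=np.int64))


def write_msh(mesh: LabeledMesh, path) -> None:
    """Write MSH 2.2 ASCII.  Triangles carry (surface_tag, territory+1),
    tets carry (hemisphere+1, 0); 0 encodes an absent label."""
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write(f"$Nodes\n{mesh.n_nodes}\n")
        for idx, (x, y, z) in enumerate(mesh.nodes, start=1):
            fh.write(f"{idx} {x:.17g} {y:.17g} {z:.17g}\n")
        fh.write("$EndNodes\n")
        ne = len(mesh.boundary_facets) + mesh.n_elements
        fh.write(f"$Elements\n{ne}\n")
        eid = 1
        for f, tri in enumerate(mesh.boundary_facets):
            t1 = int(mesh.facet_tag[f])
            t2 = int(mesh.territory[f]) + 1
            a, b, c = (int(v) + 1 for v in tri)
            fh.write(f"{eid} 2 2 {t1} {t2} {a} {b} {c}\n")
            eid += 1
        for e, tet in enumerate(mesh.tets):
            h = int(mesh.hemisphere[e]) + 1
            a, b, c, d = (int(v) + 1 for v in tet)
            fh.write(f"{eid} 4 2 {h} 0 {a} {b} {c} {d}\n")
            eid += 1
        fh.write("$EndElements\n")


def write_vtk_mesh(mesh: LabeledMesh, path, point_data=None,
                   cell_data=None) -> None:
    """Write mesh (tets then boundary triangles) as legacy VTK with the
    label arrays; extra tet-wise cell_data is padded over the triangles."""
    cells = [t for t in mesh.tets] + [f for f in mesh.boundary_facets]
    types = [VTK_TETRA] * mesh.n_elements + \
            [VTK_TRIANGLE] * len(mesh.boundary_facets)
    nf = len(mesh.boundary_facets)
    cd = {
        "boundary_tag": np.concatenate([
            np.zeros(mesh.n_elements, dtype=np.int64), mesh.facet_tag]),
        "territory": np.concatenate([
            np.full(mesh.n_elements, NO_TERRITORY, dtype=np.int64),
            mesh.territory]),
        "hemisphere": np.concatenate([
            mesh.hemisphere, np.full(nf, NO_HEMI, dtype=np.int64)]),
    }
    if cell_data:
        for name, arr in cell_data.items():
            arr = np.asarray(arr)
            pad_shape = (nf,) + arr.shape[1:]
            cd[name] = np.concatenate([arr, np.zeros(pad_shape,
                                                     dtype=arr.dtype)])
    write_vtk(path, mesh.nodes, cells, types, point_data=point_data,
              cell_data=cd)


def _read_vtk_mesh(path) -> LabeledMesh:
    data = read_vtk(path)
    cells, types = data["cells"], data["cell_types"]
    bad = set(types) - {VTK_TETRA, VTK_TRIANGLE}
    if bad:
        raise MeshError(f"{path}: non-tetrahedral volumetric cell type "
                        f"{sorted(bad)[0]}")
    tet_ids = [i for i, t in enumerate(types) if t == VTK_TETRA]
    tri_ids = [i for i, t in enumerate(types) if t == VTK_TRIANGLE]
    if not tet_ids:
        raise MeshError(f"{path}: no tetrahedra found")
    cd = data["cell_data"]
    if "boundary_tag" not in cd:
        raise MeshError(f"{path}: boundary facets lack tags "
                        "(no boundary_tag cell array)")
    tets = np.array([cells[i] for i in tet_ids], dtype=np.int64)
    tris = np.array([cells[i] for i in tri_ids], dtype=np.int64)
    ttags = np.array([cd["boundary_tag"][i] for i in tri_ids],
                     dtype=np.int64)
    if (ttags == 0).any():
        raise MeshError(f"{path}: boundary facet "
                        f"{int(np.argmax(ttags == 0))} carries no tag")
    terr = np.array([cd["territory"][i] for i in tri_ids], dtype=np.int64) \
        if "territory" in cd else None
    hemi = np.array([cd["hemisphere"][i] for i in tet_ids], dtype=np.int64) \
        if "hemisphere" in cd else None
    return LabeledMesh(data["nodes"], tets, tris, ttags,
                       territory=terr, hemisphere=hemi)
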