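"""Idealized antiparallel four-helix bundle geometry and His-site design.

The designed protein is modelled as four ideal alpha-helical CA traces
(1.5 Å rise, 100 deg twist per residue, 2.3 Å CA radius) placed on a square
lattice inside a flat membrane slab, with consecutive helices antiparallel
so that the chain threads H1-up, H2-down, H3-up, H4-down.  Helix azimuthal
phases default to pointing the mildly polar serine face of each helix at
the bundle axis, which keeps the polar stripes interior.

On top of the geometry sit the cofactor-site design rules: enumerate
inward-facing residues, require ~10 Å burial below the nearer membrane
surface, pair diametrically opposed helices for bis-His coordination, and
"hollow out" the site by mutating nearby interior leucines to alanine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .design import DesignedProtein, REAMP_PATTERN

__all__ = [
    "BundleParams",
    "BundleModel",
    "CandidateSite",
    "MutationPlan",
    "build_bundle",
    "inward_facing",
    "burial_depth",
    "select_his_sites",
    "cavity_mutations",
    "write_pdb",
    "read_pdb_ca",
]

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# Lattice corners in chain order; H1/H3 and H2/H4 are the diagonals.
_LATTICE = np.array([(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)])
_DIAGONAL_PAIRS = ((1, 3), (2, 4))


@dataclass(frozen=True)
class BundleParams:
    """Geometric constants of the idealized bundle (lengths in Å)."""

    n_res_per_helix: int = 21
    rise_per_res: float = 1.5
    twist_deg: float = 100.0
    helix_radius: float = 2.3
    inter_axis_spacing: float = 10.0
    membrane_half_thickness: float = 15.75
    #: Azimuthal phase offsets added to the default serine-inward phasing,
    #: one per helix (degrees).
    phase_offsets_deg: tuple = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self):
        for name in ("rise_per_res", "helix_radius", "inter_axis_spacing",
                     "membrane_half_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_res_per_helix < 1:
            raise ValueError("n_res_per_helix must be >= 1")


@dataclass
class BundleModel:
    """CA-trace model of the four-helix bundle.

    ``coords`` is an (4*n, 3) array in chain order; ``helix_id`` (1-4) and
    ``helix_pos`` (1-n) annotate each CA, and ``residue_id`` gives the
    chain residue number inherited from the designed protein.
    """

    params: BundleParams
    protein: DesignedProtein
    coords: np.ndarray
    helix_id: np.ndarray
    helix_pos: np.ndarray
    residue_id: np.ndarray
    helix_axes: np.ndarray          # (4, 3) unit vectors
    helix_centers: np.ndarray       # (4, 2) lattice xy positions
    membrane_normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    @property
    def bundle_axis_xy(self):
        return self.helix_centers.mean(axis=0)

    def index_of(self, residue):
        """Row index of a chain residue number; KeyError if not in the bundle."""
        hits = np.nonzero(self.residue_id == residue)[0]
        if hits.size == 0:
            raise KeyError(f"residue {residue} is not part of the bundle")
        return int(hits[0])


@dataclass(frozen=True)
class CandidateSite:
    """An interior-facing residue considered for mutation to histidine."""

    residue: int
    helix: int
    depth: float
    facing_angle: float


@dataclass(frozen=True)
class MutationPlan:
    """His substitutions plus cavity-opening Leu→Ala mutations."""

    his_sites: tuple
    mode: str
    cavity_mutations: tuple = ()

    def __post_init__(self):
        if self.mode not in ("mono", "bis"):
            raise ValueError("mode must be 'mono' or 'bis'")
        if self.mode == "mono" and len(self.his_sites) != 1:
            raise ValueError("mono plan needs exactly one site")
        if self.mode == "bis":
            if len(self.his_sites) != 2:
                raise ValueError("bis plan needs exactly two sites")
            pair = tuple(sorted(s.helix for s in self.his_sites))
            if pair not in _DIAGONAL_PAIRS:
                raise ValueError("bis sites must lie on diagonally opposite helices")


def _polar_face_phase(pattern, twist_deg, chirality):
    """Azimuth (deg) of the mean small/polar-face direction for phase 0.

    The packing face of the idealized helix is made of the serines and the
    conserved glycines (every non-h position); its mean direction defines
    the face that is rotated toward the bundle axis.
    """
    polar = [i for i, s in enumerate(pattern) if s != "h"]
    ang = np.deg2rad(chirality * twist_deg * np.asarray(polar, dtype=float))
    return float(np.rad2deg(np.arctan2(np.sin(ang).sum(), np.cos(ang).sum())))


def build_bundle(params=None, protein=None):
    """Build the idealized CA bundle for a designed protein.

    The protein must carry four helix segments of ``n_res_per_helix``
    residues.  Helix k sits at lattice corner k with axis direction
    (-1)^(k+1) z; residue helix-positions run N-to-C along the chain, so
    even helices descend through the slab.
    """
    from .design import default_construct

    params = params or BundleParams()
    protein = protein or default_construct()
    n = params.n_res_per_helix
    helices = protein.helices()
    if len(helices) != 4 or any(len(h) != n for h in helices):
        raise ValueError(f"protein must have 4 helix segments of {n} residues")

    centers = _LATTICE * params.inter_axis_spacing
    center_xy = centers.mean(axis=0)
    coords, hel_id, hel_pos, res_id = [], [], [], []
    axes = []
    for k in range(4):
        direction = 1.0 if k % 2 == 0 else -1.0
        axes.append(np.array([0.0, 0.0, direction]))
        chirality = direction  # keep the helix right-handed along its own axis
        to_center = center_xy - centers[k]
        phi_c = np.rad2deg(np.arctan2(to_center[1], to_center[0]))
        phase = (phi_c - _polar_face_phase(REAMP_PATTERN, params.twist_deg, chirality)
                 + params.phase_offsets_deg[k])
        for i in range(1, n + 1):
            theta = np.deg2rad(phase + chirality * params.twist_deg * (i - 1))
            z = direction * (i - (n + 1) / 2.0) * params.rise_per_res
            coords.append([
                centers[k, 0] + params.helix_radius * np.cos(theta),
                centers[k, 1] + params.helix_radius * np.sin(theta),
                z,
            ])
            hel_id.append(k + 1)
            hel_pos.append(i)
            res_id.append(protein.residue_index(k + 1, i))

    return BundleModel(
        params=params,
        protein=protein,
        coords=np.asarray(coords),
        helix_id=np.asarray(hel_id),
        helix_pos=np.asarray(hel_pos),
        residue_id=np.asarray(res_id),
        helix_axes=np.asarray(axes),
        helix_centers=centers,
    )


def burial_depth(bundle, residue):
    """Depth (Å) of a residue's CA below the nearer membrane surface.

    Residues outside the slab report 0.
    """
    z = bundle.coords[bundle.index_of(residue), 2]
    return float(max(bundle.params.membrane_half_thickness - abs(z), 0.0))


def _facing_angle(bundle, row):
    k = bundle.helix_id[row] - 1
    radial = bundle.coords[row, :2] - bundle.helix_centers[k]
    to_axis = bundle.bundle_axis_xy - bundle.helix_centers[k]
    cosang = np.dot(radial, to_axis) / (
        np.linalg.norm(radial) * np.linalg.norm(to_axis)
    )
    return float(np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0))))


def inward_facing(bundle, angular_cutoff_deg=60.0):
    """Residues whose side-chain direction points at the bundle interior.

    The side-chain direction is approximated by the radial CA vector from
    the helix axis; a residue is inward when the angle between that vector
    and the direction to the bundle axis is at most ``angular_cutoff_deg``.
    """
    sites = []
    for row in range(len(bundle.coords)):
        ang = _facing_angle(bundle, row)
        if ang <= angular_cutoff_deg:
            res = int(bundle.residue_id[row])
            sites.append(CandidateSite(
                residue=res,
                helix=int(bundle.helix_id[row]),
                depth=burial_depth(bundle, res),
                facing_angle=ang,
            ))
    return sites


def select_his_sites(bundle, mode="bis", depth_target=10.0, depth_tol=4.0,
                     angular_cutoff_deg=60.0, bridge_window=(9.0, 14.0)):
    """Enumerate His-substitution plans meeting the cofactor design rules.

    Candidates must face inward and lie within ``depth_target ± depth_tol``
    of the target burial.  ``mono`` plans carry one candidate each.  ``bis``
    plans pair candidates on diagonally opposite helices whose burial
    depths differ by at most ``depth_tol`` and whose CA-CA separation falls
    inside ``bridge_window`` (Å), a span a bis-His-ligated porphyrin can
    bridge.  Plans are ordered by how close their mean depth is to the
    target; no candidates is an empty list, not an error.
    """
    lo, hi = depth_target - depth_tol, depth_target + depth_tol
    cands = [s for s in inward_facing(bundle, angular_cutoff_deg) if lo <= s.depth <= hi]
    if mode == "mono":
        plans = [MutationPlan((s,), "mono") for s in cands]
    elif mode == "bis":
        plans = []
        for a, b in _DIAGONAL_PAIRS:
            on_a = [s for s in cands if s.helix == a]
            on_b = [s for s in cands if s.helix == b]
            for s1 in on_a:
                for s2 in on_b:
                    if abs(s1.depth - s2.depth) > depth_tol:
                        continue
                    d = np.linalg.norm(
                        bundle.coords[bundle.index_of(s1.residue)]
                        - bundle.coords[bundle.index_of(s2.residue)]
                    )
                    if bridge_window[0] <= d <= bridge_window[1]:
                        plans.append(MutationPlan((s1, s2), "bis"))
    else:
        raise ValueError("mode must be 'mono' or 'bis'")
    return sorted(
        plans,
        key=lambda p: abs(np.mean([s.depth for s in p.his_sites]) - depth_target),
    )


def _heme_centroid(bundle, plan):
    if plan.mode == "bis":
        pts = np.array([
            bundle.coords[bundle.index_of(s.residue)] for s in plan.his_sites
        ])
        return pts.mean(axis=0)
    # mono: porphyrin projected onto the bundle axis at the site's depth
    site = plan.his_sites[0]
    z = bundle.coords[bundle.index_of(site.residue), 2]
    cx, cy = bundle.bundle_axis_xy
    return np.array([cx, cy, z])


def cavity_mutations(bundle, plan, clash_cutoff=7.0):
    """Fill in the Leu→Ala cavity mutations of a plan.

    Every leucine whose CA lies within ``clash_cutoff`` Å of the projected
    heme centroid is opened to alanine, relieving steric clash between the
    porphyrin ring and interior leucine side chains.
    """
    centroid = _heme_centroid(bundle, plan)
    his_residues = {s.residue for s in plan.his_sites}
    muts = []
    for row in range(len(bundle.coords)):
        res = int(bundle.residue_id[row])
        if res in his_residues:
            continue
        if bundle.protein.sequence[res - 1] != "L":
            continue
        if np.linalg.norm(bundle.coords[row] - centroid) <= clash_cutoff:
            muts.append((res, "L", "A"))
    return replace(plan, cavity_mutations=tuple(sorted(muts)))


def write_pdb(bundle, path, plan=None):
    """Write the CA trace as a single-model PDB file (chain A).

    Residue names follow the designed sequence; if a mutation plan is
    given, His sites are written as HIS and cavity positions as ALA.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    names = {}
    if plan is not None:
        for s in plan.his_sites:
            names[s.residue] = "HIS"
        for res, _from, to in plan.cavity_mutations:
            names[res] = _AA3[to]

    n = len(bundle.coords)
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(bundle.coords, dtype=np.float32)
    atoms.chain_id = np.full(n, "A")
    atoms.res_id = bundle.residue_id.astype(int)
    atoms.res_name = np.array([
        names.get(int(r), _AA3[bundle.protein.sequence[int(r) - 1]])
        for r in bundle.residue_id
    ])
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def read_pdb_ca(path):
    """Read back a CA-trace PDB; returns (coords, res_ids, res_names)."""
    from biotite.structure.io.pdb import PDBFile

    atoms = PDBFile.read(str(path)).get_structure(model=1)
    ca = atoms[atoms.atom_name == "CA"]
    return np.asarray(ca.coord, dtype=float), np.asarray(ca.res_id), np.asarray(ca.res_name)
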