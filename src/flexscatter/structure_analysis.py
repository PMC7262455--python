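"""Crystal-lattice expansion, helical filament geometry, and solvent
accessibility.

Covers the structure-side analyses of a head-to-tail crystal filament:

* :func:`expand_symmetry` applies the space-group operators (gemmi's
  symmetry tables) plus lattice translations and keeps the copies in
  contact with the asymmetric unit, iterating so filaments extend over
  two or more turns;
* :func:`trace_filament` orders the molecules along the contact graph;
* :func:`fit_helix` recovers axis, radius, rise, molecules-per-turn and
  pitch from the ordered centres of mass;
* :func:`shrake_rupley` computes per-atom/per-residue solvent accessible
  surface area by golden-spiral sphere sampling;
* :func:`sasa_percentile` places a value on an empirical reference
  distribution (midpoint convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .exceptions import (
    AmbiguityError,
    ArgumentError,
    DegenerateGeometryError,
    UnknownElementError,
    UnsupportedSpaceGroupError,
    ValidationError,
)

__all__ = [
    "AtomSet",
    "Molecule",
    "Assembly",
    "HelixParams",
    "SasaResult",
    "ReferenceDistribution",
    "VDW_RADII",
    "expand_symmetry",
    "trace_filament",
    "fit_helix",
    "filament_helix",
    "shrake_rupley",
    "sasa_percentile",
    "load_reference",
    "interface_contacts",
]

#: Van der Waals radii (A) for SASA; extend per call via ``radii=``.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
             "H": 1.20, "P": 1.80}

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class AtomSet:
    """A flat collection of atoms with coordinates and identities."""

    coords: np.ndarray
    elements: np.ndarray
    names: np.ndarray
    resnames: np.ndarray
    resseq: np.ndarray
    chains: np.ndarray

    def __post_init__(self):
        c = np.atleast_2d(np.asarray(self.coords, dtype=float))
        object.__setattr__(self, "coords", c)
        n = len(c)
        for f in ("elements", "names", "resnames", "chains"):
            arr = np.asarray(getattr(self, f), dtype=object)
            if arr.shape != (n,):
                raise ValidationError(f"{f} must have one entry per atom")
            object.__setattr__(self, f, arr)
        object.__setattr__(self, "resseq",
                           np.asarray(self.resseq, dtype=int))

    def __len__(self):
        return len(self.coords)

    @classmethod
    def from_arrays(cls, coords, elements, names=None, resnames=None,
                    resseq=None, chains=None):
        n = len(coords)
        fill = lambda v, d: np.full(n, d, dtype=object) if v is None else v
        return cls(coords=coords, elements=np.asarray(elements, dtype=object),
                   names=fill(names, "X"), resnames=fill(resnames, "UNK"),
                   resseq=np.ones(n, int) if resseq is None else resseq,
                   chains=fill(chains, "A"))

    @classmethod
    def from_gemmi(cls, structure, model_index: int = 0):
        """Extract all atoms of one model of a gemmi Structure (or file)."""
        import gemmi

        if isinstance(structure, (str, Path)):
            structure = gemmi.read_structure(str(structure))
        model = structure[model_index]
        coords, el, nm, rn, rs, ch = [], [], [], [], [], []
        for chain in model:
            for res in chain:
                for atom in res:
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    el.append(atom.element.name)
                    nm.append(atom.name)
                    rn.append(res.name)
                    rs.append(res.seqid.num)
                    ch.append(chain.name)
        return cls(coords=np.array(coords),
                   elements=np.array(el, dtype=object),
                   names=np.array(nm, dtype=object),
                   resnames=np.array(rn, dtype=object),
                   resseq=np.array(rs, int),
                   chains=np.array(ch, dtype=object))

    def transformed(self, rot: np.ndarray, trans: np.ndarray) -> "AtomSet":
        return AtomSet(coords=self.coords @ rot.T + trans,
                       elements=self.elements, names=self.names,
                       resnames=self.resnames, resseq=self.resseq,
                       chains=self.chains)


@dataclass(frozen=True)
class Molecule:
    """One symmetry copy: atoms plus the operator that generated them.

    ``rot``/``trans`` act on Cartesian coordinates of the source chain:
    ``copy = source @ rot.T + trans``.
    """

    atoms: AtomSet
    chain_id: str
    op_index: int
    op_triplet: str
    shift: tuple
    rot: np.ndarray = field(repr=False, default=None)
    trans: np.ndarray = field(repr=False, default=None)

    @property
    def com(self) -> np.ndarray:
        return self.atoms.coords.mean(axis=0)

    @property
    def key(self):
        return (self.chain_id, self.op_index, self.shift)


@dataclass(frozen=True)
class Assembly:
    """Symmetry-expanded set of molecules with cell and space group."""

    molecules: tuple
    cell: tuple
    spacegroup: str

    def __post_init__(self):
        mols = tuple(self.molecules)
        keys = [m.key for m in mols]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (chain, operator, shift) entry")
        object.__setattr__(self, "molecules", mols)

    def __len__(self):
        return len(self.molecules)


def _orth_matrix(cell) -> np.ndarray:
    a, b, c, al, be, ga = cell
    al, be, ga = map(math.radians, (al, be, ga))
    v = math.sqrt(1 - math.cos(al)**2 - math.cos(be)**2 - math.cos(ga)**2
                  + 2 * math.cos(al) * math.cos(be) * math.cos(ga))
    return np.array([
        [a, b * math.cos(ga), c * math.cos(be)],
        [0, b * math.sin(ga),
         c * (math.cos(al) - math.cos(be) * math.cos(ga)) / math.sin(ga)],
        [0, 0, c * v / math.sin(ga)],
    ])


def expand_symmetry(structure, contact_radius: float = 4.0,
                    max_molecules: int = 30, shell: int = 3) -> Assembly:
    """Grow the contacting crystal environment of an asymmetric unit.

    Applies every space-group operator combined with lattice translations
    in a +/- ``shell`` cell neighbourhood, and iteratively retains copies
    having at least one atom within ``contact_radius`` (A) of the growing
    set, starting from the identity copies.  Iteration (breadth-first over
    the contact graph, up to ``max_molecules``) lets helical filaments
    extend across two or more turns rather than stopping at the first
    contact shell.
    """
    import gemmi

    if isinstance(structure, (str, Path)):
        structure = gemmi.read_structure(str(structure))
    cell = structure.cell
    if cell.a <= 1.0:
        raise ValidationError("structure has no unit cell (CRYST1 missing?)")
    sg = gemmi.find_spacegroup_by_name(structure.spacegroup_hm or "")
    if sg is None:
        raise UnsupportedSpaceGroupError(
            f"unrecognised space group symbol {structure.spacegroup_hm!r}")
    cell_params = (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
    orth = _orth_matrix(cell_params)
    frac = np.linalg.inv(orth)

    chain_atoms = {}
    full = AtomSet.from_gemmi(structure)
    for name in np.unique(full.chains):
        mask = full.chains == name
        chain_atoms[str(name)] = AtomSet(
            coords=full.coords[mask], elements=full.elements[mask],
            names=full.names[mask], resnames=full.resnames[mask],
            resseq=full.resseq[mask], chains=full.chains[mask])

    ops = list(sg.operations())
    shifts = [(i, j, k)
              for i in range(-shell, shell + 1)
              for j in range(-shell, shell + 1)
              for k in range(-shell, shell + 1)]

    def cartesian_op(op, shift):
        R_f = np.array(op.rot, dtype=float) / 24.0
        t_f = np.array(op.tran, dtype=float) / 24.0 + np.array(shift, float)
        R_c = orth @ R_f @ frac
        t_c = orth @ t_f
        return R_c, t_c

    molecules = []
    for name, aset in chain_atoms.items():
        molecules.append(Molecule(
            atoms=aset, chain_id=name, op_index=0,
            op_triplet=ops[0].triplet(), shift=(0, 0, 0),
            rot=np.eye(3), trans=np.zeros(3)))
    used = {m.key for m in molecules}

    candidates = []
    for name, aset in chain_atoms.items():
        for oi, op in enumerate(ops):
            for shift in shifts:
                key = (name, oi, shift)
                if key in used:
                    continue
                candidates.append((name, oi, op, shift))

    grown = True
    while grown and len(molecules) < max_molecules:
        grown = False
        tree = cKDTree(np.concatenate([m.atoms.coords for m in molecules]))
        remaining = []
        for name, oi, op, shift in candidates:
            if len(molecules) >= max_molecules:
                break
            R_c, t_c = cartesian_op(op, shift)
            coords = chain_atoms[name].coords @ R_c.T + t_c
            d, _ = tree.query(coords, k=1,
                              distance_upper_bound=contact_radius)
            if np.any(np.isfinite(d)):
                molecules.append(Molecule(
                    atoms=chain_atoms[name].transformed(R_c, t_c),
                    chain_id=name, op_index=oi, op_triplet=op.triplet(),
                    shift=shift, rot=R_c, trans=t_c))
                grown = True
            else:
                remaining.append((name, oi, op, shift))
        candidates = remaining
    return Assembly(molecules=molecules, cell=cell_params,
                    spacegroup=sg.hm)


def trace_filament(assembly: Assembly, contact_cutoff: float = 4.0):
    """Order the molecules of a filament along its contact graph.

    Two molecules are adjacent when any inter-atomic distance is below
    ``contact_cutoff``.  The graph must be a simple path (every degree
    <= 2, no cycle); a branch point raises :class:`AmbiguityError` with
    the degree distribution.  Returns the molecules in path order (the
    longest path when several components exist).
    """
    mols = assembly.molecules
    n = len(mols)
    if n == 0:
        raise ArgumentError("empty assembly")
    if n == 1:
        return [mols[0]]
    trees = [cKDTree(m.atoms.coords) for m in mols]
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if any(trees[i].query_ball_tree(trees[j], contact_cutoff)):
                adj[i].append(j)
                adj[j].append(i)
    degrees = [len(a) for a in adj]
    if any(d > 2 for d in degrees):
        hist = {d: degrees.count(d) for d in sorted(set(degrees))}
        raise AmbiguityError(
            f"contact graph is branched; degree distribution {hist}")
    # walk each path component from an endpoint
    seen = [False] * n
    best: list[int] = []
    for start in range(n):
        if seen[start] or degrees[start] > 1:
            continue
        path = [start]
        seen[start] = True
        cur = start
        while True:
            nxt = [j for j in adj[cur] if not seen[j]]
            if not nxt:
                break
            cur = nxt[0]
            seen[cur] = True
            path.append(cur)
        if len(path) > len(best):
            best = path
    if not best:  # all vertices have degree 2: a cycle
        raise AmbiguityError("contact graph is a closed cycle, not a path")
    return [mols[i] for i in best]


@dataclass(frozen=True)
class HelixParams:
    """Geometry of a helical filament of molecules.

    ``pitch = rise_per_molecule * molecules_per_turn`` holds exactly;
    ``radius`` is the mean centre-of-mass distance to the axis;
    outer/inner radii are atomic extremes (NaN when no atoms supplied).
    """

    axis_point: np.ndarray
    axis_direction: np.ndarray
    radius: float
    rise_per_molecule: float
    molecules_per_turn: float
    pitch: float
    outer_radius: float
    inner_radius: float
    n_molecules: int


def fit_helix(ordered_coms, atoms=None) -> HelixParams:
    """Fit helix parameters to ordered molecule centres of mass.

    The axis is initialized as the total-least-squares line through the
    COMs (principal component) and refined by minimizing the variance of
    the radial distances.  Azimuthal step and axial rise are averaged over
    consecutive molecules in cylindrical coordinates around the fitted
    axis.  ``atoms`` (any (K,3) stack) adds outer/inner atomic radii.
    """
    coms = np.asarray(ordered_coms, dtype=float)
    if coms.ndim != 2 or coms.shape[1] != 3 or len(coms) < 4:
        raise ArgumentError("need >= 4 ordered 3-D centres of mass")
    centroid = coms.mean(axis=0)
    u, s, vt = np.linalg.svd(coms - centroid)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise DegenerateGeometryError("centres of mass are collinear")
    # axis init: consecutive chord cross-products share the axial
    # direction for a regular helix (their radial parts average out)
    v = np.diff(coms, axis=0)
    cr = np.cross(v[:-1], v[1:]).sum(axis=0)
    if np.linalg.norm(cr) > 1e-9:
        w0 = cr / np.linalg.norm(cr)
    else:
        w0 = vt[0]  # degenerate turn: fall back to the principal axis
    e1, e2 = _ortho_frame(w0)
    # centre init: algebraic (Kasa) circle fit in the plane normal to w0
    x, y = (coms - centroid) @ e1, (coms - centroid) @ e2
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    sol, *_ = np.linalg.lstsq(A, x**2 + y**2, rcond=None)
    centroid = centroid + sol[0] * e1 + sol[1] * e2

    def axis_of(p):
        dx, dy, rx, ry = p
        w = w0 + rx * e1 + ry * e2
        w = w / np.linalg.norm(w)
        point = centroid + dx * e1 + dy * e2
        return point, w

    def resid(p):
        point, w = axis_of(p)
        rel = coms - point
        axial = rel @ w
        radial = rel - axial[:, None] * w
        r = np.linalg.norm(radial, axis=1)
        return r - r.mean()

    sol = least_squares(resid, np.zeros(4), xtol=1e-15, ftol=1e-15,
                        gtol=1e-15)
    point, w = axis_of(sol.x)
    rel = coms - point
    z = rel @ w
    radial = rel - z[:, None] * w
    r = np.linalg.norm(radial, axis=1)
    f1, f2 = _ortho_frame(w)
    phi = np.unwrap(np.arctan2(radial @ f2, radial @ f1))
    dphi = np.diff(phi)
    dz = np.diff(z)
    if np.mean(dz) < 0:  # orient the axis along increasing order
        w, z, dz = -w, -z, -dz
        f1, f2 = _ortho_frame(w)
        phi = np.unwrap(np.arctan2(radial @ f2, radial @ f1))
        dphi = np.diff(phi)
    mean_dphi = float(np.mean(np.abs(dphi)))
    if mean_dphi <= 0:
        raise DegenerateGeometryError("no azimuthal progression")
    mpt = 2.0 * math.pi / mean_dphi
    rise = float(np.mean(np.abs(dz)))
    outer = inner = float("nan")
    if atoms is not None and len(atoms):
        a = np.asarray(atoms, dtype=float)
        arel = a - point
        az = arel @ w
        ar = np.linalg.norm(arel - az[:, None] * w, axis=1)
        outer, inner = float(ar.max()), float(ar.min())
    return HelixParams(axis_point=point, axis_direction=w,
                       radius=float(r.mean()), rise_per_molecule=rise,
                       molecules_per_turn=mpt, pitch=mpt * rise,
                       outer_radius=outer, inner_radius=inner,
                       n_molecules=len(coms))


def _ortho_frame(w):
    a = np.array([1.0, 0, 0]) if abs(w[0]) < 0.9 else np.array([0, 1.0, 0])
    e1 = np.cross(w, a)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(w, e1)


def filament_helix(assembly_or_molecules, contact_cutoff: float = 4.0) -> HelixParams:
    """Trace a filament and fit its helix in one call."""
    if isinstance(assembly_or_molecules, Assembly):
        ordered = trace_filament(assembly_or_molecules, contact_cutoff)
    else:
        ordered = list(assembly_or_molecules)
    coms = [m.com for m in ordered]
    atoms = np.concatenate([m.atoms.coords for m in ordered])
    return fit_helix(coms, atoms=atoms)


@dataclass(frozen=True)
class SasaResult:
    """Per-atom and per-residue solvent accessible surface areas (A^2)."""

    atom_sasa: np.ndarray
    table: pd.DataFrame
    probe: float
    n_points: int


def shrake_rupley(atoms, probe: float = 1.4, n_points: int = 960,
                  radii: dict | None = None) -> SasaResult:
    """Shrake-Rupley SASA by deterministic golden-spiral sphere sampling.

    Each atom's sphere of radius ``r_vdw + probe`` is sampled at
    ``n_points`` quasi-uniform points; a point is occluded if it falls
    inside any neighbour's expanded sphere.  Per-residue sums are reported
    for side-chain atoms (everything beyond and including C-beta,
    hydrogens excluded) and for the whole residue.
    """
    atoms = _coerce_atoms(atoms)
    table = dict(VDW_RADII)
    if radii:
        table.update(radii)
    try:
        rv = np.array([table[e] for e in atoms.elements])
    except KeyError as exc:
        raise UnknownElementError(
            f"element {exc.args[0]!r} not in radius table; pass radii=")
    n = len(atoms)
    i = np.arange(n_points) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n_points)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * i
    unit = np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi), np.cos(phi)])
    R = rv + probe
    tree = cKDTree(atoms.coords)
    rmax = rv.max()
    sasa = np.empty(n)
    for k in range(n):
        pts = atoms.coords[k] + R[k] * unit
        nbr = tree.query_ball_point(atoms.coords[k],
                                    R[k] + rmax + probe)
        nbr = [j for j in nbr if j != k]
        if nbr:
            d = np.linalg.norm(
                pts[:, None, :] - atoms.coords[nbr][None, :, :], axis=2)
            buried = np.any(d < R[nbr][None, :], axis=1)
            acc = np.count_nonzero(~buried)
        else:
            acc = n_points
        sasa[k] = 4.0 * math.pi * R[k] ** 2 * acc / n_points
    rows = []
    keyarr = list(zip(atoms.chains, atoms.resseq, atoms.resnames))
    for key in dict.fromkeys(keyarr):
        mask = np.array([ka == key for ka in keyarr])
        side = mask & ~np.isin(atoms.names.astype(str), list(_BACKBONE)) \
            & (atoms.elements != "H")
        rows.append({"chain": key[0], "resnum": int(key[1]),
                     "resname": key[2],
                     "sidechain_sasa": float(sasa[side].sum()),
                     "total_sasa": float(sasa[mask].sum())})
    return SasaResult(atom_sasa=sasa, table=pd.DataFrame(rows),
                      probe=probe, n_points=n_points)


def _coerce_atoms(atoms) -> AtomSet:
    if isinstance(atoms, AtomSet):
        return atoms
    return AtomSet.from_gemmi(atoms)


@dataclass(frozen=True)
class ReferenceDistribution:
    """Empirical SASA reference: sorted values for one residue type."""

    residue_type: str
    values: np.ndarray
    source: str = ""

    def __post_init__(self):
        v = np.sort(np.asarray(self.values, dtype=float))
        if len(v) == 0:
            raise ArgumentError("empty reference distribution")
        object.__setattr__(self, "values", v)

    def __len__(self):
        return len(self.values)


def load_reference(path, residue_type: str = "TRP") -> ReferenceDistribution:
    """Read a one-value-per-line reference distribution file."""
    vals = [float(line.split()[0]) for line in open(path)
            if line.strip() and not line.startswith("#")]
    return ReferenceDistribution(residue_type=residue_type,
                                 values=np.array(vals), source=str(path))


def sasa_percentile(value: float, ref: ReferenceDistribution) -> float:
    """Empirical percentile of ``value`` with the midpoint convention:
    100 * (#below + 0.5 * #equal) / n."""
    v = ref.values
    below = int(np.count_nonzero(v < value))
    equal = int(np.count_nonzero(v == value))
    return 100.0 * (below + 0.5 * equal) / len(v)


def interface_contacts(molA, molB, cutoff: float = 3.5) -> pd.DataFrame:
    """Polar contacts across an interface.

    All nitrogen/oxygen/sulfur atom pairs between the two sets with
    distance <= ``cutoff`` (A), as a table of
    (res_a, atom_a, res_b, atom_b, distance).
    """
    A = _coerce_atoms(molA if not isinstance(molA, Molecule) else molA.atoms)
    B = _coerce_atoms(molB if not isinstance(molB, Molecule) else molB.atoms)
    if len(A) == 0 or len(B) == 0:
        raise ArgumentError("both atom sets must be non-empty")
    polar = {"N", "O", "S"}
    ia = np.nonzero([e in polar for e in A.elements])[0]
    ib = np.nonzero([e in polar for e in B.elements])[0]
    rows = []
    if len(ia) and len(ib):
        ta = cKDTree(A.coords[ia])
        tb = cKDTree(B.coords[ib])
        for pa, pb_list in enumerate(ta.query_ball_tree(tb, cutoff)):
            for pb in pb_list:
                i, j = ia[pa], ib[pb]
                d = float(np.linalg.norm(A.coords[i] - B.coords[j]))
                rows.append({
                    "res_a": f"{A.resnames[i]}{A.resseq[i]}",
                    "atom_a": A.names[i],
                    "res_b": f"{B.resnames[j]}{B.resseq[j]}",
                    "atom_b": B.names[j],
                    "distance": d})
    return pd.DataFrame(rows, columns=["res_a", "atom_a", "res_b",
                                       "atom_b", "distance"])
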