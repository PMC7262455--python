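"""Synthetic scattering datasets with known ground truth.

Every generator returns its dataset together with a :class:`GroundTruth`
record (true Rg, Dmax, generating conformer or shape parameters, seed), so
any estimator in the pipeline can be scored for bias without access to
experimental data.  The defaults emulate the study conditions of the
TDP-43 SEC-SAXS experiment: 500 log-spaced q points over 0.0084-0.35 1/A
and Gaussian noise with sigma(q) = a*I(q) + floor, a = 1%, which yields
Guinier Rg uncertainties of a few tenths of an Angstrom on an Rg ~ 41 A
particle -- the order of the reported +/- 0.4 A SEM.

A synthetic crystal stand-in for the NTD filament lattice is also provided
(:func:`make_synthetic_filament_crystal`) for exercising the
crystal-symmetry pipeline without deposited coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ArgumentError
from .model_builder import (
    ChainLayout,
    Conformer,
    LinkerSpec,
    assemble_conformer,
    default_layout,
)
from .profile_calc import BeadModel, coords_metrics, debye_profile, sphere_form_factor
from .saxs_io import FrameSeries, ScatteringCurve

__all__ = [
    "NoiseModel",
    "GroundTruth",
    "default_qgrid",
    "simulate_noise",
    "make_sphere_dataset",
    "make_flexible_dataset",
    "make_sec_series",
    "make_synthetic_filament_crystal",
]


def default_qgrid(n: int = 500, qmin: float = 0.0084,
                  qmax: float = 0.35) -> np.ndarray:
    """Log-spaced q grid over the experimental angular range (1/A)."""
    return np.geomspace(qmin, qmax, n)


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian noise with sigma(q) = a * I(q) + floor.

    ``a`` is the relative amplitude (default 1%); ``floor`` an absolute
    term (default 1e-6 of the curve's maximum, applied at noise time).
    """

    a: float = 0.01
    floor: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.a < 0:
            raise ArgumentError("relative amplitude a must be >= 0")

    def sigma(self, I: np.ndarray) -> np.ndarray:
        floor = 1e-6 * float(np.max(I)) if self.floor is None else self.floor
        s = self.a * np.abs(I) + floor
        if np.any(s <= 0):
            raise ArgumentError("sigma must be positive everywhere; "
                                "set a > 0 or floor > 0")
        return s


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually produced, for scoring estimators."""

    generator: str
    Rg: float
    Dmax: float
    seed: int
    params: dict = field(default_factory=dict)
    conformer: Conformer | None = None


def simulate_noise(ideal: ScatteringCurve, noise: NoiseModel) -> ScatteringCurve:
    """Add seeded Gaussian noise to an ideal curve and attach sigma."""
    rng = np.random.default_rng(noise.seed)
    s = noise.sigma(ideal.I)
    I = ideal.I + rng.normal(0.0, 1.0, size=len(s)) * s
    return ScatteringCurve(q=ideal.q, I=I, sigma=s,
                           label=f"{ideal.label}+noise(a={noise.a})")


def make_sphere_dataset(R: float, qgrid=None,
                        noise: NoiseModel | None = None):
    """Noisy curve of a homogeneous sphere, I(0) normalized to 1.

    Ground truth: Rg = sqrt(3/5) R, Dmax = 2R.
    """
    if R <= 0:
        raise ArgumentError("R must be positive")
    q = default_qgrid() if qgrid is None else np.asarray(qgrid, float)
    ideal = sphere_form_factor(R, q)
    noise = NoiseModel() if noise is None else noise
    curve = simulate_noise(ideal, noise)
    truth = GroundTruth(generator="sphere", Rg=math.sqrt(3.0 / 5.0) * R,
                        Dmax=2.0 * R, seed=noise.seed, params={"R": R})
    return curve, truth


def make_flexible_dataset(layout: ChainLayout | None = None, seed: int = 0,
                          qgrid=None, noise: NoiseModel | None = None,
                          conformer: Conformer | None = None):
    """Noisy Debye curve of one rigid-domain + flexible-linker conformer.

    Assembles a fresh conformer from ``layout`` (or uses the one given),
    computes its exact Debye profile on the experimental q range, and
    applies the noise model.  The ground truth stores the conformer.
    """
    if conformer is None:
        layout = default_layout() if layout is None else layout
        conformer = assemble_conformer(layout, seed=seed)
    q = default_qgrid() if qgrid is None else np.asarray(qgrid, float)
    ideal = debye_profile(BeadModel.from_conformer(conformer), q)
    noise = NoiseModel(seed=seed) if noise is None else noise
    curve = simulate_noise(ideal, noise)
    truth = GroundTruth(generator="flexible-chain", Rg=conformer.Rg,
                        Dmax=conformer.Dmax, seed=seed, conformer=conformer)
    return curve, truth


def _select_conformer(layout, target_rg, rng, tol=1.5, max_tries=12):
    """Best-of-batch conformer with Rg near ``target_rg`` (A)."""
    from .exceptions import SamplingFailureError

    best = None
    for _ in range(max_tries):
        try:
            c = assemble_conformer(layout,
                                   seed=int(rng.integers(0, 2**31 - 1)))
        except SamplingFailureError:
            continue
        if best is None or abs(c.Rg - target_rg) < abs(best.Rg - target_rg):
            best = c
        if abs(best.Rg - target_rg) < tol:
            break
    if best is None:
        raise SamplingFailureError(
            f"no conformer assembled in {max_tries} tries")
    return best


def make_sec_series(layout: ChainLayout | None = None, n_frames: int = 30,
                    rg_drift: tuple = (42.0, 39.0), seed: int = 0,
                    qgrid=None, noise: NoiseModel | None = None):
    """Synthetic SEC-SAXS elution with an imposed Rg drift.

    Per-frame conformers are drawn (best-of-batch selection) so that the
    expected Rg interpolates linearly between the two ``rg_drift``
    endpoints in Angstrom -- emulating the compaction observed between the
    first and last thirds of an elution peak.  All frames share one q grid
    and receive independent seeded noise.
    """
    if n_frames < 2:
        raise ArgumentError("n_frames must be >= 2")
    layout = default_layout() if layout is None else layout
    q = default_qgrid() if qgrid is None else np.asarray(qgrid, float)
    base = NoiseModel() if noise is None else noise
    rng = np.random.default_rng(seed)
    targets = np.linspace(rg_drift[0], rg_drift[1], n_frames)
    frames, truths = [], []
    for k, target in enumerate(targets):
        c = _select_conformer(layout, target, rng)
        ideal = debye_profile(BeadModel.from_conformer(c), q)
        nm = NoiseModel(a=base.a, floor=base.floor,
                        seed=int(rng.integers(0, 2**31 - 1)))
        frames.append(simulate_noise(ideal, nm))
        truths.append(GroundTruth(generator="sec-frame", Rg=c.Rg,
                                  Dmax=c.Dmax, seed=nm.seed, conformer=c,
                                  params={"target_Rg": float(target)}))
    return FrameSeries(frames), truths


# ---------------------------------------------------------------------------
# Synthetic crystal stand-in for the NTD filament lattice
# ---------------------------------------------------------------------------

def make_synthetic_filament_crystal(radius_com: float = 46.0,
                                    dphi_deg: float = 36.0,
                                    rise: float = 3.62,
                                    outer_radius: float = 92.0,
                                    n_asu: int = 5):
    """SYNTHETIC stand-in crystal for a head-to-tail helical filament.

    Builds a ``gemmi.Structure`` whose asymmetric unit holds ``n_asu``
    identical synthetic molecules lying on a helix (centre-of-mass radius
    ``radius_com``, azimuthal step ``dphi_deg``, axial rise ``rise`` per
    molecule) in space group P2_1 2_1 2_1 with the 2_1 screw along c
    continuing the filament, so that symmetry expansion yields a spiral
    with ``360/dphi_deg`` molecules per turn and pitch
    ``rise * 360/dphi_deg``.  Each molecule is an arc-shaped tube of
    pseudo-atoms dressed with a radial arm reaching ``outer_radius``.

    This is NOT a deposited structure: it reproduces published filament
    geometry so the symmetry-expansion, filament-tracing and helix-fitting
    machinery can be exercised without network access to the PDB archive.
    """
    import gemmi

    n_per_turn = 360.0 / dphi_deg
    pitch = rise * n_per_turn
    cell_c = rise * n_asu * 2  # one 2_1 screw step = n_asu molecules
    # a, b chosen so symmetry-related spirals (axes a/2 apart) stay clear
    # of each other's outer arms (2 * outer_radius) by a wide margin
    a_len = b_len = 420.0
    axis_x, axis_y = a_len / 4.0, 0.0  # the c-axis 2_1 screw of P212121

    # molecule template in helix coordinates (phi offset, z offset, radial)
    # arc tube: 18 stations over +/-17 deg with a 5-point cross at each
    arc_half_deg = 17.0
    stations = np.linspace(-arc_half_deg, arc_half_deg, 18)
    cross = [(0.0, 0.0), (2.5, 0.0), (-2.5, 0.0), (0.0, 2.5), (0.0, -2.5)]

    def molecule_atoms(phi0_deg, z0, r_body):
        pts = []
        for s in stations:
            phi = math.radians(phi0_deg + s)
            zc = z0 + (s / dphi_deg) * rise
            for dr, dz in cross:
                r = r_body + dr
                pts.append((axis_x + r * math.cos(phi),
                            axis_y + r * math.sin(phi), zc + dz))
        phi = math.radians(phi0_deg)
        for r in (60.0, 70.0, 80.0, outer_radius):
            pts.append((axis_x + r * math.cos(phi),
                        axis_y + r * math.sin(phi), z0))
        return np.array(pts)

    # choose the body radius so the molecule COM sits at radius_com
    r_body = radius_com
    for _ in range(8):
        m = molecule_atoms(0.0, 0.0, r_body)
        com = m.mean(axis=0)
        com_r = math.hypot(com[0] - axis_x, com[1] - axis_y)
        r_body += radius_com - com_r

    st = gemmi.Structure()
    st.name = "synthetic NTD-like filament crystal"
    st.cell = gemmi.UnitCell(a_len, b_len, cell_c, 90.0, 90.0, 90.0)
    st.spacegroup_hm = "P 21 21 21"
    model = gemmi.Model("1")
    for mi in range(n_asu):
        chain = gemmi.Chain(chr(ord("A") + mi))
        atoms = molecule_atoms(mi * dphi_deg, mi * rise, r_body)
        res = gemmi.Residue()
        res.name = "SYN"
        res.seqid = gemmi.SeqId(1, " ")
        for ai, (x, y, z) in enumerate(atoms):
            at = gemmi.Atom()
            at.name = f"C{ai + 1}"
            at.element = gemmi.Element("C")
            at.pos = gemmi.Position(x, y, z)
            at.occ = 1.0
            res.add_atom(at)
        chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    truth = {"molecules_per_turn": n_per_turn, "pitch": pitch,
             "radius_com": radius_com, "rise": rise,
             "outer_radius": outer_radius}
    return st, truth
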