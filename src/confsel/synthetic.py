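"""Synthetic input generation: structures, shifts, J couplings, RDCs, CSP tables.

Builds peptide backbones (N, H, CA, C, O, CB) with ideal covalent geometry
from backbone dihedrals, assembles two-helix peptides at a target
interhelical angle, and simulates every observable the analysis modules
consume, with Gaussian noise and full seed determinism.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from confsel.rdc import RDCRecord, RDCSet, SaupeTensor, nh_vectors, predict_rdc
from confsel.shifts import (
    AA1TO3,
    JCoupling,
    RandomCoilTable,
    ShiftRecord,
    ShiftTable,
    load_random_coil_j,
)
from confsel.structure import AtomRecord, Structure, fit_helix_axis, interhelical_angle

__all__ = [
    "PeptideSpec",
    "SimulationConfig",
    "STAT6_LIKE_SEQUENCE",
    "build_chain",
    "build_ideal_helix",
    "build_two_helix_peptide",
    "simulate_rdcs",
    "simulate_shifts",
    "simulate_csp",
]

# Synthetic 32-residue stand-in for a two-helix transactivation peptide
# (numbering 783-814): Gly termini, Trp785, Ile786/Ile790 flanking the first
# helical region, an LXXLL motif (802/805/806) inside the second, and three
# prolines in/near the linker.
STAT6_LIKE_SEQUENCE = "GAWIAAAIFAPLLPPTEAALAALLAEAAGAAG"

HELIX_PHI, HELIX_PSI = -57.0, -47.0
EXTENDED_PHI, EXTENDED_PSI = -120.0, 120.0

# idealized covalent geometry (lengths in Angstrom, angles in degrees)
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_B_C_O, _B_N_H = 1.231, 1.02
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O = 120.8


@dataclass(frozen=True)
class PeptideSpec:
    """Two-helix peptide specification with per-region helix populations."""

    sequence: str = STAT6_LIKE_SEQUENCE
    start_residue: int = 783
    helix1: tuple[int, int] = (786, 790)
    helix2: tuple[int, int] = (799, 808)
    linker: tuple[int, int] = (791, 798)
    p1: float = 0.1
    p2: float = 0.3
    target_theta: float = 134.0
    chain_id: str = "B"

    def __post_init__(self) -> None:
        for p in (self.p1, self.p2):
            if not 0.0 <= p <= 1.0:
                raise ValueError("helix populations must be in [0, 1]")
        end = self.start_residue + len(self.sequence) - 1
        for lo, hi in (self.helix1, self.helix2, self.linker):
            if not (self.start_residue <= lo <= hi <= end):
                raise ValueError(f"range {lo}-{hi} outside sequence {self.start_residue}-{end}")
        if set(range(*self.helix1)) & set(range(*self.helix2)):
            raise ValueError("helix ranges overlap")

    @property
    def residue_numbers(self) -> list[int]:
        return list(range(self.start_residue, self.start_residue + len(self.sequence)))

    def population(self, residue: int) -> float:
        if self.helix1[0] <= residue <= self.helix1[1]:
            return self.p1
        if self.helix2[0] <= residue <= self.helix2[1]:
            return self.p2
        return 0.0

    def residue_name(self, residue: int) -> str:
        return AA1TO3[self.sequence[residue - self.start_residue]]


@dataclass
class SimulationConfig:
    """Generator alignment tensor plus noise levels and the RNG seed."""

    tensor: SaupeTensor
    noise_rdc: float = 1.0
    noise_shift_h: float = 0.02
    noise_shift_heavy: float = 0.1
    noise_j: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.noise_rdc, self.noise_shift_h, self.noise_shift_heavy, self.noise_j):
            if v < 0:
                raise ValueError("noise parameters must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


# ---------------------------------------------------------------------------
# Backbone construction
# ---------------------------------------------------------------------------


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement: new atom bonded to c with given angle(b,c,new) and
    dihedral(a,b,c,new)."""
    theta = math.radians(angle_deg)
    chi = math.radians(dihedral_deg)
    d_local = np.array(
        [-bond * math.cos(theta), bond * math.sin(theta) * math.cos(chi), bond * math.sin(theta) * math.sin(chi)]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral (degrees) of the four points, IUPAC convention."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def _cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    # idealized tetrahedral CB from the backbone frame (L chirality)
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc + ca


def build_chain(
    sequence: str,
    phi: np.ndarray,
    psi: np.ndarray,
    start_residue: int = 1,
    chain_id: str = "A",
    omega: float = 180.0,
) -> Structure:
    """Build an all-ideal-geometry backbone (N, H, CA, C, O, CB) from dihedrals.

    ``phi[0]`` is unused (no preceding carbonyl); ``psi[-1]`` only orients the
    final carbonyl oxygen. Glycine gets no CB; the first residue gets no
    amide H.
    """
    nres = len(sequence)
    if nres == 0:
        raise ValueError("empty sequence")
    bad = [c for c in sequence if c not in AA1TO3]
    if bad:
        raise ValueError(f"invalid residue letters {sorted(set(bad))}")
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if phi.shape != (nres,) or psi.shape != (nres,):
        raise ValueError("phi/psi must have one value per residue")

    N = np.zeros((nres, 3))
    CA = np.zeros((nres, 3))
    C = np.zeros((nres, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = math.radians(180.0 - _A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, nres):
        N[i] = _place(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi[i - 1])
        CA[i] = _place(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, omega)
        C[i] = _place(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi[i])

    records: list[AtomRecord] = []
    for i, letter in enumerate(sequence):
        resnum = start_residue + i
        resname = AA1TO3[letter]

        def add(atom: str, pos: np.ndarray) -> None:
            records.append(AtomRecord(1, chain_id, resnum, resname, atom, pos))

        add("N", N[i])
        if i > 0:
            u1 = (C[i - 1] - N[i]) / np.linalg.norm(C[i - 1] - N[i])
            u2 = (CA[i] - N[i]) / np.linalg.norm(CA[i] - N[i])
            bis = u1 + u2
            add("H", N[i] - _B_N_H * bis / np.linalg.norm(bis))
        add("CA", CA[i])
        add("C", C[i])
        if i < nres - 1:
            o = _place(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi[i] + 180.0)
        else:
            o = _place(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi[i])
        add("O", o)
        if resname != "GLY":
            add("CB", _cb_position(N[i], CA[i], C[i]))
    return Structure(records, metadata=f"build_chain(n={nres}, start={start_residue})")


def build_ideal_helix(
    sequence: str,
    phi: float = HELIX_PHI,
    psi: float = HELIX_PSI,
    start_residue: int = 1,
    chain_id: str = "A",
) -> Structure:
    """Ideal-geometry chain at uniform dihedrals (alpha-helical by default)."""
    n = len(sequence)
    return build_chain(sequence, np.full(n, phi), np.full(n, psi), start_residue, chain_id)


def _theta_of(s: Structure, spec: PeptideSpec) -> float:
    h1 = fit_helix_axis(s, 1, spec.chain_id, *spec.helix1)
    h2 = fit_helix_axis(s, 1, spec.chain_id, *spec.helix2)
    return interhelical_angle(h1, h2)


def build_two_helix_peptide(spec: PeptideSpec, tolerance: float = 3.0, rng_seed: int = 0) -> Structure:
    """Two ideal helices joined by an extended linker, with the linker
    dihedrals adjusted so the interhelical angle hits ``spec.target_theta``.

    A bounded multi-start Nelder-Mead search over the linker phi/psi values
    is used; raises if no linker conformation within ``tolerance`` degrees is
    found.
    """
    from scipy.optimize import minimize

    if not 0.0 <= spec.target_theta <= 180.0:
        raise ValueError("target_theta must be in [0, 180]")
    nums = spec.residue_numbers
    phi = np.full(len(nums), EXTENDED_PHI)
    psi = np.full(len(nums), EXTENDED_PSI)
    for lo, hi in (spec.helix1, spec.helix2):
        for r in range(lo, hi + 1):
            i = r - spec.start_residue
            phi[i], psi[i] = HELIX_PHI, HELIX_PSI
    linker_idx = [r - spec.start_residue for r in range(spec.linker[0], spec.linker[1] + 1)]
    free = [i for i in linker_idx if not (phi[i] == HELIX_PHI and psi[i] == HELIX_PSI)]

    def build(x: np.ndarray) -> Structure:
        p, q = phi.copy(), psi.copy()
        p[free] = x[: len(free)]
        q[free] = x[len(free):]
        return build_chain(spec.sequence, p, q, spec.start_residue, spec.chain_id)

    def objective(x: np.ndarray) -> float:
        return (_theta_of(build(x), spec) - spec.target_theta) ** 2

    rng = np.random.default_rng(rng_seed)
    x0 = np.concatenate([phi[free], psi[free]])
    best_x, best_err = x0, math.sqrt(objective(x0))
    starts = [x0] + [x0 + rng.normal(0, 60.0, size=x0.size) for _ in range(11)]
    for start in starts:
        if best_err <= 0.25:
            break
        res = minimize(objective, start, method="Nelder-Mead", options={"maxiter": 400, "fatol": 0.01})
        err = math.sqrt(res.fun)
        if err < best_err:
            best_err, best_x = err, res.x
    if best_err > tolerance:
        raise ValueError(
            f"could not reach target interhelical angle {spec.target_theta} deg "
            f"(best deviation {best_err:.1f} deg after bounded search)"
        )
    out = build(best_x)
    out.metadata = f"two_helix_peptide(theta={_theta_of(out, spec):.1f} deg, target={spec.target_theta})"
    return out


# ---------------------------------------------------------------------------
# Observable simulation
# ---------------------------------------------------------------------------


def simulate_rdcs(
    s: Structure,
    cfg: SimulationConfig,
    residues: list[int] | None = None,
    model: int = 1,
    chain: str | None = None,
    scale_to_max: float | None = None,
) -> RDCSet:
    """Back-calculate N-H RDCs from the generator tensor and add Gaussian noise.

    ``scale_to_max`` rescales the tensor so the largest noiseless |D| equals
    the given value (e.g. 40 Hz for bound-state mimics, 8 Hz for free-state
    mimics).
    """
    if residues is None:
        residues = [r for r, _ in s.residues(chain=chain, model=model)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vectors = nh_vectors(s, model, residues, chain=chain)
    if not vectors:
        raise ValueError("no amide bond vectors available for RDC simulation")
    d = predict_rdc(vectors, cfg.tensor)
    if scale_to_max is not None:
        peak = max(abs(v) for v in d.values())
        if peak == 0:
            raise ValueError("cannot scale an all-zero RDC set")
        factor = scale_to_max / peak
        d = {k: v * factor for k, v in d.items()}
    rng = cfg.rng()
    noise = rng.normal(0.0, cfg.noise_rdc, size=len(d)) if cfg.noise_rdc > 0 else np.zeros(len(d))
    return RDCSet(
        [
            RDCRecord(residue_number=r, d_exp=float(d[r] + dn), error=cfg.noise_rdc or None)
            for r, dn in zip(d, noise)
        ]
    )


_HN_BASE, _N_BASE = 8.3, 119.0


def simulate_shifts(
    spec: PeptideSpec,
    rc: RandomCoilTable,
    cfg: SimulationConfig,
    j_helix: float = 4.0,
) -> tuple[ShiftTable, list[JCoupling]]:
    """Two-state shift and 3J tables from per-region helix populations.

    delta(i, atom) = rc + p(i) * full-helix secondary shift + noise;
    J(i) = p(i)*J_helix + (1-p(i))*J_coil + noise. Amide HN/N shifts are
    random-coil-like with a deterministic per-residue offset so that HSQC
    peaks are distinct.
    """
    rng = cfg.rng()
    j_coil = load_random_coil_j()
    records: list[ShiftRecord] = []
    couplings: list[JCoupling] = []
    for res in spec.residue_numbers:
        rt = spec.residue_name(res)
        p = spec.population(res)
        for atom in ("CA", "CB", "HA"):
            base = rc.rc(rt, atom)
            if base is None:
                continue
            full = rc.helix_full(rt, atom) or 0.0
            sigma = cfg.noise_shift_h if atom == "HA" else cfg.noise_shift_heavy
            val = base + p * full + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
            records.append(ShiftRecord(res, rt, atom, float(val)))
        # deterministic dispersion for the amide fingerprint (no amide H on Pro)
        if rt != "PRO":
            records.append(ShiftRecord(res, rt, "HN", _HN_BASE + 0.4 * math.sin(1.7 * res)))
        records.append(ShiftRecord(res, rt, "N", _N_BASE + 4.0 * math.cos(2.3 * res)))
        if rt != "PRO":
            j = p * j_helix + (1.0 - p) * j_coil[rt]
            if cfg.noise_j > 0:
                j += rng.normal(0.0, cfg.noise_j)
            couplings.append(JCoupling(res, float(np.clip(j, 0.0, 12.0))))
    return ShiftTable(records, state="synthetic-free"), couplings


def simulate_csp(
    base: ShiftTable,
    perturbed_residues: list[int],
    magnitudes: tuple[float, float] | dict[int, tuple[float, float]],
) -> tuple[ShiftTable, ShiftTable]:
    """Plant (ddHN, ddN) perturbations on a copy of *base*.

    Returns (free, bound) tables; running :func:`confsel.shifts.csp` on the
    pair recovers the planted weighted-average perturbations exactly.
    """
    missing = [r for r in perturbed_residues if base.get(r, "HN") is None or base.get(r, "N") is None]
    if missing:
        raise ValueError(f"perturbed residues missing amide shifts in base table: {missing}")
    if isinstance(magnitudes, tuple):
        magnitudes = {r: magnitudes for r in perturbed_residues}
    bound_records = []
    for rec in base.records:
        if rec.residue_number in perturbed_residues and rec.atom in ("HN", "N"):
            d_hn, d_n = magnitudes[rec.residue_number]
            delta = d_hn if rec.atom == "HN" else d_n
            bound_records.append(ShiftRecord(rec.residue_number, rec.residue_name, rec.atom, rec.shift + delta))
        else:
            bound_records.append(rec)
    free = ShiftTable(list(base.records), state="free")
    bound = ShiftTable(bound_records, state="bound")
    return free, bound
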