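"""Multi-model coordinate handling, helix geometry and RMSD machinery.

Structures are stored as flat, immutable-ish arrays of atom records with
author residue numbering preserved. Helix axes are fitted as the principal
component of the CA trace, sign-fixed to point from the N- to the C-terminal
end of the segment, which is robust even for one-turn (5-residue) helices.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "HelixSegment",
    "read_pdb",
    "write_pdb",
    "fit_helix_axis",
    "interhelical_angle",
    "rotate_segment",
    "backbone_rmsd",
    "kabsch_rotation",
    "superpose",
    "pairwise_rmsd_matrix",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass(frozen=True)
class AtomRecord:
    """One atom in one model, author numbering retained."""

    model_index: int
    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got shape {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")
        object.__setattr__(self, "position", pos)
        if self.model_index < 1:
            raise ValueError("model_index must be >= 1")


class Structure:
    """A (possibly multi-model) set of atoms.

    Parameters
    ----------
    atoms:
        Iterable of :class:`AtomRecord`. The key
        ``(model_index, chain_id, residue_number, atom_name)`` must be unique.
    metadata:
        Free-text provenance string.
    """

    def __init__(self, atoms: Iterable[AtomRecord], metadata: str = "") -> None:
        atoms = list(atoms)
        if not atoms:
            raise ValueError("Structure requires at least one atom")
        self.metadata = metadata
        self._model = np.array([a.model_index for a in atoms], dtype=int)
        self._chain = np.array([a.chain_id for a in atoms], dtype=object)
        self._resnum = np.array([a.residue_number for a in atoms], dtype=int)
        self._resname = np.array([a.residue_name for a in atoms], dtype=object)
        self._atname = np.array([a.atom_name for a in atoms], dtype=object)
        self._xyz = np.array([a.position for a in atoms], dtype=float)
        keys = list(zip(self._model, self._chain, self._resnum, self._atname))
        if len(set(keys)) != len(keys):
            seen: set = set()
            for k in keys:
                if k in seen:
                    raise ValueError(f"duplicate atom key {k}")
                seen.add(k)
        self._index = {k: i for i, k in enumerate(keys)}

    # -- basic introspection -------------------------------------------------

    @property
    def models(self) -> list[int]:
        """Ordered list of distinct model indices."""
        out: list[int] = []
        for m in self._model:
            if not out or out[-1] != m:
                if m in out:
                    raise ValueError("model blocks are interleaved")
                out.append(int(m))
        return out

    @property
    def n_models(self) -> int:
        return len(set(self._model.tolist()))

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self._chain:
            seen.setdefault(str(c), None)
        return list(seen)

    def __len__(self) -> int:
        return len(self._model)

    def atom_records(self) -> Iterator[AtomRecord]:
        for i in range(len(self)):
            yield AtomRecord(
                int(self._model[i]),
                str(self._chain[i]),
                int(self._resnum[i]),
                str(self._resname[i]),
                str(self._atname[i]),
                self._xyz[i].copy(),
            )

    def residues(self, chain: str | None = None, model: int | None = None) -> list[tuple[int, str]]:
        """Distinct (residue_number, residue_name) pairs, in file order."""
        mask = self._mask(model=model, chain=chain)
        out: dict[tuple[int, str], None] = {}
        for rn, rt in zip(self._resnum[mask], self._resname[mask]):
            out.setdefault((int(rn), str(rt)), None)
        return list(out)

    # -- selection -----------------------------------------------------------

    def _mask(
        self,
        model: int | None = None,
        chain: str | None = None,
        residues: Sequence[int] | None = None,
        atom_names: Sequence[str] | None = None,
    ) -> np.ndarray:
        mask = np.ones(len(self), dtype=bool)
        if model is not None:
            mask &= self._model == model
        if chain is not None:
            mask &= self._chain == chain
        if residues is not None:
            mask &= np.isin(self._resnum, list(residues))
        if atom_names is not None:
            mask &= np.isin(self._atname, list(atom_names))
        return mask

    def coords(
        self,
        model: int | None = None,
        chain: str | None = None,
        residues: Sequence[int] | None = None,
        atom_names: Sequence[str] | None = None,
    ) -> np.ndarray:
        """Coordinate array (n, 3) for the selection, in stable atom order."""
        return self._xyz[self._mask(model, chain, residues, atom_names)]

    def position(self, model: int, chain: str, residue: int, atom: str) -> np.ndarray:
        try:
            return self._xyz[self._index[(model, chain, residue, atom)]].copy()
        except KeyError:
            raise KeyError(f"no atom {atom} in model {model} chain {chain} residue {residue}") from None

    def has_atom(self, model: int, chain: str, residue: int, atom: str) -> bool:
        return (model, chain, residue, atom) in self._index

    def extract_model(self, model: int) -> "Structure":
        mask = self._mask(model=model)
        if not mask.any():
            raise ValueError(f"model {model} not present (have {self.models})")
        recs = [
            AtomRecord(1, str(c), int(rn), str(rt), str(an), xyz)
            for c, rn, rt, an, xyz in zip(
                self._chain[mask], self._resnum[mask], self._resname[mask], self._atname[mask], self._xyz[mask]
            )
        ]
        return Structure(recs, metadata=f"{self.metadata} [model {model}]".strip())

    def with_coords(self, xyz: np.ndarray) -> "Structure":
        """Copy of this structure with all coordinates replaced (same atom order)."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != self._xyz.shape:
            raise ValueError(f"coordinate shape {xyz.shape} != {self._xyz.shape}")
        new = Structure.__new__(Structure)
        new.metadata = self.metadata
        new._model = self._model
        new._chain = self._chain
        new._resnum = self._resnum
        new._resname = self._resname
        new._atname = self._atname
        new._xyz = xyz.copy()
        new._index = self._index
        return new

    @property
    def xyz(self) -> np.ndarray:
        return self._xyz.copy()

    def validate(self) -> None:
        """Check multi-model consistency and residue-number monotonicity."""
        models = self.models
        ref = None
        for m in models:
            mask = self._mask(model=m)
            keyset = set(zip(self._chain[mask], self._resnum[mask], self._atname[mask]))
            if ref is None:
                ref = keyset
            elif keyset != ref:
                raise ValueError(f"model {m} atom set differs from model {models[0]}")
        for m in models:
            for ch in self.chains:
                mask = self._mask(model=m, chain=ch)
                rn = self._resnum[mask]
                # strictly increasing over residue boundaries
                boundaries = rn[np.r_[True, rn[1:] != rn[:-1]]]
                if np.any(np.diff(boundaries) <= 0):
                    raise ValueError(f"residue numbering not strictly increasing in chain {ch}")


@dataclass(frozen=True)
class HelixSegment:
    """A fitted helix: chain, residue span, unit axis (N→C) and CA centroid."""

    chain_id: str
    start_residue: int
    end_residue: int
    axis: np.ndarray
    centroid: np.ndarray

    def __post_init__(self) -> None:
        if self.start_residue > self.end_residue:
            raise ValueError("start_residue must be <= end_residue")
        axis = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
            raise ValueError("axis must be a unit vector")
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float))


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------


def read_pdb(path, model_selection: str | int = "all") -> Structure:
    """Read a (multi-model) PDB file into a :class:`Structure`.

    HETATM records and waters are excluded. Author residue numbering is kept.

    Parameters
    ----------
    model_selection:
        ``"all"`` (default), ``"first"``, or a 1-based model index.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio = parser.get_structure("s", str(path))
    except PDBConstructionException as exc:
        raise ValueError(f"PDB format error in {path}: {exc}") from exc

    records: list[AtomRecord] = []
    for model in bio:
        midx = model.serial_num if model.serial_num >= 1 else model.id + 1
        for chain in model:
            for residue in chain:
                hetflag, resseq, _icode = residue.id
                if hetflag.strip() or residue.resname.strip() in _WATER_NAMES:
                    continue
                for atom in residue:
                    records.append(
                        AtomRecord(
                            model_index=midx,
                            chain_id=chain.id if chain.id.strip() else "A",
                            residue_number=int(resseq),
                            residue_name=residue.resname.strip(),
                            atom_name=atom.get_name(),
                            position=np.asarray(atom.get_coord(), dtype=float),
                        )
                    )
    if not records:
        raise ValueError(f"no ATOM records found in {path}")
    s = Structure(records, metadata=f"read_pdb({path})")
    if model_selection == "all":
        return s
    if model_selection == "first":
        return s.extract_model(s.models[0])
    if isinstance(model_selection, int):
        return s.extract_model(model_selection)
    raise ValueError(f"bad model_selection {model_selection!r}")


_PDB_ATOM_FMT = (
    "ATOM  {serial:>5d} {name:<4s}{altloc:1s}{resname:>3s} {chain:1s}"
    "{resseq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2s}\n"
)


def _format_atom_name(name: str) -> str:
    # PDB columns 13-16: element right-justified in 13-14 for 1-letter elements
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def write_pdb(s: Structure, path) -> None:
    """Write a Structure as multi-model PDB text (ATOM/MODEL/ENDMDL/END)."""
    buf = io.StringIO()
    models = s.models
    multi = len(models) > 1
    for m in models:
        if multi:
            buf.write(f"MODEL     {m:>4d}\n")
        serial = 1
        mask = s._mask(model=m)
        for c, rn, rt, an, xyz in zip(
            s._chain[mask], s._resnum[mask], s._resname[mask], s._atname[mask], s._xyz[mask]
        ):
            element = str(an)[0] if not str(an)[0].isdigit() else str(an)[1]
            buf.write(
                _PDB_ATOM_FMT.format(
                    serial=serial,
                    name=_format_atom_name(str(an)),
                    altloc=" ",
                    resname=str(rt),
                    chain=str(c),
                    resseq=int(rn),
                    icode=" ",
                    x=xyz[0],
                    y=xyz[1],
                    z=xyz[2],
                    occ=1.0,
                    b=0.0,
                    element=element,
                )
            )
            serial += 1
        if multi:
            buf.write("ENDMDL\n")
    buf.write("END\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Helix geometry
# ---------------------------------------------------------------------------


def fit_helix_axis(s: Structure, model: int, chain: str, start: int, end: int) -> HelixSegment:
    """Fit a helix axis to the CA trace of ``chain:start-end`` in one model.

    The axis is the principal component of the centered CA coordinates,
    sign-fixed so that it points from the N-terminal towards the C-terminal
    end of the segment.
    """
    residues = list(range(start, end + 1))
    missing = [r for r in residues if not s.has_atom(model, chain, r, "CA")]
    if missing:
        raise ValueError(f"missing CA atoms for residues {missing} (model {model}, chain {chain})")
    if len(residues) < 4:
        raise ValueError("helix axis fit requires >= 4 residues")
    ca = np.array([s.position(model, chain, r, "CA") for r in residues])
    centroid = ca.mean(axis=0)
    centered = ca - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    axis = axis / np.linalg.norm(axis)
    return HelixSegment(chain_id=chain, start_residue=start, end_residue=end, axis=axis, centroid=centroid)


def interhelical_angle(h1: HelixSegment, h2: HelixSegment) -> float:
    """Angle in degrees between two N→C helix axes, in [0, 180]."""
    n1 = np.linalg.norm(h1.axis)
    n2 = np.linalg.norm(h2.axis)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("zero-length helix axis")
    cosang = float(np.clip(np.dot(h1.axis, h2.axis) / (n1 * n2), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def perpendicular_axes(ref_axis: np.ndarray, n: int = 4, anchor: np.ndarray | None = None) -> np.ndarray:
    """``n`` evenly spaced unit directions in the plane normal to *ref_axis*.

    The in-plane zero direction is the projection of *anchor* (when given and
    non-degenerate) onto the plane, otherwise the projected global +z axis
    (+x when ref is near z). Anchoring on the rotated segment's own axis makes
    the direction set intrinsic to the molecule: direction 3 (90 deg in-plane)
    is then perpendicular to both helix axes.
    """
    a = np.asarray(ref_axis, dtype=float)
    a = a / np.linalg.norm(a)
    e = None
    if anchor is not None:
        cand = np.asarray(anchor, dtype=float)
        if np.linalg.norm(cand - np.dot(cand, a) * a) > 1e-6:
            e = cand
    if e is None:
        e = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(e, a)) > 0.9:
            e = np.array([1.0, 0.0, 0.0])
    u = e - np.dot(e, a) * a
    u /= np.linalg.norm(u)
    v = np.cross(a, u)
    angles = np.arange(n) * (np.pi / n)
    return np.array([np.cos(t) * u + np.sin(t) * v for t in angles])


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about *axis* by *angle_deg* (Rodrigues)."""
    if not np.isfinite(angle_deg):
        raise ValueError("rotation angle must be finite")
    from scipy.spatial.transform import Rotation

    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix()


def rotate_segment(
    s: Structure,
    seg: HelixSegment,
    ref: HelixSegment,
    angle_deg: float,
    axis_index: int = 1,
) -> Structure:
    """Rigidly rotate the residues of *seg* about an axis perpendicular to *ref*.

    ``axis_index`` (1..4) selects one of four evenly spaced perpendicular
    directions (0°, 45°, 90°, 135° in the plane normal to ``ref.axis``,
    anchored on ``seg.axis`` so that index 3 is perpendicular to both helix
    axes and shifts the interhelical angle by exactly the rotation angle);
    the rotation axis passes through the CA centroid of *seg*, so the
    segment's internal geometry is exactly preserved. Rotating by ``-angle``
    with the same (original) segments inverts the operation exactly.
    """
    if seg.chain_id != ref.chain_id:
        raise ValueError("segments must belong to the same chain")
    if axis_index not in (1, 2, 3, 4):
        raise ValueError("axis_index must be in 1..4")
    direction = perpendicular_axes(ref.axis, 4, anchor=seg.axis)[axis_index - 1]
    R = rotation_matrix(direction, angle_deg)
    mask = s._mask(chain=seg.chain_id, residues=range(seg.start_residue, seg.end_residue + 1))
    xyz = s.xyz
    xyz[mask] = (xyz[mask] - seg.centroid) @ R.T + seg.centroid
    out = s.with_coords(xyz)
    out.metadata = f"{s.metadata} [rotated {seg.start_residue}-{seg.end_residue} by {angle_deg} deg, axis {axis_index}]".strip()
    return out


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation (proper) carrying centered *mobile* onto centered *target*."""
    H = mobile.T @ target
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares superposition; returns transformed mobile coords and RMSD."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    R = kabsch_rotation(mobile - mc, target - tc)
    moved = (mobile - mc) @ R.T + tc
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return moved, rmsd


def pairwise_rmsd_matrix(coords: np.ndarray, block: int = 64) -> np.ndarray:
    """All-pairs optimal-superposition RMSD for conformer coords (M, N, 3).

    Uses batched 3x3 SVDs; memory bounded by ``block`` x M pair blocks.
    """
    coords = np.asarray(coords, dtype=float)
    M, N, _ = coords.shape
    centered = coords - coords.mean(axis=1, keepdims=True)
    e0 = np.einsum("mni,mni->m", centered, centered)
    out = np.zeros((M, M))
    for i0 in range(0, M, block):
        i1 = min(i0 + block, M)
        A = centered[i0:i1]  # (b, N, 3)
        # cross-covariances for all pairs in the block row: (b, M, 3, 3)
        H = np.einsum("bni,mnj->bmij", A, centered)
        U, S, Vt = np.linalg.svd(H)
        det = np.linalg.det(np.einsum("bmij,bmjk->bmik", U, Vt))
        S[..., -1] *= np.sign(det)
        msd = (e0[i0:i1, None] + e0[None, :] - 2.0 * S.sum(axis=-1)) / N
        out[i0:i1] = np.sqrt(np.maximum(msd, 0.0))
    np.fill_diagonal(out, 0.0)
    return out


def model_coords(
    s: Structure,
    chain: str | None = None,
    residues: Sequence[int] | None = None,
    atom_names: Sequence[str] = BACKBONE_ATOMS,
) -> np.ndarray:
    """Stacked per-model coordinates (n_models, n_atoms, 3) for a selection."""
    models = s.models
    sel = [s.coords(model=m, chain=chain, residues=residues, atom_names=atom_names) for m in models]
    n = {c.shape[0] for c in sel}
    if len(n) != 1:
        raise ValueError("selection differs between models")
    return np.stack(sel)


def backbone_rmsd(
    s: Structure,
    residue_range: tuple[int, int],
    chain: str,
    mode: str = "pairwise_mean",
) -> float:
    """Ensemble backbone (N, CA, C, O) RMSD over a residue range, in Å.

    ``pairwise_mean``: mean of optimal-superposition RMSDs over all model
    pairs. ``to_mean``: models superposed onto their iterated mean structure;
    the mean RMSD to that mean structure is returned.
    """
    if s.n_models < 2:
        raise ValueError("ensemble RMSD requires >= 2 models")
    start, end = residue_range
    coords = model_coords(s, chain=chain, residues=range(start, end + 1), atom_names=BACKBONE_ATOMS)
    if coords.shape[1] == 0:
        raise ValueError(f"no backbone atoms in range {start}-{end} chain {chain}")
    if mode == "pairwise_mean":
        D = pairwise_rmsd_matrix(coords)
        iu = np.triu_indices(len(D), k=1)
        return float(D[iu].mean())
    if mode == "to_mean":
        ref = coords[0]
        aligned = np.array([superpose(c, ref)[0] for c in coords])
        for _ in range(3):
            mean = aligned.mean(axis=0)
            aligned = np.array([superpose(c, mean)[0] for c in aligned])
        mean = aligned.mean(axis=0)
        rmsds = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=1))
        return float(rmsds.mean())
    raise ValueError(f"unknown mode {mode!r}")


def helix_segments_table(segments: Iterable[tuple[int, HelixSegment]], thetas: dict[int, float] | None = None):
    """Tabulate fitted segments as a DataFrame (TSV-ready)."""
    import pandas as pd

    rows = []
    for model, seg in segments:
        rows.append(
            {
                "model": model,
                "chain": seg.chain_id,
                "start": seg.start_residue,
                "end": seg.end_residue,
                "axis_x": seg.axis[0],
                "axis_y": seg.axis[1],
                "axis_z": seg.axis[2],
                "theta_deg": (thetas or {}).get(model, float("nan")),
            }
        )
    return pd.DataFrame(rows)
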