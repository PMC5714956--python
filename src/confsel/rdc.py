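"""Residual dipolar coupling analysis: tensor fitting, back-calculation, Q, NSP.

All RDCs are one-bond amide (N-H) couplings in Hz. The dipolar prefactor is
absorbed into the Saupe matrix, so the fitted tensor is directly in Hz; axial
magnitude Da and rhombicity R are derived from the eigenvalues for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from confsel.structure import Structure

__all__ = [
    "RDCRecord",
    "RDCSet",
    "SaupeTensor",
    "RDCFitResult",
    "nh_vectors",
    "predict_rdc",
    "fit_tensor_svd",
    "q_factor",
    "pearson_r",
    "nsp",
    "read_rdc_tsv",
    "write_rdc_tsv",
]


@dataclass(frozen=True)
class RDCRecord:
    residue_number: int
    d_exp: float
    atom_pair: tuple[str, str] = ("N", "H")
    error: float | None = None

    def __post_init__(self) -> None:
        if abs(self.d_exp) >= 60.0:
            raise ValueError(f"|d_exp| = {abs(self.d_exp):.1f} Hz outside sanity window (< 60 Hz)")


class RDCSet:
    """Ordered collection of per-residue N-H RDCs."""

    def __init__(self, records: Sequence[RDCRecord]) -> None:
        self.records = list(records)
        nums = [r.residue_number for r in self.records]
        if len(set(nums)) != len(nums):
            raise ValueError("duplicate residue numbers in RDC set")
        self._by_residue = {r.residue_number: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def residues(self) -> list[int]:
        return [r.residue_number for r in self.records]

    def d_exp(self, residues: Sequence[int] | None = None) -> np.ndarray:
        residues = self.residues if residues is None else list(residues)
        return np.array([self._by_residue[r].d_exp for r in residues], dtype=float)

    def subset(self, residues: Sequence[int]) -> "RDCSet":
        return RDCSet([self._by_residue[r] for r in residues if r in self._by_residue])

    def __contains__(self, residue: int) -> bool:
        return residue in self._by_residue


def _derived(S: np.ndarray) -> tuple[float, float, np.ndarray, np.ndarray]:
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(np.abs(evals))  # |Sxx| <= |Syy| <= |Szz|
    evals = evals[order]
    evecs = evecs[:, order]
    lx, ly, lz = evals
    da = lz / 2.0
    dr = (lx - ly) / 3.0
    rhombicity = abs(dr / da) if da != 0 else 0.0
    return da, rhombicity, evals, evecs


@dataclass(frozen=True)
class SaupeTensor:
    """3x3 symmetric traceless alignment matrix (units: Hz, prefactor absorbed)."""

    S: np.ndarray

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        if S.shape != (3, 3):
            raise ValueError("Saupe matrix must be 3x3")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("Saupe matrix must be symmetric")
        if abs(np.trace(S)) > 1e-10 * max(1.0, float(np.abs(S).max())):
            raise ValueError("Saupe matrix must be traceless")
        object.__setattr__(self, "S", S)

    @classmethod
    def from_elements(cls, sxx: float, syy: float, sxy: float, sxz: float, syz: float) -> "SaupeTensor":
        szz = -sxx - syy
        return cls(np.array([[sxx, sxy, sxz], [sxy, syy, syz], [sxz, syz, szz]]))

    @classmethod
    def from_parameters(cls, da: float, rhombicity: float, euler_zyz_deg: tuple[float, float, float] = (0, 0, 0)) -> "SaupeTensor":
        """Construct from axial magnitude Da (Hz), rhombicity R and frame rotation."""
        from scipy.spatial.transform import Rotation

        dr = rhombicity * da
        diag = np.diag([-da + 1.5 * dr, -da - 1.5 * dr, 2.0 * da])
        R = Rotation.from_euler("zyz", euler_zyz_deg, degrees=True).as_matrix()
        return cls(R @ diag @ R.T)

    @property
    def elements(self) -> np.ndarray:
        """Independent elements (Sxx, Syy, Sxy, Sxz, Syz)."""
        S = self.S
        return np.array([S[0, 0], S[1, 1], S[0, 1], S[0, 2], S[1, 2]])

    @property
    def da(self) -> float:
        return _derived(self.S)[0]

    @property
    def rhombicity(self) -> float:
        return _derived(self.S)[1]

    @property
    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues ordered |Sxx| <= |Syy| <= |Szz|."""
        return _derived(self.S)[2]

    @property
    def principal_frame(self) -> np.ndarray:
        """Columns are the x, y, z principal axes (|Szz| largest)."""
        return _derived(self.S)[3]

    def frobenius_norm(self) -> float:
        return float(np.linalg.norm(self.S))

    def rotated(self, R: np.ndarray) -> "SaupeTensor":
        return SaupeTensor(R @ self.S @ R.T)


@dataclass
class RDCFitResult:
    tensor: SaupeTensor
    d_calc: dict[int, float]
    q: float
    pearson_r: float
    residues_used: list[int]
    condition_number: float = float("nan")
    warnings: list[str] = field(default_factory=list)

    def to_frame(self, rdcs: "RDCSet | None" = None) -> pd.DataFrame:
        rows = []
        for res, dc in sorted(self.d_calc.items()):
            de = rdcs._by_residue[res].d_exp if (rdcs is not None and res in rdcs) else np.nan
            rows.append({"residue_number": res, "d_exp_hz": de, "d_calc_hz": dc, "fitted": res in self.residues_used})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bond vectors and prediction
# ---------------------------------------------------------------------------

_AMIDE_H_NAMES = ("H", "HN")


def nh_vectors(s: Structure, model: int, residues: Sequence[int], chain: str | None = None) -> dict[int, np.ndarray]:
    """Unit N→H amide bond vectors per residue; prolines and residues with
    missing amide protons are excluded (reported via a UserWarning)."""
    if chain is None:
        chains = s.chains
        if len(chains) != 1:
            raise ValueError(f"chain must be given for multi-chain structure (chains: {chains})")
        chain = chains[0]
    out: dict[int, np.ndarray] = {}
    skipped_pro: list[int] = []
    skipped_h: list[int] = []
    restypes = dict(s.residues(chain=chain, model=model))
    for r in residues:
        if r not in restypes:
            skipped_h.append(r)
            continue
        if restypes[r] == "PRO":
            skipped_pro.append(r)
            continue
        if not s.has_atom(model, chain, r, "N"):
            skipped_h.append(r)
            continue
        hname = next((h for h in _AMIDE_H_NAMES if s.has_atom(model, chain, r, h)), None)
        if hname is None:
            skipped_h.append(r)
            continue
        v = s.position(model, chain, r, hname) - s.position(model, chain, r, "N")
        out[r] = v / np.linalg.norm(v)
    if skipped_pro or skipped_h:
        warnings.warn(
            f"nh_vectors: excluded prolines {skipped_pro}, missing N/H {skipped_h}",
            UserWarning,
            stacklevel=2,
        )
    return out


def predict_rdc(vectors: dict[int, np.ndarray] | np.ndarray, tensor: SaupeTensor, d_max: float = 1.0):
    """Back-calculate RDCs: D = d_max * v^T S v for unit bond vectors."""
    if isinstance(vectors, dict):
        keys = list(vectors)
        V = np.array([vectors[k] for k in keys], dtype=float)
        d = d_max * np.einsum("ni,ij,nj->n", V, tensor.S, V)
        return dict(zip(keys, d.tolist()))
    V = np.atleast_2d(np.asarray(vectors, dtype=float))
    return d_max * np.einsum("ni,ij,nj->n", V, tensor.S, V)


def predict_rdc_principal_frame(vectors: np.ndarray, tensor: SaupeTensor, d_max: float = 1.0) -> np.ndarray:
    """Equivalent prediction via Da/R in the tensor's principal frame.

    D = Da*(3cos^2θ - 1) + (3/2)*Dr*sin^2θ*cos2φ, with θ, φ polar angles of
    the bond vector in the principal frame. Used as an independent cross-check
    of :func:`predict_rdc`.
    """
    da, rhomb, evals, frame = _derived(tensor.S)
    dr = (evals[0] - evals[1]) / 3.0
    V = np.atleast_2d(np.asarray(vectors, dtype=float)) @ frame  # into principal frame
    cos_t = V[:, 2]
    sin2 = 1.0 - cos_t**2
    phi = np.arctan2(V[:, 1], V[:, 0])
    return d_max * (da * (3.0 * cos_t**2 - 1.0) + 1.5 * dr * sin2 * np.cos(2.0 * phi))


# ---------------------------------------------------------------------------
# Fitting and quality metrics
# ---------------------------------------------------------------------------


def design_matrix(vectors: np.ndarray) -> np.ndarray:
    """Direction-cosine design matrix mapping (Sxx, Syy, Sxy, Sxz, Syz) to D."""
    V = np.atleast_2d(np.asarray(vectors, dtype=float))
    x, y, z = V[:, 0], V[:, 1], V[:, 2]
    return np.column_stack([x * x - z * z, y * y - z * z, 2 * x * y, 2 * x * z, 2 * y * z])


CONDITION_WARN_THRESHOLD = 1e3


def q_factor(d_exp: Sequence[float], d_calc: Sequence[float]) -> float:
    """Normalized RMS deviation: rms(d_exp - d_calc) / rms(d_exp)."""
    de = np.asarray(d_exp, dtype=float)
    dc = np.asarray(d_calc, dtype=float)
    if de.size == 0 or de.shape != dc.shape:
        raise ValueError("d_exp and d_calc must be equal-length and nonempty")
    denom = np.sqrt(np.mean(de**2))
    if denom == 0:
        raise ValueError("all-zero experimental RDCs")
    return float(np.sqrt(np.mean((de - dc) ** 2)) / denom)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 points for a correlation")
    return float(np.corrcoef(x, y)[0, 1])


def fit_tensor_from_vectors(
    vectors: dict[int, np.ndarray],
    rdcs: RDCSet,
    residues_used: Sequence[int] | None = None,
    weights: dict[int, float] | None = None,
) -> tuple[SaupeTensor, list[int], float]:
    """SVD least-squares fit of the 5 Saupe elements from bond vectors + RDCs."""
    if residues_used is None:
        residues_used = [r for r in rdcs.residues if r in vectors]
    used = [r for r in residues_used if r in vectors and r in rdcs]
    if len(used) < 5:
        raise ValueError(f"need >= 5 usable RDCs to fit an alignment tensor, have {len(used)}")
    V = np.array([vectors[r] for r in used])
    A = design_matrix(V)
    b = rdcs.d_exp(used)
    if weights is not None:
        w = np.sqrt(np.array([weights.get(r, 1.0) for r in used]))
        A = A * w[:, None]
        b = b * w
    sol, _, _, sv = np.linalg.lstsq(A, b, rcond=None)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf")
    return SaupeTensor.from_elements(*sol), used, cond


def fit_tensor_svd(
    s: Structure,
    model: int,
    rdcs: RDCSet,
    residues_used: Sequence[int] | None = None,
    chain: str | None = None,
    evaluation_residues: Sequence[int] | None = None,
    weights: dict[int, float] | None = None,
) -> RDCFitResult:
    """Fit the alignment tensor on ``residues_used`` and back-calculate RDCs
    for every residue with an amide bond vector in the structure.

    Q and Pearson r are computed over ``evaluation_residues`` (those with
    experimental values; defaults to all residues present in ``rdcs`` that
    have coordinates).
    """
    all_res = [r for r, _ in s.residues(chain=chain if chain else None, model=model)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vectors = nh_vectors(s, model, all_res, chain=chain)
    tensor, used, cond = fit_tensor_from_vectors(vectors, rdcs, residues_used, weights)
    d_calc = predict_rdc(vectors, tensor)
    if evaluation_residues is None:
        eval_res = [r for r in rdcs.residues if r in d_calc]
    else:
        eval_res = [r for r in evaluation_residues if r in rdcs and r in d_calc]
    de = rdcs.d_exp(eval_res)
    dc = np.array([d_calc[r] for r in eval_res])
    warns = []
    if cond > CONDITION_WARN_THRESHOLD:
        warns.append(f"ill-conditioned design matrix (condition number {cond:.3g})")
    return RDCFitResult(
        tensor=tensor,
        d_calc=d_calc,
        q=q_factor(de, dc),
        pearson_r=pearson_r(de, dc),
        residues_used=used,
        condition_number=cond,
        warnings=warns,
    )


def nsp(t1: SaupeTensor, t2: SaupeTensor) -> float:
    """Normalized scalar product between two Saupe tensors.

    Frobenius inner product of the two 3x3 matrices, normalized to [-1, 1]:
    1 means identical alignment up to positive scale, -1 antiparallel, 0
    orthogonal alignment frames.
    """
    a = t1.S.ravel()
    b = t2.S.ravel()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("NSP undefined for a zero tensor")
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------


def read_rdc_tsv(path) -> RDCSet:
    """Read an RDC table.

    Accepts the native TSV (residue_number, atom1, atom2, d_exp_hz[, error_hz])
    or a two-column ``residue value`` whitespace table.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "d_exp_hz" in cols:
        recs = [
            RDCRecord(
                residue_number=int(row[cols["residue_number"]]),
                d_exp=float(row[cols["d_exp_hz"]]),
                atom_pair=(str(row[cols["atom1"]]), str(row[cols["atom2"]])) if "atom1" in cols else ("N", "H"),
                error=float(row[cols["error_hz"]]) if "error_hz" in cols and pd.notna(row[cols["error_hz"]]) else None,
            )
            for _, row in df.iterrows()
        ]
    elif df.shape[1] == 2:
        recs = [RDCRecord(int(a), float(b)) for a, b in df.itertuples(index=False)]
    else:
        raise ValueError(f"unrecognized RDC table layout in {path} (columns {list(df.columns)})")
    return RDCSet(recs)


def write_rdc_tsv(rdcs: RDCSet, path) -> None:
    rows = [
        {
            "residue_number": r.residue_number,
            "atom1": r.atom_pair[0],
            "atom2": r.atom_pair[1],
            "d_exp_hz": r.d_exp,
            "error_hz": r.error if r.error is not None else "",
        }
        for r in rdcs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def fit_report(result: RDCFitResult) -> dict:
    """JSON-ready summary of a tensor fit."""
    from scipy.spatial.transform import Rotation

    frame = result.tensor.principal_frame
    if np.linalg.det(frame) < 0:
        frame = frame.copy()
        frame[:, 0] = -frame[:, 0]
    euler = Rotation.from_matrix(frame).as_euler("zyz", degrees=True)
    return {
        "saupe_elements": result.tensor.elements.tolist(),
        "da_hz": result.tensor.da,
        "rhombicity": result.tensor.rhombicity,
        "euler_zyz_deg": euler.tolist(),
        "q": result.q,
        "pearson_r": result.pearson_r,
        "n_fitted": len(result.residues_used),
        "residues_used": result.residues_used,
        "condition_number": result.condition_number,
        "warnings": result.warnings,
    }
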