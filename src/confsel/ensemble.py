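"""Conformer-ensemble generation, clustering, angle filtering and RDC scoring.

The sampler replaces a normal-mode trajectory generator with bounded Gaussian
pivot moves on the linker/terminal backbone dihedrals: both helices stay
internally rigid and a hard-sphere clash check rejects self-intersecting
conformers. Clustering is average-linkage agglomerative on pairwise backbone
RMSD with the cut level chosen by a penalty balancing cluster spread against
cluster count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from confsel.rdc import RDCSet, fit_tensor_svd
from confsel.structure import (
    Structure,
    fit_helix_axis,
    interhelical_angle,
    pairwise_rmsd_matrix,
    rotation_matrix,
)
from confsel.synthetic import PeptideSpec

__all__ = [
    "ConformerEnsemble",
    "sample_conformers",
    "cluster_ensemble",
    "filter_by_angle",
    "evaluate_ensemble_q",
    "combine_to_multimodel",
]

CLUSTER_ATOMS = ("N", "CA", "C")
_CLASH_RADII = {"H": 1.10, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
_CLASH_SCALE = 0.7


@dataclass
class ConformerEnsemble:
    """Single-model conformers plus per-conformer metadata.

    ``meta`` columns: conformer_id, theta_deg, cluster_id (nullable Int64),
    representative (bool), q_free (float, NaN until evaluated).
    """

    conformers: list[Structure]
    meta: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.conformers) != len(self.meta):
            raise ValueError("metadata rows must match conformer count")
        theta = self.meta["theta_deg"].to_numpy(float)
        if np.any((theta < 0) | (theta > 180)):
            raise ValueError("theta_deg outside [0, 180]")

    def __len__(self) -> int:
        return len(self.conformers)

    @classmethod
    def from_structures(
        cls,
        structures: list[Structure],
        spec: PeptideSpec,
        provenance: dict | None = None,
    ) -> "ConformerEnsemble":
        thetas = []
        for s in structures:
            h1 = fit_helix_axis(s, 1, spec.chain_id, *spec.helix1)
            h2 = fit_helix_axis(s, 1, spec.chain_id, *spec.helix2)
            thetas.append(interhelical_angle(h1, h2))
        meta = pd.DataFrame(
            {
                "conformer_id": np.arange(len(structures)),
                "theta_deg": thetas,
                "cluster_id": pd.array([pd.NA] * len(structures), dtype="Int64"),
                "representative": False,
                "q_free": np.nan,
            }
        )
        return cls(structures, meta, dict(provenance or {}, spec=spec))

    @property
    def spec(self) -> PeptideSpec:
        return self.provenance["spec"]

    def subset(self, indices: np.ndarray | list[int]) -> "ConformerEnsemble":
        indices = list(indices)
        return ConformerEnsemble(
            [self.conformers[i] for i in indices],
            self.meta.iloc[indices].reset_index(drop=True),
            dict(self.provenance),
        )

    def to_tsv(self, path) -> None:
        out = self.meta.copy()
        out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def _element(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch
    return "C"


class _PivotSampler:
    """Precomputed pivot-move machinery for one seed structure."""

    def __init__(self, seed: Structure, spec: PeptideSpec) -> None:
        if seed.n_models != 1:
            raise ValueError("seed structure must be single-model")
        self.seed = seed
        self.spec = spec
        model = seed.models[0]
        chain = spec.chain_id
        resnums = seed._resnum
        atnames = seed._atname
        chains = seed._chain
        helix_res = set(range(spec.helix1[0], spec.helix1[1] + 1)) | set(
            range(spec.helix2[0], spec.helix2[1] + 1)
        )
        perturbable = [
            r
            for r, rt in seed.residues(chain=chain, model=model)
            if r not in helix_res and rt != "PRO"
        ]
        self.moves: list[tuple[np.ndarray, int, int, str, str]] = []
        in_chain = chains == chain
        for r in perturbable:
            downstream = in_chain & (resnums > r)
            # phi: rotate about N->CA; carries C, O, CB of residue r
            if seed.has_atom(model, chain, r, "N") and seed.has_atom(model, chain, r, "CA"):
                mask = downstream | (in_chain & (resnums == r) & np.isin(atnames, ("C", "O", "CB")))
                self.moves.append((mask, model, r, "N", "CA"))
            # psi: rotate about CA->C; carries O of residue r
            if seed.has_atom(model, chain, r, "CA") and seed.has_atom(model, chain, r, "C"):
                mask = downstream | (in_chain & (resnums == r) & (atnames == "O"))
                self.moves.append((mask, model, r, "CA", "C"))
        if not self.moves:
            raise ValueError("no perturbable dihedrals outside the rigid helices")
        self._radii = np.array([_CLASH_RADII.get(_element(str(a)), 1.7) for a in atnames])
        sep = np.abs(resnums[:, None] - resnums[None, :])
        same_chain = chains[:, None] == chains[None, :]
        self._check_pairs = np.triu(sep >= 3, k=1) & same_chain
        self._cutoff = _CLASH_SCALE * (self._radii[:, None] + self._radii[None, :])
        self._atom_lookup = {(r, a): i for i, (r, a) in enumerate(zip(resnums, atnames)) if chains[i] == chain}

    def perturb(self, xyz: np.ndarray, angles: np.ndarray) -> np.ndarray:
        xyz = xyz.copy()
        chain = self.spec.chain_id
        for (mask, _model, r, a1, a2), angle in zip(self.moves, angles):
            i1 = self._atom_lookup[(r, a1)]
            i2 = self._atom_lookup[(r, a2)]
            axis = xyz[i2] - xyz[i1]
            R = rotation_matrix(axis, float(angle))
            pivot = xyz[i2]
            xyz[mask] = (xyz[mask] - pivot) @ R.T + pivot
        return xyz

    def has_clash(self, xyz: np.ndarray) -> bool:
        d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
        return bool(np.any(self._check_pairs & (d < self._cutoff)))


def sample_conformers(
    seed_structure: Structure,
    n: int,
    rng_seed: int,
    spec: PeptideSpec | None = None,
    amplitude_deg: float = 50.0,
    max_retries: int = 60,
) -> ConformerEnsemble:
    """Generate ``n`` clash-free conformers by Gaussian pivot moves.

    Helices stay rigid; linker and terminal backbone dihedrals are perturbed
    by N(0, amplitude) rotations. Deterministic for a given ``rng_seed``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    spec = spec or PeptideSpec()
    sampler = _PivotSampler(seed_structure, spec)
    rng = np.random.default_rng(rng_seed)
    base = seed_structure.xyz
    structures: list[Structure] = []
    attempts = 0
    failures = 0
    while len(structures) < n:
        attempts += 1
        if amplitude_deg == 0:
            xyz = base.copy()
        else:
            angles = rng.normal(0.0, amplitude_deg, size=len(sampler.moves))
            xyz = sampler.perturb(base, angles)
        if amplitude_deg > 0 and sampler.has_clash(xyz):
            failures += 1
            if attempts >= max(50, n) and failures / attempts > 0.9:
                raise RuntimeError(
                    f"clash-check rejection rate {failures/attempts:.0%} after {attempts} attempts; "
                    f"reduce amplitude_deg (currently {amplitude_deg})"
                )
            if failures > max_retries * n:
                raise RuntimeError("sampler exceeded retry budget")
            continue
        structures.append(seed_structure.with_coords(xyz))
    provenance = {
        "sampler": "gaussian-pivot",
        "n": n,
        "rng_seed": rng_seed,
        "amplitude_deg": amplitude_deg,
        "attempts": attempts,
        "rejected": failures,
    }
    return ConformerEnsemble.from_structures(structures, spec, provenance)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def _ensemble_coords(e: ConformerEnsemble, residue_range: tuple[int, int] | None) -> np.ndarray:
    spec = e.spec
    if residue_range is None:
        residue_range = (spec.start_residue + 1, spec.start_residue + len(spec.sequence) - 4)
    residues = range(residue_range[0], residue_range[1] + 1)
    coords = [
        c.coords(chain=spec.chain_id, residues=residues, atom_names=CLUSTER_ATOMS) for c in e.conformers
    ]
    return np.stack(coords)


def _penalty_cut(D: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Choose flat clusters from a linkage by the spread-vs-count penalty.

    At each agglomeration level the average spread (mean pairwise RMSD within
    clusters of >= 2 members) is normalized across levels to [1, M-1] and
    added to the number of clusters; the level minimizing the sum wins.
    """
    from scipy.cluster.hierarchy import fcluster

    M = len(D)
    members: dict[int, list[int]] = {i: [i] for i in range(M)}
    pair_sum: dict[int, float] = {i: 0.0 for i in range(M)}
    pair_cnt: dict[int, int] = {i: 0 for i in range(M)}
    av_spreads = np.full(M - 1, np.nan)
    for step in range(M - 1):
        a, b = int(Z[step, 0]), int(Z[step, 1])
        ma, mb = members.pop(a), members.pop(b)
        cross = float(D[np.ix_(ma, mb)].sum())
        new = M + step
        members[new] = ma + mb
        pair_sum[new] = pair_sum.pop(a) + pair_sum.pop(b) + cross
        pair_cnt[new] = pair_cnt.pop(a) + pair_cnt.pop(b) + len(ma) * len(mb)
        spreads = [pair_sum[k] / pair_cnt[k] for k in members if pair_cnt[k] > 0]
        if spreads:
            av_spreads[step] = float(np.mean(spreads))
    valid = np.isfinite(av_spreads)
    norm = np.full(M - 1, np.inf)
    if valid.any():
        lo, hi = av_spreads[valid].min(), av_spreads[valid].max()
        span = hi - lo if hi > lo else 1.0
        norm[valid] = (av_spreads[valid] - lo) / span * (M - 2) + 1.0
    n_clusters = M - 1 - np.arange(M - 1)  # clusters remaining after each step
    penalty = norm + n_clusters
    best_step = int(np.nanargmin(penalty))
    k = int(n_clusters[best_step])
    return fcluster(Z, t=k, criterion="maxclust")


def cluster_ensemble(
    e: ConformerEnsemble,
    residue_range: tuple[int, int] | None = None,
    fixed_k: int | None = None,
) -> ConformerEnsemble:
    """Average-linkage clustering on pairwise backbone RMSD.

    Returns a copy of the ensemble with ``cluster_id`` assigned and one
    representative (lowest mean RMSD to cluster mates) flagged per cluster.
    ``fixed_k`` overrides the automatic penalty-based cut level.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    if len(e) < 2:
        raise ValueError("clustering requires >= 2 conformers")
    coords = _ensemble_coords(e, residue_range)
    D = pairwise_rmsd_matrix(coords)
    Z = linkage(squareform(D, checks=False), method="average")
    if fixed_k is not None:
        labels = fcluster(Z, t=fixed_k, criterion="maxclust")
    else:
        labels = _penalty_cut(D, Z)
    meta = e.meta.copy()
    meta["cluster_id"] = pd.array(labels, dtype="Int64")
    meta["representative"] = False
    for cid in np.unique(labels):
        idx = np.flatnonzero(labels == cid)
        if len(idx) == 1:
            rep = idx[0]
        else:
            sub = D[np.ix_(idx, idx)]
            rep = idx[int(np.argmin(sub.mean(axis=1)))]
        meta.loc[rep, "representative"] = True
    prov = dict(e.provenance, n_clusters=int(len(np.unique(labels))))
    return ConformerEnsemble(list(e.conformers), meta, prov)


def representatives(e: ConformerEnsemble) -> ConformerEnsemble:
    """Subset containing only the cluster representatives."""
    idx = np.flatnonzero(e.meta["representative"].to_numpy(bool))
    return e.subset(idx)


# ---------------------------------------------------------------------------
# Filtering and RDC evaluation
# ---------------------------------------------------------------------------


def filter_by_angle(e: ConformerEnsemble, theta_ref: float, half_window: float) -> ConformerEnsemble:
    """Keep conformers whose interhelical angle deviates from ``theta_ref`` by
    more than ``half_window`` degrees.

    Tie rule: the exclusion band is the open interval
    (theta_ref - half_window, theta_ref + half_window), so conformers sitting
    exactly on a nonzero boundary are retained; with ``half_window == 0`` only
    exact matches of ``theta_ref`` are excluded.
    """
    theta = e.meta["theta_deg"].to_numpy(float)
    dev = np.abs(theta - theta_ref)
    keep = np.flatnonzero((dev > half_window) | ((dev == half_window) & (half_window > 0)))
    out = e.subset(keep)
    out.provenance = dict(e.provenance, angle_filter={"theta_ref": theta_ref, "half_window": half_window})
    return out


def evaluate_ensemble_q(
    e: ConformerEnsemble,
    free_rdcs: RDCSet,
    fit_residues: list[int] | None = None,
) -> ConformerEnsemble:
    """Fit an alignment tensor to ``free_rdcs`` for every conformer and record
    the per-conformer Q factor; the metadata is returned sorted as-is with
    ``q_free`` filled in."""
    spec = e.spec
    qs = []
    for s in e.conformers:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_tensor_svd(s, s.models[0], free_rdcs, residues_used=fit_residues, chain=spec.chain_id)
        qs.append(fit.q)
    out = ConformerEnsemble(list(e.conformers), e.meta.copy(), dict(e.provenance))
    out.meta["q_free"] = qs
    return out


def q_report(e: ConformerEnsemble) -> pd.DataFrame:
    """Metadata sorted by ascending q_free (best-fitting conformers first)."""
    if e.meta["q_free"].isna().all():
        raise ValueError("run evaluate_ensemble_q first")
    return e.meta.sort_values("q_free").reset_index(drop=True)


def combine_to_multimodel(e: ConformerEnsemble) -> Structure:
    """Merge single-model conformers into one multi-model Structure."""
    from confsel.structure import AtomRecord

    records: list[AtomRecord] = []
    for m, s in enumerate(e.conformers, start=1):
        for rec in s.atom_records():
            records.append(AtomRecord(m, rec.chain_id, rec.residue_number, rec.residue_name, rec.atom_name, rec.position))
    return Structure(records, metadata="ensemble")
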